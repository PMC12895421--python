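"""System-specific assembly and evaluation of the long-range expansion.

Given the two monomers' point groups and charges, this module builds the
complete list of symmetry-allowed interaction terms up to chosen
inverse-power orders and evaluates the model energy

    E(R, Omega_A, Omega_B) = E_asym
        + sum_{t,u}  Q_t^A Q_u^B T_{t,u}                      (electrostatic)
        - 1/2 sum    alpha^A_{t;t'} Q^B_u Q^B_{u'} T_{t,u} T_{t',u'}   (+ A<->B)
        - sum        D_{t,u;t',u'} T_{t,u} T_{t',u'}          (dispersion)

where every label runs only over the symmetry-adapted combinations that
survive for each molecule.  An order-n term scales as R^-n with
n = l_t + l_u + 1 for electrostatics and the sum of the two T-tensor
orders for the second-order energies.  Coefficients live in a
:class:`CoefficientSet`; the asymptotic energy of the separated monomers
is one of them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

from .symmetry import (
    MoleculeSpec,
    SystemSpec,
    SymmetryBasis,
    allowed_multipoles,
    polarizability_pattern,
)
from .tensor_core import MAX_RANK, DimerGeometry, TTensorEvaluator, labels_for_rank

__all__ = [
    "Term",
    "CoefficientSet",
    "Expansion",
    "assemble_terms",
    "evaluate_energy",
    "render_term_table",
    "spherical_coefficient_count",
    "cartesian_coefficient_count",
]

INTERACTIONS = ("electrostatic", "induction_A", "induction_B", "dispersion")


def spherical_coefficient_count(order: int) -> int:
    """Electrostatic coefficients through ``order`` in the spherical form.

    Both molecules, no symmetry: 2 * sum_{l=0}^{order-1} (2l+1) = 2 order^2.
    """
    if order < 1:
        raise ValueError("order must be >= 1")
    return 2 * order * order


def cartesian_coefficient_count(order: int) -> int:
    """Electrostatic coefficients through ``order`` in the Cartesian form.

    Each rank-p Cartesian tensor carries 3^p components:
    2 * sum_{p=0}^{order-1} 3^p = 3^order - 1.
    """
    if order < 1:
        raise ValueError("order must be >= 1")
    return 3**order - 1


@dataclass(frozen=True)
class Term:
    """One addend of the expansion.

    ``labels`` are the human-readable symmetry-adapted component labels
    ((t, u) for electrostatics, (t, u, t', u') otherwise);
    ``coefficient_role`` names the CoefficientSet entries multiplying the
    geometric factor; ``key`` is the machine-level identity used by the
    evaluator.
    """

    interaction: str
    order: int
    labels: tuple[str, ...]
    coefficient_role: tuple[str, ...]
    key: tuple

    def __str__(self) -> str:
        return f"{self.interaction} n={self.order} [{' , '.join(self.labels)}]"


@dataclass
class CoefficientSet:
    """All model coefficients for one system.

    ``Q[(mol, l)]`` holds the coordinates of the rank-l multipole in the
    molecule's symmetry-adapted basis (rank 0 is pinned to the declared
    charge); ``alpha[(mol, (l1, l2))]`` the polarizability invariants of
    one block; ``D[(Lblk, Kblk, pairing)]`` a (nA, nB) matrix of
    dispersion coefficients for one pattern-block pair.  ``easym`` is the
    fitted asymptotic energy.  Internal units: hartree / bohr / e.
    """

    easym: float = 0.0
    Q: dict = field(default_factory=dict)
    alpha: dict = field(default_factory=dict)
    D: dict = field(default_factory=dict)
    meta: dict = field(default_factory=dict)

    def copy(self) -> "CoefficientSet":
        return CoefficientSet(
            self.easym,
            {k: np.array(v, dtype=float) for k, v in self.Q.items()},
            {k: np.array(v, dtype=float) for k, v in self.alpha.items()},
            {k: np.array(v, dtype=float) for k, v in self.D.items()},
            dict(self.meta),
        )


class Expansion:
    """The symmetry-adapted term list of one system at given caps.

    ``caps`` maps 'electrostatic' / 'induction' / 'dispersion' to the
    maximum inverse-power order of that interaction (absent = excluded).
    """

    def __init__(self, sys: SystemSpec, caps: dict[str, int]):
        for k, v in caps.items():
            if k not in ("electrostatic", "induction", "dispersion"):
                raise ValueError(f"unknown interaction cap {k!r}")
            if v > MAX_RANK:
                raise ValueError(f"cap {v} for {k} exceeds {MAX_RANK}")
        self.sys = sys
        self.caps = {k: int(v) for k, v in caps.items() if v and v > 0}
        self._build()

    # -- construction -----------------------------------------------------

    def _mol(self, mol: str) -> MoleculeSpec:
        return self.sys.molA if mol == "A" else self.sys.molB

    def _build(self):
        cap_el = self.caps.get("electrostatic", 0)
        cap_in = self.caps.get("induction", 0)
        cap_di = self.caps.get("dispersion", 0)
        lmax_mult = max(cap_el - 1, cap_in - 4, 0)
        lmax_pol = max(cap_in - 4, cap_di - 4, 0)

        self.mult = {
            "A": allowed_multipoles(self.sys.molA, min(lmax_mult, MAX_RANK)),
            "B": allowed_multipoles(self.sys.molB, min(lmax_mult, MAX_RANK)),
        }
        self.pol = {
            "A": polarizability_pattern(self.sys.molA, min(lmax_pol, MAX_RANK - 1)) if lmax_pol >= 1 else {},
            "B": polarizability_pattern(self.sys.molB, min(lmax_pol, MAX_RANK - 1)) if lmax_pol >= 1 else {},
        }

        terms: list[Term] = []
        terms += self._elec_terms(cap_el)
        terms += self._ind_terms("A", cap_in)
        terms += self._ind_terms("B", cap_in)
        terms += self._disp_terms(cap_di)
        rank = {name: i for i, name in enumerate(INTERACTIONS)}
        terms.sort(key=lambda t: (rank[t.interaction], t.order, t.key))
        self.terms: tuple[Term, ...] = tuple(terms)
        self._derive_parameters()

    def _active_ranks(self, mol: str) -> list[int]:
        out = []
        for l, b in self.mult[mol].items():
            if l == 0:
                if self._mol(mol).charge != 0.0:
                    out.append(0)
            elif b.dim > 0:
                out.append(l)
        return out

    def _basis_label(self, mol: str, l: int, i: int) -> str:
        return self.mult[mol][l].component_labels()[i]

    def _pattern_label(self, mol: str, block: tuple[int, int], p: int) -> str:
        P = self.pol[mol][block][p]
        t, u = np.unravel_index(int(np.argmax(np.abs(P))), P.shape)
        la1 = str(labels_for_rank(block[0])[t])
        la2 = str(labels_for_rank(block[1])[u])
        return f"{la1};{la2}" + (f"#{p}" if len(self.pol[mol][block]) > 2 * block[0] + 1 else "")

    def _elec_terms(self, cap: int) -> list[Term]:
        out = []
        for la in self._active_ranks("A"):
            for lb in self._active_ranks("B"):
                n = la + lb + 1
                if n > cap:
                    continue
                for ia in range(self.mult["A"][la].dim):
                    for ib in range(self.mult["B"][lb].dim):
                        out.append(Term(
                            "electrostatic", n,
                            (self._basis_label("A", la, ia), self._basis_label("B", lb, ib)),
                            (self.qname("A", la, ia), self.qname("B", lb, ib)),
                            ("elec", la, ia, lb, ib),
                        ))
        return out

    def _ind_quads(self, pol_mol: str, cap: int):
        """(block, k1, k2) with l1+l2+k1+k2+2 <= cap; k ordered pairs."""
        src = "B" if pol_mol == "A" else "A"
        quads = []
        for (l1, l2) in self.pol[pol_mol]:
            for k1 in self._active_ranks(src):
                for k2 in self._active_ranks(src):
                    if l1 + l2 + k1 + k2 + 2 <= cap:
                        quads.append(((l1, l2), k1, k2))
        return quads

    def _ind_terms(self, pol_mol: str, cap: int) -> list[Term]:
        src = "B" if pol_mol == "A" else "A"
        name = f"induction_{pol_mol}"
        seen = {}
        for (blk, k1, k2) in self._ind_quads(pol_mol, cap):
            for p in range(len(self.pol[pol_mol][blk])):
                for i1 in range(self.mult[src][k1].dim):
                    for i2 in range(self.mult[src][k2].dim):
                        a, b = sorted([(k1, i1), (k2, i2)])
                        key = ("ind", pol_mol, blk, p, a, b)
                        if key in seen:
                            continue
                        seen[key] = Term(
                            name, blk[0] + blk[1] + k1 + k2 + 2,
                            (self._pattern_label(pol_mol, blk, p),
                             self._basis_label(src, a[0], a[1]),
                             self._basis_label(src, b[0], b[1])),
                            (self.aname(pol_mol, blk, p),
                             self.qname(src, a[0], a[1]),
                             self.qname(src, b[0], b[1])),
                            key,
                        )
        return list(seen.values())

    def _disp_blocks(self, cap: int):
        """(Ablock, Bblock, pairing) with total order <= cap."""
        out = []
        for (l1, l2) in self.pol["A"]:
            for (k1, k2) in self.pol["B"]:
                if l1 + l2 + k1 + k2 + 2 > cap:
                    continue
                pairings = ["s"]
                if l1 < l2 and k1 < k2:
                    pairings.append("x")
                for pr in pairings:
                    out.append(((l1, l2), (k1, k2), pr))
        return out

    def _disp_terms(self, cap: int) -> list[Term]:
        out = []
        for (Lb, Kb, pr) in self._disp_blocks(cap):
            for p in range(len(self.pol["A"][Lb])):
                for q in range(len(self.pol["B"][Kb])):
                    out.append(Term(
                        "dispersion", Lb[0] + Lb[1] + Kb[0] + Kb[1] + 2,
                        (self._pattern_label("A", Lb, p),
                         self._pattern_label("B", Kb, q) + ("(x)" if pr == "x" else "")),
                        (self.dname(Lb, p, Kb, q, pr),),
                        ("disp", Lb, p, Kb, q, pr),
                    ))
        return out

    # -- parameter bookkeeping -------------------------------------------

    def qname(self, mol: str, l: int, i: int) -> str:
        if l == 0:
            return f"Q_{mol}[00]"
        return f"Q_{mol}[{self._basis_label(mol, l, i)}]"

    def aname(self, mol: str, blk: tuple[int, int], p: int) -> str:
        return f"alpha_{mol}[{self._pattern_label(mol, blk, p)}]"

    def dname(self, Lb, p, Kb, q, pr) -> str:
        tag = "x" if pr == "x" else "s"
        return f"D[{self._pattern_label('A', Lb, p)}|{self._pattern_label('B', Kb, q)}|{tag}]"

    def _derive_parameters(self):
        """Entry keys actually used by at least one term."""
        qkeys, akeys, dkeys = [], [], []
        seen = set()

        def add(lst, key):
            if key not in seen:
                seen.add(key)
                lst.append(key)

        for t in self.terms:
            k = t.key
            if k[0] == "elec":
                _, la, ia, lb, ib = k
                if la > 0:
                    add(qkeys, ("Q", "A", la, ia))
                if lb > 0:
                    add(qkeys, ("Q", "B", lb, ib))
            elif k[0] == "ind":
                _, mol, blk, p, (k1, i1), (k2, i2) = k
                add(akeys, ("alpha", mol, blk, p))
                src = "B" if mol == "A" else "A"
                if k1 > 0:
                    add(qkeys, ("Q", src, k1, i1))
                if k2 > 0:
                    add(qkeys, ("Q", src, k2, i2))
            else:
                _, Lb, p, Kb, q, pr = k
                add(dkeys, ("D", Lb, p, Kb, q, pr))
        self.q_param_keys = tuple(qkeys)
        self.alpha_param_keys = tuple(akeys)
        self.d_param_keys = tuple(dkeys)

    @property
    def parameter_keys(self) -> tuple:
        """All scalar coefficient entries incl. the asymptote, in order."""
        return (("easym",),) + self.q_param_keys + self.alpha_param_keys + self.d_param_keys

    def parameter_name(self, key) -> str:
        if key == ("easym",):
            return "E_asym"
        if key[0] == "Q":
            return self.qname(key[1], key[2], key[3])
        if key[0] == "alpha":
            return self.aname(key[1], key[2], key[3])
        return self.dname(key[1], key[2], key[3], key[4], key[5])

    def zero_coefficients(self) -> CoefficientSet:
        """A complete CoefficientSet with charges pinned and all else 0."""
        cs = CoefficientSet(meta={"units": "atomic"})
        for mol in ("A", "B"):
            for l, b in self.mult[mol].items():
                cs.Q[(mol, l)] = np.zeros(b.dim)
            if 0 in self.mult[mol]:
                cs.Q[(mol, 0)] = np.array([self._mol(mol).charge])
            for blk, pats in self.pol[mol].items():
                cs.alpha[(mol, blk)] = np.zeros(len(pats))
        for (Lb, Kb, pr) in self._disp_blocks(self.caps.get("dispersion", 0)):
            cs.D[(Lb, Kb, pr)] = np.zeros((len(self.pol["A"][Lb]), len(self.pol["B"][Kb])))
        return cs

    def get_entry(self, cs: CoefficientSet, key) -> float:
        if key == ("easym",):
            return cs.easym
        try:
            if key[0] == "Q":
                return float(cs.Q[(key[1], key[2])][key[3]])
            if key[0] == "alpha":
                return float(cs.alpha[(key[1], key[2])][key[3]])
            return float(cs.D[(key[1], key[3], key[5])][key[2], key[4]])
        except (KeyError, IndexError):
            raise KeyError(
                f"coefficient {self.parameter_name(key)} missing from CoefficientSet"
            ) from None

    def set_entry(self, cs: CoefficientSet, key, value: float):
        if key == ("easym",):
            cs.easym = float(value)
        elif key[0] == "Q":
            cs.Q[(key[1], key[2])][key[3]] = value
        elif key[0] == "alpha":
            cs.alpha[(key[1], key[2])][key[3]] = value
        else:
            cs.D[(key[1], key[3], key[5])][key[2], key[4]] = value

    # -- evaluation -------------------------------------------------------

    @property
    def lmax(self) -> int:
        ls = [0]
        ls += [l for m in ("A", "B") for l in self.mult[m]]
        ls += [l for m in ("A", "B") for blk in self.pol[m] for l in blk]
        return max(ls)

    def evaluator(self, geoms: Sequence[DimerGeometry]) -> TTensorEvaluator:
        R = np.array([g.R for g in geoms])
        eA = np.array([g.omega_A.as_tuple() for g in geoms])
        eB = np.array([g.omega_B.as_tuple() for g in geoms])
        return TTensorEvaluator(R, self.lmax, euler_A=eA, euler_B=eB)

    def _qvec(self, cs: CoefficientSet, mol: str, l: int) -> np.ndarray:
        """Full (2l+1) component vector from basis coordinates."""
        key = (mol, l)
        if key not in cs.Q:
            raise KeyError(f"multipole Q_{mol} rank {l} missing from CoefficientSet")
        return self.mult[mol][l].vectors @ cs.Q[key]

    def _alpha_mat(self, cs: CoefficientSet, mol: str, blk) -> np.ndarray:
        key = (mol, blk)
        if key not in cs.alpha:
            raise KeyError(f"alpha_{mol} block {blk} missing from CoefficientSet")
        pats = self.pol[mol][blk]
        return np.tensordot(cs.alpha[key], np.stack(pats), axes=(0, 0))

    def energy(self, cs: CoefficientSet, ev: TTensorEvaluator) -> np.ndarray:
        """Model energy at every geometry of the evaluator batch."""
        E = np.full(ev.n, cs.easym, dtype=float)
        cap_el = self.caps.get("electrostatic", 0)
        for la in self._active_ranks("A"):
            qa = self._qvec(cs, "A", la)
            for lb in self._active_ranks("B"):
                if la + lb + 1 > cap_el:
                    continue
                qb = self._qvec(cs, "B", lb)
                E += np.einsum("a,nab,b->n", qa, ev.block(la, lb), qb)
        for mol in ("A", "B"):
            E += self._induction_energy(cs, ev, mol)
        E += self._dispersion_energy(cs, ev)
        return E

    def _induction_energy(self, cs, ev, pol_mol: str) -> np.ndarray:
        cap = self.caps.get("induction", 0)
        src = "B" if pol_mol == "A" else "A"
        out = np.zeros(ev.n)
        for (blk, k1, k2) in self._ind_quads(pol_mol, cap):
            l1, l2 = blk
            A = self._alpha_mat(cs, pol_mol, blk)
            q1 = self._qvec(cs, src, k1)
            q2 = self._qvec(cs, src, k2)
            m12 = 2.0 if l1 < l2 else 1.0
            if pol_mol == "A":
                T1 = ev.block(l1, k1)
                T2 = ev.block(l2, k2)
                val = np.einsum("ts,ntu,u,nsv,v->n", A, T1, q1, T2, q2)
            else:
                # polarized molecule carries the B index of the T tensors
                T1 = ev.block(k1, l1)
                T2 = ev.block(k2, l2)
                val = np.einsum("ts,nut,u,nvs,v->n", A, T1, q1, T2, q2)
            out -= 0.5 * m12 * val
        return out

    def _disp_geom(self, ev, Lb, Kb, pr, PA, PB) -> np.ndarray:
        l1, l2 = Lb
        k1, k2 = Kb
        if pr == "s":
            return np.einsum("ts,uv,ntu,nsv->n", PA, PB, ev.block(l1, k1), ev.block(l2, k2))
        return np.einsum("ts,uv,ntv,nsu->n", PA, PB, ev.block(l1, k2), ev.block(l2, k1))

    def _dispersion_energy(self, cs, ev) -> np.ndarray:
        cap = self.caps.get("dispersion", 0)
        out = np.zeros(ev.n)
        for (Lb, Kb, pr) in self._disp_blocks(cap):
            key = (Lb, Kb, pr)
            if key not in cs.D:
                raise KeyError(f"dispersion block {key} missing from CoefficientSet")
            d = cs.D[key]
            for p in range(d.shape[0]):
                for q in range(d.shape[1]):
                    if d[p, q] == 0.0:
                        continue
                    out -= d[p, q] * self._disp_geom(
                        ev, Lb, Kb, pr, self.pol["A"][Lb][p], self.pol["B"][Kb][q]
                    )
        return out

    # -- analytic derivatives --------------------------------------------

    def gradients(self, cs: CoefficientSet, ev: TTensorEvaluator) -> dict:
        """dE/d(entry) per parameter key, each an (n,) array.

        The energy is linear in E_asym, alpha and D entries, bilinear in
        the two molecules' multipole coordinates; all derivatives are
        exact contractions of the cached T blocks.
        """
        n = ev.n
        g: dict = {("easym",): np.ones(n)}
        for key in self.q_param_keys:
            g[key] = np.zeros(n)
        cap_el = self.caps.get("electrostatic", 0)
        VA = {l: self.mult["A"][l].vectors for l in self.mult["A"]}
        VB = {l: self.mult["B"][l].vectors for l in self.mult["B"]}

        # electrostatics
        for la in self._active_ranks("A"):
            qa = self._qvec(cs, "A", la)
            for lb in self._active_ranks("B"):
                if la + lb + 1 > cap_el:
                    continue
                qb = self._qvec(cs, "B", lb)
                T = ev.block(la, lb)
                if la > 0:
                    dA = np.einsum("ai,nab,b->ni", VA[la], T, qb)
                    for i in range(VA[la].shape[1]):
                        g[("Q", "A", la, i)] += dA[:, i]
                if lb > 0:
                    dB = np.einsum("a,nab,bi->ni", qa, T, VB[lb])
                    for i in range(VB[lb].shape[1]):
                        g[("Q", "B", lb, i)] += dB[:, i]

        # induction
        cap_in = self.caps.get("induction", 0)
        for pol_mol in ("A", "B"):
            src = "B" if pol_mol == "A" else "A"
            Vsrc = VA if src == "A" else VB
            for (blk, k1, k2) in self._ind_quads(pol_mol, cap_in):
                l1, l2 = blk
                m12 = 2.0 if l1 < l2 else 1.0
                q1 = self._qvec(cs, src, k1)
                q2 = self._qvec(cs, src, k2)
                if pol_mol == "A":
                    F1 = np.einsum("ntu,u->nt", ev.block(l1, k1), q1)
                    F2 = np.einsum("nsv,v->ns", ev.block(l2, k2), q2)
                    G1 = np.einsum("ntu,ui->nti", ev.block(l1, k1), Vsrc[k1])
                    G2 = np.einsum("nsv,vi->nsi", ev.block(l2, k2), Vsrc[k2])
                else:
                    F1 = np.einsum("nut,u->nt", ev.block(k1, l1), q1)
                    F2 = np.einsum("nvs,v->ns", ev.block(k2, l2), q2)
                    G1 = np.einsum("nut,ui->nti", ev.block(k1, l1), Vsrc[k1])
                    G2 = np.einsum("nvs,vi->nsi", ev.block(k2, l2), Vsrc[k2])
                pats = self.pol[pol_mol][blk]
                avec = cs.alpha[(pol_mol, blk)]
                for p, P in enumerate(pats):
                    val = np.einsum("ts,nt,ns->n", P, F1, F2)
                    key = ("alpha", pol_mol, blk, p)
                    g[key] = g.get(key, np.zeros(n)) - 0.5 * m12 * val
                A = self._alpha_mat(cs, pol_mol, blk)
                if k1 > 0:
                    dq = np.einsum("ts,nti,ns->ni", A, G1, F2)
                    for i in range(Vsrc[k1].shape[1]):
                        g[("Q", src, k1, i)] -= 0.5 * m12 * dq[:, i]
                if k2 > 0:
                    dq = np.einsum("ts,nt,nsi->ni", A, F1, G2)
                    for i in range(Vsrc[k2].shape[1]):
                        g[("Q", src, k2, i)] -= 0.5 * m12 * dq[:, i]

        # dispersion (linear)
        for key in self.d_param_keys:
            _, Lb, p, Kb, q, pr = key
            g[key] = -self._disp_geom(ev, Lb, Kb, pr, self.pol["A"][Lb][p], self.pol["B"][Kb][q])
        return g


# ---------------------------------------------------------------------------
# spec-level convenience functions
# ---------------------------------------------------------------------------

def assemble_terms(sys: SystemSpec, caps: dict[str, int]) -> list[Term]:
    """Every symmetry-allowed term with order <= its interaction cap,
    deterministically ordered (interaction, order, labels)."""
    return list(Expansion(sys, caps).terms)


def evaluate_energy(sys: SystemSpec, coeffs: CoefficientSet, terms: Iterable[Term],
                    geom: DimerGeometry, caps: Optional[dict] = None) -> float:
    """Term-list energy at a single geometry.

    Sums E_asym plus each term's coefficient product times its geometric
    factor; raises KeyError naming the term whose coefficient is absent.
    Used as the reference path; batch work goes through
    :meth:`Expansion.energy` (the two are tested to agree).
    """
    terms = list(terms)
    if caps is None:
        caps = {}
        for t in terms:
            k = {"electrostatic": "electrostatic", "induction_A": "induction",
                 "induction_B": "induction", "dispersion": "dispersion"}[t.interaction]
            caps[k] = max(caps.get(k, 0), t.order)
    exp = Expansion(sys, caps)
    ev = exp.evaluator([geom])
    E = coeffs.easym
    for t in terms:
        E += float(_term_value(exp, coeffs, t, ev)[0])
    return float(E)


def _term_value(exp: Expansion, cs: CoefficientSet, t: Term, ev: TTensorEvaluator) -> np.ndarray:
    """Contribution of one term at every geometry of the batch, shape (n,)."""
    try:
        k = t.key
        if k[0] == "elec":
            _, la, ia, lb, ib = k
            va = exp.mult["A"][la].vectors[:, ia]
            vb = exp.mult["B"][lb].vectors[:, ib]
            ca = exp.get_entry(cs, ("Q", "A", la, ia)) if la > 0 else cs.Q[("A", 0)][0]
            cb = exp.get_entry(cs, ("Q", "B", lb, ib)) if lb > 0 else cs.Q[("B", 0)][0]
            return ca * cb * np.einsum("a,nab,b->n", va, ev.block(la, lb), vb)
        if k[0] == "ind":
            _, mol, blk, p, (k1, i1), (k2, i2) = k
            src = "B" if mol == "A" else "A"
            l1, l2 = blk
            m12 = 2.0 if l1 < l2 else 1.0
            P = exp.pol[mol][blk][p]
            a = exp.get_entry(cs, ("alpha", mol, blk, p))
            v1 = exp.mult[src][k1].vectors[:, i1]
            v2 = exp.mult[src][k2].vectors[:, i2]
            q1 = exp.get_entry(cs, ("Q", src, k1, i1)) if k1 > 0 else cs.Q[(src, 0)][0]
            q2 = exp.get_entry(cs, ("Q", src, k2, i2)) if k2 > 0 else cs.Q[(src, 0)][0]

            def G(u1, w1, u2, w2):
                if mol == "A":
                    F1 = np.einsum("ntu,u->nt", ev.block(l1, u1), w1)
                    F2 = np.einsum("nsv,v->ns", ev.block(l2, u2), w2)
                else:
                    F1 = np.einsum("nut,u->nt", ev.block(u1, l1), w1)
                    F2 = np.einsum("nvs,v->ns", ev.block(u2, l2), w2)
                return np.einsum("nt,ts,ns->n", F1, P, F2)

            tot = G(k1, v1, k2, v2)
            if (k1, i1) != (k2, i2):
                tot = tot + G(k2, v2, k1, v1)
            return -0.5 * m12 * a * q1 * q2 * tot
        # dispersion
        _, Lb, p, Kb, q, pr = k
        d = exp.get_entry(cs, ("D", Lb, p, Kb, q, pr))
        geomfac = exp._disp_geom(ev, Lb, Kb, pr, exp.pol["A"][Lb][p], exp.pol["B"][Kb][q])
        return -d * geomfac
    except KeyError as e:
        raise KeyError(f"missing coefficient for term {t}: {e}") from None


def render_term_table(sys: SystemSpec, interaction: str, max_order: int = MAX_RANK,
                      caps: Optional[dict] = None):
    """Fig-5 style table of the relevant terms of one interaction, by order.

    Returns a pandas DataFrame with one row per order 1..max_order listing
    the active symmetry-allowed terms (empty string where none survive).
    """
    import pandas as pd

    if interaction not in ("electrostatic", "induction", "dispersion"):
        raise ValueError(f"unknown interaction {interaction!r}")
    if caps is None:
        caps = {interaction: max_order}
    exp = Expansion(sys, caps)
    names = {
        "electrostatic": ("electrostatic",),
        "induction": ("induction_A", "induction_B"),
        "dispersion": ("dispersion",),
    }[interaction]
    rows = []
    for n in range(1, max_order + 1):
        terms = [t for t in exp.terms if t.interaction in names and t.order == n]
        rows.append({
            "order": n,
            "n_terms": len(terms),
            "active": bool(terms),
            "terms": "; ".join(",".join(t.labels) for t in terms),
        })
    return pd.DataFrame(rows)
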