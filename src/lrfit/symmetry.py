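"""Point-group symmetry adaptation of the multipole expansion.

A molecule's point group decides which real multipole components,
polarizability invariants and dispersion-coefficient patterns can be
nonzero.  Everything here is computed numerically by group-averaged
projection: for rank l the projector

    P_l = (1/|G|) sum_g  M_l(g)

(with M_l the parity-aware real representation from
:func:`lrfit.tensor_core.rep_matrix_real`, so improper operations carry
their (-1)^l factor automatically) is averaged over the closure of the
generators of the molecule's oriented point group; its column space is the
surviving subspace.  For cubic and icosahedral groups the survivors are
combinations (e.g. the rank-4 mix of 40 and 44c for O_h), so the public
object is a :class:`SymmetryBasis` of orthonormal combination vectors.

Orientation conventions follow the generator table used by the expansion
(C_n about z, C_2 about x, mirrors xy/xz, S_n about z, the cubic C_3 about
x+y+z and the icosahedral C_5 about an icosahedron vertex in the xy
plane).  The continuous axial groups are realized exactly for l <= 15 by a
finite surrogate rotation C_N^z with N = 37 > 2*15 (m = N k then forces
m = 0); atoms are handled analytically.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Optional, Sequence

import numpy as np

from .tensor_core import (
    MAX_RANK,
    AtomSite,
    ComponentLabel,
    labels_for_rank,
    rep_matrix_real,
)

__all__ = [
    "MoleculeSpec",
    "SystemSpec",
    "SymmetryBasis",
    "group_elements",
    "invariant_basis",
    "allowed_multipoles",
    "polarizability_pattern",
    "leading_order",
    "exchange_constraints",
    "ExchangeConstraints",
    "group_closure",
]

#: point-group families handled (axis order n where applicable)
FAMILIES = (
    "C1", "Cs", "Ci", "Cn", "Cnh", "Cnv", "Dn", "Dnh", "Dnd", "S2n",
    "Cinfv", "Dinfh", "T", "Th", "Td", "O", "Oh", "I", "Ih", "atom",
)

#: surrogate axis order standing in for the continuous rotation; exact for l <= 15
_SURROGATE_N = 37

_GOLDEN = (1.0 + math.sqrt(5.0)) / 2.0


def _rot_axis(axis, angle) -> np.ndarray:
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    from scipy.spatial.transform import Rotation

    return Rotation.from_rotvec(angle * axis).as_matrix()


def _cz(n: int) -> np.ndarray:
    return _rot_axis([0, 0, 1], 2 * math.pi / n)


_C2X = np.diag([1.0, -1.0, -1.0])
_SIG_XY = np.diag([1.0, 1.0, -1.0])
_SIG_XZ = np.diag([1.0, -1.0, 1.0])
_INV = -np.eye(3)


def _sz(n: int) -> np.ndarray:
    """Roto-reflection S_n about z."""
    return _SIG_XY @ _cz(n)


_C3_DIAG = _rot_axis([1.0, 1.0, 1.0], 2 * math.pi / 3)
#: C_5 about an icosahedron vertex direction lying in the xy plane
_C5_ICO = _rot_axis([1.0, -_GOLDEN, 0.0], 2 * math.pi / 5)


def _parse_group(label: str, n: Optional[int]) -> tuple[str, Optional[int]]:
    """Normalize a point-group label to (family, axis order)."""
    s = label.strip()
    low = s.lower().replace("∞", "inf")
    if low in ("atom", "sphere", "spherical"):
        return "atom", None
    if low in ("cinfv", "c_infv", "coov"):
        return "Cinfv", None
    if low in ("dinfh", "d_infh", "dooh"):
        return "Dinfh", None
    for fam in ("C1", "Cs", "Ci", "T", "Th", "Td", "O", "Oh", "I", "Ih"):
        if s == fam:
            return fam, None
    if s in ("Cn", "Cnh", "Cnv", "Dn", "Dnh", "Dnd", "S2n"):
        if n is None:
            raise ValueError(f"family {s} requires an axis order n")
        return s, int(n)
    m = re.fullmatch(r"([CDS])(\d+)([hvd]?)", s)
    if m:
        kind, order, tail = m.group(1), int(m.group(2)), m.group(3)
        if kind == "C":
            fam = {"": "Cn", "h": "Cnh", "v": "Cnv"}.get(tail)
            if fam and order >= 2:
                return fam, order
            if fam == "Cn" and order == 1:
                return "C1", None
        elif kind == "D":
            fam = {"": "Dn", "h": "Dnh", "d": "Dnd"}.get(tail)
            if fam and order >= 2:
                return fam, order
        elif kind == "S" and tail == "":
            if order % 2 or order < 4:
                raise ValueError(f"S_n groups require even n >= 4, got {s}")
            return "S2n", order // 2
    raise ValueError(f"unknown point group {label!r}")


@dataclass(frozen=True)
class MoleculeSpec:
    """Identity, point group, orientation class and charge of one monomer.

    ``point_group`` accepts concrete Schoenflies labels ("C3v", "D6h",
    "S4", "Td", "Cinfv", "atom") or a family name ("Cnv") with explicit
    ``n``.  ``charge`` (in e) pins the rank-0 multipole.  ``sites`` are
    optional molecule-fixed point charges/atoms used by the distance
    filter and the Coulomb oracles.
    """

    name: str
    point_group: str
    n: Optional[int] = None
    charge: float = 0.0
    sites: Optional[tuple[AtomSite, ...]] = None

    def __post_init__(self):
        fam, order = _parse_group(self.point_group, self.n)
        object.__setattr__(self, "_family", fam)
        object.__setattr__(self, "_order", order)
        if self.sites is not None:
            object.__setattr__(self, "sites", tuple(self.sites))

    @property
    def family(self) -> str:
        return self._family

    @property
    def axis_order(self) -> Optional[int]:
        return self._order

    @property
    def shape(self) -> str:
        if self._family == "atom":
            return "atom"
        if self._family in ("Cinfv", "Dinfh"):
            return "linear"
        return "nonlinear"

    @property
    def key(self) -> tuple:
        return (self._family, self._order)


@dataclass(frozen=True)
class SystemSpec:
    """The dimer: two monomers and their mutual relation."""

    molA: MoleculeSpec
    molB: MoleculeSpec
    relation: str = "distinct"

    def __post_init__(self):
        if self.relation not in ("distinct", "identical", "chiral_partners"):
            raise ValueError(f"unknown relation {self.relation!r}")
        if self.relation in ("identical", "chiral_partners"):
            if self.molA.key != self.molB.key or self.molA.charge != self.molB.charge:
                raise ValueError(
                    f"relation {self.relation!r} requires equal point groups and charges"
                )

    @property
    def dimensionality(self) -> int:
        """Number of intermolecular coordinates (Table-1 class): R + angles."""
        return 1 + len(self.free_angles)

    @property
    def free_angles(self) -> tuple[str, ...]:
        """The free angular coordinate subset, in file-column order."""
        sa, sb = self.molA.shape, self.molB.shape
        cols = []
        if sa != "atom" and sb != "atom":
            cols.append("alpha")
        if sa != "atom":
            cols.append("beta_A")
        if sb != "atom":
            cols.append("beta_B")
        if sa == "nonlinear":
            cols.append("gamma_A")
        if sb == "nonlinear":
            cols.append("gamma_B")
        return tuple(cols)


@dataclass(frozen=True)
class SymmetryBasis:
    """Orthonormal basis of the totally symmetric rank-l subspace.

    ``vectors`` has shape (2l+1, dim); each column is one surviving
    combination in the real component basis of :func:`labels_for_rank`.
    """

    l: int
    vectors: np.ndarray

    @property
    def dim(self) -> int:
        return self.vectors.shape[1]

    def component_labels(self) -> list[str]:
        """One human-readable label per basis vector (dominant component,
        '+' joined to others above 5% weight)."""
        labs = labels_for_rank(self.l)
        out = []
        for k in range(self.dim):
            v = self.vectors[:, k]
            order = np.argsort(-np.abs(v))
            main = [str(labs[i]) for i in order if abs(v[i]) > 0.05 * abs(v[order[0]])]
            out.append("+".join(main[:3]))
        return out


# ---------------------------------------------------------------------------
# group construction
# ---------------------------------------------------------------------------

def _generators(family: str, n: Optional[int]) -> list[np.ndarray]:
    if family == "C1":
        return []
    if family == "Cs":
        return [_SIG_XY]
    if family == "Ci":
        return [_INV]
    if family == "Cn":
        return [_cz(n)]
    if family == "Cnh":
        return [_cz(n), _SIG_XY]
    if family == "Cnv":
        return [_cz(n), _SIG_XZ]
    if family == "Dn":
        return [_cz(n), _C2X]
    if family == "Dnh":
        # S_n^z and C_2^x generate D_nh only for odd n; the explicit
        # C_n/sigma_xy set below closes to the full group for every n.
        return [_cz(n), _C2X, _SIG_XY]
    if family == "Dnd":
        return [_cz(n), _C2X, _sz(2 * n)]
    if family == "S2n":
        return [_sz(2 * n)]
    if family == "T":
        return [_cz(2), _C3_DIAG]
    if family == "Th":
        return [_cz(2), _SIG_XY, _C3_DIAG]
    if family == "Td":
        return [_sz(4), _C3_DIAG]
    if family == "O":
        return [_cz(4), _C3_DIAG]
    if family == "Oh":
        return [_cz(4), _SIG_XY, _C3_DIAG]
    if family == "I":
        return [_cz(2), _C3_DIAG, _C5_ICO]
    if family == "Ih":
        return [_cz(2), _SIG_XY, _C3_DIAG, _C5_ICO]
    if family == "Cinfv":
        return [_cz(_SURROGATE_N)]
    if family == "Dinfh":
        return [_cz(_SURROGATE_N), _SIG_XY]
    raise ValueError(f"no generator table for {family}")


def group_closure(generators: Sequence[np.ndarray], max_order: int = 4096) -> list[np.ndarray]:
    """Close a generator set under multiplication (matrix hash at 1e-9)."""

    def key(g):
        return (np.round(g, 9) + 0.0).tobytes()  # +0.0 folds -0.0 into +0.0

    elems = {key(np.eye(3)): np.eye(3)}
    frontier = [np.eye(3)]
    gens = [np.asarray(g, dtype=float) for g in generators]
    while frontier:
        new = []
        for h in frontier:
            for g in gens:
                p = g @ h
                k = key(p)
                if k not in elems:
                    elems[k] = p
                    new.append(p)
        frontier = new
        if len(elems) > max_order:
            raise RuntimeError("group closure did not terminate")
    return list(elems.values())


@lru_cache(maxsize=None)
def _group_elements_cached(family: str, n: Optional[int]) -> tuple[np.ndarray, ...]:
    return tuple(group_closure(_generators(family, n)))


def group_elements(spec: MoleculeSpec) -> list[np.ndarray]:
    """All elements of the oriented (finite) point group as 3x3 matrices."""
    if spec.family == "atom":
        raise ValueError("atoms carry the full rotation group; not enumerable")
    if spec.family in ("Cinfv", "Dinfh"):
        raise ValueError(f"{spec.family} is continuous; not enumerable")
    return [g.copy() for g in _group_elements_cached(*spec.key)]


def _projection_elements(spec: MoleculeSpec) -> Optional[list[np.ndarray]]:
    """Element list used for projection (surrogate for the axial continuous
    groups, exact for l <= 15); None for atoms."""
    if spec.family == "atom":
        return None
    return list(_group_elements_cached(*spec.key))


# ---------------------------------------------------------------------------
# invariant subspaces
# ---------------------------------------------------------------------------

def _column_space(P: np.ndarray, tol: float = 1e-8) -> np.ndarray:
    """Deterministic orthonormal basis of the column space of a projector.

    Gram-Schmidt over the projected standard basis vectors in component
    order, so the basis aligns with individual components whenever the
    projector allows it (rank counted at singular-value threshold
    ``tol``); the result does not depend on LAPACK's ordering of
    degenerate singular vectors.
    """
    P = 0.5 * (P + P.T)
    P[np.abs(P) < 1e-10] = 0.0
    rank = int(np.sum(np.linalg.svd(P, compute_uv=False) > tol))
    cols: list[np.ndarray] = []
    for i in range(P.shape[0]):
        r = P[:, i].copy()
        for v in cols:
            r -= v * (v @ r)
        nrm = float(np.linalg.norm(r))
        if nrm > 1e-6:
            v = r / nrm
            i0 = int(np.argmax(np.abs(v)))
            if v[i0] < 0:
                v = -v
            v[np.abs(v) < 1e-12] = 0.0
            v /= np.linalg.norm(v)
            cols.append(v)
        if len(cols) == rank:
            break
    return np.column_stack(cols) if cols else np.zeros((P.shape[0], 0))


@lru_cache(maxsize=None)
def _invariant_basis_cached(family: str, n: Optional[int], l: int) -> np.ndarray:
    dim = 2 * l + 1
    if family == "atom":
        return np.ones((1, 1)) if l == 0 else np.zeros((dim, 0))
    elems = _group_elements_cached(family, n)
    P = np.zeros((dim, dim))
    for g in elems:
        P += rep_matrix_real(l, g)
    P /= len(elems)
    return _column_space(P)


def invariant_basis(spec: MoleculeSpec, l: int) -> SymmetryBasis:
    """Totally symmetric subspace of the rank-l real components."""
    if not 0 <= l <= MAX_RANK:
        raise ValueError(f"rank l={l} outside 0..{MAX_RANK}")
    return SymmetryBasis(l, _invariant_basis_cached(spec.family, spec.axis_order, l).copy())


def allowed_multipoles(spec: MoleculeSpec, l_max: int) -> dict[int, SymmetryBasis]:
    """Per-rank surviving bases, ranks 0..l_max with nonzero dimension.

    Rank 0 is always present; its value is pinned to the declared charge
    (zero for a neutral molecule) and never fitted.
    """
    if l_max > MAX_RANK:
        raise ValueError(f"l_max={l_max} exceeds {MAX_RANK}")
    out = {}
    for l in range(l_max + 1):
        b = invariant_basis(spec, l)
        if b.dim > 0:
            out[l] = b
    return out


@lru_cache(maxsize=None)
def _alpha_block_cached(family: str, n: Optional[int], l1: int, l2: int) -> tuple[np.ndarray, ...]:
    """Invariant patterns of the (l1, l2) polarizability block, l1 <= l2.

    Patterns are (2l1+1) x (2l2+1) matrices, Frobenius-normalized; for
    l1 == l2 they are symmetric (alpha_{t;t'} = alpha_{t';t}).
    """
    d1, d2 = 2 * l1 + 1, 2 * l2 + 1
    if family == "atom":
        if l1 != l2:
            return ()
        return (np.eye(d1) / math.sqrt(d1),)
    elems = _group_elements_cached(family, n)
    P = np.zeros((d1 * d2, d1 * d2))
    for g in elems:
        P += np.kron(rep_matrix_real(l1, g), rep_matrix_real(l2, g))
    P /= len(elems)
    if l1 == l2:
        # symmetrizer in the vec basis commutes with g (x) g
        idx = np.arange(d1 * d2).reshape(d1, d2).T.reshape(-1)
        S = np.zeros((d1 * d2, d1 * d2))
        S[np.arange(d1 * d2), idx] = 1.0
        P = 0.5 * (P + P @ S)
        P = P @ (0.5 * (np.eye(d1 * d2) + S))
    V = _column_space(P)
    return tuple(np.ascontiguousarray(V[:, j].reshape(d1, d2)) for j in range(V.shape[1]))


def polarizability_pattern(spec: MoleculeSpec, l_max: int) -> dict[tuple[int, int], tuple[np.ndarray, ...]]:
    """Symmetry-allowed polarizability patterns per (l1, l2) block.

    alpha transforms as the symmetrized product of two multipole ranks;
    the returned dict maps each block 1 <= l1 <= l2 <= l_max to its tuple
    of invariant pattern matrices (possibly empty blocks are omitted).
    """
    if l_max > MAX_RANK - 1:
        raise ValueError(f"l_max={l_max} exceeds {MAX_RANK - 1}")
    out = {}
    for l1 in range(1, l_max + 1):
        for l2 in range(l1, l_max + 1):
            pats = _alpha_block_cached(spec.family, spec.axis_order, l1, l2)
            if pats:
                out[(l1, l2)] = pats
    return out


# ---------------------------------------------------------------------------
# leading orders
# ---------------------------------------------------------------------------

def _active_multipole_ranks(spec: MoleculeSpec, l_max: int) -> list[int]:
    """Ranks that can contribute terms: 0 only when charged, l>0 when the
    symmetric subspace is nonzero."""
    ranks = []
    for l, b in allowed_multipoles(spec, l_max).items():
        if l == 0:
            if spec.charge != 0.0:
                ranks.append(0)
        elif b.dim > 0:
            ranks.append(l)
    return ranks


def _alpha_block_ranks(spec: MoleculeSpec, max_sum: int) -> list[tuple[int, int]]:
    blocks = []
    for l1 in range(1, max_sum):
        for l2 in range(l1, max_sum - l1 + 1):
            if _alpha_block_cached(spec.family, spec.axis_order, l1, l2):
                blocks.append((l1, l2))
    return blocks


def leading_order(sys: SystemSpec, interaction: str, max_order: int = MAX_RANK) -> Optional[int]:
    """Smallest inverse-power order n (term ~ R^-n) with an allowed term.

    Returns None when no term of that interaction exists at or below
    ``max_order`` (e.g. electrostatics for an icosahedral molecule with a
    rare-gas atom).
    """
    best: Optional[int] = None

    def upd(n):
        nonlocal best
        if n <= max_order and (best is None or n < best):
            best = n

    A, B = sys.molA, sys.molB
    if interaction == "electrostatic":
        ra = _active_multipole_ranks(A, max_order - 1)
        rb = _active_multipole_ranks(B, max_order - 1)
        for la in ra:
            for lb in rb:
                upd(la + lb + 1)
    elif interaction == "induction":
        for pol, src in ((A, B), (B, A)):
            rs = _active_multipole_ranks(src, max_order - 1)
            if not rs:
                continue
            k = min(rs)
            for (l1, l2) in _alpha_block_ranks(pol, max_order - 2 - 2 * k + 1):
                upd(l1 + l2 + 2 * k + 2)
    elif interaction == "dispersion":
        bA = _alpha_block_ranks(A, max_order)
        bB = _alpha_block_ranks(B, max_order)
        for (l1, l2) in bA:
            for (k1, k2) in bB:
                upd(l1 + k1 + l2 + k2 + 2)
    else:
        raise ValueError(f"unknown interaction {interaction!r}")
    return best


# ---------------------------------------------------------------------------
# exchange constraints
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ExchangeConstraints:
    """How molecule B's coefficients are determined by molecule A's.

    ``rank_maps[l]`` is the orthogonal matrix W_l acting on basis
    coordinates: coords_B = W_l coords_A.  For ``identical`` partners W_l
    is the identity; for ``chiral_partners`` it is the numeric image of
    the xz mirror (s-type components change sign) expressed in the
    symmetry-adapted basis.  Empty for distinct molecules.
    """

    relation: str
    rank_maps: dict[int, np.ndarray] = field(default_factory=dict)

    @property
    def empty(self) -> bool:
        return not self.rank_maps and self.relation == "distinct"


def exchange_constraints(sys: SystemSpec, l_max: int = MAX_RANK) -> ExchangeConstraints:
    """Constraint set tying the two monomers' coefficient sets together."""
    if sys.relation == "distinct":
        return ExchangeConstraints("distinct", {})
    maps: dict[int, np.ndarray] = {}
    for l in range(l_max + 1):
        V = _invariant_basis_cached(sys.molA.family, sys.molA.axis_order, l)
        if V.shape[1] == 0:
            continue
        if sys.relation == "identical":
            maps[l] = np.eye(V.shape[1])
        else:
            S = rep_matrix_real(l, _SIG_XZ)
            W = V.T @ S @ V
            resid = float(np.max(np.abs(S @ V - V @ W))) if V.size else 0.0
            if resid > 1e-8:
                raise RuntimeError(
                    f"xz mirror does not preserve the allowed rank-{l} subspace "
                    f"(residual {resid:.2e}); cannot tie chiral partners"
                )
            maps[l] = W
    return ExchangeConstraints(sys.relation, maps)
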