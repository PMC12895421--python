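"""Dataset I/O, the LeRoy distance filter, and coefficient/evaluator export.

File dialect (this package's own, documented here and in the docs):
whitespace-separated numeric columns, ``#`` comment lines, an optional
non-numeric header line (auto-detected and skipped).  Columns are, in
order, R, the free angular coordinates of the system's dimensionality
class, and the energy:

    1D (atom+atom)          R  E
    2D (linear+atom)        R  beta_A  E
    3D (nonlinear+atom)     R  beta_A  gamma_A  E
    4D (linear+linear)      R  alpha  beta_A  beta_B  E
    5D (nonlinear+linear)   R  alpha  beta_A  beta_B  gamma_A  E
    6D (nonlinear+nonlinear) R alpha  beta_A  beta_B  gamma_A  gamma_B  E

Default file units are angstrom / degree / cm^-1; everything is converted
to internal atomic units and radians on read.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from . import units as U
from .expansion import CoefficientSet, Expansion, Term
from .symmetry import MoleculeSpec, SystemSpec
from .tensor_core import (
    AtomSite,
    DimerGeometry,
    EulerAngles,
    dimer_site_positions,
    t_tensor_matrix,
)

__all__ = [
    "Dataset",
    "FilterMask",
    "read_dataset",
    "write_dataset",
    "leroy_filter",
    "write_coefficients",
    "read_coefficients",
    "export_evaluator",
    "reevaluate_exported",
]

COEFF_FORMAT_VERSION = 1

DEFAULT_UNITS = {"distance": "angstrom", "angle": "degree", "energy": "cm-1"}


@dataclass
class Dataset:
    """Scattered interaction energies vs. intermolecular coordinates.

    Geometries and energies are stored in internal units (bohr, radian,
    hartree); ``units`` records the originating file units.
    """

    geometries: tuple[DimerGeometry, ...]
    energies: np.ndarray
    units: dict = field(default_factory=lambda: dict(DEFAULT_UNITS))
    provenance: str = ""

    def __post_init__(self):
        self.geometries = tuple(self.geometries)
        self.energies = np.asarray(self.energies, dtype=float)
        if len(self.geometries) != self.energies.shape[0]:
            raise ValueError("geometry/energy length mismatch")
        if self.energies.size and not np.all(np.isfinite(self.energies)):
            raise ValueError("non-finite energies in dataset")

    def __len__(self) -> int:
        return len(self.geometries)

    @property
    def R(self) -> np.ndarray:
        return np.array([g.R for g in self.geometries])

    def subset(self, mask) -> "Dataset":
        mask = np.asarray(mask)
        idx = np.nonzero(mask)[0] if mask.dtype == bool else mask
        return Dataset(
            tuple(self.geometries[i] for i in idx),
            self.energies[idx],
            dict(self.units),
            self.provenance,
        )


def _angles_to_geometry(angles: dict[str, float], R: float) -> DimerGeometry:
    return DimerGeometry(
        R,
        EulerAngles(angles.get("alpha", 0.0), angles.get("beta_A", 0.0), angles.get("gamma_A", 0.0)),
        EulerAngles(0.0, angles.get("beta_B", 0.0), angles.get("gamma_B", 0.0)),
    )


def _geometry_to_columns(g: DimerGeometry, names: Sequence[str]) -> list[float]:
    vals = {
        "alpha": g.omega_A.alpha - g.omega_B.alpha,
        "beta_A": g.omega_A.beta,
        "beta_B": g.omega_B.beta,
        "gamma_A": g.omega_A.gamma,
        "gamma_B": g.omega_B.gamma,
    }
    return [vals[n] for n in names]


def read_dataset(path, units: Optional[dict] = None, sys: Optional[SystemSpec] = None) -> Dataset:
    """Read a whitespace-column energy file into internal units.

    ``units`` may override any of {'distance', 'angle', 'energy'};
    ``sys`` fixes the expected column layout (R + free angles + E) and is
    required to interpret the angle columns.
    """
    if sys is None:
        raise ValueError("read_dataset requires the SystemSpec to fix the column layout")
    u = dict(DEFAULT_UNITS)
    if units:
        u.update(units)
    names = sys.free_angles
    ncol = 2 + len(names)

    geoms, energies = [], []
    with open(path) as fh:
        lines = fh.readlines()
    first_data = True
    for ln, raw in enumerate(lines, start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        fields = line.split()
        if first_data:
            # optional header line: skip if any field is non-numeric
            try:
                [float(f) for f in fields]
            except ValueError:
                first_data = False
                continue
            first_data = False
        if len(fields) != ncol:
            raise ValueError(
                f"{path}:{ln}: expected {ncol} columns "
                f"(R, {', '.join(names)}, E) for this {sys.dimensionality}D system, "
                f"got {len(fields)}"
            )
        try:
            vals = [float(f) for f in fields]
        except ValueError as e:
            raise ValueError(f"{path}:{ln}: non-numeric field ({e})") from None
        R = U.to_internal_distance(vals[0], u["distance"])
        ang = {nm: U.to_internal_angle(v, u["angle"]) for nm, v in zip(names, vals[1:-1])}
        geoms.append(_angles_to_geometry(ang, R))
        energies.append(U.to_internal_energy(vals[-1], u["energy"]))
    if not geoms:
        warnings.warn(f"{path}: empty dataset")
    return Dataset(tuple(geoms), np.array(energies), u, provenance=str(path))


def write_dataset(data: Dataset, path, sys: SystemSpec, units: Optional[dict] = None):
    """Inverse of :func:`read_dataset` (same dialect and default units)."""
    u = dict(DEFAULT_UNITS)
    if units:
        u.update(units)
    names = sys.free_angles
    kd = 1.0 / U.DISTANCE_TO_BOHR[U._norm(u["distance"], U.DISTANCE_TO_BOHR)]
    ka = 1.0 / U.ANGLE_TO_RAD[U._norm(u["angle"], U.ANGLE_TO_RAD)]
    ke = 1.0 / U.ENERGY_TO_HARTREE[U._norm(u["energy"], U.ENERGY_TO_HARTREE)]
    with open(path, "w") as fh:
        fh.write(f"# R[{u['distance']}] {' '.join(n + '[' + u['angle'] + ']' for n in names)} "
                 f"E[{u['energy']}]\n")
        for g, e in zip(data.geometries, data.energies):
            cols = [g.R * kd] + [a * ka for a in _geometry_to_columns(g, names)] + [e * ke]
            fh.write(" ".join(f"{c:.17g}" for c in cols) + "\n")


# ---------------------------------------------------------------------------
# LeRoy filter
# ---------------------------------------------------------------------------

@dataclass
class FilterMask:
    """Admission mask from the minimal inter-fragment atom-pair distance."""

    mask: np.ndarray
    d_min: float
    min_distances: np.ndarray

    def __post_init__(self):
        self.mask = np.asarray(self.mask, dtype=bool)
        self.min_distances = np.asarray(self.min_distances, dtype=float)


def _sites_of(mol: MoleculeSpec) -> tuple[AtomSite, ...]:
    if mol.sites:
        return tuple(mol.sites)
    if mol.shape == "atom":
        return (AtomSite(mol.charge, (0.0, 0.0, 0.0)),)
    raise ValueError(
        f"molecule {mol.name!r} carries no sites; the LeRoy filter needs atom positions"
    )


def leroy_filter(data: Dataset, sys: SystemSpec, d_min: float) -> FilterMask:
    """Admit a point iff every inter-fragment atom pair is >= d_min apart.

    Sites are placed by each monomer's Euler rotation and the
    center-of-mass separation; the boundary (== d_min) admits.  d_min is
    in bohr (internal units).
    """
    sA = _sites_of(sys.molA)
    sB = _sites_of(sys.molB)
    dmin = np.empty(len(data))
    for i, g in enumerate(data.geometries):
        pA, pB = dimer_site_positions(sA, sB, g)
        dmin[i] = np.min(np.linalg.norm(pA[:, None, :] - pB[None, :, :], axis=-1))
    return FilterMask(dmin >= d_min, float(d_min), dmin)


# ---------------------------------------------------------------------------
# coefficient serialization
# ---------------------------------------------------------------------------

def _mol_to_json(m: MoleculeSpec) -> dict:
    return {
        "name": m.name,
        "point_group": m.point_group,
        "n": m.n,
        "charge": m.charge,
        "sites": [[s.charge, list(s.position)] for s in m.sites] if m.sites else None,
    }


def _mol_from_json(d: dict) -> MoleculeSpec:
    sites = tuple(AtomSite(c, tuple(p)) for c, p in d["sites"]) if d.get("sites") else None
    return MoleculeSpec(d["name"], d["point_group"], d.get("n"), d.get("charge", 0.0), sites)


def system_to_json(sys: SystemSpec) -> dict:
    return {"molA": _mol_to_json(sys.molA), "molB": _mol_to_json(sys.molB),
            "relation": sys.relation}


def system_from_json(d: dict) -> SystemSpec:
    return SystemSpec(_mol_from_json(d["molA"]), _mol_from_json(d["molB"]), d["relation"])


def _caps_of_terms(terms: Sequence[Term]) -> dict:
    caps: dict[str, int] = {}
    for t in terms:
        k = {"electrostatic": "electrostatic", "induction_A": "induction",
             "induction_B": "induction", "dispersion": "dispersion"}[t.interaction]
        caps[k] = max(caps.get(k, 0), t.order)
    return caps


def write_coefficients(coeffs: CoefficientSet, sys: SystemSpec,
                       terms: Sequence[Term], path, metadata: Optional[dict] = None):
    """Serialize system, term list and coefficient values as JSON.

    The term ordering is the deterministic expansion ordering, so two
    writes of the same fit are byte-identical; ``read_coefficients`` o
    ``write_coefficients`` is the identity on values.
    """
    caps = _caps_of_terms(terms)
    exp = Expansion(sys, caps)
    entries = []
    for key in exp.parameter_keys:
        entries.append({"name": exp.parameter_name(key), "value": exp.get_entry(coeffs, key)})
    for mol in ("A", "B"):
        entries.append({"name": f"Q_{mol}[00]",
                        "value": float(coeffs.Q[(mol, 0)][0]) if (mol, 0) in coeffs.Q else
                        (sys.molA.charge if mol == "A" else sys.molB.charge)})
    doc = {
        "format": "lrfit-coefficients",
        "version": COEFF_FORMAT_VERSION,
        "system": system_to_json(sys),
        "caps": caps,
        "units": coeffs.meta.get("units", "atomic"),
        "terms": [
            {"interaction": t.interaction, "order": t.order, "labels": list(t.labels),
             "coefficients": list(t.coefficient_role)}
            for t in exp.terms
        ],
        "coefficients": entries,
        "metadata": metadata or {},
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1, sort_keys=False)
        fh.write("\n")


def read_coefficients(path):
    """Read a coefficient file; returns (CoefficientSet, SystemSpec, terms).

    Raises on version mismatch and on any required coefficient missing
    from the file (named in the error).
    """
    with open(path) as fh:
        doc = json.load(fh)
    if doc.get("format") != "lrfit-coefficients" or doc.get("version") != COEFF_FORMAT_VERSION:
        raise ValueError(
            f"{path}: unsupported coefficient file "
            f"(format={doc.get('format')!r} version={doc.get('version')!r})"
        )
    sys = system_from_json(doc["system"])
    caps = {k: int(v) for k, v in doc["caps"].items()}
    exp = Expansion(sys, caps)
    values = {e["name"]: float(e["value"]) for e in doc["coefficients"]}
    cs = exp.zero_coefficients()
    cs.meta["units"] = doc.get("units", "atomic")
    for key in exp.parameter_keys:
        name = exp.parameter_name(key)
        if name not in values:
            raise ValueError(f"{path}: required coefficient {name!r} missing")
        exp.set_entry(cs, key, values[name])
    return cs, sys, list(exp.terms)


# ---------------------------------------------------------------------------
# standalone evaluator export
# ---------------------------------------------------------------------------

def _flatten_model(coeffs: CoefficientSet, sys: SystemSpec, terms: Sequence[Term]):
    """Reduce the model to primitive contractions of T-tensor entries.

    linear entries:    (la, ta, lb, tb, c)        E += c * T(la,lb)[ta,tb]
    quadratic entries: (l1,t,k1,u,l2,s,k2,v, c)   E += c * T(l1,k1)[t,u] * T(l2,k2)[s,v]
    """
    caps = _caps_of_terms(terms)
    exp = Expansion(sys, caps)
    lin: list[tuple] = []
    quad: list[tuple] = []

    def qvec(mol, l):
        return exp.mult[mol][l].vectors @ coeffs.Q[(mol, l)]

    cap_el = exp.caps.get("electrostatic", 0)
    for la in exp._active_ranks("A"):
        qa = qvec("A", la)
        for lb in exp._active_ranks("B"):
            if la + lb + 1 > cap_el:
                continue
            qb = qvec("B", lb)
            for ta in range(2 * la + 1):
                for tb in range(2 * lb + 1):
                    c = qa[ta] * qb[tb]
                    if c != 0.0:
                        lin.append((la, ta, lb, tb, float(c)))

    cap_in = exp.caps.get("induction", 0)
    for pol_mol in ("A", "B"):
        src = "B" if pol_mol == "A" else "A"
        for (blk, k1, k2) in exp._ind_quads(pol_mol, cap_in):
            l1, l2 = blk
            A = exp._alpha_mat(coeffs, pol_mol, blk)
            q1, q2 = qvec(src, k1), qvec(src, k2)
            ordered = [(l1, l2, A)] if l1 == l2 else [(l1, l2, A), (l2, l1, A.T)]
            for (m1, m2, Am) in ordered:
                for t in range(2 * m1 + 1):
                    for s in range(2 * m2 + 1):
                        if Am[t, s] == 0.0:
                            continue
                        for u in range(2 * k1 + 1):
                            for v in range(2 * k2 + 1):
                                c = -0.5 * Am[t, s] * q1[u] * q2[v]
                                if c == 0.0:
                                    continue
                                if pol_mol == "A":
                                    quad.append((m1, t, k1, u, m2, s, k2, v, float(c)))
                                else:
                                    quad.append((k1, u, m1, t, k2, v, m2, s, float(c)))

    cap_di = exp.caps.get("dispersion", 0)
    for (Lb, Kb, pr) in exp._disp_blocks(cap_di):
        d = coeffs.D[(Lb, Kb, pr)]
        l1, l2 = Lb
        k1, k2 = Kb
        for p in range(d.shape[0]):
            for q in range(d.shape[1]):
                if d[p, q] == 0.0:
                    continue
                PA = exp.pol["A"][Lb][p]
                PB = exp.pol["B"][Kb][q]
                for t in range(2 * l1 + 1):
                    for s in range(2 * l2 + 1):
                        if PA[t, s] == 0.0:
                            continue
                        for u in range(2 * k1 + 1):
                            for v in range(2 * k2 + 1):
                                c = -d[p, q] * PA[t, s] * PB[u, v]
                                if c == 0.0:
                                    continue
                                if pr == "s":
                                    quad.append((l1, t, k1, u, l2, s, k2, v, float(c)))
                                else:
                                    quad.append((l1, t, k2, v, l2, s, k1, u, float(c)))
    return lin, quad


def _merge_entries(entries, width):
    merged: dict[tuple, float] = {}
    for e in entries:
        key, c = tuple(e[:width]), e[width]
        merged[key] = merged.get(key, 0.0) + c
    return [k + (c,) for k, c in sorted(merged.items()) if c != 0.0]


def export_evaluator(coeffs: CoefficientSet, sys: SystemSpec,
                     terms: Sequence[Term], path) -> tuple[str, str]:
    """Export the fitted model for external evaluation.

    Writes ``<path>.json`` (the normative machine-readable term +
    coefficient file: flattened linear/quadratic contractions of
    T-tensor entries) and ``<path>.f90`` (a self-contained free-form
    Fortran subroutine ``lrf_energy(R, alpha, beta_a, gamma_a, beta_b,
    gamma_b, E)`` templated from the same tables; R in bohr, angles in
    radian, E in hartree).  Returns the two file names.
    """
    from .tensor_core import _x_real  # dimer-frame coupling tables

    path = str(path)
    stem = path[:-4] if path.endswith(".f90") else (path[:-5] if path.endswith(".json") else path)
    lin, quad = _flatten_model(coeffs, sys, terms)
    lin = _merge_entries(lin, 4)
    quad = _merge_entries(quad, 8)
    lmax = 0
    pairs = set()
    for (la, ta, lb, tb, c) in lin:
        lmax = max(lmax, la, lb)
        pairs.add((la, lb))
    for (l1, t, k1, u, l2, s, k2, v, c) in quad:
        lmax = max(lmax, l1, k1, l2, k2)
        pairs.add((l1, k1))
        pairs.add((l2, k2))
    doc = {
        "format": "lrfit-evaluator",
        "version": COEFF_FORMAT_VERSION,
        "system": system_to_json(sys),
        "easym": coeffs.easym,
        "lmax": lmax,
        "linear": [list(e) for e in lin],
        "quadratic": [list(e) for e in quad],
    }
    json_path = stem + ".json"
    with open(json_path, "w") as fh:
        json.dump(doc, fh, indent=None, separators=(",", ":"), sort_keys=False)
        fh.write("\n")

    f90_path = stem + ".f90"
    xblocks = {pair: _x_real(*pair) for pair in sorted(pairs)}
    with open(f90_path, "w") as fh:
        fh.write(_fortran_source(coeffs.easym, lmax, sorted(pairs), xblocks, lin, quad))
    return json_path, f90_path


def reevaluate_exported(json_path, geom: DimerGeometry) -> float:
    """Evaluate an exported term file inside the package (parity check)."""
    with open(json_path) as fh:
        doc = json.load(fh)
    if doc.get("format") != "lrfit-evaluator":
        raise ValueError(f"{json_path}: not an lrfit evaluator file")
    cache: dict[tuple[int, int], np.ndarray] = {}

    def T(la, lb):
        if (la, lb) not in cache:
            cache[(la, lb)] = t_tensor_matrix(la, lb, geom)
        return cache[(la, lb)]

    E = float(doc["easym"])
    for la, ta, lb, tb, c in doc["linear"]:
        E += c * T(la, lb)[ta, tb]
    for l1, t, k1, u, l2, s, k2, v, c in doc["quadratic"]:
        E += c * T(l1, k1)[t, u] * T(l2, k2)[s, v]
    return E


def _fmt(x: float) -> str:
    return f"{x:.17e}".replace("e", "d")


def _fort_list(X) -> str:
    """Column-major value list, 3 values per continued line (<=132 chars)."""
    flat = [_fmt(X[i, j]) for j in range(X.shape[1]) for i in range(X.shape[0])]
    rows = [", ".join(flat[i:i + 3]) for i in range(0, len(flat), 3)]
    return ", &\n".join("        " + r for r in rows)


def _fortran_source(easym, lmax, pairs, xblocks, lin, quad) -> str:
    """Self-contained free-form Fortran for the exported model."""
    dim = 2 * lmax + 1
    lines = []
    w = lines.append
    w("! Long-range interaction energy evaluator (generated).")
    w("! E(R, angles) = E_asym + sum_k c_k T(la,lb)[ta,tb] (+ quadratic terms),")
    w("! with T = Ma^T X Mb / R**(la+lb+1); Ma, Mb real Wigner rotation matrices.")
    w("! Self-contained; no external dependencies.  R in bohr, angles in radian,")
    w("! energy in hartree.")
    w("module lrf_evaluator")
    w("  implicit none")
    w("  integer, parameter :: dp = kind(1.0d0)")
    w(f"  integer, parameter :: lmax = {lmax}")
    w(f"  real(dp), parameter :: easym = {_fmt(easym)}")
    w("contains")
    w("")
    w("  subroutine lrf_energy(r, alpha, beta_a, gamma_a, beta_b, gamma_b, e)")
    w("    real(dp), intent(in) :: r, alpha, beta_a, gamma_a, beta_b, gamma_b")
    w("    real(dp), intent(out) :: e")
    w(f"    real(dp) :: ma(0:lmax,{dim},{dim}), mb(0:lmax,{dim},{dim})")
    w("    integer :: l")
    w("    do l = 0, lmax")
    w("      call real_rotation(l, alpha, beta_a, gamma_a, ma(l,:,:))")
    w("      call real_rotation(l, 0.0_dp, beta_b, gamma_b, mb(l,:,:))")
    w("    end do")
    w("    e = easym")
    w("    call add_terms(r, ma, mb, e)")
    w("  end subroutine lrf_energy")
    w("")
    # T block helper
    w("  subroutine t_block(la, lb, r, ma, mb, x, t)")
    w("    integer, intent(in) :: la, lb")
    w("    real(dp), intent(in) :: r")
    w(f"    real(dp), intent(in) :: ma(0:lmax,{dim},{dim}), mb(0:lmax,{dim},{dim})")
    w("    real(dp), intent(in) :: x(2*la+1, 2*lb+1)")
    w("    real(dp), intent(out) :: t(2*la+1, 2*lb+1)")
    w("    integer :: i, j, p, q")
    w("    do i = 1, 2*la+1")
    w("      do j = 1, 2*lb+1")
    w("        t(i,j) = 0.0_dp")
    w("        do p = 1, 2*la+1")
    w("          do q = 1, 2*lb+1")
    w("            t(i,j) = t(i,j) + ma(la,p,i) * x(p,q) * mb(lb,q,j)")
    w("          end do")
    w("        end do")
    w("        t(i,j) = t(i,j) / r**(la+lb+1)")
    w("      end do")
    w("    end do")
    w("  end subroutine t_block")
    w("")
    # real rotation via complex Wigner D
    w("  subroutine real_rotation(l, alpha, beta, gamma, m)")
    w("    integer, intent(in) :: l")
    w("    real(dp), intent(in) :: alpha, beta, gamma")
    w(f"    real(dp), intent(out) :: m({dim},{dim})")
    w("    complex(dp) :: d(-l:l,-l:l), c(-l:l,2*l+1), acc")
    w("    integer :: mp, mm, t, u")
    w("    real(dp) :: sq2")
    w("    sq2 = sqrt(2.0_dp)")
    w("    do mp = -l, l")
    w("      do mm = -l, l")
    w("        d(mp,mm) = exp(cmplx(0.0_dp, -mp*alpha, dp)) * smalld(l, mp, mm, beta) &")
    w("                 * exp(cmplx(0.0_dp, -mm*gamma, dp))")
    w("      end do")
    w("    end do")
    w("    ! complex-from-real transform: columns l0, l1c, l1s, l2c, l2s, ...")
    w("    c = (0.0_dp, 0.0_dp)")
    w("    c(0,1) = (1.0_dp, 0.0_dp)")
    w("    do mm = 1, l")
    w("      c( mm, 2*mm)   = (-1)**mm / sq2")
    w("      c( mm, 2*mm+1) = (-1)**mm * cmplx(0.0_dp, 1.0_dp, dp) / sq2")
    w("      c(-mm, 2*mm)   = cmplx(1.0_dp/sq2, 0.0_dp, dp)")
    w("      c(-mm, 2*mm+1) = cmplx(0.0_dp, -1.0_dp/sq2, dp)")
    w("    end do")
    w("    ! M = C^H conj(D) C (real by construction)")
    w("    do t = 1, 2*l+1")
    w("      do u = 1, 2*l+1")
    w("        acc = (0.0_dp, 0.0_dp)")
    w("        do mp = -l, l")
    w("          do mm = -l, l")
    w("            acc = acc + conjg(c(mp,t)) * conjg(d(mp,mm)) * c(mm,u)")
    w("          end do")
    w("        end do")
    w("        m(t,u) = real(acc, dp)")
    w("      end do")
    w("    end do")
    w("  end subroutine real_rotation")
    w("")
    w("  function smalld(l, mp, mm, beta) result(d)")
    w("    integer, intent(in) :: l, mp, mm")
    w("    real(dp), intent(in) :: beta")
    w("    real(dp) :: d, cb, sb, pref, term")
    w("    integer :: s")
    w("    cb = cos(beta/2.0_dp); sb = sin(beta/2.0_dp)")
    w("    pref = sqrt(fact(l+mp)*fact(l-mp)*fact(l+mm)*fact(l-mm))")
    w("    d = 0.0_dp")
    w("    do s = max(0, mm-mp), min(l+mm, l-mp)")
    w("      term = (-1.0_dp)**(mp-mm+s) / (fact(l+mm-s)*fact(s)*fact(mp-mm+s)*fact(l-mp-s))")
    w("      d = d + term * cb**(2*l+mm-mp-2*s) * sb**(mp-mm+2*s)")
    w("    end do")
    w("    d = d * pref")
    w("  end function smalld")
    w("")
    w("  function fact(n) result(f)")
    w("    integer, intent(in) :: n")
    w("    real(dp) :: f")
    w("    integer :: i")
    w("    f = 1.0_dp")
    w("    do i = 2, n")
    w("      f = f * real(i, dp)")
    w("    end do")
    w("  end function fact")
    w("")
    # term tables + add_terms
    w("  subroutine add_terms(r, ma, mb, e)")
    w("    real(dp), intent(in) :: r")
    w(f"    real(dp), intent(in) :: ma(0:lmax,{dim},{dim}), mb(0:lmax,{dim},{dim})")
    w("    real(dp), intent(inout) :: e")
    for (la, lb) in pairs:
        X = xblocks[(la, lb)]
        w(f"    block")
        w(f"      real(dp) :: x{la}_{lb}(2*{la}+1, 2*{lb}+1), t{la}_{lb}(2*{la}+1, 2*{lb}+1)")
        vals = _fort_list(X)
        w(f"      x{la}_{lb} = reshape([ &\n{vals} ], [2*{la}+1, 2*{lb}+1])")
        w(f"      call t_block({la}, {lb}, r, ma, mb, x{la}_{lb}, t{la}_{lb})")
        for (a, ta, b, tb, c) in lin:
            if (a, b) == (la, lb):
                w(f"      e = e + ({_fmt(c)}) * t{a}_{b}({ta + 1},{tb + 1})")
        w("    end block")
    if quad:
        w("    block")
        decl = {p: f"q{p[0]}_{p[1]}" for p in pairs}
        for (la, lb) in pairs:
            w(f"      real(dp) :: q{la}_{lb}(2*{la}+1, 2*{lb}+1), xq{la}_{lb}(2*{la}+1, 2*{lb}+1)")
        for (la, lb) in pairs:
            X = xblocks[(la, lb)]
            vals = _fort_list(X)
            w(f"      xq{la}_{lb} = reshape([ &\n{vals} ], [2*{la}+1, 2*{lb}+1])")
            w(f"      call t_block({la}, {lb}, r, ma, mb, xq{la}_{lb}, q{la}_{lb})")
        for (l1, t, k1, u, l2, s, k2, v, c) in quad:
            w(f"      e = e + ({_fmt(c)}) * {decl[(l1, k1)]}({t + 1},{u + 1}) * {decl[(l2, k2)]}({s + 1},{v + 1})")
        w("    end block")
    w("  end subroutine add_terms")
    w("end module lrf_evaluator")
    w("")
    return "\n".join(lines)
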