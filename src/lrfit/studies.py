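"""Reference studies: counting identities, leading-order tables, oracle
comparisons, invariance checks, and synthetic recovery campaigns.

These are the package's own benchmark computations, usable both from the
test-suite and from reporting scripts.  Every stochastic study takes an
explicit seed.
"""

from __future__ import annotations

import math
import warnings
from typing import Optional

import numpy as np

from .expansion import (
    Expansion,
    cartesian_coefficient_count,
    spherical_coefficient_count,
)
from .fitting import FitPlan, LongRangeModel, _Parametrization, default_stages, gauge_align
from .symmetry import MoleculeSpec, SystemSpec, group_elements, leading_order
from .synthetic import (
    SyntheticModel,
    random_coefficients,
    synthetic_dataset,
)
from .tensor_core import (
    AtomSite,
    DimerGeometry,
    EulerAngles,
    TTensorEvaluator,
    attitude_matrix,
    coulomb_oracle,
    exchange_attitudes,
    labels_for_rank,
    multipole_of_point_charges,
    t_tensor_direct_matrix,
    t_tensor_matrix,
)

__all__ = [
    "coefficient_counts",
    "leading_order_summary",
    "oracle_convergence_slopes",
    "t_tensor_agreement",
    "invariance_defects",
    "ih_atom_dispersion_profile",
    "recovery_study",
    "noise_recovery",
    "RECOVERY_SYSTEMS",
]


def _mol(pg, charge=0.0, name=None):
    return MoleculeSpec(name or pg, pg, charge=charge)


# ---------------------------------------------------------------------------
# desk checks
# ---------------------------------------------------------------------------

def coefficient_counts() -> dict[str, int]:
    """Electrostatic coefficient totals in both representations."""
    return {
        "cartesian_order6": cartesian_coefficient_count(6),
        "cartesian_order8": cartesian_coefficient_count(8),
        "cartesian_order10": cartesian_coefficient_count(10),
        "cartesian_order15": cartesian_coefficient_count(15),
        "spherical_order6": spherical_coefficient_count(6),
        "spherical_order15": spherical_coefficient_count(15),
    }


def leading_order_summary() -> dict[str, Optional[int]]:
    """Leading inverse-power orders for the canonical system classes."""
    ion = _mol("Cinfv", 1.0)
    anion = _mol("Cinfv", -1.0)
    polar = _mol("Cinfv")
    h2 = _mol("Dinfh")
    td = _mol("Td")
    ih = _mol("Ih")
    at = _mol("atom")
    co = _mol("Cinfv", name="CO")
    return {
        "elec_ion_pair": leading_order(SystemSpec(ion, anion), "electrostatic"),
        "elec_polar_pair": leading_order(SystemSpec(polar, polar), "electrostatic"),
        "elec_identical_pair": leading_order(SystemSpec(co, co, "identical"), "electrostatic"),
        "elec_centrosym_linear_pair": leading_order(SystemSpec(h2, h2), "electrostatic"),
        "elec_tetrahedral_pair": leading_order(SystemSpec(td, td), "electrostatic"),
        "elec_icosahedral_pair": leading_order(SystemSpec(ih, ih), "electrostatic"),
        "ind_ion_neutral": leading_order(SystemSpec(ion, h2), "induction"),
        "ind_neutral_neutral": leading_order(SystemSpec(polar, polar), "induction"),
        "disp_neutral_neutral": leading_order(SystemSpec(polar, polar), "dispersion"),
        "elec_icosahedral_atom": leading_order(SystemSpec(ih, at), "electrostatic"),
        "ind_icosahedral_atom": leading_order(SystemSpec(ih, at), "induction"),
        "disp_icosahedral_atom": leading_order(SystemSpec(ih, at), "dispersion"),
    }


def ih_atom_dispersion_profile(seed: int = 0, cap: int = 12) -> dict:
    """Dispersion structure of an icosahedral molecule with a rare-gas atom:
    which orders carry terms and where anisotropy first appears."""
    s = SystemSpec(_mol("Ih"), _mol("atom"))
    exp = Expansion(s, {"dispersion": cap})
    orders = sorted({t.order for t in exp.terms})
    rng = np.random.default_rng(seed)
    geoms = [DimerGeometry(9.0, EulerAngles(rng.uniform(0, 2 * math.pi),
                                            math.acos(rng.uniform(-1, 1)),
                                            rng.uniform(0, 2 * math.pi)))
             for _ in range(64)]
    ev = exp.evaluator(geoms)
    first_aniso = None
    for t in sorted(exp.terms, key=lambda t: t.order):
        _, Lb, p, Kb, q, pr = t.key
        g = exp._disp_geom(ev, Lb, Kb, pr, exp.pol["A"][Lb][p], exp.pol["B"][Kb][q])
        rel_spread = float(np.std(g) / max(abs(np.mean(g)), 1e-300))
        if rel_spread > 1e-6 and (first_aniso is None or t.order < first_aniso):
            first_aniso = t.order
    return {"orders": orders, "first_order": orders[0] if orders else None,
            "all_even": all(o % 2 == 0 for o in orders),
            "first_anisotropic_order": first_aniso}


# ---------------------------------------------------------------------------
# oracle comparisons
# ---------------------------------------------------------------------------

def oracle_convergence_slopes(seed: int = 0, Ns=(2, 3, 4, 5),
                              R_range=(20.0, 200.0), n_R: int = 8) -> dict[int, float]:
    """log-log slope of |truncated series - exact Coulomb sum| vs R.

    Small random point-charge fragments; an order-N truncation must decay
    as R^-(N+1).
    """
    rng = np.random.default_rng(seed)
    sitesA = [AtomSite(float(rng.normal()) + 0.5, tuple(rng.normal(size=3) * 0.25))
              for _ in range(3)]
    sitesB = [AtomSite(float(rng.normal()) - 0.5, tuple(rng.normal(size=3) * 0.25))
              for _ in range(3)]
    # averaging |error| over orientations washes out accidental sign
    # cancellations between consecutive orders that would bias the slope
    orients = [(EulerAngles(*rng.uniform(0, 2 * math.pi, 3)),
                EulerAngles(*rng.uniform(0, 2 * math.pi, 3))) for _ in range(4)]
    Rs = np.geomspace(*R_range, n_R)
    qa = {l: np.array([multipole_of_point_charges(sitesA, t) for t in labels_for_rank(l)])
          for l in range(max(Ns))}
    qb = {l: np.array([multipole_of_point_charges(sitesB, t) for t in labels_for_rank(l)])
          for l in range(max(Ns))}
    out = {}
    for N in Ns:
        errs = []
        for R in Rs:
            acc = 0.0
            for (oA, oB) in orients:
                g = DimerGeometry(float(R), oA, oB)
                E = sum(qa[la] @ t_tensor_matrix(la, lb, g) @ qb[lb]
                        for la in range(N) for lb in range(N - la) if la + lb + 1 <= N)
                acc += abs(E - coulomb_oracle(sitesA, sitesB, g))
            errs.append(acc / len(orients))
        out[N] = float(np.polyfit(np.log(Rs), np.log(errs), 1)[0])
    return out


def t_tensor_agreement(seed: int = 0, n_geoms: int = 100, lsum_max: int = 10) -> float:
    """Max relative deviation between the production T-tensor path and the
    literal contraction, every label pair with la+lb <= lsum_max."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_geoms):
        g = DimerGeometry(float(rng.uniform(3.0, 60.0)),
                          EulerAngles(*rng.uniform(0, 2 * math.pi, 3)),
                          EulerAngles(*rng.uniform(0, 2 * math.pi, 3)))
        for la in range(0, lsum_max + 1):
            for lb in range(0, lsum_max - la + 1):
                T = t_tensor_matrix(la, lb, g)
                ref = t_tensor_direct_matrix(la, lb, g)
                scale = float(np.max(np.abs(ref))) or 1.0
                worst = max(worst, float(np.max(np.abs(T - ref))) / scale)
    return worst


# ---------------------------------------------------------------------------
# symmetry invariance
# ---------------------------------------------------------------------------

#: one representative per orientation-convention row (finite members)
TABLE_ROWS = ("Cinfv", "Dinfh", "C1", "Cs", "Ci", "C3", "C3h", "C4v", "D3",
              "D4h", "D3d", "S4", "T", "Th", "Td", "O", "Oh", "I", "Ih")


def _sampled_elements(spec: MoleculeSpec, rng) -> list[np.ndarray]:
    if spec.family in ("Cinfv", "Dinfh"):
        els = []
        for a in rng.uniform(0, 2 * math.pi, 4):
            els.append(np.array([[math.cos(a), -math.sin(a), 0.0],
                                 [math.sin(a), math.cos(a), 0.0],
                                 [0.0, 0.0, 1.0]]))
        if spec.family == "Dinfh":
            els.append(np.diag([1.0, 1.0, -1.0]))
        return els
    return group_elements(spec)


def invariance_defects(seed: int = 0, rows=TABLE_ROWS, systems_per_row: int = 5,
                       caps: Optional[dict] = None) -> dict:
    """Max relative energy change under monomer group operations, the
    identical-pair exchange, and a common azimuth shift."""
    caps = caps or {"electrostatic": 6, "induction": 6, "dispersion": 6}
    rng = np.random.default_rng(seed)
    worst_group = 0.0
    for pg in rows:
        mA = _mol(pg)
        mB = _mol("Cinfv", 0.7)
        s = SystemSpec(mA, mB)
        exp = Expansion(s, caps)
        for _ in range(systems_per_row):
            cs = random_coefficients(s, caps, seed=int(rng.integers(0, 2**31)))
            g = DimerGeometry(float(rng.uniform(7.0, 15.0)),
                              EulerAngles(*rng.uniform(0, 2 * math.pi, 3)),
                              EulerAngles(*rng.uniform(0, 2 * math.pi, 3)))
            OA = attitude_matrix(g.omega_A)
            OB = attitude_matrix(g.omega_B)
            E0 = exp.energy(cs, TTensorEvaluator([g.R], exp.lmax,
                                                 attitudes_A=[OA], attitudes_B=[OB]))[0]
            ref = max(1.0, abs(E0))
            for el in _sampled_elements(mA, rng):
                ev = TTensorEvaluator([g.R], exp.lmax,
                                      attitudes_A=[OA @ el], attitudes_B=[OB])
                worst_group = max(worst_group, abs(exp.energy(cs, ev)[0] - E0) / ref)

    # exchange invariance for an identical pair
    co = _mol("Cinfv")
    s = SystemSpec(co, co, "identical")
    exp = Expansion(s, {"electrostatic": 5, "induction": 6, "dispersion": 6})
    cs = random_coefficients(s, exp.caps, seed=seed + 1)
    worst_exchange = 0.0
    for _ in range(10):
        g = DimerGeometry(float(rng.uniform(8.0, 25.0)),
                          EulerAngles(*rng.uniform(0, 2 * math.pi, 3)),
                          EulerAngles(*rng.uniform(0, 2 * math.pi, 3)))
        E1 = exp.energy(cs, exp.evaluator([g]))[0]
        OA2, OB2 = exchange_attitudes(g)
        E2 = exp.energy(cs, TTensorEvaluator([g.R], exp.lmax,
                                             attitudes_A=[OA2], attitudes_B=[OB2]))[0]
        worst_exchange = max(worst_exchange, abs(E1 - E2) / max(1.0, abs(E1)))

    # only the azimuth difference is physical
    s2 = SystemSpec(_mol("C2", 0.2), _mol("C2v"))
    exp2 = Expansion(s2, {"electrostatic": 5, "induction": 6, "dispersion": 6})
    cs2 = random_coefficients(s2, exp2.caps, seed=seed + 2)
    worst_azimuth = 0.0
    for _ in range(10):
        oA = rng.uniform(0, 2 * math.pi, 3)
        oB = rng.uniform(0, 2 * math.pi, 3)
        shift = float(rng.uniform(0, 2 * math.pi))
        g1 = DimerGeometry(10.0, EulerAngles(*oA), EulerAngles(*oB))
        g2 = DimerGeometry(10.0, EulerAngles(oA[0] + shift, oA[1], oA[2]),
                           EulerAngles(oB[0] + shift, oB[1], oB[2]))
        E1 = exp2.energy(cs2, exp2.evaluator([g1]))[0]
        E2 = exp2.energy(cs2, exp2.evaluator([g2]))[0]
        worst_azimuth = max(worst_azimuth, abs(E1 - E2) / max(1.0, abs(E1)))

    return {"group": worst_group, "exchange": worst_exchange, "azimuth": worst_azimuth}


# ---------------------------------------------------------------------------
# synthetic recovery campaign
# ---------------------------------------------------------------------------

#: 20 mixed-symmetry study systems with orders <= 6.  Full induction +
#: dispersion is paired with charged systems (a charge breaks the exact
#: induction/dispersion degeneracy through its low-order induction terms);
#: neutral systems exercise electrostatics + dispersion.
RECOVERY_SYSTEMS: list[tuple[tuple, tuple, str, dict]] = [
    (("Cinfv", 1.0), ("Dinfh", 0.0), "distinct", {"electrostatic": 6, "induction": 4, "dispersion": 6}),
    (("atom", -1.0), ("C2v", 0.0), "distinct", {"electrostatic": 6, "induction": 4, "dispersion": 6}),
    (("C3v", 1.0), ("Cinfv", 0.0), "distinct", {"electrostatic": 6, "induction": 4, "dispersion": 6}),
    (("Oh", 2.0), ("D3h", 0.0), "distinct", {"electrostatic": 6, "induction": 4}),
    (("Cs", 1.0), ("atom", 0.0), "distinct", {"electrostatic": 5, "induction": 4, "dispersion": 6}),
    (("Cs", 0.0), ("C2v", 0.0), "distinct", {"electrostatic": 5, "dispersion": 6}),
    (("D6h", 0.0), ("Dinfh", 0.0), "distinct", {"electrostatic": 6, "dispersion": 6}),
    (("S4", 0.0), ("Ci", 0.0), "distinct", {"electrostatic": 6, "dispersion": 6}),
    (("Td", 0.0), ("atom", 0.0), "distinct", {"dispersion": 6}),
    (("Cinfv", 0.0), ("Cinfv", 0.0), "identical", {"electrostatic": 5, "dispersion": 6}),
    (("C2", 0.0), ("C2", 0.0), "chiral_partners", {"electrostatic": 4}),
    (("C2v", 0.0), ("C2v", 0.0), "identical", {"electrostatic": 4}),
    (("Dinfh", 0.0), ("Dinfh", 0.0), "identical", {"electrostatic": 5, "dispersion": 6}),
    (("C4v", -1.0), ("atom", 0.0), "distinct", {"electrostatic": 6, "induction": 4, "dispersion": 6}),
    (("D2d", 0.0), ("Cinfv", 1.0), "distinct", {"electrostatic": 6, "induction": 4}),
    (("C3h", 0.0), ("atom", 0.0), "distinct", {"electrostatic": 0, "dispersion": 6}),
    (("T", 0.0), ("Dinfh", 0.0), "distinct", {"electrostatic": 6, "dispersion": 6}),
    (("C6", 1.0), ("Cinfv", 0.0), "distinct", {"electrostatic": 5, "induction": 4}),
    (("Ci", 0.0), ("Cinfv", 1.0), "distinct", {"electrostatic": 6, "induction": 4}),
    (("atom", 1.0), ("atom", -1.0), "distinct", {"electrostatic": 1, "induction": 4, "dispersion": 6}),
]


def _stages_capped(sys: SystemSpec, caps: dict) -> list[dict]:
    caps = {k: v for k, v in caps.items() if v > 0}
    stages = default_stages(sys, max(caps.values()))
    out: list[dict] = []
    for st in stages:
        st2 = {k: min(v, caps[k]) for k, v in st.items() if caps.get(k, 0) > 0}
        if st2 and (not out or st2 != out[-1]):
            out.append(st2)
    return out


def _fit_one(sys: SystemSpec, caps: dict, seed: int, n_mult: int,
             noise_sigma: float = 0.0):
    caps = {k: v for k, v in caps.items() if v > 0}
    truth = random_coefficients(sys, caps, seed=seed)
    synth = SyntheticModel(sys, truth, caps, seed)
    exp = Expansion(sys, caps)
    plan = FitPlan(stages=_stages_capped(sys, caps), seed=seed)
    par = _Parametrization(exp, plan)
    data = synthetic_dataset(synth, n_mult * max(par.n_free, 3), noise_sigma=noise_sigma)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = LongRangeModel(data, sys, plan)
        res = model.fit()
    return res, truth, model, plan


def recovery_study(seed: int = 0, n_mult: int = 8,
                   systems=None) -> dict:
    """Noiseless ground-truth recovery over the mixed-symmetry study set.

    Returns the pooled per-parameter relative errors (median/max), the
    total parameter count, and whether every staged RMSE history was
    non-increasing.
    """
    systems = systems if systems is not None else RECOVERY_SYSTEMS
    errs: list[float] = []
    monotone = True
    n_params = 0
    rmse_rel = []
    for i, ((pgA, qA), (pgB, qB), rel, caps) in enumerate(systems):
        sys = SystemSpec(_mol(pgA, qA, "A"), _mol(pgB, qB, "B"), rel)
        res, truth, model, plan = _fit_one(sys, caps, seed=seed * 1009 + i, n_mult=n_mult)
        est = gauge_align(model.expansion, res.coefficients, truth, plan)
        for key in model.expansion.parameter_keys:
            tv = model.expansion.get_entry(truth, key)
            ev = model.expansion.get_entry(est, key)
            if abs(tv) > 1e-12:
                errs.append(abs(ev - tv) / abs(tv))
        n_params += len(model.expansion.parameter_keys)
        rmses = [h["rmse"] for h in res.history]
        monotone &= all(rmses[j + 1] <= rmses[j] * (1 + 1e-9) for j in range(len(rmses) - 1))
        scale = float(np.std(model.data.energies)) or 1.0
        rmse_rel.append(res.rmse / scale)
    return {
        "median_rel_err": float(np.median(errs)),
        "max_rel_err": float(np.max(errs)),
        "n_parameters": n_params,
        "n_systems": len(systems),
        "rmse_monotone": bool(monotone),
        "max_relative_rmse": float(np.max(rmse_rel)),
    }


def noise_recovery(seed: int = 0, sigma: float = 1e-9, n_mult: int = 40) -> float:
    """Final RMSE over the injected noise level for a noisy synthetic fit."""
    sys = SystemSpec(_mol("C2v"), _mol("Cinfv"))
    res, *_ = _fit_one(sys, {"electrostatic": 5}, seed=seed + 5, n_mult=n_mult,
                       noise_sigma=sigma)
    return float(res.rmse / sigma)
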