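"""Staged nonlinear least-squares fitting of the expansion coefficients.

The public surface follows the statsmodels convention: a
:class:`LongRangeModel` is built from a :class:`~lrfit.data_io.Dataset`,
a :class:`~lrfit.symmetry.SystemSpec` and a :class:`FitPlan`; its
:meth:`~LongRangeModel.fit` returns a :class:`LongRangeResults` carrying
the coefficient estimates, the per-stage statistics table, residual
diagnostics and a ``summary()``.  The classic function forms
(:func:`initialize_fit`, :func:`fit_orders`, :func:`fit_statistics`,
:func:`detect_outliers`, :func:`residual_histogram`) are thin wrappers.

Strategy: the asymptote and the lumped coefficient products of the two
leading orders are first estimated linearly on the far-range portion of
the data; the expansion terms are then introduced order by order, each
stage warm-started from the previous optimum (so the training RMSE never
increases) and minimized by Levenberg-Marquardt-type least squares with
analytic Jacobians.  Fixed coefficients and identical/chiral-partner
exchange constraints are eliminated exactly from the free-parameter
vector, not penalized.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional


import numpy as np
from scipy.optimize import least_squares

from .data_io import Dataset
from .expansion import CoefficientSet, Expansion
from .symmetry import SystemSpec, exchange_constraints
from .tensor_core import rep_matrix_real
from .symmetry import _SIG_XZ  # xz mirror relating chiral partners

__all__ = [
    "FitPlan",
    "LongRangeModel",
    "LongRangeResults",
    "FitResult",
    "initialize_fit",
    "fit_orders",
    "fit_statistics",
    "detect_outliers",
    "residual_histogram",
    "gauge_fix",
    "gauge_align",
    "default_stages",
]


def default_stages(sys: SystemSpec, max_order: int) -> list[dict]:
    """Order-by-order stage list: at each n every interaction whose
    leading order has been reached is capped at n."""
    from .symmetry import leading_order

    lead = {k: leading_order(sys, k) for k in ("electrostatic", "induction", "dispersion")}
    stages = []
    start = min([v for v in lead.values() if v is not None], default=None)
    if start is None:
        raise ValueError("system has no allowed interaction terms at all")
    for n in range(start, max_order + 1):
        caps = {}
        if lead["electrostatic"] is not None and n >= lead["electrostatic"]:
            caps["electrostatic"] = n
        if lead["induction"] is not None and n >= lead["induction"]:
            caps["induction"] = n
        if lead["dispersion"] is not None and n >= lead["dispersion"]:
            caps["dispersion"] = n
        if caps and (not stages or caps != stages[-1]):
            stages.append(caps)
    return stages


@dataclass
class FitPlan:
    """Staging, constraints and optimizer settings for one fit.

    ``stages`` is an ordered list of per-interaction caps (each a dict
    like ``{"electrostatic": 4, "induction": 4}``); ``fixed`` maps
    coefficient names (as printed by the expansion) to known values that
    are held exactly; ``far_fraction`` selects the largest-R portion of
    the data used by the linear initialization.
    """

    stages: list[dict] = field(default_factory=list)
    fixed: dict = field(default_factory=dict)
    far_fraction: float = 0.25
    ftol: float = 1e-12
    xtol: float = 1e-10
    gtol: float = 1e-14
    max_iter: int = 2000
    seed: int = 0

    def __post_init__(self):
        if not self.stages:
            return
        prev: dict = {}
        for st in self.stages:
            inc = any(st.get(k, 0) > prev.get(k, 0) for k in
                      ("electrostatic", "induction", "dispersion"))
            if prev and not inc:
                raise ValueError("stages must strictly increase in at least one cap")
            prev = st


# ---------------------------------------------------------------------------
# free-parameter mapping (fixed values + exchange ties)
# ---------------------------------------------------------------------------

class _Parametrization:
    """theta_full = Phi theta_free + offset over the expansion's entries.

    For identical partners every B-side multipole/polarizability entry is
    tied to its A-side twin and dispersion entries are symmetrized under
    the molecule swap; for chiral partners the tie goes through the
    numeric image of the xz mirror.  Fixed coefficients become offsets.
    """

    def __init__(self, exp: Expansion, plan: FitPlan):
        self.exp = exp
        self.plan = plan
        sys = exp.sys
        name_of = exp.parameter_name
        keys = list(exp.parameter_keys)
        fixed = dict(plan.fixed)
        known_names = {name_of(k) for k in keys}
        for nm in fixed:
            if nm not in known_names:
                raise ValueError(f"fixed coefficient {nm!r} is not a parameter "
                                 f"of this expansion")

        rows: dict[tuple, list] = {}      # key -> [(free_index, coeff), ...]
        offsets: dict[tuple, float] = {}
        self.free_keys: list = []         # label objects for free params
        index: dict = {}

        def free_index(label):
            if label not in index:
                index[label] = len(self.free_keys)
                self.free_keys.append(label)
            return index[label]

        tied = sys.relation in ("identical", "chiral_partners")
        if tied:
            qmaps = exchange_constraints(sys, max(
                [l for (_, _, l, _) in exp.q_param_keys] + [0]))
            amaps = self._alpha_maps(exp) if sys.relation == "chiral_partners" else None

        for key in keys:
            name = name_of(key)
            if name in fixed:
                offsets[key] = float(fixed[name])
                rows[key] = []
                continue
            if key == ("easym",) or not tied:
                rows[key] = [(free_index(key), 1.0)]
                continue
            kind = key[0]
            if kind == "Q":
                _, mol, l, i = key
                if mol == "A":
                    rows[key] = [(free_index(key), 1.0)]
                else:
                    W = qmaps.rank_maps[l]
                    r = []
                    for j in range(W.shape[1]):
                        if abs(W[i, j]) > 1e-12:
                            akey = ("Q", "A", l, j)
                            if name_of(akey) in fixed:
                                offsets[key] = offsets.get(key, 0.0) + W[i, j] * float(fixed[name_of(akey)])
                            else:
                                r.append((free_index(akey), float(W[i, j])))
                    rows[key] = r
            elif kind == "alpha":
                _, mol, blk, p = key
                if mol == "A":
                    rows[key] = [(free_index(key), 1.0)]
                else:
                    if sys.relation == "identical":
                        rows[key] = [(free_index(("alpha", "A", blk, p)), 1.0)]
                    else:
                        Wa = amaps[blk]
                        rows[key] = [(free_index(("alpha", "A", blk, q)), float(Wa[p, q]))
                                     for q in range(Wa.shape[1]) if abs(Wa[p, q]) > 1e-12]
            else:  # dispersion: handled jointly below
                rows[key] = None
        if tied:
            self._tie_dispersion(exp, rows, free_index)
        else:
            for key in exp.d_param_keys:
                if rows.get(key) is None:
                    rows[key] = [(free_index(key), 1.0)]

        self.rows = rows
        self.offsets = offsets
        nfree = len(self.free_keys)
        self.Phi = np.zeros((len(keys), nfree))
        self.offset_vec = np.zeros(len(keys))
        self.keys = keys
        for r, key in enumerate(keys):
            self.offset_vec[r] = offsets.get(key, 0.0)
            for (c, w) in rows[key] or []:
                self.Phi[r, c] = w

    @staticmethod
    def _alpha_maps(exp: Expansion) -> dict:
        """Pattern-coordinate image of the xz mirror per alpha block."""
        maps = {}
        for blk, pats in exp.pol["A"].items():
            l1, l2 = blk
            S1 = rep_matrix_real(l1, _SIG_XZ)
            S2 = rep_matrix_real(l2, _SIG_XZ)
            n = len(pats)
            W = np.zeros((n, n))
            for p, P in enumerate(pats):
                img = S1 @ P @ S2.T
                for q, Q in enumerate(pats):
                    W[q, p] = float(np.sum(Q * img))
                resid = img - sum(W[q, p] * pats[q] for q in range(n))
                if float(np.max(np.abs(resid))) > 1e-8:
                    raise RuntimeError(f"xz mirror does not preserve alpha block {blk}")
            maps[blk] = W
        return maps

    def _tie_dispersion(self, exp: Expansion, rows, free_index):
        """Free dispersion coordinates = +1 eigenspace of the exchange map."""
        dkeys = [k for k in exp.d_param_keys]
        if not dkeys:
            return
        pos = {k: i for i, k in enumerate(dkeys)}
        nd = len(dkeys)
        T = np.zeros((nd, nd))
        chiral = exp.sys.relation == "chiral_partners"
        amapsA = self._alpha_maps(exp) if chiral else None

        for k in dkeys:
            _, Lb, p, Kb, q, pr = k
            # molecule swap: (A pattern) <-> (B pattern), pairing preserved
            img_key_base = ("D", Kb, q, Lb, p, pr)
            if not chiral:
                if img_key_base in pos:
                    T[pos[img_key_base], pos[k]] += 1.0
                else:
                    raise RuntimeError(f"dispersion exchange image of {k} missing")
            else:
                WA = amapsA[Lb]
                WB = amapsA[Kb]
                for p2 in range(WA.shape[0]):
                    for q2 in range(WB.shape[0]):
                        w = WA[p2, p] * WB[q2, q]
                        if abs(w) > 1e-12:
                            kk = ("D", Kb, q2, Lb, p2, pr)
                            T[pos[kk], pos[k]] += w
        # symmetric subspace basis
        P = 0.5 * (np.eye(nd) + T)
        from .symmetry import _column_space

        V = _column_space(P @ P.T if not np.allclose(P, P.T) else P)
        for j in range(V.shape[1]):
            free_index(("Dsym", j))
        for k in dkeys:
            if rows.get(k) is None:
                r = []
                for j in range(V.shape[1]):
                    w = V[pos[k], j]
                    if abs(w) > 1e-12:
                        r.append((free_index(("Dsym", j)), float(w)))
                rows[k] = r
        self._dsym_basis = V
        self._dkeys = dkeys

    @property
    def n_free(self) -> int:
        return len(self.free_keys)

    def to_coefficients(self, theta: np.ndarray) -> CoefficientSet:
        full = self.Phi @ theta + self.offset_vec
        cs = self.exp.zero_coefficients()
        for val, key in zip(full, self.keys):
            self.exp.set_entry(cs, key, float(val))
        return cs

    def from_coefficients(self, cs: CoefficientSet) -> np.ndarray:
        """Project a coefficient set onto the free parameters (least squares,
        exact when the set satisfies the constraints)."""
        full = np.array([self.exp.get_entry(cs, k) for k in self.keys])
        theta, *_ = np.linalg.lstsq(self.Phi, full - self.offset_vec, rcond=None)
        return theta

    def jacobian(self, grads: dict) -> np.ndarray:
        """(n_points, n_free) from per-entry gradients via the chain rule."""
        n = next(iter(grads.values())).shape[0]
        J = np.zeros((n, self.n_free))
        for r, key in enumerate(self.keys):
            g = grads.get(key)
            if g is None:
                continue
            for (c, w) in self.rows[key] or []:
                J[:, c] += w * g
        return J


# ---------------------------------------------------------------------------
# statistics / diagnostics
# ---------------------------------------------------------------------------

def fit_statistics(residuals, data) -> tuple[float, Optional[float]]:
    """(RMSE, R^2) of a fit; R^2 about the data mean, None if the data
    have zero variance."""
    res = np.asarray(residuals, dtype=float)
    y = data.energies if isinstance(data, Dataset) else np.asarray(data, dtype=float)
    if res.shape[0] < 2:
        raise ValueError("fit_statistics needs at least 2 points")
    rmse = float(np.sqrt(np.mean(res**2)))
    sstot = float(np.sum((y - y.mean()) ** 2))
    if sstot == 0.0:
        return rmse, None
    return rmse, float(1.0 - np.sum(res**2) / sstot)


def _robust_residuals(result: "LongRangeResults") -> tuple[np.ndarray, float]:
    """Residuals against a trimmed least-squares reference fit.

    A gross outlier can bend the ordinary fit enough to spread its misfit
    over the innocent points; here points whose absolute residual exceeds
    6 robust sigma are excluded and the final stage refit (warm started,
    up to 3 rounds), so the offending point stands out in its own
    residual.  A no-op on clean data.
    """
    model = result.model
    exp = model.expansion
    par = _Parametrization(exp, model.plan)
    ev = exp.evaluator(model.data.geometries)
    y = model.data.energies
    scale = float(np.std(y)) or 1.0
    theta = par.from_coefficients(result.coefficients)
    n = len(y)
    keep = np.ones(n, dtype=bool)
    min_keep = max(par.n_free + 1, int(0.8 * n))
    r = exp.energy(par.to_coefficients(theta), ev) - y
    for _ in range(3):
        sig = 1.4826 * float(np.median(np.abs(r - np.median(r))))
        if sig == 0.0:
            break
        new_keep = np.abs(r - np.median(r)) <= 6.0 * sig
        if new_keep.sum() < min_keep or np.array_equal(new_keep, keep):
            break
        keep = new_keep
        sol = least_squares(
            lambda th: (exp.energy(par.to_coefficients(th), ev) - y)[keep] / scale,
            theta,
            jac=lambda th: par.jacobian(exp.gradients(par.to_coefficients(th), ev))[keep] / scale,
            method="trf", ftol=1e-12, xtol=1e-10, max_nfev=400, x_scale="jac",
        )
        theta = sol.x
        r = exp.energy(par.to_coefficients(theta), ev) - y
    cs = par.to_coefficients(theta)
    return r, cs.easym


def detect_outliers(result: "LongRangeResults", data: Optional[Dataset] = None,
                    k: float = 4.0) -> tuple[np.ndarray, list[dict]]:
    """Flag points by relative-error weighting, more sensitive at large R.

    w_i = |res_i| / max(|E_i - E_asym|, eps) with eps = 1e-3 of the
    dataset's interaction-energy scale; a point is flagged when w_i
    exceeds k times the robust scale 1.4826*MAD(w) and its relative
    residual is above 1e-6 (so numerically perfect fits flag nothing).
    Residuals are measured against a trimmed-refit reference so a gross
    outlier cannot hide by distorting the fit, and a point is only ever
    flagged when its relative residual exceeds 25% of its local
    interaction energy.  Returns (flags, report rows).
    """
    data = data if data is not None else result.data
    res, easym = _robust_residuals(result)
    E = data.energies
    inter = np.abs(E - easym)
    scale = float(np.max(inter)) if len(E) else 1.0
    eps = max(1e-3 * scale, 1e-300)
    w = np.abs(res) / np.maximum(inter, eps)
    mad = float(np.median(np.abs(w - np.median(w))))
    robust = 1.4826 * mad
    # absolute guard: residuals at the numerical-noise floor of the energy
    # scale (including the asymptote) are never outliers
    floor = 1e-8 * max(scale, abs(easym), 1e-300)
    flags = (w > max(k * robust, 0.25)) & (np.abs(res) > floor)
    report = [
        {"index": int(i), "R": float(data.geometries[i].R),
         "residual": float(res[i]), "weight": float(w[i])}
        for i in np.nonzero(flags)[0]
    ]
    return flags, report


def residual_histogram(result: "LongRangeResults", bins: int = 20):
    """Binned residual counts (counts, edges); sum(counts) = n points."""
    if bins < 1:
        raise ValueError("bins must be >= 1")
    res = np.asarray(result.residuals, dtype=float)
    return np.histogram(res, bins=bins)


# ---------------------------------------------------------------------------
# gauge handling
# ---------------------------------------------------------------------------

def _gauge_flippable(exp: Expansion, plan: Optional[FitPlan]) -> bool:
    sys = exp.sys
    if sys.molA.charge != 0.0 or sys.molB.charge != 0.0:
        return False
    if plan and any(nm.startswith("Q_") for nm in plan.fixed):
        return False
    return True


def _flip_multipoles(cs: CoefficientSet) -> None:
    for (mol, l) in cs.Q:
        if l > 0:
            cs.Q[(mol, l)] = -cs.Q[(mol, l)]


def gauge_fix(exp: Expansion, cs: CoefficientSet, plan: Optional[FitPlan] = None) -> CoefficientSet:
    """Canonical gauge: leading nonzero multipole coordinate of molecule A
    nonnegative (resolved by the joint sign flip of both molecules'
    multipoles, an exact symmetry of every observable term; applied only
    when nothing pins the sign)."""
    cs = cs.copy()
    if not _gauge_flippable(exp, plan):
        return cs
    for l in sorted(set(l for (m, l) in cs.Q if m == "A" and l > 0)):
        v = cs.Q[("A", l)]
        nz = np.nonzero(np.abs(v) > 1e-10)[0]
        if nz.size:
            if v[nz[0]] < 0:
                _flip_multipoles(cs)
            return cs
    return cs


def _scale_gauge(cs: CoefficientSet, c: float) -> CoefficientSet:
    out = cs.copy()
    for (mol, l) in out.Q:
        if l > 0:
            out.Q[(mol, l)] = out.Q[(mol, l)] * (c if mol == "A" else 1.0 / c)
    for (mol, blk) in out.alpha:
        out.alpha[(mol, blk)] = out.alpha[(mol, blk)] * (c**2 if mol == "A" else c**-2)
    return out


def gauge_align(exp: Expansion, est: CoefficientSet, truth: CoefficientSet,
                plan: Optional[FitPlan] = None) -> CoefficientSet:
    """Map ``est`` along the model's gauge orbit closest to ``truth``.

    For distinct neutral molecules with free polarizabilities the model
    has an exact one-parameter gauge (A multipoles * c, B multipoles / c,
    alpha_A * c^2, alpha_B / c^2) on top of the joint sign flip; both are
    removed here before coefficient-wise comparison.  Charged, identical,
    chiral or fixed-coefficient systems only admit the sign flip (or
    nothing), in which case only that is applied.
    """
    if not _gauge_flippable(exp, plan):
        return est.copy()
    scale_allowed = exp.sys.relation == "distinct"

    def dist(cs):
        d = 0.0
        for key in cs.Q:
            if key[1] > 0:
                ref = truth.Q.get(key, np.zeros_like(cs.Q[key]))
                d += float(np.sum((cs.Q[key] - ref) ** 2))
        for key in cs.alpha:
            ref = truth.alpha.get(key, np.zeros_like(cs.alpha[key]))
            d += float(np.sum((cs.alpha[key] - ref) ** 2))
        return d

    best, best_d = est.copy(), dist(est)
    for sign in (1.0, -1.0):
        base = est.copy()
        if sign < 0:
            _flip_multipoles(base)
        cands = [base]
        if scale_allowed:
            from scipy.optimize import minimize_scalar

            r = minimize_scalar(lambda t: dist(_scale_gauge(base, math.exp(t))),
                                bounds=(-8, 8), method="bounded",
                                options={"xatol": 1e-14})
            cands.append(_scale_gauge(base, math.exp(float(r.x))))
        for cand in cands:
            d = dist(cand)
            if d < best_d:
                best, best_d = cand, d
    return best


# ---------------------------------------------------------------------------
# model / results
# ---------------------------------------------------------------------------

class LongRangeModel:
    """Long-range expansion model over a scattered-energy dataset.

    Parameters
    ----------
    data : Dataset
        Geometries and interaction energies (internal atomic units).
    system : SystemSpec
        Point groups, charges and mutual relation of the monomers.
    plan : FitPlan, optional
        Stages, fixed coefficients, optimizer settings.  When omitted, an
        order-by-order default plan up to order 6 is built.
    """

    def __init__(self, data: Dataset, system: SystemSpec, plan: Optional[FitPlan] = None):
        if len(data) == 0:
            raise ValueError("empty dataset")
        self.data = data
        self.system = system
        if plan is None or not plan.stages:
            stages = default_stages(system, 6)
            plan = FitPlan(stages=stages) if plan is None else \
                FitPlan(stages, plan.fixed, plan.far_fraction, plan.ftol,
                        plan.xtol, plan.gtol, plan.max_iter, plan.seed)
        self.plan = plan
        self.final_caps = plan.stages[-1]
        self.expansion = Expansion(system, self.final_caps)
        self._check_duplicates()

    def _check_duplicates(self):
        seen: dict[tuple, float] = {}
        for g, e in zip(self.data.geometries, self.data.energies):
            key = (round(g.R, 12), tuple(np.round(g.omega_A.as_tuple(), 12)),
                   tuple(np.round(g.omega_B.as_tuple(), 12)))
            if key in seen and seen[key] != e:
                warnings.warn(
                    f"duplicate geometry R={g.R:.6g} with differing energies "
                    f"({seen[key]:.6g} vs {e:.6g}); both kept as data points"
                )
            seen.setdefault(key, float(e))

    # -- initialization ---------------------------------------------------

    def initialize(self) -> CoefficientSet:
        """Linear far-range estimate of the asymptote and the lumped
        coefficient products of the two leading orders."""
        data = self.data
        frac = self.plan.far_fraction
        n_far = max(3, int(math.ceil(frac * len(data))))
        if len(data) < 3:
            raise ValueError("initialization needs at least 3 points")
        order_idx = np.argsort(-data.R)
        far = data.subset(order_idx[:n_far])

        exp = self.expansion
        orders = sorted({t.order for t in exp.terms})
        lead_orders = orders[:2]
        lead_terms = [t for t in exp.terms if t.order in lead_orders]

        ev = exp.evaluator(far.geometries)
        unknowns: dict[tuple, np.ndarray] = {}
        offset = np.zeros(len(far))
        probe = exp.zero_coefficients()
        fixed_names = dict(self.plan.fixed)

        def known_value(key):
            name = exp.parameter_name(key)
            if name in fixed_names:
                return float(fixed_names[name])
            if key[0] == "Q" and key[2] == 0:
                mol = self.system.molA if key[1] == "A" else self.system.molB
                return mol.charge
            return None

        from .expansion import _term_value

        for t in lead_terms:
            roles = self._term_param_keys(t)
            unknown = tuple(sorted(k for k in roles if known_value(k) is None))
            # geometric column: term value with unknown factors set to 1
            cs1 = exp.zero_coefficients()
            for k in roles:
                v = known_value(k)
                exp.set_entry(cs1, k, 1.0 if v is None else v)
            col = _term_value(exp, cs1, t, ev)
            if not unknown:
                offset += col
            else:
                unknowns[unknown] = unknowns.get(unknown, 0.0) + col

        prods = sorted(unknowns)
        A = np.column_stack([np.ones(len(far))] + [unknowns[p] for p in prods])
        b = far.energies - offset
        sol, *_ = np.linalg.lstsq(A, b, rcond=None)

        cs = exp.zero_coefficients()
        cs.easym = float(sol[0])
        assigned: dict[tuple, float] = {}
        for val, prod in zip(sol[1:], prods):
            todo = [k for k in prod if k not in assigned]
            knownprod = float(np.prod([assigned[k] for k in prod if k in assigned])) \
                if len(todo) < len(prod) else 1.0
            if len(todo) == 0:
                continue
            if len(todo) == 1:
                if knownprod != 0.0:
                    assigned[todo[0]] = float(val) / knownprod
            elif len(todo) == 2 and knownprod != 0.0:
                v = float(val) / knownprod
                a = math.sqrt(abs(v))
                if a > 0:
                    assigned[todo[0]] = a
                    assigned[todo[1]] = v / a
            # >2 unknown factors: left at zero for the nonlinear stages
        for k, v in assigned.items():
            exp.set_entry(cs, k, v)
        for nm, v in fixed_names.items():
            for key in exp.parameter_keys:
                if exp.parameter_name(key) == nm:
                    exp.set_entry(cs, key, float(v))
        return cs

    def _term_param_keys(self, t) -> list[tuple]:
        k = t.key
        if k[0] == "elec":
            _, la, ia, lb, ib = k
            return [("Q", "A", la, ia), ("Q", "B", lb, ib)]
        if k[0] == "ind":
            _, mol, blk, p, (k1, i1), (k2, i2) = k
            src = "B" if mol == "A" else "A"
            return [("alpha", mol, blk, p), ("Q", src, k1, i1), ("Q", src, k2, i2)]
        _, Lb, p, Kb, q, pr = k
        return [("D", Lb, p, Kb, q, pr)]

    # -- staged fit -------------------------------------------------------

    def fit(self, start: Optional[CoefficientSet] = None) -> "LongRangeResults":
        data = self.data
        plan = self.plan
        current = start.copy() if start is not None else self.initialize()
        history: list[dict] = []
        statuses: list[int] = []

        # one evaluator at the final rank ceiling, shared by all stages
        ev = self.expansion.evaluator(data.geometries)
        y = data.energies
        # scale-free residuals: tolerances act on relative quantities even
        # when absolute energies are tiny (they are, in the far long range)
        scale = float(np.std(y))
        if scale == 0.0:
            scale = max(float(np.max(np.abs(y))), 1.0)

        for si, caps in enumerate(plan.stages):
            exp_s = Expansion(self.system, caps)
            par = _Parametrization(exp_s, plan)
            nfree = par.n_free
            if si == len(plan.stages) - 1 and len(data) < nfree:
                raise ValueError(
                    f"{len(data)} points cannot determine {nfree} free parameters"
                )
            if si == len(plan.stages) - 1 and len(data) < 5 * nfree:
                warnings.warn(
                    f"dataset has {len(data)} points for {nfree} free parameters; "
                    f"5-10x is recommended"
                )
            theta0 = par.from_coefficients(self._restrict(exp_s, current))

            def residual(theta, par=par, exp_s=exp_s):
                return (exp_s.energy(par.to_coefficients(theta), ev) - y) / scale

            def jac(theta, par=par, exp_s=exp_s):
                grads = exp_s.gradients(par.to_coefficients(theta), ev)
                return par.jacobian(grads) / scale

            if nfree:
                sol = least_squares(
                    residual, theta0, jac=jac, method="trf",
                    ftol=plan.ftol, xtol=plan.xtol, gtol=plan.gtol,
                    max_nfev=plan.max_iter, x_scale="jac",
                )
                theta = sol.x
                statuses.append(int(sol.status))
            else:
                theta = theta0
                statuses.append(1)
            stage_cs = par.to_coefficients(theta)
            current = self._promote(exp_s, stage_cs)
            res = residual(theta) * scale
            rmse, r2 = fit_statistics(res, data)
            lead = self._leading_values(exp_s, stage_cs)
            history.append({
                "stage": si + 1,
                "caps": dict(caps),
                "n_free": nfree,
                "rmse": rmse,
                "r2": r2,
                "converged": statuses[-1] > 0,
                "leading": lead,
            })

        current = gauge_fix(self.expansion, current, plan)
        final_res = self.expansion.energy(current, ev) - y
        result = LongRangeResults(
            model=self,
            coefficients=current,
            history=history,
            residuals=final_res,
            statuses=statuses,
        )
        flags, report = detect_outliers(result)
        result.outlier_flags = flags
        result.outlier_report = report
        return result

    def _restrict(self, exp_s: Expansion, cs_full: CoefficientSet) -> CoefficientSet:
        """Project a final-caps CoefficientSet onto a stage expansion."""
        cs = exp_s.zero_coefficients()
        cs.easym = cs_full.easym
        for key in exp_s.parameter_keys:
            if key == ("easym",):
                continue
            try:
                exp_s.set_entry(cs, key, self.expansion.get_entry(cs_full, key))
            except KeyError:
                pass
        return cs

    def _promote(self, exp_s: Expansion, cs_stage: CoefficientSet) -> CoefficientSet:
        """Embed a stage CoefficientSet into the final-caps container."""
        cs = self.expansion.zero_coefficients()
        cs.easym = cs_stage.easym
        for key in exp_s.parameter_keys:
            if key == ("easym",):
                continue
            self.expansion.set_entry(cs, key, exp_s.get_entry(cs_stage, key))
        return cs

    def _leading_values(self, exp_s: Expansion, cs: CoefficientSet, nmax: int = 4) -> dict:
        out = {}
        for key in exp_s.q_param_keys[:nmax]:
            out[exp_s.parameter_name(key)] = exp_s.get_entry(cs, key)
        return out


@dataclass
class LongRangeResults:
    """Fit results: coefficient estimates, staged statistics, diagnostics."""

    model: LongRangeModel
    coefficients: CoefficientSet
    history: list
    residuals: np.ndarray
    statuses: list
    outlier_flags: Optional[np.ndarray] = None
    outlier_report: Optional[list] = None

    @property
    def data(self) -> Dataset:
        return self.model.data

    @property
    def converged(self) -> bool:
        return all(s > 0 for s in self.statuses)

    @property
    def rmse(self) -> float:
        return self.history[-1]["rmse"]

    @property
    def r2(self) -> Optional[float]:
        return self.history[-1]["r2"]

    def history_frame(self):
        """Stage table (Fig-6 style) as a pandas DataFrame."""
        import pandas as pd

        rows = []
        for h in self.history:
            row = {
                "stage": h["stage"],
                "elec": h["caps"].get("electrostatic", 0),
                "ind": h["caps"].get("induction", 0),
                "disp": h["caps"].get("dispersion", 0),
                "n_free": h["n_free"],
                "RMSE": h["rmse"],
                "R2": h["r2"],
                "converged": h["converged"],
            }
            row.update(h["leading"])
            rows.append(row)
        return pd.DataFrame(rows)

    def predict(self, geometries) -> np.ndarray:
        exp = self.model.expansion
        ev = exp.evaluator(list(geometries))
        return exp.energy(self.coefficients, ev)

    def summary(self) -> str:
        sys = self.model.system
        lines = [
            "Long-range expansion fit",
            "=" * 60,
            f"molecule A : {sys.molA.name} ({sys.molA.point_group}, q={sys.molA.charge:+g})",
            f"molecule B : {sys.molB.name} ({sys.molB.point_group}, q={sys.molB.charge:+g})",
            f"relation   : {sys.relation}",
            f"points     : {len(self.data)}",
            f"stages     : {len(self.history)}",
            "",
            self.history_frame().to_string(index=False, float_format=lambda v: f"{v:.6g}"),
            "",
            f"E_asym = {self.coefficients.easym:.10g} hartree",
            f"final RMSE = {self.rmse:.6g} hartree"
            + (f", R^2 = {self.r2:.8g}" if self.r2 is not None else ""),
            f"outliers flagged: {int(np.sum(self.outlier_flags)) if self.outlier_flags is not None else 0}",
        ]
        return "\n".join(lines)


#: spec-facing alias
FitResult = LongRangeResults


def initialize_fit(data: Dataset, sys: SystemSpec, plan: FitPlan) -> CoefficientSet:
    """Far-range linear initialization (asymptote + two leading orders)."""
    return LongRangeModel(data, sys, plan).initialize()


def fit_orders(data: Dataset, sys: SystemSpec, plan: FitPlan) -> LongRangeResults:
    """Run the staged fit of the plan and return the results object."""
    return LongRangeModel(data, sys, plan).fit()
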