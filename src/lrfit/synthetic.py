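"""Synthetic models, datasets and symmetric point-charge oracles.

Every other part of the package is testable without external data:
:func:`random_coefficients` draws a ground-truth :class:`CoefficientSet`
respecting all symmetry and exchange constraints of a system,
:func:`synthetic_dataset` samples scattered geometries and evaluates the
forward model (optionally with Gaussian noise), and
:func:`symmetric_point_charge_model` builds charge distributions exactly
invariant under a point group for use with the Coulomb oracle.

Default study conditions mirror typical long-range fitting campaigns:
center-of-mass separations of roughly 10-30 angstrom (20-60 bohr),
orientations uniform on the sphere (uniform in cos beta), and coefficient
magnitudes decaying as 2^-l with rank so that leading terms dominate
realistically.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .data_io import Dataset
from .expansion import CoefficientSet, Expansion
from .symmetry import MoleculeSpec, SystemSpec, group_closure, _generators
from .tensor_core import AtomSite, DimerGeometry, EulerAngles

__all__ = [
    "SyntheticModel",
    "random_coefficients",
    "synthetic_dataset",
    "symmetric_point_charge_model",
    "random_geometries",
    "DEFAULT_R_RANGE",
]

#: default long-range window, bohr (about 10-30 angstrom)
DEFAULT_R_RANGE = (20.0, 60.0)


@dataclass
class SyntheticModel:
    """Ground truth for recovery experiments: system + known coefficients."""

    sys: SystemSpec
    coeffs: CoefficientSet
    caps: dict
    seed: int

    @property
    def expansion(self) -> Expansion:
        return Expansion(self.sys, self.caps)


def _rank_scale(l: int) -> float:
    return 0.5**l


def random_coefficients(sys: SystemSpec, caps: dict, seed: int = 0,
                        easym_scale: float = 1e-4) -> CoefficientSet:
    """Draw a symmetry-respecting random CoefficientSet.

    Magnitudes decay as 2^-l per rank (and 2^-(l1+l2) per polarizability
    block) so that leading terms dominate; diagonal-type polarizability
    and dispersion entries are drawn positive (physically the static
    response is positive definite).  Identical/chiral-partner constraints
    are applied through the same parametrization the fitter uses, so the
    truth always lies in the feasible set.
    """
    from .fitting import FitPlan, _Parametrization

    exp = Expansion(sys, caps)
    rng = np.random.default_rng(seed)
    par = _Parametrization(exp, FitPlan(stages=[dict(caps)]))
    theta = np.zeros(par.n_free)
    for i, label in enumerate(par.free_keys):
        if label == ("easym",):
            theta[i] = easym_scale * rng.normal()
        elif label[0] == "Q":
            theta[i] = _rank_scale(label[2]) * rng.normal()
        elif label[0] == "alpha":
            l1, l2 = label[2]
            v = _rank_scale(l1 + l2) * rng.normal()
            theta[i] = abs(v) if l1 == l2 else v
        else:  # dispersion coordinates
            theta[i] = abs(rng.normal())
    cs = par.to_coefficients(theta)
    # rescale dispersion blocks by their rank decay
    for (Lb, Kb, pr) in list(cs.D):
        cs.D[(Lb, Kb, pr)] *= _rank_scale(sum(Lb) + sum(Kb))
    cs.meta["seed"] = seed
    return cs


def random_geometries(sys: SystemSpec, n: int, R_range=DEFAULT_R_RANGE,
                      seed: int = 0) -> list[DimerGeometry]:
    """Scattered geometries: R uniform, orientations unbiased on the sphere
    (beta sampled uniformly in cos beta), only the free angle subset."""
    rng = np.random.default_rng(seed)
    free = set(sys.free_angles)
    geoms = []
    for _ in range(n):
        R = rng.uniform(*R_range)
        a = rng.uniform(0, 2 * math.pi) if "alpha" in free else 0.0
        bA = math.acos(rng.uniform(-1, 1)) if "beta_A" in free else 0.0
        bB = math.acos(rng.uniform(-1, 1)) if "beta_B" in free else 0.0
        gA = rng.uniform(0, 2 * math.pi) if "gamma_A" in free else 0.0
        gB = rng.uniform(0, 2 * math.pi) if "gamma_B" in free else 0.0
        geoms.append(DimerGeometry(R, EulerAngles(a, bA, gA), EulerAngles(0.0, bB, gB)))
    return geoms


def synthetic_dataset(model: SyntheticModel, n: int, R_range=DEFAULT_R_RANGE,
                      noise_sigma: float = 0.0, seed: Optional[int] = None) -> Dataset:
    """Forward-model energies at scattered geometries, plus N(0, sigma) noise."""
    if n < 1:
        raise ValueError("n must be >= 1")
    seed = model.seed if seed is None else seed
    rng = np.random.default_rng(seed + 1)
    geoms = random_geometries(model.sys, n, R_range, seed)
    exp = model.expansion
    E = exp.energy(model.coeffs, exp.evaluator(geoms))
    if noise_sigma > 0:
        E = E + noise_sigma * rng.standard_normal(n)
    return Dataset(tuple(geoms), E, provenance=f"synthetic(seed={seed}, sigma={noise_sigma})")


def symmetric_point_charge_model(group, n_sites: int = 3, seed: int = 0,
                                 spread: float = 1.0) -> list[AtomSite]:
    """Random point charges symmetrized over a point group (orbit sums).

    ``group`` is a MoleculeSpec or a point-group label.  The returned
    distribution is exactly invariant under every group element; for the
    continuous axial groups charges are placed on the z axis (with the
    +/-z image for Dinfh), and an atom is a single site at the origin.
    """
    spec = group if isinstance(group, MoleculeSpec) else MoleculeSpec("pcm", group)
    rng = np.random.default_rng(seed)
    if spec.family == "atom":
        return [AtomSite(float(rng.normal()), (0.0, 0.0, 0.0))]
    if spec.family in ("Cinfv", "Dinfh"):
        sites = []
        for _ in range(n_sites):
            q = float(rng.normal())
            z = float(rng.uniform(0.2, spread))
            sites.append(AtomSite(q, (0.0, 0.0, z)))
            if spec.family == "Dinfh":
                sites.append(AtomSite(q, (0.0, 0.0, -z)))
        return sites
    elems = group_closure(_generators(spec.family, spec.axis_order))
    sites = []
    for _ in range(n_sites):
        q = float(rng.normal())
        p = rng.uniform(-spread, spread, size=3)
        for g in elems:
            sites.append(AtomSite(q, tuple(g @ p)))
    return sites
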