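"""Angular-momentum machinery and spherical interaction (T) tensors.

The long-range interaction between two rigid charge distributions A and B is
expanded in real spherical multipole components.  All distance and
orientation dependence of a multipole--multipole coupling is carried by a
purely geometric interaction tensor

    T^{(la,lb)}_{ta,tb}(R, Omega_A, Omega_B)  ~  R^-(la+lb+1),

assembled from a Wigner 3-j coupling along the dimer axis and two Wigner
rotation matrices (one per molecule).  This module provides

* :class:`ComponentLabel` -- Stone-style real component labels (l, m, c/s);
* regular real solid harmonics and point-charge multipole sums;
* Wigner 3-j symbols and real-basis Wigner rotation matrices;
* a direct, literal T-tensor evaluation (:func:`t_tensor_direct`) and a
  cached/vectorized production path (:func:`t_tensor`,
  :class:`TTensorEvaluator`) that must agree with it;
* an exact pairwise Coulomb sum over point charges
  (:func:`coulomb_oracle`) used as the validation oracle for the series.

Conventions
-----------
Real components follow 10 -> z, 11c -> x, 11s -> y:  the real pair for
m >= 1 is  Q_lmc = ((-1)^m Q_{l,m} + Q_{l,-m})/sqrt(2)  and
Q_lms = ((-1)^m Q_{l,m} - Q_{l,-m})/(i sqrt(2))  with Condon--Shortley
complex harmonics.  Euler angles are z-y-z; the attitude matrix
O(alpha,beta,gamma) = Rz(alpha) Ry(beta) Rz(gamma) maps molecule-fixed to
dimer-fixed coordinates.  Atomic units throughout (4 pi eps0 = 1).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Iterable, Sequence

import numpy as np
from scipy.spatial.transform import Rotation as _ScipyRotation

__all__ = [
    "ComponentLabel",
    "EulerAngles",
    "DimerGeometry",
    "AtomSite",
    "labels_for_rank",
    "wigner3j",
    "real_solid_harmonic",
    "multipole_of_point_charges",
    "rotation_matrix_real",
    "rep_matrix_real",
    "t_tensor_direct",
    "t_tensor_direct_matrix",
    "t_tensor",
    "t_tensor_matrix",
    "TTensorEvaluator",
    "coulomb_oracle",
    "attitude_matrix",
    "euler_from_matrix",
    "exchange_attitudes",
]

MAX_RANK = 15


# ---------------------------------------------------------------------------
# labels and elementary data types
# ---------------------------------------------------------------------------

@dataclass(frozen=True, order=True)
class ComponentLabel:
    """One real spherical multipole component t = (l, m, c/s).

    ``phase`` is ``""`` for m = 0, ``"c"`` (cosine) or ``"s"`` (sine) for
    m >= 1.  The 2l+1 components of rank l are ordered
    l0, l1c, l1s, l2c, l2s, ...
    """

    l: int
    m: int
    phase: str = ""

    def __post_init__(self):
        if not (0 <= self.l <= MAX_RANK):
            raise ValueError(f"rank l={self.l} outside 0..{MAX_RANK}")
        if not (0 <= self.m <= self.l):
            raise ValueError(f"m={self.m} outside 0..l={self.l}")
        if self.m == 0 and self.phase != "":
            raise ValueError("m=0 carries no c/s phase")
        if self.m > 0 and self.phase not in ("c", "s"):
            raise ValueError("m>=1 requires phase 'c' or 's'")

    @property
    def index(self) -> int:
        """Position within the rank-l component vector."""
        if self.m == 0:
            return 0
        return 2 * self.m - 1 + (1 if self.phase == "s" else 0)

    @classmethod
    def parse(cls, text: str) -> "ComponentLabel":
        """Parse a Stone label like ``"00"``, ``"21c"`` or ``"11s"``."""
        t = text.strip()
        phase = ""
        if t and t[-1] in "cs":
            phase, t = t[-1], t[:-1]
        if len(t) < 2:
            raise ValueError(f"bad component label {text!r}")
        # rank may be two digits (10..15); m is the trailing digit(s)
        for split in (1, 2):
            try:
                l, m = int(t[:split]), int(t[split:])
            except ValueError:
                continue
            if 0 <= m <= l <= MAX_RANK and (phase != "" or m == 0) and (m > 0 or phase == ""):
                return cls(l, m, phase)
        raise ValueError(f"bad component label {text!r}")

    def __str__(self) -> str:
        return f"{self.l}{self.m}{self.phase}"


def labels_for_rank(l: int) -> list[ComponentLabel]:
    out = [ComponentLabel(l, 0)]
    for m in range(1, l + 1):
        out.append(ComponentLabel(l, m, "c"))
        out.append(ComponentLabel(l, m, "s"))
    return out


@dataclass(frozen=True)
class EulerAngles:
    """z-y-z Euler angles in radians; beta in [0, pi]."""

    alpha: float = 0.0
    beta: float = 0.0
    gamma: float = 0.0

    def as_tuple(self):
        return (self.alpha, self.beta, self.gamma)


@dataclass(frozen=True)
class DimerGeometry:
    """Center-of-mass separation R (bohr) plus the two monomer orientations.

    Unused angles for the system's dimensionality class are stored as 0;
    only the azimuth difference alpha_A - alpha_B is physical.
    """

    R: float
    omega_A: EulerAngles = EulerAngles()
    omega_B: EulerAngles = EulerAngles()

    def __post_init__(self):
        if not self.R > 0:
            raise ValueError(f"R must be positive, got {self.R}")


@dataclass(frozen=True)
class AtomSite:
    """A point charge (in e) at a molecule-fixed position (bohr)."""

    charge: float
    position: tuple[float, float, float]

    def __post_init__(self):
        if not np.all(np.isfinite(self.position)) or not np.isfinite(self.charge):
            raise ValueError("AtomSite requires finite charge and coordinates")


# ---------------------------------------------------------------------------
# Wigner 3-j
# ---------------------------------------------------------------------------

@lru_cache(maxsize=None)
def _wigner3j_cached(j1, j2, j3, m1, m2, m3) -> float:
    from sympy.physics.wigner import wigner_3j

    return float(wigner_3j(j1, j2, j3, m1, m2, m3))


def wigner3j(j1: int, j2: int, j3: int, m1: int, m2: int, m3: int) -> float:
    """Wigner 3-j symbol (j1 j2 j3; m1 m2 m3) as a float.

    Returns 0 for violated selection rules (m1+m2+m3 != 0 or broken
    triangle inequality); raises for negative angular momenta.
    """
    for j in (j1, j2, j3):
        if j < 0:
            raise ValueError("negative angular momentum in wigner3j")
    if m1 + m2 + m3 != 0:
        return 0.0
    if abs(m1) > j1 or abs(m2) > j2 or abs(m3) > j3:
        return 0.0
    if j3 < abs(j1 - j2) or j3 > j1 + j2:
        return 0.0
    return _wigner3j_cached(int(j1), int(j2), int(j3), int(m1), int(m2), int(m3))


# ---------------------------------------------------------------------------
# real/complex basis transform and solid harmonics
# ---------------------------------------------------------------------------

@lru_cache(maxsize=None)
def _complex_from_real(l: int) -> np.ndarray:
    """Unitary matrix C with  Q_complex[m] = sum_t C[m, t] q_real[t].

    Rows are ordered m = -l..l, columns follow :func:`labels_for_rank`.
    """
    dim = 2 * l + 1
    C = np.zeros((dim, dim), dtype=complex)
    C[l, 0] = 1.0  # m = 0
    inv_sqrt2 = 1.0 / math.sqrt(2.0)
    for m in range(1, l + 1):
        ic = 2 * m - 1
        isn = 2 * m
        sign = (-1) ** m
        C[l + m, ic] = sign * inv_sqrt2
        C[l + m, isn] = sign * 1j * inv_sqrt2
        C[l - m, ic] = inv_sqrt2
        C[l - m, isn] = -1j * inv_sqrt2
    return C


def _complex_solid_harmonics(l: int, xyz: np.ndarray) -> np.ndarray:
    """Racah-normalized regular solid harmonics r^l C_lm, rows m=-l..l.

    ``xyz`` has shape (..., 3); the result has shape (2l+1, ...).
    """
    from scipy.special import sph_harm_y

    xyz = np.asarray(xyz, dtype=float)
    x, y, z = xyz[..., 0], xyz[..., 1], xyz[..., 2]
    r = np.sqrt(x * x + y * y + z * z)
    out = np.zeros((2 * l + 1,) + r.shape, dtype=complex)
    if l == 0:
        out[0] = 1.0
        return out
    with np.errstate(invalid="ignore", divide="ignore"):
        theta = np.where(r > 0, np.arccos(np.clip(np.divide(z, np.where(r > 0, r, 1.0)), -1, 1)), 0.0)
    phi = np.arctan2(y, x)
    ms = np.arange(-l, l + 1)
    norm = math.sqrt(4.0 * math.pi / (2 * l + 1))
    for i, m in enumerate(ms):
        ylm = sph_harm_y(l, m, theta, phi)
        out[i] = np.where(r > 0, r**l, 0.0) * norm * ylm
    return out


def _real_solid_harmonics(l: int, xyz: np.ndarray) -> np.ndarray:
    """All 2l+1 real regular solid harmonics, rows ordered as labels_for_rank."""
    C = _complex_from_real(l)
    cplx = _complex_solid_harmonics(l, xyz)
    # q_real = C^dagger Q_complex  (unitary transform)
    real = np.tensordot(C.conj().T, cplx, axes=(1, 0))
    return np.ascontiguousarray(real.real)


def real_solid_harmonic(label: ComponentLabel, position) -> float:
    """Regular real solid harmonic S_t(r) = r^l sqrt(4pi/(2l+1)) Y_t(r).

    Homogeneous of degree l; S_00 = 1, S_10 = z, S_11c = x, S_11s = y,
    S_20 = (3z^2 - r^2)/2, ...
    """
    vals = _real_solid_harmonics(label.l, np.asarray(position, dtype=float))
    return float(vals[label.index])


def multipole_of_point_charges(sites: Sequence[AtomSite], label: ComponentLabel) -> float:
    """Charge-weighted sum of solid harmonics: the real multipole Q_t.

    For label 00 this is the total charge of the distribution.
    """
    sites = list(sites)
    if not sites:
        raise ValueError("multipole_of_point_charges needs at least one site")
    pos = np.array([s.position for s in sites], dtype=float)
    q = np.array([s.charge for s in sites], dtype=float)
    vals = _real_solid_harmonics(label.l, pos)  # (2l+1, nsites)
    return float(np.dot(q, vals[label.index]))


# ---------------------------------------------------------------------------
# rotations
# ---------------------------------------------------------------------------

def _rot_z(a: float) -> np.ndarray:
    c, s = math.cos(a), math.sin(a)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def _rot_y(b: float) -> np.ndarray:
    c, s = math.cos(b), math.sin(b)
    return np.array([[c, 0.0, s], [0.0, 1.0, 0.0], [-s, 0.0, c]])


def attitude_matrix(omega: EulerAngles) -> np.ndarray:
    """O = Rz(alpha) Ry(beta) Rz(gamma): molecule-fixed -> dimer-fixed."""
    return _rot_z(omega.alpha) @ _rot_y(omega.beta) @ _rot_z(omega.gamma)


def euler_from_matrix(mat: np.ndarray) -> EulerAngles:
    """Inverse of :func:`attitude_matrix` (proper rotations only)."""
    if np.linalg.det(mat) < 0:
        raise ValueError("euler_from_matrix requires a proper rotation")
    a, b, c = _ScipyRotation.from_matrix(np.asarray(mat, dtype=float)).as_euler("ZYZ")
    return EulerAngles(a % (2 * math.pi), abs(b) if b >= 0 else -b, c % (2 * math.pi))


def _factorials(n: int) -> np.ndarray:
    out = np.ones(n + 1)
    for i in range(2, n + 1):
        out[i] = out[i - 1] * i
    return out


_FACT = _factorials(4 * MAX_RANK + 2)


def _small_d(l: int, beta: np.ndarray) -> np.ndarray:
    """Wigner small-d matrices d^l_{m', m}(beta), shape (..., 2l+1, 2l+1)."""
    beta = np.asarray(beta, dtype=float)
    half = beta / 2.0
    cb, sb = np.cos(half), np.sin(half)
    dim = 2 * l + 1
    out = np.zeros(beta.shape + (dim, dim))
    for mp in range(-l, l + 1):
        for m in range(-l, l + 1):
            pref = math.sqrt(
                _FACT[l + mp] * _FACT[l - mp] * _FACT[l + m] * _FACT[l - m]
            )
            acc = np.zeros_like(beta)
            for s in range(max(0, m - mp), min(l + m, l - mp) + 1):
                denom = (
                    _FACT[l + m - s] * _FACT[s] * _FACT[mp - m + s] * _FACT[l - mp - s]
                )
                term = ((-1.0) ** (mp - m + s) / denom) * cb ** (
                    2 * l + m - mp - 2 * s
                ) * sb ** (mp - m + 2 * s)
                acc = acc + term
            out[..., mp + l, m + l] = pref * acc
    return out


def _wigner_D(l: int, alpha, beta, gamma) -> np.ndarray:
    """Complex Wigner D^l_{m' m}(alpha, beta, gamma), z-y-z, shape (..., 2l+1, 2l+1)."""
    alpha = np.asarray(alpha, dtype=float)
    beta = np.asarray(beta, dtype=float)
    gamma = np.asarray(gamma, dtype=float)
    d = _small_d(l, beta)
    ms = np.arange(-l, l + 1)
    ea = np.exp(-1j * alpha[..., None] * ms)  # (..., 2l+1) over m'
    eg = np.exp(-1j * gamma[..., None] * ms)  # over m
    return ea[..., :, None] * d * eg[..., None, :]


def _real_rotation_from_D(l: int, D: np.ndarray) -> np.ndarray:
    """Transform a complex D-matrix stack to the real component basis."""
    C = _complex_from_real(l)
    M = np.einsum("mt,...mn,nu->...tu", C.conj(), D.conj(), C)
    imag = float(np.max(np.abs(M.imag))) if M.size else 0.0
    if imag > 1e-9:
        raise AssertionError(f"real rotation matrix not real: imag={imag:.3e}")
    return np.ascontiguousarray(M.real)


def rotation_matrix_real(l: int, omega: EulerAngles) -> np.ndarray:
    """Real-basis Wigner rotation matrix for rank l.

    Satisfies q_DF = M q_MF for a molecule with attitude
    O = Rz(alpha) Ry(beta) Rz(gamma); orthogonal; identity at zero angles;
    at l = 1 it is the Cartesian rotation matrix in (z, x, y) ordering.
    """
    if l < 0:
        raise ValueError("l must be >= 0")
    D = _wigner_D(l, omega.alpha, omega.beta, omega.gamma)
    return _real_rotation_from_D(l, D)


@lru_cache(maxsize=4096)
def _rep_matrix_cached(l: int, key: bytes) -> np.ndarray:
    g = np.frombuffer(key, dtype=float).reshape(3, 3)
    rng = np.random.default_rng(20240517 + l)
    pts = rng.standard_normal((4 * l + 16, 3))
    # unit sphere keeps the polynomial solve well conditioned (S_l is
    # homogeneous, and orthogonal g preserves the norm)
    pts /= np.linalg.norm(pts, axis=1, keepdims=True)
    S = _real_solid_harmonics(l, pts)            # (2l+1, npts)
    Sg = _real_solid_harmonics(l, pts @ g.T)     # values at g p
    M, *_ = np.linalg.lstsq(S.T, Sg.T, rcond=None)
    return M.T  # rows t: S_t(g p) = sum_s M[t, s] S_s(p)


def rep_matrix_real(l: int, g: np.ndarray) -> np.ndarray:
    """Representation of an arbitrary orthogonal 3x3 matrix g on rank-l
    real components: multipoles of the transformed distribution are
    q' = M(g) q.  Handles improper operations (the (-1)^l parity factor
    emerges automatically from the solid-harmonic solve)."""
    g = np.asarray(g, dtype=float)
    return _rep_matrix_cached(l, np.round(g, 12).tobytes())


# ---------------------------------------------------------------------------
# T-tensors
# ---------------------------------------------------------------------------

@lru_cache(maxsize=None)
def _x_real(la: int, lb: int) -> np.ndarray:
    """Dimer-frame real interaction matrix X (without the R power).

    In the dimer-fixed frame the irregular harmonic along +z keeps only
    m_a' + m_b' = 0, so X is assembled from the single-m coupling
    x_m = (-1)^la sqrt((2la+2lb+1)!/((2la)!(2lb)!)) * 3j(la lb la+lb; m -m 0)
    and transformed to the real component basis.
    """
    pref = (-1.0) ** la * math.sqrt(
        _FACT[2 * la + 2 * lb + 1] / (_FACT[2 * la] * _FACT[2 * lb])
    )
    Xc = np.zeros((2 * la + 1, 2 * lb + 1), dtype=complex)
    for m in range(-min(la, lb), min(la, lb) + 1):
        Xc[la + m, lb - m] = pref * wigner3j(la, lb, la + lb, m, -m, 0)
    Ca = _complex_from_real(la)
    Cb = _complex_from_real(lb)
    Xr = Ca.T @ Xc @ Cb
    imag = float(np.max(np.abs(Xr.imag)))
    if imag > 1e-12:
        raise AssertionError(f"X matrix not real, imag={imag:.3e}")
    return Xr.real


def t_tensor_direct_matrix(la: int, lb: int, geom: DimerGeometry) -> np.ndarray:
    """Literal evaluation of the full real T-tensor block.

    Contracts the dimer-frame coupling (factorial prefactor, Wigner 3-j,
    irregular harmonic along z) with the two inverse Wigner rotations in
    the complex basis, then projects onto the real components.  Serves as
    the reference implementation that the production path must match.
    """
    if not geom.R > 0:
        raise ValueError("R must be positive")
    pref = (-1.0) ** la * math.sqrt(
        _FACT[2 * la + 2 * lb + 1] / (_FACT[2 * la] * _FACT[2 * lb])
    )
    DA = _wigner_D(la, *geom.omega_A.as_tuple())
    DB = _wigner_D(lb, *geom.omega_B.as_tuple())
    # D(Omega^-1) = D(Omega)^dagger
    DAi = DA.conj().T
    DBi = DB.conj().T
    Tc = np.zeros((2 * la + 1, 2 * lb + 1), dtype=complex)
    for m in range(-min(la, lb), min(la, lb) + 1):
        x = pref * wigner3j(la, lb, la + lb, m, -m, 0)
        if x == 0.0:
            continue
        Tc += x * np.outer(DAi[:, la + m], DBi[:, lb - m])
    Ca = _complex_from_real(la)
    Cb = _complex_from_real(lb)
    Tr = Ca.T @ Tc @ Cb
    imag = float(np.max(np.abs(Tr.imag)))
    if imag > 1e-9 * (1.0 + float(np.max(np.abs(Tr.real)))):
        raise AssertionError(f"T matrix not real, imag={imag:.3e}")
    return Tr.real / geom.R ** (la + lb + 1)


def t_tensor_direct(ta: ComponentLabel, tb: ComponentLabel, geom: DimerGeometry) -> float:
    """One component of :func:`t_tensor_direct_matrix`."""
    return float(t_tensor_direct_matrix(ta.l, tb.l, geom)[ta.index, tb.index])


def t_tensor_matrix(la: int, lb: int, geom: DimerGeometry) -> np.ndarray:
    """Full real T-tensor block, shape (2la+1, 2lb+1): production path.

    T = M_A(Omega_A)^T X M_B(Omega_B) / R^(la+lb+1), with cached
    dimer-frame couplings X and real rotation matrices M.
    """
    if not geom.R > 0:
        raise ValueError("R must be positive")
    MA = rotation_matrix_real(la, geom.omega_A)
    MB = rotation_matrix_real(lb, geom.omega_B)
    return (MA.T @ _x_real(la, lb) @ MB) / geom.R ** (la + lb + 1)


def t_tensor(ta: ComponentLabel, tb: ComponentLabel, geom: DimerGeometry) -> float:
    """Production T-tensor component; agrees with :func:`t_tensor_direct`."""
    return float(t_tensor_matrix(ta.l, tb.l, geom)[ta.index, tb.index])


class TTensorEvaluator:
    """Vectorized T-tensor blocks over a batch of geometries.

    Rotation matrices for every rank are computed once per batch; each
    requested (la, lb) block is then a single einsum.  Orientations may be
    given either as Euler angles or as (possibly improper) attitude
    matrices -- the latter exercises the same parity-aware representation
    used by the symmetry machinery.
    """

    def __init__(self, R, lmax: int, *, euler_A=None, euler_B=None,
                 attitudes_A=None, attitudes_B=None):
        self.R = np.atleast_1d(np.asarray(R, dtype=float))
        if np.any(self.R <= 0):
            raise ValueError("all R must be positive")
        self.n = self.R.shape[0]
        self.lmax = int(lmax)
        self._MA = self._build(euler_A, attitudes_A)
        self._MB = self._build(euler_B, attitudes_B)
        self._cache: dict[tuple[int, int], np.ndarray] = {}

    def _build(self, euler, attitudes):
        mats = []
        if attitudes is not None:
            attitudes = np.asarray(attitudes, dtype=float)
            for l in range(self.lmax + 1):
                Ml = np.stack([rep_matrix_real(l, g) for g in attitudes])
                mats.append(Ml)
            return mats
        if euler is None:
            euler = np.zeros((self.n, 3))
        euler = np.asarray(euler, dtype=float)
        a, b, c = euler[:, 0], euler[:, 1], euler[:, 2]
        for l in range(self.lmax + 1):
            D = _wigner_D(l, a, b, c)
            mats.append(_real_rotation_from_D(l, D))
        return mats

    def block(self, la: int, lb: int) -> np.ndarray:
        """T^{(la,lb)} for every geometry, shape (n, 2la+1, 2lb+1)."""
        key = (la, lb)
        if key not in self._cache:
            X = _x_real(la, lb)
            Rpow = self.R ** (-(la + lb + 1))
            M = np.einsum("nta,tu,nub->nab", self._MA[la], X, self._MB[lb])
            self._cache[key] = M * Rpow[:, None, None]
        return self._cache[key]


# ---------------------------------------------------------------------------
# exact Coulomb oracle and exchange geometry
# ---------------------------------------------------------------------------

def dimer_site_positions(sitesA: Sequence[AtomSite], sitesB: Sequence[AtomSite],
                         geom: DimerGeometry,
                         attitude_A: np.ndarray | None = None,
                         attitude_B: np.ndarray | None = None):
    """Dimer-frame coordinates of all sites (A at origin, B at R along +z)."""
    OA = attitude_matrix(geom.omega_A) if attitude_A is None else attitude_A
    OB = attitude_matrix(geom.omega_B) if attitude_B is None else attitude_B
    pA = np.array([s.position for s in sitesA], dtype=float) @ OA.T
    pB = np.array([s.position for s in sitesB], dtype=float) @ OB.T
    pB = pB + np.array([0.0, 0.0, geom.R])
    return pA, pB


def coulomb_oracle(sitesA: Sequence[AtomSite], sitesB: Sequence[AtomSite],
                   geom: DimerGeometry,
                   attitude_A: np.ndarray | None = None,
                   attitude_B: np.ndarray | None = None) -> float:
    """Exact interaction energy of two rigid point-charge clouds (hartree).

    Molecule A sits at the origin, B at R on the +z axis, each rotated by
    its attitude.  This is the quantity the multipole series approximates
    when charge overlap is negligible.
    """
    if not sitesA or not sitesB:
        raise ValueError("both fragments need at least one site")
    pA, pB = dimer_site_positions(sitesA, sitesB, geom, attitude_A, attitude_B)
    qA = np.array([s.charge for s in sitesA], dtype=float)
    qB = np.array([s.charge for s in sitesB], dtype=float)
    d = np.linalg.norm(pA[:, None, :] - pB[None, :, :], axis=-1)
    if np.any(d < 1e-9):
        raise ValueError("coincident inter-fragment sites in coulomb_oracle")
    return float(np.einsum("i,j,ij->", qA, qB, 1.0 / d))


def exchange_attitudes(geom: DimerGeometry):
    """Attitude matrices after exchanging the roles of A and B.

    The new dimer frame is the old one rotated by pi about y (its z axis
    points from B's to A's center of mass); returns (O_A', O_B') with
    O_A' the attitude of the former molecule B, O_B' of the former A.
    """
    J = _rot_y(math.pi)
    OA = attitude_matrix(geom.omega_A)
    OB = attitude_matrix(geom.omega_B)
    return J.T @ OB, J.T @ OA


def exchange_geometry(geom: DimerGeometry) -> DimerGeometry:
    """Euler-angle form of :func:`exchange_attitudes` (proper rotations)."""
    OA2, OB2 = exchange_attitudes(geom)
    return DimerGeometry(geom.R, euler_from_matrix(OA2), euler_from_matrix(OB2))
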