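"""Angular-momentum machinery: 3-j symbols, solid harmonics, rotations,
T-tensors, and the exact Coulomb oracle."""

import math
from fractions import Fraction

import numpy as np
import pytest

from lrfit.tensor_core import (
    AtomSite,
    ComponentLabel,
    DimerGeometry,
    EulerAngles,
    TTensorEvaluator,
    attitude_matrix,
    coulomb_oracle,
    exchange_attitudes,
    exchange_geometry,
    labels_for_rank,
    multipole_of_point_charges,
    real_solid_harmonic,
    rep_matrix_real,
    rotation_matrix_real,
    t_tensor,
    t_tensor_direct,
    t_tensor_matrix,
    wigner3j,
)


def racah_3j(j1, j2, j3, m1, m2, m3):
    """Independent brute-force 3-j oracle: exact Racah sum in Fractions."""
    if m1 + m2 + m3 != 0 or j3 < abs(j1 - j2) or j3 > j1 + j2:
        return 0.0
    f = math.factorial
    delta = Fraction(f(j1 + j2 - j3) * f(j1 - j2 + j3) * f(-j1 + j2 + j3), f(j1 + j2 + j3 + 1))
    pref2 = delta * f(j1 + m1) * f(j1 - m1) * f(j2 + m2) * f(j2 - m2) * f(j3 + m3) * f(j3 - m3)
    s = Fraction(0)
    for k in range(0, j1 + j2 + j3 + 1):
        denoms = [k, j1 + j2 - j3 - k, j1 - m1 - k, j2 + m2 - k,
                  j3 - j2 + m1 + k, j3 - j1 - m2 + k]
        if any(d < 0 for d in denoms):
            continue
        term = Fraction((-1) ** k, math.prod(f(d) for d in denoms))
        s += term
    sign = (-1) ** (j1 - j2 - m3)
    return sign * float(s) * math.sqrt(float(pref2))


class TestWigner3j:
    @pytest.mark.parametrize("args,expected", [
        ((0, 0, 0, 0, 0, 0), 1.0),
        ((1, 1, 2, 0, 0, 0), math.sqrt(2.0 / 15.0)),
        ((1, 1, 1, 0, 0, 0), 0.0),          # odd j1+j2+j3 with all m = 0
        ((2, 1, 1, 0, 1, -1), math.sqrt(1.0 / 30.0)),
    ])
    def test_known_values(self, args, expected):
        assert wigner3j(*args) == pytest.approx(expected, abs=1e-14)

    def test_selection_rules(self):
        assert wigner3j(1, 1, 2, 1, 1, 0) == 0.0   # m sum nonzero
        assert wigner3j(1, 1, 5, 0, 0, 0) == 0.0   # triangle violated

    def test_negative_j_raises(self):
        with pytest.raises(ValueError):
            wigner3j(-1, 1, 1, 0, 0, 0)

    def test_against_racah_brute_force(self, rng):
        for _ in range(40):
            j1, j2 = rng.integers(0, 8, size=2)
            j3 = rng.integers(abs(j1 - j2), j1 + j2 + 1)
            m1 = rng.integers(-j1, j1 + 1)
            m2 = rng.integers(-j2, j2 + 1)
            m3 = -m1 - m2
            if abs(m3) > j3:
                continue
            assert wigner3j(int(j1), int(j2), int(j3), int(m1), int(m2), int(m3)) == \
                pytest.approx(racah_3j(int(j1), int(j2), int(j3), int(m1), int(m2), int(m3)),
                              abs=1e-12)


class TestLabels:
    def test_parse_and_ordering(self):
        assert ComponentLabel.parse("00") == ComponentLabel(0, 0)
        assert ComponentLabel.parse("21c") == ComponentLabel(2, 1, "c")
        assert ComponentLabel.parse("11s").index == 2
        assert [str(t) for t in labels_for_rank(2)] == ["20", "21c", "21s", "22c", "22s"]

    def test_component_count(self):
        for l in range(0, 16):
            assert len(labels_for_rank(l)) == 2 * l + 1

    def test_invalid_labels(self):
        with pytest.raises(ValueError):
            ComponentLabel(1, 0, "c")
        with pytest.raises(ValueError):
            ComponentLabel(1, 1)       # m>=1 needs a phase
        with pytest.raises(ValueError):
            ComponentLabel.parse("9x")


class TestSolidHarmonics:
    def test_low_rank_cartesian_forms(self, rng):
        p = rng.standard_normal(3)
        x, y, z = p
        assert real_solid_harmonic(ComponentLabel.parse("00"), p) == pytest.approx(1.0)
        assert real_solid_harmonic(ComponentLabel.parse("10"), p) == pytest.approx(z)
        assert real_solid_harmonic(ComponentLabel.parse("11c"), p) == pytest.approx(x)
        assert real_solid_harmonic(ComponentLabel.parse("11s"), p) == pytest.approx(y)
        assert real_solid_harmonic(ComponentLabel.parse("20"), (0, 0, 1.7)) == pytest.approx(1.7**2)

    def test_homogeneity(self, rng):
        for l in (1, 3, 6):
            t = labels_for_rank(l)[rng.integers(0, 2 * l + 1)]
            p = rng.standard_normal(3)
            v1 = real_solid_harmonic(t, p)
            v2 = real_solid_harmonic(t, 2.5 * p)
            assert v2 == pytest.approx(2.5**l * v1, rel=1e-12)

    def test_point_charge_multipoles(self):
        q00 = ComponentLabel.parse("00")
        q10 = ComponentLabel.parse("10")
        q20 = ComponentLabel.parse("20")
        single = [AtomSite(1.3, (0.0, 0.0, 0.0))]
        assert multipole_of_point_charges(single, q00) == pytest.approx(1.3)
        assert multipole_of_point_charges(single, q20) == pytest.approx(0.0, abs=1e-15)
        d = 0.8
        dip = [AtomSite(2.0, (0, 0, d / 2)), AtomSite(-2.0, (0, 0, -d / 2))]
        assert multipole_of_point_charges(dip, q10) == pytest.approx(2.0 * d)
        quad = [AtomSite(1.5, (0, 0, d))]
        assert multipole_of_point_charges(quad, q20) == pytest.approx(1.5 * d * d)

    def test_empty_sites_error(self):
        with pytest.raises(ValueError):
            multipole_of_point_charges([], ComponentLabel.parse("00"))


class TestRotations:
    def test_identity_angles(self):
        for l in (0, 1, 4):
            M = rotation_matrix_real(l, EulerAngles())
            assert np.allclose(M, np.eye(2 * l + 1), atol=1e-13)

    def test_l1_matches_cartesian_zxy(self, rng):
        om = EulerAngles(*rng.uniform(0, 2 * math.pi, 3))
        P = np.array([[0, 0, 1.0], [1, 0, 0], [0, 1, 0]])  # (z,x,y) ordering
        expected = P @ attitude_matrix(om) @ P.T
        assert np.allclose(rotation_matrix_real(1, om), expected, atol=1e-12)

    def test_orthogonality_high_rank(self, rng):
        for l in range(1, 9):
            om = EulerAngles(*rng.uniform(0, 2 * math.pi, 3))
            M = rotation_matrix_real(l, om)
            assert np.max(np.abs(M @ M.T - np.eye(2 * l + 1))) < 1e-12

    def test_group_homomorphism(self, rng):
        # composing rotations composes matrices
        for _ in range(20):
            l = int(rng.integers(1, 7))
            o1 = EulerAngles(*rng.uniform(0, 2 * math.pi, 3))
            o2 = EulerAngles(*rng.uniform(0, 2 * math.pi, 3))
            M12 = rep_matrix_real(l, attitude_matrix(o1) @ attitude_matrix(o2))
            assert np.max(np.abs(rotation_matrix_real(l, o1) @ rotation_matrix_real(l, o2)
                                 - M12)) < 1e-10

    def test_improper_parity(self):
        for l in (1, 2, 3):
            M = rep_matrix_real(l, -np.eye(3))
            assert np.allclose(M, (-1) ** l * np.eye(2 * l + 1), atol=1e-12)


class TestTTensor:
    def test_charge_charge(self):
        g = DimerGeometry(10.0)
        t00 = ComponentLabel.parse("00")
        assert t_tensor(t00, t00, g) == pytest.approx(0.1)
        assert t_tensor_direct(t00, t00, g) == pytest.approx(0.1)

    def test_collinear_dipole_dipole(self):
        g = DimerGeometry(10.0)
        t10 = ComponentLabel.parse("10")
        assert t_tensor(t10, t10, g) == pytest.approx(-2.0 / 1000.0, rel=1e-12)

    def test_homogeneity_in_R(self, rng):
        oA = EulerAngles(*rng.uniform(0, 2 * math.pi, 3))
        oB = EulerAngles(*rng.uniform(0, 2 * math.pi, 3))
        for la in range(0, 4):
            for lb in range(0, 7 - la):
                T1 = t_tensor_matrix(la, lb, DimerGeometry(7.0, oA, oB))
                T2 = t_tensor_matrix(la, lb, DimerGeometry(14.0, oA, oB))
                assert np.allclose(T2, T1 * 0.5 ** (la + lb + 1), rtol=1e-12)

    def test_production_matches_direct(self, rng):
        for _ in range(10):
            g = DimerGeometry(float(rng.uniform(5, 40)),
                              EulerAngles(*rng.uniform(0, 2 * math.pi, 3)),
                              EulerAngles(*rng.uniform(0, 2 * math.pi, 3)))
            for la in range(0, 5):
                for lb in range(0, 5 - la + 1):
                    T = t_tensor_matrix(la, lb, g)
                    for ta in labels_for_rank(la)[:3]:
                        for tb in labels_for_rank(lb)[:3]:
                            ref = t_tensor_direct(ta, tb, g)
                            assert T[ta.index, tb.index] == pytest.approx(ref, abs=1e-12, rel=1e-10)

    def test_nonpositive_R_raises(self):
        with pytest.raises(ValueError):
            DimerGeometry(-1.0)
        with pytest.raises(ValueError):
            t_tensor_matrix(1, 1, DimerGeometry.__new__(DimerGeometry)) if False else \
                TTensorEvaluator([-2.0], 1)

    def test_batch_matches_pointwise(self, rng):
        geoms = [DimerGeometry(float(rng.uniform(5, 30)),
                               EulerAngles(*rng.uniform(0, 2 * math.pi, 3)),
                               EulerAngles(*rng.uniform(0, 2 * math.pi, 3)))
                 for _ in range(25)]
        ev = TTensorEvaluator(np.array([g.R for g in geoms]), 3,
                              euler_A=[g.omega_A.as_tuple() for g in geoms],
                              euler_B=[g.omega_B.as_tuple() for g in geoms])
        for (la, lb) in [(0, 2), (1, 1), (2, 3), (3, 0)]:
            B = ev.block(la, lb)
            for i, g in enumerate(geoms):
                assert np.allclose(B[i], t_tensor_matrix(la, lb, g), rtol=1e-12, atol=1e-15)


class TestCoulombOracle:
    def test_unit_charges(self):
        a = [AtomSite(1.0, (0, 0, 0))]
        b = [AtomSite(1.0, (0, 0, 0))]
        assert coulomb_oracle(a, b, DimerGeometry(10.0)) == pytest.approx(0.1)

    def test_point_dipole_limit(self):
        # two collinear +/- pairs; Richardson extrapolation in the pair length
        mu = 0.7

        def energy(d):
            a = [AtomSite(mu / d, (0, 0, d / 2)), AtomSite(-mu / d, (0, 0, -d / 2))]
            b = [AtomSite(mu / d, (0, 0, d / 2)), AtomSite(-mu / d, (0, 0, -d / 2))]
            return coulomb_oracle(a, b, DimerGeometry(20.0))

        e1, e2 = energy(1e-2), energy(5e-3)
        richardson = (4 * e2 - e1) / 3.0
        expected = -2.0 * mu * mu / 20.0**3
        assert richardson == pytest.approx(expected, rel=1e-3)

    def test_exchange_symmetry(self, rng):
        a = [AtomSite(float(rng.normal()), tuple(rng.normal(size=3) * 0.4)) for _ in range(3)]
        b = [AtomSite(float(rng.normal()), tuple(rng.normal(size=3) * 0.4)) for _ in range(3)]
        g = DimerGeometry(12.0, EulerAngles(*rng.uniform(0, 2, 3)), EulerAngles(*rng.uniform(0, 2, 3)))
        e1 = coulomb_oracle(a, b, g)
        OA2, OB2 = exchange_attitudes(g)
        e2 = coulomb_oracle(b, a, g, attitude_A=OA2, attitude_B=OB2)
        assert e1 == pytest.approx(e2, rel=1e-13)
        # Euler-angle form of the exchange agrees with the attitude form
        g2 = exchange_geometry(g)
        e3 = coulomb_oracle(b, a, g2)
        assert e1 == pytest.approx(e3, rel=1e-12)

    def test_coincident_sites_error(self):
        a = [AtomSite(1.0, (0, 0, 5.0))]
        b = [AtomSite(1.0, (0, 0, -5.0))]
        with pytest.raises(ValueError):
            coulomb_oracle(a, b, DimerGeometry(10.0))


class TestSeriesVsOracle:
    def multipole_series(self, sitesA, sitesB, geom, N):
        E = 0.0
        for la in range(N):
            for lb in range(N - la):
                if la + lb + 1 > N:
                    continue
                qa = np.array([multipole_of_point_charges(sitesA, t) for t in labels_for_rank(la)])
                qb = np.array([multipole_of_point_charges(sitesB, t) for t in labels_for_rank(lb)])
                E += qa @ t_tensor_matrix(la, lb, geom) @ qb
        return E

    def test_truncation_error_slope(self, rng):
        # |E(<=N) - exact| ~ R^-(N+1): log-log slope within 0.3 of -(N+1)
        sitesA = [AtomSite(float(rng.normal()) + 0.5, tuple(rng.normal(size=3) * 0.4)) for _ in range(3)]
        sitesB = [AtomSite(float(rng.normal()) - 0.5, tuple(rng.normal(size=3) * 0.4)) for _ in range(3)]
        oA = EulerAngles(0.4, 1.0, 2.2)
        oB = EulerAngles(5.0, 0.8, 0.3)
        Rs = np.geomspace(20.0, 200.0, 8)
        for N in (2, 3, 4, 5):
            errs = []
            for R in Rs:
                g = DimerGeometry(float(R), oA, oB)
                errs.append(abs(self.multipole_series(sitesA, sitesB, g, N)
                                - coulomb_oracle(sitesA, sitesB, g)))
            slope = np.polyfit(np.log(Rs), np.log(errs), 1)[0]
            assert abs(slope + (N + 1)) < 0.3

    def test_azimuth_difference_only(self, rng):
        # adding a common constant to both azimuths leaves T-tensor energies
        sitesA = [AtomSite(1.0, (0.1, 0.2, 0.3)), AtomSite(-0.5, (-0.2, 0.1, -0.3))]
        sitesB = [AtomSite(0.7, (0.3, -0.1, 0.2))]
        qa = {l: np.array([multipole_of_point_charges(sitesA, t) for t in labels_for_rank(l)])
              for l in range(3)}
        qb = {l: np.array([multipole_of_point_charges(sitesB, t) for t in labels_for_rank(l)])
              for l in range(3)}
        oA = rng.uniform(0, 2 * math.pi, 3)
        oB = rng.uniform(0, 2 * math.pi, 3)
        shift = 0.9876

        def energy(dA, dB):
            g = DimerGeometry(9.0, EulerAngles(oA[0] + dA, oA[1], oA[2]),
                              EulerAngles(oB[0] + dB, oB[1], oB[2]))
            return sum(qa[la] @ t_tensor_matrix(la, lb, g) @ qb[lb]
                       for la in range(3) for lb in range(3))

        assert energy(0, 0) == pytest.approx(energy(shift, shift), abs=1e-10)


class TestPropertyBased:
    """Hypothesis property checks (derandomized for reproducibility)."""

    from hypothesis import given, settings, strategies as st

    @given(st.integers(0, 15), st.integers(0, 15), st.sampled_from(["", "c", "s"]))
    @settings(max_examples=60, derandomize=True)
    def test_label_str_parse_round_trip(self, l, m, phase):
        try:
            t = ComponentLabel(l, m, phase)
        except ValueError:
            return
        assert ComponentLabel.parse(str(t)) == t

    @given(st.integers(1, 6),
           st.tuples(st.floats(0, 6.28), st.floats(0, 3.14), st.floats(0, 6.28)),
           st.tuples(st.floats(-1, 1), st.floats(-1, 1), st.floats(-1, 1)))
    @settings(max_examples=40, derandomize=True)
    def test_solid_harmonics_rotation_equivariance(self, l, angles, p):
        # S(O p) = M_l(O) S(p): the rotation matrix and the harmonics share
        # one convention
        om = EulerAngles(*angles)
        O = attitude_matrix(om)
        M = rotation_matrix_real(l, om)
        S = np.array([real_solid_harmonic(t, p) for t in labels_for_rank(l)])
        Sp = np.array([real_solid_harmonic(t, O @ np.asarray(p)) for t in labels_for_rank(l)])
        assert np.allclose(Sp, M @ S, atol=1e-10)
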