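"""File dialect, units, LeRoy filter, coefficient serialization,
evaluator export, and the command-line interface."""

import json
import math
import shutil
import subprocess

import numpy as np
import pytest

from lrfit import units as U
from lrfit.data_io import (
    Dataset,
    export_evaluator,
    leroy_filter,
    read_coefficients,
    read_dataset,
    reevaluate_exported,
    write_coefficients,
    write_dataset,
)
from lrfit.expansion import Expansion
from lrfit.symmetry import SystemSpec
from lrfit.synthetic import SyntheticModel, random_coefficients, random_geometries, synthetic_dataset
from lrfit.tensor_core import AtomSite, DimerGeometry, EulerAngles

from conftest import mol


class TestUnits:
    def test_round_trips(self):
        assert U.ANGSTROM_TO_BOHR * U.BOHR_TO_ANGSTROM == pytest.approx(1.0, abs=1e-15)
        assert U.CM1_TO_HARTREE * U.HARTREE_TO_CM1 == pytest.approx(1.0, abs=1e-15)
        assert U.DEG_TO_RAD * U.RAD_TO_DEG == pytest.approx(1.0, abs=1e-15)
        assert U.to_internal_distance(1.0, "angstrom") == pytest.approx(1.8897261246, rel=1e-9)

    def test_unknown_unit(self):
        with pytest.raises(ValueError):
            U.to_internal_energy(1.0, "furlong")


class TestReadDataset:
    def test_4d_row_units(self, tmp_path):
        s = SystemSpec(mol("Cinfv", charge=1.0), mol("Dinfh"))
        p = tmp_path / "d.dat"
        p.write_text("# comment\n10.0 0.0 0.0 0.0 -12.5\n")
        ds = read_dataset(p, sys=s)
        assert len(ds) == 1
        g = ds.geometries[0]
        assert g.R == pytest.approx(10.0 * U.ANGSTROM_TO_BOHR)
        assert g.omega_A.beta == 0.0 and g.omega_B.beta == 0.0
        assert ds.energies[0] == pytest.approx(-12.5 * U.CM1_TO_HARTREE)

    def test_2d_layout_linear_atom(self, tmp_path):
        s = SystemSpec(mol("Cinfv"), mol("atom"))
        assert s.free_angles == ("beta_A",)
        p = tmp_path / "d.dat"
        p.write_text("12.0 90.0 -1.0\n")
        ds = read_dataset(p, sys=s)
        assert ds.geometries[0].omega_A.beta == pytest.approx(math.pi / 2)

    def test_header_autodetect(self, tmp_path):
        s = SystemSpec(mol("atom", charge=1.0), mol("atom"))
        p = tmp_path / "d.dat"
        p.write_text("R E\n10.0 1.0\n20.0 0.5\n")
        assert len(read_dataset(p, sys=s)) == 2

    def test_empty_file_warns(self, tmp_path):
        s = SystemSpec(mol("atom"), mol("atom"))
        p = tmp_path / "d.dat"
        p.write_text("# nothing\n")
        with pytest.warns(UserWarning, match="empty"):
            ds = read_dataset(p, sys=s)
        assert len(ds) == 0

    def test_wrong_column_count(self, tmp_path):
        s = SystemSpec(mol("Cinfv", charge=1.0), mol("Dinfh"))
        p = tmp_path / "d.dat"
        p.write_text("10.0 0.0 -12.5\n")
        with pytest.raises(ValueError, match="4D"):
            read_dataset(p, sys=s)

    def test_non_numeric_field_line_number(self, tmp_path):
        s = SystemSpec(mol("atom"), mol("atom"))
        p = tmp_path / "d.dat"
        p.write_text("10.0 1.0\nxx yy\n")
        with pytest.raises(ValueError, match=":2"):
            read_dataset(p, sys=s)

    def test_generator_round_trip_exact(self, tmp_path):
        s = SystemSpec(mol("C2v", charge=0.4), mol("Cinfv"))
        caps = {"electrostatic": 4}
        cs = random_coefficients(s, caps, seed=5)
        data = synthetic_dataset(SyntheticModel(s, cs, caps, 5), 30)
        # atomic-unit files round-trip bit-exactly (unit factors are 1)
        au = {"distance": "bohr", "angle": "rad", "energy": "hartree"}
        p = tmp_path / "d.dat"
        write_dataset(data, p, s, au)
        back = read_dataset(p, units=au, sys=s)
        assert np.array_equal(back.R, data.R)
        assert np.array_equal(back.energies, data.energies)
        for g1, g2 in zip(back.geometries, data.geometries):
            assert g1.omega_A.as_tuple() == g2.omega_A.as_tuple()
        # default spectroscopic units round-trip to rounding precision
        p2 = tmp_path / "d2.dat"
        write_dataset(data, p2, s)
        back2 = read_dataset(p2, sys=s)
        assert np.allclose(back2.energies, data.energies, rtol=1e-14)
        assert np.allclose(back2.R, data.R, rtol=1e-14)


class TestLeroyFilter:
    def test_inclusive_boundary(self):
        a = mol("atom")
        s = SystemSpec(a, a)
        data = Dataset((DimerGeometry(10.0),), np.zeros(1))
        assert leroy_filter(data, s, 10.0).mask[0]          # == d_min admits
        assert not leroy_filter(data, s, 10.0 + 1e-9).mask[0]

    def test_rod_end_on_vs_side_on(self):
        # 11-site rod of length ~12 A probed by an atom at R = 8 A
        L = 12.0 * U.ANGSTROM_TO_BOHR
        rod = tuple(AtomSite(0.1, (0.0, 0.0, z)) for z in np.linspace(-L / 2, L / 2, 11))
        s = SystemSpec(mol("Dinfh", sites=rod), mol("atom"))
        R = 8.0 * U.ANGSTROM_TO_BOHR
        dmin = 6.0 * U.ANGSTROM_TO_BOHR
        end_on = DimerGeometry(R, EulerAngles(0, 0, 0), EulerAngles())
        side_on = DimerGeometry(R, EulerAngles(0, math.pi / 2, 0), EulerAngles())
        fm = leroy_filter(Dataset((end_on, side_on), np.zeros(2)), s, dmin)
        assert fm.mask.tolist() == [False, True]
        assert fm.min_distances[0] == pytest.approx(2.0 * U.ANGSTROM_TO_BOHR, rel=1e-9)
        assert fm.min_distances[1] == pytest.approx(R, rel=1e-9)

    def test_monotone_in_dmin(self, rng):
        rod = tuple(AtomSite(0.1, (0.0, 0.0, z)) for z in np.linspace(-5, 5, 7))
        s = SystemSpec(mol("Dinfh", sites=rod), mol("atom"))
        geoms = random_geometries(s, 40, R_range=(6.0, 20.0), seed=4)
        data = Dataset(tuple(geoms), np.zeros(40))
        prev = np.ones(40, dtype=bool)
        for d in (0.0, 2.0, 5.0, 8.0, 1e6):
            m = leroy_filter(data, s, d).mask
            assert np.all(m <= prev)   # raising d_min never re-admits
            prev = m
        assert leroy_filter(data, s, 0.0).mask.all()
        assert not leroy_filter(data, s, 1e9).mask.any()

    def test_missing_sites_error(self):
        s = SystemSpec(mol("C2v"), mol("atom"))
        data = Dataset((DimerGeometry(10.0),), np.zeros(1))
        with pytest.raises(ValueError, match="sites"):
            leroy_filter(data, s, 1.0)


class TestCoefficientFiles:
    def _setup(self):
        s = SystemSpec(mol("Cinfv", charge=1.0), mol("Dinfh"))
        caps = {"electrostatic": 5, "induction": 5, "dispersion": 6}
        cs = random_coefficients(s, caps, seed=8)
        exp = Expansion(s, caps)
        return s, caps, cs, exp

    def test_round_trip_bitwise(self, tmp_path):
        s, caps, cs, exp = self._setup()
        p = tmp_path / "c.json"
        write_coefficients(cs, s, list(exp.terms), p)
        cs2, s2, terms2 = read_coefficients(p)
        for key in exp.parameter_keys:
            assert exp.get_entry(cs2, key) == exp.get_entry(cs, key)
        assert s2.molA.point_group == s.molA.point_group
        assert [t.key for t in terms2] == [t.key for t in exp.terms]

    def test_writes_byte_identical(self, tmp_path):
        s, caps, cs, exp = self._setup()
        p1, p2 = tmp_path / "c1.json", tmp_path / "c2.json"
        write_coefficients(cs, s, list(exp.terms), p1)
        write_coefficients(cs, s, list(exp.terms), p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_missing_coefficient_named(self, tmp_path):
        s, caps, cs, exp = self._setup()
        p = tmp_path / "c.json"
        write_coefficients(cs, s, list(exp.terms), p)
        doc = json.loads(p.read_text())
        dropped = doc["coefficients"].pop(3)
        p.write_text(json.dumps(doc))
        with pytest.raises(ValueError, match=dropped["name"].split("[")[0]):
            read_coefficients(p)

    def test_version_mismatch(self, tmp_path):
        s, caps, cs, exp = self._setup()
        p = tmp_path / "c.json"
        write_coefficients(cs, s, list(exp.terms), p)
        doc = json.loads(p.read_text())
        doc["version"] = 99
        p.write_text(json.dumps(doc))
        with pytest.raises(ValueError, match="version"):
            read_coefficients(p)


class TestEvaluatorExport:
    def test_zero_coefficients_constant(self, tmp_path):
        s = SystemSpec(mol("atom"), mol("atom"))
        exp = Expansion(s, {"dispersion": 6})
        cs = exp.zero_coefficients()
        cs.easym = -3.25e-5
        jp, fp = export_evaluator(cs, s, list(exp.terms), tmp_path / "ev")
        for R in (8.0, 20.0, 55.0):
            assert reevaluate_exported(jp, DimerGeometry(R)) == pytest.approx(-3.25e-5)

    def test_charge_charge_reduction(self, tmp_path):
        s = SystemSpec(mol("atom", charge=1.0), mol("atom", charge=-2.0))
        exp = Expansion(s, {"electrostatic": 1})
        cs = exp.zero_coefficients()
        cs.easym = 1e-4
        jp, _ = export_evaluator(cs, s, list(exp.terms), tmp_path / "ev")
        doc = json.loads(open(jp).read())
        assert doc["quadratic"] == []
        assert len(doc["linear"]) == 1
        assert reevaluate_exported(jp, DimerGeometry(10.0)) == pytest.approx(1e-4 - 0.2)

    def test_parity_random_model(self, tmp_path):
        s = SystemSpec(mol("Cinfv", charge=1.0), mol("Dinfh"))
        caps = {"electrostatic": 5, "induction": 5, "dispersion": 6}
        cs = random_coefficients(s, caps, seed=9)
        exp = Expansion(s, caps)
        jp, _ = export_evaluator(cs, s, list(exp.terms), tmp_path / "ev")
        geoms = random_geometries(s, 100, seed=10)
        Eref = exp.energy(cs, exp.evaluator(geoms))
        for g, e in zip(geoms, Eref):
            assert reevaluate_exported(jp, g) == pytest.approx(e, abs=1e-12, rel=1e-12)

    def test_fortran_source_compiles_and_agrees(self, tmp_path):
        if shutil.which("gfortran") is None:
            pytest.fail("gfortran unavailable; exported source cannot be verified")
        s = SystemSpec(mol("Cinfv", charge=1.0), mol("Dinfh"))
        caps = {"electrostatic": 4, "induction": 4}
        cs = random_coefficients(s, caps, seed=11)
        exp = Expansion(s, caps)
        _, fp = export_evaluator(cs, s, list(exp.terms), tmp_path / "ev")
        driver = tmp_path / "driver.f90"
        driver.write_text(
            "program main\n"
            "  use lrf_evaluator\n"
            "  implicit none\n"
            "  real(kind(1.0d0)) :: e\n"
            "  call lrf_energy(23.7d0, 0.7d0, 1.1d0, 0.0d0, 2.2d0, 0.0d0, e)\n"
            "  print '(es24.16)', e\n"
            "end program main\n")
        exe = tmp_path / "ev.x"
        subprocess.run(["gfortran", "-O1", "-J", str(tmp_path), "-o", str(exe),
                        fp, str(driver)], check=True, capture_output=True)
        out = subprocess.run([str(exe)], capture_output=True, text=True, check=True)
        g = DimerGeometry(23.7, EulerAngles(0.7, 1.1, 0.0), EulerAngles(0.0, 2.2, 0.0))
        Epy = exp.energy(cs, exp.evaluator([g]))[0]
        assert float(out.stdout) == pytest.approx(Epy, rel=1e-10)


class TestCLI:
    def _invoke(self, args):
        from click.testing import CliRunner

        from lrfit.cli import main

        return CliRunner().invoke(main, args, catch_exceptions=False)

    def test_terms_first_active_order(self):
        r = self._invoke(["terms", "--group-a", "Cinfv", "--charge-a", "1",
                          "--group-b", "Dinfh", "--max-order", "5"])
        assert r.exit_code == 0
        rows = [ln for ln in r.output.splitlines() if ln.strip().startswith(("1", "2", "3"))]
        first_active = next(ln for ln in r.output.splitlines() if "True" in ln)
        assert first_active.strip().startswith("3")

    def test_fit_eval_round_trip(self, tmp_path):
        r = self._invoke(["synth", "--group-a", "Cinfv", "--charge-a", "1",
                          "--group-b", "Dinfh", "--n", "120", "--elec", "4",
                          "--ind", "4", "--disp", "0", "--seed", "3",
                          "--out", str(tmp_path / "s.dat")])
        assert r.exit_code == 0
        r = self._invoke(["fit", "--group-a", "Cinfv", "--charge-a", "1",
                          "--group-b", "Dinfh", "--max-order", "4",
                          str(tmp_path / "s.dat"),
                          "--coefficients", str(tmp_path / "c.json"),
                          "--report", str(tmp_path / "rep.csv")])
        assert r.exit_code == 0
        import pandas as pd

        rep = pd.read_csv(tmp_path / "rep.csv")
        assert (rep["RMSE"].diff().dropna() <= 1e-18 + rep["RMSE"][:-1].values * 1e-9).all()
        r = self._invoke(["eval", str(tmp_path / "c.json"), str(tmp_path / "s.dat"),
                          "--out", str(tmp_path / "e.dat")])
        assert r.exit_code == 0
        # evaluated energies reproduce the fitted model on the training set
        s = SystemSpec(mol("Cinfv", charge=1.0), mol("Dinfh"))
        fit_ds = read_dataset(tmp_path / "e.dat", sys=s)
        data = read_dataset(tmp_path / "s.dat", sys=s)
        assert np.allclose(fit_ds.energies, data.energies,
                           atol=1e-10 * np.max(np.abs(data.energies)))

    def test_unknown_flag_exits_2(self):
        from click.testing import CliRunner

        from lrfit.cli import main

        r = CliRunner().invoke(main, ["terms", "--bogus"])
        assert r.exit_code == 2
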