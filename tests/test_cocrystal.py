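"""Solubility product, cocrystal lines, eutectics and diagram assembly."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cocrysol.cocrystal import (
    api_or_cf_line_with_cosolute,
    cc_solubility_line,
    cc_x_api_at_x_cf,
    ks_at_temperature,
    ks_from_point,
    ks_ideal_from_point,
    locate_eutectic,
)
from cocrysol.sle import ideal_solubility


class TestSolubilityProduct:
    def test_ideal_activities_arithmetic(self):
        assert ks_from_point(0.01, 0.004, 1.0, 1.0, 2, 1) == pytest.approx(4e-7, rel=1e-12)
        assert ks_ideal_from_point(0.01, 0.004, 2, 1) == pytest.approx(4e-7, rel=1e-12)

    @given(
        x_api=st.floats(1e-4, 0.2),
        x_cf=st.floats(1e-4, 0.2),
        g_api=st.floats(0.1, 10.0),
        g_cf=st.floats(0.1, 10.0),
    )
    @settings(max_examples=30, deadline=None)
    def test_gamma_ratio_identity(self, x_api, x_cf, g_api, g_cf):
        full = ks_from_point(x_api, x_cf, g_api, g_cf, 2, 1)
        ideal = ks_ideal_from_point(x_api, x_cf, 2, 1)
        assert full / ideal == pytest.approx(g_api**2 * g_cf, rel=1e-9)

    def test_nonpositive_inputs_rejected(self):
        with pytest.raises(ValueError):
            ks_from_point(0.0, 0.01, 1.0, 1.0, 2, 1)


class TestGibbsHelmholtz:
    def test_identity_at_reference(self, cc):
        assert ks_at_temperature(cc, cc.t_ref) == pytest.approx(cc.ks_ref, rel=1e-14)

    def test_exact_invertibility(self, cc):
        ks_310 = ks_at_temperature(cc, 310.15)
        back = math.exp(
            math.log(ks_310) + cc.dh_ref * 1000.0 / 8.314 * (1 / 310.15 - 1 / cc.t_ref)
        )
        assert back == pytest.approx(cc.ks_ref, rel=1e-12)

    def test_monotone_increasing_for_positive_enthalpy(self, cc):
        grid = np.linspace(280.0, 330.0, 20)
        vals = [ks_at_temperature(cc, T) for T in grid]
        assert all(b > a for a, b in zip(vals, vals[1:]))


class TestCocrystalLine:
    def test_ideal_closed_form_at_ratio_two(self, db, cc):
        # with unit gammas (2s)^2 * s = Ks, so s = (Ks/4)^(1/3)
        line = cc_solubility_line(
            cc, {"ethanol": 1.0}, 298.15, ratio_grid=[2.0], db=db, ks=3.7e-7, ideal=True
        )
        x_api, x_cf, g_api, g_cf = line.points[0]
        assert (g_api, g_cf) == (1.0, 1.0)
        assert x_cf == pytest.approx((3.7e-7 / 4.0) ** (1 / 3), rel=1e-10)
        assert x_api == pytest.approx(2 * x_cf, rel=1e-10)

    def test_every_point_reproduces_ks(self, db, cc):
        line = cc_solubility_line(
            cc, {"ethanol": 0.5, "water": 0.5}, 298.15,
            ratio_grid=np.geomspace(0.3, 10.0, 7), db=db,
        )
        for x_api, x_cf, g_api, g_cf in line.points:
            back = ks_from_point(x_api, x_cf, g_api, g_cf, cc.nu_api, cc.nu_cf)
            assert abs(back - line.ks_used) / line.ks_used < 1e-6

    def test_x_api_lookup_inverts_line(self, db, cc):
        line = cc_solubility_line(
            cc, {"ethanol": 1.0}, 298.15, ratio_grid=[1.0, 2.0, 4.0], db=db
        )
        for x_api, x_cf, _, _ in line.points:
            got = cc_x_api_at_x_cf(cc, {"ethanol": 1.0}, 298.15, x_cf, db)
            assert got == pytest.approx(x_api, rel=1e-7)


class TestCosoluteBranch:
    def test_zero_cosolute_matches_single_solute(self, db):
        from cocrysol.sle import solve_solubility

        branch = api_or_cf_line_with_cosolute(
            "SA", "NA", [0.0, 0.002], {"ethanol": 1.0}, 298.15, db
        )
        single = solve_solubility("SA", {"ethanol": 1.0}, 298.15, db)
        assert branch[0].x_solute == pytest.approx(single.x_solute, rel=1e-8)

    def test_ideal_branch_is_flat(self, db):
        branch = api_or_cf_line_with_cosolute(
            "SA", "NA", [0.0, 0.005, 0.01], {"ethanol": 1.0}, 298.15, db, ideal=True
        )
        xs = [p.x_solute for p in branch]
        assert max(xs) == min(xs)

    def test_sa_solubility_rises_with_na_additions(self, db):
        # dissolved nicotinamide salts in: succinic acid saturation increases
        branch = api_or_cf_line_with_cosolute(
            "SA", "NA", [0.0, 0.004, 0.008], {"ethanol": 0.5, "water": 0.5}, 298.15, db
        )
        xs = [p.x_solute for p in branch]
        assert xs[1] > xs[0] and xs[2] > xs[1]


class TestEutectic:
    def _ideal_lines(self, db, cc):
        x_id_na = ideal_solubility(db.melting_of("NA"), 298.15)
        branch = api_or_cf_line_with_cosolute(
            "NA", "SA", np.linspace(1e-4, 8e-4, 6), {"ethanol": 1.0}, 298.15, db, ideal=True
        )
        line = cc_solubility_line(
            cc, {"ethanol": 1.0}, 298.15, ratio_grid=np.geomspace(5, 400, 25),
            db=db, ks=3.7e-7, ideal=True,
        )
        return x_id_na, branch, line

    def test_matches_closed_form_at_ideality(self, db, cc):
        # flat API branch at x_id meets the ideal line where x_id^2 x_cf = Ks
        x_id_na, branch, line = self._ideal_lines(db, cc)
        eut = locate_eutectic(branch, line, db, ideal=True)
        assert eut is not None
        assert eut.x_api == pytest.approx(x_id_na, rel=1e-9)
        assert eut.x_cf == pytest.approx(3.7e-7 / x_id_na**2, rel=1e-9)
        assert max(abs(r) for r in eut.residuals) < 1e-6

    def test_argument_order_is_irrelevant(self, db, cc):
        _, branch, line = self._ideal_lines(db, cc)
        a = locate_eutectic(branch, line, db, ideal=True)
        b = locate_eutectic(line, branch, db, ideal=True)
        assert a.x_api == pytest.approx(b.x_api, rel=1e-9)
        assert a.x_cf == pytest.approx(b.x_cf, rel=1e-9)

    def test_absence_of_crossing_reported_as_none(self, db, cc):
        # a branch sampled far from the cocrystal line cannot cross it
        branch = api_or_cf_line_with_cosolute(
            "NA", "SA", np.linspace(0.05, 0.08, 3), {"ethanol": 1.0}, 298.15, db, ideal=True
        )
        line = cc_solubility_line(
            cc, {"ethanol": 1.0}, 298.15, ratio_grid=np.geomspace(5, 40, 5),
            db=db, ks=3.7e-7, ideal=True,
        )
        assert locate_eutectic(branch, line, db, ideal=True) is None


class TestPhaseDiagram:
    def test_assembly_and_consistency(self, db, cc):
        from cocrysol.cocrystal import build_phase_diagram
        from cocrysol.sle import solve_solubility

        tpd = build_phase_diagram(
            cc, {"ethanol": 0.5, "ethyl_acetate": 0.5}, 298.15, db, n_branch=6
        )
        # branch endpoints reconcile with the single-solute solubilities
        single = solve_solubility("NA", {"ethanol": 0.5, "ethyl_acetate": 0.5}, 298.15, db)
        assert tpd.api_line[0].x_solute == pytest.approx(single.x_solute, rel=1e-6)
        # both eutectics exist and lie on the cocrystal line
        for eut in (tpd.eutectic_api_cc, tpd.eutectic_cf_cc):
            assert eut is not None
            back = (eut.x_api ** cc.nu_api) * (eut.x_cf ** cc.nu_cf)
            assert back > 0
            assert max(abs(r) for r in eut.residuals) < 1e-6
        # cocrystal segment is clipped between the eutectics
        for x_api, x_cf, _, _ in tpd.cc_line.points:
            assert x_cf >= tpd.eutectic_api_cc.x_cf * (1 - 1e-9)
            assert x_api >= tpd.eutectic_cf_cc.x_api * (1 - 1e-9)
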