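"""Equation of state: combining rules, association, density, activity."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cocrysol.params import ParameterDB
from cocrysol.pcsaft import (
    MixtureState,
    PcSaft,
    combine_association,
    combine_sigma,
    combine_u,
    residual_helmholtz,
    solve_density,
)

T_REF = 298.15
P_ATM = 101325.0


class TestCombiningRules:
    def test_sigma_arithmetic_mean(self):
        # ethanol/ethyl acetate diameters
        assert combine_sigma(3.1771, 3.3079) == pytest.approx(3.2425, abs=1e-12)

    @given(st.floats(1.0, 5.0))
    @settings(max_examples=20, deadline=None)
    def test_sigma_identity_and_symmetry(self, s):
        assert combine_sigma(s, s) == s
        assert combine_sigma(s, 2.5) == combine_sigma(2.5, s)

    def test_u_geometric_mean(self):
        # ethanol/water dispersion energies
        expect = math.sqrt(198.24 * 353.94)
        assert combine_u(198.24, 353.94, 0.0) == pytest.approx(expect, abs=1e-12)
        assert combine_u(198.24, 353.94, -0.0382) == pytest.approx(1.0382 * expect, abs=1e-9)
        assert combine_u(198.24, 353.94, 1.0) == 0.0

    def test_association_self_combination_is_identity(self, db):
        eth = db.component("ethanol")
        eps, kap = combine_association(eth, eth)
        assert eps == eth.assoc_energy
        assert kap == pytest.approx(eth.assoc_volume, abs=1e-15)

    def test_association_induced_cross(self, db):
        eth, mecn = db.component("ethanol"), db.component("acetonitrile")
        eps, kap = combine_association(eth, mecn)
        assert eps == pytest.approx(0.5 * 2653.4, abs=1e-9)
        s_fac = (math.sqrt(3.1771 * 3.1898) / (0.5 * (3.1771 + 3.1898))) ** 3
        assert kap == pytest.approx(math.sqrt(0.03284 * 0.01) * s_fac, abs=1e-12)

    def test_association_symmetry(self, db):
        a, b = db.component("NA"), db.component("water")
        assert combine_association(a, b) == combine_association(b, a)

    def test_association_needs_sites(self, db):
        no_sites = db.component("ethanol").model_copy(
            update={"n_donor_sites": 0, "n_acceptor_sites": 0, "assoc_energy": 0.0}
        )
        with pytest.raises(ValueError):
            combine_association(no_sites, no_sites)


class TestAssociationTerm:
    def test_pure_induced_component_has_no_association(self, db):
        # an induced associator alone has zero bonding strength
        state = MixtureState(T_REF, P_ATM, ("ethyl_acetate",), (1.0,))
        eos = residual_helmholtz(db, state, 0.4)
        assert eos.helmholtz_contributions["association"] == 0.0
        assert all(x == 1.0 for x in eos.association_fractions.values())

    def test_induced_pair_mixture_has_no_association(self, db):
        # two induced associators cannot cross-bond: the cross energy is zero
        state = MixtureState(T_REF, P_ATM, ("ethyl_acetate", "acetonitrile"), (0.5, 0.5))
        eos = residual_helmholtz(db, state, 0.4)
        assert eos.helmholtz_contributions["association"] == 0.0

    def test_two_site_closed_form(self, db):
        # one-donor/one-acceptor pure fluid: X solves X = 1/(1 + rho X Delta)
        m = PcSaft(db, ["ethanol"])
        eta = m.solve_density(T_REF, P_ATM, [1.0])
        rho = m._eta_to_rho(T_REF, eta, [1.0])
        a = m.a_res(T_REF, rho, np.array([1.0]))
        td = m._tdata(T_REF)
        d = td["d"][0]
        z2 = math.pi / 6 * rho * m.m[0] * d**2
        z3 = eta
        g = (
            1 / (1 - z3)
            + (d / 2) * 3 * z2 / (1 - z3) ** 2
            + (d / 2) ** 2 * 2 * z2**2 / (1 - z3) ** 3
        )
        delta = td["pref"][0, 0] * g
        x_closed = (-1 + math.sqrt(1 + 4 * rho * delta)) / (2 * rho * delta)
        assert complex(a.XD[0]).real == pytest.approx(x_closed, rel=1e-12)
        assert a.association.real == pytest.approx(2 * (math.log(x_closed) - x_closed / 2 + 0.5), rel=1e-12)
        assert a.association.real < 0

    def test_symmetric_site_counts_give_equal_fractions(self, db):
        # SA carries two donors and two acceptors of equal strength
        state = MixtureState(T_REF, P_ATM, ("SA",), (1.0,))
        eos = residual_helmholtz(db, state, 0.45)
        assert eos.association_fractions["SA:donor"] == pytest.approx(
            eos.association_fractions["SA:acceptor"], rel=1e-12
        )

    def test_fractions_in_unit_interval_and_monotone_in_density(self, db):
        m = PcSaft(db, ["ethanol", "water"])
        x = np.array([0.4, 0.6])
        prev = None
        for eta in np.linspace(0.05, 0.55, 11):
            rho = m._eta_to_rho(T_REF, eta, x)
            a = m.a_res(T_REF, rho, x)
            frac = np.concatenate([np.real(a.XD), np.real(a.XA)])
            assert np.all(frac > 0.0) and np.all(frac <= 1.0)
            if prev is not None:
                assert np.all(frac <= prev + 1e-12)
            prev = frac


class TestHelmholtzAdditivity:
    @pytest.mark.parametrize(
        "ids,x",
        [
            (("ethanol",), (1.0,)),
            (("ethanol", "water"), (0.3, 0.7)),
            (("NA", "SA", "ethanol", "water"), (0.01, 0.005, 0.5, 0.485)),
        ],
    )
    def test_contributions_sum_to_total(self, db, ids, x):
        state = MixtureState(T_REF, P_ATM, ids, x)
        eos = residual_helmholtz(db, state, 0.4)
        c = eos.helmholtz_contributions
        total = c["hard_chain"] + c["dispersion"] + c["association"]
        assert eos.residual_helmholtz == total  # defined as the sum
        assert all(np.isfinite(v) for v in c.values())


class TestDensitySolver:
    def test_pressure_consistency(self, db):
        for ids, x in [(("water",), (1.0,)), (("ethanol", "water"), (0.4, 0.6))]:
            state = MixtureState(T_REF, P_ATM, ids, x)
            m = PcSaft(db, ids)
            eta = m.solve_density(T_REF, P_ATM, np.array(x), phase="liquid")
            rho = m._eta_to_rho(T_REF, eta, np.array(x))
            assert abs(m.pressure(T_REF, rho, np.array(x)) - P_ATM) / P_ATM < 1e-9

    def test_liquid_denser_than_vapor(self, db):
        m = PcSaft(db, ["water"])
        eta_l = m.solve_density(T_REF, P_ATM, [1.0], phase="liquid")
        eta_v = m.solve_density(T_REF, P_ATM, [1.0], phase="vapor")
        assert eta_l > eta_v

    def test_water_density_sanity(self, db):
        state = MixtureState(T_REF, P_ATM, ("water",), (1.0,))
        eos = solve_density(db, state, "liquid")
        mass_density = eos.molar_density * 18.015e-3  # kg/m^3
        assert abs(mass_density - 997.0) / 997.0 < 0.15


class TestActivityCoefficients:
    def test_pure_limit(self, db):
        m = PcSaft(db, ["ethanol", "water"])
        gamma, _ = m.activity_coefficients(T_REF, P_ATM, np.array([1.0 - 1e-12, 1e-12]))
        assert abs(gamma[0] - 1.0) < 1e-6
        gamma, _ = m.activity_coefficients(T_REF, P_ATM, np.array([1e-12, 1.0 - 1e-12]))
        assert abs(gamma[1] - 1.0) < 1e-6

    def test_identical_species_split_is_ideal(self, db):
        # formally splitting one component into two identical species must
        # give unit activity coefficients at any split ratio
        eth = db.component("ethanol")
        twin = eth.model_copy(update={"component_id": "ethanol_b"})
        db2 = ParameterDB(components=(eth, twin))
        m = PcSaft(db2, ["ethanol", "ethanol_b"])
        for split in (0.2, 0.5, 0.9):
            gamma, _ = m.activity_coefficients(T_REF, P_ATM, np.array([split, 1 - split]))
            assert np.allclose(gamma, 1.0, atol=1e-8)

    def test_gibbs_duhem_closure(self, db):
        m = PcSaft(db, ["ethanol", "water"])
        h = 2e-5

        def ln_gamma(x1):
            g, _ = m.activity_coefficients(T_REF, P_ATM, np.array([x1, 1 - x1]))
            return np.log(g)

        for x1 in (0.2, 0.5, 0.8):
            d = (ln_gamma(x1 + h) - ln_gamma(x1 - h)) / (2 * h)
            residual = x1 * d[0] + (1 - x1) * d[1]
            scale = max(abs(d[0]), abs(d[1]), 1.0)
            assert abs(residual) / scale < 1e-6

    def test_chemical_potential_matches_finite_differences(self, db):
        m = PcSaft(db, ["ethanol", "water"])
        x = np.array([0.3, 0.7])
        eta = m.solve_density(T_REF, P_ATM, x)
        rho = m._eta_to_rho(T_REF, eta, x)
        h = 1e-6
        for i in range(2):
            xp, xm = x.copy(), x.copy()
            xp[i] += h
            xm[i] -= h
            fd = (m.a_res(T_REF, rho, xp).total.real - m.a_res(T_REF, rho, xm).total.real) / (2 * h)
            xc = x.astype(complex)
            xc[i] += 1j * 1e-20
            exact = m.a_res(T_REF, rho, xc).total.imag / 1e-20
            assert abs(fd - exact) / abs(fd) < 1e-6


class TestMixtureState:
    def test_rejects_unnormalized_composition(self):
        with pytest.raises(ValueError, match="sum"):
            MixtureState(298.15, 101325.0, ("a", "b"), (0.5, 0.6))

    def test_rejects_negative_fraction(self):
        with pytest.raises(ValueError):
            MixtureState(298.15, 101325.0, ("a", "b"), (-0.1, 1.1))

    def test_rejects_nonpositive_temperature(self):
        with pytest.raises(ValueError):
            MixtureState(-1.0, 101325.0, ("a",), (1.0,))
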