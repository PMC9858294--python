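import dataclasses

import numpy as np
import pytest

import mortnet as mn
from mortnet.data_io import ValidationError
from mortnet.sir_network import EpidemicConfig, FullModelParams, SIRState

from conftest import random_flux


@pytest.fixture(scope="module")
def regions():
    return mn.generate_regions(5, seed=40)


def zero_flux(regions):
    n = regions.n
    return mn.FluxMatrix(region_ids=list(regions.region_ids),
                         values=np.zeros((n, n)), kind="total")


class TestMixingMatrices:
    def test_zero_flux_gives_identity(self, regions):
        mix = mn.mixing_matrices(zero_flux(regions), regions)
        np.testing.assert_array_equal(mix.phi, np.eye(5))
        np.testing.assert_array_equal(mix.phi_hat, np.eye(5))

    def test_columns_sum_to_one(self, regions):
        rng = np.random.default_rng(41)
        for _ in range(20):
            mix = mn.mixing_matrices(random_flux(regions, rng), regions)
            np.testing.assert_allclose(mix.phi.sum(axis=0), 1.0, atol=1e-12)
            np.testing.assert_allclose(mix.phi_hat.sum(axis=0), 1.0, atol=1e-12)
            assert np.all(mix.phi >= 0) and np.all(mix.phi_hat >= 0)

    def test_diagonal_is_one_minus_outflow(self, regions):
        rng = np.random.default_rng(42)
        flux = random_flux(regions, rng)
        mix = mn.mixing_matrices(flux, regions)
        outflow = flux.values.sum(axis=0) / regions.populations
        np.testing.assert_allclose(np.diag(mix.phi), 1.0 - outflow)

    def test_excess_outflow_rejected(self, regions):
        n = regions.n
        values = np.zeros((n, n))
        values[1, 0] = regions.populations[0] * 1.5
        flux = mn.FluxMatrix(region_ids=list(regions.region_ids),
                             values=values, kind="total")
        with pytest.raises(ValidationError, match="outflow"):
            mn.mixing_matrices(flux, regions)


class TestBetaOfTemperature:
    def test_vanishes_at_high_temperature(self):
        assert mn.beta_of_temperature(1e6, 0.1, 0.0) == pytest.approx(0.0)

    def test_cap_just_below_inverse_dt(self):
        b = mn.beta_of_temperature(0.0, 0.1, 10.0, dt=1.0)
        assert b < 1.0
        assert b == pytest.approx(1.0, abs=1e-8)

    def test_point_value(self):
        assert mn.beta_of_temperature(5.0, 0.1, -1.0) \
            == pytest.approx(np.exp(-1.5), rel=1e-12)

    def test_monotone_nonincreasing(self):
        T = np.linspace(-20, 40, 100)
        b = mn.beta_of_temperature(T, 0.08, 1.0)
        assert np.all(np.diff(b) <= 0)


class TestSirStep:
    def one_region(self):
        return mn.RegionTable(
            region_ids=["A", "B"], names=["a", "b"],
            populations=np.array([1000.0, 1000.0]),
            gdps=np.array([1.0, 1.0]),
            lats=np.array([40.0, 42.0]), lons=np.array([10.0, 12.0]),
        )

    def test_hand_computed_euler_step(self):
        # identity mixing, S=999, I=1, pop=1000, beta=0.5, gamma=0.1:
        # dI = 0.5*999*1/1000 = 0.4995
        regions = self.one_region()
        mix = mn.mixing_matrices(zero_flux(regions), regions)
        state = SIRState(S=np.array([999.0, 1000.0]),
                         I=np.array([1.0, 0.0]), R=np.zeros(2))
        cfg = EpidemicConfig(beta=np.array([0.5, 0.5]), gamma=0.1, i0=0)
        out = mn.sir_step(state, mix, cfg, regions)
        assert out.S[0] == pytest.approx(998.5005, abs=1e-12)
        assert out.I[0] == pytest.approx(1.3995, abs=1e-12)
        assert out.R[0] == pytest.approx(0.1, abs=1e-12)

    def test_null_dynamics_fixed_point(self, regions):
        rng = np.random.default_rng(43)
        mix = mn.mixing_matrices(random_flux(regions, rng), regions)
        state = SIRState(S=regions.populations - 5.0,
                         I=np.full(5, 5.0), R=np.zeros(5))
        cfg = EpidemicConfig(beta=np.zeros(5), gamma=0.0, i0=0)
        out = mn.sir_step(state, mix, cfg, regions)
        np.testing.assert_array_equal(out.S, state.S)
        np.testing.assert_array_equal(out.I, state.I)

    def test_step_conserves_population(self, regions):
        rng = np.random.default_rng(44)
        for _ in range(10):
            mix = mn.mixing_matrices(random_flux(regions, rng), regions)
            state = SIRState(S=regions.populations - 1.0,
                             I=np.ones(5), R=np.zeros(5))
            cfg = EpidemicConfig(beta=rng.uniform(0, 0.9, 5),
                                 gamma=rng.uniform(0, 0.5), i0=0)
            out = mn.sir_step(state, mix, cfg, regions)
            assert out.total() == pytest.approx(state.total(), rel=1e-12)

    def test_beta_cap_enforced(self):
        with pytest.raises(ValidationError, match="beta"):
            EpidemicConfig(beta=np.array([1.0]), gamma=0.1)


class TestMonthlyEpidemic:
    def test_beta_zero_matches_scalar_recursion(self, regions, truth6):
        params = dataclasses.replace(
            truth6.true_model, rho0=truth6.true_model.rho0[:5],
            b_beta=-80.0)  # beta ~ e^-80: effectively zero
        rng = np.random.default_rng(45)
        flux = random_flux(regions, rng)
        r30 = mn.run_monthly_epidemic(np.full(5, 10.0), 2, flux, params, regions)
        # only the single infected decays: sum R(30) = 1 - (1-gamma)^30
        expected = 1.0 - (1.0 - params.gamma) ** 30
        assert r30.sum() == pytest.approx(expected, abs=1e-12)

    def test_zero_flux_decouples_regions(self, regions, truth6):
        params = dataclasses.replace(truth6.true_model,
                                     rho0=truth6.true_model.rho0[:5])
        r30 = mn.run_monthly_epidemic(np.full(5, 2.0), 3, zero_flux(regions),
                                      params, regions)
        others = np.arange(5) != 3
        np.testing.assert_array_equal(r30[others], 0.0)
        assert r30[3] > 0

    def test_single_region_matches_scalar_euler_loop(self, truth6):
        rt = mn.generate_regions(2, seed=46)
        params = dataclasses.replace(truth6.true_model,
                                     rho0=truth6.true_model.rho0[:2])
        r30 = mn.run_monthly_epidemic(np.array([5.0, 5.0]), 0,
                                      zero_flux(rt), params, rt)
        beta = float(mn.beta_of_temperature(5.0, params.a_beta, params.b_beta))
        pop = rt.populations[0]
        S, I, R = pop - 1.0, 1.0, 0.0
        for _ in range(30):
            dI = beta * S * I / pop
            rec = params.gamma * I
            S, I, R = S - dI, I + dI - rec, R + rec
        assert r30[0] == pytest.approx(R, rel=1e-12)

    def test_two_region_symmetric_flux_oracle(self):
        # strong symmetric flux, equal pops and temps: an independent
        # plain-loop implementation must agree to 1e-10
        rt = mn.RegionTable(
            region_ids=["A", "B"], names=["a", "b"],
            populations=np.array([1e6, 1e6]), gdps=np.array([1.0, 1.0]),
            lats=np.array([40.0, 42.0]), lons=np.array([10.0, 12.0]),
        )
        f = np.array([[0.0, 1.5e5], [1.5e5, 0.0]])
        flux = mn.FluxMatrix(region_ids=["A", "B"], values=f, kind="total")
        params = FullModelParams(
            a_h=0.1, b_h=-11.0, rho0=np.array([100.0, 100.0]),
            kappa_e=0.0, d0_e=300.0, mu=0.1,
            a_beta=0.08, b_beta=-0.2, gamma=0.3,
        )
        r30 = mn.run_monthly_epidemic(np.array([5.0, 5.0]), 0, flux, params, rt)

        # independent straightforward re-implementation
        pops = rt.populations
        phi = f / pops
        np.fill_diagonal(phi, 1.0 - f.sum(axis=0) / pops)
        phi_hat = (phi / phi.sum(axis=1)[:, None]).T
        beta = float(mn.beta_of_temperature(5.0, params.a_beta, params.b_beta))
        S = pops.astype(float).copy(); S[0] -= 1
        I = np.array([1.0, 0.0]); R = np.zeros(2)
        for _ in range(30):
            dI_pool = np.empty(2)
            for l in range(2):
                dI_pool[l] = beta / pops[l] * (phi[l] @ S) * (phi[l] @ I)
            new_I = phi_hat @ dI_pool
            rec = params.gamma * I
            S = S - new_I
            I = I + new_I - rec
            R = R + rec
        np.testing.assert_allclose(r30, R, rtol=1e-10)
        assert r30[0] / r30[1] == pytest.approx(R[0] / R[1], rel=1e-10)

    def test_total_recovered_monotone_in_beta(self, regions, truth6):
        rng = np.random.default_rng(47)
        flux = random_flux(regions, rng)
        params = dataclasses.replace(truth6.true_model,
                                     rho0=truth6.true_model.rho0[:5])
        totals = []
        for b_beta in np.linspace(-2.0, 0.5, 6):
            p = dataclasses.replace(params, b_beta=b_beta)
            totals.append(mn.run_monthly_epidemic(
                np.full(5, 8.0), 1, flux, p, regions).sum())
        assert np.all(np.diff(totals) >= -1e-9)

    def test_recovered_bounded_by_population(self, regions, truth6):
        rng = np.random.default_rng(48)
        params = dataclasses.replace(truth6.true_model,
                                     rho0=truth6.true_model.rho0[:5])
        for _ in range(5):
            flux = random_flux(regions, rng)
            r30 = mn.run_monthly_epidemic(rng.uniform(-5, 25, 5),
                                          int(rng.integers(5)), flux,
                                          params, regions)
            assert np.all(r30 >= 0)
            assert r30.sum() <= regions.populations.sum()


class TestPatientZero:
    def test_equal_gdps_uniform(self):
        rt = mn.RegionTable(
            region_ids=list("ABCD"), names=list("abcd"),
            populations=np.ones(4), gdps=np.ones(4),
            lats=np.array([38.0, 40, 42, 44]), lons=np.array([8.0, 10, 12, 14]),
        )
        np.testing.assert_allclose(mn.patient_zero_distribution(rt), 0.25)

    def test_proportional_to_gdp(self):
        rt = mn.RegionTable(
            region_ids=list("ABC"), names=list("abc"),
            populations=np.ones(3), gdps=np.array([2.0, 1.0, 1.0]),
            lats=np.array([38.0, 40, 42]), lons=np.array([8.0, 10, 12]),
        )
        np.testing.assert_allclose(mn.patient_zero_distribution(rt),
                                   [0.5, 0.25, 0.25])

    def test_normalised(self, regions):
        assert mn.patient_zero_distribution(regions).sum() \
            == pytest.approx(1.0, abs=1e-15)


class TestExpectedDeaths:
    def test_component_isolation(self, regions, truth6):
        rng = np.random.default_rng(49)
        flux = random_flux(regions, rng)
        rho0 = np.array([100.0, 200.0, 300.0, 400.0, 500.0])
        base = dataclasses.replace(truth6.true_model, rho0=rho0)
        temps = np.full(5, 10.0)
        # mu = 0 and negligible warm arm -> lambda = rho0
        p1 = dataclasses.replace(base, mu=0.0, b_h=-60.0)
        np.testing.assert_allclose(
            mn.expected_deaths(temps, 0, flux, p1, regions), rho0)
        # rho0 = 0, mu = 0 -> pure warm arm
        p2 = dataclasses.replace(base, mu=0.0, rho0=np.zeros(5))
        expected = regions.populations * np.exp(p2.a_h * temps + p2.b_h)
        np.testing.assert_allclose(
            mn.expected_deaths(temps, 0, flux, p2, regions), expected)

    def test_additivity_of_components(self, regions, truth6):
        rng = np.random.default_rng(50)
        flux = random_flux(regions, rng)
        params = dataclasses.replace(truth6.true_model,
                                     rho0=truth6.true_model.rho0[:5])
        temps = np.full(5, 4.0)
        lam = mn.expected_deaths(temps, 2, flux, params, regions)
        warm = regions.populations * np.exp(params.a_h * temps + params.b_h)
        r30 = mn.run_monthly_epidemic(temps, 2, flux, params, regions)
        np.testing.assert_allclose(lam, warm + params.rho0 + params.mu * r30,
                                   rtol=1e-12)

    def test_all_zero_lambda_rejected(self, regions):
        params = FullModelParams(
            a_h=0.1, b_h=-800.0, rho0=np.zeros(5),
            kappa_e=0.0, d0_e=300.0, mu=0.0,
            a_beta=0.08, b_beta=-0.2, gamma=0.3,
        )
        with pytest.raises(ValidationError, match="not positive"):
            mn.expected_deaths(np.full(5, 10.0), 0, zero_flux(regions),
                               params, regions)


class TestConservation:
    def test_long_trajectories_conserve_population(self, regions, truth6):
        rng = np.random.default_rng(51)
        params = dataclasses.replace(truth6.true_model,
                                     rho0=truth6.true_model.rho0[:5])
        total_pop = regions.populations.sum()
        for _ in range(10):
            flux = random_flux(regions, rng)
            mix = mn.mixing_matrices(flux, regions)
            temps = rng.uniform(-5, 25, 5)
            i0 = int(rng.integers(5))
            from mortnet.sir_network import _euler_sweep, beta_of_temperature
            S = regions.populations.astype(float).copy(); S[i0] -= 1
            I = np.zeros(5); I[i0] = 1.0
            beta = beta_of_temperature(temps, params.a_beta, params.b_beta)
            S, I, R = _euler_sweep(S, I, np.zeros(5), mix.phi, mix.phi_hat,
                                   beta, params.gamma, regions.populations,
                                   1.0, 30)
            assert (S + I + R).sum() == pytest.approx(total_pop, rel=1e-9)
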