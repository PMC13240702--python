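"""Compartmental mass-balance simulation and derived exposure metrics."""

import math

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from residuecrop.dissipation import ResidueObservation, ResidueSeries
from residuecrop.errors import NumericalError, TooFewPointsError, ValidationError
from residuecrop.uptake import (
    SINK,
    Compartment,
    ModelParameterization,
    RateMatrix,
    build_rate_matrix,
    default_time_grid,
    grain_fraction,
    harvest_fraction,
    harvest_metrics,
    intake_fraction,
    model_field_agreement,
    residence_time,
    simulate,
    source_contributions,
    to_concentration,
    translocation_factor,
)

from .conftest import random_rate_matrix

C = Compartment


def decay_only_params(rates: dict) -> ModelParameterization:
    return ModelParameterization(
        degradation_rate=rates, transfer_rate={}, application_split={}
    )


class TestBuildRateMatrix:
    def test_single_compartment_decay(self):
        K = build_rate_matrix(decay_only_params({C.SOIL: 0.1})).K
        i = list(C).index(C.SOIL)
        assert K[i, i] == pytest.approx(-0.1)
        assert K[-1, i] == pytest.approx(0.1)
        assert np.allclose(K.sum(axis=0), 0.0)

    def test_symmetric_transfer_equilibrates_evenly(self):
        params = ModelParameterization(
            degradation_rate={},
            transfer_rate={(C.SOIL, C.ROOT): 0.2, (C.ROOT, C.SOIL): 0.2},
        )
        K = build_rate_matrix(params)
        sim = simulate(K, {C.SOIL: 1.0}, np.linspace(0.0, 200.0, 50))
        assert np.allclose(K.K.sum(axis=0), 0.0)
        assert sim.trajectory(C.SOIL)[-1] == pytest.approx(0.5, abs=1e-9)
        assert sim.trajectory(C.ROOT)[-1] == pytest.approx(0.5, abs=1e-9)

    def test_fixture_dominant_eigenvalue_below_fastest_process(
        self, diflufenican_params
    ):
        # the slowest (dominant non-sink) mode must be slower than any
        # single compartment's total outflow rate
        K = build_rate_matrix(diflufenican_params).K
        eig = np.linalg.eigvals(K[:-1, :-1])
        dominant = np.abs(np.real(eig)).min()
        outflows = -np.diag(K)[:-1]
        assert dominant < outflows[outflows > 0].min()

    def test_invalid_parameterization_lists_all_violations(self):
        params = ModelParameterization(
            degradation_rate={C.SOIL: -1.0},
            transfer_rate={(C.LEAF, C.LEAF): 0.1},
            applied_dose_g_per_ha=-5.0,
        )
        with pytest.raises(ValidationError) as err:
            build_rate_matrix(params)
        assert len(err.value.violations) == 3

    def test_rate_matrix_rejects_nonzero_column_sums(self):
        bad = np.zeros((9, 9))
        bad[0, 0] = -0.5  # outflow with no destination
        with pytest.raises(ValidationError):
            RateMatrix(K=bad)


class TestSimulate:
    def test_pure_decay_half_life(self):
        K = build_rate_matrix(decay_only_params({C.SOIL: math.log(2.0)}))
        sim = simulate(K, {C.SOIL: 1.0}, [0.0, 1.0])
        assert sim.trajectory(C.SOIL)[-1] == pytest.approx(0.5, abs=1e-12)
        assert sim.trajectory(SINK)[-1] == pytest.approx(0.5, abs=1e-12)

    def test_zero_matrix_is_identity(self):
        K = build_rate_matrix(decay_only_params({}))
        sim = simulate(K, {C.AIR: 0.3, C.SOIL: 0.7}, [0.0, 5.0, 50.0])
        assert np.allclose(sim.trajectory(C.AIR), 0.3)
        assert np.allclose(sim.trajectory(C.SOIL), 0.7)

    def test_mass_conserved_to_1e9(self, diflufenican_sim):
        totals = diflufenican_sim.mass.sum(axis=0)
        assert np.max(np.abs(totals - 1.0)) < 1e-9

    def test_all_masses_non_negative(self, diflufenican_sim):
        assert diflufenican_sim.mass.min() >= 0.0

    def test_leaf_has_single_interior_maximum(self, diflufenican_sim):
        leaf = diflufenican_sim.trajectory(C.LEAF)
        i_peak = int(np.argmax(leaf))
        assert 0 < i_peak < leaf.size - 1
        d = np.diff(leaf)
        assert np.all(d[:i_peak] > 0) and np.all(d[i_peak:] < 0)

    def test_matches_adaptive_ode_oracle_on_random_systems(self):
        rng = np.random.default_rng(2024)
        grid = np.array([0.0, 0.3, 1.0, 2.0, 5.0])
        for _ in range(5):
            K = random_rate_matrix(rng)
            rm = RateMatrix(K=K)
            m0 = rng.dirichlet(np.ones(9))
            sim = simulate(rm, m0, grid)
            ode = solve_ivp(
                lambda t, m: K @ m,
                (0.0, grid[-1]),
                m0,
                t_eval=grid,
                method="DOP853",
                rtol=1e-12,
                atol=1e-14,
            )
            assert np.allclose(sim.mass, ode.y, rtol=1e-8, atol=1e-12)

    def test_uncoupled_limit_is_closed_form_exponential(self):
        rates = {C.SOIL: 0.05, C.LEAF: 0.8, C.ROOT: 0.2}
        K = build_rate_matrix(decay_only_params(rates))
        grid = np.linspace(0.0, 10.0, 21)
        sim = simulate(K, {C.SOIL: 0.5, C.LEAF: 0.3}, grid)
        assert np.allclose(sim.trajectory(C.SOIL), 0.5 * np.exp(-0.05 * grid), rtol=1e-12)
        assert np.allclose(sim.trajectory(C.LEAF), 0.3 * np.exp(-0.8 * grid), rtol=1e-12)
        assert np.allclose(sim.trajectory(C.ROOT), 0.0)

    def test_bad_grid_rejected(self):
        K = build_rate_matrix(decay_only_params({}))
        with pytest.raises(ValidationError):
            simulate(K, {C.SOIL: 1.0}, [1.0, 2.0])  # does not start at 0
        with pytest.raises(ValidationError):
            simulate(K, {C.SOIL: 1.0}, [0.0, 2.0, 2.0])  # not strictly increasing


class TestSourceContributions:
    def test_single_source_accounts_for_everything(self, diflufenican_params):
        K = build_rate_matrix(diflufenican_params)
        grid = default_time_grid(t_max=100.0, n=80)
        sim = source_contributions(K, {C.SOIL: 1.0}, grid)
        assert np.allclose(sim.source_decomposition[C.SOIL], sim.mass)

    def test_symmetric_split_gives_equal_contributions(self):
        params = ModelParameterization(
            degradation_rate={C.SOIL: 0.1, C.AIR: 0.1},
            transfer_rate={(C.SOIL, C.ROOT): 0.05, (C.AIR, C.ROOT): 0.05},
        )
        K = build_rate_matrix(params)
        sim = source_contributions(
            K, {C.SOIL: 0.5, C.AIR: 0.5}, np.linspace(0.0, 20.0, 11)
        )
        a = sim.source_decomposition[C.SOIL][K.index(C.ROOT)]
        b = sim.source_decomposition[C.AIR][K.index(C.ROOT)]
        assert np.allclose(a, b)

    def test_superposition_reconstructs_full_solution(
        self, diflufenican_params, diflufenican_sim
    ):
        K = build_rate_matrix(diflufenican_params)
        sim = source_contributions(
            K, diflufenican_params.application_split, diflufenican_sim.time_grid
        )
        total = sum(sim.source_decomposition.values())
        assert np.max(np.abs(total - sim.mass)) < 1e-9
        # and the decomposition agrees with a direct single simulation
        assert np.max(np.abs(sim.mass - diflufenican_sim.mass)) < 1e-9


class TestHarvestAndIntake:
    def test_pure_decay_harvest_fraction(self):
        K = build_rate_matrix(decay_only_params({C.GRAIN: math.log(2.0)}))
        sim = simulate(K, {C.GRAIN: 1.0}, np.linspace(0.0, 2.0, 41))
        assert harvest_fraction(sim, C.GRAIN, 1.0) == pytest.approx(0.5, rel=1e-9)

    def test_nonsource_compartment_empty_at_t0(self, diflufenican_sim):
        assert harvest_fraction(diflufenican_sim, C.GRAIN, 0.0) == 0.0

    def test_fixture_grain_peak_near_published_magnitude(self, diflufenican_sim):
        # the shipped fixture is tuned so the grain harvest fraction
        # peaks around 5.5e-2 between days 10 and 30
        grain = diflufenican_sim.trajectory(C.GRAIN)
        i = int(np.argmax(grain))
        t_peak = diflufenican_sim.time_grid[i]
        assert 10.0 < t_peak < 30.0
        assert grain[i] == pytest.approx(5.5e-2, rel=0.05)

    def test_intake_fraction_applies_processing_factor(self, diflufenican_sim):
        grain_peak = float(diflufenican_sim.trajectory(C.GRAIN).max())
        i_f = intake_fraction(grain_peak, 0.33)
        assert i_f == pytest.approx(1.8e-2, rel=0.05)
        assert intake_fraction(0.0) == 0.0
        assert intake_fraction(0.25, 1.0) == 0.25

    def test_intake_fraction_domain_errors(self):
        with pytest.raises(ValidationError):
            intake_fraction(1.5)
        with pytest.raises(ValidationError):
            intake_fraction(0.5, 0.0)

    def test_peak_at_least_harvest_mass(self, diflufenican_sim, diflufenican_params):
        metrics = harvest_metrics(diflufenican_sim, diflufenican_params)
        peak, _ = metrics.peak_mass[C.GRAIN.value]
        assert peak >= metrics.hf
        assert metrics.intake_fraction == pytest.approx(0.33 * metrics.hf, rel=1e-12)


class TestTranslocationFactor:
    def _sim_with_masses(self, leaf, stem, root):
        params = ModelParameterization(
            degradation_rate={},
            transfer_rate={},
            biomass={C.LEAF: 1.0, C.STEM: 1.0, C.ROOT: 1.0, C.GRAIN: 1.0},
        )
        K = build_rate_matrix(params)
        init = {C.LEAF: leaf, C.STEM: stem, C.ROOT: root}
        sim = simulate(K, {c: m for c, m in init.items() if m > 0}, [0.0, 1.0])
        return sim, params

    def test_equal_concentrations_give_two(self):
        sim, params = self._sim_with_masses(0.2, 0.2, 0.2)
        assert translocation_factor(sim, params, 1.0) == pytest.approx(2.0)

    def test_empty_shoot_gives_zero(self):
        sim, params = self._sim_with_masses(0.0, 0.0, 0.4)
        assert translocation_factor(sim, params, 1.0) == 0.0

    def test_zero_root_concentration_is_undefined(self):
        sim, params = self._sim_with_masses(0.3, 0.3, 0.0)
        with pytest.raises(ValidationError):
            translocation_factor(sim, params, 1.0)

    def test_fixture_soil_route_plateaus_at_tuned_value(self, diflufenican_params):
        # soil application: TF rises to a plateau ~4.5 by day ~100 and
        # stays there (slowest-mode quasi-steady state)
        K = build_rate_matrix(diflufenican_params)
        sim = simulate(K, {C.SOIL: 1.0}, default_time_grid())
        tf_150 = translocation_factor(sim, diflufenican_params, 150.0)
        tf_300 = translocation_factor(sim, diflufenican_params, 300.0)
        assert tf_300 == pytest.approx(4.5, abs=0.1)
        assert tf_300 == pytest.approx(tf_150, rel=0.01)

    def test_flufenacet_like_translocates_more(
        self, diflufenican_params, flufenacet_params
    ):
        grid = default_time_grid()
        tf = {}
        for params in (diflufenican_params, flufenacet_params):
            K = build_rate_matrix(params)
            sim = simulate(K, {C.SOIL: 1.0}, grid)
            tf[params.name] = translocation_factor(sim, params, 250.0)
        assert tf["flufenacet_like"] > tf["diflufenican_like"]


class TestResidenceTime:
    def test_single_exponential_equals_inverse_rate(self):
        K = build_rate_matrix(decay_only_params({C.GRAIN: 0.05}))
        sim = simulate(K, {C.GRAIN: 1.0}, np.linspace(0.0, 100.0, 101))
        assert residence_time(sim, C.GRAIN) == pytest.approx(20.0, rel=1e-3)

    def test_cascade_tail_follows_slowest_eigenvalue(self):
        # fast surface penetration feeding a grain pool that drains at
        # 1/16.27 per day: the terminal slope must recover 16.27 days
        params = ModelParameterization(
            degradation_rate={C.GRAIN: 1.0 / 16.27},
            transfer_rate={(C.GRAIN_SURFACE, C.GRAIN): 1.0},
        )
        K = build_rate_matrix(params)
        sim = simulate(K, {C.GRAIN_SURFACE: 1.0}, np.linspace(0.0, 300.0, 301))
        assert residence_time(sim, C.GRAIN) == pytest.approx(16.27, rel=1e-3)

    def test_constant_trajectory_rejected(self):
        K = build_rate_matrix(decay_only_params({}))
        sim = simulate(K, {C.SOIL: 1.0}, np.linspace(0.0, 10.0, 21))
        with pytest.raises(ValidationError):
            residence_time(sim, C.SOIL)

    def test_grain_is_slowest_decaying_crop_compartment(
        self, diflufenican_sim, flufenacet_params
    ):
        crops = (C.LEAF, C.GRAIN, C.STEM, C.ROOT)
        taus = {c: residence_time(diflufenican_sim, c) for c in crops}
        assert max(taus, key=taus.get) is C.GRAIN
        K = build_rate_matrix(flufenacet_params)
        sim = simulate(K, flufenacet_params.application_split, default_time_grid())
        taus = {c: residence_time(sim, c) for c in crops}
        assert max(taus, key=taus.get) is C.GRAIN


class TestGrainFraction:
    def test_all_residue_in_grain(self):
        K = build_rate_matrix(decay_only_params({C.GRAIN: 0.1}))
        sim = simulate(K, {C.GRAIN: 1.0}, [0.0, 1.0])
        assert grain_fraction(sim, 1.0, "total_crop_residue") == pytest.approx(1.0)

    def test_applied_mass_denominator_is_raw_mass(self, diflufenican_sim):
        t = diflufenican_sim.time_grid[120]
        grain = float(diflufenican_sim.trajectory(C.GRAIN)[120])
        assert grain_fraction(diflufenican_sim, t, "applied_mass") == pytest.approx(grain)

    def test_crop_fraction_matches_hand_sum(self, diflufenican_sim):
        i = 150
        t = diflufenican_sim.time_grid[i]
        crops = (
            C.LEAF, C.GRAIN, C.STEM, C.ROOT, C.LEAF_SURFACE, C.GRAIN_SURFACE,
        )
        total = sum(float(diflufenican_sim.trajectory(c)[i]) for c in crops)
        expected = float(diflufenican_sim.trajectory(C.GRAIN)[i]) / total
        assert grain_fraction(diflufenican_sim, t, "total_crop_residue") == pytest.approx(
            expected, rel=1e-12
        )

    def test_grain_share_increases_over_the_season(self, diflufenican_sim):
        grid = diflufenican_sim.time_grid
        t10 = grid[np.argmin(np.abs(grid - 10))]
        t30 = grid[np.argmin(np.abs(grid - 30))]
        t100 = grid[np.argmin(np.abs(grid - 100))]
        f = [
            grain_fraction(diflufenican_sim, t, "total_crop_residue")
            for t in (t10, t30, t100)
        ]
        assert f[0] < f[1] < f[2]


class TestConcentrationAndAgreement:
    def test_hand_unit_conversion(self):
        assert to_concentration(1.0, 675.0, 0.5) == pytest.approx(135.0)
        assert to_concentration(0.0, 675.0, 0.5) == 0.0

    def test_doubling_biomass_halves_concentration(self):
        assert to_concentration(0.3, 675.0, 1.0) == pytest.approx(
            to_concentration(0.3, 675.0, 0.5) / 2.0
        )

    def test_domain_errors(self):
        with pytest.raises(ValidationError):
            to_concentration(-0.1, 675.0, 0.5)
        with pytest.raises(ValidationError):
            to_concentration(0.1, 0.0, 0.5)

    def _measured(self, times, values):
        return ResidueSeries(
            "s", "straw", [ResidueObservation(t, v) for t, v in zip(times, values)]
        )

    def test_perfect_agreement_is_one(self):
        times = [1.0, 3.0, 7.0, 14.0]
        model = [5.0, 3.0, 1.5, 0.4]
        assert model_field_agreement(times, model, self._measured(times, model)) == 1.0

    def test_seeded_noise_keeps_r2_high(self):
        rng = np.random.default_rng(7)
        times = np.array([1.0, 3.0, 5.0, 7.0, 14.0, 21.0])
        model = 6.0 * np.exp(-0.2 * times)
        measured = model * rng.lognormal(0.0, 0.05, size=times.size)
        r2 = model_field_agreement(times, model, self._measured(times, measured))
        assert r2 >= 0.95

    def test_constant_measurements_vs_varying_model_non_positive(self):
        times = [1.0, 3.0, 7.0]
        r2 = model_field_agreement(times, [3.0, 2.0, 1.0], self._measured(times, [2.0] * 3))
        assert r2 <= 0.0

    def test_insufficient_pairs_raise(self):
        with pytest.raises(TooFewPointsError):
            model_field_agreement(
                [1.0, 2.0], [1.0, 0.5], self._measured([50.0, 60.0, 70.0], [1, 1, 1])
            )
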