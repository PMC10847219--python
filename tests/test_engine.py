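import numpy as np
import pytest

from apixpbpk.engine import (
    AbsorptionSettings,
    ConcentrationTimeProfile,
    DosingRegimen,
    calibrate_absorption,
    default_time_grid,
    simulate_individual,
    simulate_population,
)
from apixpbpk.physiology import PopulationSpec, sample_population

SHORT_GRID = default_time_grid(48.0, 0.1)


def _single(dose, duration=48.0):
    return DosingRegimen(dose_mg=dose, n_doses=1, interval_h=24.0, duration_h=duration)


class TestSingleSimulation:
    def test_zero_dose_gives_identically_zero_profile(self, reference_adult, apix, apix_kp):
        prof = simulate_individual(reference_adult, apix, apix_kp, _single(0.0), SHORT_GRID)
        assert np.all(prof.conc_ng_per_ml == 0.0)

    def test_concentrations_non_negative_and_grid_preserved(
        self, reference_adult, apix, apix_kp
    ):
        prof = simulate_individual(reference_adult, apix, apix_kp, _single(10.0), SHORT_GRID)
        assert np.all(prof.conc_ng_per_ml >= 0.0)
        assert np.array_equal(prof.times_h, SHORT_GRID)
        assert prof.conc_ng_per_ml.max() > 0

    def test_mass_balance_within_tenth_percent_at_all_times(
        self, reference_adult, apix, apix_kp
    ):
        regimen = DosingRegimen(dose_mg=10.0, n_doses=4, interval_h=12.0, duration_h=60.0)
        _, diag = simulate_individual(
            reference_adult, apix, apix_kp, regimen, default_time_grid(60.0, 0.1),
            full_output=True,
        )
        assert diag.mass_balance_rel_error < 1e-3

    def test_dose_linearity_profile_scales_with_dose(self, reference_adult, apix, apix_kp):
        p10 = simulate_individual(reference_adult, apix, apix_kp, _single(10.0), SHORT_GRID)
        p25 = simulate_individual(reference_adult, apix, apix_kp, _single(25.0), SHORT_GRID)
        assert np.allclose(
            p25.conc_ng_per_ml, 2.5 * p10.conc_ng_per_ml,
            rtol=1e-6, atol=1e-6 * p25.conc_ng_per_ml.max(),
        )

    def test_superposition_of_shifted_single_doses(self, reference_adult, apix, apix_kp):
        tau, n = 12.0, 3
        grid = default_time_grid(48.0, 0.25)
        multi = simulate_individual(
            reference_adult, apix, apix_kp,
            DosingRegimen(dose_mg=10.0, n_doses=n, interval_h=tau, duration_h=48.0), grid,
        )
        single = simulate_individual(reference_adult, apix, apix_kp, _single(10.0), grid)
        expected = np.zeros_like(grid)
        for k in range(n):
            shifted = np.interp(grid - k * tau, grid, single.conc_ng_per_ml, left=0.0)
            expected += shifted
        assert np.allclose(
            multi.conc_ng_per_ml, expected, rtol=5e-4, atol=1e-4 * expected.max()
        )

    def test_grid_must_cover_dose_times(self, reference_adult, apix, apix_kp):
        regimen = DosingRegimen(dose_mg=5.0, n_doses=10, interval_h=12.0, duration_h=120.0)
        with pytest.raises(ValueError, match="cover"):
            simulate_individual(reference_adult, apix, apix_kp, regimen, SHORT_GRID)

    def test_profile_rejects_decreasing_times(self):
        with pytest.raises(ValueError, match="strictly increasing"):
            ConcentrationTimeProfile(np.array([0.0, 2.0, 1.0]), np.array([0.0, 1.0, 2.0]))


class TestPopulationSimulation:
    def test_identical_individuals_collapse_percentiles(self, reference_adult, apix):
        result = simulate_population(
            [reference_adult] * 4, apix, _single(10.0), SHORT_GRID
        )
        assert np.allclose(result.p5_profile.conc_ng_per_ml, result.mean_profile.conc_ng_per_ml)
        assert np.allclose(result.p95_profile.conc_ng_per_ml, result.mean_profile.conc_ng_per_ml)

    def test_mean_is_pointwise_arithmetic_mean(self, reference_adult, apix):
        pop = sample_population(PopulationSpec(n=5, seed=2), reference_adult)
        result = simulate_population(pop, apix, _single(10.0), SHORT_GRID)
        mat = np.vstack([p.conc_ng_per_ml for p in result.individual_profiles])
        assert np.allclose(result.mean_profile.conc_ng_per_ml, mat.mean(axis=0))

    def test_seeded_population_simulation_is_deterministic(self, reference_adult, apix):
        pop = sample_population(PopulationSpec(n=6, seed=1), reference_adult)
        r1 = simulate_population(pop, apix, _single(10.0), SHORT_GRID)
        r2 = simulate_population(pop, apix, _single(10.0), SHORT_GRID)
        assert np.array_equal(r1.mean_profile.conc_ng_per_ml, r2.mean_profile.conc_ng_per_ml)

    def test_variability_separates_percentiles_at_cmax(self, reference_adult, apix):
        pop = sample_population(PopulationSpec(n=50, seed=4), reference_adult)
        result = simulate_population(pop, apix, _single(10.0), default_time_grid(12.0, 0.5))
        i = int(np.argmax(result.mean_profile.conc_ng_per_ml))
        assert result.p95_profile.conc_ng_per_ml[i] > result.p5_profile.conc_ng_per_ml[i]

    def test_empty_population_rejected(self, apix):
        with pytest.raises(ValueError, match="non-empty"):
            simulate_population([], apix, _single(10.0))


class TestAbsorptionCalibration:
    @pytest.fixture()
    def sparse_times(self):
        return np.array([0.25, 0.5, 1, 2, 3, 4, 6, 8, 12, 24, 48])

    def _target(self, phys, cmp, kp, dose, multiplier, times):
        grid = np.concatenate([[0.0], times])
        return simulate_individual(
            phys, cmp, kp, _single(dose, 48.0), grid,
            AbsorptionSettings(area_multiplier=multiplier),
        )

    def test_self_consistent_recovery_of_known_area(
        self, reference_adult, apix, apix_kp, sparse_times
    ):
        target = self._target(reference_adult, apix, apix_kp, 2.5, 1.6, sparse_times)
        result = calibrate_absorption(apix, reference_adult, target)
        assert result.area_multiplier == pytest.approx(1.6, rel=0.05)
        assert result.effective_area_cm2 == pytest.approx(1.6 * 2e6, rel=0.05)

    def test_calibrated_area_independent_of_dose(
        self, reference_adult, apix, apix_kp, sparse_times
    ):
        lo = self._target(reference_adult, apix, apix_kp, 2.5, 1.6, sparse_times)
        hi = self._target(reference_adult, apix, apix_kp, 5.0, 1.6, sparse_times)
        m_lo = calibrate_absorption(apix, reference_adult, lo).area_multiplier
        m_hi = calibrate_absorption(apix, reference_adult, hi).area_multiplier
        assert m_lo == pytest.approx(m_hi, rel=1e-3)

    def test_flat_target_profile_rejected(self, reference_adult, apix):
        flat = ConcentrationTimeProfile(
            np.array([0.0, 1.0, 2.0, 3.0]), np.zeros(4), _single(2.5)
        )
        with pytest.raises(ValueError, match="flat"):
            calibrate_absorption(apix, reference_adult, flat)
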