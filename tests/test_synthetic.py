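"""Contracts of the synthetic-data generators."""

import numpy as np
import pytest

from tauquant.errors import ValidationError
from tauquant.synthetic import (
    AggregationTruth,
    ImageTruth,
    MotilityTruth,
    QuenchTruth,
    simulate_cell_image,
    simulate_ths_timecourse,
    simulate_titration,
    simulate_tracks,
    simulate_viability,
)

CONCS = np.array([0.0, 1e-6, 2.4e-6, 5e-6, 1e-5, 5e-5])


def plain_truth(**kw):
    defaults = dict(f_a=0.12, K=1 / 2.4e-6, noise_cv=0.0,
                    eps_ex_protein=0.0, eps_em_protein=0.0)
    defaults.update(kw)
    return QuenchTruth(**defaults)


class TestSimulateTitration:
    def test_zero_quencher_zero_absorbance_gives_f0(self):
        s = simulate_titration(plain_truth(), CONCS)
        assert s.F_obs[0] == pytest.approx(1.0e6, rel=1e-12)

    def test_strong_quencher_leaves_buried_fraction(self):
        s = simulate_titration(plain_truth(K=1e12), CONCS)
        assert s.F_obs[-1] == pytest.approx((1 - 0.12) * 1.0e6, rel=1e-4)

    def test_hand_evaluated_two_population_value(self):
        """At [Q] = K_D the accessible half is quenched twofold:
        F = (0.12/2 + 0.88) F0 = 0.94 F0."""
        s = simulate_titration(plain_truth(), CONCS)
        i = int(np.argmin(np.abs(s.quencher_conc - 2.4e-6)))
        assert s.F_obs[i] == pytest.approx(0.94e6, rel=1e-12)

    def test_matches_two_population_model_pointwise(self):
        t = plain_truth(f_a=0.37, K=3e5)
        s = simulate_titration(t, CONCS)
        q = s.quencher_conc
        expected = 0.37e6 / (1 + 3e5 * q) + 0.63e6
        np.testing.assert_allclose(s.F_obs, expected, rtol=1e-14)

    def test_attenuation_grows_with_quencher_absorbance(self):
        t = plain_truth(eps_ex_compound=1.5e4, eps_em_compound=2e3)
        s = simulate_titration(t, CONCS)
        assert np.all(np.diff(s.A_ex) > 0) and np.all(np.diff(s.A_em) > 0)
        assert s.A_ex[0] == 0.0  # protein-free-of-absorbance configuration

    def test_duplicate_concentrations_rejected(self):
        with pytest.raises(ValidationError):
            simulate_titration(plain_truth(), [0.0, 1e-6, 1e-6, 2e-6])

    def test_determinism_and_seed_isolation(self):
        a = simulate_titration(plain_truth(noise_cv=0.02, seed=5), CONCS)
        b = simulate_titration(plain_truth(noise_cv=0.02, seed=5), CONCS)
        c = simulate_titration(plain_truth(noise_cv=0.02, seed=6), CONCS)
        np.testing.assert_array_equal(a.F_obs, b.F_obs)
        assert not np.array_equal(a.F_obs, c.F_obs)

    def test_invalid_truth_rejected(self):
        with pytest.raises(ValidationError):
            QuenchTruth(f_a=0.0, K=1e5)
        with pytest.raises(ValidationError):
            QuenchTruth(f_a=0.5, K=-1.0)


class TestSimulateThS:
    def test_untreated_reaches_control_plateau(self):
        t = AggregationTruth(noise_cv=0.0)
        tc = simulate_ths_timecourse(t, 0.0, times=np.arange(0.0, 5000.0, 100.0))
        assert tc.intensity[-1] == pytest.approx(t.plateau_control, rel=1e-6)

    def test_half_inhibition_dose_gives_midpoint_plateau(self):
        t = AggregationTruth(noise_cv=0.0)
        midpoint = (t.plateau_control + t.baseline) / 2.0
        assert t.plateau_at(t.half_inhibition_conc) == pytest.approx(midpoint)

    def test_full_inhibition_clips_to_baseline(self):
        t = AggregationTruth(noise_cv=0.0)
        tc = simulate_ths_timecourse(t, 2.0 * t.half_inhibition_conc)
        np.testing.assert_allclose(tc.intensity, t.baseline, rtol=1e-12)
        tc2 = simulate_ths_timecourse(t, 5.0 * t.half_inhibition_conc)
        np.testing.assert_allclose(tc2.intensity, t.baseline, rtol=1e-12)

    def test_plateaus_monotone_nonincreasing_in_dose(self):
        t = AggregationTruth(noise_cv=0.0)
        plateaus = [t.plateau_at(c) for c in np.linspace(0.0, 80.0, 25)]
        assert np.all(np.diff(plateaus) <= 1e-12)

    def test_negative_concentration_rejected(self):
        with pytest.raises(ValidationError):
            simulate_ths_timecourse(AggregationTruth(), -1.0)


class TestSimulateViability:
    def test_median_dose_gives_half_viability(self):
        dr = simulate_viability(1.7, 3.0, [1.0, 3.0, 9.0])
        assert dr.viability[1] == pytest.approx(0.5, rel=1e-12)

    def test_steep_slope_approaches_step_function(self):
        dr = simulate_viability(200.0, 2.0, [1.0, 1.9, 2.1, 4.0])
        assert dr.viability[0] > 0.999 and dr.viability[-1] < 1e-3

    def test_closed_form_value(self):
        dr = simulate_viability(1.0, 1.6, [0.4, 1.6, 6.4])
        assert dr.viability[0] == pytest.approx(0.8, rel=1e-12)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValidationError):
            simulate_viability(-1.0, 1.0, [1.0, 2.0, 4.0])
        with pytest.raises(ValidationError):
            simulate_viability(1.0, 1.0, [0.0, 2.0, 4.0])


class TestSimulateTracks:
    def test_infinite_persistence_is_straight_line(self):
        truth = MotilityTruth(persistence_time=np.inf, seed=2)
        (tr,) = simulate_tracks(truth, 1)
        dx, dy = np.diff(tr.x), np.diff(tr.y)
        cross = dx[:-1] * dy[1:] - dx[1:] * dy[:-1]
        np.testing.assert_allclose(cross, 0.0, atol=1e-9)

    def test_zero_speed_is_stationary(self):
        (tr,) = simulate_tracks(MotilityTruth(mean_speed=0.0, seed=3), 1)
        assert np.all(tr.x == 0.0) and np.all(tr.y == 0.0)

    def test_noiseless_path_length_is_speed_times_time(self):
        truth = MotilityTruth(mean_speed=0.4, total_time=600.0, seed=4)
        (tr,) = simulate_tracks(truth, 1)
        total = np.sum(np.hypot(np.diff(tr.x), np.diff(tr.y)))
        assert total == pytest.approx(0.4 * 600.0, rel=1e-12)

    def test_frame_grid(self):
        truth = MotilityTruth(n_frames=61, total_time=600.0, seed=5)
        (tr,) = simulate_tracks(truth, 1)
        assert tr.times.size == 61
        np.testing.assert_allclose(np.diff(tr.times), 10.0)

    def test_speed_ratio_propagates_to_mean_velocity(self):
        fast = simulate_tracks(MotilityTruth(mean_speed=0.5, step_cv=0.3, seed=6), 80)
        slow = simulate_tracks(MotilityTruth(mean_speed=0.34, step_cv=0.3, seed=7), 80)
        def mean_speed(tracks):
            return np.mean([
                np.sum(np.hypot(np.diff(t.x), np.diff(t.y))) / 600.0 for t in tracks
            ])
        ratio = mean_speed(slow) / mean_speed(fast)
        assert ratio == pytest.approx(0.68, abs=0.03)


class TestSimulateCellImage:
    def test_exact_coverage_by_construction(self):
        sci = simulate_cell_image(ImageTruth(mt_coverage_of_cell=0.39, noise_sd=0.0))
        frac = sci.mt_mask.sum() / sci.cell_mask.sum()
        assert frac == pytest.approx(0.39, abs=1.0 / sci.cell_mask.sum())
        assert np.all(sci.cell_mask[sci.mt_mask])  # filaments live inside the cell

    def test_full_coverage_equals_cell_mask(self):
        sci = simulate_cell_image(ImageTruth(mt_coverage_of_cell=1.0, noise_sd=0.0))
        np.testing.assert_array_equal(sci.mt_mask, sci.cell_mask)

    def test_noiseless_bimodal_threshold_between_modes(self):
        from tauquant.imaging import otsu_threshold

        sci = simulate_cell_image(ImageTruth(noise_sd=0.0))
        thr = otsu_threshold(sci.image.tubulin_channel)
        assert 40.0 < thr < 200.0

    def test_unachievable_coverage_rejected(self):
        with pytest.raises(ValidationError, match="resolution"):
            simulate_cell_image(
                ImageTruth(width=64, height=64, cell_mask_fraction=0.02,
                           mt_coverage_of_cell=0.005)
            )

    def test_determinism(self):
        a = simulate_cell_image(ImageTruth(noise_sd=10.0, seed=9))
        b = simulate_cell_image(ImageTruth(noise_sd=10.0, seed=9))
        np.testing.assert_array_equal(a.image.tubulin_channel, b.image.tubulin_channel)
        np.testing.assert_array_equal(a.cell_mask, b.cell_mask)
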