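"""Quench-binding analysis: inner-filter correction and Stern-Volmer fits."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from tauquant.binding import (
    TitrationSeries,
    fit_modified_stern_volmer,
    fit_regular_stern_volmer,
    inner_filter_correct,
    stern_volmer_points,
)
from tauquant.errors import NonPhysicalFitError, NoQuenchError, ValidationError
from tauquant.synthetic import QuenchTruth, simulate_titration

QCT = dict(f_a=0.12, K_D=2.4e-6)
CPD1 = dict(f_a=0.39, K_D=7.0e-6)
CPD5 = dict(f_a=0.38, K_D=6.4e-6)


def noiseless_truth(f_a, K_D, inner_filter=False, **kw):
    eps = dict(eps_ex_compound=1.5e4, eps_em_compound=2.0e3) if inner_filter else dict(
        eps_ex_compound=0.0, eps_em_compound=0.0, eps_ex_protein=0.0, eps_em_protein=0.0
    )
    return QuenchTruth(f_a=f_a, K=1.0 / K_D, noise_cv=0.0, **eps, **kw)


class TestInnerFilterCorrect:
    def test_closed_form(self):
        assert inner_filter_correct(100.0, 0.0, 0.0) == 100.0
        assert inner_filter_correct(100.0, 0.1, 0.1) == pytest.approx(
            100.0 * np.e**0.1, rel=1e-12
        )

    def test_monotone_in_absorbance(self):
        assert inner_filter_correct(100, 0.2, 0.1) > inner_filter_correct(100, 0.1, 0.1)
        assert inner_filter_correct(100, 0.1, 0.2) > inner_filter_correct(100, 0.1, 0.1)

    @pytest.mark.parametrize("bad", [(-1.0, 0.1, 0.1), (10.0, -0.1, 0.1), (10.0, 0.1, -0.1)])
    def test_rejects_negative_inputs(self, bad):
        with pytest.raises(ValidationError):
            inner_filter_correct(*bad)

    @given(
        f=st.floats(1.0, 1e7),
        a_ex=st.floats(0.0, 2.0),
        a_em=st.floats(0.0, 2.0),
    )
    def test_roundtrip_with_generator_attenuation(self, f, a_ex, a_em):
        """Correction is the exact inverse of the generator's attenuation."""
        attenuated = f * np.exp(-(a_ex + a_em) / 2.0)
        assert inner_filter_correct(attenuated, a_ex, a_em) == pytest.approx(f, rel=1e-12)


class TestSternVolmerPoints:
    def test_hand_evaluated_transform(self):
        """f_a=0.5, K=1e6 at [Q]=1e-6: F0/dF = (1+K[Q])/(f_a K [Q]) = 4."""
        truth = noiseless_truth(0.5, 1e-6)
        series = simulate_titration(truth, [0.0, 0.5e-6, 1e-6, 2e-6, 4e-6])
        pts = stern_volmer_points(series)
        i = np.argmin(np.abs(pts.inv_conc - 1e6))
        assert pts.f0_over_df[i] == pytest.approx(4.0, rel=1e-12)

    def test_abscissae_are_reciprocal_concentrations(self):
        truth = noiseless_truth(0.3, 5e-6)
        q = np.array([0.0, 1e-6, 3e-6, 5e-6, 2e-5])
        pts = stern_volmer_points(simulate_titration(truth, q))
        np.testing.assert_allclose(np.sort(pts.inv_conc), np.sort(1.0 / q[1:]))

    def test_constant_intensity_is_no_quench(self):
        series = TitrationSeries("flat", [0, 1e-6, 2e-6, 3e-6, 4e-6], [100.0] * 5)
        with pytest.raises(NoQuenchError, match="no quench"):
            stern_volmer_points(series)


class TestModifiedSternVolmerFit:
    @pytest.mark.parametrize("truth_params", [QCT, CPD1, CPD5],
                             ids=["QCT", "cpd1", "cpd5"])
    @pytest.mark.parametrize("inner_filter", [False, True],
                             ids=["plain", "inner-filter"])
    def test_noiseless_round_trip(self, truth_params, inner_filter):
        """Noiseless titrations refit to <=0.1% on f_a and K_D, with and
        without inner-filter attenuation passing through the correction."""
        truth = noiseless_truth(**truth_params, inner_filter=inner_filter)
        fit = fit_modified_stern_volmer(simulate_titration(truth))
        assert fit.f_a == pytest.approx(truth_params["f_a"], rel=1e-3)
        assert fit.K_D == pytest.approx(truth_params["K_D"], rel=1e-3)
        assert fit.r_squared > 0.999

    def test_kd_k_identity_and_scale_invariance(self):
        truth = noiseless_truth(**QCT)
        series = simulate_titration(truth)
        fit = fit_modified_stern_volmer(series)
        assert fit.K_D * fit.K == pytest.approx(1.0, abs=1e-15)
        scaled = TitrationSeries(
            series.compound_id, series.quencher_conc, series.F_obs * 37.5,
            protein_conc=series.protein_conc,
        )
        fit2 = fit_modified_stern_volmer(scaled)
        assert fit2.K_D == pytest.approx(fit.K_D, rel=1e-12)

    def test_fully_accessible_reduces_to_regular_model(self):
        truth = noiseless_truth(1.0, 3e-6)
        series = simulate_titration(truth)
        fit = fit_modified_stern_volmer(series)
        assert fit.intercept == pytest.approx(1.0, rel=1e-9)
        reg = fit_regular_stern_volmer(series)
        assert reg.K_free == pytest.approx(fit.K, rel=1e-6)

    def test_agrees_with_grid_search_oracle(self):
        """Brute-force SSE minimisation over a (f_a, K) grid lands on the
        grid point nearest the linear-transform estimate."""
        truth = noiseless_truth(0.12, 2.4e-6)
        series = simulate_titration(truth, [0.0, 2e-6, 5e-6, 1e-5, 3e-5, 1e-4])
        fit = fit_modified_stern_volmer(series)
        F = series.F_obs
        F0 = F[0]
        q = series.quencher_conc
        fa_grid = np.linspace(0.02, 1.0, 200)
        k_grid = np.geomspace(1e4, 1e8, 200)
        best = None
        for fa in fa_grid:
            pred = fa * F0 / (1.0 + np.outer(k_grid, q)) + (1 - fa) * F0
            sse = np.sum((pred - F) ** 2, axis=1)
            j = int(np.argmin(sse))
            if best is None or sse[j] < best[0]:
                best = (sse[j], fa, k_grid[j])
        sse_best, fa_best, k_best = best
        sse_fit = np.sum(
            (fit.f_a * F0 / (1.0 + fit.K * q) + (1 - fit.f_a) * F0 - F) ** 2
        )
        assert sse_fit <= sse_best + 1e-9  # grid search cannot beat the transform
        assert abs(fa_best - fit.f_a) <= 2 * np.diff(fa_grid)[0]
        assert abs(np.log(k_best / fit.K)) <= 2 * np.log(k_grid[1] / k_grid[0])

    def test_non_physical_slope_rejected(self):
        # more quench at low [Q] than high: transformed slope is negative
        q = np.array([0.0, 1e-6, 2e-6, 3e-6, 4e-6])
        F = np.array([1.0, 0.5, 0.6, 0.7, 0.8])
        with pytest.raises(NonPhysicalFitError):
            fit_modified_stern_volmer(TitrationSeries("bad", q, F))

    def test_accessible_fraction_above_one_flagged(self):
        # line with intercept 0.8 implies f_a = 1.25; flagged, not raised
        q = np.array([0.0, 1e-6, 2e-6, 4e-6, 8e-6])
        y = 0.8 + 2e-6 / q[1:]  # F0/dF values on the target line
        F0 = 1000.0
        F = np.concatenate([[F0], F0 * (1.0 - 1.0 / y)])
        fit = fit_modified_stern_volmer(TitrationSeries("hot", q, F))
        assert "f_a>1" in fit.flags
        assert fit.f_a == pytest.approx(1.25, rel=1e-9)

    def test_estimator_sanity_under_noise(self):
        """Median relative K_D bias stays within 10% over 1000 noisy
        replicates at the tight-binder truth (2% CV)."""
        kds = []
        for seed in range(1000):
            truth = QuenchTruth(f_a=0.12, K=1 / 2.4e-6, noise_cv=0.02, seed=seed)
            try:
                kds.append(fit_modified_stern_volmer(simulate_titration(truth)).K_D)
            except (NoQuenchError, NonPhysicalFitError):
                continue
        assert len(kds) > 900
        median_bias = np.median(np.array(kds) / 2.4e-6 - 1.0)
        assert abs(median_bias) <= 0.10


class TestRegularSternVolmer:
    def test_heterogeneous_accessibility_degrades_linearity(self):
        truth = noiseless_truth(**QCT)
        series = simulate_titration(truth)
        reg = fit_regular_stern_volmer(series)
        mod = fit_modified_stern_volmer(series)
        assert reg.r_squared_free < mod.r_squared

    def test_no_quench_raises(self):
        series = TitrationSeries("flat", [0, 1e-6, 2e-6, 3e-6, 4e-6], [100.0] * 5)
        with pytest.raises(NoQuenchError):
            fit_regular_stern_volmer(series)


class TestTitrationSeriesValidation:
    def test_requires_zero_reference_and_monotone_concs(self):
        with pytest.raises(ValidationError):
            TitrationSeries("x", [1e-6, 2e-6, 3e-6, 4e-6], [4.0, 3.0, 2.0, 1.0])
        with pytest.raises(ValidationError):
            TitrationSeries("x", [0, 2e-6, 1e-6, 4e-6], [4.0, 3.0, 2.0, 1.0])

    def test_rejects_nonpositive_intensities(self):
        with pytest.raises(ValidationError):
            TitrationSeries("x", [0, 1e-6, 2e-6, 3e-6], [4.0, 3.0, 0.0, 1.0])
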