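"""Exponential fitting, plateau extraction, outlier screening, averaging."""

from __future__ import annotations

import itertools

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import frapcme as f
from frapcme.expfit import FitError, FitWarning

GRID = np.arange(0.0, 301.0, 10.0)


def make_trace(y0, A, R0, sigma=0.0, seed=0, modality="frap", times=GRID):
    y = y0 + A * np.exp(R0 * times)
    if sigma > 0:
        y = y + np.random.default_rng(seed).normal(0, sigma, times.size)
    return f.IntensityTrace(times, y, modality, label="t")


class TestFitExponential:
    @pytest.mark.parametrize(
        "y0,A,R0",
        [
            (0.56, -0.56, -0.0113),
            (0.48, -0.45, -0.015),
            (0.80, -0.75, -0.087),
            (0.60, 0.40, -0.026),  # loss-shaped
        ],
    )
    def test_noiseless_recovery_is_exact(self, y0, A, R0):
        modality = "frap" if A < 0 else "flap"
        fit = f.fit_exponential(make_trace(y0, A, R0, modality=modality))
        assert abs(fit.y0 - y0) < 1e-6
        assert abs(fit.A - A) < 1e-6
        assert abs(fit.R0 - R0) < 1e-6
        assert fit.residual_sse < 1e-12

    def test_noisy_fit_beats_brute_force_grid(self):
        """The LM optimum must dominate a brute-force SSE grid search and its
        R0 must sit within 3 standard errors of the generating value."""
        true = (0.56, -0.56, -0.0113)
        tr = make_trace(*true, sigma=0.02, seed=42)
        fit = f.fit_exponential(tr)
        assert abs(fit.R0 - true[2]) < 3 * fit.sigma_R0

        def sse(p):
            return float(np.sum((tr.intensities - p[0] - p[1] * np.exp(p[2] * tr.times)) ** 2))

        grid_best = min(
            (sse((y0, A, R0)), (y0, A, R0))
            for y0, A, R0 in itertools.product(
                np.linspace(0.4, 0.7, 31),
                np.linspace(-0.8, -0.3, 31),
                np.linspace(-0.03, -0.003, 55),
            )
        )
        assert fit.residual_sse <= grid_best[0] + 1e-12
        assert abs(fit.R0 - grid_best[1][2]) < 2 * (0.027 / 54)  # within two grid cells

    def test_constant_trace_rejected(self):
        tr = f.IntensityTrace([0, 10, 20, 30], [0.5, 0.5, 0.5, 0.5], "frap")
        with pytest.raises(FitError, match="constant"):
            f.fit_exponential(tr)

    def test_growing_signal_rejected(self):
        tr = make_trace(0.0, 0.1, 0.005, times=np.arange(0.0, 310.0, 10.0))
        with pytest.raises(FitError, match="decay"):
            f.fit_exponential(tr)

    def test_sign_convention_violation_warns(self):
        # decaying (FLAP-shaped) curve declared as FRAP: A > 0 triggers a warning
        tr = make_trace(0.56, 0.44, -0.01, modality="frap")
        with pytest.warns(FitWarning):
            f.fit_exponential(tr)

    def test_deterministic(self):
        tr = make_trace(0.5, -0.5, -0.02, sigma=0.03, seed=7)
        a, b = f.fit_exponential(tr), f.fit_exponential(tr)
        assert (a.y0, a.A, a.R0) == (b.y0, b.A, b.R0)

    @given(
        y0=st.floats(min_value=0.3, max_value=0.9),
        frac=st.floats(min_value=0.5, max_value=1.0),
        R0=st.floats(min_value=-0.09, max_value=-0.005),
    )
    def test_noiseless_exactness_over_rate_range(self, y0, frac, R0):
        fit = f.fit_exponential(make_trace(y0, -frac * y0, R0))
        assert fit.residual_sse < 1e-12


class TestTurnoverRate:
    @pytest.mark.parametrize("r0,expected", [(-0.015, 0.015), (-0.0113, 0.0113)])
    def test_absolute_value(self, r0, expected):
        fit = f.ExpFit(y0=0.5, A=-0.5, R0=r0, residual_sse=0.0, n_points=31)
        assert f.turnover_rate(fit) == pytest.approx(expected)

    def test_zero_rate_rejected(self):
        fit = f.ExpFit(y0=0.5, A=-0.5, R0=0.0, residual_sse=0.0, n_points=31)
        with pytest.raises(FitError):
            f.turnover_rate(fit)

    def test_recovers_generator_truth_within_ten_percent(self):
        k_t_true = 0.0257
        spec = f.GeneratorSpec(k_in=k_t_true * 0.3, k_out=k_t_true * 0.7,
                               n_traces=1, noise_sigma=0.02, seed=12)
        tr = f.generate_traces(spec)[0]
        assert f.turnover_rate(f.fit_exponential(tr)) == pytest.approx(k_t_true, rel=0.10)

    @given(scale=st.floats(min_value=0.1, max_value=10.0))
    def test_scale_invariance_under_intensity_rescaling(self, scale):
        tr = make_trace(0.56, -0.56, -0.0113, sigma=0.01, seed=3)
        scaled = f.IntensityTrace(tr.times, tr.intensities * scale, tr.modality)
        k1 = f.turnover_rate(f.fit_exponential(tr))
        k2 = f.turnover_rate(f.fit_exponential(scaled))
        assert k2 == pytest.approx(k1, rel=1e-6)


class TestStationaryConcentration:
    def test_frap_reads_last_point(self):
        tr = f.IntensityTrace([0, 10, 20, 30], [0.0, 0.3, 0.5, 0.562], "frap")
        assert f.stationary_concentration(tr, m=1) == pytest.approx(0.562)

    def test_flap_complements_exterior_plateau(self):
        tr = f.IntensityTrace([0, 10, 20, 30], [1.0, 0.7, 0.5, 0.44], "flap")
        assert f.stationary_concentration(tr, m=1) == pytest.approx(0.56)

    def test_flap_interior_override(self):
        tr = f.IntensityTrace([0, 10, 20, 30], [1.0, 0.7, 0.6, 0.56], "flap")
        assert f.stationary_concentration(tr, m=1, exterior_plateau=False) == pytest.approx(0.56)

    def test_mean_of_last_m(self):
        tr = f.IntensityTrace([0, 10, 20, 30, 40, 50],
                              [0.0, 0.3, 0.5, 0.70, 0.72, 0.71], "frap")
        assert f.stationary_concentration(tr, m=3) == pytest.approx(0.71)

    @pytest.mark.parametrize("m", [0, 7])
    def test_m_out_of_range(self, m):
        tr = f.IntensityTrace([0, 10, 20, 30], [0, 0.3, 0.5, 0.56], "frap")
        with pytest.raises(ValueError):
            f.stationary_concentration(tr, m=m)

    def test_unnormalized_trace_rejected(self):
        tr = f.IntensityTrace([0, 10, 20, 30], [0, 30, 50, 56], "frap")
        with pytest.raises(ValueError, match="normalized"):
            f.stationary_concentration(tr, m=1)


def fits_from(r0s):
    return [f.ExpFit(y0=0.5, A=-0.5, R0=r, residual_sse=0.0, n_points=31, label=f"r{i}")
            for i, r in enumerate(r0s)]


class TestRemoveOutliers:
    def test_equal_values_keep_everything(self):
        kept, bounds = f.remove_outliers(fits_from([-0.01] * 6))
        assert len(kept) == 6 and bounds.iqr == 0.0

    def test_extreme_rate_removed(self):
        kept, bounds = f.remove_outliers(fits_from([-0.010] * 8 + [-0.20]))
        assert [fit.R0 for fit in kept] == [-0.010] * 8
        # brute-force fence check with the type-7 quartile convention
        assert -0.20 < bounds.lcl

    def test_tight_sample_keeps_everything(self):
        r0s = [-0.008, -0.009, -0.010, -0.011]
        kept, bounds = f.remove_outliers(fits_from(r0s))
        # independent fence computation: type-7 quartiles of the sorted sample
        q1, q3 = np.percentile(r0s, [25, 75])
        assert bounds.q1 == pytest.approx(q1) and bounds.q3 == pytest.approx(q3)
        assert bounds.lcl == pytest.approx(q1 - 1.5 * (q3 - q1))
        assert bounds.ucl == pytest.approx(q3 + 1.5 * (q3 - q1))
        assert len(kept) == 4

    def test_fewer_than_four_rejected(self):
        with pytest.raises(ValueError):
            f.remove_outliers(fits_from([-0.01, -0.02, -0.03]))

    @given(st.permutations(list(range(9))))
    def test_removal_invariant_to_ordering(self, order):
        r0s = [-0.010, -0.011, -0.009, -0.012, -0.008, -0.010, -0.011, -0.009, -0.20]
        fits = fits_from(r0s)
        baseline = {fit.label for fit in f.remove_outliers(fits)[0]}
        permuted = [fits[i] for i in order]
        assert {fit.label for fit in f.remove_outliers(permuted)[0]} == baseline


class TestAverageTrace:
    def test_mean_of_identical_traces_is_identity(self):
        tr = make_trace(0.5, -0.5, -0.01)
        avg = f.average_trace(f.TraceSet((tr, tr)))
        np.testing.assert_allclose(avg.intensities, tr.intensities)

    def test_pointwise_mean(self):
        a = f.IntensityTrace([0, 10, 20, 30], [0, 1, 0, 1], "frap")
        b = f.IntensityTrace([0, 10, 20, 30], [1, 0, 1, 0], "frap")
        np.testing.assert_allclose(f.average_trace(f.TraceSet((a, b))).intensities, 0.5)

    def test_truncates_to_common_prefix(self):
        a = f.IntensityTrace(np.arange(0, 60, 10.0), np.linspace(0, 1, 6), "frap")
        b = f.IntensityTrace(np.arange(0, 40, 10.0), np.linspace(0, 1, 4), "frap")
        avg = f.average_trace(f.TraceSet((a, b)))
        assert len(avg) == 4

    def test_incompatible_grids_rejected(self):
        a = f.IntensityTrace([0, 10, 20, 30], [0, 1, 2, 3], "frap")
        b = f.IntensityTrace([0, 12, 24, 36], [0, 1, 2, 3], "frap")
        with pytest.raises(ValueError, match="incompatible"):
            f.average_trace(f.TraceSet((a, b)))


class TestAnalyzeTraceset:
    def test_noiseless_pipeline_recovers_truth(self):
        spec = f.GeneratorSpec(k_in=0.00494, k_out=0.00635, n_traces=6, noise_sigma=0.0)
        report = f.analyze_traceset(f.generate_traces(spec))
        assert report.rates.k_in == pytest.approx(0.00494, abs=1e-8)
        assert report.rates.k_out == pytest.approx(0.00635, abs=1e-8)
        assert report.removed_labels == []

    def test_planted_outlier_flagged(self):
        spec = f.GeneratorSpec(k_in=0.005, k_out=0.006, n_traces=9, noise_sigma=0.01, seed=2)
        ts = f.generate_outlier_set(spec, n_outliers=1, rate_multiplier=10.0)
        report = f.analyze_traceset(ts)
        assert report.removed_labels == ["outlier-synthetic-01"]
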