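"""Gumbel psychometric fits, BP/CV, slopes, bootstrap, median split, RT filter."""

import math

import numpy as np
import pandas as pd
import pytest

from viscotime.psychometrics import (
    N_BOOTSTRAP,
    GumbelPsychometric,
    PsychometricFit,
    _median_split_labels,
    bootstrap_mean_slope_ci,
    bp_vs_viscosity_slopes,
    fit_gumbel_psychometric,
    median_split_analysis,
    rt_outlier_filter,
)

DURATIONS = np.array([1.0, 1.26, 1.58, 2.0, 2.52, 3.17, 4.0])


def _binomial_choices(bp, scale, n_per, rng, durations=DURATIONS):
    """Choice counts from a generating core Gumbel curve with the given BP."""
    mu = math.log(bp) - scale * math.log(math.log(2.0))
    x = (np.log(durations) - mu) / scale
    p = 1.0 - np.exp(-np.exp(x))
    return rng.binomial(n_per, p)


class TestGumbelFit:
    def test_bp_recovery(self):
        rng = np.random.default_rng(0)
        n_long = _binomial_choices(bp=2.0, scale=0.25, n_per=200, rng=rng)
        fit = fit_gumbel_psychometric(DURATIONS, n_long, [200] * 7, seed=0)
        assert fit.bp == pytest.approx(2.0, abs=0.1)
        assert not fit.boundary

    def test_flat_data_gives_huge_cv(self):
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # boundary flag may or may not fire
            fit = fit_gumbel_psychometric(DURATIONS, [50] * 7, [100] * 7, seed=0)
        assert fit.cv > 1.0
        assert fit.scale > 1.0  # essentially flat curve

    def test_cv_identity_from_quartiles(self):
        # CV = (t75 - t25) / (2 * BP) must hold exactly on the core curve
        fit = PsychometricFit(
            location=math.log(2.4) - 0.3 * math.log(math.log(2)),
            scale=0.3, guess=0.0, lapse=0.0, bp=float("nan"), cv=float("nan"),
            nll=0.0,
        )
        bp = fit.quantile(0.5)
        cv = (fit.quantile(0.75) - fit.quantile(0.25)) / (2 * bp)
        assert bp == pytest.approx(2.4)
        rng = np.random.default_rng(1)
        n_long = _binomial_choices(bp=2.4, scale=0.3, n_per=400, rng=rng)
        fitted = fit_gumbel_psychometric(DURATIONS, n_long, [400] * 7, seed=1)
        assert fitted.cv == pytest.approx(
            (fitted.quantile(0.75) - fitted.quantile(0.25)) / (2 * fitted.bp)
        )
        # direct application of the formula: t25=1.8, t75=3.0, bp=2.4
        assert (3.0 - 1.8) / (2 * 2.4) == pytest.approx(0.25)

    def test_fitted_curve_monotone(self):
        rng = np.random.default_rng(2)
        n_long = _binomial_choices(bp=2.2, scale=0.35, n_per=50, rng=rng)
        fit = fit_gumbel_psychometric(DURATIONS, n_long, [50] * 7, seed=2)
        grid = np.geomspace(0.8, 5.0, 300)
        assert np.all(np.diff(fit.predict(grid)) >= -1e-12)

    def test_all_long_flags_boundary(self):
        with pytest.warns(UserWarning, match="outside the stimulus range"):
            fit = fit_gumbel_psychometric(DURATIONS, [100] * 7, [100] * 7, seed=0)
        assert fit.boundary
        assert not (DURATIONS[0] <= fit.bp <= DURATIONS[-1])

    def test_input_validation(self):
        with pytest.raises(ValueError):
            GumbelPsychometric([1.0, 2.0], [1, 2], [5, 5])  # < 3 durations
        with pytest.raises(ValueError):
            GumbelPsychometric([1, 2, 3], [6, 1, 1], [5, 5, 5])  # k > n

    def test_bp_recovery_cohort(self):
        # median |bp_hat - bp_true| below 5% of bp_true across simulated
        # subjects at 200 trials/duration
        rng = np.random.default_rng(3)
        errs = []
        for _ in range(30):
            bp_true = rng.uniform(1.6, 2.8)
            n_long = _binomial_choices(bp_true, 0.3, 200, rng)
            fit = fit_gumbel_psychometric(DURATIONS, n_long, [200] * 7)
            errs.append(abs(fit.bp - bp_true) / bp_true)
        assert np.median(errs) < 0.05


class TestSlopes:
    def _fits(self, bp_fn, subjects=("A", "B", "C"), viscs=(0.0, 12.0, 24.0, 36.0)):
        out = {}
        for s in subjects:
            for w in viscs:
                out[(s, w)] = PsychometricFit(
                    location=0.0, scale=0.3, guess=0.0, lapse=0.0,
                    bp=bp_fn(s, w), cv=0.2, nll=0.0,
                )
        return out

    def test_flat_bp_zero_slope(self):
        res = bp_vs_viscosity_slopes(self._fits(lambda s, w: 2.0))
        assert res.slope == pytest.approx(0.0, abs=1e-12)

    def test_exact_line(self):
        res = bp_vs_viscosity_slopes(self._fits(lambda s, w: 2.0 + 0.01 * w))
        assert res.slope == pytest.approx(0.01)
        assert res.intercept == pytest.approx(2.0)
        assert len(res.per_subject_slopes) == 3

    def test_single_viscosity_rejected(self):
        fits = self._fits(lambda s, w: 2.0, viscs=(0.0,))
        with pytest.raises(ValueError, match="single viscosity"):
            bp_vs_viscosity_slopes(fits)

    def test_positive_generating_slope_recovered(self):
        rng = np.random.default_rng(4)
        fits = {}
        for s in range(8):
            for w in (0.0, 12.0, 24.0, 36.0):
                bp_true = 2.0 + 0.008 * w
                n_long = _binomial_choices(bp_true, 0.3, 70, rng)
                fits[(f"S{s}", w)] = fit_gumbel_psychometric(
                    DURATIONS, n_long, [70] * 7
                )
        res = bp_vs_viscosity_slopes(fits)
        assert res.slope > 0


class TestBootstrap:
    def test_degenerate_sample(self):
        lo, hi = bootstrap_mean_slope_ci([1.0] * 10, seed=0)
        assert (lo, hi) == (1.0, 1.0)

    def test_default_resample_count(self):
        assert N_BOOTSTRAP == 10_000

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            bootstrap_mean_slope_ci([], seed=0)

    def test_coverage_of_true_mean(self):
        # slopes ~ N(0,1), n=30: the 95% CI should cover 0 ~95% of the time
        rng = np.random.default_rng(5)
        cover = 0
        reps = 300
        for i in range(reps):
            s = rng.standard_normal(30)
            lo, hi = bootstrap_mean_slope_ci(s, n_boot=1000, seed=i)
            cover += lo <= 0.0 <= hi
        assert 0.90 <= cover / reps <= 0.98

    def test_width_shrinks_with_cohort_size(self):
        rng = np.random.default_rng(6)
        widths = {}
        for n in (10, 40):
            ws = []
            for i in range(60):
                s = rng.standard_normal(n)
                lo, hi = bootstrap_mean_slope_ci(s, n_boot=1000, seed=1000 + i)
                ws.append(hi - lo)
            widths[n] = np.mean(ws)
        ratio = widths[10] / widths[40]
        assert 1.5 < ratio < 2.7  # ~ sqrt(40/10) = 2


class TestMedianSplit:
    def test_textbook_split(self):
        labels = _median_split_labels(np.arange(1.0, 11.0))
        assert list(labels[:5]) == ["low"] * 5
        assert list(labels[5:]) == ["high"] * 5

    def test_all_ties_balanced(self):
        labels = _median_split_labels(np.full(10, 3.3))
        assert sorted(labels).count("low") == 5

    def test_null_effect_recovery(self, kin):
        # identical generating process for every trial: split curves match
        from viscotime.ddm import DDMParams
        from viscotime.synthetic_data import (
            ConditionGrid,
            default_categorization_params,
            simulate_categorization_session,
        )

        grid = ConditionGrid(tuple(DURATIONS), (0.0,), 40, 1)
        params = default_categorization_params(grid)
        df = simulate_categorization_session(params, grid, kin, seed=7)
        fits = median_split_analysis(df)
        bp_low = fits[("S01", 0.0, "low")].bp
        bp_high = fits[("S01", 0.0, "high")].bp
        assert abs(bp_low - bp_high) < 0.3

    def test_small_cells_skipped(self, caplog):
        df = pd.DataFrame(
            {
                "subject": ["A"] * 1,
                "duration_s": [1.0],
                "viscosity": [0.0],
                "choice": ["long"],
                "move_distance_m": [0.5],
            }
        )
        with pytest.raises(ValueError, match="no cell"):
            median_split_analysis(df)


class TestRTFilter:
    def test_zero_variance_keeps_all(self):
        assert len(rt_outlier_filter([0.5] * 20)) == 20

    def test_gross_outlier_removed(self):
        rts = [0.5] * 99 + [50.0]
        rng = np.random.default_rng(8)
        rts = list(np.array(rts) * np.exp(0.05 * rng.standard_normal(100)))
        kept = rt_outlier_filter(rts)
        assert 99 not in kept
        assert len(kept) == 99

    def test_lognormal_tail_fraction(self):
        # 3-SD rule on log-RTs removes the ~0.27% normal tail mass
        rng = np.random.default_rng(9)
        rts = np.exp(rng.standard_normal(100_000) * 0.4 - 0.5)
        kept = rt_outlier_filter(rts)
        frac_removed = 1.0 - len(kept) / len(rts)
        assert 0.001 < frac_removed < 0.005

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            rt_outlier_filter([0.5, -0.1])
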