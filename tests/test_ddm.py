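"""Wiener first-passage density, simulator, likelihood, and ML fitting."""

import numpy as np
import pandas as pd
import pytest
from scipy.integrate import quad

from conftest import make_ddm_trials
from viscotime.ddm import (
    MODEL_LADDER,
    DDMModelSpec,
    DDMParams,
    DriftDiffusionModel,
    choice_probability,
    combine_duration_viscosity,
    fit_model_ladder,
    nll_ddm,
    predictive_check_ddm,
    simulate_ddm_trial,
    simulate_ddm_trials,
    wfpt_density,
)

PARAM_SETS = [
    DDMParams(v=0.8, a=1.4, z=0.4, t_nd=0.3),
    DDMParams(v=-1.5, a=0.8, z=0.6, t_nd=0.1),
    DDMParams(v=0.0, a=2.0, z=0.3, t_nd=0.0),
    DDMParams(v=2.5, a=1.0, z=0.5, t_nd=0.2),
    DDMParams(v=0.5, a=1.2, z=0.5, t_nd=0.0, sz=0.3),
]


class TestDensity:
    @pytest.mark.parametrize("p", PARAM_SETS)
    def test_reflection_symmetry(self, p):
        # density(t, long | v, z) == density(t, short | -v, 1-z) exactly
        t = np.linspace(0.01, 6.0, 80)
        mirrored = DDMParams(v=-p.v, a=p.a, z=1 - p.z, t_nd=p.t_nd, sz=p.sz)
        np.testing.assert_array_equal(
            wfpt_density(t, "long", p), wfpt_density(t, "short", mirrored)
        )

    @pytest.mark.parametrize("p", PARAM_SETS)
    def test_total_absorption(self, p):
        tot = sum(
            quad(lambda t: wfpt_density(t, b, p), 1e-7, 80.0, limit=200)[0]
            for b in ("long", "short")
        )
        assert tot == pytest.approx(1.0, abs=1e-4)

    def test_nonpositive_time_zero_density(self):
        p = PARAM_SETS[0]
        assert wfpt_density(0.0, "long", p) == 0.0
        assert wfpt_density(-1.0, "short", p) == 0.0

    def test_matches_simulation_cdf(self):
        # Euler-Maruyama paths are the independent oracle for the series
        p = DDMParams(v=0.6, a=1.2, z=0.45, t_nd=0.0)
        rng = np.random.default_rng(0)
        n = 50_000
        choice, rt = simulate_ddm_trials(p, n, rng, dt=2.5e-4)
        t_grid = np.linspace(0.05, 4.0, 40)
        dens = wfpt_density(t_grid, "long", p)
        cdf_analytic = np.array(
            [quad(lambda t: wfpt_density(t, "long", p), 1e-7, tg)[0] for tg in t_grid]
        )
        rt_long = rt[choice]
        cdf_emp = np.searchsorted(np.sort(rt_long), t_grid) / n
        assert np.max(np.abs(cdf_emp - cdf_analytic)) < 0.02

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            DDMParams(v=1.0, a=-1.0, z=0.5)
        with pytest.raises(ValueError):
            DDMParams(v=1.0, a=1.0, z=1.2)
        with pytest.raises(ValueError):
            DDMParams(v=1.0, a=1.0, z=0.1, sz=0.4)  # z - sz/2 <= 0


class TestChoiceProbability:
    @pytest.mark.parametrize(
        "p,expected",
        [
            (DDMParams(v=0.0, a=1.5, z=0.5), 0.5),
            (DDMParams(v=0.0, a=1.5, z=0.3), 0.3),
        ],
    )
    def test_zero_drift_closed_form(self, p, expected):
        assert choice_probability(p) == pytest.approx(expected)

    def test_closed_form_value(self):
        p = DDMParams(v=1.0, a=2.0, z=0.5)
        expected = (1 - np.exp(-2 * 1.0 * 0.5 * 2.0)) / (1 - np.exp(-2 * 1.0 * 2.0))
        assert choice_probability(p) == pytest.approx(expected)

    def test_matches_density_integral(self):
        for p in PARAM_SETS[:3]:
            integral = quad(
                lambda t: wfpt_density(t, "long", p), 1e-7, 80.0, limit=200
            )[0]
            assert choice_probability(p) == pytest.approx(integral, abs=1e-4)


class TestSimulator:
    def test_nondecision_time_floor(self):
        p = DDMParams(v=1.0, a=1.0, z=0.5, t_nd=0.3)
        rng = np.random.default_rng(1)
        _, rt = simulate_ddm_trials(p, 2000, rng, dt=1e-3)
        assert rt.min() > 0.3

    def test_single_trial_determinism(self):
        p = DDMParams(v=0.5, a=1.3, z=0.5, t_nd=0.2)
        assert simulate_ddm_trial(p, seed=42) == simulate_ddm_trial(p, seed=42)

    def test_absorption_frequency_matches_closed_form(self):
        p = DDMParams(v=0.7, a=1.5, z=0.45, t_nd=0.0)
        rng = np.random.default_rng(2)
        n = 40_000
        choice, _ = simulate_ddm_trials(p, n, rng, dt=2.5e-4)
        p_true = choice_probability(p)
        se = np.sqrt(p_true * (1 - p_true) / n)
        assert abs(choice.mean() - p_true) < 3 * se + 0.003  # + Euler bias margin


class TestLikelihood:
    def test_default_outlier_probability(self):
        assert DDMModelSpec().p_outlier == 0.05

    def test_outlier_floor_keeps_nll_finite(self):
        p = DDMParams(v=0.5, a=1.0, z=0.5, t_nd=0.5)
        trials = pd.DataFrame(
            {"viscosity": [0.0], "rt_s": [0.3], "choice": ["long"]}  # rt < t_nd
        )
        spec = DDMModelSpec(p_outlier=0.05)
        assert np.isfinite(nll_ddm(trials, spec, {0.0: p}))
        spec0 = DDMModelSpec(p_outlier=0.0)
        assert np.isinf(nll_ddm(trials, spec0, {0.0: p}))

    def test_unknown_condition_raises(self):
        trials = pd.DataFrame(
            {"viscosity": [12.0], "rt_s": [0.8], "choice": ["long"]}
        )
        with pytest.raises(KeyError):
            nll_ddm(trials, DDMModelSpec(), {0.0: PARAM_SETS[0]})

    def test_likelihood_concentrates_at_truth(self):
        # NLL at generating parameters beats a +/-50% drift perturbation
        # for most synthetic sessions
        truth = {
            w: DDMParams(v=1.0 - 0.025 * w, a=1.4, z=0.5, t_nd=0.35)
            for w in (0.0, 12.0, 24.0, 36.0)
        }
        spec = DDMModelSpec(varying=("v",))
        wins = 0
        n_rep = 20
        for i in range(n_rep):
            trials = make_ddm_trials(truth, n_per_cond=70, seed=100 + i)
            nll_true = nll_ddm(trials, spec, truth)
            beat = 0
            for fac in (0.5, 1.5):
                pert = {
                    w: DDMParams(v=p.v * fac, a=p.a, z=p.z, t_nd=p.t_nd)
                    for w, p in truth.items()
                }
                beat += nll_true <= nll_ddm(trials, spec, pert)
            wins += beat == 2
        assert wins / n_rep > 0.6


class TestFitting:
    def test_recovery_single_subject(self):
        truth = {
            w: DDMParams(v=1.2 - 0.03 * w, a=1.4, z=0.5, t_nd=0.35)
            for w in (0.0, 12.0, 24.0, 36.0)
        }
        trials = make_ddm_trials(truth, n_per_cond=70, seed=0)
        fit = DriftDiffusionModel(trials, DDMModelSpec(varying=("v",))).fit(
            n_starts=3, seed=0
        )
        pf = fit.params_frame().set_index("viscosity")
        slope = np.polyfit(pf.index, pf["v"], 1)[0]
        assert slope < 0
        assert fit.aic == pytest.approx(2 * fit.n_params + 2 * fit.nll)
        assert fit.bic == pytest.approx(
            fit.n_params * np.log(fit.n_trials) + 2 * fit.nll
        )

    def test_nested_ladder_ordering(self):
        truth = {
            w: DDMParams(v=0.8 - 0.02 * w, a=1.3, z=0.52, t_nd=0.3)
            for w in (0.0, 12.0, 24.0, 36.0)
        }
        trials = make_ddm_trials(truth, n_per_cond=70, seed=5)
        fits = fit_model_ladder(trials, n_starts=2, seed=1)
        nlls = [fits[v].nll for v in MODEL_LADDER]
        assert all(a >= b - 1e-6 for a, b in zip(nlls, nlls[1:]))

    def test_low_trial_warning(self):
        truth = {0.0: DDMParams(v=0.5, a=1.2, z=0.5, t_nd=0.2)}
        trials = make_ddm_trials(truth, n_per_cond=10, seed=2)
        with pytest.warns(UserWarning, match="fewer than 20"):
            DriftDiffusionModel(trials, DDMModelSpec(varying=()))


class TestCombination:
    def test_arithmetic_mean(self):
        dur = {1.0: DDMParams(v=0.5, a=1.2, z=0.4, t_nd=0.3)}
        visc = {0.0: DDMParams(v=0.3, a=1.6, z=0.6, t_nd=0.5)}
        combined = combine_duration_viscosity(dur, visc)[(1.0, 0.0)]
        assert combined.v == pytest.approx(0.4)
        assert combined.a == pytest.approx(1.4)
        assert combined.z == pytest.approx(0.5)
        assert combined.t_nd == pytest.approx(0.4)

    def test_idempotent_on_equal_inputs(self):
        p = DDMParams(v=0.7, a=1.1, z=0.45, t_nd=0.25)
        combined = combine_duration_viscosity({2.0: p}, {12.0: p})[(2.0, 12.0)]
        assert combined == p

    def test_combined_model_shifts_psychometrics_with_viscosity(self, kin):
        # viscosity-declining drift + duration-dependent start point:
        # simulated choice curves should shift toward 'short' as
        # viscosity rises, i.e. fewer 'long' responses overall
        from viscotime.synthetic_data import (
            ConditionGrid,
            default_categorization_params,
            simulate_categorization_session,
        )

        grid = ConditionGrid(
            (1.0, 1.26, 1.58, 2.0, 2.52, 3.17, 4.0), (0.0, 36.0), 40, 1
        )
        params = default_categorization_params(grid, v_visc_slope=0.03)
        df = simulate_categorization_session(params, grid, kin, seed=9)
        p_long = df.groupby("viscosity")["choice"].apply(
            lambda s: np.mean(s == "long")
        )
        assert p_long[36.0] < p_long[0.0]


class TestPredictiveCheck:
    def test_degenerate_single_draw(self):
        truth = {
            0.0: DDMParams(v=0.8, a=1.2, z=0.5, t_nd=0.3),
            36.0: DDMParams(v=0.2, a=1.2, z=0.5, t_nd=0.3),
        }
        trials = make_ddm_trials(truth, n_per_cond=50, seed=3)
        from viscotime.ddm import FitResult

        fit = FitResult(
            params_by_condition=truth, nll=0.0, n_params=5, n_trials=100,
            spec=DDMModelSpec(varying=("v",)),
        )
        pc = predictive_check_ddm(fit, trials, n_draws=1, seed=0, rel_sd=0.0)
        # a single unjittered draw: bands collapse onto the point estimate
        assert (pc["sim_p_long_lo"] == pc["sim_p_long_hi"]).all()
        assert (pc["sim_p_long"] == pc["sim_p_long_lo"]).all()

    def test_calibration_on_truth(self):
        truth = {
            w: DDMParams(v=1.0 - 0.02 * w, a=1.3, z=0.5, t_nd=0.3)
            for w in (0.0, 12.0, 24.0, 36.0)
        }
        from viscotime.ddm import FitResult

        inside = 0
        total = 0
        for rep in range(2):
            trials = make_ddm_trials(truth, n_per_cond=70, seed=40 + rep)
            fit = FitResult(
                params_by_condition=truth, nll=0.0, n_params=7, n_trials=280,
                spec=DDMModelSpec(varying=("v",)),
            )
            pc = predictive_check_ddm(fit, trials, n_draws=60, seed=rep)
            inside += (
                pc["obs_p_long"].between(pc["sim_p_long_lo"], pc["sim_p_long_hi"])
            ).sum()
            inside += (
                pc["obs_mean_rt"].between(pc["sim_mean_rt_lo"], pc["sim_mean_rt_hi"])
            ).sum()
            total += 2 * len(pc)
        assert inside / total >= 0.85
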