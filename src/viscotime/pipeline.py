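"""End-to-end demo pipeline on synthetic cohorts.

Simulates both tasks, then runs every analysis stage the package offers:
RT filtering and psychometric fits with BP-viscosity slopes and a
bootstrap CI; per-subject drift-diffusion fits with a predictive check;
observer fits with perception/production variant comparison; and
reproduction summaries with behavior-parameter correlations.  Everything
is seeded, and every output file embeds the seed and config hash.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import io, metrics, observer, psychometrics, synthetic_data
from .ddm import DDMModelSpec, DriftDiffusionModel, predictive_check_ddm
from .observer import BayesianObserverModel, PriorSpec, compare_variants
from .psychometrics import (
    bootstrap_mean_slope_ci,
    bp_vs_viscosity_slopes,
    fit_psychometric_by,
    rt_outlier_filter,
)

logger = logging.getLogger(__name__)

__all__ = ["DemoConfig", "run_demo_pipeline"]


@dataclass(frozen=True)
class DemoConfig:
    """Knobs of the demo cohort; defaults keep a laptop run in minutes."""

    n_subjects: int = 6
    seed: int = 0
    v_visc_slope: float = 0.02  # generating drift decline per Ns/m^2
    b_visc_slope: float = -0.005  # generating offset decline (s per Ns/m^2)
    n_boot: int = psychometrics.N_BOOTSTRAP
    ddm_starts: int = 3
    observer_starts: int = 3
    make_plots: bool = True


def _write_csv(df: pd.DataFrame, path: Path, seed: int, chash: str) -> None:
    """CSV with a leading comment embedding the run's seed and config hash."""
    with open(path, "w") as fh:
        fh.write(f'# {{"seed": {seed}, "config_hash": "{chash}"}}\n')
        df.to_csv(fh, index=False)


def _filter_rts(trials: pd.DataFrame) -> pd.DataFrame:
    kept = []
    for _, grp in trials.groupby("subject"):
        idx = rt_outlier_filter(grp["rt_s"].to_numpy())
        kept.append(grp.iloc[idx])
    return pd.concat(kept, ignore_index=True)


def run_demo_pipeline(config: DemoConfig, out_dir: str | Path) -> Path:
    """Run the full synthetic analysis; returns the report directory."""
    t_start = time.time()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    meta = asdict(config)
    rng = np.random.default_rng(config.seed)
    seeds = rng.integers(0, 2**31 - 1, size=8)
    chash = io.config_hash(meta)
    report: dict = {"seed": config.seed, "config_hash": chash}
    log_file = logging.FileHandler(out / "pipeline.log", mode="w")
    log_file.setFormatter(
        logging.Formatter("%(asctime)s %(levelname)s %(message)s")
    )
    logger.addHandler(log_file)
    logger.setLevel(logging.INFO)
    stage_t0 = time.time()

    def _stage(name: str) -> None:
        nonlocal stage_t0
        logger.info("stage done in %.1f s; next: %s", time.time() - stage_t0, name)
        stage_t0 = time.time()

    # --- stage 1: simulate both tasks -----------------------------------
    _stage("simulate cohorts")
    cat, cat_truth = synthetic_data.simulate_categorization_cohort(
        config.n_subjects, seed=int(seeds[0]), v_visc_slope=config.v_visc_slope
    )
    io.write_trials(cat, out / "trials_categorization.csv", config.seed, meta)
    rep, rep_truth = synthetic_data.simulate_reproduction_cohort(
        config.n_subjects, seed=int(seeds[1]), b_visc_slope=config.b_visc_slope
    )
    io.write_trials(rep, out / "trials_reproduction.csv", config.seed, meta)

    # --- stage 2: psychometrics ------------------------------------------
    _stage("psychometric fits and BP-viscosity slopes")
    cat_f = _filter_rts(cat)
    fits = fit_psychometric_by(cat_f, by=("subject", "viscosity"), seed=int(seeds[2]))
    fit_rows = [
        {"subject": s, "viscosity": w, "mu": f.location, "scale": f.scale,
         "guess": f.guess, "lapse": f.lapse, "bp_s": f.bp, "cv": f.cv, "nll": f.nll}
        for (s, w), f in fits.items()
    ]
    _write_csv(pd.DataFrame(fit_rows), out / "psychometric_fits.csv",
               config.seed, chash)
    slopes = bp_vs_viscosity_slopes(fits)
    ci = bootstrap_mean_slope_ci(
        slopes.per_subject_slopes, n_boot=config.n_boot, seed=int(seeds[3])
    )
    bp_by_visc = (
        pd.DataFrame(fit_rows).groupby("viscosity")["bp_s"].mean().to_dict()
    )
    report["psychometrics"] = {
        "mean_bp_by_viscosity_s": bp_by_visc,
        "mean_bp_slope_s_per_visc": slopes.slope,
        "bootstrap_ci_95": list(ci),
        "per_subject_slopes": list(slopes.per_subject_slopes),
    }

    # --- stage 3: drift-diffusion fits -----------------------------------
    _stage("drift-diffusion fits (viscosity axis)")
    spec = DDMModelSpec(varying=("v",), condition_axis="viscosity")
    ddm_rows, v_slopes = [], []
    pc = None
    for i, (subj, grp) in enumerate(cat.groupby("subject")):
        fit = DriftDiffusionModel(grp, spec).fit(
            n_starts=config.ddm_starts, seed=int(seeds[4]) + i
        )
        pf = fit.params_frame()
        pf.insert(0, "subject", subj)
        pf["nll"] = fit.nll
        pf["aic"] = fit.aic
        pf["bic"] = fit.bic
        ddm_rows.append(pf)
        v_slopes.append(
            np.polyfit(pf["viscosity"], pf["v"], 1)[0]
        )
        if pc is None:
            pc = predictive_check_ddm(fit, grp, n_draws=50, seed=int(seeds[5]))
    ddm_fits = pd.concat(ddm_rows, ignore_index=True)
    _write_csv(ddm_fits, out / "ddm_fits.csv", config.seed, chash)
    _write_csv(pc, out / "ddm_predictive_check.csv", config.seed, chash)
    report["ddm"] = {
        "per_subject_v_slopes": [float(s) for s in v_slopes],
        "fraction_negative_v_slope": float(np.mean(np.array(v_slopes) < 0)),
    }

    # --- stage 4: observer fits and variant comparison -------------------
    _stage("observer fits and variant comparison")
    prior = PriorSpec(
        float(rep["ts_s"].min()), float(rep["ts_s"].max())
    )
    obs_rows, cmp_rows, b_slopes, m_slopes, pref = [], [], [], [], []
    for i, (subj, grp) in enumerate(rep.groupby("subject")):
        cmp = compare_variants(
            grp, prior, n_starts=config.observer_starts, seed=int(seeds[6]) + i
        )
        fit = cmp.attrs["fits"]["perception"]
        pf = fit.params_frame()
        pf.insert(0, "subject", subj)
        obs_rows.append(pf)
        c = cmp.copy()
        c.insert(0, "subject", subj)
        cmp_rows.append(c)
        b_slopes.append(float(np.polyfit(pf["viscosity"], pf["b"], 1)[0]))
        m_slopes.append(float(np.polyfit(pf["viscosity"], pf["m"], 1)[0]))
        tot = cmp[cmp["viscosity"] == "total"].iloc[0]
        pref.append(bool(tot["nll_perception"] < tot["nll_production"]))
    cmp_all = pd.concat(cmp_rows, ignore_index=True)
    totals = cmp_all[cmp_all["viscosity"] == "total"]
    obs_fits = pd.concat(obs_rows, ignore_index=True)
    _write_csv(obs_fits, out / "observer_fits.csv", config.seed, chash)
    _write_csv(cmp_all, out / "observer_variant_comparison.csv",
               config.seed, chash)
    report["observer"] = {
        "per_subject_b_slopes": b_slopes,
        "fraction_negative_b_slope": float(np.mean(np.array(b_slopes) < 0)),
        "fraction_perception_preferred": float(np.mean(pref)),
        "cohort_nll_perception": float(totals["nll_perception"].sum()),
        "cohort_nll_production": float(totals["nll_production"].sum()),
    }

    # --- stage 5: reproduction metrics -----------------------------------
    _stage("reproduction summaries")
    summ = metrics.summarize_reproduction_by(rep)
    _write_csv(summ, out / "reproduction_summary.csv", config.seed, chash)
    ce_by_visc = summ.groupby("viscosity")["constant_error_s"].mean().to_dict()
    ce_slopes = [
        float(np.polyfit(g["viscosity"], g["constant_error_s"], 1)[0])
        for _, g in summ.groupby("subject")
    ]
    report["metrics"] = {
        "mean_constant_error_by_viscosity_s": ce_by_visc,
        "mean_ct_slope": float(summ["slope"].mean()),
        "per_subject_ce_slopes": ce_slopes,
    }
    if config.n_subjects >= 4:
        corr = metrics.slope_parameter_correlation(
            ce_slopes, {"b": b_slopes, "m": m_slopes}, reference="b"
        )
        _write_csv(corr, out / "slope_parameter_correlations.csv",
                   config.seed, chash)
        report["metrics"]["b_slope_pearson_r"] = float(
            corr.loc[corr["parameter"] == "b", "pearson_r"].iloc[0]
        )

    # --- stage 6: plots ---------------------------------------------------
    if config.make_plots:
        _make_plots(cat_f, fits, summ, out)

    report["runtime_s"] = round(time.time() - t_start, 2)
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2)
    logger.info("demo pipeline finished in %.1f s", report["runtime_s"])
    logger.removeHandler(log_file)
    log_file.close()
    return out


def _make_plots(cat: pd.DataFrame, fits, summ: pd.DataFrame, out: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    # cohort-mean psychometric curves by viscosity
    fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(10, 4))
    durations = np.sort(cat["duration_s"].unique())
    grid = np.geomspace(durations[0], durations[-1], 200)
    for w, grp in cat.groupby("viscosity"):
        p_obs = grp.groupby("duration_s")["choice"].apply(
            lambda s: np.mean(s == "long")
        )
        ax1.plot(p_obs.index, p_obs.values, "o", ms=4, label=f"{w:g}")
        curves = [f.predict(grid) for (s, wv), f in fits.items() if wv == w]
        ax1.plot(grid, np.mean(curves, axis=0), "-", lw=1)
    ax1.set_xscale("log")
    ax1.set_xlabel("tone duration (s)")
    ax1.set_ylabel("P('long')")
    ax1.legend(title="viscosity (Ns/m²)", fontsize=7)
    ax1.set_title("psychometric curves")

    for s, grp in summ.groupby("subject"):
        ax2.plot(grp["viscosity"], grp["constant_error_s"], "-o", ms=3, alpha=0.4)
    mean_ce = summ.groupby("viscosity")["constant_error_s"].mean()
    ax2.plot(mean_ce.index, mean_ce.values, "k-o", lw=2, label="cohort mean")
    ax2.axhline(0, color="gray", lw=0.5)
    ax2.set_xlabel("viscosity (Ns/m²)")
    ax2.set_ylabel("constant error (s)")
    ax2.legend(fontsize=7)
    ax2.set_title("reproduction constant error")
    fig.tight_layout()
    fig.savefig(out / "demo_overview.png", dpi=120)
    plt.close(fig)
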