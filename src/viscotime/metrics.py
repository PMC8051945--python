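"""Reproduction-task summary statistics and behavior-parameter correlations.

Constant error (mean reproduced minus presented duration), the
central-tendency slope (OLS of t_p on t_s; below 1 when reproductions
regress toward the mean of the presented range), and the coefficient of
variation (per-duration sd/mean, averaged) are computed after a single
3-SD exclusion pass on raw reproduction times.  Correlation utilities
relate per-subject behavioral slopes to per-subject model-parameter
slopes, with Steiger's Z test comparing dependent correlations that share
the behavioral variable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ReproductionSummary",
    "reproduction_summary",
    "summarize_reproduction_by",
    "exclude_tp_outliers",
    "slope_parameter_correlation",
    "fisher_z_dependent",
]


@dataclass(frozen=True)
class ReproductionSummary:
    """Summary of one subject x viscosity cell of reproduction trials."""

    constant_error: float  # s, mean(t_p - t_s) after exclusion
    slope: float  # OLS slope of t_p on t_s
    intercept: float  # s
    cv: float  # mean over durations of sd(t_p)/mean(t_p)
    n_trials: int
    n_excluded: int


def exclude_tp_outliers(tp: np.ndarray) -> np.ndarray:
    """Boolean keep-mask: reproductions within 3 SD of their mean.

    A single pass on raw t_p by design; the band is not recomputed after
    exclusion, so downstream summaries do not depend on iteration order.
    """
    tp = np.asarray(tp, dtype=float)
    if tp.size < 2:
        return np.ones(tp.size, dtype=bool)
    sd = tp.std(ddof=1)
    if sd == 0:
        return np.ones(tp.size, dtype=bool)
    return np.abs(tp - tp.mean()) <= 3.0 * sd


def reproduction_summary(trials: pd.DataFrame) -> ReproductionSummary:
    """Summaries of one cell (typically one subject x viscosity).

    Applies the 3-SD exclusion on t_p first, then computes the constant
    error, the central-tendency regression of t_p on t_s, and the CV
    averaged over durations (durations left with < 2 kept trials do not
    contribute to the CV).
    """
    ts = trials["ts_s"].to_numpy(dtype=float)
    tp = trials["tp_s"].to_numpy(dtype=float)
    n = tp.size
    keep = exclude_tp_outliers(tp)
    ts, tp = ts[keep], tp[keep]
    if tp.size < 3:
        raise ValueError("fewer than 3 trials remain after outlier exclusion")
    ce = float(np.mean(tp - ts))
    if np.ptp(ts) == 0:
        raise ValueError("central-tendency slope needs at least two durations")
    slope, intercept = np.polyfit(ts, tp, 1)
    cvs = []
    for u in np.unique(ts):
        x = tp[ts == u]
        if x.size >= 2:
            cvs.append(x.std(ddof=1) / x.mean())
    cv = float(np.mean(cvs)) if cvs else float("nan")
    return ReproductionSummary(
        constant_error=ce,
        slope=float(slope),
        intercept=float(intercept),
        cv=cv,
        n_trials=int(n),
        n_excluded=int(n - tp.size),
    )


def summarize_reproduction_by(
    trials: pd.DataFrame,
    by: Sequence[str] = ("subject", "viscosity"),
) -> pd.DataFrame:
    """Grouped reproduction summaries as a tidy table."""
    rows = []
    for key, grp in trials.groupby(list(by), sort=True):
        key = key if isinstance(key, tuple) else (key,)
        s = reproduction_summary(grp)
        rows.append(
            {
                **dict(zip(by, key)),
                "constant_error_s": s.constant_error,
                "slope": s.slope,
                "intercept_s": s.intercept,
                "cv": s.cv,
                "n_trials": s.n_trials,
                "n_excluded": s.n_excluded,
            }
        )
    return pd.DataFrame(rows)


def fisher_z_dependent(
    r_yj: float, r_yk: float, r_jk: float, n: int
) -> tuple[float, float]:
    """Steiger's Z for two dependent correlations sharing variable y.

    Compares r(y, j) with r(y, k) given the correlation r(j, k) between
    the two non-shared variables; returns (Z, two-sided p).
    """
    if n < 4:
        raise ValueError("need at least 4 observations")
    r_yj = float(np.clip(r_yj, -0.9999, 0.9999))
    r_yk = float(np.clip(r_yk, -0.9999, 0.9999))
    z1, z2 = np.arctanh(r_yj), np.arctanh(r_yk)
    rbar2 = ((r_yj + r_yk) / 2.0) ** 2
    num = r_jk * (1.0 - 2.0 * rbar2) - 0.5 * rbar2 * (1.0 - 2.0 * rbar2 - r_jk**2)
    cov = num / (1.0 - rbar2) ** 2
    z = (z1 - z2) * math.sqrt((n - 3) / (2.0 - 2.0 * cov))
    p = 2.0 * stats.norm.sf(abs(z))
    return float(z), float(p)


def slope_parameter_correlation(
    behavior_slopes: Sequence[float],
    param_slopes: Mapping[str, Sequence[float]],
    reference: str | None = None,
) -> pd.DataFrame:
    """Correlate behavioral viscosity-slopes with parameter viscosity-slopes.

    For each model parameter, Pearson and Spearman correlations of its
    per-subject slope against the behavioral slope are reported, plus a
    Steiger Z comparison of each parameter's Pearson correlation against a
    reference parameter (default: the parameter with the largest
    absolute Pearson r).  All slope vectors must align subject-wise.
    """
    y = np.asarray(behavior_slopes, dtype=float)
    if y.size < 4:
        raise ValueError("need at least 4 subjects")
    cols = {}
    for name, v in param_slopes.items():
        v = np.asarray(v, dtype=float)
        if v.size != y.size:
            raise ValueError(f"parameter {name!r} slopes do not align with behavior")
        cols[name] = v

    rows = []
    pearson = {}
    for name, v in cols.items():
        r, pr = stats.pearsonr(y, v)
        rho, ps = stats.spearmanr(y, v)
        pearson[name] = float(r)
        rows.append(
            {"parameter": name, "pearson_r": float(r), "pearson_p": float(pr),
             "spearman_rho": float(rho), "spearman_p": float(ps)}
        )
    if reference is None:
        reference = max(pearson, key=lambda k: abs(pearson[k]))
    for row in rows:
        name = row["parameter"]
        if name == reference:
            row["fisher_z_vs_ref"] = 0.0
            row["fisher_p_vs_ref"] = 1.0
        else:
            r_jk, _ = stats.pearsonr(cols[reference], cols[name])
            z, p = fisher_z_dependent(pearson[reference], pearson[name],
                                      float(r_jk), y.size)
            row["fisher_z_vs_ref"] = z
            row["fisher_p_vs_ref"] = p
    out = pd.DataFrame(rows)
    out.attrs["reference"] = reference
    return out
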