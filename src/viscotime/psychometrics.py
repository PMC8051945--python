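"""Psychometric analysis of temporal bisection choices.

Choice proportions against tone duration are fit with a cumulative Gumbel
(double-exponential) function on the natural-log duration axis — the
appropriate sigmoid for log-spaced interval sets — by binomial maximum
likelihood with fitted guess and lapse rates bounded to [0, 0.1]:

    P(long | t) = guess + (1 - guess - lapse) * G((ln t - mu) / s),
    G(x) = 1 - exp(-exp(x)).

The bisection point (BP) is the duration at which the lapse-free core
curve crosses 0.5, and the coefficient of variation is
CV = (t75 - t25) / (2 * BP), with the quartile durations taken from the
same core curve so the identity holds exactly.  Downstream analyses
regress BP on viscosity per subject (ordinary least squares), bootstrap
the cohort mean slope, and re-fit curves after a within-cell median split
of movement distance.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import xlogy

logger = logging.getLogger(__name__)

__all__ = [
    "PsychometricFit",
    "SlopeResult",
    "GumbelPsychometric",
    "fit_gumbel_psychometric",
    "fit_psychometric_by",
    "bp_vs_viscosity_slopes",
    "bootstrap_mean_slope_ci",
    "median_split_analysis",
    "rt_outlier_filter",
    "N_BOOTSTRAP",
]

#: Default number of non-parametric bootstrap resamples.
N_BOOTSTRAP = 10_000

_LN_LN2 = math.log(math.log(2.0))
_LN_Q25 = math.log(-math.log(0.75))
_LN_Q75 = math.log(-math.log(0.25))


def _gumbel_cdf(x: np.ndarray) -> np.ndarray:
    with np.errstate(over="ignore"):
        return -np.expm1(-np.exp(x))


@dataclass(frozen=True)
class PsychometricFit:
    """Cumulative-Gumbel psychometric fit on log duration.

    location/scale parameterize the core curve on ln(t); bp and cv are the
    bisection point (s) and coefficient of variation derived from it.  A
    set ``boundary`` flag marks degenerate data (all-short or all-long
    responses) whose BP falls outside the tested range.
    """

    location: float
    scale: float
    guess: float
    lapse: float
    bp: float
    cv: float
    nll: float
    boundary: bool = False

    def predict(self, durations: np.ndarray) -> np.ndarray:
        """P(long) at the given durations (s), including guess/lapse."""
        x = (np.log(np.asarray(durations, dtype=float)) - self.location) / self.scale
        return self.guess + (1.0 - self.guess - self.lapse) * _gumbel_cdf(x)

    def quantile(self, q: float) -> float:
        """Duration at which the lapse-free core curve equals ``q``."""
        return math.exp(self.location + self.scale * math.log(-math.log(1.0 - q)))

    def summary(self) -> str:
        return (
            "Gumbel psychometric fit\n"
            f"  location (ln s) : {self.location:.4f}\n"
            f"  scale (ln s)    : {self.scale:.4f}\n"
            f"  guess / lapse   : {self.guess:.4f} / {self.lapse:.4f}\n"
            f"  BP              : {self.bp:.4f} s\n"
            f"  CV              : {self.cv:.4f}\n"
            f"  NLL             : {self.nll:.4f}"
            + ("\n  [boundary fit: BP outside stimulus range]" if self.boundary else "")
        )


@dataclass(frozen=True)
class SlopeResult:
    """Per-subject OLS slopes of BP against viscosity, and their mean."""

    slope: float
    intercept: float
    per_subject_slopes: tuple[float, ...]
    per_subject_intercepts: tuple[float, ...]

    def summary(self) -> str:
        s = np.asarray(self.per_subject_slopes)
        return (
            "BP-vs-viscosity regression\n"
            f"  n subjects   : {len(s)}\n"
            f"  mean slope   : {self.slope:.5f} s per Ns/m^2\n"
            f"  mean intcpt  : {self.intercept:.4f} s\n"
            f"  slope range  : [{s.min():.5f}, {s.max():.5f}]"
        )


class GumbelPsychometric:
    """Binomial ML model of 'long'-choice counts across durations.

    Parameters
    ----------
    durations : tested durations (s), at least 3 distinct values.
    n_long, n_total : aligned counts of 'long' choices and trials.
    """

    def __init__(
        self,
        durations: Sequence[float],
        n_long: Sequence[int],
        n_total: Sequence[int],
    ):
        d = np.asarray(durations, dtype=float)
        k = np.asarray(n_long, dtype=float)
        n = np.asarray(n_total, dtype=float)
        if not (len(d) == len(k) == len(n)):
            raise ValueError("durations, n_long and n_total must align")
        if len(np.unique(d)) < 3:
            raise ValueError("need at least 3 distinct durations")
        if np.any(k > n) or np.any(k < 0) or np.any(n <= 0):
            raise ValueError("counts must satisfy 0 <= n_long <= n_total")
        if np.any(d <= 0):
            raise ValueError("durations must be positive")
        order = np.argsort(d)
        self.durations = d[order]
        self.n_long = k[order]
        self.n_total = n[order]
        self._log_d = np.log(self.durations)

    @classmethod
    def from_trials(cls, trials: pd.DataFrame) -> "GumbelPsychometric":
        """Build from a categorization trial table (duration_s, choice)."""
        g = trials.groupby("duration_s")["choice"]
        agg = g.agg(n_long=lambda s: int((s == "long").sum()), n_total="size")
        return cls(agg.index.to_numpy(), agg["n_long"], agg["n_total"])

    def _nll(self, theta: np.ndarray) -> float:
        mu, s, g, lam = theta
        x = (self._log_d - mu) / s
        p = g + (1.0 - g - lam) * _gumbel_cdf(x)
        p = np.clip(p, 1e-12, 1.0 - 1e-12)
        ll = xlogy(self.n_long, p) + xlogy(self.n_total - self.n_long, 1.0 - p)
        return float(-ll.sum())

    def fit(self, n_starts: int = 4, seed: int | None = None) -> PsychometricFit:
        """Bounded ML fit; multi-start Nelder-Mead guards local minima."""
        rng = np.random.default_rng(seed)
        lo_d, hi_d = self._log_d[0], self._log_d[-1]
        span = max(hi_d - lo_d, 0.1)
        bounds = [(lo_d - 2.0, hi_d + 2.0), (0.01, 5.0), (0.0, 0.1), (0.0, 0.1)]

        frac = self.n_long / self.n_total
        # initial location: linear interpolation of the 50% crossing
        above = np.nonzero(frac >= 0.5)[0]
        mu0 = self._log_d[above[0]] if above.size else hi_d
        starts = [np.array([mu0 - _LN_LN2 * span / 4, span / 4, 0.01, 0.01])]
        for _ in range(n_starts - 1):
            starts.append(
                np.array(
                    [
                        rng.uniform(lo_d, hi_d),
                        rng.uniform(0.05, span),
                        rng.uniform(0, 0.05),
                        rng.uniform(0, 0.05),
                    ]
                )
            )
        best = None
        for x0 in starts:
            res = minimize(
                self._nll,
                np.clip(x0, [b[0] for b in bounds], [b[1] for b in bounds]),
                method="Nelder-Mead",
                bounds=bounds,
                options={"xatol": 1e-6, "fatol": 1e-8, "maxiter": 2000},
            )
            if best is None or res.fun < best.fun:
                best = res
        mu, s, g, lam = best.x
        bp = math.exp(mu + s * _LN_LN2)
        t25 = math.exp(mu + s * _LN_Q25)
        t75 = math.exp(mu + s * _LN_Q75)
        cv = (t75 - t25) / (2.0 * bp)
        boundary = not (self.durations[0] <= bp <= self.durations[-1])
        if boundary:
            warnings.warn(
                f"bisection point {bp:.3g} s lies outside the stimulus range "
                f"[{self.durations[0]:.3g}, {self.durations[-1]:.3g}] s",
                UserWarning,
                stacklevel=2,
            )
        return PsychometricFit(
            location=float(mu),
            scale=float(s),
            guess=float(g),
            lapse=float(lam),
            bp=bp,
            cv=cv,
            nll=float(best.fun),
            boundary=boundary,
        )


def fit_gumbel_psychometric(
    durations: Sequence[float],
    n_long: Sequence[int],
    n_total: Sequence[int],
    seed: int | None = None,
) -> PsychometricFit:
    """Functional wrapper: fit the cumulative-Gumbel psychometric curve."""
    return GumbelPsychometric(durations, n_long, n_total).fit(seed=seed)


def fit_psychometric_by(
    trials: pd.DataFrame,
    by: Sequence[str] = ("subject", "viscosity"),
    seed: int | None = None,
) -> dict[tuple, PsychometricFit]:
    """One psychometric fit per group of a categorization trial table."""
    out = {}
    for key, grp in trials.groupby(list(by), sort=True):
        out[key if isinstance(key, tuple) else (key,)] = GumbelPsychometric.from_trials(
            grp
        ).fit(seed=seed)
    return out


def _ols(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Closed-form simple linear regression (slope, intercept)."""
    xm, ym = x.mean(), y.mean()
    slope = float(((x - xm) * (y - ym)).sum() / ((x - xm) ** 2).sum())
    return slope, float(ym - slope * xm)


def bp_vs_viscosity_slopes(
    fits: Mapping[tuple, PsychometricFit]
) -> SlopeResult:
    """OLS slope of bisection point on viscosity, per subject.

    ``fits`` maps (subject, viscosity) to a fit; every subject needs at
    least two viscosity levels.
    """
    by_subject: dict[object, list[tuple[float, float]]] = {}
    for (subject, visc), fit in fits.items():
        by_subject.setdefault(subject, []).append((float(visc), fit.bp))
    slopes, intercepts = [], []
    for subject in sorted(by_subject, key=str):
        pts = sorted(by_subject[subject])
        if len(pts) < 2:
            raise ValueError(
                f"subject {subject!r} has a single viscosity level; "
                "regression needs at least two"
            )
        x = np.array([p[0] for p in pts])
        y = np.array([p[1] for p in pts])
        s, i = _ols(x, y)
        slopes.append(s)
        intercepts.append(i)
    return SlopeResult(
        slope=float(np.mean(slopes)),
        intercept=float(np.mean(intercepts)),
        per_subject_slopes=tuple(slopes),
        per_subject_intercepts=tuple(intercepts),
    )


def bootstrap_mean_slope_ci(
    per_subject_slopes: Sequence[float],
    n_boot: int = N_BOOTSTRAP,
    level: float = 0.95,
    seed: int | None = None,
) -> tuple[float, float]:
    """Non-parametric percentile CI of the cohort mean slope.

    Subjects are resampled with replacement ``n_boot`` times (default
    10,000) and the central ``level`` interval of the resampled means is
    returned.
    """
    s = np.asarray(per_subject_slopes, dtype=float)
    if s.size == 0:
        raise ValueError("need at least one subject slope")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, s.size, size=(n_boot, s.size))
    means = s[idx].mean(axis=1)
    alpha = (1.0 - level) / 2.0
    return float(np.quantile(means, alpha)), float(np.quantile(means, 1.0 - alpha))


def _median_split_labels(distances: np.ndarray) -> np.ndarray:
    """'low'/'high' labels at the cell median; ties alternate for balance."""
    d = np.asarray(distances, dtype=float)
    med = np.median(d)
    labels = np.empty(d.shape, dtype=object)
    labels[d < med] = "low"
    labels[d > med] = "high"
    ties = np.flatnonzero(d == med)
    n_low = int((d < med).sum())
    n_high = int((d > med).sum())
    for j, i in enumerate(ties):
        if n_low <= n_high:
            labels[i] = "low"
            n_low += 1
        else:
            labels[i] = "high"
            n_high += 1
    return labels


def median_split_analysis(
    trials: pd.DataFrame,
    seed: int | None = None,
) -> dict[tuple, PsychometricFit]:
    """Psychometric fits after a within-cell median split of movement.

    Trials are partitioned at the median movement distance within each
    subject x duration x viscosity cell (ties alternate to keep the splits
    balanced); curves are then re-fit per (subject, viscosity, split).
    Cells with fewer than 2 trials are skipped with a logged warning.
    """
    if trials["move_distance_m"].isna().any():
        raise ValueError("median split requires move_distance_m on every trial")
    labeled = []
    for (subj, d, w), grp in trials.groupby(["subject", "duration_s", "viscosity"]):
        if len(grp) < 2:
            logger.warning(
                "median split: skipping cell (subject=%s, duration=%s, "
                "viscosity=%s) with %d trial(s)", subj, d, w, len(grp)
            )
            continue
        g = grp.copy()
        g["split"] = _median_split_labels(g["move_distance_m"].to_numpy())
        labeled.append(g)
    if not labeled:
        raise ValueError("no cell had enough trials for a median split")
    df = pd.concat(labeled, ignore_index=True)
    return fit_psychometric_by(df, by=("subject", "viscosity", "split"), seed=seed)


def rt_outlier_filter(rts: Sequence[float]) -> np.ndarray:
    """Indices of RTs within 3 SD of the mean log-transformed RT.

    Applied per subject; with zero log-RT variance every trial is kept.
    """
    rt = np.asarray(rts, dtype=float)
    if np.any(rt <= 0):
        raise ValueError("response times must be positive")
    lg = np.log(rt)
    sd = lg.std(ddof=1) if lg.size > 1 else 0.0
    if sd == 0:
        return np.arange(rt.size)
    keep = np.abs(lg - lg.mean()) <= 3.0 * sd
    return np.flatnonzero(keep)
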