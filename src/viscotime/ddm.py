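"""Second-stage drift-diffusion model of temporal categorization.

At tone offset a two-boundary Wiener process decides between the 'short'
and 'long' categories.  The accumulator starts at relative position ``z``
(the 'long' boundary sits at 1, 'short' at 0), drifts at rate ``v``
(positive toward 'long') between boundaries separated by ``a``, and the
observed response time adds a non-decision latency ``t_nd``.  Optional
uniform trial-to-trial jitter of the starting point (``sz``) is handled by
Gauss-Legendre quadrature.  The diffusion coefficient is fixed at 1, the
standard identifiability convention.

The first-passage density uses the small-time / large-time series
expansions with the usual error-bound switching rule.  Likelihoods mix the
Wiener density with a uniform outlier component; per-condition parameters
are estimated by multi-start Nelder-Mead maximum likelihood and compared
with AIC/BIC over the nested ladder null -> v -> va -> vat -> vatz.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize

__all__ = [
    "DDMParams",
    "DDMModelSpec",
    "FitResult",
    "DriftDiffusionModel",
    "wfpt_density",
    "choice_probability",
    "simulate_ddm_trial",
    "simulate_ddm_trials",
    "nll_ddm",
    "fit_ddm",
    "fit_model_ladder",
    "combine_duration_viscosity",
    "predictive_check_ddm",
    "MODEL_LADDER",
]

#: Nested model ladder used for model comparison.
MODEL_LADDER: tuple[tuple[str, ...], ...] = (
    (),
    ("v",),
    ("v", "a"),
    ("v", "a", "t_nd"),
    ("v", "a", "t_nd", "z"),
)

_GL_NODES, _GL_WEIGHTS = np.polynomial.legendre.leggauss(11)


@dataclass(frozen=True)
class DDMParams:
    """Diffusion parameters for one condition.

    v : drift rate (evidence/s, positive drives 'long' responses)
    a : boundary separation (evidence units)
    z : relative starting point in (0, 1); 'long' boundary at 1
    t_nd : non-decision time (s)
    sz : uniform range of starting-point jitter (relative units)
    """

    v: float
    a: float
    z: float = 0.5
    t_nd: float = 0.0
    sz: float = 0.0

    def __post_init__(self) -> None:
        if not (self.a > 0):
            raise ValueError(f"boundary separation a must be > 0, got {self.a}")
        if not (0.0 < self.z < 1.0):
            raise ValueError(f"relative start z must lie in (0, 1), got {self.z}")
        if self.t_nd < 0:
            raise ValueError(f"non-decision time must be >= 0, got {self.t_nd}")
        if self.sz < 0:
            raise ValueError(f"starting-point range sz must be >= 0, got {self.sz}")
        if self.sz > 0 and not (
            self.z - self.sz / 2 > 0 and self.z + self.sz / 2 < 1
        ):
            raise ValueError("z +/- sz/2 must stay strictly inside (0, 1)")


@dataclass(frozen=True)
class DDMModelSpec:
    """Which parameters vary across which condition axis.

    varying : subset of {'v', 'a', 'z', 't_nd'} that differ by condition;
        the rest are shared.
    condition_axis : trial column holding the condition ('duration' or
        'viscosity').
    p_outlier : mixture weight of the uniform contaminant (default 0.05).
    fit_sz : whether the starting-point range is estimated (shared).
    """

    varying: tuple[str, ...] = ("v",)
    condition_axis: str = "viscosity"
    p_outlier: float = 0.05
    fit_sz: bool = False

    def __post_init__(self) -> None:
        bad = set(self.varying) - {"v", "a", "z", "t_nd"}
        if bad:
            raise ValueError(f"cannot vary unknown parameters: {sorted(bad)}")
        if not (0.0 <= self.p_outlier <= 0.5):
            raise ValueError("p_outlier must lie in [0, 0.5]")
        object.__setattr__(self, "varying", tuple(self.varying))


# ---------------------------------------------------------------------------
# First-passage density (density at the *lower* boundary of a unit-diffusion
# process on [0, 1] in scaled time tau = t / a^2, then mapped back).
# ---------------------------------------------------------------------------


def _fpt_lower_scaled(tau: np.ndarray, w: float, tol: float) -> np.ndarray:
    """Density of absorption at 0 for zero drift, unit boundaries, start w.

    Chooses between the small-time and the large-time series per element by
    comparing the number of terms each needs for truncation error ``tol``.
    """
    tau = np.asarray(tau, dtype=float)
    out = np.zeros_like(tau)
    pos = tau > 0
    if not pos.any():
        return out
    t = tau[pos]

    # terms needed by each expansion (standard error bounds)
    with np.errstate(invalid="ignore", divide="ignore"):
        arg_s = 2.0 * np.sqrt(2.0 * np.pi * t) * tol
        ks = np.where(
            arg_s < 1.0,
            2.0 + np.sqrt(np.maximum(-2.0 * t * np.log(arg_s), 0.0)),
            2.0,
        )
        ks = np.maximum(ks, np.sqrt(t) + 1.0)
        arg_l = np.pi * t * tol
        kl = np.where(
            arg_l < 1.0,
            np.sqrt(np.maximum(-2.0 * np.log(arg_l), 0.0) / (np.pi**2 * t)),
            1.0 / (np.pi * np.sqrt(t)),
        )
        kl = np.maximum(kl, 1.0 / (np.pi * np.sqrt(t)))

    use_small = ks < kl
    dens = np.empty_like(t)

    if use_small.any():
        ts = t[use_small]
        K = int(math.ceil((np.max(ks[use_small]) - 1.0) / 2.0))
        k = np.arange(-K, K + 1)[:, None]
        term = (w + 2.0 * k) * np.exp(-((w + 2.0 * k) ** 2) / (2.0 * ts[None, :]))
        dens[use_small] = term.sum(axis=0) / np.sqrt(2.0 * np.pi * ts**3)
    if (~use_small).any():
        tl = t[~use_small]
        K = max(int(math.ceil(np.max(kl[~use_small]))), 1)
        k = np.arange(1, K + 1)[:, None]
        term = k * np.exp(-(k**2) * np.pi**2 * tl[None, :] / 2.0) * np.sin(
            k * np.pi * w
        )
        dens[~use_small] = np.pi * term.sum(axis=0)

    out[pos] = np.maximum(dens, 0.0)
    return out


def _wfpt_lower(t: np.ndarray, v: float, a: float, w: float, tol: float) -> np.ndarray:
    """Joint density of (decision time, lower boundary) for drift v."""
    t = np.asarray(t, dtype=float)
    tau = t / a**2
    base = _fpt_lower_scaled(tau, w, tol) / a**2
    with np.errstate(over="ignore", under="ignore"):
        fac = np.exp(-v * a * w - (v**2) * t / 2.0)
    return base * fac


def wfpt_density(
    rt_dec: float | np.ndarray,
    boundary: str,
    params: DDMParams,
    tol: float = 1e-7,
) -> float | np.ndarray:
    """Joint first-passage density of (decision time, boundary).

    Parameters
    ----------
    rt_dec : decision time in seconds (response time minus non-decision
        time); non-positive values get density 0.
    boundary : 'long' (upper) or 'short' (lower).
    params : diffusion parameters; ``sz > 0`` is integrated out with
        11-node Gauss-Legendre quadrature over the starting-point range.

    Returns
    -------
    density in 1/s, same shape as ``rt_dec``.
    """
    if boundary not in ("long", "short"):
        raise ValueError(f"boundary must be 'long' or 'short', got {boundary!r}")
    t = np.asarray(rt_dec, dtype=float)
    scalar = t.ndim == 0
    t = np.atleast_1d(t)

    if boundary == "long":
        # absorption at the upper boundary of (v, z) mirrors absorption at
        # the lower boundary of (-v, 1-z)
        v_eff, z_eff = -params.v, 1.0 - params.z
    else:
        v_eff, z_eff = params.v, params.z

    if params.sz > 0:
        half = params.sz / 2.0
        zs = z_eff + half * _GL_NODES  # sz range maps symmetrically
        dens = np.zeros_like(t)
        for zk, wk in zip(zs, _GL_WEIGHTS):
            dens += wk * _wfpt_lower(t, v_eff, params.a, zk, tol)
        dens *= 0.5  # Gauss-Legendre weights sum to 2
    else:
        dens = _wfpt_lower(t, v_eff, params.a, z_eff, tol)

    return float(dens[0]) if scalar else dens


def choice_probability(params: DDMParams) -> float:
    """Probability of absorption at the 'long' (upper) boundary.

    Closed form for the two-boundary Wiener process; starting-point jitter
    (sz > 0) is averaged by quadrature.
    """

    def _p(z: float) -> float:
        v, a = params.v, params.a
        if abs(v) < 1e-12:
            return z
        # guard overflow for strongly negative drift
        num = -np.expm1(-2.0 * v * z * a)
        den = -np.expm1(-2.0 * v * a)
        return float(num / den)

    if params.sz > 0:
        half = params.sz / 2.0
        zs = params.z + half * _GL_NODES
        return float(sum(wk * _p(zk) for zk, wk in zip(zs, _GL_WEIGHTS)) * 0.5)
    return _p(params.z)


# ---------------------------------------------------------------------------
# Simulation (Euler-Maruyama, block-vectorized)
# ---------------------------------------------------------------------------


def simulate_ddm_trials(
    params: DDMParams,
    n: int,
    rng: np.random.Generator,
    dt: float = 1e-4,
    max_t: float = 60.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Simulate ``n`` trials; returns (choices, rts).

    choices is a boolean array (True = 'long'); rts include ``t_nd``.
    Paths not absorbed within ``max_t`` simulated seconds are redrawn (with
    a warning), matching the treatment of pathological trials.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    v = np.full(n, params.v)
    a = np.full(n, params.a)
    if params.sz > 0:
        z = params.z + params.sz * (rng.random(n) - 0.5)
    else:
        z = np.full(n, params.z)
    choice, t_dec = _simulate_paths(v, a, z, rng, dt=dt, max_t=max_t)
    return choice, t_dec + params.t_nd


def _simulate_paths(
    v: np.ndarray,
    a: np.ndarray,
    z: np.ndarray,
    rng: np.random.Generator,
    dt: float = 1e-4,
    max_t: float = 60.0,
    block: int = 400,
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized Euler-Maruyama first-passage simulation.

    Accepts per-trial parameter arrays (all same length).  Increments are
    drawn in blocks and cumulated so the Python-level loop runs once per
    ``block`` steps rather than once per step.
    """
    n = len(v)
    x = z * a  # absolute position; boundaries at 0 and a
    choice = np.zeros(n, dtype=bool)
    t_dec = np.full(n, np.nan)
    active = np.arange(n)
    sdt = math.sqrt(dt)
    max_steps = int(max_t / dt)
    step0 = 0
    while active.size and step0 < max_steps:
        m = active.size
        nblk = min(block, max_steps - step0)
        inc = v[active][:, None] * dt + sdt * rng.standard_normal((m, nblk))
        paths = x[active][:, None] + np.cumsum(inc, axis=1)
        hit_up = paths >= a[active][:, None]
        hit_lo = paths <= 0.0
        hit = hit_up | hit_lo
        any_hit = hit.any(axis=1)
        first = np.argmax(hit, axis=1)
        rows = np.flatnonzero(any_hit)
        idx = active[rows]
        t_dec[idx] = (step0 + first[rows] + 1) * dt
        choice[idx] = hit_up[rows, first[rows]]
        # survivors carry the end-of-block position forward
        surv = ~any_hit
        x[active[surv]] = paths[surv, -1]
        active = active[surv]
        step0 += nblk

    if active.size:
        warnings.warn(
            f"{active.size} path(s) not absorbed within {max_t} s; redrawing",
            RuntimeWarning,
            stacklevel=2,
        )
        c2, t2 = _simulate_paths(v[active], a[active], z[active], rng, dt, max_t, block)
        choice[active] = c2
        t_dec[active] = t2
    return choice, t_dec


def simulate_ddm_trial(
    params: DDMParams, seed: int, dt: float = 1e-4, max_t: float = 60.0
) -> tuple[str, float]:
    """Simulate a single trial; returns ('long'|'short', rt in s)."""
    rng = np.random.default_rng(seed)
    choice, rt = simulate_ddm_trials(params, 1, rng, dt=dt, max_t=max_t)
    return ("long" if choice[0] else "short"), float(rt[0])


# ---------------------------------------------------------------------------
# Likelihood
# ---------------------------------------------------------------------------


def _trial_nll(
    rts: np.ndarray,
    is_long: np.ndarray,
    params: DDMParams,
    p_outlier: float,
    rt_range: float,
) -> float:
    """Negative log-likelihood of one condition's trials under the mixture."""
    t_dec = rts - params.t_nd
    dens = np.zeros_like(rts)
    if is_long.any():
        dens[is_long] = wfpt_density(t_dec[is_long], "long", params)
    if (~is_long).any():
        dens[~is_long] = wfpt_density(t_dec[~is_long], "short", params)
    lik = (1.0 - p_outlier) * dens + p_outlier / rt_range
    if np.any(lik <= 0):
        return np.inf
    return float(-np.log(lik).sum())


def nll_ddm(
    trials: pd.DataFrame,
    spec: DDMModelSpec,
    params: Mapping[object, DDMParams],
    rt_range: float | None = None,
) -> float:
    """Mixture negative log-likelihood of a trial table.

    ``trials`` needs columns ``rt_s``, ``choice`` and the condition axis
    (``duration_s`` or ``viscosity``).  ``params`` maps each condition value
    to its :class:`DDMParams`.  The uniform outlier component spans
    (0, rt_range]; by default rt_range is the maximum observed RT, the
    simplest proper support for a right-tail contaminant.

    An infinite value signals zero-likelihood data (e.g. an RT at or below
    the non-decision time with ``p_outlier = 0``).
    """
    col = _axis_column(spec.condition_axis)
    if rt_range is None:
        rt_range = float(trials["rt_s"].max())
    total = 0.0
    for cond, grp in trials.groupby(col, sort=True):
        if cond not in params:
            raise KeyError(f"no parameters for condition {cond!r}")
        rts = grp["rt_s"].to_numpy(dtype=float)
        is_long = grp["choice"].to_numpy() == "long"
        total += _trial_nll(rts, is_long, params[cond], spec.p_outlier, rt_range)
        if not np.isfinite(total):
            return np.inf
    return total


def _axis_column(axis: str) -> str:
    if axis == "duration":
        return "duration_s"
    if axis == "viscosity":
        return "viscosity"
    raise ValueError(f"unknown condition axis {axis!r}")


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------

_BOX = {"v": (-6.0, 6.0), "a": (0.1, 5.0), "z": (0.05, 0.95), "sz": (0.0, 0.8)}


@dataclass
class FitResult:
    """Maximum-likelihood fit of a :class:`DDMModelSpec`.

    params_by_condition maps condition value -> DDMParams; shared
    parameters are identical across entries.
    """

    params_by_condition: dict
    nll: float
    n_params: int
    n_trials: int
    spec: DDMModelSpec
    converged: bool = True
    model: "DriftDiffusionModel | None" = field(default=None, repr=False)

    @property
    def aic(self) -> float:
        return 2.0 * self.n_params + 2.0 * self.nll

    @property
    def bic(self) -> float:
        return self.n_params * math.log(self.n_trials) + 2.0 * self.nll

    def params_frame(self) -> pd.DataFrame:
        rows = []
        for cond, p in sorted(self.params_by_condition.items()):
            rows.append(
                {
                    self.spec.condition_axis: cond,
                    "v": p.v,
                    "a": p.a,
                    "z": p.z,
                    "t_nd": p.t_nd,
                    "sz": p.sz,
                }
            )
        return pd.DataFrame(rows)

    def summary(self) -> str:
        lines = [
            "Drift-diffusion model fit",
            f"  condition axis : {self.spec.condition_axis}",
            f"  varying        : {', '.join(self.spec.varying) or '(none)'}",
            f"  p_outlier      : {self.spec.p_outlier}",
            f"  n trials       : {self.n_trials}",
            f"  n params       : {self.n_params}",
            f"  NLL            : {self.nll:.3f}",
            f"  AIC            : {self.aic:.2f}",
            f"  BIC            : {self.bic:.2f}",
            "",
            self.params_frame().to_string(index=False, float_format="%.4f"),
        ]
        return "\n".join(lines)

    def predictive_check(
        self, n_draws: int = 100, seed: int | None = None, rel_sd: float = 0.05
    ) -> pd.DataFrame:
        if self.model is None:
            raise ValueError("result is detached from its model; "
                             "call predictive_check_ddm with explicit data")
        return predictive_check_ddm(self, self.model.trials, n_draws=n_draws,
                                    seed=seed, rel_sd=rel_sd)


class DriftDiffusionModel:
    """Per-subject ML drift-diffusion model of categorization trials.

    Parameters
    ----------
    trials : trial table with columns ``rt_s``, ``choice`` and the
        condition axis column (``viscosity`` or ``duration_s``).
    spec : which parameters vary by condition, and the outlier weight.

    Fitting maximizes the outlier-mixture Wiener likelihood with
    multi-start Nelder-Mead inside box constraints
    (0.1 < a < 5, |v| < 6, 0.05 < z < 0.95, 0 <= t_nd < min RT).
    """

    def __init__(self, trials: pd.DataFrame, spec: DDMModelSpec | None = None):
        self.spec = spec or DDMModelSpec()
        col = _axis_column(self.spec.condition_axis)
        missing = {col, "rt_s", "choice"} - set(trials.columns)
        if missing:
            raise ValueError(f"trial table lacks columns: {sorted(missing)}")
        self.trials = trials.reset_index(drop=True)
        self.conditions = sorted(trials[col].unique())
        self._col = col
        counts = trials.groupby(col).size()
        if (counts < 20).any():
            warnings.warn(
                "fewer than 20 trials in some conditions; estimates may be "
                "unstable",
                UserWarning,
                stacklevel=2,
            )
        self._min_rt = float(trials["rt_s"].min())
        self._rt_range = float(trials["rt_s"].max())

    # -- parameter vector packing ------------------------------------------
    def _layout(self) -> list[tuple[str, object | None]]:
        """Flat layout: (name, condition) per entry; condition None = shared."""
        lay: list[tuple[str, object | None]] = []
        for name in ("v", "a", "z", "t_nd"):
            if name in self.spec.varying:
                lay.extend((name, c) for c in self.conditions)
            else:
                lay.append((name, None))
        if self.spec.fit_sz:
            lay.append(("sz", None))
        return lay

    def _unpack(self, x: np.ndarray) -> dict:
        lay = self._layout()
        vals: dict[object, dict[str, float]] = {c: {} for c in self.conditions}
        for xi, (name, cond) in zip(x, lay):
            if cond is None:
                for c in self.conditions:
                    vals[c][name] = xi
            else:
                vals[cond][name] = xi
        out = {}
        for c in self.conditions:
            d = vals[c]
            out[c] = DDMParams(
                v=d["v"], a=d["a"], z=d["z"], t_nd=d["t_nd"], sz=d.get("sz", 0.0)
            )
        return out

    def _pack(self, params: Mapping[object, DDMParams]) -> np.ndarray:
        """Flat vector from a condition->params map (shared entries averaged)."""
        x = []
        for name, cond in self._layout():
            if cond is None:
                x.append(float(np.mean([getattr(p, name) for p in params.values()])))
            else:
                x.append(getattr(params[cond], name))
        return np.asarray(x)

    def _bounds(self) -> list[tuple[float, float]]:
        bounds = []
        for name, _ in self._layout():
            if name == "t_nd":
                bounds.append((0.0, max(self._min_rt - 1e-3, 1e-3)))
            else:
                bounds.append(_BOX[name])
        return bounds

    def _objective(self, x: np.ndarray) -> float:
        try:
            params = self._unpack(x)
        except ValueError:
            return np.inf
        return nll_ddm(self.trials, self.spec, params, rt_range=self._rt_range)

    def _heuristic_start(self) -> np.ndarray:
        """Data-driven initial point: drift sign from choice fractions."""
        x = []
        frac = self.trials.groupby(self._col)["choice"].apply(
            lambda s: np.mean(s == "long")
        )
        for name, cond in self._layout():
            if name == "v":
                f = frac[cond] if cond is not None else float(frac.mean())
                x.append(float(np.clip(2.0 * (f - 0.5) * 2.0, -4.0, 4.0)))
            elif name == "a":
                x.append(1.5)
            elif name == "z":
                x.append(0.5)
            elif name == "t_nd":
                x.append(0.5 * self._min_rt)
            elif name == "sz":
                x.append(0.1)
        return np.asarray(x)

    def fit(
        self,
        n_starts: int = 10,
        seed: int | None = None,
        maxiter: int | None = None,
        extra_starts: Sequence[np.ndarray] | Sequence[Mapping] | None = None,
    ) -> FitResult:
        """Best-of-multi-start simplex minimization of the mixture NLL.

        The first start is heuristic (drift signs from choice fractions);
        the rest are uniform draws inside the boxes.  ``extra_starts`` may
        supply additional initial points, either flat vectors or
        condition->DDMParams maps (e.g. a smaller nested model's solution,
        which guarantees the likelihood ordering across the ladder).
        """
        rng = np.random.default_rng(seed)
        bounds = self._bounds()
        lo = np.array([b[0] for b in bounds])
        hi = np.array([b[1] for b in bounds])
        starts = [self._heuristic_start()]
        for s in extra_starts or ():
            starts.append(self._pack(s) if isinstance(s, Mapping) else np.asarray(s))
        for _ in range(max(n_starts - 1, 0)):
            starts.append(lo + (hi - lo) * rng.random(len(bounds)))

        best = None
        errors = []
        for x0 in starts:
            x0 = np.clip(x0, lo + 1e-6, hi - 1e-6)
            try:
                res = minimize(
                    self._objective,
                    x0,
                    method="Nelder-Mead",
                    bounds=bounds,
                    options={
                        "maxiter": maxiter or 400 * len(bounds),
                        "xatol": 1e-4,
                        "fatol": 1e-4,
                    },
                )
            except Exception as exc:  # pragma: no cover - diagnostic path
                errors.append(str(exc))
                continue
            if np.isfinite(res.fun) and (best is None or res.fun < best.fun):
                best = res
        if best is None:
            raise RuntimeError(
                "all optimization starts failed; diagnostics: "
                + ("; ".join(errors) or "non-finite NLL at every start")
            )
        return FitResult(
            params_by_condition=self._unpack(best.x),
            nll=float(best.fun),
            n_params=len(bounds),
            n_trials=len(self.trials),
            spec=self.spec,
            converged=bool(best.success),
            model=self,
        )


def fit_ddm(
    trials: pd.DataFrame,
    spec: DDMModelSpec,
    n_starts: int = 10,
    seed: int | None = None,
) -> FitResult:
    """Functional wrapper: fit ``spec`` to one subject's trials."""
    return DriftDiffusionModel(trials, spec).fit(n_starts=n_starts, seed=seed)


def fit_model_ladder(
    trials: pd.DataFrame,
    condition_axis: str = "viscosity",
    p_outlier: float = 0.05,
    n_starts: int = 3,
    seed: int | None = None,
) -> dict[tuple[str, ...], FitResult]:
    """Fit the nested ladder null -> v -> va -> vat -> vatz in order.

    Each larger model is additionally warm-started from the preceding
    model's solution, so the maximized likelihoods respect the nesting
    (NLL non-increasing along the ladder) up to optimizer tolerance.
    AIC/BIC on the results provide the model comparison.
    """
    out: dict[tuple[str, ...], FitResult] = {}
    prev: FitResult | None = None
    for varying in MODEL_LADDER:
        spec = DDMModelSpec(
            varying=varying, condition_axis=condition_axis, p_outlier=p_outlier
        )
        model = DriftDiffusionModel(trials, spec)
        extra = [prev.params_by_condition] if prev is not None else None
        fit = model.fit(n_starts=n_starts, seed=seed, extra_starts=extra)
        if prev is not None and fit.nll > prev.nll:
            # the warm start bounds the optimum from above; keep it
            fit = FitResult(
                params_by_condition=prev.params_by_condition,
                nll=prev.nll,
                n_params=fit.n_params,
                n_trials=fit.n_trials,
                spec=spec,
                converged=False,
                model=model,
            )
        out[varying] = fit
        prev = fit
    return out


# ---------------------------------------------------------------------------
# Model combination and predictive checks
# ---------------------------------------------------------------------------


def combine_duration_viscosity(
    dur_params: Mapping[float, DDMParams],
    visc_params: Mapping[float, DDMParams],
) -> dict[tuple[float, float], DDMParams]:
    """Average the duration-model and viscosity-model parameters cell-wise.

    Each shared parameter of the combined (duration, viscosity) cell is the
    arithmetic mean of the two marginal models' values, yielding one full
    duration map per viscosity level.
    """
    out = {}
    for d, pd_ in dur_params.items():
        for w, pv in visc_params.items():
            out[(d, w)] = DDMParams(
                v=(pd_.v + pv.v) / 2.0,
                a=(pd_.a + pv.a) / 2.0,
                z=(pd_.z + pv.z) / 2.0,
                t_nd=(pd_.t_nd + pv.t_nd) / 2.0,
                sz=(pd_.sz + pv.sz) / 2.0,
            )
    return out


def predictive_check_ddm(
    fit: FitResult,
    trials: pd.DataFrame,
    n_draws: int = 100,
    seed: int | None = None,
    rel_sd: float = 0.05,
    dt: float = 1e-3,
) -> pd.DataFrame:
    """Parameter-predictive check of a fitted model.

    Each draw jitters the ML estimates with Gaussian noise (relative SD
    ``rel_sd``), simulates a dataset of the observed size, and summarizes
    choice proportion and mean RT per condition.  Returns a table with the
    observed summaries, the simulated means, and 95% simulation bands.
    With ``n_draws=1, rel_sd=0`` this reduces to plain simulation at the
    ML estimates.
    """
    rng = np.random.default_rng(seed)
    col = _axis_column(fit.spec.condition_axis)
    obs = (
        trials.groupby(col)
        .agg(
            n=("rt_s", "size"),
            obs_p_long=("choice", lambda s: np.mean(s == "long")),
            obs_mean_rt=("rt_s", "mean"),
        )
        .reset_index()
    )
    sims = {c: {"p": [], "rt": []} for c in obs[col]}
    for _ in range(n_draws):
        for _, row in obs.iterrows():
            c = row[col]
            p0 = fit.params_by_condition[c]
            p = _jitter_params(p0, rng, rel_sd)
            n = int(row["n"])
            choice, rts = simulate_ddm_trials(p, n, rng, dt=dt)
            sims[c]["p"].append(float(np.mean(choice)))
            sims[c]["rt"].append(float(np.mean(rts)))
    rows = []
    for _, row in obs.iterrows():
        c = row[col]
        ps = np.array(sims[c]["p"])
        ts = np.array(sims[c]["rt"])
        rows.append(
            {
                col: c,
                "n": int(row["n"]),
                "obs_p_long": row["obs_p_long"],
                "sim_p_long": ps.mean(),
                "sim_p_long_lo": np.quantile(ps, 0.025),
                "sim_p_long_hi": np.quantile(ps, 0.975),
                "obs_mean_rt": row["obs_mean_rt"],
                "sim_mean_rt": ts.mean(),
                "sim_mean_rt_lo": np.quantile(ts, 0.025),
                "sim_mean_rt_hi": np.quantile(ts, 0.975),
            }
        )
    return pd.DataFrame(rows)


def _jitter_params(
    p: DDMParams, rng: np.random.Generator, rel_sd: float
) -> DDMParams:
    if rel_sd <= 0:
        return p
    def j(x, lo=None, hi=None):
        scale = abs(x) if abs(x) > 1e-6 else 0.1
        y = x + rel_sd * scale * rng.standard_normal()
        if lo is not None:
            y = max(y, lo)
        if hi is not None:
            y = min(y, hi)
        return y

    z = j(p.z, 0.05 + p.sz / 2, 0.95 - p.sz / 2)
    return DDMParams(
        v=j(p.v),
        a=j(p.a, 0.1),
        z=z,
        t_nd=j(p.t_nd, 0.0),
        sz=p.sz,
    )
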