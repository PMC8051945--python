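"""Synthetic sessions for the two interval-timing tasks.

Emulates the trial structure of the robotic-manipulandum experiments:
7 tone durations x 4 viscosity levels x 10 trials = 280 trials per
subject, randomized with equal condition representation inside each block
(5 blocks for categorization, 10 for reproduction).  Choices and response
times come from the second-stage drift-diffusion process, reproductions
from the Bayesian observer-actor chain, and per-trial kinematic scalars
from a lognormal emulator whose expected movement distance falls — and
expected summed force rises — with viscosity, mirroring the effect of a
velocity-proportional resistive field on arm movements.

All generators are deterministic under a seed.  Times are in seconds
throughout; converters to/from milliseconds exist only at I/O boundaries.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .ddm import DDMParams, simulate_ddm_trials
from .observer import ObserverParams, PriorSpec, simulate_reproductions

__all__ = [
    "DURATIONS_CATEGORIZATION",
    "DURATIONS_REPRODUCTION",
    "VISCOSITIES",
    "RAMP_DURATION_S",
    "SessionConfig",
    "ConditionGrid",
    "KinematicsModel",
    "build_condition_grid",
    "viscosity_ramp",
    "default_categorization_params",
    "default_observer_params",
    "simulate_categorization_session",
    "simulate_reproduction_session",
    "simulate_categorization_cohort",
    "simulate_reproduction_cohort",
]

#: Tone durations of the categorization task (s); log-spaced 1-4 s.
DURATIONS_CATEGORIZATION: tuple[float, ...] = (1.0, 1.26, 1.58, 2.0, 2.52, 3.17, 4.0)
#: Tone durations of the reproduction task (s); linearly spaced 1-4 s.
DURATIONS_REPRODUCTION: tuple[float, ...] = (1.0, 1.5, 2.0, 2.5, 3.0, 3.5, 4.0)
#: Viscosity ladder of the resistive force field (Ns/m^2).
VISCOSITIES: tuple[float, ...] = (0.0, 12.0, 24.0, 36.0)
#: Warm-up ramp length to reach the target viscosity (s).
RAMP_DURATION_S: float = 2.0


@dataclass(frozen=True)
class SessionConfig:
    """Configuration of one synthetic session."""

    task: str = "categorization"
    durations: tuple[float, ...] | None = None
    viscosities: tuple[float, ...] = VISCOSITIES
    trials_per_cell: int = 10
    n_blocks: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.task not in ("categorization", "reproduction"):
            raise ValueError(
                f"task must be 'categorization' or 'reproduction', got {self.task!r}"
            )


@dataclass(frozen=True)
class ConditionGrid:
    """Fully crossed duration x viscosity design with balanced blocks."""

    durations: tuple[float, ...]
    viscosities: tuple[float, ...]
    trials_per_cell: int
    n_blocks: int

    def __post_init__(self) -> None:
        if list(self.durations) != sorted(set(self.durations)):
            raise ValueError("durations must be strictly increasing")
        if list(self.viscosities) != sorted(set(self.viscosities)):
            raise ValueError("viscosities must be strictly increasing")
        if self.viscosities[0] != 0.0:
            raise ValueError("viscosity ladder must start at 0")
        if self.trials_per_cell < 1 or self.n_blocks < 1:
            raise ValueError("trials_per_cell and n_blocks must be positive")
        if self.trials_per_cell % self.n_blocks != 0:
            raise ValueError(
                f"trials_per_cell ({self.trials_per_cell}) must divide evenly "
                f"into {self.n_blocks} blocks for equal representation"
            )

    @property
    def n_cells(self) -> int:
        return len(self.durations) * len(self.viscosities)

    @property
    def total_trials(self) -> int:
        return self.n_cells * self.trials_per_cell

    def block_schedule(self, rng: np.random.Generator) -> pd.DataFrame:
        """Trial order: each block holds every cell equally often, shuffled."""
        per_block = self.trials_per_cell // self.n_blocks
        cells = [
            (d, w) for d in self.durations for w in self.viscosities
        ] * per_block
        frames = []
        for b in range(1, self.n_blocks + 1):
            order = rng.permutation(len(cells))
            blk = pd.DataFrame(
                [cells[i] for i in order], columns=["duration_s", "viscosity"]
            )
            blk.insert(0, "block", b)
            frames.append(blk)
        return pd.concat(frames, ignore_index=True)


def build_condition_grid(config: SessionConfig) -> ConditionGrid:
    """Grid from a session config; defaults reproduce the study designs.

    Categorization: 7 log-spaced durations, 4 viscosities, 10 trials/cell
    = 280 trials in 5 blocks.  Reproduction: 7 linearly spaced durations,
    280 trials in 10 blocks.
    """
    if config.task == "categorization":
        durations = config.durations or DURATIONS_CATEGORIZATION
        n_blocks = config.n_blocks or 5
    else:
        durations = config.durations or DURATIONS_REPRODUCTION
        n_blocks = config.n_blocks or 10
    return ConditionGrid(
        durations=tuple(durations),
        viscosities=tuple(config.viscosities),
        trials_per_cell=config.trials_per_cell,
        n_blocks=n_blocks,
    )


def viscosity_ramp(t: float, v_target: float, ramp_dur: float = RAMP_DURATION_S) -> float:
    """Warm-up viscosity at time ``t``: linear to ``v_target``, then flat."""
    if ramp_dur <= 0:
        raise ValueError("ramp_dur must be > 0")
    if t < 0:
        raise ValueError("t must be >= 0")
    return v_target * min(t / ramp_dur, 1.0)


@dataclass(frozen=True)
class KinematicsModel:
    """Per-trial movement-distance and summed-force emulator.

    Distance is lognormal with median ``base_distance * distance_decay **
    viscosity``; summed force is ``force_base + force_gain * viscosity *
    distance``.  Expected distance therefore falls monotonically with
    viscosity while expected force rises, the qualitative signature of a
    resistive field.
    """

    base_distance: float = 1.0  # m, median summed path at zero viscosity
    distance_decay: float = 0.99  # per Ns/m^2 multiplicative factor
    force_base: float = 2.0  # N, baseline summed force
    force_gain: float = 0.5  # N per (Ns/m^2 * m)
    noise_cv: float = 0.3

    def __post_init__(self) -> None:
        if not (0 < self.distance_decay < 1):
            raise ValueError("distance_decay must lie in (0, 1)")
        if self.base_distance <= 0 or self.force_gain <= 0:
            raise ValueError("base_distance and force_gain must be > 0")

    def sample(
        self, viscosity: np.ndarray, rng: np.random.Generator
    ) -> tuple[np.ndarray, np.ndarray]:
        visc = np.asarray(viscosity, dtype=float)
        median = self.base_distance * self.distance_decay**visc
        sigma = math.sqrt(math.log(1.0 + self.noise_cv**2))
        dist = np.exp(np.log(median) + sigma * rng.standard_normal(visc.shape))
        force = self.force_base + self.force_gain * visc * dist
        force *= np.exp(0.05 * rng.standard_normal(visc.shape))
        return dist, force


# ---------------------------------------------------------------------------
# Default generating parameters (the study conditions of the simulator)
# ---------------------------------------------------------------------------


def default_categorization_params(
    grid: ConditionGrid,
    v_gain: float = 3.0,
    v_visc_slope: float = 0.02,
    z_gain: float = 0.5,
    a: float = 1.4,
    t_nd: float = 0.35,
    sz: float = 0.0,
) -> dict[tuple[float, float], DDMParams]:
    """Ground-truth second-stage parameters per (duration, viscosity) cell.

    The first-stage linkage is emulated by letting both the starting point
    and the drift grow with log duration (longer tones leave the
    accumulator, hence the second stage, closer to the 'long' boundary),
    while viscosity subtracts ``v_visc_slope * viscosity`` from the drift
    — the compressive effect that shifts bisection points rightward.
    """
    logs = np.log(grid.durations)
    x = (logs - logs.mean()) / (logs.max() - logs.min())  # in [-0.5, 0.5]
    out = {}
    for d, xd in zip(grid.durations, x):
        for w in grid.viscosities:
            z = float(np.clip(0.5 + z_gain * xd, 0.12, 0.88))
            if sz > 0:
                z = float(np.clip(z, sz / 2 + 0.02, 1 - sz / 2 - 0.02))
            out[(d, w)] = DDMParams(
                v=float(v_gain * xd - v_visc_slope * w),
                a=a,
                z=z,
                t_nd=t_nd,
                sz=sz,
            )
    return out


def default_observer_params(
    viscosities: Sequence[float] = VISCOSITIES,
    m: float = 0.12,
    p: float = 0.08,
    b0: float = 0.05,
    b_visc_slope: float = -0.005,
    variant: str = "perception",
) -> dict[float, ObserverParams]:
    """Ground-truth observer parameters per viscosity.

    The offset declines linearly with viscosity (default -0.005 s per
    Ns/m^2, i.e. -0.18 s across the ladder), emulating compression of
    perceived duration in resistive environments.
    """
    return {
        float(w): ObserverParams(m=m, p=p, b=b0 + b_visc_slope * w, variant=variant)
        for w in viscosities
    }


# ---------------------------------------------------------------------------
# Session simulators
# ---------------------------------------------------------------------------


def simulate_categorization_session(
    params_by_condition: Mapping[tuple[float, float], DDMParams],
    grid: ConditionGrid,
    kin: KinematicsModel,
    seed: int,
    subject: str = "S01",
    dt: float = 1e-3,
) -> pd.DataFrame:
    """One categorization session: choices and RTs from the diffusion model.

    Every (duration, viscosity) cell must resolve to a :class:`DDMParams`
    entry.  Returns the standard trial table (one row per grid slot) with
    kinematic scalars attached; fully reproducible under ``seed``.
    """
    rng = np.random.default_rng(seed)
    sched = grid.block_schedule(rng)
    for d in grid.durations:
        for w in grid.viscosities:
            if (d, w) not in params_by_condition:
                raise KeyError(f"no DDM parameters for cell (duration={d}, viscosity={w})")

    choices = np.empty(len(sched), dtype=object)
    rts = np.empty(len(sched))
    for (d, w), idx in sched.groupby(["duration_s", "viscosity"]).groups.items():
        idx = np.asarray(idx)
        params = params_by_condition[(d, w)]
        ch, rt = simulate_ddm_trials(params, len(idx), rng, dt=dt)
        choices[idx] = np.where(ch, "long", "short")
        rts[idx] = rt

    dist, force = kin.sample(sched["viscosity"].to_numpy(), rng)
    out = sched.copy()
    out.insert(0, "task", "categorization")
    out.insert(0, "subject", subject)
    out["choice"] = choices
    out["rt_s"] = rts
    out["ts_s"] = np.nan
    out["tp_s"] = np.nan
    out["move_distance_m"] = dist
    out["force_n"] = force
    return out


def simulate_reproduction_session(
    params_by_viscosity: Mapping[float, ObserverParams],
    grid: ConditionGrid,
    kin: KinematicsModel,
    seed: int,
    subject: str = "S01",
    prior: PriorSpec | None = None,
) -> pd.DataFrame:
    """One reproduction session via the full observer generative chain."""
    rng = np.random.default_rng(seed)
    sched = grid.block_schedule(rng)
    if prior is None:
        prior = PriorSpec(min(grid.durations), max(grid.durations))
    for w in grid.viscosities:
        if w not in params_by_viscosity:
            raise KeyError(f"no observer parameters for viscosity {w}")

    tp = np.empty(len(sched))
    for w, idx in sched.groupby("viscosity").groups.items():
        idx = np.asarray(idx)
        ts = sched.loc[idx, "duration_s"].to_numpy(dtype=float)
        tp[idx] = simulate_reproductions(ts, params_by_viscosity[w], prior, rng)

    dist, force = kin.sample(sched["viscosity"].to_numpy(), rng)
    out = sched.copy()
    out.insert(0, "task", "reproduction")
    out.insert(0, "subject", subject)
    out["choice"] = ""
    out["rt_s"] = np.nan
    out["ts_s"] = out["duration_s"]
    out["tp_s"] = tp
    out["move_distance_m"] = dist
    out["force_n"] = force
    out["duration_s"] = np.nan
    return out


# ---------------------------------------------------------------------------
# Cohorts (between-subject variability around the generating parameters)
# ---------------------------------------------------------------------------


def _jitter(rng: np.random.Generator, x: float, rel: float) -> float:
    return float(x * math.exp(rel * rng.standard_normal())) if x != 0 else 0.0


def simulate_categorization_cohort(
    n_subjects: int,
    grid: ConditionGrid | None = None,
    kin: KinematicsModel | None = None,
    seed: int = 0,
    v_visc_slope: float = 0.02,
    between_subject_sd: float = 0.15,
    dt: float = 1e-3,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a cohort; returns (trials, per-subject true parameters).

    Each subject's boundary separation, non-decision time, drift gain and
    drift-viscosity slope are lognormally jittered around the defaults
    (relative SD ``between_subject_sd``).
    """
    grid = grid or build_condition_grid(SessionConfig(task="categorization"))
    kin = kin or KinematicsModel()
    rng = np.random.default_rng(seed)
    frames, truths = [], []
    for i in range(n_subjects):
        sid = f"S{i + 1:02d}"
        params = default_categorization_params(
            grid,
            v_gain=_jitter(rng, 3.0, between_subject_sd),
            v_visc_slope=_jitter(rng, v_visc_slope, between_subject_sd),
            a=_jitter(rng, 1.4, between_subject_sd),
            t_nd=_jitter(rng, 0.35, between_subject_sd),
        )
        sess_seed = int(rng.integers(0, 2**31 - 1))
        frames.append(
            simulate_categorization_session(params, grid, kin, sess_seed, sid, dt=dt)
        )
        p00 = params[(grid.durations[0], 0.0)]
        vs = {w: params[(grid.durations[3], w)].v for w in grid.viscosities}
        truths.append({"subject": sid, "a": p00.a, "t_nd": p00.t_nd, **{
            f"v_visc{int(w)}": v for w, v in vs.items()}})
    return pd.concat(frames, ignore_index=True), pd.DataFrame(truths)


def simulate_reproduction_cohort(
    n_subjects: int,
    grid: ConditionGrid | None = None,
    kin: KinematicsModel | None = None,
    seed: int = 0,
    b_visc_slope: float = -0.005,
    between_subject_sd: float = 0.15,
    variant: str = "perception",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a reproduction cohort; returns (trials, true parameters)."""
    grid = grid or build_condition_grid(SessionConfig(task="reproduction"))
    kin = kin or KinematicsModel()
    rng = np.random.default_rng(seed)
    frames, truths = [], []
    for i in range(n_subjects):
        sid = f"S{i + 1:02d}"
        m = _jitter(rng, 0.12, between_subject_sd)
        p = _jitter(rng, 0.08, between_subject_sd)
        b0 = 0.05 + 0.03 * rng.standard_normal()
        slope = b_visc_slope * math.exp(between_subject_sd * rng.standard_normal())
        params = default_observer_params(
            grid.viscosities, m=m, p=p, b0=b0, b_visc_slope=slope, variant=variant
        )
        sess_seed = int(rng.integers(0, 2**31 - 1))
        frames.append(
            simulate_reproduction_session(params, grid, kin, sess_seed, sid)
        )
        truths.append(
            {"subject": sid, "m": m, "p": p, "b0": b0, "b_visc_slope": slope,
             **{f"b_visc{int(w)}": params[w].b for w in grid.viscosities}}
        )
    return pd.concat(frames, ignore_index=True), pd.DataFrame(truths)
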