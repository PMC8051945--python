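import numpy as np
import pandas as pd
import pytest

from viscotime.ddm import DDMParams
from viscotime.observer import ObserverParams, PriorSpec, simulate_reproductions
from viscotime.synthetic_data import (
    ConditionGrid,
    KinematicsModel,
    SessionConfig,
    build_condition_grid,
)


@pytest.fixture(scope="session")
def cat_grid() -> ConditionGrid:
    return build_condition_grid(SessionConfig(task="categorization"))


@pytest.fixture(scope="session")
def rep_grid() -> ConditionGrid:
    return build_condition_grid(SessionConfig(task="reproduction"))


@pytest.fixture(scope="session")
def kin() -> KinematicsModel:
    return KinematicsModel()


@pytest.fixture(scope="session")
def prior() -> PriorSpec:
    return PriorSpec(1.0, 4.0)


def make_ddm_trials(
    params_by_visc: dict[float, DDMParams],
    n_per_cond: int,
    seed: int,
    dt: float = 1e-3,
) -> pd.DataFrame:
    """Single-axis categorization trials straight from the diffusion model."""
    from viscotime.ddm import simulate_ddm_trials

    rng = np.random.default_rng(seed)
    rows = []
    for w, p in params_by_visc.items():
        ch, rt = simulate_ddm_trials(p, n_per_cond, rng, dt=dt)
        for c, r in zip(ch, rt):
            rows.append(
                {"viscosity": w, "rt_s": float(r),
                 "choice": "long" if c else "short"}
            )
    return pd.DataFrame(rows)


def make_observer_trials(
    params_by_visc: dict[float, ObserverParams],
    durations: list[float],
    n_per_cell: int,
    prior: PriorSpec,
    seed: int,
) -> pd.DataFrame:
    """Reproduction trials from the observer generative chain."""
    rng = np.random.default_rng(seed)
    rows = []
    for w, p in params_by_visc.items():
        for d in durations:
            ts = np.full(n_per_cell, d)
            tp = simulate_reproductions(ts, p, prior, rng)
            rows.extend(
                {"viscosity": w, "ts_s": float(a), "tp_s": float(b)}
                for a, b in zip(ts, tp)
            )
    return pd.DataFrame(rows)
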