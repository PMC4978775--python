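"""Synthetic phospho-time-course datasets with western-blot noise structure.

Quantitative western blots report band intensities that are positive and
whose errors scale with signal, so measurement noise is modeled as
multiplicative lognormal with a configurable coefficient of variation
(default 0.1).  Each site's series is normalized by its own 90-min value,
as blot data are, which means the 90-min point is exactly 1 by construction
and time-zero points that are exactly 0 stay 0 (multiplicative noise cannot
create signal).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .network import ReactionNetwork, build_network, build_validation_network
from .params import RateParameterSet
from .simulate import (
    DEFAULT_GRID_MIN,
    TRAINING_LABELS,
    Condition,
    observables,
    simulate,
    standard_conditions,
)


@dataclass
class ExperimentDataset:
    """One condition's normalized phospho-Y394/phospho-Y505 time series."""

    condition_label: str
    times_min: np.ndarray
    y394: np.ndarray
    y505: np.ndarray
    truth_params: RateParameterSet | None = None

    def __post_init__(self) -> None:
        self.times_min = np.asarray(self.times_min, dtype=float)
        self.y394 = np.asarray(self.y394, dtype=float)
        self.y505 = np.asarray(self.y505, dtype=float)
        n = len(self.times_min)
        if n < 2:
            raise ValueError("a dataset needs at least 2 time points")
        if len(self.y394) != n or len(self.y505) != n:
            raise ValueError("time and intensity columns differ in length")
        if np.any(self.y394 < 0) or np.any(self.y505 < 0):
            raise ValueError("normalized intensities must be >= 0")

    @property
    def n(self) -> int:
        return len(self.times_min)


def _lognormal_factors(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Mean-1 multiplicative noise with coefficient of variation ``cv``."""
    if cv == 0:
        return np.ones(size)
    sigma2 = np.log1p(cv * cv)
    return rng.lognormal(mean=-sigma2 / 2.0, sigma=np.sqrt(sigma2), size=size)


def _renormalize(times_min: np.ndarray, values: np.ndarray) -> np.ndarray:
    anchor = values[np.argmin(np.abs(times_min - 90.0))]
    if anchor <= 0:
        raise ValueError("90-min anchor value is zero; cannot renormalize")
    return values / anchor


def generate_dataset(
    params: RateParameterSet,
    condition: Condition,
    noise_cv: float = 0.1,
    seed: int = 0,
    times_min: np.ndarray | None = None,
    network: ReactionNetwork | None = None,
    rtol: float = 1e-8,
    atol: float = 1e-12,
) -> ExperimentDataset:
    """Simulate, sample on the blot time grid, apply noise, renormalize.

    The grid must contain a point at (or near) 90 min, the normalization
    anchor.  Reproducible for a fixed seed.
    """
    if noise_cv < 0:
        raise ValueError("noise_cv must be >= 0")
    if times_min is None:
        times_min = np.array(DEFAULT_GRID_MIN)
    times_min = np.asarray(times_min, dtype=float)
    if network is None:
        network = (
            build_validation_network()
            if condition.dead_lck_density > 0
            else build_network()
        )
    traj = simulate(
        network, params, condition, output_times=times_min * 60.0,
        rtol=rtol, atol=atol,
    )
    obs = observables(traj, normalization="total_lck")
    rng = np.random.default_rng(seed)
    y394 = obs.phospho_y394 * _lognormal_factors(rng, noise_cv, len(times_min))
    y505 = obs.phospho_y505 * _lognormal_factors(rng, noise_cv, len(times_min))
    return ExperimentDataset(
        condition_label=condition.label or "unnamed",
        times_min=times_min,
        y394=_renormalize(times_min, y394),
        y505=_renormalize(times_min, y505),
        truth_params=params,
    )


def generate_training_set(
    params: RateParameterSet,
    noise_cv: float = 0.1,
    seed: int = 0,
    initial_p505: float = 0.0,
    times_min: np.ndarray | None = None,
    network: ReactionNetwork | None = None,
) -> dict[str, ExperimentDataset]:
    """The four training conditions, each with an independent noise stream."""
    conds = standard_conditions(initial_p505)
    network = network or build_network()
    return {
        label: generate_dataset(
            params, conds[label], noise_cv, seed=seed + i,
            times_min=times_min, network=network,
        )
        for i, label in enumerate(TRAINING_LABELS)
    }


def generate_validation_dataset(
    params: RateParameterSet,
    noise_cv: float = 0.1,
    seed: int = 1000,
    initial_p505: float = 0.0,
    times_min: np.ndarray | None = None,
) -> ExperimentDataset:
    """The mixed active/dead condition simulated on the dead-LCK network."""
    cond = standard_conditions(initial_p505)["validation"]
    return generate_dataset(
        params, cond, noise_cv, seed=seed,
        times_min=times_min, network=build_validation_network(),
    )


# -- CSV I/O ---------------------------------------------------------------------


def write_dataset(dataset: ExperimentDataset, path: str | Path) -> None:
    """Write as wide CSV: time_min, y394, y505."""
    pd.DataFrame(
        {
            "time_min": dataset.times_min,
            "y394": dataset.y394,
            "y505": dataset.y505,
        }
    ).to_csv(path, index=False)


def load_dataset(
    path: str | Path, condition_label: str | None = None
) -> ExperimentDataset:
    """Read a wide (time_min,y394,y505) or long (time_min,variable,value) CSV.

    Raises ``ValueError`` naming the offending rows for negative or
    duplicated times and malformed values.
    """
    path = Path(path)
    df = pd.read_csv(path)
    if {"time_min", "variable", "value"}.issubset(df.columns):
        df = df.pivot(index="time_min", columns="variable", values="value")
        df = df.reset_index()
    required = {"time_min", "y394", "y505"}
    if not required.issubset(df.columns):
        raise ValueError(
            f"{path.name}: expected columns {sorted(required)}, got {list(df.columns)}"
        )
    bad = df.index[df[list(required)].isna().any(axis=1)].tolist()
    if bad:
        raise ValueError(f"{path.name}: malformed values in rows {bad}")
    neg = df.index[df["time_min"] < 0].tolist()
    if neg:
        raise ValueError(f"{path.name}: negative time in rows {neg}")
    dup = df.index[df["time_min"].duplicated()].tolist()
    if dup:
        raise ValueError(f"{path.name}: duplicated times in rows {dup}")
    df = df.sort_values("time_min")
    return ExperimentDataset(
        condition_label=condition_label or path.stem,
        times_min=df["time_min"].to_numpy(),
        y394=df["y394"].to_numpy(),
        y505=df["y505"].to_numpy(),
    )
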