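"""Stiff ODE integration of the network and the phospho-site observables.

Experimental conditions are surface densities on a supported lipid bilayer
(molecules/um^2).  The canonical training conditions are 500 LCK, 500 LCK +
500 CSK, 50 LCK, and 50 LCK + 500 CSK; the validation condition mixes 250
active with 250 catalytically dead LCK and contains no CSK.  Simulations run
to 90 min (5400 s).  Phospho-site observables count phosphate at a site over
*all* species containing an LCK molecule -- free or bound, active or dead --
and are normalized either by total LCK density (the conserved total, the
default) or by that site's own level at 90 min (how western-blot data are
normalized).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp

from .network import ReactionNetwork, build_rhs
from .params import RateParameterSet

NINETY_MIN_S = 5400.0

#: default observation grid (minutes) spanning the fast early phase
DEFAULT_GRID_MIN = (0.0, 0.25, 0.5, 1.0, 2.0, 5.0, 10.0, 15.0, 30.0, 45.0, 60.0, 90.0)


@dataclass(frozen=True)
class Condition:
    """Initial surface densities and the simulation horizon."""

    lck_density: float
    csk_density: float = 0.0
    dead_lck_density: float = 0.0
    initial_phospho_y505_fraction: float = 0.0
    duration: float = NINETY_MIN_S
    label: str = ""

    def __post_init__(self) -> None:
        for name in ("lck_density", "csk_density", "dead_lck_density"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0 <= self.initial_phospho_y505_fraction <= 1:
            raise ValueError("initial_phospho_y505_fraction must be in [0, 1]")


def standard_conditions(initial_p505: float = 0.0) -> dict[str, Condition]:
    """The four training conditions plus the mixed active/dead validation one.

    ``initial_p505`` optionally seeds a small pre-phosphorylated Y505 pool
    (the blots show ~1.5% at time zero); default 0.
    """
    f = initial_p505
    return {
        "high_lck": Condition(500.0, 0.0, initial_phospho_y505_fraction=f, label="high_lck"),
        "high_lck_csk": Condition(500.0, 500.0, initial_phospho_y505_fraction=f, label="high_lck_csk"),
        "low_lck": Condition(50.0, 0.0, initial_phospho_y505_fraction=f, label="low_lck"),
        "low_lck_csk": Condition(50.0, 500.0, initial_phospho_y505_fraction=f, label="low_lck_csk"),
        "validation": Condition(
            250.0, 0.0, dead_lck_density=250.0,
            initial_phospho_y505_fraction=f, label="validation",
        ),
    }

TRAINING_LABELS = ("high_lck", "high_lck_csk", "low_lck", "low_lck_csk")


@dataclass
class TrajectorySet:
    """Integrated species densities at the requested output times."""

    times: np.ndarray  # seconds
    densities: np.ndarray  # (n_times, n_species)
    condition: Condition
    network: ReactionNetwork

    def total(self, weights: np.ndarray) -> np.ndarray:
        return self.densities @ weights

    def conserved_residual(self) -> float:
        """Max relative drift of any conserved total along the trajectory."""
        worst = 0.0
        for w in self.network.conservation_groups.values():
            tot = self.total(w)
            if abs(tot[0]) < 1e-30:
                worst = max(worst, float(np.max(np.abs(tot))))
            else:
                worst = max(worst, float(np.max(np.abs(tot / tot[0] - 1.0))))
        return worst


@dataclass
class ObservableSeries:
    """Normalized per-site phospho levels plus species-composition fractions."""

    times: np.ndarray  # seconds
    phospho_y394: np.ndarray
    phospho_y505: np.ndarray
    # per-form fraction of total LCK: {"UU": {"total":..,"free":..,"bound":..}, ...}
    species_fractions: dict[str, dict[str, np.ndarray]] = field(default_factory=dict)

    @property
    def times_min(self) -> np.ndarray:
        return self.times / 60.0


def initial_state(network: ReactionNetwork, condition: Condition) -> np.ndarray:
    """All LCK unphosphorylated (minus the optional Y505-phosphorylated pool),
    all CSK free, no dimers."""
    y0 = np.zeros(len(network.species))
    f = condition.initial_phospho_y505_fraction
    y0[network.index["UU"]] = condition.lck_density * (1 - f)
    if f > 0:
        y0[network.index["UP"]] = condition.lck_density * f
    if condition.dead_lck_density > 0:
        if "UU*" not in network.index:
            raise ValueError(
                "condition includes dead LCK but the network has no dead species"
            )
        y0[network.index["UU*"]] = condition.dead_lck_density * (1 - f)
        if f > 0:
            y0[network.index["UP*"]] = condition.dead_lck_density * f
    if "CSK" in network.index:
        y0[network.index["CSK"]] = condition.csk_density
    return y0


def default_output_times(duration: float = NINETY_MIN_S) -> np.ndarray:
    """Dense log-spaced early points plus the standard minute grid."""
    early = np.logspace(-1, np.log10(duration), 120)
    grid = np.array(DEFAULT_GRID_MIN) * 60.0
    t = np.unique(np.concatenate([[0.0], early, grid[grid <= duration]]))
    return t[t <= duration]


def simulate(
    network: ReactionNetwork,
    params: RateParameterSet,
    condition: Condition,
    output_times: np.ndarray | None = None,
    rtol: float = 1e-8,
    atol: float = 1e-12,
    method: str = "LSODA",
) -> TrajectorySet:
    """Integrate the network under one condition with a stiff-capable solver.

    Raises ``RuntimeError`` naming the condition if the integrator fails.
    """
    if output_times is None:
        output_times = default_output_times(condition.duration)
    output_times = np.asarray(output_times, dtype=float)
    if output_times.max() > condition.duration:
        raise ValueError("output time beyond condition duration")
    rhs = build_rhs(network, params)
    y0 = initial_state(network, condition)
    sol = solve_ivp(
        rhs,
        (0.0, condition.duration),
        y0,
        method=method,
        t_eval=output_times,
        jac=rhs.jac,
        rtol=rtol,
        atol=atol,
    )
    if not sol.success:
        raise RuntimeError(
            f"integration failed for condition {condition.label or condition}: "
            f"{sol.message}"
        )
    return TrajectorySet(sol.t, sol.y.T, condition, network)


def _value_at(times: np.ndarray, series: np.ndarray, t: float) -> float:
    return float(np.interp(t, times, series))


def observables(
    traj: TrajectorySet,
    normalization: str = "total_lck",
    clip_negative: bool = True,
) -> ObservableSeries:
    """Compute normalized phospho-Y394/phospho-Y505 series and species fractions.

    ``normalization='total_lck'`` divides by the conserved total LCK density;
    ``'site_90min'`` divides each site by its own level at 90 min (matching
    blot normalization; requires the trajectory to reach 90 min).
    """
    net = traj.network
    dens = traj.densities
    if clip_negative:
        dens = np.where(np.abs(dens) < 1e-9, np.maximum(dens, 0.0), dens)
    p394 = dens @ net.phospho_y394_counts()
    p505 = dens @ net.phospho_y505_counts()
    total_lck = float(traj.total(net.lck_counts())[0])
    if normalization == "total_lck":
        if total_lck <= 0:
            raise ValueError("total LCK is zero; cannot normalize")
        n394 = n505 = total_lck
    elif normalization == "site_90min":
        if traj.times.max() < NINETY_MIN_S:
            raise ValueError("site_90min normalization needs a 90 min trajectory")
        n394 = _value_at(traj.times, p394, NINETY_MIN_S)
        n505 = _value_at(traj.times, p505, NINETY_MIN_S)
        if n394 <= 0 or n505 <= 0:
            raise ValueError("90 min phospho level is zero; cannot normalize")
    else:
        raise ValueError(f"unknown normalization {normalization!r}")

    fractions: dict[str, dict[str, np.ndarray]] = {}
    if total_lck > 0:
        free = np.array([s.kind == "free_lck" for s in net.species])
        for form in ("UU", "PU", "UP", "PP"):
            count = net.count_vector(lambda m, f=form: m.form == f)
            tot = dens @ count
            fr = dens @ (count * free)
            fractions[form] = {
                "total": tot / total_lck,
                "free": fr / total_lck,
                "bound": (tot - fr) / total_lck,
            }
    return ObservableSeries(traj.times, p394 / n394, p505 / n505, fractions)


def fraction_doubly_phosphorylated(traj: TrajectorySet, t: float) -> float:
    """Fraction of total LCK (free + bound) in the P394P505 form at time t."""
    if t > traj.times.max() + 1e-9:
        raise ValueError("t beyond the simulated horizon")
    pp = traj.total(traj.network.doubly_phospho_counts())
    total = traj.total(traj.network.lck_counts())[0]
    return _value_at(traj.times, pp, t) / total
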