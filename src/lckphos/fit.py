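"""Two-stage ensemble parameter estimation.

Stage 1 is a global particle-swarm search minimizing a hybrid weighted
sum-of-squared-residuals (WSSR) objective; stage 2 refines each swarm
result with a trust-region-reflective nonlinear least-squares fit of the
purely quantitative WSSR.

For measured points C_exp and simulated points C_sim at the same times,

    WSSR_quant = sum_i [W_i^394 (C_exp,i^394 - C_sim,i^394)]^2
               + sum_i [W_i^505 (C_exp,i^505 - C_sim,i^505)]^2

with weights W = 1/C_exp.  The hybrid objective adds a curve-order term
penalizing fits that miss the relative ordering of the two sites:

    WSSR_hybr = WSSR_quant
              + sum_i [W_i^diff ((C_exp^394 - C_exp^505) - (C_sim^394 - C_sim^505))]^2

with W^diff = 1/(C_exp^394 - C_exp^505).  Points where a weight is undefined
(C_exp = 0, or |C_exp^394 - C_exp^505| below 1e-6 for the diff term) are
excluded from that sum: a time-zero blot with no band carries no
quantitative information.  Rates span tens of orders of magnitude, so all
searching happens in log10(theta); objectives evaluate 10**x.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .network import ReactionNetwork, build_network, build_validation_network
from .params import PARAM_NAMES, RateParameterSet
from .simulate import observables, simulate, standard_conditions
from .synthdata import ExperimentDataset

DIFF_WEIGHT_FLOOR = 1e-6


@dataclass
class ObjectiveBreakdown:
    """Per-term WSSR components; quant = y394 + y505, hybr adds the diff term."""

    wssr_y394: float
    wssr_y505: float
    wssr_diff: float

    @property
    def wssr_quant(self) -> float:
        return self.wssr_y394 + self.wssr_y505

    @property
    def wssr_hybr(self) -> float:
        return self.wssr_quant + self.wssr_diff


def _as_series_map(sim) -> dict:
    return sim if isinstance(sim, dict) else {"": sim}


def _site_residuals(c_exp: np.ndarray, c_sim: np.ndarray) -> np.ndarray:
    """Weighted residuals W*(C_exp - C_sim), W = 1/C_exp, zero-signal points dropped."""
    keep = c_exp > 0
    return (c_exp[keep] - c_sim[keep]) / c_exp[keep]


def _diff_residuals(
    e394: np.ndarray, e505: np.ndarray, s394: np.ndarray, s505: np.ndarray
) -> np.ndarray:
    d_exp = e394 - e505
    d_sim = s394 - s505
    keep = np.abs(d_exp) >= DIFF_WEIGHT_FLOOR
    return (d_exp[keep] - d_sim[keep]) / d_exp[keep]


def _collect(sim, data):
    """Yield aligned (exp394, exp505, sim394, sim505) per condition."""
    sim = _as_series_map(sim)
    data = _as_series_map(data)
    if set(sim) != set(data):
        raise ValueError(f"condition mismatch: {sorted(sim)} vs {sorted(data)}")
    for label in data:
        ds: ExperimentDataset = data[label]
        s = sim[label]
        s394, s505 = (s if isinstance(s, tuple) else (s.phospho_y394, s.phospho_y505))
        s394, s505 = np.asarray(s394, float), np.asarray(s505, float)
        if len(s394) != ds.n or len(s505) != ds.n:
            raise ValueError(
                f"{label}: simulated series length {len(s394)} != data n {ds.n}"
            )
        yield ds.y394, ds.y505, s394, s505


def quant_residual_vector(sim, data) -> np.ndarray:
    """Concatenated weighted residuals of WSSR_quant over all conditions."""
    parts = []
    for e394, e505, s394, s505 in _collect(sim, data):
        parts.append(_site_residuals(e394, s394))
        parts.append(_site_residuals(e505, s505))
    return np.concatenate(parts) if parts else np.zeros(0)


def wssr_quant(sim, data) -> ObjectiveBreakdown:
    """Quantitative objective. ``sim`` maps condition label to an
    ObservableSeries (or (y394, y505) tuple) sampled at the data times."""
    y394 = y505 = 0.0
    for e394, e505, s394, s505 in _collect(sim, data):
        y394 += float(np.sum(_site_residuals(e394, s394) ** 2))
        y505 += float(np.sum(_site_residuals(e505, s505) ** 2))
    return ObjectiveBreakdown(y394, y505, 0.0)


def wssr_hybr(sim, data) -> ObjectiveBreakdown:
    """Hybrid objective: quantitative plus the curve-order (diff) term."""
    base = wssr_quant(sim, data)
    diff = 0.0
    for e394, e505, s394, s505 in _collect(sim, data):
        diff += float(np.sum(_diff_residuals(e394, e505, s394, s505) ** 2))
    return ObjectiveBreakdown(base.wssr_y394, base.wssr_y505, diff)


# -- model-bound objective ---------------------------------------------------------


class ModelObjective:
    """Maps a (log10) free-parameter vector to WSSR against a dataset bundle.

    Parameters not listed in ``free_names`` stay frozen at ``base_params``.
    Each dataset's condition is simulated on the appropriate network (the
    dead-LCK network when the condition contains dead molecules) and
    normalized per-site by its 90-min value, matching how blot-style data
    are normalized.  Integration failures return the penalty value instead
    of aborting a swarm.
    """

    def __init__(
        self,
        data: dict[str, ExperimentDataset],
        base_params: RateParameterSet,
        free_names: tuple[str, ...] | None = None,
        conditions: dict | None = None,
        initial_p505: float = 0.0,
        rtol: float = 1e-6,
        atol: float = 1e-10,
        penalty: float = 1e12,
        normalization: str = "site_90min",
    ):
        self.data = data
        self.base = base_params
        self.free_names = tuple(free_names) if free_names else PARAM_NAMES
        unknown = set(self.free_names) - set(PARAM_NAMES)
        if unknown:
            raise KeyError(f"unknown parameters: {sorted(unknown)}")
        self.conditions = conditions or standard_conditions(initial_p505)
        self.rtol, self.atol = rtol, atol
        self.penalty = penalty
        self.normalization = normalization
        self._active = build_network()
        self._dead: ReactionNetwork | None = None
        self.n_evaluations = 0
        self.n_failures = 0

    @property
    def n_free(self) -> int:
        return len(self.free_names)

    def full_params(self, x_log10: np.ndarray) -> RateParameterSet:
        """Embed the free log10 vector into a complete rate set."""
        return self.base.replace(
            **{n: 10.0 ** float(v) for n, v in zip(self.free_names, x_log10)}
        )

    def truth_x(self, truth: RateParameterSet | None = None) -> np.ndarray:
        """The log10 free vector corresponding to a full parameter set."""
        p = truth or self.base
        return np.array([np.log10(p.value_of(n)) for n in self.free_names])

    def simulate_series(self, params: RateParameterSet) -> dict:
        """Per-condition (y394, y505) tuples at the data time grids."""
        out = {}
        for label, ds in self.data.items():
            cond = self.conditions[label]
            if cond.dead_lck_density > 0:
                if self._dead is None:
                    self._dead = build_validation_network()
                net = self._dead
            else:
                net = self._active
            traj = simulate(
                net, params, cond, output_times=ds.times_min * 60.0,
                rtol=self.rtol, atol=self.atol,
            )
            obs = observables(traj, normalization=self.normalization)
            out[label] = (obs.phospho_y394, obs.phospho_y505)
        return out

    def breakdown(self, x_log10: np.ndarray) -> ObjectiveBreakdown:
        sim = self.simulate_series(self.full_params(x_log10))
        return wssr_hybr(sim, self.data)

    def _guarded(self, x_log10: np.ndarray, kind: str) -> float:
        self.n_evaluations += 1
        try:
            b = self.breakdown(x_log10)
            value = b.wssr_hybr if kind == "hybr" else b.wssr_quant
        except (RuntimeError, ValueError, FloatingPointError):
            self.n_failures += 1
            return self.penalty
        if not np.isfinite(value):
            self.n_failures += 1
            return self.penalty
        return float(value)

    def hybrid(self, x_log10: np.ndarray) -> float:
        return self._guarded(x_log10, "hybr")

    def quant(self, x_log10: np.ndarray) -> float:
        return self._guarded(x_log10, "quant")

    def residuals(self, x_log10: np.ndarray) -> np.ndarray:
        """Per-point weighted residual vector of WSSR_quant (for least squares)."""
        try:
            sim = self.simulate_series(self.full_params(x_log10))
            r = quant_residual_vector(sim, self.data)
        except (RuntimeError, ValueError, FloatingPointError):
            r = np.full(self.n_residuals(), np.sqrt(self.penalty / self.n_residuals()))
        if not np.all(np.isfinite(r)):
            r = np.full(self.n_residuals(), np.sqrt(self.penalty / self.n_residuals()))
        return r

    def n_residuals(self) -> int:
        return int(
            sum((ds.y394 > 0).sum() + (ds.y505 > 0).sum() for ds in self.data.values())
        )


# -- configuration & results -------------------------------------------------------


@dataclass
class FitConfig:
    """Knobs of the two-stage campaign.

    Bounds default to the very wide published search box (1e-20 to 1e10);
    the search itself runs in log10 space.  ``n_global_sets`` is the number
    of independent swarm runs (the full published campaign used 1000; the
    in-repo default is a desk-scale campaign).
    """

    bounds_low: float = 1e-20
    bounds_high: float = 1e10
    search_scale: str = "log10"
    n_particles: int = 31
    stall_iterations: int = 50
    max_iterations: int = 400
    n_global_sets: int = 8
    refinements_per_set: int = 2
    jitter_dex: float = 0.05
    seed: int = 0
    # swarm hyperparameters (constriction-style defaults)
    inertia: float = 0.729
    cognitive: float = 1.49445
    social: float = 1.49445
    velocity_clamp: float = 0.2

    def __post_init__(self) -> None:
        if self.bounds_low >= self.bounds_high:
            raise ValueError("bounds_low must be < bounds_high")
        if self.n_particles < 2:
            raise ValueError("need at least 2 particles")
        if self.search_scale not in ("log10", "linear"):
            raise ValueError("search_scale must be 'log10' or 'linear'")

    def search_bounds(self, n_dim: int) -> tuple[np.ndarray, np.ndarray]:
        if self.search_scale == "log10":
            lo, hi = np.log10(self.bounds_low), np.log10(self.bounds_high)
        else:
            lo, hi = self.bounds_low, self.bounds_high
        return np.full(n_dim, lo), np.full(n_dim, hi)


@dataclass
class FitResult:
    """One fitted parameter vector with its objective values and provenance."""

    x: np.ndarray  # search-space vector (log10 rates by default)
    wssr_hybr: float | None = None
    wssr_quant: float | None = None
    params: RateParameterSet | None = None
    provenance: dict = field(default_factory=dict)


# -- particle swarm ----------------------------------------------------------------


def pso(
    func,
    lb: np.ndarray,
    ub: np.ndarray,
    n_particles: int = 31,
    stall_iterations: int = 50,
    max_iterations: int = 400,
    seed: int = 0,
    inertia: float = 0.729,
    cognitive: float = 1.49445,
    social: float = 1.49445,
    velocity_clamp: float = 0.2,
) -> tuple[np.ndarray, float, int]:
    """Bounded particle swarm minimization of ``func`` over [lb, ub].

    Particles start uniformly in the box with zero velocity; velocities are
    clamped to ``velocity_clamp`` times the box width, positions clipped to
    the bounds.  Terminates when the global best has not improved for
    ``stall_iterations`` iterations (or at ``max_iterations``).  Returns
    (best position, best value, iterations used); deterministic under seed.
    """
    rng = np.random.default_rng(seed)
    lb, ub = np.asarray(lb, float), np.asarray(ub, float)
    d = len(lb)
    span = ub - lb
    vmax = velocity_clamp * span
    x = lb + span * rng.random((n_particles, d))
    v = np.zeros((n_particles, d))
    fvals = np.array([func(xi) for xi in x])
    pbest, pbest_f = x.copy(), fvals.copy()
    g = int(np.argmin(pbest_f))
    gbest, gbest_f = pbest[g].copy(), float(pbest_f[g])
    stall = 0
    it = 0
    for it in range(1, max_iterations + 1):
        r1 = rng.random((n_particles, d))
        r2 = rng.random((n_particles, d))
        v = (
            inertia * v
            + cognitive * r1 * (pbest - x)
            + social * r2 * (gbest - x)
        )
        np.clip(v, -vmax, vmax, out=v)
        x = np.clip(x + v, lb, ub)
        fvals = np.array([func(xi) for xi in x])
        improved = fvals < pbest_f
        pbest[improved] = x[improved]
        pbest_f[improved] = fvals[improved]
        g = int(np.argmin(pbest_f))
        if pbest_f[g] < gbest_f:
            gbest, gbest_f = pbest[g].copy(), float(pbest_f[g])
            stall = 0
        else:
            stall += 1
        if stall >= stall_iterations:
            break
    return gbest, gbest_f, it


def pso_minimize(objective, config: FitConfig, n_dim: int | None = None) -> list[FitResult]:
    """Run ``config.n_global_sets`` independent swarms on a scalar objective.

    ``objective`` is either a ``ModelObjective`` (its hybrid WSSR is
    minimized and n_dim inferred) or any callable on search-space vectors.
    """
    if isinstance(objective, ModelObjective):
        func = objective.hybrid
        n_dim = objective.n_free
    else:
        func = objective
        if n_dim is None:
            raise ValueError("n_dim required for a bare callable objective")
    lb, ub = config.search_bounds(n_dim)
    results = []
    for run in range(config.n_global_sets):
        seed = (config.seed + 7919 * run) % (2**31 - 1)
        x, f, iters = pso(
            func, lb, ub,
            n_particles=config.n_particles,
            stall_iterations=config.stall_iterations,
            max_iterations=config.max_iterations,
            seed=seed,
            inertia=config.inertia,
            cognitive=config.cognitive,
            social=config.social,
            velocity_clamp=config.velocity_clamp,
        )
        res = FitResult(
            x=x, wssr_hybr=f,
            provenance={"stage": "pso", "run": run, "seed": seed, "iterations": iters},
        )
        if isinstance(objective, ModelObjective):
            res.params = objective.full_params(x)
            res.wssr_quant = objective.quant(x)
        results.append(res)
    return results


# -- trust-region refinement -------------------------------------------------------


def local_refine(
    start: FitResult,
    objective: ModelObjective,
    config: FitConfig,
    return_all: bool = False,
) -> FitResult | list[FitResult]:
    """Trust-region-reflective least-squares refinement of WSSR_quant.

    Each start is refined ``config.refinements_per_set`` times: the first
    run starts exactly at the swarm solution, later runs jitter the start by
    up to ``jitter_dex`` per coordinate.  Returns the best refinement (or
    all of them), never leaving the bounds and never worse than the start
    on its own objective.
    """
    lb, ub = config.search_bounds(objective.n_free)
    x0 = np.clip(np.asarray(start.x, float), lb, ub)
    if not np.all(np.isfinite(objective.residuals(x0))):
        out = replace_result(start, objective, note="non-finite residuals at start")
        return [out] if return_all else out
    rng = np.random.default_rng((config.seed + 104729) % (2**31 - 1))
    candidates = []
    for rep in range(max(1, config.refinements_per_set)):
        xi = x0.copy()
        if rep > 0:
            xi = np.clip(
                xi + rng.uniform(-config.jitter_dex, config.jitter_dex, xi.shape),
                lb, ub,
            )
        sol = least_squares(
            objective.residuals, xi, bounds=(lb, ub), method="trf",
            xtol=1e-10, ftol=1e-10, gtol=1e-10, max_nfev=200 * objective.n_free,
        )
        res = FitResult(
            x=sol.x,
            wssr_quant=float(2 * sol.cost),
            wssr_hybr=objective.hybrid(sol.x),
            params=objective.full_params(sol.x),
            provenance={**start.provenance, "stage": "refined", "replicate": rep},
        )
        candidates.append(res)
    start_quant = (
        start.wssr_quant
        if start.wssr_quant is not None
        else objective.quant(x0)
    )
    best = min(candidates, key=lambda r: r.wssr_quant)
    if best.wssr_quant > start_quant:  # descent contract: keep the start
        best = replace_result(start, objective, note="refinement did not improve")
        candidates = [best]
    return candidates if return_all else best


def replace_result(start: FitResult, objective: ModelObjective, note: str) -> FitResult:
    x = np.asarray(start.x, float)
    return FitResult(
        x=x,
        wssr_quant=start.wssr_quant if start.wssr_quant is not None else objective.quant(x),
        wssr_hybr=start.wssr_hybr if start.wssr_hybr is not None else objective.hybrid(x),
        params=objective.full_params(x),
        provenance={**start.provenance, "note": note},
    )


def two_stage_fit(
    objective: ModelObjective, config: FitConfig, keep_all_refinements: bool = False
) -> list[FitResult]:
    """Full campaign: global swarm runs, each refined by trust-region TRF.

    With ``keep_all_refinements`` every refinement replicate is returned
    (mirroring a campaign in which each swarm solution is tailored twice),
    otherwise one best refinement per swarm run.
    """
    stage1 = pso_minimize(objective, config)
    results: list[FitResult] = []
    for res in stage1:
        refined = local_refine(res, objective, config, return_all=keep_all_refinements)
        results.extend(refined if keep_all_refinements else [refined])
    return results
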