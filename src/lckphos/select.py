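"""Reduction of a fitted ensemble to the optimal parameter sets.

Three criteria are applied in order:

1. training fit: quantitative WSSR against the training data below a cutoff
   read off the WSSR cumulative distribution (published cutoff 7.1);
2. prediction: WSSR against the held-out mixed active/dead validation data
   below a second CDF cutoff (published cutoff 3.3);
3. steady state: at least 90% of LCK doubly phosphorylated by 90 min in the
   high-LCK condition, a molecular observation of the source experiment.

Survivors are clustered by k-means on standardized log10 parameters, the
cluster count chosen by the summed silhouette score, and summarized by
per-parameter medians, 90% CIs (5th-95th percentile), and one-way ANOVA
comparing the four enzyme forms acting on each substrate site.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_samples

from .fit import FitResult, ModelObjective
from .params import FORMS, LCK_PAIRS, PARAM_NAMES, SUBSTRATE_SITES, RateParameterSet
from .simulate import fraction_doubly_phosphorylated, simulate, standard_conditions
from .synthdata import ExperimentDataset


@dataclass
class SelectionConfig:
    """Cutoffs of the three selection criteria.

    ``cdf_mode='fixed_cutoff'`` uses the numeric cutoffs below (published
    values as defaults); ``'elbow'`` re-derives each cutoff as the largest
    second difference of the sorted WSSR curve (an automated stand-in for
    reading the end of the first CDF step by eye).
    """

    training_wssr_cutoff: float = 7.1
    validation_wssr_cutoff: float = 3.3
    double_phospho_threshold: float = 0.90
    cdf_mode: str = "fixed_cutoff"

    def __post_init__(self) -> None:
        if self.training_wssr_cutoff <= 0 or self.validation_wssr_cutoff <= 0:
            raise ValueError("WSSR cutoffs must be > 0")
        if not 0 < self.double_phospho_threshold <= 1:
            raise ValueError("double_phospho_threshold must be in (0, 1]")
        if self.cdf_mode not in ("fixed_cutoff", "elbow"):
            raise ValueError("cdf_mode must be 'fixed_cutoff' or 'elbow'")


def elbow_cutoff(wssr_values: np.ndarray) -> float:
    """Cutoff at the largest second difference of the sorted WSSR curve."""
    w = np.sort(np.asarray(wssr_values, float))
    if len(w) < 3:
        return float(w[-1])
    d2 = np.diff(w, 2)
    return float(w[int(np.argmax(d2)) + 1])


@dataclass
class SelectionResult:
    """Survivors plus an audit trail of which criterion removed each set."""

    survivors: list[FitResult]
    removed: dict[int, str]  # input index -> criterion name
    survivor_indices: list[int]
    cutoffs: dict[str, float]


def select_ensemble(
    ensemble: list[FitResult],
    validation_data: ExperimentDataset | None,
    config: SelectionConfig | None = None,
    base_params: RateParameterSet | None = None,
    validation_wssr: np.ndarray | None = None,
    double_phospho: np.ndarray | None = None,
    rtol: float = 1e-6,
    atol: float = 1e-10,
) -> SelectionResult:
    """Apply the three criteria in order, recording why each set was dropped.

    Training WSSR is taken from each set's ``wssr_quant``.  Validation WSSR
    and the 90-min doubly-phosphorylated fraction are computed by simulating
    each set (dead-LCK model for validation, high-LCK for the steady-state
    check) unless precomputed arrays are supplied.  An empty survivor list is
    returned with its audit trail rather than raised.
    """
    config = config or SelectionConfig()
    n = len(ensemble)
    training = np.array(
        [r.wssr_quant if r.wssr_quant is not None else np.inf for r in ensemble]
    )
    if validation_wssr is None:
        if validation_data is None:
            raise ValueError("need validation_data or precomputed validation_wssr")
        validation_wssr = _validation_wssr(
            ensemble, validation_data, base_params, rtol, atol
        )
    validation_wssr = np.asarray(validation_wssr, float)
    if double_phospho is None:
        double_phospho = _double_phospho_fractions(ensemble, rtol, atol)
    double_phospho = np.asarray(double_phospho, float)

    if config.cdf_mode == "elbow":
        cut1 = elbow_cutoff(training)
    else:
        cut1 = config.training_wssr_cutoff
    removed: dict[int, str] = {}
    alive = []
    for i in range(n):
        if training[i] < cut1:
            alive.append(i)
        else:
            removed[i] = "training_wssr"
    if config.cdf_mode == "elbow" and alive:
        cut2 = elbow_cutoff(validation_wssr[alive])
    else:
        cut2 = config.validation_wssr_cutoff
    alive2 = []
    for i in alive:
        if validation_wssr[i] < cut2:
            alive2.append(i)
        else:
            removed[i] = "validation_wssr"
    survivors = []
    for i in alive2:
        if double_phospho[i] >= config.double_phospho_threshold:
            survivors.append(i)
        else:
            removed[i] = "double_phospho"
    return SelectionResult(
        survivors=[ensemble[i] for i in survivors],
        removed=removed,
        survivor_indices=survivors,
        cutoffs={"training": cut1, "validation": cut2,
                 "double_phospho": config.double_phospho_threshold},
    )


def _validation_wssr(ensemble, validation_data, base_params, rtol, atol) -> np.ndarray:
    base = base_params or ensemble[0].params
    obj = ModelObjective(
        {"validation": validation_data}, base, rtol=rtol, atol=atol
    )
    out = np.empty(len(ensemble))
    for i, r in enumerate(ensemble):
        p = r.params if r.params is not None else base
        try:
            sim = obj.simulate_series(p)
            from .fit import wssr_quant

            out[i] = wssr_quant(sim, obj.data).wssr_quant
        except (RuntimeError, ValueError):
            out[i] = np.inf
    return out


def _double_phospho_fractions(ensemble, rtol, atol) -> np.ndarray:
    from .network import build_network

    net = build_network()
    cond = standard_conditions()["high_lck"]
    out = np.empty(len(ensemble))
    for i, r in enumerate(ensemble):
        try:
            traj = simulate(
                net, r.params, cond,
                output_times=np.array([0.0, 5400.0]), rtol=rtol, atol=atol,
            )
            out[i] = fraction_doubly_phosphorylated(traj, 5400.0)
        except (RuntimeError, ValueError):
            out[i] = 0.0
    return out


# -- clustering --------------------------------------------------------------------


@dataclass
class ClusterResult:
    labels: np.ndarray
    k: int
    silhouette_sum: dict[int, float]
    diagnostic: str = ""


def cluster_parameter_sets(
    param_sets: list[RateParameterSet] | np.ndarray,
    k_candidates: range | tuple = range(2, 7),
    seed: int = 0,
    n_restarts: int = 10,
) -> ClusterResult:
    """K-means over standardized log10 parameters; k by max silhouette sum.

    Raw rates span many decades, so distances are computed on standardized
    log10 values.  Candidate k values larger than n-1 are skipped; if all
    points coincide the silhouette is undefined and a single cluster is
    reported with a diagnostic.
    """
    if isinstance(param_sets, np.ndarray):
        X = np.asarray(param_sets, float)
    else:
        X = np.array([p.to_vector() for p in param_sets])
        if np.any(X <= 0):
            raise ValueError("log10 clustering requires strictly positive rates")
        X = np.log10(X)
    n = X.shape[0]
    spread = X.std(axis=0)
    if np.all(spread == 0):
        return ClusterResult(
            labels=np.zeros(n, dtype=int), k=1, silhouette_sum={},
            diagnostic="all parameter sets identical; silhouette undefined",
        )
    Xs = (X - X.mean(axis=0)) / np.where(spread == 0, 1.0, spread)
    scores: dict[int, float] = {}
    labelings: dict[int, np.ndarray] = {}
    for k in k_candidates:
        if k >= n or k < 2:
            continue
        km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed)
        labels = km.fit_predict(Xs)
        if len(np.unique(labels)) < 2:
            continue
        scores[k] = float(np.sum(silhouette_samples(Xs, labels)))
        labelings[k] = labels
    if not scores:
        return ClusterResult(
            labels=np.zeros(n, dtype=int), k=1, silhouette_sum={},
            diagnostic="no valid clustering among candidate k; reporting k=1",
        )
    best_k = max(scores, key=scores.get)
    return ClusterResult(labels=labelings[best_k], k=best_k, silhouette_sum=scores)


def cluster_validation_medians(
    cluster: ClusterResult, validation_wssr: np.ndarray
) -> dict[int, float]:
    """Median validation WSSR per cluster (the basis for picking the best one)."""
    v = np.asarray(validation_wssr, float)
    return {
        int(c): float(np.median(v[cluster.labels == c]))
        for c in np.unique(cluster.labels)
    }


# -- ensemble statistics -----------------------------------------------------------


@dataclass
class EnsembleStats:
    """Per-parameter medians/CIs and enzyme-comparison ANOVA tables."""

    summary: pd.DataFrame  # index: parameter name; median, ci_low, ci_high
    anova: pd.DataFrame  # substrate site x rate kind -> F, p


def ensemble_stats(param_sets: list[RateParameterSet]) -> EnsembleStats:
    """Medians, 90% CIs (5th-95th percentile) and one-way ANOVA across enzymes.

    The ANOVA compares, for each substrate site, the log10 rates of the four
    LCK enzyme forms acting on it (separately for dissociation and catalytic
    rates); rates vary over decades, so the test is run on log10 values.
    """
    if len(param_sets) < 3:
        raise ValueError("need at least 3 parameter sets")
    X = np.array([p.to_vector() for p in param_sets])
    med = np.median(X, axis=0)
    lo = np.percentile(X, 5, axis=0)
    hi = np.percentile(X, 95, axis=0)
    summary = pd.DataFrame(
        {"median": med, "ci_low": lo, "ci_high": hi}, index=list(PARAM_NAMES)
    )
    with np.errstate(divide="ignore"):
        logX = np.log10(np.maximum(X, 1e-300))
    name_idx = {n: i for i, n in enumerate(PARAM_NAMES)}
    rows = []
    for site, host in SUBSTRATE_SITES:
        for kind in ("k_off", "k_cat"):
            groups = []
            for enz in FORMS:
                pair = LCK_PAIRS.index((enz, site, host)) + 1
                groups.append(logX[:, name_idx[f"{kind}_{pair}"]])
            if max(float(np.std(g)) for g in groups) == 0.0:
                # zero within-group variance (e.g. identical sets): F undefined
                f_stat, p_val = np.nan, 1.0
            else:
                f_stat, p_val = stats.f_oneway(*groups)
            rows.append(
                {
                    "substrate": f"{site}@{host}",
                    "rate": kind,
                    "F": float(f_stat),
                    "p": float(p_val),
                }
            )
    return EnsembleStats(summary=summary, anova=pd.DataFrame(rows))
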