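"""Extended Fourier Amplitude Sensitivity Test (eFAST).

All inputs are varied simultaneously along a space-filling search curve,
each driven at its own frequency; the Fourier spectrum of the model output
then attributes output variance to inputs.  For each parameter of interest
the algorithm assigns it the highest frequency ``omega_max`` and all other
parameters low frequencies (at most ``omega_max / (2 M)``, where M is the
interference factor), yielding

    Si  = V_i / V      variance at omega_max and its first M harmonics
    STi = 1 - Vc / V   with Vc the variance at the complementary
                       (low-frequency) band -- everything *except* the
                       parameter of interest and its interactions

so STi >= Si, with the difference measuring interaction effects.  Indices
are averaged over ``n_curves`` random phase-shifted resamplings.  A dummy
parameter that the model ignores provides the significance floor.

Model parameters are explored log-uniformly over a multiplicative range
(default 100-fold up and down from the baseline), matching how rate
constants are naturally compared.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .network import build_network
from .params import PARAM_NAMES, RateParameterSet
from .simulate import Condition, observables, simulate, standard_conditions


@dataclass
class SensitivityConfig:
    """eFAST sampling controls.

    ``samples_per_curve`` must satisfy the Nyquist constraint
    ``NS >= 2 * M * omega_max + 1``; with the defaults (NS=65, M=4) the
    driving frequency is omega_max=8 and all complementary inputs sit at
    frequency 1.
    """

    range_factor: float = 100.0
    n_curves: int = 2
    samples_per_curve: int = 65
    interference_factor: int = 4
    output_times: tuple[float, ...] = (5400.0,)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.range_factor <= 1:
            raise ValueError("range_factor must be > 1")
        if self.samples_per_curve < 2 * self.interference_factor * 2 + 1:
            raise ValueError("samples_per_curve too small for the Nyquist constraint")

    @property
    def omega_max(self) -> int:
        return (self.samples_per_curve - 1) // (2 * self.interference_factor)


@dataclass
class SensitivityResult:
    """First-order (Si) and total (STi) indices, parameters x outputs."""

    si: np.ndarray
    sti: np.ndarray
    parameter_names: list[str]
    output_names: list[str]
    n_failures: int = 0

    def top_by_sti(self, output: str, n: int = 5) -> list[str]:
        j = self.output_names.index(output)
        order = np.argsort(self.sti[:, j])[::-1]
        return [self.parameter_names[i] for i in order[:n]]

    def as_table(self):
        import pandas as pd

        rows = []
        for i, p in enumerate(self.parameter_names):
            for j, o in enumerate(self.output_names):
                rows.append(
                    {"parameter": p, "output": o,
                     "Si": self.si[i, j], "STi": self.sti[i, j]}
                )
        return pd.DataFrame(rows)


def _search_curve(omega: np.ndarray, s: np.ndarray, phase: np.ndarray) -> np.ndarray:
    """Saltelli search curve mapping s in (-pi, pi) to the unit hypercube."""
    return 0.5 + np.arcsin(np.sin(omega[:, None] * s[None, :] + phase[:, None])) / np.pi


def efast(
    func,
    n_params: int,
    config: SensitivityConfig | None = None,
    output_names: list[str] | None = None,
    parameter_names: list[str] | None = None,
) -> SensitivityResult:
    """eFAST indices of ``func`` over the unit hypercube.

    ``func`` maps a length-``n_params`` vector in [0, 1] to a 1-D array of
    outputs (or a scalar).  Samples where ``func`` raises or returns
    non-finite values are excluded from the spectra by imputing the curve
    mean, and counted in ``n_failures``.  Deterministic under the config
    seed.
    """
    config = config or SensitivityConfig()
    NS, M, Nr = config.samples_per_curve, config.interference_factor, config.n_curves
    omega_max = config.omega_max
    omega_c_max = max(1, omega_max // (2 * M))
    rng = np.random.default_rng(config.seed)
    s = np.pi * (2 * np.arange(1, NS + 1) - NS - 1) / NS

    # probe output dimensionality
    probe = np.atleast_1d(np.asarray(func(np.full(n_params, 0.5)), float))
    n_out = probe.size
    n_failures = 0

    half = (NS - 1) // 2
    freqs = np.arange(1, half + 1)
    angles = freqs[:, None] * s[None, :]
    cos_tab, sin_tab = np.cos(angles), np.sin(angles)
    harmonics = omega_max * np.arange(1, M + 1)
    low_band = np.arange(1, omega_max // 2 + 1)

    # per-parameter pooled variance components over the resample curves
    v_int = np.zeros((n_params, n_out))  # at the interest harmonics
    v_low = np.zeros((n_params, n_out))  # complementary low-frequency band
    v_tot = np.zeros((n_params, n_out))
    for i in range(n_params):
        omega = np.empty(n_params)
        omega[i] = omega_max
        others = [j for j in range(n_params) if j != i]
        omega[others] = [(k % omega_c_max) + 1 for k in range(len(others))]
        for _curve in range(Nr):
            phase = rng.uniform(0, 2 * np.pi, n_params)
            X = _search_curve(omega, s, phase)  # (n_params, NS)
            Y = np.empty((NS, n_out))
            ok = np.ones(NS, dtype=bool)
            for k in range(NS):
                try:
                    yk = np.atleast_1d(np.asarray(func(X[:, k]), float))
                    if not np.all(np.isfinite(yk)):
                        raise FloatingPointError
                    Y[k] = yk
                except (RuntimeError, ValueError, FloatingPointError):
                    ok[k] = False
            if not ok.all():
                n_failures += int((~ok).sum())
                if ok.sum() == 0:
                    continue
                Y[~ok] = Y[ok].mean(axis=0)
            A = (cos_tab @ Y) / NS  # (half, n_out)
            B = (sin_tab @ Y) / NS
            spectrum = 2.0 * (A**2 + B**2)
            v_tot[i] += spectrum.sum(axis=0)
            v_int[i] += spectrum[harmonics - 1].sum(axis=0)
            v_low[i] += spectrum[low_band - 1].sum(axis=0)
    # The total variance is the same quantity whichever input carries the
    # driving frequency, so it is pooled over all parameter runs: the
    # per-run spectral variance is the noisiest ingredient (resonances
    # between low complementary frequencies), while the harmonic sums are
    # stable.  Si and STi then share one well-averaged denominator.
    v_global = v_tot.mean(axis=0)
    v_global = np.where(v_global <= 0, np.inf, v_global)
    si = v_int / v_global
    sti = (v_tot - v_low) / v_global
    return SensitivityResult(
        si=si,
        sti=sti,
        parameter_names=parameter_names or [f"x{i}" for i in range(n_params)],
        output_names=output_names or [f"y{j}" for j in range(n_out)],
        n_failures=n_failures,
    )


def model_sensitivity(
    baseline: RateParameterSet,
    condition: Condition | str = "high_lck_csk",
    config: SensitivityConfig | None = None,
    include_dummy: bool = True,
    rtol: float = 1e-6,
    atol: float = 1e-10,
) -> SensitivityResult:
    """eFAST of the phospho-site outputs with respect to all 38 rates.

    Each rate is varied log-uniformly over [baseline/range_factor,
    baseline*range_factor].  Outputs are the total phospho-Y394 and
    phospho-Y505 fractions at the configured times.  A dummy 39th input the
    model never reads is appended by default to estimate the index floor.
    """
    config = config or SensitivityConfig()
    if isinstance(condition, str):
        condition = standard_conditions()[condition]
    net = build_network()
    base_vec = baseline.to_vector()
    log_lo = np.log10(base_vec / config.range_factor)
    log_hi = np.log10(base_vec * config.range_factor)
    times = np.array(sorted(set((0.0,) + tuple(config.output_times))))
    out_names = [
        f"{site}_t{int(t)}s" for site in ("y394", "y505") for t in config.output_times
    ]

    def evaluate(u: np.ndarray) -> np.ndarray:
        theta = 10.0 ** (log_lo + u[: len(base_vec)] * (log_hi - log_lo))
        p = RateParameterSet.from_vector(theta)
        traj = simulate(net, p, condition, output_times=times, rtol=rtol, atol=atol)
        obs = observables(traj)
        vals = []
        for series in (obs.phospho_y394, obs.phospho_y505):
            for t in config.output_times:
                vals.append(np.interp(t, traj.times, series))
        return np.array(vals)

    n_inputs = len(base_vec) + (1 if include_dummy else 0)
    names = list(PARAM_NAMES) + (["dummy"] if include_dummy else [])
    return efast(
        evaluate, n_inputs, config,
        output_names=out_names, parameter_names=names,
    )


def compare_conditions(results: dict[str, SensitivityResult]) -> dict:
    """Rank-concordance of STi profiles across conditions.

    Returns pairwise Spearman correlations of the STi vectors (averaged over
    outputs) and the shared top-5 parameter sets.  Raises if the parameter
    lists differ.
    """
    labels = list(results)
    if len(labels) < 2:
        raise ValueError("need at least two results to compare")
    names = results[labels[0]].parameter_names
    for lab in labels[1:]:
        if results[lab].parameter_names != names:
            raise ValueError("parameter lists differ between results")
    profiles = {lab: results[lab].sti.mean(axis=1) for lab in labels}
    corr = {}
    top5_overlap = {}
    for a in range(len(labels)):
        for b in range(a + 1, len(labels)):
            la, lb = labels[a], labels[b]
            rho = stats.spearmanr(profiles[la], profiles[lb]).statistic
            corr[(la, lb)] = float(rho)
            top_a = set(np.argsort(profiles[la])[::-1][:5])
            top_b = set(np.argsort(profiles[lb])[::-1][:5])
            top5_overlap[(la, lb)] = len(top_a & top_b)
    return {"spearman": corr, "top5_overlap": top5_overlap, "parameters": names}
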