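# Methods

## Model

LCK is a membrane-anchored Src-family kinase with an activating tyrosine
(Y394) and an inhibitory one (Y505).  On a supported bilayer it
phosphorylates itself exclusively in *trans*: the catalytic domain of one
molecule engages a free tyrosine of another.  The model tracks the four
phospho-forms U394U505, P394U505, U394P505 and P394P505 (abbreviated UU,
PU, UP, PP; first letter = Y394 status) and the kinase CSK, which
phosphorylates LCK only at Y505.

Every phosphorylation goes through an explicit Michaelis–Menten dimer:

    E + S  --k_on-->  E·S  --k_off-->  E + S
                      E·S  --k_cat-->  E + P

A substrate site exists only while unphosphorylated, so there are four
sites (Y394 on UU and UP; Y505 on UU and PU).  With four enzyme forms that
gives 16 LCK–LCK pairs; CSK adds two (Y505 on UU and PU).  To avoid
overparameterization all LCK pairs share one association rate `k_on`
(µm²/(molecule·s)) and all CSK pairs share `k_on_csk`; each pair keeps its
own dissociation and catalytic rate (1/s).  That is 38 rate constants:
2 + 16 + 16 + 2 + 2.  Dimers differing only in the bound site are distinct
species; a symmetric dimer (enzyme and substrate of the same form) is a
single species and no statistical factor of 2 is applied to its rates.

The fully active network enumerates to 23 species (4 free LCK + free CSK +
16 LCK dimers + 2 CSK dimers) and 54 unidirectional mass-action reactions
(18 dimers × bind/unbind/catalyze).  Stoichiometry conserves total LCK and
total CSK exactly; tests verify this both algebraically (conservation
vectors annihilate the stoichiometric matrix) and along trajectories.

### Catalytically dead LCK

The validation experiment mixes active LCK with an ATP-binding-site mutant
that can be phosphorylated and can bind but cannot catalyze.  Dead LCK is
modeled with the same binding rates as active LCK (`k_on`, the pair's
`k_off`) and catalytic rate exactly zero, participating both as a
substrate at all four of its sites and as a sequestering binder in the
enzyme role.  The policy is configurable:

| policy | CSK binding | species |
|---|---|---|
| binder (default) | yes | 77 |
| binder (default) | no  | 73 |
| substrate_only | yes | 45 |

The validation experiment contains no CSK, so the validation network drops
the CSK binding rules while keeping the CSK pool as a (zero-concentration)
seed species: 8 free LCK + 1 CSK + 64 dimers = 73 state variables, which
is the size this model variant is known by.  `build_validation_network()`
returns exactly that configuration.

### Canonical parameter values

`table1_median.json` / `table1_ci.json` transcribe the published ensemble
medians and 90% CIs verbatim, in the fixed pair order used throughout
(pair 1 = UU enzyme on Y394 of UU, …, pair 16 = PP enzyme on Y394 of UP).
Six printed intervals do not bracket their medians (`k_off_1`, `k_off_7`,
`k_off_8`, `k_off_11`, `k_cat_7`, `k_cat_csk_uu`); they are transcribed
as printed, and `ci_inconsistencies()` lists them rather than silently
correcting anything.

## Simulation

Densities are molecules/µm²; time is seconds internally (the 90-min
horizon is 5400 s) and minutes at the I/O surface.  The initial state is
all-free, all-unphosphorylated LCK (optionally a small fraction pre-
phosphorylated at Y505, default 0, configurable to ~1.5% to mimic blot
background) plus free CSK.  The canonical conditions are 500 LCK, 500 LCK
+ 500 CSK, 50 LCK, 50 LCK + 500 CSK (training) and 250 active + 250 dead
LCK without CSK (validation).

Rates span >15 orders of magnitude, so integration uses a stiff-capable
solver (LSODA) with the analytic Jacobian of the bilinear rate laws,
rtol 1e-8 / atol 1e-12 by default (1e-6 / 1e-10 inside fitting loops,
where speed matters; a convergence test checks that tightening tolerances
10× moves observables by <1e-4).  The default output grid joins ~120
log-spaced early points (the Y394 burst happens within the first 15 s)
with the minute-scale blot grid.

Phospho observables count phosphate at a site over *all* species
containing an LCK molecule — free or bound, enzyme or substrate, active or
dead.  Normalization is by total LCK (a conserved quantity) by default, or
per-site by that site's own 90-min value (`site_90min`), which is how blot
data are normalized and is what the fitting objective uses.  Densities
below 1e-9 in magnitude are clipped to zero before normalizing.  Species-
composition outputs report each form's total/free/bound fraction of total
LCK.

## Synthetic data

The generator replaces the digitized blot curves: simulate a condition,
sample at the blot grid (0, 0.25, 0.5, 1, 2, 5, 10, 15, 30, 45, 60,
90 min — the fast phase plus the 90-min anchor; the original sampling
times were never tabulated, so this grid is a configurable stand-in),
multiply each point by independent lognormal noise with mean 1 and a given
CV (default 0.1 — band intensities are positive and their errors scale
with signal), and renormalize each site by its noisy 90-min value.  Points
that are exactly zero stay zero (multiplicative noise creates no signal),
which interacts with the objective's weight rule below.  What this does
not emulate: background subtraction, saturation, or correlated loading
errors across lanes — recovery results on synthetic data are therefore an
upper bound on what the real blots support.

## Objectives and fitting

For measured points `C_exp` and simulated points `C_sim` (per-site
90-min-normalized, at the data times):

    WSSR_quant = Σ [W^394 (C_exp^394 − C_sim^394)]² + Σ [W^505 (…)]²
    WSSR_hybr  = WSSR_quant
               + Σ [W^diff ((C_exp^394 − C_exp^505) − (C_sim^394 − C_sim^505))]²

with weights `W = 1/C_exp` and `W^diff = 1/(C_exp^394 − C_exp^505)`.  The
diff term penalizes fits that miss which site leads — without it, fits
overfit the three Y394-led conditions and miss the Y505 crossover in low
LCK + CSK.  Weights are undefined at `C_exp = 0` (time-zero points) and
where the two experimental curves coincide; such points are excluded from
the corresponding sum (|difference| < 1e-6 for the diff term).  The diff
weight is used signed, exactly as the objective is written; squaring
removes the sign.  Note the diff weights diverge wherever the two
experimental curves approach each other, so with measurement noise the
hybrid objective is intrinsically noisy near curve crossings — one reason
it serves only as the stage-1 search objective.

Stage 1 is particle swarm optimization in log10(θ): 31 particles,
inertia 0.729, cognitive/social 1.49445 (standard constriction-equivalent
values; the original hyperparameters beyond particle count were never
stated), velocity clamped to 20% of the box, positions clipped to bounds,
termination when the global best stalls for 50 iterations.  Integration
failures score a 1e12 penalty instead of aborting the swarm.  Stage 2
refines each swarm result with trust-region-reflective nonlinear least
squares (`scipy.optimize.least_squares`, method `trf`) on the per-point
weighted residual vector of WSSR_quant, inside the same bounds.  Each
start is refined twice — the second start jittered ±0.05 dex, since what
distinguished the two original refinements was never specified — and the
better result kept; a refinement that fails to improve returns the start
(descent contract).

The full published campaign (1000 swarm runs × 2 refinements over bounds
1e-20 to 1e10) is cluster-scale and out of scope.  The in-repo recovery
experiment is desk-scale by design: 6 free parameters (the globally
sensitive shared association rates `k_on`, `k_on_csk` and CSK dissociation
`k_off_csk_uu`, plus identifiable pair rates `k_cat_2`, `k_off_5`,
`k_cat_15`; the other 32 frozen at truth), a ±2.5-decade search box around
the baseline, two swarm runs (stall 25 / cap 90 iterations), best-of-
refinements by WSSR_quant.  Freeing all three CSK rates at once is
deliberately avoided: `k_on_csk`, `k_off_csk_uu`, `k_cat_csk_uu` trade off
along a flux-preserving direction and are not jointly identifiable from
these data.  Under these conditions the best fit lands within 0.5 dex of
truth on every free parameter at 5% noise (and essentially exactly on
noiseless data).

## Ensemble selection, clustering, statistics

Three criteria applied in order: training WSSR below a cutoff, validation
WSSR (computed by simulating the 73-species model against the mixed
active/dead data) below a second cutoff, and ≥90% of LCK doubly
phosphorylated at 90 min in the high-LCK condition.  The published cutoffs
(7.1 and 3.3) ship as defaults; they were originally chosen by eye from
the WSSR CDF, which is not reproducible, so an automated `elbow` mode
(largest second difference of the sorted WSSR curve) is provided as an
alternative.  Selection records which criterion removed each set and is
idempotent.

Survivors are clustered by k-means on standardized log10 parameters
(raw-scale distances would be dominated by the largest rates), k chosen
from 2–6 by the summed silhouette score, fixed seed, 10 restarts.  All
points identical → silhouette undefined → k=1 with a diagnostic.  Ensemble
statistics report per-parameter medians with 90% CIs (5th–95th
percentiles) and one-way ANOVA comparing the four enzyme forms on each
substrate site, run on log10 rates for the same scale reason.

## Sensitivity analysis (eFAST)

Each parameter is explored log-uniformly over [baseline/100,
baseline×100].  For each parameter of interest the algorithm drives it at
the maximum frequency ω_max = (NS−1)/(2M) along a Saltelli search curve
(triangular in each coordinate, NS samples per curve, interference factor
M=4) with all other inputs at low frequencies ≤ ω_max/(2M), and reads
variance off the output's Fourier spectrum: Si from the M harmonics of
ω_max, STi as one minus the low-frequency (complementary) share.  Indices
are averaged over Nr random-phase resample curves (defaults NS=65, Nr=2;
the Ishigami benchmark test uses NS=1025, Nr=8).

One numerical choice departs from the textbook estimator: the total
variance in the denominators is pooled across all parameter runs and
curves rather than estimated per curve.  The per-curve spectral variance
is the noisiest ingredient (small-integer complementary frequencies
resonate, so interaction terms converge slowly along a single curve),
while the harmonic sums in the numerators are stable; since total output
variance is the same quantity whichever input carries the driving
frequency, pooling is unbiased and empirically cuts the Ishigami benchmark
error below 0.05 at NS=1025, Nr=8.  A 39th dummy input the model never
reads estimates the significance floor.  Model outputs are total
phospho-Y394 and phospho-Y505 at 90 min by default (the original output
times were only described as "specific time points"; other times are
configurable).  Failed integrations are imputed with the curve mean and
counted, never silently dropped.

## Scale of the shipped experiments

Test and demonstration runs are sized for a single CPU: two-swarm
recovery campaigns, NS=65 model sensitivity scans, 20-member perturbation
ensembles (0.3 dex lognormal spread around the baseline — a stand-in for
the unavailable fitted ensemble; the ensemble-envelope test checks the
baseline curve lies within that band's interquartile range to 0.01).
Every scaled experiment's parameters are explicit in the calling code and
widen to campaign scale by configuration only.

## Known limitations

- The printed CI table is internally inconsistent for six parameters
  (median outside CI); values are reported verbatim and flagged.
- The 73-state dead-LCK enumeration rests on the no-CSK-rules reading
  described above; the original rule files would settle it, and both
  alternative policies (45 and 77 species) remain available.
- The hybrid objective is noise-amplifying near curve crossings by
  construction (1/ΔC weights); it is used only for the global stage.
- Parameter recovery statements hold for the chosen identifiable free
  subsets; most of the 38 rates are practically unidentifiable from these
  data alone, exactly as the wide published CIs indicate.
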