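# lckphos — kinetics of LCK autoregulation on membranes

LCK is the Src-family kinase that initiates T-cell receptor signaling.
Its activity is set by two tyrosines — activating Y394 and inhibitory
Y505 — and on a membrane it phosphorylates itself in *trans* while the
kinase CSK phosphorylates it at Y505.  `lckphos` is a Python library for
building and interrogating a predictive kinetic model of this system, for
researchers studying kinase autoregulation or fitting ODE models of
signaling networks to sparse, blot-style time-course data.

The model treats every enzyme–substrate encounter as an explicit
Michaelis–Menten dimer.  With four LCK phospho-forms (U394U505, P394U505,
U394P505, P394P505) and four substrate sites (Y394 on U394U505/U394P505,
Y505 on U394U505/P394U505) there are 16 LCK–LCK pairs plus two CSK–LCK
pairs; all LCK pairs share one association rate K_on (and CSK pairs share
K_on,CSK) while each pair keeps its own K_off and K_cat — 38 rate
constants in all, over a 23-species mass-action network.  A 73-species
variant adds catalytically dead LCK (binds normally, never catalyzes) for
the mixed active/dead validation experiment.

The package provides, as composable modules:

- **network** — rule-based enumeration of species and reactions, stiff ODE
  right-hand side with analytic Jacobian, BNGL-style text export/import;
- **simulate** — the five membrane-reconstitution conditions
  (50–500 molecules/µm²), normalized phospho-Y394/phospho-Y505 observables
  and species-composition outputs;
- **synthdata** — synthetic western-blot time courses (multiplicative
  lognormal noise, per-site 90-min normalization) with known ground truth;
- **fit** — the hybrid and quantitative weighted-SSR objectives, particle
  swarm global search and trust-region least-squares refinement;
- **select** — the three-criteria ensemble filter (training WSSR < 7.1,
  validation WSSR < 3.3, ≥90% doubly phosphorylated LCK at 90 min),
  k-means/silhouette clustering, medians/CIs/ANOVA;
- **sensitivity** — eFAST first-order and total sensitivity indices.

See `docs/methods.md` for the model assumptions and numerical choices.

## Worked example

```sh
python examples/simulate_conditions.py
```

prints, with the canonical (published-median) rates:

```
active network: 23 species, 54 reactions
mixed active/dead network: 73 species

condition       pY394(90min)  pY505(90min)  PP frac
high_lck               0.998         0.987    0.985
high_lck_csk           0.999         0.994    0.994
low_lck                0.992         0.978    0.972
low_lck_csk            0.979         0.992    0.977
validation             0.993         0.774    0.771
```

Each row is one reconstitution condition; the columns give the fraction
of total LCK phosphorylated at each site after 90 minutes and the
doubly-phosphorylated (P394P505) fraction.  Y394 leads Y505 everywhere
except low LCK + CSK, where CSK's Y505 activity overtakes the dilute LCK
*trans*-activity — the qualitative switch the model was built to capture —
and in the high-LCK condition ~99% of LCK ends doubly phosphorylated, the
steady-state criterion used for ensemble selection.

Other examples: `generate_synthetic_data.py` (blot-style data),
`fit_recovery_demo.py` (two-parameter recovery in ~1 min),
`select_and_cluster.py` (ensemble filtering and clustering),
`sensitivity_scan.py` (eFAST ranking), `export_rule_model.py` (rule-text
round trip).  A thin CLI wraps the same capabilities
(`lckphos simulate|generate|fit|select|sense --help`).

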