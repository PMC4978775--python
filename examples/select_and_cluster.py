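"""Filter and cluster a synthetic fitted ensemble.

Builds an ensemble around the baseline rates: half tight replicates of the
baseline (good fits), half strongly perturbed sets (poor fits), then
applies the three selection criteria with precomputed scores and clusters
the survivors on standardized log10 parameters.
"""

import numpy as np

from lckphos import (
    FitResult,
    RateParameterSet,
    SelectionConfig,
    cluster_parameter_sets,
    ensemble_stats,
    select_ensemble,
    table1_median,
)

rng = np.random.default_rng(3)
base = table1_median().to_vector()
members, training, validation, double = [], [], [], []
for i in range(30):
    good = i < 15
    spread = 0.1 if good else 2.0
    vec = base * 10 ** rng.normal(0, spread, 38)
    members.append(FitResult(x=np.log10(vec), wssr_quant=0.0,
                             params=RateParameterSet.from_vector(vec)))
    training.append(rng.uniform(1, 6) if good else rng.uniform(8, 500))
    validation.append(rng.uniform(0.5, 3) if good else rng.uniform(4, 50))
    double.append(rng.uniform(0.92, 1.0) if good else rng.uniform(0.2, 0.95))
    members[-1].wssr_quant = training[-1]

sel = select_ensemble(members, None, SelectionConfig(),
                      validation_wssr=np.array(validation),
                      double_phospho=np.array(double))
print(f"{len(sel.survivors)}/30 sets pass the three criteria "
      f"(cutoffs {sel.cutoffs})")
from collections import Counter

print("removal reasons:", dict(Counter(sel.removed.values())))

clusters = cluster_parameter_sets([m.params for m in sel.survivors], seed=0)
print(f"silhouette-optimal cluster count: k={clusters.k}")
stats = ensemble_stats([m.params for m in sel.survivors])
print("\nper-parameter median and 90% CI (first rows):")
print(stats.summary.head(4).to_string(float_format=lambda v: f"{v:.3g}"))
print("""
Survivors are the tight replicates; the perturbed half fails the training
cutoff, validation cutoff, or the 90% double-phosphorylation requirement.""")
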