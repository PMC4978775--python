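"""Small parameter-recovery demonstration of the two-stage fit.

Generates noiseless synthetic data from the baseline rates, frees two
globally sensitive parameters (the LCK and CSK association rates), and
runs one particle-swarm search followed by trust-region refinement inside
a +-2 decade box.  Runs in about a minute.
"""

import numpy as np

from lckphos import FitConfig, ModelObjective, table1_median, two_stage_fit
from lckphos.synthdata import generate_training_set

truth = table1_median()
free = ("k_on", "k_on_csk")
data = generate_training_set(truth, noise_cv=0.0, seed=1)
objective = ModelObjective(data, truth, free_names=free)
tx = objective.truth_x()

config = FitConfig(n_global_sets=1, n_particles=15, stall_iterations=15,
                   max_iterations=40, seed=3)
config.search_bounds = lambda n: (tx - 2.0, tx + 2.0)

results = two_stage_fit(objective, config)
best = min(results, key=lambda r: r.wssr_quant)

print(f"truth   log10(k_on, k_on_csk) = {np.round(tx, 3)}")
print(f"fitted  log10(k_on, k_on_csk) = {np.round(best.x, 3)}")
print(f"WSSR_quant of the fit: {best.wssr_quant:.3g}")
print("""
On noiseless data the refined fit lands on the generating rates (WSSR near
zero); the log10 difference per parameter is the recovery error in decades.""")
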