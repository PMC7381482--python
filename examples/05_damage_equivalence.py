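"""Compare the five damage kinds on the sequential-action model.

Trains a small SRN cohort, sweeps all four stochastic damage kinds at
their published mild settings, prints the per-task error profile for
each kind (they should agree qualitatively: coffee -> omissions, tea ->
intrusions), and searches the weight-scaling failure-onset factors (the
one damage kind that behaves differently).
"""

import numpy as np

from lesionlab import build_corpus, train_cohort
from lesionlab.action_analysis import (DEFAULT_SEVERITIES, STOCHASTIC_KINDS,
                                       damage_sweep,
                                       scaling_threshold_search)

corpus, _ = build_corpus()
nets = train_cohort(2, corpus=corpus, master_seed=0)
print(f"trained {len(nets)} networks")

report = damage_sweep(nets, corpus,
                      {k: [DEFAULT_SEVERITIES[k]] for k in STOCHASTIC_KINDS},
                      episodes_per_cell=100, master_seed=0)
cols = ["intrusion", "omission", "perseveration", "within_subtask"]
summary = report.groupby(["damage_kind", "task"])[cols].sum()
print("\nerror counts at the published mild severities:")
print(summary.to_string())

grid = np.round(np.arange(0.98, 0.40, -0.02), 2)
for task in ("coffee", "tea"):
    onset = scaling_threshold_search(nets, corpus, task, grid)
    print(f"weight scaling: first failures in {task} at s = {onset}")
print("(coffee fails at a higher scaling factor than tea)")
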