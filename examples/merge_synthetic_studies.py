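"""Merge three heterogeneous studies of one receptor into a consensus.

Builds a latent ground-truth response profile, observes it through three
studies with different monotone response scales, partial odorant panels
and measurement noise, merges them, and compares the consensus ranks with
the truth.
"""

import pandas as pd
from scipy.stats import spearmanr

import odorfusion as of

cfg = of.SimulationConfig(n_odorants=60, n_studies=3, overlap_fraction=0.6,
                          noise_sd=0.05, seed=1)
truth = of.simulate_ground_truth(cfg)
datasets, meta = of.simulate_studies(truth, cfg)

for ds in datasets:
    family = meta["studies"][ds.study_id]["family"]
    print(f"{ds.study_id}: {len(ds.odorants)} odorants, {family} response scale")

consensus = of.merge_unit(datasets)
print(f"\nstrategy: {consensus.strategy}; "
      f"{len(consensus.merge_log)} pairwise merges, "
      f"{len(consensus.excluded_studies)} studies excluded")
for step in consensus.merge_log:
    print(f"  {step.left} + {step.right}: {step.chosen.label}, "
          f"MD = {step.chosen.md:.4f}")

common = consensus.values.index.intersection(truth.index)
rho = spearmanr(consensus.values[common], truth[common]).statistic
print(f"\nconsensus covers {len(common)} odorants, all scaled to [0, 1]")
print(f"Spearman(consensus, ground truth) = {rho:.3f}")
print("-> the merged profile reproduces the latent response ranking almost "
      "perfectly despite the three incompatible measurement scales")
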