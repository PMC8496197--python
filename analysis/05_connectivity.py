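#!/usr/bin/env python
"""Informational-connectivity recovery.

A feedforward coupling (A3A superficial -> A7 middle, correlated blocks,
rho_true = 0.5) is injected as a shared block-wise gain on the pattern
amplitude.  Over 20 simulated subjects the script measures the recovered
Spearman correlation of the hyperplane-distance series for the coupled
pair, the condition ordering z(correlated) > z(anti-correlated), and the
correlations of all uncoupled feedforward pairs.  Writes
results/connectivity_recovery.tsv.
"""

import logging
from pathlib import Path

import pandas as pd

from lamina.experiments import connectivity_recovery

logging.disable(logging.INFO)
ROOT = Path(__file__).resolve().parent.parent

out = connectivity_recovery(seed=3, n_seeds=20)
res = ROOT / "results"
res.mkdir(exist_ok=True)
pd.DataFrame([out]).to_csv(res / "connectivity_recovery.tsv", sep="\t",
                           index=False)

print(f"coupled pair (A3A sup -> A7 mid, correlated): "
      f"mean rho = {out['coupled_mean_rho']:.3f} (injected 0.5)")
print(f"z(correlated) > z(anti-correlated):           "
      f"{out['direction_wins']}/{out['n_seeds']} seeds")
print(f"uncoupled pairs, max |mean rho|:              "
      f"{out['uncoupled_max_abs_mean_rho']:.3f}")
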