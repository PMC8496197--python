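#!/usr/bin/env python
"""Equi-volume vs equidistant cortical depths.

Tabulates the equi-volume depth fractions across curvature (inner/outer
boundary area ratios), verifies the closed form against numerical
inversion of the wedge volume integral, and measures how often the
Euclidean two-closest-grids rule assigns voxels to a different lamina
than equidistant banding would.  Writes results/equivolume_depths.tsv.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from lamina.experiments import equivolume_oracle_error
from lamina.layers import assign_voxels, build_grids, equivolume_fraction
from lamina.synthdata import generate_cortical_patch

ROOT = Path(__file__).resolve().parent.parent

rows = []
for ratio in (0.25, 0.5, 1.0, 2.0, 4.0):
    for alpha in (1 / 3, 0.5, 2 / 3):
        rows.append({"outer_over_inner_area": ratio, "volume_fraction": alpha,
                     "equivolume_depth": equivolume_fraction(alpha, 1.0, ratio),
                     "equidistant_depth": alpha})
table = pd.DataFrame(rows)
res = ROOT / "results"
res.mkdir(exist_ok=True)
table.to_csv(res / "equivolume_depths.tsv", sep="\t", index=False)

oracle = equivolume_oracle_error(seed=0, n_draws=1000)
model = generate_cortical_patch(80, 9, seed=0)
assignment = assign_voxels(model, build_grids(model))
equidist = np.digitize(model.true_depth, [1 / 3, 2 / 3])
disagree = float((assignment.layer_id != equidist).mean())

print(table.to_string(index=False))
print(f"\nclosed form vs numerical inversion, max |error|: "
      f"{oracle['max_abs_error']:.2e} over {oracle['n_draws']} curvatures")
print(f"voxels assigned differently than equidistant banding: "
      f"{100 * disagree:.1f}% (curvature range [0.5, 2] mm^2)")
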