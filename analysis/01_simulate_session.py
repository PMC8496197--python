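#!/usr/bin/env python
"""Simulate one subject's session and export it.

Generates a three-area cortical patch, a counterbalanced 4-run block
design, and laminar BOLD with the default vascular confounds and layer
effects, then writes the session (BOLD NIfTI per area, layer-label
NIfTI, BIDS-style events TSV, grid JSON, ground-truth JSON) under
scratch/session/ and a small provenance summary under results/.
"""

import json
from pathlib import Path

from lamina.io import write_session
from lamina.layers import assign_voxels, build_grids
from lamina.pipeline import PipelineConfig

ROOT = Path(__file__).resolve().parent.parent
SEED = 1

cfg = PipelineConfig(seed=SEED)
spec = cfg.effect_spec(seed=SEED)
from lamina.synthdata import generate_cortical_patch, generate_design, simulate_bold

model = generate_cortical_patch(cfg.n_columns_per_area, cfg.voxels_per_column,
                                tuple(cfg.curvature_range), tuple(cfg.areas),
                                seed=SEED)
design = generate_design(4, tr=cfg.tr,
                         blocks_per_condition=cfg.blocks_per_condition,
                         block_duration=cfg.block_duration,
                         fixation_duration=cfg.fixation_duration, seed=SEED)
datasets, gt = simulate_bold(model, design, spec)
grids = build_grids(model)
assignment = assign_voxels(model, grids)

outdir = ROOT / "scratch" / "session"
write_session(outdir, model, design, datasets, assignment, grids, gt)

summary = {
    "seed": SEED,
    "areas": cfg.areas,
    "n_voxels": int(model.n_voxels),
    "runs": int(design.n_runs),
    "run_duration_s": design.run_duration_s,
    "trs_per_run": design.run_trs,
    "n_vein_voxels": int(len(gt.vein_voxels)),
    "signal_cells": [list(c) for c in gt.signal_cells],
}
res = ROOT / "results"
res.mkdir(exist_ok=True)
(res / "session_summary.json").write_text(json.dumps(summary, indent=1))
print(f"session written to {outdir}")
print(json.dumps(summary, indent=1))
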