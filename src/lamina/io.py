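"""NIfTI / TSV / JSON import-export.

Synthetic sessions are written in a minimal BIDS-like layout: one 4-D
BOLD NIfTI per area (columns rasterised on their grid positions), a 3-D
integer layer-label NIfTI (1 = deeper, 2 = middle, 3 = superficial,
0 = outside the ribbon), a BIDS-style events TSV (onset, duration,
trial_type), grid fractions as JSON, and ground truth as JSON.  The same
functions read real data back into the package's containers.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .core import Dataset
from .layers import GridSurfaces


def _raster_shape(model) -> tuple[int, int, int]:
    return tuple(model.voxel_grid_index.max(axis=0) + 1)


def write_bold_nifti(ds: Dataset, model, path) -> None:
    """Rasterise one area's voxel x TR matrix into a 4-D NIfTI."""
    shape = _raster_shape(model)
    vol = np.zeros(shape + (ds.n_trs,), dtype=np.float32)
    gi = model.voxel_grid_index[ds.voxel_index]
    vol[gi[:, 0], gi[:, 1], gi[:, 2], :] = ds.data
    img = nib.Nifti1Image(vol, affine=np.diag([0.8, 0.8, 0.8, 1.0]))
    img.header.set_zooms((0.8, 0.8, 0.8, ds.tr))
    nib.save(img, str(path))


def write_layer_labels(model, assignment, path) -> None:
    """Layer labels as 3-D integer NIfTI (1=deeper, 2=middle, 3=superficial)."""
    shape = _raster_shape(model)
    vol = np.zeros(shape, dtype=np.int16)
    gi = model.voxel_grid_index
    vol[gi[:, 0], gi[:, 1], gi[:, 2]] = assignment.layer_id + 1
    nib.save(nib.Nifti1Image(vol, affine=np.diag([0.8, 0.8, 0.8, 1.0])),
             str(path))


def write_events_tsv(design, path) -> None:
    """BIDS-style events table: onset (s), duration (s), trial_type."""
    df = pd.DataFrame({
        "onset": design.block_onsets * design.tr,
        "duration": design.block_duration,
        "trial_type": [f"{s}_{d}" for s, d in
                       zip(design.stereo, design.disparity)],
        "run": design.run_id,
    })
    df.to_csv(path, sep="\t", index=False)


def write_grids_json(grids: GridSurfaces, path) -> None:
    payload = {str(c): [float(f) for f in row]
               for c, row in enumerate(grids.fractions)}
    Path(path).write_text(json.dumps(payload, indent=1))


def write_ground_truth_json(gt, path) -> None:
    payload = {
        "vein_voxels": gt.vein_voxels.tolist(),
        "true_layer": gt.true_layer.tolist(),
        "signal_cells": [list(c) for c in gt.signal_cells],
        "block_gains": {"|".join(k): v.tolist()
                        for k, v in gt.block_gains.items()},
        "seed": gt.spec.seed,
    }
    Path(path).write_text(json.dumps(payload))


def load_bold(bold_path, events_path, labels_path, area: str = "ROI",
              run_column: str = "run"):
    """Real-data entry point: 4-D BOLD NIfTI + events TSV + layer labels.

    Returns ``(dataset, layer_id, events)`` where the dataset rows are the
    in-ribbon voxels (label > 0), ``layer_id`` is 0/1/2 per row, and
    ``events`` is the raw events table (onset seconds, duration,
    trial_type, run).
    """
    img = nib.load(str(bold_path))
    vol = np.asarray(img.dataobj)
    if vol.ndim != 4:
        raise ValueError("expected a 4-D BOLD image")
    tr = float(img.header.get_zooms()[3])
    labels = np.asarray(nib.load(str(labels_path)).dataobj).astype(int)
    if labels.shape != vol.shape[:3]:
        raise ValueError("label volume does not match BOLD geometry")
    mask = labels > 0
    data = vol[mask].astype(float)
    layer_id = labels[mask] - 1

    events = pd.read_csv(events_path, sep="\t")
    if run_column not in events:
        raise ValueError(f"events table lacks a {run_column!r} column")
    n_runs = int(events[run_column].nunique())
    n_trs = data.shape[1]
    if n_trs % n_runs:
        raise ValueError("TR count is not divisible by the number of runs; "
                         "equal-length runs are assumed")
    run_starts = np.arange(n_runs) * (n_trs // n_runs)
    ds = Dataset(data=data, tr=tr, run_starts=run_starts,
                 area=area, voxel_index=np.flatnonzero(mask.ravel()),
                 applied_steps=["loaded"])
    return ds, layer_id, events


def write_session(outdir, model, design, datasets, assignment, grids, gt) -> None:
    """Write a full synthetic session to ``outdir``."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    for area, ds in datasets.items():
        write_bold_nifti(ds, model, out / f"bold_{area}.nii.gz")
    write_layer_labels(model, assignment, out / "layers.nii.gz")
    write_events_tsv(design, out / "events.tsv")
    write_grids_json(grids, out / "grids.json")
    write_ground_truth_json(gt, out / "ground_truth.json")
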