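"""Shared fixtures: small simulated sessions and helpers.

Everything is generated programmatically from fixed seeds; no data files.
"""

import logging

import numpy as np
import pytest

from lamina.core import Dataset
from lamina.preprocess import block_responses, highpass_and_detrend
from lamina.synthdata import (EffectSpec, generate_cortical_patch,
                              generate_design, simulate_bold)

logging.getLogger("lamina").setLevel(logging.ERROR)


def zscore_per_run(ds: Dataset) -> Dataset:
    data = ds.data.copy()
    for sl in ds.run_slices():
        seg = data[:, sl]
        data[:, sl] = (seg - seg.mean(1, keepdims=True)) / seg.std(1, keepdims=True)
    return ds.with_data(data, "zscore")


def null_block_patterns(seed: int, n_columns: int = 15, runs: int = 4,
                        stereo: str = "correlated", **spec_kwargs):
    """Block patterns from a fully null simulation (no disparity signal)."""
    model = generate_cortical_patch(n_columns, 9, seed=seed, areas=("A1",))
    design = generate_design(runs, seed=seed + 1)
    spec = EffectSpec(seed=seed + 2, vein_fraction=0.0, **spec_kwargs)
    datasets, _ = simulate_bold(model, design, spec)
    ds = zscore_per_run(highpass_and_detrend(datasets["A1"]))
    return block_responses(ds, design).for_stereo(stereo)


@pytest.fixture(scope="session")
def small_model():
    return generate_cortical_patch(20, 9, seed=7)


@pytest.fixture(scope="session")
def flat_model():
    """Zero-curvature patch: equi-volume reduces exactly to equidistant."""
    return generate_cortical_patch(12, 9, curvature_range=(1.0, 1.0 + 1e-13),
                                   seed=3)


@pytest.fixture(scope="session")
def study_design():
    """The study's printed design: TR 2 s, 10 blocks/condition, 12 s
    blocks, 12 s lead/trail fixation."""
    return generate_design(4, tr=2.0, blocks_per_condition=10,
                           block_duration=12.0, fixation_duration=12.0, seed=11)


@pytest.fixture(scope="session")
def null_session(small_model, study_design):
    """Null simulation (no disparity signal, no veins) on the small patch."""
    spec = EffectSpec(seed=5, vein_fraction=0.0)
    datasets, gt = simulate_bold(small_model, study_design, spec)
    return datasets, gt, spec
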