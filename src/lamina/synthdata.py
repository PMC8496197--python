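"""Synthetic laminar-BOLD generator with ground-truth bookkeeping.

Emulates a 7T block-design stereoscopic-depth experiment: three visual
areas (analogues named A1, A3A, A7), a cortical ribbon parameterised as
columns with known curvature (inner/outer boundary patch areas), a
counterbalanced 2x2 block design (stereo: correlated / anti-correlated
RDS x disparity: near / far), and the vascular confounds the analysis
pipeline has to remove:

* a superficial gain gradient ``1 + b * depth`` applied to both the
  evoked signal and the physiological noise (gradient-echo BOLD amplitude
  and fluctuation both grow toward the pial surface);
* draining-vein leakage: superficial voxels receive a fraction of the
  mean deeper+middle signal of their column;
* sparse large-vein voxels with inflated amplitude and noise.

Condition information is carried by a fixed random near-vs-far pattern
direction per (area, layer); optional coupling entries impose a shared
per-block multiplicative gain on the pattern amplitude of two
(area, layer) cells, which synchronises their block-wise discriminability
without changing mean signals - the ground truth for informational
connectivity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import lfilter

from .core import (DISPARITY_LABELS, LAYER_NAMES, STEREO_CONDITIONS, Dataset,
                   convolve_blocks)
from .layers import equivolume_fraction

CONDITION_CELLS = [(s, d) for s in STEREO_CONDITIONS for d in DISPARITY_LABELS]


@dataclass
class CorticalModel:
    """Column-parameterised cortical patch (no mesh).

    ``true_depth`` is the generative depth fraction (0 = white/grey
    boundary, 1 = grey/CSF boundary); ``inner_area`` / ``outer_area`` are
    per-column boundary patch areas in mm^2 standing in for curvature.
    """

    voxel_positions: np.ndarray   # n_vox x 3, mm
    true_depth: np.ndarray
    column_id: np.ndarray
    area_id: np.ndarray           # str label per voxel
    inner_area: np.ndarray        # per column
    outer_area: np.ndarray
    column_xy: np.ndarray         # n_columns x 2, mm
    thickness: float
    vein_flag: np.ndarray = None  # filled by simulate_bold
    grid_surfaces: object = None  # filled by layers.build_grids
    voxel_grid_index: np.ndarray = None  # n_vox x 3 integer raster coords

    def __post_init__(self):
        if self.vein_flag is None:
            self.vein_flag = np.zeros(len(self.true_depth), dtype=bool)
        if np.any(self.true_depth < 0) or np.any(self.true_depth > 1):
            raise ValueError("true_depth must lie in [0, 1]")

    @property
    def n_voxels(self) -> int:
        return len(self.true_depth)

    @property
    def areas(self) -> list[str]:
        seen = dict.fromkeys(self.area_id.tolist())
        return list(seen)

    def voxels_of(self, area: str) -> np.ndarray:
        return np.flatnonzero(self.area_id == area)

    def true_layer(self) -> np.ndarray:
        """Generative lamina per voxel: bands of true_depth delimited by
        the column's equi-volume fractions at volume thirds."""
        f1 = equivolume_fraction(1 / 3, self.inner_area, self.outer_area)
        f2 = equivolume_fraction(2 / 3, self.inner_area, self.outer_area)
        f1 = np.atleast_1d(f1)[self.column_id]
        f2 = np.atleast_1d(f2)[self.column_id]
        return ((self.true_depth >= f1).astype(int)
                + (self.true_depth >= f2).astype(int))


def generate_cortical_patch(n_columns: int, voxels_per_column: int,
                            curvature_range: tuple[float, float] = (0.5, 2.0),
                            areas: tuple[str, ...] = ("A1", "A3A", "A7"),
                            seed: int = 0, pitch: float = 0.8,
                            thickness: float = 2.4) -> CorticalModel:
    """Generate a cortical patch of ``n_columns`` columns per area.

    Voxels sit at equally spaced depths ``(i+1)/(n+1)`` along each
    column's normal; inner/outer boundary patch areas are drawn uniformly
    from ``curvature_range`` (mm^2).  Columns are laid out on a
    ``pitch``-mm grid, with areas spatially offset so that neighbourhood
    queries stay within area.
    """
    if n_columns < 1 or voxels_per_column < 3:
        raise ValueError("need n_columns >= 1 and voxels_per_column >= 3")
    lo, hi = curvature_range
    if lo <= 0 or hi <= 0 or hi < lo:
        raise ValueError("curvature_range must be a positive interval")
    rng = np.random.default_rng(seed)
    n_total_cols = n_columns * len(areas)
    inner = rng.uniform(lo, hi, size=n_total_cols)
    outer = rng.uniform(lo, hi, size=n_total_cols)

    ncols_x = int(np.ceil(np.sqrt(n_columns)))
    depths = (np.arange(voxels_per_column) + 1) / (voxels_per_column + 1)

    positions, true_depth, column_id, area_id, grid_index = [], [], [], [], []
    column_xy = np.empty((n_total_cols, 2))
    area_gap = (ncols_x + 10) * pitch
    for a_idx, area in enumerate(areas):
        for c in range(n_columns):
            col = a_idx * n_columns + c
            ix, iy = c % ncols_x, c // ncols_x
            xy = np.array([a_idx * area_gap + ix * pitch, iy * pitch])
            column_xy[col] = xy
            jitter = rng.uniform(-0.01, 0.01, size=(voxels_per_column, 2))
            for i, d in enumerate(depths):
                positions.append([xy[0] + jitter[i, 0], xy[1] + jitter[i, 1],
                                  d * thickness])
                true_depth.append(d)
                column_id.append(col)
                area_id.append(area)
                grid_index.append([a_idx * (ncols_x + 2) + ix, iy, i])

    model = CorticalModel(
        voxel_positions=np.asarray(positions),
        true_depth=np.asarray(true_depth),
        column_id=np.asarray(column_id),
        area_id=np.asarray(area_id, dtype=object),
        inner_area=inner, outer_area=outer,
        column_xy=column_xy, thickness=thickness,
        voxel_grid_index=np.asarray(grid_index, dtype=int))
    from .layers import build_grids
    model.grid_surfaces = build_grids(model)
    return model


@dataclass
class BlockDesign:
    """Counterbalanced run/block/condition structure on the TR grid.

    Stimulus-level metadata (0.9 s stimuli, 0.3 s ISI, +/-10 arcmin
    disparity with +/-0.5 arcmin jitter) is carried for provenance only;
    blocks are simulated and analysed as single boxcars.
    """

    tr: float
    n_runs: int
    blocks_per_run: int
    block_duration: float
    fixation_duration: float
    block_onsets: np.ndarray    # absolute 0-based TR index per block
    stereo: np.ndarray
    disparity: np.ndarray
    run_id: np.ndarray
    stimulus_meta: dict = field(default_factory=lambda: {
        "stimulus_duration_s": 0.9, "isi_s": 0.3,
        "disparity_arcmin": 10.0, "disparity_jitter_arcmin": 0.5})

    @property
    def run_duration_s(self) -> float:
        return (2 * self.fixation_duration
                + self.blocks_per_run * self.block_duration)

    @property
    def run_trs(self) -> int:
        return int(round(self.run_duration_s / self.tr))

    @property
    def n_trs(self) -> int:
        return self.n_runs * self.run_trs

    @property
    def run_starts(self) -> np.ndarray:
        return np.arange(self.n_runs) * self.run_trs

    @property
    def n_blocks(self) -> int:
        return len(self.block_onsets)

    def blocks_of(self, stereo: str | None = None,
                  disparity: str | None = None) -> np.ndarray:
        mask = np.ones(self.n_blocks, dtype=bool)
        if stereo is not None:
            mask &= self.stereo == stereo
        if disparity is not None:
            mask &= self.disparity == disparity
        return np.flatnonzero(mask)


def generate_design(runs: int, tr: float = 2.0, blocks_per_condition: int = 10,
                    block_duration: float = 12.0, fixation_duration: float = 12.0,
                    seed: int = 0) -> BlockDesign:
    """Counterbalanced 2x2 block design.

    Each run holds ``blocks_per_condition`` chunks of four blocks; every
    chunk is a random permutation of the four (stereo x disparity) cells,
    so each cell occurs exactly ``blocks_per_condition`` times per run and
    is spread evenly through the run.
    """
    if runs < 2:
        raise ValueError("need at least 2 runs for leave-one-run-out CV")
    for name, dur in (("block_duration", block_duration),
                      ("fixation_duration", fixation_duration)):
        if abs(dur / tr - round(dur / tr)) > 1e-9:
            raise ValueError(f"{name} must be a multiple of the TR")
    rng = np.random.default_rng(seed)
    blocks_per_run = 4 * blocks_per_condition
    fix_trs = int(round(fixation_duration / tr))
    block_trs = int(round(block_duration / tr))
    run_trs = 2 * fix_trs + blocks_per_run * block_trs

    onsets, stereo, disparity, run_ids = [], [], [], []
    for r in range(runs):
        order = []
        for _ in range(blocks_per_condition):
            order.extend(rng.permutation(4))
        for j, cell in enumerate(order):
            onsets.append(r * run_trs + fix_trs + j * block_trs)
            stereo.append(CONDITION_CELLS[cell][0])
            disparity.append(CONDITION_CELLS[cell][1])
            run_ids.append(r)
    return BlockDesign(tr=tr, n_runs=runs, blocks_per_run=blocks_per_run,
                       block_duration=block_duration,
                       fixation_duration=fixation_duration,
                       block_onsets=np.asarray(onsets),
                       stereo=np.asarray(stereo, dtype=object),
                       disparity=np.asarray(disparity, dtype=object),
                       run_id=np.asarray(run_ids))


@dataclass
class Coupling:
    """Shared block-wise discriminability fluctuation between two cells."""

    source: tuple[str, str]     # (area, layer)
    target: tuple[str, str]
    stereo: str
    rho: float

    def __post_init__(self):
        if not 0 <= self.rho <= 1:
            raise ValueError("coupling rho must lie in [0, 1]")


@dataclass
class EffectSpec:
    """Generative parameters of one simulated session.

    ``pattern_amplitude`` maps (area, layer, stereo) to the per-voxel RMS
    amplitude (arbitrary BOLD units) of the near-vs-far pattern signal;
    unlisted cells carry no disparity information.  ``evoked_amplitude``
    is the condition-independent stimulus response that drives voxel
    selection and the laminar response profile.  See the module docstring
    for the vascular parameters.
    """

    pattern_amplitude: dict = field(default_factory=dict)
    evoked_amplitude: float = 1.0
    baseline: float = 100.0
    superficial_gain_slope: float = 1.0
    leak_fraction: float = 0.0
    vein_fraction: float = 0.05
    vein_noise_mult: float = 3.0
    vein_amp_mult: float = 2.0
    noise_sd: float = 1.0
    physio_ar1: float = 0.3
    coupling: list = field(default_factory=list)
    coupling_gain_sd: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if not 0 <= self.leak_fraction < 1:
            raise ValueError("leak_fraction must lie in [0, 1)")
        if not 0 <= self.vein_fraction < 1:
            raise ValueError("vein_fraction must lie in [0, 1)")
        if not 0 <= self.physio_ar1 < 1:
            raise ValueError("physio_ar1 must lie in [0, 1)")
        if any(a < 0 for a in self.pattern_amplitude.values()):
            raise ValueError("pattern amplitudes must be >= 0")


@dataclass
class GroundTruth:
    """Everything needed to score recovery of the injected structure."""

    pattern_directions: dict    # (area, layer) -> per-voxel pattern (area-local)
    block_gains: dict           # (area, layer, stereo) -> gain per block of that stereo
    vein_voxels: np.ndarray     # global voxel indices
    true_layer: np.ndarray      # global, 0/1/2
    signal_cells: list          # (area, layer, stereo) with amplitude > 0
    spec: EffectSpec


def _ar1_noise(rng, shape, sd, phi):
    white = rng.standard_normal(shape)
    if phi == 0:
        return sd * white
    innov_sd = np.sqrt(1 - phi**2)
    return sd * lfilter([1.0], [1.0, -phi], innov_sd * white, axis=-1)


def simulate_bold(model: CorticalModel, design: BlockDesign,
                  spec: EffectSpec) -> tuple[dict, GroundTruth]:
    """Simulate voxel time courses for every area of ``model``.

    Returns ``(datasets, ground_truth)`` where ``datasets`` maps area
    name to a :class:`~lamina.core.Dataset`.  See the module docstring
    for the generative model.
    """
    areas = model.areas
    layer_of = model.true_layer()
    for c in spec.coupling:
        for area, layer in (c.source, c.target):
            if area not in areas or layer not in LAYER_NAMES:
                raise ValueError(f"coupling references unknown cell {(area, layer)}")
        if c.stereo not in STEREO_CONDITIONS:
            raise ValueError(f"unknown stereo condition {c.stereo!r}")

    ss = np.random.SeedSequence(spec.seed)
    rng_pattern, rng_gain, rng_vein, rng_noise = [
        np.random.default_rng(s) for s in ss.spawn(4)]

    n_trs = design.n_trs
    basis = convolve_blocks(design.block_onsets, design.block_duration,
                            n_trs, design.tr, design.run_starts)

    # per-block multiplicative gains, one series per (area, layer, stereo)
    gains = {(a, l, s): np.zeros(len(design.blocks_of(stereo=s)))
             for a in areas for l in LAYER_NAMES for s in STEREO_CONDITIONS}
    for c in spec.coupling:
        nb = len(design.blocks_of(stereo=c.stereo))
        shared = rng_gain.standard_normal(nb)
        for area, layer in (c.source, c.target):
            own = rng_gain.standard_normal(nb)
            g = spec.coupling_gain_sd * (np.sqrt(c.rho) * shared
                                         + np.sqrt(1 - c.rho) * own)
            gains[(area, layer, c.stereo)] += g

    vein = rng_vein.random(model.n_voxels) < spec.vein_fraction
    model.vein_flag = vein

    sign = np.where(design.disparity == "near", 1.0, -1.0)
    gain_depth = 1.0 + spec.superficial_gain_slope * model.true_depth

    patterns = {}
    datasets = {}
    for area in areas:
        vox = model.voxels_of(area)
        nv = len(vox)
        amp_block = np.full((nv, design.n_blocks), spec.evoked_amplitude)
        for layer_idx, layer in enumerate(LAYER_NAMES):
            in_layer = layer_of[vox] == layer_idx
            pat = rng_pattern.standard_normal(nv) * in_layer
            patterns[(area, layer)] = pat
            for stereo in STEREO_CONDITIONS:
                amp = spec.pattern_amplitude.get((area, layer, stereo), 0.0)
                blocks = design.blocks_of(stereo=stereo)
                g = gains[(area, layer, stereo)]
                contrib = (amp * pat[:, None] * sign[blocks][None, :]
                           * (1.0 + g)[None, :])
                amp_block[:, blocks] += contrib

        signal = amp_block @ basis
        signal *= gain_depth[vox][:, None]

        if spec.leak_fraction > 0:
            sup = layer_of[vox] == 2
            deep_mid = ~sup
            for col in np.unique(model.column_id[vox]):
                in_col = model.column_id[vox] == col
                src = in_col & deep_mid
                dst = in_col & sup
                if src.any() and dst.any():
                    signal[dst] += spec.leak_fraction * signal[src].mean(axis=0)

        is_vein = vein[vox]
        signal[is_vein] *= spec.vein_amp_mult

        noise_sd = spec.noise_sd * gain_depth[vox]
        noise_sd = np.where(is_vein, noise_sd * spec.vein_noise_mult, noise_sd)
        noise = _ar1_noise(rng_noise, (nv, n_trs), 1.0, spec.physio_ar1)
        data = spec.baseline + signal + noise_sd[:, None] * noise

        datasets[area] = Dataset(data=data, tr=design.tr,
                                 run_starts=design.run_starts, area=area,
                                 voxel_index=vox,
                                 applied_steps=["simulate_bold"])

    signal_cells = [cell for cell, a in spec.pattern_amplitude.items() if a > 0]
    gt = GroundTruth(pattern_directions=patterns, block_gains=gains,
                     vein_voxels=np.flatnonzero(vein), true_layer=layer_of,
                     signal_cells=signal_cells, spec=spec)
    return datasets, gt
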