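"""Shared containers and hemodynamic utilities.

Conventions used throughout the package:

* time courses are stored as ``voxel x TR`` matrices;
* cortical depth runs from 0 (white/grey boundary) to 1 (grey/CSF boundary);
* the three depth bins are named ``deeper``, ``middle``, ``superficial``;
* disparity labels are ``near`` / ``far``; stereo conditions are
  ``correlated`` / ``anti-correlated`` (correlated vs contrast-reversed
  random-dot stereograms).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

LAYER_NAMES = ("deeper", "middle", "superficial")
STEREO_CONDITIONS = ("correlated", "anti-correlated")
DISPARITY_LABELS = ("near", "far")


def double_gamma_hrf(t: np.ndarray, peak: float = 6.0, undershoot: float = 16.0,
                     ratio: float = 6.0) -> np.ndarray:
    """Canonical double-gamma haemodynamic response, peak normalised to 1.

    ``peak`` and ``undershoot`` are the modes (in seconds) of the positive
    and negative gamma lobes (unit dispersion); ``ratio`` is the
    peak-to-undershoot amplitude ratio.
    """
    from scipy.stats import gamma

    t = np.asarray(t, dtype=float)
    h = gamma.pdf(t, peak) - gamma.pdf(t, undershoot) / ratio
    peak_val = h.max()
    if peak_val <= 0:
        raise ValueError("degenerate HRF parameters")
    return h / peak_val


def convolve_blocks(onsets_tr: np.ndarray, duration_s: float, n_trs: int, tr: float,
                    run_boundaries: np.ndarray, oversample: int = 10,
                    hrf_kwargs: dict | None = None) -> np.ndarray:
    """HRF-convolved boxcar regressors, one row per block.

    Convolution is carried out on an oversampled grid and done separately
    per run, so a block cannot bleed across a run boundary.  Returns a
    ``n_blocks x n_trs`` matrix sampled on the TR grid.
    """
    onsets_tr = np.asarray(onsets_tr)
    dt = tr / oversample
    hrf_len = int(np.ceil(32.0 / dt))
    h = double_gamma_hrf(np.arange(hrf_len) * dt, **(hrf_kwargs or {}))
    h /= h.sum()  # unit-sum kernel: a sustained block plateaus at amplitude 1
    run_edges = list(run_boundaries) + [n_trs]
    out = np.zeros((len(onsets_tr), n_trs))
    for b, onset in enumerate(onsets_tr):
        run = int(np.searchsorted(run_boundaries, onset, side="right") - 1)
        start, stop = run_edges[run], run_edges[run + 1]
        n_fine = (stop - start) * oversample
        box = np.zeros(n_fine)
        i0 = int(round((onset - start) * oversample))
        i1 = min(i0 + int(round(duration_s / dt)), n_fine)
        box[i0:i1] = 1.0
        conv = np.convolve(box, h)[:n_fine]
        out[b, start:stop] = conv[::oversample]
    return out


def condition_regressors(design, conditions: list[tuple[str, str]], n_trs: int,
                         hrf_kwargs: dict | None = None) -> np.ndarray:
    """``n_conditions x n_trs`` HRF-convolved regressors, one per
    (stereo, disparity) cell of a block design."""
    basis = convolve_blocks(design.block_onsets, design.block_duration, n_trs,
                            design.tr, design.run_starts, hrf_kwargs=hrf_kwargs)
    out = np.zeros((len(conditions), n_trs))
    for i, (stereo, disparity) in enumerate(conditions):
        sel = (design.stereo == stereo) & (design.disparity == disparity)
        out[i] = basis[sel].sum(axis=0)
    return out


@dataclass
class Dataset:
    """Voxel x TR time courses for one cortical area.

    ``voxel_index`` maps rows back to voxels of the originating
    :class:`~lamina.synthdata.CorticalModel` (or of the label volume for
    real data); ``applied_steps`` is an append-only provenance trail.
    """

    data: np.ndarray
    tr: float
    run_starts: np.ndarray      # first TR index of each run
    area: str
    voxel_index: np.ndarray
    applied_steps: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.run_starts = np.asarray(self.run_starts, dtype=int)
        self.voxel_index = np.asarray(self.voxel_index, dtype=int)
        if self.run_starts[0] != 0 or np.any(np.diff(self.run_starts) <= 0):
            raise ValueError("run_starts must start at 0 and be increasing")

    @property
    def n_voxels(self) -> int:
        return self.data.shape[0]

    @property
    def n_trs(self) -> int:
        return self.data.shape[1]

    @property
    def n_runs(self) -> int:
        return len(self.run_starts)

    def run_slices(self) -> list[slice]:
        edges = list(self.run_starts) + [self.n_trs]
        return [slice(edges[i], edges[i + 1]) for i in range(self.n_runs)]

    def with_data(self, data: np.ndarray, step: str, voxel_index=None) -> "Dataset":
        """Copy with new data and the processing step appended."""
        new = replace(self, data=data,
                      voxel_index=self.voxel_index if voxel_index is None
                      else np.asarray(voxel_index, dtype=int))
        new.applied_steps = self.applied_steps + [step]
        return new


@dataclass
class BlockPatterns:
    """Block x voxel response matrix with labels.

    ``label`` is the near/far disparity, ``stereo`` the RDS condition,
    ``run_id`` the scanning run each block belongs to.  ``layer`` is None
    for an all-depth container and a layer name once voxels have been
    restricted to one cortical depth.
    """

    responses: np.ndarray
    label: np.ndarray           # "near" / "far"
    stereo: np.ndarray
    run_id: np.ndarray
    onset_tr: np.ndarray
    voxel_index: np.ndarray
    area: str
    layer: str | None = None

    def __post_init__(self):
        n = self.responses.shape[0]
        for name in ("label", "stereo", "run_id", "onset_tr"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"{name} length does not match blocks")

    @property
    def n_blocks(self) -> int:
        return self.responses.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.responses.shape[1]

    def subset_voxels(self, cols: np.ndarray, layer: str | None = None) -> "BlockPatterns":
        cols = np.asarray(cols, dtype=int)
        return BlockPatterns(self.responses[:, cols], self.label, self.stereo,
                             self.run_id, self.onset_tr, self.voxel_index[cols],
                             self.area, layer if layer is not None else self.layer)

    def subset_blocks(self, mask: np.ndarray) -> "BlockPatterns":
        mask = np.asarray(mask)
        return BlockPatterns(self.responses[mask], self.label[mask],
                             self.stereo[mask], self.run_id[mask],
                             self.onset_tr[mask], self.voxel_index, self.area,
                             self.layer)

    def for_stereo(self, stereo: str) -> "BlockPatterns":
        return self.subset_blocks(self.stereo == stereo)
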