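"""Temporal filtering, condition GLM, and vasculature correction.

The correction pipeline follows the order: high-pass filter + detrend ->
condition GLM -> tSNR / high-t voxel exclusion -> layer voxel-count
matching + within-layer z-scoring -> (optional) spatial regression of
middle-layer neighbours out of superficial voxels -> block-response
extraction.  Every step appends a provenance label to the dataset.
"""

from __future__ import annotations

import logging
import re
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .core import BlockPatterns, Dataset, condition_regressors
from .synthdata import CONDITION_CELLS, BlockDesign

logger = logging.getLogger(__name__)


def _ols_residuals(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Residuals of Y (obs x voxels) on X (obs x p) via least squares."""
    beta, *_ = np.linalg.lstsq(x, y, rcond=None)
    return y - x @ beta


def _drift_basis(n: int, n_cycles: int) -> np.ndarray:
    """Per-run drift basis: intercept, linear trend, sin/cos at
    1..n_cycles cycles per run."""
    t = np.arange(n)
    cols = [np.ones(n), t - t.mean()]
    for k in range(1, n_cycles + 1):
        cols.append(np.sin(2 * np.pi * k * t / n))
        cols.append(np.cos(2 * np.pi * k * t / n))
    return np.column_stack(cols)


def highpass_and_detrend(ds: Dataset, n_cycles: int = 2) -> Dataset:
    """Remove intercept, linear trend, and slow Fourier drifts per run.

    The nuisance basis per run is {1, t, sin/cos at 1..n_cycles cycles per
    run}; the residual time courses are returned.
    """
    basis_rank = 2 + 2 * n_cycles
    out = np.empty_like(ds.data)
    for sl in ds.run_slices():
        n = sl.stop - sl.start
        if n < max(8, basis_rank + 1):
            raise ValueError(f"run of {n} TRs too short for the drift basis")
        x = _drift_basis(n, n_cycles)
        out[:, sl] = _ols_residuals(x, ds.data[:, sl].T).T
    return ds.with_data(out, f"highpass_detrend(n_cycles={n_cycles})")


@dataclass
class GLMResult:
    """Per-voxel condition GLM fit.

    ``t_map`` is the stimulus-vs-baseline t statistic (mean of the four
    condition betas against zero); ``residuals`` feed the LDC noise
    covariance.
    """

    betas: np.ndarray           # voxel x regressor
    t_map: np.ndarray
    residuals: np.ndarray       # voxel x TR
    dof: int
    design_matrix: np.ndarray
    column_names: list[str]
    contrast: np.ndarray


def build_design_matrix(design: BlockDesign, nuisance: np.ndarray | None = None,
                        hrf_kwargs: dict | None = None,
                        run_intercepts: bool = True):
    """Condition boxcar regressors (HRF-convolved) + per-run intercepts
    (+ optional nuisance columns)."""
    n_trs = design.n_trs
    cond = condition_regressors(design, CONDITION_CELLS, n_trs,
                                hrf_kwargs=hrf_kwargs)
    names = [f"{s}_{d}" for s, d in CONDITION_CELLS]
    cols = [cond.T]
    if run_intercepts:
        for r, sl_start in enumerate(design.run_starts):
            col = np.zeros(n_trs)
            stop = (design.run_starts[r + 1] if r + 1 < design.n_runs else n_trs)
            col[sl_start:stop] = 1.0
            cols.append(col[:, None])
            names.append(f"run{r}_intercept")
    if nuisance is not None:
        nuisance = np.atleast_2d(np.asarray(nuisance, dtype=float))
        if nuisance.shape[0] == n_trs:
            cols.append(nuisance)
        else:
            cols.append(nuisance.T)
        names.extend(f"nuisance{i}" for i in range(cols[-1].shape[1]))
    return np.column_stack(cols), names


def _filter_cycles(ds: Dataset) -> int | None:
    """Number of drift cycles already regressed out of the dataset, if any."""
    cycles = None
    for step in ds.applied_steps:
        m = re.match(r"highpass_detrend\(n_cycles=(\d+)\)", step)
        if m:
            cycles = int(m.group(1))
    return cycles


def fit_glm(ds: Dataset, design: BlockDesign, nuisance: np.ndarray | None = None,
            hrf_kwargs: dict | None = None) -> GLMResult:
    """Per-voxel OLS condition GLM with a stimulus-vs-baseline t map.

    If the dataset has been high-pass filtered, the same drift basis is
    projected out of the design matrix (and the run intercepts, which the
    filter annihilates, are dropped), so contrast variances and residual
    degrees of freedom remain exact.
    """
    cycles = _filter_cycles(ds)
    x, names = build_design_matrix(design, nuisance, hrf_kwargs,
                                   run_intercepts=cycles is None)
    if x.shape[0] != ds.n_trs:
        raise ValueError("design does not span the dataset's TRs")
    drift_dims = 0
    if cycles is not None:
        for sl in ds.run_slices():
            basis = _drift_basis(sl.stop - sl.start, cycles)
            x[sl] = _ols_residuals(basis, x[sl])
            drift_dims += basis.shape[1]
    rank = np.linalg.matrix_rank(x)
    if rank < x.shape[1]:
        # name the offending columns via the QR diagonal
        r = np.abs(np.diag(np.linalg.qr(x, mode="r")))
        bad = [names[i] for i in np.where(r < 1e-10 * r.max())[0]]
        raise ValueError(f"rank-deficient design matrix; collinear columns: {bad}")

    y = ds.data.T
    beta, *_ = np.linalg.lstsq(x, y, rcond=None)
    resid = y - x @ beta
    dof = ds.n_trs - rank - drift_dims
    if dof <= 0:
        raise ValueError("non-positive residual degrees of freedom")
    sigma2 = (resid**2).sum(axis=0) / dof

    n_cond = len(CONDITION_CELLS)
    contrast = np.zeros(x.shape[1])
    contrast[:n_cond] = 1.0 / n_cond
    xtx_inv = np.linalg.inv(x.T @ x)
    c_var = contrast @ xtx_inv @ contrast
    with np.errstate(divide="ignore", invalid="ignore"):
        t_map = (beta.T @ contrast) / np.sqrt(sigma2 * c_var)
    return GLMResult(betas=beta.T, t_map=t_map, residuals=resid.T, dof=dof,
                     design_matrix=x, column_names=names, contrast=contrast)


def roi_voxel_preselect(glm: GLMResult, t_threshold: float = 1.53) -> np.ndarray:
    """Voxels responding more to stimulation than fixation (t above
    threshold); errors if none survive."""
    keep = np.flatnonzero(glm.t_map > t_threshold)
    if keep.size == 0:
        raise ValueError(f"no voxels survive t > {t_threshold}")
    return keep


@dataclass
class VascularMask:
    """Large-vein voxel exclusion by tSNR and high-t cuts."""

    tsnr: np.ndarray
    keep_flag: np.ndarray
    tsnr_cut: float
    t_cut: float
    thresholds: dict

    @property
    def n_excluded(self) -> int:
        return int((~self.keep_flag).sum())


def compute_tsnr(ds: Dataset) -> np.ndarray:
    """Temporal mean / temporal SD per voxel; +inf where SD is zero.

    Must be computed on unfiltered data (filtering removes the mean).
    """
    mean = ds.data.mean(axis=1)
    sd = ds.data.std(axis=1, ddof=1)
    with np.errstate(divide="ignore"):
        return np.where(sd == 0, np.inf, mean / sd)


def vascular_exclusion(ds_raw: Dataset, glm: GLMResult, sd_mult: float = 2.0,
                       t_percentile: float = 90.0) -> VascularMask:
    """Exclude voxels with tSNR below mean - sd_mult*SD of the area's tSNR
    distribution, or stimulus t above the area's t_percentile-th
    percentile."""
    if ds_raw.n_voxels < 20:
        raise ValueError("need >= 20 voxels for a meaningful percentile cut")
    tsnr = compute_tsnr(ds_raw)
    finite = np.isfinite(tsnr)
    tsnr_cut = (-np.inf if np.isinf(sd_mult)
                else tsnr[finite].mean() - sd_mult * tsnr[finite].std(ddof=1))
    t_cut = np.percentile(glm.t_map, t_percentile)
    low_tsnr = tsnr < tsnr_cut
    high_t = glm.t_map > t_cut
    keep = ~(low_tsnr | high_t)
    frac = 1 - keep.mean()
    logger.info("vascular exclusion (%s): removed %.1f%% (%d low-tSNR, %d high-t)",
                ds_raw.area, 100 * frac, low_tsnr.sum(), high_t.sum())
    return VascularMask(tsnr=tsnr, keep_flag=keep, tsnr_cut=tsnr_cut,
                        t_cut=t_cut,
                        thresholds={"sd_mult": sd_mult,
                                    "t_percentile": t_percentile})


def match_and_zscore(ds: Dataset, layer_id: np.ndarray, mask: VascularMask,
                     glm: GLMResult, method: str = "top_t",
                     seed: int | None = None) -> Dataset:
    """Equalise voxel counts across the three layers, then z-score.

    ``layer_id`` and the mask/GLM align with the rows of ``ds``.  The
    minimum per-layer count after masking is kept in every layer, keeping
    the highest stimulus-t voxels (``method='top_t'``, default) or a
    seeded random subsample (``method='random'``).  Surviving time courses
    are z-scored per voxel within each run.
    """
    keep_rows = []
    per_layer = {}
    for l in range(3):
        rows = np.flatnonzero((layer_id == l) & mask.keep_flag)
        if rows.size == 0:
            from .core import LAYER_NAMES
            raise ValueError(f"area {ds.area}: layer {LAYER_NAMES[l]} empty "
                             "after vascular exclusion")
        per_layer[l] = rows
    n_keep = min(len(r) for r in per_layer.values())
    rng = np.random.default_rng(seed)
    for l in range(3):
        rows = per_layer[l]
        if method == "top_t":
            order = np.lexsort((rows, -glm.t_map[rows]))
        elif method == "random":
            order = rng.permutation(len(rows))
        else:
            raise ValueError(f"unknown matching method {method!r}")
        keep_rows.append(rows[order[:n_keep]])
    keep = np.sort(np.concatenate(keep_rows))

    data = ds.data[keep].copy()
    tmp = Dataset(data=data, tr=ds.tr, run_starts=ds.run_starts, area=ds.area,
                  voxel_index=ds.voxel_index[keep])
    for sl in tmp.run_slices():
        seg = data[:, sl]
        mu = seg.mean(axis=1, keepdims=True)
        sd = seg.std(axis=1, ddof=0, keepdims=True)
        sd[sd == 0] = 1.0
        data[:, sl] = (seg - mu) / sd
    out = ds.with_data(data, f"match_zscore(n_per_layer={n_keep})",
                       voxel_index=ds.voxel_index[keep])
    return out


def regress_out_middle(ds: Dataset, layer_id: np.ndarray, positions: np.ndarray,
                       k_neighbors: int = 3) -> Dataset:
    """Spatial draining-vein control: regress the mean time course of each
    superficial voxel's k nearest middle-layer voxels out of that voxel.

    ``layer_id`` and ``positions`` (mm) align with the rows of ``ds``;
    deeper and middle voxels pass through unchanged.
    """
    mid = np.flatnonzero(layer_id == 1)
    sup = np.flatnonzero(layer_id == 2)
    if mid.size == 0 or sup.size == 0:
        raise ValueError("spatial regression needs non-empty middle and "
                         "superficial layers")
    k = k_neighbors
    if k > mid.size:
        warnings.warn(f"k_neighbors={k_neighbors} exceeds middle-layer count "
                      f"{mid.size}; clamping")
        k = mid.size
    tree = cKDTree(positions[mid])
    _, nn = tree.query(positions[sup], k=k)
    nn = np.atleast_2d(nn.T).T  # k=1 returns 1-D

    out = ds.data.copy()
    for i, v in enumerate(sup):
        ref = ds.data[mid[nn[i]]].mean(axis=0)
        x = np.column_stack([np.ones_like(ref), ref])
        out[v] = _ols_residuals(x, ds.data[v][:, None]).ravel()
    return ds.with_data(out, f"regress_out_middle(k={k})")


def block_responses(ds: Dataset, design: BlockDesign,
                    window_trs: tuple[int, int] = (3, 7)) -> BlockPatterns:
    """Average each block's response over the 3rd-7th TR after onset.

    The window is 1-based and inclusive: TRs 3..7 after onset are 0-based
    offsets 2..6, i.e. 4-14 s at TR = 2 s, which absorbs the ~2 TR
    haemodynamic delay and the response to the last stimulus of the block.
    """
    lo, hi = window_trs
    offsets = np.arange(lo - 1, hi)
    if (design.block_onsets.max() + offsets.max()) >= ds.n_trs:
        raise ValueError("block window exceeds the end of the time series")
    resp = np.stack([ds.data[:, design.block_onsets + o] for o in offsets])
    responses = resp.mean(axis=0).T  # block x voxel
    return BlockPatterns(responses=responses, label=design.disparity.copy(),
                         stereo=design.stereo.copy(), run_id=design.run_id.copy(),
                         onset_tr=design.block_onsets.copy(),
                         voxel_index=ds.voxel_index.copy(), area=ds.area)


def layer_profile(before: Dataset, after: Dataset, layer_before: np.ndarray,
                  layer_after: np.ndarray, design: BlockDesign) -> pd.DataFrame:
    """Mean block-window response per layer, before vs after correction.

    The per-voxel response is the block-window mean minus the voxel's run
    mean (removing the baseline), averaged over blocks, then over the
    voxels of each layer.  Feeds the before/after repeated-measures ANOVA.
    """
    from .core import LAYER_NAMES

    rows = []
    for state, ds, lid in (("before", before, layer_before),
                           ("after", after, layer_after)):
        demeaned = ds.data.copy()
        for sl in ds.run_slices():
            demeaned[:, sl] -= demeaned[:, sl].mean(axis=1, keepdims=True)
        tmp = Dataset(data=demeaned, tr=ds.tr, run_starts=ds.run_starts,
                      area=ds.area, voxel_index=ds.voxel_index)
        bp = block_responses(tmp, design)
        per_voxel = bp.responses.mean(axis=0)
        for l, name in enumerate(LAYER_NAMES):
            sel = lid == l
            if not sel.any():
                raise ValueError(f"layer {name} empty in state {state}")
            rows.append({"area": ds.area, "layer": name, "state": state,
                         "response": per_voxel[sel].mean()})
    return pd.DataFrame(rows)
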