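"""Cross-validated linear discriminant contrast (LDC).

Per leave-one-run-out fold: the near-minus-far mean pattern difference of
the training blocks is whitened by the (shrinkage-regularised) covariance
of the training runs' GLM noise residuals to give a weights vector
``w = Sigma^-1 delta_train``; the fold's LDC is the dot product
``delta_test . w``.  Because the two contrast estimates come from
independent data, the statistic is centred on zero when there is no
reliable near/far difference, unlike decoding accuracy which is bounded
below by chance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import BlockPatterns


def shrinkage_covariance(x: np.ndarray,
                         shrinkage: float | None = None) -> tuple[np.ndarray, float]:
    """Shrinkage of the sample covariance toward its diagonal.

    ``x`` is obs x variables.  Unless ``shrinkage`` is given, the
    intensity for the off-diagonal entries is the Schaefer-Strimmer
    analytic estimate ``lambda* = sum Var(s_ij) / sum s_ij^2`` (i != j),
    clipped to [0, 1].  Returns (covariance, lambda).
    """
    x = np.asarray(x, dtype=float)
    n, p = x.shape
    if n < 2:
        raise ValueError("need >= 2 observations for a covariance")
    xc = x - x.mean(axis=0)
    s = xc.T @ xc / (n - 1)
    if p == 1:
        return s, 0.0
    if shrinkage is None:
        # Var(s_ij) ~ n/(n-1)^3 sum_k (w_kij - mean_k w_kij)^2, w_kij = x_ki x_kj
        w_bar = xc.T @ xc / n
        w2_sum = (xc**2).T @ (xc**2)
        var_s = n / (n - 1) ** 3 * (w2_sum - n * w_bar**2)
        off_sum = (s**2).sum() - (np.diag(s) ** 2).sum()
        lam = (1.0 if off_sum == 0 else
               float(np.clip((var_s.sum() - np.trace(var_s)) / off_sum, 0.0, 1.0)))
    else:
        lam = float(shrinkage)
    off = ~np.eye(p, dtype=bool)
    sigma = s.copy()
    sigma[off] *= 1.0 - lam
    return sigma, lam


@dataclass
class LDCResult:
    """Cross-validated LDC for one (area, layer, stereo) cell."""

    ldc: float
    fold_values: np.ndarray
    shrinkage: np.ndarray       # lambda per fold

    def __post_init__(self):
        if not np.isfinite(self.ldc):
            raise ValueError("non-finite LDC")


def _class_contrast(patterns: BlockPatterns, mask: np.ndarray) -> np.ndarray:
    near = patterns.responses[mask & (patterns.label == "near")]
    far = patterns.responses[mask & (patterns.label == "far")]
    if near.shape[0] == 0 or far.shape[0] == 0:
        raise ValueError("a fold misses one disparity class")
    return near.mean(axis=0) - far.mean(axis=0)


def ldc_crossvalidated(patterns: BlockPatterns, residuals: np.ndarray,
                       run_slices: list[slice],
                       shrinkage: float | None = None) -> LDCResult:
    """Leave-one-run-out LDC for one stereo condition.

    ``residuals`` are GLM noise residuals (voxel x TR) with rows aligned
    to the pattern voxels; the noise covariance is estimated from the
    *training* runs' residual TRs only.  ``shrinkage`` overrides the
    analytic intensity (mainly for tests).
    """
    if len(np.unique(patterns.stereo)) != 1:
        raise ValueError("compute LDC one stereo condition at a time")
    if residuals.shape[0] != patterns.n_voxels:
        raise ValueError("residual rows must align with pattern voxels")
    runs = np.unique(patterns.run_id)
    if runs.size < 2:
        raise ValueError("leave-one-run-out needs >= 2 runs")

    fold_vals, lams = [], []
    for r in runs:
        test = patterns.run_id == r
        delta_train = _class_contrast(patterns, ~test)
        delta_test = _class_contrast(patterns, test)
        train_trs = np.concatenate(
            [np.arange(sl.start, sl.stop) for i, sl in enumerate(run_slices)
             if i != r])
        resid = residuals[:, train_trs].T
        sigma, lam = shrinkage_covariance(resid, shrinkage=shrinkage)
        cond = np.linalg.cond(sigma)
        if not np.isfinite(cond) or cond > 1e12:
            raise ValueError(f"noise covariance ill-conditioned (cond={cond:.3g})")
        w = np.linalg.solve(sigma, delta_train)
        fold_vals.append(float(delta_test @ w))
        lams.append(lam)
    return LDCResult(ldc=float(np.mean(fold_vals)),
                     fold_values=np.asarray(fold_vals),
                     shrinkage=np.asarray(lams))


def ldc_table(results: dict) -> pd.DataFrame:
    """Long-format (area, layer, stereo) -> LDC table for the group ANOVA.

    ``results`` maps (area, layer, stereo) to an :class:`LDCResult` (or a
    bare float); the factorial must be complete.
    """
    from .core import LAYER_NAMES, STEREO_CONDITIONS

    areas = sorted({k[0] for k in results})
    missing = [(a, l, s) for a in areas for l in LAYER_NAMES
               for s in STEREO_CONDITIONS if (a, l, s) not in results]
    if missing:
        raise ValueError(f"incomplete LDC factorial; missing cells: {missing}")
    rows = [{"area": a, "layer": l, "stereo": s,
             "ldc": (v.ldc if isinstance(v, LDCResult) else float(v))}
            for (a, l, s), v in results.items()]
    return pd.DataFrame(rows).sort_values(["area", "layer", "stereo"],
                                          ignore_index=True)
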