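"""Layer-resolved near-vs-far decoding.

A linear soft-margin SVM (LIBSVM via scikit-learn, C = 1, no scaling
beyond the pipeline's z-scoring) is trained with leave-one-run-out
cross-validation, separately within each stereo condition.  Signed
distances to the hyperplane are stored per test block (positive = "near"
side); a block exactly on the hyperplane counts as incorrect.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.svm import SVC

from .core import BlockPatterns
from .preprocess import GLMResult


def select_voxels(glm: GLMResult, layer_id: np.ndarray, n: int = 175) -> dict:
    """Top-``n`` voxels per layer by stimulus-vs-baseline t.

    The ranking contrast is label-agnostic (stimulus vs fixation), so the
    same selection is used in every cross-validation fold without leaking
    the near/far label.  Ties are broken by voxel row index.  Returns a
    dict layer index -> row positions.
    """
    out = {}
    for l in range(3):
        rows = np.flatnonzero(layer_id == l)
        if rows.size < n:
            raise ValueError(
                f"layer {l} has {rows.size} voxels < n={n}; "
                f"choose n <= {rows.size}")
        order = np.lexsort((rows, -glm.t_map[rows]))
        out[l] = rows[order[:n]]
    return out


@dataclass
class DecodingResult:
    """Leave-one-run-out decoding outcome for one (area, layer, stereo) cell."""

    accuracy: float
    fold_accuracies: np.ndarray
    distances: np.ndarray       # signed, aligned with the input block order
    fold_of_block: np.ndarray
    n_voxels: int
    C: float


def _check_folds(y: np.ndarray, runs: np.ndarray):
    uruns = np.unique(runs)
    if uruns.size < 2:
        raise ValueError("leave-one-run-out needs >= 2 runs")
    for r in uruns:
        train = runs != r
        if len(np.unique(y[train])) < 2:
            raise ValueError(f"training fold excluding run {r} misses a class")
    return uruns


def _cv_distances(x: np.ndarray, y: np.ndarray, runs: np.ndarray,
                  C: float) -> tuple[np.ndarray, np.ndarray]:
    """Signed hyperplane distances per block (positive = class 1) and the
    fold (held-out run) each block was tested in."""
    uruns = _check_folds(y, runs)
    dist = np.empty(len(y))
    fold = np.empty(len(y), dtype=int)
    for r in uruns:
        test = runs == r
        clf = SVC(kernel="linear", C=C)
        clf.fit(x[~test], y[~test])
        d = clf.decision_function(x[test])
        if clf.classes_[1] != 1:  # keep positive = "near" side
            d = -d
        dist[test] = d
        fold[test] = r
    return dist, fold


def accuracy_from_distances(dist: np.ndarray, y: np.ndarray,
                            runs: np.ndarray) -> tuple[float, np.ndarray]:
    """Fold-mean accuracy; distance 0 counts as incorrect."""
    correct = np.where(dist > 0, y == 1, np.where(dist < 0, y == 0, False))
    folds = np.unique(runs)
    per_fold = np.array([correct[runs == r].mean() for r in folds])
    return float(per_fold.mean()), per_fold


def crossval_decode(patterns: BlockPatterns, C: float = 1.0) -> DecodingResult:
    """Leave-one-run-out near-vs-far decoding of one stereo condition."""
    if len(np.unique(patterns.stereo)) != 1:
        raise ValueError("decode one stereo condition at a time "
                         "(use patterns.for_stereo)")
    y = (patterns.label == "near").astype(int)
    dist, fold = _cv_distances(patterns.responses, y, patterns.run_id, C)
    acc, per_fold = accuracy_from_distances(dist, y, patterns.run_id)
    return DecodingResult(accuracy=acc, fold_accuracies=per_fold,
                          distances=dist, fold_of_block=fold,
                          n_voxels=patterns.n_voxels, C=C)


def permutation_null(patterns: BlockPatterns, n_perm: int = 5000,
                     seed: int = 0, C: float = 1.0):
    """Label-shuffled null distribution of the CV accuracy.

    Labels are permuted within run (preserving the run structure), the
    full leave-one-run-out decode is re-run per permutation, and
    ``p = (1 + #{null >= observed}) / (1 + n_perm)``.
    """
    if n_perm < 100:
        warnings.warn("n_perm < 100 gives unstable permutation p-values")
    rng = np.random.default_rng(seed)
    observed = crossval_decode(patterns, C=C).accuracy
    y = (patterns.label == "near").astype(int)
    runs = patterns.run_id
    null = np.empty(n_perm)
    run_rows = {r: np.flatnonzero(runs == r) for r in np.unique(runs)}
    for i in range(n_perm):
        y_perm = y.copy()
        for rows in run_rows.values():
            y_perm[rows] = y[rng.permutation(rows)]
        try:
            dist, _ = _cv_distances(patterns.responses, y_perm, runs, C)
            null[i], _ = accuracy_from_distances(dist, y_perm, runs)
        except ValueError:  # a permutation emptied a class in some fold
            null[i] = np.nan
    valid = null[~np.isnan(null)]
    p = (1 + (valid >= observed).sum()) / (1 + valid.size)
    return observed, valid, float(p)


def regress_mean_pattern(patterns: BlockPatterns) -> BlockPatterns:
    """Univariate control: remove each block's across-voxel mean response,
    leaving only the multi-voxel pattern component."""
    if patterns.n_voxels < 2:
        raise ValueError("mean-pattern regression needs >= 2 voxels")
    resp = patterns.responses - patterns.responses.mean(axis=1, keepdims=True)
    return BlockPatterns(resp, patterns.label, patterns.stereo, patterns.run_id,
                         patterns.onset_tr, patterns.voxel_index, patterns.area,
                         patterns.layer)
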