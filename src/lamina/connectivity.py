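"""Informational connectivity between cortical layers of different areas.

The signed hyperplane distance of each test block indexes how
discriminable that block's near/far pattern was.  Distances are oriented
toward the correct class (distance x label sign, so larger = more
discriminable), concatenated across leave-one-run-out folds in block
order, and the resulting per-layer series are compared between areas by
Spearman rank correlation, Fisher z-transformed.

Pathway tables follow the laminar circuit convention: feedforward =
superficial layer of the lower area with the middle layer of the higher
area; feedback = deeper layer with deeper layer.  Superficial-to-deeper
pairs are ambiguous between the two pathways and are never emitted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .decode import DecodingResult

logger = logging.getLogger(__name__)

AREA_PAIRS = [("A1", "A3A"), ("A3A", "A7"), ("A1", "A7")]


@dataclass
class DistanceSeries:
    """Correct-class-oriented hyperplane distance per block, in onset order."""

    values: np.ndarray
    block_onsets: np.ndarray
    area: str
    layer: str
    stereo: str

    def __len__(self) -> int:
        return len(self.values)


def build_distance_series(decoding: DecodingResult, patterns) -> DistanceSeries:
    """Orient a decode's distances toward the correct class and order them
    by block onset across folds."""
    sign = np.where(patterns.label == "near", 1.0, -1.0)
    oriented = decoding.distances * sign
    order = np.argsort(patterns.onset_tr, kind="stable")
    return DistanceSeries(values=oriented[order],
                          block_onsets=patterns.onset_tr[order],
                          area=patterns.area, layer=patterns.layer,
                          stereo=str(patterns.stereo[0]))


def informational_connectivity(a: DistanceSeries,
                               b: DistanceSeries) -> tuple[float, float]:
    """Spearman correlation (average ranks for ties) between two distance
    series and its Fisher z transform.  Returns (nan, nan) for a constant
    series."""
    if len(a) != len(b):
        raise ValueError("distance series differ in length")
    if len(a) < 5:
        raise ValueError("need >= 5 blocks to correlate")
    if a.stereo != b.stereo:
        raise ValueError("series come from different stereo conditions")
    if np.ptp(a.values) == 0 or np.ptp(b.values) == 0:
        logger.warning("constant distance series (%s/%s vs %s/%s); "
                       "correlation undefined", a.area, a.layer, b.area, b.layer)
        return float("nan"), float("nan")
    if not np.array_equal(a.block_onsets, b.block_onsets):
        raise ValueError("series cover different block sets")
    rho = float(spearmanr(a.values, b.values).statistic)
    z = float(np.arctanh(np.clip(rho, -1 + 1e-12, 1 - 1e-12)))
    return rho, z


def pathway_contrast(series: dict) -> dict[str, pd.DataFrame]:
    """Feedforward and feedback connectivity tables.

    ``series`` maps (area, layer, stereo) to a :class:`DistanceSeries`.
    Returns ``{"feedforward": df, "feedback": df}`` with one row per
    (area pair, stereo): columns area_pair, lower/higher layer, stereo,
    rho, z, n_blocks.
    """
    stereos = sorted({k[2] for k in series})
    layer_pairs = {"feedforward": ("superficial", "middle"),
                   "feedback": ("deeper", "deeper")}
    out = {}
    for pathway, (layer_lo, layer_hi) in layer_pairs.items():
        rows = []
        for lo, hi in AREA_PAIRS:
            for stereo in stereos:
                ka, kb = (lo, layer_lo, stereo), (hi, layer_hi, stereo)
                if ka not in series or kb not in series:
                    raise ValueError(f"missing distance series for pair "
                                     f"{lo}-{hi} ({pathway}, {stereo})")
                rho, z = informational_connectivity(series[ka], series[kb])
                rows.append({"area_pair": f"{lo}-{hi}", "lower_layer": layer_lo,
                             "higher_layer": layer_hi, "pathway": pathway,
                             "stereo": stereo, "rho": rho, "z": z,
                             "n_blocks": len(series[ka])})
        out[pathway] = pd.DataFrame(rows)
    return out
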