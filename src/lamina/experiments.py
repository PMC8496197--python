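"""Headline recovery experiments on synthetic ground truth.

Each function runs one self-contained experiment at the study's default
conditions and returns the quantities a report would print.  They are the
backbone of the numbered drivers under ``analysis/`` and of
``scripts/acceptance.py``; problem sizes are chosen so the full set runs
on a laptop in minutes (see docs/methods.md).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.integrate import quad
from scipy.optimize import brentq

from . import decode as dec
from . import preprocess as pre
from .connectivity import AREA_PAIRS
from .core import LAYER_NAMES
from .layers import equivolume_fraction
from .ldc import ldc_crossvalidated
from .pipeline import PipelineConfig, analyze_subject, run_experiment
from .stats import fdr_bh, paired_t
from .synthdata import (EffectSpec, generate_cortical_patch, generate_design,
                        simulate_bold)

logger = logging.getLogger(__name__)


def _sub_seeds(seed: int, n: int) -> list[int]:
    return [int(s.generate_state(1)[0]) % 2**31
            for s in np.random.SeedSequence(seed).spawn(n)]


def design_arithmetic() -> dict:
    """Run length implied by the printed design parameters."""
    design = generate_design(2, tr=2.0, blocks_per_condition=10,
                             block_duration=12.0, fixation_duration=12.0,
                             seed=0)
    return {"run_duration_s": design.run_duration_s,
            "trs_per_run": design.run_trs}


def equivolume_oracle_error(seed: int = 0, n_draws: int = 1000) -> dict:
    """Closed-form equi-volume depths vs numerical inversion of the
    linear-area wedge volume integral, over random curvatures."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_draws):
        a_w, a_p = rng.uniform(0.2, 5.0, size=2)
        alpha = rng.uniform(0.0, 1.0)
        closed = equivolume_fraction(alpha, a_w, a_p)

        def area(t, a_w=a_w, a_p=a_p):
            return a_w + (a_p - a_w) * t

        total = quad(area, 0, 1)[0]
        numeric = (alpha if alpha in (0.0, 1.0) else
                   brentq(lambda x: quad(area, 0, x)[0] - alpha * total,
                          0.0, 1.0, xtol=1e-13))
        worst = max(worst, abs(closed - numeric))
    flat = np.abs(equivolume_fraction(np.linspace(0, 1, 11), 1.0, 1.0)
                  - np.linspace(0, 1, 11)).max()
    return {"max_abs_error": worst, "zero_curvature_error": flat,
            "n_draws": n_draws}


def _null_patterns(seed: int, n_columns: int = 15, runs: int = 4):
    model = generate_cortical_patch(n_columns, 9, seed=seed, areas=("A1",))
    design = generate_design(runs, seed=seed + 1)
    spec = EffectSpec(seed=seed + 2, vein_fraction=0.0)
    datasets, _ = simulate_bold(model, design, spec)
    ds = pre.highpass_and_detrend(datasets["A1"])
    data = ds.data.copy()
    for sl in ds.run_slices():
        seg = data[:, sl]
        data[:, sl] = (seg - seg.mean(1, keepdims=True)) / seg.std(1, keepdims=True)
    glm = pre.fit_glm(ds, design)
    bp = pre.block_responses(ds.with_data(data, "zscore"), design)
    return bp.for_stereo("correlated"), glm, ds.run_slices()


def permutation_calibration(seed: int = 0, n_perm: int = 1000) -> dict:
    """Mean label-shuffled leave-one-run-out accuracy on null patterns."""
    bp, _, _ = _null_patterns(seed)
    _, null, _ = dec.permutation_null(bp, n_perm=n_perm, seed=seed + 10)
    return {"mean_accuracy": float(null.mean()), "n_perm": int(null.size)}


def ldc_null_centring(seed: int = 0, n_datasets: int = 200) -> dict:
    """Cross-validated LDC over many null simulations: mean and 2 SEM."""
    vals = []
    for s in _sub_seeds(seed, n_datasets):
        model = generate_cortical_patch(10, 9, seed=s, areas=("A1",))
        design = generate_design(3, blocks_per_condition=5, seed=s + 1)
        spec = EffectSpec(seed=s + 2, vein_fraction=0.0)
        datasets, _ = simulate_bold(model, design, spec)
        ds = pre.highpass_and_detrend(datasets["A1"])
        glm = pre.fit_glm(ds, design)
        data = ds.data.copy()
        for sl in ds.run_slices():
            seg = data[:, sl]
            data[:, sl] = ((seg - seg.mean(1, keepdims=True))
                           / seg.std(1, keepdims=True))
        bp = pre.block_responses(ds.with_data(data, "zscore"),
                                 design).for_stereo("correlated")
        vals.append(ldc_crossvalidated(bp, glm.residuals, ds.run_slices()).ldc)
    vals = np.asarray(vals)
    sem = float(vals.std(ddof=1) / np.sqrt(len(vals)))
    return {"mean_ldc": float(vals.mean()), "sem": sem,
            "n_datasets": len(vals)}


def vascular_correction_recovery(seed: int = 0, n_seeds: int = 20) -> dict:
    """Vein-voxel exclusion rate and superficial-bias gap reduction under
    the default vascular confounds (gain slope 1, 5% veins)."""
    cfg = PipelineConfig(signal_cells=[], coupling=[], n_columns_per_area=40)
    vein_rates, ratios = [], []
    for s in _sub_seeds(seed, n_seeds):
        res = analyze_subject(cfg, seed=s, n_runs=4)
        vein_rates.append(res.vein_recovery)
        prof = res.profile[res.profile.area == "A3A"].pivot_table(
            index="layer", columns="state", values="response")
        gap = prof.loc["superficial"] - prof.loc["deeper"]
        ratios.append(abs(gap["after"]) / abs(gap["before"]))
    ratios = np.asarray(ratios)
    return {"vein_exclusion_pct": 100 * float(np.mean(vein_rates)),
            "gap_ratio_pct": 100 * float(np.mean(ratios)),
            "seeds_below_half": int((ratios < 0.5).sum()),
            "n_seeds": n_seeds}


CONNECTIVITY_AMPLITUDE = 0.4  # strong pattern signal so block-wise
                              # discriminability, not noise, drives distances


def connectivity_recovery(seed: int = 0, n_seeds: int = 20) -> dict:
    """Recovery of the injected feedforward coupling (A3A superficial ->
    A7 middle, correlated, rho_true = 0.5)."""
    cfg = PipelineConfig(pattern_amplitude=CONNECTIVITY_AMPLITUDE)
    wins = 0
    rhos = {}
    for s in _sub_seeds(seed, n_seeds):
        res = analyze_subject(cfg, seed=s, n_runs=6)
        ff = res.connectivity["feedforward"]
        for _, row in ff.iterrows():
            rhos.setdefault((row.area_pair, row.stereo), []).append(row.rho)
        pair = ff[ff.area_pair == "A3A-A7"].set_index("stereo")
        wins += bool(pair.loc["correlated", "z"]
                     > pair.loc["anti-correlated", "z"])
    coupled = ("A3A-A7", "correlated")
    uncoupled = {k: float(np.mean(v)) for k, v in rhos.items() if k != coupled}
    return {"coupled_mean_rho": float(np.mean(rhos[coupled])),
            "uncoupled_max_abs_mean_rho": max(abs(v) for v in uncoupled.values()),
            "direction_wins": wins, "n_seeds": n_seeds}


def _experiment_recovers_pattern(rep) -> dict:
    """Score one group experiment against the injected ground truth:
    above-chance decoding in the correlated upper layers of A3A/A7,
    chance for anti-correlated everywhere (FDR across cells), and a
    condition x depth interaction in A3A and A7 but not A1."""
    acc = rep.accuracy
    inter_p = {}
    for area in ("A1", "A3A", "A7"):
        t = rep.anovas[f"accuracy_{area}"]
        inter_p[area] = float(t[t.effect == "stereo x layer"]
                              .iloc[0].p_reported)

    signal_ps = []
    for area in ("A3A", "A7"):
        for layer in ("middle", "superficial"):
            cell = acc[(acc.area == area) & (acc.layer == layer)
                       & (acc.stereo == "correlated")]
            t, _, p = paired_t(cell.accuracy,
                               np.full(len(cell), 0.5))
            signal_ps.append(p / 2 if t > 0 else 1 - p / 2)  # one-sided
    anti_ps = []
    for (area, layer), cell in acc[acc.stereo == "anti-correlated"].groupby(
            ["area", "layer"]):
        t, _, p = paired_t(cell.accuracy, np.full(len(cell), 0.5))
        anti_ps.append(p / 2 if t > 0 else 1 - p / 2)
    anti_adj = fdr_bh(anti_ps)
    return {
        "signal_above_chance": bool(max(signal_ps) < 0.05),
        "anti_at_chance": bool(min(anti_adj) >= 0.05),
        "interaction_pattern": bool(inter_p["A3A"] < 0.05
                                    and inter_p["A7"] < 0.05
                                    and inter_p["A1"] >= 0.05),
        "interaction_p": inter_p,
    }


def layer_effect_recovery(seed: int = 0, n_experiments: int = 10) -> dict:
    """Full-pipeline ground-truth recovery: n_experiments independent
    7-subject group experiments at the default study conditions."""
    recovered = 0
    sig_acc, anti_acc = [], []
    for s in _sub_seeds(seed, n_experiments):
        rep = run_experiment(PipelineConfig(seed=s))
        score = _experiment_recovers_pattern(rep)
        recovered += (score["signal_above_chance"] and score["anti_at_chance"]
                      and score["interaction_pattern"])
        acc = rep.accuracy
        sig_acc.append(acc[(acc.stereo == "correlated")
                           & (acc.layer != "deeper")
                           & (acc.area != "A1")].accuracy.mean())
        anti_acc.append(acc[acc.stereo == "anti-correlated"].accuracy.mean())
        logger.info("experiment seed %d: %s", s, score)
    return {"experiments_recovered": recovered,
            "n_experiments": n_experiments,
            "signal_cell_accuracy_pct": 100 * float(np.mean(sig_acc)),
            "anticorrelated_accuracy_pct": 100 * float(np.mean(anti_acc))}
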