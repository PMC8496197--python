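"""End-to-end orchestration: simulate -> layers -> preprocess -> decode /
LDC -> connectivity -> group statistics.

Defaults mirror the study's analysis constants: ROI preselection at
t = 1.53, tSNR cut at mean - 2 SD, high-t cut at the 90th percentile,
175 voxels per layer, linear SVM with C = 1, block window TRs 3-7,
Greenhouse-Geisser correction for epsilon < 0.75, 7 simulated subjects
with 4-6 runs each.  The default effect places disparity information in
the superficial and middle layers of the A3A and A7 analogues for
correlated stimuli only, with a feedforward coupling
(A3A superficial -> A7 middle, correlated) - the qualitative ground-truth
pattern the group analyses are expected to recover.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import connectivity as conn
from . import decode as dec
from . import ldc as ldcmod
from . import preprocess as pre
from . import stats
from .core import LAYER_NAMES, STEREO_CONDITIONS
from .layers import assign_voxels, build_grids
from .synthdata import (BlockDesign, Coupling, EffectSpec,
                        generate_cortical_patch, generate_design, simulate_bold)

logger = logging.getLogger(__name__)

DEFAULT_SIGNAL_CELLS = [["A3A", "superficial", "correlated"],
                        ["A3A", "middle", "correlated"],
                        ["A7", "superficial", "correlated"],
                        ["A7", "middle", "correlated"]]
DEFAULT_COUPLING = [{"source": ["A3A", "superficial"],
                     "target": ["A7", "middle"],
                     "stereo": "correlated", "rho": 0.5}]


@dataclass
class PipelineConfig:
    """All tunable parameters of the pipeline (defaults = study values)."""

    # experiment
    n_subjects: int = 7
    runs_choices: list = field(default_factory=lambda: [4, 5, 6])
    seed: int = 0
    # geometry
    n_columns_per_area: int = 80
    voxels_per_column: int = 9
    curvature_range: list = field(default_factory=lambda: [0.5, 2.0])
    areas: list = field(default_factory=lambda: ["A1", "A3A", "A7"])
    # design
    tr: float = 2.0
    blocks_per_condition: int = 10
    block_duration: float = 12.0
    fixation_duration: float = 12.0
    # generative effect
    pattern_amplitude: float = 0.08
    signal_cells: list = field(default_factory=lambda:
                               [list(c) for c in DEFAULT_SIGNAL_CELLS])
    evoked_amplitude: float = 1.0
    superficial_gain_slope: float = 1.0
    leak_fraction: float = 0.0
    vein_fraction: float = 0.05
    vein_noise_mult: float = 3.0
    vein_amp_mult: float = 2.0
    noise_sd: float = 1.0
    physio_ar1: float = 0.3
    coupling: list = field(default_factory=lambda:
                           [dict(c) for c in DEFAULT_COUPLING])
    coupling_gain_sd: float = 0.5
    # analysis
    highpass_cycles: int = 2
    t_preselect: float = 1.53
    tsnr_sd_mult: float = 2.0
    t_cut_percentile: float = 90.0
    match_method: str = "top_t"
    window_trs: list = field(default_factory=lambda: [3, 7])
    n_voxels: int = 175
    svm_C: float = 1.0
    spatial_regression: bool = False
    k_neighbors: int = 3
    n_permutations: int = 5000
    run_permutation_null: bool = False

    def __post_init__(self):
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if self.n_voxels < 1:
            raise ValueError("n_voxels must be >= 1")
        if min(self.runs_choices) < 2:
            raise ValueError("runs_choices entries must be >= 2")
        if self.pattern_amplitude < 0:
            raise ValueError("pattern_amplitude must be >= 0")

    def effect_spec(self, seed: int) -> EffectSpec:
        amplitudes = {tuple(c): self.pattern_amplitude
                      for c in self.signal_cells}
        coupling = [Coupling(source=tuple(c["source"]),
                             target=tuple(c["target"]),
                             stereo=c["stereo"], rho=float(c["rho"]))
                    for c in self.coupling]
        return EffectSpec(pattern_amplitude=amplitudes,
                          evoked_amplitude=self.evoked_amplitude,
                          superficial_gain_slope=self.superficial_gain_slope,
                          leak_fraction=self.leak_fraction,
                          vein_fraction=self.vein_fraction,
                          vein_noise_mult=self.vein_noise_mult,
                          vein_amp_mult=self.vein_amp_mult,
                          noise_sd=self.noise_sd,
                          physio_ar1=self.physio_ar1,
                          coupling=coupling,
                          coupling_gain_sd=self.coupling_gain_sd,
                          seed=seed)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()).hexdigest()[:12]


def validate_config(path) -> PipelineConfig:
    """Load a YAML config file, fill defaults, reject unknown keys."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ValueError("config file must hold a mapping")
    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return PipelineConfig(**raw)


def write_config(config: PipelineConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(config.to_dict(), sort_keys=True))


@dataclass
class SubjectResult:
    """Per-subject analysis tables (long format)."""

    accuracy: pd.DataFrame      # area, layer, stereo, accuracy
    ldc: pd.DataFrame           # area, layer, stereo, ldc
    profile: pd.DataFrame       # area, layer, state, response
    connectivity: dict          # pathway -> table
    vein_recovery: float        # fraction of true vein voxels excluded
    n_runs: int


def analyze_subject(config: PipelineConfig, seed: int,
                    n_runs: int | None = None,
                    spec: EffectSpec | None = None) -> SubjectResult:
    """Simulate one subject and run the full laminar analysis."""
    ss = np.random.SeedSequence(seed)
    s_geom, s_design, s_effect, s_runs = [int(s.generate_state(1)[0]) % 2**31
                                          for s in ss.spawn(4)]
    if n_runs is None:
        rng = np.random.default_rng(s_runs)
        n_runs = int(rng.choice(config.runs_choices))
    model = generate_cortical_patch(config.n_columns_per_area,
                                    config.voxels_per_column,
                                    tuple(config.curvature_range),
                                    tuple(config.areas), seed=s_geom)
    design = generate_design(n_runs, tr=config.tr,
                             blocks_per_condition=config.blocks_per_condition,
                             block_duration=config.block_duration,
                             fixation_duration=config.fixation_duration,
                             seed=s_design)
    if spec is None:
        spec = config.effect_spec(s_effect)
    datasets, gt = simulate_bold(model, design, spec)
    grids = build_grids(model)
    assignment = assign_voxels(model, grids)

    acc_rows, ldc_results, profile_rows = [], {}, []
    series = {}
    vein_excluded = vein_total = 0
    for area in config.areas:
        raw = datasets[area]
        layer_id = assignment.layer_id[raw.voxel_index]
        filtered = pre.highpass_and_detrend(raw, config.highpass_cycles)
        glm = pre.fit_glm(filtered, design)
        mask = pre.vascular_exclusion(raw, glm, config.tsnr_sd_mult,
                                      config.t_cut_percentile)
        pres = np.zeros(raw.n_voxels, dtype=bool)
        pres[pre.roi_voxel_preselect(glm, config.t_preselect)] = True
        mask.keep_flag &= pres

        true_veins = np.isin(raw.voxel_index, gt.vein_voxels)
        vein_total += true_veins.sum()
        vein_excluded += (true_veins & ~mask.keep_flag).sum()

        corrected = pre.match_and_zscore(filtered, layer_id, mask, glm,
                                         method=config.match_method,
                                         seed=seed)
        kept = np.isin(raw.voxel_index, corrected.voxel_index)
        layer_kept = layer_id[kept]
        if config.spatial_regression:
            positions = model.voxel_positions[corrected.voxel_index]
            corrected = pre.regress_out_middle(corrected, layer_kept,
                                               positions, config.k_neighbors)

        raw_kept = raw.with_data(raw.data[kept], "subset", raw.voxel_index[kept])
        profile_rows.append(pre.layer_profile(raw_kept, corrected, layer_kept,
                                              layer_kept, design))

        glm_corr = pre.fit_glm(corrected, design)
        patterns = pre.block_responses(corrected, design,
                                       tuple(config.window_trs))
        n_sel = min(config.n_voxels,
                    min(np.bincount(layer_kept, minlength=3)))
        selection = dec.select_voxels(glm_corr, layer_kept, n=n_sel)
        run_slices = corrected.run_slices()
        for l, layer in enumerate(LAYER_NAMES):
            cols = selection[l]
            for stereo in STEREO_CONDITIONS:
                bp = patterns.subset_voxels(cols, layer).for_stereo(stereo)
                res = dec.crossval_decode(bp, C=config.svm_C)
                acc_rows.append({"area": area, "layer": layer,
                                 "stereo": stereo, "accuracy": res.accuracy})
                ldc_results[(area, layer, stereo)] = ldcmod.ldc_crossvalidated(
                    bp, glm_corr.residuals[cols], run_slices)
                series[(area, layer, stereo)] = conn.build_distance_series(res, bp)

    pathway = conn.pathway_contrast(series)
    return SubjectResult(accuracy=pd.DataFrame(acc_rows),
                         ldc=ldcmod.ldc_table(ldc_results),
                         profile=pd.concat(profile_rows, ignore_index=True),
                         connectivity=pathway,
                         vein_recovery=(vein_excluded / vein_total
                                        if vein_total else float("nan")),
                         n_runs=n_runs)


@dataclass
class ExperimentReport:
    """Group-level report bundle of one simulated experiment."""

    config: PipelineConfig
    accuracy: pd.DataFrame
    ldc: pd.DataFrame
    profile: pd.DataFrame
    connectivity: dict
    anovas: dict                # name -> RMAnovaResult table
    subject_seeds: list

    def write(self, outdir) -> None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.accuracy.to_csv(out / "accuracy.tsv", sep="\t", index=False)
        self.ldc.to_csv(out / "ldc.tsv", sep="\t", index=False)
        self.profile.to_csv(out / "layer_profile.tsv", sep="\t", index=False)
        for pathway, df in self.connectivity.items():
            df.to_csv(out / f"connectivity_{pathway}.tsv", sep="\t", index=False)
        for name, table in self.anovas.items():
            table.to_csv(out / f"anova_{name}.tsv", sep="\t", index=False)
        write_config(self.config, out / "config.yaml")
        meta = {"config_hash": self.config.config_hash(),
                "subject_seeds": self.subject_seeds}
        (out / "provenance.json").write_text(json.dumps(meta, indent=1))


def group_anovas(accuracy: pd.DataFrame, ldc_df: pd.DataFrame,
                 profile: pd.DataFrame, connectivity: dict,
                 areas: list[str]) -> dict:
    """The group-level repeated-measures ANOVAs of the report."""
    anovas = {}
    anovas["accuracy_3way"] = stats.rm_anova(
        accuracy, "accuracy", ["stereo", "layer", "area"]).table
    for area in areas:
        anovas[f"accuracy_{area}"] = stats.rm_anova(
            accuracy[accuracy.area == area], "accuracy",
            ["stereo", "layer"]).table
        anovas[f"ldc_{area}"] = stats.rm_anova(
            ldc_df[ldc_df.area == area], "ldc", ["stereo", "layer"]).table
        anovas[f"profile_{area}"] = stats.rm_anova(
            profile[profile.area == area], "response",
            ["state", "layer"]).table
    for pathway, df in connectivity.items():
        anovas[f"connectivity_{pathway}"] = stats.rm_anova(
            df, "z", ["stereo", "area_pair"]).table
    return anovas


def run_experiment(config: PipelineConfig) -> ExperimentReport:
    """Simulate ``config.n_subjects`` subjects, analyse each, and compute
    the group statistics."""
    subject_seeds = [int(s.generate_state(1)[0]) % 2**31 for s in
                     np.random.SeedSequence(config.seed).spawn(config.n_subjects)]
    acc, ldc_t, prof = [], [], []
    conn_t = {"feedforward": [], "feedback": []}
    for i, seed in enumerate(subject_seeds):
        logger.info("subject %d/%d (seed %d)", i + 1, config.n_subjects, seed)
        res = analyze_subject(config, seed)
        for df_list, df in ((acc, res.accuracy), (ldc_t, res.ldc),
                            (prof, res.profile)):
            df = df.copy()
            df.insert(0, "subject", i)
            df_list.append(df)
        for pathway in conn_t:
            df = res.connectivity[pathway].copy()
            df.insert(0, "subject", i)
            conn_t[pathway].append(df)
    accuracy = pd.concat(acc, ignore_index=True)
    ldc_df = pd.concat(ldc_t, ignore_index=True)
    profile = pd.concat(prof, ignore_index=True)
    connectivity = {k: pd.concat(v, ignore_index=True)
                    for k, v in conn_t.items()}
    anovas = group_anovas(accuracy, ldc_df, profile, connectivity, config.areas)
    return ExperimentReport(config=config, accuracy=accuracy, ldc=ldc_df,
                            profile=profile, connectivity=connectivity,
                            anovas=anovas, subject_seeds=subject_seeds)
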