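"""Filtering, GLM, vascular exclusion, matching/z-scoring, spatial
regression, and block-response extraction."""

import numpy as np
import pandas as pd
import pytest

from lamina.core import Dataset
from lamina.layers import assign_voxels, build_grids
from lamina.preprocess import (block_responses, build_design_matrix,
                               compute_tsnr, fit_glm, highpass_and_detrend,
                               layer_profile, match_and_zscore,
                               regress_out_middle, roi_voxel_preselect,
                               vascular_exclusion)
from lamina.synthdata import EffectSpec, generate_design, simulate_bold
from lamina.synthdata import generate_cortical_patch

from conftest import zscore_per_run


def make_dataset(data, tr=2.0, runs=None):
    data = np.atleast_2d(np.asarray(data, dtype=float))
    runs = runs if runs is not None else [0]
    return Dataset(data=data, tr=tr, run_starts=np.asarray(runs), area="A1",
                   voxel_index=np.arange(data.shape[0]))


class TestHighpassDetrend:
    def test_removes_linear_trend(self):
        t = np.arange(252, dtype=float)
        ds = make_dataset(5.0 + 0.3 * t)
        out = highpass_and_detrend(ds)
        assert np.abs(out.data).max() < 1e-10 * np.abs(ds.data).max()

    def test_removes_two_cycle_sinusoid(self):
        t = np.arange(252)
        ds = make_dataset(np.sin(2 * np.pi * 2 * t / 252))
        out = highpass_and_detrend(ds)
        assert np.abs(out.data).max() < 1e-10

    def test_equals_explicit_ols_residual(self):
        rng = np.random.default_rng(0)
        n = 120
        y = rng.standard_normal((7, n))
        ds = make_dataset(y)
        out = highpass_and_detrend(ds, n_cycles=2)
        t = np.arange(n)
        x = np.column_stack([np.ones(n), t - t.mean(),
                             np.sin(2 * np.pi * t / n), np.cos(2 * np.pi * t / n),
                             np.sin(4 * np.pi * t / n), np.cos(4 * np.pi * t / n)])
        expected = (y.T - x @ np.linalg.pinv(x) @ y.T).T
        np.testing.assert_allclose(out.data, expected, atol=1e-10)

    def test_short_run_rejected(self):
        ds = make_dataset(np.zeros((1, 6)))
        with pytest.raises(ValueError):
            highpass_and_detrend(ds)

    def test_provenance_recorded(self):
        ds = make_dataset(np.random.default_rng(1).standard_normal((2, 60)))
        out = highpass_and_detrend(ds)
        assert out.applied_steps[-1].startswith("highpass_detrend")


class TestFitGLM:
    def test_recovers_amplitude_noiselessly(self, small_model, study_design):
        spec = EffectSpec(seed=1, evoked_amplitude=0.7, noise_sd=1e-10,
                          vein_fraction=0.0, superficial_gain_slope=0.0)
        datasets, _ = simulate_bold(small_model, study_design, spec)
        glm = fit_glm(datasets["A1"], study_design)
        contrast_est = glm.betas[:, :4].mean(axis=1)
        np.testing.assert_allclose(contrast_est, 0.7, atol=1e-6)

    def test_t_map_matches_bruteforce_formula(self, study_design):
        rng = np.random.default_rng(2)
        x, _ = build_design_matrix(study_design)
        y = rng.standard_normal((10, x.shape[0]))
        ds = make_dataset(y, runs=study_design.run_starts)
        glm = fit_glm(ds, study_design)
        c = np.zeros(x.shape[1])
        c[:4] = 0.25
        xtx_inv = np.linalg.inv(x.T @ x)
        for v in range(10):
            beta = xtx_inv @ x.T @ y[v]
            resid = y[v] - x @ beta
            sigma2 = resid @ resid / (len(y[v]) - np.linalg.matrix_rank(x))
            t = c @ beta / np.sqrt(sigma2 * c @ xtx_inv @ c)
            assert glm.t_map[v] == pytest.approx(t, abs=1e-8)

    def test_residuals_orthogonal_to_design(self, null_session, study_design):
        datasets, _, _ = null_session
        glm = fit_glm(datasets["A1"], study_design)
        scale = np.abs(datasets["A1"].data).max()
        assert np.abs(glm.design_matrix.T @ glm.residuals.T).max() < 1e-6 * scale

    def test_rank_deficient_design_named(self, study_design):
        n = study_design.n_trs
        nuis = np.ones((n, 1))  # collinear with the run intercepts
        ds = make_dataset(np.zeros((2, n)), runs=study_design.run_starts)
        with pytest.raises(ValueError, match="collinear"):
            fit_glm(ds, study_design, nuisance=nuis)


class TestRoiPreselect:
    def test_null_retention_fraction(self, study_design):
        """Under the null ~6.3% of voxels exceed t = 1.53 (the upper tail
        of the central t; the two-sided p of 1.53 is 0.125)."""
        model = generate_cortical_patch(380, 27, seed=12, areas=("A1",))
        spec = EffectSpec(seed=13, evoked_amplitude=0.0, vein_fraction=0.0,
                          physio_ar1=0.0, superficial_gain_slope=0.0)
        design = generate_design(2, seed=14)
        datasets, _ = simulate_bold(model, design, spec)
        glm = fit_glm(highpass_and_detrend(datasets["A1"]), design)
        frac = len(roi_voxel_preselect(glm, 1.53)) / model.n_voxels
        assert frac == pytest.approx(0.0625, abs=0.01)

    def test_minus_inf_keeps_all(self, null_session, study_design):
        datasets, _, _ = null_session
        glm = fit_glm(datasets["A1"], study_design)
        keep = roi_voxel_preselect(glm, -np.inf)
        assert len(keep) == datasets["A1"].n_voxels

    def test_strong_voxels_always_retained(self):
        rng = np.random.default_rng(0)
        design = generate_design(2, blocks_per_condition=5, seed=0)
        from lamina.preprocess import build_design_matrix
        x, _ = build_design_matrix(design)
        stim = x[:, :4].sum(axis=1)
        for seed in range(20):
            noise = np.random.default_rng(seed).standard_normal((10, design.n_trs))
            y = noise.copy()
            y[:3] += 5 * stim
            ds = make_dataset(y, runs=design.run_starts)
            keep = roi_voxel_preselect(fit_glm(ds, design), 1.53)
            assert {0, 1, 2} <= set(keep.tolist())

    def test_empty_selection_raises(self, null_session, study_design):
        datasets, _, _ = null_session
        glm = fit_glm(datasets["A1"], study_design)
        with pytest.raises(ValueError, match="no voxels"):
            roi_voxel_preselect(glm, np.inf)


class TestVascularExclusion:
    def test_percentile_share_removed(self, study_design):
        """Homogeneous data: the t-cut removes the top decile exactly."""
        rng = np.random.default_rng(3)
        y = 100 + rng.standard_normal((200, study_design.n_trs))
        ds = make_dataset(y, runs=study_design.run_starts)
        glm = fit_glm(ds, study_design)
        mask = vascular_exclusion(ds, glm, sd_mult=np.inf, t_percentile=90)
        assert mask.n_excluded == 20

    def test_vein_recovery(self, study_design):
        """Simulated large-vein voxels (noise x3, amplitude x2) are caught
        by the tSNR/t rules in >= 90% of cases."""
        rates = []
        for seed in range(20):
            model = generate_cortical_patch(40, 9, seed=seed, areas=("A1",))
            spec = EffectSpec(seed=seed + 100, vein_fraction=0.05)
            datasets, gt = simulate_bold(model, study_design, spec)
            ds = datasets["A1"]
            glm = fit_glm(highpass_and_detrend(ds), study_design)
            mask = vascular_exclusion(ds, glm)
            is_vein = np.isin(ds.voxel_index, gt.vein_voxels)
            if is_vein.sum():
                rates.append((is_vein & ~mask.keep_flag).sum() / is_vein.sum())
        assert np.mean(rates) >= 0.9

    def test_disabled_cuts_keep_everything(self, null_session, study_design):
        datasets, _, _ = null_session
        ds = datasets["A1"]
        glm = fit_glm(ds, study_design)
        mask = vascular_exclusion(ds, glm, sd_mult=np.inf, t_percentile=100)
        assert mask.keep_flag.all()

    def test_zero_variance_voxel_never_low_tsnr(self, study_design):
        rng = np.random.default_rng(4)
        y = 100 + rng.standard_normal((50, study_design.n_trs))
        y[7] = 42.0  # constant voxel
        ds = make_dataset(y, runs=study_design.run_starts)
        tsnr = compute_tsnr(ds)
        assert np.isinf(tsnr[7])
        glm = fit_glm(ds, study_design)
        mask = vascular_exclusion(ds, glm, t_percentile=100)
        assert mask.keep_flag[7]


class TestMatchAndZscore:
    @pytest.fixture()
    def session(self, study_design):
        model = generate_cortical_patch(30, 9, seed=6, areas=("A1",))
        spec = EffectSpec(seed=7)
        datasets, gt = simulate_bold(model, study_design, spec)
        ds = datasets["A1"]
        assignment = assign_voxels(model, build_grids(model))
        lid = assignment.layer_id[ds.voxel_index]
        glm = fit_glm(highpass_and_detrend(ds), study_design)
        mask = vascular_exclusion(ds, glm)
        return ds, lid, mask, glm

    def test_counts_equalised_keeping_top_t(self, session, study_design):
        ds, lid, mask, glm = session
        out = match_and_zscore(highpass_and_detrend(ds), lid, mask, glm)
        kept = np.isin(ds.voxel_index, out.voxel_index)
        counts = np.bincount(lid[kept], minlength=3)
        assert len(set(counts)) == 1
        # every kept voxel's t is >= every dropped same-layer voxel's t
        for l in range(3):
            pool = (lid == l) & mask.keep_flag
            dropped = pool & ~kept
            if dropped.any():
                assert glm.t_map[pool & kept].min() >= glm.t_map[dropped].max() - 1e-12

    def test_zscored_per_run(self, session):
        ds, lid, mask, glm = session
        out = match_and_zscore(highpass_and_detrend(ds), lid, mask, glm)
        for sl in out.run_slices():
            np.testing.assert_allclose(out.data[:, sl].mean(axis=1), 0, atol=1e-12)
            np.testing.assert_allclose(out.data[:, sl].std(axis=1), 1, atol=1e-12)

    def test_empty_layer_raises(self, session):
        ds, lid, mask, glm = session
        lid2 = lid.copy()
        lid2[lid2 == 2] = 1
        with pytest.raises(ValueError, match="superficial"):
            match_and_zscore(ds, lid2, mask, glm)


class TestRegressOutMiddle:
    def test_copy_of_neighbour_becomes_noise_free_residual(self):
        rng = np.random.default_rng(8)
        n = 100
        data = rng.standard_normal((4, n))
        data[3] = 2.0 + 0.5 * data[1]  # superficial copy of a middle voxel
        ds = make_dataset(data)
        lid = np.array([0, 1, 1, 2])
        pos = np.array([[0, 0, 0.4], [0, 0, 1.2], [5, 5, 1.2], [0, 0, 2.0]])
        out = regress_out_middle(ds, lid, pos, k_neighbors=1)
        assert np.abs(out.data[3]).max() < 1e-8
        np.testing.assert_array_equal(out.data[:3], data[:3])

    def test_k_clamped_with_warning(self):
        ds = make_dataset(np.random.default_rng(9).standard_normal((3, 50)))
        lid = np.array([1, 2, 2])
        pos = np.random.default_rng(10).uniform(size=(3, 3))
        with pytest.warns(UserWarning, match="clamping"):
            regress_out_middle(ds, lid, pos, k_neighbors=5)

    def test_spillover_accuracy_drops_after_correction(self, study_design):
        """Signal only in the middle layer plus 0.5 leakage: superficial
        decoding falls toward chance once middle neighbours are
        regressed out."""
        from lamina.decode import crossval_decode

        drops = []
        for seed in range(10):
            model = generate_cortical_patch(30, 9, seed=seed, areas=("A1",))
            spec = EffectSpec(
                seed=seed + 50, vein_fraction=0.0, leak_fraction=0.5,
                pattern_amplitude={("A1", "middle", "correlated"): 0.4})
            datasets, _ = simulate_bold(model, study_design, spec)
            ds = highpass_and_detrend(datasets["A1"])
            lid = model.true_layer()[ds.voxel_index]
            sup = np.flatnonzero(lid == 2)

            def sup_accuracy(d):
                bp = block_responses(zscore_per_run(d), study_design)
                return crossval_decode(
                    bp.subset_voxels(sup, "superficial")
                    .for_stereo("correlated")).accuracy

            before = sup_accuracy(ds)
            pos = model.voxel_positions[ds.voxel_index]
            after = sup_accuracy(regress_out_middle(ds, lid, pos, 3))
            drops.append(before - after)
        # sign test: corrections reduce spillover in most seeds
        assert np.mean(drops) > 0
        assert (np.array(drops) > 0).sum() >= 8


class TestBlockResponses:
    def test_window_is_offsets_2_to_6(self, study_design):
        """TRs 3-7 after onset (1-based, inclusive) = 4-14 s at TR 2 s."""
        n = study_design.n_trs
        data = np.zeros((1, n))
        onset = study_design.block_onsets[0]
        data[0, onset + 2: onset + 7] = 1.0      # exactly the window
        ds = make_dataset(data, runs=study_design.run_starts)
        bp = block_responses(ds, study_design)
        assert bp.responses[0, 0] == pytest.approx(1.0)
        data2 = np.zeros((1, n))
        data2[0, onset] = 1.0                    # outside the window
        bp2 = block_responses(make_dataset(data2, runs=study_design.run_starts),
                              study_design)
        assert bp2.responses[0, 0] == 0.0

    def test_block_count_and_labels(self, study_design):
        ds = make_dataset(np.zeros((3, study_design.n_trs)),
                          runs=study_design.run_starts)
        bp = block_responses(ds, study_design)
        assert bp.n_blocks == 160
        df = pd.DataFrame({"stereo": bp.stereo, "label": bp.label})
        assert (df.value_counts() == 40).all()

    def test_constant_series_gives_constant_response(self, study_design):
        ds = make_dataset(np.full((2, study_design.n_trs), 3.14),
                          runs=study_design.run_starts)
        bp = block_responses(ds, study_design)
        np.testing.assert_allclose(bp.responses, 3.14)

    def test_hrf_delay_captured(self, study_design):
        """The convolved response is larger in the shifted window than in
        the unshifted first TRs of the block."""
        from lamina.core import convolve_blocks
        basis = convolve_blocks(study_design.block_onsets,
                                study_design.block_duration,
                                study_design.n_trs, study_design.tr,
                                study_design.run_starts)
        ds = make_dataset(basis.sum(axis=0), runs=study_design.run_starts)
        shifted = block_responses(ds, study_design, window_trs=(3, 7))
        unshifted = block_responses(ds, study_design, window_trs=(1, 5))
        assert (shifted.responses.mean() > unshifted.responses.mean())

    def test_window_beyond_run_end_rejected(self, study_design):
        ds = make_dataset(np.zeros((1, study_design.n_trs)),
                          runs=study_design.run_starts)
        with pytest.raises(ValueError):
            block_responses(ds, study_design, window_trs=(3, 20))


class TestLayerProfile:
    def test_bias_increases_with_depth_before_and_shrinks_after(self, study_design):
        model = generate_cortical_patch(30, 9, seed=20, areas=("A1",))
        spec = EffectSpec(seed=21, superficial_gain_slope=1.0, vein_fraction=0.0)
        datasets, _ = simulate_bold(model, study_design, spec)
        ds = datasets["A1"]
        lid = model.true_layer()[ds.voxel_index]
        corrected = zscore_per_run(highpass_and_detrend(ds))
        prof = layer_profile(ds, corrected, lid, lid, study_design)
        before = prof[prof.state == "before"].set_index("layer")["response"]
        after = prof[prof.state == "after"].set_index("layer")["response"]
        assert before["deeper"] < before["middle"] < before["superficial"]
        spread = lambda s: s.max() - s.min()
        assert spread(after) < spread(before)

    def test_no_bias_no_change(self, study_design):
        model = generate_cortical_patch(30, 9, seed=22, areas=("A1",))
        spec = EffectSpec(seed=23, superficial_gain_slope=0.0, vein_fraction=0.0)
        datasets, _ = simulate_bold(model, study_design, spec)
        ds = datasets["A1"]
        lid = model.true_layer()[ds.voxel_index]
        corrected = zscore_per_run(highpass_and_detrend(ds))
        prof = layer_profile(ds, corrected, lid, lid, study_design)
        after = prof[prof.state == "after"].set_index("layer")["response"]
        assert after.max() - after.min() < 0.05
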