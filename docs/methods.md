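# Methods

`lamina` re-implements, as a tested pipeline over synthetic data with
known ground truth, the analysis chain used in laminar (cortical-depth
resolved) 7T fMRI studies of binocular-disparity processing: equi-volume
depth assignment, vascular-bias correction, depth-resolved multivoxel
decoding of near vs far disparity, a cross-validated linear discriminant
contrast, and informational connectivity between the layers of different
visual areas. This note documents the generative model, the analysis
conventions, the numerical choices, and what the synthetic experiments
do and do not establish.

## Synthetic cortical geometry

The cortical ribbon is parameterised as columns, not a mesh. Each column
carries an inner (white/grey) and outer (grey/CSF) boundary patch area
(mm², drawn uniformly from a configurable range, default [0.5, 2]),
which stand in for local curvature: a gyral crown has a larger outer
than inner area and vice versa for a sulcal fundus. Voxels sit at
equally spaced generative depths `(i+1)/(n+1)` along each column's
normal (default 9 voxels across a 2.4 mm ribbon, columns on a 0.8 mm
grid with ±0.01 mm positional jitter). Three areas — named A1, A3A, A7
after the early, intermediate and higher dorsal visual areas they
emulate — are spatially offset blocks of columns so that neighbourhood
queries never cross areas.

### Equi-volume depths

With a locally linear area profile `A(t) = A_w + (A_p − A_w) t` along
the normal, the depth `x` enclosing volume fraction `α` solves
`A_w x + (A_p − A_w) x²/2 = α (A_w + A_p)/2`, i.e.

    x = (−A_w + sqrt((1−α) A_w² + α A_p²)) / (A_p − A_w),

reducing to `x = α` (equidistant) for `A_w = A_p`. Four grids at volume
fractions {0, 1/3, 2/3, 1} bound the three laminae (deeper, middle,
superficial, coded 0/1/2; depth 0 is the white/grey boundary). Voxels
are assigned to the lamina bounded by their two nearest grids (Euclidean
distance to grid points); a voxel exactly on an interior grid goes to
the shallower band, deterministically. Note that for strongly curved
columns the two-closest-grids rule differs from banding the true depth
by the grid fractions for voxels near a band boundary (at the default
curvature range ~3–6% of voxels); this is a geometric property of the
rule itself, which the synthetic experiments therefore inherit, exactly
as a real segmentation would. The per-voxel `depth_fraction` estimate
interpolates within the bracketing grid pair (the pair whose summed
distance has least excess over the band thickness), which keeps the
estimate monotone along a column.

## Block design

Runs follow the study protocol: TR 2 s, 12 s lead/trail fixation, 40
stimulus blocks of 12 s — ten per cell of the 2×2 factorial
{correlated, anti-correlated random-dot stereogram} × {near, far
disparity} — giving 504 s = 252 TRs per run. Counterbalancing permutes
the four cells within successive chunks of four blocks, so every cell
appears exactly ten times per run and is spread evenly through the run.
Per-stimulus timing (0.9 s stimuli, 0.3 s ISI, ±10 arcmin disparity
with ±0.5 arcmin jitter) is carried as metadata only: blocks are
simulated and analysed as single boxcars, matching an analysis that
operates on block-average responses.

## Generative BOLD model

Per voxel `v` (area a, lamina l, generative depth d) and block `b`:

    response_v(b) = [ E + A(a,l,s_b) · p_v · σ_b · (1 + g_b) ] · (1 + β d)

* `E` — evoked amplitude, identical for all conditions (default 1 BOLD
  unit on a baseline of 100, i.e. ~1% signal change); this is what
  drives voxel selection and the laminar response profile.
* `A(a,l,s)` — disparity pattern amplitude of the cell (stereo condition
  s), applied to a fixed random pattern direction `p_v ~ N(0,1)` with
  sign `σ_b = ±1` for near/far. Cells without an entry carry no
  disparity information.
* `g_b` — optional shared block-wise gain (see Connectivity below).
* `β` — superficial gain slope (default 1): gradient-echo BOLD grows
  toward the pial surface.

The block time course is the boxcar convolved with a canonical
double-gamma HRF (modes 6 s and 16 s, peak:undershoot 6:1), sampled at
the TR from a 10× oversampled grid and normalised to unit kernel sum so
a sustained block plateaus at the stated amplitude. Convolution is per
run. Additive noise is AR(1) Gaussian (lag-1 correlation 0.3, SD 1).
The laminar gain multiplies the noise SD as well as the signal: at 7T
the dominant physiological fluctuations scale with the vascular signal
strength, and it is this property that makes within-layer z-scoring an
effective bias correction. Two further vascular confounds: superficial
voxels receive a fraction λ (default 0) of their column's mean
deeper+middle signal (draining-vein leakage), and a random 5% of voxels
are large-vein voxels with amplitude ×2 and noise ×3.

All randomness flows from one seed through `numpy.random.SeedSequence`
spawning, so a (model, design, spec) triple reproduces byte-identical
data.

## Analysis chain

Order: high-pass filter → condition GLM → vascular exclusion → layer
voxel-count matching + z-scoring → (optional spatial regression) →
block responses → decoding / LDC → connectivity → group statistics.

* **Filtering.** Per run, OLS removal of intercept, linear trend, and a
  Fourier basis at 1–2 cycles per run. When a filtered dataset enters
  the GLM, the same basis is projected out of the design matrix and the
  run intercepts (annihilated by the filter) are dropped, with the
  residual degrees of freedom reduced accordingly — otherwise contrast
  variances are over-estimated and t-values mis-calibrated (verified by
  a KS test of null t-maps against the central t at 10,000 voxels).
* **GLM.** Four HRF-convolved condition regressors plus intercepts and
  optional nuisance columns; the stimulus-vs-baseline t is the mean of
  the four condition betas against zero. ROI preselection keeps voxels
  with t > 1.53 (the upper tail, ≈6.3% under the null; 1.53 is the
  t whose two-sided p is 0.125).
* **Vascular exclusion.** tSNR (temporal mean/SD of the raw series)
  below the area's mean − 2 SD, or stimulus t above the area's 90th
  percentile. With the default confounds the tSNR rule catches
  essentially all simulated vein voxels (their noise inflation outweighs
  their amplitude inflation on the t scale); the t rule removes high-t
  pial voxels generally.
* **Matching and z-scoring.** Layer counts are equalised to the minimum
  across the three laminae by keeping the highest-t voxels (random
  subsampling available); surviving time courses are z-scored per voxel
  within run. Run-wise normalisation is a documented choice — the
  natural normalisation unit — where session-wise would also be
  defensible.
* **Block responses.** Mean over TRs 3–7 after block onset (1-based,
  inclusive; 0-based offsets 2..6; 4–14 s at TR 2 s), which absorbs the
  ~2 TR haemodynamic delay and includes one TR past the block's end.
* **Decoding.** Top-175 voxels per lamina by the label-agnostic
  stimulus t (selection is computed once, not per fold: the ranking
  contrast is orthogonal to the near/far label, so no label leakage is
  possible); linear soft-margin SVM (LIBSVM via scikit-learn, C = 1);
  leave-one-run-out cross-validation, run separately within each stereo
  condition; signed hyperplane distance stored per test block (positive
  = "near"); a block exactly on the hyperplane counts as incorrect.
  The permutation null shuffles labels within run and reruns the full
  cross-validation; p = (1 + #{null ≥ observed}) / (1 + n_perm).
  The mean-pattern control subtracts each block's across-voxel mean.
* **LDC.** Per fold, `w = Σ̂⁻¹ (near − far)_train` with `Σ̂` the
  covariance of the training runs' GLM residuals shrunk toward its
  diagonal by the Schäfer–Strimmer analytic intensity
  `λ* = Σ Var(s_ij) / Σ s_ij²` (off-diagonal, clipped to [0,1]); fold
  LDC = `(near − far)_test · w`; result is the unweighted fold mean.
  Estimating Σ̂ from training runs only avoids test leakage. Under the
  null the statistic centres on 0 — its defining advantage over
  accuracy, which is floored at chance.
* **Connectivity.** Distances are oriented toward the correct class
  (× label sign, so larger = more discriminable), concatenated across
  folds in block-onset order, and compared between laminae of different
  areas by Spearman correlation (average ranks), Fisher-z transformed
  (`arctanh`, |ρ| clipped below 1 − 1e−12). Pathways: feedforward =
  superficial (lower area) ↔ middle (higher area); feedback = deeper ↔
  deeper; superficial↔deeper pairs are ambiguous between the two and
  never emitted.
* **Group statistics.** Within-subject ANOVA via orthonormalised
  contrasts for up to three fully crossed factors, Greenhouse-Geisser ε
  from the contrast covariance, correction applied when ε < 0.75,
  Mauchly's W with the second-order chi-square approximation (as in
  ezANOVA/SAS); paired t-tests; Cousineau-Morey within-subject SEM;
  Benjamini-Hochberg FDR.

## Connectivity ground truth

Coupling entries impose a shared latent `u_b ~ N(0,1)` per block of one
stereo condition: each coupled cell receives gain
`g = σ_g (√ρ u + √(1−ρ) e)` with independent `e`, so the gain series of
the two cells correlate at exactly ρ while mean signals are unchanged —
informational connectivity, not univariate correlation, is what the
manipulation feeds. The classifier-distance series recover ρ only up to
attenuation by block-response noise; with σ_g = 0.5 and pattern
amplitude 0.4 in the signal cells, injected ρ = 0.5 is recovered as
mean ρ̂ ≈ 0.42–0.46 while uncoupled pairs stay within ±0.04 of zero.
The connectivity experiments therefore use amplitude 0.4 (strong,
near-ceiling decoding) so that discriminability fluctuations dominate
the distance series; the decoding experiments use the default 0.08.

## Default effect sizes

No raw per-condition effect sizes are available to copy, so the
defaults are fixed once at values a 7T block design plausibly yields
and exposed in the configuration: evoked response 1% of baseline,
pattern amplitude 0.08 in the superficial+middle laminae of A3A and A7
for correlated stimuli only (the ground-truth pattern the group
analyses are expected to recover). At these values signal cells decode
at ~75–85%, deeper laminae at ~52% (the small spillover is the
band-boundary misassignment noted above), A1 and all anti-correlated
cells at chance.

## Problem sizes

Experiments are sized to run the full suite on one CPU in minutes: 80
columns × 9 voxels per area (720 voxels/area; ≥ 175 per lamina survive
exclusion and matching), 7 subjects with 4–6 runs for group
experiments, 10 experiment replicates for the recovery rate, 20 seeds
for the vascular and connectivity recoveries, 200 null datasets for LDC
centring, 1000 permutations for the decoding null.

## Limitations

* The generator emulates the statistical structure the analyses assume
  — laminar gain and noise gradients, vein voxels, leakage, coupled
  discriminability — not vascular physiology; passing tests show the
  pipeline recovers known structure under these assumptions, not that
  real cortex satisfies them.
* Geometry is column-parameterised; mesh reconstruction, curvature
  estimation and segmentation error are out of scope (the NIfTI entry
  point accepts externally computed layer labels for real data).
* Acquisition-side preprocessing (motion, distortion, slice timing,
  coregistration) is out of scope.
* The SVM solution is order-dependent at LIBSVM's working tolerance, so
  distances are reproducible only to ~1e−3 under block reordering.
* A within-condition decode tests 20 patterns per fold, so single-subject
  accuracies are quantised at 1.25% (4 runs) and correspondingly noisy;
  inference is always at the group level.
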