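# Methods

## Problem and pipeline

`brainnets` implements a complete analysis chain for discriminating two
subject groups from resting-state fMRI and characterizing how their
large-scale brain functional networks differ:

1. **Group ICA.** All subjects' preprocessed 4-D volumes are masked to the
   voxels with nonzero temporal variance in every subject, each voxel's
   series is demeaned and variance-normalized per subject, and the subject
   matrices are concatenated in time. The concatenation is reduced to K
   spatial dimensions by PCA and unmixed by fixed-point ICA (logcosh
   contrast, symmetric decorrelation) over voxels, yielding K group-level
   spatial maps and, by pseudo-inverse projection, their concatenated time
   courses. Component maps are finally re-expressed in data units by
   multiplying with the cohort-mean per-voxel standard deviation: this
   undoes the compression that per-voxel variance normalization applies to
   strong-signal voxels, so a component map is again proportional to the
   network's BOLD amplitude profile. Maps are sign-fixed to positive
   skewness, making the decomposition reproducible for a fixed seed.

2. **Z-maps and mixture thresholding.** Each map is standardized over
   in-mask voxels. Its intensity histogram is modeled as a three-class
   mixture — a central Gaussian for background noise, a Gamma on the
   positive tail for activation, and a mirrored Gamma on the negative
   tail — fitted by EM with exact weighted M-steps (Newton on the Gamma
   shape), which makes the log-likelihood non-decreasing. A voxel is
   suprathreshold when its posterior probability of belonging to a Gamma
   class exceeds 1 − p at p = 0.5, the local false-discovery-rate rule.
   Gamma shapes are floored at 1.05 so the signal classes stay tail-like
   (a shape ≤ 1 would place density at the origin and could label z = 0 as
   signal). A class whose weight collapses below 1e-4 is dropped and
   recorded; EM restarts from three moment initializations with
   increasingly strict tail cuts and keeps the best likelihood.

3. **Component triage.** Components are clustered hierarchically (average
   linkage on 1 − r between their group time courses; spatial-correlation
   distance available by flag) and the tree is cut into its two top-level
   branches. Each branch is labeled by its members' mean low-frequency
   fraction — Welch-spectrum power in 0.01–0.1 Hz over total power above
   DC. Band-limited network time courses score near 1; broadband artifacts
   score near the flat-spectrum value (0.36 at TR = 2 s), so a branch is
   "good" when its mean clears 0.6. If no branch clears the cut the
   best-scoring branch is kept, so triage never discards every component.
   Good components are then matched to named reference maps by spatial
   Pearson correlation with greedy one-to-one assignment, rejecting pairs
   below r_min = 0.25, and reordered into the fixed canonical order
   PVN, dDMN, vDMN, PCUN, SMN, SN, LCEN, RCEN — the classifier's channel
   order. The packaged default references are the synthetic generator's
   ground-truth maps; an external reference atlas can be supplied as a 4-D
   NIfTI plus names file.

4. **Dual regression.** Stage 1 regresses the K group maps (columns
   demeaned; data demeaned rather than fitting an intercept) into each
   timepoint's voxel vector, giving subject-specific time courses for all
   K components — so the selected networks' time courses are estimated in
   the presence of the artifact regressors, which is how artifactual
   signal is regressed out before connectivity analysis. Stage 2 uses the
   (by default variance-normalized) time courses as joint temporal
   regressors per voxel, giving subject-specific spatial maps. With
   normalization on, a network's amplitude is pushed into its stage-2 map,
   so the maps encode both shape and amplitude; the flag `des_norm=False`
   disables this. Selected maps are padded to a common grid (centered,
   the smaller pad on the low-index side) and stacked as channels.

5. **Classification.** The classifier is a 3-D VGG variant: convolution
   widths 32,32 | 64,64 | 128×3 | 256×3 | 256×3, all kernels 3×3×3 with
   same padding, batch-norm + LeakyReLU (slope 0.01) pre-activations, four
   2×2×2 max pools, and three squeeze-and-excitation blocks — after the
   first convolution (width 32), after the first pool (width 32) and after
   the second pool (width 64), each with reduction ratio 16 (bottleneck
   width max(1, ⌊F/16⌋), ReLU inside, sigmoid out, no biases). The head is
   dropout (0.7) + a valid convolution with 2048 filters whose kernel
   equals the spatial extent remaining after the pools (3×3×3 for a
   48×56×48 input, so it consumes the feature map fully), LeakyReLU,
   dropout + a 1×1×1 convolution with 1024 filters, LeakyReLU, and a dense
   layer to 2 logits. He initialization throughout. Variants: `baseline`
   removes the SE blocks, `scse:<network>` feeds a single channel,
   `mcse` feeds all channels. A `width_multiplier` scales every width for
   desk-scale runs; the full-width 8-channel model has 27,303,106
   parameters.

   Training minimizes cross-entropy with Adam (lr 5e-4), L2 weight decay
   1e-5 on convolution kernels, batch size 12, learning-rate decay by 0.1
   after a 10-epoch validation-loss plateau, and early stopping.
   Evaluation is stratified k-fold cross-validation (k = 10 by default);
   validation predictions are taken from the best-validation-loss epoch.
   Each channel is z-scored with the training fold's mean and standard
   deviation (the validation fold reuses those statistics, so nothing
   leaks). The validation set serves both scheduling and evaluation, as in
   the published protocol; this is an optimistic design and is noted, not
   fixed, here.

   The network runs on a self-contained NumPy engine (offset-accumulated
   3-D convolution with analytic backprop, batch norm, SE, max-pool,
   dropout, Adam); everything is deterministic given the seed.

6. **Netmat statistics.** For each subject the selected components'
   stage-1 time courses give a ridge partial-correlation matrix: columns
   standardized, precision = (R + ρI)⁻¹ with ρ = 0.1 by default,
   pc(i,j) = −prec(i,j)/√(prec(ii)·prec(jj)), zero diagonal. Off-diagonals
   are Fisher z-transformed. Edges are compared between groups with an
   unpaired permutation test on the group mean difference: the same label
   permutation applies to all edges (preserving cross-edge dependence),
   subsets are sampled at the smaller group's size so the p-value is
   invariant to which group is called "case", and
   p = (1 + #{|T_perm| ≥ |T_obs|}) / (1 + n_perm) with n_perm = 5000 —
   always positive and exact under exchangeability. Edges at p ≤ 0.05
   (uncorrected, matching the published selection rule; a Bonferroni
   column is reported alongside) are annotated with the difference sign
   and summarized as per-group box plots (1.5·IQR whiskers).

## Synthetic cohorts

The generator emulates a single-site resting-state study: K compact
Gaussian-profile networks (values in [0,1], truncated at 3 sd, centers on
an interior lattice jittered by the seed, pairwise spatial correlation
< 0.3 when overlap is disallowed) on a 4-mm-like grid; per-subject
band-limited time courses built by frequency-domain filtering of white
noise to 0.01–0.1 Hz, exact whitening, and coloring by the matrix square
root of a target correlation matrix — so columns are exactly zero-mean,
unit-variance, band-limited, with exactly the requested sample
correlation; bilinear mixing data(v,t) = Σₖ aₖ·mapₖ(v)·tcₖ(t); and
stationary AR(1) Gaussian voxel noise (marginal sd `noise_sigma`,
lag-1 coefficient 0.3 by default).

Group differences enter as (a) per-network amplitude multipliers on the
case group, (b) integer-voxel translations of the case group's maps, and
(c) different coupling matrices per group. The packaged strong-effect
condition doubles the amplitude of three networks (the dDMN, PCUN and SN
analogues) and moves three coupling edges by ±0.4 between groups,
mirroring the hyper-/hypo-connectivity pattern the netmat stage is meant
to detect. Defaults: K = 8 networks, 180 timepoints at TR = 2 s (a
six-minute scan), 24×28×24 grid (half resolution of the padded 48×56×48
grid; the full-scale 45×54×45 source grid is available by config),
noise_sigma 0.5 (0.3 under the strong-effect condition).

`signal_sd(maps)` gives the standard deviation of the noiseless signal
over the volume; `noise_sigma = signal_sd` therefore defines whole-volume
SNR 1, the condition used for the recovery bounds.

What the generator does *not* model: physiological noise and motion,
spatial autocorrelation of the noise field, multi-site heterogeneity,
hemodynamic convolution, and eyes-open/eyes-closed differences. Passing
recovery and classification checks on these cohorts therefore validates
the estimators' correctness under their own assumptions, not their
performance on real scanner data.

## Numerical choices and problem sizes

- Dual regression solves OLS by `lstsq` (SVD) with rcond 1e-10 and raises
  a collinearity error naming the most correlated component pair when the
  design is rank-deficient.
- PCA uses an exact SVD when the smaller matrix dimension is ≤ 800 and a
  seeded randomized SVD (7 power iterations) otherwise.
- ICA non-convergence within 1000 iterations (tolerance 1e-6) raises an
  error carrying the iteration budget rather than returning a partial
  result.
- Ridge partial correlation refuses condition numbers above 1e12 and
  advises ρ > 0.
- Max pooling floor-crops odd axes (the trailing slice gets zero
  gradient) and passes axes of size 1 through, so any input at least
  3 voxels wide per axis forward-passes; tied maxima share gradient
  equally.
- The scaled study used by the acceptance checks: 30 + 30 subjects,
  quarter-width model, 4 folds, 12 epochs, 999–2000 permutations —
  desk-scale sizes chosen so the whole chain runs on one CPU core in
  minutes while leaving every estimator at its defaults.

## Known limitations

- Subject-level PCA pre-reduction before concatenation is omitted (single
  concatenation-level PCA); adequate at these cohort sizes, but a
  deviation from multi-stage group-ICA practice at scale.
- The Gamma-shape floor (1.05) biases extremely heavy single-tail
  mixtures slightly; irrelevant for z-map histograms.
- Both precision/recall conventions are computed (`standard` and the
  nonstandard `as_printed` pair precision = TP/(TP+FN),
  recall = TN/(TN+FP)); reports use `standard` unless asked otherwise.
- Model-order selection for ICA is fixed (K is a config value), and no
  multiple-testing correction is applied to edge selection beyond the
  reported Bonferroni column.
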