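# Methods

This note documents the models, the numerical choices behind them, and the
limits of what the synthetic-data validation can show.

## Synthetic data generators

The generators define the study conditions under which every downstream
stage is validated.

**Image cohorts.** Volumes are Gaussian noise fields (`noise_sd`, default 1)
optionally smoothed with a Gaussian kernel (`smoothness_sigma`, in voxels,
default 1) and rescaled so the marginal standard deviation stays `noise_sd`.
Smoothing matters: occlusion analysis estimates each patch's replacement
distribution from its spatial context, which is only meaningful on spatially
correlated images like registered diffusion scans. Disease signal is a
constant mean shift (`effect_size`) added inside axis-aligned boxes for case
subjects. The default cohort shape follows the motivating study: 51 cases
vs 100 controls; validation cohorts use 20/20 at 32³ with `effect_size=5`,
a strongly separable signal chosen so that classifier failure, not signal
weakness, would be the cause of a failed recovery test. What these cohorts
do *not* emulate: anatomical structure, registration artifacts, intensity
inhomogeneity, or correlated (non-box) lesion geometry — passing tests show
the machinery is correct, not that real scans of any particular disease
will yield the same accuracy.

**Genotypes.** Per SNP, a minor-allele frequency is drawn uniformly from
`maf_range` and genotypes are binomial(2, maf) — Hardy–Weinberg equilibrium,
independent SNPs. Linkage disequilibrium is deliberately absent: no pipeline
stage depends on it, and adding it would complicate the FPCA oracles.

**Cause–effect pairs.** Three named mechanisms keep direction-recovery
experiments reproducible: `linear` (1.5x), `quadratic` (x²), `sigmoid`
(tanh 2x), each with additive independent Gaussian noise. `direction="none"`
yields independent variables for null calibration. The "strong" pairs used
in the power suite are quadratic with `noise_sd=0.25` at n=500: the
anticausal conditional p(x|y) is sharply bimodal there, which is exactly the
asymmetry additive-noise causal discovery exploits.

## Classifier

The default schedule is the five-layer 11/5/3/3/3 stack (stride 4 in all
three directions on the first layer, stride 1 after) with 2×2×2 max pooling
after every convolutional layer, global average pooling, and a two-node
softmax. Channel widths (16/32/64/64/64) are a desk-scale choice; they are
configurable, as is a three-layer fully-connected head (`gap=False`) for the
variant architecture. Convolutions after the first use zero "same" padding
and pooling is ceil-mode, so the schedule stays valid on grids as small
as 16³; the first (valid) convolution is the binding constraint and its
error message names the offending layer.

Training is Adam on softmax cross-entropy (defaults: learning rate 1e-4,
30 epochs, batch 8 — all logged, since the reference work does not print
its settings). The whole stack is plain numpy with explicit gradients, so a
fixed seed reproduces training bit-for-bit; tests verify every layer against
numeric differentiation. Tests and examples run reduced schedules (2–3 conv
layers, learning rate 1e-3, ~10 epochs) at 12³–32³, which train in under a
second and reach training accuracy 1.0 on the strongly separable cohorts.

Evaluation reports accuracy, sensitivity and specificity with the disease
class positive, and AUC as the rank statistic on predicted disease
probability; a metric whose defining class is absent is reported as missing,
never as zero. Cross-validation is stratified, canonicalized by subject id
(fold assignment is invariant to input order), and augmentation runs inside
training folds only — an internal assertion guarantees no augmented copy of
a held-out subject reaches training.

**Augmentation composition** is pinned: per original volume, {original, one
copy per blur setting, one copy per signed one-voxel shift}, then a
left–right flip of all of those — 2 × (1 + 3 + 6) = 20 — followed by
minority-class duplication. The flip-last order is the only composition
that reaches the twenty-fold yield before balancing. "Left–right" is the
first grid axis by default and configurable, since axis semantics depend on
the registration template's orientation.

## Relevance analysis

The replacement model at each patch location is the *marginal* multivariate
normal of that patch across training volumes (mean and covariance, with a
1e-6 ridge so small training sets still factorize). The conditional variant
(sampling a patch given its surroundings) is out of scope. Defaults:
3×3×3 patch, 10 draws per location, stride 1; validation suites use stride 3
and 4 draws, which preserves full voxel coverage (a trailing window is added
when stride does not divide the grid) at a fraction of the cost. Probability
clipping to [1e-6, 1−1e-6] keeps the log-odds finite on saturated softmax
outputs. Overlapping windows are averaged by coverage count; per-subject
maps are averaged unweighted over the subject set, and each subject's
replacement draws are seeded from the volume's content hash, so the cohort
map is invariant to subject ordering.

ROI extraction keeps voxels at or above the requested percentile of W (ties
at the boundary are all retained), labels connected components (26-neighbor
default, 6-neighbor available), and indexes them in decreasing size order.
A constant map has no distinguishable top decile and returns an empty set
with a warning. The number of ROIs is an *output* of this procedure —
the reference analysis found 23 on its data — never an input.

## Functional principal components

Region (3D) scores: center the subjects × voxels matrix, optionally
pre-smooth each subject's region image (mask-normalized Gaussian inside the
region's bounding box; off by default), and take the SVD. Scores are
U·S, eigenvalues S²/(n−1). Gene (1D) scores: SNP positions are rescaled to
[0, 1]; each subject's profile is least-squares-projected onto a B-spline
basis (cubic where the SNP count allows, at most 10 basis functions); the
Gram-weighted coefficient covariance is then decomposed, which is the
classical basis-expansion route to functional PCA. Single-SNP genes bypass
the expansion and return the centered genotype; monomorphic genes are
rejected.

Component count defaults to the smallest number explaining 80% of variance,
capped at 5. Determinism is enforced by a sign convention (the
largest-magnitude loading of each component is positive). Full tensor-product
spline FPCA with roughness penalties is a non-goal; the SVD route is exact,
fast, and directly checkable against dense eigendecomposition, which the
test suite does to 1e-8.

## Causal discovery

Procedure per variable pair: (1) fit a conditional GAN from X to Y and
generate D_{X→Y} = {(x_i, ŷ_i)}; (2) likewise from Y to X for
D_{Y→X} = {(x̂_i, y_i)}; (3–5) split, and measure KNN classifier two-sample
accuracies t of real pairs {(x_i, y_i)} against each generated pair set;
(6) form T = t^{X→Y} − t^{Y→X} with null variance
σ² = 0.5/n_test − 2·cov(t^{X→Y}, t^{Y→X}).

Design choices worth recording:

* **Pairs, not marginals, in the two-sample test.** The generated dataset is
  defined as pairs, and only the joint carries the conditional fit that
  distinguishes the two factorizations. We verified empirically that
  classifying the 1-D marginals {y_i} vs {ŷ_i} has essentially no
  directional power — a competent CGAN matches the effect's marginal from
  either direction, and skewed effect marginals (e.g. x² + noise) are
  *harder* to match than Gaussian cause marginals, biasing a marginal-only
  statistic toward the wrong direction.
* **Sign convention.** Lower accuracy = better generative fit, so T
  significantly below zero calls X→Y, above zero calls Y→X, otherwise the
  result is inconclusive (two-sided normal p, α = 0.05 by default). The
  convention is covered by an exact antisymmetry test: `causal_test(y, x)`
  returns exactly −T because every sub-stream seed is derived from the data
  content rather than the argument order.
* **Covariance estimation.** The reference formula leaves cov(t, t)
  unspecified. It is estimated as the sample covariance of the two
  accuracies over 20 repeated random train/test splits of the *same* two
  fitted generators — splits, not refits, are the dominant shared noise
  source, and refitting per split is not desk-scale. The headline t's come
  from the first split (the split-averaged variants are also reported);
  σ² is floored at 0.1/n_test so a noisy covariance estimate can never
  produce a non-positive variance.
* **CGAN training.** Generator and discriminator are two-hidden-layer MLPs
  (width 32; tanh generator, leaky-ReLU discriminator), noise dimension 5,
  batch 100, 500 epochs by default (300 in the desk-scale `SMALL_CGAN` used
  by the validation suite). Two stabilizers are essential at this scale and
  are on by default: the discriminator learns at 1e-3 vs the generator's
  5e-4 (two-timescale rule), and the returned generator is an exponential
  moving average (decay 0.998) of the generator weights along training.
  Without them roughly a third of seeds produced oscillating fits and failed
  direction recovery. Both variables are standardized internally; generated
  effects are returned on the original scale. Non-finite training loss
  triggers one seeded retry, then an error.
* **KNN.** K defaults to floor(√n_train); the split is stratified 50/50.
  Accuracy agrees exactly with a brute-force all-pairs computation on small
  instances (tested), including sklearn's tie-breaking.

Measured under the study conditions (n=500): type-I error 3/100 at α=0.05
on independent pairs, and 20/20 correct direction calls on strong quadratic
pairs (the suite requires ≥ 14 correct, ≤ 2 wrong). Bonferroni screening
accepts censored table entries like "<0.00005", which count as significant
for any threshold at or above the bound and are conservatively kept
non-significant below it.

The gene–region **association test** is the permutation p-value of the first
canonical correlation between two score matrices (999 permutations by
default; subjects are content-sorted first so the p-value is invariant to
input row order). It is the associative counterpart to the causal test, not
a replacement for it.

## Pipeline

`run_pipeline` executes synth → train → relevance → fpca → causal → screen.
Each stage's seed is derived from the global seed and the stage name; the
manifest records config, seeds, timings and SHA-256 output hashes, and a
rerun with the same config and seed reproduces the hashes of every
deterministic stage (the full stack is deterministic on this numpy backend;
manifests record the package version). A stage may be disabled if its
outputs already exist on disk, which is how partial re-runs reuse upstream
results; a missing upstream output raises a dependency error naming the
stage. In pipeline runs the causal stage tests each ROI's first FPC score
against the binary disease label at the cohort's single timepoint;
cross-timepoint designs (training at one visit, testing causation at
another) are exposed through the CLI's per-manifest invocations, which
record which subject-evaluation mode was used.

## Known limitations

* The CGAN direction test is calibrated and powered for the bivariate case
  with continuous or binary scores; multivariate graphs, confounder
  adjustment and interventional analysis are out of scope.
* Direction recovery depends on adversarial fits; very small samples
  (n < ~100) or near-Gaussian linear mechanisms are unidentifiable in
  principle for additive-noise methods, and the test correctly returns
  "inconclusive" rather than forcing a call.
* The relevance map's replacement model is marginal per location; highly
  structured backgrounds would justify the conditional variant.
* Synthetic cohorts have box-shaped signals and stationary noise; Dice
  recovery numbers on them do not transfer quantitatively to real lesions.
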