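# Methods

## Generative model of the synthetic cohorts

Voxels live on a one-dimensional line of length V (default 1000; V is a
free parameter everywhere).  The RSN template consists of R Gaussian
bumps (default R = 90) with centers evenly spaced plus a ±10% jittered
offset and width one third of the spacing, z-scored per column; at the
defaults the pairwise column correlations stay below 0.3.  Latent
sources are the upper tails (above the 90th percentile) of a spread of
template columns — sparse, non-negative, strongly super-Gaussian maps,
which is the regime in which FastICA identifies a linear mixture.

Each subject's scan is `A S + ε`: the T x N time-course matrix `A` is
Gaussian-filtered white noise (temporal smoothing σ = 2 samples,
columns standardized), and `ε` is white Gaussian noise scaled so the
signal-to-noise power ratio equals `snr` (default 10; `snr = inf`
disables noise and makes the mixture exact).  For depressed subjects
(label 1) the time courses of the first ⌈N/4⌉ "effect" components are
scaled by `1 + 0.25·effect_size` and receive an added sinusoid at 0.15
cycles/sample with amplitude `0.25·effect_size` and per-subject random
phase — so both the temporal-amplitude and the spectral branch of the
classifier see recoverable signal, and the between-class power gap is
monotone in `effect_size`.  All random draws are consumed identically
for both classes, so cohorts with different effect sizes but the same
seed are sample-for-sample comparable.  The default cohort composition
is 51 depressed / 21 controls with 100 timepoints, mirroring the small
imbalanced clinical setting the pipeline targets.

What the generator does **not** emulate: hemodynamic response shapes,
head motion, physiological noise, anatomical geometry and spatial
autocorrelation of real BOLD data.  Passing tests therefore demonstrate
correctness and internal consistency of the algorithms, and recovery of
the planted structure — they do not certify classification accuracy on
real cohorts.

## Group ICA feature extraction

The first five volumes of each scan are discarded (scanner
equilibration; 100 → 95 timepoints at the defaults).  Group reduction
is the standard two-stage scheme: per-subject PCA of the row-centered
data to ⌈1.5·N⌉ temporal components, temporal concatenation across
subjects, then group PCA whitening to exactly N rows with identity
covariance across voxels.  FastICA (scikit-learn, `whiten=False`,
tol 1e-4, max 200 iterations) unmixes the whitened matrix;
non-convergence raises a warning and returns the best iterate.
Component sign is fixed by making each component's maximum-magnitude
voxel positive, and rows are normalized to unit variance.

Stability selection is a simplified restart-matching scheme: the
decomposition is repeated `n_restarts` times (default 10) from seeds
derived from the base seed, restarts are matched to the first run by
Hungarian assignment on absolute correlation, signs aligned, and the
centroid components returned together with each component's mean
|correlation| to its cluster.  With one restart this reduces exactly to
a single FastICA run.

Per-subject time courses are the least-squares solution of
`min_A ‖X − A Y‖²`.  Spatial features are obtained GIFT-style per
subject: the subject's own spatial maps are back-reconstructed by least
squares from its data and time courses, then each map is regressed on
the RSN template by ordinary least squares (`Q = Y β` with β estimated,
not fixed), giving an R x N matrix per subject.  The group-level
similarity matrix is computed and stored as well.  Whether the
template-regression features should be standardized before convolution
is not pinned down anywhere; they are used raw, and the classifier
standardizes its fused input instead.

## Multi-scale convolutional fusion

Both matrices pass through banks of odd square kernels (default 3, 5,
7, 9, 11; 8 filters per scale), same-padded cross-correlation → ReLU →
6x6 max pooling with stride 6 and ceil-mode partial edge windows.  At
the defaults this yields 16x3 pooled maps per filter for the 95x17
time-course branch and 15x3 for the 90x17 spatial branch, for a fused
vector of 5·8·48 + 5·8·45 = 3720 entries (time branch first, then
spatial, scales in configured order; the layout record stores the slice
boundaries).

The filter banks are **fixed seeded random projections** rather than
jointly trained weights: each (branch, kernel) pair draws its filters
from an independent seeded stream, so the fusion stage is fully
deterministic, adding a scale never changes existing features, and all
learnable capacity is concentrated in the classifier.  Random
convolutional projections preserve class-dependent amplitude structure
well, and freezing them removes a large, hard-to-regularize parameter
block from a setting with ~65 training subjects per fold.  The two
branches use independent filter banks.

## Class balancing

SMOTE synthesizes minority samples as `x + u·(x_nn − x)` with `x` a
uniformly drawn minority sample, `x_nn` one of its k = 5 nearest
minority neighbors (Euclidean distance on the raw fused vectors), and a
single gap `u ~ U(0,1)` shared across coordinates, until the class
counts are equal.  A singleton minority falls back to duplication with
a warning; k is clipped with a warning when the minority class is
smaller than k + 1.  Random oversampling duplicates uniformly drawn
minority rows.  Both run strictly inside the training folds; synthetic
samples carry a `synthetic:` id prefix and the cross-validation loop
asserts that no such id ever reaches a test fold.

## AFGRU classifier

The fused vector is folded back into a sequence: the time-branch blocks
become (pooled-time x channels) with channels = scales x filters x
pooled-width (16 x 120 at the defaults), and the flattened spatial
branch is appended to every timestep as static covariates (16 x 1920).
Three stacked FGRU layers (hidden size 200) process the sequence; each
gate reads the real part of the DFT of its current input, per the cell
equations in the README.  Additive attention (tanh scoring layer of
width 64, softmax over timesteps) pools the last layer's hidden
sequence.

Six branches are tapped: X1 the input projection — a tanh projection of
the **full standardized fused vector**, so the ensemble always contains
a near-linear model of the complete input — X2–X4 the final hidden
states of the three layers, X5 the attention context, X6 a dense tanh
transform of X5.  Each branch has an affine head producing a score
`s_i`; heads are zero-initialized so every branch starts at the neutral
prediction 0.5.

**Training objective.**  The loss is branch-supervised:
`Σ_i w_i · mean_j (σ(s_ij) − y_j)²`.  Supervising each branch
individually keeps every branch calibrated; training only the weighted
sum would leave the individual scores unidentified, and branches then
acquire mutually canceling offsets that behave arbitrarily on held-out
subjects (we observed exactly this failure: saturated branches emitting
a constant ~1 on every test subject).  Full-batch Adam steps at
learning rate 0.01; divergence (non-finite loss) aborts with a
diagnostic.  The prediction is `Σ_i w_i σ(s_i) ∈ [0, 1]`, thresholded
at 0.5 with ties going to the positive class.

**Adaptive branch weighting.**  The weights start from folded-Gaussian
draws normalized to the simplex and follow a multiplicative-weights
(Hedge) rule: per round, `w_i ← w_i · exp(−lr · Σ_j (p_ij − y_j)²)`,
renormalized.  The errors are measured on a stratified 20% hold-out of
the training data that never receives gradient updates (classes with
fewer than 3 samples, or single-class training sets, skip the
hold-out).  Held-out errors are essential: with ~200-dimensional heads
and ~90 training samples every branch interpolates the fitted data
within a few epochs, after which training errors carry no information
about branch quality.  Against held-out samples the updates concentrate
weight exponentially on the branches that generalize.  The number of
weight-update rounds defaults to 500 and is decoupled from the number
of gradient epochs: when training runs fewer epochs, the remaining
rounds reuse the final model's held-out errors.  Equal per-branch
errors and lr = 0 leave the weights unchanged (the common factor
cancels in the normalization), and positivity plus Σw = 1 hold after
every round by construction.

Gradients are hand-written reverse-mode (BPTT through the gates, the
attention softmax and the per-layer DFT — whose real-part matrix is
symmetric, so its adjoint is itself) and verified against central
finite differences in the test suite.  Feature standardization uses
training-set statistics stored on the model.

## Evaluation

Folds are assigned at the subject level, stratified by default: each
class is shuffled and all subjects are dealt to folds in one continuous
stream, preserving the class ratio while keeping fold sizes within one
of each other (72 subjects → sizes 8, 8, 7 ×8).  Stratification can be
disabled.  Group ICA and fusion are computed once on the full cohort
before the split — the protocol this package reproduces computes its
features that way, and the shared-decomposition caveat is inherited
knowingly; the sampler and the classifier (including its feature
standardization) are fit strictly on training folds.

ACC, SEN, PPV, F1 and Recall (≡ SEN) follow the standard 2x2-table
formulas with class 1 (depressed) positive; zero-denominator cases are
reported as 0 with a warning.  AUC is the Mann–Whitney rank statistic
with half credit per tied pair; a single-class fold reports 0.5 with a
warning (stratification prevents this in practice).  Reported metrics
are per-fold means (pooling over folds would be the alternative; the
choice is recorded here).

## Problem sizes and numerical choices

Desk-scale runs (the test suite and `scripts/acceptance.py`) use the
full 51/21 x 100 x 1000 cohort with 17 components and 5 ICA restarts,
and reduce the classifier's gradient epochs to 40 while keeping all
500 weight-update rounds; one 10-fold CV takes ~5 minutes on one CPU
core.  Smaller unit-test fixtures (12 subjects, 300 voxels, 4 sources)
exercise every code path in seconds.  Gate-matrix initialization scales
the FFT input block by 1/d (a DFT coefficient of a standardized d-dim
input has variance ~d/2), keeping pre-activations O(1).  FastICA
tolerance 1e-4 and 200 iterations; lstsq everywhere with numpy's
default rcond; max pooling pads partial windows with −inf.

## Known limitations

The shared group decomposition across CV folds mildly couples train and
test subjects (inherited protocol caveat, flagged above).  The adaptive
weighting selects branches by held-out error on ~13 samples per fold,
which is noisy; with a weak or absent class signal the weights land on
an arbitrary branch, which is harmless (predictions stay near chance)
but means the learned `w` should not be over-interpreted.  The
synthetic cohorts make linear class structure recoverable by design;
real rs-fMRI effects are weaker and less linear, and the pipeline's
real-data performance cannot be inferred from these simulations.
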