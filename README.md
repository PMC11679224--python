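# stanet

Classifying depression from small, imbalanced resting-state fMRI
cohorts with a spatio-temporal aggregation network: group independent
component analysis (ICA) for feature extraction, multi-scale 2D
convolutional fusion of temporal and spatial features, SMOTE balancing
of the training folds, and an attention-Fourier gated recurrent unit
(AFGRU) classifier with adaptive branch weighting, evaluated by
subject-level 10-fold cross-validation.

The package is aimed at neuroimaging-ML researchers who want a fully
tested, dependency-light (numpy/scipy/scikit-learn) reference of this
pipeline.  A synthetic-cohort generator reproduces the statistical
structure the method assumes — non-Gaussian spatial sources mixed by
smooth subject-specific time courses with a class-dependent
amplitude/spectral effect and a 51:21 class imbalance — so every stage
is testable end to end without downloading any data.

## The model

Each subject's scan is a T x V matrix `X` modeled as a linear mixture
`X = A S` of N spatially independent, non-Gaussian sources (rows of the
N x V matrix `S`) with time courses in the T x N matrix `A`.  Group ICA
estimates an unmixing `W` with `Y = W X_white ≈ S` from the temporally
concatenated, PCA-whitened cohort; per-subject time courses are
recovered by least squares and component maps are regressed against an
R-network RSN template (`Q = Y β`) to give spatial-similarity features.
Both matrices per subject (time courses T' x N, spatial features R x N)
pass through banks of 3x3 … 11x11 convolution kernels with ReLU and 6x6
max pooling, and the pooled maps are concatenated into one fused vector.

The AFGRU classifier views the fused vector as a short sequence and
stacks gated recurrent units whose gates read the real part of the DFT
of each input step,

    z_t = σ(W_z [h_{t-1}, Re FFT(x_t)]),   r_t = σ(W_r [h_{t-1}, Re FFT(x_t)]),
    h~  = tanh(W_h [r_t ∗ h_{t-1}, Re FFT(x_t)]),   h_t = (1 − z_t) ∗ h_{t-1} + z_t ∗ h~,

plus additive attention pooling.  Six branch taps (input projection,
the three stacked FGRU final states, the attention context and a dense
transform of it) are each trained toward the label with MSE, and the
prediction is the convex combination `Σ w_i σ(s_i)` with branch weights
`w` on the probability simplex, adapted over 500 multiplicative-update
rounds from held-out branch errors.  Performance is reported as
ACC, F1, Recall (= sensitivity) and the Mann–Whitney AUC.

## Worked example

```bash
stanet full-run --simulate --rounds 500 --epochs 40 --seed 7 --out run/
```

simulates the default cohort (51 depressed / 21 controls, 100
timepoints of 1000 voxels, 17 sources, class effect 2.0), extracts
features, fuses them, cross-validates and prints

```
ACC=1.0000 AUC=1.0000 -> run/report.json
```

meaning every held-out subject of the strongly-affected synthetic
cohort was classified correctly (mean over the ten folds; the class
effect of 2.0 scales patients' affected time-course amplitudes by 1.5x,
which is an easy contrast at this noise level — on real data the same
protocol is far from perfect).  `run/report.json` carries the per-fold
ACC/SEN/PPV/F1/Recall/AUC, the config echo and its hash.  The same
pipeline is available stage by stage (`stanet simulate`,
`extract-features`, `fuse`, `train`, `predict`, `evaluate`) and as a
library (`stanet.pipeline.full_run`).

With no class effect the report stays at chance level, e.g.
`ACC=0.6250 AUC=0.5250` for `--effect-size 0` (the accuracy sits above
0.5 because the cohort is imbalanced 51:21 and the folds are small).

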