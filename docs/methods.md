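# Methods

This note records the scientific and numerical choices behind `dualecg`:
what is modelled, which parameters matter, and what the synthetic
experiments do and do not demonstrate.

## Signal model and denoising

The input is a single-lead (ML-II-style) ECG sampled at 360 Hz, in mV,
with one annotation per beat giving the R-peak sample and a beat symbol.
Artifacts are modelled as additive: baseline wander (sub-Hz drift),
power-line interference at 50/60 Hz, and broadband noise.

Denoising uses a 9-level multi-resolution decomposition with the `db6`
wavelet under **symmetric boundary extension**, the per-level coefficient
length being `floor((n + 11)/2)`. At 360 Hz the dyadic bands put baseline
wander inside the level-9 approximation (0–0.35 Hz) and mains interference
inside details 1–2 (45–180 Hz). Denoising *nullifies* those coefficient
blocks and reconstructs — no thresholding — so the operation is linear,
idempotent on its null space, and can only remove energy. Which blocks are
zeroed is configurable (`zero_approx`, `zero_detail_levels`, default
`{1, 2}`): zeroing D2 as well as D1 is the default because 50–60 Hz mains
lies inside D2 (45–90 Hz) while its harmonics fall in D1.

Two caveats are inherent to this scheme. The filters are not brick-wall:
a pure 0.2 Hz tone retains roughly 0.8 % of its energy after A9
nullification (transition-band leakage plus boundary transients), which is
why the removal properties are asserted on signals of several minutes.
And zeroing D1–D2 removes genuine QRS energy above 45 Hz — acceptable for
classification, but the denoised signal is not a faithful reconstruction.

## Segmentation

Each eligible beat yields a window spanning three beats: from the midpoint
of (R(i−2), R(i−1)) to the midpoint of (R(i+1), R(i+2)), inclusive. An
alternative "literal" mode measures both half-RR offsets from R(i) itself,
producing a ~1-RR window; the spanning interpretation is the default
because only it is consistent with a 3-beat span and with 1201 samples
(3.34 s) covering ≥95 % of windows at ambulatory heart rates. The two
modes are never mixed within a run.

Alignment places the central R sample exactly at index 600 of a
1201-sample output, zero-padding (the post-denoising baseline is 0 mV) or
cropping symmetrically around the R anchor. At a mean RR of 0.8 s the
3-beat span is ≈864 samples, so cropping (span > 1201, i.e. RR > 1.11 s)
affects well under 5 % of beats; the crop rate is logged on every run.
Beats whose class is excluded (paced, unclassifiable, non-beat) and beats
within two annotations of a record edge are counted and skipped, never
zero-extended.

Standardization is a scalar z-score per input channel — one mean/std over
*all* entries of the training matrix, fitted separately for the segment
matrix and the spectral matrix — applied unchanged to validation and test
data. Fitting happens inside each training fold only; the contract is
enforced structurally (the standardizer is created in `train_fold` from
the training subset alone).

## Spectral features

Input 2 stacks the detail coefficients D3‖D4‖D5 of a 5-level `db6`
decomposition of the segment: bands 22.5–45, 11.25–22.5 and
5.625–11.25 Hz, which bracket the QRS complex's spectral energy. For a
1201-sample segment the section lengths are (159, 85, 48), total 292.
Symmetric extension with `floor((n + L − 1)/2)` is the unique standard
convention producing 292; periodization would give 265 and is therefore
ruled out as the length convention.

## Architecture

Two branches with identical topology but different kernels (5 for the
1201-sample branch, 3 for the 292-sample branch): one standard Conv1D
lifting 1 channel to 16 feature maps, then two functional units. A
functional unit is `sepconv(stride 1) → BN → ELU → sepconv(stride 2) → BN
→ ELU`, doubling channel depth and halving length ("same" padding, so a
stride-2 layer maps L to ⌈L/2⌉). The branches exit at 301×64 and 73×64
and are **concatenated along the time axis** — they carry equal channel
counts and unequal lengths, so the time axis is the only shape-consistent
merge; the merged 374×64 sequence passes one further functional unit
(kernel 3), a max-pool (pool 2), a flatten, and dense layers
256 → 64 → 16 → softmax(4). Dropout 0.5 after the first dense layer and
0.2 after the second.

Layer census: 12 convolution layers (2 standard + 10 separable), 10 batch
normalizations, 10 activation layers, 1 max-pool, 4 dense layers. The
builder validates this census and refuses configs that violate it. ELU
nonlinearities on the dense layers (and optionally on the initial convs)
are *fused into* those layers rather than counted as separate activation
layers, mirroring how deep-learning frameworks count a layer with a
built-in activation; the initial convs are linear by default
(`initial_activation` flag).

Conv and separable-conv layers carry no biases, so the closed-form weight
counts `k·C_i·C_o` and `k·C_i + C_i·C_o` match the introspected weight
arrays exactly; dense layers keep biases. The dense sizes (256, 64, 16),
dropout probabilities and batch size are defaults exposed to the
hyperparameter search, not claims about a unique optimum.

The layers themselves (1-D convolution, depthwise separable convolution
with depth multiplier 1, batch normalization with running statistics, ELU,
max-pooling, dense, dropout, softmax) are implemented directly in numpy
with hand-written backward passes, verified against central-difference
gradients in the test suite. Weights are stored in single precision;
initialization is He-normal for convolutions and Glorot-uniform for dense
layers, seeded through a single generator per model.

## Training

Loss is categorical cross-entropy with per-sample class weights
`w_j = total/(4·n_j)` computed from the *training fold's* class counts
(inverse-frequency "balanced" weighting; weighting, not resampling, and no
data augmentation). Probabilities at the true class are clamped at 1e−7.
The optimizer is plain SGD (momentum configurable, default 0) with the
step schedule `η = 0.01 · 0.1^⌊epoch/30⌋`, batch size 64, at most 200
epochs, early stopping when unweighted validation accuracy fails to
improve for 20 epochs, restoring the best weights seen.

Stratified k-fold assignment distributes each class across folds with
per-class counts differing by at most one, deterministically under a seed.

The hyperparameter search is pluggable: `random` (reproducible default)
and `model_based`, a sequential strategy that fits a Gaussian-process
surrogate (Matérn 5/2 + white noise) to observed scores and proposes the
candidate with maximal expected improvement from a sampled pool. Failing
configurations score −∞ and stay in the trials log.

## Evaluation

One-vs-rest reduction of the 4×4 confusion matrix (rows actual, columns
predicted; class order N, VEB, SVEB, F): Se = TP/(TP+FN),
Sp = TN/(TN+FP), PPV = TP/(TP+FP), Acc = (TP+TN)/total,
F1 = 2TP/(2TP+FP+FN), G = √(Se·Sp). The specificity denominator is
TN+FP; the TN+FN variant circulates in some write-ups and is available
behind `specificity_denominator="fn"` for auditability, but only TN+FP is
consistent with the reference per-class tables this package reproduces.
Macro accuracy is the mean of the four one-vs-rest accuracies; the
"overall F-score" is micro-averaged F1, which for single-label
classification equals trace/total. Percentages are reported to two
decimals, round-half-even; undefined ratios (zero denominators) surface as
flagged NaNs, never silently as zero.

Protocols: **inter-patient** trains and validates on one patient set via
stratified CV and tests each fold's model on a disjoint patient set (the
canonical 30/14 record split when the record ids match it, otherwise a
seeded 70/30 record-level split), asserting that no record id crosses the
partition; **intra-patient** pools beats across patients, holds out a 20 %
stratified test set and cross-validates on the remaining 80 %.

## Synthetic data

`syndata` generates annotated records from Gaussian-bump PQRST templates:
N has P/Q/R/S/T bumps; VEB has a ≥1.5×-wider QRS, no P wave and a
discordant T; SVEB is N-shaped with an inverted P and a 0.7× preceding RR
(premature); F is the pointwise mean of the N and VEB templates. Classes
are drawn i.i.d. from a configurable mix (default 70/10/10/10 — majority
normal with realistic ectopic fractions), RR intervals are
`mean_rr · rr_scale(class) + U(−jitter, +jitter)`, and per-record mean RR
varies ±10 % so synthetic "patients" differ. Noise defaults used in the
experiments: 0.15 mV baseline wander at 0.2 Hz, 0.05 mV PLI at 60 Hz,
0.03 mV white noise — amplitudes chosen once as representative of
moderately contaminated ambulatory recordings.

What this emulates: the pipeline's geometry (sampling rate, annotation
stream, class imbalance, artifact spectra, heart-rate variability). What
it does not: real inter-patient morphology drift, electrode motion
artifacts, rhythm context (bigeminy etc.), or the intra-class variability
of real ectopy. Synthetic classes are far more separable than real ones,
so the end-to-end synthetic result (macro F1 ≈ 1.0 on held-out synthetic
patients at reduced training scale) validates the pipeline's plumbing and
protocol hygiene — it is *not* evidence of clinical-grade performance,
which requires the real corpus and full-scale training.

## Problem sizes used in the automated experiments

The end-to-end check trains on a 42-record, ~4 800-beat synthetic corpus
(90 s per record) with 2 CV folds and 8 epochs per fold — sizes chosen so
the whole experiment completes in minutes on a single CPU core while still
exercising every pipeline stage at realistic imbalance. The gradient
checks run on small tensors in double precision; training runs in single
precision.

## Known limitations

- The numpy training loop is CPU-bound and single-threaded beyond BLAS;
  it is meant for correctness and moderate-scale experiments, not
  large-scale training.
- WFDB support covers format 212 single/dual-channel records and the MIT
  annotation stream — enough for the reference corpus layout, not the full
  format zoo.
- Batch-normalization backward assumes the forward pass ran in training
  mode on the same batch (standard mini-batch training usage).
- The per-class metric table this package reproduces contains one
  internally inconsistent printed cell (the N-row specificity, which
  duplicates the sensitivity value); the implementation reports the
  formula-consistent value and the test suite documents the discrepancy
  rather than matching the misprint.
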