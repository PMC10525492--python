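# Methods

This note documents the models, the synthetic study conditions, and the
numerical choices behind `ictalkit`. Everything quantitative stated here is
computed by the test suite or by `scripts/acceptance.py`; nothing is quoted
from external results.

## Problem setting

Scalp EEG (10/20 montage, 21 electrodes including the earlobe references
A1/A2, microvolts) is annotated with labeled intervals: background (`bckg`)
or one of eight seizure types — focal non-specific (`fnsz`), generalized
non-specific (`gnsz`), simple partial (`spsz`), complex partial (`cpsz`),
absence (`absz`), tonic (`tnsz`), tonic-clonic (`tcsz`), myoclonic (`mysz`).
The pipeline answers two questions per 1 s window: *is this a seizure?*
(binary detection) and, if so, *which type?* (multigroup classification),
and adds three interpretability layers: mutual-information electrode
ranking, activation maximization, and dSPM source imaging.

## Preprocessing

Each recording is low-pass filtered at 40 Hz with a zero-phase FIR filter
(order `4 * rate / cutoff` rounded odd, Hamming-windowed design,
forward-backward application so labels stay time-aligned), polyphase
resampled to the working rate (250 Hz by default; 50–250 Hz in the
acquisition sweep), and cut into consecutive **non-overlapping 1 s
windows**; a trailing remainder shorter than the window is discarded. A
window takes the label of the annotation event with the largest overlap;
exact ties break toward the seizure label, which maximizes sensitivity at
event boundaries.

Each window is turned into a spectro-temporal tensor with a 64-point
short-time Fourier transform: the window is split into 8 equal
non-overlapping segments (31 samples at 250 Hz), each segment is demeaned,
tapered with a Tukey(0.25) window, zero-padded to 64 points, and reduced to
its one-sided magnitude spectrum (33 bins). The result is a
`channels x 33 x 8` tensor at any sampling rate, which keeps the model
architecture fixed across the rate sweep.

*Why Tukey rather than Hann:* the segments are half as long as the FFT
length, so a Hann mainlobe spans about four bins of the 64-point grid; the
spectral argmax of a pure sinusoid then depends on the segment's phase.
The near-rectangular Tukey(0.25) taper keeps single-bin localization for
every phase (verified over a phase sweep in the tests) while still damping
the edge-discontinuity sidelobes of a plain rectangular cut. Magnitude
(not power, not log) spectra are used; any further standardization is left
to the first batch-normalization layer of each model.

Splits are **grouped by annotation event**: all windows cut from one event
land in the same partition, for train/val/test splits (default
0.70/0.15/0.15, stratified by label, largest-remainder allotment within
each stratum) and for the stratified group k-fold used in cross-validation
(scikit-learn's `StratifiedGroupKFold`). Non-overlapping windows already
prevent sample sharing; event grouping is the stronger guarantee that no
within-event correlation leaks across partitions. Class imbalance is
handled with inverse-frequency weights `w_c = N / (K n_c)`, which satisfy
`sum_c w_c n_c = N`.

## Models

Both classifiers are trained with Adam (learning rate 1e-3, batch size 32)
on class-weighted softmax cross-entropy; accuracy, ROC-AUC, recall and
precision are recorded per epoch. They run on a small reverse-mode
automatic-differentiation core written on numpy (`ictalkit.nn`): im2col
convolution, 2x2 max pooling, batch normalization, dropout, ConvLSTM
recurrence, and a fused weighted cross-entropy, each backward pass verified
against central finite differences in the test suite. The same machinery
exposes input gradients, which activation maximization requires.

**Binary detector** — input `(C, 33, 8)` with electrodes as feature
channels and (frequency x time) as the 2D plane: three 3x3 stride-1
convolutions of 16/32/64 maps, each followed by ReLU, 2x2 max pooling and
batch normalization *after* the pooling; then dense 256 (ReLU) and dense 2
(softmax). With the 33x8 plane the spatial sizes run 33x8 → 16x4 → 8x2 →
4x1, so the flattened width is exactly 64·4·1 = 256. Padding 1 on every
convolution preserves the pre-pooling size.

**Multigroup typer** — the 8 STFT timesteps form the sequence axis; each
step is a one-channel `(C, 33)` image. Two ConvLSTM modules (16 then 32
filters, same-padded 3x3 gates so the hidden state keeps the frame size;
forget-gate bias initialized to 1), each followed by shared-parameter batch
normalization, per-step 2x2 pooling and dropout 0.3; the first module
returns the full sequence, the second its final hidden state; then dense
256 → dense 8 softmax. Electrodes sit on a spatial axis of the ConvLSTM
frames so per-electrode patterns survive into the interpretability stage.

The composed system routes each window through the detector first; only
windows predicted as seizure reach the typer (`pipeline_predict`).

## Synthetic cohort

The generator emulates the structure of a clinical seizure corpus without
reproducing any of its data. Background EEG is per-channel 1/f ("pink")
noise at 15 µV RMS plus a posterior-dominant, slowly waxing 10 Hz alpha
rhythm (10 µV, gain 1.0 at O1/O2 falling to 0.2 frontally). Each seizure
type has a fixed spatio-spectral signature (waveform, base frequency, scalp
topography, nominal amplitude):

| type | waveform | base freq | topography | amplitude |
|------|----------|-----------|------------|-----------|
| fnsz | rhythmic sine | 6.5 Hz | focal, focus T3 | 70 µV |
| gnsz | rhythmic sine | 4 Hz | generalized, flat | 80 µV |
| spsz | rhythmic sine | 7.5 Hz | focal, focus T4 | 60 µV |
| cpsz | rhythmic sine | 6 Hz | focal, focus T5 | 70 µV |
| absz | 3 Hz spike-wave | 3 Hz | generalized, Fz/Pz emphasis | 120 µV |
| tnsz | low-voltage fast | 20 Hz | fronto-central emphasis | 40 µV |
| tcsz | evolving chirp 10→3 Hz, growing envelope | 10 Hz | generalized, flat | 150 µV |
| mysz | polyspike bursts (≤0.5 s at 1 Hz) | 18 Hz | generalized | 90 µV |

Focal gains decay as `exp(-(d/0.65)^2)` with chord distance `d` from the
focus on the unit sphere; generalized gains stay ≥ 0.7 everywhere. Each
injected event is additionally scaled by a uniform ±25% amplitude factor —
real ictal amplitudes vary between events, and without this the absolute
level would be an artificial classification cue. The three focal/partial
types deliberately share the theta band and differ mainly by onset zone
(left mid-temporal, right mid-temporal, left posterior temporal): telling
them apart requires scalp *coverage* of the temporal chain, which is the
mechanism by which montage reduction degrades type classification. T5 is
absent from the reduced 8-electrode montage, so the fnsz/cpsz contrast is
the coverage-limited pair.

Default study conditions: 12 subjects, one 120 s record each at 250 Hz,
5 seizures per record of 6–12 s, class mix weighted toward the focal and
generalized non-specific types (fnsz 0.24, gnsz 0.22, cpsz 0.16, spsz
0.09, absz 0.08, tnsz/tcsz/mysz 0.07 each) so class weighting is genuinely
exercised. All randomness flows from one integer seed through
`numpy.random.SeedSequence` spawning, with per-record substreams; cohorts
are byte-reproducible.

A Bayes-style **template-matching oracle** (`oracle_classify`) bounds the
task difficulty independently of any trained network: per-channel log band
power (1 Hz bins, 1–40 Hz) is compared against per-class templates built
from the known signatures superposed on generator background; a window is
assigned to the class minimizing distance-to-centroid plus a smaller
nearest-phase-template term (the centroid averages out the per-template
noise floor; the per-phase term keeps position coverage for the evolving
chirp and burst waveforms). The oracle reaches ≥ 95% 8-class accuracy on
default-amplitude windows, so the learning task posed to the networks is
solvable.

What the generator does **not** emulate: biophysical forward mixing (the
toy leadfield lives only in the source-reconstruction module), ocular/EMG
artifacts, electrode noise heterogeneity, inter-subject spectral
variability, or evolving seizure morphologies beyond the chirp. Passing
parameter-recovery tests therefore demonstrates that the pipeline is
correct and learnable under known conditions — not that its numbers
transfer to clinical EEG.

## Electrode importance

The informative value of an electrode is the mutual information between
its raw sample values and the window label, estimated per time index with
an **equal-frequency 8-bin histogram** (rank-based binning, hence exactly
invariant to per-electrode monotone affine rescaling), averaged over the
window's time indices, over subsampled window draws, and over repeated
runs (defaults 1000 windows x 100 runs; desk-scale experiments use fewer).
A constant electrode scores exactly zero. Scores are min-max normalized to
[0, 1] (an all-equal vector maps to zeros) and ranked descending. The
ablation experiment repeatedly removes the minimum-MI electrode and
retrains the binary detector from 21 down to 8 electrodes; the fixed
comparison runs both tasks at the full and reduced montages under k-fold
CV and compares per-fold metrics with Welch's t-test and the Mann-Whitney
U test (two-sided), with D'Agostino-Pearson normality checks (skipped with
a warning below n = 8, scipy's minimum).

## Activation maximization

For a class unit, AM ascends `logit_c(x) - 1e-3 * ||x||^2` from
N(0, 0.1^2) initial input, 256 steps of size 0.1 by default, halving the
step up to 10 times whenever a step would decrease the objective (so the
objective is non-decreasing over accepted steps), and averages the final
inputs of 100 independent runs. The pre-softmax logit is maximized because
softmax saturation kills gradients. Because the model's inputs are spectral
magnitudes, a `nonnegative=True` mode projects the ascent onto x ≥ 0 each
step; this domain constraint yields markedly more class-faithful
prototypes.

What AM prototypes do and do not show here: the typer assigns
domain-constrained prototypes to their own class with mean probability
around 0.7 (chance 1/8) — they are class-specific — but their *dominant
single frequency bin* generally does **not** fall inside the class's
generator band. The 40 Hz low-pass leaves the tensor bins above ~40 Hz
with no data energy, so the network's behavior there is unconstrained and
AM freely deposits activation in those bins; class identity is encoded in
joint spatio-spectral patterns rather than one bin. This is the standard
caveat that AM visualizes what excites the model, not a spectral
measurement of the data, and the test suite asserts the class-specificity
property rather than per-bin band alignment. Per-electrode L2 energies of the
averaged pattern, min-max normalized, are rendered as topoplots:
thin-plate-spline interpolation of the azimuthal-equidistant electrode
positions onto a 64x64 disc grid, with a ring of virtual points at radius
1.25 carrying the data minimum to tame extrapolation overshoot (this keeps
a constant map exactly constant and the peak at the peak electrode).

## dSPM source imaging

The forward model is deliberately toy-scale so localization claims are
brute-force verifiable: 64 sources on a Fibonacci lattice over the upper
hemisphere of radius 0.9 inside the unit sensor sphere, leadfield
`exp(-d^2 / (2 * 0.35^2))` in sensor-source chord distance, columns
normalized to unit norm, rank-deficient geometries rejected. The inverse
chain is standard: noise covariance = sample covariance of the 100 ms
pre-onset baseline (channel means removed) plus 5% diagonal loading
(raised with a warning when the baseline is shorter than the channel
count); whitening by the covariance inverse square root; minimum-norm
operator `M = Lw^T (Lw Lw^T + lambda^2 I)^{-1}` with `lambda^2 = 1/SNR^2`;
dSPM value `|M x_w|_j / sqrt((M M^T)_jj)`, nonnegative by construction and
homogeneous of degree 1 in the data. Onset maps average dSPM over the
first 2 s from seizure onset. The lateralization index is
`(sum_L - sum_R) / (sum_L + sum_R)` over hemisphere sums (left = negative
x), and concentration is the activation fraction of the top 10% of
sources; both are NaN for an all-zero map.

*Regularization and exact localization.* dSPM carries a known localization
bias: at small `lambda` (SNR ≥ 1) a noiseless point source can peak at a
neighboring grid source (observed here for 5–15% of the 64 sources over a
wide range of forward geometries). In the regularization-dominated regime
the operator tends to `L^T / lambda^2`, the dSPM ratio for planted column
`l_j` reduces to `|l_{j'} . l_j| / |l_{j'}| = |l_j| cos(theta)` — maximal
exactly at `j' = j` for distinct columns, independent of the whitener — so
noiseless single-source recovery is provably exact there. The package
keeps SNR = 3 as the general-purpose default (at which recovered sources
stay within one grid-neighbor spacing) and runs the exact-recovery oracle
at SNR = 0.5. Only the 100 ms *pre*-onset segment enters the noise
covariance; using post-onset (ictal) data in a noise estimate would bias
the whitener toward suppressing the very activity being imaged.

## Desk-scale problem sizes

The shipped experiments and the acceptance script run the full method at
sizes a workstation handles in minutes, as the package's own study
conditions: the default cohort above (~1800 windows), detector training
for 8 epochs, typer training for 10 epochs, the montage comparison on a
focal-heavy cohort (8 subjects, fnsz/spsz/cpsz-dominated) for 8 epochs per
montage, the MI oracle over 100 estimator seeds, and the dSPM oracle over
all 64 sources. Histories show both classifiers converge well before these
epoch counts on the synthetic task.

## Known limitations

- The numpy training stack is single-process and CPU-bound; it is built
  for the desk-scale studies above, not for large corpora.
- The EDF writer emits plain 16-bit EDF (one data record per second);
  EDF+ discontinuous records and re-referencing are out of scope.
- The toy forward model supports methodological verification only; its
  source maps are not anatomical claims.
- Macro metrics skip classes with zero support in an evaluation split
  (reported as NaN, never silently zero); with very rare classes the
  event-grouped split can leave a class unevaluated.
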