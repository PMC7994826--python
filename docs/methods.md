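# Methods

## Overview

`tftslstm` classifies univariate physiological time series by first
compressing each record into a short sequence of four per-segment features —
two *time–frequency* features (instantaneous frequency, spectral entropy) and
two *time–space* features (fuzzy recurrence image entropy, fuzzy recurrence
entropy) — and then classifying the M × 4 feature sequence with a
bidirectional LSTM. The central premise is that the feature sequence is two
orders of magnitude shorter than the raw signal (M = ⌈L/128⌉), so the
recurrent network trains dramatically faster and, because the features
summarize spectral content and recurrence structure directly, usually more
accurately than the same network fed the raw samples.

## Feature definitions

Each record is split into M = ⌈L/N⌉ consecutive segments of N = 128 samples
(the last segment may be shorter). Per segment x_k, k = 0..n−1:

**Periodogram.** The segment is zero-padded to the next power of two, nfft,
tapered with a Kaiser window of length nfft, and transformed:

    P_j = |Σ_k w_k x_k e^{−i2πjk/nfft}|² / (W · nfft),   W = (1/nfft) Σ_j w_j².

Only the one-sided bins j = 0..nfft/2 (f ∈ [0, fs/2]) are kept, without the
interior-bin ×2 energy correction — both downstream features are invariant to
positive rescaling of the spectrum, so the correction would be absorbed
anyway.

**Instantaneous frequency (IF).** The power-weighted mean frequency
IF = Σ f_j P_j / Σ P_j, i.e. the spectral centroid in Hz, a discretization of
the continuous first-moment definition of instantaneous frequency.

**Spectral entropy (SE).** Shannon entropy in bits of p_j = P_j / Σ P_j,
reported unnormalized (range [0, log₂(nfft/2+1)]). Normalizing by log₂B would
be a constant scale that feature standardization removes.

**Fuzzy recurrence plot (FRP).** The segment is embedded in phase space
(dimension d, delay φ; d = 1, φ = 1 by default, where the "vectors" are the
scalar samples), the N_e = n − (d−1)φ vectors are clustered with fuzzy
c-means (c = 3, fuzzifier 2), and the membership matrix U (rows sum to 1) is
composed into the N_e × N_e grayscale matrix

    R(i,j) = max_q min(U_iq, U_jq),  R(i,i) = 1.

Reflexivity is imposed explicitly after the max–min composition, which by
itself yields max_q U_iq < 1 on the diagonal.

**Fuzzy recurrence image entropy (E_FRI).** R is quantized to 256 gray
levels (round half away from zero on 255·R); E_FRI is the Shannon entropy of
the normalized 256-bin histogram over **all** N_e² cells, including the unit
diagonal — the FRP is treated exactly as a grayscale image. Range [0, 8]
bits.

**Fuzzy recurrence entropy (E_FR).** The De Luca–Termini fuzzy-set entropy
Σ_ij [−μ log₂ μ − (1−μ) log₂ (1−μ)], zero on crisp matrices and maximal
(N_e²) at the all-0.5 matrix. Because its scale grows with the segment
length squared, the feature column stores E_FR / N_e² (the raw value is
retained alongside) so that a short trailing segment does not enter
standardization on a wildly different scale.

## Degenerate inputs

* Constant segment: the spectrum would be dominated by window leakage and
  the phase-space set collapses to one point; all four features are defined
  as 0 (their analytic limits: DC centroid, single-bin entropy, one-level
  image, crisp FRP).
* Zero-power spectrum: IF and SE return 0 with a `RuntimeWarning` rather
  than NaN, so standardization never sees non-finite values.
* Segment shorter than c+1 samples (can only be the trailing one): features
  fall back to zeros with a warning — too few points to cluster.
* A point coinciding with an FCM center receives crisp membership for that
  center (the standard convention avoiding division by zero).
* A zero-variance feature column keeps sd = 1 in the standardizer, mapping
  it to all-zero z-scores.

FCM is initialized from seeded uniform memberships and stopped when the
objective changes by < 1e-5 or after 100 iterations. Each segment uses a
sub-seed derived from (master seed, segment index), so feature extraction is
deterministic and independent of record order.

## Data preparation

Record lengths are equalized to the **modal** length: shorter records are
discarded, longer ones contribute ⌊L/mode⌋ chunks (remainder dropped), and a
tie between modes is broken toward the longer length (more signal retained;
configurable). Classes are balanced by repeating minority records
cyclically in their original order. Both operations record provenance:
every derived chunk and balancing copy carries its source recording's id.

Balancing is applied **inside each cross-validation training split only**,
and folds are formed over source recordings (grouped, stratified,
round-robin after a seeded per-class shuffle), so no chunk or copy of a
recording can appear on both sides of a train/test boundary. Feature
standardization (per-feature z-score pooled over training segments) is
likewise fitted per training split and applied frozen to the test fold.

## Classifier

One LSTM layer (hidden size 100) reads the feature sequence forward, a
second reads the time-reversed copy; the two final hidden states are
concatenated (200-dim) and mapped by a fully connected layer to two class
scores with softmax. "Last time step" read-out is the conventional choice
for a single recurrent layer feeding a dense classifier head. Gates use
the sigmoid activation; the candidate and cell-state activations use tanh.

Training: softmax cross-entropy minimized by Adam (β₁ = 0.9, β₂ = 0.999,
ε = 1e-8) at initial learning rate 0.01, mini-batches of 150 (capped at the
dataset size), at most 80 epochs, global L2 gradient-norm clipping at
threshold 1, and an L2 penalty of 1e-4 on the weight matrices (not biases).
Weights are initialized Glorot-uniform (input and dense), orthogonal
(recurrent blocks, per gate) with zero biases except a forget-gate bias of
1. All randomness (init, shuffling) flows from one seed, so a fixed seed
reproduces training bit-for-bit. The implementation is plain NumPy with
explicit backpropagation through time; the cell recurrences are verified
against a scalar oracle and the full gradient against central finite
differences in the test suite.

All sequences in one dataset share M by construction (length equalization),
so no padding or truncation ever occurs inside a mini-batch; mixed lengths
raise an error instead.

## Metrics and cross-validation

With the disease-like class positive: ACC = (TP+TN)/(P+N), SEN = TP/P,
SPE = TN/N, PRE = TP/(TP+FP), F1 = 2TP/(2TP+FP+FN). An undefined precision
(no positive predictions) is reported as 0 with a warning so fold means stay
total. Cross-validation reports per-fold values and their mean ± sd over
folds (k = 10 by default).

## Synthetic benchmark

The generator produces two-class datasets whose classes differ in
*dynamics*, not amplitude: noisy sinusoids (f₀ drawn uniformly from 8–12 Hz
per record, amplitude 1, Gaussian noise sd 0.2, fs = 300 Hz) versus the
X-component of the Lorenz system (σ = 10, ρ = 28, β = 8/3, fixed-step RK4 at
dt = 0.01, random initial condition relaxed through a 1000-step transient).
Every record is z-scored, so a classifier cannot win on scale alone.
Per-record sub-seeds make datasets byte-reproducible.

What this emulates: one narrow-band quasi-periodic class versus one
broadband chaotic class — the qualitative contrast between rhythmic and
dysrhythmic physiology. What it does **not** emulate: waveform morphology
(QRS complexes, gait cycles), nonstationarity, artifacts, inter-subject
variability, or realistic class overlap. Passing the benchmark therefore
demonstrates that the pipeline's machinery is correct and that its
efficiency advantage is real, not that clinical-grade accuracy transfers to
any particular dataset.

The benchmark (`tftslstm.run_synthetic_benchmark`) runs 100 records per
class of length 1280 (M = 10 segments) under tenfold grouped CV twice: from
feature sequences and from the raw 1280-step signals, with the same network
(hidden 100) and the same epoch budget. The budget defaults to 4 epochs
with mini-batches of 50 — far below the 80-epoch training maximum — because
the synthetic classes separate quickly and the raw arm costs ~13 s per epoch
on one CPU; the comparison needs matched budgets, not converged raw
training. Reported quantities: per-metric mean ± sd for both arms and the
raw/feature per-epoch wall-time ratio.

## Known limitations

* Binary classification only; the dense head validates n_classes = 2.
* FCM minimizes a non-convex objective; different seeds can yield different
  (label-permuted or locally optimal) memberships. The FRP is invariant to
  cluster relabeling but not to genuinely different local optima; per-segment
  sub-seeding makes results reproducible rather than seed-free.
* The WFDB reader supports format 16 single-file records only — enough for
  locally downloaded PhysioNet data converted to that format; anything else
  should be exported to the native CSV layout.
* The NumPy training loop is single-threaded BLAS-bound; it is intended for
  feature sequences (M ≈ 10), where it trains in seconds. Raw-signal
  training exists for the comparison, not as a practical path.
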