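# Methods

This note documents the models, estimators and numerical choices behind
`eegsae`, and what its synthetic benchmarks do and do not show.

## Problem setting

The package implements an interictal-EEG classification chain for
distinguishing patients with psychogenic non-epileptic seizures (PNES, the
positive class) from healthy controls (CNT): 19-channel scalp EEG in the
10-20 montage at 256 Hz is cut into non-overlapping 5 s epochs, each epoch is
reduced to 228 engineered time-frequency features, a two-stage stacked sparse
autoencoder compresses those to a 20-dimensional code, and a softmax head maps
the code to class probabilities. Because each epoch is a separate record, a
cohort of 10 CNT + 6 PNES subjects with 20 epochs each yields 320 training
records — the epoching is the data-augmentation device that makes a deep
model trainable on a small clinical cohort. Alongside the classifier, the
package quantifies *what* the network learns, by estimating the Shannon
entropy of each hidden node's activation distribution per class.

The clinical recordings this design targets are not redistributable, so the
package ships a synthetic cohort generator that reproduces the *structure* of
such data; all shipped benchmarks are properties of that synthetic system.

## Synthetic EEG generator

Each subject's recording is

    x_c(t) = A * ( sqrt(1-m) * n_c(t) + sqrt(m) * s(t) ) + sum_k w_ck * osc_k(t)

where `n_c` and `s` are independent unit-RMS 1/f^beta pink-noise processes
(per-channel and shared, beta = 1), `m` (default 0.6) is the shared-variance
fraction producing realistic inter-channel correlation, and `A` = 10
microvolt-like units. Class-specific oscillations `osc_k` are sinusoids with
per-channel weights `w_ck` (default 1), optionally gated by Hann-windowed
bursts: a burst of `burst_duration_s` seconds is placed once per duty cycle
at a jittered onset.

Default class profiles:

| class | oscillations | character |
|---|---|---|
| CNT | 10 Hz, amplitude 8, sustained | alpha-like background rhythm |
| PNES | 3 Hz amp 14 + 5 Hz amp 10, duty 0.5, 1 s bursts | intermittent low-frequency bursts, higher relative strength |

Amplitudes are relative to the RMS-10 background. The PNES duty cycle of 0.5
guarantees that every 5 s epoch contains bursts, i.e. the class signal is
present per epoch, not only on average — the regime the epoch-level
classifier assumes. Per-subject jitter (default 5%) perturbs amplitudes and
frequencies. All randomness derives from one integer seed via
`SeedSequence(seed, spawn_key=(class, subject))`, split further into
shared-source, oscillation and per-channel streams, so cohorts are
bit-reproducible.

A matched *null* configuration (`null_class_profiles()`) gives both classes
the identical CNT-style profile with zero subject jitter. Jitter is removed
deliberately: under epoch-level leave-one-out the remaining epochs of the
test subject stay in training, so any stable per-subject offset is leakable
identity information that would push a no-signal cohort away from chance for
reasons unrelated to class.

What the generator does **not** emulate: physiological forward-model
topographies, eye-blink/EMG artifact morphology, non-stationary vigilance
drift, reactivity tasks. Passing benchmarks therefore demonstrate that the
pipeline recovers class-specific low-frequency periodic structure under
realistic noise and channel correlation — not clinical performance.

## Time-frequency features

Each epoch channel is transformed with the continuous wavelet transform

    CWT(a, tau) = a^(-1/2) * Int eeg(t) psi((t - tau)/a) dt,

discretized as a Riemann sum with dt = 1/fs over the epoch support (the
epoch is treated as compactly supported; zero padding, no reflection). The
mother wavelet is the L2-normalized Mexican hat (Ricker),

    psi(t) = 2 (sqrt(3 sigma) pi^(1/4))^(-1) (1 - t^2/sigma^2) e^(-t^2/(2 sigma^2)),

real and zero-mean. The fast implementation evaluates the same discrete sum
by FFT cross-correlation and agrees with the double-loop definition to
machine precision; the test suite keeps an independent brute-force oracle.

Scale-to-frequency mapping: a pure sinusoid of frequency f maximizes the
a^(-1/2)-normalized response at a = sqrt(5/2)/(2 pi sigma f), so
pseudo-frequency is defined as f(a) = sqrt(5/2)/(2 pi sigma a). With this
convention a sinusoid's ridge sits at its own frequency on the
pseudo-frequency axis (the common |Psi-hat|-peak convention, sqrt(2)/(2 pi
sigma a), would displace it by a factor 0.894). Default grid: 64
log-spaced scales covering 0.5-32 Hz; scales whose dilated support exceeds
ten epoch lengths are flagged as edge-dominated rather than dropped.

The scale axis is partitioned into three contiguous sub-bands, default edges
0.5 / 4 / 8 / 32 Hz (the two lower bands roughly covering the delta and
theta rhythms); the edges are configurable. For the whole map and each
sub-band map, the mean, standard deviation (population convention) and
skewness (third standardized central moment, defined as 0 when the sd is 0)
of the raw coefficients are computed — absolute or squared coefficients are
available behind a switch. 12 statistics x 19 channels = 228 features in a
fixed channel-major layout.

## Preprocessing

Recordings are band-pass filtered 0.5-70 Hz with second-order zero-phase
Butterworth sections and a Q=30 IIR notch at 50 Hz, on a 2 s mirror-padded
extension (the 0.5 Hz high-pass has ~0.6 s edge transients which must not
ring the notch inside the data). Visual artifact rejection is replaced by an
automated stand-in: an epoch is rejected if any channel exceeds a
peak-amplitude threshold (default 100 units) or its range falls below a
flatline tolerance; screening can be disabled for pre-cleaned data. Epochs
are cut greedily from t = 0 on a fixed 5 s grid; rejected windows are
skipped, preserving non-overlap and temporal order.

## Stacked sparse autoencoders

Features are min-max scaled to [0, 1] per dimension on training data only
(constant features map to 0.5; test values are clipped). Autoencoder 1 maps
228 -> 50, autoencoder 2 maps the codes 50 -> 20; both are sigmoid
encoder/decoder pairs with untied weights minimizing

    J = (1/2n) sum ||x_hat - x||^2 + (lambda/2) ||W||^2 + beta sum_j KL(rho || rho_hat_j)

with Bernoulli KL divergence on each node's mean activation rho_hat_j.
Defaults: rho = 0.05, beta = 1, lambda = 1e-4. Training is full-batch
L-BFGS (max 400 iterations), initialized with fan-in-scaled symmetric
uniform weights from a seeded generator; (data, config) reproduces weights
bitwise. The autoencoder stages never receive labels. The softmax head is a
two-way multinomial logistic regression on the 20-dimensional code, trained
by L-BFGS on the cross-entropy with the same weight decay.

Optional supervised fine-tuning backpropagates the cross-entropy through
encoder1 -> encoder2 -> softmax with full-batch gradient descent and
backtracking (a step that increases the loss is undone and the rate halved),
so the loss trace is non-increasing by construction. Fine-tuning matters:
on the synthetic benchmark cohorts it recovers class information the purely
unsupervised compression discards, lifting held-out epoch accuracy by
roughly ten points; the leave-one-out benchmark protocol therefore fine-tunes
each fold's stack for 100 epochs.

Electrode importance is read off the trained weights as the absolute-weight
path mass |W_softmax||W_enc2||W_enc1|, summed over each channel's 12 input
features and normalized to sum to one.

## Evaluation protocol

Epoch-level leave-one-out: each of the N epochs is held out in turn and the
entire chain — scaler, both autoencoders, softmax, fine-tuning — is refit on
the remaining N-1 (per-fold seeds derive from the run seed and fold index).
This is faithful to the augmentation idea but leaks subject identity (other
epochs of the held-out subject remain in training); the stricter
leave-one-subject-out protocol is available as an option. Metrics are
sensitivity, specificity, PPV, NPV and accuracy in percent with PNES
positive; zero-denominator ratios are reported as NaN with an explicit flag.
Subject-level decisions aggregate a subject's epochs by mean posterior
(default) or majority vote with mean-posterior tie-break. Shallow baselines
(shrinkage LDA, shrinkage QDA, linear- and quadratic-kernel SVM) run on
identical fold splits, verified by a fold checksum.

## Entropy analyses

Hidden-node entropy: for each node of H1 (50) and H2 (20), the activations
over all epochs of one class form a vector in (0, 1); its Shannon entropy is
estimated by a plug-in histogram with 32 equal-width bins on [0, 1], base-2
logarithm (0 log 0 := 0). The per-class reading of the node vectors is the
default; bin count is configurable and recorded. The class contrast at a
layer is mean(SE_PNES) - mean(SE_CNT) over nodes, with a two-sided
permutation p-value obtained by shuffling epoch labels (the encodings are
fixed — they never depended on labels).

Raw-signal controls: per epoch channel, Shannon entropy of the amplitude
histogram (64 bins over the epoch's own min-max range) and normalized
permutation entropy (ordinal patterns of order m = 3, delay 1, ties broken
by order of occurrence, normalized by log m!). The histogram range and the
PE parameters follow standard practice; per-epoch amplitude ranges avoid
degenerate bins when scales differ across epochs.

On the default synthetic cohorts two regularities hold and are asserted by
the benchmark suite: mean node entropy decreases from H1 to H2 for both
classes, and the between-class entropy contrast is concentrated at H2
(|contrast_H2| > |contrast_H1| in at least 4 of 5 seeds at the full cohort
size). The *sign* of the H2 contrast on synthetic data is not asserted —
which class occupies more of the code's dynamic range depends on the class
profiles, and on the burst-dominated PNES profile it can go either way.

## Problem sizes of the shipped benchmarks

Cardinality and protocol checks run on the full cohort structure (10 + 6
subjects x 20 epochs = 320 records). Leave-one-out accuracy properties run
on a reduced cohort (4 + 4 subjects x 10 epochs = 80 folds) over three
seeds, with recordings 60 s long — just enough to hold the epochs used,
since the generator is stationary; entropy-structure properties run on
full-size cohorts over five seeds. Measured on these conditions: epoch-level
LOO accuracy 91.25 / 88.75 / 96.25 % (mean 92.1 %), subject-level accuracy
100 % in every seed, null-cohort accuracy 47.5 % (chance band [39.0, 61.0] %
at n = 80).

## Known limitations

- Epoch-level LOO overstates generalization to new subjects; use
  `subject_loso` for a subject-generalization estimate.
- The synthetic effect size is a design choice; none of the shipped numbers
  estimate clinical performance.
- The histogram entropy estimator is biased for small per-class epoch
  counts; comparisons are made at matched sample sizes only.
- The hand-rolled EDF writer covers continuous 16-bit EDF with one-second
  records and integer sampling rates; EDF+ annotations are out of scope.
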