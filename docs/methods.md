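# Methods

This note documents the models, parameters and design choices behind
`ecgkey`, in the package's own terms. Nothing here states an empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## Synthetic ECG model

A subject is a template of five Gaussian waves (P, Q, R, S, T), each with an
amplitude (mV), a center (ms relative to the R peak) and a width (Gaussian
sigma, ms). A beat is the sum of the five Gaussians; a record is a train of
beats at a constant heart rate with 2% per-beat RR jitter, the first and
last beat kept 0.5 s clear of the record edges. Because beats are analytic,
every record carries exact ground-truth fiducials: wave peaks at the
Gaussian centers, wave onsets/offsets at +/-3 sigma (P and T), and the QRS
support from 3 sigma before the Q center to 3 sigma after the S center.

Template parameters are drawn from population priors whose spreads follow
standard adult lead-I normal limits (R amplitude 1.0 +/- 0.35 mV clipped to
[0.4, 2.2]; P 0.15 +/- 0.05 mV; T 0.30 +/- 0.12 mV; P center -165 +/- 20 ms;
T center 180 +/- 30 ms; widths with proportionate spreads; baseline heart
rate 72 +/- 10 bpm clipped to [55, 95]). The spreads matter: the quantizer
operates in population-standardized feature space, so the ratio of
intra-subject session drift to inter-subject spread is the single number
that governs seed stability.

Session-to-session variability emulates dry-electrode repositioning and
autonomic state: one multiplicative amplitude factor per session drawn from
U(0.85, 1.15) applied to all five waves, plus an independent additive timing
offset per wave per session from N(0, 4 ms). Noise presets add baseline
wander (a <= 0.5 Hz sinusoid, default 0.08 mV at 0.3 Hz), 60 Hz powerline
interference (default 0.04 mV) and white noise (default 0.015 mV RMS).

What the generator does **not** emulate: heart-rate-variability spectra,
respiration coupling, arrhythmia or ectopy, motion/EMG artifacts, electrode
pop, and morphology drift within a session. Passing tests on this cohort
therefore demonstrate the correctness and the qualitative behaviour of the
pipeline — not field performance on real dry-electrode recordings.

## Preprocessing

* Denoising: second-order IIR notch at 60 Hz with quality factor 30, and a
  third-order Butterworth high-pass at 0.5 Hz, both applied
  forward-backward (zero phase, so fiducials are not shifted).
* Delineation: the à-trous algorithm with the quadratic-spline filter pair
  (smoothing [1,3,3,1]/8, detail [2,-2]) gives detail signals at scales
  2^1..2^4 whose zero crossings track extrema of the smoothed signal and
  whose modulus maxima track its steepest slopes; filter group delays are
  compensated per scale. QRS complexes are groups of alternating-sign
  modulus maxima at scale 2^2 above 0.25x the 99th-percentile modulus; the
  R peak is the zero crossing of the strongest adjacent opposite-sign pair,
  refined to the waveform maximum within +/-30 ms, with a 250 ms refractory
  period. QRS onset/offset sit where the modulus falls below gamma_on = 0.05
  / gamma_off = 0.09 of the group's peak modulus, walking outward from the
  outermost extremum of the contiguous group (<= 40 ms gaps). Q and S are
  the waveform minima flanking R inside the QRS support — for this wavelet
  the scale-1 detail zero crossings coincide with those extrema, and the
  direct form is more robust. P and T waves are located the same way at
  scale 2^4 inside [R-280, R-80] ms and [R+80, R+450] ms, with
  onset/offset at the 0.25x-modulus crossings and peaks refined as the
  largest |deviation from the local median baseline| (this also handles
  inverted waves). Beats with out-of-order landmarks or windows that leave
  the record are dropped. All thresholds are exposed in
  `PreprocessConfig`.
* Upright-R assumption: R-peak refinement takes the waveform maximum, so a
  predominantly negative QRS (rare in lead I, not produced by the
  generator) would need the refinement window sign flipped.
* Normalization: the beat window (R-250 ms .. R+450 ms) is warped
  piecewise-linearly with every landmark anchored to an integer target
  index: Pon -> 0, QRSon -> 160 ms, QRSoff -> 255 ms, Toff -> 565 ms-worth
  of samples (PR 160 ms, QRS 95 ms, ST 310 ms at 500 Hz: indices 0, 80,
  128, 283), interior landmarks proportionally within their section, and
  the post-Toff tail resampled into the remainder of a fixed 600 ms output
  beat. Anchoring landmarks to integers conserves their amplitudes exactly
  and makes the warp idempotent. The observed heart rate is 60 / median RR
  and is validated against [30, 180] bpm; the standard durations are fixed
  textbook targets rather than a regression on heart rate, and are
  configurable.
* Outlier rule: template = pointwise mean of all beats; beats with Pearson
  correlation below mean(rho) - 0.5*std(rho) are removed. Note that for
  homogeneous beats with roughly normal correlation spread this removes
  ~30% of beats by construction; with ~23 beats in 20 s, 14-18 survive,
  comfortably above the 3 needed per ensemble. Identical beats (std = 0)
  are never removed; beats with zero variance get rho = 0.
* Ensemble: mean of the 3 surviving beats with the highest correlation to
  the post-removal template (ties to the earlier index); `selector_start`
  shifts the selection down the ranking so one record yields several
  independent ensembles. Ensemble fiducials default to the per-landmark
  median of the three source beats: after normalization the section
  boundaries are identical across beats by construction and interior
  landmarks differ by at most one sample, so the median is exact.
  Re-delineation of the averaged beat is implemented as an alternative
  (`ensemble_fiducials: redelineate`).

## Features

Amplitude endpoints are wave peaks (Ppk, Q, Rpeak, S, Tpk). `AB amplitude`
is amp(A) - amp(B) — the RS amplitude of an upright beat is the positive
peak-to-trough drop; `AB interval` is t(B) - t(A) in ms; slopes divide the
amplitude change by the (normalized) time difference; distance features are
the Euclidean norm of the (delta-t in ms, delta-amp in mV) vector with no
unit rescaling (documented convention — the two axes are deliberately mixed);
the QRS area integrates |signal - baseline| over the QRS support with the
baseline taken as the mean of the 20 ms preceding QRS onset.

## Personalized selection and quantization

* ReliefF: two-class, every instance used once, k = 10 neighbors (clamped
  to class size - 1 with a warning), Manhattan distance on min-max scaled
  features, weight = mean miss-difference minus mean hit-difference averaged
  over instances; constant features get weight 0. The control class is an
  equal-size sample without replacement from the population feature rows.
  The top 10 weights (ties to the lower feature index) form `Fidx`.
* Multicollinearity screen: all 45 unordered pairs of the Fidx features;
  pairs with |Pearson r| >= r_max = 0.8 on the population training matrix
  are excluded, as are pairs touching a constant column.
* Per-pair k-means: features standardized by the training mean/SD; k in
  {2, 4} fitted with 10 restarts, 300 iteration cap, tolerance 1e-4, fixed
  seed. Criterion `pm` takes the k with maximum silhouette; criterion `pu`
  requires silhouette >= theta_s = 0.4 and among qualifying k picks the one
  maximizing the minimum cluster fraction (ties: higher silhouette, then
  smaller k); when no k qualifies the pair is dropped rather than falling
  back to pm — this is what produces subject-specific seed lengths.
  theta_s and r_max are configuration values; 0.4 sits at the customary
  boundary between weak and reasonable cluster structure.
* Labels are re-assigned in ascending centroid-coordinate order
  (lexicographic on the 2-D standardized centroids) so the label-to-bit
  mapping survives refitting; nearest-centroid ties take the lower label.
  Label C with k clusters emits the binary of C-1 in k/2 bits; model order
  is the lexicographic pair order; the concatenation is zero-padded to the
  next power of two (a fixed length can be forced in configuration).
  Enrollment quantizes every surviving beat of the first session and takes
  the per-model modal label (ties to the lowest label).

## Fuzzy extractor

Code-offset construction with a shortened binary BCH code: for a seed of
length n_s, the code is the BCH code of natural length n = 2^m - 1 (the
smallest m with 2^m - 1 >= n_s) shortened to n_s, with generator polynomial
built from the minimal polynomials of alpha^1..alpha^2t and
t = ceil(tau * n_s). Decoding is syndrome computation, Berlekamp-Massey,
and a Chien search; decoding fails (reproduction failure, hence rejection)
when the error locator degree or its root count is inconsistent or an error
is located in the shortened region. Gen consumes the padded seed — the pad
count is recorded with the clustering models precisely so reproduction
matches. The key is SHA-256(salt || seed) truncated to l = 128 bits
(extended by hash chaining for longer l); Rep recovers the enrolled seed as
sketch XOR corrected-codeword and re-derives the key, so seeds differing by
more than t bits yield a different key (or an explicit failure) rather than
a silent collision. The effective entropy of the key is bounded by the seed
entropy (at most the unpadded width, in practice less), not by l; l = 128
is an interface convenience, not a security claim.

## Evaluation

Error seed rate = 100 x (#reproduced seeds differing from the enrolled) /
#trials; error bit rate = 100 x mean Hamming distance among error seeds /
seed length (flagged zero when there are no error seeds). Entropies are
empirical per-bit Shannon and min-entropy, reported both per key (then
averaged) and pooled; seed entropies are computed on the unpadded bits.
The four randomness tests use the standard closed forms (erfc for the
monobit and runs tests, the regularized upper incomplete gamma for the
block-frequency and longest-run chi-square statistics) with the tabulated
longest-run category probabilities for block sizes 8/128/10000; block sizes
below the recommended sequence lengths warn rather than refuse, since
bio-keys are short. FAR is reported exactly as defined in the source
formulation, FP / (FP + FN), with the conventional FP / (FP + TN) available
under a separate key (`far_conventional`) — the printed denominator is
unusual but is reproduced as stated rather than silently corrected.
The comparison baseline is a fixed-length binarizer: each of the 29
features is coded into equal-width bins of its population range with
ceil(152/29) = 6 bits per feature, concatenated and truncated to 152 bits —
a representative global interval coder with no personalization, labeled
approximate.

## Cohort evaluation and expected behaviour

`ecgkey.cohort` simulates a population plus a multi-session cohort, enrolls
each subject on session 0, reproduces seeds from each later session
(genuine trials) and from other subjects' sessions quantized with the
claimant's model (impostor trials), and sweeps tau over
{0.01, 0.03, 0.05, 0.07, 0.09}. The acceptance configuration is 20 subjects
x 10 sessions against a 90-subject population; preprocessing is cached so
the criterion and tau sweeps are cheap. Problem sizes in the test suite
(smaller cohorts for the examples, 500 x 10,000-bit strings for the
randomness-test calibration) are chosen to keep a full run in the
minutes range on one CPU.

Under these defaults the qualitative findings hold: FRR is non-increasing
and FAR non-decreasing in tau (accept/reject depends on the seed Hamming
distance against a capacity that grows with tau); the dynamic quantizer's
error seed rate is far below the 152-bit baseline's; and the pu criterion
outperforms pm on mean accuracy (pm keeps weakly clustered pairs whose
labels are unstable). The absolute genuine-accept rate at tau = 0.05 sits
near 0.83 with impostor accepts near 0.13 on this synthetic cohort: the
prescribed session variability (amplitude factor U(0.85, 1.15), per-wave
timing jitter N(0, 4 ms)) moves a subject's features by a substantial
fraction of the population spread, and subjects whose feature pairs sit
near cluster boundaries flip more bits than t = ceil(0.05 x seed length)
tolerates. This is a property of the simulated study conditions — with the
session factors disabled, seeds are bit-stable — and is reported as
measured rather than calibrated away.

## Known limitations

* Single-lead, upright-R, pathology-free morphology only.
* The wavelet delineator is tuned for the generator's morphology family;
  real recordings would need threshold adjustment (all config-exposed).
* The baseline binarizer is a representative reconstruction of fixed
  interval coding, not a line-by-line port of any specific prior coder.
* No attempt is made at formal entropy-loss accounting for the sketch, or
  at secure storage/transport of IDs.
* Record input is CSV (seconds, millivolts) with a JSON fiducial sidecar;
  binary waveform-database formats are out of scope.
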