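# Methods

This note documents the models, algorithms and design choices behind
`fingerbeat`: what each stage assumes, which parameters matter, what the
synthetic generator does and does not emulate, and the numerical
conventions used throughout.

## Synthetic finger-ECG model

Real finger-ECG corpora for this task are not publicly deposited, so the
package generates its own study population. Each subject is a
*morphology*: five Gaussian waves (P, Q, R, S, T), each with a centre
offset relative to R (ms), an amplitude (mV) and a width (ms), drawn
uniformly from physiologically plausible ranges (e.g. R amplitude
0.8–1.5 mV and width 9–15 ms; T centre 210–300 ms and width 40–70 ms) at a
reference RR interval of 1000 ms. The ranges are wide enough that two
random subjects are distinguishable with high probability, while overlaps
keep the population non-trivial.

A recording places beats on an RR grid derived from a heart-rate profile
interpolated piecewise-linearly over the duration; the default profile
ramps 133 → 70 BPM, the span a finger-ECG acquisition can realistically
cover, which exercises the time-normalization stage hard. RR jitter is
zero-mean Gaussian (default σ = 20 ms, an ordinary short-term heart-rate
variability), truncated so RR stays within [400, 2000] ms — the validity
band the detector enforces. Each beat is the reference shape *time-scaled*
by `RR_local / 1000 ms`: both wave offsets and widths compress at high
rate, emulating the waveform compression heart-rate changes produce. The
first beat sits half an RR interval into the recording, and no beat is
placed closer than 150 ms to the end, so every emitted beat has a complete
QRS; ground truth lists every R centre and every scaled wave centre.

Additive disturbances emulate the main finger-ECG noise sources: baseline
wander (default 0.1 mV sinusoid at 0.3 Hz), white Gaussian noise (default
σ = 0.05 mV; no quantitative SNR is established for finger ECG, so this is
exposed as the principal severity knob), and 50 Hz mains pickup (default
0.02 mV, European mains). Defaults deliberately exercise both stopbands
of the [0.5, 30] Hz filter.

**What the generator does not emulate:** arrhythmia and ectopic beats,
electrode-contact artifacts and motion transients, day-to-day morphology
drift (all recordings are single-session), T-wave rate-dependence beyond
pure linear scaling (real QT shortens roughly with √RR), and amplifier
quantization. Perfect scores on this population therefore demonstrate
correctness of the pipeline's mechanics — detection, delineation,
normalization, matching — under controlled rate variation and additive
noise; they do not predict field accuracy on real finger ECG, where
inter-subject similarity and non-stationary noise are harsher.

## Band-pass filter

A windowed-sinc (Hamming) linear-phase FIR band-pass with edges at 0.5 and
30 Hz. The tap count defaults to `1.5·fs / low` rounded to odd — 3001 taps
at 1000 Hz. The low edge drives this choice: the design must attenuate DC
by more than 20 dB with a band edge at only 0.5 Hz, and shorter designs
(e.g. ~2000 taps, −16 dB at DC) leave too much baseline wander. The
realized response at 1000 Hz is −35 dB at 0 Hz, −78 dB at 50 Hz, and flat
(|ripple| < 0.5 dB) across 2–25 Hz. Filtering convolves a
reflection-padded copy of the signal and takes the 'valid' centre, which
compensates the constant (N−1)/2-sample group delay exactly; edges carry a
startup transient of at most one group delay. A record must be longer
than the filter; at the default 1000 Hz this means recordings under ~3 s
are rejected rather than filtered badly.

One consequence worth knowing: at high heart rate the QRS narrows (σ ≈
5 ms at 133 BPM), pushing part of its energy above 30 Hz, so the filter
attenuates fast-rate R waves slightly more than slow-rate ones. This is a
property of the band, not a defect of the normalization; the per-
acquisition amplitude normalization absorbs most of it.

## QRS detection

The filtered signal passes through a differentiator, a 4-sample comb, and
a 5-point binomial smoother (weights 1, 4, 6, 4, 1), with samples before
index 0 taken as zero. The cascade's impulse response is
`[1, 3, 2, −2, −4, −4, −2, 2, 3, 1]`; a positive R spike yields a
pronounced negative lobe flanked by two smaller positive lobes.

The original algorithm's fixed thresholds assume calibrated amplitudes;
here the thresholds adapt to the signal: over non-overlapping 2 s windows
the 98th percentile of |y2| is computed, and the negative/positive
thresholds are −0.4× and +0.1× that statistic. This makes detection
invariant to overall gain while tracking slow amplitude drift. A
candidate is a contiguous run of y2 below the negative threshold whose
neighbourhood (80 ms each side) rises above the positive threshold on
*both* sides — the two-sided requirement is what rejects inverted-polarity
spikes. Each candidate is refined to the local maximum of the filtered
signal within ±50 ms, which also absorbs the cascade's ≈4.5-sample delay
without analytic correction.

RR validation enforces the physiological band: candidate pairs closer
than the 150 BPM minimum latency (400 ms at 1000 Hz) are resolved by
keeping the one with the deeper negative lobe; gaps longer than the
30 BPM maximum (2000 ms) are logged as segment boundaries but delete
nothing. A first or last peak with a single valid neighbouring RR is
accepted.

## Delineation and beat validity

Around each validated R, the y2 negative-lobe minimum is located within
±50 ms; the positive excursions of y2 immediately before and after it,
mapped back to signal coordinates by subtracting the constant 4-sample
cascade delay, give the intervals `[iStartQ, iEndQ]` and
`[iStartS, iEndS]`. Q and S are the minima of the filtered signal on
those intervals. P is the maximum on `[R − PQR-latency, iStartQ]` and T
the maximum on `[iEndS, R + RST-latency]`, with latency bounds of 250 and
400 ms — standard physiological upper limits, configurable.

Both latency bounds are multiplied by the beat's local time-scale (local
RR over the 1 s reference, clamped to [0.4, 2]). Without this, at 133 BPM
the fixed 250 ms P-window reaches into the *previous* beat and captures
its T wave as "P". The local RR comes from the validated R peaks
themselves, so the delineator needs no oracle information.

A beat is valid iff its fiducials are correctly ordered, the P and T peak
amplitudes are strictly positive, and the P peak precedes Q by at least
30 ms (the lead rule is applied peak-to-trough; the delineator produces
no P onset to apply it to). Beats whose search window falls off the
record edge are skipped with a logged reason — never an exception.

## Normalization

Each valid beat is resampled in two parts onto a fixed 300-sample grid:
`[P onset, R]` to 100 points (endpoints included, so point 99 is exactly
the R sample) and `(R, T end]` to 200 points, by linear interpolation —
monotone, overshoot-free, exact at segment endpoints. The 100/200 split
reflects that the R-to-T-end span exceeds the P-onset-to-R span
physiologically; both counts are configurable with their sum fixed at 300.

The delineator yields peak positions only, so P onset is defined as the P
peak minus 80 ms and T end as the T peak plus 120 ms, clipped to the
beat's search window. These paddings, like the latency bounds, are scaled
by the local RR: beat-anchored two-part resampling inverts rate
compression exactly only if *every* anchor, paddings included, compresses
with the beat. With scaled paddings, noise-free beats of one subject at
70 and 133 BPM normalize to the same 300-vector to within 0.2% RMS of the
R amplitude (interpolation error only); with fixed paddings the T wave
lands ~40 samples apart between those rates and the match degrades to
~15% RMS, dominating every downstream distance.

Amplitude normalization divides all of an acquisition's beats by the
single mean detected R amplitude, making the mean normalized R exactly 1;
a non-positive mean indicates an upstream polarity failure and raises.

## Templates and matching

A template is the element-wise mean of normalized beats — the features
are the amplitudes of the mean heartbeat itself, a deliberately compact
single-wave representation. Matching is Euclidean: identification picks
the enrolled subject at minimum distance (1-NN), breaking exact ties by
the lexicographically smallest identifier so results are deterministic;
authentication accepts iff distance < threshold, with equality rejecting
("inferior to" read strictly).

## Evaluation protocol

Cross-validation runs 30 independent rounds. Per round and subject, a
random permutation assigns 30 beats to the enrollment template and the
next 30 (disjoint) to the test template; all test-vs-enrollment distances
form that round's matrix. Identification decisions populate a confusion
matrix (one decision per subject per round; accuracy = trace / total,
pooled over rounds). Authentication scores pool over rounds: genuine =
distance to own enrollment; impostor = distance from each test template
to every other enrollment, attributed to the *claimed* (enrolled) subject
for per-subject analysis.

FAR(t) is the fraction of impostor scores strictly below t, FRR(t) the
fraction of genuine scores at or above t — consistent with strict accept.
Both are evaluated on 512 evenly spaced thresholds spanning [0, 1.05 ×
max score]; the EER is read at the FAR/FRR crossing by linear
interpolation between the bracketing grid points (an exact grid-point
crossing is returned as-is; curves that never bracket raise and ask for a
wider grid). User-tuned EERs repeat this per subject on that subject's
own genuine and directed impostor pools; their mean is reported. The
displayed distance matrix is the run-mean matrix min-max scaled to
[0, 1], a constant matrix mapping to zeros.

All randomness flows from one root seed through deterministic seed
derivation (population seeds, per-subject noise seeds, per-run draws), so
a fixed seed reproduces every artifact bitwise; floats are serialized at
17 significant digits, which round-trips float64 exactly.

## Problem sizes

The standard synthetic study uses 16 subjects × 2 min at 1000 Hz
(~190 beats per subject after validity filtering), the 30-run 30/30
protocol (480 identification decisions; 480 genuine and 7 200 impostor
scores pooled over the 30 runs), and a white-noise
sweep σ ∈ {0, 0.05, 0.1, 0.2} mV with baseline wander and powerline off
so a single factor varies. These sizes keep a full end-to-end evaluation
under a minute on one CPU while leaving every rate well-estimated.

## Known limitations

* The Gaussian-sum beat model has no QRS asymmetry, no U wave, and
  strictly linear rate scaling; delineation tolerances tuned here may be
  optimistic for real morphologies.
* Single-session evaluation only: enrollment/test splits come from one
  recording per subject, so day-to-day template drift is unmeasured.
* The detector targets positive-R leads; inverted-polarity recordings
  yield no candidates by design and must be rectified upstream.
* Exact score ties in authentication are resolved toward rejection, and
  identification ties toward the smaller identifier; with continuous
  scores both events have measure zero but matter for degenerate inputs.
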