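# Methods

`eogdiff` benchmarks numerical differentiation methods for saccadic
electrooculography (EOG). The central difficulty it addresses is that on
*real* recordings the exact velocity profile of the eye is unknowable —
noise in the position signal makes exact onset/offset points and exact
peak velocities undefined — so differentiators can only be compared on
synthetic records whose ground truth is known by construction. The
package therefore couples a generator with exact ground truth to a
filter bank, an event detector, biomarker extraction and a
nonparametric ranking harness.

## The differentiator bank

All sixteen methods are antisymmetric FIR filters

    v[i] = fs * sum_{k=1..M} c_k (x[i+k] - x[i-k]),    M = (N-1)/2,

differing only in how the weights `c_k` are chosen:

| family | lengths N | construction | exact degree |
| --- | --- | --- | --- |
| central difference (cd) | 3, 5, 7, 9 | derivative of the Lagrange interpolant | N − 1 |
| Lanczos (l) | 5, 7, 9, 11, 13 | centre derivative of the least-squares parabola, `c_k = 3k / (m(m+1)(2m+1))` | 2 |
| Super Lanczos (sl) | 7, 9, 11 | centre derivative of the least-squares quartic | 4 |
| smooth noise-robust (snr) | 5, 7, 9, 11 | binomial weights `c_k = 2^-(2m+1) [C(2m, m-k+1) − C(2m, m-k-1)]`, m = (N−3)/2 | 2 |

The roster id `cd9` denotes the empirically tuned 9-point coefficients
published by Inchingolo and Spanio for 200 Hz eye-movement recordings
(0.8024, −0.2022, 0.03904, −0.003732); the generic Lagrange 9-point
stencil is available as `cd9_lagrange`. Where a closed form exists,
weights are constructed in exact rational arithmetic and converted to
float once, so the unit-ramp identity `2 Σ k c_k = 1` holds to 1e−12
(the Inchingolo–Spanio values satisfy it only to ~4e−4; their filter
object carries a relaxed tolerance and nothing stronger is claimed for
them).
Smooth noise-robust weights additionally satisfy `Σ k c_k (−1)^k = 0`
exactly — zero slope of the frequency response at Nyquist, the property
that suppresses high-frequency noise.

The sampling step is always `h = 1/fs`; no pre-filtering stage is
applied before differentiation (low-pass smoothing before numerical
differentiation does not rescue the noisy families and would confound
the comparison). Edges are handled by replicate-padding `(N−1)/2`
samples so output and input indices align; record edges are fixations,
where this bias is small. `apply_differentiator(..., edge="invalid")`
returns NaN at the edge samples instead for callers that prefer to
discard them.

## The synthetic dataset

Records are generated velocity-first at 1000 Hz. A step stimulus
alternates between ±angle/2 (angles 20°, 30°, 60°) with fixation
intervals drawn uniformly from 1.5–3.0 s; each transition elicits one
saccade after a latency drawn from a truncated Gaussian. The saccade
velocity waveform is a sin² pulse

    v(t) = Vp sin²(π t / D),  0 ≤ t ≤ D,      Vp = 2|A| / D,

chosen for its compact support, symmetric bell shape and closed-form
integral (exactly the amplitude A). The waveform is a pluggable
strategy: an asymmetric (e.g. gamma-shaped) pulse can replace it
without touching the rest of the pipeline. The exact velocity profile
(EVP) is the concatenation of the pulses; the noise-free position is
its cumulative-trapezoid integral starting at −angle/2.

Subject classes enter through the duration main sequence
`D(A) = d0 + d1 |A|` (with lognormal jitter, σ = 0.08) and the latency
distribution:

| class | d0 (s) | d1 (s/deg) | latency (s) |
| --- | --- | --- | --- |
| healthy | 0.025 | 0.0025 | N(0.20, 0.03²), truncated at 0.10 |
| SCA2 | 0.060 | 0.006 | N(0.28, 0.06²), truncated at 0.10 |

Because `Vp = 2|A|/D`, the doubled-plus durations of the SCA2 class
automatically produce the hallmark saccadic slowing (≈222 vs ≈533 deg/s
at 20°), and longer, more variable latencies. These constants are
configurable and are logged with every run.

Three noises contaminate the *position* only (ground truth is never
touched): a 60 Hz mains sinusoid with random phase (amplitude 0.3°),
white Gaussian noise (σ = 0.1°), and 3–7 Hz band-limited "colored"
noise seen in patient recordings (σ = 0.05° healthy, 0.10° SCA2 — the
patient class carries twice the colored noise). The colored amplitudes
were fixed by a forward calibration to the operating regime the
benchmark is meant to probe: differentiating a 3–7 Hz position noise of
σ degrees yields ≈ 2π·5·σ deg/s of velocity noise in fixations, and at
0.10° that keeps the occurrence threshold (40 deg/s) at ≥8σ of the
fixation velocity noise of well-behaved filters — so false positives
are rare and the best-method peak-velocity errors land at the few-deg/s
scale. At several-fold larger colored amplitudes the occurrence
threshold sits at ~3–4σ and *every* method over-identifies by
construction, which is not an interesting comparison regime.

Records are then decimated 1000 → 200 Hz with the standard decimation
operator (8th-order Chebyshev type-I antialiasing low-pass applied
zero-phase, then 1-in-5 downsampling); all benchmark computation uses
the 200 Hz records. Two numerical details matter here:

* **Warm-up margins.** Both the antialiasing filter (impulse response
  ≈0.45 s to 1e−7) and the colored-noise bandpass (≈3.6 s) are applied
  with generous edge padding that is cropped afterwards. Without this,
  zero-phase startup transients at the record boundary differentiate
  into spurious 40–60 deg/s velocity spikes that the detector reports
  as false saccades — an artifact of filtering, not a property of any
  differentiator.
* **DC gain.** The even-order Chebyshev filter carries its 0.05 dB
  passband ripple at DC, so the zero-phase DC gain is 10^(−0.1/20) ≈
  0.9886. Position and EVP pass through the *same* operator, so every
  comparison (MSE, detection, biomarkers) is internally consistent;
  only absolute amplitudes are ~1.1 % below their 1000 Hz values.

The default grid is 2 classes × 3 angles × 20 records × 20 saccades =
120 records, 2400 saccades. Each record derives its seed as
`master_seed + index`; generation is a pure function of
(configuration, master seed).

## Saccade identification and matching

Detection is the classic two-threshold velocity rule: mark samples with
|v| ≥ Pt (20 deg/s), take maximal marked runs, optionally merge runs
closer than `merge_gap` (default 0: no merging), keep runs containing a
sample with |v| ≥ Ot, drop runs shorter than `min_duration` (10 ms).
Thresholding uses |v| since saccades alternate direction. Ot defaults
to 40 deg/s — well above Pt, far below the smallest generated peak
velocity (≈200 deg/s, SCA2 at 20°) — and is logged with every run.
Ground-truth events are produced by running the *same* detector on the
noise-free EVP, so detector and reference share one event definition.

Detected events are paired to exact events by greedy maximum sample
overlap: each detected event goes to the exact event it overlaps most
(ties to the earlier exact event); an exact event keeps only its
largest-overlap claimant (ties to the earlier detected event).
Unmatched exact events are misidentified (misses), unmatched detected
events over-identified (false positives).

## Biomarkers and errors

Peak velocity is max |v| inside the event; latency is onset time minus
the most recent stimulus transition (events with no preceding
transition are flagged and excluded from latency aggregation only);
duration is (offset − onset)/fs. Per matched pair, the error of each
biomarker is |biomarker(exact event on EVP) − biomarker(detected event
on AVP)|. Latency and duration errors are integer multiples of 1/fs by
construction.

## Ranking statistics

Per-record MSE against the EVP screens the field first: methods whose
median record MSE exceeds `drop_factor` (default 100) times the best
median are excluded from the biomarker rankings — under the default
noise this removes exactly the central-difference family, which sits
~40–400× above the rest. The rule is a reported, configurable flag,
not a hard-coded exclusion.

Biomarker rankings use complete blocks: only saccades matched by
*every* compared method enter, one block per saccade. The Friedman
test (within-block ranks, average ranks on ties; computed via scipy
for k ≥ 3 and by the same tie-corrected rank formula for k = 2) is the
omnibus; two-sided Wilcoxon signed-rank tests of each method against
the rank-1 method delimit the "best cluster" of statistically
indistinguishable methods at α = 0.05. Zero-difference pairs are
dropped before ranking; a method against itself reports p = 1. The
default post-hoc applies no multiplicity correction (the cluster is
descriptive, pairing rank-1 against the rest); a Holm step-down
variant is available via `holm=True`.

## Problem sizes

The default benchmark (120 records ≈ 45 s each at 200 Hz, 16 methods,
2400 saccades) runs in well under a minute, so tests and the
acceptance script operate at the full default scale; smaller grids
(`records_per_cell`, `angles`) are used only in unit tests.

## What the generator does and does not emulate

It emulates: the record structure of a clinical saccadic protocol at
three stimulation angles, the main-sequence contrast between healthy
and SCA2 saccades, and the three dominant noise types of EOG
acquisition. It does **not** model glissades, dynamic overshoot,
blinks, drift, vertical/oblique saccades, electrode-calibration error,
or the true (unpublished) noise spectra of clinical hardware. Passing
the benchmark therefore shows how differentiators rank *under this
noise model and pulse shape*; absolute error magnitudes on real
recordings will differ, and a method's rank could shift under noise
concentrated in bands this model leaves empty.

## Known limitations

* With the three modelled noise types, the MSE separation between the
  central-difference family and the smoothest short filters is bounded
  by the ratio of their frequency responses over the occupied bands
  (≈15–20× between cd3 and l7 at 60 Hz and below); "orders of
  magnitude" gaps arise against the ≥9-point smooth filters, not
  against every 7-point one.
* Wide filters pay a deterministic price even without noise: fitting a
  parabola across most of a 15-sample pulse shifts threshold crossings
  by 2–4 samples (l11, l13) and attenuates the peak by up to ~150
  deg/s. This is a property of the filters, not an artifact — it is
  exactly the waveform-fidelity trade-off the benchmark measures.
* Exact events are re-annotated on the decimated EVP rather than by
  rescaling 1000 Hz indices (the events are *defined* by thresholding
  the EVP at the analysis rate); the two differ by at most one coarse
  sample.
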