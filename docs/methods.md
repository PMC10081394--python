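# Methods

This note documents the models and procedures implemented in `hfospike`,
their assumptions, the defaults that matter, and the choices made where the
design was genuinely open. Problem sizes quoted here are the ones the test
suite and `scripts/acceptance.py` actually run.

## Signal model and event taxonomy

The pipeline targets interictal, non-REM iEEG from depth macroelectrodes
sampled at ≥ 2 kHz. Events are classified five ways: ripples (80–200 Hz) and
fast ripples (200–600 Hz), each either on the background oscillation
(RonO/fRonO) or superimposed on an epileptiform spike (RonS/fRonS), plus
sharp-spikes without an embedded HFO. The band boundary is half-open at
200 Hz so the two HFO bands partition [80, 600] Hz.

All times are seconds from recording start; intervals are half-open
`[start, end)`; signals are microvolts. Artifact handling is by exclusion
masks only: analysis is restricted to per-channel artifact-free epochs, and
event rates are computed over artifact-free minutes, not wall clock.

## Two-stage detection

**Stage 1 — Hilbert candidates.** The channel is band-passed (4th-order
Butterworth, forward–backward) in each HFO band and the analytic-signal
envelope thresholded at `median + 3 × (1.4826·MAD)`, both statistics over the
artifact-free samples. Robust statistics make the threshold insensitive to
the events themselves, and make detection exactly equivariant under amplitude
scaling. An excursion qualifies if it lasts at least 4 cycles *of the band's
upper edge* (20 ms in the ripple band, 6.7 ms in the fast-ripple band); using
the band center here would reject legitimate few-cycle oscillations in the
upper half of each band — a 4-cycle 450 Hz burst lasts 8.9 ms, less than 4
cycles of the 346 Hz band center. Excursions closer than one band period are
merged; ripple- and fast-ripple-band candidates are reconciled by taking the
union interval and analyzing it once.

**Stage 2 — wavelet contour topology.** Around each candidate (0.25 s
padding) a complex Morlet spectrogram is computed: 6-cycle wavelets on a
50-point log-spaced grid from 60 to 900 Hz, amplitude-normalized so a
unit-amplitude sinusoid yields power ≈ 1. The grid deliberately extends
above the 600 Hz classification limit so that contours of events near
600 Hz can close below the grid edge rather than being artificially open.
An extra 0.1 s is analyzed and discarded at each segment edge, where the
convolution's zero padding turns the slow-oscillation offset into a step
with spurious broadband power.

Contours are traced on the *whitened* matrix — each frequency row divided by
its median over time, an estimate of the background level at that frequency
(events occupy a small fraction of the analyzed columns). Without whitening
the 1/f background dominates the low rows and its fluctuations masquerade as
open contours. Isopower levels are log-spaced at 12 levels between an
absolute noise floor of 12 (background-relative power units; the trimmed
background rarely exceeds ~10) and the segment maximum. A percentile-based
floor is not usable here: it would place a fixed fraction of background
pixels above the lowest level by construction.

A contour is *closed* if its polyline returns to its start inside the
matrix; contours terminating on any matrix edge are *open*. Closed contours
are grouped by nesting. A group counts as an HFO if it stacks ≥ 3 isopower
levels (shallower closed islands are texture on a spike's broadband ridge)
and its mean vertex frequency lies in [80, 600] Hz — groups below 80 Hz are
background rhythms, groups above 600 Hz are the whitened high-frequency tail
of a sharp transient; both are rejected. Open contours count as *spike
evidence* only if they reach the low-frequency grid edge and span at least a
4-fold frequency range: an epileptiform transient's power enters the band
from below and crosses it broadly, whereas contours that are open only
because an oscillation leaks past a grid edge span a narrow range.

Classification follows the contour dichotomy: a qualifying closed group with
spike evidence whose open-loop onset precedes the closed-loop onset is an
HFO on a spike; a closed group without earlier spike evidence is an HFO on
the background; spike evidence alone is a sharp-spike. Within a candidate,
only closed groups overlapping the candidate interval are considered, so a
neighboring event inside the analysis padding cannot claim the candidate.

Reported quantities per event: category; onset (closed-group onset for
RonO/fRonO, open-loop onset for on-spike events and sharp-spikes); offset
(end of the outermost closed contour); duration = offset − onset; peak
frequency (grid frequency of the power maximum inside the outer contour);
spectral power (raw, un-whitened power at that maximum, which scales
quadratically with signal amplitude); log10 power. Bluntly contoured spikes
with no supra-threshold content above 80 Hz produce no candidate and are
undetectable by design.

Measured on synthetic recordings (10 min, 4 channels, ~20 events per
category, default amplitudes 25 µV bursts / 150 µV spikes on a 10 µV
broadband + 40 µV slow background): 96–99% of planted events are matched
within ±25 ms with the correct category (6 seeds), and the false-positive
rate on event-free background is 0.25–0.7 events/min/channel.

## Coincidence statistics

Latency of an HFO on oscillation to its after-going spike is the minimum
strictly positive difference between spike onsets and the HFO onset within
one channel. *Pre-spike* status uses a strict `< 300 ms` window (an event at
exactly 300 ms does not qualify); spike onsets are the events' `onset_s`,
i.e. the open-loop contour onset for RonS/fRonS. The *following* flags on
RonS/fRonS use the open interval `(onset − 300 ms, onset)`.

The bootstrap null redraws, per surrogate, the observed number of HFO onsets
per channel uniformly over that channel's artifact-free epochs, keeping
spike onsets fixed, and recounts below-window latencies; 500 surrogates by
default. Surrogate onsets are drawn independently (collisions with spikes
allowed — the simplest null, verified by calibration). The pooled statistic
sums per-channel counts with per-channel redraws. The z-score is
(observed − mean)/SD of the surrogate counts; the empirical p-value uses the
add-one convention `(1 + #{surrogate ≥ observed}) / (n + 1)`, so it is never
zero and is conservative for discrete counts — calibration over independent
Poisson channels gives a rejection rate at or slightly below nominal
(measured ≈ 1–3% at the 5% level over 200 channels).

## Event-aligned unit firing

A trial is a binary 1 ms raster over a 2 s window centered at event onset,
convolved with a Gaussian kernel of **SD 100 ms** (truncated at ±4 SD and
renormalized to unit area, so a single action potential integrates to one
spike) and averaged into 25 ms bins (80 samples at 40 Hz; bin-averaging
rather than decimation preserves rate units). `bl_fr` is the trace mean over
[−0.75, 0) s, `hfo_fr` the trace max over [0, duration); events outrunning
the 1 s half-window are truncated and flagged, as are baselines truncated at
the recording start. The wide kernel targets mean event-related firing, not
fine temporal structure.

Unit inclusion: paired t-test of `hfo_fr` vs `bl_fr` per (unit, category),
Holm step-down correction across all testable units within a category
(pooled across patients), inclusion iff adjusted p ≤ 0.001. Units with fewer
than two trials or zero-variance differences are excluded with a recorded
reason. At desk scale this test is deliberately stringent: with the ~10–40
trials per unit that a 10-minute synthetic recording yields, only extreme
modulation passes, and cohort-level inclusion fractions are typically zero.
Chronic patient recordings supply orders of magnitude more trials per unit.

The GLMM is a Gaussian-response, log-link mixed model with free dispersion
(quasi-likelihood), fixed effects `intercept + log10_power + status +
log10_power:status`, and random intercepts for unit, contact and patient
(all identifiers globally distinct). It is fitted by penalized
quasi-likelihood: the log link is linearized around the current fit
(working response `z = η + (y − μ)/μ`, weights `μ²`) and a
maximum-likelihood weighted linear mixed model is solved in the variance
components (Nelder–Mead on log-variances, Woodbury identities for the
n × n covariance; deterministic). Variance components estimated below
10⁻⁶ × dispersion are snapped to the boundary, which makes the
zero-variance case agree with a no-random-effects log-link GLM to
≈ 10⁻¹⁰ relative. Gaussian + log link permits negative observations
(e.g. `hfodiff_fr`) provided the fitted means stay positive; a table whose
response mean is non-positive raises an error rather than being nudged.
Fixed-effect p-values are Wald-normal. Parameter recovery: on simulated
tables (n = 2000 trials, 20 units, 5 contacts, 3 patients, log-scale
coefficients 1.0/0.5/0.3/0.2), all coefficient signs are recovered in
≥ 95% of 100 fits, and estimates agree with R's glmmTMB to < 0.02 on a
seeded cross-check.

## Localization metrics

SOZ and resection ratios are per-patient fractions of (selected) events on
flagged contacts; with zero selected events the ratio is flagged undefined
rather than forced. The fast-ripple rate–distance graph selects all fRonS
plus fRonO with peak frequency strictly above 350 Hz, computes per-contact
rates over artifact-free minutes, and weights the complete contact graph by
the arithmetic-mean pairwise rate times Euclidean distance (mm). Weights are
treated as connection lengths: shortest paths (Dijkstra) precede
eccentricities, the radius is the minimum eccentricity, zero-weight edges
are absent, disconnected survivors use finite distances only (flagged), and
a single node has radius 0. The resected subgraph inherits the full graph's
per-contact rates and distances. The radius difference is
`sign(Δ)·√|Δ|` with `Δ = radius(all) − radius(resected)`; the sign is kept
because removing nodes from a complete graph can lengthen surviving shortest
paths, making Δ < 0 possible and informative.

## Synthetic cohorts

The generator emulates what the downstream statistics measure, not
biophysics. Background = 1/f² broadband noise (10 µV RMS) plus a 0.5–2 Hz
band-limited slow oscillation (40 µV RMS), the non-REM regime in which
HFO analysis is performed. HFOs are Gaussian-windowed sinusoids (4–12
cycles, frequency uniform within 90–190 Hz / 220–500 Hz, 25 µV); spikes are
a sharp exponential cusp (τ = 10 ms, 150 µV) with a slow negative afterwave,
whose 1/f² spectral tail produces exactly the open-loop broadband signature
the classifier keys on; HFO-on-spike events superimpose a burst at the
apex. Default per-channel rates (events/min, SOZ vs non-SOZ): RonO 2/1,
RonS 1/0.5, fRonO 1/0.3, fRonS 0.5/0.2, sharp-spike 1/0.5 — SOZ-dominant
rates in the range reported for interictal recordings. With configurable
probability (default 0.3 on SOZ contacts, 0 elsewhere) a planted fRonO is
followed by an extra spike at a latency uniform on (0, 0.3) s; the uniform
latency matches the bootstrap null's assumption so calibration tests are
clean. Ground truth is exhaustive: one row per injected waveform.

Unit trains are inhomogeneous Poisson: baseline 5 Hz, multiplied by an
event gain of 5 inside event intervals on the unit's macro contact (burst
coupling at several times baseline), an extra 1.5× for pre-spike-flagged
fRonO, and a suppression factor of 0.5 for 0.5 s after each event offset
(post-event firing decrease); overlapping modulations combine
multiplicatively. Two units per contact mirror a microwire bundle per
macroelectrode.

What the generator does *not* emulate — and what passing tests therefore do
not show about real data: spatial propagation between channels, state
transitions and sleep architecture, non-Poisson unit statistics
(refractoriness, bursting), muscle or electrode artifacts (epochs are clean
by construction), realistic spike morphology variability, and any
biophysical link between the LFP waveform and unit spiking beyond the
planted rate modulation.

## Numerical conventions and degenerate inputs

EDF output uses one-second records and 16-bit quantization over a symmetric
per-channel range (quantization error ≤ half a step, ~0.003 µV at ±100 µV);
recordings must span whole seconds. Event tables round-trip CSV at full
float precision. Detection is deterministic given input and configuration;
the bootstrap and generator consume explicit seeds (spawned via
`numpy.random.SeedSequence`). Degenerate cases are flagged, not fudged:
zero surrogate SD (z undefined, p still reported), zero-event ratios,
empty resection sets, coincident contacts (zero weight, warning), grouping
factors with a single level (dropped with a record in the fit result).

## Problem sizes used

Detector validation: 10-minute, 4-channel recordings (~100 planted events);
false positives on 5 × 4 channel-minutes of clean background. Bootstrap
calibration: 200 independent-Poisson channels (tests) / 100 (acceptance
script), 500 surrogates each; power: planted 0.1 s coupling, 40 events.
GLMM: 100 fits of n = 2000. End-to-end: 8 patients × 4 channels × 10 min.
These sizes keep the full suite at a few minutes on one CPU while leaving
every statistical margin (3σ bands, binomial intervals) intact.

## Known limitations

The contour classifier's ripple/fast-ripple boundary inherits estimator
bias near 200 Hz (whitening amplifies the high-frequency side of a blob, so
ripples at ~190 Hz are occasionally read as fast ripples); sharp spikes
with genuine ripple-band content are sometimes labeled RonS — a taxonomy
boundary, not a bug. PQL is a first-order approximation to the mixed-model
likelihood; its variance components are slightly biased for strongly
non-linear cases, though fixed effects match glmmTMB closely at the scales
tested. The radius difference depends on the shortest-path interpretation
of rate-weighted graphs; other readings of "radius" on a similarity graph
would give different numbers.
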