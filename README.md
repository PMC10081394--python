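# hfospike

Analysis pipeline for interictal intracranial EEG (iEEG) biomarkers of
epileptogenic tissue: detection and classification of high-frequency
oscillations (HFOs) and epileptiform spikes, statistics of fast ripples that
*precede* spikes, event-aligned single-unit firing models, and patient-level
localization metrics for the seizure-onset zone (SOZ) and resection margins.

It is written for epilepsy researchers working with macro–micro depth
electrode recordings (≥ 2 kHz sampling) who want a tested, scriptable
re-implementation of this analysis chain, plus a synthetic-cohort generator
so every stage can be exercised and calibrated without patient data.

## What it computes

**Event detection and taxonomy.** A two-stage detector first finds candidate
intervals where the Hilbert envelope of the ripple (80–200 Hz) or fast-ripple
(200–600 Hz) band exceeds a robust threshold (median + 3·1.4826·MAD) for a
minimum number of oscillation cycles. Each candidate is then analyzed
topographically: a complex Morlet spectrogram (6-cycle wavelets, log-spaced
grid) is whitened per frequency and isopower contours are traced at 12
log-spaced levels. Nested contours that close inside the matrix form the
HFO's *closed-loop group*; broadband contours that terminate on the
low-frequency edge are the *open-loop* signature of a sharp transient. The
five-way classification is:

| closed-loop group | open-loop onset earlier | category |
|---|---|---|
| mean frequency in [80, 200) Hz | no | RonO (ripple on oscillation) |
| mean frequency in [80, 200) Hz | yes | RonS (ripple on spike) |
| mean frequency in [200, 600] Hz | no | fRonO (fast ripple on oscillation) |
| mean frequency in [200, 600] Hz | yes | fRonS (fast ripple on spike) |
| none | open-loop only | sharp-spike |

**Coincidence statistics.** For every RonO/fRonO the minimum positive latency
to the next spike onset (RonS, fRonS or sharp-spike) is computed per channel;
an event with latency < 300 ms is *pre-spike*. Chance levels come from a
bootstrap null in which HFO onsets are redrawn uniformly within each
channel's artifact-free epochs (n = 500 surrogates, spike onsets fixed),
yielding z = (observed − surrogate mean)/surrogate SD per channel and pooled.

**Unit firing models.** Each (event, unit) pair gives a 2 s, 1 ms-resolution
raster centered at event onset, smoothed with a 100 ms (SD) Gaussian kernel
and downsampled to 40 Hz. From it: `bl_fr` (mean rate over the 750 ms before
onset), `hfo_fr` (max rate during the event) and `hfodiff_fr = hfo_fr −
bl_fr`. Units whose `hfo_fr` does not separate from `bl_fr` (paired t-test,
Holm step-down, α = 0.001, per category) are excluded. Retained trials feed a
generalized linear mixed model — Gaussian response, log link, quasi-likelihood
(penalized quasi-likelihood implementation) — with fixed effects
`log10(power) * status` and random intercepts for unit, contact and patient,
where *status* is the pre-spike flag (RonO/fRonO models) or the
followed-by-HFO flag (RonS/fRonS models).

**Localization metrics.** Per patient: the SOZ ratio and resection ratio
(fraction of selected events on SOZ / resected contacts), and the fast-ripple
*rate–distance radius difference*: a complete contact graph weighted by
`((rᵢ + rⱼ)/2) · dᵢⱼ` (mean pairwise rate of fRonS plus fRonO > 350 Hz in
events/min, times Euclidean distance in mm), whose radius (minimum
eccentricity under shortest paths) is compared between all contacts and the
resected subset as `sign(Δ)·√|Δ|`.

## Worked example

```python
from hfospike import synth, detect, coincidence as coin
from hfospike.types import DetectionConfig, SPIKE_CATEGORIES

spec = synth.SyntheticCohortSpec(n_patients=1, n_channels=4,
                                 duration_s=600, seed=11)
rec, truth, trains, layout = synth.generate_patient(spec, "pt00", 42)

events = detect.detect_events(rec, None, DetectionConfig())
events = coin.annotate_prespike(events, window_s=0.3)
print(events["category"].value_counts().to_dict())

hfos = events[events["category"].isin(["RonO", "fRonO"])]
spikes = events[events["category"].isin(SPIKE_CATEGORIES)]
boot = coin.bootstrap_null(hfos, spikes,
                           {ch: rec.epochs_for(ch) for ch in rec.channel_labels},
                           n_surrogates=500, seed=7)
pooled = boot["pooled"]
print(f"observed < 300 ms: {pooled.observed_count}  "
      f"surrogate {pooled.surrogate_mean:.1f} +/- {pooled.surrogate_sd:.1f}  "
      f"z = {pooled.z_score:.2f}  p = {pooled.empirical_p:.4f}")
```

Output:

```
{'RonO': 60, 'fRonO': 32, 'RonS': 30, 'SharpSpike': 27, 'fRonS': 16}
observed < 300 ms: 4  surrogate 0.9 +/- 0.9  z = 3.25  p = 0.0120
```

The synthetic patient plants fRonO→spike coupling only on its SOZ contacts;
the pooled bootstrap finds 4 fast ripples preceding a spike by < 300 ms
against an expected 0.9 ± 0.9 under uniform randomization — more coincidence
than chance (z = 3.25, empirical p = 0.012 with 500 surrogates).

The same chain is available from the shell:

```bash
hfospike simulate --out cohort --seed 11
hfospike run-all --cohort cohort --out results --seed 7
```

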