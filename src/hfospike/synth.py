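"""Synthetic cohort generator: non-REM-like iEEG background, injected HFO and
spike waveforms with exact ground truth, and event-modulated unit spike trains.

The generator emulates the statistical structure the downstream stages are
built to measure: ripple (80-200 Hz) and fast-ripple (200-600 Hz) bursts
riding on a 1/f + slow-oscillation background, epileptiform spikes with or
without an embedded HFO, fRonO->spike latency coupling within 300 ms
(optionally restricted to seizure-onset-zone contacts), and
inhomogeneous-Poisson unit trains whose rate is raised during events and
suppressed after them.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal as sps

from .types import (
    FAST_RIPPLE_BAND,
    RIPPLE_BAND,
    Recording,
    ValidationError,
)
from . import io as hio

TRUTH_COLUMNS = [
    "patient_id",
    "channel",
    "onset_s",
    "offset_s",
    "category",
    "center_frequency",
    "amplitude",
    "planted_prespike",
]

#: Category -> admissible center-frequency band (Hz).  Spike transients have
#: no carrier frequency; their row stores NaN.
CATEGORY_BANDS = {
    "RonO": RIPPLE_BAND,
    "RonS": RIPPLE_BAND,
    "fRonO": FAST_RIPPLE_BAND,
    "fRonS": FAST_RIPPLE_BAND,
}

_SPIKE_TAU_S = 0.010       # decay constant of the sharp cusp
_SPIKE_ONSET_LEAD_S = 0.030  # truth onset = apex - 3*tau (cusp above ~5% of peak)


@dataclass
class SyntheticCohortSpec:
    """Parameters of a synthetic cohort.

    Event rates are events/min per channel, split by channel class (SOZ vs
    non-SOZ).  ``coupling_prob`` is the probability that a planted fRonO is
    followed by an extra epileptiform spike at a latency drawn uniformly on
    (0, 0.3) s, again split by channel class.
    """

    n_patients: int = 2
    n_channels: int = 4
    duration_s: float = 600.0
    sampling_rate: float = 2000.0
    # events/min: category -> (soz_rate, non_soz_rate)
    event_rates: dict = field(default_factory=lambda: {
        "RonO": (2.0, 1.0),
        "RonS": (1.0, 0.5),
        "fRonO": (1.0, 0.3),
        "fRonS": (0.5, 0.2),
        "SharpSpike": (1.0, 0.5),
    })
    # fRonO -> after-going spike coupling
    coupling_prob: tuple[float, float] = (0.3, 0.0)   # (SOZ, non-SOZ)
    coupling_window_s: float = 0.300
    coupled_spike_category: str = "SharpSpike"
    # frequency ranges sampled per category (Hz)
    freq_ranges: dict = field(default_factory=lambda: {
        "RonO": (90.0, 190.0),
        "RonS": (90.0, 190.0),
        "fRonO": (220.0, 500.0),
        "fRonS": (220.0, 500.0),
    })
    cycles_range: tuple[float, float] = (4.0, 12.0)
    hfo_amplitude_uv: float = 25.0
    spike_amplitude_uv: float = 150.0
    min_separation_s: float = 0.8
    # background
    broadband_rms_uv: float = 10.0
    slow_rms_uv: float = 40.0
    # layout
    soz_fraction: float = 0.5
    resected_fraction: float = 0.5
    # units
    units_per_contact: int = 2
    unit_baseline_hz: float = 5.0
    # burst gain during events: HFO-coupled units fire at several times their
    # baseline within the event window
    event_gain: float = 5.0
    prespike_extra_gain: float = 1.5
    suppression_depth: float = 0.5       # rate multiplier after events; 1 = none
    suppression_duration_s: float = 0.5
    seed: int = 0

    def validate(self) -> "SyntheticCohortSpec":
        for cat, (a, b) in self.event_rates.items():
            if a < 0 or b < 0:
                raise ValidationError(f"negative event rate for {cat}")
        for p in self.coupling_prob:
            if not 0.0 <= p <= 1.0:
                raise ValidationError("coupling_prob must be in [0, 1]")
        if self.unit_baseline_hz <= 0:
            raise ValidationError("unit baseline rate must be positive")
        if self.event_gain <= 0 or self.prespike_extra_gain <= 0:
            raise ValidationError("gains must be positive")
        if self.suppression_depth < 0:
            raise ValidationError("suppression factor must be non-negative")
        for cat, (lo, hi) in self.freq_ranges.items():
            band = CATEGORY_BANDS[cat]
            if lo < band[0] or hi > band[1]:
                raise ValidationError(
                    f"{cat} frequency range ({lo}, {hi}) outside band {band}"
                )
        return self

    def to_json(self, path=None) -> str:
        payload = {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in self.__dict__.items()}
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    @classmethod
    def from_json(cls, source) -> "SyntheticCohortSpec":
        if isinstance(source, (str, Path)) and not str(source).lstrip().startswith("{"):
            payload = json.loads(Path(source).read_text())
        else:
            payload = json.loads(str(source))
        for key in ("coupling_prob", "cycles_range"):
            if key in payload:
                payload[key] = tuple(payload[key])
        for key in ("event_rates", "freq_ranges"):
            if key in payload:
                payload[key] = {k: tuple(v) for k, v in payload[key].items()}
        return cls(**payload).validate()


# ---------------------------------------------------------------------------
# Background
# ---------------------------------------------------------------------------

def generate_background(duration_s: float, sampling_rate: float, n_channels: int,
                        seed, broadband_rms_uv: float = 10.0,
                        slow_rms_uv: float = 40.0) -> Recording:
    """Generate 1/f-shaped broadband noise plus a 0.5-2 Hz slow oscillation.

    The broadband component has power spectral density proportional to
    ``1/f^2`` above 1 Hz (flat below), scaled to ``broadband_rms_uv``; the
    slow component is band-limited Gaussian noise scaled to ``slow_rms_uv``,
    mimicking high-amplitude slow/delta activity of non-REM sleep.
    """
    if duration_s <= 0:
        raise ValidationError("duration must be positive")
    if sampling_rate < 1200:
        raise ValidationError("sampling_rate < 1200 Hz cannot represent the 600 Hz band")
    rng = np.random.default_rng(seed)
    n = int(round(duration_s * sampling_rate))
    freqs = np.fft.rfftfreq(n, d=1.0 / sampling_rate)
    shape = 1.0 / np.maximum(freqs, 1.0)  # amplitude ~ 1/f => power ~ 1/f^2
    shape[0] = 0.0
    sig = np.empty((n_channels, n))
    sos = sps.butter(4, [0.5, 2.0], btype="bandpass", fs=sampling_rate, output="sos")
    for ch in range(n_channels):
        white = rng.standard_normal(n)
        shaped = np.fft.irfft(np.fft.rfft(white) * shape, n=n)
        shaped *= broadband_rms_uv / max(shaped.std(), 1e-12)
        slow = sps.sosfiltfilt(sos, rng.standard_normal(n))
        slow *= slow_rms_uv / max(slow.std(), 1e-12)
        sig[ch] = shaped + slow
    labels = [f"ch{i:02d}" for i in range(n_channels)]
    return Recording(channel_labels=labels, signal=sig, sampling_rate=sampling_rate,
                     artifact_free_epochs={lb: [(0.0, n / sampling_rate)] for lb in labels})


# ---------------------------------------------------------------------------
# Event waveforms
# ---------------------------------------------------------------------------

def hfo_waveform(t: np.ndarray, onset_s: float, freq_hz: float, n_cycles: float,
                 amplitude_uv: float) -> np.ndarray:
    """Gaussian-windowed sinusoidal burst starting at ``onset_s``."""
    dur = n_cycles / freq_hz
    center = onset_s + dur / 2.0
    sd = dur / 6.0  # +/-3 SD spans the nominal duration
    env = np.exp(-0.5 * ((t - center) / sd) ** 2)
    return amplitude_uv * env * np.sin(2 * np.pi * freq_hz * (t - onset_s))


def spike_waveform(t: np.ndarray, apex_s: float, amplitude_uv: float) -> np.ndarray:
    """Biphasic epileptiform spike: sharp exponential cusp + slow afterwave.

    The cusp (decay constant 10 ms) carries a 1/f^2 broadband spectral tail
    that produces open-loop time-frequency contours; the afterwave keeps the
    dominant energy below 50 Hz.
    """
    cusp = np.exp(-np.abs(t - apex_s) / _SPIKE_TAU_S)
    after = -0.45 * np.exp(-0.5 * ((t - apex_s - 0.060) / 0.025) ** 2)
    return amplitude_uv * (cusp + after)


def _spike_truth_interval(apex_s: float) -> tuple[float, float]:
    return apex_s - _SPIKE_ONSET_LEAD_S, apex_s + 0.120


# ---------------------------------------------------------------------------
# Event injection
# ---------------------------------------------------------------------------

def _draw_onsets(rng, epochs, rate_per_min, min_sep, taken, margin=0.35):
    """Poisson number of onsets uniform over epochs, >= min_sep from taken."""
    total = sum(e - s for s, e in epochs)
    n = rng.poisson(rate_per_min * total / 60.0)
    onsets = []
    for _ in range(n):
        for _attempt in range(200):
            u = rng.uniform(0.0, total)
            for s, e in epochs:
                if u < e - s:
                    t = s + u
                    break
                u -= e - s
            else:
                t = epochs[-1][1] - 1e-6
            if t < margin or t > epochs[-1][1] - margin:
                continue
            if all(abs(t - t0) >= min_sep for t0 in taken):
                onsets.append(t)
                taken.append(t)
                break
    return onsets


def inject_events(recording: Recording, spec: SyntheticCohortSpec,
                  layout: pd.DataFrame, seed) -> tuple[Recording, pd.DataFrame]:
    """Inject HFO bursts, spikes and coupled fRonO->spike pairs into a recording.

    Returns the recording (signal modified in place on a copy) and an
    exhaustive ground-truth table: one row per injected waveform.
    """
    spec.validate()
    rng = np.random.default_rng(seed)
    sig = recording.signal.copy()
    fs = recording.sampling_rate
    t_axis = np.arange(recording.n_samples) / fs
    rows = []
    soz_by_contact = dict(zip(layout["contact_id"], layout["is_soz"]))

    def add_hfo(ch_idx, onset, cat):
        lo, hi = spec.freq_ranges[cat]
        freq = rng.uniform(lo, hi)
        ncyc = rng.uniform(*spec.cycles_range)
        dur = ncyc / freq
        i0 = max(int((onset - 0.05) * fs), 0)
        i1 = min(int((onset + dur + 0.05) * fs), recording.n_samples)
        sig[ch_idx, i0:i1] += hfo_waveform(t_axis[i0:i1], onset, freq, ncyc,
                                           spec.hfo_amplitude_uv)
        return freq, dur

    def add_spike(ch_idx, apex):
        i0 = max(int((apex - 0.08) * fs), 0)
        i1 = min(int((apex + 0.18) * fs), recording.n_samples)
        sig[ch_idx, i0:i1] += spike_waveform(t_axis[i0:i1], apex,
                                             spec.spike_amplitude_uv)

    for ch_idx, ch in enumerate(recording.channel_labels):
        epochs = recording.epochs_for(ch)
        is_soz = bool(soz_by_contact.get(ch, False))
        cls = 0 if is_soz else 1
        taken: list[float] = []
        for cat in ("RonO", "fRonO", "RonS", "fRonS", "SharpSpike"):
            rate = spec.event_rates.get(cat, (0.0, 0.0))[cls]
            for onset in _draw_onsets(rng, epochs, rate, spec.min_separation_s, taken):
                if cat in ("RonO", "fRonO"):
                    freq, dur = add_hfo(ch_idx, onset, cat)
                    planted_pre = False
                    if cat == "fRonO" and rng.random() < spec.coupling_prob[cls]:
                        lat = rng.uniform(0.0, spec.coupling_window_s)
                        apex = onset + lat + _SPIKE_ONSET_LEAD_S
                        add_spike(ch_idx, apex)
                        s_on, s_off = _spike_truth_interval(apex)
                        rows.append((recording.patient_id, ch, s_on, s_off,
                                     spec.coupled_spike_category, np.nan,
                                     spec.spike_amplitude_uv, False))
                        planted_pre = True
                    rows.append((recording.patient_id, ch, onset, onset + dur, cat,
                                 freq, spec.hfo_amplitude_uv, planted_pre))
                elif cat in ("RonS", "fRonS"):
                    # burst superimposed on the spike transient, at the apex
                    apex = onset + _SPIKE_ONSET_LEAD_S
                    add_spike(ch_idx, apex)
                    lo, hi = spec.freq_ranges[cat]
                    freq = rng.uniform(lo, hi)
                    ncyc = rng.uniform(*spec.cycles_range)
                    dur = ncyc / freq
                    b_on = apex - dur / 2.0
                    i0 = max(int((b_on - 0.05) * fs), 0)
                    i1 = min(int((b_on + dur + 0.05) * fs), recording.n_samples)
                    sig[ch_idx, i0:i1] += hfo_waveform(t_axis[i0:i1], b_on, freq,
                                                       ncyc, spec.hfo_amplitude_uv)
                    s_on, s_off = _spike_truth_interval(apex)
                    rows.append((recording.patient_id, ch, s_on, s_off, cat, freq,
                                 spec.hfo_amplitude_uv, False))
                else:  # SharpSpike
                    apex = onset + _SPIKE_ONSET_LEAD_S
                    add_spike(ch_idx, apex)
                    s_on, s_off = _spike_truth_interval(apex)
                    rows.append((recording.patient_id, ch, s_on, s_off, cat, np.nan,
                                 spec.spike_amplitude_uv, False))

    truth = pd.DataFrame(rows, columns=TRUTH_COLUMNS)
    truth = truth.sort_values(["channel", "onset_s"], kind="stable").reset_index(drop=True)
    out = Recording(channel_labels=recording.channel_labels, signal=sig,
                    sampling_rate=fs,
                    artifact_free_epochs=recording.artifact_free_epochs,
                    patient_id=recording.patient_id)
    return out, truth


# ---------------------------------------------------------------------------
# Unit trains
# ---------------------------------------------------------------------------

def generate_unit_trains(ground_truth: pd.DataFrame, spec: SyntheticCohortSpec,
                         seed, duration_s: float | None = None,
                         contacts: list[str] | None = None) -> pd.DataFrame:
    """Sample inhomogeneous-Poisson unit trains modulated by channel events.

    Rate = baseline x event gain inside each event interval on the unit's
    contact (x extra gain for prespike-flagged fRonO), x the suppression
    factor for ``suppression_duration_s`` after each event offset.
    Overlapping modulations combine multiplicatively.
    """
    spec.validate()
    rng = np.random.default_rng(seed)
    if duration_s is None:
        duration_s = spec.duration_s
    if contacts is None:
        contacts = sorted(ground_truth["channel"].unique())
    patient = ground_truth["patient_id"].iloc[0] if len(ground_truth) else ""
    rows = []
    for contact in contacts:
        ev = ground_truth[ground_truth["channel"] == contact]
        # multiplicative rate modifiers as (start, end, factor)
        mods: list[tuple[float, float, float]] = []
        for _, e in ev.iterrows():
            gain = spec.event_gain
            if e["category"] == "fRonO" and bool(e["planted_prespike"]):
                gain *= spec.prespike_extra_gain
            mods.append((e["onset_s"], e["offset_s"], gain))
            if spec.suppression_depth != 1.0 and spec.suppression_duration_s > 0:
                mods.append((e["offset_s"],
                             e["offset_s"] + spec.suppression_duration_s,
                             spec.suppression_depth))
        edges = np.unique(np.clip(
            np.array([0.0, duration_s]
                     + [x for m in mods for x in (m[0], m[1])]), 0.0, duration_s))
        for u in range(spec.units_per_contact):
            unit_id = f"{patient}_{contact}_u{u}"
            times = []
            for a, b in zip(edges[:-1], edges[1:]):
                if b <= a:
                    continue
                rate = spec.unit_baseline_hz
                mid = 0.5 * (a + b)
                for s, e_, f in mods:
                    if s <= mid < e_:
                        rate *= f
                k = rng.poisson(rate * (b - a))
                if k:
                    times.append(rng.uniform(a, b, size=k))
            ap = np.sort(np.concatenate(times)) if times else np.empty(0)
            for t in ap:
                rows.append((unit_id, contact, patient, t))
    return pd.DataFrame(rows, columns=["unit_id", "contact_id", "patient_id", "ap_time_s"])


# ---------------------------------------------------------------------------
# Layout + cohort
# ---------------------------------------------------------------------------

def generate_layout(spec: SyntheticCohortSpec, patient_id: str, seed) -> pd.DataFrame:
    """Random contact coordinates in a 60 mm cube; leading contacts are SOZ."""
    rng = np.random.default_rng(seed)
    n = spec.n_channels
    n_soz = int(round(spec.soz_fraction * n))
    n_res = int(round(spec.resected_fraction * n))
    coords = rng.uniform(0.0, 60.0, size=(n, 3))
    return pd.DataFrame({
        "contact_id": [f"ch{i:02d}" for i in range(n)],
        "x": coords[:, 0], "y": coords[:, 1], "z": coords[:, 2],
        "is_soz": [i < n_soz for i in range(n)],
        "is_resected": [i < n_res for i in range(n)],
        "patient_id": patient_id,
    })


def generate_patient(spec: SyntheticCohortSpec, patient_id: str, seed):
    """Generate one patient: recording, ground truth, unit trains, layout."""
    ss = np.random.SeedSequence(seed)
    s_bg, s_ev, s_un, s_lay = [int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(4)]
    layout = generate_layout(spec, patient_id, s_lay)
    rec = generate_background(spec.duration_s, spec.sampling_rate, spec.n_channels,
                              s_bg, spec.broadband_rms_uv, spec.slow_rms_uv)
    rec.patient_id = patient_id
    rec, truth = inject_events(rec, spec, layout, s_ev)
    trains = generate_unit_trains(truth, spec, s_un, duration_s=spec.duration_s,
                                  contacts=rec.channel_labels)
    if trains.empty:
        trains["patient_id"] = trains.get("patient_id", "")
    trains["patient_id"] = patient_id
    return rec, truth, trains, layout


def generate_cohort(spec: SyntheticCohortSpec, out_dir, force: bool = False) -> Path:
    """Write a full cohort directory tree consumable by the CLI end-to-end."""
    spec.validate()
    out = Path(out_dir)
    if out.exists() and any(out.iterdir()) and not force:
        raise FileExistsError(f"{out} exists and is not empty (use force=True)")
    out.mkdir(parents=True, exist_ok=True)
    ss = np.random.SeedSequence(spec.seed)
    for i, child in enumerate(ss.spawn(spec.n_patients)):
        pid = f"pt{i:02d}"
        pdir = out / pid
        pdir.mkdir(exist_ok=True)
        seed = int(child.generate_state(1)[0] % (2**31))
        rec, truth, trains, layout = generate_patient(spec, pid, seed)
        hio.write_edf(pdir / "recording.edf", rec)
        hio.write_epochs_csv(pdir / "epochs.csv", rec.artifact_free_epochs)
        truth.to_csv(pdir / "ground_truth.csv", index=False)
        hio.write_unit_trains(pdir / "unit_aps.csv", trains)
        hio.write_layout(pdir / "layout.tsv", layout)
    spec.to_json(out / "cohort_spec.json")
    return out
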