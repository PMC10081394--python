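"""Two-stage HFO detection.

Stage 1 (:func:`hilbert_candidates`) band-passes the signal in the ripple
(80-200 Hz) and fast-ripple (200-600 Hz) bands and thresholds the Hilbert
envelope at a robust multiple of its spread, yielding candidate intervals.

Stage 2 (:func:`wavelet_spectrogram` + :func:`contour_topology` +
:func:`classify_event`) computes a complex Morlet time-frequency power matrix
around each candidate and traces isopower contours.  Contours whose path
closes inside the matrix form nested *closed-loop groups* (the HFO); contours
terminating on the matrix boundary are *open-loop* (the broadband signature
of a sharp epileptiform transient).  An event with a closed-loop group whose
open-loop onset precedes the closed-loop onset is an HFO on a spike
(RonS/fRonS); a closed-loop group alone is an HFO on the background
oscillation (RonO/fRonO); open-loop contours alone are a sharp-spike.
Ripple vs fast ripple is decided by the mean frequency of the closed-loop
group (ripple [80, 200) Hz, fast ripple [200, 600] Hz).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from contourpy import LineType, contour_generator
from matplotlib.path import Path as MplPath
from scipy import signal as sps

from .types import (
    DetectionConfig,
    Recording,
    ValidationError,
    empty_events,
)

__all__ = [
    "hilbert_candidates",
    "wavelet_spectrogram",
    "contour_topology",
    "classify_event",
    "detect_events",
    "Contour",
    "ClosedGroup",
    "ContourAnalysis",
]


# ---------------------------------------------------------------------------
# Stage 1: Hilbert envelope candidates
# ---------------------------------------------------------------------------

def _band_center(band) -> float:
    return float(np.sqrt(band[0] * band[1]))


def hilbert_candidates(recording: Recording, channel: str, band,
                       config: DetectionConfig) -> list[tuple[float, float]]:
    """Candidate intervals where the band-limited envelope is elevated.

    The analytic-signal envelope of the band-passed channel must exceed
    ``median + threshold_sd * (1.4826 * MAD)`` — both statistics taken over
    the artifact-free samples — for at least ``min_cycles`` cycles of the
    band's *upper edge* frequency, so that a few-cycle oscillation anywhere
    in the band can satisfy the duration rule.  Excursions closer than one
    band period (geometric-mean frequency) are merged; candidates are
    clipped to the artifact-free epochs.
    """
    fs = recording.sampling_rate
    if band[1] >= fs / 2:
        raise ValidationError(f"band upper edge {band[1]} Hz >= Nyquist {fs / 2} Hz")
    idx = recording.channel_index(channel)
    x = recording.signal[idx]
    sos = sps.butter(4, band, btype="bandpass", fs=fs, output="sos")
    env = np.abs(sps.hilbert(sps.sosfiltfilt(sos, x)))

    mask = np.zeros(x.size, dtype=bool)
    for s, e in recording.epochs_for(channel):
        mask[int(np.ceil(s * fs)):int(np.floor(e * fs))] = True
    if not mask.any():
        return []
    inside = env[mask]
    center = np.median(inside)
    sd = 1.4826 * np.median(np.abs(inside - center))
    if sd <= 0:
        return []
    above = (env > center + config.threshold_sd * sd) & mask

    min_len = int(np.ceil(config.min_cycles / band[1] * fs))
    gap_len = int(np.ceil(1.0 / _band_center(band) * fs))

    # runs of True
    d = np.diff(above.astype(np.int8))
    starts = np.flatnonzero(d == 1) + 1
    ends = np.flatnonzero(d == -1) + 1
    if above[0]:
        starts = np.r_[0, starts]
    if above[-1]:
        ends = np.r_[ends, above.size]
    runs = list(zip(starts, ends))
    # merge nearby runs (< one band period apart), but never across epochs
    merged: list[list[int]] = []
    for s, e in runs:
        if merged and s - merged[-1][1] < gap_len and mask[merged[-1][1]:s].all():
            merged[-1][1] = e
        else:
            merged.append([s, e])
    return [(s / fs, e / fs) for s, e in merged if e - s >= min_len]


# ---------------------------------------------------------------------------
# Stage 2: wavelet spectrogram
# ---------------------------------------------------------------------------

def wavelet_spectrogram(segment: np.ndarray, sampling_rate: float,
                        config: DetectionConfig):
    """Complex-Morlet time-frequency power of a 1-D segment.

    Returns ``(power, freqs)`` with ``power`` of shape
    ``(n_freqs, n_samples)``.  Each wavelet is amplitude-normalized so that a
    unit-amplitude sinusoid at a grid frequency yields power ~= 1; power
    therefore scales quadratically with signal amplitude and isopower levels
    are comparable across events within a channel.
    """
    segment = np.asarray(segment, dtype=float)
    if not np.all(np.isfinite(segment)):
        raise ValidationError("segment contains non-finite values")
    freqs = np.geomspace(config.freq_min, config.freq_max, config.n_freqs)
    if segment.size < 3 * sampling_rate / config.freq_min:
        raise ValidationError(
            f"segment too short for {config.freq_min} Hz (need >= 3 cycles)"
        )
    power = np.empty((freqs.size, segment.size))
    for i, f in enumerate(freqs):
        sd = config.wavelet_cycles / (2 * np.pi * f)
        half = int(np.ceil(4 * sd * sampling_rate))
        t = np.arange(-half, half + 1) / sampling_rate
        gauss = np.exp(-0.5 * (t / sd) ** 2)
        kernel = gauss * np.exp(2j * np.pi * f * t)
        kernel /= 0.5 * gauss.sum()  # unit-amplitude sinusoid -> |response| ~= 1
        power[i] = np.abs(sps.fftconvolve(segment, kernel, mode="same")) ** 2
    return power, freqs


# ---------------------------------------------------------------------------
# Contour topology
# ---------------------------------------------------------------------------

@dataclass
class Contour:
    level: float
    vertices: np.ndarray  # (n, 2) columns: time (s), frequency (Hz)
    closed: bool

    @property
    def t_min(self) -> float:
        return float(self.vertices[:, 0].min())

    @property
    def t_max(self) -> float:
        return float(self.vertices[:, 0].max())

    def area(self) -> float:
        """Shoelace area (log-frequency vertical axis for scale balance)."""
        x = self.vertices[:, 0]
        y = np.log(self.vertices[:, 1])
        return 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))


@dataclass
class ClosedGroup:
    """Nested closed-loop contours sharing one outermost contour."""

    contours: list[Contour] = field(default_factory=list)

    @property
    def outer(self) -> Contour:
        return max(self.contours, key=lambda c: c.area())

    @property
    def onset(self) -> float:
        return self.outer.t_min

    @property
    def offset(self) -> float:
        return self.outer.t_max

    @property
    def peak_level(self) -> float:
        return max(c.level for c in self.contours)

    @property
    def depth(self) -> int:
        """Number of distinct isopower levels stacked in the group."""
        return len({c.level for c in self.contours})

    @property
    def mean_frequency(self) -> float:
        verts = np.concatenate([c.vertices[:, 1] for c in self.contours])
        return float(verts.mean())


@dataclass
class ContourAnalysis:
    groups: list[ClosedGroup]
    open_contours: list[Contour]
    power: np.ndarray
    times: np.ndarray
    freqs: np.ndarray

    @property
    def open_onset(self) -> float | None:
        if not self.open_contours:
            return None
        return min(c.t_min for c in self.open_contours)

    def spike_open_contours(self, min_span_ratio: float = 3.0) -> list[Contour]:
        """Open contours carrying spike evidence.

        An epileptiform transient's broadband power enters the analyzed band
        from below and spans it widely, so its open-loop contours reach the
        low-frequency edge of the matrix and cover a wide frequency range.
        Contours that are open only because an oscillation's power leaks past
        a frequency edge of the grid are not spike evidence.
        """
        f_lo = self.freqs[0] * 1.001
        out = []
        for c in self.open_contours:
            fmin = c.vertices[:, 1].min()
            fmax = c.vertices[:, 1].max()
            if fmin <= f_lo and fmax / max(fmin, 1e-12) >= min_span_ratio:
                out.append(c)
        return out

    def spike_onset(self, min_span_ratio: float = 3.0) -> float | None:
        spikes = self.spike_open_contours(min_span_ratio)
        if not spikes:
            return None
        return min(c.t_min for c in spikes)


def whiten_power(power: np.ndarray) -> np.ndarray:
    """Normalize each frequency row by its median across time.

    The 1/f background otherwise dominates the low-frequency rows and its
    fluctuations masquerade as open-loop contours.  The row median estimates
    the background level at each frequency (events occupy a small fraction
    of the analyzed columns), so the result is in background-relative (SNR)
    units that are comparable across events within a channel.
    """
    med = np.median(power, axis=1, keepdims=True)
    return power / np.maximum(med, np.finfo(float).tiny)


def contour_topology(power: np.ndarray, times: np.ndarray, freqs: np.ndarray,
                     config: DetectionConfig) -> ContourAnalysis:
    """Trace isopower contours and organize them into closed groups.

    The matrix is expected in background-relative (whitened) units; levels
    are log-spaced between the absolute ``noise_floor_snr`` and the matrix
    maximum.  A contour is closed iff its polyline returns to
    its start inside the matrix; contours terminating on any matrix edge
    (time window or frequency limits) are open.  Closed contours are grouped
    by nesting.
    """
    if not np.all(np.isfinite(power)):
        raise ValidationError("power matrix contains non-finite values")
    top = float(power.max())
    floor = float(config.noise_floor_snr)
    if top <= 0 or floor <= 0 or top <= floor * (1 + 1e-12):
        return ContourAnalysis([], [], power, times, freqs)
    levels = np.geomspace(floor, top, config.n_contour_levels + 1)[:-1]

    tt, ff = np.meshgrid(times, freqs)
    gen = contour_generator(x=tt, y=ff, z=power, line_type=LineType.Separate)
    closed: list[Contour] = []
    open_: list[Contour] = []
    for level in levels:
        for line in gen.lines(float(level)):
            if line.shape[0] < 3:
                continue
            is_closed = bool(np.allclose(line[0], line[-1]))
            c = Contour(level=float(level), vertices=line, closed=is_closed)
            (closed if is_closed else open_).append(c)

    # group closed contours by nesting: roots are contours contained in no other
    closed.sort(key=lambda c: c.area(), reverse=True)
    paths = [MplPath(c.vertices) for c in closed]
    groups: list[ClosedGroup] = []
    owner: list[int] = []
    for i, c in enumerate(closed):
        parent = None
        for j in range(i):
            if closed[j].level <= c.level and paths[j].contains_point(c.vertices[0]):
                parent = owner[j]
                break
        if parent is None:
            groups.append(ClosedGroup([c]))
            owner.append(len(groups) - 1)
        else:
            groups[parent].contours.append(c)
            owner.append(parent)
    return ContourAnalysis(groups, open_, power, times, freqs)


# ---------------------------------------------------------------------------
# Classification
# ---------------------------------------------------------------------------

def classify_event(analysis: ContourAnalysis, config: DetectionConfig,
                   candidate: tuple[float, float] | None = None,
                   raw_power: np.ndarray | None = None) -> dict | None:
    """Classify one candidate's contour topology into the five-way taxonomy.

    Returns a dict with ``category, onset_s, offset_s, duration_s,
    peak_frequency, spectral_power`` or ``None`` if nothing classifiable is
    present (e.g. the only closed group sits below 80 Hz and no open-loop
    contours exist).
    """
    ripple_lo = config.ripple_band[0]
    ripple_hi = config.ripple_band[1]

    fr_hi = config.fast_ripple_band[1]
    # a genuine HFO stacks several isopower levels above its surroundings
    # and sits inside the ripple/fast-ripple range; shallow closed islands
    # and super-band blobs are texture on a spike's broadband ridge
    groups = [g for g in analysis.groups
              if ripple_lo <= g.mean_frequency <= fr_hi
              and g.depth >= config.min_closed_depth]
    if candidate is not None:
        # only structure belonging to this candidate: a closed group from a
        # neighboring event inside the analysis padding must not leak in
        groups = [g for g in groups
                  if g.offset > candidate[0] and g.onset < candidate[1]]
    spike_contours = analysis.spike_open_contours(config.spike_min_span_ratio)
    open_onset = analysis.spike_onset(config.spike_min_span_ratio)

    if not groups:
        if open_onset is None:
            return None
        t0 = open_onset
        t1 = max(c.t_max for c in spike_contours)
        return {
            "category": "SharpSpike",
            "onset_s": t0,
            "offset_s": t1,
            "duration_s": t1 - t0,
            "peak_frequency": np.nan,
            "spectral_power": np.nan,
        }

    group = max(groups, key=lambda g: (g.peak_level, -g.onset))
    mean_f = group.mean_frequency
    is_ripple = mean_f < ripple_hi
    on_spike = open_onset is not None and open_onset < group.onset
    category = ("RonS" if is_ripple else "fRonS") if on_spike else \
               ("RonO" if is_ripple else "fRonO")
    duration = group.offset - group.onset
    onset = open_onset if on_spike else group.onset
    offset = group.offset

    # peak frequency and power: the maximum of the (raw, amplitude-scaled)
    # power inside the contoured region at the highest isopower level
    if raw_power is None:
        raw_power = analysis.power
    path = MplPath(group.outer.vertices)
    tt, ff = np.meshgrid(analysis.times, analysis.freqs)
    pts = np.column_stack([tt.ravel(), ff.ravel()])
    inside = path.contains_points(pts).reshape(tt.shape)
    if inside.any():
        masked = np.where(inside, analysis.power, -np.inf)
        i, j = np.unravel_index(np.argmax(masked), masked.shape)
        peak_f = float(analysis.freqs[i])
        peak_power = float(raw_power[i, j])
    else:
        peak_f = mean_f
        peak_power = float(raw_power.max())
    return {
        "category": category,
        "onset_s": onset,
        "offset_s": offset,
        "duration_s": offset - onset if on_spike else duration,
        "peak_frequency": peak_f,
        "spectral_power": peak_power,
    }


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------

def _merge_intervals(intervals, gap=0.02):
    """Union of intervals, joining any that overlap or lie within ``gap``."""
    if not intervals:
        return []
    intervals = sorted(intervals)
    out = [list(intervals[0])]
    for s, e in intervals[1:]:
        if s - out[-1][1] <= gap:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return [tuple(x) for x in out]


def detect_events(recording: Recording, layout: pd.DataFrame | None,
                  config: DetectionConfig) -> pd.DataFrame:
    """Run the full two-stage detector over all channels of a recording.

    Ripple-band and fast-ripple-band candidates are reconciled by analyzing
    the union interval once; the contour topology then decides the category.
    Returns the canonical event table sorted by (contact, onset).
    """
    fs = recording.sampling_rate
    pad = config.segment_pad_s
    rows = []
    for channel in recording.channel_labels:
        cands = hilbert_candidates(recording, channel, config.ripple_band, config)
        cands += hilbert_candidates(recording, channel, config.fast_ripple_band, config)
        idx = recording.channel_index(channel)
        trim = int(config.edge_trim_s * fs)
        for c_start, c_end in _merge_intervals(cands):
            s0 = max(int((c_start - pad) * fs) - trim, 0)
            s1 = min(int((c_end + pad) * fs) + trim, recording.n_samples)
            segment = recording.signal[idx, s0:s1]
            power, freqs = wavelet_spectrogram(segment, fs, config)
            # discard convolution edge artifacts before contouring
            lo = trim if s0 > 0 else 0
            hi = power.shape[1] - (trim if s1 < recording.n_samples else 0)
            power = power[:, lo:hi]
            times = np.arange(s0 + lo, s0 + hi) / fs
            snr = whiten_power(power)
            analysis = contour_topology(snr, times, freqs, config)
            result = classify_event(analysis, config, candidate=(c_start, c_end),
                                    raw_power=power)
            if result is None:
                continue
            result["patient_id"] = recording.patient_id
            result["contact_id"] = channel
            rows.append(result)

    if not rows:
        return empty_events()
    df = pd.DataFrame(rows)
    df["log10_power"] = np.log10(df["spectral_power"])
    df["prespike"] = False
    df["following_fRonO"] = False
    df["following_RonO"] = False
    df["latency_to_next_spike_s"] = np.nan
    df = df.sort_values(["contact_id", "onset_s"], kind="stable").reset_index(drop=True)
    from .types import EVENT_COLUMNS
    return df[EVENT_COLUMNS]


# ---------------------------------------------------------------------------
# Ground-truth matching harness (for validation on synthetic data)
# ---------------------------------------------------------------------------

def match_events(truth: pd.DataFrame, detected: pd.DataFrame,
                 onset_tol_s: float = 0.025) -> pd.DataFrame:
    """Greedily match ground-truth events to detections by onset proximity.

    Returns the truth table with columns ``matched`` (onset within tolerance
    on the same channel) and ``category_correct``.
    """
    out = truth.copy()
    out["matched"] = False
    out["category_correct"] = False
    used = np.zeros(len(detected), dtype=bool)
    det_on = detected["onset_s"].to_numpy() if len(detected) else np.empty(0)
    for i, row in out.iterrows():
        best, best_d = None, onset_tol_s
        for j in np.flatnonzero(~used):
            if detected.iloc[j]["contact_id"] != row["channel"]:
                continue
            d = abs(det_on[j] - row["onset_s"])
            if d <= best_d:
                best, best_d = j, d
        if best is not None:
            used[best] = True
            out.loc[i, "matched"] = True
            out.loc[i, "category_correct"] = (
                detected.iloc[best]["category"] == row["category"]
            )
    return out
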