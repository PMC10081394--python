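"""Canonical data model: recordings, electrode layouts, event tables, configuration.

Conventions used throughout the package:

* all time fields are **seconds from recording start** (float, 0-based);
* all intervals are half-open ``[start, end)``;
* signals are stored in microvolts;
* event tables are plain :class:`pandas.DataFrame` objects with the column
  set in :data:`EVENT_COLUMNS`.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

#: The five-way event taxonomy: ripples / fast ripples on background
#: oscillations (RonO / fRonO), ripples / fast ripples superimposed on
#: epileptiform spikes (RonS / fRonS), and spikes without an embedded HFO.
CATEGORIES = ("RonO", "RonS", "fRonO", "fRonS", "SharpSpike")

#: Categories that count as "iEEG spikes" for coincidence purposes.
SPIKE_CATEGORIES = ("RonS", "fRonS", "SharpSpike")

#: Ripple band, Hz.  Half-open at 200 so the two bands partition [80, 600].
RIPPLE_BAND = (80.0, 200.0)
#: Fast-ripple band, Hz.
FAST_RIPPLE_BAND = (200.0, 600.0)

EVENT_COLUMNS = [
    "patient_id",
    "contact_id",
    "onset_s",
    "offset_s",
    "category",
    "peak_frequency",
    "spectral_power",
    "log10_power",
    "duration_s",
    "prespike",
    "following_fRonO",
    "following_RonO",
    "latency_to_next_spike_s",
]

LAYOUT_COLUMNS = ["contact_id", "x", "y", "z", "is_soz", "is_resected", "patient_id"]

UNIT_TRAIN_COLUMNS = ["unit_id", "contact_id", "patient_id", "ap_time_s"]


class ValidationError(ValueError):
    """Raised when an input violates a documented invariant."""


class UnsupportedFormatError(ValueError):
    """Raised for files this package deliberately does not handle."""


Epoch = tuple[float, float]


def validate_epochs(epochs: Sequence[Epoch], duration_s: float | None = None) -> list[Epoch]:
    """Check that epochs are valid half-open intervals, sorted and disjoint.

    Returns the epochs as a sorted list of ``(start, end)`` float tuples.
    """
    out = []
    for start, end in epochs:
        start, end = float(start), float(end)
        if not (np.isfinite(start) and np.isfinite(end)):
            raise ValidationError(f"non-finite epoch ({start}, {end})")
        if start >= end:
            raise ValidationError(f"epoch start >= end: ({start}, {end})")
        if start < 0:
            raise ValidationError(f"epoch starts before recording: ({start}, {end})")
        if duration_s is not None and end > duration_s + 1e-9:
            raise ValidationError(
                f"epoch ({start}, {end}) extends beyond recording duration {duration_s}"
            )
        out.append((start, end))
    out.sort()
    for (s0, e0), (s1, e1) in zip(out, out[1:]):
        if s1 < e0:
            raise ValidationError(f"overlapping epochs ({s0}, {e0}) and ({s1}, {e1})")
    return out


@dataclass
class Recording:
    """A multichannel iEEG recording with per-channel artifact-free epochs.

    Parameters
    ----------
    channel_labels
        One label per channel, unique.
    signal
        Array of shape ``(n_channels, n_samples)`` in microvolts.
    sampling_rate
        Sampling rate in Hz.  Detection requires >= 2000 Hz.
    artifact_free_epochs
        Mapping from channel label to a sorted list of disjoint half-open
        ``[start_s, end_s)`` intervals.  Channels absent from the mapping are
        treated as artifact-free over the whole recording.
    """

    channel_labels: list[str]
    signal: np.ndarray
    sampling_rate: float
    artifact_free_epochs: dict[str, list[Epoch]] = field(default_factory=dict)
    patient_id: str = ""

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=float)
        if self.signal.ndim != 2:
            raise ValidationError("signal must be 2-D (channels x samples)")
        if self.signal.shape[0] != len(self.channel_labels):
            raise ValidationError("signal row count must match channel_labels")
        if len(set(self.channel_labels)) != len(self.channel_labels):
            raise ValidationError("duplicate channel labels")
        if self.sampling_rate <= 0:
            raise ValidationError("sampling_rate must be positive")
        dur = self.duration_s
        self.artifact_free_epochs = {
            ch: validate_epochs(eps, dur) for ch, eps in self.artifact_free_epochs.items()
        }
        for ch in self.artifact_free_epochs:
            if ch not in self.channel_labels:
                raise ValidationError(f"epochs given for unknown channel {ch!r}")

    @property
    def n_channels(self) -> int:
        return self.signal.shape[0]

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]

    @property
    def duration_s(self) -> float:
        return self.signal.shape[1] / self.sampling_rate

    def channel_index(self, label: str) -> int:
        try:
            return self.channel_labels.index(label)
        except ValueError:
            raise KeyError(f"no channel {label!r}") from None

    def epochs_for(self, channel: str) -> list[Epoch]:
        """Artifact-free epochs for a channel (whole recording if none set)."""
        if channel not in self.channel_labels:
            raise KeyError(f"no channel {channel!r}")
        eps = self.artifact_free_epochs.get(channel)
        if not eps:
            return [(0.0, self.duration_s)]
        return eps


@dataclass
class DetectionConfig:
    """Parameters of the two-stage detector.

    The candidate stage thresholds the Hilbert envelope of the band-passed
    signal at ``threshold_sd`` robust standard deviations above the median,
    and keeps excursions lasting at least ``min_cycles`` cycles of the band's
    geometric-mean frequency.  The classification stage runs a complex Morlet
    spectrogram over ``n_freqs`` log-spaced frequencies, whitens each
    frequency row by its background (median) power, and traces isopower
    contours at ``n_contour_levels`` log-spaced levels between the
    ``noise_floor_snr`` (background-relative power units) and the segment
    maximum.  ``edge_trim_s`` of spectrogram is discarded at each segment
    edge, where convolution edge artifacts would otherwise masquerade as
    broadband power.
    """

    ripple_band: tuple[float, float] = RIPPLE_BAND
    fast_ripple_band: tuple[float, float] = FAST_RIPPLE_BAND
    threshold_sd: float = 3.0
    min_cycles: float = 4.0
    wavelet_cycles: float = 6.0
    # spectrogram grid extends above the fast-ripple band so that contours of
    # events near 600 Hz can close below the grid edge
    freq_min: float = 60.0
    freq_max: float = 900.0
    n_freqs: int = 50
    n_contour_levels: int = 12
    noise_floor_snr: float = 12.0
    min_closed_depth: int = 3
    spike_min_span_ratio: float = 4.0
    segment_pad_s: float = 0.25
    edge_trim_s: float = 0.10

    def __post_init__(self) -> None:
        if self.ripple_band[1] > self.fast_ripple_band[0]:
            raise ValidationError("bands must be non-overlapping and ordered")
        if self.threshold_sd <= 0:
            raise ValidationError("threshold_sd must be positive")
        if self.n_contour_levels < 8:
            raise ValidationError("need at least 8 contour levels")


@dataclass
class AnalysisConfig:
    """Full pipeline configuration; serializable to/from JSON."""

    detection: DetectionConfig = field(default_factory=DetectionConfig)
    coincidence_window_s: float = 0.300
    n_surrogates: int = 500
    # event-aligned unit trial construction
    trial_window_s: float = 2.0
    raster_resolution_s: float = 0.001
    kernel_sd_s: float = 0.100
    out_rate_hz: float = 40.0
    baseline_s: float = 0.750
    inclusion_alpha: float = 0.001
    # GLMM optimizer settings, fixed for determinism
    glmm_tol: float = 1e-8
    glmm_max_iter: int = 500
    seed: int = 0

    def to_json(self, path=None) -> str:
        payload = dataclasses.asdict(self)
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text

    @classmethod
    def from_json(cls, source) -> "AnalysisConfig":
        if hasattr(source, "read"):
            payload = json.load(source)
        else:
            text = str(source)
            if text.lstrip().startswith("{"):
                payload = json.loads(text)
            else:
                with open(text) as fh:
                    payload = json.load(fh)
        det = payload.pop("detection", {})
        for key in ("ripple_band", "fast_ripple_band"):
            if key in det:
                det[key] = tuple(det[key])
        return cls(detection=DetectionConfig(**det), **payload)


def empty_events() -> pd.DataFrame:
    """An empty event table with the canonical column set and dtypes."""
    df = pd.DataFrame(columns=EVENT_COLUMNS)
    for col in ("onset_s", "offset_s", "peak_frequency", "spectral_power",
                "log10_power", "duration_s", "latency_to_next_spike_s"):
        df[col] = df[col].astype(float)
    for col in ("prespike", "following_fRonO", "following_RonO"):
        df[col] = df[col].astype(bool)
    return df


def validate_events(events: pd.DataFrame) -> pd.DataFrame:
    """Validate an event table's categories and interval invariants."""
    missing = [c for c in EVENT_COLUMNS if c not in events.columns]
    if missing:
        raise ValidationError(f"event table missing columns: {missing}")
    bad = set(events["category"]) - set(CATEGORIES)
    if bad:
        raise ValidationError(f"unknown event categories: {sorted(bad)}")
    if len(events) and not (events["offset_s"] > events["onset_s"]).all():
        raise ValidationError("event offset_s must exceed onset_s")
    return events
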