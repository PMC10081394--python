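"""File readers and writers: EDF signals, CSV epoch/event/AP tables, TSV layouts.

EDF reading goes through :func:`mne.io.read_raw_edf`.  Writing uses a minimal
EDF encoder implemented here (16-bit, one-second data records), which the mne
reader round-trips in the test suite.
"""

from __future__ import annotations

import struct
from pathlib import Path

import numpy as np
import pandas as pd

from .types import (
    EVENT_COLUMNS,
    LAYOUT_COLUMNS,
    UNIT_TRAIN_COLUMNS,
    Epoch,
    Recording,
    UnsupportedFormatError,
    ValidationError,
    empty_events,
    validate_epochs,
    validate_events,
)

__all__ = [
    "read_recording",
    "write_edf",
    "read_epochs_csv",
    "write_epochs_csv",
    "read_layout",
    "write_layout",
    "read_events",
    "write_events",
    "read_unit_trains",
    "write_unit_trains",
]


# ---------------------------------------------------------------------------
# EDF
# ---------------------------------------------------------------------------

def _edf_field(value, width: int) -> bytes:
    text = f"{value}"
    if len(text) > width:
        # fall back to a compact float representation that fits
        text = f"{float(value):.{max(width - 6, 1)}g}"
    if len(text) > width:
        raise ValueError(f"EDF field {value!r} does not fit in {width} bytes")
    return text.ljust(width).encode("ascii")


def write_edf(path, recording: Recording) -> None:
    """Write a :class:`Recording` as a plain EDF file.

    Uses one-second data records; the signal length must therefore be an
    integer number of seconds.  Samples are quantized to 16 bits over a
    symmetric physical range per channel.
    """
    fs = recording.sampling_rate
    if abs(fs - round(fs)) > 1e-9:
        raise UnsupportedFormatError("EDF writer requires an integer sampling rate")
    fs = int(round(fs))
    n_samp = recording.n_samples
    if n_samp % fs != 0:
        raise UnsupportedFormatError(
            "EDF writer requires a whole number of one-second records; "
            f"got {n_samp} samples at {fs} Hz"
        )
    n_records = n_samp // fs
    ns = recording.n_channels

    # symmetric physical range, at least 1 uV wide to keep the scale finite
    amax = np.maximum(np.abs(recording.signal).max(axis=1), 1.0)
    pmax = np.ceil(amax)
    pmin = -pmax

    header = b"".join([
        _edf_field("0", 8),
        _edf_field(recording.patient_id or "X", 80),
        _edf_field("synthetic iEEG", 80),
        _edf_field("01.01.00", 8),
        _edf_field("00.00.00", 8),
        _edf_field(256 * (ns + 1), 8),
        _edf_field("", 44),
        _edf_field(n_records, 8),
        _edf_field(1, 8),
        _edf_field(ns, 4),
    ])
    per_sig = [
        [_edf_field(lbl, 16) for lbl in recording.channel_labels],
        [_edf_field("", 80)] * ns,                      # transducer
        [_edf_field("uV", 8)] * ns,                     # physical dimension
        [_edf_field(int(p), 8) for p in pmin],
        [_edf_field(int(p), 8) for p in pmax],
        [_edf_field(-32768, 8)] * ns,
        [_edf_field(32767, 8)] * ns,
        [_edf_field("", 80)] * ns,                      # prefiltering
        [_edf_field(fs, 8)] * ns,                       # samples per record
        [_edf_field("", 32)] * ns,
    ]
    scale = (pmax - pmin) / (32767.0 - (-32768.0))
    digital = np.round((recording.signal - pmin[:, None]) / scale[:, None] - 32768.0)
    digital = np.clip(digital, -32768, 32767).astype("<i2")

    with open(path, "wb") as fh:
        fh.write(header)
        for fields in per_sig:
            fh.write(b"".join(fields))
        for rec in range(n_records):
            chunk = digital[:, rec * fs:(rec + 1) * fs]
            fh.write(chunk.tobytes())


def _edf_samples_per_record(path) -> list[int]:
    """Read the per-signal samples-per-record fields from an EDF header."""
    with open(path, "rb") as fh:
        head = fh.read(256)
        if len(head) < 256:
            raise UnsupportedFormatError(f"{path}: truncated EDF header")
        ns = int(head[252:256].decode("ascii", errors="replace").strip())
        sig = fh.read(256 * ns)
    off = ns * (16 + 80 + 8 + 8 + 8 + 8 + 8 + 80)
    out = []
    for i in range(ns):
        fld = sig[off + 8 * i: off + 8 * (i + 1)]
        out.append(int(fld.decode("ascii").strip()))
    return out


def read_recording(path, epochs_path=None, patient_id: str | None = None) -> Recording:
    """Read an EDF file (plus an optional artifact-free epochs CSV).

    All channels must share one sampling rate; mixed rates raise
    :class:`UnsupportedFormatError`.  Time is seconds from recording start.
    """
    import mne

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    spr = _edf_samples_per_record(path)
    if len(set(spr)) > 1:
        raise UnsupportedFormatError(
            f"{path}: mixed per-channel sampling rates {sorted(set(spr))}"
        )
    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    signal = raw.get_data() * 1e6  # mne loads Volts; the canonical unit is uV
    rec = Recording(
        channel_labels=list(raw.ch_names),
        signal=signal,
        sampling_rate=float(raw.info["sfreq"]),
        patient_id=patient_id or "",
    )
    if epochs_path is not None:
        rec.artifact_free_epochs = read_epochs_csv(
            epochs_path, channel_labels=rec.channel_labels, duration_s=rec.duration_s
        )
    return rec


# ---------------------------------------------------------------------------
# Epochs CSV
# ---------------------------------------------------------------------------

def read_epochs_csv(path, channel_labels=None, duration_s=None) -> dict[str, list[Epoch]]:
    """Read artifact-free epochs.

    Columns ``start_s,end_s`` with an optional ``channel`` column; rows
    without a channel apply to every channel.  Epochs are validated (sorted,
    disjoint, within the recording) per channel.
    """
    df = pd.read_csv(path)
    for col in ("start_s", "end_s"):
        if col not in df.columns:
            raise ValidationError(f"epochs file missing column {col!r}")
    has_channel = "channel" in df.columns
    out: dict[str, list[Epoch]] = {}
    if has_channel and channel_labels is None:
        channel_labels = sorted(df["channel"].astype(str).unique())
    if channel_labels is None:
        raise ValidationError("channel_labels required for an epochs file without a channel column")
    for ch in channel_labels:
        if has_channel:
            sub = df[(df["channel"].astype(str) == str(ch)) | df["channel"].isna()]
        else:
            sub = df
        eps = list(zip(sub["start_s"].astype(float), sub["end_s"].astype(float)))
        if eps:
            out[str(ch)] = validate_epochs(eps, duration_s)
    return out


def write_epochs_csv(path, epochs: dict[str, list[Epoch]]) -> None:
    rows = [
        {"channel": ch, "start_s": s, "end_s": e}
        for ch, eps in epochs.items()
        for s, e in eps
    ]
    pd.DataFrame(rows, columns=["channel", "start_s", "end_s"]).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Electrode layout TSV
# ---------------------------------------------------------------------------

_TRUE = {"true", "1", "yes", "t"}
_FALSE = {"false", "0", "no", "f"}


def _to_bool(value, row: int, col: str) -> bool:
    text = str(value).strip().lower()
    if text in _TRUE:
        return True
    if text in _FALSE:
        return False
    raise ValidationError(f"row {row}: cannot parse boolean {col}={value!r}")


def read_layout(path) -> pd.DataFrame:
    """Read an electrode contact table (TSV).

    Required columns: ``contact_id, x, y, z, is_soz, is_resected, patient_id``.
    ``contact_id`` must be unique within each patient; coordinates must be
    finite numbers (mm).
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in LAYOUT_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"layout missing columns: {missing}")
    out = pd.DataFrame()
    out["contact_id"] = df["contact_id"].astype(str)
    for col in ("x", "y", "z"):
        vals = []
        for i, raw in enumerate(df[col]):
            try:
                val = float(raw)
                if not np.isfinite(val):
                    raise ValueError
            except (TypeError, ValueError):
                raise ValidationError(
                    f"row {i + 2}: non-numeric coordinate {col}={raw!r}"
                ) from None
            vals.append(val)
        out[col] = vals
    out["is_soz"] = [_to_bool(v, i + 2, "is_soz") for i, v in enumerate(df["is_soz"])]
    out["is_resected"] = [
        _to_bool(v, i + 2, "is_resected") for i, v in enumerate(df["is_resected"])
    ]
    out["patient_id"] = df["patient_id"].astype(str)
    dup = out.duplicated(subset=["patient_id", "contact_id"])
    if dup.any():
        bad = out.loc[dup, "contact_id"].tolist()
        raise ValidationError(f"duplicate contact_id within patient: {bad}")
    return out


def write_layout(path, layout: pd.DataFrame) -> None:
    layout[LAYOUT_COLUMNS].to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Event tables
# ---------------------------------------------------------------------------

def write_events(events: pd.DataFrame, path) -> None:
    """Write an event table as CSV (lossless float round-trip)."""
    validate_events(events)
    events[EVENT_COLUMNS].to_csv(path, index=False)


def read_events(path) -> pd.DataFrame:
    df = pd.read_csv(path, float_precision="round_trip")
    if df.empty:
        out = empty_events()
        missing = [c for c in EVENT_COLUMNS if c not in df.columns]
        if missing:
            raise ValidationError(f"event table missing columns: {missing}")
        return out
    for col in ("prespike", "following_fRonO", "following_RonO"):
        df[col] = [_to_bool(v, i + 2, col) for i, v in enumerate(df[col])]
    return validate_events(df[EVENT_COLUMNS].copy())


# ---------------------------------------------------------------------------
# Unit AP trains
# ---------------------------------------------------------------------------

def read_unit_trains(path) -> pd.DataFrame:
    """Read unit action-potential times (CSV, one row per AP)."""
    df = pd.read_csv(path, dtype={"unit_id": str, "contact_id": str, "patient_id": str})
    missing = [c for c in UNIT_TRAIN_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"unit train table missing columns: {missing}")
    df["ap_time_s"] = df["ap_time_s"].astype(float)
    if len(df) and (df["ap_time_s"] < 0).any():
        raise ValidationError("negative AP times")
    return df[UNIT_TRAIN_COLUMNS].sort_values(
        ["patient_id", "unit_id", "ap_time_s"], kind="stable"
    ).reset_index(drop=True)


def write_unit_trains(path, trains: pd.DataFrame) -> None:
    trains[UNIT_TRAIN_COLUMNS].to_csv(path, index=False)
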