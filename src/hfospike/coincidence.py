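"""HFO -> spike latency statistics and the uniform-randomization bootstrap null.

For each HFO on a background oscillation (RonO/fRonO) the *minimum positive
latency* to an after-going epileptiform spike onset (RonS, fRonS or
sharp-spike) is computed within its channel; an HFO whose latency is strictly
below the 300 ms window is flagged *pre-spike*.  Chance levels come from a
bootstrap in which HFO onsets are redrawn uniformly within the channel's
artifact-free epochs (spike onsets fixed) and the below-window count is
recomputed per surrogate, per channel and pooled across channels.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .types import SPIKE_CATEGORIES, ValidationError

__all__ = [
    "min_positive_latency",
    "annotate_prespike",
    "annotate_following",
    "bootstrap_null",
    "latency_histogram",
    "CoincidenceResult",
]


def min_positive_latency(hfo_onsets, spike_onsets) -> np.ndarray:
    """Per-HFO minimum strictly positive latency to any spike onset.

    Returns an array aligned with ``hfo_onsets``; NaN where no spike follows.
    Both inputs are onset times (s) within a single channel.
    """
    t = np.asarray(hfo_onsets, dtype=float)
    s = np.sort(np.asarray(spike_onsets, dtype=float))
    if not (np.all(np.isfinite(t)) and np.all(np.isfinite(s))):
        raise ValidationError("onsets must be finite")
    out = np.full(t.shape, np.nan)
    if s.size == 0:
        return out
    idx = np.searchsorted(s, t, side="right")
    has = idx < s.size
    out[has] = s[idx[has]] - t[has]
    return out


def annotate_prespike(events: pd.DataFrame, window_s: float = 0.3,
                      spike_categories=SPIKE_CATEGORIES) -> pd.DataFrame:
    """Flag RonO/fRonO events whose next spike follows within < ``window_s``.

    The minimum positive latency (to the configured spike set, per channel)
    is stored in ``latency_to_next_spike_s`` whether or not it is below the
    window; ``prespike`` uses the strict inequality.
    """
    out = events.copy()
    out["prespike"] = False
    out["latency_to_next_spike_s"] = np.nan
    for (_, _), idx in out.groupby(["patient_id", "contact_id"]).groups.items():
        sub = out.loc[idx]
        hfo_mask = sub["category"].isin(["RonO", "fRonO"])
        if not hfo_mask.any():
            continue
        spikes = sub.loc[sub["category"].isin(spike_categories), "onset_s"].to_numpy()
        lat = min_positive_latency(sub.loc[hfo_mask, "onset_s"].to_numpy(), spikes)
        out.loc[sub.index[hfo_mask], "latency_to_next_spike_s"] = lat
        out.loc[sub.index[hfo_mask], "prespike"] = lat < window_s
    return out


def annotate_following(events: pd.DataFrame, window_s: float = 0.3) -> pd.DataFrame:
    """Flag RonS/fRonS events preceded (< ``window_s``) by an fRonO or RonO.

    ``following_fRonO`` is true iff some fRonO onset lies in the open
    interval ``(onset - window, onset)`` on the same channel; analogously
    ``following_RonO``.  Both flags may be true.
    """
    out = events.copy()
    out["following_fRonO"] = False
    out["following_RonO"] = False
    for (_, _), idx in out.groupby(["patient_id", "contact_id"]).groups.items():
        sub = out.loc[idx]
        ons_mask = sub["category"].isin(["RonS", "fRonS"])
        if not ons_mask.any():
            continue
        targets = sub.loc[ons_mask, "onset_s"].to_numpy()
        for col, cat in (("following_fRonO", "fRonO"), ("following_RonO", "RonO")):
            src = np.sort(sub.loc[sub["category"] == cat, "onset_s"].to_numpy())
            if src.size == 0:
                continue
            # any source onset strictly inside (t - window, t)
            lo = np.searchsorted(src, targets - window_s, side="right")
            hi = np.searchsorted(src, targets, side="left")
            out.loc[sub.index[ons_mask], col] = hi > lo
    return out


@dataclass
class CoincidenceResult:
    """Observed vs surrogate below-window latency counts for one scope."""

    scope: str
    window_s: float
    observed_count: int
    surrogate_mean: float
    surrogate_sd: float
    z_score: float                 # NaN when the surrogate sd is zero
    empirical_p: float             # add-one convention, in (0, 1]
    degenerate_sd: bool
    n_surrogates: int
    seed: int
    n_hfo: int
    latency_bin_edges: list[float] | None = None
    latency_counts: list[int] | None = None

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _count_below(onsets: np.ndarray, spikes: np.ndarray, window_s: float) -> np.ndarray:
    """Below-window latency counts; ``onsets`` may be 1-D or (n_surr, n)."""
    if spikes.size == 0:
        return np.zeros(onsets.shape[:-1] or (), dtype=int)
    idx = np.searchsorted(spikes, onsets, side="right")
    lat = np.where(idx < spikes.size, spikes[np.minimum(idx, spikes.size - 1)] - onsets,
                   np.inf)
    return ((lat > 0) & (lat < window_s)).sum(axis=-1)


def bootstrap_null(hfo_events: pd.DataFrame, spike_events: pd.DataFrame,
                   artifact_free_epochs: dict, n_surrogates: int = 500,
                   window_s: float = 0.3, seed: int = 0,
                   histogram_edges=None) -> dict[str, CoincidenceResult]:
    """Bootstrap test of HFO -> spike coincidence against a uniform null.

    Per surrogate, the same number of HFO onsets per channel is redrawn
    uniformly over that channel's artifact-free epochs; spike onsets stay
    fixed; the count of latencies below ``window_s`` is recomputed.  Returns
    one :class:`CoincidenceResult` per channel plus the pooled result under
    key ``"pooled"`` (pooled statistic = sum of per-channel counts; redraw
    done per channel, then summed).
    """
    if n_surrogates < 1:
        raise ValidationError("n_surrogates must be >= 1")
    if len(hfo_events) == 0:
        raise ValidationError("need at least one HFO event")
    rng = np.random.default_rng(seed)
    if histogram_edges is None:
        histogram_edges = np.arange(0.0, window_s + 1e-9, window_s / 6)

    channels = sorted(set(hfo_events["contact_id"]))
    results: dict[str, CoincidenceResult] = {}
    pooled_obs = 0
    pooled_surr = np.zeros(n_surrogates, dtype=int)
    all_lat = []

    def make_result(scope, obs, surr, n_hfo, lat=None):
        mean = float(surr.mean())
        sd = float(surr.std(ddof=1)) if surr.size > 1 else 0.0
        degenerate = sd == 0.0
        z = (obs - mean) / sd if not degenerate else float("nan")
        p = (1 + int((surr >= obs).sum())) / (n_surrogates + 1)
        edges = counts = None
        if lat is not None:
            hist = latency_histogram(lat[np.isfinite(lat)], histogram_edges)
            edges = [float(x) for x in histogram_edges]
            counts = [int(c) for c in hist["counts"]]
        return CoincidenceResult(
            scope=scope, window_s=window_s, observed_count=int(obs),
            surrogate_mean=mean, surrogate_sd=sd, z_score=float(z),
            empirical_p=float(p), degenerate_sd=degenerate,
            n_surrogates=n_surrogates, seed=seed, n_hfo=int(n_hfo),
            latency_bin_edges=edges, latency_counts=counts)

    for ch in channels:
        hfo_on = hfo_events.loc[hfo_events["contact_id"] == ch, "onset_s"].to_numpy()
        spikes = np.sort(
            spike_events.loc[spike_events["contact_id"] == ch, "onset_s"].to_numpy())
        epochs = artifact_free_epochs.get(ch)
        if not epochs:
            raise ValidationError(f"no artifact-free epochs for channel {ch!r}")
        lengths = np.array([e - s for s, e in epochs], dtype=float)
        starts = np.array([s for s, _ in epochs], dtype=float)
        total = lengths.sum()
        if total <= 0:
            raise ValidationError(f"zero artifact-free duration for channel {ch!r}")
        lat = min_positive_latency(hfo_on, spikes)
        all_lat.append(lat)
        obs = _count_below(np.sort(hfo_on), spikes, window_s)
        u = rng.uniform(0.0, total, size=(n_surrogates, hfo_on.size))
        seg = np.searchsorted(np.cumsum(lengths), u, side="right")
        seg = np.minimum(seg, lengths.size - 1)
        offs = u - np.concatenate([[0.0], np.cumsum(lengths)])[seg]
        draws = np.sort(starts[seg] + offs, axis=1)
        surr = _count_below(draws, spikes, window_s)
        results[ch] = make_result(ch, obs, surr, hfo_on.size, lat)
        pooled_obs += int(obs)
        pooled_surr += surr

    results["pooled"] = make_result(
        "pooled", pooled_obs, pooled_surr, len(hfo_events),
        np.concatenate(all_lat) if all_lat else None)
    return results


def latency_histogram(latencies, bin_edges) -> dict:
    """Histogram of latencies with normalized fractions.

    Latencies at or beyond the last edge are dropped and their number
    reported under ``n_dropped``.
    """
    edges = np.asarray(bin_edges, dtype=float)
    if edges.ndim != 1 or edges.size < 2 or np.any(np.diff(edges) <= 0):
        raise ValidationError("bin edges must be sorted and increasing")
    lat = np.asarray(latencies, dtype=float)
    lat = lat[np.isfinite(lat)]
    keep = lat < edges[-1]
    counts, _ = np.histogram(lat[keep], bins=edges)
    total = counts.sum()
    fractions = counts / total if total else np.zeros_like(counts, dtype=float)
    return {
        "edges": edges,
        "counts": counts,
        "fractions": fractions,
        "n_dropped": int((~keep).sum()),
    }
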