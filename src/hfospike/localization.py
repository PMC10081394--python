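"""Patient-level localization metrics.

* SOZ ratio / resection ratio: the fraction of a patient's (selected) events
  detected on seizure-onset-zone / resected contacts.
* Fast-ripple rate-distance radius difference: a complete contact graph is
  weighted by the pairwise mean fast-ripple rate (events/min) times the
  Euclidean distance (mm); the graph *radius* is the minimum eccentricity
  under shortest-path distances.  The radius difference between the full
  contact set and the resected subset is reported as a signed square root.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.sparse.csgraph import shortest_path

from .types import ValidationError

__all__ = [
    "soz_ratio",
    "resection_ratio",
    "select_fr_events",
    "rate_distance_adjacency",
    "graph_radius",
    "radius_difference",
    "LocalizationResult",
    "RateDistanceGraph",
]


@dataclass
class LocalizationResult:
    patient_id: str
    selection: str
    ratio: float          # NaN when undefined (no events)
    n_events: int
    defined: bool

    def to_dict(self) -> dict:
        return {"patient_id": self.patient_id, "selection": self.selection,
                "ratio": self.ratio, "n_events": self.n_events,
                "defined": self.defined}


def _flag_ratio(events: pd.DataFrame, layout: pd.DataFrame, flag: str,
                selection: str) -> list[LocalizationResult]:
    known = set(layout["contact_id"])
    unknown = set(events["contact_id"]) - known
    if unknown:
        raise ValidationError(f"events reference unknown contacts: {sorted(unknown)}")
    flag_by_contact = dict(zip(zip(layout["patient_id"], layout["contact_id"]),
                               layout[flag]))
    out = []
    patients = sorted(set(layout["patient_id"]))
    for pid in patients:
        sub = events[events["patient_id"] == pid]
        n = len(sub)
        if n == 0:
            out.append(LocalizationResult(pid, selection, float("nan"), 0, False))
            continue
        hits = sum(bool(flag_by_contact.get((pid, c), False))
                   for c in sub["contact_id"])
        out.append(LocalizationResult(pid, selection, hits / n, n, True))
    return out


def soz_ratio(events: pd.DataFrame, layout: pd.DataFrame,
              selection: str = "all") -> list[LocalizationResult]:
    """Per-patient fraction of events on seizure-onset-zone contacts."""
    return _flag_ratio(events, layout, "is_soz", selection)


def resection_ratio(events: pd.DataFrame, layout: pd.DataFrame,
                    selection: str = "all") -> list[LocalizationResult]:
    """Per-patient fraction of events on resected contacts."""
    return _flag_ratio(events, layout, "is_resected", selection)


def select_fr_events(events: pd.DataFrame) -> pd.DataFrame:
    """Fast-ripple selection for the rate-distance graph.

    Keeps every fRonS plus the fRonO with peak spectral frequency strictly
    above 350 Hz.
    """
    keep = (events["category"] == "fRonS") | (
        (events["category"] == "fRonO") & (events["peak_frequency"] > 350.0))
    return events[keep].copy()


@dataclass
class RateDistanceGraph:
    contact_ids: list[str]
    weights: np.ndarray   # (n, n) symmetric, zero diagonal; events/min * mm
    rates: np.ndarray     # per-contact event rate, events/min

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ValidationError("weight matrix must be square")
        if (w < 0).any():
            raise ValidationError("negative edge weight")
        if not np.allclose(w, w.T):
            raise ValidationError("weight matrix must be symmetric")
        self.weights = w

    def subgraph(self, contact_ids) -> "RateDistanceGraph":
        idx = [self.contact_ids.index(c) for c in contact_ids]
        return RateDistanceGraph(list(contact_ids),
                                 self.weights[np.ix_(idx, idx)],
                                 self.rates[idx])


def rate_distance_adjacency(events: pd.DataFrame, layout: pd.DataFrame,
                            recording_minutes: float) -> RateDistanceGraph:
    """Complete contact graph weighted by mean pairwise rate x distance.

    Per-contact rates are selected events per artifact-free minute; the
    weight between contacts i and j is ``((r_i + r_j)/2) * d_ij`` with
    ``d_ij`` the Euclidean distance in mm.  Coincident contacts (d = 0) get
    weight 0.
    """
    if recording_minutes <= 0:
        raise ValidationError("recording_minutes must be positive")
    if len(layout) < 2:
        raise ValidationError("need at least 2 contacts")
    contacts = list(layout["contact_id"])
    counts = events["contact_id"].value_counts()
    rates = np.array([counts.get(c, 0) / recording_minutes for c in contacts])
    xyz = layout[["x", "y", "z"]].to_numpy(float)
    d = np.sqrt(((xyz[:, None, :] - xyz[None, :, :]) ** 2).sum(-1))
    w = 0.5 * (rates[:, None] + rates[None, :]) * d
    np.fill_diagonal(w, 0.0)
    return RateDistanceGraph(contacts, w, rates)


def graph_radius(graph: RateDistanceGraph) -> tuple[float, bool]:
    """Graph radius: minimum eccentricity under shortest-path distances.

    Edge weights are treated as connection lengths; zero-weight edges are
    absent.  A node's eccentricity is its maximum *finite* shortest-path
    distance to the others.  Returns ``(radius, connected)``; a single node
    has radius 0.
    """
    n = len(graph.contact_ids)
    if n == 0:
        raise ValidationError("empty graph")
    if n == 1:
        return 0.0, True
    w = graph.weights.copy()
    w[w == 0.0] = np.inf
    np.fill_diagonal(w, 0.0)
    dist = shortest_path(w, method="D", directed=False)
    off = ~np.eye(n, dtype=bool)
    finite = np.isfinite(dist) & off
    connected = bool(finite.sum() == n * (n - 1))
    ecc = np.array([
        dist[i][finite[i]].max() if finite[i].any() else 0.0 for i in range(n)
    ])
    return float(ecc.min()), connected


def radius_difference(graph_all: RateDistanceGraph,
                      resected_contacts) -> dict:
    """Signed-root difference between full and resected-subgraph radii.

    ``delta = radius(all) - radius(resected)``; the statistic is
    ``sign(delta) * sqrt(|delta|)``.  The resected subgraph inherits the
    full graph's per-contact rates and distances.  An empty resected set is
    flagged rather than an error.
    """
    resected = list(resected_contacts)
    unknown = set(resected) - set(graph_all.contact_ids)
    if unknown:
        raise ValidationError(f"unknown resected contacts: {sorted(unknown)}")
    r_all, conn_all = graph_radius(graph_all)
    if not resected:
        return {"radius_all": r_all, "radius_resected": float("nan"),
                "radius_difference": float("nan"), "defined": False,
                "connected": conn_all}
    sub = graph_all.subgraph(resected)
    r_res, conn_res = graph_radius(sub)
    delta = r_all - r_res
    stat = float(np.sign(delta) * np.sqrt(abs(delta)))
    return {"radius_all": r_all, "radius_resected": r_res,
            "radius_difference": stat, "defined": True,
            "connected": conn_all and conn_res}
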