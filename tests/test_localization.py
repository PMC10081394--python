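import numpy as np
import pandas as pd
import pytest

from hfospike import localization as loc
from hfospike.types import ValidationError
from conftest import random_event_table


def make_layout(n, soz=(), resected=(), patient="p1", rng=None):
    rng = rng or np.random.default_rng(0)
    xyz = rng.uniform(0, 50, size=(n, 3))
    return pd.DataFrame({
        "contact_id": [f"c{i}" for i in range(n)],
        "x": xyz[:, 0], "y": xyz[:, 1], "z": xyz[:, 2],
        "is_soz": [i in soz for i in range(n)],
        "is_resected": [i in resected for i in range(n)],
        "patient_id": patient,
    })


def make_events(contacts, patient="p1"):
    rng = np.random.default_rng(1)
    ev = random_event_table(rng, len(contacts), channels=("x",))
    ev["contact_id"] = contacts
    ev["patient_id"] = patient
    return ev


class TestRatios:
    def test_soz_ratio_simple(self):
        layout = make_layout(4, soz=(0, 1))
        ev = make_events(["c0"] * 4 + ["c1"] * 2 + ["c2"] * 4)
        (res,) = loc.soz_ratio(ev, layout)
        assert res.defined and np.isclose(res.ratio, 0.6)

    def test_zero_events_flagged_undefined(self):
        layout = make_layout(3, soz=(0,))
        (res,) = loc.soz_ratio(make_events([]).iloc[:0], layout)
        assert not res.defined and np.isnan(res.ratio)

    def test_all_soz_gives_one(self):
        layout = make_layout(3, soz=(0, 1, 2))
        (res,) = loc.soz_ratio(make_events(["c0", "c1", "c2"]), layout)
        assert res.ratio == 1.0

    def test_resection_ratio_simple(self):
        layout = make_layout(4, resected=(3,))
        ev = make_events(["c3"] * 3 + ["c0"] * 9)
        (res,) = loc.resection_ratio(ev, layout)
        assert np.isclose(res.ratio, 0.25)

    def test_no_resected_contacts_zero(self):
        layout = make_layout(3)
        (res,) = loc.resection_ratio(make_events(["c0", "c1"]), layout)
        assert res.ratio == 0.0

    def test_unknown_contact_rejected(self):
        layout = make_layout(2)
        with pytest.raises(ValidationError):
            loc.soz_ratio(make_events(["c9"]), layout)

    def test_complement_sums_to_one(self, rng):
        layout = make_layout(6, soz=(1, 4))
        contacts = list(rng.choice([f"c{i}" for i in range(6)], 30))
        ev = make_events(contacts)
        (res,) = loc.soz_ratio(ev, layout)
        inv = layout.copy()
        inv["is_soz"] = ~inv["is_soz"]
        (res_inv,) = loc.soz_ratio(ev, inv)
        assert np.isclose(res.ratio + res_inv.ratio, 1.0)

    def test_matches_brute_force_recount(self, rng):
        for _ in range(100):
            n = int(rng.integers(2, 8))
            soz = tuple(i for i in range(n) if rng.random() < 0.4)
            layout = make_layout(n, soz=soz, rng=rng)
            contacts = list(rng.choice([f"c{i}" for i in range(n)],
                                       int(rng.integers(1, 25))))
            ev = make_events(contacts)
            (res,) = loc.soz_ratio(ev, layout)
            want = sum(int(c[1:]) in soz for c in contacts) / len(contacts)
            assert np.isclose(res.ratio, want)


class TestSelectFrEvents:
    def test_selection_rules(self):
        ev = make_events(["c0"] * 4)
        ev["category"] = ["fRonO", "fRonO", "RonS", "fRonS"]
        ev["peak_frequency"] = [360.0, 350.0, 150.0, 250.0]
        out = loc.select_fr_events(ev)
        # fRonO at 360 kept; at exactly 350 dropped; RonS dropped; fRonS kept
        assert list(out["category"]) == ["fRonO", "fRonS"]
        assert list(out["peak_frequency"]) == [360.0, 250.0]


class TestRateDistance:
    def test_two_contact_example(self):
        layout = make_layout(2)
        layout.loc[0, ["x", "y", "z"]] = [0.0, 0.0, 0.0]
        layout.loc[1, ["x", "y", "z"]] = [10.0, 0.0, 0.0]
        ev = make_events(["c0"] * 20 + ["c1"] * 40)
        graph = loc.rate_distance_adjacency(ev, layout, recording_minutes=10.0)
        # rates 2 and 4 events/min, 10 mm apart -> ((2+4)/2)*10 = 30
        assert np.isclose(graph.weights[0, 1], 30.0)
        assert graph.weights[0, 0] == 0.0

    def test_zero_rates_zero_matrix(self):
        layout = make_layout(3)
        graph = loc.rate_distance_adjacency(make_events([]).iloc[:0], layout, 5.0)
        assert np.all(graph.weights == 0)

    def test_matches_brute_force(self, rng):
        for _ in range(100):
            n = int(rng.integers(2, 7))
            layout = make_layout(n, rng=rng)
            contacts = list(rng.choice([f"c{i}" for i in range(n)],
                                       int(rng.integers(0, 20))))
            minutes = float(rng.uniform(1, 30))
            graph = loc.rate_distance_adjacency(make_events(contacts), layout,
                                                minutes)
            for i in range(n):
                for j in range(n):
                    ri = contacts.count(f"c{i}") / minutes
                    rj = contacts.count(f"c{j}") / minutes
                    d = np.linalg.norm(
                        layout.iloc[i][["x", "y", "z"]].to_numpy(float)
                        - layout.iloc[j][["x", "y", "z"]].to_numpy(float))
                    want = 0.0 if i == j else 0.5 * (ri + rj) * d
                    assert np.isclose(graph.weights[i, j], want)

    def test_negative_weight_rejected(self):
        with pytest.raises(ValidationError):
            loc.RateDistanceGraph(["a", "b"],
                                  np.array([[0.0, -1.0], [-1.0, 0.0]]),
                                  np.zeros(2))


def nx_radius(weights):
    """Independent oracle: eccentricities via networkx Dijkstra."""
    import networkx as nx
    n = weights.shape[0]
    if n == 1:
        return 0.0
    g = nx.Graph()
    g.add_nodes_from(range(n))
    for i in range(n):
        for j in range(i + 1, n):
            if weights[i, j] > 0:
                g.add_edge(i, j, weight=weights[i, j])
    lengths = dict(nx.all_pairs_dijkstra_path_length(g, weight="weight"))
    eccs = []
    for i in range(n):
        finite = [d for j, d in lengths.get(i, {}).items() if j != i]
        eccs.append(max(finite) if finite else 0.0)
    return min(eccs)


class TestGraphRadius:
    def test_single_node(self):
        g = loc.RateDistanceGraph(["a"], np.zeros((1, 1)), np.zeros(1))
        assert loc.graph_radius(g) == (0.0, True)

    def test_triangle_with_shortcut(self):
        w = np.array([[0, 12, 7], [12, 0, 5], [7, 5, 0]], dtype=float)
        g = loc.RateDistanceGraph(list("abc"), w, np.zeros(3))
        radius, connected = loc.graph_radius(g)
        assert connected
        assert np.isclose(radius, nx_radius(w))

    def test_random_graphs_match_oracle(self, rng):
        for _ in range(100):
            n = int(rng.integers(1, 13))
            w = rng.uniform(0, 10, size=(n, n))
            w = np.triu(w, 1)
            w[rng.random(w.shape) < 0.3] = 0.0  # drop some edges
            w = w + w.T
            g = loc.RateDistanceGraph([str(i) for i in range(n)], w,
                                      np.zeros(n))
            radius, _ = loc.graph_radius(g)
            assert np.isclose(radius, nx_radius(w))

    def test_radius_scales_linearly(self, rng):
        n = 8
        w = rng.uniform(1, 5, size=(n, n))
        w = np.triu(w, 1)
        w = w + w.T
        g = loc.RateDistanceGraph([str(i) for i in range(n)], w, np.zeros(n))
        r1, _ = loc.graph_radius(g)
        for k in (0.25, 0.5, 1.0):
            gk = loc.RateDistanceGraph([str(i) for i in range(n)], k * w,
                                       np.zeros(n))
            rk, _ = loc.graph_radius(gk)
            assert np.isclose(rk, k * r1)


class TestRadiusDifference:
    def _graph(self, w, ids=None):
        n = w.shape[0]
        return loc.RateDistanceGraph(ids or [str(i) for i in range(n)], w,
                                     np.zeros(n))

    def test_positive_difference_square_root(self):
        # full radius 25 (A: shortest to C is direct 25); resected {A,B}: 9
        w = np.array([[0, 9, 25], [9, 0, 34], [25, 34, 0]], dtype=float)
        out = loc.radius_difference(self._graph(w, list("ABC")), ["A", "B"])
        assert np.isclose(out["radius_all"], 25.0)
        assert np.isclose(out["radius_resected"], 9.0)
        assert np.isclose(out["radius_difference"], 4.0)

    def test_equal_radii_zero(self):
        w = np.array([[0, 5.0], [5.0, 0]])
        out = loc.radius_difference(self._graph(w), ["0", "1"])
        assert out["radius_difference"] == 0.0

    def test_negative_difference_signed_root(self):
        # hub shortcut: full radius 3; removing the hub leaves radius 10
        w = np.array([[0, 3, 10], [3, 0, 3], [10, 3, 0]], dtype=float)
        out = loc.radius_difference(self._graph(w, list("ABC")), ["A", "C"])
        assert np.isclose(out["radius_all"], 3.0)
        assert np.isclose(out["radius_resected"], 10.0)
        assert np.isclose(out["radius_difference"], -np.sqrt(7.0))

    def test_empty_resection_flagged(self):
        w = np.array([[0, 5.0], [5.0, 0]])
        out = loc.radius_difference(self._graph(w), [])
        assert not out["defined"]

    def test_unknown_contacts_rejected(self):
        w = np.array([[0, 5.0], [5.0, 0]])
        with pytest.raises(ValidationError):
            loc.radius_difference(self._graph(w), ["zz"])


def test_prespike_soz_contrast_on_ground_truth():
    """With coupling planted only on SOZ contacts, pre-spike fRonO concentrate
    in the SOZ more than solitary fRonO (rank-sum across patients)."""
    from scipy import stats
    from hfospike import coincidence as coin
    from hfospike import synth

    spec = synth.SyntheticCohortSpec(
        n_patients=6, n_channels=4, duration_s=600, seed=11,
        coupling_prob=(0.6, 0.0))
    pre_ratios, sol_ratios = [], []
    import numpy as np
    ss = np.random.SeedSequence(spec.seed)
    for i, child in enumerate(ss.spawn(spec.n_patients)):
        pid = f"pt{i:02d}"
        seed = int(child.generate_state(1)[0] % (2 ** 31))
        layout = synth.generate_layout(spec, pid, seed)
        rec = synth.generate_background(spec.duration_s, 2000, spec.n_channels,
                                        seed + 1, spec.broadband_rms_uv,
                                        spec.slow_rms_uv)
        rec.patient_id = pid
        _, truth = synth.inject_events(rec, spec, layout, seed + 2)
        # ground-truth events as an annotated event table
        ev = truth.rename(columns={"channel": "contact_id",
                                   "center_frequency": "peak_frequency"})
        ev["duration_s"] = ev["offset_s"] - ev["onset_s"]
        ev["spectral_power"] = 100.0
        ev["log10_power"] = 2.0
        ev["prespike"] = False
        ev["following_fRonO"] = False
        ev["following_RonO"] = False
        ev["latency_to_next_spike_s"] = np.nan
        ev = coin.annotate_prespike(ev)
        fr = ev[ev["category"] == "fRonO"]
        pre = fr[fr["prespike"]]
        sol = fr[~fr["prespike"]]
        if len(pre) and len(sol):
            pre_ratios.append(loc.soz_ratio(pre, layout)[0].ratio)
            sol_ratios.append(loc.soz_ratio(sol, layout)[0].ratio)
    assert len(pre_ratios) >= 4
    assert np.median(pre_ratios) > np.median(sol_ratios)
    p = stats.ranksums(pre_ratios, sol_ratios, alternative="greater").pvalue
    assert p < 0.05
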