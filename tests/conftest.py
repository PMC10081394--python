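import numpy as np
import pandas as pd
import pytest

from hfospike import synth
from hfospike.types import DetectionConfig, Recording


@pytest.fixture(scope="session")
def det_config():
    return DetectionConfig()


@pytest.fixture(scope="session")
def small_injected():
    """A 2-channel, 2-minute recording with planted events of all categories."""
    spec = synth.SyntheticCohortSpec(
        n_channels=2, duration_s=120, seed=3,
        event_rates={c: (3.0, 3.0) for c in
                     ["RonO", "RonS", "fRonO", "fRonS", "SharpSpike"]},
        coupling_prob=(0.0, 0.0))
    layout = synth.generate_layout(spec, "p0", 1)
    rec = synth.generate_background(120, 2000, 2, 7,
                                    spec.broadband_rms_uv, spec.slow_rms_uv)
    rec.patient_id = "p0"
    rec, truth = synth.inject_events(rec, spec, layout, 11)
    return rec, truth, layout, spec


@pytest.fixture()
def rng():
    return np.random.default_rng(20260926)


def random_event_table(rng, n, channels=("ch00", "ch01"), duration_s=600.0):
    """A randomized but valid event table for round-trip / oracle tests."""
    cats = rng.choice(["RonO", "RonS", "fRonO", "fRonS", "SharpSpike"], size=n)
    onset = np.sort(rng.uniform(0, duration_s, n))
    dur = rng.uniform(0.01, 0.15, n)
    peak = np.where(np.char.startswith(cats.astype(str), "f"),
                    rng.uniform(200, 600, n), rng.uniform(80, 200, n))
    peak = np.where(cats == "SharpSpike", np.nan, peak)
    power = rng.uniform(10, 1e4, n)
    return pd.DataFrame({
        "patient_id": "pt00",
        "contact_id": rng.choice(list(channels), size=n),
        "onset_s": onset,
        "offset_s": onset + dur,
        "category": cats,
        "peak_frequency": peak,
        "spectral_power": power,
        "log10_power": np.log10(power),
        "duration_s": dur,
        "prespike": rng.random(n) < 0.3,
        "following_fRonO": rng.random(n) < 0.2,
        "following_RonO": rng.random(n) < 0.2,
        "latency_to_next_spike_s": np.where(rng.random(n) < 0.5,
                                            rng.uniform(0, 1, n), np.nan),
    })


@pytest.fixture()
def make_recording():
    def _make(signal, fs=2000.0, epochs=None, patient="p0"):
        signal = np.atleast_2d(np.asarray(signal, dtype=float))
        labels = [f"ch{i:02d}" for i in range(signal.shape[0])]
        return Recording(channel_labels=labels, signal=signal, sampling_rate=fs,
                         artifact_free_epochs=epochs or {}, patient_id=patient)
    return _make
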