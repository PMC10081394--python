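import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest

from hfospike import units as un
from hfospike.types import ValidationError


class TestBuildTrial:
    def test_empty_train_zero_trace(self):
        trace = un.build_trial([], 10.0)
        assert trace.shape == (80,)
        assert np.all(trace == 0)

    def test_single_ap_integrates_to_one_spike(self):
        trace = un.build_trial([10.0], 10.0)
        assert abs(trace.sum() * 0.025 - 1.0) < 1e-3

    def test_poisson_grand_mean_within_3_sigma_everywhere(self, rng):
        rate = 10.0
        n_trials = 500
        traces = np.zeros((n_trials, 80))
        for i in range(n_trials):
            n = rng.poisson(rate * 4.0)
            ap = np.sort(rng.uniform(0, 4.0, n))
            traces[i] = un.build_trial(ap, 2.0)
        grand = traces.mean(axis=0)
        # variance of a kernel-smoothed Poisson rate estimate at a point
        kernel_l2 = 1.0 / (2 * np.sqrt(np.pi) * 0.1)
        sd = np.sqrt(rate * kernel_l2 / n_trials)
        inner = slice(16, 64)  # kernel reach (4 SD = 16 bins) from the edges
        assert np.all(np.abs(grand[inner] - rate) < 3.5 * sd)

    def test_count_conservation_for_interior_aps(self, rng):
        ap = np.sort(rng.uniform(9.5, 10.5, 17))  # >= 4 SD from window edges
        trace = un.build_trial(ap, 10.0)
        assert abs(trace.sum() * 0.025 - 17) < 1e-6


class TestFiringFeatures:
    def test_constant_trace(self):
        f = un.firing_features(np.full(80, 5.0), duration_s=0.05)
        assert (f.bl_fr, f.hfo_fr, f.hfodiff_fr) == (5.0, 5.0, 0.0)

    def test_peak_inside_event(self):
        trace = np.full(80, 2.0)
        trace[41] = 8.0
        f = un.firing_features(trace, duration_s=0.06)
        assert (f.bl_fr, f.hfo_fr, f.hfodiff_fr) == (2.0, 8.0, 6.0)

    def test_matches_brute_force(self, rng):
        for _ in range(100):
            trace = rng.uniform(0, 20, 80)
            dur = float(rng.uniform(0.01, 0.9))
            f = un.firing_features(trace, dur)
            bl = trace[10:40].mean()
            hfo = trace[40:40 + int(np.ceil(dur / 0.025))].max()
            assert np.isclose(f.bl_fr, bl) and np.isclose(f.hfo_fr, hfo)
            assert np.isclose(f.hfodiff_fr, hfo - bl)

    def test_long_event_truncated_and_flagged(self):
        f = un.firing_features(np.ones(80), duration_s=1.5)
        assert f.truncated

    def test_invariant_to_aps_outside_kernel_reach(self):
        near = [9.7, 10.02, 10.05]
        far = near + [8.3, 11.9, 12.5]
        dur = 0.08
        f1 = un.firing_features(un.build_trial(near, 10.0), dur)
        f2 = un.firing_features(un.build_trial(far, 10.0), dur)
        assert np.isclose(f1.bl_fr, f2.bl_fr)
        assert np.isclose(f1.hfo_fr, f2.hfo_fr)

    def test_zero_duration_rejected(self):
        with pytest.raises(ValidationError):
            un.firing_features(np.ones(80), duration_s=0.0)


def _trials_frame(rows):
    return pd.DataFrame(rows, columns=["unit_id", "category", "bl_fr", "hfo_fr"])


class TestUnitInclusion:
    def test_identical_rates_excluded(self):
        trials = _trials_frame([("u1", "fRonO", 5.0, 5.0)] * 100)
        res = un.unit_inclusion(trials)
        assert not res["included"].any()
        assert "zero-variance" in res["reason"].iloc[0]

    def test_single_trial_excluded(self):
        res = un.unit_inclusion(_trials_frame([("u1", "RonO", 2.0, 9.0)]))
        assert not res["included"].any()
        assert "fewer than 2" in res["reason"].iloc[0]

    def test_planted_gain_included(self, rng):
        rows = [("u1", "fRonO", b, h) for b, h in
                zip(rng.normal(10, 1, 200), rng.normal(30, 3, 200))]
        res = un.unit_inclusion(_trials_frame(rows))
        assert res["included"].all()

    def test_power_simulation_through_trial_machinery(self, rng):
        # 200 trials of a 10 Hz unit tripling its rate during 50 ms events:
        # the paired test must include the unit at alpha = 0.001
        rows = []
        for _ in range(200):
            base = rng.poisson(10.0 * 4.0)
            ap = list(rng.uniform(0, 4.0, base))
            ap += list(rng.uniform(2.0, 2.05, rng.poisson(2 * 10.0 * 0.05)))
            trace = un.build_trial(np.sort(ap), 2.0)
            f = un.firing_features(trace, 0.05)
            rows.append(("u1", "fRonO", f.bl_fr, f.hfo_fr))
        res = un.unit_inclusion(_trials_frame(rows))
        assert res["included"].all()

    def test_holm_is_monotone(self, rng):
        # Holm-adjusted inclusions are a subset of unadjusted ones
        rows = []
        for u in range(12):
            shift = rng.uniform(0, 1.5)
            for b in rng.normal(10, 1, 30):
                rows.append((f"u{u}", "RonO", b, b + shift + rng.normal(0, 1)))
        res = un.unit_inclusion(_trials_frame(rows), alpha=0.05)
        assert ((res["p_holm"] >= res["p"]) | res["p"].isna()).all()
        assert set(res.loc[res["included"], "unit_id"]) <= \
            set(res.loc[res["p"] <= 0.05, "unit_id"])


class TestAssembleModelTable:
    def _trials(self, n_events=10, units=("u1", "u2", "u3")):
        rows = []
        for e in range(n_events):
            for u in units:
                rows.append({
                    "event_id": e, "unit_id": u, "contact_id": "c1",
                    "patient_id": "p1", "category": "fRonO",
                    "bl_fr": 5.0, "hfo_fr": 9.0, "hfodiff_fr": 4.0,
                    "log10_power": 2.0, "prespike": e % 2 == 0,
                    "following_fRonO": False, "following_RonO": False,
                })
        return pd.DataFrame(rows)

    def _inclusion(self, units, category="fRonO"):
        return pd.DataFrame({"unit_id": list(units), "category": category,
                             "n_trials": 10, "t": 5.0, "p": 1e-6,
                             "p_holm": 1e-5, "included": True, "reason": ""})

    def test_row_count(self):
        table = un.assemble_model_table(self._trials(), self._inclusion(
            ["u1", "u2", "u3"]), "fRonO")
        assert len(table) == 30
        assert set(table["status"]) == {0.0, 1.0}

    def test_excluded_unit_contributes_nothing(self):
        table = un.assemble_model_table(self._trials(), self._inclusion(["u1"]),
                                        "fRonO")
        assert set(table["unit_id"]) == {"u1"}
        assert len(table) == 10

    def test_missing_annotation_rejected(self):
        trials = self._trials().drop(columns=["prespike"])
        with pytest.raises(ValidationError):
            un.assemble_model_table(trials, self._inclusion(["u1"]), "fRonO")


def simulate_model_table(rng, n=800, n_units=10, n_contacts=4, n_pat=2,
                         beta=(1.0, 0.5, 0.3, 0.2), sd_u=0.2, sd_c=0.1,
                         sd_p=0.1, noise=1.0):
    unit = rng.integers(0, n_units, n)
    contact = unit % n_contacts
    pat = contact % n_pat
    power = rng.normal(1.5, 0.4, n)
    status = rng.integers(0, 2, n).astype(float)
    uu = rng.normal(0, sd_u, n_units) if sd_u else np.zeros(n_units)
    cc = rng.normal(0, sd_c, n_contacts) if sd_c else np.zeros(n_contacts)
    pp = rng.normal(0, sd_p, n_pat) if sd_p else np.zeros(n_pat)
    eta = (beta[0] + beta[1] * power + beta[2] * status
           + beta[3] * power * status + uu[unit] + cc[contact] + pp[pat])
    y = np.exp(eta) + rng.normal(0, noise, n)
    return pd.DataFrame({
        "unit_id": unit.astype(str), "contact_id": contact.astype(str),
        "patient_id": pat.astype(str), "log10_power": power,
        "status": status, "hfodiff_fr": y})


class TestFitGlmm:
    def test_zero_variance_matches_glm_oracle(self):
        import statsmodels.api as sm
        tab = simulate_model_table(np.random.default_rng(7), n=1500,
                                   sd_u=0, sd_c=0, sd_p=0)
        res = un.fit_glmm(tab, "hfodiff_fr")
        X = np.column_stack([
            np.ones(len(tab)), tab["log10_power"], tab["status"],
            tab["log10_power"] * tab["status"]])
        glm = sm.GLM(tab["hfodiff_fr"], X,
                     family=sm.families.Gaussian(sm.families.links.Log())).fit()
        rel = np.abs(res.estimates - np.asarray(glm.params)) / \
            np.abs(np.asarray(glm.params))
        assert rel.max() < 1e-3
        assert res.converged

    def test_recovers_signs_with_random_effects(self):
        hits = 0
        for seed in range(5):
            tab = simulate_model_table(np.random.default_rng(100 + seed))
            res = un.fit_glmm(tab, "hfodiff_fr")
            if np.all(np.sign(res.estimates) == [1, 1, 1, 1]):
                hits += 1
        assert hits >= 4

    def test_single_group_drops_factor(self):
        tab = simulate_model_table(np.random.default_rng(3), n=400,
                                   n_pat=1, sd_p=0)
        res = un.fit_glmm(tab, "hfodiff_fr")
        assert "patient_id" in res.dropped_groups
        assert "patient_id" not in res.random_variances

    def test_nonpositive_mean_rejected(self):
        tab = simulate_model_table(np.random.default_rng(3), n=100)
        tab["hfodiff_fr"] -= tab["hfodiff_fr"].mean() + 1.0
        with pytest.raises(ValidationError):
            un.fit_glmm(tab, "hfodiff_fr")

    def test_type_one_error_calibrated(self):
        # status effect zero: its p-value should reject ~alpha of the time
        rejections = 0
        n_sims = 30
        for seed in range(n_sims):
            tab = simulate_model_table(np.random.default_rng(500 + seed),
                                       n=400, beta=(1.0, 0.5, 0.0, 0.0))
            res = un.fit_glmm(tab, "hfodiff_fr")
            if res.p_values[2] < 0.05:
                rejections += 1
        assert rejections <= 6  # 99th percentile of Binomial(30, 0.05)

    def test_matches_glmmtmb_cross_check(self, tmp_path):
        tab = simulate_model_table(np.random.default_rng(42), n=600,
                                   n_units=12, sd_u=0.25)
        res = un.fit_glmm(tab, "hfodiff_fr")
        csv = tmp_path / "d.csv"
        tab.to_csv(csv, index=False)
        script = textwrap.dedent(f"""
            suppressMessages(library(glmmTMB))
            d <- read.csv("{csv}", colClasses=c(unit_id="character",
                 contact_id="character", patient_id="character"))
            m <- glmmTMB(hfodiff_fr ~ log10_power*status + (1|unit_id)
                 + (1|contact_id) + (1|patient_id),
                 family=gaussian(link="log"), data=d)
            cat(fixef(m)$cond, sep="\\n")
        """)
        (tmp_path / "fit.R").write_text(script)
        proc = subprocess.run(["Rscript", str(tmp_path / "fit.R")],
                              capture_output=True, text=True, timeout=300)
        assert proc.returncode == 0, proc.stderr
        tmb = np.array([float(v) for v in proc.stdout.strip().split()])
        assert np.allclose(res.estimates, tmb, atol=0.02)
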