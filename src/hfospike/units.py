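"""Event-aligned unit firing analysis.

Each (HFO event, unit) pair yields a *trial*: a binary 1 ms action-potential
raster over a 2 s window centered at event onset, convolved with a 100 ms
(SD) Gaussian kernel and bin-averaged down to 40 Hz.  From the smoothed rate
trace, ``bl_fr`` is the mean over the 750 ms before onset, ``hfo_fr`` the
maximum during the event, and ``hfodiff_fr`` their difference.  Units whose
``hfo_fr`` does not separate from ``bl_fr`` (paired t-test, Holm step-down,
alpha = 0.001, per event category) are excluded.  The retained trials feed a
generalized linear mixed model — Gaussian response, log link, fitted by
penalized quasi-likelihood — with fixed effects for event power, coincidence
status and their interaction, and random intercepts for unit, contact and
patient.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .types import ValidationError

__all__ = [
    "build_trial",
    "firing_features",
    "build_event_unit_trials",
    "unit_inclusion",
    "assemble_model_table",
    "fit_glmm",
    "GlmmResult",
]


# ---------------------------------------------------------------------------
# Trial construction
# ---------------------------------------------------------------------------

def gaussian_kernel(sd_s: float, resolution_s: float) -> np.ndarray:
    """Unit-area Gaussian kernel sampled at the raster resolution.

    Truncated at +/-4 SD and renormalized so that one action potential
    integrates to one spike (values are in Hz per spike).
    """
    half = int(np.ceil(4 * sd_s / resolution_s))
    t = np.arange(-half, half + 1) * resolution_s
    k = np.exp(-0.5 * (t / sd_s) ** 2)
    return k / (k.sum() * resolution_s)


def build_trial(ap_times, event_onset_s: float, window_s: float = 2.0,
                resolution_s: float = 0.001, kernel_sd_s: float = 0.100,
                out_rate_hz: float = 40.0) -> np.ndarray:
    """Smoothed firing-rate trace around one event onset.

    A binary raster at ``resolution_s`` over the window centered at the
    onset is convolved with the unit-area Gaussian kernel and averaged into
    ``1/out_rate_hz`` output bins.  Returns the rate trace in Hz
    (``window_s * out_rate_hz`` samples).
    """
    n_bins = int(round(window_s / resolution_s))
    n_out = int(round(window_s * out_rate_hz))
    if n_bins % n_out != 0:
        raise ValidationError("raster bins must divide evenly into output bins")
    t0 = event_onset_s - window_s / 2.0
    ap = np.asarray(ap_times, dtype=float)
    rel = ap[(ap >= t0) & (ap < t0 + window_s)] - t0
    raster = np.zeros(n_bins)
    if rel.size:
        raster[np.minimum((rel / resolution_s).astype(int), n_bins - 1)] = 1.0
    rate = np.convolve(raster, gaussian_kernel(kernel_sd_s, resolution_s),
                       mode="same")
    return rate.reshape(n_out, n_bins // n_out).mean(axis=1)


@dataclass
class FiringFeatures:
    bl_fr: float
    hfo_fr: float
    hfodiff_fr: float
    truncated: bool = False


def firing_features(rate_trace: np.ndarray, duration_s: float,
                    window_s: float = 2.0, baseline_s: float = 0.75,
                    out_rate_hz: float = 40.0) -> FiringFeatures:
    """Baseline mean, in-event maximum, and their difference.

    ``bl_fr`` averages the trace over [-baseline, 0) s relative to onset
    (onset sits at the window center); ``hfo_fr`` is the maximum over
    [0, duration).  Events outrunning the trace half-window are truncated
    and flagged.
    """
    if duration_s <= 0:
        raise ValidationError("event duration must be positive")
    trace = np.asarray(rate_trace, dtype=float)
    n = trace.size
    dt = 1.0 / out_rate_hz
    onset_bin = n // 2
    bl_lo = onset_bin - int(round(baseline_s / dt))
    bl = float(trace[bl_lo:onset_bin].mean())
    n_ev = int(np.ceil(duration_s / dt))
    truncated = onset_bin + n_ev > n
    hfo = float(trace[onset_bin:min(onset_bin + n_ev, n)].max())
    return FiringFeatures(bl, hfo, hfo - bl, truncated)


def build_event_unit_trials(events: pd.DataFrame, unit_trains: pd.DataFrame,
                            window_s: float = 2.0, resolution_s: float = 0.001,
                            kernel_sd_s: float = 0.100, out_rate_hz: float = 40.0,
                            baseline_s: float = 0.75) -> pd.DataFrame:
    """One trial per (event, unit paired with the event's macro contact).

    Events must carry coincidence annotations.  Returns the trial table with
    firing features and the event covariates the models use.
    """
    rows = []
    trains = {
        (pid, uid): grp["ap_time_s"].to_numpy()
        for (pid, uid), grp in unit_trains.groupby(["patient_id", "unit_id"])
    }
    unit_contact = unit_trains.drop_duplicates(["patient_id", "unit_id"])
    units_by_contact: dict[tuple[str, str], list[str]] = {}
    for _, r in unit_contact.iterrows():
        units_by_contact.setdefault((r["patient_id"], r["contact_id"]), []).append(r["unit_id"])

    for event_id, ev in events.iterrows():
        key = (ev["patient_id"], ev["contact_id"])
        for uid in units_by_contact.get(key, []):
            trace = build_trial(trains[(ev["patient_id"], uid)], ev["onset_s"],
                                window_s, resolution_s, kernel_sd_s, out_rate_hz)
            feats = firing_features(trace, ev["duration_s"], window_s,
                                    baseline_s, out_rate_hz)
            rows.append({
                "event_id": event_id,
                "unit_id": uid,
                "contact_id": ev["contact_id"],
                "patient_id": ev["patient_id"],
                "category": ev["category"],
                "bl_fr": feats.bl_fr,
                "hfo_fr": feats.hfo_fr,
                "hfodiff_fr": feats.hfodiff_fr,
                "truncated": feats.truncated,
                "log10_power": ev["log10_power"],
                "prespike": bool(ev["prespike"]),
                "following_fRonO": bool(ev["following_fRonO"]),
                "following_RonO": bool(ev["following_RonO"]),
            })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Unit inclusion test
# ---------------------------------------------------------------------------

def unit_inclusion(trials: pd.DataFrame, alpha: float = 0.001) -> pd.DataFrame:
    """Paired t-test of hfo_fr vs bl_fr per (unit, category), Holm-corrected.

    The Holm step-down correction runs across all testable units within each
    event category; a unit is included iff its adjusted p-value is <= alpha.
    Units with fewer than two trials or zero-variance differences are
    excluded with a reason.
    """
    from statsmodels.stats.multitest import multipletests

    records = []
    for category, cat_trials in trials.groupby("category"):
        testable = []
        for uid, sub in cat_trials.groupby("unit_id"):
            diff = (sub["hfo_fr"] - sub["bl_fr"]).to_numpy()
            if diff.size < 2:
                records.append({"unit_id": uid, "category": category,
                                "n_trials": diff.size, "t": np.nan, "p": np.nan,
                                "p_holm": np.nan, "included": False,
                                "reason": "fewer than 2 trials"})
                continue
            if np.allclose(diff.std(ddof=1), 0.0):
                records.append({"unit_id": uid, "category": category,
                                "n_trials": diff.size, "t": np.nan, "p": np.nan,
                                "p_holm": np.nan, "included": False,
                                "reason": "zero-variance differences"})
                continue
            t, p = stats.ttest_rel(sub["hfo_fr"], sub["bl_fr"])
            testable.append({"unit_id": uid, "category": category,
                             "n_trials": diff.size, "t": float(t), "p": float(p)})
        if testable:
            adj = multipletests([r["p"] for r in testable], method="holm")[1]
            for rec, p_adj in zip(testable, adj):
                rec["p_holm"] = float(p_adj)
                rec["included"] = bool(p_adj <= alpha)
                rec["reason"] = "" if rec["included"] else "p above alpha"
                records.append(rec)
    return pd.DataFrame(records, columns=["unit_id", "category", "n_trials",
                                          "t", "p", "p_holm", "included", "reason"])


# ---------------------------------------------------------------------------
# Model table
# ---------------------------------------------------------------------------

#: event category -> name of the coincidence-status column used as the
#: model's binary fixed effect
STATUS_COLUMN = {
    "RonO": "prespike",
    "fRonO": "prespike",
    "RonS": "following_RonO",
    "fRonS": "following_fRonO",
}


def assemble_model_table(trials: pd.DataFrame, inclusion: pd.DataFrame,
                         category: str) -> pd.DataFrame:
    """Model-ready rows: included units' trials of one event category."""
    status_col = STATUS_COLUMN[category]
    for col in ("log10_power", status_col):
        if col not in trials.columns:
            raise ValidationError(f"trials missing annotation column {col!r}")
    keep_units = set(inclusion.loc[
        (inclusion["category"] == category) & inclusion["included"], "unit_id"])
    sub = trials[(trials["category"] == category)
                 & trials["unit_id"].isin(keep_units)].copy()
    sub["status"] = sub[status_col].astype(float)
    cols = ["event_id", "unit_id", "contact_id", "patient_id",
            "bl_fr", "hfo_fr", "hfodiff_fr", "log10_power", "status"]
    return sub[cols].reset_index(drop=True)


# ---------------------------------------------------------------------------
# GLMM: Gaussian response, log link, penalized quasi-likelihood
# ---------------------------------------------------------------------------

@dataclass
class GlmmResult:
    """Fitted fixed effects, random-intercept variances and diagnostics."""

    response: str
    fixed_names: list[str]
    estimates: np.ndarray
    standard_errors: np.ndarray
    z_values: np.ndarray
    p_values: np.ndarray
    random_variances: dict[str, float]
    scale: float
    n_trials: int
    n_units: int
    converged: bool
    n_iter: int
    deviance: float
    dropped_groups: list[str] = field(default_factory=list)

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame({
            "estimate": self.estimates,
            "se": self.standard_errors,
            "z": self.z_values,
            "p": self.p_values,
        }, index=self.fixed_names)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for key in ("estimates", "standard_errors", "z_values", "p_values"):
            d[key] = [float(x) for x in d[key]]
        return d


def _design(table: pd.DataFrame, fixed: tuple[str, ...]):
    cols = [np.ones(len(table))]
    names = ["intercept"]
    for term in fixed:
        if ":" in term:
            a, b = term.split(":")
            cols.append(table[a].to_numpy(float) * table[b].to_numpy(float))
        else:
            cols.append(table[term].to_numpy(float))
        names.append(term)
    return np.column_stack(cols), names


def _indicator(codes: np.ndarray, n_levels: int) -> np.ndarray:
    z = np.zeros((codes.size, n_levels))
    z[np.arange(codes.size), codes] = 1.0
    return z


def _weighted_lmm(z, w, x, zmat, blocks, theta0, tol, max_iter):
    """ML fit of the weighted LMM  z = X b + Z u + e,  e ~ N(0, phi/W).

    ``blocks`` gives the number of random-effect columns per grouping
    factor; each factor has one variance.  Optimization is over
    log-variances with Nelder-Mead (deterministic).  Returns
    (beta, u, cov_beta, tau2 per factor, phi).
    """
    n, q = zmat.shape

    def unpack(theta):
        tau2 = np.exp(theta[:-1])
        phi = np.exp(theta[-1])
        d = np.concatenate([np.full(k, t) for k, t in zip(blocks, tau2)]) \
            if q else np.empty(0)
        return tau2, phi, d

    def profile(theta):
        tau2, phi, d = unpack(theta)
        wi = w / phi                              # V^-1 = Wi - Wi Z M^-1 Z' Wi
        zw = zmat * wi[:, None]
        m = np.diag(1.0 / np.maximum(d, 1e-12)) + zmat.T @ zw if q else None

        def vinv(r):
            if q == 0:
                return wi * r
            return wi * r - zw @ np.linalg.solve(m, zw.T @ r)

        xv = np.column_stack([vinv(x[:, j]) for j in range(x.shape[1])])
        xvx = x.T @ xv
        beta = np.linalg.solve(xvx, xv.T @ z)
        resid = z - x @ beta
        vr = vinv(resid)
        logdet = np.sum(np.log(phi / w))
        if q:
            sign, ld = np.linalg.slogdet(np.eye(q) + (zmat.T @ zw) * d[None, :])
            logdet += ld
        nll = 0.5 * (logdet + resid @ vr)
        return nll, beta, resid, vinv, xvx, d, phi

    def objective(theta):
        return profile(np.clip(theta, -20, 20))[0]

    res = optimize.minimize(objective, theta0, method="Nelder-Mead",
                            options={"xatol": tol ** 0.5, "fatol": tol,
                                     "maxiter": max_iter * len(theta0)})
    theta = np.clip(res.x, -20, 20)
    # snap boundary variance components: Nelder-Mead creeps toward zero in
    # log space but stalls; a variance far below the dispersion is zero
    phi_hat = np.exp(theta[-1])
    snap = np.exp(theta[:-1]) < 1e-6 * phi_hat
    if snap.any():
        theta = theta.copy()
        theta[:-1][snap] = np.log(1e-12 * phi_hat)
    nll, beta, resid, vinv, xvx, d, phi = profile(theta)
    u = d * (zmat.T @ vinv(resid)) if q else np.empty(0)
    cov_beta = np.linalg.inv(xvx)
    tau2, phi, _ = unpack(theta)
    return beta, u, cov_beta, tau2, phi, theta


def fit_glmm(table: pd.DataFrame, response: str,
             fixed: tuple[str, ...] = ("log10_power", "status", "log10_power:status"),
             groups: tuple[str, ...] = ("unit_id", "contact_id", "patient_id"),
             tol: float = 1e-8, max_iter: int = 500) -> GlmmResult:
    """Fit a Gaussian log-link mixed model by penalized quasi-likelihood.

    PQL alternates a working linearization of the log link (working
    response ``z = eta + (y - mu)/mu``, weights ``mu^2``) with a maximum-
    likelihood weighted linear mixed model in the random intercepts.  The
    dispersion is free (quasi-likelihood); grouping factors with fewer than
    two levels are dropped with a warning entry in the result.
    """
    y = table[response].to_numpy(float)
    if y.mean() <= 0:
        raise ValidationError(
            f"mean of {response} must be positive for a log link")
    x, names = _design(table, fixed)

    dropped = []
    live_groups = []
    codes_list = []
    blocks = []
    for g in groups:
        codes, levels = pd.factorize(table[g])
        if levels.size < 2:
            dropped.append(g)
            continue
        live_groups.append(g)
        codes_list.append(codes)
        blocks.append(levels.size)
    zmat = (np.column_stack([_indicator(c, k) for c, k in zip(codes_list, blocks)])
            if blocks else np.zeros((len(table), 0)))

    # initialize at an intercept-only mean
    beta = np.zeros(x.shape[1])
    beta[0] = np.log(y.mean())
    u = np.zeros(zmat.shape[1])
    theta = np.log(np.concatenate([np.full(len(blocks), 0.05), [max(y.var(), 1e-6)]]))

    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        eta = np.clip(x @ beta + (zmat @ u if u.size else 0.0), -30.0, 30.0)
        mu = np.exp(eta)
        w = mu ** 2
        z = eta + (y - mu) / mu
        beta_new, u_new, cov_beta, tau2, phi, theta = _weighted_lmm(
            z, w, x, zmat, blocks, theta, tol, max_iter)
        step = np.max(np.abs(beta_new - beta)) if beta.size else 0.0
        if u.size:
            step = max(step, np.max(np.abs(u_new - u)))
        beta, u = beta_new, u_new
        if step < max(tol * 100, 1e-6):
            converged = True
            break

    eta = np.clip(x @ beta + (zmat @ u if u.size else 0.0), -30.0, 30.0)
    mu = np.exp(eta)
    deviance = float(np.sum((y - mu) ** 2))
    se = np.sqrt(np.diag(cov_beta))
    zvals = beta / se
    pvals = 2 * stats.norm.sf(np.abs(zvals))
    return GlmmResult(
        response=response,
        fixed_names=names,
        estimates=beta,
        standard_errors=se,
        z_values=zvals,
        p_values=pvals,
        random_variances={g: float(t) for g, t in zip(live_groups, tau2)},
        scale=float(phi),
        n_trials=len(table),
        n_units=int(table["unit_id"].nunique()) if "unit_id" in table else 0,
        converged=converged,
        n_iter=it,
        deviance=deviance,
        dropped_groups=dropped,
    )
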