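"""Cytokine stage contrasts with left-censoring and BH FDR control.

Plasma cytokine concentrations are compared at four sessions (FD7, FD180,
R+0, R+180) against the L-60 preflight baseline.  Each analyte carries a
transform: ``identity``, ``log``, or ``reciprocal_censored`` for analytes
whose values fall below the assay detection limit — the reciprocal maps a
left-censored concentration (c < L) into a right-censored one (1/c > 1/L),
which a right-censored lognormal maximum-likelihood regression handles
with standard normal-tail likelihood contributions.  All analyte x session
p-values enter a single Benjamini-Hochberg step-up, and the realized
p-value threshold is reported alongside the q-values.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.optimize
import scipy.stats
import statsmodels.api as sm

from .io import CYTOKINE_SESSIONS
from .longitudinal import ContrastRecord, mixed_contrast

logger = logging.getLogger("astrobiome")

TRANSFORMS = ("identity", "log", "reciprocal_censored")
BASELINE_SESSION = "L-60"
CONTRAST_SESSIONS = tuple(s for s in CYTOKINE_SESSIONS if s != BASELINE_SESSION)


# ---------------------------------------------------------------------------
# Benjamini-Hochberg


def bh_fdr(p_values, q: float = 0.05) -> tuple[np.ndarray, np.ndarray, float]:
    """Benjamini-Hochberg step-up.

    Returns (q-values with monotone adjustment, significance flags, realized
    p threshold).  Flags mark all p <= p_(k*) with k* the largest k such
    that p_(k) <= k*q/m; the threshold is p_(k*) (0.0 when nothing passes).
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if np.any((p <= 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order]
    qvals_sorted = ranked * m / np.arange(1, m + 1)
    qvals_sorted = np.minimum.accumulate(qvals_sorted[::-1])[::-1]
    qvals = np.empty(m)
    qvals[order] = np.minimum(qvals_sorted, 1.0)
    passing = np.flatnonzero(ranked <= np.arange(1, m + 1) * q / m)
    threshold = float(ranked[passing[-1]]) if passing.size else 0.0
    flags = p <= threshold if passing.size else np.zeros(m, dtype=bool)
    return qvals, flags, threshold


# ---------------------------------------------------------------------------
# Transforms


def validate_transform_spec(panel: pd.DataFrame, spec: dict[str, str]) -> None:
    analytes = set(panel["analyte"])
    missing = sorted(analytes - set(spec))
    if missing:
        raise ValueError(f"transform spec missing analytes: {missing}")
    for a, t in spec.items():
        if t not in TRANSFORMS:
            raise ValueError(f"unknown transform {t!r} for analyte {a!r}")
        if t == "reciprocal_censored" and a in analytes:
            if not panel.loc[panel["analyte"] == a, "censored"].any():
                raise ValueError(
                    f"reciprocal_censored requires censored records ({a!r})")


def transform_cytokine(panel: pd.DataFrame, spec: dict[str, str]) -> pd.DataFrame:
    """Apply per-analyte transforms; returns rows with ``value`` and
    ``right_censored`` (only reciprocal-transformed censored records are
    right-censored; left-censored values under other transforms stay
    clamped at the detection limit)."""
    validate_transform_spec(panel, spec)
    out = panel.copy()
    values = np.empty(len(out))
    right = np.zeros(len(out), dtype=bool)
    for i, row in enumerate(out.itertuples(index=False)):
        t = spec[row.analyte]
        c = row.concentration
        if t == "identity":
            values[i] = c
        elif t == "log":
            if c <= 0:
                raise ValueError(f"nonpositive concentration under log: {c}")
            values[i] = np.log(c)
        else:
            if c <= 0:
                raise ValueError(f"nonpositive concentration under reciprocal: {c}")
            values[i] = 1.0 / c
            right[i] = bool(row.censored)
    out["value"] = values
    out["right_censored"] = right
    out["transform"] = out["analyte"].map(spec)
    return out


# ---------------------------------------------------------------------------
# Right-censored lognormal regression


def _design(df: pd.DataFrame, baseline: str) -> tuple[np.ndarray, list[str]]:
    sessions = [s for s in CYTOKINE_SESSIONS if s in set(df["session"])]
    terms = [s for s in sessions if s != baseline]
    subjects = sorted(df["subject_id"].unique())
    cols = [np.ones(len(df))]
    names = ["intercept"]
    for s in terms:
        cols.append((df["session"] == s).to_numpy(float))
        names.append(f"session[{s}]")
    for subj in subjects[1:]:
        cols.append((df["subject_id"] == subj).to_numpy(float))
        names.append(f"subject[{subj}]")
    return np.column_stack(cols), names


def censored_lognormal_regression(
    df: pd.DataFrame, baseline: str = BASELINE_SESSION
) -> list[ContrastRecord]:
    """MLE of a lognormal regression with right-censored observations.

    ``df`` needs columns subject_id, session, value (positive, already on
    the reciprocal scale when applicable) and right_censored.  The model is
    log(value) ~ session + subject with normal errors; censored rows
    contribute upper-tail log-probabilities.  With no censored rows the
    fit reduces to (and is returned as) ordinary least squares.
    """
    df = df.copy()
    if (df["value"] <= 0).any():
        raise ValueError("values must be positive")
    cens = df["right_censored"].to_numpy(bool)
    if cens.all():
        raise ValueError("all observations censored; model unidentifiable")
    for s, grp in df.groupby("session"):
        if grp["right_censored"].all():
            raise ValueError(f"all observations censored at session {s!r}")
    y = np.log(df["value"].to_numpy(float))
    x, names = _design(df, baseline)
    n, k = x.shape

    ols = sm.OLS(y, x).fit()
    if not cens.any():
        records = []
        for i, name in enumerate(names):
            if name.startswith("session["):
                records.append(ContrastRecord(
                    term=name[len("session["):-1],
                    estimate=float(ols.params[i]), se=float(ols.bse[i]),
                    p=float(ols.pvalues[i]), method="ols_wald"))
        return records

    def nll(theta: np.ndarray) -> float:
        beta, log_sigma = theta[:k], theta[k]
        sigma = np.exp(log_sigma)
        mu = x @ beta
        z = (y - mu) / sigma
        ll = np.where(cens,
                      scipy.stats.norm.logsf(z),
                      scipy.stats.norm.logpdf(z) - log_sigma)
        return -float(ll.sum())

    def grad(theta: np.ndarray) -> np.ndarray:
        beta, log_sigma = theta[:k], theta[k]
        sigma = np.exp(log_sigma)
        z = (y - x @ beta) / sigma
        # inverse Mills ratio for the censored upper-tail terms
        mills = np.exp(scipy.stats.norm.logpdf(z) - scipy.stats.norm.logsf(z))
        dl_dz = np.where(cens, -mills, -z)          # d log-lik / dz
        dz_dbeta = -x / sigma
        g_beta = (dl_dz[:, None] * dz_dbeta).sum(axis=0)
        dl_dls = dl_dz * (-z) - np.where(cens, 0.0, 1.0)  # wrt log sigma
        return -np.append(g_beta, dl_dls.sum())

    theta0 = np.append(ols.params, np.log(max(np.sqrt(ols.mse_resid), 1e-3)))
    res = scipy.optimize.minimize(nll, theta0, jac=grad, method="BFGS",
                                  options={"maxiter": 2000, "gtol": 1e-8})
    converged = bool(res.success) or res.fun <= nll(theta0)
    theta = res.x

    # observed information by central finite differences
    h = 1e-4 * np.maximum(np.abs(theta), 1.0)
    dim = len(theta)
    hess = np.empty((dim, dim))
    for i in range(dim):
        for j in range(i, dim):
            ei = np.zeros(dim); ei[i] = h[i]
            ej = np.zeros(dim); ej[j] = h[j]
            fpp = nll(theta + ei + ej)
            fpm = nll(theta + ei - ej)
            fmp = nll(theta - ei + ej)
            fmm = nll(theta - ei - ej)
            hess[i, j] = hess[j, i] = (fpp - fpm - fmp + fmm) / (4 * h[i] * h[j])
    try:
        cov = np.linalg.inv(hess)
        se_all = np.sqrt(np.maximum(np.diag(cov), 0.0))
    except np.linalg.LinAlgError:
        converged = False
        se_all = np.full(dim, np.nan)

    records = []
    for i, name in enumerate(names):
        if not name.startswith("session["):
            continue
        est, se = float(theta[i]), float(se_all[i])
        p = (2 * scipy.stats.norm.sf(abs(est / se))
             if np.isfinite(se) and se > 0 else np.nan)
        records.append(ContrastRecord(
            term=name[len("session["):-1], estimate=est, se=se, p=float(p),
            method="censored_lognormal_mle", fallback=not converged))
    return records


def censored_loglikelihood(df: pd.DataFrame, params: np.ndarray,
                           log_sigma: float, baseline: str = BASELINE_SESSION) -> float:
    """Log-likelihood of the censored model at given coefficients (used to
    check that the MLE dominates the OLS solution under censoring)."""
    y = np.log(df["value"].to_numpy(float))
    cens = df["right_censored"].to_numpy(bool)
    x, _ = _design(df, baseline)
    sigma = np.exp(log_sigma)
    z = (y - x @ params) / sigma
    ll = np.where(cens, scipy.stats.norm.logsf(z),
                  scipy.stats.norm.logpdf(z) - log_sigma)
    return float(ll.sum())


# ---------------------------------------------------------------------------
# Stage contrasts across the panel


@dataclass
class CytokineContrastResult:
    records: pd.DataFrame          # analyte, session, estimate, se, p, q, ...
    threshold: float               # realized BH p threshold
    n_tests: int
    excluded: pd.DataFrame = field(default_factory=pd.DataFrame)


def cytokine_stage_contrasts(
    panel: pd.DataFrame,
    transform_spec: dict[str, str] | None = None,
    fdr: float = 0.05,
    max_censored_fraction: float = 0.5,
    baseline: str = BASELINE_SESSION,
) -> CytokineContrastResult:
    """Session-vs-baseline contrasts for every analyte, BH-corrected jointly.

    Analytes default to the log transform.  Analytes marked
    ``reciprocal_censored`` are fit by censored lognormal MLE (subject fixed
    effects); all others by a subject-random-intercept mixed model on the
    transformed values.  Analytes with more than ``max_censored_fraction``
    censored observations are excluded with a reason.  BH runs once across
    the full analyte x session grid of computed p-values.
    """
    analytes = sorted(panel["analyte"].unique())
    if transform_spec is None:
        transform_spec = {a: "log" for a in analytes}
    transformed = transform_cytokine(panel, transform_spec)

    rows, excluded = [], []
    for analyte in analytes:
        sub = transformed[transformed["analyte"] == analyte]
        cens_frac = float(sub["censored"].mean())
        if cens_frac > max_censored_fraction:
            excluded.append({"analyte": analyte,
                             "reason": f"censored fraction {cens_frac:.2f} exceeds "
                                       f"{max_censored_fraction:.2f}"})
            continue
        if transform_spec[analyte] == "reciprocal_censored":
            recs = censored_lognormal_regression(sub, baseline)
        else:
            obs = sub.rename(columns={"subject_id": "subject",
                                      "session": "level"})
            recs = mixed_contrast(obs, baseline=baseline)
        for r in recs:
            rows.append({"analyte": analyte, "session": r.term,
                         "estimate": r.estimate, "se": r.se, "p": r.p,
                         "method": r.method, "fallback": r.fallback})
    records = pd.DataFrame(rows, columns=["analyte", "session", "estimate",
                                          "se", "p", "method", "fallback"])
    if records.empty:
        return CytokineContrastResult(records, 0.0, 0, pd.DataFrame(excluded))
    computable = records["p"].notna() & (records["p"] > 0)
    q = np.full(len(records), np.nan)
    flags = np.zeros(len(records), dtype=bool)
    threshold = 0.0
    if computable.any():
        qv, fl, threshold = bh_fdr(records.loc[computable, "p"].to_numpy(), fdr)
        q[computable.to_numpy()] = qv
        flags[computable.to_numpy()] = fl
    records["q"] = q
    records["significant"] = flags
    return CytokineContrastResult(records, threshold, int(computable.sum()),
                                  pd.DataFrame(excluded))
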