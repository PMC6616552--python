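"""Mission-stage inference machinery.

Contains the repeated-measures tools the pipeline runs on diversity values
and distances: random-intercept mixed-model contrasts against a preflight
baseline, the within/between-stage distance design (within-astronaut pairs
only), per-timepoint distance-to-baseline trajectories, single-factor
PERMANOVA with optional within-strata permutation, Welch tests of
inter-astronaut convergence, the coefficient-of-variation reduction
ranking that attributes convergence to genera, paired Pearson correlation,
and a permutation fold-change screen that nominates differentially
abundant OTUs (or passes an externally supplied candidate list through).

Mixed-model p-values use the Wald normal approximation on REML fits; a
singular or non-convergent fit falls back to ordinary least squares and is
flagged on the record.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.formula.api as smf
from statsmodels.tools.sm_exceptions import ConvergenceWarning

from .io import OtuTable, RelAbundanceTable, genus_label
from .diversity import DistanceMatrix
from .prep import to_relative_abundance

logger = logging.getLogger("astrobiome")


# ---------------------------------------------------------------------------
# Mixed-model contrasts


@dataclass
class ContrastRecord:
    """One non-baseline level of a random-intercept mixed-model fit."""

    term: str
    estimate: float
    se: float
    p: float
    method: str = "mixed_reml_wald"
    fallback: bool = False
    q: float | None = None


def mixed_contrast(
    observations: pd.DataFrame, baseline: str,
    value: str = "value", level: str = "level", subject: str = "subject",
) -> list[ContrastRecord]:
    """Fit value ~ level with a per-subject random intercept (REML).

    Returns one record per non-baseline level with Wald (normal) inference.
    A singular or non-convergent fit falls back to fixed-effects OLS with
    ``fallback=True`` on every record.
    """
    obs = observations[[subject, level, value]].dropna().copy()
    obs.columns = ["subject", "level", "value"]
    levels = sorted(obs["level"].unique())
    if baseline not in levels:
        raise ValueError(f"baseline level {baseline!r} absent from data")
    if len(levels) < 2:
        raise ValueError("need at least 2 levels")
    if obs["subject"].nunique() < 2:
        raise ValueError("need at least 2 subjects")
    formula = f"value ~ C(level, Treatment('{baseline}'))"
    result, fallback = None, False
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error", ConvergenceWarning)
            warnings.simplefilter("error", RuntimeWarning)
            model = smf.mixedlm(formula, obs, groups=obs["subject"])
            result = model.fit(reml=True)
        if not np.all(np.isfinite(result.bse.iloc[:-1])):
            raise np.linalg.LinAlgError("non-finite standard errors")
    except Exception:  # singular fit, no convergence, zero variance
        logger.warning("mixed model fell back to OLS")
        result = smf.ols(formula, obs).fit()
        fallback = True
    records = []
    for lev in levels:
        if lev == baseline:
            continue
        name = f"C(level, Treatment('{baseline}'))[T.{lev}]"
        records.append(ContrastRecord(
            term=str(lev),
            estimate=float(result.params[name]),
            se=float(result.bse[name]),
            p=float(result.pvalues[name]),
            method="ols_wald" if fallback else "mixed_reml_wald",
            fallback=fallback,
        ))
    return records


# ---------------------------------------------------------------------------
# Within/between-stage distance design

_STAGE_SHORT = {"preflight": "pre", "inflight": "in", "postflight": "post"}


def stage_distance_table(
    dm: DistanceMatrix, metadata: pd.DataFrame, comparison: str = "pre_in"
) -> pd.DataFrame:
    """Enumerate within-astronaut sample pairs for one stage comparison.

    ``comparison`` is ``pre_in`` or ``pre_post``; only samples in the two
    stages take part.  Same-stage pairs are pooled into the
    ``within_<comparison>`` category, cross-stage pairs form
    ``between_<comparison>``.  Pairs of samples from different astronauts
    are never emitted.  For each astronaut with n participating samples,
    exactly C(n, 2) observations appear.
    """
    if comparison not in ("pre_in", "pre_post"):
        raise ValueError(f"unknown comparison {comparison!r}")
    other = "inflight" if comparison == "pre_in" else "postflight"
    stages = ("preflight", other)
    meta = metadata[metadata.index.isin(dm.sample_ids)
                    & metadata["stage"].isin(stages)
                    & metadata["subject_id"].notna()]
    rows = []
    for subj, grp in meta.groupby("subject_id"):
        ids = list(grp.index)
        for a, b in itertools.combinations(ids, 2):
            sa, sb = meta.loc[a, "stage"], meta.loc[b, "stage"]
            cat = (f"within_{comparison}" if sa == sb else f"between_{comparison}")
            rows.append({"astronaut": subj, "category": cat,
                         "sample_a": a, "sample_b": b,
                         "distance": dm.get(a, b)})
    return pd.DataFrame(rows, columns=["astronaut", "category", "sample_a",
                                       "sample_b", "distance"])


def stage_distance_contrast(
    dm: DistanceMatrix, metadata: pd.DataFrame, comparison: str = "pre_in"
) -> list[ContrastRecord]:
    """Mixed-model contrast of between- vs within-stage distances (Fig.-4
    style design: category fixed effect, astronaut random intercept)."""
    pairs = stage_distance_table(dm, metadata, comparison)
    if pairs.empty:
        raise ValueError("no within-astronaut pairs for this comparison")
    obs = pairs.rename(columns={"astronaut": "subject", "category": "level",
                                "distance": "value"})
    return mixed_contrast(obs, baseline=f"within_{comparison}")


def baseline_distance_trajectory(
    dm: DistanceMatrix, metadata: pd.DataFrame
) -> pd.DataFrame:
    """Per (astronaut, timepoint) mean distance to that astronaut's preflight
    samples; the preflight row is the mean over within-preflight pairs."""
    meta = metadata[metadata.index.isin(dm.sample_ids)
                    & metadata["subject_id"].notna()]
    rows = []
    for subj, grp in meta.groupby("subject_id"):
        pre = list(grp.index[grp["stage"] == "preflight"])
        if not pre:
            logger.warning("astronaut %s has no preflight samples; excluded", subj)
            continue
        if len(pre) >= 2:
            base = [dm.get(a, b) for a, b in itertools.combinations(pre, 2)]
            rows.append({"astronaut": subj, "timepoint": "preflight",
                         "mean_distance": float(np.mean(base)),
                         "n_pairs": len(base)})
        for tp, tgrp in grp[grp["stage"] != "preflight"].groupby("timepoint"):
            d = [dm.get(s, p) for s in tgrp.index for p in pre]
            rows.append({"astronaut": subj, "timepoint": tp,
                         "mean_distance": float(np.mean(d)), "n_pairs": len(d)})
    return pd.DataFrame(rows, columns=["astronaut", "timepoint",
                                       "mean_distance", "n_pairs"])


# ---------------------------------------------------------------------------
# PERMANOVA


@dataclass
class PermanovaResult:
    pseudo_f: float
    r_squared: float
    p: float
    n_permutations: int


def _pseudo_f(d2: np.ndarray, labels: np.ndarray, groups: np.ndarray) -> tuple[float, float]:
    n = d2.shape[0]
    ss_total = d2[np.triu_indices(n, 1)].sum() / n
    ss_within = 0.0
    for g in groups:
        mask = labels == g
        ng = int(mask.sum())
        if ng < 2:
            continue
        sub = d2[np.ix_(mask, mask)]
        ss_within += sub[np.triu_indices(ng, 1)].sum() / ng
    ss_among = ss_total - ss_within
    a = len(groups)
    f = (ss_among / (a - 1)) / (ss_within / (n - a))
    return f, ss_among / ss_total


def permanova(
    dm: DistanceMatrix,
    grouping,
    n_perm: int = 999,
    strata=None,
    seed: int | None = None,
) -> PermanovaResult:
    """Single-factor PERMANOVA; permutes labels within strata when given.

    p = (1 + #{F_perm >= F_obs}) / (1 + n_perm), so the minimum attainable
    p is 1/(n_perm + 1).
    """
    if n_perm < 99:
        raise ValueError("n_perm must be at least 99")
    labels = np.asarray(pd.Series(grouping).reindex(dm.sample_ids).to_numpy()
                        if isinstance(grouping, (pd.Series, dict))
                        else grouping)
    if len(labels) != len(dm.sample_ids):
        raise ValueError("grouping length mismatch")
    groups = np.unique(labels)
    if len(groups) < 2:
        raise ValueError("PERMANOVA requires at least 2 groups")
    d2 = dm.values ** 2
    f_obs, r2 = _pseudo_f(d2, labels, groups)

    rng = np.random.default_rng(seed)
    if strata is not None:
        strata = np.asarray(pd.Series(strata).reindex(dm.sample_ids).to_numpy()
                            if isinstance(strata, (pd.Series, dict)) else strata)
        for s in np.unique(strata):
            if len(np.unique(labels[strata == s])) < 2:
                logger.warning("stratum %r lies entirely in one group", s)
        idx_by_stratum = [np.flatnonzero(strata == s) for s in np.unique(strata)]
    exceed = 0
    perm = labels.copy()
    for _ in range(n_perm):
        if strata is None:
            perm = rng.permutation(labels)
        else:
            perm = labels.copy()
            for idx in idx_by_stratum:
                perm[idx] = labels[idx][rng.permutation(len(idx))]
        f_p, _ = _pseudo_f(d2, perm, groups)
        if f_p >= f_obs:
            exceed += 1
    return PermanovaResult(float(f_obs), float(r2),
                           (1 + exceed) / (1 + n_perm), n_perm)


# ---------------------------------------------------------------------------
# Inter-astronaut convergence


def convergence_welch(
    dm: DistanceMatrix, metadata: pd.DataFrame,
    stage_a: str = "preflight", stage_b: str = "inflight",
) -> dict:
    """Welch t-test of inter-astronaut distances in stage_a vs stage_b.

    Only pairs of samples from *different* astronauts within the same stage
    contribute.
    """
    def cross_subject(stage: str) -> np.ndarray:
        meta = metadata[metadata.index.isin(dm.sample_ids)
                        & (metadata["stage"] == stage)
                        & metadata["subject_id"].notna()]
        if meta["subject_id"].nunique() < 2:
            raise ValueError(f"stage {stage!r} has fewer than 2 astronauts")
        ids = list(meta.index)
        vals = [dm.get(a, b) for a, b in itertools.combinations(ids, 2)
                if meta.loc[a, "subject_id"] != meta.loc[b, "subject_id"]]
        return np.asarray(vals)

    a, b = cross_subject(stage_a), cross_subject(stage_b)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least 2 inter-astronaut pairs per stage")
    t, p = scipy.stats.ttest_ind(a, b, equal_var=False)
    va, vb = a.var(ddof=1) / len(a), b.var(ddof=1) / len(b)
    df = (va + vb) ** 2 / (va ** 2 / (len(a) - 1) + vb ** 2 / (len(b) - 1))
    return {"t": float(t), "df": float(df), "p": float(p),
            "mean_a": float(a.mean()), "mean_b": float(b.mean()),
            "n_a": len(a), "n_b": len(b)}


def cv_reduction_ranking(
    rel: RelAbundanceTable, metadata: pd.DataFrame,
    subjects: list[str] | None = None,
    level: str = "genus", site: str = "stool",
) -> pd.DataFrame:
    """Rank genera by preflight-to-inflight reduction of the inter-subject
    coefficient of variation of their relative abundance.

    The CV of a genus within a stage is SD/mean of the per-subject mean
    relative abundance (each subject's replicate samples are pooled first,
    so within-subject variance does not inflate the inter-subject CV).
    Positive reductions are ranked descending; ``cumulative_fraction``
    accumulates their share of the total positive reduction.  Genera with a
    zero mean in either stage are flagged and excluded from the total.
    """
    meta = metadata[metadata.index.isin(rel.sample_ids)
                    & (metadata["site"] == site)
                    & metadata["stage"].isin(["preflight", "inflight"])
                    & metadata["subject_id"].notna()]
    if subjects is not None:
        meta = meta[meta["subject_id"].isin(subjects)]
    if meta["subject_id"].nunique() < 2:
        raise ValueError("need at least 2 subjects")
    if meta["stage"].nunique() < 2:
        raise ValueError("both stages must be represented")
    vals = rel.values[meta.index]
    if level == "genus" and rel.taxonomy is not None:
        genera = pd.Series({o: genus_label(rel.taxonomy, o) for o in rel.otu_ids})
        vals = vals.groupby(genera).sum()

    def stage_cv(stage: str) -> tuple[pd.Series, pd.Series]:
        sel = meta[meta["stage"] == stage]
        per_subject = vals[sel.index].T.groupby(sel["subject_id"]).mean().T
        mean = per_subject.mean(axis=1)
        sd = per_subject.std(axis=1, ddof=1)
        return sd / mean.where(mean > 0), mean

    cv_pre, mean_pre = stage_cv("preflight")
    cv_in, mean_in = stage_cv("inflight")
    out = pd.DataFrame({
        "genus": vals.index,
        "cv_pre": cv_pre.to_numpy(),
        "cv_in": cv_in.to_numpy(),
    })
    out["flagged"] = (mean_pre.to_numpy() <= 0) | (mean_in.to_numpy() <= 0)
    out["reduction"] = out["cv_pre"] - out["cv_in"]
    out.loc[out["flagged"], "reduction"] = np.nan
    out = out.sort_values("reduction", ascending=False, na_position="last")
    pos = out["reduction"].where(out["reduction"] > 0)
    total = pos.sum()
    out["cumulative_fraction"] = (
        pos.fillna(0).cumsum() / total if total > 0 else np.nan
    )
    out.loc[~(out["reduction"] > 0), "cumulative_fraction"] = np.nan
    return out.reset_index(drop=True)


def paired_alpha_correlation(series_a, series_b) -> dict:
    """Pearson correlation of two aligned diversity series (r, R^2, p)."""
    a = np.asarray(series_a, dtype=float)
    b = np.asarray(series_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("series must be aligned 1-d arrays")
    if len(a) < 3:
        raise ValueError("need at least 3 pairs")
    if a.std() == 0 or b.std() == 0:
        raise ValueError("zero variance in a series")
    r, p = scipy.stats.pearsonr(a, b)
    return {"r": float(r), "r_squared": float(r ** 2), "p": float(p),
            "n": len(a)}


# ---------------------------------------------------------------------------
# Differential-abundance permutation screen (plumbing)


def da_screen(
    table: OtuTable,
    metadata: pd.DataFrame,
    site: str = "stool",
    fdr: float = 0.10,
    n_perm: int = 999,
    seed: int | None = None,
    candidates: list[str] | None = None,
) -> pd.DataFrame:
    """Permutation screen for OTUs whose abundance shifts inflight.

    Per OTU: log relative abundance (pseudo-abundance floor at half the
    OTU's minimum nonzero value), centered within subject; the statistic is
    the inflight-minus-preflight mean; the null is built by permuting stage
    labels within subject; BH control at ``fdr``.  An externally supplied
    ``candidates`` list bypasses the screen and is passed through verbatim.
    """
    if candidates is not None:
        return pd.DataFrame({"otu": list(candidates),
                             "estimate": np.nan, "p": np.nan, "q": np.nan,
                             "significant": True, "bypassed": True})
    from .cytokines import bh_fdr  # avoids a module cycle

    meta = metadata[metadata.index.isin(table.sample_ids)
                    & (metadata["site"] == site)
                    & metadata["stage"].isin(["preflight", "inflight"])
                    & metadata["subject_id"].notna()]
    both = [s for s, g in meta.groupby("subject_id")
            if g["stage"].nunique() == 2]
    meta = meta[meta["subject_id"].isin(both)]
    if meta.empty:
        raise ValueError("no subjects with both stages at this site")
    sub = OtuTable(table.counts[list(meta.index)], table.taxonomy)
    present = sub.counts.sum(axis=1) > 0
    if not present.all():
        sub = OtuTable(sub.counts[present], None)
    ra = to_relative_abundance(sub).values.to_numpy()
    floor = np.array([ra[i][ra[i] > 0].min() / 2 for i in range(ra.shape[0])])
    logra = np.log(np.maximum(ra, floor[:, None]))
    # center within subject
    subj = meta["subject_id"].to_numpy()
    for s in np.unique(subj):
        cols = subj == s
        logra[:, cols] -= logra[:, cols].mean(axis=1, keepdims=True)
    z = (meta["stage"] == "inflight").to_numpy()
    w = z / z.sum() - (~z) / (~z).sum()
    stat = logra @ w
    rng = np.random.default_rng(seed)
    perm_w = np.empty((len(w), n_perm))
    for k in range(n_perm):
        zp = z.copy()
        for s in np.unique(subj):
            cols = np.flatnonzero(subj == s)
            zp[cols] = z[cols][rng.permutation(len(cols))]
        perm_w[:, k] = zp / zp.sum() - (~zp) / (~zp).sum()
    null = logra @ perm_w
    p = (1 + (np.abs(null) >= np.abs(stat)[:, None]).sum(axis=1)) / (1 + n_perm)
    q, flags, _ = bh_fdr(p, fdr)
    return pd.DataFrame({"otu": sub.counts.index, "estimate": stat,
                         "p": p, "q": q, "significant": flags,
                         "bypassed": False})


def candidate_otus(screen: pd.DataFrame) -> list[str]:
    return list(screen.loc[screen["significant"], "otu"])
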