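"""Within-subject Somers' D association between gut taxa and cytokines.

The association procedure asks whether, within a subject, session-to-session
changes in a stool OTU's relative abundance move with (or against) changes
in a plasma cytokine.  Relative abundance is first discretized to dyadic
levels — Y is the nearest integer to log2(RA), so only at-least-twofold
changes register, with RA = 0 mapped one level below the OTU's smallest
observed positive level.  Session pairs are formed strictly within subject
over the five blood-matched sessions.  Somers' D conditions on the first
measure: with C concordant and Q discordant pairs among those untied on Y,

    D = (C - Q) / #{pairs with dY != 0},

so pairs tied on the cytokine but not on Y count only in the denominator.
The standard error is a delete-one-subject jackknife (the cluster-respecting
resampling estimator), the p-value a two-sided Student-t on D/SE with g - 1
degrees of freedom for g contributing subjects (the normal reference is far
too liberal at the handful of clusters this design provides), and the
screen over candidate-OTU x analyte combinations applies an exclusion rule
(too few valid comparisons) before computing p and a Benjamini-Hochberg
step-up at 1% FDR across the computed p-values only.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats

from .io import CYTOKINE_SESSIONS, RelAbundanceTable, genus_label
from .cytokines import bh_fdr

logger = logging.getLogger("astrobiome")


def _round_half_away(v: np.ndarray) -> np.ndarray:
    """Round to nearest integer, halves away from zero (dyadic boundaries)."""
    return np.sign(v) * np.floor(np.abs(v) + 0.5)


def discretize_abundance(
    rel: RelAbundanceTable,
    metadata: pd.DataFrame,
    subjects: list[str] | None = None,
    sessions: tuple[str, ...] = CYTOKINE_SESSIONS,
    site: str = "stool",
    otus: list[str] | None = None,
) -> pd.DataFrame:
    """Discretize relative abundances to integer log2 levels.

    Returns long-format rows (subject, session, otu, Y, zero_flag).  The
    zero-RA level is one below the OTU's minimum positive level across this
    analysis subset; OTUs with zero abundance everywhere in the subset are
    omitted (they carry no usable signal and are excluded downstream).
    """
    meta = metadata[metadata.index.isin(rel.sample_ids)
                    & (metadata["site"] == site)
                    & metadata["timepoint"].isin(sessions)
                    & metadata["subject_id"].notna()]
    if subjects is not None:
        meta = meta[meta["subject_id"].isin(subjects)]
    if meta.empty:
        raise ValueError("no samples match the requested subjects/sessions")
    dup = meta.duplicated(subset=["subject_id", "timepoint"])
    if dup.any():
        raise ValueError(
            f"multiple {site} samples for one subject-session: "
            f"{list(meta.index[dup])}")
    ra = rel.values[list(meta.index)]
    if otus is not None:
        ra = ra.loc[[o for o in otus if o in ra.index]]
    rows = []
    for otu, vals in ra.iterrows():
        v = vals.to_numpy(float)
        pos = v > 0
        if not pos.any():
            continue
        y = np.full(len(v), np.nan)
        y[pos] = _round_half_away(np.log2(v[pos]))
        y[~pos] = y[pos].min() - 1
        for (sid, yy, zz) in zip(meta.index, y, ~pos):
            rows.append({"subject": meta.loc[sid, "subject_id"],
                         "session": meta.loc[sid, "timepoint"],
                         "otu": otu, "Y": int(yy), "zero_flag": bool(zz)})
    return pd.DataFrame(rows, columns=["subject", "session", "otu", "Y",
                                       "zero_flag"])


def build_within_subject_pairs(
    disc: pd.DataFrame,
    panel: pd.DataFrame,
    analyte: str,
    otu: str,
    comparison_unit: str = "observations",
) -> tuple[pd.DataFrame, int]:
    """Enumerate within-subject session pairs for one cytokine-OTU combination.

    Sessions enter a pair only when both the discretized abundance level and
    the cytokine measurement exist.  X is the natural log of the cytokine
    concentration (censored records sit clamped at the detection limit).
    The returned count of valid comparisons follows ``comparison_unit``:
    ``observations`` counts subject-sessions with RA > 0 and an uncensored
    cytokine; ``pairs`` counts pairs whose both endpoints are valid.
    """
    if comparison_unit not in ("observations", "pairs"):
        raise ValueError(f"unknown comparison unit {comparison_unit!r}")
    d = disc[disc["otu"] == otu][["subject", "session", "Y", "zero_flag"]]
    c = panel[panel["analyte"] == analyte][
        ["subject_id", "session", "concentration", "censored"]
    ].rename(columns={"subject_id": "subject"})
    merged = d.merge(c, on=["subject", "session"], how="inner")
    merged["X"] = np.log(merged["concentration"].astype(float))
    merged["valid"] = ~merged["zero_flag"] & ~merged["censored"]

    order = {s: i for i, s in enumerate(CYTOKINE_SESSIONS)}
    rows = []
    for subj, grp in merged.groupby("subject"):
        grp = grp.sort_values("session", key=lambda s: s.map(order))
        for a, b in itertools.combinations(grp.index, 2):
            rows.append({
                "subject": subj,
                "session_a": grp.loc[a, "session"],
                "session_b": grp.loc[b, "session"],
                "dY": int(grp.loc[b, "Y"] - grp.loc[a, "Y"]),
                "dX": float(grp.loc[b, "X"] - grp.loc[a, "X"]),
                "valid_pair": bool(grp.loc[a, "valid"] and grp.loc[b, "valid"]),
            })
    pairs = pd.DataFrame(rows, columns=["subject", "session_a", "session_b",
                                        "dY", "dX", "valid_pair"])
    if comparison_unit == "observations":
        n_valid = int(merged["valid"].sum())
    else:
        n_valid = int(pairs["valid_pair"].sum()) if len(pairs) else 0
    return pairs, n_valid


def somers_d_pooled(pairs: pd.DataFrame) -> dict:
    """Pooled Somers' D over all within-subject pairs.

    C = #(dY*dX > 0), Q = #(dY*dX < 0); pairs tied on X but untied on Y
    count in the denominator only; D = (C - Q) / #(dY != 0).
    """
    dy = pairs["dY"].to_numpy()
    dx = pairs["dX"].to_numpy()
    untied = dy != 0
    n_untied = int(untied.sum())
    if n_untied == 0:
        raise ValueError("Somers' D undefined: all pairs tied on the "
                         "discretized abundance level")
    prod = dy[untied] * dx[untied]
    c = int((prod > 0).sum())
    q = int((prod < 0).sum())
    return {"D": (c - q) / n_untied, "n_untied": n_untied,
            "concordant": c, "discordant": q,
            "x_ties": int((prod == 0).sum())}


def jackknife_se(pairs: pd.DataFrame) -> tuple[float, int]:
    """Delete-one-subject jackknife SE of pooled Somers' D.

    SE = sqrt((g-1)/g * sum_i (D_(i) - mean D_(.))^2) over the g subjects
    contributing untied pairs; requires g >= 2.
    """
    contributing = sorted(pairs.loc[pairs["dY"] != 0, "subject"].unique())
    g = len(contributing)
    if g < 2:
        raise ValueError("jackknife requires >= 2 subjects with untied pairs")
    d_i = np.array([
        somers_d_pooled(pairs[pairs["subject"] != subj])["D"]
        for subj in contributing
    ])
    se = float(np.sqrt((g - 1) / g * np.sum((d_i - d_i.mean()) ** 2)))
    return se, g


@dataclass
class AssociationRecord:
    """One cytokine-OTU combination of the screen."""

    analyte: str
    otu: str
    genus: str
    D: float
    se: float
    n_valid: int
    n_pairs_untied: int
    p: float
    q: float
    significant: bool
    excluded: bool
    reason: str


def screen_combinations(
    rel: RelAbundanceTable,
    metadata: pd.DataFrame,
    panel: pd.DataFrame,
    candidates: list[str],
    analytes: list[str] | None = None,
    fdr: float = 0.01,
    min_comparisons: int = 10,
    comparison_unit: str = "observations",
    subjects: list[str] | None = None,
    sessions: tuple[str, ...] = CYTOKINE_SESSIONS,
    site: str = "stool",
) -> pd.DataFrame:
    """Evaluate the full candidate-OTU x analyte grid.

    The exclusion rule (fewer than ``min_comparisons`` valid comparisons,
    no untied pairs, or fewer than two contributing subjects) is applied
    before any p-value is computed; BH at ``fdr`` runs across the computed
    p-values only.  D < 0 marks a negative association.
    """
    if not candidates:
        raise ValueError("candidate OTU list is empty")
    if analytes is None:
        analytes = sorted(panel["analyte"].unique())
    disc = discretize_abundance(rel, metadata, subjects=subjects,
                                sessions=sessions, site=site, otus=candidates)
    present = set(disc["otu"].unique())

    rows: list[AssociationRecord] = []
    for otu in candidates:
        genus = genus_label(rel.taxonomy, otu)
        for analyte in analytes:
            rec = AssociationRecord(analyte, otu, genus, np.nan, np.nan, 0, 0,
                                    np.nan, np.nan, False, True, "")
            if otu not in present:
                rec.reason = "all_zero_abundance"
                rows.append(rec)
                continue
            pairs, n_valid = build_within_subject_pairs(
                disc, panel, analyte, otu, comparison_unit)
            rec.n_valid = n_valid
            if n_valid < min_comparisons:
                rec.reason = (f"fewer than {min_comparisons} valid comparisons "
                              f"({n_valid})")
                rows.append(rec)
                continue
            untied = pairs["dY"] != 0
            rec.n_pairs_untied = int(untied.sum())
            if not untied.any():
                rec.reason = "all pairs tied on abundance level"
                rows.append(rec)
                continue
            stat = somers_d_pooled(pairs)
            rec.D = stat["D"]
            try:
                se, g = jackknife_se(pairs)
            except ValueError:
                rec.reason = "fewer than 2 subjects with untied pairs"
                rows.append(rec)
                continue
            rec.se = se
            if se == 0.0:
                rec.reason = "degenerate jackknife (SE = 0)"
                rows.append(rec)
                continue
            rec.p = float(2 * scipy.stats.t.sf(abs(rec.D / se), g - 1))
            rec.p = min(max(rec.p, np.finfo(float).tiny), 1.0)
            rec.excluded = False
            rows.append(rec)

    out = pd.DataFrame([r.__dict__ for r in rows])
    computed = ~out["excluded"]
    if computed.any():
        qv, flags, _ = bh_fdr(out.loc[computed, "p"].to_numpy(), fdr)
        out.loc[computed, "q"] = qv
        out.loc[computed, "significant"] = flags
    return out
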