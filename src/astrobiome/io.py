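"""Domain types, file readers/writers and metadata derivation.

The unit every analysis stage consumes is an :class:`OtuTable` — a taxon x
sample matrix of integer 16S read counts with an optional 6-rank taxonomy —
plus a per-sample metadata table carrying subject, body/ISS site, timepoint
label and the mission stage derived from it (``L-*`` preflight, ``FD*``
inflight, ``R+*`` postflight).

Supported on-disk dialects: plain TSV (taxa as rows), the mothur ``.shared``
dialect (samples as rows; transposed on read) and a minimal dense BIOM-JSON.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("astrobiome")

# ---------------------------------------------------------------------------
# Controlled vocabularies

TIMEPOINTS: tuple[str, ...] = (
    "L-240", "L-150", "L-90", "L-60",
    "FD7", "FD90", "FD180", "FD360",
    "R+0", "R+30", "R+60", "R+180",
)

BODY_SITES: tuple[str, ...] = ("forehead", "forearm", "nares", "tongue", "stool")
ISS_SITES: tuple[str, ...] = tuple(f"iss_ss{c}" for c in "ABCDEF")
CONTROL_SITES: tuple[str, ...] = ("control_pcr", "control_kit")
SITES: tuple[str, ...] = BODY_SITES + ISS_SITES + ("water",) + CONTROL_SITES

#: Blood-draw sessions used for the cytokine panel and the association screen.
CYTOKINE_SESSIONS: tuple[str, ...] = ("L-60", "FD7", "FD180", "R+0", "R+180")

TAXONOMY_RANKS: tuple[str, ...] = (
    "domain", "phylum", "class", "order", "family", "genus",
)

STAGES: tuple[str, ...] = ("preflight", "inflight", "postflight")


def genus_label(taxonomy: pd.DataFrame | None, otu_id: str) -> str:
    """Genus label for an OTU; unclassified genera keyed family + ' (uncl.)'."""
    if taxonomy is None or otu_id not in taxonomy.index:
        return "unclassified"
    row = taxonomy.loc[otu_id]
    genus = str(row["genus"])
    if genus.lower() == "unclassified":
        return f"{row['family']} (uncl.)"
    return genus


def mission_stage(timepoint: str) -> str:
    """Derive the mission stage from a timepoint label (total over the enum)."""
    if timepoint not in TIMEPOINTS:
        raise ValueError(f"unknown timepoint label: {timepoint!r}")
    if timepoint.startswith("L-"):
        return "preflight"
    if timepoint.startswith("FD"):
        return "inflight"
    return "postflight"


# ---------------------------------------------------------------------------
# Core containers


@dataclass
class OtuTable:
    """Taxon x sample integer count matrix with an optional taxonomy map.

    ``counts`` is a DataFrame indexed by OTU id with sample ids as columns;
    ``taxonomy`` (if given) is indexed by OTU id with the six rank columns
    of :data:`TAXONOMY_RANKS` ("unclassified" allowed at any rank).
    """

    counts: pd.DataFrame
    taxonomy: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        c = self.counts
        if c.index.has_duplicates:
            dups = c.index[c.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate OTU ids: {dups}")
        if c.columns.has_duplicates:
            dups = c.columns[c.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample ids: {dups}")
        arr = c.to_numpy()
        if arr.size and not np.issubdtype(arr.dtype, np.integer):
            frac = arr != np.floor(arr)
            if frac.any():
                i, j = np.argwhere(frac)[0]
                raise ValueError(
                    f"non-integer count {arr[i, j]!r} at OTU {c.index[i]!r}, "
                    f"sample {c.columns[j]!r}"
                )
            self.counts = c.astype(np.int64)
            arr = self.counts.to_numpy()
        if arr.size and (arr < 0).any():
            i, j = np.argwhere(arr < 0)[0]
            raise ValueError(
                f"negative count at OTU {c.index[i]!r}, sample {c.columns[j]!r}"
            )

    @property
    def otu_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    def genus_of(self, otu_id: str) -> str:
        return genus_label(self.taxonomy, otu_id)


@dataclass
class RelAbundanceTable:
    """Same axes as :class:`OtuTable`; per-sample proportions summing to 1."""

    values: pd.DataFrame
    taxonomy: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        sums = self.values.sum(axis=0)
        bad = sums.index[np.abs(sums.to_numpy() - 1.0) > 1e-9]
        if len(bad):
            raise ValueError(f"sample columns do not sum to 1: {list(bad)}")

    @property
    def otu_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)


METADATA_COLUMNS = ("subject_id", "site", "timepoint", "stage", "relative_time")


def validate_metadata(meta: pd.DataFrame) -> pd.DataFrame:
    """Validate a sample-metadata frame and derive the mission stage.

    Expects an index of unique sample ids and columns ``subject_id``, ``site``,
    ``timepoint`` (``relative_time`` optional, months since study start).
    Control samples must have no subject id; ISS-surface samples may only
    occur at inflight (FD) timepoints.
    """
    meta = meta.copy()
    if meta.index.has_duplicates:
        dups = meta.index[meta.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate sample ids in metadata: {dups}")
    for col in ("site", "timepoint"):
        if col not in meta.columns:
            raise ValueError(f"metadata missing required column {col!r}")
    if "subject_id" not in meta.columns:
        meta["subject_id"] = pd.NA
    bad_site = sorted(set(meta["site"]) - set(SITES))
    if bad_site:
        raise ValueError(f"unknown site tokens: {bad_site}")
    is_control = meta["site"].isin(CONTROL_SITES)
    bad_tp = sorted(set(meta.loc[~is_control, "timepoint"]) - set(TIMEPOINTS))
    if bad_tp:
        raise ValueError(f"unknown timepoint tokens: {bad_tp}")
    has_subject = meta["subject_id"].notna() & (meta["subject_id"].astype(str) != "")
    if (is_control & has_subject).any():
        bad = meta.index[is_control & has_subject].tolist()
        raise ValueError(f"control samples must not carry a subject id: {bad}")
    if (~is_control & ~has_subject).any():
        bad = meta.index[~is_control & ~has_subject].tolist()
        raise ValueError(f"non-control samples missing subject id: {bad}")
    iss = meta["site"].isin(ISS_SITES)
    bad_iss = meta.index[iss & ~meta["timepoint"].astype(str).str.startswith("FD")]
    if len(bad_iss):
        raise ValueError(
            f"ISS-surface samples only occur at FD timepoints: {list(bad_iss)}"
        )
    meta["stage"] = [
        mission_stage(tp) if not ctl else pd.NA
        for tp, ctl in zip(meta["timepoint"], is_control)
    ]
    if "relative_time" not in meta.columns:
        meta["relative_time"] = np.nan
    else:
        rt = pd.to_numeric(meta["relative_time"], errors="coerce")
        if (rt.dropna() < 0).any():
            raise ValueError("relative_time must be nonnegative (months)")
        meta["relative_time"] = rt
    return meta[list(METADATA_COLUMNS)]


def check_samples_covered(table: OtuTable, meta: pd.DataFrame) -> None:
    """Raise if any counted sample lacks metadata (lists the offending ids)."""
    missing = sorted(set(table.sample_ids) - set(meta.index))
    if missing:
        raise ValueError(f"samples present in counts but absent in metadata: {missing}")


# ---------------------------------------------------------------------------
# Cytokine panel

CYTOKINE_COLUMNS = ("subject_id", "session", "analyte", "concentration",
                    "censored", "detection_limit")


def validate_cytokines(panel: pd.DataFrame) -> pd.DataFrame:
    """Validate a long-format cytokine panel (one row per measurement)."""
    panel = panel.copy().reset_index(drop=True)
    for col in ("subject_id", "session", "analyte", "concentration"):
        if col not in panel.columns:
            raise ValueError(f"cytokine panel missing column {col!r}")
    if "censored" not in panel.columns:
        panel["censored"] = False
    panel["censored"] = panel["censored"].astype(bool)
    if "detection_limit" not in panel.columns:
        panel["detection_limit"] = np.nan
    bad = sorted(set(panel["session"]) - set(CYTOKINE_SESSIONS))
    if bad:
        raise ValueError(f"unknown cytokine sessions: {bad}")
    unc = panel[~panel["censored"]]
    if (unc["concentration"] <= 0).any():
        raise ValueError("uncensored concentrations must be positive")
    cens = panel[panel["censored"]]
    if len(cens) and not (cens["detection_limit"] > 0).all():
        raise ValueError("censored records require a positive detection limit")
    return panel[list(CYTOKINE_COLUMNS)]


# ---------------------------------------------------------------------------
# Run configuration


@dataclass
class RunConfig:
    """Thresholds and run parameters shared across pipeline stages."""

    min_samples_per_otu: int = 4
    min_reads_per_sample: int = 4
    contaminant_min_reads: int = 5
    core_prevalence: float = 0.75
    core_min_reads: int = 4
    assoc_min_comparisons: int = 10
    assoc_fdr: float = 0.01
    cytokine_fdr: float = 0.05
    da_fdr: float = 0.10
    seed: int = 0
    permutations: int = 999
    paths: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for f in fields(self):
            if f.name in ("seed", "paths"):
                continue
            v = getattr(self, f.name)
            if v <= 0:
                raise ValueError(f"threshold {f.name} must be positive, got {v}")
        if not (0 < self.core_prevalence <= 1):
            raise ValueError("core_prevalence must lie in (0, 1]")


def load_config(path: str | Path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    known = {f.name for f in fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return RunConfig(**raw)


# ---------------------------------------------------------------------------
# Count-table readers / writers

DIALECTS = ("tsv", "mothur_shared", "biom_json")


def _check_integral(df: pd.DataFrame, path: str | Path) -> pd.DataFrame:
    arr = df.to_numpy()
    if arr.dtype == object or np.issubdtype(arr.dtype, np.floating):
        num = pd.DataFrame(df).apply(pd.to_numeric, errors="coerce")
        bad = num.isna() | (num != np.floor(num.fillna(0)))
        if bad.to_numpy().any():
            i, j = np.argwhere(bad.to_numpy())[0]
            raise ValueError(
                f"{path}: non-integer count {df.iat[i, j]!r} at row "
                f"{df.index[i]!r}, column {df.columns[j]!r}"
            )
        df = num.astype(np.int64)
    return df


def read_count_table(
    path: str | Path,
    dialect: str = "tsv",
    taxonomy: pd.DataFrame | None = None,
) -> OtuTable:
    """Read an OTU count table in one of the supported dialects.

    ``tsv``: taxa as rows, first column the OTU id, '#' comment lines
    ignored.  ``mothur_shared``: the mothur ``.shared`` layout (label /
    Group / numOtus then one column per OTU; samples as rows), transposed
    to the in-memory taxa-as-rows orientation.  ``biom_json``: minimal
    dense BIOM-JSON.
    """
    if dialect not in DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}; expected one of {DIALECTS}")
    if dialect == "biom_json":
        with open(path) as fh:
            doc = json.load(fh)
        if doc.get("matrix_type") != "dense":
            raise ValueError(f"{path}: only dense BIOM-JSON is supported")
        otus = [r["id"] for r in doc["rows"]]
        samples = [c["id"] for c in doc["columns"]]
        counts = pd.DataFrame(doc["data"], index=otus, columns=samples)
        return OtuTable(_check_integral(counts, path), taxonomy)
    df = pd.read_csv(path, sep="\t", comment="#", index_col=0, dtype=object)
    if dialect == "mothur_shared":
        if not {"Group", "numOtus"} <= set(df.columns):
            raise ValueError(f"{path}: not a mothur shared file (missing Group/numOtus)")
        df = df.set_index("Group").drop(columns=["numOtus"]).T
    counts = _check_integral(df, path)
    return OtuTable(counts, taxonomy)


def write_count_table(table: OtuTable, path: str | Path, dialect: str = "tsv") -> None:
    """Write a count table in any supported dialect (lossless round trip)."""
    if dialect not in DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}; expected one of {DIALECTS}")
    if dialect == "tsv":
        out = table.counts.copy()
        out.index.name = "otu_id"
        out.to_csv(path, sep="\t")
    elif dialect == "mothur_shared":
        t = table.counts.T
        out = pd.DataFrame(index=t.index)
        out["label"] = "0.03"
        out["Group"] = t.index
        out["numOtus"] = t.shape[1]
        for otu in t.columns:
            out[otu] = t[otu].to_numpy()
        out.to_csv(path, sep="\t", index=False)
    else:
        doc = {
            "id": None,
            "format": "Biological Observation Matrix (minimal dense)",
            "type": "OTU table",
            "matrix_type": "dense",
            "shape": list(table.counts.shape),
            "rows": [{"id": i, "metadata": None} for i in table.otu_ids],
            "columns": [{"id": s, "metadata": None} for s in table.sample_ids],
            "data": table.counts.to_numpy().tolist(),
        }
        with open(path, "w") as fh:
            json.dump(doc, fh)


def read_metadata(path: str | Path) -> pd.DataFrame:
    meta = pd.read_csv(path, sep="\t", comment="#", index_col=0, dtype=object)
    return validate_metadata(meta)


def write_metadata(meta: pd.DataFrame, path: str | Path) -> None:
    out = meta.copy()
    out.index.name = "sample_id"
    out.to_csv(path, sep="\t")


def read_taxonomy(path: str | Path) -> pd.DataFrame:
    tax = pd.read_csv(path, sep="\t", comment="#", index_col=0, dtype=str)
    missing = set(TAXONOMY_RANKS) - set(tax.columns)
    if missing:
        raise ValueError(f"{path}: taxonomy missing rank columns {sorted(missing)}")
    return tax[list(TAXONOMY_RANKS)]


def read_cytokines(path: str | Path) -> pd.DataFrame:
    panel = pd.read_csv(path, sep="\t", comment="#")
    panel["concentration"] = pd.to_numeric(panel["concentration"])
    if "detection_limit" in panel.columns:
        panel["detection_limit"] = pd.to_numeric(panel["detection_limit"])
    if "censored" in panel.columns:
        panel["censored"] = panel["censored"].astype(str).str.lower().isin(
            ("true", "1", "yes"))
    return validate_cytokines(panel)


def write_result_table(records: Sequence[Mapping] | pd.DataFrame,
                       path: str | Path,
                       columns: Iterable[str] | None = None,
                       header_comments: Iterable[str] = ()) -> None:
    """Write homogeneous result records as a TSV with deterministic columns.

    An empty record list yields a header-only file (requires ``columns``
    unless records is a DataFrame).  Comment lines are written with a
    leading '#' and ignored by all readers in this package.
    """
    if isinstance(records, pd.DataFrame):
        df = records.copy()
    else:
        records = list(records)
        if records:
            cols = list(columns) if columns is not None else list(records[0].keys())
            df = pd.DataFrame.from_records(records, columns=cols)
        else:
            if columns is None:
                raise ValueError("empty record list requires explicit columns")
            df = pd.DataFrame(columns=list(columns))
    with open(path, "w") as fh:
        for line in header_comments:
            fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_result_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")
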