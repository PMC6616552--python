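"""OTU-table QC: low-support filtering, control-based contaminant removal,
total-sum normalization, and the prevalence-based core/resident rules.

Filtering rules, read literally:

* an OTU is kept iff at least ``min_samples`` samples each carry at least
  ``min_reads`` of its reads (defaults 4 and 4);
* an OTU is a contaminant iff any single negative-control sample (PCR or
  extraction-kit) carries at least ``min_reads`` (default 5) of its reads —
  per control sample, not summed across controls;
* a site's preflight core consists of the OTUs (or genera, counts summed
  within genus) detected with at least ``min_reads`` reads in at least a
  ``prevalence`` fraction (default 75%) of that site's preflight samples.

Persistent station-surface residents are reported under two readings of the
persistence rule: *strict* (nonzero at every relative timepoint) and
*relaxed* (no run of two or more consecutive zero timepoints); strict
membership always implies relaxed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import CONTROL_SITES, OtuTable, RelAbundanceTable

logger = logging.getLogger("astrobiome")


def filter_low_support_otus(
    table: OtuTable, min_samples: int = 4, min_reads: int = 4
) -> OtuTable:
    """Keep OTUs present in >= min_samples samples with >= min_reads each.

    The sample set is unchanged; idempotent.
    """
    qualifying = (table.counts >= min_reads).sum(axis=1)
    keep = qualifying >= min_samples
    if not keep.any():
        logger.warning("filter_low_support_otus removed every OTU")
    tax = table.taxonomy.loc[keep[keep].index] if table.taxonomy is not None else None
    return OtuTable(table.counts.loc[keep], tax)


def remove_contaminants(
    table: OtuTable,
    control_sample_ids: list[str] | None,
    min_reads: int = 5,
    allow_no_controls: bool = False,
) -> tuple[OtuTable, list[str]]:
    """Drop OTUs with >= min_reads in ANY control sample; drop control columns.

    Returns the cleaned table and the removed OTU ids.  Refuses to run
    without control samples unless ``allow_no_controls`` is set.
    """
    control_sample_ids = list(control_sample_ids or [])
    if not control_sample_ids:
        if not allow_no_controls:
            raise ValueError(
                "no control samples given; pass allow_no_controls=True to skip "
                "contaminant removal explicitly"
            )
        return table, []
    missing = sorted(set(control_sample_ids) - set(table.sample_ids))
    if missing:
        raise ValueError(f"control samples absent from table: {missing}")
    ctl = table.counts[control_sample_ids]
    removed = list(ctl.index[(ctl >= min_reads).any(axis=1)])
    keep_rows = ~table.counts.index.isin(removed)
    keep_cols = [s for s in table.sample_ids if s not in set(control_sample_ids)]
    tax = (table.taxonomy.loc[table.counts.index[keep_rows]]
           if table.taxonomy is not None else None)
    return OtuTable(table.counts.loc[keep_rows, keep_cols], tax), removed


def control_sample_ids(metadata: pd.DataFrame) -> list[str]:
    """Sample ids of PCR-negative and extraction-kit control samples."""
    return list(metadata.index[metadata["site"].isin(CONTROL_SITES)])


def to_relative_abundance(table: OtuTable) -> RelAbundanceTable:
    """Total-sum scaling: divide each sample column by its read depth."""
    sums = table.counts.sum(axis=0)
    zero = list(sums.index[sums == 0])
    if zero:
        raise ValueError(f"zero-read samples cannot be normalized: {zero}")
    return RelAbundanceTable(table.counts / sums, table.taxonomy)


def genus_counts(table: OtuTable) -> pd.DataFrame:
    """Sum counts of OTUs sharing a genus label (family + ' (uncl.)' for
    unclassified genera)."""
    genera = pd.Series({otu: table.genus_of(otu) for otu in table.otu_ids})
    return table.counts.groupby(genera).sum()


@dataclass
class CoreMembership:
    """Preflight core of one site at OTU or genus level."""

    site: str
    level: str
    members: list[str]
    prevalence: pd.Series  # member -> fraction of preflight samples detected

    def __post_init__(self) -> None:
        self.members = list(self.members)


def core_microbiome(
    table: OtuTable,
    metadata: pd.DataFrame,
    site: str,
    prevalence: float = 0.75,
    min_reads: int = 4,
    level: str = "otu",
) -> CoreMembership:
    """Taxa detected (>= min_reads) in >= `prevalence` of preflight samples."""
    if site not in set(metadata["site"]):
        raise ValueError(f"unknown site {site!r}")
    pre = metadata.index[(metadata["site"] == site)
                         & (metadata["stage"] == "preflight")]
    pre = [s for s in pre if s in table.counts.columns]
    if not pre:
        raise ValueError(f"no preflight samples at site {site!r}")
    mat = genus_counts(table)[pre] if level == "genus" else table.counts[pre]
    frac = (mat >= min_reads).sum(axis=1) / len(pre)
    members = frac.index[frac >= prevalence]
    return CoreMembership(site, level, list(members), frac.loc[members])


@dataclass
class ResidentRecord:
    """Persistence of one OTU on one station surface across relative timepoints."""

    surface: str
    otu_id: str
    detected: list[bool]  # ordered by relative timepoint
    qualifies_strict: bool
    qualifies_relaxed: bool


def _max_zero_run(detected: np.ndarray) -> int:
    run = best = 0
    for d in detected:
        run = 0 if d else run + 1
        best = max(best, run)
    return best


def resident_otus(
    table: OtuTable,
    metadata: pd.DataFrame,
    surface: str,
    rule: str = "strict",
) -> list[ResidentRecord]:
    """Classify surface OTUs by persistence across relative timepoints.

    Samples on the surface are binned by ``relative_time``; an OTU is
    *detected* at a relative timepoint if any sample in the bin carries a
    nonzero count.  Returns a record (with both rule flags) for every OTU
    detected at least once; ``rule`` selects which flag downstream reports
    treat as qualifying.
    """
    if rule not in ("strict", "relaxed"):
        raise ValueError(f"unknown rule {rule!r}")
    on_surface = metadata.index[(metadata["site"] == surface)]
    on_surface = [s for s in on_surface if s in table.counts.columns]
    if not on_surface:
        raise ValueError(f"no samples on surface {surface!r}")
    times = metadata.loc[on_surface, "relative_time"]
    bins = sorted(times.dropna().unique())
    if len(bins) < 2:
        raise ValueError(f"surface {surface!r} has fewer than 2 relative timepoints")
    detected = pd.DataFrame(
        {t: (table.counts[times.index[times == t]].sum(axis=1) > 0) for t in bins}
    )
    records = []
    for otu in detected.index[detected.any(axis=1)]:
        vec = detected.loc[otu].to_numpy()
        records.append(ResidentRecord(
            surface=surface,
            otu_id=otu,
            detected=[bool(v) for v in vec],
            qualifies_strict=bool(vec.all()),
            qualifies_relaxed=_max_zero_run(vec) < 2,
        ))
    return records
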