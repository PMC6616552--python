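"""Synthetic longitudinal crew-microbiome cohorts.

Emulates the statistical structure of a nine-subject, six-to-twelve-month
orbital-station study: five body sites sampled at ten timepoints around the
mission (four preflight, three inflight, three postflight), six station
surfaces swabbed inflight, negative-control samples carrying contaminant
taxa, and a plasma cytokine panel at five blood-draw sessions with
left-censoring at per-analyte detection limits.

Counts are Dirichlet-multinomial: each site has a mean composition, each
subject perturbs it with lognormal random intercepts, mission-stage effects
multiply selected taxa, and inflight inter-subject convergence shrinks the
subject-specific deviations of selected gastrointestinal taxa toward the
cohort mean.  Station-surface samples mix a resident surface profile with
the mean skin composition of the crew on board at that time, so
skin-surface similarity analyses have signal.  Cytokine couplings act on
the generative (latent) log abundance of a stool taxon, not the realized
counts, which avoids circularity while keeping the planted concordance
recoverable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import (
    BODY_SITES,
    CYTOKINE_SESSIONS,
    ISS_SITES,
    OtuTable,
    TAXONOMY_RANKS,
    mission_stage,
    validate_cytokines,
    validate_metadata,
)

#: Core body-sampling timepoints (the 6-month design; no FD360 by default).
DEFAULT_TIMEPOINTS: tuple[str, ...] = (
    "L-240", "L-150", "L-90", "L-60",
    "FD7", "FD90", "FD180",
    "R+0", "R+30", "R+60",
)

#: Months since subject launch for each timepoint label (6-month mission).
_TIMEPOINT_MONTHS: Mapping[str, float] = {
    "L-240": -8.0, "L-150": -5.0, "L-90": -3.0, "L-60": -2.0,
    "FD7": 0.25, "FD90": 3.0, "FD180": 6.0, "FD360": 12.0,
    "R+0": 6.0, "R+30": 7.0, "R+60": 8.0, "R+180": 12.0,
}

DEFAULT_ANALYTES: tuple[str, ...] = (
    "IL-8", "IL-1b", "TNFa", "IL-17", "IL-1ra", "IFNg", "IL-2", "IL-4",
    "IL-10", "G-CSF", "FGF-basic", "Tpo", "VEGF", "MCP-1", "MIP-1b",
    "RANTES", "IL-6", "IL-12", "EGF",
)


@dataclass
class CohortSpec:
    """Parameters of the generated cohort; defaults mirror the study design."""

    n_subjects: int = 9
    stool_subjects: int = 5
    body_sites: tuple[str, ...] = BODY_SITES
    iss_sites: tuple[str, ...] = ISS_SITES
    timepoints: tuple[str, ...] = DEFAULT_TIMEPOINTS
    #: extra stool collections matching blood sessions outside the core design
    stool_extra_timepoints: tuple[str, ...] = ("R+180",)
    n_taxa: int = 150
    library_size_median: float = 20_000.0
    library_size_sigma: float = 0.5
    #: Dirichlet concentration controlling per-sample overdispersion
    base_concentration: float = 300.0
    #: SD of per-subject log-abundance random intercepts
    subject_effect_sd: float = 0.7
    #: upper SD of per-(subject, timepoint) latent log-abundance
    #: fluctuations; each taxon draws its own volatility between
    #: ``session_effect_sd_min`` and this value (taxa named in couplings or
    #: convergence_taxa are pinned to the maximum so planted temporal signal
    #: exists); this temporal wobble is what cytokine couplings can track
    session_effect_sd: float = 1.75
    session_effect_sd_min: float = 0.2
    #: upper volatility for taxa not named in any planted effect
    session_effect_sd_background: float = 0.5
    #: taxa pinned to a moderately abundant baseline (a few percent) so
    #: planted effects act on taxa the pipeline can actually detect
    abundant_taxa: tuple[str, ...] = ()
    #: (taxon, stage, log2 fold change) applied multiplicatively to the mean
    stage_effects: tuple[tuple[str, str, float], ...] = ()
    #: taxa whose inter-subject dispersion shrinks inflight (stool only)
    convergence_taxa: tuple[str, ...] = ()
    convergence_factor: float = 1.0
    #: preflight carriage contrast (ln units) for convergence taxa: each such
    #: taxon has one carrier subject at +contrast and the rest at baseline,
    #: emulating the bimodal carriage of strongly subject-specific gut taxa
    convergence_pre_contrast: float = 3.5
    #: baseline (non-carrier) stool abundance of convergence taxa; keeps the
    #: carrier's share moderate so compositional closure stays realistic
    convergence_base_abundance: float = 0.005
    #: station-surface mixing weight of the resident profile (rest = crew skin)
    surface_resident_weight: float = 0.7
    #: (analyte, taxon, strength): cytokine log-mean moves with taxon log RA
    coupling: tuple[tuple[str, str, float], ...] = ()
    analytes: tuple[str, ...] = DEFAULT_ANALYTES
    #: (analyte, session, delta) added to the analyte log-mean at that session
    cytokine_stage_effects: tuple[tuple[str, str, float], ...] = ()
    cytokine_baseline_log: float = np.log(50.0)
    cytokine_subject_sd: float = 0.3
    cytokine_noise_sd: float = 0.35
    #: analyte -> detection limit (pg/mL); values below are flagged censored
    censor_limits: Mapping[str, float] = field(default_factory=dict)
    n_contaminants: int = 5
    contaminant_control_reads: tuple[int, int] = (5, 60)
    control_noise_taxa: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.convergence_factor <= 1):
            raise ValueError("convergence_factor must lie in (0, 1]")
        if not (0 <= self.surface_resident_weight <= 1):
            raise ValueError("surface_resident_weight must lie in [0, 1]")
        if self.stool_subjects > self.n_subjects:
            raise ValueError("stool_subjects cannot exceed n_subjects")

    @property
    def taxa(self) -> list[str]:
        return [f"Otu{i + 1:06d}" for i in range(self.n_taxa)]

    @property
    def contaminant_taxa(self) -> list[str]:
        return [f"Contam{i + 1:03d}" for i in range(self.n_contaminants)]

    @property
    def subjects(self) -> list[str]:
        return [f"Ast{chr(ord('A') + i)}" for i in range(self.n_subjects)]


@dataclass
class Cohort:
    """A generated cohort: counts, metadata, cytokines and planted truth."""

    table: OtuTable
    metadata: pd.DataFrame
    truth: pd.DataFrame
    #: latent per (subject, session) log relative abundance of stool taxa,
    #: used to drive cytokine couplings without circularity
    stool_log_ra: pd.DataFrame | None = None


def _taxonomy(spec: CohortSpec) -> pd.DataFrame:
    """One synthetic genus per OTU (so genus-level == OTU-level by default)."""
    rows = {}
    for i, otu in enumerate(spec.taxa):
        rows[otu] = {
            "domain": "Bacteria",
            "phylum": f"Phylum{i % 6 + 1}",
            "class": f"Class{i % 12 + 1}",
            "order": f"Order{i % 20 + 1}",
            "family": f"Family{i % 30 + 1}",
            "genus": f"Genus{i + 1:03d}",
        }
    for j, otu in enumerate(spec.contaminant_taxa):
        rows[otu] = {r: "unclassified" for r in TAXONOMY_RANKS}
        rows[otu]["domain"] = "Bacteria"
        rows[otu]["genus"] = f"ContamGenus{j + 1:02d}"
    return pd.DataFrame.from_dict(rows, orient="index")[list(TAXONOMY_RANKS)]


def _softmax(logp: np.ndarray) -> np.ndarray:
    z = np.exp(logp - logp.max())
    return z / z.sum()


def generate_cohort(spec: CohortSpec) -> Cohort:
    """Draw a full cohort (body + station + control samples) from a spec.

    The same seed yields byte-identical tables.  Column sums equal the drawn
    library sizes exactly (multinomial sampling).
    """
    rng = np.random.default_rng(spec.seed)
    taxa = spec.taxa
    n_taxa = len(taxa)
    taxon_index = {t: i for i, t in enumerate(taxa)}
    for taxon, stage, _ in spec.stage_effects:
        if taxon not in taxon_index:
            raise ValueError(f"stage effect on unknown taxon {taxon!r}")
        if stage not in ("preflight", "inflight", "postflight"):
            raise ValueError(f"unknown stage {stage!r}")
    for taxon in spec.convergence_taxa:
        if taxon not in taxon_index:
            raise ValueError(f"convergence on unknown taxon {taxon!r}")

    # site mean compositions (log scale), shared across subjects
    site_logmean = {
        site: np.log(rng.dirichlet(np.full(n_taxa, 0.8)) + 1e-12)
        for site in list(spec.body_sites) + ["_surface_resident"]
    }
    for taxon in spec.abundant_taxa:
        if taxon not in taxon_index:
            raise ValueError(f"abundant_taxa names unknown taxon {taxon!r}")
        for site in site_logmean:
            site_logmean[site][taxon_index[taxon]] = np.log(0.03)
    # per-taxon inter-subject dispersion: most taxa moderate, convergence
    # taxa strongly subject-specific (that is what makes them converge)
    subj_scale = rng.uniform(0.3, 1.0, n_taxa) * spec.subject_effect_sd
    # per subject x site x taxon random intercepts
    subj_eff = {
        (s, site): rng.normal(0.0, 1.0, n_taxa) * subj_scale
        for s in spec.subjects
        for site in spec.body_sites
    }
    # taxon-specific temporal volatility; cytokine-coupled taxa are pinned
    # fully volatile so the planted temporal signal exists
    wobble_scale = rng.uniform(spec.session_effect_sd_min,
                               spec.session_effect_sd_background, n_taxa)
    for taxon in {t for _, t, _ in spec.coupling}:
        if taxon in taxon_index:
            wobble_scale[taxon_index[taxon]] = spec.session_effect_sd
    conv_idx = np.array([taxon_index[t] for t in spec.convergence_taxa], dtype=int)
    if len(conv_idx):
        site_logmean["stool"][conv_idx] = np.log(spec.convergence_base_abundance)
        # one carrier subject per convergence taxon, round-robin over the
        # subjects who collect inflight stool
        carriers = [spec.subjects[i % spec.stool_subjects]
                    for i in range(len(conv_idx))]
        for s in spec.subjects:
            eff = subj_eff[(s, "stool")]
            eff[conv_idx] = np.where(
                np.array(carriers) == s, spec.convergence_pre_contrast, 0.0)
    stage_shift = {st: np.zeros(n_taxa) for st in ("preflight", "inflight", "postflight")}
    for taxon, stage, l2fc in spec.stage_effects:
        stage_shift[stage][taxon_index[taxon]] += l2fc * np.log(2.0)

    launch_month = {s: 8.0 + 3.0 * i for i, s in enumerate(spec.subjects)}
    stool_set = set(spec.subjects[: spec.stool_subjects])

    sample_counts: dict[str, np.ndarray] = {}
    meta_rows: dict[str, dict] = {}
    stool_latent: dict[tuple[str, str], np.ndarray] = {}
    skin_latent: dict[tuple[str, str], list[np.ndarray]] = {}

    def draw_counts(composition: np.ndarray) -> np.ndarray:
        lib = int(round(rng.lognormal(np.log(spec.library_size_median),
                                      spec.library_size_sigma)))
        lib = max(lib, 100)
        alpha = composition * spec.base_concentration
        p = rng.dirichlet(np.maximum(alpha, 1e-8))
        return rng.multinomial(lib, p)

    def latent_logmean(subject: str, site: str, timepoint: str) -> np.ndarray:
        stage = mission_stage(timepoint)
        eff = subj_eff[(subject, site)]
        wobble = rng.normal(0.0, 1.0, n_taxa) * wobble_scale
        if site == "stool" and stage == "inflight" and len(conv_idx):
            # convergence shrinks the whole inter-subject deviation (random
            # intercept and temporal wobble) of the selected taxa
            eff = eff.copy()
            eff[conv_idx] *= spec.convergence_factor
            wobble[conv_idx] *= spec.convergence_factor
        return site_logmean[site] + eff + stage_shift[stage] + wobble

    n = 0
    for subject in spec.subjects:
        for site in spec.body_sites:
            tps = list(spec.timepoints)
            if site == "stool":
                if subject not in stool_set:
                    # subjects who opted out still provide pre/postflight stool
                    tps = [t for t in tps if mission_stage(t) != "inflight"]
                tps += [t for t in spec.stool_extra_timepoints if t not in tps]
            for tp in tps:
                n += 1
                sid = f"s{n:04d}"
                logm = latent_logmean(subject, site, tp)
                comp = _softmax(logm)
                sample_counts[sid] = draw_counts(comp)
                meta_rows[sid] = {
                    "subject_id": subject, "site": site, "timepoint": tp,
                    "relative_time": launch_month[subject] + _TIMEPOINT_MONTHS[tp],
                }
                if site == "stool":
                    stool_latent[(subject, tp)] = logm - np.log(np.exp(logm).sum())
                if site in ("forehead", "forearm") and tp.startswith("FD"):
                    month = launch_month[subject] + _TIMEPOINT_MONTHS[tp]
                    skin_latent.setdefault((tp, subject), []).append(comp)

    # station surfaces: one set per inflight timepoint per crew "era";
    # surface composition mixes a resident profile with concurrent crew skin
    resident_comp = _softmax(site_logmean["_surface_resident"])
    fd_tps = [t for t in spec.timepoints if t.startswith("FD")]
    for subject in spec.subjects:
        for tp in fd_tps:
            month = launch_month[subject] + _TIMEPOINT_MONTHS[tp]
            skins = [c for (t, subj), comps in skin_latent.items()
                     if t == tp and subj == subject for c in comps]
            if not skins:
                continue
            crew_skin = np.mean(skins, axis=0)
            mix = (spec.surface_resident_weight * resident_comp
                   + (1 - spec.surface_resident_weight) * crew_skin)
            for site in spec.iss_sites:
                n += 1
                sid = f"s{n:04d}"
                sample_counts[sid] = draw_counts(mix)
                meta_rows[sid] = {
                    "subject_id": subject, "site": site, "timepoint": tp,
                    "relative_time": month,
                }

    counts = pd.DataFrame(sample_counts, index=taxa)

    # contaminants: low-level presence everywhere, strong in controls
    contam = spec.contaminant_taxa
    if contam:
        contam_rows = rng.poisson(0.3, size=(len(contam), counts.shape[1]))
        counts = pd.concat(
            [counts, pd.DataFrame(contam_rows, index=contam, columns=counts.columns)]
        )

    for ctrl_site, label in (("control_pcr", "ctlP"), ("control_kit", "ctlK")):
        sid = f"{label}01"
        col = np.zeros(len(counts), dtype=np.int64)
        for t in contam:
            lo, hi = spec.contaminant_control_reads
            col[counts.index.get_loc(t)] = rng.integers(lo, hi + 1)
        noise_idx = rng.choice(len(taxa), size=min(spec.control_noise_taxa, n_taxa),
                               replace=False)
        for i in noise_idx:
            col[i] = rng.integers(1, 5)  # below the 5-read contaminant rule
        counts[sid] = col
        meta_rows[sid] = {"subject_id": pd.NA, "site": ctrl_site,
                          "timepoint": "FD7", "relative_time": np.nan}

    meta = validate_metadata(pd.DataFrame.from_dict(meta_rows, orient="index"))
    table = OtuTable(counts.astype(np.int64), _taxonomy(spec))

    truth_rows = [
        {"kind": "contaminant", "target": t, "param": "", "value": np.nan}
        for t in contam
    ] + [
        {"kind": "stage_effect", "target": t, "param": st, "value": fc}
        for t, st, fc in spec.stage_effects
    ] + [
        {"kind": "convergence", "target": t, "param": "factor",
         "value": spec.convergence_factor}
        for t in spec.convergence_taxa
    ] + [
        {"kind": "coupling", "target": t, "param": a, "value": s}
        for a, t, s in spec.coupling
    ]
    truth = pd.DataFrame(truth_rows,
                         columns=["kind", "target", "param", "value"])

    stool_df = None
    if stool_latent:
        stool_df = pd.DataFrame(stool_latent, index=taxa).T
        stool_df.index.names = ["subject_id", "timepoint"]
    return Cohort(table, meta, truth, stool_df)


def generate_cytokine_panel(spec: CohortSpec, cohort: Cohort) -> pd.DataFrame:
    """Draw the plasma cytokine panel coupled to the cohort's stool taxa.

    Analyte log-concentration = baseline + planted session effects + subject
    intercept + sum of coupling strengths times the centered latent log
    relative abundance of the coupled taxon + noise.  Values below the
    analyte's detection limit are flagged censored with the concentration
    clamped to the limit.
    """
    rng = np.random.default_rng(np.random.default_rng(spec.seed).integers(2**31) + 1)
    latent = cohort.stool_log_ra
    for analyte, taxon, _ in spec.coupling:
        if analyte not in spec.analytes:
            raise ValueError(f"coupling to unknown analyte {analyte!r}")
        if latent is None or taxon not in latent.columns:
            raise ValueError(f"coupling to taxon absent from cohort: {taxon!r}")

    stage_fx = {(a, s): d for a, s, d in spec.cytokine_stage_effects}
    subj_int = {
        (s, a): rng.normal(0.0, spec.cytokine_subject_sd)
        for s in spec.subjects for a in spec.analytes
    }
    # center couplings over the analysis sessions so baselines stay meaningful
    centered: dict[str, pd.Series] = {}
    if latent is not None:
        for _, taxon, _ in spec.coupling:
            if taxon not in centered:
                col = latent[taxon]
                centered[taxon] = col - col.mean()

    rows = []
    for subject in spec.subjects:
        for session in CYTOKINE_SESSIONS:
            for analyte in spec.analytes:
                mu = spec.cytokine_baseline_log + subj_int[(subject, analyte)]
                mu += stage_fx.get((analyte, session), 0.0)
                for a, taxon, strength in spec.coupling:
                    if a != analyte:
                        continue
                    key = (subject, session)
                    if key in centered[taxon].index:
                        mu += strength * centered[taxon].loc[key]
                conc = float(np.exp(rng.normal(mu, spec.cytokine_noise_sd)))
                limit = spec.censor_limits.get(analyte, np.nan)
                censored = bool(np.isfinite(limit) and conc < limit)
                rows.append({
                    "subject_id": subject, "session": session, "analyte": analyte,
                    "concentration": limit if censored else conc,
                    "censored": censored,
                    "detection_limit": limit if np.isfinite(limit) else np.nan,
                })
    return validate_cytokines(pd.DataFrame(rows))
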