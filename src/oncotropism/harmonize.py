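"""Sample eligibility, variant/CNA quality control, and classification.

Heterogeneous panel cohorts can only be compared on what they share: samples
sequenced over full exonic regions, variants that survive a common QC
ladder, and genes covered by most panels.  This module applies those rules
and classifies metastatic samples into site sets and receptor/histology
subtypes for the downstream contrasts.

The variant filter ladder runs in a fixed order — in-sample duplicates →
depth → VAF → classification allow-list — so per-reason removal counts are
reproducible; cohort-wise mutation-count outliers are flagged in a separate
pass.  Records missing depth or VAF pass those filters: several source
cohorts do not report the fields, and missingness must not delete data.
"""

from __future__ import annotations

import math
import re
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .io import CnaRecord, MutationRecord, PanelDefinition, SampleRecord

#: MAF classes retained for analysis (protein-affecting variants).
VARIANT_CLASS_ALLOWLIST = frozenset(
    {
        "Frame_Shift_Del",
        "Frame_Shift_Ins",
        "In_Frame_Del",
        "In_Frame_Ins",
        "Missense_Mutation",
        "Nonsense_Mutation",
        "Nonstop_Mutation",
        "Splice_Region",
        "Splice_Site",
        "Translation_Start_Site",
    }
)


@dataclass(slots=True)
class QcConfig:
    """Tunable QC thresholds.

    ``min_depth``/``min_vaf`` are strict lower bounds: a record is removed
    when depth < 10 or VAF < 0.01 (records exactly at the bound are kept).
    ``panel_min_fraction`` defaults to 7/11 — a gene must be covered by at
    least that fraction of panels to enter the analysis.  ``outlier_k`` is
    the Tukey multiplier for cohort-wise mutation-count outliers.
    """

    min_depth: int = 10
    min_vaf: float = 0.01
    variant_class_allowlist: frozenset[str] = VARIANT_CLASS_ALLOWLIST
    outlier_rule: str = "iqr"  # "iqr" | "fixed"
    outlier_k: float = 3.0
    outlier_cutoff: float = math.inf  # used when outlier_rule == "fixed"
    panel_min_fraction: float = 7 / 11
    cna_keep_levels: frozenset[float] = frozenset({-2.0, 2.0})

    def __post_init__(self) -> None:
        if not 0.0 <= self.min_vaf <= 1.0:
            raise ValueError("min_vaf must lie in [0, 1]")
        if not self.variant_class_allowlist:
            raise ValueError("variant_class_allowlist must be non-empty")


@dataclass(slots=True)
class QcSummary:
    """Audit trail of one QC pass: removal counts by reason."""

    n_input: int = 0
    n_retained: int = 0
    removed: Counter = field(default_factory=Counter)
    excluded_samples: dict[str, str] = field(default_factory=dict)

    def to_rows(self) -> list[dict]:
        rows = [
            {"stage": "filter_variants", "reason": reason, "count": count}
            for reason, count in sorted(self.removed.items())
        ]
        rows.append(
            {"stage": "filter_variants", "reason": "retained", "count": self.n_retained}
        )
        return rows


# ---------------------------------------------------------------------------
# sample selection


def select_samples(
    samples: Sequence[SampleRecord],
    panels: Mapping[str, PanelDefinition],
    mode: str = "single_site",
) -> tuple[list[SampleRecord], dict[str, str]]:
    """Apply eligibility rules; returns kept samples and an exclusion log.

    ``single_site`` (default) keeps female (or unknown-sex) samples from
    full-exonic panels, excluding patients whose metastatic samples span
    more than one biopsy site — multiple biopsies of one patient would
    otherwise be double-counted.  ``multi_site`` inverts the last rule: it
    keeps exactly the patients with metastatic samples from two or more
    sites, for within-patient site comparisons.
    """
    if mode not in {"single_site", "multi_site"}:
        raise ValueError(f"unknown selection mode {mode!r}")
    exclusions: dict[str, str] = {}
    eligible: list[SampleRecord] = []
    for s in samples:
        if s.sex == "male":
            exclusions[s.sample_id] = "male"
            continue
        panel = panels.get(s.panel_id)
        if panel is not None and not panel.full_exonic:
            exclusions[s.sample_id] = "hotspot_only_panel"
            continue
        eligible.append(s)

    sites_per_patient: dict[str, set[str]] = {}
    for s in eligible:
        if s.tumor_type == "metastasis":
            sites_per_patient.setdefault(s.patient_id, set()).add(s.biopsy_site)

    kept: list[SampleRecord] = []
    for s in eligible:
        n_sites = len(sites_per_patient.get(s.patient_id, ()))
        if mode == "single_site" and n_sites > 1:
            exclusions[s.sample_id] = "multiple_metastatic_sites"
        elif mode == "multi_site" and n_sites < 2:
            exclusions[s.sample_id] = "fewer_than_two_metastatic_sites"
        else:
            kept.append(s)
    return kept, exclusions


# ---------------------------------------------------------------------------
# variant QC


def filter_variants(
    records: Sequence[MutationRecord], qc: QcConfig | None = None
) -> tuple[list[MutationRecord], QcSummary]:
    """Run the fixed-order variant QC ladder.

    Order: in-sample duplicates (same sample, chrom, start, end, ref, alt;
    protein annotation is ignored for identity) → depth < ``min_depth`` →
    VAF < ``min_vaf`` → classification outside the allow-list.  Removal
    counts by reason plus the retained count always add up to the input
    count.
    """
    qc = qc or QcConfig()
    summary = QcSummary(n_input=len(records))
    seen: set[tuple] = set()
    kept: list[MutationRecord] = []
    for rec in records:
        key = (
            rec.sample_id,
            rec.chrom,
            rec.pos_start,
            rec.pos_end,
            rec.ref_allele,
            rec.alt_allele,
        )
        if key in seen:
            summary.removed["duplicate"] += 1
            continue
        seen.add(key)
        if rec.depth is not None and rec.depth < qc.min_depth:
            summary.removed["low_depth"] += 1
            continue
        if rec.vaf is not None and rec.vaf < qc.min_vaf:
            summary.removed["low_vaf"] += 1
            continue
        if rec.variant_classification not in qc.variant_class_allowlist:
            summary.removed["classification"] += 1
            continue
        kept.append(rec)
    summary.n_retained = len(kept)
    return kept, summary


def flag_outlier_samples(
    records: Sequence[MutationRecord], qc: QcConfig | None = None
) -> set[str]:
    """Identify hypermutated outlier samples, cohort by cohort.

    Under the ``iqr`` rule a sample is an outlier when its variant count
    exceeds Q3 + k·IQR of its cohort's per-sample counts (linear-interpolation
    quartiles, default k = 3), computed over samples with at least one
    variant.  Counts are integers, so the IQR is floored at one mutation:
    on sparse panels most samples carry exactly one variant and a zero IQR
    would otherwise flag every second variant as an outlier.  Cohorts with
    fewer than 4 sequenced samples are skipped — quartiles would be
    meaningless.
    """
    qc = qc or QcConfig()
    per_cohort: dict[str, Counter] = {}
    for rec in records:
        per_cohort.setdefault(rec.cohort, Counter())[rec.sample_id] += 1

    outliers: set[str] = set()
    for cohort, counts in per_cohort.items():
        values = np.array(sorted(counts.values()), dtype=float)
        if qc.outlier_rule == "fixed":
            bound = qc.outlier_cutoff
        else:
            if len(values) < 4:
                continue
            q1, q3 = np.percentile(values, [25, 75], method="linear")
            bound = q3 + qc.outlier_k * max(q3 - q1, 1.0)
        outliers.update(s for s, n in counts.items() if n > bound)
    return outliers


def remove_outlier_samples(
    records: Sequence[MutationRecord], qc: QcConfig | None = None
) -> tuple[list[MutationRecord], set[str]]:
    """Drop every variant of cohort-wise outlier samples."""
    outliers = flag_outlier_samples(records, qc)
    kept = [r for r in records if r.sample_id not in outliers]
    return kept, outliers


# ---------------------------------------------------------------------------
# gene / CNA selection


def select_concurrent_genes(
    panels: Mapping[str, PanelDefinition] | Iterable[PanelDefinition],
    min_fraction: float = 7 / 11,
) -> list[str]:
    """Genes covered by at least ``min_fraction`` of the panels, sorted.

    The threshold is the smallest integer panel count ≥ min_fraction × n
    (computed with a tolerance so 7/11 of 11 panels is exactly 7).
    Monotone: raising ``min_fraction`` never adds genes.
    """
    defs = list(panels.values()) if isinstance(panels, Mapping) else list(panels)
    if not defs:
        raise ValueError("no panels supplied")
    threshold = math.ceil(min_fraction * len(defs) - 1e-9)
    counts = Counter(g for p in defs for g in p.genes)
    return sorted(g for g, n in counts.items() if n >= threshold)


def filter_cna(
    records: Sequence[CnaRecord], qc: QcConfig | None = None
) -> list[CnaRecord]:
    """Keep only high-confidence CNA levels (default ±2).

    Low-level gains/losses (±1) and the MSK-style −1.5 shallow deletion are
    removed; categorical labels were already mapped to ±2 at read time.
    """
    qc = qc or QcConfig()
    return [r for r in records if r.level in qc.cna_keep_levels]


# ---------------------------------------------------------------------------
# site sets and subtypes

SPECIFIC_DISTANT_SITES = (
    "liver",
    "lymph_nodes",
    "bone",
    "chest_wall_thorax",
    "skin",
    "lung",
    "soft",
    "pleura",
    "brain",
    "ovary",
    "peritoneum",
    "other_distant",
)


@dataclass(slots=True)
class SiteSetMap:
    """Ordered pattern → site-set matcher for free-text biopsy sites.

    ``local_patterns`` are checked first (ipsilateral breast / chest wall
    relapse and regional lymph nodes annotated as local recurrence); the
    remaining patterns assign one specific distant site.  Unmatched sites
    fall into ``other_distant``.
    """

    local_patterns: tuple[str, ...] = (
        r"local.?recurrence",
        r"ipsilateral breast",
        r"sync_local_lymph_node",
        r"regional lymph nodes",
        r"contralateral breast",
    )
    site_patterns: tuple[tuple[str, str], ...] = (
        (r"liver|hepat", "liver"),
        (r"lymph", "lymph_nodes"),
        (r"bone|osseous|spine|vertebra", "bone"),
        (r"chest wall|thorax|thoracic|mediastin", "chest_wall_thorax"),
        (r"skin|cutaneous", "skin"),
        (r"lung|pulmonary", "lung"),
        (r"soft tissue|soft|muscle", "soft"),
        (r"pleura", "pleura"),
        (r"brain|cns|central nervous", "brain"),
        (r"ovary|ovarian", "ovary"),
        (r"peritoneum|peritoneal|omentum", "peritoneum"),
    )


DEFAULT_SITE_MAP = SiteSetMap()


def classify_site_set(
    sample: SampleRecord, site_map: SiteSetMap | None = None
) -> frozenset[str]:
    """Resolve a metastatic sample's biopsy site into site-set labels.

    Every metastatic sample belongs to ``pan`` and then either ``local`` or
    ``distant`` plus exactly one specific distant set; unmatched site text
    falls through to ``other_distant``.
    """
    if sample.tumor_type != "metastasis":
        raise ValueError("site sets are defined for metastatic samples only")
    site_map = site_map or DEFAULT_SITE_MAP
    text = sample.biopsy_site.lower()
    for pattern in site_map.local_patterns:
        if re.search(pattern, text):
            return frozenset({"pan", "local"})
    for pattern, site_set in site_map.site_patterns:
        if re.search(pattern, text):
            return frozenset({"pan", "distant", site_set})
    return frozenset({"pan", "distant", "other_distant"})


@dataclass(slots=True)
class Dataset:
    """A bundle of harmonized inputs: samples, variants, CNAs, panels."""

    samples: list[SampleRecord] = field(default_factory=list)
    mutations: list[MutationRecord] = field(default_factory=list)
    cnas: list[CnaRecord] = field(default_factory=list)
    panels: dict[str, PanelDefinition] = field(default_factory=dict)

    def site_sets(self, site_map: SiteSetMap | None = None) -> dict[str, frozenset[str]]:
        """Site-set labels per metastatic sample id."""
        return {
            s.sample_id: classify_site_set(s, site_map)
            for s in self.samples
            if s.tumor_type == "metastasis"
        }


RECEPTOR_SUBTYPES = ("HR+/HER2-", "HR+/HER2+", "HR-/HER2+", "Triple-negative")


def classify_subtype(sample: SampleRecord) -> dict[str, object]:
    """Receptor and histology subtype labels for one sample.

    A sample annotated only as HER2-positive (HR status NA) contributes to
    both HER2+ receptor subtypes; any other missing receptor yields no
    receptor subtype.  Histology passes through the controlled vocabulary.
    """
    hr, her2 = sample.hr_status, sample.her2_status
    receptor: tuple[str, ...]
    if hr == "pos" and her2 == "neg":
        receptor = ("HR+/HER2-",)
    elif hr == "pos" and her2 == "pos":
        receptor = ("HR+/HER2+",)
    elif hr == "neg" and her2 == "pos":
        receptor = ("HR-/HER2+",)
    elif hr == "neg" and her2 == "neg":
        receptor = ("Triple-negative",)
    elif hr == "NA" and her2 == "pos":
        receptor = ("HR+/HER2+", "HR-/HER2+")
    else:
        receptor = ()
    return {"receptor": receptor, "histology": sample.histology}
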