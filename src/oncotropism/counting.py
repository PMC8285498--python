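"""Carrier counting: from QC-filtered records to stratified 2×2 tables.

Carrier status is binary at the sample level — a sample either harbors a
qualifying alteration of a feature or it does not; multiple variants in the
same gene count once.  Features are gene-level (any allow-listed SNV/indel,
an amplification, or a deep deletion) or variant-level (a specific amino-acid
change, or the pooled truncating class "Trunc").

Every comparison the pipeline runs (metastasis vs primary, one metastatic
site vs the other sites, treatment contrasts) reduces to per-cohort 2×2
carrier tables, assembled here.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, NamedTuple, Sequence

from .io import CnaRecord, MutationRecord, SampleRecord

#: MAF classes counted as truncating (protein-terminating) events.
TRUNCATING_CLASSES = frozenset(
    {"Nonsense_Mutation", "Splice_Site", "Frame_Shift_Del", "Frame_Shift_Ins"}
)

MUTATION_TYPES = ("snv_indel", "amplification", "deletion")


@dataclass(frozen=True, slots=True)
class CarrierKey:
    """A countable feature: a gene, or a specific variant within a gene.

    ``variant`` is an amino-acid change in HGVSp-short form without the
    ``p.`` prefix (e.g. ``"D538G"``) or the literal ``"Trunc"`` for the
    pooled truncating class; variant keys are only meaningful for SNV/indel
    features.
    """

    gene: str
    mutation_type: str = "snv_indel"
    variant: str | None = None

    def __post_init__(self) -> None:
        if self.mutation_type not in MUTATION_TYPES:
            raise ValueError(f"unknown mutation_type {self.mutation_type!r}")
        if self.variant is not None and self.mutation_type != "snv_indel":
            raise ValueError("variant keys are only valid for snv_indel features")

    @property
    def feature(self) -> str:
        if self.variant is None:
            return self.gene
        return f"{self.gene} {self.variant}"


class CohortStratum(NamedTuple):
    """One cohort's 2×2 cells: (case carrier, case non, control carrier, control non)."""

    cohort: str
    a: int
    b: int
    c: int
    d: int


@dataclass(slots=True)
class StratifiedContingency:
    """Per-cohort 2×2 carrier tables for one feature × one comparison."""

    feature: CarrierKey
    comparison: str
    strata: list[CohortStratum] = field(default_factory=list)
    untestable: bool = False

    def collapse(self) -> tuple[int, int, int, int]:
        """Pool cells over cohorts (for descriptive totals only)."""
        a = sum(s.a for s in self.strata)
        b = sum(s.b for s in self.strata)
        c = sum(s.c for s in self.strata)
        d = sum(s.d for s in self.strata)
        return a, b, c, d

    def to_rows(self) -> list[dict]:
        return [
            {
                "feature": self.feature.feature,
                "mutation_type": self.feature.mutation_type,
                "comparison": self.comparison,
                "cohort": s.cohort,
                "a": s.a,
                "b": s.b,
                "c": s.c,
                "d": s.d,
            }
            for s in self.strata
        ]


def normalize_protein_change(protein_change: str) -> str:
    """Strip the leading ``p.`` of an HGVSp-short annotation."""
    text = protein_change.strip()
    return text[2:] if text.startswith("p.") else text


def _qualifies(rec: MutationRecord, key: CarrierKey) -> bool:
    if rec.gene != key.gene:
        return False
    if key.variant is None:
        return True
    if key.variant == "Trunc":
        return rec.variant_classification in TRUNCATING_CLASSES
    return normalize_protein_change(rec.protein_change) == key.variant


def carrier_status(
    records: Iterable[MutationRecord | CnaRecord],
    sample_id: str,
    key: CarrierKey,
) -> bool:
    """True iff the sample carries ≥1 qualifying record for the key."""
    for rec in records:
        if rec.sample_id != sample_id:
            continue
        if key.mutation_type == "snv_indel":
            if isinstance(rec, MutationRecord) and _qualifies(rec, key):
                return True
        elif isinstance(rec, CnaRecord) and rec.gene == key.gene:
            if key.mutation_type == "amplification" and rec.level == 2:
                return True
            if key.mutation_type == "deletion" and rec.level == -2:
                return True
    return False


class CarrierIndex:
    """Sample-id sets per feature, for repeated carrier lookups.

    Indexes gene-level SNV/indel carriers, per-amino-acid-change carriers,
    pooled truncating carriers, and CNA amplification/deletion carriers in
    one pass over the records.
    """

    def __init__(
        self,
        mutations: Sequence[MutationRecord] = (),
        cnas: Sequence[CnaRecord] = (),
    ) -> None:
        self.gene: dict[str, set[str]] = {}
        self.variant: dict[tuple[str, str], set[str]] = {}
        self.trunc: dict[str, set[str]] = {}
        self.amp: dict[str, set[str]] = {}
        self.dele: dict[str, set[str]] = {}
        self.cna_cohorts: set[str] = set()
        for rec in mutations:
            self.gene.setdefault(rec.gene, set()).add(rec.sample_id)
            if rec.variant_classification in TRUNCATING_CLASSES:
                self.trunc.setdefault(rec.gene, set()).add(rec.sample_id)
            elif rec.protein_change:
                aa = normalize_protein_change(rec.protein_change)
                self.variant.setdefault((rec.gene, aa), set()).add(rec.sample_id)
        for rec in cnas:
            self.cna_cohorts.add(rec.cohort)
            if rec.level == 2:
                self.amp.setdefault(rec.gene, set()).add(rec.sample_id)
            elif rec.level == -2:
                self.dele.setdefault(rec.gene, set()).add(rec.sample_id)

    def carriers(self, key: CarrierKey) -> set[str]:
        if key.mutation_type == "amplification":
            return self.amp.get(key.gene, set())
        if key.mutation_type == "deletion":
            return self.dele.get(key.gene, set())
        if key.variant is None:
            return self.gene.get(key.gene, set())
        if key.variant == "Trunc":
            return self.trunc.get(key.gene, set())
        return self.variant.get((key.gene, key.variant), set())


Grouping = Callable[[SampleRecord], str | None]


def build_contingency(
    records: Sequence[MutationRecord] | CarrierIndex,
    samples: Sequence[SampleRecord],
    key: CarrierKey,
    comparison: str,
    grouping: Grouping,
    cnas: Sequence[CnaRecord] = (),
) -> StratifiedContingency:
    """Assemble per-cohort 2×2 carrier tables for one feature.

    ``grouping`` maps each sample to ``"case"``, ``"control"`` or ``None``
    (excluded).  A cohort contributes a stratum only when it has at least
    one case and one control sample; for CNA features, only cohorts with
    any CNA data contribute.  Strata are sorted by cohort label, and each
    eligible sample lands in exactly one cell, so per-stratum cell sums
    equal the cohort's eligible sample count.  A comparison with zero
    eligible strata is flagged ``untestable``.
    """
    index = records if isinstance(records, CarrierIndex) else CarrierIndex(records, cnas)
    carriers = index.carriers(key)

    per_cohort: dict[str, list[int]] = {}
    for s in samples:
        group = grouping(s)
        if group is None:
            continue
        if key.mutation_type != "snv_indel" and s.cohort not in index.cna_cohorts:
            continue
        cells = per_cohort.setdefault(s.cohort, [0, 0, 0, 0])
        carrier = s.sample_id in carriers
        if group == "case":
            cells[0 if carrier else 1] += 1
        elif group == "control":
            cells[2 if carrier else 3] += 1
        else:
            raise ValueError(f"grouping returned {group!r}")

    strata = [
        CohortStratum(cohort, *cells)
        for cohort, cells in sorted(per_cohort.items())
        if (cells[0] + cells[1]) > 0 and (cells[2] + cells[3]) > 0
    ]
    return StratifiedContingency(
        feature=key,
        comparison=comparison,
        strata=strata,
        untestable=not strata,
    )


def mbc_vs_pbc_grouping(site_sets: Mapping[str, frozenset[str]] | None = None,
                        site_set: str | None = None) -> Grouping:
    """Case = metastatic samples (optionally of one site set), control = primary."""

    def group(s: SampleRecord) -> str | None:
        if s.tumor_type == "primary":
            return "control"
        if site_set is not None:
            labels = (site_sets or {}).get(s.sample_id, frozenset())
            return "case" if site_set in labels else None
        return "case"

    return group


def site_vs_other_grouping(
    site_sets: Mapping[str, frozenset[str]],
    site_set: str,
    cohort_subset: frozenset[str] | None = None,
    within: str = "distant",
) -> Grouping:
    """Case = metastatic samples of one site set, control = other metastatic sites.

    Restricted to cohorts with per-sample site resolution when
    ``cohort_subset`` is given; by default only distant-metastasis samples
    with a resolvable specific site enter either arm.
    """

    def group(s: SampleRecord) -> str | None:
        if s.tumor_type != "metastasis":
            return None
        if cohort_subset is not None and s.cohort not in cohort_subset:
            return None
        labels = site_sets.get(s.sample_id, frozenset())
        if within and within not in labels and site_set not in labels:
            return None
        return "case" if site_set in labels else "control"

    return group


# ---------------------------------------------------------------------------
# multi-site patients


@dataclass(slots=True)
class MultiSitePatientTable:
    """Per-patient, per-gene carrier status across ≥2 biopsied metastatic sites."""

    #: patient_id → gene → {site_set: carrier?}
    patients: dict[str, dict[str, dict[str, bool]]] = field(default_factory=dict)
    #: gene → (concordant site-pair count, discordant site-pair count)
    pair_summary: dict[str, tuple[int, int]] = field(default_factory=dict)


def multi_site_table(
    records: Sequence[MutationRecord] | CarrierIndex,
    samples: Sequence[SampleRecord],
    genes: Sequence[str],
    site_sets: Mapping[str, frozenset[str]],
) -> MultiSitePatientTable:
    """Carrier-status table for patients biopsied at multiple metastatic sites.

    For each patient with metastatic samples from ≥2 site sets, records
    carrier status per gene at each site and summarizes concordant vs
    discordant site pairs per gene across patients.
    """
    index = records if isinstance(records, CarrierIndex) else CarrierIndex(records)

    by_patient: dict[str, list[SampleRecord]] = {}
    for s in samples:
        if s.tumor_type == "metastasis":
            by_patient.setdefault(s.patient_id, []).append(s)

    table = MultiSitePatientTable()
    pair_counts = {g: [0, 0] for g in genes}
    for patient_id, pat_samples in sorted(by_patient.items()):
        site_of: dict[str, str] = {}
        for s in pat_samples:
            specific = [
                lab
                for lab in site_sets.get(s.sample_id, frozenset())
                if lab not in {"pan", "local", "distant"}
            ]
            label = specific[0] if specific else ("local" if "local" in site_sets.get(s.sample_id, frozenset()) else "")
            if label:
                site_of[s.sample_id] = label
        if len(set(site_of.values())) < 2:
            continue
        gene_rows: dict[str, dict[str, bool]] = {}
        for gene in genes:
            carriers = index.carriers(CarrierKey(gene))
            per_site: dict[str, bool] = {}
            for sid, site in site_of.items():
                per_site[site] = per_site.get(site, False) or (sid in carriers)
            gene_rows[gene] = per_site
            sites = sorted(per_site)
            for i in range(len(sites)):
                for j in range(i + 1, len(sites)):
                    same = per_site[sites[i]] == per_site[sites[j]]
                    pair_counts[gene][0 if same else 1] += 1
        table.patients[patient_id] = gene_rows
    table.pair_summary = {g: (c[0], c[1]) for g, c in pair_counts.items()}
    return table
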