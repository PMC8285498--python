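"""Knowledge-guided candidate driver-mutation calling.

Oncogenes (OGs) accumulate recurrent missense mutations at hotspot protein
positions; tumor suppressor genes (TSGs) accumulate truncating mutations
(nonsense, splice-site, frameshift indels).  Within the metastasis-enriched
gene list, candidate driver mutations are variants matching their gene's
pattern, scored for functional impact (the integer Func score) and tested
for enrichment vs primaries and for metastatic-site preference.

Func scoring: an OG missense variant sums per-tool impact points from three
missense predictors (high/medium impact 2, low 1, neutral or missing 0)
plus 1 when it sits at a hotspot position; a TSG truncation scores a base
of 4 plus literature-evidence points (strong 2, weak 1).  Variants with
Func score ≥ 5 and enough carriers are eligible.  The point table is
config-overridable.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .counting import (
    CarrierIndex,
    CarrierKey,
    TRUNCATING_CLASSES,
    build_contingency,
    mbc_vs_pbc_grouping,
    normalize_protein_change,
    site_vs_other_grouping,
)
from .io import MutationRecord
from .pipeline import AnalysisPlan, PreparedData, SPECIFIC_DISTANT_SITES
from .stats import (
    MetaResult,
    RegressionResult,
    bh_fdr,
    finalize_meta_family,
    logistic_from_contingency,
    meta_analyze,
)

ROLES = ("oncogene", "tsg", "both", "none")


@dataclass(frozen=True, slots=True)
class GeneRole:
    gene: str
    role: str

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ValueError(f"unknown role {self.role!r}")


def classify_role(gene: str, role_table: Mapping[str, str]) -> GeneRole:
    """Look up a gene's cancer-gene role; unannotated genes get ``none``
    and are discarded from driver analysis."""
    return GeneRole(gene, role_table.get(gene, "none"))


def is_truncating(variant_classification: str, include_splice_region: bool = False) -> bool:
    """True for protein-truncating classes (nonsense, splice-site,
    frameshift indels); splice-region variants only when opted in."""
    if include_splice_region and variant_classification == "Splice_Region":
        return True
    return variant_classification in TRUNCATING_CLASSES


_POSITION_RE = re.compile(r"^[A-Za-z*]{0,3}?(\d+)")


def parse_protein_position(protein_change: str) -> int | None:
    """Protein position of an HGVSp-short change (p.D538G → 538)."""
    text = normalize_protein_change(protein_change)
    match = _POSITION_RE.match(text)
    return int(match.group(1)) if match else None


def is_hotspot(record: MutationRecord, hotspot_table: Mapping[str, set[int]]) -> bool:
    """True iff a non-truncating variant's protein position is a known
    hotspot of its gene (position match only, not exact substitution)."""
    if is_truncating(record.variant_classification):
        return False
    pos = parse_protein_position(record.protein_change)
    if pos is None:
        return False
    return pos in hotspot_table.get(record.gene, set())


# ---------------------------------------------------------------------------
# Func score


@dataclass(slots=True)
class FuncScoreConfig:
    """Point table for the Func score (all values overridable)."""

    impact_points: Mapping[str, int] = field(
        default_factory=lambda: {"high": 2, "medium": 2, "low": 1, "neutral": 0}
    )
    tool_impacts: Mapping[str, Mapping[str, str]] = field(
        default_factory=lambda: {
            "mutation_assessor": {
                "high": "high",
                "medium": "medium",
                "low": "low",
                "neutral": "neutral",
            },
            "polyphen2": {
                "probably_damaging": "high",
                "possibly_damaging": "low",
                "benign": "neutral",
            },
            "sift": {"deleterious": "high", "tolerated": "neutral"},
        }
    )
    hotspot_bonus: int = 1
    truncation_base: int = 4
    evidence_points: Mapping[str, int] = field(
        default_factory=lambda: {"strong": 2, "weak": 1, "none": 0}
    )
    threshold: int = 5
    #: "more than two carriers": ≥3 by the strict reading (config ≥2 allowed).
    min_carriers: int = 3


def func_score(
    pattern: str,
    annotation: Mapping[str, str] | None,
    hotspot: bool = False,
    config: FuncScoreConfig | None = None,
) -> int:
    """Integer Func score for one candidate variant.

    ``pattern`` is ``"hotspot"`` (OG missense: per-tool points + hotspot
    bonus) or ``"truncating"`` (TSG: truncation base + evidence points).
    Missing annotations contribute zero.
    """
    cfg = config or FuncScoreConfig()
    annotation = annotation or {}
    if pattern == "truncating":
        evidence = str(annotation.get("tsg_evidence", "none")).lower()
        return cfg.truncation_base + cfg.evidence_points.get(evidence, 0)
    if pattern != "hotspot":
        raise ValueError(f"unknown pattern {pattern!r}")
    score = cfg.hotspot_bonus if hotspot else 0
    for tool, category_map in cfg.tool_impacts.items():
        category = str(annotation.get(tool, "")).lower()
        impact = category_map.get(category)
        if impact is not None:
            score += cfg.impact_points.get(impact, 0)
    return score


# ---------------------------------------------------------------------------
# table readers


def read_roles(path: str | Path) -> dict[str, str]:
    frame = pd.read_csv(path, sep="\t", dtype=str)
    if not {"gene", "role"} <= set(frame.columns):
        raise ValueError("role table requires gene and role columns")
    table = {}
    for row in frame.itertuples(index=False):
        role = str(row.role).strip().lower()
        if role not in ROLES:
            raise ValueError(f"unknown role {role!r} for {row.gene}")
        table[str(row.gene).strip()] = role
    return table


def read_hotspots(path: str | Path) -> dict[str, set[int]]:
    frame = pd.read_csv(path, sep="\t", dtype=str)
    if not {"gene", "position"} <= set(frame.columns):
        raise ValueError("hotspot table requires gene and position columns")
    table: dict[str, set[int]] = {}
    for row in frame.itertuples(index=False):
        table.setdefault(str(row.gene).strip(), set()).add(int(row.position))
    return table


def read_annotations(path: str | Path) -> dict[str, dict[str, str]]:
    """Per-variant functional annotations, keyed ``GENE:AAchange`` or
    ``GENE:Trunc`` (e.g. ``ESR1:D538G``)."""
    frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if "variant" not in frame.columns:
        raise ValueError("annotation table requires a variant column")
    table: dict[str, dict[str, str]] = {}
    for row in frame.itertuples(index=False):
        row = dict(zip(frame.columns, row))
        key = str(row.pop("variant")).strip()
        table[key] = {k: str(v).strip() for k, v in row.items() if str(v).strip()}
    return table


# ---------------------------------------------------------------------------
# calling


@dataclass(slots=True)
class DriverMutationCall:
    """One candidate driver mutation with its eligibility and statistics."""

    key: CarrierKey
    role: str
    pattern: str  # "hotspot" | "truncating"
    func_score: int
    carriers: int
    eligible: bool
    vs_pbc: MetaResult | None = None
    site_preference: dict[str, RegressionResult] = field(default_factory=dict)

    def to_row(self, kind: str = "driver") -> dict:
        top_site, top = "", None
        for site, fit in self.site_preference.items():
            if fit.carrier is None or fit.q is None:
                continue
            if top is None or fit.q < top.q:
                top_site, top = site, fit
        return {
            "variant": self.key.feature,
            "gene": self.key.gene,
            "role": self.role,
            "pattern": self.pattern,
            "func_score": self.func_score,
            "carriers": self.carriers,
            "eligible": int(self.eligible),
            "vs_pbc_or": self.vs_pbc.pooled.or_value
            if self.vs_pbc and self.vs_pbc.pooled
            else "",
            "vs_pbc_q": self.vs_pbc.q if self.vs_pbc and self.vs_pbc.q is not None else "",
            "top_site": top_site,
            "top_site_or": top.carrier.or_value if top else "",
            "top_site_q": top.q if top else "",
        }


def _candidate_keys(
    prep: PreparedData,
    genes: Sequence[str],
    role_table: Mapping[str, str],
    hotspots: Mapping[str, set[int]],
) -> list[tuple[CarrierKey, str, str, bool]]:
    """Enumerate (key, role, pattern, is_hotspot) candidates per gene.

    OG-pattern candidates are the distinct amino-acid changes observed at
    hotspot positions; the TSG pattern pools all truncations of a gene
    under one ``Trunc`` key.  Collapsing by amino-acid change can only
    partition a gene's carriers, never exceed them.
    """
    candidates: list[tuple[CarrierKey, str, str, bool]] = []
    for gene in genes:
        role = classify_role(gene, role_table).role
        if role == "none":
            continue
        if role in ("oncogene", "both"):
            positions = hotspots.get(gene, set())
            seen: set[str] = set()
            for (g, aa), _samples in prep.index.variant.items():
                if g != gene or aa in seen:
                    continue
                seen.add(aa)
                match = _POSITION_RE.match(aa)
                if match and int(match.group(1)) in positions:
                    candidates.append((CarrierKey(gene, variant=aa), role, "hotspot", True))
        if role in ("tsg", "both"):
            if prep.index.trunc.get(gene):
                candidates.append((CarrierKey(gene, variant="Trunc"), role, "truncating", False))
    return candidates


def call_driver_mutations(
    prep: PreparedData,
    enriched_genes: Sequence[str],
    role_table: Mapping[str, str],
    hotspots: Mapping[str, set[int]],
    annotations: Mapping[str, Mapping[str, str]],
    plan: AnalysisPlan | None = None,
    config: FuncScoreConfig | None = None,
) -> list[DriverMutationCall]:
    """Score and test candidate driver mutations within enriched genes.

    Eligible candidates (Func score ≥ threshold, carriers ≥ min) are
    meta-analyzed vs primaries (FDR within the candidate family) and
    tested for site preference by cohort-adjusted regression per specific
    metastatic site; site-preference p-values form their own family.
    """
    plan = plan or AnalysisPlan()
    cfg = config or FuncScoreConfig()
    mbc_ids = {s.sample_id for s in prep.samples if s.tumor_type == "metastasis"}

    calls: list[DriverMutationCall] = []
    for key, role, pattern, hot in _candidate_keys(prep, enriched_genes, role_table, hotspots):
        annotation = annotations.get(f"{key.gene}:{key.variant}")
        score = func_score(pattern, annotation, hotspot=hot, config=cfg)
        carriers = len(prep.index.carriers(key) & mbc_ids)
        calls.append(
            DriverMutationCall(
                key=key,
                role=role,
                pattern=pattern,
                func_score=score,
                carriers=carriers,
                eligible=score >= cfg.threshold and carriers >= cfg.min_carriers,
            )
        )

    eligible = [c for c in calls if c.eligible]
    grouping = mbc_vs_pbc_grouping()
    metas = []
    for call in eligible:
        cont = build_contingency(prep.index, prep.samples, call.key, "mbc_vs_pbc", grouping)
        call.vs_pbc = meta_analyze(cont)
        metas.append(call.vs_pbc)
    finalize_meta_family(metas, het_gate=plan.het_gate)

    counts: dict[str, int] = {}
    for labels in prep.site_sets.values():
        for lab in labels:
            counts[lab] = counts.get(lab, 0) + 1
    sites = [
        s
        for s in SPECIFIC_DISTANT_SITES
        if s != "other_distant" and counts.get(s, 0) >= plan.min_site_n
    ]
    fits: list[RegressionResult] = []
    for call in eligible:
        for site in sites:
            grouping_site = site_vs_other_grouping(prep.site_sets, site, plan.site_cohorts)
            cont = build_contingency(
                prep.index, prep.samples, call.key, f"{site}_vs_other_sites", grouping_site
            )
            if cont.untestable:
                continue
            fit = logistic_from_contingency(cont)
            call.site_preference[site] = fit
            if fit.converged and fit.carrier is not None:
                fits.append(fit)
    if fits:
        qs = bh_fdr([f.carrier.p for f in fits])
        for f, q in zip(fits, qs):
            f.q = float(q)
    return calls
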