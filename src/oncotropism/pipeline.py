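"""Orchestration of the three enrichment analyses.

1. *Pan-metastasis*: for each gene × mutation type, carrier frequency in
   metastatic vs primary samples — stratified meta-analysis across cohorts,
   confirmed by cohort-adjusted logistic regression.
2. *Site-specific*: stage 1 compares each metastatic site set against
   primaries; stage 2 compares, for stage-1-significant genes, the site
   against all other metastatic sites (cohort-adjusted logistic regression
   on the site-resolvable cohort subset).  A gene is called organotropic
   for a site only when both stages pass the q threshold (the
   dual-criterion call); subtype-adjusted refits then probe whether the
   preference survives histology and receptor covariates.
3. *Treatment contrasts*: treatment-naive primaries vs de novo metastases
   and vs post-treatment metastases, separating metastasis-associated from
   treatment-selected alterations.

All model fitting is delegated to :mod:`oncotropism.stats`; this module
owns grouping, family bookkeeping for FDR, and report emission.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

from . import io as io_formats
from .counting import (
    CarrierIndex,
    CarrierKey,
    build_contingency,
    mbc_vs_pbc_grouping,
    site_vs_other_grouping,
)
from .harmonize import (
    Dataset,
    QcConfig,
    QcSummary,
    SPECIFIC_DISTANT_SITES,
    SiteSetMap,
    classify_site_set,
    classify_subtype,
    filter_cna,
    filter_variants,
    remove_outlier_samples,
    select_concurrent_genes,
    select_samples,
)
from .io import SampleRecord
from .stats import (
    MetaResult,
    RegressionResult,
    bh_fdr,
    fisher_exact_2x2,
    finalize_meta_family,
    logistic_fit,
    logistic_from_contingency,
    meta_analyze,
)

#: Site sets tested in the site-specific analysis: the two broad classes
#: plus the named specific distant sites.  ``other_distant`` is a catch-all
#: and is excluded from per-site testing by default; ``pan`` is the
#: pan-metastasis analysis itself.
DEFAULT_SITE_SETS = ("local", "distant") + tuple(
    s for s in SPECIFIC_DISTANT_SITES if s != "other_distant"
)


@dataclass(slots=True)
class AnalysisPlan:
    """What to test, at which thresholds, on which cohort subsets."""

    genes: tuple[str, ...] | None = None  # None → concurrent-panel selection
    mutation_types: tuple[str, ...] = ("snv_indel",)
    site_sets: tuple[str, ...] = DEFAULT_SITE_SETS
    q_threshold: float = 0.05
    min_site_n: int = 20
    #: Cohorts with per-sample site resolution, used for site-vs-other
    #: contrasts; None = all cohorts.
    site_cohorts: frozenset[str] | None = None
    het_gate: str = "fdr"  # heterogeneity gate on FDR-adjusted p ("raw" optional)
    stage2_all_genes: bool = False
    panel_min_fraction: float = 7 / 11

    def __post_init__(self) -> None:
        if not 0.0 < self.q_threshold < 1.0:
            raise ValueError("q_threshold must lie in (0, 1)")


@dataclass(slots=True)
class PreparedData:
    """QC-filtered, classified data ready for counting and testing."""

    samples: list[SampleRecord]
    index: CarrierIndex
    genes: list[str]
    site_sets: dict[str, frozenset[str]]
    qc_summary: QcSummary
    sample_exclusions: dict[str, str]
    outlier_samples: set[str]
    n_mutations: int = 0
    n_cnas: int = 0


def prepare(
    dataset: Dataset,
    qc: QcConfig | None = None,
    mode: str = "single_site",
    site_map: SiteSetMap | None = None,
) -> PreparedData:
    """Run sample selection, the variant QC ladder, outlier exclusion and
    CNA filtering; classify metastatic sites; index carriers."""
    qc = qc or QcConfig()
    samples, exclusions = select_samples(dataset.samples, dataset.panels, mode)
    sample_ids = {s.sample_id for s in samples}

    records = [m for m in dataset.mutations if m.sample_id in sample_ids]
    records, summary = filter_variants(records, qc)
    records, outliers = remove_outlier_samples(records, qc)
    summary.removed["outlier_sample_variants"] += summary.n_retained - len(records)
    summary.n_retained = len(records)
    for sid in outliers:
        summary.excluded_samples[sid] = "outlier"

    cnas = filter_cna([c for c in dataset.cnas if c.sample_id in sample_ids], qc)
    genes = (
        select_concurrent_genes(dataset.panels, qc.panel_min_fraction)
        if dataset.panels
        else sorted({m.gene for m in records})
    )
    sites = {
        s.sample_id: classify_site_set(s, site_map)
        for s in samples
        if s.tumor_type == "metastasis"
    }
    return PreparedData(
        samples=samples,
        index=CarrierIndex(records, cnas),
        genes=genes,
        site_sets=sites,
        qc_summary=summary,
        sample_exclusions=exclusions,
        outlier_samples=outliers,
        n_mutations=len(records),
        n_cnas=len(cnas),
    )


# ---------------------------------------------------------------------------
# pan-metastasis


@dataclass(slots=True)
class PanResult:
    """Per-feature meta + logistic results and the called gene list."""

    meta: list[MetaResult] = field(default_factory=list)
    logistic: list[RegressionResult] = field(default_factory=list)
    enriched: list[tuple[str, str]] = field(default_factory=list)  # (gene, mutation_type)


def run_pan_metastasis(prep: PreparedData, plan: AnalysisPlan) -> PanResult:
    """Metastasis-vs-primary enrichment for every gene × mutation type.

    The meta-analysis and the cohort-adjusted logistic regression each get
    an FDR family per mutation type; a gene is reported enriched when both
    q-values fall below the threshold and the pooled OR exceeds 1.
    """
    genes = list(plan.genes) if plan.genes is not None else prep.genes
    grouping = mbc_vs_pbc_grouping()
    out = PanResult()
    for mtype in plan.mutation_types:
        metas, fits = [], []
        for gene in genes:
            key = CarrierKey(gene, mtype)
            cont = build_contingency(prep.index, prep.samples, key, "mbc_vs_pbc", grouping)
            metas.append(meta_analyze(cont))
            fits.append(logistic_from_contingency(cont))
        finalize_meta_family(metas, het_gate=plan.het_gate)
        ok = [f for f in fits if f.converged and f.carrier is not None]
        if ok:
            qs = bh_fdr([f.carrier.p for f in ok])
            for f, q in zip(ok, qs):
                f.q = float(q)
        for gene, meta, fit in zip(genes, metas, fits):
            if (
                not meta.untestable
                and meta.q is not None
                and meta.q < plan.q_threshold
                and meta.pooled.log_or > 0
                and fit.q is not None
                and fit.q < plan.q_threshold
            ):
                out.enriched.append((gene, mtype))
        out.meta.extend(metas)
        out.logistic.extend(fits)
    return out


# ---------------------------------------------------------------------------
# site-specific


@dataclass(slots=True)
class OrganotropismCall:
    """A gene × site pair passing the dual criterion.

    ``vs_pbc`` is the stage-1 meta-analysis of the site set against
    primaries (with its confirming logistic fit); ``vs_other`` the stage-2
    cohort-adjusted regression of the site against all other metastatic
    sites.  Direction follows the stage-2 OR sign (``depleted`` mirrors a
    gene enriched in metastases overall but rarer at the site).
    """

    gene: str
    site_set: str
    vs_pbc: MetaResult
    vs_pbc_logistic: RegressionResult
    vs_other: RegressionResult
    direction: str
    subtype_robust: bool | None = None
    ilc_fisher_p: float | None = None

    def to_row(self, kind: str = "organotropism") -> dict:
        return {
            "gene": self.gene,
            "site_set": self.site_set,
            "direction": self.direction,
            "vs_pbc_or": self.vs_pbc.pooled.or_value,
            "vs_pbc_q": self.vs_pbc.q,
            "vs_other_or": self.vs_other.carrier.or_value,
            "vs_other_q": self.vs_other.q,
            "subtype_robust": "NA" if self.subtype_robust is None else int(self.subtype_robust),
        }


@dataclass(slots=True)
class SiteSpecificResult:
    stage1_meta: list[MetaResult] = field(default_factory=list)
    stage1_logistic: list[RegressionResult] = field(default_factory=list)
    stage1_hits: list[tuple[str, str]] = field(default_factory=list)  # (gene, site)
    stage2: list[RegressionResult] = field(default_factory=list)
    calls: list[OrganotropismCall] = field(default_factory=list)
    skipped_sites: list[str] = field(default_factory=list)


def _site_counts(prep: PreparedData) -> dict[str, int]:
    counts: dict[str, int] = {}
    for labels in prep.site_sets.values():
        for lab in labels:
            counts[lab] = counts.get(lab, 0) + 1
    return counts


def run_site_specific(prep: PreparedData, plan: AnalysisPlan) -> SiteSpecificResult:
    """Two-stage metastatic-site analysis with the dual-criterion call."""
    genes = list(plan.genes) if plan.genes is not None else prep.genes
    out = SiteSpecificResult()
    counts = _site_counts(prep)
    sites = []
    for site in plan.site_sets:
        if counts.get(site, 0) >= plan.min_site_n:
            sites.append(site)
        else:
            out.skipped_sites.append(site)

    # stage 1: each site set vs primaries
    records: list[tuple[str, str, MetaResult, RegressionResult]] = []
    for site in sites:
        grouping = mbc_vs_pbc_grouping(prep.site_sets, site)
        for gene in genes:
            cont = build_contingency(
                prep.index,
                prep.samples,
                CarrierKey(gene),
                f"{site}_vs_pbc",
                grouping,
            )
            meta = meta_analyze(cont)
            fit = logistic_from_contingency(cont)
            records.append((gene, site, meta, fit))
    metas = [r[2] for r in records]
    finalize_meta_family(metas, het_gate=plan.het_gate)
    fits = [r[3] for r in records if r[3].converged and r[3].carrier is not None]
    if fits:
        qs = bh_fdr([f.carrier.p for f in fits])
        for f, q in zip(fits, qs):
            f.q = float(q)
    stage1_by_key: dict[tuple[str, str], tuple[MetaResult, RegressionResult]] = {}
    for gene, site, meta, fit in records:
        stage1_by_key[(gene, site)] = (meta, fit)
        if (
            not meta.untestable
            and meta.q is not None
            and meta.q < plan.q_threshold
            and meta.pooled.log_or > 0
        ):
            out.stage1_hits.append((gene, site))
    out.stage1_meta = metas
    out.stage1_logistic = [r[3] for r in records]

    # stage 2: site vs all other metastatic sites (specific sites only)
    specific = set(SPECIFIC_DISTANT_SITES)
    if plan.stage2_all_genes:
        stage2_keys = [(g, s) for s in sites if s in specific for g in genes]
    else:
        stage2_keys = [(g, s) for (g, s) in out.stage1_hits if s in specific]
    stage2_fits: list[tuple[str, str, RegressionResult]] = []
    for gene, site in stage2_keys:
        grouping = site_vs_other_grouping(prep.site_sets, site, plan.site_cohorts)
        cont = build_contingency(
            prep.index,
            prep.samples,
            CarrierKey(gene),
            f"{site}_vs_other_sites",
            grouping,
        )
        fit = logistic_from_contingency(cont)
        stage2_fits.append((gene, site, fit))
    ok = [f for (_, _, f) in stage2_fits if f.converged and f.carrier is not None]
    if ok:
        qs = bh_fdr([f.carrier.p for f in ok])
        for f, q in zip(ok, qs):
            f.q = float(q)
    out.stage2 = [f for (_, _, f) in stage2_fits]

    for gene, site, fit in stage2_fits:
        meta, s1_fit = stage1_by_key[(gene, site)]
        if fit.q is not None and fit.q < plan.q_threshold and (gene, site) in set(out.stage1_hits):
            out.calls.append(
                OrganotropismCall(
                    gene=gene,
                    site_set=site,
                    vs_pbc=meta,
                    vs_pbc_logistic=s1_fit,
                    vs_other=fit,
                    direction="enriched" if fit.carrier.log_or > 0 else "depleted",
                )
            )
    return out


# ---------------------------------------------------------------------------
# subtype-adjusted refits


def _receptor_label(sample: SampleRecord) -> str:
    receptor = classify_subtype(sample)["receptor"]
    return receptor[0] if len(receptor) == 1 else "NA"


def _refit_with_covariate(
    prep: PreparedData,
    plan: AnalysisPlan,
    call: OrganotropismCall,
    covariate: str,
) -> RegressionResult | None:
    """Stage-2 regression with a histology or receptor covariate added.

    Fits on per-sample rows of the site-resolvable metastatic subset,
    dropping samples with missing covariate; returns None when the
    covariate is degenerate (fewer than two observed levels).
    """
    grouping = site_vs_other_grouping(prep.site_sets, call.site_set, plan.site_cohorts)
    carriers = prep.index.carriers(CarrierKey(call.gene))
    rows_y, rows_c, cohorts, covs = [], [], [], []
    for s in prep.samples:
        group = grouping(s)
        if group is None:
            continue
        value = s.histology if covariate == "histology" else _receptor_label(s)
        if value == "NA":
            continue
        rows_y.append(1 if group == "case" else 0)
        rows_c.append(1 if s.sample_id in carriers else 0)
        cohorts.append(s.cohort)
        covs.append(value)
    if len(set(covs)) < 2 or not rows_y:
        return None
    covariates: dict = {covariate: covs}
    if len(set(cohorts)) > 1:
        covariates["cohort"] = cohorts
    fit = logistic_fit(rows_y, rows_c, covariates)
    fit.feature = call.gene
    fit.comparison = f"{call.site_set}_vs_other_sites+{covariate}"
    return fit


def run_subtype_adjusted(
    prep: PreparedData, calls: Sequence[OrganotropismCall], plan: AnalysisPlan
) -> list[OrganotropismCall]:
    """Annotate calls with robustness to histology and receptor covariates.

    Each covariate's refits form their own FDR family across calls; a call
    is subtype-robust when the carrier term stays below the q threshold in
    both refit families.  Insufficient annotation yields ``None`` (NA).
    Also records the two-sided Fisher p for the ILC–gene association among
    metastatic samples (the lobular-confounding check for ovary/peritoneum
    style calls).
    """
    refits: dict[str, list[tuple[int, RegressionResult]]] = {"histology": [], "receptor": []}
    for i, call in enumerate(calls):
        for cov in ("histology", "receptor"):
            fit = _refit_with_covariate(prep, plan, call, cov)
            if fit is not None and fit.converged and fit.carrier is not None:
                refits[cov].append((i, fit))

    robust: dict[int, dict[str, bool]] = {}
    for cov, fits in refits.items():
        if not fits:
            continue
        qs = bh_fdr([f.carrier.p for _, f in fits])
        for (i, fit), q in zip(fits, qs):
            fit.q = float(q)
            robust.setdefault(i, {})[cov] = fit.q < plan.q_threshold

    mbc = [s for s in prep.samples if s.tumor_type == "metastasis"]
    out = []
    for i, call in enumerate(calls):
        verdicts = robust.get(i, {})
        if len(verdicts) < 2:
            subtype_robust = None
        else:
            subtype_robust = all(verdicts.values())
        carriers = prep.index.carriers(CarrierKey(call.gene))
        a = sum(1 for s in mbc if s.histology == "ILC" and s.sample_id in carriers)
        b = sum(1 for s in mbc if s.histology == "ILC" and s.sample_id not in carriers)
        c = sum(1 for s in mbc if s.histology in {"IDC", "Other"} and s.sample_id in carriers)
        d = sum(1 for s in mbc if s.histology in {"IDC", "Other"} and s.sample_id not in carriers)
        out.append(
            replace(call, subtype_robust=subtype_robust, ilc_fisher_p=fisher_exact_2x2(a, b, c, d))
        )
    return out


# ---------------------------------------------------------------------------
# treatment contrasts


@dataclass(slots=True)
class TreatmentResult:
    """Per-gene de novo and post-treatment contrasts and the verdict."""

    gene: str
    denovo: RegressionResult | None
    post: RegressionResult | None
    classification: str = "not_significant"  # metastasis_associated | treatment_associated


def _treatment_grouping(case_status: str):
    def group(s: SampleRecord) -> str | None:
        if s.tumor_type == "primary" and s.treatment_status == "naive_primary":
            return "control"
        if s.tumor_type == "metastasis" and s.treatment_status == case_status:
            return "case"
        return None

    return group


def run_treatment_contrasts(
    prep: PreparedData, plan: AnalysisPlan, genes: Sequence[str] | None = None
) -> list[TreatmentResult]:
    """Naive-primary vs de novo / post-treatment metastasis contrasts.

    A gene significant (q < threshold) in the de novo contrast is
    metastasis-associated: the enrichment exists before any therapy.  A
    gene significant only post-treatment likely reflects treatment
    selection.  Each contrast is its own FDR family.
    """
    genes = list(genes) if genes is not None else (
        list(plan.genes) if plan.genes is not None else prep.genes
    )
    results = {g: TreatmentResult(g, None, None) for g in genes}
    for status, attr in (
        ("denovo_metastasis", "denovo"),
        ("post_treatment_metastasis", "post"),
    ):
        grouping = _treatment_grouping(status)
        fits = []
        for gene in genes:
            cont = build_contingency(
                prep.index,
                prep.samples,
                CarrierKey(gene),
                f"naive_pbc_vs_{attr}",
                grouping,
            )
            if cont.untestable:
                continue
            fit = logistic_from_contingency(cont)
            if fit.converged and fit.carrier is not None:
                fits.append((gene, fit))
        if fits:
            qs = bh_fdr([f.carrier.p for _, f in fits])
            for (gene, fit), q in zip(fits, qs):
                fit.q = float(q)
                setattr(results[gene], attr, fit)
    for res in results.values():
        denovo_sig = (
            res.denovo is not None
            and res.denovo.q is not None
            and res.denovo.q < plan.q_threshold
            and res.denovo.carrier.log_or > 0
        )
        post_sig = (
            res.post is not None
            and res.post.q is not None
            and res.post.q < plan.q_threshold
            and res.post.carrier.log_or > 0
        )
        if denovo_sig:
            res.classification = "metastasis_associated"
        elif post_sig:
            res.classification = "treatment_associated"
    return [results[g] for g in genes]


# ---------------------------------------------------------------------------
# end-to-end driver with report emission


def run_all(
    dataset: Dataset,
    plan: AnalysisPlan | None = None,
    qc: QcConfig | None = None,
    out_dir: str | Path | None = None,
    seed: int | None = None,
) -> dict:
    """Run QC + all three analyses; optionally write TSV reports + manifest.

    Re-running on identical inputs produces byte-identical reports: the
    pipeline is deterministic and floats are formatted at fixed precision.
    """
    plan = plan or AnalysisPlan()
    prep = prepare(dataset, qc)
    pan = run_pan_metastasis(prep, plan)
    site = run_site_specific(prep, plan)
    site.calls = run_subtype_adjusted(prep, site.calls, plan)
    treatment = run_treatment_contrasts(prep, plan)
    results = {"prep": prep, "pan": pan, "site": site, "treatment": treatment}
    if out_dir is not None:
        write_reports(results, plan, out_dir, seed=seed)
    return results


def write_reports(
    results: Mapping, plan: AnalysisPlan, out_dir: str | Path, seed: int | None = None
) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    pan, site, prep = results["pan"], results["site"], results["prep"]
    io_formats.write_report(pan.meta, out / "pan_meta.tsv", "meta")
    io_formats.write_report(pan.logistic, out / "pan_logistic.tsv", "regression")
    io_formats.write_report(site.stage1_meta, out / "site_stage1_meta.tsv", "meta")
    io_formats.write_report(site.stage2, out / "site_stage2_logistic.tsv", "regression")
    io_formats.write_report(site.calls, out / "organotropism_calls.tsv", "organotropism")
    io_formats.write_report(prep.qc_summary.to_rows(), out / "qc_summary.tsv", "qc")
    plan_desc = {
        "genes": list(plan.genes) if plan.genes else None,
        "mutation_types": list(plan.mutation_types),
        "site_sets": list(plan.site_sets),
        "q_threshold": plan.q_threshold,
        "min_site_n": plan.min_site_n,
    }
    manifest = {
        "seed": seed,
        "plan": plan_desc,
        "config_hash": hashlib.sha256(
            json.dumps(plan_desc, sort_keys=True).encode()
        ).hexdigest(),
        "n_samples": len(prep.samples),
        "n_mutations": prep.n_mutations,
        "n_cnas": prep.n_cnas,
        "enriched": pan.enriched,
        "n_calls": len(site.calls),
    }
    (out / "run_manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
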