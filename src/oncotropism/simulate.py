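"""Synthetic multi-cohort metastatic/primary breast cancer datasets.

Every pipeline stage is testable without any download: the generator emits
clinical tables, MAF-style mutation tables, gene-level CNA tables and panel
definitions for a configurable set of cohorts, together with a ground-truth
manifest of the effects that were injected.

Carrier status is simulated at the sample × gene level with the same
logistic model the analysis assumes::

    logit P(carrier) = logit(baseline)
                     + mbc_log_or · [metastasis]
                     + site_log_or[site set]        (metastatic samples)
                     + histology_log_or[histology]  (optional confounding)

Carriers receive one or more variant records with gene-appropriate
classifications (hotspot missense vs truncating), sequencing depth from a
shifted negative binomial and VAF from a Beta distribution.  Filter-fodder
noise (silent variants, low-depth and low-VAF calls, exact duplicates,
hypermutated outlier samples) is injected at configurable rates with full
bookkeeping, so QC tests can assert that the filters remove exactly the
injected noise.  Genes absent from a cohort's panel emit nothing in that
cohort.  This is deliberately *not* a per-base mutational process — the
pipeline tests effect recovery, not mutational signatures.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .counting import CarrierKey, CohortStratum, StratifiedContingency
from .harmonize import Dataset
from .io import (
    CnaRecord,
    MutationRecord,
    PanelDefinition,
    SampleRecord,
)

TRUNCATING_CHOICES = (
    "Nonsense_Mutation",
    "Splice_Site",
    "Frame_Shift_Del",
    "Frame_Shift_Ins",
)

#: Display strings written into clinical tables per site set; the
#: harmonization matcher must resolve each back to its set.
SITE_DISPLAY: Mapping[str, str] = {
    "liver": "Liver",
    "lymph_nodes": "Distant lymph nodes",
    "bone": "Bone",
    "chest_wall_thorax": "Chest wall",
    "skin": "Skin",
    "lung": "Lung",
    "soft": "Soft tissue",
    "pleura": "Pleura",
    "brain": "Brain",
    "ovary": "Ovary",
    "peritoneum": "Peritoneum",
    "other_distant": "Distant organ",
}


@dataclass(slots=True)
class CohortSpec:
    """Size and data availability of one simulated cohort."""

    label: str
    n_mbc: int
    n_pbc: int
    panel_id: str = ""
    panel_genes: frozenset[str] | None = None  # None = all configured genes
    has_cna: bool = False
    has_depth_vaf: bool = True


@dataclass(slots=True)
class GeneSpec:
    """True effect structure of one gene.

    ``baseline`` is the carrier probability in primary samples;
    ``mbc_log_or`` the metastasis enrichment; ``site_log_or`` maps site
    sets to tropism log odds ratios; ``histology_log_or`` injects
    subtype→carrier confounding.  ``hotspot_fraction`` /
    ``truncating_fraction`` control the variant class mix among carriers
    (the remainder are non-hotspot missense).
    """

    gene: str
    baseline: float
    mbc_log_or: float = 0.0
    site_log_or: Mapping[str, float] = field(default_factory=dict)
    histology_log_or: Mapping[str, float] = field(default_factory=dict)
    #: Extra log OR per treatment status of metastatic samples (e.g.
    #: {"post_treatment_metastasis": ln 3} for a treatment-selected effect).
    treatment_log_or: Mapping[str, float] = field(default_factory=dict)
    role: str = "none"  # oncogene | tsg | both | none
    hotspot_fraction: float = 0.0
    truncating_fraction: float = 0.0
    hotspot_aa: str = "D538G"
    hotspot_position: int = 538
    cna_baseline: float = 0.0
    cna_mbc_log_or: float = 0.0


@dataclass(slots=True)
class NoiseConfig:
    """Rates of filter-fodder records (per sample unless noted)."""

    silent_rate: float = 0.02
    low_depth_rate: float = 0.02
    low_vaf_rate: float = 0.02
    duplicate_rate: float = 0.02  # per emitted qualifying record
    outlier_rate: float = 0.0  # per sample; adds ``outlier_extra`` variants
    outlier_extra: int = 40
    cna_low_rate: float = 0.02
    depth_shift: int = 10
    depth_nbinom_n: float = 8.0
    depth_nbinom_p: float = 0.08
    vaf_beta_a: float = 5.0
    vaf_beta_b: float = 10.0


DEFAULT_SITE_DISTRIBUTION: Mapping[str, float] = {
    "bone": 0.25,
    "liver": 0.22,
    "lymph_nodes": 0.14,
    "lung": 0.10,
    "chest_wall_thorax": 0.07,
    "skin": 0.05,
    "soft": 0.04,
    "pleura": 0.04,
    "brain": 0.04,
    "ovary": 0.02,
    "peritoneum": 0.02,
    "other_distant": 0.01,
}

DEFAULT_HISTOLOGY_DISTRIBUTION: Mapping[str, float] = {
    "IDC": 0.62,
    "ILC": 0.12,
    "Other": 0.21,
    "NA": 0.05,
}

DEFAULT_RECEPTOR_DISTRIBUTION: Mapping[tuple[str, str], float] = {
    ("pos", "neg"): 0.52,
    ("pos", "pos"): 0.08,
    ("neg", "pos"): 0.05,
    ("neg", "neg"): 0.12,
    ("NA", "pos"): 0.03,
    ("NA", "NA"): 0.20,
}


@dataclass(slots=True)
class SimConfig:
    """Full description of one synthetic study."""

    seed: int = 2021
    cohorts: Sequence[CohortSpec] = ()
    genes: Sequence[GeneSpec] = ()
    site_distribution: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_SITE_DISTRIBUTION)
    )
    #: Optional histology-specific site distributions (subtype→site
    #: confounding); falls back to ``site_distribution``.
    site_distribution_by_histology: Mapping[str, Mapping[str, float]] = field(
        default_factory=dict
    )
    histology_distribution: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_HISTOLOGY_DISTRIBUTION)
    )
    receptor_distribution: Mapping[tuple[str, str], float] = field(
        default_factory=lambda: dict(DEFAULT_RECEPTOR_DISTRIBUTION)
    )
    local_fraction: float = 0.10
    pbc_naive_fraction: float = 0.30
    mbc_denovo_fraction: float = 0.06
    mbc_post_fraction: float = 0.50
    multi_site_fraction: float = 0.0  # fraction of MBC patients with a 2nd site
    noise: NoiseConfig = field(default_factory=NoiseConfig)

    def validate(self) -> None:
        if not self.cohorts:
            raise ValueError("SimConfig needs at least one cohort")
        if not self.genes:
            raise ValueError("SimConfig needs at least one gene")
        for g in self.genes:
            if not 0.0 <= g.baseline <= 1.0:
                raise ValueError(f"baseline out of [0,1] for {g.gene}")
        for dist in (self.site_distribution, *self.site_distribution_by_histology.values()):
            total = sum(dist.values())
            if abs(total - 1.0) > 1e-6:
                raise ValueError("site distribution must sum to 1")
            if any(p < 0 for p in dist.values()):
                raise ValueError("site probabilities must be non-negative")


@dataclass(slots=True)
class GroundTruth:
    """What was injected, for recovery and filter-accounting tests."""

    gene_effects: dict = field(default_factory=dict)
    #: gene → sorted list of sample ids that carry an emitted (on-panel,
    #: QC-passing) SNV/indel of the gene.
    observed_carriers: dict = field(default_factory=dict)
    cna_carriers: dict = field(default_factory=dict)
    noise_counts: dict = field(default_factory=dict)
    outlier_samples: list = field(default_factory=list)
    sample_sites: dict = field(default_factory=dict)

    def to_json(self) -> str:
        payload = {
            "gene_effects": self.gene_effects,
            "observed_carriers": {g: sorted(s) for g, s in self.observed_carriers.items()},
            "cna_carriers": {g: sorted(s) for g, s in self.cna_carriers.items()},
            "noise_counts": self.noise_counts,
            "outlier_samples": sorted(self.outlier_samples),
            "sample_sites": self.sample_sites,
        }
        return json.dumps(payload, indent=1, sort_keys=True)


def _choice(rng: np.random.Generator, dist: Mapping) -> object:
    keys = list(dist.keys())
    probs = np.array([dist[k] for k in keys], dtype=float)
    probs = probs / probs.sum()
    return keys[rng.choice(len(keys), p=probs)]


class _Emitter:
    """Allocates unique genomic coordinates and renders variant records."""

    def __init__(self, genes: Sequence[GeneSpec], noise: NoiseConfig, rng):
        self.noise = noise
        self.rng = rng
        self.gene_anchor = {
            g.gene: (str(i % 22 + 1), 1_000_000 * (i + 1))
            for i, g in enumerate(genes)
        }
        self._offset = 0

    def _coords(self, gene: str) -> tuple[str, int]:
        chrom, base = self.gene_anchor[gene]
        self._offset += 1
        return chrom, base + self._offset

    def depth_vaf(self, enabled: bool) -> tuple[int | None, float | None]:
        if not enabled:
            return None, None
        depth = int(
            self.noise.depth_shift
            + self.rng.negative_binomial(self.noise.depth_nbinom_n, self.noise.depth_nbinom_p)
        )
        vaf = float(
            np.clip(self.rng.beta(self.noise.vaf_beta_a, self.noise.vaf_beta_b), 0.02, 0.98)
        )
        return depth, vaf

    def variant(
        self,
        sample: SampleRecord,
        spec: GeneSpec,
        with_depth: bool,
        classification: str | None = None,
        depth: int | None = -1,
        vaf: float | None = -1.0,
    ) -> MutationRecord:
        rng = self.rng
        if classification is None:
            classification = "Missense_Mutation"
        chrom, pos = self._coords(spec.gene)
        d, f = self.depth_vaf(with_depth)
        if depth != -1:
            d = depth
        if vaf != -1.0:
            f = vaf
        if classification in TRUNCATING_CHOICES:
            protein = f"p.Q{int(rng.integers(30, 900))}*"
            ref, alt = ("AG", "-") if classification.startswith("Frame_Shift") else ("C", "T")
        else:
            protein = f"p.A{int(rng.integers(30, 900))}V"
            ref, alt = "A", "G"
        return MutationRecord(
            sample_id=sample.sample_id,
            cohort=sample.cohort,
            gene=spec.gene,
            chrom=chrom,
            pos_start=pos,
            pos_end=pos + (1 if ref == "AG" else 0),
            ref_allele=ref,
            alt_allele=alt,
            variant_classification=classification,
            protein_change=protein,
            depth=d,
            vaf=f,
        )


def _carrier_variants(
    emitter: _Emitter, sample: SampleRecord, spec: GeneSpec, with_depth: bool, rng
) -> list[MutationRecord]:
    """Render the record(s) a carrier sample shows for a gene."""
    u = rng.random()
    if u < spec.truncating_fraction:
        cls = TRUNCATING_CHOICES[rng.integers(len(TRUNCATING_CHOICES))]
        rec = emitter.variant(sample, spec, with_depth, classification=cls)
    elif u < spec.truncating_fraction + spec.hotspot_fraction:
        rec = emitter.variant(sample, spec, with_depth, classification="Missense_Mutation")
        rec.protein_change = f"p.{spec.hotspot_aa}"
    else:
        rec = emitter.variant(sample, spec, with_depth, classification="Missense_Mutation")
    return [rec]


def generate(
    config: SimConfig, out_dir: str | Path | None = None
) -> tuple[Dataset, GroundTruth]:
    """Simulate a multi-cohort dataset and its ground-truth manifest.

    Deterministic given ``config.seed``; the same config produces
    byte-identical files.  When ``out_dir`` is given, per-cohort clinical /
    mutation / CNA tables, the panel table and the JSON manifest are
    written there in the dialects the readers understand.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    noise = config.noise
    emitter = _Emitter(config.genes, noise, rng)

    all_genes = [g.gene for g in config.genes]
    panels: dict[str, PanelDefinition] = {}
    for cohort in config.cohorts:
        pid = cohort.panel_id or f"{cohort.label}-PANEL"
        genes = cohort.panel_genes if cohort.panel_genes is not None else frozenset(all_genes)
        panels[pid] = PanelDefinition(pid, frozenset(genes), True)

    truth = GroundTruth(
        gene_effects={
            g.gene: {
                "baseline": g.baseline,
                "mbc_log_or": g.mbc_log_or,
                "site_log_or": dict(g.site_log_or),
                "histology_log_or": dict(g.histology_log_or),
                "treatment_log_or": dict(g.treatment_log_or),
                "role": g.role,
            }
            for g in config.genes
        },
        observed_carriers={g.gene: set() for g in config.genes},
        cna_carriers={g.gene: set() for g in config.genes},
        noise_counts={k: 0 for k in ("silent", "low_depth", "low_vaf", "duplicate", "cna_low")},
    )

    samples: list[SampleRecord] = []
    mutations: list[MutationRecord] = []
    cnas: list[CnaRecord] = []

    for cohort in config.cohorts:
        pid = cohort.panel_id or f"{cohort.label}-PANEL"
        on_panel = panels[pid].genes
        n_total = cohort.n_mbc + cohort.n_pbc
        for i in range(n_total):
            is_mbc = i < cohort.n_mbc
            sid = f"{cohort.label}-S{i:05d}"
            patient = f"{cohort.label}-P{i:05d}"
            histology = _choice(rng, config.histology_distribution)
            hr, her2 = _choice(rng, config.receptor_distribution)
            if is_mbc:
                if rng.random() < config.local_fraction:
                    site_set, biopsy = "local", "Local recurrence"
                else:
                    dist = config.site_distribution_by_histology.get(
                        histology, config.site_distribution
                    )
                    site_set = _choice(rng, dist)
                    biopsy = SITE_DISPLAY[site_set]
                u = rng.random()
                if u < config.mbc_denovo_fraction:
                    treatment = "denovo_metastasis"
                elif u < config.mbc_denovo_fraction + config.mbc_post_fraction:
                    treatment = "post_treatment_metastasis"
                else:
                    treatment = "NA"
            else:
                site_set, biopsy = "", "Breast"
                treatment = (
                    "naive_primary" if rng.random() < config.pbc_naive_fraction else "NA"
                )
            sample = SampleRecord(
                sample_id=sid,
                patient_id=patient,
                cohort=cohort.label,
                tumor_type="metastasis" if is_mbc else "primary",
                biopsy_site=biopsy,
                sex="female",
                histology=histology,
                hr_status=hr,
                her2_status=her2,
                treatment_status=treatment,
                age=float(np.round(rng.normal(55, 10), 1)),
                panel_id=pid,
            )
            samples.append(sample)
            if is_mbc:
                truth.sample_sites[sid] = site_set

            multi_sites = [site_set]
            if (
                is_mbc
                and config.multi_site_fraction > 0
                and rng.random() < config.multi_site_fraction
            ):
                others = [s for s in config.site_distribution if s != site_set]
                second = others[rng.integers(len(others))]
                multi_sites.append(second)
                extra_sid = f"{sid}-M2"
                samples.append(
                    SampleRecord(
                        sample_id=extra_sid,
                        patient_id=patient,
                        cohort=cohort.label,
                        tumor_type="metastasis",
                        biopsy_site=SITE_DISPLAY[second],
                        sex="female",
                        histology=histology,
                        hr_status=hr,
                        her2_status=her2,
                        treatment_status=treatment,
                        age=sample.age,
                        panel_id=pid,
                    )
                )
                truth.sample_sites[extra_sid] = second

            sample_list = [samples[-1 - (len(multi_sites) - 1)]] if len(multi_sites) == 1 else samples[-2:]
            for s_rec, s_site in zip(sample_list, multi_sites):
                for spec in config.genes:
                    eta = logit(spec.baseline)
                    if is_mbc:
                        eta += spec.mbc_log_or + spec.site_log_or.get(s_site, 0.0)
                        eta += spec.treatment_log_or.get(treatment, 0.0)
                    eta += spec.histology_log_or.get(histology, 0.0)
                    carrier = rng.random() < expit(eta)
                    if carrier and spec.gene in on_panel:
                        recs = _carrier_variants(
                            emitter, s_rec, spec, cohort.has_depth_vaf, rng
                        )
                        mutations.extend(recs)
                        truth.observed_carriers[spec.gene].add(s_rec.sample_id)
                        for rec in recs:
                            if rng.random() < noise.duplicate_rate:
                                mutations.append(MutationRecord(**asdict(rec)))
                                truth.noise_counts["duplicate"] += 1
                    if (
                        cohort.has_cna
                        and spec.cna_baseline > 0
                        and spec.gene in on_panel
                    ):
                        eta_c = logit(spec.cna_baseline) + (
                            spec.cna_mbc_log_or if is_mbc else 0.0
                        )
                        if rng.random() < expit(eta_c):
                            cnas.append(CnaRecord(s_rec.sample_id, cohort.label, spec.gene, 2.0))
                            truth.cna_carriers[spec.gene].add(s_rec.sample_id)
                        elif rng.random() < noise.cna_low_rate:
                            cnas.append(CnaRecord(s_rec.sample_id, cohort.label, spec.gene, 1.0))
                            truth.noise_counts["cna_low"] += 1

                # filter-fodder noise, bookkept per reason
                panel_specs = [g for g in config.genes if g.gene in on_panel]
                if panel_specs:
                    if rng.random() < noise.silent_rate:
                        spec = panel_specs[rng.integers(len(panel_specs))]
                        mutations.append(
                            emitter.variant(
                                s_rec, spec, cohort.has_depth_vaf, classification="Silent"
                            )
                        )
                        truth.noise_counts["silent"] += 1
                    if cohort.has_depth_vaf and rng.random() < noise.low_depth_rate:
                        spec = panel_specs[rng.integers(len(panel_specs))]
                        mutations.append(
                            emitter.variant(
                                s_rec,
                                spec,
                                True,
                                classification="Missense_Mutation",
                                depth=int(rng.integers(1, 10)),
                            )
                        )
                        truth.noise_counts["low_depth"] += 1
                    if cohort.has_depth_vaf and rng.random() < noise.low_vaf_rate:
                        spec = panel_specs[rng.integers(len(panel_specs))]
                        mutations.append(
                            emitter.variant(
                                s_rec,
                                spec,
                                True,
                                classification="Missense_Mutation",
                                vaf=float(rng.uniform(0.001, 0.009)),
                            )
                        )
                        truth.noise_counts["low_vaf"] += 1
                    if rng.random() < noise.outlier_rate:
                        for _ in range(noise.outlier_extra):
                            spec = panel_specs[rng.integers(len(panel_specs))]
                            mutations.append(
                                emitter.variant(
                                    s_rec,
                                    spec,
                                    cohort.has_depth_vaf,
                                    classification="Missense_Mutation",
                                )
                            )
                        truth.outlier_samples.append(s_rec.sample_id)

    dataset = Dataset(samples=samples, mutations=mutations, cnas=cnas, panels=panels)
    if out_dir is not None:
        write_dataset(dataset, truth, out_dir)
    return dataset, truth


# ---------------------------------------------------------------------------
# file emission


def write_dataset(dataset: Dataset, truth: GroundTruth, out_dir: str | Path) -> None:
    """Write per-cohort TSV tables, the panel table and the manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cohorts = sorted({s.cohort for s in dataset.samples})
    for cohort in cohorts:
        _write_mutations(
            [m for m in dataset.mutations if m.cohort == cohort],
            out / f"{cohort}_mutations.maf",
        )
        _write_clinical(
            [s for s in dataset.samples if s.cohort == cohort],
            out / f"{cohort}_clinical.tsv",
        )
        cohort_cnas = [c for c in dataset.cnas if c.cohort == cohort]
        if cohort_cnas:
            _write_cna(cohort_cnas, out / f"{cohort}_cna.tsv")
    rows = []
    for pid in sorted(dataset.panels):
        panel = dataset.panels[pid]
        for gene in sorted(panel.genes):
            rows.append(
                {"panel_id": pid, "gene": gene, "full_exonic": int(panel.full_exonic)}
            )
    pd.DataFrame(rows).to_csv(out / "panels.tsv", sep="\t", index=False)
    (out / "ground_truth.json").write_text(truth.to_json())


def _write_mutations(records: Sequence[MutationRecord], path: Path) -> None:
    rows = [
        {
            "Hugo_Symbol": r.gene,
            "Chromosome": r.chrom,
            "Start_Position": r.pos_start,
            "End_Position": r.pos_end,
            "Reference_Allele": r.ref_allele,
            "Tumor_Seq_Allele2": r.alt_allele,
            "Variant_Classification": r.variant_classification,
            "HGVSp_Short": r.protein_change,
            "Tumor_Sample_Barcode": r.sample_id,
            "t_depth": "" if r.depth is None else r.depth,
            "t_alt_count": ""
            if (r.depth is None or r.vaf is None)
            else int(round(r.vaf * r.depth)),
        }
        for r in records
    ]
    pd.DataFrame(
        rows,
        columns=[
            "Hugo_Symbol",
            "Chromosome",
            "Start_Position",
            "End_Position",
            "Reference_Allele",
            "Tumor_Seq_Allele2",
            "Variant_Classification",
            "HGVSp_Short",
            "Tumor_Sample_Barcode",
            "t_depth",
            "t_alt_count",
        ],
    ).to_csv(path, sep="\t", index=False)


def _write_clinical(samples: Sequence[SampleRecord], path: Path) -> None:
    rows = [
        {
            "sample_id": s.sample_id,
            "patient_id": s.patient_id,
            "tumor_type": s.tumor_type,
            "biopsy_site": s.biopsy_site,
            "sex": s.sex,
            "histology": s.histology,
            "hr_status": s.hr_status,
            "her2_status": s.her2_status,
            "treatment_status": s.treatment_status,
            "age": s.age,
            "panel_id": s.panel_id,
        }
        for s in samples
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def _write_cna(records: Sequence[CnaRecord], path: Path) -> None:
    rows = [
        {"sample_id": r.sample_id, "gene": r.gene, "level": r.level} for r in records
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# fast count-level simulation and exact-count fixtures


def simulate_stratified_counts(
    rng: np.random.Generator,
    n_strata: int = 4,
    n_case: int = 500,
    n_control: int = 500,
    baseline: float = 0.05,
    log_or: float = 0.0,
    feature: str = "GENE1",
    comparison: str = "mbc_vs_pbc",
) -> StratifiedContingency:
    """Draw per-cohort 2×2 carrier counts directly under the logistic model.

    Count-level shortcut for recovery / calibration studies: per stratum,
    case carriers ~ Binomial(n_case, expit(logit(baseline) + log_or)) and
    control carriers ~ Binomial(n_control, baseline).
    """
    p_case = float(expit(logit(baseline) + log_or))
    strata = []
    for i in range(n_strata):
        a = int(rng.binomial(n_case, p_case))
        c = int(rng.binomial(n_control, baseline))
        strata.append(CohortStratum(f"C{i + 1}", a, n_case - a, c, n_control - c))
    return StratifiedContingency(CarrierKey(feature), comparison, strata)


# ---------------------------------------------------------------------------
# constructed dual-criterion scenarios

#: Site menu for the constructed scenarios.  The tropism site (liver or
#: ovary) is kept at low prevalence: in a one-vs-rest contrast, enrichment
#: at one site mechanically depletes every other site (the enriched site is
#: part of their "rest"), and keeping the enriched site small keeps that
#: mirror term far below detectability so each scenario isolates exactly
#: one mechanism.
SCENARIO_SITES: Mapping[str, float] = {
    "liver": 0.05,
    "bone": 0.32,
    "lymph_nodes": 0.26,
    "lung": 0.26,
    "ovary": 0.11,
}

_SCENARIO_COHORTS = (("COH1", 1200, 1200), ("COH2", 1200, 1200))


def _scenario_base(seed: int, genes: Sequence[GeneSpec], **kwargs) -> SimConfig:
    kwargs.setdefault("site_distribution", dict(SCENARIO_SITES))
    return SimConfig(
        seed=seed,
        cohorts=[CohortSpec(lab, m, p) for lab, m, p in _SCENARIO_COHORTS],
        genes=list(genes),
        local_fraction=0.08,
        **kwargs,
    )


def tropism_scenario(seed: int = 2021) -> SimConfig:
    """Tropism + enrichment: one gene enriched in metastases (log OR ln 4)
    with genuine liver tropism (log OR ln 3), subtype-independent; two
    frequently-mutated null background genes."""
    return _scenario_base(
        seed,
        [
            GeneSpec(
                "ESR1",
                0.05,
                mbc_log_or=float(np.log(4.0)),
                site_log_or={"liver": float(np.log(3.0))},
                role="oncogene",
                hotspot_fraction=0.6,
            ),
            GeneSpec("TP53", 0.30),
            GeneSpec("PIK3CA", 0.25),
        ],
    )


def enrichment_only_scenario(seed: int = 2021) -> SimConfig:
    """Enrichment without tropism: the gene is more frequent in metastases
    (log OR ln 3) but uniform across metastatic sites."""
    return _scenario_base(
        seed,
        [
            GeneSpec("NF1", 0.05, mbc_log_or=float(np.log(3.0))),
            GeneSpec("TP53", 0.30),
        ],
    )


def confounded_subtype_scenario(seed: int = 2021) -> SimConfig:
    """Tropism confounded by histology: the gene is strongly associated
    with lobular (ILC) histology (log OR ln 6) and ILC tumors
    preferentially seed the ovary — the gene has *no* direct site effect,
    so the marginal ovary preference should vanish under a histology
    covariate."""
    # ILC differs from the baseline distribution only at the ovary; the
    # shortfall is spread proportionally over the other sites so that no
    # second (genuine) site-histology association is injected.
    ilc_sites = {
        "liver": 0.087,
        "bone": 0.245,
        "lymph_nodes": 0.188,
        "lung": 0.180,
        "ovary": 0.300,
    }
    base = {"liver": 0.12, "bone": 0.34, "lymph_nodes": 0.26, "lung": 0.25, "ovary": 0.03}
    return _scenario_base(
        seed,
        [
            GeneSpec(
                "CDH1",
                0.04,
                mbc_log_or=float(np.log(3.0)),
                histology_log_or={"ILC": float(np.log(6.0))},
                role="tsg",
                truncating_fraction=0.8,
            ),
            GeneSpec("TP53", 0.30),
        ],
        site_distribution=base,
        site_distribution_by_histology={"ILC": ilc_sites},
        histology_distribution={"IDC": 0.65, "ILC": 0.20, "Other": 0.10, "NA": 0.05},
    )


def fixture_from_counts(
    a: int,
    b: int,
    c: int,
    d: int,
    gene: str = "ESR1",
    site: str = "liver",
    comparison: str = "site_vs_other_sites",
    cohort: str = "FIX",
) -> Dataset:
    """Minimal dataset whose contingency reproduces (a, b, c, d) exactly.

    For ``site_vs_other_sites``, cases are metastatic samples biopsied at
    ``site`` and controls are metastatic samples at a different distant
    site; for ``mbc_vs_pbc``, controls are primary samples.  Carriers get
    one missense record each.
    """
    if min(a, b, c, d) < 0:
        raise ValueError("negative cell count")
    other_site = "bone" if site != "bone" else "liver"
    samples: list[SampleRecord] = []
    mutations: list[MutationRecord] = []

    def add(n: int, carrier: bool, group: str, start: int) -> None:
        for i in range(n):
            sid = f"{cohort}-{group}{'M' if carrier else 'W'}{start + i:05d}"
            if comparison == "mbc_vs_pbc" and group == "ctrl":
                tumor_type, biopsy = "primary", "Breast"
            else:
                tumor_type = "metastasis"
                biopsy = SITE_DISPLAY[site if group == "case" else other_site]
            samples.append(
                SampleRecord(
                    sample_id=sid,
                    patient_id=sid,
                    cohort=cohort,
                    tumor_type=tumor_type,
                    biopsy_site=biopsy,
                    sex="female",
                    panel_id=f"{cohort}-PANEL",
                )
            )
            if carrier:
                mutations.append(
                    MutationRecord(
                        sample_id=sid,
                        cohort=cohort,
                        gene=gene,
                        chrom="1",
                        pos_start=1_000_000 + start + i,
                        pos_end=1_000_000 + start + i,
                        ref_allele="A",
                        alt_allele="G",
                        variant_classification="Missense_Mutation",
                        protein_change="p.D538G",
                        depth=100,
                        vaf=0.3,
                    )
                )

    add(a, True, "case", 0)
    add(b, False, "case", a)
    add(c, True, "ctrl", 0)
    add(d, False, "ctrl", c)
    panels = {f"{cohort}-PANEL": PanelDefinition(f"{cohort}-PANEL", frozenset({gene}), True)}
    return Dataset(samples=samples, mutations=mutations, panels=panels)
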