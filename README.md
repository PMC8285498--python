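# oncotropism

Multi-cohort enrichment and organotropism analysis of somatic mutations in
metastatic versus primary breast cancer.

Metastatic breast cancer (MBC) genomes are mostly sequenced on heterogeneous
targeted panels across many clinical cohorts.  Individually these cohorts are
underpowered to detect the rare alterations that distinguish metastases from
primary tumors (PBC) — let alone alterations specific to *where* a tumor
metastasizes (organotropism: the preference of disseminating tumor cells for
particular organs such as liver, bone, or brain).  This package provides the
full pipeline for that kind of aggregated analysis:

- **Harmonization & QC** of MAF-style variant tables, gene-level copy-number
  calls and clinical tables from cohorts with different panels, vocabularies
  and data availability: variant-class allow-listing, depth/VAF filters,
  in-sample duplicate removal, cohort-wise hypermutation-outlier exclusion,
  and restriction to genes covered by most panels.
- **Stratified meta-analysis** of carrier frequencies (per gene × mutation
  type), with heterogeneity-driven switching between fixed- and
  random-effects pooling, confirmed by cohort-adjusted logistic regression.
- **A dual-criterion organotropism caller**: a gene is called organotropic
  for a metastatic site only when it is (1) enriched at that site relative
  to primaries *and* (2) enriched (or depleted) at that site relative to all
  other metastatic sites, both at FDR < 5%, with subtype-adjusted refits to
  flag calls explained by histology or receptor-status confounding.
- **A pattern-based candidate-driver-mutation scorer** (hotspot missense for
  oncogenes, truncations for tumor suppressors, integer Func-score
  eligibility).
- **A synthetic multi-cohort generator** with known ground truth (injected
  enrichment/tropism log odds ratios, filter-fodder noise, panel masking),
  so every stage is testable without any controlled-access download.

## The statistical model

For gene *g* and cohort *k*, carriers are counted in a 2×2 table
(case/control × carrier/non-carrier).  The per-cohort effect is the Woolf
log odds ratio with standard error

```
y_k = log(a_k d_k / b_k c_k),    se_k = sqrt(1/a_k + 1/b_k + 1/c_k + 1/d_k)
```

(Haldane–Anscombe 0.5 correction when a cell is zero).  Cohorts are pooled
by inverse-variance weighting, `w_k = 1/se_k²`.  Heterogeneity is assessed
with Cochran's Q and I² = max(0, (Q−df)/Q)·100; when the FDR-adjusted
heterogeneity p-value falls below 0.05 the pooled estimate switches to a
random-effects model with between-cohort variance τ² estimated by REML
(weights `1/(se_k² + τ²)`).  All confidence intervals and p-values are Wald;
p-values are Benjamini–Hochberg adjusted within declared test families.
Cohort-adjusted logistic regressions (metastasis status ~ carrier status +
cohort indicators, fit by IRLS on grouped data) confirm each pooled result,
and Fisher's exact test backs the lobular-histology checks.

## Worked example

```python
import numpy as np
from oncotropism.stats import odds_ratio_2x2
from oncotropism.simulate import generate, tropism_scenario
from oncotropism.pipeline import (
    AnalysisPlan, prepare, run_pan_metastasis, run_site_specific, run_subtype_adjusted,
)

# Published carrier counts: ESR1, metastatic liver vs other metastatic sites
est = odds_ratio_2x2(163, 420, 161, 1416)
print(f"ESR1 liver vs other metastatic sites: OR={est.or_value:.2f} "
      f"(95% CI {est.ci_low:.2f}-{est.ci_high:.2f}), p={est.p:.2e}")

# Synthetic two-cohort study with injected ESR1 enrichment + liver tropism
dataset, truth = generate(tropism_scenario())
prep = prepare(dataset)
plan = AnalysisPlan()
pan = run_pan_metastasis(prep, plan)
print("MBC-enriched:", pan.enriched)
site = run_site_specific(prep, plan)
for c in run_subtype_adjusted(prep, site.calls, plan):
    print(f"organotropism call: {c.gene} -> {c.site_set} ({c.direction}), "
          f"vs PBC q={c.vs_pbc.q:.2e}, vs other sites OR={c.vs_other.carrier.or_value:.2f} "
          f"q={c.vs_other.q:.2e}, subtype_robust={c.subtype_robust}")
```

prints

```
ESR1 liver vs other metastatic sites: OR=3.41 (95% CI 2.68-4.35), p=4.97e-23
MBC-enriched: [('ESR1', 'snv_indel')]
organotropism call: ESR1 -> liver (enriched), vs PBC q=7.43e-28, vs other sites OR=2.91 q=2.73e-06, subtype_robust=True
```

The first line reproduces a published odds ratio directly from printed
contingency counts.  The rest runs the full pipeline on a simulated
two-cohort study (2400 metastatic + 2400 primary samples) in which ESR1 was
generated with a metastasis log OR of ln 4 and a liver-tropism log OR of
ln 3: the pan-metastasis stage recovers the enrichment, and the
dual-criterion caller emits exactly the injected liver call, robust to
histology and receptor covariates.

A thin CLI mirrors the library: `oncotropism simulate --config sim.yaml
--out fixtures/` writes a synthetic dataset with its ground-truth manifest,
and `oncotropism run --mutations COHORT=path ... --panels panels.tsv --out
reports/` runs QC plus all analyses and writes TSV reports and a JSON run
manifest.

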