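# Methods

## Problem setting and data model

The pipeline compares somatic alteration frequencies between metastatic
(MBC) and primary (PBC) breast cancer samples pooled from multiple clinical
sequencing cohorts, and between metastatic samples from different biopsy
sites.  The unit of analysis is the *carrier*: a sample with at least one
qualifying alteration of a feature.  Features are gene-level (any
allow-listed SNV/indel; a high-level amplification; a deep deletion) or
variant-level (a specific amino-acid change, or all truncating events of a
gene pooled as "Trunc").  Multiplicity within a sample is deliberately
discarded — every comparison is a comparison of carrier proportions.

Inputs are MAF-style tab-delimited variant tables (GRCh37 coordinates, MAF
`Variant_Classification` vocabulary, HGVSp-short protein changes),
gene-level CNA tables (long or matrix layout, integer levels or AMP/HOM_DEL
labels), clinical sample tables, panel definitions, and small lookup tables
(symbol aliases, gene roles, hotspot positions, functional annotations).
Parsing is total: each row becomes exactly one record or one logged
rejection, so load accounting is exact.  Genome-build conversion and variant
annotation are out of scope; inputs are assumed pre-annotated.

## Harmonization and quality control

Sample eligibility (single-site mode): female samples, full-exonic panels
only (hotspot-only panels cannot support carrier calling), and at most one
metastatic biopsy site per patient, to avoid counting one patient's clone
twice.  Multi-site mode inverts the last rule for within-patient
comparisons.

The variant QC ladder runs in a fixed order so removal counts are
reproducible: in-sample duplicates (identity = sample + coordinates +
alleles) → depth < 10 → VAF < 0.01 → classification outside the allow-list
{Frame_Shift_Del, Frame_Shift_Ins, In_Frame_Del, In_Frame_Ins,
Missense_Mutation, Nonsense_Mutation, Nonstop_Mutation, Splice_Region,
Splice_Site, Translation_Start_Site}.  Both depth/VAF bounds are strict
(records exactly at the bound are kept), and records *missing* depth or VAF
pass those filters — several source cohorts do not report the fields, and
missingness must not delete data.

Hypermutated outliers are flagged per cohort with a Tukey rule on
per-sample variant counts (samples with at least one variant): count >
Q3 + k·IQR, default k = 3, linear-interpolation quartiles.  Two numerical
choices matter here.  First, counts are integers, so the IQR is floored at
one mutation: on sparse panels most samples carry exactly one variant, the
raw IQR is zero, and an unfloored rule would flag every two-variant sample.
Second, cohorts with fewer than four counted samples skip the rule
entirely.  The rule itself is a stand-in for a threshold the source data
only supports graphically; both k and a fixed-cutoff alternative are
exposed in `QcConfig`.

CNA levels are kept losslessly at read time (including the −1.5
shallow-deletion code some sources use) and filtered to {−2, +2} during
harmonization.  Gene selection keeps genes covered by at least
`panel_min_fraction` (default 7/11) of the panels; the integer threshold is
`ceil(fraction · n_panels − 1e−9)` — the tolerance matters because
`ceil(7/11 · 11)` is 8 in floating point.

Metastatic biopsy sites map through an ordered, case-insensitive pattern
table to site sets: every metastatic sample is `pan` plus either `local`
(ipsilateral breast/chest-wall relapse, regional nodes) or `distant` plus
exactly one specific site among {liver, lymph_nodes, bone,
chest_wall_thorax, skin, lung, soft, pleura, brain, ovary, peritoneum};
unmatched text falls into `other_distant`, which is excluded from per-site
testing as a catch-all.  Receptor subtype comes from (HR, HER2) status; a
HER2-positive-only annotation contributes to both HER2+ subtypes, mirroring
how such cohorts must be handled, but yields no single label for
regression covariates.

## Statistical kernel

Per-cohort 2×2 tables give Woolf log odds ratios, `se = sqrt(Σ 1/cell)`,
with the Haldane–Anscombe 0.5 added to all four cells of a stratum when any
cell is zero; strata with zero carriers in both arms carry no information
and are dropped; cohorts lacking one comparison arm never form a stratum.
Fixed-effects pooling is inverse-variance on the log scale.  The fixed
model is the default because that is what the standard meta-analysis
packages compute for odds ratios under "fixed effects"; a Mantel–Haenszel
pooled estimate is available as a sensitivity option, as is the
Breslow–Day/Tarone homogeneity test beside the default Cochran's Q.

Heterogeneity: Q = Σ w_k (y_k − ŷ_FE)², df = k−1, chi-square p,
I² = max(0, (Q−df)/Q)·100.  τ² is estimated by the standard REML
fixed-point iteration (DerSimonian–Laird start, floor at zero, tolerance
1e−10); tests verify it against a direct grid search over the restricted
likelihood to 1e−4.  Model switching is decided at the family level: the
heterogeneity p-values of one analysis form their own BH-FDR family, and a
feature switches to random effects when its heterogeneity q < 0.05 (a
raw-p gate is available).  Pooled p-values of the chosen models are then
FDR-adjusted together.  FDR families are one per analysis × mutation type;
every result row records its family through the comparison label.

Logistic regressions are ML fits via IRLS (statsmodels GLM, binomial
family, ≤100 iterations).  Stratified 2×2 analyses enter as grouped
frequency-weighted rows with cohort indicators (reference level = first
sorted cohort), which makes the carrier coefficient the cohort-adjusted
log OR and keeps fits fast regardless of sample count.  Complete or
quasi-separation (an empty weighted carrier × outcome cell, a diverging
coefficient, or a failed fit) flags the result non-converged and excludes
it from FDR families.  Wald CIs and p-values are used throughout — matching
the OR ± 1.96·se presentation convention of the field — rather than
profile-likelihood intervals.  Fisher's exact test (two-sided, minimum
likelihood rule) is delegated to scipy and verified against exhaustive
hypergeometric enumeration.

## The three analyses

**Pan-metastasis.** Every concurrent-panel gene × mutation type is tested
MBC vs PBC by meta-analysis and by cohort-adjusted logistic regression;
a gene is reported enriched when both q-values are below threshold and the
pooled OR exceeds 1.

**Site-specific.** Stage 1 tests each site set vs PBC (meta + logistic;
site sets below a minimum sample count, default 20, are skipped).  Stage 2
takes the stage-1-significant (gene, site) pairs at specific distant sites
and tests site vs all other metastatic sites by cohort-adjusted logistic
regression, restricted to the cohort subset with per-sample site
resolution (configurable, `AnalysisPlan.site_cohorts`).  An
`OrganotropismCall` is emitted when the stage-1 meta-analysis q *and* the
stage-2 regression q are both below threshold; the meta-analysis gates
stage 1 (the logistic fit is recorded as confirmation), and the call's
direction follows the stage-2 OR sign, so a gene enriched in metastases
overall but rarer at one site surfaces as `depleted`.  Stage-1 genes with
pooled OR < 1 are reported but never called organotropic.

Subtype-adjusted refits re-fit stage 2 per call on per-sample rows adding a
histology covariate and, separately, a receptor-status covariate (samples
with missing covariate dropped; a covariate with fewer than two observed
levels is degenerate and yields NA).  Each covariate's refits form their
own FDR family across calls; `subtype_robust` is true when the carrier term
stays significant in both, false when either refit loses it, NA when
annotation is insufficient.  The two-sided Fisher association between ILC
histology and gene carriage among metastatic samples is recorded per call
(the classic lobular/ovary-peritoneum confounding check).

**Treatment contrasts.** Treatment-naive primaries vs treatment-naive de
novo metastases, and vs post-treatment metastases, per gene, each contrast
its own FDR family.  Significant-in-de-novo classifies a gene
metastasis-associated (the enrichment predates therapy); significant only
post-treatment classifies it treatment-associated.

**Driver patterns.** Within enriched genes annotated in the role table,
oncogene candidates are distinct amino-acid changes at hotspot positions
(position match only), TSG candidates the pooled `Trunc` key (truncating =
nonsense, splice-site, frameshift; splice-region excluded by default,
configurable).  The Func score is an integer: OG missense sums per-tool
impact points over three missense predictors (high/medium 2, low 1,
neutral/missing 0) plus 1 for a hotspot position; TSG truncation scores a
base 4 plus literature-evidence points (strong 2, weak 1).  The exact point
table is a reconstruction honoring the printed facts (three tools, an
evidence ladder, threshold ≥ 5) and is fully overridable in
`FuncScoreConfig`.  Eligibility additionally requires more than two
carriers (≥3; a ≥2 override exists because the source description is
ambiguous).  Eligible candidates are meta-analyzed vs PBC and tested for
per-site preference, each family FDR-adjusted.

## Synthetic data generator

The generator emulates the multi-cohort study design at the sample × gene
level with the same logistic model the analysis assumes:

```
logit P(carrier) = logit(baseline) + mbc_log_or·[metastasis]
                 + site_log_or[site] + treatment_log_or[status]
                 + histology_log_or[histology]
```

Cohorts differ in size, panel content (off-panel genes emit nothing),
CNA availability and depth/VAF reporting.  Carriers receive variant records
with a configurable hotspot-missense/truncating mix; depth is a shifted
negative binomial (shift 10, NB(8, 0.08), mean ≈ 102×), VAF a Beta(5, 10)
clipped to [0.02, 0.98].  Filter-fodder noise — silent variants, low-depth
(<10) and low-VAF (<0.01) calls, exact duplicates, hypermutated outlier
samples — is injected at configurable rates (defaults ≈ 2%, so QC filter
tests are non-vacuous) with per-reason bookkeeping, which lets tests assert
that QC removes *exactly* the injected noise.  Clinical structure (site
distribution, optionally histology-specific; receptor and histology mixes;
treatment-status frequencies; a multi-site-patient fraction) follows
configured distributions whose defaults reflect typical metastatic breast
cancer series (bone/liver/lymph-node-dominated site mix, ~60% ductal, ~12%
lobular, hormone-receptor-positive majority).

What the generator does *not* emulate: mutational signatures or per-base
mutation processes, copy-number segments (gene-level calls only), tumor
purity, within-gene variant multiplicity beyond one record per carrier, and
panel differences beyond gene membership.  Passing recovery tests therefore
demonstrates that the statistical machinery recovers carrier-level effects
under the assumed logistic model — not that the pipeline is robust to
mis-specified real-world noise.

`fixture_from_counts` inverts counting exactly: given (a, b, c, d) it emits
a minimal one-cohort dataset whose contingency reproduces those cells,
which is how published contingency rows are replayed through the counting
path.

## Constructed scenarios and calibration studies

Three fixed scenarios (two cohorts × 1200 MBC + 1200 PBC each, default
noise, seed 2021) probe the dual-criterion caller:

1. *Tropism + enrichment*: one gene with metastasis log OR ln 4 and liver
   tropism ln 3 → exactly one call, subtype-robust.
2. *Enrichment only*: metastasis log OR ln 3, uniform across sites → no
   call.
3. *Confounded by subtype*: metastasis log OR ln 3, a strong ILC–carrier
   association (ln 6) and ILC-specific ovary preference, but no direct site
   effect → one call, not subtype-robust.

Two constructed-scenario choices are deliberate.  The tropism site is kept
at low prevalence (5–11% of distant biopsies): in a one-vs-rest contrast,
enrichment at one site mechanically depletes every other site (the
enriched site is part of their "rest"), and a low-prevalence tropism site
keeps that mirror term far below detectability, so each scenario isolates
exactly one mechanism.  Likewise the ILC site distribution in scenario 3
deviates from baseline only at the ovary, the shortfall spread
proportionally, so no second genuine site–histology association is
injected.  Because stage 2 still runs ~10 null tests at FDR 0.05, a ~5%
per-scenario chance of one extra borderline call at an arbitrary seed is
irreducible by design of FDR control; the scenarios are defined at the
fixed seed above.

Calibration studies use a count-level shortcut (per-cohort binomial draws
under the same logistic model): 4 cohorts × 500 samples/arm, 5% baseline.
With an injected log OR of ln 3 over 200 replicates the pooled
fixed-effects estimator shows |mean bias| < 0.05 on the log scale and
~95% CI coverage; under the null over 1000 replicates the unadjusted
pooled Wald test rejects at ~4–6%.  These problem sizes were chosen to
match the scale at which the per-stratum normal approximation for log odds
ratios is trustworthy while keeping the whole suite fast.

## Known limitations

- The outlier rule and the Func-score point table are faithful
  reconstructions of procedures whose exact parameters are not published;
  both are config-overridable and their defaults are documented above.
- Indel representation fix-ups some sources require (adjusting start/end
  and alleles before MAF conversion) are not guessed; the readers expose a
  normalization hook but apply no transformation.
- Wald inference on sparse strata (few carriers) is approximate even with
  the Haldane correction; exact conditional methods are out of scope.
- The het-q model switch tests many features jointly; a feature whose
  heterogeneity is real but modest may remain on the fixed-effects model
  after FDR adjustment.
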