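"""Statistical kernel: 2×2 odds ratios, inverse-variance meta-analysis with
heterogeneity-driven model switching, cohort-adjusted logistic regression,
Fisher's exact test, and Benjamini–Hochberg FDR.

The pooling model follows the standard two-stage odds-ratio meta-analysis:
per-cohort log odds ratios with Woolf standard errors are combined with
inverse-variance weights under a fixed-effects model; when between-cohort
heterogeneity is significant (FDR-adjusted heterogeneity p < 0.05 within the
analysis family), the pooled estimate switches to a random-effects model
with the between-cohort variance tau² estimated by REML.  Wald 95% CIs and
p-values are used throughout, matching the OR ± 1.96·se presentation of the
source tables.

Pure computation — no file I/O; every operation is deterministic given its
inputs.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm

from .counting import StratifiedContingency

__all__ = [
    "EffectEstimate",
    "HeterogeneityResult",
    "MetaResult",
    "RegressionResult",
    "odds_ratio_2x2",
    "fixed_effects_pool",
    "random_effects_pool",
    "heterogeneity",
    "reml_tau2",
    "logistic_fit",
    "logistic_from_contingency",
    "fisher_exact_2x2",
    "bh_fdr",
    "meta_analyze",
    "finalize_meta_family",
    "cmh_pool",
    "tarone_q",
]

Z95 = scipy.stats.norm.ppf(0.975)


def _wald_p(log_or: float, se: float) -> float:
    if se <= 0 or not math.isfinite(se):
        return 1.0
    p = 2.0 * scipy.stats.norm.sf(abs(log_or) / se)
    return min(max(p, 5e-324), 1.0)


@dataclass(slots=True)
class EffectEstimate:
    """A log odds ratio with its Wald standard error, CI, and p-value."""

    log_or: float
    se: float
    or_value: float = field(init=False)
    ci_low: float = field(init=False)
    ci_high: float = field(init=False)
    p: float = field(init=False)

    def __post_init__(self) -> None:
        def _exp(x: float) -> float:
            try:
                return math.exp(x)
            except OverflowError:
                return math.inf
        self.or_value = _exp(self.log_or)
        self.ci_low = _exp(self.log_or - Z95 * self.se)
        self.ci_high = _exp(self.log_or + Z95 * self.se)
        self.p = _wald_p(self.log_or, self.se)


@dataclass(slots=True)
class HeterogeneityResult:
    """Cochran's Q with its chi-square p, I² percentage, and REML tau²."""

    q_stat: float = 0.0
    df: int = 0
    i2: float = 0.0
    het_p: float = 1.0
    tau2: float = 0.0


def odds_ratio_2x2(
    a: float, b: float, c: float, d: float, continuity: str | None = "haldane"
) -> EffectEstimate:
    """Woolf log odds ratio for one 2×2 table.

    With ``continuity="haldane"`` (default), 0.5 is added to all four cells
    when any cell is zero (Haldane–Anscombe).  se = sqrt(1/a+1/b+1/c+1/d).

    Raises ``ValueError`` when either comparison arm is empty.
    """
    if min(a, b, c, d) < 0:
        raise ValueError("negative cell count")
    if a + b == 0 or c + d == 0:
        raise ValueError("untestable: empty comparison arm")
    if continuity == "haldane" and min(a, b, c, d) == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    if min(a, b, c, d) == 0:
        raise ValueError("zero cell without continuity correction")
    log_or = math.log((a * d) / (b * c))
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    return EffectEstimate(log_or, se)


def fixed_effects_pool(estimates: Sequence[EffectEstimate]) -> EffectEstimate:
    """Inverse-variance fixed-effects pooling of per-stratum log ORs."""
    if not estimates:
        raise ValueError("no estimates to pool")
    y = np.array([e.log_or for e in estimates])
    w = np.array([1.0 / e.se**2 for e in estimates])
    return EffectEstimate(float((w * y).sum() / w.sum()), float(math.sqrt(1.0 / w.sum())))


def random_effects_pool(
    estimates: Sequence[EffectEstimate], tau2: float
) -> EffectEstimate:
    """Random-effects pooling with weights 1/(se² + tau²)."""
    if tau2 < 0:
        raise ValueError("tau2 must be non-negative")
    if not estimates:
        raise ValueError("no estimates to pool")
    y = np.array([e.log_or for e in estimates])
    w = 1.0 / (np.array([e.se**2 for e in estimates]) + tau2)
    return EffectEstimate(float((w * y).sum() / w.sum()), float(math.sqrt(1.0 / w.sum())))


def reml_tau2(
    y: Sequence[float],
    v: Sequence[float],
    tol: float = 1e-10,
    max_iter: int = 500,
) -> float:
    """Between-stratum variance tau² by the REML fixed-point iteration.

    Iterates ``tau² ← Σw²[(y−μ̂)² − v]/Σw² + 1/Σw`` with ``w = 1/(v + tau²)``
    and ``μ̂`` the weighted mean, starting from the DerSimonian–Laird
    estimate and floored at zero.
    """
    y = np.asarray(y, dtype=float)
    v = np.asarray(v, dtype=float)
    k = len(y)
    if k < 2:
        return 0.0
    w = 1.0 / v
    mu = (w * y).sum() / w.sum()
    q = (w * (y - mu) ** 2).sum()
    c = w.sum() - (w**2).sum() / w.sum()
    tau2 = max(0.0, (q - (k - 1)) / c) if c > 0 else 0.0
    for _ in range(max_iter):
        w = 1.0 / (v + tau2)
        mu = (w * y).sum() / w.sum()
        num = (w**2 * ((y - mu) ** 2 - v)).sum()
        new = max(0.0, float(num / (w**2).sum() + 1.0 / w.sum()))
        if abs(new - tau2) < tol:
            return new
        tau2 = new
    return tau2


def heterogeneity(
    estimates: Sequence[EffectEstimate],
    pooled: EffectEstimate | None = None,
) -> HeterogeneityResult:
    """Cochran's Q across strata, its chi-square p, I², and REML tau².

    With fewer than two strata, returns the Q=0, df=0, p=1 convention.
    I² = max(0, (Q − df)/Q) × 100.
    """
    k = len(estimates)
    if k < 2:
        return HeterogeneityResult()
    y = np.array([e.log_or for e in estimates])
    v = np.array([e.se**2 for e in estimates])
    w = 1.0 / v
    mu = pooled.log_or if pooled is not None else float((w * y).sum() / w.sum())
    q = float((w * (y - mu) ** 2).sum())
    df = k - 1
    het_p = float(scipy.stats.chi2.sf(q, df)) if q > 0 else 1.0
    i2 = max(0.0, (q - df) / q) * 100.0 if q > 0 else 0.0
    return HeterogeneityResult(
        q_stat=q,
        df=df,
        i2=i2,
        het_p=min(max(het_p, 5e-324), 1.0),
        tau2=reml_tau2(y, v),
    )


# ---------------------------------------------------------------------------
# logistic regression


@dataclass(slots=True)
class RegressionResult:
    """A fitted logistic model keyed by term name.

    ``carrier`` is the term of interest (the mutation-carrier indicator);
    its exponentiated coefficient is the covariate-adjusted odds ratio.
    Separation (any arm of the carrier × outcome table empty, or a
    diverging coefficient) marks the fit non-converged; such results are
    excluded from FDR families.
    """

    terms: dict[str, EffectEstimate] = field(default_factory=dict)
    converged: bool = False
    separation_flag: bool = False
    feature: str = ""
    mutation_type: str = "snv_indel"
    comparison: str = ""
    q: float | None = None

    @property
    def carrier(self) -> EffectEstimate | None:
        return self.terms.get("carrier")

    def to_row(self, kind: str = "regression") -> dict:
        est = self.carrier
        return {
            "feature": self.feature,
            "mutation_type": self.mutation_type,
            "comparison": self.comparison,
            "or": est.or_value if est else "",
            "ci_low": est.ci_low if est else "",
            "ci_high": est.ci_high if est else "",
            "p": est.p if est else "",
            "q": "" if self.q is None else self.q,
            "converged": int(self.converged),
            "separation": int(self.separation_flag),
        }


def _encode_covariates(covariates, n: int) -> pd.DataFrame:
    if covariates is None:
        return pd.DataFrame(index=range(n))
    frame = pd.DataFrame(covariates)
    frame.index = range(n)
    out = {}
    for col in frame.columns:
        series = frame[col]
        if series.dtype == object or isinstance(series.dtype, pd.CategoricalDtype):
            levels = sorted(series.astype(str).unique())
            for level in levels[1:]:  # first sorted level is the reference
                out[f"{col}[{level}]"] = (series.astype(str) == level).astype(float)
        else:
            out[str(col)] = series.astype(float)
    return pd.DataFrame(out, index=range(n))


def logistic_fit(
    outcome,
    carrier,
    covariates=None,
    weights=None,
) -> RegressionResult:
    """Maximum-likelihood logistic regression of outcome on carrier status.

    Fit by IRLS (statsmodels GLM, binomial family), max 100 iterations.
    ``covariates`` is a mapping/DataFrame; string columns are dummy-encoded
    with the first sorted level as reference (cohort indicators enter this
    way).  ``weights`` are frequency weights for grouped data — a stratified
    2×2 analysis is the grouped special case.

    Complete/quasi-separation (an empty cell of the weighted carrier ×
    outcome margin, or a diverging coefficient) sets ``separation_flag`` and
    marks the fit non-converged.
    """
    outcome = np.asarray(outcome, dtype=float)
    carrier = np.asarray(carrier, dtype=float)
    n = len(outcome)
    w = np.ones(n) if weights is None else np.asarray(weights, dtype=float)

    separation = False
    if carrier.std() > 0:
        mask = w > 0
        for o_val in (0.0, 1.0):
            for c_val in (0.0, 1.0):
                if w[mask & (outcome == o_val) & (carrier == c_val)].sum() == 0:
                    separation = True

    exog = _encode_covariates(covariates, n)
    exog.insert(0, "carrier", carrier)
    exog.insert(0, "const", 1.0)
    if carrier.std() == 0:
        exog = exog.drop(columns="carrier")

    result = RegressionResult(separation_flag=separation)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            glm = sm.GLM(
                outcome, exog.to_numpy(), family=sm.families.Binomial(), freq_weights=w
            )
            fit = glm.fit(maxiter=100, tol=1e-10)
    except Exception:
        result.converged = False
        result.separation_flag = True
        return result

    params = np.asarray(fit.params, dtype=float)
    bse = np.asarray(fit.bse, dtype=float)
    for name, coef, se in zip(exog.columns, params, bse):
        se = float(se) if math.isfinite(se) and se > 0 else float("inf")
        if math.isfinite(se):
            result.terms[name] = EffectEstimate(float(coef), se)
    if np.any(np.abs(params) > 15) or np.any(~np.isfinite(bse)) or np.any(bse > 100):
        result.separation_flag = True
    result.converged = bool(getattr(fit, "converged", True)) and not result.separation_flag
    return result


def logistic_from_contingency(
    contingency: StratifiedContingency,
    extra_covariates: Mapping[str, Sequence] | None = None,
) -> RegressionResult:
    """Cohort-adjusted logistic regression from grouped 2×2 strata.

    Expands each stratum into its four weighted cells with a cohort
    covariate; the carrier coefficient is then the cohort-adjusted log OR.
    """
    rows_outcome, rows_carrier, rows_cohort, rows_w = [], [], [], []
    for s in contingency.strata:
        for outcome, carrier, weight in (
            (1, 1, s.a),
            (1, 0, s.b),
            (0, 1, s.c),
            (0, 0, s.d),
        ):
            rows_outcome.append(outcome)
            rows_carrier.append(carrier)
            rows_cohort.append(s.cohort)
            rows_w.append(weight)
    covs: dict = {}
    if len(set(rows_cohort)) > 1:
        covs["cohort"] = rows_cohort
    if extra_covariates:
        covs.update(extra_covariates)
    result = logistic_fit(rows_outcome, rows_carrier, covs or None, weights=rows_w)
    result.feature = contingency.feature.feature
    result.mutation_type = contingency.feature.mutation_type
    result.comparison = contingency.comparison
    return result


# ---------------------------------------------------------------------------
# exact test and FDR


def fisher_exact_2x2(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher's exact p for one 2×2 table.

    Sum of hypergeometric probabilities of tables (at fixed margins) no more
    probable than the observed one; degenerate margins give p = 1.
    """
    if min(a, b, c, d) < 0:
        raise ValueError("negative cell count")
    if a + b == 0 or c + d == 0 or a + c == 0 or b + d == 0:
        return 1.0
    return float(scipy.stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")[1])


def bh_fdr(p_values: Sequence[float], family_labels: Sequence | None = None) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values, computed within families.

    Within each family of m tests: sort p ascending (stable),
    q_(i) = min_{j ≥ i} p_(j)·m/j, capped at 1; original order restored.
    """
    p = np.asarray(p_values, dtype=float)
    q = np.empty_like(p)
    if family_labels is None:
        families: dict = {None: np.arange(len(p))}
    else:
        families = {}
        for i, lab in enumerate(family_labels):
            families.setdefault(lab, []).append(i)
        families = {k: np.asarray(v) for k, v in families.items()}
    for idx in families.values():
        pf = p[idx]
        m = len(pf)
        order = np.argsort(pf, kind="stable")
        ranked = pf[order] * m / np.arange(1, m + 1)
        qf = np.minimum.accumulate(ranked[::-1])[::-1]
        out = np.empty(m)
        out[order] = np.minimum(qf, 1.0)
        q[idx] = out
    return q


# ---------------------------------------------------------------------------
# meta-analysis of a stratified contingency


@dataclass(slots=True)
class MetaResult:
    """Pooled effect for one feature with heterogeneity diagnostics.

    Both the fixed- and random-effects pooled estimates are retained;
    ``model`` selects which one ``pooled`` reports.  The switch to the
    random-effects model is made at the family level (FDR-adjusted
    heterogeneity p < 0.05) by :func:`finalize_meta_family`.
    """

    feature: str
    mutation_type: str
    comparison: str
    strata: list[EffectEstimate] = field(default_factory=list)
    pooled_fixed: EffectEstimate | None = None
    pooled_random: EffectEstimate | None = None
    het: HeterogeneityResult = field(default_factory=HeterogeneityResult)
    model: str = "fixed"
    q: float | None = None
    het_q: float | None = None
    untestable: bool = False
    counts: tuple[int, int, int, int] = (0, 0, 0, 0)

    @property
    def pooled(self) -> EffectEstimate | None:
        return self.pooled_random if self.model == "random" else self.pooled_fixed

    def to_row(self, kind: str = "meta") -> dict:
        est = self.pooled
        return {
            "feature": self.feature,
            "mutation_type": self.mutation_type,
            "comparison": self.comparison,
            "n_strata": len(self.strata),
            "or": est.or_value if est else "",
            "ci_low": est.ci_low if est else "",
            "ci_high": est.ci_high if est else "",
            "p": est.p if est else "",
            "q": "" if self.q is None else self.q,
            "i2": self.het.i2,
            "het_p": self.het.het_p,
            "het_q": "" if self.het_q is None else self.het_q,
            "tau2": self.het.tau2,
            "model": self.model if not self.untestable else "untestable",
        }


def meta_analyze(
    contingency: StratifiedContingency, continuity: str | None = "haldane"
) -> MetaResult:
    """Per-stratum odds ratios pooled across cohorts.

    Strata with zero carriers in both arms carry no information about the
    odds ratio and are dropped before pooling; remaining zero cells receive
    the Haldane–Anscombe correction within their stratum only.  The result
    holds both pooled models; the fixed/random choice and the FDR q-values
    are finalized over the whole analysis family.
    """
    result = MetaResult(
        feature=contingency.feature.feature,
        mutation_type=contingency.feature.mutation_type,
        comparison=contingency.comparison,
        counts=contingency.collapse(),
    )
    informative = [s for s in contingency.strata if s.a + s.c > 0]
    if contingency.untestable or not informative:
        result.untestable = True
        return result
    result.strata = [odds_ratio_2x2(s.a, s.b, s.c, s.d, continuity) for s in informative]
    result.pooled_fixed = fixed_effects_pool(result.strata)
    result.het = heterogeneity(result.strata, result.pooled_fixed)
    result.pooled_random = random_effects_pool(result.strata, result.het.tau2)
    return result


def finalize_meta_family(
    results: Sequence[MetaResult],
    alpha_het: float = 0.05,
    het_gate: str = "fdr",
) -> None:
    """Choose pooling models and assign q-values across one test family.

    Heterogeneity p-values form their own FDR family; a feature switches to
    the random-effects model when its heterogeneity q (or raw p, with
    ``het_gate="raw"``) falls below ``alpha_het``.  Pooled p-values of the
    chosen models are then FDR-adjusted together.  Untestable features are
    excluded from both families.
    """
    testable = [r for r in results if not r.untestable]
    if not testable:
        return
    het_q = bh_fdr([r.het.het_p for r in testable])
    for r, hq in zip(testable, het_q):
        r.het_q = float(hq)
        gate = r.het_q if het_gate == "fdr" else r.het.het_p
        r.model = "random" if gate < alpha_het else "fixed"
    qs = bh_fdr([r.pooled.p for r in testable])
    for r, qv in zip(testable, qs):
        r.q = float(qv)


# ---------------------------------------------------------------------------
# sensitivity options (Mantel-Haenszel pooling, Tarone homogeneity)


def _stratified_table(contingency: StratifiedContingency):
    tables = [
        np.array([[s.a, s.b], [s.c, s.d]], dtype=float) for s in contingency.strata
    ]
    return sm.stats.StratifiedTable(tables)


def cmh_pool(contingency: StratifiedContingency) -> EffectEstimate:
    """Mantel–Haenszel pooled odds ratio (sensitivity alternative to IV)."""
    st = _stratified_table(contingency)
    log_or = float(st.logodds_pooled)
    se = float(st.logodds_pooled_se)
    return EffectEstimate(log_or, se)


def tarone_q(contingency: StratifiedContingency) -> tuple[float, float]:
    """Breslow–Day homogeneity statistic with Tarone's adjustment.

    Returns (statistic, p); sensitivity alternative to Cochran's Q.
    """
    st = _stratified_table(contingency)
    res = st.test_equal_odds(adjust=True)
    return float(res.statistic), float(res.pvalue)
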