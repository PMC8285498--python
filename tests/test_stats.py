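"""Statistical kernel: odds ratios, pooling, heterogeneity, REML, logistic
regression, Fisher's exact test, and BH FDR — each checked against hand
computations or independent oracles."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from statsmodels.stats.multitest import multipletests

from oncotropism.counting import CarrierKey, CohortStratum, StratifiedContingency
from oncotropism.stats import (
    EffectEstimate,
    bh_fdr,
    cmh_pool,
    finalize_meta_family,
    fisher_exact_2x2,
    fixed_effects_pool,
    heterogeneity,
    logistic_fit,
    logistic_from_contingency,
    meta_analyze,
    odds_ratio_2x2,
    random_effects_pool,
    reml_tau2,
    tarone_q,
)

from _oracles import fisher_enumeration, reml_grid_search


def contingency(*strata, feature="G", comparison="mbc_vs_pbc"):
    return StratifiedContingency(
        CarrierKey(feature),
        comparison,
        [CohortStratum(f"C{i}", *cells) for i, cells in enumerate(strata)],
    )


class TestOddsRatio:
    def test_table_counts_hand_example(self):
        est = odds_ratio_2x2(163, 420, 161, 1416)
        assert est.or_value == pytest.approx(3.4133, abs=5e-4)
        assert est.se == pytest.approx(math.sqrt(1 / 163 + 1 / 420 + 1 / 161 + 1 / 1416))

    def test_symmetric_table_is_null(self):
        est = odds_ratio_2x2(5, 5, 5, 5)
        assert est.log_or == 0.0 and est.or_value == 1.0

    def test_haldane_correction(self):
        # (0,10,5,10): corrected cells (0.5,10.5,5.5,10.5)
        est = odds_ratio_2x2(0, 10, 5, 10, continuity="haldane")
        assert est.or_value == pytest.approx((0.5 * 10.5) / (10.5 * 5.5), rel=1e-12)

    def test_empty_arm_untestable(self):
        with pytest.raises(ValueError):
            odds_ratio_2x2(0, 0, 5, 5)

    @given(
        a=st.integers(1, 200), b=st.integers(1, 200),
        c=st.integers(1, 200), d=st.integers(1, 200),
    )
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_antisymmetry(self, a, b, c, d):
        fwd = odds_ratio_2x2(a, b, c, d, continuity=None)
        rev = odds_ratio_2x2(c, d, a, b, continuity=None)
        assert fwd.log_or == pytest.approx(-rev.log_or, abs=1e-12)

    def test_ci_brackets_estimate(self):
        est = odds_ratio_2x2(20, 80, 10, 90)
        assert est.ci_low <= est.or_value <= est.ci_high


class TestPooling:
    def test_single_stratum_identity(self):
        est = odds_ratio_2x2(10, 90, 5, 95)
        pooled = fixed_effects_pool([est])
        assert pooled.log_or == pytest.approx(est.log_or)
        assert pooled.se == pytest.approx(est.se)

    def test_equal_precision_is_log_scale_mean(self):
        e1, e2 = EffectEstimate(math.log(2), 0.5), EffectEstimate(math.log(8), 0.5)
        pooled = fixed_effects_pool([e1, e2])
        assert pooled.or_value == pytest.approx(4.0)

    def test_duplicating_a_stratum_shrinks_se_by_sqrt2(self):
        est = odds_ratio_2x2(10, 90, 5, 95)
        pooled = fixed_effects_pool([est, est])
        assert pooled.log_or == pytest.approx(est.log_or)
        assert pooled.se == pytest.approx(est.se / math.sqrt(2))

    def test_pooled_within_stratum_range(self):
        rng = np.random.default_rng(2021)
        for _ in range(20):
            ests = [
                EffectEstimate(float(rng.normal(0, 1)), float(rng.uniform(0.1, 1)))
                for _ in range(rng.integers(2, 6))
            ]
            pooled = fixed_effects_pool(ests)
            logs = [e.log_or for e in ests]
            assert min(logs) - 1e-12 <= pooled.log_or <= max(logs) + 1e-12

    def test_random_effects_reduces_to_fixed_at_zero_tau2(self):
        ests = [EffectEstimate(0.2, 0.3), EffectEstimate(0.7, 0.2)]
        fe = fixed_effects_pool(ests)
        re = random_effects_pool(ests, 0.0)
        assert re.log_or == pytest.approx(fe.log_or) and re.se == pytest.approx(fe.se)

    def test_random_effects_limits_to_unweighted_mean(self):
        ests = [EffectEstimate(0.0, 0.1), EffectEstimate(1.0, 0.5)]
        re = random_effects_pool(ests, 1e8)
        assert re.log_or == pytest.approx(0.5, abs=1e-4)


class TestHeterogeneity:
    def test_identical_strata(self):
        ests = [EffectEstimate(0.5, 0.2)] * 3
        het = heterogeneity(ests)
        assert het.q_stat == pytest.approx(0.0, abs=1e-12)
        assert het.i2 == 0.0 and het.tau2 == 0.0 and het.het_p == 1.0

    def test_hand_computed_q_and_i2(self):
        # y = (ln2, ln8), both variances 0.25: Q ~= 3.844, I2 ~= 74.0%
        ests = [EffectEstimate(math.log(2), 0.5), EffectEstimate(math.log(8), 0.5)]
        het = heterogeneity(ests)
        assert het.q_stat == pytest.approx(3.8436, abs=5e-4)
        assert het.i2 == pytest.approx(74.0, abs=0.05)
        assert het.df == 1

    def test_single_stratum_convention(self):
        het = heterogeneity([EffectEstimate(0.5, 0.2)])
        assert (het.q_stat, het.df, het.het_p) == (0.0, 0, 1.0)


class TestReml:
    def test_non_negative_and_zero_when_homogeneous(self):
        y = [0.5, 0.5, 0.5]
        v = [0.04, 0.09, 0.04]
        assert reml_tau2(y, v) == 0.0

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_grid_search_oracle(self, seed):
        rng = np.random.default_rng(100 + seed)
        k = int(rng.integers(3, 6))
        y = rng.normal(0, 1, k)
        v = rng.uniform(0.05, 0.5, k)
        assert reml_tau2(y, v) == pytest.approx(reml_grid_search(y, v), abs=1e-4)

    def test_zero_when_q_below_df(self):
        # tight agreement relative to large within-variances
        y = np.array([0.50, 0.52, 0.48])
        v = np.array([0.2, 0.25, 0.2])
        ests = [EffectEstimate(float(a), float(math.sqrt(b))) for a, b in zip(y, v)]
        het = heterogeneity(ests)
        assert het.q_stat <= het.df
        assert het.tau2 == 0.0


class TestLogistic:
    def test_grouped_2x2_matches_crude_or(self):
        cont = contingency((163, 420, 161, 1416))
        fit = logistic_from_contingency(cont)
        assert fit.converged
        assert fit.carrier.or_value == pytest.approx(163 * 1416 / (420 * 161), abs=1e-6)

    def test_intercept_only_reproduces_prevalence_logit(self):
        outcome = [1] * 30 + [0] * 70
        fit = logistic_fit(outcome, [0] * 100)
        prev_logit = math.log(30 / 70)
        assert fit.terms["const"].log_or == pytest.approx(prev_logit, abs=1e-8)

    def test_independent_predictor_coef_zero(self):
        # perfectly balanced: carrier split identically among cases/controls
        outcome = [1, 1, 1, 1, 0, 0, 0, 0]
        carrier = [1, 1, 0, 0, 1, 1, 0, 0]
        fit = logistic_fit(outcome, carrier)
        assert fit.carrier.log_or == pytest.approx(0.0, abs=1e-8)

    def test_complete_separation_flagged(self):
        outcome = [1, 1, 1, 0, 0, 0]
        carrier = [1, 1, 1, 0, 0, 0]
        fit = logistic_fit(outcome, carrier)
        assert fit.separation_flag and not fit.converged

    def test_cohort_adjustment_recovers_common_or(self):
        # two strata with the same true OR 3 but very different baselines
        cont = contingency((30, 70, 13, 87), (60, 40, 33, 67))
        fit = logistic_from_contingency(cont)
        crude = odds_ratio_2x2(90, 110, 46, 154)
        assert "cohort[C1]" in fit.terms
        # adjusted estimate sits near 3; the crude one is confounded downward
        assert abs(fit.carrier.log_or - math.log(3)) < abs(crude.log_or - math.log(3)) + 0.25


class TestFisher:
    def test_hand_enumerated_example(self):
        assert fisher_exact_2x2(3, 1, 1, 3) == pytest.approx(34 / 70, rel=1e-10)

    def test_degenerate_margins(self):
        assert fisher_exact_2x2(0, 5, 0, 7) == 1.0
        assert fisher_exact_2x2(0, 0, 3, 4) == 1.0

    @given(
        a=st.integers(0, 8), b=st.integers(0, 8),
        c=st.integers(0, 8), d=st.integers(0, 8),
    )
    @settings(max_examples=150, deadline=None, derandomize=True)
    def test_matches_enumeration(self, a, b, c, d):
        assert fisher_exact_2x2(a, b, c, d) == pytest.approx(
            fisher_enumeration(a, b, c, d), rel=1e-9, abs=1e-12
        )


class TestBhFdr:
    def test_step_up_hand_examples(self):
        assert bh_fdr([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04] * 4)
        assert bh_fdr([0.005, 0.5]) == pytest.approx([0.01, 0.5])
        assert bh_fdr([0.2]) == pytest.approx([0.2])

    def test_families_adjusted_independently(self):
        q = bh_fdr([0.01, 0.02, 0.01, 0.02], family_labels=["A", "A", "B", "B"])
        assert q == pytest.approx([0.02, 0.02, 0.02, 0.02])

    def test_original_order_restored(self):
        p = [0.5, 0.001, 0.03]
        q = bh_fdr(p)
        assert q[1] == min(q) and q[0] == max(q)

    @given(st.lists(st.floats(1e-8, 1.0), min_size=1, max_size=30))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_properties_and_statsmodels_agreement(self, p):
        q = bh_fdr(p)
        assert np.all(q >= np.asarray(p) - 1e-15) and np.all(q <= 1.0)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-15)  # monotone along sorted p
        expected = multipletests(p, method="fdr_bh")[1]
        assert q == pytest.approx(expected, rel=1e-12)


class TestMetaAnalyze:
    def test_single_cohort_equals_stratum(self):
        cont = contingency((20, 80, 10, 90))
        res = meta_analyze(cont)
        finalize_meta_family([res])
        assert res.model == "fixed"
        assert res.pooled.log_or == pytest.approx(res.strata[0].log_or)

    def test_zero_carrier_strata_dropped(self):
        cont = contingency((0, 100, 0, 100), (20, 80, 10, 90))
        res = meta_analyze(cont)
        assert len(res.strata) == 1

    def test_untestable_flag(self):
        cont = contingency((0, 10, 0, 10))
        res = meta_analyze(cont)
        assert res.untestable
        finalize_meta_family([res])
        assert res.q is None  # excluded from the family

    def test_opposing_strata_switch_to_random_effects(self):
        # one wildly heterogeneous feature among homogeneous ones
        heterogeneous = contingency((20, 80, 83, 17), (83, 17, 20, 80), feature="HET")
        family = [meta_analyze(heterogeneous)]
        for i in range(6):
            family.append(meta_analyze(contingency((20, 80, 10, 90), (22, 78, 11, 89),
                                                   feature=f"HOM{i}")))
        finalize_meta_family(family)
        assert family[0].model == "random"
        assert family[0].het_q < 0.05
        assert all(r.model == "fixed" for r in family[1:])
        assert family[0].het.tau2 > 0

    def test_model_choice_matches_het_q_rule(self):
        cont = contingency((20, 80, 10, 90), (25, 75, 12, 88))
        res = meta_analyze(cont)
        finalize_meta_family([res])
        assert res.model == ("random" if res.het_q < 0.05 else "fixed")


class TestSensitivityOptions:
    def test_cmh_close_to_iv_on_balanced_data(self):
        cont = contingency((30, 70, 15, 85), (28, 72, 14, 86))
        iv = fixed_effects_pool(meta_analyze(cont).strata)
        mh = cmh_pool(cont)
        assert mh.log_or == pytest.approx(iv.log_or, abs=0.05)

    def test_tarone_statistic_valid(self):
        cont = contingency((30, 70, 15, 85), (10, 90, 30, 70))
        stat, p = tarone_q(cont)
        assert stat >= 0 and 0 < p <= 1
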