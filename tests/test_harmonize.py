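"""QC ladder, outlier rule, panel-intersection gene selection, site/subtype
classification, and sample eligibility."""

import math

import pytest
from hypothesis import given, settings, strategies as st

from oncotropism.harmonize import (
    QcConfig,
    SiteSetMap,
    classify_site_set,
    classify_subtype,
    filter_cna,
    filter_variants,
    flag_outlier_samples,
    select_concurrent_genes,
    select_samples,
)
from oncotropism.io import CnaRecord, MutationRecord, PanelDefinition, SampleRecord


def mut(sample="S1", gene="ESR1", pos=100, depth=50, vaf=0.3,
        vclass="Missense_Mutation", cohort="C1", ref="A", alt="G"):
    return MutationRecord(
        sample_id=sample, cohort=cohort, gene=gene, chrom="1",
        pos_start=pos, pos_end=pos, ref_allele=ref, alt_allele=alt,
        variant_classification=vclass, depth=depth, vaf=vaf,
    )


def sample(sid="S1", patient=None, tumor="metastasis", site="Liver", sex="female",
           hr="NA", her2="NA", histology="NA", panel="P1", cohort="C1"):
    return SampleRecord(
        sample_id=sid, patient_id=patient or sid, cohort=cohort, tumor_type=tumor,
        biopsy_site=site, sex=sex, histology=histology, hr_status=hr,
        her2_status=her2, panel_id=panel,
    )


class TestFilterVariants:
    @pytest.mark.parametrize(
        "record, removed_as",
        [
            (mut(depth=9), "low_depth"),
            (mut(vaf=0.005), "low_vaf"),
            (mut(vclass="Silent"), "classification"),
            (mut(vclass="5'Flank"), "classification"),
        ],
    )
    def test_removals(self, record, removed_as):
        kept, summary = filter_variants([record])
        assert kept == []
        assert summary.removed[removed_as] == 1

    @pytest.mark.parametrize(
        "record",
        [
            mut(depth=10, vaf=0.01),  # strict-inequality boundary: kept
            mut(depth=None, vaf=None),  # missing fields are not filterable
            mut(vclass="Splice_Region"),
        ],
    )
    def test_kept(self, record):
        kept, _ = filter_variants([record])
        assert kept == [record]

    def test_in_sample_duplicates_removed_first(self):
        a = mut(pos=100)
        dup = mut(pos=100, depth=5)  # same coordinates+alleles, bad depth
        other_sample = mut(sample="S2", pos=100)
        kept, summary = filter_variants([a, dup, other_sample])
        assert kept == [a, other_sample]
        # the duplicate is charged to "duplicate", not "low_depth"
        assert summary.removed == {"duplicate": 1}

    def test_conservation_and_idempotence(self):
        records = [
            mut(pos=p, depth=d, vaf=v, vclass=c)
            for p, d, v, c in [
                (1, 50, 0.3, "Missense_Mutation"),
                (1, 50, 0.3, "Missense_Mutation"),  # duplicate
                (2, 5, 0.3, "Missense_Mutation"),
                (3, 50, 0.001, "Missense_Mutation"),
                (4, 50, 0.3, "Silent"),
                (5, 50, 0.3, "Nonsense_Mutation"),
            ]
        ]
        kept, summary = filter_variants(records)
        assert summary.n_input == len(records)
        assert sum(summary.removed.values()) + len(kept) == len(records)
        again, summary2 = filter_variants(kept)
        assert again == kept and sum(summary2.removed.values()) == 0


class TestOutlierRule:
    def _records_with_counts(self, counts, cohort="C1", prefix="S"):
        records = []
        for i, n in enumerate(counts):
            for k in range(n):
                records.append(mut(sample=f"{prefix}{i}", pos=1000 * i + k, cohort=cohort))
        return records

    def test_tukey_rule_hand_example(self):
        # counts [2,3,3,4,50]: Q3=4, IQR=1, bound 4+3*1=7 -> only 50 out
        records = self._records_with_counts([2, 3, 3, 4, 50])
        assert flag_outlier_samples(records, QcConfig(outlier_k=3.0)) == {"S4"}

    def test_all_equal_counts_no_outliers(self):
        records = self._records_with_counts([3, 3, 3, 3, 3])
        assert flag_outlier_samples(records) == set()

    def test_infinite_k_disables_rule(self):
        records = self._records_with_counts([1, 1, 1, 1, 100])
        assert flag_outlier_samples(records, QcConfig(outlier_k=math.inf)) == set()

    def test_small_cohort_skipped(self):
        records = self._records_with_counts([1, 1, 50])
        assert flag_outlier_samples(records) == set()

    def test_cohorts_judged_separately(self):
        records = self._records_with_counts([2, 3, 3, 4, 50], cohort="A", prefix="A")
        records += self._records_with_counts([48, 50, 52, 50, 49], cohort="B", prefix="B")
        flagged = flag_outlier_samples(records)
        assert {r.sample_id for r in records if r.cohort == "A"} & flagged == {"A4"}
        assert {r.sample_id for r in records if r.cohort == "B"} & flagged == set()


class TestConcurrentGenes:
    def _panels(self, membership):
        return {
            f"P{i}": PanelDefinition(f"P{i}", frozenset(genes))
            for i, genes in enumerate(membership)
        }

    def test_seven_of_eleven_threshold(self):
        # GENE_A in 7/11 panels (kept), GENE_B in 6/11 (dropped), CORE in all
        membership = [
            {"CORE", "GENE_A", "GENE_B"} if i < 6 else
            ({"CORE", "GENE_A"} if i == 6 else {"CORE"})
            for i in range(11)
        ]
        genes = select_concurrent_genes(self._panels(membership), 7 / 11)
        assert genes == ["CORE", "GENE_A"]

    def test_gene_in_all_panels_kept_at_any_fraction(self):
        panels = self._panels([{"CORE"}] * 5)
        assert select_concurrent_genes(panels, 1.0) == ["CORE"]

    def test_no_panels_is_hard_error(self):
        with pytest.raises(ValueError):
            select_concurrent_genes({})

    @given(frac1=st.floats(0.1, 1.0), frac2=st.floats(0.1, 1.0))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_monotone_in_min_fraction(self, frac1, frac2):
        membership = [{"A", "B"}, {"A"}, {"A", "C"}, {"B", "C"}, {"A", "B", "C"}]
        panels = self._panels(membership)
        lo, hi = sorted([frac1, frac2])
        assert set(select_concurrent_genes(panels, hi)) <= set(
            select_concurrent_genes(panels, lo)
        )


class TestFilterCna:
    def test_low_levels_removed(self):
        records = [
            CnaRecord("S1", "C", "ERBB2", 2.0),
            CnaRecord("S1", "C", "PTEN", -2.0),
            CnaRecord("S2", "C", "ERBB2", 1.0),
            CnaRecord("S2", "C", "PTEN", -1.0),
            CnaRecord("S3", "C", "PTEN", -1.5),
        ]
        kept = filter_cna(records)
        assert {(r.sample_id, r.gene) for r in kept} == {("S1", "ERBB2"), ("S1", "PTEN")}


class TestSiteSets:
    @pytest.mark.parametrize(
        "biopsy, expected",
        [
            ("Liver", {"pan", "distant", "liver"}),
            ("Regional lymph nodes", {"pan", "local"}),
            ("Distant lymph nodes", {"pan", "distant", "lymph_nodes"}),
            ("Local recurrence", {"pan", "local"}),
            ("", {"pan", "distant", "other_distant"}),
            ("Pleural effusion", {"pan", "distant", "pleura"}),
        ],
    )
    def test_classification(self, biopsy, expected):
        assert classify_site_set(sample(site=biopsy)) == frozenset(expected)

    def test_primary_sample_rejected(self):
        with pytest.raises(ValueError):
            classify_site_set(sample(tumor="primary"))

    @given(st.text(max_size=30))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_labels_partition_metastatic_samples(self, text):
        labels = classify_site_set(sample(site=text), SiteSetMap())
        assert "pan" in labels
        assert ("local" in labels) != ("distant" in labels)
        specific = labels - {"pan", "local", "distant"}
        assert len(specific) == (1 if "distant" in labels else 0)


class TestSubtypes:
    @pytest.mark.parametrize(
        "hr, her2, expected",
        [
            ("pos", "neg", ("HR+/HER2-",)),
            ("neg", "neg", ("Triple-negative",)),
            ("NA", "pos", ("HR+/HER2+", "HR-/HER2+")),  # HER2-positive-only
            ("NA", "NA", ()),
        ],
    )
    def test_receptor_subtypes(self, hr, her2, expected):
        assert classify_subtype(sample(hr=hr, her2=her2))["receptor"] == expected


class TestSelectSamples:
    PANELS = {
        "P1": PanelDefinition("P1", frozenset({"ESR1"}), full_exonic=True),
        "HOT": PanelDefinition("HOT", frozenset({"ESR1"}), full_exonic=False),
    }

    def test_male_and_hotspot_panel_excluded(self):
        samples = [
            sample("S1", sex="male"),
            sample("S2", panel="HOT"),
            sample("S3"),
        ]
        kept, log = select_samples(samples, self.PANELS)
        assert [s.sample_id for s in kept] == ["S3"]
        assert log == {"S1": "male", "S2": "hotspot_only_panel"}

    def test_multi_site_patient_modes(self):
        samples = [
            sample("S1", patient="P1", site="Liver"),
            sample("S2", patient="P1", site="Bone"),
            sample("S3", patient="P2", site="Liver"),
        ]
        single, _ = select_samples(samples, self.PANELS, "single_site")
        assert [s.sample_id for s in single] == ["S3"]
        multi, _ = select_samples(samples, self.PANELS, "multi_site")
        assert [s.sample_id for s in multi] == ["S1", "S2"]
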