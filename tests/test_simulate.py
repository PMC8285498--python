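"""Generator contracts: determinism, panel masking, carrier-frequency
convergence, and exact filter accounting of injected noise."""

import dataclasses
import filecmp

import numpy as np
import pytest

from oncotropism.counting import CarrierIndex
from oncotropism.harmonize import filter_variants, remove_outlier_samples
from oncotropism.simulate import (
    CohortSpec,
    GeneSpec,
    NoiseConfig,
    SimConfig,
    fixture_from_counts,
    generate,
    simulate_stratified_counts,
)
from oncotropism.stats import meta_analyze, finalize_meta_family


class TestDeterminism:
    def test_same_seed_same_records(self, small_sim_config):
        ds1, t1 = generate(small_sim_config)
        ds2, t2 = generate(small_sim_config)
        assert ds1.mutations == ds2.mutations
        assert ds1.samples == ds2.samples
        assert ds1.cnas == ds2.cnas
        assert t1.to_json() == t2.to_json()

    def test_same_seed_byte_identical_files(self, small_sim_config, tmp_path):
        generate(small_sim_config, out_dir=tmp_path / "a")
        generate(small_sim_config, out_dir=tmp_path / "b")
        files = sorted(p.name for p in (tmp_path / "a").iterdir())
        assert files
        for name in files:
            assert filecmp.cmp(tmp_path / "a" / name, tmp_path / "b" / name, shallow=False)

    def test_different_seed_differs(self, small_sim_config):
        ds1, _ = generate(small_sim_config)
        other = dataclasses.replace(small_sim_config, seed=99)
        ds2, _ = generate(other)
        assert ds1.mutations != ds2.mutations


class TestStructure:
    def test_panel_masking(self, quiet_noise):
        cfg = SimConfig(
            seed=7,
            cohorts=[
                CohortSpec("FULL", 100, 100),
                CohortSpec("MASKED", 100, 100, panel_genes=frozenset({"TP53"})),
            ],
            genes=[GeneSpec("ESR1", 0.3), GeneSpec("TP53", 0.3)],
            noise=quiet_noise,
        )
        ds, truth = generate(cfg)
        masked = [m for m in ds.mutations if m.cohort == "MASKED"]
        assert masked and all(m.gene == "TP53" for m in masked)
        assert all(not s.startswith("MASKED") for s in truth.observed_carriers["ESR1"])

    def test_invalid_config_rejected_before_writing(self, tmp_path):
        cfg = SimConfig(
            seed=1,
            cohorts=[CohortSpec("C", 10, 10)],
            genes=[GeneSpec("G", 1.5)],  # invalid baseline
        )
        with pytest.raises(ValueError):
            generate(cfg, out_dir=tmp_path / "out")
        assert not (tmp_path / "out").exists()

    def test_manifest_matches_emitted_files(self, small_dataset):
        ds, truth = small_dataset
        index = CarrierIndex(ds.mutations)
        for gene, expected in truth.observed_carriers.items():
            # carriers recomputed from records must cover the manifest;
            # noise records may only add apparent carriers pre-QC
            assert expected <= index.gene.get(gene, set())

    def test_multi_site_mode_emits_second_samples(self, quiet_noise):
        cfg = SimConfig(
            seed=3,
            cohorts=[CohortSpec("C", 200, 0)],
            genes=[GeneSpec("G", 0.1)],
            multi_site_fraction=0.5,
            noise=quiet_noise,
        )
        ds, _ = generate(cfg)
        by_patient = {}
        for s in ds.samples:
            by_patient.setdefault(s.patient_id, set()).add(s.biopsy_site)
        assert any(len(sites) >= 2 for sites in by_patient.values())


class TestCarrierFrequencies:
    def test_law_of_large_numbers(self, quiet_noise):
        baseline = 0.3
        cfg = SimConfig(
            seed=11,
            cohorts=[CohortSpec("BIG", 0, 50_000)],
            genes=[GeneSpec("G", baseline)],
            noise=quiet_noise,
        )
        ds, truth = generate(cfg)
        freq = len(truth.observed_carriers["G"]) / 50_000
        se = np.sqrt(baseline * (1 - baseline) / 50_000)
        assert abs(freq - baseline) < 3 * se

    def test_mbc_log_or_shifts_frequency(self, quiet_noise):
        cfg = SimConfig(
            seed=12,
            cohorts=[CohortSpec("C", 20_000, 20_000)],
            genes=[GeneSpec("G", 0.05, mbc_log_or=float(np.log(3)))],
            noise=quiet_noise,
        )
        ds, truth = generate(cfg)
        mbc = {s.sample_id for s in ds.samples if s.tumor_type == "metastasis"}
        carriers = truth.observed_carriers["G"]
        f_mbc = len(carriers & mbc) / len(mbc)
        f_pbc = len(carriers - mbc) / (len(ds.samples) - len(mbc))
        from scipy.special import expit, logit

        assert f_pbc == pytest.approx(0.05, abs=0.01)
        assert f_mbc == pytest.approx(float(expit(logit(0.05) + np.log(3))), abs=0.01)


class TestFilterAccounting:
    def test_qc_removes_exactly_injected_noise(self):
        cfg = SimConfig(
            seed=21,
            cohorts=[CohortSpec("C1", 800, 800), CohortSpec("C2", 800, 800)],
            genes=[GeneSpec("A", 0.10), GeneSpec("B", 0.15), GeneSpec("C", 0.05)],
            noise=NoiseConfig(
                silent_rate=0.05,
                low_depth_rate=0.05,
                low_vaf_rate=0.05,
                duplicate_rate=0.05,
                outlier_rate=0.0,
            ),
        )
        ds, truth = generate(cfg)
        kept, summary = filter_variants(ds.mutations)
        assert summary.removed["duplicate"] == truth.noise_counts["duplicate"]
        assert summary.removed["low_depth"] == truth.noise_counts["low_depth"]
        assert summary.removed["low_vaf"] == truth.noise_counts["low_vaf"]
        assert summary.removed["classification"] == truth.noise_counts["silent"]
        # what remains is exactly the true carrier records
        index = CarrierIndex(kept)
        for gene, expected in truth.observed_carriers.items():
            assert index.gene.get(gene, set()) == expected

    def test_outlier_samples_recovered(self):
        cfg = SimConfig(
            seed=22,
            cohorts=[CohortSpec("C1", 500, 500)],
            genes=[GeneSpec("A", 0.10), GeneSpec("B", 0.15), GeneSpec("C", 0.20)],
            noise=NoiseConfig(
                silent_rate=0.0, low_depth_rate=0.0, low_vaf_rate=0.0,
                duplicate_rate=0.0, outlier_rate=0.01, outlier_extra=40,
            ),
        )
        ds, truth = generate(cfg)
        kept, _ = filter_variants(ds.mutations)
        _, flagged = remove_outlier_samples(kept)
        assert flagged == set(truth.outlier_samples)


class TestCountLevelSimulator:
    def test_null_simulation_is_calibrated_in_distribution(self):
        rng = np.random.default_rng(5)
        cont = simulate_stratified_counts(rng, baseline=0.05, log_or=0.0)
        assert len(cont.strata) == 4
        for s in cont.strata:
            assert s.a + s.b == 500 and s.c + s.d == 500

    def test_recovers_large_effect(self):
        rng = np.random.default_rng(6)
        res = meta_analyze(
            simulate_stratified_counts(rng, n_case=2000, n_control=2000, log_or=np.log(3))
        )
        finalize_meta_family([res])
        assert res.pooled.ci_low < 3.0 < res.pooled.ci_high


class TestFixtureFromCounts:
    def test_degenerate_zero_carriers(self):
        ds = fixture_from_counts(0, 5, 0, 5)
        from oncotropism.counting import CarrierKey, build_contingency, site_vs_other_grouping

        cont = build_contingency(
            ds.mutations, ds.samples, CarrierKey("ESR1"), "x",
            site_vs_other_grouping(ds.site_sets(), "liver"),
        )
        assert meta_analyze(cont).untestable

    def test_degenerate_margins_no_crash(self):
        ds = fixture_from_counts(1, 0, 0, 1)
        assert len(ds.samples) == 2
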