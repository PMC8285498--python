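"""Shared fixtures: small hand-written input tables and simulated datasets."""

from __future__ import annotations

import numpy as np
import pytest

from oncotropism.pipeline import AnalysisPlan, prepare
from oncotropism.simulate import (
    CohortSpec,
    GeneSpec,
    NoiseConfig,
    SimConfig,
    generate,
)

MAF_HEADER = (
    "Hugo_Symbol\tChromosome\tStart_Position\tEnd_Position\tReference_Allele\t"
    "Tumor_Seq_Allele2\tVariant_Classification\tHGVSp_Short\t"
    "Tumor_Sample_Barcode\tt_depth\tt_alt_count"
)


def write_tsv(path, lines):
    path.write_text("\n".join(lines) + "\n")
    return path


@pytest.fixture
def maf_file(tmp_path):
    """Three clean rows: a missense, a hotspot missense, and a nonsense."""
    return write_tsv(
        tmp_path / "muts.maf",
        [
            MAF_HEADER,
            "ESR1\tchr6\t152419920\t152419920\tA\tG\tMissense_Mutation\tp.D538G\tS1\t120\t40",
            "TP53\t17\t7577120\t7577120\tC\tT\tNonsense_Mutation\tp.R306*\tS2\t80\t20",
            "MLL\t11\t118352430\t118352430\tG\tA\tMissense_Mutation\tp.A100T\tS1\t60\t15",
        ],
    )


@pytest.fixture
def small_sim_config():
    """Two cohorts, three genes, one injected enrichment + liver tropism."""
    return SimConfig(
        seed=2021,
        cohorts=[
            CohortSpec("COH1", 600, 600),
            CohortSpec("COH2", 600, 600, has_cna=True, has_depth_vaf=False),
        ],
        genes=[
            GeneSpec(
                "ESR1",
                0.05,
                mbc_log_or=float(np.log(4)),
                site_log_or={"liver": float(np.log(3))},
                role="oncogene",
                hotspot_fraction=0.6,
                cna_baseline=0.02,
                cna_mbc_log_or=float(np.log(3)),
            ),
            GeneSpec("TP53", 0.30, role="tsg", truncating_fraction=0.5),
            GeneSpec("PIK3CA", 0.20),
        ],
    )


@pytest.fixture
def small_dataset(small_sim_config):
    return generate(small_sim_config)


@pytest.fixture
def small_prepared(small_dataset):
    dataset, _truth = small_dataset
    return prepare(dataset)


@pytest.fixture
def default_plan():
    return AnalysisPlan()


@pytest.fixture
def quiet_noise():
    """All filter-fodder rates zero (clean signal)."""
    return NoiseConfig(
        silent_rate=0.0,
        low_depth_rate=0.0,
        low_vaf_rate=0.0,
        duplicate_rate=0.0,
        outlier_rate=0.0,
        cna_low_rate=0.0,
    )
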