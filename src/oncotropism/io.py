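"""Readers and writers for the tabular formats the pipeline touches.

Somatic variant calls arrive as MAF-style tab-delimited tables (GRCh37
coordinates, the MAF ``Variant_Classification`` vocabulary, HGVSp-short
protein changes), copy-number calls as gene-level integer matrices or long
tables, and clinical/panel/alias metadata as plain TSV.  Cohorts differ in
column naming and vocabulary; everything is normalized here, before any
analysis sees the data.

Parsing is *total*: every input row becomes exactly one record or one logged
rejection carrying a reason code, so record + rejection counts always equal
the input row count.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple, Sequence

import pandas as pd

logger = logging.getLogger("oncotropism")

# Full MAF controlled vocabulary (closed set; QC later restricts to an
# allow-list of protein-affecting classes).
MAF_VARIANT_CLASSES = frozenset(
    {
        "Frame_Shift_Del",
        "Frame_Shift_Ins",
        "In_Frame_Del",
        "In_Frame_Ins",
        "Missense_Mutation",
        "Nonsense_Mutation",
        "Nonstop_Mutation",
        "Splice_Region",
        "Splice_Site",
        "Translation_Start_Site",
        "Silent",
        "Intron",
        "5'Flank",
        "3'Flank",
        "5'UTR",
        "3'UTR",
        "IGR",
        "RNA",
        "Targeted_Region",
    }
)

#: Gene-level CNA call levels; -1.5 is the MSK-style shallow-deletion code,
#: retained at read time and filtered during harmonization.
CNA_LEVELS = frozenset({-2.0, -1.5, -1.0, 1.0, 2.0})

#: WTSI-style categorical CNA labels mapped onto the integer scale.
CNA_LABELS: Mapping[str, float] = {"AMP": 2.0, "HOM_DEL": -2.0}

MISSING_TOKENS = {"", ".", "NA", "N/A", "NAN", "NONE", "NULL"}


class Rejection(NamedTuple):
    """One input row that could not become a record, and why."""

    row: int
    reason: str
    detail: str = ""


@dataclass(slots=True)
class MutationRecord:
    """One harmonized somatic variant call attached to a sample and cohort."""

    sample_id: str
    cohort: str
    gene: str
    chrom: str
    pos_start: int
    pos_end: int
    ref_allele: str
    alt_allele: str
    variant_classification: str
    protein_change: str = ""
    depth: int | None = None
    vaf: float | None = None
    flags: tuple[str, ...] = ()


@dataclass(slots=True)
class CnaRecord:
    """Gene-level copy-number call for one sample (non-zero levels only)."""

    sample_id: str
    cohort: str
    gene: str
    level: float


@dataclass(slots=True)
class SampleRecord:
    """Clinical and sequencing metadata driving eligibility and grouping."""

    sample_id: str
    patient_id: str
    cohort: str
    tumor_type: str  # "primary" | "metastasis"
    biopsy_site: str = ""
    sex: str = "unknown"  # "female" | "male" | "unknown"
    histology: str = "NA"  # "IDC" | "ILC" | "Other" | "NA"
    hr_status: str = "NA"  # "pos" | "neg" | "NA"
    her2_status: str = "NA"
    treatment_status: str = "NA"  # naive_primary | denovo_metastasis |
    # post_treatment_metastasis | NA
    age: float | None = None
    panel_id: str = ""


@dataclass(slots=True)
class PanelDefinition:
    """A targeted-sequencing panel: its gene set and coverage style.

    ``full_exonic`` is False for hotspot-only panels, which are excluded
    from sample selection because carrier status cannot be called for
    off-hotspot variants.
    """

    panel_id: str
    genes: frozenset[str]
    full_exonic: bool = True


# ---------------------------------------------------------------------------
# column maps

#: Canonical MAF column names for each internal field.
MAF_COLUMN_MAP: Mapping[str, str] = {
    "sample_id": "Tumor_Sample_Barcode",
    "gene": "Hugo_Symbol",
    "chrom": "Chromosome",
    "pos_start": "Start_Position",
    "pos_end": "End_Position",
    "ref_allele": "Reference_Allele",
    "alt_allele": "Tumor_Seq_Allele2",
    "variant_classification": "Variant_Classification",
    "protein_change": "HGVSp_Short",
    "depth": "t_depth",
    "alt_count": "t_alt_count",
}

#: Named per-source presets.  The cohorts the pipeline was built around all
#: distribute (or are converted upstream into) standard MAF columns, so the
#: presets share the generic mapping; a genuinely different dialect is
#: expressed by passing a custom ``column_map`` or editing config.
COLUMN_MAP_PRESETS: Mapping[str, Mapping[str, str]] = {
    name: MAF_COLUMN_MAP
    for name in ("maf", "genie", "msk", "fmad", "wtsi", "inserm", "tcga")
}

_REQUIRED_FIELDS = (
    "sample_id",
    "gene",
    "chrom",
    "pos_start",
    "pos_end",
    "ref_allele",
    "alt_allele",
    "variant_classification",
)

REASON_NO_ALLELES = "no reference allele, alternative allele"
REASON_IDENTICAL_ALLELES = "identical reference and alternative alleles"
REASON_BAD_COORDINATE = "bad coordinate"
REASON_UNKNOWN_CLASSIFICATION = "unknown classification"
REASON_BAD_VAF = "invalid vaf"
REASON_BAD_LEVEL = "level outside closed set"


def normalize_chrom(label: str) -> str:
    """Strip a leading ``chr`` prefix and uppercase X/Y/MT."""
    label = str(label).strip()
    if label.lower().startswith("chr"):
        label = label[3:]
    return label.upper() if label.lower() in {"x", "y", "mt", "m"} else label


def _is_missing(value) -> bool:
    if value is None:
        return True
    if isinstance(value, float) and math.isnan(value):
        return True
    return str(value).strip().upper() in MISSING_TOKENS


def _clean_allele(value) -> str:
    return "" if _is_missing(value) else str(value).strip().upper()


def read_mutations(
    path: str | Path,
    cohort_label: str,
    column_map: str | Mapping[str, str] | None = None,
) -> tuple[list[MutationRecord], list[Rejection]]:
    """Read a MAF-style tab-delimited mutation table.

    Parameters
    ----------
    path:
        Tab-delimited file with a header line.  Lines starting with ``#``
        (MAF version pragmas) are skipped.
    cohort_label:
        Cohort the records belong to; stamped on every record.
    column_map:
        Either a preset name (``"maf"``, ``"genie"``, ...) or an explicit
        mapping from internal field names to file column names.

    Returns
    -------
    (records, rejections):
        Row order is preserved in ``records``; each rejected row appears in
        ``rejections`` with its 0-based row index and a reason code.

    Raises
    ------
    ValueError
        If a required column is absent from the file.
    """
    if column_map is None:
        column_map = MAF_COLUMN_MAP
    elif isinstance(column_map, str):
        column_map = COLUMN_MAP_PRESETS[column_map]

    frame = pd.read_csv(path, sep="\t", dtype=str, comment="#", keep_default_na=False)
    for fld in _REQUIRED_FIELDS:
        col = column_map.get(fld)
        if col is None or col not in frame.columns:
            raise ValueError(f"required column missing: {fld!r} (expected {col!r})")

    def col(fld):
        name = column_map.get(fld)
        return name if name in frame.columns else None

    records: list[MutationRecord] = []
    rejections: list[Rejection] = []
    for i, row in enumerate(frame.itertuples(index=False)):
        row = dict(zip(frame.columns, row))
        ref = _clean_allele(row[column_map["ref_allele"]])
        alt = _clean_allele(row[column_map["alt_allele"]])
        if not ref and not alt:
            rejections.append(Rejection(i, REASON_NO_ALLELES))
            continue
        # MAF encodes a pure insertion/deletion with "-" on one side
        ref = ref or "-"
        alt = alt or "-"
        if ref == alt:
            rejections.append(Rejection(i, REASON_IDENTICAL_ALLELES, ref))
            continue
        try:
            pos_start = int(float(row[column_map["pos_start"]]))
            pos_end = int(float(row[column_map["pos_end"]]))
        except (TypeError, ValueError):
            rejections.append(Rejection(i, REASON_BAD_COORDINATE))
            continue
        if pos_start <= 0 or pos_start > pos_end:
            rejections.append(
                Rejection(i, REASON_BAD_COORDINATE, f"{pos_start}-{pos_end}")
            )
            continue
        vclass = str(row[column_map["variant_classification"]]).strip()
        if vclass not in MAF_VARIANT_CLASSES:
            rejections.append(Rejection(i, REASON_UNKNOWN_CLASSIFICATION, vclass))
            continue

        depth: int | None = None
        vaf: float | None = None
        c = col("depth")
        if c is not None and not _is_missing(row[c]):
            try:
                depth = int(float(row[c]))
            except ValueError:
                depth = None
        c = col("vaf")
        if c is not None and not _is_missing(row[c]):
            try:
                vaf = float(row[c])
            except ValueError:
                vaf = None
        elif depth is not None and col("alt_count") is not None:
            raw = row[col("alt_count")]
            if not _is_missing(raw) and depth > 0:
                try:
                    vaf = float(raw) / depth
                except ValueError:
                    vaf = None
        if vaf is not None and not (0.0 <= vaf <= 1.0):
            rejections.append(Rejection(i, REASON_BAD_VAF, f"{vaf}"))
            continue

        pchange = ""
        c = col("protein_change")
        if c is not None and not _is_missing(row[c]):
            pchange = str(row[c]).strip()

        records.append(
            MutationRecord(
                sample_id=str(row[column_map["sample_id"]]).strip(),
                cohort=cohort_label,
                gene=str(row[column_map["gene"]]).strip(),
                chrom=normalize_chrom(row[column_map["chrom"]]),
                pos_start=pos_start,
                pos_end=pos_end,
                ref_allele=ref,
                alt_allele=alt,
                variant_classification=vclass,
                protein_change=pchange,
                depth=depth,
                vaf=vaf,
            )
        )
    if rejections:
        logger.info(
            "read_mutations(%s): %d records, %d rejections",
            cohort_label,
            len(records),
            len(rejections),
        )
    return records, rejections


def harmonize_symbols(
    records: Sequence[MutationRecord | CnaRecord],
    alias_table: Mapping[str, str],
    canonical_symbols: Iterable[str] | None = None,
) -> tuple[list, list[tuple[str, str, int]]]:
    """Rewrite legacy gene symbols (e.g. MLL → KMT2A) to HGNC symbols.

    Idempotent: symbols already canonical pass through untouched.  When a
    ``canonical_symbols`` universe is supplied, symbols found in neither it
    nor the alias table are kept but flagged ``unrecognized_symbol``.

    Returns the rewritten records and a rename log of (old, new, count).
    """
    canonical = frozenset(canonical_symbols) if canonical_symbols is not None else None
    counts: dict[tuple[str, str], int] = {}
    out: list = []
    for rec in records:
        gene = rec.gene
        if gene in alias_table and alias_table[gene] != gene:
            new = alias_table[gene]
            counts[(gene, new)] = counts.get((gene, new), 0) + 1
            rec = replace(rec, gene=new)
        elif (
            canonical is not None
            and gene not in canonical
            and isinstance(rec, MutationRecord)
            and "unrecognized_symbol" not in rec.flags
        ):
            rec = replace(rec, flags=rec.flags + ("unrecognized_symbol",))
        out.append(rec)
    log = sorted((old, new, n) for (old, new), n in counts.items())
    return out, log


def read_cna(
    path: str | Path, cohort_label: str
) -> tuple[list[CnaRecord], list[Rejection]]:
    """Read gene-level CNA calls from a long table or a gene × sample matrix.

    Zero levels mean "no alteration" and emit nothing.  Non-numeric labels
    ``AMP`` / ``HOM_DEL`` map to +2 / −2.  Values outside the closed level
    set are rejected with a reason.
    """
    frame = pd.read_csv(path, sep="\t", dtype=str, comment="#", keep_default_na=False)
    cols_lower = {c.lower(): c for c in frame.columns}
    records: list[CnaRecord] = []
    rejections: list[Rejection] = []

    def emit(i: int, sample: str, gene: str, raw) -> None:
        if _is_missing(raw):
            return
        text = str(raw).strip()
        if text.upper() in CNA_LABELS:
            level = CNA_LABELS[text.upper()]
        else:
            try:
                level = float(text)
            except ValueError:
                rejections.append(Rejection(i, REASON_BAD_LEVEL, text))
                return
            if level == 0:
                return
            if level not in CNA_LEVELS:
                rejections.append(Rejection(i, REASON_BAD_LEVEL, text))
                return
        records.append(CnaRecord(str(sample), cohort_label, str(gene), level))

    if {"sample_id", "gene", "level"} <= set(cols_lower):
        for i, row in enumerate(frame.itertuples(index=False)):
            row = dict(zip(frame.columns, row))
            emit(
                i,
                row[cols_lower["sample_id"]],
                row[cols_lower["gene"]],
                row[cols_lower["level"]],
            )
    else:
        # cBioPortal-style matrix: first column Hugo_Symbol, one column per sample
        gene_col = cols_lower.get("hugo_symbol", frame.columns[0])
        sample_cols = [c for c in frame.columns if c != gene_col]
        for i, row in enumerate(frame.itertuples(index=False)):
            row = dict(zip(frame.columns, row))
            for sample in sample_cols:
                emit(i, sample, row[gene_col], row[sample])
    return records, rejections


# ---------------------------------------------------------------------------
# clinical vocabulary

DEFAULT_VOCAB: Mapping[str, Mapping[str, str]] = {
    "tumor_type": {
        "primary": "primary",
        "metastasis": "metastasis",
        "metastatic": "metastasis",
        "local recurrence": "metastasis",
    },
    "sex": {"female": "female", "f": "female", "male": "male", "m": "male"},
    "histology": {
        "idc": "IDC",
        "ilc": "ILC",
        "ductal": "IDC",
        "lobular": "ILC",
        "breast invasive ductal carcinoma": "IDC",
        "breast invasive lobular carcinoma": "ILC",
        "others": "Other",
        "other": "Other",
    },
    "receptor": {
        "pos": "pos",
        "positive": "pos",
        "+": "pos",
        "1": "pos",
        "neg": "neg",
        "negative": "neg",
        "-": "neg",
        "0": "neg",
    },
    "treatment_status": {
        "naive_primary": "naive_primary",
        "treatment-naive primary": "naive_primary",
        "denovo_metastasis": "denovo_metastasis",
        "de novo metastasis": "denovo_metastasis",
        "post_treatment_metastasis": "post_treatment_metastasis",
        "post-treatment metastasis": "post_treatment_metastasis",
    },
}

_CLINICAL_COLUMNS = {
    "sample_id": "sample_id",
    "patient_id": "patient_id",
    "tumor_type": "tumor_type",
    "biopsy_site": "biopsy_site",
    "sex": "sex",
    "histology": "histology",
    "hr_status": "hr_status",
    "her2_status": "her2_status",
    "treatment_status": "treatment_status",
    "age": "age",
    "panel_id": "panel_id",
}


def _map_vocab(raw, vocab: Mapping[str, str], default: str, field_name: str) -> str:
    if _is_missing(raw):
        return default
    key = str(raw).strip()
    mapped = vocab.get(key) or vocab.get(key.lower())
    if mapped is None:
        logger.warning("unmapped %s label %r -> %s", field_name, key, default)
        return default
    return mapped


def read_clinical(
    path: str | Path,
    cohort_label: str,
    vocab_map: Mapping[str, Mapping[str, str]] | None = None,
) -> list[SampleRecord]:
    """Read a clinical sample table, enforcing controlled vocabularies.

    ``vocab_map`` overlays the default label maps per field (cohorts spell
    histology and receptor status differently).  Unmapped labels become NA
    with a warning; an unmapped ``tumor_type`` or a duplicate ``sample_id``
    is a hard error.
    """
    vocab = {k: dict(v) for k, v in DEFAULT_VOCAB.items()}
    if vocab_map:
        for fld, mapping in vocab_map.items():
            vocab.setdefault(fld, {}).update(mapping)

    frame = pd.read_csv(path, sep="\t", dtype=str, comment="#", keep_default_na=False)
    if "sample_id" not in frame.columns or "tumor_type" not in frame.columns:
        raise ValueError("clinical table requires sample_id and tumor_type columns")

    samples: list[SampleRecord] = []
    seen: set[str] = set()
    for row in frame.itertuples(index=False):
        row = dict(zip(frame.columns, row))
        sid = str(row["sample_id"]).strip()
        if sid in seen:
            raise ValueError(f"duplicate sample_id: {sid}")
        seen.add(sid)
        tumor_type = _map_vocab(row["tumor_type"], vocab["tumor_type"], "", "tumor_type")
        if tumor_type not in {"primary", "metastasis"}:
            raise ValueError(f"unresolvable tumor_type for sample {sid}")
        age = None
        if not _is_missing(row.get("age")):
            try:
                age = float(row["age"])
            except ValueError:
                age = None
        samples.append(
            SampleRecord(
                sample_id=sid,
                patient_id=str(row.get("patient_id", sid)).strip() or sid,
                cohort=cohort_label,
                tumor_type=tumor_type,
                biopsy_site=str(row.get("biopsy_site", "")).strip(),
                sex=_map_vocab(row.get("sex"), vocab["sex"], "unknown", "sex"),
                histology=_map_vocab(
                    row.get("histology"), vocab["histology"], "NA", "histology"
                ),
                hr_status=_map_vocab(
                    row.get("hr_status"), vocab["receptor"], "NA", "hr_status"
                ),
                her2_status=_map_vocab(
                    row.get("her2_status"), vocab["receptor"], "NA", "her2_status"
                ),
                treatment_status=_map_vocab(
                    row.get("treatment_status"),
                    vocab["treatment_status"],
                    "NA",
                    "treatment_status",
                ),
                age=age,
                panel_id=str(row.get("panel_id", "")).strip(),
            )
        )
    return samples


def read_panels(path: str | Path) -> dict[str, PanelDefinition]:
    """Read a panel table (panel_id, gene[, full_exonic]) into definitions."""
    frame = pd.read_csv(path, sep="\t", dtype=str, comment="#", keep_default_na=False)
    if not {"panel_id", "gene"} <= set(frame.columns):
        raise ValueError("panel table requires panel_id and gene columns")
    panels: dict[str, PanelDefinition] = {}
    genes: dict[str, set[str]] = {}
    exonic: dict[str, bool] = {}
    for row in frame.itertuples(index=False):
        row = dict(zip(frame.columns, row))
        pid = str(row["panel_id"]).strip()
        genes.setdefault(pid, set()).add(str(row["gene"]).strip())
        if "full_exonic" in frame.columns and not _is_missing(row["full_exonic"]):
            exonic[pid] = str(row["full_exonic"]).strip().lower() in {
                "1",
                "true",
                "yes",
            }
    for pid, gset in genes.items():
        if not gset:
            raise ValueError(f"panel {pid} has no genes")
        panels[pid] = PanelDefinition(pid, frozenset(gset), exonic.get(pid, True))
    return panels


def read_alias(path: str | Path) -> dict[str, str]:
    """Read an old-symbol → HGNC-symbol alias table."""
    frame = pd.read_csv(path, sep="\t", dtype=str, comment="#", keep_default_na=False)
    if frame.shape[1] < 2:
        raise ValueError("alias table requires two columns (old, new)")
    old_col, new_col = frame.columns[:2]
    table: dict[str, str] = {}
    for row in frame.itertuples(index=False):
        row = dict(zip(frame.columns, row))
        old, new = str(row[old_col]).strip(), str(row[new_col]).strip()
        if old in table and table[old] != new:
            raise ValueError(f"alias table maps {old!r} to multiple targets")
        table[old] = new
    return table


# ---------------------------------------------------------------------------
# report writing

#: Column layouts per report kind; rows come from the result objects'
#: ``to_row`` methods (stats / pipeline / drivers modules).
REPORT_COLUMNS: Mapping[str, tuple[str, ...]] = {
    "meta": (
        "feature",
        "mutation_type",
        "comparison",
        "n_strata",
        "or",
        "ci_low",
        "ci_high",
        "p",
        "q",
        "i2",
        "het_p",
        "het_q",
        "tau2",
        "model",
    ),
    "regression": (
        "feature",
        "mutation_type",
        "comparison",
        "or",
        "ci_low",
        "ci_high",
        "p",
        "q",
        "converged",
        "separation",
    ),
    "organotropism": (
        "gene",
        "site_set",
        "direction",
        "vs_pbc_or",
        "vs_pbc_q",
        "vs_other_or",
        "vs_other_q",
        "subtype_robust",
    ),
    "driver": (
        "variant",
        "gene",
        "role",
        "pattern",
        "func_score",
        "carriers",
        "eligible",
        "vs_pbc_or",
        "vs_pbc_q",
        "top_site",
        "top_site_or",
        "top_site_q",
    ),
    "contingency": ("feature", "mutation_type", "comparison", "cohort", "a", "b", "c", "d"),
    "qc": ("stage", "reason", "count"),
}

FLOAT_FORMAT = "%.6g"


def write_report(results: Iterable, path: str | Path, kind: str) -> None:
    """Write analysis results as a deterministic tab-delimited report.

    ``results`` is any iterable of objects exposing ``to_row(kind)`` (or
    plain dicts); column order is fixed per ``kind`` and floats are rendered
    with 6 significant digits so identical runs produce identical bytes.
    """
    if kind not in REPORT_COLUMNS:
        raise ValueError(f"unknown report kind: {kind!r}")
    columns = REPORT_COLUMNS[kind]
    rows = []
    for res in results:
        row = res if isinstance(res, dict) else res.to_row(kind)
        rows.append({c: row.get(c, "") for c in columns})
    frame = pd.DataFrame(rows, columns=list(columns))
    frame.to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT)


def read_report(path: str | Path) -> pd.DataFrame:
    """Read back a report written by :func:`write_report`."""
    return pd.read_csv(path, sep="\t")
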