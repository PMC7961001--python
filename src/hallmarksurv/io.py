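"""Readers and writers for the standard file formats the pipeline touches.

Supported formats: TSV count matrices (genes on rows, samples in the
header), MatrixMarket MTX triplets with row/column name sidecars, clinical
TSV tables, MAF mutation tables, and GMT gene-set files. All writers emit
UTF-8, tab-separated text with '.' decimals and deterministic row order, so
write-then-read round-trips are exact.
"""

from __future__ import annotations

import csv
import re
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from .containers import (
    CLINICAL_COLUMNS,
    ClinicalTable,
    CountMatrix,
    ExpressionMatrix,
    GeneSet,
    GeneSetCollection,
    MutationTable,
)
from .errors import FormatError, ValidationError

__all__ = [
    "read_counts",
    "write_counts",
    "read_expression",
    "write_expression",
    "read_clinical",
    "write_clinical",
    "read_maf",
    "write_maf",
    "read_gmt",
    "write_gmt",
    "read_gene_mapping",
]

#: Tokens treated as missing wherever a value is optional (case-insensitive).
MISSING_TOKENS = {"", "na", "nan"}

_ROMAN = {"i": 1, "ii": 2, "iii": 3, "iv": 4, "0": 0}

_MAF_REQUIRED = ("Hugo_Symbol", "Tumor_Sample_Barcode", "Variant_Classification")


def _is_missing(token) -> bool:
    if token is None or (isinstance(token, float) and np.isnan(token)):
        return True
    return str(token).strip().lower() in MISSING_TOKENS


# ---------------------------------------------------------------------------
# count / expression matrices
# ---------------------------------------------------------------------------


def read_counts(
    path: str | Path,
    format: str = "tsv",
    gene_mapping: dict[str, str] | None = None,
) -> CountMatrix:
    """Read a raw count matrix.

    ``format='tsv'`` expects gene ids in the first column and sample ids in
    the header. ``format='mtx'`` expects a MatrixMarket triplet file plus
    sidecar files ``<stem>.rownames.txt`` / ``<stem>.colnames.txt`` with one
    identifier per line. ``gene_mapping`` optionally renames gene ids at
    load (e.g. a user-supplied Ensembl-to-symbol table).
    """
    path = Path(path)
    if format == "tsv":
        df = _read_matrix_tsv(path)
    elif format == "mtx":
        df = _read_matrix_mtx(path)
    else:
        raise ValueError(f"unknown count format {format!r}")
    if gene_mapping:
        df.index = [gene_mapping.get(g, g) for g in df.index]
    values = df.to_numpy()
    if np.any(values != np.floor(values)):
        raise ValidationError(f"non-integer counts in {path}")
    return CountMatrix(df)


def _read_matrix_tsv(path: Path) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep="\t", index_col=0)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise FormatError(f"cannot parse matrix TSV {path}: {exc}") from exc
    if df.columns.size == 0:
        raise FormatError(f"{path}: header has no sample columns")
    if df.index.hasnans or any(_is_missing(g) for g in df.index):
        raise FormatError(f"{path}: empty gene id in first column")
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    df.index.name = None
    df.columns.name = None
    return df


def _read_matrix_mtx(path: Path) -> pd.DataFrame:
    stem = path.with_suffix("")
    rows_file = stem.with_suffix(".rownames.txt")
    cols_file = stem.with_suffix(".colnames.txt")
    for sidecar in (rows_file, cols_file):
        if not sidecar.exists():
            raise FormatError(f"missing MTX sidecar {sidecar}")
    matrix = scipy.io.mmread(path)
    genes = rows_file.read_text().split()
    samples = cols_file.read_text().split()
    dense = np.asarray(matrix.todense() if scipy.sparse.issparse(matrix) else matrix)
    if dense.shape != (len(genes), len(samples)):
        raise FormatError(
            f"{path}: matrix shape {dense.shape} does not match sidecars "
            f"({len(genes)} genes, {len(samples)} samples)"
        )
    return pd.DataFrame(dense, index=genes, columns=samples)


def write_counts(matrix: CountMatrix, path: str | Path) -> None:
    matrix.data.to_csv(path, sep="\t", index_label="gene_id")


def read_expression(path: str | Path, stage: str = "mean_rescaled") -> ExpressionMatrix:
    df = _read_matrix_tsv(Path(path))
    return ExpressionMatrix(df.astype(float), stage=stage)


def write_expression(expr: ExpressionMatrix, path: str | Path) -> None:
    expr.data.to_csv(path, sep="\t", index_label="gene_id", float_format="%.10g")


# ---------------------------------------------------------------------------
# clinical tables
# ---------------------------------------------------------------------------


def parse_stage(token) -> float:
    """Map a stage string to its ordinal 0-4.

    Accepts Roman numerals and arabic digits, with or without a "Stage "
    prefix; sub-stages (IIa, IIIb) truncate to the major stage.
    """
    if _is_missing(token):
        return np.nan
    text = str(token).strip().lower()
    text = re.sub(r"^stage\s*", "", text)
    m = re.match(r"^(iv|iii|ii|i|[0-4])\s*[abc]?$", text)
    if not m:
        raise ValidationError(f"unparseable stage {token!r}")
    key = m.group(1)
    return float(_ROMAN[key] if key in _ROMAN else int(key))


def _parse_float(token, what: str, sample: str) -> float:
    if _is_missing(token):
        return np.nan
    try:
        return float(token)
    except (TypeError, ValueError) as exc:
        raise ValidationError(f"unparseable {what} {token!r} for sample {sample}") from exc


def _parse_event(token, what: str, sample: str) -> float:
    value = _parse_float(token, what, sample)
    if not np.isnan(value) and value not in (0.0, 1.0):
        raise ValidationError(f"{what} must be 0/1, got {token!r} for sample {sample}")
    return value


def _parse_category(token, allowed: dict[str, str] | None = None):
    if _is_missing(token):
        return np.nan
    text = str(token).strip()
    if allowed is not None:
        key = text.lower()
        if key not in allowed:
            raise ValidationError(f"unexpected category {token!r}")
        return allowed[key]
    return text


def read_clinical(path: str | Path) -> ClinicalTable:
    """Read a clinical TSV into a validated :class:`ClinicalTable`.

    Requires a ``sample_id`` column plus at least one (time, event) pair;
    optional columns are filled with missing values. Tokens "", "NA" and
    "NaN" (any case) are missing.
    """
    path = Path(path)
    raw = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if "sample_id" not in raw.columns:
        raise FormatError(f"{path}: no sample_id column")
    has_os = {"os_time", "os_event"} <= set(raw.columns)
    has_rfs = {"rfs_time", "rfs_event"} <= set(raw.columns)
    if not (has_os or has_rfs):
        raise FormatError(f"{path}: need os_time/os_event or rfs_time/rfs_event columns")

    records = {}
    sex_map = {"f": "F", "m": "M", "female": "F", "male": "M"}
    grade_map = {"low": "low", "high": "high"}
    for _, row in raw.iterrows():
        sid = str(row["sample_id"]).strip()
        if not sid or sid in records:
            raise ValidationError(f"missing or duplicate sample_id {sid!r} in {path}")
        get = lambda col: row[col] if col in raw.columns else ""
        records[sid] = {
            "os_time": _parse_float(get("os_time"), "os_time", sid),
            "os_event": _parse_event(get("os_event"), "os_event", sid),
            "rfs_time": _parse_float(get("rfs_time"), "rfs_time", sid),
            "rfs_event": _parse_event(get("rfs_event"), "rfs_event", sid),
            "sex": _parse_category(get("sex"), sex_map),
            "race": _parse_category(get("race")),
            "stage": parse_stage(get("stage")),
            "grade": _parse_category(get("grade"), grade_map),
            "age": _parse_float(get("age"), "age", sid),
        }
    df = pd.DataFrame.from_dict(records, orient="index", columns=CLINICAL_COLUMNS)
    df.index.name = "sample_id"
    return ClinicalTable(df)


def write_clinical(clinical: ClinicalTable, path: str | Path) -> None:
    df = clinical.data.copy()
    for col in ("os_event", "rfs_event", "stage"):
        df[col] = df[col].map(lambda v: "" if pd.isna(v) else str(int(v)))
    df.to_csv(path, sep="\t", index_label="sample_id", na_rep="", float_format="%.10g")


# ---------------------------------------------------------------------------
# MAF mutation tables
# ---------------------------------------------------------------------------


def read_maf(path: str | Path) -> MutationTable:
    """Read a MAF file (tab-separated, '#' comment lines, header-driven)."""
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", comment="#", dtype=str, keep_default_na=False)
    except Exception as exc:
        raise FormatError(f"cannot parse MAF {path}: {exc}") from exc
    missing = [c for c in _MAF_REQUIRED if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: MAF lacks mandatory columns {missing}")
    table = pd.DataFrame(
        {
            "sample_id": df["Tumor_Sample_Barcode"].str.strip(),
            "gene_symbol": df["Hugo_Symbol"].str.strip(),
            "variant_classification": df["Variant_Classification"].str.strip(),
        }
    )
    return MutationTable(table)


def write_maf(mutations: MutationTable, path: str | Path) -> None:
    out = pd.DataFrame(
        {
            "Hugo_Symbol": mutations.data["gene_symbol"],
            "Tumor_Sample_Barcode": mutations.data["sample_id"],
            "Variant_Classification": mutations.data["variant_classification"],
        }
    )
    out.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# GMT gene sets
# ---------------------------------------------------------------------------


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a GMT file: one set per line, ``name TAB description TAB genes...``.

    Duplicate genes within one set are deduplicated (first occurrence
    order kept); overlap across sets is preserved.
    """
    path = Path(path)
    sets = []
    with open(path, encoding="utf-8", newline="") as fh:
        for lineno, fields in enumerate(csv.reader(fh, delimiter="\t"), start=1):
            if not fields or (len(fields) == 1 and not fields[0].strip()):
                continue
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: GMT line has < 3 fields")
            name, description = fields[0].strip(), fields[1].strip()
            genes = []
            for g in fields[2:]:
                g = g.strip()
                if g and g not in genes:
                    genes.append(g)
            if not genes:
                raise FormatError(f"{path}:{lineno}: gene set {name!r} has no genes")
            sets.append(GeneSet(name, description, tuple(genes)))
    return GeneSetCollection(tuple(sets))


def write_gmt(sets: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for name in sets:
            s = sets[name]
            fh.write("\t".join([s.name, s.description, *s.genes]) + "\n")


def example_hallmarks() -> GeneSetCollection:
    """Bundled illustrative gene-set collection: eight small synthetic sets
    named after the cancer hallmarks, with gene ids matching the synthetic
    count generator (not a real hallmark catalog)."""
    from importlib import resources

    with resources.as_file(
        resources.files("hallmarksurv") / "data" / "example_hallmarks.gmt"
    ) as path:
        return read_gmt(path)


def read_gene_mapping(path: str | Path) -> dict[str, str]:
    """Read a two-column TSV mapping (source id -> gene symbol), no header."""
    mapping = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 2:
                raise FormatError(f"{path}:{lineno}: expected two columns")
            mapping[fields[0].strip()] = fields[1].strip()
    return mapping
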