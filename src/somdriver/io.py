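"""Readers and writers for somatic-mutation tables.

Three tabular inputs are supported:

* MAF (mutation annotation format) cohort files — tab-separated with the
  standard TCGA column vocabulary (``Hugo_Symbol``,
  ``Tumor_Sample_Barcode``, ``Variant_Classification`` and an HGVS-style
  CDS-change column such as ``HGVSc``).
* A reference-mutation TSV dialect with columns
  ``gene``, ``sample``, ``cds_pos``, ``variant_class`` — the format the
  reference step consumes (a COSMIC mutant export can be converted to it
  with ``scripts/convert_cosmic.py``).
* A CDS-length TSV: ``gene <TAB> [transcript <TAB>] cds_length``.

Variant classifications are mapped onto three method categories:
OG mutations (missense + in-frame indels), TSG mutations (nonsense +
frameshift indels) and SILENT (synonymous).  Everything else — splice
site, nonstop, translation start, UTR, intron, RNA — is EXCLUDED and
counted in the load report; the method defines no category for it.

All mutation tables are returned as :class:`pandas.DataFrame` with
columns ``gene``, ``sample``, ``cds_pos`` (nullable integer),
``pos_valid`` (bool), ``category`` and ``source_class``.
"""

from __future__ import annotations

import contextlib
import os
import re
import tempfile
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterator, Mapping

import pandas as pd


class Category(str, Enum):
    """Method-level mutation category."""

    OG = "OG"
    TSG = "TSG"
    SILENT = "SILENT"
    EXCLUDED = "EXCLUDED"


# Standard MAF Variant_Classification vocabulary, lower-cased.
_OG_CLASSES = {"missense_mutation", "in_frame_ins", "in_frame_del"}
_TSG_CLASSES = {"nonsense_mutation", "frame_shift_ins", "frame_shift_del"}
_SILENT_CLASSES = {"silent", "synonymous", "synonymous_variant"}


@dataclass(frozen=True)
class MutationRecord:
    """One somatic mutation call."""

    gene: str
    sample: str
    category: Category
    cds_pos: int | None = None
    source_class: str = ""


@dataclass
class LoadReport:
    """Row-level accounting for one table load."""

    n_rows: int = 0
    per_category: dict[str, int] = field(default_factory=dict)
    n_missing_pos: int = 0
    n_pos_out_of_range: int = 0
    n_duplicates_collapsed: int = 0
    n_unrecognized_class: int = 0

    def as_dict(self) -> dict[str, object]:
        return {
            "n_rows": self.n_rows,
            "per_category": dict(self.per_category),
            "n_missing_pos": self.n_missing_pos,
            "n_pos_out_of_range": self.n_pos_out_of_range,
            "n_duplicates_collapsed": self.n_duplicates_collapsed,
            "n_unrecognized_class": self.n_unrecognized_class,
        }


def classify_variant(variant_classification: str) -> Category:
    """Map a MAF ``Variant_Classification`` string onto a method category.

    Matching is case-insensitive; unrecognized strings map to
    :attr:`Category.EXCLUDED` (never raises).
    """
    vc = str(variant_classification).strip().lower()
    if vc in _OG_CLASSES:
        return Category.OG
    if vc in _TSG_CLASSES:
        return Category.TSG
    if vc in _SILENT_CLASSES:
        return Category.SILENT
    return Category.EXCLUDED


_KNOWN_CLASSES = _OG_CLASSES | _TSG_CLASSES | _SILENT_CLASSES | {
    "splice_site",
    "nonstop_mutation",
    "translation_start_site",
    "5'utr",
    "3'utr",
    "5'flank",
    "3'flank",
    "intron",
    "rna",
    "igr",
    "targeted_region",
    "de_novo_start_inframe",
    "de_novo_start_outofframe",
}

_CDS_POS_RE = re.compile(r"c\.\*?\s*(\d+)")


def parse_cds_position(value: object) -> int | None:
    """Extract a 1-based CDS nucleotide position from an HGVS-style string.

    Accepts ``c.1624G>A``, ``c.76_78del`` (first affected nucleotide) or a
    plain integer; returns ``None`` when no position can be parsed.
    """
    if value is None or (isinstance(value, float) and pd.isna(value)):
        return None
    text = str(value).strip()
    if not text or text.lower() in {"nan", "", ".", "-"}:
        return None
    if text.isdigit():
        pos = int(text)
        return pos if pos >= 1 else None
    m = _CDS_POS_RE.search(text)
    if m:
        pos = int(m.group(1))
        return pos if pos >= 1 else None
    return None


# Column aliases accepted for the CDS-change field of a MAF, in priority order.
_MAF_CDS_COLUMNS = ("HGVSc", "cDNA_Change", "CDS_Change", "Mutation_CDS", "CDS_Position")
_MAF_REQUIRED = ("Hugo_Symbol", "Tumor_Sample_Barcode", "Variant_Classification")


def _finalize_table(
    df: pd.DataFrame,
    cds_lengths: Mapping[str, int] | None,
    report: LoadReport,
) -> pd.DataFrame:
    """Classify, validate positions, and collapse duplicate rows."""
    df = df.copy()
    df["category"] = [classify_variant(v).value for v in df["source_class"]]
    unrecognized = ~df["source_class"].str.strip().str.lower().isin(_KNOWN_CLASSES)
    report.n_unrecognized_class = int(unrecognized.sum())

    before = len(df)
    df = df.drop_duplicates(subset=["gene", "sample", "cds_pos", "source_class"])
    report.n_duplicates_collapsed = before - len(df)

    report.n_rows = len(df)
    report.per_category = df["category"].value_counts().to_dict()
    report.n_missing_pos = int(df["cds_pos"].isna().sum())

    # Positions beyond the annotated CDS are kept for count statistics but
    # flagged so per-position tallies can skip them.
    valid = df["cds_pos"].notna()
    if cds_lengths is not None:
        lengths = df["gene"].map(cds_lengths)
        out_of_range = valid & lengths.notna() & (df["cds_pos"] > lengths)
        report.n_pos_out_of_range = int(out_of_range.sum())
        valid = valid & ~out_of_range
    df["pos_valid"] = valid
    df["cds_pos"] = df["cds_pos"].astype("Int64")
    return df.reset_index(drop=True)


def read_maf(
    path: str | Path,
    cds_lengths: Mapping[str, int] | None = None,
    primary_tumour_only: bool = False,
) -> tuple[pd.DataFrame, LoadReport]:
    """Read a MAF cohort file into the internal mutation-table form.

    Parameters
    ----------
    path
        Tab-separated MAF; lines starting with ``#`` are ignored.
    cds_lengths
        Optional gene -> CDS length mapping used to flag out-of-range
        positions.
    primary_tumour_only
        If true and a ``Sample_Type`` column exists, keep only rows whose
        sample type mentions "primary".

    Raises
    ------
    ValueError
        If a mandatory column is missing or the file has no data rows.
    """
    raw = pd.read_csv(path, sep="\t", comment="#", dtype=str, low_memory=False)
    if raw.empty:
        raise ValueError(f"MAF file contains no data rows: {path}")
    for col in _MAF_REQUIRED:
        if col not in raw.columns:
            raise ValueError(f"MAF file is missing mandatory column {col!r}: {path}")
    cds_col = next((c for c in _MAF_CDS_COLUMNS if c in raw.columns), None)
    if cds_col is None:
        raise ValueError(
            "MAF file is missing a CDS-change column "
            f"(one of {', '.join(_MAF_CDS_COLUMNS)}): {path}"
        )
    if primary_tumour_only and "Sample_Type" in raw.columns:
        raw = raw[raw["Sample_Type"].str.contains("primary", case=False, na=False)]

    report = LoadReport()
    df = pd.DataFrame(
        {
            "gene": raw["Hugo_Symbol"].astype(str),
            "sample": raw["Tumor_Sample_Barcode"].astype(str),
            "cds_pos": [parse_cds_position(v) for v in raw[cds_col]],
            "source_class": raw["Variant_Classification"].astype(str),
        }
    )
    return _finalize_table(df, cds_lengths, report), report


def read_mutation_table(
    path: str | Path,
    cds_lengths: Mapping[str, int] | None = None,
) -> tuple[pd.DataFrame, LoadReport]:
    """Read the reference-mutation TSV dialect.

    Expected columns: ``gene``, ``sample``, ``cds_pos``, ``variant_class``
    (``cds_pos`` may be empty; ``variant_class`` uses the MAF vocabulary).
    """
    raw = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    if raw.empty:
        raise ValueError(f"mutation table contains no data rows: {path}")
    for col in ("gene", "sample", "variant_class"):
        if col not in raw.columns:
            raise ValueError(f"mutation table is missing column {col!r}: {path}")
    pos_col = "cds_pos" if "cds_pos" in raw.columns else None
    report = LoadReport()
    df = pd.DataFrame(
        {
            "gene": raw["gene"].astype(str),
            "sample": raw["sample"].astype(str),
            "cds_pos": [parse_cds_position(v) for v in raw[pos_col]]
            if pos_col
            else [None] * len(raw),
            "source_class": raw["variant_class"].astype(str),
        }
    )
    return _finalize_table(df, cds_lengths, report), report


def write_mutation_table(df: pd.DataFrame, path: str | Path) -> None:
    """Write a mutation table in the reference TSV dialect (round-trippable)."""
    out = pd.DataFrame(
        {
            "gene": df["gene"],
            "sample": df["sample"],
            "cds_pos": df["cds_pos"],
            "variant_class": df["source_class"],
        }
    )
    with atomic_write(path) as handle:
        out.to_csv(handle, sep="\t", index=False)


def read_cds_lengths(path: str | Path) -> dict[str, int]:
    """Read a gene -> CDS length (nucleotides) table.

    The file is tab-separated with 2 or 3 columns: gene, optional
    transcript id, CDS length; a header line is detected and skipped.
    Duplicate genes resolve to the longest CDS (canonical = longest).

    Raises
    ------
    ValueError
        On a non-numeric or non-positive length, naming the row.
    """
    lengths: dict[str, int] = {}
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ValueError(f"{path}: row {lineno}: expected >= 2 columns")
            gene, raw_len = fields[0].strip(), fields[-1].strip()
            if lineno == 1 and not raw_len.lstrip("-").isdigit():
                continue  # header line
            try:
                length = int(raw_len)
            except ValueError as exc:
                raise ValueError(
                    f"{path}: row {lineno}: CDS length {raw_len!r} is not an integer"
                ) from exc
            if length < 3:
                raise ValueError(
                    f"{path}: row {lineno}: CDS length must be >= 3, got {length}"
                )
            if gene not in lengths or length > lengths[gene]:
                lengths[gene] = length
    if not lengths:
        raise ValueError(f"CDS-length table contains no data rows: {path}")
    return lengths


def write_cds_lengths(lengths: Mapping[str, int], path: str | Path) -> None:
    with atomic_write(path) as handle:
        handle.write("gene\ttranscript\tcds_length\n")
        for gene in sorted(lengths):
            handle.write(f"{gene}\t{gene}-tx1\t{lengths[gene]}\n")


@contextlib.contextmanager
def atomic_write(path: str | Path) -> Iterator:
    """Write to a temp file in the target directory, rename on success."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=f".{path.name}.", suffix=".tmp")
    try:
        with os.fdopen(fd, "w") as handle:
            yield handle
        os.replace(tmp, path)
    except BaseException:
        with contextlib.suppress(OSError):
            os.unlink(tmp)
        raise
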