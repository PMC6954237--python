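"""Variant-table I/O: VCF v4.2 (via pysam) and TSV, with error collection.

Coordinates are 1-based fully closed throughout, matching VCF. Unknown
INFO keys are carried through as extra columns.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import pysam

CORE_COLUMNS = ["chrom", "pos", "ref", "alt"]
TSV_REQUIRED = ["chrom", "pos", "ref", "alt", "depth", "alt_count"]


@dataclass
class ParseReport:
    """Malformed-record report; parsing aborts when >1% of records fail."""

    n_records: int = 0
    errors: list[tuple[int, str]] = field(default_factory=list)

    @property
    def error_fraction(self) -> float:
        total = self.n_records + len(self.errors)
        return len(self.errors) / total if total else 0.0


class MalformedInputError(ValueError):
    def __init__(self, report: ParseReport, path):
        self.report = report
        lines = "; ".join(f"line {ln}: {msg}" for ln, msg in report.errors[:5])
        super().__init__(
            f"{path}: {len(report.errors)} malformed record(s) "
            f"({report.error_fraction:.1%}) — {lines}")


def read_variants(path, fmt: str | None = None,
                  max_error_fraction: float = 0.01
                  ) -> tuple[pd.DataFrame, ParseReport]:
    """Read a variant table from VCF or TSV into a normalised DataFrame.

    Format is inferred from the suffix when ``fmt`` is None. The returned
    frame always has chrom/pos/ref/alt plus whatever depth/count and INFO
    columns the file provides. Malformed records are collected with their
    line numbers; more than ``max_error_fraction`` of them aborts.
    """
    path = Path(path)
    if fmt is None:
        fmt = "vcf" if path.suffix.lower() == ".vcf" else "tsv"
    if fmt == "vcf":
        return _read_vcf(path, max_error_fraction)
    if fmt == "tsv":
        return _read_tsv(path, max_error_fraction)
    raise ValueError(f"unknown format {fmt!r}; use 'vcf' or 'tsv'")


def _read_vcf(path: Path, max_error_fraction: float):
    report = ParseReport()
    rows = []
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            if rec.alts is None:
                report.errors.append((rec.pos, "record without ALT allele"))
                continue
            row = {"chrom": rec.chrom, "pos": rec.pos, "ref": rec.ref,
                   "alt": rec.alts[0]}
            for key, val in rec.info.items():
                if isinstance(val, tuple) and len(val) == 1:
                    val = val[0]
                row[key.lower()] = True if val is None else val
            rows.append(row)
            report.n_records += 1
    df = pd.DataFrame(rows)
    if report.error_fraction > max_error_fraction:
        raise MalformedInputError(report, path)
    if len(df):
        df = df.rename(columns={"dp": "depth", "alt_count": "alt_count",
                                "gt_gen": "generation", "lineage": "lineage_index",
                                "burst": "is_burst", "zyg": "zygosity"})
        if "is_burst" in df.columns:
            df["is_burst"] = df["is_burst"].notna() & (df["is_burst"] != False)  # noqa: E712
    return df, report


def _read_tsv(path: Path, max_error_fraction: float):
    report = ParseReport()

    def _bad_line(fields):  # wrong field count: record and skip
        report.errors.append((-1, f"bad field count ({len(fields)})"))
        return None

    # pandas handles CRLF transparently
    df = pd.read_csv(path, sep="\t", engine="python", on_bad_lines=_bad_line)
    missing = [c for c in ("chrom", "pos") if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    keep = pd.Series(True, index=df.index)
    for i, row in df.iterrows():
        if pd.isna(row["pos"]):
            report.errors.append((i + 2, "missing position"))
            keep[i] = False
    report.n_records = int(keep.sum())
    if report.error_fraction > max_error_fraction:
        raise MalformedInputError(report, path)
    df = df[keep].copy()
    df["pos"] = df["pos"].astype(int)
    return df, report


def write_variants_tsv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, lineterminator="\n")


def require_columns(df: pd.DataFrame, columns, path="variant table") -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required field(s): {', '.join(missing)}")
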