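"""Readers and writers for the on-disk artifacts the pipeline consumes.

All formats are plain tab-separated text: BED3/BED5 for interval calls,
4-column segment files, TSV matrices (first column = gene id), and a
3-column survival table. Outputs are UTF-8 with ``\\n`` line endings and a
deterministic column order, so write -> read round-trips are identities.

Readers are strict: a malformed line raises :class:`~crcprior.core.ParseError`
naming the line number; rows are never silently dropped.
"""

from __future__ import annotations

import os
from pathlib import Path

import pandas as pd

from .core import (
    CopyNumberSegment,
    ExpressionMatrix,
    GenomicInterval,
    ParseError,
    SampleTable,
    SchemaError,
    SurvivalTable,
    ValidationError,
)

__all__ = [
    "read_bed",
    "write_bed",
    "read_segments",
    "write_segments",
    "read_matrix",
    "write_matrix",
    "read_survival",
    "write_survival",
    "read_genes",
    "write_table",
]


def _normalize_chrom(chrom: str, chrom_prefix: str | None) -> str:
    if chrom_prefix == "add" and not chrom.startswith("chr"):
        return "chr" + chrom
    if chrom_prefix == "strip" and chrom.startswith("chr"):
        return chrom[3:]
    return chrom


def _data_lines(path):
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            yield lineno, line.split("\t")


def read_bed(
    path,
    has_score: bool = False,
    sample_id: str | None = None,
    one_based: bool = False,
    chrom_prefix: str | None = None,
) -> SampleTable:
    """Read a BED3/BED5 file into a sorted, validated :class:`SampleTable`.

    Parameters
    ----------
    has_score
        Parse column 5 (or 4 if only four columns) as the signal score.
    one_based
        Input coordinates are 1-based inclusive; converted to 0-based
        half-open on read.
    chrom_prefix
        ``"add"``/``"strip"`` optionally normalizes the ``chr`` prefix;
        by default chromosome names are taken literally.
    """
    path = Path(path)
    if sample_id is None:
        sample_id = path.stem
    intervals = []
    for lineno, fields in _data_lines(path):
        if len(fields) < 3:
            raise ParseError(f"{path}:{lineno}: expected >=3 tab-separated columns")
        chrom = _normalize_chrom(fields[0], chrom_prefix)
        try:
            start, end = int(fields[1]), int(fields[2])
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: non-integer coordinate") from exc
        if one_based:
            start -= 1
        score = None
        if has_score:
            score_field = fields[4] if len(fields) >= 5 else fields[3]
            try:
                score = float(score_field)
            except (ValueError, IndexError) as exc:
                raise ParseError(f"{path}:{lineno}: missing or non-numeric score") from exc
        try:
            intervals.append(GenomicInterval(chrom, start, end, score))
        except ValidationError as exc:
            raise ValidationError(f"{path}:{lineno}: {exc}") from exc
    return SampleTable(sample_id, intervals)


def write_bed(table: SampleTable, path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for iv in table.intervals:
            if iv.score is None:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")
            else:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t.\t{iv.score:g}\n")


def read_segments(path, chrom_prefix: str | None = None) -> list[CopyNumberSegment]:
    """Read a 4-column chrom/start/end/log2 segment file."""
    segments = []
    for lineno, fields in _data_lines(path):
        if len(fields) < 4:
            raise ParseError(f"{path}:{lineno}: expected 4 columns chrom/start/end/log2")
        chrom = _normalize_chrom(fields[0], chrom_prefix)
        try:
            start, end = int(fields[1]), int(fields[2])
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: non-integer coordinate") from exc
        try:
            log2 = float(fields[3])
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: non-numeric log2 ratio {fields[3]!r}") from exc
        if log2 != log2:  # NaN
            raise ParseError(f"{path}:{lineno}: non-numeric log2 ratio {fields[3]!r}")
        try:
            segments.append(CopyNumberSegment(chrom, start, end, log2))
        except ValidationError as exc:
            raise ValidationError(f"{path}:{lineno}: {exc}") from exc
    return segments


def write_segments(segments, path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for seg in segments:
            fh.write(f"{seg.chrom}\t{seg.start}\t{seg.end}\t{seg.log2_ratio:.6g}\n")


def read_matrix(path) -> ExpressionMatrix:
    """Read a TSV expression matrix; first column = gene id, header = samples."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.columns.empty:
        raise SchemaError(f"{path}: matrix has no sample columns")
    try:
        return ExpressionMatrix(df)
    except ValidationError as exc:
        raise ValidationError(f"{path}: {exc}") from exc


def write_matrix(matrix: ExpressionMatrix, path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        matrix.values.to_csv(fh, sep="\t", index_label="gene_id", lineterminator="\n")


def read_survival(path) -> SurvivalTable:
    """Read a sample_id/time/event TSV with a header row."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    try:
        return SurvivalTable(df)
    except (SchemaError, ValidationError) as exc:
        raise type(exc)(f"{path}: {exc}") from exc


def write_survival(survival: SurvivalTable, path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        survival.table.to_csv(fh, sep="\t", index=False, lineterminator="\n")


_GENE_COLUMNS = ["gene_id", "symbol", "chrom", "start", "end", "strand", "biotype", "is_tf"]


def read_genes(path) -> pd.DataFrame:
    """Read a gene annotation TSV (gene_id, symbol, chrom, start, end, strand,
    biotype, is_tf)."""
    df = pd.read_csv(path, sep="\t")
    missing = set(_GENE_COLUMNS) - set(df.columns)
    if missing:
        raise SchemaError(f"{path}: gene table missing columns {sorted(missing)}")
    if df["gene_id"].duplicated().any():
        dup = df.loc[df["gene_id"].duplicated(), "gene_id"].iloc[0]
        raise ValidationError(f"{path}: duplicate gene id {dup!r}")
    df["is_tf"] = df["is_tf"].astype(bool)
    return df[_GENE_COLUMNS]


def write_table(records: pd.DataFrame, path) -> None:
    """Write any DataFrame as TSV with deterministic column order and ``\\n``."""
    os.makedirs(os.path.dirname(os.path.abspath(path)), exist_ok=True)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        records.to_csv(fh, sep="\t", index=False, lineterminator="\n")
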