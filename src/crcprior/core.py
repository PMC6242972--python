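"""Core in-memory types shared by every stage of the pipeline.

Coordinates are 0-based half-open (BED convention) everywhere. Chromosome
names are taken literally: ``"chr17"`` and ``"17"`` are different
chromosomes unless the caller normalizes them on read.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ValidationError",
    "ParseError",
    "SchemaError",
    "GenomicInterval",
    "SampleTable",
    "CopyNumberSegment",
    "ExpressionMatrix",
    "SurvivalTable",
    "GeneModel",
]


class ValidationError(ValueError):
    """An in-memory object violates one of its invariants."""


class ParseError(ValueError):
    """A file could not be parsed; the message names the offending line."""


class SchemaError(ValueError):
    """A table is missing a required column or header."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Half-open genomic interval ``[start, end)`` with an optional score.

    The score, when present, is a non-negative signal value (for SE calls
    this is the H3K27ac stitched-enhancer score in arbitrary units).
    """

    chrom: str
    start: int
    end: int
    score: float | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValidationError("chromosome name must be non-empty")
        if self.start < 0:
            raise ValidationError(f"start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValidationError(
                f"end must exceed start, got [{self.start}, {self.end})"
            )
        if self.score is not None and self.score < 0:
            raise ValidationError(f"score must be non-negative, got {self.score}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def distance_to(self, pos: int) -> int:
        """Gap from a point to this interval; 0 if the point is inside.

        For a point at or beyond the half-open end, the gap is measured
        from the end coordinate (bedtools convention), so a point at
        ``end + d`` is ``d`` away.
        """
        if pos < self.start:
            return self.start - pos
        if pos >= self.end:
            return pos - self.end
        return 0


@dataclass
class SampleTable:
    """All intervals belonging to one sample, sorted by (chrom, start)."""

    sample_id: str
    intervals: list[GenomicInterval]

    def __post_init__(self) -> None:
        if not self.sample_id:
            raise ValidationError("sample_id must be non-empty")
        self.intervals = sorted(
            self.intervals, key=lambda iv: (iv.chrom, iv.start, iv.end)
        )

    def __len__(self) -> int:
        return len(self.intervals)


@dataclass(frozen=True)
class CopyNumberSegment:
    """A copy-number segment with its log2 tumor/normal ratio."""

    chrom: str
    start: int
    end: int
    log2_ratio: float

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValidationError("chromosome name must be non-empty")
        if self.end <= self.start:
            raise ValidationError(
                f"segment end must exceed start, got [{self.start}, {self.end})"
            )

    @property
    def size(self) -> int:
        return self.end - self.start

    def overlap_bp(self, interval: GenomicInterval) -> int:
        if self.chrom != interval.chrom:
            return 0
        return max(0, min(self.end, interval.end) - max(self.start, interval.start))


class ExpressionMatrix:
    """Genes x samples matrix of log2-scale expression values.

    Thin wrapper around a pandas DataFrame that enforces unique gene and
    sample identifiers.
    """

    def __init__(self, values: pd.DataFrame):
        if values.index.duplicated().any():
            dup = values.index[values.index.duplicated()][0]
            raise ValidationError(f"duplicate gene id {dup!r}")
        if values.columns.duplicated().any():
            dup = values.columns[values.columns.duplicated()][0]
            raise ValidationError(f"duplicate sample id {dup!r}")
        self.values = values.astype(float)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def gene(self, gene_id: str) -> pd.Series:
        if gene_id not in self.values.index:
            raise KeyError(gene_id)
        return self.values.loc[gene_id]

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ExpressionMatrix):
            return NotImplemented
        return self.values.equals(other.values)


class SurvivalTable:
    """Follow-up time (days, > 0) and event indicator per sample."""

    def __init__(self, table: pd.DataFrame):
        missing = {"sample_id", "time", "event"} - set(table.columns)
        if missing:
            raise SchemaError(f"survival table missing columns {sorted(missing)}")
        if table["sample_id"].duplicated().any():
            dup = table.loc[table["sample_id"].duplicated(), "sample_id"].iloc[0]
            raise ValidationError(f"duplicate sample id {dup!r}")
        if (table["time"] <= 0).any():
            raise ValidationError("follow-up times must be > 0")
        if not table["event"].isin([0, 1]).all():
            raise ValidationError("event indicator must be 0 or 1")
        self.table = (
            table[["sample_id", "time", "event"]]
            .astype({"time": float, "event": int})
            .reset_index(drop=True)
        )

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table["sample_id"])

    def subset(self, sample_ids) -> "SurvivalTable":
        sub = self.table[self.table["sample_id"].isin(set(sample_ids))]
        return SurvivalTable(sub.reset_index(drop=True))

    def __len__(self) -> int:
        return len(self.table)


@dataclass(frozen=True)
class GeneModel:
    """Gene annotation record; ``tss`` is strand-aware (start for +, end-1 for -)."""

    gene_id: str
    symbol: str
    chrom: str
    start: int
    end: int
    strand: str
    is_tf: bool = False
    biotype: str = "protein_coding"

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise ValidationError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.end <= self.start:
            raise ValidationError("gene end must exceed start")

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end - 1

    def span(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.start, self.end)


def as_bool_array(values, n: int, name: str) -> np.ndarray:
    """Coerce a boolean-ish vector to a numpy bool array of length ``n``."""
    arr = np.asarray(values)
    if arr.shape != (n,):
        raise ValidationError(f"{name} must have length {n}, got shape {arr.shape}")
    return arr.astype(bool)
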