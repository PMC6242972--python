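"""Small curated annotation tables shipped with the package."""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .core import GeneModel
from .io import read_genes

__all__ = ["load_chr17q23_genes", "gene_models_from_table"]


def load_chr17q23_genes() -> pd.DataFrame:
    """Gene annotations around the 17q23.2 amplicon (hg19, approximate).

    Covers the six protein-coding genes inside the recurrent neuroblastoma
    focal amplification (PPM1D, BCAS3, TBX2, C17orf82, TBX4, NACA2) plus
    flanking entries (APPBP2, MIR21, the lncRNA TBX2-AS1) that fall
    outside the amplicon or outside the protein-coding class, so that
    overlap and biotype filters have something to reject.
    """
    path = resources.files("crcprior").joinpath("data/chr17q23_genes.tsv")
    with resources.as_file(path) as p:
        return read_genes(p)


def gene_models_from_table(table: pd.DataFrame) -> list[GeneModel]:
    return [
        GeneModel(
            gene_id=row.gene_id,
            symbol=row.symbol,
            chrom=row.chrom,
            start=int(row.start),
            end=int(row.end),
            strand=row.strand,
            is_tf=bool(row.is_tf),
            biotype=row.biotype,
        )
        for row in table.itertuples(index=False)
    ]
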