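"""Rank-based signature scoring and correlation testing.

A signature score summarizes, per sample, how high a gene set ranks in
that sample's expression profile: all genes are ranked (1 = lowest,
average ranks for ties), ranks are rescaled to [0, 1] via (r - 1) /
(G - 1), and the score is the mean rescaled rank of the up genes minus
the mean rescaled rank of the down genes (minus 0.5 when the signature
has no down set, centering the score at 0). Being rank-based, the score
is invariant under any monotone transform of a sample's expression.

Correlation between two per-sample quantities uses Pearson when the
homoscedasticity assumption holds (Breusch-Pagan test on the y ~ x
residuals, not rejected at alpha = 0.05) and Spearman otherwise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .core import ExpressionMatrix, ValidationError

__all__ = ["GeneSignature", "signature_score", "correlate"]


@dataclass
class GeneSignature:
    up_genes: frozenset
    down_genes: frozenset = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        self.up_genes = frozenset(self.up_genes)
        self.down_genes = frozenset(self.down_genes)
        if not self.up_genes:
            raise ValidationError("signature must have at least one up gene")
        if self.up_genes & self.down_genes:
            raise ValidationError("up and down gene sets must be disjoint")

    def swapped(self) -> "GeneSignature":
        if not self.down_genes:
            raise ValidationError("cannot swap a signature with no down genes")
        return GeneSignature(self.down_genes, self.up_genes)


def signature_score(matrix: ExpressionMatrix, sig: GeneSignature) -> pd.Series:
    """Per-sample rank score of a signature (higher = signature more 'up').

    Signature genes absent from the matrix are dropped with a warning;
    scoring fails only if none remain.
    """
    present = set(matrix.gene_ids)
    up = sorted(sig.up_genes & present)
    down = sorted(sig.down_genes & present)
    dropped = (sig.up_genes | sig.down_genes) - present
    if dropped:
        warnings.warn(
            f"{len(dropped)} signature gene(s) absent from the matrix",
            stacklevel=2,
        )
    if not up and not down:
        raise ValidationError("no signature gene present in the matrix")
    if not up:
        raise ValidationError("no up-signature gene present in the matrix")

    values = matrix.values
    n_genes = len(values.index)
    if n_genes < 2:
        raise ValidationError("need >= 2 genes to rank")
    ranks = values.rank(axis=0, method="average")
    rescaled = (ranks - 1.0) / (n_genes - 1.0)
    up_score = rescaled.loc[up].mean(axis=0)
    if down:
        score = up_score - rescaled.loc[down].mean(axis=0)
    else:
        score = up_score - 0.5
    score.name = "signature_score"
    return score


def correlate(x, y, alpha: float = 0.05) -> dict:
    """Correlate two per-sample vectors, choosing Pearson vs Spearman by a
    Breusch-Pagan homoscedasticity check on the y ~ x residuals."""
    import statsmodels.api as sm
    from statsmodels.stats.diagnostic import het_breuschpagan

    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValidationError("x and y must align")
    if len(x) < 5:
        raise ValidationError("need >= 5 paired observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValidationError("zero variance in input")

    exog = sm.add_constant(x)
    resid = sm.OLS(y, exog).fit().resid
    bp_p = het_breuschpagan(resid, exog)[1]
    if np.isnan(bp_p) or bp_p >= alpha:
        r, p = stats.pearsonr(x, y)
        method = "pearson"
    else:
        r, p = stats.spearmanr(x, y)
        method = "spearman"
    return {"method": method, "coefficient": float(r), "p": float(p), "bp_p": float(bp_p)}
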