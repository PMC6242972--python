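"""Copy-number dosage analysis.

Focal gains over a locus are copy-number segments that overlap the locus,
reach a log2 ratio of at least 0.3 (inclusive) and span at most 5 Mb
(inclusive). Arm-level gain status is the length-weighted mean log2 ratio
over the arm, called gained when strictly above 0.3. The dosage effect of
a gain on expression is quantified with a two-way fixed-effects ANOVA
(stage x gain, type-II sums of squares) plus the headline one-way test of
gain within the high-stage stratum.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core import CopyNumberSegment, GenomicInterval, ValidationError

__all__ = [
    "DosageConfig",
    "detect_focal_gains",
    "call_arm_gain",
    "dosage_anova",
]


@dataclass
class DosageConfig:
    min_log2: float = 0.3
    max_focal_size: int = 5_000_000
    arm_gain_log2: float = 0.3

    def __post_init__(self) -> None:
        if self.min_log2 <= 0:
            raise ValidationError("min_log2 must be > 0")
        if self.max_focal_size <= 0:
            raise ValidationError("max_focal_size must be > 0")


def detect_focal_gains(
    segments: list[CopyNumberSegment],
    locus: GenomicInterval,
    config: DosageConfig | None = None,
) -> list[tuple[CopyNumberSegment, int]]:
    """Return (segment, size_bp) for focal gains overlapping ``locus``.

    A segment qualifies iff it overlaps the locus by >= 1 bp, its log2
    ratio is >= ``min_log2`` and its size is <= ``max_focal_size``; both
    bounds are inclusive.
    """
    config = config or DosageConfig()
    hits = []
    for seg in segments:
        if seg.chrom != locus.chrom:
            continue
        if seg.overlap_bp(locus) < 1:
            continue
        if seg.log2_ratio < config.min_log2:
            continue
        if seg.size > config.max_focal_size:
            continue
        hits.append((seg, seg.size))
    return hits


def call_arm_gain(
    segments: list[CopyNumberSegment],
    arm_region: GenomicInterval,
    config: DosageConfig | None = None,
) -> bool | None:
    """Per-sample arm gain status: length-weighted mean log2 over the arm
    strictly above ``arm_gain_log2``. Returns None ("unknown") when no
    segment overlaps the arm."""
    config = config or DosageConfig()
    weights, values = [], []
    for seg in segments:
        ov = seg.overlap_bp(arm_region)
        if ov > 0:
            weights.append(ov)
            values.append(seg.log2_ratio)
    if not weights:
        return None
    mean = float(np.average(values, weights=weights))
    return mean > config.arm_gain_log2


def dosage_anova(
    expression: np.ndarray,
    stage_high,
    gain_status,
) -> dict:
    """Two-way ANOVA of expression on tumor stage and copy-number gain.

    Parameters are aligned per-sample vectors: log2 expression, a binary
    high-stage indicator (stage 3/4 vs other) and a binary gain indicator.
    Returns the type-II two-way table (factors ``stage``, ``gain`` and
    their interaction) plus the headline quantity: the one-way ANOVA of
    gain within the high-stage stratum (``headline_F``, ``headline_p``).
    """
    import statsmodels.api as sm
    from statsmodels.formula.api import ols

    expr = np.asarray(expression, dtype=float)
    n = len(expr)
    stage = np.asarray(stage_high).astype(bool)
    gain = np.asarray(gain_status).astype(bool)
    if stage.shape != (n,) or gain.shape != (n,):
        raise ValidationError("expression, stage and gain vectors must align")
    for name, factor in (("stage", stage), ("gain", gain)):
        if len(np.unique(factor)) < 2:
            raise ValidationError(f"factor '{name}' has one level")
    counts = pd.crosstab(stage, gain)
    occupied = counts.to_numpy()[counts.to_numpy() > 0]
    if (occupied < 2).any():
        raise ValidationError("each occupied stage x gain cell needs >= 2 samples")

    df = pd.DataFrame({"expr": expr, "stage": stage, "gain": gain})
    model = ols("expr ~ C(stage) * C(gain)", data=df).fit()
    table = sm.stats.anova_lm(model, typ=2)

    def _cell(row, col):
        return float(table.loc[row, col])

    result = {
        "stage_F": _cell("C(stage)", "F"),
        "stage_p": _cell("C(stage)", "PR(>F)"),
        "gain_F": _cell("C(gain)", "F"),
        "gain_p": _cell("C(gain)", "PR(>F)"),
        "interaction_F": _cell("C(stage):C(gain)", "F"),
        "interaction_p": _cell("C(stage):C(gain)", "PR(>F)"),
        "anova_table": table,
    }

    high = stage
    if len(np.unique(gain[high])) == 2:
        f, p = stats.f_oneway(expr[high & gain], expr[high & ~gain])
        result["headline_F"], result["headline_p"] = float(f), float(p)
    else:
        result["headline_F"] = result["headline_p"] = float("nan")
    return result


def gain_effect_oneway(expression, gain_status) -> tuple[float, float]:
    """One-way ANOVA of a binary gain factor on expression (no stratification)."""
    expr = np.asarray(expression, dtype=float)
    gain = np.asarray(gain_status).astype(bool)
    if len(np.unique(gain)) < 2:
        raise ValidationError("factor 'gain' has one level")
    f, p = stats.f_oneway(expr[gain], expr[~gain])
    return float(f), float(p)
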