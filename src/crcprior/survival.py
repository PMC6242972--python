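"""Kaplan-Meier stratification by median expression and log-rank testing.

Candidates are ranked by splitting a cohort at the median expression of a
gene (ties to the low group) and comparing overall survival of the high
and low groups with the standard two-group log-rank test (chi-square, 1
degree of freedom). Curve estimation and the test statistic are computed
with lifelines; events precede censoring at tied times, the usual
convention.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank

from .core import SurvivalTable, ValidationError

__all__ = ["KMResult", "median_split", "logrank_test"]


@dataclass
class KMResult:
    high_samples: list[str]
    low_samples: list[str]
    km_curves: dict[str, pd.DataFrame]
    logrank_stat: float
    p: float


def median_split(values) -> np.ndarray:
    """Label samples by median cut-off: value > median -> high (True),
    value <= median -> low (ties go to the low group)."""
    arr = np.asarray(values, dtype=float)
    if len(arr) < 4:
        raise ValidationError("median split needs >= 4 samples")
    med = float(np.median(arr))
    labels = arr > med
    if labels.all() or not labels.any():
        raise ValidationError("no split possible: expression is constant")
    return labels


def logrank_test(survival: SurvivalTable, labels) -> KMResult:
    """Two-group log-rank test with Kaplan-Meier curves per group.

    ``labels`` is either a mapping sample_id -> bool (True = high) or a
    boolean vector aligned with the survival table's row order. Every
    labeled sample must have a survival record.
    """
    table = survival.table
    if isinstance(labels, dict):
        missing = [s for s in labels if s not in set(table["sample_id"])]
        if missing:
            raise ValidationError(
                f"labeled samples missing survival records: {missing[:5]}"
            )
        table = table[table["sample_id"].isin(labels)].reset_index(drop=True)
        high = table["sample_id"].map(labels).to_numpy(dtype=bool)
    else:
        high = np.asarray(labels, dtype=bool)
        if high.shape != (len(table),):
            raise ValidationError("label vector must align with the survival table")

    if high.all() or not high.any():
        raise ValidationError("both groups must be non-empty")
    if int(table["event"].sum()) == 0:
        raise ValidationError("log-rank statistic undefined: zero events overall")

    times = table["time"].to_numpy(dtype=float)
    events = table["event"].to_numpy(dtype=int)
    res = _ll_logrank(times[high], times[~high], events[high], events[~high])

    curves = {}
    for name, mask in (("high", high), ("low", ~high)):
        kmf = KaplanMeierFitter()
        kmf.fit(times[mask], events[mask])
        sf = kmf.survival_function_
        curves[name] = pd.DataFrame(
            {"time": sf.index.to_numpy(dtype=float), "survival": sf.iloc[:, 0].to_numpy()}
        )

    return KMResult(
        high_samples=list(table.loc[high, "sample_id"]),
        low_samples=list(table.loc[~high, "sample_id"]),
        km_curves=curves,
        logrank_stat=float(res.test_statistic),
        p=float(res.p_value),
    )
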