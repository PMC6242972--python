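import numpy as np
import pandas as pd
import pytest

from crcprior.core import ExpressionMatrix, GenomicInterval, SurvivalTable
from crcprior.se import SECall


@pytest.fixture
def toy_matrix():
    """4 genes x 3 samples with easily hand-ranked columns."""
    return ExpressionMatrix(
        pd.DataFrame(
            {
                "s1": [1.0, 2.0, 3.0, 4.0],
                "s2": [4.0, 3.0, 2.0, 1.0],
                "s3": [2.0, 2.0, 5.0, 1.0],
            },
            index=["g1", "g2", "g3", "g4"],
        )
    )


@pytest.fixture
def six_sample_survival():
    """The classic alternating 6-sample cohort: times 1..6, one censored."""
    return SurvivalTable(
        pd.DataFrame(
            {
                "sample_id": [f"P{i}" for i in range(1, 7)],
                "time": [1.0, 2.0, 3.0, 4.0, 5.0, 6.0],
                "event": [1, 1, 1, 1, 0, 1],
            }
        )
    )


def make_call(chrom, start, end, sample="A", signal=1.0, rank=1):
    return SECall(
        GenomicInterval(chrom, start, end, signal),
        sample_id=sample,
        signal=signal,
        within_sample_rank=rank,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
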