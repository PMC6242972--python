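"""Simulation studies validating the pipeline's statistical behavior.

These studies are the package's own evidence that its bespoke statistics
behave as designed: the interval clusterer agrees with a brute-force
transitive-closure oracle, the 4C caller controls its false-call rate on
null tracks and recovers planted interaction windows, the end-to-end
prioritization recovers a planted driver, the log-rank and dosage-ANOVA
p-values are uniform under their nulls, and excess-over-Bliss is exactly
zero (and unbiased under noise) on Bliss-independent checkerboards.

Every function takes a single integer seed and is deterministic given it.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .core import GenomicInterval, SurvivalTable
from .dosage import dosage_anova
from .fourc import FourCConfig, binarize, call_interactions, sliding_zscore
from .se import (
    PrioritizationConfig,
    SECall,
    cluster_se_calls,
    run_prioritization,
)
from .simulate import (
    CheckerboardSpec,
    CohortSpec,
    FourCSpec,
    LandscapeSpec,
    gen_checkerboard,
    gen_cohort,
    gen_fourc,
    gen_se_landscape,
)
from .survival import logrank_test
from .synergy import excess_over_bliss

__all__ = [
    "closure_cluster_oracle",
    "clustering_oracle_agreement",
    "fourc_null_false_call_rate",
    "fourc_recovery_rate",
    "driver_recovery_rate",
    "logrank_null_pvalues",
    "anova_null_pvalues",
    "bliss_identity_study",
    "ks_uniformity_p",
]


def closure_cluster_oracle(calls: list[SECall], max_gap: int) -> list[frozenset]:
    """O(n^2) transitive closure of the pairwise overlap-or-gap relation.

    Independent of the sorted-sweep implementation: builds the full dense
    pairwise adjacency (two calls are adjacent iff same chromosome and
    gap <= max_gap, where a negative gap means overlap) and takes
    connected components of that graph. Returns the partition as a list
    of frozensets of call indices.
    """
    from scipy.sparse import csr_matrix
    from scipy.sparse.csgraph import connected_components

    n = len(calls)
    if n == 0:
        return []
    starts = np.array([c.interval.start for c in calls])
    ends = np.array([c.interval.end for c in calls])
    chroms = pd.factorize(np.array([c.interval.chrom for c in calls]))[0]
    gap = np.maximum.outer(starts, starts) - np.minimum.outer(ends, ends)
    adjacency = (gap <= max_gap) & np.equal.outer(chroms, chroms)
    _, labels = connected_components(csr_matrix(adjacency), directed=False)
    components: dict[int, set] = {}
    for i, lab in enumerate(labels):
        components.setdefault(int(lab), set()).add(i)
    return [frozenset(v) for v in components.values()]


def _random_instance(rng, max_n: int = 200):
    n = int(rng.integers(1, max_n + 1))
    max_gap = int(rng.integers(0, 1000))
    calls = []
    for i in range(n):
        chrom = "chr17" if rng.random() < 0.8 else "chr2"
        start = int(rng.integers(0, 50_000))
        length = int(rng.integers(1, 2_000))
        calls.append(
            SECall(
                GenomicInterval(chrom, start, start + length, 1.0),
                sample_id=f"S{i}",
                signal=1.0,
                within_sample_rank=1,
            )
        )
    return calls, max_gap


def clustering_oracle_agreement(
    n_instances: int = 1000, max_n: int = 200, seed: int = 0
) -> float:
    """Fraction of random instances on which the sweep clustering equals
    the brute-force closure oracle's partition."""
    rng = np.random.default_rng(seed)
    agree = 0
    for _ in range(n_instances):
        calls, max_gap = _random_instance(rng, max_n)
        clusters = cluster_se_calls(calls, max_gap)
        got = set()
        for cl in clusters:
            # recover member call indices by re-scanning: a call belongs to
            # the cluster whose span contains it on the same chromosome
            members = frozenset(
                i
                for i, c in enumerate(calls)
                if c.interval.chrom == cl.interval.chrom
                and cl.interval.start <= c.interval.start
                and c.interval.end <= cl.interval.end
            )
            got.add(members)
        expected = set(closure_cluster_oracle(calls, max_gap))
        if got == expected:
            agree += 1
    return agree / n_instances


def fourc_null_false_call_rate(
    n_tracks: int = 200,
    n_fragments: int = 5_000,
    p_bg: float = 0.1,
    fdr: float = 0.01,
    seed: int = 0,
) -> float:
    """Fraction of windows called significant across pure-null tracks."""
    root = np.random.default_rng(seed)
    config = FourCConfig(fdr_cis=fdr)
    called = tested = 0
    for sub in root.integers(0, 2**31 - 1, n_tracks):
        track, _ = gen_fourc(FourCSpec(seed=int(sub), n_fragments=n_fragments, p_bg=p_bg))
        calls = call_interactions(track, mode="cis", config=config)
        tested += len(calls)
        called += sum(c.significant for c in calls)
    return called / tested


def fourc_recovery_rate(
    n_tracks: int = 100,
    n_fragments: int = 5_000,
    p_bg: float = 0.05,
    p_hi: float = 0.5,
    width: int = 100,
    n_planted: int = 3,
    seed: int = 0,
) -> float:
    """Fraction of tracks on which every planted window is recovered
    (a significant window center falls inside the planted span)."""
    root = np.random.default_rng(seed)
    config = FourCConfig()
    positions = np.linspace(500, n_fragments - 500 - width, n_planted).astype(int)
    planted = [(int(p), width, p_hi) for p in positions]
    recovered = 0
    for sub in root.integers(0, 2**31 - 1, n_tracks):
        track, truth = gen_fourc(
            FourCSpec(
                seed=int(sub),
                n_fragments=n_fragments,
                p_bg=p_bg,
                planted_windows=planted,
            )
        )
        calls = call_interactions(track, mode="cis", config=config)
        sig_centers = np.array(
            [c.center_index for c in calls if c.significant], dtype=int
        )
        ok = all(
            ((sig_centers >= s) & (sig_centers < s + w)).any()
            for s, w, _ in planted
        )
        recovered += ok
    return recovered / n_tracks


def driver_recovery_rate(
    n_runs: int = 50,
    n_tumors: int = 200,
    driver_hr: float = 2.5,
    seed: int = 0,
) -> float:
    """Fraction of synthetic landscape+cohort runs in which the planted
    driver TF is ranked first in the prioritization report."""
    root = np.random.default_rng(seed)
    hits = 0
    for sub in root.integers(0, 2**31 - 1, n_runs):
        sub = int(sub)
        se_tables, genes, tss_peaks, truth = gen_se_landscape(LandscapeSpec(seed=sub))
        expression, survival, segments, stage, _ = gen_cohort(
            CohortSpec(seed=sub + 1, n_tumors=n_tumors, driver_hr=driver_hr),
            gene_ids=[g.gene_id for g in genes],
            driver_gene_id=truth["driver_gene_id"],
        )
        report = run_prioritization(
            se_tables,
            genes,
            expression,
            survival,
            config=PrioritizationConfig(min_recurrence=20),
            tss_peaks=tss_peaks,
        )
        if not report.empty and report.loc[0, "gene_id"] == truth["driver_gene_id"]:
            hits += 1
    return hits / n_runs


def logrank_null_pvalues(
    n_reps: int = 2000, n: int = 100, censoring: float = 0.3, seed: int = 0
) -> np.ndarray:
    """Log-rank p-values under a null of exponential times and random labels."""
    rng = np.random.default_rng(seed)
    pvals = np.empty(n_reps)
    c_rate = censoring / (1 - censoring)
    for r in range(n_reps):
        t_event = rng.exponential(1.0, n)
        t_cens = rng.exponential(1.0 / c_rate, n) if censoring > 0 else np.full(n, np.inf)
        time = np.minimum(t_event, t_cens)
        event = (t_event <= t_cens).astype(int)
        labels = np.zeros(n, dtype=bool)
        labels[: n // 2] = True
        labels = rng.permutation(labels)
        table = SurvivalTable(
            pd.DataFrame(
                {"sample_id": [f"S{i}" for i in range(n)], "time": time, "event": event}
            )
        )
        pvals[r] = logrank_test(table, labels).p
    return pvals


def anova_null_pvalues(n_reps: int = 2000, n: int = 100, seed: int = 0) -> np.ndarray:
    """Headline dosage-ANOVA p-values (gain within high stage) under a
    pure-noise expression null."""
    rng = np.random.default_rng(seed)
    pvals = np.empty(n_reps)
    r = 0
    while r < n_reps:
        expr = rng.normal(0, 1, n)
        stage = rng.random(n) < 0.5
        gain = rng.random(n) < 0.5
        counts = [
            np.sum(stage & gain),
            np.sum(stage & ~gain),
            np.sum(~stage & gain),
            np.sum(~stage & ~gain),
        ]
        if min(counts) < 2:
            continue
        pvals[r] = dosage_anova(expr, stage, gain)["headline_p"]
        r += 1
    return pvals


def bliss_identity_study(
    n_reps: int = 100, noise_sd: float = 0.05, seed: int = 0
) -> dict:
    """Excess-over-Bliss on Bliss-independent checkerboards.

    Returns the maximum |eob| over a noiseless board (an exact-zero
    check), the grand mean eob over combination cells of noisy boards,
    and the mean of the per-replicate |mean eob| (how far each noisy
    board's average synergy estimate strays from the planted zero).
    """
    root = np.random.default_rng(seed)
    noiseless, _ = gen_checkerboard(CheckerboardSpec(seed=int(root.integers(2**31))))
    max_abs_noiseless = float(
        np.abs(excess_over_bliss(noiseless).eob[1:, 1:]).max()
    )
    means = []
    for sub in root.integers(0, 2**31 - 1, n_reps):
        board, _ = gen_checkerboard(
            CheckerboardSpec(seed=int(sub), noise_sd=noise_sd)
        )
        eob = excess_over_bliss(board).eob[1:, 1:]
        means.append(eob.mean())
    means = np.array(means)
    return {
        "noiseless_max_abs_eob": max_abs_noiseless,
        "noisy_mean_eob": float(means.mean()),
        "noisy_mean_abs_error": float(np.abs(means).mean()),
    }


def ks_uniformity_p(pvalues: np.ndarray) -> float:
    """Kolmogorov-Smirnov p-value against Uniform(0, 1)."""
    return float(stats.kstest(pvalues, "uniform").pvalue)
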