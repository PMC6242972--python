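"""Super-enhancer landscape prioritization.

Per-sample SE calls (stitched H3K27ac regions with a signal score) from a
panel of cell lines are merged into cross-sample clusters, ranked by the
median of the member samples' within-sample SE ranks, filtered for
recurrence across the panel, annotated with nearby genes, and reduced to
transcription factors whose TSS carries an active H3K27ac peak in every
cell line harboring the SE. Survival and copy-number dosage statistics are
then attached per candidate and the report is ranked by the survival
p-value.

Two calls belong to the same cluster iff they are connected by a chain of
pairwise relations (overlap, or gap <= ``max_gap``); on a line this
transitive closure is computed by a single sorted sweep per chromosome.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .core import GeneModel, GenomicInterval, SampleTable, ValidationError
from .dosage import DosageConfig, call_arm_gain, dosage_anova
from .survival import logrank_test, median_split

__all__ = [
    "SECall",
    "SECluster",
    "CandidateGene",
    "PrioritizationConfig",
    "assign_within_sample_ranks",
    "cluster_se_calls",
    "rank_and_filter_clusters",
    "annotate_candidate_genes",
    "filter_active_tfs",
    "run_prioritization",
]


@dataclass(frozen=True)
class SECall:
    """One per-sample super-enhancer call with its within-sample rank
    (1 = strongest SE of that sample)."""

    interval: GenomicInterval
    sample_id: str
    signal: float
    within_sample_rank: int

    def __post_init__(self) -> None:
        if self.signal < 0:
            raise ValidationError("SE signal must be non-negative")
        if self.within_sample_rank < 1:
            raise ValidationError("within-sample rank must be >= 1")


@dataclass
class SECluster:
    """A cross-sample merged SE region."""

    cluster_id: int
    interval: GenomicInterval
    members: dict[str, SECall]

    @property
    def recurrence(self) -> int:
        return len(self.members)

    @property
    def median_rank(self) -> float:
        # median over harboring samples only; a cluster absent from a
        # sample has no rank there
        return float(np.median([c.within_sample_rank for c in self.members.values()]))


@dataclass
class CandidateGene:
    gene: GeneModel
    clusters: list[int]
    active_tss_in_all_harboring: bool | None = None
    survival_p: float | None = None
    survival_stat: float | None = None
    dosage_p: float | None = None
    cluster_median_rank: float = field(default=float("nan"))
    cluster_recurrence: int = 0


@dataclass
class PrioritizationConfig:
    """Tunable thresholds of the prioritization cascade.

    Defaults mirror the study conditions: SEs within 500 bp are clustered,
    the top 500 clusters by median rank are kept, recurrence in at least 20
    of the panel's cell lines is required, genes within 500 kb of a cluster
    are annotated, and a TSS peak is sought within +/- 1 kb of the TSS.
    """

    max_gap: int = 500
    top_n: int = 500
    min_recurrence: int = 20
    gene_window: int = 500_000
    tss_window: int = 1_000
    region: GenomicInterval | None = None

    def __post_init__(self) -> None:
        for name in ("max_gap", "top_n", "min_recurrence", "gene_window", "tss_window"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be non-negative")


def assign_within_sample_ranks(tables: dict[str, SampleTable]) -> list[SECall]:
    """Turn per-sample SE SampleTables (with signal scores) into ranked SECalls.

    Ranks are assigned per sample by descending signal (1 = strongest);
    ties broken by leftmost start, then chromosome name.
    """
    calls: list[SECall] = []
    for sample_id, table in tables.items():
        ivs = table.intervals
        for iv in ivs:
            if iv.score is None:
                raise ValidationError(
                    f"SE call {iv.chrom}:{iv.start}-{iv.end} in sample "
                    f"{sample_id!r} has no signal score"
                )
        order = sorted(
            range(len(ivs)),
            key=lambda i: (-ivs[i].score, ivs[i].chrom, ivs[i].start),
        )
        for rank, idx in enumerate(order, start=1):
            iv = ivs[idx]
            calls.append(SECall(iv, sample_id, iv.score, rank))
    return calls


def cluster_se_calls(calls: list[SECall], max_gap: int = 500) -> list[SECluster]:
    """Single-linkage clustering of SE calls along each chromosome.

    Two calls are linked if their intervals overlap or lie within
    ``max_gap`` bp of each other; clusters are the connected components of
    this relation. Calls on different chromosomes are never merged. When a
    sample contributes several calls to one cluster the strongest
    (lowest-rank) call represents it.
    """
    if max_gap < 0:
        raise ValidationError("max_gap must be >= 0")
    by_chrom: dict[str, list[SECall]] = {}
    for call in calls:
        by_chrom.setdefault(call.interval.chrom, []).append(call)

    clusters: list[SECluster] = []
    for chrom in sorted(by_chrom):
        chrom_calls = sorted(
            by_chrom[chrom], key=lambda c: (c.interval.start, c.interval.end)
        )
        group: list[SECall] = []
        group_end = -1
        for call in chrom_calls:
            if group and call.interval.start - group_end > max_gap:
                clusters.append(_finish_cluster(len(clusters), chrom, group))
                group, group_end = [], -1
            group.append(call)
            group_end = max(group_end, call.interval.end)
        if group:
            clusters.append(_finish_cluster(len(clusters), chrom, group))
    return clusters


def _finish_cluster(cluster_id: int, chrom: str, group: list[SECall]) -> SECluster:
    members: dict[str, SECall] = {}
    for call in group:
        prev = members.get(call.sample_id)
        if prev is None or call.within_sample_rank < prev.within_sample_rank:
            members[call.sample_id] = call
    span = GenomicInterval(
        chrom,
        min(c.interval.start for c in group),
        max(c.interval.end for c in group),
    )
    return SECluster(cluster_id, span, members)


def rank_and_filter_clusters(
    clusters: list[SECluster],
    top_n: int = 500,
    min_recurrence: int = 20,
    region: GenomicInterval | None = None,
) -> list[SECluster]:
    """Keep the ``top_n`` clusters by ascending median rank, then those
    recurrent in at least ``min_recurrence`` samples (inclusive bound).

    Ties in median rank are broken by higher recurrence, then leftmost
    interval, so the cut is deterministic.
    """
    if region is not None:
        clusters = [c for c in clusters if c.interval.overlaps(region)]
    ordered = sorted(
        clusters,
        key=lambda c: (
            c.median_rank,
            -c.recurrence,
            c.interval.chrom,
            c.interval.start,
            c.interval.end,
        ),
    )
    kept = ordered[:top_n]
    return [c for c in kept if c.recurrence >= min_recurrence]


def annotate_candidate_genes(
    clusters: list[SECluster],
    genes: list[GeneModel],
    gene_window: int = 500_000,
) -> list[CandidateGene]:
    """Annotate every gene whose TSS lies within ``gene_window`` bp of a
    cluster span (inclusive; distance 0 if the TSS is inside the span)."""
    candidates: list[CandidateGene] = []
    for gene in genes:
        hits = [
            c
            for c in clusters
            if c.interval.chrom == gene.chrom
            and c.interval.distance_to(gene.tss) <= gene_window
        ]
        if hits:
            best = min(hits, key=lambda c: c.median_rank)
            candidates.append(
                CandidateGene(
                    gene=gene,
                    clusters=[c.cluster_id for c in hits],
                    cluster_median_rank=best.median_rank,
                    cluster_recurrence=max(c.recurrence for c in hits),
                )
            )
    return candidates


def filter_active_tfs(
    candidates: list[CandidateGene],
    clusters: list[SECluster],
    tss_peaks: dict[str, SampleTable],
    tss_window: int = 1_000,
    harboring: str = "union",
) -> list[CandidateGene]:
    """Keep transcription factors with an H3K27ac-marked TSS in every cell
    line harboring the SE.

    ``harboring`` selects how "cell lines harboring the SE" is read for a
    gene annotated to several clusters: ``"union"`` (default) requires a
    TSS peak in the union of member samples across the gene's clusters;
    ``"per-cluster"`` requires it for the members of at least one cluster.
    """
    if harboring not in {"union", "per-cluster"}:
        raise ValidationError(f"unknown harboring mode {harboring!r}")
    by_id = {c.cluster_id: c for c in clusters}
    kept: list[CandidateGene] = []
    for cand in candidates:
        if not cand.gene.is_tf:
            continue
        member_sets = [set(by_id[cid].members) for cid in cand.clusters]
        for samples in member_sets:
            for sample in samples:
                if sample not in tss_peaks:
                    raise ValidationError(
                        f"sample {sample!r} harbors an SE but has no TSS peak table"
                    )
        if harboring == "union":
            required = [set().union(*member_sets)]
        else:
            required = member_sets
        ok = any(
            all(
                _has_tss_peak(tss_peaks[s], cand.gene, tss_window)
                for s in sample_set
            )
            for sample_set in required
        )
        if ok:
            cand.active_tss_in_all_harboring = True
            kept.append(cand)
    return kept


def _has_tss_peak(peaks: SampleTable, gene: GeneModel, tss_window: int) -> bool:
    lo, hi = gene.tss - tss_window, gene.tss + tss_window
    for iv in peaks.intervals:
        if iv.chrom == gene.chrom and iv.start < hi and lo < iv.end:
            return True
    return False


def run_prioritization(
    se_tables: dict[str, SampleTable],
    genes: list[GeneModel],
    expression,
    survival,
    config: PrioritizationConfig | None = None,
    tss_peaks: dict[str, SampleTable] | None = None,
    segments: dict[str, list] | None = None,
    stage_high: dict[str, bool] | None = None,
    arm_region: GenomicInterval | None = None,
    dosage_config: DosageConfig | None = None,
) -> pd.DataFrame:
    """End-to-end prioritization: cluster, rank, filter, annotate, test.

    Returns the candidate report sorted ascending by the raw log-rank
    p-value (candidates without expression are retained with missing
    survival_p and sorted last); BH-adjusted p-values are reported
    alongside. Fully deterministic given its inputs.
    """
    config = config or PrioritizationConfig()
    calls = assign_within_sample_ranks(se_tables)
    clusters = cluster_se_calls(calls, config.max_gap)
    retained = rank_and_filter_clusters(
        clusters, config.top_n, config.min_recurrence, config.region
    )
    candidates = annotate_candidate_genes(retained, genes, config.gene_window)
    if tss_peaks is not None:
        candidates = filter_active_tfs(
            candidates, retained, tss_peaks, config.tss_window
        )
    else:
        candidates = [c for c in candidates if c.gene.is_tf]

    gain_status: dict[str, bool | None] = {}
    if segments is not None and arm_region is not None:
        dosage_config = dosage_config or DosageConfig()
        gain_status = {
            sid: call_arm_gain(segs, arm_region, dosage_config)
            for sid, segs in segments.items()
        }

    rows = []
    for cand in candidates:
        _attach_statistics(cand, expression, survival, gain_status, stage_high)
        rows.append(
            {
                "gene_id": cand.gene.gene_id,
                "symbol": cand.gene.symbol,
                "n_clusters": len(cand.clusters),
                "cluster_median_rank": cand.cluster_median_rank,
                "cluster_recurrence": cand.cluster_recurrence,
                "survival_stat": cand.survival_stat,
                "survival_p": cand.survival_p,
                "dosage_p": cand.dosage_p,
            }
        )
    report = pd.DataFrame(
        rows,
        columns=[
            "gene_id",
            "symbol",
            "n_clusters",
            "cluster_median_rank",
            "cluster_recurrence",
            "survival_stat",
            "survival_p",
            "dosage_p",
        ],
    )
    if report.empty:
        report["survival_q"] = pd.Series(dtype=float)
        return report
    pvals = report["survival_p"]
    adjusted = np.full(len(pvals), np.nan)
    ok = pvals.notna().to_numpy()
    if ok.any():
        adjusted[ok] = multipletests(pvals[ok].to_numpy(), method="fdr_bh")[1]
    report["survival_q"] = adjusted
    report = report.sort_values(
        ["survival_p", "cluster_median_rank", "gene_id"],
        na_position="last",
        kind="mergesort",
    ).reset_index(drop=True)
    return report


def _attach_statistics(cand, expression, survival, gain_status, stage_high) -> None:
    if expression is None or cand.gene.gene_id not in expression.gene_ids:
        return
    expr = expression.gene(cand.gene.gene_id)
    if survival is not None:
        common = [s for s in expr.index if s in set(survival.sample_ids)]
        if len(common) >= 4:
            try:
                labels = median_split(expr[common])
                result = logrank_test(survival.subset(common), dict(zip(common, labels)))
                cand.survival_p = result.p
                cand.survival_stat = result.logrank_stat
            except ValidationError:
                pass
    if gain_status and stage_high is not None:
        samples = [
            s
            for s in expr.index
            if gain_status.get(s) is not None and s in stage_high
        ]
        if samples:
            try:
                result = dosage_anova(
                    expr[samples].to_numpy(),
                    np.array([stage_high[s] for s in samples]),
                    np.array([gain_status[s] for s in samples]),
                )
                cand.dosage_p = result["headline_p"]
            except ValidationError:
                pass
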