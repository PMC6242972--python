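"""Clustering, ranking and candidate-filter logic of the SE prioritization."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import make_call
from crcprior.calibration import clustering_oracle_agreement
from crcprior.core import GeneModel, GenomicInterval, SampleTable, ValidationError
from crcprior.se import (
    CandidateGene,
    PrioritizationConfig,
    SECluster,
    annotate_candidate_genes,
    assign_within_sample_ranks,
    cluster_se_calls,
    filter_active_tfs,
    rank_and_filter_clusters,
)


class TestClustering:
    def test_single_call_identity(self):
        [c] = cluster_se_calls([make_call("chr17", 100, 200, rank=7)], 500)
        assert (c.interval.start, c.interval.end) == (100, 200)
        assert c.recurrence == 1 and c.median_rank == 7

    def test_gap_rule_two_clusters(self):
        calls = [
            make_call("chr17", 100, 200, sample="A"),
            make_call("chr17", 650, 900, sample="B"),
            make_call("chr17", 1500, 1600, sample="C"),
        ]
        spans = [(c.interval.start, c.interval.end) for c in cluster_se_calls(calls, 500)]
        assert spans == [(100, 900), (1500, 1600)]

    def test_transitive_chain_merges(self):
        # outer pair is 950 apart, but the chain through the middle links them
        calls = [
            make_call("chr17", 0, 100, "A"),
            make_call("chr17", 550, 600, "B"),
            make_call("chr17", 1050, 1100, "C"),
        ]
        [c] = cluster_se_calls(calls, 500)
        assert (c.interval.start, c.interval.end) == (0, 1100)

    def test_never_merges_across_chromosomes(self):
        calls = [make_call("chr17", 0, 100, "A"), make_call("chr2", 0, 100, "B")]
        assert len(cluster_se_calls(calls, 10**9)) == 2

    def test_matches_closure_oracle_on_random_instances(self):
        assert clustering_oracle_agreement(n_instances=200, max_n=120, seed=7) == 1.0

    def test_recurrence_counts_each_sample_once(self):
        calls = [
            make_call("chr17", 0, 100, "A", rank=1),
            make_call("chr17", 150, 300, "A", rank=2),
            make_call("chr17", 200, 400, "B", rank=1),
        ]
        [c] = cluster_se_calls(calls, 500)
        assert c.recurrence == 2
        # strongest call represents a sample contributing several
        assert c.members["A"].within_sample_rank == 1

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.data())
    def test_raising_max_gap_never_increases_cluster_count(self, data):
        n = data.draw(st.integers(1, 30))
        starts = data.draw(
            st.lists(st.integers(0, 5000), min_size=n, max_size=n)
        )
        calls = [
            make_call("chr17", s, s + 1 + (i % 40), sample=f"S{i}")
            for i, s in enumerate(starts)
        ]
        gap1 = data.draw(st.integers(0, 500))
        gap2 = data.draw(st.integers(0, 500))
        lo, hi = sorted([gap1, gap2])
        assert len(cluster_se_calls(calls, hi)) <= len(cluster_se_calls(calls, lo))

    def test_no_call_double_counted(self, rng):
        calls = [
            make_call("chr17", int(s), int(s) + 50, sample=f"S{i}")
            for i, s in enumerate(rng.integers(0, 20_000, 100))
        ]
        clusters = cluster_se_calls(calls, 300)
        assert sum(c.recurrence for c in clusters) == len(calls)


class TestRankFilter:
    def _cluster(self, cid, ranks, start=0):
        end = start + 100
        members = {
            f"S{i}": make_call("chr17", start, end, f"S{i}", rank=r)
            for i, r in enumerate(ranks)
        }
        return SECluster(cid, GenomicInterval("chr17", start, end), members)

    def test_median_rank_ordering(self):
        a = self._cluster(0, [3, 10, 20])
        b = self._cluster(1, [1, 2])
        assert a.median_rank == 10 and b.median_rank == 1.5
        out = rank_and_filter_clusters([a, b], top_n=10, min_recurrence=1)
        assert [c.cluster_id for c in out] == [1, 0]

    def test_min_recurrence_inclusive(self):
        clusters = [
            self._cluster(0, [1] * 26),
            self._cluster(1, [1] * 19),
            self._cluster(2, [1] * 20),
        ]
        out = rank_and_filter_clusters(clusters, top_n=10, min_recurrence=20)
        assert sorted(c.recurrence for c in out) == [20, 26]

    def test_tie_broken_by_recurrence_then_position(self):
        a = self._cluster(0, [2, 2], start=5000)
        b = self._cluster(1, [2, 2, 2], start=9000)
        out = rank_and_filter_clusters([a, b], top_n=1, min_recurrence=1)
        assert [c.cluster_id for c in out] == [1]  # higher recurrence wins
        c = self._cluster(2, [2, 2], start=100)
        out = rank_and_filter_clusters([a, c], top_n=1, min_recurrence=1)
        assert [x.cluster_id for x in out] == [2]  # leftmost wins

    def test_permissive_settings_keep_everything(self, rng):
        clusters = [
            self._cluster(i, list(rng.integers(1, 50, rng.integers(1, 8))))
            for i in range(20)
        ]
        out = rank_and_filter_clusters(clusters, top_n=10**9, min_recurrence=1)
        assert len(out) == 20


class TestGeneAnnotation:
    def _one_cluster(self):
        return [
            SECluster(
                0,
                GenomicInterval("chr17", 1_000_000, 1_010_000),
                {"A": make_call("chr17", 1_000_000, 1_010_000, "A")},
            )
        ]

    @pytest.mark.parametrize(
        "tss,included",
        [
            (1_510_000, True),   # exactly 500 kb away: inclusive
            (1_005_000, True),   # inside the span: distance 0
            (1_510_001, False),  # 1 bp beyond the window
            (500_000, True),     # 500 kb upstream of the span start
            (499_999, False),
        ],
    )
    def test_distance_window(self, tss, included):
        gene = GeneModel("g", "G", "chr17", tss, tss + 10, "+")
        out = annotate_candidate_genes(self._one_cluster(), [gene], 500_000)
        assert bool(out) == included

    def test_minus_strand_tss_is_end(self):
        gene = GeneModel("g", "G", "chr17", 100, 1_510_001, "-")
        assert gene.tss == 1_510_000
        assert annotate_candidate_genes(self._one_cluster(), [gene], 500_000)


class TestActiveTfFilter:
    def _setup(self, peak_samples, clusters_members=({"A", "B", "C"},), is_tf=True):
        clusters = []
        for i, samples in enumerate(clusters_members):
            members = {
                s: make_call("chr17", 1000 * i, 1000 * i + 100, s) for s in samples
            }
            clusters.append(
                SECluster(i, GenomicInterval("chr17", 1000 * i, 1000 * i + 100), members)
            )
        gene = GeneModel("g", "G", "chr17", 5_000, 6_000, "+", is_tf=is_tf)
        cand = CandidateGene(gene=gene, clusters=[c.cluster_id for c in clusters])
        peaks = {
            s: SampleTable(
                s,
                [GenomicInterval("chr17", 4_900, 5_100)] if s in peak_samples else [],
            )
            for s in {"A", "B", "C", "D"}
        }
        return [cand], clusters, peaks

    def test_non_tf_excluded_despite_peaks(self):
        cands, clusters, peaks = self._setup({"A", "B", "C"}, is_tf=False)
        assert filter_active_tfs(cands, clusters, peaks) == []

    def test_requires_peak_in_every_harboring_sample(self):
        cands, clusters, peaks = self._setup({"A", "B", "C"})
        assert len(filter_active_tfs(cands, clusters, peaks)) == 1
        cands, clusters, peaks = self._setup({"A", "B"})
        assert filter_active_tfs(cands, clusters, peaks) == []

    def test_union_semantics_for_multi_cluster_gene(self):
        # two clusters with members {A,B} and {B,C}: union {A,B,C} checked,
        # sample D (in the cohort but harboring nothing) is not required
        cands, clusters, peaks = self._setup(
            {"A", "B", "C"}, clusters_members=({"A", "B"}, {"B", "C"})
        )
        assert len(filter_active_tfs(cands, clusters, peaks)) == 1
        cands, clusters, peaks = self._setup(
            {"A", "B"}, clusters_members=({"A", "B"}, {"B", "C"})
        )
        assert filter_active_tfs(cands, clusters, peaks) == []
        # per-cluster mode: a peak in all members of one cluster suffices
        cands, clusters, peaks = self._setup(
            {"A", "B"}, clusters_members=({"A", "B"}, {"B", "C"})
        )
        assert len(
            filter_active_tfs(cands, clusters, peaks, harboring="per-cluster")
        ) == 1

    def test_missing_peak_table_is_explicit_error(self):
        cands, clusters, peaks = self._setup({"A", "B", "C"})
        del peaks["B"]
        with pytest.raises(ValidationError, match="'B'"):
            filter_active_tfs(cands, clusters, peaks)


class TestRankAssignment:
    def test_ranks_by_descending_signal_ties_leftmost(self):
        table = SampleTable(
            "s",
            [
                GenomicInterval("chr17", 0, 10, 5.0),
                GenomicInterval("chr17", 100, 110, 9.0),
                GenomicInterval("chr17", 50, 60, 5.0),
            ],
        )
        calls = assign_within_sample_ranks({"s": table})
        by_start = {c.interval.start: c.within_sample_rank for c in calls}
        assert by_start == {100: 1, 0: 2, 50: 3}

    def test_missing_score_rejected(self):
        table = SampleTable("s", [GenomicInterval("chr17", 0, 10)])
        with pytest.raises(ValidationError, match="signal score"):
            assign_within_sample_ranks({"s": table})


def test_config_rejects_negative_values():
    with pytest.raises(ValidationError):
        PrioritizationConfig(max_gap=-1)
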