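"""The 4C sliding-window interaction caller and its track utilities."""

import numpy as np
import pytest
from scipy import stats

from crcprior.core import ValidationError
from crcprior.fourc import (
    FourCConfig,
    FragmentTrack,
    binarize,
    call_interactions,
    domainogram,
    merge_significant,
    sliding_zscore,
    smooth_track,
)


def make_track(counts, viewpoint=None):
    counts = np.asarray(counts)
    starts = np.arange(len(counts)) * 1000 + 1_000_000
    return FragmentTrack("chr17", starts, counts, viewpoint_index=viewpoint)


def brute_force_window(x, i, k):
    """Recompute the centered shrinking window [i - k//2, i + k - k//2)."""
    lo = max(0, i - k // 2)
    hi = min(len(x), i + (k - k // 2))
    return x[lo:hi]


class TestBinarize:
    @pytest.mark.parametrize(
        "counts,expected",
        [([0, 3, 1, 0], [0, 1, 1, 0]), ([0, 0], [0, 0]), ([1], [1])],
    )
    def test_covered_means_at_least_one_read(self, counts, expected):
        assert list(binarize(make_track(counts))) == expected


class TestSlidingZ:
    def test_uniform_signal_gives_zero_everywhere(self):
        z = sliding_zscore(np.ones(500), FourCConfig(w=10, W=100))
        np.testing.assert_allclose(z, 0.0)

    def test_planted_window_formula(self):
        # background 10% over W=3000, small window 30/100 covered:
        # z = (0.3 - 0.1) / sqrt(0.1*0.9/100) = 6.666...
        n = 3000
        binary = np.zeros(n, dtype=int)
        center = n // 2
        w_lo, w_hi = center - 50, center + 50
        binary[w_lo : w_lo + 30] = 1  # 30 covered inside the w-window
        outside = [i for i in range(n) if not w_lo <= i < w_hi]
        binary[np.array(outside[:270])] = 1  # 270 covered elsewhere in W
        assert binary.sum() == 300
        z = sliding_zscore(binary, FourCConfig(w=100, W=3000))
        expected = (0.3 - 0.1) / np.sqrt(0.1 * 0.9 / 100)
        assert z[center] == pytest.approx(expected)
        assert expected == pytest.approx(6.6667, abs=1e-3)
        # sanity: the exact binomial tail for 30/100 at p=0.1 is far out
        # in the same tail as the normal approximation
        assert stats.binom.sf(29, 100, 0.1) < stats.norm.sf(4.0)

    def test_edges_use_actual_window_sizes(self, rng):
        binary = (rng.random(400) < 0.3).astype(int)
        config = FourCConfig(w=20, W=80)
        z = sliding_zscore(binary, config)
        for i in [0, 1, 5, 199, 395, 399]:
            small = brute_force_window(binary, i, 20)
            big = brute_force_window(binary, i, 80)
            p_w, p_W, n_w = small.mean(), big.mean(), len(small)
            if p_W in (0.0, 1.0):
                expected = 0.0
            else:
                expected = (p_w - p_W) / np.sqrt(p_W * (1 - p_W) / n_w)
            assert z[i] == pytest.approx(expected, abs=1e-12)

    def test_monotone_in_covered_count(self, rng):
        binary = (rng.random(600) < 0.2).astype(int)
        config = FourCConfig(w=20, W=200)
        i = 300
        binary[i] = 0
        z_before = sliding_zscore(binary, config)[i]
        binary2 = binary.copy()
        # add coverage inside the small window only
        free = [j for j in range(i - 10, i + 10) if binary2[j] == 0]
        binary2[free[0]] = 1
        z_after = sliding_zscore(binary2, config)[i]
        assert z_after >= z_before

    def test_short_track_errors(self):
        with pytest.raises(ValidationError, match="fewer than w"):
            sliding_zscore(np.ones(50), FourCConfig(w=100, W=3000))


def bh_stepup_oracle(pvals, alpha):
    """By-hand Benjamini-Hochberg step-up: reject p_(i) <= i/m * alpha up to
    the largest such i."""
    m = len(pvals)
    order = np.argsort(pvals)
    reject = np.zeros(m, dtype=bool)
    k = 0
    for rank, idx in enumerate(order, start=1):
        if pvals[idx] <= rank / m * alpha:
            k = rank
    reject[order[:k]] = True
    return reject


class TestCallInteractions:
    def test_all_zero_z_gives_no_calls(self):
        track = make_track(np.ones(500))
        calls = call_interactions(track, "cis", FourCConfig(w=10, W=100))
        assert all(not c.significant for c in calls)

    def test_planted_windows_only_with_bh_oracle(self, rng):
        config = FourCConfig(w=10, W=100, fdr_cis=0.01)
        binary = (rng.random(1000) < 0.1).astype(int)
        for start in (200, 500, 800):
            binary[start : start + 10] = 1
        track = make_track(np.zeros(1000))
        z = sliding_zscore(binary, config)
        calls = call_interactions(track, "cis", config, z=z)
        pvals = np.array([c.p for c in calls])
        expected_reject = bh_stepup_oracle(pvals, config.fdr_cis)
        got_reject = np.array([c.significant for c in calls])
        np.testing.assert_array_equal(got_reject, expected_reject)
        sig_centers = {c.center_index for c in calls if c.significant}
        for start in (200, 500, 800):
            assert sig_centers & set(range(start, start + 10))

    def test_trans_calls_subset_of_cis_calls(self, rng):
        binary = (rng.random(2000) < 0.08).astype(int)
        binary[1000:1020] = 1
        track = make_track(binary)
        config = FourCConfig(w=20, W=300)
        z = sliding_zscore(binary, config)
        cis = {
            c.center_index
            for c in call_interactions(track, "cis", config, z=z)
            if c.significant
        }
        trans = {
            c.center_index
            for c in call_interactions(track, "trans", config, z=z)
            if c.significant
        }
        assert trans <= cis

    def test_viewpoint_exclusion_masks_windows(self):
        track = make_track(np.ones(1000), viewpoint=500)
        config = FourCConfig(w=10, W=100, viewpoint_exclusion=50)
        calls = call_interactions(track, "cis", config)
        tested = {c.center_index for c in calls}
        assert not tested & set(range(450, 551))
        # trans mode tests everything
        calls_t = call_interactions(track, "trans", config)
        assert len(calls_t) == 1000

    def test_unknown_mode_errors(self):
        with pytest.raises(ValidationError, match="mode"):
            call_interactions(make_track(np.ones(200)), "nonsense", FourCConfig(w=10, W=50))

    def test_merge_significant_runs(self, rng):
        binary = np.zeros(1000, dtype=int)
        binary[(rng.random(1000) < 0.05)] = 1
        binary[300:340] = 1
        track = make_track(binary)
        config = FourCConfig(w=10, W=200)
        calls = call_interactions(track, "cis", config)
        merged = merge_significant(calls)
        assert len(merged) >= 1
        spans = [(m.start, m.end) for m in merged]
        assert spans == sorted(spans)
        for a, b in zip(merged, merged[1:]):
            assert a.end < b.start  # maximal runs do not touch


class TestSmoothTrack:
    def test_constant_counts_identity_at_unit_library(self):
        track = make_track(np.full(100, 7.0))
        out = smooth_track(track, FourCConfig(smooth_k=21), library_size=1e6)
        np.testing.assert_allclose(out, 7.0)

    def test_single_spike_plateau(self):
        counts = np.zeros(200)
        counts[100] = 21
        track = make_track(counts)
        out = smooth_track(track, FourCConfig(smooth_k=21), library_size=1e6)
        plateau = out[out > 0.999]
        assert len(plateau) == 21
        np.testing.assert_allclose(plateau, 1.0)

    def test_edge_windows_shrink(self):
        counts = np.ones(50)
        counts[0] = 11.0
        track = make_track(counts)
        out = smooth_track(track, FourCConfig(smooth_k=21), library_size=1e6)
        # at position 0 the window holds ceil(21/2) = 11 fragments
        assert out[0] == pytest.approx((11 + 10) / 11)

    def test_library_normalization(self):
        track = make_track(np.full(100, 2.0))
        out = smooth_track(track, FourCConfig(smooth_k=21), library_size=2e6)
        np.testing.assert_allclose(out, 1.0)

    def test_bad_library_size(self):
        with pytest.raises(ValidationError, match="library_size"):
            smooth_track(make_track(np.ones(30)), library_size=0)


class TestDomainogram:
    def test_all_ones_matrix_of_ones(self):
        mat = domainogram(np.ones(50), [1, 5, 9])
        np.testing.assert_allclose(mat, 1.0)

    def test_window_one_row_is_the_signal(self, rng):
        binary = (rng.random(80) < 0.5).astype(int)
        mat = domainogram(binary, [1, 3])
        np.testing.assert_allclose(mat[0], binary)

    def test_cells_match_brute_force_recount(self, rng):
        binary = (rng.random(200) < 0.3).astype(int)
        sizes = [1, 4, 7, 21, 50]
        mat = domainogram(binary, sizes)
        for s_idx, k in enumerate(sizes):
            for i in range(0, 200, 13):
                window = brute_force_window(binary, i, k)
                assert mat[s_idx, i] == pytest.approx(window.mean())

    def test_row_reproduces_sliding_zscore_p_w(self, rng):
        binary = (rng.random(300) < 0.2).astype(int)
        config = FourCConfig(w=10, W=100)
        mat = domainogram(binary, [10])
        s, n = np.zeros(300), np.zeros(300)
        # reconstruct p_w from the z formula inputs via brute force
        for i in range(300):
            win = brute_force_window(binary, i, 10)
            s[i], n[i] = win.sum(), len(win)
        np.testing.assert_allclose(mat[0], s / n)

    def test_unsorted_sizes_rejected(self):
        with pytest.raises(ValidationError, match="sorted"):
            domainogram(np.ones(10), [5, 3])


class TestFourCConfig:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"w": 100, "W": 100},
            {"w": 0},
            {"fdr_cis": 0.0},
            {"fdr_trans": 1.0},
            {"smooth_k": 20},
        ],
    )
    def test_invalid_configs(self, kwargs):
        with pytest.raises(ValidationError):
            FourCConfig(**kwargs)
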