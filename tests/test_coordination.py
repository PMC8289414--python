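"""Peak detection, the activity rule and coordinated-region merging."""

import numpy as np
import pytest

from syncscope.coordination import (
    BlockTraceSet,
    active_fraction,
    classify_active,
    detect_peaks,
    largest_coordinated_fraction,
    merge_coordinated,
    noise_scale,
)
from syncscope.errors import InputError, UndefinedResultError


def _blocks(traces, n_pixels=None):
    traces = np.asarray(traces, float)
    n = len(traces)
    if n_pixels is None:
        n_pixels = np.full(n, 25)
    return BlockTraceSet(
        traces=traces,
        centroids_px=np.column_stack([np.arange(n), np.zeros(n)]).astype(float),
        z=np.zeros(n, dtype=int),
        n_pixels=np.asarray(n_pixels),
        tile_index=np.column_stack([np.arange(n), np.zeros(n, dtype=int)]),
    )


class TestDetectPeaks:
    def test_flat_trace_has_no_peaks(self):
        assert detect_peaks(np.full(50, 3.0)) == []

    def test_triangular_bump_yields_one_peak_of_its_height(self):
        trace = np.zeros(100)
        trace[40:50] = np.linspace(0, 10, 10)
        trace[50:60] = np.linspace(10, 0, 10)[:10]
        peaks = detect_peaks(trace)
        assert len(peaks) == 1
        idx, amp = peaks[0]
        assert abs(idx - 49) <= 1
        assert amp == pytest.approx(10.0, rel=0.1)

    def test_noisy_bump_dominant_peak_has_the_right_amplitude(self, rng):
        t = np.arange(100, dtype=float)
        bump = 10.0 * np.exp(-0.5 * ((t - 50) / 4.0) ** 2)
        trace = bump + rng.normal(0, 1.0, 100)
        peaks = detect_peaks(trace)
        idx, amp = max(peaks, key=lambda p: p[1])
        assert abs(idx - 50) <= 2
        assert amp == pytest.approx(10.0, rel=0.25)

    def test_adjacent_maxima_are_merged(self):
        trace = np.zeros(30)
        trace[10], trace[11] = 5.0, 4.9  # maxima one frame apart
        trace += 0.01 * np.sin(np.arange(30))
        peaks = detect_peaks(trace)
        assert len([p for p in peaks if abs(p[0] - 10) <= 1]) == 1


class TestClassifyActive:
    def test_exactly_1p5x_background_is_inactive(self):
        assert classify_active([(5, 1.5)], background=1.0) is False

    def test_twice_background_is_active(self):
        assert classify_active([(5, 2.0)], background=1.0) is True

    def test_nonpositive_background_rejected(self):
        with pytest.raises(InputError):
            classify_active([(5, 2.0)], background=0.0)


class TestMerge:
    def test_identical_traces_form_one_region(self, rng):
        base = np.sin(np.linspace(0, 6 * np.pi, 80))
        blocks = _blocks([base] * 6)
        cmap = merge_coordinated(blocks, active=np.ones(6, bool))
        assert cmap.n_regions == 1
        assert largest_coordinated_fraction(cmap) == 1.0

    def test_antiphase_halves_form_two_equal_regions(self):
        base = np.sin(np.linspace(0, 6 * np.pi, 80))
        blocks = _blocks([base] * 4 + [-base] * 4)
        cmap = merge_coordinated(blocks, active=np.ones(8, bool))
        assert cmap.n_regions == 2
        assert largest_coordinated_fraction(cmap) == 0.5

    def test_partition_matches_union_find_over_correlation_matrix(self, rng):
        """Brute-force union-find oracle over the explicit all-pairs matrix."""
        n, t = 20, 120
        groups = rng.integers(0, 4, n)
        sources = rng.normal(size=(4, t))
        traces = sources[groups] + 0.05 * rng.normal(size=(n, t))
        blocks = _blocks(traces)
        cmap = merge_coordinated(blocks, active=np.ones(n, bool))

        corr = np.corrcoef(traces)
        parent = list(range(n))

        def find(i):
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        for i in range(n):
            for j in range(i + 1, n):
                if corr[i, j] > 0.7:
                    parent[find(i)] = find(j)
        oracle = [find(i) for i in range(n)]
        # same partition (up to label names)
        for i in range(n):
            for j in range(n):
                same_a = cmap.region_label[i] == cmap.region_label[j]
                same_b = oracle[i] == oracle[j]
                assert same_a == same_b

    def test_rmin_extremes(self, rng):
        traces = rng.normal(size=(6, 100))
        blocks = _blocks(traces)
        everything = merge_coordinated(blocks, r_min=-1.0, active=np.ones(6, bool))
        assert everything.n_regions == 1
        singletons = merge_coordinated(blocks, r_min=1.0, active=np.ones(6, bool))
        assert singletons.n_regions == 6

    def test_largest_fraction_non_increasing_in_rmin(self, rng):
        traces = rng.normal(size=(12, 150))
        traces[:6] += 3 * np.sin(np.linspace(0, 8 * np.pi, 150))
        blocks = _blocks(traces)
        fractions = [
            largest_coordinated_fraction(
                merge_coordinated(blocks, r_min=r, active=np.ones(12, bool))
            )
            for r in (-0.5, 0.0, 0.5, 0.9)
        ]
        assert all(a >= b for a, b in zip(fractions, fractions[1:]))

    def test_block_order_does_not_change_fractions(self, rng):
        traces = rng.normal(size=(10, 90))
        traces[:5] += 2 * np.cos(np.linspace(0, 4 * np.pi, 90))
        perm = rng.permutation(10)
        f1 = largest_coordinated_fraction(
            merge_coordinated(_blocks(traces), active=np.ones(10, bool))
        )
        f2 = largest_coordinated_fraction(
            merge_coordinated(_blocks(traces[perm]), active=np.ones(10, bool))
        )
        assert f1 == pytest.approx(f2)


class TestFractions:
    def test_trivial_active_fractions(self):
        base = np.sin(np.linspace(0, 4 * np.pi, 60))
        blocks = _blocks([base] * 4)
        all_active = merge_coordinated(
            blocks, active=np.ones(4, bool), n_kept_pixels=100
        )
        assert active_fraction(all_active) == 1.0
        half = merge_coordinated(
            blocks, active=np.array([True, True, False, False]), n_kept_pixels=100
        )
        assert active_fraction(half) == 0.5

    def test_no_active_pixels_is_undefined(self):
        base = np.sin(np.linspace(0, 4 * np.pi, 60))
        with pytest.warns(UserWarning):
            cmap = merge_coordinated(
                _blocks([base] * 3), active=np.zeros(3, bool), n_kept_pixels=75
            )
        assert active_fraction(cmap) == 0.0
        with pytest.raises(UndefinedResultError):
            largest_coordinated_fraction(cmap)

    def test_activity_fraction_matches_constructed_share(self, rng):
        """3 of 10 blocks oscillate well above noise -> active fraction 0.30."""
        t = np.linspace(0, 10 * np.pi, 200)
        traces = 0.01 * rng.normal(size=(10, 200))
        traces[:3] += np.sin(t)
        blocks = _blocks(traces)
        cmap = merge_coordinated(blocks, n_kept_pixels=250)
        assert active_fraction(cmap) == pytest.approx(0.30, abs=0.02)


class TestRecovery:
    @pytest.mark.parametrize("k,expected", [(1, 1.0), (2, 0.5), (4, 0.25)])
    def test_domain_count_and_area_recovered_from_movies(self, sim_factory, k, expected):
        fractions, counts = [], []
        for seed in range(5):
            state = sim_factory(seed, n_domains=k)
            fractions.append(largest_coordinated_fraction(state.cmap))
            counts.append(state.cmap.regions_holding_at_least(0.10))
        assert np.mean(fractions) == pytest.approx(expected, abs=0.03)
        assert sum(c == k for c in counts) >= 4
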