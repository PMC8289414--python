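"""Functional-network construction, metrics and threshold calibration."""

import numpy as np
import pytest
from scipy import stats as sps

from syncscope.errors import InputError
from syncscope.network import (
    FunctionalNetwork,
    build_adjacency,
    calibrate_threshold,
    characteristic_path_length,
    clustering_coefficient,
    degree_distribution,
    global_efficiency,
    hub_fraction,
    mean_pairwise_correlation,
    shortest_paths,
    transitivity_clustering,
)


def net_from_adjacency(a: np.ndarray) -> FunctionalNetwork:
    a = np.asarray(a, bool)
    r = np.where(a, 1.0, -1.0)
    np.fill_diagonal(r, 0.0)
    return FunctionalNetwork(
        R=r, A=a, r_th=0.95, cell_ids=np.arange(len(a)),
        excluded_cells=np.array([], dtype=int),
    )


def graph(n, edges):
    a = np.zeros((n, n), dtype=bool)
    for i, j in edges:
        a[i, j] = a[j, i] = True
    return net_from_adjacency(a)


CHAIN3 = graph(3, [(0, 1), (1, 2)])
K3 = graph(3, [(0, 1), (1, 2), (0, 2)])
STAR5 = graph(5, [(0, i) for i in range(1, 5)])
DISJOINT4 = graph(4, [(0, 1), (2, 3)])


class TestAdjacency:
    def test_identical_and_negated_traces(self, rng):
        base = rng.normal(size=100)
        net = build_adjacency(np.vstack([base, base, -base]), r_th=0.95)
        assert net.A[0, 1] and not net.A[0, 2]
        assert net.R[0, 1] == pytest.approx(1.0)
        assert net.R[0, 2] == pytest.approx(-1.0)
        assert np.all(np.diag(net.R) == 0)

    def test_constant_trace_excluded_with_warning(self, rng):
        traces = rng.normal(size=(4, 50))
        traces[2] = 5.0
        with pytest.warns(UserWarning):
            net = build_adjacency(traces)
        assert net.n_cells == 3
        assert 2 in net.excluded_cells

    def test_independent_noise_produces_no_links(self, rng):
        for _ in range(10):
            net = build_adjacency(rng.normal(size=(20, 200)), r_th=0.95)
            assert net.n_links == 0


class TestMetricsClosedForms:
    def test_degree_distribution_star_and_complete(self):
        pct, _, _ = degree_distribution(STAR5)
        assert pct[0] == 100.0
        assert np.allclose(pct[1:], 25.0)
        pct_k, _, _ = degree_distribution(graph(5, [(i, j) for i in range(5) for j in range(i + 1, 5)]))
        assert np.allclose(pct_k, 100.0)

    def test_mean_pairwise_correlation_hand_enumeration(self):
        base = np.sin(np.linspace(0, 8 * np.pi, 64))
        traces = np.vstack([base, base, -base, -base])
        net = build_adjacency(traces)
        r_avg, _ = mean_pairwise_correlation(net)
        assert r_avg == pytest.approx(-1.0 / 3.0, abs=1e-9)

    def test_mean_pairwise_correlation_matches_double_loop_oracle(self, rng):
        traces = rng.normal(size=(8, 60))
        net = build_adjacency(traces)
        vals = []
        for i in range(8):
            for j in range(i + 1, 8):
                vals.append(sps.pearsonr(traces[i], traces[j])[0])
        r_avg, r_sd = mean_pairwise_correlation(net)
        assert r_avg == pytest.approx(np.mean(vals), abs=1e-12)
        assert r_sd == pytest.approx(np.std(vals, ddof=1), abs=1e-12)

    def test_hub_boundary_is_inclusive(self):
        # 9 cells, one with exactly 2/8 = 25% links
        net = graph(9, [(0, 1), (0, 2)])
        share = net.degrees / 8
        assert share[0] == 0.25
        assert hub_fraction(net) == pytest.approx(1 / 9)
        assert hub_fraction(STAR5) == 1.0  # center 100%, leaves exactly 25%
        assert hub_fraction(graph(5, [])) == 0.0

    def test_clustering_is_normalised_degree(self):
        c, c_avg = clustering_coefficient(graph(4, [(0, 1), (0, 2)]))
        assert c[0] == pytest.approx(2 / 3)
        _, c_k = clustering_coefficient(K3)
        assert c_k == 1.0
        # degree-count oracle on a random graph
        rng = np.random.default_rng(7)
        a = rng.random((10, 10)) < 0.3
        a = np.triu(a, 1)
        net = net_from_adjacency(a | a.T)
        _, c_avg = clustering_coefficient(net)
        assert c_avg == pytest.approx(net.degrees.mean() / 9)

    def test_transitivity_differs_from_printed_form_on_star(self):
        assert transitivity_clustering(STAR5) == 0.0
        assert clustering_coefficient(STAR5)[1] > 0.0

    def test_shortest_paths_chain_and_disconnected(self):
        p = shortest_paths(CHAIN3)
        assert p[0, 2] == 2.0
        pd = shortest_paths(DISJOINT4)
        assert np.isinf(pd[0, 2])

    def test_characteristic_path_length_closed_forms(self):
        assert characteristic_path_length(shortest_paths(CHAIN3), 3) == pytest.approx(4 / 3)
        assert characteristic_path_length(shortest_paths(K3), 3) == 1.0
        assert characteristic_path_length(shortest_paths(DISJOINT4), 4) == pytest.approx(1 / 3)

    def test_global_efficiency_closed_forms(self):
        assert global_efficiency(shortest_paths(K3), 3) == 1.0
        assert global_efficiency(shortest_paths(CHAIN3), 3) == pytest.approx(5 / 6)
        assert global_efficiency(shortest_paths(DISJOINT4), 4) == pytest.approx(1 / 3)


class TestGraphProperties:
    def test_paths_match_floyd_warshall_oracle(self, rng):
        for _ in range(30):
            n = int(rng.integers(4, 12))
            a = np.triu(rng.random((n, n)) < 0.3, 1)
            net = net_from_adjacency(a | a.T)
            got = shortest_paths(net)
            # independent Floyd-Warshall
            d = np.where(net.A, 1.0, np.inf)
            np.fill_diagonal(d, 0.0)
            for k in range(n):
                for i in range(n):
                    for j in range(n):
                        d[i, j] = min(d[i, j], d[i, k] + d[k, j])
            assert np.array_equal(got, d)

    def test_adding_an_edge_never_hurts_efficiency(self, rng):
        for _ in range(10):
            n = 10
            a = np.triu(rng.random((n, n)) < 0.2, 1)
            a = a | a.T
            net = net_from_adjacency(a)
            e0 = global_efficiency(shortest_paths(net), n)
            free = np.argwhere(~a & np.triu(np.ones((n, n), bool), 1))
            if len(free) == 0:
                continue
            i, j = free[rng.integers(len(free))]
            a2 = a.copy()
            a2[i, j] = a2[j, i] = True
            e1 = global_efficiency(shortest_paths(net_from_adjacency(a2)), n)
            assert e1 >= e0 - 1e-12

    def test_metrics_invariant_under_relabeling(self, rng):
        traces = rng.normal(size=(12, 80))
        traces[:6] += 2 * np.sin(np.linspace(0, 6 * np.pi, 80))
        net = build_adjacency(traces, r_th=0.5)
        perm = rng.permutation(12)
        net_p = build_adjacency(traces[perm], r_th=0.5)
        m1, m2 = net.metrics(), net_p.metrics()
        for key in m1:
            assert m1[key] == pytest.approx(m2[key], abs=1e-12)


class TestCalibration:
    def test_identical_traces_degenerate_scan_returns_default(self):
        base = np.sin(np.linspace(0, 10 * np.pi, 200))
        traces = np.vstack([base] * 12)
        with pytest.warns(UserWarning):
            scan = calibrate_threshold(traces, check_significance=False)
        assert not scan.qualified
        assert scan.r_th == 0.95

    def test_hub_structured_traces_yield_a_qualifying_threshold(self, rng):
        # follower groups with power-law sizes: degree histogram counts
        # (2, 4, 8, 16, 32) over degrees (1, 3, 7, 15, 31) fall on a
        # perfect log-log line at thresholds that resolve the groups
        sizes = [32, 16, 8, 4, 2]
        traces = []
        for g, size in enumerate(sizes):
            generator = rng.normal(size=300)
            for _ in range(size):
                traces.append(generator + 0.05 * rng.normal(size=300))
        traces = np.array(traces)
        scan = calibrate_threshold(traces, check_significance=True)
        assert scan.qualified
        assert 0.80 <= scan.r_th <= 0.999
        assert scan.link_significance_fraction is not None
        assert scan.link_significance_fraction > 0.9

    def test_mean_degree_non_increasing_in_threshold(self, rng):
        traces = rng.normal(size=(15, 100))
        traces += np.sin(np.linspace(0, 6 * np.pi, 100))
        with pytest.warns(UserWarning):  # noisy traces need not qualify
            scan = calibrate_threshold(traces, check_significance=False)
        degs = [row["mean_degree"] for row in scan.scan]
        assert all(a >= b for a, b in zip(degs, degs[1:]))

    def test_too_few_cells_rejected(self, rng):
        with pytest.raises(InputError):
            calibrate_threshold(rng.normal(size=(5, 50)))


class TestGroupRecovery:
    def test_block_structure_recovered_exactly_without_noise(self, rng):
        g = 4
        sources = rng.normal(size=(g, 100))
        membership = np.repeat(np.arange(g), 5)
        traces = sources[membership]
        net = build_adjacency(traces, r_th=0.95)
        expected = membership[:, None] == membership[None, :]
        np.fill_diagonal(expected, False)
        assert np.array_equal(net.A, expected)

    def test_mean_correlation_decreases_with_group_count(self, rng):
        r_avgs = []
        gs = [1, 2, 4, 8]
        for g in gs:
            vals = []
            for _ in range(10):
                sources = rng.normal(size=(g, 80))
                membership = np.tile(np.arange(g), 16 // g)
                traces = sources[membership] + 0.01 * rng.normal(size=(16, 80))
                net = build_adjacency(traces)
                vals.append(mean_pairwise_correlation(net)[0])
            r_avgs.append(np.mean(vals))
        rho, p = sps.spearmanr(gs, r_avgs)
        assert rho < 0
        assert all(a > b for a, b in zip(r_avgs, r_avgs[1:]))
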