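import numpy as np
import pytest

from netcentral.graph import build_edge_arrays
from netcentral.netgen import BAParams, generate_ba
from netcentral.oracle import _adjacency, enumerate_geodesics, serial_bfs_distances
from netcentral.sssp import (
    UNREACHABLE,
    accumulate_dependencies,
    accumulate_path_counts,
    apsp,
    bfs_edge_parallel,
)
from conftest import er_graph

ENGINES = ["ref", "vec"]


def _serial_d(graph, source):
    """Queue-based oracle distances, UNREACHABLE sentinel substituted."""
    dist = serial_bfs_distances(_adjacency(graph), source)
    return np.array([UNREACHABLE if d < 0 else d for d in dist], dtype=np.int64)


@pytest.mark.parametrize("engine", ENGINES)
class TestBFS:
    def test_star_from_center(self, star4, engine):
        arrays = build_edge_arrays(star4)
        res = bfs_edge_parallel(arrays, 4, 0, engine=engine)
        assert res.d.tolist() == [0, 1, 1, 1]
        assert res.sigma.tolist() == [1, 1, 1, 1]

    def test_cycle_two_geodesics(self, cycle4, engine):
        arrays = build_edge_arrays(cycle4)
        res = bfs_edge_parallel(arrays, 4, 0, engine=engine)
        assert res.d.tolist() == [0, 1, 2, 1]
        assert res.sigma.tolist() == [1, 1, 2, 1]

    def test_disconnected(self, disjoint_edges, engine):
        arrays = build_edge_arrays(disjoint_edges)
        res = bfs_edge_parallel(arrays, 4, 0, engine=engine)
        assert res.d[2] == UNREACHABLE and res.d[3] == UNREACHABLE
        assert res.sigma[2] == 0 and res.sigma[3] == 0

    def test_source_invariants(self, path3, engine):
        arrays = build_edge_arrays(path3)
        res = bfs_edge_parallel(arrays, 3, 0, engine=engine)
        assert res.d[0] == 0 and res.sigma[0] == 1
        assert not res.delta.any()

    def test_source_out_of_range(self, path3, engine):
        arrays = build_edge_arrays(path3)
        with pytest.raises(ValueError, match="out of range"):
            bfs_edge_parallel(arrays, 3, 3, engine=engine)
        with pytest.raises(ValueError, match="out of range"):
            bfs_edge_parallel(arrays, 3, -1, engine=engine)

    def test_pred_flag_sigma_identity(self, engine):
        g = er_graph(12, 0.4, seed=5)
        arrays = build_edge_arrays(g)
        for res in apsp(arrays, g.n, engine=engine):
            for v in range(g.n):
                if v == res.source or res.d[v] == UNREACHABLE:
                    continue
                incoming = res.pred_flag & (arrays.tail == v)
                assert res.sigma[v] == res.sigma[arrays.head[incoming]].sum()

    def test_idempotence(self, engine):
        g = er_graph(15, 0.3, seed=2)
        arrays = build_edge_arrays(g)
        a = bfs_edge_parallel(arrays, g.n, 3, engine=engine)
        b = bfs_edge_parallel(arrays, g.n, 3, engine=engine)
        assert np.array_equal(a.d, b.d)
        assert np.array_equal(a.sigma, b.sigma)
        assert np.array_equal(a.pred_flag, b.pred_flag)

    def test_max_level_is_source_eccentricity(self, engine):
        g = er_graph(20, 0.2, seed=8)
        arrays = build_edge_arrays(g)
        for s in range(g.n):
            res = bfs_edge_parallel(arrays, g.n, s, engine=engine)
            reached = res.d[res.d != UNREACHABLE]
            assert res.max_level() == reached.max()

    def test_matches_serial_bfs_on_random_graphs(self, engine):
        # level-synchrony: identical to textbook queue BFS on 100 graphs
        cases = 0
        for seed in range(34):
            for p in (0.15, 0.35, 0.6):
                g = er_graph(5 + seed % 8, p, seed=seed)
                arrays = build_edge_arrays(g)
                for s in range(g.n):
                    res = bfs_edge_parallel(arrays, g.n, s, engine=engine)
                    assert np.array_equal(res.d, _serial_d(g, s))
                cases += 1
        assert cases >= 100

    def test_sigma_matches_exhaustive_enumeration(self, engine):
        for seed in range(10):
            g = er_graph(9, 0.35, seed=100 + seed)
            adj = _adjacency(g)
            dist = [serial_bfs_distances(adj, s) for s in range(g.n)]
            arrays = build_edge_arrays(g)
            for s in range(g.n):
                res = bfs_edge_parallel(arrays, g.n, s, engine=engine)
                for t in range(g.n):
                    if t == s:
                        continue
                    expected = len(enumerate_geodesics(adj, s, t, dist[s], dist[t]))
                    assert res.sigma[t] == expected


@pytest.mark.parametrize("engine", ENGINES)
class TestDependencies:
    def _deps(self, graph, source, engine):
        arrays = build_edge_arrays(graph)
        res = bfs_edge_parallel(arrays, graph.n, source, engine=engine)
        return accumulate_dependencies(res, arrays, engine=engine).delta

    def test_path_from_endpoint(self, path3, engine):
        delta = self._deps(path3, 0, engine)
        assert delta[1] == 1.0 and delta[2] == 0.0

    def test_star_from_leaf(self, star4, engine):
        delta = self._deps(star4, 1, engine)
        assert delta[0] == 2.0  # center mediates the 2 other-leaf targets
        assert delta[2] == 0.0 and delta[3] == 0.0

    def test_star_from_center(self, star4, engine):
        delta = self._deps(star4, 0, engine)
        assert delta[1:].tolist() == [0.0, 0.0, 0.0]

    def test_requires_zeroed_delta(self, path3, engine):
        arrays = build_edge_arrays(path3)
        res = bfs_edge_parallel(arrays, 3, 0, engine=engine)
        accumulate_dependencies(res, arrays, engine=engine)
        with pytest.raises(ValueError, match="zero-initialized"):
            accumulate_dependencies(res, arrays, engine=engine)

    def test_dependency_sum_identity(self, engine):
        # connected graphs: sum_v delta[v] = sum_t (d[t] - 1)
        for seed in range(5):
            g = generate_ba(BAParams(n=60, beta=2, seed=seed))
            arrays = build_edge_arrays(g)
            for s in range(0, g.n, 7):
                res = bfs_edge_parallel(arrays, g.n, s, engine=engine)
                accumulate_dependencies(res, arrays, engine=engine)
                mask = np.arange(g.n) != s
                expected = (res.d[mask] - 1).sum()
                assert res.delta[mask].sum() == pytest.approx(expected, rel=1e-12)

    def test_path_counts_nonnegative(self, engine):
        g = er_graph(10, 0.4, seed=3)
        arrays = build_edge_arrays(g)
        res = bfs_edge_parallel(arrays, g.n, 0, engine=engine)
        counts = accumulate_path_counts(res, arrays, engine=engine)
        assert (counts >= 0).all()


class TestAPSP:
    def test_distance_matrix_path(self, path3):
        arrays = build_edge_arrays(path3)
        rows = [res.d.tolist() for res in apsp(arrays, 3)]
        assert rows == [[0, 1, 2], [1, 0, 1], [2, 1, 0]]

    def test_symmetry(self):
        g = er_graph(12, 0.3, seed=17)
        arrays = build_edge_arrays(g)
        dmat = np.stack([res.d for res in apsp(arrays, g.n)])
        assert np.array_equal(dmat, dmat.T)

    def test_matches_serial_oracle(self):
        g = er_graph(10, 0.3, seed=4)
        arrays = build_edge_arrays(g)
        for res in apsp(arrays, g.n):
            assert np.array_equal(res.d, _serial_d(g, res.source))

    def test_streaming(self, path3):
        arrays = build_edge_arrays(path3)
        it = apsp(arrays, 3)
        first = next(it)
        assert first.source == 0  # lazily yields one result at a time

    def test_bad_engine(self, path3):
        arrays = build_edge_arrays(path3)
        with pytest.raises(ValueError, match="engine"):
            bfs_edge_parallel(arrays, 3, 0, engine="gpu")

    def test_n_mismatch(self, path3):
        arrays = build_edge_arrays(path3)
        with pytest.raises(ValueError, match="disagrees"):
            bfs_edge_parallel(arrays, 5, 0)


class TestEngineEquivalence:
    def test_bitwise_identical_results(self):
        for seed in range(6):
            g = er_graph(14, 0.3, seed=seed)
            arrays = build_edge_arrays(g)
            for s in range(g.n):
                a = bfs_edge_parallel(arrays, g.n, s, engine="ref")
                b = bfs_edge_parallel(arrays, g.n, s, engine="vec")
                assert np.array_equal(a.d, b.d)
                assert np.array_equal(a.sigma, b.sigma)
                assert np.array_equal(a.pred_flag, b.pred_flag)
                accumulate_dependencies(a, arrays, engine="ref")
                accumulate_dependencies(b, arrays, engine="vec")
                np.testing.assert_allclose(a.delta, b.delta, rtol=1e-12, atol=0)
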