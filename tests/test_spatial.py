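"""Lattice construction, Leroux precision and autocorrelation diagnostics."""

import numpy as np
import pytest

from refrate.spatial import (
    AreaLattice,
    build_grid_lattice,
    lag1_autocorrelation,
    leroux_precision,
    morans_i,
    read_dense_adjacency,
    read_edge_list,
    write_dense_adjacency,
    write_edge_list,
)


def _morans_i_bruteforce(values, W):
    """O(N^2) double-loop definition of Moran's I."""
    v = np.asarray(values, dtype=float)
    n = len(v)
    vbar = v.mean()
    num = sum(
        W[i, j] * (v[i] - vbar) * (v[j] - vbar) for i in range(n) for j in range(n)
    )
    s0 = W.sum()
    return n / s0 * num / ((v - vbar) ** 2).sum()


def _leroux_bruteforce(rho, W):
    """Entry-by-entry Leroux precision via explicit loops."""
    n = W.shape[0]
    Q = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            if i == j:
                Q[i, j] = rho * W[i].sum() + (1 - rho)
            else:
                Q[i, j] = -rho * W[i, j]
    return Q


class TestGridLattice:
    def test_two_cell_chain(self):
        lat = build_grid_lattice(1, 2, "rook")
        assert np.array_equal(lat.W, [[0, 1], [1, 0]])

    def test_2x2_queen_is_complete(self):
        lat = build_grid_lattice(2, 2, "queen")
        assert np.array_equal(lat.W, np.ones((4, 4)) - np.eye(4))

    def test_3x3_rook_degrees_and_edge_count(self):
        lat = build_grid_lattice(3, 3, "rook")
        deg = lat.degrees
        assert deg[4] == 4  # centre
        assert deg[0] == deg[2] == deg[6] == deg[8] == 2  # corners
        assert lat.W.sum() / 2 == 12  # enumerated horizontal + vertical edges

    def test_interior_queen_degree(self):
        lat = build_grid_lattice(5, 5, "queen")
        assert lat.degrees[12] == 8

    @pytest.mark.parametrize("rows,cols", [(1, 1), (0, 5)])
    def test_too_small_rejected(self, rows, cols):
        with pytest.raises(ValueError):
            build_grid_lattice(rows, cols, "rook")

    def test_invariants_enforced(self):
        with pytest.raises(ValueError, match="symmetric"):
            AreaLattice(("a", "b"), np.array([[0.0, 1.0], [0.0, 0.0]]))
        with pytest.raises(ValueError, match="neighbour"):
            AreaLattice(("a", "b"), np.zeros((2, 2)))


class TestLerouxPrecision:
    def test_independence_limit(self):
        lat = build_grid_lattice(3, 3, "queen")
        assert np.allclose(leroux_precision(0.0, lat).Q, np.eye(9))

    def test_intrinsic_limit_two_nodes(self):
        lat = build_grid_lattice(1, 2, "rook")
        pm = leroux_precision(1.0, lat)
        assert np.allclose(pm.Q, [[1, -1], [-1, 1]])
        assert pm.is_singular
        assert np.allclose(pm.Q.sum(axis=1), 0)

    def test_2x2_queen_half(self):
        lat = build_grid_lattice(2, 2, "queen")
        Q = leroux_precision(0.5, lat).Q
        assert np.allclose(Q, _leroux_bruteforce(0.5, lat.W))
        assert np.linalg.eigvalsh(Q).min() > 0

    @pytest.mark.parametrize("rho", [-0.1, 1.5])
    def test_domain_error(self, rho):
        lat = build_grid_lattice(1, 2, "rook")
        with pytest.raises(ValueError):
            leroux_precision(rho, lat)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_bruteforce_random_lattices(self, seed):
        rng = np.random.default_rng(seed)
        rows, cols = rng.integers(2, 6, size=2)
        contig = ("rook", "queen")[seed % 2]
        lat = build_grid_lattice(int(rows), int(cols), contig)
        assert lat.n_areas <= 25
        rho = float(rng.uniform())
        assert np.allclose(
            leroux_precision(rho, lat).Q, _leroux_bruteforce(rho, lat.W)
        )


class TestMoransI:
    def test_alternating_chain_is_minus_one(self):
        lat = build_grid_lattice(1, 4, "rook")
        stat, _ = morans_i([1, -1, 1, -1], lat, n_perm=99, seed=0)
        assert stat == pytest.approx(-1.0)

    def test_null_expectation(self):
        # E[I] = -1/(N-1) for exchangeable values
        lat = build_grid_lattice(5, 5, "queen")
        rng = np.random.default_rng(42)
        stats = [
            morans_i(rng.standard_normal(25), lat, n_perm=1, seed=0)[0]
            for _ in range(400)
        ]
        assert np.mean(stats) == pytest.approx(-1 / 24, abs=0.015)

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_bruteforce(self, seed):
        rng = np.random.default_rng(seed)
        lat = build_grid_lattice(int(rng.integers(2, 6)), int(rng.integers(2, 6)), "queen")
        v = rng.standard_normal(lat.n_areas)
        stat, _ = morans_i(v, lat, n_perm=1, seed=0)
        assert stat == pytest.approx(_morans_i_bruteforce(v, lat.W), rel=1e-12)

    def test_shift_and_scale_invariance(self):
        lat = build_grid_lattice(4, 4, "rook")
        rng = np.random.default_rng(7)
        v = rng.standard_normal(16)
        base, _ = morans_i(v, lat, n_perm=1, seed=0)
        shifted, _ = morans_i(v + 100.0, lat, n_perm=1, seed=0)
        scaled, _ = morans_i(3.5 * v, lat, n_perm=1, seed=0)
        assert shifted == pytest.approx(base, rel=1e-10)
        assert scaled == pytest.approx(base, rel=1e-10)

    def test_constant_vector_rejected(self):
        lat = build_grid_lattice(2, 2, "rook")
        with pytest.raises(ValueError, match="constant"):
            morans_i([2.0, 2.0, 2.0, 2.0], lat, n_perm=9, seed=0)

    def test_seed_reproducibility(self):
        lat = build_grid_lattice(3, 3, "queen")
        v = np.arange(9.0)
        r1 = morans_i(v, lat, n_perm=199, seed=11)
        r2 = morans_i(v, lat, n_perm=199, seed=11)
        assert r1 == r2

    def test_permutation_pvalue_calibration(self):
        # type-I error of the two-sided permutation test at the 5% level
        lat = build_grid_lattice(5, 5, "queen")
        rng = np.random.default_rng(123)
        rejections = 0
        n_rep = 500
        for _ in range(n_rep):
            _, p = morans_i(rng.standard_normal(25), lat, n_perm=199, seed=rng)
            rejections += p <= 0.05
        assert abs(rejections / n_rep - 0.05) <= 0.02


class TestLag1Autocorrelation:
    def test_alternating_series(self):
        # plug-in estimator: T-1 cross terms over T squared terms -> -(T-1)/T
        series = np.array([[1.0, -1, 1, -1, 1, -1, 1, -1]])
        acf, mean = lag1_autocorrelation(series)
        assert acf[0] == pytest.approx(-7 / 8)
        assert mean == pytest.approx(-7 / 8)

    def test_monotone_series_hand_value(self):
        # centred (1..8): num = sum c_t c_{t+1} = 26.25, denom = 42
        acf, _ = lag1_autocorrelation(np.array([[1.0, 2, 3, 4, 5, 6, 7, 8]]))
        assert acf[0] == pytest.approx(26.25 / 42.0)

    def test_identical_areas_mean(self):
        series = np.array([[1.0, 2, 3, 5, 4], [1.0, 2, 3, 5, 4]])
        acf, mean = lag1_autocorrelation(series)
        assert mean == pytest.approx(acf[0])

    def test_constant_series_excluded_with_warning(self):
        series = np.array([[1.0, 2, 3, 4], [5.0, 5, 5, 5]])
        with pytest.warns(RuntimeWarning, match="constant"):
            acf, mean = lag1_autocorrelation(series)
        assert np.isnan(acf[1])
        assert mean == pytest.approx(acf[0])

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            lag1_autocorrelation(np.array([[1.0, 2.0]]))


class TestAdjacencyIO:
    def test_edge_list_roundtrip(self, tmp_path):
        lat = build_grid_lattice(3, 4, "queen")
        path = tmp_path / "edges.csv"
        write_edge_list(lat, path)
        back = read_edge_list(path, lat.area_ids)
        assert back.area_ids == lat.area_ids
        assert np.array_equal(back.W, lat.W)

    def test_dense_roundtrip(self, tmp_path):
        lat = build_grid_lattice(2, 3, "rook")
        path = tmp_path / "W.csv"
        write_dense_adjacency(lat, path)
        back = read_dense_adjacency(path)
        assert np.array_equal(back.W, lat.W)
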