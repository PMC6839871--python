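import numpy as np
import pytest

from pollinet.metrics import (
    SAConfig,
    barber_modularity,
    basic_descriptors,
    drop_empty,
    exhaustive_max_modularity,
    h2_extremes,
    h2_extremes_exhaustive,
    h2prime,
    nodf,
    optimize_modularity,
    robustness,
    robustness_exhaustive,
)

TRIANGLE3 = [[1, 1, 1], [1, 1, 0], [1, 0, 0]]
BLOCKS = np.block([[np.ones((2, 2)), np.zeros((2, 2))],
                   [np.zeros((2, 2)), np.ones((2, 2))]])


class TestNodf:
    @pytest.mark.parametrize("matrix, expected", [
        (TRIANGLE3, 100.0),
        (np.eye(2), 0.0),  # tied marginal totals contribute nothing
        ([[1, 1, 1, 0], [1, 1, 0, 0], [1, 0, 1, 0], [1, 0, 0, 0]], 700 / 12),
    ])
    def test_known_values(self, matrix, expected):
        assert nodf(matrix) == pytest.approx(expected)

    def test_needs_two_rows_and_columns(self):
        with pytest.raises(ValueError):
            nodf([[1, 1]])

    def test_counts_binarized(self):
        assert nodf(np.asarray(TRIANGLE3) * 7) == pytest.approx(100.0)


class TestH2prime:
    def test_diagonal_is_maximally_specialized(self):
        assert h2prime(np.eye(5) * 10) == pytest.approx(1.0)

    def test_uniform_matrix_has_no_specialization(self):
        assert h2prime(np.full((2, 2), 3.0)) == pytest.approx(0.0)

    def test_matches_exhaustive_extremes(self):
        A = [[4, 1, 0], [1, 2, 1], [0, 1, 2]]
        exact = h2prime(A, extremes=h2_extremes_exhaustive(A))
        assert h2prime(A) == pytest.approx(exact)

    def test_stable_under_integer_scaling(self):
        # scaling all counts changes the achievable entropy extremes only
        # through integer granularity, so H2' moves very little
        A = np.array([[4, 1, 0], [1, 2, 1], [0, 1, 2]])
        assert h2prime(3 * A) == pytest.approx(h2prime(A), abs=0.05)

    def test_clamped_to_unit_interval(self, rng):
        for _ in range(20):
            A = rng.integers(0, 6, size=(4, 5))
            if A.sum() == 0:
                continue
            assert 0.0 <= h2prime(A) <= 1.0


class TestBarberModularity:
    def test_single_module_is_zero(self, rng):
        A = rng.integers(0, 5, size=(4, 6)) + 1
        assert barber_modularity(A, [0] * 10) == pytest.approx(0.0)

    def test_two_disjoint_blocks(self):
        assert barber_modularity(BLOCKS, [0, 0, 1, 1, 0, 0, 1, 1]) == pytest.approx(0.5)

    def test_partition_must_cover_all_species(self):
        with pytest.raises(ValueError):
            barber_modularity(BLOCKS, [0, 0, 1, 1])


class TestOptimizeModularity:
    def test_recovers_two_blocks(self):
        g, q = optimize_modularity(BLOCKS, seed=1)
        assert q == pytest.approx(0.5)
        assert len(np.unique(g)) == 2
        # plants and visitors of the same block share a module
        assert g[0] == g[1] == g[4] == g[5] and g[2] == g[3] == g[6] == g[7]

    def test_complete_bipartite_has_no_modules(self):
        _, q_exh = exhaustive_max_modularity(np.ones((4, 4)))
        _, q_sa = optimize_modularity(np.ones((4, 4)), seed=3)
        assert q_exh == pytest.approx(0.0, abs=1e-12)
        assert q_sa == pytest.approx(0.0, abs=1e-12)

    def test_deterministic_given_seed(self):
        A = np.array([[3, 1, 0, 0], [1, 2, 1, 0], [0, 0, 2, 3], [0, 1, 1, 2]])
        g1, q1 = optimize_modularity(A, seed=7)
        g2, q2 = optimize_modularity(A, seed=7)
        assert q1 == q2 and np.array_equal(g1, g2)

    def test_never_below_tested_partitions(self, rng):
        A = rng.integers(0, 4, size=(3, 4)).astype(float)
        A[A.sum(axis=1) == 0, 0] = 1
        A[0, A.sum(axis=0) == 0] = 1
        _, q = optimize_modularity(A, seed=0)
        for _ in range(30):
            g = rng.integers(0, 3, size=7)
            assert q >= barber_modularity(A, g) - 1e-9


class TestRobustness:
    @pytest.mark.parametrize("matrix, expected", [
        ([[1]], 0.5),
        (np.ones((2, 2)), 0.75),
        (np.eye(2), 0.5),
    ])
    def test_known_values(self, matrix, expected):
        R, _ = robustness(matrix, n_orders=8, seed=0)
        assert R == pytest.approx(expected)

    def test_matches_exhaustive_orders(self):
        A = np.array([[1, 1, 0], [0, 1, 1], [1, 0, 1], [1, 1, 1]])
        R, _ = robustness(A, n_orders=2000, seed=0)
        assert R == pytest.approx(robustness_exhaustive(A), abs=0.01)

    def test_curve_endpoints(self, rng):
        A = rng.integers(0, 3, size=(5, 6))
        A[A.sum(axis=1) == 0, 0] = 1
        A[0, A.sum(axis=0) == 0] = 1
        _, curve = robustness(A, n_orders=20, seed=1)
        assert curve[0] == pytest.approx(1.0) and curve[-1] == pytest.approx(0.0)

    def test_visitor_removal_guild(self):
        R, curve = robustness(np.ones((2, 3)), removal_guild="visitors", n_orders=5, seed=0)
        assert len(curve) == 4  # three visitors removed stepwise

    def test_rejects_bad_order_count(self):
        with pytest.raises(ValueError):
            robustness(np.ones((2, 2)), n_orders=0)


class TestInvariances:
    def test_permutation_invariance(self, rng):
        for _ in range(5):
            A = rng.integers(0, 5, size=(5, 6)).astype(float)
            A[A.sum(axis=1) == 0, 0] = 1
            A[0, A.sum(axis=0) == 0] = 1
            P = A[rng.permutation(5)][:, rng.permutation(6)]
            assert nodf(P) == pytest.approx(nodf(A))
            assert h2prime(P) == pytest.approx(h2prime(A))
            R1, _ = robustness(A, n_orders=3000, seed=1)
            R2, _ = robustness(P, n_orders=3000, seed=2)
            assert R1 == pytest.approx(R2, abs=0.02)

    def test_heuristic_extremes_bracket_observed(self, rng):
        for _ in range(10):
            A = rng.integers(0, 5, size=(3, 4))
            if A.sum() == 0:
                continue
            h2min, h2max = h2_extremes(A)
            assert h2min <= h2max + 1e-12


class TestBasicDescriptors:
    @pytest.mark.parametrize("matrix, conn, lps, n_int", [
        (np.eye(2), 0.5, 0.5, 2),
        (np.ones((3, 4)), 1.0, 12 / 7, 12),
        (np.array([[1, 1, 0, 0], [1, 1, 0, 0], [1, 0, 0, 0], [1, 0, 0, 0]]),
         0.375, 0.75, 6),
    ])
    def test_values(self, matrix, conn, lps, n_int):
        d = basic_descriptors(matrix)
        assert d["connectance"] == pytest.approx(conn)
        assert d["links_per_species"] == pytest.approx(lps)
        assert d["n_pairwise_interactions"] == n_int


def test_nodf_matches_vegan(tmp_path, rng):
    """Independent cross-check against the reference NODF implementation
    (vegan::nestednodf) on random binary matrices."""
    import subprocess

    for k in range(3):
        A = (rng.random((5 + k, 7)) < 0.45).astype(int)
        A[A.sum(axis=1) == 0, 0] = 1
        A[0, A.sum(axis=0) == 0] = 1
        path = tmp_path / f"m{k}.csv"
        np.savetxt(path, A, fmt="%d", delimiter=",")
        res = subprocess.run(
            ["Rscript", "-e",
             f'm <- as.matrix(read.csv("{path}", header=FALSE)); '
             'cat(sprintf("%.10f", vegan::nestednodf(m)$statistic["NODF"]))'],
            capture_output=True, text=True, check=True)
        assert nodf(A) == pytest.approx(float(res.stdout.strip()), abs=1e-8)


def test_drop_empty_warns_and_removes():
    A = np.array([[1, 0, 2], [0, 0, 0], [3, 0, 1]])
    with pytest.warns(UserWarning):
        B = drop_empty(A)
    assert B.shape == (2, 2)
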