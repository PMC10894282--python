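import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from myorsa import (rank_distance, kendall_tau_a, build_rdm,
                    build_split_rdm, compute_edi, edi_randomization_test,
                    rdm_relatedness_test, nonmetric_mds, RDM, SplitRDM,
                    UndefinedStatisticError)
from conftest import make_summary


# ---------------------------------------------------------------------------
# brute-force pair-counting oracles

def brute_tau_b(x, y):
    n = len(x)
    conc = disc = tx = ty = 0
    for i, j in itertools.combinations(range(n), 2):
        dx, dy = x[i] - x[j], y[i] - y[j]
        if dx == 0 and dy == 0:
            continue
        if dx == 0:
            tx += 1
        elif dy == 0:
            ty += 1
        elif dx * dy > 0:
            conc += 1
        else:
            disc += 1
    denom = np.sqrt((conc + disc + tx) * (conc + disc + ty))
    return (conc - disc) / denom


def brute_tau_a(x, y):
    n = len(x)
    s = sum(np.sign(x[i] - x[j]) * np.sign(y[i] - y[j])
            for i, j in itertools.combinations(range(n), 2))
    return s / (n * (n - 1) / 2)


def brute_edi(mat):
    n = mat.shape[0]
    off = [mat[i, j] for i in range(n) for j in range(n) if i != j]
    return np.mean(off) - np.mean(np.diag(mat))


vector6 = st.lists(st.integers(0, 5), min_size=2, max_size=6)


class TestRankDistance:
    def test_self_distance_zero(self):
        u = np.array([3.0, 1.0, 4.0, 2.0])
        assert rank_distance(u, u) == pytest.approx(0.0)

    def test_reversed_distance_two(self):
        u = np.array([1.0, 2.0, 3.0, 4.0])
        assert rank_distance(u, u[::-1]) == pytest.approx(2.0)

    def test_one_swap_example(self):
        u = np.array([1.0, 2.0, 3.0, 4.0])
        v = np.array([1.0, 3.0, 2.0, 4.0])
        assert rank_distance(u, v) == pytest.approx(1.0 - 4.0 / 6.0)

    def test_fully_tied_vector_undefined(self):
        with pytest.raises(UndefinedStatisticError):
            rank_distance(np.ones(4), np.array([1.0, 2.0, 3.0, 4.0]))

    @given(vector6, vector6)
    @settings(max_examples=150, deadline=None)
    def test_matches_pair_counting_oracle(self, x, y):
        n = min(len(x), len(y))
        x, y = np.array(x[:n], float), np.array(y[:n], float)
        if n < 2 or np.ptp(x) == 0 or np.ptp(y) == 0:
            return
        assert rank_distance(x, y) == pytest.approx(
            1.0 - brute_tau_b(x, y), abs=1e-12)


class TestTauA:
    def test_identity_and_reversal(self):
        x = np.array([2.0, 5.0, 1.0, 7.0])
        assert kendall_tau_a(x, x) == pytest.approx(1.0)
        order = np.argsort(x)
        assert kendall_tau_a(x, -x) == pytest.approx(-1.0)

    def test_one_tied_pair_example(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        y = np.array([1.0, 1.0, 2.0, 3.0])
        assert kendall_tau_a(x, y) == pytest.approx(5.0 / 6.0)

    @given(vector6, vector6)
    @settings(max_examples=150, deadline=None)
    def test_matches_pair_counting_oracle(self, x, y):
        n = min(len(x), len(y))
        if n < 2:
            return
        x, y = np.array(x[:n], float), np.array(y[:n], float)
        assert kendall_tau_a(x, y) == pytest.approx(
            brute_tau_a(x, y), abs=1e-12)


class TestRDMConstruction:
    def test_identical_vectors_zero_matrix(self):
        vec = [1.0, 2.0, 3.0, 4.0]
        summary = make_summary({m: vec for m in ("A", "B", "C")})
        rdm = build_rdm(summary, "RMS-median")
        assert np.allclose(rdm.matrix, 0.0)
        assert rdm.conditions == ("A", "B", "C")

    def test_reversed_vectors_distance_two(self):
        summary = make_summary({"A": [1, 2, 3, 4], "B": [4, 3, 2, 1]})
        rdm = build_rdm(summary, "RMS-median")
        assert rdm.matrix[0, 1] == pytest.approx(2.0)
        assert np.allclose(rdm.matrix, rdm.matrix.T)
        assert np.all(np.diag(rdm.matrix) == 0)

    def test_three_movement_toy_matches_oracle(self):
        vecs = {"A": [1.0, 3.0, 2.0, 4.0],
                "B": [2.0, 1.0, 4.0, 3.0],
                "C": [4.0, 2.0, 3.0, 1.0]}
        rdm = build_rdm(make_summary(vecs), "RMS-median")
        for i, mi in enumerate("ABC"):
            for j, mj in enumerate("ABC"):
                if i != j:
                    expected = 1.0 - brute_tau_b(
                        np.array(vecs[mi]), np.array(vecs[mj]))
                    assert rdm.matrix[i, j] == pytest.approx(expected)

    def test_split_identity_zero_diagonal(self):
        vecs = {"A": [1.0, 3.0, 2.0], "B": [2.0, 1.0, 3.0]}
        even = make_summary(vecs)
        odd = make_summary(vecs)
        sdrdm = build_split_rdm(even, odd, "RMS-median")
        assert np.allclose(np.diag(sdrdm.matrix), 0.0)

    def test_split_rdm_entries_match_direct_tau(self):
        even = {"A": [1.0, 2.0, 3.0], "B": [3.0, 1.0, 2.0]}
        odd = {"A": [2.0, 1.0, 3.0], "B": [1.0, 3.0, 2.0]}
        sdrdm = build_split_rdm(make_summary(even), make_summary(odd),
                                "RMS-median")
        for i, mi in enumerate("AB"):
            for j, mj in enumerate("AB"):
                expected = 1.0 - brute_tau_b(
                    np.array(even[mi]), np.array(odd[mj]))
                assert sdrdm.matrix[i, j] == pytest.approx(expected)

    def test_iqr_measure_uses_iqr_column(self):
        summary = make_summary({"A": [1, 2, 3], "B": [3, 2, 1]},
                               statistic="iqr")
        rdm = build_rdm(summary, "RMS-IQR")
        assert rdm.matrix[0, 1] == pytest.approx(2.0)


class TestEDI:
    def test_constant_matrix_zero(self):
        assert compute_edi(np.full((4, 4), 0.7)) == pytest.approx(0.0)

    def test_unit_contrast(self):
        mat = np.ones((5, 5)) - np.eye(5)
        assert compute_edi(mat) == pytest.approx(1.0)

    def test_three_by_three_means(self):
        mat = np.full((3, 3), 0.6)
        np.fill_diagonal(mat, [0.1, 0.2, 0.3])
        assert compute_edi(mat) == pytest.approx(0.4)

    @given(st.integers(0, 2 ** 30), st.integers(2, 6))
    @settings(max_examples=50, deadline=None)
    def test_matches_direct_means(self, seed, n):
        mat = np.random.default_rng(seed).uniform(0, 2, size=(n, n))
        assert compute_edi(mat) == pytest.approx(brute_edi(mat), abs=1e-12)


class TestEDIRandomization:
    def test_constant_matrix_p_one(self):
        res = edi_randomization_test(np.full((4, 4), 0.5),
                                     mode="exhaustive")
        assert res.p == 1.0

    def test_two_condition_null(self):
        mat = np.ones((2, 2)) - np.eye(2)
        res = edi_randomization_test(mat, mode="exhaustive")
        # null over both permutations is {1, -1}; observed 1
        assert res.null_size == 2
        assert res.p == pytest.approx(0.5)

    def test_three_condition_exhaustive_matches_enumeration(self):
        rng = np.random.default_rng(8)
        mat = rng.uniform(0, 2, size=(3, 3))
        res = edi_randomization_test(mat, mode="exhaustive")
        null = []
        for perm in itertools.permutations(range(3)):
            null.append(brute_edi(mat[list(perm), :]))
        observed = brute_edi(mat)
        expected_p = np.mean([e >= observed - 1e-12 for e in null])
        assert res.null_size == 6
        assert res.p == pytest.approx(expected_p)

    def test_monte_carlo_includes_identity(self):
        rng = np.random.default_rng(1)
        mat = rng.uniform(0, 2, size=(7, 7))
        res = edi_randomization_test(mat, mode="monte_carlo",
                                     n_draws=500, seed=0)
        assert res.null_size == 500
        assert 1 / 500 <= res.p <= 1.0

    def test_monte_carlo_deterministic_by_seed(self):
        mat = np.random.default_rng(2).uniform(0, 2, size=(6, 6))
        a = edi_randomization_test(mat, "monte_carlo", 1000, seed=5)
        b = edi_randomization_test(mat, "monte_carlo", 1000, seed=5)
        assert a.p == b.p

    def test_exhaustive_rejected_above_ten(self):
        with pytest.raises(ValueError):
            edi_randomization_test(np.zeros((11, 11)), mode="exhaustive")


def _rdm(matrix, conditions=None, measure="RMS-median"):
    matrix = np.asarray(matrix, dtype=float)
    conditions = conditions or tuple(
        f"M{i}" for i in range(matrix.shape[0]))
    return RDM(conditions, matrix, measure)


class TestRelatedness:
    def test_self_relatedness_significant(self):
        rng = np.random.default_rng(0)
        n = 10
        mat = np.zeros((n, n))
        iu = np.triu_indices(n, 1)
        vals = rng.permutation(np.linspace(0.1, 1.9, iu[0].size))
        mat[iu] = vals
        mat += mat.T
        res = rdm_relatedness_test(_rdm(mat), _rdm(mat),
                                   n_permutations=2000, seed=3)
        assert res.tau_a == pytest.approx(1.0)
        assert res.p <= 0.01

    def test_constant_affected_p_one(self):
        rng = np.random.default_rng(1)
        n = 6
        other = rng.uniform(0, 2, size=(n, n))
        other = (other + other.T) / 2
        np.fill_diagonal(other, 0)
        res = rdm_relatedness_test(_rdm(np.ones((n, n)) - np.eye(n)),
                                   _rdm(other), n_permutations=500, seed=0)
        assert res.p == 1.0

    def test_monte_carlo_matches_exhaustive_small_n(self):
        rng = np.random.default_rng(7)
        n = 4
        def sym(m):
            m = (m + m.T) / 2
            np.fill_diagonal(m, 0)
            return m
        a = sym(rng.uniform(0, 2, size=(n, n)))
        b = sym(rng.uniform(0, 2, size=(n, n)))
        iu = np.triu_indices(n, 1)
        observed = brute_tau_a(a[iu], b[iu])
        null = []
        for perm in itertools.permutations(range(n)):
            p = np.array(perm)
            null.append(brute_tau_a(a[np.ix_(p, p)][iu], b[iu]))
        exact_p = np.mean([e >= observed - 1e-12 for e in null])
        res = rdm_relatedness_test(_rdm(a), _rdm(b),
                                   n_permutations=10_000, seed=11)
        se = np.sqrt(exact_p * (1 - exact_p) / 10_000)
        assert abs(res.p - exact_p) <= 3 * se + 2 / 10_000

    def test_condition_mismatch_rejected(self):
        a = _rdm(np.zeros((3, 3)), ("A", "B", "C"))
        b = _rdm(np.zeros((3, 3)), ("A", "C", "B"))
        with pytest.raises(ValueError):
            rdm_relatedness_test(a, b)


class TestNonmetricMDS:
    def test_recovers_exact_euclidean_structure(self):
        rng = np.random.default_rng(0)
        pts = rng.normal(size=(5, 3))
        dist = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
        emb = nonmetric_mds(dist, dims=3, seed=0)
        assert emb.stress < 1e-4

    def test_line_distances_embed_on_a_line(self):
        dist = np.array([[0.0, 1.0, 2.0],
                         [1.0, 0.0, 1.0],
                         [2.0, 1.0, 0.0]])
        emb = nonmetric_mds(dist, dims=1, seed=0)
        assert emb.stress < 1e-6
        x = emb.coordinates[:, 0]
        # the point with the two short distances lies between the others
        assert min(x[0], x[2]) < x[1] < max(x[0], x[2])

    def test_deterministic_for_fixed_seed(self):
        rng = np.random.default_rng(5)
        mat = rng.uniform(0.2, 1.8, size=(8, 8))
        mat = (mat + mat.T) / 2
        np.fill_diagonal(mat, 0)
        a = nonmetric_mds(mat, seed=4)
        b = nonmetric_mds(mat, seed=4)
        assert np.array_equal(a.coordinates, b.coordinates)
        assert a.stress == b.stress

    def test_stress_history_non_increasing(self):
        rng = np.random.default_rng(6)
        mat = rng.uniform(0.2, 1.8, size=(9, 9))
        mat = (mat + mat.T) / 2
        np.fill_diagonal(mat, 0)
        emb = nonmetric_mds(mat, seed=1)
        hist = np.array(emb.stress_history)
        assert np.all(np.diff(hist) <= 1e-12)

    def test_too_few_conditions_rejected(self):
        with pytest.raises(ValueError):
            nonmetric_mds(np.zeros((3, 3)), dims=3)
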