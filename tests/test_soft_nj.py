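import numpy as np
import pytest
from autograd import jacobian
from autograd.tracer import getval

from phylograd import (
    PhyloTree,
    nj_q_matrix,
    simulate_tree,
    soft_argmin,
    soft_nj_decode,
    soft_sort_permutation,
    tree_path_distances,
)
from phylograd.soft_nj import BRANCH_LENGTH_FLOOR, smooth_branch_floor

from .conftest import classical_nj, rf_oracle


def _upper(vals, n):
    """Symmetric matrix from upper-triangle values (row-major)."""
    M = np.zeros((n, n))
    M[np.triu_indices(n, 1)] = vals
    return M + M.T


class TestSoftSort:
    def test_hard_descending_permutation(self):
        P = np.asarray(getval(soft_sort_permutation(np.array([3.0, 1.0, 2.0]), 1e-6)))
        expect = np.array([[1, 0, 0], [0, 0, 1], [0, 1, 0]], dtype=float)
        assert np.allclose(P, expect, atol=1e-6)

    def test_constant_vector_uniform_rows(self):
        P = np.asarray(getval(soft_sort_permutation(np.full(4, 2.5), 0.1)))
        assert np.allclose(P, 0.25)

    def test_rows_sum_to_one(self):
        rng = np.random.default_rng(0)
        for eta in (1e-6, 1e-2, 1.0):
            P = np.asarray(getval(soft_sort_permutation(rng.normal(size=7), eta)))
            assert np.allclose(P.sum(axis=1), 1.0, atol=1e-10)

    def test_nonpositive_temperature_errors(self):
        with pytest.raises(ValueError, match="eta"):
            soft_sort_permutation(np.ones(3), 0.0)
        with pytest.raises(ValueError, match="eta"):
            soft_sort_permutation(np.ones(3), -1.0)

    def test_nonfinite_input_errors(self):
        with pytest.raises(ValueError, match="finite"):
            soft_sort_permutation(np.array([1.0, np.inf]), 0.1)


class TestSoftArgmin:
    def test_unique_minimum(self):
        Q = _upper([5.0, 2.0, 1.0], 3)  # entries (0,1)=5 (0,2)=2 (1,2)=1
        sel = soft_argmin(Q, 1e-6)
        wr = np.asarray(getval(sel.row_weights))
        wc = np.asarray(getval(sel.col_weights))
        assert np.argmax(wr) == 1 and wr[1] > 1 - 1e-4
        assert np.argmax(wc) == 2 and wc[2] > 1 - 1e-4
        assert sel.hard_indices() == (1, 2)

    def test_tie_selects_first_in_flattened_order(self):
        # minima tied at flat positions (0,2) and (1,2)
        Q = _upper([5.0, 1.0, 1.0], 3)
        sel = soft_argmin(Q, 1e-6)
        assert sel.hard_indices() == (0, 2)
        wr = np.asarray(getval(sel.row_weights))
        assert np.argmax(wr) == 0

    def test_tie_determinism_under_position_swap(self):
        # swapping which positions hold the tied minimum moves the selection
        Q1 = _upper([1.0, 1.0, 5.0], 4 * 0 + 3)
        sel1 = soft_argmin(Q1, 1e-6)
        assert sel1.hard_indices() == (0, 1)  # first tied entry
        Q2 = _upper([5.0, 1.0, 1.0], 3)
        sel2 = soft_argmin(Q2, 1e-6)
        assert sel2.hard_indices() == (0, 2)

    def test_weights_sum_to_one(self):
        rng = np.random.default_rng(1)
        Q = _upper(rng.normal(size=10), 5)
        sel = soft_argmin(Q, 0.1)
        assert float(np.sum(getval(sel.row_weights))) == pytest.approx(1.0, abs=1e-6)
        assert float(np.sum(getval(sel.col_weights))) == pytest.approx(1.0, abs=1e-6)

    def test_gradient_matches_finite_differences(self):
        rng = np.random.default_rng(2)
        q0 = rng.normal(size=10)
        a = rng.normal(size=5)
        b = rng.normal(size=5)
        eta = 0.1

        def f(q):
            sel = soft_argmin(_upper_box(q, 5), eta)
            return sel.row_weights @ a + sel.col_weights @ b

        from autograd import grad
        g = np.asarray(getval(grad(f)(q0)))
        h = 1e-6
        for i in range(10):
            qp, qm = q0.copy(), q0.copy()
            qp[i] += h
            qm[i] -= h
            fd = (float(getval(f(qp))) - float(getval(f(qm)))) / (2 * h)
            assert g[i] == pytest.approx(fd, rel=1e-3, abs=1e-8)

    def test_too_small_errors(self):
        with pytest.raises(ValueError):
            soft_argmin(np.zeros((1, 1)), 0.1)


def _upper_box(vals, n):
    """Differentiable symmetric scatter of upper-triangle values."""
    rows, cols = np.triu_indices(n, 1)
    S = np.zeros((n * n, len(rows)))
    for k, (r, c) in enumerate(zip(rows, cols)):
        S[r * n + c, k] = 1.0
        S[c * n + r, k] = 1.0
    return (S @ vals).reshape(n, n)


class TestQMatrix:
    def test_m3_off_diagonals_equal(self):
        rng = np.random.default_rng(3)
        D = _upper(rng.uniform(1, 2, size=3), 3)
        Q = np.asarray(getval(nj_q_matrix(D)))
        off = Q[np.triu_indices(3, 1)]
        assert np.allclose(off, off[0])

    def test_textbook_four_taxon_pairs(self):
        # tree ((A:1,B:2):1,(C:3,D:4)) -> path distances
        D = np.array([
            [0, 3, 5, 6],
            [3, 0, 6, 7],
            [5, 6, 0, 7],
            [6, 7, 7, 0],
        ], dtype=float)
        Q = np.asarray(getval(nj_q_matrix(D)))
        iu = np.triu_indices(4, 1)
        flat = Q[iu]
        best = np.argmin(flat)
        pair = (iu[0][best], iu[1][best])
        assert pair in ((0, 1), (2, 3))

    def test_matches_brute_force_loop(self):
        rng = np.random.default_rng(4)
        D = _upper(rng.uniform(0.5, 3.0, size=15), 6)
        Q = np.asarray(getval(nj_q_matrix(D)))
        m = 6
        S = D.sum(axis=1)
        for i in range(m):
            for j in range(m):
                if i == j:
                    assert Q[i, j] == pytest.approx(1e10)
                else:
                    assert Q[i, j] == pytest.approx((m - 2) * D[i, j] - S[i] - S[j], rel=1e-12)

    def test_too_small_errors(self):
        with pytest.raises(ValueError):
            nj_q_matrix(np.zeros((2, 2)))


class TestSmoothFloor:
    def test_above_floor_is_identity(self):
        assert float(getval(smooth_branch_floor(0.01))) == pytest.approx(0.01, abs=1e-12)

    def test_below_floor_clamps(self):
        out = float(getval(smooth_branch_floor(-0.5)))
        assert abs(out - BRANCH_LENGTH_FLOOR) < 1e-6


class TestSoftNJDecode:
    def test_four_taxon_additive_recovery(self):
        D = np.array([
            [0, 3, 5, 6],
            [3, 0, 6, 7],
            [5, 6, 0, 7],
            [6, 7, 7, 0],
        ], dtype=float)
        tree = soft_nj_decode(D, 1e-5, labels=["A", "B", "C", "D"])
        tree.validate()
        bl = np.sort(tree.lengths_value())
        assert np.allclose(bl, np.sort([1.0, 2.0, 1.0, 3.0, 4.0]), atol=1e-6)
        truth = PhyloTree(4, ["A", "B", "C", "D"],
                          edges=[(0, 4), (1, 4), (2, 5), (3, 5), (4, 5)],
                          branch_lengths=np.array([1, 2, 3, 4, 1.0]))
        assert rf_oracle(tree, truth) == 0

    def test_three_taxon_three_point_formulas(self):
        D = np.array([[0, 2, 3], [2, 0, 4.2], [3, 4.2, 0]])
        tree = soft_nj_decode(D, 1e-5)
        bl = tree.lengths_value()
        expect = [0.5 * (2 + 3 - 4.2), 0.5 * (2 + 4.2 - 3), 0.5 * (3 + 4.2 - 2)]
        assert np.allclose(np.sort(bl), np.sort(expect), atol=1e-6)

    def test_matches_classical_nj_on_random_matrices(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            tree = simulate_tree(10, seed=rng)
            D = np.asarray(tree_path_distances(tree).values)
            # metric noise keeps it a plausible (non-additive) distance matrix
            noise = rng.uniform(0, 0.02, size=D.shape)
            D = D + noise + noise.T
            np.fill_diagonal(D, 0.0)
            soft = soft_nj_decode(D, 1e-5)
            hard = classical_nj(D)
            assert rf_oracle(soft, hard) == 0
            assert np.allclose(np.sort(soft.lengths_value()),
                               np.sort(hard.lengths_value()), atol=1e-6)

    def test_differentiable_jacobian_vs_finite_differences(self):
        rng = np.random.default_rng(6)
        tree = simulate_tree(5, seed=7)
        v0 = np.asarray(tree_path_distances(tree).values)[np.triu_indices(5, 1)]
        eta = 0.1

        def f(v):
            return soft_nj_decode(_upper_box(v, 5), eta).branch_lengths

        J = np.asarray(getval(jacobian(f)(v0)))
        h = 1e-6
        for k in range(len(v0)):
            vp, vm = v0.copy(), v0.copy()
            vp[k] += h
            vm[k] -= h
            fd = (np.asarray(getval(f(vp))) - np.asarray(getval(f(vm)))) / (2 * h)
            assert np.allclose(J[:, k], fd, rtol=1e-3, atol=1e-7)

    def test_gradients_reach_every_branch(self):
        tree = simulate_tree(6, seed=8)
        v0 = np.asarray(tree_path_distances(tree).values)[np.triu_indices(6, 1)]

        def f(v):
            return soft_nj_decode(_upper_box(v, 6), 1e-5).branch_lengths

        J = np.asarray(getval(jacobian(f)(v0)))
        assert J.shape == (2 * 6 - 3, len(v0))
        # every output branch depends on at least one input distance
        assert np.all(np.abs(J).sum(axis=1) > 1e-12)

    def test_decoded_tree_is_valid(self):
        rng = np.random.default_rng(9)
        for n in (4, 7, 12):
            tree = simulate_tree(n, seed=rng)
            dec = soft_nj_decode(tree_path_distances(tree), 1e-5)
            dec.with_lengths(dec.lengths_value()).validate()

    def test_nonfinite_matrix_errors(self):
        D = np.zeros((4, 4))
        D[0, 1] = D[1, 0] = np.nan
        with pytest.raises(ValueError, match="finite"):
            soft_nj_decode(D, 1e-5)

    def test_labels_preserved(self):
        tree = simulate_tree(5, seed=10, labels=list("ABCDE"))
        dec = soft_nj_decode(tree_path_distances(tree), 1e-5)
        assert dec.taxon_labels == list("ABCDE")


class TestPhyloTree:
    def test_validate_counts(self):
        t = simulate_tree(10, seed=0)
        assert t.n_edges == 17
        assert t.n_nodes - t.n_tips == 8
        t.validate()

    def test_validate_rejects_negative_lengths(self):
        t = simulate_tree(4, seed=0)
        bad = t.with_lengths(np.array([-1.0] + [0.1] * (t.n_edges - 1)))
        with pytest.raises(ValueError, match="non-negative"):
            bad.validate()

    def test_total_length(self):
        t = simulate_tree(5, seed=1)
        assert float(getval(t.total_length())) == pytest.approx(float(t.lengths_value().sum()))
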