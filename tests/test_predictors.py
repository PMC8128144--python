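"""Base predictors: label propagation, graph-regularized NMF, consistency projection."""

import numpy as np
import pytest

from cmaf import (
    DrugDiseaseNetwork,
    LnsParams,
    LpParams,
    NmfParams,
    SimilarityMatrix,
    label_propagation,
    linear_neighborhood_similarity,
    lpria_predict,
    ncpria_predict,
    nmfria_fit,
    nmfria_predict,
)
from cmaf.errors import MatrixValueError, ValidationError
from cmaf.predictors import nmf_objective, _laplacian_parts


def _net(Y):
    Y = np.asarray(Y, dtype=float)
    m, n = Y.shape
    return DrugDiseaseNetwork([f"r{i}" for i in range(m)], [f"d{j}" for j in range(n)], Y)


def _lns(S):
    S = np.asarray(S, dtype=float)
    return SimilarityMatrix([f"e{i}" for i in range(S.shape[0])], S, "linear_neighborhood")


def _random_row_stochastic(rng, p):
    S = rng.uniform(size=(p, p))
    np.fill_diagonal(S, 0.0)
    return S / S.sum(axis=1, keepdims=True)


class TestLabelPropagation:
    def test_worked_two_node_example(self):
        S = np.array([[0.0, 1.0], [1.0, 0.0]])
        y = label_propagation(S, np.array([[1.0], [0.0]]), LpParams(alpha=0.5))
        np.testing.assert_allclose(y.ravel(), [2 / 3, 1 / 3], atol=1e-12)

    def test_zero_labels_stay_zero(self, rng):
        S = _random_row_stochastic(rng, 5)
        assert not label_propagation(S, np.zeros((5, 3))).any()

    def test_all_ones_fixed_point(self, rng):
        S = _random_row_stochastic(rng, 6)
        y = label_propagation(S, np.ones((6, 1)))
        np.testing.assert_allclose(y, 1.0, atol=1e-10)

    def test_closed_form_agrees_with_iteration(self, rng):
        for _ in range(50):
            p, q = int(rng.integers(2, 20)), int(rng.integers(1, 20))
            S = _random_row_stochastic(rng, p)
            Y0 = rng.uniform(size=(p, q))
            alpha = float(rng.uniform(0.1, 0.9))
            closed = label_propagation(S, Y0, LpParams(alpha=alpha, mode="closed_form"))
            iterated = label_propagation(
                S, Y0, LpParams(alpha=alpha, mode="iterative", tol=1e-13)
            )
            np.testing.assert_allclose(closed, iterated, atol=1e-8)

    def test_output_bounded_in_unit_interval(self, rng):
        S = _random_row_stochastic(rng, 8)
        y = label_propagation(S, rng.uniform(size=(8, 4)))
        assert y.min() >= -1e-12 and y.max() <= 1 + 1e-12

    def test_alpha_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            LpParams(alpha=1.0).validate()


class TestLpria:
    def test_zero_network_scores_zero(self, rng):
        net = _net(np.zeros((4, 3)))
        Sr, Sd = _lns(_random_row_stochastic(rng, 4)), _lns(_random_row_stochastic(rng, 3))
        assert not lpria_predict(net, Sr, Sd).R.any()

    def test_transpose_equivariance(self, rng):
        Y = rng.uniform(size=(5, 4))
        Sr, Sd = _random_row_stochastic(rng, 5), _random_row_stochastic(rng, 4)
        fwd = lpria_predict(_net(Y), _lns(Sr), _lns(Sd)).R
        swapped = lpria_predict(_net(Y.T), _lns(Sd), _lns(Sr)).R
        np.testing.assert_allclose(swapped, fwd.T, atol=1e-12)

    def test_matches_naive_two_sided_oracle(self, rng):
        Y = rng.uniform(size=(3, 2))
        Sr, Sd = _random_row_stochastic(rng, 3), _random_row_stochastic(rng, 2)
        alpha = 0.5
        drug_side = (1 - alpha) * np.linalg.inv(np.eye(3) - alpha * Sr) @ Y
        disease_side = ((1 - alpha) * np.linalg.inv(np.eye(2) - alpha * Sd) @ Y.T).T
        expected = (drug_side + disease_side) / 2
        got = lpria_predict(_net(Y), _lns(Sr), _lns(Sd)).R
        np.testing.assert_allclose(got, expected, atol=1e-10)


class TestNmfria:
    def test_exact_factorization_is_fixed_point(self, rng):
        W0 = rng.uniform(0.1, 1.0, size=(5, 2))
        H0 = rng.uniform(0.1, 1.0, size=(4, 2))
        net = _net(W0 @ H0.T)
        params = NmfParams(k=2, lam_l=0, lam_r=0, lam_d=0, max_iter=5, rel_tol=0)
        fit = nmfria_fit(net, np.eye(5), np.eye(4), params, init=(W0, H0))
        np.testing.assert_allclose(fit.W, W0, atol=1e-10)
        np.testing.assert_allclose(fit.H, H0, atol=1e-10)
        assert fit.objective_trace[0] == pytest.approx(0.0, abs=1e-18)

    def test_scalar_hand_iteration(self):
        # Y=[2], W=H=[1], no regularization: W <- 2, then H <- 1, so WH' = Y
        net = _net([[2.0]])
        params = NmfParams(k=1, lam_l=0, lam_r=0, lam_d=0, max_iter=1, rel_tol=0)
        fit = nmfria_fit(
            net, np.ones((1, 1)), np.ones((1, 1)), params,
            init=(np.ones((1, 1)), np.ones((1, 1))),
        )
        assert fit.W[0, 0] == pytest.approx(2.0)
        assert fit.H[0, 0] == pytest.approx(1.0)
        np.testing.assert_allclose(nmfria_predict(fit).R, [[2.0]])

    def test_objective_nonincreasing_on_seeded_instances(self, rng):
        for trial in range(20):
            Y = rng.uniform(size=(8, 6))
            Sr = _random_row_stochastic(rng, 8)
            Sd = _random_row_stochastic(rng, 6)
            params = NmfParams(k=3, max_iter=60, rel_tol=0, seed=trial)
            fit = nmfria_fit(_net(Y), _lns(Sr), _lns(Sd), params)
            trace = np.array(fit.objective_trace)
            assert np.all(np.diff(trace) <= 1e-9 * np.maximum(trace[:-1], 1.0))

    def test_trace_matches_direct_objective_evaluation(self, rng):
        Y = rng.uniform(size=(6, 5))
        Sr = _random_row_stochastic(rng, 6)
        Sd = _random_row_stochastic(rng, 5)
        params = NmfParams(k=2, max_iter=10, rel_tol=0, seed=3)
        fit = nmfria_fit(_net(Y), _lns(Sr), _lns(Sd), params)
        Sr_sym, dr = _laplacian_parts(Sr)
        Sd_sym, dd = _laplacian_parts(Sd)
        final = nmf_objective(Y, fit.W, fit.H, Sr_sym, dr, Sd_sym, dd, params)
        # direct Frobenius/trace evaluation of the penalized objective
        Lr = np.diag(dr) - Sr_sym
        Ld = np.diag(dd) - Sd_sym
        expected = (
            np.linalg.norm(Y - fit.W @ fit.H.T, "fro") ** 2
            + params.lam_l * (np.linalg.norm(fit.W, "fro") ** 2 + np.linalg.norm(fit.H, "fro") ** 2)
            + params.lam_r * np.trace(fit.W.T @ Lr @ fit.W)
            + params.lam_d * np.trace(fit.H.T @ Ld @ fit.H)
        )
        assert final == pytest.approx(expected, rel=1e-10)
        assert fit.objective_trace[-1] == pytest.approx(expected, rel=1e-10)

    def test_zero_factors_predict_zero(self):
        from cmaf.predictors import FactorPair

        fp = FactorPair(np.zeros((2, 1)), np.zeros((3, 1)), [0.0], ["a", "b"], ["x", "y", "z"])
        assert not nmfria_predict(fp).R.any()

    def test_prediction_nonnegative(self, rng):
        Y = rng.uniform(size=(6, 4))
        params = NmfParams(k=2, max_iter=30, seed=0)
        fit = nmfria_fit(_net(Y), _lns(_random_row_stochastic(rng, 6)),
                         _lns(_random_row_stochastic(rng, 4)), params)
        assert nmfria_predict(fit).R.min() >= 0


class TestNcpria:
    def test_perfectly_consistent_singleton(self):
        got = ncpria_predict(_net([[1.0]]), np.ones((1, 1)), np.ones((1, 1)))
        assert got.R[0, 0] == pytest.approx(1.0)

    def test_hand_evaluated_two_by_two(self):
        eps = 1e-30
        Y = np.array([[1.0, eps], [eps, eps]])
        net = DrugDiseaseNetwork(["r0", "r1"], ["d0", "d1"], Y)
        Sr = np.array([[1.0, 0.5], [0.5, 1.0]])
        Sd = np.array([[1.0, 0.2], [0.2, 1.0]])
        got = ncpria_predict(net, Sr, Sd)
        expected = 2.0 / (np.sqrt(1.25) + np.sqrt(1.04))
        assert got.R[0, 0] == pytest.approx(expected, abs=1e-6)

    def test_matches_literal_per_pair_loop(self, rng):
        for _ in range(10):
            m, n = int(rng.integers(2, 7)), int(rng.integers(2, 7))
            Y = (rng.uniform(size=(m, n)) < 0.4) * rng.uniform(size=(m, n))
            Sr = rng.uniform(size=(m, m))
            Sd = rng.uniform(size=(n, n))
            got = ncpria_predict(_net(Y), Sr, Sd).R
            Yp = np.where(Y == 0, 1e-30, Y)
            expected = np.empty((m, n))
            for i in range(m):
                for j in range(n):
                    ncp_r = Sr[i, :] @ Yp[:, j] / np.linalg.norm(Yp[:, j])
                    ncp_d = Yp[i, :] @ Sd[:, j] / np.linalg.norm(Yp[i, :])
                    expected[i, j] = (ncp_r + ncp_d) / (
                        np.linalg.norm(Sr[i, :]) + np.linalg.norm(Sd[:, j])
                    )
            np.testing.assert_allclose(got, expected, atol=1e-12)
            assert got.min() >= 0 and got.max() <= 1

    def test_transpose_equivariance(self, rng):
        Y = (rng.uniform(size=(5, 4)) < 0.5).astype(float)
        Sr = rng.uniform(size=(5, 5))
        Sr = (Sr + Sr.T) / 2
        Sd = rng.uniform(size=(4, 4))
        Sd = (Sd + Sd.T) / 2
        fwd = ncpria_predict(_net(Y), Sr, Sd).R
        swapped = ncpria_predict(_net(Y.T), Sd, Sr).R
        np.testing.assert_allclose(swapped, fwd.T, atol=1e-12)

    def test_zero_similarity_row_and_column_rejected(self):
        with pytest.raises(MatrixValueError):
            ncpria_predict(_net([[1.0]]), np.zeros((1, 1)), np.zeros((1, 1)))
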