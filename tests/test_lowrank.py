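"""Proximal operators and the three decomposition solvers.

The proximal operators are checked against an independent optimality
oracle (random-perturbation minimality of the convex objective), the
solvers against generating ground truth and against each other.
"""

import numpy as np
import pytest
import scipy.linalg
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from ctrestore.lowrank import (
    SolverOptions,
    brp_approx,
    godec,
    ladmap_rpca,
    rpca_alm,
    soft_threshold,
    svd_shrink,
)


def _rank2_corrupted(m=200, n=50, frac=0.02, mag=50.0, seed=0):
    """Rank-2 matrix from Gaussian factors + random-sign sparse corruption."""
    rng = np.random.default_rng(seed)
    L = rng.standard_normal((m, 2)) @ rng.standard_normal((2, n))
    mask = rng.random((m, n)) < frac
    E = np.where(mask, mag * np.sign(rng.standard_normal((m, n))), 0.0)
    return L, E, mask


class TestSoftThreshold:
    @pytest.mark.parametrize("x,tau,expected", [
        (3.0, 1.0, 2.0), (-0.5, 1.0, 0.0), (-3.0, 1.0, -2.0), (0.0, 5.0, 0.0),
    ])
    def test_hand_values(self, x, tau, expected):
        assert soft_threshold(np.array([[x]]), tau)[0, 0] == expected

    def test_tau_zero_is_identity(self, rng):
        X = rng.standard_normal((4, 4))
        np.testing.assert_array_equal(soft_threshold(X, 0.0), X)

    def test_negative_tau_rejected(self):
        with pytest.raises(ValueError):
            soft_threshold(np.zeros((2, 2)), -0.1)

    def test_minimizes_l1_proximal_objective(self, rng):
        """Result beats a dense grid of candidates on tau*||E||_1 + 0.5||E-X||_F^2.

        The objective is separable across entries, so a per-entry 1-D
        brute force over a fine value grid is an exhaustive oracle."""
        X = np.array([[1.3, -0.4], [0.1, -2.2]])
        tau = 0.7
        P = soft_threshold(X, tau)
        grid = np.linspace(-3, 3, 6001)
        for x, p in zip(X.reshape(-1), P.reshape(-1)):
            scal = lambda e: tau * abs(e) + 0.5 * (e - x) ** 2
            best = min(scal(e) for e in grid)
            assert scal(p) <= best + 1e-9
        # and joint local minimality under random perturbations
        obj = lambda E: tau * np.abs(E).sum() + 0.5 * np.sum((E - X) ** 2)
        assert all(obj(P + 0.01 * rng.standard_normal((2, 2))) >= obj(P) - 1e-12
                   for _ in range(100))


class TestSvdShrink:
    def test_diagonal_case(self):
        X = np.diag([3.0, 1.0])
        np.testing.assert_allclose(svd_shrink(X, 2.0), np.diag([1.0, 0.0]),
                                   atol=1e-12)

    def test_tau_zero_reproduces_input(self, rng):
        X = rng.standard_normal((5, 3))
        np.testing.assert_allclose(svd_shrink(X, 0.0), X, atol=1e-12)

    def test_minimizes_nuclear_proximal_objective(self, rng):
        """Optimality oracle: no perturbed candidate does better on
        tau*||A||_* + 0.5||A-X||_F^2 (convex, so local => global)."""
        for seed in range(3):
            r = np.random.default_rng(seed)
            X = r.standard_normal((3, 3))
            tau = 0.6
            P = svd_shrink(X, tau)
            obj = lambda A: (tau * scipy.linalg.svdvals(A).sum()
                             + 0.5 * np.sum((A - X) ** 2))
            fp = obj(P)
            for scale in (0.3, 0.03, 0.003):
                assert all(
                    obj(P + scale * r.standard_normal((3, 3))) >= fp - 1e-12
                    for _ in range(100)
                )


class TestRpcaAlm:
    def test_uncorrupted_rank_one_input(self, rng):
        # bounded-magnitude factors: the incoherent regime where the
        # nuclear+l1 optimum leaves the sparse part exactly empty
        u = rng.uniform(0.5, 1.5, 60) * rng.choice([-1, 1], 60)
        v = rng.uniform(0.5, 1.5, 12) * rng.choice([-1, 1], 12)
        D = np.outer(u, v)
        res = rpca_alm(D)
        assert res.converged
        assert np.linalg.norm(D - res.low_rank) / np.linalg.norm(D) < 1e-6

    def test_recovers_rank2_under_sparse_corruption(self):
        L, E, mask = _rank2_corrupted()
        res = rpca_alm(L + E)
        assert np.linalg.norm(res.low_rank - L) / np.linalg.norm(L) < 1e-5
        recovered_support = np.abs(res.sparse) > 1e-3
        np.testing.assert_array_equal(recovered_support, mask)

    def test_converged_flag_implies_residual_below_tol(self):
        L, E, _ = _rank2_corrupted(seed=3)
        opts = SolverOptions(tol=1e-7)
        res = rpca_alm(L + E, opts)
        assert res.converged and res.residual <= opts.tol

    def test_additivity_within_residual(self):
        L, E, _ = _rank2_corrupted(seed=5)
        D = L + E
        res = rpca_alm(D)
        rel = np.linalg.norm(D - res.reconstruction()) / np.linalg.norm(D)
        assert rel <= res.residual + 1e-12

    def test_nonfinite_input_rejected(self):
        with pytest.raises(ValueError):
            rpca_alm(np.array([[np.inf, 0.0]]))


class TestLadmap:
    def test_agrees_with_alm_on_convex_program(self):
        L, E, _ = _rank2_corrupted()
        D = L + E
        a = rpca_alm(D)
        b = ladmap_rpca(D)
        rel = np.linalg.norm(a.low_rank - b.low_rank) / np.linalg.norm(a.low_rank)
        assert rel < 1e-4

    def test_penalty_sequence_nondecreasing_and_capped(self):
        L, E, _ = _rank2_corrupted(seed=2)
        opts = SolverOptions()
        res = ladmap_rpca(L + E, opts)
        mus = np.asarray(res.mu_history)
        assert np.all(np.diff(mus) >= 0)
        assert mus[-1] <= 1e7 * mus[0] + 1e-9

    def test_zero_input_returns_zeros_immediately(self):
        res = ladmap_rpca(np.zeros((10, 4)))
        assert res.iterations <= 1 and res.converged
        assert not np.any(res.low_rank) and not np.any(res.sparse)


class TestBrpApprox:
    def test_exact_for_rank_r_input(self, rng):
        X = rng.standard_normal((40, 8)) @ rng.standard_normal((8, 20))
        app = brp_approx(X, r=8, q=2, seed=0)
        assert np.linalg.norm(X - app) / np.linalg.norm(X) < 1e-8

    def test_error_within_10x_of_optimal_truncation(self):
        for seed in range(5):
            rng = np.random.default_rng(seed)
            U, _ = np.linalg.qr(rng.standard_normal((100, 40)))
            V, _ = np.linalg.qr(rng.standard_normal((40, 40)))
            sv = 2.0 ** (-np.arange(40) / 3)
            X = U @ np.diag(sv) @ V.T
            r = 5
            optimal = np.sqrt(np.sum(sv[r:] ** 2))  # Eckart-Young
            err = np.linalg.norm(X - brp_approx(X, r, q=2, seed=seed))
            assert err <= 10 * optimal

    def test_same_seed_bitwise_identical(self, rng):
        X = rng.standard_normal((30, 12))
        a = brp_approx(X, 4, q=1, seed=9)
        b = brp_approx(X, 4, q=1, seed=9)
        np.testing.assert_array_equal(a, b)

    def test_rank_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            brp_approx(np.zeros((5, 3)), r=4)


class TestGodec:
    def test_exact_rank_r_with_zero_cardinality(self, rng):
        X = rng.standard_normal((50, 10)) @ rng.standard_normal((10, 8))[:, :4]
        X = X @ rng.standard_normal((4, 8))
        res = godec(X, SolverOptions(r=4, k=0))
        assert np.linalg.norm(X - res.low_rank) / np.linalg.norm(X) < 1e-6
        assert not np.any(res.sparse)
        assert np.linalg.norm(res.noise) / np.linalg.norm(X) < 1e-6

    def test_rank_and_cardinality_constraints(self, rng):
        X = rng.standard_normal((80, 10))
        res = godec(X, SolverOptions(r=3, k=25))
        assert res.rank_used <= 3
        assert res.card_used <= 25

    def test_objective_monotone_nonincreasing(self, rng):
        X = (rng.standard_normal((100, 10)) @ rng.standard_normal((10, 10))
             + rng.normal(0, 0.5, (100, 10)))
        res = godec(X, SolverOptions(r=3, k=40, q=2))
        h = res.objective_history
        assert all(a >= b - 1e-9 * max(a, 1.0) for a, b in zip(h, h[1:]))

    def test_noise_component_tracks_injected_noise(self):
        """||G||_F within 20% of the generating noise norm, 10-seed average,
        on a 4096x10 instance with well-separated magnitudes."""
        ratios = []
        for seed in range(10):
            rng = np.random.default_rng(100 + seed)
            L0 = 20.0 * rng.standard_normal((4096, 3)) @ rng.standard_normal((3, 10))
            mask = rng.random((4096, 10)) < 0.02
            S0 = np.where(mask, 60.0 * np.sign(rng.standard_normal((4096, 10))), 0.0)
            G0 = rng.normal(0.0, 1.0, (4096, 10))
            res = godec(L0 + S0 + G0,
                        SolverOptions(r=3, k=int(mask.sum()), seed=seed))
            ratios.append(np.linalg.norm(res.noise) / np.linalg.norm(G0))
        assert abs(np.mean(ratios) - 1.0) < 0.2

    def test_reconstruction_identity(self, rng):
        X = rng.standard_normal((60, 8))
        res = godec(X, SolverOptions(r=2, k=10))
        np.testing.assert_allclose(res.reconstruction(), X, atol=1e-12)


@settings(deadline=None, derandomize=True, max_examples=20)
@given(arrays(np.float64, (6, 4), elements=st.floats(-100, 100)),
       st.floats(0, 10))
def test_soft_threshold_shrinks_toward_zero(X, tau):
    P = soft_threshold(X, tau)
    assert np.all(np.abs(P) <= np.abs(X) + 1e-12)
    assert np.all(np.sign(P) * np.sign(X) >= 0)
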