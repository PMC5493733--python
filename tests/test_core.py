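"""Penalized objective, LQA solver and the three penalty variants."""

import itertools
import warnings

import numpy as np
import pytest
from scipy.linalg import lstsq

from agbridge.core import (
    FitControls,
    PenaltySpec,
    fit_agb,
    fit_group_bridge,
    fit_group_lasso,
    fit_penalized,
    lqa_weight_matrix,
    ols_init,
    profiled_objective,
)
from agbridge.design import make_design

from conftest import random_design


class TestProfiledObjective:
    def test_zero_penalty_at_ols_equals_rss(self, small_design):
        pen = PenaltySpec.constant(0.0, 0.5, small_design.n_groups)
        beta = ols_init(small_design)
        rss = np.sum((small_design.y_star - small_design.X_star @ beta) ** 2)
        assert profiled_objective(beta, small_design, pen) == pytest.approx(rss)

    def test_zero_beta_gives_null_deviance(self, small_design):
        pen = PenaltySpec.constant(2.0, 0.5, small_design.n_groups)
        expected = float(small_design.y_star @ small_design.y_star)
        got = profiled_objective(np.zeros(small_design.p_total), small_design, pen)
        assert got == pytest.approx(expected)

    def test_matches_naive_two_term_sum(self, rng, small_design):
        pen = PenaltySpec(
            gamma=0.5, lambda_per_group=rng.uniform(0.1, 2.0, small_design.n_groups)
        )
        beta = rng.standard_normal(small_design.p_total)
        resid = small_design.y_star - small_design.X_star @ beta
        naive = resid @ resid + sum(
            pen.lambda_per_group[j] * np.linalg.norm(beta[s]) ** 0.5
            for j, s in enumerate(small_design.slices)
        )
        assert profiled_objective(beta, small_design, pen) == pytest.approx(naive)


class TestOlsInit:
    def test_orthonormal_design_closed_form(self, rng):
        # build X whose residualized columns are orthonormalized
        n = 60
        u = rng.uniform(0, 1, n)
        raw = rng.standard_normal((n, 4))
        d0 = make_design(rng.standard_normal(n), raw, u, [2, 2])
        Q, _ = np.linalg.qr(d0.X_star)
        y = rng.standard_normal(n)
        d = make_design(y, Q, u, [2, 2])
        # columns of Q are already residualized, so X* = Q and beta = Q'y*
        np.testing.assert_allclose(ols_init(d), Q.T @ d.y_star, atol=1e-8)

    def test_recovers_truth_noiseless_linear(self, rng):
        n, P = 80, 5
        X = rng.standard_normal((n, P))
        beta0 = rng.standard_normal(P)
        u = rng.uniform(0, 1, n)
        d = make_design(X @ beta0, X, u, [2, 3])  # f == 0, eps == 0
        np.testing.assert_allclose(ols_init(d), beta0, atol=1e-6)

    def test_matches_lstsq_oracle(self, rng, small_design):
        expected, *_ = lstsq(small_design.X_star, small_design.y_star)
        np.testing.assert_allclose(ols_init(small_design), expected, atol=1e-8)

    def test_singular_design_raises(self, rng):
        n = 12
        X = rng.standard_normal((n, 20))  # P > n
        d = make_design(rng.standard_normal(n), X, rng.uniform(0, 1, n), [10, 10])
        with pytest.raises(np.linalg.LinAlgError, match="ridge"):
            ols_init(d)


class TestLqaWeights:
    def test_closed_form_entries(self, small_design):
        beta = np.zeros(small_design.p_total)
        beta[0:2] = [1.2, 1.6]  # ||beta_1|| = 2
        pen = PenaltySpec(gamma=1.0, lambda_per_group=np.ones(3))
        w = lqa_weight_matrix(beta, pen, small_design, active_groups=np.array([0]))
        np.testing.assert_allclose(w, [0.5, 0.5])  # lambda*gamma*t^(gamma-2)

    def test_ridge_limit_gamma_two(self, small_design):
        beta = np.ones(small_design.p_total)
        pen = PenaltySpec(gamma=2.0, lambda_per_group=np.full(3, 1.7))
        w = lqa_weight_matrix(beta, pen, small_design)
        np.testing.assert_allclose(w, 2 * 1.7)  # norm-free ridge weight

    def test_matches_finite_difference_derivative(self, small_design):
        lam, gamma, t, h = 1.3, 0.5, 0.7, 1e-6
        p = lambda x: lam * x**gamma
        fd = (p(t + h) - p(t - h)) / (2 * h)
        assert fd == pytest.approx(lam * gamma * t ** (gamma - 1), abs=1e-5)
        beta = np.zeros(small_design.p_total)
        beta[0] = t
        pen = PenaltySpec(gamma=gamma, lambda_per_group=np.full(3, lam))
        w = lqa_weight_matrix(beta, pen, small_design, active_groups=np.array([0]))
        np.testing.assert_allclose(w[0], fd / t, rtol=1e-5)

    def test_rejects_active_group_below_threshold(self, small_design):
        beta = np.zeros(small_design.p_total)
        beta[0] = 1e-5
        pen = PenaltySpec(gamma=0.5, lambda_per_group=np.ones(3))
        with pytest.raises(ValueError, match="zero"):
            lqa_weight_matrix(beta, pen, small_design, active_groups=np.array([0]))


class TestFitPenalized:
    def test_zero_penalty_returns_ols(self, small_design):
        pen = PenaltySpec.constant(0.0, 0.5, small_design.n_groups)
        beta0 = ols_init(small_design)
        fit = fit_penalized(small_design, pen, beta0)
        np.testing.assert_allclose(fit.beta, beta0, atol=1e-8)
        assert fit.converged

    def test_huge_penalty_zeroes_everything(self, small_design):
        lam = 1e6 * np.linalg.norm(small_design.moment)
        pen = PenaltySpec.constant(lam, 0.5, small_design.n_groups)
        fit = fit_penalized(small_design, pen, ols_init(small_design))
        assert fit.n_selected == 0
        np.testing.assert_array_equal(fit.beta, 0.0)

    def test_thresholded_groups_are_exact_zeros(self, rng):
        for seed in range(5):
            d, _ = random_design(np.random.default_rng(seed), n=50)
            lam = 0.3 * np.max(np.abs(d.moment))
            fit = fit_group_bridge(d, lam, gamma=0.5)
            dropped = set(range(d.n_groups)) - set(fit.selected_groups.tolist())
            for j in dropped:
                np.testing.assert_array_equal(fit.beta[d.slices[j]], 0.0)

    def test_objective_descent_over_random_instances(self):
        """Q_n along the LQA iterate path never increases (MM property),
        including across the hard-thresholding steps."""
        count = 0
        for seed in range(50):
            rng = np.random.default_rng(seed)
            d, _ = random_design(rng, n=int(rng.integers(30, 60)))
            gamma = (0.5, 1.0)[seed % 2]
            lam = float(rng.uniform(0.05, 0.5)) * np.max(np.abs(d.moment))
            pen = PenaltySpec.constant(lam, gamma, d.n_groups)
            fit = fit_penalized(d, pen, ols_init(d))
            diffs = np.diff(fit.objective_trace)
            assert np.all(diffs <= 1e-10), f"objective rose at seed {seed}"
            count += 1
        assert count == 50

    def test_permutation_equivariance(self, rng):
        d, _ = random_design(rng, n=60, group_sizes=(2, 3, 1))
        lams = np.array([0.4, 0.8, 1.2]) * np.max(np.abs(d.moment)) * 0.2
        pen = PenaltySpec(gamma=0.5, lambda_per_group=lams)
        fit = fit_penalized(d, pen, ols_init(d))
        perm = [2, 0, 1]  # group permutation
        sizes = [d.group_sizes[p] for p in perm]
        cols = np.concatenate([np.arange(d.slices[p].start, d.slices[p].stop) for p in perm])
        d2 = make_design(d.y, d.X[:, cols], d.u, sizes)
        pen2 = PenaltySpec(gamma=0.5, lambda_per_group=lams[perm])
        fit2 = fit_penalized(d2, pen2, ols_init(d2))
        np.testing.assert_allclose(fit2.beta, fit.beta[cols], atol=1e-8)

    def test_matches_exact_group_lasso_bcd(self, rng):
        """LQA at gamma = 1 agrees with an exact block-coordinate-descent
        group lasso solve, across the regularization path."""
        d, _ = random_design(rng, n=80, group_sizes=(3, 3, 3))
        scale = np.max(np.abs(d.moment))
        for lam in scale * np.array([0.05, 0.2, 0.8]):
            fit = fit_group_lasso(d, lam)
            b = _group_lasso_bcd(d, lam)
            np.testing.assert_allclose(fit.beta, b, atol=2e-4)

    def test_group_soft_threshold_fixed_point_single_group(self, rng):
        """Orthonormalized single group: the nonzero group-lasso solution
        satisfies ||b|| = ||X'y|| - lam/2 (scalar fixed point)."""
        n = 50
        u = rng.uniform(0, 1, n)
        raw = rng.standard_normal((n, 2))
        d0 = make_design(rng.standard_normal(n), raw, u, [2])
        Q, _ = np.linalg.qr(d0.X_star)
        y = rng.standard_normal(n)
        d = make_design(y, Q, u, [2])
        z = Q.T @ d.y_star
        lam = 0.6 * np.linalg.norm(z)
        fit = fit_group_lasso(d, lam, FitControls(tol=1e-12))
        expected_norm = np.linalg.norm(z) - lam / 2.0
        assert np.linalg.norm(fit.beta) == pytest.approx(expected_norm, rel=1e-6)


def _group_lasso_bcd(d, lam, sweeps=5000, tol=1e-10):
    """Independent oracle: exact group lasso by block coordinate descent."""
    b = np.zeros(d.p_total)
    G, m = d.gram, d.moment
    for _ in range(sweeps):
        b_prev = b.copy()
        for s in d.slices:
            ridx = np.arange(s.start, s.stop)
            rj = m[ridx] - G[ridx] @ b + G[np.ix_(ridx, ridx)] @ b[ridx]
            if np.linalg.norm(rj) <= lam / 2:
                b[ridx] = 0.0
                continue
            bj = b[ridx] if np.linalg.norm(b[ridx]) > 0 else rj * 1e-3
            Gjj = G[np.ix_(ridx, ridx)]
            for _ in range(200):
                t = np.linalg.norm(bj)
                new = np.linalg.solve(Gjj + lam / (2 * t) * np.eye(len(bj)), rj)
                if np.max(np.abs(new - bj)) < 1e-13:
                    bj = new
                    break
                bj = new
            b[ridx] = bj
        if np.max(np.abs(b - b_prev)) < tol:
            break
    return b


class TestDirectMinimizationOracle:
    def test_small_instance_reaches_global_minimum(self, rng):
        """LQA objective matches pattern-enumeration + smooth multistart
        minimization on a tiny instance (the spec for the larger
        acceptance check lives in test_acceptance)."""
        d, _ = random_design(rng, n=40, group_sizes=(2, 2, 2))
        lam = 0.2 * np.max(np.abs(d.moment))
        pen = PenaltySpec.constant(lam, 0.5, 3)
        fit = fit_penalized(d, pen, ols_init(d))
        q = profiled_objective(fit.beta, d, pen)
        q_direct = direct_minimum(d, pen)
        assert q <= q_direct * (1 + 1e-4)


def direct_minimum(design, penalty, n_starts=4, seed=0):
    """Enumerate group zero-patterns; smooth multistart minimization within
    each pattern.  Independent of the LQA path."""
    from scipy.optimize import minimize

    rng = np.random.default_rng(seed)
    best = profiled_objective(np.zeros(design.p_total), design, penalty)
    for pattern in itertools.product([0, 1], repeat=design.n_groups):
        act = [j for j, a in enumerate(pattern) if a]
        if not act:
            continue
        idx = np.concatenate(
            [np.arange(s.start, s.stop) for s in (design.slices[j] for j in act)]
        )

        def obj(v):
            b = np.zeros(design.p_total)
            b[idx] = v
            return profiled_objective(b, design, penalty)

        starts = [ols_init(design)[idx]]
        starts += [starts[0] * rng.uniform(0.2, 1.5, len(idx)) for _ in range(n_starts - 1)]
        for s0 in starts:
            r = minimize(
                obj, s0, method="Nelder-Mead",
                options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 20000},
            )
            best = min(best, r.fun)
    return best


class TestMethodWrappers:
    def test_agb_lambda_zero_is_ols(self, small_design):
        fit = fit_agb(small_design, 0.0, 0.5)
        np.testing.assert_allclose(fit.beta, ols_init(small_design), atol=1e-8)

    def test_gb_gamma_one_equals_gl(self, small_design):
        lam = 0.3 * np.max(np.abs(small_design.moment))
        gb = fit_group_bridge(small_design, lam, gamma=1.0)
        gl = fit_group_lasso(small_design, lam)
        np.testing.assert_allclose(gb.beta, gl.beta, atol=1e-10)

    def test_gb_lambda_zero_is_ols(self, small_design):
        fit = fit_group_bridge(small_design, 0.0, gamma=0.5)
        np.testing.assert_allclose(fit.beta, ols_init(small_design), atol=1e-8)

    def test_gl_huge_lambda_all_zero(self, small_design):
        lam = 1e6 * np.linalg.norm(small_design.moment)
        fit = fit_group_lasso(small_design, lam)
        assert fit.n_selected == 0

    def test_agb_selection_monotone_in_lambda(self, rng):
        """Doubling lambda along a 10-point ladder never grows the
        selected set on a fixed dataset."""
        d, _ = random_design(np.random.default_rng(3), n=100, group_sizes=(3, 3, 3, 3))
        scale = np.max(np.abs(d.moment))
        lams = scale * 0.01 * 2.0 ** np.arange(10)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            counts = [fit_agb(d, lam, 0.5).n_selected for lam in lams]
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_adaptive_weight_floor_warns(self, rng):
        norms = np.array([1.0, 1e-12, 0.5])
        with pytest.warns(UserWarning, match="capping"):
            pen = PenaltySpec.adaptive(1.0, 0.5, norms)
        assert pen.lambda_per_group[1] == pytest.approx(1.0 / 1e-8)


class TestEmpiricalConsistency:
    """Scaled-down empirical check of estimation/selection consistency;
    the full sweep lives in the acceptance tests."""

    def test_l2_loss_shrinks_with_n(self):
        from agbridge.simulate import SimScenario, evaluate_fit, simulate_dataset

        losses = {}
        for n in (100, 800):
            vals = []
            for r in range(8):
                scen = SimScenario(n=n, p_n=5, sigma=1.0, seed=100 + r)
                y, X, u, sizes, bt = simulate_dataset(scen)
                d = make_design(y, X, u, sizes)
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    fit = fit_agb(d, 0.5 * np.max(np.abs(d.moment)) * 0.05, 0.5)
                vals.append(evaluate_fit(fit, bt, sizes)[0])
            losses[n] = np.median(vals)
        assert losses[800] < losses[100]
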