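"""MAP estimation tests: design construction, neuron/glia fits, QP variant."""

import numpy as np
import pytest
import scipy.optimize
import scipy.special

import gliaglm as gg
from gliaglm.fit import (
    HybridDesign,
    _penalty_block_diag,
    build_design,
    fit_logistic_map,
    kkt_residual,
    solve_bound_qp,
)


def obs_from_arrays(spikes, glia, normalize=False):
    return gg.ObservationSeries(spikes, glia, normalize=normalize)


class TestBuildDesign:
    def test_minimal_three_columns(self):
        obs = obs_from_arrays(np.zeros((20, 1), np.uint8),
                              np.random.default_rng(0).normal(size=(20, 1)),
                              normalize=True)
        w = gg.HistoryWindows(1, 1, 1, 1)
        d = build_design(obs, ("neuron", 0), w, gg.NetworkStructure.full(1, 1))
        assert d.X.shape[1] == 3
        assert d.column_map == [(-1, "bias", 0), (0, "NN", 1), (0, "GN", 1)]

    def test_lag_one_column_is_shifted_train(self):
        spikes = np.tile([0, 1], 10)[:, None].astype(np.uint8)
        obs = obs_from_arrays(spikes, np.zeros((20, 0)))
        w = gg.HistoryWindows(1, 1, 1, 1)
        d = build_design(obs, ("neuron", 0), w, gg.NetworkStructure.full(1, 0))
        np.testing.assert_array_equal(d.X[:, 1], spikes[:-1, 0])

    def test_every_cell_matches_naive_indexing(self):
        rng = np.random.default_rng(77)
        spikes = (rng.random((40, 2)) < 0.3).astype(np.uint8)
        glia = rng.normal(size=(40, 2))
        obs = obs_from_arrays(spikes, glia, normalize=True)
        w = gg.HistoryWindows(3, 2, 2, 3)
        d = build_design(obs, ("neuron", 0), w, gg.NetworkStructure.full(2, 2))
        burn = w.burn_in
        data = {"NN": obs.spikes.astype(float), "GN": obs.glia}
        for col, (sender, block, lag) in enumerate(d.column_map):
            if block == "bias":
                continue
            for row in range(d.n_rows):
                t = burn + row
                assert d.X[row, col] == data[block][t - lag, sender]

    def test_too_short_series_errors(self):
        obs = obs_from_arrays(np.zeros((5, 1), np.uint8), np.zeros((5, 0)))
        w = gg.HistoryWindows(4, 4, 4, 4)
        with pytest.raises(ValueError, match="too short"):
            build_design(obs, ("neuron", 0), w, gg.NetworkStructure.full(1, 0))


class TestFitNeuron:
    def test_intercept_only_recovers_logit_rate(self):
        rng = np.random.default_rng(1)
        spikes = (rng.random((4000, 1)) < 0.12).astype(np.uint8)
        obs = obs_from_arrays(spikes, np.zeros((4000, 0)))
        w = gg.HistoryWindows(2, 2, 2, 2)
        struct = gg.NetworkStructure(np.zeros((1, 1), bool),
                                     np.zeros((1, 0), bool),
                                     np.zeros((0, 1), bool),
                                     np.zeros((0, 0), bool))
        res = gg.fit_neuron(obs, 0, w, struct,
                            gg.PriorConfig(0, 0, 0, 0, 0, 0, 0, 0))
        p_hat = spikes[w.burn_in:, 0].mean()
        assert res.converged
        assert res.params.bias == pytest.approx(scipy.special.logit(p_hat),
                                                abs=1e-6)

    def test_infinite_shrinkage_kills_weights(self):
        rng = np.random.default_rng(2)
        spikes = (rng.random((3000, 2)) < 0.1).astype(np.uint8)
        obs = obs_from_arrays(spikes, np.zeros((3000, 0)))
        w = gg.HistoryWindows(2, 2, 2, 2)
        struct = gg.NetworkStructure.full(2, 0)
        huge = gg.PriorConfig(lam_nn=1e6, lam_gn=1e6, lam_ng=1e6, lam_gg=1e6,
                              eta_nn=0, eta_gn=0, eta_ng=0, eta_gg=0)
        res = gg.fit_neuron(obs, 0, w, struct, huge)
        assert np.max(np.abs(res.params.w_nn)) < 1e-3
        p_hat = spikes[w.burn_in:, 0].mean()
        assert res.params.bias == pytest.approx(scipy.special.logit(p_hat),
                                                abs=1e-2)

    def test_simulation_recovery_within_wald_intervals(self):
        # fit the true structure on long simulated data; most coordinates
        # should land inside +/- 2.58 SE (99%) Wald intervals of the truth
        scen = gg.build_scenario(n_neurons=2, n_glia=1, density_gn=1.0,
                                 density_ng=0.0, T=200_000, seed=5, window=4)
        obs = gg.simulate(scen)
        w = scen.windows
        struct = scen.true_structure
        tiny = gg.PriorConfig(1e-8, 1e-8, 1e-8, 1e-8, 0, 0, 0, 0)
        res = gg.fit_neuron(obs, 0, w, struct, tiny)
        d = build_design(obs, ("neuron", 0), w, struct)
        a = d.X @ np.concatenate([[res.params.bias],
                                  res.params.w_nn[struct.mask_nn[0]].ravel(),
                                  res.params.w_gn[struct.mask_gn[0]].ravel()])
        mu = scipy.special.expit(a)
        H = (d.X * (mu * (1 - mu))[:, None]).T @ d.X
        se = np.sqrt(np.diag(np.linalg.inv(H)))
        truth = np.concatenate([
            [scen.neuron_params[0].bias],
            scen.neuron_params[0].w_nn[struct.mask_nn[0]].ravel(),
            scen.neuron_params[0].w_gn[struct.mask_gn[0]].ravel()])
        est = np.concatenate([[res.params.bias],
                              res.params.w_nn[struct.mask_nn[0]].ravel(),
                              res.params.w_gn[struct.mask_gn[0]].ravel()])
        frac = np.mean(np.abs(est - truth) <= 2.58 * se)
        assert frac >= 0.9

    def test_objective_not_worse_than_zero_start(self, rng):
        spikes = (rng.random((2000, 2)) < 0.15).astype(np.uint8)
        glia = rng.normal(size=(2000, 1))
        obs = obs_from_arrays(spikes, glia, normalize=True)
        w = gg.HistoryWindows(3, 3, 3, 3)
        struct = gg.NetworkStructure.full(2, 1)
        prior = gg.PriorConfig()
        res = gg.fit_neuron(obs, 0, w, struct, prior)
        zero = gg.fit_neuron(obs, 0, w, struct, prior, max_iter=0)
        assert res.objective >= zero.objective


class TestFitGlia:
    def test_intercept_only_mean_and_variance(self, rng):
        glia = rng.normal(2.0, 1.5, size=(500, 1))
        obs = obs_from_arrays(np.zeros((500, 0), np.uint8), glia)
        w = gg.HistoryWindows(2, 2, 2, 2)
        struct = gg.NetworkStructure(np.zeros((0, 0), bool),
                                     np.zeros((0, 1), bool),
                                     np.zeros((1, 0), bool),
                                     np.zeros((1, 1), bool))
        res = gg.fit_glia(obs, 0, w, struct, gg.PriorConfig())
        y = glia[w.burn_in:, 0]
        assert res.params.bias == pytest.approx(y.mean(), abs=1e-10)
        assert res.params.noise_var == pytest.approx(y.var(), rel=1e-10)

    def test_closed_form_matches_numerical_optimizer(self, rng):
        spikes = (rng.random((800, 2)) < 0.2).astype(np.uint8)
        glia = rng.normal(size=(800, 2))
        obs = obs_from_arrays(spikes, glia, normalize=True)
        w = gg.HistoryWindows(2, 2, 2, 2)
        struct = gg.NetworkStructure.full(2, 2)
        prior = gg.PriorConfig()
        res = gg.fit_glia(obs, 0, w, struct, prior)
        d = build_design(obs, ("glia", 0), w, struct)
        P = _penalty_block_diag(d.column_map, prior)

        def cost(theta):
            r = d.y - d.X @ theta
            return 0.5 * r @ r + theta @ P @ theta

        x0 = np.zeros(d.X.shape[1])
        opt = scipy.optimize.minimize(cost, x0, method="L-BFGS-B",
                                      options={"gtol": 1e-12, "ftol": 1e-15,
                                               "maxiter": 2000})
        closed = np.concatenate([[res.params.bias],
                                 res.params.w_ng.ravel(),
                                 res.params.w_gg.ravel()])
        assert np.max(np.abs(closed - opt.x)) < 1e-6

    def test_ar1_coefficient_recovery(self):
        rng = np.random.default_rng(9)
        T = 100_000
        g = np.zeros(T)
        for t in range(1, T):
            g[t] = 0.9 * g[t - 1] + rng.normal()
        obs = obs_from_arrays(np.zeros((T, 0), np.uint8), g[:, None],
                              normalize=False)
        w = gg.HistoryWindows(1, 1, 1, 1)
        struct = gg.NetworkStructure(np.zeros((0, 0), bool),
                                     np.zeros((0, 1), bool),
                                     np.zeros((1, 0), bool),
                                     np.ones((1, 1), bool))
        prior = gg.PriorConfig(1e-6, 1e-6, 1e-6, 1e-6, 0, 0, 0, 0)
        res = gg.fit_glia(obs, 0, w, struct, prior)
        assert res.params.w_gg[0, 0] == pytest.approx(0.9, abs=0.02)

    def test_row_permutation_invariance(self, rng):
        # batch least squares only sees X'X and X'y, so shuffling training
        # rows must leave the estimate unchanged
        spikes = (rng.random((400, 1)) < 0.2).astype(np.uint8)
        glia = rng.normal(size=(400, 1))
        obs = obs_from_arrays(spikes, glia, normalize=True)
        w = gg.HistoryWindows(2, 2, 2, 2)
        struct = gg.NetworkStructure.full(1, 1)
        rows = np.arange(398)
        perm = rng.permutation(rows)
        a = gg.fit_glia(obs, 0, w, struct, gg.PriorConfig(), rows=rows)
        b = gg.fit_glia(obs, 0, w, struct, gg.PriorConfig(), rows=perm)
        np.testing.assert_allclose(a.params.w_gg, b.params.w_gg, atol=1e-10)
        np.testing.assert_allclose(a.params.w_ng, b.params.w_ng, atol=1e-10)


class TestFitGliaPositive:
    def _setup(self, ng_sign, seed=13):
        scen = gg.build_scenario(n_neurons=2, n_glia=1, density_gn=0.0,
                                 density_ng=1.0, T=30_000, seed=seed,
                                 window=4, ng_sign=ng_sign, ng_peak=1.0)
        obs = gg.simulate(scen)
        return obs, scen.windows, scen.true_structure

    def test_inactive_constraints_match_unconstrained(self):
        obs, w, struct = self._setup(ng_sign=+1.0)
        prior = gg.PriorConfig()
        unc = gg.fit_glia(obs, 0, w, struct, prior)
        if np.min(unc.params.w_ng[struct.mask_ng[0]]) >= 0:
            pos = gg.fit_glia_positive(obs, 0, w, struct, prior)
            np.testing.assert_allclose(pos.params.w_ng, unc.params.w_ng,
                                       atol=1e-6)
            np.testing.assert_allclose(pos.params.w_gg, unc.params.w_gg,
                                       atol=1e-6)

    def test_negative_truth_clamped_to_boundary(self):
        obs, w, struct = self._setup(ng_sign=-1.0)
        res = gg.fit_glia_positive(obs, 0, w, struct, gg.PriorConfig())
        w_ng = res.params.w_ng[struct.mask_ng[0]]
        assert np.all(w_ng >= 0.0)
        assert np.all(w_ng <= 1e-8)
        assert res.final_grad_norm < 1e-6

    def test_constrained_objective_beats_zero_projection(self):
        obs, w, struct = self._setup(ng_sign=-1.0, seed=14)
        prior = gg.PriorConfig()
        pos = gg.fit_glia_positive(obs, 0, w, struct, prior)
        unc = gg.fit_glia(obs, 0, w, struct, prior)
        # projecting the unconstrained fit's w_ng to zero is feasible, so
        # the QP optimum must score at least as well
        d = build_design(obs, ("glia", 0), w, struct)
        P = _penalty_block_diag(d.column_map, prior)
        proj = np.concatenate([[unc.params.bias],
                               np.zeros_like(unc.params.w_ng[struct.mask_ng[0]]).ravel(),
                               unc.params.w_gg[struct.mask_gg[0]].ravel()])
        r = d.y - d.X @ proj
        proj_obj = -(0.5 * r @ r + proj @ P @ proj)
        assert pos.objective >= proj_obj - 1e-8


class TestOptimizerMachinery:
    def test_bound_qp_solves_known_nnls(self):
        # min 0.5 x'Ax - b'x with identity A is projection of b onto the
        # feasible set
        A = np.eye(3)
        b = np.array([1.0, -2.0, 3.0])
        x = solve_bound_qp(A, b, np.array([True, True, False]))
        np.testing.assert_allclose(x, [1.0, 0.0, 3.0], atol=1e-12)
        assert kkt_residual(A, b, np.array([True, True, False]), x) < 1e-10

    def test_dual_backend_agreement(self, rng):
        # Newton and L-BFGS optimize the same concave posterior and must
        # land on the same unique optimum
        for _ in range(5):
            n, p = 600, 6
            X = rng.normal(size=(n, p))
            beta_true = rng.normal(size=p) * 0.5
            y = (rng.random(n) < scipy.special.expit(X @ beta_true)).astype(float)
            P = 0.5 * np.eye(p)
            b1, c1, *_ = fit_logistic_map(X, y, P, method="newton")
            b2, c2, *_ = fit_logistic_map(X, y, P, method="lbfgs")
            assert c1 and c2
            assert np.max(np.abs(b1 - b2)) < 1e-5

    def test_hybrid_design_equals_dense(self, rng):
        dense = rng.normal(size=(50, 3))
        sparse_part = (rng.random((50, 4)) < 0.1).astype(float)
        X = np.hstack([dense, sparse_part])
        import scipy.sparse
        hyb = HybridDesign(dense, scipy.sparse.csr_matrix(sparse_part))
        beta = rng.normal(size=7)
        v = rng.normal(size=50)
        w = rng.random(50)
        np.testing.assert_allclose(hyb.matvec(beta), X @ beta, atol=1e-12)
        np.testing.assert_allclose(hyb.rmatvec(v), X.T @ v, atol=1e-12)
        np.testing.assert_allclose(hyb.hessian_weighted(w),
                                   (X * w[:, None]).T @ X, atol=1e-12)
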