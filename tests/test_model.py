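"""Unit tests for the hybrid generative model: conditionals, prior, posterior."""

import numpy as np
import pytest

import gliaglm as gg
from gliaglm.model import glia_loglik, neuron_loglik


def tiny_obs(T=40, N=2, G=1, seed=0):
    rng = np.random.default_rng(seed)
    spikes = (rng.random((T, N)) < 0.2).astype(np.uint8)
    glia = rng.normal(size=(T, G))
    return gg.ObservationSeries(spikes, glia)


def zero_neuron_params(N, G, w):
    return gg.NeuronParams(0.0, np.zeros((N, w.t_nn)), np.zeros((G, w.t_gn)))


def zero_glia_params(N, G, w, noise_var=1.0):
    return gg.GliaParams(0.0, noise_var, np.zeros((N, w.t_ng)),
                         np.zeros((G, w.t_gg)))


class TestObservationSeries:
    def test_rejects_non_binary_spikes(self):
        with pytest.raises(ValueError, match="non-binary"):
            gg.ObservationSeries(np.full((10, 1), 2), np.zeros((10, 0)))

    def test_glia_normalized_on_construction(self):
        obs = tiny_obs(T=200, G=2)
        assert np.all(np.abs(obs.glia.mean(axis=0)) < 1e-10)
        assert np.all(np.abs(obs.glia.var(axis=0) - 1) < 1e-8)

    def test_mismatched_time_axes_rejected(self):
        with pytest.raises(ValueError, match="time axis"):
            gg.ObservationSeries(np.zeros((10, 1)), np.random.normal(size=(9, 1)))


class TestNeuronSpikeProbability:
    def setup_method(self):
        self.obs = tiny_obs()
        self.w = gg.HistoryWindows(2, 2, 2, 2)
        self.struct = gg.NetworkStructure.full(2, 1)

    def test_zero_params_give_half(self):
        p = gg.neuron_spike_probability(self.obs, 10, 0,
                                        zero_neuron_params(2, 1, self.w),
                                        self.w, self.struct)
        assert p == pytest.approx(0.5)

    def test_bias_only_closed_form(self):
        params = zero_neuron_params(2, 1, self.w)
        params.bias = -10.0
        p = gg.neuron_spike_probability(self.obs, 10, 0, params, self.w,
                                        self.struct)
        assert p == pytest.approx(4.5398e-5, rel=1e-4)

    def test_single_sender_spike_log3_weight(self):
        # a lone spike at lag 1 with weight ln 3 gives logistic(ln 3) = 3/4
        spikes = np.zeros((20, 2), np.uint8)
        spikes[9, 1] = 1
        obs = gg.ObservationSeries(spikes, np.random.default_rng(0).normal(size=(20, 1)))
        params = zero_neuron_params(2, 1, self.w)
        params.w_nn[1, 0] = np.log(3.0)
        p = gg.neuron_spike_probability(obs, 10, 0, params, self.w, self.struct)
        assert p == pytest.approx(0.75)

    def test_burn_in_bin_rejected(self):
        with pytest.raises(ValueError, match="burn-in"):
            gg.neuron_spike_probability(self.obs, 1, 0,
                                        zero_neuron_params(2, 1, self.w),
                                        self.w, self.struct)

    def test_monotone_in_bias_and_bounded(self):
        probs = []
        for bias in (-3.0, -1.0, 0.0, 2.0, 5.0):
            params = zero_neuron_params(2, 1, self.w)
            params.bias = bias
            p = gg.neuron_spike_probability(self.obs, 10, 0, params, self.w,
                                            self.struct)
            assert 0.0 < p < 1.0
            probs.append(p)
        assert np.all(np.diff(probs) > 0)


class TestGliaConditionalMean:
    def test_bias_only(self):
        obs = tiny_obs()
        w = gg.HistoryWindows(2, 2, 2, 2)
        params = zero_glia_params(2, 1, w)
        params.bias = 3.5
        m = gg.glia_conditional_mean(obs, 10, 0, params, w,
                                     gg.NetworkStructure.full(2, 1))
        assert m == pytest.approx(3.5)

    def test_self_ar1(self):
        obs = tiny_obs()
        w = gg.HistoryWindows(2, 2, 2, 2)
        params = zero_glia_params(2, 1, w)
        params.w_gg[0, 0] = 0.7
        m = gg.glia_conditional_mean(obs, 10, 0, params, w,
                                     gg.NetworkStructure.full(2, 1))
        assert m == pytest.approx(0.7 * obs.glia[9, 0])

    def test_matches_naive_double_loop(self):
        rng = np.random.default_rng(42)
        obs = tiny_obs(T=60, N=3, G=2, seed=7)
        w = gg.HistoryWindows(3, 4, 4, 3)
        struct = gg.NetworkStructure.full(3, 2)
        params = gg.GliaParams(rng.normal(), 1.0,
                               rng.normal(size=(3, w.t_ng)),
                               rng.normal(size=(2, w.t_gg)))
        t, j = 20, 1
        expected = params.bias
        for i in range(3):
            for tau in range(1, w.t_ng + 1):
                expected += params.w_ng[i, tau - 1] * obs.spikes[t - tau, i]
        for jp in range(2):
            for tau in range(1, w.t_gg + 1):
                expected += params.w_gg[jp, tau - 1] * obs.glia[t - tau, jp]
        m = gg.glia_conditional_mean(obs, t, j, params, w, struct)
        assert m == pytest.approx(expected, abs=1e-12)


class TestLogLikelihood:
    def test_zero_params_bernoulli_half(self):
        obs = tiny_obs(T=50, N=1, G=0)
        w = gg.HistoryWindows(3, 3, 3, 3)
        struct = gg.NetworkStructure.full(1, 0)
        ll = gg.log_likelihood(obs, [zero_neuron_params(1, 0, w)], [], w, struct)
        assert ll == pytest.approx((50 - 3) * np.log(0.5))

    def test_gaussian_residual_identity(self):
        obs = tiny_obs(T=50, N=0, G=1, seed=5)
        w = gg.HistoryWindows(2, 2, 2, 2)
        struct = gg.NetworkStructure.full(0, 1)
        ll = gg.log_likelihood(obs, [], [zero_glia_params(0, 1, w)], w, struct)
        r = obs.glia[2:, 0]
        assert ll == pytest.approx(np.sum(-0.5 * np.log(2 * np.pi) - r**2 / 2))

    def test_per_cell_sums_to_total(self):
        rng = np.random.default_rng(3)
        obs = tiny_obs(T=80, N=2, G=2, seed=9)
        w = gg.HistoryWindows(2, 2, 2, 2)
        struct = gg.NetworkStructure.full(2, 2)
        nps = [gg.NeuronParams(rng.normal(), rng.normal(size=(2, 2)) * 0.3,
                               rng.normal(size=(2, 2)) * 0.3) for _ in range(2)]
        gps = [gg.GliaParams(rng.normal(), 0.8, rng.normal(size=(2, 2)) * 0.3,
                             rng.normal(size=(2, 2)) * 0.3) for _ in range(2)]
        total = gg.log_likelihood(obs, nps, gps, w, struct)
        parts = sum(neuron_loglik(obs, i, nps[i], w, struct) for i in range(2))
        parts += sum(glia_loglik(obs, j, gps[j], w, struct) for j in range(2))
        assert total == pytest.approx(parts, abs=1e-10)


class TestLogPrior:
    def test_zero_weights_zero_prior(self):
        w = gg.HistoryWindows(3, 3, 3, 3)
        lp = gg.log_prior([zero_neuron_params(1, 1, w)],
                          [zero_glia_params(1, 1, w)], gg.PriorConfig())
        assert lp == 0.0

    def test_hand_evaluated_quadratics(self):
        # kernel (1,1,1): lam part 3, smoothness 0
        w = gg.HistoryWindows(3, 1, 1, 1)
        p = gg.NeuronParams(0.0, np.array([[1.0, 1.0, 1.0]]), np.zeros((0, 1)))
        prior = gg.PriorConfig(lam_nn=1.0, eta_nn=1.0)
        assert gg.log_prior([p], [], prior) == pytest.approx(-3.0)
        # kernel (1,-1): lam=0, eta=1 -> -(−1−1)^2 = -4
        w2 = gg.HistoryWindows(2, 1, 1, 1)
        p2 = gg.NeuronParams(0.0, np.array([[1.0, -1.0]]), np.zeros((0, 1)))
        prior2 = gg.PriorConfig(lam_nn=0.0, eta_nn=1.0)
        assert gg.log_prior([p2], [], prior2) == pytest.approx(-4.0)

    def test_nonpositive_with_equality_iff_zero(self, rng):
        w = gg.HistoryWindows(4, 4, 4, 4)
        for _ in range(10):
            p = gg.NeuronParams(rng.normal(), rng.normal(size=(2, 4)),
                                rng.normal(size=(1, 4)))
            lp = gg.log_prior([p], [], gg.PriorConfig())
            assert lp < 0.0


class TestLogPosterior:
    def test_flat_prior_equals_likelihood(self):
        obs = tiny_obs(T=60, N=1, G=1)
        w = gg.HistoryWindows(2, 2, 2, 2)
        struct = gg.NetworkStructure.full(1, 1)
        nps = [zero_neuron_params(1, 1, w)]
        gps = [zero_glia_params(1, 1, w)]
        flat = gg.PriorConfig(0, 0, 0, 0, 0, 0, 0, 0)
        assert gg.log_posterior(obs, nps, gps, w, struct, flat) == \
            gg.log_likelihood(obs, nps, gps, w, struct)

    def test_matches_naive_recomputation(self):
        rng = np.random.default_rng(21)
        obs = tiny_obs(T=60, N=2, G=1, seed=2)
        w = gg.HistoryWindows(2, 2, 2, 2)
        struct = gg.NetworkStructure.full(2, 1)
        nps = [gg.NeuronParams(rng.normal(), rng.normal(size=(2, 2)) * 0.2,
                               rng.normal(size=(1, 2)) * 0.2) for _ in range(2)]
        gps = [gg.GliaParams(rng.normal(), 1.2, rng.normal(size=(2, 2)) * 0.2,
                             rng.normal(size=(1, 2)) * 0.2)]
        prior = gg.PriorConfig()
        # naive recomputation from the per-time-step conditionals
        burn = w.burn_in
        naive = 0.0
        for t in range(burn, obs.T):
            for i in range(2):
                p = gg.neuron_spike_probability(obs, t, i, nps[i], w, struct)
                naive += np.log(p) if obs.spikes[t, i] else np.log1p(-p)
            for j in range(1):
                mu = gg.glia_conditional_mean(obs, t, j, gps[j], w, struct)
                naive += (-0.5 * np.log(2 * np.pi * gps[j].noise_var)
                          - (obs.glia[t, j] - mu) ** 2 / (2 * gps[j].noise_var))
        naive += gg.log_prior(nps, gps, prior)
        total = gg.log_posterior(obs, nps, gps, w, struct, prior)
        assert total == pytest.approx(naive, abs=1e-10)

    def test_masked_weights_never_influence_output(self):
        rng = np.random.default_rng(8)
        obs = tiny_obs(T=60, N=2, G=1, seed=4)
        w = gg.HistoryWindows(2, 2, 2, 2)
        masked = gg.NetworkStructure.full(2, 1)
        masked.mask_gn[:, 0] = False  # forbid the glia sender
        params = gg.NeuronParams(0.3, rng.normal(size=(2, 2)),
                                 rng.normal(size=(1, 2)))
        base = neuron_loglik(obs, 0, params, w, masked)
        params.w_gn[0] = 99.0  # forbidden weights, must be inert
        assert neuron_loglik(obs, 0, params, w, masked) == base

    def test_per_neuron_concavity_spot_check(self, rng):
        # second difference of the per-neuron log posterior along random
        # directions is never positive (strict concavity up to fp noise)
        obs = tiny_obs(T=80, N=1, G=1, seed=6)
        w = gg.HistoryWindows(2, 2, 2, 2)
        struct = gg.NetworkStructure.full(1, 1)
        prior = gg.PriorConfig()

        def f(vec):
            p = gg.NeuronParams(vec[0], vec[1:3][None, :], vec[3:5][None, :])
            return (neuron_loglik(obs, 0, p, w, struct)
                    + gg.log_prior([p], [], prior))

        for _ in range(5):
            x = rng.normal(size=5)
            d = rng.normal(size=5)
            h = 1e-3
            second = f(x + h * d) - 2 * f(x) + f(x - h * d)
            assert second <= 1e-8
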