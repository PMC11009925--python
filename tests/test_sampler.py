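import dataclasses

import numpy as np
import pytest

import surveylca as slc
from surveylca.sampler import WeightedCounts, _one_hot


def dirichlet_mean(a):
    a = np.asarray(a, dtype=float)
    return a / a.sum()


class TestWeightedCounts:
    def test_unit_weights_reduce_to_plain_counts(self, tiny_data):
        w = slc.SurveyWeights.unit(6)
        z = np.array([1, 1, 1, 2, 2, 2])
        counts = slc.weighted_counts(tiny_data, z, w, K=2)
        assert counts.class_counts.tolist() == [3.0, 3.0]
        # item 1, class 1 saw levels (1, 1, 2)
        assert counts.item_counts[0, :, 0].tolist() == [2.0, 1.0, 0.0]

    def test_normalised_class_counts_sum_to_n(self, tiny_data):
        w = slc.SurveyWeights(np.array([5.0, 1.0, 2.0, 2.0, 3.0, 8.0]))
        z = np.array([1, 2, 1, 2, 1, 2])
        counts = slc.weighted_counts(tiny_data, z, w, K=3)
        assert counts.class_counts.sum() == pytest.approx(6.0)
        # per (j, k) the item counts marginalise to the class count
        assert np.allclose(
            counts.item_counts.sum(axis=1),
            np.broadcast_to(counts.class_counts, (2, 3)),
        )

    def test_derived_weighted_count_arithmetic(self, tiny_data):
        # w=(2,2,1,1), kappa=1.5, z=(1,1,2,2): weighted counts (4/1.5, 2/1.5)
        data = slc.CategoricalMatrix(tiny_data.y[:4], tiny_data.level_counts)
        w = slc.SurveyWeights(np.array([2.0, 2.0, 1.0, 1.0]))
        counts = slc.weighted_counts(data, np.array([1, 1, 2, 2]), w, K=2)
        assert counts.class_counts == pytest.approx([4 / 1.5, 2 / 1.5])


class TestUpdatePi:
    def test_no_subjects_draws_from_the_prior(self):
        rng = np.random.default_rng(0)
        counts = WeightedCounts(np.zeros(3), np.zeros((1, 2, 3)))
        draws = np.array([slc.update_pi(counts, 0.7, rng) for _ in range(4000)])
        assert np.allclose(draws.sum(axis=1), 1.0)
        assert draws.mean(axis=0) == pytest.approx([1 / 3] * 3, abs=0.02)

    def test_weighted_conditional_posterior_mean(self, tiny_data):
        # Dir(0.5 + 4/1.5, 0.5 + 2/1.5) = Dir(19/6, 11/6): mean pi_1 = 19/30
        data = slc.CategoricalMatrix(tiny_data.y[:4], tiny_data.level_counts)
        w = slc.SurveyWeights(np.array([2.0, 2.0, 1.0, 1.0]))
        counts = slc.weighted_counts(data, np.array([1, 1, 2, 2]), w, K=2)
        rng = np.random.default_rng(1)
        draws = np.array(
            [slc.update_pi(counts, 0.5, rng) for _ in range(20000)]
        )
        se = draws[:, 0].std() / np.sqrt(draws.shape[0])
        assert abs(draws[:, 0].mean() - 19 / 30) < 4 * se + 1e-4


class TestVectorAlpha:
    def test_asymmetric_prior_accepted_and_used(self, tiny_data):
        # an informative prior may favour the first classes
        cfg = slc.SamplerConfig(
            K=4, alpha=np.array([2.0, 1.0, 1.0, 0.01]),
            n_iter=40, burn_in=20, thin=2, seed=0,
        )
        draws = slc.run_gibbs(tiny_data, None, cfg)
        assert draws.pi_draws.shape == (10, 4)
        rng = np.random.default_rng(0)
        counts = WeightedCounts(np.zeros(3), np.zeros((1, 2, 3)))
        sample = np.array(
            [slc.update_pi(counts, np.array([8.0, 1.0, 1.0]), rng)
             for _ in range(4000)]
        )
        assert sample.mean(axis=0) == pytest.approx([0.8, 0.1, 0.1], abs=0.02)

    def test_wrong_length_alpha_rejected(self):
        with pytest.raises(ValueError, match="length-K"):
            slc.SamplerConfig(K=4, alpha=np.ones(3))


class TestUpdateTheta:
    def test_empty_class_draws_from_prior(self, tiny_data):
        w = slc.SurveyWeights.unit(6)
        counts = slc.weighted_counts(
            tiny_data, np.ones(6, dtype=int), w, K=2
        )
        rng = np.random.default_rng(2)
        draws = np.array(
            [
                slc.update_theta(counts, tiny_data.level_mask(), 1.0, rng)[
                    :, :, 1
                ]
                for _ in range(4000)
            ]
        )
        # class 2 is empty: prior Dir(1,1,1) mean is uniform over d_j=3
        assert draws.mean(axis=0) == pytest.approx(
            np.full((2, 3), 1 / 3), abs=0.02
        )

    def test_single_subject_conditional_mean(self):
        # one subject, w=1, y_11 = 3, d=4, gamma=1 -> Dir(1,1,2,1)
        data = slc.CategoricalMatrix(np.array([[3]]), np.array([4]))
        w = slc.SurveyWeights.unit(1)
        counts = slc.weighted_counts(data, np.array([1]), w, K=1)
        rng = np.random.default_rng(3)
        draws = np.array(
            [
                slc.update_theta(counts, data.level_mask(), 1.0, rng)[0, :, 0]
                for _ in range(20000)
            ]
        )
        se = draws.std(axis=0).max() / np.sqrt(draws.shape[0])
        assert draws.mean(axis=0) == pytest.approx(
            [0.2, 0.2, 0.4, 0.2], abs=4 * se + 1e-3
        )

    def test_doubling_all_weights_changes_nothing(self, tiny_data):
        z = np.array([1, 2, 1, 2, 1, 2])
        w1 = slc.SurveyWeights(np.array([5.0, 1.0, 2.0, 2.0, 3.0, 8.0]))
        w2 = slc.SurveyWeights(2 * w1.w)
        c1 = slc.weighted_counts(tiny_data, z, w1, K=2)
        c2 = slc.weighted_counts(tiny_data, z, w2, K=2)
        assert np.allclose(c1.item_counts, c2.item_counts)
        t1 = slc.update_theta(
            c1, tiny_data.level_mask(), 1.0, np.random.default_rng(7)
        )
        t2 = slc.update_theta(
            c2, tiny_data.level_mask(), 1.0, np.random.default_rng(7)
        )
        assert np.array_equal(t1, t2)


class TestUpdateZ:
    def test_single_class_is_deterministic(self, tiny_data):
        w = slc.SurveyWeights.unit(6)
        pi = np.array([1.0])
        theta = np.full((2, 3, 1), 1 / 3)
        z = slc.update_z(tiny_data, pi, theta, w, True, np.random.default_rng(0))
        assert np.all(z == 1)

    def test_tempered_exponent_sharpens_the_conditional(self):
        # identical theta across classes, pi=(0.8,0.2), subject with
        # normalised weight 2: P(z=1) = 0.8^2/(0.8^2+0.2^2) = 16/17
        data = slc.CategoricalMatrix(
            np.array([[1], [1], [1]]), np.array([2])
        )
        w = slc.SurveyWeights(np.array([4.0, 1.0, 1.0]))  # normalised (2, .5, .5)
        pi = np.array([0.8, 0.2])
        theta = np.full((1, 2, 2), 0.5)
        rng = np.random.default_rng(5)
        hits = np.array(
            [
                slc.update_z(data, pi, theta, w, True, rng)[0] == 1
                for _ in range(20000)
            ]
        )
        p = 0.8**2 / (0.8**2 + 0.2**2)
        se = np.sqrt(p * (1 - p) / hits.size)
        assert abs(hits.mean() - p) < 4 * se

    def test_unit_weights_make_tempering_a_no_op(self, tiny_data):
        w = slc.SurveyWeights.unit(6)
        pi = np.array([0.3, 0.7])
        rng1 = np.random.default_rng(9)
        rng2 = np.random.default_rng(9)
        theta = np.random.default_rng(1).dirichlet(
            np.ones(3), size=(2, 2)
        ).transpose(0, 2, 1)
        z1 = slc.update_z(tiny_data, pi, theta, w, True, rng1)
        z2 = slc.update_z(tiny_data, pi, theta, w, False, rng2)
        assert np.array_equal(z1, z2)


class TestPermuteLabels:
    @pytest.fixture()
    def state(self, tiny_data):
        rng = np.random.default_rng(3)
        theta = rng.dirichlet(np.ones(3), size=(2, 4)).transpose(0, 2, 1)
        return slc.SamplerState(
            z=np.array([1, 2, 3, 4, 1, 2]),
            pi=np.array([0.1, 0.2, 0.3, 0.4]),
            theta=theta,
        )

    def test_identity_permutation_is_identity(self, state):
        out = slc.permute_labels(state, sigma=np.arange(4))
        assert np.array_equal(out.z, state.z)
        assert np.array_equal(out.pi, state.pi)

    def test_applying_sigma_then_inverse_restores_state(self, state):
        sigma = np.array([2, 0, 3, 1])
        inverse = np.argsort(sigma)
        back = slc.permute_labels(
            slc.permute_labels(state, sigma=sigma), sigma=inverse
        )
        assert np.array_equal(back.z, state.z)
        assert np.array_equal(back.pi, state.pi)
        assert np.array_equal(back.theta, state.theta)

    def test_likelihood_invariant_under_relabelling(self, state, tiny_data):
        w = slc.SurveyWeights(np.array([3.0, 1.0, 1.0, 2.0, 4.0, 1.0]))
        before = slc.log_pseudo_likelihood(tiny_data, w, state.pi, state.theta)
        out = slc.permute_labels(state, np.random.default_rng(0))
        after = slc.log_pseudo_likelihood(tiny_data, w, out.pi, out.theta)
        assert after == pytest.approx(before, rel=1e-12)

    def test_permuted_parameters_keep_class_association(self, state):
        sigma = np.array([1, 2, 3, 0])
        out = slc.permute_labels(state, sigma=sigma)
        # old class k's parameters now live at label sigma[k]
        for k in range(4):
            assert out.pi[sigma[k]] == state.pi[k]
            assert np.array_equal(out.theta[:, :, sigma[k]], state.theta[:, :, k])
        assert np.array_equal(out.z, sigma[state.z - 1] + 1)


class TestLogPseudoLikelihood:
    def test_uniform_single_class_single_item(self):
        data = slc.CategoricalMatrix(np.array([[2]]), np.array([4]))
        w = slc.SurveyWeights.unit(1)
        val = slc.log_pseudo_likelihood(
            data, w, np.array([1.0]), np.full((1, 4, 1), 0.25)
        )
        assert val == pytest.approx(np.log(0.25))

    def test_unit_weights_equal_plain_mixture_loglik(self, tiny_data):
        rng = np.random.default_rng(4)
        pi = rng.dirichlet(np.ones(3))
        theta = rng.dirichlet(np.ones(3), size=(2, 3)).transpose(0, 2, 1)
        w = slc.SurveyWeights.unit(6)
        # independent brute-force evaluation of the mixture likelihood
        total = 0.0
        for i in range(6):
            mix = 0.0
            for k in range(3):
                term = pi[k]
                for j in range(2):
                    term *= theta[j, tiny_data.y[i, j] - 1, k]
                mix += term
            total += np.log(mix)
        assert slc.log_pseudo_likelihood(tiny_data, w, pi, theta) == (
            pytest.approx(total, rel=1e-10)
        )

    def test_em_steps_never_decrease_the_loglik(self):
        # EM on a tiny unweighted LCM is an independent oracle for the
        # likelihood code: its loglik sequence must be monotone
        rng = np.random.default_rng(8)
        y = rng.integers(1, 4, size=(10, 2))
        data = slc.CategoricalMatrix(y, np.array([3, 3]))
        w = slc.SurveyWeights.unit(10)
        K, p, d = 2, 2, 3
        pi = np.array([0.5, 0.5])
        theta = rng.dirichlet(np.ones(d), size=(p, K)).transpose(0, 2, 1)
        last = -np.inf
        for _ in range(25):
            ll = slc.log_pseudo_likelihood(data, w, pi, theta)
            assert ll >= last - 1e-10
            last = ll
            # E step: responsibilities
            lik = np.ones((10, K))
            for k in range(K):
                for j in range(p):
                    lik[:, k] *= theta[j, y[:, j] - 1, k]
                lik[:, k] *= pi[k]
            resp = lik / lik.sum(axis=1, keepdims=True)
            # M step
            pi = resp.mean(axis=0)
            for j in range(p):
                for k in range(K):
                    for c in range(d):
                        theta[j, c, k] = resp[y[:, j] == c + 1, k].sum()
                    theta[j, :, k] /= theta[j, :, k].sum()


class TestRunGibbs:
    def test_weight_scale_invariance_is_exact(self, tiny_data, small_config):
        w1 = slc.SurveyWeights(np.array([5.0, 1.0, 2.0, 2.0, 3.0, 8.0]))
        w2 = slc.SurveyWeights(3.0 * w1.w)
        d1 = slc.run_gibbs(tiny_data, w1, small_config)
        d2 = slc.run_gibbs(tiny_data, w2, small_config)
        assert np.array_equal(d1.pi_draws, d2.pi_draws)
        assert np.array_equal(d1.z_draws, d2.z_draws)
        assert d2.kappa == pytest.approx(3 * d1.kappa)

    def test_retained_draws_satisfy_simplex_invariants(
        self, short_weighted_draws
    ):
        d = short_weighted_draws
        assert d.T == d.config.n_retained
        assert np.allclose(d.pi_draws.sum(axis=1), 1.0)
        sums = d.theta_draws.astype(np.float64).sum(axis=2)
        assert np.allclose(sums, 1.0, atol=1e-5)
        assert d.z_draws.min() >= 1 and d.z_draws.max() <= d.K

    def test_mismatched_weight_length_rejected(self, tiny_data, small_config):
        with pytest.raises(ValueError, match="length"):
            slc.run_gibbs(tiny_data, slc.SurveyWeights.unit(5), small_config)

    def test_single_class_data_concentrates_on_one_class(self):
        y = np.tile(np.array([[2, 1, 3, 2, 1]]), (60, 1))
        data = slc.CategoricalMatrix(y, np.full(5, 3))
        cfg = slc.SamplerConfig(K=25, n_iter=800, burn_in=400, thin=2, seed=2)
        draws = slc.run_gibbs(data, None, cfg)
        assert slc.select_n_classes(draws.pi_draws, draws.z_draws) == 1
        summary, _, _ = slc.postprocess_draws(draws)
        assert summary.n_classes == 1
        assert summary.prevalence[0] > 0.9
        assert summary.modal_pattern[0].tolist() == [2, 1, 3, 2, 1]

    def test_permutation_sampler_preserves_posterior_summaries(self, tiny_data):
        base = slc.SamplerConfig(K=4, n_iter=3000, burn_in=500, thin=1, seed=6)
        permuted = dataclasses.replace(base, permute_labels=True, seed=7)
        w = slc.SurveyWeights(np.array([2.0, 1.0, 1.0, 3.0, 1.0, 4.0]))
        d1 = slc.run_gibbs(tiny_data, w, base)
        d2 = slc.run_gibbs(tiny_data, w, permuted)
        # label-free summaries agree: sorted pi means and co-clustering
        s1 = np.sort(d1.pi_draws, axis=1).mean(axis=0)
        s2 = np.sort(d2.pi_draws, axis=1).mean(axis=0)
        assert s1 == pytest.approx(s2, abs=0.05)

    def test_one_hot_design_matches_responses(self, tiny_data):
        X = _one_hot(tiny_data)
        assert X.shape == (6, 6)
        assert np.allclose(X.sum(axis=1), 2)
        assert X[0, 0] == 1 and X[0, 3 + 1] == 1  # y_11=1, y_12=2
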