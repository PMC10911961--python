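import json

import numpy as np
import pytest
from scipy import special, stats

import ternhmm as th
from ternhmm._kernels import forward_loglik, forward_backward, viterbi_path
from ternhmm.model import ForagingHMMResults, ModelSpecError, AmbiguousStateError

from conftest import random_hmm_instance
from oracles import enumerate_hmm


def make_series(step, angle, dist=None, behaviour=None, track_id="s"):
    step = np.asarray(step, dtype=float)
    return th.StepAngleSeries(
        track_id=track_id, step=step, angle=np.asarray(angle, dtype=float),
        dist_colony=np.zeros_like(step) if dist is None else np.asarray(dist),
        behaviour=behaviour)


def manual_results(series, spec, **block_overrides):
    """Results object at hand-set parameters (no optimisation)."""
    model = th.ForagingHMM(series, spec)
    blocks = model._data_driven_start()
    blocks.update(block_overrides)
    x = model.layout.pack(blocks)
    return ForagingHMMResults(model, x, llf=model.loglik(x), converged=True,
                              n_restarts=0, n_converged=0, restart_seed=None,
                              best_restart=0, niter=0)


class TestKernelsAgainstEnumeration:
    def test_forward_viterbi_posterior_match_bruteforce(self):
        rng = np.random.default_rng(2024)
        for _ in range(60):
            delta, gammas, b = random_hmm_instance(rng)
            want_ll, want_path, want_post = enumerate_hmm(delta, gammas, b)
            ld, lg, lb = np.log(delta), np.log(gammas), np.log(b)
            assert forward_loglik(ld, lg, lb) == pytest.approx(want_ll, abs=1e-10)
            post, ll = forward_backward(ld, lg, lb)
            assert ll == pytest.approx(want_ll, abs=1e-10)
            np.testing.assert_allclose(post, want_post, atol=1e-10)
            np.testing.assert_array_equal(viterbi_path(ld, lg, lb), want_path)

    def test_single_point_single_state(self):
        # T = 1, N = 1: the likelihood is just the observation density
        lb = np.array([[np.log(0.37)]])
        ll = forward_loglik(np.array([0.0]), np.zeros((0, 1, 1)), lb)
        assert ll == pytest.approx(np.log(0.37), abs=1e-14)

    def test_single_point_posterior_is_bayes(self):
        delta = np.array([0.3, 0.7])
        b = np.array([[2.0, 0.5]])
        post, _ = forward_backward(np.log(delta), np.zeros((0, 2, 2)), np.log(b))
        want = delta * b[0] / np.sum(delta * b[0])
        np.testing.assert_allclose(post[0], want, atol=1e-12)

    def test_label_permutation_invariance(self):
        rng = np.random.default_rng(9)
        delta, gammas, b = random_hmm_instance(rng, tmax=6)
        ll = forward_loglik(np.log(delta), np.log(gammas), np.log(b))
        perm = [1, 0]
        ll_p = forward_loglik(np.log(delta[perm]),
                              np.log(gammas[:, perm][:, :, perm]),
                              np.log(b[:, perm]))
        assert ll == pytest.approx(ll_p, abs=1e-12)

    def test_viterbi_tie_breaks_to_lower_state(self):
        # identical emissions, symmetric transitions: every sequence ties
        T = 6
        lb = np.zeros((T, 2))
        lg = np.log(np.full((T - 1, 2, 2), 0.5))
        path = viterbi_path(np.log([0.5, 0.5]), lg, lb)
        np.testing.assert_array_equal(path, np.zeros(T, dtype=int))

    def test_viterbi_dominance_limit(self):
        # near-uniform transitions + well separated emissions: Viterbi equals
        # the pointwise max-density state
        rng = np.random.default_rng(4)
        T = 40
        lb = rng.normal(0, 5, (T, 2))
        lg = np.log(np.full((T - 1, 2, 2), 0.5))
        path = viterbi_path(np.log([0.5, 0.5]), lg, lb)
        np.testing.assert_array_equal(path, np.argmax(lb, axis=1))

    def test_smoothing_rows_sum_to_one_and_match_filter_at_end(self, small_fit):
        posts = small_fit.local_probabilities("smoothed")
        filts = small_fit.local_probabilities("filtered")
        for p, f in zip(posts, filts):
            np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-12)
            np.testing.assert_allclose(p[-1], f[-1], atol=1e-9)


class TestModelLikelihood:
    """Full-path check: emissions + transitions + forward vs scipy/enumeration."""

    def _toy(self):
        step = np.array([0.004, 0.021, 0.018, 0.006])
        angle = np.array([np.nan, 0.3, -2.0, 1.1])
        series = make_series(step, angle)
        mu = np.array([0.005, 0.020])
        sigma = np.array([0.003, 0.008])
        rho = np.array([0.1, -0.2])
        kappa = np.array([1.0, 15.0])
        g12, g21 = 0.2, 0.4
        blocks = dict(log_mu=np.log(mu)[None], log_sigma=np.log(sigma)[None],
                      rho=rho, log_kappa=np.log(kappa),
                      trans_beta0=np.array([[special.logit(g12),
                                             special.logit(g21)]]),
                      delta_logit=np.array([[np.log(0.7 / 0.3)]]))
        return series, blocks, (mu, sigma, rho, kappa, g12, g21)

    def test_against_scipy_enumeration(self):
        series, blocks, (mu, sigma, rho, kappa, g12, g21) = self._toy()
        model = th.ForagingHMM([series], 0)
        got = model.loglik(blocks)

        # independent densities via scipy.stats
        shape = (mu / sigma) ** 2
        scale = sigma**2 / mu
        b = stats.gamma.pdf(series.step[:, None], shape, scale=scale)
        vm = stats.vonmises.pdf(series.angle[1:, None], kappa, loc=rho)
        b[1:] *= vm
        delta = np.array([0.3, 0.7])
        gam = np.array([[1 - g12, g12], [g21, 1 - g21]])
        want, _, want_post = enumerate_hmm(delta, np.tile(gam, (3, 1, 1)), b)
        assert got == pytest.approx(want, abs=1e-10)

        res = ForagingHMMResults(model, model.layout.pack(blocks), got, True,
                                 0, 0, None, 0, 0)
        np.testing.assert_allclose(res.local_probabilities()[0], want_post,
                                   atol=1e-10)

    def test_nan_leading_angle_contributes_step_only(self):
        series, blocks, _ = self._toy()
        model = th.ForagingHMM([series], 0)
        base = model.loglik(blocks)
        # changing rho/kappa must not affect the t=0 term; flipping the first
        # step must change the likelihood
        series2 = make_series(series.step.copy(), series.angle.copy())
        series2.step[0] = 0.03
        assert th.ForagingHMM([series2], 0).loglik(blocks) != pytest.approx(base)


class TestSpecAndParams:
    @pytest.mark.parametrize("model_id,expected", [
        (0, 11), (1, 17), (2, 19), (3, 25), (4, 13), (5, 15), (6, 17),
    ])
    def test_free_parameter_counts_three_tracks(self, small_series, model_id,
                                                expected):
        model = th.ForagingHMM(small_series, model_id)
        assert model.layout.n_params == expected

    def test_table_of_variants(self):
        spec0 = th.HMMSpec.from_model_id(0)
        assert spec0.pool_state and spec0.pool_observed
        assert not spec0.covariate_on_state and not spec0.covariate_on_observed
        spec6 = th.HMMSpec.from_model_id(6)
        assert spec6.covariate_on_state and spec6.covariate_on_observed

    def test_per_track_models_need_two_tracks(self, small_series):
        for mid in (1, 2, 3):
            with pytest.raises(ModelSpecError):
                th.ForagingHMM(small_series[:1], mid)

    def test_unknown_model_id(self):
        with pytest.raises(ModelSpecError):
            th.HMMSpec.from_model_id(7)


class TestLabellingAndAic:
    def _series(self):
        rng = np.random.default_rng(0)
        step = rng.gamma(2.0, 0.005, 50)
        angle = np.concatenate([[np.nan], rng.vonmises(0, 2, 49)])
        return [make_series(step, angle, dist=rng.uniform(0, 5, 50))]

    def test_short_step_state_is_foraging(self):
        res = manual_results(self._series(), 0,
                             log_mu=np.log([[0.005, 0.020]]),
                             log_sigma=np.log([[0.003, 0.008]]))
        assert res.state_labels() == {0: "foraging", 1: "not_foraging"}

    def test_relabelling_symmetry(self):
        res = manual_results(self._series(), 0,
                             log_mu=np.log([[0.020, 0.005]]),
                             log_sigma=np.log([[0.008, 0.003]]))
        assert res.state_labels() == {1: "foraging", 0: "not_foraging"}

    def test_equal_means_ambiguous(self):
        res = manual_results(self._series(), 0,
                             log_mu=np.log([[0.01, 0.01]]))
        with pytest.raises(AmbiguousStateError):
            res.state_labels()

    def test_covariate_driven_means_compared_at_median(self):
        # beta chosen so the ordering flips away from the median covariate:
        # at median c the first state must win
        series = self._series()
        model = th.ForagingHMM(series, 5)
        med = model.median_covariate
        res = manual_results(series, 5,
                             mu_beta0=np.array([np.log(0.005) - 1.0 * med,
                                                np.log(0.020)]),
                             mu_beta1=np.array([1.0, 0.0]))
        assert res.state_labels()[0] == "foraging"

    def test_aic_formula(self):
        res = manual_results(self._series(), 0)
        res.llf = 0.0
        assert res.aic == pytest.approx(2 * res.n_params)
        res.llf = -1.0
        assert res.aic == pytest.approx(2 * res.n_params + 2.0)


class TestFitting:
    def test_mle_dominates_truth(self, small_dataset, small_series, small_fit):
        cfg = small_dataset.config
        model = th.ForagingHMM(small_series, 0)
        truth = model._data_driven_start()
        truth.update(
            log_mu=np.log(np.array(cfg.mu))[None],
            log_sigma=np.log(np.array(cfg.sigma))[None],
            rho=np.array(cfg.rho), log_kappa=np.log(np.array(cfg.kappa)),
            trans_beta0=special.logit(np.array(cfg.gamma_offdiag))[None],
        )
        assert small_fit.llf >= model.loglik(truth) - 1e-6

    def test_fit_is_deterministic_given_seed(self, small_series):
        r1 = th.ForagingHMM(small_series, 0).fit(n_restarts=2, seed=10)
        r2 = th.ForagingHMM(small_series, 0).fit(n_restarts=2, seed=10)
        np.testing.assert_array_equal(r1.working_params, r2.working_params)
        assert r1.llf == r2.llf

    def test_covariate_slopes_null_when_absent(self, small_series):
        # covariate-free generating process: Model 4 slopes ~ 0 within 2 SE
        res = th.ForagingHMM(small_series, 4).fit(n_restarts=2, seed=3)
        b1 = res.blocks["trans_beta1"][0]
        se = res.bse()["trans_beta1"][0]
        assert np.all(np.abs(b1) < 2.0 * se)

    def test_serialisation_roundtrip(self, small_series, small_fit, tmp_path):
        path = tmp_path / "fit.json"
        small_fit.save(path)
        with open(path) as fh:
            restored = ForagingHMMResults.from_json(json.load(fh), small_series)
        assert restored.llf == pytest.approx(small_fit.llf)
        assert restored.n_params == small_fit.n_params
        for a, b in zip(restored.viterbi(), small_fit.viterbi()):
            np.testing.assert_array_equal(a, b)

    def test_summary_mentions_key_quantities(self, small_fit):
        text = small_fit.summary()
        assert "log-likelihood" in text and "AIC" in text
        assert "foraging" in text
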