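import numpy as np
import pytest
from scipy import stats as sps

from spikemux import reference as ref
from spikemux.models import (GammaPosterior, QuadConfig, assignment_scores,
                             classify_triplet, log_marglik_intermediate,
                             log_marglik_mixture, log_marglik_outside,
                             log_marglik_single, plugin_scores, rate_posterior)
from spikemux.screen import Triplet

from conftest import TEST_QUAD


class TestRatePosterior:
    def test_conjugate_update_zero_spikes(self):
        post = rate_posterior(np.zeros(10, dtype=int))
        assert (post.shape, post.rate) == (0.5, 10.0)

    def test_conjugate_arithmetic(self):
        counts = [4, 5, 6, 4, 5, 4, 4, 3, 4, 3]  # sums to 42
        post = rate_posterior(counts)
        assert (post.shape, post.rate) == (42.5, 10.0)
        assert post.mean == pytest.approx(4.25)

    def test_posterior_mean_approaches_sample_mean(self, rng):
        counts = rng.poisson(9, 5000)
        assert rate_posterior(counts).mean == pytest.approx(counts.mean(), abs=0.01)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            rate_posterior([])


class TestSingleMarginal:
    def test_empty_product_is_log_one(self):
        assert log_marglik_single([], GammaPosterior(20.5, 5)) == 0.0

    def test_matches_numerical_integral(self):
        post = GammaPosterior(20.5, 5.0)
        mine = log_marglik_single([3], post)
        assert mine == pytest.approx(ref.ref_log_marglik_single([3], post), abs=1e-6)

    def test_chain_rule_of_sequential_predictives(self, rng):
        # closed form equals the sum of one-step-ahead predictive log pmfs
        y = rng.poisson(7, 8)
        post = GammaPosterior(30.5, 4.0)
        total = 0.0
        a, b = post.shape, post.rate
        for yi in y:
            total += sps.nbinom.logpmf(yi, a, b / (b + 1.0))
            a, b = a + yi, b + 1.0
        assert log_marglik_single(y, post) == pytest.approx(total, abs=1e-10)


class TestDrawBasedMarginals:
    def _instance(self, rng, regime="intermediate"):
        ca, cb = rng.poisson(16, 10), rng.poisson(4, 10)
        y = {"intermediate": rng.poisson(10, 4),
             "outside": rng.poisson(28, 4),
             "mixture": np.where(rng.random(4) < 0.5, rng.poisson(16, 4),
                                 rng.poisson(4, 4))}[regime]
        return rate_posterior(ca), rate_posterior(cb), y

    @pytest.mark.parametrize("regime", ["intermediate", "outside", "mixture"])
    def test_grid_oracle_agreement(self, rng, regime):
        pa, pb, y = self._instance(rng, regime)
        quad = QuadConfig(n_draws=65536, seed=11)
        mine = {
            "mixture": log_marglik_mixture(y, pa, pb, quad)[0],
            "intermediate": log_marglik_intermediate(y, pa, pb, quad)[0],
            "outside": log_marglik_outside(y, pa, pb, quad)[0]}[regime]
        oracle = {
            "mixture": ref.ref_log_marglik_mixture(y, pa, pb, n_rate=161, n_alpha=401),
            "intermediate": ref.ref_log_marglik_intermediate(y, pa, pb,
                                                             n_rate=161, n_inner=401),
            "outside": ref.ref_log_marglik_outside(y, pa, pb,
                                                   n_rate=161, n_inner=401)}[regime]
        assert mine == pytest.approx(oracle, abs=1e-3)

    def test_alpha_quadrature_cross_check(self, rng):
        pa, pb, y = self._instance(rng, "mixture")
        exact = log_marglik_mixture(y, pa, pb, QuadConfig(n_draws=4096, seed=3))[0]
        simpson = log_marglik_mixture(
            y, pa, pb, QuadConfig(n_draws=4096, n_alpha=401,
                                  alpha_method="simpson", seed=3))[0]
        assert exact == pytest.approx(simpson, abs=1e-8)

    def test_mixture_of_identical_components_degenerates(self):
        # one AB count: the mixture marginal collapses to the shared single
        post = GammaPosterior(100.5, 10.0)
        mix, se = log_marglik_mixture([7], post, post, TEST_QUAD)
        single = log_marglik_single([7], post)
        assert mix == pytest.approx(single, abs=max(3 * se, 3e-3))

    def test_vanishing_interval_recovers_single(self):
        # tight identical posteriors: (min, max) shrinks onto the shared rate
        post_a = GammaPosterior(10000.5, 1000.0)
        post_b = GammaPosterior(10000.2, 1000.0)
        y = [9, 11, 10]
        mid = log_marglik_intermediate(y, post_a, post_b, TEST_QUAD)[0]
        single = log_marglik_single(y, post_a)
        assert mid == pytest.approx(single, abs=0.02)

    def test_empty_ab_counts_are_log_one(self):
        pa, pb = GammaPosterior(20.5, 5), GammaPosterior(5.5, 5)
        assert log_marglik_mixture([], pa, pb, TEST_QUAD) == (0.0, 0.0)
        assert log_marglik_intermediate([], pa, pb, TEST_QUAD) == (0.0, 0.0)
        assert log_marglik_outside([], pa, pb, TEST_QUAD) == (0.0, 0.0)

    def test_outside_loses_to_intermediate_for_interior_data(self, rng):
        pa, pb, y = self._instance(rng, "intermediate")
        out = log_marglik_outside(y, pa, pb, TEST_QUAD)[0]
        mid = log_marglik_intermediate(y, pa, pb, TEST_QUAD)[0]
        assert out < mid

    def test_outside_bound_sensitivity_is_mild(self, rng):
        pa, pb, y = self._instance(rng, "outside")
        t = Triplet("u", "c", rng.poisson(16, 10), rng.poisson(4, 10), y)
        p1 = classify_triplet(t, TEST_QUAD, require_screened=False,
                              fit_mixture=False).posterior
        from dataclasses import replace
        p2 = classify_triplet(t, replace(TEST_QUAD, upper_factor=20.0),
                              require_screened=False, fit_mixture=False).posterior
        assert abs(p1.win_prob - p2.win_prob) < 0.5


class TestClassification:
    def test_posterior_probabilities_sum_to_one(self, mixture_triplet):
        p = classify_triplet(mixture_triplet, TEST_QUAD,
                             require_screened=False).posterior
        assert sum(p.probs.values()) == pytest.approx(1.0, abs=1e-9)
        assert p.win_prob == max(p.probs.values())
        assert p.probs[p.winner] == p.win_prob

    @pytest.mark.parametrize("regime, build", [
        ("single", lambda rng: rng.permutation(rng.poisson(20, 20))),
        ("mixture", lambda rng: np.concatenate([rng.poisson(20, 10),
                                                rng.poisson(5, 10)])),
        ("intermediate", lambda rng: rng.poisson(12.5, 20)),
        ("outside", lambda rng: rng.poisson(40, 20)),
    ])
    def test_generating_regime_recovered(self, rng, regime, build):
        t = Triplet("u", "c", rng.poisson(20, 20), rng.poisson(5, 20), build(rng))
        p = classify_triplet(t, TEST_QUAD, require_screened=False,
                             fit_mixture=False).posterior
        assert p.winner == regime

    def test_unscreened_triplet_refused(self, mixture_triplet):
        with pytest.raises(ValueError, match="screen"):
            classify_triplet(mixture_triplet, TEST_QUAD)

    def test_deterministic_given_seed(self, mixture_triplet):
        a = classify_triplet(mixture_triplet, TEST_QUAD, require_screened=False)
        b = classify_triplet(mixture_triplet, TEST_QUAD, require_screened=False)
        assert a.posterior == b.posterior
        assert np.array_equal(a.scores, b.scores)


class TestLabelSymmetry:
    def test_swap_preserves_category_and_flips_scores_exactly(self, mixture_triplet):
        a = classify_triplet(mixture_triplet, TEST_QUAD, require_screened=False)
        b = classify_triplet(mixture_triplet.swapped(), TEST_QUAD,
                             require_screened=False)
        assert a.posterior.winner == b.posterior.winner
        for h in a.posterior.probs:
            assert a.posterior.probs[h] == b.posterior.probs[h]
        assert np.array_equal(b.scores, 1.0 - a.scores)
        assert b.mixture.alpha_mean == 1.0 - a.mixture.alpha_mean
        assert b.mixture.alpha_ci == (1.0 - a.mixture.alpha_ci[1],
                                      1.0 - a.mixture.alpha_ci[0])


class TestAssignmentScores:
    def test_scores_lie_in_unit_interval(self, mixture_triplet):
        s = assignment_scores(mixture_triplet, TEST_QUAD)
        assert len(s) == len(mixture_triplet.counts_AB)
        assert np.all((s >= 0) & (s <= 1))

    def test_plugin_score_half_where_pmfs_equal(self):
        # Poi(y|a) == Poi(y|b) at y = (a-b)/log(a/b); choose b so y = 8
        r = 4.0
        b = 8 * np.log(r) / (r - 1)
        a = r * b
        s = plugin_scores([8], 0.5, a, b)
        assert s[0] == pytest.approx(0.5, abs=1e-12)

    def test_high_counts_assigned_to_higher_rate(self, mixture_triplet):
        s = assignment_scores(mixture_triplet, TEST_QUAD)
        y = mixture_triplet.counts_AB
        assert s[np.argmax(y)] > 0.99
        assert s[np.argmin(y)] < 0.01

    def test_plugin_limit_score_goes_to_one(self):
        assert plugin_scores([60], 0.5, 20.0, 5.0)[0] > 1 - 1e-9

    def test_bayes_and_plugin_agree_roughly(self, mixture_triplet):
        sb = assignment_scores(mixture_triplet, TEST_QUAD, method="bayes")
        sp = assignment_scores(mixture_triplet, TEST_QUAD, method="plugin")
        assert np.max(np.abs(sb - sp)) < 0.25
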