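import numpy as np
import pytest
from hypothesis import given, strategies as st

from spikemux import reference as ref
from spikemux.screen import (Triplet, assemble_triplets, poisson_gof_pvalue,
                             screen_triplet, separation_bayes_factor)
from spikemux.synth import inject_overdispersion


class TestPoissonGof:
    def test_constant_counts_strongly_rejected(self):
        # zero variance is grossly non-Poisson at rate 7
        p = poisson_gof_pvalue(np.full(50, 7), n_mc=5000, seed=0)
        assert p < 0.01

    def test_true_poisson_samples_mostly_retained(self, rng):
        ps = [poisson_gof_pvalue(rng.poisson(12, 21), n_mc=1000, seed=i)
              for i in range(20)]
        assert np.mean(np.array(ps) > 0.10) >= 0.7

    @given(perm_seed=st.integers(0, 10))
    def test_order_invariance(self, perm_seed):
        counts = np.random.default_rng(3).poisson(8, 21)
        shuffled = np.random.default_rng(perm_seed).permutation(counts)
        p0 = poisson_gof_pvalue(counts, n_mc=1000, seed=5)
        p1 = poisson_gof_pvalue(shuffled, n_mc=1000, seed=5)
        assert p0 == p1

    def test_add_one_correction_keeps_p_positive(self):
        p = poisson_gof_pvalue(np.full(50, 7), n_mc=1000, seed=0)
        assert p >= 1 / 1001

    def test_all_zero_sample_is_perfectly_poisson(self):
        assert poisson_gof_pvalue(np.zeros(10, dtype=int), n_mc=1000, seed=0) == 1.0

    def test_too_few_counts_rejected(self):
        with pytest.raises(ValueError):
            poisson_gof_pvalue([1, 2], n_mc=1000)


class TestSeparationBayesFactor:
    def test_well_separated_rates_pass_threshold(self, rng):
        bf = separation_bayes_factor(rng.poisson(20, 20), rng.poisson(5, 20))
        assert bf > 3

    def test_identical_samples_favour_common_rate(self, rng):
        a = rng.poisson(10, 20)
        assert separation_bayes_factor(a, a.copy()) < 1

    def test_exchange_symmetry(self, rng):
        a, b = rng.poisson(15, 12), rng.poisson(6, 12)
        assert separation_bayes_factor(a, b) == pytest.approx(
            separation_bayes_factor(b, a), rel=1e-12)

    def test_monotone_in_mean_separation(self):
        # fixed total rate and sample sizes, growing separation
        bfs = []
        for d in (1, 3, 5, 7):
            a = np.full(10, 10 + d)
            b = np.full(10, 10 - d)
            bfs.append(separation_bayes_factor(a, b))
        assert np.all(np.diff(bfs) > 0)

    def test_matches_numerical_oracle(self, rng):
        a, b = rng.poisson(12, 4), rng.poisson(4, 4)
        mine = separation_bayes_factor(a, b)
        oracle = ref.ref_separation_bayes_factor(a, b)
        assert np.log(mine) == pytest.approx(np.log(oracle), abs=1e-4)

    def test_fractional_variant_agrees_in_direction(self, rng):
        a, b = rng.poisson(20, 20), rng.poisson(5, 20)
        assert separation_bayes_factor(a, b, method="fractional") > 3

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            separation_bayes_factor([], [1, 2])


class TestScreenTriplet:
    def _triplet(self, ca, cb, cab=None):
        cab = cab if cab is not None else np.full(10, 10)
        return Triplet("u", "c", np.asarray(ca), np.asarray(cb), np.asarray(cab))

    def test_well_behaved_triplets_mostly_pass(self, rng):
        results = [screen_triplet(self._triplet(rng.poisson(20, 21),
                                                rng.poisson(5, 21)), seed=i)
                   for i in range(12)]
        assert np.mean([r.passed for r in results]) >= 0.5
        assert all(r.separation_bf > 3 for r in results)
        ok = next(r for r in results if r.passed)
        assert ok.fail_reasons == ()

    def test_overdispersed_condition_fails_gof(self, rng):
        bad = inject_overdispersion(rng.poisson(20, 50), dispersion=4.0, seed=1)
        t = self._triplet(bad, rng.poisson(5, 21))
        res = screen_triplet(t, seed=0)
        assert not res.passed
        assert "A not Poisson" in res.fail_reasons

    def test_unseparated_rates_fail_bf(self, rng):
        a = rng.poisson(10, 21)
        t = self._triplet(a, rng.poisson(10, 21))
        res = screen_triplet(t, seed=0)
        assert not res.passed
        assert "rates not separated" in res.fail_reasons

    def test_passed_iff_all_rules(self, rng):
        t = self._triplet(rng.poisson(18, 21), rng.poisson(4, 21))
        res = screen_triplet(t, seed=0)
        expect = (res.gof_p_A > 0.10 and res.gof_p_B > 0.10
                  and res.separation_bf > 3)
        assert res.passed == expect == (len(res.fail_reasons) == 0)


class TestAssembleTriplets:
    def test_groups_by_unit_and_condition(self, rng):
        import pandas as pd
        pids = ([f"a{i}" for i in range(6)] + [f"b{i}" for i in range(6)]
                + [f"x{i}" for i in range(6)])
        conds = ["A"] * 6 + ["B"] * 6 + ["AB"] * 6
        meta = pd.DataFrame({"presentation_id": pids, "condition": conds,
                             "condition_key": "k1"})
        counts = pd.DataFrame(
            [(u, p, int(rng.poisson(8))) for u in ("u1", "u2") for p in pids],
            columns=["unit_id", "presentation_id", "count"])
        trips = assemble_triplets(counts, meta)
        assert [t.unit_id for t in trips] == ["u1", "u2"]
        assert all(len(t.counts_A) == len(t.counts_B) == len(t.counts_AB) == 6
                   for t in trips)

    def test_minimum_trial_requirement(self, rng):
        import pandas as pd
        meta = pd.DataFrame({"presentation_id": ["a1", "a2", "b1", "x1"],
                             "condition": ["A", "A", "B", "AB"],
                             "condition_key": "k1"})
        counts = pd.DataFrame([("u1", p, 3) for p in meta["presentation_id"]],
                              columns=["unit_id", "presentation_id", "count"])
        assert assemble_triplets(counts, meta) == []

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            Triplet("u", "c", np.array([-1, 2]), np.array([1]), np.array([1]))
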