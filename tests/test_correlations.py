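import numpy as np
import pandas as pd
import pytest

from spikemux import correlations as corr
from spikemux.models import classify_triplet
from spikemux.synth import PopulationConfig, generate_triplets

from conftest import TEST_QUAD


class TestPreference:
    def test_higher_mean_wins(self):
        assert corr.preference([12, 12.2], [4, 4]).preferred == "A"
        assert corr.preference([4, 4], [12, 12.2]).preferred == "B"

    def test_exact_tie_flagged(self):
        assert corr.preference([5, 5], [5, 5]).preferred is None


class TestSpikeCountCorrelation:
    def test_hand_computed_pearson(self):
        r, n = corr.spike_count_correlation([2, 0, 4, 2], [1, 3, 1, 3])
        assert r == pytest.approx(-0.707, abs=5e-4)
        assert n == 4

    def test_identical_vectors_give_unity(self):
        r, _ = corr.spike_count_correlation([1, 5, 3, 7], [1, 5, 3, 7])
        assert r == pytest.approx(1.0)

    def test_outlier_presentation_excluded(self):
        # last presentation is >3 SD for x; r computed on the rest
        x = np.array([10, 11, 9, 10, 11, 9, 10, 11, 9, 10, 11, 9, 100])
        y = np.arange(13)
        r, n = corr.spike_count_correlation(x, y)
        assert n == 12
        r_manual = np.corrcoef(x[:12], y[:12])[0, 1]
        assert r == pytest.approx(r_manual)

    def test_exclusion_noop_without_outliers(self, rng):
        x = rng.poisson(10, 30)
        y = rng.poisson(10, 30)
        assert np.abs(x - x.mean()).max() <= 3 * x.std()
        r, n = corr.spike_count_correlation(x, y)
        assert n == 30
        assert r == pytest.approx(np.corrcoef(x, y)[0, 1])

    def test_zero_variance_flagged_missing(self):
        r, _ = corr.spike_count_correlation([5, 5, 5, 5], [1, 2, 3, 4])
        assert np.isnan(r)

    def test_symmetric_in_pair_order(self, rng):
        x, y = rng.poisson(8, 20), rng.poisson(12, 20)
        assert corr.spike_count_correlation(x, y) == corr.spike_count_correlation(y, x)


class TestLabelPair:
    def _pref(self, which, key="k"):
        return corr.PreferenceLabel("u", key, which)

    def test_congruence_rules(self):
        assert corr.label_pair(self._pref("A"), self._pref("A"), "mixture", "single")[0] \
            == "congruent"
        assert corr.label_pair(self._pref("B"), self._pref("B"), "mixture", "mixture")[0] \
            == "congruent"
        assert corr.label_pair(self._pref("A"), self._pref("B"), "mixture", "mixture")[0] \
            == "incongruent"

    def test_class_combo_is_unordered(self):
        _, c1 = corr.label_pair(self._pref("A"), self._pref("A"), "mixture", "single")
        _, c2 = corr.label_pair(self._pref("A"), self._pref("A"), "single", "mixture")
        assert c1 == c2 == ("mixture", "single")

    def test_condition_mismatch_rejected(self):
        with pytest.raises(ValueError):
            corr.label_pair(self._pref("A", "k1"), self._pref("A", "k2"), "m", "m")


class TestMedianShuffleTest:
    def test_identical_groups_give_p_one(self):
        g = [0.1, 0.2, 0.3, 0.4]
        p, d = corr.median_shuffle_test(g, list(g), n_shuffles=500, seed=0)
        assert d == 0.0
        assert p == 1.0

    def test_separated_groups_detected(self, rng):
        g1 = rng.normal(1.0, 0.1, 40)
        g2 = rng.normal(-1.0, 0.1, 40)
        p, d = corr.median_shuffle_test(g1, g2, n_shuffles=10_000, seed=0)
        assert p == pytest.approx(1 / 10_001)
        assert d == pytest.approx(2.0, abs=0.2)

    def test_deterministic_given_seed(self, rng):
        g1, g2 = rng.normal(0, 1, 25), rng.normal(0.4, 1, 25)
        out1 = corr.median_shuffle_test(g1, g2, n_shuffles=2000, seed=7)
        out2 = corr.median_shuffle_test(g1, g2, n_shuffles=2000, seed=7)
        assert out1 == out2

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            corr.median_shuffle_test([], [1.0])


class TestAssignmentCorrelation:
    def test_identical_scores_give_unity(self):
        s = [0.1, 0.9, 0.4, 0.8]
        r, n = corr.assignment_correlation(s, list(s))
        assert r == pytest.approx(1.0) and n == 4

    def test_sign_relation_with_spike_count_correlation(self, rng):
        """Congruent pairs: sign(r_as) == sign(r_sc); incongruent: opposite."""
        cfg = PopulationConfig(n_units=6, regime_proportions=(0, 0, 0, 1.0),
                               fidelity_phi=0.95, seed=4)
        trips = generate_triplets(cfg).triplets()
        cls, scores = {}, {}
        for t in trips:
            an = classify_triplet(t, TEST_QUAD, require_screened=False)
            cls[(t.unit_id, t.condition_key)] = "mixture"
            scores[(t.unit_id, t.condition_key)] = an.scores
        rec = corr.build_pair_records(trips, cls, scores)
        ab = rec[(rec.stimulus_set == "AB") & np.isfinite(rec.r_as)
                 & (np.abs(rec.r_sc) > 0.2) & (np.abs(rec.r_as) > 0.2)]
        assert len(ab) >= 5
        cong = ab[ab.congruence == "congruent"]
        incong = ab[ab.congruence == "incongruent"]
        assert (np.sign(cong.r_as) == np.sign(cong.r_sc)).all()
        assert (np.sign(incong.r_as) == -np.sign(incong.r_sc)).all()


class TestSummarize:
    def _records(self):
        rows = []
        for i in range(6):
            rows.append({"unit_i": f"u{i}", "unit_j": f"v{i}", "condition_key": "k",
                         "stimulus_set": "AB", "r_sc": 0.3, "r_as": np.nan,
                         "n_used": 10, "congruence": "congruent",
                         "class_combo": "mixture|mixture", "pref_i": "A",
                         "pref_j": "A", "driven": None})
            rows.append({"unit_i": f"u{i}", "unit_j": f"w{i}", "condition_key": "k",
                         "stimulus_set": "AB", "r_sc": -0.1, "r_as": np.nan,
                         "n_used": 10, "congruence": "incongruent",
                         "class_combo": "mixture|mixture", "pref_i": "A",
                         "pref_j": "B", "driven": None})
        return pd.DataFrame(rows)

    def test_constant_cell_median(self):
        summ = corr.summarize_population(self._records(), n_shuffles=200, seed=0)
        cell = summ[(summ.class_combo == "mixture|mixture")
                    & (summ.congruence == "congruent")]
        assert cell["median_r_sc"].iloc[0] == pytest.approx(0.3)
        assert cell["n"].iloc[0] == 6

    def test_empty_cells_reported_missing(self):
        summ = corr.summarize_population(self._records(), n_shuffles=200, seed=0)
        empty = summ[summ.class_combo == "single|single"]
        assert (empty["n"] == 0).all()
        assert empty["median_r_sc"].isna().all()

    def test_grid_covers_all_class_combinations(self):
        summ = corr.summarize_population(self._records(), n_shuffles=200, seed=0)
        combos = set(summ[summ.stimulus_set == "AB"]["class_combo"])
        assert combos == {"all", "intermediate|intermediate", "intermediate|mixture",
                          "intermediate|single", "mixture|mixture", "mixture|single",
                          "single|single"}

    def test_empty_records_rejected(self):
        with pytest.raises(ValueError):
            corr.summarize_population(pd.DataFrame(columns=["r_sc"]))


class TestPairSignificance:
    def test_matches_scipy_pearson_p(self, rng):
        from scipy import stats
        x, y = rng.normal(size=30), rng.normal(size=30)
        r, p = stats.pearsonr(x, y)
        assert corr.pair_significance(r, 30) == pytest.approx(p, rel=1e-6)
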