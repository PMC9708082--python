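import numpy as np
import pytest

from spikemux import io as spio
from spikemux.screen import assemble_triplets, poisson_gof_pvalue
from spikemux.synth import (EyeTraceConfig, PopulationConfig, generate_eye_traces,
                            generate_triplets, inject_overdispersion,
                            sample_latent_states, sample_unit_rates)


class TestUnitRates:
    def test_rate_constraints_enforced(self, rng):
        cfg = PopulationConfig(n_units=200, min_rate_ratio=3.0, rate_range=(2, 40))
        rates = sample_unit_rates(cfg, rng)
        hi = np.maximum(rates.lam_A, rates.lam_B)
        lo = np.minimum(rates.lam_A, rates.lam_B)
        assert (hi / lo >= 3.0 - 1e-12).all()
        assert (lo >= 2.0).all() and (hi <= 40.0).all()

    def test_all_units_prefer_a_when_asked(self, rng):
        cfg = PopulationConfig(n_units=20, pref_A_fraction=1.0)
        rates = sample_unit_rates(cfg, rng)
        assert (rates.preference == "A").all()
        assert (rates.lam_A > rates.lam_B).all()

    def test_infeasible_range_rejected(self):
        with pytest.raises(ValueError):
            PopulationConfig(rate_range=(2.0, 4.0), min_rate_ratio=3.0)


class TestLatentStates:
    def test_degenerate_bias_all_a(self, rng):
        cfg = PopulationConfig(bias_beta=1.0)
        assert sample_latent_states(cfg, rng).all()

    def test_balanced_bias_concentrates(self, rng):
        cfg = PopulationConfig(trials_AB=10_000, bias_beta=0.5)
        states = sample_latent_states(cfg, rng)
        assert states.mean() == pytest.approx(0.5, abs=0.02)
        # independence across trials: negligible lag-1 autocorrelation
        lag1 = np.corrcoef(states[:-1], states[1:])[0, 1]
        assert abs(lag1) < 0.05


class TestGenerateTriplets:
    def test_one_hot_proportions_yield_single_regime(self):
        cfg = PopulationConfig(n_units=12, regime_proportions=(1.0, 0, 0, 0), seed=1)
        ds = generate_triplets(cfg)
        assert (ds.truth.regime == "single").all()

    def test_truth_alpha_identity(self):
        # alpha = beta*phi + (1-beta)*(1-phi); empirical state fractions agree
        cfg = PopulationConfig(n_units=60, regime_proportions=(0, 0, 0, 1.0),
                               trials_AB=50, bias_beta=0.7, fidelity_phi=0.9, seed=2)
        ds = generate_triplets(cfg)
        expect = 0.7 * 0.9 + 0.3 * 0.1
        assert ds.truth.alpha_true.unique() == pytest.approx([expect])
        # the whole population shares one latent state sequence, so the
        # empirical check conditions on the realised state frequency
        beta_hat = ds.latent_states.mean()
        expect_emp = beta_hat * 0.9 + (1 - beta_hat) * 0.1
        assert ds.truth.alpha_empirical.mean() == pytest.approx(expect_emp, abs=0.02)

    def test_mixture_means_lie_between_rates(self):
        cfg = PopulationConfig(n_units=40, regime_proportions=(0, 0, 0, 1.0), seed=3)
        ds = generate_triplets(cfg)
        for t, (_, row) in zip(ds.triplets(), ds.truth.iterrows()):
            lo, hi = sorted([row.lam_A, row.lam_B])
            assert lo - 3 * np.sqrt(hi) < t.counts_AB.mean() < hi + 3 * np.sqrt(hi)

    def test_single_stimulus_samples_pass_gof_at_nominal_rate(self):
        cfg = PopulationConfig(n_units=150, seed=4)
        ds = generate_triplets(cfg)
        rng = np.random.default_rng(5)
        retained = [poisson_gof_pvalue(t.counts_A, n_mc=1000,
                                       seed=int(rng.integers(2 ** 31))) > 0.10
                    for t in ds.triplets()]
        assert np.mean(retained) == pytest.approx(0.9, abs=0.06)

    def test_dataset_roundtrips_through_io(self, tmp_path):
        cfg = PopulationConfig(n_units=4, seed=6)
        ds = generate_triplets(cfg)
        ds.to_csv(tmp_path)
        counts = spio.read_counts(tmp_path / "counts.csv")
        meta = spio.read_metadata(tmp_path / "metadata.csv")
        trips = assemble_triplets(counts, meta)
        direct = ds.triplets()
        assert len(trips) == len(direct)
        for a, b in zip(trips, direct):
            assert np.array_equal(a.counts_AB, b.counts_AB)

    def test_spike_events_reproduce_counts(self):
        cfg = PopulationConfig(n_units=3, seed=7)
        ds = generate_triplets(cfg)
        window = spio.AreaWindow.for_area("V1")
        spikes = ds.spike_events(window)
        counted = spio.count_spikes_in_window(
            spikes, window, units=ds.counts.unit_id.unique(),
            presentations=ds.meta.presentation_id)
        merged = counted.merge(ds.counts, on=["unit_id", "presentation_id"],
                               suffixes=("_rec", "_true"))
        assert (merged.count_rec == merged.count_true).all()


class TestOverdispersion:
    def test_moments_of_injected_counts(self, rng):
        base = rng.poisson(12.0, 5000)
        nb = inject_overdispersion(base, dispersion=2.0, seed=1)
        assert nb.mean() == pytest.approx(base.mean(), rel=0.05)
        assert nb.var() / nb.mean() == pytest.approx(3.0, rel=0.15)

    def test_overdispersed_population_fails_screen_often(self):
        cfg = PopulationConfig(n_units=60, overdispersion=2.0, seed=8)
        ds = generate_triplets(cfg)
        rng = np.random.default_rng(9)
        excluded = [poisson_gof_pvalue(t.counts_A, n_mc=1000,
                                       seed=int(rng.integers(2 ** 31))) <= 0.10
                    for t in ds.triplets()]
        assert np.mean(excluded) > 0.5

    def test_invalid_dispersion_rejected(self):
        with pytest.raises(ValueError):
            inject_overdispersion([1, 2, 3], dispersion=0.0)


class TestEyeTraces:
    def test_quiet_traces_respect_fixation_window(self):
        cfg = EyeTraceConfig(n_presentations=20, saccade_fraction=0.0, seed=0)
        traces, truth = generate_eye_traces(cfg)
        assert not truth.has_event.any()
        for tr in traces.values():
            assert np.abs(tr.x).max() <= 0.5 and np.abs(tr.y).max() <= 0.5

    def test_zero_noise_trace_triggers_nothing(self):
        cfg = EyeTraceConfig(n_presentations=3, saccade_fraction=0.0,
                             scatter_sd=0.0, drift_speed_sd=0.0, seed=0)
        traces, _ = generate_eye_traces(cfg)
        for tr in traces.values():
            assert spio.detect_microsaccades(tr) == []

    def test_truth_table_marks_injections(self):
        cfg = EyeTraceConfig(n_presentations=50, saccade_fraction=1.0, seed=1)
        traces, truth = generate_eye_traces(cfg)
        assert truth.has_event.all()
        assert (truth.start_idx >= 0).all()
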