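"""Input-stream generator: Poisson statistics, templates, schedules,
corruption operators and weight initialization."""

import numpy as np
import pytest
from scipy import stats

from baplearn import rng, spikegen


class TestPoissonTrain:
    def test_zero_rate_gives_empty_train(self, rng_fixed):
        assert len(spikegen.generate_poisson_train(0.0, 1000.0, 0.1, rng_fixed)) == 0

    def test_mean_count_matches_binomial_oracle(self):
        # oracle: per-step Bernoulli(rate*dt) over duration/dt steps
        rate, dur, dt = 5.0, 100.0, 0.1
        n_steps, p = int(dur / dt), rate * dt * 1e-3
        expected_mean = n_steps * p  # 0.5
        g = np.random.default_rng(0)
        counts = [len(spikegen.generate_poisson_train(rate, dur, dt, g))
                  for _ in range(10_000)]
        sem = np.sqrt(expected_mean / len(counts))
        assert abs(np.mean(counts) - expected_mean) < 4 * sem

    def test_count_distribution_matches_binomial(self):
        rate, dur, dt = 20.0, 500.0, 0.1
        n_steps, p = int(dur / dt), rate * dt * 1e-3
        g = np.random.default_rng(1)
        counts = np.array([len(spikegen.generate_poisson_train(rate, dur, dt, g))
                           for _ in range(10_000)])
        kmax = counts.max()
        observed = np.bincount(counts, minlength=kmax + 1)
        expected = stats.binom.pmf(np.arange(kmax + 1), n_steps, p) * len(counts)
        keep = expected > 5
        chi2 = ((observed[keep] - expected[keep]) ** 2 / expected[keep]).sum()
        pval = stats.chi2.sf(chi2, keep.sum() - 1)
        assert pval > 0.01

    def test_deterministic_under_fixed_seed(self):
        a = spikegen.generate_poisson_train(5.0, 1000.0, 0.1, np.random.default_rng(7))
        b = spikegen.generate_poisson_train(5.0, 1000.0, 0.1, np.random.default_rng(7))
        np.testing.assert_array_equal(a, b)

    def test_invalid_parameters_rejected(self, rng_fixed):
        with pytest.raises(ValueError):
            spikegen.generate_poisson_train(-1.0, 100.0, 0.1, rng_fixed)
        with pytest.raises(ValueError):
            spikegen.generate_poisson_train(5.0, 100.0, 0.0, rng_fixed)

    def test_coarse_grid_warns(self, rng_fixed):
        with pytest.warns(UserWarning):
            spikegen.generate_poisson_train(100.0, 100.0, 1.0, rng_fixed)


class TestPatternTemplate:
    def test_interspike_intervals_exponential_without_bursts(self):
        # mean ISI (10 ms) << window (2 s) so truncation bias is negligible
        spec = spikegen.InputStreamSpec(n_exc=200, n_inh=200, t_pat=2000.0,
                                        noise_gap_range=(2000.0, 6000.0),
                                        trial_duration=10_000.0, n_patterns=1,
                                        rate=100.0, burst_fraction=0.0,
                                        community_size=300)
        g = np.random.default_rng(2)
        comm = spikegen.build_communities(spec, g)["pattern0"]
        tpl = spikegen.build_pattern_template(spec, comm, g)
        isis = np.concatenate([np.diff(t) for t in tpl.unit_spikes.values()
                               if len(t) > 1])
        # grid-Bernoulli ISIs are geometric = discretized exponential; at
        # n=2000 the 0.1 ms discretization sits below KS resolution
        sample = np.random.default_rng(0).choice(isis, 2000, replace=False)
        _, pval = stats.kstest(sample, "expon", args=(0.0, 1000.0 / spec.rate))
        assert pval > 0.01

    def test_burst_fraction_selects_exact_count(self):
        spec = spikegen.InputStreamSpec(burst_fraction=0.2)
        g = np.random.default_rng(3)
        tpl = spikegen.build_pattern_template(spec, np.arange(100), g)
        assert len(tpl.burst_unit_ids) == 20

    def test_template_reproducible_from_seed(self):
        spec = spikegen.InputStreamSpec(burst_fraction=0.1)
        t1 = spikegen.build_pattern_template(spec, np.arange(50),
                                             np.random.default_rng(5))
        t2 = spikegen.build_pattern_template(spec, np.arange(50),
                                             np.random.default_rng(5))
        assert t1.burst_unit_ids == t2.burst_unit_ids
        for u in t1.unit_spikes:
            np.testing.assert_array_equal(t1.unit_spikes[u], t2.unit_spikes[u])

    def test_empty_community_rejected(self, rng_fixed):
        with pytest.raises(ValueError):
            spikegen.build_pattern_template(spikegen.InputStreamSpec(),
                                            np.array([]), rng_fixed)

    def test_template_times_bounded_and_increasing(self, toy_template):
        for t in toy_template.unit_spikes.values():
            if len(t):
                assert t.min() >= 0 and t.max() < toy_template.t_pat
                assert np.all(np.diff(t) > 0)


class TestStreamAssembly:
    def test_pattern_epochs_have_exact_duration(self, toy_stream):
        stream, schedule = toy_stream
        for s, e, lab in zip(schedule.start, schedule.end, schedule.label):
            if lab != spikegen.NOISE_LABEL:
                assert e - s == pytest.approx(100.0)

    def test_schedule_covers_trial_contiguously(self, toy_stream):
        _, schedule = toy_stream
        assert schedule.start[0] == 0.0
        np.testing.assert_allclose(schedule.start[1:], schedule.end[:-1])
        assert schedule.end[-1] == pytest.approx(2000.0)

    def test_consecutive_patterns_separated_by_noise(self, toy_stream):
        _, schedule = toy_stream
        pat = schedule.label != spikegen.NOISE_LABEL
        assert not np.any(pat[:-1] & pat[1:])

    def test_gap_lengths_uniform_moments(self):
        spec = spikegen.InputStreamSpec(n_exc=10, n_inh=10, community_size=8,
                                        trial_duration=300_000.0)
        schedule = spikegen.build_schedule(spec, np.random.default_rng(4))
        gaps = (schedule.end - schedule.start)[schedule.label == spikegen.NOISE_LABEL]
        gaps = gaps[:-1]  # last gap may be truncated by the trial end
        assert gaps.min() >= 100.0 and gaps.max() <= 300.0
        assert abs(gaps.mean() - 200.0) < 4 * gaps.std() / np.sqrt(len(gaps))

    def test_presentation_frequencies_equal(self):
        spec = spikegen.InputStreamSpec(n_exc=10, n_inh=10, community_size=8,
                                        trial_duration=200_000.0)
        schedule = spikegen.build_schedule(spec, np.random.default_rng(6))
        counts = schedule.presentation_counts()
        n = sum(counts.values())
        assert n >= 500
        chi2, pval = stats.chisquare(list(counts.values()))
        assert pval > 0.01

    def test_template_replay_identical_without_corruption(self):
        spec = spikegen.InputStreamSpec(n_exc=30, n_inh=30, community_size=20,
                                        p_fail=0.0, trial_duration=5000.0,
                                        n_patterns=1)
        stream, schedule = spikegen.build_input_stream(
            spec, rng=np.random.default_rng(8),
            failure_rng=np.random.default_rng(9))
        tpl = stream.templates["pattern0"]
        for s, e, lab in zip(schedule.start, schedule.end, schedule.label):
            if lab != "pattern0":
                continue
            for u in stream.communities["pattern0"]:
                got = stream.times[(stream.units == u) & (stream.times >= s)
                                   & (stream.times < e)] - s
                np.testing.assert_allclose(np.sort(got), tpl.unit_spikes[int(u)],
                                           atol=1e-9)

    def test_seeded_stream_bit_identical(self, fig1_spec):
        spec = spikegen.InputStreamSpec(n_exc=50, n_inh=50, community_size=30,
                                        trial_duration=3000.0)
        s1, _ = spikegen.build_input_stream(spec, rng=rng.stream(11, "input"),
                                            failure_rng=rng.stream(11, "failure"))
        s2, _ = spikegen.build_input_stream(spec, rng=rng.stream(11, "input"),
                                            failure_rng=rng.stream(11, "failure"))
        np.testing.assert_array_equal(s1.units, s2.units)
        np.testing.assert_array_equal(s1.times, s2.times)


class TestCorruption:
    def test_failure_identity_at_zero(self, rng_fixed):
        spikes = np.arange(10.0)
        np.testing.assert_array_equal(
            spikegen.apply_transmission_failure(spikes, 0.0, rng_fixed), spikes)

    def test_failure_rate_one_rejected(self, rng_fixed):
        with pytest.raises(ValueError):
            spikegen.apply_transmission_failure(np.arange(5.0), 1.0, rng_fixed)

    def test_failure_survival_fraction_binomial(self):
        spikes = np.arange(10_000, dtype=float)
        kept = spikegen.apply_transmission_failure(spikes, 0.3,
                                                   np.random.default_rng(10))
        frac = len(kept) / len(spikes)
        assert abs(frac - 0.7) < 4 * np.sqrt(0.3 * 0.7 / len(spikes))

    def test_jitter_identity_at_zero(self, rng_fixed):
        spikes = np.sort(np.random.default_rng(0).uniform(0, 100, 50))
        np.testing.assert_array_equal(
            spikegen.apply_jitter(spikes, 0.0, rng_fixed), spikes)

    def test_jitter_mean_absolute_displacement(self):
        # displacement ~ U(-2m, 2m) has mean |d| = m
        spikes = np.full(20_000, 500.0)
        out = spikegen.apply_jitter(spikes, 50.0, np.random.default_rng(11),
                                    0.0, 1000.0)
        disp = np.abs(out - 500.0)
        assert abs(disp.mean() - 50.0) < 4 * disp.std() / np.sqrt(len(disp))

    def test_jitter_respects_bounds_and_sorting(self):
        spikes = np.sort(np.random.default_rng(1).uniform(0, 100, 500))
        out = spikegen.apply_jitter(spikes, 80.0, np.random.default_rng(12),
                                    0.0, 100.0)
        assert out.min() >= 0.0 and out.max() < 100.0
        assert np.all(np.diff(out) >= 0)


class TestWeightInit:
    def test_lognormal_variance_matches_unit_gaussian(self):
        spec = spikegen.WeightInitSpec(distribution="lognormal")
        w = spikegen.sample_initial_weights(spec, 100_000, 0,
                                            np.random.default_rng(13))
        assert np.var(w) == pytest.approx(1.0, rel=0.1)

    def test_uniform_bounds(self):
        spec = spikegen.WeightInitSpec(distribution="uniform")
        w = spikegen.sample_initial_weights(spec, 5000, 5000,
                                            np.random.default_rng(14))
        assert np.all(np.abs(w) <= 3.0)

    @pytest.mark.parametrize("dist", ["gaussian", "uniform", "lognormal"])
    def test_sign_convention(self, dist):
        spec = spikegen.WeightInitSpec(distribution=dist)
        w = spikegen.sample_initial_weights(spec, 500, 500,
                                            np.random.default_rng(15))
        assert np.all(w[:500] >= 0)
        assert np.all(w[500:] <= 0)

    def test_unknown_distribution_rejected(self, rng_fixed):
        with pytest.raises(ValueError):
            spikegen.sample_initial_weights(
                spikegen.WeightInitSpec(distribution="cauchy"), 10, 10, rng_fixed)
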