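import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from optokit import (
    SpikeTrain,
    StimProtocol,
    SynthConfig,
    TTLTrace,
    ValidationError,
    WrongProtocolError,
    build_ttl,
    expected_pulse_response,
    firing_rate,
    generate_chr2_events,
    generate_nphr_events,
    latency_mode,
    parse_schedule,
    psth,
    silencing_metrics,
    spike_fidelity,
)


def train_from(gt, duration):
    return SpikeTrain(gt.true_spike_times_s, duration, source="ground_truth")


class TestParseSchedule:
    def test_61_trains_of_100_pulses_at_20hz(self):
        proto = StimProtocol(kind="pulse_train", frequency_hz=20.0,
                             pulses_per_train=100, n_trains=61,
                             inter_train_interval_s=120.0)
        sched = parse_schedule(build_ttl(proto))
        assert sched.n_trains == 61
        assert sched.n_pulses == 6100
        assert sched.protocol_kind == "pulse_train"
        for k in range(61):
            assert sched.train_frequency_hz(k) == pytest.approx(20.0)

    def test_empty_ttl_gives_empty_schedule(self):
        sched = parse_schedule(TTLTrace(np.empty((0, 2))))
        assert sched.n_pulses == 0 and sched.n_trains == 0

    @given(st.lists(st.floats(0.05, 3.0), min_size=1, max_size=30))
    @settings(max_examples=50, deadline=None)
    def test_grouping_matches_brute_force_gap_scan(self, gaps):
        """Irregular inter-onset gaps straddling the threshold: grouping
        equals the O(n) scan comparing each consecutive gap to 1 s."""
        onsets = np.cumsum([1.0] + gaps)
        ttl = TTLTrace(np.column_stack([onsets, onsets + 0.01]))
        sched = parse_schedule(ttl, train_gap_s=1.0)
        expected_breaks = 1 + sum(g > 1.0 for g in gaps)
        assert sched.n_trains == expected_breaks
        assert sum(b - a for a, b in sched.train_slices) == onsets.size

    def test_continuous_light_recognized(self):
        proto = StimProtocol(kind="continuous", light_duration_s=10.0,
                             n_trains=5, inter_train_interval_s=30.0)
        assert parse_schedule(build_ttl(proto)).protocol_kind == "continuous"


class TestFidelity:
    def test_no_spikes_gives_zero_probability_and_no_mode(
            self, short_chr2_protocol):
        sched = parse_schedule(build_ttl(short_chr2_protocol))
        empty = SpikeTrain(np.empty(0), 30.0)
        res = spike_fidelity(empty, sched)
        assert res.mean_prob == 0.0
        assert not np.any(res.per_position_prob)
        assert res.latency_mode_ms is None

    def test_unit_fidelity_recovered_exactly(self, clean_config,
                                             short_chr2_protocol):
        ttl, gt = generate_chr2_events(clean_config, short_chr2_protocol)
        res = spike_fidelity(train_from(gt, 30.0), parse_schedule(ttl))
        assert res.mean_prob == pytest.approx(1.0)
        ipi_ms = 1000.0 / short_chr2_protocol.frequency_hz
        assert np.all((res.latencies_ms > 0) & (res.latencies_ms <= ipi_ms))

    def test_recovery_tracks_generator_expectation(self):
        """mean_prob lands within 3 SEs of the analytic per-pulse mean,
        including the >1 regime created by doublets."""
        proto = StimProtocol(kind="pulse_train", frequency_hz=20.0,
                             pulses_per_train=100, n_trains=10,
                             inter_train_interval_s=10.0)
        for p, d in [(0.9, 0.0), (1.0, 0.9)]:
            cfg = SynthConfig(seed=21, spont_rate_hz=1.0, evoked_prob=p,
                              doublet_prob=d)
            ttl, gt = generate_chr2_events(cfg, proto)
            res = spike_fidelity(
                train_from(gt, proto.session_duration_s()),
                parse_schedule(ttl))
            mean, var = expected_pulse_response(cfg, proto)
            se = np.sqrt(var / ttl.n_pulses)
            assert abs(res.mean_prob - mean) <= 3 * se
        assert res.mean_prob > 1.0  # doublet regime

    def test_wrong_protocol_rejected(self, nphr_protocol):
        sched = parse_schedule(build_ttl(nphr_protocol))
        with pytest.raises(WrongProtocolError):
            spike_fidelity(SpikeTrain(np.empty(0), 1000.0), sched)

    def test_sem_across_trains_option(self, clean_config,
                                      short_chr2_protocol):
        ttl, gt = generate_chr2_events(clean_config, short_chr2_protocol)
        sched = parse_schedule(ttl)
        spikes = train_from(gt, 30.0)
        a = spike_fidelity(spikes, sched, sem_across="positions")
        b = spike_fidelity(spikes, sched, sem_across="trains")
        assert a.mean_prob == b.mean_prob


class TestLatencyMode:
    def test_single_value_maps_to_bin_center(self):
        assert latency_mode([5.2, 5.2, 5.2]) == pytest.approx(5.5)

    def test_brute_force_bin_count_example(self):
        assert latency_mode([1.1, 1.2, 3.4]) == pytest.approx(1.5)

    def test_empty_input_gives_none(self):
        assert latency_mode([]) is None

    def test_tie_breaks_toward_smaller_latency(self):
        assert latency_mode([1.5, 3.5]) == pytest.approx(1.5)


class TestPSTH:
    def test_no_spikes_all_zero_bins(self):
        h = psth(SpikeTrain(np.empty(0), 10.0), [1.0, 5.0], (0.0, 1.0), 0.1)
        assert not np.any(h.counts)

    def test_zero_events_rejected(self):
        with pytest.raises(ValidationError):
            psth(SpikeTrain([1.0], 10.0), [], (0.0, 1.0), 0.1)

    def test_bin_must_divide_window(self):
        with pytest.raises(ValidationError):
            psth(SpikeTrain([1.0], 10.0), [0.0], (0.0, 1.0), 0.3)

    @given(seed=st.integers(0, 1000))
    @settings(max_examples=25, deadline=None)
    def test_counts_conserved_against_direct_window_count(self, seed):
        rng = np.random.default_rng(seed)
        t = np.unique(rng.uniform(0, 60.0, 300))
        spikes = SpikeTrain(t, 60.0)
        events = np.arange(5.0, 55.0, 10.0)
        h = psth(spikes, events, (-1.0, 2.0), 0.1)
        direct = sum(np.count_nonzero((t >= e - 1.0) & (t < e + 2.0))
                     for e in events)
        assert h.counts.sum() == direct

    def test_peak_bin_matches_latency_mode(self, clean_config):
        """1 ms PSTH of a 20 Hz train peaks at the latency-mode bin."""
        proto = StimProtocol(kind="pulse_train", frequency_hz=20.0,
                             pulses_per_train=100, n_trains=10,
                             inter_train_interval_s=10.0)
        ttl, gt = generate_chr2_events(clean_config, proto)
        spikes = train_from(gt, proto.session_duration_s())
        res = spike_fidelity(spikes, parse_schedule(ttl))
        h = psth(spikes, ttl.onsets_s, (0.0, 0.05), 0.001)
        peak_lag_ms = h.bin_centers_s[np.argmax(h.counts)] * 1000.0
        assert peak_lag_ms == pytest.approx(res.latency_mode_ms)

    def test_rate_conversion(self):
        spikes = SpikeTrain(np.arange(0.05, 10.0, 0.1), 10.0)  # 10 Hz
        h = psth(spikes, [2.0, 5.0], (0.0, 1.0), 0.5)
        np.testing.assert_allclose(h.rate_hz(), 10.0)


class TestFiringRate:
    def test_empty_train_zero_rate(self):
        assert firing_rate(SpikeTrain(np.empty(0), 10.0), (0.0, 5.0)) == 0.0

    def test_ten_spikes_in_five_seconds(self):
        spikes = SpikeTrain(np.linspace(0.1, 4.9, 10), 10.0)
        assert firing_rate(spikes, (0.0, 5.0)) == pytest.approx(2.0)

    def test_degenerate_window_rejected(self):
        with pytest.raises(ValidationError):
            firing_rate(SpikeTrain([1.0], 10.0), (2.0, 2.0))

    def test_baseline_rate_recovers_generator_rate(self):
        """Mean per-train 5 s baseline rate tracks spont_rate_hz within
        3 Poisson SEs."""
        rate = 2.0
        proto = StimProtocol(kind="pulse_train", frequency_hz=20.0,
                             pulses_per_train=100, n_trains=30,
                             inter_train_interval_s=20.0)
        cfg = SynthConfig(seed=22, spont_rate_hz=rate, evoked_prob=0.0)
        ttl, gt = generate_chr2_events(cfg, proto)
        spikes = train_from(gt, proto.session_duration_s())
        sched = parse_schedule(ttl)
        baselines = [firing_rate(spikes, (on - 5.0, on))
                     for on in sched.train_onsets_s]
        se = np.sqrt(rate / (5.0 * len(baselines)))
        assert abs(np.mean(baselines) - rate) <= 3 * se


class TestSilencing:
    def test_complete_suppression(self, nphr_protocol):
        cfg = SynthConfig(seed=23, spont_rate_hz=3.0, silencing_efficacy=1.0)
        ttl, gt = generate_nphr_events(cfg, nphr_protocol)
        res = silencing_metrics(
            train_from(gt, nphr_protocol.session_duration_s()),
            parse_schedule(ttl))
        assert res.n_breakthrough_trials == 0
        assert not np.any(res.during_rate_hz)

    def test_breakthrough_fraction_matches_ground_truth(self, nphr_protocol):
        cfg = SynthConfig(seed=24, spont_rate_hz=2.0, silencing_efficacy=0.9)
        ttl, gt = generate_nphr_events(cfg, nphr_protocol)
        res = silencing_metrics(
            train_from(gt, nphr_protocol.session_duration_s()),
            parse_schedule(ttl))
        assert res.breakthrough_fraction == pytest.approx(
            gt.per_trial_breakthrough.mean())
        assert res.n_trials == 30

    def test_during_rate_below_pre_rate(self, nphr_protocol):
        cfg = SynthConfig(seed=25, spont_rate_hz=2.0, silencing_efficacy=0.9)
        ttl, gt = generate_nphr_events(cfg, nphr_protocol)
        res = silencing_metrics(
            train_from(gt, nphr_protocol.session_duration_s()),
            parse_schedule(ttl))
        assert res.during_rate_hz.mean() < res.pre_rate_hz.mean()

    def test_wrong_protocol_rejected(self, short_chr2_protocol):
        sched = parse_schedule(build_ttl(short_chr2_protocol))
        with pytest.raises(WrongProtocolError):
            silencing_metrics(SpikeTrain([1.0], 100.0), sched)

    def test_overlapping_windows_truncated_with_warning(self):
        proto = StimProtocol(kind="continuous", light_duration_s=10.0,
                             n_trains=3, inter_train_interval_s=12.0)
        cfg = SynthConfig(seed=26, spont_rate_hz=2.0, silencing_efficacy=0.5)
        ttl, gt = generate_nphr_events(cfg, proto)
        with pytest.warns(UserWarning, match="truncated"):
            silencing_metrics(
                train_from(gt, proto.session_duration_s()),
                parse_schedule(ttl), pre_s=5.0, post_s=5.0)


class TestTimeShiftEquivariance:
    def test_fidelity_invariant_under_common_shift(self, clean_config,
                                                   short_chr2_protocol):
        ttl, gt = generate_chr2_events(clean_config, short_chr2_protocol)
        spikes = train_from(gt, 30.0)
        sched = parse_schedule(ttl)
        dt = 3.7
        shifted = parse_schedule(TTLTrace(ttl.intervals + dt))
        res0 = spike_fidelity(spikes, sched)
        res1 = spike_fidelity(spikes.shifted(dt), shifted)
        np.testing.assert_allclose(res1.per_position_prob,
                                   res0.per_position_prob)
        np.testing.assert_allclose(res1.latencies_ms, res0.latencies_ms,
                                   atol=1e-9)
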