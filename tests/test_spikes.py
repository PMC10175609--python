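"""Spike detection, trial segmentation, binning, and pooling."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cxcompass import (
    VoltageTrace,
    bin_counts,
    counts_from_trace,
    detect_spikes,
    gen_voltage_trace,
    pool_direction,
    segment_trials,
)


def spaced_spike_times(n, duration, min_gap, rng):
    """n random spike times with a minimum separation."""
    slack = duration - n * min_gap
    gaps = rng.dirichlet(np.ones(n + 1)) * slack
    return np.cumsum(gaps[:-1] + min_gap)


class TestDetectSpikes:
    def test_flat_trace_has_no_spikes(self):
        trace = VoltageTrace(np.zeros(50_000), sample_rate=10_000.0)
        assert detect_spikes(trace, threshold=5.0).size == 0

    def test_recovers_known_spikes_at_snr_10(self):
        # 200 spikes, amplitude 10x the noise SD: >= 99% recovered within
        # +-1 ms and no false positives
        rng = np.random.default_rng(42)
        true_times = spaced_spike_times(200, 20.0, 0.01, rng)
        trace, _ = gen_voltage_trace(true_times, duration=20.0, noise_sd=3.0,
                                     spike_amplitude=30.0, drift_amplitude=4.0,
                                     seed=1)
        # manual threshold at 60% of the spike amplitude: 6 noise SDs,
        # comfortably below the spike peaks
        detected = detect_spikes(trace, threshold=18.0)
        matched = 0
        for t in true_times:
            if np.any(np.abs(detected - t) <= 1e-3):
                matched += 1
        assert matched >= 0.99 * true_times.size
        # every detection matches a true spike (no false positives)
        for d in detected:
            assert np.min(np.abs(true_times - d)) <= 1e-3

    def test_constant_offset_does_not_change_spike_times(self):
        rng = np.random.default_rng(0)
        times = spaced_spike_times(30, 5.0, 0.02, rng)
        trace, _ = gen_voltage_trace(times, duration=5.0, noise_sd=2.0, seed=2)
        shifted = VoltageTrace(trace.samples + 25.0, trace.sample_rate)
        a = detect_spikes(trace, threshold=15.0)
        b = detect_spikes(shifted, threshold=15.0)
        assert np.array_equal(a, b)

    def test_events_within_refractory_period_merge(self):
        # two waveform peaks 1 ms apart count as one spike
        trace, _ = gen_voltage_trace([0.100, 0.101], duration=0.5, noise_sd=0.0,
                                     drift_amplitude=0.0)
        assert detect_spikes(trace, threshold=15.0).size == 1

    def test_empty_or_invalid_trace_raises(self):
        with pytest.raises(ValueError, match="empty"):
            detect_spikes(VoltageTrace(np.array([]), 10_000.0), threshold=5.0)
        bad = np.zeros(1000)
        bad[10] = np.nan
        with pytest.raises(ValueError, match="non-finite"):
            detect_spikes(VoltageTrace(bad, 10_000.0), threshold=5.0)


def event_table(rows):
    return pd.DataFrame(rows, columns=["direction", "phase", "t_start", "t_end",
                                       "series_index"])


class TestSegmentTrials:
    def test_adaptation_discarded_and_trials_paired(self):
        rows = [("forward", "adaptation", 0.0, 5.0, 0)]
        t = 5.0
        for _ in range(3):
            rows.append(("forward", "motion", t, t + 5.0, 0))
            rows.append(("forward", "stationary", t + 5.0, t + 10.0, 0))
            t += 10.0
        windows = segment_trials(event_table(rows))
        assert len(windows) == 3
        assert all(w.direction == "forward" for w in windows)
        assert windows[0].motion == (5.0, 10.0)
        assert windows[0].stationary == (10.0, 15.0)

    def test_repeated_series_pool_into_one(self):
        # two forward series of 2 trials each -> 4 pooled forward trials
        rows, t = [], 0.0
        for series in range(2):
            rows.append(("forward", "adaptation", t, t + 5.0, series))
            t += 5.0
            for _ in range(2):
                rows.append(("forward", "motion", t, t + 5.0, series))
                rows.append(("forward", "stationary", t + 5.0, t + 10.0, series))
                t += 10.0
        windows = segment_trials(event_table(rows))
        assert len(windows) == 4
        counts = counts_from_trace(
            VoltageTrace(np.zeros(int(t * 10_000)), 10_000.0),
            event_table(rows), threshold=5.0, neuron_id="n")
        assert counts["forward"].n_motion == 4 * 2500

    def test_overlapping_phases_raise(self):
        rows = [("forward", "motion", 0.0, 5.0, 0),
                ("forward", "stationary", 4.0, 9.0, 0)]
        with pytest.raises(ValueError, match="overlapping"):
            segment_trials(event_table(rows))

    def test_motion_without_stationary_raises(self):
        rows = [("forward", "motion", 0.0, 5.0, 0),
                ("backward", "motion", 5.0, 10.0, 0),
                ("backward", "stationary", 10.0, 15.0, 0)]
        with pytest.raises(ValueError, match="row 0"):
            segment_trials(event_table(rows))

    def test_six_second_phases_accepted(self):
        rows = [("forward", "motion", 0.0, 6.0, 0),
                ("forward", "stationary", 6.0, 12.0, 0)]
        assert len(segment_trials(event_table(rows))) == 1


class TestBinCounts:
    def test_no_spikes(self):
        assert bin_counts([], (0.0, 5.0)) == (0, 2500)

    def test_spikes_in_distinct_bins(self):
        assert bin_counts([0.0005, 0.0025, 0.0045], (0.0, 5.0)) == (3, 2500)

    def test_bin_occupancy_not_spike_count(self):
        # two spikes inside one 2 ms bin occupy a single bin
        assert bin_counts([0.0102, 0.0108], (0.0, 5.0)) == (1, 2500)

    def test_window_truncated_to_analysis_span(self):
        # spike at 5.5 s falls outside the first 5 s of a 6 s phase
        assert bin_counts([5.5], (0.0, 6.0)) == (0, 2500)

    def test_short_window_raises(self):
        with pytest.raises(ValueError, match="shorter"):
            bin_counts([], (0.0, 4.0))

    @given(shift=st.floats(min_value=0.0, max_value=1000.0,
                           allow_nan=False, allow_infinity=False))
    @settings(deadline=None)
    def test_translation_invariance(self, shift):
        spikes = np.array([0.0101, 0.2503, 1.75, 3.3333, 4.9999])
        base = bin_counts(spikes, (0.0, 5.0))
        moved = bin_counts(spikes + shift, (shift, shift + 5.0))
        assert moved == base


class TestPoolDirection:
    def test_counts_add_over_trials(self):
        pooled = pool_direction([("forward", (10, 2500, 5, 2500)),
                                 ("forward", (20, 2500, 5, 2500))], "n")
        assert (pooled.k_motion, pooled.n_motion) == (30, 5000)
        assert (pooled.k_stationary, pooled.n_stationary) == (10, 5000)
        assert pooled.per_trial == [(10, 2500, 5, 2500), (20, 2500, 5, 2500)]

    def test_single_trial_is_identity(self):
        pooled = pool_direction([("forward", (7, 2500, 3, 2500))], "n")
        assert (pooled.k_motion, pooled.k_stationary) == (7, 3)

    def test_conservation_over_many_trials(self):
        rng = np.random.default_rng(9)
        ks = rng.integers(0, 2500, size=(8, 2))
        trials = [("forward", (int(a), 2500, int(b), 2500)) for a, b in ks]
        pooled = pool_direction(trials, "n")
        assert pooled.k_motion == int(ks[:, 0].sum())
        assert pooled.k_stationary == int(ks[:, 1].sum())

    def test_mixed_directions_rejected(self):
        with pytest.raises(ValueError, match="mixed directions"):
            pool_direction([("forward", (1, 2500, 1, 2500)),
                            ("backward", (1, 2500, 1, 2500))], "n")

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            pool_direction([], "n")
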