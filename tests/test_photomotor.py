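"""LFR metrics, event detection, triggered averages, spontaneous activity."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from zebraphen import simulate as sim
from zebraphen.datatypes import ActivityTrace, StimulusProtocol
from zebraphen.errors import DataValidationError, ProtocolMismatchError
from zebraphen.photomotor import (
    LFR_WINDOW_S,
    detect_events,
    lfr_simple,
    spontaneous_activity,
    triggered_average,
)


def merged_truth_count(truth):
    """Interval-union oracle: number of merged truth pulse intervals."""
    ivs = sorted((b.onset_slice, b.onset_slice + b.duration_slices)
                 for b in truth)
    n = 0
    end = -1
    for s, e in ivs:
        if s > end:  # gap of >= 1 slice starts a new run
            n += 1
            end = e
        else:
            end = max(end, e)
    return n


class TestDetectEvents:
    @pytest.mark.parametrize(
        "values,threshold,gap,expected",
        [
            ([0, 5, 0, 7, 7, 0], 1, 0, 2),
            ([0, 0, 0], 1, 0, 0),
            ([0, 5, 0, 7, 7, 0], 1, 1, 1),  # gap of one slice merged
            ([5, 0, 0, 5], 1, 1, 2),  # gap of two slices not merged
            ([1, 1, 1], 1, 0, 1),  # threshold is inclusive
        ],
    )
    def test_run_counting(self, values, threshold, gap, expected):
        assert detect_events(np.array(values, float), threshold, gap) == expected

    def test_nonpositive_threshold_rejected(self):
        with pytest.raises(DataValidationError):
            detect_events(np.zeros(3), 0.0)

    @settings(max_examples=40, derandomize=True)
    @given(st.lists(st.floats(0, 50, allow_nan=False), min_size=1, max_size=60),
           st.floats(0.5, 25))
    def test_monotone_in_threshold_and_gap(self, values, threshold):
        v = np.array(values)
        n_lo = detect_events(v, threshold)
        n_hi = detect_events(v, threshold * 2)
        assert n_hi <= n_lo
        assert detect_events(v, threshold, merge_gap_slices=3) <= n_lo

    def test_noiseless_recovery_equals_merged_truth(self, extended_protocol):
        eff = sim.GenotypeEffect(bout_rate_hz=0.4, flash_response_prob=0.8,
                                 response_amp_mean=20.0, response_amp_sd=2.0)
        traces, truths = sim.simulate_actinteg(extended_protocol, eff,
                                               n_larvae=10, seed=17)
        for tr, truth in zip(traces, truths):
            if not truth:
                continue
            thr = 0.5 * min(b.amplitude for b in truth)
            assert detect_events(tr.values, thr) == merged_truth_count(truth)


class TestLfrSimple:
    def test_window_is_60_slices_of_light_epoch(self, simple_protocol):
        # activity placed in slice 59 after light onset is seen; slice 60 not
        onset = simple_protocol.slice_of(300.0)
        v = np.zeros(simple_protocol.n_slices)
        v[onset + 59] = 7.0
        m = lfr_simple(ActivityTrace("w", v, simple_protocol), threshold=1.0)
        assert m.max_activity == 7.0 and m.n_events == 1
        v2 = np.zeros(simple_protocol.n_slices)
        v2[onset + 60] = 7.0
        m2 = lfr_simple(ActivityTrace("w", v2, simple_protocol), threshold=1.0)
        assert m2.max_activity == 0.0 and m2.n_events == 0
        assert LFR_WINDOW_S == 4.0

    def test_zero_trace(self, simple_protocol):
        m = lfr_simple(ActivityTrace("w", np.zeros(simple_protocol.n_slices),
                                     simple_protocol), threshold=1.0)
        assert m.max_activity == 0.0 and m.n_events == 0

    def test_wrong_protocol_rejected(self, extended_protocol):
        tr = ActivityTrace("w", np.zeros(extended_protocol.n_slices),
                           extended_protocol)
        with pytest.raises(ProtocolMismatchError):
            lfr_simple(tr, threshold=1.0)

    def test_responder_vs_nonresponder_event_difference(self, simple_protocol):
        high = sim.GenotypeEffect(bout_rate_hz=0.0, flash_response_prob=0.9,
                                  response_amp_sd=0.0)
        low = sim.GenotypeEffect(bout_rate_hz=0.0, flash_response_prob=0.3,
                                 response_amp_sd=0.0)
        n = 300
        # simple protocol has one flash; count wells with >= 1 event
        def frac_responding(eff, seed):
            traces, _ = sim.simulate_actinteg(simple_protocol, eff,
                                              n_larvae=n, seed=seed)
            return np.mean([lfr_simple(t, threshold=1.0).n_events > 0
                            for t in traces])

        diff = frac_responding(high, 1) - frac_responding(low, 2)
        se = np.sqrt(0.9 * 0.1 / n) + np.sqrt(0.3 * 0.7 / n)
        assert abs(diff - 0.6) < 3 * se


class TestTriggeredAverage:
    def test_constant_trace_gives_15c_per_second(self, extended_protocol):
        c = 2.0
        tr = ActivityTrace("w", np.full(extended_protocol.n_slices, c),
                           extended_protocol)
        ta = triggered_average(tr)
        assert ta.v1 == pytest.approx(15 * c)
        assert ta.v2 == pytest.approx(15 * c)

    def test_impulse_arithmetic(self, extended_protocol):
        A = 48.0
        v = np.zeros(extended_protocol.n_slices)
        onset = extended_protocol.slice_of(
            extended_protocol.flash_onsets_s()[0]
        )
        v[onset] = A
        ta = triggered_average(ActivityTrace("w", v, extended_protocol))
        assert ta.v1 == pytest.approx(A / 16.0)  # (A/2 s) averaged over 8
        assert ta.v2 == 0.0

    def test_v1_is_mean_of_per_flash_column(self, extended_protocol):
        traces, _ = sim.simulate_actinteg(extended_protocol,
                                          sim.GenotypeEffect(), seed=2)
        ta = triggered_average(traces[0])
        assert ta.v1 == pytest.approx(ta.per_flash[:, 0].mean())
        assert ta.v2 == pytest.approx(ta.per_flash[:, 1].mean())
        assert ta.per_flash.shape == (8, 2)

    def test_pooled_equals_per_flash_average(self, extended_protocol):
        # equal window lengths make flash-wise then averaged == pooled mean
        traces, _ = sim.simulate_actinteg(extended_protocol,
                                          sim.GenotypeEffect(), seed=3)
        tr = traces[0]
        ta = triggered_average(tr)
        proto = tr.protocol
        pooled = np.concatenate([
            tr.values[proto.slice_of(o): proto.slice_of(o) + 30]
            for o in proto.flash_onsets_s()
        ])
        assert ta.v1 == pytest.approx(pooled.reshape(8, 30).mean() * 15)

    def test_fatigue_declines_across_flashes(self, extended_protocol):
        eff = sim.GenotypeEffect(bout_rate_hz=0.0, flash_response_prob=1.0,
                                 fatigue=0.7, response_amp_sd=0.0)
        traces, _ = sim.simulate_actinteg(extended_protocol, eff,
                                          n_larvae=400, seed=5)
        col = np.mean([triggered_average(t).per_flash[:, 0] for t in traces],
                      axis=0)
        slope = np.polyfit(np.arange(8), col, 1)[0]
        assert slope < 0

    def test_window_beyond_trace_rejected(self, extended_protocol):
        tr = ActivityTrace("w", np.zeros(extended_protocol.n_slices),
                           extended_protocol)
        with pytest.raises(DataValidationError):
            triggered_average(tr, flash_onsets_s=[1120.0])


class TestSpontaneous:
    def test_zero_and_constant_traces(self, extended_protocol):
        z = ActivityTrace("w", np.zeros(extended_protocol.n_slices),
                          extended_protocol)
        assert spontaneous_activity(z) == 0.0
        c = ActivityTrace("w", np.full(extended_protocol.n_slices, 3.0),
                          extended_protocol)
        assert spontaneous_activity(c) == pytest.approx(45.0)

    def test_window_excludes_adaptation(self, extended_protocol):
        v = np.zeros(extended_protocol.n_slices)
        v[: 300 * 15] = 100.0  # activity only during the adaptation epoch
        tr = ActivityTrace("w", v, extended_protocol)
        assert spontaneous_activity(tr) == 0.0

    def test_point_process_mean_recovered(self, extended_protocol):
        rate, amp = 0.5, 20.0
        eff = sim.GenotypeEffect(bout_rate_hz=rate, flash_response_prob=0.0,
                                 response_amp_mean=amp, response_amp_sd=0.0)
        traces, _ = sim.simulate_actinteg(extended_protocol, eff,
                                          n_larvae=300, seed=8)
        vals = np.array([spontaneous_activity(t) for t in traces])
        expect = rate * amp * 3.5  # mean pulse length (2+3+4+5)/4 slices
        se = vals.std(ddof=1) / np.sqrt(len(vals))
        assert abs(vals.mean() - expect) < 3 * se


class TestScaleEquivariance:
    def test_scaling_actinteg_scales_metrics(self, extended_protocol):
        traces, _ = sim.simulate_actinteg(extended_protocol,
                                          sim.GenotypeEffect(), seed=13)
        tr = traces[0]
        k = 3.7
        scaled = ActivityTrace(tr.well_id, tr.values * k, extended_protocol)
        ta, tas = triggered_average(tr), triggered_average(scaled)
        assert tas.v1 == pytest.approx(k * ta.v1)
        assert tas.v2 == pytest.approx(k * ta.v2)
        assert spontaneous_activity(scaled) == pytest.approx(
            k * spontaneous_activity(tr)
        )
        thr = 5.0
        assert detect_events(scaled.values, k * thr) == detect_events(
            tr.values, thr
        )
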