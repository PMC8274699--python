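"""Scan state machine: triggering, breath declaration, re-acquisition, modes."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cinegate import (ScanParams, ScanTimeoutError, TTLSignal, centre_out_order,
                      run_localiser, run_scan, run_scan_ccrt, run_scan_dg,
                      scan_time_summary, trigger_jitter_stats)
from cinegate.errors import InvalidInputError


def _pulse_train(onsets, width=16.0, t1=None):
    t1 = t1 if t1 is not None else onsets[-1] + 200.0
    return TTLSignal.from_intervals([(t, t + width) for t in onsets], 0.0, t1)


def _always_high(t1):
    return TTLSignal.from_intervals([(0.0, t1)], 0.0, t1)


class TestTssm:
    def test_always_high_back_to_back_blocks(self):
        params = ScanParams(n_phase_encodes=8)
        sched = run_scan(_always_high(5000.0), params)
        assert len(sched.kept_blocks) == 8
        assert len(sched.breath_declarations) == 0
        triggers = [b.trigger_time for b in sched.blocks]
        np.testing.assert_allclose(np.diff(triggers), params.cine_block_duration)
        assert sched.total_duration == pytest.approx(
            8 * params.cine_block_duration - params.tr)

    def test_constant_tr_contract(self):
        """tSSM: RF interval multiset is exactly {TR} whatever the gating."""
        onsets = np.concatenate([np.arange(1, 7) * 134.0,
                                 1500.0 + np.arange(1, 7) * 134.0])
        sched = run_scan(_pulse_train(onsets), ScanParams(n_phase_encodes=8))
        np.testing.assert_allclose(np.diff(sched.rf_pulse_times), 4.0)

    def test_breath_declaration_and_reacquisition(self):
        """Six blocks, then a long gap: blocks 4 and 5 are re-queued and the
        final schedule keeps each index exactly once."""
        params = ScanParams(n_phase_encodes=6)
        onsets = list(np.arange(1, 7) * 100.0)            # blocks 0..5
        onsets += list(1000.0 + np.arange(1, 4) * 100.0)  # post-breath triggers
        sched = run_scan(_pulse_train(onsets), params)
        assert len(sched.breath_declarations) == 1
        re = sorted(b.phase_encode_index for b in sched.reacquired_blocks)
        assert re == [4, 5]
        kept = sorted(b.phase_encode_index for b in sched.kept_blocks)
        assert kept == [0, 1, 2, 3, 4, 5]
        # re-queued indices acquired first after the breath
        post = [b for b in sched.kept_blocks if b.trigger_time > 1000.0]
        assert [b.phase_encode_index for b in post[:2]] == [4, 5]

    def test_threshold_is_strict(self):
        """Exactly 25 idle ticks between triggers must NOT declare a breath."""
        params = ScanParams(n_phase_encodes=2)
        # block 0 at t=0 runs to 80; 25 idle ticks -> next trigger at 180
        ttl = TTLSignal.from_intervals([(0.0, 16.0), (180.0, 196.0)], 0.0, 300.0)
        sched = run_scan(ttl, params)
        assert sched.breath_declarations == []
        # one more idle tick does declare (extra triggers cover the re-queue)
        ttl2 = TTLSignal.from_intervals(
            [(0.0, 16.0), (184.0, 200.0), (300.0, 316.0), (420.0, 436.0)],
            0.0, 600.0)
        sched2 = run_scan(ttl2, ScanParams(n_phase_encodes=2))
        assert len(sched2.breath_declarations) == 1

    def test_gate_never_high_times_out(self):
        ttl = TTLSignal.from_intervals([], 0.0, 2000.0)
        with pytest.raises(ScanTimeoutError) as err:
            run_scan(ttl, ScanParams(n_phase_encodes=4))
        assert err.value.missing == [0, 1, 2, 3]

    def test_early_breath_requeues_only_existing_blocks(self):
        """A breath before n_reacquire blocks exist re-queues what exists."""
        onsets = [100.0, 500.0, 600.0, 700.0, 800.0]
        sched = run_scan(_pulse_train(onsets, t1=900.0),
                         ScanParams(n_phase_encodes=3))
        assert len(sched.reacquired_blocks) == 1
        assert sorted(b.phase_encode_index for b in sched.kept_blocks) == [0, 1, 2]

    @given(gaps=st.lists(st.integers(5, 60), min_size=3, max_size=25))
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_declaration_matches_brute_force_gap_scanner(self, gaps):
        """A breath is declared iff an inter-trigger idle stretch exceeds the
        count threshold; oracle = direct scan of the tick-quantized gaps.

        The pulse train carries one trigger per gap, followed by a long
        always-high tail so that re-queued blocks never starve the queue and
        every gap is traversed.
        """
        params = ScanParams(n_phase_encodes=3 * len(gaps) + 1,
                            breath_count_threshold=25)
        tr, ne = params.tr, params.n_frames
        onsets = [8.0]
        for g in gaps:
            onsets.append(onsets[-1] + ne * tr + g * tr)
        tail_start = onsets[-1] + ne * tr
        t1 = tail_start + (params.n_phase_encodes + 1) * ne * tr
        intervals = [(t, t + tr + 1.0) for t in onsets] + [(tail_start, t1)]
        ttl = TTLSignal.from_intervals(intervals, 0.0, t1)
        sched = run_scan(ttl, params)

        expected = sum(1 for g in gaps if g > params.breath_count_threshold)
        assert len(sched.breath_declarations) == expected

    def test_reacquisition_conservation(self):
        """kept + discarded = launched; discarded = n_reacquire * breaths when
        breaths are well separated."""
        rng = np.random.default_rng(8)
        onsets, t = [], 100.0
        for k in range(60):
            t += 134.0 if (k + 1) % 12 else 700.0   # a breath every 12 beats
            onsets.append(t)
        params = ScanParams(n_phase_encodes=40)
        sched = run_scan(_pulse_train(np.asarray(onsets)), params)
        s = scan_time_summary(sched)
        assert s["kept_blocks"] + s["reacquired_blocks"] == len(sched.blocks)
        assert s["reacquired_blocks"] == params.n_reacquire * s["breaths_declared"]


class TestJitter:
    def test_uniform_phase_gives_half_tr_mean(self):
        rng = np.random.default_rng(99)
        n = 4000
        onsets = np.arange(1, n + 1) * 134.0 + rng.uniform(0, 4.0, size=n)
        ttl = _pulse_train(onsets, t1=onsets[-1] + 100.0)
        sched = run_scan(ttl, ScanParams(n_phase_encodes=n))
        js = trigger_jitter_stats(sched, ttl, tr=4.0)
        assert abs(js.mean_in_tr - 0.5) < 0.02
        assert js.delays.min() >= 0.0 and js.delays.max() <= 4.0

    def test_phase_locked_triggers_give_constant_delay(self):
        onsets = np.arange(1, 30) * 136.0   # multiple of TR: fixed phase
        ttl = _pulse_train(onsets, t1=onsets[-1] + 90.0)
        sched = run_scan(ttl, ScanParams(n_phase_encodes=29))
        js = trigger_jitter_stats(sched, ttl, tr=4.0)
        assert np.ptp(js.delays) == pytest.approx(0.0)


class TestCcrtAndDg:
    def _beats(self, rr=134.0, n=200, start=100.0):
        return start + np.arange(n) * rr

    def test_ccrt_inter_block_gap_is_rr_minus_block(self):
        onsets = self._beats()
        ttl = _pulse_train(onsets)
        acq = _always_high(ttl.t1)
        params = ScanParams(n_phase_encodes=20, mode="cCRT")
        sched = run_scan_ccrt(ttl, acq, params)
        trig = np.array([b.trigger_time for b in sched.blocks])
        gaps = trig[1:] - (trig[:-1] + params.cine_block_duration)
        np.testing.assert_allclose(gaps, 134.0 - params.cine_block_duration)

    def test_ccrt_suspends_during_breath(self):
        onsets = self._beats(n=40)
        ttl = _pulse_train(onsets)
        # breath spanning beats 5..7
        breath = (onsets[4] - 10, onsets[7] - 10)
        acq = TTLSignal.from_intervals([(0, breath[0]), (breath[1], ttl.t1)],
                                       0, ttl.t1)
        sched = run_scan_ccrt(ttl, acq, ScanParams(n_phase_encodes=10, mode="cCRT"))
        rf = sched.rf_pulse_times
        assert not np.any((rf >= breath[0]) & (rf < breath[1]))

    def test_ccrt_rf_gaps_show_mixed_tr(self):
        onsets = self._beats()
        ttl = _pulse_train(onsets)
        sched = run_scan_ccrt(ttl, _always_high(ttl.t1),
                              ScanParams(n_phase_encodes=20, mode="cCRT"))
        gaps = np.unique(np.round(np.diff(sched.rf_pulse_times), 9))
        assert gaps.size >= 2   # intra-block TR and the inter-block wait

    def test_dg_no_hiatus_when_rr_equals_block(self):
        onsets = self._beats(rr=80.0, n=100)
        ttl = _pulse_train(onsets, width=16.0)
        sched = run_scan_dg(ttl, ScanParams(n_phase_encodes=50, mode="DG"))
        np.testing.assert_allclose(np.diff(sched.rf_pulse_times), 4.0)

    def test_dg_hiatus_is_rr_minus_block(self):
        onsets = self._beats()
        ttl = _pulse_train(onsets)
        params = ScanParams(n_phase_encodes=20, mode="DG")
        sched = run_scan_dg(ttl, params)
        trig = np.array([b.trigger_time for b in sched.blocks])
        hiatus = trig[1:] - (trig[:-1] + params.cine_block_duration)
        np.testing.assert_allclose(hiatus, 54.0)

    def test_dg_missed_trigger_doubles_hiatus(self):
        onsets = np.delete(self._beats(n=40), 10)   # one missed beat
        ttl = _pulse_train(onsets)
        params = ScanParams(n_phase_encodes=30, mode="DG")
        sched = run_scan_dg(ttl, params)
        trig = np.array([b.trigger_time for b in sched.blocks])
        hiatus = trig[1:] - (trig[:-1] + params.cine_block_duration)
        assert np.isclose(hiatus, 2 * 134.0 - 80.0).sum() == 1

    def test_dg_rf_continues_during_breath_but_data_discarded(self):
        onsets = self._beats(n=60)
        ttl = _pulse_train(onsets)
        breath = (onsets[9] - 10, onsets[12] - 10)
        acq = TTLSignal.from_intervals([(0, breath[0]), (breath[1], ttl.t1)],
                                       0, ttl.t1)
        sched = run_scan_dg(ttl, ScanParams(n_phase_encodes=20, mode="DG"),
                            resp_acquire_ttl=acq)
        rf = sched.rf_pulse_times
        assert np.any((rf >= breath[0]) & (rf < breath[1]))   # RF during breath
        trig = [b.trigger_time for b in sched.blocks]
        assert not any(breath[0] <= t < breath[1] for t in trig)  # no data kept


class TestSummaryAndLocaliser:
    def test_degenerate_scan_time_arithmetic(self):
        """128 encodes at one block per 134 ms beat -> ~17.2 s."""
        onsets = 134.0 * np.arange(1, 140)
        sched = run_scan(_pulse_train(onsets), ScanParams())
        s = scan_time_summary(sched)
        assert s["breaths_declared"] == 0
        assert s["total_duration_ms"] == pytest.approx(128 * 134.0, rel=0.01)

    def test_summary_on_incomplete_schedule_raises(self):
        onsets = 134.0 * np.arange(1, 10)
        with pytest.raises(ScanTimeoutError):
            run_scan(_pulse_train(onsets), ScanParams(n_phase_encodes=50))

    def test_centre_out_ordering(self):
        order = centre_out_order(8)
        assert order[0] == 4
        assert sorted(order) == list(range(8))
        dist = [abs(i - 4) for i in order]
        assert dist == sorted(dist)

    def test_localiser_acquires_segments_per_trigger(self):
        onsets = 134.0 * np.arange(1, 40)
        params = ScanParams(n_phase_encodes=16, localiser_segments=4)
        sched = run_localiser(_pulse_train(onsets), params)
        assert sorted(b.phase_encode_index for b in sched.blocks) == list(range(16))
        first_four = [b.phase_encode_index for b in sched.blocks[:4]]
        assert first_four == centre_out_order(16)[:4]
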