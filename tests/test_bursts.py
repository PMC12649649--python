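"""Burst/burstlet detectors validated against exhaustive brute-force oracles."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from respicpg import bursts as ba
from respicpg.fixtures import planted_burst_raster, planted_latency_raster
from respicpg.raster import SpikeRaster


from helpers import brute_force_bursts


class TestNeuronBursts:
    def test_forced_examples(self):
        out = ba.detect_neuron_bursts(np.array([0.0, 30.0, 60.0, 500.0]), 3, 40.0)
        assert [(b.onset, b.offset, b.n_spikes) for b in out] == [(0.0, 60.0, 3)]
        assert ba.detect_neuron_bursts(np.array([0.0, 50.0, 100.0]), 3, 40.0) == []

    def test_unsorted_rejected(self):
        with pytest.raises(ValueError):
            ba.detect_neuron_bursts(np.array([10.0, 5.0]), 2, 40.0)

    @given(st.lists(st.floats(0, 2000), min_size=0, max_size=40),
           st.integers(2, 4), st.floats(5.0, 120.0))
    @settings(max_examples=300, deadline=None)
    def test_matches_exhaustive_enumeration(self, times, min_spikes, isi_max):
        train = np.unique(np.round(times, 3))
        ours = [(b.onset, b.offset, b.n_spikes)
                for b in ba.detect_neuron_bursts(train, min_spikes, isi_max)]
        assert ours == brute_force_bursts(train, min_spikes, isi_max)

    @given(st.lists(st.floats(0, 1000), min_size=5, max_size=30))
    @settings(max_examples=100, deadline=None)
    def test_relaxing_isi_never_loses_bursts(self, times):
        train = np.unique(np.round(times, 3))
        tight = ba.detect_neuron_bursts(train, 3, 30.0)
        loose = ba.detect_neuron_bursts(train, 3, 60.0)
        assert sum(b.n_spikes for b in loose) >= sum(b.n_spikes for b in tight)
        assert len({b.onset for b in loose}) >= 0  # sanity: no exception


def _single_window_raster(n=10, t0=1000.0, duration=5000.0):
    ids = np.repeat(np.arange(n), 4)
    times = np.concatenate([t0 + 5 * i + 20.0 * np.arange(4) for i in range(n)])
    return SpikeRaster(neuron_ids=ids, times=times,
                       population=np.array(["rhythm"] * n), duration=duration)


class TestPopulationEvents:
    def test_full_participation_single_burst(self):
        ras = _single_window_raster()
        events = ba.classify_population_events(ras, ba.BurstCriteria.rhythm_defaults())
        assert len(events) == 1
        assert events[0].is_burst
        assert events[0].participation == 1.0
        assert events[0].onset == 1000.0

    def test_partial_participation_is_burstlet(self):
        n = 10
        ids = np.repeat(np.arange(3), 4)
        times = np.concatenate([1000.0 + 5 * i + 20.0 * np.arange(4)
                                for i in range(3)])
        ras = SpikeRaster(neuron_ids=ids, times=times,
                          population=np.array(["rhythm"] * n), duration=5000.0)
        events = ba.classify_population_events(ras, ba.BurstCriteria.rhythm_defaults())
        assert len(events) == 1
        assert not events[0].is_burst
        assert events[0].participation == pytest.approx(0.3)

    def test_burstlet_vetoed_by_pattern_activation(self):
        n = 10
        ids = np.repeat(np.arange(3), 4)
        times = np.concatenate([1000.0 + 5 * i + 20.0 * np.arange(4)
                                for i in range(3)])
        ras = SpikeRaster(neuron_ids=ids, times=times,
                          population=np.array(["rhythm"] * n), duration=5000.0)
        veto = [ba.PopulationEvent(population="pattern", kind="burst",
                                   onset=1100.0, offset=1400.0,
                                   participation=1.0, members=np.arange(5))]
        events = ba.classify_population_events(
            ras, ba.BurstCriteria.rhythm_defaults(), veto_events=veto)
        assert events == []

    def test_planted_fixture_recovered_exactly(self):
        ras = planted_burst_raster(seed=3)
        events = ba.classify_population_events(ras, ba.BurstCriteria.rhythm_defaults())
        n_bursts = sum(1 for e in events if e.is_burst)
        n_burstlets = sum(1 for e in events if not e.is_burst)
        assert n_bursts == ras.meta["planted_bursts"]
        assert n_burstlets == ras.meta["planted_burstlets"]

    def test_events_disjoint_and_participation_bounded(self):
        ras = planted_burst_raster(seed=11, burstlet_fraction=0.25)
        events = ba.classify_population_events(ras, ba.BurstCriteria.rhythm_defaults())
        for e in events:
            assert 0.0 <= e.participation <= 1.0
            assert e.onset <= e.offset
        spans = sorted((e.onset, e.offset) for e in events)
        for (a1, b1), (a2, b2) in zip(spans, spans[1:]):
            assert b1 <= a2

    def test_translation_invariance(self):
        ras = planted_burst_raster(seed=5)
        shifted = ras.shifted(730.0)
        ev0 = ba.classify_population_events(ras, ba.BurstCriteria.rhythm_defaults())
        ev1 = ba.classify_population_events(shifted,
                                            ba.BurstCriteria.rhythm_defaults())
        # window grid anchoring may merge differently in pathological cases,
        # but planted events are isolated: onsets must shift exactly
        assert len(ev0) == len(ev1)
        for a, b in zip(ev0, ev1):
            assert b.onset == pytest.approx(a.onset + 730.0, abs=1e-9)
            assert b.kind == a.kind


class TestRates:
    def test_uniform_isi_rates(self):
        ras = _single_window_raster()
        [event] = ba.classify_population_events(ras,
                                                ba.BurstCriteria.rhythm_defaults())
        assert event.mean_intraburst_rate == pytest.approx(50.0)
        assert ba.intraburst_frequency(event, ras) == pytest.approx(50.0)

    def test_pattern_like_isi(self):
        n = 5
        ids = np.repeat(np.arange(n), 3)
        times = np.concatenate([500.0 + 45.45 * np.arange(3) for _ in range(n)])
        ras = SpikeRaster(neuron_ids=ids, times=times,
                          population=np.array(["pattern"] * n), duration=3000.0)
        [event] = ba.classify_population_events(
            ras, ba.BurstCriteria.pattern_defaults())
        assert event.mean_intraburst_rate == pytest.approx(22.0, abs=0.05)

    def test_interburst_frequency_from_onsets(self):
        evs = [ba.PopulationEvent("rhythm", "burst", t, t + 300.0, 1.0,
                                  np.arange(3)) for t in (0.0, 4000.0, 9000.0)]
        f = ba.interburst_frequency(evs)
        assert f == pytest.approx(np.mean([1000 / 4000, 1000 / 5000]))

    def test_undefined_statistic_raises(self):
        ev = ba.PopulationEvent("rhythm", "burst", 0.0, 1.0, 1.0,
                                np.array([0]), {0: (0.0, 0.0)})
        ras = SpikeRaster(neuron_ids=np.array([0]), times=np.array([0.0]),
                          population=np.array(["rhythm"]), duration=10.0)
        with pytest.raises(ValueError):
            ba.intraburst_frequency(ev, ras)


class TestSlidingParticipation:
    def test_empty_raster_all_zero(self):
        ras = SpikeRaster(neuron_ids=np.empty(0, int), times=np.empty(0),
                          population=np.array(["rhythm"] * 4), duration=1000.0)
        _, frac = ba.sliding_participation(ras, 20.0, 10.0)
        assert np.all(frac == 0)

    def test_single_window_peak(self):
        n = 8
        ras = SpikeRaster(neuron_ids=np.arange(n),
                          times=np.full(n, 500.0) + np.arange(n) * 0.5,
                          population=np.array(["rhythm"] * n), duration=1000.0)
        starts, frac = ba.sliding_participation(ras, 20.0, 10.0)
        assert frac.max() == 1.0
        assert frac[0] == 0.0 and frac[-1] == 0.0

    @given(st.lists(st.tuples(st.integers(0, 9), st.floats(0, 900)),
                    min_size=0, max_size=60),
           st.sampled_from([(20.0, 10.0), (50.0, 25.0), (40.0, 40.0)]))
    @settings(max_examples=150, deadline=None)
    def test_matches_per_window_counting(self, spikes, ws):
        window, step = ws
        n = 10
        ids = np.array([s[0] for s in spikes], dtype=int)
        times = np.round([s[1] for s in spikes], 3)
        ras = SpikeRaster(neuron_ids=ids, times=np.array(times, dtype=float),
                          population=np.array(["rhythm"] * n), duration=1000.0)
        starts, frac = ba.sliding_participation(ras, window, step)
        for t0, f in zip(starts, frac):
            active = {i for i, t in zip(ids, times) if t0 <= t < t0 + window}
            assert f == pytest.approx(len(active) / n)


class TestSynchronizationTime:
    def test_constructed_buildup_duration(self):
        """10% of neurons active from exactly 300 ms before a full burst."""
        n = 20
        ids, times = [], []
        # neurons 0-3 tick at 40 ms ISI (no burst), staggered by 10 ms, so
        # every 20 ms sliding window holds 2 of 20 active neurons (10%)
        for i in range(4):
            for t in np.arange(700.0 + 10.0 * i, 1000.0, 40.0):
                ids.append(i)
                times.append(t)
        # neurons 4-19 produce a full burst at t=1000 (16/20 = 80%)
        for i in range(4, n):
            for k in range(4):
                ids.append(i)
                times.append(1000.0 + 3 * (i - 4) + 20.0 * k)
        ras = SpikeRaster(neuron_ids=np.array(ids), times=np.array(times),
                          population=np.array(["rhythm"] * n), duration=3000.0)
        durations = ba.rhythm_synchronization_time(
            ras, ba.BurstCriteria.rhythm_defaults(full_participation=0.8))
        assert len(durations) == 1
        assert durations[0] == pytest.approx(300.0, abs=10.0)

    def test_translation_leaves_durations_unchanged(self):
        ras = planted_burst_raster(seed=9, burstlet_onsets=())
        d0 = ba.rhythm_synchronization_time(ras, ba.BurstCriteria.rhythm_defaults())
        d1 = ba.rhythm_synchronization_time(ras.shifted(500.0),
                                            ba.BurstCriteria.rhythm_defaults())
        assert d1 == pytest.approx(d0, abs=1e-9)

    def test_no_bursts_empty_list(self):
        ras = SpikeRaster(neuron_ids=np.empty(0, int), times=np.empty(0),
                          population=np.array(["rhythm"] * 5), duration=1000.0)
        assert ba.rhythm_synchronization_time(
            ras, ba.BurstCriteria.rhythm_defaults()) == []


class TestOnsetLatency:
    def test_simple_pairing(self):
        r = [ba.PopulationEvent("rhythm", "burst", 1000.0, 1300.0, 1.0, np.arange(2))]
        p = [ba.PopulationEvent("pattern", "burst", 1040.0, 1400.0, 1.0, np.arange(2))]
        [pair] = ba.burst_onset_latency(r, p)
        assert pair.latency == pytest.approx(40.0)
        assert not pair.propagation_failure

    def test_missing_pattern_flags_failure(self):
        r = [ba.PopulationEvent("rhythm", "burst", 1000.0, 1300.0, 1.0, np.arange(2))]
        [pair] = ba.burst_onset_latency(r, [], lookahead=500.0)
        assert pair.propagation_failure
        assert math.isnan(pair.latency)

    def test_planted_latency_recovered(self):
        ras = planted_latency_raster(latency=40.0, seed=2)
        ev_r = ba.classify_population_events(ras.select("rhythm"),
                                             ba.BurstCriteria.rhythm_defaults())
        ev_p = ba.classify_population_events(ras.select("pattern"),
                                             ba.BurstCriteria.pattern_defaults())
        pairs = ba.burst_onset_latency(ev_r, ev_p)
        assert len(pairs) == ras.meta["planted_bursts"]
        for pair in pairs:
            assert not pair.propagation_failure
            assert pair.latency == pytest.approx(40.0, abs=1e-6)
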