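"""Burst and burstlet detection in spike rasters.

Definitions follow the interspike-interval conventions of the respiratory
rhythmogenesis literature:

* a *neuron burst* is a maximal run of at least ``min_spikes`` consecutive
  spikes whose ISIs are all below ``isi_max`` (3 spikes / 40 ms for rhythm
  neurons, 2 spikes / 100 ms for pattern neurons);
* a *population burst* is a window (default 250 ms) in which at least
  ``full_participation`` of the population exhibits a neuron burst;
* a *burstlet* is a partial synchronization: a window in which a non-zero
  fraction below ``burstlet_max_participation`` (default 40%) bursts, and the
  downstream pattern population produces no output.

Windows are scanned on a fixed grid with step = window / 5 and overlapping
qualifying windows are merged into maximal events; an event's onset is the
earliest member-burst onset inside the merged span.  Intra-burst firing
frequency is the mean of 1/ISI over all member intra-burst intervals.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .raster import SpikeRaster

__all__ = [
    "BurstCriteria",
    "NeuronBurst",
    "PopulationEvent",
    "detect_neuron_bursts",
    "classify_population_events",
    "interburst_frequency",
    "intraburst_frequency",
    "sliding_participation",
    "rhythm_synchronization_time",
    "burst_onset_latency",
    "PairedOnset",
]


@dataclass(frozen=True)
class BurstCriteria:
    """Thresholds of the burst/burstlet classification."""

    min_spikes: int = 3
    isi_max: float = 40.0                 # ms
    window: float = 250.0                 # ms, population window
    full_participation: float = 1.0
    burstlet_max_participation: float = 0.40
    sliding_window: float = 20.0          # ms
    sliding_step: float = 10.0            # ms
    sync_onset_fraction: float = 0.10

    def __post_init__(self) -> None:
        if not 0 < self.burstlet_max_participation < self.full_participation <= 1:
            raise ValueError(
                "need 0 < burstlet_max_participation < full_participation <= 1")
        if self.isi_max <= 0:
            raise ValueError("isi_max must be positive")
        if self.min_spikes < 2:
            raise ValueError("a burst needs at least two spikes")
        if not self.sliding_window >= self.sliding_step > 0:
            raise ValueError("need sliding_window >= sliding_step > 0")

    @classmethod
    def rhythm_defaults(cls, **overrides) -> "BurstCriteria":
        base = dict(min_spikes=3, isi_max=40.0, sliding_window=20.0)
        base.update(overrides)
        return cls(**base)

    @classmethod
    def pattern_defaults(cls, **overrides) -> "BurstCriteria":
        base = dict(min_spikes=2, isi_max=100.0, sliding_window=50.0)
        base.update(overrides)
        return cls(**base)


@dataclass(frozen=True)
class NeuronBurst:
    onset: float
    offset: float
    n_spikes: int


def detect_neuron_bursts(train: np.ndarray, min_spikes: int = 3,
                         isi_max: float = 40.0) -> list[NeuronBurst]:
    """Maximal runs of >= ``min_spikes`` consecutive spikes with ISI < ``isi_max``.

    ``train`` must be sorted ascending.  Returned bursts are non-overlapping
    and ordered.
    """
    t = np.asarray(train, dtype=float)
    if t.size and np.any(np.diff(t) < 0):
        raise ValueError("spike train must be sorted ascending")
    if t.size < min_spikes:
        return []
    close = np.diff(t) < isi_max
    bursts: list[NeuronBurst] = []
    run_start = 0
    for i in range(close.size + 1):
        if i == close.size or not close[i]:
            run_len = i - run_start + 1  # spikes in the run ending at index i
            if run_len >= min_spikes:
                bursts.append(NeuronBurst(float(t[run_start]), float(t[i]), run_len))
            run_start = i + 1
    return bursts


@dataclass
class PopulationEvent:
    """A merged population-level synchronization event."""

    population: str
    kind: str                      # "burst" | "burstlet"
    onset: float
    offset: float
    participation: float
    members: np.ndarray = field(repr=False)
    member_bursts: dict[int, tuple[float, float]] = field(repr=False, default_factory=dict)
    mean_intraburst_rate: float = math.nan

    @property
    def is_burst(self) -> bool:
        return self.kind == "burst"


def _merge_window_runs(starts: np.ndarray, qualifying: np.ndarray,
                       window: float) -> list[tuple[float, float]]:
    """Spans of maximal runs of overlapping qualifying windows."""
    spans: list[tuple[float, float]] = []
    run_start = None
    prev_end = None
    for s, ok in zip(starts, qualifying):
        if ok:
            if run_start is None or s > prev_end:
                if run_start is not None:
                    spans.append((run_start, prev_end))
                run_start = s
            prev_end = s + window
        # non-qualifying windows do not break a run unless the gap exceeds
        # the window overlap; handled by the s > prev_end test above
    if run_start is not None:
        spans.append((run_start, prev_end))
    return spans


def _event_from_span(raster: SpikeRaster, trains: list[np.ndarray],
                     all_bursts: list[list[NeuronBurst]],
                     span: tuple[float, float], kind: str) -> PopulationEvent:
    lo, hi = span
    members = []
    member_bursts: dict[int, tuple[float, float]] = {}
    inv_isis: list[float] = []
    for i, bursts in enumerate(all_bursts):
        hit = [b for b in bursts if lo <= b.onset < hi]
        if not hit:
            continue
        members.append(i)
        onset = min(b.onset for b in hit)
        offset = max(b.offset for b in hit)
        member_bursts[i] = (onset, offset)
        t = trains[i]
        inside = t[(t >= onset) & (t <= offset)]
        isis = np.diff(inside)
        inv_isis.extend(1000.0 / isis[isis > 0])
    onset = min(b[0] for b in member_bursts.values())
    offset = max(b[1] for b in member_bursts.values())
    return PopulationEvent(
        population=str(raster.population[0]) if raster.n_neurons else "",
        kind=kind,
        onset=onset,
        offset=offset,
        participation=len(members) / raster.n_neurons,
        members=np.array(members, dtype=np.int64),
        member_bursts=member_bursts,
        mean_intraburst_rate=float(np.mean(inv_isis)) if inv_isis else math.nan,
    )


def classify_population_events(
    raster: SpikeRaster,
    criteria: BurstCriteria,
    veto_events: list[PopulationEvent] | None = None,
) -> list[PopulationEvent]:
    """Population bursts and burstlets of a single-population raster.

    ``veto_events`` (typically the pattern population's bursts) suppress
    burstlet classification for candidate spans that did in fact recruit the
    downstream population.
    """
    n = raster.n_neurons
    if n == 0:
        return []
    trains = raster.spike_trains()
    all_bursts = [detect_neuron_bursts(t, criteria.min_spikes, criteria.isi_max)
                  for t in trains]
    onsets_per_neuron = [np.array([b.onset for b in bl]) for bl in all_bursts]

    step = criteria.window / 5.0
    if raster.duration <= 0:
        return []
    starts = np.arange(0.0, max(raster.duration - criteria.window, 0.0) + step,
                       step)
    frac = np.zeros(starts.size)
    for ons in onsets_per_neuron:
        if ons.size == 0:
            continue
        lo = np.searchsorted(ons, starts, side="left")
        hi = np.searchsorted(ons, starts + criteria.window, side="left")
        frac += (hi > lo)
    frac /= n

    events: list[PopulationEvent] = []
    burst_spans = _merge_window_runs(starts, frac >= criteria.full_participation,
                                     criteria.window)
    for span in burst_spans:
        events.append(_event_from_span(raster, trains, all_bursts, span, "burst"))

    is_candidate = (frac > 0) & (frac < criteria.burstlet_max_participation)
    for lo, hi in burst_spans:
        is_candidate &= ~((starts + criteria.window > lo) & (starts < hi))
    burstlet_spans = _merge_window_runs(starts, is_candidate, criteria.window)
    for span in burstlet_spans:
        ev = _event_from_span(raster, trains, all_bursts, span, "burstlet")
        if any(b.is_burst and b.onset < ev.offset and b.offset > ev.onset
               for b in events):
            continue
        if veto_events and any(
                v.onset <= ev.offset + 500.0 and v.offset >= ev.onset
                for v in veto_events):
            continue
        events.append(ev)
    events.sort(key=lambda e: e.onset)
    return events


def interburst_frequency(events: list[PopulationEvent]) -> float:
    """Mean inverse interval between consecutive burst onsets, in Hz."""
    onsets = np.array([e.onset for e in events if e.is_burst])
    if onsets.size < 2:
        return math.nan
    return float(np.mean(1000.0 / np.diff(np.sort(onsets))))


def intraburst_frequency(event: PopulationEvent, raster: SpikeRaster) -> float:
    """Mean of 1/ISI (Hz) over all member intra-burst intervals of one event."""
    trains = raster.spike_trains()
    inv: list[float] = []
    for i, (onset, offset) in event.member_bursts.items():
        t = trains[i]
        inside = t[(t >= onset) & (t <= offset)]
        isis = np.diff(inside)
        inv.extend(1000.0 / isis[isis > 0])
    if not inv:
        raise ValueError("event has no qualifying intra-burst intervals")
    return float(np.mean(inv))


def sliding_participation(raster: SpikeRaster, window: float,
                          step: float) -> tuple[np.ndarray, np.ndarray]:
    """Fraction of the population with >= 1 spike per sliding window.

    Returns ``(window_starts, fraction)``; windows are ``[t, t + window)`` on
    a fixed grid from zero.
    """
    if not window >= step > 0:
        raise ValueError("need window >= step > 0")
    starts = np.arange(0.0, max(raster.duration - window, 0.0) + step, step)
    frac = np.zeros(starts.size)
    for t in raster.spike_trains():
        if t.size == 0:
            continue
        lo = np.searchsorted(t, starts, side="left")
        hi = np.searchsorted(t, starts + window, side="left")
        frac += (hi > lo)
    return starts, frac / max(raster.n_neurons, 1)


def rhythm_synchronization_time(
    raster: SpikeRaster,
    criteria: BurstCriteria,
    events: list[PopulationEvent] | None = None,
) -> list[float]:
    """Per-burst synchronization build-up durations (ms).

    For each population burst, the time from the onset of the contiguous
    stretch of sliding windows in which at least ``sync_onset_fraction`` of
    neurons are active, back-tracked from the burst onset, to the burst
    onset itself.
    """
    if events is None:
        events = classify_population_events(raster, criteria)
    bursts = [e for e in events if e.is_burst]
    if not bursts:
        return []
    starts, frac = sliding_participation(
        raster, criteria.sliding_window, criteria.sliding_step)
    active = frac >= criteria.sync_onset_fraction
    durations: list[float] = []
    prev_offset = -math.inf
    for ev in bursts:
        i = int(np.searchsorted(starts, ev.onset, side="right")) - 1
        # find the nearest active window at or before the burst onset
        while i >= 0 and not active[i] and starts[i] > prev_offset:
            i -= 1
        if i < 0 or not active[i]:
            durations.append(0.0)
            prev_offset = ev.offset
            continue
        # walk to the start of the contiguous active run
        while i > 0 and active[i - 1] and starts[i - 1] > prev_offset:
            i -= 1
        durations.append(float(ev.onset - starts[i]))
        prev_offset = ev.offset
    return durations


@dataclass(frozen=True)
class PairedOnset:
    """A rhythm burst paired (or not) with the following pattern burst."""

    rhythm_onset: float
    pattern_onset: float | None
    latency: float                # ms; NaN when propagation failed
    propagation_failure: bool


def burst_onset_latency(
    rhythm_events: list[PopulationEvent],
    pattern_events: list[PopulationEvent],
    lookahead: float = 500.0,
) -> list[PairedOnset]:
    """Pair each rhythm burst with the first pattern burst within ``lookahead`` ms.

    Rhythm bursts with no pattern output in the window are flagged as
    propagation failures (burstlet-like events).
    """
    p_onsets = sorted(e.onset for e in pattern_events if e.is_burst)
    pairs: list[PairedOnset] = []
    used = 0
    for ev in sorted((e for e in rhythm_events if e.is_burst), key=lambda e: e.onset):
        while used < len(p_onsets) and p_onsets[used] < ev.onset:
            used += 1
        if used < len(p_onsets) and p_onsets[used] <= ev.onset + lookahead:
            pairs.append(PairedOnset(ev.onset, p_onsets[used],
                                     p_onsets[used] - ev.onset, False))
            used += 1
        else:
            pairs.append(PairedOnset(ev.onset, None, math.nan, True))
    return pairs
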