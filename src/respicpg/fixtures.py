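"""Synthetic rasters with planted, exactly known events.

These generators build spike rasters containing a prescribed number of
population bursts, burstlets and rhythm->pattern onset latencies, so the
burst analyzers can be validated against ground truth.  All rasters are
synthetic constructions, reproducible from a seed; they emulate the *shape*
of network output (tight per-neuron bursts inside a synchronization window),
not its dynamics.
"""

from __future__ import annotations

import numpy as np

from .raster import SpikeRaster

__all__ = ["planted_burst_raster", "planted_latency_raster"]


def planted_burst_raster(
    n_neurons: int = 20,
    duration: float = 20_000.0,
    burst_onsets: tuple[float, ...] = (2_000.0, 8_000.0, 14_000.0),
    burstlet_onsets: tuple[float, ...] = (5_000.0, 11_000.0),
    burstlet_fraction: float = 0.3,
    spikes_per_burst: int = 4,
    isi: float = 20.0,
    jitter: float = 30.0,
    seed: int = 0,
    label: str = "rhythm",
) -> SpikeRaster:
    """Raster with known full bursts and partial burstlets.

    At each burst onset every neuron emits ``spikes_per_burst`` spikes at
    ``isi`` spacing, each neuron's burst delayed by an independent uniform
    jitter < ``jitter`` ms; at each burstlet onset only a ``burstlet_fraction``
    subset does.  Events are detectable with the rhythm criteria
    (>=3 spikes, ISI < 40 ms, 250 ms window) as exactly
    ``len(burst_onsets)`` bursts and ``len(burstlet_onsets)`` burstlets.
    """
    rng = np.random.default_rng(seed)
    ids, times = [], []
    n_sub = max(1, int(round(burstlet_fraction * n_neurons)))
    for onset in burst_onsets:
        starts = onset + rng.uniform(0.0, jitter, size=n_neurons)
        for i, s in enumerate(starts):
            for k in range(spikes_per_burst):
                ids.append(i)
                times.append(s + k * isi)
    for onset in burstlet_onsets:
        subset = rng.choice(n_neurons, size=n_sub, replace=False)
        starts = onset + rng.uniform(0.0, jitter, size=n_sub)
        for i, s in zip(subset, starts):
            for k in range(spikes_per_burst):
                ids.append(int(i))
                times.append(s + k * isi)
    return SpikeRaster(
        neuron_ids=np.array(ids, dtype=np.int64),
        times=np.array(times),
        population=np.array([label] * n_neurons),
        duration=duration,
        seed=seed,
        meta={"planted_bursts": len(burst_onsets),
              "planted_burstlets": len(burstlet_onsets)},
    )


def planted_latency_raster(
    n_rhythm: int = 10,
    n_pattern: int = 30,
    duration: float = 30_000.0,
    burst_onsets: tuple[float, ...] = (3_000.0, 12_000.0, 21_000.0),
    latency: float = 40.0,
    seed: int = 0,
) -> SpikeRaster:
    """Two-population raster where every pattern burst lags rhythm by ``latency`` ms."""
    rng = np.random.default_rng(seed)
    ids, times = [], []
    for onset in burst_onsets:
        r_starts = onset + rng.uniform(0.0, 10.0, size=n_rhythm)
        r_starts[0] = onset  # pin the earliest member onset to the planted value
        for i, s in enumerate(r_starts):
            for k in range(4):
                ids.append(i)
                times.append(s + k * 20.0)
        p_starts = onset + latency + rng.uniform(0.0, 10.0, size=n_pattern)
        p_starts[0] = onset + latency
        for i, s in enumerate(p_starts):
            for k in range(3):
                ids.append(n_rhythm + i)
                times.append(s + k * 45.0)
    population = np.array(["rhythm"] * n_rhythm + ["pattern"] * n_pattern)
    return SpikeRaster(
        neuron_ids=np.array(ids, dtype=np.int64),
        times=np.array(times),
        population=population,
        duration=duration,
        seed=seed,
        meta={"planted_bursts": len(burst_onsets), "planted_latency_ms": latency},
    )
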