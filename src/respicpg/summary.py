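"""Canonical summary statistics of a default-network run.

These are the emergent quantities the model is judged by: population
inter-burst frequency, intra-burst firing rates of both populations, and the
rhythm-to-pattern burst-onset latency.  The analysis conventions (window
sizes, participation thresholds, ISI criteria) are fixed here so that every
entry point — tests, command line, reproduction scripts — computes them the
same way.
"""

from __future__ import annotations

import numpy as np

from .bursts import (
    BurstCriteria,
    burst_onset_latency,
    classify_population_events,
    detect_neuron_bursts,
    interburst_frequency,
)
from .network import PATTERN, RHYTHM
from .raster import SpikeRaster

__all__ = ["network_criteria", "neuron_level_intraburst_hz", "run_statistics"]


def network_criteria() -> dict[str, BurstCriteria]:
    """Population-event criteria used for network-level analysis.

    Rhythm population bursts require 90% participation (full participation in
    principle; 90% absorbs the occasional non-participating neuron), pattern
    bursts 87%, matching the participation levels reported for each
    population.
    """
    return {
        RHYTHM: BurstCriteria.rhythm_defaults(full_participation=0.90),
        PATTERN: BurstCriteria.pattern_defaults(full_participation=0.87),
    }


def neuron_level_intraburst_hz(raster: SpikeRaster, min_spikes: int,
                               isi_max: float) -> float:
    """Mean of 1/ISI (Hz) over all intra-burst ISIs of all neurons."""
    inv: list[np.ndarray] = []
    for train in raster.spike_trains():
        for burst in detect_neuron_bursts(train, min_spikes, isi_max):
            seg = train[(train >= burst.onset) & (train <= burst.offset)]
            inv.append(1000.0 / np.diff(seg))
    if not inv:
        return float("nan")
    return float(np.mean(np.concatenate(inv)))


def run_statistics(raster: SpikeRaster, lookahead: float = 500.0) -> dict:
    """All headline statistics of one two-population simulation."""
    rhythm = raster.select(RHYTHM)
    pattern = raster.select(PATTERN)
    criteria = network_criteria()
    ev_r = classify_population_events(rhythm, criteria[RHYTHM])
    bursts_r = [e for e in ev_r if e.is_burst]
    ev_p = classify_population_events(pattern, criteria[PATTERN],
                                      veto_events=None)
    bursts_p = [e for e in ev_p if e.is_burst]
    pairs = burst_onset_latency(bursts_r, bursts_p, lookahead=lookahead)
    latencies = [p.latency for p in pairs if not p.propagation_failure]
    return {
        "n_rhythm_bursts": len(bursts_r),
        "n_pattern_bursts": len(bursts_p),
        "n_burstlets": sum(1 for e in ev_r if not e.is_burst),
        "interburst_hz": interburst_frequency(ev_r),
        "rhythm_intraburst_hz": neuron_level_intraburst_hz(rhythm, 3, 40.0),
        "pattern_intraburst_hz": neuron_level_intraburst_hz(pattern, 2, 100.0),
        "onset_latency_ms": float(np.mean(latencies)) if latencies else float("nan"),
        "propagation_failures": sum(1 for p in pairs if p.propagation_failure),
        "rhythm_events": ev_r,
        "pattern_events": ev_p,
    }
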