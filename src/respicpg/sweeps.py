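"""Multi-run protocols: seed-variability sweeps.

Stochastic variability enters the model through connectivity realization and
escape-noise spiking, both derived from a master seed.  Repeating the same
configuration under different seeds quantifies how much the emergent rhythm
depends on the particular random realization.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .bursts import (
    BurstCriteria,
    burst_onset_latency,
    classify_population_events,
    interburst_frequency,
)
from .network import PATTERN, RHYTHM, ConnectivitySpec, simulate

__all__ = ["seed_sweep"]


def seed_sweep(
    spec: ConnectivitySpec,
    n_seeds: int,
    duration: float = 60_000.0,
    params_by_population=None,
    base_seed: int = 0,
    rhythm_criteria: BurstCriteria | None = None,
    pattern_criteria: BurstCriteria | None = None,
) -> pd.DataFrame:
    """One simulation per seed; per-seed rhythm statistics.

    Returns a DataFrame with one row per seed: time of the first population
    burst, spread of member onsets within that burst, inter-burst frequency,
    intra-burst rates of both populations and the mean rhythm->pattern onset
    latency.  Pooled statistics are the column means/SDs.
    """
    if n_seeds < 2:
        raise ValueError("a sweep needs at least two seeds")
    rhythm_criteria = rhythm_criteria or BurstCriteria.rhythm_defaults(
        full_participation=0.9)
    pattern_criteria = pattern_criteria or BurstCriteria.pattern_defaults(
        full_participation=0.87)
    rows = []
    for k in range(n_seeds):
        seed = base_seed + k
        raster = simulate(spec, params_by_population, duration=duration, seed=seed)
        rhythm = raster.select(RHYTHM)
        pattern = raster.select(PATTERN)
        ev_r = classify_population_events(rhythm, rhythm_criteria)
        ev_p = classify_population_events(pattern, pattern_criteria)
        bursts_r = [e for e in ev_r if e.is_burst]
        bursts_p = [e for e in ev_p if e.is_burst]
        lats = [p.latency for p in burst_onset_latency(bursts_r, bursts_p)
                if not p.propagation_failure]
        first = bursts_r[0] if bursts_r else None
        rows.append({
            "seed": seed,
            "n_bursts": len(bursts_r),
            "first_burst_ms": first.onset if first else np.nan,
            "first_burst_onset_spread_ms": (
                float(np.ptp([b[0] for b in first.member_bursts.values()]))
                if first else np.nan),
            "interburst_hz": interburst_frequency(ev_r),
            "intraburst_rhythm_hz": (
                float(np.mean([e.mean_intraburst_rate for e in bursts_r]))
                if bursts_r else np.nan),
            "intraburst_pattern_hz": (
                float(np.mean([e.mean_intraburst_rate for e in bursts_p]))
                if bursts_p else np.nan),
            "onset_latency_ms": float(np.mean(lats)) if lats else np.nan,
        })
    return pd.DataFrame(rows)
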