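"""Closed-loop breathing regulation from streamed arterial CO2 readings.

Every controller segment (default 3 s) one PaCO2 sample is converted through
the piecewise chemoreflex map into a commanded respiratory rate; the
chemosensory generator bank is re-programmed to repeat its bursts at that
rate (or silenced below the first threshold), and the network is advanced by
one segment *without resetting any state* — neuron variables, in-flight
synaptic deliveries and the spiking stream all carry over, so the stitched
run is bit-identical to a single continuous simulation with the same
piecewise drive.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .bursts import BurstCriteria, classify_population_events
from .eglif import EGLIFParameters
from .network import RHYTHM, ConnectivitySpec, NetworkSimulation, default_initial_v
from .physiology import ChemoreflexMap, rr_from_paco2
from .raster import SpikeRaster
from .rtn import RTNDriveSpec, make_rtn_trains

__all__ = [
    "SensorSample",
    "LoopRecord",
    "run_closed_loop",
    "generate_sensor_trace",
    "read_sensor_csv",
    "write_sensor_csv",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SensorSample:
    """One PaCO2 reading: time in seconds, pressure in mmHg."""

    t: float
    paco2: float

    def __post_init__(self) -> None:
        if self.paco2 <= 0:
            raise ValueError(f"paco2 must be positive, got {self.paco2}")


@dataclass(frozen=True)
class LoopRecord:
    """Controller log for one segment."""

    t: float                 # s, segment start
    paco2: float             # mmHg
    rr_command: float        # bpm
    rtn_interval: float      # ms between chemosensory bursts
    rtn_silenced: bool
    bursts_in_segment: int


def _segment_values(stream: list[SensorSample], segment_s: float) -> list[float]:
    """Hold-last-value resampling of the stream onto the segment grid."""
    times = [s.t for s in stream]
    if any(b < a for a, b in zip(times, times[1:])):
        raise ValueError("sensor stream times must be non-decreasing")
    n_segments = int(np.floor(times[-1] / segment_s)) + 1
    values = []
    j = 0
    last = stream[0].paco2
    last_t = stream[0].t
    for k in range(n_segments):
        t0 = k * segment_s
        while j < len(stream) and stream[j].t <= t0:
            last = stream[j].paco2
            last_t = stream[j].t
            j += 1
        if t0 - last_t > segment_s:
            logger.warning("sensor gap at t=%.1f s: holding value from t=%.1f s",
                           t0, last_t)
        values.append(last)
    return values


def run_closed_loop(
    spec: ConnectivitySpec,
    drive: RTNDriveSpec,
    cmap: ChemoreflexMap,
    stream: list[SensorSample],
    params_by_population: dict[str, EGLIFParameters] | None = None,
    segment_s: float = 3.0,
    dt: float = 0.1,
    seed: int = 0,
    initial_v: dict[str, float] | None = None,
    criteria: BurstCriteria | None = None,
) -> tuple[SpikeRaster, list[LoopRecord]]:
    """Regulate the network from a PaCO2 stream; one drive update per segment.

    Returns the stitched raster over all segments and one :class:`LoopRecord`
    per segment.  The commanded respiratory rate sets the chemosensory
    burst-repeat interval (60000 / RR ms); below the first chemoreflex
    threshold the drive is silenced and the network free-runs.
    """
    if not stream:
        raise ValueError("sensor stream is empty")
    if segment_s <= 0:
        raise ValueError("segment must be positive")
    if drive.n_generators != spec.n_rtn:
        # the wired generator bank defines how many trains are needed
        drive = replace(drive, n_generators=spec.n_rtn)
    values = _segment_values(stream, segment_s)
    segment_ms = segment_s * 1000.0

    if initial_v is None:
        initial_v = default_initial_v(params_by_population)
    sim = NetworkSimulation(spec, params_by_population, dt=dt, seed=seed,
                            initial_v=initial_v)
    records: list[LoopRecord] = []
    for k, paco2 in enumerate(values):
        command = rr_from_paco2(paco2, cmap)
        t0 = k * segment_ms
        if command.rtn_silenced:
            trains = None
        else:
            seg_drive = replace(
                drive,
                repeat_frequency=command.rr_bpm / 60.0,
                epoch=(t0, t0 + segment_ms),
            )
            trains = make_rtn_trains(seg_drive, t0 + segment_ms)
        sim.advance(segment_ms, external_trains=trains)
        records.append(LoopRecord(
            t=k * segment_s, paco2=paco2, rr_command=command.rr_bpm,
            rtn_interval=command.rtn_interval_ms,
            rtn_silenced=command.rtn_silenced, bursts_in_segment=0,
        ))

    raster = sim.raster()
    criteria = criteria or BurstCriteria.rhythm_defaults(full_participation=0.9)
    events = [e for e in
              classify_population_events(raster.select(RHYTHM), criteria)
              if e.is_burst]
    counted = []
    for k, rec in enumerate(records):
        lo, hi = k * segment_ms, (k + 1) * segment_ms
        n_bursts = sum(1 for e in events if lo <= e.onset < hi)
        counted.append(replace(rec, bursts_in_segment=n_bursts))
    return raster, counted


def generate_sensor_trace(
    duration_s: float,
    paco2_range: tuple[float, float] = (36.8, 61.0),
    step_s: float = 3.0,
    seed: int = 0,
    sigma: float = 1.5,
) -> list[SensorSample]:
    """Synthetic PaCO2 stream: a bounded random walk sampled every ``step_s``.

    Emulates a bloodline CO2 sensor drifting through the configured range;
    reflection keeps every sample inside it.  Reproducible from ``seed``.
    """
    lo, hi = paco2_range
    if not 0 < lo < hi < 200:
        raise ValueError(f"paco2 range must satisfy 0 < lo < hi < 200, got {paco2_range}")
    rng = np.random.default_rng(seed)
    n = int(round(duration_s / step_s))
    x = (lo + hi) / 2.0
    samples = []
    for k in range(n):
        samples.append(SensorSample(t=k * step_s, paco2=round(x, 2)))
        x += rng.normal(0.0, sigma)
        # reflect at the bounds
        if x < lo:
            x = lo + (lo - x)
        if x > hi:
            x = hi - (x - hi)
        x = min(max(x, lo), hi)
    return samples


def write_sensor_csv(samples: list[SensorSample], path) -> None:
    pd.DataFrame(
        {"time_s": [s.t for s in samples], "paco2_mmHg": [s.paco2 for s in samples]}
    ).to_csv(path, index=False)


def read_sensor_csv(path) -> list[SensorSample]:
    df = pd.read_csv(path)
    expected = ["time_s", "paco2_mmHg"]
    if list(df.columns) != expected:
        raise ValueError(f"sensor CSV must have columns {expected}, got {list(df.columns)}")
    return [SensorSample(t=float(r.time_s), paco2=float(r.paco2_mmHg))
            for r in df.itertuples()]
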