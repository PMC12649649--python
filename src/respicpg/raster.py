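"""Spike-raster container and its plain-text interchange format.

A :class:`SpikeRaster` holds every spike of a simulation as flat, time-sorted
arrays plus per-neuron population labels, so both per-neuron spike trains and
population-level views are cheap.  Rasters round-trip losslessly through a
TSV format with a single metadata header line::

    # respicpg raster v1; duration_ms=...; dt_ms=...; seed=...; populations=rhythm:250,pattern:750
    neuron_id<TAB>population<TAB>spike_time_ms

rows sorted by spike time.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["SpikeRaster", "write_raster_tsv", "read_raster_tsv"]

_FORMAT_TAG = "respicpg raster v1"


@dataclass
class SpikeRaster:
    """All spikes of one simulation.

    ``neuron_ids`` and ``times`` are parallel arrays sorted by time;
    ``population`` labels every neuron (including silent ones), so the raster
    knows the full population sizes, not just the neurons that happened to
    fire.
    """

    neuron_ids: np.ndarray
    times: np.ndarray
    population: np.ndarray
    duration: float
    dt: float = 0.1
    seed: int = 0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.neuron_ids = np.asarray(self.neuron_ids, dtype=np.int64)
        self.times = np.asarray(self.times, dtype=np.float64)
        self.population = np.asarray(self.population)
        if self.neuron_ids.shape != self.times.shape:
            raise ValueError("neuron_ids and times must have equal length")
        if self.times.size and np.any(np.diff(self.times) < 0):
            order = np.argsort(self.times, kind="stable")
            self.times = self.times[order]
            self.neuron_ids = self.neuron_ids[order]

    @property
    def n_neurons(self) -> int:
        return int(self.population.shape[0])

    @property
    def n_spikes(self) -> int:
        return int(self.times.shape[0])

    def spike_trains(self) -> list[np.ndarray]:
        """Per-neuron sorted spike-time arrays (empty array for silent neurons)."""
        trains: list[np.ndarray] = [np.empty(0) for _ in range(self.n_neurons)]
        if self.n_spikes == 0:
            return trains
        order = np.lexsort((self.times, self.neuron_ids))
        ids = self.neuron_ids[order]
        ts = self.times[order]
        bounds = np.searchsorted(ids, np.arange(self.n_neurons + 1))
        for i in range(self.n_neurons):
            trains[i] = ts[bounds[i]:bounds[i + 1]]
        return trains

    def select(self, label: str) -> "SpikeRaster":
        """Sub-raster of one population, neuron ids remapped to 0..m-1."""
        keep = np.flatnonzero(self.population == label)
        if keep.size == 0:
            raise KeyError(f"no population named {label!r}")
        remap = -np.ones(self.n_neurons, dtype=np.int64)
        remap[keep] = np.arange(keep.size)
        mask = np.isin(self.neuron_ids, keep)
        return SpikeRaster(
            neuron_ids=remap[self.neuron_ids[mask]],
            times=self.times[mask],
            population=self.population[keep],
            duration=self.duration, dt=self.dt, seed=self.seed,
            meta=dict(self.meta),
        )

    def shifted(self, delta_ms: float) -> "SpikeRaster":
        """Raster with every spike time shifted by ``delta_ms``."""
        return SpikeRaster(
            neuron_ids=self.neuron_ids.copy(), times=self.times + delta_ms,
            population=self.population.copy(),
            duration=self.duration + max(delta_ms, 0.0),
            dt=self.dt, seed=self.seed, meta=dict(self.meta),
        )

    def validate(self, t_ref_by_population: dict[str, float] | None = None) -> None:
        """Check raster invariants; raises ``ValueError`` on the first violation.

        Per-neuron times must be strictly increasing, lie within
        ``[0, duration]`` and, when refractory periods are given, consecutive
        spikes of one neuron must be separated by more than ``t_ref``.
        """
        if self.times.size == 0:
            return
        if self.times.min() < 0 or self.times.max() > self.duration:
            raise ValueError("spike times outside [0, duration]")
        for i, train in enumerate(self.spike_trains()):
            if train.size < 2:
                continue
            isi = np.diff(train)
            if np.any(isi <= 0):
                raise ValueError(f"non-increasing spike times for neuron {i}")
            if t_ref_by_population is not None:
                t_ref = t_ref_by_population.get(str(self.population[i]))
                if t_ref is not None and np.any(isi < t_ref):
                    raise ValueError(f"refractory violation for neuron {i}")


def write_raster_tsv(raster: SpikeRaster, path: str | Path) -> None:
    path = Path(path)
    labels, counts = np.unique(raster.population, return_counts=True)
    # preserve first-appearance order of populations, not lexical order
    seen: dict[str, int] = {}
    for lab in raster.population:
        seen.setdefault(str(lab), 0)
        seen[str(lab)] += 1
    pops = ",".join(f"{k}:{v}" for k, v in seen.items())
    header = (
        f"# {_FORMAT_TAG}; duration_ms={raster.duration:.10g}; "
        f"dt_ms={raster.dt:.10g}; seed={raster.seed}; populations={pops}\n"
    )
    with path.open("w") as fh:
        fh.write(header)
        for nid, t in zip(raster.neuron_ids, raster.times):
            fh.write(f"{nid}\t{raster.population[nid]}\t{t:.10g}\n")


def read_raster_tsv(path: str | Path) -> SpikeRaster:
    path = Path(path)
    with path.open() as fh:
        header = fh.readline().strip()
        if not header.startswith(f"# {_FORMAT_TAG}"):
            raise ValueError(f"{path} is not a {_FORMAT_TAG} file")
        fields = dict(
            item.strip().split("=", 1)
            for item in header.split(";")[1:]
        )
        body = pd.read_csv(
            fh, sep="\t", names=["neuron_id", "population", "spike_time_ms"],
            dtype={"neuron_id": np.int64, "spike_time_ms": np.float64},
        )
    population: list[str] = []
    for chunk in fields["populations"].split(","):
        name, count = chunk.split(":")
        population.extend([name] * int(count))
    return SpikeRaster(
        neuron_ids=body["neuron_id"].to_numpy(),
        times=body["spike_time_ms"].to_numpy(),
        population=np.array(population),
        duration=float(fields["duration_ms"]),
        dt=float(fields["dt_ms"]),
        seed=int(fields["seed"]),
    )
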