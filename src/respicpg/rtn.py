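"""Chemosensory (RTN) drive: deterministic burst-train spike generators.

The retrotrapezoid nucleus is represented not by model neurons but by a bank
of identical spike generators, each emitting short bursts — by default three
spikes at 100 Hz (10 ms spacing) — repeated at a programmable frequency.  The
repeat frequency is the single knob through which blood-gas chemistry
modulates the rhythm-generating network.  Train generation is fully
deterministic: no random stream is consumed.

Only complete repeat periods are emitted: an epoch of length ``L`` at repeat
frequency ``f`` contains ``floor(L * f)`` bursts, with onsets at the start of
each period.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace

import numpy as np

__all__ = ["RTNDriveSpec", "make_rtn_trains", "schedule_frequency_profile"]

#: Connectivity below which chemosensory input no longer reliably reaches
#: the rhythm population.
MIN_RELIABLE_PROJECTION = 0.15


@dataclass(frozen=True)
class RTNDriveSpec:
    """Configuration of the chemosensory generator bank.

    ``repeat_frequency`` is in Hz (0 silences the drive); ``intra_burst_rate``
    in Hz sets the within-burst spike spacing; ``epoch`` bounds the active
    window in ms.  ``projection_p`` / ``projection_weight`` describe the
    Bernoulli projection onto the rhythm population.
    """

    n_generators: int = 120
    spikes_per_burst: int = 3
    intra_burst_rate: float = 100.0
    repeat_frequency: float = 0.0
    epoch: tuple[float, float] = (0.0, math.inf)
    projection_p: float = 0.17
    projection_weight: float = 2.9
    phase_jitter: float = 0.0

    def __post_init__(self) -> None:
        if self.repeat_frequency < 0:
            raise ValueError("repeat_frequency must be >= 0")
        if self.intra_burst_rate <= 0:
            raise ValueError("intra_burst_rate must be positive")
        if self.spikes_per_burst < 1:
            raise ValueError("spikes_per_burst must be >= 1")
        if self.repeat_frequency > 0:
            span_ms = (self.spikes_per_burst - 1) / self.intra_burst_rate * 1000.0
            period_ms = 1000.0 / self.repeat_frequency
            if span_ms >= period_ms:
                raise ValueError(
                    f"burst span {span_ms:g} ms does not fit in the repeat "
                    f"period {period_ms:g} ms"
                )
        if self.projection_p > 0 and self.projection_p < MIN_RELIABLE_PROJECTION:
            warnings.warn(
                f"RTN projection probability {self.projection_p:g} is below "
                f"{MIN_RELIABLE_PROJECTION:g}; chemosensory drive may fail to "
                "entrain the rhythm population",
                stacklevel=3,
            )


def _burst_offsets(spec: RTNDriveSpec) -> np.ndarray:
    spacing_ms = 1000.0 / spec.intra_burst_rate
    return np.arange(spec.spikes_per_burst) * spacing_ms


def make_rtn_trains(spec: RTNDriveSpec, duration: float,
                    rng: np.random.Generator | None = None) -> list[np.ndarray]:
    """Spike-time arrays (ms), one per generator, for a run of ``duration`` ms.

    All generators fire the identical deterministic train unless a non-zero
    ``phase_jitter`` is configured (then each generator's bursts are shifted
    by an independent uniform offset, which requires ``rng``).
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    start = max(0.0, spec.epoch[0])
    end = min(duration, spec.epoch[1])
    if spec.repeat_frequency <= 0 or end <= start:
        return [np.empty(0) for _ in range(spec.n_generators)]
    period_ms = 1000.0 / spec.repeat_frequency
    n_bursts = int(math.floor((end - start) / period_ms))
    onsets = start + np.arange(n_bursts) * period_ms
    base = (onsets[:, None] + _burst_offsets(spec)[None, :]).ravel()
    if spec.phase_jitter > 0:
        if rng is None:
            raise ValueError("phase_jitter > 0 requires an rng")
        shifts = rng.uniform(0.0, spec.phase_jitter, size=spec.n_generators)
    else:
        shifts = np.zeros(spec.n_generators)
    trains = []
    for g in range(spec.n_generators):
        t = base + shifts[g]
        trains.append(t[t < duration])
    return trains


def schedule_frequency_profile(
    spec: RTNDriveSpec,
    segments: list[tuple[float, float, float]],
    duration: float | None = None,
    rng: np.random.Generator | None = None,
) -> list[np.ndarray]:
    """Concatenated trains for a piecewise-constant repeat-frequency profile.

    ``segments`` is an ordered list of ``(start_ms, end_ms, repeat_hz)``;
    each segment restarts its burst phase at its own start.  Segments must
    not overlap.
    """
    for (s0, e0, _), (s1, _, _) in zip(segments, segments[1:]):
        if s1 < e0:
            raise ValueError(f"overlapping segments at {s1:g} ms")
    for s0, e0, f in segments:
        if e0 <= s0:
            raise ValueError(f"empty segment ({s0:g}, {e0:g})")
    total = duration if duration is not None else max((e for _, e, _ in segments), default=0.0)
    parts: list[list[np.ndarray]] = []
    for s0, e0, f in segments:
        seg_spec = replace(spec, repeat_frequency=f, epoch=(s0, e0))
        parts.append(make_rtn_trains(seg_spec, total, rng=rng))
    out = []
    for g in range(spec.n_generators):
        merged = np.concatenate([p[g] for p in parts]) if parts else np.empty(0)
        out.append(np.sort(merged))
    return out
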