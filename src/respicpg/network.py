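"""Two-population rhythm/pattern network: wiring, normalization, simulation.

The circuit is 1000 purely excitatory point neurons: a rhythm-generating
population (250 pre-inspiratory neurons, recurrently connected at 13%) and a
pattern-forming population (750 output-shaping neurons, sparsely connected at
2%), reciprocally coupled at 30%.  An external bank of chemosensory spike
generators projects onto the rhythm population only.  All connections are
drawn independently per ordered pair (pairwise-Bernoulli), carry a fixed
dimensionless efficacy and a conduction delay, and drive the target through
an exponentially decaying current kernel.

The overall excitatory coupling is summarized by the normalization index
``J = sum_i P_i * n_i * w_i`` over projections ``i``, with ``n_i`` counted as
the number of eligible ordered source-target pairs.  Rescaling all efficacies
to hold J fixed preserves rhythmic activity when connection probabilities are
varied.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from . import eglif
from ._kernel import run_steps
from .eglif import EGLIFParameters, affine_propagator
from .raster import SpikeRaster
from .rtn import RTNDriveSpec

__all__ = [
    "Projection",
    "ConnectivitySpec",
    "ConnectionSet",
    "build_connectivity",
    "compute_excitation_index",
    "excitation_index_terms",
    "rescale_weights_to_J",
    "NetworkSimulation",
    "simulate",
    "connectivity_sweep",
    "default_connectivity",
    "default_parameters",
    "default_initial_v",
]

logger = logging.getLogger(__name__)

RHYTHM = "rhythm"
PATTERN = "pattern"
RTN = "rtn"

#: Peak postsynaptic-potential amplitude (mV) per unit dimensionless efficacy,
#: per target population.  The synaptic pulse amplitude on an edge is
#: w * psp_mv * C_target / tau_syn, i.e. a fixed voltage kick independent of
#: the target's capacitance, as for conductance-based synapses.  These are
#: the free coupling constants of the synapse model; the defaults come from
#: the network calibration (see docs/methods.md).
DEFAULT_PSP_MV = {RHYTHM: 0.12, PATTERN: 2.6}


@dataclass(frozen=True)
class Projection:
    """One source->target pathway: connection probability and efficacy."""

    p: float
    weight: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.p <= 1.0:
            raise ValueError(f"connection probability must be in [0, 1], got {self.p}")
        if self.weight < 0:
            raise ValueError(f"weights are excitatory (>= 0), got {self.weight}")


def _default_projections() -> dict[tuple[str, str], Projection]:
    return {
        (RHYTHM, RHYTHM): Projection(0.13, 9.4),
        (RHYTHM, PATTERN): Projection(0.30, 1.0),
        (PATTERN, RHYTHM): Projection(0.30, 0.1),
        (PATTERN, PATTERN): Projection(0.02, 0.5),
        (RTN, RHYTHM): Projection(0.17, 2.9),
    }


@dataclass(frozen=True)
class ConnectivitySpec:
    """Population sizes and per-projection wiring rules."""

    n_rhythm: int = 250
    n_pattern: int = 750
    n_rtn: int = 120
    projections: dict[tuple[str, str], Projection] = field(
        default_factory=_default_projections)
    delay: float = 1.0           # ms, uniform conduction delay
    synapse_tau: float = 20.0    # ms, exponential synaptic-current decay
    allow_autapses: bool = False
    allow_multapses: bool = False
    #: mV voltage kick per unit efficacy; a float applies to every target
    #: population, a dict gives one scale per target population label
    psp_mv: float | dict = field(default_factory=lambda: dict(DEFAULT_PSP_MV))

    def __post_init__(self) -> None:
        if self.n_rhythm + self.n_pattern <= 0:
            raise ValueError("network must contain at least one neuron")
        if self.delay <= 0:
            raise ValueError("delay must be positive")
        if self.synapse_tau <= 0:
            raise ValueError("synapse_tau must be positive")
        for pair in self.projections:
            if pair[0] not in (RHYTHM, PATTERN, RTN) or pair[1] not in (RHYTHM, PATTERN):
                raise ValueError(f"unknown projection {pair}")

    def population_size(self, label: str) -> int:
        return {RHYTHM: self.n_rhythm, PATTERN: self.n_pattern, RTN: self.n_rtn}[label]

    def population_offset(self, label: str) -> int:
        return {RHYTHM: 0, PATTERN: self.n_rhythm,
                RTN: self.n_rhythm + self.n_pattern}[label]

    @property
    def n_neurons(self) -> int:
        return self.n_rhythm + self.n_pattern

    @property
    def n_sources(self) -> int:
        return self.n_neurons + self.n_rtn

    def eligible_pairs(self, src: str, tgt: str) -> int:
        ns, nt = self.population_size(src), self.population_size(tgt)
        pairs = ns * nt
        if src == tgt and not self.allow_autapses:
            pairs -= ns
        return pairs

    def scaled(self, factor: float) -> "ConnectivitySpec":
        """Spec with every population count multiplied by ``factor``."""
        return replace(
            self,
            n_rhythm=round(self.n_rhythm * factor),
            n_pattern=round(self.n_pattern * factor),
            n_rtn=round(self.n_rtn * factor),
        )


@dataclass
class ConnectionSet:
    """Realized edges: parallel arrays of global source/target ids."""

    source: np.ndarray
    target: np.ndarray
    weight: np.ndarray       # dimensionless efficacy
    delay_ms: np.ndarray
    n_sources: int
    n_neurons: int
    edge_counts: dict[tuple[str, str], int]

    @property
    def n_edges(self) -> int:
        return int(self.source.shape[0])

    def to_csr(self) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        """(indptr, targets, weights, delays) grouped by source id."""
        order = np.argsort(self.source, kind="stable")
        src = self.source[order]
        indptr = np.searchsorted(src, np.arange(self.n_sources + 1)).astype(np.int64)
        return (indptr, self.target[order].astype(np.int64),
                self.weight[order].astype(np.float64), self.delay_ms[order])


def build_connectivity(spec: ConnectivitySpec,
                       rng: np.random.Generator) -> ConnectionSet:
    """Draw every eligible ordered pair independently with its projection's p."""
    srcs, tgts, ws = [], [], []
    counts: dict[tuple[str, str], int] = {}
    for (sp, tp), proj in sorted(spec.projections.items()):
        ns, nt = spec.population_size(sp), spec.population_size(tp)
        if ns == 0 or nt == 0 or proj.p == 0.0:
            counts[(sp, tp)] = 0
            continue
        mask = rng.random((ns, nt)) < proj.p
        if sp == tp and not spec.allow_autapses:
            np.fill_diagonal(mask, False)
        si, ti = np.nonzero(mask)
        srcs.append(si + spec.population_offset(sp))
        tgts.append(ti + spec.population_offset(tp))
        ws.append(np.full(si.size, proj.weight))
        counts[(sp, tp)] = int(si.size)
    if srcs:
        source = np.concatenate(srcs).astype(np.int64)
        target = np.concatenate(tgts).astype(np.int64)
        weight = np.concatenate(ws)
    else:
        source = np.empty(0, np.int64)
        target = np.empty(0, np.int64)
        weight = np.empty(0)
    return ConnectionSet(
        source=source, target=target, weight=weight,
        delay_ms=np.full(source.size, spec.delay),
        n_sources=spec.n_sources, n_neurons=spec.n_neurons,
        edge_counts=counts,
    )


#: Convention used by the excitation index: n_i counts eligible ordered
#: source-target pairs (autapses excluded where disallowed), not realized
#: edges.
EXCITATION_INDEX_CONVENTION = "n_i = eligible ordered source-target pairs"


def excitation_index_terms(spec: ConnectivitySpec) -> dict[tuple[str, str], float]:
    """Per-projection terms ``P_i * n_i * w_i`` of the excitation index."""
    return {
        pair: proj.p * spec.eligible_pairs(*pair) * proj.weight
        for pair, proj in spec.projections.items()
    }


def compute_excitation_index(spec: ConnectivitySpec) -> float:
    """Excitation-normalization index J = sum_i P_i * n_i * w_i."""
    return float(sum(excitation_index_terms(spec).values()))


def rescale_weights_to_J(spec: ConnectivitySpec, j_target: float) -> ConnectivitySpec:
    """Spec with all efficacies multiplied so that J equals ``j_target``."""
    j = compute_excitation_index(spec)
    if j <= 0:
        raise ValueError("cannot rescale a spec with zero excitation index")
    factor = j_target / j
    projections = {
        pair: Projection(proj.p, proj.weight * factor)
        for pair, proj in spec.projections.items()
    }
    return replace(spec, projections=projections)


def default_connectivity(**overrides) -> ConnectivitySpec:
    return ConnectivitySpec(**overrides)


def default_parameters() -> dict[str, EGLIFParameters]:
    return {RHYTHM: eglif.rhythm_parameters(), PATTERN: eglif.pattern_parameters()}


def default_initial_v(params: dict[str, EGLIFParameters] | None = None) -> dict[str, float]:
    """Canonical initial membrane potentials: rhythm at -60 mV, pattern at rest."""
    params = params or default_parameters()
    init = {label: p.E_L for label, p in params.items()}
    if RHYTHM in init:
        init[RHYTHM] = -60.0
    return init


class NetworkSimulation:
    """Stateful stepped simulation supporting segmented (carry-over) runs.

    Connectivity is drawn once at construction from the master seed; repeated
    :meth:`advance` calls continue the same trajectory, and a run split into
    segments is bit-identical to an uninterrupted run of the same total
    length (the spiking stream is counter-based on absolute step index).
    """

    def __init__(
        self,
        spec: ConnectivitySpec,
        params_by_population: dict[str, EGLIFParameters] | None = None,
        dt: float = 0.1,
        seed: int = 0,
        initial_v: dict[str, float] | None = None,
    ) -> None:
        if dt <= 0:
            raise ValueError("dt must be positive")
        if spec.delay < dt:
            raise ValueError(f"delay {spec.delay} ms is below the step {dt} ms")
        self.spec = spec
        self.dt = float(dt)
        self.seed = int(seed)
        self.params = dict(params_by_population or default_parameters())
        self._labels = [lab for lab in (RHYTHM, PATTERN)
                        if spec.population_size(lab) > 0]
        missing = [lab for lab in self._labels if lab not in self.params]
        if missing:
            raise ValueError(f"missing parameters for population(s): {missing}")

        delay_steps = spec.delay / dt
        rounded = round(delay_steps)
        if abs(delay_steps - rounded) > 1e-9:
            logger.warning("delay %.4g ms is not a multiple of dt=%.4g ms; "
                           "rounded to %d steps", spec.delay, dt, rounded)
        self._delay_steps = max(1, int(rounded))

        ss = np.random.SeedSequence([self.seed, 0x5250])
        conn_seed, kernel_seed = ss.spawn(2)
        self.connections = build_connectivity(
            spec, np.random.default_rng(conn_seed))
        self._kernel_seed = np.uint64(kernel_seed.generate_state(1, np.uint64)[0])

        n = spec.n_neurons
        self._pop = np.zeros(n, np.int64)
        labels = np.empty(n, dtype=object)
        for idx, lab in enumerate(self._labels):
            off = spec.population_offset(lab)
            size = spec.population_size(lab)
            self._pop[off:off + size] = idx
            labels[off:off + size] = lab
        self.population_labels = labels.astype(str)

        npop = len(self._labels)
        self._A = np.zeros((npop, 4, 4))
        self._b = np.zeros((npop, 4))
        self._Ac = np.zeros((npop, 2, 2))
        self._bc = np.zeros((npop, 2))
        self._es = np.zeros(npop)
        self._lam0 = np.zeros(npop)
        self._tauV = np.zeros(npop)
        self._Vth = np.zeros(npop)
        self._Vr = np.zeros(npop)
        self._A2 = np.zeros(npop)
        self._A1 = np.zeros(npop)
        self._depinc = np.zeros(npop)
        self._tref = np.zeros(npop, np.int64)
        for idx, lab in enumerate(self._labels):
            p = self.params[lab]
            M = np.array([
                [-1.0 / p.tau_m, -1.0 / p.C_m, 1.0 / p.C_m, 1.0 / p.C_m],
                [p.k_adap, -p.k_2, 0.0, 0.0],
                [0.0, 0.0, -p.k_1, 0.0],
                [0.0, 0.0, 0.0, -1.0 / spec.synapse_tau],
            ])
            u = np.array([p.E_L / p.tau_m + (p.I_e + p.I_stim) / p.C_m,
                          -p.k_adap * p.E_L, 0.0, 0.0])
            self._A[idx], self._b[idx] = affine_propagator(M, u, dt)
            Mc = np.array([[-p.k_2, 0.0], [0.0, -p.k_1]])
            uc = np.array([p.k_adap * (p.V_r - p.E_L), 0.0])
            self._Ac[idx], self._bc[idx] = affine_propagator(Mc, uc, dt)
            self._es[idx] = math.exp(-dt / spec.synapse_tau)
            self._lam0[idx] = p.lambda_0
            self._tauV[idx] = p.tau_V
            self._Vth[idx] = p.V_th
            self._Vr[idx] = p.V_r
            self._A2[idx] = p.A_2
            self._A1[idx] = p.A_1
            self._depinc[idx] = 1.0 if p.dep_increment else 0.0
            self._tref[idx] = int(round(p.t_ref / dt))

        init = dict(initial_v or {})
        self.V = np.array([
            init.get(self._labels[self._pop[i]],
                     self.params[self._labels[self._pop[i]]].E_L)
            for i in range(n)
        ])
        # adaptation current starts at its quasi-equilibrium for the initial
        # voltage; a zero start would inject a large artificial transient that
        # fires the whole population synchronously at t=0
        self.I_adap = np.array([
            (lambda p, v: p.k_adap * (v - p.E_L) / p.k_2 if p.k_2 > 0 else 0.0)(
                self.params[self._labels[self._pop[i]]], self.V[i])
            for i in range(n)
        ])
        self.I_dep = np.zeros(n)
        self.I_syn = np.zeros(n)
        self.refrac = np.zeros(n, np.int64)
        self.ring = np.zeros((self._delay_steps + 2, n))

        csr = self.connections.to_csr()
        self._indptr, self._targets, self._cweights, cdelay = csr
        # current-pulse amplitude per edge: fixed voltage kick on the target
        if isinstance(spec.psp_mv, dict):
            kappa = np.array([spec.psp_mv[self._labels[self._pop[t]]]
                              for t in self._targets])
        else:
            kappa = spec.psp_mv
        c_tgt = np.array([self.params[self._labels[self._pop[t]]].C_m
                          for t in self._targets])
        self._cweights = self._cweights * kappa * c_tgt / spec.synapse_tau
        self._cdelays = np.maximum(
            1, np.rint(cdelay / dt).astype(np.int64))

        self._step = 0
        self._spike_steps: list[np.ndarray] = []
        self._spike_ids: list[np.ndarray] = []

    @property
    def time_ms(self) -> float:
        return self._step * self.dt

    def advance(self, duration_ms: float,
                external_trains: list[np.ndarray] | None = None) -> None:
        """Run for ``duration_ms`` more milliseconds, carrying all state.

        ``external_trains`` holds one absolute spike-time array per generator
        in the chemosensory bank; only spikes whose emission step falls in
        this segment are delivered.
        """
        if duration_ms <= 0:
            raise ValueError("duration must be positive")
        n_steps = int(round(duration_ms / self.dt))
        ext_steps, ext_src = self._external_events(external_trains)
        sp_step, sp_id, err = run_steps(
            self._step, n_steps, self.dt,
            self._pop, self._A, self._b, self._Ac, self._bc, self._es,
            self._lam0, self._tauV, self._Vth, self._Vr, self._A2, self._A1,
            self._depinc, self._tref,
            self.V, self.I_adap, self.I_dep, self.I_syn, self.refrac,
            self.ring,
            self._indptr, self._targets, self._cweights, self._cdelays,
            ext_steps, ext_src,
            self._kernel_seed,
        )
        if err >= 0:
            raise FloatingPointError(
                f"non-finite membrane potential at step {err} "
                f"(t = {err * self.dt:.1f} ms)")
        self._spike_steps.append(sp_step)
        self._spike_ids.append(sp_id)
        self._step += n_steps

    def _external_events(self, trains: list[np.ndarray] | None
                         ) -> tuple[np.ndarray, np.ndarray]:
        if not trains:
            return np.empty(0, np.int64), np.empty(0, np.int64)
        if len(trains) != self.spec.n_rtn:
            raise ValueError(
                f"expected {self.spec.n_rtn} external trains, got {len(trains)}")
        off = self.spec.population_offset(RTN)
        steps, srcs = [], []
        for g, t in enumerate(trains):
            if len(t) == 0:
                continue
            s = np.rint(np.asarray(t) / self.dt).astype(np.int64)
            steps.append(s)
            srcs.append(np.full(s.size, off + g, np.int64))
        if not steps:
            return np.empty(0, np.int64), np.empty(0, np.int64)
        steps = np.concatenate(steps)
        srcs = np.concatenate(srcs)
        order = np.argsort(steps, kind="stable")
        return steps[order], srcs[order]

    def raster(self) -> SpikeRaster:
        """Raster of everything simulated so far."""
        if self._spike_steps:
            steps = np.concatenate(self._spike_steps)
            ids = np.concatenate(self._spike_ids)
        else:
            steps = np.empty(0, np.int64)
            ids = np.empty(0, np.int64)
        return SpikeRaster(
            neuron_ids=ids,
            times=(steps + 1) * self.dt,
            population=self.population_labels,
            duration=self.time_ms,
            dt=self.dt,
            seed=self.seed,
            meta={"psp_mv": str(self.spec.psp_mv),
                  "excitation_index": compute_excitation_index(self.spec)},
        )


def simulate(
    spec: ConnectivitySpec,
    params_by_population: dict[str, EGLIFParameters] | None = None,
    duration: float = 120_000.0,
    dt: float = 0.1,
    external_trains: list[np.ndarray] | None = None,
    seed: int = 0,
    initial_v: dict[str, float] | None = None,
) -> SpikeRaster:
    """One-shot simulation: build, run ``duration`` ms, return the raster.

    Reproducible bit-for-bit from ``(seed, spec, params)``.  ``initial_v``
    defaults to the canonical initial conditions (rhythm at -60 mV, pattern
    at its resting potential).
    """
    params = params_by_population or default_parameters()
    if initial_v is None:
        initial_v = default_initial_v(params)
    sim = NetworkSimulation(spec, params, dt=dt, seed=seed, initial_v=initial_v)
    sim.advance(duration, external_trains=external_trains)
    return sim.raster()


def connectivity_sweep(
    spec: ConnectivitySpec,
    p_rr_values: list[float],
    duration: float = 60_000.0,
    seed: int = 0,
    params_by_population: dict[str, EGLIFParameters] | None = None,
    criteria=None,
):
    """Vary the rhythm-rhythm connection probability and summarize each run.

    Returns a DataFrame with one row per probability: realized edge count,
    detected population-burst count, mean inter-burst frequency and mean
    firing rate of the rhythm population.
    """
    import pandas as pd

    from .bursts import BurstCriteria, classify_population_events, interburst_frequency

    criteria = criteria or BurstCriteria.rhythm_defaults()
    rows = []
    for p_rr in p_rr_values:
        if not 0.0 <= p_rr <= 1.0:
            raise ValueError(f"p_rr must be in [0, 1], got {p_rr}")
        proj = dict(spec.projections)
        proj[(RHYTHM, RHYTHM)] = Projection(p_rr, proj[(RHYTHM, RHYTHM)].weight)
        sw_spec = replace(spec, projections=proj)
        raster = simulate(sw_spec, params_by_population, duration=duration, seed=seed)
        rhythm = raster.select(RHYTHM)
        events = [e for e in classify_population_events(rhythm, criteria)
                  if e.is_burst]
        f_ib = interburst_frequency(events)
        rate = rhythm.n_spikes / rhythm.n_neurons / (duration / 1000.0)
        rows.append({
            "p_rr": p_rr,
            "n_bursts": len(events),
            "interburst_hz": f_ib,
            "mean_rate_hz": rate,
        })
    return pd.DataFrame(rows)
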