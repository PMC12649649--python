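# Methods

## Model overview

The package simulates a reduced respiratory central pattern generator: two
excitatory E-GLIF populations (rhythm-generating and pattern-forming)
representing the PreBötzinger complex, an external chemosensory generator
bank standing in for the retrotrapezoid nucleus (RTN), an acid–base /
ventilation module that converts blood chemistry into drive frequency, and a
closed-loop runtime that updates the drive from PaCO₂ samples every 3 s.

All subthreshold dynamics are linear, so the simulator advances the
four-variable state (V, I_adap, I_dep, I_syn) with the exact matrix
exponential per population and step size; only spike generation, resets and
synaptic delivery are event-like.  The time step is 0.1 ms.

## Single-neuron parameters

Fixed constants (identical in both populations unless noted): escape-rate
scale λ₀ = 10⁻⁴ ms⁻¹, escape widths τ_V = 1.7 mV (rhythm) / 0.9 mV
(pattern), adaptation coupling k_adap = 0.53 pA·mV⁻¹·ms⁻¹ with decay
k₂ = 0.0331 ms⁻¹ (rhythm) / 1/30 ms⁻¹ (pattern), spike-current decay
k₁ = 0.007 ms⁻¹, adaptation increment A₂ = 5 pA, refractory period 2 ms,
initial membrane potential −60 mV (rhythm) / E_L = −70.6 mV (pattern).

The remaining constants are free and set by calibration:

| parameter | rhythm | pattern | role |
|---|---|---|---|
| C_m | 15 500 pF | 111 pF | timescale of the collective dynamics (below) |
| τ_m | 20 000 ms | 30 ms | leak; pattern's satisfies k₂ = 1/τ_m |
| E_L | −65 mV | −70.6 mV | resting anchor |
| V_th | −50 mV | −50 mV | escape-rate reference |
| V_r | −60 mV | −60 mV | reset |
| I_e | from calibration | from calibration | places the rest point |
| A₁ | −1495 pA (accumulating) | −420 pA (accumulating) | slow after-spike suppression |

Two structural choices follow from the two populations' distinct roles:

* **Rhythm population — slow overdamped relaxation.**  With k₂ not tied to
  1/τ_m, a large capacitance with weak leak makes the (V, I_adap) subsystem
  overdamped with a slow mode τ ≈ C_m/(C_m/τ_m + k_adap/k₂) ≈ 0.9 s.  The
  10 mV reset is recovered along this mode, which produces both the ~10 s
  autonomous interspike interval of an unconnected neuron and, collectively,
  the seconds-scale interburst interval.  This was the only arrangement we
  found in which the fixed constants support a seconds-scale rhythm at all:
  with a 30 ms membrane, parameter scans over capacitance, reset, synaptic
  scale and A₁ produced only silent or tonic network states.
* **Pattern population — 22 Hz resonator.**  k₂ = 1/τ_m makes the subsystem
  an underdamped ("non-damping") resonator at √(k_adap/C_m).  C_m = 111 pF
  puts the post-spike half-period swing near 45 ms, pacing the ~22 Hz
  intra-burst rate.

**Spike-triggered current (A₁).**  Whether this current is *set* or
*accumulated* at a spike is ambiguous in the source formulation; the package
supports both (`dep_increment`, default off to match the set-convention
surface).  The calibrated populations use accumulate-mode with negative
amplitude: an integrating after-hyperpolarization with the slowest available
decay (1/k₁ = 143 ms).  This is the burst-terminating mechanism — without an
accumulating slow negative feedback the collective high-firing state has no
way to end, because the adaptation current equilibrates within ~30 ms and
acts proportionally, not integrally.

**Rate calibration.**  I_e is set in closed form so the subthreshold fixed
point sits where λ equals the target 0.1 Hz (λ₀ = 10⁻⁴ ms⁻¹ means rest at
V_th), plus a +0.6 mV empirical correction for the post-spike recovery dead
time; a 50-neuron, 300 s check then measures 0.100 Hz.  The pattern
population rests 38.75 mV below threshold (negative I_e) and is silent until
driven.

## Synapses

Connections are static and excitatory, with an exponential current kernel
(τ_syn = 20 ms) and a 1 ms conduction delay (rounded to whole steps).  The
dimensionless efficacies of the connectivity table are converted to current
pulses as `w · κ · C_target / τ_syn`, i.e. a fixed peak voltage kick of
`w · κ` mV on the target, independent of the target's capacitance — the
behavior of conductance-based synapses.  The two voltage scales are
κ_rhythm = 0.12 mV and κ_pattern = 2.6 mV.  A 20 ms kernel (rather than a
few-ms AMPA-like constant) is required for rhythmogenesis in this model: the
recruitment cascade that builds a population burst is staggered over tens of
milliseconds, and with a 2 ms kernel its inputs never sum, leaving no
bursting regime at any coupling strength.  Slow excitatory components play
the same role in other network-synchronization models of this circuit.

## Mechanism of the emergent rhythm

After a population burst every rhythm neuron is reset and carries an
accumulated after-hyperpolarization; the population recovers together along
the slow membrane mode (~1–3 s).  As it approaches the rest point the
population escape hazard rises; stochastic first spikes kick coupled
neighbors (0.13 × 250 partners × 1.13 mV), and once the recurrent gain
exceeds unity the cascade percolates into a full burst within a few hundred
milliseconds — the measured synchronization build-up.  Inside the burst,
firing self-organizes into ~20 ms cycles (≈50 Hz) set by the balance of
recurrent drive against the per-spike adaptation and A₁ kicks; the
accumulating A₁ current then tips the balance and the burst collapses.  The
pattern population integrates the rhythm population's output and crosses its
deep rest gap tens of milliseconds after burst onset, ringing at its ~22 Hz
resonance; its own A₁ prevents it from locking to every rhythm volley.

## Analysis conventions

Neuron bursts: ≥3 consecutive spikes with ISI < 40 ms (rhythm), ≥2 with
ISI < 100 ms (pattern).  Population events scan 250 ms windows on a fixed
grid with step = window/5 and merge overlapping qualifying windows; an
event's onset is the earliest member-burst onset.  Population bursts require
90% participation for rhythm (nominally all neurons; 90% absorbs stragglers)
and 87% for pattern; burstlets are events with participation below 40% and
no pattern output.  Intra-burst frequency is the mean of 1/ISI over member
intra-burst intervals.  Synchronization build-up uses a 20 ms sliding window
with 10 ms step and a 10% activity threshold; rhythm→pattern latency pairs
each rhythm burst with the first pattern burst within a 500 ms lookahead
(chosen wide relative to the expected 30–55 ms latencies).

## Randomness and reproducibility

A master seed derives independent streams for connectivity and spiking.
Spiking uses a counter-based generator (a splitmix64-style hash of
(seed, step, neuron)), so a run split into segments that carry the neuron
state and delivery buffer is bit-identical to an uninterrupted run — the
property the closed-loop controller is tested against.  All artifacts are
reproducible from (config, seed).

## What the synthetic data emulate — and what they do not

The sensor-trace generator emulates only the statistics of a bloodline PaCO₂
sensor (36.8–61.0 mmHg range, 3 s sampling) as a bounded random walk; it has
no physiological CO₂ kinetics, so closed-loop tests demonstrate correct
control-loop plumbing and chemoreflex mapping, not gas-exchange dynamics.
The planted-event rasters used to validate the burst analyzers reproduce the
shape of network output (jittered per-neuron bursts inside a window), not
its generative dynamics.  Passing tests therefore certify the implementation
and its emergent statistics, not agreement with in-vivo recordings.

## Problem sizes and dispersion

The default analyses use a single 120 s run of the 1000-neuron network
(≈26–28 bursts); multi-run protocols (seed sweeps, connectivity sweeps) use
60 s per run.  Across master seeds the run-level statistics disperse as
roughly: inter-burst frequency 0.23 ± 0.005 Hz, rhythm intra-burst rate
53 ± 3.5 Hz, pattern intra-burst rate 22.5 ± 1.3 Hz, onset latency
42 ± 13 ms.  The latency is the most seed-sensitive quantity: per-burst
latencies cluster around discrete ~20 ms volley modes and the realized
connectivity biases a run toward one mode or another.

## Known limitations

* Burstlets (partial synchronizations) are rare under the calibrated
  defaults — ignition usually percolates fully once started; the burstlet
  classification is exercised mainly through constructed rasters.
* The calibrated capacitances are effective dynamical scales, not
  biophysical membrane capacitances.
* No inhibition, gap junctions, plasticity or spatial structure; the 4000
  neuron scale-up is supported via proportional population scaling with
  J-preserving weight rescale but is not part of the validated surface.
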