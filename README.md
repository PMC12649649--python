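# respicpg

A spiking-network model of the respiratory central pattern generator, built
around the PreBötzinger complex — the brainstem nucleus that generates the
inspiratory rhythm — together with the acid–base physiology that couples
breathing to blood CO₂, and a closed-loop controller that regulates a
simulated breathing rhythm from streamed arterial CO₂ (PaCO₂) readings.

It is aimed at computational neuroscientists and biomedical engineers
studying network-level rhythmogenesis (the "burstlet" view, in which rhythm
emerges from synchronization of non-pacemaker neurons) and biomimetic
respiratory control, e.g. as a candidate controller for ventilation during
ECMO weaning.

## The model

**Neurons.** Both populations use an extended generalized leaky
integrate-and-fire (E-GLIF) point neuron with three linear state variables —
membrane potential *V*, adaptation current *I*<sub>adap</sub>, spike-triggered
current *I*<sub>dep</sub>:

```
C_m dV/dt      = −(C_m/τ_m)(V − E_L) + I_e + I_stim + I_dep − I_adap + I_syn
dI_adap/dt     = k_adap (V − E_L) − k_2 I_adap
dI_dep/dt      = −k_1 I_dep
```

Spiking is stochastic with escape rate λ(V) = λ₀·exp((V − V_th)/τ_V); a spike
resets V to V_r, adds A₂ to the adaptation current, updates the spike current
by A₁ and opens a 2 ms refractory window.  Propagation between spikes uses
the exact matrix exponential of the linear system, so trajectories do not
depend on step refinement.

**Network.** 1000 excitatory neurons: a rhythm-generating population (250,
13% recurrent connectivity, efficacy 9.4) and a pattern-forming population
(750, 2% / 0.5), reciprocally coupled at 30% (efficacies 1.0 and 0.1), wired
by independent per-pair Bernoulli draws.  A bank of 120 chemosensory spike
generators (the RTN drive) projects onto the rhythm population (17% / 2.9),
each emitting bursts of 3 spikes at 100 Hz repeated at a programmable
frequency.  An excitation index J = Σᵢ Pᵢ·nᵢ·wᵢ summarizes total coupling and
supports weight renormalization when connectivities are varied.

**Physiology.** The Henderson–Hasselbalch equation
pH = pK_a + log₁₀([HCO₃⁻]/(α·pCO₂)), alveolar ventilation
V̇_A = 0.863·V̇CO₂/PaCO₂, breaths-per-minute bpm = V̇_A/V_A and the piecewise
chemoreflex RR(PaCO₂) (basal 13 bpm below 44.3 mmHg, slopes 0.7 and
1.5 bpm/mmHg above) convert blood chemistry into the drive frequency.

**Emergent behavior.** With no pacemaker cells and no rhythmic input the
network produces population bursts at ~0.22 Hz (eupneic range) with ~50 Hz
intra-burst firing in the rhythm population, ~22 Hz in the pattern
population, and a rhythm→pattern onset latency of a few tens of ms; a
0.26–0.62 Hz chemosensory drive entrains the rhythm 1:1 and releases it on
offset.

## Worked example

```
$ python examples/emergent_rhythm.py
rhythm population bursts       28
pattern population bursts      28
inter-burst frequency         0.233 Hz
rhythm intra-burst rate        52.9 Hz
pattern intra-burst rate       22.5 Hz
pattern onset latency          34.6 ms
```

That is 120 s of the default 1000-neuron circuit: 28 population bursts
(≈0.23 Hz breathing rhythm), rhythm neurons firing ≈53 Hz inside bursts,
pattern neurons ≈22 Hz, and the motor-output population recruited ≈35 ms
after each rhythm burst begins.  `examples/` also contains single-neuron,
chemoreflex-drive and closed-loop walkthroughs, and the `respicpg` command
line exposes `simulate`, `analyze`, `physiology-table`, `closed-loop`,
`seed-sweep` and `make-fixtures` subcommands.

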