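"""A single rhythm-generating neuron firing autonomously.

Builds one unconnected E-GLIF neuron with the rhythm-population parameters,
simulates 300 s, and prints the autonomous firing rate (calibrated to
~0.1 Hz) together with the slow subthreshold relaxation mode that sets the
seconds-long recovery after each spike.
"""

import numpy as np

from respicpg import eglif, network

params = eglif.rhythm_parameters()
ev = eglif.subthreshold_eigenvalues(params)
slow = max(ev, key=lambda z: z.real)
print(f"rest potential          {eglif.fixed_point(params).V_m:8.2f} mV")
print(f"slow relaxation mode    {-1.0 / slow.real / 1000:8.2f} s")

spec = network.ConnectivitySpec(
    n_rhythm=50, n_pattern=0, n_rtn=0,
    projections={("rhythm", "rhythm"): network.Projection(0.0, 0.0)})
raster = network.simulate(spec, {"rhythm": params}, duration=300_000.0,
                          seed=1, initial_v={"rhythm": -60.0})
rate = raster.n_spikes / 50 / 300.0
print(f"autonomous firing rate  {rate:8.3f} Hz  (50 neurons, 300 s)")
print("Each neuron drifts back to rest over seconds after a spike and then")
print("waits for a stochastic escape: spiking is probabilistic, not a hard")
print("threshold crossing.")
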