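"""Simulate spike trains and characterize the network state.

Generates two 16-unit networks -- one with 10% natural-frequency disorder
(asynchronous) and one with identical frequencies and no noise (global
in-phase locking) -- and compares their binned coherence.  Saturating
coherence at small bins signals synchrony; roughly linear growth with bin
size signals asynchronous, uniformly spread firing.
"""

import numpy as np

from phasebayes import SynthConfig, coherence, cycles_to_duration, generate_network, simulate_phases

for label, sigma_rel, D in (("heterogeneous", 0.1, 4e-4), ("identical+noiseless", 0.0, 0.0)):
    cfg = SynthConfig(n_units=16, k_in=4, coupling_scale=0.05,
                      sigma_rel=sigma_rel, D=D, seed=1)
    net = generate_network(cfg)
    ds, flagged = simulate_phases(net, cycles_to_duration(net, 300), seed=2)
    rates = ds.n_spikes() / (ds.t_end - ds.t_start) * 1000.0
    print(f"{label}: {int(ds.n_spikes().sum())} spikes, "
          f"rates {rates.min():.0f}-{rates.max():.0f} /s")
    bins = [net.mean_period * f for f in (0.1, 0.25, 0.5, 1.0)]
    res = coherence(ds, bins)
    for b in bins:
        print(f"  bin = {b / net.mean_period:4.2f} periods: kappa = {res.kappa_mean[b]:.3f}")
    print()

print("The locked network saturates near kappa = 1 already at a tenth of a")
print("period; the heterogeneous one grows gradually -- the asynchronous regime")
print("in which the spike-based estimator works best.")
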