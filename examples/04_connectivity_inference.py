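"""Infer synaptic connectivity from estimated interaction functions.

The summed Fourier power of each estimated pairwise interaction separates
connected from unconnected pairs when enough data are available; Otsu's
threshold on the normalized powers yields a binary adjacency scored by the
Matthews correlation coefficient against the simulated truth.
"""

import numpy as np

from phasebayes import (
    SynthConfig,
    cycles_to_duration,
    fit_network,
    generate_network,
    infer_connections,
    simulate_phases,
)

cfg = SynthConfig(n_units=16, k_in=4, coupling_scale=0.05, seed=11)
net = generate_network(cfg)
ds_full, _ = simulate_phases(net, cycles_to_duration(net, 1000), seed=12)

for cycles in (100, 1000):
    ds = ds_full.restrict(0.0, cycles_to_duration(net, cycles))
    estimates = fit_network(ds)
    pairs = {(r, j): e.couplings[j] for r, e in estimates.items()
             for j in e.sender_ids}
    inf = infer_connections(pairs, truth=net.adjacency)
    conn = [p for k, p in enumerate(inf.normalized_powers)
            if net.adjacency[inf.pairs[k][0], inf.pairs[k][1]]]
    unc = [p for k, p in enumerate(inf.normalized_powers)
           if not net.adjacency[inf.pairs[k][0], inf.pairs[k][1]]]
    print(f"{cycles:5d} cycles: threshold = {inf.threshold:.3f}, "
          f"MCC = {inf.mcc:.3f}, confusion = {inf.confusion}")
    print(f"        normalized powers: unconnected median {np.median(unc):.4f} "
          f"(max {max(unc):.3f}), connected median {np.median(conn):.4f} "
          f"(min {min(conn):.3f})")

print("\nAt 100 cycles the two power distributions overlap and inference is"
      "\nunreliable; at 1000 cycles they separate and the MCC approaches 1.")
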