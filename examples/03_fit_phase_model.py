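"""Fit the phase model to spikes alone and compare with the ground truth.

Simulates an 8-unit network (in-degree 3, inhibitory first-harmonic coupling
b1 = -0.05 rad/ms), reconstructs interpolated phases from the spike times,
fits every receiver's effective frequency, noise intensity and per-sender
interaction function by conjugate Bayesian regression, and prints the
estimates next to the simulated truth, including a 95% credible band value.
"""

import numpy as np

from phasebayes import (
    SynthConfig,
    cycles_to_duration,
    fit_network,
    generate_network,
    interaction_credible_band,
    simulate_phases,
)

cfg = SynthConfig(n_units=8, k_in=3, coupling_scale=0.05, seed=21)
net = generate_network(cfg)
ds, _ = simulate_phases(net, cycles_to_duration(net, 1000), seed=22)
print(f"simulated {int(ds.n_spikes().sum())} spikes over {ds.t_end:.0f} ms "
      f"({net.n_units} units, 1000 cycles)\n")

estimates = fit_network(ds)

r = 0
e = estimates[r]
print(f"receiver {r}: omega_hat = {e.omega_hat:.4f} (true {net.omega[r]:.4f}) rad/ms, "
      f"D_hat = {e.D_hat:.2e} (true {net.D[r]:.2e}) rad^2/ms, M = {e.M_selected}")
print(f"{'sender':>6} {'true b1':>9} {'est b1':>9} {'est a1':>9}  connected")
for j in e.sender_ids:
    b_true = net.couplings[(r, j)].b[0] if net.adjacency[r, j] else 0.0
    print(f"{j:6d} {b_true:9.4f} {e.couplings[j].b[0]:9.4f} "
          f"{e.couplings[j].a[0]:9.4f}  {bool(net.adjacency[r, j])}")

j = next(j for j in e.sender_ids if net.adjacency[r, j])
grid = np.linspace(0, 2 * np.pi, 5, endpoint=False)
mean, lo, hi = interaction_credible_band(e, j, grid, level=0.95)
print(f"\n95% credible band of Gamma_hat for edge {j}->{r} (rad/ms):")
for x, m, l, h in zip(grid, mean, lo, hi):
    print(f"  dphi = {x:4.2f}: {m:+.4f}  [{l:+.4f}, {h:+.4f}]")
print("\nConnected senders show a clear -b*sin(dphi) shape; unconnected ones"
      "\nstay near zero with bands covering zero.")
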