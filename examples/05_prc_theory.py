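"""Theoretical interaction functions from a phase response curve.

Convolves a PRC with an inhibitory synaptic kernel to obtain the averaged
interaction Gamma(dphi), fits its Fourier series, scans the odd part across
firing periods for bifurcations of the locked states, and computes the PRC
of an analytic limit-cycle oscillator with the adjoint method.
"""

import numpy as np

from phasebayes import InputKernel, PRCTable, adjoint_prc, interaction_from_prc, odd_part_scan

TWO_PI = 2 * np.pi

# A type-II-like PRC (sinusoidal) at several firing periods, driven by an
# inhibitory exponential synapse.
kernel = InputKernel(kind="exponential", weight=-1.0, tau_d=2.0)
tables = {}
for T in (8.0, 10.0, 12.0):
    tau = np.linspace(0, T, 256, endpoint=False)
    tables[T] = PRCTable(period=T, tau=tau, Z=np.sin(TWO_PI * tau / T))

grid = np.linspace(0, TWO_PI, 256, endpoint=False)
gamma, (a0, four) = interaction_from_prc(tables[10.0], kernel, grid, fit_harmonics=3)
print(f"period 10 ms: Gamma range [{gamma.min():+.4f}, {gamma.max():+.4f}] rad/ms, "
      f"a0 = {a0:+.4f}, b1 = {four.b[0]:+.4f}")

results, flag = odd_part_scan(tables, kernel)
for T, res in results.items():
    print(f"period {T:5.1f} ms: stable phase differences "
          f"{[round(r, 3) for r in res.stable_roots]}")
print(f"bifurcation across periods: {flag}\n")

# Adjoint PRC of the radial isochron clock (rho' = rho(1-rho^2), theta' = 2).
omega = 2.0

def rhs(x):
    r2 = x[0] ** 2 + x[1] ** 2
    return np.array([x[0] * (1 - r2) - omega * x[1],
                     x[1] * (1 - r2) + omega * x[0]])

def jac(x):
    r2 = x[0] ** 2 + x[1] ** 2
    return np.array([[1 - r2 - 2 * x[0] ** 2, -omega - 2 * x[0] * x[1]],
                     [omega - 2 * x[0] * x[1], 1 - r2 - 2 * x[1] ** 2]])

table, xs = adjoint_prc(rhs, jac, x0=[1.3, 0.0], guess_period=TWO_PI / omega,
                        n_samples=32)
tang = np.array([[-x[1], x[0]] / np.linalg.norm(x) for x in xs])
print(f"adjoint PRC: period = {table.period:.6f} (analytic {TWO_PI / omega:.6f})")
print(f"tangential sensitivity: mean {np.mean(np.sum(table.Z * tang, axis=1)):.4f} "
      "(analytic 1.0; radial isochrons make the radial component vanish)")
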