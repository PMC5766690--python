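"""Theoretical interaction functions from phase response curves.

For a receiver with phase response curve Z(t) (phase shift per unit
perturbation at cycle position t, period T) driven by a T-periodic input
waveform w*k(t) from a sender firing at its own phase zero, the averaged
interaction function is

    Gamma(dphi) = (1/T) * integral_0^T  Z(tau) * w * k((tau - dphi*T/(2*pi)) mod T) dtau,

evaluated here by trapezoidal quadrature on the PRC grid.  Scanning Gamma's
odd part across firing periods detects bifurcations of the stable
phase-locked states.  ``adjoint_prc`` computes Z for a user-supplied smooth
limit-cycle ODE by backward integration of the adjoint variational equation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Dict, Optional, Sequence, Tuple

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import brentq

from .model_core import FourierInteraction, StabilityResult, stable_phase_differences
from .synthesize import TWO_PI

__all__ = [
    "PRCTable",
    "InputKernel",
    "interaction_from_prc",
    "fit_fourier",
    "odd_part_scan",
    "adjoint_prc",
]


@dataclass
class PRCTable:
    """Sampled phase response curve on one period, treated as T-periodic.

    Z is in radians of asymptotic phase shift per unit perturbation; the
    normalization convention puts phase in [0, 2*pi) so that Z . f = 2*pi/T
    along the cycle.
    """

    period: float
    tau: np.ndarray
    Z: np.ndarray

    def __post_init__(self):
        self.tau = np.asarray(self.tau, dtype=float)
        self.Z = np.asarray(self.Z, dtype=float)
        if self.tau.size == 0:
            raise ValueError("empty PRC table")
        if self.tau.size != self.Z.shape[0]:
            raise ValueError("tau and Z lengths differ")
        if np.any(np.diff(self.tau) <= 0):
            raise ValueError("tau must be strictly increasing")
        if self.tau[0] < 0 or self.tau[-1] >= self.period:
            raise ValueError("tau samples must lie in [0, period)")

    def eval(self, t) -> np.ndarray:
        """Periodic linear interpolation (wraps the last segment to tau[0]+T)."""
        t = np.mod(np.asarray(t, dtype=float) - self.tau[0], self.period) + self.tau[0]
        tau_ext = np.append(self.tau, self.tau[0] + self.period)
        Z_ext = np.vstack([self.Z, self.Z[:1]]) if self.Z.ndim == 2 else np.append(self.Z, self.Z[0])
        if self.Z.ndim == 1:
            return np.interp(t, tau_ext, Z_ext)
        out = np.empty(t.shape + (self.Z.shape[1],))
        for k in range(self.Z.shape[1]):
            out[..., k] = np.interp(t, tau_ext, Z_ext[:, k])
        return out


@dataclass(frozen=True)
class InputKernel:
    """Periodic synaptic input waveform emitted at the sender's phase zero.

    kinds: "delta" (unit impulse), "exponential" (decay tau_d), "bi_exponential"
    (rise tau_r, decay tau_d), "tabulated" (samples on [0, T)).  Continuous
    kernels are normalized to unit integral per period, so ``weight`` (signed;
    negative = inhibitory) carries the full input strength.
    """

    kind: str
    weight: float = 1.0
    tau_d: Optional[float] = None
    tau_r: Optional[float] = None
    t_samples: Optional[np.ndarray] = None
    k_samples: Optional[np.ndarray] = None

    def periodic_eval(self, t: np.ndarray, period: float) -> np.ndarray:
        """Kernel wrapped onto one period (without the weight factor)."""
        t = np.mod(np.asarray(t, dtype=float), period)
        if self.kind == "exponential":
            td = self.tau_d
            if td is None or td <= 0:
                raise ValueError("exponential kernel needs tau_d > 0")
            # sum over wrapped periods of exp(-t/td)/td, closed form
            return np.exp(-t / td) / (td * (1.0 - math.exp(-period / td)))
        if self.kind == "bi_exponential":
            td, tr = self.tau_d, self.tau_r
            if not (td and tr and td > 0 and tr > 0 and td != tr):
                raise ValueError("bi-exponential kernel needs tau_d != tau_r, both > 0")
            gd = np.exp(-t / td) / (1.0 - math.exp(-period / td))
            gr = np.exp(-t / tr) / (1.0 - math.exp(-period / tr))
            return (gd - gr) / (td - tr)
        if self.kind == "tabulated":
            if self.t_samples is None or self.k_samples is None:
                raise ValueError("tabulated kernel needs samples")
            ts = np.append(self.t_samples, self.t_samples[0] + period)
            ks = np.append(self.k_samples, self.k_samples[0])
            return np.interp(t, ts, ks)
        if self.kind == "delta":
            raise ValueError("delta kernel has no pointwise density; handled analytically")
        raise ValueError(f"unknown kernel kind {self.kind!r}")

    def eval_on_period(self, s: np.ndarray, period: float) -> np.ndarray:
        """Kernel on the closed interval [0, period] *without* wrapping, so
        the wrap-point jump of causal kernels sits at the endpoints (keeps
        trapezoidal quadrature second-order)."""
        s = np.asarray(s, dtype=float)
        if self.kind in ("exponential", "bi_exponential", "tabulated"):
            if self.kind == "exponential":
                td = self.tau_d
                if td is None or td <= 0:
                    raise ValueError("exponential kernel needs tau_d > 0")
                return np.exp(-s / td) / (td * (1.0 - math.exp(-period / td)))
            if self.kind == "bi_exponential":
                td, tr = self.tau_d, self.tau_r
                if not (td and tr and td > 0 and tr > 0 and td != tr):
                    raise ValueError("bi-exponential kernel needs tau_d != tau_r, both > 0")
                gd = np.exp(-s / td) / (1.0 - math.exp(-period / td))
                gr = np.exp(-s / tr) / (1.0 - math.exp(-period / tr))
                return (gd - gr) / (td - tr)
            ts = np.append(self.t_samples, self.t_samples[0] + period)
            ks = np.append(self.k_samples, self.k_samples[0])
            return np.interp(np.mod(s, period + 1e-30), ts, ks)
        raise ValueError(f"kernel kind {self.kind!r} has no density")


def interaction_from_prc(
    Z: PRCTable,
    kernel: InputKernel,
    dphi_grid: np.ndarray,
    fit_harmonics: Optional[int] = None,
):
    """Sampled Gamma(dphi) on ``dphi_grid`` (plus an optional Fourier fit).

    The sender fires at its phase zero, so its waveform is shifted by the
    receiver-minus-sender phase difference: the kernel argument is
    (tau - dphi*T/(2*pi)) mod T.  Delta kernels reduce to a pure PRC lookup,
    (w/T) * Z(dphi*T/(2*pi)).

    Returns ``gamma`` or ``(gamma, (a0, FourierInteraction))`` when
    ``fit_harmonics`` is given.
    """
    x = np.asarray(dphi_grid, dtype=float)
    T = Z.period
    shift = x * T / TWO_PI
    if kernel.kind == "delta":
        gamma = (kernel.weight / T) * Z.eval(shift)
    else:
        # integrate in the sender frame s = tau - shift, so causal kernels'
        # wrap-point jump sits at the interval endpoints (trapezoid stays
        # second-order); quadrature resolution follows the PRC grid
        s = np.linspace(0.0, T, Z.tau.size + 1)
        k = kernel.eval_on_period(s, T)
        zmat = Z.eval(s[None, :] + shift[:, None])
        gamma = np.trapezoid(zmat * (kernel.weight * k)[None, :], s, axis=1) / T
    if fit_harmonics is None:
        return gamma
    return gamma, fit_fourier(x, gamma, fit_harmonics)


def fit_fourier(
    x: np.ndarray, y: np.ndarray, M: int
) -> Tuple[float, FourierInteraction]:
    """Discrete least-squares Fourier fit up to harmonic M; returns
    (constant term a0, FourierInteraction for harmonics 1..M)."""
    x = np.asarray(x, dtype=float)
    cols = [np.ones_like(x)]
    for m in range(1, M + 1):
        cols.append(np.cos(m * x))
        cols.append(np.sin(m * x))
    A = np.column_stack(cols)
    coef, *_ = np.linalg.lstsq(A, np.asarray(y, dtype=float), rcond=None)
    return float(coef[0]), FourierInteraction(a=coef[1::2], b=coef[2::2])


def odd_part_scan(
    tables: Dict[float, PRCTable],
    kernel: InputKernel,
    dphi_grid: Optional[np.ndarray] = None,
    fit_harmonics: int = 5,
    root_tol: float = 0.1,
):
    """Per firing period: Gamma, its odd part and the stable/unstable zeros;
    flags whether the stable set changes across periods (a bifurcation of
    the locked states).

    Returns (results: {period: StabilityResult}, bifurcation_flag).
    """
    if not tables:
        raise ValueError("need at least one period entry")
    if dphi_grid is None:
        dphi_grid = np.linspace(0.0, TWO_PI, 256, endpoint=False)
    results: Dict[float, StabilityResult] = {}
    for period in sorted(tables):
        gamma, (_, four) = interaction_from_prc(
            tables[period], kernel, dphi_grid, fit_harmonics=fit_harmonics
        )
        results[period] = stable_phase_differences(four)

    def stable_set(res: StabilityResult):
        return sorted(res.stable_roots)

    periods = sorted(results)
    ref = stable_set(results[periods[0]])
    flag = False
    for p in periods[1:]:
        cur = stable_set(results[p])
        if len(cur) != len(ref) or any(
            min(abs(c - r), TWO_PI - abs(c - r)) > root_tol
            for c, r in zip(cur, ref)
        ):
            flag = True
            break
    return results, flag


# ---------------------------------------------------------------------------
# Adjoint PRC for user-supplied smooth limit-cycle ODEs (optional tier)

def _find_limit_cycle(rhs, x0, guess_period, tol, transient_periods=30, rtol=1e-10):
    """Settle onto the attractor, then refine the period with a Poincare
    section through a point on the cycle (normal = local flow direction)."""
    sol = solve_ivp(
        lambda t, x: rhs(x), (0.0, transient_periods * guess_period), np.asarray(x0, float),
        rtol=rtol, atol=1e-12, dense_output=False, method="RK45",
        max_step=guess_period / 20,
    )
    x_star = sol.y[:, -1]
    n_vec = np.asarray(rhs(x_star), dtype=float)
    nn = np.linalg.norm(n_vec)
    if nn == 0:
        raise RuntimeError("flow vanishes at candidate cycle point (fixed point?)")
    n_vec = n_vec / nn

    def section(t, x):
        return float(np.dot(x - x_star, n_vec))

    section.direction = 1.0
    section.terminal = False
    sol2 = solve_ivp(
        lambda t, x: rhs(x), (0.0, 3.0 * guess_period), x_star,
        rtol=rtol, atol=1e-12, events=section, method="RK45",
        max_step=guess_period / 20,
    )
    crossings = sol2.t_events[0]
    crossings = crossings[crossings > 0.1 * guess_period]
    if crossings.size == 0:
        raise RuntimeError("no return to the Poincare section; no limit cycle found")
    period = float(crossings[0])
    x_ret = sol2.sol(period) if sol2.sol else None
    # verify closure
    sol3 = solve_ivp(
        lambda t, x: rhs(x), (0.0, period), x_star, rtol=rtol, atol=1e-12,
        dense_output=True, method="RK45", max_step=period / 50,
    )
    gap = np.linalg.norm(sol3.y[:, -1] - x_star)
    if gap > max(tol, 1e-6) * max(1.0, np.linalg.norm(x_star)):
        raise RuntimeError(f"cycle did not close (gap {gap:.2e}); no convergence to a limit cycle")
    return x_star, period, sol3


def adjoint_prc(
    rhs: Callable[[np.ndarray], np.ndarray],
    jac: Callable[[np.ndarray], np.ndarray],
    x0: Sequence[float],
    guess_period: float,
    tol: float = 1e-8,
    n_samples: int = 256,
    n_adjoint_periods: int = 12,
) -> Tuple[PRCTable, np.ndarray]:
    """Phase response curve of an attracting limit cycle via the adjoint
    variational equation.

    The cycle is located by long integration plus Poincare-section period
    refinement; the adjoint system dZ/dt = -J(x(t))^T Z is integrated
    backward over ``n_adjoint_periods`` periods (its periodic solution is the
    attractor of the backward flow), then normalized so Z(t).f(x(t)) = 2*pi/T
    at every sample with phase zero at the section crossing.

    Returns (PRCTable with vector-valued Z of shape (n_samples, dim),
    cycle samples x(t) of the same shape).
    """
    x_star, period, cyc = _find_limit_cycle(rhs, x0, guess_period, tol)
    ts = np.linspace(0.0, period, n_samples, endpoint=False)
    xs = cyc.sol(ts).T  # (n_samples, dim)

    def x_of(t):
        return cyc.sol(np.mod(t, period))

    # backward integration: let s = -t; dZ/ds = +J(x(-s))^T Z
    def adj_rhs(s, z):
        return jac(x_of(-s)).T @ z

    z = np.asarray(rhs(x_star), dtype=float)
    z = z / (z @ z) * (TWO_PI / period)  # rough normalization at phase 0
    prev = None
    for _ in range(n_adjoint_periods):
        sol = solve_ivp(
            adj_rhs, (0.0, period), z, rtol=1e-10, atol=1e-12,
            dense_output=True, max_step=period / 50,
        )
        z = sol.y[:, -1]
        # renormalize along the flow at phase 0
        z = z * (TWO_PI / period) / (z @ rhs(x_star))
        if prev is not None and np.linalg.norm(z - prev) < tol * np.linalg.norm(z):
            prev = z
            break
        prev = z
    else:
        raise RuntimeError("adjoint iteration did not converge to a periodic solution")

    # one converged backward period, sampled; Z(t) = y(s = -t mod period)
    sol = solve_ivp(
        adj_rhs, (0.0, period), prev, rtol=1e-10, atol=1e-12,
        dense_output=True, max_step=period / 50,
    )
    Z = np.empty((n_samples, xs.shape[1]))
    for k, t in enumerate(ts):
        s = (-t) % period
        Z[k] = sol.sol(s)
        f = np.asarray(rhs(xs[k]), dtype=float)
        Z[k] *= (TWO_PI / period) / (Z[k] @ f)  # pointwise drift correction
    return PRCTable(period=period, tau=ts, Z=Z), xs
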