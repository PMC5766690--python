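"""Domain types for phase dynamics and interaction-function algebra.

A weakly coupled network of limit-cycle oscillators reduces to phase
dynamics

    dphi_i/dt = omega_i + sum_j Gamma_ij(phi_i - phi_j) + xi_i(t),

where each pairwise interaction function ``Gamma_ij`` is 2*pi-periodic and
is represented here by a finite Fourier series.  The odd part of a shared
interaction function governs the phase-difference dynamics of a symmetric
pair; its stable zeros are the phase-locked states.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Tuple

import numpy as np

__all__ = [
    "FourierInteraction",
    "PhaseModel",
    "StabilityResult",
    "DegenerateInteractionError",
    "eval_interaction",
    "odd_part",
    "pair_difference_function",
    "stable_phase_differences",
]


class DegenerateInteractionError(ValueError):
    """Raised when an odd part is identically zero (every phase difference neutral)."""


@dataclass(frozen=True)
class FourierInteraction:
    """Interaction function Gamma(dphi) = sum_m a[m] cos(m dphi) + b[m] sin(m dphi).

    Coefficients are in rad/ms.  The constant (m=0) term is *not* part of this
    type: in the estimation model it is absorbed into the effective frequency
    omega_hat and is therefore unidentifiable on its own.
    """

    a: Tuple[float, ...]
    b: Tuple[float, ...]

    def __init__(self, a, b):
        a = tuple(float(x) for x in np.atleast_1d(a))
        b = tuple(float(x) for x in np.atleast_1d(b))
        if len(a) != len(b) or len(a) < 1:
            raise ValueError(
                f"need len(a) == len(b) >= 1, got {len(a)} and {len(b)}"
            )
        if not all(math.isfinite(x) for x in a + b):
            raise ValueError("non-finite Fourier coefficient")
        object.__setattr__(self, "a", a)
        object.__setattr__(self, "b", b)

    @property
    def M(self) -> int:
        """Number of harmonics."""
        return len(self.a)

    def __call__(self, dphi):
        return eval_interaction(self, dphi)

    def as_coeff_vector(self, n_pad: int | None = None) -> np.ndarray:
        """Interleaved coefficient vector [a1, b1, a2, b2, ...], zero-padded
        per-harmonic to ``n_pad`` harmonics."""
        n = self.M if n_pad is None else int(n_pad)
        if n < self.M:
            raise ValueError(f"n_pad={n} < M={self.M}")
        out = np.zeros(2 * n)
        out[0 : 2 * self.M : 2] = self.a
        out[1 : 2 * self.M : 2] = self.b
        return out

    def to_dict(self) -> dict:
        return {"M": self.M, "a": list(self.a), "b": list(self.b)}

    @classmethod
    def from_dict(cls, d: dict) -> "FourierInteraction":
        f = cls(d["a"], d["b"])
        if "M" in d and int(d["M"]) != f.M:
            raise ValueError(f"declared M={d['M']} but {f.M} coefficients given")
        return f


def eval_interaction(f: FourierInteraction, dphi):
    """Evaluate Gamma at phase difference(s) ``dphi`` (radians) -> rad/ms.

    Accepts scalars or arrays; any real value is valid (the series is
    2*pi-periodic by construction).
    """
    x = np.asarray(dphi, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite phase difference")
    m = np.arange(1, f.M + 1)
    mx = np.multiply.outer(x, m)  # (..., M)
    val = np.cos(mx) @ np.array(f.a) + np.sin(mx) @ np.array(f.b)
    return float(val) if np.isscalar(dphi) or np.ndim(dphi) == 0 else val


def odd_part(f: FourierInteraction) -> FourierInteraction:
    """Gamma_odd(dphi) = Gamma(dphi) - Gamma(-dphi): zero cosine part, sine
    coefficients doubled."""
    return FourierInteraction(a=[0.0] * f.M, b=[2.0 * bm for bm in f.b])


def pair_difference_function(
    f_ij: FourierInteraction, f_ji: FourierInteraction
) -> FourierInteraction:
    """Phase-difference velocity for an *asymmetric* pair (extension).

    For receivers with distinct interaction functions the difference
    dphi = phi_i - phi_j obeys d(dphi)/dt = Gamma_ij(dphi) - Gamma_ji(-dphi)
    (plus the frequency mismatch, excluded here).  Reduces to the symmetric
    odd part when f_ij == f_ji.
    """
    n = max(f_ij.M, f_ji.M)
    a1 = np.zeros(n)
    b1 = np.zeros(n)
    a1[: f_ij.M] = f_ij.a
    b1[: f_ij.M] = f_ij.b
    a2 = np.zeros(n)
    b2 = np.zeros(n)
    a2[: f_ji.M] = f_ji.a
    b2[: f_ji.M] = f_ji.b
    # Gamma_ji(-x) has cosine part unchanged, sine part negated.
    return FourierInteraction(a=a1 - a2, b=b1 + b2)


@dataclass
class PhaseModel:
    """A fitted or ground-truth phase-oscillator network.

    omega_hat is the per-unit effective frequency (rad/ms; absorbs the
    constant Fourier terms of all incoming couplings), D the per-unit noise
    intensity (rad^2/ms), and couplings maps (receiver, sender) -> Gamma.
    """

    n_units: int
    omega_hat: np.ndarray
    D: np.ndarray
    couplings: Dict[Tuple[int, int], FourierInteraction] = field(default_factory=dict)

    def __post_init__(self):
        self.omega_hat = np.asarray(self.omega_hat, dtype=float)
        self.D = np.asarray(self.D, dtype=float)
        if self.omega_hat.shape != (self.n_units,) or self.D.shape != (self.n_units,):
            raise ValueError("omega_hat and D must have length n_units")
        if np.any(self.omega_hat <= 0):
            raise ValueError("omega_hat must be positive (units must oscillate)")
        if np.any(self.D < 0):
            raise ValueError("noise intensity D must be non-negative")
        for (i, j) in self.couplings:
            if i == j:
                raise ValueError(f"self-coupling entry ({i},{i}) not allowed")


@dataclass(frozen=True)
class StabilityResult:
    """Zeros of an odd interaction function on [0, 2*pi) with their stability.

    ``stability`` labels are "stable" (negative slope), "unstable" (positive
    slope) or "degenerate" (slope within tolerance of zero -- e.g. a tangent
    zero), never silently dropped.
    """

    roots: Tuple[float, ...]
    stability: Tuple[str, ...]
    slope: Tuple[float, ...]

    @property
    def stable_roots(self) -> Tuple[float, ...]:
        return tuple(
            r for r, s in zip(self.roots, self.stability) if s == "stable"
        )


def _series_derivative(f: FourierInteraction, x: float) -> float:
    """Analytic d/dx of the Fourier series (exact, no finite differences)."""
    m = np.arange(1, f.M + 1)
    return float(
        np.sum(-m * np.array(f.a) * np.sin(m * x) + m * np.array(f.b) * np.cos(m * x))
    )


def stable_phase_differences(
    f: FourierInteraction,
    grid_n: int = 1024,
    tol: float = 1e-10,
    slope_tol: float = 1e-9,
) -> StabilityResult:
    """Find the simple zeros of the odd part of ``f`` on [0, 2*pi) and
    classify them by the analytic derivative of the sine series.

    A sign-change scan on ``grid_n`` points brackets each zero; bisection
    refines it to ``tol`` radians.  Roots where |slope| <= ``slope_tol`` are
    labelled "degenerate".
    """
    if grid_n < 64:
        raise ValueError("grid_n must be >= 64")
    g = odd_part(f)
    if all(abs(bm) < 1e-300 for bm in g.b):
        raise DegenerateInteractionError(
            "odd part identically zero: every phase difference is neutral"
        )

    xs = np.linspace(0.0, 2.0 * np.pi, grid_n, endpoint=False)
    ys = eval_interaction(g, xs)

    roots: List[float] = []
    for k in range(grid_n):
        x0, x1 = xs[k], xs[k] + (2.0 * np.pi / grid_n)
        y0, y1 = ys[k], ys[(k + 1) % grid_n]
        if y0 == 0.0:
            roots.append(float(x0))
            continue
        if y0 * y1 < 0.0:
            lo, hi, flo = x0, x1, y0
            while hi - lo > tol:
                mid = 0.5 * (lo + hi)
                fm = eval_interaction(g, mid)
                if fm == 0.0:
                    lo = hi = mid
                    break
                if flo * fm < 0.0:
                    hi = mid
                else:
                    lo, flo = mid, fm
            roots.append(0.5 * (lo + hi) % (2.0 * np.pi))

    roots = sorted(roots)
    # merge near-duplicates from grid-point hits
    merged: List[float] = []
    for r in roots:
        if not merged or (r - merged[-1] > 10 * tol and (2 * np.pi - r + merged[0]) > 10 * tol):
            merged.append(r)

    slopes = [_series_derivative(g, r) for r in merged]
    labels = [
        "degenerate" if abs(s) <= slope_tol else ("stable" if s < 0 else "unstable")
        for s in slopes
    ]
    return StabilityResult(
        roots=tuple(merged), stability=tuple(labels), slope=tuple(slopes)
    )
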