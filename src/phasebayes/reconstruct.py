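"""Spike times -> interpolated phase series on a shared uniform grid.

A spike marks phase zero (mod 2*pi).  Between consecutive spikes t_s and
t_{s+1} the unwrapped phase is linear,

    phi(t) = 2*pi*s + 2*pi*(t - t_s)/(t_{s+1} - t_s),

so the phase increment per grid step (the regression response) is constant
within each inter-spike interval.  All units are sampled on one global grid
anchored at the common window start, which makes pairwise phase differences
well-defined across units.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, List, Sequence, Tuple

import numpy as np

from .synthesize import SpikeDataset, TWO_PI

__all__ = [
    "PhasePath",
    "RegressionData",
    "UnusableUnitError",
    "InsufficientOverlapError",
    "GridMismatchError",
    "interpolate_phase",
    "common_window",
    "build_regression",
    "dataset_paths",
]


class UnusableUnitError(ValueError):
    """Unit has fewer than 2 spikes in the analysis window."""


class InsufficientOverlapError(ValueError):
    """The units' recordings share no common window."""


class GridMismatchError(ValueError):
    """Phase paths do not share grid step and alignment."""


@dataclass
class PhasePath:
    """Unwrapped phase of one unit sampled on a uniform grid.

    phi[k] is the phase at time t0 + k*dt; phi is strictly increasing and
    equals a multiple of 2*pi exactly at spike times.
    """

    unit_id: int
    dt: float
    t0: float
    phi: np.ndarray
    spike_grid_marks: np.ndarray  # grid indices whose step crosses a 2*pi multiple

    @property
    def times(self) -> np.ndarray:
        return self.t0 + self.dt * np.arange(self.phi.size)


def interpolate_phase(
    spikes: Sequence[float],
    dt: float,
    window: Tuple[float, float],
    unit_id: int = 0,
    grid_origin: float | None = None,
) -> PhasePath:
    """Linearly interpolated unwrapped phase on the global grid.

    The grid is ``grid_origin + k*dt`` (origin defaults to the window start),
    restricted to [first spike, last spike] intersected with ``window``.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    s = np.asarray(spikes, dtype=float)
    t_lo, t_hi = window
    if s.size < 2:
        raise UnusableUnitError(f"unit {unit_id}: fewer than 2 spikes")
    isi = np.diff(s)
    if np.any(isi <= 0):
        raise ValueError(f"unit {unit_id}: zero-length or negative inter-spike interval")

    origin = t_lo if grid_origin is None else grid_origin
    lo = max(s[0], t_lo)
    hi = min(s[-1], t_hi)
    if hi <= lo:
        raise UnusableUnitError(f"unit {unit_id}: no phase support inside window")
    k0 = int(np.ceil((lo - origin) / dt - 1e-9))
    k1 = int(np.floor((hi - origin) / dt + 1e-9))
    if k1 < k0:
        raise UnusableUnitError(f"unit {unit_id}: grid has no point inside support")
    t = origin + dt * np.arange(k0, k1 + 1)

    idx = np.clip(np.searchsorted(s, t, side="right") - 1, 0, s.size - 2)
    phi = TWO_PI * (idx + (t - s[idx]) / isi[idx])

    cyc = np.floor(phi / TWO_PI + 1e-12).astype(int)
    marks = np.nonzero(np.diff(cyc) > 0)[0] + 1
    return PhasePath(
        unit_id=unit_id, dt=dt, t0=float(origin + dt * k0), phi=phi,
        spike_grid_marks=marks,
    )


def common_window(
    spike_trains: Iterable[Sequence[float]],
) -> Tuple[float, float]:
    """[max of first spikes, min of last spikes] across units.

    Phase is undefined before a unit's first and after its last spike, so
    the shared analysis window is the intersection of the units' supports.
    """
    firsts, lasts = [], []
    for u, s in enumerate(spike_trains):
        s = np.asarray(s, dtype=float)
        if s.size < 2:
            raise UnusableUnitError(f"unit {u}: fewer than 2 spikes")
        firsts.append(s[0])
        lasts.append(s[-1])
    t_lo, t_hi = max(firsts), min(lasts)
    if t_hi <= t_lo:
        raise InsufficientOverlapError(
            f"no common window: max first spike {t_lo} >= min last spike {t_hi}"
        )
    return float(t_lo), float(t_hi)


@dataclass
class RegressionData:
    """Response and regressor phases for one receiver.

    delta[tau] = (phi_r(tau+1) - phi_r(tau)) / dt  (rad/ms); dphi[tau, k] is
    the receiver-minus-sender phase difference for the k-th other unit
    (column order = ``sender_ids``).  ``receiver_cycle[tau]`` indexes the
    receiver inter-spike interval containing sample tau (used to collapse
    duplicated within-cycle rows during fitting).
    """

    receiver: int
    sender_ids: Tuple[int, ...]
    delta: np.ndarray
    dphi: np.ndarray
    dt: float
    receiver_cycle: np.ndarray

    @property
    def n_samples(self) -> int:
        return self.delta.size


def dataset_paths(
    dataset: SpikeDataset, dt: float, units: Sequence[int] | None = None
) -> List[PhasePath]:
    """Interpolate all (or a subset of) units on the shared grid of their
    common window."""
    units = list(range(dataset.n_units)) if units is None else list(units)
    window = common_window([dataset.spikes[u] for u in units])
    return [
        interpolate_phase(dataset.spikes[u], dt, window, unit_id=u,
                          grid_origin=window[0])
        for u in units
    ]


def build_regression(paths: Sequence[PhasePath], receiver: int) -> RegressionData:
    """Assemble the receiver's response vector and the pairwise phase
    differences of every other observed unit, truncated to the samples all
    paths share."""
    by_id = {p.unit_id: p for p in paths}
    if receiver not in by_id:
        raise ValueError(f"receiver {receiver} not among observed paths")
    p_r = by_id[receiver]
    for p in paths:
        if abs(p.dt - p_r.dt) > 1e-12 or abs((p.t0 - p_r.t0) / p.dt - round((p.t0 - p_r.t0) / p.dt)) > 1e-6:
            raise GridMismatchError(
                f"unit {p.unit_id} grid (dt={p.dt}, t0={p.t0}) not aligned with receiver"
            )
    # overlap in grid index space
    k_lo = max(int(round(p.t0 / p.dt)) for p in paths)
    k_hi = min(int(round(p.t0 / p.dt)) + p.phi.size - 1 for p in paths)
    if k_hi <= k_lo:
        raise InsufficientOverlapError("paths share fewer than 2 grid points")

    def seg(p: PhasePath) -> np.ndarray:
        off = k_lo - int(round(p.t0 / p.dt))
        return p.phi[off : off + (k_hi - k_lo + 1)]

    phi_r = seg(p_r)
    delta = np.diff(phi_r) / p_r.dt
    senders = tuple(sorted(u for u in by_id if u != receiver))
    dphi = np.column_stack([phi_r[:-1] - seg(by_id[u])[:-1] for u in senders]) \
        if senders else np.zeros((delta.size, 0))
    cycle = np.floor((phi_r[:-1] + phi_r[1:]) / 2.0 / TWO_PI).astype(int)
    return RegressionData(
        receiver=receiver,
        sender_ids=senders,
        delta=delta,
        dphi=dphi,
        dt=p_r.dt,
        receiver_cycle=cycle,
    )
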