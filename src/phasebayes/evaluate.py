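"""Estimation-quality metrics and synaptic-connectivity inference.

The coefficient L2 distance compares estimated and reference interaction
functions harmonic by harmonic; the summed Fourier power of each estimated
pairwise interaction, normalized by the maximum and thresholded with Otsu's
method, yields a binary adjacency whose agreement with the ground truth is
scored by the Matthews correlation coefficient.  A binned spike-train
coherence measure characterizes the degree of network synchrony.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .model_core import FourierInteraction
from .synthesize import SpikeDataset

__all__ = [
    "ConnectivityInference",
    "CoherenceResult",
    "DegenerateValuesError",
    "l2_distance",
    "summed_power",
    "otsu_threshold",
    "infer_connections",
    "mcc",
    "coherence",
]


class DegenerateValuesError(ValueError):
    """All values identical: no threshold can separate two classes."""


def l2_distance(
    c_true: FourierInteraction,
    c_est: FourierInteraction,
    n_pad: int = 10,
    sqrt: bool = True,
) -> float:
    """Coefficient-space distance between two interaction functions.

    Both coefficient vectors are zero-padded per-harmonic to ``n_pad``
    harmonics (harmonics absent from one function are penalized against
    zero); constant terms are excluded, being absorbed into omega_hat.
    ``sqrt=False`` returns the plain sum of squared differences.
    """
    if n_pad < max(c_true.M, c_est.M):
        raise ValueError("n_pad must cover both harmonic counts")
    d = c_true.as_coeff_vector(n_pad) - c_est.as_coeff_vector(n_pad)
    ss = float(d @ d)
    return float(np.sqrt(ss)) if sqrt else ss


def summed_power(f: FourierInteraction) -> float:
    """sum_m a_m^2 + b_m^2: the magnitude criterion for connection presence."""
    a = np.array(f.a)
    b = np.array(f.b)
    return float(a @ a + b @ b)


def otsu_threshold(values: Sequence[float]) -> float:
    """Otsu's threshold by exhaustive search over midpoints between
    consecutive sorted unique values (exact for the few hundred pairs used
    here; no histogram binning).  Maximizes the between-class variance
    w0*w1*(mu0-mu1)^2; ties break toward the smallest threshold.
    """
    v = np.sort(np.asarray(values, dtype=float))
    if v.size < 2:
        raise ValueError("need at least 2 values")
    uniq = np.unique(v)
    if uniq.size < 2:
        raise DegenerateValuesError("all values identical; no threshold exists")
    candidates = 0.5 * (uniq[:-1] + uniq[1:])
    n = v.size
    best_t, best_score = None, -np.inf
    for t in candidates:
        left = v[v <= t]
        right = v[v > t]
        w0 = left.size / n
        w1 = right.size / n
        score = w0 * w1 * (left.mean() - right.mean()) ** 2
        if score > best_score + 1e-15:
            best_t, best_score = t, score
    return float(best_t)


def mcc(w_est: np.ndarray, w_act: np.ndarray) -> float:
    """Matthews correlation coefficient between two binary adjacency
    matrices, diagonal excluded.  Any zero factor in the denominator returns
    0 with a warning (standard convention)."""
    w_est = np.asarray(w_est, dtype=int)
    w_act = np.asarray(w_act, dtype=int)
    if w_est.shape != w_act.shape:
        raise ValueError(f"shape mismatch {w_est.shape} vs {w_act.shape}")
    if w_est.ndim == 2 and w_est.shape[0] == w_est.shape[1]:
        mask = ~np.eye(w_est.shape[0], dtype=bool)
        e, a = w_est[mask], w_act[mask]
    else:
        e, a = w_est.ravel(), w_act.ravel()
    tp = int(np.sum((e == 1) & (a == 1)))
    tn = int(np.sum((e == 0) & (a == 0)))
    fp = int(np.sum((e == 1) & (a == 0)))
    fn = int(np.sum((e == 0) & (a == 1)))
    denom2 = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom2 == 0:
        warnings.warn("MCC denominator zero (one-class prediction or truth); returning 0")
        return 0.0
    return float((tp * tn - fp * fn) / np.sqrt(denom2))


@dataclass
class ConnectivityInference:
    """Summed-power connectivity inference for a set of ordered pairs."""

    pairs: Tuple[Tuple[int, int], ...]  # (receiver, sender)
    powers: np.ndarray
    normalized_powers: np.ndarray
    threshold: float
    w_est: Dict[Tuple[int, int], int]
    mcc: Optional[float] = None
    confusion: Optional[Dict[str, int]] = None


def infer_connections(
    estimates: Dict[Tuple[int, int], FourierInteraction],
    truth: Optional[np.ndarray] = None,
) -> ConnectivityInference:
    """Powers -> normalize by max -> Otsu -> binarize; score against a true
    adjacency when given.

    ``estimates`` maps ordered (receiver, sender) pairs to estimated
    interaction functions; ``truth[i, j] == 1`` marks a true synapse j -> i.
    """
    pairs = tuple(sorted(estimates))
    if len(pairs) < 2:
        raise ValueError("need at least 2 pairs to infer a threshold")
    powers = np.array([summed_power(estimates[p]) for p in pairs])
    pmax = powers.max()
    if pmax == 0:
        raise DegenerateValuesError("all interaction powers are zero")
    norm = powers / pmax
    thr = otsu_threshold(norm)
    w_est = {p: int(norm[k] > thr) for k, p in enumerate(pairs)}

    result = ConnectivityInference(
        pairs=pairs, powers=powers, normalized_powers=norm,
        threshold=thr, w_est=w_est,
    )
    if truth is not None:
        truth = np.asarray(truth, dtype=int)
        e = np.array([w_est[p] for p in pairs])
        a = np.array([truth[i, j] for (i, j) in pairs])
        result.confusion = {
            "TP": int(np.sum((e == 1) & (a == 1))),
            "FP": int(np.sum((e == 1) & (a == 0))),
            "TN": int(np.sum((e == 0) & (a == 0))),
            "FN": int(np.sum((e == 0) & (a == 1))),
        }
        result.mcc = mcc(e, a)
    return result


@dataclass
class CoherenceResult:
    """Pairwise binned-spike coherence at one or more bin sizes."""

    bin_sizes: Tuple[float, ...]
    kappa_per_pair: Dict[float, Dict[Tuple[int, int], float]]
    kappa_mean: Dict[float, float]
    excluded_pairs: Dict[float, int]


def coherence(
    dataset: SpikeDataset,
    bin_sizes: Sequence[float] | float,
    pairs: Optional[Sequence[Tuple[int, int]]] = None,
) -> CoherenceResult:
    """Binned zero-one coherence kappa_ij = sum(x_i x_j) / sqrt(sum x_i sum x_j).

    x_i(t_n) is 1 when unit i spikes at least once in bin n.  kappa is in
    [0, 1]: it saturates quickly with bin size under synchrony and grows
    roughly linearly under asynchronous (uniformly spread) firing.  Pairs in
    which either unit occupies no bin are excluded and counted.
    """
    if np.isscalar(bin_sizes):
        bin_sizes = [float(bin_sizes)]
    bin_sizes = [float(b) for b in bin_sizes]
    if any(b <= 0 for b in bin_sizes):
        raise ValueError("bin sizes must be positive")
    if all(s.size == 0 for s in dataset.spikes):
        raise ValueError("empty dataset")
    if pairs is None:
        n = dataset.n_units
        pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]

    per_pair: Dict[float, Dict[Tuple[int, int], float]] = {}
    means: Dict[float, float] = {}
    excluded: Dict[float, int] = {}
    span = dataset.t_end - dataset.t_start
    for b in bin_sizes:
        n_bins = max(int(np.ceil(span / b)), 1)
        edges = dataset.t_start + b * np.arange(n_bins + 1)
        occ = [
            (np.histogram(s, bins=edges)[0] > 0).astype(float)
            for s in dataset.spikes
        ]
        counts = [float(x.sum()) for x in occ]
        kp: Dict[Tuple[int, int], float] = {}
        skipped = 0
        for (i, j) in pairs:
            if counts[i] == 0 or counts[j] == 0:
                skipped += 1
                continue
            kp[(i, j)] = float(occ[i] @ occ[j] / np.sqrt(counts[i] * counts[j]))
        per_pair[b] = kp
        excluded[b] = skipped
        means[b] = float(np.mean(list(kp.values()))) if kp else float("nan")
    return CoherenceResult(
        bin_sizes=tuple(bin_sizes), kappa_per_pair=per_pair,
        kappa_mean=means, excluded_pairs=excluded,
    )
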