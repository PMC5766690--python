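"""File formats, configuration and the seeded end-to-end scenario runner.

All artifacts are plain text: spikes as two-column TSV (unit id, time in
ms), ground-truth networks and fitted models as versioned JSON.  Scenario
runs orchestrate simulate -> estimate -> evaluate -> infer over sweeps of
data length, frequency heterogeneity, noise intensity, observed subset or
network size, with per-cell seeds derived deterministically from the master
seed via ``numpy.random.SeedSequence(master, spawn_key=(cell_index,))``.
"""

from __future__ import annotations

import hashlib
import json
import time
import warnings
from dataclasses import dataclass, field, asdict
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml

from . import __version__ as _pkg_version
from .bayes import EstimatorConfig, PhaseModelEstimate, fit_network
from .evaluate import coherence, infer_connections, l2_distance
from .model_core import FourierInteraction
from .synthesize import (
    GroundTruthNetwork,
    SpikeDataset,
    SynthConfig,
    cycles_to_duration,
    generate_network,
    simulate_phases,
)

__all__ = [
    "read_spikes",
    "write_spikes",
    "read_truth",
    "write_truth",
    "read_model",
    "write_model",
    "ScenarioConfig",
    "RunManifest",
    "run_scenario",
    "cell_seed",
]

FORMAT_VERSION = 1


# ---------------------------------------------------------------------------
# Spike TSV

def write_spikes(dataset: SpikeDataset, path) -> None:
    """Two-column TSV ``unit_id<TAB>time_ms`` sorted by time, with the
    recording window in '#' header comments."""
    rows = []
    for u, s in enumerate(dataset.spikes):
        rows.extend((u, t) for t in s)
    rows.sort(key=lambda r: (r[1], r[0]))
    with open(path, "w") as fh:
        fh.write("# phasebayes spikes v%d\n" % FORMAT_VERSION)
        fh.write(f"# t_start={dataset.t_start!r} t_end={dataset.t_end!r}\n")
        for u, t in rows:
            fh.write(f"{u}\t{t:.6f}\n")


def read_spikes(path) -> SpikeDataset:
    """Parse a spike TSV; '#' lines are comments.  Unsorted times are sorted
    with a warning, duplicate times within a unit deduplicated with a
    warning, negative times and malformed lines are errors (with line
    numbers)."""
    per_unit: Dict[int, List[float]] = {}
    t_start = t_end = None
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                if "t_start=" in line:
                    try:
                        parts = dict(
                            kv.split("=") for kv in line[1:].split() if "=" in kv
                        )
                        t_start = float(parts.get("t_start"))
                        t_end = float(parts.get("t_end"))
                    except Exception:
                        pass
                continue
            fields = line.split("\t")
            if len(fields) == 1:
                fields = line.split()
            if len(fields) != 2:
                raise ValueError(f"{path}:{ln}: expected 2 columns, got {len(fields)}")
            try:
                u = int(fields[0])
                t = float(fields[1])
            except ValueError as exc:
                raise ValueError(f"{path}:{ln}: malformed line {line!r}") from exc
            if t < 0:
                raise ValueError(f"{path}:{ln}: negative spike time {t}")
            per_unit.setdefault(u, []).append(t)
    if not per_unit:
        raise ValueError(f"{path}: no spikes")
    n_units = max(per_unit) + 1
    spikes: List[np.ndarray] = []
    for u in range(n_units):
        s = np.array(per_unit.get(u, []), dtype=float)
        if s.size and np.any(np.diff(s) < 0):
            warnings.warn(f"unit {u}: spike times unsorted; sorting")
            s = np.sort(s)
        if s.size:
            keep = np.concatenate([[True], np.diff(s) > 0])
            if not keep.all():
                warnings.warn(f"unit {u}: duplicate spike times deduplicated")
                s = s[keep]
        spikes.append(s)
    all_t = np.concatenate([s for s in spikes if s.size])
    lo = t_start if t_start is not None else float(all_t.min())
    hi = t_end if t_end is not None else float(all_t.max())
    return SpikeDataset(spikes=spikes, t_start=lo, t_end=hi)


# ---------------------------------------------------------------------------
# Truth / model JSON

def write_truth(net: GroundTruthNetwork, path) -> None:
    doc = {
        "format_version": FORMAT_VERSION,
        "n_units": net.n_units,
        "omega": net.omega.tolist(),
        "D": net.D.tolist(),
        "adjacency": net.adjacency.tolist(),
        "couplings": [
            {"receiver": int(i), "sender": int(j), **net.couplings[(i, j)].to_dict()}
            for (i, j) in sorted(net.couplings)
        ],
        "seed": net.seed,
        "units": {"omega": "rad/ms", "D": "rad^2/ms", "coupling": "rad/ms"},
    }
    doc.update(net.extra)
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)


_TRUTH_REQUIRED = ("format_version", "n_units", "omega", "D", "adjacency", "couplings")


def read_truth(path) -> GroundTruthNetwork:
    with open(path) as fh:
        doc = json.load(fh)
    for key in _TRUTH_REQUIRED:
        if key not in doc:
            raise ValueError(f"{path}: missing required field /{key}")
    couplings = {}
    for k, entry in enumerate(doc["couplings"]):
        for key in ("receiver", "sender", "a", "b"):
            if key not in entry:
                raise ValueError(f"{path}: missing field /couplings/{k}/{key}")
        couplings[(int(entry["receiver"]), int(entry["sender"]))] = (
            FourierInteraction.from_dict(entry)
        )
    known = set(_TRUTH_REQUIRED) | {"seed", "units"}
    extra = {k: v for k, v in doc.items() if k not in known}
    return GroundTruthNetwork(
        n_units=int(doc["n_units"]),
        omega=np.array(doc["omega"], dtype=float),
        D=np.array(doc["D"], dtype=float),
        adjacency=np.array(doc["adjacency"], dtype=int),
        couplings=couplings,
        seed=doc.get("seed"),
        extra=extra,
    )


def write_model(estimates: Dict[int, PhaseModelEstimate], path, meta: dict | None = None) -> None:
    doc = {
        "format_version": FORMAT_VERSION,
        "software": f"phasebayes {_pkg_version}",
        "receivers": {str(r): est.to_dict() for r, est in estimates.items()},
    }
    if meta:
        doc["meta"] = meta
    with open(path, "w") as fh:
        json.dump(doc, fh)


def read_model(path) -> Dict[int, PhaseModelEstimate]:
    with open(path) as fh:
        doc = json.load(fh)
    for key in ("format_version", "receivers"):
        if key not in doc:
            raise ValueError(f"{path}: missing required field /{key}")
    return {
        int(r): PhaseModelEstimate.from_dict(d) for r, d in doc["receivers"].items()
    }


# ---------------------------------------------------------------------------
# Scenario runner

def cell_seed(master_seed: int, cell_index: int) -> int:
    """Per-cell seed: counter-based derivation from the master seed."""
    ss = np.random.SeedSequence(master_seed, spawn_key=(cell_index,))
    return int(ss.generate_state(1)[0] % (2 ** 31))


@dataclass
class ScenarioConfig:
    """A sweep experiment: simulate networks, fit, evaluate, infer.

    ``sweep`` names the swept variable ("sigma_rel", "D", "subset",
    "n_units" or "none"); ``sweep_values`` its values.  Each (sweep value,
    seed) cell simulates one network at max(cycle_counts) and evaluates
    every entry of ``cycle_counts`` on truncated windows of the same
    recording.  For the "n_units" sweep, coupling_scale is halved each time
    the network size doubles from the base config, and k_in doubled, which
    emulates the study's network-size scaling design.
    """

    synth: SynthConfig = field(default_factory=SynthConfig)
    estimator: EstimatorConfig = field(default_factory=EstimatorConfig)
    cycle_counts: Tuple[int, ...] = (100, 500, 1000)
    seeds: Tuple[int, ...] = (0, 1, 2)
    sweep: str = "none"
    sweep_values: Tuple = (None,)
    coherence_bins_per_period: Tuple[float, ...] = (0.1, 0.5, 1.0)

    def __post_init__(self):
        if len(set(self.seeds)) != len(self.seeds):
            raise ValueError("seeds must be distinct")
        if not self.cycle_counts or any(c <= 0 for c in self.cycle_counts):
            raise ValueError("cycle_counts must be positive and non-empty")
        if not self.sweep_values:
            raise ValueError("sweep_values must be non-empty")
        if self.sweep not in ("none", "sigma_rel", "D", "subset", "n_units"):
            raise ValueError(f"unknown sweep variable {self.sweep!r}")

    @classmethod
    def from_yaml(cls, path) -> "ScenarioConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        synth = SynthConfig(**doc.get("synth", {}))
        est = EstimatorConfig(**doc.get("estimator", {}))
        kwargs = {
            k: tuple(v) if isinstance(v, list) else v
            for k, v in doc.items()
            if k not in ("synth", "estimator")
        }
        return cls(synth=synth, estimator=est, **kwargs)

    def canonical_json(self) -> str:
        doc = {
            "synth": asdict(self.synth) if not isinstance(self.synth.coupling_template, FourierInteraction)
            else {**asdict(self.synth), "coupling_template": self.synth.coupling_template.to_dict()},
            "estimator": asdict(self.estimator),
            "cycle_counts": list(self.cycle_counts),
            "seeds": list(self.seeds),
            "sweep": self.sweep,
            "sweep_values": list(self.sweep_values),
        }
        return json.dumps(doc, sort_keys=True, default=str)


@dataclass
class RunManifest:
    config_hash: str
    master_seed: Optional[int]
    software_version: str
    runtimes_s: Dict[str, float] = field(default_factory=dict)
    output_checksums: Dict[str, str] = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=1, sort_keys=True)


def _apply_sweep(cfg: ScenarioConfig, value):
    synth = cfg.synth
    subset = cfg.estimator.subset
    if cfg.sweep == "sigma_rel":
        synth = SynthConfig(**{**asdict(synth), "sigma_rel": float(value)})
    elif cfg.sweep == "D":
        synth = SynthConfig(**{**asdict(synth), "D": float(value)})
    elif cfg.sweep == "subset":
        subset = tuple(range(int(value)))
    elif cfg.sweep == "n_units":
        base = cfg.synth
        factor = int(value) // base.n_units
        if factor < 1 or int(value) % base.n_units:
            raise ValueError("n_units sweep values must be multiples of the base size")
        synth = SynthConfig(**{
            **asdict(base),
            "n_units": int(value),
            "k_in": base.k_in * factor,
            "coupling_scale": base.coupling_scale / factor,
        })
    return synth, subset


def run_scenario(cfg: ScenarioConfig, master_seed: Optional[int] = None):
    """Run the sweep and return (results DataFrame, RunManifest).

    One row per (seed, sweep value, cycle count) with the mean and median
    coefficient L2 distance over ordered pairs, the connectivity MCC, and
    the mean coherence at the largest configured bin.  Cell failures are
    recorded in the 'error' column; the run continues.
    """
    t_run0 = time.perf_counter()
    rows = []
    cell = 0
    for value in cfg.sweep_values:
        try:
            synth, subset = _apply_sweep(cfg, value)
        except Exception as exc:
            for seed_idx in range(len(cfg.seeds)):
                rows.append({"sweep_value": value, "seed": cfg.seeds[seed_idx],
                             "cycles": None, "error": str(exc)})
            continue
        for seed in cfg.seeds:
            cseed = cell_seed(master_seed if master_seed is not None else 0,
                              cell) if master_seed is not None else seed
            cell += 1
            try:
                net = generate_network(
                    SynthConfig(**{**asdict(synth), "seed": cseed})
                )
                duration = cycles_to_duration(net, max(cfg.cycle_counts))
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    ds_full, _ = simulate_phases(net, duration, seed=cseed + 1)
            except Exception as exc:
                for cyc in cfg.cycle_counts:
                    rows.append({"sweep_value": value, "seed": seed,
                                 "cycles": cyc, "error": f"simulate: {exc}"})
                continue
            for cyc in cfg.cycle_counts:
                row = {"sweep_value": value, "seed": seed, "cycles": cyc,
                       "error": ""}
                try:
                    ds = ds_full.restrict(0.0, cycles_to_duration(net, cyc))
                    est_cfg = EstimatorConfig(
                        **{**asdict(cfg.estimator), "subset": subset}
                    )
                    estimates = fit_network(ds, est_cfg)
                    pair_est = {
                        (r, j): e.couplings[j]
                        for r, e in estimates.items()
                        for j in e.sender_ids
                    }
                    zero = FourierInteraction(a=[0.0], b=[0.0])
                    dists = [
                        l2_distance(net.couplings.get((r, j), zero), f)
                        for (r, j), f in pair_est.items()
                    ]
                    inf = infer_connections(pair_est, truth=net.adjacency)
                    bin_ms = max(cfg.coherence_bins_per_period) * net.mean_period
                    coh = coherence(ds, bin_ms)
                    row.update(
                        mean_l2=float(np.mean(dists)),
                        median_l2=float(np.median(dists)),
                        mcc=inf.mcc,
                        threshold=inf.threshold,
                        kappa_mean=coh.kappa_mean[bin_ms],
                        n_pairs=len(dists),
                    )
                except Exception as exc:
                    row["error"] = f"estimate: {exc}"
                rows.append(row)
    df = pd.DataFrame(rows)
    manifest = RunManifest(
        config_hash=hashlib.sha256(cfg.canonical_json().encode()).hexdigest(),
        master_seed=master_seed,
        software_version=_pkg_version,
        runtimes_s={"total": time.perf_counter() - t_run0},
        output_checksums={
            "results": hashlib.sha256(
                df.drop(columns=["error"]).round(12).to_csv(index=False).encode()
            ).hexdigest()
        },
    )
    return df, manifest
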