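"""File formats: spike-train data, model files, and fit-trace archives.

Spike data use a plain-text, diff-able format, one trial per line:

    # latentlangevin-spikes v1
    # design: reaction-time
    # time_unit: second
    <trial_id> <t_start> <t_end> <n_spikes> <t_1> ... <t_N>

Times are absolute within a trial (clocks need not be aligned across
trials) and serialized with ``repr`` so the round trip is exact.

Models are JSON (grid spec, nodal Phi/p0/f, D, boundary mode, free-form
provenance); fit traces are NumPy ``.npz`` archives, one array stacked
over iterations per model component.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .grid import make_grid
from .inference import FitTrace
from .model import Dataset, LatentModel, TrialObservations

__all__ = [
    "read_spike_data",
    "write_spike_data",
    "read_model",
    "write_model",
    "read_trace",
    "write_trace",
]

SPIKE_MAGIC = "# latentlangevin-spikes v1"
MODEL_FORMAT_VERSION = 1


def write_spike_data(data: Dataset, path) -> None:
    lines = [SPIKE_MAGIC, f"# design: {data.design}", "# time_unit: second"]
    for i, t in enumerate(data.trials):
        tid = t.trial_id if t.trial_id is not None else i
        fields = [str(tid), repr(float(t.t_start)), repr(float(t.t_end)),
                  str(t.n_spikes)]
        fields += [repr(float(s)) for s in t.spike_times]
        lines.append(" ".join(fields))
    Path(path).write_text("\n".join(lines) + "\n")


def read_spike_data(path) -> Dataset:
    lines = Path(path).read_text().splitlines()
    if not lines or lines[0].strip() != SPIKE_MAGIC:
        raise ValueError(f"{path}: not a latentlangevin spike file (bad header)")
    design = None
    trials = []
    for ln in lines[1:]:
        ln = ln.strip()
        if not ln:
            continue
        if ln.startswith("#"):
            if ln.startswith("# design:"):
                design = ln.split(":", 1)[1].strip()
            continue
        parts = ln.split()
        if len(parts) < 4:
            raise ValueError(f"{path}: malformed trial record {ln!r}")
        tid = int(parts[0])
        try:
            t0, t_end = float(parts[1]), float(parts[2])
            n = int(parts[3])
            spikes = np.array([float(v) for v in parts[4:]])
        except ValueError as e:
            raise ValueError(f"{path}: trial {tid}: unparseable field ({e})")
        if len(spikes) != n:
            raise ValueError(
                f"{path}: trial {tid}: spike count field {n} does not match "
                f"{len(spikes)} listed times"
            )
        try:
            trials.append(
                TrialObservations(t_start=t0, spike_times=spikes, t_end=t_end,
                                  design=design, trial_id=tid)
            )
        except ValueError as e:
            raise ValueError(f"{path}: trial {tid}: {e}")
    if design is None:
        raise ValueError(f"{path}: missing '# design:' header")
    if not trials:
        raise ValueError(f"{path}: no trials")
    return Dataset(trials=tuple(trials), design=design)


def write_model(model: LatentModel, path, provenance: dict | None = None) -> None:
    doc = {
        "format_version": MODEL_FORMAT_VERSION,
        "grid": {"n_points": model.grid.n_points,
                 "rule": "gauss-lobatto-legendre"},
        "potential": model.potential.tolist(),
        "p0": model.p0.tolist(),
        "rate_fn": model.rate_fn.tolist(),
        "noise": model.noise,
        "boundary_mode": model.boundary_mode,
        "provenance": provenance or {},
    }
    Path(path).write_text(json.dumps(doc, indent=1))


def read_model(path) -> LatentModel:
    doc = json.loads(Path(path).read_text())
    if doc.get("format_version") != MODEL_FORMAT_VERSION:
        raise ValueError(f"{path}: unsupported model format version")
    grid = make_grid(int(doc["grid"]["n_points"]))
    return LatentModel(
        grid=grid,
        potential=np.asarray(doc["potential"], dtype=float),
        noise=float(doc["noise"]),
        p0=np.asarray(doc["p0"], dtype=float),
        rate_fn=np.asarray(doc["rate_fn"], dtype=float),
        boundary_mode=doc["boundary_mode"],
    )


def write_trace(trace: FitTrace, path) -> None:
    m0 = trace.models[0]
    np.savez_compressed(
        path,
        n_points=m0.grid.n_points,
        boundary_mode=np.asarray(m0.boundary_mode),
        rate_fn=m0.rate_fn,
        potentials=np.stack([m.potential for m in trace.models]),
        p0s=np.stack([m.p0 for m in trace.models]),
        noises=np.array([m.noise for m in trace.models]),
        logliks=trace.logliks,
        complexities=(trace.complexities if trace.complexities is not None
                      else np.full(len(trace), np.nan)),
    )


def read_trace(path) -> FitTrace:
    with np.load(path, allow_pickle=False) as z:
        grid = make_grid(int(z["n_points"]))
        mode = str(z["boundary_mode"])
        rate = z["rate_fn"]
        models = [
            LatentModel(grid=grid, potential=phi, noise=float(D), p0=p0,
                        rate_fn=rate, boundary_mode=mode)
            for phi, p0, D in zip(z["potentials"], z["p0s"], z["noises"])
        ]
        compl = z["complexities"]
        return FitTrace(
            models=models,
            logliks=z["logliks"],
            complexities=None if np.all(np.isnan(compl)) else compl,
        )
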