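"""Persistence: experiment configs (YAML), rasters (CSV), weights (NPZ)."""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import yaml

from .drivers import ExperimentConfig, RunRecord
from .engine import SpikeRaster
from .model import ConfigurationError, ModelSpec


def write_config(cfg: ExperimentConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(dataclasses.asdict(cfg),
                                         sort_keys=False))


def read_config(path) -> ExperimentConfig:
    data = yaml.safe_load(Path(path).read_text())
    if not isinstance(data, dict):
        raise ConfigurationError(f"malformed config file {path}")
    fields = {f.name for f in dataclasses.fields(ExperimentConfig)}
    unknown = set(data) - fields
    if unknown:
        raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
    return ExperimentConfig(**data)


def write_raster(raster: SpikeRaster, path) -> None:
    """Delimited text: one 'time_ms,neuron_id' row per event, with the
    population layout in '#'-prefixed header lines."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# duration_ms={raster.duration}\n")
        fh.write("# populations="
                 + json.dumps({k: list(v) for k, v in
                               raster.populations.items()}) + "\n")
        fh.write("time_ms,neuron_id\n")
        for t, i in zip(raster.times, raster.ids):
            fh.write(f"{t:.1f},{int(i)}\n")


def read_raster(path) -> SpikeRaster:
    path = Path(path)
    duration = 0.0
    populations: dict = {}
    times, ids = [], []
    with path.open() as fh:
        for line in fh:
            line = line.strip()
            if line.startswith("# duration_ms="):
                duration = float(line.split("=", 1)[1])
            elif line.startswith("# populations="):
                raw = json.loads(line.split("=", 1)[1])
                populations = {k: tuple(v) for k, v in raw.items()}
            elif not line or line.startswith(("#", "time_ms")):
                continue
            else:
                t, i = line.split(",")
                times.append(float(t))
                ids.append(int(i))
    return SpikeRaster(times=np.asarray(times),
                       ids=np.asarray(ids, dtype=np.int32),
                       duration=duration, populations=populations)


def write_weights(model: ModelSpec, path, plastic_only: bool = True) -> None:
    """Dense per-block weight matrices in an .npz container with block
    metadata (source/target populations and plasticity rule)."""
    blocks = model.plastic_blocks() if plastic_only else model.blocks
    arrays = {f"W::{b.name}": b.W for b in blocks}
    arrays["meta"] = np.array(json.dumps(
        [{"name": b.name, "source": b.source, "target": b.target,
          "plastic": b.plastic, "rule": b.rule} for b in blocks]))
    np.savez_compressed(path, **arrays)


def load_weights(model: ModelSpec, path) -> None:
    """Load matching blocks' weights into ``model`` in place."""
    with np.load(path, allow_pickle=False) as data:
        for key in data.files:
            if not key.startswith("W::"):
                continue
            name = key[3:]
            blk = model.block(name)
            W = data[key]
            if W.shape != blk.W.shape:
                raise ConfigurationError(
                    f"stored block {name} has shape {W.shape}, model "
                    f"expects {blk.W.shape}")
            blk.W[...] = W


def write_record(record: RunRecord, path) -> None:
    """Error curves of a learning run as JSON."""
    out = {
        "config": dataclasses.asdict(record.config),
        "evaluations": [
            {"presentation": ev["presentation"],
             "errors": {name: {"motif_error": r.motif_error,
                               "ordering_error": r.ordering_error,
                               "total_error": r.total_error,
                               "per_trial": list(map(float, r.per_trial))}
                        for name, r in ev["errors"].items()}}
            for ev in record.evaluations],
    }
    Path(path).write_text(json.dumps(out, indent=1, allow_nan=True))
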