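"""Clock-driven simulation loop coupling dynamics, plasticity and stimuli.

One engine step: sample external (baseline + scheduled) Poisson input,
decay/inject conductances, advance membranes, deliver this step's spikes to
the next step's conductances (scaled by the short-term depression variable
where a population uses it), update plasticity traces and plastic weights,
record events. Spikes emitted at step k affect conductances from step k+1;
there are no further transmission delays.

Each population draws its external input from its own RNG stream (spawned
from the master seed), so perturbing or re-scheduling one population leaves
every other population's input realization unchanged. Identical
(model, schedule, config, seed) produce bit-identical rasters.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .dynamics import (
    IntegrationError,
    State,
    init_state,
    sample_external_input,
    step_neurons,
    update_conductances,
)
from .model import ConfigurationError, ModelSpec
from .params import DepressionParams
from .plasticity import (
    apply_short_term_depression,
    apply_stdp,
    update_traces,
)
from .protocols import OverrideEntry, StimulusSchedule


@dataclass
class SimulationConfig:
    duration: float                 # ms of protocol time (after warm-up)
    dt: float = 0.1                 # ms
    seed: int = 0
    plasticity_on: bool = False
    record: bool = True
    warmup: float = 0.0             # ms of background-only settling
    snapshot_interval: Optional[float] = None   # ms between weight snapshots

    def __post_init__(self) -> None:
        if self.duration < 0:
            raise ConfigurationError("duration must be non-negative")
        if self.dt <= 0:
            raise ConfigurationError("dt must be positive")
        if self.warmup < 0:
            raise ConfigurationError("warmup must be non-negative")


@dataclass
class SpikeRaster:
    """Spike events (time ms, global neuron id), time-sorted, with the
    population layout needed to interpret the ids."""

    times: np.ndarray
    ids: np.ndarray
    duration: float
    populations: dict[str, tuple[int, int, str, Optional[int]]]  # start,size,kind,n_clusters

    @classmethod
    def layout_of(cls, model: ModelSpec) -> dict:
        return {name: (p.start, p.size, p.kind, p.n_clusters)
                for name, p in model.populations.items()}

    def pop_events(self, name: str) -> tuple[np.ndarray, np.ndarray]:
        """(times, local ids) of one population."""
        start, size, _, _ = self.populations[name]
        m = (self.ids >= start) & (self.ids < start + size)
        return self.times[m], self.ids[m] - start

    def cluster_events(self, name: str, cluster: int
                       ) -> tuple[np.ndarray, np.ndarray]:
        start, size, _, n_clusters = self.populations[name]
        if not n_clusters:
            raise ConfigurationError(f"population {name} has no clusters")
        cs = size // n_clusters
        a = start + cluster * cs
        m = (self.ids >= a) & (self.ids < a + cs)
        return self.times[m], self.ids[m] - a

    @property
    def n_events(self) -> int:
        return self.times.size


@dataclass
class SimResult:
    raster: SpikeRaster
    final_weights: dict[str, np.ndarray]
    snapshots: list = field(default_factory=list)   # (t_ms, {name: W copy})


def apply_perturbation(schedule: StimulusSchedule, subset: tuple,
                       t0: float, duration: float = 250.0
                       ) -> StimulusSchedule:
    """Return a schedule whose baseline excitatory external input is zeroed
    for ``subset = (population, local indices or None)`` in
    [t0, t0 + duration). A zero-length window leaves the schedule unchanged."""
    pop, idx = subset
    out = StimulusSchedule(duration=schedule.duration)
    out.entries = list(schedule.entries)
    out.overrides = list(schedule.overrides)
    if duration > 0:
        if idx is not None and len(idx) == 0:
            raise ConfigurationError("perturbation subset is empty")
        out.overrides.append(OverrideEntry(pop, idx, t0, t0 + duration))
    return out


def _resolve_idx(model: ModelSpec, pop: str, idx) -> np.ndarray:
    p = model.pop(pop)
    if idx is None:
        return np.arange(p.start, p.stop)
    idx = np.asarray(idx, dtype=int)
    if idx.size and (idx.min() < 0 or idx.max() >= p.size):
        raise ConfigurationError(
            f"indices out of range for population {pop}")
    return p.start + idx


def run(model: ModelSpec, schedule: StimulusSchedule | None,
        config: SimulationConfig) -> SimResult:
    """Simulate ``model`` under ``schedule`` and return raster + weights.

    The warm-up period (background input only, plasticity frozen) precedes
    the protocol; raster times are relative to the end of the warm-up.
    Plastic weight matrices are updated in place on the model, so driver
    loops carry learning across calls.
    """
    if schedule is None:
        schedule = StimulusSchedule()
    neuron, syn = model.neuron, model.synapse
    dt = config.dt
    n = model.n_neurons
    pops = list(model.populations.values())

    ss = np.random.SeedSequence(config.seed)
    children = ss.spawn(len(pops) + 1)
    rng_init = np.random.default_rng(children[0])
    pop_rngs = [np.random.default_rng(c) for c in children[1:]]

    state = init_state(model.exc_mask, neuron, rng_init)
    exc = state.exc

    W_ext = np.where(exc, syn.W_ext_E, syn.W_ext_I)
    base_rate = np.where(exc, syn.r_ext_E, syn.r_ext_I)
    for p in pops:
        if p.ext_rate is not None:
            base_rate[p.sl] = p.ext_rate
    base_on = np.ones(n)               # perturbation mask on baseline input
    extra = {"exc": np.zeros(n), "inh": np.zeros(n)}

    warm_steps = int(round(config.warmup / dt))
    total_steps = warm_steps + int(round(config.duration / dt))

    # event boundaries: step -> list of (channel/'base', global idx, delta)
    bounds: dict[int, list] = {}

    def _step_of(t: float) -> int:
        return warm_steps + int(round(t / dt))

    for e in schedule.entries:
        gidx = _resolve_idx(model, e.pop, e.idx)
        s0, s1 = _step_of(e.t0), _step_of(e.t1)
        if s1 > s0 and e.rate_kHz > 0:
            bounds.setdefault(s0, []).append((e.channel, gidx, e.rate_kHz))
            bounds.setdefault(s1, []).append((e.channel, gidx, -e.rate_kHz))
    for o in schedule.overrides:
        gidx = _resolve_idx(model, o.pop, o.idx)
        s0, s1 = _step_of(o.t0), _step_of(o.t1)
        if s1 > s0:
            bounds.setdefault(s0, []).append(("base", gidx, -1.0))
            bounds.setdefault(s1, []).append(("base", gidx, 1.0))

    # plasticity traces, shared per (population, time constant)
    plastic = model.plastic_blocks()
    traces: dict[tuple[str, float], np.ndarray] = {}
    for blk in plastic:
        tau = blk.plasticity.tau
        for pname in (blk.source, blk.target):
            traces.setdefault((pname, tau), np.zeros(model.pop(pname).size))

    dep_pops = [p for p in pops if p.depression]
    dep_params = DepressionParams()

    lam = np.maximum(base_rate * base_on + extra["exc"], 0.0) * dt
    lam_inh = extra["inh"] * dt
    inh_active = False

    rec_t: list[np.ndarray] = []
    rec_i: list[np.ndarray] = []
    snap_every = (int(round(config.snapshot_interval / dt))
                  if config.snapshot_interval else 0)
    snapshots: list = []

    prev_idx = np.empty(0, dtype=np.intp)
    imp_exc = np.zeros(n)
    imp_inh = np.zeros(n)
    blocks = model.blocks
    blk_src = [model.pop(b.source) for b in blocks]
    blk_tgt = [model.pop(b.target) for b in blocks]

    for step in range(total_steps):
        if step in bounds:
            for channel, gidx, delta in bounds[step]:
                if channel == "base":
                    base_on[gidx] += delta
                else:
                    extra[channel][gidx] += delta
            np.clip(base_on, 0.0, 1.0, out=base_on)
            lam = np.maximum(base_rate * base_on + extra["exc"], 0.0) * dt
            lam_inh = np.maximum(extra["inh"], 0.0) * dt
            inh_active = bool(np.any(lam_inh > 0))

        imp_exc[:] = 0.0
        imp_inh[:] = 0.0
        for p, rng in zip(pops, pop_rngs):
            counts = rng.poisson(lam[p.sl])
            imp_exc[p.sl] = counts * W_ext[p.sl]
            if inh_active:
                sub = lam_inh[p.sl]
                if np.any(sub > 0):
                    imp_inh[p.sl] = rng.poisson(sub) * W_ext[p.sl]

        # deliver previous step's recurrent spikes
        if prev_idx.size:
            prev_mask = np.zeros(n, dtype=bool)
            prev_mask[prev_idx] = True
            for blk, src, tgt in zip(blocks, blk_src, blk_tgt):
                local = np.flatnonzero(prev_mask[src.sl])
                if not local.size:
                    continue
                contrib = blk.W[:, local]
                if src.depression:
                    contrib = contrib * state.x_d[src.start + local]
                summed = contrib.sum(axis=1)
                if src.kind == "E":
                    imp_exc[tgt.sl] += summed
                else:
                    imp_inh[tgt.sl] += summed

        update_conductances(state, syn, imp_exc, imp_inh, dt)
        try:
            spikes = step_neurons(state, neuron, syn, dt)
        except IntegrationError as err:
            t_ms = (step - warm_steps) * dt
            raise IntegrationError(
                f"{err} at step {step} (t = {t_ms:.1f} ms)") from err

        for p in dep_pops:
            apply_short_term_depression(state.x_d[p.sl], spikes[p.sl], dt,
                                        dep_params)

        if config.plasticity_on and step >= warm_steps and plastic:
            for (pname, tau), y in traces.items():
                update_traces(y, spikes[model.pop(pname).sl], tau, dt)
            for blk, src, tgt in zip(blocks, blk_src, blk_tgt):
                if not blk.plastic:
                    continue
                pp = blk.plasticity
                apply_stdp(blk.W,
                           traces[(blk.source, pp.tau)],
                           traces[(blk.target, pp.tau)],
                           spikes[src.sl], spikes[tgt.sl], pp, dt)

        idx = np.flatnonzero(spikes)
        if config.record and step >= warm_steps and idx.size:
            rec_t.append(np.full(idx.size, (step - warm_steps + 1) * dt))
            rec_i.append(idx.astype(np.int32))
        if snap_every and step >= warm_steps and \
                (step - warm_steps + 1) % snap_every == 0:
            snapshots.append(((step - warm_steps + 1) * dt,
                              {b.name: b.W.copy() for b in plastic}))
        prev_idx = idx

    times = (np.concatenate(rec_t) if rec_t else np.empty(0))
    ids = (np.concatenate(rec_i) if rec_i else np.empty(0, dtype=np.int32))
    raster = SpikeRaster(times=times, ids=ids, duration=config.duration,
                         populations=SpikeRaster.layout_of(model))
    final = {b.name: b.W for b in plastic}
    return SimResult(raster=raster, final_weights=final, snapshots=snapshots)
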