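"""Experiment drivers: end-to-end learning, replay and capacity protocols.

These functions reproduce the study protocols: repeated supervised target
presentations with periodic evaluation (spontaneous replays scored against
one or more targets), relearning with a target switch, perturbed replays,
and multi-sequence learning with attentional gating. Each presentation and
each replay is an independent simulation from a cold start (the plastic
weights persist on the model between runs).
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .engine import SimResult, SimulationConfig, SpikeRaster, apply_perturbation, run
from .metrics import ErrorReport, motif_error, ordering_error, total_error
from .model import (
    ConfigurationError,
    ModelSpec,
    assemble_hierarchical,
    assemble_serial,
    motif_labels,
)
from .protocols import (
    MotifTemplate,
    StimulusSchedule,
    TargetSequence,
    compose_target,
    learning_schedule,
    make_motif,
    spontaneous_schedule,
)

log = logging.getLogger("motifnet")


@dataclass
class ExperimentConfig:
    """Validated description of a complete learning experiment."""

    kind: str = "hierarchical"          # hierarchical | serial
    n_motifs: int = 2
    n_sequences: int = 1
    scale: float = 1.0
    variant: str = "excitatory"
    seed: int = 0
    # protocol
    order: str = "AAB"
    motif_duration: float = 200.0       # ms
    n_groups: int = 5                   # stimulation blocks per motif
    gap: float = 150.0                  # ms silent period after each motif
    presentations: int = 50
    eval_every: int = 5                 # evaluate after every k-th presentation
    eval_replays: int = 3               # spontaneous replays per evaluation
    rate_multiplier: float = 1.0        # learning-rate scaling
    supervisor_rate: float = 50.0       # kHz; reduced-scale runs use more
    fc_start_rate: float = 50.0         # kHz; fast-clock start current
    replay_margin: float = 100.0        # extra replay time beyond the target

    def __post_init__(self) -> None:
        if self.kind not in ("hierarchical", "serial"):
            raise ConfigurationError(f"unknown model kind {self.kind!r}")
        if self.presentations < 0 or self.eval_replays < 1:
            raise ConfigurationError("bad protocol sizes")
        if self.eval_every < 1:
            raise ConfigurationError("eval_every must be >= 1")
        labels = set(motif_labels(self.n_motifs))
        if not set(self.order) <= labels:
            raise ConfigurationError(
                f"order {self.order!r} uses labels outside {sorted(labels)}")


@dataclass
class RunRecord:
    """Evaluation history of one learning run."""

    config: ExperimentConfig
    evaluations: list = field(default_factory=list)
    # each entry: {"presentation": k, "errors": {target_name: ErrorReport}}

    def curve(self, target_name: str, which: str = "total_error"
              ) -> tuple[np.ndarray, np.ndarray]:
        xs, ys = [], []
        for ev in self.evaluations:
            if target_name in ev["errors"]:
                xs.append(ev["presentation"])
                ys.append(getattr(ev["errors"][target_name], which))
        return np.asarray(xs), np.asarray(ys)


def build_model(cfg: ExperimentConfig) -> ModelSpec:
    if cfg.kind == "serial":
        return assemble_serial(cfg.n_motifs, cfg.n_sequences, cfg.scale,
                               seed=cfg.seed)
    return assemble_hierarchical(cfg.n_motifs, cfg.n_sequences, cfg.scale,
                                 variant=cfg.variant, seed=cfg.seed)


def make_target(model: ModelSpec, cfg: ExperimentConfig,
                order: str | None = None) -> TargetSequence:
    labels = model.motif_labels
    motifs = {lab: make_motif(lab, cfg.motif_duration, cfg.n_groups)
              for lab in labels}
    first = model.readout_pops()[0]
    n_re = model.pop(first).size
    order = cfg.order if order is None else order
    return compose_target(motifs, order, [cfg.gap] * len(order),
                          n_exc_per_motif=n_re)


def scale_learning_rate(model: ModelSpec, factor: float) -> None:
    """Multiply the potentiation/depression amplitudes of every plastic
    block by ``factor`` (bounds unchanged)."""
    if factor == 1.0:
        return
    for blk in model.plastic_blocks():
        pp = blk.plasticity
        blk.plasticity = dataclasses.replace(
            pp, A_pot=pp.A_pot * factor, A_dep=pp.A_dep * factor)


def evaluate(model: ModelSpec, targets: dict[str, TargetSequence],
             cfg: ExperimentConfig, seed: int, sequence: int = 0,
             attended: int | None = None,
             with_motif_errors: bool = False) -> dict[str, ErrorReport]:
    """Score spontaneous replays against each target.

    ``cfg.eval_replays`` independent replays are simulated; total and
    ordering errors are averaged across replays per target. Motif errors
    (decoupled fast-clock protocol) are computed once per motif label when
    requested; for the serial model the motif error is not defined and is
    reported as NaN.
    """
    reports: dict[str, ErrorReport] = {}
    replays: list[SpikeRaster] = []
    dur = max(t.duration for t in targets.values()) + cfg.replay_margin
    for r in range(cfg.eval_replays):
        sched = spontaneous_schedule(model, dur, attended)
        res = run(model, sched, SimulationConfig(duration=dur,
                                                 seed=seed + 17 * r))
        replays.append(res.raster)
    serial = model.meta["kind"] == "serial"
    for name, tgt in targets.items():
        totals = [total_error(model, r, tgt, sequence) for r in replays]
        if serial:
            orders = [np.nan]
        else:
            orders = [ordering_error(model, r, tgt, sequence)
                      for r in replays]
        if with_motif_errors and not serial:
            mot = float(np.mean([motif_error(model, tgt, lab,
                                             seed=seed + 31 * i)
                                 for i, lab in enumerate(tgt.labels)]))
        else:
            mot = np.nan
        reports[name] = ErrorReport(
            motif_error=mot,
            ordering_error=float(np.nanmean(orders)),
            total_error=float(np.mean(totals)),
            per_trial=totals)
    return reports


def cmd_learn(cfg: ExperimentConfig, model: ModelSpec | None = None,
              eval_targets: dict[str, TargetSequence] | None = None,
              record: RunRecord | None = None,
              presentation_offset: int = 0,
              attended: int | None = None,
              with_motif_errors: bool = False) -> tuple[ModelSpec, RunRecord]:
    """Run a learning phase: repeated supervised presentations of
    ``cfg.order`` with periodic evaluation.

    Pass an existing ``model``/``record`` to continue (e.g. relearning with
    a different ``cfg.order``); ``eval_targets`` are scored at every
    evaluation (default: the trained target only).
    """
    if model is None:
        model = build_model(cfg)
    scale_learning_rate(model, cfg.rate_multiplier)
    try:
        target = make_target(model, cfg)
        if eval_targets is None:
            eval_targets = {cfg.order: target}
        if record is None:
            record = RunRecord(config=cfg)
            reports = evaluate(model, eval_targets, cfg, seed=cfg.seed + 7,
                               attended=attended,
                               with_motif_errors=with_motif_errors)
            record.evaluations.append(
                {"presentation": presentation_offset, "errors": reports})
            _log_eval(presentation_offset, reports)
        sched = learning_schedule(model, target, n_presentations=1,
                                  sequence=attended or 0,
                                  supervisor_rate=cfg.supervisor_rate,
                                  fc_start_rate=cfg.fc_start_rate)
        for k in range(1, cfg.presentations + 1):
            pk = presentation_offset + k
            run(model, sched,
                SimulationConfig(duration=target.duration,
                                 seed=cfg.seed + 1000 + 13 * pk,
                                 plasticity_on=True))
            if k % cfg.eval_every == 0 or k == cfg.presentations:
                reports = evaluate(model, eval_targets, cfg,
                                   seed=cfg.seed + 7 + 101 * pk,
                                   attended=attended,
                                   with_motif_errors=with_motif_errors)
                record.evaluations.append(
                    {"presentation": pk, "errors": reports})
                _log_eval(pk, reports)
    finally:
        scale_learning_rate(model, 1.0 / cfg.rate_multiplier)
    return model, record


def _log_eval(k: int, reports: dict[str, ErrorReport]) -> None:
    parts = [f"{name}: total={r.total_error:.3f} order={r.ordering_error:.3f}"
             for name, r in reports.items()]
    log.info("presentation %d | %s", k, "; ".join(parts))


def learn_two_sequences(cfg: ExperimentConfig, orders: tuple[str, str],
                        iterations: int, seed_offset: int = 0
                        ) -> tuple[ModelSpec, dict[str, TargetSequence]]:
    """Alternate supervised presentations of two sequences, gating the
    interneuron networks with the attentional inhibitory drive."""
    cfg = dataclasses.replace(cfg, n_sequences=2)
    model = build_model(cfg)
    scale_learning_rate(model, cfg.rate_multiplier)
    targets = {o: make_target(model, cfg, order=o) for o in orders}
    scheds = {}
    for s, o in enumerate(orders):
        base = learning_schedule(model, targets[o], sequence=s,
                                 supervisor_rate=cfg.supervisor_rate,
                                 fc_start_rate=cfg.fc_start_rate)
        att = spontaneous_schedule(model, targets[o].duration,
                                   attended_sequence=s)
        # attention drive without the duplicate start kick
        att.entries = [e for e in att.entries if e.channel == "inh"]
        scheds[s] = base.merged(att)
    for k in range(iterations):
        s = k % 2
        o = orders[s]
        run(model, scheds[s],
            SimulationConfig(duration=targets[o].duration,
                             seed=cfg.seed + seed_offset + 211 * k,
                             plasticity_on=True))
    scale_learning_rate(model, 1.0 / cfg.rate_multiplier)
    return model, targets


def cmd_replay(model: ModelSpec, target: TargetSequence,
               cfg: ExperimentConfig | None = None, seed: int = 0,
               attended: int | None = None,
               perturb: tuple | None = None,
               duration: float | None = None) -> tuple[SpikeRaster, ErrorReport]:
    """One spontaneous replay, optionally perturbed.

    ``perturb = (population, local indices or None, t0, duration_ms)``
    removes the baseline excitatory external input of that subset during
    the window.
    """
    cfg = cfg or ExperimentConfig()
    dur = duration or target.duration + cfg.replay_margin
    sched = spontaneous_schedule(model, dur, attended)
    if perturb is not None:
        pop, idx, t0, pdur = perturb
        sched = apply_perturbation(sched, (pop, idx), t0, pdur)
    res = run(model, sched, SimulationConfig(duration=dur, seed=seed))
    serial = model.meta["kind"] == "serial"
    rep = ErrorReport(
        motif_error=np.nan,
        ordering_error=(np.nan if serial else
                        ordering_error(model, res.raster, target,
                                       attended or 0)),
        total_error=total_error(model, res.raster, target, attended or 0))
    return res.raster, rep
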