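"""Target sequences and stimulus schedules for learning and replay.

A *motif* is a short (<= one fast-clock period) spatiotemporal pattern on a
read-out network: the motif's excitatory neurons are partitioned into
ordered groups, each stimulated for an equal share of the motif duration.
A *target sequence* strings motifs together with silent gaps; its total
length (through the last motif) must fit within one slow-clock period.

Schedules are pure data: lists of time-windowed Poisson drives (and
zero-rate override windows) that the engine resolves against a model.
Supervisor and start/stop "currents" are realized as Poisson spike sources
at the stated kHz rates delivered through the external synapses.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .model import ConfigurationError, ModelSpec, PERIOD_FAST, PERIOD_SLOW

#: protocol drive constants (kHz, ms)
START_RATE = 5.0           # slow-clock / serial-clock start current
START_DURATION = 10.0
FC_START_RATE = 50.0       # fast-clock start current at each motif onset
FC_START_DURATION = 40.0
SUPERVISOR_RATE = 50.0     # supervisor drive to read-out groups
STOP_RATE = 50.0           # fast-clock stop signal (same rate as the start)
STOP_DURATION = 10.0
ATTENTION_RATE = 20.0      # inhibitory drive silencing non-attended syntax


@dataclass(frozen=True)
class DriveEntry:
    """Poisson drive at ``rate_kHz`` to ``idx`` (local indices, None = all)
    of population ``pop`` over [t0, t1), through the 'exc' or 'inh'
    conductance channel."""

    pop: str
    idx: object                # np.ndarray of local indices, or None
    rate_kHz: float
    channel: str               # 'exc' | 'inh'
    t0: float
    t1: float

    def __post_init__(self) -> None:
        if self.idx is not None:
            # hashable/comparable form keeps schedules pure data
            object.__setattr__(self, "idx",
                               tuple(int(i) for i in np.atleast_1d(self.idx)))
        if self.rate_kHz < 0:
            raise ConfigurationError("rates must be non-negative")
        if self.channel not in ("exc", "inh"):
            raise ConfigurationError(f"unknown channel {self.channel!r}")
        if self.t1 < self.t0:
            raise ConfigurationError("drive window must have t1 >= t0")


@dataclass(frozen=True)
class OverrideEntry:
    """Zero the baseline excitatory external input of a neuron subset."""

    pop: str
    idx: object
    t0: float
    t1: float


@dataclass
class StimulusSchedule:
    """Time-windowed external drives plus perturbation overrides."""

    entries: list = field(default_factory=list)
    overrides: list = field(default_factory=list)
    duration: float = 0.0

    def add(self, pop: str, idx, rate_kHz: float, channel: str,
            t0: float, t1: float) -> None:
        self.entries.append(DriveEntry(pop, idx, rate_kHz, channel, t0, t1))
        self.duration = max(self.duration, t1)

    def shifted(self, offset: float) -> "StimulusSchedule":
        out = StimulusSchedule(duration=self.duration + offset)
        out.entries = [replace(e, t0=e.t0 + offset, t1=e.t1 + offset)
                       for e in self.entries]
        out.overrides = [replace(o, t0=o.t0 + offset, t1=o.t1 + offset)
                         for o in self.overrides]
        return out

    def merged(self, other: "StimulusSchedule") -> "StimulusSchedule":
        out = StimulusSchedule(duration=max(self.duration, other.duration))
        out.entries = self.entries + other.entries
        out.overrides = self.overrides + other.overrides
        return out


# ---------------------------------------------------------------------------
# motifs and targets


@dataclass(frozen=True)
class MotifTemplate:
    """One motif: ``n_groups`` sequential equal-length stimulation blocks
    over an ordered partition of the read-out's excitatory neurons."""

    label: str
    duration: float            # ms
    n_groups: int

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ConfigurationError("motif duration must be positive")
        if self.n_groups < 1:
            raise ConfigurationError("need at least one group")

    def group_bounds(self, n_neurons: int) -> list[tuple[int, int]]:
        """Neuron index ranges of the groups (remainder to the last group)."""
        base = n_neurons // self.n_groups
        bounds = [(g * base, (g + 1) * base) for g in range(self.n_groups)]
        g0, _ = bounds[-1]
        bounds[-1] = (g0, n_neurons)
        return bounds

    def block_duration(self) -> float:
        return self.duration / self.n_groups


def make_motif(label: str, duration: float, n_groups: int) -> MotifTemplate:
    """Build a motif of ``n_groups`` sequential ``duration/n_groups`` ms
    stimulation blocks."""
    return MotifTemplate(label=label, duration=duration, n_groups=n_groups)


@dataclass
class TargetSequence:
    """An ordered arrangement of motifs with silent gaps.

    ``matrix`` is the binary target over all read-out excitatory neurons
    (motif-label order) x 1 ms time bins. ``onsets``/``offsets`` give each
    motif occurrence's window; ``gaps[k]`` follows occurrence ``k`` (the
    trailing gap is included).
    """

    motifs: dict[str, MotifTemplate]
    order: list[str]
    gaps: list[float]
    n_exc_per_motif: int
    matrix: np.ndarray
    onsets: np.ndarray
    offsets: np.ndarray

    @property
    def duration(self) -> float:
        return float(self.matrix.shape[1])

    @property
    def labels(self) -> list[str]:
        return sorted(self.motifs)

    def motif_row_slice(self, label: str) -> slice:
        m = self.labels.index(label)
        n = self.n_exc_per_motif
        return slice(m * n, (m + 1) * n)

    def motif_target(self, label: str) -> np.ndarray:
        """Binary target of a single motif (neurons x 1 ms bins)."""
        tpl = self.motifs[label]
        n = self.n_exc_per_motif
        T = int(round(tpl.duration))
        mat = np.zeros((n, T))
        block = tpl.duration / tpl.n_groups
        for g, (a, b) in enumerate(tpl.group_bounds(n)):
            mat[a:b, int(round(g * block)):int(round((g + 1) * block))] = 1.0
        return mat

    def interneuron_target(self, group_size: int) -> np.ndarray:
        """Binary target for an interneuron network: one group per motif
        (label order) active during that motif's occurrences, the 'silent'
        group active during the gaps."""
        labels = self.labels
        n_groups = len(labels) + 1
        T = self.matrix.shape[1]
        mat = np.zeros((n_groups * group_size, T))
        for k, lab in enumerate(self.order):
            g = labels.index(lab)
            a, b = int(round(self.onsets[k])), int(round(self.offsets[k]))
            mat[g * group_size:(g + 1) * group_size, a:b] = 1.0
            gap_end = min(int(round(b + self.gaps[k])), T)
            mat[-group_size:, b:gap_end] = 1.0
        return mat


def compose_target(motifs: dict[str, MotifTemplate], order, gaps,
                   n_exc_per_motif: int = 300,
                   slow_period: float = PERIOD_SLOW) -> TargetSequence:
    """Compose motifs into a target sequence.

    ``order`` is a sequence of motif labels (a string like ``"AAB"`` works);
    ``gaps`` gives one silent duration per occurrence, the trailing gap
    included. The sequence through the last motif offset must fit within one
    slow-clock period (10% slack for the period's variability).
    """
    order = list(order)
    gaps = [float(g) for g in (gaps if np.iterable(gaps)
                               else [gaps] * len(order))]
    if len(gaps) != len(order):
        raise ConfigurationError("need one gap per motif occurrence")
    if any(g < 0 for g in gaps):
        raise ConfigurationError("gaps must be non-negative")
    for lab in order:
        if lab not in motifs:
            raise ConfigurationError(f"no template for motif {lab!r}")

    labels = sorted(motifs)
    onsets, offsets = [], []
    t = 0.0
    for k, lab in enumerate(order):
        onsets.append(t)
        t += motifs[lab].duration
        offsets.append(t)
        t += gaps[k]
    if offsets and offsets[-1] > 1.1 * slow_period:
        raise ConfigurationError(
            f"sequence of {offsets[-1]:.0f} ms exceeds the slow-clock "
            f"period (~{slow_period:.0f} ms)")

    T = int(round(t))
    n = n_exc_per_motif
    mat = np.zeros((len(labels) * n, T))
    for k, lab in enumerate(order):
        tpl = motifs[lab]
        m = labels.index(lab)
        block = tpl.duration / tpl.n_groups
        for g, (a, b) in enumerate(tpl.group_bounds(n)):
            c0 = int(round(onsets[k] + g * block))
            c1 = int(round(onsets[k] + (g + 1) * block))
            mat[m * n + a:m * n + b, c0:c1] = 1.0
    return TargetSequence(motifs=dict(motifs), order=order, gaps=gaps,
                          n_exc_per_motif=n, matrix=mat,
                          onsets=np.array(onsets), offsets=np.array(offsets))


# ---------------------------------------------------------------------------
# schedules


def _clock_start(schedule: StimulusSchedule, model: ModelSpec, pop: str,
                 t0: float, rate: float, duration: float) -> None:
    p = model.pop(pop)
    idx = np.arange(p.cluster_slice(0, local=True).stop)
    schedule.add(pop, idx, rate, "exc", t0, t0 + duration)


def learning_schedule(model: ModelSpec, target: TargetSequence,
                      n_presentations: int = 1, sequence: int = 0,
                      fast_period: float = PERIOD_FAST,
                      supervisor_rate: float = SUPERVISOR_RATE,
                      fc_start_rate: float = FC_START_RATE
                      ) -> StimulusSchedule:
    """Supervised presentation(s) of ``target``.

    Per presentation: a 5 kHz x 10 ms start current to the first cluster of
    the (slow or serial) clock at t=0; at each motif onset a 50 kHz x 40 ms
    current to the fast clock's first cluster (hierarchical only); a 50 kHz
    supervisor drive to the currently stimulated read-out group for each of
    its blocks; and, for motifs shorter than the fast-clock period, a 10 ms
    stop signal to the fast clock's penultimate cluster at motif offset.
    Presentations are tiled back-to-back at the target duration.
    """
    serial = model.meta["kind"] == "serial"
    one = StimulusSchedule(duration=target.duration)
    clock_pop = "Sm_E" if serial else "Sc_E"
    _clock_start(one, model, clock_pop, 0.0, START_RATE, START_DURATION)
    readouts = model.readout_pops(sequence if serial else None)
    labels = target.labels

    for k, lab in enumerate(target.order):
        tpl = target.motifs[lab]
        on, off = float(target.onsets[k]), float(target.offsets[k])
        if not serial:
            _clock_start(one, model, "Fc_E", on, fc_start_rate,
                         FC_START_DURATION)
            if tpl.duration < fast_period:
                fc = model.pop("Fc_E")
                pen = fc.cluster_slice(fc.n_clusters - 2, local=True)
                one.add("Fc_E", np.arange(pen.start, pen.stop), STOP_RATE,
                        "exc", off, off + STOP_DURATION)
        rpop = readouts[labels.index(lab)]
        n_re = model.pop(rpop).size
        block = tpl.duration / tpl.n_groups
        for g, (a, b) in enumerate(tpl.group_bounds(n_re)):
            one.add(rpop, np.arange(a, b), supervisor_rate, "exc",
                    on + g * block, on + (g + 1) * block)

    if n_presentations == 0:
        return StimulusSchedule()
    out = one
    for i in range(1, n_presentations):
        out = out.merged(one.shifted(i * target.duration))
    return out


def spontaneous_schedule(model: ModelSpec, duration: float,
                         attended_sequence: int | None = None
                         ) -> StimulusSchedule:
    """Spontaneous replay: a start kick to the clock plus, when attending to
    one of several stored sequences, a sustained inhibitory drive silencing
    every other interneuron network."""
    sched = StimulusSchedule(duration=duration)
    if duration <= 0:
        return sched
    serial = model.meta["kind"] == "serial"
    clock_pop = "Sm_E" if serial else "Sc_E"
    _clock_start(sched, model, clock_pop, 0.0, START_RATE, START_DURATION)
    if attended_sequence is not None:
        n_seq = model.meta.get("n_sequences", 1)
        if serial:
            raise ConfigurationError(
                "attention targets interneuron networks; the serial model "
                "has none")
        if not (0 <= attended_sequence < n_seq):
            raise ConfigurationError(
                f"unknown sequence {attended_sequence}")
        for s in range(n_seq):
            if s != attended_sequence:
                sched.add(f"In{s}", None, ATTENTION_RATE, "inh",
                          0.0, duration)
    return sched
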