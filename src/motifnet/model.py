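"""Network construction: clocks, read-outs, interneurons, full models.

The hierarchical model couples four kinds of recurrent spiking networks:

* a *fast clock* whose excitatory clusters activate cyclically with a period
  of ~200 ms, discretising the time span of one motif;
* a *slow clock* (period ~1000 ms) spanning the whole sequence;
* one balanced *read-out network* per motif, driven by plastic all-to-all
  synapses from the fast clock (the motif synapses);
* one *interneuron network* per stored sequence, driven by plastic synapses
  from the slow clock (the syntax synapses), with one inhibitory group per
  motif plus a 'silent' group that suppresses the fast clock and read-outs
  between motifs.

The serial baseline replaces both clocks by a single 48-cluster clock wired
directly to the read-outs, with no interneurons. Builders accept a ``scale``
in (0, 1] that shrinks every population (cluster counts fixed, cluster sizes
scaled) and recomputes clock weights by the f = 1/sqrt(N/1000) law.
Assembled models additionally (a) floor the clock and gate networks at
scale 0.5, (b) keep each read-out neuron's expected in-degree (denser
recurrent wiring, unscaled weights), (c) compensate all-to-all
inter-network weights and plastic bounds by full/scaled source size so
every target's mean drive is preserved, and (d) realize scaled gate
networks' recurrent inhibition densely with mean-preserving weights; see
docs/methods.md for why each rule exists.
"""

from __future__ import annotations

import math
import string
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .params import (
    NeuronParams,
    PlasticityParams,
    SynapseParams,
    inverted_syntax_plasticity,
    motif_plasticity,
    syntax_plasticity,
)

#: connection probability within every recurrent network
P_RECURRENT = 0.2

#: initial plastic weights (pF, full scale)
W0_MOTIF = 0.3
W0_SYNTAX = 0.1

#: fixed inter-network weights (pF, full scale)
W_LATERAL_IN_R = 50.0      # interneuron motif group -> other read-outs
W_SILENT_IN_R = 20.0       # 'silent' group -> all read-out neurons
W_SILENT_IN_FC = 20.0      # 'silent' group -> fast-clock clusters (not last)
W_R_IN = 0.4               # read-out E -> its interneuron group
W_FC_PENULT_IN = 1.5       # penultimate fast-clock cluster -> 'silent' group
W_FC_LAST_IN = 0.4         # last fast-clock cluster -> 'silent' group

#: nominal clock periods (ms) used by protocols and heuristics
PERIOD_FAST = 200.0
PERIOD_SLOW = 1000.0

#: assembled models never scale their clock networks below this fraction:
#: below ~50 neurons per cluster the slow clock's marginal bump propagation
#: stalls (the weak forward coupling that makes it slow cannot overcome the
#: relative population fluctuations of smaller clusters), so desk-scale
#: models shrink the read-outs and interneurons fully but floor the clocks.
CLOCK_MIN_SCALE = 0.5


class InvalidScaleError(ValueError):
    """Scale would produce clusters too small to sustain sequential dynamics."""


class ConfigurationError(ValueError):
    """Inconsistent or unsupported model configuration."""


# ---------------------------------------------------------------------------
# specs


@dataclass(frozen=True)
class ClusteredClockSpec:
    """A clustered recurrent network producing cyclic sequential dynamics.

    ``w_*`` are the effective baseline strengths in pF (scaling factor ``f``
    already applied where the reference parameters are expressed as multiples
    of ``f``). Cluster-internal excitatory (or, for the all-inhibitory
    variant, inhibitory) weights are ``w * within_factor``; weights from
    cluster i to cluster i+1 (mod n_clusters) are ``w * forward_factor``.
    """

    name: str
    n_exc: int
    n_inh: int
    n_clusters: int
    cluster_size: int
    f: float
    w_EE: float
    w_IE: float
    w_EI: float
    w_II: float
    within_factor: float
    forward_factor: float
    p: float = P_RECURRENT
    restart_last: bool = False    # last cluster exempt from 'silent' inhibition
    inhibitory_clusters: bool = False  # clusters live on the I population
    depression: bool = False      # short-term depression on outgoing weights

    def __post_init__(self) -> None:
        expected = self.n_clusters * self.cluster_size
        clustered = self.n_inh if self.inhibitory_clusters else self.n_exc
        if clustered != expected:
            raise ConfigurationError(
                f"{clustered} clustered neurons != "
                f"{self.n_clusters} x {self.cluster_size}")
        if self.f <= 0:
            raise ConfigurationError("f must be positive")
        if not (0 < self.p <= 1):
            raise ConfigurationError("p must lie in (0, 1]")
        if not self.inhibitory_clusters and not (
                self.within_factor > self.forward_factor > 0):
            raise ConfigurationError(
                "excitatory clocks need within_factor > forward_factor > 0")

    @property
    def n_total(self) -> int:
        return self.n_exc + self.n_inh


@dataclass(frozen=True)
class ReadoutSpec:
    """Per-motif balanced read-out network (Table-2 parameters at scale 1)."""

    n_exc: int = 300
    n_inh: int = 75
    w_EE: float = 3.0
    w_IE: float = 6.0
    w_EI: float = 190.0
    w_II: float = 60.0
    p: float = P_RECURRENT


@dataclass(frozen=True)
class InterneuronSpec:
    """Per-sequence inhibitory gating network: one group per motif + 'silent'."""

    n_motifs: int = 2
    group_size: int = 100
    w_II: float = 25.0
    p: float = P_RECURRENT

    @property
    def n_groups(self) -> int:
        return self.n_motifs + 1

    @property
    def n_total(self) -> int:
        return self.n_groups * self.group_size

    @property
    def silent_group(self) -> int:
        """Index of the 'silent' group (last)."""
        return self.n_motifs


# ---------------------------------------------------------------------------
# assembled model


@dataclass
class Population:
    """A contiguous range of neurons of one type within the global index."""

    name: str
    kind: str                  # 'E' or 'I'
    size: int
    start: int = 0
    n_clusters: Optional[int] = None
    restart_cluster: Optional[int] = None  # cluster exempt from silencing
    depression: bool = False
    ext_rate: Optional[float] = None       # kHz; None = type default

    @property
    def stop(self) -> int:
        return self.start + self.size

    @property
    def sl(self) -> slice:
        return slice(self.start, self.stop)

    @property
    def cluster_size(self) -> int:
        if not self.n_clusters:
            raise ConfigurationError(f"population {self.name} has no clusters")
        return self.size // self.n_clusters

    def cluster_slice(self, i: int, local: bool = False) -> slice:
        """Slice of cluster ``i`` (0-based), global unless ``local``."""
        cs = self.cluster_size
        off = 0 if local else self.start
        if not (0 <= i < self.n_clusters):
            raise ConfigurationError(
                f"cluster {i} out of range for {self.name}")
        return slice(off + i * cs, off + (i + 1) * cs)


@dataclass
class ConnectionBlock:
    """Dense weight matrix from one population to another.

    ``W[i, j]`` is the weight (pF, non-negative) from source neuron ``j`` to
    target neuron ``i``; the sign of the interaction is carried by the source
    population's type (reversal potentials), never by the weights.
    """

    name: str
    source: str
    target: str
    W: np.ndarray              # shape (n_target, n_source)
    plastic: bool = False
    rule: Optional[str] = None          # 'motif' | 'syntax' | 'inverted-syntax'
    plasticity: Optional[PlasticityParams] = None

    def __post_init__(self) -> None:
        if np.any(self.W < 0):
            raise ConfigurationError(f"block {self.name} has negative weights")
        if self.plastic:
            if self.plasticity is None:
                raise ConfigurationError(
                    f"plastic block {self.name} needs plasticity parameters")
            pp = self.plasticity
            if np.any(self.W < pp.W_min) or np.any(self.W > pp.W_max):
                raise ConfigurationError(
                    f"initial weights of {self.name} outside bounds")


@dataclass
class ModelSpec:
    """A fully assembled model: populations, connection blocks, metadata."""

    populations: dict[str, Population]
    blocks: list[ConnectionBlock]
    meta: dict = field(default_factory=dict)
    neuron: NeuronParams = field(default_factory=NeuronParams)
    synapse: SynapseParams = field(default_factory=SynapseParams)

    def __post_init__(self) -> None:
        offset = 0
        for pop in self.populations.values():
            pop.start = offset
            offset += pop.size
        self._n_neurons = offset
        names = set(self.populations)
        for blk in self.blocks:
            if blk.source not in names or blk.target not in names:
                raise ConfigurationError(
                    f"block {blk.name} references unknown population")
            src, tgt = self.populations[blk.source], self.populations[blk.target]
            if blk.W.shape != (tgt.size, src.size):
                raise ConfigurationError(
                    f"block {blk.name} shape {blk.W.shape} does not match "
                    f"({tgt.size}, {src.size})")

    @property
    def n_neurons(self) -> int:
        return self._n_neurons

    @property
    def exc_mask(self) -> np.ndarray:
        mask = np.zeros(self.n_neurons, dtype=bool)
        for pop in self.populations.values():
            if pop.kind == "E":
                mask[pop.sl] = True
        return mask

    def pop(self, name: str) -> Population:
        try:
            return self.populations[name]
        except KeyError:
            raise ConfigurationError(f"unknown population {name!r}") from None

    def block(self, name: str) -> ConnectionBlock:
        for blk in self.blocks:
            if blk.name == name:
                return blk
        raise ConfigurationError(f"unknown block {name!r}")

    def plastic_blocks(self) -> list[ConnectionBlock]:
        return [b for b in self.blocks if b.plastic]

    @property
    def motif_labels(self) -> list[str]:
        return list(self.meta.get("motif_labels", []))

    def readout_pops(self, sequence: int | None = None) -> list[str]:
        """Names of read-out E populations in motif-label order."""
        if self.meta["kind"] == "serial":
            seq = 0 if sequence is None else sequence
            return [f"R{seq}_{lab}_E" for lab in self.motif_labels]
        return [f"R_{lab}_E" for lab in self.motif_labels]

    def motif_weight_matrix(self, sequence: int | None = None) -> np.ndarray:
        """Stacked plastic motif weights, rows = read-out E neurons in
        motif-label order, columns = clock E neurons."""
        labels = self.motif_labels
        if self.meta["kind"] == "serial":
            seq = 0 if sequence is None else sequence
            names = [f"motif:{seq}:{lab}" for lab in labels]
        else:
            names = [f"motif:{lab}" for lab in labels]
        return np.vstack([self.block(n).W for n in names])

    def syntax_weight_matrix(self, sequence: int = 0) -> np.ndarray:
        return self.block(f"syntax:{sequence}").W


@dataclass(frozen=True)
class ResourceCount:
    """Neuron and synapse counts of the capacity accounting."""

    n_neurons: int
    n_synapses: int

    def __post_init__(self) -> None:
        if self.n_neurons < 0 or self.n_synapses < 0:
            raise ConfigurationError("resource counts must be non-negative")


# ---------------------------------------------------------------------------
# clock builders


def _scaled_clock(name: str, scale: float, n_exc_full: int, n_inh_full: int,
                  n_clusters: int, forward_factor: float,
                  restart_last: bool = False) -> ClusteredClockSpec:
    if not (0 < scale <= 1):
        raise InvalidScaleError(f"scale must lie in (0, 1], got {scale}")
    cluster_size = round(n_exc_full / n_clusters * scale)
    if cluster_size < 2:
        raise InvalidScaleError(
            f"scale {scale} gives cluster size {cluster_size} < 2")
    n_exc = n_clusters * cluster_size
    n_inh = round(n_inh_full * scale)
    f = 1.0 / math.sqrt((n_exc + n_inh) / 1000.0)
    return ClusteredClockSpec(
        name=name, n_exc=n_exc, n_inh=n_inh, n_clusters=n_clusters,
        cluster_size=cluster_size, f=f,
        w_EE=5.0 * f, w_IE=3.5 * f, w_EI=110.0 * f, w_II=36.0 * f,
        within_factor=25.0, forward_factor=forward_factor,
        restart_last=restart_last)


def build_fast_clock(scale: float = 1.0, seed: int | None = None
                     ) -> ClusteredClockSpec:
    """Fast clock: 20 clusters of 100 E neurons, 500 I, period ~200 ms.

    The last cluster is flagged as the restart cluster: it is exempt from
    'silent'-interneuron inhibition, stays active through silent gaps and
    re-ignites cluster 1 when the gap ends.
    """
    return _scaled_clock("Fc", scale, 2000, 500, 20,
                         forward_factor=12.5, restart_last=True)


def build_slow_clock(scale: float = 1.0, seed: int | None = None
                     ) -> ClusteredClockSpec:
    """Slow clock: 28 clusters of 100 E neurons, 700 I, period ~1000 ms."""
    return _scaled_clock("Sc", scale, 2800, 700, 28, forward_factor=4.7)


def build_serial_clock(scale: float = 1.0, seed: int | None = None
                       ) -> ClusteredClockSpec:
    """Serial-model clock: 48 clusters of 100 E neurons, 1200 I."""
    return _scaled_clock("Sm", scale, 4800, 1200, 48, forward_factor=6.0)


def build_inhibitory_slow_clock(scale: float = 1.0, seed: int | None = None
                                ) -> ClusteredClockSpec:
    """All-inhibitory slow clock variant: 20 clusters of 100 I neurons.

    Weak within-group coupling (30/30 = 1 pF) and strong forward inhibition
    (30/2 = 15 pF); sequential dynamics arises through short-term depression
    of the outgoing weights rather than through recurrent excitation.
    """
    if not (0 < scale <= 1):
        raise InvalidScaleError(f"scale must lie in (0, 1], got {scale}")
    cluster_size = round(100 * scale)
    if cluster_size < 2:
        raise InvalidScaleError(
            f"scale {scale} gives cluster size {cluster_size} < 2")
    n_inh = 20 * cluster_size
    return ClusteredClockSpec(
        name="Sc", n_exc=0, n_inh=n_inh, n_clusters=20,
        cluster_size=cluster_size, f=1.0,
        w_EE=0.0, w_IE=0.0, w_EI=0.0, w_II=30.0,
        within_factor=1.0 / 30.0, forward_factor=0.5,
        p=min(1.0, P_RECURRENT / scale),
        inhibitory_clusters=True, depression=True)


# ---------------------------------------------------------------------------
# weight-matrix realization


def _p_mask(rng: np.random.Generator, n_tgt: int, n_src: int, p: float,
            no_self: bool = False) -> np.ndarray:
    mask = rng.random((n_tgt, n_src)) < p
    if no_self:
        np.fill_diagonal(mask, False)
    return mask


def _cluster_factor_matrix(n: int, n_clusters: int, within: float,
                           forward: float) -> np.ndarray:
    """Per-pair weight multipliers for a clustered cyclic network."""
    cs = n // n_clusters
    cl = np.arange(n) // cs
    factors = np.ones((n, n))
    same = cl[:, None] == cl[None, :]
    fwd = cl[:, None] == (cl[None, :] + 1) % n_clusters
    factors[same] = within
    factors[fwd] = forward
    return factors


def realize_clock(spec: ClusteredClockSpec, rng: np.random.Generator,
                  prefix: str | None = None
                  ) -> tuple[dict[str, Population], list[ConnectionBlock]]:
    """Draw the recurrent weight matrices of one clock network."""
    name = prefix or spec.name
    pops: dict[str, Population] = {}
    blocks: list[ConnectionBlock] = []
    if spec.inhibitory_clusters:
        # the all-inhibitory clock stands in for an excitatory clock and is
        # driven at the excitatory external rate; at the inhibitory baseline
        # rate the network self-silences and no wave propagates
        pops[f"{name}_I"] = Population(
            f"{name}_I", "I", spec.n_inh, n_clusters=spec.n_clusters,
            depression=spec.depression, ext_rate=4.5)
        W = spec.w_II * _cluster_factor_matrix(
            spec.n_inh, spec.n_clusters, spec.within_factor,
            spec.forward_factor)
        W *= _p_mask(rng, spec.n_inh, spec.n_inh, spec.p, no_self=True)
        blocks.append(ConnectionBlock(f"{name}:II", f"{name}_I", f"{name}_I", W))
        return pops, blocks

    restart = spec.n_clusters - 1 if spec.restart_last else None
    pops[f"{name}_E"] = Population(
        f"{name}_E", "E", spec.n_exc, n_clusters=spec.n_clusters,
        restart_cluster=restart)
    pops[f"{name}_I"] = Population(f"{name}_I", "I", spec.n_inh)

    W_ee = spec.w_EE * _cluster_factor_matrix(
        spec.n_exc, spec.n_clusters, spec.within_factor, spec.forward_factor)
    W_ee *= _p_mask(rng, spec.n_exc, spec.n_exc, spec.p, no_self=True)
    blocks.append(ConnectionBlock(f"{name}:EE", f"{name}_E", f"{name}_E", W_ee))
    blocks.append(ConnectionBlock(
        f"{name}:IE", f"{name}_E", f"{name}_I",
        spec.w_IE * _p_mask(rng, spec.n_inh, spec.n_exc, spec.p)))
    blocks.append(ConnectionBlock(
        f"{name}:EI", f"{name}_I", f"{name}_E",
        spec.w_EI * _p_mask(rng, spec.n_exc, spec.n_inh, spec.p)))
    blocks.append(ConnectionBlock(
        f"{name}:II", f"{name}_I", f"{name}_I",
        spec.w_II * _p_mask(rng, spec.n_inh, spec.n_inh, spec.p,
                            no_self=True)))
    return pops, blocks


def _realize_readout(label: str, scale: float, rng: np.random.Generator,
                     prefix: str = "R"
                     ) -> tuple[dict[str, Population], list[ConnectionBlock]]:
    # scaled-down read-outs keep each neuron's expected in-degree (denser
    # connectivity, unscaled weights) so recurrent input statistics match
    # the full-size network
    spec = ReadoutSpec()
    n_e, n_i = round(spec.n_exc * scale), round(spec.n_inh * scale)
    p = min(1.0, spec.p / scale)
    e, i = f"{prefix}_{label}_E", f"{prefix}_{label}_I"
    pops = {e: Population(e, "E", n_e), i: Population(i, "I", n_i)}
    blocks = [
        ConnectionBlock(f"{prefix}_{label}:EE", e, e,
                        spec.w_EE * _p_mask(rng, n_e, n_e, p, True)),
        ConnectionBlock(f"{prefix}_{label}:IE", e, i,
                        spec.w_IE * _p_mask(rng, n_i, n_e, p)),
        ConnectionBlock(f"{prefix}_{label}:EI", i, e,
                        spec.w_EI * _p_mask(rng, n_e, n_i, p)),
        ConnectionBlock(f"{prefix}_{label}:II", i, i,
                        spec.w_II * _p_mask(rng, n_i, n_i, p, True)),
    ]
    return pops, blocks


def motif_labels(n_motifs: int) -> list[str]:
    """Default motif labels A, B, C, ..."""
    if n_motifs < 0:
        raise ConfigurationError("n_motifs must be non-negative")
    if n_motifs > 26:
        return [f"M{i}" for i in range(n_motifs)]
    return list(string.ascii_uppercase[:n_motifs])


# ---------------------------------------------------------------------------
# full models


def assemble_hierarchical(n_motifs: int = 2, n_sequences: int = 1,
                          scale: float = 1.0, variant: str = "excitatory",
                          seed: int = 0) -> ModelSpec:
    """Assemble the full hierarchical model.

    Parameters
    ----------
    n_motifs
        Number of read-out networks (one per motif label A, B, ...).
    n_sequences
        Number of interneuron networks (one per storable sequence).
    scale
        Population-size scale in (0, 1]; see the module docstring.
    variant
        ``"excitatory"`` for the standard slow clock, or
        ``"inhibitory-slow-clock"`` for the all-inhibitory variant with
        short-term depression and an inverted-window syntax rule.
    """
    if n_motifs < 1 or n_sequences < 1:
        raise ConfigurationError("need n_motifs >= 1 and n_sequences >= 1")
    if variant not in ("excitatory", "inhibitory-slow-clock"):
        raise ConfigurationError(f"unsupported variant {variant!r}")
    rng = np.random.default_rng(seed)
    labels = motif_labels(n_motifs)
    wf = 1.0 / scale
    clock_scale = min(max(scale, CLOCK_MIN_SCALE), 1.0)

    fast = build_fast_clock(clock_scale)
    pops, blocks = realize_clock(fast, rng)
    if variant == "excitatory":
        slow = build_slow_clock(clock_scale)
        sc_src, sc_full = "Sc_E", 2800
        syn_rule = "syntax"
        syn_base = syntax_plasticity()
    else:
        slow = build_inhibitory_slow_clock(clock_scale)
        sc_src, sc_full = "Sc_I", 2000
        syn_rule = "inverted-syntax"
        syn_base = inverted_syntax_plasticity()
    p2, b2 = realize_clock(slow, rng)
    pops.update(p2)
    blocks.extend(b2)

    for lab in labels:
        p3, b3 = _realize_readout(lab, scale, rng)
        pops.update(p3)
        blocks.extend(b3)

    # the interneuron gates scale with the clocks (they are part of the
    # timing core; their winner-take-all switching is the scale-limiting
    # element of the architecture)
    ispec = InterneuronSpec(n_motifs=n_motifs,
                            group_size=round(100 * clock_scale))
    fc = pops["Fc_E"]
    n_fc = fc.size
    # weight compensation of inter-network blocks preserves each target's
    # mean drive: factor = full source-population size / scaled size
    fc_wf = 2000 / n_fc
    mot = motif_plasticity().scaled(fc_wf)

    # plastic motif synapses: all fast-clock E -> all read-out E
    for lab in labels:
        n_re = pops[f"R_{lab}_E"].size
        blocks.append(ConnectionBlock(
            f"motif:{lab}", "Fc_E", f"R_{lab}_E",
            np.full((n_re, n_fc), W0_MOTIF * fc_wf), plastic=True,
            rule="motif", plasticity=mot))

    gs, n_groups = ispec.group_size, ispec.n_groups
    n_in = gs * n_groups
    in_wf = 100 / gs
    n_sc = pops[sc_src].size
    sc_wf = sc_full / n_sc
    syn_params = syn_base.scaled(sc_wf)
    for s in range(n_sequences):
        iname = f"In{s}"
        pops[iname] = Population(iname, "I", n_in, n_clusters=n_groups)
        # gate-network recurrent inhibition: printed sparsity at full size;
        # scaled-down gates use dense connectivity with mean-preserving
        # weights (many small IPSPs instead of few large ones), because the
        # winner-take-all exclusivity between gate groups is destroyed by
        # the coarser inhibition granularity of a sparsely wired small net
        if clock_scale >= 1.0:
            W_ii = ispec.w_II * _p_mask(rng, n_in, n_in, ispec.p, True)
        else:
            w_dense = ispec.w_II * ispec.p * (100 * ispec.n_groups) / n_in
            W_ii = np.full((n_in, n_in), w_dense)
            np.fill_diagonal(W_ii, 0.0)
        blocks.append(ConnectionBlock(f"{iname}:II", iname, iname, W_ii))
        # plastic syntax synapses: all slow-clock -> all interneurons
        blocks.append(ConnectionBlock(
            f"syntax:{s}", sc_src, iname,
            np.full((n_in, n_sc), W0_SYNTAX * sc_wf), plastic=True,
            rule=syn_rule, plasticity=syn_params))
        # interneurons -> read-outs: lateral 50 pF from other motifs' groups,
        # 20 pF from the 'silent' group to every read-out neuron
        for m, lab in enumerate(labels):
            for kind in ("E", "I"):
                tgt = pops[f"R_{lab}_{kind}"]
                W = np.zeros((tgt.size, n_in))
                for g in range(n_motifs):
                    if g != m:
                        W[:, g * gs:(g + 1) * gs] = W_LATERAL_IN_R * in_wf
                W[:, n_groups * gs - gs:] = W_SILENT_IN_R * in_wf
                blocks.append(ConnectionBlock(
                    f"{iname}->R_{lab}_{kind}", iname, f"R_{lab}_{kind}", W))
            # read-out E -> its interneuron group
            n_re = pops[f"R_{lab}_E"].size
            W = np.zeros((n_in, n_re))
            W[m * gs:(m + 1) * gs, :] = W_R_IN * (300 / n_re)
            blocks.append(ConnectionBlock(
                f"R_{lab}_E->{iname}", f"R_{lab}_E", iname, W))
        # 'silent' group -> fast-clock E clusters except the restart cluster
        W = np.zeros((n_fc, n_in))
        last = fc.cluster_slice(fc.n_clusters - 1, local=True)
        W[:, n_groups * gs - gs:] = W_SILENT_IN_FC * in_wf
        W[last, :] = 0.0
        blocks.append(ConnectionBlock(f"{iname}->Fc_E", iname, "Fc_E", W))
        # penultimate / last fast-clock clusters -> 'silent' group
        W = np.zeros((n_in, n_fc))
        pen = fc.cluster_slice(fc.n_clusters - 2, local=True)
        cs_wf = 100 / fc.cluster_size
        W[n_groups * gs - gs:, pen] = W_FC_PENULT_IN * cs_wf
        W[n_groups * gs - gs:, last] = W_FC_LAST_IN * cs_wf
        blocks.append(ConnectionBlock(f"Fc_E->{iname}", "Fc_E", iname, W))

    meta = dict(kind="hierarchical", scale=scale, variant=variant,
                clock_scale=clock_scale, n_motifs=n_motifs,
                n_sequences=n_sequences, motif_labels=labels, seed=seed,
                period_fast=PERIOD_FAST, period_slow=PERIOD_SLOW,
                weight_factor=wf)
    return ModelSpec(populations=pops, blocks=blocks, meta=meta)


def assemble_serial(n_motifs: int = 2, n_sequences: int = 1,
                    scale: float = 1.0, seed: int = 0) -> ModelSpec:
    """Assemble the serial baseline: one 48-cluster clock driving per-sequence
    read-out networks through plastic motif synapses; no interneurons."""
    if n_motifs < 1 or n_sequences < 0:
        raise ConfigurationError("need n_motifs >= 1 and n_sequences >= 0")
    rng = np.random.default_rng(seed)
    labels = motif_labels(n_motifs)
    clock_scale = min(max(scale, CLOCK_MIN_SCALE), 1.0)

    clock = build_serial_clock(clock_scale)
    pops, blocks = realize_clock(clock, rng)
    n_sm = pops["Sm_E"].size
    sm_wf = 4800 / n_sm
    mot = motif_plasticity().scaled(sm_wf)
    for s in range(n_sequences):
        for lab in labels:
            p3, b3 = _realize_readout(lab, scale, rng, prefix=f"R{s}")
            pops.update(p3)
            blocks.extend(b3)
            n_re = pops[f"R{s}_{lab}_E"].size
            blocks.append(ConnectionBlock(
                f"motif:{s}:{lab}", "Sm_E", f"R{s}_{lab}_E",
                np.full((n_re, n_sm), W0_MOTIF * sm_wf), plastic=True,
                rule="motif", plasticity=mot))

    meta = dict(kind="serial", scale=scale, clock_scale=clock_scale,
                n_motifs=n_motifs, n_sequences=n_sequences,
                motif_labels=labels, seed=seed,
                weight_factor=1.0 / scale)
    return ModelSpec(populations=pops, blocks=blocks, meta=meta)


def clock_network(spec: ClusteredClockSpec, seed: int = 0) -> ModelSpec:
    """A standalone clock network (for period and variability measurements)."""
    rng = np.random.default_rng(seed)
    pops, blocks = realize_clock(spec, rng)
    meta = dict(kind="clock", clock=spec.name, scale=None, seed=seed,
                n_clusters=spec.n_clusters)
    return ModelSpec(populations=pops, blocks=blocks, meta=meta)


# ---------------------------------------------------------------------------
# capacity accounting


def count_resources(model_kind: str, n_sequences: int,
                    n_motifs: int = 2) -> ResourceCount:
    """Neurons and synapses needed to store ``n_sequences`` sequences.

    The synapse count covers the plastic synapses plus, for the hierarchical
    model, the fixed lateral wiring added with each interneuron network;
    inter-network projections are counted as full all-to-all blocks between
    the named groups. The serial model is charged one read-out network per
    motif per sequence (motifs cannot be shared across its sequences).
    """
    if n_sequences < 0:
        raise ConfigurationError("n_sequences must be non-negative")
    if n_motifs < 0:
        raise ConfigurationError("n_motifs must be non-negative")
    readout = 375 * n_motifs          # neurons per full motif set
    readout_e = 300 * n_motifs
    if model_kind == "serial":
        neurons = 6000 + readout * n_sequences
        synapses = 4800 * readout_e * n_sequences
    elif model_kind == "hierarchical":
        n_in = 100 * (n_motifs + 1)
        neurons = 6000 + readout + n_in * n_sequences
        per_seq = (2800 * n_in          # slow clock -> interneurons
                   + readout * n_in     # interneurons -> read-outs
                   + readout_e * n_in   # read-out E -> interneurons
                   + 2000 * 100         # 'silent' group -> fast clock
                   + 200 * 100)         # last two fast clusters -> 'silent'
        synapses = 2000 * readout_e + per_seq * n_sequences
    else:
        raise ConfigurationError(f"unknown model kind {model_kind!r}")
    return ResourceCount(n_neurons=neurons, n_synapses=synapses)
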