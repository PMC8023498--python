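"""Parameter containers for neurons, synapses and plasticity rules.

All membrane/synaptic constants default to the reference parameter set of the
hierarchical sequence-learning model: conductance-based adaptive exponential
integrate-and-fire (AdEx) excitatory neurons, leaky integrate-and-fire
inhibitory neurons, difference-of-exponentials conductance kernels, and
trace-based symmetric STDP with constant depression.

Units follow the field's conventions: ms, mV, pF, pA, nS, kHz.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace


@dataclass(frozen=True)
class NeuronParams:
    """Membrane dynamics constants (shared by every network in the model).

    Excitatory neurons are AdEx: leak + exponential spike-initiation term,
    adaptive threshold ``V_T^E`` (jumps by ``A_T`` per spike, relaxes with
    ``tau_T``) and adaptation current ``a`` (subthreshold coupling ``alpha``,
    spike-triggered jump ``beta``). Inhibitory neurons are plain LIF with a
    fixed threshold ``V_T``.
    """

    tau_E: float = 20.0        # ms, E membrane time constant
    tau_I: float = 20.0        # ms, I membrane time constant
    tau_abs: float = 5.0       # ms, absolute refractory period (E and I)
    E_exc: float = 0.0         # mV, excitatory reversal potential
    E_inh: float = -75.0       # mV, inhibitory reversal potential
    E_L_E: float = -70.0       # mV, excitatory resting potential
    E_L_I: float = -62.0       # mV, inhibitory resting potential
    V_r: float = -60.0         # mV, reset potential (E and I)
    C: float = 300.0           # pF, capacitance
    Delta_T: float = 2.0       # mV, exponential slope
    tau_T: float = 30.0        # ms, adaptive threshold time constant
    V_T: float = -52.0         # mV, threshold
    A_T: float = 10.0          # mV, adaptive threshold increase per spike
    tau_a: float = 100.0       # ms, adaptation current time constant
    alpha: float = 4.0         # nS, subthreshold adaptation coupling
    beta: float = 0.805        # pA, spike-triggered adaptation increment
    spike_cutoff: float = 20.0  # mV, divergence cutoff declaring an E spike
    #: if True, each spike adds A_T to the threshold; if False (default), a
    #: spike sets the threshold to V_T + A_T, a fixed post-spike ceiling that
    #: relaxes back to V_T with tau_T. The ceiling reading follows this
    #: parameter set's lineage (it models sodium-channel inactivation) and is
    #: the one under which the clock networks run at their stated periods.
    cumulative_threshold: bool = False

    def __post_init__(self) -> None:
        for name in ("tau_E", "tau_I", "tau_abs", "tau_T", "tau_a"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not (self.E_inh < self.V_r < self.spike_cutoff):
            raise ValueError("require E_inh < V_r < spike_cutoff")


@dataclass(frozen=True)
class SynapseParams:
    """Conductance kernel time constants and external-input parameters.

    The conductance kernel is the normalized difference of exponentials
    ``K(t) = (exp(-t/tau_d) - exp(-t/tau_r)) / (tau_d - tau_r)`` whose time
    integral is 1, so a spike through a weight ``W`` injects total conductance
    area ``W``. Kernel constants depend on the *source* type (E or I).
    External Poisson input enters every neuron through ``W_ext`` of the
    target's type.
    """

    tau_d_E: float = 6.0       # ms, decay of E-sourced conductance
    tau_r_E: float = 1.0       # ms, rise of E-sourced conductance
    tau_d_I: float = 2.0       # ms, decay of I-sourced conductance
    tau_r_I: float = 0.5       # ms, rise of I-sourced conductance
    W_ext_E: float = 1.6       # pF, external synapse onto E neurons
    W_ext_I: float = 1.52      # pF, external synapse onto I neurons
    r_ext_E: float = 4.5       # kHz, external Poisson rate onto E neurons
    r_ext_I: float = 2.25      # kHz, external Poisson rate onto I neurons

    def __post_init__(self) -> None:
        if not (self.tau_d_E > self.tau_r_E > 0):
            raise ValueError("require tau_d_E > tau_r_E > 0")
        if not (self.tau_d_I > self.tau_r_I > 0):
            raise ValueError("require tau_d_I > tau_r_I > 0")


@dataclass(frozen=True)
class PlasticityParams:
    """Trace-based symmetric STDP with constant depression.

    ``dW/dt = sign * (-A_dep + A_pot * (y_post s_pre + y_pre s_post))`` where
    ``y`` are spike trains low-pass filtered with time constant ``tau`` and a
    unit jump per spike. ``A_pot`` acts per pre/post coincidence (pF scale);
    ``A_dep`` is interpreted as pF per integration step of 0.1 ms (the printed
    depression amplitudes are commensurate with the weight bounds over a
    training run under this reading; ``dep_per_ms`` flips to a per-ms
    reading). ``sign=-1`` gives the inverted window used by the
    all-inhibitory slow-clock variant.
    """

    A_pot: float               # pF per coincidence
    A_dep: float               # pF per 0.1 ms step (see dep_per_ms)
    tau: float                 # ms, trace time constant
    W_min: float = 0.0         # pF
    W_max: float = 1.0         # pF
    sign: int = 1              # +1 symmetric, -1 inverted window
    dep_per_ms: bool = False   # alternative unit reading for A_dep

    def __post_init__(self) -> None:
        if self.tau <= 0:
            raise ValueError("tau must be positive")
        if self.W_min > self.W_max:
            raise ValueError("W_min must not exceed W_max")
        if self.sign not in (-1, 1):
            raise ValueError("sign must be +1 or -1")

    def dep_per_step(self, dt: float) -> float:
        """Depression decrement per integration step of length ``dt`` ms."""
        if self.dep_per_ms:
            return self.A_dep * dt
        return self.A_dep * (dt / 0.1)

    def scaled(self, factor: float) -> "PlasticityParams":
        """Rescale weight-valued constants (for scaled-down networks)."""
        return replace(
            self,
            A_pot=self.A_pot * factor,
            A_dep=self.A_dep * factor,
            W_min=self.W_min * factor,
            W_max=self.W_max * factor,
        )


def motif_plasticity() -> PlasticityParams:
    """STDP rule for fast-clock -> read-out (motif) synapses."""
    return PlasticityParams(A_pot=0.03, A_dep=2.0 / 3.0 * 1e-6, tau=5.0,
                            W_min=0.0, W_max=1.0, sign=1)


def syntax_plasticity() -> PlasticityParams:
    """STDP rule for slow-clock -> interneuron (syntax) synapses."""
    return PlasticityParams(A_pot=0.025, A_dep=0.10e-5, tau=20.0,
                            W_min=0.0, W_max=0.3, sign=1)


def inverted_syntax_plasticity() -> PlasticityParams:
    """Inverted-window syntax rule for the all-inhibitory slow clock."""
    return PlasticityParams(A_pot=0.03, A_dep=0.25e-5, tau=25.0,
                            W_min=0.0, W_max=0.3, sign=-1)


@dataclass(frozen=True)
class DepressionParams:
    """Short-term depression of outgoing weights (inhibitory clock variant).

    ``tau_xd dx/dt = 1 - x``; on a spike ``x <- (1 - decrement) * x``; the
    neuron's outgoing weights are multiplied by ``x`` at delivery time.
    """

    tau_xd: float = 200.0      # ms, recovery time constant
    decrement: float = 0.07    # fraction removed per spike

    def __post_init__(self) -> None:
        if not (0.0 < self.decrement < 1.0):
            raise ValueError("decrement must lie in (0, 1)")
        if self.tau_xd <= 0:
            raise ValueError("tau_xd must be positive")
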