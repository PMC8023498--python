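"""Neuron and synapse dynamics: forward-Euler AdEx/LIF with conductance
synapses realized as exact difference-of-exponentials filters.

Membrane equations are integrated with forward Euler at ``dt`` (0.1 ms by
default). Each neuron carries two conductance channels — one for excitatory
sources, one for inhibitory sources — and each channel is realized by two
auxiliary first-order states whose difference reproduces the normalized
kernel ``K(t) = (e^{-t/tau_d} - e^{-t/tau_r})/(tau_d - tau_r)`` exactly for
impulse inputs (the auxiliary states decay by exact exponential factors per
step, so the kernel holds at machine precision). A spike through a weight
``W`` (pF) adds an impulse of total conductance area ``W`` (pF/ms = nS once
filtered).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .params import NeuronParams, SynapseParams


class IntegrationError(RuntimeError):
    """A neuron's state became non-finite during integration."""


@dataclass
class State:
    """Per-neuron dynamical variables (global index order).

    ``sd_e/sr_e`` and ``sd_i/sr_i`` are the decay/rise auxiliary states of
    the excitatory- and inhibitory-source conductance channels; the physical
    conductances are ``(sd - sr)/(tau_d - tau_r)``. ``x_d`` is the
    short-term depression variable (1 everywhere unless a population uses
    depression).
    """

    V: np.ndarray
    V_T: np.ndarray            # adaptive threshold (E only; I entries unused)
    a: np.ndarray              # adaptation current (E only)
    refr: np.ndarray           # remaining refractory time, ms
    sd_e: np.ndarray
    sr_e: np.ndarray
    sd_i: np.ndarray
    sr_i: np.ndarray
    x_d: np.ndarray
    exc: np.ndarray            # bool: excitatory neuron

    @property
    def n(self) -> int:
        return self.V.size

    def g_exc(self, syn: SynapseParams) -> np.ndarray:
        return (self.sd_e - self.sr_e) / (syn.tau_d_E - syn.tau_r_E)

    def g_inh(self, syn: SynapseParams) -> np.ndarray:
        return (self.sd_i - self.sr_i) / (syn.tau_d_I - syn.tau_r_I)


def init_state(exc_mask: np.ndarray, neuron: NeuronParams,
               rng: np.random.Generator | None = None) -> State:
    """Initial conditions: V uniform in [V_r, V_T], thresholds at rest,
    no adaptation, no conductance, full depression recovery."""
    n = exc_mask.size
    if rng is None:
        V = np.full(n, neuron.V_r)
    else:
        V = rng.uniform(neuron.V_r, neuron.V_T, size=n)
    return State(
        V=V,
        V_T=np.full(n, neuron.V_T),
        a=np.zeros(n),
        refr=np.zeros(n),
        sd_e=np.zeros(n), sr_e=np.zeros(n),
        sd_i=np.zeros(n), sr_i=np.zeros(n),
        x_d=np.ones(n),
        exc=np.asarray(exc_mask, dtype=bool).copy(),
    )


#: cap on the exponent of the spike-initiation term; any membrane this far
#: above threshold fires within the step, so the exact value is irrelevant
_EXP_CAP = 10.0


def step_neurons(state: State, neuron: NeuronParams, syn: SynapseParams,
                 dt: float, E_L_E: np.ndarray | float | None = None
                 ) -> np.ndarray:
    """Advance membranes by one step; return the boolean spike vector.

    Excitatory neurons follow AdEx (leak + exponential term + conductance
    drive - adaptation) with adaptive threshold; inhibitory neurons follow
    LIF. Spikes: E when V exceeds the divergence cutoff (20 mV), I when V
    crosses V_T. On a spike V resets to V_r and the neuron is clamped there
    for the absolute refractory period; E spikes additionally raise the
    threshold by A_T and the adaptation current by beta.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    V, exc = state.V, state.exc
    inh = ~exc
    g_e = state.g_exc(syn)
    g_i = state.g_inh(syn)

    drive = (g_e * (neuron.E_exc - V) + g_i * (neuron.E_inh - V)) / neuron.C
    dV = np.empty_like(V)
    # AdEx excitatory branch
    expo = np.exp(np.minimum((V - state.V_T) / neuron.Delta_T, _EXP_CAP))
    dV_e = ((neuron.E_L_E - V + neuron.Delta_T * expo) / neuron.tau_E
            + drive - state.a / neuron.C)
    # LIF inhibitory branch
    dV_i = (neuron.E_L_I - V) / neuron.tau_I + drive
    dV[exc] = dV_e[exc]
    dV[inh] = dV_i[inh]

    refractory = state.refr > 0
    V_new = V + dt * dV
    V_new[refractory] = neuron.V_r

    # threshold and adaptation relax regardless of refractoriness
    state.V_T += dt / neuron.tau_T * (neuron.V_T - state.V_T)
    state.a += dt / neuron.tau_a * (-state.a + neuron.alpha
                                    * (V - neuron.E_L_E))

    spikes = np.where(exc, V_new > neuron.spike_cutoff,
                      V_new > neuron.V_T) & ~refractory
    if not np.all(np.isfinite(V_new)):
        bad = int(np.flatnonzero(~np.isfinite(V_new))[0])
        raise IntegrationError(f"non-finite membrane potential at neuron {bad}")

    V_new[spikes] = neuron.V_r
    state.refr[spikes] = neuron.tau_abs
    state.refr[refractory] -= dt
    np.clip(state.refr, 0.0, None, out=state.refr)
    es = spikes & exc
    if neuron.cumulative_threshold:
        state.V_T[es] += neuron.A_T
    else:
        state.V_T[es] = neuron.V_T + neuron.A_T
    state.a[es] += neuron.beta
    state.V = V_new
    return spikes


def update_conductances(state: State, syn: SynapseParams,
                        imp_exc: np.ndarray | None,
                        imp_inh: np.ndarray | None, dt: float) -> None:
    """Decay the conductance filters by one step and inject new impulses.

    ``imp_exc``/``imp_inh`` are per-neuron impulse areas (pF): summed weights
    of all spikes delivered this step through excitatory / inhibitory
    sources. Decay uses exact exponential factors so an impulse of weight W
    produces the trace ``W * K(t)`` exactly.
    """
    fd_e = np.exp(-dt / syn.tau_d_E)
    fr_e = np.exp(-dt / syn.tau_r_E)
    fd_i = np.exp(-dt / syn.tau_d_I)
    fr_i = np.exp(-dt / syn.tau_r_I)
    state.sd_e *= fd_e
    state.sr_e *= fr_e
    state.sd_i *= fd_i
    state.sr_i *= fr_i
    if imp_exc is not None:
        if np.any(imp_exc < 0):
            raise ValueError("synaptic weights must be non-negative")
        state.sd_e += imp_exc
        state.sr_e += imp_exc
    if imp_inh is not None:
        if np.any(imp_inh < 0):
            raise ValueError("synaptic weights must be non-negative")
        state.sd_i += imp_inh
        state.sr_i += imp_inh


def sample_external_input(rate_kHz: float | np.ndarray, n_neurons: int,
                          dt: float, rng: np.random.Generator) -> np.ndarray:
    """Independent Poisson spike counts per neuron for one step.

    ``rate_kHz`` (spikes/ms) may be a scalar or a per-neuron vector; counts
    have mean ``rate * dt``.
    """
    lam = np.broadcast_to(np.asarray(rate_kHz, dtype=float) * dt,
                          (n_neurons,))
    if np.any(lam < 0):
        raise ValueError("rates must be non-negative")
    return rng.poisson(lam)


def kernel(t: np.ndarray, tau_d: float, tau_r: float) -> np.ndarray:
    """The normalized conductance kernel K(t) (zero for t < 0)."""
    t = np.asarray(t, dtype=float)
    out = (np.exp(-t / tau_d) - np.exp(-t / tau_r)) / (tau_d - tau_r)
    return np.where(t >= 0, out, 0.0)
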