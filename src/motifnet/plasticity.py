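"""Trace-based symmetric STDP, the inverted-window variant, and short-term
depression.

The learning rule for a plastic weight W_ij (pre j, post i) is

    dW/dt = sign * ( -A_dep + A_pot * (y_i s_j + y_j s_i) )

with spike trains ``s`` and their low-pass filtered traces ``y``
(``tau dy/dt = s - y``). In the stepped implementation a spike increments
its neuron's trace by 1/tau (the filter's impulse response, so traces
approximate firing rates in kHz), potentiation is applied per spike event using the
traces *including* the current step's spikes (so an exact pre/post
coincidence counts fully on both sides), and the constant depression is
applied every step. Weights are clipped to [W_min, W_max] after every
update. The inverted rule (sign = -1) negates the whole right-hand side;
bounds are unchanged.
"""

from __future__ import annotations

import numpy as np
from numba import njit

from .params import DepressionParams, PlasticityParams


@njit(cache=True)
def _depress_and_clip(W, dep, lo, hi):
    # fused single pass; the depression term dominates the per-step cost of
    # large plastic blocks
    n, m = W.shape
    for i in range(n):
        for j in range(m):
            w = W[i, j] - dep
            if w < lo:
                w = lo
            elif w > hi:
                w = hi
            W[i, j] = w


def update_traces(traces: np.ndarray, spikes: np.ndarray, tau: float,
                  dt: float) -> np.ndarray:
    """Decay traces by exp(-dt/tau), then add 1/tau for each spiking neuron.

    The 1/tau jump is the impulse response of the low-pass filter
    ``tau dy/dt = s - y`` driven by Dirac spikes, so a trace approximates
    the neuron's firing rate in kHz. ``spikes`` may be a boolean mask or
    integer spike counts.
    """
    if tau <= 0:
        raise ValueError("tau must be positive")
    traces *= np.exp(-dt / tau)
    traces += np.asarray(spikes) / tau
    return traces


def apply_stdp(W: np.ndarray, traces_pre: np.ndarray, traces_post: np.ndarray,
               spikes_pre: np.ndarray, spikes_post: np.ndarray,
               params: PlasticityParams, dt: float) -> np.ndarray:
    """One plasticity step on the weight matrix ``W`` (post x pre), in place.

    Call *after* ``update_traces`` for this step, so that the traces include
    the current spikes. ``spikes_*`` are boolean vectors.
    """
    sign = params.sign
    pre_idx = np.flatnonzero(spikes_pre)
    post_idx = np.flatnonzero(spikes_post)
    if pre_idx.size:
        W[:, pre_idx] += sign * params.A_pot * traces_post[:, None]
    if post_idx.size:
        W[post_idx, :] += sign * params.A_pot * traces_pre[None, :]
    _depress_and_clip(W, sign * params.dep_per_step(dt),
                      params.W_min, params.W_max)
    return W


def apply_short_term_depression(x_d: np.ndarray, spikes: np.ndarray,
                                dt: float,
                                params: DepressionParams | None = None
                                ) -> np.ndarray:
    """Advance the depression variable: recover toward 1 with tau_xd, then
    multiply by (1 - decrement) for each spiking neuron, in place.

    The outgoing weights of a neuron are multiplied by its ``x_d`` at spike
    delivery time; the stored weight matrices are never modified.
    """
    if params is None:
        params = DepressionParams()
    x_d += dt / params.tau_xd * (1.0 - x_d)
    x_d[np.asarray(spikes, dtype=bool)] *= 1.0 - params.decrement
    return x_d


def stdp_event_oracle(spikes_pre: np.ndarray, spikes_post: np.ndarray,
                      w0: float, params: PlasticityParams, T: float,
                      dt: float) -> float:
    """Event-driven reference integration of the STDP rule on one synapse.

    Walks the same discrete-time convention as the stepped implementation
    (traces decay per step by exp(-dt/tau); potentiation uses traces
    including the current step; depression every step; clip every step) but
    evaluates trace decays in closed form between events, so it shares no
    code with :func:`apply_stdp`. Spike times are given as step indices.
    Intended for small event counts.
    """
    pre = set(int(s) for s in np.atleast_1d(spikes_pre))
    post = set(int(s) for s in np.atleast_1d(spikes_post))
    n_steps = int(round(T / dt))
    w = float(w0)
    sign = params.sign
    dep = params.dep_per_step(dt)

    def trace_at(spike_steps: set[int], k: int) -> float:
        # closed form: sum of (1/tau) exp(-(k - s) dt / tau) over spikes s <= k
        return sum(np.exp(-(k - s) * dt / params.tau) / params.tau
                   for s in spike_steps if s <= k)

    for k in range(n_steps):
        w -= sign * dep
        if k in pre:
            w += sign * params.A_pot * trace_at(post, k)
        if k in post:
            w += sign * params.A_pot * trace_at(pre, k)
        w = min(max(w, params.W_min), params.W_max)
    return w
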