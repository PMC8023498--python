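"""Error and variability measures on spike rasters.

All measures work on smoothed firing-rate proxies: per-neuron spike counts
in 1 ms bins convolved with a Gaussian kernel (sigma ~ 10 ms, truncated at
+-3 sigma) and normalized per neuron to [0, 1]. Replay errors compare these
rate matrices to binary targets with multivariate dynamic time warping
(frame cost = Euclidean distance over the neuron dimension, accumulated
cost divided by the warping-path length); the warping removes the timing
variability of spontaneous replays. Variability statistics (inter-motif CV,
motif cross-correlation, cluster activation-time std) are computed without
warping.

Every function here is a pure function of rasters/targets and stored
weights; nothing touches engine state.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace as dc_replace

import numpy as np
from numba import njit
from scipy.signal import fftconvolve, find_peaks

from .engine import SimResult, SimulationConfig, SpikeRaster, run
from .model import ConfigurationError, ModelSpec
from .protocols import (
    FC_START_DURATION,
    FC_START_RATE,
    StimulusSchedule,
    TargetSequence,
)


@dataclass
class RateMatrix:
    """Smoothed, normalized firing rates: neurons x time bins in [0, 1]."""

    rates: np.ndarray
    bin_ms: float = 1.0

    def __post_init__(self) -> None:
        if np.any(self.rates < 0) or np.any(self.rates > 1 + 1e-12):
            raise ConfigurationError("rates must lie in [0, 1]")


@dataclass
class ErrorReport:
    """Replay errors of one evaluation (averages over its trials)."""

    motif_error: float
    ordering_error: float
    total_error: float
    per_trial: list = None

    def __post_init__(self) -> None:
        if self.per_trial is None:
            self.per_trial = []


def _gauss_kernel(sigma_bins: float) -> np.ndarray:
    r = int(np.ceil(3 * sigma_bins))
    k = np.exp(-0.5 * (np.arange(-r, r + 1) / sigma_bins) ** 2)
    return k / k.sum()


def _binned(times: np.ndarray, ids: np.ndarray, n_neurons: int,
            duration: float, bin_ms: float) -> np.ndarray:
    n_bins = int(np.ceil(duration / bin_ms)) if duration > 0 else 0
    out = np.zeros((n_neurons, max(n_bins, 1)))
    if times.size:
        b = np.minimum((times / bin_ms).astype(int), out.shape[1] - 1)
        np.add.at(out, (ids, b), 1.0)
    return out


def _smooth(counts: np.ndarray, sigma_bins: float) -> np.ndarray:
    if sigma_bins <= 0:
        return counts
    k = _gauss_kernel(sigma_bins)
    return fftconvolve(counts, k[None, :], mode="same", axes=1)


def smooth_normalize(raster: SpikeRaster, pops, sigma: float = 10.0,
                     bin_ms: float = 1.0, t0: float = 0.0,
                     t1: float | None = None,
                     per_neuron: bool = True) -> RateMatrix:
    """Rate proxy for the named population(s), rows concatenated in order.

    Each neuron's binned spike counts are convolved with a Gaussian of width
    ``sigma`` ms and divided by that neuron's maximum over the trial
    (all-zero rows stay zero); ``per_neuron=False`` divides by the global
    maximum instead.
    """
    if isinstance(pops, str):
        pops = [pops]
    if not pops:
        raise ConfigurationError("need at least one population")
    t1 = raster.duration if t1 is None else t1
    rows = []
    for name in pops:
        times, local = raster.pop_events(name)
        m = (times >= t0) & (times < t1)
        size = raster.populations[name][1]
        rows.append(_binned(times[m] - t0, local[m], size, t1 - t0, bin_ms))
    counts = np.vstack(rows)
    sm = _smooth(counts, sigma / bin_ms)
    sm = np.maximum(sm, 0.0)    # fft round-off
    if per_neuron:
        mx = sm.max(axis=1, keepdims=True)
        mx[mx == 0] = 1.0
    else:
        mx = sm.max() or 1.0
    return RateMatrix(rates=sm / mx, bin_ms=bin_ms)


# ---------------------------------------------------------------------------
# dynamic time warping


@njit(cache=True)
def _dtw_accumulate(cost: np.ndarray) -> tuple[float, int]:
    n1, n2 = cost.shape
    D = np.full((n1 + 1, n2 + 1), np.inf)
    D[0, 0] = 0.0
    for i in range(1, n1 + 1):
        for j in range(1, n2 + 1):
            best = D[i - 1, j - 1]
            if D[i - 1, j] < best:
                best = D[i - 1, j]
            if D[i, j - 1] < best:
                best = D[i, j - 1]
            D[i, j] = cost[i - 1, j - 1] + best
    # backtrack to count the warping-path length
    i, j = n1, n2
    length = 1
    while i > 1 or j > 1:
        if i == 1:
            j -= 1
        elif j == 1:
            i -= 1
        else:
            d_diag = D[i - 1, j - 1]
            d_up = D[i - 1, j]
            d_left = D[i, j - 1]
            if d_diag <= d_up and d_diag <= d_left:
                i -= 1
                j -= 1
            elif d_up <= d_left:
                i -= 1
            else:
                j -= 1
        length += 1
    return D[n1, n2], length


def dtw_error(rates_a, rates_b) -> float:
    """Multivariate DTW distance between two rate matrices (neurons x time),
    accumulated Euclidean frame cost divided by warping-path length.

    Zero iff the two matrices are equal up to a monotone time warping of
    identical frame sequences.
    """
    a = rates_a.rates if isinstance(rates_a, RateMatrix) else np.asarray(rates_a, float)
    b = rates_b.rates if isinstance(rates_b, RateMatrix) else np.asarray(rates_b, float)
    if a.ndim == 1:
        a = a[None, :]
    if b.ndim == 1:
        b = b[None, :]
    if a.shape[0] != b.shape[0]:
        raise ConfigurationError(
            f"neuron dimensions differ: {a.shape[0]} vs {b.shape[0]}")
    if a.shape[1] == 0 or b.shape[1] == 0:
        return 0.0
    # frame-to-frame Euclidean cost without forming huge intermediates
    aa = np.einsum("nt,nt->t", a, a)
    bb = np.einsum("nt,nt->t", b, b)
    ab = a.T @ b
    sq = np.maximum(aa[:, None] + bb[None, :] - 2 * ab, 0.0)
    sq[sq < 1e-12] = 0.0          # identical frames cost exactly zero
    total, length = _dtw_accumulate(np.sqrt(sq))
    return float(total / length)


# ---------------------------------------------------------------------------
# replay errors


def _decoupled_motif_model(model: ModelSpec, label: str) -> ModelSpec:
    """Fast clock + one read-out network, uncoupled from slow clock and
    interneurons; weight matrices are shared with the parent model."""
    keep = {"Fc_E", "Fc_I", f"R_{label}_E", f"R_{label}_I"}
    if not keep <= set(model.populations):
        raise ConfigurationError(f"unknown motif label {label!r}")
    pops = {name: dc_replace(model.populations[name]) for name in keep}
    blocks = [b for b in model.blocks
              if b.source in keep and b.target in keep]
    meta = dict(model.meta)
    meta["kind"] = "motif-subsystem"
    return ModelSpec(populations=pops, blocks=blocks, meta=meta,
                     neuron=model.neuron, synapse=model.synapse)


def motif_error(model: ModelSpec, target: TargetSequence, label: str,
                seed: int = 0, margin: float = 60.0) -> float:
    """Replay error of a single motif.

    The fast clock and the motif's read-out network are uncoupled from the
    rest of the model; the fast clock's first cluster is kicked and the
    decoupled subsystem runs for one fast-clock cycle. The read-out
    excitatory rates are then compared to the binary motif target by DTW.
    """
    if label not in target.motifs:
        raise ConfigurationError(f"unknown motif label {label!r}")
    sub = _decoupled_motif_model(model, label)
    fc = sub.pop("Fc_E")
    duration = target.motifs[label].duration + margin
    sched = StimulusSchedule(duration=duration)
    first = np.arange(fc.cluster_slice(0, local=True).stop - fc.cluster_slice(0, local=True).start)
    sched.add("Fc_E", first, FC_START_RATE, "exc", 0.0, FC_START_DURATION)
    res = run(sub, sched, SimulationConfig(duration=duration, seed=seed))
    rates = smooth_normalize(res.raster, f"R_{label}_E")
    return dtw_error(rates, target.motif_target(label))


def ordering_error(model: ModelSpec, raster: SpikeRaster,
                   target: TargetSequence, sequence: int = 0) -> float:
    """Syntax error: interneuron rates vs the binary interneuron target."""
    pop = f"In{sequence}"
    group_size = raster.populations[pop][1] // (len(target.labels) + 1)
    rates = smooth_normalize(raster, pop, t1=target.duration)
    return dtw_error(rates, target.interneuron_target(group_size))


def total_error(model: ModelSpec, raster: SpikeRaster,
                target: TargetSequence, sequence: int = 0) -> float:
    """Whole-sequence error: read-out E rates vs the binary target."""
    pops = model.readout_pops(sequence if model.meta["kind"] == "serial"
                              else None)
    rates = smooth_normalize(raster, pops, t1=target.duration)
    return dtw_error(rates, target.matrix)


# ---------------------------------------------------------------------------
# variability statistics


def _pop_rate(raster: SpikeRaster, pop: str, sigma: float = 10.0,
              bin_ms: float = 1.0) -> np.ndarray:
    times, _ = raster.pop_events(pop)
    counts = _binned(times, np.zeros(times.size, dtype=int), 1,
                     raster.duration, bin_ms)
    return _smooth(counts, sigma / bin_ms)[0]


def motif_onsets(raster: SpikeRaster, model: ModelSpec,
                 target: TargetSequence, sigma: float = 10.0,
                 min_separation: float = 100.0) -> np.ndarray | None:
    """Onset time of each motif occurrence, or None if detection fails.

    A motif's occurrence time is the first bin at which its read-out
    population rate crosses half of its maximum over the trial; successive
    occurrences of the same motif are separated by at least
    ``min_separation`` ms.
    """
    serial = model.meta["kind"] == "serial"
    readouts = model.readout_pops(0 if serial else None)
    labels = target.labels
    crossings: dict[str, list[float]] = {}
    for lab, pop in zip(labels, readouts):
        rate = _pop_rate(raster, pop, sigma)
        if rate.max() <= 0:
            crossings[lab] = []
            continue
        above = rate >= 0.5 * rate.max()
        up = np.flatnonzero(above[1:] & ~above[:-1]) + 1
        if above[0]:
            up = np.concatenate([[0], up])
        sel: list[float] = []
        for t in up:
            if not sel or t - sel[-1] >= min_separation:
                sel.append(float(t))
        crossings[lab] = sel
    onsets = []
    used = {lab: 0 for lab in labels}
    for lab in target.order:
        k = used[lab]
        if k >= len(crossings[lab]):
            return None
        onsets.append(crossings[lab][k])
        used[lab] += 1
    return np.asarray(onsets)


def inter_motif_cv(rasters: list[SpikeRaster], model: ModelSpec,
                   target: TargetSequence) -> np.ndarray:
    """Coefficient of variation of each successive inter-onset gap across
    trials. Trials in which a motif occurrence cannot be detected are
    excluded with a warning."""
    if len(rasters) < 2:
        raise ConfigurationError("need at least two trials")
    gaps = []
    for k, raster in enumerate(rasters):
        ons = motif_onsets(raster, model, target)
        if ons is None:
            warnings.warn(f"trial {k}: motif occurrence not detected; "
                          "excluded", stacklevel=2)
            continue
        gaps.append(np.diff(ons))
    if len(gaps) < 2:
        raise ConfigurationError("fewer than two trials with detected motifs")
    g = np.vstack(gaps)
    mean = g.mean(axis=0)
    mean[mean == 0] = np.nan
    return g.std(axis=0, ddof=1) / mean


def motif_crosscorr_max(raster: SpikeRaster, model: ModelSpec,
                        occurrences: list[tuple[float, float]],
                        pops=None, sigma: float = 10.0) -> np.ndarray:
    """Similarity of repeated motif renditions within one trial.

    Per-neuron smoothed-rate segments of occurrence k are cross-correlated
    with occurrence 1, summed over neurons, normalized by occurrence 1's
    zero-lag autocorrelation sum; the maximum over lags is returned for each
    k >= 2 (1.0 means a time-shifted copy).
    """
    if len(occurrences) < 2:
        raise ConfigurationError("need at least two occurrences")
    if pops is None:
        pops = model.readout_pops(0 if model.meta["kind"] == "serial"
                                  else None)
    segs = []
    for (a, b) in occurrences:
        if not (0 <= a < b <= raster.duration):
            raise ConfigurationError(f"bad occurrence window ({a}, {b})")
        rm = smooth_normalize(raster, pops, sigma=sigma, t0=a, t1=b)
        segs.append(rm.rates)
    ref = segs[0]
    norm = float(np.einsum("nt,nt->", ref, ref))
    if norm == 0:
        raise ConfigurationError("reference occurrence has no activity")
    out = []
    for seg in segs[1:]:
        cc = fftconvolve(seg, ref[:, ::-1], mode="full", axes=1).sum(axis=0)
        out.append(float(cc.max() / norm))
    return np.asarray(out)


def cluster_activation_times(raster: SpikeRaster, pop: str,
                             sigma: float = 5.0, first: bool = True,
                             t0: float = 0.0) -> np.ndarray:
    """Activation time (ms) of each cluster: the first peak of its smoothed
    population rate reaching at least half the cluster's maximum (after
    ``t0``), or the global peak with ``first=False``. NaN for clusters that
    never fire."""
    start, size, _, n_clusters = raster.populations[pop]
    if not n_clusters:
        raise ConfigurationError(f"population {pop} has no clusters")
    times = np.full(n_clusters, np.nan)
    for c in range(n_clusters):
        t, _ = raster.cluster_events(pop, c)
        t = t[t >= t0]
        if t.size == 0:
            continue
        counts = _binned(t - t0, np.zeros(t.size, dtype=int), 1,
                         raster.duration - t0, 1.0)
        rate = _smooth(counts, sigma)[0]
        if first:
            peaks, _ = find_peaks(rate, height=0.5 * rate.max())
            times[c] = t0 + (float(peaks[0]) if peaks.size
                             else float(np.argmax(rate)))
        else:
            times[c] = t0 + float(np.argmax(rate))
    return times


def cluster_activation_std(rasters: list[SpikeRaster], pop: str,
                           sigma: float = 5.0
                           ) -> tuple[np.ndarray, float]:
    """Across-trial std (ms) of each cluster's activation time, and the
    maximum over clusters. Trials in which a cluster never fires are
    excluded for that cluster, with a warning."""
    if len(rasters) < 2:
        raise ConfigurationError("need at least two trials")
    acts = np.vstack([cluster_activation_times(r, pop, sigma)
                      for r in rasters])
    if np.any(np.isnan(acts)):
        warnings.warn("some clusters were inactive in some trials; those "
                      "trials are excluded per cluster", stacklevel=2)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        stds = np.array([np.nanstd(col[~np.isnan(col)], ddof=1)
                         if np.sum(~np.isnan(col)) >= 2 else np.nan
                         for col in acts.T])
    return stds, float(np.nanmax(stds))


def cluster_recurrence_times(raster: SpikeRaster, pop: str, cluster: int = 0,
                             sigma: float = 5.0,
                             min_separation: float = 100.0) -> np.ndarray:
    """Activation-event times of one cluster (peaks of its smoothed rate at
    least half the trial maximum, separated by ``min_separation`` ms); the
    diffs of successive events measure the clock's cycle duration."""
    t, _ = raster.cluster_events(pop, cluster)
    if t.size == 0:
        return np.empty(0)
    counts = _binned(t, np.zeros(t.size, dtype=int), 1, raster.duration, 1.0)
    rate = _smooth(counts, sigma)[0]
    peaks, _ = find_peaks(rate, height=0.5 * rate.max(),
                          distance=max(int(min_separation), 1))
    return peaks.astype(float)
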