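import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from motifnet import (
    ConfigurationError,
    SpikeRaster,
    compose_target,
    dtw_error,
    inter_motif_cv,
    make_motif,
    motif_crosscorr_max,
    smooth_normalize,
)
from motifnet.metrics import (
    RateMatrix,
    _dtw_accumulate,
    cluster_activation_std,
    cluster_activation_times,
    ordering_error,
)


def raster_from_events(times, ids, duration, populations):
    order = np.argsort(times, kind="stable")
    return SpikeRaster(times=np.asarray(times, float)[order],
                       ids=np.asarray(ids, np.int32)[order],
                       duration=duration, populations=populations)


ONE_POP = {"P": (0, 4, "E", None)}


class TestSmoothNormalize:
    def test_empty_raster(self):
        r = raster_from_events([], [], 100.0, ONE_POP)
        rm = smooth_normalize(r, "P")
        assert rm.rates.shape == (4, 100)
        assert not rm.rates.any()

    def test_single_spike_peaks_at_one(self):
        r = raster_from_events([50.0], [2], 100.0, ONE_POP)
        rm = smooth_normalize(r, "P")
        assert rm.rates.max() == pytest.approx(1.0)
        assert np.argmax(rm.rates[2]) == 50
        assert not rm.rates[[0, 1, 3]].any()

    def test_two_spikes_match_gaussian_sum_oracle(self):
        """Two spikes 5 ms apart: the smoothed rate equals the direct sum of
        two (normalized) Gaussian kernels."""
        sigma = 10.0
        r = raster_from_events([40.0, 45.0], [0, 0], 100.0, ONE_POP)
        rm = smooth_normalize(r, "P", sigma=sigma)
        radius = int(np.ceil(3 * sigma))
        k = np.exp(-0.5 * (np.arange(-radius, radius + 1) / sigma) ** 2)
        k /= k.sum()
        t = np.arange(100)
        oracle = np.zeros(100)
        for s in (40, 45):
            m = np.abs(t - s) <= radius
            oracle[m] += k[(t - s)[m] + radius]
        oracle /= oracle.max()
        assert np.allclose(rm.rates[0], oracle, atol=1e-9)
        # peak lies between the two spikes
        assert 40 <= np.argmax(rm.rates[0]) <= 45

    def test_time_shift_invariance(self):
        base = [30.0, 42.0, 55.0]
        r1 = raster_from_events(base, [1] * 3, 200.0, ONE_POP)
        r2 = raster_from_events([t + 60 for t in base], [1] * 3, 200.0,
                                ONE_POP)
        a = smooth_normalize(r1, "P").rates[1]
        b = smooth_normalize(r2, "P").rates[1]
        assert np.allclose(a[:120], b[60:180], atol=1e-12)

    def test_values_in_unit_interval(self, rng):
        times = rng.uniform(0, 500, 300)
        ids = rng.integers(0, 4, 300)
        r = raster_from_events(times, ids, 500.0, ONE_POP)
        rm = smooth_normalize(r, "P")
        assert rm.rates.min() >= 0 and rm.rates.max() <= 1 + 1e-12


def brute_force_dtw(cost):
    """Exhaustive enumeration of all monotone warping paths."""
    n1, n2 = cost.shape
    best = [np.inf]

    def walk(i, j, acc):
        acc += cost[i, j]
        if acc >= best[0]:
            return
        if (i, j) == (n1 - 1, n2 - 1):
            best[0] = acc
            return
        if i + 1 < n1:
            walk(i + 1, j, acc)
        if j + 1 < n2:
            walk(i, j + 1, acc)
        if i + 1 < n1 and j + 1 < n2:
            walk(i + 1, j + 1, acc)

    walk(0, 0, 0.0)
    return best[0]


class TestDTW:
    def test_identical_is_zero(self, rng):
        x = rng.random((6, 20))
        assert dtw_error(x, x) == 0.0

    def test_pure_time_shift_absorbed(self):
        assert dtw_error(np.array([[0.0, 1.0, 0.0]]),
                         np.array([[0.0, 0.0, 1.0, 0.0]])) == 0.0

    def test_symmetry(self, rng):
        a, b = rng.random((4, 15)), rng.random((4, 12))
        assert dtw_error(a, b) == pytest.approx(dtw_error(b, a), rel=1e-12)

    def test_dimension_mismatch(self):
        with pytest.raises(ConfigurationError):
            dtw_error(np.zeros((3, 5)), np.zeros((4, 5)))

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_exhaustive_oracle(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.random((3, rng.integers(2, 6)))
        b = rng.random((3, rng.integers(2, 6)))
        aa = (a * a).sum(0)
        bb = (b * b).sum(0)
        cost = np.sqrt(np.maximum(
            aa[:, None] + bb[None, :] - 2 * a.T @ b, 0))
        total, length = _dtw_accumulate(cost)
        assert total == pytest.approx(brute_force_dtw(cost), rel=1e-12)
        assert max(cost.shape) <= length <= sum(cost.shape) - 1

    @settings(derandomize=True, max_examples=20, deadline=None)
    @given(st.integers(0, 10_000))
    def test_nonnegative_and_zero_only_when_warp_equal(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.random((2, 8))
        b = rng.random((2, 8))
        d = dtw_error(a, b)
        assert d >= 0
        if not np.array_equal(a, b):
            assert d > 0 or dtw_error(a, b) == 0  # degenerate equal-warp


class TestVariabilityStats:
    def test_inter_motif_cv_arithmetic(self):
        """Gaps {200, 210, 190} against a fixed first onset give
        CV = std/mean ~ 0.0408 (sample std)."""
        pops = {"R_A_E": (0, 2, "E", None)}
        import motifnet.metrics as M

        class FakeModel:
            meta = {"kind": "hierarchical"}
            motif_labels = ["A"]

            def readout_pops(self, sequence=None):
                return ["R_A_E"]

        motifs = {"A": make_motif("A", 50.0, 1)}
        target = compose_target(motifs, "AA", [150.0, 150.0],
                                n_exc_per_motif=2)
        rasters = []
        for gap in (200.0, 210.0, 190.0):
            times, ids = [], []
            for onset in (10.0, 10.0 + gap):
                times += [onset + k for k in range(5)]
                ids += [0, 1, 0, 1, 0]
            rasters.append(raster_from_events(times, ids, 500.0, pops))
        cv = inter_motif_cv(rasters, FakeModel(), target)
        gaps = np.array([200.0, 210.0, 190.0])
        assert cv[0] == pytest.approx(gaps.std(ddof=1) / gaps.mean(),
                                      abs=1e-3)
        assert cv[0] == pytest.approx(0.05, abs=0.011)

    def test_identical_trials_have_zero_cv(self):
        pops = {"R_A_E": (0, 2, "E", None)}

        class FakeModel:
            meta = {"kind": "hierarchical"}
            motif_labels = ["A"]

            def readout_pops(self, sequence=None):
                return ["R_A_E"]

        motifs = {"A": make_motif("A", 50.0, 1)}
        target = compose_target(motifs, "AA", [150.0, 150.0],
                                n_exc_per_motif=2)
        times = [10, 11, 12, 260, 261, 262]
        ids = [0, 1, 0, 1, 0, 1]
        rasters = [raster_from_events(times, ids, 400.0, pops)
                   for _ in range(3)]
        cv = inter_motif_cv(rasters, FakeModel(), target)
        assert cv[0] == 0.0

    def test_crosscorr_identical_and_shifted(self):
        pops = {"R_A_E": (0, 3, "E", None)}

        class FakeModel:
            meta = {"kind": "hierarchical"}

            def readout_pops(self, sequence=None):
                return ["R_A_E"]

        times, ids = [], []
        for onset in (20.0, 220.0, 430.0):       # third shifted by 10 ms
            shift = 10.0 if onset == 430.0 else 0.0
            for k, n in enumerate([0, 1, 2, 0, 1]):
                times.append(onset + shift + 8 * k)
                ids.append(n)
        r = raster_from_events(times, ids, 700.0, pops)
        occurrences = [(0.0, 120.0), (200.0, 320.0), (400.0, 520.0)]
        vals = motif_crosscorr_max(r, FakeModel(), occurrences)
        assert vals[0] == pytest.approx(1.0, abs=1e-6)
        assert vals[1] == pytest.approx(1.0, abs=1e-6)

    def test_crosscorr_orthogonal_is_zero(self):
        pops = {"R_A_E": (0, 4, "E", None)}

        class FakeModel:
            meta = {"kind": "hierarchical"}

            def readout_pops(self, sequence=None):
                return ["R_A_E"]

        times = [10.0, 20.0, 30.0, 110.0, 120.0, 130.0]
        ids = [0, 1, 0, 2, 3, 2]                 # disjoint neuron sets
        r = raster_from_events(times, ids, 200.0, pops)
        vals = motif_crosscorr_max(r, FakeModel(),
                                   [(0.0, 100.0), (100.0, 200.0)])
        assert vals[0] == pytest.approx(0.0, abs=1e-9)

    def test_cluster_activation_std_arithmetic(self):
        pops = {"C": (0, 4, "E", 2)}
        rasters = []
        for t0 in (100.0, 104.0, 96.0):
            times = [t0, t0 + 0.5, t0 + 1.0, 5.0, 5.5]
            ids = [0, 1, 0, 2, 3]
            rasters.append(raster_from_events(times, ids, 200.0, pops))
        stds, mx = cluster_activation_std(rasters, "C")
        assert stds[0] == pytest.approx(4.0, abs=0.5)
        assert stds[1] == pytest.approx(0.0, abs=0.5)
        assert mx == stds[0]

    def test_identical_trials_zero_std(self):
        pops = {"C": (0, 4, "E", 2)}
        r = raster_from_events([10.0, 11.0, 60.0, 61.0], [0, 1, 2, 3],
                               100.0, pops)
        stds, mx = cluster_activation_std([r, r, r], "C")
        assert np.allclose(stds, 0.0) and mx == 0.0


class TestOrderingError:
    def test_exact_target_spiking_scores_zero_like(self):
        """Interneurons firing exactly per the binary target give a small
        ordering error (zero up to smoothing-edge effects)."""
        motifs = {"A": make_motif("A", 40.0, 1), "B": make_motif("B", 40.0, 1)}
        target = compose_target(motifs, "AB", [40.0, 40.0],
                                n_exc_per_motif=2)
        gs = 2
        pops = {"In0": (0, 3 * gs, "I", 3)}
        it = target.interneuron_target(gs)
        times, ids = [], []
        for n in range(it.shape[0]):
            on = np.flatnonzero(it[n])
            times += [float(t) + 0.5 for t in on[::2]]
            ids += [n] * len(on[::2])
        r = raster_from_events(times, ids, target.duration, pops)

        class FakeModel:
            meta = {"kind": "hierarchical"}

        err = ordering_error(FakeModel(), r, target)
        scrambled = raster_from_events(times, ids[::-1], target.duration,
                                       pops)
        err_bad = ordering_error(FakeModel(), scrambled, target)
        assert err < 0.5
        assert err < 0.7 * err_bad
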