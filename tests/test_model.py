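import math

import numpy as np
import pytest

from motifnet import (
    ConfigurationError,
    InvalidScaleError,
    assemble_hierarchical,
    assemble_serial,
    build_fast_clock,
    build_inhibitory_slow_clock,
    build_serial_clock,
    build_slow_clock,
    clock_network,
    count_resources,
)


class TestClockBuilders:
    @pytest.mark.parametrize("build,n_exc,n_inh,n_clusters,f,fwd", [
        (build_fast_clock, 2000, 500, 20, 0.6325, 12.5),
        (build_slow_clock, 2800, 700, 28, 0.5345, 4.7),
        (build_serial_clock, 4800, 1200, 48, 0.4082, 6.0),
    ])
    def test_full_scale_parameters(self, build, n_exc, n_inh, n_clusters,
                                   f, fwd):
        spec = build(1.0)
        assert spec.n_exc == n_exc
        assert spec.n_inh == n_inh
        assert spec.n_clusters == n_clusters
        assert spec.forward_factor == fwd
        assert spec.within_factor == 25.0
        assert spec.p == 0.2
        # the scaling factor follows f = 1/sqrt(N/1000)
        assert spec.f == pytest.approx(f, abs=5e-5)
        assert spec.f == pytest.approx(
            1.0 / math.sqrt((n_exc + n_inh) / 1000), rel=1e-12)

    def test_fast_clock_restart_cluster(self):
        assert build_fast_clock().restart_last
        assert not build_slow_clock().restart_last

    def test_proportional_scaling_keeps_cluster_count(self):
        spec = build_fast_clock(0.5)
        assert (spec.n_exc, spec.n_clusters, spec.cluster_size) == (1000, 20, 50)
        assert spec.f == pytest.approx(1 / math.sqrt(1.25), rel=1e-12)

    @pytest.mark.parametrize("build", [build_fast_clock, build_slow_clock,
                                       build_serial_clock,
                                       build_inhibitory_slow_clock])
    def test_tiny_scale_rejected(self, build):
        with pytest.raises(InvalidScaleError):
            build(0.01)
        with pytest.raises(InvalidScaleError):
            build(0.0)
        with pytest.raises(InvalidScaleError):
            build(1.5)

    def test_serial_cluster_count_is_fast_plus_slow(self):
        assert (build_serial_clock().n_clusters
                == build_fast_clock().n_clusters
                + build_slow_clock().n_clusters)

    def test_inhibitory_slow_clock(self):
        spec = build_inhibitory_slow_clock()
        assert spec.n_inh == 2000 and spec.n_exc == 0
        assert spec.w_II == 30.0
        assert spec.w_II * spec.within_factor == pytest.approx(1.0)
        assert spec.w_II * spec.forward_factor == pytest.approx(15.0)
        assert spec.depression and spec.inhibitory_clusters


class TestRealization:
    def test_connectivity_density_binomial(self):
        model = clock_network(build_fast_clock(0.5), seed=3)
        W = model.block("Fc:EE").W
        n = W.shape[0]
        pairs = n * (n - 1)           # self-connections excluded
        density = np.count_nonzero(W) / pairs
        sigma = math.sqrt(0.2 * 0.8 / pairs)
        assert abs(density - 0.2) < 3 * sigma

    def test_no_self_connections(self):
        model = clock_network(build_fast_clock(0.25), seed=3)
        assert np.all(np.diag(model.block("Fc:EE").W) == 0)
        assert np.all(np.diag(model.block("Fc:II").W) == 0)

    def test_cluster_weight_structure(self):
        spec = build_fast_clock(0.25)
        model = clock_network(spec, seed=0)
        W = model.block("Fc:EE").W
        cs = spec.cluster_size
        within = W[:cs, :cs][W[:cs, :cs] > 0]
        fwd = W[cs:2 * cs, :cs][W[cs:2 * cs, :cs] > 0]
        base = W[3 * cs:4 * cs, :cs][W[3 * cs:4 * cs, :cs] > 0]
        wrap = W[:cs, 19 * cs:][W[:cs, 19 * cs:] > 0]
        assert np.allclose(within, spec.w_EE * 25)
        assert np.allclose(fwd, spec.w_EE * 12.5)
        assert np.allclose(wrap, spec.w_EE * 12.5)   # i -> i+1 mod 20
        assert np.allclose(base, spec.w_EE)


@pytest.fixture(scope="module")
def model():
    return assemble_hierarchical(n_motifs=2, n_sequences=1, scale=1.0, seed=0)


class TestHierarchicalAssembly:
    def test_population_sizes_match_capacity_accounting(self, model):
        rc = count_resources("hierarchical", 1, 2)
        assert model.n_neurons == rc.n_neurons == 7050

    def test_plastic_blocks(self, model):
        names = {b.name for b in model.plastic_blocks()}
        assert names == {"motif:A", "motif:B", "syntax:0"}
        for lab in "AB":
            blk = model.block(f"motif:{lab}")
            assert blk.W.shape == (300, 2000)
            assert np.all(blk.W == 0.3)
            assert (blk.plasticity.W_min, blk.plasticity.W_max) == (0, 1)
        syn = model.block("syntax:0")
        assert syn.W.shape == (300, 2800)
        assert np.all(syn.W == 0.1)
        assert syn.plasticity.W_max == pytest.approx(0.3)

    def test_interneuron_group_wiring(self, model):
        # group 0 (motif A) laterally inhibits read-out B, not A;
        # the silent group (last 100) inhibits every read-out neuron
        to_b = model.block("In0->R_B_E").W
        to_a = model.block("In0->R_A_E").W
        assert np.all(to_b[:, :100] == 50.0)      # A-group -> B
        assert np.all(to_b[:, 100:200] == 0.0)    # B-group -> B: none
        assert np.all(to_b[:, 200:] == 20.0)      # silent -> B
        assert np.all(to_a[:, :100] == 0.0)
        assert np.all(to_a[:, 100:200] == 50.0)

    def test_silent_group_spares_the_restart_cluster(self, model):
        W = model.block("In0->Fc_E").W
        assert np.all(W[1900:, :] == 0.0)         # last cluster untouched
        assert np.all(W[:1900, 200:] == 20.0)
        assert np.all(W[:, :200] == 0.0)          # motif groups don't gate Fc

    def test_fast_clock_to_silent_group(self, model):
        W = model.block("Fc_E->In0").W
        assert np.all(W[200:, 1800:1900] == 1.5)  # penultimate cluster
        assert np.all(W[200:, 1900:] == 0.4)      # last cluster
        assert np.all(W[200:, :1800] == 0.0)      # other clusters: none
        assert np.all(W[:200, :] == 0.0)

    def test_readout_excites_own_group(self, model):
        W = model.block("R_A_E->In0").W
        assert np.all(W[:100, :] == 0.4)
        assert np.all(W[100:, :] == 0.0)

    def test_two_sequences_are_disjoint_replicas(self):
        model = assemble_hierarchical(n_motifs=2, n_sequences=2, scale=1.0,
                                      seed=0)
        assert model.pop("In0").size == model.pop("In1").size == 300
        w0 = model.block("In0->R_A_E").W
        w1 = model.block("In1->R_A_E").W
        assert np.array_equal(w0, w1)
        # no block couples the two interneuron networks
        for blk in model.blocks:
            assert not (blk.source == "In0" and blk.target == "In1")
            assert not (blk.source == "In1" and blk.target == "In0")

    def test_unsupported_variant(self):
        with pytest.raises(ConfigurationError):
            assemble_hierarchical(variant="nonsense")

    def test_inhibitory_variant_uses_inverted_rule(self):
        model = assemble_hierarchical(scale=1.0, seed=1,
                                      variant="inhibitory-slow-clock")
        syn = model.block("syntax:0")
        assert syn.rule == "inverted-syntax"
        assert syn.plasticity.sign == -1
        assert "Sc_E" not in model.populations
        assert model.pop("Sc_I").depression


class TestSerialAssembly:
    def test_neuron_total(self):
        model = assemble_serial(n_motifs=2, n_sequences=1, scale=1.0, seed=0)
        assert model.n_neurons == 6000 + 750

    def test_plastic_synapse_count(self):
        model = assemble_serial(n_motifs=2, n_sequences=2, scale=1.0, seed=0)
        total = sum(b.W.size for b in model.plastic_blocks())
        assert total == 4800 * 600 * 2

    def test_clock_only(self):
        model = assemble_serial(n_motifs=2, n_sequences=0, scale=1.0, seed=0)
        assert model.n_neurons == 6000
        assert model.plastic_blocks() == []


class TestCountResources:
    @pytest.mark.parametrize("kind,ns,nm,neurons,synapses", [
        ("serial", 2, 2, 7500, 5_760_000),
        ("hierarchical", 2, 2, 7350, 4_130_000),
        ("serial", 2, 6, 10_500, 17_280_000),
        ("hierarchical", 2, 6, 9650, 13_630_000),
        ("serial", 0, 2, 6000, 0),
        ("serial", 1, 2, 6750, 2_880_000),
    ])
    def test_printed_totals(self, kind, ns, nm, neurons, synapses):
        rc = count_resources(kind, ns, nm)
        assert (rc.n_neurons, rc.n_synapses) == (neurons, synapses)

    def test_negative_rejected(self):
        with pytest.raises(ConfigurationError):
            count_resources("serial", -1)
        with pytest.raises(ConfigurationError):
            count_resources("unknown", 1)
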