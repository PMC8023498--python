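import numpy as np
import pytest

from motifnet import (
    ConfigurationError,
    assemble_hierarchical,
    assemble_serial,
    compose_target,
    learning_schedule,
    make_motif,
    spontaneous_schedule,
)
from motifnet.protocols import (
    ATTENTION_RATE,
    FC_START_RATE,
    START_RATE,
    SUPERVISOR_RATE,
)


@pytest.fixture(scope="module")
def model():
    return assemble_hierarchical(n_motifs=2, n_sequences=1, scale=0.5, seed=2)


@pytest.fixture(scope="module")
def motifs():
    return {lab: make_motif(lab, 200.0, 5) for lab in "AB"}


@pytest.fixture(scope="module")
def target(model, motifs):
    n_re = model.pop("R_A_E").size
    return compose_target(motifs, "AAB", [150.0] * 3, n_exc_per_motif=n_re)


class TestMotifTemplates:
    @pytest.mark.parametrize("n_groups,block", [(5, 40.0), (8, 25.0),
                                                (10, 20.0)])
    def test_equal_blocks(self, n_groups, block):
        tpl = make_motif("A", 200.0, n_groups)
        assert tpl.block_duration() == pytest.approx(block)
        bounds = tpl.group_bounds(300)
        assert bounds[0] == (0, 300 // n_groups)
        assert bounds[-1][1] == 300
        sizes = [b - a for a, b in bounds]
        assert sum(sizes) == 300 and max(sizes) - min(sizes) <= n_groups

    def test_degenerate_single_group(self):
        tpl = make_motif("A", 200.0, 1)
        assert tpl.group_bounds(300) == [(0, 300)]

    def test_invalid(self):
        with pytest.raises(ConfigurationError):
            make_motif("A", 0.0, 5)
        with pytest.raises(ConfigurationError):
            make_motif("A", 200.0, 0)


class TestComposeTarget:
    def test_aab_layout(self, motifs):
        tgt = compose_target(motifs, "AAB", [150.0] * 3)
        assert tgt.duration == 3 * 200 + 3 * 150 == 1050
        assert list(tgt.onsets) == [0.0, 350.0, 700.0]
        assert list(tgt.offsets) == [200.0, 550.0, 900.0]
        assert tgt.matrix.shape == (600, 1050)
        # motif A rows are active during both A occurrences
        a_rows = tgt.matrix[:300]
        assert a_rows[:, :200].any(axis=1).all()
        assert not a_rows[:, 700:900].any()
        b_rows = tgt.matrix[300:]
        assert b_rows[:, 700:900].any(axis=1).all()
        assert not b_rows[:, :550].any()

    def test_row_sums_equal_stimulated_time(self, motifs):
        tgt = compose_target(motifs, "AAB", [150.0] * 3)
        # each A neuron is stimulated 40 ms per occurrence, two occurrences
        assert np.allclose(tgt.matrix[:300].sum(axis=1), 80.0)
        assert np.allclose(tgt.matrix[300:].sum(axis=1), 40.0)

    def test_empty_order(self, motifs):
        tgt = compose_target(motifs, "", [])
        assert tgt.matrix.shape[1] == 0 and tgt.duration == 0

    def test_variable_length_sequence_accepted(self):
        """Four motifs of different durations with unequal gaps."""
        durs = {"A": 200.0, "B": 200.0, "C": 150.0, "D": 120.0}
        motifs = {k: make_motif(k, d, 5) for k, d in durs.items()}
        tgt = compose_target(motifs, "ABCD", [70.0, 50.0, 80.0, 0.0])
        assert tgt.duration == 200 + 70 + 200 + 50 + 150 + 80 + 120
        assert list(tgt.onsets) == [0.0, 270.0, 520.0, 750.0]

    def test_too_long_sequence_rejected(self, motifs):
        with pytest.raises(ConfigurationError):
            compose_target(motifs, "AAAAAA", [150.0] * 6)

    def test_gap_count_mismatch(self, motifs):
        with pytest.raises(ConfigurationError):
            compose_target(motifs, "AAB", [150.0] * 2)

    def test_interneuron_target_layout(self, motifs):
        tgt = compose_target(motifs, "AB", [100.0, 100.0])
        it = tgt.interneuron_target(group_size=10)
        assert it.shape == (30, 600)
        assert it[:10, :200].all() and not it[:10, 200:].any()     # A group
        assert it[10:20, 300:500].all()                            # B group
        assert it[20:, 200:300].all() and it[20:, 500:600].all()   # silent
        assert not it[20:, :200].any()


class TestLearningSchedule:
    def test_pulse_structure(self, model, target):
        sched = learning_schedule(model, target)
        starts = [e for e in sched.entries
                  if e.pop == "Sc_E" and e.rate_kHz == START_RATE]
        fc = [e for e in sched.entries
              if e.pop == "Fc_E" and e.rate_kHz == FC_START_RATE
              and e.t1 - e.t0 == 40.0]
        sup = [e for e in sched.entries if e.pop.startswith("R_")]
        assert len(starts) == 1 and (starts[0].t0, starts[0].t1) == (0, 10)
        assert len(fc) == 3                       # one per motif occurrence
        assert sorted(e.t0 for e in fc) == [0.0, 350.0, 700.0]
        assert len(sup) == 15                     # 3 occurrences x 5 groups
        assert all(e.rate_kHz == SUPERVISOR_RATE for e in sup)

    def test_supervisor_tiles_each_motif(self, model, target):
        sched = learning_schedule(model, target)
        for onset, label in zip((0.0, 350.0, 700.0), "AAB"):
            wins = sorted((e.t0, e.t1) for e in sched.entries
                          if e.pop == f"R_{label}_E"
                          and onset <= e.t0 < onset + 200)
            assert wins[0][0] == onset and wins[-1][1] == onset + 200
            for (a0, a1), (b0, b1) in zip(wins, wins[1:]):
                assert a1 == b0                  # no overlap, no holes

    def test_stop_signal_for_short_motifs(self, model):
        n_re = model.pop("R_A_E").size
        motifs = {"A": make_motif("A", 150.0, 5), "B": make_motif("B", 200.0, 5)}
        tgt = compose_target(motifs, "A", [100.0], n_exc_per_motif=n_re)
        sched = learning_schedule(model, tgt)
        fc = model.pop("Fc_E")
        pen = fc.cluster_slice(fc.n_clusters - 2, local=True)
        stops = [e for e in sched.entries
                 if e.pop == "Fc_E" and e.t1 - e.t0 == 10.0
                 and np.array_equal(e.idx, np.arange(pen.start, pen.stop))]
        assert len(stops) == 1 and stops[0].t0 == 150.0

    def test_no_stop_for_full_period_motifs(self, model, target):
        sched = learning_schedule(model, target)
        stops = [e for e in sched.entries
                 if e.pop == "Fc_E" and e.t1 - e.t0 == 10.0]
        assert stops == []

    def test_zero_presentations(self, model, target):
        sched = learning_schedule(model, target, n_presentations=0)
        assert sched.entries == []

    def test_tiled_presentations(self, model, target):
        one = learning_schedule(model, target, n_presentations=1)
        three = learning_schedule(model, target, n_presentations=3)
        assert len(three.entries) == 3 * len(one.entries)
        assert three.duration == pytest.approx(3 * target.duration)

    def test_serial_schedule_has_no_fast_clock_pulses(self, target):
        serial = assemble_serial(n_motifs=2, scale=0.5, seed=1)
        n_re = serial.pop("R0_A_E").size
        motifs = {lab: make_motif(lab, 200.0, 5) for lab in "AB"}
        tgt = compose_target(motifs, "AAB", [150.0] * 3,
                             n_exc_per_motif=n_re)
        sched = learning_schedule(serial, tgt)
        pops = {e.pop for e in sched.entries}
        assert "Fc_E" not in pops
        assert any(p == "Sm_E" for p in pops)


class TestSpontaneousSchedule:
    def test_plain_replay(self, model):
        sched = spontaneous_schedule(model, 1000.0)
        assert len(sched.entries) == 1
        e = sched.entries[0]
        assert (e.pop, e.rate_kHz, e.t0, e.t1) == ("Sc_E", START_RATE, 0, 10)

    def test_zero_duration(self, model):
        assert spontaneous_schedule(model, 0.0).entries == []

    def test_attention_inhibits_other_sequences(self):
        m2 = assemble_hierarchical(n_motifs=2, n_sequences=2, scale=0.5,
                                   seed=3)
        sched = spontaneous_schedule(m2, 800.0, attended_sequence=0)
        inh = [e for e in sched.entries if e.channel == "inh"]
        assert len(inh) == 1
        assert inh[0].pop == "In1"
        assert inh[0].rate_kHz == ATTENTION_RATE
        assert (inh[0].t0, inh[0].t1) == (0.0, 800.0)

    def test_unknown_sequence_rejected(self, model):
        with pytest.raises(ConfigurationError):
            spontaneous_schedule(model, 500.0, attended_sequence=3)

    def test_schedules_are_pure_data(self, model, target):
        s1 = learning_schedule(model, target)
        s2 = learning_schedule(model, target)
        assert s1.entries == s2.entries and s1.overrides == s2.overrides
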