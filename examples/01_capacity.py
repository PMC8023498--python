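"""Capacity accounting: hardware needed to store multiple sequences.

Builds no network — evaluates the neuron/synapse accounting for the serial
and hierarchical architectures as the number of stored two-motif sequences
grows. The hierarchical model adds one ~300-neuron interneuron network per
sequence and re-uses its motif synapses, while the serial model duplicates
whole read-out networks, so the hierarchical totals grow much more slowly.
"""

from motifnet import count_resources

print(f"{'N_S':>4} | {'serial neurons':>14} {'serial synapses':>15} | "
      f"{'hier neurons':>12} {'hier synapses':>13}")
for n_seq in range(0, 9, 2):
    s = count_resources("serial", n_seq, n_motifs=2)
    h = count_resources("hierarchical", n_seq, n_motifs=2)
    print(f"{n_seq:>4} | {s.n_neurons:>14,} {s.n_synapses:>15,} | "
          f"{h.n_neurons:>12,} {h.n_synapses:>13,}")

print("\nTwo sequences of two motifs: serial needs "
      f"{count_resources('serial', 2).n_synapses:,} synapses, hierarchical "
      f"{count_resources('hierarchical', 2).n_synapses:,} — the savings come "
      "from sharing the motif synapses across sequences.")
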