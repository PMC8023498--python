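"""The all-inhibitory slow-clock variant.

The slow clock can also be built from inhibitory neurons only: 20 groups of
100 I neurons with weak within-group (1 pF) and strong forward (15 pF)
inhibition. Such a ring cannot sequence on its own — short-term depression
(tau = 200 ms, 7% per spike) fatigues the active group's outgoing
inhibition so the next group is released, producing slow disinhibition
waves. In the full variant model the syntax synapses onto the gates then
use an inverted STDP window (active slow-clock groups *release* rather
than drive their gates).
"""

import numpy as np

from motifnet import (
    SimulationConfig,
    StimulusSchedule,
    build_inhibitory_slow_clock,
    clock_network,
    run,
)

spec = build_inhibitory_slow_clock(scale=0.5)
print(f"inhibitory slow clock: {spec.n_inh} I neurons in {spec.n_clusters} "
      f"groups; within {spec.w_II * spec.within_factor:.1f} pF, forward "
      f"{spec.w_II * spec.forward_factor:.1f} pF, short-term depression on")

model = clock_network(spec, seed=2)
sched = StimulusSchedule(duration=1200.0)
sched.add("Sc_I", np.arange(spec.cluster_size), 5.0, "exc", 0.0, 10.0)
res = run(model, sched, SimulationConfig(duration=1200.0, seed=4))

r = res.raster
cs = spec.cluster_size
print("\nmost active group per 150 ms window (the wave advances around "
      "the ring as depression fatigues each group's outgoing inhibition):")
for w0 in range(0, 1200, 150):
    m = (r.times >= w0) & (r.times < w0 + 150)
    if m.sum() < 5:
        print(f"  t={w0:4.0f} ms: quiet")
        continue
    counts = np.bincount(r.ids[m] // cs, minlength=spec.n_clusters)
    print(f"  t={w0:4.0f} ms: group {counts.argmax():2d} "
          f"(population rate {m.sum() / spec.n_inh / 0.15:.0f} Hz)")
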