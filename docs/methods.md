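# Methods

`motifnet` simulates a hierarchical spiking-network architecture that learns
compositional temporal sequences: short stereotyped *motifs* realized by
dedicated read-out networks, and their temporal ordering (*syntax*) realized
by an inhibitory gating circuit. This note records the model equations, the
numerical conventions the package commits to, the design choices that were
genuinely open, and what the reduced-scale test models do and do not show.

## Model

### Neurons

Excitatory neurons are conductance-based adaptive exponential
integrate-and-fire (AdEx):

    dV/dt = (E_L - V + Delta_T exp((V - V_T)/Delta_T)) / tau_E
            + g_E (E_exc - V)/C + g_I (E_inh - V)/C - a/C

with an adaptive threshold V_T (time constant tau_T = 30 ms) and an
adaptation current a (tau_a = 100 ms, subthreshold coupling alpha = 4 nS,
spike jump beta = 0.805 pA). A spike is declared when the divergence passes
+20 mV; V resets to -60 mV and is clamped there for the 5 ms absolute
refractory period. Inhibitory neurons are plain leaky integrate-and-fire
with a fixed -52 mV threshold. All membrane constants are in
`motifnet.params.NeuronParams`.

**Threshold-jump convention.** After a spike the excitatory threshold is
*set to* V_T + A_T = -42 mV (a fixed post-spike ceiling, relaxing back to
-52 mV with tau_T), rather than accumulating +A_T per spike. The ceiling
reading follows the convention of the parameter set's lineage (it models
transient sodium-channel inactivation), and it is the reading under which
the clock networks below run at their stated cycle durations; the
accumulating alternative halves the fast-clock period and quarters the
slow-clock period. The additive variant remains available via
`NeuronParams(cumulative_threshold=True)`.

### Synapses

Each neuron carries one conductance channel per source type (E/I), realized
as two auxiliary states whose difference reproduces the normalized
difference-of-exponentials kernel K(t) exactly for impulse inputs (the
auxiliary states decay by exact exponential factors per step; the membrane
equations use forward Euler at dt = 0.1 ms). A spike through a weight W
(pF) injects total conductance area W; weights are non-negative and the
sign of an interaction is carried by the source type's reversal potential.
External input is an independent Poisson process per neuron (4.5 kHz
through 1.6 pF onto E neurons, 2.25 kHz through 1.52 pF onto I neurons,
including the gating interneurons). Spikes emitted at step k reach their
targets' conductances at step k+1; there are no further delays.

### Networks

* **Fast clock**: 2000 E in 20 clusters + 500 I. Baseline weights are
  multiples of f = 1/sqrt(N/1000) = 0.6325; within-cluster E-E x25,
  cluster i to i+1 (mod 20) x12.5. The asymmetric ring makes an activity
  bump travel around the cycle in ~200 ms. The *last* cluster is special:
  it is exempt from 'silent'-gate inhibition, stays active through silent
  gaps and re-ignites cluster 1 when the gap ends.
* **Slow clock**: 2800 E in 28 clusters + 700 I, f = 0.5345, forward
  coupling x4.7, cycling in ~1000 ms and spanning a whole sequence.
* **Read-outs**: one balanced 300 E / 75 I network per motif (absolute
  weights, Table-style: 3/6/190/60 pF), no connections between read-outs.
* **Interneuron (gate) networks**: one per stored sequence; one 100-neuron
  group per motif plus one 'silent' group, all-to-all-ish recurrent
  inhibition at 25 pF. The group for motif m is excited by motif m's
  read-out (0.4 pF) and laterally inhibits the *other* read-outs (50 pF);
  the silent group inhibits every read-out neuron (20 pF) and every fast
  clock cluster except the last (20 pF), and is excited by the fast
  clock's penultimate (1.5 pF) and last (0.4 pF) clusters.
* **Serial baseline**: a single 4800 E / 1200 I clock of 48 clusters
  (f = 0.4082, forward x6) wired straight to per-sequence read-outs; no
  gates.

Plastic projections are all-to-all: fast-clock E to read-out E (motif
synapses, initial 0.3 pF, bounds [0, 1] pF) and slow-clock to interneurons
(syntax synapses, initial 0.1 pF, bounds [0, 0.3] pF). Recurrent
connectivity within every network is Bernoulli p = 0.2 without
self-connections. The all-to-all inter-network blocks are what makes the
capacity accounting in `count_resources` exact.

### Plasticity

Both plastic pathways follow a symmetric trace-based STDP rule with
constant depression:

    dW/dt = -A_dep + A_pot (y_post s_pre + y_pre s_post),

where y is the spike train low-pass filtered with the rule's tau. Two unit
conventions had to be fixed:

* **Trace jump = 1/tau per spike** — the literal impulse response of the
  filter, so traces approximate firing rates in kHz. With unit jumps the
  motif pathway saturates in ~10 presentations and the syntax pathway in
  ~1, destroying the gate bootstrap; with 1/tau both pathways learn over
  tens of presentations, matching the intended learning timescales.
* **A_dep is pF per 0.1 ms step** (the printed depression amplitudes are
  then commensurate with the weight bounds over a training run);
  `PlasticityParams(dep_per_ms=True)` switches to a per-ms reading.

Potentiation is applied per spike event using traces that include the
current step's spikes (an exact coincidence counts fully on both sides);
weights are clipped to their bounds after every step. Plasticity runs
during target presentations and is frozen during evaluation replays. The
all-inhibitory slow-clock variant uses the same rule with the right-hand
side negated (inverted window) and adds short-term depression
(tau = 200 ms, 7% per spike) multiplying each neuron's outgoing weights at
delivery time.

## Protocols

Every run starts *cold*: V uniform in [V_r, V_T], thresholds at rest, zero
conductances and adaptation. This is deliberate: the clocks are
self-starting attractors, and after any settling period a free-running
bump forms whose phase the weak 5 kHz / 10 ms start current cannot
capture. From a cold start the kick captures reliably (the fast clock's
kick-to-recurrence time is then 200 ms). A warm-up option exists in
`SimulationConfig` for studying the free-running regime.

Learning presents the target repeatedly (each presentation an independent
run; weights persist): a 5 kHz x 10 ms start current to the slow clock's
first cluster, a 50 kHz x 40 ms current to the fast clock's first cluster
at each motif onset, a 50 kHz supervisor Poisson drive tiling each motif's
read-out groups, and — for motifs shorter than the fast-clock period — a
10 ms stop signal (same rate as the start) to the penultimate fast-clock
cluster at motif offset. Spontaneous replay uses only the slow-clock kick
plus background input; with several stored sequences, a 20 kHz inhibitory
drive (a chosen constant; the attention magnitude is an open protocol
parameter) silences the non-attended gate networks. Perturbation
experiments zero the baseline excitatory external input of a neuron subset
for a 250 ms window.

## Error measures

Spike trains are binned at 1 ms, convolved with a Gaussian (sigma = 10 ms,
truncated at +-3 sigma — "width ~10 ms" is read as the standard
deviation), and normalized per neuron to [0, 1] (per-neuron rather than
global maxima, because normalization follows per-neuron rate estimation;
the global alternative is a flag). Replay errors are multivariate dynamic
time warping distances between rate matrices and binary targets: frame
cost is the Euclidean distance over neurons, and the accumulated cost is
divided by the warping-path length so errors are comparable across
sequence lengths. The motif error decouples the fast clock + one read-out
from the rest of the model, kicks the fast clock, and runs one cycle; the
ordering error compares interneuron rates to the binary gate target (group
m active during motif m, silent group during gaps); the total error
compares all read-out E rates to the full sequence target.

Variability statistics avoid warping: motif onsets are the first crossing
of half the trial-maximum population rate (a declared convention); the
inter-motif interval CV uses sample std over trials; motif
cross-correlations are normalized by the first occurrence's zero-lag
autocorrelation; cluster activation times are first half-maximum peaks of
the smoothed cluster rate (sigma = 5 ms for the clock measurements).

## Reduced-scale models

Scaled-down fixtures are a design of this package, not of the reference
architecture, and three rules emerged from testing:

1. **Standalone clock builders** scale every population proportionally
   (cluster counts fixed) and recompute f = 1/sqrt(N/1000).
2. **Assembled models floor the clocks and gates at scale 0.5**
   (`CLOCK_MIN_SCALE`): below ~50 neurons per cluster the slow clock's
   marginal bump propagation stalls, and the gate competition becomes
   fluctuation-dominated. Read-out networks scale fully, keeping each
   neuron's expected in-degree (denser connectivity, unscaled weights);
   all-to-all inter-network weights, plastic bounds and plasticity
   amplitudes are multiplied by full/scaled source size so every target's
   mean drive is preserved.
3. **Scale 0.5 is the smallest configuration at which the full
   learn-park-restart-replay loop functions**; at 0.25 the parked restart
   cluster's drive to the silent gate outweighs the supervisor-driven gate
   switch and learning collapses after the first silent gap. Desk-scale
   learning experiments therefore run at 0.5.
4. **Scaled gate networks use dense recurrent inhibition with
   mean-preserving weights** (many small IPSPs instead of p = 0.2 large
   ones): the gate groups' winner-take-all exclusivity — silent group off
   during motifs, exactly one motif group on — is destroyed by the coarser
   IPSP granularity of a sparsely wired small network. Full-size models
   keep the printed sparse wiring.
5. **Desk learning protocol**: supervisor and fast-clock start currents are
   doubled to 100 kHz (the architecture requires the supervisor to
   overwrite stored dynamics and the start current to evict the parked
   restart cluster; at half scale the full-scale 50 kHz values lose these
   races), and plasticity amplitudes run at x2 (hierarchical) or x4
   (serial) so the learning and unlearning timescales fit a desk run. The
   serial baseline uses 100 ms motifs with 75 ms gaps.

Desk-scale limits worth knowing: the slow clock's accumulated timing
jitter (~35 ms max activation-time std by design) smears gap/motif
boundaries in cluster space, so the silent gate's syntax weights retain
weight inside motif windows and spontaneous-replay gate switching — which,
unlike learning, has no supervisor to bias it — succeeds for only part of
the sequence's motif slots per replay at half scale (at full scale, most).
Desk replay errors therefore improve far less than the full, hours-scale
experiments would; the weight-structure readouts (motif saturation, syntax
block structure of the motif rows) are the reliable desk-scale evidence of
learning.

Reduced-scale models halve per-synapse fluctuation smoothing relative to
the full model, so they underestimate gate-switch reliability and somewhat
shorten clock periods; passing tests at desk scale demonstrate the
mechanisms (independent motif/syntax learning, relearning dissociation,
robustness), not the full model's quantitative error levels.

## Numerical choices and degenerate inputs

* dt = 0.1 ms forward Euler; halving dt moves subthreshold trajectories by
  < 0.5 mV over 200 ms and slow-clock periods by ~4%.
* The AdEx exponential argument is capped (a membrane that far above
  threshold fires within the step regardless).
* Empty schedules, zero-duration runs and zero-rate inputs are exact
  no-ops; non-finite states abort with the step and neuron identified.
* Weight matrices are dense; blocks with no source spikes in a step are
  skipped.
* DTW frame costs below 1e-12 (squared) are clamped to zero so identical
  sequences score exactly 0.

## Known limitations

* The slow clock's free cycle in this implementation is ~15-25% longer
  than its nominal 1000 ms design target (the fast clock lands on 200 ms).
  The cycle duration of these clustered rings is extremely sensitive to
  integration conventions; the residual gap survived every alternative
  convention tested (threshold jump semantics, self-connections, dt,
  adaptation increments) without breaking some other stated property.
* At replay time the first motif's internal alignment depends on the fast
  clock's free-running phase at sequence start; the warping-based errors
  absorb this, but un-warped measures see it.
* Gate switching at reduced scale is less reliable than at full scale (see
  above); results at scale < 0.5 are not meaningful.
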