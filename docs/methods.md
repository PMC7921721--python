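# Model and methods

`spikeseq` simulates a spiking network that memorizes short spatial-symbol
sequences in a working-memory circuit (WMC), learns a production grammar —
*repeat* (same order) or *mirror* (reversed order) — in a reinforcement
learning circuit (RLC), and reads the two out jointly through a small motor
layer.  This note records the model equations, the constants they use, the
mechanisms behind each stage, and the design choices made where the model
itself leaves the implementation open.

## Neuron model

All neurons are discrete-time leaky integrate-and-fire units integrated
with forward Euler at `dt = 1 ms`:

    tau_m dV/dt = -(V - V_s) + I / g,     V -> V_reset  when  V >= V_threshold,

with membrane capacitance `C_m = 30 nF`, `tau_m = 30 ms`, leak conductance
`g = C_m / tau_m = 1 µS`, `V_reset = V_s = -65 mV` (the leak reversal is
tied to the reset), `V_threshold = -35 mV`, and an absolute refractory
period `tau_ref = 10 ms` during which the voltage is clamped at reset.  A
neuron's input current is the sum of synaptic current (previous step's
presynaptic spikes weighted by the connection matrix, i.e. a one-step
transmission delay), external Poisson-encoded stimulation, and optional
zero-mean Gaussian background current of variance σ² (the noise intensity
swept in the robustness experiments).

Forward Euler at 1 ms is accurate here because every membrane time
constant is ≥ 20 ms; the simulated constant-current interspike interval
matches the closed-form LIF period within one step (tested).

Motor-layer neurons are the one deliberate exception to homogeneity: they
use a slower leak (`tau_m = 40 ms`), which lets them integrate the
conjunction of their two input streams across a production slot, and a
sub-step refractory period, which allows the persistent-activity loop of
the competitive-queuing readout (below) to reverberate.

## Plasticity

**Pairwise STDP** with Δt = t_post − t_pre:

    dw = +A_plus  * exp(-|Δt|/tau_s)   for 0 < Δt < tau_w   (pre leads)
    dw = -A_minus * exp(-|Δt|/tau_s)   for -tau_w < Δt < 0  (post leads)

with `A_plus = 4`, `A_minus = 0.95`, `tau_s = 15 ms`, `tau_w = 10 ms`.
Pairing is nearest-neighbor: each spike pairs with the most recent spike
on the opposite side; simultaneous spikes contribute nothing.  Weights are
clipped to `[0, w_max]` after every update.  Nearest-neighbor pairing was
chosen over all-to-all because the potentiation rate (A_plus = 4) is large;
unbounded pairing would saturate every co-active connection within a single
presentation.

**Reward-modulated STDP.**  On the reinforcement-learning synapses the same
pairing increments do not change weights directly; they accumulate in a
per-synapse eligibility trace with Euler dynamics
`e += (-e/tau_e) dt + STDP increments` (`tau_e = 200 ms`, long enough to
bridge the gap between production activity and the end-of-trial outcome).
When the neuromodulator is present the weights move as `ΔW = eta * R * e * dt`
(R-max policy, M = R), with `R(t) = C_r = +10` for `T_R = 5` steps after a
reward, `C_p = -10` for `T_R` after a punishment, 0 otherwise, and gain
`eta = 0.02`.  The increments are treated as impulses per pairing event,
and `T_R` is counted in steps (identical to ms at dt = 1).

## Symbol encoding

A displayed symbol is translated into Poisson-encoded current pulses into
its population: per step, each neuron independently receives an event of
amplitude 2400 nA with probability `rate·dt` (rate 150 Hz), preceded by a
brief onset transient (800 Hz for the first 5 ms).  Two properties of this
encoding matter:

* a single event is supra-threshold, so a stimulated neuron fires promptly
  after its first event and then at its own event-driven rhythm — the
  population stays *desynchronized*, which makes the STDP pairing mass at
  window boundaries statistically stable from trial to trial;
* the onset transient gives short first-spike latencies at each window
  boundary, so the pre-window's trailing spikes and the next window's
  leading spikes fall inside the ±10 ms pairing window.

The production start signal (begin/cue populations) instead uses dense
small events (800 Hz, 600 nA): the start populations then fire in
synchronous volleys, which is what ignites replay (below).

## Working memory: population coding, chain formation, replay

One excitatory population of `C = 60` neurons per symbol (six symbols)
plus a "begin" population; each population drives its own pool of 20
inhibitory neurons (gain +18 nA), and each symbol population's inhibitory
pool projects −2 nA onto every other symbol population (lateral
inhibition).  All ordered pairs of distinct populations (begin→symbol,
symbol→symbol) are connected all-to-all with STDP synapses initialized
uniformly on `[0, 0.01·w_max]`.

During the memory stage the begin population and then each symbol's
population are stimulated for 60 ms each, the whole sequence presented 10
times.  Only at the window boundaries do pre/post spikes fall within the
STDP window, so the weights that grow are exactly the directed chain
begin→s1→s2→s3; with 10 presentations the chain edges saturate at
`w_max = 13` while reverse and skip edges stay near zero.  The saturation
cap is deliberate: it makes the trained chain weight nearly deterministic
(independent of the stochastic pairing history), and it keeps a single
60-neuron volley sub-threshold (60·13/30 = 26 mV < 30 mV), so replay
propagates by temporal summation of successive volleys rather than as a
one-step synfire flash.

During replay (production or a recall probe) the begin population fires in
volleys; each downstream population crosses threshold after integrating
two to three volleys of its predecessor, so the sequence unrolls as a wave
with a hop of roughly 24 ms per symbol.  Replay is decoded by strict
majority: a population "outputs its symbol" once more than half of its
excitatory neurons have fired, and the decoded sequence is the order of
those majority crossings.

Two regimes of the same circuit are used deliberately:

* **recall probes** give a long start signal (140 ms), which sustains the
  wave so late populations are fully recruited — this is the memory test;
* **production** gives a start signal just long enough to carry the wave
  across all positions, because production reads the wave's timing.

The stimulation rate (150 Hz) is low enough that a stimulated population's
asynchronous firing, minus lateral inhibition, stays below the ignition
threshold of downstream populations.  This blocks spontaneous mid-memory
replay (which would otherwise wire spurious skip/reverse edges once the
chain is strong) while the pulsed volleys of true replay still pass.

## Motor layer: conjunction readout with competitive queuing

The motor circuit has one position population per output slot with one
motor neuron per symbol.  Motor neuron (s, k) receives:

* +7.5 nA from every neuron of symbol population s (sub-threshold charge
  that tracks which symbols are currently replaying), and
* +10 nA from every neuron of RLC postsynaptic position population k (the
  position gate; also sub-threshold alone).

Only the conjunction — symbol s replaying while position k is gated —
drives a motor neuron over threshold.  The readout then follows a
competitive-queuing discipline built from static projections:

* each motor neuron has a "hold" partner in a strong reciprocal loop;
  once the motor neuron has fired twice in quick succession the pair
  reverberates for the rest of production (a persistent-activity latch —
  one isolated spike, e.g. noise-driven, is deliberately not enough);
* the winner's hold neuron persistently inhibits the other symbols of its
  position (winner-take-all: one symbol per position) and its own symbol
  in every other position (inhibition of return: a produced symbol is
  withdrawn from the competition).

The inhibition of return is what disambiguates replay: during the wave an
earlier symbol's population keeps volleying in near-synchrony with its
successor's onset, so "currently replaying" alone cannot distinguish them
— but the earlier symbol has already been produced and its motor neurons
are silenced.  This also makes slot binding rank-based and tolerant of
replay-timing jitter: at each slot the strongest unsuppressed charge wins.
The produced sequence is decoded per position by the first motor spike
(ties broken toward the lowest symbol id; a silent position is a gap and
counts as wrong).

## Reinforcement learning circuit

The presynaptic side (cue + one population per position) is stepped
through the output slots by externally timed stimulation windows (40 ms
wide, 24 ms apart — one per replay hop; the final window is extended by
two hops to absorb accumulated replay jitter, having no later symbol to
collide with).  The postsynaptic side (end
+ one population per position) receives only the reward-modulated
projections from the presynaptic side, all pairs initialized identically
near zero.  What the network learns is *which postsynaptic position each
slot drives*: after training, the mean-weight block matrix has its row
argmaxes on the identity (repeat) or the anti-diagonal (mirror), and that
permutation routes the currently replayed symbol into the right output
position.

Training follows the animal-style shaping that the task requires: in each
trial a fresh random sequence is memorized and produced; during the
shaping phase the correct postsynaptic population is additionally cued in
its slot, so the network produces mostly correct sequences, collects
rewards, and the eligibility laid down between co-active presynaptic and
postsynaptic populations is converted into weight.  A single reward is
delivered per trial, after the full output; during the shaping phase an
incorrect trial simply earns nothing (errorless shaping — punishing
cued-but-failed trials would drain exactly the projections being taught),
while in free trials any error is punished.  During shaping the slot
windows are narrowed to 24 ms so they do not overlap: with the ±10 ms STDP
window this confines the eligibility to the cued slot, and the learned
blocks saturate at their heterogeneous ceilings, which makes the trained
position map nearly deterministic.  Exploration noise into the
postsynaptic side is available for free (unshaped) trials but is disabled
while the shaping cue is on, for the same reason.  The cue population is
not stimulated during production: if it were, its reward-modulated links
to the postsynaptic side would learn to open position gates at production
onset, outside any slot.  Working-memory weights are re-initialized every
trial (short-term plasticity); only the RLC weights persist across trials
(long-term plasticity).

## Chunking

For six-symbol sequences the chunked network instantiates two full
working-memory units that share a single three-position RLC and motor
circuit.  A chunked trial memorizes and immediately produces one chunk at
a time; under the mirror grammar the chunk order is reversed and each
chunk is mirrored, so the concatenated output equals the full reversed
sequence.  The unchunked control spans all six symbols with one
working-memory unit and a six-position RLC.  The chunked network's
advantage under noise comes from re-anchoring: each chunk restarts the
replay wave and the slot clock, so timing jitter and wave attenuation
accumulate over three hops instead of six.

## Noise experiments and statistics

Background noise is i.i.d. Gaussian current (mean 0, variance σ²) injected
into every neuron at every step.  The experiments sweep σ² on a small grid
chosen so accuracy falls from ceiling toward chance across the grid; the
claims tested are qualitative orderings (accuracy non-increasing in σ²,
larger populations more robust, middle positions weakest, chunked above
unchunked), not absolute curve values.  Accuracies carry binomial standard
errors `sqrt(a(1-a)/n)`, and orderings are asserted outside two standard
errors.

Population size C scales the synaptic drive each population delivers, so
recall degrades gracefully with C: at C = 60 replay is reliable at zero
noise, at C = 30 it is marginal, and a single neuron per symbol (C = 1)
cannot sustain replay at all — the population code, not any single cell,
carries the sequence.

## Problem sizes

Default experiment sizes keep a full trial (memory stage, delay,
production) around one second of wall time at C = 60: 10 presentations ×
4–7 windows × 60 ms of memory stage, 200 ms delay, and a 200–450 ms
production stage, simulated at 1 ms resolution for networks of roughly
600–2000 neurons.  The end-to-end experiments use 150 training trials per
grammar, all 120 enumerated sequences for the zero-noise recall check,
100–200 evaluation trials per noise cell for the production experiments,
and 40 trials per grid point for the chunking comparison; the noise grids
use three points.

## Known limitations

* The replay wave's timing calibration (slot offset and spacing) is tied
  to the default membrane constants; changing `tau_m`, `tau_ref` or the
  encoding parameters requires re-measuring the hop length.
* Chunk segmentation is supplied by the protocol, not discovered by the
  network, and chunks must have equal length.
* Learning relies on shaping; pure trial-and-error exploration is
  implemented but converges far more slowly and is not part of the default
  study conditions.
* Training outcome varies with the random state (initial weights,
  stimulus draws, trial sequences): typical held-out accuracy after 150
  shaping trials is 90-98%, and occasional states converge poorly.  The
  experiments therefore report per-run accuracies rather than a single
  canonical number.
* Sequences use distinct symbols only, and the alphabet tops out at the
  configured six symbols by default.
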