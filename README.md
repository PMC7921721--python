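# spikeseq

A spiking-network model of sequence working memory and grammar-guided
sequence production.  The package is for computational neuroscientists who
want a compact, fully inspectable model of how a network of leaky
integrate-and-fire neurons can memorize a short sequence of spatial
symbols, acquire a *supra-regular* production grammar by reinforcement,
and reproduce the sequence either in the same order (**repeat**,
`ABC → ABC`) or reversed (**mirror**, `ABC → CBA`) — the task used to
probe whether nonhuman primates can cross the "syntax barrier" between
regular and supra-regular grammars.

## Model in brief

* **Neurons** — discrete-time LIF: `τ_m dV/dt = −(V − V_s) + I/g`, spike
  and reset at threshold, absolute refractory period.  Constants:
  C_m = 30 nF, τ_m = 30 ms, V_reset = V_s = −65 mV, V_th = −35 mV,
  τ_ref = 10 ms; forward Euler at dt = 1 ms.
* **Working memory** — one population of C = 60 excitatory neurons per
  symbol plus lateral inhibition.  Symbols are Poisson-encoded; pairwise
  STDP (`Δw = ±A_± e^{−|Δt|/τ_s}` inside a ±τ_w window; A_+ = 4,
  A_− = 0.95, τ_s = 15 ms, τ_w = 10 ms) wires the presented order into a
  directed synaptic chain, which a start signal later replays as a
  traveling wave of population volleys.
* **Grammar learning** — reward-modulated STDP: pairings accumulate in a
  per-synapse eligibility trace `ė = −e/τ_e + STDP(t)`, and weights update
  only under a neuromodulator, `ΔW = η·R·e`, with R = +10 for 5 steps after
  a reward, −10 after a punishment (R-max policy).  What is learned is a
  position map — identity for repeat, anti-diagonal for mirror — in the
  reinforcement learning circuit, which routes each replayed symbol into
  its output slot.
* **Readout** — motor neurons fire only for the conjunction "this symbol
  is replaying now AND this output position is selected", with a
  competitive-queuing mechanism (persistent winner activity, one symbol
  per position, inhibition-of-return on produced symbols).

The experiments reproduce the model's qualitative findings: population
coding makes recall robust to background noise (accuracy grows with C),
per-position production accuracy keeps a U-shaped serial-position profile
under noise, and chunking a six-symbol sequence into two three-symbol
chunks improves production accuracy.

## Worked example

```bash
python examples/03_sequence_memory.py
```

prints (numbers from an actual run, seed 0):

```
memorized sequence: (1, 2, 5)
mean chain weights after STDP:
  begin->sym1  12.5   sym1->sym2  12.8   sym2->sym5  12.7
  sym2->sym1    2.3   sym1->sym5   1.2   (reverse/skip stay near zero)
replayed sequence : (1, 2, 5)
```

The presented order — and only it — is wired into strong forward
connections (the saturation cap is 13), so the start signal alone replays
`1, 2, 5`.  `examples/04_grammar_training.py` continues the story: after
~150 shaped reinforcement trials the RLC weight matrix develops an
anti-diagonal block structure and the network produces held-out sequences
reversed.  The other examples cover the LIF/STDP primitives, the
population-size noise sweep, and the chunked six-symbol task.

A thin CLI wraps the same experiments:

```bash
spikeseq demo --rule mirror --seed 1
spikeseq memory-sweep --C 1,30,60 --seed 1 --out results/
```

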