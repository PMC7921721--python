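"""Trial protocol: sequence sampling, memory/production stages, training.

A trial runs in two stages.  In the **memory stage** the begin population
and then each symbol's population are stimulated in order (Poisson
encoding), for a configurable number of repeated presentations; STDP on the
working-memory synapses lays down a directed chain.  After a delay, the
**production stage** delivers only a start signal (begin population plus
the RLC cue).  The working-memory chain replays on its own while the RLC's
presynaptic side steps through the output slots; motor neurons fire where
a currently-recalled symbol coincides with a currently-selected position,
and their first spikes are decoded into the produced sequence.

Training follows a reinforcement loop: per trial the working-memory
weights are re-initialized (short-term plasticity), a fresh random sequence
is memorized and produced, the output is compared against the grammar
target (repeat = identity, mirror = reversal), and a single reward or
punishment is delivered whose window converts the RLC eligibility traces
into weight change.  Exploration during training comes from extra Gaussian
current injected into the RLC postsynaptic side; optionally ("guided"
shaping, used for the long-sequence networks) the correct postsynaptic
population is also cued during its slot, mirroring the staged way animals
are shaped toward a task before unaided testing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import permutations

import numpy as np

from spikeseq.config import ExperimentConfig
from spikeseq.dynamics import SpikeRecord, StimulusSpec
from spikeseq.network import Network

__all__ = [
    "SequenceTrial",
    "generate_sequence",
    "enumerate_sequences",
    "apply_grammar",
    "chunk_sequence",
    "reset_wmc",
    "run_memory_stage",
    "run_production_stage",
    "run_recall_probe",
    "run_trial",
    "run_chunked_trial",
    "train",
]


@dataclass
class SequenceTrial:
    """Bookkeeping for one memorize-and-produce trial."""

    input_seq: tuple[int, ...]
    rule: str
    target_seq: tuple[int, ...]
    output_seq: tuple = ()
    correct: bool = False
    reward_given: float = 0.0


# ---------------------------------------------------------------------------
# sequences and grammars


def generate_sequence(
    length: int, alphabet_size: int, rng: np.random.Generator
) -> tuple[int, ...]:
    """Uniform random ordered selection of ``length`` distinct symbols."""
    if length > alphabet_size:
        raise ValueError("sequence length cannot exceed alphabet size")
    return tuple(int(s) + 1 for s in rng.choice(alphabet_size, size=length, replace=False))


def enumerate_sequences(length: int, alphabet_size: int) -> list[tuple[int, ...]]:
    """All ordered selections of distinct symbols (120 for length 3 of 6)."""
    if length > alphabet_size:
        raise ValueError("sequence length cannot exceed alphabet size")
    return [tuple(p) for p in permutations(range(1, alphabet_size + 1), length)]


def apply_grammar(rule: str, seq: tuple[int, ...]) -> tuple[int, ...]:
    """Target under the production grammar: repeat = identity, mirror = reversal."""
    if rule == "repeat":
        return tuple(seq)
    if rule == "mirror":
        return tuple(reversed(seq))
    raise ValueError(f"unknown grammar rule {rule!r}")


def chunk_sequence(seq: tuple[int, ...], chunk_size: int) -> list[tuple[int, ...]]:
    """Consecutive equal-length chunks whose concatenation recovers ``seq``."""
    if len(seq) % chunk_size != 0:
        raise ValueError("sequence length must be divisible by chunk_size")
    return [tuple(seq[i : i + chunk_size]) for i in range(0, len(seq), chunk_size)]


# ---------------------------------------------------------------------------
# stages


def _unit_prefixes(net: Network) -> list[str]:
    return [u["prefix"] for u in net.meta["units"]]


def reset_wmc(net: Network, rng: np.random.Generator | None = None) -> Network:
    """Re-initialize all working-memory (stdp) weights near zero.

    Models the short-term nature of the sequence memory: each trial starts
    from a blank memory while the reinforcement-learning weights persist.
    """
    rng = rng if rng is not None else net.rng
    cfg: ExperimentConfig = net.meta["config"]
    eps = cfg.architecture.init_eps_frac * cfg.stdp.w_max
    for p in net.projections:
        if p.group.mode == "stdp":
            p.group.w[:] = rng.uniform(0.0, eps, p.group.w.shape)
    return net


def run_memory_stage(
    net: Network,
    seq: tuple[int, ...],
    config: ExperimentConfig | None = None,
    record: SpikeRecord | None = None,
    unit: str = "",
) -> SpikeRecord | None:
    """Present begin + each symbol in order, repeatedly; STDP forms the chain."""
    cfg = config or net.meta["config"]
    tm, st = cfg.timing, cfg.stimulus
    sw = tm.stim_window
    for _ in range(tm.presentations):
        stimuli = [
            StimulusSpec(
                f"{unit}begin", 0.0, sw, st.rate, st.amplitude,
                onset_rate=st.onset_rate, onset_ms=st.onset_ms,
            )
        ]
        for i, s in enumerate(seq):
            stimuli.append(
                StimulusSpec(
                    f"{unit}sym{s}", (i + 1) * sw, (i + 2) * sw, st.rate, st.amplitude,
                    onset_rate=st.onset_rate, onset_ms=st.onset_ms,
                )
            )
        net.run((len(seq) + 1) * sw, stimuli, record=record)
    return record


def run_production_stage(
    net: Network,
    config: ExperimentConfig | None = None,
    record: SpikeRecord | None = None,
    unit: str = "",
    explore: bool = False,
    guided_map: dict[int, int] | None = None,
    train_windows: bool = False,
) -> tuple[SpikeRecord | None, tuple]:
    """Produce the memorized sequence; decode motor first spikes.

    The begin population receives the start signal (synchronous encoding,
    long enough to sustain the replay wave across all positions); the RLC
    presynaptic side is stepped through the output slots by externally
    timed stimulation windows (cue first, then one window per position).
    ``guided_map`` (slot -> post position) optionally cues the correct
    postsynaptic population during its slot (training shaping).  Returns
    (record, output sequence); silent positions are reported as 0.
    """
    from spikeseq.evaluation import decode_motor_output

    cfg = config or net.meta["config"]
    tm, st, sym = cfg.timing, cfg.start_stimulus, cfg.stimulus
    n_pos = net.meta.get("n_positions", net.meta["length"])
    duration = tm.production_duration(n_pos)

    # The motor layer integrates only what happens during production: clear
    # any depolarization accumulated while symbols were being displayed.
    net.reset_membranes(net.meta["motor"] + net.meta.get("hold", []))
    net.reset_first_spikes()

    stimuli = [
        StimulusSpec(
            f"{unit}begin", 0.0, tm.production_begin(n_pos), st.rate, st.amplitude
        ),
    ]
    for k in range(1, n_pos + 1):
        t0, t1 = tm.slot_window(k)
        if train_windows:
            # Narrow, non-overlapping windows while shaping: the STDP
            # pairing window then cannot bridge neighboring slots, so the
            # eligibility stays confined to the cued position mapping.
            t1 = t0 + tm.slot_width_train
        if k == n_pos:
            # the final slot has no later symbols to collide with, so its
            # window can absorb accumulated replay jitter
            t1 += 2 * tm.slot_spacing
        stimuli.append(
            StimulusSpec(
                f"pre_pos{k}", t0, t1, sym.rate, sym.amplitude,
                onset_rate=sym.onset_rate, onset_ms=sym.onset_ms,
            )
        )
    if guided_map:
        # Shaping cue confined to the slot core so eligibility does not
        # leak onto the neighboring (overlapping) slots' presynaptic pools.
        for slot, post in guided_map.items():
            t0, _ = tm.slot_window(slot)
            t1 = t0 + tm.slot_width_train
            if slot == n_pos:
                t1 += 2 * tm.slot_spacing
            stimuli.append(
                StimulusSpec(
                    f"post_pos{post}", t0 + 10.0, t1,
                    400.0, sym.amplitude, onset_rate=sym.onset_rate, onset_ms=4.0,
                )
            )
    explore_arg = None
    if explore and cfg.training.explore_sigma2 > 0:
        post_names = [nm for nm in net.populations if nm.startswith("post_pos")]
        explore_arg = (post_names, cfg.training.explore_sigma2)

    net.run(duration, stimuli, record=record, explore=explore_arg)
    output = decode_motor_output(net)
    return record, output


def run_recall_probe(
    net: Network,
    config: ExperimentConfig | None = None,
    record: SpikeRecord | None = None,
    unit: str = "",
) -> tuple[int, ...]:
    """Start-signal-only replay of a memory-only network, decoded from the
    working-memory populations themselves (majority-firing order)."""
    from spikeseq.evaluation import decode_wmc_sequence

    cfg = config or net.meta["config"]
    tm, st = cfg.timing, cfg.start_stimulus
    length = net.meta["length"]
    duration = tm.production_duration(length)
    net.reset_first_spikes()
    rec = record if record is not None else SpikeRecord()
    t0 = net.t
    net.run(
        duration,
        [StimulusSpec(f"{unit}begin", 0.0, tm.begin_window, st.rate, st.amplitude)],
        record=rec,
    )
    return decode_wmc_sequence(rec, net, unit=unit, t0=t0)


# ---------------------------------------------------------------------------
# whole trials


def run_trial(
    net: Network,
    seq: tuple[int, ...],
    rule: str,
    config: ExperimentConfig | None = None,
    rng: np.random.Generator | None = None,
    explore: bool = False,
    guided: bool = False,
    record: SpikeRecord | None = None,
) -> SequenceTrial:
    """One full memorize→delay→produce trial on an unchunked network."""
    cfg = config or net.meta["config"]
    target = apply_grammar(rule, seq)
    net.reset_state()
    reset_wmc(net, rng)
    run_memory_stage(net, seq, cfg, record=record)
    net.run(cfg.timing.delay)
    guided_map = None
    if guided:
        n_pos = net.meta.get("n_positions", len(seq))
        perm = _rule_permutation(rule, n_pos)
        guided_map = {i: perm[i] for i in perm}
    _, output = run_production_stage(
        net, cfg, record=record, explore=explore, guided_map=guided_map,
        train_windows=guided_map is not None,
    )
    trial = SequenceTrial(tuple(seq), rule, target)
    trial.output_seq = output
    trial.correct = tuple(output) == tuple(target)
    return trial


def _rule_permutation(rule: str, n_pos: int) -> dict[int, int]:
    """Slot i (presynaptic order) -> output position (postsynaptic)."""
    if rule == "repeat":
        return {i: i for i in range(1, n_pos + 1)}
    if rule == "mirror":
        return {i: n_pos + 1 - i for i in range(1, n_pos + 1)}
    raise ValueError(f"unknown grammar rule {rule!r}")


def run_chunked_trial(
    net: Network,
    seq: tuple[int, ...],
    rule: str,
    config: ExperimentConfig | None = None,
    rng: np.random.Generator | None = None,
    explore: bool = False,
    guided: bool = False,
    reset: bool = True,
) -> SequenceTrial:
    """Chunk-by-chunk memorize-and-produce on a chunked network.

    Chunks are processed in grammar order (reversed for mirror, so that the
    concatenated output equals the full mirrored sequence); each chunk is
    memorized into its own working-memory unit and produced immediately
    through the shared RLC.
    """
    if not net.meta.get("chunking"):
        raise ValueError("run_chunked_trial requires a chunked network")
    cfg = config or net.meta["config"]
    chunk_size = net.meta["chunk_size"]
    chunks = chunk_sequence(seq, chunk_size)
    prefixes = _unit_prefixes(net)
    order = list(range(len(chunks)))
    if rule == "mirror":
        order = order[::-1]
    target = apply_grammar(rule, seq)
    if reset:
        net.reset_state()
        reset_wmc(net, rng)
    guided_map = None
    if guided:
        perm = _rule_permutation(rule, chunk_size)
        guided_map = {i: perm[i] for i in perm}
    output: list[int] = []
    for idx in order:
        chunk = chunks[idx]
        unit = prefixes[idx]
        run_memory_stage(net, chunk, cfg, unit=unit)
        net.run(cfg.timing.delay)
        _, out = run_production_stage(
            net, cfg, unit=unit, explore=explore, guided_map=guided_map,
            train_windows=guided_map is not None,
        )
        output.extend(out)
    trial = SequenceTrial(tuple(seq), rule, target)
    trial.output_seq = tuple(output)
    trial.correct = trial.output_seq == tuple(target)
    return trial


def train(
    net: Network,
    rule: str,
    n_trials: int,
    config: ExperimentConfig | None = None,
    rng: np.random.Generator | None = None,
    reward_scale: float = 1.0,
) -> tuple[Network, list[bool]]:
    """Reinforcement training loop; returns the per-trial correctness curve.

    Each trial memorizes a fresh random sequence, produces it with
    exploration, and delivers exactly one reward (correct) or punishment
    (any error), whose window applies the reward-modulated weight update.
    ``reward_scale`` = 0 silences the neuromodulator (control runs).
    """
    cfg = config or net.meta["config"]
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    length = net.meta["length"]
    alphabet = cfg.architecture.alphabet_size
    curve: list[bool] = []
    for k in range(n_trials):
        # Shaping phase first (correct postsynaptic population cued), then
        # free trials in which errors are punished away.
        guided = cfg.training.guided and k < cfg.training.guided_trials
        # Exploration noise only once the shaping cue is removed: while the
        # correct postsynaptic population is being cued, extra random
        # firing would smear the eligibility onto neighboring slots.
        explore = not guided
        seq = generate_sequence(length, alphabet, rng)
        if net.meta.get("chunking"):
            trial = run_chunked_trial(net, seq, rule, cfg, rng, explore=explore, guided=guided)
        else:
            trial = run_trial(net, seq, rule, cfg, rng, explore=explore, guided=guided)
        if reward_scale != 0.0:
            if trial.correct:
                net.reward.deliver_reward(net.t)
                trial.reward_given = net.reward.c_r
            elif not guided:
                # Punishment applies when the network acts on its own;
                # during the shaping phase an incorrect (cued) trial simply
                # earns nothing, as in staged animal training.
                net.reward.deliver_punishment(net.t)
                trial.reward_given = net.reward.c_p
            net.run(net.reward.t_r_window)
        curve.append(trial.correct)
    return net, curve
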