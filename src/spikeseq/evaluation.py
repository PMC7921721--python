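"""Spike decoding, accuracy metrics, and the experiment harnesses.

Decoding follows a strict-majority population code: a population "outputs
its symbol" when more than half of its excitatory neurons have fired; the
motor layer is read out by first spikes (per output position, the symbol of
the earliest motor spike; ties broken toward the lowest symbol id).

Three harnesses reproduce the study's qualitative results:

* ``recall_accuracy`` / ``population_size_sweep`` — memory-only recall under
  Gaussian background noise for different population sizes C (robustness of
  population coding).
* ``position_accuracy`` — per-position production accuracy of a trained
  network under noise (U-shaped serial-position curve).
* ``chunking_comparison`` — full-sequence production accuracy of chunked
  vs. unchunked 6-symbol networks across a noise grid.

Accuracies carry binomial standard errors se = sqrt(a(1-a)/n).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from spikeseq.config import ExperimentConfig
from spikeseq.dynamics import SpikeRecord
from spikeseq.network import Network, Population

__all__ = [
    "decode_population",
    "decode_wmc_sequence",
    "decode_motor_output",
    "recall_accuracy",
    "population_size_sweep",
    "position_accuracy",
    "chunking_comparison",
    "rlc_rule_readout",
    "binomial_se",
]


def binomial_se(acc: float, n: int) -> float:
    return float(np.sqrt(acc * (1.0 - acc) / n)) if n > 0 else float("nan")


def decode_population(
    spikes: SpikeRecord, population: Population, window: tuple[float, float]
) -> bool:
    """True iff strictly more than half of the population's excitatory
    neurons spiked within [t0, t1)."""
    t0, t1 = window
    count = spikes.distinct_count(population.exc_start, population.exc_stop, t0, t1)
    return count > population.n_exc / 2


def _majority_onset(
    spikes: SpikeRecord, population: Population, t0: float
) -> float | None:
    """Time at which the population crossed strict-majority firing, or None."""
    m = (
        (spikes.ids >= population.exc_start)
        & (spikes.ids < population.exc_stop)
        & (spikes.times >= t0)
    )
    ids = spikes.ids[m]
    if ids.size == 0:
        return None
    times = spikes.times[m]
    # Records are appended chronologically: the first occurrence of each id
    # is its first spike.
    _, first_idx = np.unique(ids, return_index=True)
    firsts = np.sort(times[first_idx])
    need = population.n_exc // 2  # index of the (floor(C/2)+1)-th neuron
    if firsts.size <= need:
        return None
    return float(firsts[need])


def decode_wmc_sequence(
    spikes: SpikeRecord, net: Network, unit: str = "", t0: float = 0.0
) -> tuple[int, ...]:
    """Replay order of the working-memory symbol populations.

    Populations reaching strict-majority firing after ``t0`` are ordered by
    the time of that crossing.  The begin population is not part of the
    output alphabet.
    """
    cfg: ExperimentConfig = net.meta["config"]
    onsets = []
    for s in range(1, cfg.architecture.alphabet_size + 1):
        pop = net.populations[f"{unit}sym{s}"]
        onset = _majority_onset(spikes, pop, t0)
        if onset is not None:
            onsets.append((onset, s))
    onsets.sort()
    return tuple(s for _, s in onsets)


def decode_motor_output(net: Network, n_positions: int | None = None) -> tuple[int, ...]:
    """First-spike readout of the motor position populations.

    For each output position, the symbol of the first motor neuron of that
    position population to fire since the production stage began; a silent
    position decodes as 0 (a gap, never equal to any symbol).
    """
    motor_names = net.meta["motor"]
    if n_positions is not None:
        motor_names = motor_names[:n_positions]
    out = []
    for nm in motor_names:
        fs = net.population_first_spikes(nm)
        if np.all(np.isinf(fs)):
            out.append(0)
        else:
            out.append(int(np.argmin(fs)) + 1)  # argmin ties -> lowest symbol id
    return tuple(out)


# ---------------------------------------------------------------------------
# harnesses


def _override(cfg: ExperimentConfig, **kw) -> ExperimentConfig:
    data = cfg.model_dump()
    for key, val in kw.items():
        if "." in key:
            head, tail = key.split(".", 1)
            data[head][tail] = val
        else:
            data[key] = val
    return ExperimentConfig.model_validate(data)


def recall_accuracy(
    config: ExperimentConfig,
    sigma2: float,
    c: int,
    n_trials: int,
    rng: np.random.Generator,
    sequences: list[tuple[int, ...]] | None = None,
) -> dict:
    """Fraction of memory→replay trials recalled fully and in order.

    Builds a memory-only network with population size ``c`` and background
    noise ``sigma2``; each trial memorizes a sequence (sampled, or taken
    from ``sequences``) and replays it from the start signal alone.
    """
    from spikeseq.architecture import build_wmc
    from spikeseq.protocol import (
        generate_sequence,
        reset_wmc,
        run_memory_stage,
        run_recall_probe,
    )

    cfg = _override(config, **{"architecture.n_exc": c, "noise_sigma2": sigma2})
    net = build_wmc(cfg, rng)
    n_correct = 0
    n = n_trials if sequences is None else len(sequences)
    for k in range(n):
        seq = (
            sequences[k]
            if sequences is not None
            else generate_sequence(cfg.sequence_length, cfg.architecture.alphabet_size, rng)
        )
        net.reset_state()
        reset_wmc(net, rng)
        run_memory_stage(net, seq, cfg)
        net.run(cfg.timing.delay)
        decoded = run_recall_probe(net, cfg)
        n_correct += decoded == tuple(seq)
    acc = n_correct / n
    return {
        "condition": c,
        "sigma2": sigma2,
        "accuracy": acc,
        "n_trials": n,
        "se": binomial_se(acc, n),
    }


def population_size_sweep(
    config: ExperimentConfig,
    c_values: list[int],
    sigma2_grid: list[float],
    n_trials: int,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Recall accuracy for each population size across the noise grid."""
    rows = []
    for c in c_values:
        for s2 in sigma2_grid:
            rows.append(recall_accuracy(config, s2, c, n_trials, rng))
    return pd.DataFrame(rows)


def position_accuracy(
    net: Network,
    rule: str,
    sigma2: float,
    n_trials: int,
    rng: np.random.Generator,
    config: ExperimentConfig | None = None,
) -> dict:
    """Per-position production accuracy of a trained network under noise."""
    from spikeseq.protocol import apply_grammar, generate_sequence, run_trial

    cfg = config or net.meta["config"]
    n_pos = net.meta.get("n_positions", net.meta["length"])
    prev_noise = net.noise_sigma2
    net.noise_sigma2 = sigma2
    hits = np.zeros(n_pos, dtype=int)
    try:
        for _ in range(n_trials):
            seq = generate_sequence(
                net.meta["length"], cfg.architecture.alphabet_size, rng
            )
            trial = run_trial(net, seq, rule, cfg, rng)
            target = apply_grammar(rule, seq)
            for k in range(n_pos):
                hits[k] += (
                    len(trial.output_seq) > k and trial.output_seq[k] == target[k]
                )
    finally:
        net.noise_sigma2 = prev_noise
    accs = hits / n_trials
    return {
        "sigma2": sigma2,
        "positions": {k + 1: float(accs[k]) for k in range(n_pos)},
        "mean": float(accs.mean()),
        "n_trials": n_trials,
        "se": {k + 1: binomial_se(float(accs[k]), n_trials) for k in range(n_pos)},
    }


def chunking_comparison(
    config: ExperimentConfig,
    sigma2_grid: list[float],
    n_trials: int,
    rng: np.random.Generator,
    rule: str = "repeat",
    train_trials: int = 60,
) -> pd.DataFrame:
    """Full-sequence production accuracy, chunked vs. unchunked networks.

    Both 6-symbol networks are trained with guided shaping, then evaluated
    unaided across the noise grid.
    """
    from spikeseq.architecture import build_network
    from spikeseq.protocol import run_chunked_trial, run_trial, train, generate_sequence

    rows = []
    for chunked in (False, True):
        cfg = _override(
            config,
            **{
                "sequence_length": 6,
                "chunking": chunked,
                "training.guided": True,
                "noise_sigma2": 0.0,
            },
        )
        net = build_network(cfg, rng)
        train(net, rule, train_trials, cfg, rng)
        for s2 in sigma2_grid:
            net.noise_sigma2 = s2
            n_correct = 0
            for _ in range(n_trials):
                seq = generate_sequence(6, cfg.architecture.alphabet_size, rng)
                if chunked:
                    trial = run_chunked_trial(net, seq, rule, cfg, rng)
                else:
                    trial = run_trial(net, seq, rule, cfg, rng)
                n_correct += trial.correct
            acc = n_correct / n_trials
            rows.append(
                {
                    "condition": "chunked" if chunked else "unchunked",
                    "sigma2": s2,
                    "accuracy": acc,
                    "n_trials": n_trials,
                    "se": binomial_se(acc, n_trials),
                }
            )
    return pd.DataFrame(rows)


def rlc_rule_readout(net: Network) -> np.ndarray:
    """Mean pre_pos_i→post_pos_j weight matrix (the learned permutation).

    Row argmaxes are the identity for a repeat-trained network and the
    anti-diagonal for a mirror-trained one.
    """
    n_pos = net.meta.get("n_positions", net.meta["length"])
    mat = np.zeros((n_pos, n_pos))
    for i in range(1, n_pos + 1):
        for j in range(1, n_pos + 1):
            groups = net.find_groups(pre_pop=f"pre_pos{i}", post_pop=f"post_pos{j}")
            mat[i - 1, j - 1] = float(np.mean([g.w.mean() for g in groups]))
    return mat
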