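"""Tests for sequence generation, grammars, trial stages and bookkeeping."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from spikeseq.architecture import build_network, build_wmc
from spikeseq.config import ExperimentConfig
from spikeseq.protocol import (
    apply_grammar,
    chunk_sequence,
    enumerate_sequences,
    generate_sequence,
    reset_wmc,
    run_memory_stage,
    run_trial,
    train,
)


def tiny_cfg(**kw):
    """Reduced population sizes for fast structural tests."""
    base = {
        "architecture": {"n_exc": 10, "n_inh": 4},
        "timing": {"presentations": 2, "stim_window": 40, "delay": 50},
    }
    for key, val in kw.items():
        if isinstance(val, dict) and key in base:
            base[key].update(val)
        else:
            base[key] = val
    return ExperimentConfig.model_validate(base)


class TestSequences:
    def test_enumeration_counts_all_ordered_selections(self):
        assert len(enumerate_sequences(3, 6)) == 120
        assert len(enumerate_sequences(6, 6)) == 720
        assert len(enumerate_sequences(1, 6)) == 6

    def test_sampling_is_distinct_and_reproducible(self):
        a = generate_sequence(3, 6, np.random.default_rng(5))
        b = generate_sequence(3, 6, np.random.default_rng(5))
        assert a == b
        assert len(set(a)) == 3
        assert all(1 <= s <= 6 for s in a)

    def test_length_cannot_exceed_alphabet(self):
        with pytest.raises(ValueError):
            generate_sequence(7, 6, np.random.default_rng(0))


class TestGrammar:
    def test_known_transformations(self):
        assert apply_grammar("mirror", (1, 2, 5)) == (5, 2, 1)
        assert apply_grammar("repeat", (1, 2, 5)) == (1, 2, 5)
        assert apply_grammar("mirror", (3,)) == (3,)

    def test_unknown_rule_rejected(self):
        with pytest.raises(ValueError):
            apply_grammar("shuffle", (1, 2))

    @given(st.lists(st.integers(1, 6), min_size=1, max_size=6, unique=True))
    @settings(max_examples=50, deadline=None)
    def test_mirror_is_an_involution(self, seq):
        seq = tuple(seq)
        assert apply_grammar("mirror", apply_grammar("mirror", seq)) == seq


class TestChunking:
    def test_splits_and_recovers(self):
        assert chunk_sequence((1, 2, 5, 3, 6, 4), 3) == [(1, 2, 5), (3, 6, 4)]
        assert chunk_sequence((1, 2, 5), 3) == [(1, 2, 5)]

    def test_non_divisible_rejected(self):
        with pytest.raises(ValueError):
            chunk_sequence((1, 2, 3, 4), 3)

    @given(st.lists(st.integers(1, 6), min_size=6, max_size=6, unique=True))
    @settings(max_examples=20, deadline=None)
    def test_concatenation_identity(self, seq):
        chunks = chunk_sequence(tuple(seq), 3)
        assert sum(chunks, ()) == tuple(seq)

    @given(st.lists(st.integers(1, 6), min_size=6, max_size=6, unique=True))
    @settings(max_examples=20, deadline=None)
    def test_mirror_equals_reversed_chunks_each_mirrored(self, seq):
        """Reversal decomposes as: reverse chunk order, mirror within chunks."""
        seq = tuple(seq)
        chunks = chunk_sequence(seq, 3)
        recomposed = sum(
            (apply_grammar("mirror", c) for c in reversed(chunks)), ()
        )
        assert recomposed == apply_grammar("mirror", seq)


class TestResetWMC:
    def test_reset_bounds_and_selectivity(self):
        cfg = tiny_cfg()
        net = build_network(cfg, np.random.default_rng(0))
        for g in net.groups_by_mode("stdp"):
            g.w += 3.0
        rlc_before = [g.w.copy() for g in net.groups_by_mode("rstdp")]
        static_before = net.static_weight_checksum()
        reset_wmc(net, np.random.default_rng(1))
        eps = cfg.architecture.init_eps_frac * cfg.stdp.w_max
        for g in net.groups_by_mode("stdp"):
            assert g.w.max() <= eps
        for g, w0 in zip(net.groups_by_mode("rstdp"), rlc_before):
            assert np.array_equal(g.w, w0)
        assert net.static_weight_checksum() == static_before

    def test_reset_reproducible_under_seed(self):
        cfg = tiny_cfg()
        net = build_network(cfg, np.random.default_rng(0))
        reset_wmc(net, np.random.default_rng(7))
        snap = [g.w.copy() for g in net.groups_by_mode("stdp")]
        reset_wmc(net, np.random.default_rng(7))
        for g, w0 in zip(net.groups_by_mode("stdp"), snap):
            assert np.array_equal(g.w, w0)


class TestMemoryStage:
    def test_forward_chain_outweighs_reverse_and_skip(self):
        """Memorizing (1,2,5) strengthens begin->1, 1->2, 2->5 far above
        the reverse and skip connections (directed chain structure)."""
        cfg = ExperimentConfig()
        net = build_wmc(cfg, np.random.default_rng(0))
        rng = np.random.default_rng(1)
        reset_wmc(net, rng)
        run_memory_stage(net, (1, 2, 5), cfg)

        def wmean(a, b):
            return net.find_groups(pre_pop=a, post_pop=b)[0].w.mean()

        for fwd, others in [
            ("begin->sym1", ["begin->sym5", "begin->sym3"]),
            ("sym1->sym2", ["sym2->sym1", "sym1->sym5", "sym1->sym3"]),
            ("sym2->sym5", ["sym5->sym2", "sym2->sym3"]),
        ]:
            a, b = fwd.split("->")
            for other in others:
                c, d = other.split("->")
                assert wmean(a, b) > 3 * wmean(c, d), (fwd, other)

    def test_different_sequences_strengthen_different_edges(self):
        cfg = tiny_cfg()
        net = build_wmc(cfg, np.random.default_rng(0))
        rng = np.random.default_rng(1)

        def strengthened(seq):
            net.reset_state()
            reset_wmc(net, np.random.default_rng(2))
            run_memory_stage(net, seq, cfg)
            eps = 3 * cfg.architecture.init_eps_frac * cfg.stdp.w_max
            return {
                (g.pre_pop, g.post_pop)
                for g in net.groups_by_mode("stdp")
                if g.w.mean() > eps
            }

        assert strengthened((1, 2, 3)) != strengthened((4, 5, 6))


class TestTrainingBookkeeping:
    def test_no_reward_leaves_rlc_weights_untouched(self):
        """With the neuromodulator silenced, a full training run must leave
        every reward-modulated weight bit-identical to initialization."""
        cfg = tiny_cfg()
        net = build_network(cfg, np.random.default_rng(0))
        before = [g.w.copy() for g in net.groups_by_mode("rstdp")]
        train(net, "repeat", 2, cfg, np.random.default_rng(1), reward_scale=0.0)
        for g, w0 in zip(net.groups_by_mode("rstdp"), before):
            assert np.array_equal(g.w, w0)

    def test_learning_curve_length_and_reward_bookkeeping(self):
        cfg = tiny_cfg()
        net = build_network(cfg, np.random.default_rng(0))
        net, curve = train(net, "mirror", 3, cfg, np.random.default_rng(1))
        assert len(curve) == 3

    def test_static_weights_survive_training(self):
        cfg = tiny_cfg()
        net = build_network(cfg, np.random.default_rng(0))
        before = net.static_weight_checksum()
        train(net, "repeat", 2, cfg, np.random.default_rng(1))
        assert net.static_weight_checksum() == before

    def test_wmc_resets_each_trial_while_rlc_persists(self):
        """Short-term vs long-term plasticity: working-memory weights are
        re-initialized near zero every trial; RLC weights accumulate."""
        cfg = tiny_cfg()
        net = build_network(cfg, np.random.default_rng(0))
        eps = cfg.architecture.init_eps_frac * cfg.stdp.w_max
        rng = np.random.default_rng(1)
        rlc_snapshots = []
        for _ in range(2):
            train(net, "repeat", 1, cfg, rng)
            rlc_snapshots.append(
                np.concatenate([g.w.ravel() for g in net.groups_by_mode("rstdp")])
            )
        seq = (1, 2, 3)
        trial = run_trial(net, seq, "repeat", cfg, rng)
        # a fresh trial re-initialized the WMC before its memory stage, so
        # only chain edges of the current sequence can exceed eps
        touched = {
            (g.pre_pop, g.post_pop)
            for g in net.groups_by_mode("stdp")
            if g.w.max() > 2 * eps
        }
        allowed = {("begin", "sym1"), ("sym1", "sym2"), ("sym2", "sym3")}
        assert touched <= allowed | {("begin", "sym2"), ("sym1", "sym3"), ("sym2", "sym1"), ("sym3", "sym2")}
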