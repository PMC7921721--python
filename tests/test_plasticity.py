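"""Tests for STDP, eligibility traces and reward-modulated updates."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from spikeseq.plasticity import (
    EligibilityTrace,
    RewardSchedule,
    STDPParams,
    SynapseGroup,
    apply_rstdp,
    apply_stdp,
    reward_signal,
    stdp_delta,
    update_eligibility,
)

WIDE = dict(w_min=-1e9, w_max=1e9)


def bruteforce_nearest_neighbor(pre_trains, post_trains, params):
    """Offline nearest-neighbor STDP pairing sum.

    For every spike, find the most recent opposite-side spike at or before
    it; simultaneous spikes (delta = 0) contribute nothing.  Returns the
    unclipped increment matrix (n_post, n_pre).
    """
    n_pre, n_post = len(pre_trains), len(post_trains)
    out = np.zeros((n_post, n_pre))
    for j, pre in enumerate(pre_trains):
        for i, post in enumerate(post_trains):
            for t_post in post:
                earlier = [t for t in pre if t <= t_post]
                if earlier:
                    out[i, j] += stdp_delta(t_post - max(earlier), params)
            for t_pre in pre:
                earlier = [t for t in post if t <= t_pre]
                if earlier:
                    out[i, j] += stdp_delta(max(earlier) - t_pre, params)
    return out


def run_group_on_trains(pre_trains, post_trains, params, mode="stdp"):
    """Feed spike trains step-by-step through a SynapseGroup; return raw
    accumulated increments (wide bounds so clipping never binds)."""
    n_pre, n_post = len(pre_trains), len(post_trains)
    group = SynapseGroup(
        w=np.zeros((n_post, n_pre)), mode=mode, params=params
    )
    t_max = int(max((max(t) for t in pre_trains + post_trains if t), default=0))
    for t in range(1, t_max + 1):
        pre_f = np.array([j for j, tr in enumerate(pre_trains) if t in tr], dtype=np.intp)
        post_f = np.array([i for i, tr in enumerate(post_trains) if t in tr], dtype=np.intp)
        if mode == "stdp":
            apply_stdp(group, pre_f, post_f, float(t))
        else:
            inc = group.pairing_increments(pre_f, post_f, float(t))
            update_eligibility(group, inc, 1.0)
    return group


class TestSTDPDelta:
    def test_pre_before_post_potentiates(self):
        p = STDPParams()
        assert stdp_delta(5.0, p) == pytest.approx(4.0 * np.exp(-1.0 / 3.0))

    def test_post_before_pre_depresses(self):
        p = STDPParams()
        assert stdp_delta(-5.0, p) == pytest.approx(-0.95 * np.exp(-1.0 / 3.0))

    def test_outside_window_and_simultaneous_are_zero(self):
        p = STDPParams()
        assert stdp_delta(12.0, p) == 0.0
        assert stdp_delta(-12.0, p) == 0.0
        assert stdp_delta(0.0, p) == 0.0

    @given(st.floats(0.01, 9.99))
    @settings(max_examples=50, deadline=None)
    def test_asymmetry_and_window_compactness(self, dt):
        p = STDPParams()
        assert stdp_delta(dt, p) > 0 > stdp_delta(-dt, p)
        assert stdp_delta(dt + p.tau_w, p) == 0.0
        assert stdp_delta(-(dt + p.tau_w), p) == 0.0


class TestApplySTDP:
    def test_no_spikes_leaves_weights(self):
        g = SynapseGroup(w=np.full((2, 2), 5.0), mode="stdp", params=STDPParams())
        apply_stdp(g, np.array([], dtype=np.intp), np.array([], dtype=np.intp), 3.0)
        assert np.all(g.w == 5.0)

    def test_single_pair_increment(self):
        p = STDPParams(**WIDE)
        g = run_group_on_trains([{10}], [{15}], p)
        assert g.w[0, 0] == pytest.approx(stdp_delta(5.0, p))

    def test_wrong_mode_rejected(self):
        g = SynapseGroup(w=np.zeros((1, 1)), mode="static")
        with pytest.raises(ValueError):
            apply_stdp(g, np.array([0]), np.array([0]), 1.0)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=15, deadline=None)
    def test_matches_bruteforce_nearest_neighbor(self, seed):
        """Online application on random 3x3 spike trains equals the offline
        brute-force nearest-neighbor pairing sum."""
        rng = np.random.default_rng(seed)
        p = STDPParams(**WIDE)
        pre = [set(np.flatnonzero(rng.random(60) < 0.08) + 1) for _ in range(3)]
        post = [set(np.flatnonzero(rng.random(60) < 0.08) + 1) for _ in range(3)]
        g = run_group_on_trains(pre, post, p)
        expected = bruteforce_nearest_neighbor(
            [sorted(t) for t in pre], [sorted(t) for t in post], p
        )
        assert np.allclose(g.w, expected, rtol=1e-9, atol=1e-12)

    def test_clipping_bounds_respected(self):
        p = STDPParams(w_min=0.0, w_max=1.0)
        g = SynapseGroup(w=np.full((1, 1), 0.5), mode="stdp", params=p)
        for t in range(1, 200, 20):
            apply_stdp(g, np.array([], dtype=np.intp), np.array([0]), float(t))
            apply_stdp(g, np.array([0]), np.array([], dtype=np.intp), float(t + 5))
        assert 0.0 <= g.w[0, 0] <= 1.0


class TestEligibility:
    def test_homogeneous_decay(self):
        g = SynapseGroup(w=np.zeros((1, 1)), mode="rstdp", params=STDPParams())
        g.trace.e[:] = 1.0
        for _ in range(100):
            update_eligibility(g, None, 1.0)
        expected = np.exp(-100.0 / g.trace.tau_e)
        # Euler error is O(dt/tau_e) per step
        assert g.trace.e[0, 0] == pytest.approx(expected, rel=0.15)

    def test_single_impulse_follows_exponential_kernel(self):
        g = SynapseGroup(w=np.zeros((1, 1)), mode="rstdp", params=STDPParams())
        update_eligibility(g, np.array([[2.0]]), 1.0)
        for _ in range(50):
            update_eligibility(g, None, 1.0)
        assert g.trace.e[0, 0] == pytest.approx(2.0 * np.exp(-50.0 / 200.0), rel=0.1)

    def test_matches_discrete_convolution(self):
        """Euler-integrated trace equals the convolution of the increment
        train with the discrete exponential kernel."""
        rng = np.random.default_rng(5)
        g = SynapseGroup(w=np.zeros((2, 2)), mode="rstdp", params=STDPParams())
        tau_e = g.trace.tau_e
        incs = [rng.normal(size=(2, 2)) * (rng.random() < 0.3) for _ in range(120)]
        for inc in incs:
            update_eligibility(g, inc, 1.0)
        decay = 1.0 - 1.0 / tau_e
        expected = np.zeros((2, 2))
        for k, inc in enumerate(incs):
            expected = expected * decay + inc
        assert np.allclose(g.trace.e, expected, rtol=1e-12)

    def test_linearity_of_superposed_trains(self):
        rng = np.random.default_rng(9)
        trains = [rng.normal(size=(1, 1)) * (rng.random() < 0.5) for _ in range(60)]
        half_a = trains[::2]
        g_all = SynapseGroup(w=np.zeros((1, 1)), mode="rstdp", params=STDPParams())
        g_a = SynapseGroup(w=np.zeros((1, 1)), mode="rstdp", params=STDPParams())
        g_b = SynapseGroup(w=np.zeros((1, 1)), mode="rstdp", params=STDPParams())
        for k, inc in enumerate(trains):
            update_eligibility(g_all, inc, 1.0)
            update_eligibility(g_a, inc if k % 2 == 0 else None, 1.0)
            update_eligibility(g_b, inc if k % 2 == 1 else None, 1.0)
        assert np.allclose(g_all.trace.e, g_a.trace.e + g_b.trace.e, rtol=1e-12)


class TestRewardSignal:
    def test_reward_window_values(self):
        sched = RewardSchedule()
        sched.deliver_reward(100.0)
        assert reward_signal(103.0, sched) == 10.0
        assert reward_signal(107.0, sched) == 0.0

    def test_punishment_window(self):
        sched = RewardSchedule()
        sched.deliver_punishment(50.0)
        assert reward_signal(52.0, sched) == -10.0
        assert reward_signal(56.0, sched) == 0.0

    def test_silent_without_events(self):
        assert reward_signal(1e6, RewardSchedule()) == 0.0


class TestApplyRSTDP:
    def _group(self):
        g = SynapseGroup(
            w=np.full((1, 1), 5.0), mode="rstdp", params=STDPParams(w_min=0.0, w_max=100.0)
        )
        return g

    def test_zero_reward_is_noop(self):
        g = self._group()
        g.trace.e[:] = 3.0
        apply_rstdp(g, 0.0, 1.0, eta=1.0)
        assert g.w[0, 0] == 5.0

    def test_reward_times_trace_scales_update(self):
        g = self._group()
        g.trace.e[:] = 0.5
        apply_rstdp(g, 10.0, 1.0, eta=1.0)
        assert g.w[0, 0] == pytest.approx(10.0)  # +eta*R*e*dt = 5

    def test_punishment_with_positive_trace_decreases(self):
        g = self._group()
        g.trace.e[:] = 0.5
        apply_rstdp(g, -10.0, 1.0, eta=1.0)
        assert g.w[0, 0] == pytest.approx(0.0)

    def test_wrong_mode_rejected(self):
        g = SynapseGroup(w=np.zeros((1, 1)), mode="stdp")
        with pytest.raises(ValueError):
            apply_rstdp(g, 1.0, 1.0)
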