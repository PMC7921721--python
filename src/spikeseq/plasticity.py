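"""Synaptic learning rules: pairwise STDP and reward-modulated STDP.

Two rules act on dense weight matrices between neuron populations:

* **STDP** — with Δt = t_post − t_pre, a pre-before-post pairing inside the
  window (0 < Δt < tau_w) potentiates by ``A_plus * exp(-Δt/tau_s)``; a
  post-before-pre pairing (−tau_w < Δt < 0) depresses by
  ``A_minus * exp(-|Δt|/tau_s)``.  Pairing is nearest-neighbor: every new
  spike pairs with the most recent spike on the opposite side; simultaneous
  spikes (Δt = 0) contribute nothing.  Weights are clipped to
  [w_min, w_max] after every update.

* **R-STDP** — the same pairing increments are accumulated not into the
  weights but into a per-synapse eligibility trace that decays with time
  constant tau_e (low-pass filter of the STDP outcome).  Weights change
  only while a neuromodulator signal is present:
  ``ΔW = eta * R * e * dt`` (R-max policy, M = R), where R(t) is +C_r for
  T_R after a reward, C_p for T_R after a punishment, and 0 otherwise.

Defaults: A_plus = 4, A_minus = 0.95, tau_s = 15 ms, tau_w = 10 ms,
C_r = +10, C_p = −10, T_R = 5 steps (= 5 ms at dt = 1 ms).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "STDPParams",
    "EligibilityTrace",
    "RewardSchedule",
    "SynapseGroup",
    "stdp_delta",
    "apply_stdp",
    "update_eligibility",
    "reward_signal",
    "apply_rstdp",
]


@dataclass(frozen=True)
class STDPParams:
    a_plus: float = 4.0  # potentiation learning rate
    a_minus: float = 0.95  # depression learning rate
    tau_s: float = 15.0  # ms, exponential decay of the pairing kernel
    tau_w: float = 10.0  # ms, half-width of the pairing window
    w_min: float = 0.0
    w_max: float = 15.0

    def __post_init__(self) -> None:
        if min(self.a_plus, self.a_minus, self.tau_s, self.tau_w) <= 0:
            raise ValueError("STDP rates and time constants must be positive")
        if self.w_min >= self.w_max:
            raise ValueError("w_min must be below w_max")


@dataclass
class EligibilityTrace:
    """Per-synapse low-pass filter of STDP outcomes (R-STDP memory)."""

    e: np.ndarray
    tau_e: float = 200.0  # ms

    @classmethod
    def zeros(cls, shape: tuple[int, int], tau_e: float = 200.0) -> "EligibilityTrace":
        return cls(e=np.zeros(shape), tau_e=tau_e)


@dataclass
class RewardSchedule:
    """Step reward signal: C_r for T_R after reward, C_p for T_R after punishment."""

    c_r: float = 10.0
    c_p: float = -10.0
    t_r_window: float = 5.0  # ms with dt = 1 ms (window length T_R)
    t_r: float = -np.inf  # latest reward time
    t_p: float = -np.inf  # latest punishment time

    def deliver_reward(self, t: float) -> None:
        self.t_r = t

    def deliver_punishment(self, t: float) -> None:
        self.t_p = t


def reward_signal(t: float, schedule: RewardSchedule) -> float:
    """R(t): C_r within T_R of the latest reward, C_p within T_R of the
    latest punishment, else 0.  The trial protocol guarantees the two
    windows never overlap."""
    if t - schedule.t_r <= schedule.t_r_window:
        return schedule.c_r
    if t - schedule.t_p <= schedule.t_r_window:
        return schedule.c_p
    return 0.0


def stdp_delta(delta_t, params: STDPParams):
    """Weight increment for a single pairing with Δt = t_post − t_pre.

    Vectorized over ``delta_t``; zero outside (−tau_w, tau_w) and at Δt = 0.
    """
    dt = np.asarray(delta_t, dtype=float)
    out = np.zeros_like(dt)
    pot = (dt > 0) & (dt < params.tau_w)
    dep = (dt < 0) & (dt > -params.tau_w)
    out = np.where(pot, params.a_plus * np.exp(-np.abs(dt) / params.tau_s), out)
    out = np.where(dep, -params.a_minus * np.exp(-np.abs(dt) / params.tau_s), out)
    if np.isscalar(delta_t):
        return float(out)
    return out


@dataclass
class SynapseGroup:
    """Dense weight matrix (n_post × n_pre) between two populations.

    ``mode`` selects plasticity: "static" (frozen), "stdp" (pairings applied
    directly to W), or "rstdp" (pairings accumulate in the eligibility
    trace; W changes only under a reward signal).  ``last_spike_pre`` /
    ``last_spike_post`` hold the most recent spike time per neuron for
    nearest-neighbor pairing.
    """

    w: np.ndarray
    mode: str = "static"  # static | stdp | rstdp
    params: STDPParams = field(default_factory=STDPParams)
    trace: EligibilityTrace | None = None
    last_spike_pre: np.ndarray = field(default=None)  # type: ignore[assignment]
    last_spike_post: np.ndarray = field(default=None)  # type: ignore[assignment]
    pre_pop: str = ""
    post_pop: str = ""
    # optional per-synapse ceiling (e.g. heterogeneous saturation levels);
    # overrides params.w_max where given
    w_cap: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("static", "stdp", "rstdp"):
            raise ValueError(f"unknown plasticity mode {self.mode!r}")
        n_post, n_pre = self.w.shape
        if self.last_spike_pre is None:
            self.last_spike_pre = np.full(n_pre, -np.inf)
        if self.last_spike_post is None:
            self.last_spike_post = np.full(n_post, -np.inf)
        self._newest_pre = float(self.last_spike_pre.max())
        self._newest_post = float(self.last_spike_post.max())
        if self.mode == "rstdp" and self.trace is None:
            self.trace = EligibilityTrace.zeros(self.w.shape)

    @property
    def n_pre(self) -> int:
        return self.w.shape[1]

    @property
    def n_post(self) -> int:
        return self.w.shape[0]

    def clip(self) -> None:
        hi = self.w_cap if self.w_cap is not None else self.params.w_max
        np.clip(self.w, self.params.w_min, hi, out=self.w)

    def apply_pairings_inplace(
        self,
        pre_spikes: np.ndarray,
        post_spikes: np.ndarray,
        t: float,
        target: np.ndarray,
    ) -> None:
        """Add this step's nearest-neighbor pairing increments to ``target``.

        Same semantics as :meth:`pairing_increments` without allocating the
        dense increment matrix; ``target`` is the weight matrix (stdp) or
        the eligibility trace (rstdp).
        """
        p = self.params
        prev_pre_newest = self._newest_pre
        prev_post_newest = self._newest_post
        if pre_spikes.size:
            self.last_spike_pre[pre_spikes] = t
            self._newest_pre = t
        if post_spikes.size:
            self.last_spike_post[post_spikes] = t
            self._newest_post = t
        # Pairings exist only if the opposite side spiked strictly earlier
        # within the window; newest-spike stamps make the silent case free.
        touched = False
        if post_spikes.size and t - prev_pre_newest < p.tau_w:
            age = t - self.last_spike_pre
            pot = np.where(
                (age > 0) & (age < p.tau_w), p.a_plus * np.exp(-age / p.tau_s), 0.0
            )
            target[post_spikes, :] += pot[None, :]
            touched = True
        if pre_spikes.size and t - prev_post_newest < p.tau_w:
            age = t - self.last_spike_post
            dep = np.where(
                (age > 0) & (age < p.tau_w), -p.a_minus * np.exp(-age / p.tau_s), 0.0
            )
            target[:, pre_spikes] += dep[:, None]
            touched = True
        return touched

    def pairing_increments(
        self, pre_spikes: np.ndarray, post_spikes: np.ndarray, t: float
    ) -> np.ndarray | None:
        """Nearest-neighbor pairing increments for spikes arriving at time t.

        ``pre_spikes`` / ``post_spikes`` are integer index arrays of neurons
        spiking at this step.  Updates the last-spike bookkeeping (including
        the current spikes, so simultaneous pairs yield Δt = 0 and vanish)
        and returns the dense increment matrix, or None if nothing fired.
        """
        pre_spikes = np.asarray(pre_spikes, dtype=np.intp)
        post_spikes = np.asarray(post_spikes, dtype=np.intp)
        if pre_spikes.size == 0 and post_spikes.size == 0:
            return None
        inc = np.zeros_like(self.w)
        self.apply_pairings_inplace(pre_spikes, post_spikes, t, inc)
        return inc


def apply_stdp(
    group: SynapseGroup, pre_spikes: np.ndarray, post_spikes: np.ndarray, t: float
) -> SynapseGroup:
    """Apply nearest-neighbor STDP for the spikes of one step; clips W."""
    if group.mode != "stdp":
        raise ValueError(f"apply_stdp called on {group.mode!r} group")
    inc = group.pairing_increments(pre_spikes, post_spikes, t)
    if inc is not None:
        group.w += inc
        group.clip()
    return group


def update_eligibility(
    group: SynapseGroup, stdp_increments: np.ndarray | None, dt: float
) -> SynapseGroup:
    """One Euler step of the eligibility trace: e += (−e/tau_e)·dt + increments.

    Weights are untouched; only ``apply_rstdp`` converts the trace into
    weight change.
    """
    if group.mode != "rstdp":
        raise ValueError(f"update_eligibility called on {group.mode!r} group")
    tr = group.trace
    tr.e += (-tr.e / tr.tau_e) * dt
    if stdp_increments is not None:
        tr.e += stdp_increments
    return group


def apply_rstdp(group: SynapseGroup, r: float, dt: float, eta: float = 0.01) -> SynapseGroup:
    """Reward-gated weight update: W ← clip(W + eta·R·e·dt).  No-op at R = 0."""
    if group.mode != "rstdp":
        raise ValueError(f"apply_rstdp called on {group.mode!r} group")
    if r != 0.0:
        group.w += eta * r * group.trace.e * dt
        group.clip()
    return group
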