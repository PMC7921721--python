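"""Runnable network: populations, synapse groups, and the simulation loop.

The engine keeps one global state vector for all neurons (so the LIF update
is a single vectorized step) and a list of :class:`SynapseGroup` objects
whose pre/post index ranges address contiguous blocks of that vector.
Synaptic transmission uses the previous step's spikes (one-step delay);
plasticity and eligibility bookkeeping run inside the same loop.  Groups
whose presynaptic block was silent on the previous step are skipped, which
makes the cost per step proportional to the number of active populations
rather than to the full connection count.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from spikeseq.dynamics import (
    CurrentInput,
    LIFParams,
    LIFState,
    SpikeRecord,
    StimulusSpec,
    poisson_stimulus,
    step_lif,
)
from spikeseq.plasticity import (
    RewardSchedule,
    SynapseGroup,
    apply_rstdp,
    reward_signal,
    update_eligibility,
)

__all__ = ["Population", "Network"]


@dataclass(frozen=True)
class Population:
    """A named block of neurons: excitatory range plus optional inhibitory range."""

    name: str
    role: str  # wmc | motor | rlc_pre | rlc_post
    exc_start: int
    exc_stop: int
    inh_start: int = 0
    inh_stop: int = 0

    @property
    def n_exc(self) -> int:
        return self.exc_stop - self.exc_start

    @property
    def n_inh(self) -> int:
        return self.inh_stop - self.inh_start

    @property
    def exc_slice(self) -> slice:
        return slice(self.exc_start, self.exc_stop)

    @property
    def inh_slice(self) -> slice:
        return slice(self.inh_start, self.inh_stop)


@dataclass
class _Projection:
    """A SynapseGroup bound to global index ranges of the network."""

    group: SynapseGroup
    pre_start: int
    pre_stop: int
    post_start: int
    post_stop: int


class Network:
    """Wired circuit with a global clock, noise setting and reward schedule."""

    def __init__(
        self,
        n_neurons: int,
        params: LIFParams,
        populations: dict[str, Population],
        dt: float = 1.0,
        noise_sigma2: float = 0.0,
        eta: float = 0.01,
        reward: RewardSchedule | None = None,
        rng: np.random.Generator | None = None,
        meta: dict | None = None,
    ):
        self.n = n_neurons
        self.params = params
        self.populations = populations
        self.dt = dt
        self.noise_sigma2 = noise_sigma2
        self.eta = eta
        self.reward = reward if reward is not None else RewardSchedule()
        self.rng = rng if rng is not None else np.random.default_rng()
        self.meta = meta or {}
        self.projections: list[_Projection] = []
        self.state = LIFState.at_rest(n_neurons, params)
        self.fired_prev_idx = np.empty(0, dtype=np.intp)
        self.first_spike = np.full(n_neurons, np.inf)
        self.t = 0.0

    # ---- wiring -------------------------------------------------------

    def add_projection(
        self, group: SynapseGroup, pre: slice, post: slice
    ) -> SynapseGroup:
        if group.w.shape != (post.stop - post.start, pre.stop - pre.start):
            raise ValueError("weight matrix does not match pre/post ranges")
        self.projections.append(
            _Projection(group, pre.start, pre.stop, post.start, post.stop)
        )
        return group

    def groups_by_mode(self, mode: str) -> list[SynapseGroup]:
        return [p.group for p in self.projections if p.group.mode == mode]

    def find_groups(self, pre_pop: str | None = None, post_pop: str | None = None):
        out = []
        for p in self.projections:
            if pre_pop is not None and p.group.pre_pop != pre_pop:
                continue
            if post_pop is not None and p.group.post_pop != post_pop:
                continue
            out.append(p.group)
        return out

    # ---- state management --------------------------------------------

    def reset_state(self) -> None:
        """Fresh membranes, clock, spike history and eligibility traces.

        Weights are untouched; use :func:`spikeseq.protocol.reset_wmc` for
        the short-term-memory weight reset.
        """
        self.state = LIFState.at_rest(self.n, self.params)
        self.fired_prev_idx = np.empty(0, dtype=np.intp)
        self.first_spike.fill(np.inf)
        self.t = 0.0
        self.reward.t_r = -np.inf
        self.reward.t_p = -np.inf
        for p in self.projections:
            p.group.last_spike_pre.fill(-np.inf)
            p.group.last_spike_post.fill(-np.inf)
            p.group._newest_pre = -np.inf
            p.group._newest_post = -np.inf
            if p.group.trace is not None:
                p.group.trace.e.fill(0.0)

    def reset_membranes(self, names: list[str]) -> None:
        """Return the listed populations' voltages to rest (refractory cleared)."""
        for name in names:
            pop = self.populations[name]
            for sl in (pop.exc_slice, pop.inh_slice):
                self.state.v[sl] = np.broadcast_to(
                    np.asarray(self.params.v_reset, dtype=float), self.state.v.shape
                )[sl]
                self.state.refractory_until[sl] = -np.inf

    def reset_first_spikes(self) -> None:
        self.first_spike.fill(np.inf)

    # ---- simulation ---------------------------------------------------

    def run(
        self,
        duration: float,
        stimuli: list[StimulusSpec] = (),
        record: SpikeRecord | None = None,
        plastic: bool = True,
        explore: tuple[list[str], float] | None = None,
    ) -> None:
        """Advance the network by ``duration`` ms.

        ``stimuli`` windows are interpreted relative to the current clock.
        ``explore`` = (population names, sigma2) injects extra Gaussian
        exploration current into those populations' excitatory neurons
        (used during reinforcement training).  Plasticity (STDP, eligibility
        accumulation, reward-gated updates) runs unless ``plastic=False``.
        """
        dt = self.dt
        n_steps = int(round(duration / dt))
        t0 = self.t
        rng = self.rng

        # Pre-draw the Poisson stimulation currents for each window.
        stim_arrays = []
        for spec in stimuli:
            pop = self.populations[spec.target_population]
            arr = poisson_stimulus(spec, pop.n_exc, dt, rng)
            start_step = int(round((t0 + spec.t_start - t0) / dt))  # relative
            start_step = int(round(spec.t_start / dt))
            stim_arrays.append((pop.exc_slice, start_step, arr))

        explore_slices: list[slice] = []
        explore_sd = 0.0
        if explore is not None:
            names, sigma2 = explore
            explore_sd = float(np.sqrt(sigma2))
            explore_slices = [self.populations[nm].exc_slice for nm in names]

        noise_sd = float(np.sqrt(self.noise_sigma2))
        projs = self.projections
        rstdp_projs = [p for p in projs if p.group.mode == "rstdp"]
        plastic_projs = [p for p in projs if p.group.mode != "static"]

        # Batched range bounds so one searchsorted per step locates the
        # active pre/post spikes of every projection at once.
        pre_bounds = np.array([[p.pre_start, p.pre_stop] for p in projs]).ravel()
        pl_bounds = np.array(
            [
                [p.pre_start, p.pre_stop, p.post_start, p.post_stop]
                for p in plastic_projs
            ]
        ).ravel()
        decay = 1.0 - dt / np.array(
            [p.group.trace.tau_e for p in rstdp_projs], dtype=float
        ) if rstdp_projs else None

        for k in range(n_steps):
            t_next = self.t + dt
            i_ext = np.zeros(self.n)
            if noise_sd > 0:
                i_ext += rng.normal(0.0, noise_sd, self.n)
            for sl, start_step, arr in stim_arrays:
                row = k - start_step
                if 0 <= row < arr.shape[0]:
                    i_ext[sl] += arr[row]
            if explore_sd > 0:
                for sl in explore_slices:
                    i_ext[sl] += rng.normal(0.0, explore_sd, sl.stop - sl.start)

            i_syn = np.zeros(self.n)
            prev = self.fired_prev_idx
            if prev.size:
                cuts = np.searchsorted(prev, pre_bounds)
                for gi in np.nonzero(cuts[1::2] > cuts[0::2])[0]:
                    p = projs[gi]
                    local = prev[cuts[2 * gi] : cuts[2 * gi + 1]] - p.pre_start
                    i_syn[p.post_start : p.post_stop] += p.group.w[:, local].sum(axis=1)

            self.state = step_lif(
                self.state,
                self.params,
                CurrentInput(i_syn=i_syn, i_s=i_ext),
                dt,
            )
            fired_idx = np.flatnonzero(self.state.fired)

            if fired_idx.size:
                fresh = fired_idx[np.isinf(self.first_spike[fired_idx])]
                self.first_spike[fresh] = t_next
                if record is not None:
                    record.append(fired_idx, t_next)

            if plastic:
                # Trace decay acts on the previous value; this step's
                # pairings are then added undecayed (forward Euler).
                for i, p in enumerate(rstdp_projs):
                    p.group.trace.e *= decay[i]
                if fired_idx.size and plastic_projs:
                    cuts = np.searchsorted(fired_idx, pl_bounds)
                    touched = np.nonzero(
                        (cuts[1::4] > cuts[0::4]) | (cuts[3::4] > cuts[2::4])
                    )[0]
                    for gi in touched:
                        p = plastic_projs[gi]
                        g = p.group
                        pre_f = fired_idx[cuts[4 * gi] : cuts[4 * gi + 1]] - p.pre_start
                        post_f = (
                            fired_idx[cuts[4 * gi + 2] : cuts[4 * gi + 3]]
                            - p.post_start
                        )
                        target = g.w if g.mode == "stdp" else g.trace.e
                        touched = g.apply_pairings_inplace(pre_f, post_f, t_next, target)
                        if touched and g.mode == "stdp":
                            g.clip()
                r = reward_signal(t_next, self.reward)
                if r != 0.0:
                    for p in rstdp_projs:
                        apply_rstdp(p.group, r, dt, eta=self.eta)

            self.fired_prev_idx = fired_idx
            self.t = t_next

    # ---- convenience --------------------------------------------------

    def population_first_spikes(self, name: str, part: str = "exc") -> np.ndarray:
        pop = self.populations[name]
        sl = pop.exc_slice if part == "exc" else pop.inh_slice
        return self.first_spike[sl]

    def static_weight_checksum(self) -> float:
        """Sum over all static weights — a cheap audit that they never change."""
        return float(sum(p.group.w.sum() for p in self.projections if p.group.mode == "static"))
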