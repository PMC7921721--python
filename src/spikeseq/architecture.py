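"""Construction of the three circuits and their wiring into a runnable network.

* **Working memory circuit (WMC)** — a "begin" population plus one
  population per alphabet symbol.  Every ordered pair of distinct
  populations (begin→symbol and symbol→symbol) is connected all-to-all with
  STDP synapses initialized to small random values, so that sequentially
  stimulated populations form a directed synaptic chain.  Each population
  also drives its own inhibitory pool, and each symbol population's
  inhibitory pool projects negatively onto every other symbol population
  (lateral inhibition / winner-take-all).

* **Motor circuit** — one position population per output slot, containing
  one motor neuron per symbol.  Every WMC symbol population projects
  statically onto the motor neuron of its symbol in *every* position
  population with a sub-threshold gain; each reinforcement-learning
  postsynaptic position population projects onto all motor neurons of its
  position with a gain that completes the threshold crossing.  A motor
  neuron therefore fires only for the conjunction "this symbol is currently
  recalled AND this output position is currently selected".  Motor/hold
  reverberating pairs plus winner-take-all and inhibition-of-return
  projections turn the raw conjunctions into an orderly competitive-queuing
  readout (see docs/methods.md).

* **Reinforcement learning circuit (RLC)** — a presynaptic side (cue
  population plus one population per output position, paced through the
  slots by externally timed stimulation windows) and a postsynaptic side
  (end population plus one population per position).  All
  presynaptic→postsynaptic projections are reward-modulated STDP synapses;
  the learned block structure of these weights is the acquired grammar
  (identity permutation for "repeat", anti-diagonal for "mirror").

The chunked variant instantiates two working-memory units that share a
single RLC and motor circuit, so a 6-symbol sequence is memorized and
produced as two 3-symbol chunks.
"""

from __future__ import annotations

import numpy as np

from spikeseq.config import ExperimentConfig
from spikeseq.dynamics import LIFParams
from spikeseq.network import Network, Population
from spikeseq.plasticity import (
    EligibilityTrace,
    RewardSchedule,
    STDPParams,
    SynapseGroup,
)

__all__ = ["build_wmc", "build_motor", "build_rlc", "build_network"]


class _Builder:
    def __init__(self, config: ExperimentConfig, rng: np.random.Generator):
        self.cfg = config
        self.rng = rng
        self.n = 0
        self.pops: dict[str, Population] = {}
        self.projections: list[tuple[SynapseGroup, slice, slice]] = []
        self.motor_tau: list[tuple[int, int]] = []  # ranges using motor_tau_m
        self.hold_tau: list[tuple[int, int]] = []  # ranges using hold_tau_m
        self.hold_names: list[str] = []

    def alloc(self, count: int) -> tuple[int, int]:
        start = self.n
        self.n += count
        return start, self.n

    def add_pop(self, name: str, role: str, n_exc: int, n_inh: int = 0) -> Population:
        e0, e1 = self.alloc(n_exc)
        i0, i1 = self.alloc(n_inh) if n_inh else (e1, e1)
        pop = Population(name, role, e0, e1, i0, i1)
        self.pops[name] = pop
        return pop

    def connect(
        self,
        pre: slice,
        post: slice,
        w: np.ndarray,
        mode: str,
        params: STDPParams,
        pre_pop: str = "",
        post_pop: str = "",
        tau_e: float = 200.0,
        w_cap: np.ndarray | None = None,
    ) -> SynapseGroup:
        group = SynapseGroup(
            w=w,
            mode=mode,
            params=params,
            trace=EligibilityTrace.zeros(w.shape, tau_e) if mode == "rstdp" else None,
            pre_pop=pre_pop,
            post_pop=post_pop,
            w_cap=w_cap,
        )
        self.projections.append((group, pre, post))
        return group

    def finish(self, meta: dict) -> Network:
        cfg = self.cfg
        meta = dict(meta, config=cfg)
        tau_m = np.full(self.n, cfg.lif.tau_m)
        tau_ref = np.full(self.n, cfg.lif.tau_ref)
        for a, b in self.motor_tau:
            tau_m[a:b] = cfg.lif.motor_tau_m
            tau_ref[a:b] = cfg.lif.motor_tau_ref
        for a, b in self.hold_tau:
            tau_m[a:b] = cfg.lif.hold_tau_m
            tau_ref[a:b] = cfg.lif.motor_tau_ref
        params = LIFParams(
            c_m=cfg.lif.c_m,
            tau_m=tau_m,
            v_reset=cfg.lif.v_reset,
            v_threshold=cfg.lif.v_threshold,
            tau_ref=tau_ref,
        )
        net = Network(
            n_neurons=self.n,
            params=params,
            populations=self.pops,
            dt=cfg.timing.dt,
            noise_sigma2=cfg.noise_sigma2,
            eta=cfg.rstdp.eta,
            reward=RewardSchedule(
                c_r=cfg.rstdp.c_r, c_p=cfg.rstdp.c_p, t_r_window=cfg.rstdp.t_r_window
            ),
            rng=self.rng,
            meta=meta,
        )
        for group, pre, post in self.projections:
            net.add_projection(group, pre, post)
        return net


def _wmc_unit(b: _Builder, prefix: str) -> dict:
    """Populations and wiring of one working-memory unit."""
    cfg = b.cfg
    arch = cfg.architecture
    a = arch.alphabet_size
    n_e, n_i = arch.n_exc, arch.n_inh
    stdp_params = STDPParams(
        a_plus=cfg.stdp.a_plus,
        a_minus=cfg.stdp.a_minus,
        tau_s=cfg.stdp.tau_s,
        tau_w=cfg.stdp.tau_w,
        w_min=cfg.stdp.w_min,
        w_max=cfg.stdp.w_max,
    )
    static = STDPParams(w_min=-1e9, w_max=1e9)
    eps = arch.init_eps_frac * cfg.stdp.w_max

    # Excitatory blocks first (contiguous across the unit's symbol
    # populations, so the motor projection can address them as one range),
    # then the inhibitory pools.
    names = [f"{prefix}begin"] + [f"{prefix}sym{i}" for i in range(1, a + 1)]
    exc_ranges = {nm: b.alloc(n_e) for nm in names}
    inh_ranges = {nm: (b.alloc(n_i) if n_i else None) for nm in names}
    for nm in names:
        e0, e1 = exc_ranges[nm]
        if inh_ranges[nm] is not None:
            i0, i1 = inh_ranges[nm]
        else:
            i0 = i1 = e1
        b.pops[nm] = Population(nm, "wmc", e0, e1, i0, i1)

    # Plastic chain substrate: begin->sym and sym->sym, all ordered pairs.
    sym_names = names[1:]
    for pre in names:
        for post in sym_names:
            if pre == post:
                continue
            w0 = b.rng.uniform(0.0, eps, (n_e, n_e))
            b.connect(
                slice(*exc_ranges[pre]),
                slice(*exc_ranges[post]),
                w0,
                "stdp",
                stdp_params,
                pre_pop=pre,
                post_pop=post,
            )

    # Inhibitory pools: driven by their own population, suppressing the
    # excitatory neurons of the other symbol populations.
    if n_i:
        for nm in names:
            w_ei = np.full((n_i, n_e), arch.w_exc_inh)
            b.connect(
                slice(*exc_ranges[nm]),
                slice(*inh_ranges[nm]),
                w_ei,
                "static",
                static,
                pre_pop=nm,
                post_pop=nm,
            )
        for src in sym_names:
            for dst in sym_names:
                if src == dst:
                    continue
                w_ie = np.full((n_e, n_i), arch.w_inh_exc)
                b.connect(
                    slice(*inh_ranges[src]),
                    slice(*exc_ranges[dst]),
                    w_ie,
                    "static",
                    static,
                    pre_pop=src,
                    post_pop=dst,
                )

    sym_exc_start = exc_ranges[sym_names[0]][0]
    sym_exc_stop = exc_ranges[sym_names[-1]][1]
    return {
        "prefix": prefix,
        "names": names,
        "sym_exc": (sym_exc_start, sym_exc_stop),
    }


def _motor_unit(b: _Builder, n_positions: int, wmc_units: list[dict]) -> list[str]:
    """Motor position populations with competitive-queuing dynamics.

    Each position population holds one motor neuron per symbol, driven
    sub-threshold by its symbol's working-memory population (in every
    position) and pushed over threshold by its position's RLC gate.  Three
    intra-motor projections implement orderly readout: self-excitation
    latches a winner, within-position inhibition enforces one symbol per
    position, and across-position same-symbol inhibition suppresses a
    symbol once produced (inhibition of return).
    """
    cfg = b.cfg
    arch = cfg.architecture
    a = arch.alphabet_size
    n_e = arch.n_exc
    static = STDPParams(w_min=-1e9, w_max=1e9)
    motor_names = []
    pops = []
    for k in range(1, n_positions + 1):
        nm = f"motor_pos{k}"
        pop = b.add_pop(nm, "motor", a)
        b.motor_tau.append((pop.exc_start, pop.exc_stop))
        motor_names.append(nm)
        pops.append(pop)
        for unit in wmc_units:
            s0, s1 = unit["sym_exc"]
            w = np.zeros((a, s1 - s0))
            for s in range(a):
                w[s, s * n_e : (s + 1) * n_e] = arch.w_wmc_motor
            b.connect(
                slice(s0, s1),
                slice(pop.exc_start, pop.exc_stop),
                w,
                "static",
                static,
                pre_pop=f"{unit['prefix']}symbols",
                post_pop=nm,
            )
    # Competitive queuing: each motor neuron pairs with a "hold" neuron in
    # a strong reciprocal loop.  One motor spike ignites the loop, which
    # then reverberates for the rest of production (period two steps) and
    # persistently broadcasts the two inhibitions that keep the readout
    # orderly: winner-take-all within the position, and suppression of the
    # produced symbol in every other position (inhibition of return).
    eye = np.eye(a)
    hold_names = []
    for j, pj in enumerate(pops):
        w_intra = -arch.w_motor_wta * (1 - eye)
        b.connect(
            pj.exc_slice, pj.exc_slice, w_intra, "static", static,
            pre_pop=motor_names[j], post_pop=motor_names[j],
        )
        hold_nm = f"hold_pos{j + 1}"
        hold = b.add_pop(hold_nm, "motor", a)
        b.hold_tau.append((hold.exc_start, hold.exc_stop))
        hold_names.append(hold_nm)
        # A winner spike ignites the hold loop only in coincidence with
        # its position gate (wired in the RLC builder): one spurious motor
        # spike outside the slot cannot permanently consume a symbol.
        b.connect(
            pj.exc_slice, hold.exc_slice, 820.0 * eye, "static", static,
            pre_pop=motor_names[j], post_pop=hold_nm,
        )
        w_back = arch.w_motor_self * eye - arch.w_motor_wta * (1 - eye)
        b.connect(
            hold.exc_slice, pj.exc_slice, w_back, "static", static,
            pre_pop=hold_nm, post_pop=motor_names[j],
        )
        for k, pk in enumerate(pops):
            if j == k:
                continue
            b.connect(
                pj.exc_slice, pk.exc_slice, -arch.w_motor_sup * eye,
                "static", static,
                pre_pop=motor_names[j], post_pop=motor_names[k],
            )
            b.connect(
                hold.exc_slice, pk.exc_slice, -arch.w_motor_sup * eye,
                "static", static,
                pre_pop=hold_nm, post_pop=motor_names[k],
            )
    b.hold_names = hold_names
    return motor_names


def _rlc_unit(b: _Builder, n_positions: int, motor_names: list[str] | None) -> dict:
    cfg = b.cfg
    arch = cfg.architecture
    n_e = arch.n_exc
    a = arch.alphabet_size
    static = STDPParams(w_min=-1e9, w_max=1e9)
    rstdp_params = STDPParams(
        a_plus=cfg.stdp.a_plus,
        a_minus=cfg.stdp.a_minus,
        tau_s=cfg.stdp.tau_s,
        tau_w=cfg.stdp.tau_w,
        w_min=cfg.rstdp.w_min,
        w_max=cfg.rstdp.w_max,
    )
    eps = arch.init_eps_frac * cfg.rstdp.w_max

    pre_names = ["cue"] + [f"pre_pos{k}" for k in range(1, n_positions + 1)]
    post_names = ["end"] + [f"post_pos{k}" for k in range(1, n_positions + 1)]
    for nm in pre_names:
        b.add_pop(nm, "rlc_pre", n_e)
    for nm in post_names:
        b.add_pop(nm, "rlc_post", n_e)

    # Reward-modulated projections: every presynaptic population to every
    # postsynaptic population, identically initialized near zero.
    for pre in pre_names:
        for post in post_names:
            w0 = b.rng.uniform(0.0, eps, (n_e, n_e))
            # Heterogeneous saturation ceilings (per postsynaptic neuron):
            # trained weights inherit the spread, which keeps the
            # postsynaptic populations desynchronized when driven.
            cap = cfg.rstdp.w_max * b.rng.uniform(0.7, 1.3, n_e)[:, None]
            b.connect(
                b.pops[pre].exc_slice,
                b.pops[post].exc_slice,
                w0,
                "rstdp",
                rstdp_params,
                pre_pop=pre,
                post_pop=post,
                tau_e=cfg.rstdp.tau_e,
                w_cap=np.broadcast_to(cap, (n_e, n_e)).copy(),
            )

    if motor_names is not None:
        for k, motor_nm in enumerate(motor_names, start=1):
            post = b.pops[f"post_pos{k}"]
            motor = b.pops[motor_nm]
            w = np.full((a, n_e), arch.w_rlc_motor)
            b.connect(
                post.exc_slice,
                motor.exc_slice,
                w,
                "static",
                static,
                pre_pop=f"post_pos{k}",
                post_pop=motor_nm,
            )
            hold = b.pops[f"hold_pos{k}"]
            b.connect(
                post.exc_slice,
                hold.exc_slice,
                np.full((a, n_e), 4.5),
                "static",
                static,
                pre_pop=f"post_pos{k}",
                post_pop=f"hold_pos{k}",
            )
    return {"pre": pre_names, "post": post_names}


def build_wmc(
    config: ExperimentConfig | None = None, rng: np.random.Generator | None = None
) -> Network:
    """A standalone working-memory unit (begin + symbol populations)."""
    config = config or ExperimentConfig()
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    b = _Builder(config, rng)
    unit = _wmc_unit(b, "")
    return b.finish({"kind": "wmc", "length": config.sequence_length, "units": [unit]})


def build_motor(
    config: ExperimentConfig | None = None, rng: np.random.Generator | None = None
) -> Network:
    """A standalone motor circuit fed by one working-memory unit."""
    config = config or ExperimentConfig()
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    b = _Builder(config, rng)
    unit = _wmc_unit(b, "")
    motor = _motor_unit(b, config.sequence_length, [unit])
    return b.finish(
        {
            "kind": "motor",
            "length": config.sequence_length,
            "units": [unit],
            "motor": motor,
            "hold": b.hold_names,
        }
    )


def build_rlc(
    config: ExperimentConfig | None = None, rng: np.random.Generator | None = None
) -> Network:
    """A standalone reinforcement-learning circuit (cue/positions/end)."""
    config = config or ExperimentConfig()
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    b = _Builder(config, rng)
    rlc = _rlc_unit(b, config.sequence_length, None)
    return b.finish({"kind": "rlc", "length": config.sequence_length, "rlc": rlc})


def build_network(
    config: ExperimentConfig | None = None, rng: np.random.Generator | None = None
) -> Network:
    """The full production network (WMC + motor + RLC), chunked if requested.

    Without chunking, one working-memory unit spans the whole sequence and
    the RLC/motor circuits have one position per sequence element.  With
    chunking (length divisible by chunk_size), one working-memory unit per
    chunk shares a single RLC and motor circuit of chunk_size positions.
    """
    config = config or ExperimentConfig()
    if config.chunking and config.sequence_length % config.chunk_size != 0:
        raise ValueError("chunking requires sequence_length divisible by chunk_size")
    if config.chunking and config.sequence_length == config.chunk_size:
        raise ValueError("chunking is only meaningful for sequences longer than one chunk")
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    b = _Builder(config, rng)
    if config.chunking:
        n_chunks = config.sequence_length // config.chunk_size
        units = [_wmc_unit(b, f"c{i}:") for i in range(n_chunks)]
        n_positions = config.chunk_size
    else:
        units = [_wmc_unit(b, "")]
        n_positions = config.sequence_length
    motor = _motor_unit(b, n_positions, units)
    rlc = _rlc_unit(b, n_positions, motor)
    return b.finish(
        {
            "kind": "full",
            "length": config.sequence_length,
            "chunking": config.chunking,
            "chunk_size": config.chunk_size,
            "units": units,
            "motor": motor,
            "hold": b.hold_names,
            "rlc": rlc,
            "n_positions": n_positions,
        }
    )
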