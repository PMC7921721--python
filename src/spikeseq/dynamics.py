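"""Discrete-time leaky integrate-and-fire dynamics.

The membrane equation is integrated with forward Euler,

    tau_m * dV/dt = -(V - V_s) + I / g,        V -> V_reset  once V >= V_threshold,

with an absolute refractory period during which the voltage is clamped at
``V_reset``.  The leak reversal potential ``V_s`` equals the reset potential,
and the leak conductance is derived as ``g = C_m / tau_m``.  Input current is
the sum of synaptic current (spikes of the previous step weighted by the
connection matrix), external stimulation (Poisson-encoded symbol onsets) and
optional Gaussian background noise.

All functions operate on NumPy arrays; scalars broadcast.  Units: ms, mV, nA,
nF, µS.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "LIFParams",
    "LIFState",
    "CurrentInput",
    "StimulusSpec",
    "SpikeRecord",
    "step_lif",
    "synaptic_current",
    "poisson_stimulus",
    "gaussian_noise",
]


@dataclass(frozen=True)
class LIFParams:
    """Constants of the leaky integrate-and-fire neuron.

    Defaults are the model's standard values: C_m = 30 nF, tau_m = 30 ms,
    V_reset = V_s = -65 mV, V_threshold = -35 mV, tau_ref = 10 ms.  Fields
    may be scalars or per-neuron arrays (heterogeneous populations, e.g.
    slow-leak motor neurons).
    """

    c_m: float | np.ndarray = 30.0  # nF
    tau_m: float | np.ndarray = 30.0  # ms
    v_reset: float | np.ndarray = -65.0  # mV
    v_threshold: float | np.ndarray = -35.0  # mV
    tau_ref: float | np.ndarray = 10.0  # ms

    def __post_init__(self) -> None:
        if not np.all(np.asarray(self.v_reset) < np.asarray(self.v_threshold)):
            raise ValueError("V_reset must lie below V_threshold")
        for name in ("c_m", "tau_m", "tau_ref"):
            if not np.all(np.asarray(getattr(self, name)) > 0):
                raise ValueError(f"{name} must be positive")

    @property
    def g(self) -> float | np.ndarray:
        """Leak conductance, g = C_m / tau_m (µS)."""
        return self.c_m / self.tau_m

    @property
    def v_s(self) -> float | np.ndarray:
        """Leak reversal potential; tied to the reset potential."""
        return self.v_reset


@dataclass
class LIFState:
    """Per-neuron dynamical state: voltage, refractory deadline, spike flag."""

    v: np.ndarray
    refractory_until: np.ndarray
    fired: np.ndarray
    t: float = 0.0

    @classmethod
    def at_rest(cls, n: int, params: LIFParams) -> "LIFState":
        v = np.full(n, params.v_reset, dtype=float) if np.isscalar(params.v_reset) else np.array(
            np.broadcast_to(params.v_reset, (n,)), dtype=float
        )
        return cls(
            v=v,
            refractory_until=np.full(n, -np.inf),
            fired=np.zeros(n, dtype=bool),
        )


@dataclass
class CurrentInput:
    """Input current decomposition: synaptic + external stimulation + noise (nA)."""

    i_syn: np.ndarray | float = 0.0
    i_s: np.ndarray | float = 0.0
    i_noise: np.ndarray | float = 0.0

    @property
    def total(self) -> np.ndarray | float:
        return self.i_syn + self.i_s + self.i_noise


@dataclass(frozen=True)
class StimulusSpec:
    """Poisson-encoded stimulation of one population.

    Within ``[t_start, t_end)`` every neuron of the target population
    independently receives current pulses of size ``amplitude`` as Bernoulli
    events with per-step probability ``rate * dt / 1000`` (rate in Hz).
    """

    target_population: str
    t_start: float
    t_end: float
    rate: float  # Hz
    amplitude: float  # nA per event
    onset_rate: float = 0.0  # Hz during the first onset_ms (stimulus transient)
    onset_ms: float = 0.0

    def __post_init__(self) -> None:
        if self.t_start >= self.t_end:
            raise ValueError("stimulus window must satisfy t_start < t_end")
        if self.rate < 0 or self.onset_rate < 0:
            raise ValueError("Poisson rate must be non-negative")


class SpikeRecord:
    """Columnar record of spike events: (neuron id, time in ms).

    Built incrementally by the simulation loop; exposes NumPy views and a
    CSV round-trip.
    """

    def __init__(self, ids: np.ndarray | None = None, times: np.ndarray | None = None):
        self._chunks_ids: list[np.ndarray] = []
        self._chunks_times: list[np.ndarray] = []
        self._ids = np.asarray(ids, dtype=np.int64) if ids is not None else None
        self._times = np.asarray(times, dtype=float) if times is not None else None

    def append(self, ids: np.ndarray, t: float) -> None:
        if ids.size:
            self._chunks_ids.append(np.asarray(ids, dtype=np.int64))
            self._chunks_times.append(np.full(ids.size, t))
            self._ids = None
            self._times = None

    def _consolidate(self) -> None:
        if self._ids is None:
            if self._chunks_ids:
                self._ids = np.concatenate(self._chunks_ids)
                self._times = np.concatenate(self._chunks_times)
            else:
                self._ids = np.empty(0, dtype=np.int64)
                self._times = np.empty(0)

    @property
    def ids(self) -> np.ndarray:
        self._consolidate()
        return self._ids

    @property
    def times(self) -> np.ndarray:
        self._consolidate()
        return self._times

    def __len__(self) -> int:
        return self.ids.size

    def in_window(self, t0: float, t1: float) -> "SpikeRecord":
        m = (self.times >= t0) & (self.times < t1)
        return SpikeRecord(self.ids[m], self.times[m])

    def distinct_count(self, lo: int, hi: int, t0: float, t1: float) -> int:
        """Number of distinct neuron ids in [lo, hi) spiking within [t0, t1)."""
        m = (self.times >= t0) & (self.times < t1) & (self.ids >= lo) & (self.ids < hi)
        return int(np.unique(self.ids[m]).size)

    def to_csv(self, path) -> None:
        import pandas as pd

        pd.DataFrame({"neuron_id": self.ids, "time_ms": self.times}).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "SpikeRecord":
        import pandas as pd

        df = pd.read_csv(path)
        return cls(df["neuron_id"].to_numpy(), df["time_ms"].to_numpy())


def step_lif(
    state: LIFState,
    params: LIFParams,
    current: CurrentInput,
    dt: float,
) -> LIFState:
    """Advance the LIF state by one Euler step of size ``dt``.

    Non-refractory neurons integrate
    ``dV = (-(V - V_s) + I/g) * dt / tau_m``; any neuron reaching threshold
    fires, resets to ``V_reset`` and becomes refractory for ``tau_ref``.
    Refractory neurons are clamped at ``V_reset`` and cannot fire.

    Raises ``FloatingPointError`` on non-finite voltage or current.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    i_total = np.asarray(current.total, dtype=float)
    # a NaN/inf anywhere poisons the sum, so one reduction audits the array
    if not np.isfinite(i_total.sum() + state.v.sum()):
        raise FloatingPointError("non-finite input current or membrane potential")

    t_next = state.t + dt
    v = state.v.copy()
    # A neuron integrates over (t, t+dt] only once its refractory period
    # has fully elapsed at the step's start.
    active = state.t >= state.refractory_until
    v_s = params.v_s
    at_threshold = active & (v >= params.v_threshold)
    dv = (-(v - v_s) + i_total / params.g) * (dt / params.tau_m)
    v = np.where(active, v + dv, np.broadcast_to(params.v_reset, v.shape))
    fired = active & ((v >= params.v_threshold) | at_threshold)
    refractory_until = np.where(fired, t_next + params.tau_ref, state.refractory_until)
    v = np.where(fired, np.broadcast_to(params.v_reset, v.shape), v)
    return LIFState(v=v, refractory_until=refractory_until, fired=fired, t=t_next)


def synaptic_current(weights: np.ndarray, pre_fired_prev: np.ndarray) -> np.ndarray:
    """Postsynaptic current from the previous step's presynaptic spikes.

    ``weights`` has shape (n_post, n_pre); transmission is delayed by one
    step, so the caller passes the spike indicator of step t-1.
    """
    w = np.asarray(weights)
    sigma = np.asarray(pre_fired_prev)
    if w.ndim != 2 or sigma.shape != (w.shape[1],):
        raise ValueError(
            f"shape mismatch: weights {w.shape} vs presynaptic spikes {sigma.shape}"
        )
    return w @ sigma.astype(float)


def poisson_stimulus(
    spec: StimulusSpec,
    n_neurons: int,
    dt: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Poisson-encoded stimulation currents for the spec's window.

    Returns an array of shape (n_steps, n_neurons): ``amplitude`` where a
    Bernoulli(rate*dt) event occurred, else 0.  Deterministic under a fixed
    generator state.
    """
    n_steps = int(round((spec.t_end - spec.t_start) / dt))
    p = np.full(n_steps, spec.rate * dt / 1000.0)
    n_onset = min(n_steps, int(round(spec.onset_ms / dt)))
    if n_onset:
        p[:n_onset] = spec.onset_rate * dt / 1000.0
    if not p.any():
        return np.zeros((n_steps, n_neurons))
    events = rng.random((n_steps, n_neurons)) < p[:, None]
    return events * spec.amplitude


def gaussian_noise(sigma2: float, n_neurons: int, rng: np.random.Generator) -> np.ndarray:
    """Zero-mean Gaussian background current with variance ``sigma2`` (nA²)."""
    if sigma2 < 0:
        raise ValueError("noise variance must be non-negative")
    if sigma2 == 0:
        return np.zeros(n_neurons)
    return rng.normal(0.0, np.sqrt(sigma2), n_neurons)
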