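"""Experiment configuration: validated, serializable, fully defaulted.

Every constant of the model lives here.  Membrane and STDP constants carry
the model's standard values (C_m = 30 nF, tau_m = 30 ms, V_reset = V_s =
-65 mV, V_threshold = -35 mV, tau_ref = 10 ms; A+ = 4, A- = 0.95,
tau_s = 15 ms, tau_w = 10 ms; C_r = +10, C_p = -10, T_R = 5).  Quantities
the model leaves open (integration step, Poisson encoding rate and
amplitude, weight bounds, circuit gains, eligibility time constant,
reinforcement gain) are exposed with defaults calibrated once at zero
noise; the calibration rationale is documented in docs/methods.md.

Configs round-trip through YAML or JSON via :func:`load_config` /
:func:`save_config`; unknown keys are rejected.
"""

from __future__ import annotations

import json
from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

__all__ = [
    "LIFConfig",
    "STDPConfig",
    "RSTDPConfig",
    "StimulusConfig",
    "ArchitectureConfig",
    "TimingConfig",
    "TrainingConfig",
    "ExperimentConfig",
    "load_config",
    "save_config",
]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid", validate_assignment=True)


class LIFConfig(_Strict):
    """Membrane constants (ms, mV, nF).  g is derived as C_m / tau_m."""

    c_m: float = Field(30.0, gt=0)
    tau_m: float = Field(30.0, gt=0)
    v_reset: float = -65.0
    v_threshold: float = -35.0
    tau_ref: float = Field(10.0, gt=0)
    # Motor neurons integrate with a slower leak so that the working-memory
    # trace they hold survives until the matching output position.
    motor_tau_m: float = Field(40.0, gt=0)
    # Short motor refractory so the motor/hold pair can reverberate.
    motor_tau_ref: float = Field(0.5, gt=0)
    # Hold neurons integrate fast enough that their gate drive vanishes
    # soon after the slot closes (sharp gate-coincidence ignition).
    hold_tau_m: float = Field(20.0, gt=0)

    @model_validator(mode="after")
    def _check(self) -> "LIFConfig":
        if self.v_reset >= self.v_threshold:
            raise ValueError("v_reset must be below v_threshold")
        return self


class STDPConfig(_Strict):
    """Pairwise STDP constants for the working-memory circuit."""

    a_plus: float = Field(4.0, gt=0)
    a_minus: float = Field(0.95, gt=0)
    tau_s: float = Field(15.0, gt=0)
    tau_w: float = Field(10.0, gt=0)
    w_min: float = 0.0
    w_max: float = Field(13.0, gt=0)


class RSTDPConfig(_Strict):
    """Reward-modulated STDP: eligibility trace, reward schedule, gain."""

    tau_e: float = Field(200.0, gt=0)
    eta: float = Field(0.02, gt=0)
    c_r: float = 10.0
    c_p: float = -10.0
    t_r_window: float = Field(5.0, gt=0)
    w_min: float = 0.0
    w_max: float = Field(12.0, gt=0)


class StimulusConfig(_Strict):
    """Poisson encoding of a symbol onset into stimulation current.

    The default symbol encoding uses sparse, large events (a single event
    drives a spike), which keeps the neurons of a stimulated population
    desynchronized; the production start signal instead uses dense smaller
    events, which locks the begin/cue populations into the synchronous
    volleys that ignite replay.
    """

    rate: float = Field(150.0, ge=0)  # Hz; Bernoulli p = rate*dt/1000 per step
    amplitude: float = Field(2400.0, gt=0)  # nA per event
    onset_rate: float = Field(800.0, ge=0)  # Hz during the onset transient
    onset_ms: float = Field(5.0, ge=0)


class ArchitectureConfig(_Strict):
    """Population sizes and fixed circuit gains (all currents in nA)."""

    n_exc: int = Field(60, ge=1)  # C, neurons per coding population
    n_inh: int = Field(20, ge=0)  # inhibitory neurons per WMC population
    alphabet_size: int = Field(6, ge=1)
    init_eps_frac: float = Field(0.01, gt=0)  # plastic init ~ U[0, frac*w_max]
    w_exc_inh: float = Field(18.0, gt=0)  # within-population drive of inhibition
    w_inh_exc: float = Field(-2.0, lt=0)  # lateral inhibition onto other symbols
    w_wmc_motor: float = Field(7.5, gt=0)  # sub-threshold symbol trace gain
    w_rlc_motor: float = Field(10.0, gt=0)  # position gate gain
    w_motor_self: float = Field(1000.0, ge=0)  # hold->motor reverberation gain
    w_motor_wta: float = Field(2400.0, ge=0)  # within-position winner-take-all
    w_motor_sup: float = Field(2400.0, ge=0)  # produced-symbol suppression


class TimingConfig(_Strict):
    """Trial phase layout (ms)."""

    dt: float = Field(1.0, gt=0)
    stim_window: float = Field(60.0, gt=0)  # per-symbol presentation
    presentations: int = Field(10, ge=1)  # memory-stage repetitions
    delay: float = Field(200.0, ge=0)  # gap between memory and production
    begin_window: float = Field(140.0, gt=0)  # start signal for recall probes
    slot_offset: float = Field(7.0, ge=0)  # first production slot opens (ms)
    slot_spacing: float = Field(24.0, gt=0)  # one slot per replay hop
    slot_width: float = Field(40.0, gt=0)  # pre-position stimulation window
    slot_width_train: float = Field(24.0, gt=0)  # narrow leak-free window for shaping
    production_margin: float = Field(120.0, ge=0)

    def production_begin(self, n_positions: int) -> float:
        return self.slot_offset + self.slot_spacing * n_positions + 55.0

    def production_duration(self, n_positions: int) -> float:
        return self.production_begin(n_positions) + self.production_margin

    def slot_window(self, k: int) -> tuple[float, float]:
        t0 = self.slot_offset + self.slot_spacing * (k - 1)
        return t0, t0 + self.slot_width


class TrainingConfig(_Strict):
    """Reinforcement-stage settings."""

    explore_sigma2: float = Field(6400.0, ge=0)  # exploration noise into RLC post side
    guided: bool = True  # shaping: cue the correct post population while training
    guided_trials: int = Field(150, ge=0)  # shaping phase length before free trials
    n_trials: int = Field(150, ge=1)


class ExperimentConfig(_Strict):
    """Root configuration; one master seed spawns all component streams."""

    seed: int = 0
    noise_sigma2: float = Field(0.0, ge=0)  # background Gaussian noise intensity
    sequence_length: int = Field(3, ge=1)
    chunking: bool = False
    chunk_size: int = Field(3, ge=1)
    lif: LIFConfig = Field(default_factory=LIFConfig)
    stdp: STDPConfig = Field(default_factory=STDPConfig)
    rstdp: RSTDPConfig = Field(default_factory=RSTDPConfig)
    stimulus: StimulusConfig = Field(default_factory=StimulusConfig)
    start_stimulus: StimulusConfig = Field(
        default_factory=lambda: StimulusConfig(
            rate=800.0, amplitude=600.0, onset_rate=0.0, onset_ms=0.0
        )
    )
    architecture: ArchitectureConfig = Field(default_factory=ArchitectureConfig)
    timing: TimingConfig = Field(default_factory=TimingConfig)
    training: TrainingConfig = Field(default_factory=TrainingConfig)

    @model_validator(mode="after")
    def _check(self) -> "ExperimentConfig":
        if self.sequence_length > self.architecture.alphabet_size:
            raise ValueError("sequence_length cannot exceed alphabet_size")
        if self.chunking and self.sequence_length % self.chunk_size != 0:
            raise ValueError("chunking requires length divisible by chunk_size")
        return self


def load_config(path: str | Path | None = None) -> ExperimentConfig:
    """Load a YAML or JSON config; missing keys take defaults, unknown keys fail."""
    if path is None:
        return ExperimentConfig()
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    text = path.read_text()
    data = yaml.safe_load(text) if path.suffix in (".yml", ".yaml") else json.loads(text or "{}")
    if data is None:
        data = {}
    return ExperimentConfig.model_validate(data)


def save_config(config: ExperimentConfig, path: str | Path) -> None:
    path = Path(path)
    payload = config.model_dump(mode="json")
    if path.suffix in (".yml", ".yaml"):
        path.write_text(yaml.safe_dump(payload, sort_keys=False))
    else:
        path.write_text(json.dumps(payload, indent=2))
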