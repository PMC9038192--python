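"""Experiment configuration: YAML round-trip, validation, run records.

Every number the simulation protocols use is a named key with the
protocol value as default, so a minimal config only names the
experiment.  Unknown keys and out-of-range values are rejected with the
offending key named.
"""

from __future__ import annotations

import time
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

from .experiments import TaskConfig
from .neuron import (
    RectifiedQuadraticTransfer,
    ShiftedTransfer,
    SigmoidTransfer,
    SynapticKernel,
    TransferFunction,
)

__all__ = ["ExperimentConfig", "RunRecord", "load_config"]

_EXPERIMENTS = (
    "simulate",
    "learn",
    "fisher",
    "democratic",
    "variance",
    "grid",
    "coefficients",
    "angles",
    "robustness",
    "vector_field",
)


@dataclass
class ExperimentConfig:
    """Flat, validated configuration for all CLI entry points."""

    experiment: str = "learn"
    seed: int = 0

    # task geometry and input statistics
    n: int = 100
    rate_low_hz: float = 10.0
    rate_high_hz: float = 50.0
    input_rate_hz: float = 5.0  # single-synapse protocols
    teacher_rate_hz: float = 20.0

    # neuron model
    epsilon0: float = 1.0  # kernel integral, mV*s
    tau_m_ms: float = 10.0
    tau_s_ms: float = 3.0
    transfer: str = "sigmoid"
    phi_max_hz: float = 100.0
    beta: float = 0.3
    theta_mv: float = 10.0
    baseline_shift_mv: float = 0.0

    # learning
    rule: str = "natural"
    eta: float | None = None  # None: tuned value for the rate pattern
    dt_ms: float = 0.5
    duration_s: float = 4000.0
    n_trials: int = 50
    record_every_s: float = 50.0
    weight_scale: float = 1.0
    cu: float = 0.95
    cw: float = 0.05
    refresh_every: int = 1
    dkl_threshold: float = 5e-5
    scales: list = field(default_factory=lambda: [0.5, 0.75, 1.0, 1.5, 2.0])

    # geometry / parametrization
    attenuation: str = "reciprocal"
    lambda_um: float = 200.0
    distances_um: list = field(default_factory=lambda: [float(d) for d in range(0, 461, 46)])

    # sampling protocols
    n_weight_draws: int = 20
    n_usp_draws: int = 20
    n_spike_draws: int = 20

    def __post_init__(self) -> None:
        if self.experiment not in _EXPERIMENTS:
            raise ValueError(f"experiment must be one of {_EXPERIMENTS}, got {self.experiment!r}")
        if self.rule not in ("natural", "euclidean", "approx", "quadratic"):
            raise ValueError(f"rule: unknown rule {self.rule!r}")
        if self.transfer not in ("sigmoid", "quadratic"):
            raise ValueError(f"transfer: unknown transfer {self.transfer!r}")
        if self.attenuation not in ("reciprocal", "exponential", "identity"):
            raise ValueError(f"attenuation: unknown variant {self.attenuation!r}")
        positive = (
            "epsilon0", "tau_m_ms", "tau_s_ms", "phi_max_hz", "beta", "dt_ms",
            "duration_s", "record_every_s", "lambda_um", "dkl_threshold",
        )
        for key in positive:
            if not getattr(self, key) > 0:
                raise ValueError(f"{key}: must be positive, got {getattr(self, key)}")
        non_negative = ("rate_low_hz", "rate_high_hz", "input_rate_hz", "teacher_rate_hz")
        for key in non_negative:
            if getattr(self, key) < 0:
                raise ValueError(f"{key}: rates must be non-negative, got {getattr(self, key)}")
        for key in ("n", "n_trials", "n_weight_draws", "n_usp_draws", "n_spike_draws",
                    "refresh_every"):
            if int(getattr(self, key)) < 1:
                raise ValueError(f"{key}: must be a positive integer")
        if self.eta is not None and self.eta < 0:
            raise ValueError(f"eta: must be non-negative, got {self.eta}")
        if any(d < 0 for d in self.distances_um):
            raise ValueError("distances_um: distances must be non-negative")

    # -- derived model objects -------------------------------------------
    @property
    def dt(self) -> float:
        return self.dt_ms / 1e3

    def kernel(self) -> SynapticKernel:
        return SynapticKernel(
            epsilon0=self.epsilon0, tau_m=self.tau_m_ms / 1e3, tau_s=self.tau_s_ms / 1e3
        )

    def transfer_function(self) -> TransferFunction:
        if self.transfer == "sigmoid":
            tf: TransferFunction = SigmoidTransfer(
                phi_max=self.phi_max_hz, beta=self.beta, theta=self.theta_mv
            )
        else:
            tf = RectifiedQuadraticTransfer(theta=self.theta_mv)
        if self.baseline_shift_mv != 0.0:
            tf = ShiftedTransfer(base=tf, shift=self.baseline_shift_mv)
        return tf

    def task(self) -> TaskConfig:
        return TaskConfig(
            n=self.n,
            rate_low=self.rate_low_hz,
            rate_high=self.rate_high_hz,
            rule=self.rule,
            eta=self.eta,
            dt=self.dt,
            duration=self.duration_s,
            n_trials=self.n_trials,
            record_every=self.record_every_s,
            seed=self.seed,
            kernel=self.kernel(),
            tf=self.transfer_function(),
            weight_scale=self.weight_scale,
            cu=self.cu,
            cw=self.cw,
            refresh_every=self.refresh_every,
        )

    # -- persistence ------------------------------------------------------
    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))

    @classmethod
    def from_mapping(cls, data: dict) -> "ExperimentConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


def load_config(path) -> ExperimentConfig:
    """Parse and validate a YAML config file."""
    data = yaml.safe_load(Path(path).read_text())
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ValueError(f"config {path} must be a mapping")
    return ExperimentConfig.from_mapping(data)


@dataclass
class RunRecord:
    """Provenance of one CLI run: config snapshot, timings, outputs."""

    config: dict
    seed: int
    package_version: str
    stage_seconds: dict = field(default_factory=dict)
    manifest: list = field(default_factory=list)
    _t0: float = field(default_factory=time.perf_counter, repr=False)

    def stage_done(self, name: str) -> None:
        now = time.perf_counter()
        self.stage_seconds[name] = round(now - self._t0, 3)
        self._t0 = now

    def add_output(self, path) -> None:
        name = str(path)
        if name in self.manifest:
            raise ValueError(f"output {name} already recorded in the manifest")
        self.manifest.append(name)

    def write(self, path) -> None:
        payload = {
            "config": self.config,
            "seed": self.seed,
            "package_version": self.package_version,
            "stage_seconds": self.stage_seconds,
            "manifest": self.manifest,
        }
        Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))
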