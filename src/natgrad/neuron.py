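"""Poisson neuron model: synaptic kernel, transfer functions, afferents.

The neuron is a current-based point-process GLM.  Presynaptic spike
trains are low-pass filtered by a double-exponential postsynaptic
potential (PSP) kernel into unweighted synaptic potentials (USPs); the
somatic potential above rest is the weight-inner-product of the USPs,
and output spikes are drawn per time bin as a Bernoulli with parameter
``phi(V) * dt``, where ``phi`` is a positive, non-decreasing transfer
function (sigmoidal by default, rectified-quadratic as an analytically
convenient special case).

Units: mV and seconds; rates in Hz.  The kernel formulas themselves are
unit-agnostic (plain algebra in whatever units the caller supplies); the
defaults below encode the simulation convention of a kernel integral of
1 mV*s with tau_m = 10 ms and tau_s = 3 ms, which puts USP kernel peaks
near 60 mV per unit weight and membrane potentials for weights of order
1/n within the dynamic range of the sigmoid.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

__all__ = [
    "SynapticKernel",
    "AfferentConfig",
    "TransferFunction",
    "SigmoidTransfer",
    "RectifiedQuadraticTransfer",
    "membrane_potential",
    "DEFAULT_KERNEL",
    "DEFAULT_TRANSFER",
]


@dataclass(frozen=True)
class SynapticKernel:
    """Double-exponential PSP kernel.

    ``epsilon(t) = epsilon0 / (tau_m - tau_s) * (exp(-t/tau_m) - exp(-t/tau_s))``
    for ``t >= 0`` and zero otherwise.  The kernel integrates to
    ``epsilon0`` (units mV*ms), so a Poisson train of rate ``r`` drives a
    stationary USP with mean ``epsilon0 * r`` and variance ``r / c_epsilon``.

    Parameters
    ----------
    epsilon0:
        Kernel scale (time-integral of the kernel), mV times time unit.
        Default 1.0 mV*s.
    tau_m:
        Membrane time constant (default 10 ms = 0.010 s).
    tau_s:
        Synaptic time constant; must satisfy ``tau_m > tau_s > 0``.
    """

    epsilon0: float = 1.0
    tau_m: float = 0.010
    tau_s: float = 0.003

    def __post_init__(self) -> None:
        # the formula is symmetric under tau_m <-> tau_s; only equality is
        # degenerate (variance-scan protocols sweep tau_s past tau_m)
        if self.tau_m <= 0.0 or self.tau_s <= 0.0 or self.tau_m == self.tau_s:
            raise ValueError(
                f"require tau_m, tau_s > 0 and tau_m != tau_s, got "
                f"tau_m={self.tau_m}, tau_s={self.tau_s}"
            )
        if self.epsilon0 <= 0.0:
            raise ValueError(f"epsilon0 must be positive, got {self.epsilon0}")

    def value(self, t):
        """Kernel value epsilon(t) in mV; zero for t < 0."""
        t = np.asarray(t, dtype=float)
        out = np.zeros_like(t)
        pos = t >= 0.0
        tp = t[pos] if t.ndim else (t if pos else None)
        if t.ndim == 0:
            if pos:
                return float(
                    self.epsilon0
                    / (self.tau_m - self.tau_s)
                    * (np.exp(-t / self.tau_m) - np.exp(-t / self.tau_s))
                )
            return 0.0
        out[pos] = (
            self.epsilon0
            / (self.tau_m - self.tau_s)
            * (np.exp(-tp / self.tau_m) - np.exp(-tp / self.tau_s))
        )
        return out

    @property
    def c_epsilon(self) -> float:
        """Inverse integral of the squared kernel, 2*(tau_m + tau_s)/epsilon0**2.

        Links the input rate to the USP precision: ``Var(x_eps) = r / c_epsilon``.
        """
        return 2.0 * (self.tau_m + self.tau_s) / self.epsilon0**2

    @property
    def peak_time(self) -> float:
        """Time of the kernel maximum, tau_m*tau_s/(tau_m - tau_s)*ln(tau_m/tau_s)."""
        return (
            self.tau_m * self.tau_s / (self.tau_m - self.tau_s) * np.log(self.tau_m / self.tau_s)
        )

    @property
    def peak_amplitude(self) -> float:
        """Kernel value at its maximum (mV per unit weight)."""
        return float(self.value(self.peak_time))

    def with_epsilon0(self, epsilon0: float) -> "SynapticKernel":
        return SynapticKernel(epsilon0=epsilon0, tau_m=self.tau_m, tau_s=self.tau_s)

    def usp_moments(self, rate):
        """Stationary mean and variance of the USP for Poisson input at `rate`.

        mean = epsilon0 * r,  var = r / c_epsilon (exact for constant rates).
        """
        rate = np.asarray(rate, dtype=float)
        return self.epsilon0 * rate, rate / self.c_epsilon


DEFAULT_KERNEL = SynapticKernel()


@dataclass(frozen=True)
class AfferentConfig:
    """A population of independently firing Poisson afferents.

    Parameters
    ----------
    rates:
        Per-afferent firing rates in Hz (length n, all >= 0).
    kernel:
        Shared PSP kernel.
    """

    rates: np.ndarray
    kernel: SynapticKernel = field(default=DEFAULT_KERNEL)

    def __post_init__(self) -> None:
        rates = np.atleast_1d(np.asarray(self.rates, dtype=float))
        if rates.ndim != 1 or rates.size < 1:
            raise ValueError("rates must be a 1-d array with at least one afferent")
        if np.any(rates < 0) or not np.all(np.isfinite(rates)):
            raise ValueError("rates must be finite and non-negative")
        object.__setattr__(self, "rates", rates)

    @property
    def n(self) -> int:
        return int(self.rates.size)


class TransferFunction:
    """Voltage-to-rate nonlinearity phi with derivative.

    Subclasses implement ``phi`` (Hz) and ``dphi``; the ratios
    ``(phi')^2/phi`` and ``phi'/phi`` used by the learning rules are
    provided here, with an optional floor on phi to keep ratios finite
    at the edge of the transfer function's support.
    """

    #: floor applied to phi inside ratios only (Hz); 0 disables it
    phi_floor: float = 0.0

    def phi(self, v):  # pragma: no cover - abstract
        raise NotImplementedError

    def dphi(self, v):  # pragma: no cover - abstract
        raise NotImplementedError

    def __call__(self, v):
        return self.phi(v)

    def _floored(self, phi_v):
        if self.phi_floor > 0.0:
            return np.maximum(phi_v, self.phi_floor)
        if np.any(np.asarray(phi_v) <= 0.0):
            raise ValueError(
                "phi = 0 encountered in a ratio; restrict voltages to the "
                "transfer function's support or set phi_floor > 0"
            )
        return phi_v

    def fisher_ratio(self, v):
        """(phi'(v))^2 / phi(v) — the per-bin Fisher information density."""
        return self.dphi(v) ** 2 / self._floored(self.phi(v))

    def slope_ratio(self, v):
        """phi'(v) / phi(v) — the sensitivity factor of the learning rules."""
        return self.dphi(v) / self._floored(self.phi(v))


@dataclass(frozen=True)
class SigmoidTransfer(TransferFunction):
    """Sigmoidal transfer phi(V) = phi_max / (1 + exp(-beta (V - theta))).

    Defaults: beta = 0.3/mV, theta = 10 mV above rest, phi_max = 100 Hz.
    """

    phi_max: float = 100.0
    beta: float = 0.3
    theta: float = 10.0
    phi_floor: float = 0.0

    def phi(self, v):
        v = np.asarray(v, dtype=float)
        return self.phi_max * expit(self.beta * (v - self.theta))

    def dphi(self, v):
        p = self.phi(v)
        return self.beta * p * (1.0 - p / self.phi_max)


@dataclass(frozen=True)
class RectifiedQuadraticTransfer(TransferFunction):
    """Rectified quadratic transfer phi(V) = (1/4)(V - theta)^2 for V > theta.

    Satisfies (phi')^2 / phi = 1 on its support, which collapses the
    Fisher geometry to a weight-independent form.  Ratios below theta
    raise unless ``phi_floor`` is set.
    """

    theta: float = 10.0
    phi_floor: float = 0.0

    def phi(self, v):
        v = np.asarray(v, dtype=float)
        d = v - self.theta
        return 0.25 * d * d * (d > 0.0)

    def dphi(self, v):
        v = np.asarray(v, dtype=float)
        d = v - self.theta
        return 0.5 * d * (d > 0.0)


@dataclass(frozen=True)
class ShiftedTransfer(TransferFunction):
    """Transfer function with a constant voltage offset: phi(V + shift).

    Models tonic (inhibitory, for negative shift) background input: the
    learning rules and Fisher moments see the weight-driven potential
    ``w . x_eps`` while the firing rate is read out at the shifted value.
    """

    base: TransferFunction = None  # type: ignore[assignment]
    shift: float = 0.0

    @property
    def phi_floor(self):  # type: ignore[override]
        return self.base.phi_floor

    def phi(self, v):
        return self.base.phi(np.asarray(v, dtype=float) + self.shift)

    def dphi(self, v):
        return self.base.dphi(np.asarray(v, dtype=float) + self.shift)


DEFAULT_TRANSFER = SigmoidTransfer()


def membrane_potential(weights, usp, baseline_shift: float = 0.0):
    """Somatic potential above rest: V = w . x_eps + baseline_shift.

    `weights` has shape (n,) or (replicas, n); `usp` shape (n,) or
    (..., n).  A constant negative `baseline_shift` models tonic
    inhibition.
    """
    weights = np.asarray(weights, dtype=float)
    usp = np.asarray(usp, dtype=float)
    return np.sum(weights * usp, axis=-1) + baseline_shift
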