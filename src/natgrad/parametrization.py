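"""Component-wise weight parametrizations.

A parametrization is a smooth, strictly monotone per-synapse map ``f``
between a chosen weight coordinate ``w`` (e.g. the dendritic PSP
amplitude) and the somatic PSP amplitude ``w_s = f(w)``.  Passive
dendritic attenuation is the canonical example: ``f(w) = alpha(d) w``
with either an exponential length-constant profile or a linear
inverse-distance profile.
"""

from __future__ import annotations

from typing import Callable

import numpy as np

__all__ = ["Parametrization", "identity", "exponential_attenuation", "reciprocal_attenuation"]


class Parametrization:
    """Per-synapse coordinate change with derivative and inverse."""

    def __init__(
        self,
        f: Callable[[np.ndarray], np.ndarray],
        fprime: Callable[[np.ndarray], np.ndarray],
        inverse: Callable[[np.ndarray], np.ndarray] | None = None,
        name: str = "custom",
        linear_alpha=None,
    ):
        self._f = f
        self._fp = fprime
        self._inv = inverse
        self.name = name
        #: attenuation factors if the map is linear (f = alpha * w); lets
        #: the compiled learning engine take its fast path
        self.linear_alpha = None if linear_alpha is None else np.asarray(linear_alpha, dtype=float)

    def f(self, w):
        """Somatic amplitude for coordinate w (component-wise)."""
        return self._f(np.asarray(w, dtype=float))

    def fprime(self, w):
        """Derivative f'(w); must be finite and positive on the working range."""
        fp = np.asarray(self._fp(np.asarray(w, dtype=float)), dtype=float)
        if np.any(fp == 0.0) or not np.all(np.isfinite(fp)):
            raise ValueError("parametrization derivative must be finite and non-zero")
        return fp

    def from_somatic(self, ws):
        """Coordinate value whose somatic image is ws."""
        if self._inv is None:
            raise NotImplementedError(f"no inverse registered for parametrization {self.name!r}")
        return self._inv(np.asarray(ws, dtype=float))

    def compose(self, other: "Parametrization") -> "Parametrization":
        """self after other: w -> self.f(other.f(w)) (chain rule derivative)."""
        return Parametrization(
            f=lambda w: self.f(other.f(w)),
            fprime=lambda w: self.fprime(other.f(w)) * other.fprime(w),
            inverse=(
                None
                if (self._inv is None or other._inv is None)
                else lambda ws: other.from_somatic(self.from_somatic(ws))
            ),
            name=f"{self.name}∘{other.name}",
        )


def identity() -> Parametrization:
    """Somatic coordinates: f = id."""
    return Parametrization(
        f=lambda w: w,
        fprime=np.ones_like,
        inverse=lambda ws: ws,
        name="identity",
        linear_alpha=1.0,
    )


def _linear(alpha: np.ndarray, name: str) -> Parametrization:
    alpha = np.asarray(alpha, dtype=float)
    if np.any(alpha <= 0.0):
        raise ValueError("attenuation factors must be positive")
    return Parametrization(
        f=lambda w: alpha * w,
        fprime=lambda w: np.broadcast_to(alpha, np.shape(w)).copy(),
        inverse=lambda ws: ws / alpha,
        name=name,
        linear_alpha=alpha,
    )


def exponential_attenuation(distances_um, lambda_um: float) -> Parametrization:
    """Passive cable attenuation alpha(d) = exp(-d / lambda).

    `lambda_um` is the electrotonic length constant; distances in the
    same unit (conventionally micrometres).
    """
    if lambda_um <= 0:
        raise ValueError("length constant must be positive")
    alpha = np.exp(-np.asarray(distances_um, dtype=float) / lambda_um)
    return _linear(alpha, name="exp_attenuation")


def reciprocal_attenuation(distances_um, d0_um: float = 1.0) -> Parametrization:
    """Linear inverse-distance attenuation alpha(d) = d0 / max(d, d0).

    Equals 1 within `d0_um` of the soma and decays like 1/d beyond it.
    """
    if d0_um <= 0:
        raise ValueError("reference distance must be positive")
    d = np.asarray(distances_um, dtype=float)
    alpha = d0_um / np.maximum(d, d0_um)
    return _linear(alpha, name="reciprocal_attenuation")
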