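"""Spike trains: generation, binning, USP filtering and text I/O.

Spike trains live on a regular grid with step ``dt`` (default 0.5 ms =
5e-4 s; all times in seconds);
at most one spike per bin per train (Bernoulli approximation of the
Poisson process).  USP traces are computed with exact per-bin
exponential state updates of the two kernel branches, so the trace
equals the spike-train/kernel convolution at grid points up to the
binning of spike times.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .neuron import AfferentConfig, SynapticKernel, TransferFunction

__all__ = [
    "SpikeTrain",
    "generate_poisson_train",
    "generate_poisson_matrix",
    "sample_output_spikes",
    "filter_spikes",
    "filter_spike_matrix",
    "UspFilter",
    "sample_stationary_usps",
    "write_spike_trains",
    "read_spike_trains",
    "DEFAULT_DT",
]

#: default forward-Euler time step in seconds (0.5 ms)
DEFAULT_DT = 5e-4


@dataclass(frozen=True)
class SpikeTrain:
    """Event times (seconds, sorted ascending) within [0, duration]."""

    times: np.ndarray
    duration: float

    def __post_init__(self) -> None:
        times = np.atleast_1d(np.asarray(self.times, dtype=float))
        if times.size and (not np.all(np.isfinite(times))):
            raise ValueError("spike times must be finite")
        times = np.sort(times)
        if times.size and (times[0] < 0.0 or times[-1] > self.duration):
            raise ValueError("spike times must lie in [0, duration]")
        object.__setattr__(self, "times", times)

    def __len__(self) -> int:
        return int(self.times.size)

    def to_counts(self, dt: float, n_bins: int | None = None) -> np.ndarray:
        """Bin the train to the grid; bin k covers [k*dt, (k+1)*dt)."""
        if n_bins is None:
            n_bins = int(round(self.duration / dt))
        idx = np.minimum((self.times / dt).astype(int), n_bins - 1)
        counts = np.zeros(n_bins)
        np.add.at(counts, idx, 1.0)
        return counts

    @classmethod
    def from_counts(cls, counts: np.ndarray, dt: float) -> "SpikeTrain":
        counts = np.asarray(counts)
        idx = np.nonzero(counts)[0]
        times = np.repeat(idx * dt, counts[idx].astype(int))
        return cls(times=times, duration=len(counts) * dt)


def generate_poisson_train(
    rate: float, duration: float, dt: float, rng: np.random.Generator
) -> SpikeTrain:
    """Bernoulli-per-bin approximation of a homogeneous Poisson process."""
    if rate < 0:
        raise ValueError("rate must be non-negative")
    p = rate * dt
    if p >= 1.0:
        raise ValueError(f"rate*dt = {p} >= 1; choose a finer time step")
    n_bins = int(round(duration / dt))
    hits = rng.random(n_bins) < p
    return SpikeTrain(times=np.nonzero(hits)[0] * dt, duration=duration)


def generate_poisson_matrix(
    rates: np.ndarray, n_bins: int, dt: float, rng: np.random.Generator
) -> np.ndarray:
    """Spike-count matrix (n_afferents, n_bins) of independent Poisson trains."""
    rates = np.atleast_1d(np.asarray(rates, dtype=float))
    p = rates * dt
    if np.any(p >= 1.0):
        raise ValueError("rate*dt >= 1 for some afferent; choose a finer time step")
    return (rng.random((rates.size, n_bins)) < p[:, None]).astype(float)


def sample_output_spikes(
    v_trace: np.ndarray,
    tf: TransferFunction,
    dt: float,
    rng: np.random.Generator,
) -> SpikeTrain:
    """Draw output spikes per bin with probability phi(V_t)*dt."""
    v_trace = np.asarray(v_trace, dtype=float)
    p = tf.phi(v_trace) * dt
    if np.any(p >= 1.0):
        raise ValueError("phi(V)*dt >= 1 in some bin; time step too coarse")
    if np.any(p > 0.5):
        warnings.warn("phi(V)*dt > 0.5; Bernoulli approximation is getting coarse")
    hits = rng.random(p.shape) < p
    return SpikeTrain(times=np.nonzero(hits)[0] * dt, duration=len(v_trace) * dt)


def _branch_decays(kernel: SynapticKernel, dt: float) -> tuple[float, float, float]:
    em = np.exp(-dt / kernel.tau_m)
    es = np.exp(-dt / kernel.tau_s)
    scale = kernel.epsilon0 / (kernel.tau_m - kernel.tau_s)
    return em, es, scale


def filter_spikes(
    train: SpikeTrain, kernel: SynapticKernel, dt: float, duration: float | None = None
) -> np.ndarray:
    """USP trace (mV per unit weight) of one spike train on the grid.

    Exact at grid points: trace[k] = sum_f epsilon(k*dt - t_f) with spike
    times binned to the grid.
    """
    if duration is None:
        duration = train.duration
    counts = train.to_counts(dt, n_bins=int(round(duration / dt)))
    return filter_spike_matrix(counts[None, :], kernel, dt)[0]


def filter_spike_matrix(
    counts: np.ndarray, kernel: SynapticKernel, dt: float, state: "UspFilter | None" = None
) -> np.ndarray:
    """Filter a (..., n_bins) spike-count array into USP traces."""
    if state is None:
        state = UspFilter(kernel, dt, batch_shape=np.asarray(counts).shape[:-1])
    return state.filter(counts)


class UspFilter:
    """Streaming double-exponential filter with carried state.

    Allows long simulations to be processed in time chunks while keeping
    the USP traces exactly continuous across chunk boundaries.
    """

    def __init__(
        self, kernel: SynapticKernel, dt: float, batch_shape: tuple = (), dtype=np.float64
    ):
        self.kernel = kernel
        self.dt = dt
        self.dtype = np.dtype(dtype)
        self._em, self._es, self._scale = _branch_decays(kernel, dt)
        self._b = np.ones(1, dtype=self.dtype)
        self._am = np.array([1.0, -self._em], dtype=self.dtype)
        self._as = np.array([1.0, -self._es], dtype=self.dtype)
        self._zi_m = np.zeros(batch_shape + (1,), dtype=self.dtype)
        self._zi_s = np.zeros(batch_shape + (1,), dtype=self.dtype)

    def filter(self, counts: np.ndarray) -> np.ndarray:
        counts = np.asarray(counts, dtype=self.dtype)
        a_m, self._zi_m = lfilter(self._b, self._am, counts, axis=-1, zi=self._zi_m)
        a_s, self._zi_s = lfilter(self._b, self._as, counts, axis=-1, zi=self._zi_s)
        return self.dtype.type(self._scale) * (a_m - a_s)


def sample_stationary_usps(
    afferents: AfferentConfig,
    n_samples: int,
    dt: float,
    rng: np.random.Generator,
    spacing_bins: int = 1,
    burn_in: float | None = None,
    chunk_bins: int = 200_000,
) -> np.ndarray:
    """Sample USP vectors from the stationary filtered-Poisson process.

    Simulates Poisson input and returns the USP state at every
    ``spacing_bins``-th grid point after a burn-in of several membrane
    time constants; consecutive samples are correlated on the kernel
    time scale unless ``spacing_bins`` exceeds it.

    Returns an array of shape (n_samples, n).
    """
    kernel = afferents.kernel
    if burn_in is None:
        burn_in = 15.0 * kernel.tau_m
    burn_bins = int(round(burn_in / dt))
    total_bins = burn_bins + n_samples * spacing_bins
    filt = UspFilter(kernel, dt, batch_shape=(afferents.n,))
    out = np.empty((n_samples, afferents.n))
    written = 0
    offset = 0  # bins consumed so far
    while offset < total_bins:
        nb = min(chunk_bins, total_bins - offset)
        counts = generate_poisson_matrix(afferents.rates, nb, dt, rng)
        trace = filt.filter(counts)  # (n, nb)
        # absolute bin indices offset..offset+nb-1; samples sit at
        # burn_bins + spacing-1 + k*spacing (the end of each spacing block)
        first = burn_bins + spacing_bins - 1
        idx = np.arange(offset, offset + nb)
        take = idx[(idx >= first) & ((idx - first) % spacing_bins == 0)]
        if take.size:
            out[written : written + take.size] = trace[:, take - offset].T
            written += take.size
        offset += nb
    assert written == n_samples
    return out


def write_spike_trains(trains: dict[int, SpikeTrain], path) -> None:
    """Write spike trains as two-column delimited text (afferent_id, time_ms)."""
    ids, times = [], []
    for aff_id, train in trains.items():
        ids.extend([aff_id] * len(train))
        times.extend((train.times * 1e3).tolist())
    pd.DataFrame({"afferent_id": ids, "time_ms": times}).to_csv(
        path, sep="\t", index=False, float_format="%.17g"
    )


def read_spike_trains(path, duration: float) -> dict[int, SpikeTrain]:
    """Inverse of :func:`write_spike_trains`; `duration` in seconds."""
    df = pd.read_csv(path, sep="\t")
    if list(df.columns) != ["afferent_id", "time_ms"]:
        raise ValueError(f"expected columns (afferent_id, time_ms), got {list(df.columns)}")
    return {
        int(aff_id): SpikeTrain(times=group["time_ms"].to_numpy() / 1e3, duration=duration)
        for aff_id, group in df.groupby("afferent_id")
    }
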