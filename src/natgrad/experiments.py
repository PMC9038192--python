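"""Simulation protocols: teacher-student learning, democratic plasticity,
variance scaling, homo-/heterosynaptic regimes, coefficient sampling and
update-angle comparisons.

Every experiment takes a master seed and derives named substreams, so a
full run is reproducible and rule comparisons share their input
realizations.  Results come back as plain dataclasses / DataFrames that
the CLI writes as delimited text.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .fisher import coefficients_for, fisher_matrix, voltage_statistics
from .neuron import (
    AfferentConfig,
    ShiftedTransfer,
    SigmoidTransfer,
    SynapticKernel,
    TransferFunction,
)
from .parametrization import exponential_attenuation, reciprocal_attenuation
from .rules import run_online
from .spikes import (
    DEFAULT_DT,
    SpikeTrain,
    UspFilter,
    generate_poisson_train,
    sample_stationary_usps,
)
from .utils import substream

__all__ = [
    "TABLE1_RATES",
    "TaskConfig",
    "LearningCurve",
    "PlasticityGrid",
    "CoefficientSamples",
    "make_afferents",
    "sample_usp_test_set",
    "estimate_dkl",
    "output_rate_rmse",
    "run_teacher_student",
    "gradient_vector_field",
    "democratic_plasticity",
    "variance_dependence",
    "homo_hetero_grid",
    "sample_coefficients",
    "compare_update_angles",
    "learning_rate_robustness",
]

#: tuned learning rates per input pattern (Hz, Hz) -> {rule: eta}
TABLE1_RATES: dict[tuple[float, float], dict[str, float]] = {
    (10.0, 30.0): {"natural": 6.55e-4, "approx": 5.5e-4, "euclidean": 1.10e-6},
    (10.0, 50.0): {"natural": 6.00e-4, "approx": 4.5e-4, "euclidean": 4.50e-7},
    (20.0, 20.0): {"natural": 6.50e-4, "approx": 5.3e-4, "euclidean": 1.18e-6},
    (20.0, 40.0): {"natural": 5.80e-4, "approx": 4.5e-4, "euclidean": 5.50e-7},
}


@dataclass
class TaskConfig:
    """Two-rate-group supervised learning task with a realizable teacher.

    Defaults follow the standard protocol: n = 100 afferents, half at
    10 Hz and half at 50 Hz; initial and target weights uniform on
    (-1/n, 1/n); dt = 0.5 ms; sigmoidal transfer.  `eta = None` looks
    the rate up in :data:`TABLE1_RATES` for the given rule and pattern.
    """

    n: int = 100
    rate_low: float = 10.0
    rate_high: float = 50.0
    rule: str = "natural"
    eta: float | None = None
    dt: float = DEFAULT_DT
    duration: float = 4000.0
    n_trials: int = 20
    record_every: float = 50.0
    seed: int = 0
    kernel: SynapticKernel = field(default_factory=SynapticKernel)
    tf: TransferFunction = field(default_factory=SigmoidTransfer)
    weight_scale: float = 1.0  # weights drawn from weight_scale * U(-1/n, 1/n)
    test_set_size: int = 50
    test_train_duration: float = 0.25
    cu: float = 0.95
    cw: float = 0.05
    refresh_every: int = 1
    #: if set, stop once the trial-mean RMSE improves by less than this
    #: relative fraction per plateau window; `duration` becomes the cap
    plateau_rtol: float | None = None
    plateau_window: float = 1000.0

    def resolved_eta(self) -> float:
        if self.eta is not None:
            return self.eta
        key = (self.rate_low, self.rate_high)
        try:
            return TABLE1_RATES[key][self.rule]
        except KeyError as exc:
            raise ValueError(
                f"no tuned learning rate for pattern {key} and rule {self.rule!r}; "
                "set eta explicitly"
            ) from exc


@dataclass
class LearningCurve:
    """Per-trial and trial-averaged learning trajectories."""

    times: np.ndarray  # (T,)
    dkl: np.ndarray  # (T, R) per-bin KL divergence on the test set
    rmse: np.ndarray  # (T, R) output-rate RMSE (Hz)
    weight_distance: np.ndarray  # (T, R) ||w - w*||
    diverged: np.ndarray  # (R,)
    w_final: np.ndarray  # (R, n)
    w_star: np.ndarray  # (R, n)
    w_init: np.ndarray  # (R, n)

    @property
    def mean_dkl(self) -> np.ndarray:
        return self.dkl.mean(axis=1)

    @property
    def mean_rmse(self) -> np.ndarray:
        return self.rmse.mean(axis=1)

    def to_frame(self) -> pd.DataFrame:
        recs = []
        for j in range(self.dkl.shape[1]):
            for i, t in enumerate(self.times):
                recs.append(
                    {
                        "time_s": t,
                        "trial": j,
                        "dkl": self.dkl[i, j],
                        "rmse_hz": self.rmse[i, j],
                        "weight_distance": self.weight_distance[i, j],
                    }
                )
        return pd.DataFrame.from_records(recs)


@dataclass
class PlasticityGrid:
    """Weight changes on a grid of initial stimulated/unstimulated weights."""

    w_stim_axis: np.ndarray
    w_unstim_axis: np.ndarray
    dw_stim: np.ndarray  # (n_stim_axis, n_unstim_axis)
    dw_unstim: np.ndarray
    labels: np.ndarray  # regime codes 'O1', 'O2', 'S' (or 'P' for joint potentiation)


@dataclass
class CoefficientSamples:
    """Sampled inverse-coefficient statistics across input conditions."""

    by_rate: pd.DataFrame  # g1..g4 vs afferent rate
    by_n: pd.DataFrame  # g1..g4 vs afferent count
    gammas: pd.DataFrame  # gamma_u vs its surrogate s, gamma_w vs g4*V / cw*V


def make_afferents(
    n: int, rate_low: float, rate_high: float, kernel: SynapticKernel | None = None
) -> AfferentConfig:
    """Two equal groups of afferents firing at `rate_low` / `rate_high` Hz."""
    if n % 2:
        raise ValueError("n must be even for the two-group task")
    rates = np.r_[np.full(n // 2, float(rate_low)), np.full(n // 2, float(rate_high))]
    return AfferentConfig(rates=rates, kernel=kernel or SynapticKernel())


def generate_scenario(
    config: TaskConfig, duration: float, rng: np.random.Generator
) -> tuple[dict[int, SpikeTrain], np.ndarray, np.ndarray]:
    """Seeded task instance: afferent spike trains, initial and target weights.

    Weight components are uniform on weight_scale * (-1/n, 1/n); spike
    trains are Bernoulli-binned homogeneous Poisson processes.
    """
    aff = make_afferents(config.n, config.rate_low, config.rate_high, config.kernel)
    n = config.n
    w0 = config.weight_scale * rng.uniform(-1.0 / n, 1.0 / n, n)
    w_star = config.weight_scale * rng.uniform(-1.0 / n, 1.0 / n, n)
    trains = {
        i: generate_poisson_train(aff.rates[i], duration, config.dt, rng) for i in range(n)
    }
    return trains, w0, w_star


def sample_usp_test_set(
    afferents: AfferentConfig,
    n_draws: int,
    dt: float,
    rng: np.random.Generator,
    train_duration: float = 0.25,
) -> np.ndarray:
    """USP vectors at the end of `n_draws` independent input spike trains.

    250 ms of spiking (the default) is ~25 membrane time constants, so
    the returned vectors are draws from the stationary USP distribution.
    """
    n_bins = int(round(train_duration / dt))
    n = afferents.n
    counts = (
        rng.random((n_draws, n, n_bins)) < (afferents.rates * dt)[None, :, None]
    ).astype(float)
    filt = UspFilter(afferents.kernel, dt, batch_shape=(n_draws, n))
    return filt.filter(counts)[:, :, -1]


def estimate_dkl(w_student, w_teacher, usp_test, tf: TransferFunction, dt: float):
    """Per-bin Bernoulli KL divergence D(p* || p_w), averaged over USPs.

    ``p* = phi(w* . x) dt`` and ``p = phi(w . x) dt`` per test USP x;
    the expectation over output spikes is the exact two-outcome sum.
    Supports batched weights of shape (..., n).
    """
    x = np.atleast_2d(np.asarray(usp_test, dtype=float))  # (S, n)
    p = tf.phi(np.einsum("sn,...n->...s", x, np.asarray(w_student, dtype=float))) * dt
    p_star = tf.phi(np.einsum("sn,...n->...s", x, np.asarray(w_teacher, dtype=float))) * dt
    if np.any(p <= 0) or np.any(p >= 1) or np.any(p_star <= 0) or np.any(p_star >= 1):
        raise ValueError("phi*dt outside (0, 1); invalid configuration for the DKL")
    dkl = p_star * np.log(p_star / p) + (1.0 - p_star) * np.log((1.0 - p_star) / (1.0 - p))
    return dkl.mean(axis=-1)


def output_rate_rmse(w_student, w_teacher, usp_test, tf: TransferFunction):
    """RMSE between student and teacher instantaneous output rates (Hz)."""
    x = np.atleast_2d(np.asarray(usp_test, dtype=float))
    f_s = tf.phi(np.einsum("sn,...n->...s", x, np.asarray(w_student, dtype=float)))
    f_t = tf.phi(np.einsum("sn,...n->...s", x, np.asarray(w_teacher, dtype=float)))
    return np.sqrt(np.mean((f_s - f_t) ** 2, axis=-1))


def run_teacher_student(config: TaskConfig) -> LearningCurve:
    """Run the supervised task for `config.n_trials` seeded trials.

    Trials are batched through the online learner; each trial has its
    own input realization, teacher spikes, initial/target weights and
    USP test set (drawn from independent named substreams of the master
    seed, so switching the rule leaves the task instance unchanged).
    With `plateau_rtol` set, learning proceeds in `plateau_window`
    segments and stops once the trial-mean output-rate RMSE improves by
    less than that fraction per window (or `duration` is reached).
    """
    aff = make_afferents(config.n, config.rate_low, config.rate_high, config.kernel)
    n, R = config.n, config.n_trials
    scen = substream(config.seed, "scenario")
    w0 = config.weight_scale * scen.uniform(-1.0 / n, 1.0 / n, (R, n))
    w_star = config.weight_scale * scen.uniform(-1.0 / n, 1.0 / n, (R, n))

    test_rng = substream(config.seed, "test-set")
    xt = np.stack(
        [
            sample_usp_test_set(
                aff, config.test_set_size, config.dt, test_rng, config.test_train_duration
            )
            for _ in range(R)
        ]
    )  # (R, S, n): per-trial test set, as in the protocol

    input_rng = substream(config.seed, "input")
    teacher_rng = substream(config.seed, "teacher")
    window = config.duration if config.plateau_rtol is None else config.plateau_window
    w_cur = w0
    elapsed = 0.0
    snapshots, times, diverged = [], [], None
    prev_rmse = None
    while elapsed < config.duration - 1e-9:
        seg = min(window, config.duration - elapsed)
        res = run_online(
            config.rule,
            w_cur,
            aff,
            config.tf,
            None,
            config.resolved_eta(),
            config.dt,
            seg,
            input_rng=input_rng,
            teacher_rng=teacher_rng,
            w_star=w_star,
            record_every=config.record_every,
            cu=config.cu,
            cw=config.cw,
            refresh_every=config.refresh_every,
        )
        snapshots.append(res.snapshots)
        times.append(res.snapshot_times + elapsed)
        w_cur = res.w
        diverged = res.diverged
        elapsed += seg
        if config.plateau_rtol is not None:
            cur_rmse = float(
                np.mean(
                    [
                        output_rate_rmse(w_cur[j], w_star[j], xt[j], config.tf)
                        for j in range(R)
                    ]
                )
            )
            if prev_rmse is not None and cur_rmse > (1.0 - config.plateau_rtol) * prev_rmse:
                break
            prev_rmse = cur_rmse

    snaps = np.concatenate(snapshots, axis=0)
    times = np.concatenate(times)
    T = len(times)
    dkl = np.empty((T, R))
    rmse = np.empty((T, R))
    wdist = np.empty((T, R))
    for j in range(R):
        traj = snaps[:, j, :]  # (T, n)
        dkl[:, j] = estimate_dkl(traj, w_star[j], xt[j], config.tf, config.dt)
        rmse[:, j] = output_rate_rmse(traj, w_star[j], xt[j], config.tf)
        wdist[:, j] = np.linalg.norm(traj - w_star[j], axis=-1)
    return LearningCurve(
        times=times,
        dkl=dkl,
        rmse=rmse,
        weight_distance=wdist,
        diverged=diverged,
        w_final=w_cur,
        w_star=w_star,
        w_init=w0,
    )


def gradient_vector_field(
    w_points,
    w_star,
    afferents: AfferentConfig,
    tf: TransferFunction,
    rng: np.random.Generator,
    n_usp_samples: int = 2000,
    dt: float = DEFAULT_DT,
) -> pd.DataFrame:
    """Expected negative Euclidean and natural gradient directions.

    At each weight point the teacher expectation is taken analytically
    (E[Y*] = phi(V*)), and the USP expectation by Monte Carlo over
    stationary samples.  Returns unit vectors and their angles to the
    direction pointing at the target weights.
    """
    x = sample_stationary_usps(afferents, n_usp_samples, dt, rng, spacing_bins=40)
    w_star = np.asarray(w_star, dtype=float)
    phi_star = tf.phi(x @ w_star)
    rows = []
    for w in np.atleast_2d(np.asarray(w_points, dtype=float)):
        v = x @ w
        err = (phi_star - tf.phi(v)) * tf.slope_ratio(v)  # (S,)
        g_euc = (err[:, None] * x).mean(axis=0)
        coeffs = coefficients_for(w, afferents, tf)
        ce = afferents.kernel.c_epsilon
        e0 = afferents.kernel.epsilon0
        sx = x.sum(axis=1)
        gamma_u = -ce * e0 * (coeffs.g1 * ce * e0 * sx + coeffs.g3 * v)
        gamma_w = coeffs.g2 * ce * e0 * sx + coeffs.g4 * v
        hom = ce * x / afferents.rates
        bracket = hom - gamma_u[:, None] + gamma_w[:, None] * w
        g_nat = coeffs.gamma_s * (err[:, None] * bracket).mean(axis=0)

        to_target = w_star - w

        def angle(u, ref):
            c = u @ ref / (np.linalg.norm(u) * np.linalg.norm(ref))
            return np.degrees(np.arccos(np.clip(c, -1.0, 1.0)))

        rows.append(
            {
                "w1": w[0],
                "w2": w[-1],
                "euc_angle_to_target": angle(g_euc, to_target),
                "nat_angle_to_target": angle(g_nat, to_target),
                **{f"euc_{i}": c for i, c in enumerate(g_euc / np.linalg.norm(g_euc))},
                **{f"nat_{i}": c for i, c in enumerate(g_nat / np.linalg.norm(g_nat))},
            }
        )
    return pd.DataFrame.from_records(rows)


def democratic_plasticity(
    distances_um,
    seed: int,
    attenuation: str = "reciprocal",
    lambda_um: float = 200.0,
    input_rate: float = 5.0,
    teacher_rate: float = 20.0,
    duration: float = 5.0,
    w_somatic0: float = 0.05,
    eta: float = 6e-4,
    dt: float = DEFAULT_DT,
    kernel: SynapticKernel | None = None,
    tf: TransferFunction | None = None,
) -> pd.DataFrame:
    """Single stimulated synapse at varying dendritic distance.

    Dendritic initial weights are pre-scaled by 1/alpha(d) so every
    synapse starts with the same somatic amplitude; all distances see
    the same input and teacher spike realization.  Democratic
    plasticity predicts identical somatic-amplitude changes while the
    dendritic change grows like 1/alpha(d).
    """
    distances = np.asarray(distances_um, dtype=float)
    R = distances.size
    if attenuation == "reciprocal":
        par = reciprocal_attenuation(distances[:, None])
    elif attenuation == "exponential":
        par = exponential_attenuation(distances[:, None], lambda_um)
    else:
        raise ValueError(f"unknown attenuation variant {attenuation!r}")
    alpha = par.linear_alpha[:, 0]
    kernel = kernel or SynapticKernel()
    tf = tf or SigmoidTransfer()
    aff = AfferentConfig(rates=np.array([input_rate]), kernel=kernel)
    w0 = (w_somatic0 / alpha)[:, None]  # (R, 1) dendritic coordinates

    res = run_online(
        "natural",
        w0,
        aff,
        tf,
        par,
        eta,
        dt,
        duration,
        input_rng=substream(seed, "democratic-input"),
        teacher_rng=substream(seed, "democratic-teacher"),
        teacher_rate=teacher_rate,
        shared_input=True,
        shared_teacher=True,
    )
    w_end = res.w[:, 0]
    dw_dend = w_end - w0[:, 0]
    dw_soma = alpha * w_end - w_somatic0
    return pd.DataFrame(
        {
            "distance_um": distances,
            "alpha": alpha,
            "w_dend_init": w0[:, 0],
            "w_dend_final": w_end,
            "dw_dendritic": dw_dend,
            "dw_dendritic_rel": dw_dend / w0[:, 0],
            "dw_somatic": dw_soma,
        }
    )


def variance_dependence(
    seed: int,
    tau_s_values_ms=np.linspace(1.0, 20.0, 8),
    rate_values=np.linspace(10.0, 50.0, 8),
    base_rate: float = 10.0,
    base_tau_s_ms: float = 20.0,
    teacher_rate: float = 80.0,
    duration: float = 5.0,
    w0: float = 0.05,
    eta: float = 6e-4,
    dt: float = DEFAULT_DT,
    n_repeats: int = 10,
    tau_m_ms: float = 10.0,
    mean_usp_mv: float = 10.0,
) -> pd.DataFrame:
    """Weight change of a single synapse versus USP variance.

    Conditions vary either the synaptic time constant (at fixed rate) or
    the input rate (at fixed tau_s).  The kernel scale is renormalized
    proportionally to the rate so the mean USP stays at `mean_usp_mv`,
    isolating the variance dependence.
    """
    conds = [(base_rate, ts) for ts in np.asarray(tau_s_values_ms, dtype=float)]
    conds += [(rv, base_tau_s_ms) for rv in np.asarray(rate_values, dtype=float)]
    tf = SigmoidTransfer()
    rows = []
    for idx, (rate, tau_s_ms) in enumerate(conds):
        kernel = SynapticKernel(
            epsilon0=mean_usp_mv / rate, tau_m=tau_m_ms / 1e3, tau_s=tau_s_ms / 1e3
        )
        aff = AfferentConfig(rates=np.array([rate]), kernel=kernel)
        res = run_online(
            "natural",
            np.full((n_repeats, 1), w0),
            aff,
            tf,
            None,
            eta,
            dt,
            duration,
            input_rng=substream(seed, "variance-input", str(idx)),
            teacher_rng=substream(seed, "variance-teacher", str(idx)),
            teacher_rate=teacher_rate,
        )
        dw = res.w[:, 0] - w0
        rows.append(
            {
                "rate_hz": rate,
                "tau_s_ms": tau_s_ms,
                "usp_var": rate / kernel.c_epsilon,
                "hom_scale": kernel.c_epsilon / rate,
                "dw_mean": dw.mean(),
                "dw_sem": dw.std(ddof=1) / np.sqrt(n_repeats),
            }
        )
    return pd.DataFrame.from_records(rows)


def homo_hetero_grid(
    seed: int,
    n_axis: int = 10,
    n_synapses: int = 10,
    n_stimulated: int = 5,
    input_rate: float = 5.0,
    teacher_rate: float = 20.0,
    duration: float = 60.0,
    eta: float = 0.01,
    baseline_shift: float = -5.0,
    dt: float = DEFAULT_DT,
    refresh_every: int = 10,
) -> PlasticityGrid:
    """Homosynaptic vs heterosynaptic plasticity over initial weights.

    Half the synapses are driven at `input_rate`, the rest are silent;
    tonic inhibition shifts the operating point by `baseline_shift` mV.
    Initial weights within each group are equal and swept over
    [1/n, 5/n] x [1/n, 5/n]; all grid cells share one spike/teacher
    realization.  Sign regimes: 'O1' stimulated LTP / unstimulated LTD,
    'O2' the reverse, 'S' joint depression ('P' joint potentiation is
    not expected).
    """
    n = n_synapses
    axis = np.linspace(1.0 / n, 5.0 / n, n_axis)
    ws_grid, wu_grid = np.meshgrid(axis, axis, indexing="ij")
    R = n_axis * n_axis
    w0 = np.empty((R, n))
    w0[:, :n_stimulated] = ws_grid.reshape(-1, 1)
    w0[:, n_stimulated:] = wu_grid.reshape(-1, 1)
    rates = np.r_[np.full(n_stimulated, input_rate), np.zeros(n - n_stimulated)]
    aff = AfferentConfig(rates=rates, kernel=SynapticKernel())
    tf = ShiftedTransfer(base=SigmoidTransfer(), shift=baseline_shift)
    res = run_online(
        "natural",
        w0,
        aff,
        tf,
        None,
        eta,
        dt,
        duration,
        input_rng=substream(seed, "grid-input"),
        teacher_rng=substream(seed, "grid-teacher"),
        teacher_rate=teacher_rate,
        shared_input=True,
        shared_teacher=True,
        refresh_every=refresh_every,
    )
    dw = res.w - w0
    dw_stim = dw[:, :n_stimulated].mean(axis=1).reshape(n_axis, n_axis)
    dw_unstim = dw[:, n_stimulated:].mean(axis=1).reshape(n_axis, n_axis)
    labels = np.where(
        (dw_stim > 0) & (dw_unstim <= 0),
        "O1",
        np.where(
            (dw_stim <= 0) & (dw_unstim > 0),
            "O2",
            np.where((dw_stim <= 0) & (dw_unstim <= 0), "S", "P"),
        ),
    )
    return PlasticityGrid(
        w_stim_axis=axis,
        w_unstim_axis=axis.copy(),
        dw_stim=dw_stim,
        dw_unstim=dw_unstim,
        labels=labels,
    )


def sample_coefficients(
    seed: int,
    rate_values=np.arange(5.0, 56.0, 5.0),
    n_values=(10, 25, 50, 75, 100, 150, 200),
    n_fixed: int = 100,
    rate_fixed: float = 20.0,
    n_weight_draws: int = 20,
    n_usp_draws: int = 20,
    cw: float = 0.05,
    dt: float = DEFAULT_DT,
    kernel: SynapticKernel | None = None,
    tf: TransferFunction | None = None,
) -> CoefficientSamples:
    """Sample g1..g4 and the gamma factors across input conditions.

    Weights are drawn from U(-5/n, 5/n); USP vectors from the
    stationary input distribution.  Also tabulates the surrogate
    quantities: s = c_eps sum(x)/sum(r) for gamma_u, and g4*V / cw*V
    for gamma_w.
    """
    kernel = kernel or SynapticKernel()
    tf = tf or SigmoidTransfer()
    ce, e0 = kernel.c_epsilon, kernel.epsilon0
    rng = substream(seed, "coefficients")

    def draw_block(n, rate, want_gammas):
        aff = AfferentConfig(rates=np.full(n, rate), kernel=kernel)
        w = rng.uniform(-5.0 / n, 5.0 / n, (n_weight_draws, n))
        co = coefficients_for(w, aff, tf)
        stats = voltage_statistics(w, aff)
        block = pd.DataFrame(
            {
                "n": n,
                "rate_hz": rate,
                "draw": np.arange(n_weight_draws),
                "g1": co.g1,
                "g2": co.g2,
                "g3": co.g3,
                "g4": co.g4,
                "gamma_s": co.gamma_s,
                "q": stats.q,
            }
        )
        gam = None
        if want_gammas:
            x = sample_stationary_usps(aff, n_usp_draws, dt, rng, spacing_bins=80)
            sx = x.sum(axis=1)  # (U,)
            v = w @ x.T  # (W, U)
            gamma_u = -ce * e0 * (co.g1[:, None] * ce * e0 * sx[None, :] + co.g3[:, None] * v)
            gamma_w = co.g2[:, None] * ce * e0 * sx[None, :] + co.g4[:, None] * v
            s = ce * sx / np.sum(aff.rates)
            wd, ud = np.meshgrid(np.arange(n_weight_draws), np.arange(n_usp_draws), indexing="ij")
            gam = pd.DataFrame(
                {
                    "n": n,
                    "rate_hz": rate,
                    "weight_draw": wd.ravel(),
                    "usp_draw": ud.ravel(),
                    "gamma_u": gamma_u.ravel(),
                    "s": np.broadcast_to(s[None, :], v.shape).ravel(),
                    "gamma_w": gamma_w.ravel(),
                    "g4_v": (co.g4[:, None] * v).ravel(),
                    "cw_v": (cw * v).ravel(),
                    "v": v.ravel(),
                }
            )
        return block, gam

    by_rate, gammas = [], []
    for rate in np.asarray(rate_values, dtype=float):
        block, gam = draw_block(n_fixed, rate, want_gammas=True)
        by_rate.append(block)
        gammas.append(gam)
    by_n = [draw_block(int(n), rate_fixed, want_gammas=False)[0] for n in n_values]
    return CoefficientSamples(
        by_rate=pd.concat(by_rate, ignore_index=True),
        by_n=pd.concat(by_n, ignore_index=True),
        gammas=pd.concat(gammas, ignore_index=True),
    )


def _angle_deg(u, v, metric=None):
    if metric is None:
        num = np.sum(u * v, axis=-1)
        den = np.linalg.norm(u, axis=-1) * np.linalg.norm(v, axis=-1)
    else:
        num = np.einsum("...i,ij,...j->...", u, metric, v)
        den = np.sqrt(
            np.einsum("...i,ij,...j->...", u, metric, u)
            * np.einsum("...i,ij,...j->...", v, metric, v)
        )
    return np.degrees(np.arccos(np.clip(num / den, -1.0, 1.0)))


def compare_update_angles(
    seed: int,
    patterns=((10.0, 10.0), (10.0, 30.0), (10.0, 50.0), (20.0, 20.0), (20.0, 40.0)),
    n: int = 100,
    n_weight_draws: int = 20,
    n_spike_draws: int = 20,
    duration: float = 1.0,
    dt: float = DEFAULT_DT,
    cu: float = 0.95,
    cw: float = 0.05,
    kernel: SynapticKernel | None = None,
) -> pd.DataFrame:
    """Angles between accumulated natural, approximated and Euclidean updates.

    For each input pattern and random initial weight (U(-5/n, 5/n), the
    target fixed at 0.15/n per synapse), the three rules' updates are
    accumulated over `duration` of spiking with the weights held at
    their initial value, and the angles between the resulting update
    vectors are measured both in the Euclidean metric and in the Fisher
    metric G(w) of the initial weights.
    """
    kernel = kernel or SynapticKernel()
    tf = SigmoidTransfer()
    ce, e0 = kernel.c_epsilon, kernel.epsilon0
    rng = substream(seed, "angles")
    n_bins = int(round(duration / dt))
    rows = []
    for rate_low, rate_high in patterns:
        aff = make_afferents(n, rate_low, rate_high, kernel)
        w_star = np.full(n, 0.15 / n)
        for draw in range(n_weight_draws):
            w = rng.uniform(-5.0 / n, 5.0 / n, n)
            coeffs = coefficients_for(w, aff, tf)
            gmat = fisher_matrix(w, aff, tf, coeffs=coeffs)
            S = n_spike_draws
            counts = (
                rng.random((S, n, n_bins), dtype=np.float32)
                < (aff.rates * dt).astype(np.float32)[None, :, None]
            ).astype(np.float32)
            usps = UspFilter(kernel, dt, batch_shape=(S, n)).filter(counts)
            v = np.einsum("n,snb->sb", w, usps)
            v_star = np.einsum("n,snb->sb", w_star, usps)
            y = (rng.random((S, n_bins)) < tf.phi(v_star) * dt).astype(float)
            err = (y / dt - tf.phi(v)) * tf.slope_ratio(v) * dt  # (S, B)

            d_euc = np.einsum("sb,snb->sn", err, usps)
            sx = usps.sum(axis=1)  # (S, B)
            hom = np.einsum("sb,snb->sn", err, usps) * (ce / aff.rates)
            gamma_u = -ce * e0 * (coeffs.g1 * ce * e0 * sx + coeffs.g3 * v)
            gamma_w = coeffs.g2 * ce * e0 * sx + coeffs.g4 * v
            d_nat = coeffs.gamma_s * (
                hom
                - np.einsum("sb,sb->s", err, gamma_u)[:, None]
                + np.einsum("sb,sb->s", err, gamma_w)[:, None] * w
            )
            gamma_w_a = cw * v
            d_app = coeffs.gamma_s * (
                hom
                - (cu * ce) * err.sum(axis=1)[:, None]
                + np.einsum("sb,sb->s", err, gamma_w_a)[:, None] * w
            )
            rows.append(
                {
                    "rate_low": rate_low,
                    "rate_high": rate_high,
                    "weight_draw": draw,
                    "euc_angle_approx_nat": _angle_deg(d_app, d_nat).mean(),
                    "euc_angle_euclid_nat": _angle_deg(d_euc, d_nat).mean(),
                    "fisher_angle_approx_nat": _angle_deg(d_app, d_nat, gmat).mean(),
                    "fisher_angle_euclid_nat": _angle_deg(d_euc, d_nat, gmat).mean(),
                }
            )
    return pd.DataFrame.from_records(rows)


def learning_rate_robustness(
    base_config: TaskConfig,
    scales=(0.5, 0.75, 1.0, 1.5, 2.0),
    threshold: float = 5e-5,
) -> pd.DataFrame:
    """Time until the trial-averaged DKL first drops below `threshold`.

    Runs the task once per learning-rate scale; a run whose mean curve
    never crosses the threshold is flagged (`reached = False`) with the
    time set to NaN, not dropped.
    """
    rows = []
    for scale in scales:
        cfg = replace(base_config, eta=scale * base_config.resolved_eta())
        if scale == 0:
            rows.append(
                {"scale": 0.0, "eta": 0.0, "time_to_threshold_s": np.nan, "reached": False}
            )
            continue
        curve = run_teacher_student(cfg)
        mean_dkl = curve.mean_dkl
        below = np.nonzero(mean_dkl <= threshold)[0]
        reached = below.size > 0
        rows.append(
            {
                "scale": scale,
                "eta": cfg.eta,
                "time_to_threshold_s": curve.times[below[0]] if reached else np.nan,
                "reached": reached,
            }
        )
    return pd.DataFrame.from_records(rows)
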