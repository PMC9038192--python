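"""Synaptic learning rules and the online trainer.

Four rules share the per-bin error factor ``[Y* - phi(V)] phi'/phi``:

* ``euclidean`` — the classical error-correcting (perceptron-like) rule;
  its update in coordinates ``w`` carries a factor ``f'(w)`` and is
  therefore *not* invariant under reparametrization.
* ``natural`` — the Euclidean update premultiplied by the inverse Fisher
  matrix, in closed form: a variance-normalized homosynaptic term
  ``c_eps x_eps / r``, a uniform heterosynaptic term ``-gamma_u`` and a
  weight-proportional heterosynaptic term ``gamma_w f(w)``, all scaled
  by the global factor ``gamma_s`` and ``1/f'(w)``.  Invariant under any
  smooth component-wise parametrization.
* ``approx`` — the natural rule with the synapse-local surrogates
  ``gamma_u -> cu c_eps`` and ``gamma_w -> cw V`` (defaults cu=0.95,
  cw=0.05); ``gamma_s`` is kept exact.
* ``quadratic`` — the simplified closed form valid for a rectified
  quadratic transfer function, where the Fisher matrix loses its weight
  dependence.

Teacher spikes enter as unit impulses: the per-bin teacher signal is
``y/dt`` for a bin containing a spike and 0 otherwise, so the error
factor integrates to ``y - phi dt`` over the bin (forward Euler).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._engine import HAVE_NUMBA, RULE_APPROX, RULE_EUCLIDEAN, RULE_NATURAL, run_chunk_sigmoid
from .fisher import FisherCoefficients, _gh_nodes, coefficients_for
from .neuron import AfferentConfig, ShiftedTransfer, SigmoidTransfer, TransferFunction
from .parametrization import Parametrization, identity
from .spikes import UspFilter, _branch_decays

__all__ = [
    "GammaFactors",
    "WeightUpdate",
    "gamma_factors",
    "euclidean_update",
    "natural_update",
    "approximated_update",
    "quadratic_limit_update",
    "somatic_image",
    "run_online",
    "OnlineResult",
]


@dataclass(frozen=True)
class GammaFactors:
    """The three scaling factors of the natural-gradient rule.

    gamma_s: global output-dependent scaling (1/c1, always > 0)
    gamma_u: uniform heterosynaptic coefficient
    gamma_w: weight-proportional heterosynaptic coefficient
    """

    gamma_s: np.ndarray
    gamma_u: np.ndarray
    gamma_w: np.ndarray


@dataclass(frozen=True)
class WeightUpdate:
    """Per-bin weight change with its plasticity decomposition.

    ``total = common_factor * (hom + het_u + het_w)`` component-wise;
    `common_factor` is the shared prefactor
    ``eta gamma_s [Y* - phi] phi'/phi / f'(w)`` times dt (per synapse,
    since f' is).
    """

    total: np.ndarray
    hom: np.ndarray
    het_u: np.ndarray
    het_w: np.ndarray
    common_factor: np.ndarray


def gamma_factors(
    w_somatic,
    usp,
    coeffs: FisherCoefficients,
    afferents: AfferentConfig,
) -> GammaFactors:
    """Evaluate gamma_s, gamma_u, gamma_w at the current USP vector.

    gamma_u = -c_eps eps0 (g1 c_eps eps0 sum_i x_i + g3 V)
    gamma_w =  g2 c_eps eps0 sum_i x_i + g4 V

    with V = w_somatic . usp (the weight-driven potential, excluding any
    tonic baseline shift).  Broadcasts over leading replica axes.
    """
    w_somatic = np.asarray(w_somatic, dtype=float)
    usp = np.asarray(usp, dtype=float)
    ce = afferents.kernel.c_epsilon
    e0 = afferents.kernel.epsilon0
    sx = np.sum(usp, axis=-1)
    v = np.sum(w_somatic * usp, axis=-1)
    gamma_u = -ce * e0 * (coeffs.g1 * ce * e0 * sx + coeffs.g3 * v)
    gamma_w = coeffs.g2 * ce * e0 * sx + coeffs.g4 * v
    return GammaFactors(gamma_s=coeffs.gamma_s, gamma_u=gamma_u, gamma_w=gamma_w)


def _error_common(teacher_signal, v, tf: TransferFunction, eta: float, dt: float):
    """eta [Y* - phi(V)] phi'/phi dt, the Euclidean part of the prefactor."""
    err = np.asarray(teacher_signal, dtype=float) - tf.phi(v)
    return eta * err * tf.slope_ratio(v) * dt


def euclidean_update(
    teacher_signal,
    v,
    usp,
    tf: TransferFunction,
    eta: float,
    dt: float,
    par: Parametrization | None = None,
    w=None,
) -> WeightUpdate:
    """Euclidean-gradient rule; in coordinates w it picks up a factor f'(w).

    `teacher_signal` is the per-bin spike indicator scaled by 1/dt;
    `v` the membrane potential the transfer function is read out at.
    """
    usp = np.asarray(usp, dtype=float)
    common = np.asarray(_error_common(teacher_signal, v, tf, eta, dt))[..., None]
    if par is not None:
        common = common * par.fprime(w)
    zeros = np.zeros_like(usp)
    return WeightUpdate(
        total=common * usp, hom=usp, het_u=zeros, het_w=zeros, common_factor=common
    )


def _assemble(common, hom, het_u, het_w) -> WeightUpdate:
    hom, het_u, het_w = np.broadcast_arrays(hom, het_u, het_w)
    return WeightUpdate(
        total=common * (hom + het_u + het_w),
        hom=hom,
        het_u=het_u,
        het_w=het_w,
        common_factor=common,
    )


def _hom_term(usp, afferents: AfferentConfig) -> np.ndarray:
    """Variance-normalized homosynaptic drive c_eps x/r; 0 for silent afferents."""
    r = afferents.rates
    ce = afferents.kernel.c_epsilon
    with np.errstate(divide="ignore", invalid="ignore"):
        hom = np.where(r > 0.0, ce * np.asarray(usp, dtype=float) / np.where(r > 0, r, 1.0), 0.0)
    return hom


def natural_update(
    teacher_signal,
    v,
    usp,
    w,
    par: Parametrization,
    gammas: GammaFactors,
    afferents: AfferentConfig,
    tf: TransferFunction,
    eta: float,
    dt: float,
) -> WeightUpdate:
    """Full natural-gradient rule in coordinates w.

    total = eta gamma_s [Y*-phi] phi'/phi (1/f'(w))
            [ c_eps x/r - gamma_u 1 + gamma_w f(w) ]
    """
    usp = np.asarray(usp, dtype=float)
    w = np.asarray(w, dtype=float)
    fp = par.fprime(w)
    base = np.asarray(_error_common(teacher_signal, v, tf, eta, dt) * gammas.gamma_s)
    common = base[..., None] / fp
    hom = _hom_term(usp, afferents)
    het_u = -np.asarray(gammas.gamma_u)[..., None] * np.ones_like(hom)
    het_w = np.asarray(gammas.gamma_w)[..., None] * par.f(w)
    return _assemble(common, hom, het_u, het_w)


def approximated_update(
    teacher_signal,
    v,
    usp,
    w,
    par: Parametrization,
    afferents: AfferentConfig,
    tf: TransferFunction,
    eta: float,
    dt: float,
    cu: float = 0.95,
    cw: float = 0.05,
    coeffs: FisherCoefficients | None = None,
) -> WeightUpdate:
    """Natural rule with synapse-local surrogates for the hetero terms.

    gamma_u -> cu * c_eps and gamma_w -> cw * V; gamma_s stays exact
    (computed from the Fisher coefficients of the current weights).
    """
    usp = np.asarray(usp, dtype=float)
    w = np.asarray(w, dtype=float)
    ws = par.f(w)
    if coeffs is None:
        coeffs = coefficients_for(ws, afferents, tf)
    v_drive = np.sum(ws * usp, axis=-1)
    gammas = GammaFactors(
        gamma_s=coeffs.gamma_s,
        gamma_u=np.broadcast_to(cu * afferents.kernel.c_epsilon, np.shape(v_drive)),
        gamma_w=cw * v_drive,
    )
    return natural_update(teacher_signal, v, usp, w, par, gammas, afferents, tf, eta, dt)


def quadratic_limit_update(
    teacher_signal,
    v,
    usp,
    w,
    par: Parametrization,
    afferents: AfferentConfig,
    tf: TransferFunction,
    eta: float,
    dt: float,
) -> WeightUpdate:
    """Simplified rule for the rectified quadratic transfer function.

    total = eta [Y*-phi] (1/phi') (1/f'(w)) (c_eps x/r - gamma_u 1),
    gamma_u = c_eps^2 eps0^2 sum_i x_i / (q + 1).

    Requires V > theta at evaluated bins (phi' > 0).
    """
    usp = np.asarray(usp, dtype=float)
    w = np.asarray(w, dtype=float)
    ce = afferents.kernel.c_epsilon
    e0 = afferents.kernel.epsilon0
    q = ce * e0**2 * np.sum(afferents.rates)
    dphi = tf.dphi(v)
    if np.any(dphi <= 0):
        raise ValueError("quadratic-limit rule needs V > theta (phi' > 0) at every bin")
    err = np.asarray(teacher_signal, dtype=float) - tf.phi(v)
    common = (eta * err / dphi * dt)[..., None] / par.fprime(w)
    hom = _hom_term(usp, afferents)
    gamma_u = ce**2 * e0**2 * np.sum(usp, axis=-1) / (q + 1.0)
    het_u = -gamma_u[..., None] * np.ones_like(hom)
    return _assemble(common, hom, het_u, np.zeros_like(hom))


def somatic_image(update, par: Parametrization, w) -> np.ndarray:
    """Somatic-coordinate change f'(w) * dw of an update taken in w."""
    dw = update.total if isinstance(update, WeightUpdate) else np.asarray(update, dtype=float)
    return par.fprime(w) * dw


@dataclass
class OnlineResult:
    """Outcome of an online learning run."""

    w: np.ndarray  # final coordinates, (R, n)
    snapshots: np.ndarray | None  # (K, R, n) coordinate snapshots
    snapshot_times: np.ndarray | None  # (K,) seconds
    diverged: np.ndarray | None = None  # (R,) flags for non-finite weights


def run_online(
    rule: str,
    w0,
    afferents: AfferentConfig,
    tf: TransferFunction,
    par: Parametrization | None,
    eta: float,
    dt: float,
    duration: float,
    input_rng: np.random.Generator,
    teacher_rng: np.random.Generator,
    w_star=None,
    teacher_rate: float | None = None,
    shared_input: bool = False,
    refresh_every: int = 1,
    record_every: float | None = None,
    shared_teacher: bool = False,
    cu: float = 0.95,
    cw: float = 0.05,
    n_nodes: int = 200,
    chunk_bins: int = 2000,
) -> OnlineResult:
    """Simulate online learning, vectorized over weight replicas.

    Parameters
    ----------
    rule:
        'natural', 'euclidean', 'approx' or 'quadratic'.
    w0:
        Initial coordinates, shape (R, n) (replicas x afferents) or (n,).
    w_star:
        Somatic teacher weights for a realizable teacher (same shape
        rules as w0); mutually exclusive with `teacher_rate`, a
        constant-rate Poisson teacher in Hz.
    shared_input:
        If True, a single input spike realization drives all replicas
        (used when replicas differ only in their initial weights).
    refresh_every:
        Bins between recomputations of the Fisher coefficients (gamma_s
        and the g-coefficients); the per-bin factors gamma_u/gamma_w are
        always evaluated on the current USP vector.
    record_every:
        Seconds between coordinate snapshots (None: none are taken).

    Notes
    -----
    The per-bin inner loop reimplements the rule formulas above in
    batched form; agreement with the single-step reference functions is
    pinned by tests.
    """
    if rule not in ("natural", "euclidean", "approx", "quadratic"):
        raise ValueError(f"unknown rule {rule!r}")
    if (w_star is None) == (teacher_rate is None):
        raise ValueError("provide exactly one of w_star or teacher_rate")
    if shared_teacher and teacher_rate is None:
        raise ValueError("shared_teacher requires the constant-rate teacher")
    par = par if par is not None else identity()
    w = np.atleast_2d(np.asarray(w0, dtype=float)).copy()
    n_rep, n = w.shape
    r = afferents.rates
    if n != r.size:
        raise ValueError("w0 does not match the number of afferents")
    ce = afferents.kernel.c_epsilon
    e0 = afferents.kernel.epsilon0
    active = r > 0.0
    inv_r = np.zeros(n)
    inv_r[active] = ce / r[active]
    if w_star is not None:
        w_star = np.broadcast_to(np.atleast_2d(np.asarray(w_star, dtype=float)), w.shape)

    n_bins = int(round(duration / dt))
    rec_stride = 0 if record_every is None else max(1, int(round(record_every / dt)))

    # the compiled engine covers sigmoid transfer + linear parametrization
    shift = 0.0
    base_tf = tf
    if isinstance(tf, ShiftedTransfer):
        shift = tf.shift
        base_tf = tf.base
    fast = (
        HAVE_NUMBA
        and rule != "quadratic"
        and par.linear_alpha is not None
        and isinstance(base_tf, SigmoidTransfer)
        and base_tf.phi_floor == 0.0
    )

    in_shape = (1, n) if shared_input else (n_rep, n)
    filt = UspFilter(afferents.kernel, dt, batch_shape=in_shape)
    # spike thresholding happens in float32 (cheap uniforms, identical in
    # both code paths); filter state stays float64
    p_spike = (r * dt).astype(np.float32)[None, :, None]

    def input_chunk(nb):
        u = input_rng.random(in_shape + (nb,), dtype=np.float32)
        return (u < p_spike).astype(np.float64)

    n_teach = 1 if shared_teacher else n_rep

    def teacher_draws(usps, nb):
        if w_star is not None:
            subs = "rn,inb->rb" if in_shape[0] == 1 else "rn,rnb->rb"
            p_star = tf.phi(np.einsum(subs, w_star, usps)) * dt
        else:
            p_star = np.full((n_teach, nb), teacher_rate * dt)
        return (teacher_rng.random((n_teach, nb)) < p_star).astype(float)

    if fast:
        alpha = np.ascontiguousarray(
            np.broadcast_to(par.linear_alpha, (n_rep, n)), dtype=float
        )
        gh_x, gh_w = _gh_nodes(n_nodes)
        gcoef = np.zeros((n_rep, 5))
        n_snaps = 0 if rec_stride == 0 else n_bins // rec_stride
        snap_buf = np.zeros((max(n_snaps, 1), n_rep, n))
        snap_count = np.zeros(1, dtype=np.int64)
        rule_id = {
            "euclidean": RULE_EUCLIDEAN,
            "natural": RULE_NATURAL,
            "approx": RULE_APPROX,
        }[rule]
        em, es, scale = _branch_decays(afferents.kernel, dt)
        state_m = np.zeros(in_shape)
        state_s = np.zeros(in_shape)
        x_buf = np.zeros(in_shape)
        p32 = (r * dt).astype(np.float32)
        w_star_arr = (
            np.ascontiguousarray(w_star, dtype=float)
            if w_star is not None
            else np.zeros((n_rep, n))
        )
        teacher_p_const = -1.0 if teacher_rate is None else float(teacher_rate * dt)
        done = 0
        while done < n_bins:
            nb = min(chunk_bins, n_bins - done)
            u_in = input_rng.random(in_shape + (nb,), dtype=np.float32)
            u_teach = teacher_rng.random((n_teach, nb))
            run_chunk_sigmoid(
                rule_id, w, alpha, u_in, p32, state_m, state_s, em, es, scale,
                u_teach, w_star_arr, teacher_p_const, r, inv_r, ce, e0, eta, dt,
                base_tf.phi_max, base_tf.beta, base_tf.theta, shift, cu, cw,
                gh_x, gh_w, refresh_every, done, gcoef, rec_stride,
                snap_buf, snap_count, x_buf,
            )
            done += nb
        k = int(snap_count[0])
        snapshots = snap_buf[:k] if rec_stride else None
        snap_times = np.arange(1, k + 1) * rec_stride * dt if rec_stride else None
    else:
        snaps, snap_t = [], []
        coeffs = None
        gamma_s = None
        done = 0
        while done < n_bins:
            nb = min(chunk_bins, n_bins - done)
            usps = filt.filter(input_chunk(nb))  # (Rin, n, nb)
            y_star = teacher_draws(usps, nb)

            for k in range(nb):
                x = usps[:, :, k]  # (Rin, n)
                ws = par.f(w)
                fp = par.fprime(w)
                v = np.sum(ws * x, axis=-1)  # (R,)
                phi = tf.phi(v)
                err = y_star[:, k] / dt - phi
                if rule == "euclidean":
                    dw = (eta * dt * err * tf.dphi(v) / phi)[:, None] * x * fp
                elif rule == "quadratic":
                    dphi = tf.dphi(v)
                    if np.any(dphi <= 0):
                        raise ValueError("quadratic rule left its domain (V <= theta)")
                    q = ce * e0**2 * np.sum(r)
                    gamma_u = ce**2 * e0**2 * np.sum(x, axis=-1) / (q + 1.0)
                    bracket = inv_r * x - gamma_u[:, None]
                    dw = (eta * dt * err / dphi)[:, None] * bracket / fp
                else:
                    if coeffs is None or (done + k) % refresh_every == 0:
                        coeffs = coefficients_for(ws, afferents, tf, n_nodes=n_nodes)
                        gamma_s = coeffs.gamma_s
                    sx = np.sum(x, axis=-1)
                    v_drive = v  # tonic baseline handled via a shifted transfer
                    if rule == "natural":
                        gamma_u = -ce * e0 * (coeffs.g1 * ce * e0 * sx + coeffs.g3 * v_drive)
                        gamma_w = coeffs.g2 * ce * e0 * sx + coeffs.g4 * v_drive
                    else:  # approx
                        gamma_u = np.broadcast_to(cu * ce, v.shape)
                        gamma_w = cw * v_drive
                    bracket = inv_r * x - gamma_u[:, None] + gamma_w[:, None] * ws
                    dw = (eta * dt * err * gamma_s * tf.dphi(v) / phi)[:, None] * bracket / fp
                w += dw
                if rec_stride and (done + k + 1) % rec_stride == 0:
                    snaps.append(w.copy())
                    snap_t.append((done + k + 1) * dt)
            done += nb
        snapshots = np.asarray(snaps) if rec_stride else None
        snap_times = np.asarray(snap_t) if rec_stride else None

    diverged = ~np.all(np.isfinite(w), axis=-1)
    return OnlineResult(w=w, snapshots=snapshots, snapshot_times=snap_times, diverged=diverged)
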