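"""Compiled inner loop for online learning (numba).

The generic per-bin loop in :mod:`natgrad.rules` is the reference
implementation; this module provides a numerically equivalent fast path
for the common heavy case — sigmoidal transfer (optionally with a tonic
baseline shift) and a linear (identity / attenuation) parametrization.
The kernel fuses Bernoulli spike generation (from pre-drawn uniforms),
the double-exponential USP filter, teacher sampling and the weight
update, so one chunk is a single compiled call.  Tests pin the two
paths against each other.
"""

from __future__ import annotations

import numpy as np

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    HAVE_NUMBA = True
except Exception:  # pragma: no cover
    HAVE_NUMBA = False

    def njit(*args, **kwargs):  # type: ignore
        def deco(f):
            return f

        return deco if not (args and callable(args[0])) else args[0]


RULE_EUCLIDEAN = 0
RULE_NATURAL = 1
RULE_APPROX = 2

_SQRT2 = np.sqrt(2.0)


@njit(cache=True)
def run_chunk_sigmoid(
    rule_id,
    w,  # (R, n) in/out
    alpha,  # (R, n) linear parametrization factors
    u_in,  # (Rin, n, nb) float32 input-spike uniforms
    p_spike,  # (n,) float32 per-bin spike probabilities
    state_m,  # (Rin, n) in/out membrane-branch filter state
    state_s,  # (Rin, n) in/out synaptic-branch filter state
    em,  # exp(-dt/tau_m)
    es,  # exp(-dt/tau_s)
    scale,  # eps0/(tau_m - tau_s)
    u_teach,  # (R, nb) teacher uniforms
    w_star,  # (R, n) somatic teacher weights (zeros when unused)
    teacher_p_const,  # >= 0: constant per-bin teacher probability; < 0: realizable
    r,  # (n,) rates
    inv_r,  # (n,) c_eps/r (0 for silent afferents)
    ce,
    e0,
    eta,
    dt,
    phi_max,
    beta,
    theta,
    shift,
    cu,
    cw,
    gh_x,  # (K,) Gauss-Hermite nodes
    gh_w,  # (K,) Gauss-Hermite weights (normalized)
    refresh_every,
    bin0,  # global index of first bin in this chunk
    gcoef,  # (R, 5) persistent [gamma_s, g1, g2, g3, g4]
    rec_stride,  # 0: no snapshots
    snaps,  # (K_max, R, n) snapshot buffer
    snap_count,  # int64[1] in/out
    x_buf,  # (Rin, n) scratch for the current USP vector
):
    n_rep, n = w.shape
    n_in = u_in.shape[0]
    shared = n_in == 1
    shared_teacher = u_teach.shape[0] == 1
    nb = u_in.shape[2]
    q = 0.0
    for i in range(n):
        q += r[i]
    q *= ce * e0 * e0
    n_nodes = gh_x.shape[0]

    for k in range(nb):
        gbin = bin0 + k

        # advance the USP filter; a spike lands with epsilon(0) = 0
        for src in range(n_in):
            for i in range(n):
                sm = state_m[src, i] * em
                ss = state_s[src, i] * es
                if u_in[src, i, k] < p_spike[i]:
                    sm += 1.0
                    ss += 1.0
                state_m[src, i] = sm
                state_s[src, i] = ss
                x_buf[src, i] = scale * (sm - ss)

        needs_coeffs = rule_id != RULE_EUCLIDEAN
        if needs_coeffs and gbin % refresh_every == 0:
            for rep in range(n_rep):
                mu = 0.0
                s2 = 0.0
                for i in range(n):
                    wsi = alpha[rep, i] * w[rep, i]
                    mu += wsi * r[i]
                    s2 += wsi * wsi * r[i]
                mu *= e0
                s2 /= ce
                if s2 <= 0.0:
                    raise ValueError("degenerate voltage variance in coefficient refresh")
                sig = np.sqrt(s2)
                i1 = 0.0
                i2 = 0.0
                i3 = 0.0
                for j in range(n_nodes):
                    u = mu + _SQRT2 * sig * gh_x[j]
                    p = phi_max / (1.0 + np.exp(-beta * (u + shift - theta)))
                    ratio = beta * beta * p * (1.0 - p / phi_max) ** 2
                    gw_j = gh_w[j]
                    i1 += gw_j * ratio
                    i2 += gw_j * ratio * u
                    i3 += gw_j * ratio * u * u
                c1 = i1
                c2 = (i2 - i1 * mu) / s2
                c3 = (i3 - i1 * (mu * mu + s2) - 2.0 * c2 * mu * s2) / (s2 * s2)
                k1 = 1.0 / (c1 * (c1 * (q + 1.0) + c2 * mu))
                a = c1 * mu + c2 * s2
                b = c2 * q + c3 * mu
                k2 = 1.0 / (1.0 + (c2 * mu + c3 * s2) / c1 - k1 * a * b)
                gcoef[rep, 0] = 1.0 / c1
                gcoef[rep, 1] = c1 * (-k1 * c1 + k1 * k2 * c2 * a / c1 - k1 * k1 * k2 * c1 * a * b)
                gcoef[rep, 2] = c1 * (-k1 * c2 + k1 * k2 * c3 * a / c1 - k1 * k1 * k2 * c2 * a * b)
                gcoef[rep, 3] = c1 * (k1 * k2 * b - k2 * c2 / (c1 * c1))
                gcoef[rep, 4] = c1 * (k1 * k2 * c2 * b / c1 - k2 * c3 / (c1 * c1))

        for rep in range(n_rep):
            src = 0 if shared else rep
            v = 0.0
            sx = 0.0
            v_star = 0.0
            for i in range(n):
                x_i = x_buf[src, i]
                v += alpha[rep, i] * w[rep, i] * x_i
                sx += x_i
                v_star += w_star[rep, i] * x_i
            if teacher_p_const >= 0.0:
                p_star = teacher_p_const
            else:
                p_star = dt * phi_max / (1.0 + np.exp(-beta * (v_star + shift - theta)))
            tsrc = 0 if shared_teacher else rep
            y = 1.0 if u_teach[tsrc, k] < p_star else 0.0

            p = phi_max / (1.0 + np.exp(-beta * (v + shift - theta)))
            dp = beta * p * (1.0 - p / phi_max)
            err = y / dt - p
            if rule_id == RULE_EUCLIDEAN:
                c = eta * dt * err * dp / p
                for i in range(n):
                    w[rep, i] += c * x_buf[src, i] * alpha[rep, i]
            else:
                if rule_id == RULE_NATURAL:
                    gamma_u = -ce * e0 * (gcoef[rep, 1] * ce * e0 * sx + gcoef[rep, 3] * v)
                    gamma_w = gcoef[rep, 2] * ce * e0 * sx + gcoef[rep, 4] * v
                else:
                    gamma_u = cu * ce
                    gamma_w = cw * v
                c = eta * dt * err * gcoef[rep, 0] * dp / p
                for i in range(n):
                    br = inv_r[i] * x_buf[src, i] - gamma_u + gamma_w * alpha[rep, i] * w[rep, i]
                    w[rep, i] += c * br / alpha[rep, i]

        if rec_stride > 0 and (gbin + 1) % rec_stride == 0:
            idx = snap_count[0]
            for rep in range(n_rep):
                for i in range(n):
                    snaps[idx, rep, i] = w[rep, i]
            snap_count[0] = idx + 1
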