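"""Fisher information of the Poisson neuron's input-output distribution.

For a GLM neuron spiking per bin with probability ``phi(w . x) dt``,
the per-bin Fisher matrix is ``G(w) = E[dt (phi')^2/phi x x^T]`` over
the stationary USP distribution.  For many afferents the membrane
potential is approximately Gaussian with mean ``mu_v = eps0 sum w_i r_i``
and variance ``sigma_v^2 = (1/c_eps) sum w_i^2 r_i``, which collapses G
to a rank-structured closed form

    G = c1 (eps0^2 r r^T + Sigma) + c2 eps0 [S w r^T + r (S w)^T]
        + c3 (S w)(S w)^T,        S = Sigma_usp = diag(r_i / c_eps),

whose inverse follows from two Sherman-Morrison steps:

    G^-1 = (1/c1) [Sigma^-1 + (g1 rt + g2 w) rt^T + (g3 rt + g4 w) w^T],

with ``rt = eps0 Sigma^-1 r = c_eps eps0 1`` a constant vector.  The
coefficients c1..c3, k1, k2, g1..g4 are scalar functions of three
generalized voltage moments I1..I3 (Gaussian expectations of
``(phi')^2/phi {1, u, u^2}``), the voltage mean/variance and the total
rate factor ``q = c_eps eps0^2 sum r_i``.

All coefficient functions broadcast over leading (replica) axes so the
online learner can refresh them for many trials at once.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import roots_hermite

from .neuron import AfferentConfig, TransferFunction

__all__ = [
    "VoltageStatistics",
    "GeneralizedMoments",
    "FisherCoefficients",
    "voltage_statistics",
    "gauss_expectation",
    "generalized_moments",
    "fisher_coefficients",
    "coefficients_for",
    "fisher_matrix",
    "fisher_inverse",
    "fisher_inverse_woodbury",
    "empirical_fisher",
    "reparametrized_fisher",
]


@dataclass(frozen=True)
class VoltageStatistics:
    """Mean/variance of the membrane potential and the total-rate factor q.

    ``mu_v = eps0 sum w_i r_i`` (mV), ``sigma2_v = (1/c_eps) sum w_i^2 r_i``
    (mV^2), ``q = c_eps eps0^2 sum r_i`` (dimensionless).  Fields may be
    arrays with a common leading shape (one entry per weight replica).
    """

    mu_v: np.ndarray
    sigma2_v: np.ndarray
    q: np.ndarray


@dataclass(frozen=True)
class GeneralizedMoments:
    """Gaussian-weighted integrals of (phi')^2/phi times {1, u, u^2}."""

    I1: np.ndarray
    I2: np.ndarray
    I3: np.ndarray


@dataclass(frozen=True)
class FisherCoefficients:
    """Scalar coefficients of the Fisher decomposition and its inverse."""

    c1: np.ndarray
    c2: np.ndarray
    c3: np.ndarray
    k1: np.ndarray
    k2: np.ndarray
    g1: np.ndarray
    g2: np.ndarray
    g3: np.ndarray
    g4: np.ndarray

    @property
    def gamma_s(self) -> np.ndarray:
        """Global output-dependent scaling of the natural-gradient rule, 1/c1."""
        return 1.0 / self.c1


def voltage_statistics(w, afferents: AfferentConfig) -> VoltageStatistics:
    """Exact voltage mean/variance for given weights; w shape (..., n)."""
    w = np.asarray(w, dtype=float)
    r = afferents.rates
    if w.shape[-1] != r.size:
        raise ValueError(f"weight dim {w.shape[-1]} != number of afferents {r.size}")
    eps0 = afferents.kernel.epsilon0
    c_eps = afferents.kernel.c_epsilon
    mu_v = eps0 * (w @ r)
    sigma2_v = (w * w) @ r / c_eps
    q = c_eps * eps0**2 * np.sum(r)
    return VoltageStatistics(mu_v=mu_v, sigma2_v=sigma2_v, q=np.broadcast_to(q, np.shape(mu_v)))


_GH_CACHE: dict[int, tuple[np.ndarray, np.ndarray]] = {}


def _gh_nodes(n_nodes: int) -> tuple[np.ndarray, np.ndarray]:
    if n_nodes not in _GH_CACHE:
        # scipy's Golub-Welsch routine stays stable for large node counts
        x, w = roots_hermite(n_nodes)
        _GH_CACHE[n_nodes] = (x, w / np.sqrt(np.pi))
    return _GH_CACHE[n_nodes]


def gauss_expectation(fun, mu_v, sigma2_v, n_nodes: int = 200):
    """E[fun(U)] for U ~ N(mu_v, sigma2_v) by Gauss-Hermite quadrature.

    Broadcasts over array-valued mu_v/sigma2_v (nodes on the last axis).
    """
    x, w = _gh_nodes(n_nodes)
    mu_v = np.asarray(mu_v, dtype=float)
    sigma = np.sqrt(np.asarray(sigma2_v, dtype=float))
    u = mu_v[..., None] + np.sqrt(2.0) * sigma[..., None] * x
    return np.sum(fun(u) * w, axis=-1)


def _fisher_ratio_density(tf: TransferFunction, u: np.ndarray) -> np.ndarray:
    """(phi')^2/phi with the convention 0 where phi = 0 (outside support)."""
    p = tf.phi(u)
    d = tf.dphi(u)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(p > 0.0, d * d / np.where(p > 0.0, p, 1.0), 0.0)
    return ratio


def generalized_moments(
    stats: VoltageStatistics,
    tf: TransferFunction,
    n_nodes: int = 200,
    check_convergence: bool = True,
    rtol: float = 1e-6,
) -> GeneralizedMoments:
    """Moments I1..I3 of (phi')^2/phi under the Gaussian voltage density.

    A degenerate ``sigma2_v = 0`` reduces to the integrand at ``mu_v``.
    With ``check_convergence`` the node count is doubled once and a
    relative disagreement beyond ``rtol`` raises.
    """
    mu = np.asarray(stats.mu_v, dtype=float)
    s2 = np.asarray(stats.sigma2_v, dtype=float)
    if np.any(s2 < 0):
        raise ValueError("sigma2_v must be non-negative")

    def compute(k: int) -> tuple[np.ndarray, ...]:
        i1 = gauss_expectation(lambda u: _fisher_ratio_density(tf, u), mu, s2, k)
        i2 = gauss_expectation(lambda u: _fisher_ratio_density(tf, u) * u, mu, s2, k)
        i3 = gauss_expectation(lambda u: _fisher_ratio_density(tf, u) * u * u, mu, s2, k)
        return i1, i2, i3

    i1, i2, i3 = compute(n_nodes)
    if check_convergence:
        j1, j2, j3 = compute(2 * n_nodes)
        for a, b in ((i1, j1), (i2, j2), (i3, j3)):
            scale = np.maximum(np.abs(b), 1e-300)
            if np.any(np.abs(a - b) / scale > max(rtol, 1e-6)):
                raise RuntimeError(
                    "generalized moments did not converge under node doubling; "
                    "increase n_nodes or check the transfer function"
                )
        i1, i2, i3 = j1, j2, j3
    return GeneralizedMoments(I1=i1, I2=i2, I3=i3)


def fisher_coefficients(
    moments: GeneralizedMoments, stats: VoltageStatistics
) -> FisherCoefficients:
    """Decomposition coefficients c1..c3 and inverse coefficients g1..g4.

    c1 = I1
    c2 = (I2 - I1 mu_v) / sigma_v^2
    c3 = (I3 - I1 (mu_v^2 + sigma_v^2) - 2 c2 mu_v sigma_v^2) / sigma_v^4
    k1 = { c1 [ c1 (q+1) + c2 mu_v ] }^-1
    k2 = [ 1 + (c2 mu_v + c3 sigma_v^2)/c1
             - k1 (c1 mu_v + c2 sigma_v^2)(c2 q + c3 mu_v) ]^-1
    g1 = c1 { -k1 c1 + k1 k2 c2 (c1 mu_v + c2 sv2)/c1
              - k1^2 k2 c1 (c1 mu_v + c2 sv2)(c2 q + c3 mu_v) }
    g2 = c1 { -k1 c2 + k1 k2 c3 (c1 mu_v + c2 sv2)/c1
              - k1^2 k2 c2 (c1 mu_v + c2 sv2)(c2 q + c3 mu_v) }
    g3 = c1 [ k1 k2 (c2 q + c3 mu_v) - k2 c2 / c1^2 ]
    g4 = c1 [ k1 k2 c2 (c2 q + c3 mu_v)/c1 - k2 c3 / c1^2 ]
    """
    mu = np.asarray(stats.mu_v, dtype=float)
    s2 = np.asarray(stats.sigma2_v, dtype=float)
    q = np.asarray(stats.q, dtype=float)
    i1, i2, i3 = moments.I1, moments.I2, moments.I3
    if np.any(s2 <= 0):
        raise ValueError("fisher_coefficients requires sigma2_v > 0")
    if np.any(i1 <= 0):
        raise ValueError("I1 must be positive (transfer function degenerate?)")

    c1 = i1
    c2 = (i2 - i1 * mu) / s2
    c3 = (i3 - i1 * (mu**2 + s2) - 2.0 * c2 * mu * s2) / s2**2

    d1 = c1 * (c1 * (q + 1.0) + c2 * mu)
    if np.any(d1 == 0):
        raise ZeroDivisionError("vanishing k1 denominator: degenerate configuration")
    k1 = 1.0 / d1

    a = c1 * mu + c2 * s2  # w-tilde^T (c1 rt + c2 w)
    b = c2 * q + c3 * mu  # rt^T (c2 eps0 r + c3 w-tilde)
    d2 = 1.0 + (c2 * mu + c3 * s2) / c1 - k1 * a * b
    if np.any(d2 == 0):
        raise ZeroDivisionError("vanishing k2 denominator: degenerate configuration")
    k2 = 1.0 / d2

    g1 = c1 * (-k1 * c1 + k1 * k2 * c2 * a / c1 - k1**2 * k2 * c1 * a * b)
    g2 = c1 * (-k1 * c2 + k1 * k2 * c3 * a / c1 - k1**2 * k2 * c2 * a * b)
    g3 = c1 * (k1 * k2 * b - k2 * c2 / c1**2)
    g4 = c1 * (k1 * k2 * c2 * b / c1 - k2 * c3 / c1**2)
    return FisherCoefficients(c1=c1, c2=c2, c3=c3, k1=k1, k2=k2, g1=g1, g2=g2, g3=g3, g4=g4)


def coefficients_for(
    w, afferents: AfferentConfig, tf: TransferFunction, n_nodes: int = 200
) -> FisherCoefficients:
    """Convenience: voltage stats -> moments -> coefficients for weights w."""
    stats = voltage_statistics(w, afferents)
    moments = generalized_moments(stats, tf, n_nodes=n_nodes, check_convergence=False)
    return fisher_coefficients(moments, stats)


def _structure_vectors(afferents: AfferentConfig):
    r = afferents.rates
    kernel = afferents.kernel
    eps0 = kernel.epsilon0
    c_eps = kernel.c_epsilon
    sigma_usp = r / c_eps  # diagonal of Sigma_usp
    return r, eps0, c_eps, sigma_usp


def fisher_matrix(
    w,
    afferents: AfferentConfig,
    tf: TransferFunction,
    dt: float = 1.0,
    coeffs: FisherCoefficients | None = None,
) -> np.ndarray:
    """Closed-form per-bin Fisher matrix, scaled by dt."""
    w = np.asarray(w, dtype=float)
    r, eps0, _, sigma_usp = _structure_vectors(afferents)
    if coeffs is None:
        coeffs = coefficients_for(w, afferents, tf)
    sw = sigma_usp * w  # Sigma_usp w
    g = coeffs.c1 * (eps0**2 * np.outer(r, r) + np.diag(sigma_usp))
    g += coeffs.c2 * eps0 * (np.outer(sw, r) + np.outer(r, sw))
    g += coeffs.c3 * np.outer(sw, sw)
    return dt * g


def fisher_inverse(
    w,
    afferents: AfferentConfig,
    tf: TransferFunction,
    dt: float = 1.0,
    coeffs: FisherCoefficients | None = None,
) -> np.ndarray:
    """Closed-form inverse of the per-bin Fisher matrix (divided by dt).

    Requires strictly positive rates; zero-rate afferents make Sigma_usp
    singular and must be excluded upstream.
    """
    w = np.asarray(w, dtype=float)
    r, eps0, c_eps, sigma_usp = _structure_vectors(afferents)
    if np.any(r <= 0):
        raise ValueError("fisher_inverse requires strictly positive rates")
    if coeffs is None:
        coeffs = coefficients_for(w, afferents, tf)
    rt = c_eps * eps0 * np.ones_like(r)  # eps0 Sigma_usp^-1 r
    ginv = np.diag(1.0 / sigma_usp)
    ginv += np.outer(coeffs.g1 * rt + coeffs.g2 * w, rt)
    ginv += np.outer(coeffs.g3 * rt + coeffs.g4 * w, w)
    return ginv / (coeffs.c1 * dt)


def fisher_inverse_woodbury(
    w,
    afferents: AfferentConfig,
    tf: TransferFunction,
    dt: float = 1.0,
    coeffs: FisherCoefficients | None = None,
) -> np.ndarray:
    """Alternative rank-2 Woodbury inverse; cross-check of fisher_inverse."""
    w = np.asarray(w, dtype=float)
    r, eps0, _, sigma_usp = _structure_vectors(afferents)
    if np.any(r <= 0):
        raise ValueError("woodbury inverse requires strictly positive rates")
    if coeffs is None:
        coeffs = coefficients_for(w, afferents, tf)
    c1, c2, c3 = coeffs.c1, coeffs.c2, coeffs.c3
    u = np.stack([r, sigma_usp * w], axis=1)  # n x 2
    cmat = np.array([[c1 * eps0**2, c2 * eps0], [c2 * eps0, c3]])
    a_inv_diag = 1.0 / (c1 * sigma_usp)
    ut = a_inv_diag[:, None] * u
    core = np.linalg.inv(np.linalg.inv(cmat) + u.T @ ut)
    return (np.diag(a_inv_diag) - ut @ core @ ut.T) / dt


def empirical_fisher(w, usp_samples, tf: TransferFunction, dt: float) -> np.ndarray:
    """Monte-Carlo Fisher: average of dt (phi')^2/phi x x^T over USP samples."""
    x = np.atleast_2d(np.asarray(usp_samples, dtype=float))  # (S, n)
    v = x @ np.asarray(w, dtype=float)
    p = tf.phi(v)
    if np.any(p <= 0):
        raise ValueError("phi = 0 at a USP sample: outside the transfer domain")
    weights = dt * tf.dphi(v) ** 2 / p
    return (x.T * weights) @ x / x.shape[0]


def reparametrized_fisher(g_somatic: np.ndarray, fprime) -> np.ndarray:
    """Congruence transform diag(f') G_s diag(f') for a coordinate change."""
    fprime = np.asarray(fprime, dtype=float)
    if np.any(fprime == 0) or not np.all(np.isfinite(fprime)):
        raise ValueError("parametrization derivative must be finite and non-zero")
    return fprime[:, None] * np.asarray(g_somatic) * fprime[None, :]
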