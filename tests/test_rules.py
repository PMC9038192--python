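"""Learning rules: invariance, decomposition, rule equivalences, trainer."""

import numpy as np
import pytest

import natgrad.rules as rules_mod
from natgrad.fisher import coefficients_for, fisher_inverse, voltage_statistics
from natgrad.neuron import (
    AfferentConfig,
    RectifiedQuadraticTransfer,
    ShiftedTransfer,
    SigmoidTransfer,
)
from natgrad.parametrization import (
    Parametrization,
    exponential_attenuation,
    identity,
)
from natgrad.rules import (
    approximated_update,
    euclidean_update,
    gamma_factors,
    natural_update,
    quadratic_limit_update,
    run_online,
    somatic_image,
)
from natgrad.spikes import sample_stationary_usps

from conftest import SIM_KERNEL


def _setup(rng, n=6, rates=25.0):
    aff = AfferentConfig(rates=np.full(n, rates), kernel=SIM_KERNEL)
    ws = rng.uniform(0.02, 0.08, n)  # somatic weights
    usp = sample_stationary_usps(aff, 1, 5e-4, rng, spacing_bins=1)[0]
    return aff, ws, usp


def _affine_par(a, b):
    return Parametrization(
        f=lambda w: a * w + b,
        fprime=lambda w: np.broadcast_to(a, np.shape(w)).astype(float).copy(),
        inverse=lambda ws: (ws - b) / a,
        name="affine",
    )


def _exp_par():
    return Parametrization(
        f=np.exp, fprime=np.exp, inverse=np.log, name="exp-coords"
    )


@pytest.mark.parametrize("make_par", [lambda rng, n: _affine_par(rng.uniform(0.2, 3.0, n), 0.0),
                                      lambda rng, n: _exp_par(),
                                      lambda rng, n: exponential_attenuation(rng.uniform(0, 400, n), 200.0)],
                         ids=["affine", "exponential-map", "cable-attenuation"])
def test_natural_rule_is_parametrization_invariant(rng, make_par):
    """The somatic image of the natural update is the same in any smooth
    component-wise coordinate system (relative error < 1e-10)."""
    aff, ws, usp = _setup(rng)
    par = make_par(rng, aff.n)
    w_coord = par.from_somatic(ws)
    tf = SigmoidTransfer()
    v = ws @ usp
    coeffs = coefficients_for(ws, aff, tf)
    gam = gamma_factors(ws, usp, coeffs, aff)
    ts = 1.0 / 5e-4  # a teacher spike in this bin
    upd_somatic = natural_update(ts, v, usp, ws, identity(), gam, aff, tf, 1e-3, 5e-4)
    upd_coord = natural_update(ts, v, usp, w_coord, par, gam, aff, tf, 1e-3, 5e-4)
    image = somatic_image(upd_coord, par, w_coord)
    assert np.linalg.norm(image - upd_somatic.total) < 1e-10 * np.linalg.norm(upd_somatic.total)


def test_euclidean_rule_breaks_invariance_by_fprime_squared(rng):
    """Transporting the Euclidean update through coordinates multiplies its
    somatic image by exactly f'(w)^2."""
    aff, ws, usp = _setup(rng)
    par = _affine_par(rng.uniform(0.2, 3.0, aff.n), 0.0)
    w_coord = par.from_somatic(ws)
    tf = SigmoidTransfer()
    v = ws @ usp
    ts = 1.0 / 5e-4
    upd_somatic = euclidean_update(ts, v, usp, tf, 1e-3, 5e-4)
    upd_coord = euclidean_update(ts, v, usp, tf, 1e-3, 5e-4, par=par, w=w_coord)
    image = somatic_image(upd_coord, par, w_coord)
    fp2 = par.fprime(w_coord) ** 2
    assert image == pytest.approx(fp2 * upd_somatic.total, rel=1e-12)


def test_natural_direction_equals_inverse_fisher_times_euclidean(rng):
    """n=2: the natural update is G^-1 applied to the Euclidean update."""
    aff = AfferentConfig(rates=np.array([10.0, 50.0]), kernel=SIM_KERNEL)
    ws = np.array([0.03, -0.02])
    usp = sample_stationary_usps(aff, 1, 5e-4, rng)[0]
    tf = SigmoidTransfer()
    v = ws @ usp
    coeffs = coefficients_for(ws, aff, tf)
    gam = gamma_factors(ws, usp, coeffs, aff)
    ts = 1.0 / 5e-4
    nat = natural_update(ts, v, usp, ws, identity(), gam, aff, tf, 1e-3, 5e-4)
    euc = euclidean_update(ts, v, usp, tf, 1e-3, 5e-4)
    ginv = fisher_inverse(ws, aff, tf, coeffs=coeffs)  # per-unit-time scale
    assert nat.total == pytest.approx(ginv @ euc.total, rel=1e-9)


def test_update_decomposition_structure(rng):
    """total = common * (hom + het_u + het_w); hom = c_eps x/r with
    silent afferents contributing no homosynaptic change."""
    kernel = SIM_KERNEL
    aff = AfferentConfig(rates=np.array([20.0, 40.0, 0.0]), kernel=kernel)
    ws = np.array([0.05, 0.02, 0.04])
    usp = np.array([30.0, 10.0, 0.0])
    tf = SigmoidTransfer()
    stats_ok = np.array([0.05, 0.02])  # only driven afferents enter sigma_v
    coeffs = coefficients_for(ws, aff, tf)
    gam = gamma_factors(ws, usp, coeffs, aff)
    upd = natural_update(1.0 / 5e-4, ws @ usp, usp, ws, identity(), gam, aff, tf, 1e-3, 5e-4)
    assert upd.total == pytest.approx(
        upd.common_factor * (upd.hom + upd.het_u + upd.het_w), rel=1e-12
    )
    assert upd.hom[:2] == pytest.approx(kernel.c_epsilon * usp[:2] / aff.rates[:2])
    assert upd.hom[2] == 0.0  # no input rate, no homosynaptic term
    assert upd.het_u[2] != 0.0  # heterosynaptic terms still act
    assert upd.het_w[2] != 0.0


def test_zero_error_gives_zero_update(rng):
    aff, ws, usp = _setup(rng)
    tf = SigmoidTransfer()
    v = ws @ usp
    coeffs = coefficients_for(ws, aff, tf)
    gam = gamma_factors(ws, usp, coeffs, aff)
    upd = natural_update(tf.phi(v), v, usp, ws, identity(), gam, aff, tf, 1e-3, 5e-4)
    assert np.all(upd.total == 0.0)


def test_mean_update_vanishes_at_matched_rates(rng):
    """With teacher spikes drawn at the student's own rate the update
    averages to zero over many bins (within Monte-Carlo error)."""
    aff, ws, usp = _setup(rng)
    tf = SigmoidTransfer()
    v = float(ws @ usp)
    dt = 5e-4
    p = tf.phi(v) * dt
    n_bins = 200_000
    y = (rng.random(n_bins) < p).astype(float)
    coeffs = coefficients_for(ws, aff, tf)
    gam = gamma_factors(ws, usp, coeffs, aff)
    upd = natural_update(y / dt, np.full(n_bins, v), usp, ws, identity(), gam, aff, tf, 1.0, dt)
    mean_update = upd.total.mean(axis=0)
    scale = np.abs(upd.total).mean(axis=0)
    assert np.all(np.abs(mean_update) < 4 * scale / np.sqrt(p * n_bins))


class TestGammaFactors:
    def test_quadratic_transfer_limits(self, rng):
        aff, ws, usp = _setup(rng)
        stats = voltage_statistics(ws, aff)
        tf = RectifiedQuadraticTransfer(theta=stats.mu_v - 12 * np.sqrt(stats.sigma2_v))
        coeffs = coefficients_for(ws, aff, tf)
        gam = gamma_factors(ws, usp, coeffs, aff)
        assert gam.gamma_s == pytest.approx(1.0, rel=1e-8)
        assert gam.gamma_w == pytest.approx(0.0, abs=1e-8)

    def test_large_n_uniform_term_approaches_c_epsilon(self):
        rng = np.random.default_rng(21)
        n = 200
        aff = AfferentConfig(rates=np.full(n, 20.0), kernel=SIM_KERNEL)
        w = rng.uniform(-5.0 / n, 5.0 / n, n)
        coeffs = coefficients_for(w, aff, SigmoidTransfer())
        x = sample_stationary_usps(aff, 50, 5e-4, rng, spacing_bins=50)
        gam = gamma_factors(w, x, coeffs, aff)
        assert gam.gamma_u.mean() / SIM_KERNEL.c_epsilon == pytest.approx(1.0, abs=0.15)

    def test_gamma_u_tracks_its_surrogate(self):
        """gamma_u ~ s = c_eps sum(x)/sum(r): regression slope near one."""
        rng = np.random.default_rng(22)
        n = 100
        aff = AfferentConfig(rates=np.full(n, 20.0), kernel=SIM_KERNEL)
        gus, ss = [], []
        for _ in range(10):
            w = rng.uniform(-5.0 / n, 5.0 / n, n)
            coeffs = coefficients_for(w, aff, SigmoidTransfer())
            x = sample_stationary_usps(aff, 10, 5e-4, rng, spacing_bins=80)
            gam = gamma_factors(w, x, coeffs, aff)
            gus.extend(gam.gamma_u)
            ss.extend(SIM_KERNEL.c_epsilon * x.sum(axis=1) / aff.rates.sum())
        slope = np.polyfit(ss, gus, 1)[0]
        assert slope == pytest.approx(1.0, abs=0.15)


class TestApproximatedRule:
    def test_reduces_to_natural_when_surrogates_are_exact(self, rng):
        aff, ws, usp = _setup(rng)
        tf = SigmoidTransfer()
        v = ws @ usp
        coeffs = coefficients_for(ws, aff, tf)
        gam = gamma_factors(ws, usp, coeffs, aff)
        ce = aff.kernel.c_epsilon
        cu = float(gam.gamma_u / ce)
        cw = float(gam.gamma_w / v)
        nat = natural_update(1 / 5e-4, v, usp, ws, identity(), gam, aff, tf, 1e-3, 5e-4)
        app = approximated_update(
            1 / 5e-4, v, usp, ws, identity(), aff, tf, 1e-3, 5e-4, cu=cu, cw=cw, coeffs=coeffs
        )
        assert app.total == pytest.approx(nat.total, rel=1e-10)

    def test_heterosynaptic_terms_vanish_for_zero_surrogates(self, rng):
        aff, ws, usp = _setup(rng)
        tf = SigmoidTransfer()
        upd = approximated_update(
            1 / 5e-4, 0.0, np.zeros_like(usp), ws, identity(), aff, tf, 1e-3, 5e-4, cu=0.0, cw=0.05
        )
        assert np.all(upd.het_u == 0.0)
        assert np.all(upd.het_w == 0.0)  # gamma_w = cw * V with V = 0


class TestQuadraticLimitRule:
    def test_matches_full_natural_rule_under_quadratic_transfer(self, rng):
        aff, ws, usp = _setup(rng)
        stats = voltage_statistics(ws, aff)
        tf = RectifiedQuadraticTransfer(theta=stats.mu_v - 12 * np.sqrt(stats.sigma2_v))
        v = ws @ usp
        coeffs = coefficients_for(ws, aff, tf)
        gam = gamma_factors(ws, usp, coeffs, aff)
        nat = natural_update(1 / 5e-4, v, usp, ws, identity(), gam, aff, tf, 1e-3, 5e-4)
        quad = quadratic_limit_update(1 / 5e-4, v, usp, ws, identity(), aff, tf, 1e-3, 5e-4)
        assert quad.total == pytest.approx(nat.total, rel=1e-6)

    def test_zero_usp_vector_gives_zero_update(self, rng):
        aff, ws, _ = _setup(rng)
        tf = RectifiedQuadraticTransfer(theta=-50.0)
        upd = quadratic_limit_update(1 / 5e-4, 0.0, np.zeros(aff.n), ws, identity(), aff, tf, 1e-3, 5e-4)
        assert np.all(upd.total == 0.0)

    def test_domain_violation_raises(self, rng):
        aff, ws, usp = _setup(rng)
        tf = RectifiedQuadraticTransfer(theta=10.0)
        with pytest.raises(ValueError):
            quadratic_limit_update(0.0, 5.0, usp, ws, identity(), aff, tf, 1e-3, 5e-4)


class TestSomaticImage:
    def test_identity_is_noop(self, rng):
        dw = rng.normal(size=5)
        assert somatic_image(dw, identity(), np.zeros(5)) == pytest.approx(dw)

    def test_composition_multiplies_derivatives(self, rng):
        a1 = rng.uniform(0.5, 2.0, 5)
        p1, p2 = _affine_par(a1, 0.0), _exp_par()
        comp = p1.compose(p2)
        w = rng.uniform(0.1, 1.0, 5)
        assert comp.fprime(w) == pytest.approx(p1.fprime(p2.f(w)) * p2.fprime(w))
        assert comp.from_somatic(comp.f(w)) == pytest.approx(w)

    def test_uniform_attenuation_scales(self, rng):
        """alpha = 0.5: natural somatic image invariant; Euclidean image
        scaled by alpha^2 = 0.25."""
        aff, ws, usp = _setup(rng)
        par = _affine_par(np.full(aff.n, 0.5), 0.0)
        wd = par.from_somatic(ws)
        tf = SigmoidTransfer()
        v = ws @ usp
        coeffs = coefficients_for(ws, aff, tf)
        gam = gamma_factors(ws, usp, coeffs, aff)
        nat_s = natural_update(1 / 5e-4, v, usp, ws, identity(), gam, aff, tf, 1e-3, 5e-4)
        nat_d = natural_update(1 / 5e-4, v, usp, wd, par, gam, aff, tf, 1e-3, 5e-4)
        assert somatic_image(nat_d, par, wd) == pytest.approx(nat_s.total, rel=1e-10)
        euc_s = euclidean_update(1 / 5e-4, v, usp, tf, 1e-3, 5e-4)
        euc_d = euclidean_update(1 / 5e-4, v, usp, tf, 1e-3, 5e-4, par=par, w=wd)
        assert somatic_image(euc_d, par, wd) == pytest.approx(0.25 * euc_s.total, rel=1e-12)


class TestOnlineTrainer:
    @pytest.mark.parametrize("rule", ["natural", "euclidean", "approx"])
    def test_fast_and_generic_paths_agree(self, rule):
        """The compiled engine reproduces the reference numpy loop."""
        if not rules_mod.HAVE_NUMBA:
            pytest.skip("numba unavailable; only the generic path exists")
        n, R = 20, 3
        rng = np.random.default_rng(1)
        aff = AfferentConfig(rates=rng.uniform(10, 50, n), kernel=SIM_KERNEL)
        w0 = rng.uniform(-1 / n, 1 / n, (R, n))
        ws = rng.uniform(-1 / n, 1 / n, (R, n))
        kwargs = dict(
            eta=6e-4, dt=5e-4, duration=0.5, w_star=ws, refresh_every=1, record_every=0.25
        )
        res_fast = run_online(
            rule, w0, aff, SigmoidTransfer(), None,
            input_rng=np.random.default_rng(2), teacher_rng=np.random.default_rng(3), **kwargs
        )
        rules_mod.HAVE_NUMBA = False
        try:
            res_ref = run_online(
                rule, w0, aff, SigmoidTransfer(), None,
                input_rng=np.random.default_rng(2), teacher_rng=np.random.default_rng(3), **kwargs
            )
        finally:
            rules_mod.HAVE_NUMBA = True
        assert res_fast.w == pytest.approx(res_ref.w, rel=1e-6, abs=1e-12)
        assert res_fast.snapshots == pytest.approx(res_ref.snapshots, rel=1e-6, abs=1e-12)

    def test_trainer_single_step_matches_rule_function(self):
        """One bin of the trainer equals the reference per-bin update."""
        n = 5
        rng = np.random.default_rng(4)
        aff = AfferentConfig(rates=rng.uniform(20, 40, n), kernel=SIM_KERNEL)
        w0 = rng.uniform(0.01, 0.05, (1, n))
        res = run_online(
            "natural", w0, aff, SigmoidTransfer(), None, 1e-3, 5e-4, 5e-4,
            input_rng=np.random.default_rng(5), teacher_rng=np.random.default_rng(6),
            teacher_rate=500.0,
        )
        # replay the same single bin by hand
        u = np.random.default_rng(5).random((1, n, 1), dtype=np.float32)
        spikes = (u[:, :, 0] < (aff.rates * 5e-4).astype(np.float32)).astype(float)
        from natgrad.spikes import UspFilter

        x = UspFilter(SIM_KERNEL, 5e-4, batch_shape=(1, n)).filter(spikes[:, :, None])[:, :, 0]
        y = float(np.random.default_rng(6).random((1, 1))[0, 0] < 500.0 * 5e-4)
        tf = SigmoidTransfer()
        v = float(w0[0] @ x[0])
        coeffs = coefficients_for(w0[0], aff, tf)
        gam = gamma_factors(w0[0], x[0], coeffs, aff)
        upd = natural_update(y / 5e-4, v, x[0], w0[0], identity(), gam, aff, tf, 1e-3, 5e-4)
        assert res.w[0] - w0[0] == pytest.approx(upd.total, rel=1e-6, abs=1e-15)

    def test_seed_reproducibility_and_divergence_flag(self):
        n = 10
        rng = np.random.default_rng(11)
        aff = AfferentConfig(rates=np.full(n, 20.0), kernel=SIM_KERNEL)
        w0 = rng.uniform(-0.05, 0.05, (2, n))
        ws = rng.uniform(-0.05, 0.05, (2, n))
        runs = [
            run_online(
                "natural", w0, aff, SigmoidTransfer(), None, 6e-4, 5e-4, 1.0,
                input_rng=np.random.default_rng(7), teacher_rng=np.random.default_rng(8),
                w_star=ws,
            )
            for _ in range(2)
        ]
        assert np.array_equal(runs[0].w, runs[1].w)
        assert not runs[0].diverged.any()

    def test_invalid_arguments_rejected(self):
        aff = AfferentConfig(rates=np.full(4, 20.0), kernel=SIM_KERNEL)
        w0 = np.full((1, 4), 0.05)
        with pytest.raises(ValueError, match="rule"):
            run_online("sgd", w0, aff, SigmoidTransfer(), None, 1e-3, 5e-4, 0.1,
                       np.random.default_rng(0), np.random.default_rng(1), teacher_rate=20.0)
        with pytest.raises(ValueError, match="exactly one"):
            run_online("natural", w0, aff, SigmoidTransfer(), None, 1e-3, 5e-4, 0.1,
                       np.random.default_rng(0), np.random.default_rng(1))

    def test_tonic_inhibition_via_shifted_transfer(self):
        """A -5 mV baseline shift lowers the output rate of the fast path
        exactly as the reference path says it should."""
        n = 6
        rng = np.random.default_rng(13)
        aff = AfferentConfig(rates=np.full(n, 20.0), kernel=SIM_KERNEL)
        w0 = rng.uniform(0.02, 0.06, (1, n))
        tf = ShiftedTransfer(base=SigmoidTransfer(), shift=-5.0)
        res = run_online(
            "natural", w0, aff, tf, None, 6e-4, 5e-4, 0.5,
            input_rng=np.random.default_rng(14), teacher_rng=np.random.default_rng(15),
            teacher_rate=20.0,
        )
        rules_mod.HAVE_NUMBA = False
        try:
            ref = run_online(
                "natural", w0, aff, tf, None, 6e-4, 5e-4, 0.5,
                input_rng=np.random.default_rng(14), teacher_rng=np.random.default_rng(15),
                teacher_rate=20.0,
            )
        finally:
            rules_mod.HAVE_NUMBA = True
        assert res.w == pytest.approx(ref.w, rel=1e-6)
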