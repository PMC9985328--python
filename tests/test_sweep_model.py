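import numpy as np
import pytest

from haploscan.sweep_model import (
    ModelConfig,
    haldane,
    inverse_haldane,
    log_composite_likelihood,
    mcl_selection_arrays,
    mean_delta_r,
    no_recomb_prob,
    sweep_age,
)


@pytest.fixture
def cfg():
    return ModelConfig(ne=10_000.0, delta_r=1e-4, s_min=0.005)


class TestHaldane:
    def test_anchor_values(self):
        assert haldane(0.0) == 0.0
        assert haldane(50.0) == pytest.approx((1 - np.exp(-1)) / 2, rel=1e-12)
        assert haldane(1e6) > 0.4999999  # asymptote at 1/2

    def test_strictly_increasing(self):
        d = np.linspace(0, 300, 1000)
        assert np.all(np.diff(haldane(d)) > 0)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            haldane(-1.0)

    def test_inverse_round_trip(self):
        d = np.array([0.0, 0.01, 1.0, 50.0, 200.0])
        assert np.allclose(inverse_haldane(haldane(d)), d, rtol=1e-10)


class TestSweepAge:
    def test_unit_time_inverse_relation(self):
        s, y0 = 0.03, 1e-4
        # choose y so that the frequency ratio equals e^s -> t = 1
        ratio = np.exp(s)
        y = ratio * y0 / (1 - y0 + ratio * y0)
        assert sweep_age(s, y, y0) == pytest.approx(1.0, rel=1e-9)

    def test_reference_value(self):
        # logistic trajectory from one copy in 2Ne=20,000 to half the
        # population: ln(0.5 * (1 - 5e-5) / (5e-5 * 0.5)) / 0.05
        assert sweep_age(0.05, 0.5, 1 / 20_000) == pytest.approx(198.069, abs=0.005)

    def test_decreasing_in_s(self):
        s = np.linspace(0.005, 0.2, 50)
        t = sweep_age(s, 0.3, 5e-5)
        assert np.all(np.diff(t) < 0)

    def test_logistic_trajectory_cross_check(self):
        """Integrating dy/dt = s y (1 - y) forward reproduces the closed form."""
        s, y0, target = 0.02, 5e-5, 0.4
        t_closed = sweep_age(s, target, y0)
        y, dt = y0, 0.01
        t = 0.0
        while y < target:
            y += dt * s * y * (1 - y)
            t += dt
        assert t == pytest.approx(t_closed, rel=1e-3)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            sweep_age(0.05, 1e-5, 1e-4)  # y below y0
        with pytest.raises(ValueError):
            sweep_age(-0.1, 0.5, 1e-4)


class TestNoRecombProb:
    def test_no_recombination_is_certain(self):
        assert no_recomb_prob(0.05, 0.0, 0.5, 5e-5) == 1.0

    def test_closed_form_identity(self, rng):
        """e^{-rt} (1 - y0 (1 - e^{st}))^{r/s} == (y0/y)^{r/s} to 12 digits."""
        for _ in range(200):
            s = rng.uniform(0.005, 0.3)
            r = rng.uniform(0, 0.49)
            y0 = 10 ** rng.uniform(-6, -2)
            y = rng.uniform(y0 * 1.5, 0.999)
            assert no_recomb_prob(s, r, y, y0) == pytest.approx(
                (y0 / y) ** (r / s), rel=1e-12
            )

    def test_reference_value(self):
        # r/s = 0.2 and y0/y = 1e-4
        assert no_recomb_prob(0.05, 0.01, 0.5, 5e-5) == pytest.approx(
            1e-4 ** 0.2, rel=1e-12
        )


class TestLogCompositeLikelihood:
    def test_linear_in_block_size(self, cfg):
        a = log_composite_likelihood(0.02, 0.01, 0.3, 10, cfg)
        b = log_composite_likelihood(0.02, 0.01, 0.3, 20, cfg)
        assert b == pytest.approx(2 * a, rel=1e-12)

    def test_matches_product_form(self, cfg, rng):
        """Log form equals ln of the product likelihood (2k-th power of the
        per-edge probabilities) within 1e-9 relative."""
        for _ in range(100):
            s = rng.uniform(0.01, 0.2)
            r = rng.uniform(1e-4, 0.05)
            y = rng.uniform(0.05, 0.95)
            k = int(rng.integers(2, 50))
            c_flank = no_recomb_prob(s, r, y, cfg.y0_single)
            c_edge = no_recomb_prob(s, cfg.delta_r, y, cfg.y0_single)
            expected = 2 * k * (np.log(c_flank) + np.log1p(-c_edge))
            got = log_composite_likelihood(s, r, y, k, cfg)
            assert got == pytest.approx(expected, rel=1e-9)

    def test_decreases_beyond_optimum(self, cfg):
        s_grid = np.linspace(0.5, 5.0, 20)
        ll = log_composite_likelihood(s_grid, 0.01, 0.5, 10, cfg)
        assert np.all(np.diff(ll) < 0)

    def test_invalid_s_rejected(self, cfg):
        with pytest.raises(ValueError):
            log_composite_likelihood(0.0, 0.01, 0.5, 10, cfg)


def golden_section_argmax(f, lo, hi, tol=1e-10):
    invphi = (np.sqrt(5) - 1) / 2
    a, b = lo, hi
    c, d = b - invphi * (b - a), a + invphi * (b - a)
    fc, fd = f(c), f(d)
    while b - a > tol:
        if fc > fd:
            b, d, fd = d, c, fc
            c = b - invphi * (b - a)
            fc = f(c)
        else:
            a, c, fc = c, d, fd
            d = a + invphi * (b - a)
            fd = f(d)
    return (a + b) / 2


class TestMclSelection:
    def test_reference_estimate_matches_grid_maximization(self, cfg):
        """r=0.01, dr=1e-4, y=0.5, Ne=10,000 -> s_hat ~ 0.0926, agreeing
        with an independent golden-section maximization to 4 digits."""
        s_hat, _, _, _, est = mcl_selection_arrays(0.01, 0.5, 100, cfg)
        assert est[0]
        assert s_hat[0] == pytest.approx(0.0926, abs=5e-5)
        argmax = golden_section_argmax(
            lambda s: log_composite_likelihood(s, 0.01, 0.5, 100, cfg), 1e-4, 1.0
        )
        assert s_hat[0] == pytest.approx(argmax, rel=1e-4)

    def test_maximizer_property_random_draws(self, cfg, rng):
        for _ in range(60):
            r = 10 ** rng.uniform(-4, -1.5)
            y = rng.uniform(0.01, 0.99)
            ne = rng.choice([1e3, 1e4, 1e5])
            dr = 10 ** rng.uniform(-7, -4)
            c = ModelConfig(ne=ne, delta_r=dr, s_min=0.005)
            s_hat, _, _, _, _ = mcl_selection_arrays(r, y, 10, c)
            argmax = golden_section_argmax(
                lambda s: log_composite_likelihood(s, r, y, 10, c), 1e-5, 1.0
            )
            assert s_hat[0] == pytest.approx(argmax, rel=1e-4)

    def test_monotone_in_r_and_y(self, cfg):
        r = np.linspace(1e-4, 0.05, 50)
        s_r, *_ = mcl_selection_arrays(r, np.full_like(r, 0.5), 10, cfg)
        assert np.all(np.diff(s_r) > 0)
        y = np.linspace(0.01, 0.99, 50)
        s_y, *_ = mcl_selection_arrays(np.full_like(y, 0.01), y, 10, cfg)
        assert np.all(np.diff(s_y) > 0)

    def test_degenerate_blocks_flagged_zero(self, cfg):
        s_hat, _, _, _, est = mcl_selection_arrays(
            [0.0, 0.01], [0.5, cfg.y0_single], 2, cfg, k_sample=100
        )
        assert not est.any()
        assert np.all(s_hat == 0.0)

    def test_age_ordering(self, cfg, rng):
        """t_hat1 > t_hat2 > 0 for every estimable block (y0 single < pair)."""
        r = 10 ** rng.uniform(-4, -2, size=50)
        y = rng.uniform(0.01, 0.99, size=50)
        _, _, t1, t2, est = mcl_selection_arrays(r, y, 5, cfg)
        assert est.all()
        assert np.all(t1 > t2) and np.all(t2 > 0)

    def test_fixed_block_substitution(self, cfg):
        """y = 1 blocks are dated one sample chromosome short of fixation."""
        s_hat, _, t1, _, est = mcl_selection_arrays(0.01, 1.0, 200, cfg, k_sample=200)
        s_ref, _, t1_ref, _, _ = mcl_selection_arrays(
            0.01, 1 - 1 / 400, 200, cfg, k_sample=200
        )
        assert est[0]
        assert s_hat[0] == s_ref[0]
        assert np.isfinite(t1[0]) and t1[0] == t1_ref[0]


def test_mean_delta_r_from_map():
    cm = np.array([0.0, 0.1, 0.2, 0.3])
    assert mean_delta_r(cm) == pytest.approx(haldane(0.1), rel=1e-12)


def test_model_config_invariants():
    c = ModelConfig(ne=10_000.0)
    assert c.y0_single == pytest.approx(5e-5)
    assert c.y0_pair == pytest.approx(1e-4)
    assert 0 < c.y0_single < c.y0_pair < 1
    with pytest.raises(ValueError):
        ModelConfig(ne=1.0)
    with pytest.raises(ValueError):
        ModelConfig(delta_r=0.7)
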