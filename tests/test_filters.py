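import numpy as np
import pytest
from scipy.integrate import quad
from scipy.linalg import expm
from scipy.stats import gamma as gamma_dist

from haploscan.filters import (
    DriftFilterParams,
    TmrcaLookupTable,
    adaptive_quantile,
    allele_age_cdf,
    allele_age_quantile,
    build_lookup_table,
    coalescent_filter,
    drift_filter,
    gamma_approx_params,
    tmrca_exact_cdf,
    tmrca_exact_quantile,
    tmrca_rates,
)
from haploscan.io_formats import read_lookup_table, write_lookup_table

NE = 10_000.0


def phase_type_cdf(t, lam):
    """Independent oracle: hypoexponential CDF via the stage-chain generator."""
    T = np.diag(-lam) + np.diag(lam[:-1], 1)
    return 1.0 - expm(T * t)[0].sum()


def phase_type_quantile(q, lam):
    from scipy.optimize import brentq

    mu = (1 / lam).sum()
    hi = 10 * mu
    while phase_type_cdf(hi, lam) < q:
        hi *= 2
    return brentq(lambda t: phase_type_cdf(t, lam) - q, 0, hi, xtol=1e-10 * mu)


class TestAlleleAge:
    def test_age_zero_value(self):
        assert allele_age_cdf(0.0, 0.5, 1000) == pytest.approx(0.5**999)

    def test_monotone_in_t(self, rng):
        t = np.sort(rng.uniform(0, 5, size=100))
        cdf = allele_age_cdf(t, 0.3, 500)
        assert np.all(np.diff(cdf) >= 0)

    def test_clipped_at_one(self):
        assert allele_age_cdf(1e9, 0.5, 1000) == 1.0

    @pytest.mark.parametrize("q", [1e-4, 1e-3, 1e-2])
    @pytest.mark.parametrize("p", [0.01, 0.5, 0.99])
    @pytest.mark.parametrize("n", [100, 2000])
    def test_quantile_inverts_cdf(self, q, p, n):
        t = allele_age_quantile(q, p, n)
        assert allele_age_cdf(t, p, n) == pytest.approx(q, rel=1e-9)

    def test_reference_quantile(self):
        assert allele_age_quantile(0.01, 0.5, 2000) == pytest.approx(0.26065, abs=5e-6)

    def test_larger_p_gives_older_quantile(self):
        t = [allele_age_quantile(0.01, p, 2000) for p in (0.1, 0.3, 0.5, 0.9)]
        assert np.all(np.diff(t) > 0)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            allele_age_cdf(1.0, 1.5, 100)
        with pytest.raises(ValueError):
            allele_age_quantile(0.0, 0.5, 100)


class TestAdaptiveQuantile:
    def test_always_clamped(self, rng):
        for _ in range(50):
            params = DriftFilterParams(
                p=float(rng.uniform(1e-3, 0.999)),
                n_chrom=int(rng.integers(10, 5000)),
                s_min=float(rng.uniform(0.001, 0.1)),
                ne=float(rng.choice([1e3, 1e4, 1e5])),
            )
            assert 0.0001 <= adaptive_quantile(params) <= 0.01

    def test_upper_clamp_hit(self):
        # rare block: q' far above 1% -> exactly the upper clamp
        params = DriftFilterParams(p=0.02, n_chrom=2000, s_min=0.005, ne=NE)
        assert adaptive_quantile(params) == 0.01

    def test_matches_hand_evaluated_chain(self):
        """Independent re-evaluation of the t' -> q' -> clamp chain."""
        p, n, s_min = 0.5, 2000, 0.005
        y0 = 1 / (2 * NE)
        t_prime = np.log(p * (1 - y0) / (y0 * (1 - p))) / s_min
        t_units = t_prime / (2 * NE)
        q_prime = (1 - p) ** (-1 + n / (1 + n * t_units / 2))
        expected = min(0.01, max(0.0001, q_prime))
        params = DriftFilterParams(p=p, n_chrom=n, s_min=s_min, ne=NE)
        assert adaptive_quantile(params) == pytest.approx(expected, rel=1e-12)

    def test_degenerate_rare_block(self):
        params = DriftFilterParams(p=1e-5, n_chrom=2000, s_min=0.005, ne=NE)
        assert adaptive_quantile(params) == 0.01


class TestDriftFilter:
    def test_vanishing_selection_fails(self):
        params = DriftFilterParams(p=0.5, n_chrom=2000, s_min=0.005, ne=NE)
        ok, thr = drift_filter(np.inf, params)  # s_hat -> 0 gives infinite age
        assert not ok and np.isfinite(thr)

    def test_age_zero_passes(self):
        params = DriftFilterParams(p=0.5, n_chrom=2000, s_min=0.005, ne=NE)
        ok, _ = drift_filter(0.0, params)
        assert ok

    def test_end_to_end_decision(self):
        """Ne=10,000, p=0.5, n=2000, s_hat=0.05: decision matches the fully
        hand-computed age-vs-threshold comparison."""
        s_hat, p, n = 0.05, 0.5, 2000
        y0 = 1 / (2 * NE)
        t_hat1 = np.log(p * (1 - y0) / (y0 * (1 - p))) / s_hat
        params = DriftFilterParams(p=p, n_chrom=n, s_min=0.005, ne=NE)
        q = adaptive_quantile(params)
        thr_expected = 2 * NE * (2 * np.log(1 - p) / (np.log(q) + np.log(1 - p)) - 2 / n)
        ok, thr = drift_filter(t_hat1, params)
        assert thr == pytest.approx(thr_expected, rel=1e-12)
        assert ok == (t_hat1 < thr_expected)
        assert ok  # a 198-generation sweep age is comfortably young


class TestTmrcaExact:
    def test_two_lineages_exponential(self):
        lam2 = 1 / NE  # i=2, r=0
        t = np.array([50.0, 200.0, 1000.0])
        got = tmrca_exact_cdf(t, 0.0, NE, 2)
        assert np.allclose(got, 1 - np.exp(-lam2 * t), rtol=1e-8)

    @pytest.mark.parametrize("k,r", [(3, 1e-4), (8, 1e-3), (32, 1e-2)])
    def test_mean_identity(self, k, r):
        """Mean of the distribution equals sum of stage means (survival
        function integration)."""
        lam = tmrca_rates(r, NE, k)
        mean_expected = (1 / lam).sum()
        mean_num, _ = quad(
            lambda t: 1 - tmrca_exact_cdf(t, r, NE, k), 0, 50 * mean_expected, limit=200
        )
        assert mean_num == pytest.approx(mean_expected, rel=1e-6)

    def test_stochastically_smaller_for_larger_r(self):
        t = 500.0
        cdfs = [tmrca_exact_cdf(t, r, NE, 8) for r in (0, 1e-4, 1e-3, 1e-2)]
        assert np.all(np.diff(cdfs) > 0)

    def test_large_k_route_agrees_with_phase_type(self):
        """Talbot inversion (large-k path) vs matrix exponential oracle."""
        for k, r in [(500, 0.0), (500, 1e-3), (800, 1e-4)]:
            lam = tmrca_rates(r, NE, k)
            for frac in (0.3, 1.0, 2.0):
                t = frac * (1 / lam).sum()
                assert tmrca_exact_cdf(t, r, NE, k) == pytest.approx(
                    phase_type_cdf(t, lam), abs=1e-7
                )

    def test_k_below_two_rejected(self):
        with pytest.raises(ValueError):
            tmrca_exact_cdf(100.0, 0.0, NE, 1)


class TestGammaApprox:
    def test_k2_exact_exponential(self):
        shape, scale = gamma_approx_params(1e-4, NE, 2)
        assert shape == 1.0
        assert scale == pytest.approx(1 / tmrca_rates(1e-4, NE, 2)[0], rel=1e-12)

    @pytest.mark.parametrize("k", [3, 8, 32])
    @pytest.mark.parametrize("r", [1e-6, 1e-4, 1e-2])
    def test_mean_conserved(self, k, r):
        shape, scale = gamma_approx_params(r, NE, k)
        mu = (1 / tmrca_rates(r, NE, k)).sum()
        assert shape * scale == pytest.approx(mu, rel=1e-9)

    @pytest.mark.parametrize("k", [3, 8, 32])
    @pytest.mark.parametrize("r", [1e-6, 1e-4, 1e-2])
    def test_first_percentile_within_15pct_of_oracle(self, k, r):
        shape, scale = gamma_approx_params(r, NE, k)
        q_gamma = gamma_dist.ppf(0.01, shape, scale=scale)
        q_oracle = phase_type_quantile(0.01, tmrca_rates(r, NE, k))
        assert q_gamma == pytest.approx(q_oracle, rel=0.15)

    def test_scale_within_printed_bounds(self):
        for k in (3, 8, 32, 200):
            for r in (0.0, 1e-6, 1e-4, 1e-2):
                shape, scale = gamma_approx_params(r, NE, k)
                beta = 1 / tmrca_rates(r, NE, k)
                assert beta.sum() / (k - 1) <= scale <= beta.max() * (1 + 1e-9)


@pytest.fixture(scope="module")
def table():
    return build_lookup_table(NE, k_max=64)


class TestLookupTable:
    def test_monotone_invariants(self, table):
        assert np.all(table.q01 > 0)
        # more recombination shifts the distribution left: non-increasing in r
        assert np.all(np.diff(table.q01, axis=1) <= 1e-9)
        # more lineages add coalescence stages: non-decreasing in k
        # (confirmed against the phase-type oracle in TestGammaApprox)
        assert np.all(np.diff(table.q01, axis=0) >= -1e-9)

    def test_rebuild_is_bit_identical(self, table):
        again = build_lookup_table(NE, k_max=64)
        assert np.array_equal(table.q01, again.q01)

    def test_serialization_round_trip_exact(self, table, tmp_path):
        path = tmp_path / "table.tsv"
        write_lookup_table(table, path)
        back = read_lookup_table(path)
        assert back.ne == table.ne
        assert np.array_equal(back.k_grid, table.k_grid)
        assert np.array_equal(back.r_grid, table.r_grid)
        assert np.array_equal(back.q01, table.q01)

    def test_lookup_exact_at_grid_nodes(self, table):
        for a in (0, 3, len(table.k_grid) - 1):
            for b in (0, 1, 10, len(table.r_grid) - 1):
                got = table.lookup(int(table.k_grid[a]), float(table.r_grid[b]))[0]
                assert got == pytest.approx(table.q01[a, b], rel=1e-12)

    def test_interpolation_within_5pct_of_direct(self, table, rng):
        """100 random off-grid (k, r) points vs directly computed q01."""
        for _ in range(100):
            k = int(rng.integers(2, 65))
            r = float(10 ** rng.uniform(-7, -1.5))
            interp = table.lookup(k, r)[0]
            shape, scale = gamma_approx_params(r, NE, k)
            direct = gamma_dist.ppf(0.01, shape, scale=scale)
            assert interp == pytest.approx(direct, rel=0.05)


class TestCoalescentFilter:
    def test_age_zero_passes(self, table):
        ok, thr = coalescent_filter(0.0, 10, 1e-3, table)
        assert ok and thr > 0

    def test_infinite_age_fails(self, table):
        """s_hat -> 0 gives an infinite age estimate: plausibly neutral."""
        ok, _ = coalescent_filter(np.inf, 10, 1e-3, table)
        assert not ok

    def test_end_to_end_decision(self, table):
        """|K|=10, r=1e-3, s_hat=0.05, y=0.3: decision equals the
        hand-evaluated age-vs-first-percentile comparison."""
        s_hat, y = 0.05, 0.3
        t_hat2 = np.log(y * (1 - 1 / NE) / ((1 / NE) * (1 - y))) / s_hat
        shape, scale = gamma_approx_params(1e-3, NE, 10)
        q01 = gamma_dist.ppf(0.01, shape, scale=scale)
        ok, thr = coalescent_filter(t_hat2, 10, 1e-3, table)
        assert thr == pytest.approx(q01, rel=0.05)  # table interpolates
        assert ok == (t_hat2 < thr)



def test_filter_verdict_combines_both_filters(table):
    from haploscan.filters import evaluate_filters

    params = DriftFilterParams(p=0.3, n_chrom=2000, s_min=0.005, ne=NE)
    v = evaluate_filters(t_hat1=150.0, t_hat2=120.0, k_block=10, r=1e-3,
                         params=params, table=table)
    d_ok, d_thr = drift_filter(150.0, params)
    c_ok, c_thr = coalescent_filter(120.0, 10, 1e-3, table)
    assert (v.pass_drift, v.pass_coalescent) == (d_ok, c_ok)
    assert (v.drift_threshold, v.coalescent_threshold) == (d_thr, c_thr)
    assert v.reported == (d_ok and c_ok)


def test_filter_composition_order_independent(rng):
    """Drift and coalescent filters are independent predicates: applying
    them in either order keeps exactly the same blocks."""
    table = build_lookup_table(NE, k_max=32)
    n = 200
    t1 = 10 ** rng.uniform(1, 4, size=n)
    t2 = t1 * rng.uniform(0.5, 0.99, size=n)
    p = rng.uniform(0.005, 0.9, size=n)
    k = rng.integers(2, 33, size=n)
    r = 10 ** rng.uniform(-6, -2, size=n)
    from haploscan.filters import coalescent_filter_arrays, drift_filter_arrays

    d, _ = drift_filter_arrays(t1, p, 2000, 0.005, NE)
    c, _ = coalescent_filter_arrays(t2, k, r, table)
    both_a = d & c
    c2, _ = coalescent_filter_arrays(t2, k, r, table)
    d2, _ = drift_filter_arrays(t1, p, 2000, 0.005, NE)
    both_b = c2 & d2
    assert np.array_equal(both_a, both_b)
    assert np.array_equal(both_a, d & c)
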