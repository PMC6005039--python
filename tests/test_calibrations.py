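import math

import numpy as np
import pytest
from scipy import integrate, stats

from chronodate.calibrations import (
    GammaDensity,
    SkewNormalMixture,
    SkewT,
    SoftBoundUniform,
    TruncatedCauchy,
    fit_gamma_moments,
    fit_skew_t_ml,
    parse_calibration,
)

# the published calibration set exercised throughout: all five families
PUBLISHED = [
    "B(0.075,0.10,0.01,0.20)",
    "B(0.112,0.28,0.01,0.10)",
    "B(0.25,0.337,0.01,0.10)",
    "ST(0.4754,0.0632,0.98,22.85)",
    "S2N(0.474,0.65,0.0365,-3400,0.6502,0.1375,11409)",
    "G(36,36.9)",
    "L(0.0725,0.1,2,0.05)",
    "L(0.556,0.1,2,0.05)",
]


@pytest.mark.parametrize("text", PUBLISHED)
def test_density_normalization_and_quantile_inversion(text):
    """Every family integrates to 1 on (0, inf) and cdf inverts quantile."""
    d = parse_calibration(text)
    # integrate up to the 1 - 1e-7 quantile; the heavy Cauchy tail makes a
    # full (0, inf) quadrature ill-conditioned, so the cap carries the rest
    cap = 1e-7
    hi = d.quantile(1 - cap)
    lo = min(d._bracket()[0], 0.0)
    mass, _ = integrate.quad(d.pdf, max(lo, 0), hi, limit=400, points=[d.quantile(0.5)])
    assert mass == pytest.approx(1.0 - cap, abs=1e-6)
    for q in (0.025, 0.25, 0.5, 0.9, 0.975):
        t = d.quantile(q)
        assert d.cdf(t) == pytest.approx(q, abs=1e-8)


def test_soft_bound_mass_split_is_exact():
    d = SoftBoundUniform(0.112, 0.28, 0.01, 0.10)
    assert d.cdf(0.112) == pytest.approx(0.01)
    assert d.cdf(0.28) == pytest.approx(1 - 0.10)
    core, _ = integrate.quad(d.pdf, 0.112, 0.28)
    assert core == pytest.approx(0.89, abs=1e-9)
    # density continuous at both bounds
    h = (1 - 0.01 - 0.10) / (0.28 - 0.112)
    assert d.pdf(0.112 - 1e-9) == pytest.approx(h, rel=1e-4)
    assert d.pdf(0.28 + 1e-9) == pytest.approx(h, rel=1e-4)


def test_soft_bound_two_argument_form_has_default_tails():
    d = parse_calibration("B(0.99,1.01)")
    assert d.params == (0.99, 1.01, 0.025, 0.025)


def test_truncated_cauchy_contract():
    d = TruncatedCauchy(0.337, 0.1, 2, 0.05)
    assert d.cdf(0.337) == pytest.approx(0.05)
    # mode at t_min*(1+p); density decreasing on both sides of it
    mode = 0.337 * 1.1
    grid = np.linspace(0.337, 3.0, 400)
    vals = d.pdf(grid)
    assert grid[np.argmax(vals)] == pytest.approx(mode, abs=0.01)


def test_gamma_mean_and_published_intervals():
    g40 = GammaDensity(2, 40)
    assert g40.a / g40.b == pytest.approx(0.05)
    assert g40.quantile(0.025) == pytest.approx(0.00606, abs=5e-6)
    assert g40.quantile(0.975) == pytest.approx(0.139, abs=5e-4)
    g8 = GammaDensity(2, 8)
    assert g8.quantile(0.025) == pytest.approx(0.0302, abs=1e-4)  # printed to 3 s.f.
    assert g8.quantile(0.975) == pytest.approx(0.696, abs=5e-4)


def test_skew_t_symmetric_large_df_limits():
    # alpha=0, huge df: collapses to a normal
    st = SkewT(0.5, 0.05, 0.0, 1e6)
    assert st.pdf(0.5) == pytest.approx(stats.norm.pdf(0.5, 0.5, 0.05), rel=1e-4)
    # alpha=0 equals Student-t at any df
    st2 = SkewT(0.0, 1.0, 0.0, 5.0)
    grid = np.linspace(-3, 3, 20)
    assert np.allclose(st2.pdf(grid), stats.t.pdf(grid, df=5), rtol=1e-10)
    # nu -> inf equals a skew-normal
    st3 = SkewT(0.2, 0.1, 2.0, 1e6)
    sn = stats.skewnorm(2.0, loc=0.2, scale=0.1)
    grid = np.linspace(0.0, 0.6, 20)
    assert np.allclose(st3.pdf(grid), sn.pdf(grid), rtol=1e-4)


def test_s2n_degenerates_to_first_component():
    mix = SkewNormalMixture(1 - 1e-12, 0.65, 0.0365, -3.0, 2.0, 0.1, 1.0)
    sn = stats.skewnorm(-3.0, loc=0.65, scale=0.0365)
    grid = np.linspace(0.4, 0.8, 30)
    assert np.allclose(mix.pdf(grid), sn.pdf(grid), rtol=1e-9)


class TestSampling:
    def test_gamma_sample_mean(self):
        d = GammaDensity(2, 8)
        x = d.sample(100000, seed=1)
        se = math.sqrt(2 / 8**2 / x.size)
        assert abs(x.mean() - 0.25) < 3 * se

    def test_soft_bound_tail_mass(self):
        d = SoftBoundUniform(0.25, 0.337, 0.01, 0.10)
        x = d.sample(100000, seed=2)
        frac = np.mean(x < 0.25)
        se = math.sqrt(0.01 * 0.99 / x.size)
        assert abs(frac - 0.01) < 3 * se

    def test_skew_t_sampler_matches_numeric_cdf(self):
        d = SkewT(0.5, 0.05, 3.0, 20.0)
        x = d.sample(10000, seed=3)
        res = stats.kstest(x, d.cdf)
        assert res.pvalue > 0.01

    def test_reproducible_under_seed(self):
        d = TruncatedCauchy(0.45, 0.1, 2)
        assert np.array_equal(d.sample(50, seed=9), d.sample(50, seed=9))


class TestFitting:
    def test_skew_t_ml_recovers_quantiles(self):
        truth = SkewT(0.5, 0.05, 3.0, 20.0)
        x = truth.sample(100000, seed=4)
        fit = fit_skew_t_ml(x, seed=0)
        assert fit.converged
        for q in (0.025, 0.5, 0.975):
            assert fit.density.quantile(q) == pytest.approx(truth.quantile(q), rel=0.02)

    def test_symmetric_data_gives_small_alpha(self):
        rng = np.random.default_rng(5)
        x = rng.normal(1.0, 0.1, size=20000)
        fit = fit_skew_t_ml(x, seed=0)
        assert abs(fit.density.alpha) <= 0.3

    def test_degenerate_input_flagged_not_crashed(self):
        fit = fit_skew_t_ml(np.full(10, 0.5))
        assert not fit.converged

    def test_gamma_moments_algebra(self):
        rng = np.random.default_rng(6)
        x = rng.gamma(78.6, 1 / 77.6, size=200000)
        d = fit_gamma_moments(x)
        assert d.a / d.b == pytest.approx(float(np.mean(x)), rel=1e-9)
        assert d.a / d.b**2 == pytest.approx(float(np.var(x, ddof=1)), rel=1e-9)

    def test_gamma_moments_scaling_law(self):
        rng = np.random.default_rng(7)
        x = rng.gamma(3.0, 2.0, size=5000)
        d1 = fit_gamma_moments(x)
        d2 = fit_gamma_moments(10 * x)
        assert d2.a == pytest.approx(d1.a, rel=1e-9)  # shape is dimensionless
        assert d2.b == pytest.approx(d1.b / 10, rel=1e-9)

    def test_gamma_moments_recovers_exponential_shape(self):
        rng = np.random.default_rng(8)
        x = rng.exponential(scale=2.0, size=100000)
        d = fit_gamma_moments(x)
        assert d.a == pytest.approx(1.0, rel=0.05)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            fit_gamma_moments(np.full(10, 1.0))


class TestValidation:
    @pytest.mark.parametrize(
        "bad",
        [
            lambda: SoftBoundUniform(0.3, 0.2, 0.01, 0.01),
            lambda: SoftBoundUniform(0.1, 0.2, 0.6, 0.5),
            lambda: TruncatedCauchy(-1.0),
            lambda: SkewT(0, -1, 0, 10),
            lambda: SkewNormalMixture(1.5, 0, 1, 0, 1, 1, 0),
            lambda: GammaDensity(0, 1),
        ],
    )
    def test_invalid_parameters_fail_at_construction(self, bad):
        with pytest.raises(ValueError):
            bad()

    def test_quantile_level_out_of_range(self):
        with pytest.raises(ValueError):
            GammaDensity(2, 8).quantile(1.2)
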