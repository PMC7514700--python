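"""Scalar Gaussian predictive coders: closed forms, oracles, invariances."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import integrate
from scipy.special import gammaln

from atypicality.core import LN2, DegenerateStatistics, InsufficientData
from atypicality.scalar import (
    GaussianStats,
    nlm_var_pred,
    ordinary_pred,
    redundancy_comparison,
    ssm_mean_pred,
    ssm_mean_var_pred,
    ssm_var_pred,
    staged_bits_mean_var,
    staged_bits_var,
)


def stats_of(values):
    st_ = GaussianStats()
    for v in values:
        st_.push(v)
    return st_


class TestGaussianStats:
    @given(st.lists(st.floats(min_value=-50, max_value=50), min_size=1, max_size=30))
    def test_totals_order_insensitive(self, values):
        a = stats_of(values)
        b = stats_of(values[::-1])
        assert a.n == b.n == len(values)
        assert a.sum_x == pytest.approx(b.sum_x, abs=1e-9)
        assert a.sum_x2 == pytest.approx(b.sum_x2, abs=1e-9)
        # Cauchy-Schwarz on moments
        assert a.sum_x2 * a.n >= a.sum_x**2 - 1e-9

    def test_derived_quantities(self):
        s = stats_of([1.0, 3.0])
        assert s.mean == 2.0
        assert s.raw_var == 5.0
        assert s.centered_ss == pytest.approx(2.0)
        assert s.s2 == pytest.approx(2.0)


class TestSsmMean:
    def test_first_sample_inflated_variance(self):
        # n=1 history: predictive variance sigma^2 (1 + 1/n) = 2
        s = stats_of([0.0])
        assert ssm_mean_pred(s, 1.0, 0.0) == pytest.approx(
            1.0 / math.sqrt(4 * math.pi), rel=1e-12
        )

    def test_large_n_approaches_plugin(self):
        s = stats_of([0.1] * 100000)
        plugin = math.exp(-0.5 * math.log(2 * math.pi) - 0.5 * (1.0 - 0.1) ** 2)
        assert ssm_mean_pred(s, 1.0, 1.0) == pytest.approx(plugin, rel=1e-4)

    def test_normalizes(self):
        s = stats_of([0.7, -0.2])
        val, _ = integrate.quad(lambda x: ssm_mean_pred(s, 2.0, x), -np.inf, np.inf)
        assert val == pytest.approx(1.0, abs=1e-8)

    def test_requires_history(self):
        with pytest.raises(InsufficientData):
            ssm_mean_pred(GaussianStats(), 1.0, 0.0)


class TestSsmVar:
    def test_one_sample_closed_form(self):
        # with history (1,), the density at 0 reduces to |x1| / (pi (x1^2 + x2^2))
        s = stats_of([1.0])
        assert ssm_var_pred(s, 0.0) == pytest.approx(1.0 / math.pi, rel=1e-12)

    def test_matches_posterior_integration(self):
        # oracle: average N(x; 0, v) over the inverse-chi-square law of v
        x1, x2 = 0.8, -1.3
        s = stats_of([x1])
        n, vhat = 1, x1**2

        def integrand(v):
            post = (
                (n * vhat / 2.0) ** (n / 2.0)
                / math.gamma(n / 2.0)
                * v ** (-(n + 2) / 2.0)
                * math.exp(-n * vhat / (2.0 * v))
            )
            return post * math.exp(-0.5 * math.log(2 * math.pi * v) - x2**2 / (2 * v))

        val, _ = integrate.quad(integrand, 0, np.inf)
        assert ssm_var_pred(s, x2) == pytest.approx(val, rel=1e-8)

    def test_second_sample_codelength_printed_form(self):
        # L(x2) = log((x1^2+x2^2)/|x1|) + log(sqrt(pi) Gamma(1/2) / Gamma(1))
        x1, x2 = 0.37, -2.1
        s = stats_of([x1])
        bits = -math.log2(ssm_var_pred(s, x2))
        expected = (
            math.log((x1**2 + x2**2) / abs(x1))
            + math.log(math.sqrt(math.pi) * math.gamma(0.5) / math.gamma(1.0))
        ) / LN2
        assert bits == pytest.approx(expected, abs=1e-10)

    def test_even_symmetry(self):
        s = stats_of([0.5, -1.0, 2.0])
        assert ssm_var_pred(s, 1.3) == pytest.approx(ssm_var_pred(s, -1.3), rel=1e-14)

    def test_normalizes(self):
        s = stats_of([0.5, -1.0, 2.0])
        val, _ = integrate.quad(lambda x: ssm_var_pred(s, x), -np.inf, np.inf)
        assert val == pytest.approx(1.0, abs=1e-6)

    def test_degenerate_history_rejected(self):
        with pytest.raises(DegenerateStatistics):
            ssm_var_pred(stats_of([0.0, 0.0]), 1.0)


class TestNlmVar:
    def test_matches_quadrature_ratio(self):
        # C(x^n) = integral of the zero-mean likelihood over the variance
        hist = [0.3, -1.2, 0.7]
        x4 = 0.45

        def C(xs):
            xs = np.asarray(xs)

            def lik(v):
                return (2 * math.pi * v) ** (-len(xs) / 2.0) * math.exp(
                    -0.5 * float(xs @ xs) / v
                )

            val, _ = integrate.quad(lik, 0, np.inf)
            return val

        oracle = C(hist + [x4]) / C(hist)
        assert nlm_var_pred(stats_of(hist), x4) == pytest.approx(oracle, rel=1e-6)

    @given(st.floats(min_value=0.05, max_value=20.0))
    def test_scale_equivariance(self, a):
        # y = a x transforms the density by 1/a
        hist = [0.3, -1.2, 0.7]
        x4 = 0.45
        base = nlm_var_pred(stats_of(hist), x4)
        scaled = nlm_var_pred(stats_of([a * v for v in hist]), a * x4)
        assert scaled == pytest.approx(base / a, rel=1e-9)

    def test_normalizes(self):
        s = stats_of([0.3, -1.2, 0.7])
        val, _ = integrate.quad(lambda x: nlm_var_pred(s, x), -np.inf, np.inf)
        assert val == pytest.approx(1.0, abs=1e-6)

    def test_needs_three_samples(self):
        # Gamma((n-2)/2) diverges at n=2, so the NLM starts at n=3
        with pytest.raises(InsufficientData):
            nlm_var_pred(stats_of([1.0, 2.0]), 0.0)


class TestSsmMeanVar:
    def test_location_invariance(self):
        hist = [0.2, 1.4, -0.7]
        x, b = 0.9, 5.3
        base = ssm_mean_var_pred(stats_of(hist), x)
        shifted = ssm_mean_var_pred(stats_of([v + b for v in hist]), x + b)
        assert shifted == pytest.approx(base, rel=1e-10)

    def test_normalizes_smallest_n(self):
        s = stats_of([0.0, 1.0])
        val, _ = integrate.quad(lambda x: ssm_mean_var_pred(s, x), -np.inf, np.inf)
        assert val == pytest.approx(1.0, abs=1e-6)

    def test_constant_history_rejected(self):
        with pytest.raises(DegenerateStatistics):
            ssm_mean_var_pred(stats_of([2.0, 2.0]), 0.0)


class TestOrdinary:
    def test_plugin_density(self):
        s = stats_of([2.0])
        assert ordinary_pred(s, 0.0) == pytest.approx(
            1.0 / math.sqrt(8 * math.pi), rel=1e-12
        )

    def test_second_sample_codelength_printed_form(self):
        # L(x2) = 1/2 log(2 pi x1^2) + (x2^2 / x1^2) log(e) / 2
        x1, x2 = 0.37, -2.1
        bits = -math.log2(ordinary_pred(stats_of([x1]), x2))
        expected = (0.5 * math.log(2 * math.pi * x1**2) + 0.5 * x2**2 / x1**2) / LN2
        assert bits == pytest.approx(expected, abs=1e-10)


class TestReparameterizationInvariance:
    def test_sigma_parameterization_gives_same_predictive(self, rng):
        # re-derive the SSM unknown-variance predictive by parameterizing in
        # sigma instead of sigma^2: with n vhat / sigma^2 ~ chi2(n), sigma =
        # sqrt(n vhat / z) has density f_sigma(s) = f_{sigma^2}(s^2) * 2 s;
        # averaging the data model over it must give the same density
        hist = rng.normal(size=4)
        s = stats_of(hist)
        n, vhat = s.n, s.raw_var

        def sigma_density(sig):
            v = sig * sig
            f_v = (
                (n * vhat / 2.0) ** (n / 2.0)
                / math.gamma(n / 2.0)
                * v ** (-(n + 2) / 2.0)
                * math.exp(-n * vhat / (2.0 * v))
            )
            return f_v * 2.0 * sig

        for x in rng.normal(scale=2.0, size=20):
            val, _ = integrate.quad(
                lambda sig: sigma_density(sig)
                * math.exp(-0.5 * math.log(2 * math.pi * sig**2) - x**2 / (2 * sig**2)),
                0,
                np.inf,
            )
            assert val == pytest.approx(ssm_var_pred(s, x), rel=1e-3)


class TestStagedStreams:
    def test_sequential_consistency_with_pointwise(self, rng):
        # vectorized staged bits equal the per-sample predictive increments
        x = rng.normal(size=64)
        bits = staged_bits_mean_var(x, 2.05)
        assert bits[0] == pytest.approx(2.05)
        s = stats_of(x[:1])
        assert bits[1] == pytest.approx(-math.log2(ssm_var_pred(s, x[1])), abs=1e-8)
        for i in range(2, 64):
            si = stats_of(x[:i])
            assert bits[i] == pytest.approx(
                -math.log2(ssm_mean_var_pred(si, x[i])), abs=1e-8
            )

    def test_nlm_stream_telescopes(self, rng):
        # sum of NLM increments from n0=3 equals log C(x^3) - log C(x^l)
        x = rng.normal(size=40)

        def logC(xs):
            n = len(xs)
            s = float(np.sum(np.square(xs)))
            return (
                -(n / 2.0) * math.log(math.pi)
                - math.log(2.0)
                + gammaln((n - 2) / 2.0)
                - ((n - 2) / 2.0) * math.log(s)
            )

        inc = sum(
            -math.log2(nlm_var_pred(stats_of(x[:i]), x[i])) for i in range(3, 40)
        )
        assert inc == pytest.approx((logC(x[:3]) - logC(x)) / LN2, abs=1e-8)

    def test_degenerate_prefix_falls_back_to_default(self):
        bits = staged_bits_mean_var(np.array([0.0, 0.0, 1.0, 2.0]), 3.0)
        assert bits[0] == 3.0
        assert bits[1] == 3.0  # all-zero history
        assert np.isfinite(bits[2:]).all()

    def test_var_ladder_matches_ssm(self, rng):
        x = rng.normal(size=16)
        bits = staged_bits_var(x, 1.5)
        for i in range(1, 16):
            assert bits[i] == pytest.approx(
                -math.log2(ssm_var_pred(stats_of(x[:i]), x[i])), abs=1e-9
            )


class TestRedundancy:
    def test_ssm_suppresses_plugin_tail(self, rng):
        red = redundancy_comparison(2000, 8, 4.0, rng)
        assert red["ssm"].mean() < red["ordinary"].mean()
        assert np.percentile(red["ssm"], 99) < np.percentile(red["ordinary"], 99)
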