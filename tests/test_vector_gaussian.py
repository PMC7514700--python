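"""Vector Gaussian predictive coders: reductions, oracles, invariances."""

import math

import numpy as np
import pytest
from scipy.stats import invwishart, ortho_group

from atypicality.core import DegenerateStatistics, InsufficientData
from atypicality.scalar import (
    GaussianStats,
    nlm_var_pred,
    ssm_mean_pred,
    ssm_mean_var_pred,
    ssm_var_pred,
    staged_bits_mean_var,
)
from atypicality.vector import (
    VectorStats,
    VectorStreamCoder,
    from_rows,
    nlm_cov_pred,
    nlm_mean_cov_pred,
    pred_mean_knownSigma,
    ssm_cov_pred,
    ssm_isotropic_pred,
    ssm_mean_cov_pred,
    ssm_mean_cov_logpdf,
)


def scalar_stats(values):
    s = GaussianStats()
    for v in values:
        s.push(v)
    return s


@pytest.fixture
def history(rng):
    return rng.normal(size=(8, 1))


class TestReductions:
    """Every M=1 vector density must reduce to its scalar counterpart."""

    def test_cov_ssm_reduces_to_scalar(self, history):
        st, gs = from_rows(history), scalar_stats(history.ravel())
        assert ssm_cov_pred(st, [0.37]) == pytest.approx(
            ssm_var_pred(gs, 0.37), rel=1e-10
        )

    def test_cov_nlm_reduces_to_scalar(self, history):
        st, gs = from_rows(history), scalar_stats(history.ravel())
        assert nlm_cov_pred(st, [0.37]) == pytest.approx(
            nlm_var_pred(gs, 0.37), rel=1e-10
        )

    def test_mean_cov_ssm_reduces_to_scalar(self, history):
        st, gs = from_rows(history), scalar_stats(history.ravel())
        assert ssm_mean_cov_pred(st, [0.37]) == pytest.approx(
            ssm_mean_var_pred(gs, 0.37), rel=1e-10
        )

    def test_known_sigma_reduces_to_scalar(self, history):
        st, gs = from_rows(history), scalar_stats(history.ravel())
        assert pred_mean_knownSigma(st, [[2.0]], [0.37]) == pytest.approx(
            ssm_mean_pred(gs, 2.0, 0.37), rel=1e-10
        )

    def test_isotropic_reduces_to_scalar(self, history):
        gs = scalar_stats(history.ravel())
        assert ssm_isotropic_pred(
            8, float(np.sum(history**2)), 1, [0.37]
        ) == pytest.approx(ssm_var_pred(gs, 0.37), rel=1e-10)


class TestKnownSigmaMean:
    def test_zero_history_closed_form(self):
        # n=1 at the origin with Sigma = I: (4 pi)^{-M/2}
        M = 3
        st = from_rows(np.zeros((1, M)))
        assert pred_mean_knownSigma(st, np.eye(M), np.zeros(M)) == pytest.approx(
            (4 * math.pi) ** (-M / 2.0), rel=1e-12
        )

    def test_ratio_form_identity(self, rng):
        # independent oracle: the NLM ratio C(x^{n+1})/C(x^n) written via
        # exponential traces equals the closed-form N(mean, (1+1/n) Sigma)
        M = 2
        rows = rng.normal(size=(5, M))
        A = rng.normal(size=(M, M))
        Sigma = A @ A.T + M * np.eye(M)
        Sinv = np.linalg.inv(Sigma)
        st = from_rows(rows)
        n = st.n

        def etr_term(rows_):
            s = from_rows(rows_)
            mat = s.raw_scatter - s.n * np.outer(s.mean, s.mean)
            return math.exp(-0.5 * float(np.trace(mat @ Sinv)))

        for _ in range(20):
            x = rng.normal(size=M)
            ratio = (
                (n / (n + 1)) ** (M / 2.0)
                * (2 * math.pi) ** (-M / 2.0)
                * np.linalg.det(Sigma) ** -0.5
                * etr_term(np.vstack([rows, x]))
                / etr_term(rows)
            )
            assert pred_mean_knownSigma(st, Sigma, x) == pytest.approx(
                ratio, rel=1e-9
            )

    def test_rejects_non_spd_sigma(self):
        st = from_rows(np.ones((2, 2)))
        with pytest.raises(DegenerateStatistics):
            pred_mean_knownSigma(st, np.array([[1.0, 2.0], [2.0, 1.0]]), [0.0, 0.0])


class TestCovSSM:
    def test_inverse_wishart_monte_carlo_oracle(self):
        # construction oracle: Sigma | scatter ~ InvWishart(scatter, n);
        # the predictive is the average of N(0, Sigma) over that law
        rows = np.array([[1.0, 0.2], [-0.3, 0.8]])
        st = from_rows(rows)
        x = np.array([0.5, -0.1])
        draws = invwishart(df=2, scale=st.raw_scatter).rvs(
            size=120_000, random_state=np.random.default_rng(7)
        )
        _, ld = np.linalg.slogdet(draws)
        sol = np.linalg.solve(draws, np.broadcast_to(x, (len(draws), 2))[..., None])
        q = np.sum(x * sol[..., 0], axis=1)
        dens = np.exp(-0.5 * (2 * np.log(2 * np.pi) + ld + q))
        mc, se = dens.mean(), dens.std() / math.sqrt(len(dens))
        assert abs(ssm_cov_pred(st, x) - mc) < 3 * se

    def test_rotation_invariance(self, rng):
        M = 3
        rows = rng.normal(size=(6, M))
        Q = ortho_group.rvs(M, random_state=np.random.default_rng(5))
        x = rng.normal(size=M)
        assert ssm_cov_pred(from_rows(rows @ Q.T), Q @ x) == pytest.approx(
            ssm_cov_pred(from_rows(rows), x), rel=1e-9
        )

    def test_needs_full_rank_scatter(self):
        with pytest.raises(InsufficientData):
            ssm_cov_pred(from_rows(np.ones((1, 2))), [0.0, 0.0])


class TestCovNLM:
    def test_minimal_n_is_2m_plus_1(self, rng):
        M = 2
        rows = rng.normal(size=(2 * M + 1, M))
        assert nlm_cov_pred(from_rows(rows), rng.normal(size=M)) > 0
        with pytest.raises(InsufficientData):
            nlm_cov_pred(from_rows(rows[:-1]), rng.normal(size=M))

    def test_scale_equivariance(self, rng):
        # y = a x divides the M-dim density by a^M
        M, a = 2, 3.7
        rows = rng.normal(size=(7, M))
        x = rng.normal(size=M)
        assert nlm_cov_pred(from_rows(a * rows), a * x) == pytest.approx(
            nlm_cov_pred(from_rows(rows), x) / a**M, rel=1e-9
        )

    def test_normalizes_on_grid(self, rng):
        rows = rng.normal(size=(12, 2))
        st = from_rows(rows)
        g = np.linspace(-14, 14, 281)
        pts = np.stack(np.meshgrid(g, g), axis=-1).reshape(-1, 2)
        total = nlm_cov_pred(st, pts).sum() * (g[1] - g[0]) ** 2
        assert total == pytest.approx(1.0, abs=1e-4)


class TestMeanCov:
    def test_affine_invariance(self, rng):
        M = 2
        rows = rng.normal(size=(8, M))
        b = np.array([3.0, -7.0])
        x = rng.normal(size=M)
        for fn in (ssm_mean_cov_pred, nlm_mean_cov_pred):
            assert fn(from_rows(rows + b), x + b) == pytest.approx(
                fn(from_rows(rows), x), rel=1e-9
            )

    def test_both_normalize_on_grid(self, rng):
        rows = rng.normal(size=(12, 2))
        st = from_rows(rows)
        g = np.linspace(-14, 14, 281)
        pts = np.stack(np.meshgrid(g, g), axis=-1).reshape(-1, 2)
        dx2 = (g[1] - g[0]) ** 2
        assert ssm_mean_cov_pred(st, pts).sum() * dx2 == pytest.approx(1.0, abs=1e-4)
        assert nlm_mean_cov_pred(st, pts).sum() * dx2 == pytest.approx(1.0, abs=1e-4)

    def test_nlm_minimal_n_is_2m_plus_2(self, rng):
        M = 2
        rows = rng.normal(size=(2 * M + 2, M))
        assert nlm_mean_cov_pred(from_rows(rows), rng.normal(size=M)) > 0
        with pytest.raises(InsufficientData):
            nlm_mean_cov_pred(from_rows(rows[:-1]), rng.normal(size=M))


class TestIsotropic:
    def test_spherical_symmetry(self, rng):
        w = rng.normal(size=3)
        r = np.linalg.norm(w)
        other = np.array([r, 0.0, 0.0])
        assert ssm_isotropic_pred(5, 7.3, 3, w) == pytest.approx(
            ssm_isotropic_pred(5, 7.3, 3, other), rel=1e-12
        )

    def test_normalizes_dim2(self):
        g = np.linspace(-18, 18, 361)
        pts = np.stack(np.meshgrid(g, g), axis=-1).reshape(-1, 2)
        total = ssm_isotropic_pred(6, 11.0, 2, pts).sum() * (g[1] - g[0]) ** 2
        assert total == pytest.approx(1.0, abs=1e-4)


class TestStreamCoder:
    def test_first_vector_coded_as_scalar_stream(self, rng):
        M = 3
        x1 = rng.normal(size=M)
        coder = VectorStreamCoder(M, model="mean_cov", method="ssm", default_bits=2.0)
        bits = coder.push(x1)
        assert bits == pytest.approx(
            float(staged_bits_mean_var(x1, 2.0).sum()), abs=1e-12
        )

    def test_switches_to_vector_coder_when_defined(self, rng):
        M = 2
        rows = rng.normal(size=(6, M))
        coder = VectorStreamCoder(M, model="mean_cov", method="ssm")
        per = coder.stream_bits(rows)
        st = from_rows(rows[:5])
        assert per[5] == pytest.approx(
            -math.log2(ssm_mean_cov_pred(st, rows[5])), abs=1e-9
        )

    def test_vectorized_logpdf_matches_scalar_calls(self, rng):
        rows = rng.normal(size=(9, 2))
        st = from_rows(rows)
        pts = rng.normal(size=(5, 2))
        batch = ssm_mean_cov_logpdf(st, pts)
        single = [float(ssm_mean_cov_logpdf(st, p)) for p in pts]
        np.testing.assert_allclose(batch, single, rtol=1e-12)
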