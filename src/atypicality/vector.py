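"""Predictive densities for iid vector Gaussian models.

Covers unknown mean with known covariance, unknown covariance (SSM via the
inverse-Wishart construction and NLM), unknown mean and covariance (both
methods), and the isotropic coder used by the sparse-transform method.  All
densities are evaluated in the log domain with Cholesky log-determinants and
the multivariate log-gamma; updates of the (n+1)-sample scatter are rank-1,
so ``x_next`` may carry leading batch axes everywhere.

The stream coder :class:`VectorStreamCoder` applies the staging rule for
small n: until a vector coder's precondition holds the incoming vectors are
encoded componentwise with the staged scalar coder, so only the very first
scalar component of the stream needs the default distribution.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln, multigammaln

from .core import LN2, DegenerateStatistics, InsufficientData
from .scalar import staged_bits_mean_var

_LOG_PI = math.log(math.pi)
_JITTER = 1e-12
_JITTER_MAX = 1e-6


def _chol_logdet(S: np.ndarray) -> tuple[np.ndarray, float]:
    """Cholesky factor and log-determinant of an SPD matrix.

    Near-singular matrices get diagonal jitter ``1e-12 * trace/M``; if more
    than ``1e-6 * trace/M`` would be needed the matrix is treated as
    singular and an error is raised.
    """
    S = np.asarray(S, dtype=float)
    M = S.shape[0]
    scale = max(np.trace(S) / M, np.finfo(float).tiny)
    jitter = 0.0
    for _ in range(3):
        try:
            L = np.linalg.cholesky(S + jitter * np.eye(M))
            return L, 2.0 * float(np.sum(np.log(np.diag(L))))
        except np.linalg.LinAlgError:
            jitter = _JITTER * scale if jitter == 0.0 else jitter * 1e3
            if jitter > _JITTER_MAX * scale:
                break
    raise DegenerateStatistics("scatter matrix is singular")


def _logdet_rank1(L: np.ndarray, logdet: float, v: np.ndarray) -> np.ndarray:
    """log det(S + v v^T) from chol(S) via the matrix determinant lemma.

    ``v`` may have leading batch axes.
    """
    v = np.asarray(v, dtype=float)
    w = np.linalg.solve(L, v[..., None])[..., 0]
    q = np.sum(w * w, axis=-1)
    return logdet + np.log1p(q)


@dataclass
class VectorStats:
    """Sequential statistics (n, sum, raw scatter) for M-vector streams.

    ``raw_scatter`` is ``sum x_i x_i^T``; the centered scatter
    ``sum (x_i - mean)(x_i - mean)^T`` is derived by a rank-1 correction.
    """

    M: int
    n: int = 0
    sum_x: np.ndarray = None  # type: ignore[assignment]
    raw_scatter: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self):
        if self.sum_x is None:
            self.sum_x = np.zeros(self.M)
        if self.raw_scatter is None:
            self.raw_scatter = np.zeros((self.M, self.M))

    def push(self, x) -> "VectorStats":
        x = np.asarray(x, dtype=float).ravel()
        if x.size != self.M:
            raise ValueError(f"expected an {self.M}-vector, got size {x.size}")
        self.n += 1
        self.sum_x = self.sum_x + x
        self.raw_scatter = self.raw_scatter + np.outer(x, x)
        return self

    def copy(self) -> "VectorStats":
        return VectorStats(self.M, self.n, self.sum_x.copy(), self.raw_scatter.copy())

    @property
    def mean(self) -> np.ndarray:
        if self.n == 0:
            raise InsufficientData("mean of empty statistics")
        return self.sum_x / self.n

    @property
    def centered_scatter(self) -> np.ndarray:
        if self.n == 0:
            raise InsufficientData("scatter of empty statistics")
        return self.raw_scatter - np.outer(self.sum_x, self.sum_x) / self.n


def from_rows(rows) -> VectorStats:
    """Batch-build :class:`VectorStats` from an (n, M) array of vectors."""
    rows = np.atleast_2d(np.asarray(rows, dtype=float))
    st = VectorStats(rows.shape[1])
    st.n = rows.shape[0]
    st.sum_x = rows.sum(axis=0)
    st.raw_scatter = rows.T @ rows
    return st


# ---------------------------------------------------------------------------
# unknown mean, known covariance


def pred_mean_known_sigma_logpdf(stats: VectorStats, Sigma, x_next):
    """Predictive log-density for unknown mean, known covariance Sigma.

    SSM and NLM coincide here: ``N(mean_n, (1 + 1/n) Sigma)``.
    """
    if stats.n < 1:
        raise InsufficientData("mean predictor needs n >= 1")
    Sigma = np.asarray(Sigma, dtype=float)
    try:
        L, logdet = _chol_logdet(Sigma)
    except DegenerateStatistics as e:
        raise DegenerateStatistics("Sigma is not SPD") from e
    n, M = stats.n, stats.M
    c = 1.0 + 1.0 / n
    d = np.asarray(x_next, dtype=float) - stats.mean
    w = np.linalg.solve(L, d[..., None])[..., 0]
    q = np.sum(w * w, axis=-1) / c
    return -0.5 * (M * math.log(2.0 * math.pi * c) + logdet + q)


def pred_mean_knownSigma(stats: VectorStats, Sigma, x_next):
    return np.exp(pred_mean_known_sigma_logpdf(stats, Sigma, x_next))


# ---------------------------------------------------------------------------
# zero mean, unknown covariance


def _scatter_pair_logdets(S, x_next):
    L, ld_n = _chol_logdet(S)
    ld_n1 = _logdet_rank1(L, ld_n, x_next)
    return ld_n, ld_n1


def ssm_cov_logpdf(stats: VectorStats, x_next):
    """SSM predictive log-density for N(0, Sigma), Sigma unknown.

    Derived from the inverse-Wishart law of Sigma given the raw scatter:
    ``pi^{-M/2} det(S_n)^{n/2} / det(S_{n+1})^{(n+1)/2} *
    Gamma_M((n+1)/2) / Gamma_M(n/2)``.
    """
    n, M = stats.n, stats.M
    if n < M:
        raise InsufficientData(f"SSM covariance predictor needs n >= M = {M}")
    ld_n, ld_n1 = _scatter_pair_logdets(stats.raw_scatter, x_next)
    return (
        -0.5 * M * _LOG_PI
        + multigammaln((n + 1) / 2.0, M)
        - multigammaln(n / 2.0, M)
        + (n / 2.0) * ld_n
        - ((n + 1) / 2.0) * ld_n1
    )


def ssm_cov_pred(stats: VectorStats, x_next):
    return np.exp(ssm_cov_logpdf(stats, x_next))


def nlm_cov_logpdf(stats: VectorStats, x_next):
    """NLM predictive log-density for N(0, Sigma), Sigma unknown.

    ``pi^{-M/2} det(S_n)^{(n-M-1)/2} / det(S_{n+1})^{(n-M)/2} *
    Gamma_M((n-M)/2) / Gamma_M((n-M-1)/2)``; the multivariate-gamma
    arguments are positive iff n >= 2M+1, the smallest valid n.
    """
    n, M = stats.n, stats.M
    if n < 2 * M + 1:
        raise InsufficientData(
            f"NLM covariance predictor needs n >= 2M+1 = {2 * M + 1}"
        )
    ld_n, ld_n1 = _scatter_pair_logdets(stats.raw_scatter, x_next)
    return (
        -0.5 * M * _LOG_PI
        + multigammaln((n - M) / 2.0, M)
        - multigammaln((n - M - 1) / 2.0, M)
        + ((n - M - 1) / 2.0) * ld_n
        - ((n - M) / 2.0) * ld_n1
    )


def nlm_cov_pred(stats: VectorStats, x_next):
    return np.exp(nlm_cov_logpdf(stats, x_next))


# ---------------------------------------------------------------------------
# unknown mean and covariance


def _centered_pair_logdets(stats: VectorStats, x_next):
    C = stats.centered_scatter
    L, ld_n = _chol_logdet(C)
    # C_{n+1} = C_n + n/(n+1) (x - mean_n)(x - mean_n)^T
    d = np.asarray(x_next, dtype=float) - stats.mean
    v = math.sqrt(stats.n / (stats.n + 1.0)) * d
    ld_n1 = _logdet_rank1(L, ld_n, v)
    return ld_n, ld_n1


def ssm_mean_cov_logpdf(stats: VectorStats, x_next):
    """SSM predictive log-density for N(mu, Sigma), both unknown.

    ``pi^{-M/2} (n/(n+1))^{M/2} det(C_n)^{(n-1)/2} / det(C_{n+1})^{n/2} *
    Gamma_M(n/2) / Gamma_M((n-1)/2)`` with centered scatters C.
    """
    n, M = stats.n, stats.M
    if n < M + 1:
        raise InsufficientData(
            f"SSM mean/covariance predictor needs n >= M+1 = {M + 1}"
        )
    ld_n, ld_n1 = _centered_pair_logdets(stats, x_next)
    return (
        -0.5 * M * _LOG_PI
        + 0.5 * M * (math.log(n) - math.log(n + 1))
        + multigammaln(n / 2.0, M)
        - multigammaln((n - 1) / 2.0, M)
        + ((n - 1) / 2.0) * ld_n
        - (n / 2.0) * ld_n1
    )


def ssm_mean_cov_pred(stats: VectorStats, x_next):
    return np.exp(ssm_mean_cov_logpdf(stats, x_next))


def nlm_mean_cov_logpdf(stats: VectorStats, x_next):
    """NLM predictive log-density for N(mu, Sigma), both unknown.

    ``pi^{-M/2} (n/(n+1))^{M/2} det(C_n)^{(n-M-2)/2} / det(C_{n+1})^{(n-M-1)/2}
    * Gamma_M((n-M-1)/2) / Gamma_M((n-M-2)/2)``; valid from n >= 2M+2.
    """
    n, M = stats.n, stats.M
    if n < 2 * M + 2:
        raise InsufficientData(
            f"NLM mean/covariance predictor needs n >= 2M+2 = {2 * M + 2}"
        )
    ld_n, ld_n1 = _centered_pair_logdets(stats, x_next)
    return (
        -0.5 * M * _LOG_PI
        + 0.5 * M * (math.log(n) - math.log(n + 1))
        + multigammaln((n - M - 1) / 2.0, M)
        - multigammaln((n - M - 2) / 2.0, M)
        + ((n - M - 2) / 2.0) * ld_n
        - ((n - M - 1) / 2.0) * ld_n1
    )


def nlm_mean_cov_pred(stats: VectorStats, x_next):
    return np.exp(nlm_mean_cov_logpdf(stats, x_next))


# ---------------------------------------------------------------------------
# isotropic coder (sparse-transform complement)


def ssm_isotropic_logpdf(n: int, sumsq: float, dim: int, w_next):
    """SSM predictive log-density for iid N(0, tau I_dim) noise vectors.

    ``pi^{-d/2} Gamma(d(n+1)/2) / Gamma(dn/2) *
    (n tau_n)^{dn/2} / ((n+1) tau_{n+1})^{d(n+1)/2}`` where
    ``n tau_n = sum_i |w_i|^2`` is the accumulated squared norm.
    """
    if n < 1:
        raise InsufficientData("isotropic predictor needs n >= 1")
    if dim < 1:
        raise ValueError("dim must be >= 1")
    if sumsq <= 0.0:
        raise DegenerateStatistics("isotropic predictor: all-zero history")
    w = np.asarray(w_next, dtype=float)
    s_n1 = sumsq + np.sum(w * w, axis=-1)
    d = float(dim)
    return (
        -0.5 * d * _LOG_PI
        + gammaln(d * (n + 1) / 2.0)
        - gammaln(d * n / 2.0)
        + (d * n / 2.0) * math.log(sumsq)
        - (d * (n + 1) / 2.0) * np.log(s_n1)
    )


def ssm_isotropic_pred(n: int, sumsq: float, dim: int, w_next):
    return np.exp(ssm_isotropic_logpdf(n, sumsq, dim, w_next))


def isotropic_stream_bits(rows, default_bits) -> np.ndarray:
    """Per-vector bits of the isotropic stream coder over (B, d) rows.

    The first vector is encoded componentwise with the staged scalar coder;
    later vectors use the isotropic SSM, falling back to componentwise
    scalar coding while the accumulated squared norm is zero.
    """
    rows = np.atleast_2d(np.asarray(rows, dtype=float))
    B, d = rows.shape
    if B == 0:
        return np.empty(0)
    bits = np.empty(B)
    bits[0] = staged_bits_mean_var(rows[0], default_bits).sum()
    if B == 1:
        return bits
    sq = np.sum(rows * rows, axis=1)
    csq = np.cumsum(sq)
    i = np.arange(1, B)
    n = i.astype(float)
    s_n = csq[i - 1]
    s_n1 = csq[i]
    with np.errstate(divide="ignore", invalid="ignore"):
        logf = (
            -0.5 * d * _LOG_PI
            + gammaln(d * (n + 1) / 2.0)
            - gammaln(d * n / 2.0)
            + (d * n / 2.0) * np.log(s_n)
            - (d * (n + 1) / 2.0) * np.log(s_n1)
        )
    ok = s_n > 0.0
    out = np.where(ok, -logf / LN2, 0.0)
    for k in np.nonzero(~ok)[0]:
        out[k] = staged_bits_mean_var(rows[k + 1], default_bits).sum()
    bits[1:] = out
    return bits


# ---------------------------------------------------------------------------
# stream coder with scalar initialization


@dataclass
class VectorStreamCoder:
    """Sequential coder for a stream of M-vectors with scalar initialization.

    ``model`` selects the parameterization ("cov" for zero-mean unknown
    covariance, "mean_cov" for unknown mean and covariance) and ``method``
    the predictive family ("ssm" or "nlm").  Vectors arriving before the
    chosen coder's precondition holds are encoded componentwise with the
    staged scalar coder as one continuing scalar stream, so only the first
    scalar component of the whole stream is charged to the default
    distribution.
    """

    M: int
    model: str = "mean_cov"
    method: str = "ssm"
    default_bits: float = 2.05
    stats: VectorStats = field(init=False)
    _scalar_prefix: list = field(init=False, default_factory=list)

    def __post_init__(self):
        if self.model not in ("cov", "mean_cov"):
            raise ValueError(f"unknown model {self.model!r}")
        if self.method not in ("ssm", "nlm"):
            raise ValueError(f"unknown method {self.method!r}")
        self.stats = VectorStats(self.M)

    def _logpdf(self, x):
        table = {
            ("cov", "ssm"): ssm_cov_logpdf,
            ("cov", "nlm"): nlm_cov_logpdf,
            ("mean_cov", "ssm"): ssm_mean_cov_logpdf,
            ("mean_cov", "nlm"): nlm_mean_cov_logpdf,
        }
        return table[(self.model, self.method)](self.stats, x)

    def push(self, x) -> float:
        """Encode one vector; returns its codelength in bits."""
        x = np.asarray(x, dtype=float).ravel()
        try:
            bits = float(-self._logpdf(x) / LN2)
        except (InsufficientData, DegenerateStatistics):
            flat = np.concatenate(self._scalar_prefix + [x]) if self._scalar_prefix else x
            per = staged_bits_mean_var(flat, self.default_bits)
            bits = float(per[-self.M :].sum())
            self._scalar_prefix.append(x)
        self.stats.push(x)
        return bits

    def stream_bits(self, rows) -> np.ndarray:
        rows = np.atleast_2d(np.asarray(rows, dtype=float))
        return np.array([self.push(r) for r in rows])
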