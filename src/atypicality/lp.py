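"""NLM coder for the order-M linear prediction (AR) model.

The likelihood of the data given prediction coefficients ``w`` and
innovation variance ``tau`` conditions on the first M samples; integrating
it over ``(w, tau)`` gives

    C(x^n) = pi^{-(n-2M)/2} / 2 * det(R_n)^{-1/2}
             * Gamma((n-2M-2)/2) * tau_n^{-(n-2M-2)/2}

with ``R_n`` the lagged-vector scatter and ``tau_n = r0 - p^T R_n^{-1} p``
the residual power of the exact least-squares fit.  The predictive density
is the ratio ``C(x^{n+1}) / C(x^n)``; every statistic updates by a single
rank-1 term per sample.  No sufficient-statistic variant exists for AR
models: the minimal sufficient statistic has dimension three for two
parameters already at M = 1, so only the NLM is provided — by design.

The gamma argument of ``C(x^n)`` is positive only for n >= 2M+3, which is
the validity bound enforced here.  The staged stream coder fills in the
ramp-up: the first sample is charged to the default distribution, the
next two to the scalar unknown-variance SSM, and from then on the largest
valid order up to ``M_max`` takes over (order 0 being the scalar NLM).

A trainable plug-in coder (:class:`ARTypical`) with per-segment
least-squares coefficients serves as the typical-model codelength for the
scanner; its default order is 10.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln

from .core import LN2, DegenerateStatistics, InsufficientData
from .scalar import staged_bits_var

_LOG_PI = math.log(math.pi)
_CHUNK = 16384
_RCOND = 1e-12


@dataclass
class ARStats:
    """Recursive autocovariance statistics for the order-M NLM coder.

    ``r0``, ``p`` and ``R`` accumulate ``x_i^2``, ``x_i x_{i-k}`` and the
    lagged-vector outer products over i = M+1..n; ``last`` is the ring of
    the latest M samples needed to extend them by one sample.
    """

    M: int
    n: int = 0
    r0: float = 0.0
    p: np.ndarray = None  # type: ignore[assignment]
    R: np.ndarray = None  # type: ignore[assignment]
    last: list = field(default_factory=list)

    def __post_init__(self):
        if self.p is None:
            self.p = np.zeros(self.M)
        if self.R is None:
            self.R = np.zeros((self.M, self.M))

    def copy(self) -> "ARStats":
        return ARStats(self.M, self.n, self.r0, self.p.copy(), self.R.copy(), list(self.last))

    def lag_vector(self) -> np.ndarray:
        """Latest M samples, most recent first (the regressor for the next sample)."""
        return np.array(self.last[::-1], dtype=float)

    def push(self, x_new: float) -> "ARStats":
        x = float(x_new)
        if self.n >= self.M:
            v = self.lag_vector()
            self.r0 += x * x
            self.p += x * v
            self.R += np.outer(v, v)
        self.last.append(x)
        if len(self.last) > self.M:
            self.last.pop(0)
        self.n += 1
        return self

    def tau(self) -> float:
        """Residual power ``r0 - p^T R^{-1} p`` of the least-squares fit."""
        if self.M == 0:
            return self.r0
        L = np.linalg.cholesky(self.R)
        w = np.linalg.solve(L, self.p)
        return self.r0 - float(w @ w)


def ar_update(stats: ARStats, x_new: float) -> ARStats:
    """Return a copy of ``stats`` extended by one sample."""
    return stats.copy().push(x_new)


def nlm_ar_logpdf(stats: ARStats, x_next: float) -> float:
    """NLM predictive log-density of the next sample under the order-M model.

    ``sqrt(det R_n / det R_{n+1}) * Gamma((n-2M-1)/2) / Gamma((n-2M-2)/2)
    / sqrt(pi) * tau_n^{(n-2M-2)/2} / tau_{n+1}^{(n-2M-1)/2}``.
    Requires n >= 2M+3 so that all gamma arguments are positive.
    """
    n, M = stats.n, stats.M
    if n < 2 * M + 3:
        raise InsufficientData(
            f"order-{M} NLM predictor needs n >= 2M+3 = {2 * M + 3}"
        )
    nxt = ar_update(stats, x_next)
    if M == 0:
        ld_a = ld_b = 0.0
    else:
        sa, ld_a = np.linalg.slogdet(stats.R)
        sb, ld_b = np.linalg.slogdet(nxt.R)
        if sa <= 0 or sb <= 0:
            raise DegenerateStatistics("singular lagged-vector scatter")
    ta, tb = stats.tau(), nxt.tau()
    if ta <= 0.0 or tb <= 0.0:
        raise DegenerateStatistics("nonpositive residual power")
    a = n - 2 * M
    return (
        0.5 * (ld_a - ld_b)
        + gammaln((a - 1) / 2.0)
        - gammaln((a - 2) / 2.0)
        - 0.5 * _LOG_PI
        + ((a - 2) / 2.0) * math.log(ta)
        - ((a - 1) / 2.0) * math.log(tb)
    )


def nlm_ar_pred(stats: ARStats, x_next: float) -> float:
    return math.exp(nlm_ar_logpdf(stats, x_next))


# ---------------------------------------------------------------------------
# staged stream coder (vectorized)


def _pointwise_order_bits(x: np.ndarray, m: int, i: int, default_bits: float) -> float:
    """Bits for sample i under the largest workable order <= m (fallback path)."""
    for order in range(m, -1, -1):
        if i < 2 * order + 3:
            continue
        st = ARStats(order)
        for t in range(i):
            st.push(x[t])
        try:
            return -nlm_ar_logpdf(st, x[i]) / LN2
        except (InsufficientData, DegenerateStatistics, np.linalg.LinAlgError):
            continue
    s = float(np.sum(x[:i] ** 2))
    if s > 0.0:
        n = float(i)
        logf = (
            gammaln((n + 1) / 2.0)
            - gammaln(n / 2.0)
            - 0.5 * _LOG_PI
            + (n / 2.0) * math.log(s)
            - ((n + 1) / 2.0) * math.log(s + x[i] ** 2)
        )
        return -logf / LN2
    return default_bits


def _order_bits_range(
    x: np.ndarray, m: int, lo: int, hi: int, default_bits: np.ndarray
) -> np.ndarray:
    """Order-m NLM bits for samples lo..hi-1 (history = all preceding samples).

    Statistics are accumulated as cumulative rank-1 sums and the
    determinant/solve work is done on stacked matrices, chunked to bound
    memory; numerically unusable samples (singular R, nonpositive residual
    power) fall back to the largest lower order that works.
    """
    out = np.empty(hi - lo)
    if m == 0:
        csq = np.cumsum(x[: hi] ** 2)
        i = np.arange(lo, hi)
        n = i.astype(float)
        s_n = csq[i - 1]
        s_n1 = csq[i]
        with np.errstate(divide="ignore", invalid="ignore"):
            logf = (
                gammaln((n - 1) / 2.0)
                - gammaln((n - 2) / 2.0)
                - 0.5 * _LOG_PI
                + ((n - 2) / 2.0) * np.log(s_n)
                - ((n - 1) / 2.0) * np.log(s_n1)
            )
        bad = ~np.isfinite(logf) | (s_n <= 0.0)
        out[:] = np.where(bad, 0.0, -logf / LN2)
        for k in np.nonzero(bad)[0]:
            out[k] = default_bits[lo + k] if np.sum(x[: lo + k] ** 2) <= 0 else out[k]
            if np.sum(x[: lo + k] ** 2) > 0 and bad[k]:
                out[k] = _pointwise_order_bits(x, 0, lo + k, default_bits[lo + k])
        return out

    # lag vectors v_j (most recent first) regressing x[j] on x[j-1..j-m]
    sw = np.lib.stride_tricks.sliding_window_view(x[: hi], m)  # sw[t] = x[t:t+m]
    carry_R = np.zeros((m, m))
    carry_p = np.zeros(m)
    carry_r0 = 0.0
    # absorb j = m .. lo-1 into the carry
    if lo > m:
        V0 = sw[0 : lo - m, ::-1]
        xj0 = x[m:lo]
        carry_R = V0.T @ V0
        carry_p = V0.T @ xj0
        carry_r0 = float(xj0 @ xj0)
    pos = 0
    for cs in range(lo, hi, _CHUNK):
        ce = min(hi, cs + _CHUNK)
        V = sw[cs - m : ce - m, ::-1]  # v_j for j = cs..ce-1
        xj = x[cs:ce]
        O = V[:, :, None] * V[:, None, :]
        cum_R = np.cumsum(O, axis=0) + carry_R
        cum_p = np.cumsum(xj[:, None] * V, axis=0) + carry_p
        cum_r0 = np.cumsum(xj * xj) + carry_r0
        R_a = np.concatenate([carry_R[None], cum_R[:-1]], axis=0)
        p_a = np.concatenate([carry_p[None], cum_p[:-1]], axis=0)
        r0_a = np.concatenate([[carry_r0], cum_r0[:-1]])
        with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
            sa, ld_a = np.linalg.slogdet(R_a)
            sb, ld_b = np.linalg.slogdet(cum_R)
            try:
                sol_a = np.linalg.solve(R_a, p_a[..., None])[..., 0]
                sol_b = np.linalg.solve(cum_R, cum_p[..., None])[..., 0]
            except np.linalg.LinAlgError:
                sol_a = np.full_like(p_a, np.nan)
                sol_b = np.full_like(cum_p, np.nan)
            tau_a = r0_a - np.sum(p_a * sol_a, axis=1)
            tau_b = cum_r0 - np.sum(cum_p * sol_b, axis=1)
            n = np.arange(cs, ce, dtype=float)
            a = n - 2 * m
            logf = (
                0.5 * (ld_a - ld_b)
                + gammaln((a - 1) / 2.0)
                - gammaln((a - 2) / 2.0)
                - 0.5 * _LOG_PI
                + ((a - 2) / 2.0) * np.log(tau_a)
                - ((a - 1) / 2.0) * np.log(tau_b)
            )
        bad = (
            ~np.isfinite(logf)
            | (sa <= 0)
            | (sb <= 0)
            | (tau_a <= _RCOND * r0_a)
            | (tau_b <= 0.0)
        )
        vals = np.where(bad, 0.0, -logf / LN2)
        for k in np.nonzero(bad)[0]:
            vals[k] = _pointwise_order_bits(x, m - 1, cs + k, default_bits[cs + k])
        out[pos : pos + (ce - cs)] = vals
        pos += ce - cs
        carry_R = cum_R[-1]
        carry_p = cum_p[-1]
        carry_r0 = float(cum_r0[-1])
    return out


def staged_ar_bits(x, m_max: int, default_bits) -> np.ndarray:
    """Per-sample bits of the staged linear-prediction coder.

    Sample 1 is charged to the default distribution, samples with history
    n in {1, 2} to the scalar unknown-variance SSM, and each later sample
    to the NLM linear predictor of order ``min(m_max, (n-3)//2)`` — the
    largest order whose statistics are defined at that point.
    """
    x = np.asarray(x, dtype=float).ravel()
    l = x.size
    if m_max < 0:
        raise ValueError("m_max must be >= 0")
    if l == 0:
        return np.empty(0)
    db = np.broadcast_to(np.asarray(default_bits, dtype=float), (l,))
    bits = np.empty(l)
    head = min(l, 3)
    bits[:head] = staged_bits_var(x[:head], db[:head])
    i = 3
    while i < l:
        m = min(m_max, (i - 3) // 2)
        hi = l if m == m_max else min(l, 2 * (m + 1) + 3)
        bits[i:hi] = _order_bits_range(x, m, i, hi, db)
        i = hi
    return bits


def staged_ar_codelength(x, m_max: int, default_bits) -> tuple[float, np.ndarray]:
    """Total bits and per-sample trace of the staged LP coder."""
    per = staged_ar_bits(x, m_max, default_bits)
    return float(per.sum()), per


def nlm_ar_stream_logC(x, M: int) -> float:
    """Natural-log integrated likelihood ``ln C(x^n)`` of the order-M model.

    Used to verify the telescoping identity of the sequential coder.
    """
    x = np.asarray(x, dtype=float).ravel()
    n = x.size
    if n < 2 * M + 3:
        raise InsufficientData("C(x^n) defined for n >= 2M+3")
    st = ARStats(M)
    for t in x:
        st.push(t)
    if M == 0:
        ld = 0.0
    else:
        s, ld = np.linalg.slogdet(st.R)
        if s <= 0:
            raise DegenerateStatistics("singular lagged-vector scatter")
    tau = st.tau()
    a = n - 2 * M
    return (
        -math.log(2.0)
        - (a / 2.0) * _LOG_PI
        - 0.5 * ld
        + gammaln((a - 2) / 2.0)
        - ((a - 2) / 2.0) * math.log(tau)
    )


# ---------------------------------------------------------------------------
# trainable typical coder (plug-in)


@dataclass
class TypicalARModel:
    """Plug-in AR model: fixed coefficients and innovation variance."""

    M: int
    w: np.ndarray
    tau: float
    segment_len: int | None = None


def fit_typical_ar(x, M: int = 10, segment_len: int | None = None) -> TypicalARModel:
    """Least-squares fit of an order-M predictor on one segment.

    Solves the normal equations on the covariance-method design matrix;
    if they are rank deficient the order falls back until they are not.
    """
    x = np.asarray(x, dtype=float).ravel()
    n = x.size
    order = min(M, max(n - 1, 0))
    while order > 0:
        A = np.lib.stride_tricks.sliding_window_view(x[: n - 1], order)[:, ::-1]
        b = x[order:]
        sol, _, rank, _ = np.linalg.lstsq(A, b, rcond=None)
        if rank == order:
            res = b - A @ sol
            tau = float(res @ res) / max(res.size, 1)
            if tau > 0.0:
                return TypicalARModel(order, sol, tau, segment_len)
        order -= 1
    var = float(np.var(x)) if n else 1.0
    return TypicalARModel(0, np.empty(0), max(var, np.finfo(float).tiny), segment_len)


def typical_codelength(model: TypicalARModel, x) -> float:
    """Plug-in innovation codelength of a segment under a fitted AR model.

    Samples with fewer than M predecessors in the segment are coded with
    the zero-mean Gaussian of the segment's marginal power.
    """
    return float(typical_ar_sample_bits(model, x).sum())


def typical_ar_sample_bits(model: TypicalARModel, x, context=None) -> np.ndarray:
    """Per-sample plug-in bits; ``context`` supplies preceding stream samples."""
    x = np.asarray(x, dtype=float).ravel()
    M = model.M
    ctx = np.asarray(context, dtype=float).ravel() if context is not None else np.empty(0)
    full = np.concatenate([ctx, x])
    c = ctx.size
    bits = np.empty(x.size)
    head = max(M - c, 0)
    if head > 0:
        var = max(float(np.var(x)) if x.size > 1 else model.tau, np.finfo(float).tiny)
        bits[:head] = (
            0.5 * (np.log(2.0 * math.pi * var) + x[:head] ** 2 / var) / LN2
        )
    if x.size > head:
        if M > 0:
            A = np.lib.stride_tricks.sliding_window_view(full[: full.size - 1], M)[:, ::-1]
            pred = A[c + head - M :] @ model.w
        else:
            pred = 0.0
        e = x[head:] - pred
        bits[head:] = 0.5 * (np.log(2.0 * math.pi * model.tau) + e * e / model.tau) / LN2
    return bits


class ARTypical:
    """Typical coder: order-M plug-in AR codelength, refitted per segment.

    The default order is 10; coefficients are estimated per
    ``segment_len``-sample window (all samples included — atypical content
    is assumed rare and short enough to barely move the estimate; pass
    pre-cleaned data otherwise).
    """

    def __init__(self, order: int = 10, segment_len: int | None = None):
        self.order = order
        self.segment_len = segment_len
        self.models_: list[TypicalARModel] = []

    def per_sample_bits(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float).ravel()
        seg = self.segment_len or x.size
        self.models_ = []
        bits = np.empty(x.size)
        for s in range(0, x.size, seg):
            e = min(x.size, s + seg)
            model = fit_typical_ar(x[s:e], self.order, seg)
            self.models_.append(model)
            bits[s:e] = typical_ar_sample_bits(model, x[s:e], context=x[max(0, s - model.M) : s])
        return bits


class GaussianTypical:
    """Typical coder for iid Gaussian data with known (or fitted) mean/variance."""

    def __init__(self, mean: float = 0.0, var: float = 1.0):
        if var <= 0:
            raise ValueError("var must be positive")
        self.mean = mean
        self.var = var

    @classmethod
    def fit(cls, x) -> "GaussianTypical":
        x = np.asarray(x, dtype=float)
        return cls(float(x.mean()), max(float(x.var()), np.finfo(float).tiny))

    def per_sample_bits(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float).ravel()
        return (
            0.5
            * (np.log(2.0 * math.pi * self.var) + (x - self.mean) ** 2 / self.var)
            / LN2
        )
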