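"""Blockwise sparse-transform coder (DCT / real DFT).

The signal is cut into blocks of M samples and rotated by an orthonormal
transform.  N "signal" components — the coefficients with the largest
average power over the whole block stream — are coded as independent
scalar Gaussian streams (they may carry deterministic offsets, so the
unknown-mean/variance coder is used); the remaining M-N components are
coded jointly by the isotropic vector coder.  The selected index set J is
communicated to the decoder for ``M H2(N/M) + log2(M)/2`` bits, and N is
chosen greedily, increasing from 0 until the total codelength stops
improving.

The default transform is the orthonormal DCT-II; a real orthonormal DFT
packing (DC, cosine/sine pairs scaled by sqrt(2), Nyquist for even M) is
available as well.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.fft import dct, idct

from .core import LN2
from .scalar import staged_bits_mean_var
from .vector import isotropic_stream_bits


def transform_block(x, kind: str = "dct") -> np.ndarray:
    """Orthonormal transform of one block (or a (B, M) stack of blocks)."""
    x = np.asarray(x, dtype=float)
    M = x.shape[-1]
    if M < 2:
        raise ValueError("block size must be >= 2")
    if kind == "dct":
        return dct(x, type=2, norm="ortho", axis=-1)
    if kind == "dft":
        Y = np.fft.rfft(x, axis=-1)
        out = np.empty_like(x)
        out[..., 0] = Y[..., 0].real / math.sqrt(M)
        half = (M - 1) // 2
        scale = math.sqrt(2.0 / M)
        for k in range(1, half + 1):
            out[..., 2 * k - 1] = scale * Y[..., k].real
            out[..., 2 * k] = -scale * Y[..., k].imag
        if M % 2 == 0:
            out[..., M - 1] = Y[..., M // 2].real / math.sqrt(M)
        return out
    raise ValueError(f"unknown transform kind {kind!r}")


def inverse_block(y, kind: str = "dct") -> np.ndarray:
    """Inverse of :func:`transform_block`."""
    y = np.asarray(y, dtype=float)
    M = y.shape[-1]
    if kind == "dct":
        return idct(y, type=2, norm="ortho", axis=-1)
    if kind == "dft":
        half = (M - 1) // 2
        Y = np.zeros(y.shape[:-1] + (M // 2 + 1,), dtype=complex)
        Y[..., 0] = y[..., 0] * math.sqrt(M)
        scale = math.sqrt(M / 2.0)
        for k in range(1, half + 1):
            Y[..., k] = scale * (y[..., 2 * k - 1] - 1j * y[..., 2 * k])
        if M % 2 == 0:
            Y[..., M // 2] = y[..., M - 1] * math.sqrt(M)
        return np.fft.irfft(Y, M, axis=-1)
    raise ValueError(f"unknown transform kind {kind!r}")


def select_components(blocks, N: int, kind: str = "dct") -> np.ndarray:
    """Indices of the N transform components with maximum average power.

    Power is measured over the whole block stream (end-of-block powers, so
    the decoder never needs to know how J was chosen); ties break toward
    the lower index.
    """
    Y = transform_block(np.atleast_2d(np.asarray(blocks, dtype=float)), kind)
    M = Y.shape[-1]
    if not 0 <= N <= M:
        raise ValueError("N must be between 0 and M")
    power = np.mean(Y * Y, axis=0)
    order = np.lexsort((np.arange(M), -power))
    return np.sort(order[:N])


def side_bits(N: int, M: int) -> float:
    """Cost of communicating the selected set J: ``M H2(N/M) + log2(M)/2``."""
    if not 0 <= N <= M:
        raise ValueError("N must be between 0 and M")
    p = N / M
    h = 0.0
    if 0.0 < p < 1.0:
        h = -p * math.log2(p) - (1.0 - p) * math.log2(1.0 - p)
    return M * h + 0.5 * math.log2(M)


def sparse_codelength(
    blocks,
    N: int,
    kind: str = "dct",
    default_bits: float = 2.05,
) -> tuple[float, np.ndarray]:
    """Total bits of the block stream with N signal components.

    Returns ``(bits, J)``.  The total is the side information for J, the
    staged scalar streams of the selected coefficients, and the isotropic
    stream of the complement.
    """
    B = np.atleast_2d(np.asarray(blocks, dtype=float))
    if B.shape[0] < 2:
        raise ValueError("need at least 2 blocks")
    Y = transform_block(B, kind)
    M = Y.shape[-1]
    J = select_components(B, N, kind)
    total = side_bits(N, M)
    for j in J:
        total += float(staged_bits_mean_var(Y[:, j], default_bits).sum())
    comp = np.setdiff1d(np.arange(M), J)
    if comp.size:
        total += float(isotropic_stream_bits(Y[:, comp], default_bits).sum())
    return total, J


def choose_N(
    blocks,
    kind: str = "dct",
    default_bits: float = 2.05,
    full_sweep: bool = False,
) -> tuple[int, float]:
    """Greedy choice of the number of signal components.

    Starting from N = 0, N is increased by one until the codelength no
    longer decreases (first local minimum); ``full_sweep`` evaluates every
    N and returns the global minimum instead.
    """
    B = np.atleast_2d(np.asarray(blocks, dtype=float))
    M = B.shape[-1]
    best_n, best_bits = 0, sparse_codelength(B, 0, kind, default_bits)[0]
    for N in range(1, M + 1):
        bits = sparse_codelength(B, N, kind, default_bits)[0]
        if bits < best_bits:
            best_n, best_bits = N, bits
        elif not full_sweep:
            break
    return best_n, best_bits
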