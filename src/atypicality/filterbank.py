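"""Orthonormal sub-band coder with tree weighting.

A signal is split recursively into low/high sub-bands by an orthonormal
perfect-reconstruction filter pair; each node's samples can be coded
directly with the iid Gaussian unknown-mean/variance coder (the "leaf"
choice) or split further.  Rather than searching the huge space of
decomposition trees, every internal node mixes both choices with weight
1/2 each (the context-tree-weighting idea):

    L_w = -log2( 1/2 * 2^{-L_leaf} + 1/2 * 2^{-(L_pass + L_wL + L_wH)} )

which is within one bit per decision of the best single tree.  At the
maximum depth no choice exists and the weight is dropped.

Startup transients are handled by the pass-through rule: the first
``filter_length - 1`` input samples of a node are transmitted verbatim
(coded by the node's own scalar stream) and only the remainder is
filtered.  That remainder is analyzed with circular (periodized)
filtering, which keeps the per-node transform exactly orthonormal — and
hence energy preserving and perfectly reconstructible — for any even
block length.  An odd trailing sample joins the pass-through set so the
filtered block is always even.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pywt

from .core import InsufficientData
from .scalar import staged_bits_mean_var


@dataclass(frozen=True)
class FilterPair:
    """Orthonormal analysis filter pair (low-pass, high-pass)."""

    low: np.ndarray
    high: np.ndarray
    name: str = "custom"

    @classmethod
    def haar(cls) -> "FilterPair":
        s = 1.0 / math.sqrt(2.0)
        return cls(np.array([s, s]), np.array([s, -s]), "haar")

    @classmethod
    def from_wavelet(cls, name: str = "db4") -> "FilterPair":
        w = pywt.Wavelet(name)
        return cls(np.asarray(w.dec_lo, dtype=float), np.asarray(w.dec_hi, dtype=float), name)

    @property
    def length(self) -> int:
        return len(self.low)


def _pad_circular(f: np.ndarray, m: int) -> np.ndarray:
    out = np.zeros(m)
    for idx, c in enumerate(f):
        out[idx % m] += c
    return out


def analyze(x, pair: FilterPair):
    """Split a node's samples into (passthrough, low, high).

    The first ``filter_length - 1`` samples (plus an odd trailing sample)
    are returned verbatim; the even-length remainder is circularly
    filtered and downsampled by two into each band.
    """
    x = np.asarray(x, dtype=float).ravel()
    L = pair.length
    T = L - 1
    m = x.size - T
    m -= m % 2
    if m < 2:
        raise InsufficientData("segment too short to split")
    z = x[T : T + m]
    tail = x[T + m :]
    lo = np.fft.rfft(_pad_circular(pair.low, m))
    hi = np.fft.rfft(_pad_circular(pair.high, m))
    Z = np.fft.rfft(z)
    low = np.fft.irfft(Z * np.conj(lo), m)[::2]
    high = np.fft.irfft(Z * np.conj(hi), m)[::2]
    passthrough = np.concatenate([x[:T], tail])
    return passthrough, low, high


def synthesize(passthrough, low, high, pair: FilterPair):
    """Inverse of :func:`analyze`; restores the node's samples exactly."""
    low = np.asarray(low, dtype=float)
    high = np.asarray(high, dtype=float)
    passthrough = np.asarray(passthrough, dtype=float)
    m = 2 * low.size
    T = pair.length - 1
    lo = np.fft.rfft(_pad_circular(pair.low, m))
    hi = np.fft.rfft(_pad_circular(pair.high, m))
    up_l = np.zeros(m)
    up_l[::2] = low
    up_h = np.zeros(m)
    up_h[::2] = high
    z = np.fft.irfft(np.fft.rfft(up_l) * lo + np.fft.rfft(up_h) * hi, m)
    return np.concatenate([passthrough[:T], z, passthrough[T:]])


def splittable(n_samples: int, pair: FilterPair) -> bool:
    return n_samples - (pair.length - 1) >= 2


def _default_bits(s: np.ndarray, override: float | None) -> float:
    if override is not None:
        return override
    # standard-normal default for the node stream's first sample
    return 0.5 * (math.log(2.0 * math.pi) + float(s[0]) ** 2) / math.log(2.0)


def leaf_bits(s: np.ndarray, default_bits: float | None = None) -> float:
    """Bits of a node's samples under the staged scalar Gaussian coder."""
    s = np.asarray(s, dtype=float).ravel()
    if s.size == 0:
        return 0.0
    return float(staged_bits_mean_var(s, _default_bits(s, default_bits)).sum())


def weighted_codelength(
    x,
    pair: FilterPair | None = None,
    D: int = 4,
    default_bits: float | None = None,
) -> float:
    """Weighted codelength of ``x`` over all decomposition trees of depth <= D.

    ``default_bits`` overrides the default-coder bits for the root stream's
    first sample (child streams always use the standard-normal default).
    """
    if D < 0:
        raise ValueError("D must be >= 0")
    pair = pair or FilterPair.from_wavelet("db4")
    x = np.asarray(x, dtype=float).ravel()

    def node(s: np.ndarray, depth: int, db: float | None) -> float:
        direct = leaf_bits(s, db)
        if depth >= D or not splittable(s.size, pair):
            return direct
        passthrough, low, high = analyze(s, pair)
        split = leaf_bits(passthrough, db) + node(low, depth + 1, None) + node(high, depth + 1, None)
        # 1-bit mixture of the leaf and split alternatives
        return float(-np.logaddexp2(-direct, -split) + 1.0)

    return node(x, 0, default_bits)


def count_trees(D: int) -> int:
    """Number of decomposition trees of maximum depth D with the root split.

    Each node either terminates or splits into two children down to the
    depth limit; the no-split tree is excluded by the root-split
    convention.  ``count(D) = g(D-1)^2`` with ``g(0) = 1`` and
    ``g(d) = 1 + g(d-1)^2``; D = 4 gives 676.
    """
    if D < 1:
        raise ValueError("count_trees requires D >= 1")
    g = 1
    for _ in range(D - 1):
        g = 1 + g * g
    return g * g


def best_tree_bits(
    x,
    pair: FilterPair | None = None,
    D: int = 3,
    default_bits: float | None = None,
) -> tuple[float, float]:
    """Exhaustive search over all depth-<=D trees (no-split tree included).

    Returns ``(best, best_penalized)``: the smallest tree codelength, and
    the smallest codelength-plus-decision-count over trees (one bit per
    leaf/split decision).  The weighted codelength is bracketed by the
    two.  Exponential in D; meant for verification at D <= 3.
    """
    pair = pair or FilterPair.from_wavelet("db4")
    x = np.asarray(x, dtype=float).ravel()

    def node(s: np.ndarray, depth: int, db: float | None) -> tuple[float, float]:
        direct = leaf_bits(s, db)
        if depth >= D or not splittable(s.size, pair):
            return direct, direct
        passthrough, low, high = analyze(s, pair)
        bl, pl = node(low, depth + 1, None)
        bh, ph = node(high, depth + 1, None)
        pass_bits = leaf_bits(passthrough, db)
        split = pass_bits + bl + bh
        pen_split = pass_bits + pl + ph + 1.0
        return min(direct, split), min(direct + 1.0, pen_split)

    return node(x, 0, default_bits)
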