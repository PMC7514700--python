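"""Codelength primitives shared by every coder.

All codelengths are in bits (base-2 logarithms).  A codelength for a
real-valued sample is ``-log2 f(x)`` where ``f`` is the coding density;
the quantization-resolution constant common to all coders cancels in every
comparison and is never represented.  Densities are carried as natural-log
values internally and converted to bits only at the API boundary.
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np
from scipy.special import logsumexp

LN2 = math.log(2.0)

#: Rissanen's normalizing constant for the universal integer code, in bits.
#: The Kraft sum of 2^-(c + log* i) over all positive integers equals 1 for
#: c = log2(2.865064...).
RISSANEN_C = math.log2(2.865064)


class CodingError(ValueError):
    """Base class for coder errors."""


class InsufficientData(CodingError):
    """A predictive density was requested before its statistics are defined."""


class DegenerateStatistics(CodingError):
    """Statistics are degenerate (e.g. an all-zero history for a scale model)."""


def nll_bits(density_value: float) -> float:
    """Codelength in bits of a sample under a coding density value.

    Parameters
    ----------
    density_value
        Value of the coding pdf at the sample; must be strictly positive
        and finite.
    """
    d = float(density_value)
    if not math.isfinite(d) or d <= 0.0:
        raise CodingError(f"invalid density value {density_value!r}")
    return -math.log2(d)


def log_star(i: int, c: float = RISSANEN_C) -> float:
    """Universal code length for a positive integer, ``c + log* i`` bits.

    ``log* i = log2 i + log2 log2 i + ...`` with the sum continuing while
    the iterated logarithm stays positive.
    """
    if i < 1:
        raise CodingError(f"log_star requires a positive integer, got {i}")
    total = 0.0
    v = math.log2(i)
    while v > 0.0:
        total += v
        v = math.log2(v)
    return c + total


def log_star_lengths(max_i: int, c: float = RISSANEN_C) -> np.ndarray:
    """Vector of ``log_star(i, c)`` for i = 1..max_i (index 0 unused, = inf)."""
    out = np.empty(max_i + 1)
    out[0] = np.inf
    for i in range(1, max_i + 1):
        out[i] = log_star(i, c)
    return out


def mixture_codelength(
    lengths: Sequence[float],
    ordinals: Sequence[int] | None = None,
    c: float = RISSANEN_C,
) -> float:
    """Codelength of the model mixture over a finite coder set.

    Each model contributes its stream codelength plus the universal-code
    cost of its ordinal; the mixture codelength is

        -log2 sum_i 2^(-lengths[i] - (c + log* ordinals[i]))

    computed in the log domain.  It never exceeds the best single penalized
    model and the implied code is Kraft-valid.
    """
    L = np.asarray(lengths, dtype=float)
    if L.ndim != 1 or L.size == 0:
        raise CodingError("mixture_codelength needs a nonempty list of lengths")
    if ordinals is None:
        ordinals = range(1, L.size + 1)
    ords = list(ordinals)
    if len(ords) != L.size:
        raise CodingError("lengths and ordinals must have the same size")
    pen = L + np.array([log_star(o, c) for o in ords])
    return float(-logsumexp(-pen * LN2) / LN2)
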