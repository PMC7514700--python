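"""Codelength scanner for atypical subsequences.

A subsequence of a long signal is atypical when some alternative coder
describes it in fewer bits than the typical coder, after paying for the
model identity (universal integer code over the coder ordinal) and the
subsequence length (``log* l``).  For every start position the scanner
scores

    dL(n) = max_l  L_T(X(n, l)) - L_A(X(n, l))

and a detection is any interval with ``dL > tau``, where the threshold
``tau`` is the length of the header announcing an atypical segment — the
log-frequency of atypical events.

The search runs in three stages, because computing dL everywhere is
quadratic: a coarse stage compares codelengths of non-overlapping dyadic
blocks (each block is scored repeated twice, so that a pattern too weak
at one block length still surfaces; the resulting false positives are
removed later), a fine stage exhaustively scores every subsequence of the
expanded flagged blocks, and a segmentation stage greedily accepts
non-overlapping candidates in decreasing dL order — a tractable surrogate
for globally minimizing the total codelength of the stream.

Atypical codelengths are the model mixture over the configured coder set
(a valid code), attributed to the single best coder for reporting.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import RISSANEN_C, log_star, mixture_codelength
from .filterbank import FilterPair, weighted_codelength
from .lp import staged_ar_bits
from .scalar import staged_bits_mean_var
from .sparse import choose_N

__all__ = [
    "Detection",
    "ScanConfig",
    "atypical_bits",
    "delta_L",
    "coarse_search",
    "fine_search",
    "segment",
    "scan",
    "precision_recall",
    "stream_codelength",
]


@dataclass(frozen=True)
class Detection:
    """Scored atypical interval [start, end), 0-based, with dL in bits."""

    start: int
    end: int
    delta_bits: float
    coder: str = ""

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class ScanConfig:
    """Scanner settings.

    ``tau`` is the detection header in bits (default 20, about one false
    event per 10^6 scored positions under the typical model).  Coarse
    blocks have lengths ``2^i`` for i in ``i_min..i_max``; flagged blocks
    are expanded by ``margin_blocks`` blocks on each side before the fine
    stage, and subsequence lengths are capped at ``l_max`` (default four
    times the largest coarse block).  ``coders`` lists the atypical coder
    set in complexity order; the ordinal of each is its position + 1.
    """

    tau: float = 20.0
    i_min: int = 6
    i_max: int = 9
    l_max: int | None = None
    margin_blocks: int = 1
    coders: tuple[str, ...] = ("gauss", "lp")
    lp_order: int = 10
    fb_depth: int = 4
    fb_wavelet: str = "db4"
    dct_block: int = 32
    c: float = RISSANEN_C

    def __post_init__(self):
        if self.tau < 0:
            raise ValueError("tau must be >= 0")
        if self.i_min < 3:
            raise ValueError("i_min must be >= 3")
        if self.i_max < self.i_min:
            raise ValueError("i_max must be >= i_min")

    @property
    def effective_l_max(self) -> int:
        return self.l_max if self.l_max is not None else 4 * (1 << self.i_max)


# ---------------------------------------------------------------------------
# atypical coders


class _GaussCoder:
    """Staged scalar Gaussian coder (unknown mean and variance)."""

    name = "gauss"

    def cum_bits(self, seg, default_bits, config):
        return np.cumsum(staged_bits_mean_var(seg, default_bits))


class _LPCoder:
    """Staged NLM linear-prediction coder."""

    name = "lp"

    def cum_bits(self, seg, default_bits, config):
        return np.cumsum(staged_ar_bits(seg, config.lp_order, default_bits))


class _DyadicCoder:
    """Base for coders without a per-sample recursion.

    They are evaluated only at dyadic prefix lengths (and the full
    segment); other entries are +inf, so the mixture simply ignores them
    there.
    """

    min_len = 8

    def full_bits(self, seg, default_bits, config) -> float:  # pragma: no cover
        raise NotImplementedError

    def cum_bits(self, seg, default_bits, config):
        seg = np.asarray(seg, dtype=float)
        l = seg.size
        out = np.full(l, np.inf)
        m = self.min_len
        while m <= l:
            out[m - 1] = self.full_bits(seg[:m], default_bits, config)
            m *= 2
        if l >= self.min_len:
            out[l - 1] = min(out[l - 1], self.full_bits(seg, default_bits, config))
        return out


class _FBCoder(_DyadicCoder):
    """Weighted sub-band coder."""

    name = "fb"

    def full_bits(self, seg, default_bits, config):
        pair = FilterPair.from_wavelet(config.fb_wavelet)
        return weighted_codelength(seg, pair, config.fb_depth, default_bits)


class _DCTCoder(_DyadicCoder):
    """Greedy-N sparse DCT coder; a partial trailing block is coded by the
    staged scalar stream."""

    name = "dct"

    @property
    def min_len(self):
        return 2 * 32

    def full_bits(self, seg, default_bits, config):
        M = config.dct_block
        nb = seg.size // M
        if nb < 2:
            return float(staged_bits_mean_var(seg, default_bits).sum())
        blocks = seg[: nb * M].reshape(nb, M)
        _, bits = choose_N(blocks, default_bits=default_bits)
        tail = seg[nb * M :]
        if tail.size:
            bits += float(staged_bits_mean_var(tail, default_bits).sum())
        return bits


_CODERS = {c.name: c for c in (_GaussCoder(), _LPCoder(), _FBCoder(), _DCTCoder())}


def _coder_set(config: ScanConfig):
    try:
        return [_CODERS[name] for name in config.coders]
    except KeyError as e:
        raise ValueError(f"unknown atypical coder {e.args[0]!r}") from None


_LOGSTAR_CACHE = np.empty(0)


def _log_star_array(l: int, c: float) -> np.ndarray:
    """``c + log*`` for lengths 1..l (index i-1), cached."""
    global _LOGSTAR_CACHE
    if _LOGSTAR_CACHE.size < l:
        grown = np.empty(max(l, 2 * _LOGSTAR_CACHE.size, 1024))
        for i in range(grown.size):
            grown[i] = log_star(i + 1, 0.0)
        _LOGSTAR_CACHE = grown
    return _LOGSTAR_CACHE[:l] + c


def _mixture_cum(seg, default_bits, config: ScanConfig):
    """Per-prefix mixture bits and per-coder penalized cumulative bits."""
    coders = _coder_set(config)
    pen = np.stack(
        [
            coder.cum_bits(seg, default_bits, config) + log_star(k + 1, config.c)
            for k, coder in enumerate(coders)
        ]
    )
    with np.errstate(invalid="ignore"):
        mix = -np.logaddexp2.reduce(-pen, axis=0)
    return mix, pen


def atypical_bits(x_seg, config: ScanConfig | None = None, default_bits: float = 2.05):
    """Mixture codelength of one segment, with best-coder attribution.

    Returns ``(bits, coder_name)`` where bits include the universal-code
    cost of the segment length and of the coder ordinal.
    """
    config = config or ScanConfig()
    seg = np.asarray(x_seg, dtype=float).ravel()
    if seg.size == 0:
        raise ValueError("empty segment")
    mix, pen = _mixture_cum(seg, default_bits, config)
    bits = float(mix[-1]) + log_star(seg.size, config.c)
    best = int(np.argmin(pen[:, -1]))
    return bits, _coder_set(config)[best].name


def delta_L(
    x,
    n: int,
    config: ScanConfig | None = None,
    typical=None,
    typ_bits=None,
    l_cap: int | None = None,
):
    """Best codelength saving over subsequences starting at sample n.

    Returns ``(dL, l, coder)`` for the maximizing length.  ``typ_bits``
    (per-sample typical bits) may be passed to avoid refitting the
    typical coder; otherwise ``typical`` must provide ``per_sample_bits``.
    """
    config = config or ScanConfig()
    x = np.asarray(x, dtype=float).ravel()
    if not 0 <= n < x.size:
        raise ValueError("start index out of range")
    if typ_bits is None:
        if typical is None:
            raise ValueError("need a typical coder or its per-sample bits")
        typ_bits = typical.per_sample_bits(x)
    lcap = min(config.effective_l_max, x.size - n)
    if l_cap is not None:
        lcap = min(lcap, l_cap)
    seg = x[n : n + lcap]
    mix, pen = _mixture_cum(seg, float(typ_bits[n]), config)
    typ_cum = np.cumsum(typ_bits[n : n + lcap])
    dl = typ_cum - mix - _log_star_array(lcap, config.c)
    best = int(np.argmax(dl))
    coder = _coder_set(config)[int(np.argmin(pen[:, best]))].name
    return float(dl[best]), best + 1, coder


# ---------------------------------------------------------------------------
# search stages


def coarse_search(x, config: ScanConfig | None = None, typical=None, typ_bits=None):
    """Dyadic block screen with block doubling.

    For each level i, the stream is tiled with non-overlapping blocks of
    length 2^i (any remainder is ignored) and each block, repeated twice,
    is coded typically and atypically; blocks whose doubled atypical
    codelength is the smaller are flagged as ``(level, start, end)``.
    """
    config = config or ScanConfig()
    x = np.asarray(x, dtype=float).ravel()
    if typ_bits is None:
        typ_bits = typical.per_sample_bits(x)
    flags = []
    for i in range(config.i_min, config.i_max + 1):
        B = 1 << i
        if B > x.size:
            break
        for k in range(x.size // B):
            s, e = k * B, (k + 1) * B
            doubled = np.tile(x[s:e], 2)
            atyp, _ = atypical_bits(doubled, config, float(typ_bits[s]))
            typ = 2.0 * float(typ_bits[s:e].sum())
            if typ - atyp > 0.0:
                flags.append((i, s, e))
    return flags


def _merge_windows(flags, config: ScanConfig, n_total: int):
    windows = []
    for level, s, e in flags:
        B = 1 << level
        windows.append((max(0, s - config.margin_blocks * B), min(n_total, e + config.margin_blocks * B)))
    windows.sort()
    merged: list[list[int]] = []
    for a, b in windows:
        if merged and a <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], b)
        else:
            merged.append([a, b])
    return [(a, b) for a, b in merged]


def fine_search(x, flagged, config: ScanConfig | None = None, typical=None, typ_bits=None):
    """Exhaustive subsequence scoring inside expanded flagged blocks.

    Every subsequence of each expanded window (length capped at ``l_max``)
    is scored; for each start the best length is kept, and starts whose
    best saving exceeds ``tau`` become candidate detections.
    """
    config = config or ScanConfig()
    x = np.asarray(x, dtype=float).ravel()
    if typ_bits is None:
        typ_bits = typical.per_sample_bits(x)
    typ_cum = np.concatenate([[0.0], np.cumsum(typ_bits)])
    candidates = []
    for wa, wb in _merge_windows(flagged, config, x.size):
        for n in range(wa, wb):
            lcap = min(config.effective_l_max, wb - n)
            seg = x[n : n + lcap]
            mix, pen = _mixture_cum(seg, float(typ_bits[n]), config)
            dl = (
                typ_cum[n + 1 : n + lcap + 1]
                - typ_cum[n]
                - mix
                - _log_star_array(lcap, config.c)
            )
            best = int(np.argmax(dl))
            if dl[best] > config.tau:
                coder = _coder_set(config)[int(np.argmin(pen[:, best]))].name
                candidates.append(Detection(n, n + best + 1, float(dl[best]), coder))
    return candidates


def segment(candidates, config: ScanConfig | None = None) -> list[Detection]:
    """Greedy non-overlapping selection of candidates above threshold.

    Candidates are taken in decreasing dL order (ties to the earlier
    start); each is accepted if it overlaps no previously accepted
    interval.  Detections are returned sorted by start.
    """
    config = config or ScanConfig()
    ordered = sorted(candidates, key=lambda d: (-d.delta_bits, d.start))
    accepted: list[Detection] = []
    for cand in ordered:
        if cand.delta_bits <= config.tau:
            continue
        if all(cand.end <= a.start or cand.start >= a.end for a in accepted):
            accepted.append(cand)
    return sorted(accepted, key=lambda d: d.start)


def scan(x, typical, config: ScanConfig | None = None) -> list[Detection]:
    """Full three-stage scan of a stream; returns non-overlapping detections."""
    config = config or ScanConfig()
    x = np.asarray(x, dtype=float).ravel()
    typ_bits = typical.per_sample_bits(x)
    flags = coarse_search(x, config, typ_bits=typ_bits)
    candidates = fine_search(x, flags, config, typ_bits=typ_bits)
    return segment(candidates, config)


# ---------------------------------------------------------------------------
# evaluation and accounting


def precision_recall(detections, truth, min_overlap: float = 0.0):
    """Overlap-based precision and recall of detections against truth.

    A detection is correct when it overlaps some truth interval (by more
    than ``min_overlap`` fraction of the truth interval, default any
    overlap); recall is the fraction of truth intervals hit, precision
    the fraction of detections that are correct (1.0 when there are no
    detections, by convention).
    """

    def _iv(d):
        return (d.start, d.end) if isinstance(d, Detection) else (int(d[0]), int(d[1]))

    dets = [_iv(d) for d in detections]
    gts = [_iv(t) for t in truth]

    def overlaps(a, b):
        inter = min(a[1], b[1]) - max(a[0], b[0])
        need = min_overlap * (b[1] - b[0])
        return inter > need if min_overlap > 0 else inter > 0

    hit_truth = sum(1 for g in gts if any(overlaps(d, g) for d in dets))
    correct_dets = sum(1 for d in dets if any(overlaps(d, g) for g in gts))
    recall = hit_truth / len(gts) if gts else 1.0
    precision = correct_dets / len(dets) if dets else 1.0
    return precision, recall


def stream_codelength(x, detections, config: ScanConfig | None = None, typical=None, typ_bits=None):
    """Total decodable bits of the stream given a detection set.

    Typical bits over the gaps plus, for each detection, its atypical
    mixture bits (length cost included) and the ``tau``-bit header.  With
    no detections this is the all-typical codelength.
    """
    config = config or ScanConfig()
    x = np.asarray(x, dtype=float).ravel()
    if typ_bits is None:
        typ_bits = typical.per_sample_bits(x)
    total = 0.0
    pos = 0
    for det in sorted(detections, key=lambda d: d.start):
        total += float(typ_bits[pos : det.start].sum())
        atyp, _ = atypical_bits(x[det.start : det.end], config, float(typ_bits[det.start]))
        total += atyp + config.tau
        pos = det.end
    total += float(typ_bits[pos:].sum())
    return total
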