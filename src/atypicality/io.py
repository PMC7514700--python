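"""Signal and interval I/O.

WAV (integer PCM scaled to [-1, 1), or float) via scipy; CSV with an
optional header, one column per channel (a ``sample`` index column is
dropped).  All intervals are 0-based, half-open, in sample coordinates.
Non-finite samples are rejected at load with the offending row.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.io import wavfile


@dataclass
class SignalFile:
    """Loaded signal: samples (1-D, or samples x channels) and optional rate."""

    samples: np.ndarray
    rate: float | None = None

    @property
    def n_channels(self) -> int:
        return 1 if self.samples.ndim == 1 else self.samples.shape[1]


def _check_finite(x: np.ndarray, origin: str) -> None:
    bad = ~np.isfinite(x)
    if bad.any():
        row = int(np.argwhere(bad)[0][0])
        raise ValueError(f"{origin}: non-finite sample at row {row}")


def read_signal(path, channel: int | None = None) -> SignalFile:
    """Read a WAV or CSV signal file.

    WAV integer PCM is scaled to [-1, 1); multichannel data returns the
    full matrix unless ``channel`` selects one (WAV defaults to the first
    channel).  CSV headers are optional; a ``sample`` column is treated
    as an index and dropped.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    suffix = path.suffix.lower()
    if suffix == ".wav":
        rate, data = wavfile.read(path)
        if np.issubdtype(data.dtype, np.integer):
            data = data.astype(np.float64) / float(2 ** (8 * data.dtype.itemsize - 1))
        else:
            data = data.astype(np.float64)
        if data.ndim > 1:
            data = data[:, channel if channel is not None else 0]
        _check_finite(data, str(path))
        return SignalFile(data, float(rate))
    if suffix == ".csv":
        try:
            df = pd.read_csv(path)
        except pd.errors.EmptyDataError:
            raise ValueError(f"{path}: empty file") from None
        if df.empty and df.columns.size == 0:
            raise ValueError(f"{path}: empty file")
        # headerless numeric files: first row was consumed as a header
        if all(_is_number(c) for c in df.columns):
            df = pd.read_csv(path, header=None)
        cols = [c for c in df.columns if str(c).strip().lower() != "sample"]
        mat = df[cols].to_numpy(dtype=float)
        if np.isnan(mat).any():
            row = int(np.argwhere(np.isnan(mat))[0][0])
            raise ValueError(f"{path}: malformed or missing value at data row {row}")
        _check_finite(mat, str(path))
        data = mat[:, 0] if mat.shape[1] == 1 else mat
        if channel is not None and data.ndim > 1:
            data = data[:, channel]
        return SignalFile(data, None)
    raise ValueError(f"unrecognized signal format {suffix!r} (expected .wav or .csv)")


def _is_number(c) -> bool:
    try:
        float(c)
        return True
    except (TypeError, ValueError):
        return False


def write_signal(path, samples, rate: int = 8000) -> None:
    """Write a signal as float32 WAV or CSV, by extension."""
    path = Path(path)
    samples = np.asarray(samples, dtype=float)
    if path.suffix.lower() == ".wav":
        wavfile.write(path, int(rate), samples.astype(np.float32))
    elif path.suffix.lower() == ".csv":
        pd.DataFrame({"value": samples}).to_csv(path, index=False)
    else:
        raise ValueError(f"unrecognized signal format {path.suffix!r}")


def write_detections(path, detections) -> None:
    """Write detections as CSV: start_sample,end_sample,delta_bits,coder."""
    rows = [
        {
            "start_sample": d.start,
            "end_sample": d.end,
            "delta_bits": d.delta_bits,
            "coder": d.coder,
        }
        for d in detections
    ]
    pd.DataFrame(rows, columns=["start_sample", "end_sample", "delta_bits", "coder"]).to_csv(
        path, index=False
    )


def read_detections(path):
    """Read a detections CSV back into Detection objects."""
    from .scanner import Detection

    df = pd.read_csv(path)
    return [
        Detection(int(r.start_sample), int(r.end_sample), float(r.delta_bits), str(r.coder))
        for r in df.itertuples()
    ]


def read_truth(path) -> list[tuple[int, int]]:
    """Read ground-truth intervals (CSV of start,end; header optional)."""
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise ValueError(f"{path}: empty file") from None
    if all(_is_number(c) for c in df.columns):
        df = pd.read_csv(path, header=None)
    mat = df.to_numpy()
    out = []
    for i, row in enumerate(mat):
        try:
            s, e = int(row[0]), int(row[1])
        except (TypeError, ValueError, IndexError):
            raise ValueError(f"{path}: malformed interval at data row {i}") from None
        if e <= s:
            raise ValueError(f"{path}: empty interval at data row {i}")
        out.append((s, e))
    return out


def write_truth(path, intervals) -> None:
    pd.DataFrame(intervals, columns=["start", "end"]).to_csv(path, index=False)
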