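"""Audio streams and analyst selection tables.

Continuous passive-acoustic recordings are represented as mono
:class:`AudioStream` objects (pressure amplitude in [-1, 1], sample rate in
Hz).  Analyst annotations — time-frequency bounding boxes around sound
events — travel as :class:`Annotation` lists and are serialized as Raven-style
tab-separated selection tables, the de-facto exchange format in bioacoustics.

Times are seconds from stream start; intervals are half-open ``[begin, end)``.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace
from fractions import Fraction

import numpy as np
import pandas as pd
from scipy.io import wavfile
from scipy.signal import resample_poly

from .errors import (
    AudioFileError,
    ChannelError,
    SelectionTableError,
    UnsupportedEncodingError,
)

__all__ = [
    "AudioStream",
    "Annotation",
    "read_audio",
    "write_audio",
    "resample_to",
    "read_selection_table",
    "write_selection_table",
]

#: Required selection-table columns, in canonical order.
REQUIRED_COLUMNS = (
    "Begin Time (s)",
    "End Time (s)",
    "Low Freq (Hz)",
    "High Freq (Hz)",
)
LABEL_COLUMN = "Label"


@dataclass(frozen=True)
class AudioStream:
    """A mono pressure-amplitude sequence with a sample rate and time origin."""

    samples: np.ndarray
    sample_rate_hz: float
    start_time_s: float = 0.0
    source_id: str = ""

    def __post_init__(self):
        samples = np.asarray(self.samples, dtype=np.float64)
        if self.sample_rate_hz <= 0:
            raise ValueError("sample_rate_hz must be positive")
        if samples.ndim != 1:
            raise ValueError("AudioStream is mono: samples must be 1-D")
        if not np.all(np.isfinite(samples)):
            raise ValueError("samples must be finite")
        object.__setattr__(self, "samples", samples)

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sample_rate_hz

    def slice_seconds(self, begin_s: float, end_s: float) -> "AudioStream":
        """Cut ``[begin_s, end_s)`` (stream time), zero-padding outside."""
        i0 = int(round((begin_s - self.start_time_s) * self.sample_rate_hz))
        i1 = int(round((end_s - self.start_time_s) * self.sample_rate_hz))
        n = i1 - i0
        out = np.zeros(n, dtype=np.float64)
        lo, hi = max(i0, 0), min(i1, self.n_samples)
        if hi > lo:
            out[lo - i0 : hi - i0] = self.samples[lo:hi]
        return replace(self, samples=out, start_time_s=begin_s)


@dataclass(frozen=True)
class Annotation:
    """A time-frequency bounding box with a category label."""

    begin_time_s: float
    end_time_s: float
    low_freq_hz: float
    high_freq_hz: float
    label: str = "upcall"
    source: str = ""
    extra: dict = field(default_factory=dict, compare=False)

    def __post_init__(self):
        if not self.end_time_s > self.begin_time_s:
            raise ValueError("end_time_s must exceed begin_time_s")
        if not (self.high_freq_hz > self.low_freq_hz >= 0):
            raise ValueError("need high_freq_hz > low_freq_hz >= 0")

    @property
    def midpoint_s(self) -> float:
        return 0.5 * (self.begin_time_s + self.end_time_s)

    @property
    def duration_s(self) -> float:
        return self.end_time_s - self.begin_time_s


def read_audio(path: str | os.PathLike, channel: int = 0) -> AudioStream:
    """Read one channel of a PCM/float WAV file as an :class:`AudioStream`.

    Integer PCM is scaled to [-1, 1] by the convention ``x / 2**(bits-1)``
    (a full-scale 16-bit sample maps to 32767/32768).  Multi-channel files
    are not mixed down; ``channel`` selects one sensor.
    """
    if not os.path.exists(path):
        raise AudioFileError(f"no such audio file: {path}")
    try:
        rate, data = wavfile.read(path)
    except AudioFileError:
        raise
    except Exception as exc:  # scipy raises bare ValueError for exotic encodings
        raise UnsupportedEncodingError(f"cannot decode {path}: {exc}") from exc

    if data.ndim == 2:
        if not 0 <= channel < data.shape[1]:
            raise ChannelError(
                f"channel {channel} out of range for {data.shape[1]}-channel file"
            )
        data = data[:, channel]
    elif channel != 0:
        raise ChannelError(f"channel {channel} requested from mono file")

    if data.dtype == np.int16:
        samples = data.astype(np.float64) / 32768.0
    elif data.dtype == np.int32:
        samples = data.astype(np.float64) / 2147483648.0
    elif data.dtype == np.uint8:
        samples = (data.astype(np.float64) - 128.0) / 128.0
    elif data.dtype in (np.float32, np.float64):
        samples = data.astype(np.float64)
    else:
        raise UnsupportedEncodingError(f"unsupported WAV sample dtype {data.dtype}")
    return AudioStream(samples, float(rate), source_id=os.fspath(path))


def write_audio(stream: AudioStream, path: str | os.PathLike, encoding: str = "int16"):
    """Write a stream as PCM WAV (``int16``, clipped+rounded) or ``float32``."""
    if encoding == "int16":
        data = np.clip(np.round(stream.samples * 32768.0), -32768, 32767).astype(
            np.int16
        )
    elif encoding == "float32":
        data = stream.samples.astype(np.float32)
    else:
        raise UnsupportedEncodingError(f"unsupported write encoding {encoding!r}")
    wavfile.write(path, int(round(stream.sample_rate_hz)), data)


def resample_to(stream: AudioStream, target_hz: float) -> AudioStream:
    """Resample with a polyphase anti-aliasing filter; no-op at equal rates."""
    if target_hz <= 0:
        raise ValueError("target_hz must be positive")
    if target_hz == stream.sample_rate_hz:
        return stream
    frac = Fraction(target_hz / stream.sample_rate_hz).limit_denominator(10**6)
    out = resample_poly(stream.samples, frac.numerator, frac.denominator)
    return replace(stream, samples=out, sample_rate_hz=float(target_hz))


def _parse_row(row: pd.Series, idx: int, extra_cols: list[str]) -> Annotation:
    vals = []
    for col in REQUIRED_COLUMNS:
        v = row[col]
        try:
            vals.append(float(v))
        except (TypeError, ValueError):
            raise SelectionTableError(
                f"non-numeric value {v!r} in column {col!r}", row=idx
            ) from None
    begin, end, low, high = vals
    if begin >= end:
        raise SelectionTableError(f"begin time {begin} >= end time {end}", row=idx)
    label = str(row[LABEL_COLUMN]) if LABEL_COLUMN in row.index else "upcall"
    extra = {c: row[c] for c in extra_cols}
    try:
        return Annotation(begin, end, low, high, label=label, extra=extra)
    except ValueError as exc:
        raise SelectionTableError(str(exc), row=idx) from None


def read_selection_table(path: str | os.PathLike) -> list[Annotation]:
    """Read a Raven-style tab-separated selection table.

    The four time/frequency columns are required; a ``Label`` column and any
    unknown extra columns are preserved (extras round-trip via
    ``Annotation.extra``).
    """
    if not os.path.exists(path):
        raise SelectionTableError(f"no such selection table: {path}")
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SelectionTableError(f"missing required column(s): {missing}")
    extra_cols = [
        c
        for c in df.columns
        if c not in REQUIRED_COLUMNS and c not in (LABEL_COLUMN, "Selection")
    ]
    return [_parse_row(row, idx + 1, extra_cols) for idx, row in df.iterrows()]


def write_selection_table(annotations: list[Annotation], path: str | os.PathLike):
    """Write annotations sorted by begin time, preserving extra columns.

    Fields are written with 10 significant digits so a round-trip preserves
    them well beyond the 6-digit contract.
    """
    anns = sorted(annotations, key=lambda a: a.begin_time_s)
    extra_cols: list[str] = []
    for a in anns:
        for c in a.extra:
            if c not in extra_cols:
                extra_cols.append(c)
    rows = []
    for i, a in enumerate(anns, start=1):
        row = {
            "Selection": i,
            "Begin Time (s)": f"{a.begin_time_s:.10g}",
            "End Time (s)": f"{a.end_time_s:.10g}",
            "Low Freq (Hz)": f"{a.low_freq_hz:.10g}",
            "High Freq (Hz)": f"{a.high_freq_hz:.10g}",
            LABEL_COLUMN: a.label,
        }
        for c in extra_cols:
            row[c] = a.extra.get(c, "")
        rows.append(row)
    cols = ["Selection", *REQUIRED_COLUMNS, LABEL_COLUMN, *extra_cols]
    pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False)
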