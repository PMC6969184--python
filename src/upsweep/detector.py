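"""Sliding-window detection over continuous audio.

A trained patch classifier is advanced across the stream as a 2 s window
every 0.1 s, producing a dense :class:`ScoreTrack` of upcall probabilities.
Greedy non-maximum suppression (restricted to probabilities >= 0.05 by
default) reduces the track to isolated :class:`Detection` events at the
window centers of local score maxima.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import StreamTooShortError
from .features import SpectrogramPatch, normalize_patch
from .signal_io import AudioStream, Annotation
from scipy.signal.windows import hann

__all__ = ["ScoreTrack", "Detection", "score_stream", "non_max_suppress", "detections_to_annotations"]


@dataclass(frozen=True)
class ScoreTrack:
    """Dense per-window upcall probabilities along a stream."""

    times: np.ndarray  # window start times, strictly increasing, constant hop
    scores: np.ndarray  # probabilities in [0, 1]
    hop_s: float = 0.1
    window_s: float = 2.0

    def __post_init__(self):
        t = np.asarray(self.times, dtype=np.float64)
        s = np.asarray(self.scores, dtype=np.float64)
        if t.shape != s.shape:
            raise ValueError("times and scores must have equal length")
        if np.any((s < 0) | (s > 1)):
            raise ValueError("scores must lie in [0, 1]")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "scores", s)


@dataclass(frozen=True)
class Detection:
    """A suppressed score peak: window-center time plus its probability."""

    peak_time_s: float
    score: float
    window_begin_s: float
    window_end_s: float
    stream_id: str = ""


def _featurize_windows(
    stream: AudioStream, starts_samples: np.ndarray, params, normalization_mode: str
) -> list[SpectrogramPatch]:
    """Cut + featurize many windows at once (vectorized over windows).

    Equivalent to per-window ``patch_from_clip`` + ``normalize_patch``: each
    window is framed with the same zero-padded tail convention.
    """
    win = params.fft_length_samples
    hop = params.hop_samples
    n_frames = params.n_time_frames
    need = (n_frames - 1) * hop + win
    clip_len = params.clip_samples
    padded = np.concatenate(
        [stream.samples, np.zeros(need - clip_len, dtype=np.float64)]
    )
    window_fn = hann(win, sym=False)
    patches = []
    frame_idx = np.arange(n_frames)[:, None] * hop + np.arange(win)[None, :]
    for chunk_start in range(0, len(starts_samples), 512):
        chunk = starts_samples[chunk_start : chunk_start + 512]
        idx = chunk[:, None, None] + frame_idx[None, :, :]
        frames = padded[idx]
        # per-window convention: samples past each clip end are zeroed
        rel = frame_idx[None, :, :]
        frames = np.where(rel < clip_len, frames, 0.0)
        spec = np.fft.rfft(frames * window_fn, axis=2)
        lo = params.low_bin_index
        mags = np.abs(spec[:, :, lo : lo + params.n_freq_bins])
        for w, start in zip(mags, chunk):
            patch = SpectrogramPatch(
                values=w.T.copy(),
                time_origin_s=stream.start_time_s + start / stream.sample_rate_hz,
                freq_origin_hz=params.freq_origin_hz,
                params=params,
            )
            patches.append(normalize_patch(patch, normalization_mode))
    return patches


def score_stream(scorer, stream: AudioStream, hop_s: float = 0.1) -> ScoreTrack:
    """Score every 2 s window at ``hop_s`` spacing across the stream.

    Windows are featurized and normalized exactly as in training; batching
    is an implementation detail (results equal per-window evaluation).
    """
    params = scorer.feature_params
    if abs(stream.sample_rate_hz - params.sample_rate_hz) > 1e-9:
        raise StreamTooShortError(
            f"stream rate {stream.sample_rate_hz} != analysis rate {params.sample_rate_hz}"
        )
    window_samples = params.clip_samples
    hop_samples = int(round(hop_s * stream.sample_rate_hz))
    n_windows = (stream.n_samples - window_samples) // hop_samples + 1
    if n_windows < 1:
        raise StreamTooShortError(
            f"stream of {stream.duration_s:.3f} s is shorter than one 2 s window"
        )
    starts = np.arange(n_windows) * hop_samples
    patches = _featurize_windows(stream, starts, params, scorer.normalization_mode)
    scores = scorer.predict_proba(patches)
    times = stream.start_time_s + starts / stream.sample_rate_hz
    return ScoreTrack(
        times=times,
        scores=scores,
        hop_s=hop_s,
        window_s=window_samples / stream.sample_rate_hz,
    )


def non_max_suppress(
    track: ScoreTrack,
    min_prob: float = 0.05,
    radius_s: float = 1.0,
    stream_id: str = "",
) -> list[Detection]:
    """Greedy 1-D non-maximum suppression of a score track.

    Repeatedly take the highest remaining score >= ``min_prob`` (ties go to
    the earlier window), emit a detection at that window's center, and
    suppress every window whose center lies strictly within ``radius_s`` of
    it.  Output is time-sorted; detections are never closer than
    ``radius_s``.
    """
    half = track.window_s / 2.0
    centers = track.times + half
    keep = track.scores >= min_prob
    order = np.lexsort((centers, -track.scores))
    alive = keep.copy()
    out = []
    for i in order:
        if not alive[i]:
            continue
        out.append(
            Detection(
                peak_time_s=float(centers[i]),
                score=float(track.scores[i]),
                window_begin_s=float(track.times[i]),
                window_end_s=float(track.times[i] + track.window_s),
                stream_id=stream_id,
            )
        )
        alive &= np.abs(centers - centers[i]) >= radius_s
    out.sort(key=lambda d: d.peak_time_s)
    return out


def detections_to_annotations(
    detections: list[Detection], low_freq_hz: float = 39.0625, high_freq_hz: float = 343.75
) -> list[Annotation]:
    """Export detections as selection-table rows (score in an extra column)."""
    return [
        Annotation(
            begin_time_s=d.peak_time_s - 1.0,
            end_time_s=d.peak_time_s + 1.0,
            low_freq_hz=low_freq_hz,
            high_freq_hz=high_freq_hz,
            label="upcall",
            extra={"Score": f"{d.score:.6g}"},
        )
        for d in detections
    ]
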