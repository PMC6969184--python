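"""Spectrogram-patch features.

A 2 s clip at 2 kHz becomes a square 40x40 matrix of STFT magnitudes:
40 frames (128 ms Hann window, 50 ms advance, the last frames zero-padded
past the clip end) by 40 frequency bins (FFT bins 5-44 of a 256-point
transform, bin centers 39.0625-343.75 Hz at 7.8125 Hz spacing).  The framing
starts every frame at k*hop, k = 0..39, which is what makes the patch exactly
square; the usual (N-W)/hop+1 rule would give 38 frames.

Patches are normalized either by the literal sum of squared elements
(``sum_square``: x -> x / sum(x^2), not gain-invariant) or to unit Frobenius
norm (``unit_frobenius``: x -> x / sqrt(sum(x^2)), gain-invariant).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.signal.windows import hann

from .errors import ClipContractError
from .signal_io import AudioStream

__all__ = ["StftParams", "SpectrogramPatch", "patch_from_clip", "normalize_patch"]

NORMALIZATION_MODES = ("sum_square", "unit_frobenius")


@dataclass(frozen=True)
class StftParams:
    """STFT analysis geometry for patch extraction."""

    window_s: float = 0.128
    hop_s: float = 0.050
    sample_rate_hz: float = 2000.0
    low_bin_index: int = 5
    n_freq_bins: int = 40
    n_time_frames: int = 40

    def __post_init__(self):
        if not self.window_s > self.hop_s > 0:
            raise ValueError("need window_s > hop_s > 0")
        nyq = self.sample_rate_hz / 2
        top = (self.low_bin_index + self.n_freq_bins) * self.bin_width_hz
        if top > nyq + 1e-9:
            raise ValueError("frequency bins exceed Nyquist")

    @property
    def fft_length_samples(self) -> int:
        return int(round(self.window_s * self.sample_rate_hz))

    @property
    def hop_samples(self) -> int:
        return int(round(self.hop_s * self.sample_rate_hz))

    @property
    def bin_width_hz(self) -> float:
        return self.sample_rate_hz / self.fft_length_samples

    @property
    def freq_origin_hz(self) -> float:
        """Center frequency of the lowest retained bin (39.0625 Hz default)."""
        return self.low_bin_index * self.bin_width_hz

    @property
    def clip_samples(self) -> int:
        """Nominal clip length: 2 s at the default geometry."""
        return self.hop_samples * self.n_time_frames


@dataclass(frozen=True)
class SpectrogramPatch:
    """A normalized (or raw) time-frequency magnitude matrix.

    ``values`` rows are frequency bins ascending, columns time frames
    ascending.
    """

    values: np.ndarray
    time_origin_s: float = 0.0
    freq_origin_hz: float = 39.0625
    normalization_mode: str = "none"
    zero_energy: bool = False
    params: StftParams = field(default_factory=StftParams, compare=False)

    def __post_init__(self):
        v = np.asarray(self.values, dtype=np.float64)
        if v.ndim != 2:
            raise ValueError("patch values must be a 2-D matrix")
        if not np.all(np.isfinite(v)) or np.any(v < 0):
            raise ValueError("patch values must be finite and non-negative")
        object.__setattr__(self, "values", v)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


def frame_clip(samples: np.ndarray, params: StftParams) -> np.ndarray:
    """Cut a clip into ``n_time_frames`` frames of ``fft_length_samples``.

    Frame k starts at ``k * hop_samples``; the tail is zero-padded so the
    final frames (whose windows run past the clip end) are well defined.
    Returns an array of shape ``(n_time_frames, fft_length_samples)``.
    """
    hop, win, n = params.hop_samples, params.fft_length_samples, params.n_time_frames
    need = (n - 1) * hop + win
    padded = np.zeros(need, dtype=np.float64)
    padded[: samples.shape[0]] = samples[:need]
    idx = np.arange(n)[:, None] * hop + np.arange(win)[None, :]
    return padded[idx]


def patch_from_clip(clip: AudioStream, params: StftParams | None = None) -> SpectrogramPatch:
    """Featurize a 2 s clip into an un-normalized magnitude patch.

    The clip must be at the analysis sample rate and of the nominal length to
    within one sample; anything else raises :class:`ClipContractError`.
    """
    params = params or StftParams()
    if abs(clip.sample_rate_hz - params.sample_rate_hz) > 1e-9:
        raise ClipContractError(
            f"clip rate {clip.sample_rate_hz} Hz != {params.sample_rate_hz} Hz"
        )
    if abs(clip.n_samples - params.clip_samples) > 1:
        raise ClipContractError(
            f"clip has {clip.n_samples} samples, expected {params.clip_samples} +/- 1"
        )
    frames = frame_clip(clip.samples, params)
    window = hann(params.fft_length_samples, sym=False)
    spec = np.fft.rfft(frames * window, axis=1)
    lo = params.low_bin_index
    mag = np.abs(spec[:, lo : lo + params.n_freq_bins])  # (time, freq)
    return SpectrogramPatch(
        values=mag.T.copy(),
        time_origin_s=clip.start_time_s,
        freq_origin_hz=params.freq_origin_hz,
        normalization_mode="none",
        params=params,
    )


def normalize_patch(patch: SpectrogramPatch, mode: str = "sum_square") -> SpectrogramPatch:
    """Normalize a patch by its energy.

    ``sum_square`` divides each element by the sum of squared elements;
    ``unit_frobenius`` divides by its square root, giving Frobenius norm 1.
    A zero-energy patch is returned unchanged with ``zero_energy=True``.
    """
    if mode not in NORMALIZATION_MODES:
        raise ValueError(f"unknown normalization mode {mode!r}; use {NORMALIZATION_MODES}")
    energy = float(np.sum(patch.values**2))
    if energy == 0.0:
        return replace(patch, normalization_mode=mode, zero_energy=True)
    denom = energy if mode == "sum_square" else np.sqrt(energy)
    return replace(patch, values=patch.values / denom, normalization_mode=mode)
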