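"""Preprocessing chain: normalization, bandpass, segmentation, spectrograms.

Per channel the chain is

    min–max normalize to [-1, 1]  →  3rd-order Butterworth 3–100 Hz
    →  2.5 s windows with 0.1 s overlap  →  80-point Hamming STFT
    →  40 × 126 greyscale image with values in [0, 128]

The normalization is the affine map ``x_bar = 2 (x - x_min)/(x_max - x_min) - 1``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from fecgsqi.errors import ConfigError, DegenerateSignalError
from fecgsqi.synth import CHANNEL_NAMES, Recording

__all__ = [
    "NormalizationParams",
    "Segment",
    "SpectrogramImage",
    "normalize",
    "bandpass",
    "segment",
    "stft_image",
    "preprocess_recording",
    "WINDOW_S",
    "OVERLAP_S",
    "IMAGE_SHAPE",
    "GREY_MAX",
]

WINDOW_S = 2.5
OVERLAP_S = 0.1
#: Spectrogram image shape: 40 frequency rows × 126 time frames.
IMAGE_SHAPE = (40, 126)
#: Upper bound of the greyscale pixel range.
GREY_MAX = 128.0

_NFFT = 80


@dataclass(frozen=True)
class NormalizationParams:
    """The min/max used by the [-1, 1] rescale (for inversion/provenance)."""

    x_min: float
    x_max: float

    def __post_init__(self) -> None:
        if not self.x_max > self.x_min:
            raise ConfigError("x_max must exceed x_min")


@dataclass
class Segment:
    """A 2.5 s four-channel window cut from a recording."""

    channels: np.ndarray  # (4, round(window_s * fs))
    recording_id: str
    start_sample: int
    label: str
    fs: float = 1000.0

    @property
    def n_samples(self) -> int:
        return self.channels.shape[1]

    def channel(self, name: str) -> np.ndarray:
        return self.channels[CHANNEL_NAMES.index(name)]


@dataclass
class SpectrogramImage:
    """A 40 × 126 greyscale time-frequency image of one channel segment."""

    pixels: np.ndarray
    freq_axis: np.ndarray  # 40 bin-center frequencies, Hz
    time_axis: np.ndarray  # 126 frame-center times, s

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        # 40 frequency rows always; the time axis is 126 frames under the
        # default framing (hop 20, centered) and 97 in the hop-25 variant.
        if self.pixels.ndim != 2 or self.pixels.shape[0] != IMAGE_SHAPE[0]:
            raise ConfigError(f"spectrogram image must have {IMAGE_SHAPE[0]} frequency rows")
        if self.pixels.min() < 0 or self.pixels.max() > GREY_MAX:
            raise ConfigError(f"pixel values must lie in [0, {GREY_MAX}]")


def normalize(x: np.ndarray) -> tuple[np.ndarray, NormalizationParams]:
    """Affine rescale of a signal to exactly [-1, +1].

    Raises :class:`DegenerateSignalError` on constant input, where the map
    is undefined (a constant channel usually means a dead electrode).
    """
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise ConfigError("cannot normalize an empty signal")
    x_min, x_max = float(x.min()), float(x.max())
    if x_max == x_min:
        raise DegenerateSignalError("constant signal: min-max normalization undefined")
    out = 2.0 * (x - x_min) / (x_max - x_min) - 1.0
    return out, NormalizationParams(x_min=x_min, x_max=x_max)


def bandpass(
    x: np.ndarray,
    fs: float,
    low: float = 3.0,
    high: float = 100.0,
    order: int = 3,
) -> np.ndarray:
    """Causal single-pass Butterworth bandpass (default 3–100 Hz, order 3)."""
    if not 0 < low < high < fs / 2:
        raise ConfigError("band edges must satisfy 0 < low < high < fs/2")
    sos = sps.butter(order, [low, high], btype="bandpass", fs=fs, output="sos")
    return sps.sosfilt(sos, np.asarray(x, dtype=float))


def segment(
    recording: Recording,
    window_s: float = WINDOW_S,
    overlap_s: float = OVERLAP_S,
) -> list[Segment]:
    """Cut a recording into fixed windows with the configured overlap.

    The stride is ``window_s - overlap_s``; a recording shorter than one
    window yields an empty list.  Each segment inherits the recording
    label.
    """
    if not window_s > overlap_s >= 0:
        raise ConfigError("require window_s > overlap_s >= 0")
    fs = recording.fs
    win = int(round(window_s * fs))
    stride = int(round((window_s - overlap_s) * fs))
    n = recording.n_samples
    segments: list[Segment] = []
    for start in range(0, n - win + 1, stride):
        segments.append(
            Segment(
                channels=recording.channels[:, start : start + win].copy(),
                recording_id=recording.id,
                start_sample=start,
                label=recording.label,
                fs=fs,
            )
        )
    return segments


def stft_image(
    channel_segment: np.ndarray,
    fs: float = 1000.0,
    hop: int = 20,
    centered: bool = True,
) -> SpectrogramImage:
    """80-point Hamming-window magnitude STFT rendered as a greyscale image.

    The one-sided spectrum minus the DC bin gives 40 frequency rows
    (12.5–500 Hz at 1 kHz); with the default hop of 20 samples and
    centered framing a 2500-sample input yields exactly 126 time frames.
    The literal hop-25, left-aligned variant (97 frames) is available via
    ``hop=25, centered=False``.  Magnitudes are min–max rescaled per image
    to [0, 128]; an all-zero input maps to the all-zero image.
    """
    x = np.asarray(channel_segment, dtype=float)
    if x.ndim != 1 or x.size != 2500:
        raise ConfigError("stft_image expects a 1-D segment of exactly 2500 samples")
    n = x.size
    win = np.hamming(_NFFT)
    if centered:
        pad = _NFFT // 2
        padded = np.concatenate([np.zeros(pad), x, np.zeros(_NFFT)])
        n_frames = n // hop + 1
        starts = np.arange(n_frames) * hop
        centers = starts / fs
    else:
        n_frames = (n - _NFFT) // hop + 1
        padded = x
        starts = np.arange(n_frames) * hop
        centers = (starts + _NFFT / 2) / fs
    frames = np.lib.stride_tricks.sliding_window_view(padded, _NFFT)[starts]
    spec = np.abs(np.fft.rfft(frames * win, n=_NFFT, axis=1))  # (frames, 41)
    mag = spec[:, 1 : _NFFT // 2 + 1].T  # drop DC -> (40, frames)
    lo, hi = float(mag.min()), float(mag.max())
    if hi > lo:
        pixels = (mag - lo) / (hi - lo) * GREY_MAX
    else:
        pixels = np.zeros_like(mag)
    freqs = np.fft.rfftfreq(_NFFT, d=1.0 / fs)[1 : _NFFT // 2 + 1]
    return SpectrogramImage(pixels=pixels, freq_axis=freqs, time_axis=centers)


def preprocess_recording(
    recording: Recording,
    window_s: float = WINDOW_S,
    overlap_s: float = OVERLAP_S,
    hop: int = 20,
) -> tuple[list[Segment], np.ndarray]:
    """Full chain: normalize → bandpass → segment → spectrogram per channel.

    Returns the segments (with normalized+filtered channels) and an image
    tensor of shape ``(n_segments, 4, 40, 126)``.
    """
    if recording.fs != 1000.0:
        raise ConfigError("the pipeline expects recordings sampled at 1 kHz")
    processed = np.empty_like(recording.channels)
    for i, name in enumerate(CHANNEL_NAMES):
        try:
            normed, _ = normalize(recording.channels[i])
        except DegenerateSignalError as exc:
            raise DegenerateSignalError(f"channel {name}: {exc}") from exc
        processed[i] = bandpass(normed, recording.fs)
    filtered = Recording(
        channels=processed,
        fs=recording.fs,
        mqrs=recording.mqrs,
        fqrs=recording.fqrs,
        label=recording.label,
        id=recording.id,
        meta=dict(recording.meta),
    )
    segments = segment(filtered, window_s=window_s, overlap_s=overlap_s)
    images = np.empty((len(segments), 4) + IMAGE_SHAPE, dtype=np.float32)
    for s_idx, seg in enumerate(segments):
        for c in range(4):
            images[s_idx, c] = stft_image(seg.channels[c], fs=recording.fs, hop=hop).pixels
    return segments, images
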