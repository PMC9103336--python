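"""Maternal-ECG cancellation by template subtraction with PCA (TSpca).

Fixed-length windows centered on the maternal R peaks are stacked,
mean-centered per window and decomposed by principal components; each
window is reconstructed from the leading components and subtracted in
place.  What remains is the residual — foetal ECG plus noise — since the
quasi-periodic maternal beat dominates the leading components.  Samples
outside every maternal window pass through unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from fecgsqi.errors import ConfigError, ExtractionError

__all__ = ["TspcaConfig", "extract_fecg"]


@dataclass(frozen=True)
class TspcaConfig:
    """Parameters of the template-subtraction + PCA cancellation.

    cycle_window_ms:
        Length of the beat window centered on each maternal R peak.
    n_components:
        Number of principal components used for the reconstruction.
    min_cycles:
        Minimum number of maternal beats required.
    """

    cycle_window_ms: float = 500.0
    n_components: int = 2
    min_cycles: int = 3

    def __post_init__(self) -> None:
        if self.cycle_window_ms <= 0:
            raise ConfigError("cycle_window_ms must be positive")
        if self.n_components < 1:
            raise ConfigError("n_components must be >= 1")


def extract_fecg(
    abdominal: np.ndarray,
    mqrs: np.ndarray,
    fs: float,
    config: TspcaConfig | None = None,
) -> np.ndarray:
    """Cancel the maternal component of one abdominal channel.

    Windows that would overlap (maternal rates above ~120 bpm) or run past
    the signal edges are truncated — at the midpoint between adjacent
    maternal beats and at the signal boundaries respectively.  The
    per-window mean is removed before the decomposition and not restored
    (the pipeline's bandpass has already removed the baseline).

    Raises :class:`ExtractionError` with fewer than ``min_cycles`` beats.
    """
    config = config or TspcaConfig()
    x = np.asarray(abdominal, dtype=float)
    mqrs = np.asarray(mqrs, dtype=np.int64)
    if mqrs.size < config.min_cycles:
        raise ExtractionError(
            f"need at least {config.min_cycles} maternal beats, got {mqrs.size}"
        )
    half = int(round(config.cycle_window_ms / 2000.0 * fs))
    win_len = 2 * half

    n = x.size
    # valid (possibly truncated) extent of each beat window
    mids_lo = np.concatenate(([0], (mqrs[:-1] + mqrs[1:]) // 2))
    mids_hi = np.concatenate(((mqrs[:-1] + mqrs[1:]) // 2, [n]))
    starts = np.maximum(mqrs - half, mids_lo)
    stops = np.minimum(mqrs + half, mids_hi)

    stack = np.zeros((mqrs.size, win_len))
    masks = np.zeros((mqrs.size, win_len), dtype=bool)
    for k, (b, lo, hi) in enumerate(zip(mqrs, starts, stops)):
        off_lo = lo - (b - half)
        off_hi = off_lo + (hi - lo)
        stack[k, off_lo:off_hi] = x[lo:hi]
        masks[k, off_lo:off_hi] = True

    row_means = stack.sum(axis=1, keepdims=True) / np.maximum(masks.sum(axis=1, keepdims=True), 1)
    centered = np.where(masks, stack - row_means, 0.0)

    k = min(config.n_components, min(centered.shape))
    u, s, vt = np.linalg.svd(centered, full_matrices=False)
    recon = (u[:, :k] * s[:k]) @ vt[:k]

    residual = x.copy()
    for kk, (lo, hi) in enumerate(zip(starts, stops)):
        off_lo = lo - (mqrs[kk] - half)
        off_hi = off_lo + (hi - lo)
        residual[lo:hi] = centered[kk, off_lo:off_hi] - recon[kk, off_lo:off_hi]
    return residual
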