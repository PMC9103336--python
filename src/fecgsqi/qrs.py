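"""QRS detection and beat-annotation matching.

Five detector families with deliberately different detection functions are
provided — ``maxsearch`` (rate-constrained local-maximum search seeded by
an autocorrelation RR estimate), ``jqrs`` (band-energy with adaptive
threshold and search-back), ``pan_tompkins`` (derivative → square →
moving-window integration with dual adaptive thresholds), ``gqrs``
(data-driven matched-filter correlation) and ``wqrs`` (curve-length
transform).  Behavioural diversity across the families is what the
detector-agreement quality features (bSQI) measure; the detectors are not
numerical replicas of their WFDB namesakes.

Each detector can target the maternal or the foetal rhythm; the target
sets the refractory period (200 ms maternal, 150 ms foetal) and the RR
prior used by rate-constrained stages (maternal 50–110 bpm, foetal
100–180 bpm).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from fecgsqi.errors import ConfigError

__all__ = [
    "DETECTOR_METHODS",
    "QrsAnnotation",
    "detect",
    "match_annotations",
]

DETECTOR_METHODS = ("maxsearch", "jqrs", "pan_tompkins", "gqrs", "wqrs")

_TARGETS = {
    # refractory_s, (bpm_min, bpm_max), qrs band (Hz)
    "maternal": (0.200, (50.0, 110.0), (5.0, 25.0)),
    "foetal": (0.150, (100.0, 180.0), (10.0, 45.0)),
}


@dataclass
class QrsAnnotation:
    """Sample indices of detected (or reference) R peaks."""

    detector: str
    indices: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        self.indices = np.asarray(self.indices, dtype=np.int64)
        if self.indices.size and np.any(np.diff(self.indices) <= 0):
            raise ConfigError("annotation indices must be strictly increasing")

    def __len__(self) -> int:
        return int(self.indices.size)


def _bandpass(x: np.ndarray, fs: float, lo: float, hi: float, order: int = 2) -> np.ndarray:
    sos = sps.butter(order, [lo, hi], btype="bandpass", fs=fs, output="sos")
    return sps.sosfiltfilt(sos, x)


def _moving_avg(x: np.ndarray, width: int) -> np.ndarray:
    width = max(1, width)
    kernel = np.ones(width) / width
    return np.convolve(x, kernel, mode="same")


def _estimate_rr(detection_fn: np.ndarray, fs: float, bpm_range: tuple[float, float]) -> float:
    """Dominant RR (samples) from the autocorrelation of a detection function."""
    lo = int(fs * 60.0 / bpm_range[1])
    hi = int(fs * 60.0 / bpm_range[0])
    d = detection_fn - detection_fn.mean()
    n = d.size
    if hi >= n:
        hi = n - 1
    if hi <= lo:
        return fs * 60.0 / np.mean(bpm_range)
    ac = sps.fftconvolve(d, d[::-1], mode="full")[n - 1 :]
    return float(lo + np.argmax(ac[lo : hi + 1]))


def _refine(x: np.ndarray, idx: np.ndarray, fs: float, radius_s: float = 0.04) -> np.ndarray:
    """Snap detections to the nearest local |x| maximum (R fiducial)."""
    if idx.size == 0:
        return idx
    r = int(round(radius_s * fs))
    ax = np.abs(x)
    out = np.empty_like(idx)
    for k, i in enumerate(idx):
        lo, hi = max(0, i - r), min(x.size, i + r + 1)
        out[k] = lo + int(np.argmax(ax[lo:hi]))
    return out


def _enforce_refractory(idx: np.ndarray, strength: np.ndarray, min_dist: int) -> np.ndarray:
    """Greedy strongest-first pruning so detections are >= min_dist apart."""
    if idx.size == 0:
        return idx
    order = np.argsort(strength[idx])[::-1]
    kept: list[int] = []
    for i in idx[order]:
        if all(abs(i - j) >= min_dist for j in kept):
            kept.append(int(i))
    return np.sort(np.asarray(kept, dtype=np.int64))


def _search_back(
    peaks: np.ndarray, det_fn: np.ndarray, threshold: float, refractory: int
) -> np.ndarray:
    """Recover missed beats in long gaps using a halved threshold."""
    if peaks.size < 3:
        return peaks
    rr_med = float(np.median(np.diff(peaks)))
    extra: list[int] = []
    gaps = np.diff(peaks)
    for g, (a, b) in zip(gaps, zip(peaks[:-1], peaks[1:])):
        if g > 1.66 * rr_med:
            lo, hi = a + refractory, b - refractory
            if hi > lo:
                cand = lo + int(np.argmax(det_fn[lo:hi]))
                if det_fn[cand] > 0.5 * threshold:
                    extra.append(cand)
    if extra:
        peaks = np.sort(np.concatenate([peaks, np.asarray(extra, dtype=np.int64)]))
    return peaks


def _maxsearch(x: np.ndarray, fs: float, target: str) -> np.ndarray:
    refractory_s, bpm_range, _ = _TARGETS[target]
    env = _moving_avg(x**2, int(0.05 * fs))
    rr = _estimate_rr(env, fs, bpm_range)
    dist = max(1, int(0.72 * rr))
    height = 0.2 * float(np.quantile(env, 0.99))
    peaks, _ = sps.find_peaks(env, distance=dist, height=height)
    return peaks


def _jqrs(x: np.ndarray, fs: float, target: str) -> np.ndarray:
    refractory_s, _, band = _TARGETS[target]
    energy = _moving_avg(_bandpass(x, fs, *band) ** 2, int(0.08 * fs))
    refractory = int(refractory_s * fs)
    peaks, props = sps.find_peaks(energy, distance=refractory)
    if peaks.size == 0:
        return peaks
    thr = 0.25 * float(np.median(np.sort(energy[peaks])[-max(3, peaks.size // 3) :]))
    strong = peaks[energy[peaks] >= thr]
    return _search_back(strong, energy, thr, refractory)


def _pan_tompkins(x: np.ndarray, fs: float, target: str) -> np.ndarray:
    refractory_s, _, band = _TARGETS[target]
    filtered = _bandpass(x, fs, *band)
    deriv = np.gradient(filtered)
    mwi_width = int((0.150 if target == "maternal" else 0.075) * fs)
    mwi = _moving_avg(deriv**2, mwi_width)
    refractory = int(refractory_s * fs)
    candidates, _ = sps.find_peaks(mwi, distance=refractory)
    if candidates.size == 0:
        return candidates
    # dual adaptive thresholds (signal / noise peak running estimates)
    spki = float(np.quantile(mwi[candidates], 0.75))
    npki = float(np.quantile(mwi[candidates], 0.25))
    beats: list[int] = []
    for c in candidates:
        thr = npki + 0.25 * (spki - npki)
        if mwi[c] >= thr:
            beats.append(int(c))
            spki = 0.125 * mwi[c] + 0.875 * spki
        else:
            npki = 0.125 * mwi[c] + 0.875 * npki
    peaks = np.asarray(beats, dtype=np.int64)
    thr = npki + 0.25 * (spki - npki)
    return _search_back(peaks, mwi, thr, refractory)


def _gqrs(x: np.ndarray, fs: float, target: str) -> np.ndarray:
    refractory_s, _, band = _TARGETS[target]
    refractory = int(refractory_s * fs)
    rough = _bandpass(x, fs, *band)
    seeds, _ = sps.find_peaks(np.abs(rough), distance=refractory)
    if seeds.size == 0:
        return seeds
    # template from the strongest seed beats
    top = seeds[np.argsort(np.abs(rough[seeds]))[::-1][: max(3, seeds.size // 3)]]
    half = int(0.05 * fs)
    wins = [x[s - half : s + half] for s in top if s - half >= 0 and s + half <= x.size]
    if not wins:
        return np.empty(0, dtype=np.int64)
    template = np.mean(wins, axis=0)
    template = template - template.mean()
    tnorm = float(np.linalg.norm(template))
    if tnorm == 0:
        return np.empty(0, dtype=np.int64)
    corr = sps.fftconvolve(x, template[::-1] / tnorm, mode="same")
    peaks, _ = sps.find_peaks(np.abs(corr), distance=refractory)
    if peaks.size == 0:
        return peaks
    thr = 0.35 * float(np.quantile(np.abs(corr[peaks]), 0.98))
    return peaks[np.abs(corr[peaks]) >= thr]


def _wqrs(x: np.ndarray, fs: float, target: str) -> np.ndarray:
    refractory_s, _, band = _TARGETS[target]
    refractory = int(refractory_s * fs)
    filtered = _bandpass(x, fs, band[0], band[1])
    dy = np.diff(filtered, prepend=filtered[0])
    c = float(np.mean(dy**2)) + 1e-24
    length = np.sqrt(c + dy**2)
    w = int(0.13 * fs)
    clt = np.convolve(length, np.ones(w), mode="same")
    clt = clt - _moving_avg(clt, int(1.0 * fs))  # remove slow trend
    peaks, _ = sps.find_peaks(clt, distance=refractory)
    # the trend estimate is unreliable within a window of the signal edges
    peaks = peaks[(peaks >= w) & (peaks < clt.size - w)]
    if peaks.size == 0:
        return peaks
    thr = 0.3 * float(np.quantile(clt[peaks], 0.98))
    return peaks[clt[peaks] >= thr]


_DETECTORS = {
    "maxsearch": _maxsearch,
    "jqrs": _jqrs,
    "pan_tompkins": _pan_tompkins,
    "gqrs": _gqrs,
    "wqrs": _wqrs,
}


def detect(
    signal: np.ndarray,
    fs: float,
    method: str = "pan_tompkins",
    target: str = "maternal",
) -> QrsAnnotation:
    """Run one QRS detector on a single-channel signal.

    Detections are snapped to the nearest local ``|signal|`` maximum and
    pruned to respect the target's refractory period.  A flat signal
    yields an empty annotation.
    """
    if method not in _DETECTORS:
        raise ConfigError(f"unknown detector {method!r}; choose from {DETECTOR_METHODS}")
    if target not in _TARGETS:
        raise ConfigError("target must be 'maternal' or 'foetal'")
    x = np.asarray(signal, dtype=float)
    if x.size < fs:
        raise ConfigError("detection requires at least 1 s of signal")
    if np.ptp(x) == 0:
        return QrsAnnotation(detector=method, indices=np.empty(0, dtype=np.int64), fs=fs)
    raw = np.asarray(_DETECTORS[method](x, fs, target), dtype=np.int64)
    refined = np.unique(_refine(x, raw, fs))
    refractory = int(_TARGETS[target][0] * fs)
    final = _enforce_refractory(refined, np.abs(x), refractory)
    return QrsAnnotation(detector=method, indices=final, fs=fs)


def match_annotations(
    test: QrsAnnotation,
    reference: QrsAnnotation,
    tol_ms: float = 50.0,
) -> tuple[int, int, int]:
    """Greedy one-to-one nearest matching within a tolerance window.

    Candidate pairs are taken in order of increasing time difference (ties
    toward the earlier reference beat); each test and reference beat is
    used at most once.  Returns ``(TP, FP, FN)`` with ``TP + FP = |test|``
    and ``TP + FN = |reference|``.
    """
    if test.fs != reference.fs:
        raise ConfigError("annotations must share a sampling rate")
    tol = tol_ms / 1000.0 * test.fs
    t, r = test.indices, reference.indices
    pairs = [
        (abs(int(ti) - int(rj)), j, i)
        for i, ti in enumerate(t)
        for j, rj in enumerate(r)
        if abs(int(ti) - int(rj)) <= tol
    ]
    pairs.sort()
    used_t: set[int] = set()
    used_r: set[int] = set()
    tp = 0
    for _, j, i in pairs:
        if i not in used_t and j not in used_r:
            used_t.add(i)
            used_r.add(j)
            tp += 1
    return tp, len(t) - tp, len(r) - tp
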