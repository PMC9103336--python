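"""Classical foetal signal-quality indices and the 45-feature vector.

The feature families:

- time-domain moments of the extracted foetal signal (stdSQI, sSQI =
  skewness, kSQI = non-excess kurtosis);
- band-power ratios (pSQI over the QRS band, basSQI for baseline power);
- detection-based agreement and regularity features computed from QRS
  annotations (bSQI detector-pair F1, iSQI inter-lead agreement, rSQI
  heart-rate regularity, cSQI beat-morphology conformity, xSQI beat
  "extravagance");
- maternal-residual features on the extracted signal (mxSQI, mpSQI
  maternal-harmonic power, mcSQI spectral coherence, miSQI maternal
  residual detections).

Apart from the three time-domain moments every feature lies in [0, 1];
degenerate inputs map to a sentinel value of 0 so downstream classifiers
need no missing-value handling.

The assembled benchmark vector has exactly 45 entries: 10 features
computed once per segment, F1 agreement for each of the 10 unordered
pairs of the five QRS detectors, and {iSQI, rSQI, cSQI, xSQI, miSQI} for
each of the five detectors.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from fecgsqi.errors import ConfigError
from fecgsqi.extract import TspcaConfig, extract_fecg
from fecgsqi.preprocess import Segment
from fecgsqi.qrs import DETECTOR_METHODS, QrsAnnotation, detect, match_annotations

__all__ = [
    "FEATURE_NAMES",
    "LAYOUT_VERSION",
    "FeatureVector",
    "std_sqi",
    "s_sqi",
    "k_sqi",
    "p_sqi",
    "bas_sqi",
    "b_sqi",
    "i_sqi",
    "r_sqi",
    "c_sqi",
    "x_sqi",
    "mx_sqi",
    "mp_sqi",
    "mc_sqi",
    "mi_sqi",
    "feature_vector",
]

LAYOUT_VERSION = "fecgsqi-45-v1"

_SINGLE = ("stdSQI", "sSQI", "kSQI", "pSQI", "basSQI", "mxSQI", "mpSQIa", "mpSQIb", "mcSQIa", "mcSQIb")
_PAIRS = tuple(itertools.combinations(DETECTOR_METHODS, 2))
_PER_DETECTOR = ("iSQI", "rSQI", "cSQI", "xSQI", "miSQI")

#: Stable 45-name layout of the benchmark feature vector.
FEATURE_NAMES: tuple[str, ...] = (
    _SINGLE
    + tuple(f"bSQI_{a}_{b}" for a, b in _PAIRS)
    + tuple(f"{s}_{d}" for d in DETECTOR_METHODS for s in _PER_DETECTOR)
)
assert len(FEATURE_NAMES) == 45


@dataclass
class FeatureVector:
    """The 45 named classical SQI values for one segment."""

    values: np.ndarray
    segment_id: str = ""
    layout_version: str = LAYOUT_VERSION
    quality_mask: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (45,):
            raise ConfigError("a FeatureVector has exactly 45 values")

    def as_dict(self) -> dict[str, float]:
        return dict(zip(FEATURE_NAMES, self.values))

    def __getitem__(self, name: str) -> float:
        return float(self.values[FEATURE_NAMES.index(name)])


# ---------------------------------------------------------------- moments


def std_sqi(x: np.ndarray) -> float:
    """Population standard deviation of the signal."""
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        raise ConfigError("need at least 2 samples")
    return float(np.sqrt(np.mean((x - x.mean()) ** 2)))


def s_sqi(x: np.ndarray) -> float:
    """Third standardized moment (skewness); 0 for constant input."""
    x = np.asarray(x, dtype=float)
    std = std_sqi(x)
    if std == 0:
        return 0.0
    return float(np.mean((x - x.mean()) ** 3) / std**3)


def k_sqi(x: np.ndarray) -> float:
    """Fourth standardized moment (kurtosis, non-excess); 0 for constant."""
    x = np.asarray(x, dtype=float)
    std = std_sqi(x)
    if std == 0:
        return 0.0
    return float(np.mean((x - x.mean()) ** 4) / std**4)


# ----------------------------------------------------------- band powers


def _band_power(freqs: np.ndarray, psd: np.ndarray, lo: float, hi: float) -> float:
    sel = (freqs >= lo) & (freqs <= hi)
    return float(np.trapezoid(psd[sel], freqs[sel])) if sel.sum() > 1 else float(psd[sel].sum())


def p_sqi(x: np.ndarray, fs: float) -> float:
    """One minus the fraction of 5–45 Hz power lying in 5–15 Hz.

    High values mean the spectral energy sits in the upper part of the
    QRS band.  Zero power in 5–45 Hz yields the sentinel 0.
    """
    if fs <= 90:
        raise ConfigError("p_sqi requires fs > 90 Hz")
    freqs, psd = sps.periodogram(np.asarray(x, dtype=float), fs=fs)
    den = _band_power(freqs, psd, 5.0, 45.0)
    total = _band_power(freqs, psd, 0.0, fs / 2)
    # leakage-level band power counts as empty, not as a valid ratio
    if den <= 1e-12 * max(total, 1e-300):
        return 0.0
    return float(np.clip(1.0 - _band_power(freqs, psd, 5.0, 15.0) / den, 0.0, 1.0))


def bas_sqi(x: np.ndarray, fs: float) -> float:
    """Fraction of 0–100 Hz power below 3 Hz (baseline / contraction band)."""
    if fs <= 200:
        raise ConfigError("bas_sqi requires fs > 200 Hz")
    freqs, psd = sps.periodogram(np.asarray(x, dtype=float), fs=fs)
    den = _band_power(freqs, psd, 0.0, 100.0)
    if den <= 0:
        return 0.0
    return float(np.clip(_band_power(freqs, psd, 0.0, 3.0) / den, 0.0, 1.0))


# ------------------------------------------------------- detection-based


def b_sqi(a: QrsAnnotation, b: QrsAnnotation, tol_ms: float = 50.0) -> float:
    """F1 agreement between two detectors' annotations."""
    tp, fp, fn = match_annotations(a, b, tol_ms)
    if 2 * tp + fp + fn == 0:
        return 0.0
    return 2.0 * tp / (2 * tp + fp + fn)


def i_sqi(
    lead_annotations: list[QrsAnnotation],
    current: int,
    tol_ms: float = 50.0,
) -> float:
    """Fraction of current-lead beats found on every other lead."""
    cur = lead_annotations[current]
    if len(cur) == 0:
        return 0.0
    tol = tol_ms / 1000.0 * cur.fs
    found = np.ones(len(cur), dtype=bool)
    for j, other in enumerate(lead_annotations):
        if j == current:
            continue
        if len(other) == 0:
            return 0.0
        dist = np.min(np.abs(cur.indices[:, None] - other.indices[None, :]), axis=1)
        found &= dist <= tol
    return float(found.mean())


def r_sqi(fqrs: QrsAnnotation, outlier_bpm: float = 30.0) -> float:
    """Heart-rate regularity: 1 − (fraction of beat-to-beat HR outliers).

    An outlier is an instantaneous HR more than ``outlier_bpm`` away from
    the median instantaneous HR.  Fewer than 3 detections → sentinel 0.
    """
    if len(fqrs) < 3:
        return 0.0
    rr_s = np.diff(fqrs.indices) / fqrs.fs
    hr = 60.0 / rr_s
    n_out = int(np.sum(np.abs(hr - np.median(hr)) > outlier_bpm))
    return 1.0 - n_out / hr.size


def _beat_windows(x: np.ndarray, ann: QrsAnnotation, window_ms: float) -> np.ndarray:
    half = int(round(window_ms / 2000.0 * ann.fs))
    wins = [
        x[i - half : i + half]
        for i in ann.indices
        if i - half >= 0 and i + half <= x.size
    ]
    return np.asarray(wins) if wins else np.empty((0, 2 * half))


def c_sqi(fecg: np.ndarray, fqrs: QrsAnnotation, window_ms: float = 100.0) -> float:
    """Beat-morphology conformity: mean correlation with the mean beat.

    Each full beat window is correlated with the average beat template;
    negative correlations are clipped to zero before averaging.
    """
    wins = _beat_windows(np.asarray(fecg, dtype=float), fqrs, window_ms)
    if wins.shape[0] < 2:
        return 0.0
    template = wins.mean(axis=0)
    t = template - template.mean()
    tn = np.linalg.norm(t)
    if tn == 0:
        return 0.0
    corrs = []
    for w in wins:
        wc = w - w.mean()
        wn = np.linalg.norm(wc)
        corrs.append(0.0 if wn == 0 else max(0.0, float(wc @ t / (wn * tn))))
    return float(np.mean(corrs))


def _in_window_mask(n: int, ann: QrsAnnotation, window_ms: float) -> np.ndarray:
    half = int(round(window_ms / 2000.0 * ann.fs))
    mask = np.zeros(n, dtype=bool)
    for i in ann.indices:
        mask[max(0, i - half) : min(n, i + half)] = True
    return mask


def x_sqi(fecg: np.ndarray, fqrs: QrsAnnotation, window_ms: float = 100.0) -> float:
    """Beat extravagance: in-window energy density over total density.

    ``E_in / (E_in + E_out)`` where ``E_in`` is the mean squared amplitude
    inside the ±50 ms beat windows and ``E_out`` outside.  1 means all
    energy is concentrated at the annotated beats.
    """
    x = np.asarray(fecg, dtype=float)
    if len(fqrs) == 0 or not np.any(x):
        return 0.0
    mask = _in_window_mask(x.size, fqrs, window_ms)
    if mask.all() or not mask.any():
        return 0.0
    e_in = float(np.mean(x[mask] ** 2))
    e_out = float(np.mean(x[~mask] ** 2))
    if e_in + e_out == 0:
        return 0.0
    return e_in / (e_in + e_out)


def mx_sqi(fecg: np.ndarray, mqrs: QrsAnnotation, window_ms: float = 100.0) -> float:
    """Maternal-cancellation quality: 1 − xSQI over the maternal windows.

    High values mean little residual energy remains around the maternal R
    positions in the extracted signal.  Sentinel 0 when undefined.
    """
    x = np.asarray(fecg, dtype=float)
    if len(mqrs) == 0 or not np.any(x):
        return 0.0
    mask = _in_window_mask(x.size, mqrs, window_ms)
    if mask.all() or not mask.any():
        return 0.0
    return 1.0 - x_sqi(x, mqrs, window_ms)


def mp_sqi(
    fecg: np.ndarray,
    mqrs: QrsAnnotation,
    fs: float,
    variant: str = "a",
) -> float:
    """Relative spectral power at maternal heart-rate harmonics.

    The fundamental is the mean maternal beat rate; power is summed in
    ±0.2 Hz bands around its first five harmonics (variant ``a``) or all
    harmonics within [0.5, 10] Hz (variant ``b``) and divided by the
    total [0.5, 100] Hz power.
    """
    if variant not in ("a", "b"):
        raise ConfigError("variant must be 'a' or 'b'")
    if len(mqrs) < 2:
        return 0.0
    x = np.asarray(fecg, dtype=float)
    span_s = (mqrs.indices[-1] - mqrs.indices[0]) / fs
    if span_s <= 0:
        return 0.0
    f0 = (len(mqrs) - 1) / span_s
    freqs, psd = sps.periodogram(x, fs=fs)
    den = _band_power(freqs, psd, 0.5, 100.0)
    if den <= 0:
        return 0.0
    if variant == "a":
        harmonics = [f0 * k for k in range(1, 6)]
    else:
        harmonics = [f0 * k for k in range(1, int(10.0 / f0) + 1) if 0.5 <= f0 * k <= 10.0]
    num = sum(_band_power(freqs, psd, h - 0.2, h + 0.2) for h in harmonics)
    return float(np.clip(num / den, 0.0, 1.0))


def mc_sqi(x: np.ndarray, y: np.ndarray, fs: float) -> float:
    """Mean magnitude-squared coherence over 3–100 Hz (Welch averaging)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ConfigError("coherence inputs must have equal length")
    nperseg = max(8, x.size // 4)
    freqs, coh = sps.coherence(x, y, fs=fs, nperseg=nperseg)
    sel = (freqs >= 3.0) & (freqs <= 100.0)
    if not sel.any():
        return 0.0
    return float(np.clip(np.mean(coh[sel]), 0.0, 1.0))


def mi_sqi(fqrs: QrsAnnotation, mqrs: QrsAnnotation, tol_ms: float = 50.0) -> float:
    """1 − fraction of foetal detections coinciding with maternal beats.

    Exposes falsely detected maternal residuals: near 0 when the foetal
    detector is really tracking the maternal rhythm.
    """
    if len(fqrs) == 0:
        return 0.0
    if len(mqrs) == 0:
        return 1.0
    tol = tol_ms / 1000.0 * fqrs.fs
    dist = np.min(np.abs(fqrs.indices[:, None] - mqrs.indices[None, :]), axis=1)
    return 1.0 - float(np.mean(dist <= tol))


# ------------------------------------------------------- vector assembly

_ABD = (1, 2, 3)  # abdominal channel rows within a Segment


def feature_vector(
    segment: Segment,
    mqrs: QrsAnnotation | None = None,
    tspca: TspcaConfig | None = None,
) -> FeatureVector:
    """Assemble the 45-feature benchmark vector for one segment.

    The maternal annotation comes from the chest channel (Pan–Tompkins)
    when not supplied.  TSpca extraction runs once per abdominal channel;
    the single-segment features and the foetal detections are taken from
    the "best" abdominal channel — the one with the highest xSQI under
    the Pan–Tompkins foetal detector.  If the maternal annotation has too
    few beats for extraction, all detection-dependent features fall back
    to the sentinel 0 and the quality mask records the failure.
    """
    tspca = tspca or TspcaConfig()
    fs = segment.fs
    chest = segment.channel("M")
    if mqrs is None:
        mqrs = detect(chest, fs, method="pan_tompkins", target="maternal")

    values = np.zeros(45)
    mask: dict = {"extraction_ok": True}
    out = {name: 0.0 for name in FEATURE_NAMES}

    try:
        residuals = [extract_fecg(segment.channels[c], mqrs.indices, fs, tspca) for c in _ABD]
    except Exception as exc:  # extraction failure -> sentinel features
        mask["extraction_ok"] = False
        mask["reason"] = str(exc)
        vec = FeatureVector(values=values, segment_id=_segment_id(segment), quality_mask=mask)
        return vec

    # best channel by xSQI under the Pan-Tompkins foetal detector
    pt_anns = [detect(r, fs, method="pan_tompkins", target="foetal") for r in residuals]
    x_scores = [x_sqi(r, a) for r, a in zip(residuals, pt_anns)]
    best = int(np.argmax(x_scores))
    fecg = residuals[best]
    abd_raw = segment.channels[_ABD[best]]
    mask["best_channel"] = ("A1", "A2", "A3")[best]

    out["stdSQI"] = std_sqi(fecg)
    out["sSQI"] = s_sqi(fecg)
    out["kSQI"] = k_sqi(fecg)
    out["pSQI"] = p_sqi(fecg, fs)
    out["basSQI"] = bas_sqi(fecg, fs)
    out["mxSQI"] = mx_sqi(fecg, mqrs)
    out["mpSQIa"] = mp_sqi(fecg, mqrs, fs, "a")
    out["mpSQIb"] = mp_sqi(fecg, mqrs, fs, "b")
    out["mcSQIa"] = mc_sqi(chest, fecg, fs)
    out["mcSQIb"] = mc_sqi(abd_raw, fecg, fs)

    # five foetal detectors on the best channel plus the other leads for iSQI
    anns = {m: detect(fecg, fs, method=m, target="foetal") for m in DETECTOR_METHODS}
    per_lead = {
        m: [
            anns[m] if c == best else detect(residuals[c], fs, method=m, target="foetal")
            for c in range(3)
        ]
        for m in DETECTOR_METHODS
    }

    for a, b in _PAIRS:
        out[f"bSQI_{a}_{b}"] = b_sqi(anns[a], anns[b])
    for m in DETECTOR_METHODS:
        out[f"iSQI_{m}"] = i_sqi(per_lead[m], best)
        out[f"rSQI_{m}"] = r_sqi(anns[m])
        out[f"cSQI_{m}"] = c_sqi(fecg, anns[m])
        out[f"xSQI_{m}"] = x_sqi(fecg, anns[m])
        out[f"miSQI_{m}"] = mi_sqi(anns[m], mqrs)

    values = np.array([out[name] for name in FEATURE_NAMES])
    return FeatureVector(values=values, segment_id=_segment_id(segment), quality_mask=mask)


def _segment_id(segment: Segment) -> str:
    return f"{segment.recording_id}@{segment.start_sample}"
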