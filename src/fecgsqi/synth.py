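"""Synthetic four-channel NI-FECG generator.

Produces labelled recordings with one maternal chest channel (M) and three
abdominal channels (A1–A3) at 1 kHz.  The abdominal channels are a mixture
of a maternal ECG render, a lower-amplitude foetal ECG render, baseline
wander, powerline interference and broadband sensor noise.  The foetal
gains are rescaled so that the foetal signal-to-noise ratio on the best
abdominal channel hits a configurable target, and the good/bad quality
label is a pure threshold function of that target SNR — mirroring the
clinical labelling rule where a recording is "good" when the foetal heart
rate can be read off at least one abdominal lead.

Beat morphology is the classic sum-of-Gaussian-lobes model (five lobes for
the P, Q, R, S and T waves on a beat-phase axis), with the foetal template
a narrowed, independently scaled version of the maternal one.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from fecgsqi.errors import ConfigError

__all__ = [
    "EcgTemplate",
    "SynthConfig",
    "Recording",
    "CHANNEL_NAMES",
    "MATERNAL_TEMPLATE",
    "FOETAL_TEMPLATE",
    "generate_beat_train",
    "render_ecg",
    "generate_recording",
    "snr_db",
    "generate_dataset",
]

CHANNEL_NAMES = ("M", "A1", "A2", "A3")

#: Default label threshold: recordings at or above this target foetal SNR
#: are labelled good.
LABEL_THRESHOLD_DB = 3.0


@dataclass(frozen=True)
class EcgTemplate:
    """Sum-of-Gaussian-lobes beat morphology.

    Parameters
    ----------
    wave_params:
        Five ``(amplitude, center, width)`` triples for the P, Q, R, S and
        T lobes.  Centers and widths are in beat-phase radians: one beat
        spans ``2*pi`` with the R peak at phase 0.
    qrs_width_scale:
        Multiplier applied to the widths of the Q, R and S lobes; < 1
        narrows the QRS complex (used for the foetal template).
    """

    wave_params: tuple[tuple[float, float, float], ...]
    qrs_width_scale: float = 1.0

    def __post_init__(self) -> None:
        if len(self.wave_params) != 5:
            raise ConfigError("an ECG template needs exactly 5 lobes (P,Q,R,S,T)")
        amps = [abs(a) for a, _, _ in self.wave_params]
        if max(amps[:2] + amps[3:]) >= amps[2]:
            raise ConfigError("R lobe must have strictly the largest |amplitude|")
        if any(w <= 0 for _, _, w in self.wave_params):
            raise ConfigError("lobe widths must be strictly positive")

    def effective_params(self) -> np.ndarray:
        """(5, 3) array with the QRS width scaling applied to Q, R, S."""
        p = np.asarray(self.wave_params, dtype=float)
        p[1:4, 2] *= self.qrs_width_scale
        return p


# Lobe layout modelled on the standard dynamical ECG simulator, amplitudes
# rescaled so the rendered R peak is ~1 signal-unit.
MATERNAL_TEMPLATE = EcgTemplate(
    wave_params=(
        (0.04, -np.pi / 3, 0.25),   # P
        (-0.17, -np.pi / 12, 0.1),  # Q
        (1.0, 0.0, 0.1),            # R
        (-0.25, np.pi / 12, 0.1),   # S
        (0.13, np.pi / 2, 0.4),     # T
    ),
)

#: Foetal morphology: same lobe layout with a narrowed QRS.
FOETAL_TEMPLATE = replace(MATERNAL_TEMPLATE, qrs_width_scale=0.5)


@dataclass(frozen=True)
class SynthConfig:
    """Configuration for one synthetic recording.

    Amplitudes are in the arbitrary signal units of the rendered maternal
    R peak (~1.0 before channel gains).
    """

    fs: float = 1000.0
    duration_s: float = 60.0
    mhr_bpm: float = 80.0
    fhr_bpm: float = 135.0
    rr_jitter_frac: float = 0.03
    maternal_gain_per_channel: tuple[float, float, float] = (0.5, 0.4, 0.6)
    foetal_gain_per_channel: tuple[float, float, float] = (0.15, 0.25, 0.2)
    baseline_amp: float = 0.1
    baseline_freq: float = 0.3
    powerline_amp: float = 0.05
    powerline_freq: float = 50.0
    noise_sigma: float = 0.02
    target_foetal_snr_db: float = 6.0
    label_threshold_db: float = LABEL_THRESHOLD_DB
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fs <= 0 or self.duration_s <= 0:
            raise ConfigError("fs and duration_s must be positive")
        if not 50.0 <= self.mhr_bpm <= 110.0:
            raise ConfigError("mhr_bpm outside the supported range [50, 110]")
        if not 100.0 <= self.fhr_bpm <= 180.0:
            raise ConfigError("fhr_bpm outside the supported range [100, 180]")
        if self.rr_jitter_frac < 0:
            raise ConfigError("rr_jitter_frac must be >= 0")
        # highest deliberate frequency content is the powerline tone
        if self.fs <= 2 * self.powerline_freq:
            raise ConfigError("fs must exceed twice the powerline frequency")


@dataclass
class Recording:
    """Four synchronized channels with beat annotations and a label.

    ``channels`` has shape ``(4, n)`` ordered as ``CHANNEL_NAMES``
    (M, A1, A2, A3).
    """

    channels: np.ndarray
    fs: float
    mqrs: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))
    fqrs: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))
    label: str = "unknown"
    id: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.channels = np.atleast_2d(np.asarray(self.channels, dtype=float))
        if self.channels.shape[0] != 4:
            raise ConfigError("a Recording has exactly 4 channels (M, A1, A2, A3)")
        n = self.channels.shape[1]
        for name, ann in (("mqrs", self.mqrs), ("fqrs", self.fqrs)):
            ann = np.asarray(ann, dtype=np.int64)
            if ann.size and (np.any(np.diff(ann) <= 0) or ann[0] < 0 or ann[-1] >= n):
                raise ConfigError(f"{name} must be strictly increasing within [0, {n})")
            setattr(self, name, ann)
        if self.label not in ("good", "bad", "unknown"):
            raise ConfigError("label must be good, bad or unknown")

    @property
    def n_samples(self) -> int:
        return self.channels.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def channel(self, name: str) -> np.ndarray:
        return self.channels[CHANNEL_NAMES.index(name)]


def _rng_streams(seed: int, names: Sequence[str]) -> dict[str, np.random.Generator]:
    """Named, independent RNG streams derived from one integer seed."""
    children = np.random.SeedSequence(seed).spawn(len(names))
    return {name: np.random.default_rng(ss) for name, ss in zip(names, children)}


def generate_beat_train(
    rate_bpm: float,
    duration_s: float,
    rr_jitter_frac: float = 0.0,
    fs: float = 1000.0,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Strictly increasing R-peak sample indices at a jittered rate.

    Inter-beat intervals are the nominal ``60/rate_bpm`` seconds perturbed
    multiplicatively by Gaussian jitter with standard deviation
    ``rr_jitter_frac``, truncated at three standard deviations.  The first
    beat lands at a random phase within the first nominal interval.
    """
    if rate_bpm <= 0 or duration_s <= 0:
        raise ConfigError("rate_bpm and duration_s must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    rr_nominal = 60.0 / rate_bpm
    n_max = int(np.ceil(duration_s / rr_nominal)) + 2
    jitter = np.clip(rng.standard_normal(n_max) * rr_jitter_frac, -3 * rr_jitter_frac, 3 * rr_jitter_frac)
    intervals = rr_nominal * (1.0 + jitter)
    t0 = rr_nominal * rng.uniform(0.05, 0.95)
    times = t0 + np.concatenate(([0.0], np.cumsum(intervals)))
    times = times[times < duration_s]
    beats = np.unique(np.round(times * fs).astype(np.int64))
    return beats[beats < int(round(duration_s * fs))]


def render_ecg(
    template: EcgTemplate,
    beats: np.ndarray,
    fs: float,
    n_samples: int,
) -> np.ndarray:
    """Render a beat train into a sample series of length ``n_samples``.

    Each beat contributes five Gaussian lobes; the beat-phase axis spans
    ``2*pi`` over the local inter-beat interval (median interval for a
    single beat, 1 s fallback).
    """
    beats = np.asarray(beats, dtype=np.int64)
    if beats.size and (beats.min() < 0 or beats.max() >= n_samples):
        raise ConfigError("beat index outside [0, n_samples)")
    out = np.zeros(n_samples)
    if beats.size == 0:
        return out
    if beats.size > 1:
        period = float(np.median(np.diff(beats))) / fs
    else:
        period = 1.0
    params = template.effective_params()
    t = np.arange(n_samples) / fs
    # Render each beat over a local window of +-0.6 period (lobes decay fast).
    half = int(round(0.6 * period * fs))
    for b in beats:
        lo, hi = max(0, b - half), min(n_samples, b + half + 1)
        phase = (t[lo:hi] - b / fs) * (2 * np.pi / period)
        seg = np.zeros(hi - lo)
        for amp, center, width in params:
            seg += amp * np.exp(-0.5 * ((phase - center) / width) ** 2)
        out[lo:hi] += seg
    return out


def snr_db(signal_component: np.ndarray, noise_component: np.ndarray) -> float:
    """Power SNR in decibels: ``10 log10(P_signal / P_noise)``."""
    signal_component = np.asarray(signal_component, dtype=float)
    noise_component = np.asarray(noise_component, dtype=float)
    if signal_component.shape != noise_component.shape:
        raise ConfigError("signal and noise must have equal length")
    p_noise = float(np.mean(noise_component**2))
    if p_noise <= 0:
        raise ConfigError("noise power must be strictly positive")
    p_signal = float(np.mean(signal_component**2))
    return 10.0 * np.log10(p_signal / p_noise)


def generate_recording(config: SynthConfig) -> Recording:
    """Generate one labelled four-channel recording.

    The chest channel M carries the maternal render plus a small sensor
    noise floor and no foetal content.  Each abdominal channel Ai is
    ``maternal_gain_i * mecg + foetal_gain_i * fecg + baseline + powerline
    + broadband noise``; the foetal gains are rescaled by a common factor
    so the achieved foetal SNR (foetal render power against the summed
    non-maternal noise) on the *best* abdominal channel equals
    ``target_foetal_snr_db`` exactly.  The label is good iff the target
    SNR meets ``label_threshold_db``.
    """
    fs = config.fs
    n = int(round(config.duration_s * fs))
    rngs = _rng_streams(config.seed, ["mbeats", "fbeats", "noise", "phase"])

    mqrs = generate_beat_train(config.mhr_bpm, config.duration_s, config.rr_jitter_frac, fs, rngs["mbeats"])
    fqrs = generate_beat_train(config.fhr_bpm, config.duration_s, config.rr_jitter_frac, fs, rngs["fbeats"])
    mecg = render_ecg(MATERNAL_TEMPLATE, mqrs, fs, n)
    fecg = render_ecg(FOETAL_TEMPLATE, fqrs, fs, n)

    t = np.arange(n) / fs
    noise_rng = rngs["noise"]
    phase_rng = rngs["phase"]
    m_gain = np.asarray(config.maternal_gain_per_channel, dtype=float)
    f_gain = np.asarray(config.foetal_gain_per_channel, dtype=float)

    noise = np.zeros((3, n))
    for i in range(3):
        if config.baseline_amp > 0:
            noise[i] += config.baseline_amp * np.sin(
                2 * np.pi * config.baseline_freq * t + phase_rng.uniform(0, 2 * np.pi)
            )
        if config.powerline_amp > 0:
            noise[i] += config.powerline_amp * np.sin(
                2 * np.pi * config.powerline_freq * t + phase_rng.uniform(0, 2 * np.pi)
            )
        if config.noise_sigma > 0:
            noise[i] += config.noise_sigma * noise_rng.standard_normal(n)

    # Rescale foetal gains so the best abdominal channel hits the target SNR.
    p_fecg = float(np.mean(fecg**2))
    p_noise = np.mean(noise**2, axis=1)
    achieved = np.full(3, -np.inf)
    ok = (p_noise > 0) & (f_gain**2 * p_fecg > 0)
    achieved[ok] = 10 * np.log10(f_gain[ok] ** 2 * p_fecg / p_noise[ok])
    if np.any(ok):
        best = int(np.argmax(achieved))
        scale = 10 ** ((config.target_foetal_snr_db - achieved[best]) / 20.0)
        f_gain = f_gain * scale

    abdominal = m_gain[:, None] * mecg + f_gain[:, None] * fecg + noise
    chest = mecg + 0.005 * noise_rng.standard_normal(n)
    channels = np.vstack([chest, abdominal])

    label = "good" if config.target_foetal_snr_db >= config.label_threshold_db else "bad"
    meta = {
        "target_foetal_snr_db": config.target_foetal_snr_db,
        "mhr_bpm": config.mhr_bpm,
        "fhr_bpm": config.fhr_bpm,
        "seed": config.seed,
        "foetal_gain_effective": tuple(f_gain),
    }
    return Recording(channels=channels, fs=fs, mqrs=mqrs, fqrs=fqrs, label=label, meta=meta)


def generate_dataset(
    n_good: int,
    n_bad: int,
    base_config: SynthConfig | None = None,
    snr_ranges: tuple[tuple[float, float], tuple[float, float]] = ((6.0, 18.0), (-12.0, 0.0)),
    seed: int = 0,
) -> list[Recording]:
    """Generate a labelled corpus of good and bad recordings.

    Per recording, the target foetal SNR is drawn uniformly within its
    class interval, the foetal heart rate uniformly in [110, 160] bpm and
    the maternal heart rate in [65, 95] bpm.  The two class intervals must
    be disjoint so no recording is borderline.
    """
    base_config = base_config or SynthConfig()
    (good_lo, good_hi), (bad_lo, bad_hi) = snr_ranges
    if good_lo > good_hi or bad_lo > bad_hi:
        raise ConfigError("SNR intervals must be non-empty")
    if not (bad_hi < good_lo or good_hi < bad_lo):
        raise ConfigError("good and bad SNR intervals must be disjoint")
    if bad_hi >= base_config.label_threshold_db or good_lo < base_config.label_threshold_db:
        raise ConfigError("SNR intervals must sit on opposite sides of the label threshold")

    ss = np.random.SeedSequence(seed)
    draw = np.random.default_rng(ss.spawn(1)[0])
    rec_seeds = np.random.default_rng(ss.spawn(2)[1]).integers(0, 2**31 - 1, size=n_good + n_bad)
    recordings: list[Recording] = []
    specs = [("good", good_lo, good_hi)] * n_good + [("bad", bad_lo, bad_hi)] * n_bad
    for i, (cls, lo, hi) in enumerate(specs):
        cfg = replace(
            base_config,
            target_foetal_snr_db=float(draw.uniform(lo, hi)),
            fhr_bpm=float(draw.uniform(110.0, 160.0)),
            mhr_bpm=float(draw.uniform(65.0, 95.0)),
            seed=int(rec_seeds[i]),
        )
        rec = generate_recording(cfg)
        rec.id = f"rec{i:04d}_{cls}"
        assert rec.label == cls
        recordings.append(rec)
    return recordings
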