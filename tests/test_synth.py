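"""The synthetic generator: beat trains, renders, SNR calibration, labels."""

import numpy as np
import pytest

from fecgsqi.errors import ConfigError
from fecgsqi.synth import (
    FOETAL_TEMPLATE,
    MATERNAL_TEMPLATE,
    EcgTemplate,
    SynthConfig,
    generate_beat_train,
    generate_dataset,
    generate_recording,
    render_ecg,
    snr_db,
)


class TestBeatTrain:
    def test_zero_jitter_is_periodic(self):
        beats = generate_beat_train(60, 10, 0.0, 1000, seed=0)
        assert len(beats) in (10, 11)
        assert np.all(np.diff(beats) == 1000)

    def test_count_tracks_rate_under_jitter(self):
        beats = generate_beat_train(140, 60, 0.03, 1000, seed=1)
        assert 136 <= len(beats) <= 144

    def test_intervals_bounded_by_jitter(self):
        jitter = 0.05
        beats = generate_beat_train(100, 30, jitter, 1000, seed=2)
        rr = np.diff(beats)
        nominal = 600
        assert np.all(np.abs(rr - nominal) <= 3 * jitter * nominal + 1)

    @pytest.mark.parametrize("rate,duration", [(0, 10), (-5, 10), (60, 0)])
    def test_invalid_arguments(self, rate, duration):
        with pytest.raises(ConfigError):
            generate_beat_train(rate, duration, 0.0, 1000, seed=0)


class TestRenderEcg:
    def test_empty_beats_all_zero(self):
        out = render_ecg(MATERNAL_TEMPLATE, np.array([], dtype=int), 1000, 5000)
        assert np.all(out == 0)

    def test_r_peak_near_beat_annotation(self):
        beats = np.array([1000, 2000, 3000])
        out = render_ecg(MATERNAL_TEMPLATE, beats, 1000, 4000)
        peak = np.argmax(np.abs(out))
        assert min(abs(peak - b) for b in beats) <= 20

    def test_identical_beats_correlate(self):
        beats = np.array([1000, 2000])
        out = render_ecg(MATERNAL_TEMPLATE, beats, 1000, 3000)
        w1 = out[800:1200]
        w2 = out[1800:2200]
        r = np.corrcoef(w1, w2)[0, 1]
        assert r >= 0.99

    def test_out_of_range_beat_rejected(self):
        with pytest.raises(ConfigError):
            render_ecg(MATERNAL_TEMPLATE, np.array([6000]), 1000, 5000)


class TestTemplateInvariants:
    def test_r_lobe_must_dominate(self):
        with pytest.raises(ConfigError):
            EcgTemplate(wave_params=((2.0, -1.0, 0.2), (-0.2, -0.3, 0.1), (1.0, 0.0, 0.1), (-0.2, 0.3, 0.1), (0.1, 1.5, 0.4)))

    def test_widths_positive(self):
        with pytest.raises(ConfigError):
            EcgTemplate(wave_params=((0.1, -1.0, 0.2), (-0.2, -0.3, 0.1), (1.0, 0.0, -0.1), (-0.2, 0.3, 0.1), (0.1, 1.5, 0.4)))


class TestSnr:
    def test_identical_signals_zero_db(self, rng):
        x = rng.standard_normal(1000)
        assert snr_db(x, x) == pytest.approx(0.0)

    def test_amplitude_doubling_adds_six_db(self, rng):
        x = rng.standard_normal(1000)
        n = rng.standard_normal(1000)
        assert snr_db(2 * x, n) - snr_db(x, n) == pytest.approx(20 * np.log10(2))

    def test_analytic_sine_vs_unit_noise(self):
        t = np.arange(100000) / 1000
        sine = np.sqrt(2) * np.sin(2 * np.pi * 10 * t)  # power 1
        noise = np.random.default_rng(0).standard_normal(t.size)  # power ~1
        assert snr_db(sine, noise) == pytest.approx(0.0, abs=0.1)

    def test_zero_noise_rejected(self):
        with pytest.raises(ConfigError):
            snr_db(np.ones(10), np.zeros(10))


class TestGenerateRecording:
    def test_deterministic_given_seed(self):
        cfg = SynthConfig(duration_s=5.0, seed=3)
        a = generate_recording(cfg)
        b = generate_recording(cfg)
        assert np.array_equal(a.channels, b.channels)
        assert np.array_equal(a.fqrs, b.fqrs)

    def test_pure_maternal_mixture_is_scalar_multiple(self):
        cfg = SynthConfig(
            duration_s=5.0,
            foetal_gain_per_channel=(0.0, 0.0, 0.0),
            baseline_amp=0.0,
            powerline_amp=0.0,
            noise_sigma=0.0,
            seed=4,
        )
        rec = generate_recording(cfg)
        mecg = render_ecg(MATERNAL_TEMPLATE, rec.mqrs, cfg.fs, rec.n_samples)
        for i, gain in enumerate(cfg.maternal_gain_per_channel):
            np.testing.assert_allclose(rec.channels[1 + i], gain * mecg, atol=1e-12)

    def test_label_threshold_rule(self):
        good = generate_recording(SynthConfig(duration_s=5.0, target_foetal_snr_db=12.0, seed=5))
        bad = generate_recording(SynthConfig(duration_s=5.0, target_foetal_snr_db=-6.0, seed=5))
        assert good.label == "good" and bad.label == "bad"

    def test_achieved_snr_matches_target(self):
        from fecgsqi.synth import FOETAL_TEMPLATE, render_ecg

        for seed in range(5):
            cfg = SynthConfig(duration_s=10.0, target_foetal_snr_db=6.0, seed=seed)
            rec = generate_recording(cfg)
            foetal = render_ecg(FOETAL_TEMPLATE, rec.fqrs, cfg.fs, rec.n_samples)
            gains = rec.meta["foetal_gain_effective"]
            best = -np.inf
            for i, g in enumerate(gains):
                mecg = render_ecg(MATERNAL_TEMPLATE, rec.mqrs, cfg.fs, rec.n_samples)
                noise = rec.channels[1 + i] - cfg.maternal_gain_per_channel[i] * mecg - g * foetal
                best = max(best, snr_db(g * foetal, noise))
            assert best == pytest.approx(6.0, abs=0.5)

    def test_beat_count_in_analysis_windows(self):
        """2.5 s windows hold 4-6 foetal R peaks for FHR in [110, 140] bpm."""
        for fhr in (110.0, 125.0, 140.0):
            rec = generate_recording(SynthConfig(duration_s=30.0, fhr_bpm=fhr, rr_jitter_frac=0.02, seed=9))
            for start in range(0, rec.n_samples - 2500, 2400):
                count = np.sum((rec.fqrs >= start) & (rec.fqrs < start + 2500))
                assert 4 <= count <= 6

    def test_annotations_align_with_render_peaks(self):
        cfg = SynthConfig(duration_s=10.0, noise_sigma=0.0, baseline_amp=0.0, powerline_amp=0.0, seed=6)
        rec = generate_recording(cfg)
        x = rec.channels[1]
        for b in rec.mqrs[1:-1]:
            window = np.abs(x[b - 100 : b + 100])
            assert abs(int(np.argmax(window)) - 100) <= 20


class TestGenerateDataset:
    def test_counts_and_labels(self):
        recs = generate_dataset(5, 5, SynthConfig(duration_s=5.0), seed=0)
        labels = [r.label for r in recs]
        assert labels.count("good") == 5 and labels.count("bad") == 5

    def test_reproducible(self):
        a = generate_dataset(3, 3, SynthConfig(duration_s=5.0), seed=1)
        b = generate_dataset(3, 3, SynthConfig(duration_s=5.0), seed=1)
        for ra, rb in zip(a, b):
            assert np.array_equal(ra.channels, rb.channels)

    def test_foetal_rates_within_drawn_range(self):
        recs = generate_dataset(4, 4, SynthConfig(duration_s=30.0), seed=2)
        for rec in recs:
            rate = (len(rec.fqrs) - 1) / ((rec.fqrs[-1] - rec.fqrs[0]) / rec.fs) * 60
            assert 105 <= rate <= 165

    def test_overlapping_intervals_rejected(self):
        with pytest.raises(ConfigError):
            generate_dataset(2, 2, SynthConfig(duration_s=5.0), snr_ranges=((0.0, 10.0), (-5.0, 5.0)), seed=0)
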