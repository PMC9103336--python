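"""Classical SQI features: oracle agreement, ranges, assembly."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fecgsqi.qrs import QrsAnnotation
from fecgsqi.sqi import (
    FEATURE_NAMES,
    b_sqi,
    bas_sqi,
    c_sqi,
    feature_vector,
    i_sqi,
    k_sqi,
    mc_sqi,
    mi_sqi,
    mp_sqi,
    mx_sqi,
    p_sqi,
    r_sqi,
    s_sqi,
    std_sqi,
    x_sqi,
)

FS = 1000.0


def _ann(indices, fs=FS):
    return QrsAnnotation(detector="reference", indices=np.asarray(indices, dtype=int), fs=fs)


class TestMoments:
    def test_brute_force_oracle_agreement(self, rng):
        """Moment SQIs equal their definitional sums to 1e-9."""
        for n in (10, 1000, 10000):
            x = rng.standard_normal(n) * rng.uniform(0.5, 3) + rng.uniform(-2, 2)
            mean = sum(x) / n
            var = sum((v - mean) ** 2 for v in x) / n
            std = var**0.5
            skew = sum((v - mean) ** 3 for v in x) / n / std**3
            kurt = sum((v - mean) ** 4 for v in x) / n / std**4
            assert std_sqi(x) == pytest.approx(std, abs=1e-9)
            assert s_sqi(x) == pytest.approx(skew, abs=1e-9)
            assert k_sqi(x) == pytest.approx(kurt, abs=1e-9)

    def test_symmetric_signal_zero_skew(self):
        tri = np.concatenate([np.linspace(-1, 1, 100), np.linspace(1, -1, 100)])
        assert s_sqi(tri) == pytest.approx(0.0, abs=1e-9)

    def test_gaussian_kurtosis(self):
        x = np.random.default_rng(0).standard_normal(10**6)
        assert k_sqi(x) == pytest.approx(3.0, abs=0.02)

    def test_two_point_distribution_kurtosis(self):
        assert k_sqi(np.array([-1.0, 1.0] * 50)) == pytest.approx(1.0)

    def test_constant_input_sentinels(self):
        assert s_sqi(np.ones(10)) == 0.0
        assert k_sqi(np.ones(10)) == 0.0


class TestBandPowerSqis:
    def _tone(self, freq, n=2500):
        return np.sin(2 * np.pi * freq * np.arange(n) / FS)

    def test_p_sqi_tone_inside_low_band(self):
        assert p_sqi(self._tone(10), FS) == pytest.approx(0.0, abs=0.02)

    def test_p_sqi_tone_above_low_band(self):
        assert p_sqi(self._tone(30), FS) == pytest.approx(1.0, abs=0.02)

    def test_p_sqi_no_power_in_band_sentinel(self):
        assert p_sqi(self._tone(200), FS) == pytest.approx(0.0, abs=0.05)

    def test_bas_sqi_baseline_tone(self):
        assert bas_sqi(self._tone(1), FS) == pytest.approx(1.0, abs=0.02)

    def test_bas_sqi_qrs_band_tone(self):
        assert bas_sqi(self._tone(50), FS) <= 0.01

    def test_bas_sqi_zero_signal_sentinel(self):
        assert bas_sqi(np.zeros(2500), FS) == 0.0


class TestDetectionSqis:
    def test_b_sqi_identical(self):
        a = _ann([100, 600, 1100])
        assert b_sqi(a, a) == 1.0

    def test_b_sqi_disjoint(self):
        assert b_sqi(_ann([100, 600]), _ann([350, 850])) == 0.0

    def test_b_sqi_partial(self):
        ref = _ann(np.arange(10) * 500 + 100)
        test = _ann(ref.indices[:5])
        assert b_sqi(test, ref) == pytest.approx(2 * 5 / (10 + 5))

    def test_i_sqi_enumeration(self):
        current = _ann([100, 600, 1100, 1600])
        other1 = _ann([100, 600, 1100])
        other2 = _ann([105, 605, 1105, 2100])
        assert i_sqi([current, other1, other2], 0) == pytest.approx(0.75)
        assert i_sqi([current, current, current], 0) == 1.0
        assert i_sqi([current, _ann([]), other2], 0) == 0.0

    def test_r_sqi_regular_and_outliers(self):
        regular = _ann(np.arange(12) * 430)
        assert r_sqi(regular) == 1.0
        rr = [600] * 10
        rr[3] = 300
        rr[7] = 300  # HR doubles on two of ten intervals
        train = _ann(np.concatenate([[0], np.cumsum(rr)]))
        assert r_sqi(train) == pytest.approx(1 - 2 / 10)
        assert r_sqi(_ann([0, 500])) == 0.0

    def test_c_sqi_identical_beats(self, clean_foetal):
        x, beats = clean_foetal
        assert c_sqi(x, _ann(beats)) >= 0.99

    def test_c_sqi_alternating_negation(self):
        beat = np.exp(-0.5 * ((np.arange(100) - 50) / 8.0) ** 2)
        x = np.zeros(3000)
        centers = [400, 900, 1400, 1900, 2400]
        for i, c in enumerate(centers):
            x[c - 50 : c + 50] += beat if i % 2 == 0 else -beat
        # template ~ +beat (3 of 5); correlations {1,1,1} and {-1,-1} -> clipped
        assert c_sqi(x, _ann(centers)) == pytest.approx(3 / 5, abs=0.05)

    def test_x_sqi_impulse_train(self):
        x = np.zeros(3000)
        centers = [500, 1000, 1500, 2000]
        for c in centers:
            x[c] = 1.0
        assert x_sqi(x, _ann(centers)) == pytest.approx(1.0)

    def test_x_sqi_white_noise_half(self, rng):
        vals = []
        for _ in range(10):
            x = rng.standard_normal(5000)
            centers = np.sort(rng.choice(np.arange(200, 4800), 8, replace=False))
            centers = centers[np.concatenate([[True], np.diff(centers) > 150])]
            vals.append(x_sqi(x, _ann(centers)))
        assert np.mean(vals) == pytest.approx(0.5, abs=0.05)

    def test_x_sqi_zero_signal_sentinel(self):
        assert x_sqi(np.zeros(1000), _ann([500])) == 0.0

    def test_mx_sqi_clean_residual(self):
        x = np.random.default_rng(0).standard_normal(3000) * 0.1
        centers = [500, 1500, 2500]
        for c in centers:
            x[c - 50 : c + 50] = 0.0  # no energy at maternal positions
        assert mx_sqi(x, _ann(centers)) >= 0.95

    def test_mx_sqi_pure_maternal_residual(self):
        x = np.zeros(3000)
        centers = [500, 1500, 2500]
        for c in centers:
            x[c] = 1.0
        assert mx_sqi(x, _ann(centers)) == pytest.approx(0.0)

    def test_mi_sqi_cases(self):
        m = _ann([500, 1500, 2500])
        assert mi_sqi(m, m) == 0.0
        assert mi_sqi(_ann([1000, 2000, 3000]), m) == 1.0
        assert mi_sqi(_ann([]), m) == 0.0


class TestSpectralMaternalSqis:
    def test_mp_sqi_pure_fundamental(self):
        f0 = 1.25  # 75 bpm
        n = 8000
        x = np.sin(2 * np.pi * f0 * np.arange(n) / FS)
        mqrs = _ann(np.arange(0, n, int(FS / f0)))
        assert mp_sqi(x, mqrs, FS, "a") >= 0.95

    def test_mp_sqi_broadband_matches_bandwidth_ratio(self, rng):
        # white noise: harmonic power ~ (total harmonic bandwidth / full band)
        n = 8000
        x = rng.standard_normal(n)
        f0 = 1.25
        mqrs = _ann(np.arange(0, n, int(FS / f0)))
        expected = 5 * 0.4 / 99.5
        assert mp_sqi(x, mqrs, FS, "a") == pytest.approx(expected, abs=0.02)

    def test_mp_sqi_empty_annotation_sentinel(self):
        assert mp_sqi(np.ones(1000), _ann([]), FS, "a") == 0.0

    def test_mc_sqi_delayed_copy(self, rng):
        # delay leaves coherence ~1; Welch estimation costs a little
        x = rng.standard_normal(4000)
        y = np.roll(x, 37)
        assert mc_sqi(x, y, FS) >= 0.95

    def test_mc_sqi_independent_noise_low(self, rng):
        x = rng.standard_normal(4000)
        y = rng.standard_normal(4000)
        assert mc_sqi(x, y, FS) <= 0.3

    def test_mc_sqi_length_mismatch(self):
        from fecgsqi.errors import ConfigError

        with pytest.raises(ConfigError):
            mc_sqi(np.zeros(100), np.zeros(200), FS)


class TestFeatureVector:
    def test_layout_is_45_named_features(self):
        assert len(FEATURE_NAMES) == 45
        assert len(set(FEATURE_NAMES)) == 45

    def test_assembly_and_determinism(self, good_segments):
        segs, _ = good_segments
        a = feature_vector(segs[0])
        b = feature_vector(segs[0])
        assert a.values.shape == (45,)
        np.testing.assert_array_equal(a.values, b.values)
        assert a.quality_mask["extraction_ok"]

    def test_range_law(self, good_segments):
        """All features outside the time-domain moments lie in [0, 1]."""
        segs, _ = good_segments
        vec = feature_vector(segs[1])
        unconstrained = {"stdSQI", "sSQI", "kSQI"}
        for name, value in vec.as_dict().items():
            if name not in unconstrained:
                assert 0.0 <= value <= 1.0, name

    def test_snr_separation_in_x_sqi(self, good_segments, bad_recording):
        from fecgsqi.preprocess import preprocess_recording

        good_segs, _ = good_segments
        bad_segs, _ = preprocess_recording(bad_recording)
        good_x = np.mean([feature_vector(s)["xSQI_pan_tompkins"] for s in good_segs])
        bad_x = np.mean([feature_vector(s)["xSQI_pan_tompkins"] for s in bad_segs])
        assert good_x > bad_x


class TestRangeLawFuzz:
    @settings(max_examples=15, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_band_sqis_bounded_on_random_signals(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.standard_normal(2500) * rng.uniform(0.01, 100)
        for value in (p_sqi(x, FS), bas_sqi(x, FS)):
            assert 0.0 <= value <= 1.0
        ann = _ann(np.sort(rng.choice(2300, 5, replace=False) + 100))
        idx = np.concatenate([[True], np.diff(ann.indices) > 150])
        ann = _ann(ann.indices[idx])
        for value in (x_sqi(x, ann), c_sqi(x, ann), r_sqi(ann), mx_sqi(x, ann)):
            assert 0.0 <= value <= 1.0

    def test_amplitude_invariance_of_ratio_sqis(self, rng):
        x = rng.standard_normal(2500)
        ann = _ann([300, 800, 1300, 1800, 2300])
        for fn in (lambda v: p_sqi(v, FS), lambda v: bas_sqi(v, FS), lambda v: x_sqi(v, ann), lambda v: c_sqi(v, ann)):
            assert fn(x) == pytest.approx(fn(7.3 * x), abs=1e-9)
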