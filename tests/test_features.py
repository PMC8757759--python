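"""Scalar map features against closed-form and brute-force oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from hdsemg import (
    ContractionSegment,
    SimulationConfig,
    coefficient_of_variation,
    differential_intensity,
    feature_set,
    intensity,
    mean_rms,
    median_frequency,
    modified_entropy,
    simulate_recording,
)

FS = 1024.0


def _flat_map(make_map, values59):
    """59 values on the default differential grid (12x5, one pair missing)."""
    mask = np.ones((12, 5), dtype=bool)
    mask[0, 0] = False
    grid = np.zeros((12, 5))
    grid[mask] = values59
    return make_map(grid, mask=mask, mode="single_differential")


class TestEntropy:
    def test_uniform_59_channels_is_log2_59(self, uniform_59_map):
        assert modified_entropy(uniform_59_map) == pytest.approx(np.log2(59), abs=1e-12)

    def test_single_active_channel_is_zero(self, make_map):
        v = np.zeros((12, 5))
        v[3, 2] = 0.7
        assert modified_entropy(make_map(v)) == 0.0

    def test_two_equal_channels_is_one_bit(self, make_map):
        v = np.zeros((12, 5))
        v[3, 2] = v[8, 4] = 0.4
        assert modified_entropy(make_map(v)) == pytest.approx(1.0, abs=1e-12)

    def test_matches_brute_force_sum(self, make_map):
        rng = np.random.default_rng(8)
        v = rng.uniform(0.01, 1.0, size=(12, 5))
        amap = make_map(v)
        p = v.ravel() ** 2 / np.sum(v.ravel() ** 2)
        brute = -sum(pi * np.log2(pi) for pi in p if pi > 0)
        assert modified_entropy(amap) == pytest.approx(brute, rel=1e-10)

    def test_all_zero_map_rejected(self, make_map):
        with pytest.raises(ValueError):
            modified_entropy(make_map(np.zeros((12, 5))))

    @settings(max_examples=30, derandomize=True, deadline=None)
    @given(
        values=hnp.arrays(
            float,
            (6, 4),
            elements=st.floats(0.0, 10.0, allow_nan=False),
        ),
        scale=st.floats(0.01, 100.0),
    )
    def test_bounds_and_scale_invariance(self, values, scale):
        from hdsemg import ActivationMap

        if values.sum() == 0:
            return
        mask = np.ones_like(values, dtype=bool)
        amap = ActivationMap(values=values, valid_mask=mask, window=(0, 1))
        e = modified_entropy(amap)
        assert 0.0 <= e <= np.log2(amap.n_valid) + 1e-9
        scaled = ActivationMap(values=values * scale, valid_mask=mask, window=(0, 1))
        assert modified_entropy(scaled) == pytest.approx(e, abs=1e-9)


class TestIntensity:
    def test_uniform_tenth_mv_gives_minus_one(self, uniform_59_map):
        assert intensity(uniform_59_map) == pytest.approx(-1.0, abs=1e-12)

    def test_uniform_one_mv_gives_zero(self, make_map):
        assert intensity(make_map(np.ones((13, 5)))) == pytest.approx(0.0, abs=1e-12)

    def test_tenfold_scaling_adds_one(self, make_map):
        rng = np.random.default_rng(3)
        v = rng.uniform(0.01, 0.5, (13, 5))
        assert intensity(make_map(10 * v)) == pytest.approx(intensity(make_map(v)) + 1.0, abs=1e-12)

    def test_identity_with_log_mean_rms(self, make_map):
        rng = np.random.default_rng(4)
        amap = make_map(rng.uniform(0.01, 0.5, (13, 5)))
        assert abs(intensity(amap) - np.log10(mean_rms(amap))) < 1e-12

    def test_all_zero_rejected(self, make_map):
        with pytest.raises(ValueError):
            intensity(make_map(np.zeros((13, 5))))


class TestDifferentialIntensity:
    def test_uniform_59_differential(self, uniform_59_map):
        assert differential_intensity(uniform_59_map) == pytest.approx(-1.0, abs=1e-12)

    def test_monopolar_map_rejected(self, make_map):
        with pytest.raises(ValueError, match="single-differential"):
            differential_intensity(make_map(np.ones((13, 5))))

    def test_no_differential_activity_rejected(self, make_map):
        zero = make_map(np.zeros((12, 5)), mode="single_differential")
        with pytest.raises(ValueError, match="differential activity"):
            differential_intensity(zero)

    def test_tenfold_scaling_adds_one(self, make_map):
        rng = np.random.default_rng(5)
        v = rng.uniform(0.01, 0.5, (12, 5))
        a = make_map(v, mode="single_differential")
        b = make_map(10 * v, mode="single_differential")
        assert differential_intensity(b) == pytest.approx(differential_intensity(a) + 1, abs=1e-12)


class TestCoV:
    def test_uniform_map_is_zero(self, uniform_59_map):
        assert coefficient_of_variation(uniform_59_map) == pytest.approx(0.0, abs=1e-10)

    def test_two_level_map_matches_direct_formula(self, make_map):
        values = np.array([1.0] * 29 + [2.0] * 30)
        amap = _flat_map(make_map, values)
        mean = values.sum() / 59
        sd = np.sqrt(((values - mean) ** 2).sum() / 59)
        assert coefficient_of_variation(amap) == pytest.approx(100 * sd / mean, rel=1e-10)

    def test_scale_invariance(self, make_map):
        rng = np.random.default_rng(6)
        v = rng.uniform(0.01, 0.5, (12, 5))
        a = coefficient_of_variation(make_map(v))
        b = coefficient_of_variation(make_map(7.3 * v))
        assert b == pytest.approx(a, rel=1e-10)


class TestMeanRMS:
    def test_constant_map(self, make_map):
        assert mean_rms(make_map(np.full((13, 5), 0.07))) == pytest.approx(0.07)

    def test_masked_positions_excluded(self, make_map):
        v = np.full((13, 5), 0.1)
        mask = np.ones((13, 5), bool)
        mask[0, 0] = False
        v[0, 0] = 99.0  # masked garbage must not leak into the mean
        assert mean_rms(make_map(v, mask=mask)) == pytest.approx(0.1)


class TestMedianFrequency:
    def test_pure_tone(self):
        t = np.arange(int(FS)) / FS
        x = np.sin(2 * np.pi * 80 * t)
        assert median_frequency(x, FS) == pytest.approx(80.0, abs=1.0)

    def test_two_equal_tones_take_lower_median(self):
        t = np.arange(int(2 * FS)) / FS
        x = np.sin(2 * np.pi * 50 * t) + np.sin(2 * np.pi * 150 * t)
        med = median_frequency(x, FS)
        # independent oracle: cumulative Hann periodogram
        from scipy.signal import periodogram

        f, p = periodogram(x, FS, window="hann")
        oracle = f[np.argmax(np.cumsum(p) >= 0.5 * p.sum())]
        assert med == pytest.approx(oracle, abs=1e-9)
        assert 45.0 <= med <= 55.0

    def test_flat_band_median_is_band_midpoint(self):
        meds = []
        for seed in range(8):
            rng = np.random.default_rng(seed)
            n = int(4 * FS)
            spec = np.fft.rfft(rng.standard_normal(n))
            f = np.fft.rfftfreq(n, 1 / FS)
            spec[(f < 20) | (f > 400)] = 0
            x = np.fft.irfft(spec, n)
            meds.append(median_frequency(x, FS))
        assert np.mean(meds) == pytest.approx(210.0, abs=5.0)

    def test_band_limited_noise_median_inside_band(self):
        for seed in range(5):
            rec, _ = simulate_recording(SimulationConfig(seed=seed, duration_s=2.0, onset_s=0.25, ramp_s=0.25, plateau_s=1.0))
            mid = rec.n_samples // 2
            med = median_frequency(rec.signals[:, mid - 256 : mid + 256], rec.fs_hz)
            assert 20.0 <= med <= 400.0

    def test_silent_input_rejected(self):
        with pytest.raises(ValueError, match="silent"):
            median_frequency(np.zeros((4, 512)), FS)

    def test_short_epoch_rejected(self):
        with pytest.raises(ValueError, match="128"):
            median_frequency(np.ones((1, 64)), FS)


class TestFeatureSet:
    def test_uniform_recording_limits(self, geometry):
        # near-uniform spatial envelope: entropy at its ceiling, CoV small
        cfg = SimulationConfig(seed=9, sigma_rows=50.0, sigma_cols=50.0, duration_s=2.5)
        rec, _ = simulate_recording(cfg)
        from hdsemg import bandpass_filter, segment_contraction

        rec = bandpass_filter(rec)
        seg = segment_contraction(rec)
        fs = feature_set(rec, seg)
        assert fs.entropy > 0.98 * np.log2(59)
        assert fs.cov < 20.0
        assert abs(fs.intensity - np.log10(fs.mean_rms)) < 1e-12
        assert 20.0 <= fs.median_frequency <= 400.0

    def test_localized_source_lowers_entropy(self):
        from hdsemg import bandpass_filter, segment_contraction

        out = {}
        for name, sig in (("broad", 50.0), ("narrow", 1.2)):
            cfg = SimulationConfig(seed=10, sigma_rows=sig, sigma_cols=sig / 2, duration_s=2.5)
            rec, _ = simulate_recording(cfg)
            rec = bandpass_filter(rec)
            out[name] = feature_set(rec, segment_contraction(rec))
        assert out["narrow"].entropy < out["broad"].entropy
        assert out["narrow"].cov > out["broad"].cov
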