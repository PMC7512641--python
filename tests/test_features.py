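"""Wavelet front end: mother wavelet, CWT oracle equivalence, sub-band statistics."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import quad

from eegsae.core import CHANNELS_1020, Epoch
from eegsae.features import (
    EdgeDominatedScaleWarning,
    FeatureDataset,
    SubBandPartition,
    WaveletSpec,
    build_feature_dataset,
    build_feature_vector,
    cwt_map,
    feature_names,
    mexican_hat,
    pseudo_freq_for_scale,
    scale_for_freq,
    subband_statistics,
)


def brute_force_cwt(x, spec):
    """Independent Riemann-sum evaluation of the transform definition."""
    n = len(x)
    dt = 1.0 / spec.fs
    t = np.arange(n) * dt
    out = np.empty((len(spec.scales), n))
    for r, a in enumerate(spec.scales):
        for j in range(n):
            out[r, j] = np.sum(x * mexican_hat((t - t[j]) / a, spec.sigma)) * dt / np.sqrt(a)
    return out


class TestMexicanHat:
    def test_zero_crossings_at_plus_minus_sigma(self):
        for sigma in (0.5, 1.0, 2.0):
            assert mexican_hat(sigma, sigma) == pytest.approx(0.0, abs=1e-15)
            assert mexican_hat(-sigma, sigma) == pytest.approx(0.0, abs=1e-15)

    def test_maximum_at_zero_equals_normalization(self):
        sigma = 1.5
        peak = mexican_hat(0.0, sigma)
        assert peak == pytest.approx(2.0 / (np.sqrt(3.0 * sigma) * np.pi**0.25))
        grid = np.linspace(-5 * sigma, 5 * sigma, 2001)
        assert np.max(mexican_hat(grid, sigma)) <= peak + 1e-15

    def test_zero_mean_admissibility(self):
        val, _ = quad(lambda t: mexican_hat(t, 1.0), -10.0, 10.0, limit=200)
        assert abs(val) < 1e-8

    def test_sigma_must_be_positive(self):
        with pytest.raises(ValueError, match="sigma"):
            mexican_hat(0.0, 0.0)


class TestWaveletSpec:
    def test_default_grid_spans_half_to_32_hz(self):
        spec = WaveletSpec.default()
        f = spec.pseudo_freqs
        assert len(spec.scales) == 64
        assert f[0] == pytest.approx(32.0)
        assert f[-1] == pytest.approx(0.5)
        assert np.all(np.diff(spec.scales) > 0)
        assert np.all(np.diff(f) < 0)

    def test_scale_freq_mapping_inverts(self):
        freqs = np.array([0.5, 4.0, 8.0, 32.0])
        assert pseudo_freq_for_scale(scale_for_freq(freqs)) == pytest.approx(freqs)

    def test_non_monotonic_scales_rejected(self):
        with pytest.raises(ValueError, match="increasing"):
            WaveletSpec(scales=(0.2, 0.1))


class TestCwtMap:
    def test_zero_signal_gives_zero_map(self):
        spec = WaveletSpec.default(n_scales=8)
        tfm = cwt_map(np.zeros(256), spec)
        assert np.all(tfm.coefficients == 0.0)
        assert tfm.coefficients.shape == (8, 256)
        assert len(tfm.times) == 256

    def test_matches_brute_force_oracle(self, rng):
        """Fast FFT path vs direct Riemann integration: <=1e-6 relative error."""
        x = rng.normal(size=64)
        spec = WaveletSpec.default(fs=256.0, n_scales=8)
        with pytest.warns(EdgeDominatedScaleWarning):
            fast = cwt_map(x, spec).coefficients
        slow = brute_force_cwt(x, spec)
        rel = np.max(np.abs(fast - slow)) / np.max(np.abs(slow))
        assert rel <= 1e-6

    def test_sinusoid_peaks_at_its_own_pseudo_frequency(self):
        fs = 256.0
        t = np.arange(int(5 * fs)) / fs
        spec = WaveletSpec.default(fs=fs, n_scales=64)
        tfm = cwt_map(np.sin(2 * np.pi * 8.0 * t), spec)
        ridge = np.abs(tfm.coefficients).mean(axis=1)
        k = int(np.argmax(ridge))
        step = spec.pseudo_freqs[0] / spec.pseudo_freqs[1]
        assert spec.pseudo_freqs[k] / 8.0 <= step + 1e-9
        assert 8.0 / spec.pseudo_freqs[k] <= step + 1e-9

    @given(k=st.floats(min_value=0.1, max_value=10.0))
    @settings(max_examples=20, deadline=None)
    def test_scaling_covariance(self, k):
        """Scaling the signal by k scales every coefficient by k."""
        rng = np.random.default_rng(99)
        x = rng.normal(size=128)
        spec = WaveletSpec.default(fs=256.0, n_scales=4, fmin=8.0, fmax=32.0)
        base = cwt_map(x, spec).coefficients
        scaled = cwt_map(k * x, spec).coefficients
        assert np.allclose(scaled, k * base, rtol=1e-10, atol=1e-12)

    def test_edge_dominated_scale_warns(self):
        spec = WaveletSpec(scales=(0.01, 5.0), fs=256.0)
        with pytest.warns(EdgeDominatedScaleWarning):
            cwt_map(np.ones(64), spec)


class TestSubbandStatistics:
    def _map_with(self, coeff, freqs):
        from eegsae.features import TFMap
        return TFMap(coefficients=np.asarray(coeff, float),
                     scales=1.0 / np.asarray(freqs),
                     pseudo_freqs=np.asarray(freqs, float),
                     times=np.arange(np.asarray(coeff).shape[1], dtype=float))

    def test_constant_map_degenerates_to_mu_c(self):
        freqs = [16.0, 6.0, 2.0]
        tfm = self._map_with(np.full((3, 10), 3.5), freqs)
        stats = subband_statistics(tfm, SubBandPartition())
        assert stats == pytest.approx([3.5, 0, 0] * 4)

    def test_known_multiset_moments(self):
        """One band holding {1,2,3,4}: mu=2.5, population sd=sqrt(1.25)."""
        freqs = [16.0, 6.0, 2.0]
        coeff = np.zeros((3, 4))
        coeff[2] = [1.0, 2.0, 3.0, 4.0]  # 2 Hz -> band 1 (lowest frequencies)
        tfm = self._map_with(coeff, freqs)
        stats = subband_statistics(tfm, SubBandPartition())
        b1 = stats[3:6]
        assert b1[0] == pytest.approx(2.5)
        assert b1[1] == pytest.approx(np.sqrt(1.25))
        assert b1[2] == pytest.approx(0.0, abs=1e-12)

    def test_symmetric_coefficients_have_zero_skew(self):
        freqs = [16.0, 6.0, 2.0]
        vals = np.array([-2.0, -1.0, 1.0, 2.0])
        tfm = self._map_with(np.tile(vals, (3, 1)), freqs)
        stats = subband_statistics(tfm, SubBandPartition())
        assert stats[2::3] == pytest.approx([0.0] * 4, abs=1e-12)

    def test_whole_map_mean_is_count_weighted_band_mean(self, rng):
        spec = WaveletSpec.default(n_scales=16)
        tfm = cwt_map(rng.normal(size=256), spec)
        part = SubBandPartition()
        stats = subband_statistics(tfm, part)
        idx = part.assign(tfm.pseudo_freqs)
        counts = np.array([(idx == b).sum() for b in range(3)]) * tfm.coefficients.shape[1]
        weighted = np.sum(stats[3::3] * counts) / counts.sum()
        assert stats[0] == pytest.approx(weighted, abs=1e-10)

    def test_empty_subband_rejected(self):
        freqs = [30.0, 20.0, 10.0]  # nothing below 8 Hz
        tfm = self._map_with(np.ones((3, 5)), freqs)
        with pytest.raises(ValueError, match=r"\[0.5, 4"):
            subband_statistics(tfm, SubBandPartition())

    def test_uncovered_scale_rejected(self):
        freqs = [64.0, 6.0, 2.0]
        tfm = self._map_with(np.ones((3, 5)), freqs)
        with pytest.raises(ValueError, match="outside"):
            subband_statistics(tfm, SubBandPartition())


class TestFeatureVector:
    def _epoch(self, samples, fs=256.0):
        return Epoch(samples, fs=fs, T_epoch=samples.shape[1] / fs,
                     channel_labels=CHANNELS_1020[: samples.shape[0]])

    def test_length_is_228_for_19_channels(self, small_epochs):
        fv = build_feature_vector(small_epochs[0])
        assert fv.values.shape == (228,)
        assert len(fv.names) == 228

    def test_all_zero_epoch_gives_all_zero_features(self):
        fv = build_feature_vector(self._epoch(np.zeros((19, 1280))))
        assert np.all(fv.values == 0.0)

    def test_channel_permutation_permutes_blocks(self, small_epochs):
        ep = small_epochs[0]
        base = build_feature_vector(ep).values
        swapped = ep.samples.copy()
        swapped[[0, 5]] = swapped[[5, 0]]
        out = build_feature_vector(self._epoch(swapped)).values
        assert np.allclose(out[0:12], base[60:72])
        assert np.allclose(out[60:72], base[0:12])
        mask = np.ones(228, bool)
        mask[0:12] = mask[60:72] = False
        assert np.allclose(out[mask], base[mask])

    def test_channel_locality(self, small_epochs):
        ep = small_epochs[0]
        base = build_feature_vector(ep).values
        mod = ep.samples.copy()
        mod[7] *= 2.0
        out = build_feature_vector(self._epoch(mod)).values
        changed = np.nonzero(~np.isclose(out, base))[0]
        assert np.all((changed >= 7 * 12) & (changed < 8 * 12))

    def test_wrong_channel_count_rejected_unless_overridden(self):
        ep = self._epoch(np.zeros((5, 1280)))
        with pytest.raises(ValueError, match="19 channels"):
            build_feature_vector(ep)
        fv = build_feature_vector(ep, allow_any_channel_count=True)
        assert fv.values.shape == (60,)

    def test_layout_names(self):
        names = feature_names(("Fp1", "Fp2"))
        assert names[:4] == ["Fp1_all_mu", "Fp1_all_sd", "Fp1_all_skew", "Fp1_b1_mu"]
        assert names[12] == "Fp2_all_mu"


class TestFeatureDataset:
    def test_one_record_per_epoch_with_labels(self, small_epochs, small_features):
        assert len(small_features) == len(small_epochs)
        assert set(small_features.y) == {"CNT", "PNES"}
        assert small_features.X.shape == (len(small_epochs), 228)

    def test_empty_epoch_list_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            build_feature_dataset([])

    def test_mixed_channel_counts_rejected(self, small_epochs):
        bad = Epoch(np.zeros((5, 1280)), fs=256.0, T_epoch=5.0,
                    channel_labels=CHANNELS_1020[:5])
        with pytest.raises(ValueError, match="mixed"):
            build_feature_dataset([small_epochs[0], bad])

    def test_tsv_roundtrip_lossless(self, tmp_path, small_features):
        path = tmp_path / "features.tsv"
        small_features.save(path)
        back = FeatureDataset.load(path)
        assert back.feature_names == small_features.feature_names
        assert np.array_equal(back.X, small_features.X)
        assert back.meta["partition_edges_hz"] == [0.5, 4.0, 8.0, 32.0]
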