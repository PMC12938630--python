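"""Masking, bias correction, and histogram-peak normalization."""

import numpy as np
import pytest

from cmbdetect import (
    BrainMask,
    HistogramPeak,
    PhantomSpec,
    PreprocessConfig,
    ScanVolume,
    apply_brain_mask,
    correct_bias,
    find_histogram_peak,
    generate_phantom,
    normalize_intensity,
    preprocess_scan,
)


def _ball_mask(shape=(32, 32, 24)):
    grids = np.meshgrid(*[np.arange(n) for n in shape], indexing="ij")
    c = [(n - 1) / 2 for n in shape]
    return BrainMask(
        sum(((g - cc) / (0.45 * n)) ** 2 for g, cc, n in zip(grids, c, shape)) <= 1
    )


class TestApplyBrainMask:
    def test_all_true_mask_is_identity(self, rng):
        vol = ScanVolume(rng.random((8, 8, 8)))
        out = apply_brain_mask(vol, BrainMask(np.ones((8, 8, 8), bool)))
        np.testing.assert_array_equal(out.intensities, vol.intensities)

    def test_single_voxel_mask(self, rng):
        vol = ScanVolume(rng.random((8, 8, 8)) + 1)
        m = np.zeros((8, 8, 8), bool)
        m[3, 4, 5] = True
        out = apply_brain_mask(vol, BrainMask(m))
        assert np.count_nonzero(out.intensities) == 1
        assert out.intensities[3, 4, 5] == vol.intensities[3, 4, 5]

    def test_idempotent(self, rng):
        vol = ScanVolume(rng.random((8, 8, 8)))
        mask = _ball_mask((8, 8, 8))
        once = apply_brain_mask(vol, mask)
        twice = apply_brain_mask(once, mask)
        np.testing.assert_array_equal(once.intensities, twice.intensities)

    def test_shape_mismatch(self, rng):
        with pytest.raises(ValueError):
            apply_brain_mask(
                ScanVolume(rng.random((8, 8, 8))), BrainMask(np.ones((8, 8, 9), bool))
            )


class TestCorrectBias:
    def test_bias_free_input_nearly_unchanged(self):
        vol, mask, _ = generate_phantom(
            PhantomSpec(noise_sd=0.0, bias_amplitude=0.0, seed=5)
        )
        out, _ = correct_bias(vol, mask)
        inside = mask.mask
        rms = np.sqrt(
            np.mean(
                (out.intensities[inside] - vol.intensities[inside]) ** 2
            )
        ) / vol.intensities[inside].mean()
        assert rms < 0.01

    def test_known_field_recovered(self):
        spec = PhantomSpec(bias_amplitude=0.3, noise_sd=0.0, seed=6)
        vol, mask, _ = generate_phantom(spec)
        flat, _, _ = generate_phantom(
            PhantomSpec(bias_amplitude=0.0, noise_sd=0.0, seed=6)
        )
        with np.errstate(divide="ignore", invalid="ignore"):
            true_field = np.where(
                flat.intensities > 0, vol.intensities / np.where(flat.intensities > 0, flat.intensities, 1), 1.0
            )
        _, est_field = correct_bias(vol, mask)
        inside = mask.mask & (flat.intensities > 0)
        corr = np.corrcoef(true_field[inside], est_field[inside])[0, 1]
        assert corr > 0.9

    def test_exterior_stays_zero_and_mean_preserved(self, default_phantom):
        vol, mask, _ = default_phantom
        out, field = correct_bias(vol, mask)
        assert np.all(out.intensities[~mask.mask] == 0)
        assert np.all(field > 0)
        assert out.intensities[mask.mask].mean() == pytest.approx(
            vol.intensities[mask.mask].mean(), rel=1e-6
        )

    def test_tiny_mask_rejected(self, rng):
        vol = ScanVolume(rng.random((8, 8, 8)) + 1)
        m = np.zeros((8, 8, 8), bool)
        m[0, 0, :5] = True
        with pytest.raises(ValueError):
            correct_bias(vol, BrainMask(m))


class TestFindHistogramPeak:
    def test_constant_volume(self):
        data = np.zeros((10, 10, 10))
        data[2:8, 2:8, 2:8] = 7.0
        peak = find_histogram_peak(ScanVolume(data))
        assert abs(peak.value - 7.0) <= peak.bin_width / 2

    def test_zeros_excluded(self):
        # 90% zeros must not drag the peak toward zero
        data = np.zeros((10, 10, 10))
        data.flat[:100] = 5.0
        peak = find_histogram_peak(ScanVolume(data))
        assert abs(peak.value - 5.0) <= peak.bin_width / 2

    def test_bimodal_matches_bruteforce(self, rng):
        lo = rng.normal(20, 1, 4000)
        hi = rng.normal(60, 1, 6000)
        data = np.abs(np.concatenate([lo, hi])).reshape(20, 20, 25)
        vol = ScanVolume(data)
        peak = find_histogram_peak(vol, n_bins=128)
        # brute-force oracle: count positives per uniform bin
        pos = data[data > 0]
        edges = np.linspace(0, pos.max(), 129)
        counts = [
            ((pos >= a) & (pos < b)).sum() for a, b in zip(edges[:-2], edges[1:-1])
        ] + [((pos >= edges[-2]) & (pos <= edges[-1])).sum()]
        best = int(np.argmax(counts))
        expected = (edges[best] + edges[best + 1]) / 2
        assert peak.value == pytest.approx(expected, abs=1e-9)

    def test_all_zero_volume_rejected(self):
        with pytest.raises(ValueError):
            find_histogram_peak(ScanVolume(np.zeros((5, 5, 5))))


class TestNormalizeIntensity:
    @pytest.mark.parametrize("i,expected", [(8.0, 0.5), (0.0, 0.0), (24.0, 1.5)])
    def test_linear_map(self, i, expected):
        peak = HistogramPeak(value=8.0, bin_width=0.1, n_bins=256)
        vol = ScanVolume(np.full((4, 4, 4), i))
        out = normalize_intensity(vol, peak)
        assert out.intensities[0, 0, 0] == pytest.approx(expected, abs=0)

    def test_monotone_order_preserving(self, rng):
        vals = rng.random((6, 6, 6)) * 100
        peak = HistogramPeak(value=30.0, bin_width=1.0, n_bins=256)
        out = normalize_intensity(ScanVolume(vals), peak)
        order_in = np.argsort(vals.ravel())
        order_out = np.argsort(out.intensities.ravel())
        np.testing.assert_array_equal(order_in, order_out)

    def test_non_positive_peak_rejected(self):
        with pytest.raises(ValueError):
            HistogramPeak(value=0.0, bin_width=0.1, n_bins=256)


class TestPreprocessScan:
    def _peak_of(self, vol, n_bins=256):
        return find_histogram_peak(vol, n_bins=n_bins)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_peak_lands_at_half(self, seed):
        vol, mask, _ = generate_phantom(PhantomSpec(seed=seed))
        out = preprocess_scan(vol, mask)
        peak = self._peak_of(out)
        assert abs(peak.value - 0.5) <= peak.bin_width

    @pytest.mark.parametrize("n_bins", [128, 512])
    def test_peak_robust_to_binning(self, n_bins):
        vol, mask, _ = generate_phantom(PhantomSpec(seed=3))
        out = preprocess_scan(vol, mask, PreprocessConfig(n_bins=n_bins))
        peak = self._peak_of(out, n_bins=n_bins)
        assert abs(peak.value - 0.5) <= peak.bin_width

    def test_scanner_scaling_compensated(self):
        p1 = preprocess_scan(*generate_phantom(PhantomSpec(tissue_mean=100, seed=4))[:2])
        p2 = preprocess_scan(*generate_phantom(PhantomSpec(tissue_mean=1000, seed=4))[:2])
        k1, k2 = self._peak_of(p1), self._peak_of(p2)
        assert abs(k1.value - k2.value) <= max(k1.bin_width, k2.bin_width)

    def test_renormalization_stable(self):
        vol, mask, _ = generate_phantom(PhantomSpec(seed=5))
        once = preprocess_scan(vol, mask)
        twice = preprocess_scan(once, mask, PreprocessConfig(skip_bias=True))
        peak = self._peak_of(twice)
        assert abs(peak.value - 0.5) <= peak.bin_width

    def test_never_negative(self):
        vol, mask, _ = generate_phantom(PhantomSpec(seed=6, noise_sd=20.0))
        out = preprocess_scan(vol, mask)
        assert out.intensities.min() >= 0
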