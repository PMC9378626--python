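import numpy as np
import pytest

import ptytomo as pt
from ptytomo.metrics import (MetricsError, RESOLUTION_NOT_REACHED,
                             _histogram_peak)
from ptytomo.optics import DoseSpec


def _regions(shape, n=400, seed=0):
    """Three disjoint equal-count index masks over a flat array."""
    rng = np.random.default_rng(seed)
    idx = rng.permutation(np.prod(shape))[:3 * n]
    masks = []
    for i in range(3):
        m = np.zeros(np.prod(shape), bool)
        m[idx[i * n:(i + 1) * n]] = True
        masks.append(m.reshape(shape))
    return masks


class TestNormalise:
    def test_background_peak_maps_to_zero(self):
        rng = np.random.default_rng(0)
        data = rng.normal(5.0, 0.1, (64, 64))
        bkgd, _, gold = _regions((64, 64))
        data[gold] = 12.0
        out = pt.normalise(data, bkgd, gold)
        assert abs(_histogram_peak(out[bkgd])) < 0.05

    def test_gold_mean_maps_to_one(self):
        rng = np.random.default_rng(1)
        data = rng.normal(0.0, 0.05, (64, 64))
        bkgd, _, gold = _regions((64, 64))
        data[gold] += 3.0
        out = pt.normalise(data, bkgd, gold)
        assert out[gold].mean() == pytest.approx(1.0, abs=1e-9)

    def test_affine_invariance(self):
        rng = np.random.default_rng(2)
        data = rng.normal(0.0, 1.0, (64, 64))
        bkgd, _, gold = _regions((64, 64))
        data[gold] += 5.0
        a = pt.normalise(data, bkgd, gold)
        b = pt.normalise(3.7 * data - 11.0, bkgd, gold)
        np.testing.assert_allclose(a, b, atol=1e-9)

    def test_degenerate(self):
        data = np.ones((32, 32))
        bkgd, _, gold = _regions((32, 32), n=50)
        with pytest.raises(MetricsError):
            pt.normalise(data, bkgd, gold)


class TestHistogramPeaks:
    def test_constant_region_peak(self):
        data = np.zeros((64, 64))
        bkgd, dna, gold = _regions((64, 64))
        data[dna] = 0.3
        data[gold] = 1.0
        stats = pt.histogram_peaks(data, bkgd, dna, gold)
        assert stats.p_dna == pytest.approx(0.3, abs=stats.bin_width)
        assert stats.p_bkgd == pytest.approx(0.0, abs=stats.bin_width)
        assert stats.p_gold == pytest.approx(1.0, abs=1e-12)

    def test_two_gaussian_oracle(self):
        # oracle: the generating parameters (mu = 0 and 0.2, sigma 0.03)
        rng = np.random.default_rng(7)
        n = 100_000
        data = np.concatenate([rng.normal(0.0, 0.03, n),
                               rng.normal(0.2, 0.03, n),
                               np.ones(n)])
        bkgd = np.zeros(3 * n, bool)
        bkgd[:n] = True
        dna = np.zeros(3 * n, bool)
        dna[n:2 * n] = True
        gold = np.zeros(3 * n, bool)
        gold[2 * n:] = True
        stats = pt.histogram_peaks(data, bkgd, dna, gold, bin_count=256)
        assert stats.p_bkgd == pytest.approx(0.0, abs=0.01)
        assert stats.p_dna == pytest.approx(0.2, abs=0.01)

    def test_shuffle_invariant(self):
        rng = np.random.default_rng(3)
        values = np.concatenate([rng.normal(0, 0.05, 500),
                                 rng.normal(0.4, 0.05, 500),
                                 rng.normal(1.0, 0.05, 500)])
        order = rng.permutation(1500)
        masks = [np.zeros(1500, bool) for _ in range(3)]
        for i in range(3):
            masks[i][i * 500:(i + 1) * 500] = True
        a = pt.histogram_peaks(values, *masks)
        b = pt.histogram_peaks(values[order],
                               masks[0][order], masks[1][order],
                               masks[2][order])
        assert a.p_dna == b.p_dna and a.p_bkgd == b.p_bkgd

    def test_unequal_regions_rejected(self):
        data = np.zeros(100)
        a = np.zeros(100, bool)
        b = np.zeros(100, bool)
        c = np.zeros(100, bool)
        a[:10], b[10:25], c[25:35] = True, True, True
        with pytest.raises(MetricsError):
            pt.histogram_peaks(data, a, b, c)


class TestContrastRatio:
    def test_paper_offset_value(self):
        # DNA separated from the carbon background by 0.17 on the
        # normalized scale translates directly into R
        assert pt.contrast_ratio(0.17, 0.0, 1.0) == pytest.approx(0.17)

    def test_edges(self):
        assert pt.contrast_ratio(0.0, 0.0, 1.0) == 0.0
        assert pt.contrast_ratio(1.0, 0.0, 1.0) == 1.0

    def test_zero_denominator(self):
        with pytest.raises(MetricsError):
            pt.contrast_ratio(0.5, 1.0, 1.0)

    def test_affine_invariance_of_r(self):
        r1 = pt.contrast_ratio(0.3, 0.1, 0.9)
        r2 = pt.contrast_ratio(0.3 * 7 + 2, 0.1 * 7 + 2, 0.9 * 7 + 2)
        assert r1 == pytest.approx(r2)


class TestSplitDataset:
    def _stack(self, shape=(10, 9)):
        optics = pt.OpticsConfig(60.0, 1.5, defocus_nm=-4000.0)
        scan = pt.make_raster_scan(shape, 2.0, (0.0, 0.0))
        phi = np.zeros((128, 128))
        return pt.simulate_4dstem(phi, optics, scan, DoseSpec(88.0, 2.0),
                                  pixel_size=1.0, window=64, noiseless=True)

    def test_90_patterns_split_45_45(self):
        stack = self._stack((10, 9))
        a, b = pt.split_dataset(stack)
        assert a.scan.n_positions == 45 and b.scan.n_positions == 45
        pos_a = set(a.scan.positions_nm)
        pos_b = set(b.scan.positions_nm)
        assert not pos_a & pos_b
        assert pos_a | pos_b == set(stack.scan.positions_nm)

    def test_checkerboard_no_adjacent_same_half(self):
        stack = self._stack((10, 10))
        a, _ = pt.split_dataset(stack, "checkerboard")
        picked = {p for p in a.scan.positions_nm}
        all_pos = list(stack.scan.positions_nm)
        for i, p in enumerate(all_pos):
            row, col = divmod(i, 10)
            if col + 1 < 10:
                neighbour = all_pos[i + 1]
                assert (p in picked) != (neighbour in picked)

    def test_halved_dose_metadata(self):
        stack = self._stack((4, 4))
        a, b = pt.split_dataset(stack)
        assert a.dose.dose_per_area == stack.dose.dose_per_area / 2
        assert b.dose.dose_per_area == stack.dose.dose_per_area / 2

    def test_deterministic(self):
        stack = self._stack((6, 6))
        a1, _ = pt.split_dataset(stack)
        a2, _ = pt.split_dataset(stack)
        np.testing.assert_array_equal(a1.intensities, a2.intensities)


class TestFrcFsc:
    def test_self_correlation_is_one(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal((128, 128))
        result = pt.frc(x, x, 1.0)
        assert np.all(result.correlation >= 1.0 - 1e-12)

    def test_white_noise_null(self):
        a = np.random.default_rng(1).standard_normal((256, 256))
        b = np.random.default_rng(2).standard_normal((256, 256))
        result = pt.frc(a, b, 1.0)
        bound = 3.0 / np.sqrt(result.n_samples)
        assert np.mean(np.abs(result.correlation) < bound) >= 0.95

    def test_constructed_crossing(self):
        rng = np.random.default_rng(0)
        kc = 0.25 * 0.5  # quarter of Nyquist at 1 nm pixels
        grid = pt.Grid2D((256, 256), 1.0)
        mask = np.sqrt(grid.freq_squared()) <= kc
        sig = np.real(np.fft.ifft2(
            np.fft.fft2(rng.standard_normal((256, 256))) * mask))
        sig /= sig.std()
        n1 = np.random.default_rng(3).standard_normal((256, 256))
        n2 = np.random.default_rng(4).standard_normal((256, 256))
        result = pt.frc(sig + n1, sig + n2, 1.0)
        assert result.crossed
        assert 1.0 / result.resolution == pytest.approx(kc, rel=0.15)

    def test_symmetry(self):
        a = np.random.default_rng(5).standard_normal((64, 64))
        b = a + 0.5 * np.random.default_rng(6).standard_normal((64, 64))
        r1 = pt.frc(a, b, 1.0)
        r2 = pt.frc(b, a, 1.0)
        np.testing.assert_array_equal(r1.correlation, r2.correlation)
        assert r1.resolution == r2.resolution

    def test_no_crossing_sentinel(self):
        x = np.random.default_rng(0).standard_normal((64, 64))
        result = pt.frc(x, x, 1.0)
        assert result.resolution == RESOLUTION_NOT_REACHED
        assert not result.crossed
        assert len(result.correlation) == len(result.threshold)

    def test_fsc_3d(self):
        rng = np.random.default_rng(0)
        v = rng.standard_normal((32, 32, 32))
        result = pt.fsc(v, v, 1.0)
        assert np.all(result.correlation >= 1.0 - 1e-10)

    def test_fsc_accepts_volume3d(self):
        v = np.random.default_rng(1).standard_normal((24, 24, 24))
        vol = pt.Volume3D(v, 0.8)
        result = pt.fsc(vol, pt.Volume3D(v.copy(), 0.8))
        assert result.frequencies[0] > 0

    def test_alternative_criteria(self):
        a = np.random.default_rng(7).standard_normal((64, 64))
        for criterion in ("0.143", "0.5"):
            r = pt.frc(a, a, 1.0, criterion=criterion)
            assert np.all(r.threshold == float(criterion))

    def test_mismatched_grids(self):
        with pytest.raises(MetricsError):
            pt.frc(np.zeros((32, 32)), np.zeros((64, 64)))


class TestHalfBitThreshold:
    def test_asymptotic_limit(self):
        t = pt.half_bit_threshold(np.array([1e8]))[0]
        assert t == pytest.approx(0.2071 / 1.2071, abs=1e-3)

    def test_decreasing_in_n(self):
        n = np.array([1.0, 10.0, 100.0, 1e4, 1e8])
        t = pt.half_bit_threshold(n)
        assert np.all(np.diff(t) < 0)


class TestDoseSeriesReport:
    def _entry(self, seed, scale=1.0):
        rng = np.random.default_rng(seed)
        img = rng.normal(0.0, 0.02, (64, 64))
        bkgd, dna, gold = _regions((64, 64), n=300, seed=1)
        img[dna] += 0.2 * scale
        img[gold] += 1.0
        return img, (bkgd, dna, gold)

    def test_identical_images_identical_r(self):
        img, (bkgd, dna, gold) = self._entry(0)
        rows = pt.dose_series_report([(88.0, img), (26.0, img)],
                                     bkgd, dna, gold)
        assert rows[0]["contrast_ratio"] == rows[1]["contrast_ratio"]

    def test_fading_signal_gives_decreasing_r(self):
        entries = []
        for dose, scale in [(88.0, 1.0), (45.0, 0.7), (26.0, 0.4)]:
            img, (bkgd, dna, gold) = self._entry(0, scale)
            entries.append((dose, img))
        rows = pt.dose_series_report(entries, bkgd, dna, gold)
        rs = [r["contrast_ratio"] for r in rows]
        assert rs[0] > rs[1] > rs[2]

    def test_row_count_and_csv(self, tmp_path):
        img, (bkgd, dna, gold) = self._entry(0)
        path = tmp_path / "doses.csv"
        rows = pt.dose_series_report([(88.0, img), (45.0, img), (26.0, img)],
                                     bkgd, dna, gold, csv_path=path)
        assert len(rows) == 3
        assert path.exists()
        header = path.read_text().splitlines()[0]
        assert "contrast_ratio" in header

    def test_needs_two_entries(self):
        img, (bkgd, dna, gold) = self._entry(0)
        with pytest.raises(MetricsError):
            pt.dose_series_report([(88.0, img)], bkgd, dna, gold)
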