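"""Immunofluorescence quantification pipeline tests."""

import numpy as np
import pandas as pd
import pytest

from probemech import histology_quant as hq
from probemech import synthetic_data as sd


@pytest.fixture(scope="module")
def clean_image():
    """Noise-free synthetic image with known amplitude and decay length."""
    gt = sd.IHCGroundTruth(amplitude=2.0, decay_um=120.0, noise_sd=0.0, seed=1)
    img, rec = sd.generate_ihc_image(gt)
    return img, rec


@pytest.fixture(scope="module")
def noisy_image():
    gt = sd.IHCGroundTruth(amplitude=2.0, decay_um=120.0, noise_sd=100.0, seed=2)
    img, rec = sd.generate_ihc_image(gt)
    return img, rec


class TestRoiBands:
    def test_pixel_dimensions_at_unit_pixel_size(self):
        data = np.full((2000, 4000), 1000, dtype=np.uint16)
        img = hq.FluorescenceImage(data=data, pixel_size=1.0,
                                   tip_center=(1500, 2000))
        bands = hq.define_roi_bands(img)
        assert len(bands) == hq.N_BANDS
        b = bands[0]
        assert (b.row1 - b.row0, b.col1 - b.col0) == (50, 2348)

    def test_bands_tile_500_um_above_tip(self, clean_image):
        img, _ = clean_image
        bands = hq.define_roi_bands(img)
        rows = sorted((b.row0, b.row1) for b in bands)
        # contiguous, non-overlapping, ending at the tip row
        for (a0, a1), (b0, b1) in zip(rows[:-1], rows[1:]):
            assert a1 == b0
        total = rows[-1][1] - rows[0][0]
        assert total * img.pixel_size == pytest.approx(500.0)
        assert rows[-1][1] == img.tip_center[0]

    def test_pixel_size_scales_band_extent(self):
        data = np.full((2000, 4000), 1000, dtype=np.uint16)
        img = hq.FluorescenceImage(data=data, pixel_size=2.0,
                                   tip_center=(1500, 2000))
        b = hq.define_roi_bands(img)[0]
        assert (b.row1 - b.row0, b.col1 - b.col0) == (25, 1174)

    def test_insufficient_extent_rejected(self):
        data = np.full((100, 4000), 1000, dtype=np.uint16)
        img = hq.FluorescenceImage(data=data, pixel_size=1.0,
                                   tip_center=(80, 2000))
        with pytest.raises(ValueError):
            hq.define_roi_bands(img)


class TestProbeDetection:
    def test_track_width_recovered(self, clean_image):
        img, rec = clean_image
        band = hq.define_roi_bands(img)[0].extract(img.data)
        i0, i1 = hq.detect_probe_region(band)
        width_um = (i1 - i0 + 1) * img.pixel_size
        assert width_um == pytest.approx(rec["track_width_um"],
                                         abs=2 * img.pixel_size)

    def test_track_position_matches_ground_truth(self, noisy_image):
        img, rec = noisy_image
        bands = hq.define_roi_bands(img)
        band = bands[3]
        i0, i1 = hq.detect_probe_region(band.extract(img.data))
        center_px = band.col0 + (i0 + i1) / 2
        assert center_px == pytest.approx(rec["tip_center"][1], abs=2)

    def test_uniform_band_raises(self):
        band = np.full((25, 1174), 2000.0)
        with pytest.raises(hq.ProbeDetectionError):
            hq.detect_probe_region(band)


class TestBandProfiles:
    def test_constant_band_gives_flat_profiles(self):
        band = np.full((25, 400), 1500.0)
        band[:, 180:220] = 0.0
        left, right = hq.band_profile(band, (180, 219), pixel_size=2.0)
        assert np.allclose(left.intensity, 1500.0)
        assert np.allclose(right.intensity, 1500.0)
        assert left.distance[0] == pytest.approx(1.0)  # half-pixel offset
        assert np.all(np.diff(left.distance) > 0)

    def test_column_mean_equals_bruteforce(self):
        rng = np.random.default_rng(0)
        band = rng.uniform(0, 4000, size=(25, 300))
        left, right = hq.band_profile(band, (140, 160), pixel_size=1.0)
        expected_left = band[:, :140].mean(axis=0)[::-1]
        np.testing.assert_allclose(left.intensity, expected_left)
        expected_right = band[:, 161:].mean(axis=0)
        np.testing.assert_allclose(right.intensity, expected_right)

    def test_mirror_symmetric_band_gives_identical_sides(self):
        rng = np.random.default_rng(4)
        half = rng.uniform(0, 4000, size=(25, 150))
        track = np.zeros((25, 20))
        band = np.hstack([half[:, ::-1], track, half])
        left, right = hq.band_profile(band, (150, 169), pixel_size=1.0)
        np.testing.assert_allclose(left.intensity, right.intensity)
        np.testing.assert_allclose(left.distance, right.distance)


class TestAveragingAndBinning:
    def _profile(self, d, v):
        return hq.IntensityProfile(distance=np.asarray(d, float),
                                   intensity=np.asarray(v, float))

    def test_identical_bands_average_to_single_band(self):
        d = np.arange(0.5, 100, 1.0)
        v = 1000 + 10 * d
        pairs = [(self._profile(d, v), self._profile(d, v))] * 5
        avg = hq.side_and_band_average(pairs)
        np.testing.assert_allclose(
            avg.intensity, np.interp(avg.distance, d, v)
        )

    def test_two_constant_bands_average_to_midpoint(self):
        d = np.arange(0.5, 50, 1.0)
        pairs = [
            (self._profile(d, np.full_like(d, 100.0)),
             self._profile(d, np.full_like(d, 100.0))),
            (self._profile(d, np.full_like(d, 300.0)),
             self._profile(d, np.full_like(d, 300.0))),
        ]
        avg = hq.side_and_band_average(pairs)
        np.testing.assert_allclose(avg.intensity, 200.0)

    def test_nested_mean_matches_bruteforce(self):
        rng = np.random.default_rng(9)
        d = np.arange(0.5, 80, 1.0)
        pairs = []
        vals = []
        for _ in range(4):
            a, b = rng.uniform(500, 1500, (2, len(d)))
            pairs.append((self._profile(d, a), self._profile(d, b)))
            vals.append(0.5 * (a + b))
        avg = hq.side_and_band_average(pairs, grid=d)
        np.testing.assert_allclose(avg.intensity, np.mean(vals, axis=0))

    def test_no_valid_bands_rejected(self):
        with pytest.raises(ValueError):
            hq.side_and_band_average([])

    def test_background_normalization(self):
        d = np.arange(0.5, 800, 1.0)
        v = np.where(d < 300, 2.0, 1.0) * 1200.0
        prof = hq.normalize_background(self._profile(d, v))
        assert prof.normalized
        assert prof.intensity[0] == pytest.approx(2.0)
        assert prof.intensity[-1] == pytest.approx(1.0)
        flat = hq.normalize_background(self._profile(d, np.full_like(d, 700.0)))
        np.testing.assert_allclose(flat.intensity, 1.0)

    def test_normalization_requires_background_data(self):
        d = np.arange(0.5, 300, 1.0)
        with pytest.raises(ValueError):
            hq.normalize_background(self._profile(d, np.ones_like(d)))

    def test_linear_ramp_bins_at_midpoints(self):
        d = np.arange(0.25, 500, 0.5)
        prof = self._profile(d, 2.0 * d)  # intensity = 2 x distance
        binned = hq.bin_profile(prof)
        mids = np.arange(25.0, 500, 50.0)
        np.testing.assert_allclose(binned.values, 2.0 * mids, rtol=1e-12)

    def test_constant_profile_bins_to_ones(self):
        d = np.arange(0.5, 520, 1.0)
        binned = hq.bin_profile(self._profile(d, np.ones_like(d)))
        np.testing.assert_allclose(binned.values, 1.0)
        assert len(binned.values) == 10

    def test_binning_equals_masked_average(self):
        rng = np.random.default_rng(21)
        d = np.sort(rng.uniform(0, 520, 600))
        v = rng.uniform(0.5, 2.0, 600)
        binned = hq.bin_profile(self._profile(d, v))
        for i in range(10):
            m = (d >= 50.0 * i) & (d < 50.0 * (i + 1))
            assert binned.values[i] == pytest.approx(v[m].mean())


class TestMeanRegionIntensity:
    def test_constant_image(self, clean_image):
        data = np.full((1500, 3000), 1234, dtype=np.uint16)
        img = hq.FluorescenceImage(data=data, pixel_size=2.0,
                                   tip_center=(1100, 1500))
        assert hq.mean_region_intensity(img) == pytest.approx(1234.0)

    def test_equals_bruteforce_pixel_mean(self, noisy_image):
        img, _ = noisy_image
        trow, tcol = img.tip_center
        px = img.pixel_size
        r0, r1 = trow - int(550 / px), trow + int(200 / px)
        c0 = tcol - int(1000 / px) // 2
        c1 = c0 + int(1000 / px)
        expected = img.data[r0:r1, c0:c1].mean()
        assert hq.mean_region_intensity(img) == pytest.approx(expected)

    def test_shifting_tip_moves_the_mask(self):
        rng = np.random.default_rng(6)
        data = rng.integers(0, 4000, size=(1500, 3000)).astype(np.uint16)
        img = hq.FluorescenceImage(data=data, pixel_size=2.0)
        a = hq.mean_region_intensity(img, tip_center=(1000, 1500))
        b = hq.mean_region_intensity(img, tip_center=(1050, 1500))
        px = 2.0
        r0 = 1050 - int(550 / px)
        r1 = 1050 + int(200 / px)
        c0 = 1500 - int(1000 / px) // 2
        expected = data[r0:r1, c0:c0 + int(1000 / px)].mean()
        assert b == pytest.approx(expected)
        assert a != b

    def test_out_of_bounds_rejected(self):
        img = hq.FluorescenceImage(
            data=np.zeros((300, 300), dtype=np.uint16), pixel_size=2.0,
            tip_center=(100, 150),
        )
        with pytest.raises(ValueError):
            hq.mean_region_intensity(img)


class TestGroupStats:
    def test_identical_groups_flagged_degenerate(self):
        groups = {m: np.full(4, 5.0) for m in ("a", "b", "c")}
        anova, tukey = hq.group_stats_oneway(groups)
        assert bool(anova["degenerate"].iloc[0])
        assert anova["F"].iloc[0] == 0.0

    def test_f_statistic_matches_textbook_formula(self):
        groups = {"a": np.array([1.0, 2.0, 3.0]), "b": np.array([4.0, 6.0, 8.0])}
        anova, _ = hq.group_stats_oneway(groups)
        # hand computation: grand mean 4, SSB = 3*(2-4)^2 + 3*(6-4)^2 = 24
        # SSW = 2 + 8 = 10, F = (24/1)/(10/4) = 9.6
        assert anova["F"].iloc[0] == pytest.approx(9.6)

    def test_separated_groups_all_tukey_significant(self):
        rng = np.random.default_rng(0)
        groups = {
            "steel": 10.0 + 0.01 * rng.normal(size=5),
            "PC": 5.0 + 0.01 * rng.normal(size=5),
            "hydrogel": 1.0 + 0.01 * rng.normal(size=5),
        }
        _, tukey = hq.group_stats_oneway(groups)
        assert tukey["reject"].astype(bool).all()

    def test_insufficient_replication_rejected(self):
        with pytest.raises(ValueError):
            hq.group_stats_oneway({"a": [1.0], "b": [2.0]})

    def test_twoway_detects_material_effect_in_near_bins_only(self):
        rng = np.random.default_rng(5)
        rows = []
        for material, amp in (("steel", 1.0), ("hydrogel", 0.0)):
            for rep in range(6):
                for b in range(1, 11):
                    mu = 1.0 + (amp if b == 1 else 0.0)
                    rows.append(
                        dict(material=material, bin=b, replicate=rep,
                             intensity=mu + 0.05 * rng.normal())
                    )
        df = pd.DataFrame(rows)
        anova, per_bin = hq.group_stats_twoway(df)
        assert anova.loc["C(material):C(bin)", "PR(>F)"] < 0.01
        assert (per_bin[1]["reject"].astype(bool)).all()
        for b in range(5, 11):
            assert not per_bin[b]["reject"].astype(bool).any()

    def test_twoway_null_controls_type_I(self):
        rng = np.random.default_rng(7)
        hits = 0
        n_sim = 40
        for _ in range(n_sim):
            rows = [
                dict(material=m, bin=b, replicate=r,
                     intensity=1.0 + 0.1 * rng.normal())
                for m in ("a", "b") for b in range(1, 6) for r in range(4)
            ]
            anova, _ = hq.group_stats_twoway(pd.DataFrame(rows))
            if anova.loc["C(material)", "PR(>F)"] < 0.05:
                hits += 1
        assert hits / n_sim <= 0.20  # ~5% nominal; generous binomial margin

    def test_empty_cells_rejected(self):
        df = pd.DataFrame(
            [dict(material="a", bin=1, replicate=0, intensity=1.0),
             dict(material="a", bin=2, replicate=0, intensity=1.0),
             dict(material="b", bin=1, replicate=0, intensity=1.0)]
        )
        with pytest.raises(ValueError):
            hq.group_stats_twoway(df)


class TestOverlay:
    def test_identical_curves_agree_trivially(self):
        d = np.linspace(0, 500, 51)
        prof = {m: (d, np.exp(-d / 100) * a)
                for a, m in zip((4, 3, 2, 1), ("steel", "silica", "PC", "hydrogel"))}
        out = hq.overlay_with_strain(prof, prof)
        assert out["ordering_agrees"]
        assert out["intensity_order"] == ["steel", "silica", "PC", "hydrogel"]
        for m in prof:
            assert out["intensity"][m].min() == pytest.approx(0.0)
            assert out["intensity"][m].max() == pytest.approx(1.0)

    def test_reversed_ordering_reported_as_disagreement(self):
        d = np.linspace(0, 500, 51)
        amps = dict(steel=4.0, silica=3.0, PC=2.0, hydrogel=1.0)
        intensity = {m: (d, a * np.exp(-d / 100)) for m, a in amps.items()}
        strain = {m: (d, (5 - a) * np.exp(-d / 100)) for m, a in amps.items()}
        out = hq.overlay_with_strain(intensity, strain)
        assert not out["ordering_agrees"]
        assert out["strain_order"] == list(reversed(out["intensity_order"]))

    def test_mismatched_material_sets_rejected(self):
        d = np.linspace(0, 500, 11)
        with pytest.raises(ValueError):
            hq.overlay_with_strain(
                {"steel": (d, d)}, {"hydrogel": (d, d)}
            )


class TestImagePipeline:
    def test_zero_amplitude_normalizes_to_unity(self):
        gt = sd.IHCGroundTruth(amplitude=0.0, noise_sd=50.0, seed=3)
        img, _ = sd.generate_ihc_image(gt)
        norm, binned = hq.image_profile(img)
        np.testing.assert_allclose(binned.values, 1.0, atol=0.02)

    def test_noise_free_image_recovers_parameters_exactly(self):
        gt = sd.IHCGroundTruth(amplitude=2.0, decay_um=120.0, noise_sd=0.0,
                               seed=4)
        img, _ = sd.generate_ihc_image(gt)
        norm, binned = hq.image_profile(img)
        # log-linear fit on the excess over background
        m = (norm.distance < 300) & (norm.intensity > 1.02)
        y = np.log(norm.intensity[m] - 1.0)
        slope, icept = np.polyfit(norm.distance[m], y, 1)
        assert -1.0 / slope == pytest.approx(gt.decay_um, rel=0.02)
        assert np.exp(icept) == pytest.approx(gt.amplitude, rel=0.02)

    def test_tiff_roundtrip(self, tmp_path, noisy_image):
        img, _ = noisy_image
        path = tmp_path / "section.tiff"
        img.save(path)
        back = hq.FluorescenceImage.load(path)
        np.testing.assert_array_equal(back.data, img.data)
        assert back.pixel_size == img.pixel_size
        assert back.tip_center == img.tip_center
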