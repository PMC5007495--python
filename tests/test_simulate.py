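import numpy as np
import pytest

from rhdtyper.simulate import (
    DEFAULT_CLASS_COUNTS,
    DEFAULT_INTENSITY_MODELS,
    FieldGeometry,
    NoiseModel,
    PopulationIntensityModel,
    build_default_manifest,
    default_intensity_model,
    draw_peak_targets,
    place_cells,
    psf_window_sum_3x3,
    simulate_image,
    simulate_sample,
)
from rhdtyper.types import AntibodyChannel, RhDLabel


class TestManifest:
    def test_class_counts(self):
        manifest = build_default_manifest(seed=0)
        counts = manifest.class_counts()
        assert counts[RhDLabel.D_POS] == 12
        assert counts[RhDLabel.WEAK_D] == 14
        assert counts[RhDLabel.DEL] == 12
        assert counts[RhDLabel.D_NEG] == 13

    def test_total_is_51(self):
        assert len(build_default_manifest(seed=7).samples) == 51

    def test_images_per_sample_in_range(self):
        manifest = build_default_manifest(seed=3, images_per_sample_range=(11, 15))
        assert all(11 <= e.images_per_sample <= 15 for e in manifest.samples)

    def test_unique_ids_and_determinism(self):
        m1 = build_default_manifest(seed=5)
        m2 = build_default_manifest(seed=5)
        assert [e.seed for e in m1.samples] == [e.seed for e in m2.samples]
        assert len({e.sample_id for e in m1.samples}) == 51


class TestModels:
    def test_photon_conversion(self):
        assert NoiseModel().counts_to_photons(1.0) == pytest.approx(0.3)

    def test_default_calibration_present_for_all_pairs(self):
        for label in RhDLabel:
            for channel in AntibodyChannel:
                m = default_intensity_model(label, channel)
                assert m.sd_peak_intensity > 0

    def test_h41_dpos_calibration(self):
        m = DEFAULT_INTENSITY_MODELS[(RhDLabel.D_POS, AntibodyChannel.H41)]
        assert m.mean_peak_intensity == pytest.approx(11.7e3)
        assert m.sd_peak_intensity == pytest.approx(4.0e3)

    def test_labelled_fractions(self):
        h41 = AntibodyChannel.H41
        assert default_intensity_model(RhDLabel.D_POS, h41).labelled_fraction == 1.0
        assert default_intensity_model(RhDLabel.WEAK_D, h41).labelled_fraction == 1.0
        assert default_intensity_model(RhDLabel.DEL, h41).labelled_fraction == pytest.approx(0.10)
        assert default_intensity_model(RhDLabel.D_NEG, h41).labelled_fraction == pytest.approx(0.01)

    def test_invalid_models_rejected(self):
        with pytest.raises(ValueError):
            PopulationIntensityModel(1e3, -1.0, 0.5, 1.0)
        with pytest.raises(ValueError):
            PopulationIntensityModel(1e3, 1.0, 1.5, 1.0)
        with pytest.raises(ValueError):
            PopulationIntensityModel(1e3, 1.0, 0.5, -2.0)
        with pytest.raises(ValueError):
            NoiseModel(background_sd=0.0)

    def test_field_width(self):
        geo = FieldGeometry()
        assert geo.width_px == 512
        assert geo.field_width_um == pytest.approx(81.92)


class TestPeakTargets:
    def test_truncation_floor(self, rng, noise):
        model = default_intensity_model(RhDLabel.DEL, AntibodyChannel.H41)
        targets = draw_peak_targets(model, noise, 5000, rng)
        assert (targets >= noise.min_peak_sum).all()

    @pytest.mark.parametrize("label", list(RhDLabel))
    @pytest.mark.parametrize("channel", list(AntibodyChannel))
    def test_mean_roundtrip_within_2pct(self, label, channel, noise):
        # truncation at the default background shifts the mean by < 2%
        rng = np.random.default_rng(hash((label, channel)) % 2**31)
        model = default_intensity_model(label, channel)
        targets = draw_peak_targets(model, noise, 20000, rng)
        assert targets.mean() == pytest.approx(model.mean_peak_intensity, rel=0.02)


class TestPlaceCells:
    def test_minimum_separation(self, fast_geometry, rng):
        cells = place_cells(fast_geometry, 8, 2, rng)
        min_sep = 1.5 * fast_geometry.cell_radius_mean_px
        for i, a in enumerate(cells):
            for b in cells[i + 1 :]:
                assert np.hypot(a.row - b.row, a.col - b.col) >= min_sep

    def test_edge_cells_cross_border(self, fast_geometry, rng):
        cells = place_cells(fast_geometry, 0, 4, rng)
        h, w = fast_geometry.height_px, fast_geometry.width_px
        for c in cells:
            assert c.touches_edge
            assert (
                c.row - c.radius < 0
                or c.row + c.radius > h - 1
                or c.col - c.radius < 0
                or c.col + c.radius > w - 1
            )

    def test_too_small_field_fails(self, rng):
        geo = FieldGeometry(width_px=16, height_px=16, cell_radius_mean_px=23)
        with pytest.raises(ValueError):
            place_cells(geo, 1, 0, rng)


class TestSimulateImage:
    def test_stack_layout(self, fast_geometry, rng):
        stack, _ = simulate_image(
            RhDLabel.WEAK_D, AntibodyChannel.H41, fast_geometry, rng=rng
        )
        assert stack.n_bright_field == fast_geometry.n_bright_field_frames
        assert stack.n_fluorescence == fast_geometry.n_fluorescence_frames
        assert stack.frames.dtype == np.uint16

    def test_zero_labelled_fraction_means_no_peaks(self, fast_geometry, rng):
        model = PopulationIntensityModel(6e3, 1e3, 0.0, 5.0)
        _, truth = simulate_image(
            RhDLabel.D_NEG,
            AntibodyChannel.H41,
            fast_geometry,
            intensity_model=model,
            rng=rng,
        )
        assert truth.true_peaks == []

    def test_dpos_every_cell_has_a_peak(self, fast_geometry, rng):
        _, truth = simulate_image(
            RhDLabel.D_POS, AntibodyChannel.H41, fast_geometry, rng=rng
        )
        with_peaks = {p.cell_id for p in truth.true_peaks}
        for cell in truth.cells:
            if not cell.touches_edge:
                assert cell.cell_id in with_peaks

    def test_peaks_inside_their_cell(self, fast_geometry, rng):
        _, truth = simulate_image(
            RhDLabel.D_POS, AntibodyChannel.H41, fast_geometry, rng=rng
        )
        cells = {c.cell_id: c for c in truth.cells}
        for p in truth.true_peaks:
            c = cells[p.cell_id]
            assert np.hypot(p.row - c.row, p.col - c.col) <= c.radius + 1e-9
            assert p.true_3x3_sum_counts >= 0

    def test_del_labelled_fraction(self, fast_geometry):
        rng = np.random.default_rng(0)
        labelled = total = 0
        while total < 200:
            _, truth = simulate_image(
                RhDLabel.DEL, AntibodyChannel.H41, fast_geometry, rng=rng
            )
            labelled += sum(c.is_labelled for c in truth.cells)
            total += len(truth.cells)
        assert 0.05 <= labelled / total <= 0.16

    def test_dneg_labelled_fraction(self, fast_geometry):
        rng = np.random.default_rng(1)
        labelled = total = 0
        while total < 1000:
            _, truth = simulate_image(
                RhDLabel.D_NEG, AntibodyChannel.H41, fast_geometry, rng=rng
            )
            labelled += sum(c.is_labelled for c in truth.cells)
            total += len(truth.cells)
        assert 0.002 <= labelled / total <= 0.025

    def test_negative_rate_fails(self, fast_geometry, rng):
        with pytest.raises(ValueError):
            simulate_image(
                RhDLabel.DEL,
                AntibodyChannel.H41,
                fast_geometry,
                intensity_model=PopulationIntensityModel(6e3, 1e3, 0.1, -1.0),
                rng=rng,
            )


class TestSimulateSample:
    def _entry(self, n_images=2, seed=99):
        from rhdtyper.simulate import ManifestEntry

        return ManifestEntry("s0", RhDLabel.WEAK_D, AntibodyChannel.H41, n_images, seed)

    def test_deterministic(self, fast_geometry):
        a = simulate_sample(self._entry(), fast_geometry)
        b = simulate_sample(self._entry(), fast_geometry)
        for (sa, _), (sb, _) in zip(a.images, b.images):
            np.testing.assert_array_equal(sa.frames, sb.frames)

    def test_image_count(self, fast_geometry):
        ds = simulate_sample(self._entry(n_images=4), fast_geometry)
        assert len(ds.images) == 4

    def test_expected_cells_per_sample(self, fast_geometry):
        # 13 images x 8.8 cells/image ~ 114 expected cells per sample
        from rhdtyper.simulate import ManifestEntry

        rng = np.random.default_rng(2)
        counts = []
        for seed in rng.integers(0, 2**31 - 1, size=25):
            entry = ManifestEntry(
                "s", RhDLabel.D_NEG, AntibodyChannel.H41, 13, int(seed)
            )
            ds = simulate_sample(entry, fast_geometry)
            counts.append(sum(len(t.cells) for _, t in ds.images))
        assert np.mean(counts) == pytest.approx(13 * 8.8, rel=0.08)


def test_psf_window_sum_reference_value():
    # brute-force evaluation of the 3x3 Gaussian sample sum at sigma=1
    expected = sum(
        np.exp(-(i * i + j * j) / 2.0) for i in (-1, 0, 1) for j in (-1, 0, 1)
    )
    assert psf_window_sum_3x3(1.0) == pytest.approx(expected)
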