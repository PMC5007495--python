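import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from rhdtyper.segmentation import detect_cells
from rhdtyper.simulate import (
    FieldGeometry,
    NoiseModel,
    PopulationIntensityModel,
    simulate_image,
)
from rhdtyper.spots import (
    Peak,
    SpotParams,
    assign_peaks,
    conservative_smooth,
    detect_peaks,
    estimate_snr,
    peak_intensity,
)
from rhdtyper.types import AntibodyChannel, RhDLabel

from conftest import make_fluo_frame


class TestPeakIntensity:
    def test_zero_frame(self):
        assert peak_intensity(np.zeros((5, 5)), 2, 2) == 0.0

    def test_uniform_frame(self):
        assert peak_intensity(np.full((7, 7), 100.0), 3, 3) == pytest.approx(900.0)

    def test_off_frame_window_fails(self):
        frame = np.zeros((5, 5))
        for r, c in [(0, 2), (4, 2), (2, 0), (2, 4)]:
            with pytest.raises(ValueError):
                peak_intensity(frame, r, c)

    @given(
        hnp.arrays(
            dtype=np.float64,
            shape=st.tuples(st.integers(3, 12), st.integers(3, 12)),
            elements=st.floats(0, 1e5, allow_nan=False),
        ),
        st.data(),
    )
    @settings(max_examples=50, deadline=None)
    def test_matches_bruteforce(self, frame, data):
        h, w = frame.shape
        row = data.draw(st.integers(1, h - 2))
        col = data.draw(st.integers(1, w - 2))
        brute = 0.0
        for dr in (-1, 0, 1):
            for dc in (-1, 0, 1):
                brute += frame[row + dr, col + dc]
        assert peak_intensity(frame, row, col) == pytest.approx(brute, rel=1e-12)


class TestConservativeSmooth:
    def test_lonely_spike_clamped(self):
        img = np.zeros((5, 5))
        img[2, 2] = 100.0
        out = conservative_smooth(img, 1)
        assert out[2, 2] == 0.0

    def test_flat_image_unchanged(self):
        img = np.full((6, 6), 7.0)
        np.testing.assert_array_equal(conservative_smooth(img, 1), img)


class TestDetectPeaks:
    def test_blank_frame_false_positive_rate(self, noise):
        rng = np.random.default_rng(4)
        total = 0
        n_frames = 60
        for _ in range(n_frames):
            img = np.clip(
                np.round(rng.normal(noise.background_mean, noise.background_sd, (256, 256))),
                0,
                65535,
            ).astype(np.uint16)
            total += len(detect_peaks(make_fluo_frame(img)))
        assert total / n_frames <= 0.2

    def test_five_isolated_spots_found_exactly(self, noise):
        rng = np.random.default_rng(9)
        img = rng.normal(noise.background_mean, noise.background_sd, (256, 256))
        positions = [(40, 40), (40, 200), (128, 128), (200, 60), (210, 210)]
        amp = 31 * noise.background_sd  # printed-order SNR
        for r, c in positions:
            rr, cc = np.mgrid[r - 4 : r + 5, c - 4 : c + 5]
            img[r - 4 : r + 5, c - 4 : c + 5] += amp * np.exp(
                -((rr - r) ** 2 + (cc - c) ** 2) / 2.0
            )
        peaks = detect_peaks(make_fluo_frame(np.clip(np.round(img), 0, 65535)))
        assert len(peaks) == 5
        for r, c in positions:
            assert any(abs(p.row - r) <= 1 and abs(p.col - c) <= 1 for p in peaks)

    def test_recall_precision_on_simulated_dpos(self, fast_geometry):
        rng = np.random.default_rng(21)
        n_true = n_det = n_match = 0
        for _ in range(12):
            stack, truth = simulate_image(
                RhDLabel.D_POS, AntibodyChannel.H41, fast_geometry, rng=rng
            )
            peaks = detect_peaks(stack.fluorescence(0))
            true_pos = [(p.row, p.col) for p in truth.true_peaks]
            n_true += len(true_pos)
            n_det += len(peaks)
            for p in peaks:
                if any(
                    math.hypot(p.row - r, p.col - c) <= 1.5 for r, c in true_pos
                ):
                    n_match += 1
        assert n_match / n_true >= 0.93
        assert n_match / n_det >= 0.95

    def test_offset_invariance(self, noise):
        rng = np.random.default_rng(3)
        img = rng.normal(noise.background_mean, noise.background_sd, (256, 256))
        for r, c in [(60, 60), (180, 100)]:
            rr, cc = np.mgrid[r - 4 : r + 5, c - 4 : c + 5]
            img[r - 4 : r + 5, c - 4 : c + 5] += 2000 * np.exp(
                -((rr - r) ** 2 + (cc - c) ** 2) / 2.0
            )
        base = detect_peaks(make_fluo_frame(img))
        shifted = detect_peaks(make_fluo_frame(img + 500.0))
        assert {(p.row, p.col) for p in base} == {(p.row, p.col) for p in shifted}

    def test_invariants_of_returned_peaks(self, fast_geometry, rng):
        stack, _ = simulate_image(
            RhDLabel.D_POS, AntibodyChannel.H41, fast_geometry, rng=rng
        )
        frame = stack.fluorescence(0)
        peaks = detect_peaks(frame)
        h, w = frame.shape
        params = SpotParams()
        for i, p in enumerate(peaks):
            assert 1 <= p.row <= h - 2 and 1 <= p.col <= w - 2
            assert p.intensity_counts >= 0
            for q in peaks[i + 1 :]:
                assert (
                    math.hypot(p.row - q.row, p.col - q.col)
                    >= params.min_peak_separation_px
                )


class TestAssignPeaks:
    def _scene(self, fast_geometry, rng):
        stack, truth = simulate_image(
            RhDLabel.D_POS, AntibodyChannel.H41, fast_geometry, rng=rng
        )
        contours = detect_cells(stack.bright_field(0))
        peaks = assign_peaks(detect_peaks(stack.fluorescence(0)), contours)
        return truth, contours, peaks

    def test_peak_at_centroid_assigned(self, fast_geometry, rng):
        _, contours, _ = self._scene(fast_geometry, rng)
        contour = next(c for c in contours if not c.touches_edge)
        peak = Peak(int(contour.centroid[0]), int(contour.centroid[1]), 0.0)
        assign_peaks([peak], contours)
        assert peak.cell_id == contour.cell_id

    def test_background_peak_unassigned(self, fast_geometry, rng):
        _, contours, _ = self._scene(fast_geometry, rng)
        outside = np.ones((512, 512), dtype=bool)
        for c in contours:
            outside &= ~c.mask
        r, c = np.argwhere(outside)[0]
        peak = Peak(int(r), int(c), 0.0)
        assign_peaks([peak], contours)
        assert peak.cell_id is None
        assert peak.excluded_from_features

    def test_assignment_matches_ground_truth(self, fast_geometry):
        rng = np.random.default_rng(31)
        ok = checked = 0
        for _ in range(4):
            truth, contours, peaks = self._scene(fast_geometry, rng)
            true_cells = {c.cell_id: c for c in truth.cells}
            for p in peaks:
                if p.cell_id is None:
                    continue
                true_owner = None
                for tc in true_cells.values():
                    if math.hypot(p.row - tc.row, p.col - tc.col) <= tc.radius:
                        true_owner = tc
                        break
                if true_owner is None:
                    continue
                contour = contours[p.cell_id]
                checked += 1
                dist = math.hypot(
                    contour.centroid[0] - true_owner.row,
                    contour.centroid[1] - true_owner.col,
                )
                if dist < 0.5 * true_owner.radius:
                    ok += 1
        assert checked >= 100
        assert ok / checked >= 0.98


class TestEstimateSnr:
    def test_noiseless_definition(self):
        rng = np.random.default_rng(0)
        sd = 10.0
        img = rng.normal(0.0, sd, (64, 64))
        amp = 500.0
        img[32, 32] += amp
        peak = Peak(32, 32, 0.0)
        result = estimate_snr(img, [peak])
        # median ~ 0, robust SD ~ sd
        assert result.per_peak[0] == pytest.approx(amp / sd, rel=0.25)

    def test_linearity_in_amplitude(self):
        rng = np.random.default_rng(1)
        noise_field = rng.normal(0, 5.0, (64, 64))
        snr = {}
        for amp in (0.0, 300.0, 600.0):
            img = noise_field.copy()
            img[30, 30] += amp
            snr[amp] = estimate_snr(img, [Peak(30, 30, 0.0)]).per_peak[0]
        # background median/SD are identical, so SNR is affine in amplitude
        assert snr[600.0] - snr[0.0] == pytest.approx(
            2 * (snr[300.0] - snr[0.0]), rel=1e-9
        )

    def test_zero_background_sd_fails(self):
        img = np.full((64, 64), 5.0)
        with pytest.raises(ValueError):
            estimate_snr(img, [Peak(32, 32, 0.0)])

    def test_empty_peak_list_fails(self):
        with pytest.raises(ValueError):
            estimate_snr(np.zeros((16, 16)), [])

    def test_simulator_calibration(self, fast_geometry):
        rng = np.random.default_rng(11)
        snrs = []
        for _ in range(4):
            stack, _ = simulate_image(
                RhDLabel.D_POS, AntibodyChannel.H41, fast_geometry, rng=rng
            )
            frame = stack.fluorescence(0)
            snrs.append(estimate_snr(frame, detect_peaks(frame)).per_peak)
        mean = float(np.concatenate(snrs).mean())
        assert 27.0 <= mean <= 35.0


class TestParams:
    def test_threshold_ordering_enforced(self):
        with pytest.raises(ValueError):
            SpotParams(threshold_k=2.0, region_grow_low_k=3.0)
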