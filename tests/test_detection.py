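"""Band-pass filtering, maxima, sub-pixel centroids and per-cell counting."""

import numpy as np
import pytest

from macscount import (
    CellGeometry,
    DetectionConfig,
    MoleculeSet,
    OpticsModel,
    PopulationSpec,
    apply_camera,
    assign_and_count,
    bandpass,
    detect_frame,
    evaluate_detection,
    find_maxima,
    localize,
    render_expected_photons,
    sample_population,
)
from macscount.detect import SpotRecord, truth_mask
from macscount.simulate import CameraModel, ImageFrame

PX_UM = 0.064


def noise_free_spot_image(x_px, y_px, shape=(64, 64), photons=5000.0):
    opt = OpticsModel(
        photons_per_molecule=photons, autofluorescence_density=0.0, extracellular_background=0.0
    )
    mols = [MoleculeSet(0, np.array([[(x_px + 0.5) * PX_UM, (y_px + 0.5) * PX_UM]]))]
    return render_expected_photons([], mols, opt, shape, PX_UM)


class TestBandpass:
    def test_constant_image_zeroed(self, detection):
        out = bandpass(np.full((50, 50), 321.0), detection)
        assert np.allclose(out, 0.0, atol=1e-9)

    def test_broad_background_suppressed(self, detection):
        """Features much wider than sigma_high barely survive the filter."""
        y, x = np.mgrid[0:200, 0:200]
        amp = 100.0
        bg = amp * np.exp(-((x - 100.0) ** 2 + (y - 100.0) ** 2) / (2 * 50.0**2))
        out = bandpass(bg, detection)
        assert out.max() < 0.01 * amp

    def test_spot_survives_at_its_location(self, detection):
        img = noise_free_spot_image(30, 20)
        out = bandpass(img, detection)
        r, c = np.unravel_index(np.argmax(out), out.shape)
        assert abs(r - 20) <= 1 and abs(c - 30) <= 1

    def test_degenerate_sigmas_rejected(self):
        with pytest.raises(ValueError):
            DetectionConfig(sigma_low=2.0, sigma_high=1.0)


class TestFindMaxima:
    def test_blank_image_no_peaks(self, detection):
        assert len(find_maxima(np.zeros((40, 40)), detection)) == 0

    def test_two_separated_spots_two_peaks(self, detection):
        img = noise_free_spot_image(20, 20) + noise_free_spot_image(30, 20)
        out = bandpass(img, detection)
        assert len(find_maxima(out, detection)) == 2

    def test_threshold_above_max_empty(self, detection):
        img = bandpass(noise_free_spot_image(20, 20), detection)
        cfg = DetectionConfig(peak_threshold=img.max() * 2)
        assert len(find_maxima(img, cfg)) == 0

    def test_threshold_monotonicity(self, detection, pressed_cell, camera, rng):
        """Raising the threshold never finds more spots."""
        from macscount import sample_positions

        opt = OpticsModel()
        mols = sample_positions(pressed_cell, 6, rng)
        img = render_expected_photons([pressed_cell], [mols], opt, (80, 80), PX_UM)
        frame = apply_camera(img, camera, rng)
        filtered = bandpass(frame, detection)
        n_prev = np.inf
        for thr in (5.0, 15.0, 30.0, 60.0, 120.0):
            n = len(find_maxima(filtered, DetectionConfig(peak_threshold=thr)))
            assert n <= n_prev
            n_prev = n


class TestLocalize:
    def test_symmetric_spot_exact_centroid(self, detection):
        img = bandpass(noise_free_spot_image(20, 20), detection)
        spots = localize(img, np.array([[20, 20]]), detection)
        assert spots[0].x == pytest.approx(20.0, abs=1e-6)
        assert spots[0].y == pytest.approx(20.0, abs=1e-6)

    def test_subpixel_position_recovered(self, detection):
        img = bandpass(noise_free_spot_image(20.30, 20.00), detection)
        peaks = find_maxima(img, detection)
        spots = localize(img, peaks, detection)
        assert abs(spots[0].x - 20.30) < 0.15
        assert abs(spots[0].y - 20.00) < 0.15

    def test_border_peak_flagged(self, detection):
        img = bandpass(noise_free_spot_image(2, 2), detection)
        spots = localize(img, np.array([[2, 2]]), detection)
        assert spots[0].border_clipped

    def test_translation_invariance(self, detection):
        """Whole-pixel shifts move centroids by exactly the shift."""
        img = noise_free_spot_image(20.3, 21.7, shape=(80, 80))
        f0 = bandpass(img, detection)
        s0 = localize(f0, find_maxima(f0, detection), detection)[0]
        shifted = np.zeros_like(img)
        shifted[5:, 7:] = img[:-5, :-7]
        f1 = bandpass(shifted, detection)
        s1 = localize(f1, find_maxima(f1, detection), detection)[0]
        assert s1.x - s0.x == pytest.approx(7.0, abs=1e-9)
        assert s1.y - s0.y == pytest.approx(5.0, abs=1e-9)


class TestAssignAndCount:
    def make_mask(self):
        mask = np.zeros((40, 40), dtype=np.int32)
        mask[5:15, 5:30] = 1
        mask[25:35, 5:30] = 2
        return mask

    def test_no_spots_all_zero_counts(self):
        table = assign_and_count([], self.make_mask(), PX_UM)
        assert (table["count"] == 0).all()
        assert len(table) == 2

    def test_spots_counted_in_their_cell(self):
        spots = [SpotRecord(0, 10.0, 10.0, 5.0), SpotRecord(0, 20.0, 10.0, 5.0),
                 SpotRecord(0, 25.0, 7.0, 5.0)]
        table = assign_and_count(spots, self.make_mask(), PX_UM)
        assert table.set_index("cell_id")["count"].to_dict() == {0: 3, 1: 0}

    def test_background_spot_unassigned(self):
        spots = [SpotRecord(0, 10.0, 10.0, 5.0), SpotRecord(0, 1.0, 1.0, 5.0)]
        table = assign_and_count(spots, self.make_mask(), PX_UM)
        assert table["count"].sum() == 1
        assert spots[1].cell_id == -1

    def test_border_clipped_excluded(self):
        spots = [SpotRecord(0, 10.0, 10.0, 5.0, border_clipped=True)]
        table = assign_and_count(spots, self.make_mask(), PX_UM)
        assert table["count"].sum() == 0


class TestEvaluateDetection:
    def test_perfect_detection(self):
        truth = np.array([[1.0, 1.0], [2.0, 1.0], [3.0, 1.0], [1.0, 2.0], [2.0, 2.0]])
        spots = [SpotRecord(0, x / PX_UM, y / PX_UM, 1.0) for x, y in truth]
        ev = evaluate_detection(spots, truth, PX_UM)
        assert ev["recall"] == 1.0 and ev["precision"] == 1.0
        assert ev["rmse_nm"] == pytest.approx(0.0, abs=1e-6)

    def test_empty_detection_zero_recall(self):
        ev = evaluate_detection([], np.ones((5, 2)), PX_UM)
        assert ev["recall"] == 0.0

    def test_each_side_matches_once(self):
        truth = np.array([[1.0, 1.0]])
        spots = [SpotRecord(0, 1.0 / PX_UM, 1.0 / PX_UM, 1.0),
                 SpotRecord(0, 1.05 / PX_UM, 1.0 / PX_UM, 1.0)]
        ev = evaluate_detection(spots, truth, PX_UM)
        assert ev["n_matched"] == 1
        assert ev["precision"] == 0.5


class TestEndToEnd:
    def test_well_separated_bright_spots_high_quality(self, bright_optics, camera, rng):
        """Recall and precision >= 0.95 for well-separated spots at SNR >= 5."""
        cell = CellGeometry(length=4.0, width=1.0, center=(3.0, 3.0)).pressed_twin()
        cfg = DetectionConfig()
        n_truth = n_det = n_match = 0
        for _ in range(40):
            # three spots pinned far apart along the cell axis
            xs = np.array([[1.7, 3.0], [3.0, 3.0], [4.3, 3.0]])
            xs = xs + rng.uniform(-0.1, 0.1, size=xs.shape)
            mols = [MoleculeSet(0, xs)]
            img = render_expected_photons([cell], mols, bright_optics, (96, 96), PX_UM)
            frame = apply_camera(img, camera, rng)
            spots, _ = detect_frame(frame, cfg)
            ev = evaluate_detection(spots, xs, PX_UM)
            n_truth += ev["n_truth"]
            n_det += ev["n_detected"]
            n_match += ev["n_matched"]
        assert n_match / n_truth >= 0.95
        assert n_match / n_det >= 0.95

    def test_blank_cells_few_false_positives(self, optics, camera, rng):
        """Unlabelled cells show at most ~1 spurious spot per cell; a
        stricter threshold pushes that below 0.3."""
        spec = PopulationSpec(n_cells=60, copy_number_mean=0.0, seed=3)
        cells, molecules, _ = sample_population(spec, rng)
        from macscount.simulate import grid_shape_for

        shape = grid_shape_for(spec, PX_UM)
        img = render_expected_photons(cells, molecules, optics, shape, PX_UM)
        frame = apply_camera(img, camera, rng)
        for threshold, bound in [(30.0, 1.0), (60.0, 0.3)]:
            spots, _ = detect_frame(frame, DetectionConfig(peak_threshold=threshold))
            per_cell = sum(not s.border_clipped for s in spots) / spec.n_cells
            assert per_cell <= bound

    def test_sparse_counts_match_truth(self, camera, rng):
        """At 3 molecules/cell overlap is negligible: detected mean within
        10% of the true mean."""
        spec = PopulationSpec(n_cells=150, copy_number_mean=3.0, seed=11)
        cells, molecules, truth = sample_population(spec, rng)
        from macscount.simulate import grid_shape_for, render_segmentation_channel

        shape = grid_shape_for(spec, PX_UM)
        opt = OpticsModel(photons_per_molecule=400.0)
        img = render_expected_photons(cells, molecules, opt, shape, PX_UM)
        frame = apply_camera(img, camera, rng)
        mask = truth_mask(cells, shape, PX_UM)
        _, table = detect_frame(frame, DetectionConfig(), mask=mask)
        assert table["count"].mean() == pytest.approx(truth["true_count"].mean(), rel=0.10)
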