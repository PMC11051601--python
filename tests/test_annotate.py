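"""Heuristic calibration and darknet label round trips."""

import numpy as np
import pytest

from holotrack.annotate import (
    Annotation,
    HeuristicCalibration,
    box_size_from_z,
    calibration_pairs,
    fit_heuristic,
    load_calibration,
    make_annotations,
    measure_apparent_radius,
    read_labels,
    save_calibration,
    write_labels,
)
from holotrack.depthmap import z_from_size
from holotrack.reconstruct import Localization3D


class TestFitHeuristic:
    def test_noiseless_line_recovered_to_machine_precision(self):
        z = np.linspace(60.0, 190.0, 12)
        pairs = list(zip(z, 1.2 * z + 15.0))
        cal = fit_heuristic(pairs, offset=0.0)
        assert cal.slope_m == pytest.approx(1.2, abs=1e-12)
        assert cal.intercept_c == pytest.approx(15.0, abs=1e-9)

    def test_out_of_regime_pairs_are_ignored(self):
        z_in = np.linspace(60.0, 190.0, 8)
        in_regime = list(zip(z_in, 1.0 * z_in + 10.0))
        # wildly wrong sizes outside (50, 200] must not perturb the fit
        outliers = [(10.0, 500.0), (30.0, -50.0), (250.0, 3.0)]
        cal_a = fit_heuristic(in_regime)
        cal_b = fit_heuristic(in_regime + outliers)
        assert cal_a.slope_m == cal_b.slope_m
        assert cal_a.intercept_c == cal_b.intercept_c

    def test_noisy_fit_matches_normal_equations_oracle(self, rng):
        z = rng.uniform(55.0, 195.0, size=60)
        sigma = 3.0
        s = 0.9 * z + 20.0 + rng.normal(scale=sigma, size=z.size)
        cal = fit_heuristic(list(zip(z, s)))
        # independent normal-equations solution
        A = np.stack([z, np.ones_like(z)], axis=1)
        slope, intercept = np.linalg.solve(A.T @ A, A.T @ s)
        assert cal.slope_m == pytest.approx(slope, abs=1e-9)
        assert cal.intercept_c == pytest.approx(intercept, abs=1e-9)
        # and the slope is within 3 standard errors of the truth
        se = sigma / np.sqrt(np.sum((z - z.mean()) ** 2))
        assert abs(cal.slope_m - 0.9) < 3 * se

    def test_radii_flag_doubles_sizes(self):
        z = np.linspace(60.0, 190.0, 6)
        cal_r = fit_heuristic(list(zip(z, 0.5 * z + 5.0)), sizes_are_radii=True)
        cal_s = fit_heuristic(list(zip(z, 1.0 * z + 10.0)))
        assert cal_r.slope_m == pytest.approx(cal_s.slope_m)
        assert cal_r.intercept_c == pytest.approx(cal_s.intercept_c)

    def test_too_few_in_regime_pairs_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            fit_heuristic([(60.0, 70.0), (20.0, 30.0), (230.0, 250.0)])

    def test_negative_slope_rejected(self):
        z = np.linspace(60.0, 190.0, 6)
        with pytest.raises(ValueError, match="slope"):
            fit_heuristic(list(zip(z, -0.5 * z + 300.0)))

    def test_nonpositive_intercept_raised_to_min_box(self):
        z = np.linspace(60.0, 190.0, 6)
        cal = fit_heuristic(list(zip(z, 1.0 * z - 30.0)), min_box_px=12.0)
        assert cal.intercept_c == 12.0
        assert box_size_from_z(cal, 0.0) > 0

    def test_offset_shifts_intercept(self):
        z = np.linspace(60.0, 190.0, 6)
        cal = fit_heuristic(list(zip(z, 1.0 * z + 5.0)), offset=7.0)
        assert cal.intercept_c == pytest.approx(12.0)


class TestBoxSize:
    def test_direct_evaluation_and_intercept(self):
        cal = HeuristicCalibration(slope_m=1.0, intercept_c=10.0)
        assert box_size_from_z(cal, 100.0) == pytest.approx(110.0)
        assert box_size_from_z(cal, 0.0) == pytest.approx(10.0)

    def test_strictly_increasing_in_z(self):
        cal = HeuristicCalibration(slope_m=0.8, intercept_c=14.0)
        z = np.linspace(0.0, 280.0, 100)
        assert np.all(np.diff(box_size_from_z(cal, z)) > 0)

    def test_round_trip_with_depth_inverse(self):
        cal = HeuristicCalibration(slope_m=1.3, intercept_c=9.0)
        for z in (0.0, 17.3, 140.0, 275.0):
            assert z_from_size(cal, box_size_from_z(cal, z)) == pytest.approx(z, abs=1e-12)

    def test_invalid_calibration_rejected(self):
        with pytest.raises(ValueError):
            HeuristicCalibration(slope_m=-1.0, intercept_c=10.0)
        with pytest.raises(ValueError):
            HeuristicCalibration(slope_m=1.0, intercept_c=0.0)


class TestMakeAnnotations:
    cal = HeuristicCalibration(slope_m=1.0, intercept_c=14.0)

    def test_centered_cell_normalization(self, optics):
        # box side 64 px at z = 50 with m=1, c=14
        loc = Localization3D(x=256 * optics.pixel_pitch, y=256 * optics.pixel_pitch, z=50.0)
        (ann,) = make_annotations([loc], self.cal, optics)
        assert ann.x_center == pytest.approx(0.5)
        assert ann.y_center == pytest.approx(0.5)
        assert ann.width == pytest.approx(64 / 512)
        assert ann.height == pytest.approx(64 / 512)

    def test_edge_box_clipped_to_rectangle(self, optics):
        loc = Localization3D(x=10 * optics.pixel_pitch, y=256 * optics.pixel_pitch, z=50.0)
        (ann,) = make_annotations([loc], self.cal, optics)
        assert ann.width == pytest.approx((10 + 32) / 512)
        assert ann.height == pytest.approx(64 / 512)

    def test_outside_frame_skipped_with_warning(self, optics):
        loc = Localization3D(x=-100.0, y=100.0, z=50.0)
        with pytest.warns(UserWarning, match="outside"):
            anns = make_annotations([loc], self.cal, optics)
        assert anns == []

    def test_every_ground_truth_cell_yields_one_annotation(self, optics):
        from holotrack.simulate import MotionParams, simulate_scene
        _, tracks = simulate_scene(MotionParams(n_cells=8, n_frames=5, seed=2), optics)
        locs = [
            Localization3D(x=p.x, y=p.y, z=p.z, frame_index=p.frame_index)
            for t in tracks for p in t.points
        ]
        anns = make_annotations(locs, self.cal, optics)
        assert len(anns) == len(locs)


class TestLabelFiles:
    def test_write_read_round_trip(self, tmp_path):
        anns = [
            Annotation(0.5, 0.5, 0.125, 0.125, frame_index=0),
            Annotation(0.25, 0.75, 0.06, 0.043, frame_index=0),
            Annotation(0.9, 0.1, 0.02, 0.02, frame_index=2),
        ]
        write_labels(anns, tmp_path / "labels")
        back = read_labels(tmp_path / "labels")
        assert len(back) == 3
        for a, b in zip(sorted(anns, key=lambda a: (a.frame_index, a.x_center)),
                        sorted(back, key=lambda a: (a.frame_index, a.x_center))):
            assert a.frame_index == b.frame_index
            for f in ("x_center", "y_center", "width", "height"):
                assert getattr(a, f) == pytest.approx(getattr(b, f), abs=1e-6)

    def test_empty_frames_produce_empty_files(self, tmp_path):
        """Frames without cells still get a (empty) label file — the
        negative controls of detector training."""
        paths = write_labels([], tmp_path / "labels", frame_indices=range(3))
        assert len(paths) == 3
        for p in paths:
            assert p.exists() and p.read_text() == ""
        assert read_labels(tmp_path / "labels") == []

    def test_exact_line_format(self, tmp_path):
        d = tmp_path / "labels"
        d.mkdir()
        (d / "frame_000000.txt").write_text("0 0.5 0.5 0.125 0.125\n")
        (ann,) = read_labels(d)
        assert ann.class_id == 0
        assert (ann.x_center, ann.y_center) == (0.5, 0.5)
        assert (ann.width, ann.height) == (0.125, 0.125)

    @pytest.mark.parametrize("line", [
        "0 0.5 0.5 0.125",          # wrong field count
        "0 0.5 0.5 0.125 1.2",      # value outside [0, 1]
        "0 0.5 x 0.125 0.125",      # non-numeric
    ])
    def test_malformed_lines_name_file_and_line(self, tmp_path, line):
        d = tmp_path / "labels"
        d.mkdir()
        (d / "frame_000001.txt").write_text(line + "\n")
        with pytest.raises(ValueError, match=r"frame_000001\.txt:1"):
            read_labels(d)


class TestApparentSize:
    def test_apparent_radius_grows_with_depth(self, optics):
        radii = [measure_apparent_radius(z, optics) for z in (40.0, 80.0, 120.0)]
        assert np.all(np.diff(radii) > 0)

    def test_calibration_from_rendered_sweep_is_linear(self, optics):
        pairs = calibration_pairs(optics, np.arange(60.0, 200.0, 20.0))
        cal = fit_heuristic(pairs, sizes_are_radii=True)
        # geometric NA cone: radius slope = NA/sqrt(n² − NA²) μm/μm
        na, n = optics.numerical_aperture, optics.medium_index
        expected = 2.0 * na / np.sqrt(n**2 - na**2) / optics.pixel_pitch
        assert cal.slope_m == pytest.approx(expected, rel=0.15)


def test_dataset_layout_splits_images_and_labels(tmp_path, rng):
    from holotrack.annotate import write_dataset

    frames = rng.uniform(0.9, 1.1, size=(19, 16, 16))
    anns = [Annotation(0.5, 0.5, 0.1, 0.1, frame_index=i) for i in range(19)]
    splits = write_dataset(frames, anns, tmp_path / "ds", seed=3)
    assert sorted(sum(splits.values(), [])) == list(range(19))
    assert [len(splits[s]) for s in ("train", "val", "test")] == [14, 3, 2]
    for split, idx in splits.items():
        imgs = sorted((tmp_path / "ds" / "images" / split).glob("*.tif"))
        labels = sorted((tmp_path / "ds" / "labels" / split).glob("*.txt"))
        assert [p.stem for p in imgs] == [p.stem for p in labels]
        assert len(imgs) == len(idx)


def test_calibration_json_round_trip(tmp_path):
    cal = HeuristicCalibration(slope_m=1.234, intercept_c=11.5, fit_z_range=(50.0, 200.0))
    save_calibration(cal, tmp_path / "cal.json")
    back = load_calibration(tmp_path / "cal.json")
    assert back == cal
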