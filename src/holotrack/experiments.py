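"""Reusable simulation studies exercising the pipeline end to end.

These drivers define the package's reference study conditions: the
hologram geometry of the default :class:`~holotrack.config.OpticalConfig`
(512×512 px ↔ 360×360 μm, 642 nm illumination through water), weak point
scatterers of amplitude 0.15–0.2, and modest sensor noise.  They are the
basis of the validation suite and of ``scripts/acceptance.py``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from . import annotate, depthmap, detect, evaluate, preprocess, track
from .config import OpticalConfig
from .reconstruct import Localization3D, localize_frame
from .simulate import MotionParams, SceneFrame, Scatterer, render_hologram, simulate_scene

__all__ = [
    "gouy_localization_study",
    "depth_correction_study",
    "end_to_end_study",
]


def gouy_localization_study(
    seed: int,
    n_scatterers: int = 50,
    z_range: tuple[float, float] = (20.0, 250.0),
    dz: float = 2.0,
    noise_sd: float = 0.01,
    amplitude: float = 0.2,
    optics: OpticalConfig | None = None,
) -> dict:
    """Round-trip axial/lateral recovery of isolated point scatterers.

    One scatterer per frame at a uniformly random position (laterally in
    the central 90 % of the field, axially in ``z_range``); each frame
    is rendered, back-propagated onto a Δz-spaced stack spanning the
    chamber, and localized via the Gouy criterion.  Recovery means the
    nearest localization lies within ±dz axially and ±1 px laterally.
    """
    optics = optics or OpticalConfig()
    rng = np.random.default_rng(seed)
    fov_x, fov_y = optics.fov
    z_planes = np.arange(0.0, optics.chamber_depth + 1e-9, dz)
    axial_err, lateral_err_px, recovered = [], [], []
    for i in range(n_scatterers):
        x = rng.uniform(0.05 * fov_x, 0.95 * fov_x)
        y = rng.uniform(0.05 * fov_y, 0.95 * fov_y)
        z = rng.uniform(*z_range)
        scene = SceneFrame(i, [Scatterer(x, y, z, amplitude)])
        frame = render_hologram(scene, optics, noise_sd=noise_sd, rng=rng)
        locs = localize_frame(frame, optics, z_planes, frame_index=i)
        if not locs:
            axial_err.append(np.nan)
            lateral_err_px.append(np.nan)
            recovered.append(False)
            continue
        truth = np.array([x, y, z])
        best = min(locs, key=lambda l: np.linalg.norm(l.as_array() - truth))
        dz_err = best.z - z
        dlat = np.hypot(best.x - x, best.y - y) / optics.pixel_pitch
        axial_err.append(dz_err)
        lateral_err_px.append(dlat)
        recovered.append(abs(dz_err) <= dz and dlat <= 1.0)
    axial = np.asarray(axial_err)
    ok = np.asarray(recovered)
    return {
        "n": n_scatterers,
        "recovered_fraction": float(ok.mean()),
        "mean_axial_error_um": float(np.nanmean(axial)),
        "mean_abs_axial_error_um": float(np.nanmean(np.abs(axial))),
        "axial_errors_um": axial,
        "lateral_errors_px": np.asarray(lateral_err_px),
        "dz": dz,
    }


#: monotone quartic linking a detector's raw depth to the true depth,
#: emulating the smooth systematic box-sizing bias of a trained network
_DISTORTION = (0.0, 1.22, -1.8e-3, 6.0e-6, 1.0e-8)


def distort_z(z_true: np.ndarray) -> np.ndarray:
    """Forward distortion: the raw depth a biased detector would report."""
    # inverse of the quartic _DISTORTION via bisection on [0, 400]
    z_true = np.asarray(z_true, dtype=float)
    lo = np.zeros_like(z_true)
    hi = np.full_like(z_true, 400.0)
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        val = np.polynomial.polynomial.polyval(mid, _DISTORTION)
        lo = np.where(val < z_true, mid, lo)
        hi = np.where(val >= z_true, mid, hi)
    return 0.5 * (lo + hi)


def depth_correction_study(
    seed: int,
    n_repetitions: int = 100,
    n_pairs: int = 60,
    z_range: tuple[float, float] = (10.0, 160.0),
    noise_sd_um: float = 2.0,
) -> dict:
    """Does the 4th-order correction reduce held-out depth error?

    Each repetition draws (z_raw, z_true) pairs from the monotone
    quartic distortion plus Gaussian noise on z_raw, fits the correction
    on half the pairs and compares corrected vs uncorrected RMSE on the
    held-out half.
    """
    rng = np.random.default_rng(seed)
    improved = 0
    rmse_c, rmse_u = [], []
    for _ in range(n_repetitions):
        z_true = rng.uniform(*z_range, size=n_pairs)
        z_raw = distort_z(z_true) + rng.normal(scale=noise_sd_um, size=n_pairs)
        z_raw = np.maximum(z_raw, 0.0)
        half = n_pairs // 2
        corr = depthmap.fit_depth_correction(list(zip(z_raw[:half], z_true[:half])))
        z_corr = depthmap.apply_correction(corr, z_raw[half:]).z
        e_c = float(np.sqrt(np.mean((z_corr - z_true[half:]) ** 2)))
        e_u = float(np.sqrt(np.mean((z_raw[half:] - z_true[half:]) ** 2)))
        rmse_c.append(e_c)
        rmse_u.append(e_u)
        improved += e_c < e_u
    return {
        "n": n_repetitions,
        "improved_fraction": improved / n_repetitions,
        "mean_rmse_corrected_um": float(np.mean(rmse_c)),
        "mean_rmse_uncorrected_um": float(np.mean(rmse_u)),
    }


@dataclass
class EndToEndResult:
    rmse_corrected_um: float
    rmse_uncorrected_um: float
    n_matched_tracks: int
    n_detections: int
    detection_report: evaluate.EvalReport
    calibration: annotate.HeuristicCalibration
    correction: depthmap.DepthCorrection
    tracks_corrected: list = field(default_factory=list)
    ground_truth: list = field(default_factory=list)


def _smooth_artifact(optics: OpticalConfig, rng: np.random.Generator, strength: float = 0.05) -> np.ndarray:
    """Static multiplicative background: smooth pseudo-dust pattern."""
    raw = rng.normal(size=optics.shape)
    sm = ndimage.gaussian_filter(raw, sigma=20)
    sm /= max(np.abs(sm).max(), 1e-12)
    return 1.0 + strength * sm


def end_to_end_study(
    seed: int,
    n_cells: int = 10,
    n_frames: int = 100,
    noise_sd: float = 0.002,
    chamber_depth: float = 150.0,
    score_threshold: float = 0.3,
    max_disp: float = 30.0,
    max_gap: int = 2,
    min_length: int = 5,
    apply_distortion: bool = True,
) -> EndToEndResult:
    """Full pipeline on one simulated video.

    simulate → static-artifact + noise rendering → median normalization
    → heuristic calibration → reference detection → (optional) synthetic
    systematic box distortion → depth correction fitted on the first
    half of the video (validation) → tracking of the second half (test)
    with raw and corrected depths → RMSE against ground truth.

    The chamber is restricted to the depth range over which fringe
    contrast supports box detection, mirroring the practical working
    depth of holographic detectors.
    """
    optics = OpticalConfig(chamber_depth=chamber_depth)
    rng = np.random.default_rng(seed)
    params = MotionParams(n_cells=n_cells, n_frames=n_frames,
                          seed=int(rng.integers(2**31 - 1)))
    scenes, truth_tracks = simulate_scene(params, optics)

    artifact = _smooth_artifact(optics, rng)
    frames = np.stack([
        render_hologram(s, optics, noise_sd=noise_sd,
                        artifact_pattern=artifact, rng=rng)
        for s in scenes
    ])
    background = preprocess.compute_median_background(frames)
    normalized = [preprocess.normalize_frame(f, background).image for f in frames]

    pairs = annotate.calibration_pairs(
        optics, z_values=np.arange(20.0, chamber_depth + 1e-9, 10.0)
    )
    cal = annotate.fit_heuristic(pairs, sizes_are_radii=True)
    bank = detect.TemplateBank(optics, cal)

    detections: list[detect.Detection] = []
    for i, frame in enumerate(normalized):
        detections.extend(
            detect.detect_reference(frame, cal, optics, bank=bank,
                                    score_threshold=score_threshold, frame_index=i)
        )

    # detector quality against ground-truth annotations (undistorted boxes)
    gt_annotations = [
        annotate.make_annotations(
            [Localization3D(x=p.x, y=p.y, z=p.z, frame_index=p.frame_index)
             for p in t.points],
            cal, optics,
        )
        for t in truth_tracks
    ]
    gt_dets = [
        detect.Detection(
            x_center=(a.x_center * optics.frame_width),
            y_center=(a.y_center * optics.frame_height),
            width=a.width * optics.frame_width,
            height=a.height * optics.frame_height,
            confidence=1.0, frame_index=a.frame_index,
        )
        for anns in gt_annotations for a in anns
    ]
    report = evaluate.evaluate_detections(detections, gt_dets,
                                          confidence_threshold=score_threshold)

    # emulate a trained detector's smooth systematic depth bias
    truth_pos = {
        (p.frame_index, t.track_id): (p.x, p.y, p.z)
        for t in truth_tracks for p in t.points
    }
    by_frame_truth: dict[int, list[tuple[float, float, float]]] = {}
    for (f, _), xyz in truth_pos.items():
        by_frame_truth.setdefault(f, []).append(xyz)

    val_pairs: list[tuple[float, float]] = []
    locs_raw: list[Localization3D] = []
    locs_corr_input: list[tuple[detect.Detection, float]] = []
    for d in detections:
        z_raw = depthmap.z_from_box(cal, d)
        if apply_distortion:
            z_raw = float(distort_z(z_raw))
        x_um, y_um = d.x_center * optics.pixel_pitch, d.y_center * optics.pixel_pitch
        if d.frame_index < n_frames // 2:
            cands = by_frame_truth.get(d.frame_index, [])
            if cands:
                arr = np.asarray(cands)
                j = int(np.argmin(np.hypot(arr[:, 0] - x_um, arr[:, 1] - y_um)))
                if np.hypot(arr[j, 0] - x_um, arr[j, 1] - y_um) < 8 * optics.pixel_pitch:
                    val_pairs.append((z_raw, arr[j, 2]))
        else:
            locs_raw.append(Localization3D(x=x_um, y=y_um, z=z_raw,
                                           frame_index=d.frame_index, source="box_proxy"))
            locs_corr_input.append((d, z_raw))

    correction = depthmap.fit_depth_correction(val_pairs)
    locs_corr = [
        Localization3D(
            x=d.x_center * optics.pixel_pitch, y=d.y_center * optics.pixel_pitch,
            z=float(depthmap.apply_correction(correction, z_raw).z),
            frame_index=d.frame_index, source="box_proxy",
        )
        for d, z_raw in locs_corr_input
    ]

    def _rmse(locs: list[Localization3D]) -> tuple[float, int]:
        tracks = track.link(locs, max_disp=max_disp, max_gap=max_gap,
                            min_length=min_length)
        pairs_ = track.match_tracks(tracks, truth_tracks)
        if not pairs_:
            return float("nan"), 0
        vals = [track.track_rmse(p, r) for p, r in pairs_]
        return float(np.mean(vals)), len(pairs_)

    rmse_u, _ = _rmse(locs_raw)
    rmse_c, n_matched = _rmse(locs_corr)
    tracks_c = track.link(locs_corr, max_disp=max_disp, max_gap=max_gap,
                          min_length=min_length)
    return EndToEndResult(
        rmse_corrected_um=rmse_c,
        rmse_uncorrected_um=rmse_u,
        n_matched_tracks=n_matched,
        n_detections=len(detections),
        detection_report=report,
        calibration=cal,
        correction=correction,
        tracks_corrected=tracks_c,
        ground_truth=truth_tracks,
    )
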