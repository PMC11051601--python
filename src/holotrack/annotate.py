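"""Box-size↔depth heuristic calibration and detector label generation.

A defocused point scatterer's ring pattern grows with its distance z
from the focal plane; with a finite-NA objective the apparent extent is
close to linear in z over an intermediate depth range.  A straight line
``side = m·z + c`` fitted in that regime (optionally raised by a
vertical offset so boxes stay positive near the focal plane) converts
classical 3D localizations into square bounding boxes, which are
exported as darknet-style normalized label files for training an object
detector.
"""

from __future__ import annotations

import json
import re
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy import ndimage

from .config import OpticalConfig
from .reconstruct import Localization3D
from .simulate import render_point_contrast

__all__ = [
    "HeuristicCalibration",
    "Annotation",
    "fit_heuristic",
    "box_size_from_z",
    "make_annotations",
    "write_labels",
    "read_labels",
    "measure_apparent_radius",
    "calibration_pairs",
    "write_dataset",
    "save_calibration",
    "load_calibration",
]

#: default regime bounds, μm: the size–depth relation is taken as linear
#: only for z_lo < z ≤ z_hi
INTERMEDIATE_REGIME = (50.0, 200.0)

#: smallest admissible box side at z = 0, px
MIN_BOX_PX = 12.0


@dataclass(frozen=True)
class HeuristicCalibration:
    """Linear box-size↔depth map ``side_px = slope_m · z + intercept_c``.

    ``fit_z_range`` records the intermediate regime the line was fitted
    on; ``near`` (≤ fit_z_range[0]) and ``far`` (> fit_z_range[1])
    depths fall outside the linear regime.
    """

    slope_m: float
    intercept_c: float
    fit_z_range: tuple[float, float] = INTERMEDIATE_REGIME

    def __post_init__(self) -> None:
        if self.slope_m <= 0:
            raise ValueError("slope_m must be positive (boxes grow with depth)")
        if self.intercept_c <= 0:
            raise ValueError("intercept_c must be positive (size(0) > 0)")

    @property
    def regime_near(self) -> float:
        return self.fit_z_range[0]

    @property
    def regime_far(self) -> float:
        return self.fit_z_range[1]


@dataclass(frozen=True)
class Annotation:
    """A darknet-style normalized bounding box: all coordinates in [0, 1]."""

    x_center: float
    y_center: float
    width: float
    height: float
    class_id: int = 0
    frame_index: int = 0

    def __post_init__(self) -> None:
        for name in ("x_center", "y_center", "width", "height"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.width <= 0 or self.height <= 0:
            raise ValueError("box width and height must be positive")

    def corners_px(self, optics: OpticalConfig) -> tuple[float, float, float, float]:
        """(x1, y1, x2, y2) in pixels."""
        w, h = self.width * optics.frame_width, self.height * optics.frame_height
        cx, cy = self.x_center * optics.frame_width, self.y_center * optics.frame_height
        return (cx - w / 2, cy - h / 2, cx + w / 2, cy + h / 2)


def fit_heuristic(
    pairs: Sequence[tuple[float, float]],
    offset: float = 0.0,
    z_range: tuple[float, float] = INTERMEDIATE_REGIME,
    sizes_are_radii: bool = False,
    min_box_px: float = MIN_BOX_PX,
) -> HeuristicCalibration:
    """Least-squares line through (z, apparent size) pairs in the
    intermediate regime.

    Only pairs with ``z_lo < z ≤ z_hi`` enter the fit; the near and far
    regimes are excluded because the size–depth relation flattens there.
    ``offset`` (px) is added to the fitted intercept afterwards — raising
    the line above the conservatively estimated apparent sizes improves
    downstream reconstruction fidelity and keeps box sizes positive at
    the focal plane.  If the offset intercept still is not positive, the
    intercept is raised to ``min_box_px``.  ``sizes_are_radii`` doubles
    the second element of each pair (semi-major-axis measurements) into
    side lengths before fitting.
    """
    z_lo, z_hi = z_range
    data = np.asarray(pairs, dtype=float)
    if data.ndim != 2 or data.shape[1] != 2:
        raise ValueError("pairs must be (z, size) tuples")
    if sizes_are_radii:
        data = data.copy()
        data[:, 1] *= 2.0
    in_regime = (data[:, 0] > z_lo) & (data[:, 0] <= z_hi)
    if in_regime.sum() < 2:
        raise ValueError(
            f"need at least 2 pairs with z in ({z_lo}, {z_hi}] to fit the "
            f"heuristic, got {int(in_regime.sum())}"
        )
    z, s = data[in_regime, 0], data[in_regime, 1]
    slope, intercept = np.polyfit(z, s, 1)
    if slope <= 0:
        raise ValueError(
            f"fitted slope {slope:.4g} px/μm is not positive; data are "
            "inconsistent with a size-grows-with-depth heuristic"
        )
    intercept += offset
    if intercept <= 0:
        intercept = min_box_px
    return HeuristicCalibration(
        slope_m=float(slope), intercept_c=float(intercept), fit_z_range=(z_lo, z_hi)
    )


def box_size_from_z(cal: HeuristicCalibration, z: float | np.ndarray) -> float | np.ndarray:
    """Square box side in px for depth z (μm); positive for all z ≥ 0."""
    return cal.slope_m * z + cal.intercept_c


def make_annotations(
    localizations: Iterable[Localization3D],
    cal: HeuristicCalibration,
    optics: OpticalConfig,
) -> list[Annotation]:
    """Square boxes of side ``box_size_from_z(z)`` centred on each
    localization, clipped to the frame, normalized to [0, 1].

    Localizations entirely outside the frame are skipped with a warning.
    """
    W, H = optics.frame_width, optics.frame_height
    out: list[Annotation] = []
    for loc in localizations:
        s = float(box_size_from_z(cal, loc.z))
        cx, cy = loc.x / optics.pixel_pitch, loc.y / optics.pixel_pitch
        x1, x2 = max(cx - s / 2, 0.0), min(cx + s / 2, float(W))
        y1, y2 = max(cy - s / 2, 0.0), min(cy + s / 2, float(H))
        if x2 <= x1 or y2 <= y1:
            warnings.warn(
                f"localization at ({loc.x:.1f}, {loc.y:.1f}) μm, frame "
                f"{loc.frame_index}, lies outside the frame; skipped",
                stacklevel=2,
            )
            continue
        out.append(
            Annotation(
                x_center=(x1 + x2) / 2 / W,
                y_center=(y1 + y2) / 2 / H,
                width=(x2 - x1) / W,
                height=(y2 - y1) / H,
                class_id=0,
                frame_index=loc.frame_index,
            )
        )
    return out


# ---------------------------------------------------------------------------
# Darknet-style label files

_STEM = "frame_{:06d}"


def _frame_of_stem(stem: str) -> int:
    m = re.search(r"(\d+)$", stem)
    if m is None:
        raise ValueError(f"cannot parse a frame index from file stem {stem!r}")
    return int(m.group(1))


def write_labels(
    annotations: Iterable[Annotation],
    directory: str | Path,
    frame_indices: Iterable[int] | None = None,
) -> list[Path]:
    """One text file per frame, one ``class x y w h`` line per object.

    Coordinates are normalized, 6-decimal fixed precision.  Frames with
    no annotations get an empty file (negative controls), so
    ``frame_indices`` may list frames beyond those present in
    ``annotations``; by default files cover 0..max(frame).
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    anns = list(annotations)
    by_frame: dict[int, list[Annotation]] = {}
    for a in anns:
        by_frame.setdefault(a.frame_index, []).append(a)
    if frame_indices is None:
        frame_indices = range(max(by_frame, default=-1) + 1)
    paths = []
    for f in frame_indices:
        p = directory / (_STEM.format(f) + ".txt")
        lines = [
            f"{a.class_id} {a.x_center:.6f} {a.y_center:.6f} "
            f"{a.width:.6f} {a.height:.6f}"
            for a in by_frame.get(f, [])
        ]
        p.write_text("\n".join(lines) + ("\n" if lines else ""))
        paths.append(p)
    return paths


def read_labels(directory: str | Path) -> list[Annotation]:
    """Parse every ``*.txt`` label file in a directory.

    Malformed lines (wrong field count, values outside [0, 1]) raise a
    :class:`ValueError` naming the file and line number.
    """
    directory = Path(directory)
    out: list[Annotation] = []
    for p in sorted(directory.glob("*.txt")):
        frame = _frame_of_stem(p.stem)
        for i, line in enumerate(p.read_text().splitlines(), start=1):
            if not line.strip():
                continue
            fields = line.split()
            if len(fields) != 5:
                raise ValueError(
                    f"{p}:{i}: expected 5 fields (class x y w h), got {len(fields)}"
                )
            try:
                cls = int(fields[0])
                vals = [float(v) for v in fields[1:]]
            except ValueError as e:
                raise ValueError(f"{p}:{i}: {e}") from None
            if any(not 0.0 <= v <= 1.0 for v in vals):
                raise ValueError(f"{p}:{i}: box values outside [0, 1]: {line!r}")
            try:
                out.append(
                    Annotation(
                        x_center=vals[0], y_center=vals[1],
                        width=vals[2], height=vals[3],
                        class_id=cls, frame_index=frame,
                    )
                )
            except ValueError as e:
                raise ValueError(f"{p}:{i}: {e}") from None
    return out


def write_dataset(
    frames: "np.ndarray",
    annotations: Iterable[Annotation],
    root: str | Path,
    split_fractions: tuple[float, float] = (14 / 19, 3 / 19),
    seed: int = 0,
) -> dict[str, list[int]]:
    """Detector-training dataset layout: ``images/{split}`` TIFFs with
    parallel ``labels/{split}`` files, stems matching.

    Frames are assigned at random to train/val/test; the default
    fractions mirror a 14/3/2 video split.  Returns the frame indices
    per split.
    """
    import tifffile

    root = Path(root)
    frames = np.asarray(frames)
    n = frames.shape[0]
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    n_train = int(round(split_fractions[0] * n))
    n_val = int(round(split_fractions[1] * n))
    splits = {
        "train": sorted(int(i) for i in order[:n_train]),
        "val": sorted(int(i) for i in order[n_train:n_train + n_val]),
        "test": sorted(int(i) for i in order[n_train + n_val:]),
    }
    anns = list(annotations)
    for split, idx in splits.items():
        img_dir = root / "images" / split
        img_dir.mkdir(parents=True, exist_ok=True)
        for i in idx:
            tifffile.imwrite(img_dir / (_STEM.format(i) + ".tif"),
                             frames[i].astype(np.float32))
        write_labels([a for a in anns if a.frame_index in set(idx)],
                     root / "labels" / split, idx)
    return splits


# ---------------------------------------------------------------------------
# Apparent-size measurement (calibration data source)


def measure_apparent_radius(
    z: float,
    optics: OpticalConfig,
    rel_threshold: float = 0.1,
    envelope_px: int = 9,
) -> float:
    """Apparent radius (μm) of a point scatterer's ring pattern at depth z.

    Renders the noise-free pattern through the objective pupil, forms a
    fringe envelope with a local maximum filter, and returns the largest
    radius at which the envelope still exceeds ``rel_threshold`` of its
    peak — the programmatic analogue of drawing an ellipse around the
    pattern where it fades into noise.
    """
    c = np.abs(render_point_contrast(z, optics))
    env = ndimage.maximum_filter(c, size=envelope_px)
    cy, cx = c.shape[0] // 2, c.shape[1] // 2
    prof = env[cy, cx:]
    above = np.nonzero(prof > rel_threshold * prof.max())[0]
    return float(above.max()) * optics.pixel_pitch


def calibration_pairs(
    optics: OpticalConfig,
    z_values: Sequence[float] | None = None,
    rel_threshold: float = 0.1,
) -> list[tuple[float, float]]:
    """(z, apparent radius in px) pairs measured from rendered patterns.

    The radius is returned in pixels so the pairs feed
    :func:`fit_heuristic` with ``sizes_are_radii=True``.
    """
    if z_values is None:
        z_values = np.arange(20.0, min(optics.chamber_depth, 260.0) + 1e-9, 10.0)
    return [
        (float(z), measure_apparent_radius(z, optics, rel_threshold) / optics.pixel_pitch)
        for z in z_values
    ]


# ---------------------------------------------------------------------------
# Persistence


def save_calibration(cal: HeuristicCalibration, path: str | Path) -> None:
    Path(path).write_text(
        json.dumps(
            {
                "slope_m_px_per_um": cal.slope_m,
                "intercept_c_px": cal.intercept_c,
                "fit_z_range_um": list(cal.fit_z_range),
            },
            indent=1,
        )
    )


def load_calibration(path: str | Path) -> HeuristicCalibration:
    d = json.loads(Path(path).read_text())
    return HeuristicCalibration(
        slope_m=d["slope_m_px_per_um"],
        intercept_c=d["intercept_c_px"],
        fit_z_range=tuple(d["fit_z_range_um"]),
    )
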