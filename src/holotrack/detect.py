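"""Per-frame bounding-box detection of scattering patterns.

The pipeline treats the detector as a pluggable boundary: anything that
emits confidence-scored darknet-style boxes (e.g. a trained CNN) can
feed depth mapping and tracking through :func:`load_detections`.  The
built-in reference detector is classical: a bank of rendered ring
templates spanning a grid of depths is correlated with the frame
contrast, and per-scale local maxima become detections whose box side
encodes the template depth through the heuristic calibration.

Because scattering is weak (Rayleigh-Gans), overlapping patterns add
linearly, so the detector scores with a template-normalized matched
filter rather than an image-normalized correlation: a neighbour's
fringes then perturb a cell's score additively instead of deflating it
through the local-variance normalization.  The score is mapped to a
[0, 1] confidence by the response a perfectly matched scatterer of the
maximum single-scattering amplitude would produce.  Templates are
rendered through a *narrower* pupil than the imaging NA so the
correlation uses only comfortably sampled fringes; the imaging pupil of
the default geometry cuts off close to the grid Nyquist frequency, and
fringes there decorrelate under subpixel displacements.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.signal import fftconvolve
from skimage.feature import peak_local_max

from .annotate import HeuristicCalibration, box_size_from_z
from .config import OpticalConfig
from .simulate import render_point_contrast

__all__ = [
    "Detection",
    "TemplateBank",
    "default_z_templates",
    "detect_reference",
    "nms",
    "load_detections",
    "write_detections",
]

#: detection-band numerical aperture: templates keep only fringes well
#: below the grid Nyquist frequency (see module docstring)
DETECTION_NA = 0.3

#: template depth grid, μm: spacing matches the ≈4 μm axial correlation
#: length of the fringe pattern; the upper end matches the depth range
#: over which fringe contrast supports reliable matching
DEFAULT_Z_MIN = 16.0
DEFAULT_Z_MAX = 160.0
DEFAULT_Z_STEP = 4.0

#: reference amplitude defining confidence 1.0 (the largest amplitude
#: compatible with single scattering)
REFERENCE_AMPLITUDE = 0.2

_TEMPLATE_AMPLITUDE = 0.02
_MAX_TEMPLATE_SIDE = 401


@dataclass(frozen=True)
class Detection:
    """A confidence-scored axis-aligned box in pixel coordinates."""

    x_center: float
    y_center: float
    width: float
    height: float
    confidence: float = 1.0
    frame_index: int = 0

    def __post_init__(self) -> None:
        if self.width <= 0 or self.height <= 0:
            raise ValueError("box width and height must be positive")
        if not 0.0 <= self.confidence <= 1.0:
            raise ValueError(f"confidence {self.confidence} outside [0, 1]")

    def corners(self) -> tuple[float, float, float, float]:
        """(x1, y1, x2, y2) in px."""
        return (
            self.x_center - self.width / 2,
            self.y_center - self.height / 2,
            self.x_center + self.width / 2,
            self.y_center + self.height / 2,
        )

    @property
    def longest_edge(self) -> float:
        return max(self.width, self.height)


def default_z_templates() -> np.ndarray:
    return np.arange(DEFAULT_Z_MIN, DEFAULT_Z_MAX + 1e-9, DEFAULT_Z_STEP)


class TemplateBank:
    """Pre-rendered matched-filter kernels, one per template depth.

    Building the bank costs a hologram render per depth; reuse one bank
    across the frames of a video.
    """

    def __init__(
        self,
        optics: OpticalConfig,
        cal: HeuristicCalibration,
        z_templates: Sequence[float] | None = None,
        detection_na: float = DETECTION_NA,
    ) -> None:
        if z_templates is None:
            z_templates = default_z_templates()
        z_templates = np.asarray(z_templates, dtype=float)
        if z_templates.size < 2:
            raise ValueError("need at least 2 template depths")
        self.optics = optics
        self.cal = cal
        self.z_templates = z_templates
        self.detection_na = detection_na
        self._entries: list[tuple[float, float, np.ndarray, float]] = []
        for zt in z_templates:
            side = float(box_size_from_z(cal, zt))
            t = render_point_contrast(
                zt, optics, amplitude=_TEMPLATE_AMPLITUDE, numerical_aperture=detection_na
            )
            cy, cx = t.shape[0] // 2, t.shape[1] // 2
            h = min(int(side) // 2, (_MAX_TEMPLATE_SIDE - 1) // 2, cy, cx)
            t = t[cy - h : cy + h + 1, cx - h : cx + h + 1]
            t = t - t.mean()
            norm = float(np.sqrt((t * t).sum()))
            kern = t[::-1, ::-1] / norm
            conf_scale = _TEMPLATE_AMPLITUDE / (REFERENCE_AMPLITUDE * norm)
            self._entries.append((float(zt), side, kern, conf_scale))

    def __len__(self) -> int:
        return len(self._entries)

    def responses(self, contrast: np.ndarray):
        """Yield (z, box side, confidence map) per template."""
        for zt, side, kern, scale in self._entries:
            yield zt, side, fftconvolve(contrast, kern, mode="same") * scale


def _iou_corners(a: tuple, b: tuple) -> float:
    iw = min(a[2], b[2]) - max(a[0], b[0])
    ih = min(a[3], b[3]) - max(a[1], b[1])
    if iw <= 0 or ih <= 0:
        return 0.0
    inter = iw * ih
    area_a = (a[2] - a[0]) * (a[3] - a[1])
    area_b = (b[2] - b[0]) * (b[3] - b[1])
    return inter / (area_a + area_b - inter)


def nms(detections: Sequence[Detection], iou_threshold: float = 0.45) -> list[Detection]:
    """Greedy non-maximum suppression in descending confidence order.

    A detection is removed if its IoU with any higher-confidence kept
    detection exceeds ``iou_threshold``.  Ties in confidence are broken
    by position so the result is independent of input order.
    """
    if not 0.0 < iou_threshold < 1.0:
        raise ValueError("iou_threshold must lie in (0, 1)")
    ordered = sorted(
        detections, key=lambda d: (-d.confidence, d.x_center, d.y_center, d.width)
    )
    kept: list[Detection] = []
    corners = []
    for d in ordered:
        c = d.corners()
        if all(_iou_corners(c, kc) <= iou_threshold for kc in corners):
            kept.append(d)
            corners.append(c)
    return kept


def detect_reference(
    frame: np.ndarray,
    cal: HeuristicCalibration,
    optics: OpticalConfig,
    z_templates: Sequence[float] | None = None,
    score_threshold: float = 0.3,
    bank: TemplateBank | None = None,
    nms_iou: float = 0.45,
    min_distance: int = 5,
    frame_index: int = 0,
) -> list[Detection]:
    """Detect scattering patterns in a normalized frame.

    Per template depth, local maxima of the matched-filter confidence
    map above ``score_threshold`` become candidate detections with
    square box side ``box_size_from_z(cal, z_template)``; candidates are
    merged across scales by :func:`nms`.
    """
    frame = np.asarray(frame, dtype=float)
    if frame.shape != optics.shape:
        raise ValueError("frame geometry does not match optics")
    if bank is None:
        bank = TemplateBank(optics, cal, z_templates)
    contrast = frame - 1.0
    candidates: list[Detection] = []
    for zt, side, conf_map in bank.responses(contrast):
        peaks = peak_local_max(
            conf_map, min_distance=min_distance, threshold_abs=score_threshold
        )
        for py, px in peaks:
            candidates.append(
                Detection(
                    x_center=float(px),
                    y_center=float(py),
                    width=side,
                    height=side,
                    confidence=min(float(conf_map[py, px]), 1.0),
                    frame_index=frame_index,
                )
            )
    return nms(candidates, nms_iou)


# ---------------------------------------------------------------------------
# Darknet-style detection files (optional 6th confidence column)


def write_detections(
    detections: Sequence[Detection],
    directory: str | Path,
    optics: OpticalConfig,
    frame_indices: Sequence[int] | None = None,
) -> list[Path]:
    """One file per frame: ``class x y w h confidence`` (normalized)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    W, H = float(optics.frame_width), float(optics.frame_height)
    by_frame: dict[int, list[Detection]] = {}
    for d in detections:
        by_frame.setdefault(d.frame_index, []).append(d)
    if frame_indices is None:
        frame_indices = range(max(by_frame, default=-1) + 1)
    paths = []
    for f in frame_indices:
        p = directory / f"frame_{f:06d}.txt"
        lines = [
            f"0 {d.x_center / W:.6f} {d.y_center / H:.6f} "
            f"{d.width / W:.6f} {d.height / H:.6f} {d.confidence:.6f}"
            for d in by_frame.get(f, [])
        ]
        p.write_text("\n".join(lines) + ("\n" if lines else ""))
        paths.append(p)
    return paths


def load_detections(directory: str | Path, optics: OpticalConfig) -> list[Detection]:
    """Parse darknet-style files into pixel-space detections.

    The 6th (confidence) field is optional and defaults to 1.0.
    Malformed lines or out-of-range values raise :class:`ValueError`
    naming the file and line.
    """
    directory = Path(directory)
    W, H = float(optics.frame_width), float(optics.frame_height)
    out: list[Detection] = []
    for p in sorted(directory.glob("*.txt")):
        m = re.search(r"(\d+)$", p.stem)
        if m is None:
            raise ValueError(f"cannot parse a frame index from {p.name!r}")
        frame = int(m.group(1))
        for i, line in enumerate(p.read_text().splitlines(), start=1):
            if not line.strip():
                continue
            fields = line.split()
            if len(fields) not in (5, 6):
                raise ValueError(f"{p}:{i}: expected 5 or 6 fields, got {len(fields)}")
            try:
                vals = [float(v) for v in fields[1:]]
            except ValueError as e:
                raise ValueError(f"{p}:{i}: {e}") from None
            if any(not 0.0 <= v <= 1.0 for v in vals):
                raise ValueError(f"{p}:{i}: value outside [0, 1]: {line!r}")
            conf = vals[4] if len(vals) == 5 else 1.0
            out.append(
                Detection(
                    x_center=vals[0] * W,
                    y_center=vals[1] * H,
                    width=vals[2] * W,
                    height=vals[3] * H,
                    confidence=conf,
                    frame_index=frame,
                )
            )
    return out
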