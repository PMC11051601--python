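"""Median-image background estimation and per-frame normalization.

Static artifacts (dust on optics, fixed-pattern diffraction, uneven
illumination) survive in every frame of a holographic video, while
swimming cells do not stay put: the per-pixel median over frames
therefore estimates the static background, and dividing each frame by it
leaves the cells' diffraction rings on a background of 1.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np

__all__ = ["MedianBackground", "NormalizedFrame", "compute_median_background", "normalize_frame"]

#: background pixels below this fraction of the median image's own
#: median are clamped before division (dead-pixel guard)
BACKGROUND_FLOOR_FRAC = 1e-6


@dataclass
class MedianBackground:
    """Per-pixel median intensity over the frames of a video."""

    image: np.ndarray
    n_source_frames: int

    def __post_init__(self) -> None:
        self.image = np.asarray(self.image, dtype=float)
        if self.image.ndim != 2:
            raise ValueError("background must be a 2D image")


class NormalizedFrame(NamedTuple):
    """A background-divided frame plus the count of floored background
    pixels (pixels where the background had to be clamped)."""

    image: np.ndarray
    n_floored: int


def compute_median_background(frames: Sequence[np.ndarray] | np.ndarray) -> MedianBackground:
    """Per-pixel median over ≥ 3 identically shaped frames."""
    stack = np.asarray(frames, dtype=float)
    if stack.ndim != 3:
        raise ValueError("frames must be a sequence of 2D images of one geometry")
    if stack.shape[0] < 3:
        raise ValueError(
            f"median background needs at least 3 frames, got {stack.shape[0]}"
        )
    return MedianBackground(
        image=np.median(stack, axis=0), n_source_frames=stack.shape[0]
    )


def normalize_frame(
    frame: np.ndarray,
    background: MedianBackground,
    floor_frac: float = BACKGROUND_FLOOR_FRAC,
) -> NormalizedFrame:
    """Divide a frame pixelwise by the median background.

    Background pixels below ``floor_frac`` × median(background) are
    clamped to that floor before the division so dead pixels cannot blow
    up the ratio; the number of clamped pixels is reported alongside the
    image.
    """
    frame = np.asarray(frame, dtype=float)
    bg = background.image
    if frame.shape != bg.shape:
        raise ValueError(
            f"frame geometry {frame.shape} does not match background {bg.shape}"
        )
    floor = floor_frac * max(float(np.median(bg)), np.finfo(float).tiny)
    floored = bg < floor
    safe_bg = np.where(floored, floor, bg)
    return NormalizedFrame(image=frame / safe_bg, n_floored=int(floored.sum()))
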