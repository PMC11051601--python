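"""Bounding boxes → axial positions, with polynomial correction.

The raw depth of a detection is read off its box through the inverse of
the linear heuristic, using the longest edge for boxes clipped at the
frame border.  Detectors trained on heuristic labels systematically
mis-size their boxes in a smooth, depth-dependent way; a 4th-order
polynomial ``z_corr = Σ aₖ z_rawᵏ``, fitted on validation data against
classical depths, removes that systematic deviation before tracking.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import NamedTuple, Sequence

import numpy as np

from .annotate import HeuristicCalibration
from .detect import Detection

__all__ = [
    "DepthCorrection",
    "z_from_box",
    "z_from_size",
    "fit_depth_correction",
    "apply_correction",
    "save_correction",
    "load_correction",
]


@dataclass(frozen=True)
class DepthCorrection:
    """Polynomial axial correction with its validity domain.

    ``coefficients`` are ascending (a₀..a₄ for the default 4th order);
    applying the correction outside ``fit_domain`` is flagged as
    extrapolation.
    """

    coefficients: tuple[float, ...]
    fit_domain: tuple[float, float]

    def __post_init__(self) -> None:
        if len(self.coefficients) < 2:
            raise ValueError("need at least a linear correction")
        if self.fit_domain[1] <= self.fit_domain[0]:
            raise ValueError("fit_domain must be a non-empty interval")

    @classmethod
    def identity(cls, domain: tuple[float, float] = (0.0, 280.0)) -> "DepthCorrection":
        return cls(coefficients=(0.0, 1.0, 0.0, 0.0, 0.0), fit_domain=domain)


class CorrectionResult(NamedTuple):
    z: np.ndarray | float
    extrapolated: np.ndarray | bool


def z_from_size(cal: HeuristicCalibration, side_px: float | np.ndarray) -> float | np.ndarray:
    """Invert the heuristic: z_raw = (side − c) / m, floored at 0 μm."""
    return np.maximum((np.asarray(side_px, dtype=float) - cal.intercept_c) / cal.slope_m, 0.0)[()]


def z_from_box(cal: HeuristicCalibration, det: Detection) -> float:
    """Raw depth of a detection from its longest edge (μm).

    The longest edge is used so boxes truncated by the frame border
    still reflect the pattern's true extent.
    """
    return float(z_from_size(cal, det.longest_edge))


def fit_depth_correction(
    pairs: Sequence[tuple[float, float]], order: int = 4
) -> DepthCorrection:
    """Least-squares polynomial through (z_raw, z_true) pairs.

    Needs at least ``order + 1`` pairs with enough distinct z_raw values
    for a full-rank design; the fit domain is the data's z_raw range.  A
    non-monotone fit on its own domain triggers a warning — a
    non-monotone size→depth correction makes depth inversion ambiguous.
    """
    data = np.asarray(pairs, dtype=float)
    if data.ndim != 2 or data.shape[1] != 2:
        raise ValueError("pairs must be (z_raw, z_true) tuples")
    if data.shape[0] < order + 1:
        raise ValueError(
            f"need at least {order + 1} pairs for an order-{order} fit, "
            f"got {data.shape[0]}"
        )
    z_raw, z_true = data[:, 0], data[:, 1]
    if np.unique(z_raw).size < order + 1:
        raise ValueError(
            "rank-deficient design: fewer distinct z_raw values than "
            "polynomial coefficients"
        )
    # least squares on the rescaled variable z/s for conditioning,
    # coefficients mapped back to ascending powers of z
    s = float(np.abs(z_raw).max())
    V = np.vander(z_raw / s, order + 1, increasing=True)
    scaled, _, rank, _ = np.linalg.lstsq(V, z_true, rcond=None)
    if rank < order + 1:
        raise ValueError("rank-deficient design matrix; cannot fit correction")
    coeffs = scaled / s ** np.arange(order + 1)
    domain = (float(z_raw.min()), float(z_raw.max()))
    corr = DepthCorrection(coefficients=tuple(float(c) for c in coeffs), fit_domain=domain)
    zz = np.linspace(domain[0], domain[1], 256)
    if np.any(np.diff(np.polynomial.polynomial.polyval(zz, coeffs)) < 0):
        warnings.warn(
            "fitted depth correction is not monotone on its domain; "
            "depth inversion is ambiguous there",
            stacklevel=2,
        )
    return corr


def apply_correction(
    corr: DepthCorrection, z_raw: float | np.ndarray
) -> CorrectionResult:
    """Evaluate the correction polynomial, floored at 0 μm.

    Values outside the fit domain are still evaluated but flagged as
    extrapolated.
    """
    z_raw = np.asarray(z_raw, dtype=float)
    if not np.all(np.isfinite(z_raw)):
        raise ValueError("z_raw must be finite")
    z = np.polynomial.polynomial.polyval(z_raw, np.asarray(corr.coefficients))
    z = np.maximum(z, 0.0)
    extrapolated = (z_raw < corr.fit_domain[0]) | (z_raw > corr.fit_domain[1])
    return CorrectionResult(z=z[()], extrapolated=extrapolated[()])


def save_correction(corr: DepthCorrection, path: str | Path) -> None:
    Path(path).write_text(
        json.dumps(
            {
                "coefficients": list(corr.coefficients),
                "fit_domain_um": list(corr.fit_domain),
                "model": "polynomial_ascending_powers",
            },
            indent=1,
        )
    )


def load_correction(path: str | Path) -> DepthCorrection:
    d = json.loads(Path(path).read_text())
    return DepthCorrection(
        coefficients=tuple(d["coefficients"]), fit_domain=tuple(d["fit_domain_um"])
    )
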