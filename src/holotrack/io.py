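"""File I/O for frames, ground truth and localizations.

Video frames travel as multi-page 32-bit float TIFF stacks; tabular
artifacts (ground-truth positions, localizations) as CSV via pandas.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import tifffile

from .reconstruct import Localization3D
from .track import Track

__all__ = [
    "write_stack",
    "read_stack",
    "write_ground_truth",
    "read_ground_truth",
    "write_localizations",
    "read_localizations",
]


def write_stack(path: str | Path, frames: np.ndarray | Sequence[np.ndarray]) -> None:
    """Write frames as a multi-page float32 TIFF."""
    arr = np.asarray(frames, dtype=np.float32)
    if arr.ndim != 3:
        raise ValueError("expected a (n_frames, H, W) stack")
    tifffile.imwrite(Path(path), arr)


def read_stack(path: str | Path) -> np.ndarray:
    arr = tifffile.imread(Path(path))
    if arr.ndim == 2:
        arr = arr[np.newaxis]
    return arr.astype(np.float64)


def write_ground_truth(tracks: Iterable[Track], path: str | Path) -> None:
    """Ground truth as CSV: frame, cell_id, x_um, y_um, z_um."""
    rows = [
        {"frame": p.frame_index, "cell_id": t.track_id,
         "x_um": p.x, "y_um": p.y, "z_um": p.z}
        for t in tracks
        for p in t.points
    ]
    pd.DataFrame(rows, columns=["frame", "cell_id", "x_um", "y_um", "z_um"]).to_csv(
        Path(path), index=False
    )


def read_ground_truth(path: str | Path) -> list[Track]:
    df = pd.read_csv(Path(path))
    tracks = []
    for cid, grp in df.sort_values(["cell_id", "frame"]).groupby("cell_id"):
        pts = [
            Localization3D(x=r.x_um, y=r.y_um, z=r.z_um,
                           frame_index=int(r.frame), source="ground_truth")
            for r in grp.itertuples()
        ]
        tracks.append(Track(track_id=int(cid), points=pts))
    return tracks


def write_localizations(locs: Iterable[Localization3D], path: str | Path) -> None:
    """Localizations as CSV: frame, x_um, y_um, z_um, response, source."""
    rows = [
        {"frame": l.frame_index, "x_um": l.x, "y_um": l.y, "z_um": l.z,
         "response": l.response, "source": l.source}
        for l in locs
    ]
    pd.DataFrame(
        rows, columns=["frame", "x_um", "y_um", "z_um", "response", "source"]
    ).to_csv(Path(path), index=False)


def read_localizations(path: str | Path) -> list[Localization3D]:
    df = pd.read_csv(Path(path))
    return [
        Localization3D(x=r.x_um, y=r.y_um, z=r.z_um, frame_index=int(r.frame),
                       source=str(r.source), response=float(r.response))
        for r in df.itertuples()
    ]
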