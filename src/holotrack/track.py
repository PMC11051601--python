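"""Link per-frame 3D localizations into cell tracks.

Frame-to-frame correspondence is solved as an optimal bipartite
assignment (Hungarian algorithm) on 3D Euclidean distance, with a hard
per-link distance gate, a gap tolerance for momentarily missed cells,
and a minimum-length filter that rejects spurious transient signals.
"""

from __future__ import annotations

import json
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .reconstruct import Localization3D

__all__ = ["Track", "link", "track_rmse", "match_tracks", "write_tracks", "read_tracks"]


@dataclass
class Track:
    """A time-ordered sequence of 3D localizations for one object."""

    track_id: int
    points: list[Localization3D] = field(default_factory=list)

    def __post_init__(self) -> None:
        frames = [p.frame_index for p in self.points]
        if any(b <= a for a, b in zip(frames, frames[1:])):
            raise ValueError("track frame indices must be strictly increasing")

    def __len__(self) -> int:
        return len(self.points)

    @property
    def frames(self) -> np.ndarray:
        return np.array([p.frame_index for p in self.points], dtype=int)

    @property
    def positions(self) -> np.ndarray:
        """(n, 3) array of (x, y, z) in μm."""
        return np.array([[p.x, p.y, p.z] for p in self.points], dtype=float)

    def gaps(self) -> np.ndarray:
        """Per-link frame gaps (1 = consecutive frames)."""
        f = self.frames
        return np.diff(f)


def link(
    localizations: list[Localization3D],
    max_disp: float = 30.0,
    max_gap: int = 2,
    min_length: int = 5,
) -> list[Track]:
    """Assemble localizations into tracks.

    Parameters
    ----------
    localizations : list of Localization3D
        All per-frame localizations of a video (any order).
    max_disp : float
        Hard cap on the 3D displacement of a single link, μm.  The
        default 30 μm is roughly the largest per-frame swimming
        displacement at 30 Hz.
    max_gap : int
        A track may skip up to this many frames before being closed.
    min_length : int
        Tracks with fewer localizations are discarded; with
        ``min_length > 1`` single-frame transients never survive.

    Frame pairs are matched by minimum total 3D distance (optimal
    bipartite assignment), so the result does not depend on the
    within-frame ordering of the input.
    """
    if max_disp <= 0:
        raise ValueError("max_disp must be positive")
    if max_gap < 0 or min_length < 1:
        raise ValueError("max_gap must be >= 0 and min_length >= 1")

    by_frame: dict[int, list[Localization3D]] = defaultdict(list)
    for loc in localizations:
        by_frame[loc.frame_index].append(loc)
    if not by_frame:
        return []

    BIG = 1e12
    active: list[dict] = []  # {"points": [...], "last": Localization3D}
    finished: list[list[Localization3D]] = []

    for frame in range(min(by_frame), max(by_frame) + 1):
        # sort candidates deterministically (position-based, order-free)
        locs = sorted(by_frame.get(frame, []), key=lambda p: (p.x, p.y, p.z))
        still_active = []
        for tr in active:
            if frame - tr["last"].frame_index > max_gap + 1:
                finished.append(tr["points"])
            else:
                still_active.append(tr)
        active = still_active
        if not locs:
            continue
        if active:
            heads = np.array([[t["last"].x, t["last"].y, t["last"].z] for t in active])
            pts = np.array([[p.x, p.y, p.z] for p in locs])
            dist = np.linalg.norm(heads[:, None, :] - pts[None, :, :], axis=2)
            cost = np.where(dist <= max_disp, dist, BIG)
            rows, cols = linear_sum_assignment(cost)
            matched_locs = set()
            for r, c in zip(rows, cols):
                if dist[r, c] <= max_disp:
                    active[r]["points"].append(locs[c])
                    active[r]["last"] = locs[c]
                    matched_locs.add(c)
            new = [locs[c] for c in range(len(locs)) if c not in matched_locs]
        else:
            new = locs
        for loc in new:
            active.append({"points": [loc], "last": loc})

    finished.extend(tr["points"] for tr in active)
    tracks = [
        Track(track_id=i, points=pts)
        for i, pts in enumerate(
            sorted(
                (pts for pts in finished if len(pts) >= min_length),
                key=lambda pts: (pts[0].frame_index, pts[0].x, pts[0].y, pts[0].z),
            )
        )
    ]
    return tracks


def track_rmse(predicted: Track, reference: Track) -> float:
    """RMSE of 3D point-to-point distances over common frames.

    Requires at least 3 overlapping frames, the pairing contract for
    comparing a proxy-derived track against its classical counterpart.
    """
    pf = {p.frame_index: p for p in predicted.points}
    rf = {p.frame_index: p for p in reference.points}
    common = sorted(set(pf) & set(rf))
    if len(common) < 3:
        raise ValueError(
            f"tracks share only {len(common)} frames; need >= 3 for an RMSE"
        )
    d2 = [
        (pf[f].x - rf[f].x) ** 2 + (pf[f].y - rf[f].y) ** 2 + (pf[f].z - rf[f].z) ** 2
        for f in common
    ]
    return float(np.sqrt(np.mean(d2)))


def match_tracks(
    predicted: list[Track], reference: list[Track], min_overlap: int = 3
) -> list[tuple[Track, Track]]:
    """Pair each predicted track with the reference track of maximal
    frame overlap (ties broken by smaller mean 3D distance)."""
    pairs: list[tuple[Track, Track]] = []
    for p in predicted:
        pf = {pt.frame_index: pt for pt in p.points}
        best = None
        for r in reference:
            rf = {pt.frame_index: pt for pt in r.points}
            common = set(pf) & set(rf)
            if len(common) < min_overlap:
                continue
            mean_d = float(
                np.mean(
                    [
                        np.linalg.norm(pf[f].as_array() - rf[f].as_array())
                        for f in common
                    ]
                )
            )
            key = (-len(common), mean_d)
            if best is None or key < best[0]:
                best = (key, r)
        if best is not None:
            pairs.append((p, best[1]))
    return pairs


# ---------------------------------------------------------------------------
# I/O


def _tracks_frame(tracks: list[Track]) -> pd.DataFrame:
    rows = [
        {
            "track_id": t.track_id,
            "frame": p.frame_index,
            "x_um": p.x,
            "y_um": p.y,
            "z_um": p.z,
            "source": p.source,
        }
        for t in tracks
        for p in t.points
    ]
    return pd.DataFrame(rows, columns=["track_id", "frame", "x_um", "y_um", "z_um", "source"])


def write_tracks(tracks: list[Track], path: str | Path) -> None:
    """Write tracks as CSV (track_id, frame, x_um, y_um, z_um, source) or JSON."""
    path = Path(path)
    df = _tracks_frame(tracks)
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(df.to_dict(orient="records"), indent=1))
    else:
        df.to_csv(path, index=False)


def read_tracks(path: str | Path) -> list[Track]:
    path = Path(path)
    if path.suffix.lower() == ".json":
        df = pd.DataFrame(json.loads(path.read_text()))
    else:
        df = pd.read_csv(path)
    tracks = []
    if df.empty:
        return tracks
    for tid, grp in df.sort_values(["track_id", "frame"]).groupby("track_id"):
        pts = [
            Localization3D(
                x=row.x_um, y=row.y_um, z=row.z_um,
                frame_index=int(row.frame), source=str(row.source),
            )
            for row in grp.itertuples()
        ]
        tracks.append(Track(track_id=int(tid), points=pts))
    return tracks
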