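"""Whole-cell translational tracking.

Cells are segmented per frame by a binary threshold plus connected
components, linked frame-to-frame by greedy nearest-neighbor association,
and each linked cell is re-cut into a movie in the reference frame of its
own centroid (the input to rotation tracking).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.measure import label, regionprops

__all__ = [
    "CellTrack",
    "CellStack",
    "segment_cells",
    "segment_movie",
    "link_cell_tracks",
    "cell_velocity",
    "crop_cell_frame",
]


@dataclass
class CellTrack:
    """One cell's centroid trajectory.

    Positions are in um with x along the flow direction; ``v_um_s`` is
    filled by :func:`cell_velocity` and ``d_um`` by downstream rotation
    analysis (or from segmented area).
    """

    frames: np.ndarray
    t: np.ndarray
    x_um: np.ndarray
    y_um: np.ndarray
    v_um_s: np.ndarray | None = None
    d_um: float | None = None
    meta: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.frames)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {"frame": self.frames, "t": self.t, "x_um": self.x_um, "y_um": self.y_um}
        )
        if self.v_um_s is not None:
            df["v_um_s"] = self.v_um_s
        return df


def segment_cells(
    frame: np.ndarray,
    pixel_size: float,
    threshold_method: str | float = "otsu",
    min_area_px: int = 50,
) -> pd.DataFrame:
    """Segment bright cells in one frame.

    Returns a DataFrame with columns ``x_um, y_um, area_px, eq_diameter_um``
    sorted by x.  An empty frame yields an empty DataFrame, not an error.
    """
    frame = np.asarray(frame, dtype=float)
    cols = ["x_um", "y_um", "area_px", "eq_diameter_um"]
    if frame.max() == frame.min():
        return pd.DataFrame(columns=cols)
    if threshold_method == "otsu":
        thr = threshold_otsu(frame)
    else:
        thr = float(threshold_method)
    mask = frame > thr
    mask = ndimage.binary_fill_holes(mask)
    lab = label(mask)
    rows = []
    for rp in regionprops(lab):
        if rp.area < min_area_px:
            continue
        cy, cx = rp.centroid
        rows.append(
            {
                "x_um": cx * pixel_size,
                "y_um": cy * pixel_size,
                "area_px": int(rp.area),
                "eq_diameter_um": rp.equivalent_diameter_area * pixel_size,
            }
        )
    df = pd.DataFrame(rows, columns=cols)
    return df.sort_values("x_um", ignore_index=True)


def segment_movie(
    movie: np.ndarray,
    pixel_size: float,
    threshold_method: str | float = "otsu",
    min_area_px: int = 50,
) -> pd.DataFrame:
    """Run :func:`segment_cells` on every frame; adds a ``frame`` column."""
    parts = []
    for i, frame in enumerate(movie):
        df = segment_cells(frame, pixel_size, threshold_method, min_area_px)
        df.insert(0, "frame", i)
        parts.append(df)
    return pd.concat(parts, ignore_index=True)


def _greedy_assign(
    prev_xy: np.ndarray, new_xy: np.ndarray, gate: float
) -> list[tuple[int, int]]:
    """Greedy nearest-neighbor assignment within ``gate``.

    Ties (equal distance) are broken deterministically by the smaller
    detection y, then x.
    """
    if len(prev_xy) == 0 or len(new_xy) == 0:
        return []
    d = np.linalg.norm(prev_xy[:, None, :] - new_xy[None, :, :], axis=2)
    pairs = [
        (d[i, j], new_xy[j, 1], new_xy[j, 0], i, j)
        for i in range(d.shape[0])
        for j in range(d.shape[1])
        if d[i, j] <= gate
    ]
    pairs.sort()
    used_i: set[int] = set()
    used_j: set[int] = set()
    out = []
    for _, _, _, i, j in pairs:
        if i in used_i or j in used_j:
            continue
        used_i.add(i)
        used_j.add(j)
        out.append((i, j))
    return out


def link_cell_tracks(
    detections: pd.DataFrame,
    max_jump_um: float,
    frame_interval: float = 1.0 / 30.0,
    max_gap_frames: int = 0,
    min_length: int = 2,
) -> list[CellTrack]:
    """Link per-frame centroids into tracks by greedy nearest-neighbor.

    A track ends when no detection lies within ``max_jump_um`` for more than
    ``max_gap_frames`` consecutive frames; each detection is used at most
    once.
    """
    if max_jump_um <= 0:
        raise ValueError("max_jump_um must be > 0")
    if detections.empty:
        return []
    active: list[dict] = []  # {frames, xs, ys, last_frame}
    done: list[dict] = []
    for fr in range(int(detections["frame"].min()), int(detections["frame"].max()) + 1):
        det = detections[detections["frame"] == fr]
        new_xy = det[["x_um", "y_um"]].to_numpy(dtype=float)
        # close stale tracks
        still = []
        for tr in active:
            if fr - tr["last_frame"] > max_gap_frames + 1:
                done.append(tr)
            else:
                still.append(tr)
        active = still
        prev_xy = np.array([[tr["xs"][-1], tr["ys"][-1]] for tr in active]).reshape(-1, 2)
        matches = _greedy_assign(prev_xy, new_xy, max_jump_um)
        matched_j = set()
        for i, j in matches:
            active[i]["frames"].append(fr)
            active[i]["xs"].append(new_xy[j, 0])
            active[i]["ys"].append(new_xy[j, 1])
            active[i]["last_frame"] = fr
            matched_j.add(j)
        for j in range(len(new_xy)):
            if j not in matched_j:
                active.append(
                    {
                        "frames": [fr],
                        "xs": [new_xy[j, 0]],
                        "ys": [new_xy[j, 1]],
                        "last_frame": fr,
                    }
                )
    done.extend(active)
    tracks = []
    for tr in done:
        if len(tr["frames"]) < min_length:
            continue
        frames = np.asarray(tr["frames"], dtype=int)
        tracks.append(
            CellTrack(
                frames=frames,
                t=frames * frame_interval,
                x_um=np.asarray(tr["xs"]),
                y_um=np.asarray(tr["ys"]),
            )
        )
    tracks.sort(key=lambda tr: (tr.frames[0], tr.x_um[0]))
    return tracks


def cell_velocity(track: CellTrack, smoothing_window: int = 1) -> np.ndarray:
    """Instantaneous rolling velocity dx/dt (um/s).

    Central differences in the interior, one-sided at the ends; an optional
    moving average of ``smoothing_window`` samples (edge-replicated).  Also
    stored on ``track.v_um_s``.
    """
    if len(track) < 2:
        raise ValueError("track must have length >= 2 to compute a velocity")
    if smoothing_window > len(track):
        raise ValueError(
            f"smoothing_window ({smoothing_window}) longer than track ({len(track)})"
        )
    v = np.gradient(track.x_um, track.t)
    if smoothing_window > 1:
        v = moving_average(v, smoothing_window)
    track.v_um_s = v
    return v


def moving_average(x: np.ndarray, window: int) -> np.ndarray:
    """Edge-replicated moving average; window is clipped to odd length."""
    window = int(window) | 1
    pad = window // 2
    xp = np.pad(x, pad, mode="edge")
    kernel = np.ones(window) / window
    return np.convolve(xp, kernel, mode="valid")


@dataclass
class CellStack:
    """A movie re-cut in the reference frame of one cell's centroid.

    Cropping is integer-pixel; the sub-pixel residual (centroid minus crop
    center, in px) is recorded per frame and applied downstream as a
    coordinate offset rather than by interpolation.
    """

    frames: np.ndarray  # (n, h, w)
    residual_px: np.ndarray  # (n, 2) -> (dx, dy)
    padded: np.ndarray  # (n,) bool
    pixel_size: float
    track: CellTrack

    def __len__(self) -> int:
        return len(self.frames)


def crop_cell_frame(
    movie: np.ndarray,
    track: CellTrack,
    box_half_width_um: float,
    pixel_size: float,
    pad_value: float | None = None,
) -> CellStack:
    """Cut a square cell-centered sub-movie around a track.

    Frames where the box extends past the movie edge are padded with
    ``pad_value`` (default: per-frame border median) and flagged.
    """
    n_mov, H, W = movie.shape
    if track.d_um is not None and 2 * box_half_width_um < track.d_um:
        raise ValueError("crop box must contain the cell diameter")
    half_px = int(np.ceil(box_half_width_um / pixel_size))
    size = 2 * half_px + 1
    n = len(track)
    out = np.empty((n, size, size), dtype=movie.dtype)
    residual = np.empty((n, 2))
    padded = np.zeros(n, dtype=bool)
    for k, fr in enumerate(track.frames):
        if fr < 0 or fr >= n_mov:
            raise ValueError(f"track frame {fr} outside movie (n={n_mov})")
        cx = track.x_um[k] / pixel_size
        cy = track.y_um[k] / pixel_size
        if not (0 <= cx < W and 0 <= cy < H):
            raise ValueError(f"track centroid outside movie bounds at frame {fr}")
        ix, iy = int(round(cx)), int(round(cy))
        residual[k] = (cx - ix, cy - iy)
        x_lo, x_hi = ix - half_px, ix + half_px + 1
        y_lo, y_hi = iy - half_px, iy + half_px + 1
        src = movie[fr]
        fill = pad_value
        if fill is None:
            border = np.concatenate([src[0], src[-1], src[:, 0], src[:, -1]])
            fill = float(np.median(border))
        tile = np.full((size, size), fill, dtype=movie.dtype)
        sx_lo, sx_hi = max(0, x_lo), min(W, x_hi)
        sy_lo, sy_hi = max(0, y_lo), min(H, y_hi)
        if sx_lo > x_lo or sx_hi < x_hi or sy_lo > y_lo or sy_hi < y_hi:
            padded[k] = True
        tile[sy_lo - y_lo : sy_hi - y_lo, sx_lo - x_lo : sx_hi - x_lo] = src[
            sy_lo:sy_hi, sx_lo:sx_hi
        ]
        out[k] = tile
    return CellStack(
        frames=out, residual_px=residual, padded=padded, pixel_size=pixel_size, track=track
    )
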