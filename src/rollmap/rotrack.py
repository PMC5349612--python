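"""Rotation reconstruction from intracellular scatterer trajectories.

A rolling sphere carries bright scatterers whose cell-frame x projection is
``x_cm(t) = R*cos(theta(t) + phi)``.  This module detects those features
(stable-extremal-region or Laplacian-of-Gaussian blobs), links them into
trajectories, estimates the radial distance R, inverts the projection with
``arccos`` (unfolding the 0..pi degeneracy by flipping alternating intervals
about pi), accumulates the angle across cycles, and derives the angular
velocity, the traction metric ``r*dtheta/dx`` and the cell circumference.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit
from scipy.signal import find_peaks
from skimage.feature import blob_log, peak_local_max
from skimage.measure import label

from .trackcore import CellStack, CellTrack, moving_average

TWO_PI = 2.0 * np.pi

__all__ = [
    "SpotTrajectory",
    "AngleTrace",
    "detect_spot_features",
    "link_spot_trajectory",
    "estimate_radial_distance",
    "reconstruct_angle",
    "accumulate_angle",
    "merge_feature_angles",
    "angular_velocity",
    "traction_classification",
    "circumference_from_slope",
    "rotation_pipeline",
]

LABEL_ROLLING = "rolling"
LABEL_DETACHED = "detached"
LABEL_AMBIGUOUS = "ambiguous"


@dataclass
class SpotTrajectory:
    """Cell-frame trajectory of one scatterer (um)."""

    spot_id: int
    frames: np.ndarray
    x_cm: np.ndarray
    y_cm: np.ndarray
    R: float | None = None
    meta: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.frames)


@dataclass
class AngleTrace:
    """Reconstructed rotation of one cell.

    ``theta_rel`` in [0, 2*pi); ``theta_cum`` non-decreasing during rolling;
    ``omega`` in rad/s; ``labels`` per-frame traction classification.
    """

    frames: np.ndarray
    t: np.ndarray
    theta_rel: np.ndarray
    theta_cum: np.ndarray
    omega: np.ndarray | None = None
    labels: np.ndarray | None = None
    slope_metric: np.ndarray | None = None
    quality_sd: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "frame": self.frames,
                "t": self.t,
                "theta_rel": self.theta_rel,
                "theta_cum": self.theta_cum,
            }
        )
        for name in ("omega", "labels", "slope_metric"):
            val = getattr(self, name)
            if val is not None:
                df[name if name != "labels" else "label"] = val
        return df


# --------------------------------------------------------------------------
# feature detection
# --------------------------------------------------------------------------

def _refine_centroid(
    img: np.ndarray,
    cy: float,
    cx: float,
    radius: int = 4,
    n_iter: int = 4,
    taper_sigma: float = 2.0,
) -> tuple[float, float]:
    """Gaussian-tapered, background-subtracted weighted centroid.

    The taper localizes the estimate so that neighboring spots and the
    bright cell rim inside the window tail do not pull the centroid.
    """
    h, w = img.shape
    for _ in range(n_iter):
        iy, ix = int(round(cy)), int(round(cx))
        y_lo, y_hi = max(0, iy - radius), min(h, iy + radius + 1)
        x_lo, x_hi = max(0, ix - radius), min(w, ix + radius + 1)
        win = img[y_lo:y_hi, x_lo:x_hi].astype(float)
        border = np.concatenate([win[0], win[-1], win[:, 0], win[:, -1]])
        yy, xx = np.mgrid[y_lo:y_hi, x_lo:x_hi]
        taper = np.exp(-((yy - cy) ** 2 + (xx - cx) ** 2) / (2.0 * taper_sigma**2))
        wgt = np.clip(win - np.median(border), 0.0, None) * taper
        tot = wgt.sum()
        if tot <= 0:
            break
        cy_new = float((wgt * yy).sum() / tot)
        cx_new = float((wgt * xx).sum() / tot)
        if abs(cy_new - cy) < 1e-4 and abs(cx_new - cx) < 1e-4:
            cy, cx = cy_new, cx_new
            break
        cy, cx = cy_new, cx_new
    return cy, cx


def _detect_mser_frame(
    frame: np.ndarray,
    min_area: int = 4,
    max_area: int = 150,
    n_levels: int = 24,
    delta: int = 2,
    max_variation: float = 0.5,
    noise_k: float = 5.0,
    rel_floor: float = 0.25,
) -> list[dict]:
    """Stable-extremal-region detection of bright blobs in one frame.

    Seeds at local intensity maxima; for each seed the connected region
    above a descending ladder of thresholds is tracked, and the seed is kept
    if its region area is stable (relative growth over ``delta`` levels
    below ``max_variation``) somewhere on the ladder while staying within
    the area bounds.
    """
    img = np.asarray(frame, dtype=float)
    bg = float(np.median(img))
    mad = float(np.median(np.abs(img - bg))) * 1.4826
    vmax = float(img.max())
    if vmax <= bg:
        return []
    thr_abs = bg + max(noise_k * mad, rel_floor * (vmax - bg))
    seeds = peak_local_max(img, min_distance=2, threshold_abs=thr_abs)
    if len(seeds) == 0:
        return []
    levels = np.linspace(vmax, thr_abs, n_levels)
    # region area per seed per level
    areas = np.zeros((len(seeds), n_levels), dtype=float)
    for li, lev in enumerate(levels):
        lab = label(img >= lev)
        for si, (sy, sx) in enumerate(seeds):
            lid = lab[sy, sx]
            areas[si, li] = np.sum(lab == lid) if lid > 0 else 0.0
    feats = []
    claimed: set[tuple[int, int]] = set()
    for si, (sy, sx) in enumerate(seeds):
        a = areas[si]
        valid = a >= min_area
        best_q, best_li = np.inf, -1
        for li in range(delta, n_levels - delta):
            if not (valid[li] and a[li] <= max_area):
                continue
            q = (a[li + delta] - a[li - delta]) / a[li]
            if q < best_q:
                best_q, best_li = q, li
        if best_li < 0 or best_q > max_variation:
            continue
        lab = label(img >= levels[best_li])
        lid = lab[sy, sx]
        if lid == 0:
            continue
        key = tuple(np.argwhere(lab == lid)[0])
        if key in claimed:  # two seeds inside the same stable region
            continue
        claimed.add(key)
        ys, xs = np.nonzero(lab == lid)
        wgt = img[ys, xs] - levels[best_li]
        wgt = np.clip(wgt, 0, None) + 1e-12
        cy = float((wgt * ys).sum() / wgt.sum())
        cx = float((wgt * xs).sum() / wgt.sum())
        cy, cx = _refine_centroid(img, cy, cx)
        feats.append(
            {"y_px": cy, "x_px": cx, "area_px": float(a[best_li]), "score": 1.0 - best_q}
        )
    return feats


def _detect_log_frame(
    frame: np.ndarray,
    min_sigma: float = 1.0,
    max_sigma: float = 4.0,
    threshold_rel: float = 0.2,
) -> list[dict]:
    img = np.asarray(frame, dtype=float)
    bg = np.median(img)
    pos = np.clip(img - bg, 0, None)
    if pos.max() <= 0:
        return []
    blobs = blob_log(
        pos / pos.max(), min_sigma=min_sigma, max_sigma=max_sigma, threshold=threshold_rel
    )
    feats = []
    for by, bx, bs in blobs:
        cy, cx = _refine_centroid(img, by, bx)
        feats.append({"y_px": cy, "x_px": cx, "area_px": np.pi * bs**2, "score": float(bs)})
    return feats


def detect_spot_features(
    cell_stack: CellStack | np.ndarray,
    method: str = "mser",
    pixel_size: float | None = None,
    **params,
) -> list[pd.DataFrame]:
    """Detect bright-blob features in every frame of a cell-centered stack.

    Returns one DataFrame per frame with cell-frame positions ``x_um, y_um``
    (origin at the cell centroid, sub-pixel crop residual folded in), plus
    ``area_px`` and a detector ``score``.  A frame without features yields
    an empty DataFrame (trace gap).
    """
    if isinstance(cell_stack, CellStack):
        frames = cell_stack.frames
        residual = cell_stack.residual_px
        px = cell_stack.pixel_size
    else:
        frames = np.asarray(cell_stack)
        residual = np.zeros((len(frames), 2))
        if pixel_size is None:
            raise ValueError("pixel_size required when passing a bare array")
        px = pixel_size
    detect = {"mser": _detect_mser_frame, "log": _detect_log_frame}[method]
    h, w = frames.shape[1:]
    cy0, cx0 = (h - 1) / 2.0, (w - 1) / 2.0
    out = []
    for i, frame in enumerate(frames):
        feats = detect(frame, **params)
        rows = [
            {
                "x_um": (f["x_px"] - cx0 - residual[i, 0]) * px,
                "y_um": (f["y_px"] - cy0 - residual[i, 1]) * px,
                "area_px": f["area_px"],
                "score": f["score"],
            }
            for f in feats
        ]
        out.append(pd.DataFrame(rows, columns=["x_um", "y_um", "area_px", "score"]))
    return out


# --------------------------------------------------------------------------
# trajectory linking
# --------------------------------------------------------------------------

def link_spot_trajectory(
    features: list[pd.DataFrame],
    gate_um: float = 2.0,
    max_gap_frames: int = 3,
    min_length: int = 10,
) -> list[SpotTrajectory]:
    """Greedy nearest-neighbor linking of per-frame features in the cell frame.

    Gaps up to ``max_gap_frames`` are bridged; trajectories shorter than
    ``min_length`` are discarded.
    """
    active: list[dict] = []
    done: list[dict] = []
    for fr, df in enumerate(features):
        new_xy = df[["x_um", "y_um"]].to_numpy(dtype=float) if len(df) else np.empty((0, 2))
        still = []
        for tr in active:
            if fr - tr["frames"][-1] > max_gap_frames + 1:
                done.append(tr)
            else:
                still.append(tr)
        active = still
        prev_xy = np.array([[tr["xs"][-1], tr["ys"][-1]] for tr in active]).reshape(-1, 2)
        # greedy assignment, ties broken by smaller y then x
        pairs = []
        if len(prev_xy) and len(new_xy):
            d = np.linalg.norm(prev_xy[:, None] - new_xy[None, :], axis=2)
            pairs = sorted(
                (d[i, j], new_xy[j, 1], new_xy[j, 0], i, j)
                for i in range(d.shape[0])
                for j in range(d.shape[1])
                if d[i, j] <= gate_um
            )
        used_i: set[int] = set()
        used_j: set[int] = set()
        for _, _, _, i, j in pairs:
            if i in used_i or j in used_j:
                continue
            used_i.add(i)
            used_j.add(j)
            active[i]["frames"].append(fr)
            active[i]["xs"].append(new_xy[j, 0])
            active[i]["ys"].append(new_xy[j, 1])
        for j in range(len(new_xy)):
            if j not in used_j:
                active.append({"frames": [fr], "xs": [new_xy[j, 0]], "ys": [new_xy[j, 1]]})
    done.extend(active)
    done.sort(key=lambda tr: (tr["frames"][0], tr["ys"][0], tr["xs"][0]))
    out = []
    for k, tr in enumerate(done):
        if len(tr["frames"]) < min_length:
            continue
        out.append(
            SpotTrajectory(
                spot_id=len(out),
                frames=np.asarray(tr["frames"], dtype=int),
                x_cm=np.asarray(tr["xs"]),
                y_cm=np.asarray(tr["ys"]),
            )
        )
    return out


# --------------------------------------------------------------------------
# radial distance
# --------------------------------------------------------------------------

def _oscillation_turning_points(x: np.ndarray) -> np.ndarray:
    span = x.max() - x.min()
    if span <= 0:
        return np.empty(0, dtype=int)
    prom = 0.1 * span
    hi, _ = find_peaks(x, prominence=prom)
    lo, _ = find_peaks(-x, prominence=prom)
    return np.sort(np.concatenate([hi, lo]))


def estimate_radial_distance(
    traj: SpotTrajectory,
    estimator: str = "max",
    percentile: float = 95.0,
) -> float:
    """Estimate the spot's radial distance R from its cell-frame x trace.

    ``max`` (default) takes the maximal |x_cm|, ``percentile`` a high
    percentile of |x_cm| (robust to outliers; the default 95th keeps the
    noise-induced bias small), and ``cosine`` the amplitude of a cosine fit.
    The trace must span at least one full oscillation.
    """
    x = np.asarray(traj.x_cm, dtype=float)
    turning = _oscillation_turning_points(x)
    if len(turning) < 2:
        raise ValueError(
            "trajectory does not span a full oscillation of x_cm "
            f"({len(turning)} turning points found; constant or too-short trace)"
        )
    if estimator == "max":
        R = float(np.max(np.abs(x)))
    elif estimator == "percentile":
        R = float(np.percentile(np.abs(x), percentile))
    elif estimator == "cosine":
        t = np.arange(len(x), dtype=float)
        # frequency seed from the dominant FFT component
        xf = np.fft.rfft(x - x.mean())
        f0 = np.argmax(np.abs(xf[1:])) + 1
        w0 = TWO_PI * f0 / len(x)

        def model(tt, A, w, ph, c):
            return A * np.cos(w * tt + ph) + c

        p, _ = curve_fit(model, t, x, p0=[0.5 * (x.max() - x.min()), w0, 0.0, x.mean()])
        R = float(abs(p[0]))
    else:
        raise ValueError(f"unknown estimator {estimator!r}")
    traj.R = R
    traj.meta["R_estimator"] = estimator
    return R


# --------------------------------------------------------------------------
# angle reconstruction
# --------------------------------------------------------------------------

def reconstruct_angle(
    traj: SpotTrajectory | np.ndarray,
    R: float | None = None,
    hysteresis: float = 0.15,
    clamp_tolerance: float = 0.1,
) -> tuple[np.ndarray, dict]:
    """Relative rotation angle theta_rel(t) in [0, 2*pi) from x_cm = R*cos(theta).

    The raw angle ``arccos(clip(x/R, -1, 1))`` lives on [0, pi]; the
    degeneracy is removed by flipping alternating intervals about pi
    (``theta' = 2*pi - theta``).  Turning points near 0 and pi are detected
    with a hysteresis band of width ``hysteresis`` (rad) since arccos
    amplifies noise at its ends.  Samples with |x|/R beyond
    ``1 + clamp_tolerance`` are dropped (NaN); those between 1 and the
    tolerance are clamped and flagged.
    """
    if isinstance(traj, SpotTrajectory):
        x = np.asarray(traj.x_cm, dtype=float)
        R = R if R is not None else traj.R
    else:
        x = np.asarray(traj, dtype=float)
    if R is None or R <= 0:
        raise ValueError("R must be a positive radial distance")
    ratio = x / R
    dropped = np.abs(ratio) > 1.0 + clamp_tolerance
    clamped = (np.abs(ratio) > 1.0) & ~dropped
    raw = np.arccos(np.clip(ratio, -1.0, 1.0))
    raw[dropped] = np.nan

    valid = ~np.isnan(raw)
    theta = np.full_like(raw, np.nan)
    if valid.sum() >= 2:
        rv = raw[valid]
        # Turning points of the raw angle mark the 0/pi degeneracy flips.
        # Peaks are committed only once the trace moves away by the
        # hysteresis band (prominence), so an R slightly over-estimated
        # (raw never reaching pi exactly) still flips correctly.
        hi, _ = find_peaks(rv, prominence=hysteresis)
        lo, _ = find_peaks(-rv, prominence=hysteresis)
        hi = hi[rv[hi] > np.pi / 2]
        lo = lo[rv[lo] < np.pi / 2]
        turning = np.sort(np.concatenate([hi, lo]))
        d = np.diff(rv)
        nz = np.nonzero(np.abs(d) > 1e-12)[0]
        increasing = bool(d[nz[0]] > 0) if len(nz) else True
        flipped = np.zeros(len(rv), dtype=bool)
        state = not increasing
        prev = 0
        for tp in turning:
            flipped[prev : tp + 1] = state
            state = not state
            prev = tp + 1
        flipped[prev:] = state
        th = np.where(flipped, TWO_PI - rv, rv)
        theta[valid] = np.mod(th, TWO_PI)
    elif valid.sum() == 1:
        theta[valid] = raw[valid]

    info = {"clamped": clamped, "dropped": dropped, "n_clamped": int(clamped.sum())}
    return theta, info


def accumulate_angle(theta_rel: np.ndarray) -> np.ndarray:
    """Cumulative angle: add 2*pi at every wrap of theta_rel.

    A wrap is a negative jump larger than pi between consecutive valid
    samples.  NaN gaps are carried through (offset preserved across them).
    """
    theta_rel = np.asarray(theta_rel, dtype=float)
    out = np.full_like(theta_rel, np.nan)
    valid = np.nonzero(~np.isnan(theta_rel))[0]
    if len(valid) == 0:
        return out
    offset = 0.0
    prev = theta_rel[valid[0]]
    out[valid[0]] = prev
    for i in valid[1:]:
        cur = theta_rel[i]
        if cur - prev < -np.pi:
            offset += TWO_PI
        out[i] = cur + offset
        prev = cur
    return out


# --------------------------------------------------------------------------
# multi-feature merge
# --------------------------------------------------------------------------

def _circ_mean(angles: np.ndarray, weights: np.ndarray | None = None) -> float:
    w = np.ones_like(angles) if weights is None else weights
    z = np.sum(w * np.exp(1j * angles))
    return float(np.mod(np.angle(z), TWO_PI))


def _circ_dist(a: np.ndarray, b: np.ndarray | float) -> np.ndarray:
    return np.mod(a - b + np.pi, TWO_PI) - np.pi


def merge_feature_angles(
    angle_traces: list[tuple[np.ndarray, np.ndarray]],
    max_residual: float = np.pi / 4,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, list[int]]:
    """Merge per-feature relative-angle traces into one.

    Input: list of ``(frames, theta_rel)``; traces differ from the cell's
    rotation angle by a constant phase offset (the spot's phi), which is
    estimated against the longest trace by a circular mean and removed.
    Traces whose circular residual SD exceeds ``max_residual`` are excluded.
    The merge is a per-frame circular mean weighted by ``|sin theta|``
    (arccos is noise-amplifying where x_cm is near an extremum), and the
    per-frame circular SD is returned as a quality metric.

    Returns ``(frames, theta_rel_merged, per_frame_sd, excluded_indices)``.
    """
    if not angle_traces:
        raise ValueError("need at least one angle trace")
    n_frames = 1 + max(int(fr.max()) for fr, _ in angle_traces)
    mats = np.full((len(angle_traces), n_frames), np.nan)
    for i, (fr, th) in enumerate(angle_traces):
        mats[i, np.asarray(fr, dtype=int)] = th
    ref = int(np.argmax([np.sum(~np.isnan(m)) for m in mats]))
    excluded = []
    aligned = np.full_like(mats, np.nan)
    aligned[ref] = mats[ref]
    for i in range(len(mats)):
        if i == ref:
            continue
        common = ~np.isnan(mats[i]) & ~np.isnan(mats[ref])
        if common.sum() < 3:
            excluded.append(i)
            continue
        diff = mats[i, common] - mats[ref, common]
        off = _circ_mean(diff)
        resid = _circ_dist(mats[i, common] - off, mats[ref, common])
        if np.sqrt(np.mean(resid**2)) > max_residual:
            excluded.append(i)
            continue
        aligned[i] = np.mod(mats[i] - off, TWO_PI)
    keep = [i for i in range(len(mats)) if i not in excluded]
    merged = np.full(n_frames, np.nan)
    sd = np.full(n_frames, np.nan)
    for f in range(n_frames):
        vals = aligned[keep, f]
        ok = ~np.isnan(vals)
        if not ok.any():
            continue
        v = vals[ok]
        w = np.abs(np.sin(v)) + 0.05
        m = _circ_mean(v, w)
        merged[f] = m
        sd[f] = np.sqrt(np.mean(_circ_dist(v, m) ** 2))
    frames = np.nonzero(~np.isnan(merged))[0]
    return frames, merged[frames], sd[frames], excluded


# --------------------------------------------------------------------------
# derivatives and traction
# --------------------------------------------------------------------------

def angular_velocity(trace: AngleTrace, smoothing_window: int = 1) -> np.ndarray:
    """Angular velocity omega = dtheta_cum/dt (rad/s), optionally smoothed."""
    if smoothing_window > len(trace.frames):
        raise ValueError("smoothing_window longer than trace")
    om = np.gradient(trace.theta_cum, trace.t)
    if smoothing_window > 1:
        om = moving_average(om, smoothing_window)
    trace.omega = om
    return om


def traction_classification(
    trace: AngleTrace,
    cell_track: CellTrack,
    radius_um: float,
    window: int = 11,
    rolling_min: float = 0.75,
    detached_max: float = 0.5,
    min_dx_um: float = 0.05,
) -> tuple[np.ndarray, np.ndarray]:
    """Classify traction from the normalized slope ``r*dtheta/dx``.

    The metric is evaluated over a sliding window of ``window`` frames;
    values >= ``rolling_min`` are labeled rolling, <= ``detached_max``
    detached, anything else (including stalled windows with |dx| below
    ``min_dx_um``) ambiguous.  The trace and track must share their frames.
    """
    common, ia, ib = np.intersect1d(trace.frames, cell_track.frames, return_indices=True)
    if len(common) == 0:
        raise ValueError("trace and track share no frames")
    theta = trace.theta_cum[ia]
    x = cell_track.x_um[ib]
    n = len(common)
    half = max(1, window // 2)
    metric = np.full(n, np.nan)
    labels = np.array([LABEL_AMBIGUOUS] * n, dtype=object)
    for i in range(n):
        j0, j1 = max(0, i - half), min(n - 1, i + half) + 1
        xw = x[j0:j1]
        tw = theta[j0:j1]
        ok = ~np.isnan(tw)
        dx = xw[ok].max() - xw[ok].min() if ok.sum() >= 2 else 0.0
        if dx < min_dx_um or ok.sum() < 2:
            continue
        # windowed least-squares slope dtheta/dx (less noisy than endpoints)
        xc = xw[ok] - xw[ok].mean()
        m = radius_um * float(np.dot(xc, tw[ok] - tw[ok].mean()) / np.dot(xc, xc))
        metric[i] = m
        if m >= rolling_min:
            labels[i] = LABEL_ROLLING
        elif m <= detached_max:
            labels[i] = LABEL_DETACHED
    full_metric = np.full(len(trace.frames), np.nan)
    full_labels = np.array([LABEL_AMBIGUOUS] * len(trace.frames), dtype=object)
    full_metric[ia] = metric
    full_labels[ia] = labels
    trace.slope_metric = full_metric
    trace.labels = full_labels
    return full_labels, full_metric


def circumference_from_slope(
    trace: AngleTrace,
    cell_track: CellTrack,
    min_cycles: float = 4.0,
) -> float:
    """Cell diameter from the slope of cumulative theta vs x on rolling samples.

    For pure rolling theta = x/r, so the least-squares slope s gives
    d = 2/s.  Detached/ambiguous samples are excluded; at least
    ``min_cycles`` full rotation cycles of rolling are required.
    """
    if trace.labels is None:
        raise ValueError("run traction_classification first")
    common, ia, ib = np.intersect1d(trace.frames, cell_track.frames, return_indices=True)
    rolling = (trace.labels[ia] == LABEL_ROLLING) & ~np.isnan(trace.theta_cum[ia])
    theta = trace.theta_cum[ia]
    x = cell_track.x_um[ib]
    if rolling.sum() < 2:
        raise ValueError("no rolling samples available for the slope fit")
    # Contiguous rolling runs: a detachment advances x without the matching
    # rotation, so the runs are offset from one another.  Demeaning x and
    # theta per run before the pooled fit removes those offsets (a
    # within-segment least-squares slope).
    edges = np.nonzero(np.diff(rolling.astype(int)))[0] + 1
    runs = [
        seg
        for seg in np.split(np.arange(len(rolling)), edges)
        if rolling[seg[0]] and len(seg) >= 3
    ]
    if not runs:
        raise ValueError("no rolling run long enough for the slope fit")
    n_cycles = sum(theta[s].max() - theta[s].min() for s in runs) / TWO_PI
    if n_cycles < min_cycles:
        raise ValueError(
            f"only {n_cycles:.2f} rolling cycles available; {min_cycles} required"
        )
    xc = np.concatenate([x[s] - x[s].mean() for s in runs])
    tc_ = np.concatenate([theta[s] - theta[s].mean() for s in runs])
    s = np.polyfit(xc, tc_, 1)[0]
    if s <= 0:
        warnings.warn("negative theta-vs-x slope: reverse rolling? sign flipped")
        s = -s
    return 2.0 / s


# --------------------------------------------------------------------------
# pipeline assembly
# --------------------------------------------------------------------------

def rotation_pipeline(
    cell_stack: CellStack,
    frame_interval: float,
    detector: str = "mser",
    r_estimator: str = "max",
    gate_um: float = 2.0,
    min_traj_length: int = 10,
    smoothing_window: int = 1,
    detector_params: dict | None = None,
) -> tuple[AngleTrace, list[SpotTrajectory]]:
    """Feature detection -> linking -> R -> unfold -> merge -> cumulative theta.

    Per feature the relative angle is unfolded first; the merged relative
    trace is then accumulated and differentiated into omega.
    """
    feats = detect_spot_features(cell_stack, method=detector, **(detector_params or {}))
    trajs = link_spot_trajectory(feats, gate_um=gate_um, min_length=min_traj_length)
    rel_traces = []
    used = []
    for traj in trajs:
        try:
            R = estimate_radial_distance(traj, estimator=r_estimator)
        except ValueError:
            continue
        theta_rel, _ = reconstruct_angle(traj, R)
        rel_traces.append((traj.frames, theta_rel))
        used.append(traj)
    if not rel_traces:
        raise ValueError("no usable spot trajectory spans a full oscillation")
    frames, rel, sd, excluded = merge_feature_angles(rel_traces)
    cum = accumulate_angle(rel)
    trace = AngleTrace(
        frames=frames,
        t=frames * frame_interval,
        theta_rel=rel,
        theta_cum=cum,
        quality_sd=sd,
        meta={
            "n_features": len(used),
            "excluded_features": excluded,
            "cross_spot_merge": len(used) > 1,
        },
    )
    angular_velocity(trace, smoothing_window=smoothing_window)
    return trace, used
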