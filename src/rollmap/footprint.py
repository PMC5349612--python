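"""Fluorescent adhesion-footprint image pipeline.

Rupture events of digital DNA tension sensors left behind by a rolling cell
are imaged as TIRF tiles.  The pipeline mirrors standard fluorescence
processing: flat-field correction ``I_corrected = (I0 - I_bg)/I_illum``
with the illumination profile estimated from the normalized average of many
tiles; integer-pixel stitching of overlapping tiles (cropped and joined
without averaging); then periodicity extraction -- normalized 2D
cross-correlation against a single repeating unit, per-period averaging,
and a 1D autocorrelation along the track whose lag axis is normalized by
the rolling circumference pi*d.  Contact geometry (width, circular contact
area, fraction of the sphere surface) comes from the transverse intensity
profile.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter
from scipy.signal import find_peaks
from skimage.feature import match_template

from .adhesionmap import PeriodicityResult, _acf_biased

TWO_PI = 2.0 * np.pi

__all__ = [
    "FootprintImage",
    "StitchResult",
    "estimate_illumination",
    "correct_illumination",
    "stitch_tiles",
    "track_cross_correlation",
    "average_period_unit",
    "footprint_autocorrelation",
    "population_footprint_autocorrelation",
    "contact_width",
    "contact_geometry",
]


@dataclass
class FootprintImage:
    """A calibrated footprint intensity grid with correction provenance."""

    data: np.ndarray
    pixel_size: float
    bg_subtracted: bool = False
    flat_fielded: bool = False
    stitched: bool = False
    meta: dict = field(default_factory=dict)


def estimate_illumination(
    images: np.ndarray | list[np.ndarray],
    dark_frame: np.ndarray | None = None,
    smooth_sigma: float = 0.0,
) -> np.ndarray:
    """Normalized illumination profile from a stack sharing the same field.

    Pixelwise mean of ``I0 - I_bg`` over the stack, optionally Gaussian
    smoothed, scaled by its maximum so max = 1.
    """
    stack = np.asarray(images, dtype=float)
    if stack.ndim == 2:
        stack = stack[None]
    if len(stack) < 2:
        warnings.warn("single image: illumination profile equals that image normalized")
    mean = stack.mean(axis=0)
    if dark_frame is not None:
        mean = mean - np.asarray(dark_frame, dtype=float)
    if smooth_sigma > 0:
        mean = gaussian_filter(mean, smooth_sigma)
        # read the scale at the argmax of a heavily smoothed copy: the plain
        # maximum overshoots by the extreme residual noise over many pixels
        coarse = gaussian_filter(mean, 4.0 * smooth_sigma)
        peak = float(mean[np.unravel_index(np.argmax(coarse), mean.shape)])
    else:
        peak = float(mean.max())
    if peak <= 0:
        raise ValueError("no signal: illumination profile maximum is non-positive")
    # profile values live in (0, 1] with the peak region at exactly 1
    return np.clip(mean / peak, 1e-6, 1.0)


def correct_illumination(
    I0: np.ndarray,
    Ibg: np.ndarray | float,
    illum: np.ndarray,
    eps: float = 1e-3,
) -> tuple[np.ndarray, np.ndarray]:
    """Flat-field correction ``(I0 - Ibg)/illum`` elementwise.

    Pixels where the illumination profile falls below ``eps`` are masked
    (set to 0) rather than divided; returns ``(corrected, mask)`` where mask
    marks the skipped pixels.
    """
    I0 = np.asarray(I0, dtype=float)
    illum = np.asarray(illum, dtype=float)
    if np.ndim(Ibg):
        Ibg = np.asarray(Ibg, dtype=float)
        if Ibg.shape != I0.shape:
            raise ValueError(f"shape mismatch: I0 {I0.shape} vs Ibg {Ibg.shape}")
    if illum.shape != I0.shape:
        raise ValueError(f"shape mismatch: I0 {I0.shape} vs illum {illum.shape}")
    mask = illum < eps
    out = np.zeros_like(I0)
    np.divide(I0 - Ibg, illum, out=out, where=~mask)
    return out, mask


# --------------------------------------------------------------------------
# stitching
# --------------------------------------------------------------------------

@dataclass
class StitchResult:
    mosaic: np.ndarray
    offsets: np.ndarray  # (n_tiles, 2): (dx, dy) of each tile origin, px
    fallback: np.ndarray  # per adjacent pair: True if nominal offset used


def _ncc(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    denom = np.linalg.norm(a) * np.linalg.norm(b)
    if denom == 0:
        return 0.0
    return float(np.sum(a * b) / denom)


def stitch_tiles(
    tiles: list[np.ndarray],
    nominal_overlap_px: int,
    search_px: int = 5,
    min_corr: float = 0.5,
) -> StitchResult:
    """Stitch ordered, x-overlapping tiles into a mosaic.

    Pairwise integer offsets are found by maximizing the normalized
    cross-correlation of the overlap strips over ``nominal +- search_px`` in
    x and ``+- search_px`` in y; a pair whose best correlation falls below
    ``min_corr`` falls back to the nominal offset and is flagged.  Tiles are
    cropped and joined without blending (later tiles overwrite).
    """
    if nominal_overlap_px < 8:
        raise ValueError("overlap must be >= 8 px")
    tiles = [np.asarray(t, dtype=float) for t in tiles]
    n = len(tiles)
    h, w = tiles[0].shape
    offsets = np.zeros((n, 2), dtype=int)
    fallback = np.zeros(max(0, n - 1), dtype=bool)
    for k in range(1, n):
        a, b = tiles[k - 1], tiles[k]
        nominal_dx = w - nominal_overlap_px
        best = (-np.inf, nominal_dx, 0)
        for dx in range(nominal_dx - search_px, nominal_dx + search_px + 1):
            ov = w - dx
            if ov < 4 or dx < 0:
                continue
            for dy in range(-search_px, search_px + 1):
                a_rows = slice(max(0, dy), min(h, h + dy))
                b_rows = slice(max(0, -dy), min(h, h - dy))
                strip_a = a[a_rows, dx:]
                strip_b = b[b_rows, :ov]
                c = _ncc(strip_a, strip_b)
                if c > best[0]:
                    best = (c, dx, dy)
        corr, dx, dy = best
        if corr < min_corr:
            dx, dy = nominal_dx, 0
            fallback[k - 1] = True
        offsets[k] = offsets[k - 1] + (dx, dy)
    y_min = offsets[:, 1].min()
    y_max = offsets[:, 1].max()
    mosaic = np.zeros((h + y_max - y_min, offsets[-1, 0] + w))
    for k in range(n):
        x0 = offsets[k, 0]
        y0 = offsets[k, 1] - y_min
        mosaic[y0 : y0 + h, x0 : x0 + w] = tiles[k]
    return StitchResult(mosaic=mosaic, offsets=offsets, fallback=fallback)


# --------------------------------------------------------------------------
# periodicity
# --------------------------------------------------------------------------

@dataclass
class CrossCorrResult:
    corr_map: np.ndarray
    peak_x_px: np.ndarray  # peak centers in track-image x coordinates
    peak_values: np.ndarray
    period_um: float | None


def track_cross_correlation(
    track_image: np.ndarray,
    unit_image: np.ndarray,
    pixel_size: float,
    peak_threshold: float = 0.3,
    min_separation_px: int | None = None,
) -> CrossCorrResult:
    """Normalized 2D cross-correlation of a footprint track with one unit.

    The correlation map is zero-mean and unit-norm per window
    (``skimage.feature.match_template``).  Local maxima of the columnwise
    maximum above ``peak_threshold`` (separated by at least half the
    expected period, i.e. half the unit width, by default) mark the repeats;
    the period is the median inter-peak distance in um, undefined with fewer
    than two peaks.
    """
    track = np.asarray(track_image, dtype=float)
    unit = np.asarray(unit_image, dtype=float)
    if unit.shape[0] > track.shape[0] or unit.shape[1] > track.shape[1]:
        raise ValueError("unit_image must be smaller than track_image")
    corr = match_template(track, unit)
    profile = corr.max(axis=0)
    if min_separation_px is None:
        min_separation_px = max(1, unit.shape[1] // 2)
    peaks, props = find_peaks(profile, height=peak_threshold, distance=min_separation_px)
    centers = peaks + unit.shape[1] // 2  # window origin -> window center
    period = (
        float(np.median(np.diff(peaks)) * pixel_size) if len(peaks) >= 2 else None
    )
    return CrossCorrResult(
        corr_map=corr,
        peak_x_px=centers.astype(float),
        peak_values=props["peak_heights"] if len(peaks) else np.empty(0),
        period_um=period,
    )


def average_period_unit(
    track_image: np.ndarray,
    period_px: int,
    peak_positions_px: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, int]:
    """Pixelwise mean of period-wide crops centered on the repeat positions.

    Partial periods at the track ends are excluded (and counted via the
    returned ``n_used``).  Also returns the contour-ready normalization of
    the mean (background -> 0, maximum -> 1).
    """
    track = np.asarray(track_image, dtype=float)
    period_px = int(round(period_px))
    w = track.shape[1]
    crops = []
    for c in np.asarray(peak_positions_px, dtype=float):
        x0 = int(round(c)) - period_px // 2
        if x0 < 0 or x0 + period_px > w:
            continue
        crops.append(track[:, x0 : x0 + period_px])
    if len(crops) < 2:
        raise ValueError(
            f"need >= 2 complete periods inside the track, got {len(crops)}"
        )
    mean = np.mean(crops, axis=0)
    border = np.concatenate([mean[0], mean[-1]])
    bg = float(np.median(border))
    peak = mean.max()
    norm = np.clip((mean - bg) / (peak - bg) if peak > bg else mean * 0, 0.0, 1.0)
    return mean, norm, len(crops)


def _detect_band_rows(
    track: np.ndarray, k_sd: float = 3.0, n_flank: int = 5
) -> tuple[np.ndarray, float, float]:
    """Rows belonging to the track band, from the transverse mean profile.

    Background statistics come from ``n_flank`` rows at each image edge.
    The threshold is background + max(k_sd * SD, 10% of the profile peak
    above background) -- the relative floor keeps noise-free synthetic bands
    from being inflated by PSF tails.
    """
    profile = track.mean(axis=1)
    flank = np.concatenate([profile[:n_flank], profile[-n_flank:]])
    bg, sd = float(flank.mean()), float(flank.std())
    thr = bg + max(k_sd * sd, 0.1 * (profile.max() - bg))
    above = np.nonzero(profile > thr)[0]
    return above, bg, sd


def footprint_autocorrelation(
    track_image: np.ndarray,
    diameter_um: float,
    pixel_size: float,
    peak_threshold: float = 0.1,
) -> PeriodicityResult:
    """1D autocorrelation of the footprint along x, lag normalized by pi*d.

    The 1D profile is the transverse sum over the detected track band; the
    autocorrelation is mean-subtracted with biased normalization.  The peak
    near normalized lag 1 gives the measured period in um (stored in
    ``meta['period_um']`` and ``period``).
    """
    if diameter_um <= 0:
        raise ValueError("diameter must be > 0")
    track = np.asarray(track_image, dtype=float)
    band, _, _ = _detect_band_rows(track)
    if len(band) < 3:
        raise ValueError(f"detected band is {len(band)} px; >= 3 required")
    profile = track[band].sum(axis=0)
    n_lags = len(profile) - 1
    acf = _acf_biased(profile, n_lags)
    lags_um = np.arange(n_lags + 1) * pixel_size
    circ = np.pi * diameter_um
    lags_norm = lags_um / circ
    # peaks at multiples of the circumference
    min_sep = max(1, int(0.5 * circ / pixel_size))
    peaks, props = find_peaks(acf, height=peak_threshold, distance=min_sep)
    peaks = peaks[peaks > 0]
    period_um = None
    if len(peaks):
        # first repeat peak: the one closest to normalized lag 1 within +-20%
        cand = [p for p in peaks if 0.8 <= lags_norm[p] <= 1.2]
        if cand:
            p0 = cand[int(np.argmax(acf[cand]))]
            period_um = float(lags_um[p0])
    return PeriodicityResult(
        lags=lags_norm,
        acf=acf,
        peak_lags=lags_norm[peaks],
        peak_values=acf[peaks],
        period=period_um,
        lag_unit="circumference",
        meta={"period_um": period_um, "band_rows": band},
    )


def population_footprint_autocorrelation(
    results: list[PeriodicityResult],
    grid: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Average footprint autocorrelations on a common normalized-lag grid."""
    if not results:
        raise ValueError("empty population")
    if grid is None:
        upper = min(r.lags[-1] for r in results)
        grid = np.linspace(0.0, upper, 200)
    acfs = [np.interp(grid, r.lags, r.acf) for r in results]
    return grid, np.mean(acfs, axis=0)


# --------------------------------------------------------------------------
# contact geometry
# --------------------------------------------------------------------------

def contact_width(
    track_image: np.ndarray,
    pixel_size: float,
    k_sd: float = 3.0,
    n_flank: int = 5,
) -> float:
    """Cell-surface contact width (um) from the transverse intensity extent.

    Width spans the contiguous rows whose mean intensity exceeds background
    plus ``k_sd`` flanking-noise SDs (with a 10% relative floor).
    """
    track = np.asarray(track_image, dtype=float)
    band, bg, sd = _detect_band_rows(track, k_sd=k_sd, n_flank=n_flank)
    if len(band) == 0:
        raise ValueError("transverse profile never exceeds the detection threshold")
    return float((band[-1] - band[0] + 1) * pixel_size)


def contact_geometry(width_um: float, diameter_um: float) -> tuple[float, float]:
    """Circular contact area (um^2) and its fraction of the sphere surface (%).

    ``area = pi*(width/2)^2``; ``fraction = 100 * area / (pi * d^2)`` since
    the sphere surface area is pi*d^2.
    """
    if width_um <= 0 or diameter_um <= 0:
        raise ValueError("width and diameter must be > 0")
    if width_um >= diameter_um:
        raise ValueError("contact width must be smaller than the cell diameter")
    area = np.pi * (width_um / 2.0) ** 2
    fraction = 100.0 * area / (np.pi * diameter_um**2)
    return float(area), float(fraction)
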