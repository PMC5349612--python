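"""Synthetic inputs with known ground truth for rolling-adhesion analysis.

Everything downstream (translation/rotation tracking, dwell-time adhesion
maps, fluorescent footprint processing) is validated against the generators
in this module:

* :func:`simulate_rolling_movie` renders a dark-field movie of a sphere
  rolling along the flow axis, driven by an angular adhesion profile
  ``tau(theta)`` (dwell time per radian).  Bright intracellular scatterers
  are rendered as Gaussian spots whose cell-frame projection follows
  ``x_cm = rho * cos(theta + phi)``.
* :func:`simulate_footprint_tiles` lays down rupture events of digital
  (~12 pN threshold) DNA tension sensors along the rolling track as an
  inhomogeneous Poisson process, images them at TIRF resolution, applies a
  vignette and splits the result into overlapping camera tiles.
* :func:`simulate_microvilli_contacts` places microvilli uniformly at random
  on the sphere and counts, per rotation cycle, the tethers formed inside the
  contact band -- the statistical null against which patchy adhesion is
  judged.
* :func:`wall_shear_stress` is the parallel-plate flow-chamber calculator.

All randomness flows through a single integer seed per generator, so equal
seeds give bit-identical outputs.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

TWO_PI = 2.0 * np.pi

__all__ = [
    "AdhesionPatch",
    "AdhesionProfile",
    "CellGeometry",
    "ImagingParams",
    "FlowChannel",
    "FootprintSimParams",
    "RollingTruth",
    "FootprintTruth",
    "ContactCensus",
    "make_adhesion_profile",
    "simulate_rolling_kinematics",
    "simulate_rolling_movie",
    "simulate_rolling_population",
    "simulate_footprint_tiles",
    "simulate_microvilli_contacts",
    "instantaneous_contact_counts",
    "wall_shear_stress",
]


# --------------------------------------------------------------------------
# adhesion profile
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class AdhesionPatch:
    """One adhesive patch on the contact circumference.

    ``center`` and ``width`` are angles in radians; inside the patch the
    dwell time is multiplied by ``1 + multiplier`` relative to baseline
    (overlapping patches combine additively).
    """

    center: float
    width: float
    multiplier: float

    def __post_init__(self) -> None:
        if not (0.0 < self.width < TWO_PI):
            raise ValueError(f"patch width must be in (0, 2*pi), got {self.width}")
        if self.multiplier < 1.0:
            raise ValueError(f"patch multiplier must be >= 1, got {self.multiplier}")


@dataclass(frozen=True)
class AdhesionProfile:
    """2*pi-periodic dwell-time-per-angle profile tau(theta), in s/rad.

    ``tau(theta) = baseline_dwell * (1 + sum of patch multipliers covering
    theta)``; it is strictly positive everywhere.
    """

    baseline_dwell: float
    patches: tuple[AdhesionPatch, ...] = ()
    period: float = field(default=TWO_PI, init=False)

    def __post_init__(self) -> None:
        if self.baseline_dwell <= 0:
            raise ValueError(
                f"baseline_dwell must be > 0 s/rad, got {self.baseline_dwell}"
            )

    def dwell(self, theta: np.ndarray | float) -> np.ndarray:
        """Dwell time tau(theta) in s/rad (vectorized, 2*pi-periodic)."""
        th = np.mod(np.asarray(theta, dtype=float), TWO_PI)
        factor = np.ones_like(th)
        for p in self.patches:
            # periodic distance to patch center
            d = np.abs(np.mod(th - p.center + np.pi, TWO_PI) - np.pi)
            factor = factor + p.multiplier * (d <= p.width / 2.0)
        return self.baseline_dwell * factor

    def omega(self, theta: np.ndarray | float) -> np.ndarray:
        """Angular velocity 1/tau(theta) in rad/s."""
        return 1.0 / self.dwell(theta)

    def cycle_time(self, n_grid: int = 4096) -> float:
        """Time to complete one full rotation: integral of tau over [0, 2*pi)."""
        th = (np.arange(n_grid) + 0.5) * TWO_PI / n_grid
        return float(np.sum(self.dwell(th)) * TWO_PI / n_grid)


def make_adhesion_profile(
    patch_specs: Sequence[tuple[float, float, float]] = (),
    baseline_dwell: float = 0.1,
) -> AdhesionProfile:
    """Build an :class:`AdhesionProfile` from ``(center, width, multiplier)`` triples."""
    patches = tuple(AdhesionPatch(*spec) for spec in patch_specs)
    return AdhesionProfile(baseline_dwell=baseline_dwell, patches=patches)


# --------------------------------------------------------------------------
# geometry / imaging / channel parameter containers
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class CellGeometry:
    """Rolling sphere with intracellular scatterers.

    ``spot_positions`` are 3D coordinates (x, y, z) in um relative to the
    cell center; the rotation axis is y (perpendicular to the flow axis x and
    the optical axis z), so a spot's imaged cell-frame x oscillates as
    ``rho*cos(theta + phi)`` with ``rho = hypot(x, z)``.
    """

    diameter: float = 14.0
    spot_positions: tuple[tuple[float, float, float], ...] = ((4.5, 0.0, 0.0),)

    def __post_init__(self) -> None:
        if self.diameter <= 0:
            raise ValueError(f"diameter must be > 0 um, got {self.diameter}")
        for p in self.spot_positions:
            if np.linalg.norm(p) >= self.diameter / 2.0:
                raise ValueError(
                    f"spot {p} lies outside the sphere (radius {self.diameter / 2.0} um)"
                )

    @property
    def radius(self) -> float:
        return self.diameter / 2.0

    @property
    def spot_rho(self) -> np.ndarray:
        """In-plane radial distance of each spot from the rotation axis (um)."""
        p = np.asarray(self.spot_positions, dtype=float)
        return np.hypot(p[:, 0], p[:, 2])

    @property
    def spot_phase(self) -> np.ndarray:
        """Initial rotation phase of each spot, so x_cm(theta)=rho*cos(theta+phi)."""
        p = np.asarray(self.spot_positions, dtype=float)
        return np.arctan2(p[:, 2], p[:, 0])

    @property
    def spot_y(self) -> np.ndarray:
        p = np.asarray(self.spot_positions, dtype=float)
        return p[:, 1]


@dataclass(frozen=True)
class ImagingParams:
    """Dark-field movie rendering parameters.

    Defaults: 30 fps acquisition and 0.53 um/px (25x magnification on a
    16-um-pixel EMCCD).  ``noise_model`` is ``(gaussian_sd, poisson_scale)``;
    both zero means a noise-free movie.
    """

    pixel_size: float = 0.53
    frame_interval: float = 1.0 / 30.0
    image_shape: tuple[int, int] | None = None
    psf_sigma: float = 0.8
    background_level: float = 10.0
    cell_body_level: float = 25.0
    rim_level: float = 55.0
    rim_sigma: float = 0.5
    spot_amplitude: float = 200.0
    depth_contrast: float = 0.0  # optional visibility modulation with spot depth
    noise_model: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        for name in ("pixel_size", "frame_interval", "psf_sigma"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0, got {getattr(self, name)}")


@dataclass(frozen=True)
class FlowChannel:
    """Parallel-plate flow chamber cross-section and flow conditions.

    ``h0``/``w0`` in um, viscosity ``mu`` in Pa*s, flow rate ``Q`` in uL/hr.
    """

    h0: float = 80.0
    w0: float = 2000.0
    mu: float = 1.0e-3
    Q: float = 100.0

    def __post_init__(self) -> None:
        for name in ("h0", "w0", "mu"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0, got {getattr(self, name)}")
        if self.Q < 0:
            raise ValueError(f"Q must be >= 0 uL/hr, got {self.Q}")
        if self.h0 > self.w0:
            raise ValueError("channel height h0 must not exceed width w0")


def wall_shear_stress(channel: FlowChannel) -> float:
    """Wall shear stress tau_w = 6*mu*Q / (w0 * h0^2) in Pa.

    Infinite-parallel-plate law; valid for wide, shallow channels
    (the default cross-section has a 25:1 aspect ratio).
    """
    q_m3s = channel.Q * 1e-9 / 3600.0  # uL/hr -> m^3/s
    h_m = channel.h0 * 1e-6
    w_m = channel.w0 * 1e-6
    return 6.0 * channel.mu * q_m3s / (w_m * h_m**2)


# --------------------------------------------------------------------------
# rolling kinematics and movie rendering
# --------------------------------------------------------------------------

@dataclass
class RollingTruth:
    """Ground truth for a simulated rolling cell.

    ``theta`` is the cumulative rotation angle (rad), ``x_um`` the centroid
    position along flow, ``detached`` a per-frame flag.  ``spot_phase`` are
    the per-spot phase offsets phi such that the cell-frame projection is
    ``x_cm = rho*cos(theta + phi)``.
    """

    t: np.ndarray
    x_um: np.ndarray
    y_um: np.ndarray
    theta: np.ndarray
    omega: np.ndarray
    detached: np.ndarray
    detachment_intervals: tuple[tuple[float, float], ...]
    diameter: float
    spot_rho: np.ndarray
    spot_phase: np.ndarray
    spot_y: np.ndarray

    def spot_xy_cm(self, i_spot: int) -> tuple[np.ndarray, np.ndarray]:
        """Cell-frame (x, y) trajectory of one spot, in um."""
        x = self.spot_rho[i_spot] * np.cos(self.theta + self.spot_phase[i_spot])
        y = np.full_like(x, self.spot_y[i_spot])
        return x, y


def _in_interval(t: float, intervals: Sequence[tuple[float, float]]) -> bool:
    return any(a <= t < b for a, b in intervals)


def simulate_rolling_kinematics(
    profile: AdhesionProfile,
    geometry: CellGeometry,
    frame_interval: float = 1.0 / 30.0,
    n_cycles: float = 4.0,
    detachment_intervals: Sequence[tuple[float, float]] = (),
    detach_rotation_ratio: float = 0.3,
    detach_speed_factor: float = 3.0,
    y_um: float = 0.0,
    substeps: int = 20,
) -> RollingTruth:
    """Integrate theta(t), x(t) for a rolling sphere without rendering images.

    During traction the sphere advances by ``dx = r*dtheta`` with
    ``dtheta = dt / tau(theta)``.  Inside ``detachment_intervals`` (seconds)
    the cell floats: translational speed is elevated by
    ``detach_speed_factor`` relative to the mean rolling speed and rotation
    per distance drops to ``r*dtheta/dx = detach_rotation_ratio`` (<= 0.5).
    """
    if n_cycles < 1:
        raise ValueError(f"n_cycles must be >= 1, got {n_cycles}")
    r = geometry.radius
    cycle_time = profile.cycle_time()
    mean_speed = TWO_PI * r / cycle_time  # um/s while rolling
    detach_total = sum(b - a for a, b in detachment_intervals)
    total_time = n_cycles * cycle_time + detach_total
    n_frames = int(np.ceil(total_time / frame_interval)) + 1

    dt_sub = frame_interval / substeps
    t = 0.0
    theta = 0.0
    x = 0.0
    ts = np.empty(n_frames)
    xs = np.empty(n_frames)
    thetas = np.empty(n_frames)
    detached = np.zeros(n_frames, dtype=bool)
    for i in range(n_frames):
        ts[i] = t
        xs[i] = x
        thetas[i] = theta
        detached[i] = _in_interval(t, detachment_intervals)
        for _ in range(substeps):
            if _in_interval(t, detachment_intervals):
                v = detach_speed_factor * mean_speed
                dx = v * dt_sub
                dth = detach_rotation_ratio * dx / r
            else:
                dth = dt_sub / float(profile.dwell(theta))
                dx = r * dth
            theta += dth
            x += dx
            t += dt_sub
    omega = np.gradient(thetas, ts)
    return RollingTruth(
        t=ts,
        x_um=xs,
        y_um=np.full(n_frames, y_um),
        theta=thetas,
        omega=omega,
        detached=detached,
        detachment_intervals=tuple(tuple(iv) for iv in detachment_intervals),
        diameter=geometry.diameter,
        spot_rho=geometry.spot_rho,
        spot_phase=geometry.spot_phase,
        spot_y=geometry.spot_y,
    )


def _render_frames(
    truth: RollingTruth,
    geometry: CellGeometry,
    imaging: ImagingParams,
    rng: np.random.Generator | None,
) -> np.ndarray:
    px = imaging.pixel_size
    r = geometry.radius
    margin = r + 4.0 * imaging.psf_sigma + 2.0  # um on each side
    x_min = truth.x_um.min() - margin
    x_max = truth.x_um.max() + margin
    width_req = int(np.ceil((x_max - x_min) / px))
    height_req = int(np.ceil(2.0 * margin / px))
    if imaging.image_shape is not None:
        h, w = imaging.image_shape
        if h < height_req or w < width_req:
            raise ValueError(
                "movie would exceed image bounds: requires at least "
                f"({height_req}, {width_req}) px, got ({h}, {w})"
            )
    else:
        h, w = height_req, width_req

    yy = (np.arange(h) - (h - 1) / 2.0) * px  # um, 0 at image center row
    xx = np.arange(w) * px + x_min  # um in lab frame
    X, Y = np.meshgrid(xx, yy)
    rho = geometry.spot_rho
    phase = geometry.spot_phase
    spot_y = geometry.spot_y

    frames = np.empty((len(truth.t), h, w), dtype=np.float32)
    sig2 = 2.0 * imaging.psf_sigma**2
    for i, (xc, yc, th) in enumerate(zip(truth.x_um, truth.y_um, truth.theta)):
        d = np.hypot(X - xc, Y - yc)
        img = np.full((h, w), imaging.background_level, dtype=float)
        img += imaging.cell_body_level * (d < r)
        img += imaging.rim_level * np.exp(-((d - r) ** 2) / (2.0 * imaging.rim_sigma**2))
        for j in range(len(rho)):
            sx = xc + rho[j] * np.cos(th + phase[j])
            sy = yc + spot_y[j]
            amp = imaging.spot_amplitude
            if imaging.depth_contrast:
                depth = np.sin(th + phase[j])  # +1 near objective, -1 far side
                amp = amp * (1.0 + imaging.depth_contrast * depth)
            img += amp * np.exp(-((X - sx) ** 2 + (Y - sy) ** 2) / sig2)
        g_sd, p_scale = imaging.noise_model
        if rng is not None and p_scale > 0:
            img = rng.poisson(np.clip(img, 0, None) * p_scale) / p_scale
        if rng is not None and g_sd > 0:
            img = img + rng.normal(0.0, g_sd, size=img.shape)
        frames[i] = img
    return frames


def simulate_rolling_movie(
    profile: AdhesionProfile,
    geometry: CellGeometry,
    imaging: ImagingParams | None = None,
    detachment_intervals: Sequence[tuple[float, float]] = (),
    n_cycles: float = 4.0,
    seed: int | None = None,
    **kinematics_kwargs,
) -> tuple[np.ndarray, RollingTruth]:
    """Render a dark-field movie of one rolling cell and return its ground truth.

    The cell body is a dim disk with a brighter rim; each scatterer is a
    Gaussian of ``psf_sigma`` at its projected position.  Returns
    ``(movie, truth)`` with ``movie`` of shape ``(n_frames, H, W)`` float32.
    """
    imaging = imaging or ImagingParams()
    truth = simulate_rolling_kinematics(
        profile,
        geometry,
        frame_interval=imaging.frame_interval,
        n_cycles=n_cycles,
        detachment_intervals=detachment_intervals,
        **kinematics_kwargs,
    )
    rng = np.random.default_rng(seed) if seed is not None else None
    movie = _render_frames(truth, geometry, imaging, rng)
    return movie, truth


def simulate_rolling_population(
    n_cells: int = 30,
    diameter_mean: float = 14.1,
    diameter_sd: float = 1.0,
    baseline_dwell: float = 0.2,
    n_cycles: float = 6.5,
    angular_noise_deg: float = 2.0,
    tracking_noise_um: float = 0.5,
    detach_every_cycles: tuple[float, float] = (1.0, 2.0),
    detach_duration_cycles: tuple[float, float] = (0.3, 1.0),
    seed: int = 0,
) -> list[dict]:
    """A population of rolling cells with patchy adhesion and detachments.

    Each cell gets a diameter drawn from N(mean, sd), 1-3 random adhesion
    patches, transient detachments roughly every 1-2 rolling cycles, and
    measurement noise at the tracking precision (~0.5 um translation, ~2 deg
    angle).  Returns one record per cell with the ground truth and the
    noise-added measured traces (``theta_meas``, ``x_meas``).
    """
    rng = np.random.default_rng(seed)
    cells = []
    for _ in range(n_cells):
        d = float(rng.normal(diameter_mean, diameter_sd))
        patches = [
            (rng.uniform(0, TWO_PI), rng.uniform(0.3, 0.9) * np.pi, rng.uniform(3, 8))
            for _ in range(rng.integers(1, 4))
        ]
        profile = make_adhesion_profile(patches, baseline_dwell)
        ct = profile.cycle_time()
        det_ivs = []
        t_next = rng.uniform(*detach_every_cycles) * ct
        for _ in range(4):
            dur = rng.uniform(*detach_duration_cycles) * ct
            det_ivs.append((t_next, t_next + dur))
            t_next = t_next + dur + rng.uniform(*detach_every_cycles) * ct
        geometry = CellGeometry(diameter=d, spot_positions=((0.3 * d, 0.0, 0.0),))
        truth = simulate_rolling_kinematics(
            profile, geometry, n_cycles=n_cycles, detachment_intervals=det_ivs
        )
        n = len(truth.t)
        cells.append(
            {
                "truth": truth,
                "profile": profile,
                "diameter": d,
                "theta_meas": truth.theta
                + rng.normal(0.0, np.deg2rad(angular_noise_deg), n),
                "x_meas": truth.x_um + rng.normal(0.0, tracking_noise_um, n),
            }
        )
    return cells


# --------------------------------------------------------------------------
# adhesion footprint tiles
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class FootprintSimParams:
    """Parameters for the fluorescent adhesion-footprint simulator.

    ``rupture_density_scale`` is the surface density of rupture events
    (events/um^2) where the dwell multiplier is 1; patches scale it by
    ``tau/baseline``.  ``rupture_force_threshold`` documents the digital
    sensor threshold (pN); events below it are by construction absent.
    ``event_sigma_um`` is the rendered PSF sigma (~250 nm FWHM optics).
    """

    track_band_width: float = 5.7
    rupture_density_scale: float = 5.0
    rupture_force_threshold: float = 12.0
    event_sigma_um: float = 0.25 / 2.355
    pixel_size: float = 0.16
    tile_shape: tuple[int, int] = (80, 256)
    tile_overlap: int = 32
    illum_field: np.ndarray | None = None
    background_level: float = 5.0
    noise_sd: float = 0.0
    tile_jitter_px: int = 0  # random stage error on each tile cut position

    def __post_init__(self) -> None:
        if self.track_band_width <= 0:
            raise ValueError("track_band_width must be > 0 um")
        if self.tile_overlap >= min(self.tile_shape):
            raise ValueError("tile_overlap must be smaller than the tile dimensions")
        if self.illum_field is not None:
            f = np.asarray(self.illum_field, dtype=float)
            if f.shape != tuple(self.tile_shape):
                raise ValueError("illum_field must have tile_shape")
            if f.min() <= 0 or not np.isclose(f.max(), 1.0):
                raise ValueError("illum_field values must be in (0, 1] with max 1")


@dataclass
class FootprintTruth:
    """Ground truth for a simulated footprint: event coordinates (um, track
    frame), true tile x-offsets (px), the clean un-split mosaic, and the true
    spatial period pi*d (um)."""

    event_xy_um: np.ndarray
    tile_offsets_px: np.ndarray
    clean_image: np.ndarray
    pixel_size: float
    band_center_row: int
    band_width_um: float
    period_um: float


def simulate_footprint_tiles(
    profile: AdhesionProfile,
    geometry: CellGeometry,
    fp_params: FootprintSimParams | None = None,
    track_length_cycles: float = 3.0,
    seed: int | None = 0,
) -> tuple[list[np.ndarray], FootprintTruth]:
    """Simulate overlapping TIRF tiles of one rolling-cell adhesion footprint.

    Rupture events follow an inhomogeneous Poisson process with surface rate
    ``rupture_density_scale * tau(x/r)/baseline`` inside a transverse top-hat
    band of width ``track_band_width``; each event is rendered as a Gaussian
    at optical resolution.  Tiles are cut along x with ``tile_overlap``
    columns of overlap; each tile is multiplied by the illumination field and
    offset by the background level.
    """
    if track_length_cycles < 2:
        raise ValueError(
            f"track_length_cycles must be >= 2 for periodicity, got {track_length_cycles}"
        )
    fp = fp_params or FootprintSimParams()
    if fp.rupture_density_scale <= 0:
        raise ValueError("rupture_density_scale must be > 0 (zero event rate everywhere)")
    px = fp.pixel_size
    tile_h, tile_w = fp.tile_shape
    if fp.track_band_width >= tile_h * px:
        raise ValueError(
            f"track band ({fp.track_band_width} um) wider than image height ({tile_h * px} um)"
        )
    r = geometry.radius
    track_len = track_length_cycles * TWO_PI * r  # um along x
    margin = 2.0  # um of empty track on each end
    x0 = margin

    # --- full-width layout so tiles cover the mosaic exactly -------------
    step = tile_w - fp.tile_overlap
    width_min = int(np.ceil((track_len + 2 * margin) / px))
    n_tiles = max(1, int(np.ceil((width_min - fp.tile_overlap) / step)))
    width = (n_tiles - 1) * step + tile_w
    height = tile_h

    rng = np.random.default_rng(seed)

    # --- inhomogeneous Poisson draw along x ------------------------------
    n_grid = max(2048, int(track_len / 0.05))
    xg = np.linspace(0.0, track_len, n_grid)
    rate_x = fp.rupture_density_scale * (
        profile.dwell(xg / r) / profile.baseline_dwell
    )  # events per um^2, uniform across the band
    lam_total = np.trapezoid(rate_x, xg) * fp.track_band_width
    n_events = rng.poisson(lam_total)
    cdf = np.cumsum(rate_x)
    cdf = cdf / cdf[-1]
    ev_x = x0 + np.interp(rng.random(n_events), cdf, xg)
    band_center = height * px / 2.0
    ev_y = band_center + (rng.random(n_events) - 0.5) * fp.track_band_width
    events = np.column_stack([ev_x, ev_y])

    # --- render the clean mosaic -----------------------------------------
    clean = np.zeros((height, width), dtype=float)
    sig_px = fp.event_sigma_um / px
    half = max(3, int(np.ceil(4 * sig_px)))
    for ex, ey in events:
        cx, cy = ex / px, ey / px
        ix, iy = int(round(cx)), int(round(cy))
        x_lo, x_hi = max(0, ix - half), min(width, ix + half + 1)
        y_lo, y_hi = max(0, iy - half), min(height, iy + half + 1)
        if x_lo >= x_hi or y_lo >= y_hi:
            continue
        gx = np.arange(x_lo, x_hi) - cx
        gy = np.arange(y_lo, y_hi) - cy
        clean[y_lo:y_hi, x_lo:x_hi] += np.exp(
            -(gy[:, None] ** 2 + gx[None, :] ** 2) / (2.0 * sig_px**2)
        )

    # --- split into overlapping tiles; vignette is a camera-frame property
    offsets = np.array([k * step for k in range(n_tiles)], dtype=int)
    if fp.tile_jitter_px > 0 and n_tiles > 1:
        jit = rng.integers(-fp.tile_jitter_px, fp.tile_jitter_px + 1, size=n_tiles)
        jit[0] = 0
        offsets = np.clip(offsets + jit, 0, width - tile_w)
        offsets = np.maximum.accumulate(offsets)  # keep tiles ordered
    tiles = []
    for off in offsets:
        tile = clean[:, off : off + tile_w].copy()
        if fp.illum_field is not None:
            tile = tile * np.asarray(fp.illum_field, dtype=float)
        tile = tile + fp.background_level
        if fp.noise_sd > 0:
            tile = tile + rng.normal(0.0, fp.noise_sd, size=tile.shape)
        tiles.append(tile)

    truth = FootprintTruth(
        event_xy_um=events,
        tile_offsets_px=offsets,
        clean_image=clean,
        pixel_size=px,
        band_center_row=height // 2,
        band_width_um=fp.track_band_width,
        period_um=TWO_PI * r,
    )
    return tiles, truth


# --------------------------------------------------------------------------
# microvilli contact Monte-Carlo
# --------------------------------------------------------------------------

@dataclass
class ContactCensus:
    """Per-angular-bin microvilli tether counts for a rolling sphere.

    ``tether_counts`` has shape ``(n_cycles, n_bins)``; rows are identical
    because villus placement is fixed after the random draw (every band
    villus re-forms a tether at the same rotation angle each cycle).
    """

    n_villi: int
    receptors_per_villus: int
    diameter: float
    band_width: float
    bin_edges: np.ndarray
    tether_counts: np.ndarray
    expected_footprint: np.ndarray
    footprint_extent_um: tuple[float, float]  # (x span, y span)
    villi_xyz: np.ndarray
    truncated_last_bin: bool


def simulate_microvilli_contacts(
    geometry: CellGeometry,
    n_villi: int = 730,
    receptors_per_villus: int = 17,
    band_width: float = 5.7,
    n_cycles: int = 3,
    bin_width: float = TWO_PI / 12,
    seed: int | None = 0,
    footprint_bin_um: float = 0.2,
) -> ContactCensus:
    """Roll a sphere with randomly placed microvilli and census its tethers.

    Villi are placed area-uniformly on the sphere.  A villus within
    ``band_width/2`` of the rolling plane forms one tether per rotation
    cycle, binned at the rotation angle at which it enters the bottom contact
    region.  The expected footprint is the receptor-weighted event map at the
    unrolled contact coordinates.
    """
    if n_villi < 1:
        raise ValueError("n_villi must be >= 1")
    r = geometry.radius
    if band_width >= geometry.diameter:
        raise ValueError("band_width must be smaller than the cell diameter")
    rng = np.random.default_rng(seed)

    # area-uniform placement: y uniform in [-r, r], azimuth uniform
    y = r * (2.0 * rng.random(n_villi) - 1.0)
    psi = TWO_PI * rng.random(n_villi)
    rho = np.sqrt(np.clip(r**2 - y**2, 0.0, None))
    xyz = np.column_stack([rho * np.cos(psi), y, rho * np.sin(psi)])

    n_bins_exact = TWO_PI / bin_width
    n_bins = int(np.floor(n_bins_exact + 1e-9))
    truncated = not np.isclose(n_bins_exact, round(n_bins_exact))
    if truncated:
        n_bins += 1  # last bin truncated at 2*pi
    edges = np.minimum(np.arange(n_bins + 1) * bin_width, TWO_PI)

    in_band = np.abs(y) <= band_width / 2.0
    entry_angle = np.mod(-psi, TWO_PI)  # rotation angle at which villus reaches contact
    counts_one = np.histogram(entry_angle[in_band], bins=edges)[0]
    tether_counts = np.tile(counts_one, (n_cycles, 1))

    # receptor-weighted expected footprint at unrolled contact coordinates
    x_unrolled = r * entry_angle[in_band]
    y_contact = y[in_band]
    x_span = TWO_PI * r
    nx = max(4, int(np.ceil(x_span / footprint_bin_um)))
    ny = max(4, int(np.ceil(band_width / footprint_bin_um)))
    fp, _, _ = np.histogram2d(
        y_contact,
        x_unrolled,
        bins=[ny, nx],
        range=[[-band_width / 2.0, band_width / 2.0], [0.0, x_span]],
    )
    fp *= receptors_per_villus

    return ContactCensus(
        n_villi=n_villi,
        receptors_per_villus=receptors_per_villus,
        diameter=geometry.diameter,
        band_width=band_width,
        bin_edges=edges,
        tether_counts=tether_counts,
        expected_footprint=fp,
        footprint_extent_um=(x_span, band_width),
        villi_xyz=xyz,
        truncated_last_bin=truncated,
    )


def instantaneous_contact_counts(
    census: ContactCensus,
    thetas: np.ndarray | None = None,
) -> np.ndarray:
    """Number of villi inside the contact patch at each rotation angle.

    The contact patch is circular (geodesic cap of radius ``band_width/2``
    around the instantaneous bottom point of the sphere), consistent with the
    circular contact-area approximation; its area is ~pi*(band_width/2)^2.
    """
    r = census.diameter / 2.0
    cap = census.band_width / 2.0  # geodesic radius, um
    cos_cap = np.cos(cap / r)
    if thetas is None:
        thetas = np.linspace(0.0, TWO_PI, 73)[:-1]
    xyz = census.villi_xyz
    rho = np.hypot(xyz[:, 0], xyz[:, 2])
    psi = np.arctan2(xyz[:, 2], xyz[:, 0])
    y = xyz[:, 1]
    counts = np.empty(len(thetas), dtype=int)
    # bottom point direction in the rolling plane advances with theta
    for i, th in enumerate(thetas):
        # villus unit position after rotating by th about y; bottom = azimuth 0 plane
        az = psi + th
        cos_gc = (rho * np.cos(az)) / r  # cos of geodesic angle to bottom point,
        # bottom point at (r, 0, 0) in this convention; y contributes via rho<r
        counts[i] = int(np.sum(cos_gc >= cos_cap))
    return counts
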