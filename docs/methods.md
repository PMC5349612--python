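# Methods

`rollmap` analyzes rolling adhesion — the passive rolling of leukocyte-like
cells along a receptor-coated wall under shear flow — by two complementary
routes: (i) label-free rotation tracking of intracellular scatterers in
dark-field movies, which yields a dwell-time adhesion map around the cell's
contact circumference, and (ii) fluorescent adhesion footprints left by
digital DNA tension sensors, imaged as TIRF tiles. Everything is validated
against synthetic data with exact ground truth; this note records the models,
the parameters that matter, and the design decisions taken where a choice was
genuinely open.

## Rolling model and simulators

A cell of diameter `d` (default 14–14.1 µm) is modeled as a rigid sphere
rolling along the flow axis x, rotation axis y. Local adhesion strength is
encoded as a 2π-periodic dwell time per unit angle `τ(θ)` (s/rad):

```
τ(θ) = τ0 · (1 + Σ_patches m_i · 1[|θ − c_i| ≤ w_i/2])
```

with baseline `τ0` (default 0.2–0.3 s/rad, giving rolling speeds of a few
µm/s at `v = rω`, typical of slow selectin-mediated rolling at low shear) and
additive patch multipliers. During traction the kinematics are `dθ = dt/τ(θ)`
and `dx = r·dθ`. Transient detachments — the cell lifting off and being
convected near the wall — elevate the translational speed (default 3× the
mean rolling speed) while the rotation per distance drops to
`r·dθ/dx = 0.3` (configurable; anything ≤ 0.5 reads as detached). The
integrator uses 20 Euler substeps per frame at 30 fps, which keeps the
per-frame integration error far below the imaging noise.

Movies are rendered at 0.53 µm/px (25× on a 16-µm-pixel EMCCD): the cell body
as a dim disk with a brighter rim (dark-field contrast), each scatterer as a
Gaussian of σ = 0.8 µm at its projected position
`x_cm = ρ·cos(θ + φ)`, `y_cm` constant. Out-of-focus blur is not modeled and
depth-dependent spot amplitude is available but off by default. Noise is
optional Gaussian read noise plus Poisson shot noise; the default movie is
noise-free so that parameter-recovery tests isolate algorithmic error.

What the movie simulator deliberately does not emulate: cell deformation,
off-axis precession of the rotation axis, spot mobility inside the cell, and
focus drift. Passing tests therefore demonstrate correctness of the
reconstruction pipeline, not robustness to every pathology of real data.

The footprint simulator draws rupture events of ~12 pN-threshold DNA tension
sensors from an inhomogeneous Poisson process with surface density
`ρ(x) = ρ0 · τ(x/r)/τ0` inside a transverse top-hat band of width 5.7 µm
(the measured contact width): regions where the cell dwells longer rupture
proportionally more tethers. Events are rendered as Gaussians at the
optical resolution (σ ≈ 106 nm, i.e. 250 nm FWHM) at 0.16 µm/px, multiplied
per tile by an illumination vignette (vignetting is a camera-frame property,
so it applies to each tile, not to the assembled mosaic), offset by a
constant background, and cut into overlapping tiles whose positions can
carry a random stage jitter.

The microvilli Monte-Carlo places `n` villi (default 730, each carrying 17
PSGL-1) area-uniformly on the sphere. A villus within half a band width of
the rolling plane forms exactly one tether per rotation cycle, binned at the
rotation angle at which it reaches the contact region; the instantaneous
contact count uses a circular contact patch (geodesic cap of radius half the
band width, area ≈ π·(w/2)² ≈ 26 µm²), consistent with the circular
contact-area approximation used for the geometry numbers. This is the
statistical null: random placement produces Poisson-level bin-to-bin
variation (CV ≈ 1/√mean), never order-of-magnitude patches.

The flow-chamber calculator uses the infinite-parallel-plate law
`τw = 6µQ/(w0·h0²)` (80 µm × 2 mm cross-section, 25:1 aspect ratio;
µ defaults to 1.0 mPa·s and is configurable).

## Rotation reconstruction

1. **Segmentation/linking** — per-frame Otsu threshold, hole filling,
   connected components (≥ 50 px), greedy nearest-neighbor linking with a
   one-radius gate and deterministic ties (smaller y). Tracking precision on
   synthetic movies is well under 0.5 µm.
2. **Cell frame** — integer-pixel crops centered on the centroid; the
   sub-pixel residual is recorded and folded into feature coordinates rather
   than interpolating the image (interpolation would smooth the spots).
3. **Feature detection** — a stable-extremal-region detector: seeds at local
   maxima above background + max(5·MAD, 25% of dynamic range), region area
   tracked over a descending 24-level threshold ladder, kept where the
   relative area growth over ±2 levels is below 0.5 and the area stays in
   [4, 150] px. Centroids are refined by an iterated Gaussian-tapered
   (σ = 2 px), background-subtracted weighted centroid — the taper stops
   neighboring spots and the bright rim from pulling the estimate. A
   Laplacian-of-Gaussian detector is available behind the same contract.
4. **Radial distance** — default `R = max|x_cm|` over the trajectory (it
   requires at least one full oscillation, i.e. ≥ 2 prominent turning
   points). The max is biased high under noise; a percentile estimator
   (default 95th — the 99th retains most of the max's bias) and a cosine fit
   are provided. The cosine fit assumes constant ω and is unreliable for
   strongly patchy profiles.
5. **Angle unfolding** — `θ_raw = arccos(clip(x/R, −1, 1))` lives on [0, π];
   alternating intervals are flipped about π (`θ' = 2π − θ`). Turning points
   are peaks of `θ_raw` committed only at a prominence of 0.15 rad
   (hysteresis): arccos amplifies noise near its ends, and a
   prominence criterion also tolerates an over-estimated R, with which the
   raw angle never quite reaches 0 or π. Samples with |x|/R above 1.1 are
   dropped as mislinks; those between 1 and 1.1 are clamped and flagged.
6. **Merging** — per-feature relative angles differ from the cell's rotation
   by a constant phase; offsets are removed by circular means against the
   longest trace (traces with circular residual RMS > π/4 are excluded) and
   the merged angle is a per-frame circular mean weighted by `|sin θ| + 0.05`,
   down-weighting each trace exactly where its arccos is noise-amplifying.
   Unfolding happens per feature, before merging.
7. **Cumulative angle, ω, traction** — 2π is added at every wrap (negative
   jump > π); ω is a central-difference derivative with optional moving
   average. The traction metric `r·dθ/dx` is a windowed (11-frame)
   least-squares slope — less noisy than endpoint differences — labeled
   rolling ≥ 0.75, detached ≤ 0.5, else ambiguous; windows with |Δx| below
   0.05 µm (stalls) are ambiguous rather than division errors.
8. **Circumference** — the slope of θ vs x on rolling samples gives
   `d = 2/slope`. Rolling segments separated by detachments are demeaned
   independently before a pooled fit (a detachment advances x without the
   matching rotation, so a naive single fit is biased). At least 4 rolling
   cycles are required.

On noise-free rendered movies the full pipeline recovers cumulative θ with
RMS ≈ 0.017 rad (≈ 1°, against a 2° benchmark) and the diameter to 0.1%.
A practical geometry note: scatterers closer than ~3 µm along the rotation
axis produce blended images whenever their projected x positions cross,
which fragments trajectories; real cells with 2–4 well-separated granules
are the favorable case this models.

## Dwell-time maps and periodicity

`τ = 1/ω` on rolling samples (samples with ω below 1% of the median are
excluded as stalls) is resampled by linear interpolation onto a uniform
cumulative-θ grid of 100 bins per 2π (3.6°/bin, above the ~2° angular noise).
Stacking across cycles (boundaries at 2πk) gives the per-angle mean ± SD map;
the polar export shows the log-scale radial profile with an SD band plus a
linear color ring.

The periodicity estimator is the mean-subtracted autocorrelation with biased
(1/N) normalization — chosen for variance stability at long lags; note it
multiplies the true correlation by (1 − k/N), so finite-sample peak heights
at lag 2πn are attenuated accordingly. Peaks are local maxima within ±0.2π
of 2πn. The characteristic patch size is the full width of the zero-lag peak
at half height divided by 2π, where "half height" is midway between 1 and
the minimum of the autocorrelation within the first period: for a top-hat
patch of width w this definition returns exactly w (a fixed 0.5 crossing
does not, because the mean-subtracted baseline shifts with patch duty
cycle); a fixed-0.5 variant is available. When the autocorrelation never
falls below the level, the fraction is reported as ≥ 0.5 and flagged.

The positional control repeats the analysis with dwell per unit distance
(1/v, from translational tracking alone) over x. On a 30-cell population
(d ~ N(14.1, 1.0) µm, 1–3 random patches each, transient detachments every
1–2 cycles, 2° angular and 0.5 µm positional noise) the angle-based
population autocorrelation keeps its 2π peak while diameter dispersion and
detachment phase slips wash out the peak at π⟨d⟩ — the quantitative argument
for rotation tracking, reproduced at a ≥ 3× peak ratio.

## Footprint image pipeline

Flat-field correction follows `I_corr = (I0 − Ibg)/I_illum`, with the
illumination profile estimated as the normalized average of many tiles
(optionally Gaussian-smoothed; the normalization reads the scale at the
argmax of a heavily smoothed copy, because the plain maximum of a noisy
average overshoots and biases the whole profile low). Pixels with
illumination below a floor are masked and counted. Stitching estimates
pairwise integer offsets by maximizing the normalized cross-correlation of
overlap strips within a search window (set it to at least twice the stage
jitter); a pair whose best correlation is below 0.5 falls back to the
nominal offset and is flagged; tiles are joined without blending.

Periodicity comes from two estimators that must agree: (i) normalized 2D
cross-correlation of the track with one repeating unit (zero-mean, unit-norm
per window), peaks along x above 0.3 separated by at least half the expected
period, period = median peak spacing; and (ii) the 1D autocorrelation of the
transverse band sum along x, lag axis normalized by πd. Per-period crops
centered on the peaks average into the mean repeating unit (background → 0,
max → 1 for contour display). The contact width is the contiguous transverse
extent above background + max(3·SD, 10% of peak) — the relative floor keeps
the estimate from inflating along PSF tails when the flanking noise is
negligible — and the contact geometry is `area = π(w/2)²`,
`fraction = area/(πd²)`.

## Numerical choices and degenerate inputs

- All random draws flow through `numpy.random.default_rng(seed)`; identical
  seeds give bit-identical outputs (tested).
- Empty frames, zero-cell movies, featureless overlaps, stalled cells and
  aperiodic tracks are reported (empty results, flags, "period undefined"),
  not raised; genuinely unusable inputs (zero event rate, band wider than
  the image, fewer than 2 cycles/periods, R = 0) are rejected with messages
  naming the offending quantity.
- CSV outputs carry a config-hash comment line; the hash excludes the output
  directory so identical analyses reproduce identical bytes anywhere.

## Known limitations

- The rigid-sphere model ignores deformation-induced contact-area changes
  and rotation-plane drift; both reduce footprint periodicity in real data
  (the fraction of real tracks without clear periodicity has no synthetic
  counterpart here).
- The dwell-time proxy conflates bond lifetime, receptor density and tether
  mechanics into one number per angle; no catch-bond kinetics are modeled.
- MSER stability parameters are detector defaults chosen on synthetic
  dark-field renders; real movies may need retuning, which is why the LoG
  fallback exists.
- The parallel-plate shear formula with µ = 1.0 mPa·s gives 0.013–0.65 Pa
  over 100–5000 µL/hr; the upper end depends on the viscosity actually used,
  which is exposed as a parameter.
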