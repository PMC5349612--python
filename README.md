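# rollmap

Label-free mapping of cell-surface adhesion from rolling motion.

Leukocytes (and circulating tumor cells) roll along vessel walls under shear
flow, held by transient selectin–ligand bonds. Where on the cell surface the
adhesive strength actually sits is invisible to conventional assays, which
track only the cell centroid. `rollmap` implements two complementary ways to
see it:

1. **Rotation tracking.** Dark-field movies of rolling cells show bright
   intracellular granules that rotate with the cell. Tracking them in the
   cell's own reference frame gives the projected trace
   `x_cm(t) = R·cos θ(t)`; inverting it (with the arccos degeneracy unfolded
   by flipping alternating intervals about π) yields the cumulative rotation
   angle θ(t). The **dwell time per unit angle, τ(θ) = 1/ω(θ)**, is the
   proxy for local adhesion strength: stacking it over 2π rolling cycles
   produces a per-angle adhesion map, and the autocorrelation of τ over
   cumulative θ shows peaks at 2nπ when the adhesion pattern repeats each
   cycle. The traction metric **r·dθ/dx** separates true rolling (≈ 1) from
   transient detachment (≤ 0.5), and the slope of θ vs x measures the cell
   circumference (d = 2/slope).
2. **Adhesion footprints.** Rolling over a lawn of ~12 pN digital DNA
   tension sensors ruptures tethers wherever the cell grips; labeling the
   ruptured strands leaves a fluorescent track whose intensity pattern
   repeats with spatial period **πd**. The pipeline flat-fields
   (`(I0 − Ibg)/I_illum`), stitches overlapping TIRF tiles at integer
   offsets, extracts the period by 2D cross-correlation against one
   repeating unit and by 1D autocorrelation normalized by πd, and measures
   the contact width/area.

A third component simulates all inputs with exact ground truth (rolling
movies with patchy adhesion profiles and detachments, footprint tiles with
vignette and stage jitter, a rolling sphere with randomly placed microvilli),
so every stage is testable without experimental data. See
`docs/methods.md` for models, parameters and design decisions.

## Worked example

Simulate a rolling cell with one strong adhesion patch, then run the full
rotation pipeline:

```python
import numpy as np
from rollmap import synthlab as sl, trackcore as tc, rotrack as rt, adhesionmap as am

profile = sl.make_adhesion_profile([(np.pi, np.pi/2, 5.0)], baseline_dwell=0.3)
geom = sl.CellGeometry(diameter=14.0,
                       spot_positions=((4.5, 0, 0), (-1.0, 3.2, 4.2), (2.5, -3.3, -3.0)))
movie, truth = sl.simulate_rolling_movie(profile, geom, n_cycles=4.5)

detections = tc.segment_movie(movie, pixel_size=0.53)
track = tc.link_cell_tracks(detections, max_jump_um=7.0)[0]
stack = tc.crop_cell_frame(movie, track, box_half_width_um=10.0, pixel_size=0.53)
trace, trajs = rt.rotation_pipeline(stack, frame_interval=1/30)
rt.traction_classification(trace, track, radius_um=7.0)

d = rt.circumference_from_slope(trace, track)
rms = np.sqrt(np.mean((trace.theta_cum - truth.theta[trace.frames]
                       - np.median(trace.theta_cum - truth.theta[trace.frames]))**2))
print(f"diameter {d:.2f} um, theta RMS {np.degrees(rms):.2f} deg")

grid, tau = am.resample_dwell(am.dwell_time(trace))
res = am.dwell_autocorrelation(grid, tau)
print("autocorrelation peaks at", np.round(res.peak_lags / np.pi, 2), "x pi")
```

Output:

```
diameter 14.00 um, theta RMS 1.00 deg
autocorrelation peaks at [2. 4.] x pi
```

The diameter is recovered to 0.01 µm from the θ-vs-x slope, the rotation
angle to 1° RMS, and the dwell-time autocorrelation peaks at even multiples
of π — the signature of an adhesion pattern repeating every rolling cycle.

A command-line interface wraps the same pipelines:

```bash
rollmap simulate-movie --out sim --seed 3
rollmap map --movie sim/movie.tif --pixel-size 0.53 --frame-interval 0.0333 --out mapped
rollmap simulate-footprint --out fpt --seed 5
rollmap footprint --tiles fpt/tiles.tif --pixel-size 0.16 --overlap 32 --out fpo
rollmap report --per-track fpo/per_track.csv --out report.json
```

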