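# Methods

This note documents the models, algorithms, parameter choices and known
limitations of `sostrack`, in the order the pipeline runs.

## Coordinate conventions

0-based row/column pixel indices, origin top-left, `x` = column
(rightward), `y` = row (downward). Points are `(x, y)` pairs; images are
indexed `[row, col]`. Bounding boxes are half-open `(x0, y0, w, h)` with
the offset at the top-left corner. Pixel `(r, c)` has its centre at arena
position `(c·s, r·s)` for scale `s` mm/px. Angles are degrees, 0° along
+x, increasing clockwise on screen (because y points down).

## Synthetic fixtures

The generator renders the body as a **constant-halfwidth capsule**: the
set of points within one halfwidth `w` of a midline polyline, giving
semicircular caps whose area (`2ℓw + πw²`) and cap curvature (`1/w`) are
analytically checkable. Rasterization is a hard test `dist ≤ w` at pixel
centres (no anti-aliasing by default, so segmentation oracles are exact;
a 1-px soft edge is available via `soft_edge`). Gaussian pixel noise
(i.i.d., clipped to [0, 255]) is added after compositing; one
`numpy` generator seeded from `CrawlParams.seed` drives all randomness,
so identical parameters give bit-identical sequences.

Kinematics use three primitives: **runs** (a pivot point one third of the
body length behind the head advances at `speed·body_length` mm/s along the
heading; the body is straight), **head casts** (the anterior third swings
to `cast_amplitude` degrees and back following half a sine period over a
fixed 1 s window, alternating sides, while the pivot is frozen), and
**turns** (instantaneous heading changes at stated times). Instantaneous
turns keep the ground truth analytic; their abruptness is harsher than a
real reorientation, which makes the event-detection benchmark
conservative.

Defaults describe the reference preparation: a 4 mm × 0.5 mm animal at
0.1 body lengths/s, an 80 mm field of view at 0.08 mm/px (50 px per body
length), 7 Hz sampling, background 200, contrast 100 (dark on light),
noise sd 5. What the generator does **not** emulate: peristaltic width
modulation, body tapering, motion blur, illumination drift, shadows and
lens distortion. Passing tests therefore demonstrate correctness of the
algorithms under controlled contrast and noise, not robustness to every
artefact of real video.

## Online stage

*Thresholding.* `suggest_threshold` maximizes between-class variance of
the 8-bit histogram (Otsu's criterion), returning the midpoint of the
maximizing plateau so that a two-level image gets a threshold strictly
between its modes. The *pipeline default*, however, is a contrast-midpoint
rule (`auto_threshold`): midway between the median intensity (the
background level) and the extreme tail on the animal side. The reason is
class imbalance: an animal occupying a fraction of a percent of the frame
contributes too little histogram mass, and the between-class-variance
optimum degenerates into the background mode. Both are overridable in the
config; a `--preview` flag on `sos track` prints the suggestion.

*Background reconstruction.* The animal is found in frame 0, a box
(dilated by 5 px) cropped around it, and the box contents replaced from
the first frame whose own animal box is disjoint from it. Disjointness of
the two boxes is the "moved away" test. If the animal never vacates the
box the partial background is returned with `completed=False` inside the
raised error.

*Tracking loop.* Per frame: polarity-folded background subtraction
(clipped at zero), threshold, largest 8-connected component (8-connectivity
keeps thin diagonal bodies whole; exact ties broken by first pixel in
row-major order), bounding box dilated by half the object's major-axis
length (config-overridable). The next frame is searched inside the
previous dilated box, falling back to the whole frame when nothing is
found there. Stops: frame budget exhausted (`completed`), object touching
the frame border (`left_field_of_view`). The real-time stop (`too_slow`)
applies only to live acquisition; file replay has no real-time constraint.
Crops store raw frame pixels, so crops + offsets reconstruct the animal's
pixels losslessly.

## Posture extraction

Holes are filled before any contour or skeleton work so that segmentation
noise cannot change the body topology. A light morphological closing +
opening (disk radius 1, `smooth_px`) suppresses boundary pixel noise
before thinning; it is unnecessary on noise-free masks and can be set
to 0.

*Contour.* Sub-pixel boundary at the 0.5 level between body and
background, orientation normalized to positive signed area. Smoothing is
a cyclic moving average.

*Curvature.* At each contour point, the turning angle between the chords
to the points one `arc_window` of arc behind and ahead, divided by the arc
between the chord midpoints; positive = convex. The default window is 5%
of the contour length (minimum 3 px). For a circle of radius `r` this
estimator is exact up to discretization (`κ = 1/r`).

*Head/tail candidates from curvature.* The two highest positive local
maxima separated by at least 25% of the contour length, each required to
exceed `max(1.5 × median |κ|, 2 × 2π/perimeter)` — the second term is the
mean curvature of any closed convex curve, which rejects near-circular
blobs whose curvature is uniform (flagged `blob_like`). Note the maxima
sit at the cap *apices*, one halfwidth beyond the midline endpoints.

*Thinning.* The classic two-subiteration parallel thinning rule
(Zhang-Suen): delete a foreground pixel when it has 2-6 foreground
neighbours, exactly one 0→1 transition around its 8-neighbourhood, and
passes the subiteration's directional tests; all deletions in a
subiteration are decided on a snapshot. The package implementation is
vectorized; the test suite contains an independent naive per-pixel loop of
the same published rule and requires identical pixel sets on small masks.
Endpoints are skeleton pixels with ≤1 skeleton neighbour (an isolated
pixel counts); a count other than two raises the `spur` flag. Spur frames
are flagged, not auto-repaired; optional pruning exists but is off by
default because shaving tips also shortens true ends.

*Endpoint refinement.* Thinning systematically stops short of the midline
tips (one to a few pixels inside each cap), and can consume a short,
sharply bent anterior limb — the head-cast posture — almost entirely,
truncating the skeleton at the bend. Each end is therefore refined by
hill-climbing inside the mask away from an interior anchor (a skeleton
point ~2 halfwidths in): the climb follows the limb to the cap tip
whatever its curvature, and the refined endpoint is the tip pulled back by
one halfwidth — the cap centre, i.e. the midline extremity. The halfwidth
is the median of the Euclidean distance transform along the skeleton
interior. Refinement only ever extends, never retracts, an endpoint.

*Metrics.* Area = pixel count; perimeter = Euclidean step lengths along
the contour; skeleton length measured over 3-px chords of the ordered path
(per-pixel steps overestimate digital staircase lines by up to ~8%);
midpoint = skeleton vertex at half the arc length. `blob_like` =
head-tail chord under 0.3 of the skeleton length, or a skeleton under
5 px.

## Head/tail identity

Seeded once from hints (config/CLI coordinates replacing an on-screen
click; the pipeline can also auto-seed from the early direction of
travel), then propagated by the distance rule: the endpoint nearest the
previous head is the head. The rule uses position only, so it tolerates
pauses and backward crawling; it requires under half a body length of head
displacement per sample. Near-ties (< 1 px difference) are resolved by
continuity of the tail→head axis direction and flagged. Flagged frames:
blob-like postures, ties, and head jumps above 0.5 × skeleton length.
Corrections (`swap` — from that frame until the next correction,
`discard`, `keep`) are a replayable CSV; swapping twice restores the
original labels.

## Calibration

A single isotropic factor: mm/px = mean over landmark pairs of known
distance / pixel distance, with a warning when pairs disagree by more
than 2% relative. Coordinates transform as `(c + offset)·s`; areas by
`s²`; timestamps as frame index / fps (default fps = 1/sampling interval).
Anisotropic pixels and lens distortion are out of scope.

## Landscapes

Linear: `v(p) = v₀ + g·((p − p₀)·û)`, gradient `g·û` everywhere. Radial
(odor plume around a point source): `v = v_peak·e^{−r/λ_d}`, gradient of
magnitude `v_peak·e^{−r/λ_d}/λ_d` pointing at the source, undefined at the
source itself. Sideways light: intensity `I₀·e^{−d/λ_d}` in the distance
`d` from a source line, plus a lit/shadow half-plane for exposure; the
field's gradient is discontinuous on the source line (zero returned
there). The exponential forms are conventions — the real profiles of an
assay are measured, and a `GriddedLandscape` (bilinear interpolation over
a CSV `x,y,value` grid) accepts such maps.

Contour light exposure = 100 × (lit arc length / total arc length), with
edges crossing the boundary split at the crossing point, which makes the
result independent of contour point density (< 0.5% change under
refinement). `side_light_fractions` splits the contour into left/right
arcs at the points nearest head and tail, classifying each by the cross
product with the tail→head axis.

## Sensorimotor records and events

One record per retained frame: stimulus at the head, central-difference
time derivative (one-sided at ends; optional width-3 boxcar, off by
default), bearing to the gradient in [0°, 180°] (missing, not an error,
in flat fields), values along the skeleton, contour light fraction for
sideways-light landscapes, per-frame relative change in percent.

*Heading* is the direction of centroid displacement over a 3-frame
window, falling back to the tail→head body axis below 0.05 body lengths/s.
*Head bend* is the deviation from 180° of the angle at the skeleton
midpoint between the head→midpoint and midpoint→tail chords; for an
anterior-third bend of 60° this chord measure reads ≈ 41°, which the
default `cast_angle` of 30° accommodates.

*Events.* Casts: bend > `cast_angle` (default 30°) while the centroid is
slower than the run gate — by default 1.5 × the trial's median speed
(headroom for the residual centroid motion the head sweep itself
induces), or `run_speed_bl` body lengths/s when set. Turns: centred
heading rate > `turn_rate` (default 20°/s) sustained for `min_duration`
(default two sampling intervals); frames inside or within ~0.5 s of a
head-sweep window (contiguous bend > `cast_angle`/3 containing a
super-threshold bend) are excluded from turn detection, because the
lateral head sweep perturbs the centroid-path heading without reorienting
the body. Runs are the remaining frames; every frame carries exactly one
label, cast taking precedence over turn. Turn magnitude compares median
headings over the three frames before and after the span; cast magnitude
is the peak bend. All thresholds are config-exposed; the defaults are
placeholders validated on the synthetic benchmark, not measurements of any
particular species.

*Merging.* Trials are row-concatenated with a `trial_id` column; stimulus
units must agree (`incompatible_units` otherwise).

## Planner

`posture_resolution(P, L/λ) = P/(L/λ)` px per body length (e.g. 1024 px at
ratio 20 → 51.2). `time_to_edge` reports both conventions — centre start
(`(L/λ)/2v`) and far-edge start (`(L/λ)/v`) — since either may describe an
experiment. Storage floors the frame count (a partial frame is never
stored). The planner warns when `v·τ ≥ 0.5` body lengths per sample, the
regime where the identity distance rule can fail.

## Validation benchmarks (problem sizes)

The `validation` module regenerates every quantity the acceptance script
reports. Sizes: tracking fidelity — 20 trials × 50 frames at 1 Hz,
0.1 BL/frame, 48 mm arena at 0.08 mm/px; event recovery — 20 trials × 38 s
at 7 Hz with 2 turns (50-110°) and 2 casts (60°) each, 36 mm arena at
0.09 mm/px; background fidelity — 21 noise-free frames with one static
clutter blob smaller than the animal; gradient checks — 100 random points
per landscape kind against central differences (h = 10⁻⁴ mm); thinning
agreement — 40 random masks ≤ 30 × 30 versus the naive per-pixel rule.

## Known limitations

- Constant body width is assumed by the endpoint refinement; strong
  tapering (real larvae) would bias the halfwidth estimate and hence the
  tip pull-back by a fraction of the taper.
- At extreme bends the skeleton between the refined endpoints still cuts
  the elbow short, so skeleton-resolved stimulus profiles under-sample the
  anterior body during the deepest casts.
- The event detector's thresholds are validated against the synthetic
  kinematics only; real species need tuning via the config.
- Multi-animal scenes, camera motion and time-varying landscapes are out
  of scope.
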