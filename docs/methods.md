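# Methods

## The static string-on-pulley model

The middle deltoid (MD) on a planar slice is an inextensible, massless
string under equal tension F1 = F2 at its two insertions, wrapping the
in-plane section of the implant sphere (the "pulley", a circle of radius
ρ).  Three lines are constructed per slice: the *MD line* (external
tangent from the distal insertion point to the circle, on the lateral
side), the *proximal line* (tangent from the slice's acromial insertion
site), and the humeral diaphysis axis Y′Y, which the slice frame makes
its +y axis.  The measured angles are

- **E** — the unsigned acute angle between the MD line and Y′Y;
- **B** — the angle the MD line and the proximal line form at their
  intersection, measured between the two fiber segments leaving the
  pulley; **T = B/2**.

For a string wrapping an arc α, B = 180° − α.  This convention is forced
by the force balance: the two tensions pull away from the pulley along
the tangent segments, the angle between them is B, and projecting
equilibrium on Y′Y gives Ry = F1 cos E + F1 cos(2T+E) = 2F1 cos T cos(T+E)
with reaction magnitude |R| = 2F1 cos T.  The limits are the sanity
checks: a straight string (α → 0, B → 180°, T → 90°) exerts no radial
reaction and CER → 0; a hairpin wrap (α → 180°, T → 0) gives |R| = 2F1
and CER → 2/cos E.  CER is reported as a positive magnitude although the
coapting component formally opposes the elevating one (the derivation
carries a minus sign).

Angles are kept at full precision internally; reported tables round to
two decimals.  E is unsigned: a slice whose MD line crosses the axis
medially is treated the same as the mirror case.

## Sphere fitting (ILSS)

The implant least-squares sphere is fitted to oriented points picked on
the MD's internal aspect:

1. **Algebraic fit** — the linearization ‖p‖² = 2p·c + (r² − ‖c‖²)
   solved by least squares, then **geometric refinement** minimizing
   Σ(‖p − c‖ − r)² (Levenberg–Marquardt).  The refinement is standard
   practice and exact on clean data either way.
2. **Normal filter** — a point is eliminated when normal · (point −
   center) is over 0, i.e. when its normal contradicts the *inward*
   convention (internal-aspect normals point toward the implant).  The
   convention is explicit (`FitConfig.normal_sign`) because the rule's
   sign depends on how surface normals were oriented upstream.
3. **Distance pruning** — the ⌈10%⌉ of points with the largest
   dist² = |‖p − c‖² − r²| are removed (stable tie-break by original
   index, earlier points retained).

The loop alternates fit → filter → prune until the radius changes by
less than `radius_tol` (default 0.05 mm) or `max_iterations` (default 5)
is reached — a reproducible automation of an interactive click-driven
procedure.  The acromial reference sphere is fitted with the same
machinery with pruning disabled by default (a flag re-enables it).

## Slice planes and resampling

Each slice plane passes through Point 1 (acromial sphere center),
Point 2 (an insertion site on the acromial arc, candidates every 10°)
and Point 3 (center of the humeral diaphysis).  The four sites map to
slices as S1=P1, S2=M1, S3=A3, S4=A2.  The in-plane y axis is the
projection of the diaphysis direction (so Y′Y is a coordinate axis of
every slice); +x is oriented lateral.  Frames are rigid: plane-space
distances equal world distances.

Volumes are resampled with the falloff kernel w(t) = 2t³ − 3t² + 1
applied to the eight corners of the enclosing voxel cell, t the
per-axis distance in voxel units, weights multiplied across axes.  The
multi-axis combination rule is a design choice: the separable product
was chosen because w(t) + w(1−t) = 1 makes the eight corner weights a
partition of unity, so constants are reproduced exactly.  Integer labels
cannot be interpolated, so the label image takes the weighted-majority
label; a blended intensity channel is kept for visual checks.  Slice
raster defaults (0.5 mm pixels, 160 mm extent) are package choices — the
source protocol never states them.

The pulley circle is the sphere-plane intersection: ρ = √(r² − d²).
Lateralization translates the sphere by 6/9/12 mm along world +X with
radius unchanged and re-intersects; the humerus is *not* co-translated
(a flag enables it, to explore the variant where humeral lateralization
preserves the moment arm).

## The deltoid moment arm

Two readings of "the distance between the implant center and the line
perpendicular to F1" are implemented, because the phrase does not pin
down the construction:

- `perpendicular_to_F1_line` (default) — perpendicular distance from the
  in-plane implant center to the MD line of action: the classical moment
  arm, equal to ρ for a tangent line;
- `paper_perpendicular_line` — distance from the center to the line
  through the distal insertion perpendicular to F1.

Published DMA magnitudes depend on the original patients' geometry and
are not reproduction targets; DMA is validated structurally (tangent
distance = ρ, zero for a line of action through the center).

## The synthetic shoulder phantom

The generator builds a post-RSA shoulder in the humerus-fixed frame
(X lateral, Y along the diaphysis, Z anterior; right-shoulder
convention, left shoulders are mirrored at ingest): an implant sphere at
the origin; a cylindrical diaphysis (radius 11 mm) slightly lateral and
distal; an acromial spherical patch whose arc carries the four insertion
sites; and a deltoid sheet of wrapping fibers built from the same
closed-form tangent geometry the model measures, so every slice's
E/B/T, CER, DMA and ρ are known exactly.  Tangency is by construction:
contact-band points lie on the implant sphere to machine precision, with
normals pointing at the center.

The default geometry encodes the supine imaging position with the arm at
80° of abduction, under which the acromion sits nearly above the implant
and the deltoid wraps an arc of ≈70° (B ≈ 110°, T ≈ 55°, E ≈ 8° at
0 mm).  How the 80° arm position maps to relative landmark positions is
not constrained by any published measurement, so the mapping is exposed
as the free parameter `arm_angle` (rotating the scapular complex about
the implant center).  The default landmark constants were chosen, once,
so that the phantom (a) shows the study's qualitative configuration and
its lateralization response — T strictly decreasing, E and CER strictly
increasing over 0/6/9/12 mm on every slice — and (b) remains
geometrically valid for the full range of published implant radii
(25.7–39.4 mm), whose fixed millimetric offsets act like scaled-up
offsets after the radius-proportional scaling of the phantom.

Noise models, deliberately distinct:

- `noise_sd` (point clouds) — independent per-click selection error
  (RMS magnitude in mm), the right model for manual point picking;
- `perturb_segmentation` (volumes) — a *smooth* random displacement
  field (RMS amplitude in mm, decorrelating over roughly centimetre
  scales) warping label boundaries, the right model for repeat manual
  segmentations, whose errors are spatially correlated;
- `outlier_fraction` — stray picks on the straight fiber runs near the
  implant, half of them with flipped (external-aspect) normals, to
  exercise the normal filter and the pruning loop.

Cohorts use the seven published implant radii with a seeded 1 mm
landmark jitter; jitter draws that break the wrap construction (string
detached, insertion inside the pulley) are resampled deterministically.

What the phantom does **not** emulate: MRI physics (artifacts, fat
saturation), anatomically detailed scapulae, muscle mass/thickness
effects on the force model (thickness is used only to rasterize the
sheet), and inter-patient variation beyond landmark jitter and implant
size.  Passing tests therefore show the measurement chain is correct and
stable under controlled noise — not that the model captures in-vivo
deltoid mechanics.

## Statistics

- Descriptives: mean, sample SD (n−1), min–max, rendered
  "mean±SD (min–max)".
- Mann-Whitney U: exact two-sided p by full enumeration of the
  permutation null for n1+n2 ≤ 20 (midranks on ties; tail doubling,
  capped at 1; normal approximation beyond).  With 7 shoulders per
  condition the attainable floor is 2/3432 ≈ 0.000583.
- ICC: two-way random-effects, absolute-agreement, single-measure
  ICC(2,1) from the mean-squares decomposition (the model choice is
  recorded in the output; the source never states its ICC form), with
  the consistency form ICC(3,1) reported alongside.  Agreement on "3D
  models" is operationalized as agreement on structure volumes (mm³)
  and on ILSS radii refitted from repeat segmentations.
- No multiple-testing correction (α = 0.05 per test), noted in the
  report footer.

## Problem sizes and numerical choices

Default runs use 7 phantoms × 4 slices × 4 offsets (112 cells, a few
seconds); the deltoid pick cloud has ≈1400 points from 48 fibers; volumes
are rasterized at 1.5 × 1.5 × 3 mm (3 mm slice spacing matching the
imaging protocol emulated; the agreement study uses 2 × 2 × 3 mm).
Degenerate inputs raise explicit errors rather than returning NaN:
collinear plane points, planes missing the sphere, insertions inside the
pulley, a string that clears the pulley (no wrap), fewer than 4 points
in a fit, all points eliminated by the normal filter, and zero
between-subject variance in the ICC.

## Known limitations

- The volume-extracted ILSS radius carries a voxel-scale bias (the
  marching-cubes surface of a rasterized sheet is not the true contact
  surface); the agreement analysis is unaffected (the bias is common to
  repeats), but absolute radii from volumes should not be compared with
  radii from point picks.
- The planar model ignores out-of-plane fiber force components; slices
  are treated independently.
- CER from mean angles is not the mean of per-patient CERs
  (mean-of-ratios vs ratio-of-means); tables therefore average CER per
  cell, never re-derive it from averaged angles.
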