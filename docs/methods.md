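# Methods

`cbctpano` synthesizes panoramic radiographs from dental cone-beam CT
volumes by curved planar reformation in three steps: (1) a dental arch
curve is created from the axial maximum intensity projection (MIP); (2) a
3D panoramic curved surface is extracted through the long axes of the upper
and lower teeth; (3) the surface is developed isometrically into a 2D
radiograph, optionally thickened along the surface normals. A synthetic jaw
phantom with closed-form ground truth makes every stage quantitatively
testable without patient data.

## Step 1 — dental arch curve

**MIP.** Enamel is the densest tissue in the body, so the axial MIP
(per-pixel maximum over slices) shows the dentition as the brightest
horseshoe. An optional fractional z-band crop is available; the default
projects the full range.

**Bone segmentation.** Pixel intensities are clustered by seeded 1-D
k-means++ (Lloyd iterations to convergence, `k_mip` = 5). The bone mask is
the union of the top cluster(s). The default rule (`auto`) includes every
cluster whose center is at least 80% of the top center: enamel and dense
cortical bone are close in intensity and may or may not share a cluster
depending on noise, and the bone area of interest contains both the
dentition and the jaws. An integer `top_clusters` overrides the rule.

**Spatial quadrangle.** The jaws are wider than the dental arch, so the
mask is restricted to an axis-aligned rectangle about the bone centroid,
grown from zero with its aspect fixed to the mask's per-axis standard
deviations until it covers at least a fraction `p` = 0.75 of the bone
pixels; the smallest such rectangle is used. This removes the posterior
jaw-only structures while keeping the dentition.

**Parabola.** A parabola `y = a x² + b x + c` is fitted to all isolated
arch pixels in a PCA-rotated frame (mask's minor principal axis vertical,
making the step orientation-invariant). The plain vertical-residual fit is
refined by three Sampson-weighted iterations (weights `1/(1 + y'²)`) toward
the geometric least-squares fit: on a wide pixel band the unweighted fit
lets the steep arms dominate and biases the apex by about one pixel.

**Control points and spline.** `n_control_points` (default 7, odd) points
are placed on the parabola, uniform in arc length and symmetric about the
apex, spanning the arc positions of the extreme mask pixels. The arch curve
is the piecewise cubic Hermite interpolant with Catmull–Rom (central finite
difference) tangents, one-sided at the ends. Arc length is tabulated by
dense chord sampling (200 samples/segment), supporting arc-length inversion.
On tightly curved arches the spline's fidelity is limited by control-point
spacing relative to the apex curvature radius; 7 points suffice for ~1 px
fidelity on the default phantom, and the count is configurable.

**Normal lines.** Feet are placed at uniform arc-length steps (`step_px`,
default 10 — one section per ten curve pixels; per-pixel image width is
recovered later by interpolation during rendering). All normals share one
rotation sense of the tangent, flipped globally so they point outward
(away from the control-point centroid, i.e. labially).

## Step 2 — panoramic curved surface

**Sections.** For each normal line an oblique sagittal section is resampled
(bilinear in-plane, one column per integer offset `u ∈ [−half_length,
+half_length]`, default half-length 50 px, one row per axial slice);
out-of-volume samples take the volume minimum (air-like).

**Per-section tooth mask.** The same seeded k-means++ rule segments the
section (`k_section` = 4 for open-bite scans; 2 suits closed-bite scans
where teeth dominate the histogram); the mask is the top cluster with
connected components smaller than `min_area` = 10 px removed — least
squares on salt noise is catastrophic.

**Long axial curve.** A single least-squares polynomial `u(z)` of degree 5
(configurable 1–7) is fitted through the combined upper+lower mask; the
bite gap contributes no pixels and the polynomial bridges it. Outside the
fitted z-range the curve is clamped to its boundary value (no polynomial
blow-up at the volume top/bottom). Sections spanning fewer than degree+1
slices fall back to a vertical line and are replaced in the surface by
linear interpolation (in arc length) of the nearest fitted neighbors.
Degree 5 is the default because degree 4 lacks the freedom to follow the
opposing, differently tilted upper and lower axes (it measurably misses
tilted incisors), while degree 7 overfits — its coefficients vary several
times more between adjacent sections.

**Surface and normals.** Vertex `(i, j) = foot_i + u_i(z_j)·direction_i` at
slice `z_j`; triangle strips connect adjacent columns. Per-vertex normals
are PCA plane fits (smallest-eigenvalue eigenvector of the neighborhood
covariance) over the k nearest vertices *in the surface's own sampling
metric*: a grid window whose row half-width scales with the arc step, so
the neighborhood stays physically near-isotropic. (Euclidean k-nearest
neighbors would collapse onto single columns whenever the arc step exceeds
the slice spacing.) Normals are oriented to agree with the generating
line's outward direction; degenerate neighborhoods fall back to that
direction lifted to 3D.

## Step 3 — synthesis

**Development.** The surface columns, joined at a reference transverse row
(default: mid-height; `per_row_mean` averages segment lengths over all
rows), form a 3D polyline that is straightened by the arc-length rule:
`w_i = Σ_{j≤i} L_j` with `w_0 = 0`, and `h_j = z_j`. The development is
isometric along the reference row by construction.

**Single-slice radiograph.** Width = number of pixels the straightened
polyline passes through (`round(w_last) + 1`); height = number of axial
slices. Each pixel inverts the development (linear interpolation in `w`
between surface columns) and samples the volume trilinearly.

**Thickened radiograph.** Mean (optionally max) of samples at integer voxel
offsets `t ∈ {−(n−1)/2 … (n−1)/2}` along the interpolated unit normal;
`n = 1` reduces bitwise to the single-slice render. Offsets are voxels; a
`--thickness-mm` CLI option converts from millimetres.

**Cylinder baseline.** The classical alternative extrudes the 2D arch curve
vertically and samples the volume on that sheet; thickening offsets run
along the curve's 2D outward normal. Because tooth long axes are tilted
(most strongly at the incisors), the sheet misses crowns and pulp cavities
that the curved surface captures — the phantom experiments quantify this.

## The phantom

The generator renders, deterministically for a fixed config (the seed only
drives the final additive Gaussian noise):

- a soft-tissue head ellipse in an air background;
- a parabolic dental arch (default apex (80, 40), half-span 50 px in a
  160³ volume at 0.3 mm voxels) carrying `n_teeth_per_jaw` = 10 teeth per
  jaw as capsules (cylinder + hemispherical caps, axis length 12 mm, crown
  radius 1.8 mm) with concentric enamel shell (0.6 mm), dentine body and
  pulp core (0.6 mm);
- labial tooth tilts interpolated from 15° at the incisors to 0° at the
  molars, mandibular tilts scaled by 2/3, and a 0.6 mm maxillary overjet —
  the asymmetries that defeat the cylinder baseline in practice;
- trabecular jaw-bone bands centered on the arch around the root zones,
  plus two dense cortical rami posterior of the arch ends whose intensity
  (2600) sits between dentine and enamel: they contaminate the top
  intensity clusters (so the gray threshold alone cannot isolate the arch)
  but are spatially extreme (so the quadrangle removes them);
- optionally a mandibular canal: a soft-tissue-intensity tube under the
  posterior teeth on both sides (real canals end at the mental foramina),
  7 px lingual of the lower root line — about 10 voxels lingual of the
  extracted surface, whose bottom clamp sits slightly labial of the root
  line;
- optionally a single very-high-intensity capsule standing in for a
  metallic implant (a config flag, not a physics model);
- open bite (3 mm gap) or closed bite (crown tips interdigitate with 2
  voxels of z-overlap, enamel shells disjoint).

Intensities default to background 0, soft tissue 100, trabecular bone and
dentine 2000, cortical rami 2600, enamel 2800, pulp 800 — scanner-style raw
units with enamel the strict maximum. With zero noise the histogram
contains exactly these values, which many constructive tests rely on.

What the phantom does **not** emulate: scanner physics (no point-spread
function — tissue boundaries are hard voxel steps), metal artifacts, beam
hardening, anatomical tooth shapes, sinuses or condyles. Consequences:
tests demonstrate geometric correctness of the reconstruction chain, not
image quality on clinical data; and sub-pixel disagreements between
renderers show up amplified at the step edges.

### The degenerate (tilt-free) phantom

The equivalence check "surface method ≡ cylinder method when all tooth
axes are vertical" uses a purpose-built degenerate phantom: a gentle arch
(a = 0.012, so the 10-px section step resolves the curvature — sagitta
κ·step²/8 ≪ 1 voxel), eight homogeneous vertical teeth (no layering, so
residual sub-pixel offsets do not toggle internal boundaries), no overjet,
no rami; the pipeline runs with the enamel-only bone rule, no quadrangle
and 17 control points. On the standard tilted, tightly curved phantom the
two methods legitimately differ (that contrast is itself a tested claim),
and even with the exact true arch curve the hard-edged tissues turn the
honest ~1 px geometric difference into a ~1.7% mean absolute difference.

## Numerical choices

- k-means++ seeded (`n_init = 1`); k reduced with a warning when an image
  has fewer distinct values than k; empty bone mask is an error, empty
  section masks flow into the fallback path.
- Quadrangle growth quantile is exact (the smallest covering rectangle),
  so it always discards ≈ (1 − p) of the mask — the phantom's jaw-only
  structures are sized accordingly.
- Parabola fit requires ≥ 3 non-collinear pixels; collinear masks raise.
- Interpolation is bilinear in-plane for sections, trilinear for renders;
  out-of-volume samples take the volume minimum so slab averages stay
  defined at the edges.
- Windowing (width/level → [0, 1]) is display-only; all pipeline math uses
  raw intensities. Radiographs are written 16-bit by default with a JSON
  rescale sidecar so original values are recoverable to quantization.
- Thickness offsets are voxels (the axial spacing equals the in-plane
  spacing for the isotropic volumes targeted here).

## Problem sizes

Default experiments use 160³ phantoms (the arch-recovery study spans a 3×3
grid of arch parabolas, clean and at noise σ = 0.2·(enamel−dentine)),
112³ phantoms for end-to-end determinism, and analytic surfaces (random 3D
polylines, planes, semicircular cylinders) for the development and normal
oracles. The full test suite runs in about half a minute; the acceptance
script in about fifteen seconds.

## Known limitations

- The Hermite arch curve corner-cuts where control spacing exceeds the
  local curvature radius; increase `n_control_points` for small, tightly
  curved fields of view.
- The quintic's clamped extrapolation below the roots sits a few pixels
  labial of the true root line — relevant when placing structures relative
  to the surface at canal depth.
- Per-section fits carry ±0.3–0.5 px rasterization noise, which at
  `step_px = 1` accumulates into visible development stretch; the default
  1-in-10 sampling plus render-time interpolation is both faster and more
  stable.
- Geometric distortion of the developed image (inherent to flattening a
  doubly sampled surface) and jagged artifacts in thickened renders from
  normal estimation error are not corrected.
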