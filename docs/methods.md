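# Methods

This note records the models, conventions and numerical choices behind
the package, what the synthetic phantom does and does not emulate, and
the known limitations.

## Imaging model

Volumes are 3D scalar grids in `(z, y, x)` order with isotropic voxel
size in µm; physical positions refer to voxel centres.  In the
edge-detection regime of propagation phase contrast, each interface
between materials of different density appears as an antisymmetric pair
of bright and dark bands, bright on the denser side, with the physical
interface at the zero-crossing between them.  The phantom reproduces this
with a band-pass (difference-of-Gaussians) filter of the density field,
σ₁ = width/2 and σ₂ = 2·width, normalized so a unit density step yields a
fringe pair of peak amplitude `amplitude_fraction` (default 0.5, fringe
width 2 px).  This is the simplest antisymmetric edge response consistent
with the regime; it is exactly mean-preserving and linear, so fringe
amplitudes scale with step heights.  It is *not* a Fresnel propagation
model: fringe shape, secondary oscillations and energy dependence are out
of scope.  Defaults are fixture conventions, not measured values.

## Tooth phantom

An axisymmetric crown cap: a paraboloid-like outer enamel surface (radius
∝ √(d/H) of the distance d below the cusp tip) over a dentine core whose
EDJ apex sits `cuspal_thickness_um` below the tip.  Densities are
arbitrary units with air 0 < matrix 0.15 < dentine 0.55 < enamel 1.0;
edges are anti-aliased over one voxel so interfaces are sub-voxel
defined.  Features:

- **Perikymata**: a cosine radial modulation of the OES with surface
  spacing `retzius_spacing_um` (default 24 µm, a mid-crown anterior-tooth
  value) and relief amplitude 2 µm; crests at (k + ½)·spacing are the
  ground-truth positions.  The ridge count is ⌊H/s + ¼⌋: crests closer
  than a quarter period to the cervix are excluded because the crown base
  clips them.
- **Internal long-period lines**: a 1–2 % density modulation of the
  enamel, tilted so the spacing along the growth direction equals
  CuDSR × periodicity (defaults 3.57 µm/day × 8 days).
- **Hypoplasias / stress lines**: each defect (height fraction,
  amplitude, width) cuts a circumferential groove into the OES *and*
  applies a fractional (density-proportional) drop of 3 %/µm-of-amplitude
  across both tissues.  Because the drop is proportional to density, the
  enamel–dentine step itself dips at the defect, which is what makes the
  stress line visible in the EDJ fringe contrast.
- **Demineralized subsurface layer**: a 5 µm-thick shell at a given
  depth below the OES with a fractional density drop.  With
  `half_period_offset=True` the layer is interrupted by narrow protected
  bands (σ 2.5 µm) midway between ridge crests — emulating internal
  long-period subdivisions protected by a thin surface sheet of intact
  enamel.
- **Crypt matrix**: optionally the whole background is embedding matrix
  (density between air and dentine) in continuous contact with the OES.

Determinism: the phantom is a closed-form function of its spec; the seed
only enters `add_noise`.

What the phantom does **not** emulate: prism-level daily
cross-striations, anisotropic enamel texture, non-axisymmetric crown
shape, cracks, wear facets, reconstruction artifacts other than rings.
Tests passing on the phantom therefore validate the *operations*
(segmentation accuracy, counting, registration) under controlled
conditions, not performance on arbitrary fossil material.

### The subdivision artifact

Degrading resolution is modelled as an isotropic Gaussian blur of FWHM
equal to the target voxel size followed by linear resampling.  At full
resolution a subsurface demineralized layer does not move the apparent
surface (the mid-level crossing).  After degradation to 5 µm, the blurred
density deficit drags the crossing several µm inward — except under the
protected bands, which therefore appear as *outward* ridges midway
between the true crests, doubling the apparent ridge count.  The default
layer (depth 1 µm, drop fraction 0.7) produces an apparent shift of
about 4–5 µm against a 2 µm ridge relief, a robust doubling; the
behaviour is a threshold phenomenon in depth and drop (a layer deeper
than ~2 µm at 5 µm FWHM barely moves the crossing), which mirrors why the
artifact occurs only over strongly altered enamel.

## Pre-processing

- 32→16-bit conversion is a linear window [lo, hi] → [0, 65535] with
  clipping and round-half-up; the default window is the 0.1/99.9
  percentile range.
- 2×2×2 binning is a block mean; trailing odd planes are dropped; the
  voxel size doubles (4.96 → 9.92 µm) and the origin shifts half an input
  voxel to the block centres.
- Ring suppression (optional) resamples each slice to polar coordinates
  about the slice centre, takes the angular mean per radius, subtracts a
  running median (default width 21 px) to isolate the narrow ring
  component, maps it back and subtracts it, then restores the slice mean
  exactly.  Any filter satisfying the residual/identity invariants would
  do; this one assumes rings centred on the slice centre.
- Virtual slices: the slab is sampled on ⌈thickness/voxel⌉ planes spaced
  one voxel apart, trilinearly interpolated (nearest-edge beyond the
  grid) and mean-projected.  For axis-aligned normals the in-plane axes
  are the remaining volume axes in (z, y, x) order, so a one-voxel
  axis-aligned slab reproduces the raw slice bit-exactly.

## Segmentation

The OES is grown (26-connectivity) over voxels ≥ `threshold_fraction`
(default 0.5, half the symmetric fringe peak) of the local bright-band
peak measured around the seed.  The exterior is the border-connected
background below a cut placed 30 % of the way from the background level
(median of the grid's outermost shell) to the tissue level — this rejects
interior tissue cut by the grid faces while keeping air *and* embedding
matrix, which is what makes crypt-enclosed crowns segmentable.  Surface
elements are the region voxels adjacent to the exterior, refined along
the mask-gradient normal (smoothed at σ = 1.5 voxels) to the sub-voxel
crossing of the background/tissue mid-level — for an antisymmetric fringe
this crossing *is* the white/black junction, i.e. the physical interface.

The EDJ mask is the dark band plus the dentine interior: voxels between a
lower cut (¼ of the way from background to the dentine level, below the
dark-band minimum but above matrix) and the dentine/enamel mid-level.
The exposed boundary facing values above the mid-level is the EDJ.  A
probe 4–8 px beyond the bright side distinguishes a true enamel shell
(tissue-level values persist) from a bare dentine body's own fringe
(background beyond); in the bare case the body's whole outer boundary is
returned — the degenerate "EDJ equals the dentine's outer surface" case.
Normals point out of the segmented mask (OES: denser → less dense; EDJ:
dentine → enamel).

`attach_density` probes ±`probe_depth_px` (default 3) along each normal
and stores the bright-band maximum, dark-band minimum, and their
difference (signed fringe contrast).  The contrast is invariant to global
intensity offsets and dips where low-density stress lines meet the
interface.

## Rendering, compositing, unwrapping

Orthographic projection; surface elements are splatted as single-pixel
points with a z-buffer after back-face culling (`floor(x+0.5)` pixel
binning — round-half-to-even would collapse adjacent half-integer
columns).  Shading per light: ambient + diffuse·max(0, N·L) +
specular·max(0, R·V)^shininess, each term tinted by its component color
(intensities on a linear 0–255 convention; shininess default 30 — both
declared conventions, since the original software's semantics are not
published).  "Orange" is RGB (1.0, 0.6, 0.2) and "pale blue"
(0.8, 0.9, 1.0).  In `phong` mode a present density attribute modulates
the diffuse albedo over [0.25, 1] (topo-densitometric rendering);
`normalize_gradient` ignores it (topography only); `density` is flat
attribute shading.

Reinforcement: `combined = clip(((top + HP(bottom)) + (bottom +
HP(top)))/2)` with `HP` a Gaussian high-pass of σ = cutoff/2 (default
cutoff 20 px) — the closest standard operator to "subtract structures
smaller than N pixels".  Averaging the two reinforced images is this
package's choice of merge rule.  RGB images are combined in luminance
with the mean chroma reattached.

Unwrapping renders the model at each rotation step about its long axis
(counterclockwise seen from the cusp, a declared convention) under fixed
lights and framing centred on the axis, and concatenates the central
pixel columns.  Radial distortion where the local radius differs from the
mean radius is inherent to the method.  `suggest_angle_step` returns
360/(2π·r_max) degrees so the outermost arc per step is ≤ 1 px.  For
stripe *counting* on unwrapped maps, diffuse-only lighting (head-on fill
plus an azimuthal grazing light) is the right protocol: a specular lobe
highlights both flanks of a vertical ridge and doubles the stripe count.

## Ridge counting

Profiles are per-row means of unwrapped maps or renders, or the
apparent-surface-radius profile measured directly on the volume (rays
cast from the axis; outermost mid-level crossing, sub-voxel, averaged
over azimuth — robust to fringe amplitude because the crossing sits at
the fringe zero).  Detection: local maxima of the profile minus a running
mean of width 3× the expected spacing, with prominence ≥ `min_prominence`
and separation ≥ the lower spacing-band edge; deterministic, and emitted
with prominences for manual review.  Decile bins are equal tenths of
*projected* crown height (the geodesic alternative is not implemented);
boundary ridges go to the cuspal-side bin.  Observer summaries report
each observer's mean ± sd over sessions and the mean of observer means ±
the sd of those means — the quantity used for formation times.

`flag_subdivisions` marks degraded-resolution ridges with no
full-resolution counterpart within a tolerance.  Blur shifts the apparent
cusp tip, so an optional translation search (1 µm grid) co-registers the
two height scales first, matching at half the flagging tolerance and
breaking ties toward the smallest shift — with exactly half-period
subdivisions, a half-period shift can align the spurious set onto the
true crests equally well, and the small-shift tie-break resolves this.
In practice the tolerance should be well below half the subdivided
spacing (s/5 is used in the validation suite), and counting is restricted
to the lateral crown (first period below the tip excluded), where crest
prominences are stable for thresholds between 10 % and 60 % of the ridge
amplitude.

## Chronology

CFT = cuspal + lateral time; cuspal = thickness/CuDSR, lateral =
count × periodicity; years use a 365-day year (the only convention
consistent with the published day/year pairs).  Sums and years are
computed on unrounded values; integer day figures are rounded only for
reporting (published tables rounded inconsistently — e.g. a printed 171
days where the quotient gives 170.46 — and this package does not imitate
that).  Where a published cuspal time is not reconstructable from its
printed rate, `CuspalMeasure.overrides` accepts the day value directly
rather than guessing the intermediate step.  The only propagated
uncertainty is the count sd × periodicity; the CuDSR range is expressed
by tabulating one chronology per rate.  `measure_cudsr` is mean
long-period spacing along the prism path divided by periodicity.

## EDJ barcode

Surface elements are binned into circumferential bands (2 px) along the
growth axis; per-band means of the white/black attributes form the
barcode, with positions measured from the cusp tip (pass `tip_z_px` to
reference the OES tip rather than the EDJ apex).  Events are peaks of the
|detrended contrast| (median-filter trend, 60 µm window) with prominence
≥ 3× the MAD of the detrended signal.  Matching reduces the original
manual 2D warping to a 1D similarity registration: exhaustive grid search
over (scale, offset) maximizing the normalized cross-correlation of
prominence-weighted Gaussian event trains (σ 10 µm), evaluated on the
union of both domains so unpaired events count against a candidate; ties
break toward scale 1.  Perspective and skew are not modelled.  The
projected band width of a stress line meeting the EDJ at half-angle a is
t/sin(a) — equal to the true thickness at perpendicular intercept and
divergent as the intercept becomes tangential, which is why early
stresses spread into broad bands over the dentine horn.  (Schematic
illustrations of this geometry elsewhere use drawing conventions that do
not follow 1/sin exactly; the closed form is used here.)

## Problem sizes and validation scope

The validation suite uses a 240 µm crown at 2 µm voxels (~128³) for unit
tests, a 470 µm crown at 2 µm (~250³) for end-to-end parameter recovery,
and a 410 µm crown at 1 µm (~28M voxels) degraded to 5 µm for the
subdivision artifact — sizes chosen so the full suite runs in about a
minute and a half on one CPU while keeping ≥ 8 samples per ridge period
at the degraded resolution.  Measured performance at these sizes: OES and
EDJ mean localization error ≈ 0.4–0.65 voxels (≤ 2 voxels after 5 µm
degradation), exact ridge-count recovery at full resolution, barcode
events within 2 µm of planted defects, and similarity-transform recovery
within one grid step for scales in [0.5, 2].

## Known limitations

- The fringe model is phenomenological; quantitative densitometry from
  fringe contrast is relative, not absolute.
- Segmentation assumes a single dominant tissue level per region; heavy
  cracking or mixed mineralization would need seeded masks per fragment.
- The rotational unwrap is neither area-true nor conformal.
- Barcode matching assumes a global 1D similarity; strong differential
  growth between teeth would require piecewise registration.
- Automatic ridge counts are a screening tool; the package deliberately
  exposes prominences rather than certifying counts.
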