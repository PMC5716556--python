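# Methods

`dtsetup` simulates and evaluates clip-based patient setup with digital
tomosynthesis (DTS): short-arc cone-beam imaging of a target volume
containing surgical clips, reconstruction of pseudo-3D volumes by
shift-and-add back-projection, synthesis of matched reference volumes from
a planning CT, normalized cross-correlation matching, and triangulation of
two or more arcs into a 3D couch correction. This note records the model,
its assumptions, the defaults that matter, and the limits of what the
synthetic experiments demonstrate.

## Coordinate conventions

Room coordinates follow IEC 61217 with the isocenter at the origin:
x lateral (patient left), y longitudinal (superior), z vertical (anterior);
units are mm throughout, angles in degrees. Gantry angle 0° places the kV
source directly above the isocenter and the angle grows toward patient
left. Each arc center angle θc defines an orthonormal right-handed beam
frame (u, v, w): w points from source to isocenter (depth), v is the
longitudinal room axis, u = v × w spans the slice plane. DTS volumes are
stacks of (u, v) slices along w, isocenter-centered with an odd slice
count (counts round up).

## Imaging model

Projections are noiseless line integrals of the linear attenuation
coefficient, μ = μ_water·(1 + HU/1000) clamped at zero with
μ_water = 0.02 mm⁻¹, computed by trilinear ray marching at half-voxel
steps (accuracy contract: ±1 % against analytic slab path lengths). The
acquisition model adds i.i.d. Gaussian noise (σ = 0.01, configurable) to
the line integrals of each treatment projection. Gaussian noise on line
integrals — rather than Poisson on detector counts — keeps the pipeline
linear and exactly seedable; it ignores the signal dependence of real
quantum noise, which mainly matters at object edges that play no role in
the clip-region matching. Scatter, beam hardening, detector lag and
bow-tie filtration are not modelled.

Default chain geometry is the standard Varian OBI layout (source–axis
1000 mm, source–detector 1500 mm, 300 × 300 mm detector at 1 mm pitch).
An alternative preset `compact` (source–axis 500 mm, source–detector
1000 mm) reproduces the other set of distances quoted for this imaging
chain; the two disagree in the literature and neither is assumed correct.
Arcs sample every 0.5°, so a 10° arc yields 21 projections — an
approximation to clinical CBCT frame density; the exact clinical frame
rate is not published and only the arc subset matters downstream.

## Phantoms

Phantoms are water-equivalent bodies (box or hemiellipsoid, HU 0) in air
(HU −1000) with cylindrical clips rendered by volume-fraction
anti-aliasing (12³ midpoint subsamples per boundary voxel; total clip
signal is conserved under sub-voxel repositioning to < 1 %). The body
surface is anti-aliased the same way so ray path lengths match the
continuous geometry. The `rectangular` preset is a 120 × 200 × 40 mm box
with five 1 × 4 mm clips (default HU 1200) spread ±10–20 mm around the
isocenter; the `breast` preset is a representative 100 × 100 × 60 mm
hemiellipsoid — the physical breast mold it stands in for has no published
dimensions. The voxel grid adds a 10 mm air margin laterally and
longitudinally (so ±7.5 mm search-region shifts never clip anatomy) and
20 mm vertically, mirroring the vertical clearance of a real planning scan
and keeping beam-aligned reference volumes at tangential angles inside the
grid. Applied couch shifts translate the volume by trilinear resampling;
the registration sign convention is fixed so a correct registration
reports exactly the applied shift.

## Reconstruction

Shift-and-add: each depth plane (perpendicular to the central beam,
spanning a 150 mm initial stack) collects the mean of all projections
sampled at each voxel's perspective projection, so structures lying in a
plane are in focus there and out-of-plane structures smear along the
tomographic sweep direction. Voxels that project off-detector in some
projections average over the covering subset only (flagged in a coverage
mask), never zero-filled.

Deblurring is classic selective plane removal: for each slice, the mean of
the other slices in a centered window covering `deblur_fraction` of the
initial stack — each rescaled about the central ray by
(sad + w_j)/(sad + w_i) to the target slice's diverging-beam geometry — is
subtracted, after which the stack is cropped to the final volume
(60 × 60 × 75 mm treatment, 60 × 60 × 33 mm reference). A window holding
only the slice itself is the identity. The proprietary deblurring filter
of the clinical software is not reproduced; this subtraction design
satisfies the contracts that matter downstream (out-of-plane impulse
suppression ≥ 50 % at full window, background flattening versus the raw
stack, noise decreasing with arc length) but is nearly insensitive to the
window fraction on smooth backgrounds, because the out-of-plane estimate
is built from slices that carry almost the same leakage as the target
slice. Consequently in-focus contrast *rises* slightly with arc length
here, whereas the clinical filter makes it fall; no result in this package
depends on that direction.

Reference DTS volumes reslice the planning CT into the beam frame
(trilinear, grid padded 20 mm beyond the reconstruction footprint), then
reproject the resliced volume into noise-free virtual projections (DRRs)
at the identical arc angles and run the same back-projection/deblurring
chain. Because the resliced region is finite, the reference background
omits anatomy outside it that the treatment projections do contain; the
residual smooth mismatch is the main source of the ≈0.3–0.5 mm noise-free
registration bias and is tolerated by the zero-mean matching.

## Registration

Both volumes are smoothed in-plane with a Gaussian (σ = 1.5 mm default —
the clinical filter width is unpublished) to equalize resolution, then a
cube template (24 mm side) centered on the clip centroid of the planning
CT is matched by zero-mean normalized cross-correlation over the integer
displacement lattice within a 15 × 15 × 15 mm search region, with
separable quadratic sub-voxel refinement and ties broken toward the
smallest displacement. A match is invalid when the peak correlation falls
below `min_ncc` (0.3 — operationalizing "cross-correlation failed"; no
threshold is published) or when the in-plane peak sits on the search
boundary. A depth (w) peak on the boundary does not invalidate the match:
the depth correlation profile is nearly flat — effective depth resolution
is roughly the template width divided by tan(δθ/2), far beyond the search
region — so boundary depth peaks occur even for small in-range shifts, and
the depth component is excluded from triangulation anyway.

Triangulation solves for the room-frame shift by weighted least squares
over the per-arc in-plane equations u·s = d_u, v·s = d_v (weight 1); the
depth equations w·s = d_w carry weight `w_depth` (default 0, i.e.
discarded; exposed for sensitivity studies). Two arcs 20° apart condition
the depth direction at roughly 1/(2·sin 10°) ≈ 2.9× the in-plane error. A
single arc leaves the system rank-deficient: the result is flagged
3D-invalid and depth falls back to the arc's own unreliable w component.
Candidate arc orientations can be scored before treatment by projecting
clip centers into the beam's-eye view and flagging pairs closer than 3 mm
(overlap) or fewer than three well-separated clips.

## Parameter studies and problem sizes

The sweep harness runs full factorial grids of arc length × arc
separation × slice spacing × applied shift, memoizing projection sets and
reference reconstructions shared between cells, with per-cell failures
recorded rather than raised. Random applied shifts are uniform within
±5 mm per axis (inside the ±7.5 mm search half-width), five repeats per
cell by default; the accuracy grid in the test suite uses one noise-free
shift per cell, and the slice-spacing comparison uses two noise-free
shifts — deterministic problem sizes chosen so the full suite and the
acceptance script each complete in minutes on a single CPU while leaving
every qualitative comparison intact. The headline numbers recomputed by
`scripts/acceptance.py` (optimal-geometry accuracy, low-HU bound, clip
depth elongation) use the full 5-shift protocol with noise.

## What the synthetic experiments do and do not show

The phantoms isolate the geometry and algorithm chain: rigid anatomy,
ideal clip contrast, no ribs, breast surface, breathing motion, clip
migration or deformation, and no scatter/beam-hardening artifacts.
Passing accuracy bounds therefore demonstrates correctness of the
reconstruction-matching-triangulation chain under controlled conditions —
not clinical performance on patients, where clip/rib overlap in specific
beam's-eye views (here only represented by the orientation score) and
tissue deformation dominate the failure modes. Patient-specific tables
and figures are deliberately out of scope.

## Numerical choices

Counts of slices/pixels round up to odd so the isocenter is always a
sample point; ray marching clips each ray to the volume bounding box and
integrates by midpoint sampling; off-grid samples are air. The NCC peak
tie-break (smallest displacement magnitude, then lexicographic) makes
degenerate flat correlation surfaces deterministic. All random number use
flows through explicit integer seeds (numpy `default_rng`), making every
simulation, sweep and acceptance figure exactly reproducible.
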