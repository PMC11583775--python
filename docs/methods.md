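# Methods

`printqa` models the digital-to-physical chain of medical 3D printing —
CT acquisition → threshold segmentation → digital editing → fused-filament
(FFF) printing — entirely in software, so that the error contributed by
each stage can be measured against known ground truth and combined into a
total error budget. This note documents the models, their assumptions, the
parameters that matter, and what the synthetic pipeline can and cannot say
about real clinical data.

## Error taxonomy and statistical summary

Each stage is characterised by a signed surface-deviation analysis between
an *analyzed* mesh and a *reference* mesh:

* **SegE** (segmentation error): ground-truth phantom vs. the direct
  segmentation result;
* **DEE** (digital-editing error): direct segmentation vs. the smoothed
  print-STL;
* **PrE** (printing error): print-STL vs. the (simulated) printed model.

For each sample point on the analyzed surface, the deviation is the
distance to the closest point on the reference surface, signed positive
outside the reference solid and negative inside; a negative mean therefore
means the analyzed object is smaller than the reference. Two summary
statistics are reported: the mean deviation ∆S̄ (location) and the
6σ-interval, the width of [mean − 3σ, mean + 3σ] (spread), which covers
≈ 99.73 % of normally distributed deviations. σ is the population standard
deviation of the samples (ddof = 0); at the sample sizes used (≥ 10⁴) the
distinction from the unbiased estimator is immaterial.

Assuming independent stages, the total error follows Gaussian error
propagation:

    ∆mean_total = ∆mean_SegE + ∆mean_DEE + ∆mean_PrE
    σ_total     = sqrt(σ_SegE² + σ_DEE² + σ_PrE²)

Independence is an assumption of the study design, documented here rather
than tested; no covariance terms are included. Note that a 6σ value
computed from a 4-decimal-rounded σ differs in the last digit from one
computed at full precision; reports include both to make the rounding
explicit.

## The phantom

`generate_benchy(complexity, seed)` builds a femur-like solid — spherical
head (r = 16 mm), angled cylindrical neck (r = 10 mm), flat-faced shaft
(34 × 24 × 36 mm) — joined by smooth-minimum fillets (k = 4 mm), with a
seeded ±0.5 mm free-form ripple and a flat base at z = 0. It is defined as
an implicit field and surfaced by marching cubes at pitch 1.2 mm /
`complexity`, so it is watertight by construction and bit-reproducible for
fixed `(complexity, seed)`. The enclosed volume (~54,200 mm³) matches the
scale of an adult proximal femur head–neck–shaft segment (≈ 52,000 mm³),
the object scale the 30,000 mm³ cut-off rule (below) was designed around,
so the cut-off partitions the threshold sweep realistically. The enclosed volume converges well within 1 % between complexity 3
and 5. The shape is designed to print base-down with only mild overhangs;
overhang angles are not formally verified.

## CT simulation

`simulate_ct(mesh, protocol)` is a stylised scanner, not a physics code:

1. **Partial volume.** Per-voxel solid occupancy `f ∈ [0, 1]` is computed
   by exact planar cross-sections of the mesh (shapely polygons, even–odd
   parity over closed rings) sampled on a 4 × 4 in-plane sub-grid, averaged
   over `max(4, ceil(dz / 0.4 mm))` through-slice sub-sections. Thick
   slices therefore smear the boundary exactly as the partial-volume effect
   does.
2. **HU mapping.** `HU = −1000 + f · (HU_object + 1000)` with
   `HU_object = +200` by default, placing the half-occupancy iso-level at
   −400 HU. The +200 value is a model choice for a plastic phantom scanned
   in air: it makes −400 HU the threshold that recovers the true surface
   and puts the surface break-up of noisy scans slightly above 0 HU. It is
   configurable.
3. **Kernel character.** `soft`: Gaussian PSF of FWHM 1.2 mm, noise
   σ = 15 HU. `bone`: sharper PSF (0.6 mm), an unsharp-mask edge boost
   (weight 0.5, base blur 2 mm), noise σ = 60 HU. These defaults are
   stylised; they are only meant to reproduce *orderings* (bone sharper and
   noisier than soft), never absolute scanner accuracy.
4. Values are clamped to [−1024, 3071] HU; noise is seeded and
   reproducible. Volumes are indexed (slice, row, col) with the world
   position of voxel (i, j, k) at `origin + (k·dx, j·dy, i·dz)`, voxel
   values at voxel centers.

The grid must contain the mesh plus a 3 × PSF margin (enforced). Occupancy
is cached per slice thickness and reused across kernels and noise seeds.

## Segmentation

A voxel is object iff HU ≥ threshold. The surface is extracted by marching
cubes either on the continuous HU field (sub-voxel interpolation, the
default — matching the smooth threshold response of clinical tools) or on
the binary mask (half-voxel staircase, used by the `d2p_like` profile).
The volume is padded with −1024 HU so boundary-touching surfaces close.
`keep_all` retains every closed component (reproducing island formation in
noisy bone-kernel data); `largest_component` keeps the largest-volume one.
A threshold at or above the volume maximum raises an explicit
empty-segmentation error (the iso-surface is degenerate there).

Bookkeeping follows the study's rules: the relative volume error is
100 · (V_seg − V_ref)/V_ref; segmentations with volume *less than*
30,000 mm³ (boundary inclusive: exactly 30,000 passes) are excluded from
surface-deviation analysis, because alignment between grossly different
surfaces is unreliable.

## Digital editing (smoothing)

Clinical tools expose smoothing on incompatible scales, so three generic
*profiles* reproduce parameterisations rather than vendor algorithms:

| profile         | method                      | low | medium | high |
|-----------------|-----------------------------|-----|--------|------|
| `slicer_like`   | volume median filter (mm)   | 1   | 3      | 5    |
| `brainlab_like` | mesh Taubin factor          | 0.66| 1.33   | 2.00 |
| `d2p_like`      | volume median filter (mm)   | 1   | —      | —    |

The mm median kernel is converted per axis to an odd voxel window (≥ 1);
sub-voxel kernels degrade to the identity with a warning. The mesh path is
Taubin-style two-step Laplacian smoothing (λ = 0.5, µ = −0.45,
`round(10·factor)` iteration pairs); the deliberate under-compensation
(|µ| < λ) produces the mild monotone shrinkage clinical smoothing shows,
while preserving triangle count and watertightness. Whether the commercial
tools smooth the label volume or the mesh is unpublished; both paths are
provided and profile-selected. Only within-profile orderings are
meaningful; absolute DEE magnitudes are not comparable between profiles.

**Known limitation.** The relative file-size change ∆Fi rel (file size
proxy: binary STL, 84 + 50·n_triangles bytes) is grid-bound under
marching-cubes re-extraction, so the empirical pattern that thinner-slice
models lose relatively *more* file size under heavy smoothing — an effect
of vendor remeshing/decimation — does not reproduce here (decimation is
deliberately out of scope). Volume and deviation orderings are unaffected.

## Print simulation

`simulate_print` deforms vertices only (connectivity, and hence
watertightness, is preserved):

* **Layer staircase**: z-coordinates are blended halfway toward the floor
  of their 0.3 mm extrusion layer (full snapping would self-intersect);
  the residual deviation stays below the layer height.
* **Warping**: vertical lift
  `w = A · exp(−d_interior / λ) · max(0, 1 − (z − z_min)/h)` with
  amplitude A (0 ≈ well-adhering printer, 1.0–1.5 mm ≈ poorly adhering),
  lateral decay λ = 10 mm from the base-footprint boundary inward, and
  affected height h = 5 mm. Corners and edges of the footprint lift most.
  A > h is rejected as self-intersecting.

The printing study draws five replicate amplitudes per printer around the
spec mean (relative σ 15 %, seeded), mimicking print-bed-position effects;
all draws are logged in the run manifest.

## Deviation engine

Built for exactness rather than speed-records, with no external spatial
index:

* **Closest point**: exact point-to-triangle distance (Ericson's
  region-based algorithm, vectorised) over candidates shortlisted by a
  KD-tree on triangle centroids (k = 16) plus the faces incident to the
  nearest vertex; verified against brute force to machine precision on the
  near-uniform tessellations iso-surfacing produces.
* **Sign**: solid inside/outside by vertical-ray crossing parity,
  accelerated by a uniform 2D grid over triangle xy-bounding-boxes, with a
  deterministic sub-nanometre xy jitter to step off edge-on ties. Chosen
  over normal-dot-product signing because it stays correct for internal
  islands and sharp edges; it requires a watertight reference.
* **Sampling**: all analyzed vertices when there are at most `n_samples`
  (default 100,000; the study pipeline uses 20,000 as a runtime choice),
  otherwise seeded area-weighted surface sampling.
* **ICP**: rigid only (no scaling, matching metrology "best fit");
  initialised by centroid match + principal-axes alignment with all four
  proper axis-sign combinations, each refined for up to 15 coarse
  iterations on a 500-point subset; the best candidate is polished with
  2,000 points until the RMS improves by < 10⁻⁶ mm (cap 200 iterations).
  Synthetic rigid motions (≤ 30°, ≤ 20 mm) are recovered to < 10⁻³ mm.
  A final RMS above 25 % of the reference bounding-box diagonal raises an
  error (alignment impossible); above 2 % the result is flagged
  `reliable=False` — grossly eroded shapes (e.g. a 55 %-volume copy) land
  in this band.
* **Export**: plain-text ASCII with five header lines (summary statistics)
  and one `x y z deviation` line per sample at 6 decimals; re-import
  reproduces the mean to 10⁻⁶ mm.

Deviation statistics are invariant under a common rigid transform of both
meshes, and swapping analyzed/reference for nested solids flips the mean's
sign (both tested).

## Study pipeline and default conditions

The default `StudyConfig` mirrors the full study design: 5 slice
thicknesses (0.4/0.6/1.5/3.0/5.0 mm) × 2 kernels = 10 protocols, the
seven-step threshold grid {−800, −600, −400, −200, 0, 100, 200} HU (the
non-uniform grid containing every discussed value), 3 software profiles
(= 210 segmentation records), the editing study on bone-kernel scans at
−600 HU and thicknesses 0.4/1.5/5.0 mm (3 + 3 + 1 levels × 3 thicknesses
= 21 print-STLs), two printers ("accurate" A = 0.1 mm, "warped"
A = 1.2 mm) × 5 replicates, and two total-error presets: configuration 1
(optimal: 0.4 mm, −400 HU, low smoothing, accurate printer) and
configuration 2 (worst-case: 5.0 mm, −600 HU, high smoothing, accurate
printer). In-plane spacing is 0.5 mm; the phantom is generated at
complexity 2, and 20,000 deviation samples are used per comparison —
problem sizes chosen so a full run finishes in minutes on one CPU while
every reported ordering is stable. Every random draw is derived from one
base seed via stable hashing and logged in a run manifest; re-running a
configuration reproduces every table bit-for-bit on the same platform.

## What the synthetic study does and does not show

The generator reproduces the *mechanisms* behind each stage's error —
partial volume, kernel noise and edge boost, threshold response, island
formation, smoothing shrinkage, layer quantisation, warping lift-off — and
the tests pin down the resulting orderings (volume monotone in threshold;
6σ growing with slice thickness; smoothing effects growing with level and
dominating slice thickness; bone-kernel fragmentation; warped printers
spreading the PrE; optimal vs. worst-case total error). Absolute deviation
magnitudes, however, are *not* comparable to measurements made with
physical scanners, commercial segmentation software, optical 3D scanners
and real printers: no beam hardening or scatter, no scanner-calibrated PSF
or noise texture, no vendor mesh post-processing, no extrusion-path or
infill mechanics, no optical-scan uncertainty. Consequently the pipeline's
total-error numbers demonstrate the propagation method and the relative
effect of parameter choices, not the accuracy of any specific device
chain.
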