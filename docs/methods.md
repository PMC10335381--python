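# Methods

This note documents the measurement definitions, the synthetic phantom that
validates them, the parameter choices that matter, and the numerical
conventions — in enough detail that every number the pipeline emits can be
traced to a definition here.

## Label volumes

The universal input is a 3D grid of integer class labels indexed
`(z, y, x)` with isotropic in-plane pixels (`dx = dy`, default 6 nm) and a
coarser section thickness (`dz`, default 120 nm; 100 nm also common).
Labels are mutually exclusive per voxel, matching "material"-style
segmentation tools; overlapping materials are out of scope.  A pixel's
physical position is its centre; all in-plane distances below are
centre-to-centre Euclidean distances in nm.  Class names come from a
controlled vocabulary (background, lumen, endothelium, basement_membrane,
pericyte, macroglia, neuron, other); at most one label per class.  On disk
a volume is a multi-page TIFF plus a JSON sidecar with the voxel sizes and
class map — plain text chosen over TIFF tags for transparency.  Upstream
raw-image processing (DM3 reading, contrast normalisation, drift
correction) and the segmentation itself are explicitly not part of this
package: labels are the input.

## Boundary proximity

**Boundary pixel.** A mask pixel with at least one 4-neighbour outside the
mask; the image border counts as outside.  4-connectivity of the test
yields closed 8-connected boundary chains and is applied uniformly.

**Minimal distances.** For an ordered pair (A → B) in one slice, each
A-boundary pixel contributes the distance to its nearest B-boundary pixel
(k-d tree; exact, ties irrelevant since only the distance is kept).
Distances are strictly in-plane: the anisotropic section spacing (6 vs
100–120 nm) makes through-plane pixel distances a different quantity, which
this pipeline deliberately does not compute.

**Histograms and CDF.** Distances are binned left-closed right-open with a
terminal overflow bin; defaults 6 nm bins (one pixel) to 2004 nm.
Per-slice histograms are normalised; the stack histogram is the
*unweighted mean* of per-slice histograms (so stack mean ± SD summaries are
well defined), with a pooled-pixels mode behind a flag.  Slices where
either class has no boundary pixels are excluded and the exclusion count
reported.  The CDF is the running sum × 100: its value at an upper bin edge
is the percentage of A-boundary pixels strictly below that edge.  Summary
readings at 10/100/250/500/1000 nm are therefore quantised to bin edges;
the contact fraction below is computed on raw distances instead.

**Contact fraction.** % of A-boundary pixels within 10 nm of B (default;
configurable).  With 6 nm pixels, 10 nm admits exactly the one-pixel axial
(6 nm) and diagonal (8.49 nm) offsets — pixels that are effectively
touching.

**Ensheathment coverage.** The abluminal endothelial boundary is the
endothelial boundary minus pixels 4-adjacent to the lumen.  Coverage in a
slice is the % of those pixels within 200 nm (default) of the pericyte
boundary; the full-mask distance is available behind a flag and differs
only when a pericyte is thinner than the threshold.  Slices with no
pericyte score 0 % and are *included* in the stack aggregate by default
(exclusion available), since an unensheathed stretch of capillary is a
biological 0 %, not missing data.

## Slice morphometrics

Objects are 8-connected components of a class mask with at least
`min_area_px = 16` pixels; smaller fragments are dropped and counted
(single pixels and 1-px lines make the hull and chain ratios ill-defined).
Border-touching objects are measured but flagged: their true extent is
censored by the field of view.

* **Area** A: pixel count (× dx² for nm²).
* **Perimeter** P: the Freeman chain code of the closed Moore-neighbour
  trace of the *outer* contour, starting at the topmost-leftmost pixel and
  walking clockwise; axial codes contribute 1 pixel, diagonal codes √2, no
  corner-correction factor (the classic chain-code estimator).  Interior
  holes do not contribute to P — for annular objects (endothelial tubes,
  BM sheaths) P is the outer perimeter.
* **Convex hull** CA/CP: the hull of the boundary pixel centres is
  rasterised back to a mask (pixel centre inside or on the hull, half-space
  test with 1e-9 tolerance) and then measured *with the same estimators* as
  A and P.  This "equivalent measurement" convention makes convex digital
  shapes score convexity = solidity = 1 exactly, at the cost of CA/CP being
  grid quantities rather than polygon quantities; the continuous-polygon
  variant is available via `hull_mode="polygon"`.  Degenerate (collinear)
  objects get flagged null hull metrics.
* **Radii**: centroid of *all* object pixels; distances from it to each
  boundary pixel, summarised as mean/min/max.
* **Ratios**: convexity CP:P, solidity A:CA, sphericity Rmin:Rmax.
* **Summaries**: per slice and class, area-weighted means Σ(Aᵢmᵢ)/Σ(Aᵢ).

A 10×10 digital square gives sphericity √(0.5² + 4.5²)/(4.5√2) ≈ 0.711 —
a useful analytic anchor — and a radius-50 digital disk scores ≥ 0.98 on
all three ratios except sphericity (≈ 0.98).

## Peg-and-socket detection

Pericyte–endothelial pegs are detected in both directions (pericyte finger
in the endothelium, and vice versa).

**Candidates.** Per slice, the host class is dilated by a Euclidean disk
(`dilation_px = 2`, i.e. 12 nm — just above the direct-contact scale) and
intersected with the protruding class; the intersection seeds an
8-connected geodesic flood fill within the protruder up to
`context_radius_px = 18`, chosen to exceed the half-width of any plausible
peg so the whole finger is captured; grown voxels are merged into
26-connected 3D components.  Adjacency across sections is topological,
not metric, despite the anisotropy.  This stage intentionally over-tags:
flat close-apposition patches and the host-side lining of a true peg of
the partner class all become candidates, and the criteria must reject them.

**Protrusion core.** The grown candidate necessarily includes a collar of
its own cell body.  The core is the candidate minus an in-plane Chebyshev
dilation of the residual body (the protruder class minus the candidate) by
`core_margin = context_radius + dilation = 20 px`.  A real peg retains a
substantial core; contact strips and most socket linings lose theirs.

**The five criteria.**
1. *z-span*: distinct member sections × dz ≥ 200 nm, closed inequality
   (so 2 × 100 nm qualifies, 1 × 120 nm does not, 3 × 120 nm = 360 nm
   comfortably does).
2. *Attachment*: in ≥ 1 member slice the candidate is 8-adjacent to the
   slice's largest same-class component excluding itself ("cell body"
   operationalised as the largest component; detached islands fail).
3. *BM traversal*: the BM break band is (morphological closing of the BM
   mask by a disk of `r_bm_px = 12`) minus the BM.  A 12 px (72 nm) disk
   bridges breaks up to ~24 px across — wide enough for pegs at and above
   the 70 nm minimum width — while leaving wide BM-absent sectors
   unbridged, so candidates there correctly fail.  The criterion passes
   when the core, re-dilated by the core margin (it was carved away from
   the band by exactly that margin), meets the band.
4. *Engulfment*: in ≥ 1 member slice, the dominant connected component of
   the core must have ≥ θ = 2/3 of its exposed boundary pixels (those with
   a non-self-class 8-neighbour) adjacent to the host, the component must
   be compact (rasterised-hull solidity ≥ 0.75), and host contact must
   come from opposing directions (two contact pixels ≥ 120° apart as seen
   from the component centroid).  The last two conditions encode what
   "engulfed" means geometrically — a solid finger gripped on both flanks —
   and are what reject socket linings, which are concave around their
   apparent host or touched from one side only.  θ ≤ 0 degenerates to
   "any host contact".
5. *Minimum extent*: some single core component in some slice measures
   ≥ 100 nm along its principal major axis and ≥ 70 nm along the minor
   axis (projection extent + one pixel of footprint; a single pixel counts
   one pixel).

A candidate is an accepted peg iff all five hold.  The per-slice
z-distribution counts accepted pegs present in each section (a peg
spanning N sections appears in all N); the object-level count is the
number of accepted candidates.  Determinism: all steps are
order-independent morphology; reruns are identical.

Known limitation: two pegs engulfed in the same sections at small angular
offset (< ~30° on the phantom geometry) grip the host tissue between them
from both sides, creating a genuinely ambiguous sandwich that can be
mis-scored; the detector makes no attempt to split such interlocked pairs.

## The phantom generator

The generator renders what the analyses expect to see in a segmented
capillary stack, at desk scale (512 × 512 px at 6 nm/px rather than
3000 × 3000; thicknesses in real nm so all thresholds keep their meaning):

* concentric rings per slice — lumen radius 700 nm, endothelium 350 nm
  thick, BM 60 nm, pericyte sheath 250 nm, an outer macroglia/neuron
  patchwork (70/30 by angle, 6 patches) to 1500 nm, background beyond.
  The BM and cell thicknesses are order-of-magnitude anatomical choices —
  capillary BM is a few tens of nm, pericyte processes a few hundred — and
  are parameters, not claims;
* a pericyte arc covering a target fraction of the circumference.  The
  *rendered* arc is shrunk by the arc-end capture angle
  √(cov² − g²)/√(r₁r₂) (g = BM thickness, r₁, r₂ the abluminal and
  pericyte-inner radii) so the *measured* ensheathment at the calibration
  threshold (200 nm) equals the requested fraction: abluminal pixels just
  beyond the arc end still fall within the threshold of the arc-end edge,
  and an uncalibrated arc reads ~5 points high.  Default target 0.35,
  matching reported pericyte ensheathment of retinal capillary endothelium
  (~35 %, between classic lower 2D estimates of 41–58 % partial coverage
  measures);
* band-limited boundary jitter (harmonics 2–5 of angle, slowly drifting
  with z, total amplitude ≤ `jitter_nm`, default 12 nm) so classes stay
  simply connected — per-pixel noise would shred the thin BM;
* BM gaps: angular sectors over a z-range whose inner half becomes
  endothelium and outer half takes the class just outside the BM, bringing
  the neighbours into direct contact as real BM gaps do;
* pegs: rectangular-cross-section radial fingers (corner rounding omitted
  — the criteria are extent-based, not curvature-based) with an 18 nm base
  overlap into the parent sheath (attachment), an optional exactly
  peg-wide BM carve (traversal), a 42 nm BM plug for detached decoys, and
  an L-shaped flank + tip BM exposure for under-engulfed decoys.

Determinism: identical parameters (including seed) render byte-identical
volumes; all randomness flows through one seeded generator.

The canonical fixture suite holds a full sheath, a half sheath, and a
16-slice gallery with six valid pegs (both directions) and five decoys,
each violating exactly one criterion; a 24° BM-free sector doubles as the
traversal decoy's home and as a flat contact patch exercising the
candidate superset behaviour.  Gallery pegs are spaced ≥ 32° apart and
staggered in z (see the sandwich limitation above).

**What the phantom does not emulate** — and hence what passing tests do
not show about acquired data: irregular non-annular cell shapes, branching
pegs, segmentation errors and inter-annotator variability, staining/imaging
artefacts, capillary curvature through the stack, and multiple capillaries
per field.  Validation here demonstrates that the *measurements* are
correct on known geometry, not that segmentations of real tissue are.

## Pipeline

`RunConfig` (YAML/JSON round-trippable) drives simulate/load → proximity →
morphometrics → pegs; every artifact is CSV or JSON under one output
directory with a manifest recording parameters, seed, package version and
per-stage status.  Proximity runs all ordered pairs among the five
analysis classes by default.  CSV floats are written at 10 significant
digits; reruns with identical configuration are byte-identical, which the
test suite asserts.  `report` condenses a run into the pairwise CDF
readings at 10/100/250/500/1000 nm, the coverage summary, per-class shape
ratios and the peg z-distribution.

## Problem sizes

Tests and the acceptance script use 2–16 slice phantoms at 512 × 512 px,
200 random mask pairs on ≤ 64 × 64 grids for the distance oracle, and a
radius-50 digital disk — sizes chosen so the full validation runs in a few
minutes on one CPU while every geometric regime (full/partial/absent
sheath, narrow and wide BM breaks, both peg directions, all five decoy
modes) is exercised.  All statistics scale linearly in slices and pairs;
nothing in the implementation assumes desk scale.
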