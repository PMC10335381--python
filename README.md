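# nvuquant

Quantitative analysis of segmented serial block-face SEM (SBF-SEM) volumes
of retinal capillaries — the cellular architecture of the neurovascular
unit (NVU) measured from voxel-label segmentations.

SBF-SEM stacks of capillaries (typically 3000 × 3000 px sections at
6 nm/px, cut at 100–120 nm) are segmented into lumen, endothelium,
basement membrane (BM), pericyte, macroglia and neuron labels.  `nvuquant`
takes such label volumes (multi-page TIFF + JSON metadata sidecar) and
computes three families of measurements:

1. **Boundary proximity** — for each ordered class pair (A → B) and each
   slice, the in-plane distance from every boundary pixel of A to the
   nearest boundary pixel of B; per-slice normalised histograms, the
   unweighted stack-mean histogram ± SD, and the cumulative distribution
   function CDF(d) = % of A-boundary pixels within d of B.  Derived
   summaries: the *direct-contact fraction* (d ≤ 10 nm, i.e. within two
   pixels) and *pericyte ensheathment* — the % of the abluminal endothelial
   boundary within 200 nm of the pericyte layer, per slice and as stack
   mean ± SD with range.
2. **Slice morphometrics** — per object: area A (pixel count), perimeter P
   from the Freeman chain code of the Moore boundary trace (axial steps 1,
   diagonal √2), convex-hull area CA and perimeter CP measured on the
   rasterised hull with the same estimators, and centroid-boundary radii;
   ratios convexity = CP:P, solidity = A:CA, sphericity = Rmin:Rmax, with
   area-weighted per-slice class means.
3. **Peg-and-socket detection** — membrane fingers of pericyte or
   endothelium engulfed by the partner cell through a BM break.  Candidates
   come from per-slice dilation–intersection of the two classes, grown into
   3D components, and are accepted only if they pass five compulsory
   criteria: z-span ≥ 200 nm, attachment to the cell body, BM traversal,
   engulfment by the host, and minimum 100 nm × 70 nm extents.

Because acquired stacks are enormous and segmentation is manual, every
stage is validated against a **synthetic capillary phantom generator**
(`nvuquant.phantom`) that renders the same anatomy at desk scale with
exact ground truth: calibrated pericyte coverage, BM gaps, and pegs
annotated with exactly which criteria they satisfy.

## Worked example

```python
from nvuquant import PhantomParams, analyze_pair, ensheathment_coverage, \
    generate_capillary_volume

vol, truth = generate_capillary_volume(
    PhantomParams(n_slices=6, pericyte_coverage_frac=0.35, seed=42))
cov = ensheathment_coverage(vol, coverage_nm=200.0)
print(f"ensheathment {cov.mean_pct:.1f} +/- {cov.sd_pct:.1f} %")
res = analyze_pair(vol, "pericyte", "endothelium")
print(f"contact {res.contact_pct_mean:.2f} %, CDF(500 nm) {res.cdf_at(500):.1f} %")
```

prints

```
ensheathment 33.7 +/- 0.0 %
contact 0.00 %, CDF(500 nm) 100.0 %
```

— the phantom was asked for 35 % pericyte coverage and the measured
ensheathment lands within a point of it; with an intact ~60 nm BM between
the cells there is no direct contact, while every pericyte boundary pixel
is within 500 nm of the endothelium it wraps.

The `examples/` directory holds one short script per capability
(phantom + I/O, proximity, morphometrics, peg detection, full pipeline);
each prints the numbers it computes and what they mean.  A thin CLI wraps
the pipeline: `nvuquant simulate | run-all | proximity | morph | pegs |
report` (see `nvuquant --help`).

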