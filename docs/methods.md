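# Methods

This note documents the models, conventions, parameters and numerical
choices behind `meniscovasc`, and what the phantom-based validation does and
does not establish.

## Conventions

All volumes are `(z, y, x)` arrays; z runs proximal → distal with the
superior (femoral) surface at low z. Coordinates are 0-based voxel indices;
physical positions come from the per-axis spacing in μm (nominal 30 μm
isotropic; NRRD headers store mm and are converted ×1000). Anisotropic
spacing is supported throughout: distance transforms, path metrics and the
zone-0 margin all use physical units.

## Segmentation

The vessel mask is `(volume > T_kapur) ∪ (tophat > T_tophat)` followed by
removal of 26-connected components below `min_component_vox` (default 27
voxels ≈ a 3³ speckle; the despeckling size is an implementation choice).

* **Kapur threshold.** For histogram probabilities `p_i`, the threshold `t`
  maximizes the summed Shannon entropies of the two normalized class
  distributions (`level ≤ t` vs `level > t`); splits leaving a class empty
  are excluded, and exact ties break toward the smallest `t` (deterministic,
  and the sensitive choice for bright vessels). Integer images whose range
  fits the bin budget use exact per-level histograms, so the threshold is a
  gray level; otherwise the range is binned (default 256 bins).
* **White top-hat.** Volume minus its grey opening by a discrete Euclidean
  ball (default radius 2 voxels). The response is non-negative and
  anti-extensive; structures wider than the element are suppressed, so the
  detector targets vessels up to ~4–5 voxels (120–150 μm) across; thicker
  vessels are the global threshold's job.
* **Binarizing the top-hat.** The response is itself thresholded by the
  Kapur rule (mode `entropy_on_tophat`; a fixed cutoff is available). When
  an organ mask is supplied, the top-hat detection is restricted to the
  organ interior — voxels deeper than one structuring-element radius (+1)
  from the organ boundary. A grey opening responds wherever the *organ
  itself* is thinner than the element, most prominently the tapering free
  edge of the meniscal wedge, because its local background estimate there is
  taken from outside the organ; inside the interior the estimate is genuine
  tissue and the response measures local vessel contrast. This is what makes
  the union genuinely complementary: under shading/bias fields the global
  threshold under-segments dim fine vessels in dark regions while the
  background-subtracting top-hat still detects them, and on ideal phantoms
  the interior restriction removes all boundary artifacts so segmentation is
  exact.

## Centerlines and the vessel graph

Skeletonization is 3D topology-preserving thinning; the skeleton is a subset
of the mask with the same 26-connected component count. Thinning of objects
that are exactly mirror-symmetric about an *inter-voxel* plane can collapse
entirely (a parallel-deletion degeneracy); the phantom therefore uses an odd
z extent so generated tubes are voxel-plane-centered. Real, asymmetric data
are unaffected.

Graph construction: skeleton voxels with ≠ 2 neighbors (26-connectivity)
are node voxels; adjacent node voxels merge into one node (endpoint or
branch by maximal degree); segments are maximal degree-2 chains between
nodes, plus pure cycles. Spurs — endpoint-terminated segments shorter than
`prune_spur_um` (default 60 μm = 2 voxels, removing thinning artifacts) —
are deleted and nodes recomputed once.

* **Length.** Summing raw voxel steps (1, √2, √3 × spacing) overestimates
  smooth curves by ~5% on average (staircase bias), which would bias
  tortuosity upward. The default estimator sums chords of the centerline
  resampled every 5 voxels (endpoints included): exact on digitized straight
  lines, residual bias below ~1% at vessel-scale curvature (measured −2% on
  a semicircle of 40-voxel radius, against +3% for the step metric). The raw
  metric remains available (`length_metric="steps"`).
* **Tortuosity** = length/chord. Closed loops (chord 0) are reported as NaN
  and excluded from means rather than assigned a value. Digitization jitter
  (±0.5 voxel) means oblique straight tubes measure up to ~1.02; axis-aligned
  tubes are exact.
* **Diameter** = 2 × mean EDT of the mask along the centerline, in μm.
  Border-touching path voxels are excluded (with a warning) because the EDT
  underestimates where the field of view cuts the vessel. Accuracy is ~10%
  for radii ≥ 3 voxels; below that the half-voxel surface-rasterization
  bias dominates (a 1-voxel line reads 60 μm at 30 μm spacing). The
  documented recovery bound used in tests is 10% relative plus one voxel
  absolute.
* **Segment volume.** Every mask voxel is assigned to its nearest centerline
  voxel (physical distance), so per-segment volumes sum exactly to the mask
  voxel count. Exact distance ties resolve deterministically by query order.

## Zonation

* **Transverse layers.** Each (y, x) column of the organ mask is split into
  local-thickness thirds along z, following the curved femoral/tibial
  surfaces (mode `local`; a `global` z-extent cut is available). Remainder
  rule is center-biased: `m ≡ 1 (mod 3)` gives the extra voxel to the
  intermediate layer (a 1-voxel column is intermediate); `m ≡ 2` gives the
  extras to superior and inferior.
* **Circumferential (ISAKOS) zones.** Per axial slice, boundary pixels are
  classified by the angle between the outward normal (pixel minus the
  centroid of its in-mask 3×3 neighborhood) and the radial direction from
  the arc center (Kåsa circle fit to the projection boundary): outer rim if
  the normal points outward (cos ≥ 0.5), inner edge if inward (≤ −0.5); the
  flat end caps of the C-arc have tangential normals and belong to neither
  set. The normalized width `w = d_outer/(d_outer + d_inner)` (exact 2D
  EDTs to the two sets) defines zones 1–3 at thirds; `w` is computed
  per-slice, so on a wedge the zones follow each slice's local width.
  Zone 0 is the set of extra-meniscal voxels within `margin_um` (default
  500 μm; the perimeniscal extent is not standardized and is configurable)
  of the outer-rim voxel set and no closer to any other part of the organ
  surface. Layer and radial labels are extended onto this shell by
  nearest-organ-voxel inheritance so extra-meniscal vessels are attributable
  to a layer.
* **Radial thirds.** The C-arc centerline is the longest weighted path of
  the 2D skeleton of the axial projection. Two voxel-scale artifacts are
  corrected: the flat arc caps grow diagonal medial-axis branches into the
  corners (the projection is opened with a disk at 80% of the typical half
  band-width first, rounding the caps so the skeleton ends on-axis), and
  thinning retracts each end by about the local half band-width (each end is
  extrapolated along its tangent, capped at the EDT value there). The
  parameter of a voxel is then its position along the arc: when a circle
  fitted to the centerline is good to < 1.5 px rms — the generic C-shape —
  the angular coordinate about the fitted center is used (smooth, and
  identical to arc length on a true arc); otherwise each voxel takes the
  cumulative length at its nearest centerline vertex. Thirds of the total
  parameter define anterior/middle/posterior. Which end is anterior cannot
  be inferred from a mask; the `orientation` field (e.g. `anterior=+y`)
  declares it.

## Quantification and statistics

Volume contributions are voxel ratios (`100·|vessel ∩ L ∩ Z|/|vessel ∩ L|`),
computed on mask voxels, not on graph segment volumes; both normalizations
(per layer and per zone) are emitted because published zone tables use
either. Layers with no vessel voxels yield missing percentages. Segments
are attributed to layers by majority of centerline voxels (ties →
intermediate). SEM uses the n−1 standard deviation over √n. The Tukey–Kramer
statistic is `q = |m_a − m_b| / sqrt(MSW/2·(1/n_a + 1/n_b))` against the
studentized-range distribution with N−k error df; with equal group sizes it
is the plain Tukey HSD. With zero within-group variance and equal means, F
is defined as 0 (p = 1). The sampling unit for layer comparisons (segment
vs specimen) is the caller's declaration (`compare_layers(..., unit=...)`).

## Phantom and what validation shows

The phantom is a 180° half-annulus (outer 66 / inner 38 voxels at 30 μm —
a scaled-down organ that keeps all three zonation axes resolvable on a
desk-sized grid) with a triangular wedge cross-section, 36 voxels high at
the rim and tapering to the free edge. Vessel trees root in the
perimeniscal shell and grow inward, bifurcating with diameters tapering
×0.68 per level over 30–160 μm; roots are spread over the rim height so
every transverse layer receives supply, matching the organ's described
vascular pattern. Intensities are background/tissue/vessel = 20/90/230 with
additive Gaussian noise σ = 7 (5% of the vessel–tissue contrast) as the
default noisy condition. Tubes are rasterized by exact point-to-polyline
distance; a `straight` layout (non-touching radial tubes at declared angles
and transverse offsets) provides cases where every downstream count has a
closed-form answer. Tree density and branching order are free parameters of
the generator, not anatomical claims.

Ground truth is computed from the generating geometry: masks and centerlines
analytically, and per-zone voxel counts by a brute-force *reference
zonation* (per-column loops, per-pixel normal classification, direct
point-set distance minimization) that implements the same label definitions
as the pipeline independently; the only shared non-trivial primitive is the
EDT feature transform used for shell label inheritance, where tie-break
determinism requires it. On the default phantom the reference and pipeline
layer/circumferential/extended maps agree bit-exactly; radial labels agree
away from the third boundaries (the reference uses the analytic arc angle).

Passing tests therefore establish: exact equivalence of the entropy
threshold with exhaustive search; exact segmentation of ideal phantoms and
≥0.95 Dice at 5% contrast noise; tortuosity and diameter recovery within
the stated bounds; zonation agreement ≥95% with closed-form annulus rules
and exact partition properties; exact end-to-end recovery of per-zone
contributions for non-touching tubes and ≤3-point recovery under noise;
and statistics matching textbook/reference computations with a calibrated
family-wise error rate. They do **not** establish robustness to
reconstruction artifacts (rings, beam hardening), intensity inhomogeneity,
contrast-agent filling defects, organ-mask errors, or anatomies whose
projection is far from a circular C — the phantom deliberately omits all of
these.

## Problem sizes

Validation uses the default 45×177×100-voxel grid (~0.8 M voxels), 10 seeds
for the stochastic checks, and 2,000 replicates for the Monte-Carlo null
calibration — sizes chosen so the full suite and the acceptance script each
run in minutes on a single core while leaving the stochastic bounds
well-resolved.

## Known limitations

Sub-voxel vessels (< 60 μm at 30 μm spacing) are detected but their
diameters carry the half-voxel bias described above; junction voxel
clusters can split hub geometry into short segments on noisy masks (spur
pruning mitigates this); the per-slice width coordinate makes circumferential
zones follow the local slice width on strongly tapered organs; and the
radial axis requires a declared anterior orientation.
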