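# Methods

## Scope and assumptions

The package operates on *detected-spot exports*, not images: a membrane
channel reduced to a dense point cloud with per-spot cell labels, and mRNA
channels reduced to per-molecule coordinates. Everything upstream —
staining, imaging, deconvolution, the segmentation that produced the cell
labels, and spot detection itself — is assumed done by acquisition
software. Coordinates are continuous physical micrometres throughout.

The central modelling choice is that a cell is the **convex hull** of its
membrane spots. Blastoderm cells are near-convex columnar prisms, and
convexity gives exact containment tests (face half-spaces), exact pairwise
distances (a small convex program), and an exact expansion–intersection
rule. Strongly non-convex cells would be clipped to their convex envelope;
alpha-shape reconstruction is a known, deliberate omission.

## Contact neighbours

Two cells are immediate neighbours when their polygons, each expanded in 3D
by a radius *r*, intersect. Expansion by *r* is a Minkowski sum with a ball
of radius *r*; for convex bodies the expanded pair intersects **iff** the
original pair distance is `< 2r`. The implementation therefore never
offsets meshes (vertex-push offsetting under-expands near large faces and
depends on the triangulation) and instead evaluates:

1. a k-d tree prefilter on centroids with the conservative bound
   `‖cᵢ − cⱼ‖ ≤ circumradiusᵢ + circumradiusⱼ + 2r`, which cannot discard a
   true pair;
2. cheap exact bounds per candidate: the minimum vertex–vertex distance
   (upper bound) and the best separating gap along the centroid direction
   and coordinate axes (lower bound);
3. only for the rare undecided pair, the full distance: an LP feasibility
   test for intersection, then the convex QP `min ‖x − y‖²` with `x`, `y`
   constrained to the two hulls (SLSQP, started from the closest vertex
   pair, `ftol 1e-14`).

The default *r* = 0.6 μm is ~10% of a cell diameter — small enough that
only true membrane-sharing pairs come within `2r`, large enough to absorb
reconstruction noise. It can instead be given as a fraction of the median
cell diameter (equivalent-sphere diameter `2(3V/4π)^⅓`). A pair at exactly
`2r` counts as non-adjacent (strict `<`): a measure-zero tie resolved for
determinism. Containment and convexity checks use a 1e-9 μm tolerance.

The radius alternative links every pair of cells whose centre points lie
within a user radius *R*; `R = 0` yields no edges, and coincident centroids
of distinct cells are linked and logged. It suits "cells within a
neighbourhood area" questions, whereas the contact method stays strictly
"cells sharing membrane" even when cell sizes vary.

Cells whose spot cloud cannot support a 3D hull (< 4 non-coplanar points)
are excluded from geometry and reported as degenerate, never fabricated.

## Spot assignment

A spot inside exactly one unexpanded hull takes that cell; inside several
(reconstructed hulls can overlap slightly under membrane noise) it takes
the nearest-centroid cell and is flagged ambiguous — deterministic and
order-independent; inside none it stays unassigned, mirroring transcripts
basal to the membrane-ingression limit whose cell of origin is unknowable.
Unassigned/ambiguous fractions are logged and recorded in the run manifest.

## Variability statistics

For a focal cell *i* with counts *x*, neighbours *j = 1..k*, and the group
G = {i} ∪ neighbours:

- `Fano = Var(G) / Mean(G)`, population (divide-by-n) variance, since
  variance and mean are population measures of the group; the sample
  variance is exposed as an option. Every group member shares the value in
  spirit, but the table stores it per focal cell as a moving-group
  statistic. Mean-zero groups score 0 by convention (not NaN) so heatmaps
  stay well defined; Poisson-distributed counts give Fano ≈ 1.
- `NV_i = meanⱼ |x_i − x_j| / X_max`, with `X_max` the per-gene maximum
  over the analysed cells only. Adding a constant to focal and neighbours
  leaves the numerator unchanged, so equal absolute contrasts at different
  baselines score identically.
- `PV_i = meanⱼ |x_i − x_j| / max(G)`. The focal cell belongs to the group
  maximum — forced by the defining case, one transcript amid zeros, which
  must score exactly 1 rather than divide by zero. Equal absolute contrasts
  on a higher baseline score *lower*: proportionality.
- The PV filter zeroes `pv_filtered` when `Mean(G)` is below the threshold
  (default 1 mRNA, inclusive at exactly 1); the group includes the focal
  cell, consistent with the Fano group, so the isolated-single-transcript
  cell is filtered out. `pv_raw` is always kept.

Isolated cells (no neighbours) score 0 on all three measures and carry an
`isolated` flag rather than being dropped, keeping tables rectangular.
Count histograms use right-closed integer bins `[1..w], [w+1..2w], ...`
(default width 5) with zero-count cells excluded by default; with zeros
included they get their own `0` bin so the positive bin edges are stable.

Two utilities round out the statistics: the nascent ratio (transcription-
site intensity over a reference single-mRNA intensity, typically the
embryo-wide median) estimating nascent-transcript number, and a Spearman
rank concordance between per-cell counts of two colour channels reporting
the same transcripts (constant vectors are reported as undefined, NaN).

## Synthetic embryo generator

The generator defines the study conditions the tests run under.

| parameter | default | rationale |
| --- | --- | --- |
| cells | 2000 target (2002 realised, 26 × 77 sheet) | blastoderm-scale monolayer |
| cell diameter | 6.0 μm | columnar blastoderm cells (5–6 μm) |
| depth | 9.6 μm | apical → basal membrane-ingression limit |
| membrane spots/cell | 40 (≈ 80,000 total) | dense membrane representation |
| membrane jitter | 0.1 μm Gaussian | free choice: no measured placement-noise model exists; exposed as a parameter |
| mRNA inset | 0.1 μm | keeps sampled molecules off shared boundaries |
| count noise | negative binomial, variance/mean = 3 | transcriptional counts are overdispersed relative to Poisson |
| gene panel | 7-stripe (peak 80), broad domains (peaks 120/60/50), gradient (peak 100) | pair-rule-like and gap-gene-like patterns at realistic peak levels (order 10² mRNA/cell) |

Cells are hexagonal prisms on a row-offset hexagonal lattice, so footprints
tile the plane exactly and the ground-truth adjacency (pairs one spacing
apart) coincides with hexagon-edge sharing; interior cells have exactly six
true neighbours. The AP axis maps to lattice x normalised to [0, 1];
profiles are 1-D in AP and constant dorsoventrally. Stripe profiles are
sums of Gaussian bumps at evenly spaced centres, broad domains
logistic-edged plateaus, gradients exponentials — all with graded borders.
Membrane clouds always include the 12 prism corners, so a zero-jitter cloud
reconstructs the exact prism. A two-channel mode thins each cell's count
twice, independently, with detection probability p (default 0.5), emulating
interleaved probe sets.

What the generator does **not** emulate: optical blur and detection
error (spots are never lost, split or merged), cell-shape irregularity and
curvature of the real embryo surface, basal mRNA leakage between cells, and
segmentation errors in the membrane channel other than isotropic spot
jitter. Passing tests therefore certify the computational pipeline —
geometry, assignment, statistics, determinism — under controlled noise, not
robustness to every imaging pathology.

## Verification choices and problem sizes

- Adjacency recovery runs on the full-scale default embryo (2002 cells,
  jitter 0.1 μm): contact detection at r = 0.6 μm must match lattice truth
  exactly for ≥ 85% of cells with per-cell degree error ≤ 1 (it is in fact
  exact for all cells at these settings).
- Exact count recovery runs at zero membrane jitter, where hulls equal the
  prisms: every inset-sampled spot must return to its generating cell and
  the count table reproduce exactly. Under default jitter a handful of
  spots (~0.04%) near jittered corner cut-offs fall outside every hull, so
  exactness is asserted where it is a property of the machinery rather than
  of noise.
- The geometry oracle is independent of the implementation: hull surfaces
  densely sampled (all vertices, subdivided edges, area-weighted face
  points) and projected onto the opposing mesh with exact point-to-triangle
  distances (trimesh); the closest polytope–polytope feature always
  includes a vertex/edge of one side or a face-parallel region, so the
  sampled minimum is essentially unbiased.
- Bounds of NV/PV are checked by exhaustive enumeration (focal 0–20 ×
  all neighbour multisets of sizes 2–3 over 0–20) plus 10⁵ seeded random
  configurations of sizes 4–8; statistical calibrations use 10⁵ Poisson
  draws (tolerance ±0.02 around 1), 10⁴ negative-binomial cells (±0.2
  around 3), and 500-cell thinned channels (Spearman > 0.9).
- Determinism is asserted byte-for-byte on all CSVs across repeated
  pipeline runs (400-cell runs in the suite; determinism is
  size-independent). One embryo seed fans out to stage seeds by fixed
  offsets (+0 lattice, +1 counts, +2 membrane, +3 mRNA) so stages can be
  regenerated in isolation.

## Known limitations

Convex cells only; single monolayer (no 3D cell packing); patterns vary
along one axis; no image-level simulation; the Fano/NV/PV machinery assumes
integer counts and will refuse negative or fractional input rather than
guessing intent. SLSQP distances are accurate to ≪ 1e-3 μm but are not
symbolic: ties within ~1e-9 of the 2r threshold are resolved by the strict
inequality.
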