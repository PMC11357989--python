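# Methods

This note documents the models, conventions and numerical choices behind
`morphoheart`, and what the synthetic test bed does and does not establish.

## Frame and units

All coordinates are micrometres in a fixed anatomical frame:
x = left(−)→right(+), y = ventral(−)→dorsal(+), z = caudal(0)→cranial(+).
Meshes imported from mirrored image data are expected to be flipped before
analysis; the frame tag is carried on every `LandmarkSet`. No implicit
rescaling happens anywhere.

## Distances on tissues

Landmark-to-landmark distances are graph geodesics: shortest paths along
mesh edges with Euclidean weights (Dijkstra on the edge graph). For tissue
meshes at a few-µm edge length the difference to exact polyhedral geodesics
is far below measurement noise. Border lengths (d1, d2) are measured along
the *outline* of the open midsurface: each landmark is projected to its
closest boundary vertex and the shorter of the two boundary arcs between
the projections is summed edge by edge. The dorsal closure gap *l* is the
minimum Euclidean distance between the two dorsal lip sub-arcs, each
densely resampled (boundary vertices plus uniform subdivisions, ≥100
samples per lip).

## Midsurface extraction

Thin tissue shells (≈20 µm wall-to-wall) are collapsed to a zero-thickness
midsurface by wall pairing:

1. An inward normal ray is cast from every vertex; hits on an opposing
   wall (face normal vs. vertex normal dot < −0.3) at a plausible distance
   estimate the local thickness. If more than 5% of opposing-wall rays
   exceed `max_thickness` the input is rejected as not thin.
2. The two walls are identified by 2-colouring the vertex graph with a
   parity union-find. Constraints are applied in decreasing order of
   trust: ray pairings with near-antiparallel normals at 0.4–1.5× the
   median thickness (opposite walls); edges between vertices with agreeing
   normals, most-agreeing first (same wall); tangential crease edges
   (appendages continue their wall). Later constraints that contradict
   established parity are dropped, which makes the labelling robust to
   grazing-ray artefacts at rim rings and sharp creases. A final majority
   relaxation over confidently smooth edges cleans isolated mislabels.
3. The wall with the larger area supplies the output connectivity. Each of
   its vertices is paired with its nearest opposing-normal vertex on the
   other wall (for a thin shell the true partner is one thickness away,
   all other candidates at least a mesh spacing farther); the midpoint of
   the pair is the midsurface position. Vertices without a valid pairing
   (rim ring, sharp creases) inherit the mean pairing offset of their
   neighbours.
4. The result is smoothed with 10 fixed Laplacian iterations at step
   λ = 0.05 (boundary fixed). The step is deliberately small: at ~100 µm
   curvature radii, stronger smoothing shrinks the surface by several µm,
   comparable to the quarter-thickness accuracy the method targets.

Limitations: the method assumes a locally thin two-walled shell; it does
not compute curve skeletons and makes no guarantee for branching solids or
features whose width is comparable to the shell thickness.

## Landmark surface maps and sequence propagation

Maps between topologically equivalent meshes are built from ≥4
non-coplanar landmark pairs: a thin-plate-spline warp (exact at the
landmarks, reproducing affine motions) deforms the reference, and each
warped vertex is projected to its closest point on the target surface
(k-d-tree-pruned exact point-triangle distance; ties to the lowest face
index). Bijectivity is *not* guaranteed; the duplicate-target-face rate is
reported as an a-posteriori diagnostic. Along a staged sequence,
consecutive maps are composed so every mesh is re-expressed on the first
mesh's connectivity, then all shapes are rigidly aligned (orthogonal
Procrustes, SVD with reflection excluded; no scaling) to the first.

Torus-topology stages (the dorsally closed heart tube) are opened along a
user-supplied non-separating edge cycle: the cycle vertices are
duplicated, one side's faces re-wired, and both emerging boundary loops are
fan-triangulated from their centroids, yielding genus 0 (verified by Euler
count). The cosmetic seam extrusion some pipelines apply is omitted.

## Staging

`compute_measurements` returns d1, d2, h, w (axis-aligned extents in the
standard frame), the dorsal gap, a myocardial width (geodesic between the
ventral midpoints of the two borders) and optional precomputed e1/e2
scalars, plus the derived ratios. Ratios are invariant under rigid motion
and uniform scaling by construction.

Group structure is found with 1-D k-means (scikit-learn, best of 50
restarts from a fixed seed) scored by the average silhouette coefficient;
members of singleton clusters score 0 (common convention). The selector
returns the (parameter, k) pair with the highest s̄; ties break toward
earlier columns and then smaller k, constant columns are excluded with a
warning and rows with missing values are dropped listwise.

Stage prediction against a mean-shape sequence maps each candidate
keyframe onto the specimen, computes the size-normalised morphological
distance D, and fits a Gaussian (amplitude, mean, σ; nonlinear least
squares initialised at the best match) to 1/(D+ε) as a function of the
keyframes' d1/d2, ε = 1e−9 × mean edge length. The fitted peak, clamped to
the 5-keyframe bracket (the keyframe with closest d1/d2 ± 2), is the
predicted stage; a failed fit falls back to the closest keyframe, flagged.

## Shape statistics

Mean shapes average per-vertex positions of rigidly aligned corresponding
point sets. Per-vertex variability is √λ_max of the 3×3 covariance of each
vertex's corresponding points, population convention (÷n); it is NaN when
a group has fewer than two members, and exactly 0 where all corresponding
points coincide. The morphological distance D between two corresponding
point sets is the mean Euclidean distance over pairs; with size
normalisation both sets are centred, scaled to unit centroid size
(root-mean-square distance to the centroid) and D is rescaled by the
geometric mean of the two original sizes — this keeps D symmetric and in
µm. The medoid minimises q_i = Σ_{j≠i} D(S_i, S_j); ties go to the lowest
index. The group reference is the specimen whose d1/d2 is closest to the
group mean.

## Insertion angles

The inflow-tract direction **v** is the principal axis of the region's
vertex coordinates (largest eigenvalue of the 3×3 covariance), requiring a
principal/secondary spread ratio ≥ 1.5, sign-oriented from the centroid
toward the farthest region vertex. θ = atan2(v_x, v_y) in degrees in the
transverse plane, with v_x negated for the right side so mirror-symmetric
pairs give θ_l − θ_r = 0; φ = angle(v, +z) − 90°, so transverse directions
score 0. The θ zero direction (+y) and sign are package conventions —
absolute values may differ from other conventions by a fixed offset/sign,
but left–right *differences*, the scientific output, do not. The θ plane is
taken transverse to the embryo with z the cranio-caudal axis.

`mirror_fit` reflects one side of a mesh across the given medial-sagittal
plane, refines the overlay with up to 10 closest-point rigid (ICP)
iterations, and reports the per-vertex closest-surface distance of the
reflected side.

## 3D+t atlas

Keyframes sharing one connectivity are densified by uniform linear
interpolation (`n_between` = 30 by default, the convention that turns 11
keyframes into 311 frames); keyframe slots carry the keyframes exactly and
stage values interpolate linearly. Per-vertex trajectories are then
smoothed over frame index with a Savitzky–Golay filter (default window 7,
order 3, polynomial boundary treatment); polynomials up to the filter
order pass unchanged and the first and last frames are preserved exactly.
Smoothing is applied after densification. Frames export as PLY plus a JSON
manifest mapping frame index to stage value.

## The synthetic embryo generator

The generator emulates the crescent→tube trajectory as a tapered partial
cylinder: cross-sections are circular arcs of half-angle φ_max swept along
z with radius R(u) = R0·(1 + (r−1)u), R0 = 100 µm. Its design goal is
*exactly known truths*, so every construction choice is made so that a
measurement has a closed form:

- d1/d2 equals the taper ratio r exactly (both rim arcs have the same
  angular sampling, so chord-sum discretisation cancels in the ratio).
- The dorsal gap fixes φ_max via gap = 2 R(u_lip) sin(π − φ_max); the
  minimum lip separation is attained at the caudal lip landmark exactly.
- h/w is realised exactly by scaling the height to the realised width.
- Each inflow tract is a band of the surface near the venous (caudal) pole
  flattened onto the vertical plane whose in-plane horizontal direction
  *is* the prescribed insertion vector (with smooth transition rows, and a
  chord capped so the dent stays shallow relative to the band height).
  Because the flattened vertices form a product grid on that plane, the
  region's principal axis equals the prescribed vector exactly, and
  trimming the most ventral columns makes the dorsal end the farthest
  vertex, fixing the sign deterministically. Left and right angles (and
  hence the planted asymmetry θ_l − θ_r) are therefore exact truths.
  A planted asymmetry that would push a facet off the surface (very early
  stages with wide gaps) raises a parameter error instead of silently
  bending the truth.
- The closed shell is the midsurface offset ±thickness/2 along vertex
  normals with a rim strip joining the walls (genus 0 by construction).

Vertex noise models specimen-to-specimen variability as a smooth Gaussian
random field on the parametric grid (correlation over tens of µm — the
bulge-like regional differences seen between real specimens) plus 20%
independent per-vertex jitter, applied along vertex normals and tapered to
zero at the tissue borders. The taper encodes the assumption that the
tissue *borders* (the d1/d2 curves and the dorsal lips) are anatomically
sharp while interior shape varies; it is what keeps border-derived truths
recoverable at σ = 2 µm. What the generator does **not** emulate:
segmentation artefacts, topological noise, imaging anisotropy, genuinely
asymmetric global deformations, or tissues other than the myocardial
analog. Passing recovery tests on this family therefore demonstrates the
correctness and noise robustness of the measurement pipeline, not
performance on raw microscopy segmentations.

Default study conditions: 11-stage sequences (t = 0…1), R0 = 100 µm,
shell thickness 20 µm, noise σ = 2 µm, grid 36×61 (~2200 vertices per
midsurface, edges ~4–20 µm). These sizes keep a full pipeline run in
seconds while leaving every feature several mesh cells wide.

## Determinism

Every stochastic step (generator noise, k-means restarts, test oracles)
derives from an explicit integer seed; the CLI pipeline writes
byte-identical tables for a fixed config, and all outputs are written
atomically (temp file + rename).
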