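# Methods

This note records the algorithms, conventions and numerical choices behind
each morphometric parameter, what the phantom generators do and do not
emulate, and the known limitations.

## Volume model

All computation happens on a `VoxelImage`: a 3D array indexed `(z, y, x)`
with one isotropic voxel size `h` in mm (reference value 0.018 mm, typical
of trabecular micro-CT).  Binary volumes hold exactly 0/1; the total volume
TV is always the full cubical ROI.  Anisotropic spacing in input files is
rejected rather than resampled, because every algorithm below assumes cubic
voxels.  The ROI cut planes sit half a voxel outside the outermost voxel
centres, i.e. at −h/2 and (N−½)h per axis.

## Segmentation chain

Grayscale scans are segmented by: Gaussian smoothing (σ = 1.2 voxels, kernel
truncated at 2σ — "support 2" in vendor terminology) → single-level
threshold → retention of the largest 26-connected foreground component →
morphological closing → opening with a 3×3×3 cube.  Choices the chain's
description leaves open, resolved here:

* the structuring element is 3D (3×3×3); a per-slice 3×3 variant is
  available for sensitivity checks (`morph_3d=False`);
* smoothing uses mirror boundary conditions; the morphological operators run
  on an edge-replicated pad so foreground touching the ROI face is not
  eroded by the implicit background border;
* component-removal connectivity defaults to 26 (6 available); ties between
  equal-size components go to the one whose lexicographically smallest
  voxel comes first;
* binary inputs skip the smooth+threshold stage — a mask is already past
  that point — which also makes the chain idempotent on its own output;
* only foreground components are filtered; unconnected *pores* are kept.

## Bone surface

The interface is extracted by marching cubes (scikit-image, Lewiner
orientation-consistent tables) at iso-level 0.5 on the binary field, after a
virtual one-voxel background pad, so foreground touching an ROI face is
closed by planar cap triangles.  A vertex is "on the boundary" when it lies
on any cut plane (tolerance 10⁻⁹ mm); a triangle is an artificial boundary
face when all three of its vertices are — this also catches the chamfer
triangles marching cubes emits along ROI edges and corners, so a whole-ROI
solid has exactly zero interior surface.  BS(include) − BS(exclude) equals
the summed boundary-triangle area identically (it is a partition).

Marching cubes on *binary* data overestimates curved areas by up to ~10%
(staircase chamfering; an axis-aligned cube is within 5%, a digital sphere
about +9%).  This dialect is kept deliberately: surface-area inflation of
exactly this kind is one of the mechanisms separating published tools.

Mesh-enclosed volume uses signed-tetrahedron summation over the capped
(closed, checked edge-by-edge) mesh; on smooth phantoms it differs from
voxel counting by well under 0.02 in BV/TV terms.

## Local thickness (Tb.Th. / Tb.Sp.)

Model-independent thickness: the value at a voxel is the diameter of the
largest sphere entirely inside the phase that covers the voxel.  Pipeline:
exact Euclidean distance transform (no chamfer approximation — chamfer
metrics bias thickness by several percent, comparable to the inter-tool
gaps of interest) → pruning to a distance-ridge superset (a voxel is
dropped when a 26-neighbour's inscribed sphere contains its own; painting
from any ridge superset is exact) → per-radius sphere painting, largest
radius first, with each dilation realised as one distance transform to the
seed set.

Radii are centre-to-centre distances with a one-voxel diameter
compensation: thickness = (2·EDT − 1)·h.  Consequences, both deliberate:
an isolated voxel reports h and an n-voxel slab reports n·h for odd n;
*even* widths report (n−1)·h, because no voxel-centred sphere of full width
exists (the true maximal sphere is centred between voxels).  The
convention with no compensation (2·EDT) errs +1 voxel on odd widths
instead; either way the discretisation error is one voxel.

Edge policies:

* `include_edges` (default): ROI faces act as phase boundary; spheres
  cannot cross a face, every phase voxel gets a value.  Near faces the
  values sag — the deficit on the phase mean scales roughly with
  r²/(in-plane extent), where r is the structure's sphere radius in voxels.
* `exclude_edge_voxels`: spheres are limited only by real interface; voxels
  covered solely by spheres truncated at a cut plane are flagged and
  omitted from the statistics (the behaviour of tools that leave the
  cut-affected rim out of the thickness statistics).  For structures fully
  interior to the ROI both
  policies agree exactly.

Tb.Sp. is literally Tb.Th. of the complemented volume — a single code path.
Statistics are the mean and SD (n−1) of the per-voxel field after the edge
policy.  Degenerate phases (empty, or background of a solid ROI) raise
errors instead of returning 0, so pipelines cannot silently mix conventions.

## Anisotropy

**Test-line MIL.**  Directions are Fibonacci-spiral hemisphere points
(deterministic for a given count; default 128).  Per direction, a grid of
parallel lines (default spacing 1 voxel, seeded random in-plane offset) is
clipped to the continuum ROI box and sampled every 0.5 voxel with
nearest-voxel lookup; a crossing is a background→foreground sign change
between consecutive samples, and MIL = total in-ROI line length / crossing
count.  Directions with zero crossings are excluded from the fit rather
than imputed (imputation would bias the tensor for sparse structures).

**Projected-surface MIL.**  MIL(n) = 2·BV / A_p(n) with A_p(n) =
Σ_t |n̂_t·n|·a_t/2 over interior triangles; BV from voxel counting.  When no
mesh is supplied, the surface is extracted from the field after 1-voxel
Gaussian smoothing (uncapped, so ROI cut faces contribute nothing):
smoothing leaves the 0.5-level interface essentially in place but removes
the staircase quantisation of triangle normals, which otherwise biases
projected areas by ~10% between axis and diagonal directions (on a digital
sphere the MIL spread drops from ~10% to ~0.5%).

**Fit and DA.**  The quadratic form in 1/MIL² (not MIL) is fitted by least
squares over the six tensor components; the eigen-decomposition gives the
MIL ellipsoid.  DA conventions: `eigen_ratio` λmax/λmin (default),
`semi_axis_ratio` √(λmax/λmin), `one_minus_inverse` 1 − λmin/λmax.  The
principal direction reported is the longest MIL semi-axis.  A
non-positive-definite fit raises an error — and genuinely occurs for ideal
plate or rod phantoms, whose continuum 1/MIL² is an exactly singular
quadratic (cos²θ resp. sin²θ): infinite parallel plates/rods have a
degenerate fabric, and machine-level noise decides the sign of the zero
eigenvalues.  Realistic (foam-like) structures are well-conditioned.
Cross-method direction agreement on such degenerate phantoms is therefore
asserted on the raw MIL extrema, not on fitted tensors.

DA from test lines is permutation/rotation-stable only to sampling accuracy
(the direction set is not permuted with the volume); on isotropic foams the
observed spread is ≲0.05 in eigen-ratio.  The projected-surface variant is
deterministic given the mesh, but with a fixed direction set and a
non-ellipsoidal true MIL its DA moves by up to ~10⁻² under axis
permutation; exact invariance would require rotating the direction set with
the volume.

## Agreement statistics

Percent differences 100·(a−b)/denominator with the denominator an explicit
choice: reference = second series (default, matching reference-based
comparison plots), reference = first, or pair mean (exactly antisymmetric).
Bland–Altman: mean ± SD (n−1) of the percent differences, limits of
agreement at ±1.96·SD.  Regression: OLS with R² = squared Pearson r; the
report regresses the first label on the second (reference on the x-axis),
so a variant shifted by +5% against its reference shows mean difference
+5.00% and slope 1.05.  Zero-denominator samples are excluded with a
warning and n reported accordingly; n < 3 is an error.  Report tables round
percent values to two decimals.

## Phantoms

Generators return the volume plus closed-form truth; same spec + seed is
bit-identical.

* **plate_stack** — full-extent slabs, thickness t, gap g voxels, periodic
  along one axis starting with a plate.  Choosing the axis length as
  k(t+g)+t makes both ends complete plates, so every gap has nominal width.
* **rod_array** — parallel cylinders (voxel centre within d/2 of an axis)
  on a square lattice of pitch s, or a single rod through a voxel centre
  (odd diameters voxelise exactly).  Diameter voxelisation error ±1 voxel.
  Rods clipped by the ROI cross-section faces distort MIL; validation
  configurations keep the lattice fully interior.
* **sphere**, **solid_cube** — analytic volume/surface; the full-ROI solid
  exercises the degenerate conventions (Tb.Sp. undefined, interior BS 0).
* **isotropic_foam** — Gaussian white noise smoothed at the correlation
  length (periodic boundaries keep the field stationary), thresholded at
  the quantile matching the target volume fraction (default 0.25,
  correlation length 4 voxels — coarse-trabecular-like at h = 0.018 mm).
  Isotropic in distribution; realised BV/TV equals the target to within
  quantile ties.

What the phantoms do *not* emulate: real trabecular topology (connectivity,
plate-rod mixtures), segmentation noise, beam hardening, or resolution
effects.  Passing the phantom suite shows the algorithms implement their
definitions correctly — it does not bound disagreement between tools on
real bone, which is precisely the quantity the comparison harness is for.

## Problem sizes and determinism

Validation runs use 64³ volumes for statistical checks (50 foams for the
BV/TV dual-path comparison, 10 seeds for foam DA) and ~128-scale volumes
for the thickness oracles — small enough for a desk machine, large enough
that boundary bands are minority fractions.  All randomness flows from
explicit seeds; reruns are bit-identical, and the CLI embeds the config
hash and seed in its outputs.

## Known limitations

* Marching-cubes-on-binary area inflation (above) is inherent to the
  chosen dialect; smooth-field extraction is used only for projection MIL.
* Thickness is voxel-centred: sub-voxel structure widths and even/odd
  effects are resolved only to one voxel.
* MIL test lines use nearest-voxel sampling at 0.5-voxel steps; very thin
  (≤1 voxel) walls oblique to the grid can be skipped, inflating MIL.
* The fabric fit assumes an ellipsoidal MIL; strongly non-ellipsoidal
  distributions (ideal plates/rods) are reported as fit failures by design.
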