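# Methods

This note documents the models, parameter defaults, numerical choices and
known limitations of `craniomorph`. It is written for a user deciding
whether the defaults fit their problem and for a maintainer wondering why
something is the way it is.

## Coordinate conventions

All images are axis-aligned scalar grids in Hounsfield units; the world
coordinate of voxel index `i` is `origin + i * spacing` (mm, 0-based). No
orientation matrix is carried: plane alignment (below) rotates the data into
a canonical frame before everything else, so downstream code can assume the
mid-sagittal plane coincides with a grid plane of axis 0. NIfTI-1 stores
grid metadata in 32-bit floats, so spacing/origin survive a NIfTI round trip
to ~1e-7 relative; MetaImage keeps doubles.

## Pre-processing

*Plane alignment* takes three user-selected points spanning the mid-sagittal
plane (the choice of points is input, not estimated — automatic plane
detection is out of scope) and applies the minimal rigid rotation carrying
the plane normal onto axis 0, pivoted at the projection of the volume center
onto the plane. The output grid is centered on the world origin; a plane
offset along its own normal translates the output by the same amount, so
the plane always lands on the central voxel plane.

*Symmetrization* copies one half (default: the upper-coordinate half) onto
the other by reflection. For an even-sized axis the reflection plane lies
between the two central layers and no voxel sits on the plane; for an odd
size the central layer is shared. The side-label image is 1 on the kept
side, 0 on the mirrored side (plane voxels, when they exist, are labelled 1
— an arbitrary but fixed convention; the labels' only consumer is the SD
cost term, which is insensitive to the plane layer itself).

*Head/neck segmentation* thresholds above air (default −900 HU, "slightly
above" the −1000 HU of air), then closes with a Euclidean ball of radius 3
voxels and dilates by 1 voxel (defaults; both configurable). Closing is
computed on a padded array so the image border cannot clip the intermediate
dilation. The mask only gates cost-function sampling — air–tissue interfaces
inside the head keep their intensities and thus their NCC information.

*Bone-only images* set every voxel below the bone threshold (default
+200 HU, between soft tissue at ≲100 HU and bone at ≳300 HU) to −1000 HU,
plus everything inside an optional hyoid mask, because the hyoid does not
fossilize and must not help a registration meant to emulate fossil data.

## Transformation model

The FFD is a cubic tensor-product B-spline displacement field added to an
affine pre-transform. Cubic order is required for a well-defined continuous
Hessian (the bending-energy integrand). Control lattices are built with one
extra control span beyond the domain on each side, so every domain point has
its full 4×4×4 support; along the plane axis the control coordinates are
exactly mirror-symmetric about the mid-sagittal plane, with one control
point on the plane. Symmetry of the *coefficients* is not hard-constrained:
the SD cost term and the symmetric lattice are the only symmetry mechanisms,
which keeps the parameterization unbiased.

Multi-resolution continuation uses the exact two-scale relation of cubic
B-splines (fine coefficients `(c_{i−1} + 6c_i + c_{i+1})/8` and
`(c_i + c_{i+1})/2`), which reproduces the coarse displacement field to
round-off over the whole valid support — verified to < 1e−10 mm in tests.
Gradient and Hessian of the transformation are analytic B-spline derivative
weights; finite differences appear only as test oracles.

The landmark-fitted affine initialization estimates translation + rotation +
anisotropic scaling by minimizing the mean Euclidean distance over a
landmark subset (conventionally ids 2, 4, 7, 20, 21: incisor, palate, mental
spine and the two orbital points — the two off-midline landmarks make the
subset non-coplanar). The fit warm-starts from the polar decomposition of
the closed-form full-affine least-squares solution and polishes with a
derivative-free optimizer on the mean-distance objective itself. A coplanar
subset triggers a warning and pins the out-of-plane scale.

## Cost function and optimizer

`F = NC + α·SD + β·D + γ·P`, all terms evaluated on the same random sample
of head/neck mask voxels each iteration (one sampling pass; default 20000
points). NC is the negative Pearson correlation of
fixed vs warped-moving intensities (affine-intensity invariant; a
zero-variance sample vector is uninformative and scored 0). SD is the mean
squared side-label difference; D the mean landmark distance in mm,
evaluated on all 21 landmarks every iteration (it is cheap); P the bending
energy. During optimization P and its gradient are estimated on a random
sub-sample (default 1000 points) of the iteration's samples — a stochastic
estimate of the mask mean in the same spirit as NC/SD — while the *reported*
bending energy is always the exact mean over the mask. Weights are not
normalized across terms; defaults are the study schedule α = 1,
β = (0, 0.05, 0.1), γ = (0, λ2/2, λ2) coarse→fine.

The image pyramid smooths with a Gaussian of σ = factor/2 voxels before
factor-2 subsampling. The binary side labels go through the same smoothing,
so at coarse levels the labels grade through [0, 1] near the plane and the
SD term has a capture range of several fine voxels; at full resolution the
labels are the original 0/1 images. Masks are subsampled without smoothing.

The optimizer is stochastic gradient descent with the decaying step
`a / (A + t)^0.602`, A = 20, and `a` auto-scaled per level so the first
update moves the most-driven control point by `initial_step_mm`
(default 1 mm). Default 2000 iterations per level. Gradients of NC/SD flow
through precomputed central-difference gradient volumes of the moving
images interpolated at the mapped points — the standard approximation; the
D and P gradients are exact. A fixed `rng_seed` makes runs bit-reproducible;
a non-finite cost aborts with the trace attached. If the mask at a coarse
level holds fewer voxels than the sample count, sampling falls back to
replacement with a warning.

## Assessment and selection

Accuracy is either the mean exact point-to-triangle distance from
delineated organ-surface points to the warped mesh surface (when the target
organ is visible) or the mean node-to-node distance over surface nodes
between two predictions derived from the same reference mesh (when it is
not). "Surface nodes" are the nodes referenced by the surface triangles; if
no explicit surface is stored, the boundary faces of the tet mesh (faces
belonging to exactly one element) are used. J10% averages the
`ceil(0.10 n)` lowest Jacobian determinants over the organ's voxels (ceil:
the 10% tail is never empty). The selection score is
`accuracy × (J10% − 1)²`; ties break on larger J10%, then smaller λ1 —
preferring smoother, better-conditioned meshes.

## Uncertainty quantification

The QoI is any scalar evaluator over λ = (λ1, λ2); for the bone-based study
it is the node-to-node distance between the bone-based prediction and the
best soft-tissue prediction, for the soft-tissue study the point-to-surface
accuracy (both are supplied as plug-ins; evaluators may return a record
carrying accuracy and J10% so the selection step can run over the evaluated
vertices). Marginals: λ1 ~ truncated Gaussian N(20, 4) mm on [8, 32]
(renormalized), λ2 ~ uniform on [0, 1000]. The four domain corners are
always included in the initial sample so the metamodel's hull covers the
whole domain; the L1 norm of the interpolation error is used throughout (a
practical choice, robust for near-discontinuous responses), estimated by
fixed-seed Monte-Carlo quadrature with 10⁴ draws from π.

Per-vertex Hessians of the QoI are recovered by a weighted least-squares
quadratic fit over the vertex's triangulation patch — the 1-ring, expanded
ring by ring until it holds at least 6 neighbours, with Gaussian distance
weights (bandwidth = median patch distance) and ridge regularization if the
patch is rank-deficient. A k-nearest-neighbour stencil was considered and
rejected: on strongly graded tessellations its neighbourhoods span
disparate scales and smear curvature into flat regions, visibly
de-localizing the refinement; the patch-based fit is the standard recovery
in metric-based mesh adaptation and is exact on quadratics.

The optimal metric under a sample budget C is
`M = C^(2/n) (∫ det(π|H|)^(1/(2+n)))^(−2/n) det(π|H|)^(−1/(2+n)) π|H|`
with `|H|` taken through absolute eigenvalues floored at 1e−12 (so saddle
and flat points still yield SPD metrics); the matching error estimate is
`n C^(−2/n) (∫ det(π|H|)^(1/(2+n)))^((2+n)/n)`, i.e. C⁻¹ for n = 2. Inside
the integrals the determinant is *not* floored, so a truly flat response
contributes zero (and an all-flat response falls back to an isotropic
metric with a warning). Integrals use per-triangle vertex-mean quadrature
on the current tessellation.

Refinement bisects the edges with the greatest metric length
`sqrt(eᵀ M̄ e)` (M̄ = endpoint average; ties break on the lowest vertex-index
pair), re-triangulates by Delaunay, and evaluates the QoI only at the new
midpoints; new vertices inherit the edge-average metric, duplicates are
perturbed by 1e−9 of the edge. The adaptive loop distributes the remaining
budget evenly over `n_adap` rounds (default 4; remainder to the last) and
finally reports π-weighted mean and variance of the metamodel.

## The phantom: what it does and does not emulate

The generator emulates the *structure* the registration exploits: three HU
strata (air −1000, soft tissue +40, bone +700 — representative clinical
values), a closed bone shell around a soft-tissue body, an air cavity whose
lower boundary is a tongue-like organ, 21 landmarks on bone (19 mid-sagittal
+ 2 lateral, mirroring the conventional anatomical layout), and
mirror symmetry about the central plane. Tissue interfaces are smoothed
over ~1.5 mm so image gradients are well-defined at the working resolutions.
The ground-truth deformation is a random smooth FFD on a ≥20 mm lattice
(representable by the registration's own model), symmetrized so it commutes
with the mirror, scaled to a prescribed maximum displacement (default 8 mm)
and verified diffeomorphic (min J > 0.2 over the head region) at
generation; generation fails loudly otherwise. The moving volume evaluates
the analytic phantom at the numerically inverted ground truth (fixed-point
iteration, valid for these contractive fields) plus Gaussian noise
(default sd 10 HU).

It does **not** emulate: anatomically realistic bone shapes or intensity
textures, CT artifacts (beam hardening, metal, partial volume beyond
trilinear smoothing), asymmetric anatomy, inter-species shape differences
of the magnitude separating a human from a non-human primate, or landmark placement
error. Passing tests on the phantom therefore demonstrate the *mechanics*
of the pipeline — cost terms, derivatives, multi-resolution continuation,
mesh morphing, selection, UQ — under controlled ground truth; they do not
certify accuracy figures on real cross-species CT data.

## Study sizes used by the tests and the acceptance script

The shipped end-to-end runs use a 64³ phantom at 2.5 mm spacing (and 48³ at
3.33 mm for the symmetry experiment), 4000–5000 cost samples per iteration
and 250–300 iterations per level at (λ1, λ2) = (24, 400) — sizes chosen so a
full two-registration study completes in minutes on one core while leaving
the library defaults at the full-study values (20000 samples, 2000
iterations). The symmetry experiment registers the default noisy phantom
and scores `mean|I∘T − mirror(I∘T)|` on the noise-free twin volume warped
through each fitted transform: warped sensor noise would otherwise dominate
the score and hide the transform's own asymmetry, which is the quantity the
SD term controls.

## Known limitations

- The NC/SD gradients use interpolated image-gradient volumes, so the
  optimizer's descent direction is approximate near sharp interfaces
  (standard practice; the analytic-derivative guarantees apply to the
  transformation model, not the image interpolant).
- `register` assumes plane-aligned, symmetrized, affine-initialized inputs
  on a shared grid convention; it does not re-check alignment.
- The bending-energy mask mean is exact but O(|mask|); for very large masks
  the reported P is the only full-mask pass per run.
- Metric-driven refinement inserts geometric edge midpoints; strongly
  anisotropic optimal metrics are honoured in edge *selection* but not by
  anisotropic point placement.
- The UQ module is fixed at n = 2 parameters by construction of its metric
  algebra (the study's setting); higher dimensions are out of scope.
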