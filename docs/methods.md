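# Methods

This note documents the models, numerical choices and open design decisions
behind `mcsquant`, in the package's own terms. All distances are in
nanometres; volumes are indexed (z, y, x) with higher density = more mass.

## Surface reconstruction and distance statistics (`surface`)

**Model.** One contact site = one PM point cloud + one ER point cloud,
clicked along the cytosolic leaflets. The PM surface is recovered in three
steps:

1. *Plane fit.* Total least squares: the normal is the right singular
   vector of the centered cloud with the smallest singular value; it is
   oriented so its z (then y, then x) component is non-negative. Collinear
   clouds are rejected with the site named in the error.
2. *Rotation.* For the standalone `rotate_to_plane` operation, a Rodrigues
   rotation maps the normal to +z about the centroid. The full surface
   pipeline (`fit_surface`) instead uses the cloud's complete SVD basis —
   in-plane principal axis to +x, normal to +z. The distinction matters:
   the interpolation grid is an axis-aligned bounding box in the rotated
   frame, and only a frame built covariantly from the data makes the grid
   (and hence the distance statistics) invariant under rigid motions of the
   input. Sign conventions of the axes are irrelevant because distances are
   unsigned and a sign flip only mirrors the grid.
3. *Biharmonic spline.* Radial basis interpolation with the biharmonic
   Green's function g(r) = r²(ln r − 1), g(0) = 0, augmented with an affine
   term (1, x, y) under the usual orthogonality side conditions, and a
   ridge of λ = 1e−8 on the radial block. The affine augmentation makes the
   interpolant reproduce constants and planes exactly (pure biharmonic RBF
   does not: on a 4-corner constant-height configuration it deviates by
   order 1); the ridge keeps near-duplicate clicks from making the system
   singular. Duplicate (x, y) locations are averaged before solving. The
   surface is evaluated on a regular 20×20 grid over the rotated PM cloud's
   bounding box.

**Distance.** The grid is triangulated (two triangles per cell, diagonal
from (i,j) to (i+1,j+1)) and each ER point takes its minimum Euclidean
point-to-triangle distance over the mesh (brute force over the 722
triangles, via trimesh). Per site: mean, SD (n−1; a single-point site
reports SD 0), min, max. ER points whose closest mesh point lies on the
grid boundary are counted but flagged (the value is an extrapolation beyond
the clicked PM footprint). `buckle_distance` is the min field of the same
computation — the automated counterpart of clicking the shortest gap at a
local ER buckle.

**Accuracy.** Validated two ways: parallel-plane exactness (flat site, zero
jitter → mean = separation, SD = 0 at any orientation) and a dense-grid
oracle (evaluate the continuous spline on a 400×400 lattice, take
nearest-vertex distances; mesh route agrees within 0.2 nm on ~200-point
curved sites). The 20×20 grid is an approximation of the continuous spline;
with heavy click jitter (≳0.5 nm SD at 10/5.5 nm click spacing) the spline
oscillates between clicks faster than the grid samples it and the
mesh-vs-spline gap grows beyond 0.2 nm. Distances to a jittered, wiggly
surface are also slightly *below* the planted separation (the minimum over
a rough surface is biased low); at 1 nm jitter the grand-mean bias is about
−0.2 nm, well inside the 0.5 nm recovery band used in the tests.

**Splitting complex sites** into separate site_ids is the caller's job,
mirroring the manual division used when one fluorescent signal spans
morphologically distinct cER; no automatic splitting is attempted.

## Particle tilt geometry (`particles`)

The four clicked points (A = ER rod base, B = PM rod end, C/D = auxiliary
points ~10 nm along ER and PM) are projected onto their common TLS plane
(identity when already coplanar). With u = B−A and PM tangent t = D−B, the
deviation from perpendicular to the PM is α = |90° − ∠(u, t)|, clipped to
[0°, 90°]. α is measured against the PM tangent only; C is kept for QC and
box orientation but does not enter α — using both tangents would change α
whenever the membranes are not parallel, and the quantity of interest is
defined relative to the PM. The in-plane rotation prior is the signed angle
of the ER-ward axis from the in-plane PM normal. Summaries use SD with n−1
and half-open 5° bins over [0°, 90°] (a value of exactly 90° falls in the
last bin).

## Synthetic generators (`synthetic`)

The generators emulate the statistical structure of the annotated inputs,
not the imaging physics. What they deliberately do not model: missing
wedge, CTF, defocus gradients, reconstruction artefacts, segmentation
error, pinning-robot artefacts beyond multiplicative effects, or optical
PSF beyond the ring's Gaussian cross-section. Passing recovery tests
therefore demonstrates correctness of the measurement chain on idealized
data of realistic geometry and noise, not robustness to every instrument
artefact.

* **Membrane sites.** Clicks on a regular grid (10 nm in x, 5.5 nm in y —
  the slice-tracing direction), PM flat at z = 0; the ER offset by the true
  separation along the local normal, optionally with a Gaussian buckle
  toward the PM (apex gap = separation − depth) or as the lower surface of
  a tubule. Click jitter is Gaussian along the local surface normal
  (isotropic click error has no preferred direction in the membrane plane
  after projection; the normal component is what distance measurements
  see).
* **Contact volumes.** Each membrane = two Gaussian leaflet sheets, σ 1 nm,
  centres 4 nm apart (bilayer appearance at ~2 nm resolution; amplitude 1).
  Rods = antialiased cylinders of 2.5 nm radius spanning the cytosolic
  leaflets at their stated tilt (amplitude 0.5); records longer than the
  gap at their tilt are rejected. The coat is a uniform slab (amplitude
  0.8) starting 3 nm cytosolic of the PM cytosolic-leaflet centre — i.e.
  adjacent to the membrane surface once the leaflet half-width is counted —
  rendered with partial-voxel z-coverage so its half-maximum width equals
  the requested thickness to within a voxel. Default voxel 0.37 nm (the
  average tomogram pixel); the averaging pipelines run 2×-binned at
  0.74 nm. Noise is additive Gaussian. Membrane thickness and rod radius
  are plausible defaults, not measured values.
* **Picks.** A/B at the rod endpoints, C/D displaced 10 nm along the
  membranes in the rod's azimuthal direction, isotropic Gaussian click
  jitter on all four points.
* **Plates.** control = plate·row·column effect × lognormal noise; query
  additionally × per-gene fitness factor. Multiplicative throughout:
  colony sizes are positive and plate artefacts act as growth-rate factors.
* **Cortex rings.** Ring of Gaussian cross-section (σ 2 px); per-channel
  intensity follows angular bright-domain specifications plus background
  and noise; the generating circle is returned as the contour.

All generators are deterministic given their seed (single
`numpy.random.default_rng` stream each).

## Collapse-to-2D averaging (`collapse`)

**Extraction.** Paths clicked along a membrane are fitted with a
chord-length-parameterized cubic smoothing spline (smoothing reduced until
max control-point residual ≤ 1 nm, falling back to interpolation). Boxes
are centred at fixed arc-length steps (must overlap: step < box) and
resampled trilinearly on a rotated grid: image columns along the membrane
normal (cytosol toward +columns), rows along the tangent, projection depth
perpendicular to both. Because the grid itself absorbs the tangent angle,
the residual rotation prior of along-path boxes is 0 (the angle is kept as
metadata). Particle boxes (444 Å default, px = round(Å / (10·voxel_nm)))
are cut axis-aligned at the A–B midpoint and carry the 4-point in-plane
rotation as their live prior. Out-of-bounds boxes/picks are dropped with a
log entry.

**Collapse.** Plain sum over the full box depth; linear and
intensity-conserving. Whether a central slab would be preferable is
unresolved on real data; the full-depth sum is exact for the synthetic
geometry (membranes parallel to the projection axis).

**Alignment/classification.** Constrained multi-reference alignment with
hard assignment: references initialized from a seeded random partition;
per iteration each image is scored by normalized cross-correlation against
every reference over rotations in prior ± 15° (1° steps) and integer
shifts within the window, after Gaussian band-limiting with FWHM equal to
the low-pass cutoff (default 2 nm — an operating choice, not a measured
value); references are rebuilt as aligned within-class means; stops when
< 1% of assignments change. Emptied classes are reseeded from the
worst-scoring image. k = 1 degenerates to constrained global averaging.
This replaces a regularized-likelihood classifier on purpose: it is
deterministic given the seed, dependency-free, and sufficient for the
separable classes the generator produces; it does not model per-pixel
noise weighting and will be greedier than a likelihood method on
marginally separable real data. Refined rotations are asserted never to
leave the prior window.

**Measurements.** `layer_thickness`: profile across the membrane (averaged
along it); the bilayer is the most prominent peak plus its partner 2.5–6 nm
away; on the cytosolic side of the cytosolic leaflet, the first local
minimum starts a 15 nm search region whose *internal* maxima are layer
candidates — a profile that merely rises toward the far end (the partner
membrane's tail) is not a layer. Background = median of the lower half of
the region; detection requires peak ≥ background + 3·noise SD (noise from
a MAD of the region residuals when not supplied); thickness = FWHM above
background with interpolated crossings. `rod_length`: profile along the
particle axis averaged over 15 perpendicular pixels centred on the rod;
detected peaks are split at the midpoint of the outermost pair and the
innermost peak of each side taken — the cytosolic leaflets — with length
their separation. Peak-to-peak and FWHM operators make both measurements
invariant under intensity scaling; on 0.74 nm voxels both recover planted
truths within one voxel (the rod measurement sits ~0.4 nm low because the
rod density overlapping the leaflets pulls the inner peaks together —
within the stated voxel tolerance).

## Coat coverage (`coverage`)

Pure mask arithmetic: volumes = voxel count × voxel³, ratio =
layer/cER. Masks are inputs (interactive segmentation on real data); a
threshold helper builds masks from synthetic volumes at half slab
amplitude. No outlier rule is applied to coverage values — any exclusion
is a downstream, per-study decision.

## SGA scoring (`sga`)

Normalization is multiplicative median polish: divide by the plate median
(nonzero wells), then alternately by row and column medians to
convergence (max 25 iterations, tolerance 1e−12). On plates that decompose
into row/column effects plus a minority of outlier wells the polish
terminates at an exact fixed point and is exactly idempotent; under
well-level noise the even-sized rows/columns make the interpolated median
converge only asymptotically (~5% per iteration), so idempotence then
holds to the convergence tolerance — medians were kept regardless because
robustness to hit wells is the point of median normalization. Zero/missing
wells are excluded from all medians and flagged. Plates under 50% growth
are rejected.

Scores: replicate wells averaged per arm (mean of normalized sizes);
score = log2(query/control); query mean 0 → lethal sentinel (−inf, always
a hit). The hit cutoff is *strictly* below −1.00 — a gene at exactly −1.00
is not a hit. The rescue matrix marks a gene rescued when its base score
is below the cutoff and its per-construct score is at or above it. With
noise SD 0.1 and 4 replicates the null false-positive rate is < 1% and
planted factor-0.4 interactions are detected with > 95% power (the score
SD is ≈ 0.1·√(2/4)/ln 2 ≈ 0.10, putting −1.00 about 10 SD below the null
and 3 SD above a factor-0.4 gene's −1.32).

## Cortex profiles (`cortex`)

The contour is resampled at fixed arc-length steps, traversed clockwise on
screen from the marked start point; at each step the profile records the
maximum bilinear intensity over a ±2 px band along the inward normal
(cortical signals are thin and sit slightly inside a hand-traced contour;
the max makes the profile robust to sub-pixel contour error). Pearson
correlation summarizes channel co-occurrence and is undefined (NaN,
flagged) for zero-variance channels. Equivalence with any particular
interactive straightening tool is not claimed — agreement is demonstrated
on synthetic rings (plateau fractions within ~1 step of the generating
domains).

## Problem sizes and determinism

The shipped analyses and acceptance run use: 29–45 sites of 200×200 nm
(~780 clicks each), 100–1513 picks, ~110 boxes of 64³ at 0.74 nm voxels
for the coat chain, 50 boxes of 60³ for the rod chain, 100-seed Monte
Carlo for the SGA error-rate properties. These sizes put every recovery
well inside its tolerance while keeping a full run in tens of seconds on
one CPU. All stochastic steps consume explicit seeds; fixed seed ⇒
bit-identical outputs.
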