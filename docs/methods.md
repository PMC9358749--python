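# Methods

This note documents the models, numerical choices and open design decisions
behind `surfmorph`, in the order the pipeline runs them.  It states no
empirical result that the test suite or the analysis scripts do not
themselves compute.

## The phantom: a stated world with analytic ground truth

All validation runs on a parametric solid rather than an anatomical bone,
because the scientific questions here (does segmentation recover the
surface? does the statistics pipeline recover an injected effect?) need a
ground truth that real scans cannot provide.

The phantom is a surface of revolution with angular modulation,

    r(z, theta) = r0 + a_l cos(L theta) + f_p(z) + f_d(z) + detail(z, theta),

with a non-circular shaft (`L = 3` lobes, amplitude 0.8 mm — fibula-like),
cosine-ramp flares standing in for the proximal/distal epiphyses (4 mm and
3 mm amplitude over 12% / 10% of the length), and a seeded band-limited
random field (`detail`, RMS 0.15 mm, 6 Fourier modes) standing in for
surface texture.  Default shaft radius is 7 mm.  The anatomical shaft length
is ~330 mm; analysis scripts and tests use a 60 mm shaft with everything
else unchanged — per-voxel segmentation behavior, curvatures and landmark
geometry are preserved while volumes stay desk-sized.  End caps are
triangulated as concentric rings so that edge lengths stay near the target
resolution everywhere (this also keeps closest-point query certificates
cheap).

Because `r(z, theta)` is analytic, the inside/outside indicator, surface
points, and outward normals are exact; meshes, templates and voxelizations
are all checked against them.

Voxelization emulates CT acquisition: even-odd ray parity on a node-centered
grid (`world = origin + index * spacing`, used everywhere), Gaussian
partial-volume blur (sigma 0.4 mm at the 0.625 mm voxel default), optional
multiplicative low-order bias field, and i.i.d. Gaussian noise.  Out of
scope on purpose: scanner spectra, reconstruction filters, texture.

## The simulated study

The replicate design is 13 specimens x 4 digitizations (CT-HMH, CT-MIA,
LASER, LASER replica).  Per specimen:

* biological variation: a thin-plate-spline warp of the whole template driven
  by a 22-point control lattice perturbed by N(0, sd^2), default sd 1.5 mm —
  smooth, landmark-consistent variation of controllable magnitude;
* every digitization carries its own independent *tangential* operator
  jitter (default sd 0.1 mm).  Note this deviates from the narrower reading
  in which only the replica is jittered: each configuration is a separate
  template application, so each carries intra-observer error.  With all
  noise terms zero the four configurations are identical, as required;
* CT digitizations additionally get a systematic outward normal offset
  (default 0.2 mm — CT surfaces run slightly large) plus isotropic device
  noise (default 0.1 mm).

No quantitative biological-variance estimate exists for the original 13
bones; the defaults above are this package's stated world, chosen at the
scale of digitization errors reported for long bones, and are not revisited.

## Segmentation

**HMH.** Per selected slice, the pixel row with the sharpest transition
provides the edge profile; the crossing is the max-|gradient| sample and
each plateau is the median of 5 pixels starting 2 pixels beyond the
crossing.  A row is accepted only if both plateau medians lie within 15% of
the robust material levels (1st/99th intensity percentiles) — rows through
thin or cap-adjacent structure are resampled.  The published protocol says
only "a row of pixels on the bone-to-air transition"; max-gradient selection
is deterministic and captures the sharpest edge.  The 5-pixel median (rather
than 3) halves the estimator variance and is needed to meet the stated
noise-robustness bound; the noiseless behavior is identical.

**Fuzzy c-means.** Standard fixed point with fuzzifier m = 2 (the cited
clustering leaves m unstated) and deterministic quantile initialization; the
objective is recorded per iteration and is non-increasing.  Degenerate
(single-valued) inputs are flagged, not iterated.

**MIA clustering.** Global c-means fixes reference centers; cubic regions of
edge `grid_size x base_edge` voxels (defaults 3 x 32) with 50% overlap run
local c-means seeded from the global centers; per-voxel memberships are
blended with linear taper weights; voxels whose blended top-two membership
margin falls below 2% fall back to the global classification; bone = the
cluster(s) whose centers exceed the midpoint of the global center range.
The upstream description names "grid size of 3 pixels" and "a 2% threshold"
without defining their semantics; both interpretations here (region edge
multiplier; minimum membership margin) are explicit, configurable
parameters.

**Isosurfaces** come from marching cubes at level 0.5 on binary masks (no
hidden pre-smoothing — smoothing is its own pipeline stage), in world mm,
outward-oriented, largest component kept with the drop count recorded.

## Mesh comparison

Smoothing follows the desktop-tool trial grid {0.5, 1, 3, 5}: a "0.5
iteration" is implemented as one pass with the step scaled by 0.5 (an
integer pass count cannot be halved; this reproduces a weaker-than-one-pass
level).  "Surface preserve" re-projects each vertex onto the *input* surface
after every pass — the strongest literal reading of surface preservation,
since the original filter is undocumented.  Taubin defaults are the
classical pass-band pair lambda = 0.5, mu = -0.53.

Alignment: candidate rotations are the principal-axes frames under all four
proper sign combinations (covering 180-degree ambiguities); each candidate
is refined by ICP with 200 iterations and 200 sampled points (seeded,
closed-form Kabsch updates, reflections excluded), and the lowest final RMSE
wins.  ICP correspondence queries use a fast uncertified closest-point mode;
all reported distances use the certified exact mode (vertex k-NN candidates
with a nearest-vertex + longest-edge exactness bound, ball-query fallback,
ties broken toward the lowest face index).

Deviations are exact point-to-triangle distances from each target vertex to
the reference surface, signed positive outside (so "CT larger than laser"
reads positive).  Summary statistics are over unsigned distances — the
published tables' minima of zero indicate unsigned values — and
`%var = mean / max midshaft caliper diameter x 100`, the caliper taken on
the convex hull of the mid-shaft cross-section polygon.  Colored exports use
the +/-2.5 mm diverging scale with the +/-0.2 mm green band and white
beyond range.

## Geometric morphometrics

The volumetric TPS uses kernel `phi(r) = r`.  The bending energy is reported
on the physical scale `E = integral of the squared second derivatives =
-8 pi sum_d w_d^T K w_d` (the biharmonic Green's function in 3D is
`-r / 8 pi`); the bending-energy matrix form `sum_d X_d^T Be X_d` is scaled
identically, so both routes agree to machine precision and quadrature
oracles can check the constant, not just proportionality.

Sliding: curve points move along chain tangents (central differences on the
ordered, closed chains), surface points in tangent planes (mesh face normal
when a mesh is available, else supplied analytic normals); the step is the
closed-form least-squares minimizer of the bending energy to the reference,
which provably never increases it; slid points are re-projected onto the
mesh.  GPA centers, scales to unit centroid size, and rotates to the
recursive consensus (SVD, det +1 enforced — all specimens are same-sided
bones, no mirroring), then slides against the consensus and re-superimposes,
up to 5 cycles with a 1e-6 movement tolerance.  The converged fit is rotated
to a canonical frame (consensus principal axes, deterministic signs) so
results do not depend on input order or orientation.  Proximal (94) and
distal (48) point sets are always separate GPAs.

Procrustes ANOVA: SS_total is the summed squared distance to the grand mean;
the factor SS comes from group means; `p = (#{F* >= F} + 1)/(n_perm + 1)`
over 1000 randomizations of reduced-model residuals, `Z` standardizes log F
in the permutation distribution.  Two randomization schemes are provided:

* **free** (reduced model = intercept): the published model `shape ~ device`.
  Under the replicate design this test is *valid but very conservative* —
  device groups are balanced within specimen, so the observed F only sees
  digitization noise while permuted Fs absorb between-specimen biological
  variance.  On simulated null worlds its rejection rate is ~0 with p near 1.
* **specimen-blocked** (`blocks=` argument; reduced model = specimen,
  permutations restricted within specimens): the exchangeable null for
  repeated digitizations of the same bones.  This is the scheme under which
  the type-I calibration criterion (rejection rate ~ alpha) is met; the
  acceptance suite measures it at 500 simulated null studies.

The pipeline default stays the published free randomization; the blocked
variant is used where a calibrated test is the point.

The pairwise post-hoc draws every pair's null distances from the *same*
permutation stream (one seeded generator, identical residual placements for
all statistics), reporting d, the 95th percentile of permuted d (UCL95), Z
on the raw distance scale, and p.  Centroid sizes get a classical one-way
ANOVA.

## Calibration of the effect-recovery check

The device offset whose population device-variance fraction equals a target
(0.014, the scale of the published finding) is found by scalar root-finding
on a pilot study of 40 specimens: the random draws do not depend on the
offset, so Rsq(offset) is smooth and monotone and Brent's method applies.
The pilot seed is disjoint from the evaluation seeds.

## What a green test does and does not establish

The phantom establishes internal correctness: segmentation recovers a known
surface to sub-voxel accuracy, injected effects of known size are recovered,
the randomization test is calibrated in its exchangeable form.  It does not
establish anything about anatomical realism (no trabecular structure, no
cortical-thickness variation, no scanner artifacts), nor does it reproduce
the published deviation magnitudes, which depend on the real scans (only
"available upon request").  The published landmark coordinates are public
(Zenodo record 6425379); `analysis/05_deposit_reproduction.py` recomputes
the device ANOVA from them when network access is available.  Exact
agreement with the published tables is limited by unstated details of the
deposited coordinates (pre- or post-sliding; sliding criterion), which is
why the reproduction tolerance is loose (+/-0.005 on Rsq).

## Known limitations

* MIA region handling merges degenerate slivers implicitly via overlap
  rather than explicit neighbor merging.
* The deposit loader guesses file layouts (TPS blocks / delimited tables /
  spreadsheets, method labels from identifiers); a dedicated parser may be
  needed once the layout is known.
* ICP convergence is linear; the 200-iteration default reaches ~1e-6 mm RMSE
  on clean geometry but tight tolerances need the full budget.
* Voxelization ray parity assumes a closed mesh and rejects open ones rather
  than repairing them.
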