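# surfmorph

Are bone surface models digitized with different devices interchangeable?
Skeletal collections get digitized with whatever is at hand — clinical CT
(segmentation of a grayscale volume) or structured-light/laser surface
scanners — and morphometric studies routinely pool meshes from both.
`surfmorph` implements, as a tested and reusable pipeline, the validation
workflow behind that practice for long-bone surfaces: it quantifies how much
of the measured shape variation is attributable to the digitization route
rather than to biology, from the raw volume all the way to the shape
statistics.

It is written for biological anthropologists, anatomists and imaging
scientists who need to run (or audit) such a comparability trial, and it
ships a fully synthetic test bed — an analytic bone phantom — so every stage
is verifiable against ground truth without access to real scans.

## What it computes

**Segmentation of CT-like volumes** (`surfmorph.volseg`)

* single intensity thresholds;
* the half-maximum-height (HMH) threshold: for an edge profile crossing the
  bone/air boundary, the threshold midway between the two material plateaus,
  `tau = (I_bone + I_air) / 2`, estimated on randomly chosen slices and
  averaged;
* MIA clustering: global fuzzy c-means (memberships
  `u_ik = 1 / sum_j (d_ik / d_jk)^(2/(m-1))`, centers
  `c_k = sum_i u_ik^m x_i / sum_i u_ik^m`) followed by local c-means in
  overlapping cubic regions with linear-taper membership blending — robust to
  intensity inhomogeneity (bias fields);
* marching-cubes isosurface extraction in world millimetres.

**Mesh processing** (`surfmorph.meshops`)

* Laplacian smoothing (with optional re-projection onto the original
  surface), Taubin lambda/mu smoothing;
* rigid alignment by principal axes with all proper sign flips, each refined
  by sampled iterative closest point (ICP, closed-form Kabsch updates),
  keeping the minimum-RMSE candidate;
* exact vertex-to-surface signed distances (positive = target outside the
  reference) and deviation statistics: mean, SD, max of |d| and
  `%var = mean / (max midshaft caliper diameter) * 100`.

**Geometric morphometrics** (`surfmorph.gm`)

* 3D thin-plate splines with kernel `phi(r) = r`; the bending energy is the
  integral of squared second derivatives, `8 pi * sum_d w_d^T K w_d` in
  kernel form;
* semilandmark sliding along curve tangents / surface tangent planes by the
  closed-form least-squares minimizer of the bending energy to a reference,
  with re-projection onto the mesh;
* generalized Procrustes analysis (GPA) with sliding against the recursive
  consensus; centroid size `CS = sqrt(sum_i |x_i - xbar|^2)`;
* PCA of shape coordinates; Procrustes ANOVA with residual randomization
  (RRPP: `p = (#{F* >= F} + 1) / (n_perm + 1)`, effect size `Z` on the log-F
  permutation scale), with optional specimen-blocked randomization for
  repeated-digitization designs; pairwise group distances sharing one
  permutation stream; one-way ANOVA on centroid sizes.

**Synthetic test bed** (`surfmorph.phantom`) — an analytic surface of
revolution with angular lobes, flared ends and seeded smooth surface detail;
CT-like voxelization (partial-volume blur, noise, bias field); a 142-point
landmark template (94 proximal, 48 distal; fixed / curve / surface roles);
and a simulated 13 specimen x 4 digitization study (CT-HMH, CT-MIA, LASER,
LASER replica) with controllable biological variation, systematic CT
inflation, and operator jitter.

## Worked example

The numbered scripts under `analysis/` run the study end to end and write
tables under `results/`:

```
python analysis/01_phantom_data.py          # phantom, volume, template, study
python analysis/02_segmentation_comparison.py
python analysis/03_smoothing_trials.py
python analysis/04_gm_validation.py
```

`02_segmentation_comparison.py` segments each specimen's volume six ways and
tabulates deviations from the reference surface (mm):

```
specimen    protocol  mean    sd   max  min  pct_var
     S01        -550 0.2710 0.1346 0.8866 0.0001  1.8429
     S01        -700 0.5129 0.2554 1.2123 0.0004  3.4876
     S01         HMH 0.1286 0.0986 0.3763 0.0000  0.8746
     S01         MIA 0.1324 0.0993 0.4270 0.0000  0.9000
     ALL Average MIA 0.1354 0.1016 0.4389 0.0000  0.9170
     ALL Average HMH 0.1309 0.0997 0.3774 0.0000  0.8869
```

Reading: the choice of a single global threshold moves the surface by up to
half a millimetre, while the HMH and MIA protocols sit near 0.13 mm — well
below the 0.625 mm voxel — and deviations are under 1% of the midshaft
diameter.

`04_gm_validation.py` runs the GM validation on a simulated study with a
0.2 mm systematic CT offset (proximal epiphysis shown):

```
device model (CT vs LASER):
           Df       SS       MS      Rsq        F        p
factor      1  0.00187  0.00187  0.00845  0.42604  0.82118
Residuals  50  0.21895  0.00438  0.99155
Total      51  0.22082

pairwise Procrustes distances:
                        d    UCL95        Z        p
CT-HMH:CT-MIA     0.00897  0.04045 -1.95018  0.99900
CT-HMH:LASER      0.01365  0.03895 -1.36298  0.94705
LASER:LASER-REP   0.00512  0.03860 -2.56510  1.00000
```

Reading: the device explains well under a percent-level fraction of shape
variance (Rsq), no test is significant, and the two digitizations of the
same laser surface are closer (d = 0.005) than any pair of different
methods — device differences are of the order of operator error.

## Acceptance script

```
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

re-runs the package's main computation from scratch — a seeded phantom
study through segmentation, deviation mapping and the GM validation — and
writes its JSON summary to `--out`.
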