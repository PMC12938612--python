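# Methods

`hipshape` quantifies left–right shape asymmetry of the proximal femur from
binary segmentation masks, evaluates segmentation quality, fits T1rho/T2
relaxation maps for cartilage, and runs the cohort statistics that relate
asymmetry to cartilage composition and functional performance. Every stage
can be exercised end-to-end on synthetic phantoms and cohorts with known
ground truth; this note records the models, the defaults, and the choices
made where the design was genuinely open.

## Coordinate conventions

Voxel indices are 0-based. World coordinates are millimetres with a diagonal
affine: `world = origin + index * spacing`. Orientation is a three-letter
RAS-style code naming the anatomical direction of increasing index per array
axis. All bilateral analysis happens in a *left-hip frame*: right-hip masks
are mirrored across the left–right axis first, and "medial" denotes the
patient-right direction of that left-oriented frame.

## Shape-asymmetry pipeline

1. **Mirroring.** The right mask is flipped along the L–R array axis (about
   the grid mid-plane) and its orientation letter swapped; the operation is
   an exact involution. Any mid-plane offset between the two volumes is
   irrelevant because the meshes are subsequently registered rigidly.
2. **Meshing.** Marching cubes at level 0.5 on the binary grid, in physical
   mm. Duplicate vertices are merged, unreferenced vertices dropped, and
   only the largest shell kept. The surface is relaxed by Laplacian
   smoothing with *inverse-vertex-distance umbrella weights*:
   `v_i <- v_i + lambda * (sum_j w_ij v_j / sum_j w_ij - v_i)` over 1-ring
   neighbours with `w_ij = 1/||v_j - v_i||`, recomputed each pass.
   Defaults: `lambda = 0.5`, 10 iterations. The weights and iteration count
   are exposed in the config; smoothing mildly shrinks the surface (a 22 mm
   sphere loses ~0.05 mm of radius at the defaults), which cancels in the
   left-vs-right difference because both sides are smoothed identically.
3. **Rigid registration.** Point-to-point ICP: KD-tree closest-vertex
   matching alternated with an SVD (Kabsch) rigid fit, stopping when the
   RMS residual changes by < 1e-6 mm or after 100 iterations. The femur is
   nearly a surface of revolution about its long axis, so a centroid-only
   start leaves rotations about the shaft in a shallow local minimum; the
   default initialization therefore aligns the principal-axis frames of the
   two vertex clouds and scores the four proper sign combinations by
   nearest-neighbour RMS, keeping the best. A pure centroid start remains
   available (`init="centroid"`). For speed the source cloud may be
   subsampled with a deterministic even stride (`max_points`, default
   10,000 in the pipeline); matching always runs against the full target.
4. **Correspondence.** Each left-mesh vertex is matched to its closest
   point *on* the registered right surface (exact point-to-triangle
   minimizer over candidate faces incident to the k = 4 nearest target
   vertices; ties break toward the lowest face index). On the dense,
   pre-registered meshes this pipeline produces, the candidate set contains
   the true nearest triangle; the test suite checks this against an
   exhaustive all-triangles oracle.
5. **Distance map.** `d_i = ||p_right,i - p_left,i||` per vertex (mm). The
   map is invariant under any common rigid motion of both meshes, so
   alignment of whole cohorts to a reference atlas (`align_to_atlas`)
   changes reporting frames only, never the distances.
6. **Head ROI and octants.** The femoral-head centre is an algebraic
   least-squares sphere fit to the vertices in the proximal 40% of the
   shaft-axis extent, refined by trimming vertices whose radial residual
   exceeds 2.5 robust standard deviations (floored at 0.2 mm so exact
   spheres are recovered exactly) — the trimming removes neck-junction
   leverage. The ROI is the 55 mm-diameter sphere about that centre
   (configurable; 55 mm covers a healthy femoral head). ROI vertices are
   labelled by the signs of their point-to-plane distances to the three
   planes through the centre normal to the anterior–posterior,
   medial–lateral and superior–inferior axes, giving the eight octants
   AMS … PLI; a distance of exactly zero counts as the positive
   (anterior/medial/superior) side.
7. **BSDM table.** Mean and SD (population normalization) of `d` plus
   vertex counts for the whole head ROI and each octant; empty octants are
   reported missing, never zero.

The shaft-axis estimate is the dominant principal axis of the vertex
scatter, oriented from the head (the wider end, judged by mean radial
spread of the extreme quartiles) toward the shaft. A cohort-uniform shaft
cutoff (`apply_shaft_cutoff`, length measured from the head centre along
that axis) reproduces the usual practice of trimming all subjects to the
shortest shaft in the cohort.

Spectral-embedding surface matching is deliberately not implemented: for near-isometric left/right pairs of the same bone,
closest-point correspondence after rigid ICP yields the same per-vertex
distances to within discretization error. A spectral correspondence could
be slotted in behind the same `Correspondence` interface.

## Segmentation evaluation

Border voxels are foreground voxels with at least one background
6-neighbour; distances between border-voxel centres use the full
anisotropic spacing, so ASSD and HD are in mm while DSC and RAVD are
dimensionless percentages. RAVD is the absolute volume difference relative
to the ground truth (asymmetric by definition). HD is the symmetric
Hausdorff distance over the two border sets. Cohort summaries report the
mean with a t-based 95% confidence interval across cases. Not covered by
design: Jaccard, HD95, surface Dice.

## Relaxometry

Per-voxel mono-exponential model `S(t) = S0 exp(-t/T)` over the spin-lock
times (T1rho: 0, 15, 30, 45 ms) or echo times (T2: 0, 10.4, 20.8,
41.6 ms). The first time point of 0 ms is taken at face value
(`S(0) = S0`). Fits run Levenberg–Marquardt least squares initialized from
the log-linear closed form over positive samples (exact on noiseless
data); voxels with fewer than 3 finite samples, no positive samples, a
non-convergent solve, or parameters outside `0 < T <= 500 ms`, `S0 > 0`
are flagged invalid rather than raising. Fluid exclusion marks fitted
values above 100 ms (T1rho) or 80 ms (T2). Cartilage subregion means are
taken over the four sagittal slices nearest the hip-centre slice (default:
the label-mass centroid slice, overridable), over valid non-excluded
voxels only, and a subregion must contribute *strictly more than* 50
pixels to be reported; SD uses population normalization. Femoral cartilage
reports R2–R7, acetabular R2–R6. Invalid-fit voxels are excluded from the
means alongside thresholded voxels, and the two exclusions are counted
separately. Atlas-based cartilage segmentation is out of scope — subregion
masks are inputs.

## Cohort statistics

Group comparisons are ANCOVA: OLS of the outcome on a group indicator plus
age, sex and BMI, reading the two-sided p of the group coefficient. This is
the standard reading of "unpaired t-test adjusted for age, gender and BMI";
with `covariates=None` the computation reduces *algebraically* to the
pooled-variance unpaired t-test (verified to 1e-12). Correlation method is
gated per pair by Shapiro–Wilk on each marginal at alpha = 0.05: both
normal → Pearson, otherwise Spearman (also the fallback when a marginal is
constant and the test is undefined — the conservative choice). All
correlation pairs of one analysis run form a single Benjamini–Hochberg
family (step-up, `adj_(i) = min_{j>=i} m p_(j)/j`, clipped at 1); group
comparisons are reported with raw p-values. The sensitivity computation
finds the smallest Cohen's d at which the two-sided two-sample t-test with
noncentrality `d sqrt(n1 n2/(n1+n2))` reaches the requested power, by
bisection on the noncentral-t power function to 1e-6; the default power is
the conventional 0.80. When a table carries per-hip columns
(`<name>_left`/`<name>_right`), the hip with the higher Kellgren–Lawrence
grade is analyzed; ties resolve to the left hip, deterministically.

## Synthetic data: what it emulates and what it does not

**Femur phantom.** A stylized three-primitive femur: a spherical head
(radius 22 mm), a cylindrical neck (radius 9 mm, length 30 mm) meeting the
vertical shaft (radius 14 mm, length 70 mm) at a 135° neck–shaft angle,
voxelized at 0.8 mm isotropic (the acquisition resolution of the bone
sequence). The voxel lattice is anchored to multiples of the spacing so
phantoms sharing a spacing share voxel centres. Asymmetry ground truth is
a Gaussian radial bump on the head surface: local radius
`R + h exp(-g^2 / 2 sigma^2)` where `g` is the geodesic distance from the
seeded octant's central direction (peak height `h`, lateral scale
`sigma = 5 mm`). An asymmetric pair is the unbumped phantom (left) plus
the mirrored bumped phantom (right), so the pipeline must mirror, mesh,
register, and localize the bump to recover `h` in the seeded octant. The
phantom exercises shaft-axis estimation, sphere fitting and octant
partitioning; it makes no attempt at cortical/trabecular realism,
osteophytes or cam lesions, and a real femoral head is not a perfect
sphere — passing localization tests shows the machinery is correct, not
that anatomical effect sizes are detectable.

**Relaxometry phantom.** Exact mono-exponential decay from known T and S0
maps plus *additive Gaussian* noise. Real magnitude MR noise is Rician;
at the signal-to-noise ratios exercised the distinction is immaterial to
the fitting path, and the Gaussian choice keeps the log-linear recovery
oracle closed-form. Documented as a limitation.

**Cohort.** Control and OA groups (defaults 30/17, the study sizes) with
group-specific covariates (controls: age 48.7 ± 10.9 y, BMI 23.7 ± 3.5,
47% female; OA: 62.7 ± 9.9 y, 25.8 ± 4.5, 47% female), KL grades
consistent with the group rule (OA iff KL > 1 on either hip, all grades
< 4), and continuous outcomes joined through a Gaussian copula. Spearman
targets convert to copula correlations via `r = 2 sin(pi rho / 6)`;
infeasible (non positive-semidefinite) target sets are rejected with the
offending pairs named. Marginals: BSDMs log-normal centred near
2.1 ± 0.8 mm (control-level asymmetry; these are plausible generator
centres, not ground truth for real controls), cartilage T1rho ~ 35 ± 6 ms
and T2 ~ 30 ± 5 ms, chair-stand repetitions integer-rounded normal
15 ± 4, stair-climb and walk times log-normal around 12 s and 26 s. An
optional group effect (mm) shifts selected octant BSDM means in the OA
group. Integer rounding of the chair-stand count introduces ties that
attenuate seeded rank correlations by roughly 0.02 at n = 47 — within the
recovery tolerance used in testing. All generators take explicit integer
seeds; nothing reads global random state.

## Numerical choices and degenerate inputs

- Rotations are validated orthonormal (1e-9) with det +1; Kabsch fits are
  reflection-corrected.
- ICP convergence: |ΔRMS| < 1e-6 mm or 100 iterations; the residual is
  non-increasing across iterations by construction.
- Zero-length smoothing edges cannot occur after duplicate-vertex merging;
  weights are floored at 1e-12 regardless.
- Empty masks, empty foregrounds, empty ROIs, all-background relaxometry
  voxels, constant covariates, non-PSD copula targets, and p-values
  outside [0, 1] all raise (or flag, where the contract says flag) with
  messages naming the offending quantity.
- Problem sizes used by the validation suite: phantoms at the default
  0.8 mm spacing (~30,000-vertex meshes), 100 registration trials, a
  24-run localization sweep (3 heights × 8 octants), 10,000-voxel
  relaxometry noise runs, 2,000-replicate null-calibration and
  500-seed correlation-recovery Monte Carlo.

## Known limitations

- Closest-point correspondence is exact only relative to the discretized
  surfaces; sub-voxel asymmetry below ~0.05 mm is at the isosurface noise
  floor.
- The ANCOVA reading of the covariate-adjusted comparison is one of
  several possible mechanics (residualization, stratification); the plain
  t-test is available via `covariates=None`.
- Gaussian (not Rician) relaxometry noise; no B0/B1 correction, no
  multi-component relaxometry.
- Acetabular bone shape is out of scope, as is statistical shape modeling
  (PCA mode analysis) and non-rigid registration.
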