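# hipshape

Quantitative analysis of **proximal-femur bone shape asymmetry** from
bilateral hip MRI segmentations, with the surrounding machinery a hip
osteoarthritis (OA) imaging study needs: segmentation-quality metrics,
cartilage T1rho/T2 relaxometry, and cohort statistics linking asymmetry to
cartilage composition and functional performance. Synthetic phantom and
cohort generators with known ground truth make every stage testable
without any imaging data.

Intended users: musculoskeletal imaging researchers who have left/right
proximal-femur masks (e.g. from an automatic segmentation model) and want
region-resolved, reproducible asymmetry measurements.

## What it computes

**Bone shape difference measurements (BSDMs).** The right-hip mask is
mirrored into the left frame; both masks are meshed (marching cubes +
Laplacian smoothing with inverse-distance umbrella weights) and rigidly
registered with ICP. Each left vertex *i* is matched to its closest point
on the right surface and the per-vertex distance

> d_i = sqrt((x2−x1)² + (y2−y1)² + (z2−z1)²)

forms the shape-difference map. The femoral-head region of interest (a
55 mm-diameter sphere about the fitted head centre) is split into eight
octants — {anterior, posterior} × {medial, lateral} × {superior,
inferior}, AMS … PLI — by the signs of point-to-plane distances along the
anatomical axes; the BSDM table reports mean ± SD of d per region.

**Segmentation evaluation.** DSC = 2|V_seg ∩ V_GT| / (|V_seg| + |V_GT|),
average symmetric surface distance, relative absolute volume difference
and Hausdorff distance over 6-connected border voxels, in physical mm,
with t-based 95% confidence intervals across cases.

**Relaxometry.** Per-voxel Levenberg–Marquardt fits of
S(t) = S0·exp(−t/T) over multi-TSL/TE stacks, fluid exclusion at
100 ms (T1rho) / 80 ms (T2), and cartilage subregion means (R2–R7) over
the four slices nearest the hip centre with a >50-pixel rule.

**Cohort statistics.** Covariate-adjusted (age, sex, BMI) group
comparison of each BSDM region; Shapiro–Wilk-gated Pearson/Spearman
correlations of BSDMs against cartilage means and functional scores
(chair-stand, stair-climb, 40 m walk), Benjamini–Hochberg corrected as one
family; and the two-sample t sensitivity analysis (minimum detectable
Cohen's d via the noncentral t distribution).

## Worked example

Seed a 3 mm bump in the posterior–lateral–superior (PLS) octant of one
side of a synthetic femur pair, then run the full pipeline:

```python
import hipshape as hs

spec = hs.FemurPhantomSpec(bump_region="PLS", bump_height=3.0)
pair = hs.make_asymmetric_pair(spec)       # left + mirrored bumped right
result = hs.compare_pair(pair.left, pair.right)
print(result.table)
```

```
        mean_mm  sd_mm  n_vertices
region
head      0.097  0.305       14444
AMS       0.028  0.016        1787
ALS       0.023  0.014        1778
AMI       0.056  0.007        1794
ALI       0.025  0.013        1865
PMS       0.021  0.014        1785
PLS       0.580  0.695        1793
PMI       0.022  0.014        1777
PLI       0.029  0.016        1865
```

The seeded octant (PLS) carries an order of magnitude more asymmetry than
any other region — the bump is localized correctly — while the unbumped
octants sit at the ~0.03 mm isosurface discretization floor. The fitted
head sphere recovers the construction geometry (centre within 0.01 mm,
radius 21.96 mm vs the true 22 mm after smoothing shrink).

The sensitivity analysis for the study design (30 controls vs 17 OA,
alpha 0.05 two-tailed, power 0.80):

```python
>>> hs.sensitivity_effect_size(30, 17, alpha=0.05, power=0.80)
0.8692
```

i.e. the design is sensitive to large between-group effects (d ≈ 0.87).

A command-line interface mirrors the library:

```bash
hipshape simulate femur --out data/        # phantom pair + ground truth
hipshape shape --left data/left.nii.gz --right data/right.nii.gz --out out/
hipshape stats --cohort cohort.csv --out report/
hipshape run --out full_run/               # staged pipeline with manifest
```

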