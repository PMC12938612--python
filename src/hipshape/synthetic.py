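"""Synthetic inputs for the asymmetry pipeline.

Three generators cover everything the downstream stages consume:

* stylized proximal-femur phantoms (sphere head + inclined neck cylinder +
  shaft cylinder) voxelized on an isotropic grid, optionally with a
  Gaussian radial bump of known height seeded in one femoral-head octant —
  the ground truth for asymmetry-localization tests;
* mono-exponential relaxation image stacks with known per-voxel T and S0
  maps and additive Gaussian noise;
* subject cohorts (control vs OA) whose cross-variable Spearman rank
  correlations are induced through a Gaussian copula.

All generators take explicit integer seeds; none touches global random
state.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .volume import LabelVolume

#: Femoral-head octant codes: anterior/posterior x medial/lateral x
#: superior/inferior.
OCTANTS = ("AMS", "ALS", "AMI", "ALI", "PMS", "PLS", "PMI", "PLI")

#: BSDM summary regions: whole head ROI plus the eight octants.
BSDM_REGIONS = ("head",) + OCTANTS

#: Cartilage subregion labels (posterior .. anterior-inferior).
FEMUR_CARTILAGE = ("R2", "R3", "R4", "R5", "R6", "R7")
ACETABULAR_CARTILAGE = ("R2", "R3", "R4", "R5", "R6")


# ---------------------------------------------------------------------------
# femur phantom
# ---------------------------------------------------------------------------


@dataclass
class FemurPhantomSpec:
    """Geometry of the stylized three-primitive femur phantom.

    The head is a sphere, the neck a cylinder inclined 135 degrees to the
    shaft (within the anatomical 120-140 degree range), and the shaft a
    vertical cylinder. Dimensions are millimetres; ``spacing`` is the
    isotropic voxel size. ``bump_region`` seeds a Gaussian radial
    protrusion of peak height ``bump_height`` and lateral (geodesic) scale
    ``bump_sigma`` on the head surface inside one octant.
    """

    head_radius: float = 22.0
    neck_radius: float = 9.0
    neck_length: float = 30.0
    shaft_radius: float = 14.0
    shaft_length: float = 70.0
    spacing: float = 0.8
    bump_region: str | None = None
    bump_height: float = 0.0
    bump_sigma: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("head_radius", "neck_radius", "neck_length",
                     "shaft_radius", "shaft_length", "spacing"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0, got {getattr(self, name)}")
        if self.bump_height < 0:
            raise ValueError(f"bump_height must be >= 0, got {self.bump_height}")
        if self.bump_sigma <= 0:
            raise ValueError(f"bump_sigma must be > 0, got {self.bump_sigma}")
        if self.bump_region is not None and self.bump_region not in OCTANTS:
            raise ValueError(
                f"bump_region must be one of {OCTANTS} or None, got {self.bump_region!r}"
            )


def octant_direction(code: str, anterior: np.ndarray, medial: np.ndarray,
                     superior: np.ndarray) -> np.ndarray:
    """Unit vector through the centre of an octant given the three axes."""
    if code not in OCTANTS:
        raise ValueError(f"unknown octant {code!r}")
    sa = 1.0 if code[0] == "A" else -1.0
    sm = 1.0 if code[1] == "M" else -1.0
    ss = 1.0 if code[2] == "S" else -1.0
    v = sa * np.asarray(anterior) + sm * np.asarray(medial) + ss * np.asarray(superior)
    return v / np.linalg.norm(v)


def _segment_distance(pts: np.ndarray, a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Distance from each point to segment a-b."""
    ab = b - a
    length2 = float(ab @ ab)
    t = np.clip((pts - a) @ ab / length2, 0.0, 1.0)
    return np.linalg.norm(pts - a - t[:, None] * ab, axis=1)


# neck-shaft angle 135 deg: neck axis 45 deg off the (inferior) shaft axis,
# running infero-laterally from the head centre in the coronal plane
_NECK_TILT = np.deg2rad(45.0)


def femur_geometry(spec: FemurPhantomSpec) -> dict:
    """Construction ground truth of the left-frame phantom (mm, world).

    Keys: ``head_center``, ``neck_end`` (head-centre end of the shaft),
    ``shaft_end``, and the anatomical unit vectors ``anterior``,
    ``medial``, ``superior`` of the left-oriented RAS frame.
    """
    medial = np.array([1.0, 0.0, 0.0])
    anterior = np.array([0.0, 1.0, 0.0])
    superior = np.array([0.0, 0.0, 1.0])
    head_center = np.zeros(3)
    neck_dir = -np.sin(_NECK_TILT) * medial - np.cos(_NECK_TILT) * superior
    neck_end = head_center + spec.neck_length * neck_dir
    return {
        "head_center": head_center,
        "neck_end": neck_end,
        "shaft_end": neck_end - spec.shaft_length * superior,
        "anterior": anterior,
        "medial": medial,
        "superior": superior,
    }


def make_femur_volume(spec: FemurPhantomSpec, side: str = "left") -> LabelVolume:
    """Voxelize the femur phantom as a binary RAS-oriented volume.

    Built in the left-hip frame (medial = +x, anterior = +y, superior = +z)
    and mirrored across the left-right axis for ``side="right"``. The
    result is a single 6-connected component; geometry that disconnects
    head from shaft at the requested spacing raises ``ValueError``.
    """
    if side not in ("left", "right"):
        raise ValueError(f"side must be 'left' or 'right', got {side!r}")

    h = spec.spacing
    geo = femur_geometry(spec)
    medial, anterior, superior = geo["medial"], geo["anterior"], geo["superior"]
    head_center, neck_end, shaft_end = (geo["head_center"], geo["neck_end"],
                                        geo["shaft_end"])

    # bounding box of the union, with a 2-voxel margin
    pad = 2 * h
    rmax = spec.head_radius + spec.bump_height
    lo = np.minimum.reduce([
        head_center - rmax,
        neck_end - spec.neck_radius,
        shaft_end - spec.shaft_radius,
        neck_end - spec.shaft_radius,
    ]) - pad
    hi = np.maximum.reduce([
        head_center + rmax,
        neck_end + spec.neck_radius,
        shaft_end + spec.shaft_radius,
    ]) + pad
    # anchor the lattice to multiples of the spacing so phantoms sharing a
    # spacing (e.g. the bumped/unbumped halves of a pair) share voxel centres
    lo = np.floor(lo / h) * h
    shape = np.ceil((hi - lo) / h).astype(int) + 1
    origin = tuple(lo)

    ii, jj, kk = np.indices(shape, dtype=np.float32, sparse=True)
    x = ii * h + lo[0]
    y = jj * h + lo[1]
    z = kk * h + lo[2]

    # head sphere
    d2 = (x - head_center[0]) ** 2 + (y - head_center[1]) ** 2 + (z - head_center[2]) ** 2
    mask = d2 <= spec.head_radius**2

    # neck capsule and shaft cylinder need full coordinates; restrict to a
    # bounding slab to keep memory modest
    pts = np.stack(np.broadcast_arrays(x, y, z), axis=-1).reshape(-1, 3)
    neck_d = _segment_distance(pts, head_center, neck_end)
    mask |= (neck_d <= spec.neck_radius).reshape(shape)
    shaft_d = _segment_distance(pts, neck_end, shaft_end)
    mask |= (shaft_d <= spec.shaft_radius).reshape(shape)

    if spec.bump_region is not None and spec.bump_height > 0:
        u = octant_direction(spec.bump_region, anterior, medial, superior)
        rel = pts - head_center
        r = np.linalg.norm(rel, axis=1)
        with np.errstate(invalid="ignore"):
            cosang = np.clip((rel @ u) / np.where(r > 0, r, 1.0), -1.0, 1.0)
        # geodesic lateral distance from the bump axis on the head sphere
        d_perp = spec.head_radius * np.arccos(cosang)
        local_r = spec.head_radius + spec.bump_height * np.exp(
            -0.5 * (d_perp / spec.bump_sigma) ** 2
        )
        mask |= ((r <= local_r) & (r > 0)).reshape(shape)

    vol = LabelVolume(mask.astype(np.uint8), (h, h, h), origin, "RAS")
    n = vol.connected_components()
    if n != 1:
        raise ValueError(
            f"phantom is not a single 6-connected component ({n} found); "
            f"neck_radius={spec.neck_radius} mm or neck_length={spec.neck_length} mm "
            f"too extreme for spacing={h} mm"
        )
    if side == "right":
        vol = vol.mirrored()
    return vol


class AsymmetricPair(NamedTuple):
    """A left/right phantom pair with its construction ground truth."""

    left: LabelVolume
    right: LabelVolume
    bump_region: str | None
    bump_height: float


def make_asymmetric_pair(spec: FemurPhantomSpec) -> AsymmetricPair:
    """Left = unbumped phantom; right = mirrored phantom carrying the bump.

    The bump octant is specified in the left-oriented anatomical frame, so
    after the analysis pipeline mirrors the right volume back, the excess
    surface sits in ``spec.bump_region`` with peak height ``spec.bump_height``.
    """
    from dataclasses import replace

    base = replace(spec, bump_region=None, bump_height=0.0)
    left = make_femur_volume(base, "left")
    bumped = make_femur_volume(spec, "left")
    return AsymmetricPair(left, bumped.mirrored(), spec.bump_region, spec.bump_height)


# ---------------------------------------------------------------------------
# relaxometry phantom
# ---------------------------------------------------------------------------


@dataclass
class RelaxPhantomSpec:
    """Known-truth mono-exponential decay phantom.

    ``true_map`` holds per-voxel relaxation times (ms), ``s0_map`` the
    amplitudes; ``times`` are the spin-lock times (T1rho) or echo times
    (T2) in ms. Noise is additive Gaussian with standard deviation
    ``noise_sigma`` in signal units.
    """

    true_map: np.ndarray
    s0_map: np.ndarray
    times: Sequence[float]
    noise_sigma: float = 0.0
    kind: str = "t1rho"
    spacing: tuple[float, float, float] = (0.8, 0.8, 4.0)
    seed: int = 0

    def __post_init__(self) -> None:
        self.true_map = np.asarray(self.true_map, dtype=float)
        self.s0_map = np.asarray(self.s0_map, dtype=float)
        if self.true_map.shape != self.s0_map.shape:
            raise ValueError("true_map and s0_map must share a shape")
        if self.true_map.ndim != 3:
            raise ValueError("maps must be 3D")
        t = np.asarray(self.times, dtype=float)
        if t.size < 3 or np.any(np.diff(t) <= 0) or np.any(t < 0):
            raise ValueError(
                f"times must be >=3 strictly increasing non-negative values, got {list(t)}"
            )
        self.times = tuple(float(v) for v in t)
        active = self.s0_map > 0
        if np.any(self.true_map[active] <= 0):
            raise ValueError("true_map must be > 0 wherever s0_map > 0")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if self.kind not in ("t1rho", "t2"):
            raise ValueError(f"kind must be 't1rho' or 't2', got {self.kind!r}")


def make_relax_series(spec: RelaxPhantomSpec):
    """Simulate the multi-time-point stack S(v, t) = S0(v) exp(-t/T(v)) + noise."""
    from .relaxometry import RelaxSeries

    rng = np.random.default_rng(spec.seed)
    t = np.asarray(spec.times)
    with np.errstate(divide="ignore", invalid="ignore"):
        decay = np.exp(-t[None, None, None, :] / spec.true_map[..., None])
    decay = np.where(spec.s0_map[..., None] > 0, decay, 0.0)
    stack = spec.s0_map[..., None] * decay
    if spec.noise_sigma > 0:
        stack = stack + rng.normal(0.0, spec.noise_sigma, size=stack.shape)
    return RelaxSeries(stack=stack, times=spec.times, kind=spec.kind,
                       spacing=spec.spacing)


# ---------------------------------------------------------------------------
# cohort generator
# ---------------------------------------------------------------------------

#: Continuous outcome columns modelled through the Gaussian copula.
BSDM_COLUMNS = tuple(f"bsdm_{r}" for r in BSDM_REGIONS)
CARTILAGE_COLUMNS = tuple(
    [f"t1rho_femur_{r}" for r in FEMUR_CARTILAGE]
    + [f"t2_femur_{r}" for r in FEMUR_CARTILAGE]
    + [f"t1rho_acet_{r}" for r in ACETABULAR_CARTILAGE]
    + [f"t2_acet_{r}" for r in ACETABULAR_CARTILAGE]
)
FUNCTIONAL_COLUMNS = ("cst", "sct", "fpwt")
COPULA_COLUMNS = BSDM_COLUMNS + CARTILAGE_COLUMNS + FUNCTIONAL_COLUMNS


@dataclass
class CohortSpec:
    """Control/OA cohort with controllable group effects and rank structure.

    ``rho_targets`` is a list of ``((column_a, column_b), rho)`` Spearman
    targets over the outcome columns; they are converted to Gaussian-copula
    correlations via r = 2 sin(pi * rho / 6). ``group_effect`` (mm) is added
    to the BSDM means of ``effect_regions`` in the OA group. Covariate
    distributions default to the study cohort: controls age 48.7 +- 10.9 y,
    BMI 23.7 +- 3.5, 47% female; OA age 62.7 +- 9.9 y, BMI 25.8 +- 4.5.
    """

    n_control: int = 30
    n_oa: int = 17
    group_effect: float = 0.0
    effect_regions: Sequence[str] = ("ALI", "PMS")
    rho_targets: Sequence[tuple[tuple[str, str], float]] = ()
    age_mean: tuple[float, float] = (48.7, 62.7)
    age_sd: tuple[float, float] = (10.9, 9.9)
    bmi_mean: tuple[float, float] = (23.7, 25.8)
    bmi_sd: tuple[float, float] = (3.5, 4.5)
    female_fraction: tuple[float, float] = (0.47, 0.47)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_control < 2 or self.n_oa < 2:
            raise ValueError("each group needs at least 2 subjects")
        for region in self.effect_regions:
            if region not in BSDM_REGIONS:
                raise ValueError(f"unknown BSDM region {region!r}")
        for (a, b), rho in self.rho_targets:
            if not -1.0 <= rho <= 1.0:
                raise ValueError(f"target rho for ({a}, {b}) outside [-1, 1]: {rho}")
            for col in (a, b):
                if col not in COPULA_COLUMNS:
                    raise ValueError(
                        f"rho target column {col!r} is not a copula-modelled "
                        f"outcome column"
                    )


# marginal parameters for the copula columns, loosely matched to the study's
# control-group summaries (BSDM ~ 2.1 +- 0.8 mm; hip cartilage T1rho ~ 35 ms,
# T2 ~ 30 ms; CST ~ 15 reps; SCT ~ 12 s; FPWT ~ 26 s)
def _marginal_ppf(col: str, u: np.ndarray) -> np.ndarray:
    if col.startswith("bsdm_"):
        return np.exp(stats.norm.ppf(u, loc=np.log(2.0), scale=0.35))
    if col.startswith("t1rho_"):
        return stats.norm.ppf(u, loc=35.0, scale=6.0)
    if col.startswith("t2_"):
        return stats.norm.ppf(u, loc=30.0, scale=5.0)
    if col == "cst":
        return np.round(stats.norm.ppf(u, loc=15.0, scale=4.0)).clip(0)
    if col == "sct":
        return np.exp(stats.norm.ppf(u, loc=np.log(12.0), scale=0.30))
    if col == "fpwt":
        return np.exp(stats.norm.ppf(u, loc=np.log(26.0), scale=0.20))
    raise KeyError(col)


def _copula_correlation(spec: CohortSpec) -> np.ndarray:
    m = len(COPULA_COLUMNS)
    idx = {c: i for i, c in enumerate(COPULA_COLUMNS)}
    corr = np.eye(m)
    for (a, b), rho in spec.rho_targets:
        r = 2.0 * np.sin(np.pi * rho / 6.0)
        corr[idx[a], idx[b]] = corr[idx[b], idx[a]] = r
    eigvals = np.linalg.eigvalsh(corr)
    if eigvals.min() < -1e-10:
        pairs = ", ".join(f"({a}, {b})" for (a, b), _ in spec.rho_targets)
        raise ValueError(
            f"rho_targets yield a non positive-semidefinite copula correlation "
            f"matrix (min eigenvalue {eigvals.min():.3g}); offending pairs: {pairs}"
        )
    return corr


def make_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Generate the per-subject cohort table.

    Columns: ``id``, ``group`` (control/oa), ``age``, ``sex`` (1=female),
    ``bmi``, ``kl_left``/``kl_right``, nine BSDM summaries, cartilage
    subregion means (worst hip), and the three functional scores.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_control + spec.n_oa
    group = np.array(["control"] * spec.n_control + ["oa"] * spec.n_oa)
    gi = (group == "oa").astype(int)

    corr = _copula_correlation(spec)
    # eigen factor handles semidefinite matrices that Cholesky rejects
    w, v = np.linalg.eigh(corr)
    factor = v * np.sqrt(np.clip(w, 0.0, None))
    z = rng.standard_normal((n, corr.shape[0])) @ factor.T
    u = stats.norm.cdf(z)

    table = {"id": [f"S{i:03d}" for i in range(n)], "group": group}
    table["age"] = np.clip(
        rng.normal(np.take(spec.age_mean, gi), np.take(spec.age_sd, gi)), 18, None
    )
    table["sex"] = (rng.random(n) < np.take(spec.female_fraction, gi)).astype(int)
    table["bmi"] = np.clip(
        rng.normal(np.take(spec.bmi_mean, gi), np.take(spec.bmi_sd, gi)), 12, None
    )

    # KL grades: controls 0-1 both hips; OA subjects carry grade 2-3 on the
    # affected side (KL > 1 on either hip defines OA, KL < 4 throughout)
    kl_left = rng.integers(0, 2, size=n)
    kl_right = rng.integers(0, 2, size=n)
    affected_left = rng.random(n) < 0.5
    oa_grade = rng.integers(2, 4, size=n)
    kl_left = np.where((group == "oa") & affected_left, oa_grade, kl_left)
    kl_right = np.where((group == "oa") & ~affected_left, oa_grade, kl_right)
    table["kl_left"] = kl_left
    table["kl_right"] = kl_right

    for j, col in enumerate(COPULA_COLUMNS):
        table[col] = _marginal_ppf(col, u[:, j])
    frame = pd.DataFrame(table)

    if spec.group_effect != 0.0:
        for region in spec.effect_regions:
            frame.loc[frame["group"] == "oa", f"bsdm_{region}"] += spec.group_effect
    return frame
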