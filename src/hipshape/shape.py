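"""Left/right proximal-femur shape-asymmetry pipeline.

Stages (all coordinates in mm, left-hip frame):

1. mirror the right-hip mask across the left-right axis;
2. extract triangulated surfaces (marching cubes at level 0.5) and relax
   them with Laplacian smoothing using inverse-vertex-distance umbrella
   weights;
3. rigidly register the mirrored-right mesh onto the left mesh with
   point-to-point ICP (principal-axes initialization, SVD fit, KD-tree
   matching);
4. match every left vertex to its closest point on the registered right
   surface (closest point on triangle, not nearest vertex);
5. per-vertex Euclidean distance d = ||p_right - p_left|| forms the bone
   shape difference map;
6. restrict to the femoral-head ROI (55 mm diameter sphere about the
   fitted head centre) and split it into eight octants by the signs of
   point-to-plane distances along the anterior-posterior, medial-lateral
   and superior-inferior axes;
7. summarize mean/SD per region (head + 8 octants) into a BSDM table.

The per-vertex distance map is invariant under any common rigid motion of
both meshes, which is what makes the subsequent atlas alignment purely a
matter of reporting in a common frame.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
import trimesh
from scipy.spatial import cKDTree
from skimage import measure

from .synthetic import OCTANTS, BSDM_REGIONS
from .volume import LabelVolume, _AXIS_GROUP

__all__ = [
    "SurfaceMesh", "RigidTransform", "Correspondence", "DistanceMap",
    "mirror_right", "extract_mesh", "icp_register", "correspond",
    "vertex_distance", "estimate_axes", "fit_head_sphere",
    "apply_shaft_cutoff", "measure_shaft_length", "cohort_shaft_cutoff",
    "partition_head", "bsdm_summary", "align_to_atlas", "compare_pair",
]


# ---------------------------------------------------------------------------
# types
# ---------------------------------------------------------------------------


@dataclass
class SurfaceMesh:
    """Triangle mesh in physical mm with anatomical orientation metadata."""

    vertices: np.ndarray  # (N, 3) mm
    faces: np.ndarray  # (M, 3) int
    side: str | None = None
    subject_id: str | None = None
    axes: str = "RAS"

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.faces = np.asarray(self.faces, dtype=np.int64)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise ValueError("vertices must be (N, 3)")
        if self.faces.ndim != 2 or self.faces.shape[1] != 3:
            raise ValueError("faces must be (M, 3)")
        if self.faces.size and (self.faces.min() < 0
                                or self.faces.max() >= len(self.vertices)):
            raise ValueError("faces index out of range")

    def direction(self, letter: str) -> np.ndarray:
        """Unit world vector of an anatomical direction (R/L/A/P/S/I)."""
        letter = letter.upper()
        group = _AXIS_GROUP[letter]
        for ax, c in enumerate(self.axes):
            if _AXIS_GROUP[c] == group:
                vec = np.zeros(3)
                vec[ax] = 1.0 if c == letter else -1.0
                return vec
        raise ValueError(f"no axis for {letter!r} in code {self.axes!r}")

    def as_trimesh(self) -> trimesh.Trimesh:
        return trimesh.Trimesh(self.vertices.copy(), self.faces.copy(),
                               process=False)

    def transformed(self, transform: "RigidTransform") -> "SurfaceMesh":
        return replace(self, vertices=transform.apply(self.vertices))


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid motion x -> R x + t."""

    rotation: np.ndarray  # (3, 3)
    translation: np.ndarray  # (3,)
    rms_history: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "rotation", np.asarray(self.rotation, float))
        object.__setattr__(self, "translation",
                           np.asarray(self.translation, float))
        R = self.rotation
        if not np.allclose(R.T @ R, np.eye(3), atol=1e-9):
            raise ValueError("rotation is not orthonormal")
        if np.linalg.det(R) < 0:
            raise ValueError("rotation has det -1 (reflection)")

    def apply(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points) @ self.rotation.T + self.translation

    def inverse(self) -> "RigidTransform":
        return RigidTransform(self.rotation.T,
                              -self.rotation.T @ self.translation)

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """self o other: apply ``other`` first, then ``self``."""
        return RigidTransform(self.rotation @ other.rotation,
                              self.rotation @ other.translation
                              + self.translation)

    @property
    def rms(self) -> float:
        return self.rms_history[-1] if self.rms_history else float("nan")


@dataclass(frozen=True)
class Correspondence:
    """Per source-vertex match on the target surface."""

    source_points: np.ndarray  # (N, 3)
    matched_points: np.ndarray  # (N, 3) closest points on target triangles
    face_index: np.ndarray  # (N,)
    vertex_index: np.ndarray  # (N,) nearest vertex of the matched triangle


@dataclass
class DistanceMap:
    """Per-vertex left-vs-right distances with head ROI and octant labels."""

    vertices: np.ndarray  # (N, 3) source-mesh vertices, mm
    d: np.ndarray  # (N,) mm
    head_center: np.ndarray | None = None
    roi: np.ndarray | None = None  # (N,) bool
    octant: np.ndarray | None = None  # (N,) '<U3', '' outside ROI


class AxisSet(NamedTuple):
    """Shaft axis (oriented head -> shaft) and anatomical unit axes."""

    shaft: np.ndarray
    anterior: np.ndarray
    medial: np.ndarray
    superior: np.ndarray


# ---------------------------------------------------------------------------
# mirroring and meshing
# ---------------------------------------------------------------------------


def mirror_right(v: LabelVolume) -> LabelVolume:
    """Reflect a right-hip mask across the L-R axis into the left frame."""
    return v.mirrored()


def _laplacian_smooth(vertices: np.ndarray, faces: np.ndarray,
                      iterations: int, lam: float) -> np.ndarray:
    """Umbrella-operator smoothing with inverse-distance weights.

    v_i <- v_i + lam * (sum_j w_ij v_j / sum_j w_ij - v_i) over 1-ring
    neighbours j, w_ij = 1 / ||v_j - v_i|| recomputed each pass.
    """
    if iterations <= 0:
        return vertices
    e = np.vstack([faces[:, [0, 1]], faces[:, [1, 2]], faces[:, [2, 0]]])
    e = np.unique(np.vstack([e, e[:, ::-1]]), axis=0)  # directed, deduped
    src, dst = e[:, 0], e[:, 1]
    n = len(vertices)
    v = vertices.astype(float).copy()
    for _ in range(iterations):
        diff = v[dst] - v[src]
        dist = np.linalg.norm(diff, axis=1)
        w = 1.0 / np.maximum(dist, 1e-12)
        sw = np.bincount(src, weights=w, minlength=n)
        centroid = np.column_stack([
            np.bincount(src, weights=w * v[dst, k], minlength=n)
            for k in range(3)
        ])
        has = sw > 0
        v[has] += lam * (centroid[has] / sw[has, None] - v[has])
    return v


def extract_mesh(v: LabelVolume, smoothing_iters: int = 10,
                 lam: float = 0.5, side: str | None = None,
                 subject_id: str | None = None) -> SurfaceMesh:
    """Isosurface at level 0.5 in mm, cleaned and Laplacian-smoothed.

    Duplicate vertices are merged and unreferenced vertices dropped before
    smoothing; if the isosurface has several shells only the largest is
    kept (the masks this pipeline consumes are single components).
    """
    if not (v.grid > 0).any():
        raise ValueError("cannot mesh an empty mask")
    grid = np.pad(v.grid.astype(np.float32), 1)
    verts, faces, _, _ = measure.marching_cubes(grid, level=0.5,
                                                spacing=v.spacing)
    verts = verts - np.asarray(v.spacing) + np.asarray(v.origin)
    tm = trimesh.Trimesh(verts, faces, process=True, validate=True)
    parts = tm.split(only_watertight=False)
    if len(parts) > 1:
        tm = max(parts, key=lambda p: len(p.vertices))
    verts = _laplacian_smooth(np.asarray(tm.vertices), np.asarray(tm.faces),
                              smoothing_iters, lam)
    return SurfaceMesh(verts, np.asarray(tm.faces), side=side,
                       subject_id=subject_id, axes=v.axes)


# ---------------------------------------------------------------------------
# rigid registration
# ---------------------------------------------------------------------------


def _kabsch(p: np.ndarray, q: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares rigid fit p -> q (SVD, reflection-corrected)."""
    pc, qc = p.mean(axis=0), q.mean(axis=0)
    h = (p - pc).T @ (q - qc)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    r = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    return r, qc - r @ pc


def _check_not_collinear(points: np.ndarray) -> None:
    if len(points) < 3:
        raise ValueError("need at least 3 vertices")
    c = points - points.mean(axis=0)
    s = np.linalg.svd(c, compute_uv=False)
    if s[1] <= 1e-9 * max(s[0], 1.0):
        raise ValueError("degenerate (collinear) geometry")


def _pca_init(src: np.ndarray, tgt: np.ndarray,
              tree: cKDTree) -> tuple[np.ndarray, np.ndarray]:
    """Coarse alignment of the principal-axis frames.

    The two shapes are congruent up to the sought rigid motion, so mapping
    the source eigenvector frame onto the target's recovers the rotation
    up to axis sign flips; the four proper-rotation sign combinations are
    scored by nearest-neighbour RMS on a small subsample and the best kept.
    """
    sc, tc = src.mean(axis=0), tgt.mean(axis=0)
    _, vs = np.linalg.eigh((src - sc).T @ (src - sc))
    _, vt = np.linalg.eigh((tgt - tc).T @ (tgt - tc))
    probe = src[np.linspace(0, len(src) - 1,
                            min(len(src), 1000)).astype(int)]
    best: tuple[float, np.ndarray, np.ndarray] | None = None
    for s1 in (1.0, -1.0):
        for s2 in (1.0, -1.0):
            signs = np.array([s1, s2, 1.0])
            rot = vt @ np.diag(signs) @ vs.T
            if np.linalg.det(rot) < 0:
                rot = vt @ np.diag(signs * [1.0, 1.0, -1.0]) @ vs.T
            trans = tc - rot @ sc
            d, _ = tree.query(probe @ rot.T + trans)
            rms = float(np.sqrt(np.mean(d**2)))
            if best is None or rms < best[0]:
                best = (rms, rot, trans)
    assert best is not None
    return best[1], best[2]


def icp_register(source: SurfaceMesh, target: SurfaceMesh,
                 max_iterations: int = 100, tol: float = 1e-6,
                 max_points: int | None = None,
                 init: str = "pca") -> RigidTransform:
    """Point-to-point ICP returning the rigid motion source -> target.

    Initialized by centroid alignment plus, by default, a principal-axes
    orientation guess (``init="pca"``): on elongated bones that are nearly
    rotationally symmetric about the shaft, plain centroid initialization
    (``init="centroid"``) leaves rotations about the long axis in a
    shallow local minimum. The loop alternates KD-tree closest-vertex
    matching with an SVD rigid fit until the RMS residual changes by less
    than ``tol`` mm or ``max_iterations`` is reached. ``max_points``
    optionally subsamples the source vertices with a deterministic even
    stride (matching still runs against the full target).
    """
    src = source.vertices
    tgt = target.vertices
    _check_not_collinear(src)
    _check_not_collinear(tgt)
    if max_points is not None and len(src) > max_points:
        idx = np.unique(np.linspace(0, len(src) - 1, max_points).astype(int))
        src = src[idx]

    tree = cKDTree(tgt)
    if init == "pca":
        rot, trans = _pca_init(src, tgt, tree)
    elif init == "centroid":
        rot = np.eye(3)
        trans = tgt.mean(axis=0) - src.mean(axis=0)
    else:
        raise ValueError(f"init must be 'pca' or 'centroid', got {init!r}")
    history: list[float] = []
    prev = np.inf
    for _ in range(max_iterations):
        moved = src @ rot.T + trans
        _, j = tree.query(moved)
        matched = tgt[j]
        rot, trans = _kabsch(src, matched)
        resid = src @ rot.T + trans - matched
        rms = float(np.sqrt(np.mean(np.sum(resid**2, axis=1))))
        history.append(rms)
        if abs(prev - rms) < tol:
            break
        prev = rms
    return RigidTransform(rot, trans, tuple(history))


# ---------------------------------------------------------------------------
# correspondence: closest point on the target surface
# ---------------------------------------------------------------------------


def _closest_point_on_triangles(p: np.ndarray, a: np.ndarray, b: np.ndarray,
                                c: np.ndarray) -> np.ndarray:
    """Closest point to p on each triangle (a, b, c); all arrays (N, 3)."""
    ab, ac, ap = b - a, c - a, p - a
    d1 = np.einsum("ij,ij->i", ab, ap)
    d2 = np.einsum("ij,ij->i", ac, ap)
    bp = p - b
    d3 = np.einsum("ij,ij->i", ab, bp)
    d4 = np.einsum("ij,ij->i", ac, bp)
    cp = p - c
    d5 = np.einsum("ij,ij->i", ab, cp)
    d6 = np.einsum("ij,ij->i", ac, cp)
    vc = d1 * d4 - d3 * d2
    vb = d5 * d2 - d1 * d6
    va = d3 * d6 - d5 * d4

    out = np.empty_like(p)
    unset = np.ones(len(p), dtype=bool)

    def settle(mask: np.ndarray, value: np.ndarray) -> None:
        m = mask & unset
        out[m] = value[m]
        unset[m] = False

    settle((d1 <= 0) & (d2 <= 0), a)  # vertex A
    settle((d3 >= 0) & (d4 <= d3), b)  # vertex B
    settle((d6 >= 0) & (d5 <= d6), c)  # vertex C
    with np.errstate(divide="ignore", invalid="ignore"):
        t_ab = np.where(d1 - d3 != 0, d1 / (d1 - d3), 0.0)
        settle((vc <= 0) & (d1 >= 0) & (d3 <= 0), a + t_ab[:, None] * ab)
        t_ac = np.where(d2 - d6 != 0, d2 / (d2 - d6), 0.0)
        settle((vb <= 0) & (d2 >= 0) & (d6 <= 0), a + t_ac[:, None] * ac)
        den_bc = (d4 - d3) + (d5 - d6)
        t_bc = np.where(den_bc != 0, (d4 - d3) / den_bc, 0.0)
        settle((va <= 0) & (d4 - d3 >= 0) & (d5 - d6 >= 0),
               b + t_bc[:, None] * (c - b))
        denom = np.where(va + vb + vc != 0, va + vb + vc, 1.0)
        v = vb / denom
        w = vc / denom
        settle(unset, a + v[:, None] * ab + w[:, None] * ac)  # interior
    return out


def _vertex_face_incidence(faces: np.ndarray, n_vertices: int):
    """CSR-style (indptr, face_ids) listing faces incident to each vertex."""
    flat = faces.ravel()
    order = np.argsort(flat, kind="stable")
    face_ids = np.repeat(np.arange(len(faces)), 3)[order]
    indptr = np.searchsorted(flat[order], np.arange(n_vertices + 1))
    return indptr, face_ids


def correspond(source: SurfaceMesh, target: SurfaceMesh,
               k_candidates: int = 4) -> Correspondence:
    """Match each source vertex to its closest point on the target surface.

    Candidate triangles are those incident to the ``k_candidates`` nearest
    target vertices of each source vertex; the exact point-to-triangle
    minimizer is evaluated on all candidates and the closest (ties broken
    toward the lowest face index) is kept. On the densely triangulated,
    rigidly pre-registered meshes this pipeline produces, the candidate
    set contains the true nearest triangle.
    """
    if len(target.vertices) == 0 or len(target.faces) == 0:
        raise ValueError("target mesh is empty")
    pts = source.vertices
    tv, tf = target.vertices, target.faces
    k = min(k_candidates, len(tv))
    _, nn = cKDTree(tv).query(pts, k=k)
    nn = np.atleast_2d(nn.reshape(len(pts), -1))

    indptr, face_ids = _vertex_face_incidence(tf, len(tv))
    nnf = nn.ravel()
    starts = indptr[nnf]
    counts = indptr[nnf + 1] - starts
    offsets = np.concatenate([[0], np.cumsum(counts)])
    flat = (np.arange(offsets[-1]) - np.repeat(offsets[:-1], counts)
            + np.repeat(starts, counts))
    cand = face_ids[flat]
    owner = np.repeat(np.arange(nnf.size) // k, counts)

    tri = tf[cand]
    closest = _closest_point_on_triangles(
        pts[owner], tv[tri[:, 0]], tv[tri[:, 1]], tv[tri[:, 2]]
    )
    dist = np.linalg.norm(closest - pts[owner], axis=1)
    order = np.lexsort((cand, dist, owner))
    _, first = np.unique(owner[order], return_index=True)
    best = order[first]

    matched = closest[best]
    faces_best = cand[best]
    corners = tv[tf[faces_best]]  # (N, 3, 3)
    corner_d = np.linalg.norm(corners - matched[:, None, :], axis=2)
    vertex_idx = tf[faces_best, np.argmin(corner_d, axis=1)]
    return Correspondence(pts.copy(), matched, faces_best, vertex_idx)


def barycentric_coordinates(corr: Correspondence,
                            target: SurfaceMesh) -> np.ndarray:
    """Barycentric coordinates of each matched point in its triangle."""
    tri = target.vertices[target.faces[corr.face_index]]
    a, b, c = tri[:, 0], tri[:, 1], tri[:, 2]
    v0, v1 = b - a, c - a
    v2 = corr.matched_points - a
    d00 = np.einsum("ij,ij->i", v0, v0)
    d01 = np.einsum("ij,ij->i", v0, v1)
    d11 = np.einsum("ij,ij->i", v1, v1)
    d20 = np.einsum("ij,ij->i", v2, v0)
    d21 = np.einsum("ij,ij->i", v2, v1)
    denom = np.where(d00 * d11 - d01 * d01 != 0, d00 * d11 - d01 * d01, 1.0)
    v = (d11 * d20 - d01 * d21) / denom
    w = (d00 * d21 - d01 * d20) / denom
    return np.column_stack([1.0 - v - w, v, w])


def vertex_distance(corr: Correspondence) -> DistanceMap:
    """Per-vertex Euclidean distance between corresponding points, mm."""
    d = np.linalg.norm(corr.matched_points - corr.source_points, axis=1)
    return DistanceMap(vertices=corr.source_points.copy(), d=d)


# ---------------------------------------------------------------------------
# anatomy: axes, head sphere, shaft cutoff, octants
# ---------------------------------------------------------------------------


def _shaft_axis_from_points(points: np.ndarray) -> np.ndarray:
    """Dominant scatter axis oriented head -> shaft (head end = wider)."""
    c = points.mean(axis=0)
    rel = points - c
    cov = rel.T @ rel / len(points)
    w, v = np.linalg.eigh(cov)
    if w[2] < 1.5 * w[1]:
        raise ValueError("no dominant axis: vertex scatter is near-isotropic")
    axis = v[:, 2]
    t = rel @ axis
    q1, q3 = np.quantile(t, [0.25, 0.75])
    radial = rel - np.outer(t, axis)
    rnorm = np.linalg.norm(radial, axis=1)
    spread_lo = rnorm[t <= q1].mean()
    spread_hi = rnorm[t >= q3].mean()
    # head (sphere, radius > shaft radius) is the wider end; point away from it
    return axis if spread_lo > spread_hi else -axis


def estimate_axes(mesh: SurfaceMesh) -> AxisSet:
    """Shaft axis from the vertex scatter plus anatomical axes from the code.

    The anatomical directions come from the mesh's orientation code
    (medial = patient-right in the left-oriented frame) and are
    orthonormalized against the superior-inferior direction.
    """
    shaft = _shaft_axis_from_points(mesh.vertices)
    superior = mesh.direction("S")
    anterior = mesh.direction("A")
    medial = mesh.direction("R")
    anterior = anterior - (anterior @ superior) * superior
    anterior /= np.linalg.norm(anterior)
    medial = (medial - (medial @ superior) * superior
              - (medial @ anterior) * anterior)
    medial /= np.linalg.norm(medial)
    return AxisSet(shaft, anterior, medial, superior)


def _algebraic_sphere(points: np.ndarray) -> tuple[np.ndarray, float]:
    a = np.column_stack([2.0 * points, np.ones(len(points))])
    b = np.einsum("ij,ij->i", points, points)
    sol, *_ = np.linalg.lstsq(a, b, rcond=None)
    center = sol[:3]
    r = float(np.sqrt(max(sol[3] + center @ center, 0.0)))
    return center, r


def fit_head_sphere(mesh: SurfaceMesh, shaft_axis: np.ndarray | None = None,
                    head_fraction: float = 0.4) -> tuple[np.ndarray, float]:
    """Least-squares sphere fit to the femoral-head vertices.

    Candidates are the vertices in the proximal ``head_fraction`` of the
    extent along the shaft axis; an algebraic (linear) fit is refined by
    trimming vertices whose radial residual is large (neck/junction
    leverage) and refitting. Exact sphere point sets are recovered exactly.
    """
    pts = mesh.vertices
    if shaft_axis is None:
        shaft_axis = _shaft_axis_from_points(pts)
    t = pts @ shaft_axis
    tmin, tmax = t.min(), t.max()
    cand = pts[t <= tmin + head_fraction * (tmax - tmin)]
    if len(cand) < 4 or np.linalg.matrix_rank(cand - cand.mean(0)) < 3:
        raise ValueError("fewer than 4 non-coplanar head candidate vertices")
    center, radius = _algebraic_sphere(cand)
    for _ in range(10):
        resid = np.abs(np.linalg.norm(cand - center, axis=1) - radius)
        # floor the cutoff at sub-voxel scale so exact spheres keep all points
        cutoff = max(2.5 * 1.4826 * np.median(resid), 0.2)
        keep = resid <= cutoff
        if keep.sum() < 10 or keep.all():
            break
        cand = cand[keep]
        center, radius = _algebraic_sphere(cand)
    return center, radius


def measure_shaft_length(mesh: SurfaceMesh,
                         axes: AxisSet | None = None,
                         center: np.ndarray | None = None) -> float:
    """Extent (mm) from the head centre to the distal end along the shaft."""
    if axes is None:
        axes = estimate_axes(mesh)
    if center is None:
        center, _ = fit_head_sphere(mesh, axes.shaft)
    return float(((mesh.vertices - center) @ axes.shaft).max())


def cohort_shaft_cutoff(meshes: Sequence[SurfaceMesh]) -> float:
    """Uniform cutoff = minimum measured shaft length over the cohort."""
    if not meshes:
        raise ValueError("empty cohort")
    return min(measure_shaft_length(m) for m in meshes)


def apply_shaft_cutoff(obj, cutoff_length: float):
    """Drop everything farther than ``cutoff_length`` from the head centre
    along the shaft axis. Accepts a SurfaceMesh or a LabelVolume and
    returns the same type."""
    if isinstance(obj, SurfaceMesh):
        axes = estimate_axes(obj)
        center, _ = fit_head_sphere(obj, axes.shaft)
        t = (obj.vertices - center) @ axes.shaft
        keep = t <= cutoff_length
        if keep.sum() < 3:
            raise ValueError(
                f"cutoff {cutoff_length} mm removes the entire head"
            )
        if keep.all():
            return replace(obj, vertices=obj.vertices.copy(),
                           faces=obj.faces.copy())
        new_index = -np.ones(len(obj.vertices), dtype=np.int64)
        new_index[keep] = np.arange(keep.sum())
        fkeep = keep[obj.faces].all(axis=1)
        return replace(obj, vertices=obj.vertices[keep].copy(),
                       faces=new_index[obj.faces[fkeep]])
    if isinstance(obj, LabelVolume):
        from .segeval import border_voxels

        border = border_voxels(obj).coords
        shaft = _shaft_axis_from_points(border)
        center, _ = fit_head_sphere(
            SurfaceMesh(border, np.zeros((0, 3), dtype=np.int64),
                        axes=obj.axes),
            shaft,
        )
        idx = np.argwhere(obj.grid > 0)
        t = (obj.world_coords(idx) - center) @ shaft
        drop = idx[t > cutoff_length]
        grid = obj.grid.copy()
        grid[tuple(drop.T)] = 0
        if not (grid > 0).any():
            raise ValueError(
                f"cutoff {cutoff_length} mm removes the entire head"
            )
        return replace(obj, grid=grid)
    raise TypeError(f"unsupported type {type(obj).__name__}")


def partition_head(dmap: DistanceMap, axes: AxisSet, center: np.ndarray,
                   roi_diameter: float = 55.0) -> DistanceMap:
    """Label the head-ROI vertices with their octant (AMS ... PLI).

    ROI = vertices within ``roi_diameter / 2`` of the head centre. Octants
    come from the signs of point-to-plane distances to the three planes
    through the centre normal to the anterior-posterior, medial-lateral
    and superior-inferior axes; a distance of exactly zero is assigned to
    the positive (anterior/medial/superior) side.
    """
    rel = dmap.vertices - np.asarray(center)
    roi = np.linalg.norm(rel, axis=1) <= roi_diameter / 2.0
    if not roi.any():
        raise ValueError(f"no vertices inside the {roi_diameter} mm ROI")
    sa = rel @ axes.anterior
    sm = rel @ axes.medial
    ss = rel @ axes.superior
    labels = np.char.add(
        np.char.add(np.where(sa >= 0, "A", "P"), np.where(sm >= 0, "M", "L")),
        np.where(ss >= 0, "S", "I"),
    ).astype("<U3")
    labels[~roi] = ""
    return replace(dmap, head_center=np.asarray(center, float),
                   roi=roi, octant=labels)


def bsdm_summary(dmap: DistanceMap) -> pd.DataFrame:
    """Mean/SD (mm) of d and vertex counts for the head ROI and octants.

    Empty octants are reported as missing (NaN), never as zero. SD uses
    population (n) normalization.
    """
    if dmap.roi is None or dmap.octant is None:
        raise ValueError("partition the head ROI before summarizing")
    rows = []
    for region in BSDM_REGIONS:
        sel = dmap.roi if region == "head" else (dmap.octant == region)
        values = dmap.d[sel]
        if values.size == 0:
            rows.append((region, np.nan, np.nan, 0))
        else:
            rows.append((region, float(values.mean()),
                         float(values.std(ddof=0)), int(values.size)))
    return pd.DataFrame(rows, columns=["region", "mean_mm", "sd_mm",
                                       "n_vertices"]).set_index("region")


# ---------------------------------------------------------------------------
# atlas alignment and the end-to-end pair pipeline
# ---------------------------------------------------------------------------


def align_to_atlas(
    meshes: Sequence[SurfaceMesh], atlas: SurfaceMesh, **icp_kwargs
) -> list[tuple[SurfaceMesh, RigidTransform]]:
    """Rigidly register each mesh onto the reference atlas.

    The atlas is a user-designated mesh (in the source study: the control
    subject with the lowest radiographic severity). Returns the transformed
    meshes with the transforms for reproducibility; per-vertex distance
    maps are unchanged by this common rigid motion.
    """
    out = []
    for mesh in meshes:
        transform = icp_register(mesh, atlas, **icp_kwargs)
        out.append((mesh.transformed(transform), transform))
    return out


class PairResult(NamedTuple):
    """Full left-vs-right comparison output for one subject."""

    table: pd.DataFrame  # BSDM summary
    distance_map: DistanceMap
    transform: RigidTransform  # mirrored-right -> left registration
    head_center: np.ndarray
    head_radius: float
    left_mesh: SurfaceMesh


def compare_pair(left: LabelVolume, right: LabelVolume,
                 smoothing_iters: int = 10, lam: float = 0.5,
                 roi_diameter: float = 55.0,
                 shaft_cutoff: float | None = None,
                 max_icp_points: int | None = 10000,
                 subject_id: str | None = None) -> PairResult:
    """Run the whole asymmetry pipeline on a left/right mask pair."""
    right_m = mirror_right(right)
    mesh_l = extract_mesh(left, smoothing_iters, lam, side="left",
                          subject_id=subject_id)
    mesh_r = extract_mesh(right_m, smoothing_iters, lam, side="right",
                          subject_id=subject_id)
    if shaft_cutoff is not None:
        mesh_l = apply_shaft_cutoff(mesh_l, shaft_cutoff)
        mesh_r = apply_shaft_cutoff(mesh_r, shaft_cutoff)
    transform = icp_register(mesh_r, mesh_l, max_points=max_icp_points)
    mesh_r_reg = mesh_r.transformed(transform)
    corr = correspond(mesh_l, mesh_r_reg)
    dmap = vertex_distance(corr)
    axes = estimate_axes(mesh_l)
    center, radius = fit_head_sphere(mesh_l, axes.shaft)
    dmap = partition_head(dmap, axes, center, roi_diameter)
    return PairResult(bsdm_summary(dmap), dmap, transform, center, radius,
                      mesh_l)
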