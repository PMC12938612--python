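"""Segmentation agreement metrics: DSC, ASSD, RAVD and Hausdorff distance.

Border voxels are foreground voxels with at least one 6-neighbour in the
background; surface distances are Euclidean distances between border-voxel
centres in millimetres, so anisotropic spacing is respected. DSC and RAVD
are reported in percent, ASSD and HD in mm.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage, stats
from scipy.spatial import cKDTree

from .volume import LabelVolume


@dataclass(frozen=True)
class BorderSet:
    """Boundary voxels of a label volume, in mm world coordinates."""

    coords: np.ndarray  # (N, 3) mm
    indices: np.ndarray  # (N, 3) voxel indices


@dataclass(frozen=True)
class SegEvalResult:
    dsc: float  # %
    assd: float  # mm
    ravd: float  # %
    hd: float  # mm


def _check_pair(a: LabelVolume, b: LabelVolume) -> None:
    if a.grid.shape != b.grid.shape:
        raise ValueError(
            f"grid shapes differ: {a.grid.shape} vs {b.grid.shape}"
        )
    if not np.allclose(a.spacing, b.spacing):
        raise ValueError(f"spacings differ: {a.spacing} vs {b.spacing}")


def border_voxels(v: LabelVolume) -> BorderSet:
    """Foreground voxels with a background 6-neighbour, as mm coordinates."""
    fg = v.grid > 0
    if not fg.any():
        raise ValueError("volume has empty foreground")
    structure = ndimage.generate_binary_structure(3, 1)
    interior = ndimage.binary_erosion(fg, structure=structure, border_value=0)
    idx = np.argwhere(fg & ~interior)
    return BorderSet(coords=v.world_coords(idx), indices=idx)


def dice(a: LabelVolume, b: LabelVolume) -> float:
    """Dice similarity coefficient in percent: 100 * 2|A n B| / (|A| + |B|)."""
    _check_pair(a, b)
    fa, fb = a.grid > 0, b.grid > 0
    denom = int(fa.sum()) + int(fb.sum())
    if denom == 0:
        raise ValueError("both masks are empty; DSC is undefined")
    return 200.0 * int((fa & fb).sum()) / denom


def ravd(seg: LabelVolume, gt: LabelVolume) -> float:
    """Relative absolute volume difference in percent of the GT volume."""
    _check_pair(seg, gt)
    n_gt = int((gt.grid > 0).sum())
    if n_gt == 0:
        raise ValueError("ground-truth mask is empty; RAVD is undefined")
    n_seg = int((seg.grid > 0).sum())
    return 100.0 * abs(n_seg - n_gt) / n_gt


def assd(a: LabelVolume, b: LabelVolume) -> float:
    """Average symmetric surface distance between border sets, in mm."""
    _check_pair(a, b)
    ba, bb = border_voxels(a), border_voxels(b)
    d_ab = cKDTree(bb.coords).query(ba.coords)[0]
    d_ba = cKDTree(ba.coords).query(bb.coords)[0]
    return float((d_ab.sum() + d_ba.sum()) / (len(d_ab) + len(d_ba)))


def hausdorff(a: LabelVolume, b: LabelVolume) -> float:
    """Symmetric Hausdorff distance between border sets, in mm."""
    _check_pair(a, b)
    ba, bb = border_voxels(a), border_voxels(b)
    d_ab = cKDTree(bb.coords).query(ba.coords)[0]
    d_ba = cKDTree(ba.coords).query(bb.coords)[0]
    return float(max(d_ab.max(), d_ba.max()))


def evaluate(seg: LabelVolume, gt: LabelVolume) -> SegEvalResult:
    """All four metrics for one segmentation/ground-truth pair."""
    return SegEvalResult(
        dsc=dice(seg, gt), assd=assd(seg, gt), ravd=ravd(seg, gt),
        hd=hausdorff(seg, gt),
    )


def evaluate_cohort(
    pairs: Sequence[tuple[LabelVolume, LabelVolume]],
) -> pd.DataFrame:
    """Per-case metrics plus mean and t-based 95% confidence interval.

    Returns a frame indexed by metric with columns ``mean``, ``ci_low``,
    ``ci_high``, ``n`` and attribute-style access to the per-case table via
    ``frame.attrs["cases"]``.
    """
    if len(pairs) < 2:
        raise ValueError("need at least 2 pairs for a confidence interval")
    cases = pd.DataFrame(
        [evaluate(seg, gt).__dict__ for seg, gt in pairs],
        columns=["dsc", "assd", "ravd", "hd"],
    )
    n = len(cases)
    mean = cases.mean()
    sem = cases.std(ddof=1) / np.sqrt(n)
    tcrit = stats.t.ppf(0.975, df=n - 1)
    out = pd.DataFrame(
        {
            "mean": mean,
            "ci_low": mean - tcrit * sem,
            "ci_high": mean + tcrit * sem,
            "n": n,
        }
    )
    out.attrs["cases"] = cases
    return out
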