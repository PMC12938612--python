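"""Labeled 3D volumes with physical spacing and anatomical orientation.

Conventions used throughout the package:

* voxel indices are 0-based; the world coordinate of voxel ``(i, j, k)`` is
  ``origin + (i, j, k) * spacing`` (diagonal affine, mm);
* ``axes`` is a three-letter orientation code giving the anatomical
  direction of *increasing* index along each array axis, drawn from
  ``R/L`` (right/left), ``A/P`` (anterior/posterior), ``S/I``
  (superior/inferior) — e.g. ``"RAS"``;
* all bilateral analysis is carried out in a left-hip frame: right-hip
  volumes are mirrored across the left–right axis first, and "medial"
  denotes the patient-right (``R``) direction of that left-oriented frame.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

_OPPOSITE = {"R": "L", "L": "R", "A": "P", "P": "A", "S": "I", "I": "S"}
_AXIS_GROUP = {"R": "LR", "L": "LR", "A": "AP", "P": "AP", "S": "SI", "I": "SI"}


@dataclass
class LabelVolume:
    """A 3D binary/label grid with physical spacing, origin and orientation."""

    grid: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    axes: str = "RAS"

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid)
        if self.grid.ndim != 3:
            raise ValueError(f"grid must be 3D, got shape {self.grid.shape}")
        self.spacing = tuple(float(s) for s in self.spacing)
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be positive, got {self.spacing}")
        self.origin = tuple(float(o) for o in self.origin)
        if sorted(_AXIS_GROUP.get(c, "?") for c in self.axes.upper()) != [
            "AP",
            "LR",
            "SI",
        ]:
            raise ValueError(
                f"axes code {self.axes!r} must name one of R/L, A/P, S/I per axis"
            )
        self.axes = self.axes.upper()

    # -- geometry -----------------------------------------------------------

    @property
    def affine(self) -> np.ndarray:
        """4x4 voxel-to-world affine (diagonal spacing + origin)."""
        aff = np.eye(4)
        aff[:3, :3] = np.diag(self.spacing)
        aff[:3, 3] = self.origin
        return aff

    def axis_of(self, letter: str) -> int:
        """Array axis running along the given anatomical pair (e.g. 'R' or 'L')."""
        group = _AXIS_GROUP[letter.upper()]
        for i, c in enumerate(self.axes):
            if _AXIS_GROUP[c] == group:
                return i
        raise ValueError(f"no axis for {letter!r} in code {self.axes!r}")

    def direction(self, letter: str) -> np.ndarray:
        """Unit world vector pointing in the given anatomical direction."""
        letter = letter.upper()
        ax = self.axis_of(letter)
        vec = np.zeros(3)
        vec[ax] = 1.0 if self.axes[ax] == letter else -1.0
        return vec

    def world_coords(self, indices: np.ndarray) -> np.ndarray:
        """World (mm) coordinates of voxel indices, shape (N, 3)."""
        idx = np.atleast_2d(np.asarray(indices, dtype=float))
        return idx * np.asarray(self.spacing) + np.asarray(self.origin)

    # -- operations ---------------------------------------------------------

    def mirrored(self) -> "LabelVolume":
        """Reflect across the left–right axis (about the grid mid-plane).

        The grid is flipped along the L–R array axis and the orientation
        letter of that axis is swapped (R<->L); spacing and origin are kept so
        world coordinates remain attached to the same grid. Applying the
        operation twice returns the original volume exactly.
        """
        ax = self.axis_of("R")
        code = list(self.axes)
        code[ax] = _OPPOSITE[code[ax]]
        return replace(
            self, grid=np.flip(self.grid, axis=ax).copy(), axes="".join(code)
        )

    def foreground_count(self) -> int:
        return int(np.count_nonzero(self.grid))

    def connected_components(self) -> int:
        """Number of 6-connected foreground components."""
        structure = ndimage.generate_binary_structure(3, 1)
        _, n = ndimage.label(self.grid > 0, structure=structure)
        return int(n)
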