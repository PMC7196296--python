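"""Lattice containers for volumes and atlas labels.

All volumes in a study live on congruent 3-D lattices: same shape, same
voxel spacing, same world origin.  World coordinates are continuous, in mm,
with the center of voxel ``(i, j, k)`` at ``origin + (index + 0.5) * spacing``
(0-based indices).  Voxels masked out of the brain (extrameningeal tissue)
are encoded as NaN and excluded from every statistic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: tolerance, in mm, for congruence of spacings and origins
CONGRUENCE_TOL_MM = 1e-6

MODALITIES = ("SPECT", "MRI", "PARAMETRIC")


@dataclass
class VolumeGrid:
    """A 3-D scalar lattice with physical voxel size and world origin.

    Parameters
    ----------
    values : ndarray, shape (nx, ny, nz)
        Voxel values.  NaN marks masked-out (non-brain) voxels.
    voxel_size_mm : 3-tuple of float
        Per-axis spacing, strictly positive.
    origin_mm : 3-tuple of float
        World coordinate of the corner of voxel (0, 0, 0); the voxel center
        is at ``origin + 0.5 * spacing``.
    modality : str
        One of ``SPECT``, ``MRI``, ``PARAMETRIC``.
    """

    values: np.ndarray
    voxel_size_mm: tuple[float, float, float]
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    modality: str = "SPECT"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 3:
            raise ValueError(
                f"expected 3-D volume, got {self.values.ndim}-D array"
            )
        if any(n < 1 for n in self.values.shape):
            raise ValueError("every axis must have at least one voxel")
        vs = tuple(float(v) for v in np.atleast_1d(self.voxel_size_mm).ravel())
        if len(vs) == 1:
            vs = vs * 3
        if len(vs) != 3 or any(v <= 0 for v in vs):
            raise ValueError("voxel_size_mm must be 3 strictly positive spacings")
        self.voxel_size_mm = vs
        self.origin_mm = tuple(float(v) for v in self.origin_mm)
        if len(self.origin_mm) != 3:
            raise ValueError("origin_mm must have 3 components")
        if self.modality not in MODALITIES:
            raise ValueError(f"unknown modality {self.modality!r}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def voxel_volume_mm3(self) -> float:
        """Volume of a single voxel in mm^3 (product of spacings)."""
        return float(np.prod(self.voxel_size_mm))

    @property
    def finite_mask(self) -> np.ndarray:
        """Boolean lattice of in-brain (finite) voxels."""
        return np.isfinite(self.values)

    def voxel_centers_mm(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """World coordinates of voxel centers, as three broadcastable axes."""
        axes = []
        for n, sp, o in zip(self.shape, self.voxel_size_mm, self.origin_mm):
            axes.append(o + (np.arange(n) + 0.5) * sp)
        x, y, z = np.meshgrid(*axes, indexing="ij", sparse=True)
        return x, y, z

    def world_bounds_mm(self) -> tuple[np.ndarray, np.ndarray]:
        lo = np.asarray(self.origin_mm)
        hi = lo + np.asarray(self.shape) * np.asarray(self.voxel_size_mm)
        return lo, hi

    def like(self, values: np.ndarray, modality: str | None = None) -> "VolumeGrid":
        """A new VolumeGrid on this grid's lattice carrying ``values``."""
        return VolumeGrid(
            values=np.asarray(values, dtype=np.float64),
            voxel_size_mm=self.voxel_size_mm,
            origin_mm=self.origin_mm,
            modality=modality or self.modality,
        )


@dataclass
class LabelVolume:
    """Integer atlas labels congruent with a :class:`VolumeGrid`.

    ``region_ids`` carries atlas region ids (0 = outside any region);
    ``hemisphere_ids`` covers the whole lattice (1 = ipsilesional/left,
    2 = contralesional/right) so that tissue appearing outside the static
    atlas (e.g. a swollen rim on MRI) still has a hemisphere;
    ``ventricle_mask`` marks ventricle voxels, which are excluded from
    ``region_ids``.
    """

    region_ids: np.ndarray
    hemisphere_ids: np.ndarray
    voxel_size_mm: tuple[float, float, float]
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    ventricle_mask: np.ndarray | None = None

    HEMI_LEFT = 1   # ipsilesional
    HEMI_RIGHT = 2  # contralesional

    def __post_init__(self) -> None:
        self.region_ids = np.asarray(self.region_ids)
        self.hemisphere_ids = np.asarray(self.hemisphere_ids)
        if self.region_ids.ndim != 3:
            raise ValueError("region_ids must be a 3-D lattice")
        if not np.issubdtype(self.region_ids.dtype, np.integer):
            raise ValueError("region_ids must be integer-valued")
        if self.hemisphere_ids.shape != self.region_ids.shape:
            raise ValueError("hemisphere_ids shape differs from region_ids")
        if self.ventricle_mask is None:
            self.ventricle_mask = np.zeros(self.region_ids.shape, dtype=bool)
        else:
            self.ventricle_mask = np.asarray(self.ventricle_mask, dtype=bool)
            if self.ventricle_mask.shape != self.region_ids.shape:
                raise ValueError("ventricle_mask shape differs from region_ids")
        vs = tuple(float(v) for v in np.atleast_1d(self.voxel_size_mm).ravel())
        if len(vs) == 1:
            vs = vs * 3
        self.voxel_size_mm = vs
        self.origin_mm = tuple(float(v) for v in self.origin_mm)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.region_ids.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.voxel_size_mm))

    def hemisphere_mask(self, side: str) -> np.ndarray:
        hid = {"left": self.HEMI_LEFT, "right": self.HEMI_RIGHT}[side]
        return self.hemisphere_ids == hid

    def present_region_ids(self) -> np.ndarray:
        ids = np.unique(self.region_ids)
        return ids[ids > 0]


def check_congruent(a, b, tol_mm: float = CONGRUENCE_TOL_MM) -> bool:
    """True iff the two lattices share shape, spacing and origin within tol.

    Accepts any mix of :class:`VolumeGrid` and :class:`LabelVolume`.  Pure
    predicate: never raises for mismatches.
    """
    if a.shape != b.shape:
        return False
    for attr in ("voxel_size_mm", "origin_mm"):
        va = np.asarray(getattr(a, attr), dtype=float)
        vb = np.asarray(getattr(b, attr), dtype=float)
        if np.any(np.abs(va - vb) > tol_mm):
            return False
    return True


def require_congruent(*grids, what: str = "volumes") -> None:
    first = grids[0]
    for other in grids[1:]:
        if not check_congruent(first, other):
            raise ValueError(f"incongruent {what}: shapes/spacings/origins differ")
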