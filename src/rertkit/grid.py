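"""Regular-grid geometry, rigid transforms, resampling, and margin expansion.

Conventions
-----------
* Physical coordinates are millimetres in the patient LPS frame.
* A :class:`Grid3D` is axis-aligned; voxel ``(i, j, k)`` has its *centre* at
  ``origin + (i, j, k) * spacing``, with index axis ``i -> x (L)``,
  ``j -> y (P)``, ``k -> z (S)`` and 0-based indices. Dose and mask arrays are
  therefore indexed ``values[i, j, k]``.
* A :class:`RigidTransform` used for resampling maps *target-space* points
  into *source* space (the standard resampling/pull-back convention):
  ``p_src = R @ p_tgt + t``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Mapping

import numpy as np
from scipy import ndimage

__all__ = [
    "Grid3D",
    "Modality",
    "DoseGrid",
    "OrganClass",
    "StructureMask",
    "Trust",
    "RigidTransform",
    "InvalidTransformError",
    "resample_dose",
    "resample_mask",
    "expand_prv",
    "overlap_fraction",
]

_ORTHO_TOL = 1e-9
# snap tolerance so that exact-grid resampling (identity, whole-voxel shifts)
# reproduces source voxel values bit-identically despite float round-off
_SNAP = 1e-9


class Modality(str, Enum):
    EBRT = "EBRT"
    SBRT_SRS = "SBRT_SRS"


class OrganClass(str, Enum):
    CNS = "CNS"
    OTHER = "OTHER"
    TARGET = "TARGET"


class Trust(str, Enum):
    TRUSTED = "TRUSTED"
    UNTRUSTED = "UNTRUSTED"


class InvalidTransformError(ValueError):
    """Rotation matrix is not a proper rotation (orthonormal, det = +1)."""


@dataclass(frozen=True)
class Grid3D:
    """Axis-aligned regular grid: origin (mm, voxel-centre), spacing (mm), shape."""

    origin: tuple[float, float, float]
    spacing: tuple[float, float, float]
    shape: tuple[int, int, int]

    def __post_init__(self) -> None:
        object.__setattr__(self, "origin", tuple(float(v) for v in self.origin))
        object.__setattr__(self, "spacing", tuple(float(v) for v in self.spacing))
        object.__setattr__(self, "shape", tuple(int(v) for v in self.shape))
        if len(self.origin) != 3 or len(self.spacing) != 3 or len(self.shape) != 3:
            raise ValueError("origin, spacing and shape must have 3 components")
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be positive, got {self.spacing}")
        if any(n < 1 for n in self.shape):
            raise ValueError(f"shape must be >= 1 on all axes, got {self.shape}")

    @property
    def voxel_volume_cc(self) -> float:
        """Volume of one voxel in cubic centimetres (spacing is in mm)."""
        return float(np.prod(self.spacing)) / 1000.0

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.shape))

    def voxel_centres(self) -> np.ndarray:
        """(N, 3) array of voxel-centre coordinates in index (C) order."""
        axes = [
            self.origin[a] + np.arange(self.shape[a]) * self.spacing[a]
            for a in range(3)
        ]
        grids = np.meshgrid(*axes, indexing="ij")
        return np.stack([g.ravel() for g in grids], axis=1)

    def physical_to_index(self, points: np.ndarray) -> np.ndarray:
        """Continuous voxel indices of physical points; snaps near-integers."""
        idx = (np.asarray(points, dtype=float) - self.origin) / self.spacing
        rounded = np.round(idx)
        near = np.abs(idx - rounded) < _SNAP
        return np.where(near, rounded, idx)


@dataclass(frozen=True)
class DoseGrid:
    """Physical dose (Gy per voxel) delivered by one treatment course."""

    grid: Grid3D
    values: np.ndarray
    n_fractions: int
    modality: Modality = Modality.EBRT
    course_id: str = ""
    treatment_date: str | None = None
    out_of_extent_voxels: int | None = None  # set by resample_dose

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if tuple(values.shape) != self.grid.shape:
            raise ValueError(
                f"values shape {values.shape} != grid shape {self.grid.shape}"
            )
        if not np.all(np.isfinite(values)) or np.any(values < 0):
            raise ValueError("dose values must be finite and non-negative")
        if int(self.n_fractions) < 1:
            raise ValueError("n_fractions must be >= 1")
        object.__setattr__(self, "n_fractions", int(self.n_fractions))
        object.__setattr__(self, "modality", Modality(self.modality))


@dataclass(frozen=True)
class StructureMask:
    """Boolean voxel mask of one structure (OAR or target volume)."""

    grid: Grid3D
    values: np.ndarray
    name: str
    organ_class: OrganClass = OrganClass.OTHER
    prv_margin_mm: float = 0.0

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=bool)
        object.__setattr__(self, "values", values)
        if tuple(values.shape) != self.grid.shape:
            raise ValueError(
                f"mask shape {values.shape} != grid shape {self.grid.shape}"
            )
        if self.prv_margin_mm < 0:
            raise ValueError("prv_margin_mm must be >= 0")
        object.__setattr__(self, "organ_class", OrganClass(self.organ_class))

    @property
    def volume_cc(self) -> float:
        return float(np.count_nonzero(self.values)) * self.grid.voxel_volume_cc

    @property
    def is_empty(self) -> bool:
        return not bool(self.values.any())


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid transform ``p -> R @ p + t`` with per-OAR registration trust.

    When used for resampling, maps target-grid points into source space. The
    ``trust`` map records, per OAR name, whether the rigid registration was
    judged reliable enough for 3D dose mapping; untrusted OARs fall back to
    conservative per-course metric summation downstream.
    """

    rotation: np.ndarray = field(
        default_factory=lambda: np.eye(3)
    )
    translation: np.ndarray = field(
        default_factory=lambda: np.zeros(3)
    )
    trust: Mapping[str, Trust] = field(default_factory=dict)

    def __post_init__(self) -> None:
        rot = np.asarray(self.rotation, dtype=float)
        tra = np.asarray(self.translation, dtype=float)
        object.__setattr__(self, "rotation", rot)
        object.__setattr__(self, "translation", tra)
        object.__setattr__(
            self, "trust", {k: Trust(v) for k, v in dict(self.trust).items()}
        )
        self.validate()

    def validate(self) -> None:
        rot = self.rotation
        if rot.shape != (3, 3) or self.translation.shape != (3,):
            raise InvalidTransformError("rotation must be 3x3, translation length 3")
        if not np.allclose(rot.T @ rot, np.eye(3), atol=1e-8, rtol=0):
            raise InvalidTransformError("rotation matrix is not orthonormal")
        if np.linalg.det(rot) < 0:
            raise InvalidTransformError("rotation matrix has det = -1 (reflection)")

    @classmethod
    def identity(cls, trust: Mapping[str, Trust] | None = None) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3), trust or {})

    @classmethod
    def from_translation(
        cls, translation, trust: Mapping[str, Trust] | None = None
    ) -> "RigidTransform":
        return cls(np.eye(3), np.asarray(translation, dtype=float), trust or {})

    def apply(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points, dtype=float) @ self.rotation.T + self.translation

    def inverse(self) -> "RigidTransform":
        rot_inv = self.rotation.T
        return RigidTransform(rot_inv, -rot_inv @ self.translation, self.trust)


def _map_to_source_indices(
    source_grid: Grid3D, target: Grid3D, transform: RigidTransform
) -> tuple[np.ndarray, np.ndarray]:
    """Continuous source indices for each target voxel centre + in-extent mask."""
    transform.validate()
    pts = transform.apply(target.voxel_centres())
    idx = source_grid.physical_to_index(pts)
    upper = np.asarray(source_grid.shape, dtype=float) - 1.0
    inside = np.all((idx >= 0.0) & (idx <= upper), axis=1)
    return idx, inside


def resample_dose(
    source: DoseGrid, target: Grid3D, transform: RigidTransform
) -> DoseGrid:
    """Resample a dose grid onto ``target`` through a rigid transform.

    Trilinear interpolation at mapped voxel centres; points falling outside
    the source extent receive 0 Gy and are counted in
    ``out_of_extent_voxels`` on the returned grid (never silently dropped).
    Fraction count, modality and course identity are carried over.
    """
    idx, inside = _map_to_source_indices(source.grid, target, transform)
    vals = ndimage.map_coordinates(
        source.values, idx.T, order=1, mode="constant", cval=0.0
    )
    vals[~inside] = 0.0
    return DoseGrid(
        grid=target,
        values=vals.reshape(target.shape),
        n_fractions=source.n_fractions,
        modality=source.modality,
        course_id=source.course_id,
        treatment_date=source.treatment_date,
        out_of_extent_voxels=int(np.count_nonzero(~inside)),
    )


def resample_mask(
    source: StructureMask, target: Grid3D, transform: RigidTransform
) -> StructureMask:
    """Nearest-neighbour resampling of a boolean mask; outside extent -> False."""
    idx, inside = _map_to_source_indices(source.grid, target, transform)
    nearest = np.round(idx).astype(int)
    nearest_clipped = np.clip(nearest, 0, np.asarray(source.grid.shape) - 1)
    vals = source.values[tuple(nearest_clipped.T)]
    vals = vals & inside
    return StructureMask(
        grid=target,
        values=vals.reshape(target.shape),
        name=source.name,
        organ_class=source.organ_class,
        prv_margin_mm=source.prv_margin_mm,
    )


def expand_prv(mask: StructureMask, margin_mm: float) -> StructureMask:
    """Euclidean dilation of a mask by ``margin_mm`` (planning risk volume).

    A voxel enters the PRV if any set voxel centre lies within ``margin_mm``
    of its own centre; spacing anisotropy is honoured.
    """
    if margin_mm < 0:
        raise ValueError("PRV margin must be >= 0")
    if margin_mm == 0 or mask.is_empty:
        return replace(mask, prv_margin_mm=mask.prv_margin_mm + margin_mm)
    dist = ndimage.distance_transform_edt(
        ~mask.values, sampling=mask.grid.spacing
    )
    return StructureMask(
        grid=mask.grid,
        values=dist <= margin_mm + 1e-9,
        name=mask.name,
        organ_class=mask.organ_class,
        prv_margin_mm=mask.prv_margin_mm + margin_mm,
    )


def overlap_fraction(a: StructureMask, b: StructureMask) -> float:
    """Fraction of ``b``'s volume covered by ``a``: |a AND b| / |b|."""
    if a.grid != b.grid:
        raise ValueError("masks must live on the same grid; resample first")
    n_b = np.count_nonzero(b.values)
    if n_b == 0:
        raise ValueError("overlap fraction undefined for an empty reference mask")
    return float(np.count_nonzero(a.values & b.values)) / float(n_b)
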