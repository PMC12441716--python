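"""Synthetic dose/structure phantoms for self-contained testing and demos.

The phantom emulates the geometry that matters to a reirradiation
feasibility check: a spherical high-dose target receiving the prescription,
an isotropic Gaussian dose falloff away from the target surface (the
controllable stand-in for a treated plan's dose gradient), and analytically
rasterised OARs (sphere, cylinder or slab) placed at a chosen distance so
that overlapping and non-overlapping course pairs can both be constructed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np

from .grid import DoseGrid, Grid3D, Modality, OrganClass, StructureMask

__all__ = ["OARShape", "OARSpec", "PhantomSpec", "generate_phantom"]


class OARShape(str, Enum):
    SPHERE = "sphere"
    CYLINDER = "cylinder"  # axis along z
    SLAB = "slab"


@dataclass(frozen=True)
class OARSpec:
    """Analytic organ geometry. ``size_mm`` meaning depends on the shape:
    sphere -> (radius,); cylinder -> (radius, half_length_z);
    slab -> (half_x, half_y, half_z)."""

    name: str
    shape: OARShape
    centre_mm: tuple[float, float, float]
    size_mm: tuple[float, ...]
    organ_class: OrganClass = OrganClass.OTHER

    def __post_init__(self) -> None:
        object.__setattr__(self, "shape", OARShape(self.shape))
        object.__setattr__(self, "centre_mm", tuple(float(v) for v in self.centre_mm))
        object.__setattr__(self, "size_mm", tuple(float(v) for v in self.size_mm))
        need = {OARShape.SPHERE: 1, OARShape.CYLINDER: 2, OARShape.SLAB: 3}
        if len(self.size_mm) != need[self.shape]:
            raise ValueError(
                f"{self.shape.value} needs {need[self.shape]} size components"
            )
        if any(s <= 0 for s in self.size_mm):
            raise ValueError("geometry dimensions must be > 0")


@dataclass(frozen=True)
class PhantomSpec:
    grid: Grid3D
    target_centre_mm: tuple[float, float, float]
    target_radius_mm: float
    prescription_gy: float
    falloff_sigma_mm: float
    n_fractions: int
    modality: Modality = Modality.EBRT
    oars: tuple[OARSpec, ...] = ()
    target_name: str = "GTV"
    course_id: str = "phantom"
    noise_sigma_gy: float = 0.0  # optional multiplicative-free additive jitter
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "target_centre_mm", tuple(float(v) for v in self.target_centre_mm)
        )
        object.__setattr__(self, "oars", tuple(self.oars))
        object.__setattr__(self, "modality", Modality(self.modality))
        if self.target_radius_mm <= 0:
            raise ValueError("target radius must be > 0")
        if self.falloff_sigma_mm <= 0:
            raise ValueError("falloff length must be > 0")
        if self.prescription_gy <= 0:
            raise ValueError("prescription must be > 0")
        lo = np.asarray(self.grid.origin)
        hi = lo + (np.asarray(self.grid.shape) - 1) * np.asarray(self.grid.spacing)
        centre = np.asarray(self.target_centre_mm)
        if np.any(centre - self.target_radius_mm < lo) or np.any(
            centre + self.target_radius_mm > hi
        ):
            raise ValueError("target sphere extends outside the grid")
        for oar in self.oars:
            c = np.asarray(oar.centre_mm)
            half = _bounding_half_extent(oar)
            if np.any(c - half < lo) or np.any(c + half > hi):
                raise ValueError(f"OAR '{oar.name}' extends outside the grid")


def _bounding_half_extent(oar: OARSpec) -> np.ndarray:
    if oar.shape is OARShape.SPHERE:
        return np.full(3, oar.size_mm[0])
    if oar.shape is OARShape.CYLINDER:
        r, hz = oar.size_mm
        return np.array([r, r, hz])
    return np.asarray(oar.size_mm)


def _rasterise(oar: OARSpec, grid: Grid3D) -> np.ndarray:
    pts = grid.voxel_centres()
    rel = pts - np.asarray(oar.centre_mm)
    if oar.shape is OARShape.SPHERE:
        inside = np.linalg.norm(rel, axis=1) <= oar.size_mm[0]
    elif oar.shape is OARShape.CYLINDER:
        r, hz = oar.size_mm
        inside = (np.linalg.norm(rel[:, :2], axis=1) <= r) & (np.abs(rel[:, 2]) <= hz)
    else:
        inside = np.all(np.abs(rel) <= np.asarray(oar.size_mm), axis=1)
    return inside.reshape(grid.shape)


def generate_phantom(
    spec: PhantomSpec,
) -> tuple[DoseGrid, dict[str, StructureMask]]:
    """Deterministic phantom: (dose grid, {name: mask}) for a fixed spec/seed.

    Dose is the prescription inside the target sphere and falls off as
    ``Rx * exp(-r**2 / (2 * sigma**2))`` with ``r`` the distance beyond the
    target surface. With ``noise_sigma_gy > 0``, seeded Gaussian jitter is
    added and clipped at zero (off by default).
    """
    grid = spec.grid
    pts = grid.voxel_centres()
    r_centre = np.linalg.norm(pts - np.asarray(spec.target_centre_mm), axis=1)
    r_outside = np.maximum(0.0, r_centre - spec.target_radius_mm)
    dose = spec.prescription_gy * np.exp(
        -(r_outside**2) / (2.0 * spec.falloff_sigma_mm**2)
    )
    if spec.noise_sigma_gy > 0:
        rng = np.random.default_rng(spec.seed)
        dose = np.maximum(0.0, dose + rng.normal(0, spec.noise_sigma_gy, dose.shape))
    dose_grid = DoseGrid(
        grid=grid,
        values=dose.reshape(grid.shape),
        n_fractions=spec.n_fractions,
        modality=spec.modality,
        course_id=spec.course_id,
    )
    masks: dict[str, StructureMask] = {
        spec.target_name: StructureMask(
            grid=grid,
            values=(r_centre <= spec.target_radius_mm).reshape(grid.shape),
            name=spec.target_name,
            organ_class=OrganClass.TARGET,
        )
    }
    for oar in spec.oars:
        masks[oar.name] = StructureMask(
            grid=grid,
            values=_rasterise(oar, grid),
            name=oar.name,
            organ_class=oar.organ_class,
        )
    return dose_grid, masks
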