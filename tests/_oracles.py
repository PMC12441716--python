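"""Independent brute-force oracles and random-case builders for the tests.

The oracles deliberately use plain Python loops over explicit voxel lists so
they share no code path with the vectorised implementations they check.
"""

from __future__ import annotations

import numpy as np

from rertkit import (
    DoseGrid,
    Grid3D,
    Modality,
    PriorCourse,
    RigidTransform,
    StructureMask,
)


def oracle_mean(doses: list[float]) -> float:
    return sum(doses) / len(doses)


def oracle_dose_at_volume(
    doses: list[float], voxel_cc: float, volume_cc: float
) -> float:
    """Sort-and-count: walk the descending dose list accumulating volume and
    linearly interpolate between the bracketing voxels."""
    ordered = sorted(doses, reverse=True)
    total = len(ordered) * voxel_cc
    if volume_cc >= total:
        return ordered[-1]
    cum = 0.0
    prev_dose = ordered[0]
    prev_cum = 0.0
    for d in ordered:
        cum += voxel_cc
        if cum >= volume_cc:
            if prev_cum == 0.0:
                # less than one voxel deep: clamp at the hottest voxel
                if volume_cc <= voxel_cc:
                    return ordered[0]
            frac = (volume_cc - prev_cum) / (cum - prev_cum)
            return prev_dose + frac * (d - prev_dose)
        prev_dose = d
        prev_cum = cum
    return ordered[-1]


def oracle_volume_at_dose(doses: list[float], threshold: float) -> float:
    n = sum(1 for d in doses if d >= threshold)
    return 100.0 * n / len(doses)


def random_dose_and_mask(
    rng: np.random.Generator, max_voxels: int = 10_000
) -> tuple[DoseGrid, StructureMask]:
    """A random grid (<= max_voxels), random non-negative dose, random
    nonempty mask."""
    while True:
        shape = tuple(int(v) for v in rng.integers(2, 14, size=3))
        if int(np.prod(shape)) <= max_voxels:
            break
    spacing = tuple(float(v) for v in rng.uniform(0.5, 4.0, size=3))
    grid = Grid3D((0.0, 0.0, 0.0), spacing, shape)
    values = rng.uniform(0, 80, size=shape)
    mask_vals = rng.random(size=shape) < 0.4
    if not mask_vals.any():
        mask_vals.flat[int(rng.integers(0, mask_vals.size))] = True
    dose = DoseGrid(grid, values, n_fractions=int(rng.integers(1, 40)))
    mask = StructureMask(grid, mask_vals, "random")
    return dose, mask


def random_two_course_case(
    rng: np.random.Generator,
) -> tuple[list[PriorCourse], StructureMask]:
    """Two overlapping Gaussian-blob courses on a shared grid with random
    sub-voxel shifts, plus an OAR mask on the reference grid."""
    n = 14
    grid = Grid3D((0.0, 0.0, 0.0), (2.0, 2.0, 2.0), (n, n, n))
    axes = np.arange(n) * 2.0
    xx, yy, zz = np.meshgrid(axes, axes, axes, indexing="ij")

    def blob(centre, peak, sigma):
        r2 = (xx - centre[0]) ** 2 + (yy - centre[1]) ** 2 + (zz - centre[2]) ** 2
        return peak * np.exp(-r2 / (2 * sigma**2))

    courses = []
    for i in range(2):
        centre = rng.uniform(8, 18, size=3)
        dose = DoseGrid(
            grid,
            blob(centre, rng.uniform(20, 60), rng.uniform(4, 9)),
            n_fractions=int(rng.integers(1, 35)),
            modality=Modality.EBRT,
            course_id=f"c{i + 1}",
        )
        shift = rng.uniform(-1.0, 1.0, size=3)  # keeps mask well inside extent
        courses.append(
            PriorCourse(dose, RigidTransform.from_translation(shift))
        )
    centre = rng.uniform(10, 16, size=3)
    radius = rng.uniform(4, 8)
    r2 = (xx - centre[0]) ** 2 + (yy - centre[1]) ** 2 + (zz - centre[2]) ** 2
    mask = StructureMask(grid, r2 <= radius**2, "OAR")
    return courses, mask
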