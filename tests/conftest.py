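import numpy as np
import pytest

from rertkit import DoseGrid, Grid3D, StructureMask


@pytest.fixture
def unit_grid() -> Grid3D:
    """10x10x10 grid, 1 mm isotropic, origin at (0,0,0)."""
    return Grid3D((0.0, 0.0, 0.0), (1.0, 1.0, 1.0), (10, 10, 10))


@pytest.fixture
def ramp_dose(unit_grid) -> DoseGrid:
    """Dose equal to the x index in Gy (the index-shift oracle field)."""
    vals = np.broadcast_to(
        np.arange(10, dtype=float)[:, None, None], (10, 10, 10)
    ).copy()
    return DoseGrid(unit_grid, vals, n_fractions=10, course_id="ramp")


def make_uniform_dose(grid: Grid3D, value: float, n_fractions: int, **kw) -> DoseGrid:
    return DoseGrid(grid, np.full(grid.shape, float(value)), n_fractions, **kw)


def make_full_mask(grid: Grid3D, name: str = "OAR", **kw) -> StructureMask:
    return StructureMask(grid, np.ones(grid.shape, dtype=bool), name, **kw)
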