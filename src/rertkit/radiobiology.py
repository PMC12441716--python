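"""Linear-quadratic EQD2 conversion and the spinal-cord recovery model.

All prior treatment courses are converted to the equieffective dose in 2 Gy
fractions before accumulation::

    EQD2 = D * (d + alpha/beta) / (2 + alpha/beta),   d = D / n

with ``D`` the total (voxel) dose, ``n`` the course's fraction count and
``alpha/beta`` the tissue-specific LQ ratio — 2 Gy for central nervous system
tissue (including spinal cord) and 3 Gy for all other normal tissues. EQD2 is
additive across courses voxel-wise; no time factor is applied except the
optional spinal-cord recovery model.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .grid import DoseGrid, Grid3D, OrganClass, StructureMask

__all__ = [
    "AlphaBetaPolicy",
    "EQD2Grid",
    "CordRecoveryModel",
    "eqd2_scalar",
    "eqd2_grid",
    "assign_alpha_beta",
    "cord_cumulative_tolerance",
]


@dataclass(frozen=True)
class AlphaBetaPolicy:
    """Tissue alpha/beta assignment: CNS 2 Gy, other 3 Gy, per-name overrides."""

    default_cns: float = 2.0
    default_other: float = 3.0
    overrides: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        vals = [self.default_cns, self.default_other, *self.overrides.values()]
        if any(v <= 0 for v in vals):
            raise ValueError("all alpha/beta values must be > 0")
        object.__setattr__(self, "overrides", dict(self.overrides))


@dataclass(frozen=True)
class EQD2Grid:
    """Voxel-wise EQD2 (Gy) on a grid, with the course ids it accumulates."""

    grid: Grid3D
    values: np.ndarray
    component_courses: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "component_courses", tuple(self.component_courses))
        if tuple(values.shape) != self.grid.shape:
            raise ValueError("values shape does not match grid shape")
        if not np.all(np.isfinite(values)) or np.any(values < 0):
            raise ValueError("EQD2 values must be finite and non-negative")


def eqd2_scalar(total_dose: float, n_fractions: int, alpha_beta: float) -> float:
    """EQD2 of ``total_dose`` Gy given in ``n_fractions`` fractions.

    ``D * (D/n + ab) / (2 + ab)``; equals ``D`` exactly at 2 Gy per fraction.
    """
    if alpha_beta <= 0:
        raise ValueError("alpha/beta must be > 0")
    if n_fractions < 1:
        raise ValueError("n_fractions must be >= 1")
    if total_dose < 0:
        raise ValueError("dose must be >= 0")
    d = total_dose / n_fractions
    return total_dose * (d + alpha_beta) / (2.0 + alpha_beta)


def eqd2_grid(dose: DoseGrid, alpha_beta: float) -> EQD2Grid:
    """Voxel-wise EQD2 conversion using the course's nominal fraction count."""
    if alpha_beta <= 0:
        raise ValueError("alpha/beta must be > 0")
    d = dose.values / dose.n_fractions
    values = dose.values * (d + alpha_beta) / (2.0 + alpha_beta)
    return EQD2Grid(
        grid=dose.grid,
        values=values,
        component_courses=(dose.course_id,) if dose.course_id else (),
    )


def assign_alpha_beta(structure: StructureMask, policy: AlphaBetaPolicy) -> float:
    """alpha/beta for a structure: override by name, else class default."""
    if structure.name in policy.overrides:
        return float(policy.overrides[structure.name])
    if structure.organ_class is OrganClass.CNS:
        return policy.default_cns
    return policy.default_other


@dataclass(frozen=True)
class CordRecoveryModel:
    """Partial time-dependent recovery of prior spinal-cord EQD2.

    ``recovery_fraction_by_interval`` maps elapsed months (breakpoints) to the
    fraction of the prior cord EQD2 considered recovered at or beyond that
    interval; the fraction is piecewise constant between breakpoints and 0
    below the first one. The published recovery formula this parameterises is
    not bundled — constants are configuration, with their source recorded in
    ``provenance``. No recovery is applied to any other OAR.
    """

    enabled: bool = False
    recovery_fraction_by_interval: Mapping[float, float] = field(default_factory=dict)
    provenance: str = ""

    def __post_init__(self) -> None:
        table = {float(k): float(v) for k, v in
                 dict(self.recovery_fraction_by_interval).items()}
        object.__setattr__(self, "recovery_fraction_by_interval", table)
        if any(k < 0 for k in table):
            raise ValueError("interval breakpoints must be >= 0 months")
        if any(not 0.0 <= v <= 1.0 for v in table.values()):
            raise ValueError("recovery fractions must lie in [0, 1]")
        keys = sorted(table)
        fracs = [table[k] for k in keys]
        if any(b < a for a, b in zip(fracs, fracs[1:])):
            raise ValueError("recovery fraction must be non-decreasing in interval")

    def recovery_fraction(self, interval_months: float) -> float:
        if interval_months < 0:
            raise ValueError("elapsed interval must be >= 0 months")
        if not self.enabled:
            return 0.0
        frac = 0.0
        for breakpoint_months in sorted(self.recovery_fraction_by_interval):
            if interval_months >= breakpoint_months:
                frac = self.recovery_fraction_by_interval[breakpoint_months]
        return frac


def cord_cumulative_tolerance(
    prior_cord_eqd2: float,
    interval_months: float,
    base_tolerance: float,
    model: CordRecoveryModel,
) -> float:
    """Allowed *new* cord EQD2 after discounting the (partially recovered) prior dose.

    ``max(0, base_tolerance - prior * (1 - recovery_fraction(interval)))``.
    With the model disabled the recovery fraction is 0 (plain subtraction).
    """
    if prior_cord_eqd2 < 0 or base_tolerance < 0:
        raise ValueError("doses must be >= 0")
    effective_prior = prior_cord_eqd2 * (1.0 - model.recovery_fraction(interval_months))
    return max(0.0, base_tolerance - effective_prior)
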