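"""Dose-volume-histogram metrics for OAR tolerance and target-coverage checks.

``DxCC`` follows the "minimum dose to the hottest x cc" convention on the
sorted differential DVH with linear interpolation between bracketing voxels;
``V`` metrics use a closed (>=) threshold. Partial-voxel geometry is not
modelled: a voxel is in a structure iff its mask bit is set.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Union

import numpy as np

from .grid import DoseGrid, StructureMask
from .radiobiology import EQD2Grid

__all__ = [
    "MetricKind",
    "MetricSpec",
    "DoseProvenance",
    "MetricResult",
    "mean_dose",
    "dose_at_volume",
    "dose_at_relative_volume",
    "volume_at_dose",
    "coverage",
    "evaluate_metric",
    "cumulative_dvh_table",
]

AnyDose = Union[DoseGrid, EQD2Grid]


class MetricKind(str, Enum):
    MEAN = "MEAN"
    DOSE_AT_ABS_VOLUME = "DOSE_AT_ABS_VOLUME"  # DxCC [Gy], parameter in cc
    DOSE_AT_REL_VOLUME = "DOSE_AT_REL_VOLUME"  # Dx% [Gy], parameter in %
    VOLUME_AT_DOSE = "VOLUME_AT_DOSE"          # Vx [Gy] -> %, parameter in Gy
    COVERAGE = "COVERAGE"                      # Vx% of Rx -> %, parameter in %


class DoseProvenance(str, Enum):
    MAPPED_3D = "MAPPED_3D"
    CONSERVATIVE_SUM = "CONSERVATIVE_SUM"
    NEW_PLAN_ONLY = "NEW_PLAN_ONLY"


@dataclass(frozen=True)
class MetricSpec:
    """A DVH metric: kind + its defining parameter (cc, %, or Gy)."""

    kind: MetricKind
    parameter: float | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "kind", MetricKind(self.kind))
        if self.kind is MetricKind.MEAN:
            if self.parameter is not None:
                raise ValueError("MEAN takes no parameter")
        else:
            if self.parameter is None or self.parameter <= 0:
                raise ValueError(f"{self.kind.value} requires a positive parameter")
            object.__setattr__(self, "parameter", float(self.parameter))

    @property
    def unit(self) -> str:
        """Unit of the metric *value* ('Gy' for D-metrics, '%' for V-metrics)."""
        if self.kind in (MetricKind.VOLUME_AT_DOSE, MetricKind.COVERAGE):
            return "%"
        return "Gy"

    @property
    def is_dose_metric(self) -> bool:
        return self.unit == "Gy"

    def label(self) -> str:
        if self.kind is MetricKind.MEAN:
            return "Dmean [Gy]"
        if self.kind is MetricKind.DOSE_AT_ABS_VOLUME:
            return f"D{self.parameter:g}cc [Gy]"
        if self.kind is MetricKind.DOSE_AT_REL_VOLUME:
            return f"D{self.parameter:g}%"
        if self.kind is MetricKind.VOLUME_AT_DOSE:
            return f"V{self.parameter:g}Gy [%]"
        return f"V{self.parameter:g}%Rx [%]"


@dataclass(frozen=True)
class MetricResult:
    spec: MetricSpec
    value: float
    structure: str
    dose_provenance: DoseProvenance = DoseProvenance.MAPPED_3D

    def __post_init__(self) -> None:
        if not np.isfinite(self.value) or self.value < 0:
            raise ValueError("metric value must be finite and >= 0")


def _in_mask_doses(dose: AnyDose, mask: StructureMask) -> np.ndarray:
    if dose.grid != mask.grid:
        raise ValueError("dose and mask must share a grid; resample first")
    if mask.is_empty:
        raise ValueError(f"structure '{mask.name}' is empty on this grid")
    return dose.values[mask.values]


def mean_dose(dose: AnyDose, mask: StructureMask) -> float:
    """Mean structure dose (uniform voxels, so the arithmetic mean)."""
    return float(np.mean(_in_mask_doses(dose, mask)))


def dose_at_volume(dose: AnyDose, mask: StructureMask, volume_cc: float) -> float:
    """Minimum dose received by the hottest ``volume_cc`` of the structure.

    Voxel doses are sorted descending; the cumulative-volume curve is
    interpolated linearly between bracketing voxels. If ``volume_cc`` meets
    or exceeds the structure volume, the in-mask minimum dose is returned.
    """
    if volume_cc <= 0:
        raise ValueError("volume_cc must be > 0")
    doses = np.sort(_in_mask_doses(dose, mask))[::-1]
    voxel_cc = mask.grid.voxel_volume_cc
    cum_cc = np.arange(1, doses.size + 1) * voxel_cc
    if volume_cc >= cum_cc[-1]:
        return float(doses[-1])
    # np.interp needs ascending x; clamps to doses[0] for volume <= one voxel
    return float(np.interp(volume_cc, cum_cc, doses))


def dose_at_relative_volume(
    dose: AnyDose, mask: StructureMask, percent: float
) -> float:
    """Dx% — dose to the hottest ``percent`` of the structure volume."""
    if not 0 < percent <= 100:
        raise ValueError("percent must lie in (0, 100]")
    return dose_at_volume(dose, mask, percent / 100.0 * mask.volume_cc)


def volume_at_dose(dose: AnyDose, mask: StructureMask, threshold: float) -> float:
    """Percent of the structure volume receiving >= ``threshold``."""
    doses = _in_mask_doses(dose, mask)
    return 100.0 * float(np.count_nonzero(doses >= threshold)) / doses.size


def coverage(
    dose: DoseGrid,
    target: StructureMask,
    prescription: float,
    percent_of_rx: float,
) -> float:
    """Percent of the target receiving >= ``percent_of_rx``% of the prescription.

    Evaluated on the new course's *physical* dose — the coverage floors are
    prescription-relative plan-quality criteria, not EQD2 tolerances.
    """
    if prescription <= 0:
        raise ValueError("prescription must be > 0")
    if percent_of_rx <= 0:
        raise ValueError("percent_of_rx must be > 0")
    return volume_at_dose(dose, target, percent_of_rx / 100.0 * prescription)


def evaluate_metric(dose: AnyDose, mask: StructureMask, spec: MetricSpec) -> float:
    """Dispatch a :class:`MetricSpec` (COVERAGE is excluded: it needs an Rx)."""
    if spec.kind is MetricKind.MEAN:
        return mean_dose(dose, mask)
    if spec.kind is MetricKind.DOSE_AT_ABS_VOLUME:
        return dose_at_volume(dose, mask, spec.parameter)
    if spec.kind is MetricKind.DOSE_AT_REL_VOLUME:
        return dose_at_relative_volume(dose, mask, spec.parameter)
    if spec.kind is MetricKind.VOLUME_AT_DOSE:
        return volume_at_dose(dose, mask, spec.parameter)
    raise ValueError("COVERAGE requires a prescription; use coverage()")


def cumulative_dvh_table(
    dose: AnyDose, mask: StructureMask, n_bins: int = 100
) -> np.ndarray:
    """Simple cumulative DVH export: (n_bins, 2) array of [dose Gy, volume %]."""
    doses = _in_mask_doses(dose, mask)
    edges = np.linspace(0.0, float(doses.max()) if doses.max() > 0 else 1.0, n_bins)
    vol = [100.0 * np.count_nonzero(doses >= e) / doses.size for e in edges]
    return np.column_stack([edges, vol])
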