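"""Reirradiation feasibility: case classification, EQD2 accumulation, residuals.

A further radiotherapy course is *type 1* reirradiation when a prior course's
high-dose region (an isodose volume, by default half of that course's maximum
dose) geometrically overlaps the new target; *type 2* when there is no overlap
but toxicity is still a concern; everything else is repeat irradiation.

Prior dose is accumulated on the current planning grid by rigid mapping and
voxel-wise EQD2 summation. Where the rigid registration is recorded as
untrustworthy for an OAR, a conservative estimate replaces 3D mapping: the
per-course near-maximum (or mean) EQD2 metric values are summed as if all hot
spots coincided spatially. The tolerance limit minus the accumulated prior
value, floored at zero, is the residual dose allowance available to the new
plan.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Mapping, Sequence

import numpy as np

from .dvh import DoseProvenance, MetricKind, MetricResult, MetricSpec, evaluate_metric
from .grid import (
    DoseGrid,
    Grid3D,
    RigidTransform,
    StructureMask,
    Trust,
    expand_prv,
    resample_dose,
    resample_mask,
)
from .radiobiology import AlphaBetaPolicy, EQD2Grid, assign_alpha_beta, eqd2_grid
from .tolerances import LimitKind, ToleranceEntry

__all__ = [
    "ReRTType",
    "PriorCourse",
    "ResidualAllowance",
    "UnsupportedMetricError",
    "MissingTrustError",
    "classify_rert_type",
    "accumulate_prior_eqd2",
    "conservative_metric_sum",
    "prior_metric",
    "residual_allowance",
]

DEFAULT_OVERLAP_ISODOSE_FRACTION = 0.5


class ReRTType(str, Enum):
    TYPE_1 = "TYPE_1"
    TYPE_2 = "TYPE_2"
    REPEAT = "REPEAT"


class UnsupportedMetricError(ValueError):
    """Metric cannot be combined this way (e.g. summing V-type percentages)."""


class MissingTrustError(KeyError):
    """No registration-trust flag recorded for an OAR.

    Trust must be explicit: the reliability of each rigid registration is
    reviewed and recorded per OAR, and the engine refuses to guess.
    """


@dataclass(frozen=True)
class PriorCourse:
    """One previously delivered course: dose, mapping to the current frame,
    and (optionally) its own structure set."""

    dose: DoseGrid
    transform_to_reference: RigidTransform = field(
        default_factory=RigidTransform.identity
    )
    structures: tuple[StructureMask, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "structures", tuple(self.structures))

    def find_structure(self, name: str) -> StructureMask | None:
        for s in self.structures:
            if s.name == name:
                return s
        return None


@dataclass(frozen=True)
class ResidualAllowance:
    """Remaining EQD2 budget for one OAR metric after prior courses."""

    structure: str
    metric: MetricSpec
    prior_value_eqd2: float
    tolerance_objective: float | None  # None = open / no constraint
    tolerance_variation: float | None
    residual_objective: float | None
    residual_variation: float | None
    provenance: DoseProvenance
    discuss_case_by_case: bool = False


def classify_rert_type(
    prior: Sequence[PriorCourse],
    new_target: StructureMask,
    overlap_isodose_fraction: float = DEFAULT_OVERLAP_ISODOSE_FRACTION,
    toxicity_concern: bool = False,
) -> ReRTType:
    """Classify the retreatment situation.

    A course counts as overlapping when its isodose volume — voxels at or
    above ``overlap_isodose_fraction`` of that course's maximum dose, mapped
    onto the new planning grid — intersects the new target volume.
    """
    if not prior:
        raise ValueError("at least one prior course is required")
    if new_target.is_empty:
        raise ValueError("new target mask is empty")
    if not 0 < overlap_isodose_fraction <= 1:
        raise ValueError("overlap_isodose_fraction must lie in (0, 1]")
    for course in prior:
        source_max = float(course.dose.values.max())
        if source_max <= 0:
            continue
        mapped = resample_dose(
            course.dose, new_target.grid, course.transform_to_reference
        )
        isodose = mapped.values >= overlap_isodose_fraction * source_max
        if bool(np.any(isodose & new_target.values)):
            return ReRTType.TYPE_1
    return ReRTType.TYPE_2 if toxicity_concern else ReRTType.REPEAT


def accumulate_prior_eqd2(
    prior: Sequence[PriorCourse],
    reference: Grid3D,
    policy: AlphaBetaPolicy,
    structure: StructureMask,
) -> EQD2Grid:
    """Voxel-wise EQD2 sum of all prior courses on the reference grid.

    Each course is rigidly mapped onto the reference grid and converted to
    EQD2 with the structure's alpha/beta and that course's own fraction count
    (the LQ correction is course-specific), then summed. An empty course list
    yields a zero grid.
    """
    alpha_beta = assign_alpha_beta(structure, policy)
    total = np.zeros(reference.shape, dtype=float)
    course_ids: list[str] = []
    for course in prior:
        mapped = resample_dose(course.dose, reference, course.transform_to_reference)
        total += eqd2_grid(mapped, alpha_beta).values
        course_ids.append(course.dose.course_id or f"course{len(course_ids) + 1}")
    return EQD2Grid(grid=reference, values=total, component_courses=tuple(course_ids))


def conservative_metric_sum(
    prior: Sequence[PriorCourse],
    structure: StructureMask,
    metric: MetricSpec,
    policy: AlphaBetaPolicy,
) -> float:
    """Worst-case prior estimate: sum of each course's own EQD2 metric value.

    Used when rigid registration is untrustworthy for this OAR — assumes the
    per-course hot spots coincide spatially, so it always bounds the mapped
    3D accumulation from above. Only dose-type metrics (Gy) can be summed
    this way; volume-percentage metrics cannot.

    When a course lacks its own contour for the structure, the current mask
    is mapped back onto that course's grid through the inverse transform and
    expanded by one voxel diagonal — the estimate must err high, and the
    margin absorbs the sub-voxel rounding of the mask mapping.
    """
    if not metric.is_dose_metric:
        raise UnsupportedMetricError(
            f"{metric.label()} is a volume percentage; conservative summation "
            "applies to dose-type metrics only"
        )
    if metric.kind is MetricKind.DOSE_AT_REL_VOLUME:
        # a percentage refers to the organ's volume; pin it to the current
        # structure so mask approximations on prior grids cannot deepen it
        metric = MetricSpec(
            MetricKind.DOSE_AT_ABS_VOLUME,
            metric.parameter / 100.0 * structure.volume_cc,
        )
    total = 0.0
    for course in prior:
        own = course.find_structure(structure.name)
        if own is None:
            own = resample_mask(
                structure,
                course.dose.grid,
                course.transform_to_reference.inverse(),
            )
            if not own.is_empty:
                own = expand_prv(
                    own, float(np.linalg.norm(course.dose.grid.spacing))
                )
            if own.is_empty:
                # structure maps entirely outside this course's grid: the
                # course cannot contribute dose inside it
                continue
        alpha_beta = assign_alpha_beta(structure, policy)
        course_eqd2 = eqd2_grid(course.dose, alpha_beta)
        total += evaluate_metric(course_eqd2, own, metric)
    return total


def prior_metric(
    accumulated: EQD2Grid,
    prior: Sequence[PriorCourse],
    structure: StructureMask,
    metric: MetricSpec,
    trust: Mapping[str, Trust],
    policy: AlphaBetaPolicy,
) -> MetricResult:
    """Prior-dose metric for one OAR, routed by the recorded registration trust.

    TRUSTED -> DVH metric on the 3D-mapped accumulated EQD2 grid;
    UNTRUSTED -> conservative per-course summation. The route taken is
    recorded as the result's dose provenance, mirroring how the type of dose
    accumulation is documented in the patient record.
    """
    if structure.is_empty:
        raise ValueError(f"structure '{structure.name}' is empty")
    if structure.name not in trust:
        raise MissingTrustError(
            f"no registration trust flag recorded for OAR '{structure.name}'"
        )
    if Trust(trust[structure.name]) is Trust.TRUSTED:
        value = evaluate_metric(accumulated, structure, metric)
        provenance = DoseProvenance.MAPPED_3D
    else:
        value = conservative_metric_sum(prior, structure, metric, policy)
        provenance = DoseProvenance.CONSERVATIVE_SUM
    return MetricResult(
        spec=metric, value=value, structure=structure.name,
        dose_provenance=provenance,
    )


def residual_allowance(
    entry: ToleranceEntry, prior: MetricResult
) -> ResidualAllowance:
    """Residual EQD2 allowance: ``max(0, limit - prior)`` per tolerance level.

    Open-ended limits yield an unbounded residual and no-constraint entries a
    non-evaluable one; both are flagged for case-by-case discussion.
    """
    if entry.metric is None or entry.metric != prior.spec:
        raise ValueError(
            f"tolerance entry metric {entry.metric and entry.metric.label()} "
            f"does not match prior result metric {prior.spec.label()}"
        )
    if entry.metric.kind is MetricKind.VOLUME_AT_DOSE:
        raise UnsupportedMetricError(
            "residual allowance is defined for dose-type (Gy) metrics; "
            f"{entry.metric.label()} is a volume percentage"
        )

    def split(limit):
        if limit.kind is LimitKind.VALUE:
            return limit.value, max(0.0, limit.value - prior.value)
        return None, None

    tol_obj, res_obj = split(entry.objective)
    tol_var, res_var = split(entry.variation)
    discuss = (
        entry.objective.kind is not LimitKind.VALUE
        or entry.variation.kind is not LimitKind.VALUE
    )
    return ResidualAllowance(
        structure=entry.structure,
        metric=entry.metric,
        prior_value_eqd2=prior.value,
        tolerance_objective=tol_obj,
        tolerance_variation=tol_var,
        residual_objective=res_obj,
        residual_variation=res_var,
        provenance=prior.dose_provenance,
        discuss_case_by_case=discuss,
    )
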