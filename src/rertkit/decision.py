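"""Hierarchical plan-evaluation cascade and cohort summary reporting.

The decision procedure trades target coverage against cumulative OAR
protection in three levels:

1. **L1** — standard (de novo) OAR constraints are met by the cumulative dose
   at full PTV coverage: plan as for a first course. Only available when a
   standard constraint table is supplied; no de novo limits are bundled.
2. **L2** — reirradiation-specific limits: first the stricter *Objective*
   tolerances at full coverage, then the *Variation* tolerances at full
   coverage, then the Variation tolerances with a coverage-compromised plan
   whose minimum target coverage still reaches the floor (V95% of the
   prescription > 80 % of GTV/CTV/ITV for conventional EBRT; V100% > 80 % of
   the GTV for SBRT/SRS).
3. **L3** — even the compromise fails: the prescription itself must change.

The engine evaluates candidate plans; it never optimises them. The compromise
branch therefore examines a caller-supplied compromised plan (or, absent one,
the original plan at the relaxed coverage floor).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from enum import Enum
from typing import Mapping, Sequence

from .dvh import (
    DoseProvenance,
    MetricKind,
    MetricSpec,
    coverage,
    evaluate_metric,
)
from .feasibility import (
    PriorCourse,
    conservative_metric_sum,
    accumulate_prior_eqd2,
)
from .grid import DoseGrid, Modality, StructureMask, Trust, expand_prv
from .radiobiology import (
    AlphaBetaPolicy,
    CordRecoveryModel,
    EQD2Grid,
    cord_cumulative_tolerance,
    eqd2_grid,
)
from .tolerances import LimitKind, Region, ToleranceEntry, ToleranceTable

__all__ = [
    "DecisionLevel",
    "MetricStatus",
    "CordSettings",
    "DecisionPolicy",
    "MetricEvaluation",
    "DecisionOutcome",
    "evaluate_case",
    "cohort_summary",
    "CohortSummary",
    "round_half_away",
]

_TOL = 1e-9


class DecisionLevel(Enum):
    L1_STANDARD = 1
    L2_OBJECTIVE = 2
    L2_VARIATION = 3
    L2_COMPROMISE = 4
    L3_PRESCRIPTION_CHANGE = 5


class MetricStatus(str, Enum):
    PASS_OBJECTIVE = "PASS_OBJECTIVE"
    PASS_VARIATION = "PASS_VARIATION"
    FAIL = "FAIL"
    NOT_EVALUABLE = "NOT_EVALUABLE"


@dataclass(frozen=True)
class CordSettings:
    """Dynamic spinal-cord tolerance: base cumulative limit + recovery model."""

    base_tolerance_eqd2: float
    interval_months: float
    model: CordRecoveryModel = field(default_factory=CordRecoveryModel)
    structure_name: str = "Spinal Canal"


@dataclass(frozen=True)
class DecisionPolicy:
    """Tables, coverage rules and cord settings driving the cascade."""

    rert_table: ToleranceTable
    standard_table: ToleranceTable | None = None
    alpha_beta_policy: AlphaBetaPolicy = field(default_factory=AlphaBetaPolicy)
    coverage_floor_percent: float = 80.0
    full_coverage_percent: float = 95.0
    coverage_percent_of_rx_ebrt: float = 95.0   # V95% for conventional EBRT
    coverage_percent_of_rx_srs: float = 100.0   # V100% for SBRT/SRS
    cord: CordSettings | None = None

    def __post_init__(self) -> None:
        for v in (self.coverage_floor_percent, self.full_coverage_percent):
            if not 0 < v <= 100:
                raise ValueError("coverage thresholds must lie in (0, 100]")


@dataclass(frozen=True)
class MetricEvaluation:
    """One tolerance-table row evaluated against the cumulative dose."""

    structure: str
    metric: MetricSpec | None
    region: Region
    cumulative_value: float | None      # EQD2 Gy, or % for V-type rows
    limit_objective: float | None
    limit_variation: float | None
    status: MetricStatus
    provenance: DoseProvenance | None = None
    note: str = ""


@dataclass(frozen=True)
class DecisionOutcome:
    level: DecisionLevel
    per_metric: tuple[MetricEvaluation, ...]
    coverage_achieved: float
    coverage_metric_label: str
    ptv_compromised: bool
    discussion_flags: tuple[str, ...] = ()

    @property
    def exit_code(self) -> int:
        """0 = plan acceptable as-is, 2 = coverage compromise, 3 = re-prescribe."""
        if self.level is DecisionLevel.L2_COMPROMISE:
            return 2
        if self.level is DecisionLevel.L3_PRESCRIPTION_CHANGE:
            return 3
        return 0


def combined_trust(prior: Sequence[PriorCourse]) -> dict[str, Trust]:
    """Per-OAR trust across courses: trusted only if trusted in every course."""
    names: set[str] = set()
    for course in prior:
        names.update(course.transform_to_reference.trust)
    out: dict[str, Trust] = {}
    for name in names:
        flags = [
            Trust(course.transform_to_reference.trust[name])
            for course in prior
            if name in course.transform_to_reference.trust
        ]
        complete = len(flags) == len(prior)
        out[name] = (
            Trust.TRUSTED
            if complete and all(f is Trust.TRUSTED for f in flags)
            else Trust.UNTRUSTED
        )
    return out


def _limit_value(limit) -> float | None:
    return limit.value if limit.kind is LimitKind.VALUE else None


def _entry_status(
    value: float, objective: float | None, variation: float | None,
    objective_open: bool, variation_open: bool,
) -> MetricStatus:
    if objective_open or (objective is not None and value <= objective + _TOL):
        return MetricStatus.PASS_OBJECTIVE
    if variation_open or (variation is not None and value <= variation + _TOL):
        return MetricStatus.PASS_VARIATION
    return MetricStatus.FAIL


def _evaluate_table(
    table: ToleranceTable,
    region: Region,
    new_plan: DoseGrid,
    oars: Sequence[StructureMask],
    prior: Sequence[PriorCourse],
    trust: Mapping[str, Trust],
    policy: DecisionPolicy,
) -> tuple[list[MetricEvaluation], list[str]]:
    evaluations: list[MetricEvaluation] = []
    flags: list[str] = []
    oar_by_name = {m.name: m for m in oars}
    for entry in table.entries:
        if entry.region is not Region(region):
            continue
        mask = oar_by_name.get(entry.base_structure)
        if mask is None or mask.is_empty:
            continue
        if entry.prv_margin_mm > 0:
            mask = expand_prv(mask, entry.prv_margin_mm)
        evaluations.append(
            _evaluate_entry(entry, mask, new_plan, prior, trust, policy, flags)
        )
    return evaluations, flags


def _evaluate_entry(
    entry: ToleranceEntry,
    mask: StructureMask,
    new_plan: DoseGrid,
    prior: Sequence[PriorCourse],
    trust: Mapping[str, Trust],
    policy: DecisionPolicy,
    flags: list[str],
) -> MetricEvaluation:
    ab_policy = policy.alpha_beta_policy
    new_eqd2 = eqd2_grid(new_plan, entry.alpha_beta)

    if entry.limits_deferred:
        cord = policy.cord
        if cord is None or entry.base_structure != cord.structure_name:
            flags.append(
                f"{entry.structure}: limits deferred but no dynamic tolerance "
                "configured — discuss case-by-case"
            )
            return MetricEvaluation(
                structure=entry.structure, metric=entry.metric,
                region=entry.region, cumulative_value=None,
                limit_objective=None, limit_variation=None,
                status=MetricStatus.NOT_EVALUABLE,
            )
        # dynamic cord tolerance: allowance for the NEW plan derived from the
        # prior cord dose and the elapsed time
        accumulated = accumulate_prior_eqd2(prior, new_plan.grid, ab_policy, mask)
        trusted = Trust(trust.get(mask.name, Trust.UNTRUSTED)) is Trust.TRUSTED
        if trusted:
            prior_val = evaluate_metric(accumulated, mask, entry.metric)
            provenance = DoseProvenance.MAPPED_3D
        else:
            prior_val = conservative_metric_sum(prior, mask, entry.metric, ab_policy)
            provenance = DoseProvenance.CONSERVATIVE_SUM
        allowed_new = cord_cumulative_tolerance(
            prior_val, cord.interval_months, cord.base_tolerance_eqd2, cord.model
        )
        new_val = evaluate_metric(new_eqd2, mask, entry.metric)
        status = _entry_status(new_val, allowed_new, allowed_new, False, False)
        return MetricEvaluation(
            structure=entry.structure, metric=entry.metric, region=entry.region,
            cumulative_value=new_val, limit_objective=allowed_new,
            limit_variation=allowed_new, status=status, provenance=provenance,
            note="new-plan dose vs time-dependent cord allowance",
        )

    if not entry.is_evaluable:
        flags.append(f"{entry.structure}: no defined constraint — discuss case-by-case")
        return MetricEvaluation(
            structure=entry.structure, metric=entry.metric, region=entry.region,
            cumulative_value=None, limit_objective=None, limit_variation=None,
            status=MetricStatus.NOT_EVALUABLE,
        )

    trusted = Trust(trust.get(mask.name, Trust.UNTRUSTED)) is Trust.TRUSTED
    note = ""
    if entry.metric.kind is MetricKind.VOLUME_AT_DOSE or trusted:
        accumulated = accumulate_prior_eqd2(prior, new_plan.grid, ab_policy, mask)
        cumulative = accumulated.values + new_eqd2.values
        cum_grid = EQD2Grid(grid=new_plan.grid, values=cumulative)
        value = evaluate_metric(cum_grid, mask, entry.metric)
        provenance = DoseProvenance.MAPPED_3D
        if not trusted and entry.metric.kind is MetricKind.VOLUME_AT_DOSE:
            note = (
                "volume metric cannot be conservatively summed; mapped "
                "accumulation used despite untrusted registration"
            )
            flags.append(f"{entry.structure}: {note}")
    else:
        prior_val = conservative_metric_sum(prior, mask, entry.metric, ab_policy)
        value = prior_val + evaluate_metric(new_eqd2, mask, entry.metric)
        provenance = DoseProvenance.CONSERVATIVE_SUM

    obj = _limit_value(entry.objective)
    var = _limit_value(entry.variation)
    obj_open = entry.objective.kind is LimitKind.OPEN
    var_open = entry.variation.kind is LimitKind.OPEN
    status = _entry_status(value, obj, var, obj_open, var_open)
    if var_open and status is MetricStatus.PASS_VARIATION:
        flags.append(
            f"{entry.structure} {entry.metric.label()}: above objective with "
            "open-ended variation — discuss case-by-case"
        )
    return MetricEvaluation(
        structure=entry.structure, metric=entry.metric, region=entry.region,
        cumulative_value=value, limit_objective=obj, limit_variation=var,
        status=status, provenance=provenance, note=note,
    )


_EBRT_TARGET_PREFIXES = ("GTV", "CTV", "ITV")


def _coverage_achieved(
    plan: DoseGrid,
    targets: Sequence[StructureMask],
    policy: DecisionPolicy,
    prescription: float,
) -> tuple[float, str]:
    """Minimum target coverage and the label of the metric used."""
    if plan.modality is Modality.SBRT_SRS:
        pct_rx = policy.coverage_percent_of_rx_srs
        relevant = [t for t in targets if t.name.upper().startswith("GTV")]
        label = f"GTV V{pct_rx:g}%"
    else:
        pct_rx = policy.coverage_percent_of_rx_ebrt
        relevant = [
            t for t in targets if t.name.upper().startswith(_EBRT_TARGET_PREFIXES)
        ]
        label = f"GTV/CTV/ITV V{pct_rx:g}%"
    if not relevant:
        raise ValueError(
            "no coverage-relevant target volume supplied "
            "(GTV/CTV/ITV for EBRT, GTV for SBRT/SRS)"
        )
    return min(coverage(plan, t, prescription, pct_rx) for t in relevant), label


def evaluate_case(
    new_plan: DoseGrid,
    targets: Sequence[StructureMask],
    oars: Sequence[StructureMask],
    prior: Sequence[PriorCourse],
    policy: DecisionPolicy,
    prescription: float,
    region: Region,
    trust: Mapping[str, Trust] | None = None,
    compromised_plan: DoseGrid | None = None,
) -> DecisionOutcome:
    """Run the hierarchical cascade for one candidate (pair of) plan(s).

    ``trust`` defaults to the conjunction of the per-course registration
    trust flags. ``compromised_plan`` is the caller's coverage-compromised
    alternative examined only if the uncompromised plan fails Level 2.
    """
    if prescription is None or prescription <= 0:
        raise ValueError("a positive prescription dose is required")
    if trust is None:
        trust = combined_trust(prior)
    region = Region(region)

    per_metric, flags = _evaluate_table(
        policy.rert_table, region, new_plan, oars, prior, trust, policy
    )
    evaluable = [e for e in per_metric if e.status is not MetricStatus.NOT_EVALUABLE]
    if not evaluable:
        raise ValueError("no evaluable tolerance entries for the supplied OARs")
    for name, flag in trust.items():
        if Trust(flag) is Trust.UNTRUSTED:
            flags.append(f"{name}: registration untrusted — conservative summation")

    cov, cov_label = _coverage_achieved(new_plan, targets, policy, prescription)
    full_cov = cov >= policy.full_coverage_percent - _TOL

    def passes(evals: Sequence[MetricEvaluation], level: MetricStatus) -> bool:
        ok = {MetricStatus.PASS_OBJECTIVE}
        if level is MetricStatus.PASS_VARIATION:
            ok.add(MetricStatus.PASS_VARIATION)
        return all(
            e.status in ok for e in evals
            if e.status is not MetricStatus.NOT_EVALUABLE
        )

    def outcome(level, evals, cov_val, compromised):
        return DecisionOutcome(
            level=level, per_metric=tuple(evals), coverage_achieved=cov_val,
            coverage_metric_label=cov_label, ptv_compromised=compromised,
            discussion_flags=tuple(dict.fromkeys(flags)),
        )

    # Level 1: standard de novo constraints met by the cumulative dose
    if policy.standard_table is not None and full_cov:
        std_eval, std_flags = _evaluate_table(
            policy.standard_table, region, new_plan, oars, prior, trust, policy
        )
        if std_eval and passes(std_eval, MetricStatus.PASS_OBJECTIVE):
            flags.extend(std_flags)
            return outcome(DecisionLevel.L1_STANDARD, per_metric, cov, False)

    # Level 2a/2b: reRT Objective, then Variation, at full coverage
    if full_cov and passes(per_metric, MetricStatus.PASS_OBJECTIVE):
        return outcome(DecisionLevel.L2_OBJECTIVE, per_metric, cov, False)
    if full_cov and passes(per_metric, MetricStatus.PASS_VARIATION):
        return outcome(DecisionLevel.L2_VARIATION, per_metric, cov, False)

    # Level 2c: Variation limits with permitted coverage compromise
    candidate = compromised_plan if compromised_plan is not None else new_plan
    if candidate is not new_plan:
        cand_metrics, cand_flags = _evaluate_table(
            policy.rert_table, region, candidate, oars, prior, trust, policy
        )
        flags.extend(cand_flags)
        cand_cov, _ = _coverage_achieved(candidate, targets, policy, prescription)
    else:
        cand_metrics, cand_cov = per_metric, cov
    if (
        cand_cov >= policy.coverage_floor_percent - _TOL
        and passes(cand_metrics, MetricStatus.PASS_VARIATION)
    ):
        return outcome(DecisionLevel.L2_COMPROMISE, cand_metrics, cand_cov, True)

    # Level 3: prescription must change
    flags.append("variation tolerances unreachable within the permitted "
                 "coverage compromise — modify the prescription")
    return outcome(
        DecisionLevel.L3_PRESCRIPTION_CHANGE, cand_metrics, cand_cov, True
    )


def round_half_away(x: float, ndigits: int = 0) -> float:
    """Round half away from zero (the convention of printed percentages)."""
    q = Decimal(1).scaleb(-ndigits)
    d = Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP)
    return float(d)


@dataclass(frozen=True)
class CohortSummary:
    total: int
    counts_by_kind: Mapping[str, int]
    percent_by_kind: Mapping[str, float]     # integer precision
    rert_type_1_2_count: int
    rert_type_1_2_percent: float             # integer precision
    counts_by_site: Mapping[str, int]
    percent_by_site: Mapping[str, float]     # one-decimal precision


def cohort_summary(
    records: Sequence[tuple[str, str | None]]
) -> CohortSummary:
    """Counts and printed-precision percentages for a cohort of courses.

    ``records`` holds ``(course_kind, site)`` pairs; ``site`` may be None for
    courses outside the reirradiation subgroup. Kind percentages are over all
    courses at integer precision; site percentages are over the courses
    carrying a site, at one decimal. Both use round-half-away-from-zero.
    """
    if not records:
        raise ValueError("cohort is empty")
    total = len(records)
    counts_kind: dict[str, int] = {}
    counts_site: dict[str, int] = {}
    for kind, site in records:
        counts_kind[kind] = counts_kind.get(kind, 0) + 1
        if site is not None:
            counts_site[site] = counts_site.get(site, 0) + 1
    pct_kind = {
        k: round_half_away(100.0 * c / total) for k, c in counts_kind.items()
    }
    n_site = sum(counts_site.values())
    pct_site = {
        s: round_half_away(100.0 * c / n_site, 1) for s, c in counts_site.items()
    }
    rert = sum(
        c for k, c in counts_kind.items()
        if k in ("TYPE_1", "TYPE_2", "RERT_TYPE_1", "RERT_TYPE_2")
    )
    return CohortSummary(
        total=total,
        counts_by_kind=counts_kind,
        percent_by_kind=pct_kind,
        rert_type_1_2_count=rert,
        rert_type_1_2_percent=round_half_away(100.0 * rert / total),
        counts_by_site=counts_site,
        percent_by_site=pct_site,
    )
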