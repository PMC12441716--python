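"""Retreatment classification, EQD2 accumulation, conservative sums, residuals."""

import numpy as np
import pytest

from rertkit import (
    AlphaBetaPolicy,
    DoseGrid,
    DoseProvenance,
    Grid3D,
    MetricKind,
    MetricResult,
    MetricSpec,
    MissingTrustError,
    PriorCourse,
    ReRTType,
    RigidTransform,
    StructureMask,
    Trust,
    UnsupportedMetricError,
    accumulate_prior_eqd2,
    classify_rert_type,
    conservative_metric_sum,
    prior_metric,
    residual_allowance,
)
from rertkit.tolerances import default_table, Region

from conftest import make_full_mask, make_uniform_dose
from _oracles import random_two_course_case

D01CC = MetricSpec(MetricKind.DOSE_AT_ABS_VOLUME, 0.1)


def _sphere_dose(grid, centre, radius, peak):
    pts = grid.voxel_centres()
    r = np.linalg.norm(pts - np.asarray(centre, float), axis=1)
    vals = np.where(r <= radius, peak, 0.0).reshape(grid.shape)
    return vals


@pytest.fixture
def coarse_grid():
    return Grid3D((0, 0, 0), (2.0, 2.0, 2.0), (20, 20, 20))


class TestClassifyRertType:
    def _case(self, coarse_grid, prior_centre, target_centre):
        prior_dose = DoseGrid(
            coarse_grid, _sphere_dose(coarse_grid, prior_centre, 8, 60.0), 30,
            course_id="c1",
        )
        target = StructureMask(
            coarse_grid,
            _sphere_dose(coarse_grid, target_centre, 6, 1.0) > 0,
            "GTV", "TARGET",
        )
        return [PriorCourse(prior_dose)], target

    def test_overlapping_high_dose_is_type_1(self, coarse_grid):
        prior, target = self._case(coarse_grid, (16, 16, 16), (20, 20, 20))
        assert classify_rert_type(prior, target) is ReRTType.TYPE_1

    def test_disjoint_with_concern_is_type_2(self, coarse_grid):
        prior, target = self._case(coarse_grid, (10, 10, 10), (30, 30, 30))
        assert (
            classify_rert_type(prior, target, toxicity_concern=True)
            is ReRTType.TYPE_2
        )

    def test_disjoint_without_concern_is_repeat(self, coarse_grid):
        prior, target = self._case(coarse_grid, (10, 10, 10), (30, 30, 30))
        assert classify_rert_type(prior, target) is ReRTType.REPEAT

    def test_monotone_in_isodose_fraction(self, coarse_grid):
        # lowering the isodose fraction enlarges the overlap volume, so a
        # TYPE_1 call can never revert to TYPE_2/REPEAT
        prior, target = self._case(coarse_grid, (14, 14, 14), (24, 24, 24))
        was_type1 = False
        for frac in (0.9, 0.7, 0.5, 0.3, 0.1):
            outcome = classify_rert_type(prior, target, overlap_isodose_fraction=frac)
            if was_type1:
                assert outcome is ReRTType.TYPE_1
            was_type1 = was_type1 or outcome is ReRTType.TYPE_1

    def test_empty_target_rejected(self, coarse_grid):
        prior, _ = self._case(coarse_grid, (10, 10, 10), (30, 30, 30))
        empty = StructureMask(
            coarse_grid, np.zeros(coarse_grid.shape, bool), "GTV", "TARGET"
        )
        with pytest.raises(ValueError):
            classify_rert_type(prior, empty)


class TestAccumulatePriorEqd2:
    def test_no_courses_gives_zero_grid(self, unit_grid):
        mask = make_full_mask(unit_grid)
        acc = accumulate_prior_eqd2([], unit_grid, AlphaBetaPolicy(), mask)
        assert np.all(acc.values == 0.0)

    def test_two_uniform_courses_sum_in_eqd2(self, unit_grid):
        # 60 Gy / 30 fx -> 60 EQD2; 20 Gy / 5 fx at a/b 3 -> 20*(4+3)/5 = 28
        prior = [
            PriorCourse(make_uniform_dose(unit_grid, 60.0, 30, course_id="a")),
            PriorCourse(make_uniform_dose(unit_grid, 20.0, 5, course_id="b")),
        ]
        mask = make_full_mask(unit_grid)
        acc = accumulate_prior_eqd2(prior, unit_grid, AlphaBetaPolicy(), mask)
        np.testing.assert_allclose(acc.values, 88.0)
        assert acc.component_courses == ("a", "b")

    def test_order_invariance_and_zero_course_identity(self, unit_grid):
        rng = np.random.default_rng(21)
        c1 = PriorCourse(DoseGrid(unit_grid, rng.uniform(0, 50, (10,) * 3), 20))
        c2 = PriorCourse(DoseGrid(unit_grid, rng.uniform(0, 30, (10,) * 3), 4))
        zero = PriorCourse(make_uniform_dose(unit_grid, 0.0, 1))
        mask = make_full_mask(unit_grid)
        ab = AlphaBetaPolicy()
        forward = accumulate_prior_eqd2([c1, c2], unit_grid, ab, mask)
        reverse = accumulate_prior_eqd2([c2, c1], unit_grid, ab, mask)
        padded = accumulate_prior_eqd2([c1, zero, c2], unit_grid, ab, mask)
        np.testing.assert_allclose(forward.values, reverse.values)
        np.testing.assert_allclose(forward.values, padded.values)


class TestConservativeMetricSum:
    def test_sums_per_course_values(self, unit_grid):
        # uniform 40 and 30 EQD2 courses (2 Gy/fx): D0.1cc sums to 70
        prior = [
            PriorCourse(make_uniform_dose(unit_grid, 40.0, 20)),
            PriorCourse(make_uniform_dose(unit_grid, 30.0, 15)),
        ]
        mask = make_full_mask(unit_grid)
        total = conservative_metric_sum(prior, mask, D01CC, AlphaBetaPolicy())
        assert total == pytest.approx(70.0)

    def test_single_course_is_its_own_value(self, unit_grid):
        prior = [PriorCourse(make_uniform_dose(unit_grid, 40.0, 5))]
        mask = make_full_mask(unit_grid)
        total = conservative_metric_sum(prior, mask, D01CC, AlphaBetaPolicy())
        assert total == pytest.approx(88.0)  # 40*(8+3)/5

    def test_uses_course_own_structures_when_present(self, unit_grid):
        vals = np.zeros((10, 10, 10))
        vals[0] = 50.0
        own = StructureMask(unit_grid, vals > 0, "OAR")
        course = PriorCourse(
            DoseGrid(unit_grid, vals, 25), structures=(own,)
        )
        current = make_full_mask(unit_grid, "OAR")
        total = conservative_metric_sum([course], current, D01CC, AlphaBetaPolicy())
        assert total == pytest.approx(50.0)

    def test_volume_metric_rejected(self, unit_grid):
        prior = [PriorCourse(make_uniform_dose(unit_grid, 40.0, 20))]
        v20 = MetricSpec(MetricKind.VOLUME_AT_DOSE, 20)
        with pytest.raises(UnsupportedMetricError):
            conservative_metric_sum(prior, make_full_mask(unit_grid), v20,
                                    AlphaBetaPolicy())

    @pytest.mark.parametrize("seed", range(8))
    def test_bounds_mapped_accumulation_from_above(self, seed):
        # near-maximum hot spots assumed coincident, so the per-course sum
        # dominates 3D mapping (the property the manual estimate relies on)
        from rertkit import evaluate_metric

        rng = np.random.default_rng(500 + seed)
        courses, mask = random_two_course_case(rng)
        policy = AlphaBetaPolicy()
        acc = accumulate_prior_eqd2(courses, mask.grid, policy, mask)
        for metric in (MetricSpec(MetricKind.DOSE_AT_ABS_VOLUME, 0.03),
                       D01CC,
                       MetricSpec(MetricKind.DOSE_AT_REL_VOLUME, 2)):
            mapped = evaluate_metric(acc, mask, metric)
            conservative = conservative_metric_sum(courses, mask, metric, policy)
            assert conservative >= mapped - 1e-6

    def test_mean_is_exactly_additive_under_identity_registration(self, unit_grid):
        # the mean is additive, so with aligned anatomy the conservative sum
        # coincides with (and hence bounds) the mapped value
        from rertkit import evaluate_metric

        rng = np.random.default_rng(99)
        courses = [
            PriorCourse(DoseGrid(unit_grid, rng.uniform(0, 60, (10,) * 3), 30)),
            PriorCourse(DoseGrid(unit_grid, rng.uniform(0, 40, (10,) * 3), 8)),
        ]
        mask = make_full_mask(unit_grid)
        policy = AlphaBetaPolicy()
        acc = accumulate_prior_eqd2(courses, unit_grid, policy, mask)
        mean_spec = MetricSpec(MetricKind.MEAN)
        mapped = evaluate_metric(acc, mask, mean_spec)
        conservative = conservative_metric_sum(courses, mask, mean_spec, policy)
        assert conservative == pytest.approx(mapped, rel=1e-12)


class TestPriorMetric:
    def test_trusted_routes_to_mapped_3d(self, unit_grid):
        prior = [PriorCourse(make_uniform_dose(unit_grid, 50.0, 25))]
        mask = make_full_mask(unit_grid, "Esophagus")
        acc = accumulate_prior_eqd2(prior, unit_grid, AlphaBetaPolicy(), mask)
        result = prior_metric(
            acc, prior, mask, D01CC, {"Esophagus": Trust.TRUSTED}, AlphaBetaPolicy()
        )
        assert result.value == pytest.approx(50.0)
        assert result.dose_provenance is DoseProvenance.MAPPED_3D

    def test_untrusted_routes_to_conservative_sum(self, unit_grid):
        prior = [
            PriorCourse(make_uniform_dose(unit_grid, 40.0, 20)),
            PriorCourse(make_uniform_dose(unit_grid, 30.0, 15)),
        ]
        mask = make_full_mask(unit_grid, "Esophagus")
        acc = accumulate_prior_eqd2(prior, unit_grid, AlphaBetaPolicy(), mask)
        result = prior_metric(
            acc, prior, mask, D01CC, {"Esophagus": Trust.UNTRUSTED},
            AlphaBetaPolicy(),
        )
        assert result.value == pytest.approx(70.0)
        assert result.dose_provenance is DoseProvenance.CONSERVATIVE_SUM

    def test_missing_trust_flag_is_an_error(self, unit_grid):
        prior = [PriorCourse(make_uniform_dose(unit_grid, 40.0, 20))]
        mask = make_full_mask(unit_grid, "Esophagus")
        acc = accumulate_prior_eqd2(prior, unit_grid, AlphaBetaPolicy(), mask)
        with pytest.raises(MissingTrustError):
            prior_metric(acc, prior, mask, D01CC, {}, AlphaBetaPolicy())


class TestResidualAllowance:
    def _entry(self, structure="Brachial Plexus", region=Region.THORAX):
        entries = default_table().lookup(structure, region)
        return [e for e in entries if e.metric.parameter == 0.03][0]

    def test_subtraction(self):
        entry = self._entry()  # objective 90, variation 110
        prior = MetricResult(entry.metric, 60.0, entry.structure)
        res = residual_allowance(entry, prior)
        assert res.residual_objective == pytest.approx(30.0)
        assert res.residual_variation == pytest.approx(50.0)
        assert res.residual_objective <= res.residual_variation

    def test_floored_at_zero_when_exhausted(self):
        entry = self._entry()
        prior = MetricResult(entry.metric, 120.0, entry.structure)
        res = residual_allowance(entry, prior)
        assert res.residual_objective == 0.0
        assert res.residual_variation == 0.0

    def test_open_variation_is_unbounded_and_flagged(self):
        (entry,) = default_table().lookup("Great Vessels", Region.THORAX)
        prior = MetricResult(entry.metric, 100.0, entry.structure)
        res = residual_allowance(entry, prior)
        assert res.residual_objective == pytest.approx(20.0)
        assert res.residual_variation is None  # open-ended
        assert res.discuss_case_by_case

    def test_metric_mismatch_rejected(self):
        entry = self._entry()
        wrong = MetricResult(MetricSpec(MetricKind.MEAN), 10.0, entry.structure)
        with pytest.raises(ValueError):
            residual_allowance(entry, wrong)
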