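"""Habit classification: decision boundary, Mahalanobis distance, margin refit."""

import numpy as np
import pandas as pd
import pytest

from empdcc.classify import (
    Habit,
    MahalanobisReference,
    classify_boundary,
    classify_boundary_ar5,
    classify_mahalanobis,
    fit_linear_boundary,
    mahalanobis_distance,
)
from empdcc.fixtures import dataset_table, testing_sets as reference_testing_sets
from empdcc.metrics import DomainError
from empdcc.population import summarize


class TestBoundary:
    @pytest.mark.parametrize(
        "cf, pi, expected",
        [
            (0.459, 0.29, Habit.ASBESTIFORM),  # lowest-margin asbestiform reference set
            (0.000, 0.77, Habit.NON_ASBESTIFORM),
            (0.25, 0.40, Habit.UNDETERMINED),  # first mixed-sample rectangle
            (0.15, 0.45, Habit.UNDETERMINED),  # second rectangle
            (0.15, 0.33, Habit.NON_ASBESTIFORM),  # outside both rectangles
        ],
    )
    def test_rules(self, cf, pi, expected):
        assert classify_boundary(cf, pi).label is expected

    def test_mixed_rules_off_collapses_to_two_classes(self):
        assert classify_boundary(0.25, 0.40, mixed_rules=False).label is Habit.NON_ASBESTIFORM

    def test_boundary_inclusive(self):
        pi = 0.2
        assert classify_boundary(0.58 * pi + 0.12, pi).label is Habit.ASBESTIFORM

    def test_out_of_range_inputs(self):
        with pytest.raises(DomainError):
            classify_boundary(1.2, 0.0)
        with pytest.raises(DomainError):
            classify_boundary(0.5, -1.5)

    def test_reproduces_all_reference_labels(self):
        for _, row in dataset_table().iterrows():
            call = classify_boundary(row["criteria_fraction"], row["pearson_index"])
            assert call.label.value == row["habit_aposteriori"], row["dataset"]


class TestBoundaryAr5:
    @pytest.mark.parametrize(
        "cf, pi, expected",
        [
            (0.35, 0.40, Habit.ASBESTIFORM),  # threshold 0.30
            (0.0, 0.30, Habit.ASBESTIFORM),  # negative threshold
            (0.5, 0.45, Habit.NON_ASBESTIFORM),  # threshold 0.59
        ],
    )
    def test_examples(self, cf, pi, expected):
        assert classify_boundary_ar5(cf, pi).label is expected


class TestMahalanobis:
    def make_ref(self, centroid, cov, n=100):
        return MahalanobisReference(np.array(centroid, float), np.array(cov, float), n)

    def test_zero_distance_at_reference_centroid(self):
        ref = self.make_ref([10, 0.4], [[4, 0], [0, 0.25]])
        sample = self.make_ref([10, 0.4], [[4, 0], [0, 0.25]])
        assert mahalanobis_distance(sample, ref) == pytest.approx(0.0)

    def test_identity_covariance_unit_shift(self):
        ref = self.make_ref([0, 0], [[1, 0], [0, 1]])
        sample = self.make_ref([1, 0], [[1, 0], [0, 1]])
        assert mahalanobis_distance(sample, ref) == pytest.approx(1.0)

    def test_hand_computed_two_by_two(self):
        # sqrt(2^2/4 + 0.9^2/0.25) with equal group covariances
        ref = self.make_ref([8, 1.3], [[4, 0], [0, 0.25]])
        sample = self.make_ref([10, 0.4], [[4, 0], [0, 0.25]])
        assert mahalanobis_distance(sample, ref) == pytest.approx(2.0591, abs=1e-3)

    def test_tie_is_undetermined(self):
        a = self.make_ref([0, 0], [[1, 0], [0, 1]])
        b = self.make_ref([2, 0], [[1, 0], [0, 1]])
        sample = self.make_ref([1, 0], [[1, 0], [0, 1]])
        call = classify_mahalanobis(sample, a, b)
        assert call.label is Habit.UNDETERMINED

    def test_positive_definite_required(self):
        with pytest.raises(ValueError):
            self.make_ref([0, 0], [[1, 2], [2, 1]])

    def test_synthetic_non_asbestiform_population_classified(self):
        from dataclasses import replace

        from empdcc.synthetic import (
            ASBESTIFORM_DEFAULT,
            NON_ASBESTIFORM_DEFAULT,
            generate_population,
        )

        sample = generate_population(replace(NON_ASBESTIFORM_DEFAULT, n=300, seed=7))
        ref_asb = MahalanobisReference.from_particles(
            generate_population(replace(ASBESTIFORM_DEFAULT, n=2000, seed=11))
        )
        ref_non = MahalanobisReference.from_particles(
            generate_population(replace(NON_ASBESTIFORM_DEFAULT, n=2000, seed=12))
        )
        assert classify_mahalanobis(sample, ref_asb, ref_non).label is Habit.NON_ASBESTIFORM


class TestMahalanobisOnReferencePopulations:
    def _loo_reference(self, table5_pops, habit, exclude):
        t = reference_testing_sets()
        names = t.loc[t["habit_apriori"] == habit, "dataset"]
        pool = pd.concat([table5_pops[n] for n in names if n != exclude], ignore_index=True)
        return MahalanobisReference.from_particles(pool)

    def test_at_most_one_testing_set_misclassified(self, table5_pops):
        t = reference_testing_sets()
        mis = 0
        boundary_agree = 0
        for _, row in t.iterrows():
            name, habit = row["dataset"], row["habit_apriori"]
            ref_asb = self._loo_reference(table5_pops, "asbestiform", name)
            ref_non = self._loo_reference(table5_pops, "non_asbestiform", name)
            call = classify_mahalanobis(table5_pops[name], ref_asb, ref_non)
            mis += call.label.value != habit
            s = summarize(table5_pops[name])
            bcall = classify_boundary(s.criteria_fraction, s.pearson_index)
            boundary_agree += bcall.label is call.label
        assert mis <= 1
        assert boundary_agree >= 14


class TestFitLinearBoundary:
    def test_symmetric_toy_recovers_flat_midline(self):
        pts = [(0.2, 0.8), (0.6, 0.8), (0.2, 0.2), (0.6, 0.2)]
        fit = fit_linear_boundary(pts, [1, 1, 0, 0])
        assert fit.slope == pytest.approx(0.0, abs=1e-6)
        assert fit.intercept == pytest.approx(0.5, abs=1e-6)
        assert fit.n_misclassified == 0

    def test_reference_points_separated_with_zero_error(self):
        t = reference_testing_sets()
        pts = t[["pearson_index", "criteria_fraction"]].values
        labels = (t["habit_apriori"] == "asbestiform").values
        fit = fit_linear_boundary(pts, labels)
        assert fit.n_misclassified == 0
        # refit agrees with the fixed published boundary on every point
        for (pi, cf), asb in zip(pts, labels):
            refit_call = cf >= fit.slope * pi + fit.intercept
            fixed_call = classify_boundary(cf, pi).label is Habit.ASBESTIFORM
            assert refit_call == fixed_call == asb

    def test_non_separable_flags_violations(self):
        # asbestiform points generally above but interleaved with the other class
        pts = [(0.1, 0.30), (0.2, 0.70), (0.15, 0.40), (0.25, 0.20)]
        fit = fit_linear_boundary(pts, [1, 1, 0, 0])
        assert fit.n_margin_violations >= 1

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            fit_linear_boundary([(0.1, 0.2), (0.2, 0.3)], [1, 1])
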