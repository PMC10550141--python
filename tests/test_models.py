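"""Forward models (true / apparent matrices), transition points, and the
bias-correction inversion."""

import math

import pytest
from hypothesis import given
from hypothesis import strategies as st

from refbias.confusion import MetricSet, is_undefined, prevalence_of
from refbias.models import (
    ClassifierProfile,
    ReferenceProfile,
    apparent_matrix,
    apparent_matrix_correlated,
    apparent_matrix_independent,
    apparent_prevalence,
    correct_independent,
    transition_prevalence,
    true_matrix,
)

GOOD = ClassifierProfile(0.8, 0.8)
REF90_IND = ReferenceProfile(0.9, 0.9, "independent")
REF90_CORR = ReferenceProfile(0.9, 0.9, "correlated")

probs_open = st.floats(min_value=0.01, max_value=0.99, allow_nan=False)
rates = st.floats(min_value=0.05, max_value=0.95, allow_nan=False)


class TestTrueMatrix:
    def test_good_classifier_at_low_prevalence(self):
        m = true_matrix(0.1, GOOD)
        assert m.cells == pytest.approx((0.08, 0.18, 0.02, 0.72))

    def test_perfect_classifier_is_diagonal(self):
        m = true_matrix(0.5, ClassifierProfile(1.0, 1.0))
        assert m.cells == pytest.approx((0.5, 0.0, 0.0, 0.5))

    def test_asymmetric_profile(self):
        m = true_matrix(0.3, ClassifierProfile(0.9, 0.7))
        assert m.cells == pytest.approx((0.27, 0.21, 0.03, 0.49))
        assert m.n == pytest.approx(1.0)

    @pytest.mark.parametrize("p", [0.0, 1.0, -0.1, 1.5])
    def test_prevalence_endpoints_rejected(self, p):
        with pytest.raises(ValueError):
            true_matrix(p, GOOD)

    @given(p=probs_open, r=rates, s=rates)
    def test_gold_reference_recovers_generating_profile_at_any_prevalence(
        self, p, r, s
    ):
        clf = ClassifierProfile(r, s)
        ms = MetricSet.from_matrix(true_matrix(p, clf))
        assert ms.recall == pytest.approx(r, abs=1e-12)
        assert ms.specificity == pytest.approx(s, abs=1e-12)
        assert prevalence_of(true_matrix(p, clf)) == pytest.approx(p, abs=1e-12)


class TestIndependentModel:
    def test_reproduces_worked_apparent_matrix(self):
        m = apparent_matrix_independent(0.1, GOOD, REF90_IND).scaled(1000)
        assert m.cells == pytest.approx((90, 170, 90, 650))

    def test_gold_reference_reduces_to_true_matrix(self):
        gold = ReferenceProfile.gold()
        for p in (0.05, 0.3, 0.7):
            assert apparent_matrix_independent(p, GOOD, gold).cells == pytest.approx(
                true_matrix(p, GOOD).cells
            )

    def test_rejects_correlated_profile(self):
        with pytest.raises(ValueError):
            apparent_matrix_independent(0.1, GOOD, REF90_CORR)

    @given(p=probs_open, rc=rates, sc=rates, rr=rates, sr=rates)
    def test_row_marginals_conserved_and_cells_normalised(self, p, rc, sc, rr, sr):
        clf = ClassifierProfile(rc, sc)
        ref = ReferenceProfile(rr, sr, "independent")
        t = true_matrix(p, clf)
        a = apparent_matrix_independent(p, clf, ref)
        assert a.tp + a.fp == pytest.approx(t.tp + t.fp, abs=1e-12)
        assert a.fn + a.tn == pytest.approx(t.fn + t.tn, abs=1e-12)
        assert a.n == pytest.approx(1.0, abs=1e-12)
        assert all(c >= 0 for c in a.cells)


class TestCorrelatedModel:
    def test_reproduces_worked_apparent_matrix(self):
        m = apparent_matrix_correlated(0.1, GOOD, REF90_CORR).scaled(1000)
        assert m.cells == pytest.approx((170, 90, 10, 730))

    def test_balanced_prevalence_with_18pct_reference(self):
        ref = ReferenceProfile(0.82, 0.82, "correlated")
        m = apparent_matrix_correlated(0.5, GOOD, ref)
        assert m.cells == pytest.approx((0.49, 0.01, 0.01, 0.49))
        assert MetricSet.from_matrix(m).mcc == pytest.approx(0.96)

    def test_gold_reference_reduces_to_true_matrix(self):
        m = apparent_matrix_correlated(0.3, GOOD, ReferenceProfile.gold())
        assert m.cells == pytest.approx(true_matrix(0.3, GOOD).cells)

    def test_infeasible_parameters_name_the_violated_inequality(self):
        weak_ref = ReferenceProfile(0.6, 0.9, "correlated")
        with pytest.raises(ValueError, match="recall"):
            apparent_matrix_correlated(0.1, GOOD, weak_ref)

    @given(p=probs_open, rc=rates, sc=rates, dr=rates, ds=rates)
    def test_column_marginals_match_independent_model(self, p, rc, sc, dr, ds):
        # reference at least as accurate per class, inside the feasible region
        rr = rc + (1 - rc) * dr
        sr = sc + (1 - sc) * ds
        clf = ClassifierProfile(rc, sc)
        corr = apparent_matrix_correlated(
            p, clf, ReferenceProfile(rr, sr, "correlated")
        )
        ind = apparent_matrix_independent(
            p, clf, ReferenceProfile(rr, sr, "independent")
        )
        assert corr.tp + corr.fn == pytest.approx(ind.tp + ind.fn, abs=1e-12)
        assert corr.n == pytest.approx(1.0, abs=1e-12)
        t = true_matrix(p, clf)
        assert corr.tp + corr.fp == pytest.approx(t.tp + t.fp, abs=1e-12)


class TestApparentPrevalence:
    def test_worked_example(self):
        assert apparent_prevalence(0.1, REF90_IND) == pytest.approx(0.18)

    def test_gold_reference_is_identity(self):
        assert apparent_prevalence(0.37, ReferenceProfile.gold()) == pytest.approx(0.37)

    def test_rare_class_with_18pct_error_inflates_over_18x(self):
        ref = ReferenceProfile(0.82, 0.82, "independent")
        ap = apparent_prevalence(0.01, ref)
        assert ap == pytest.approx(0.1864)
        assert ap / 0.01 > 18

    @given(p=probs_open, rr=rates, sr=rates)
    def test_equals_matrix_prevalence_under_both_structures(self, p, rr, sr):
        ap = apparent_prevalence(p, ReferenceProfile(rr, sr, "independent"))
        m = apparent_matrix_independent(
            p, GOOD, ReferenceProfile(rr, sr, "independent")
        )
        assert prevalence_of(m) == pytest.approx(ap, abs=1e-12)


class TestTransitionPrevalence:
    def test_symmetric_reference_transitions_at_midpoint(self):
        assert transition_prevalence(REF90_IND, "precision") == pytest.approx(0.5)

    def test_asymmetric_reference(self):
        ref = ReferenceProfile(0.95, 0.85, "independent")
        assert transition_prevalence(ref, "precision") == pytest.approx(0.75)
        assert transition_prevalence(ref, "npv") == pytest.approx(0.25)

    def test_precision_transition_is_sign_change_when_classifier_uninformative(self):
        # the classical expression marks the exact precision crossing
        # when recall_C + spec_C = 1 (here a coin-tossing classifier)
        coin = ClassifierProfile(0.5, 0.5)
        ref = ReferenceProfile(0.95, 0.85, "independent")
        pstar = transition_prevalence(ref, "precision")
        assert pstar == pytest.approx(0.75)
        for eps in (0.05, 0.01):
            lo = MetricSet.from_matrix(apparent_matrix_independent(pstar - eps, coin, ref))
            hi = MetricSet.from_matrix(apparent_matrix_independent(pstar + eps, coin, ref))
            true_lo = MetricSet.from_matrix(true_matrix(pstar - eps, coin))
            true_hi = MetricSet.from_matrix(true_matrix(pstar + eps, coin))
            assert (lo.precision - true_lo.precision) * (hi.precision - true_hi.precision) < 0

    def test_exact_precision_crossing_depends_on_classifier(self):
        # for the 0.8/0.8 classifier vs a symmetric 0.9/0.9 reference the
        # true crossing sits at p/(1-p) = (1-s_R)(1-s_C)/(r_C(1-r_R)) -> p=0.2
        ref = ReferenceProfile(0.9, 0.9, "independent")
        for p, sign in ((0.15, 1), (0.25, -1)):
            app = MetricSet.from_matrix(apparent_matrix_independent(p, GOOD, ref))
            tru = MetricSet.from_matrix(true_matrix(p, GOOD))
            assert sign * (app.precision - tru.precision) > 0
        at = MetricSet.from_matrix(apparent_matrix_independent(0.2, GOOD, ref))
        tr = MetricSet.from_matrix(true_matrix(0.2, GOOD))
        assert at.precision == pytest.approx(tr.precision, abs=1e-12)

    def test_prevalence_transition_is_fixed_point(self):
        pstar = transition_prevalence(REF90_IND, "prevalence")
        assert pstar == pytest.approx(0.5)
        assert apparent_prevalence(pstar, REF90_IND) == pytest.approx(pstar)

    def test_gold_reference_has_no_transition(self):
        with pytest.raises(ValueError):
            transition_prevalence(ReferenceProfile.gold(), "precision")

    def test_unknown_quantity_rejected(self):
        with pytest.raises(ValueError):
            transition_prevalence(REF90_IND, "mcc")


class TestCorrection:
    def test_recovers_worked_example(self):
        from refbias.confusion import ConfusionMatrix

        res = correct_independent(ConfusionMatrix(90, 170, 90, 650), REF90_IND)
        assert res.prevalence == pytest.approx(0.1, abs=1e-12)
        assert res.recall == pytest.approx(0.8, abs=1e-12)
        assert res.specificity == pytest.approx(0.8, abs=1e-12)
        assert not res.flagged

    def test_gold_reference_returns_apparent_rates(self):
        from refbias.confusion import ConfusionMatrix

        m = ConfusionMatrix(80, 180, 20, 720)
        res = correct_independent(m, ReferenceProfile.gold())
        ms = MetricSet.from_matrix(m)
        assert res.prevalence == pytest.approx(ms.prevalence)
        assert res.recall == pytest.approx(ms.recall)
        assert res.specificity == pytest.approx(ms.specificity)

    def test_boundary_prevalence_flags_indeterminate_recall(self):
        # apparent prevalence exactly 1 - spec_R: recovered p = 0, recall 0/0
        ref = ReferenceProfile(0.82, 0.82, "independent")
        m = apparent_matrix_independent(1e-9, GOOD, ref)  # p -> 0 limit
        res = correct_independent(m, ref)
        assert res.prevalence == pytest.approx(0.0, abs=1e-6)

    def test_inconsistent_matrix_is_clamped_and_flagged(self):
        from refbias.confusion import ConfusionMatrix

        # apparent prevalence below 1 - spec_R: impossible under this reference
        ref = ReferenceProfile(0.82, 0.82, "independent")
        res = correct_independent(ConfusionMatrix(5, 95, 5, 895), ref)
        assert res.flagged
        assert 0.0 <= res.prevalence <= 1.0

    def test_uninformative_reference_is_singular(self):
        from refbias.confusion import ConfusionMatrix

        with pytest.raises(ValueError):
            correct_independent(
                ConfusionMatrix(1, 1, 1, 1), ReferenceProfile(0.3, 0.7, "independent")
            )

    @given(p=probs_open, rc=rates, sc=rates)
    def test_round_trip_identity_over_lattice(self, p, rc, sc):
        clf = ClassifierProfile(rc, sc)
        for ref in (
            ReferenceProfile(0.98, 0.98, "independent"),
            ReferenceProfile(0.9, 0.9, "independent"),
            ReferenceProfile(0.82, 0.82, "independent"),
            ReferenceProfile(0.95, 0.85, "independent"),
        ):
            res = correct_independent(apparent_matrix_independent(p, clf, ref), ref)
            assert res.prevalence == pytest.approx(p, abs=1e-10)
            assert res.recall == pytest.approx(rc, abs=1e-10)
            assert res.specificity == pytest.approx(sc, abs=1e-10)


class TestProfiles:
    def test_probability_validation(self):
        with pytest.raises(ValueError):
            ClassifierProfile(1.2, 0.5)
        with pytest.raises(ValueError):
            ReferenceProfile(0.9, 0.9, "sideways")

    def test_gold_requires_perfect_rates(self):
        with pytest.raises(ValueError):
            ReferenceProfile(0.9, 1.0, "gold")

    def test_dispatcher_routes_by_structure(self):
        ind = apparent_matrix(0.1, GOOD, REF90_IND)
        corr = apparent_matrix(0.1, GOOD, REF90_CORR)
        gold = apparent_matrix(0.1, GOOD, ReferenceProfile.gold())
        assert ind.cells == pytest.approx(
            apparent_matrix_independent(0.1, GOOD, REF90_IND).cells
        )
        assert corr.cells == pytest.approx(
            apparent_matrix_correlated(0.1, GOOD, REF90_CORR).cells
        )
        assert gold.cells == pytest.approx(true_matrix(0.1, GOOD).cells)
        assert not gold.apparent and ind.apparent and corr.apparent
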