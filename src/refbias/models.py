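"""Closed-form forward models for true and apparent confusion matrices.

A binary classification of known quality (recall and specificity against
ground truth) scored at prevalence ``p`` against a gold-standard
reference produces the *true* matrix

    tp = p*recall,  fn = p*(1-recall),
    fp = (1-p)*(1-specificity),  tn = (1-p)*specificity.

When the reference standard itself is imperfect, the observed matrix is
*apparent* (primed). Two error structures are modelled:

independent
    Reference errors are conditionally independent of classifier
    errors given the true class: each apparent cell is the sum of the
    joint correctness/error probabilities of the two labellings.

correlated
    Maximal positive error dependence: every reference error falls on a
    case the classifier also mislabelled. Truly positive cases that
    both labellings call negative move from FN to TN'; truly negative
    cases both call positive move from FP to TP'. This requires the
    reference to be at least as accurate as the classifier on each
    class; outside that region the construction is undefined and a
    ValueError is raised.

Under either structure only the cells and column (reference) marginals
move: the classifier's row marginals are fixed, and the reference-
positive marginal — the apparent prevalence — is the same linear
function of p (the classical apparent-prevalence relation, whose
inversion is the Rogan–Gladen estimator).

The module also provides the inverse map ``correct_independent``, which
recovers the true prevalence and classifier profile from an apparent
matrix when reference quality is known and its errors are independent.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .confusion import ConfusionMatrix, UNDEFINED, prevalence_of

__all__ = [
    "ERROR_STRUCTURES",
    "ClassifierProfile",
    "ReferenceProfile",
    "CorrectionResult",
    "true_matrix",
    "apparent_matrix_independent",
    "apparent_matrix_correlated",
    "apparent_matrix",
    "apparent_prevalence",
    "transition_prevalence",
    "correct_independent",
    "check_correlated_feasible",
]

ERROR_STRUCTURES = ("gold", "independent", "correlated")


def _check_prob(name: str, v: float) -> None:
    if not (0.0 <= v <= 1.0):
        raise ValueError(f"{name} must be a probability in [0, 1], got {v!r}")


def _check_p(p: float) -> None:
    if not (0.0 < p < 1.0):
        raise ValueError(
            f"prevalence must lie strictly inside (0, 1), got {p!r}; "
            "the endpoints make one class empty"
        )


@dataclass(frozen=True)
class ClassifierProfile:
    """Per-class correctness rates of the classification under evaluation."""

    recall: float
    specificity: float

    def __post_init__(self) -> None:
        _check_prob("classifier recall", self.recall)
        _check_prob("classifier specificity", self.specificity)


@dataclass(frozen=True)
class ReferenceProfile:
    """Per-class correctness rates of the reference standard.

    ``structure`` states how reference errors relate to classifier
    errors: "gold" (error-free, recall = specificity = 1),
    "independent", or "correlated" (maximal dependence).
    """

    recall: float
    specificity: float
    structure: str = "independent"

    def __post_init__(self) -> None:
        _check_prob("reference recall", self.recall)
        _check_prob("reference specificity", self.specificity)
        if self.structure not in ERROR_STRUCTURES:
            raise ValueError(
                f"unknown error structure {self.structure!r}; "
                f"expected one of {ERROR_STRUCTURES}"
            )
        if self.structure == "gold" and not (
            self.recall == 1.0 and self.specificity == 1.0
        ):
            raise ValueError("a gold reference must have recall = specificity = 1")

    @classmethod
    def gold(cls) -> "ReferenceProfile":
        return cls(1.0, 1.0, "gold")

    @property
    def is_perfect(self) -> bool:
        return self.recall == 1.0 and self.specificity == 1.0


def true_matrix(p: float, clf: ClassifierProfile) -> ConfusionMatrix:
    """True confusion matrix (proportions, n = 1) at prevalence *p*."""
    _check_p(p)
    return ConfusionMatrix(
        tp=p * clf.recall,
        fp=(1.0 - p) * (1.0 - clf.specificity),
        fn=p * (1.0 - clf.recall),
        tn=(1.0 - p) * clf.specificity,
        apparent=False,
    )


def apparent_matrix_independent(
    p: float, clf: ClassifierProfile, ref: ReferenceProfile
) -> ConfusionMatrix:
    """Apparent matrix when reference errors are independent of classifier errors.

    Each primed cell sums the two ways a case can land there: both
    labellings correct for that cell's classes, or both wrong. E.g.
    TP' collects truly positive cases that both call positive plus
    truly negative cases that both call positive.
    """
    _check_p(p)
    if ref.structure == "correlated":
        raise ValueError(
            "reference profile declares correlated errors; "
            "use apparent_matrix_correlated"
        )
    rc, sc = clf.recall, clf.specificity
    rr, sr = ref.recall, ref.specificity
    q = 1.0 - p
    return ConfusionMatrix(
        tp=p * rr * rc + q * (1.0 - sr) * (1.0 - sc),
        fp=p * (1.0 - rr) * rc + q * sr * (1.0 - sc),
        fn=p * rr * (1.0 - rc) + q * (1.0 - sr) * sc,
        tn=p * (1.0 - rr) * (1.0 - rc) + q * sr * sc,
        apparent=not ref.is_perfect,
    )


def check_correlated_feasible(clf: ClassifierProfile, ref: ReferenceProfile) -> None:
    """Raise if the maximal-correlation construction is undefined.

    Reference errors must fit inside the classifier's errors on each
    class, i.e. the reference must be at least as accurate per class.
    """
    if ref.recall < clf.recall:
        raise ValueError(
            "correlated-error model infeasible: reference recall "
            f"{ref.recall} < classifier recall {clf.recall}"
        )
    if ref.specificity < clf.specificity:
        raise ValueError(
            "correlated-error model infeasible: reference specificity "
            f"{ref.specificity} < classifier specificity {clf.specificity}"
        )


def apparent_matrix_correlated(
    p: float, clf: ClassifierProfile, ref: ReferenceProfile
) -> ConfusionMatrix:
    """Apparent matrix under maximally correlated reference errors.

    Starting from the true matrix, the reference's false negatives are
    drawn from the classifier's false negatives (FN -> TN') and its
    false positives from the classifier's false positives (FP -> TP'),
    so both error pools shrink and the diagonal inflates.
    """
    _check_p(p)
    if ref.structure == "independent":
        raise ValueError(
            "reference profile declares independent errors; "
            "use apparent_matrix_independent"
        )
    check_correlated_feasible(clf, ref)
    rc, sc = clf.recall, clf.specificity
    rr, sr = ref.recall, ref.specificity
    q = 1.0 - p
    return ConfusionMatrix(
        tp=p * rc + q * (1.0 - sr),
        fp=q * (sr - sc),
        fn=p * (rr - rc),
        tn=q * sc + p * (1.0 - rr),
        apparent=not ref.is_perfect,
    )


def apparent_matrix(
    p: float, clf: ClassifierProfile, ref: ReferenceProfile
) -> ConfusionMatrix:
    """Dispatch on ``ref.structure``; a gold reference returns the true matrix."""
    if ref.structure == "gold" or ref.is_perfect:
        return true_matrix(p, clf)
    if ref.structure == "independent":
        return apparent_matrix_independent(p, clf, ref)
    return apparent_matrix_correlated(p, clf, ref)


def apparent_prevalence(p: float, ref: ReferenceProfile) -> float:
    """Reference-positive marginal p*Recall_R + (1-p)*(1-Specificity_R).

    Identical under both error structures: correlation of errors moves
    cases within columns, not between them.
    """
    _check_p(p)
    return p * ref.recall + (1.0 - p) * (1.0 - ref.specificity)


def transition_prevalence(ref: ReferenceProfile, which: str) -> float:
    """Classical transition point between under- and over-estimation.

    Returns the standard expressions quoted in the diagnostic-accuracy
    literature for independent reference errors:
    (1-Spec_R)/(2-Recall_R-Spec_R) for precision (and for prevalence,
    where it is exactly the fixed point of the apparent-prevalence
    map), and (1-Recall_R)/(2-Recall_R-Spec_R) for NPV.

    Note these expressions involve only the reference profile. Under
    this package's forward model the exact sign change of apparent
    minus true precision also depends on the classifier — it occurs at
    p/(1-p) = (1-Spec_R)(1-Spec_C) / (Recall_C (1-Recall_R)) — and
    coincides with the classical expression only when
    Recall_C + Spec_C = 1 (see the methods note). The prevalence fixed
    point is exact for any classifier. A gold reference has no
    transition.
    """
    if which not in ("precision", "npv", "prevalence"):
        raise ValueError(
            f"unknown transition {which!r}; expected 'precision', 'npv' "
            "or 'prevalence'"
        )
    denom = 2.0 - ref.recall - ref.specificity
    if denom <= 0.0:
        raise ValueError("a perfect (gold) reference has no transition point")
    if which == "npv":
        return (1.0 - ref.recall) / denom
    return (1.0 - ref.specificity) / denom


@dataclass(frozen=True)
class CorrectionResult:
    """Recovered true prevalence and classifier rates, with a warning flag.

    ``flagged`` is True when a recovered value fell outside [0, 1] and
    was clamped, or when a rate was indeterminate (recovered prevalence
    of exactly 0 or 1 leaves one per-class rate 0/0, reported as NaN):
    the apparent matrix is then inconsistent with, or on the boundary
    of, the stated reference quality.
    """

    prevalence: float
    recall: float
    specificity: float
    flagged: bool

    @property
    def classifier(self) -> ClassifierProfile:
        """The recovered rates as a validated profile (rejects NaN recoveries)."""
        return ClassifierProfile(self.recall, self.specificity)


def _clamp01(v: float) -> tuple[float, bool]:
    if math.isnan(v):
        return v, True
    if v < 0.0:
        return 0.0, True
    if v > 1.0:
        return 1.0, True
    return v, False


def correct_independent(
    apparent: ConfusionMatrix, ref: ReferenceProfile
) -> CorrectionResult:
    """Invert the independent-error model: estimate (p, recall_C, spec_C).

    Each row of the apparent matrix is a known 2x2 mixture of the
    underlying quantities a = p*recall_C, b = (1-p)*(1-spec_C) (top
    row) and c = p*(1-recall_C), d = (1-p)*spec_C (bottom row), with
    mixing matrix [[Recall_R, 1-Spec_R], [1-Recall_R, Spec_R]] and
    determinant Recall_R + Spec_R - 1. Solving both rows gives
    p = a + c (equivalently the Rogan–Gladen estimate from the apparent
    prevalence), recall_C = a/p and spec_C = d/(1-p).

    Requires Recall_R + Spec_R != 1 (the misclassification map is
    singular when the reference is uninformative) and an independent or
    gold error structure.
    """
    if ref.structure == "correlated":
        raise ValueError("correction implemented for independent errors only")
    det = ref.recall + ref.specificity - 1.0
    if abs(det) < 1e-12:
        raise ValueError(
            "reference with recall + specificity = 1 is uninformative; "
            "the apparent matrix cannot be inverted"
        )
    if apparent.n <= 0:
        raise ValueError("cannot correct a zero-total matrix")
    m = apparent.scaled(1.0)
    rr, sr = ref.recall, ref.specificity
    a = (sr * m.tp - (1.0 - sr) * m.fp) / det
    b = (rr * m.fp - (1.0 - rr) * m.tp) / det
    c = (sr * m.fn - (1.0 - sr) * m.tn) / det
    d = (rr * m.tn - (1.0 - rr) * m.fn) / det

    p_raw = a + c
    recall_raw = a / p_raw if p_raw > 0.0 else UNDEFINED
    pos_col = b + d  # = 1 - p when consistent
    spec_raw = d / pos_col if pos_col > 0.0 else UNDEFINED

    p, f1 = _clamp01(p_raw)
    recall, f2 = _clamp01(recall_raw)
    spec, f3 = _clamp01(spec_raw)
    return CorrectionResult(
        prevalence=p, recall=recall, specificity=spec, flagged=f1 or f2 or f3
    )
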