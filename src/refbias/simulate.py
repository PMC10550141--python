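"""Case-level sampling with the joint label law the closed forms assume.

Each simulated case carries three binary labels: the true class, the
classifier's label, and the reference standard's label. Truth is
Bernoulli(p); the classifier is correct with probability recall (on
positives) or specificity (on negatives). The reference label depends
on the declared error structure:

independent
    Correct with probability recall_R / specificity_R, drawn
    independently of the classifier's outcome given truth.

correlated
    Errs only on cases the classifier also got wrong, with conditional
    error probability (1-recall_R)/(1-recall_C) on positives and
    (1-specificity_R)/(1-specificity_C) on negatives. The marginal
    reference error rates are then exactly 1-recall_R and
    1-specificity_R — the same marginals as the independent scheme —
    while every reference error coincides with a classifier error.
    This is the sampling analogue of the deterministic expected-count
    relabelling used by the closed-form correlated model.

Cross-tabulating classifier against reference labels therefore
converges (in proportion) to the corresponding apparent matrix from
:mod:`refbias.models`; :func:`mc_check` packages that comparison as a
z-score report and serves as the Monte-Carlo oracle for the closed
forms.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .confusion import ConfusionMatrix, MetricSet
from .models import (
    ClassifierProfile,
    ReferenceProfile,
    apparent_matrix,
    check_correlated_feasible,
)

__all__ = ["CaseSample", "MCReport", "sample_cases", "crosstab", "crosstab_truth", "mc_check"]


@dataclass(frozen=True)
class CaseSample:
    """A finite sample of (truth, classifier label, reference label) triples.

    Labels are boolean arrays (True = positive). Regenerating with the
    same (p, profiles, n, seed) reproduces the sample bit-for-bit; case
    order carries no meaning.
    """

    truth: np.ndarray
    clf_label: np.ndarray
    ref_label: np.ndarray
    p: float
    classifier: ClassifierProfile
    reference: ReferenceProfile
    seed: int

    @property
    def n(self) -> int:
        return self.truth.size

    def to_dataframe(self) -> pd.DataFrame:
        """Columns truth, ref_label, clf_label with values pos/neg."""
        enc = np.array(["neg", "pos"])
        return pd.DataFrame(
            {
                "truth": enc[self.truth.astype(int)],
                "ref_label": enc[self.ref_label.astype(int)],
                "clf_label": enc[self.clf_label.astype(int)],
            }
        )


def sample_cases(
    n: int,
    p: float,
    clf: ClassifierProfile,
    ref: ReferenceProfile,
    seed: int,
) -> CaseSample:
    """Draw *n* cases at prevalence *p* under the scenario's error structure."""
    if n <= 0:
        raise ValueError(f"sample size must be positive, got {n!r}")
    if not (0.0 < p < 1.0):
        raise ValueError(f"prevalence must lie in (0, 1), got {p!r}")
    if ref.structure == "correlated":
        check_correlated_feasible(clf, ref)

    rng = np.random.default_rng(seed)
    truth = rng.random(n) < p
    clf_correct = rng.random(n) < np.where(truth, clf.recall, clf.specificity)
    clf_label = truth ^ ~clf_correct

    if ref.structure == "gold":
        ref_label = truth.copy()
    elif ref.structure == "independent":
        ref_correct = rng.random(n) < np.where(truth, ref.recall, ref.specificity)
        ref_label = truth ^ ~ref_correct
    else:
        # Conditional error rates on classifier-error cases; 0/0 (perfect
        # classifier on a class forces a perfect reference there) -> 0.
        q_pos = (1.0 - ref.recall) / (1.0 - clf.recall) if clf.recall < 1.0 else 0.0
        q_neg = (
            (1.0 - ref.specificity) / (1.0 - clf.specificity)
            if clf.specificity < 1.0
            else 0.0
        )
        ref_err = ~clf_correct & (rng.random(n) < np.where(truth, q_pos, q_neg))
        ref_label = truth ^ ref_err

    return CaseSample(
        truth=truth,
        clf_label=clf_label,
        ref_label=ref_label,
        p=p,
        classifier=clf,
        reference=ref,
        seed=seed,
    )


def _tabulate(rows: np.ndarray, cols: np.ndarray, apparent: bool) -> ConfusionMatrix:
    return ConfusionMatrix(
        tp=int(np.sum(rows & cols)),
        fp=int(np.sum(rows & ~cols)),
        fn=int(np.sum(~rows & cols)),
        tn=int(np.sum(~rows & ~cols)),
        apparent=apparent,
    )


def crosstab(sample: CaseSample) -> ConfusionMatrix:
    """Integer-count matrix of classifier labels against *reference* labels.

    This is the matrix an analyst actually observes; the truth field is
    ignored (see :func:`crosstab_truth` for the audit version).
    """
    if sample.n == 0:
        raise ValueError("cannot cross-tabulate an empty sample")
    return _tabulate(
        sample.clf_label, sample.ref_label, apparent=not sample.reference.is_perfect
    )


def crosstab_truth(sample: CaseSample) -> ConfusionMatrix:
    """Audit matrix of classifier labels against the true classes."""
    if sample.n == 0:
        raise ValueError("cannot cross-tabulate an empty sample")
    return _tabulate(sample.clf_label, sample.truth, apparent=False)


@dataclass(frozen=True)
class MCReport:
    """Monte-Carlo agreement report between a sample and the closed form."""

    expected: ConfusionMatrix  # closed-form cell proportions
    observed: ConfusionMatrix  # integer counts from the sample
    z_scores: dict[str, float]  # per-cell (obs - exp)/binomial SE
    expected_metrics: MetricSet
    observed_metrics: MetricSet
    n: int
    seed: int
    tolerance_se: float
    passed: bool

    def summary(self) -> str:
        lines = [
            f"Monte-Carlo check: n={self.n}, seed={self.seed}, "
            f"tolerance={self.tolerance_se} SE -> "
            f"{'PASS' if self.passed else 'FAIL'}"
        ]
        for cell in ("tp", "fp", "fn", "tn"):
            exp = getattr(self.expected, cell)
            obs = getattr(self.observed, cell) / self.n
            lines.append(
                f"  {cell}: expected {exp:.6f}, observed {obs:.6f}, "
                f"z={self.z_scores[cell]:+.3f}"
            )
        return "\n".join(lines)


def mc_check(
    n: int,
    p: float,
    clf: ClassifierProfile,
    ref: ReferenceProfile,
    seed: int,
    tolerance_se: float = 4.0,
) -> MCReport:
    """Compare empirical cell proportions against the closed-form matrix.

    Draws a sample, cross-tabulates it against the reference labels and
    z-scores each cell against its closed-form expectation using the
    binomial standard error sqrt(q(1-q)/n). Passes iff every |z| is
    within *tolerance_se*.
    """
    if tolerance_se <= 0:
        raise ValueError("tolerance_se must be positive")
    sample = sample_cases(n, p, clf, ref, seed)
    expected = apparent_matrix(p, clf, ref)
    observed = crosstab(sample)
    z: dict[str, float] = {}
    for cell in ("tp", "fp", "fn", "tn"):
        q = getattr(expected, cell)
        se = math.sqrt(q * (1.0 - q) / n)
        diff = getattr(observed, cell) / n - q
        z[cell] = diff / se if se > 0 else (0.0 if diff == 0 else math.inf)
    passed = all(abs(v) <= tolerance_se for v in z.values())
    return MCReport(
        expected=expected,
        observed=observed,
        z_scores=z,
        expected_metrics=MetricSet.from_matrix(expected),
        observed_metrics=MetricSet.from_matrix(observed),
        n=n,
        seed=seed,
        tolerance_se=tolerance_se,
        passed=passed,
    )
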