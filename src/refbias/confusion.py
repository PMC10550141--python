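"""Binary confusion matrix and the standard accuracy-metric suite.

The matrix follows the epidemiological / remote-sensing convention:
reference labels in the columns, classifier labels in the rows, so

    tp = classifier-positive and reference-positive
    fp = classifier-positive and reference-negative
    fn = classifier-negative and reference-positive
    tn = classifier-negative and reference-negative

Cell masses are non-negative reals: expected-count matrices produced by
the forward models in :mod:`refbias.models` are fractional, and every
metric here is invariant to scaling all four cells by a positive
constant, so proportions and counts are interchangeable.

Degenerate matrices (a zero denominator somewhere) never raise; the
affected metric is returned as the NaN sentinel so that sweeps over
extreme prevalence can proceed and report "undefined" downstream.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields

__all__ = [
    "UNDEFINED",
    "is_undefined",
    "ConfusionMatrix",
    "MetricSet",
    "METRIC_NAMES",
    "rate_metrics",
    "composite_metrics",
    "likelihood_ratios",
    "prevalence_of",
]

#: Sentinel for a metric whose defining ratio has a zero denominator.
UNDEFINED: float = math.nan


def is_undefined(x: float) -> bool:
    """True if *x* is the undefined-metric sentinel (NaN)."""
    return isinstance(x, float) and math.isnan(x)


@dataclass(frozen=True)
class ConfusionMatrix:
    """A 2x2 confusion matrix with fixed orientation (reference in columns).

    Parameters
    ----------
    tp, fp, fn, tn:
        Non-negative cell masses; proportions or counts.
    apparent:
        Provenance flag: ``True`` if the column labels come from an
        imperfect reference standard (a primed, "apparent" matrix),
        ``False`` if they are ground truth. Purely informational; no
        computation depends on it.
    """

    tp: float
    fp: float
    fn: float
    tn: float
    apparent: bool = field(default=False, compare=False)

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "fn", "tn"):
            v = getattr(self, name)
            if not math.isfinite(v):
                raise ValueError(f"cell {name} must be finite, got {v!r}")
            if v < -1e-9:
                raise ValueError(f"cell {name} must be non-negative, got {v!r}")
            if v < 0.0:  # tolerate tiny negative float dust from model algebra
                object.__setattr__(self, name, 0.0)

    @property
    def n(self) -> float:
        """Total mass (sum of the four cells)."""
        return self.tp + self.fp + self.fn + self.tn

    @property
    def cells(self) -> tuple[float, float, float, float]:
        """Cells in the fixed order (tp, fp, fn, tn)."""
        return (self.tp, self.fp, self.fn, self.tn)

    def scaled(self, total: float) -> "ConfusionMatrix":
        """Rescale the matrix so its cells sum to *total* (e.g. a sample size)."""
        if self.n <= 0:
            raise ValueError("cannot rescale a zero-total matrix")
        if total <= 0:
            raise ValueError(f"target total must be positive, got {total!r}")
        k = total / self.n
        return ConfusionMatrix(
            self.tp * k, self.fp * k, self.fn * k, self.tn * k, apparent=self.apparent
        )

    def metrics(self) -> "MetricSet":
        """Shorthand for :meth:`MetricSet.from_matrix`."""
        return MetricSet.from_matrix(self)


def _ratio(num: float, den: float) -> float:
    return num / den if den > 0 else UNDEFINED


def rate_metrics(m: ConfusionMatrix) -> tuple[float, float, float, float]:
    """The four basic per-class rates: (recall, precision, specificity, npv).

    recall = tp/(tp+fn) (sensitivity, producer's accuracy),
    precision = tp/(tp+fp) (positive predictive value, user's accuracy),
    specificity = tn/(tn+fp), npv = tn/(tn+fn). A zero denominator
    yields the NaN sentinel.
    """
    return (
        _ratio(m.tp, m.tp + m.fn),
        _ratio(m.tp, m.tp + m.fp),
        _ratio(m.tn, m.tn + m.fp),
        _ratio(m.tn, m.tn + m.fn),
    )


def composite_metrics(m: ConfusionMatrix) -> tuple[float, float, float, float]:
    """Whole-matrix summaries: (accuracy, youden_j, f1, mcc).

    accuracy = (tp+tn)/n; J = recall + specificity - 1 (true skill
    statistic); F1 = 2tp/(2tp+fn+fp); MCC is the Matthews correlation
    coefficient, equal to the phi (Pearson) correlation of the two
    binary label vectors. MCC is undefined if any of its four marginals
    is zero; J is undefined if recall or specificity is.
    """
    accuracy = _ratio(m.tp + m.tn, m.n)
    recall, _, specificity, _ = rate_metrics(m)
    if is_undefined(recall) or is_undefined(specificity):
        youden_j = UNDEFINED
    else:
        youden_j = recall + specificity - 1.0
    f1 = _ratio(2.0 * m.tp, 2.0 * m.tp + m.fn + m.fp)
    marginals = (m.tp + m.fp, m.tp + m.fn, m.tn + m.fp, m.tn + m.fn)
    if any(g <= 0 for g in marginals):
        mcc = UNDEFINED
    else:
        mcc = (m.tp * m.tn - m.fp * m.fn) / math.sqrt(math.prod(marginals))
    return (accuracy, youden_j, f1, mcc)


def likelihood_ratios(m: ConfusionMatrix) -> tuple[float, float]:
    """Diagnostic likelihood ratios (lr_pos, lr_neg).

    LR+ = recall/(1-specificity), LR- = (1-recall)/specificity.
    A perfect specificity gives LR+ = +inf; zero specificity gives
    LR- = +inf. Undefined recall/specificity propagates the sentinel.
    """
    recall, _, specificity, _ = rate_metrics(m)
    if is_undefined(recall) or is_undefined(specificity):
        return (UNDEFINED, UNDEFINED)
    lr_pos = math.inf if specificity >= 1.0 else recall / (1.0 - specificity)
    lr_neg = math.inf if specificity <= 0.0 else (1.0 - recall) / specificity
    return (lr_pos, lr_neg)


def prevalence_of(m: ConfusionMatrix) -> float:
    """Proportion of reference-positive cases, (tp+fn)/n.

    Raises ``ValueError`` for a zero-total matrix: prevalence of an
    empty sample is not a degenerate metric but an invalid input.
    """
    if m.n <= 0:
        raise ValueError("prevalence of a zero-total matrix is undefined")
    return (m.tp + m.fn) / m.n


#: Canonical metric column order used in tables and serialisation.
METRIC_NAMES: tuple[str, ...] = (
    "accuracy",
    "recall",
    "precision",
    "specificity",
    "npv",
    "youden_j",
    "f1",
    "mcc",
    "lr_pos",
    "lr_neg",
    "prevalence",
)


@dataclass(frozen=True)
class MetricSet:
    """All eleven metrics computed from a single confusion matrix."""

    accuracy: float
    recall: float
    precision: float
    specificity: float
    npv: float
    youden_j: float
    f1: float
    mcc: float
    lr_pos: float
    lr_neg: float
    prevalence: float

    @classmethod
    def from_matrix(cls, m: ConfusionMatrix) -> "MetricSet":
        recall, precision, specificity, npv = rate_metrics(m)
        accuracy, youden_j, f1, mcc = composite_metrics(m)
        lr_pos, lr_neg = likelihood_ratios(m)
        return cls(
            accuracy=accuracy,
            recall=recall,
            precision=precision,
            specificity=specificity,
            npv=npv,
            youden_j=youden_j,
            f1=f1,
            mcc=mcc,
            lr_pos=lr_pos,
            lr_neg=lr_neg,
            prevalence=prevalence_of(m) if m.n > 0 else UNDEFINED,
        )

    def to_dict(self, ndigits: int | None = None) -> dict[str, float]:
        d = {f.name: getattr(self, f.name) for f in fields(self)}
        if ndigits is not None:
            d = {
                k: (round(v, ndigits) if math.isfinite(v) else v)
                for k, v in d.items()
            }
        return d

    def to_json_dict(self) -> dict[str, object]:
        """JSON-safe mapping: NaN -> null, +inf -> "inf"."""
        out: dict[str, object] = {}
        for k, v in self.to_dict().items():
            if is_undefined(v):
                out[k] = None
            elif math.isinf(v):
                out[k] = "inf"
            else:
                out[k] = v
        return out
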