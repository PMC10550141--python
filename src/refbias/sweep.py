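"""Prevalence sweeps: true vs apparent metrics across scenario grids.

A :class:`Scenario` pairs a classifier profile with a reference profile
and a prevalence grid. :func:`run_sweep` evaluates the closed-form
models at every grid point and returns a tidy table with one
true-provenance row and one apparent-provenance row per (scenario, p),
which is the numeric content behind metric-vs-prevalence figures.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .confusion import METRIC_NAMES, MetricSet
from .models import (
    ClassifierProfile,
    ReferenceProfile,
    apparent_matrix,
    true_matrix,
)

__all__ = [
    "Scenario",
    "SWEEP_COLUMNS",
    "prevalence_grid",
    "default_scenarios",
    "run_sweep",
    "summarize_extrema",
    "plot_sweep",
]


def prevalence_grid() -> tuple[float, ...]:
    """Standard 21-point prevalence grid: 0.01, 0.05, 0.10, ..., 0.95, 0.99.

    The interior runs in 0.05 increments; the endpoints are pulled in
    from 0 and 1 to 0.01 and 0.99 so neither class is ever empty.
    Values are built from integer hundredths, so 0.50 (say) is exact.
    """
    return tuple(i / 100 for i in (1, *range(5, 100, 5), 99))


@dataclass(frozen=True)
class Scenario:
    """One sweep: a classifier scored against one reference over a grid."""

    label: str
    clf: ClassifierProfile
    ref: ReferenceProfile
    grid: tuple[float, ...] = field(default_factory=prevalence_grid)
    n: float = 1000.0

    def __post_init__(self) -> None:
        if not self.grid:
            raise ValueError("scenario grid must be non-empty")
        if any(not (0.0 < p < 1.0) for p in self.grid):
            raise ValueError("grid values must lie strictly inside (0, 1)")
        if any(b <= a for a, b in zip(self.grid, self.grid[1:])):
            raise ValueError("grid must be strictly increasing")
        if self.n <= 0:
            raise ValueError("sample size n must be positive")


# Reference error levels: 2%, 10%, 18% per-class error, i.e. recall =
# specificity = 0.98 / 0.90 / 0.82, crossed with both error structures;
# plus a coin-tossing classifier scored against a 30%-error correlated
# reference — the scenario where a worthless classifier earns a high
# apparent MCC.
_ERROR_LEVELS = ((2, 0.98), (10, 0.90), (18, 0.82))


def default_scenarios() -> list[Scenario]:
    """The built-in scenario set: 7 scenarios on the standard grid, n=1000."""
    good = ClassifierProfile(0.8, 0.8)
    out: list[Scenario] = []
    for structure, tag in (("independent", "ind"), ("correlated", "corr")):
        for pct, rate in _ERROR_LEVELS:
            out.append(
                Scenario(
                    label=f"{tag}{pct:02d}",
                    clf=good,
                    ref=ReferenceProfile(rate, rate, structure),
                )
            )
    out.append(
        Scenario(
            label="poor_corr30",
            clf=ClassifierProfile(0.5, 0.5),
            ref=ReferenceProfile(0.7, 0.7, "correlated"),
        )
    )
    return out


SWEEP_COLUMNS: tuple[str, ...] = (
    "scenario",
    "p",
    "provenance",
    "tp",
    "fp",
    "fn",
    "tn",
    *METRIC_NAMES[:-1],  # accuracy ... lr_neg
    "prevalence_apparent",
)


def run_sweep(scenarios: list[Scenario]) -> pd.DataFrame:
    """Evaluate every scenario at every grid point.

    Returns a DataFrame with columns :data:`SWEEP_COLUMNS`: cell counts
    scaled to the scenario sample size, the eleven metrics, and the
    prevalence of the row's own matrix (true p for true rows, the
    apparent prevalence for apparent rows). Fully deterministic.
    """
    rows: list[dict[str, object]] = []
    for sc in scenarios:
        for p in sc.grid:
            try:
                pairs = (
                    ("true", true_matrix(p, sc.clf)),
                    ("apparent", apparent_matrix(p, sc.clf, sc.ref)),
                )
            except ValueError as e:
                raise ValueError(f"scenario {sc.label!r}: {e}") from e
            for provenance, m in pairs:
                counts = m.scaled(sc.n)
                ms = MetricSet.from_matrix(m)
                row: dict[str, object] = {
                    "scenario": sc.label,
                    "p": p,
                    "provenance": provenance,
                    "tp": counts.tp,
                    "fp": counts.fp,
                    "fn": counts.fn,
                    "tn": counts.tn,
                }
                row.update(ms.to_dict())
                row["prevalence_apparent"] = row.pop("prevalence")
                rows.append(row)
    return pd.DataFrame(rows, columns=list(SWEEP_COLUMNS))


def summarize_extrema(table: pd.DataFrame, metric: str) -> pd.DataFrame:
    """Per-scenario extrema of an apparent metric over the grid.

    Returns one row per scenario with the minimum, maximum, the grid
    point where the maximum occurs, and the number of grid points where
    the metric was undefined (excluded from the extrema).
    """
    if metric not in METRIC_NAMES[:-1]:
        raise ValueError(
            f"unknown metric {metric!r}; valid names: "
            + ", ".join(METRIC_NAMES[:-1])
        )
    if table.empty:
        raise ValueError("empty sweep table")
    app = table[table["provenance"] == "apparent"]
    out = []
    for label, grp in app.groupby("scenario", sort=False):
        vals = grp[metric]
        defined = grp[vals.notna()]
        if defined.empty:
            out.append(
                {
                    "scenario": label,
                    "p_at_max": float("nan"),
                    "min": float("nan"),
                    "max": float("nan"),
                    "n_undefined": int(vals.isna().sum()),
                }
            )
            continue
        imax = defined[metric].idxmax()
        out.append(
            {
                "scenario": label,
                "p_at_max": defined.loc[imax, "p"],
                "min": defined[metric].min(),
                "max": defined[metric].max(),
                "n_undefined": int(vals.isna().sum()),
            }
        )
    return pd.DataFrame(out)


def plot_sweep(table: pd.DataFrame, metric: str, ax=None):
    """Plot apparent *metric* vs prevalence, one line per scenario, with the
    true relationship dashed. Cosmetic convenience; requires matplotlib."""
    import matplotlib.pyplot as plt  # deferred: plotting is optional

    if ax is None:
        _, ax = plt.subplots()
    app = table[table["provenance"] == "apparent"]
    for label, grp in app.groupby("scenario", sort=False):
        ax.plot(grp["p"], grp[metric], marker="o", ms=3, label=label)
    truth = table[table["provenance"] == "true"]
    first = truth[truth["scenario"] == truth["scenario"].iloc[0]]
    ax.plot(first["p"], first[metric], "k--", label="true (gold reference)")
    ax.set_xlabel("prevalence")
    ax.set_ylabel(metric)
    ax.legend(fontsize=7)
    return ax
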