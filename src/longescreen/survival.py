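"""Lifespan-assay statistics.

Group summaries (mean/median lifespan), percent extension between group
means, Kaplan-Meier survival curves, the two-group log-rank test, and a
LOESS dose-response smooth of knockdown level against lifespan extension.

Censoring: each record carries an ``observed`` flag (False = right-
censored).  Group means are computed over observed lifespans only; the
Kaplan-Meier estimator and log-rank test use the censoring information
properly (via lifelines).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from scipy import stats
from statsmodels.nonparametric.smoothers_lowess import lowess

__all__ = [
    "LifespanRecord",
    "SurvivalSummary",
    "DoseResponsePoint",
    "LogRankResult",
    "summarize_group",
    "percent_extension",
    "kaplan_meier",
    "log_rank_test",
    "loess_dose_response",
    "plot_km",
]


@dataclass(frozen=True)
class LifespanRecord:
    """One individual's lifespan: group label, value, and censoring flag.

    ``lifespan`` is in the assay's units (divisions for yeast replicative
    lifespan, days for worms, months for mice) — the unit travels as
    metadata with the file, not the record.  ``observed=False`` marks a
    right-censored individual.
    """

    group: str
    lifespan: float
    observed: bool = True

    def __post_init__(self):
        if not (self.lifespan > 0):
            raise ValueError(f"lifespan must be positive, got {self.lifespan}")


@dataclass(frozen=True)
class SurvivalSummary:
    group: str
    n: int
    mean: float
    median: float
    n_observed: int
    unit: str = ""


@dataclass(frozen=True)
class DoseResponsePoint:
    """One (dose, response) pair, e.g. expression fold change vs percent
    lifespan extension."""

    dose_or_foldchange: float
    response: float

    def __post_init__(self):
        if not (np.isfinite(self.dose_or_foldchange) and np.isfinite(self.response)):
            raise ValueError("dose and response must be finite")


@dataclass(frozen=True)
class LogRankResult:
    chi_square: float
    p_value: float
    n_a: int
    n_b: int


def _split(records: Sequence[LifespanRecord]):
    t = np.array([r.lifespan for r in records], dtype=float)
    e = np.array([r.observed for r in records], dtype=bool)
    return t, e


def summarize_group(
    records: Sequence[LifespanRecord], group: str, unit: str = ""
) -> SurvivalSummary:
    """Mean (over observed lifespans) and median lifespan for one group.

    The median is the sample median when nothing is censored, otherwise
    the 50% point of the Kaplan-Meier curve.
    """
    recs = [r for r in records if r.group == group]
    if not recs:
        raise ValueError(f"no records for group {group!r}")
    t, e = _split(recs)
    if not e.any():
        raise ValueError(f"group {group!r} has no observed lifespans")
    mean = float(t[e].mean())
    if e.all():
        median = float(np.median(t))
    else:
        kmf = KaplanMeierFitter().fit(t, e)
        median = float(kmf.median_survival_time_)
    return SurvivalSummary(
        group=group, n=len(recs), mean=mean, median=median, n_observed=int(e.sum()), unit=unit
    )


def percent_extension(mean_treatment: float, mean_control: float) -> tuple[float, float]:
    """Percent lifespan extension of treatment over control means.

    Returns ``(rounded, exact)``: 100*(mt - mc)/mc rounded to one decimal
    (the headline convention) alongside full precision.
    """
    if not mean_control > 0:
        raise ValueError("control mean must be positive")
    exact = 100.0 * (mean_treatment - mean_control) / mean_control
    return round(exact, 1), exact


def kaplan_meier(records: Sequence[LifespanRecord]) -> pd.DataFrame:
    """Product-limit survival curve: columns time, survival, at_risk.

    Includes the time-zero row (survival 1).  With no censoring this is
    the empirical survival function.
    """
    if not records:
        raise ValueError("no records")
    t, e = _split(records)
    kmf = KaplanMeierFitter().fit(t, e)
    surv = kmf.survival_function_
    at_risk = kmf.event_table["at_risk"].reindex(surv.index)
    out = pd.DataFrame(
        {
            "time": surv.index.to_numpy(dtype=float),
            "survival": surv.iloc[:, 0].to_numpy(dtype=float),
            "at_risk": at_risk.to_numpy(dtype=float).astype(int),
        }
    )
    return out.reset_index(drop=True)


def _logrank_chi2(ta, ea, tb, eb) -> float:
    """Log-rank chi-square from the counting-process tabulation.

    At each distinct event time, observed-minus-expected events in group
    A under the hypergeometric null, with the hypergeometric variance
    (no continuity correction); chi2 = (sum O-E)^2 / sum V.
    """
    times = np.unique(np.concatenate([ta[ea], tb[eb]]))
    # risk-set sizes and event counts at each event time, vectorised
    n1 = (ta[None, :] >= times[:, None]).sum(axis=1)
    n2 = (tb[None, :] >= times[:, None]).sum(axis=1)
    d1 = ((ta[None, :] == times[:, None]) & ea[None, :]).sum(axis=1)
    d2 = ((tb[None, :] == times[:, None]) & eb[None, :]).sum(axis=1)
    n = n1 + n2
    d = d1 + d2
    keep = n > 1
    n1, n2, n, d, d1 = n1[keep], n2[keep], n[keep], d[keep], d1[keep]
    o_minus_e = (d1 - d * n1 / n).sum()
    var = (d * (n1 / n) * (n2 / n) * (n - d) / (n - 1)).sum()
    if var == 0:
        return 0.0
    return float(o_minus_e**2 / var)


def log_rank_test(
    a: Sequence[LifespanRecord], b: Sequence[LifespanRecord]
) -> LogRankResult:
    """Two-group log-rank test (1 df chi-square), symmetric in group order."""
    if not a or not b:
        raise ValueError("both groups must be non-empty")
    ta, ea = _split(a)
    tb, eb = _split(b)
    if not (ea.any() or eb.any()):
        raise ValueError("log-rank test needs at least one observed event")
    chi2 = _logrank_chi2(ta, ea, tb, eb)
    return LogRankResult(
        chi_square=chi2,
        p_value=float(stats.chi2.sf(chi2, df=1)),
        n_a=len(a),
        n_b=len(b),
    )


def loess_dose_response(
    points: Sequence[DoseResponsePoint],
    span: float = 0.75,
    grid: np.ndarray | None = None,
) -> pd.DataFrame:
    """LOESS smooth (local linear, tricube weights, no robustness passes).

    Returns fitted values at the input doses, plus the smooth evaluated on
    ``grid`` (default: 100 points across the dose range) in extra rows
    flagged by ``is_grid``.
    """
    if len(points) < 4:
        raise ValueError("need at least 4 points for a LOESS fit")
    if not (0 < span <= 1):
        raise ValueError("span must lie in (0, 1]")
    x = np.array([p.dose_or_foldchange for p in points], dtype=float)
    y = np.array([p.response for p in points], dtype=float)
    if int(np.ceil(span * len(points))) < 3:
        raise ValueError(
            f"span {span} gives fewer than 3 neighbours at n={len(points)}; increase span"
        )
    if grid is None:
        grid = np.linspace(x.min(), x.max(), 100)
    fitted = lowess(y, x, frac=span, it=0, xvals=x)
    smooth = lowess(y, x, frac=span, it=0, xvals=np.asarray(grid, dtype=float))
    a = pd.DataFrame({"dose": x, "response": y, "fitted": fitted, "is_grid": False})
    b = pd.DataFrame(
        {"dose": np.asarray(grid, dtype=float), "response": np.nan, "fitted": smooth, "is_grid": True}
    )
    return pd.concat([a, b], ignore_index=True)


def plot_km(groups: dict[str, Sequence[LifespanRecord]], ax=None, unit: str = ""):
    """Step plot of Kaplan-Meier curves for several groups."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    for label, recs in groups.items():
        curve = kaplan_meier(recs)
        ax.step(curve["time"], curve["survival"], where="post", label=label)
    ax.set_xlabel(f"lifespan ({unit})" if unit else "lifespan")
    ax.set_ylabel("surviving fraction")
    ax.set_ylim(0, 1.02)
    ax.legend()
    return ax
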