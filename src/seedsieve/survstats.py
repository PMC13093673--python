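"""Right-censoring-aware flowering-onset statistics.

Flowering onset is treated as a time-to-event outcome: plants that had
not flowered by the end of the experiment are right-censored.  This
module wraps the product-limit (Kaplan-Meier) estimator and the log-rank
test from ``lifelines`` behind a small, array-in / dataclass-out surface,
and adds germination-rate summaries with Wilson intervals.

Tie convention: events precede censorings at the same time (the standard
risk-set convention).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank
from statsmodels.stats.proportion import proportion_confint


@dataclass(frozen=True)
class KMCurve:
    """Product-limit estimate evaluated at the distinct event times.

    ``survival[i]`` is S(t) just after ``event_times[i]``; ``at_risk[i]``
    and ``events[i]`` are the risk-set size and event count at that time.
    """

    event_times: np.ndarray
    at_risk: np.ndarray
    events: np.ndarray
    survival: np.ndarray

    def survival_at(self, t: float) -> float:
        """Step-function lookup: S(t) = product over event times <= t."""
        idx = np.searchsorted(self.event_times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


def _as_sample(times, event_flags) -> Tuple[np.ndarray, np.ndarray]:
    t = np.asarray(times, dtype=float)
    if event_flags is None:
        e = np.ones_like(t, dtype=int)
    else:
        e = np.asarray(event_flags, dtype=int)
    if t.size == 0:
        raise ValueError("empty time-to-event sample")
    if t.shape != e.shape:
        raise ValueError("times and event_flags must have equal length")
    if np.any(t <= 0):
        raise ValueError("event/censoring times must be positive")
    if not np.isin(e, (0, 1)).all():
        raise ValueError("event flags must be 0 (censored) or 1 (event)")
    return t, e


def km_estimate(times, event_flags=None) -> KMCurve:
    """Kaplan-Meier product-limit estimate of P(not yet flowered at t).

    ``event_flags``: 1 = flowered (event), 0 = right-censored; omitted
    means no censoring.
    """
    t, e = _as_sample(times, event_flags)
    kmf = KaplanMeierFitter()
    kmf.fit(t, event_observed=e)
    table = kmf.event_table
    mask = table["observed"] > 0
    event_times = table.index.to_numpy(dtype=float)[mask]
    return KMCurve(
        event_times=event_times,
        at_risk=table["at_risk"].to_numpy(dtype=float)[mask],
        events=table["observed"].to_numpy(dtype=float)[mask],
        survival=kmf.survival_function_at_times(event_times).to_numpy(dtype=float),
    )


def km_median(curve: KMCurve) -> float:
    """Smallest event time at which S(t) <= 0.5; ``inf`` if never reached."""
    below = curve.survival <= 0.5
    if not below.any():
        return math.inf
    return float(curve.event_times[int(np.argmax(below))])


def logrank_test(
    times_a, events_a, times_b, events_b
) -> Tuple[float, float]:
    """One-degree-of-freedom log-rank comparison of two censored samples.

    Returns ``(chi2_statistic, p_value)`` from the observed-minus-expected
    event counts over the pooled risk sets.  Raises ``ValueError`` when
    neither group contributes any event (the statistic is undefined).
    """
    ta, ea = _as_sample(times_a, events_a)
    tb, eb = _as_sample(times_b, events_b)
    if ea.sum() + eb.sum() == 0:
        raise ValueError("log-rank statistic undefined: no events in either group")
    res = _ll_logrank(ta, tb, event_observed_A=ea, event_observed_B=eb)
    return float(res.test_statistic), float(res.p_value)


@dataclass
class GerminationSummary:
    """Per-group germination rates and pairwise rate differences.

    ``rates`` has one row per group (n planted, n germinated, rate,
    Wilson 95% interval, undefined flag for empty groups); ``differences``
    lists each pair's rate difference in percentage points.
    """

    rates: pd.DataFrame
    differences: pd.DataFrame


def germination_summary(
    table: pd.DataFrame,
    group_cols: Sequence[str] = ("treatment", "priority"),
    germinated_col: str = "germinated",
) -> GerminationSummary:
    """Germination rate per group with Wilson binomial confidence intervals.

    Groups with zero planted seeds are kept, flagged ``undefined`` with
    NaN rate.  Differences are reported for every unordered group pair,
    in percentage points (rate_a - rate_b).
    """
    group_cols = list(group_cols)
    missing = [c for c in group_cols + [germinated_col] if c not in table.columns]
    if missing:
        raise ValueError(f"table lacks columns: {missing}")
    rows = []
    for key, grp in table.groupby(group_cols, sort=True, dropna=False):
        key = key if isinstance(key, tuple) else (key,)
        n = int(grp[germinated_col].notna().sum())
        k = int(pd.to_numeric(grp[germinated_col], errors="coerce").fillna(0).sum())
        if n == 0:
            rate, lo, hi = math.nan, math.nan, math.nan
        else:
            rate = k / n
            lo, hi = proportion_confint(k, n, alpha=0.05, method="wilson")
        rows.append(dict(zip(group_cols, key), n=n, germinated=k, rate=rate,
                         ci_low=lo, ci_high=hi, undefined=(n == 0)))
    rates = pd.DataFrame(rows)
    labels = [
        " / ".join(str(v) for v in row) if len(group_cols) > 1 else str(row[0])
        for row in rates[group_cols].itertuples(index=False)
    ]
    diffs = []
    for i in range(len(rates)):
        for j in range(i + 1, len(rates)):
            diffs.append(
                {
                    "group_a": labels[i],
                    "group_b": labels[j],
                    "diff_points": 100.0 * (rates["rate"].iloc[i] - rates["rate"].iloc[j]),
                }
            )
    return GerminationSummary(rates=rates, differences=pd.DataFrame(diffs))


def km_compare(
    table: pd.DataFrame,
    group_cols: Sequence[str],
    pairs: Iterable[Tuple[str, str]],
    time_col: str = "flowering_day",
    censor_col: str = "censored",
) -> pd.DataFrame:
    """Pairwise log-rank comparisons between labelled groups of a table.

    Group labels are the ``group_cols`` values joined with ``" / "``; rows
    lacking a time (e.g. non-germinated) are excluded.  No multiplicity
    correction is applied (pairwise reporting only).
    """
    group_cols = list(group_cols)
    labels = table[group_cols].astype(str).agg(" / ".join, axis=1)
    out = []
    for a, b in pairs:
        rows_a = table[(labels == a) & table[time_col].notna()]
        rows_b = table[(labels == b) & table[time_col].notna()]
        stat, p = logrank_test(
            rows_a[time_col], 1 - rows_a[censor_col].astype(int),
            rows_b[time_col], 1 - rows_b[censor_col].astype(int),
        )
        out.append({"group_a": a, "group_b": b, "statistic": stat, "p_value": p})
    return pd.DataFrame(out)
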