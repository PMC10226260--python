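"""Kaplan-Meier estimation, log-rank testing and expression dichotomization.

Survival curves and two-group tests are delegated to lifelines; this module
adds the cohort conventions used throughout the pipeline: overall-survival
times in days with 0/1 censoring flags, median-split and best-cutoff
dichotomization of a gene's expression, and the minimum-expression filter
(summed linear-scale expression of at least 1 across samples) applied
before any gene is considered for survival association.

Best-cutoff dichotomization scans every distinct observed expression value
between the 10th and 90th percentile (the median always included) and
returns the threshold minimizing the log-rank p-value. That minimized
p-value is optimization-biased and is flagged as such in the output rather
than adjusted, mirroring common practice in tumor-cohort reports.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test


class SurvivalError(ValueError):
    pass


@dataclass
class SurvivalData:
    """Aligned survival times (days), event flags and group labels."""

    time: np.ndarray
    event: np.ndarray
    group: np.ndarray | None = None

    def __post_init__(self):
        self.time = np.asarray(self.time, dtype=float)
        self.event = np.asarray(self.event, dtype=int)
        if self.time.shape != self.event.shape:
            raise SurvivalError("time and event must align")
        if (self.time < 0).any() or not np.isfinite(self.time).all():
            raise SurvivalError("times must be finite and non-negative")
        if not np.isin(self.event, [0, 1]).all():
            raise SurvivalError("event flags must be 0 or 1")
        if self.group is not None:
            self.group = np.asarray(self.group)
            if self.group.shape != self.time.shape:
                raise SurvivalError("group labels must align with times")


def km_curve(times, events) -> pd.DataFrame:
    """Product-limit survival estimate as a (time, survival) step table.

    S(0) = 1; the curve is non-increasing and right-continuous; with no
    events the estimate is identically 1.
    """
    data = SurvivalData(times, events)
    kmf = KaplanMeierFitter()
    kmf.fit(data.time, data.event)
    sf = kmf.survival_function_
    return pd.DataFrame({"time": sf.index.to_numpy(dtype=float),
                         "survival": sf.iloc[:, 0].to_numpy(dtype=float)})


def logrank(data: SurvivalData) -> tuple[float, float]:
    """Two-group log-rank test: (chi-square statistic on 1 df, p-value)."""
    if data.group is None:
        raise SurvivalError("group labels required")
    labels = pd.unique(data.group)
    if len(labels) != 2:
        raise SurvivalError(f"need exactly 2 groups, got {len(labels)}")
    mask = data.group == labels[0]
    if mask.all() or not mask.any():
        raise SurvivalError("a group has zero samples")
    res = logrank_test(data.time[mask], data.time[~mask],
                       event_observed_A=data.event[mask],
                       event_observed_B=data.event[~mask])
    return float(res.test_statistic), float(res.p_value)


def expression_sum_filter(values, is_log_scale: bool,
                          min_sum: float = 1.0) -> bool:
    """True when summed linear-scale expression across samples >= min_sum."""
    v = np.asarray(values, dtype=float)
    linear = np.exp2(v) if is_log_scale else v
    return float(linear.sum()) >= min_sum


def split_by_expression(values, data: SurvivalData, method: str = "median",
                        is_log_scale: bool = True,
                        expr_filter_min_sum: float | None = 1.0) -> dict:
    """Dichotomize samples by a gene's expression and log-rank test the split.

    ``method`` is ``median`` (threshold at the median of log2-transformed
    values) or ``best_cutoff`` (threshold minimizing the log-rank p over the
    distinct observed values within [P10, P90], median included). High group
    = strictly above the cutoff. Returns a dict with labels, cutoff, the
    log-rank statistic and p at the cutoff, and ``p_is_optimized`` marking
    the multiple-testing bias of the best-cutoff mode. A gene failing the
    minimum-sum expression filter returns ``{"filtered_out": True}``.
    """
    v = np.asarray(values, dtype=float)
    if v.shape != data.time.shape:
        raise SurvivalError("expression values must align with samples")
    if expr_filter_min_sum is not None and not expression_sum_filter(
            v, is_log_scale, expr_filter_min_sum):
        return {"filtered_out": True}
    logv = v if is_log_scale else np.log2(v + 1.0)
    if np.ptp(logv) == 0:
        raise SurvivalError("constant expression: no valid split")

    def _test(cutoff: float):
        labels = np.where(logv > cutoff, "high", "low")
        if (labels == "high").all() or (labels == "low").all():
            return None
        stat, p = logrank(SurvivalData(data.time, data.event, labels))
        return labels, stat, p

    median = float(np.median(logv))
    if method == "median":
        res = _test(median)
        if res is None:
            raise SurvivalError("median split leaves an empty group")
        labels, stat, p = res
        cutoff = median
        optimized = False
    elif method == "best_cutoff":
        lo, hi = np.percentile(logv, [10, 90])
        grid = sorted(set(logv[(logv >= lo) & (logv <= hi)]) | {median})
        best = None
        for c in grid:
            res = _test(float(c))
            if res is None:
                continue
            if best is None or res[2] < best[2]:
                best = (res[0], res[1], res[2], float(c))
        if best is None:
            raise SurvivalError("no candidate cutoff produces two groups")
        labels, stat, p, cutoff = best
        optimized = True
    else:
        raise SurvivalError(f"unknown method {method!r}")
    return {"filtered_out": False, "labels": labels, "cutoff": cutoff,
            "statistic": stat, "p": p, "p_is_optimized": optimized}
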