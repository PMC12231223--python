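"""Inferential toolkit for diet comparisons.

Pearson correlation and OLS regression relate morphometrics (SVL, MW, BM)
to each other and to prey size; Kendall's tau-b tests monotone association
between body size and per-stomach prey volume; the Wilcoxon rank-sum /
Mann-Whitney test contrasts prey-size and prey-count distributions between
sexes or age classes.  All tests are two-sided.  Exact null distributions
are used where enumeration is cheap and ties permit (Mann-Whitney for
``n_a * n_b <= 400``, tau for ``n <= 10``); otherwise normal
approximations with tie-corrected variance are used.  The samples
compared (males vs. females) are independent, so the "rank sum" test is
the two-independent-sample Mann-Whitney form; both the rank-sum W of the
first sample and U are reported to bracket software conventions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .data import Dataset, GeckodietError
from .composition import prey_volume

__all__ = [
    "TestResult",
    "pearson_correlation",
    "linear_regression",
    "kendall_tau_b",
    "wilcoxon_rank_sum",
    "compare_groups",
    "results_frame",
    "EXACT_MWU_MAX_PRODUCT",
    "EXACT_TAU_MAX_N",
]

#: Enumeration thresholds: exact null distributions stay sub-second here.
EXACT_MWU_MAX_PRODUCT = 400
EXACT_TAU_MAX_N = 10


@dataclass(frozen=True)
class TestResult:
    """Statistic + p-value container for every test in the toolkit."""

    statistic_name: str
    statistic: float
    p_value: float
    n: tuple[int, ...]
    method_detail: str
    extra: dict = field(default_factory=dict)

    def __post_init__(self):
        if not 0.0 <= self.p_value <= 1.0:
            raise GeckodietError(f"p-value {self.p_value} outside [0, 1]")


def _check_pair(x, y, min_n: int) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise GeckodietError("x and y must be 1-D vectors of equal length")
    if x.size < min_n:
        raise GeckodietError(f"need at least {min_n} paired observations, got {x.size}")
    return x, y


def pearson_correlation(x, y) -> TestResult:
    """Product-moment correlation with the two-sided t-transform p (n-2 df)."""
    x, y = _check_pair(x, y, 3)
    for name, v in (("x", x), ("y", y)):
        if np.ptp(v) == 0:
            raise GeckodietError(f"{name} is constant; correlation undefined")
    r, p = sps.pearsonr(x, y)
    return TestResult("r", float(r), float(p), (x.size,),
                      "two-sided t transform, n-2 df")


def linear_regression(x, y) -> TestResult:
    """Ordinary least-squares fit of y on x; p tests slope != 0.

    ``extra`` carries intercept, r_squared and the slope standard error.
    """
    x, y = _check_pair(x, y, 3)
    if np.ptp(x) == 0:
        raise GeckodietError("x is constant; regression undefined")
    fit = sps.linregress(x, y)
    p = float(fit.pvalue) if np.ptp(y) != 0 else 0.0
    return TestResult(
        "slope", float(fit.slope), p, (x.size,),
        "OLS, two-sided t test on slope",
        extra={"intercept": float(fit.intercept),
               "r_squared": float(fit.rvalue) ** 2,
               "stderr": float(fit.stderr)},
    )


def kendall_tau_b(x, y) -> TestResult:
    """Kendall's tau-b (tie correction in both margins).

    p is exact by enumeration for n <= 10 tie-free samples, otherwise the
    tie-corrected normal approximation.
    """
    x, y = _check_pair(x, y, 2)
    for name, v in (("x", x), ("y", y)):
        if np.ptp(v) == 0:
            raise GeckodietError(f"{name} is all-tied; tau undefined")
    tie_free = (np.unique(x).size == x.size) and (np.unique(y).size == y.size)
    if x.size <= EXACT_TAU_MAX_N and tie_free:
        method = "exact"
        detail = "exact enumeration (tie-free, small n)"
    else:
        method = "asymptotic"
        detail = "normal approximation, tie-corrected variance"
    res = sps.kendalltau(x, y, variant="b", method=method)
    return TestResult("tau_b", float(res.statistic), float(res.pvalue),
                      (x.size,), detail)


def wilcoxon_rank_sum(a, b) -> TestResult:
    """Two-independent-sample Wilcoxon rank-sum / Mann-Whitney test.

    The statistic reported is W, the sum of (mid-)ranks of the first
    sample in the pooled ranking; ``extra["U"]`` carries the Mann-Whitney
    U of the first sample (``U = W - n_a(n_a+1)/2``).  p is two-sided:
    exact by enumeration when ``n_a*n_b <= 400`` and the pooled sample is
    tie-free, otherwise a normal approximation with tie-corrected variance
    and continuity correction.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise GeckodietError("both samples must be non-empty")
    pooled = np.concatenate([a, b])
    tie_free = np.unique(pooled).size == pooled.size
    if a.size * b.size <= EXACT_MWU_MAX_PRODUCT and tie_free:
        method = "exact"
        detail = "exact enumeration (tie-free, n_a*n_b <= 400)"
    else:
        method = "asymptotic"
        detail = ("normal approximation, tie-corrected variance, "
                  "continuity correction")
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method,
                           use_continuity=True)
    u = float(res.statistic)
    w = u + a.size * (a.size + 1) / 2.0
    return TestResult("W", w, float(res.pvalue), (int(a.size), int(b.size)),
                      detail, extra={"U": u})


_METRICS = ("item_length", "item_width", "item_volume", "count_per_stomach",
            "total_volume_per_stomach")

_GROUPINGS = {
    # grouping key -> (label_a, groups_a, label_b, groups_b)
    "sex": ("male", ("male",), "female", ("female",)),
    "age": ("adult", ("male", "female"), "subadult", ("subadult", "juvenile")),
}


def _metric_values(dataset: Dataset, groups: Sequence[str], metric: str,
                   pi_mode: str) -> np.ndarray:
    sub = dataset.subset(groups)
    items = sub.prey_items
    if metric == "item_length":
        return np.array([p.length_mm for p in items])
    if metric == "item_width":
        return np.array([p.width_mm for p in items])
    if metric == "item_volume":
        return np.array([
            p.volume_mm3 if p.volume_mm3 is not None
            else prey_volume(p.length_mm, p.width_mm, pi_mode)
            for p in items
        ])
    per: dict[str, float] = {}
    for p in items:
        if metric == "count_per_stomach":
            per[p.specimen_id] = per.get(p.specimen_id, 0.0) + 1.0
        else:
            v = (p.volume_mm3 if p.volume_mm3 is not None
                 else prey_volume(p.length_mm, p.width_mm, pi_mode))
            per[p.specimen_id] = per.get(p.specimen_id, 0.0) + v
    return np.array(list(per.values()))


def compare_groups(
    dataset: Dataset,
    grouping: str = "sex",
    metrics: Iterable[str] = _METRICS,
    pi_mode: str = "exact",
) -> list[TestResult]:
    """Mann-Whitney contrasts of diet metrics between two groups.

    ``grouping="sex"`` contrasts males vs. females; ``"age"`` contrasts
    adults (males + females) vs. subadults/juveniles.  Per-item metrics
    pool items within each group; per-stomach metrics aggregate per
    specimen first.  Each result's ``extra`` records the metric and group
    labels.
    """
    if grouping not in _GROUPINGS:
        raise GeckodietError(f"grouping must be one of {sorted(_GROUPINGS)}")
    label_a, groups_a, label_b, groups_b = _GROUPINGS[grouping]
    results = []
    for metric in metrics:
        if metric not in _METRICS:
            raise GeckodietError(f"unknown metric {metric!r}; choose from {_METRICS}")
        va = _metric_values(dataset, groups_a, metric, pi_mode)
        vb = _metric_values(dataset, groups_b, metric, pi_mode)
        if va.size == 0:
            raise GeckodietError(f"group {label_a!r} has no data for {metric!r}")
        if vb.size == 0:
            raise GeckodietError(f"group {label_b!r} has no data for {metric!r}")
        res = wilcoxon_rank_sum(va, vb)
        res.extra.update(metric=metric, group_a=label_a, group_b=label_b)
        results.append(res)
    return results


def results_frame(results: Iterable[TestResult]) -> pd.DataFrame:
    """Tidy export of test results (one row per test)."""
    rows = []
    for r in results:
        rows.append({
            "metric": r.extra.get("metric", ""),
            "group_a": r.extra.get("group_a", ""),
            "group_b": r.extra.get("group_b", ""),
            "n_a": r.n[0],
            "n_b": r.n[1] if len(r.n) > 1 else r.n[0],
            "statistic_name": r.statistic_name,
            "statistic": r.statistic,
            "U": r.extra.get("U", float("nan")),
            "p_value": r.p_value,
            "method_detail": r.method_detail,
        })
    return pd.DataFrame(rows)
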