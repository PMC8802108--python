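"""Group-comparison statistics for dose-response experiments.

The layer a drug-screening analysis needs on top of per-recording metrics:

* ROUT-style outlier screening (robust location/scale residuals + FDR);
* heteroscedasticity-robust ANOVA: Welch and Brown-Forsythe variants, with
  Games-Howell pairwise comparisons against the studentized-range
  distribution;
* classical one-way ANOVA and the rank-based Kruskal-Wallis test;
* dose-trend regression of mean relative response on log10(concentration).

Welch, Brown-Forsythe and Games-Howell are computed from their closed forms
(scipy supplies the reference distributions); one-way ANOVA and
Kruskal-Wallis delegate to scipy.stats.  Parametric and rank-based results
are meant to be reported side by side rather than gated on normality tests.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .errors import DegenerateDataError, InputError

__all__ = [
    "GroupTable",
    "TestResult",
    "PairwiseComparison",
    "OutlierScreen",
    "RegressionResult",
    "screen_outliers",
    "welch_anova",
    "brown_forsythe_anova",
    "games_howell",
    "one_way_anova",
    "kruskal_wallis",
    "dose_trend_regression",
]

log = logging.getLogger(__name__)


@dataclass
class GroupTable:
    """Labelled per-recording values, one array per group."""

    values: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        self.values = {k: np.asarray(v, dtype=float) for k, v in self.values.items()}
        if len(self.values) < 2:
            raise InputError("at least 2 groups required")
        for k, v in self.values.items():
            if v.ndim != 1 or v.size < 2:
                raise InputError(f"group {k!r} needs at least 2 values")
            if not np.all(np.isfinite(v)):
                raise InputError(f"group {k!r} contains non-finite values")

    @property
    def labels(self) -> list[str]:
        return list(self.values)

    @property
    def k(self) -> int:
        return len(self.values)

    def arrays(self) -> list[np.ndarray]:
        return list(self.values.values())


def _as_table(groups: "GroupTable | Mapping[str, Sequence[float]]") -> GroupTable:
    if isinstance(groups, GroupTable):
        return groups
    return GroupTable({k: np.asarray(v, dtype=float) for k, v in groups.items()})


@dataclass(frozen=True)
class PairwiseComparison:
    group_a: str
    group_b: str
    statistic: float   # studentized-range q for Games-Howell
    df: float
    p_value: float


@dataclass
class TestResult:
    test: str
    statistic: float
    df: tuple[float, float] | float
    p_value: float
    pairwise: list[PairwiseComparison] = field(default_factory=list)


@dataclass
class OutlierScreen:
    kept: np.ndarray
    flagged_indices: np.ndarray
    q_percent: float


@dataclass
class RegressionResult:
    slope: float
    intercept: float
    r_squared: float
    slope_p_value: float
    n_points: int


# ---------------------------------------------------------------------------
# outlier screening


def screen_outliers(values: Sequence[float], q_percent: float = 1.0) -> OutlierScreen:
    """ROUT-style outlier screen for a single column of scalar metrics.

    The original method fits a robust regression and FDR-screens residuals;
    applied to one group of scalars it degenerates to a robust
    location/scale screen: residuals from the median, scale = 1.4826 * MAD,
    two-sided t-tail p-values, Benjamini-Hochberg at rate ``q_percent``.
    With n < 3 screening is skipped with a warning.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 3:
        log.warning("outlier screening skipped: n=%d < 3", x.size)
        return OutlierScreen(kept=x, flagged_indices=np.empty(0, dtype=int),
                             q_percent=q_percent)
    med = np.median(x)
    resid = x - med
    scale = 1.4826 * np.median(np.abs(resid))
    if scale == 0:
        flagged = np.flatnonzero(resid != 0)  # zero spread: any deviant is gross
        keep = np.setdiff1d(np.arange(x.size), flagged)
        return OutlierScreen(kept=x[keep], flagged_indices=flagged,
                             q_percent=q_percent)
    z = np.abs(resid) / scale
    p = 2 * stats.t.sf(z, df=x.size - 1)
    order = np.argsort(p)
    q = q_percent / 100.0
    thresh = q * (np.arange(1, x.size + 1)) / x.size
    passed = p[order] <= thresh
    n_rej = int(np.max(np.flatnonzero(passed)) + 1) if passed.any() else 0
    flagged = np.sort(order[:n_rej])
    keep = np.setdiff1d(np.arange(x.size), flagged)
    return OutlierScreen(kept=x[keep], flagged_indices=flagged, q_percent=q_percent)


# ---------------------------------------------------------------------------
# ANOVA family


def _group_moments(table: GroupTable):
    arrays = table.arrays()
    n = np.array([a.size for a in arrays], dtype=float)
    mean = np.array([a.mean() for a in arrays])
    var = np.array([a.var(ddof=1) for a in arrays])
    if np.all(var == 0):
        raise DegenerateDataError("all groups have zero variance")
    return n, mean, var


def welch_anova(groups: "GroupTable | Mapping[str, Sequence[float]]") -> TestResult:
    """Welch's heteroscedasticity-robust one-way ANOVA.

    F* = sum w_i (m_i - m_w)^2 / (k-1) over 1 + 2(k-2)/(k^2-1) * A, with
    w_i = n_i / s_i^2, m_w the weighted grand mean,
    A = sum ((1 - w_i/W)^2 / (n_i - 1)), and Satterthwaite denominator
    df2 = (k^2 - 1) / (3 A).
    """
    table = _as_table(groups)
    n, mean, var = _group_moments(table)
    if np.any(var == 0):
        raise DegenerateDataError("Welch ANOVA requires nonzero variance per group")
    k = table.k
    w = n / var
    w_sum = w.sum()
    m_w = np.sum(w * mean) / w_sum
    a = np.sum((1 - w / w_sum) ** 2 / (n - 1))
    num = np.sum(w * (mean - m_w) ** 2) / (k - 1)
    den = 1 + 2 * (k - 2) / (k**2 - 1) * a
    f = num / den
    df1 = k - 1.0
    df2 = (k**2 - 1) / (3 * a)
    p = float(stats.f.sf(f, df1, df2))
    return TestResult("welch_anova", float(f), (df1, float(df2)), p)


def brown_forsythe_anova(
    groups: "GroupTable | Mapping[str, Sequence[float]]",
) -> TestResult:
    """Brown-Forsythe F* test (unequal-variance one-way ANOVA).

    F* = sum n_i (m_i - m)^2 / sum (1 - n_i/N) s_i^2, with Satterthwaite
    denominator df.  (This is the mean-comparison F* test, not the
    Brown-Forsythe spread test on median-centered data.)
    """
    table = _as_table(groups)
    n, mean, var = _group_moments(table)
    if np.any(var == 0):
        raise DegenerateDataError("Brown-Forsythe requires nonzero variance per group")
    big_n = n.sum()
    grand = np.sum(n * mean) / big_n
    num = np.sum(n * (mean - grand) ** 2)
    c = (1 - n / big_n) * var
    den = c.sum()
    f = num / den
    df1 = table.k - 1.0
    df2 = den**2 / np.sum(c**2 / (n - 1))
    p = float(stats.f.sf(f, df1, df2))
    return TestResult("brown_forsythe_anova", float(f), (df1, float(df2)), p)


def _welch_pair(n1, m1, v1, n2, m2, v2):
    se2 = v1 / n1 + v2 / n2
    t = (m1 - m2) / np.sqrt(se2)
    df = se2**2 / ((v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1))
    return t, df


def games_howell(groups: "GroupTable | Mapping[str, Sequence[float]]") -> TestResult:
    """Games-Howell pairwise comparisons after a robust ANOVA.

    For each pair: Welch t statistic and df; q = |t| * sqrt(2) referred to the
    studentized-range distribution with k groups.  The reported overall
    statistic/p is the smallest adjusted pairwise p (family-level summary).
    """
    table = _as_table(groups)
    n, mean, var = _group_moments(table)
    if np.any(var == 0):
        raise DegenerateDataError("Games-Howell requires nonzero variance per group")
    labels = table.labels
    k = table.k
    pairwise = []
    for i, j in combinations(range(k), 2):
        t, df = _welch_pair(n[i], mean[i], var[i], n[j], mean[j], var[j])
        q = abs(t) * np.sqrt(2.0)
        p = float(stats.studentized_range.sf(q, k, df))
        pairwise.append(
            PairwiseComparison(labels[i], labels[j], float(q), float(df),
                               min(max(p, 0.0), 1.0))
        )
    best = min(pairwise, key=lambda c: c.p_value)
    return TestResult("games_howell", best.statistic, best.df, best.p_value,
                      pairwise=pairwise)


def one_way_anova(groups: "GroupTable | Mapping[str, Sequence[float]]") -> TestResult:
    """Classical (pooled-variance) one-way ANOVA."""
    table = _as_table(groups)
    _group_moments(table)  # degenerate-data guard
    arrays = table.arrays()
    f, p = stats.f_oneway(*arrays)
    df1 = table.k - 1.0
    df2 = float(sum(a.size for a in arrays) - table.k)
    return TestResult("one_way_anova", float(f), (df1, df2), float(p))


def kruskal_wallis(groups: "GroupTable | Mapping[str, Sequence[float]]") -> TestResult:
    """Kruskal-Wallis rank H test (tie-corrected)."""
    table = _as_table(groups)
    arrays = table.arrays()
    if np.ptp(np.concatenate(arrays)) == 0:
        raise DegenerateDataError("all values identical: ranks undefined")
    h, p = stats.kruskal(*arrays)
    return TestResult("kruskal_wallis", float(h), float(table.k - 1), float(p))


# ---------------------------------------------------------------------------
# dose-trend regression


def dose_trend_regression(
    concentrations: Sequence[float],
    responses: Sequence[float],
    log_scale: bool = True,
    aggregate: bool = True,
) -> RegressionResult:
    """OLS of relative response on (log10) concentration with a slope t-test.

    With ``aggregate=True`` (default) responses sharing a concentration are
    averaged first and the line is fitted through the per-concentration means,
    so lack of fit from a non-monotone dose-response inflates the residual and
    deflates the trend test, as it should.
    """
    c = np.asarray(concentrations, dtype=float)
    y = np.asarray(responses, dtype=float)
    if c.shape != y.shape:
        raise InputError("concentrations and responses must align")
    if np.any(c <= 0) and log_scale:
        raise InputError("concentrations must be positive for a log10 fit")
    if np.unique(c).size < 3:
        raise InputError("at least 3 distinct concentrations required")
    if aggregate:
        uc = np.unique(c)
        y = np.array([y[c == ci].mean() for ci in uc])
        c = uc
    x = np.log10(c) if log_scale else c
    res = stats.linregress(x, y)
    return RegressionResult(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        slope_p_value=float(res.pvalue),
        n_points=int(x.size),
    )
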