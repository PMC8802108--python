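"""Cutoff-based arrhythmia scoring and contingency statistics.

Rhythm irregularity is quantified operationally as the number of extreme R-R
intervals — intervals strictly exceeding a model-specific cutoff (3 s for
human PSC-derived cardiomyocyte clusters, whose spontaneous rate is slow;
1 s for the faster murine HL-1 line).  Counts are expressed per 1000
contractions, pooled across recordings within an arm, arranged in a 2x2
treatment-vs-control contingency table, and tested with the chi-square test
with Yates' continuity correction.  Poincare (lag-1 return map) data supports
visual inspection of tachy-brady alternation and pauses.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .errors import InputError, UndefinedMetricError

__all__ = [
    "ArrhythmiaConfig",
    "HPSC_CONFIG",
    "HL1_CONFIG",
    "ExtremeCount",
    "ArrhythmiaTable",
    "PoincareData",
    "count_extreme_rr",
    "build_contingency",
    "chi_square_yates",
    "poincare",
]


@dataclass(frozen=True)
class ArrhythmiaConfig:
    """cutoff: R-R intervals strictly greater than this (seconds) are extreme."""

    cutoff: float = 3.0

    def __post_init__(self) -> None:
        if self.cutoff <= 0:
            raise InputError("cutoff must be positive")


HPSC_CONFIG = ArrhythmiaConfig(cutoff=3.0)
HL1_CONFIG = ArrhythmiaConfig(cutoff=1.0)


@dataclass(frozen=True)
class ExtremeCount:
    extreme: int
    total: int

    @property
    def per_1000(self) -> float:
        return 1000.0 * self.extreme / self.total


@dataclass(frozen=True)
class ArrhythmiaTable:
    """2x2 counts: (extreme, normal) x (treatment, control)."""

    a: int  # treatment extreme
    b: int  # treatment normal
    c: int  # control extreme
    d: int  # control normal

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise InputError("contingency counts must be nonnegative")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def treatment_per_1000(self) -> float:
        return 1000.0 * self.a / (self.a + self.b)

    @property
    def control_per_1000(self) -> float:
        return 1000.0 * self.c / (self.c + self.d)

    def swapped(self) -> "ArrhythmiaTable":
        return ArrhythmiaTable(self.c, self.d, self.a, self.b)


@dataclass(frozen=True)
class PoincareData:
    """Lag-1 return map of R-R intervals with the cutoff annotation."""

    pairs: np.ndarray      # shape (n-1, 2): (RR_n, RR_{n+1}) in order
    cutoff: float
    flagged: np.ndarray    # pairs with either coordinate > cutoff


def count_extreme_rr(
    rr: Sequence[float] | np.ndarray, config: ArrhythmiaConfig
) -> ExtremeCount:
    """Count R-R intervals strictly exceeding the cutoff."""
    rr = np.asarray(rr, dtype=float)
    if rr.size == 0:
        raise UndefinedMetricError("extreme-interval rate undefined for empty R-R list")
    if np.any(rr <= 0):
        raise InputError("R-R intervals must be positive")
    return ExtremeCount(extreme=int(np.sum(rr > config.cutoff)), total=int(rr.size))


def build_contingency(
    treatment: ExtremeCount | Iterable[ExtremeCount],
    control: ExtremeCount | Iterable[ExtremeCount],
) -> ArrhythmiaTable:
    """Pool per-recording counts within each arm into one 2x2 table."""

    def pool(arm) -> tuple[int, int]:
        counts = [arm] if isinstance(arm, ExtremeCount) else list(arm)
        extreme = sum(c.extreme for c in counts)
        total = sum(c.total for c in counts)
        if total == 0:
            raise InputError("arm with zero total intervals")
        return extreme, total

    te, tt = pool(treatment)
    ce, ct = pool(control)
    return ArrhythmiaTable(a=te, b=tt - te, c=ce, d=ct - ce)


def chi_square_yates(table: ArrhythmiaTable) -> tuple[float, int, float]:
    """Chi-square test with Yates' continuity correction on a 2x2 table.

    statistic = N * (max(|ad - bc| - N/2, 0))^2 / ((a+b)(c+d)(a+c)(b+d)),
    referred to the chi-square distribution with 1 df.  The correction is
    clamped at zero so near-homogeneous tables cannot yield a spurious
    positive statistic.
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    n = table.n
    margins = [(a + b), (c + d), (a + c), (b + d)]
    if any(m == 0 for m in margins):
        raise InputError("chi-square requires all marginals > 0")
    num = max(abs(a * d - b * c) - n / 2.0, 0.0)
    statistic = n * num * num / float(np.prod([float(m) for m in margins]))
    p = float(stats.chi2.sf(statistic, df=1))
    return float(statistic), 1, p


def poincare(
    rr: Sequence[float] | np.ndarray, config: ArrhythmiaConfig
) -> PoincareData:
    """Lag-1 pairs (RR_n, RR_{n+1}); pairs touching the cutoff are flagged."""
    rr = np.asarray(rr, dtype=float)
    if rr.size < 2:
        return PoincareData(
            pairs=np.empty((0, 2)), cutoff=config.cutoff,
            flagged=np.empty(0, dtype=bool),
        )
    pairs = np.column_stack([rr[:-1], rr[1:]])
    flagged = np.any(pairs > config.cutoff, axis=1)
    return PoincareData(pairs=pairs, cutoff=config.cutoff, flagged=flagged)
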