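"""Comet-assay statistics: %tail-DNA summaries and group comparisons.

Per-cell %tail-DNA values (the fraction of a cell's DNA fluorescence in the
electrophoretic tail) are summarized as mean +/- Delta, where Delta is the
square root of the variance of the mean,

    Delta = sqrt( 1/(n(n-1)) * sum_i (tbar - t_i)^2 )

algebraically identical to SD/sqrt(n) with the n-1 denominator.  Group
comparisons use the two-sample t-test without assuming equal variances
(Welch), at a 95% significance level, with no multiplicity correction by
default (a Bonferroni option exists).
"""

from __future__ import annotations

import enum
import itertools
import logging
import math
from dataclasses import dataclass
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InputDomainError

__all__ = [
    "ExperimentalGroup",
    "CometSample",
    "GroupSummary",
    "WelchResult",
    "variance_of_mean",
    "summarize",
    "welch_t_test",
    "welch_from_summary",
    "compare_conditions",
]

logger = logging.getLogger(__name__)

ALPHA = 0.05


class ExperimentalGroup(str, enum.Enum):
    """Experimental arms: irradiated with/without boron and the two controls."""

    IR_B = "IR_B"
    IR = "IR"
    C_B = "C_B"
    C = "C"


@dataclass(frozen=True)
class CometSample:
    """Per-cell %tail-DNA values for one (group, time) sample."""

    values: tuple
    group: ExperimentalGroup
    time_h: float
    cell_line: str = ""
    dose_group: str = "none"

    def __post_init__(self):
        arr = np.asarray(self.values, dtype=float)
        if arr.size == 0:
            raise InputDomainError("a comet sample needs at least one cell")
        if arr.min() < 0 or arr.max() > 100:
            raise InputDomainError("%tail-DNA values must lie in [0, 100]")
        object.__setattr__(self, "values", tuple(arr.tolist()))

    @property
    def n(self) -> int:
        return len(self.values)


class GroupSummary(NamedTuple):
    mean: float
    delta: float
    n: int


class WelchResult(NamedTuple):
    t: float
    df: float
    p: float
    significant: bool


def variance_of_mean(values: Sequence[float]) -> float:
    """Uncertainty of the mean: sqrt(sum((tbar - t_i)^2) / (n(n-1))).

    Raises for n < 2, where the spread of the mean is undefined.
    """
    arr = np.asarray(values, dtype=float)
    n = arr.size
    if n < 2:
        raise InputDomainError("variance of the mean needs at least two values")
    tbar = arr.mean()
    return math.sqrt(np.sum((tbar - arr) ** 2) / (n * (n - 1)))


def summarize(values: Sequence[float]) -> GroupSummary:
    """Mean +/- Delta for one sample."""
    arr = np.asarray(values, dtype=float)
    return GroupSummary(float(arr.mean()), variance_of_mean(arr), int(arr.size))


def _welch_df(s1, n1, s2, n2) -> float:
    v1, v2 = s1**2 / n1, s2**2 / n2
    denom = v1**2 / (n1 - 1) + v2**2 / (n2 - 1)
    if denom == 0:
        return float(n1 + n2 - 2)
    return (v1 + v2) ** 2 / denom


def welch_t_test(a: Sequence[float], b: Sequence[float], alpha: float = ALPHA) -> WelchResult:
    """Two-sided Welch (unequal-variance) t-test on raw values.

    Both samples degenerate with equal means is reported as t = 0, p = 1.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise InputDomainError("each sample needs n >= 2")
    if np.std(a, ddof=1) == 0 and np.std(b, ddof=1) == 0:
        if a.mean() == b.mean():
            return WelchResult(0.0, float(a.size + b.size - 2), 1.0, False)
        return WelchResult(math.copysign(math.inf, a.mean() - b.mean()),
                           float(a.size + b.size - 2), 0.0, True)
    res = stats.ttest_ind(a, b, equal_var=False)
    df = _welch_df(np.std(a, ddof=1), a.size, np.std(b, ddof=1), b.size)
    p = float(res.pvalue)
    return WelchResult(float(res.statistic), df, p, p < alpha)


def welch_from_summary(
    mean_a: float, sd_a: float, n_a: int,
    mean_b: float, sd_b: float, n_b: int,
    alpha: float = ALPHA,
) -> WelchResult:
    """Welch test from summary statistics (mean, SD, n) of each side."""
    if n_a < 2 or n_b < 2:
        raise InputDomainError("each side needs n >= 2")
    if sd_a == 0 and sd_b == 0:
        if mean_a == mean_b:
            return WelchResult(0.0, float(n_a + n_b - 2), 1.0, False)
        return WelchResult(math.copysign(math.inf, mean_a - mean_b),
                           float(n_a + n_b - 2), 0.0, True)
    res = stats.ttest_ind_from_stats(
        mean_a, sd_a, n_a, mean_b, sd_b, n_b, equal_var=False
    )
    df = _welch_df(sd_a, n_a, sd_b, n_b)
    p = float(res.pvalue)
    return WelchResult(float(res.statistic), df, p, p < alpha)


_DEFAULT_PAIRS = (
    (ExperimentalGroup.IR_B, ExperimentalGroup.IR),
    (ExperimentalGroup.IR_B, ExperimentalGroup.C),
    (ExperimentalGroup.IR, ExperimentalGroup.C),
)


def compare_conditions(
    samples: Iterable[CometSample],
    pairs: Sequence[tuple] = _DEFAULT_PAIRS,
    bonferroni: bool = False,
    alpha: float = ALPHA,
) -> pd.DataFrame:
    """Pairwise Welch tests within each (cell_line, dose_group, time) stratum.

    Cells are pooled within a sample (replicate structure is not modelled);
    missing strata members are skipped with a log entry.  With
    ``bonferroni=True`` the significance threshold is divided by the number
    of tests performed per stratum.
    """
    by_stratum: dict[tuple, dict[ExperimentalGroup, list[float]]] = {}
    for s in samples:
        key = (s.cell_line, s.dose_group, s.time_h)
        by_stratum.setdefault(key, {}).setdefault(s.group, []).extend(s.values)

    rows = []
    for key in sorted(by_stratum):
        groups = by_stratum[key]
        present = [(ga, gb) for ga, gb in pairs if ga in groups and gb in groups]
        thr = alpha / len(present) if (bonferroni and present) else alpha
        for ga, gb in pairs:
            if ga not in groups or gb not in groups:
                logger.info("stratum %s: pair %s vs %s missing, skipped", key, ga.value, gb.value)
                continue
            res = welch_t_test(groups[ga], groups[gb], alpha=thr)
            rows.append(
                {
                    "cell_line": key[0],
                    "dose_group": key[1],
                    "time_h": key[2],
                    "group_a": ga.value,
                    "group_b": gb.value,
                    "mean_a": float(np.mean(groups[ga])),
                    "mean_b": float(np.mean(groups[gb])),
                    "delta_a": variance_of_mean(groups[ga]),
                    "delta_b": variance_of_mean(groups[gb]),
                    "t": res.t,
                    "df": res.df,
                    "p": res.p,
                    "significant": res.p < thr,
                }
            )
    cols = [
        "cell_line", "dose_group", "time_h", "group_a", "group_b",
        "mean_a", "mean_b", "delta_a", "delta_b", "t", "df", "p", "significant",
    ]
    return pd.DataFrame(rows, columns=cols)
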