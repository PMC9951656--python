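"""Stratified descriptive statistics for age-at-death data.

Mean ages with normal-quantile confidence intervals, monthly death
distributions with peak months, frequency cross-tabulations, and the
percent difference in newborn life expectancy between the sexes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .records import DeathRecord, cause_class

__all__ = [
    "MeanAgeEstimate",
    "CrossTab",
    "MonthlyDistribution",
    "mean_age_ci",
    "mean_age_excluding",
    "monthly_distribution",
    "crosstab",
    "sex_longevity_ratio",
    "SexLongevityRatio",
]


@dataclass
class MeanAgeEstimate:
    """Mean age-at-death in one stratum with a normal-quantile CI.

    The interval is ``mean ± z_{(1+level)/2} * sd / sqrt(n)`` with the
    sample (n-1) standard deviation.  With ``n = 1`` the CI is undefined
    and flagged via ``ci_defined``.
    """

    stratum: str
    n: int
    mean: float
    sd: float
    ci_low: float
    ci_high: float
    level: float = 0.95
    n_excluded: int = 0

    @property
    def ci_defined(self) -> bool:
        return math.isfinite(self.ci_low) and math.isfinite(self.ci_high)

    def __str__(self) -> str:
        ci = (
            f"95% CI [{self.ci_low:.2f}, {self.ci_high:.2f}]"
            if self.ci_defined
            else "CI undefined (n=1)"
        )
        return f"{self.stratum}: mean {self.mean:.1f} y ({ci}, n={self.n})"


def _extract_ages(data: Sequence) -> list[int]:
    return [
        r.age_years if isinstance(r, DeathRecord) else int(r) for r in data
    ]


def mean_age_ci(
    data: Sequence, level: float = 0.95, stratum: str = "all"
) -> MeanAgeEstimate:
    """Mean age-at-death with a z-based confidence interval.

    ``data`` may be records or plain integer ages.
    """
    if not 0.0 < level < 1.0:
        raise ValueError(f"level must be in (0, 1), got {level}")
    ages = _extract_ages(data)
    n = len(ages)
    if n == 0:
        raise ValueError("cannot estimate a mean from zero ages")
    arr = np.asarray(ages, dtype=float)
    mean = float(arr.mean())
    if n == 1:
        return MeanAgeEstimate(stratum, n, mean, float("nan"),
                               float("nan"), float("nan"), level)
    sd = float(arr.std(ddof=1))
    z = stats.norm.ppf(0.5 + level / 2.0)
    half = z * sd / math.sqrt(n)
    return MeanAgeEstimate(stratum, n, mean, sd, mean - half, mean + half, level)


def mean_age_excluding(
    data: Sequence, min_age: int, level: float = 0.95, stratum: str | None = None
) -> MeanAgeEstimate:
    """Mean age-at-death over individuals aged at least ``min_age``."""
    ages = _extract_ages(data)
    kept = [a for a in ages if a >= min_age]
    if not kept:
        raise ValueError(f"no individuals aged >= {min_age}")
    est = mean_age_ci(kept, level=level,
                      stratum=stratum or f"age>={min_age}")
    est.n_excluded = len(ages) - len(kept)
    return est


@dataclass
class MonthlyDistribution:
    """Per-group monthly death proportions (columns 1..12, rows per group)."""

    counts: pd.DataFrame
    proportions: pd.DataFrame
    peaks: dict[str, set[int]]
    n_undated: int = 0

    def peak_month(self, group: str) -> set[int]:
        return self.peaks[group]


def _group_label(record: DeathRecord, by: Sequence[str]) -> str | None:
    parts = []
    for factor in by:
        if factor == "sex":
            parts.append(record.sex.value)
        elif factor in ("cause_class", "cause2"):
            cc = cause_class(record)
            if cc is None:
                return None
            parts.append(cc)
        elif factor == "cause":
            parts.append(record.cause.value)
        else:
            raise ValueError(f"unknown grouping factor {factor!r}")
    return "/".join(parts) if parts else "all"


def monthly_distribution(
    records: Sequence[DeathRecord], by: Sequence[str] = ("sex",)
) -> MonthlyDistribution:
    """Monthly death proportions per group, with peak month(s).

    Groups by ``sex`` and/or the traffic dichotomy ``cause_class``.  Records
    without a death month are excluded (count reported); month ties at the
    maximum are reported as a set, never broken arbitrarily.
    """
    dated = [r for r in records if r.death_month is not None]
    if not dated:
        raise ValueError("no records carry a death month")
    rows: dict[str, np.ndarray] = {}
    for r in dated:
        label = _group_label(r, by)
        if label is None:
            continue
        rows.setdefault(label, np.zeros(12, dtype=int))[r.death_month - 1] += 1
    counts = pd.DataFrame.from_dict(rows, orient="index",
                                    columns=range(1, 13)).sort_index()
    counts.index.name = "group"
    props = counts.div(counts.sum(axis=1), axis=0)
    peaks = {
        g: set(counts.columns[counts.loc[g] == counts.loc[g].max()])
        for g in counts.index
    }
    return MonthlyDistribution(
        counts=counts,
        proportions=props,
        peaks=peaks,
        n_undated=len(records) - len(dated),
    )


@dataclass
class CrossTab:
    """Frequency cross-tabulation with margins and percentage views."""

    rows: str
    cols: str
    counts: pd.DataFrame  # without margins

    @property
    def row_margin(self) -> pd.Series:
        return self.counts.sum(axis=1)

    @property
    def col_margin(self) -> pd.Series:
        return self.counts.sum(axis=0)

    @property
    def total(self) -> int:
        return int(self.counts.to_numpy().sum())

    def percent_total(self) -> pd.DataFrame:
        return 100.0 * self.counts / self.total

    def percent_row(self) -> pd.DataFrame:
        return 100.0 * self.counts.div(self.row_margin.replace(0, np.nan), axis=0).fillna(0.0)

    def percent_col(self) -> pd.DataFrame:
        return 100.0 * self.counts.div(self.col_margin.replace(0, np.nan), axis=1).fillna(0.0)


def _factor_values(records: Sequence[DeathRecord], factor: str) -> list[str]:
    out = []
    for r in records:
        if factor in ("cause_class", "cause2"):
            out.append(cause_class(r))
        elif factor in ("sex", "cause", "habitat", "age_years", "death_month"):
            v = getattr(r, factor)
            out.append(None if v is None else getattr(v, "value", str(v)))
        else:
            raise ValueError(f"unknown factor {factor!r}")
    return out


def crosstab(
    records: Sequence[DeathRecord], rows: str, cols: str | None = None
) -> CrossTab:
    """Cross-tabulate two record factors (or one, against a single column).

    Records with a missing value on either factor are excluded.
    """
    rvals = _factor_values(records, rows)
    cvals = (
        _factor_values(records, cols) if cols is not None else ["n"] * len(records)
    )
    mask = [rv is not None and cv is not None for rv, cv in zip(rvals, cvals)]
    rv = pd.Series([v for v, m in zip(rvals, mask) if m], dtype="object")
    cv = pd.Series([v for v, m in zip(cvals, mask) if m], dtype="object")
    if rv.empty:
        raise ValueError(f"no records carry values for {rows!r}/{cols!r}")
    table = pd.crosstab(rv, cv)
    table.index.name = rows
    table.columns.name = cols or "count"
    return CrossTab(rows=rows, cols=cols or "count", counts=table)


@dataclass
class SexLongevityRatio:
    """Percent by which male newborn life expectancy exceeds female."""

    full_precision: float
    rounded_inputs: float

    def __str__(self) -> str:
        return (
            f"males live {self.full_precision:+.1f}% longer "
            f"({self.rounded_inputs:+.1f}% on 1-d.p. life expectancies)"
        )


def sex_longevity_ratio(e0_male: float, e0_female: float) -> SexLongevityRatio:
    """100 * (e0_male / e0_female - 1), on full-precision inputs and on
    inputs rounded to one decimal (the precision at which life
    expectancies are usually quoted) — both surfaced because the two can
    differ noticeably at small e0."""
    if e0_male <= 0 or e0_female <= 0:
        raise ValueError("life expectancies must be positive")
    full = 100.0 * (e0_male / e0_female - 1.0)
    rounded = 100.0 * (round(e0_male, 1) / round(e0_female, 1) - 1.0)
    return SexLongevityRatio(full_precision=full, rounded_inputs=rounded)
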