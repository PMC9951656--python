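"""Empirical cohort (actuarial) life tables and mortality trajectories.

A single-year cohort life table is built from age-at-death counts by
treating the observed deaths as a synthetic cohort: ``lx`` survivors
entering age ``x`` are the deaths at ages ``>= x``.  Columns follow the
standard actuarial nomenclature:

====  =======================================================
x     exact age at the start of the interval (years)
lx    individuals entering the interval
ndx   deaths in [x, x+1)
nqx   probability of dying, ndx / lx
npx   probability of surviving, 1 - nqx
nLx   person-years lived in the interval, lx - nax * ndx
Tx    person-years lived above age x
ex    life expectancy from age x, Tx / lx
nmx   death rate in the interval, ndx / nLx
nax   mean fraction of the interval lived by those dying (0.5)
====  =======================================================

``nax`` is fixed at 0.5 in every interval (deaths uniform within the year),
including the last — hence an interval in which everyone dies has
``nmx = 1/0.5 = 2`` deaths per person-year.  Internal values are kept at
full precision; rounding happens only when rendering.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from io import StringIO
from pathlib import Path
import numpy as np
import pandas as pd

from .glm import fit_quasipoisson
from .records import AgeCountTable

__all__ = [
    "LifeTable",
    "SurvivorshipType",
    "SurvivorshipClassification",
    "build_life_table",
    "survivorship_curve",
    "hazard_curve",
    "classify_survivorship",
]

COLUMNS = ["x", "lx", "ndx", "nqx", "npx", "nLx", "Tx", "ex", "nmx", "nax"]
NAX = 0.5


class SurvivorshipType(str, Enum):
    TYPE_I = "Type I"     # mortality concentrated late in life (risk rises with age)
    TYPE_II = "Type II"   # constant risk of death with age
    TYPE_III = "Type III"  # mortality concentrated early in life


@dataclass
class SurvivorshipClassification:
    """Hazard-trend diagnostic behind a survivorship-type call.

    ``slope`` is the log-linear trend of the death rate with age, estimated
    by Poisson regression of interval deaths with person-years as exposure;
    the qualitative type is the sign of the slope when it differs from zero
    at level ``alpha``, else Type II.
    """

    survivorship_type: SurvivorshipType
    slope: float
    se: float
    zvalue: float
    pvalue: float
    alpha: float
    n_intervals: int

    def __str__(self) -> str:
        return (
            f"{self.survivorship_type.value} (hazard log-trend {self.slope:+.4f} "
            f"± {self.se:.4f} per year, z = {self.zvalue:.2f}, p = {self.pvalue:.4g}, "
            f"{self.n_intervals} intervals)"
        )


class LifeTable:
    """An empirical single-year cohort life table.

    Build with :meth:`from_counts`; the table carries one row for every
    integer age from 0 through the maximum observed age (ages with zero
    deaths included — survivors pass through them) plus a terminal row at
    max+1 with ``lx = 0`` whose ratio columns are missing (NaN, rendered
    as ``-`` in text output).
    """

    def __init__(self, frame: pd.DataFrame, stratum: str = "all"):
        self.frame = frame
        self.stratum = stratum

    @classmethod
    def from_counts(cls, age_counts: AgeCountTable) -> "LifeTable":
        counts = age_counts.counts
        if not counts or sum(counts.values()) == 0:
            raise ValueError("cannot build a life table from empty age counts")
        max_age = max(counts)
        x = np.arange(max_age + 2)
        ndx = np.array([counts.get(int(a), 0) for a in x], dtype=float)
        lx = ndx[::-1].cumsum()[::-1]
        alive = lx > 0
        with np.errstate(divide="ignore", invalid="ignore"):
            nqx = np.where(alive, ndx / lx, np.nan)
            npx = 1.0 - nqx
            nLx = np.where(alive, lx - NAX * ndx, np.nan)
            Tx = np.nancumsum(np.nan_to_num(nLx)[::-1])[::-1]
            ex = np.where(alive, Tx / lx, np.nan)
            nmx = np.where(alive & (np.nan_to_num(nLx) > 0), ndx / nLx, np.nan)
        frame = pd.DataFrame(
            {
                "x": x,
                "lx": lx,
                "ndx": ndx,
                "nqx": nqx,
                "npx": npx,
                "nLx": nLx,
                "Tx": Tx,
                "ex": ex,
                "nmx": nmx,
                "nax": np.full_like(ndx, NAX),
            }
        )
        return cls(frame, stratum=age_counts.stratum)

    # -- accessors ---------------------------------------------------------
    @property
    def l0(self) -> float:
        return float(self.frame["lx"].iloc[0])

    def __len__(self) -> int:
        return len(self.frame)

    def row(self, age: int) -> pd.Series:
        match = self.frame.loc[self.frame["x"] == age]
        if match.empty:
            raise KeyError(f"age {age} not in life table")
        return match.iloc[0]

    # -- trajectories ------------------------------------------------------
    def survivorship(self) -> pd.Series:
        """Proportion surviving to exact age x (lx / l0); starts at 1."""
        s = self.frame["lx"] / self.l0
        s.index = pd.Index(self.frame["x"], name="x")
        return s.rename("lx_over_l0")

    def hazard(self) -> pd.Series:
        """Death rate nmx by age (missing where no person-years)."""
        h = self.frame["nmx"].copy()
        h.index = pd.Index(self.frame["x"], name="x")
        return h.rename("nmx")

    def conditional_death_probability(self) -> pd.Series:
        """nqx by age, the discrete-time alternative to the death rate."""
        q = self.frame["nqx"].copy()
        q.index = pd.Index(self.frame["x"], name="x")
        return q.rename("nqx")

    # -- survivorship-type classification ---------------------------------
    def classify(self, alpha: float = 0.05) -> SurvivorshipClassification:
        """Classify the survivorship curve via the hazard trend with age.

        Interval deaths are regressed on age by a log-link Poisson model
        with person-years (nLx) as exposure, i.e. a log-linear trend in
        nmx; terminal intervals in which every entrant dies are excluded
        (their rate is pinned at 2 by the nax convention and carries no
        trend information).  Slope significantly positive -> Type I,
        significantly negative -> Type III, otherwise Type II.
        """
        f = self.frame
        usable = (
            (f["lx"] > 0)
            & (f["nLx"] > 0)
            & ~((f["ndx"] == f["lx"]) & (f["lx"] > 0))
        )
        sub = f.loc[usable]
        if len(sub) < 3:
            raise ValueError(
                f"need at least 3 usable intervals to classify, have {len(sub)}"
            )
        X = np.column_stack([np.ones(len(sub)), sub["x"].to_numpy(float)])
        res = fit_quasipoisson(
            sub["ndx"].to_numpy(),
            X,
            exog_names=["const", "age"],
            offset=np.log(sub["nLx"].to_numpy(float)),
            scale=1.0,
            use_t=False,
        )
        slope, se, z, p = (
            float(res.params[1]),
            float(res.bse[1]),
            float(res.tvalues[1]),
            float(res.pvalues[1]),
        )
        if p < alpha and slope > 0:
            stype = SurvivorshipType.TYPE_I
        elif p < alpha and slope < 0:
            stype = SurvivorshipType.TYPE_III
        else:
            stype = SurvivorshipType.TYPE_II
        return SurvivorshipClassification(
            survivorship_type=stype,
            slope=slope,
            se=se,
            zvalue=z,
            pvalue=p,
            alpha=alpha,
            n_intervals=len(sub),
        )

    # -- rendering ---------------------------------------------------------
    def to_text(self, path: str | Path | None = None, delimiter: str = "\t") -> str:
        """Render with the conventional rounding: counts as integers,
        probabilities/rates/ex to 3 decimals, person-years to 1 decimal,
        missing ratio cells as ``-``."""
        out = StringIO()
        out.write(delimiter.join(COLUMNS) + "\n")

        def fmt(v: float, spec: str) -> str:
            return "-" if not np.isfinite(v) else format(v, spec)

        for _, r in self.frame.iterrows():
            cells = [
                f"{int(r['x'])}",
                f"{int(r['lx'])}",
                f"{int(r['ndx'])}",
                fmt(r["nqx"], ".3f"),
                fmt(r["npx"], ".3f"),
                fmt(r["nLx"], ".1f"),
                fmt(r["Tx"], ".1f"),
                fmt(r["ex"], ".3f"),
                fmt(r["nmx"], ".3f"),
                f"{r['nax']:.1f}",
            ]
            out.write(delimiter.join(cells) + "\n")
        text = out.getvalue()
        if path is not None:
            Path(path).write_text(text, encoding="utf-8")
        return text

    def plot(self, ax=None):
        """Survivorship (log scale) and hazard panels; returns the axes."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(1, 2, figsize=(9, 3.5))
        s = self.survivorship()
        h = self.hazard().dropna()
        ax[0].plot(s.index, s.to_numpy(), marker="o", label=self.stratum)
        ax[0].set_yscale("log")
        ax[0].set_xlabel("age (years)")
        ax[0].set_ylabel("proportion surviving  lx/l0")
        ax[1].plot(h.index, h.to_numpy(), marker="o", label=self.stratum)
        ax[1].set_xlabel("age (years)")
        ax[1].set_ylabel("death rate  nmx")
        for a in ax:
            a.legend(frameon=False)
        return ax


# ---------------------------------------------------------------------------
# functional surface


def build_life_table(age_counts: AgeCountTable) -> LifeTable:
    """Build an empirical single-year cohort life table from death counts."""
    return LifeTable.from_counts(age_counts)


def survivorship_curve(lt: LifeTable) -> pd.Series:
    return lt.survivorship()


def hazard_curve(lt: LifeTable) -> pd.Series:
    return lt.hazard()


def classify_survivorship(
    lt: LifeTable, alpha: float = 0.05
) -> SurvivorshipClassification:
    return lt.classify(alpha=alpha)
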