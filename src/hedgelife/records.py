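"""Death-record data model, delimited-text I/O and age tabulation.

The unit of observation is one dead animal with an integer age-at-death in
completed years (for hibernating species, the number of periosteal growth
lines, one per survived hibernation).  Sex and cause of death are closed
categorical codes in which ``unknown`` is an explicit first-class category,
never missing data: studies report counts of unsexed and uncategorised
carcasses and those counts are part of the analysis.
"""

from __future__ import annotations

import csv
import datetime
import logging
from dataclasses import dataclass, field, fields
from enum import Enum
from pathlib import Path
from typing import Callable, Iterable, Sequence

logger = logging.getLogger(__name__)

__all__ = [
    "Sex",
    "Cause",
    "Habitat",
    "DeathRecord",
    "AgeCountTable",
    "read_records",
    "write_records",
    "tabulate_ages",
    "cause_class",
]


class Sex(str, Enum):
    FEMALE = "female"
    MALE = "male"
    UNKNOWN = "unknown"


class Cause(str, Enum):
    TRAFFIC = "traffic"
    IN_CARE = "in_care"
    WILD = "wild"
    UNKNOWN = "unknown"


class Habitat(str, Enum):
    URBAN = "urban"
    RURAL = "rural"
    UNCLASSIFIED = "unclassified"


_SEX_ALIASES = {
    "f": Sex.FEMALE,
    "female": Sex.FEMALE,
    "m": Sex.MALE,
    "male": Sex.MALE,
    "u": Sex.UNKNOWN,
    "unknown": Sex.UNKNOWN,
    "": Sex.UNKNOWN,
}

_CAUSE_ALIASES = {
    "traffic": Cause.TRAFFIC,
    "roadkill": Cause.TRAFFIC,
    "road_kill": Cause.TRAFFIC,
    "in_care": Cause.IN_CARE,
    "in care": Cause.IN_CARE,
    "care": Cause.IN_CARE,
    "wild": Cause.WILD,
    "natural": Cause.WILD,
    "unknown": Cause.UNKNOWN,
    "": Cause.UNKNOWN,
}

_HABITAT_ALIASES = {
    "urban": Habitat.URBAN,
    "rural": Habitat.RURAL,
    "unclassified": Habitat.UNCLASSIFIED,
}


@dataclass
class DeathRecord:
    """One observed animal.

    Parameters
    ----------
    id : str
        Free-text identifier.
    sex : Sex
    age_years : int
        Completed years at death (growth-line count); non-negative.
    death_month : int or None
        Calendar month 1-12; only the month is modelled because all timing
        analyses are monthly.
    cause : Cause
    latitude, longitude : float or None
        Decimal degrees (or a projected coordinate pair, by convention of
        the grid used for habitat classification).
    heterozygosity : float or None
        Observed individual heterozygosity iH_O in [0, 1]; an inverse proxy
        for inbreeding.
    habitat : Habitat or None
    """

    id: str
    sex: Sex
    age_years: int
    death_month: int | None = None
    cause: Cause = Cause.UNKNOWN
    latitude: float | None = None
    longitude: float | None = None
    heterozygosity: float | None = None
    habitat: Habitat | None = None

    def __post_init__(self) -> None:
        self.sex = Sex(self.sex)
        self.cause = Cause(self.cause)
        if self.habitat is not None:
            self.habitat = Habitat(self.habitat)
        if not float(self.age_years).is_integer() or self.age_years < 0:
            raise ValueError(
                f"age_years must be a non-negative integer, got {self.age_years!r}"
            )
        self.age_years = int(self.age_years)
        if self.death_month is not None and not 1 <= self.death_month <= 12:
            raise ValueError(f"death_month must be in 1..12, got {self.death_month!r}")
        if self.heterozygosity is not None and not 0.0 <= self.heterozygosity <= 1.0:
            raise ValueError(
                f"heterozygosity must lie in [0, 1], got {self.heterozygosity!r}"
            )


def cause_class(record: DeathRecord) -> str | None:
    """Dichotomise cause of death into ``traffic`` vs ``non_traffic``.

    In-care and wild deaths merge into ``non_traffic``; unknown causes
    return None and are excluded from dichotomised analyses.
    """
    if record.cause is Cause.TRAFFIC:
        return "traffic"
    if record.cause in (Cause.IN_CARE, Cause.WILD):
        return "non_traffic"
    return None


@dataclass
class AgeCountTable:
    """Counts of deaths per completed age within one stratum.

    Ages absent from ``counts`` mean zero deaths at that age.
    """

    stratum: str
    counts: dict[int, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        clean: dict[int, int] = {}
        for age, n in self.counts.items():
            if int(age) != age or age < 0:
                raise ValueError(f"ages must be non-negative integers, got {age!r}")
            if int(n) != n or n < 0:
                raise ValueError(f"counts must be non-negative integers, got {n!r}")
            if n:
                clean[int(age)] = int(n)
        self.counts = dict(sorted(clean.items()))

    @property
    def n_total(self) -> int:
        return sum(self.counts.values())

    @property
    def max_age(self) -> int:
        if not self.counts:
            raise ValueError("empty age-count table has no maximum age")
        return max(self.counts)

    @classmethod
    def from_ages(cls, ages: Iterable[int], stratum: str = "all") -> "AgeCountTable":
        counts: dict[int, int] = {}
        for a in ages:
            counts[int(a)] = counts.get(int(a), 0) + 1
        return cls(stratum=stratum, counts=counts)

    def ages(self) -> list[int]:
        """Expand back to one age per individual (sorted)."""
        out: list[int] = []
        for age, n in self.counts.items():
            out.extend([age] * n)
        return out


_MANDATORY = ("id", "sex", "age_years")
_COLUMNS = (
    "id",
    "sex",
    "age_years",
    "death_date",
    "cause",
    "latitude",
    "longitude",
    "heterozygosity",
    "habitat",
)


def _parse_month(raw: str) -> int | None:
    raw = raw.strip()
    if not raw:
        return None
    try:
        month = int(raw)
    except ValueError:
        # ISO-8601 date or year-month prefix
        try:
            month = datetime.date.fromisoformat(raw[:10]).month
        except ValueError:
            try:
                month = int(raw[5:7])
            except (ValueError, IndexError):
                raise ValueError(f"cannot parse death date {raw!r}") from None
    if not 1 <= month <= 12:
        raise ValueError(f"death month out of range: {raw!r}")
    return month


def _parse_float(raw: str) -> float | None:
    raw = raw.strip()
    return float(raw) if raw else None


def read_records(path: str | Path, delimiter: str = ",") -> list[DeathRecord]:
    """Read death records from a delimited text file with a header row.

    Unrecognised sex/cause values fall back to ``unknown`` with a logged
    warning; a missing mandatory column (id, sex, age_years) or an invalid
    age is a hard error naming the offender.
    """
    path = Path(path)
    records: list[DeathRecord] = []
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter=delimiter)
        header = reader.fieldnames or []
        for col in _MANDATORY:
            if col not in header:
                raise ValueError(f"mandatory column {col!r} missing from {path}")
        for lineno, row in enumerate(reader, start=2):
            raw_age = (row.get("age_years") or "").strip()
            try:
                age_f = float(raw_age)
            except ValueError:
                raise ValueError(f"{path}:{lineno}: unparseable age {raw_age!r}")
            if not age_f.is_integer() or age_f < 0:
                raise ValueError(
                    f"{path}:{lineno}: age_years must be a non-negative integer, "
                    f"got {raw_age!r}"
                )
            sex_raw = (row.get("sex") or "").strip().lower()
            sex = _SEX_ALIASES.get(sex_raw)
            if sex is None:
                logger.warning("%s:%d: unrecognised sex %r -> unknown", path, lineno, sex_raw)
                sex = Sex.UNKNOWN
            cause_raw = (row.get("cause") or "").strip().lower()
            cause = _CAUSE_ALIASES.get(cause_raw)
            if cause is None:
                logger.warning(
                    "%s:%d: unrecognised cause %r -> unknown", path, lineno, cause_raw
                )
                cause = Cause.UNKNOWN
            habitat_raw = (row.get("habitat") or "").strip().lower()
            habitat = _HABITAT_ALIASES.get(habitat_raw) if habitat_raw else None
            records.append(
                DeathRecord(
                    id=(row.get("id") or "").strip(),
                    sex=sex,
                    age_years=int(age_f),
                    death_month=_parse_month(row.get("death_date") or ""),
                    cause=cause,
                    latitude=_parse_float(row.get("latitude") or ""),
                    longitude=_parse_float(row.get("longitude") or ""),
                    heterozygosity=_parse_float(row.get("heterozygosity") or ""),
                    habitat=habitat,
                )
            )
    return records


def write_records(
    records: Sequence[DeathRecord], path: str | Path, delimiter: str = ","
) -> None:
    """Write records as delimited text; inverse of :func:`read_records`."""
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter=delimiter)
        writer.writerow(_COLUMNS)
        for r in records:
            writer.writerow(
                [
                    r.id,
                    r.sex.value,
                    r.age_years,
                    "" if r.death_month is None else r.death_month,
                    r.cause.value,
                    "" if r.latitude is None else repr(r.latitude),
                    "" if r.longitude is None else repr(r.longitude),
                    "" if r.heterozygosity is None else repr(r.heterozygosity),
                    "" if r.habitat is None else r.habitat.value,
                ]
            )


_FIELD_NAMES = {f.name for f in fields(DeathRecord)}


def tabulate_ages(
    records: Sequence[DeathRecord],
    stratifier: str | Callable[[DeathRecord], str] | None = None,
) -> dict[str, AgeCountTable]:
    """Tabulate age-at-death counts per stratum.

    ``stratifier`` is a record field name (e.g. ``"sex"``), a callable
    mapping a record to a stratum label, or None for a single ``"all"``
    stratum.  Strata are disjoint and exhaustive over the records whose
    stratifier value is not None (records mapping to None are skipped).
    """
    if stratifier is None:
        key: Callable[[DeathRecord], str | None] = lambda r: "all"
    elif callable(stratifier):
        key = stratifier
    else:
        if stratifier not in _FIELD_NAMES:
            raise ValueError(f"unknown record field {stratifier!r}")
        name = stratifier

        def key(r: DeathRecord) -> str | None:
            value = getattr(r, name)
            if value is None:
                return None
            return value.value if isinstance(value, Enum) else str(value)

    counts: dict[str, dict[int, int]] = {}
    for r in records:
        label = key(r)
        if label is None:
            continue
        stratum = counts.setdefault(label, {})
        stratum[r.age_years] = stratum.get(r.age_years, 0) + 1
    return {
        label: AgeCountTable(stratum=label, counts=c) for label, c in counts.items()
    }
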