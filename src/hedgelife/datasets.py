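"""Packaged study data: the published age-at-death distribution.

The Danish citizen-science hedgehog sample (2016; 388 aged carcasses) is
published as a per-sex age-at-death frequency table; the counts below are
that table verbatim.  A packaged delimited file expands the same counts to
one row per animal so the full record pipeline can be exercised without any
download.  Only id, sex and age are known at the individual level here —
months, causes, coordinates and heterozygosity are not printed per
individual and are left blank (the synthetic-cohort generator emulates
their joint structure instead).
"""

from __future__ import annotations

from importlib import resources

from .records import AgeCountTable, DeathRecord, read_records

__all__ = [
    "MALE_AGE_COUNTS",
    "FEMALE_AGE_COUNTS",
    "UNKNOWN_AGE_COUNTS",
    "study_age_counts",
    "study_records",
]

# Deaths per completed age, by sex (177 male, 109 female, 102 unsexed; 388 total).
MALE_AGE_COUNTS: dict[int, int] = {
    0: 43, 1: 54, 2: 23, 3: 29, 4: 6, 5: 7, 6: 8, 9: 2, 10: 2, 11: 1, 13: 1, 16: 1,
}
FEMALE_AGE_COUNTS: dict[int, int] = {0: 39, 1: 21, 2: 15, 3: 18, 4: 9, 5: 6, 6: 1}
UNKNOWN_AGE_COUNTS: dict[int, int] = {0: 27, 1: 40, 2: 16, 3: 6, 4: 7, 5: 2, 6: 2, 10: 2}


def study_age_counts() -> dict[str, AgeCountTable]:
    """Per-sex age-count tables for the packaged study sample."""
    return {
        "male": AgeCountTable("male", dict(MALE_AGE_COUNTS)),
        "female": AgeCountTable("female", dict(FEMALE_AGE_COUNTS)),
        "unknown": AgeCountTable("unknown", dict(UNKNOWN_AGE_COUNTS)),
    }


def study_records() -> list[DeathRecord]:
    """The packaged study sample expanded to one record per animal (n=388)."""
    ref = resources.files("hedgelife.data").joinpath("danish_hedgehog_ages.csv")
    with resources.as_file(ref) as path:
        return read_records(path)
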