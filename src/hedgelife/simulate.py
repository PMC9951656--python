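"""Synthetic death-record cohorts with the statistical structure the
analyses assume.

The generator states a simple demographic world and samples records from
it: sex is multinomial; age-at-death follows sequential annual Bernoulli
survival under a sex-specific hazard schedule (constant annual death
probability for males, a discrete Gompertz ``q(x) = min(1, a e^{bx})`` for
females, a 50/50 latent mixture for unsexed animals); cause of death,
month of death (given sex and the traffic/non-traffic dichotomy) and
habitat (given traffic status) are categorical; individual heterozygosity
is a truncated normal on [0, 1].  A non-zero ``ihet_age_slope`` couples
heterozygosity to longevity by thinning the annual death odds by
``exp(-slope * (iH_O - mean))``, which for a constant hazard scales the
expected age-at-death exactly by ``exp(slope * (iH_O - mean))`` — the
quantity a log-link age regression estimates.

Identical ``(config, seed)`` gives byte-identical output: all draws come
from one integer-seeded generator in a fixed order.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .records import Cause, DeathRecord, Habitat, Sex

__all__ = ["CohortSimConfig", "default_study_config", "simulate_cohort"]

_SIMPLEX_TOL = 1e-12

# Monthly death distributions (per sex x traffic dichotomy), in percent.
# Shaped to the described seasonal structure of a May-December carcass
# collection: both sexes peak in July for traffic deaths (mating-season
# movement), males peak in July and females in September for non-traffic
# deaths (post-lactation condition loss).  Illustrative shapes, not
# estimates: only the peaks are constrained by the study.
_MONTH_PCT: dict[tuple[str, str], list[int]] = {
    ("male", "traffic"): [0, 0, 0, 1, 6, 16, 30, 20, 12, 8, 5, 2],
    ("male", "non_traffic"): [0, 0, 0, 1, 8, 18, 28, 16, 12, 9, 5, 3],
    ("female", "traffic"): [0, 0, 0, 1, 7, 15, 26, 20, 14, 9, 5, 3],
    ("female", "non_traffic"): [0, 0, 0, 1, 5, 8, 12, 18, 26, 16, 9, 5],
}


def _default_month_dist() -> dict[tuple[str, str], tuple[float, ...]]:
    return {k: tuple(v / 100.0 for v in pct) for k, pct in _MONTH_PCT.items()}


def _check_simplex(name: str, probs: Sequence[float]) -> None:
    arr = np.asarray(probs, dtype=float)
    if np.any(arr < 0) or abs(arr.sum() - 1.0) > _SIMPLEX_TOL:
        raise ValueError(f"{name} must be a probability simplex, got {probs!r}")


@dataclass
class CohortSimConfig:
    """All generator parameters.

    Defaults are the packaged study-like world: sex mix 45.6/28.1/26.3 %
    (male/female/unknown), cause mix 55.7/22.2/21.6/0.5 %
    (traffic/in-care/wild/unknown), constant male annual death probability
    0.32 (newborn life expectancy ~2.6 y), female discrete Gompertz
    (0.25, 0.25) (life expectancy ~2.2 y), heterozygosity
    TruncNormal(0.240, 0.074) on [0, 1] with no age effect, and habitat
    37.5/62.5 % urban/rural for traffic deaths.
    """

    n: int = 388
    sex_probs: tuple[float, float, float] = (0.456, 0.281, 0.263)  # male, female, unknown
    male_hazard: float = 0.32
    female_hazard: tuple[float, float] = (0.25, 0.25)  # (a, b): q(x)=min(1, a e^{bx})
    max_age: int = 20
    cause_probs: tuple[float, float, float, float] = (0.557, 0.222, 0.216, 0.005)
    month_dist: dict[tuple[str, str], tuple[float, ...]] = field(
        default_factory=_default_month_dist
    )
    ihet_mean: float = 0.240
    ihet_sd: float = 0.074
    ihet_age_slope: float = 0.0
    habitat_probs: tuple[float, float] = (0.652, 0.348)  # urban, rural | non-traffic
    habitat_probs_traffic: tuple[float, float] = (0.375, 0.625)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 0:
            raise ValueError("cohort size must be non-negative")
        _check_simplex("sex_probs", self.sex_probs)
        _check_simplex("cause_probs", self.cause_probs)
        _check_simplex("habitat_probs", self.habitat_probs)
        _check_simplex("habitat_probs_traffic", self.habitat_probs_traffic)
        for key, dist in self.month_dist.items():
            if len(dist) != 12:
                raise ValueError(f"month_dist[{key!r}] must have 12 entries")
            _check_simplex(f"month_dist[{key!r}]", dist)
        if not 0.0 < self.male_hazard <= 1.0:
            raise ValueError("male_hazard must lie in (0, 1]")
        a, _ = self.female_hazard
        if not 0.0 < a <= 1.0:
            raise ValueError("female_hazard baseline must lie in (0, 1]")
        if self.max_age < 1:
            raise ValueError("max_age must be at least 1")
        if self.ihet_sd <= 0:
            raise ValueError("ihet_sd must be positive")

    # -- plumbing ----------------------------------------------------------
    def to_dict(self) -> dict:
        d = asdict(self)
        d["month_dist"] = {
            f"{sex}/{cc}": list(dist) for (sex, cc), dist in self.month_dist.items()
        }
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "CohortSimConfig":
        d = dict(d)
        if "month_dist" in d:
            parsed = {}
            for key, dist in d["month_dist"].items():
                sex, cc = key.split("/") if isinstance(key, str) else key
                parsed[(sex, cc)] = tuple(float(v) for v in dist)
            d["month_dist"] = parsed
        for key in ("sex_probs", "female_hazard", "cause_probs",
                    "habitat_probs", "habitat_probs_traffic"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "CohortSimConfig":
        import yaml

        with Path(path).open(encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path: str | Path) -> None:
        import yaml

        with Path(path).open("w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    # -- the hazard world --------------------------------------------------
    def hazard(self, sex: str, age: int) -> float:
        """Annual death probability at completed age ``age`` for a latent sex."""
        if sex == "male":
            return self.male_hazard
        a, b = self.female_hazard
        return min(1.0, a * np.exp(b * age))


def default_study_config(n: int = 388, seed: int = 0) -> CohortSimConfig:
    """The packaged configuration emulating the study's structure."""
    return CohortSimConfig(n=n, seed=seed)


def simulate_cohort(
    config: CohortSimConfig | None = None, seed: int | None = None
) -> list[DeathRecord]:
    """Draw a cohort of death records from the configured world.

    ``seed`` overrides ``config.seed``; identical (config, seed) pairs give
    identical record lists.
    """
    config = config or default_study_config()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    n = config.n
    if n == 0:
        return []

    # 1. sex, and the latent hazard schedule for unsexed animals
    u_sex = rng.random(n)
    cum_sex = np.cumsum(config.sex_probs)
    sex_idx = np.searchsorted(cum_sex, u_sex, side="right").clip(0, 2)
    sexes = np.array(["male", "female", "unknown"])[sex_idx]
    latent = sexes.copy()
    unk = latent == "unknown"
    latent[unk] = np.where(rng.random(n)[unk] < 0.5, "male", "female")

    # 2. heterozygosity: truncated normal on [0, 1] via inverse CDF
    lo = (0.0 - config.ihet_mean) / config.ihet_sd
    hi = (1.0 - config.ihet_mean) / config.ihet_sd
    ihet = stats.truncnorm.ppf(
        rng.random(n), lo, hi, loc=config.ihet_mean, scale=config.ihet_sd
    )

    # odds-thinning multiplier coupling heterozygosity to longevity
    odds_mult = np.exp(-config.ihet_age_slope * (ihet - config.ihet_mean))

    # 3. age: sequential annual Bernoulli survival, capped at max_age
    age = np.full(n, config.max_age, dtype=int)
    alive = np.ones(n, dtype=bool)
    q_male_by_age = np.array(
        [config.hazard("male", x) for x in range(config.max_age)]
    )
    q_female_by_age = np.array(
        [config.hazard("female", x) for x in range(config.max_age)]
    )
    is_male_sched = latent == "male"
    for x in range(config.max_age):
        q = np.where(is_male_sched, q_male_by_age[x], q_female_by_age[x])
        with np.errstate(divide="ignore", invalid="ignore"):
            odds = np.where(q < 1.0, q / (1.0 - q), np.inf) * odds_mult
            q_eff = np.where(np.isinf(odds), 1.0, odds / (1.0 + odds))
        dies = alive & (rng.random(n) < q_eff)
        age[dies] = x
        alive &= ~dies

    # 4. cause and its dichotomy
    u_cause = rng.random(n)
    cause_idx = np.searchsorted(np.cumsum(config.cause_probs), u_cause,
                                side="right").clip(0, 3)
    causes = np.array(["traffic", "in_care", "wild", "unknown"])[cause_idx]
    traffic = causes == "traffic"

    # 5. month of death, given latent sex and traffic status
    months = np.empty(n, dtype=int)
    u_month = rng.random(n)
    for sex_key in ("male", "female"):
        for cc, mask in (("traffic", traffic), ("non_traffic", ~traffic)):
            sel = (latent == sex_key) & mask
            if not sel.any():
                continue
            cum = np.cumsum(config.month_dist[(sex_key, cc)])
            months[sel] = np.searchsorted(cum, u_month[sel], side="right").clip(0, 11) + 1

    # 6. habitat, given traffic status
    u_hab = rng.random(n)
    p_urban = np.where(
        traffic, config.habitat_probs_traffic[0], config.habitat_probs[0]
    )
    habitats = np.where(u_hab < p_urban, "urban", "rural")

    width = max(6, len(str(n)))
    return [
        DeathRecord(
            id=f"sim-{i + 1:0{width}d}",
            sex=Sex(sexes[i]),
            age_years=int(age[i]),
            death_month=int(months[i]),
            cause=Cause(causes[i]),
            heterozygosity=float(ihet[i]),
            habitat=Habitat(habitats[i]),
        )
        for i in range(n)
    ]
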