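# hedgelife

Cohort life tables, mortality trajectories and quasi-Poisson age-at-death
models for wildlife death-record data.

`hedgelife` is aimed at wildlife demographers working with opportunistically
collected carcass samples — road kills, animals dying in care, natural
deaths found by volunteers — where each animal contributes a sex, an
integer age-at-death (for hibernators, a periosteal growth-line count: one
line per survived hibernation), a death date, a cause category, and
optionally a location and a genetic heterozygosity score.  It ships with a
packaged sample of 388 aged European hedgehogs (*Erinaceus europaeus*) from
a Danish citizen-science collection, and a synthetic-cohort generator so
every analysis can be exercised and validated without any download.

## What it computes

**Cohort life tables.** Treating the observed deaths as a synthetic cohort,
the single-year actuarial table carries, for each age `x`: survivors `lx`,
deaths `ndx`, death probability `nqx = ndx/lx`, survival probability
`npx = 1 − nqx`, person-years `nLx = lx − nax·ndx` (with `nax = 0.5`:
deaths uniform within the year), cumulative person-years `Tx`, life
expectancy `ex = Tx/lx`, and death rate `nmx = ndx/nLx`.

**Survivorship typing.** The survivorship curve (`lx/l0`) is classified as
Type I (risk rising with age), Type II (constant risk) or Type III (risk
falling with age) via a log-linear hazard-trend test: interval deaths are
regressed on age by a Poisson model with person-years as exposure, and the
type is the sign of the slope when it differs from zero at the 5% level.
The slope, its standard error and p-value are always reported so the
qualitative call is auditable.

**Stratified summaries.** Mean age-at-death with z-based 95% confidence
intervals per stratum, monthly death distributions with peak months (ties
reported as sets), and cause/habitat cross-tabulations.

**Quasi-Poisson GLMs.** Age-at-death regressed on individual
heterozygosity (optionally interacting with the traffic/non-traffic
dichotomy) under a log link with variance `φ·μ`: coefficients are Poisson
maximum likelihood via IRLS, standard errors are scaled by the Pearson
dispersion, and Wald tests use Student's t with `n − p` degrees of freedom.

**Habitat classification.** Each site is labelled urban or rural by
majority vote over the land-cover cells within a 500 m radius of its grid
cell (exactly 81 cells at 100 m resolution), after reclassifying the
integer land-cover codes to urban / rural / other (a CORINE-style default
mapping is included; ties are surfaced as `unclassified`).

## Worked example

```python
import hedgelife as hl

records = hl.study_records()                      # 388 packaged records
strata  = hl.tabulate_ages(records, "sex")        # 177 M / 109 F / 102 unknown
male    = hl.build_life_table(strata["male"])
female  = hl.build_life_table(strata["female"])

print(male.to_text().splitlines()[1])
print(hl.mean_age_ci(records))
print(male.classify())
print(female.classify())
print(hl.sex_longevity_ratio(float(male.row(0)["ex"]),
                             float(female.row(0)["ex"])))
```

prints

```
0	177	43	0.243	0.757	155.5	460.5	2.602	0.277	0.5
all: mean 1.8 y (95% CI [1.62, 2.04], n=388)
Type II (hazard log-trend +0.0005 ± 0.0291 per year, z = 0.02, p = 0.9871, 16 intervals)
Type I (hazard log-trend +0.1916 ± 0.0674 per year, z = 2.84, p = 0.00449, 6 intervals)
males live +22.5% longer (+23.8% on 1-d.p. life expectancies)
```

The first line is the age-0 row of the male life table: 177 males enter,
43 die before age 1 (`nqx = 0.243`), and a newborn male can expect to live
2.602 years.  Male risk of death is flat with age (Type II) while female
risk rises (Type I), so despite heavier male traffic mortality in summer,
males outlive females — by 22.5% on the full-precision life expectancies.

The same pipeline runs from the shell:

```sh
hedgelife simulate --n 400 --seed 11 --out records.csv
hedgelife report --records records.csv --out report/
```

`report` writes the age-count table, per-sex life tables, survivorship
classifications, mean-age estimates, monthly distributions, cause and
road-kill habitat cross-tabs, and (when heterozygosity is present) the
quasi-Poisson coefficient tables.

## Acceptance script

`scripts/acceptance.py` rebuilds the per-sex life tables from the packaged
records and reports the headline cells (life expectancies at birth, death
probabilities and death rates at selected ages) as JSON:

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

## Layout

- `hedgelife.records` — record model, delimited I/O, age tabulation
- `hedgelife.lifetable` — life tables, trajectories, survivorship typing
- `hedgelife.summaries` — means/CIs, monthly peaks, cross-tabs
- `hedgelife.glm` — quasi-Poisson IRLS (model/results objects)
- `hedgelife.habitat` — land-cover grids and urban/rural majority calls
- `hedgelife.simulate` — synthetic-cohort generator
- `hedgelife.reporting`, `hedgelife.cli` — end-to-end pipeline and CLI
- `hedgelife.datasets` — the packaged study sample

See `docs/methods.md` for the statistical conventions, generator design
and known limitations.
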