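"""End-to-end study pipeline: records file in, full table set out.

``run_report`` reads a records file, tabulates ages per sex, builds the
per-sex life tables with survivorship-type diagnostics, computes the
stratified mean-age estimates, monthly distributions, cause and habitat
cross-tabulations, and — when heterozygosity is present — the
quasi-Poisson age models.  Every filter step logs its row count and all
outputs are deterministic given the input file.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
import pandas as pd

from . import glm, summaries
from .lifetable import LifeTable
from .records import read_records, tabulate_ages

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_report"]


@dataclass
class RunConfig:
    records_path: str | Path
    out_dir: str | Path
    delimiter: str = ","
    ci_level: float = 0.95
    stratify: str = "sex"
    min_adult_age: int = 1
    glm_interaction: bool = True
    verbosity: int = logging.INFO


def _write(df: pd.DataFrame, path: Path, float_format: str = "%.6g") -> None:
    df.to_csv(path, sep="\t", float_format=float_format)


def run_report(config: RunConfig) -> dict[str, Path]:
    """Run the full pipeline; returns a name -> path map of outputs."""
    logging.basicConfig(level=config.verbosity)
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, Path] = {}

    records = read_records(config.records_path, delimiter=config.delimiter)
    logger.info("report: %d records read from %s", len(records), config.records_path)

    # age-count table per stratum
    strata = tabulate_ages(records, config.stratify)
    all_ages = sorted({a for t in strata.values() for a in t.counts})
    count_frame = pd.DataFrame(
        {label: {a: t.counts.get(a, 0) for a in all_ages} for label, t in strata.items()}
    ).fillna(0).astype(int)
    count_frame.index.name = "age"
    path = out_dir / "age_counts.tsv"
    _write(count_frame, path)
    outputs["age_counts"] = path

    # per-sex life tables with classification (unknown sex excluded)
    classifications = []
    for label in ("male", "female"):
        if label not in strata:
            continue
        lt = LifeTable.from_counts(strata[label])
        path = out_dir / f"life_table_{label}.tsv"
        path.write_text(lt.to_text(), encoding="utf-8")
        outputs[f"life_table_{label}"] = path
        try:
            cls = lt.classify()
            classifications.append((label, str(cls)))
        except ValueError as exc:
            logger.info("report: survivorship classification skipped for %s (%s)",
                        label, exc)
    if classifications:
        path = out_dir / "survivorship_classification.txt"
        path.write_text(
            "".join(f"{label}\t{text}\n" for label, text in classifications),
            encoding="utf-8",
        )
        outputs["survivorship_classification"] = path

    # mean ages: overall, per stratum, per cause, adults only
    estimates = [summaries.mean_age_ci(records, config.ci_level, stratum="all")]
    for label, table in sorted(strata.items()):
        estimates.append(
            summaries.mean_age_ci(table.ages(), config.ci_level, stratum=label)
        )
    for label, table in sorted(tabulate_ages(records, "cause").items()):
        estimates.append(
            summaries.mean_age_ci(table.ages(), config.ci_level,
                                  stratum=f"cause:{label}")
        )
    estimates.append(
        summaries.mean_age_excluding(records, config.min_adult_age, config.ci_level)
    )
    mean_frame = pd.DataFrame(
        [
            {
                "stratum": e.stratum, "n": e.n, "mean": round(e.mean, 4),
                "sd": round(e.sd, 4) if e.ci_defined else "",
                "ci_low": round(e.ci_low, 4) if e.ci_defined else "",
                "ci_high": round(e.ci_high, 4) if e.ci_defined else "",
            }
            for e in estimates
        ]
    ).set_index("stratum")
    path = out_dir / "mean_ages.tsv"
    _write(mean_frame, path)
    outputs["mean_ages"] = path

    # monthly distributions (sexed, dated records)
    sexed = [r for r in records if r.sex.value != "unknown"]
    logger.info("report: %d records of known sex", len(sexed))
    dated = [r for r in sexed if r.death_month is not None]
    if dated:
        dist = summaries.monthly_distribution(dated, by=("sex", "cause_class"))
        path = out_dir / "monthly_distribution.tsv"
        _write(dist.proportions.round(6), path)
        outputs["monthly_distribution"] = path
        path = out_dir / "peak_months.tsv"
        path.write_text(
            "group\tpeak_months\n"
            + "".join(
                f"{g}\t{','.join(map(str, sorted(m)))}\n"
                for g, m in sorted(dist.peaks.items())
            ),
            encoding="utf-8",
        )
        outputs["peak_months"] = path
    else:
        logger.info("report: monthly distribution skipped (no dated sexed records)")

    # cause mixture
    cause_tab = summaries.crosstab(records, "cause")
    cause_frame = cause_tab.counts.copy()
    cause_frame["percent"] = cause_tab.percent_total()["n"].round(1)
    path = out_dir / "cause_crosstab.tsv"
    _write(cause_frame, path)
    outputs["cause_crosstab"] = path

    # habitat split of traffic deaths
    located = [r for r in records if r.habitat is not None]
    logger.info("report: %d records with habitat classification", len(located))
    roadkill = [r for r in located if r.cause.value == "traffic"]
    if roadkill:
        hab_tab = summaries.crosstab(roadkill, "habitat")
        hab_frame = hab_tab.counts.copy()
        hab_frame["percent"] = hab_tab.percent_total()["n"].round(1)
        path = out_dir / "roadkill_habitat.tsv"
        _write(hab_frame, path)
        outputs["roadkill_habitat"] = path

    # quasi-Poisson age models, when heterozygosity is present
    with_het = [r for r in records if r.heterozygosity is not None]
    logger.info("report: %d records with heterozygosity", len(with_het))
    if len(with_het) >= 3:
        fits = [("age_ihet", glm.fit_age_inbreeding(records))]
        if config.glm_interaction:
            try:
                fits.append(
                    ("age_ihet_x_cause",
                     glm.fit_age_inbreeding(records, interaction_with_cause=True))
                )
            except ValueError as exc:
                logger.info("report: interaction model skipped (%s)", exc)
        path = out_dir / "glm_age_models.txt"
        path.write_text(
            "\n\n".join(f"== {name} ==\n{res.summary()}" for name, res in fits)
            + "\n",
            encoding="utf-8",
        )
        outputs["glm_age_models"] = path
    else:
        logger.info("report: GLM stage skipped (heterozygosity absent)")

    logger.info("report: wrote %d output files to %s", len(outputs), out_dir)
    return outputs
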