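"""End-to-end orchestration: load -> ladder -> map -> join -> aggregate -> report.

Stage order and every intermediate artefact are fixed so a run is auditable:
the free-sugar assignment table (with rung provenance), the SFQ map (with
match methods), the consumptions table, per-subject summaries, the cohort
report, the coverage report and the under-reporting results are all written
to the output directory.  Reruns on identical inputs and config are
byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import diary as diary_mod
from . import food_composition as fc
from . import fs_ladder, intake_metrics, sfq_mapping, under_reporting

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline", "PipelineError"]


class PipelineError(RuntimeError):
    """A stage failure, carrying the stage name for diagnosis."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")


@dataclass
class PipelineConfig:
    food_table: Path
    diary: Path
    subjects: Path
    sfq_groups: Path
    output_dir: Path
    overrides: list[tuple[str, str]] = field(default_factory=list)
    ladder: fs_ladder.LadderConfig = field(default_factory=fs_ladder.LadderConfig)
    match: sfq_mapping.MatchConfig = field(default_factory=sfq_mapping.MatchConfig)
    who_cutoffs: tuple[float, float] = intake_metrics.WHO_CUTOFFS
    bmr_coefficients: Path | None = None  # None -> shipped Schofield set
    under_reporting_cutoff: float = under_reporting.DEFAULT_CUTOFF
    energy_factor: float = intake_metrics.ENERGY_MJ_PER_G_SUGAR
    quantile_method: str = "linear"
    pct_tei_method: str = "ratio_of_means"

    def __post_init__(self) -> None:
        if self.energy_factor <= 0:
            raise PipelineError("config", "energy conversion factor must be positive")
        lo, hi = self.who_cutoffs
        if not lo < hi:
            raise PipelineError("config", f"WHO cutoffs must be ordered, got {self.who_cutoffs}")


@dataclass
class PipelineResult:
    cohort_report: intake_metrics.CohortReport
    coverage: sfq_mapping.CoverageReport
    under_reporting_prevalence: float
    summaries: pd.DataFrame
    consumptions: pd.DataFrame
    assignments: list[fs_ladder.FSAssignment]
    mapping: list[sfq_mapping.MappingEntry]


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:  # keep the stage name in the error
                raise PipelineError(name, str(exc)) from exc

        return wrapped

    return deco


@_stage("load")
def _load(config: PipelineConfig):
    for p in (config.food_table, config.diary, config.subjects, config.sfq_groups):
        if not Path(p).exists():
            raise FileNotFoundError(f"input not found: {p}")
    foods = fc.load_food_table(config.food_table)
    entries = diary_mod.load_diary(config.diary)
    subjects = diary_mod.load_subjects(config.subjects)
    groups = sfq_mapping.load_sfq_groups(config.sfq_groups)
    return foods, entries, subjects, groups


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Run the full analysis and write every intermediate plus final reports."""
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)

    foods, entries, subjects, groups = _load(config)

    assignments = _stage("ladder")(fs_ladder.apply_ladder)(foods, config.ladder)
    pd.DataFrame(
        {
            "food_code": [a.food_code for a in assignments],
            "fs_per100g": [a.fs_per100g for a in assignments],
            "step": [a.step for a in assignments],
            "objective": [a.objective for a in assignments],
            "rationale": [a.rationale for a in assignments],
        }
    ).to_csv(outdir / "fs_assignments.csv", index=False)

    mapping = _stage("map")(sfq_mapping.build_map)(
        foods, groups, config.match, config.overrides
    )
    sfq_mapping.write_map(mapping, outdir / "sfq_map.csv")

    consumptions = _stage("join")(diary_mod.join_nutrients)(entries, foods, assignments)
    consumptions = _stage("map")(sfq_mapping.classify_coverage)(consumptions, mapping)
    consumptions.to_csv(outdir / "consumptions.csv", index=False)

    coverage = _stage("aggregate")(sfq_mapping.coverage_metrics)(consumptions)
    dailies = _stage("aggregate")(intake_metrics.daily_intakes)(consumptions)
    summaries = _stage("aggregate")(intake_metrics.subject_summaries)(
        dailies,
        config.who_cutoffs,
        energy_factor=config.energy_factor,
        pct_tei_method=config.pct_tei_method,  # type: ignore[arg-type]
    )
    report = _stage("report")(intake_metrics.cohort_table)(
        summaries, quantile_method=config.quantile_method
    )
    report.group_contributions = _stage("report")(intake_metrics.group_contributions)(
        consumptions, summaries, energy_factor=config.energy_factor
    )

    coeffs = under_reporting.load_bmr_coefficients(config.bmr_coefficients)
    bmr = _stage("under_reporting")(
        lambda: [under_reporting.predict_bmr(s, coeffs) for s in subjects]
    )()
    results, prevalence = _stage("under_reporting")(
        under_reporting.flag_under_reporters
    )(summaries, bmr, config.under_reporting_cutoff)
    logger.info("under-reporting prevalence: %.1f%%", prevalence)

    dailies.to_csv(outdir / "daily_intakes.csv", index=False)
    summaries.to_csv(outdir / "subject_summaries.csv", index=False)
    pd.DataFrame([dataclasses.asdict(r) for r in results]).to_csv(
        outdir / "under_reporting.csv", index=False
    )
    report.write_json(outdir / "cohort_report.json")
    (outdir / "coverage_report.json").write_text(
        json.dumps(
            {
                **dataclasses.asdict(coverage),
                "fs_noncovered_share": coverage.fs_noncovered_share,
                "ts_noncovered_share": coverage.ts_noncovered_share,
                "schema_version": "1",
            },
            indent=2,
            sort_keys=True,
        ),
        encoding="utf-8",
    )
    (outdir / "under_reporting_prevalence.json").write_text(
        json.dumps({"prevalence_pct": prevalence, "cutoff": config.under_reporting_cutoff}),
        encoding="utf-8",
    )

    return PipelineResult(
        cohort_report=report,
        coverage=coverage,
        under_reporting_prevalence=prevalence,
        summaries=summaries,
        consumptions=consumptions,
        assignments=assignments,
        mapping=mapping,
    )
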