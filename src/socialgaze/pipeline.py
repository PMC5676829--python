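"""End-to-end orchestration: detect -> segment/QC -> metrics -> statistics.

The pipeline is deterministic given its inputs and configuration; every
run can write the resolved configuration next to its outputs so the
bundle is self-describing and re-runnable.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd
import yaml

from . import events, io, stats, trials
from .events import FilterParams, Fixation, combine_eyes, detect_fixations, interpolate_gaps
from .io import RoiSet, TrialInfo
from .simulate import Cohort
from .stats import AnalysisResults, StatsConfig, run_association_analysis
from .trials import ParticipantSummary, QCParams, TrialRecord


@dataclass
class RunConfig:
    """Resolved configuration of one pipeline run."""

    filter_params: FilterParams = field(default_factory=FilterParams)
    qc: QCParams = field(default_factory=QCParams)
    stats: StatsConfig = field(default_factory=StatsConfig)
    seed: int = 0

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(
                {
                    "filter_params": asdict(self.filter_params),
                    "qc": asdict(self.qc),
                    "stats": asdict(self.stats),
                    "seed": self.seed,
                },
                fh,
                sort_keys=False,
            )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(
            filter_params=FilterParams(**raw.get("filter_params", {})),
            qc=QCParams(**raw.get("qc", {})),
            stats=StatsConfig(**raw.get("stats", {})),
            seed=int(raw.get("seed", 0)),
        )


@dataclass
class ParticipantResult:
    participant_id: str
    fixations: list[Fixation]
    records: list[TrialRecord]
    summary: ParticipantSummary


@dataclass
class CohortResults:
    trial_metrics: pd.DataFrame
    summaries: pd.DataFrame
    analysis: AnalysisResults | None
    log_lines: list[str]

    def log(self) -> str:
        return "\n".join(self.log_lines) + "\n"


def process_participant(
    participant_id: str,
    gaze: pd.DataFrame,
    trial_infos: Sequence[TrialInfo],
    roi_set: RoiSet,
    filter_params: FilterParams = FilterParams(),
    qc: QCParams = QCParams(),
) -> ParticipantResult:
    """Run detection, segmentation, QC and metrics for one recording."""
    points = interpolate_gaps(combine_eyes(gaze), filter_params.max_gap_interp_ms)
    fixations = detect_fixations(points, filter_params)
    records = trials.process_trials(
        gaze, trial_infos, fixations, roi_set, qc, points=points
    )
    summary = trials.summarize_participant(participant_id, records, qc)
    return ParticipantResult(participant_id, fixations, records, summary)


def analyze_cohort(
    gaze_by_participant: dict[str, pd.DataFrame],
    trial_infos: Sequence[TrialInfo],
    roi_set: RoiSet,
    traits: pd.DataFrame,
    config: RunConfig = RunConfig(),
    run_stats: bool = True,
) -> CohortResults:
    """Process every participant and run the association analysis."""
    log: list[str] = []
    metric_frames = []
    summaries: list[ParticipantSummary] = []
    reason_counts: Counter[str] = Counter()
    n_trials = 0
    n_excluded = 0
    dropped: list[str] = []
    for pid in sorted(gaze_by_participant):
        res = process_participant(
            pid, gaze_by_participant[pid], trial_infos, roi_set,
            config.filter_params, config.qc,
        )
        metric_frames.append(trials.trial_metrics_frame(pid, res.records))
        n_trials += len(res.records)
        for r in res.records:
            if not r.included:
                n_excluded += 1
                reason_counts.update(r.qc_reasons)
        if res.summary.n_included_trials == 0:
            dropped.append(pid)
            log.append(f"participant {pid}: no included trials; dropped from analysis")
        else:
            summaries.append(res.summary)

    log.append(
        f"trials: read={n_trials} included={n_trials - n_excluded} excluded={n_excluded}"
    )
    for reason, count in sorted(reason_counts.items()):
        log.append(f"excluded_reason {reason}: {count}")
    log.append(
        f"participants: read={len(gaze_by_participant)} retained={len(summaries)} "
        f"dropped={len(dropped)}"
    )
    summary_df = trials.summaries_frame(summaries)
    if len(summary_df):
        n_eligible = int(summary_df["contrast_eligible"].sum())
        log.append(f"participants eligible for cued/silent contrast: {n_eligible}")

    analysis = None
    if run_stats:
        analysis = run_association_analysis(summary_df, traits, config.stats)
        log.append(
            f"association analysis over {analysis.n_participants} complete cases"
        )
    return CohortResults(
        trial_metrics=pd.concat(metric_frames, ignore_index=True)
        if metric_frames
        else pd.DataFrame(),
        summaries=summary_df,
        analysis=analysis,
        log_lines=log,
    )


def analyze_cohort_object(
    cohort: Cohort, config: RunConfig = RunConfig(), run_stats: bool = True
) -> CohortResults:
    """Convenience wrapper for an in-memory synthetic cohort."""
    return analyze_cohort(
        cohort.gaze, cohort.trial_infos, cohort.roi_set, cohort.traits,
        config=config, run_stats=run_stats,
    )


def load_cohort_dir(input_dir: str | Path) -> tuple[dict[str, pd.DataFrame], list[TrialInfo], RoiSet, pd.DataFrame]:
    """Load a cohort directory written by the generator (or equivalent)."""
    input_dir = Path(input_dir)
    trial_infos = io.read_trial_log(input_dir / "trial_log.csv")
    roi_set = io.read_roi_config(input_dir / "roi_config.json")
    traits = io.read_trait_table(input_dir / "traits.csv")
    gaze = {}
    for path in sorted(input_dir.glob("gaze_*.tsv")):
        pid = path.stem.removeprefix("gaze_")
        gaze[pid] = io.read_gaze_log(path)
    if not gaze:
        raise io.GazeIOError(f"no gaze logs (gaze_*.tsv) found in {input_dir}")
    return gaze, trial_infos, roi_set, traits


def run_all(
    input_dir: str | Path,
    output_dir: str | Path,
    config: RunConfig = RunConfig(),
) -> CohortResults:
    """Disk-to-disk run: read a cohort directory, write the results bundle.

    The bundle holds the trial metrics CSV, the participant summary CSV,
    the statistics results CSV, a text report, the run log and the
    resolved configuration.
    """
    output_dir = Path(output_dir)
    output_dir.mkdir(parents=True, exist_ok=True)
    gaze, trial_infos, roi_set, traits = load_cohort_dir(input_dir)
    results = analyze_cohort(gaze, trial_infos, roi_set, traits, config=config)
    results.trial_metrics.to_csv(output_dir / "trial_metrics.csv", index=False)
    results.summaries.to_csv(output_dir / "participant_summaries.csv", index=False)
    if results.analysis is not None:
        results.analysis.tests.to_csv(output_dir / "results.csv", index=False)
        with open(output_dir / "report.txt", "w") as fh:
            fh.write(results.analysis.report())
    with open(output_dir / "run.log", "w") as fh:
        fh.write(results.log())
    config.to_yaml(output_dir / "resolved_config.yaml")
    return results
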