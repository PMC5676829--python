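"""Trial segmentation, quality control, and ROI attention metrics.

Each stimulus presentation is checked against four inclusion rules
before its dependent measures are used:

* ``anticipatory`` — the first fixation on the target (eyes) ROI started
  less than 100 ms after array onset; the trial is discarded entirely.
* ``low_validity`` — fewer than 33% of the trial's raw samples have
  high-quality data from both eyes (validity codes 0 or 1).
* ``baseline_fail`` — gaze was inside the central ROI for less than 50%
  of the pre-onset baseline interval; missing samples count against.
* ``no_target_fixation`` — no fixation landed on the eyes ROI; the trial
  contributes to neither dependent measure but still counts as a valid
  recording for condition-eligibility accounting.

The two dependent measures are the latency from array onset to the start
of the first fixation in the eyes ROI (bottom-up orienting), and the
first-pass dwell: total fixation time in the eyes ROI from first entry
until the first fixation outside it (maintained engagement).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .events import Fixation, GazePoints, combine_eyes
from .io import Rect, RoiSet, TrialInfo, point_in_roi

#: QC reasons that invalidate the recording itself (used for the
#: cued/silent eligibility rule); no_target_fixation is behavioural and
#: keeps the trial countable as validly recorded.
RECORDING_QC_REASONS = ("anticipatory", "low_validity", "baseline_fail")


@dataclass(frozen=True)
class QCParams:
    """Trial inclusion thresholds."""

    anticipatory_ms: float = 100.0
    validity_min: float = 0.33
    baseline_min: float = 0.5
    contrast_eligibility: float = 0.5

    def __post_init__(self) -> None:
        if not 0 < self.validity_min <= 1 or not 0 < self.baseline_min <= 1:
            raise ValueError("validity_min and baseline_min must lie in (0, 1]")
        if self.anticipatory_ms < 0:
            raise ValueError("anticipatory_ms must be non-negative")


@dataclass
class TrialRecord:
    """One stimulus presentation with its samples, fixations and QC state."""

    info: TrialInfo
    t: np.ndarray  # sample times in [onset, offset)
    both_valid: np.ndarray  # per-sample: both eyes validity in {0, 1}
    baseline_x: np.ndarray  # cyclopean positions in the baseline interval
    baseline_y: np.ndarray
    fixations: list[Fixation]  # clipped to [onset, offset), time-ordered
    qc_reasons: list[str] = field(default_factory=list)
    latency_to_eyes_ms: float | None = None
    first_pass_dwell_ms: float | None = None

    @property
    def included(self) -> bool:
        return not self.qc_reasons

    @property
    def valid_recording(self) -> bool:
        """Passes the recording-quality rules (behavioural absence allowed)."""
        return not any(r in RECORDING_QC_REASONS for r in self.qc_reasons)

    @property
    def n_samples(self) -> int:
        return len(self.t)


@dataclass
class ParticipantSummary:
    """Per-participant aggregation of the two attention measures."""

    participant_id: str
    mean_latency_ms: float
    mean_dwell_ms: float
    mean_latency_silent_ms: float
    mean_latency_cued_ms: float
    mean_dwell_silent_ms: float
    mean_dwell_cued_ms: float
    n_included_trials: int
    n_trials: int
    valid_fraction_silent: float
    valid_fraction_cued: float
    contrast_eligible: bool


def segment_trials(
    samples: pd.DataFrame,
    trials: Sequence[TrialInfo],
    fixations: Sequence[Fixation],
    points: GazePoints | None = None,
) -> list[TrialRecord]:
    """Cut a recording into per-trial records.

    A trial owns the samples with ``onset <= t < offset`` plus its
    baseline-interval samples.  Fixations overlapping the stimulus window
    are attached clipped to it, so a fixation straddling the onset
    contributes only its post-onset portion to trial accounting.
    """
    if points is None:
        points = combine_eyes(samples)
    t = samples["t_ms"].to_numpy(dtype=float)
    both_valid = (
        (samples["left_validity"].to_numpy() <= 1)
        & (samples["right_validity"].to_numpy() <= 1)
    )
    records = []
    for info in trials:
        sel = (t >= info.onset_ms) & (t < info.offset_ms)
        bsel = (points.t >= info.baseline_start_ms) & (points.t < info.baseline_end_ms)
        fixs = [
            f.clipped(info.onset_ms, info.offset_ms)
            for f in fixations
            if f.end_ms > info.onset_ms and f.start_ms < info.offset_ms
        ]
        records.append(
            TrialRecord(
                info=info,
                t=t[sel],
                both_valid=both_valid[sel],
                baseline_x=points.x[bsel],
                baseline_y=points.y[bsel],
                fixations=fixs,
            )
        )
    return records


def validity_fraction(trial: TrialRecord) -> float:
    """Fraction of trial samples with both eyes reliably tracked."""
    if trial.n_samples == 0:
        return 0.0
    return float(np.mean(trial.both_valid))


def baseline_center_fraction(trial: TrialRecord, center_roi: Rect) -> float:
    """Fraction of the baseline interval spent inside the central ROI.

    Missing samples count against the fraction (they are in the
    denominator but can never be inside the ROI).
    """
    n = len(trial.baseline_x)
    if n == 0:
        return 0.0
    inside = sum(
        point_in_roi(x, y, center_roi)
        for x, y in zip(trial.baseline_x, trial.baseline_y)
    )
    return inside / n


def latency_to_target(
    trial: TrialRecord, eyes_roi: Rect
) -> float | None:
    """Latency from array onset to the first fixation in the eyes ROI.

    Fixation membership is by centroid.  Returns None when no trial
    fixation lands in the ROI.
    """
    for f in trial.fixations:
        if point_in_roi(f.centroid_x, f.centroid_y, eyes_roi):
            return f.start_ms - trial.info.onset_ms
    return None


def first_pass_dwell(trial: TrialRecord, eyes_roi: Rect) -> float | None:
    """Total fixation time in the eyes ROI from first entry to first exit.

    Sums the durations of the maximal run of consecutive fixations whose
    centroids stay in the ROI, starting at the first in-ROI fixation;
    inter-fixation gaps are not counted, and the run ends at the first
    fixation outside the ROI or at trial offset (fixations are already
    clipped to the trial window).
    """
    dwell = 0.0
    entered = False
    for f in trial.fixations:
        if point_in_roi(f.centroid_x, f.centroid_y, eyes_roi):
            entered = True
            dwell += f.duration_ms
        elif entered:
            break
    return dwell if entered else None


def apply_qc(
    trial: TrialRecord, roi_set: RoiSet, qc: QCParams = QCParams()
) -> TrialRecord:
    """Evaluate all inclusion rules and compute the trial's measures in place."""
    trial.qc_reasons = []
    if trial.n_samples == 0 or validity_fraction(trial) < qc.validity_min:
        trial.qc_reasons.append("low_validity")
    center = roi_set.center_roi(trial.info.array_id)
    if len(trial.baseline_x) == 0 or baseline_center_fraction(trial, center) < qc.baseline_min:
        trial.qc_reasons.append("baseline_fail")
    eyes = roi_set.eyes_roi(trial.info.array_id)
    latency = latency_to_target(trial, eyes)
    if latency is None:
        trial.qc_reasons.append("no_target_fixation")
    else:
        if latency < qc.anticipatory_ms:
            trial.qc_reasons.append("anticipatory")
        trial.latency_to_eyes_ms = latency
        trial.first_pass_dwell_ms = first_pass_dwell(trial, eyes)
    return trial


def process_trials(
    samples: pd.DataFrame,
    trials: Sequence[TrialInfo],
    fixations: Sequence[Fixation],
    roi_set: RoiSet,
    qc: QCParams = QCParams(),
    points: GazePoints | None = None,
) -> list[TrialRecord]:
    """Segment, QC and measure all trials of one recording."""
    records = segment_trials(samples, trials, fixations, points=points)
    for r in records:
        apply_qc(r, roi_set, qc)
    return records


def _mean_or_nan(vals: list[float]) -> float:
    return float(np.mean(vals)) if vals else float("nan")


def summarize_participant(
    participant_id: str,
    records: Sequence[TrialRecord],
    qc: QCParams = QCParams(),
) -> ParticipantSummary:
    """Aggregate trial measures for one participant.

    Means are taken only over included trials carrying the measure.  A
    participant is eligible for the cued/silent contrast when at least
    ``qc.contrast_eligibility`` of the trials in *each* condition are
    valid recordings.
    """
    included = [r for r in records if r.included]

    def _means(rs: Iterable[TrialRecord]) -> tuple[float, float]:
        rs = list(rs)
        lat = [r.latency_to_eyes_ms for r in rs if r.latency_to_eyes_ms is not None]
        dw = [r.first_pass_dwell_ms for r in rs if r.first_pass_dwell_ms is not None]
        return _mean_or_nan(lat), _mean_or_nan(dw)

    lat_all, dwell_all = _means(included)
    lat_s, dwell_s = _means(r for r in included if r.info.condition == "silent")
    lat_c, dwell_c = _means(r for r in included if r.info.cued)

    silent = [r for r in records if r.info.condition == "silent"]
    cued = [r for r in records if r.info.cued]
    vf_s = (
        sum(r.valid_recording for r in silent) / len(silent) if silent else float("nan")
    )
    vf_c = sum(r.valid_recording for r in cued) / len(cued) if cued else float("nan")
    eligible = (
        bool(silent)
        and bool(cued)
        and vf_s >= qc.contrast_eligibility
        and vf_c >= qc.contrast_eligibility
    )
    return ParticipantSummary(
        participant_id=participant_id,
        mean_latency_ms=lat_all,
        mean_dwell_ms=dwell_all,
        mean_latency_silent_ms=lat_s,
        mean_latency_cued_ms=lat_c,
        mean_dwell_silent_ms=dwell_s,
        mean_dwell_cued_ms=dwell_c,
        n_included_trials=len(included),
        n_trials=len(records),
        valid_fraction_silent=vf_s,
        valid_fraction_cued=vf_c,
        contrast_eligible=eligible,
    )


def trial_metrics_frame(
    participant_id: str, records: Sequence[TrialRecord]
) -> pd.DataFrame:
    """Per-trial metrics table for CSV export."""
    rows = []
    for r in records:
        rows.append(
            (
                participant_id,
                r.info.trial_id,
                r.info.condition,
                "included" if r.included else "excluded",
                ";".join(r.qc_reasons),
                r.latency_to_eyes_ms if r.included else np.nan,
                r.first_pass_dwell_ms if r.included else np.nan,
            )
        )
    return pd.DataFrame(
        rows,
        columns=[
            "participant_id",
            "trial_id",
            "condition",
            "qc_status",
            "qc_reasons",
            "latency_to_eyes_ms",
            "first_pass_dwell_ms",
        ],
    )


def summaries_frame(summaries: Sequence[ParticipantSummary]) -> pd.DataFrame:
    """Participant-summary table for CSV export and the statistics layer."""
    return pd.DataFrame([vars(s) for s in summaries])
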