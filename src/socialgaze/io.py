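"""Readers and writers for gaze logs, trial logs, ROI configs and trait tables.

Conventions used throughout the package:

* Screen coordinates are pixels with the origin at the top-left corner,
  x increasing rightward and y increasing downward.
* Times are milliseconds from recording start, stored as floats.
* ROI rectangles are half-open on both axes (a point on the right or
  bottom edge is outside), so rectangles sharing an edge never both
  contain a point.
* A gaze log is a tab-separated file with one header line and columns
  ``t_ms, left_x, left_y, left_validity, right_x, right_y,
  right_validity``.  A missing position is an empty field, never (0, 0).
  Validity codes follow the 0-4 tracker convention where 0-1 means the
  eye was reliably tracked.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

GAZE_COLUMNS = (
    "t_ms",
    "left_x",
    "left_y",
    "left_validity",
    "right_x",
    "right_y",
    "right_validity",
)

TRIAL_COLUMNS = (
    "trial_id",
    "array_id",
    "onset_ms",
    "offset_ms",
    "condition",
    "baseline_start_ms",
    "baseline_end_ms",
)

CONDITIONS = ("silent", "phoneme", "beep")
CUED_CONDITIONS = ("phoneme", "beep")

STIMULUS_LABELS = ("eyes", "distractor_1", "distractor_2", "distractor_3")
CENTER_LABEL = "center"

#: nominal inter-sample interval of a 120 Hz recording, in ms
SAMPLE_INTERVAL_MS = 1000.0 / 120.0


class GazeIOError(ValueError):
    """Raised for unrecoverable problems in an on-disk artifact."""


class RoiValidationError(GazeIOError):
    """Raised when an ROI configuration violates the geometry contract."""


# ---------------------------------------------------------------------------
# geometry
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Rect:
    """Axis-aligned screen rectangle, half-open on both axes."""

    x0: float
    y0: float
    width: float
    height: float

    def __post_init__(self) -> None:
        if not (self.width > 0 and self.height > 0):
            raise RoiValidationError(f"rectangle must have positive size, got {self}")

    @property
    def center(self) -> tuple[float, float]:
        return (self.x0 + self.width / 2.0, self.y0 + self.height / 2.0)

    def contains(self, x: float, y: float) -> bool:
        return point_in_roi(x, y, self)

    def overlaps(self, other: "Rect") -> bool:
        return (
            self.x0 < other.x0 + other.width
            and other.x0 < self.x0 + self.width
            and self.y0 < other.y0 + other.height
            and other.y0 < self.y0 + self.height
        )

    def to_dict(self) -> dict:
        return {"x0": self.x0, "y0": self.y0, "width": self.width, "height": self.height}


def point_in_roi(x: float, y: float, rect: Rect) -> bool:
    """Half-open membership test: ``x0 <= x < x0+width`` and likewise in y.

    Non-finite coordinates (missing samples) are never inside any ROI.
    """
    if not (math.isfinite(x) and math.isfinite(y)):
        return False
    return (rect.x0 <= x < rect.x0 + rect.width) and (
        rect.y0 <= y < rect.y0 + rect.height
    )


@dataclass
class RoiSet:
    """ROI geometry for a stimulus-array paradigm.

    One entry per array: the four equally sized stimulus rectangles
    (``eyes`` plus three distractors) and a ``center`` rectangle used for
    the baseline attention check.
    """

    arrays: dict[int, dict[str, Rect]]
    screen_width: float = 1280.0
    screen_height: float = 1024.0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        ref_size: tuple[float, float] | None = None
        for array_id, rois in sorted(self.arrays.items()):
            labels = set(rois)
            missing = (set(STIMULUS_LABELS) | {CENTER_LABEL}) - labels
            if missing:
                raise RoiValidationError(
                    f"array {array_id}: missing ROI labels {sorted(missing)}"
                )
            stim = [rois[lab] for lab in STIMULUS_LABELS]
            sizes = {(r.width, r.height) for r in stim}
            if len(sizes) != 1:
                raise RoiValidationError(
                    f"array {array_id}: stimulus ROIs must be of equal size, got {sizes}"
                )
            if ref_size is None:
                ref_size = next(iter(sizes))
            for i, a in enumerate(stim):
                for b in stim[i + 1 :]:
                    if a.overlaps(b):
                        raise RoiValidationError(
                            f"array {array_id}: overlapping stimulus ROIs {a} and {b}"
                        )

    def stimulus_rois(self, array_id: int) -> dict[str, Rect]:
        return {lab: self.arrays[array_id][lab] for lab in STIMULUS_LABELS}

    def eyes_roi(self, array_id: int) -> Rect:
        return self.arrays[array_id]["eyes"]

    def center_roi(self, array_id: int) -> Rect:
        return self.arrays[array_id][CENTER_LABEL]


# ---------------------------------------------------------------------------
# trial metadata and traits
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TrialInfo:
    """Metadata for one stimulus-array presentation."""

    trial_id: int
    array_id: int
    onset_ms: float
    offset_ms: float
    condition: str
    baseline_start_ms: float
    baseline_end_ms: float

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS:
            raise GazeIOError(
                f"trial {self.trial_id}: unknown condition {self.condition!r}"
            )
        if not self.onset_ms < self.offset_ms:
            raise GazeIOError(f"trial {self.trial_id}: onset must precede offset")
        if not self.baseline_start_ms < self.baseline_end_ms:
            raise GazeIOError(f"trial {self.trial_id}: empty baseline interval")
        if self.baseline_end_ms > self.onset_ms:
            raise GazeIOError(
                f"trial {self.trial_id}: baseline interval must precede stimulus onset"
            )

    @property
    def cued(self) -> bool:
        return self.condition in CUED_CONDITIONS


# ---------------------------------------------------------------------------
# gaze logs
# ---------------------------------------------------------------------------


def _parse_position(fx: str, fy: str, validity: int, row: int) -> tuple[float, float]:
    if fx == "" and fy == "":
        if validity <= 1:
            raise _RowError(f"row {row}: missing position for a valid eye")
        return (math.nan, math.nan)
    if fx == "" or fy == "":
        raise _RowError(f"row {row}: half-missing position")
    return (float(fx), float(fy))


class _RowError(ValueError):
    pass


def read_gaze_log(path: str | Path) -> pd.DataFrame:
    """Read a gaze log into a DataFrame with the canonical seven columns.

    Missing positions come back as NaN.  Rows that cannot be parsed are
    skipped and reported in ``df.attrs["rejected_rows"]`` as
    ``(row_number, reason)`` pairs (row numbers are 1-based and count the
    header), so ``len(df) + len(rejects)`` always equals the number of
    data rows in the file.  Structural problems — wrong header, an
    unknown validity code, non-monotone timestamps — raise
    :class:`GazeIOError` naming the first offending row.
    """
    path = Path(path)
    rows: list[tuple] = []
    rejects: list[tuple[int, str]] = []
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if tuple(header) != GAZE_COLUMNS:
            raise GazeIOError(
                f"{path}: bad header {header!r}, expected {list(GAZE_COLUMNS)}"
            )
        last_t = -math.inf
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 7:
                rejects.append((lineno, f"expected 7 fields, got {len(fields)}"))
                continue
            try:
                t = float(fields[0])
                lv = int(fields[3])
                rv = int(fields[6])
            except ValueError as exc:
                rejects.append((lineno, f"unparseable field: {exc}"))
                continue
            for code, eye in ((lv, "left"), (rv, "right")):
                if code not in (0, 1, 2, 3, 4):
                    raise GazeIOError(
                        f"{path}: row {lineno}: unknown {eye} validity code {code}"
                    )
            if t <= last_t:
                raise GazeIOError(
                    f"{path}: row {lineno}: non-monotone timestamp {t} after {last_t}"
                )
            try:
                lx, ly = _parse_position(fields[1], fields[2], lv, lineno)
                rx, ry = _parse_position(fields[4], fields[5], rv, lineno)
            except (_RowError, ValueError) as exc:
                rejects.append((lineno, str(exc)))
                continue
            last_t = t
            rows.append((t, lx, ly, lv, rx, ry, rv))
    df = pd.DataFrame(rows, columns=list(GAZE_COLUMNS))
    df["left_validity"] = df["left_validity"].astype(int) if len(df) else df["left_validity"]
    df["right_validity"] = df["right_validity"].astype(int) if len(df) else df["right_validity"]
    df.attrs["rejected_rows"] = rejects
    return df


def _fmt_pos(v: float) -> str:
    return "" if not math.isfinite(v) else f"{v:.2f}"


def write_gaze_log(df: pd.DataFrame, path: str | Path) -> None:
    """Write a gaze DataFrame in the canonical tab-separated dialect.

    Times are written with three decimals, positions with two; a missing
    position is an empty field.  ``write_gaze_log(read_gaze_log(f))``
    reproduces ``f`` byte for byte for files in this dialect.
    """
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(GAZE_COLUMNS) + "\n")
        for t, lx, ly, lv, rx, ry, rv in df[list(GAZE_COLUMNS)].itertuples(index=False):
            fh.write(
                f"{t:.3f}\t{_fmt_pos(lx)}\t{_fmt_pos(ly)}\t{int(lv)}\t"
                f"{_fmt_pos(rx)}\t{_fmt_pos(ry)}\t{int(rv)}\n"
            )


# ---------------------------------------------------------------------------
# trial logs
# ---------------------------------------------------------------------------


def read_trial_log(path: str | Path, require_paradigm: bool = False) -> list[TrialInfo]:
    """Read a trial log CSV into a list of :class:`TrialInfo`.

    With ``require_paradigm`` the standard 12-trial composition (4 silent,
    8 cued) is enforced.
    """
    df = pd.read_csv(path)
    missing = set(TRIAL_COLUMNS) - set(df.columns)
    if missing:
        raise GazeIOError(f"{path}: trial log missing columns {sorted(missing)}")
    trials = [
        TrialInfo(
            trial_id=int(r.trial_id),
            array_id=int(r.array_id),
            onset_ms=float(r.onset_ms),
            offset_ms=float(r.offset_ms),
            condition=str(r.condition),
            baseline_start_ms=float(r.baseline_start_ms),
            baseline_end_ms=float(r.baseline_end_ms),
        )
        for r in df.itertuples(index=False)
    ]
    for a, b in zip(trials, trials[1:]):
        if b.onset_ms < a.offset_ms:
            raise GazeIOError(
                f"trials {a.trial_id} and {b.trial_id} have overlapping intervals"
            )
    if require_paradigm:
        n_silent = sum(t.condition == "silent" for t in trials)
        n_cued = sum(t.cued for t in trials)
        if len(trials) != 12 or n_silent != 4 or n_cued != 8:
            raise GazeIOError(
                f"expected 12 trials (4 silent, 8 cued); got {len(trials)} "
                f"({n_silent} silent, {n_cued} cued)"
            )
    return trials


def write_trial_log(trials: Sequence[TrialInfo], path: str | Path) -> None:
    df = pd.DataFrame(
        [
            (
                t.trial_id,
                t.array_id,
                t.onset_ms,
                t.offset_ms,
                t.condition,
                t.baseline_start_ms,
                t.baseline_end_ms,
            )
            for t in trials
        ],
        columns=list(TRIAL_COLUMNS),
    )
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# ROI configs
# ---------------------------------------------------------------------------


def read_roi_config(path: str | Path, require_complete: bool = True) -> RoiSet:
    """Load an ROI configuration (JSON) and validate its geometry.

    The file lists each array's ROIs explicitly so that duplicate labels
    are detectable::

        {"screen": {"width": 1280, "height": 1024},
         "arrays": [{"array_id": 1,
                     "rois": [{"label": "eyes", "x0": .., "y0": .., ...}, ...]},
                    ...]}
    """
    with open(path) as fh:
        cfg = json.load(fh)
    arrays: dict[int, dict[str, Rect]] = {}
    for entry in cfg["arrays"]:
        array_id = int(entry["array_id"])
        rois: dict[str, Rect] = {}
        for r in entry["rois"]:
            label = r["label"]
            if label in rois:
                raise RoiValidationError(
                    f"array {array_id}: duplicate ROI label {label!r}"
                )
            rois[label] = Rect(
                float(r["x0"]), float(r["y0"]), float(r["width"]), float(r["height"])
            )
        arrays[array_id] = rois
    if require_complete and sorted(arrays) != list(range(1, 13)):
        raise RoiValidationError(
            f"ROI config must list arrays 1-12, got {sorted(arrays)}"
        )
    screen = cfg.get("screen", {})
    return RoiSet(
        arrays,
        screen_width=float(screen.get("width", 1280)),
        screen_height=float(screen.get("height", 1024)),
    )


def write_roi_config(roi_set: RoiSet, path: str | Path) -> None:
    cfg = {
        "screen": {"width": roi_set.screen_width, "height": roi_set.screen_height},
        "arrays": [
            {
                "array_id": array_id,
                "rois": [
                    {"label": lab, **rect.to_dict()} for lab, rect in rois.items()
                ],
            }
            for array_id, rois in sorted(roi_set.arrays.items())
        ],
    }
    with open(path, "w") as fh:
        json.dump(cfg, fh, indent=1)
        fh.write("\n")


# ---------------------------------------------------------------------------
# trait tables
# ---------------------------------------------------------------------------

TRAIT_REQUIRED = ("participant_id", "srs_total", "spaic_total")

SRS_SUBSCALES = (
    "srs_social_awareness",
    "srs_social_communication",
    "srs_social_cognition",
    "srs_social_motivation",
    "srs_rrb",
)


def read_trait_table(path: str | Path) -> pd.DataFrame:
    """Read a participant trait table (SRS / SPAI-C raw scores).

    ``spaic_total`` may be missing for individual participants (NaN);
    negative scores are rejected.
    """
    df = pd.read_csv(path)
    missing = set(TRAIT_REQUIRED) - set(df.columns)
    if missing:
        raise GazeIOError(f"{path}: trait table missing columns {sorted(missing)}")
    score_cols = [
        c for c in df.columns if c.startswith("srs") or c.startswith("spaic")
    ]
    for c in score_cols:
        vals = df[c].dropna()
        if (vals < 0).any():
            raise GazeIOError(f"{path}: negative scores in column {c}")
    if df["participant_id"].duplicated().any():
        raise GazeIOError(f"{path}: duplicate participant ids")
    return df


def write_trait_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False)
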