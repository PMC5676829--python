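"""Fixation detection from binocular gaze samples.

Implements the sliding-window mean-difference family of fixation filters
used by screen-based remote eye trackers: a displacement signal is
computed at every sample as the Euclidean distance between the mean gaze
position of a short window before the sample and a window after it;
local maxima of that signal above a pixel threshold mark saccade
boundaries; the runs between boundaries become candidate fixations, and
adjacent candidates whose centroids lie closer than a distance threshold
are merged.  Both thresholds are in pixels, matching how this filter
family is parameterized for fixed-distance screen recordings.

Preprocessing (eye combination and short-gap interpolation) lives here
too, since the detector is defined on a single "cyclopean" gaze stream.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class FilterParams:
    """Parameters of the sliding-window fixation filter.

    velocity_threshold_px
        Window-mean displacement (pixels) above which a local maximum of
        the displacement signal is treated as a saccade boundary.
    distance_threshold_px
        Centroid distance (pixels) below which adjacent candidate
        fixations are merged.
    window_halfwidth_samples
        Samples on each side of the evaluation point (5 samples is about
        42 ms at 120 Hz).
    max_gap_interp_ms
        Longest run of missing samples bridged by linear interpolation;
        longer runs always terminate a fixation.
    min_fixation_ms
        Fixations shorter than this (after merging) are discarded.
    """

    velocity_threshold_px: float = 35.0
    distance_threshold_px: float = 35.0
    window_halfwidth_samples: int = 5
    max_gap_interp_ms: float = 75.0
    min_fixation_ms: float = 60.0

    def __post_init__(self) -> None:
        for name in (
            "velocity_threshold_px",
            "distance_threshold_px",
            "window_halfwidth_samples",
            "max_gap_interp_ms",
            "min_fixation_ms",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")


@dataclass
class GazePoints:
    """A time-ordered cyclopean gaze stream.

    ``x``/``y`` are NaN where no position is available; ``measured`` is
    False for samples whose position was interpolated (or is missing).
    """

    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    measured: np.ndarray

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.measured = np.asarray(self.measured, dtype=bool)

    def __len__(self) -> int:
        return len(self.t)

    @property
    def valid(self) -> np.ndarray:
        return np.isfinite(self.x) & np.isfinite(self.y)

    @property
    def interpolated(self) -> np.ndarray:
        return self.valid & ~self.measured


@dataclass(frozen=True)
class Fixation:
    """A detected fixation: interval, centroid, and sample bookkeeping."""

    start_ms: float
    end_ms: float
    centroid_x: float
    centroid_y: float
    n_samples: int
    mean_validity_fraction: float = 1.0

    @property
    def duration_ms(self) -> float:
        return self.end_ms - self.start_ms

    def clipped(self, t0: float, t1: float) -> "Fixation":
        """Restrict the fixation interval to [t0, t1) for duration accounting."""
        return replace(self, start_ms=max(self.start_ms, t0), end_ms=min(self.end_ms, t1))


def combine_eyes(samples: pd.DataFrame) -> GazePoints:
    """Collapse a binocular gaze DataFrame to one cyclopean stream.

    The cyclopean position is the mean of the two eyes when both carry a
    high-quality validity code (0 or 1), the single qualifying eye when
    only one does, and missing otherwise.
    """
    lx = samples["left_x"].to_numpy(dtype=float)
    ly = samples["left_y"].to_numpy(dtype=float)
    rx = samples["right_x"].to_numpy(dtype=float)
    ry = samples["right_y"].to_numpy(dtype=float)
    left_ok = (samples["left_validity"].to_numpy() <= 1) & np.isfinite(lx)
    right_ok = (samples["right_validity"].to_numpy() <= 1) & np.isfinite(rx)
    x = np.full(len(samples), np.nan)
    y = np.full(len(samples), np.nan)
    both = left_ok & right_ok
    x[both] = (lx[both] + rx[both]) / 2.0
    y[both] = (ly[both] + ry[both]) / 2.0
    only_l = left_ok & ~right_ok
    x[only_l], y[only_l] = lx[only_l], ly[only_l]
    only_r = right_ok & ~left_ok
    x[only_r], y[only_r] = rx[only_r], ry[only_r]
    return GazePoints(
        t=samples["t_ms"].to_numpy(dtype=float), x=x, y=y, measured=left_ok | right_ok
    )


def interpolate_gaps(points: GazePoints, max_gap_interp_ms: float = 75.0) -> GazePoints:
    """Linearly bridge short runs of missing samples.

    A missing run is bridged when its duration — the number of missing
    samples times the nominal sample interval — does not exceed
    ``max_gap_interp_ms`` and valid samples flank it on both sides.
    Bridged samples keep ``measured == False`` so downstream quality
    accounting can tell them apart.
    """
    valid = points.valid
    if valid.all() or not valid.any():
        return GazePoints(points.t, points.x.copy(), points.y.copy(), points.measured.copy())
    dt = float(np.median(np.diff(points.t))) if len(points) > 1 else 0.0
    x = points.x.copy()
    y = points.y.copy()
    idx = np.flatnonzero(~valid)
    # split missing indices into consecutive runs
    splits = np.flatnonzero(np.diff(idx) > 1) + 1
    for run in np.split(idx, splits):
        i0, i1 = run[0], run[-1]
        if i0 == 0 or i1 == len(points) - 1:
            continue
        span_ms = points.t[i1] - points.t[i0] + dt
        if span_ms > max_gap_interp_ms:
            continue
        t0, t1 = points.t[i0 - 1], points.t[i1 + 1]
        w = (points.t[run] - t0) / (t1 - t0)
        x[run] = points.x[i0 - 1] + w * (points.x[i1 + 1] - points.x[i0 - 1])
        y[run] = points.y[i0 - 1] + w * (points.y[i1 + 1] - points.y[i0 - 1])
    return GazePoints(points.t, x, y, points.measured.copy())


def displacement_signal(points: GazePoints, w: int) -> np.ndarray:
    """Window-mean displacement d(i) in pixels.

    d(i) is the Euclidean distance between the mean position of the ``w``
    samples before i (indices ``[i-w, i)``) and the mean of the ``w``
    samples starting at i (indices ``[i, i+w)``); NaN where either window
    contains a missing sample or falls off the array.
    """
    n = len(points)
    d = np.full(n, np.nan)
    if n < 2 * w + 1:
        return d
    valid = points.valid.astype(float)
    xz = np.where(points.valid, points.x, 0.0)
    yz = np.where(points.valid, points.y, 0.0)
    c = lambda a: np.concatenate(([0.0], np.cumsum(a)))
    cx, cy, cv = c(xz), c(yz), c(valid)
    sx = cx[w:] - cx[:-w]
    sy = cy[w:] - cy[:-w]
    sv = cv[w:] - cv[:-w]
    full = sv == w
    i = np.arange(w, n - w + 1)
    ok = full[i - w] & full[i]
    dx = (sx[i] - sx[i - w]) / w
    dy = (sy[i] - sy[i - w]) / w
    vals = np.hypot(dx, dy)
    d[i[ok]] = vals[ok]
    return d


def saccade_boundaries(d: np.ndarray, velocity_threshold_px: float) -> np.ndarray:
    """Indices that are local maxima of d above the threshold.

    The local-maximum test (strictly greater than the left neighbour,
    at least as great as the right) does not depend on the threshold, so
    raising the threshold can only shrink the boundary set.  On an exact
    tie the earlier sample is the boundary.
    """
    n = len(d)
    if n == 0:
        return np.array([], dtype=int)
    left = np.concatenate(([-np.inf], d[:-1]))
    right = np.concatenate((d[1:], [-np.inf]))
    with np.errstate(invalid="ignore"):
        is_max = (d > velocity_threshold_px) & ~(d <= left) & ~(d < right)
    # NaN comparisons are False, so missing d never yields a boundary,
    # and a NaN neighbour behaves like -inf.
    is_max &= np.isfinite(d)
    return np.flatnonzero(is_max)


@dataclass
class _Candidate:
    i0: int  # first member sample
    i1: int  # last member sample (inclusive)

    def members(self) -> np.ndarray:
        return np.arange(self.i0, self.i1 + 1)


def _centroid(points: GazePoints, i0: int, i1: int) -> tuple[float, float]:
    return (
        float(np.mean(points.x[i0 : i1 + 1])),
        float(np.mean(points.y[i0 : i1 + 1])),
    )


def merge_candidates(
    points: GazePoints, cands: list[_Candidate], distance_threshold_px: float
) -> list[_Candidate]:
    """Merge adjacent candidates whose pooled centroids are close.

    Candidates separated by a missing span are never merged (missing
    spans terminate fixations).  Merging repeats until no adjacent pair
    qualifies, recomputing pooled centroids, so a second pass is a
    no-op.
    """
    cands = list(cands)
    changed = True
    while changed:
        changed = False
        out: list[_Candidate] = []
        k = 0
        while k < len(cands):
            if k + 1 < len(cands):
                a, b = cands[k], cands[k + 1]
                gap_has_missing = not points.valid[a.i1 : b.i0 + 1].all()
                ca = _centroid(points, a.i0, a.i1)
                cb = _centroid(points, b.i0, b.i1)
                dist = float(np.hypot(ca[0] - cb[0], ca[1] - cb[1]))
                if not gap_has_missing and dist < distance_threshold_px:
                    cands[k + 1] = _Candidate(a.i0, b.i1)
                    changed = True
                    k += 1
                    continue
            out.append(cands[k])
            k += 1
        cands = out
    return cands


def detect_fixations(points: GazePoints, params: FilterParams = FilterParams()) -> list[Fixation]:
    """Detect fixations in a cyclopean gaze stream.

    Returns a time-ordered list of non-overlapping fixations; every
    returned fixation lasts at least ``params.min_fixation_ms``.  With
    fewer than ``2 * window_halfwidth + 1`` samples no detection is
    possible and an empty list is returned with a warning.
    """
    n = len(points)
    w = params.window_halfwidth_samples
    if n < 2 * w + 1:
        warnings.warn(
            f"too few samples ({n}) for window half-width {w}; no fixations detected",
            stacklevel=2,
        )
        return []
    d = displacement_signal(points, w)
    boundaries = set(saccade_boundaries(d, params.velocity_threshold_px).tolist())

    valid = points.valid
    cands: list[_Candidate] = []
    i = 0
    while i < n:
        if not valid[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and valid[j + 1] and (j + 1) not in boundaries:
            j += 1
        cands.append(_Candidate(i, j))
        i = j + 1
    cands = merge_candidates(points, cands, params.distance_threshold_px)

    fixations = []
    for c in cands:
        start, end = points.t[c.i0], points.t[c.i1]
        if end - start < params.min_fixation_ms:
            continue
        cx, cy = _centroid(points, c.i0, c.i1)
        fixations.append(
            Fixation(
                start_ms=float(start),
                end_ms=float(end),
                centroid_x=cx,
                centroid_y=cy,
                n_samples=c.i1 - c.i0 + 1,
                mean_validity_fraction=float(
                    np.mean(points.measured[c.i0 : c.i1 + 1])
                ),
            )
        )
    return fixations


def fixations_to_frame(fixations: list[Fixation], participant_id: str | None = None) -> pd.DataFrame:
    """Tabulate fixations for CSV export."""
    df = pd.DataFrame(
        [
            (f.start_ms, f.end_ms, f.centroid_x, f.centroid_y, f.duration_ms, f.n_samples)
            for f in fixations
        ],
        columns=["start_ms", "end_ms", "centroid_x", "centroid_y", "duration_ms", "n_samples"],
    )
    if participant_id is not None:
        df.insert(0, "participant_id", participant_id)
    return df
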