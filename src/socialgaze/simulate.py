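"""Synthetic visual-search eye-tracking cohorts with planted ground truth.

Emulates a 120 Hz binocular recording of the eyes-among-distractors
paradigm: each of 12 trials shows a centering animation, a blank
interval, then a four-image array (one eyes region, three distractors)
for a few seconds; 4 trials are silent, 8 preceded by an auditory cue.
Two participant traits are drawn (autistic-trait and social-anxiety raw
scores, bivariate normal with a configurable correlation) and coupled to
behaviour through two planted effects:

* ``beta_latency`` — ms of extra mean orienting latency to the eyes per
  SD of trait A (slower orienting with higher autistic traits);
* ``beta_dwell`` — ms of change in mean first-pass dwell per SD of
  trait B (shorter engagement with higher social anxiety).

Latencies and dwells are drawn lognormally (empirical orienting-latency
distributions are right-skewed) with means and SDs anchored to the
defaults in :class:`CohortParams`.  Every planted latency and dwell is
retained in a ground-truth ledger so downstream recovery can be checked
sample by sample.  Trait standardization uses the configured population
moments, not sample moments, so the betas have a fixed meaning at any n.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

from .io import (
    CENTER_LABEL,
    SAMPLE_INTERVAL_MS,
    STIMULUS_LABELS,
    GAZE_COLUMNS,
    Rect,
    RoiSet,
    TrialInfo,
    write_gaze_log,
    write_roi_config,
    write_trait_table,
    write_trial_log,
)

DISTRACTOR_LABELS = ("distractor_1", "distractor_2", "distractor_3")

#: fixed condition order shared by all participants (4 silent, 4 phoneme, 4 beep)
CONDITION_ORDER = (
    "silent", "phoneme", "beep", "phoneme",
    "silent", "beep", "phoneme", "silent",
    "beep", "phoneme", "silent", "beep",
)


@dataclass(frozen=True)
class CohortParams:
    """All knobs of the synthetic study; defaults are the study conditions.

    Trait means/SDs and their correlation, the silent/cued latency means
    and SDs, and the trial composition are anchored to the adolescent
    social-anxiety cohort the paradigm models; timing and geometry
    defaults are realistic free choices documented in the methods note.
    """

    n_participants: int = 25
    # trait A: autistic traits (SRS raw total); trait B: social anxiety (SPAI-C)
    trait_mean_a: float = 49.0
    trait_sd_a: float = 19.0
    trait_mean_b: float = 35.0
    trait_sd_b: float = 7.3
    trait_correlation: float = 0.36
    # orienting latency (ms), by condition
    base_latency_silent_ms: float = 711.0
    latency_sd_silent_ms: float = 268.0
    base_latency_cued_ms: float = 611.0
    latency_sd_cued_ms: float = 173.0
    beta_latency_ms_per_sd: float = 60.0
    # first-pass dwell (ms)
    base_dwell_ms: float = 500.0
    dwell_sd_ms: float = 200.0
    beta_dwell_ms_per_sd: float = -80.0
    # behaviour / data quality
    p_first_look_target: float = 0.6
    anticipatory_rate: float = 0.05
    missingness_rate: float = 0.08
    mean_missing_run_samples: float = 12.0
    noise_sd_px: float = 8.0
    interocular_disparity_px: float = 30.0
    # paradigm timing
    trials_per_participant: int = 12
    animation_ms: float = 1000.0
    blank_ms: float = 500.0
    stimulus_ms: float = 3000.0
    baseline_ms: float = 500.0
    # geometry
    screen_width: float = 1280.0
    screen_height: float = 1024.0
    roi_width: float = 300.0
    roi_height: float = 225.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("trait_sd_a", "trait_sd_b", "latency_sd_silent_ms",
                     "latency_sd_cued_ms", "dwell_sd_ms"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("p_first_look_target", "anticipatory_rate", "missingness_rate"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")
        if not -1 < self.trait_correlation < 1:
            raise ValueError("trait_correlation must lie in (-1, 1)")

    @property
    def trial_period_ms(self) -> float:
        return self.animation_ms + self.blank_ms + self.stimulus_ms

    def base_latency(self, condition: str) -> tuple[float, float]:
        if condition == "silent":
            return self.base_latency_silent_ms, self.latency_sd_silent_ms
        return self.base_latency_cued_ms, self.latency_sd_cued_ms


@dataclass
class TrialSchedule:
    """Planted gaze itinerary for one trial, with its ground truth."""

    trial_id: int
    array_id: int
    condition: str
    events: list[tuple[str, float, float]]  # (roi label, start_ms, end_ms)
    planted_latency_ms: float
    planted_dwell_ms: float
    first_look_roi: str
    anticipatory: bool


# ---------------------------------------------------------------------------
# geometry and schedule
# ---------------------------------------------------------------------------


def default_roi_set(params: CohortParams = CohortParams()) -> RoiSet:
    """Quadrant layout with the eyes position counterbalanced over arrays."""
    w, h = params.roi_width, params.roi_height
    sw, sh = params.screen_width, params.screen_height
    mx, my = sw * 0.125, sh * 0.125  # quadrant margins
    slots = [
        (mx, my),
        (sw - mx - w, my),
        (mx, sh - my - h),
        (sw - mx - w, sh - my - h),
    ]
    center = Rect((sw - w) / 2.0, (sh - h) / 2.0, w, h)
    arrays: dict[int, dict[str, Rect]] = {}
    for array_id in range(1, 13):
        eyes_slot = (array_id - 1) % 4
        rois = {CENTER_LABEL: center}
        order = [eyes_slot] + [s for s in range(4) if s != eyes_slot]
        for label, slot in zip(("eyes",) + DISTRACTOR_LABELS, order):
            x0, y0 = slots[slot]
            rois[label] = Rect(x0, y0, w, h)
        arrays[array_id] = rois
    return RoiSet(arrays, screen_width=sw, screen_height=sh)


def default_trial_infos(params: CohortParams = CohortParams()) -> list[TrialInfo]:
    """The shared 12-trial schedule (4 silent, 4 phoneme, 4 beep)."""
    infos = []
    for k in range(params.trials_per_participant):
        t0 = k * params.trial_period_ms
        onset = t0 + params.animation_ms + params.blank_ms
        infos.append(
            TrialInfo(
                trial_id=k + 1,
                array_id=(k % 12) + 1,
                onset_ms=onset,
                offset_ms=onset + params.stimulus_ms,
                condition=CONDITION_ORDER[k % 12],
                baseline_start_ms=onset - params.baseline_ms,
                baseline_end_ms=onset,
            )
        )
    return infos


# ---------------------------------------------------------------------------
# traits
# ---------------------------------------------------------------------------

_SUBSCALE_FRACTIONS = {
    "srs_social_awareness": 0.10,
    "srs_social_communication": 0.31,
    "srs_social_cognition": 0.13,
    "srs_social_motivation": 0.35,
    "srs_rrb": 0.11,
}


def generate_traits(params: CohortParams, rng: np.random.Generator) -> pd.DataFrame:
    """Draw the participant trait table.

    Bivariate normal with the configured means, SDs and correlation,
    truncated at zero and rounded to integer raw scores; SRS subscales
    are noisy proportional splits of the total.
    """
    n = params.n_participants
    if n < 2:
        raise ValueError("need at least 2 participants")
    cov = np.array(
        [
            [params.trait_sd_a**2, params.trait_correlation * params.trait_sd_a * params.trait_sd_b],
            [params.trait_correlation * params.trait_sd_a * params.trait_sd_b, params.trait_sd_b**2],
        ]
    )
    draws = rng.multivariate_normal([params.trait_mean_a, params.trait_mean_b], cov, size=n)
    srs = np.maximum(0, np.round(draws[:, 0])).astype(int)
    spaic = np.maximum(0, np.round(draws[:, 1])).astype(int)
    df = pd.DataFrame(
        {
            "participant_id": [f"p{i + 1:03d}" for i in range(n)],
            "srs_total": srs,
            "spaic_total": spaic,
        }
    )
    for col, frac in _SUBSCALE_FRACTIONS.items():
        noisy = srs * frac * (1.0 + 0.15 * rng.standard_normal(n))
        df[col] = np.maximum(0, np.round(noisy)).astype(int)
    df["sex"] = np.where(rng.random(n) < 0.84, "F", "M")
    df["age"] = np.round(rng.normal(15.2, 1.2, size=n), 1)
    return df


# ---------------------------------------------------------------------------
# trial planning
# ---------------------------------------------------------------------------


def _lognormal(rng: np.random.Generator, mean: float, sd: float) -> float:
    """Draw from a lognormal with the given arithmetic mean and SD."""
    sigma2 = math.log(1.0 + (sd / mean) ** 2)
    mu = math.log(mean) - sigma2 / 2.0
    return float(rng.lognormal(mu, math.sqrt(sigma2)))


#: gap left between consecutive fixation events, rendered as a 2-sample saccade
SACCADE_GAP_MS = 2 * SAMPLE_INTERVAL_MS


def plan_trial(
    z_a: float,
    z_b: float,
    info: TrialInfo,
    params: CohortParams,
    rng: np.random.Generator,
) -> TrialSchedule:
    """Plan one trial's gaze itinerary.

    Gaze rests at the center through the animation and blank, orients to
    the array at the planted latency (possibly via one distractor first),
    dwells on the eyes for the planted first-pass time, then wanders the
    distractors until offset.
    """
    onset, offset = info.onset_ms, info.offset_ms
    block_start = onset - params.animation_ms - params.blank_ms
    base, lat_sd = params.base_latency(info.condition)

    anticipatory = rng.random() < params.anticipatory_rate
    if anticipatory:
        latency = float(rng.uniform(20.0, 90.0))
    else:
        mean_lat = max(150.0, base + params.beta_latency_ms_per_sd * z_a)
        latency = _lognormal(rng, mean_lat, lat_sd)
        latency = float(np.clip(latency, 120.0, params.stimulus_ms - 300.0))

    mean_dwell = max(120.0, params.base_dwell_ms + params.beta_dwell_ms_per_sd * z_b)
    dwell = max(80.0, _lognormal(rng, mean_dwell, params.dwell_sd_ms))

    eyes_start = onset + latency
    eyes_end = min(eyes_start + dwell, offset)
    planted_dwell = eyes_end - eyes_start

    events: list[tuple[str, float, float]] = []
    first_look = "eyes"
    distractor_first = (
        not anticipatory
        and rng.random() > params.p_first_look_target
        and latency > 450.0
    )
    if distractor_first:
        d_lat = min(_lognormal(rng, 250.0, 60.0), latency - 200.0)
        first_look = str(rng.choice(DISTRACTOR_LABELS))
        events.append((CENTER_LABEL, block_start, onset + d_lat - SACCADE_GAP_MS))
        events.append((first_look, onset + d_lat, eyes_start - SACCADE_GAP_MS))
    else:
        events.append((CENTER_LABEL, block_start, eyes_start - SACCADE_GAP_MS))
    events.append(("eyes", eyes_start, eyes_end))

    # wander the distractors after the first pass
    t = eyes_end + SACCADE_GAP_MS
    prev = "eyes"
    while offset - t > 100.0:
        dur = _lognormal(rng, 300.0, 80.0)
        label = str(rng.choice([d for d in DISTRACTOR_LABELS if d != prev]))
        end = min(t + dur, offset)
        events.append((label, t, end))
        prev = label
        t = end + SACCADE_GAP_MS

    return TrialSchedule(
        trial_id=info.trial_id,
        array_id=info.array_id,
        condition=info.condition,
        events=events,
        planted_latency_ms=latency,
        planted_dwell_ms=planted_dwell,
        first_look_roi=first_look,
        anticipatory=anticipatory,
    )


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------


def render_stream(
    schedules: Sequence[TrialSchedule],
    roi_set: RoiSet,
    params: CohortParams,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Render planned trials into a 120 Hz binocular gaze DataFrame.

    Fixation samples sit at the ROI center plus isotropic Gaussian noise;
    the ~17 ms gaps between events come out as 2-sample saccadic
    transitions; missing data is injected as runs of validity-4 samples
    with absent positions.  Both eyes carry the same cyclopean position
    offset by a constant horizontal disparity, so eye combination is
    exact.
    """
    n_trials = len(schedules)
    total_ms = n_trials * params.trial_period_ms
    n = int(round(total_ms / SAMPLE_INTERVAL_MS))
    t = np.arange(n) * SAMPLE_INTERVAL_MS

    wp_t: list[float] = []
    wp_x: list[float] = []
    wp_y: list[float] = []
    for sched in schedules:
        rois = roi_set.arrays[sched.array_id]
        for label, start, end in sched.events:
            if end - start < 2 * SAMPLE_INTERVAL_MS:
                continue
            cx, cy = rois[label].center
            wp_t += [start, end - SAMPLE_INTERVAL_MS]
            wp_x += [cx, cx]
            wp_y += [cy, cy]
    wpt = np.asarray(wp_t)
    order = np.argsort(wpt, kind="stable")
    wpt = wpt[order]
    wpx = np.asarray(wp_x)[order]
    wpy = np.asarray(wp_y)[order]
    x = np.interp(t, wpt, wpx)
    y = np.interp(t, wpt, wpy)
    if params.noise_sd_px > 0:
        x = x + rng.normal(0.0, params.noise_sd_px, size=n)
        y = y + rng.normal(0.0, params.noise_sd_px, size=n)

    missing = np.zeros(n, dtype=bool)
    if params.missingness_rate > 0:
        # alternating-renewal model: mean gap chosen so that the stationary
        # missing fraction equals missingness_rate
        f = params.missingness_rate
        p_run = f / (params.mean_missing_run_samples * (1.0 - f)) if f < 1 else 1.0
        p_run = min(p_run, 1.0)
        pos = 0
        while pos < n:
            gap = int(rng.geometric(p_run))
            pos += gap
            if pos >= n:
                break
            run = int(rng.geometric(1.0 / params.mean_missing_run_samples))
            missing[pos : pos + run] = True
            pos += run

    half_d = params.interocular_disparity_px / 2.0
    lx, ly = x - half_d, y.copy()
    rx, ry = x + half_d, y.copy()
    validity = np.zeros(n, dtype=int)
    for arr in (lx, ly, rx, ry):
        arr[missing] = np.nan
    validity[missing] = 4
    return pd.DataFrame(
        {
            "t_ms": t,
            "left_x": lx,
            "left_y": ly,
            "left_validity": validity,
            "right_x": rx,
            "right_y": ry,
            "right_validity": validity,
        }
    )


# ---------------------------------------------------------------------------
# cohort assembly
# ---------------------------------------------------------------------------


@dataclass
class Cohort:
    """An in-memory synthetic study."""

    params: CohortParams
    roi_set: RoiSet
    trial_infos: list[TrialInfo]
    traits: pd.DataFrame
    gaze: dict[str, pd.DataFrame]  # participant_id -> gaze samples
    ledger: pd.DataFrame  # planted ground truth per trial


def simulate_participant(
    participant_id: str,
    z_a: float,
    z_b: float,
    trial_infos: Sequence[TrialInfo],
    roi_set: RoiSet,
    params: CohortParams,
    rng: np.random.Generator,
) -> tuple[pd.DataFrame, list[dict]]:
    """Plan and render one participant; returns (gaze samples, ledger rows)."""
    schedules = [plan_trial(z_a, z_b, info, params, rng) for info in trial_infos]
    gaze = render_stream(schedules, roi_set, params, rng)
    ledger = [
        {
            "participant_id": participant_id,
            "trial_id": s.trial_id,
            "condition": s.condition,
            "planted_latency_ms": s.planted_latency_ms,
            "planted_dwell_ms": s.planted_dwell_ms,
            "first_look_roi": s.first_look_roi,
            "anticipatory": s.anticipatory,
        }
        for s in schedules
    ]
    return gaze, ledger


def simulate_cohort(params: CohortParams) -> Cohort:
    """Generate a full in-memory cohort from the master seed.

    The master seed spawns one substream per participant (plus one for
    the trait table), so any participant's recording is reproducible in
    isolation.
    """
    ss = np.random.SeedSequence(params.seed)
    children = ss.spawn(params.n_participants + 1)
    traits = generate_traits(params, np.random.default_rng(children[0]))
    trial_infos = default_trial_infos(params)
    roi_set = default_roi_set(params)
    gaze: dict[str, pd.DataFrame] = {}
    ledger_rows: list[dict] = []
    for i, row in enumerate(traits.itertuples(index=False)):
        rng = np.random.default_rng(children[i + 1])
        z_a = (row.srs_total - params.trait_mean_a) / params.trait_sd_a
        z_b = (row.spaic_total - params.trait_mean_b) / params.trait_sd_b
        g, led = simulate_participant(
            row.participant_id, z_a, z_b, trial_infos, roi_set, params, rng
        )
        gaze[row.participant_id] = g
        ledger_rows.extend(led)
    return Cohort(
        params=params,
        roi_set=roi_set,
        trial_infos=trial_infos,
        traits=traits,
        gaze=gaze,
        ledger=pd.DataFrame(ledger_rows),
    )


def generate_cohort(
    params: CohortParams, outdir: str | Path, overwrite: bool = False
) -> Path:
    """Write a complete synthetic study to disk.

    Produces one gaze log per participant plus four shared files (trial
    log, ROI config, trait table, ground-truth ledger) and a manifest
    recording all parameters and the seed.
    """
    outdir = Path(outdir)
    if outdir.exists() and any(outdir.iterdir()) and not overwrite:
        raise FileExistsError(
            f"{outdir} is not empty; pass overwrite=True to regenerate"
        )
    outdir.mkdir(parents=True, exist_ok=True)
    cohort = simulate_cohort(params)
    write_roi_config(cohort.roi_set, outdir / "roi_config.json")
    write_trial_log(cohort.trial_infos, outdir / "trial_log.csv")
    write_trait_table(cohort.traits, outdir / "traits.csv")
    cohort.ledger.to_csv(outdir / "ground_truth.csv", index=False)
    for pid, gaze in cohort.gaze.items():
        write_gaze_log(gaze, outdir / f"gaze_{pid}.tsv")
    manifest = {"params": asdict(params), "n_files": len(cohort.gaze) + 4}
    with open(outdir / "cohort_manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
        fh.write("\n")
    return outdir


def load_cohort_params(manifest_path: str | Path) -> CohortParams:
    """Re-create the parameters recorded in a cohort manifest."""
    with open(manifest_path) as fh:
        manifest = json.load(fh)
    return CohortParams(**manifest["params"])
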