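# Methods

`socialgaze` implements a complete analysis path for a visual-search
eye-tracking paradigm used to separate two constructs of social
attention — how quickly gaze *orients to* a social target (the eye
region of a face) presented among distractors, and how long gaze stays
there before *reorienting away* — and to relate each construct to a
different trait dimension (autistic traits, measured by SRS raw scores,
and social anxiety, measured by SPAI-C raw scores) within a single
sample. This note documents the models, the parameters that matter, the
numerical choices, and what the synthetic data can and cannot show.

## Fixation detection

Raw input is a 120 Hz binocular stream: per sample, a timestamp, each
eye's screen position in pixels, and a 0–4 validity code (0–1 = reliably
tracked). Processing steps:

1. **Eye combination.** The cyclopean position is the mean of the two
   eyes when both carry validity 0–1, the single qualifying eye when
   only one does, missing otherwise. Trackers report the two eyes with
   a roughly constant horizontal disparity; averaging cancels it.
2. **Gap interpolation.** Runs of missing samples no longer than
   `max_gap_interp_ms` (default 75 ms ≈ 9 samples, the blink-artifact
   scale) are bridged linearly between their flanking valid samples and
   flagged, so quality accounting can still tell measured from inferred
   positions. Longer runs are left missing and always terminate a
   fixation.
3. **Sliding-window displacement.** For each sample *i*, d(*i*) is the
   Euclidean distance between the mean position of the
   `window_halfwidth_samples` samples before *i* and the mean of those
   starting at *i* (default half-width 5 samples ≈ 42 ms at 120 Hz).
   Window means suppress tracker noise; a saccade shows up as a peak in
   d.
4. **Boundary rule.** Samples where d exceeds `velocity_threshold_px`
   (default 35 px) *and* d is a local maximum are saccade boundaries.
   The local-maximum test is threshold-independent, so raising the
   threshold can only remove boundaries — a monotonicity the tests
   exercise. On an exact tie between adjacent d values the earlier
   sample is the boundary.
5. **Candidates and merging.** Maximal runs between boundaries that
   contain no missing span become candidate fixations with
   sample-mean centroids. Adjacent candidates whose centroids lie
   closer than `distance_threshold_px` (default 35 px) are merged, the
   pooled centroid recomputed, repeating until stable (the merge pass
   is idempotent — rerunning it changes nothing). Candidates are never
   merged across a surviving missing span.
6. **Duration floor.** Fixations shorter than `min_fixation_ms`
   (default 60 ms) are dropped *after* merging, since merging can
   legitimately reunite a fixation that noise split into short pieces.

Both thresholds are in pixels rather than degrees: the paradigm uses a
fixed-distance screen setup, and this filter family is conventionally
parameterized that way. The window half-width and gap cap are not fixed
by that convention; they are exposed parameters with the defaults above.

On noise-free step streams the detector localizes every change point to
within the window half-width (5 samples), which is the boundary
tolerance quoted everywhere below: one sample period (8.33 ms) plus
5 samples ≈ 50 ms.

## Trial quality control and measures

Each of the 12 array presentations (4 silent, 8 preceded by an auditory
alerting cue) is checked against four rules:

* **anticipatory** — first fixation on the eyes ROI starts < 100 ms
  after array onset; too fast to be stimulus-driven, trial discarded
  entirely.
* **low_validity** — fewer than 33% of the trial's raw samples have
  both eyes at validity 0–1.
* **baseline_fail** — gaze was inside the central ROI for less than
  50% of the 500 ms baseline interval immediately preceding onset.
  Missing baseline samples count against the fraction (a conservative
  reading of the attention check: absent data cannot demonstrate
  fixation at center).
* **no_target_fixation** — no fixation centroid ever fell in the eyes
  ROI. The trial contributes to neither measure but still counts as a
  validly recorded trial when deciding whether a participant qualifies
  for the cued/silent contrast (that eligibility rule — at least 50%
  valid trials in each condition — concerns recording quality, not
  behaviour).

Thresholds sit at the boundaries stated above and comparisons are
strict (`fraction < 0.33` excludes, so exactly one-third is retained).

The two dependent measures, computed per included trial:

* **Latency to the eyes** — start of the first fixation whose centroid
  lies in the eyes ROI, minus array onset. ROI membership is by
  fixation centroid (the standard fixation-level AOI convention; a
  per-sample variant was considered and rejected as it conflates
  saccade flight paths with looking).
* **First-pass dwell** — summed duration of the maximal run of
  consecutive fixations remaining in the eyes ROI, from first entry to
  the first fixation outside it; inter-fixation (saccade) time is not
  counted, and fixations are clipped to the trial window so a dwell
  running into the offset is truncated there.

ROI rectangles are half-open on both axes so shared edges are
unambiguous. Trials own samples with `onset <= t < offset`; a fixation
straddling the onset is clipped at onset for within-trial accounting.

Participant summaries average each measure over included trials
(overall and by condition). Excluded trials never contribute, so
filtering then summarizing equals summarizing directly — an invariant
under test.

## Statistics

With two measures and two traits in one sample, the key question —
does each trait relate *selectively* to its measure — requires
comparing dependent correlations. The layer provides:

* **Pearson r** with the exact t test, t = r·sqrt((n−2)/(1−r²)) on
  n−2 df, two-tailed; complete-case n recorded per pair.
* **First-order partial correlation**
  r_xy·z = (r_xy − r_xz·r_yz) / sqrt((1−r_xz²)(1−r_yz²)), tested on
  n−3 df. Identical to the Pearson correlation of the two least-squares
  residual vectors (verified to 1e-10 in tests).
* **Steiger's Z** for two correlations sharing a variable, in the
  Fisher-transform form with pooled rbar = (r12+r13)/2:
  psi = r23(1−2·rbar²) − rbar²(1−2·rbar²−r23²)/2,
  s = psi/(1−rbar²)², Z = (z(r12)−z(r13))·sqrt((n−3)/(2(1−s))).
  Z is exactly antisymmetric in (r12, r13) and zero when they are
  equal; its type-I error is calibrated at ~5% under simulated
  trivariate-normal nulls in the acceptance tests.
* **Cook's distance** for the simple regression of each measure on
  each trait, h_ii = 1/n + (x_i−x̄)²/Σ(x_j−x̄)², D_i =
  e_i²·h_ii/(2·s²·(1−h_ii)²), flagging D_i > 4/n (the threshold is
  configurable; the originating analysis named the statistic but no
  cutoff). Screening is applied per measure–trait pair, not globally,
  and removals are logged. The Steiger comparison uses the unscreened
  complete-case sample: its three correlations must come from one
  sample, and pair-specific removal has no unambiguous extension to a
  triple.
* **Shapiro–Wilk** on every analysis variable, reported as a screen
  only — it never gates or alters the pipeline.
* **Paired t** for the silent-vs-cued latency contrast over eligible
  participants.

All tests are two-tailed; no multiple-testing correction is applied
(matching the analysis style the pipeline reproduces). SRS subscale
correlations with latency (zero-order and SPAI-C-partialled) are
optional and on by default.

## Synthetic cohorts

No participant recordings are available, so the generator produces
complete on-disk studies with ground truth:

* **Traits**: bivariate normal, SRS mean 49 SD 19, SPAI-C mean 35.0 SD
  7.3, correlation 0.36, truncated at zero and rounded to integers as
  questionnaire raw scores are. Subscales are noisy proportional splits
  of the SRS total. Standardization inside the generator uses these
  configured population moments — not sample moments — so the coupling
  coefficients below have the same meaning at any cohort size.
* **Couplings**: mean orienting latency shifts by `beta_latency` ms per
  SD of trait A (default +60); mean first-pass dwell shifts by
  `beta_dwell` ms per SD of trait B (default −80).
* **Latency and dwell draws**: lognormal (empirical saccade-latency
  distributions are right-skewed), parameterized by arithmetic mean and
  SD. Condition means/SDs: silent 711/268 ms, cued 611/173 ms; dwell
  500/200 ms. Participant-level means remain approximately normal, so
  a normality screen passes on cohort summaries.
* **Trial plan**: gaze rests at the center ROI through a 1000 ms
  animation and 500 ms blank; at the planted latency the first eyes
  fixation begins (with probability 1 − `p_first_look_target` = 0.4 a
  distractor is visited first, provided the latency leaves room); the
  eyes fixation lasts the planted dwell; gaze then wanders the
  distractors (~300 ms fixations, never repeating the previous one)
  until offset at 3000 ms. With probability `anticipatory_rate` (0.05)
  the first eyes look is planted at 20–90 ms, which the QC layer must
  catch.
* **Rendering**: 120 Hz samples at ROI centers plus isotropic Gaussian
  noise (SD 8 px), 2-sample saccadic transitions, a constant 30 px
  interocular disparity (so eye combination is exact), and missing data
  as validity-4 runs (rate 0.08, mean run 100 ms) from an
  alternating-renewal model whose stationary missing fraction equals
  the configured rate.
* **Ground truth**: every planted latency, dwell, first-look ROI and
  anticipatory flag is written to a ledger CSV beside the rendered
  streams; a manifest records all parameters and the master seed. The
  seed spawns one substream per participant, so any single recording is
  reproducible in isolation.

**What the generator does not emulate**: smooth pursuit, head movement
and drift, calibration error varying across the screen, pupil data, any
cue-by-trait interaction (conditions differ only in base latency), and
the full range of real-world exclusion causes — under defaults about
11 of 12 trials survive QC, more than the ~8 completed trials typical
of adolescent clinical recordings. Passing recovery tests therefore
demonstrates correctness of the measurement and statistics chain, not
robustness to every artifact of real data.

## Problem sizes and numerical choices

* The end-to-end dissociation-recovery study uses couplings of +36 and
  −34 ms/SD, calibrated by variance decomposition of the participant
  means (within-trial SD ~61 ms over ~11 effective trials) so the
  planted population correlations are +0.5 and −0.5; 100 replicates of
  100 participants for the effect condition and the same for the null,
  with recovery bands of ±0.15 on mean estimated r, ≥80% replicate
  power for both partial correlations, and null centering |mean r| <
  0.05.
* Calibration checks (type-I error of the Pearson and Steiger tests)
  use 2000 replicates at n = 30 and n = 50 with acceptance band
  [0.035, 0.065] at α = .05.
* Noise-free recovery tolerances are one sample period plus the
  detector's boundary localization slack (8.33 + 5·8.33 ≈ 50 ms);
  observed errors are under 16 ms.
* Degenerate inputs raise typed errors rather than returning NaN:
  constant vectors (correlation, Shapiro–Wilk, regression designs),
  collinear controls (|r| within 1e-9 of 1), correlation configurations
  with s̄ ≥ 1 in Steiger's formula, and zero-variance nonzero paired
  differences. A paired test of identical vectors returns t = 0, p = 1.
* Gaze logs store times with three decimals and positions with two;
  reading and rewriting a canonical file is byte-identical. The
  quantization can move single samples across fixation boundaries,
  perturbing an n = 12 correlation by ~0.01 relative to the in-memory
  path — far below any tolerance used.

## Known limitations

* The vendor fixation filter the paradigm originally used is
  proprietary; this is the documented sliding-window mean-difference
  variant of that family, with window size and gap handling exposed
  rather than claimed as the original's exact values.
* The empirical headline statistics of the motivating study were
  computed on ~21–25 real adolescents and are not recoverable without
  the raw recordings; the pipeline's claims are correctness and
  calibration on synthetic ground truth, plus frozen hand-oracle
  checkpoints of the named formulas.
* `first_pass_dwell` counts fixation time only; whether saccade time
  inside the ROI should count is unspecified in the field's common
  usage, and the fixation-time reading matches the "total fixation
  time" convention.
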