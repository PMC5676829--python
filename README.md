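# socialgaze

Attention metrics and dependent-correlation statistics for
stimulus-array eye-tracking studies.

`socialgaze` is for researchers who record screen-based gaze while a
social target (the eye region of a face) competes with distractor
images, and who want to relate *how fast* gaze orients to the target
and *how long* it stays before reorienting to dimensional trait
measures — for example autistic traits (SRS raw scores) and social
anxiety (SPAI-C raw scores) within one clinical sample. Because the
two attention measures and the two traits live in the same sample, the
selective-association question ("is trait A more strongly related to
this measure than trait B is?") requires comparing *dependent*
correlations, which is the statistical core of the package.

## What it computes

From a raw 120 Hz binocular gaze log, a trial log, an ROI geometry
config and a trait table:

1. **Fixation detection** — a sliding-window displacement filter:
   d(i) is the distance between mean gaze position in windows before
   and after sample *i*; local maxima of d above a 35 px threshold are
   saccade boundaries; adjacent candidates with centroids closer than
   35 px merge; fixations under 60 ms are discarded.
2. **Trial quality control** — trials are excluded when the first
   target fixation is anticipatory (< 100 ms after onset), when fewer
   than 33% of samples have both eyes reliably tracked, or when gaze
   was at screen center for less than 50% of the pre-onset baseline.
3. **Two dependent measures per trial** — latency to the first
   fixation in the eyes ROI, and first-pass dwell (total fixation time
   in the ROI from first entry to first exit).
4. **Association statistics** — Pearson r with exact t tests, partial
   correlations r_xy·z = (r_xy − r_xz·r_yz)/√((1−r_xz²)(1−r_yz²)),
   Steiger's Z for dependent correlations,
   Z = (z(r₁₂) − z(r₁₃))·√((n−3)/(2(1−s̄))) with z the Fisher
   transform, Cook's-distance outlier screening (D_i > 4/n), a
   Shapiro–Wilk normality screen, and a paired silent-vs-cued
   contrast.
5. **Synthetic cohorts** — a generator that renders complete studies
   (gaze logs, trial log, ROI config, traits) with planted
   trait–attention couplings and a ground-truth ledger, so the whole
   chain is testable end to end.

See `docs/methods.md` for the full model description and all defaults.

## Worked example

Simulate a 25-participant study and run the full pipeline:

```sh
socialgaze simulate --out demo/cohort --n-participants 25 --seed 42
socialgaze run-all demo/cohort --out demo/results
```

The run log reports the QC accounting:

```
trials: read=300 included=276 excluded=24
excluded_reason anticipatory: 15
excluded_reason baseline_fail: 9
participants: read=25 retained=25 dropped=0
```

and `demo/results/report.txt` contains the statistics, e.g.:

```
Cued vs silent latency (paired, n = 25): silent M = 734, SD = 189;
  cued M = 613, SD = 99; t(24) = 3.33, p = 0.003
latency_to_eyes ~ srs:          r =  0.713, t(22) =  4.77, p = 0.000 (n = 24, removed 1)
latency_to_eyes ~ srs | spaic:  r =  0.494, t(22) =  2.67, p = 0.014 (n = 25)
first_pass_dwell ~ spaic:       r = -0.916, t(22) = -10.69, p = 0.000 (n = 24, removed 1)
first_pass_dwell ~ spaic | srs: r = -0.865, t(22) = -8.10, p = 0.000 (n = 25)
first_pass_dwell: srs vs spaic: Z = 3.935, p = 0.000 (n = 25)
```

Read: orienting latency rises with autistic traits even after
controlling social anxiety (partial r = .49), while first-pass dwell
falls with social anxiety after controlling autistic traits (partial
r = −.87); Steiger's Z confirms the dwell–anxiety association is
stronger than the dwell–autistic-traits one. That is the planted
double-dissociation pattern of the default generator: +60 ms of mean
latency per SD of trait A, −80 ms of dwell per SD of trait B. The
`removed 1` annotations are per-pair Cook's-distance screenings.

The same steps are available as a library:

```python
from socialgaze import CohortParams, simulate_cohort, analyze_cohort_object

cohort = simulate_cohort(CohortParams(n_participants=25, seed=42))
results = analyze_cohort_object(cohort)
print(results.analysis.report())
```

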