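# Methods

## Setting and data model

The package analyses paired stroke-volume (SV) readings from a
lower-body-negative-pressure (LBNP) protocol: each subject lies in a sealed
chamber whose sub-atmospheric pressure pools blood in the legs, simulating
progressive haemorrhage. The protocol is a sequence of steps, each with a
fractional SV target relative to the subject's own baseline; at every step
the reference monitor and one or more candidate devices read the same
underlying SV. A study has two arms ("strands"): LBNP alone and LBNP with
bilateral thigh tourniquets; the simulator treats the tourniquet arm as a
label only (no systematic SV modification), since the study design it
emulates found essentially no difference between arms.

## Synthetic cohort generator

For subject *i* with baseline `B_i ~ N(baseline_sv_mean, baseline_sv_sd²)`
and step target `f_s`:

- true SV: `T_is = B_i · f_s · (1 + ε)`, `ε ~ N(0, within_step_cv²)`
- reference reading: `R_is = T_is · (1 + η)`, `η ~ N(0, ref_cv²)`
- device reading: `D_is = slope·T_is + offset + u_i + e_is`, with
  `u_i ~ N(0, subject_sd²)` drawn once per subject/session and
  `e_is ~ N(0, noise_sd²)` per reading; an optional multiplicative jitter
  (`trend_noise_sd`) degrades trend readings without shifting the mean.

All readings are truncated below at 1 ml so that percent-change arithmetic
is always defined. Defaults: 21 subjects, baseline 100 ± 15 ml,
`within_step_cv = 0.03`, `ref_cv = 0.05`, step targets
(1.00, 0.92, 0.85, 0.80, 0.675, 0.595, 1.00). The protocol only pins SV
targets for the titrated steps (80%, the 65–70% and 55–64% bands, taken at
midpoints unless `sample_within_bands` draws uniformly within them); the
fractions 0.92 and 0.85 for the two fixed suction steps are this package's
own defaults, chosen to give a graded monotone fall, and are configurable.

Two stock device models reproduce the qualitative failure modes this
analysis style is designed to separate:

- **TEB-like** (`slope 0.5, offset 5, noise_sd 6`): a large negative bias
  that grows with SV — proportional bias.
- **SSD-like** (`slope 1, offset 0, noise_sd 10, subject_sd 15`): near-zero
  bias but wide limits of agreement. The split between per-subject
  calibration error and per-reading noise matters: pure per-reading noise
  of the same total magnitude would destroy trend correlation (r ≈ 0.4)
  in a way real Doppler monitors do not exhibit, because much of their
  disagreement is a per-patient calibration offset that cancels in
  percent change. With the split, simulated trending lands at r ≈ 0.6–0.75
  and concordance near 90% while the single-difference SD stays ≈ 18.5 ml
  (percentage error ≈ 40%).

Measurement noise is independent across steps within a subject (beyond the
per-subject offset); the generator does not model baroreflex dynamics,
heart-rate compensation, or serial correlation of device drift, so passing
tests demonstrate the statistical machinery, not physiological realism.

## Repeated-measures Bland-Altman

Differences `d = SV_dev − SV_ref` are grouped by subject. The bias is the
grand mean of all differences. For limits of agreement the default
(`repeated_varying`) rebuilds the SD of a *single* difference from a
one-way variance-component decomposition (the multiple-observations-per-
individual method for a measurand that varies within subjects):

    MSB = Σ m_i (d̄_i − d̄)² / (k−1),   MSW = Σ Σ (d_ij − d̄_i)² / (N−k)
    n0  = (N − Σ m_i²/N) / (k−1)
    σ_d² = max(0, (MSB − MSW)/n0) + MSW

with `k` subjects, `m_i` pairs each, `N` total. Subjects with a single
pair contribute no within-subject information and are flagged
(`SINGLETON_SUBJECTS`); when every subject has one pair the estimate
reduces exactly to the pooled SD, and with fewer than two subjects the fit
falls back to `pooled_naive` with a `FALLBACK_POOLED` warning. This
variant was chosen because the study design induces a *range* of SVs per
subject; the naive pooled SD is kept as an explicit alternative.

Percentage error is `100 · 1.96 σ_d / mean(SV_ref)` with the grand mean of
reference readings over the included pairs (equal weight per pair).

**Proportional bias.** The slope of `d` on a measurand proxy is tested and,
when significant at `slope_p_threshold` (default 0.05), the limits of
agreement and percentage error are marked not reportable
(`LOA_SUPPRESSED`) — mirroring how devices whose bias visibly grows with SV
are reported. Two numerical choices here were genuinely open:

- *Regressor.* The classical difference-vs-mean plot is kept for plotting,
  but the default regression uses the **reference** reading. When the
  candidate is far noisier than the reference, the candidate's noise enters
  both the difference and the pair mean, producing a spurious positive
  slope that flags even a perfectly linear slope-1 device; regressing on
  the reference answers the question actually posed (does the error grow
  with the measurand as estimated by the standard?) at the cost of mild
  attenuation from reference noise (ref_cv ≈ 5%). `proportional_regressor
  ="mean"` restores the classical variant.
- *Inference.* Repeated differences within a subject share the calibration
  error, so ordinary least-squares p-values treat ~150 correlated pairs as
  independent and over-reject. The p-value therefore uses cluster-robust
  standard errors grouped by subject (t reference, `statsmodels` OLS),
  reducing to ordinary inference when subjects are singletons or fewer
  than three.

## Trend analysis

Deltas are percent change from the subject's own baseline, reference and
device each against their own baseline reading — which is why a purely
proportional device error cancels in trend space. The baseline step is
excluded (its delta is identically zero); subjects without a baseline are
skipped with a `MISSING_BASELINE` warning.

Four-quadrant concordance excludes pairs in the central square
`|Δref| < t AND |Δdev| < t` (default `t = 15%`; `or` and reference-only
variants are available because the literature varies). Among the rest, a
pair is concordant when both deltas have the same strict sign; pairs with
an exactly zero delta outside the square leave the denominator (sign
agreement is undefined at zero). Pearson r is computed over **all** pairs,
since it is reported alongside, not within, the concordance analysis.

## Error grid

Each questionnaire respondent supplies two action thresholds (the % SV
fall at which action is *indicated* and at which it is *essential*) and a
none/mild/moderate/severe harm rating for every cell of the actual ×
measured fall grid (default 0–60% in 10% steps; diagonal cells are by
construction "none"). The synthetic respondent rates a cell by the
mismatch between the action categories its two coordinates imply: same
category → none; two categories apart → severe; adjacent → moderate when
the device underestimates a fall that made action essential (missed
resuscitation), otherwise mild. An optional per-cell jitter (default
probability 0.1) moves a rating one category to emulate panel
disagreement.

Scores use weights none 0, mild 2, moderate 5, severe 10, **summed** over
respondents (so 15 respondents span 0–150) and rescaled to percent of the
maximum. Cells are banded at percent thresholds (13.3, 35, 75): below a
mean per-respondent weight of 1.33 the cell is treated as no-risk, 75%+ is
severe-dominant, 35 splits the mild/moderate transition midway. Any
programmatic banding of what was originally a hand-drawn colour judgement
is a design decision; the thresholds are configurable and a hand-drawn
zone file can be loaded from JSON instead (`provenance =
loaded_from_file`).

Same-band cells are merged into rectilinear polygons on cell boundaries
(midpoints between grid steps; no smoothing, for testability — a zone may
have two components, one above and one below the diagonal). Points are
classified by polygon cover, checked severe → none so boundary ties go to
the higher-harm zone (conservative clinical reporting), with two
refinements: points outside the domain are clamped to its edge rather than
dropped (the published analysis plots all matched pairs), and a point with
`actual == measured` carries no measurement error, so it is classified
"none" whenever the none zone contains it — without this, a zero-error
point whose coordinates land exactly on a cell corner (e.g. a −15% step
under the default grid) would be labelled harmful by the tie-break. The
grid is never symmetrised: over- and under-estimation of blood loss harm
differently.

Zone percentages are displayed as integers (half-up); the pooled
severe-harm rate across strands is reported to one decimal. Both
conventions reproduce the display style of published error-grid summaries.

## Pipeline determinism and problem sizes

`run()` derives independent sub-seeds for each strand and for the
questionnaire from the single user seed via `numpy` seed sequences, so
re-running a configuration is byte-identical (no timestamps in outputs)
and removing a device from the configuration does not alter the RNG
stream... with one caveat: per-step draws interleave devices, so per-device
reproducibility is guaranteed at the report level by re-running, not by
stream splicing. Stage failures are isolated per device × strand and
recorded in the report rather than aborting the run.

Default problem sizes throughout the tests and examples — 21 subjects × 7
steps × 2 strands, 15 respondents, 200 replicate cohorts for the
parameter-recovery check, 1,000 random instances for the four-quadrant
brute-force equivalence — keep any single check under a few seconds while
leaving Monte-Carlo standard errors well inside the asserted tolerances.

## Known limitations

- Phenomenological device models only; no physiological feedback loops.
- No confidence intervals for the limits of agreement.
- No polar-plot (half-moon) trend analysis; four-quadrant only.
- The derived zone polygons are rectilinear; the optional smoothing of
  hand-drawn grids is supported only by loading externally drawn polygons.
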