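# svagree

Method-comparison statistics for validating non-invasive stroke-volume (SV)
monitors against a reference standard, built around the study design used in
lower-body-negative-pressure (LBNP) simulated-haemorrhage experiments: every
subject contributes paired readings at several induced stroke volumes, so
all of the agreement statistics must respect repeated measures.

The package is for clinical researchers comparing cardiac-output or
stroke-volume monitors (echocardiography vs bioimpedance, Doppler,
pulse-contour, ...) who need, in one place:

- **Repeated-measures Bland-Altman** — bias `d̄ = mean(SV_dev − SV_ref)`
  with limits of agreement `d̄ ± 1.96·σ_d`, where `σ_d²` combines the
  between-subject and within-subject variance components of the differences
  (one-way decomposition for multiple observations per individual with a
  varying measurand). A `pooled_naive` variant (plain SD of all
  differences) is available; the two coincide when each subject has one
  pair.
- **Percentage error** — `PE = 100 · 1.96·σ_d / mean(SV_ref)`, with 30%
  the conventional acceptability limit.
- **Proportional-bias screening** — the slope of the differences on the
  reference reading, tested with cluster-robust (by-subject) standard
  errors; when significant, limits of agreement and percentage error are
  marked not reportable rather than printed misleadingly.
- **Four-quadrant trend concordance** — percent change from each subject's
  own baseline, `Δ = 100·(SV_step − SV_base)/SV_base`, per device; pairs
  inside a central 15% exclusion square are dropped and the concordance
  rate is the share of remaining pairs whose changes agree in sign
  (~90% is conventionally acceptable), with Pearson r over all pairs.
- **Expert-opinion error grid** — clinician harm ratings (none / mild /
  moderate / severe, weighted 0 / 2 / 5 / 10) over an actual-vs-measured
  SV-fall grid are summed into cell scores (0 to 10·n_respondents),
  banded into four risk-zone polygons, and each measurement pair is
  classified by the zone it falls in — translating statistical error into
  potential patient harm.
- **A synthetic LBNP cohort and questionnaire simulator** so the entire
  pipeline runs, and is tested, without any clinical data: subjects step
  from baseline through suction levels targeting 80%, 65–70% and 55–64%
  of baseline SV, and candidate devices read the true SV through
  configurable error models (gain, offset, per-subject calibration error,
  per-reading noise).

## Worked example

```bash
svagree run-all --seed 42 --out-dir out/
```

simulates both study arms (LBNP alone, and LBNP with thigh tourniquets)
for 21 subjects × 7 protocol steps with two default device models — a
bioimpedance-like monitor (gain 0.5, so its bias grows with SV) and a
Doppler-like monitor (gain 1, wide noise) — then runs every analysis and
prints:

```
svagree run (seed 42)

device: teb
  strand: no_tourniquet
    bias -38.1 ml (n=147), LoA suppressed (proportional bias), PE suppressed
    concordance 85% (126 pairs, 33 excluded), r = 0.67
    error grid: none 85 (67%), mild 36 (29%), moderate 3 (2%), severe 2 (2%)
  strand: tourniquet
    bias -36.7 ml (n=147), LoA suppressed (proportional bias), PE suppressed
    concordance 89% (126 pairs, 34 excluded), r = 0.71
    error grid: none 88 (70%), mild 32 (25%), moderate 5 (4%), severe 1 (1%)
  combined severe-harm rate: 1.2%

device: ssd
  strand: no_tourniquet
    bias 5.9 ml (n=147), LoA -29.0 to 40.8 ml, PE 40.7%
    concordance 89% (126 pairs, 36 excluded), r = 0.69
    error grid: none 86 (68%), mild 34 (27%), moderate 5 (4%), severe 1 (1%)
  strand: tourniquet
    bias -4.4 ml (n=147), LoA -39.1 to 30.3 ml, PE 41.5%
    concordance 85% (126 pairs, 32 excluded), r = 0.64
    error grid: none 82 (65%), mild 30 (24%), moderate 12 (10%), severe 2 (2%)
  combined severe-harm rate: 1.2%
```

Read it as a device-validation verdict. The bioimpedance-like device's
error grows with stroke volume, so a single pair of limits of agreement
would misrepresent it — they are suppressed and no percentage error is
quoted. The Doppler-like device has near-zero bias but a percentage error
around 40%, well above the 30% acceptability limit. Both devices *trend*
acceptably (concordance 85–89%), yet the error grid shows that a minority
of readings would still have prompted decisions clinicians rate as
moderately or severely harmful — the central message this analysis style
is designed to expose. All intermediate tables (Bland-Altman points,
four-quadrant points, harm grid, zone polygons, classified points) are
written to `out/` as CSV/JSON.

The same analyses run on your own data from Python:

```python
import pandas as pd
from svagree import BlandAltman, FourQuadrant, compute_deltas
from svagree.simulate import frame_to_cohort

df = pd.read_csv("cohort.csv")         # subject_id, strand, step_index, sv_ref, sv_<device>
res = BlandAltman.from_dataframe(df, "ssd").fit().suppress_if_proportional()
print(res.summary())
print(FourQuadrant(compute_deltas(frame_to_cohort(df), "ssd")).fit().summary())
```

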