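"""Synthetic LBNP cohorts and expert-questionnaire returns.

Lower body negative pressure (LBNP) pools blood in the pelvis and legs of a
supine volunteer, simulating progressive haemorrhage without blood loss.  The
protocol emulated here starts at a resting baseline, applies two fixed
suction steps (nominally -10 and -20 mmHg), then titrates suction to stroke
volume (SV) targets of 80%, 65-70% and 55-64% of baseline, and finally
releases suction (recovery).  At each step the reference monitor
(echocardiography-like) and one or more candidate devices read the same
underlying true SV through their own error models.

A candidate device is phenomenological: reading = slope * SV_true + offset +
noise.  A proportional device (slope != 1) produces a bias that grows with
SV — the signature failure mode of thoracic bioimpedance in this setting —
while a slope-1 device with wide noise mimics suprasternal Doppler.

The questionnaire generator emulates an expert-elicitation exercise: each
respondent states the percentage SV fall at which action is *indicated* and
at which it is *essential*, and then rates the clinical harm of every
(actual fall, measured fall) discrepancy on a grid as none / mild /
moderate / severe.  Ratings follow a deterministic category-mismatch rule
derived from the respondent's own thresholds, optionally jittered.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "HARM_CATEGORIES",
    "ProtocolConfig",
    "DeviceModel",
    "MeasurementRecord",
    "RespondentProfile",
    "QuestionnaireReturn",
    "TEB_LIKE",
    "SSD_LIKE",
    "simulate_cohort",
    "simulate_questionnaire",
    "rate_cell",
    "make_return",
    "cohort_to_frame",
    "frame_to_cohort",
    "questionnaire_to_frame",
    "frame_to_questionnaire",
]

#: Harm categories in increasing severity; indices are used for the
#: category-mismatch arithmetic below.
HARM_CATEGORIES = ("none", "mild", "moderate", "severe")

STRANDS = ("no_tourniquet", "tourniquet")

#: Default protocol: baseline, two fixed suction steps, three SV-target
#: steps (band targets represented by their midpoints), recovery.
DEFAULT_STEP_TARGETS = (1.00, 0.92, 0.85, 0.80, 0.675, 0.595, 1.00)
DEFAULT_STEP_LABELS = (
    "baseline",
    "lbnp_-10mmHg",
    "lbnp_-20mmHg",
    "target_80",
    "target_65-70",
    "target_55-64",
    "recovery",
)
#: step index -> (low, high) fractional-SV band, used when
#: ``sample_within_bands`` is set instead of the midpoint target.
DEFAULT_TARGET_BANDS = {4: (0.65, 0.70), 5: (0.55, 0.64)}


@dataclass(frozen=True)
class ProtocolConfig:
    """Cohort-level simulation parameters for one study strand.

    ``step_targets`` are fractions of each subject's own baseline SV; the
    first entry must be 1.0 (the baseline step) and the last entry must not
    undercut the preceding minimum (recovery).  ``within_step_cv`` is the
    coefficient of variation of the realised true SV around its target;
    ``ref_cv`` is the multiplicative measurement noise of the reference
    monitor.
    """

    n_subjects: int = 21
    strand: str = "no_tourniquet"
    baseline_sv_mean: float = 100.0
    baseline_sv_sd: float = 15.0
    step_targets: tuple[float, ...] = DEFAULT_STEP_TARGETS
    step_labels: tuple[str, ...] | None = None
    within_step_cv: float = 0.03
    ref_cv: float = 0.05
    sample_within_bands: bool = False
    target_bands: dict[int, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_TARGET_BANDS)
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if self.strand not in STRANDS:
            raise ValueError(f"strand must be one of {STRANDS}")
        if self.baseline_sv_mean <= 0:
            raise ValueError("baseline_sv_mean must be positive")
        if self.baseline_sv_sd < 0:
            raise ValueError("baseline_sv_sd must be >= 0")
        if len(self.step_targets) == 0:
            raise ValueError("step_targets must be non-empty")
        if any(not (0 < t <= 1.1) for t in self.step_targets):
            raise ValueError("step_targets must lie in (0, 1.1]")
        if self.step_targets[0] != 1.0:
            raise ValueError("first step target must be 1.0 (baseline)")
        if len(self.step_targets) > 2:
            if self.step_targets[-1] < min(self.step_targets[:-1]):
                raise ValueError("final step target must be >= preceding minimum")
        if self.step_labels is not None and len(self.step_labels) != len(self.step_targets):
            raise ValueError("step_labels length must match step_targets")
        if self.within_step_cv < 0 or self.ref_cv < 0:
            raise ValueError("coefficients of variation must be >= 0")

    @property
    def labels(self) -> tuple[str, ...]:
        if self.step_labels is not None:
            return self.step_labels
        if self.step_targets == DEFAULT_STEP_TARGETS:
            return DEFAULT_STEP_LABELS
        return tuple(f"step_{i}" for i in range(len(self.step_targets)))


@dataclass(frozen=True)
class DeviceModel:
    """Phenomenological error model of a candidate SV monitor.

    reading = slope * SV_true + offset + subject_offset + N(0, noise_sd),
    where subject_offset ~ N(0, subject_sd) is drawn once per subject and
    session: a calibration error that widens absolute limits of agreement
    but largely cancels in percent change from baseline, the way real
    monitors disagree more between patients than within one.  Readings may
    additionally be scaled by a multiplicative jitter with SD
    ``trend_noise_sd``, which degrades trend readings without shifting the
    mean.
    """

    name: str
    slope: float = 1.0
    offset: float = 0.0
    noise_sd: float = 0.0
    subject_sd: float = 0.0
    trend_noise_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.slope <= 0:
            raise ValueError("slope must be positive")
        if min(self.noise_sd, self.subject_sd, self.trend_noise_sd) < 0:
            raise ValueError("noise SDs must be >= 0")


#: Defaults chosen to reproduce the qualitative published pattern: a
#: bioimpedance-like device whose bias grows with SV, and a Doppler-like
#: device with near-zero bias but wide limits of agreement.
TEB_LIKE = DeviceModel(name="teb", slope=0.5, offset=5.0, noise_sd=6.0)
SSD_LIKE = DeviceModel(name="ssd", slope=1.0, offset=0.0, noise_sd=10.0, subject_sd=15.0)

#: Simulated readings are truncated below at this value (ml): percent-change
#: maths downstream requires strictly positive baselines.
SV_FLOOR = 1.0


@dataclass(frozen=True)
class MeasurementRecord:
    """One protocol step for one subject: true SV, the reference reading and
    one reading per candidate device."""

    subject_id: str
    strand: str
    step_index: int
    step_label: str
    sv_true: float
    sv_ref: float
    sv_dev: dict[str, float]

    def __post_init__(self) -> None:
        if self.sv_true <= 0 or self.sv_ref <= 0:
            raise ValueError("stroke volumes must be positive")
        if any(v <= 0 for v in self.sv_dev.values()):
            raise ValueError("device readings must be positive")


def simulate_cohort(
    config: ProtocolConfig, devices: list[DeviceModel]
) -> list[MeasurementRecord]:
    """Simulate one strand of the LBNP protocol for a cohort of subjects.

    For subject *i* at step *s*: ``sv_true = baseline_i * target_s *
    (1 + N(0, within_step_cv))``, the reference reads ``sv_true *
    (1 + N(0, ref_cv))`` and each device reads through its own
    :class:`DeviceModel`.  All readings are truncated below at 1 ml.
    Bit-reproducible under a fixed ``config.seed``.
    """
    if not devices:
        raise ValueError("at least one device model is required")
    names = [d.name for d in devices]
    if len(set(names)) != len(names):
        raise ValueError("device names must be unique")

    rng = np.random.default_rng(config.seed)
    baselines = rng.normal(
        config.baseline_sv_mean, config.baseline_sv_sd, config.n_subjects
    )
    baselines = np.maximum(baselines, SV_FLOOR)

    records: list[MeasurementRecord] = []
    labels = config.labels
    for i in range(config.n_subjects):
        subject_id = f"{config.strand}_s{i + 1:02d}"
        subject_offsets = {
            dev.name: rng.normal(0.0, dev.subject_sd) if dev.subject_sd > 0 else 0.0
            for dev in devices
        }
        for s, target in enumerate(config.step_targets):
            if config.sample_within_bands and s in config.target_bands:
                lo, hi = config.target_bands[s]
                target = rng.uniform(lo, hi)
            sv_true = baselines[i] * target * (1.0 + rng.normal(0.0, config.within_step_cv))
            sv_true = max(sv_true, SV_FLOOR)
            sv_ref = sv_true * (1.0 + rng.normal(0.0, config.ref_cv))
            sv_ref = max(sv_ref, SV_FLOOR)
            readings: dict[str, float] = {}
            for dev in devices:
                value = (
                    dev.slope * sv_true
                    + dev.offset
                    + subject_offsets[dev.name]
                    + rng.normal(0.0, dev.noise_sd)
                )
                if dev.trend_noise_sd > 0:
                    value *= 1.0 + rng.normal(0.0, dev.trend_noise_sd)
                readings[dev.name] = max(value, SV_FLOOR)
            records.append(
                MeasurementRecord(
                    subject_id=subject_id,
                    strand=config.strand,
                    step_index=s,
                    step_label=labels[s],
                    sv_true=sv_true,
                    sv_ref=sv_ref,
                    sv_dev=readings,
                )
            )
    return records


def cohort_to_frame(records: list[MeasurementRecord]) -> pd.DataFrame:
    """Wide table: one row per subject-step, one ``sv_<device>`` column per device."""
    if not records:
        raise ValueError("no records")
    rows = []
    for r in records:
        row = {
            "subject_id": r.subject_id,
            "strand": r.strand,
            "step_index": r.step_index,
            "step_label": r.step_label,
            "sv_true": r.sv_true,
            "sv_ref": r.sv_ref,
        }
        for name, value in r.sv_dev.items():
            row[f"sv_{name}"] = value
        rows.append(row)
    return pd.DataFrame(rows)


def frame_to_cohort(df: pd.DataFrame) -> list[MeasurementRecord]:
    """Inverse of :func:`cohort_to_frame`; device columns are ``sv_<name>``."""
    reserved = {"subject_id", "strand", "step_index", "step_label", "sv_true", "sv_ref"}
    device_cols = [c for c in df.columns if c.startswith("sv_") and c not in reserved]
    records = []
    for _, row in df.iterrows():
        records.append(
            MeasurementRecord(
                subject_id=str(row["subject_id"]),
                strand=str(row["strand"]),
                step_index=int(row["step_index"]),
                step_label=str(row["step_label"]),
                sv_true=float(row.get("sv_true", row["sv_ref"])),
                sv_ref=float(row["sv_ref"]),
                sv_dev={c[3:]: float(row[c]) for c in device_cols if pd.notna(row[c])},
            )
        )
    return records


# ---------------------------------------------------------------------------
# Expert questionnaire
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RespondentProfile:
    """One clinician's action thresholds (% SV fall) and rating jitter.

    Falls below ``threshold_action_indicated`` need no action; falls at or
    above ``threshold_action_essential`` make action essential; in between,
    action is indicated.
    """

    respondent_id: str
    threshold_action_indicated: float
    threshold_action_essential: float
    rating_noise: float = 0.0

    def __post_init__(self) -> None:
        if not (0 < self.threshold_action_indicated < self.threshold_action_essential <= 60):
            raise ValueError(
                "need 0 < threshold_action_indicated < threshold_action_essential <= 60"
            )
        if not (0 <= self.rating_noise <= 1):
            raise ValueError("rating_noise must be a probability")

    def action_category(self, fall_pct: float) -> int:
        """0 = no action, 1 = action indicated, 2 = action essential."""
        if fall_pct >= self.threshold_action_essential:
            return 2
        if fall_pct >= self.threshold_action_indicated:
            return 1
        return 0


@dataclass(frozen=True)
class QuestionnaireReturn:
    """One respondent's harm ratings over the (actual, measured) fall grid.

    ``ratings[i, j]`` is the category for actual fall ``grid_steps[i]`` and
    measured fall ``grid_steps[j]``; the diagonal (no measurement error) is
    always "none".
    """

    respondent_id: str
    grid_steps: tuple[float, ...]
    ratings: tuple[tuple[str, ...], ...]

    def __post_init__(self) -> None:
        _validate_grid_steps(self.grid_steps)
        n = len(self.grid_steps)
        if len(self.ratings) != n or any(len(row) != n for row in self.ratings):
            raise ValueError("ratings must cover every grid_steps x grid_steps cell")
        for row in self.ratings:
            for cat in row:
                if cat not in HARM_CATEGORIES:
                    raise ValueError(f"unknown harm category {cat!r}")
        for i in range(n):
            if self.ratings[i][i] != "none":
                raise ValueError("diagonal cells (actual == measured) must be rated none")


def _validate_grid_steps(grid_steps: tuple[float, ...]) -> None:
    if len(grid_steps) < 2:
        raise ValueError("grid_steps needs at least 2 values")
    if grid_steps[0] != 0:
        raise ValueError("grid_steps must start at 0")
    if any(b <= a for a, b in zip(grid_steps, grid_steps[1:])):
        raise ValueError("grid_steps must be strictly increasing")


def rate_cell(profile: RespondentProfile, actual: float, measured: float) -> str:
    """Deterministic harm rating for one grid cell under a respondent's thresholds.

    Same action category -> none.  Two categories apart -> severe.  Adjacent
    categories -> moderate when the device underestimates the fall and action
    was actually essential (missed resuscitation), otherwise mild.
    """
    if actual == measured:
        return "none"
    cat_a = profile.action_category(actual)
    cat_m = profile.action_category(measured)
    gap = abs(cat_a - cat_m)
    if gap == 0:
        return "none"
    if gap == 2:
        return "severe"
    if cat_m < cat_a and cat_a == 2:
        return "moderate"
    return "mild"


def make_return(
    profile: RespondentProfile,
    grid_steps: tuple[float, ...],
    rng: np.random.Generator | None = None,
) -> QuestionnaireReturn:
    """Build one questionnaire return; jitter applied off-diagonal only."""
    _validate_grid_steps(tuple(grid_steps))
    n = len(grid_steps)
    out: list[list[str]] = []
    for i in range(n):
        row = []
        for j in range(n):
            cat = rate_cell(profile, grid_steps[i], grid_steps[j])
            if (
                i != j
                and profile.rating_noise > 0
                and rng is not None
                and rng.random() < profile.rating_noise
            ):
                idx = HARM_CATEGORIES.index(cat)
                idx += 1 if rng.random() < 0.5 else -1
                cat = HARM_CATEGORIES[int(np.clip(idx, 0, 3))]
            row.append(cat)
        out.append(row)
    return QuestionnaireReturn(
        respondent_id=profile.respondent_id,
        grid_steps=tuple(float(g) for g in grid_steps),
        ratings=tuple(tuple(row) for row in out),
    )


DEFAULT_GRID_STEPS = (0.0, 10.0, 20.0, 30.0, 40.0, 50.0, 60.0)


def simulate_questionnaire(
    n_respondents: int,
    grid_steps: tuple[float, ...] = DEFAULT_GRID_STEPS,
    profiles_seed: int = 0,
    rating_noise: float = 0.1,
    profiles: list[RespondentProfile] | None = None,
) -> list[QuestionnaireReturn]:
    """Simulate expert returns over a fall-percentage grid.

    Unless explicit ``profiles`` are given, action thresholds are drawn per
    respondent (indicated: 10-30% fall, essential: a further 10-25%, both
    rounded to 5% as clinicians answer in round figures) and each rating is
    jittered by one category with probability ``rating_noise``.
    """
    if n_respondents < 1:
        raise ValueError("n_respondents must be >= 1")
    grid_steps = tuple(float(g) for g in grid_steps)
    _validate_grid_steps(grid_steps)
    rng = np.random.default_rng(profiles_seed)
    if profiles is None:
        profiles = []
        for r in range(n_respondents):
            t1 = 5 * round(rng.uniform(10, 30) / 5)
            t2 = 5 * round((t1 + rng.uniform(10, 25)) / 5)
            t1 = float(np.clip(t1, 5, 50))
            t2 = float(np.clip(max(t2, t1 + 5), t1 + 5, 60))
            profiles.append(
                RespondentProfile(
                    respondent_id=f"r{r + 1:02d}",
                    threshold_action_indicated=t1,
                    threshold_action_essential=t2,
                    rating_noise=rating_noise,
                )
            )
    elif len(profiles) != n_respondents:
        raise ValueError("len(profiles) must equal n_respondents")
    return [make_return(p, grid_steps, rng) for p in profiles]


def questionnaire_to_frame(returns: list[QuestionnaireReturn]) -> pd.DataFrame:
    """Long-form table: respondent_id, actual_reduction_pct, measured_reduction_pct, rating."""
    rows = []
    for ret in returns:
        for i, a in enumerate(ret.grid_steps):
            for j, m in enumerate(ret.grid_steps):
                rows.append(
                    {
                        "respondent_id": ret.respondent_id,
                        "actual_reduction_pct": a,
                        "measured_reduction_pct": m,
                        "rating": ret.ratings[i][j],
                    }
                )
    return pd.DataFrame(rows)


def frame_to_questionnaire(df: pd.DataFrame) -> list[QuestionnaireReturn]:
    """Inverse of :func:`questionnaire_to_frame`."""
    returns = []
    for rid, grp in df.groupby("respondent_id", sort=True):
        steps = tuple(sorted(grp["actual_reduction_pct"].unique()))
        index = {v: k for k, v in enumerate(steps)}
        n = len(steps)
        ratings = [["none"] * n for _ in range(n)]
        for _, row in grp.iterrows():
            i = index[row["actual_reduction_pct"]]
            j = index[row["measured_reduction_pct"]]
            ratings[i][j] = str(row["rating"])
        returns.append(
            QuestionnaireReturn(
                respondent_id=str(rid),
                grid_steps=tuple(float(s) for s in steps),
                ratings=tuple(tuple(r) for r in ratings),
            )
        )
    return returns
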