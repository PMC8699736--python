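"""Trend agreement: change-from-baseline deltas and four-quadrant concordance.

A monitor that mis-scales stroke volume can still track its *direction* of
change: a purely proportional gain cancels exactly in percent change from
baseline, which is why trending is analysed separately from absolute
agreement.  Each reading is expressed as a signed percent change from the
subject's own baseline, reference and device each against their own
baseline reading.  The four-quadrant analysis scatters reference change
against device change, drops pairs inside a central exclusion square
(conventionally 15%, where direction is dominated by noise), and reports
the fraction of remaining pairs whose changes agree in sign — the
concordance rate, with ~90% the conventional acceptability mark.  Pearson
correlation of the deltas is reported alongside, computed over all pairs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .simulate import MeasurementRecord

__all__ = [
    "DeltaPair",
    "ConcordanceSummary",
    "FourQuadrant",
    "FourQuadrantResults",
    "compute_deltas",
    "four_quadrant",
    "pearson",
]

logger = logging.getLogger(__name__)

DEFAULT_EXCLUSION_PCT = 15.0


@dataclass(frozen=True)
class DeltaPair:
    """Signed percent change from baseline (negative = reduction) for one
    observation: reference vs device, each against its own baseline."""

    subject_id: str
    strand: str
    step_index: int
    delta_ref: float
    delta_dev: float


def compute_deltas(
    records: list[MeasurementRecord],
    device: str,
    baseline_step: int = 0,
) -> list[DeltaPair]:
    """Percent change from each subject's baseline for reference and device.

    delta = 100 * (value_at_step - baseline_value) / baseline_value, with the
    baseline step itself excluded (its delta is identically zero).  Subjects
    lacking a baseline record, or lacking the device reading at baseline, are
    skipped with a warning.
    """
    by_subject: dict[str, list[MeasurementRecord]] = {}
    for r in records:
        by_subject.setdefault(r.subject_id, []).append(r)

    deltas: list[DeltaPair] = []
    for subject_id, recs in by_subject.items():
        base = [r for r in recs if r.step_index == baseline_step]
        if not base or device not in base[0].sv_dev:
            logger.warning("MISSING_BASELINE subject=%s device=%s", subject_id, device)
            continue
        base_ref = base[0].sv_ref
        base_dev = base[0].sv_dev[device]
        if base_ref <= 0 or base_dev <= 0:
            raise ValueError(f"non-positive baseline for subject {subject_id}")
        for r in recs:
            if r.step_index == baseline_step or device not in r.sv_dev:
                continue
            deltas.append(
                DeltaPair(
                    subject_id=subject_id,
                    strand=r.strand,
                    step_index=r.step_index,
                    delta_ref=100.0 * (r.sv_ref - base_ref) / base_ref,
                    delta_dev=100.0 * (r.sv_dev[device] - base_dev) / base_dev,
                )
            )
    return deltas


@dataclass(frozen=True)
class ConcordanceSummary:
    """Four-quadrant outcome. ``concordance_rate`` is ``None`` when every
    pair is excluded (direction agreement undefined)."""

    n_total: int
    n_excluded: int
    n_concordant: int
    concordance_rate: float | None
    pearson_r: float | None
    pearson_p: float | None
    exclusion_threshold: float
    exclusion_mode: str = "and"


def _excluded_mask(
    dref: np.ndarray, ddev: np.ndarray, threshold: float, mode: str
) -> np.ndarray:
    if mode == "and":  # central square
        return (np.abs(dref) < threshold) & (np.abs(ddev) < threshold)
    if mode == "or":
        return (np.abs(dref) < threshold) | (np.abs(ddev) < threshold)
    if mode == "ref_only":
        return np.abs(dref) < threshold
    raise ValueError("exclusion_mode must be 'and', 'or' or 'ref_only'")


class FourQuadrant:
    """Four-quadrant concordance model over a set of delta pairs.

    ``exclusion_mode`` controls zone membership: ``"and"`` (default, the
    central square — both deltas small), ``"or"``, or ``"ref_only"``.
    """

    def __init__(
        self,
        deltas: list[DeltaPair],
        exclusion_threshold: float = DEFAULT_EXCLUSION_PCT,
        exclusion_mode: str = "and",
    ):
        if not deltas:
            raise ValueError("need at least one delta pair")
        if exclusion_threshold < 0:
            raise ValueError("exclusion_threshold must be >= 0")
        self.deltas = list(deltas)
        self.exclusion_threshold = float(exclusion_threshold)
        self.exclusion_mode = exclusion_mode
        self.dref = np.array([d.delta_ref for d in deltas], dtype=float)
        self.ddev = np.array([d.delta_dev for d in deltas], dtype=float)

    def fit(self) -> "FourQuadrantResults":
        excluded = _excluded_mask(
            self.dref, self.ddev, self.exclusion_threshold, self.exclusion_mode
        )
        # Sign agreement is undefined at zero: a zero delta outside the
        # square leaves the denominator too.
        zero_sign = (~excluded) & ((self.dref == 0) | (self.ddev == 0))
        out = excluded | zero_sign
        included = ~out
        concordant = included & (np.sign(self.dref) == np.sign(self.ddev))

        n_total = int(self.dref.size)
        n_excluded = int(out.sum())
        n_concordant = int(concordant.sum())
        denom = n_total - n_excluded
        rate = 100.0 * n_concordant / denom if denom > 0 else None
        if rate is None:
            logger.warning("ALL_PAIRS_EXCLUDED n=%d", n_total)

        r = p = None
        if n_total >= 3 and self.dref.std() > 0 and self.ddev.std() > 0:
            r_, p_ = stats.pearsonr(self.dref, self.ddev)
            r, p = float(r_), float(p_)

        summary = ConcordanceSummary(
            n_total=n_total,
            n_excluded=n_excluded,
            n_concordant=n_concordant,
            concordance_rate=rate,
            pearson_r=r,
            pearson_p=p,
            exclusion_threshold=self.exclusion_threshold,
            exclusion_mode=self.exclusion_mode,
        )
        return FourQuadrantResults(self, summary, included, concordant)


class FourQuadrantResults:
    """Fitted four-quadrant results with per-pair flags for plotting."""

    def __init__(self, model, summary, included, concordant):
        self.model = model
        self._summary = summary
        self.included = included
        self.concordant = concordant

    def __getattr__(self, name):
        try:
            return getattr(self._summary, name)
        except AttributeError:
            raise AttributeError(name) from None

    def as_summary(self) -> ConcordanceSummary:
        return self._summary

    def plot_data(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "subject_id": [d.subject_id for d in self.model.deltas],
                "delta_ref": self.model.dref,
                "delta_dev": self.model.ddev,
                "included": self.included,
                "concordant": self.concordant,
            }
        )

    def summary(self) -> str:
        s = self._summary
        rate = "undefined" if s.concordance_rate is None else f"{s.concordance_rate:.1f}%"
        r = "n/a" if s.pearson_r is None else f"{s.pearson_r:.3f} (p = {s.pearson_p:.3g})"
        return "\n".join(
            [
                "Four-quadrant concordance",
                f"  pairs (excluded)   {s.n_total} ({s.n_excluded} inside "
                f"{s.exclusion_threshold:g}% zone or zero)",
                f"  concordant         {s.n_concordant}",
                f"  concordance rate   {rate}",
                f"  Pearson r          {r}",
            ]
        )


def four_quadrant(
    deltas: list[DeltaPair],
    exclusion_threshold: float = DEFAULT_EXCLUSION_PCT,
    exclusion_mode: str = "and",
) -> ConcordanceSummary:
    """Functional entry point over :class:`FourQuadrant`."""
    return FourQuadrant(deltas, exclusion_threshold, exclusion_mode).fit().as_summary()


def pearson(deltas: list[DeltaPair]) -> tuple[float, float]:
    """Product-moment correlation of (delta_ref, delta_dev) with two-sided p."""
    if len(deltas) < 3:
        raise ValueError("need at least 3 pairs")
    x = np.array([d.delta_ref for d in deltas])
    y = np.array([d.delta_dev for d in deltas])
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance in deltas")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)
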