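"""Absolute-value agreement: repeated-measures Bland-Altman and percentage error.

In an LBNP protocol every subject contributes paired readings at several
induced stroke volumes, so the plain SD of the pooled differences is not a
valid basis for limits of agreement.  The default here is the Bland-Altman
multiple-observations-per-individual method for a measurand that varies
within subjects: the SD of a single device-minus-reference difference is
rebuilt from a one-way variance-component decomposition of the differences
grouped by subject, combining the between-subject variance of the mean
difference with the within-subject variance.  A ``pooled_naive`` alternative
(plain SD of all differences) is available for comparison; the two coincide
when every subject contributes exactly one pair.

Percentage error follows the cardiac-output convention: 100 * 1.96 * SD of
the differences divided by the mean reference stroke volume, with 30%
usually quoted as the acceptability limit.  When the difference grows with
the underlying stroke volume (proportional bias, detected by regressing the
differences on the pair means), a single pair of limits of agreement is
misleading; :meth:`BlandAltmanResults.suppress_if_proportional` marks the
limits and the percentage error as not reportable in that case.

The proportional-bias regression uses the reference reading as regressor by
default rather than the pair mean: when the candidate is much noisier than
the reference, its noise appears in both the difference and the mean,
manufacturing a spurious positive slope that would flag well-behaved
devices.  Regressing on the reference tests the question actually asked —
does the error grow with the measurand as estimated by the standard?  The
pair mean remains available via ``proportional_regressor="mean"``.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "AgreementSummary",
    "BlandAltman",
    "BlandAltmanResults",
    "bland_altman_repeated",
    "percentage_error",
    "suppress_loa_if_proportional",
]

Z_LOA = 1.96


@dataclass(frozen=True)
class AgreementSummary:
    """Bland-Altman statistics for one device against the reference.

    ``loa_low``/``loa_high``/``percentage_error`` are ``None`` when marked
    not reportable (proportional bias).  ``warnings`` carries structured
    codes: SINGLETON_SUBJECTS, FALLBACK_POOLED, LOA_SUPPRESSED.
    """

    device: str
    method: str
    n_pairs: int
    n_subjects: int
    bias: float
    sd_diff: float
    loa_low: float | None
    loa_high: float | None
    percentage_error: float | None
    mean_ref: float
    proportional_bias_slope: float
    proportional_bias_p: float
    warnings: tuple[str, ...] = ()


def percentage_error(sd_diff: float, mean_ref: float) -> float:
    """100 * (1.96 * sd_diff) / mean_ref — the limit of agreement as a
    percentage of the mean reference stroke volume."""
    if mean_ref <= 0:
        raise ValueError("mean_ref must be positive")
    if sd_diff < 0:
        raise ValueError("sd_diff must be >= 0")
    return 100.0 * Z_LOA * sd_diff / mean_ref


class BlandAltman:
    """Agreement model for paired readings grouped by subject.

    Parameters
    ----------
    ref, dev : array-like
        Reference and device readings, pairwise aligned, all positive.
    subjects : array-like
        Subject identifier per pair (grouping for the repeated-measures
        variance decomposition).
    device_name : str
        Label carried through to the summary.
    """

    def __init__(self, ref, dev, subjects, device_name: str = "device"):
        ref = np.asarray(ref, dtype=float)
        dev = np.asarray(dev, dtype=float)
        subjects = np.asarray(subjects)
        if ref.shape != dev.shape or ref.shape != subjects.shape:
            raise ValueError("ref, dev and subjects must be aligned 1-d arrays")
        if ref.size < 2:
            raise ValueError("need at least 2 pairs")
        if np.any(ref <= 0) or np.any(dev <= 0):
            raise ValueError("stroke volumes must be positive")
        self.ref = ref
        self.dev = dev
        self.subjects = subjects
        self.device_name = device_name

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        device: str,
        ref_col: str = "sv_ref",
        subject_col: str = "subject_id",
    ) -> "BlandAltman":
        """Build from a cohort table with a ``sv_<device>`` column; rows with
        a missing device reading are dropped (per-device missingness)."""
        dev_col = device if device in df.columns else f"sv_{device}"
        if dev_col not in df.columns:
            raise KeyError(f"no column {device!r} or 'sv_{device}' in frame")
        sub = df[[subject_col, ref_col, dev_col]].dropna()
        return cls(
            sub[ref_col].to_numpy(),
            sub[dev_col].to_numpy(),
            sub[subject_col].to_numpy(),
            device_name=device,
        )

    @property
    def differences(self) -> np.ndarray:
        return self.dev - self.ref

    @property
    def means(self) -> np.ndarray:
        return (self.dev + self.ref) / 2.0

    def fit(
        self,
        method: str = "repeated_varying",
        proportional_regressor: str = "ref",
    ) -> "BlandAltmanResults":
        if method not in ("repeated_varying", "pooled_naive"):
            raise ValueError("method must be 'repeated_varying' or 'pooled_naive'")
        if proportional_regressor not in ("ref", "mean"):
            raise ValueError("proportional_regressor must be 'ref' or 'mean'")
        d = self.differences
        warnings: list[str] = []

        counts = pd.Series(d).groupby(pd.Series(self.subjects)).count()
        n_subjects = len(counts)
        if (counts == 1).any() and method == "repeated_varying":
            warnings.append("SINGLETON_SUBJECTS")
        if method == "repeated_varying" and n_subjects < 2:
            method = "pooled_naive"
            warnings.append("FALLBACK_POOLED")

        bias = float(d.mean())
        if method == "pooled_naive":
            sd = float(d.std(ddof=1))
        else:
            sd = _repeated_varying_sd(d, self.subjects)

        x = self.ref if proportional_regressor == "ref" else self.means
        slope, p_value = _proportional_slope(x, d, self.subjects)

        mean_ref = float(self.ref.mean())
        summary = AgreementSummary(
            device=self.device_name,
            method=method,
            n_pairs=int(d.size),
            n_subjects=n_subjects,
            bias=bias,
            sd_diff=sd,
            loa_low=bias - Z_LOA * sd,
            loa_high=bias + Z_LOA * sd,
            percentage_error=percentage_error(sd, mean_ref),
            mean_ref=mean_ref,
            proportional_bias_slope=float(slope),
            proportional_bias_p=float(p_value),
            warnings=tuple(warnings),
        )
        return BlandAltmanResults(self, summary)


def _proportional_slope(x: np.ndarray, d: np.ndarray, subjects) -> tuple[float, float]:
    """Least-squares slope of difference on ``x`` with its two-sided p.

    Repeated measurements within a subject are correlated (shared
    calibration error), so the p-value uses cluster-robust standard errors
    grouped by subject (t reference distribution); with a single subject per
    pair this reduces to ordinary OLS inference.
    """
    if np.ptp(x) == 0:  # constant regressor: no proportional trend estimable
        return 0.0, 1.0
    n_subjects = len(pd.unique(subjects))
    if n_subjects < 3 or n_subjects == len(d):
        res = stats.linregress(x, d)
        return float(res.slope), float(res.pvalue)
    model = sm.OLS(d, sm.add_constant(x))
    fit = model.fit(cov_type="cluster", cov_kwds={"groups": np.asarray(subjects)}, use_t=True)
    return float(fit.params[1]), float(fit.pvalues[1])


def _repeated_varying_sd(d: np.ndarray, subjects: np.ndarray) -> float:
    """SD of a single difference via one-way variance components.

    With subjects i = 1..k contributing m_i differences (N total), the
    between- and within-subject mean squares give sigma^2_between =
    (MSB - MSW) / n0 (floored at 0) with n0 = (N - sum m_i^2 / N)/(k - 1),
    and the variance of one difference is sigma^2_between + MSW.
    """
    s = pd.Series(d)
    g = s.groupby(pd.Series(subjects))
    m = g.count().to_numpy(dtype=float)
    group_means = g.mean().to_numpy()
    k = m.size
    n_total = float(d.size)
    if k == int(n_total):  # every subject a single pair: identical to pooled SD
        return float(s.std(ddof=1))
    grand = d.mean()
    ssb = float(np.sum(m * (group_means - grand) ** 2))
    msb = ssb / (k - 1)
    ssw = float(((s - g.transform("mean")) ** 2).sum())
    msw = ssw / (n_total - k)
    n0 = (n_total - float(np.sum(m**2)) / n_total) / (k - 1)
    var_between = max(0.0, (msb - msw) / n0)
    return float(np.sqrt(var_between + msw))


class BlandAltmanResults:
    """Fitted agreement results; exposes the summary fields as attributes."""

    def __init__(self, model: BlandAltman, summary: AgreementSummary):
        self.model = model
        self._summary = summary

    def __getattr__(self, name):
        try:
            return getattr(self._summary, name)
        except AttributeError:
            raise AttributeError(name) from None

    @property
    def loa(self) -> tuple[float | None, float | None]:
        return (self._summary.loa_low, self._summary.loa_high)

    def as_summary(self) -> AgreementSummary:
        return self._summary

    def suppress_if_proportional(self, slope_p_threshold: float = 0.05) -> "BlandAltmanResults":
        """Return results with LoA and percentage error withheld when the
        difference-vs-mean slope is significant at ``slope_p_threshold``."""
        new = suppress_loa_if_proportional(self._summary, slope_p_threshold)
        return BlandAltmanResults(self.model, new)

    def plot_data(self) -> pd.DataFrame:
        """Per-pair Bland-Altman coordinates (mean, difference)."""
        return pd.DataFrame(
            {
                "subject_id": self.model.subjects,
                "mean": self.model.means,
                "difference": self.model.differences,
            }
        )

    def summary(self) -> str:
        s = self._summary
        fmt = lambda v: "not reported" if v is None else f"{v:.2f}"
        lines = [
            f"Bland-Altman agreement: {s.device} vs reference ({s.method})",
            f"  pairs / subjects       {s.n_pairs} / {s.n_subjects}",
            f"  bias (ml)              {s.bias:.2f}",
            f"  SD of differences (ml) {s.sd_diff:.2f}",
            f"  95% LoA (ml)           {fmt(s.loa_low)} to {fmt(s.loa_high)}",
            f"  percentage error       {fmt(s.percentage_error)}"
            + ("%" if s.percentage_error is not None else ""),
            f"  proportional bias      slope {s.proportional_bias_slope:.3f}, "
            f"p = {s.proportional_bias_p:.3g}",
        ]
        if s.warnings:
            lines.append(f"  warnings               {', '.join(s.warnings)}")
        return "\n".join(lines)


def bland_altman_repeated(pairs, method: str = "repeated_varying") -> AgreementSummary:
    """Functional entry point: ``pairs`` is an iterable of
    ``(subject_id, sv_ref, sv_dev)`` tuples."""
    subjects, ref, dev = zip(*pairs)
    model = BlandAltman(ref, dev, np.asarray(subjects))
    return model.fit(method=method).as_summary()


def suppress_loa_if_proportional(
    summary: AgreementSummary, slope_p_threshold: float = 0.05
) -> AgreementSummary:
    """Withhold LoA and percentage error when proportional bias is significant.

    Mirrors the reporting convention for devices whose bias grows with the
    measurand: a single pair of limits would misrepresent the error.
    """
    if summary.proportional_bias_p < slope_p_threshold:
        return replace(
            summary,
            loa_low=None,
            loa_high=None,
            percentage_error=None,
            warnings=summary.warnings + ("LOA_SUPPRESSED",),
        )
    return summary
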