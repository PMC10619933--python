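"""Scan-rescan reproducibility statistics on ROI medians.

Subjects are scanned twice (exam 1 / exam 2); each ROI is summarized by
its median (metric distributions within ROIs are skewed).  Agreement
between exams is quantified with Bland-Altman bias and 95% limits of
agreement, the repeatability coefficient RC = 1.96*sqrt(2)*sigma_w with
within-subject SD ``sigma_w = sqrt(sum d_i^2 / 2n)``, the coefficient
of variation COV = 100*sigma_w/grand mean, the intraclass correlation
coefficient (two-way random effects, absolute agreement, single
measurement), and a two-sided one-sample t-test on the exam
differences.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "roi_median", "bland_altman", "repeatability_coefficient",
    "cov_percent", "icc", "paired_bias_test", "summarize", "ROITable",
]

log = logging.getLogger(__name__)

TABLE_COLUMNS = ["exam1_mean", "exam1_sd", "exam2_mean", "exam2_sd",
                 "bias", "loa_neg", "loa_pos", "rc", "cov_percent", "icc",
                 "t_stat", "p_value"]


@dataclass
class ROITable:
    """Long-format records of (subject, exam, roi, metric, value)."""

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"subject", "exam", "roi", "metric", "value"}
        missing = required - set(self.frame.columns)
        if missing:
            raise ValueError(f"ROI table missing columns: {sorted(missing)}")
        dup = self.frame.duplicated(["subject", "exam", "roi", "metric"])
        if dup.any():
            raise ValueError("duplicate (subject, exam, roi, metric) records")
        if not self.frame["exam"].isin([1, 2]).all():
            raise ValueError("exam index must be 1 or 2")

    @classmethod
    def from_csv(cls, path) -> "ROITable":
        return cls(pd.read_csv(path))

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)

    def pairs(self, roi: str, metric: str) -> np.ndarray:
        """(n_subjects, 2) array of exam-1/exam-2 values, subject sorted."""
        sub = self.frame[(self.frame["roi"] == roi)
                         & (self.frame["metric"] == metric)]
        wide = sub.pivot(index="subject", columns="exam", values="value")
        wide = wide.reindex(columns=[1, 2]).dropna().sort_index()
        return wide.to_numpy()


def roi_median(volume: np.ndarray, roi_mask: np.ndarray) -> float:
    """Median of the map over in-mask voxels with defined (finite) values."""
    roi_mask = np.asarray(roi_mask, dtype=bool)
    if not roi_mask.any():
        raise ValueError("ROI mask is empty")
    vals = np.asarray(volume)[roi_mask]
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        raise ValueError("ROI contains no defined voxels")
    return float(np.median(vals))


def _as_pairs(pairs: np.ndarray, min_n: int = 2) -> np.ndarray:
    arr = np.asarray(pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("pairs must have shape (n_subjects, 2)")
    if arr.shape[0] < min_n:
        raise ValueError(f"need at least {min_n} subject pairs")
    return arr


def bland_altman(pairs: np.ndarray) -> tuple[float, float, float]:
    """Bland-Altman bias and 95% limits of agreement.

    bias = mean(exam2 - exam1); LOA = bias +/- 1.96 * SD(differences)
    with the sample (n-1) standard deviation.
    """
    arr = _as_pairs(pairs)
    diff = arr[:, 1] - arr[:, 0]
    bias = float(diff.mean())
    sd = float(diff.std(ddof=1))
    return bias, bias - 1.96 * sd, bias + 1.96 * sd


def _sigma_within(pairs: np.ndarray) -> float:
    arr = _as_pairs(pairs)
    diff = arr[:, 1] - arr[:, 0]
    return float(np.sqrt(np.sum(diff**2) / (2 * arr.shape[0])))


def repeatability_coefficient(pairs: np.ndarray) -> float:
    """RC = 1.96 * sqrt(2) * sigma_w (smallest detectable difference)."""
    return 1.96 * np.sqrt(2.0) * _sigma_within(pairs)


def cov_percent(pairs: np.ndarray) -> float:
    """Within-subject coefficient of variation, 100 * sigma_w / grand mean."""
    arr = _as_pairs(pairs)
    grand = float(arr.mean())
    if grand == 0:
        raise ValueError("grand mean is zero; COV undefined")
    return 100.0 * _sigma_within(arr) / grand


def icc(pairs: np.ndarray) -> float:
    """ICC(2,1): two-way random effects, absolute agreement, single rater.

    Computed from the ANOVA mean squares of the subjects x exams table:
    ``(MSR - MSE) / (MSR + (k-1)MSE + k/n (MSC - MSE))`` with k = 2.
    """
    arr = _as_pairs(pairs)
    n, k = arr.shape
    grand = arr.mean()
    row_means = arr.mean(axis=1)
    col_means = arr.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((arr - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + (k / n) * (msc - mse)
    if denom == 0:
        return 1.0 if msr == mse else 0.0
    return float((msr - mse) / denom)


def paired_bias_test(pairs: np.ndarray) -> tuple[float, float]:
    """Two-sided one-sample t-test of the exam differences against zero."""
    arr = _as_pairs(pairs)
    diff = arr[:, 1] - arr[:, 0]
    res = sps.ttest_1samp(diff, 0.0)
    return float(res.statistic), float(res.pvalue)


def summarize(table: ROITable, metric: str,
              rois: "list[str] | None" = None) -> pd.DataFrame:
    """Per-ROI reproducibility report plus an unweighted mean row.

    Columns: per-exam mean and SD, Bland-Altman bias and LOAs, RC, COV
    (percent), ICC, and the paired t-test.  ROIs with incomplete exam
    pairs are skipped with a warning.  The ``Mean`` row is the
    unweighted arithmetic mean of each column across ROIs.
    """
    if rois is None:
        rois = list(dict.fromkeys(
            table.frame.loc[table.frame["metric"] == metric, "roi"]))
    rows = {}
    for roi in rois:
        pairs = table.pairs(roi, metric)
        if pairs.shape[0] < 2:
            log.warning("ROI %r skipped: fewer than 2 complete exam pairs", roi)
            continue
        bias, lo, hi = bland_altman(pairs)
        t, p = paired_bias_test(pairs)
        rows[roi] = {
            "exam1_mean": pairs[:, 0].mean(),
            "exam1_sd": pairs[:, 0].std(ddof=1),
            "exam2_mean": pairs[:, 1].mean(),
            "exam2_sd": pairs[:, 1].std(ddof=1),
            "bias": bias, "loa_neg": lo, "loa_pos": hi,
            "rc": repeatability_coefficient(pairs),
            "cov_percent": cov_percent(pairs),
            "icc": icc(pairs),
            "t_stat": t, "p_value": p,
        }
    report = pd.DataFrame.from_dict(rows, orient="columns").T
    report = report.reindex(columns=TABLE_COLUMNS)
    if len(report):
        report.loc["Mean"] = report.mean(axis=0)
    report.index.name = "roi"
    return report
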