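"""Validation statistics for card-vs-titration comparisons.

The device is judged two ways. As a *survey* tool it must separate
adequately iodized salt (>= 15 ppm I) from inadequately iodized salt; as a
*quality-control* tool it must place production samples relative to the
30-50 ppm band required at the time of iodization, with the associated
process actions (a technician raises the spray rate below 32 ppm and lowers
it above 46 ppm). This module provides those classifiers plus the generic
machinery behind every printed figure of merit: contingency tables and
their per-row accuracies, ROC/AUC, the mean-absolute-deviation "accuracy"
and duplicate-SD "precision" estimators, the paired t comparison against
titration, and the count-weighted process-action match rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "SURVEY_CUTOFF",
    "QC_BAND",
    "SPRAY_INCREASE_BELOW",
    "SPRAY_DECREASE_ABOVE",
    "classify_survey",
    "classify_qc",
    "process_action",
    "ContingencyTable",
    "build_contingency",
    "contingency_accuracy",
    "ROCCurve",
    "roc_curve",
    "MethodComparison",
    "accuracy_precision",
    "paired_diff_test",
    "action_match_rate",
]

#: adequately iodized salt contains at least this much iodine (ppm I)
SURVEY_CUTOFF = 15.0
#: production-time band required for sale, both edges inclusive (ppm I)
QC_BAND = (30.0, 50.0)
#: process-control action thresholds at the fortification line (ppm I)
SPRAY_INCREASE_BELOW = 32.0
SPRAY_DECREASE_ABOVE = 46.0


def _check_ppm(ppm: float) -> float:
    ppm = float(ppm)
    if ppm < 0:
        raise ValueError("ppm must be >= 0")
    return ppm


def classify_survey(ppm: float) -> str:
    """'adequate' iff the salt carries at least 15 ppm iodine."""
    return "adequate" if _check_ppm(ppm) >= SURVEY_CUTOFF else "inadequate"


def classify_qc(ppm: float) -> str:
    """Position relative to the 30-50 ppm production band (edges in-band)."""
    ppm = _check_ppm(ppm)
    if ppm < QC_BAND[0]:
        return "below"
    if ppm > QC_BAND[1]:
        return "above"
    return "in_band"


def process_action(ppm: float) -> str:
    """Spray-rate adjustment the reading calls for at the iodization line."""
    ppm = _check_ppm(ppm)
    if ppm < SPRAY_INCREASE_BELOW:
        return "increase_spray"
    if ppm > SPRAY_DECREASE_ABOVE:
        return "decrease_spray"
    return "none"


# ---------------------------------------------------------------------------
# contingency tables

@dataclass(frozen=True)
class ContingencyTable:
    """Counts of reference category (rows) x card category (columns)."""

    row_labels: tuple[str, ...]
    col_labels: tuple[str, ...]
    counts: np.ndarray  # (rows, cols), non-negative ints

    def __post_init__(self) -> None:
        c = np.asarray(self.counts)
        if c.shape != (len(self.row_labels), len(self.col_labels)):
            raise ValueError("counts shape does not match labels")
        if (c < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return int(np.asarray(self.counts).sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            np.asarray(self.counts), index=self.row_labels, columns=self.col_labels
        )

    @classmethod
    def from_counts(
        cls,
        counts: Sequence[Sequence[int]],
        row_labels: Sequence[str],
        col_labels: Sequence[str],
    ) -> "ContingencyTable":
        return cls(tuple(row_labels), tuple(col_labels), np.asarray(counts, dtype=int))


def build_contingency(
    reference: Sequence[float],
    device: Sequence,
    row_binner: Callable[[float], str],
    col_binner: Callable[[float], str] | None,
    row_labels: Sequence[str],
    col_labels: Sequence[str],
) -> ContingencyTable:
    """Cross-tabulate paired reference/device values.

    ``row_binner`` maps a reference ppm to a row label. ``col_binner`` does
    the same for device ppm values; pass None when ``device`` already holds
    category labels. Binners are callables (not numeric edges) so that
    closed bands like the inclusive 30-50 QC band are expressible.
    """
    if len(reference) != len(device):
        raise ValueError("reference and device inputs must be the same length")
    counts = np.zeros((len(row_labels), len(col_labels)), dtype=int)
    ri = {lab: i for i, lab in enumerate(row_labels)}
    ci = {lab: i for i, lab in enumerate(col_labels)}
    for ref, dev in zip(reference, device):
        r = row_binner(ref)
        c = col_binner(dev) if col_binner is not None else dev
        counts[ri[r], ci[c]] += 1
    return ContingencyTable(tuple(row_labels), tuple(col_labels), counts)


def contingency_accuracy(
    table: ContingencyTable,
    correct_map: Mapping[str, Iterable[str]],
    rows: Sequence[str] | None = None,
) -> float:
    """Fraction of readings in ``rows`` whose column is acceptable for their
    row: sum of correct cells over the subset / sum of all cells over it."""
    rows = tuple(rows) if rows is not None else table.row_labels
    for r in rows:
        if r not in table.row_labels:
            raise KeyError(f"row {r!r} not in table")
    counts = np.asarray(table.counts)
    num = den = 0
    for r in rows:
        i = table.row_labels.index(r)
        den += counts[i].sum()
        ok_cols = set(correct_map.get(r, ()))
        for j, c in enumerate(table.col_labels):
            if c in ok_cols:
                num += counts[i, j]
    if den == 0:
        raise ValueError("no readings in the selected rows")
    return float(num) / float(den)


# ---------------------------------------------------------------------------
# ROC

@dataclass(frozen=True)
class ROCCurve:
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc: float


def roc_curve(scores: Sequence[float], labels: Sequence[bool]) -> ROCCurve:
    """Operating points over all score thresholds, and the trapezoidal AUC.

    The trapezoid rule walks tie groups along diagonal segments, so the AUC
    equals the Mann-Whitney probability of correct ranking with half credit
    for ties. Requires both classes present.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise ValueError("scores and labels must be equal-length 1-D")
    n_pos = int(labels.sum())
    n_neg = int(len(labels) - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    order = np.argsort(-scores, kind="stable")
    s, y = scores[order], labels[order]
    # cumulative counts at the end of each tie group
    distinct = np.r_[np.nonzero(np.diff(s))[0], len(s) - 1]
    tp = np.cumsum(y)[distinct]
    fp = np.cumsum(~y)[distinct]
    tpr = np.r_[0.0, tp / n_pos]
    fpr = np.r_[0.0, fp / n_neg]
    thresholds = np.r_[np.inf, s[distinct]]
    auc = float(np.trapezoid(tpr, fpr))
    return ROCCurve(fpr=fpr, tpr=tpr, thresholds=thresholds, auc=auc)


# ---------------------------------------------------------------------------
# method comparison

@dataclass(frozen=True)
class MethodComparison:
    """Summary of card-vs-titration agreement.

    ``accuracy`` is the mean over samples of |mean(card replicates) -
    titration| and ``precision`` the mean of the duplicate sample SDs
    (ddof=1), both in ppm I. The paired-test fields describe the two-sided
    one-sample t test on the per-sample differences.
    """

    n: int
    accuracy: float | None = None
    precision: float | None = None
    mean_difference: float | None = None
    sd_difference: float | None = None
    t_statistic: float | None = None
    p_value: float | None = None
    confidence: float | None = None
    ci: tuple[float, float] | None = None
    indistinguishable: bool | None = None


def accuracy_precision(data: pd.DataFrame) -> MethodComparison:
    """Accuracy and duplicate precision from a replicate table.

    ``data`` holds one row per card reading with columns ``sample_id``,
    ``pad_ppm`` and ``titration_ppm`` (constant within a sample). Precision
    averages the replicate SDs of the samples that have >= 2 readings.
    """
    required = {"sample_id", "pad_ppm", "titration_ppm"}
    if not required.issubset(data.columns):
        raise ValueError(f"data must have columns {sorted(required)}")
    if data.empty:
        raise ValueError("no readings supplied")
    g = data.groupby("sample_id")
    per_sample = g.agg(
        pad_mean=("pad_ppm", "mean"),
        pad_sd=("pad_ppm", lambda s: s.std(ddof=1)),
        n_rep=("pad_ppm", "size"),
        titration=("titration_ppm", "mean"),
    )
    accuracy = float((per_sample.pad_mean - per_sample.titration).abs().mean())
    dup = per_sample[per_sample.n_rep >= 2]
    if dup.empty:
        raise ValueError("precision requires at least one sample with >= 2 replicates")
    precision = float(dup.pad_sd.mean())
    return MethodComparison(n=len(per_sample), accuracy=accuracy, precision=precision)


def paired_diff_test(
    pad: Sequence[float], titration: Sequence[float], confidence: float = 0.95
) -> MethodComparison:
    """Two-sided paired t test of card minus titration.

    The methods are declared 'indistinguishable' when zero lies inside the
    confidence interval of the mean difference at the stated level.
    """
    pad = np.asarray(pad, dtype=float)
    tit = np.asarray(titration, dtype=float)
    if pad.shape != tit.shape or pad.ndim != 1:
        raise ValueError("pad and titration must be equal-length 1-D")
    n = len(pad)
    if n < 2:
        raise ValueError("paired test requires n >= 2")
    if not 0.0 < confidence < 1.0:
        raise ValueError("confidence must be in (0, 1)")
    diff = pad - tit
    mean = float(diff.mean())
    sd = float(diff.std(ddof=1))
    res = sps.ttest_1samp(diff, 0.0)
    half = sps.t.ppf(0.5 + confidence / 2.0, n - 1) * sd / np.sqrt(n)
    ci = (mean - half, mean + half)
    return MethodComparison(
        n=n,
        mean_difference=mean,
        sd_difference=sd,
        t_statistic=float(res.statistic),
        p_value=float(res.pvalue),
        confidence=confidence,
        ci=ci,
        indistinguishable=bool(ci[0] <= 0.0 <= ci[1]),
    )


def action_match_rate(
    proportions: Sequence[float], counts: Sequence[int]
) -> float:
    """Count-weighted mean of per-category match proportions."""
    p = np.asarray(proportions, dtype=float)
    n = np.asarray(counts, dtype=float)
    if p.shape != n.shape or p.ndim != 1 or p.size == 0:
        raise ValueError("proportions and counts must be equal-length 1-D")
    if (n <= 0).any():
        raise ValueError("counts must be positive")
    if ((p < 0) | (p > 1)).any():
        raise ValueError("proportions must lie in [0, 1]")
    return float((p * n).sum() / n.sum())
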