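"""Quantile normalization and two-group differential expression calling.

The calling convention follows the microarray-console workflow the study
platforms used: intensities are quantile-normalized per platform on the log2
scale, fold changes are ratios of *linear* group means reported as signed
values with magnitude >= 1, and significance comes from a one-way two-group
ANOVA (equivalent to the pooled-variance t-test, F = t^2) on the log2
normalized values. A transcript cluster is called differentially expressed
when |FC| >= 1.3 (inclusive) and p < 0.05 (strict). No multiple-testing
correction is applied — deliberately, to mirror the published thresholds;
interpret single-TC calls accordingly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io import ExpressionMatrix, Group, Platform, SampleSheet, TranscriptSet

__all__ = [
    "ComparisonSpec",
    "ComparisonResult",
    "quantile_normalize",
    "signed_fold_change",
    "anova_p",
    "run_comparison",
    "DEFAULT_FC_THRESHOLD",
    "DEFAULT_ALPHA",
]

DEFAULT_FC_THRESHOLD = 1.3
DEFAULT_ALPHA = 0.05


@dataclass(frozen=True)
class ComparisonSpec:
    """A two-group comparison; ``group_a`` is the numerator of the FC."""

    name: str
    group_a: Group
    group_b: Group
    platform: Platform

    def __post_init__(self) -> None:
        object.__setattr__(self, "group_a", Group(self.group_a))
        object.__setattr__(self, "group_b", Group(self.group_b))
        object.__setattr__(self, "platform", Platform(self.platform))
        if self.group_a == self.group_b:
            raise ValueError(f"{self.name}: group_a == group_b")

    def key(self) -> str:
        return f"{self.group_a.value}_vs_{self.group_b.value}"


@dataclass
class ComparisonResult:
    """Per-TC signed fold change, ANOVA p-value and up/down/none call."""

    spec: ComparisonSpec
    table: pd.DataFrame = field(repr=False)  # columns: fc, p, call
    gene_symbols: pd.Series = field(default=None, repr=False)

    @property
    def tc_ids(self) -> pd.Index:
        return self.table.index

    def calls(self) -> pd.Series:
        return self.table["call"]

    def called_set(self) -> TranscriptSet:
        """All TCs called up or down, as a TranscriptSet."""
        called = self.table[self.table["call"] != "none"]
        return TranscriptSet(dict(called["call"]), source=self.spec.name)

    def up_set(self) -> TranscriptSet:
        up = self.table[self.table["call"] == "up"]
        return TranscriptSet({tc: "up" for tc in up.index}, source=self.spec.name)

    def down_set(self) -> TranscriptSet:
        down = self.table[self.table["call"] == "down"]
        return TranscriptSet({tc: "down" for tc in down.index}, source=self.spec.name)


def quantile_normalize(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Quantile-normalize all samples of a matrix on the log2 scale.

    After normalization every column shares one sorted multiset of values:
    the across-column mean of order statistics. Within-column ranks are
    preserved; tied values within a column receive the mean of the tied
    order-statistic means (rank-stable and deterministic). The result is
    returned on the linear scale.
    """
    if matrix.values.shape[1] < 2:
        raise ValueError("quantile normalization needs at least 2 samples")
    log_vals = np.log2(matrix.values.to_numpy(dtype=float))
    n_rows, n_cols = log_vals.shape
    order = np.argsort(log_vals, axis=0, kind="stable")
    sorted_vals = np.take_along_axis(log_vals, order, axis=0)
    reference = sorted_vals.mean(axis=1)  # mean of order statistics

    out = np.empty_like(log_vals)
    for j in range(n_cols):
        col_sorted = sorted_vals[:, j]
        assigned = reference.copy()
        # average the reference over runs of tied values in this column
        run_start = 0
        for i in range(1, n_rows + 1):
            if i == n_rows or col_sorted[i] != col_sorted[run_start]:
                if i - run_start > 1:
                    assigned[run_start:i] = reference[run_start:i].mean()
                run_start = i
        out[order[:, j], j] = assigned

    normalized = pd.DataFrame(
        np.exp2(out), index=matrix.values.index, columns=matrix.values.columns
    )
    return ExpressionMatrix(normalized, matrix.gene_symbols)


def signed_fold_change(mean_a: float, mean_b: float) -> float:
    """Linear-ratio fold change with sign encoding direction, |FC| >= 1.

    Returns ``mean_a / mean_b`` when ``mean_a >= mean_b`` and
    ``-(mean_b / mean_a)`` otherwise, so +2 and -2 denote a twofold change
    in either direction and equality maps to +1.
    """
    if mean_a <= 0 or mean_b <= 0:
        raise ValueError("group means must be positive")
    if mean_a >= mean_b:
        return mean_a / mean_b
    return -(mean_b / mean_a)


def anova_p(values_a: np.ndarray, values_b: np.ndarray) -> float:
    """One-way two-group ANOVA p-value (df 1, n_a + n_b - 2).

    Identical to the two-sided pooled-variance t-test p-value on the same
    data (F = t^2). Degenerate convention when the pooled within-group
    variance is zero: p = 1 for equal means, p = 0 for unequal means.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least 2 values per group")
    n_a, n_b = a.size, b.size
    mean_a, mean_b = a.mean(), b.mean()
    ss_within = ((a - mean_a) ** 2).sum() + ((b - mean_b) ** 2).sum()
    if ss_within == 0.0:
        return 1.0 if mean_a == mean_b else 0.0
    grand = (a.sum() + b.sum()) / (n_a + n_b)
    ss_between = n_a * (mean_a - grand) ** 2 + n_b * (mean_b - grand) ** 2
    df2 = n_a + n_b - 2
    f_stat = ss_between / (ss_within / df2)
    return float(stats.f.sf(f_stat, 1, df2))


def _anova_p_matrix(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Vectorized anova_p over rows of two (n_tc, n_rep) arrays."""
    n_a, n_b = a.shape[1], b.shape[1]
    mean_a = a.mean(axis=1)
    mean_b = b.mean(axis=1)
    ss_within = ((a - mean_a[:, None]) ** 2).sum(axis=1) + (
        (b - mean_b[:, None]) ** 2
    ).sum(axis=1)
    grand = (a.sum(axis=1) + b.sum(axis=1)) / (n_a + n_b)
    ss_between = n_a * (mean_a - grand) ** 2 + n_b * (mean_b - grand) ** 2
    df2 = n_a + n_b - 2
    with np.errstate(divide="ignore", invalid="ignore"):
        f_stat = ss_between / (ss_within / df2)
        p = stats.f.sf(f_stat, 1, df2)
    degenerate = ss_within == 0.0
    p[degenerate & (mean_a == mean_b)] = 1.0
    p[degenerate & (mean_a != mean_b)] = 0.0
    return p


def run_comparison(
    matrix: ExpressionMatrix,
    sheet: SampleSheet,
    spec: ComparisonSpec,
    fc_threshold: float = DEFAULT_FC_THRESHOLD,
    alpha: float = DEFAULT_ALPHA,
) -> ComparisonResult:
    """Call differential expression for one group-vs-group comparison.

    ``matrix`` is expected to be already quantile-normalized (normalization
    is performed once per platform across all its samples, see
    :func:`quantile_normalize`). Fold changes come from linear group means;
    p-values from the ANOVA on log2 values. The FC gate is inclusive
    (>= +threshold / <= -threshold), the p gate strict (< alpha).
    """
    samples_a = sheet.samples_in_group(spec.group_a)
    samples_b = sheet.samples_in_group(spec.group_b)
    for group, samples in ((spec.group_a, samples_a), (spec.group_b, samples_b)):
        present = [s for s in samples if s in matrix.sample_ids]
        if len(present) < 2:
            raise ValueError(
                f"{spec.name}: group {group.value} has {len(present)} sample(s) "
                "in the matrix; need at least 2"
            )
    a_lin = matrix.values[samples_a].to_numpy(dtype=float)
    b_lin = matrix.values[samples_b].to_numpy(dtype=float)
    mean_a = a_lin.mean(axis=1)
    mean_b = b_lin.mean(axis=1)
    ratio = mean_a / mean_b
    fc = np.where(ratio >= 1.0, ratio, -1.0 / ratio)
    p = _anova_p_matrix(np.log2(a_lin), np.log2(b_lin))

    call = np.full(matrix.n_tc, "none", dtype=object)
    call[(fc >= fc_threshold) & (p < alpha)] = "up"
    call[(fc <= -fc_threshold) & (p < alpha)] = "down"

    table = pd.DataFrame({"fc": fc, "p": p, "call": call}, index=matrix.tc_ids)
    return ComparisonResult(spec, table, matrix.gene_symbols)
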