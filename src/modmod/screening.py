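"""Record exclusion, depression screening, descriptives, and bias checks.

The intake pipeline mirrors a routine mental-health screening survey:

1. drop contaminated questionnaires (incomplete answers, straight-line
   responding, or a mechanical answer pattern);
2. score the retained records and band depression severity;
3. keep respondents at or above the positive-screen threshold (total >= 5)
   for the moderation analysis.

The module also provides the standard preliminary statistics: score-table
descriptives and Pearson correlations, pooled-variance gender t-tests, and
Harman's single-factor test for common-method bias (share of total variance
carried by the first unrotated principal component of the pooled standardized
items; values below 40% are conventionally taken as unproblematic).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateVariableError, GroupingError, ValidationError
from .scales import SCALES, all_item_columns, item_columns, score_frame

__all__ = [
    "EXCLUSION_RULES",
    "exclusion_flags",
    "apply_exclusions",
    "screen_positive",
    "ScreeningReport",
    "screening_report",
    "CorrelationSummary",
    "pearson_matrix",
    "gender_t_test",
    "harman_single_factor",
    "harman_from_scores",
]

EXCLUSION_RULES = ("incomplete", "straight_line", "patterned")

#: Instruments whose constant response flags straight-lining.  The binary
#: family-support scale is deliberately excluded: answering "yes" to every
#: support item is a plausible honest response, so constancy there is
#: uninformative.
_STRAIGHT_LINE_SCALES = ("dep", "is", "psycap")

#: Long instruments checked for mechanical two-value alternation.  Short
#: scales are skipped: a nine-item alternation arises by honest chance too
#: often to be diagnostic.
_PATTERN_SCALES = ("psycap", "fs")


def _is_alternating(row: np.ndarray) -> bool:
    if np.isnan(row).any():
        return False
    a, b = row[0], row[1]
    if a == b:
        return False
    return bool(np.all(row[0::2] == a) and np.all(row[1::2] == b))


def exclusion_flags(frame: pd.DataFrame) -> pd.DataFrame:
    """Boolean flags per record and exclusion rule.

    ``incomplete``: any missing item.  ``straight_line``: identical response
    on every item of all polytomous instruments.  ``patterned``: strict
    two-value alternation across a long instrument.
    """
    items = frame[all_item_columns()].to_numpy(dtype=float)
    incomplete = np.isnan(items).any(axis=1)

    straight = np.ones(len(frame), dtype=bool)
    for name in _STRAIGHT_LINE_SCALES:
        block = frame[item_columns(SCALES[name])].to_numpy(dtype=float)
        const = (~np.isnan(block).any(axis=1)) & (block == block[:, :1]).all(axis=1)
        straight &= const

    patterned = np.zeros(len(frame), dtype=bool)
    for name in _PATTERN_SCALES:
        block = frame[item_columns(SCALES[name])].to_numpy(dtype=float)
        patterned |= np.array([_is_alternating(row) for row in block])

    return pd.DataFrame(
        {
            "incomplete": incomplete,
            "straight_line": straight,
            "patterned": patterned,
        },
        index=frame.index,
    )


def apply_exclusions(frame: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split a cohort into retained records and excluded records with reasons.

    A record is excluded iff it triggers at least one rule; the ``reason``
    column lists every triggered rule.  Row order is preserved, and the
    operation is idempotent: re-screening the retained set excludes nothing.
    """
    if len(frame) == 0:
        empty = frame.copy()
        empty["reason"] = pd.Series(dtype=str)
        return frame.copy(), empty
    flags = exclusion_flags(frame)
    excluded_mask = flags.any(axis=1)
    retained = frame.loc[~excluded_mask].copy()
    excluded = frame.loc[excluded_mask].copy()
    excluded["reason"] = [
        "+".join(rule for rule in EXCLUSION_RULES if flags.loc[i, rule])
        for i in excluded.index
    ]
    return retained, excluded


def screen_positive(scores: pd.DataFrame, threshold: float = 5) -> pd.DataFrame:
    """Rows whose depression total meets the positive-screen threshold."""
    if "dep" not in scores.columns:
        raise ValidationError("score table lacks a 'dep' column")
    return scores.loc[scores["dep"] >= threshold].copy()


@dataclass
class ScreeningReport:
    """Counts and rates produced by the intake pipeline."""

    n_raw: int
    n_excluded: int
    exclusion_breakdown: dict[str, int]
    n_retained: int
    n_positive: int
    prevalence_pct: float
    exclusion_pct: float
    band_counts: dict[str, int] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "n_raw": self.n_raw,
            "n_excluded": self.n_excluded,
            "exclusion_breakdown": dict(self.exclusion_breakdown),
            "n_retained": self.n_retained,
            "n_positive": self.n_positive,
            "prevalence_pct": self.prevalence_pct,
            "exclusion_pct": self.exclusion_pct,
            "band_counts": dict(self.band_counts),
        }


def screening_report(
    frame: pd.DataFrame, threshold: float = 5
) -> tuple[ScreeningReport, pd.DataFrame]:
    """Run exclusions + scoring + banding; return the report and scored rows.

    The returned score table covers all retained records (not only positive
    screens), with severity bands; prevalence is 100 * positives / retained.
    """
    retained, excluded = apply_exclusions(frame)
    breakdown = {rule: 0 for rule in EXCLUSION_RULES}
    for reason in excluded.get("reason", ()):
        for rule in reason.split("+"):
            breakdown[rule] += 1
    scores = score_frame(retained)
    band_counts = {
        label: int((scores["band"] == label).sum())
        for label in ("none", "mild", "moderate", "moderately_severe", "severe")
    }
    n_positive = int((scores["dep"] >= threshold).sum())
    n_retained = len(retained)
    report = ScreeningReport(
        n_raw=len(frame),
        n_excluded=len(excluded),
        exclusion_breakdown=breakdown,
        n_retained=n_retained,
        n_positive=n_positive,
        prevalence_pct=100.0 * n_positive / n_retained if n_retained else float("nan"),
        exclusion_pct=100.0 * len(excluded) / len(frame) if len(frame) else 0.0,
        band_counts=band_counts,
    )
    return report, scores


@dataclass
class CorrelationSummary:
    """Descriptives plus the Pearson correlation matrix of the scale totals."""

    variables: list[str]
    means: pd.Series
    sds: pd.Series
    r: pd.DataFrame
    p: pd.DataFrame
    n: int

    def table(self) -> pd.DataFrame:
        """Report layout: M, SD, then the correlation columns."""
        out = pd.DataFrame({"M": self.means, "SD": self.sds})
        return pd.concat([out, self.r], axis=1)


def pearson_matrix(
    scores: pd.DataFrame, variables: tuple[str, ...] = ("dep", "is", "psycap", "fs")
) -> CorrelationSummary:
    """Pairwise Pearson correlations with two-sided p from the t transform."""
    data = scores[list(variables)].dropna()
    n = len(data)
    if n < 3:
        raise ValidationError("need at least 3 complete rows for correlations")
    mat = data.to_numpy(dtype=float)
    if np.any(mat.std(axis=0) <= 0):
        bad = [v for v, s in zip(variables, mat.std(axis=0)) if s <= 0]
        raise DegenerateVariableError(f"zero variance in column(s): {bad}")
    r = np.corrcoef(mat, rowvar=False)
    with np.errstate(divide="ignore"):
        t = r * np.sqrt((n - 2) / (1.0 - r**2))
    p = 2 * stats.t.sf(np.abs(t), n - 2)
    np.fill_diagonal(p, 0.0)
    idx = list(variables)
    return CorrelationSummary(
        variables=idx,
        means=pd.Series(mat.mean(axis=0), index=idx),
        sds=pd.Series(mat.std(axis=0, ddof=1), index=idx),
        r=pd.DataFrame(r, index=idx, columns=idx),
        p=pd.DataFrame(p, index=idx, columns=idx),
        n=n,
    )


def gender_t_test(
    scores: pd.DataFrame, variable: str, welch: bool = False
) -> tuple[float, float, float]:
    """Two-sample t-test of a scale total between genders.

    Student's pooled-variance form by default (two-sided); pass ``welch=True``
    for the unequal-variance variant.  Returns (t, df, p).
    """
    present = scores.dropna(subset=[variable])
    groups = [
        present.loc[present["gender"] == g, variable].to_numpy(dtype=float)
        for g in ("male", "female")
    ]
    if any(len(g) < 2 for g in groups):
        raise GroupingError("both gender groups need at least 2 observations")
    res = stats.ttest_ind(groups[0], groups[1], equal_var=not welch)
    return float(res.statistic), float(res.df), float(res.pvalue)


def harman_single_factor(item_matrix) -> float:
    """Variance share (%) of the first unrotated principal component.

    Items are pooled across instruments and standardized, so the statistic is
    100 * lambda_max / k for the item correlation matrix.
    """
    m = np.asarray(item_matrix, dtype=float)
    m = m[~np.isnan(m).any(axis=1)]
    if m.ndim != 2 or m.shape[1] < 2 or m.shape[0] < 3:
        raise ValidationError("need a complete-case matrix with >= 2 items, >= 3 rows")
    sds = m.std(axis=0)
    if np.any(sds <= 0):
        raise DegenerateVariableError("constant item in the pooled matrix")
    corr = np.corrcoef(m, rowvar=False)
    lam = np.linalg.eigvalsh(corr)[-1]
    return float(100.0 * lam / m.shape[1])


def harman_from_scores(
    scores: pd.DataFrame, variables: tuple[str, ...] = ("dep", "is", "psycap", "fs")
) -> float:
    """Harman's test on scale totals instead of pooled items."""
    return harman_single_factor(scores[list(variables)].to_numpy(dtype=float))
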