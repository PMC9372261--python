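"""Instrument definitions, scale scoring, severity banding, and reliability.

Four self-report instruments make up the survey battery:

* ``dep`` — PHQ-9 depression screener, 9 items scored 0-3, total 0-27.
* ``is`` — SCL-90 interpersonal-sensitivity subscale, 9 items scored 0-4,
  total 0-36.
* ``psycap`` — Psychological Capital Questionnaire (PCQ-24), 24 items on a
  1-6 Likert scale, total 24-144.
* ``fs`` — Perceived Social Support from Family, 20 yes/no items, total 0-20.

Scale totals are plain item sums.  A missing item voids the whole scale total
(listwise principle): incomplete questionnaires are excluded upstream rather
than pro-rated.

Reliability: Cronbach's alpha for polytomous scales; the Kuder-Richardson
KR-21 approximation is additionally available for the binary family-support
scale.  Variances inside both coefficients use the population (divide by n)
convention; for alpha the convention cancels in the variance ratio, for KR-21
it matters in the fourth decimal at survey sample sizes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import UndefinedReliabilityError, ValidationError

__all__ = [
    "ScaleDefinition",
    "SCALES",
    "SEVERITY_BANDS",
    "item_columns",
    "all_item_columns",
    "score_scale",
    "score_items",
    "score_frame",
    "severity_band",
    "cronbach_alpha",
    "kr21",
    "score_pcq_components",
]


@dataclass(frozen=True)
class ScaleDefinition:
    """One instrument: its item count, item range, and CSV column prefix."""

    name: str
    n_items: int
    item_min: int
    item_max: int
    prefix: str
    severity_thresholds: tuple[int, ...] = field(default=())

    def __post_init__(self) -> None:
        if self.item_min >= self.item_max:
            raise ValidationError(f"{self.name}: item_min must be < item_max")
        if self.severity_thresholds != tuple(sorted(set(self.severity_thresholds))):
            raise ValidationError(f"{self.name}: thresholds must strictly increase")

    @property
    def total_min(self) -> int:
        return self.n_items * self.item_min

    @property
    def total_max(self) -> int:
        return self.n_items * self.item_max


#: Severity thresholds for the depression screener: totals of 5, 10, 15 and 20
#: open the mild, moderate, moderately-severe and severe bands.
SEVERITY_BANDS: tuple[tuple[int, str], ...] = (
    (20, "severe"),
    (15, "moderately_severe"),
    (10, "moderate"),
    (5, "mild"),
    (0, "none"),
)

SCALES: dict[str, ScaleDefinition] = {
    "dep": ScaleDefinition("dep", 9, 0, 3, "phq", (5, 10, 15, 20)),
    "is": ScaleDefinition("is", 9, 0, 4, "is"),
    "psycap": ScaleDefinition("psycap", 24, 1, 6, "pcq"),
    "fs": ScaleDefinition("fs", 20, 0, 1, "fs"),
}

#: PCQ-24 component structure (six consecutive items per component).
PCQ_COMPONENTS = ("self_efficacy", "hope", "resilience", "optimism")


def item_columns(scale: ScaleDefinition) -> list[str]:
    """CSV column names of one instrument, e.g. ``phq1 .. phq9``."""
    return [f"{scale.prefix}{i}" for i in range(1, scale.n_items + 1)]


def all_item_columns() -> list[str]:
    """All 62 item columns in canonical order (phq, is, pcq, fs)."""
    cols: list[str] = []
    for name in ("dep", "is", "psycap", "fs"):
        cols.extend(item_columns(SCALES[name]))
    return cols


def _validate_items(values: np.ndarray, scale: ScaleDefinition, who: str) -> None:
    present = ~np.isnan(values)
    bad = present & ((values < scale.item_min) | (values > scale.item_max))
    if np.any(bad):
        idx = int(np.argmax(bad))
        raise ValidationError(
            f"respondent {who}: item {scale.prefix}{idx + 1} value "
            f"{values[idx]:g} outside [{scale.item_min}, {scale.item_max}]"
        )


def score_scale(items, scale: ScaleDefinition, respondent_id: str = "?") -> float:
    """Sum one respondent's items; NaN if any item is missing.

    Raises :class:`ValidationError` naming the respondent and item when a
    present value falls outside the instrument's range.
    """
    values = np.asarray(items, dtype=float)
    if values.shape != (scale.n_items,):
        raise ValidationError(
            f"respondent {respondent_id}: expected {scale.n_items} "
            f"{scale.name} items, got {values.shape}"
        )
    _validate_items(values, scale, respondent_id)
    if np.isnan(values).any():
        return float("nan")
    return float(values.sum())


def score_items(frame: pd.DataFrame, scale: ScaleDefinition) -> pd.Series:
    """Vectorised scale totals for a cohort frame; NaN where any item missing."""
    cols = item_columns(scale)
    block = frame[cols].to_numpy(dtype=float)
    ids = frame["id"].astype(str) if "id" in frame.columns else frame.index.astype(str)
    present = ~np.isnan(block)
    bad = present & ((block < scale.item_min) | (block > scale.item_max))
    if bad.any():
        r, c = map(int, np.argwhere(bad)[0])
        raise ValidationError(
            f"respondent {ids.iloc[r]}: item {cols[c]} value "
            f"{block[r, c]:g} outside [{scale.item_min}, {scale.item_max}]"
        )
    totals = block.sum(axis=1)
    totals[np.isnan(block).any(axis=1)] = np.nan
    return pd.Series(totals, index=frame.index, name=scale.name)


def severity_band(dep_total: float) -> str:
    """Map a PHQ-9 total to its severity band.

    0-4 none, 5-9 mild, 10-14 moderate, 15-19 moderately_severe, 20-27 severe.
    """
    if not 0 <= dep_total <= 27:
        raise ValidationError(f"dep total {dep_total} outside [0, 27]")
    for threshold, label in SEVERITY_BANDS:
        if dep_total >= threshold:
            return label
    raise AssertionError("unreachable")


def score_frame(frame: pd.DataFrame) -> pd.DataFrame:
    """Score a cohort frame into a per-respondent score table.

    Returns columns ``id, gender, dep, is, psycap, fs, band``; ``band`` is NaN
    when the depression total itself is missing.
    """
    out = pd.DataFrame(index=frame.index)
    out["id"] = frame["id"] if "id" in frame.columns else frame.index.astype(str)
    out["gender"] = frame.get("gender", pd.Series("missing", index=frame.index))
    for name in ("dep", "is", "psycap", "fs"):
        out[name] = score_items(frame, SCALES[name])
    out["band"] = [
        severity_band(t) if np.isfinite(t) else np.nan for t in out["dep"]
    ]
    return out


def _as_complete_matrix(item_matrix) -> np.ndarray:
    m = np.asarray(item_matrix, dtype=float)
    if m.ndim != 2 or m.shape[1] < 2:
        raise ValidationError("reliability needs a 2-D matrix with >= 2 items")
    m = m[~np.isnan(m).any(axis=1)]
    if m.shape[0] < 2:
        raise ValidationError("reliability needs >= 2 complete respondents")
    return m


def cronbach_alpha(item_matrix) -> float:
    """Cronbach's alpha: k/(k-1) * (1 - sum of item variances / total variance)."""
    m = _as_complete_matrix(item_matrix)
    k = m.shape[1]
    item_var = m.var(axis=0).sum()
    total_var = m.sum(axis=1).var()
    if total_var <= 0:
        raise UndefinedReliabilityError("total score has zero variance")
    return k / (k - 1) * (1.0 - item_var / total_var)


def kr21(binary_item_matrix) -> float:
    """KR-21 reliability for binary items, assuming equal item difficulty.

    KR-21 = k/(k-1) * (1 - M(k-M) / (k * var(total))) with M the mean total.
    """
    m = _as_complete_matrix(binary_item_matrix)
    if not np.isin(m, (0.0, 1.0)).all():
        raise ValidationError("KR-21 requires strictly 0/1 items")
    k = m.shape[1]
    totals = m.sum(axis=1)
    mean_total = totals.mean()
    total_var = totals.var()
    if total_var <= 0:
        raise UndefinedReliabilityError("total score has zero variance")
    return k / (k - 1) * (1.0 - mean_total * (k - mean_total) / (k * total_var))


def score_pcq_components(frame: pd.DataFrame) -> pd.DataFrame:
    """Six-item PCQ-24 component sums (self-efficacy, hope, resilience, optimism).

    Provided for completeness; the downstream moderation analysis uses only
    the composite total.
    """
    scale = SCALES["psycap"]
    cols = item_columns(scale)
    out = pd.DataFrame(index=frame.index)
    for j, comp in enumerate(PCQ_COMPONENTS):
        block = frame[cols[6 * j : 6 * (j + 1)]].to_numpy(dtype=float)
        vals = block.sum(axis=1)
        vals[np.isnan(block).any(axis=1)] = np.nan
        out[comp] = vals
    return out
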