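"""Simple slopes, pairwise slope-difference tests, and interaction plot data.

On the standardized scale the conditional effect of X at moderator values
(m, w) is b1 + b3 m + b5 w + b7 m w.  The four conventional probes sit at the
(+/-1 SD, +/-1 SD) corners:

    slope 1: high M, high W      slope 2: high M, low W
    slope 3: low M, high W       slope 4: low M, low W

Each of the six pairwise differences is a linear contrast of (b3, b5, b7);
its standard error is sqrt(c' V c) with V the coefficient covariance matrix,
and the test statistic is referred to the standard normal with a 1.96-based
95% interval, the convention of the slope-difference procedure for probing
three-way interactions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import SpecificationError
from .models import ModelFit, conditional_effect

__all__ = [
    "SLOPE_CORNERS",
    "SLOPE_LABELS",
    "SLOPE_PAIRS",
    "SlopeSet",
    "SlopeDifference",
    "simple_slopes",
    "slope_difference_tests",
    "slope_table",
    "interaction_plot_data",
]

#: Moderator corner (m, w) for each slope label.
SLOPE_CORNERS: dict[int, tuple[float, float]] = {
    1: (+1.0, +1.0),
    2: (+1.0, -1.0),
    3: (-1.0, +1.0),
    4: (-1.0, -1.0),
}

SLOPE_LABELS: dict[int, str] = {
    1: "high PsyCap, high FS",
    2: "high PsyCap, low FS",
    3: "low PsyCap, high FS",
    4: "low PsyCap, low FS",
}

#: Pair ordering of the report table.
SLOPE_PAIRS: tuple[tuple[int, int], ...] = ((1, 2), (1, 3), (1, 4), (2, 3), (2, 4), (3, 4))


@dataclass
class SlopeSet:
    """The four labelled simple slopes with their standard errors."""

    estimates: dict[int, float]
    ses: dict[int, float]
    levels: float = 1.0

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "label": [SLOPE_LABELS[i] for i in sorted(self.estimates)],
                "slope": [self.estimates[i] for i in sorted(self.estimates)],
                "se": [self.ses[i] for i in sorted(self.estimates)],
            },
            index=sorted(self.estimates),
        )


@dataclass
class SlopeDifference:
    """One pairwise contrast between simple slopes (a report-table row)."""

    pair: tuple[int, int]
    difference: float
    se: float
    z: float
    llci: float
    ulci: float
    p: float


def _require_model3(fit: ModelFit) -> None:
    if fit.model_id != 3:
        raise SpecificationError("slope probing requires a Model-3 fit")


def simple_slopes(fit: ModelFit, levels: float = 1.0) -> SlopeSet:
    """Conditional X->Y slopes at the four (+/-levels SD) moderator corners."""
    _require_model3(fit)
    estimates, ses = {}, {}
    for label, (m, w) in SLOPE_CORNERS.items():
        est, se = conditional_effect(fit, levels * m, levels * w)
        estimates[label] = est
        ses[label] = se
    return SlopeSet(estimates=estimates, ses=ses, levels=levels)


def _corner_contrast(m: float, w: float) -> np.ndarray:
    return np.array([0.0, 1.0, 0.0, m, 0.0, w, 0.0, m * w])


def slope_difference_tests(
    fit: ModelFit, levels: float = 1.0, ci_level: float = 0.95
) -> list[SlopeDifference]:
    """All six pairwise slope-difference z-tests in report order.

    difference(a, b) = slope_a - slope_b; se = sqrt(c' V c) for the contrast
    c = c_a - c_b; CI = difference +/- z_{0.975} * se; two-sided normal p.
    """
    _require_model3(fit)
    crit = stats.norm.ppf(0.5 + ci_level / 2)
    out = []
    for a, b in SLOPE_PAIRS:
        ma, wa = SLOPE_CORNERS[a]
        mb, wb = SLOPE_CORNERS[b]
        c = _corner_contrast(levels * ma, levels * wa) - _corner_contrast(
            levels * mb, levels * wb
        )
        diff = float(c @ fit.params)
        var = float(c @ fit.cov_params @ c)
        se = float(np.sqrt(var))
        z = diff / se if se > 0 else float("nan")
        out.append(
            SlopeDifference(
                pair=(a, b),
                difference=diff,
                se=se,
                z=z,
                llci=diff - crit * se,
                ulci=diff + crit * se,
                p=float(2 * stats.norm.sf(abs(z))) if np.isfinite(z) else float("nan"),
            )
        )
    return out


def slope_table(differences: list[SlopeDifference]) -> pd.DataFrame:
    """Slope-difference results as a tidy report frame."""
    return pd.DataFrame(
        {
            "pair": [f"({a}) and ({b})" for a, b in (d.pair for d in differences)],
            "difference": [d.difference for d in differences],
            "se": [d.se for d in differences],
            "z": [d.z for d in differences],
            "llci": [d.llci for d in differences],
            "ulci": [d.ulci for d in differences],
            "p": [d.p for d in differences],
        }
    )


def interaction_plot_data(fit: ModelFit, levels: float = 1.0) -> pd.DataFrame:
    """Predicted outcome at X in {-1, +1} for each moderator corner.

    Returns a tidy frame (line_label, x, y_hat): four two-point line segments
    whose slopes equal the simple slopes exactly.
    """
    _require_model3(fit)
    rows = []
    for label, (m, w) in SLOPE_CORNERS.items():
        m, w = levels * m, levels * w
        for x in (-1.0, 1.0):
            design = np.array([1.0, x, m, x * m, w, x * w, m * w, x * m * w])
            rows.append(
                {
                    "line": label,
                    "line_label": SLOPE_LABELS[label],
                    "x": x,
                    "y_hat": float(design @ fit.params),
                }
            )
    return pd.DataFrame(rows)
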