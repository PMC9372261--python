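"""Two-way and three-way interaction OLS on standardized variables.

Model 1 regresses the outcome Y on X, M and their product XM; the XM
coefficient measures how the X->Y slope changes per SD of the moderator M.
Model 3 adds a second moderator W and all remaining products:

    Y = b0 + b1 X + b2 M + b3 XM + b4 W + b5 XW + b6 MW + b7 XMW + e

All component variables are standardized (mean 0, SD 1, n-1 denominator)
*before* products are formed, which makes the +/-1 SD simple-slope algebra
exact.  Estimation is ordinary least squares via a QR factorisation; standard
errors come from sigma2 * (X'X)^-1 with sigma2 = RSS/(n-k-1), t-based p-values
and confidence intervals use n-k-1 degrees of freedom.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.linalg import solve_triangular

from .errors import (
    CollinearityError,
    DegenerateVariableError,
    SpecificationError,
    ValidationError,
)

__all__ = [
    "MODEL1_TERMS",
    "MODEL3_TERMS",
    "ModelSpec",
    "ModelFit",
    "standardize",
    "interaction_design",
    "fit_ols",
    "fit_model",
    "fit_interaction",
    "conditional_effect",
]

MODEL1_TERMS = ("const", "x", "m", "xm")
MODEL3_TERMS = ("const", "x", "m", "xm", "w", "xw", "mw", "xmw")


@dataclass(frozen=True)
class ModelSpec:
    """Which columns of a score table play which role in the interaction model."""

    model_id: int = 3
    outcome: str = "dep"
    predictor: str = "is"
    moderator: str = "psycap"
    second_moderator: str = "fs"
    ci_level: float = 0.95

    def __post_init__(self) -> None:
        if self.model_id not in (1, 3):
            raise SpecificationError("model_id must be 1 or 3")
        if not 0 < self.ci_level < 1:
            raise SpecificationError("ci_level must lie in (0, 1)")

    @property
    def terms(self) -> tuple[str, ...]:
        return MODEL1_TERMS if self.model_id == 1 else MODEL3_TERMS


def standardize(values, ddof: int = 1) -> np.ndarray:
    """Center to mean 0 and scale to SD 1 (sample SD by default)."""
    v = np.asarray(values, dtype=float)
    sd = v.std(ddof=ddof)
    if not np.isfinite(sd) or sd <= 0:
        raise DegenerateVariableError("cannot standardize a constant variable")
    return (v - v.mean()) / sd


def interaction_design(x, m, w=None) -> np.ndarray:
    """Design matrix [1, X, M, XM] or [1, X, M, XM, W, XW, MW, XMW].

    Inputs are used as given: standardize first when fitting the reported
    (beta-weight) form of the model.
    """
    x = np.asarray(x, dtype=float)
    m = np.asarray(m, dtype=float)
    cols = [np.ones_like(x), x, m, x * m]
    if w is not None:
        w = np.asarray(w, dtype=float)
        cols += [w, x * w, m * w, x * m * w]
    return np.column_stack(cols)


@dataclass
class ModelFit:
    """Full inferential output of one interaction model fit.

    ``params`` follows the term order of :data:`MODEL1_TERMS` /
    :data:`MODEL3_TERMS` (b0..b3 or b0..b7).  ``cov_params`` is the estimated
    coefficient covariance matrix; desk-constructed fits built from a printed
    coefficient table carry NaN there, so contrast point estimates remain
    available while standard errors are undefined.
    """

    terms: tuple[str, ...]
    params: np.ndarray
    se: np.ndarray
    tvalues: np.ndarray
    pvalues: np.ndarray
    llci: np.ndarray
    ulci: np.ndarray
    cov_params: np.ndarray
    sigma2: float
    r_squared: float
    f_stat: float
    df1: int
    df2: float
    n: int
    model_id: int
    ci_level: float = 0.95

    @property
    def k(self) -> int:
        """Number of non-constant regressors."""
        return len(self.terms) - 1

    @classmethod
    def from_coefficients(
        cls,
        params,
        cov_params=None,
        n: int | None = None,
        ci_level: float = 0.95,
    ) -> "ModelFit":
        """Build a fit object from a coefficient vector (e.g. a printed table).

        With ``cov_params`` supplied, standard errors and z-based inference are
        filled in; without it they are NaN and only linear contrasts of the
        coefficients are meaningful.
        """
        params = np.asarray(params, dtype=float)
        if params.shape == (4,):
            model_id, terms = 1, MODEL1_TERMS
        elif params.shape == (8,):
            model_id, terms = 3, MODEL3_TERMS
        else:
            raise SpecificationError("coefficient vector must have length 4 or 8")
        p = len(params)
        if cov_params is None:
            cov = np.full((p, p), np.nan)
        else:
            cov = np.asarray(cov_params, dtype=float)
            if cov.shape != (p, p):
                raise SpecificationError("covariance shape does not match params")
        se = np.sqrt(np.diag(cov))
        z = params / se
        crit = stats.norm.ppf(0.5 + ci_level / 2)
        return cls(
            terms=terms,
            params=params,
            se=se,
            tvalues=z,
            pvalues=2 * stats.norm.sf(np.abs(z)),
            llci=params - crit * se,
            ulci=params + crit * se,
            cov_params=cov,
            sigma2=float("nan"),
            r_squared=float("nan"),
            f_stat=float("nan"),
            df1=p - 1,
            df2=float(n - p) if n else float("nan"),
            n=int(n) if n else 0,
            model_id=model_id,
            ci_level=ci_level,
        )

    def summary_frame(self) -> pd.DataFrame:
        """Coefficient table in the conventional report layout."""
        return pd.DataFrame(
            {
                "coefficient": self.params,
                "se": self.se,
                "t": self.tvalues,
                "p": self.pvalues,
                "llci": self.llci,
                "ulci": self.ulci,
            },
            index=list(self.terms),
        )

    def to_dict(self) -> dict:
        d = {
            "model_id": self.model_id,
            "terms": list(self.terms),
            "n": self.n,
            "ci_level": self.ci_level,
            "r_squared": self.r_squared,
            "f_stat": self.f_stat,
            "df1": self.df1,
            "df2": self.df2,
            "sigma2": self.sigma2,
            "cov_params": self.cov_params.tolist(),
        }
        for key in ("params", "se", "tvalues", "pvalues", "llci", "ulci"):
            d[key] = getattr(self, key).tolist()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ModelFit":
        return cls(
            terms=tuple(d["terms"]),
            params=np.asarray(d["params"], dtype=float),
            se=np.asarray(d["se"], dtype=float),
            tvalues=np.asarray(d["tvalues"], dtype=float),
            pvalues=np.asarray(d["pvalues"], dtype=float),
            llci=np.asarray(d["llci"], dtype=float),
            ulci=np.asarray(d["ulci"], dtype=float),
            cov_params=np.asarray(d["cov_params"], dtype=float),
            sigma2=d["sigma2"],
            r_squared=d["r_squared"],
            f_stat=d["f_stat"],
            df1=d["df1"],
            df2=d["df2"],
            n=d["n"],
            model_id=d["model_id"],
            ci_level=d.get("ci_level", 0.95),
        )


def fit_ols(
    design: np.ndarray,
    y,
    terms: tuple[str, ...],
    model_id: int,
    ci_level: float = 0.95,
) -> ModelFit:
    """OLS with full inference on an explicit design matrix (first column = 1)."""
    y = np.asarray(y, dtype=float)
    n, p = design.shape
    if n <= p:
        raise ValidationError(f"need n > {p} observations, got {n}")
    q, r = np.linalg.qr(design)
    rdiag = np.abs(np.diag(r))
    tol = max(n, p) * np.finfo(float).eps * rdiag.max()
    if np.any(rdiag < tol):
        bad = [terms[i] for i in np.nonzero(rdiag < tol)[0]]
        raise CollinearityError(bad)
    params = solve_triangular(r, q.T @ y)
    resid = y - design @ params
    df2 = n - p
    rss = float(resid @ resid)
    sigma2 = rss / df2
    r_inv = solve_triangular(r, np.eye(p))
    cov = sigma2 * (r_inv @ r_inv.T)
    se = np.sqrt(np.diag(cov))
    tvals = params / se
    pvals = 2 * stats.t.sf(np.abs(tvals), df2)
    crit = stats.t.ppf(0.5 + ci_level / 2, df2)
    tss = float(((y - y.mean()) ** 2).sum())
    if tss <= 0:
        raise DegenerateVariableError("outcome has zero variance")
    r2 = 1.0 - rss / tss
    k = p - 1
    f = (r2 / k) / ((1.0 - r2) / df2) if r2 < 1.0 else float("inf")
    return ModelFit(
        terms=terms,
        params=params,
        se=se,
        tvalues=tvals,
        pvalues=pvals,
        llci=params - crit * se,
        ulci=params + crit * se,
        cov_params=cov,
        sigma2=sigma2,
        r_squared=r2,
        f_stat=f,
        df1=k,
        df2=float(df2),
        n=n,
        model_id=model_id,
        ci_level=ci_level,
    )


def fit_interaction(
    x, m, y, w=None, standardized: bool = False, ci_level: float = 0.95
) -> ModelFit:
    """Fit the interaction model directly on arrays.

    With ``standardized=True`` each variable (including the outcome) is
    z-scored first, reproducing the reported beta-weight scale; with the
    default ``False`` the arrays are used as given, which is the right mode
    for data already generated on the model's own scale.
    """
    if standardized:
        x, m, y = standardize(x), standardize(m), standardize(y)
        if w is not None:
            w = standardize(w)
    design = interaction_design(x, m, w)
    terms = MODEL1_TERMS if w is None else MODEL3_TERMS
    return fit_ols(design, np.asarray(y, float), terms, 1 if w is None else 3, ci_level)


def fit_model(scores: pd.DataFrame, spec: ModelSpec) -> ModelFit:
    """Fit Model 1 or Model 3 on a score table per the analysis convention.

    Rows with any missing analysis variable are dropped (listwise deletion),
    every variable is standardized, then products are formed.
    """
    cols = [spec.outcome, spec.predictor, spec.moderator]
    if spec.model_id == 3:
        cols.append(spec.second_moderator)
    missing = [c for c in cols if c not in scores.columns]
    if missing:
        raise ValidationError(f"score table lacks column(s): {', '.join(missing)}")
    data = scores[cols].dropna()
    w = data[spec.second_moderator] if spec.model_id == 3 else None
    return fit_interaction(
        data[spec.predictor],
        data[spec.moderator],
        data[spec.outcome],
        w=w,
        standardized=True,
        ci_level=spec.ci_level,
    )


def _effect_contrast(fit: ModelFit, m: float, w: float | None) -> np.ndarray:
    if fit.model_id == 1:
        if w is not None:
            raise SpecificationError("Model 1 has no second moderator W")
        return np.array([0.0, 1.0, 0.0, m])
    if w is None:
        raise SpecificationError("Model 3 conditional effect requires w")
    return np.array([0.0, 1.0, 0.0, m, 0.0, w, 0.0, m * w])


def conditional_effect(
    fit: ModelFit, m: float, w: float | None = None
) -> tuple[float, float]:
    """Effect of X on Y at fixed moderator values, with its standard error.

    Model 3: b1 + b3 m + b5 w + b7 m w; Model 1: b1 + b3 m.  The standard
    error is sqrt(c' V c) for the corresponding contrast c.
    """
    c = _effect_contrast(fit, m, w)
    effect = float(c @ fit.params)
    se = float(np.sqrt(c @ fit.cov_params @ c))
    return effect, se
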