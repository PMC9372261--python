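"""Synthetic freshman-survey cohorts with a known moderated-moderation structure.

The generator works latent-first: standardized interpersonal sensitivity (X),
psychological capital (M) and family support (W) are drawn from a trivariate
normal with configurable correlations, and the standardized depression outcome
Y follows the three-way interaction equation

    Y = b0 + b1 X + b2 M + b3 XM + b4 W + b5 XW + b6 MW + b7 XMW + e,

with e ~ Normal(0, noise_sd).  Latent scores are then mapped to bounded
integer scale totals at the configured means/SDs, and each total is spread
over an instrument's items by a uniform constrained allocation (multivariate
hypergeometric), the simplest scheme that preserves totals exactly — and
totals are all the downstream analysis uses.

Defaults reproduce the screened freshman cohort the package emulates: scale
moments and correlations of the observed score table, the fitted Model-3
coefficient vector, residual SD 0.8, and 59.65% women.

Contaminated records exercise the exclusion rules.  Each contaminated record
violates exactly one rule:

* ``incomplete`` — one to three items blanked;
* ``straight_line`` — the same response on every item of every polytomous
  instrument (a classic lazy-respondent column of identical answers);
* ``patterned`` — a strict two-value alternation across the two long
  instruments (PCQ-24 and the family-support scale).

Randomness is split into named sub-streams of one root seed, so e.g. adding
contamination never perturbs the clean records.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigurationError, ValidationError
from .models import interaction_design
from .scales import SCALES, ScaleDefinition, all_item_columns, item_columns

__all__ = [
    "SCALE_ORDER",
    "DEFAULT_SCALE_MEANS",
    "DEFAULT_SCALE_SDS",
    "DEFAULT_LATENT_CORRELATIONS",
    "DEFAULT_COEFFICIENTS",
    "DEFAULT_FEMALE_FRACTION",
    "GeneratorConfig",
    "generate_latents",
    "equation_moments",
    "discretize_to_items",
    "generate_cohort",
    "cohort_with_band_counts",
    "write_cohort",
    "read_cohort",
]

SCALE_ORDER = ("dep", "is", "psycap", "fs")

#: Score-table moments of the screened cohort the generator emulates.
DEFAULT_SCALE_MEANS = {"dep": 7.909, "is": 14.442, "psycap": 102.107, "fs": 13.895}
DEFAULT_SCALE_SDS = {"dep": 3.147, "is": 6.148, "psycap": 13.064, "fs": 4.833}

#: Correlations among the latent predictors, order (IS, PsyCap, FS).
DEFAULT_LATENT_CORRELATIONS = np.array(
    [
        [1.000, -0.361, -0.286],
        [-0.361, 1.000, 0.229],
        [-0.286, 0.229, 1.000],
    ]
)

#: Fitted standardized coefficient vector (b0..b7) of the three-way model.
DEFAULT_COEFFICIENTS = np.array(
    [-0.058, 0.343, -0.006, -0.106, -0.033, -0.032, 0.011, 0.076]
)

DEFAULT_FEMALE_FRACTION = 0.5965

CONTAMINATION_KINDS = ("incomplete", "straight_line", "patterned")

_STAGES = {"latents": 0, "gender": 1, "items": 2, "contamination": 3, "bands": 4}


def _stage_rng(seed: int, stage: str) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(seed, spawn_key=(_STAGES[stage],))
    )


@dataclass
class GeneratorConfig:
    """Everything that determines a synthetic cohort, including its seed."""

    n_respondents: int = 694
    latent_correlations: np.ndarray = field(
        default_factory=lambda: DEFAULT_LATENT_CORRELATIONS.copy()
    )
    scale_means: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_SCALE_MEANS))
    scale_sds: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_SCALE_SDS))
    true_coefficients: np.ndarray = field(
        default_factory=lambda: DEFAULT_COEFFICIENTS.copy()
    )
    noise_sd: float = 0.8
    female_fraction: float = DEFAULT_FEMALE_FRACTION
    contamination: dict[str, float] = field(default_factory=dict)
    seed: int = 0

    def validate(self) -> None:
        if self.n_respondents <= 0:
            raise ConfigurationError("n_respondents must be positive")
        corr = np.asarray(self.latent_correlations, dtype=float)
        if corr.shape != (3, 3):
            raise ConfigurationError("latent_correlations must be 3x3")
        if not np.allclose(corr, corr.T) or not np.allclose(np.diag(corr), 1.0):
            raise ConfigurationError(
                "latent_correlations must be symmetric with unit diagonal"
            )
        if np.linalg.eigvalsh(corr).min() <= 0:
            raise ConfigurationError("latent_correlations must be positive definite")
        if np.asarray(self.true_coefficients, float).shape != (8,):
            raise ConfigurationError("true_coefficients must have length 8 (b0..b7)")
        if self.noise_sd <= 0:
            raise ConfigurationError("noise_sd must be positive")
        if not 0.0 <= self.female_fraction <= 1.0:
            raise ConfigurationError("female_fraction must lie in [0, 1]")
        unknown = set(self.contamination) - set(CONTAMINATION_KINDS)
        if unknown:
            raise ConfigurationError(f"unknown contamination kind(s): {unknown}")
        rates = [self.contamination.get(k, 0.0) for k in CONTAMINATION_KINDS]
        if any(r < 0 for r in rates):
            raise ConfigurationError("contamination rates must be non-negative")
        if sum(rates) >= 1.0:
            raise ConfigurationError("contamination rates must sum to < 1")
        for name in SCALE_ORDER:
            if self.scale_sds.get(name, 0.0) <= 0:
                raise ConfigurationError(f"scale_sds[{name!r}] must be positive")
            if name not in self.scale_means:
                raise ConfigurationError(f"scale_means missing {name!r}")

    def contamination_counts(self) -> dict[str, int]:
        counts = {
            k: int(np.rint(self.contamination.get(k, 0.0) * self.n_respondents))
            for k in CONTAMINATION_KINDS
        }
        if sum(counts.values()) > self.n_respondents:
            raise ConfigurationError(
                "n_respondents too small for the requested contamination counts"
            )
        return counts

    @classmethod
    def from_mapping(cls, d: dict) -> "GeneratorConfig":
        kwargs = dict(d)
        if "latent_correlations" in kwargs:
            kwargs["latent_correlations"] = np.asarray(
                kwargs["latent_correlations"], dtype=float
            )
        if "true_coefficients" in kwargs:
            kwargs["true_coefficients"] = np.asarray(
                kwargs["true_coefficients"], dtype=float
            )
        cfg = cls(**kwargs)
        cfg.validate()
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "GeneratorConfig":
        with open(path) as fh:
            return cls.from_mapping(yaml.safe_load(fh) or {})

    def to_mapping(self) -> dict:
        return {
            "n_respondents": self.n_respondents,
            "latent_correlations": np.asarray(self.latent_correlations).tolist(),
            "scale_means": dict(self.scale_means),
            "scale_sds": dict(self.scale_sds),
            "true_coefficients": np.asarray(self.true_coefficients).tolist(),
            "noise_sd": self.noise_sd,
            "female_fraction": self.female_fraction,
            "contamination": dict(self.contamination),
            "seed": self.seed,
        }


def equation_moments(
    latent_correlations, coefficients, noise_sd: float
) -> tuple[float, float]:
    """Exact mean and SD of the outcome under the generating equation.

    Uses Isserlis moment identities for the trivariate normal: products of two
    standardized normals have mean equal to their correlation and the triple
    product covaries with the linear terms, so the outcome variance is
    b' C b + noise_sd**2 with C the covariance of the seven regressor terms.
    """
    corr = np.asarray(latent_correlations, dtype=float)
    b = np.asarray(coefficients, dtype=float)
    rxm, rxw, rmw = corr[0, 1], corr[0, 2], corr[1, 2]
    # term order: X, M, XM, W, XW, MW, XMW  (design order minus the constant)
    mean = b[0] + b[3] * rxm + b[5] * rxw + b[6] * rmw
    C = np.zeros((7, 7))
    C[0, 0] = C[1, 1] = C[3, 3] = 1.0
    C[0, 1] = C[1, 0] = rxm
    C[0, 3] = C[3, 0] = rxw
    C[1, 3] = C[3, 1] = rmw
    C[2, 2] = 1 + rxm**2
    C[4, 4] = 1 + rxw**2
    C[5, 5] = 1 + rmw**2
    C[2, 4] = C[4, 2] = rmw + rxm * rxw
    C[2, 5] = C[5, 2] = rxw + rxm * rmw
    C[4, 5] = C[5, 4] = rxm + rxw * rmw
    C[6, 6] = 1 + 2 * (rxm**2 + rxw**2 + rmw**2) + 8 * rxm * rxw * rmw
    C[0, 6] = C[6, 0] = rmw + 2 * rxm * rxw
    C[1, 6] = C[6, 1] = rxw + 2 * rxm * rmw
    C[3, 6] = C[6, 3] = rxm + 2 * rxw * rmw
    var = float(b[1:] @ C @ b[1:]) + noise_sd**2
    return float(mean), float(np.sqrt(var))


def generate_latents(config: GeneratorConfig, seed: int | None = None) -> pd.DataFrame:
    """Standardized latent (x, m, w, y) draws under the generating equation."""
    config.validate()
    rng = _stage_rng(config.seed if seed is None else seed, "latents")
    corr = np.asarray(config.latent_correlations, dtype=float)
    n = config.n_respondents
    chol = np.linalg.cholesky(corr)
    z = rng.standard_normal((n, 3)) @ chol.T
    x, m, w = z[:, 0], z[:, 1], z[:, 2]
    design = interaction_design(x, m, w)
    y = design @ np.asarray(config.true_coefficients, float)
    y += rng.normal(0.0, config.noise_sd, size=n)
    return pd.DataFrame({"x": x, "m": m, "w": w, "y": y})


def discretize_to_items(
    latent_totals, scale: ScaleDefinition, seed_or_rng
) -> np.ndarray:
    """Spread integer-rounded totals over an instrument's items.

    Each total is rounded, clipped to the feasible range [k*min, k*max] and
    allocated over the k items by a multivariate hypergeometric draw, i.e.
    uniformly over all item vectors with that exact sum.  Deterministic for a
    given seed.
    """
    rng = (
        seed_or_rng
        if isinstance(seed_or_rng, np.random.Generator)
        else np.random.default_rng(seed_or_rng)
    )
    totals = np.asarray(latent_totals, dtype=float)
    if not np.isfinite(totals).all():
        raise ValidationError("latent totals must be finite")
    totals = np.clip(np.rint(totals), scale.total_min, scale.total_max).astype(int)
    k = scale.n_items
    span = scale.item_max - scale.item_min
    colors = np.full(k, span)
    out = np.empty((len(totals), k), dtype=int)
    for i, total in enumerate(totals):
        out[i] = scale.item_min + rng.multivariate_hypergeometric(
            colors, total - k * scale.item_min
        )
    return out


def _censored_normal_moments(mu: float, sigma: float, lo: float, hi: float):
    """Mean and SD of clip(Normal(mu, sigma), lo, hi) in closed form."""
    from scipy.stats import norm

    a, b = (lo - mu) / sigma, (hi - mu) / sigma
    pa, pb = norm.cdf(a), norm.cdf(b)
    da, db = norm.pdf(a), norm.pdf(b)
    mid = pb - pa
    mean = lo * pa + hi * (1 - pb) + mu * mid + sigma * (da - db)
    second = (
        lo**2 * pa
        + hi**2 * (1 - pb)
        + (mu**2 + sigma**2) * mid
        + 2 * mu * sigma * (da - db)
        + sigma**2 * (a * da - b * db)
    )
    var = second - mean**2
    return mean, np.sqrt(max(var, 0.0))


def _latent_moments_for_targets(
    mean: float, sd: float, lo: float, hi: float
) -> tuple[float, float]:
    """Latent (mu, sigma) whose clipped totals reproduce the target moments.

    Bounded instruments censor the latent scale: near a floor or ceiling, a
    latent normal at the target moments would land visibly short of the
    target SD (the family-support scale, totals 0-20 with mean near 14, is
    the affected case here).  Inverting the censoring keeps the generated
    totals on target; where clipping is negligible the solution collapses to
    (mean, sd) itself.
    """
    from scipy.optimize import root

    def eqs(params):
        mu, log_sigma = params
        m, s = _censored_normal_moments(mu, np.exp(log_sigma), lo, hi)
        return [m - mean, s - sd]

    sol = root(eqs, x0=[mean, np.log(sd)], method="hybr")
    if not sol.success:  # extreme target moments: fall back to the naive map
        return mean, sd
    return float(sol.x[0]), float(np.exp(sol.x[1]))


def _items_from_latents(
    standardized: dict[str, np.ndarray], config: GeneratorConfig, rng: np.random.Generator
) -> pd.DataFrame:
    frame = {}
    for name in SCALE_ORDER:
        scale = SCALES[name]
        mu, sigma = _latent_moments_for_targets(
            config.scale_means[name],
            config.scale_sds[name],
            scale.total_min,
            scale.total_max,
        )
        totals = mu + sigma * standardized[name]
        items = discretize_to_items(totals, scale, rng)
        for j, col in enumerate(item_columns(scale)):
            frame[col] = items[:, j].astype(float)
    return pd.DataFrame(frame)


def _corrupt_incomplete(frame: pd.DataFrame, rows, rng: np.random.Generator) -> None:
    cols = all_item_columns()
    locs = [frame.columns.get_loc(c) for c in cols]
    for r in rows:
        n_missing = int(rng.integers(1, 4))
        for j in rng.choice(len(locs), size=n_missing, replace=False):
            frame.iat[r, locs[j]] = np.nan


def _corrupt_straight_line(frame: pd.DataFrame, rows, rng: np.random.Generator) -> None:
    choices = {"dep": (1, 3), "is": (1, 4), "psycap": (2, 6), "fs": (0, 2)}
    for r in rows:
        for name in SCALE_ORDER:
            value = float(rng.integers(*choices[name]))
            for col in item_columns(SCALES[name]):
                frame.iat[r, frame.columns.get_loc(col)] = value


def _corrupt_patterned(frame: pd.DataFrame, rows, rng: np.random.Generator) -> None:
    pcq_cols = item_columns(SCALES["psycap"])
    fs_cols = item_columns(SCALES["fs"])
    for r in rows:
        a, b = rng.choice(6, size=2, replace=False) + 1
        for j, col in enumerate(pcq_cols):
            frame.iat[r, frame.columns.get_loc(col)] = float(a if j % 2 == 0 else b)
        start = int(rng.integers(0, 2))
        for j, col in enumerate(fs_cols):
            frame.iat[r, frame.columns.get_loc(col)] = float((start + j) % 2)


_CORRUPTERS = {
    "incomplete": _corrupt_incomplete,
    "straight_line": _corrupt_straight_line,
    "patterned": _corrupt_patterned,
}


def _assign_ids(frame: pd.DataFrame) -> pd.DataFrame:
    frame = frame.reset_index(drop=True)
    frame.insert(0, "id", [f"r{i + 1:05d}" for i in range(len(frame))])
    return frame


def generate_cohort(config: GeneratorConfig) -> pd.DataFrame:
    """Generate one item-level cohort frame (id, gender, 62 item columns).

    Deterministic in ``config.seed``.  Clean records decode to item sets whose
    totals reproduce the configured moments, correlations, and regression
    structure; contaminated records each violate exactly one exclusion rule,
    with class counts equal to round(rate * n).
    """
    config.validate()
    counts = config.contamination_counts()
    latents = generate_latents(config)
    mean_y, sd_y = equation_moments(
        config.latent_correlations, config.true_coefficients, config.noise_sd
    )
    standardized = {
        "dep": (latents["y"].to_numpy() - mean_y) / sd_y,
        "is": latents["x"].to_numpy(),
        "psycap": latents["m"].to_numpy(),
        "fs": latents["w"].to_numpy(),
    }
    items = _items_from_latents(standardized, config, _stage_rng(config.seed, "items"))
    gender_rng = _stage_rng(config.seed, "gender")
    gender = np.where(
        gender_rng.random(config.n_respondents) < config.female_fraction,
        "female",
        "male",
    )
    frame = pd.concat([pd.DataFrame({"gender": gender}), items], axis=1)

    total = sum(counts.values())
    if total:
        rng = _stage_rng(config.seed, "contamination")
        chosen = rng.choice(config.n_respondents, size=total, replace=False)
        offset = 0
        for kind in CONTAMINATION_KINDS:
            rows = chosen[offset : offset + counts[kind]]
            offset += counts[kind]
            _CORRUPTERS[kind](frame, rows, rng)
    return _assign_ids(frame)


def cohort_with_band_counts(
    band_counts: dict[str, int],
    contamination_counts: dict[str, int],
    seed: int = 0,
    config: GeneratorConfig | None = None,
) -> pd.DataFrame:
    """Cohort whose retained records hit exact depression-severity band counts.

    A clean cohort is generated, ranked by depression total, and each record's
    total is clipped into the band assigned to its rank so that the prescribed
    counts hold exactly while the ordering (hence the correlation structure)
    is preserved.  Contaminated records are appended on top and the rows
    shuffled, so the screened pipeline recovers the prescribed breakdown.
    """
    from .scales import SEVERITY_BANDS  # band edges

    band_order = [label for _, label in reversed(SEVERITY_BANDS)]
    unknown = set(band_counts) - set(band_order)
    if unknown:
        raise ConfigurationError(f"unknown severity band(s): {unknown}")
    n_clean = sum(band_counts.values())
    base = config if config is not None else GeneratorConfig()
    base = replace(base, n_respondents=n_clean, contamination={}, seed=seed)
    frame = generate_cohort(base)

    dep_cols = item_columns(SCALES["dep"])
    totals = frame[dep_cols].sum(axis=1).to_numpy()
    order = np.argsort(totals, kind="stable")
    edges = {"none": (0, 4), "mild": (5, 9), "moderate": (10, 14),
             "moderately_severe": (15, 19), "severe": (20, 27)}
    target = np.empty(n_clean, dtype=int)
    pos = 0
    for label in band_order:
        count = band_counts.get(label, 0)
        lo, hi = edges[label]
        rows = order[pos : pos + count]
        target[rows] = np.clip(totals[rows], lo, hi).astype(int)
        pos += count
    changed = target != totals
    if changed.any():
        rng = _stage_rng(seed, "bands")
        new_items = discretize_to_items(target[changed], SCALES["dep"], rng)
        frame.loc[frame.index[changed], dep_cols] = new_items.astype(float)

    n_contam = sum(contamination_counts.values())
    if n_contam:
        contam_seed = int(
            np.random.SeedSequence(seed, spawn_key=(9,)).generate_state(1)[0] % 2**31
        )
        extra = generate_cohort(replace(base, n_respondents=n_contam, seed=contam_seed))
        rng = _stage_rng(seed, "contamination")
        offset = 0
        for kind in CONTAMINATION_KINDS:
            count = contamination_counts.get(kind, 0)
            _CORRUPTERS[kind](extra, range(offset, offset + count), rng)
            offset += count
        frame = pd.concat([frame, extra], ignore_index=True)
        perm = rng.permutation(len(frame))
        frame = frame.iloc[perm].drop(columns="id")
        frame = _assign_ids(frame)
    return frame


def write_cohort(frame: pd.DataFrame, path) -> None:
    """Write a cohort CSV; missing items become empty fields."""
    out = frame.copy()
    for col in all_item_columns():
        out[col] = out[col].astype("Int64")
    out.to_csv(path, index=False)


def read_cohort(path_or_buffer) -> pd.DataFrame:
    """Read a cohort CSV back into the canonical float-item frame."""
    if isinstance(path_or_buffer, str) and "\n" in path_or_buffer:
        path_or_buffer = io.StringIO(path_or_buffer)
    frame = pd.read_csv(path_or_buffer, dtype={"id": str, "gender": str})
    missing = [c for c in ("id", "gender", *all_item_columns()) if c not in frame.columns]
    if missing:
        raise ValidationError(f"cohort CSV lacks column(s): {', '.join(missing[:5])}")
    for col in all_item_columns():
        frame[col] = pd.to_numeric(frame[col], errors="raise").astype(float)
    frame["gender"] = frame["gender"].fillna("missing")
    return frame
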