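"""Monte-Carlo power for the two-way and three-way interaction coefficients.

Each replicate draws standardized predictors (X, M, W), forms the outcome
from the three-way interaction equation with Normal(0, noise_sd) residuals,
fits the full Model 3, and records whether the tested coefficient's two-sided
t-based p-value falls below alpha.  Power at an effect size is the rejection
fraction over replicates; its Monte-Carlo standard error is the binomial
sqrt(p(1-p)/reps).

Scenario A varies the two-way coefficient b3 (XM) with the three-way b7 held
at its fitted value; scenario B varies b7 (XMW) with b3 held fixed.

Predictor source (``predictor_mode``):

* ``simulate_mvn`` (default) — fresh trivariate-normal predictors per
  replicate at the configured correlations;
* ``fixed_design`` — one predictor matrix drawn once and reused across
  replicates, so only the residuals resample.

Because only the tested coefficient moves along the grid, each replicate is
fitted once with that coefficient at zero; adding e * (tested column) to the
outcome shifts only the tested estimate by e and leaves residuals and
standard errors unchanged, so the whole grid is evaluated from a single fit
per replicate.  Replicate sub-seeds are spawned from the scenario seed and
shared across grid points (common random numbers), making every grid point
individually reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.linalg import solve_triangular

from .cohort import DEFAULT_COEFFICIENTS, DEFAULT_LATENT_CORRELATIONS
from .errors import ConfigurationError
from .models import interaction_design

__all__ = [
    "SCENARIO_TESTED_TERM",
    "DEFAULT_GRID_A",
    "DEFAULT_GRID_B",
    "PowerScenario",
    "PowerCurve",
    "scenario_a",
    "scenario_b",
    "run_power",
    "power_at",
]

#: Index of the tested coefficient in the b0..b7 vector, per scenario.
SCENARIO_TESTED_TERM = {"A": 3, "B": 7}

DEFAULT_GRID_A = tuple(np.round(np.arange(-0.03, -0.121, -0.01), 2))
DEFAULT_GRID_B = tuple(np.round(np.arange(0.01, 0.101, 0.01), 2))


@dataclass
class PowerScenario:
    """Configuration of one Monte-Carlo power run."""

    scenario: str
    effect_grid: tuple[float, ...]
    fixed_coefficients: np.ndarray = field(
        default_factory=lambda: DEFAULT_COEFFICIENTS.copy()
    )
    noise_sd: float = 0.8
    n: int = 694
    reps: int = 1000
    alpha: float = 0.05
    predictor_mode: str = "simulate_mvn"
    latent_correlations: np.ndarray = field(
        default_factory=lambda: DEFAULT_LATENT_CORRELATIONS.copy()
    )
    seed: int = 0

    def validate(self) -> None:
        if self.scenario not in SCENARIO_TESTED_TERM:
            raise ConfigurationError("scenario must be 'A' or 'B'")
        if len(self.effect_grid) == 0:
            raise ConfigurationError("effect_grid must be nonempty")
        if self.reps < 1:
            raise ConfigurationError("reps must be >= 1")
        if not 0 < self.alpha < 1:
            raise ConfigurationError("alpha must lie in (0, 1)")
        if self.predictor_mode not in ("simulate_mvn", "fixed_design"):
            raise ConfigurationError(
                "predictor_mode must be 'simulate_mvn' or 'fixed_design'"
            )
        if self.noise_sd <= 0:
            raise ConfigurationError("noise_sd must be positive")
        corr = np.asarray(self.latent_correlations, dtype=float)
        if corr.shape != (3, 3) or not np.allclose(corr, corr.T):
            raise ConfigurationError("latent_correlations must be symmetric 3x3")
        if np.linalg.eigvalsh(corr).min() <= 0:
            raise ConfigurationError("latent_correlations must be positive definite")

    @property
    def tested_index(self) -> int:
        return SCENARIO_TESTED_TERM[self.scenario]


@dataclass
class PowerCurve:
    """Estimated rejection rates over the effect grid."""

    scenario: str
    tested_term: str
    results: pd.DataFrame  # columns: effect, power, mc_se, reps

    def power_at(self, effect: float) -> float:
        row = self.results.loc[np.isclose(self.results["effect"], effect)]
        if row.empty:
            raise KeyError(f"effect {effect} not on the grid")
        return float(row["power"].iloc[0])


def scenario_a(**overrides) -> PowerScenario:
    """Vary the two-way (XM) coefficient; three-way held at its fitted value."""
    return PowerScenario(scenario="A", effect_grid=DEFAULT_GRID_A, **overrides)


def scenario_b(**overrides) -> PowerScenario:
    """Vary the three-way (XMW) coefficient; two-way held at its fitted value."""
    return PowerScenario(scenario="B", effect_grid=DEFAULT_GRID_B, **overrides)


def _draw_predictors(rng: np.random.Generator, n: int, chol: np.ndarray) -> np.ndarray:
    z = rng.standard_normal((n, 3)) @ chol.T
    return interaction_design(z[:, 0], z[:, 1], z[:, 2])


def run_power(scenario: PowerScenario) -> PowerCurve:
    """Estimate power across the effect grid; deterministic given the seed."""
    scenario.validate()
    idx = scenario.tested_index
    base = np.asarray(scenario.fixed_coefficients, dtype=float).copy()
    base[idx] = 0.0
    grid = np.asarray(scenario.effect_grid, dtype=float)
    chol = np.linalg.cholesky(np.asarray(scenario.latent_correlations, dtype=float))
    n, reps, p = scenario.n, scenario.reps, 8
    df = n - p
    tcrit = stats.t.ppf(1.0 - scenario.alpha / 2, df)

    root = np.random.SeedSequence(scenario.seed)
    rep_seeds = root.spawn(reps + 1)
    fixed_design_matrix = None
    if scenario.predictor_mode == "fixed_design":
        fixed_design_matrix = _draw_predictors(
            np.random.default_rng(rep_seeds[-1]), n, chol
        )

    rejections = np.zeros(len(grid), dtype=int)
    eye = np.eye(p)
    for r in range(reps):
        rng = np.random.default_rng(rep_seeds[r])
        if fixed_design_matrix is None:
            design = _draw_predictors(rng, n, chol)
        else:
            design = fixed_design_matrix
        y0 = design @ base + rng.normal(0.0, scenario.noise_sd, size=n)
        q, rmat = np.linalg.qr(design)
        beta0 = solve_triangular(rmat, q.T @ y0)
        resid = y0 - design @ beta0
        sigma2 = float(resid @ resid) / df
        # (X'X)^-1 = R^-1 R^-T, so its (idx, idx) entry is ||R^-T e_idx||^2
        u = solve_triangular(rmat, eye[:, idx], trans="T")
        se = np.sqrt(sigma2 * float(u @ u))
        # adding e * design[:, idx] to y shifts only beta[idx] by e
        tvals = (beta0[idx] + grid) / se
        rejections += (np.abs(tvals) > tcrit).astype(int)

    power = rejections / reps
    results = pd.DataFrame(
        {
            "effect": grid,
            "power": power,
            "mc_se": np.sqrt(power * (1.0 - power) / reps),
            "reps": reps,
        }
    )
    term = "xm" if scenario.scenario == "A" else "xmw"
    return PowerCurve(scenario=scenario.scenario, tested_term=term, results=results)


def power_at(scenario: PowerScenario, effect_value: float) -> tuple[float, float]:
    """Power and Monte-Carlo SE at a single effect size.

    Identical to running the full grid and reading off the point, because
    replicate randomness is shared across grid points.
    """
    from dataclasses import replace

    single = replace(scenario, effect_grid=(float(effect_value),))
    curve = run_power(single)
    return float(curve.results["power"].iloc[0]), float(curve.results["mc_se"].iloc[0])
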