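"""Stage orchestration: simulate -> score -> screen -> fit -> slopes -> power.

Every stage is a pure function of (inputs, configuration, seed).  Artifacts
are written to an output directory in CSV/JSON, stamped with a hash of the
canonical configuration and the global seed; display rounding (3 decimals in
the text report) never touches the stored full-precision values.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
import yaml

from .cohort import GeneratorConfig, generate_cohort, read_cohort, write_cohort
from .errors import ConfigurationError, DependencyError
from .models import ModelFit, ModelSpec, fit_model
from .scales import all_item_columns, score_frame
from .screening import (
    apply_exclusions,
    harman_single_factor,
    pearson_matrix,
    screen_positive,
    screening_report,
)
from .slopes import interaction_plot_data, simple_slopes, slope_difference_tests, slope_table
from .power import run_power, scenario_a, scenario_b

__all__ = ["PipelineConfig", "run_pipeline", "STAGES"]

log = logging.getLogger("modmod")

STAGES = ("simulate", "score", "screen", "fit", "slopes", "power")


@dataclass
class PipelineConfig:
    """End-to-end run configuration."""

    stages: tuple[str, ...] = STAGES[:-1]  # power is opt-in: it is the slow stage
    outdir: str = "modmod_out"
    seed: int = 0
    generator: GeneratorConfig | None = None
    cohort_csv: str | None = None
    screen_threshold: float = 5.0
    ci_level: float = 0.95
    power_reps: int = 1000

    def validate(self) -> None:
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ConfigurationError(f"unknown stage(s): {sorted(unknown)}")
        order = [STAGES.index(s) for s in self.stages]
        if order != sorted(order):
            raise ConfigurationError("stages must respect pipeline order")
        if "simulate" in self.stages and self.generator is None:
            self.generator = GeneratorConfig(seed=self.seed)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        gen = raw.pop("generator", None)
        cfg = cls(**{k: tuple(v) if k == "stages" else v for k, v in raw.items()})
        if gen is not None:
            gen.setdefault("seed", cfg.seed)
            cfg.generator = GeneratorConfig.from_mapping(gen)
        cfg.validate()
        return cfg

    def to_mapping(self) -> dict:
        d = {
            "stages": list(self.stages),
            "outdir": self.outdir,
            "seed": self.seed,
            "cohort_csv": self.cohort_csv,
            "screen_threshold": self.screen_threshold,
            "ci_level": self.ci_level,
            "power_reps": self.power_reps,
        }
        if self.generator is not None:
            d["generator"] = self.generator.to_mapping()
        return d

    def digest(self) -> str:
        blob = json.dumps(self.to_mapping(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _stamp(config: PipelineConfig) -> dict:
    return {"config_hash": config.digest(), "seed": config.seed}


def _write_json(path: Path, payload: dict, config: PipelineConfig) -> None:
    payload = {**payload, "stamp": _stamp(config)}
    path.write_text(json.dumps(payload, indent=2, allow_nan=True))


def _fmt_table(frame: pd.DataFrame) -> str:
    return frame.round(3).to_string()


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the configured stages; returns a dict of produced artifact paths.

    Raises :class:`DependencyError` when a stage needs an artifact that no
    earlier stage produced and no input file supplies.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, Path] = {}
    report_lines: list[str] = [f"modmod run  config={config.digest()}  seed={config.seed}"]

    cohort = None
    scores = None
    screened = None
    fits: dict[int, ModelFit] = {}

    def timed(stage):
        start = time.perf_counter()
        log.info("stage %s started", stage)
        return lambda: log.info(
            "stage %s finished in %.2fs", stage, time.perf_counter() - start
        )

    if "simulate" in config.stages:
        done = timed("simulate")
        cohort = generate_cohort(config.generator)
        path = outdir / "cohort.csv"
        write_cohort(cohort, path)
        artifacts["cohort"] = path
        done()
    elif config.cohort_csv:
        cohort = read_cohort(config.cohort_csv)

    if "score" in config.stages:
        if cohort is None:
            raise DependencyError("score stage needs a cohort (simulate or cohort_csv)")
        done = timed("score")
        retained, _ = apply_exclusions(cohort)
        scores = score_frame(retained)
        path = outdir / "scores.csv"
        scores.to_csv(path, index=False)
        artifacts["scores"] = path
        done()

    if "screen" in config.stages:
        if cohort is None:
            raise DependencyError("screen stage needs a cohort")
        done = timed("screen")
        report, full_scores = screening_report(cohort, config.screen_threshold)
        scores = full_scores if scores is None else scores
        screened = screen_positive(scores, config.screen_threshold)
        retained, _ = apply_exclusions(cohort)
        harman_pct = harman_single_factor(
            retained[all_item_columns()].to_numpy(dtype=float)
        )
        corr = pearson_matrix(screened)
        payload = {
            "screening": report.to_dict(),
            "harman_first_factor_pct": harman_pct,
            "harman_flag_ok": bool(harman_pct < 40.0),
        }
        path = outdir / "screening.json"
        _write_json(path, payload, config)
        artifacts["screening"] = path
        table1 = corr.table()
        t1path = outdir / "descriptives.csv"
        table1.to_csv(t1path)
        artifacts["descriptives"] = t1path
        report_lines += [
            "",
            f"screening: raw={report.n_raw} excluded={report.n_excluded} "
            f"({report.exclusion_pct:.2f}%) retained={report.n_retained} "
            f"positive={report.n_positive} prevalence={report.prevalence_pct:.2f}%",
            f"Harman first-factor variance: {harman_pct:.2f}%",
            "",
            "descriptives and correlations (screened sample):",
            _fmt_table(table1),
        ]
        done()

    if "fit" in config.stages:
        if screened is None:
            if scores is None:
                raise DependencyError("fit stage needs scores (run score/screen first)")
            screened = screen_positive(scores, config.screen_threshold)
        done = timed("fit")
        for model_id in (1, 3):
            spec = ModelSpec(model_id=model_id, ci_level=config.ci_level)
            fit = fit_model(screened, spec)
            fits[model_id] = fit
            payload = fit.to_dict()
            path = outdir / f"model{model_id}.json"
            _write_json(path, payload, config)
            artifacts[f"model{model_id}"] = path
            report_lines += [
                "",
                f"Model {model_id} (n={fit.n}, R2={fit.r_squared:.3f}, "
                f"F={fit.f_stat:.3f}):",
                _fmt_table(fit.summary_frame()),
            ]
        done()

    if "slopes" in config.stages:
        if 3 not in fits:
            raise DependencyError("slopes stage needs the Model-3 fit")
        done = timed("slopes")
        fit = fits[3]
        slope_set = simple_slopes(fit)
        diffs = slope_difference_tests(fit, ci_level=config.ci_level)
        table = slope_table(diffs)
        path = outdir / "slope_differences.csv"
        table.to_csv(path, index=False)
        artifacts["slope_differences"] = path
        plot = interaction_plot_data(fit)
        ppath = outdir / "interaction_plot.csv"
        plot.to_csv(ppath, index=False)
        artifacts["interaction_plot"] = ppath
        report_lines += [
            "",
            "simple slopes:",
            _fmt_table(slope_set.as_frame()),
            "",
            "slope differences:",
            _fmt_table(table),
        ]
        done()

    if "power" in config.stages:
        done = timed("power")
        for name, factory in (("A", scenario_a), ("B", scenario_b)):
            scn = factory(seed=config.seed, reps=config.power_reps)
            curve = run_power(scn)
            path = outdir / f"power_{name.lower()}.csv"
            curve.results.to_csv(path, index=False)
            artifacts[f"power_{name.lower()}"] = path
            report_lines += [
                "",
                f"power scenario {name} (tested term {curve.tested_term}):",
                _fmt_table(curve.results),
            ]
        done()

    report_path = outdir / "report.txt"
    report_path.write_text("\n".join(report_lines) + "\n")
    artifacts["report"] = report_path
    return {k: str(v) for k, v in artifacts.items()}
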