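"""End-to-end orchestration: load or simulate, validate, recalibrate, report.

``run_pipeline`` sequences the analysis stages deterministically for a given
seed and writes a reproducible bundle (report.json, table2.csv, nomogram.csv,
model.json, run.log) to the output directory.  All arithmetic lives in the
library modules; this layer only wires them together and logs warnings.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

from . import simulate
from .calibration import quartile_audit
from .cohort import Cohort, read_cohort
from .nomogram import build_nomogram
from .recalibration import ScoreRecalibration, fit_correction
from .report import full_report

__all__ = ["RunConfig", "run_pipeline", "PipelineError"]

logger = logging.getLogger("esrecal")


class PipelineError(RuntimeError):
    """A stage failure; the message carries the stage label."""


@dataclass
class RunConfig:
    """Configuration of one pipeline run.

    Exactly one input source per group: a CSV path, or (when both paths are
    None) seeded synthetic cohorts with the default study-like parameters.
    """

    oncab_path: str | None = None
    opcab_path: str | None = None
    seed: int | None = None
    hl_groups: int = 10
    df_convention: str = "validation"
    quartile_boundaries: tuple[float, ...] | None = None
    fit_method: str = "per_patient"
    constrain_oe: bool = False
    fit_group: str = "ONCAB"
    nomogram_max: float = 85.0
    nomogram_step: float = 0.5
    out_dir: str = "esrecal-run"

    def __post_init__(self) -> None:
        if (self.oncab_path is None) != (self.opcab_path is None):
            raise ValueError("provide CSV paths for both groups or neither")
        if self.oncab_path is None and self.seed is None:
            raise ValueError("synthetic input requires a seed")

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        text = Path(path).read_text()
        if str(path).endswith((".yaml", ".yml")):
            import yaml

            data = yaml.safe_load(text)
        else:
            data = json.loads(text)
        if "quartile_boundaries" in data and data["quartile_boundaries"] is not None:
            data["quartile_boundaries"] = tuple(data["quartile_boundaries"])
        return cls(**data)


def _load_inputs(config: RunConfig) -> tuple[Cohort, Cohort]:
    if config.oncab_path is not None:
        return (
            read_cohort(config.oncab_path, label="ONCAB"),
            read_cohort(config.opcab_path, label="OPCAB"),
        )
    return simulate.paper_like_pair(config.seed)


def run_pipeline(config: RunConfig) -> dict[str, Path]:
    """Run every stage and write the output bundle; returns the file map.

    Stages: load/generate cohorts -> per-group discrimination + calibration
    -> fit the correction on the miscalibrated group -> validate it ->
    nomogram + consolidated report.  Any stage error aborts with a
    stage-labelled message and removes partial outputs.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    files = {
        "report": out / "report.json",
        "table2": out / "table2.csv",
        "nomogram": out / "nomogram.csv",
        "model": out / "model.json",
        "log": out / "run.log",
    }
    handler = logging.FileHandler(files["log"], mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    stage = "load"
    try:
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")

            oncab, opcab = _load_inputs(config)
            logger.info("loaded cohorts: %d ONCAB, %d OPCAB", len(oncab), len(opcab))

            stage = "fit"
            fit_on = oncab if config.fit_group == "ONCAB" else opcab
            results = ScoreRecalibration.from_cohort(fit_on).fit(
                method=config.fit_method, constrain_oe=config.constrain_oe
            )
            model = results.correction
            model.to_json(files["model"], n_fit=len(fit_on))
            logger.info("fitted correction a=%.4f b=%.5f", model.a, model.b)

            stage = "report"
            report = full_report(
                oncab,
                opcab,
                model=model,
                n_groups=config.hl_groups,
                df_convention=config.df_convention,
                quartile_boundaries=config.quartile_boundaries,
            )
            report.to_json(files["report"])

            stage = "tables"
            quartile_audit(
                fit_on, boundaries=config.quartile_boundaries
            ).to_csv(files["table2"])
            grid_max = config.nomogram_max
            if model.b < 0:  # parabola turns over at -a/(2b)
                limit = -model.a / (2.0 * model.b)
                if limit <= grid_max:
                    grid_max = max(
                        config.nomogram_step,
                        (limit - config.nomogram_step)
                        // config.nomogram_step * config.nomogram_step,
                    )
                    logger.warning(
                        "nomogram grid capped at %.2f%% (monotone span of the fit)",
                        grid_max,
                    )
            build_nomogram(model, 0.0, grid_max, config.nomogram_step).to_csv(
                files["nomogram"]
            )

            for w in caught:
                logger.warning("%s", w.message)
    except Exception as exc:
        for f in files.values():
            if f != files["log"] and f.exists():
                f.unlink()
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc
    finally:
        logger.removeHandler(handler)
        handler.close()
    return files


def config_as_dict(config: RunConfig) -> dict:
    d = dataclasses.asdict(config)
    if d.get("quartile_boundaries") is not None:
        d["quartile_boundaries"] = list(d["quartile_boundaries"])
    return d
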