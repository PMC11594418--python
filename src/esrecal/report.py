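"""Consolidated two-group analysis report.

Bundles, for the on-pump and off-pump cohorts and their pool: summaries,
ROC discrimination, calibration audits, quartile tables, and — when a
correction model is supplied — the post-correction calibration of the
miscalibrated group.  Pooled observed mortality is pooled deaths over pooled
n; pooled predicted mortality is the size-weighted mean of the group means.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

from .calibration import QuartileTable, calibration_report, oe_ratio, quartile_audit
from .cohort import Cohort, merge, summarize
from .discrimination import compute_auc
from .recalibration import CorrectionModel, validate_correction

__all__ = ["AnalysisReport", "full_report"]


@dataclass
class AnalysisReport:
    """All numbers of one end-to-end validation run, JSON-serialisable."""

    pooled: dict
    oncab: dict
    opcab: dict
    correction: dict | None = None

    def as_dict(self) -> dict:
        d = {"pooled": self.pooled, "oncab": self.oncab, "opcab": self.opcab}
        if self.correction is not None:
            d["correction"] = self.correction
        return d

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.as_dict(), indent=2, sort_keys=True) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "AnalysisReport":
        d = json.loads(Path(path).read_text())
        return cls(
            pooled=d["pooled"],
            oncab=d["oncab"],
            opcab=d["opcab"],
            correction=d.get("correction"),
        )


def _group_section(cohort: Cohort, n_groups: int, df_convention: str,
                   quartile_boundaries=None) -> dict:
    s = summarize(cohort)
    cal = calibration_report(cohort, n_groups=n_groups, df_convention=df_convention)
    disc = compute_auc(cohort)
    quart: QuartileTable = quartile_audit(cohort, boundaries=quartile_boundaries)
    return {
        "summary": s.as_dict(),
        "discrimination": disc.as_dict(),
        "calibration": cal.as_dict(),
        "quartiles": [vars(r) for r in quart.rows],
    }


def full_report(
    oncab: Cohort,
    opcab: Cohort,
    model: CorrectionModel | None = None,
    n_groups: int = 10,
    df_convention: str = "validation",
    quartile_boundaries: tuple[float, ...] | None = None,
) -> AnalysisReport:
    """Pooled and per-group validation report, optionally with a correction.

    When ``model`` is given, its post-correction calibration is evaluated on
    the on-pump cohort (the miscalibrated group in the motivating study).
    """
    s_on = summarize(oncab)
    s_off = summarize(opcab)
    n = s_on.n + s_off.n
    deaths = s_on.deaths + s_off.deaths
    pooled_observed = 100.0 * deaths / n
    pooled_predicted = (s_on.n * s_on.mean_es2_pct + s_off.n * s_off.mean_es2_pct) / n
    pooled = {
        "n": n,
        "deaths": deaths,
        "observed_pct": pooled_observed,
        "predicted_pct": pooled_predicted,
        "oe_ratio": oe_ratio(pooled_observed, pooled_predicted),
        "expected_deaths": n * pooled_predicted / 100.0,
    }
    pooled_cohort = merge(oncab, opcab, label="pooled")
    pooled["discrimination"] = compute_auc(pooled_cohort).as_dict()
    pooled["quartiles"] = [
        vars(r) for r in quartile_audit(pooled_cohort, boundaries=quartile_boundaries).rows
    ]

    report = AnalysisReport(
        pooled=pooled,
        oncab=_group_section(oncab, n_groups, df_convention, quartile_boundaries),
        opcab=_group_section(opcab, n_groups, df_convention, quartile_boundaries),
    )
    if model is not None:
        corrected = validate_correction(
            oncab, model, n_groups=n_groups, df_convention=df_convention
        )
        report.correction = {
            "model": model.as_dict(),
            "oncab_corrected_calibration": corrected.as_dict(),
        }
    return report
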