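"""Calibration assessment: O/E ratios, Hosmer-Lemeshow test, quartile audit.

All predicted mortalities are percentages.  The observed-to-expected ratio
(O/E) is observed mortality divided by mean predicted mortality: 1.0 means
perfect calibration-in-the-large, values above 1 mean the score underpredicts
death.  The Hosmer-Lemeshow statistic compares observed and expected deaths
across risk-ordered patient groups using both the death and survival cells,

    H = sum_g (O_g - E_g)^2 / (E_g (1 - E_g / n_g)),

referred to an upper chi-square tail with df = g (external validation of a
fixed model, the default) or g - 2 (model developed on the same data).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import Cohort

__all__ = [
    "BinRow",
    "CalibrationReport",
    "QuartileTable",
    "oe_ratio",
    "expected_deaths",
    "hosmer_lemeshow",
    "HosmerLemeshowResult",
    "calibration_report",
    "quartile_audit",
]


def oe_ratio(observed_pct: float, predicted_pct: float) -> float:
    """Observed/expected mortality ratio at full precision."""
    if predicted_pct <= 0:
        raise ValueError("predicted mortality must be positive")
    return float(observed_pct) / float(predicted_pct)


def expected_deaths(cohort: Cohort, predicted: np.ndarray | None = None) -> float:
    """Expected death count: sum of per-patient predicted mortality / 100."""
    p = np.asarray(cohort.scores if predicted is None else predicted, dtype=float)
    if len(p) != len(cohort):
        raise ValueError("predicted vector must align with cohort records")
    if np.any(p <= 0) or np.any(p > 100):
        raise ValueError("predicted mortality must lie in (0, 100]")
    return float(p.sum() / 100.0)


@dataclass(frozen=True)
class BinRow:
    """One risk group of the Hosmer-Lemeshow partition or quartile audit."""

    low: float
    high: float
    n: int
    observed_deaths: int
    expected_deaths: float


@dataclass(frozen=True)
class HosmerLemeshowResult:
    statistic: float
    df: int
    p_value: float
    bins: tuple[BinRow, ...] = field(default=())

    def __iter__(self):
        return iter((self.statistic, self.df, self.p_value))


def _risk_groups(predicted: np.ndarray, n_groups: int) -> np.ndarray:
    """Group codes from risk-ordered near-equal splits, ties kept together."""
    codes = pd.qcut(predicted, n_groups, labels=False, duplicates="drop")
    codes = np.asarray(codes, dtype=int)
    if codes.max() + 1 < n_groups:
        warnings.warn(
            f"ties reduced the risk grouping from {n_groups} to {codes.max() + 1} groups",
            stacklevel=3,
        )
    return codes


def hosmer_lemeshow(
    cohort: Cohort,
    predicted: np.ndarray | None = None,
    n_groups: int = 10,
    df_convention: str = "validation",
) -> HosmerLemeshowResult:
    """Hosmer-Lemeshow goodness-of-fit test on deciles of predicted risk.

    Patients are sorted by predicted mortality and split into ``n_groups``
    near-equal groups (ties kept together).  Groups whose expected deaths are
    exactly 0 or n_g have an undefined contribution and are merged with a
    neighbour with a warning.
    """
    if n_groups < 2:
        raise ValueError("need at least 2 risk groups")
    if len(cohort) < n_groups:
        raise ValueError("cohort smaller than the number of risk groups")
    if df_convention not in ("validation", "development"):
        raise ValueError(f"unknown df convention {df_convention!r}")
    p = np.asarray(cohort.scores if predicted is None else predicted, dtype=float)
    if np.any(p <= 0) or np.any(p >= 100):
        raise ValueError("predicted mortality must lie strictly inside (0, 100)")
    died = cohort.died

    codes = _risk_groups(p, n_groups)
    order = np.unique(codes)
    rows = []
    for g in order:
        mask = codes == g
        rows.append(
            [float(p[mask].min()), float(p[mask].max()), int(mask.sum()),
             int(died[mask].sum()), float(p[mask].sum() / 100.0)]
        )

    # merge groups with degenerate expected counts into their neighbour
    merged = []
    for row in rows:
        if merged and (merged[-1][4] <= 0.0 or merged[-1][4] >= merged[-1][2]):
            prev = merged.pop()
            warnings.warn("merged a risk group with degenerate expected deaths", stacklevel=2)
            row = [min(prev[0], row[0]), max(prev[1], row[1]),
                   prev[2] + row[2], prev[3] + row[3], prev[4] + row[4]]
        merged.append(row)
    if len(merged) > 1 and (merged[-1][4] <= 0.0 or merged[-1][4] >= merged[-1][2]):
        last = merged.pop()
        prev = merged.pop()
        warnings.warn("merged a risk group with degenerate expected deaths", stacklevel=2)
        merged.append([min(prev[0], last[0]), max(prev[1], last[1]),
                       prev[2] + last[2], prev[3] + last[3], prev[4] + last[4]])

    stat = 0.0
    bins = []
    for low, high, n_g, obs, exp in merged:
        stat += (obs - exp) ** 2 / (exp * (1.0 - exp / n_g))
        bins.append(BinRow(low, high, n_g, obs, exp))
    g = len(merged)
    df = g if df_convention == "validation" else max(g - 2, 1)
    return HosmerLemeshowResult(
        statistic=float(stat),
        df=df,
        p_value=float(stats.chi2.sf(stat, df)),
        bins=tuple(bins),
    )


@dataclass(frozen=True)
class CalibrationReport:
    """Cohort-level calibration audit of one predicted-mortality vector."""

    observed_pct: float
    predicted_pct: float
    oe_ratio: float
    expected_deaths: float
    observed_deaths: int
    n: int
    hl_statistic: float
    hl_df: int
    hl_p: float
    bins: tuple[BinRow, ...]
    auc_invariant: bool | None = None

    def as_dict(self) -> dict:
        d = {
            "n": self.n,
            "observed_pct": self.observed_pct,
            "predicted_pct": self.predicted_pct,
            "oe_ratio": self.oe_ratio,
            "observed_deaths": self.observed_deaths,
            "expected_deaths": self.expected_deaths,
            "hl_statistic": self.hl_statistic,
            "hl_df": self.hl_df,
            "hl_p": self.hl_p,
            "bins": [vars(b) for b in self.bins],
        }
        if self.auc_invariant is not None:
            d["auc_invariant"] = self.auc_invariant
        return d


def calibration_report(
    cohort: Cohort,
    predicted: np.ndarray | None = None,
    n_groups: int = 10,
    df_convention: str = "validation",
) -> CalibrationReport:
    """Full calibration audit: O/E, expected deaths, Hosmer-Lemeshow."""
    p = np.asarray(cohort.scores if predicted is None else predicted, dtype=float)
    n = len(cohort)
    observed_deaths = int(cohort.died.sum())
    observed_pct = 100.0 * observed_deaths / n
    predicted_pct = float(p.mean())
    hl = hosmer_lemeshow(cohort, p, n_groups=n_groups, df_convention=df_convention)
    return CalibrationReport(
        observed_pct=observed_pct,
        predicted_pct=predicted_pct,
        oe_ratio=oe_ratio(observed_pct, predicted_pct),
        expected_deaths=expected_deaths(cohort, p),
        observed_deaths=observed_deaths,
        n=n,
        hl_statistic=hl.statistic,
        hl_df=hl.df,
        hl_p=hl.p_value,
        bins=hl.bins,
    )


@dataclass(frozen=True)
class QuartileRow:
    low: float
    high: float
    n: int
    observed_pct: float
    predicted_pct: float
    oe_ratio: float
    observed_deaths: int
    expected_deaths: float


@dataclass(frozen=True)
class QuartileTable:
    """Per-quartile observed vs predicted mortality audit."""

    rows: tuple[QuartileRow, ...]

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame([vars(r) for r in self.rows])
        df.insert(0, "interval", [f"{r.low:.2f}-{r.high:.2f}%" for r in self.rows])
        return df

    def to_csv(self, path) -> None:
        df = self.to_dataframe()
        for col in ("observed_pct", "predicted_pct", "oe_ratio", "expected_deaths"):
            df[col] = df[col].round(2)
        df.to_csv(path, index=False)


def quartile_audit(
    cohort: Cohort,
    predicted: np.ndarray | None = None,
    boundaries: tuple[float, ...] | None = None,
) -> QuartileTable:
    """Audit calibration across quartiles of the predicted-score range.

    With ``boundaries`` omitted, cut points are the empirical quartiles of the
    predicted scores, assigned half-open on the left with the last interval
    closed.  ``boundaries`` may supply fixed interior cut points, e.g.
    ``(0.88, 1.92, 3.05, 5.14)`` for intervals [0.88,1.92), [1.92,3.05),
    [3.05,5.14), [5.14,max]; every patient must be assigned.
    """
    if len(cohort) < 4:
        raise ValueError("quartile audit needs at least 4 patients")
    p = np.asarray(cohort.scores if predicted is None else predicted, dtype=float)
    died = cohort.died

    if boundaries is None:
        qs = np.quantile(p, [0.0, 0.25, 0.5, 0.75])
        edges = np.unique(qs)
        if len(edges) < 4:
            warnings.warn(
                "tied scores collapsed the quartile cut points; "
                f"returning {len(edges)} effective bins",
                stacklevel=2,
            )
    else:
        edges = np.asarray(boundaries, dtype=float)
        if np.any(np.diff(edges) <= 0):
            raise ValueError("boundaries must be strictly increasing")
        if p.min() < edges[0]:
            raise ValueError(
                f"scores below the first boundary ({p.min():.4g} < {edges[0]:.4g})"
            )

    cut = np.concatenate([edges, [np.inf]])
    rows = []
    for i in range(len(edges)):
        mask = (p >= cut[i]) & (p < cut[i + 1])
        n_q = int(mask.sum())
        if n_q == 0:
            continue
        obs = int(died[mask].sum())
        obs_pct = 100.0 * obs / n_q
        pred_pct = float(p[mask].mean())
        rows.append(
            QuartileRow(
                low=float(cut[i]),
                high=float(p[mask].max()) if i == len(edges) - 1 else float(cut[i + 1]),
                n=n_q,
                observed_pct=obs_pct,
                predicted_pct=pred_pct,
                oe_ratio=obs_pct / pred_pct,
                observed_deaths=obs,
                expected_deaths=float(p[mask].sum() / 100.0),
            )
        )
    table = QuartileTable(rows=tuple(rows))
    assert sum(r.n for r in rows) == len(cohort), "quartile rows must partition the cohort"
    return table
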