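"""Least-squares recalibration of a mortality score.

The correction keeps the original score as the only input and rescales it
inside the multiplicative-quadratic family

    mod(x) = x * (a + b * x),        x in percent,

which fixes mod(0) = 0 structurally (a risk score of zero stays zero) and is
linear in the coefficients (a, b), so every fit below is closed-form least
squares.  Three estimators are provided:

``per_patient``
    OLS of 100 * died on the regressors (x, x^2) with no intercept — the
    simplest estimator that is consistent for the calibration curve within
    the family.
``binned``
    Patients are grouped into risk bins (deciles of the score by default);
    weighted least squares of the bin observed mortality % on the bin means
    of (x, x^2), weights proportional to bin size.
``constrain_oe``
    Either objective minimised subject to the single linear constraint
    sum_i mod(x_i) = 100 * sum_i died_i, i.e. exact cohort observed-to-
    expected ratio of 1.0, solved by a Lagrange step (still closed-form).

Usage follows the Model/Results convention::

    model = ScoreRecalibration.from_cohort(cohort)
    res = model.fit(method="per_patient", constrain_oe=True)
    res.summary()
    corrected = res.predict(cohort.scores)
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .cohort import Cohort

__all__ = [
    "CorrectionModel",
    "ScoreRecalibration",
    "RecalibrationResults",
    "apply_correction",
    "fit_correction",
    "validate_correction",
]


@dataclass(frozen=True)
class CorrectionModel:
    """Coefficients of the multiplicative correction mod(x) = x(a + bx).

    ``a`` is dimensionless, ``b`` has units of 1/percent.  ``valid_range`` is
    the score interval (percent) over which monotonicity was verified at fit
    time; the correction is strictly increasing there iff a + 2bx > 0.
    """

    a: float
    b: float
    fit_method: str = "external"
    valid_range: tuple[float, float] = (0.0, 100.0)

    def apply(self, x: np.ndarray | float) -> np.ndarray | float:
        """Corrected score x(a + bx), clamped into [0, 100] with a warning."""
        arr = np.asarray(x, dtype=float)
        if np.any(arr < 0) or np.any(arr > 100):
            raise ValueError("scores must lie in [0, 100]")
        out = arr * (self.a + self.b * arr)
        clipped = (out < 0.0) | (out > 100.0)
        if np.any(clipped):
            warnings.warn(
                f"clamped {int(np.sum(clipped))} corrected scores into [0, 100]",
                stacklevel=2,
            )
            out = np.clip(out, 0.0, 100.0)
        return float(out) if np.isscalar(x) else out

    def is_monotone(self, lo: float, hi: float) -> bool:
        """Strictly increasing on [lo, hi]?  d/dx = a + 2bx is linear."""
        return (self.a + 2.0 * self.b * lo > 0.0) and (self.a + 2.0 * self.b * hi > 0.0)

    def as_dict(self) -> dict:
        return {
            "a": self.a,
            "b": self.b,
            "fit_method": self.fit_method,
            "valid_range": list(self.valid_range),
        }

    def to_json(self, path: str | Path, **extra) -> None:
        payload = {**self.as_dict(), **extra}
        Path(path).write_text(json.dumps(payload, indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "CorrectionModel":
        d = json.loads(Path(path).read_text())
        return cls(
            a=float(d["a"]),
            b=float(d["b"]),
            fit_method=d.get("fit_method", "external"),
            valid_range=tuple(d.get("valid_range", (0.0, 100.0))),
        )


class ScoreRecalibration:
    """Least-squares model for the quadratic score correction.

    Parameters
    ----------
    scores : per-patient original scores, percent in (0, 100].
    died : aligned 0/1 in-hospital death indicators.
    """

    def __init__(self, scores: np.ndarray, died: np.ndarray, label: str = "") -> None:
        scores = np.asarray(scores, dtype=float)
        died = np.asarray(died, dtype=int)
        if scores.shape != died.shape or scores.ndim != 1:
            raise ValueError("scores and died must be aligned 1-d arrays")
        if len(scores) < 2 or len(np.unique(scores)) < 2:
            raise ValueError("need at least 2 distinct score values")
        self.scores = scores
        self.died = died
        self.label = label

    @classmethod
    def from_cohort(cls, cohort: Cohort) -> "ScoreRecalibration":
        return cls(cohort.scores, cohort.died, label=cohort.label)

    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, score_col: str = "euroscore2", outcome_col: str = "died"
    ) -> "ScoreRecalibration":
        return cls(df[score_col].to_numpy(float), df[outcome_col].to_numpy(int))

    # ------------------------------------------------------------------
    def _design(self, method: str, n_bins: int):
        """(response, design, weights) for the chosen objective."""
        x = self.scores
        if method == "per_patient":
            y = 100.0 * self.died.astype(float)
            X = np.column_stack([x, x**2])
            w = np.ones_like(y)
        elif method == "binned":
            codes = pd.qcut(x, n_bins, labels=False, duplicates="drop")
            grp = pd.DataFrame({"x": x, "x2": x**2, "d": self.died, "g": codes}).groupby("g")
            agg = grp.agg(x=("x", "mean"), x2=("x2", "mean"), d=("d", "mean"), n=("d", "size"))
            y = 100.0 * agg["d"].to_numpy()
            X = np.column_stack([agg["x"].to_numpy(), agg["x2"].to_numpy()])
            w = agg["n"].to_numpy(float)
        else:
            raise ValueError(f"unknown fit method {method!r}")
        return y, X, w

    def fit(
        self,
        method: str = "per_patient",
        constrain_oe: bool = False,
        n_bins: int = 10,
    ) -> "RecalibrationResults":
        """Estimate (a, b); optionally force exact cohort O/E = 1."""
        if self.died.sum() == 0:
            warnings.warn(
                "cohort has no deaths: degenerate all-zero correction returned",
                stacklevel=2,
            )
        y, X, w = self._design(method, n_bins)
        base = sm.WLS(y, X, weights=w).fit()
        params = base.params.copy()
        cov = np.asarray(base.cov_params())

        if constrain_oe:
            # one linear constraint  c' beta = d  with  c = (sum x, sum x^2),
            # d = 100 * total deaths: Lagrange step off the unconstrained fit
            c = np.array([self.scores.sum(), (self.scores**2).sum()])
            d = 100.0 * float(self.died.sum())
            Xw = X * np.sqrt(w)[:, None]
            Q = np.linalg.inv(Xw.T @ Xw)
            gain = (Q @ c) / float(c @ Q @ c)
            params = params + gain * (d - float(c @ params))
            # restricted-LS covariance: A Var(beta) A' with A = I - gain c'
            A = np.eye(2) - np.outer(gain, c)
            cov = A @ cov @ A.T

        resid = (y - X @ params) * np.sqrt(w)
        ssr = float(resid @ resid)
        lo, hi = float(self.scores.min()), float(self.scores.max())
        fit_method = "constrained" if constrain_oe else method
        corr = CorrectionModel(
            a=float(params[0]), b=float(params[1]),
            fit_method=fit_method, valid_range=(lo, hi),
        )
        if not corr.is_monotone(lo, hi):
            warnings.warn(
                f"fitted correction is not monotone on [{lo:.3g}, {hi:.3g}]",
                stacklevel=2,
            )
        return RecalibrationResults(
            model=self, params=np.asarray(params, float), cov_params=cov,
            method=method, constrained=constrain_oe, ssr=ssr,
            nobs=len(self.scores), correction=corr,
        )


class RecalibrationResults:
    """Estimates, uncertainties and diagnostics of one recalibration fit."""

    def __init__(self, model, params, cov_params, method, constrained, ssr, nobs, correction):
        self.model = model
        self.params = params
        self.cov_params = cov_params
        self.method = method
        self.constrained = constrained
        self.ssr = ssr
        self.nobs = nobs
        self.correction = correction

    @property
    def bse(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov_params))

    def conf_int(self, alpha: float = 0.05) -> np.ndarray:
        from scipy import stats

        z = stats.norm.ppf(1.0 - alpha / 2.0)
        return np.column_stack([self.params - z * self.bse, self.params + z * self.bse])

    def predict(self, x: np.ndarray | float) -> np.ndarray | float:
        return self.correction.apply(x)

    def validate(self, cohort: Cohort, **kwargs):
        return validate_correction(cohort, self.correction, **kwargs)

    def summary(self) -> str:
        ci = self.conf_int()
        lines = [
            "Quadratic score recalibration  mod(x) = x*(a + b*x)",
            "=" * 56,
            f"method: {self.method}"
            + ("  (constrained to cohort O/E = 1)" if self.constrained else ""),
            f"n obs: {self.nobs}    SSR: {self.ssr:.4g}",
            f"valid score range: [{self.correction.valid_range[0]:.3f}, "
            f"{self.correction.valid_range[1]:.3f}] %",
            "-" * 56,
            f"{'coef':>6} {'estimate':>12} {'std err':>10} {'[0.025':>10} {'0.975]':>10}",
            f"{'a':>6} {self.params[0]:>12.4f} {self.bse[0]:>10.4f} {ci[0,0]:>10.4f} {ci[0,1]:>10.4f}",
            f"{'b':>6} {self.params[1]:>12.5f} {self.bse[1]:>10.5f} {ci[1,0]:>10.5f} {ci[1,1]:>10.5f}",
            "=" * 56,
        ]
        return "\n".join(lines)


# -- functional surface ----------------------------------------------------

def apply_correction(model: CorrectionModel, x) -> np.ndarray | float:
    """Corrected score mod(x) = x(a + bx); see :meth:`CorrectionModel.apply`."""
    return model.apply(x)


def fit_correction(
    cohort: Cohort,
    method: str = "per_patient",
    constrain_oe: bool = False,
    n_bins: int = 10,
) -> CorrectionModel:
    """Fit the quadratic correction on a cohort and return its coefficients."""
    return ScoreRecalibration.from_cohort(cohort).fit(
        method=method, constrain_oe=constrain_oe, n_bins=n_bins
    ).correction


def validate_correction(
    cohort: Cohort,
    model: CorrectionModel,
    n_groups: int = 10,
    df_convention: str = "validation",
):
    """Calibration audit of the corrected scores, plus AUC invariance.

    Returns a :class:`~esrecal.calibration.CalibrationReport` computed on
    ``model.apply(scores)``, with ``auc_invariant`` recording whether the
    correction left discrimination unchanged (it must, when monotone).
    """
    from dataclasses import replace

    from .calibration import calibration_report
    from .discrimination import auc_invariance_check

    corrected = np.asarray(model.apply(cohort.scores), dtype=float)
    # predictions of exactly 0% or 100% make the grouped chi-square cells
    # degenerate; nudge them off the bounds for the audit
    eps = 1e-3
    at_bounds = (corrected < eps) | (corrected > 100.0 - eps)
    if at_bounds.any():
        warnings.warn(
            f"{int(at_bounds.sum())} corrected predictions at the 0/100% bounds "
            "were nudged inside (0, 100) for the calibration audit",
            stacklevel=2,
        )
        corrected = np.clip(corrected, eps, 100.0 - eps)
    report = calibration_report(
        cohort, corrected, n_groups=n_groups, df_convention=df_convention
    )
    try:
        invariant = auc_invariance_check(cohort, model)
    except ValueError as exc:
        warnings.warn(f"AUC-invariance check aborted: {exc}", stacklevel=2)
        invariant = None
    return replace(report, auc_invariant=invariant)
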