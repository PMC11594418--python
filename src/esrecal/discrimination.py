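"""ROC discrimination: AUC with DeLong or bootstrap confidence intervals.

The AUC is computed with the midrank (Mann-Whitney) convention, identical to
trapezoidal integration of the empirical ROC curve with ties counted one half.
The default confidence interval and the test against AUC = 0.5 use DeLong's
asymptotically exact covariance estimator for the placement values; a seeded
stratified nonparametric bootstrap is available as an alternative.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = ["DiscriminationReport", "compute_auc", "auc_invariance_check", "roc_points"]


@dataclass(frozen=True)
class DiscriminationReport:
    """AUC, its 95% CI, and a two-sided test against no discrimination."""

    auc: float
    ci_low: float
    ci_high: float
    p_value: float
    n_pos: int
    n_neg: int
    method: str

    def __post_init__(self) -> None:
        assert 0.0 <= self.ci_low <= self.auc <= self.ci_high <= 1.0
        assert self.n_pos >= 1 and self.n_neg >= 1

    def as_dict(self) -> dict:
        return {
            "auc": self.auc,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "p_value": self.p_value,
            "n_pos": self.n_pos,
            "n_neg": self.n_neg,
            "method": self.method,
        }


def _auc_and_delong_variance(scores: np.ndarray, died: np.ndarray) -> tuple[float, float]:
    """Midrank AUC and DeLong variance from placement values."""
    pos = scores[died == 1]
    neg = scores[died == 0]
    m, n = len(pos), len(neg)
    ranks_all = stats.rankdata(np.concatenate([pos, neg]))
    ranks_pos = stats.rankdata(pos)
    ranks_neg = stats.rankdata(neg)
    auc = (ranks_all[:m].sum() - m * (m + 1) / 2.0) / (m * n)
    # placement values: v10_i = P(score_i > random survivor), v01_j symmetric
    v10 = (ranks_all[:m] - ranks_pos) / n
    v01 = 1.0 - (ranks_all[m:] - ranks_neg) / m
    s10 = v10.var(ddof=1) if m > 1 else 0.0
    s01 = v01.var(ddof=1) if n > 1 else 0.0
    return float(auc), float(s10 / m + s01 / n)


def compute_auc(
    cohort,
    scores: np.ndarray | None = None,
    method: str = "delong",
    alpha: float = 0.05,
    n_boot: int = 2000,
    seed: int | None = None,
) -> DiscriminationReport:
    """AUC of a score against in-hospital death, with CI and p-value.

    Parameters
    ----------
    cohort : Cohort providing the 0/1 death indicators.
    scores : optional score vector aligned to the records; defaults to the
        cohort's EuroSCORE II values.
    method : ``delong`` (deterministic, default) or ``bootstrap``
        (stratified percentile bootstrap; requires ``seed``).
    """
    died = np.asarray(cohort.died)
    x = np.asarray(cohort.scores if scores is None else scores, dtype=float)
    if len(x) != len(died):
        raise ValueError("scores must align with cohort records")
    n_pos = int(died.sum())
    n_neg = int(len(died) - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC undefined: need at least one death and one survivor")

    auc, var = _auc_and_delong_variance(x, died)
    se = np.sqrt(var)
    if se > 0:
        z = (auc - 0.5) / se
        p = float(2.0 * stats.norm.sf(abs(z)))
    else:
        p = 1.0 if auc == 0.5 else 0.0

    if method == "delong":
        zcrit = stats.norm.ppf(1.0 - alpha / 2.0)
        lo = float(np.clip(auc - zcrit * se, 0.0, auc))
        hi = float(np.clip(auc + zcrit * se, auc, 1.0))
    elif method == "bootstrap":
        if seed is None:
            raise ValueError("bootstrap CI requires a seed")
        rng = np.random.default_rng(seed)
        pos_idx = np.flatnonzero(died == 1)
        neg_idx = np.flatnonzero(died == 0)
        boots = np.empty(n_boot)
        for i in range(n_boot):
            bp = rng.choice(pos_idx, size=n_pos, replace=True)
            bn = rng.choice(neg_idx, size=n_neg, replace=True)
            idx = np.concatenate([bp, bn])
            boots[i], _ = _auc_and_delong_variance(x[idx], died[idx])
        lo = float(np.clip(np.quantile(boots, alpha / 2.0), 0.0, auc))
        hi = float(np.clip(np.quantile(boots, 1.0 - alpha / 2.0), auc, 1.0))
    else:
        raise ValueError(f"unknown CI method {method!r}")

    return DiscriminationReport(
        auc=auc, ci_low=lo, ci_high=hi, p_value=p,
        n_pos=n_pos, n_neg=n_neg, method=method,
    )


def auc_invariance_check(cohort, correction, tol: float = 1e-12) -> bool:
    """True iff correcting the scores leaves the AUC unchanged (within tol).

    A strictly increasing correction cannot reorder patients, so adjustment
    changes calibration but not discrimination.  The correction must be
    monotone over the cohort's score range; otherwise the check aborts.
    """
    x = cohort.scores
    lo, hi = float(x.min()), float(x.max())
    if not correction.is_monotone(lo, hi):
        raise ValueError(
            f"correction not strictly increasing on [{lo:.4g}, {hi:.4g}]; check aborted"
        )
    before = compute_auc(cohort).auc
    after = compute_auc(cohort, scores=correction.apply(x)).auc
    return abs(before - after) <= tol


def roc_points(cohort, scores: np.ndarray | None = None):
    """(FPR, TPR, thresholds) coordinates of the empirical ROC curve."""
    from sklearn.metrics import roc_curve

    x = cohort.scores if scores is None else np.asarray(scores, dtype=float)
    return roc_curve(cohort.died, x)
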