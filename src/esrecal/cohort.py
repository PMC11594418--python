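"""Patient-level cohort containers, validation and CSV/JSON input-output.

A cohort is a collection of patients each carrying a surgical-group label
(on-pump ``ONCAB`` vs off-pump ``OPCAB``), a EuroSCORE II predicted
in-hospital mortality in **percent** (strictly positive, at most 100), and a
binary in-hospital death indicator.  Scores are kept on the percent scale
everywhere in this package; probabilities on [0, 1] appear only transiently
inside statistical routines.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
import pandas as pd

__all__ = [
    "GROUPS",
    "PatientRecord",
    "Cohort",
    "CohortSummary",
    "CohortValidationError",
    "read_cohort",
    "write_cohort",
    "summarize",
    "split_by_group",
    "merge",
]

GROUPS = ("ONCAB", "OPCAB")

#: accepted spellings for the surgical group column, normalised at load
_GROUP_SYNONYMS = {
    "oncab": "ONCAB",
    "on-pump": "ONCAB",
    "on_pump": "ONCAB",
    "onpump": "ONCAB",
    "opcab": "OPCAB",
    "off-pump": "OPCAB",
    "off_pump": "OPCAB",
    "offpump": "OPCAB",
}

_REQUIRED_COLUMNS = ("patient_id", "group", "euroscore2", "died")


class CohortValidationError(ValueError):
    """Raised for rows or cohorts violating the patient-record invariants."""


def normalize_group(value: object) -> str:
    """Map a group spelling onto the canonical {ONCAB, OPCAB} labels."""
    key = str(value).strip().lower()
    try:
        return _GROUP_SYNONYMS[key]
    except KeyError:
        raise CohortValidationError(f"unknown surgical group label: {value!r}") from None


@dataclass(frozen=True)
class PatientRecord:
    """One patient: identifier, surgical group, EuroSCORE II (%), death flag."""

    patient_id: str
    group: str
    euroscore2: float
    died: int

    def __post_init__(self) -> None:
        if not str(self.patient_id).strip():
            raise CohortValidationError("patient_id must be a non-empty string")
        object.__setattr__(self, "group", normalize_group(self.group))
        es2 = float(self.euroscore2)
        if not (0.0 < es2 <= 100.0) or math.isnan(es2):
            raise CohortValidationError(
                f"euroscore2 must lie in (0, 100], got {self.euroscore2!r}"
            )
        object.__setattr__(self, "euroscore2", es2)
        if self.died not in (0, 1):
            raise CohortValidationError(f"died must be 0 or 1, got {self.died!r}")
        object.__setattr__(self, "died", int(self.died))


@dataclass(frozen=True)
class CohortSummary:
    """Counts and score moments for one cohort.

    ``observed_mortality_pct`` is 100 * deaths / n at full precision; the
    score standard deviation uses the n-1 denominator.
    """

    n: int
    deaths: int
    observed_mortality_pct: float
    mean_es2_pct: float
    sd_es2_pct: float

    def as_dict(self) -> dict:
        return {
            "n": self.n,
            "deaths": self.deaths,
            "observed_mortality_pct": self.observed_mortality_pct,
            "mean_es2_pct": self.mean_es2_pct,
            "sd_es2_pct": self.sd_es2_pct,
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.as_dict(), indent=2) + "\n")


class Cohort:
    """Ordered, validated collection of :class:`PatientRecord`.

    Backed by a :class:`pandas.DataFrame` with columns
    ``patient_id, group, euroscore2, died``.  Patient ids must be unique.
    """

    def __init__(
        self,
        records: Iterable[PatientRecord] | pd.DataFrame,
        label: str = "",
        n_dropped: int = 0,
    ) -> None:
        if isinstance(records, pd.DataFrame):
            df = records.loc[:, list(_REQUIRED_COLUMNS)].reset_index(drop=True).copy()
            df["patient_id"] = df["patient_id"].astype(str)
            df["group"] = [normalize_group(g) for g in df["group"]]
            df["euroscore2"] = df["euroscore2"].astype(float)
            df["died"] = df["died"].astype(int)
            bad = ~((df["euroscore2"] > 0) & (df["euroscore2"] <= 100))
            if bad.any():
                raise CohortValidationError(
                    f"{int(bad.sum())} rows have euroscore2 outside (0, 100]"
                )
            if not df["died"].isin((0, 1)).all():
                raise CohortValidationError("died must be 0 or 1 for every row")
        else:
            recs = list(records)
            df = pd.DataFrame(
                {
                    "patient_id": [r.patient_id for r in recs],
                    "group": [r.group for r in recs],
                    "euroscore2": [r.euroscore2 for r in recs],
                    "died": [r.died for r in recs],
                }
            )
        if df["patient_id"].duplicated().any():
            dupes = df.loc[df["patient_id"].duplicated(), "patient_id"].tolist()[:5]
            raise CohortValidationError(f"duplicate patient ids: {dupes}")
        self._df = df
        self.label = label
        self.n_dropped = int(n_dropped)

    # -- container protocol -------------------------------------------------
    def __len__(self) -> int:
        return len(self._df)

    def __iter__(self) -> Iterator[PatientRecord]:
        return iter(self.records)

    def __repr__(self) -> str:
        return f"Cohort(n={len(self)}, label={self.label!r}, n_dropped={self.n_dropped})"

    # -- views --------------------------------------------------------------
    @property
    def df(self) -> pd.DataFrame:
        """Read-only view of the underlying table."""
        return self._df.copy()

    @property
    def records(self) -> list[PatientRecord]:
        return [
            PatientRecord(r.patient_id, r.group, r.euroscore2, r.died)
            for r in self._df.itertuples(index=False)
        ]

    @property
    def scores(self) -> np.ndarray:
        """EuroSCORE II values in percent, aligned to record order."""
        return self._df["euroscore2"].to_numpy(dtype=float)

    @property
    def died(self) -> np.ndarray:
        """0/1 in-hospital death indicators, aligned to record order."""
        return self._df["died"].to_numpy(dtype=int)

    @property
    def groups(self) -> np.ndarray:
        return self._df["group"].to_numpy(dtype=object)

    # -- IO -----------------------------------------------------------------
    def write_csv(self, path: str | Path) -> None:
        """Write the cohort in the canonical CSV dialect (RFC 4180, UTF-8)."""
        self._df.to_csv(path, index=False)


def _row_error(row: pd.Series) -> str | None:
    """Return the first invariant violated by a raw CSV row, or None."""
    if pd.isna(row["patient_id"]) or not str(row["patient_id"]).strip():
        return "missing patient_id"
    try:
        normalize_group(row["group"])
    except CohortValidationError:
        return f"unknown group {row['group']!r}"
    try:
        es2 = float(row["euroscore2"])
    except (TypeError, ValueError):
        return f"non-numeric euroscore2 {row['euroscore2']!r}"
    if math.isnan(es2) or not (0.0 < es2 <= 100.0):
        return f"euroscore2 {row['euroscore2']!r} outside (0, 100]"
    try:
        died = float(row["died"])
    except (TypeError, ValueError):
        return f"non-numeric died {row['died']!r}"
    if died not in (0.0, 1.0):
        return f"died {row['died']!r} not in {{0, 1}}"
    return None


def read_cohort(path: str | Path, strict: bool = False, label: str | None = None) -> Cohort:
    """Load a cohort from CSV.

    The header must declare ``patient_id, group, euroscore2, died``.  Rows
    violating the patient-record invariants (score outside (0, 100], death
    flag not 0/1, missing fields) are dropped and counted in ``n_dropped``
    with a warning, or raise immediately when ``strict`` is true.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    raw = pd.read_csv(path, dtype={"patient_id": str})
    missing = [c for c in _REQUIRED_COLUMNS if c not in raw.columns]
    if missing:
        raise CohortValidationError(f"{path}: missing required columns {missing}")

    errors = raw.apply(_row_error, axis=1)
    bad = errors.notna()
    if bad.any():
        # +2: header line and 1-based numbering
        detail = "; ".join(
            f"row {i + 2}: {errors[i]}" for i in raw.index[bad][:10]
        )
        if strict:
            raise CohortValidationError(f"{path}: invalid rows ({detail})")
        warnings.warn(
            f"{path}: dropped {int(bad.sum())} invalid rows ({detail})",
            stacklevel=2,
        )
    kept = raw.loc[~bad]
    if kept.empty:
        raise CohortValidationError(f"{path}: no valid rows")
    return Cohort(kept, label=label if label is not None else path.stem, n_dropped=int(bad.sum()))


def write_cohort(cohort: Cohort, path: str | Path) -> None:
    cohort.write_csv(path)


def summarize(cohort: Cohort) -> CohortSummary:
    """Counts, observed mortality %, and score mean/SD (denominator n-1)."""
    n = len(cohort)
    if n == 0:
        raise CohortValidationError("cannot summarize an empty cohort")
    deaths = int(cohort.died.sum())
    scores = cohort.scores
    if n == 1:
        warnings.warn("single-record cohort: score SD undefined, reported as 0", stacklevel=2)
        sd = 0.0
    else:
        sd = float(np.std(scores, ddof=1))
    return CohortSummary(
        n=n,
        deaths=deaths,
        observed_mortality_pct=100.0 * deaths / n,
        mean_es2_pct=float(scores.mean()),
        sd_es2_pct=sd,
    )


def split_by_group(cohort: Cohort) -> tuple[Cohort, Cohort]:
    """Partition into (ONCAB, OPCAB) sub-cohorts, labels inheriting a suffix."""
    df = cohort.df
    parts = []
    for grp in GROUPS:
        sub = df.loc[df["group"] == grp]
        if sub.empty:
            warnings.warn(f"cohort {cohort.label!r} has no {grp} records", stacklevel=2)
        parts.append(Cohort(sub, label=f"{cohort.label}/{grp}") if not sub.empty
                     else _empty_like(cohort, grp))
    return parts[0], parts[1]


@dataclass
class _EmptyCohort:
    """Degenerate stand-in for an empty partition (no analysis allowed)."""

    label: str
    n_dropped: int = 0
    scores: np.ndarray = field(default_factory=lambda: np.empty(0))
    died: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))

    def __len__(self) -> int:
        return 0


def _empty_like(cohort: Cohort, grp: str) -> _EmptyCohort:
    return _EmptyCohort(label=f"{cohort.label}/{grp}")


def merge(*cohorts: Cohort, label: str = "merged") -> Cohort:
    """Concatenate cohorts; patient ids must remain unique."""
    frames = [c.df for c in cohorts if len(c)]
    if not frames:
        raise CohortValidationError("nothing to merge")
    return Cohort(
        pd.concat(frames, ignore_index=True),
        label=label,
        n_dropped=sum(c.n_dropped for c in cohorts),
    )
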