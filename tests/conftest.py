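import numpy as np
import pandas as pd
import pytest

from esrecal import Cohort


def make_cohort(scores, died, group="ONCAB", label="test") -> Cohort:
    scores = np.asarray(scores, dtype=float)
    died = np.asarray(died, dtype=int)
    if np.isscalar(group) or isinstance(group, str):
        group = [group] * len(scores)
    df = pd.DataFrame(
        {
            "patient_id": [f"p{i}" for i in range(len(scores))],
            "group": group,
            "euroscore2": scores,
            "died": died,
        }
    )
    return Cohort(df, label=label)


@pytest.fixture
def toy_csv(tmp_path):
    """12-row two-group CSV with deaths and survivors in each group."""
    path = tmp_path / "toy.csv"
    rows = ["patient_id,group,euroscore2,died"]
    scores = [1.2, 2.5, 3.1, 4.8, 7.9, 15.0]
    for i, s in enumerate(scores):
        rows.append(f"on{i},ONCAB,{s},{1 if i >= 4 else 0}")
        rows.append(f"off{i},OPCAB,{s + 0.1},{1 if i >= 4 else 0}")
    path.write_text("\n".join(rows) + "\n")
    return path


@pytest.fixture
def mortality_cohort():
    """2729 patients, 224 deaths, scores varying around a 5.06% mean."""
    scores = np.concatenate([[5.06], np.full(1364, 4.06), np.full(1364, 6.06)])
    died = np.zeros(2729, dtype=int)
    died[:224] = 1
    return make_cohort(scores, died)
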