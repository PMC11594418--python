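"""Nomogram: lookup table from original score to corrected predicted mortality."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .recalibration import CorrectionModel

__all__ = ["NomogramTable", "build_nomogram"]


@dataclass(frozen=True)
class NomogramTable:
    """Grid of original scores (percent) and their corrected mortalities."""

    grid: np.ndarray
    adjusted: np.ndarray
    model: CorrectionModel

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({"euroscore2": self.grid, "adjusted_mortality": self.adjusted})

    def to_csv(self, path: str | Path) -> None:
        self.to_dataframe().round(2).to_csv(path, index=False)

    def plot(self, path: str | Path) -> None:
        """Optional score-vs-corrected-score plot with identity reference."""
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(6, 5))
        ax.plot(self.grid, self.adjusted, lw=2, label="corrected score")
        ax.plot(self.grid, self.grid, ls="--", color="grey", label="identity")
        ax.set_xlabel("original EuroSCORE II (%)")
        ax.set_ylabel("adjusted predicted mortality (%)")
        ax.legend()
        fig.tight_layout()
        fig.savefig(path, dpi=150)
        plt.close(fig)


def build_nomogram(
    model: CorrectionModel,
    grid_min: float = 0.0,
    grid_max: float = 85.0,
    step: float = 0.5,
) -> NomogramTable:
    """Tabulate the correction over an even grid of original scores.

    Full precision internally; :meth:`NomogramTable.to_csv` rounds to 2 dp.
    The model must be strictly increasing over the grid span.
    """
    if not (grid_min < grid_max):
        raise ValueError("grid_min must be below grid_max")
    if step <= 0:
        raise ValueError("step must be positive")
    if not model.is_monotone(grid_min, grid_max):
        raise ValueError(
            f"correction not monotone on [{grid_min}, {grid_max}]; nomogram refused"
        )
    n_steps = int(round((grid_max - grid_min) / step))
    grid = grid_min + step * np.arange(n_steps + 1)
    grid = grid[grid <= grid_max + 1e-12]
    adjusted = np.asarray(model.apply(grid), dtype=float)
    return NomogramTable(grid=grid, adjusted=adjusted, model=model)
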