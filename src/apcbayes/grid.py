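"""Age-period-cohort index arithmetic and long-format data tables.

An APC table is indexed by age group ``i = 1..I`` and period group ``j = 1..J``
on the same interval scale, which pins the birth-cohort index to
``k = j - i + I`` with ``K = I + J - 1`` cohort groups.  Everything downstream
(the identification problem included) flows from that single linear relation.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["APCGrid", "build_grid", "centered_index", "expand_design", "Dataset"]


@dataclass(frozen=True)
class APCGrid:
    """Dimensions of an equal-interval age-period-cohort grid.

    Parameters
    ----------
    I, J : int
        Number of age and period groups.  Both must be at least 2 so that
        every effect block supports a linear/nonlinear decomposition.
    """

    I: int
    J: int

    def __post_init__(self) -> None:
        if int(self.I) != self.I or int(self.J) != self.J:
            raise TypeError("grid dimensions must be integers")
        if self.I < 2 or self.J < 2:
            raise ValueError(
                f"need I >= 2 and J >= 2 (got I={self.I}, J={self.J}); "
                "a linear component is undefined on a single point"
            )

    @property
    def K(self) -> int:
        """Number of cohort groups, K = I + J - 1."""
        return self.I + self.J - 1

    def cohort_of(self, i, j):
        """Cohort index k = j - i + I for 1-based age ``i`` and period ``j``."""
        i = np.asarray(i)
        j = np.asarray(j)
        if np.any(i < 1) or np.any(i > self.I) or np.any(j < 1) or np.any(j > self.J):
            raise ValueError("age/period index out of range")
        k = j - i + self.I
        return k if k.ndim else int(k)

    @property
    def n_cells(self) -> int:
        return self.I * self.J


def build_grid(I: int, J: int) -> APCGrid:
    """Construct an :class:`APCGrid`; alias kept for the functional API."""
    return APCGrid(I, J)


def centered_index(M: int) -> np.ndarray:
    """Centered index ``v_m = m - (M+1)/2`` for ``m = 1..M``.

    The entries sum to zero exactly and step by one, so regressing an effect
    vector on ``v`` isolates its linear component.
    """
    if int(M) != M:
        raise TypeError("M must be an integer")
    if M < 2:
        raise ValueError(f"need M >= 2 (got {M})")
    return np.arange(1, M + 1, dtype=float) - (M + 1) / 2.0


@dataclass(frozen=True)
class Dataset:
    """Long-format APC observations.

    ``df`` has integer columns ``i, j, k`` (1-based, satisfying
    ``k = j - i + I``) and a float column ``y``; ``y`` may be NaN for a design
    skeleton whose responses have not been generated yet.
    """

    df: pd.DataFrame = field(repr=False)
    grid: APCGrid

    def __post_init__(self) -> None:
        required = ["i", "j", "k", "y"]
        if list(self.df.columns[:4]) != required and not set(required) <= set(self.df.columns):
            raise ValueError(f"dataset needs columns {required}")
        i = self.df["i"].to_numpy()
        j = self.df["j"].to_numpy()
        k = self.df["k"].to_numpy()
        if np.any(i < 1) or np.any(i > self.grid.I):
            raise ValueError("age index out of range")
        if np.any(j < 1) or np.any(j > self.grid.J):
            raise ValueError("period index out of range")
        if np.any(k != j - i + self.grid.I):
            raise ValueError("cohort index violates k = j - i + I")

    @property
    def N(self) -> int:
        return len(self.df)

    @property
    def y(self) -> np.ndarray:
        return self.df["y"].to_numpy(dtype=float)

    def indices(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """1-based (i, j, k) arrays of length N."""
        return (
            self.df["i"].to_numpy(),
            self.df["j"].to_numpy(),
            self.df["k"].to_numpy(),
        )

    def cell_stats(self) -> tuple[np.ndarray, np.ndarray, float]:
        """Per-cell counts and response sums in row-major (i, j) order,
        plus the total sum of squared responses.

        These are the sufficient statistics of the Gaussian likelihood: the
        cell mean only depends on (i, j), so replicates collapse.
        """
        I, J = self.grid.I, self.grid.J
        i, j, _ = self.indices()
        cell = (i - 1) * J + (j - 1)
        y = self.y
        counts = np.bincount(cell, minlength=I * J).astype(float)
        sums = np.bincount(cell, weights=y, minlength=I * J)
        return counts, sums, float(y @ y)

    def with_y(self, y: np.ndarray) -> "Dataset":
        df = self.df.copy()
        df["y"] = np.asarray(y, dtype=float)
        return Dataset(df, self.grid)

    # --- CSV round trip (header: i, j, k, y) -------------------------------
    def to_csv(self, path) -> None:
        self.df[["i", "j", "k", "y"]].to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, grid: APCGrid | None = None) -> "Dataset":
        df = pd.read_csv(path)
        df = df.astype({"i": int, "j": int, "k": int, "y": float})
        if grid is None:
            grid = APCGrid(int(df["i"].max()), int(df["j"].max()))
        return cls(df, grid)


def expand_design(grid: APCGrid, replicates: int = 1) -> Dataset:
    """Dataset skeleton with ``N = I * J * replicates`` rows and unset ``y``.

    Row order is fixed and documented: age outermost, period next, replicate
    innermost — so seeded data generation is bit-reproducible.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    I, J = grid.I, grid.J
    i = np.repeat(np.arange(1, I + 1), J * replicates)
    j = np.tile(np.repeat(np.arange(1, J + 1), replicates), I)
    k = j - i + I
    df = pd.DataFrame({"i": i, "j": j, "k": k, "y": np.nan})
    return Dataset(df, grid)
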