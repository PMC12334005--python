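"""Effect vectors, the linear/nonlinear decomposition, and the shift algebra.

The APC identification problem in executable form: because the centered
indexes satisfy ``v_i^A - v_j^P + v_k^C = 0`` on every cell, adding ``s * v``
to the age and cohort effects while subtracting it from the period effects
leaves every fitted cell mean unchanged (:func:`apply_shift`).  Only the
*nonlinear* residual of each effect vector after regression on its centered
index (:func:`decompose`) is identified by the likelihood alone.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .grid import APCGrid, centered_index

__all__ = [
    "EffectSet",
    "Decomposition",
    "decompose",
    "apply_shift",
    "index_weight_gap",
]

#: absolute tolerance for the sum-to-zero constraint on construction
SUM_ZERO_TOL = 1e-8


@dataclass(frozen=True)
class EffectSet:
    """Intercept plus the three sum-to-zero effect vectors.

    Parameters
    ----------
    b0 : float
        Global intercept.
    bA, bP, bC : array-like
        Age (length I), period (length J) and cohort (length K) effects.
        Each block must sum to zero within ``1e-8``; violations raise.
    """

    b0: float
    bA: np.ndarray = field(repr=False)
    bP: np.ndarray = field(repr=False)
    bC: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        for name in ("bA", "bP", "bC"):
            v = np.asarray(getattr(self, name), dtype=float)
            object.__setattr__(self, name, v)
            if v.ndim != 1 or v.size < 2:
                raise ValueError(f"{name} must be a vector of length >= 2")
            if abs(v.sum()) > SUM_ZERO_TOL:
                raise ValueError(
                    f"{name} violates the sum-to-zero constraint "
                    f"(sum = {v.sum():.3e}, tol = {SUM_ZERO_TOL})"
                )
        object.__setattr__(self, "b0", float(self.b0))

    @property
    def grid(self) -> APCGrid:
        return APCGrid(self.bA.size, self.bP.size)

    def conforms_to(self, grid: APCGrid) -> bool:
        return (
            self.bA.size == grid.I
            and self.bP.size == grid.J
            and self.bC.size == grid.K
        )

    def cell_means(self, grid: APCGrid | None = None) -> np.ndarray:
        """Fitted mean ``b0 + bA_i + bP_j + bC_k`` for every cell, shape (I, J)."""
        grid = grid or self.grid
        if not self.conforms_to(grid):
            raise ValueError("effect set does not conform to grid")
        i = np.arange(1, grid.I + 1)[:, None]
        j = np.arange(1, grid.J + 1)[None, :]
        k = j - i + grid.I
        return self.b0 + self.bA[i - 1] + self.bP[j - 1] + self.bC[k - 1]

    def blocks(self) -> dict[str, np.ndarray]:
        return {"A": self.bA, "P": self.bP, "C": self.bC}


@dataclass(frozen=True)
class Decomposition:
    """Linear slope on the centered index plus the orthogonal nonlinear part."""

    slope: float
    nonlinear: np.ndarray = field(repr=False)

    def reconstruct(self, v: np.ndarray) -> np.ndarray:
        return self.slope * np.asarray(v, dtype=float) + self.nonlinear


def decompose(b: np.ndarray, v: np.ndarray) -> Decomposition:
    """Split ``b`` into ``slope * v + nonlinear`` with ``v`` the centered index.

    ``slope = <v, b> / <v, v>`` is the least-squares regression slope of the
    effect vector on its centered index; the residual is orthogonal to ``v``
    and is the identified nonlinear component.
    """
    b = np.asarray(b, dtype=float)
    v = np.asarray(v, dtype=float)
    if b.shape != v.shape or b.ndim != 1:
        raise ValueError(f"shape mismatch: b{b.shape} vs v{v.shape}")
    if b.size < 2:
        raise ValueError("need at least two points to fit a slope")
    slope = float(v @ b) / float(v @ v)
    return Decomposition(slope, b - slope * v)


def apply_shift(e: EffectSet, s: float, grid: APCGrid | None = None) -> EffectSet:
    """General-solution shift: ``(bA + s vA, bP - s vP, bC + s vC)``.

    Leaves every fitted cell mean (and ``b0``) unchanged for any real ``s``
    because ``v_i^A - v_j^P + v_k^C = 0``; the sum-to-zero constraints are
    preserved because each centered index sums to zero.
    """
    grid = grid or e.grid
    if not e.conforms_to(grid):
        raise ValueError("effect set does not conform to grid")
    vA = centered_index(grid.I)
    vP = centered_index(grid.J)
    vC = centered_index(grid.K)
    return EffectSet(e.b0, e.bA + s * vA, e.bP - s * vP, e.bC + s * vC)


def index_weight_gap(I: int, J: int) -> float:
    """Excess of the cohort/period index-weight ratio of magnitude-shrinkage
    priors over that of the random-walk prior.

    Returns ``sum(vC^2)/sum(vP^2) - (K-1)/(J-1)``, which equals the closed
    form ``(K-1)(2J+I)(I-1) / [J(J+1)(J-1)]`` and is strictly positive for
    all I, J >= 2: shrinking parameter magnitudes always presses harder on
    the cohort slope than shrinking adjacent differences does.
    """
    grid = APCGrid(I, J)
    vP = centered_index(grid.J)
    vC = centered_index(grid.K)
    return float(vC @ vC) / float(vP @ vP) - (grid.K - 1) / (grid.J - 1)
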