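"""Artificial APC parameters and synthetic data generation.

Each effect vector is built from a linear slope on the centered index plus a
trigonometric nonlinear component ``amp * cos(pi * m)`` — chosen because the
cosine alternation carries (essentially) no linear component, lets the two
components be dialed independently, and deliberately does *not* match any of
the normal priors, so recovery is not an artifact of prior/data agreement.
A small intercept correction restores the exact sum-to-zero constraint when
a block has odd length.

Study conditions: a 10x10 grid, 10 replicates per cell (N = 1000) and noise
SD ``gamma = 0.1``, so sampling noise is small relative to the structured
components (slopes 0.1, amplitudes 0.05 in the systematic design).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .effects import EffectSet, decompose
from .grid import APCGrid, Dataset, centered_index, expand_design

__all__ = [
    "TrueParams",
    "make_trig_params",
    "generate_data",
    "Sim1Case",
    "enumerate_sim1_cases",
    "ComponentDraw",
    "draw_sim2",
    "draw_sim3",
    "PolySpec",
    "polynomial_params",
]

#: systematic-design magnitudes: slope step and nonlinear amplitude
SIM1_SLOPE = 0.1
SIM1_AMP = 0.05

#: SD of the replicated studies' Normal(0, 0.1) component draws.  The 0.1 is
#: a variance: the aggregate bias delta of the replicated studies is only on
#: the documented scale with component SD sqrt(0.1) (the likelihood noise
#: gamma = 0.1, by contrast, is an SD — the systematic study pins that down).
COMPONENT_SD = float(np.sqrt(0.1))


def _cos_pi(m: np.ndarray) -> np.ndarray:
    """cos(pi*m) for integer m, computed exactly as (-1)^m."""
    return np.where(np.asarray(m) % 2 == 0, 1.0, -1.0)


@dataclass(frozen=True)
class TrueParams:
    """Artificial-parameter specification and the realized effect vectors.

    ``slopes`` and ``amps`` are (age, period, cohort) triples of the linear
    slope per unit index and the nonlinear cosine amplitude; ``intercepts``
    are the zero-sum corrections; ``gamma`` is the observation noise SD.
    """

    grid: APCGrid
    slopes: tuple[float, float, float]
    amps: tuple[float, float, float]
    intercepts: tuple[float, float, float]
    beta_a: np.ndarray = field(repr=False)
    beta_p: np.ndarray = field(repr=False)
    beta_c: np.ndarray = field(repr=False)
    gamma: float = 0.1

    def __post_init__(self) -> None:
        if self.gamma < 0:
            raise ValueError("gamma must be nonnegative")
        for name, M in (("beta_a", self.grid.I), ("beta_p", self.grid.J),
                        ("beta_c", self.grid.K)):
            v = np.asarray(getattr(self, name), dtype=float)
            object.__setattr__(self, name, v)
            if v.size != M:
                raise ValueError(f"{name} must have length {M}")
            if abs(v.sum()) > 1e-10:
                raise ValueError(f"{name} violates the zero-sum condition")

    def effects(self) -> EffectSet:
        """The true parameters as an EffectSet (zero global intercept)."""
        return EffectSet(0.0, self.beta_a, self.beta_p, self.beta_c)

    def cell_means(self) -> np.ndarray:
        return self.effects().cell_means(self.grid)

    def to_dict(self) -> dict:
        return {
            "I": self.grid.I,
            "J": self.grid.J,
            "slopes": list(self.slopes),
            "amps": list(self.amps),
            "intercepts": list(self.intercepts),
            "beta_a": self.beta_a.tolist(),
            "beta_p": self.beta_p.tolist(),
            "beta_c": self.beta_c.tolist(),
            "gamma": self.gamma,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TrueParams":
        return make_trig_params(
            APCGrid(d["I"], d["J"]),
            tuple(d["slopes"]),
            tuple(d["amps"]),
            gamma=d.get("gamma", 0.1),
        )


def make_trig_params(
    grid: APCGrid,
    slopes: tuple[float, float, float] = (0.0, 0.0, 0.0),
    amps: tuple[float, float, float] = (0.0, 0.0, 0.0),
    gamma: float = 0.1,
) -> TrueParams:
    """Build trigonometric artificial parameters on ``grid``.

    Per block of length M: ``beta_m = beta0 + slope * v_m + amp * cos(pi m)``
    with ``beta0 = -(amp / 2M) (cos(pi M) - 1)`` — zero for even M, ``amp/M``
    for odd M — which makes each block sum to zero exactly.
    """
    lens = (grid.I, grid.J, grid.K)
    intercepts = []
    vectors = []
    for M, slope, amp in zip(lens, slopes, amps):
        m = np.arange(1, M + 1)
        beta0 = -amp / (2.0 * M) * (_cos_pi(np.array(M)) - 1.0)
        beta = beta0 + slope * centered_index(M) + amp * _cos_pi(m)
        beta = beta - beta.sum() / M  # absorb float round-off; beta0 is exact math
        intercepts.append(float(beta0))
        vectors.append(beta)
    return TrueParams(
        grid=grid,
        slopes=tuple(float(s) for s in slopes),
        amps=tuple(float(a) for a in amps),
        intercepts=tuple(intercepts),
        beta_a=vectors[0],
        beta_p=vectors[1],
        beta_c=vectors[2],
        gamma=float(gamma),
    )


def generate_data(
    params: TrueParams, replicates: int = 10, seed: int | np.random.Generator = 0
) -> Dataset:
    """Draw ``y ~ Normal(beta_a_i + beta_p_j + beta_c_k, gamma)`` independently
    over the deterministic row order of :func:`expand_design`."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    skel = expand_design(params.grid, replicates)
    i, j, k = skel.indices()
    mu = params.beta_a[i - 1] + params.beta_p[j - 1] + params.beta_c[k - 1]
    y = mu + params.gamma * rng.standard_normal(skel.N)
    return skel.with_y(y)


# ---------------------------------------------------------------------------
# Simulation 1: systematic sign combinations of the linear components


@dataclass(frozen=True)
class Sim1Case:
    """One row of the systematic design: sign triple and magnitudes."""

    number: int
    signs: tuple[int, int, int]  # (age, period, cohort) in {-1, 0, +1}
    slopes: tuple[float, float, float]
    amps: tuple[float, float, float]

    def label(self) -> str:
        sym = {1: "+", 0: "0", -1: "-"}
        return "".join(sym[s] for s in self.signs)


#: sign triples (age, period, cohort) in the canonical table order
_SIM1_SIGNS = [
    (1, 0, 0),
    (0, 1, 0),
    (0, 0, 1),
    (1, 1, 0),
    (1, 0, 1),
    (0, 1, 1),
    (0, 1, -1),
    (-1, 0, 1),
    (-1, 1, 0),
    (1, 1, -1),
    (1, 1, 1),
    (-1, 1, 1),
    (1, -1, 1),
]


def enumerate_sim1_cases() -> list[Sim1Case]:
    """The 13 systematic cases: (3^3 - 1)/2 sign triples over the three
    effects, excluding the all-zero triple and one member of each global
    sign-flip pair.  ``+`` means slope +0.1 with amplitude +0.05; ``-`` the
    negation; ``0`` means both zero.
    """
    cases = []
    for n, signs in enumerate(_SIM1_SIGNS, start=1):
        slopes = tuple(s * SIM1_SLOPE for s in signs)
        amps = tuple(s * SIM1_AMP for s in signs)
        cases.append(Sim1Case(n, signs, slopes, amps))
    return cases


# ---------------------------------------------------------------------------
# Simulations 2 and 3: random component draws


@dataclass(frozen=True)
class ComponentDraw:
    """Randomly drawn linear slopes and nonlinear amplitudes, (A, P, C)."""

    slopes: tuple[float, float, float]
    amps: tuple[float, float, float]

    def to_dict(self) -> dict:
        return {"slopes": list(self.slopes), "amps": list(self.amps)}


def draw_sim2(seed: int | np.random.Generator = 0) -> ComponentDraw:
    """Independent Normal(0, variance 0.1) draws for the three slopes, then
    the three amplitudes: linear-only and nonlinear-only patterns are equally
    likely."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    slopes = tuple(rng.normal(0.0, COMPONENT_SD, size=3))
    amps = tuple(rng.normal(0.0, COMPONENT_SD, size=3))
    return ComponentDraw(slopes, amps)


def draw_sim3(
    seed: int | np.random.Generator = 0, literal_coupling: bool = False
) -> ComponentDraw:
    """Nonlinear-first draws that make purely linear patterns vanishingly rare.

    Per effect: ``amp ~ Normal(0, variance 0.1)`` then ``slope ~ Normal(0,
    SD |amp|)``, so a zero amplitude forces a zero slope and a slope can only
    be large where its own nonlinear component is too.
    ``literal_coupling=True`` scales every slope by the *age* amplitude
    instead (an alternative reading of the design, kept as an option; it
    destroys the nonlinear-first property for period and cohort).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    amps: list[float] = []
    slopes: list[float] = []
    for _ in range(3):
        amp = float(rng.normal(0.0, COMPONENT_SD))
        sd = abs(amps[0]) if (literal_coupling and amps) else abs(amp)
        amps.append(amp)
        slopes.append(float(rng.normal(0.0, sd)))
    return ComponentDraw(tuple(slopes), tuple(amps))


# ---------------------------------------------------------------------------
# polynomial generators (applicability of the nonlinear-first assumption)


@dataclass(frozen=True)
class PolySpec:
    """A centered random polynomial effect and its decomposition.

    ``eta = sum_h w_h * z_h`` with ``z_h`` the standardized h-th power of the
    centered index; ``eta_l`` is the least-squares slope on the centered
    index, ``eta_nl`` the orthogonal residual and ``sd_nl`` its root mean
    square.
    """

    M: int
    H: int
    weights: np.ndarray = field(repr=False)
    eta: np.ndarray = field(repr=False)
    eta_l: float
    eta_nl: np.ndarray = field(repr=False)
    sd_nl: float

    def in_gray_area(self, ratio: float = 0.5) -> bool:
        """True when the draw is (near-)purely linear: sd_nl <= ratio*|eta_l|."""
        return self.sd_nl <= ratio * abs(self.eta_l)


def polynomial_params(
    M: int,
    H: int,
    seed: int | np.random.Generator = 0,
    weights: np.ndarray | None = None,
) -> PolySpec:
    """Random centered polynomial ``eta_m = sum_h w_h z_{m,h}`` of degree H.

    Each power column ``z_h`` is the population-standardized ``v_m^h`` (zero
    mean, unit SD); ``w_h ~ Normal(0, 0.1)`` unless supplied.  Raises if any
    power column is constant.
    """
    if M < 3:
        raise ValueError("need M >= 3")
    if H < 1:
        raise ValueError("need H >= 1")
    v = centered_index(M)
    Z = np.empty((M, H))
    for h in range(1, H + 1):
        col = v**h
        sd = col.std()  # population SD
        if sd == 0:
            raise ValueError(f"power column h={h} has zero variance")
        Z[:, h - 1] = (col - col.mean()) / sd
    if weights is None:
        rng = (
            seed
            if isinstance(seed, np.random.Generator)
            else np.random.default_rng(seed)
        )
        weights = rng.normal(0.0, 0.1, size=H)
    weights = np.asarray(weights, dtype=float)
    if weights.shape != (H,):
        raise ValueError(f"weights must have shape ({H},)")
    eta = Z @ weights
    eta = eta - eta.mean()
    d = decompose(eta, v)
    sd_nl = float(np.sqrt(np.mean(d.nonlinear**2)))
    return PolySpec(M, H, weights, eta, d.slope, d.nonlinear, sd_nl)
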