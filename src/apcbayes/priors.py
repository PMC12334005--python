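"""Gaussian APC log-likelihood and the three regularization log-priors.

Three Gaussian priors distinguish the models:

* ``random_effects`` — each effect block has its own zero-mean normal prior
  (the multilevel-analysis constraint): penalizes parameter magnitudes.
* ``ridge`` — the same with a single shared scale ``lambda`` (equivalent in
  effect to the intrinsic estimator / minimum-norm solution).
* ``random_walk`` — first differences of each ordered block are zero-mean
  normal (the Bayesian cohort-model constraint): penalizes adjacent changes.

All values exclude additive normalization constants.  The
index-weighted forms (``*_indexed``) re-express each prior through the
linear/nonlinear decomposition and are used to verify the algebra that makes
magnitude-shrinkage priors flatten the cohort slope.
"""
from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np

from .effects import EffectSet, decompose
from .grid import APCGrid, Dataset, centered_index

__all__ = [
    "ModelKind",
    "ScaleParams",
    "log_likelihood",
    "log_prior_re",
    "log_prior_rr",
    "log_prior_rw",
    "log_prior_re_indexed",
    "log_prior_rw_indexed",
    "log_posterior",
]


class ModelKind(str, enum.Enum):
    """The three Bayesian-regularization models."""

    RANDOM_EFFECTS = "random_effects"
    RIDGE = "ridge"
    RANDOM_WALK = "random_walk"

    @classmethod
    def coerce(cls, kind: "ModelKind | str") -> "ModelKind":
        if isinstance(kind, cls):
            return kind
        try:
            return cls(kind)
        except ValueError:
            raise ValueError(
                f"unknown model kind {kind!r}; expected one of "
                f"{[m.value for m in cls]}"
            ) from None


MODEL_KINDS = tuple(ModelKind)


@dataclass(frozen=True)
class ScaleParams:
    """Scale (standard-deviation) parameters of likelihood and priors.

    ``sigma`` is the observation SD; ``sigma_a/p/c`` the per-block prior SDs;
    ``lam`` the shared ridge scale.  For the ridge model the block SDs all
    equal ``lam`` by construction.
    """

    sigma: float = 1.0
    sigma_a: float = 1.0
    sigma_p: float = 1.0
    sigma_c: float = 1.0
    lam: float = 1.0

    def __post_init__(self) -> None:
        for name in ("sigma", "sigma_a", "sigma_p", "sigma_c", "lam"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be strictly positive")

    @classmethod
    def for_ridge(cls, sigma: float, lam: float) -> "ScaleParams":
        return cls(sigma=sigma, sigma_a=lam, sigma_p=lam, sigma_c=lam, lam=lam)

    def block_sds(self) -> tuple[float, float, float]:
        return (self.sigma_a, self.sigma_p, self.sigma_c)


def log_likelihood(data: Dataset, e: EffectSet, sigma: float) -> float:
    """Gaussian log-likelihood ``-N log(sigma) - SSR / (2 sigma^2)``.

    ``SSR`` is the sum of squared residuals about the cell means
    ``mu_n = b0 + bA_i + bP_j + bC_k``.  The additive normalization constant
    is excluded.
    """
    if not sigma > 0:
        raise ValueError("sigma must be strictly positive")
    if not e.conforms_to(data.grid):
        raise ValueError("effect set does not conform to the data grid")
    i, j, k = data.indices()
    mu = e.b0 + e.bA[i - 1] + e.bP[j - 1] + e.bC[k - 1]
    r = data.y - mu
    return float(-data.N * np.log(sigma) - (r @ r) / (2.0 * sigma**2))


def log_prior_re(e: EffectSet, scales: ScaleParams) -> float:
    """Random-effects log-prior (constant excluded):

    ``-(I log sA + J log sP + K log sC)
    - 1/2 [sum(bA^2)/sA^2 + sum(bP^2)/sP^2 + sum(bC^2)/sC^2]``
    """
    out = 0.0
    for b, sd in zip((e.bA, e.bP, e.bC), scales.block_sds()):
        out += -b.size * np.log(sd) - (b @ b) / (2.0 * sd**2)
    return float(out)


def log_prior_rr(e: EffectSet, lam: float) -> float:
    """Ridge log-prior: the random-effects prior with one shared scale."""
    if not lam > 0:
        raise ValueError("lam must be strictly positive")
    ss = sum(float(b @ b) for b in (e.bA, e.bP, e.bC))
    n = e.bA.size + e.bP.size + e.bC.size
    return float(-n * np.log(lam) - ss / (2.0 * lam**2))


def log_prior_rw(e: EffectSet, scales: ScaleParams) -> float:
    """Random-walk log-prior (constant excluded):

    ``-[(I-1) log sA + (J-1) log sP + (K-1) log sC]
    - 1/2 sum_blocks sum(adjacent differences^2) / block SD^2``
    """
    out = 0.0
    for b, sd in zip((e.bA, e.bP, e.bC), scales.block_sds()):
        d = np.diff(b)
        out += -(b.size - 1) * np.log(sd) - (d @ d) / (2.0 * sd**2)
    return float(out)


def log_prior_re_indexed(e: EffectSet, scales: ScaleParams) -> float:
    """Random-effects log-prior via the linear/nonlinear decomposition.

    Per block: ``-M log s - [slope^2 sum(v^2) + sum(nl^2)] / (2 s^2)``.
    Algebraically identical to :func:`log_prior_re` by orthogonality of the
    centered index and the nonlinear residual.
    """
    out = 0.0
    for b, sd in zip((e.bA, e.bP, e.bC), scales.block_sds()):
        v = centered_index(b.size)
        d = decompose(b, v)
        quad = d.slope**2 * float(v @ v) + float(d.nonlinear @ d.nonlinear)
        out += -b.size * np.log(sd) - quad / (2.0 * sd**2)
    return float(out)


def log_prior_rw_indexed(e: EffectSet, scales: ScaleParams) -> float:
    """Random-walk log-prior via the decomposition.

    Per block of length M: adjacent differences are ``slope + diff(nl)``, so
    the quadratic expands to ``slope^2 (M-1) + 2 slope (nl_M - nl_1)
    + sum(diff(nl)^2)``.  Identical to :func:`log_prior_rw`.
    """
    out = 0.0
    for b, sd in zip((e.bA, e.bP, e.bC), scales.block_sds()):
        M = b.size
        v = centered_index(M)
        d = decompose(b, v)
        nl = d.nonlinear
        dn = np.diff(nl)
        quad = d.slope**2 * (M - 1) + 2.0 * d.slope * (nl[-1] - nl[0]) + float(dn @ dn)
        out += -(M - 1) * np.log(sd) - quad / (2.0 * sd**2)
    return float(out)


def log_posterior(
    kind: ModelKind | str,
    e: EffectSet,
    scales: ScaleParams,
    data: Dataset,
) -> float:
    """Log-posterior = log-likelihood + the model's log-prior.

    Flat hyperpriors on the scale parameters contribute zero, so the three
    models differ only through their effect priors.
    """
    kind = ModelKind.coerce(kind)
    ll = log_likelihood(data, e, scales.sigma)
    if kind is ModelKind.RANDOM_EFFECTS:
        return ll + log_prior_re(e, scales)
    if kind is ModelKind.RIDGE:
        return ll + log_prior_rr(e, scales.lam)
    return ll + log_prior_rw(e, scales)
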