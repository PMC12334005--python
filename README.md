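# apcbayes

Bayesian-regularized **age–period–cohort (APC) analysis**: three Gaussian
priors for the classic identification problem, exact Gibbs sampling, a
closed-form bias statistic for simulation studies, and the simulation
harness to compare how well each prior recovers true linear trends.

## The problem

An outcome tabulated by age group `i = 1..I` and period group `j = 1..J`
(equal intervals) determines the birth cohort `k = j − i + I`, giving the
additive model

```
y_ij = b0 + bA_i + bP_j + bC_k + ε_ij,     ε ~ Normal(0, σ),
```

with each effect block summing to zero.  Because the centered indexes
satisfy `vA_i − vP_j + vC_k = 0`, the transformation

```
bA + s·vA,   bP − s·vP,   bC + s·vC        (any real s)
```

leaves every fitted mean unchanged: the *linear* components of the three
effects are not identified by the data.  Bayesian regularization resolves
the indeterminacy through the prior:

| model            | prior on effects                         | field analogue        |
|------------------|------------------------------------------|-----------------------|
| `random_effects` | `bX_m ~ N(0, σX)` per block              | multilevel / HAPC     |
| `ridge`          | `bX_m ~ N(0, λ)`, one shared scale       | intrinsic estimator   |
| `random_walk`    | `bX_{m+1} ~ N(bX_m, σX)` per block       | Bayesian cohort model |

Magnitude-shrinkage priors weight the three linear components by
`Σ vX²`, which grows like `M³`, so the longest block — always the cohort,
since `K = I + J − 1` — gets flattened hardest.  The random-walk prior
weights them by `M − 1` instead, and the package exposes the exact gap
between the two weighting schemes (`index_weight_gap`, positive for every
grid).

Recovery is measured by the bias statistic `s`: the identification shift
that best aligns the posterior-median effects with the true parameters
(closed form in `solve_s`).  `|s| < 0.02/0.04/0.06/0.08` is banded into
grades A–D, otherwise E; replicated studies are summarized by
`δ = mean(s²)` over converged runs.

## Worked example

```python
from apcbayes import (APCGrid, BayesianAPC, SamplerConfig,
                      make_trig_params, generate_data)

grid = APCGrid(10, 10)
# a pure cohort trend: slope +0.1 per cohort step, cosine wiggle 0.05
truth = make_trig_params(grid, slopes=(0, 0, 0.1), amps=(0, 0, 0.05), gamma=0.1)
data = generate_data(truth, replicates=10, seed=42)       # N = 1000

for kind in ("random_effects", "ridge", "random_walk"):
    res = BayesianAPC(data, kind).fit(SamplerConfig(seed=7))
    s, g = res.bias(truth)
    print(f"{kind:16s} s = {s:+.3f}  grade {g}  converged={res.converged}")
```

prints

```
random_effects   s = -0.097  grade E  converged=True
ridge            s = -0.077  grade D  converged=True
random_walk      s = -0.001  grade A  converged=True
```

The random-effects model reassigns nearly the whole cohort trend to the
age and period effects (`s ≈ −0.1` undoes a true slope of `+0.1`), ridge
reassigns about three quarters of it, and the random-walk prior recovers
the truth.  `res.summary()` gives the per-parameter medians, posterior
SDs and split-R̂ values behind these numbers.

The simulation drivers reproduce whole studies:

```python
from apcbayes import run_simulation1, run_simulation3
table = run_simulation1(SamplerConfig(seed=1)).table()   # 13 cases x 3 models
rep3 = run_simulation3(replicates=100, config=SamplerConfig(seed=1))
rep3.deltas   # {'random_effects': ..., 'ridge': ..., 'random_walk': ...}
```

A CLI mirrors the library: `apcbayes generate|fit|sim1|sim2|sim3|grade`
(see `apcbayes --help`).

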