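# prevchain

Discrete-time Markov chain forecasting of health-state prevalences, built
around a five-state chain for hypertension and its risk factors in Rwanda
(hypertension, tobacco use, overweight, obesity, and a residual "others"
state, with 2015 WHO STEPS survey marginals P = (0.153, 0.262, 0.143,
0.028, 0.417)).

The package is for epidemiologists and health planners who have repeated
cross-sectional prevalence estimates — not individual-level longitudinal
data — and want a transparent, reproducible multi-state projection with its
long-run behaviour and Monte-Carlo validation machinery in one place.

## Model

Let S = {1, …, k} be mutually exclusive health states and
x_t ∈ [0, 1]^k the prevalence row vector in year t. A row-stochastic
transition matrix T (rows = origin, columns = destination, 0 ≤ T_mn ≤ 1,
Σ_n T_mn = 1) drives the annual update

    x_{t+1} = x_t · T,

which conserves Σ x_t exactly. When only marginal prevalences P are
available, off-diagonal transition probabilities are constructed as a Bayes
posterior over destinations with the marginals as priors and a flat
likelihood, excluding the origin state from the normalizer:

    T_mn = P_n / Σ_{j≠m} P_j   (n ≠ m),

with the diagonal set to a small floor (default 1e-5) and the row
renormalized. For an irreducible aperiodic chain the iterates converge to
the stationary vector π with π·T = π, computed by left-eigenvector
extraction (power-iteration fallback).

Validation machinery: trajectory sampling from T (empirical occupancy →
π), a systematic-scan bivariate Gibbs sampler for an explicit joint table
p(x, y), and — on small tables — exact enumeration of the per-sweep Gibbs
kernel, whose stationary distribution provably equals the target joint; the
test suite checks this identity to 1e-9. A synthetic-data module generates
Dirichlet profiles, noisy multi-year panels, and individual trajectories
from known chains, and recovers T by maximum-likelihood row-normalized
transition counts for parameter-recovery checks.

## Worked example

```python
>>> import numpy as np
>>> from prevchain import fixtures, project, stationary_distribution
>>> series = project(fixtures.start_2015(), fixtures.reference_matrix(), 10)
>>> np.round(series.vector(2025) * 100, 2)
array([17.82, 26.26, 17.13,  4.8 , 33.99])
>>> np.round(stationary_distribution(fixtures.reference_matrix()), 5)
array([0.17821, 0.26266, 0.17128, 0.04805, 0.3398 ])
```

Starting from the 2015 prevalences, ten annual applications of the
reference matrix put hypertension at 17.82% in 2025 (tobacco use 26.26%,
overweight 17.13%, obesity 4.80%, others 33.99%); the ten-year forecast is
already within 5e-3 of the chain's stationary distribution. The same
pipeline is available from the shell:

```
$ prevchain reproduce-reference
...
checked 55 cells: 55 match, 0 mismatch, 2 annotated misprints
```

which recomputes the full 2015–2025 grid and diffs it against the
circulated reference table cell by cell. Two cells of that table are known
misprints (the 2016 tobacco value has a shifted decimal, "0.02789" for
0.2789, and the 2025 "others" cell is printed at 5 dp); the fixture stores
the table exactly as printed together with machine-readable annotations,
and comparisons consult the annotations. Note also that the construction
formula above reproduces only row 1 of the reference matrix (to 1e-4);
rows 2–5 — row 4 with its 0.214 diagonal especially — follow no stated
rule, and the worked intermediates that accompany the circulated
conditional-probability examples (0.0393, 0.1257, 0.02145, 0.1275) have no
recoverable definition (0.0393 = 0.262×0.15 and 0.1257 is consistent with
a typo for 0.1275 = 0.85×0.15, but neither yields rows 2–5). The matrix
therefore ships as a verbatim fixture and all forecasts iterate it as
printed.

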