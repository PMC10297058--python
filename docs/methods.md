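# Methods

## The chain and its orientation

The model is a time-homogeneous first-order Markov chain on k named,
mutually exclusive health states. The population-level prevalence row
vector x_t evolves by right-multiplication with a row-stochastic matrix,
x_{t+1} = x_t · T, with the fixed convention that **rows are origin states
and columns are destinations**. This orientation is a contract, not a
preference: with the reference Rwanda matrix, left-multiplication of the
row vector reproduces every cell of the circulated 2015–2025 forecast grid
to 4 dp, whereas multiplying powers of T into a column vector does not.
Every function in the package states and assumes this convention.

Two start vectors ship with the fixture: the 3-dp survey marginals
(0.153, 0.262, 0.143, 0.028, 0.417), which sum to 1.003, and the 4-dp
2015 column of the circulated grid (0.1500, …, 0.4170), which sums to 1.
Only the latter reproduces the 2016 column exactly, so grid reproduction
uses it; the survey profile is kept for the matrix-construction check.
Profiles are deliberately **not** renormalized to sum to 1 — reported
marginals routinely sum slightly off, and left-multiplication conserves
whatever the total is — a deviation is logged, never corrected silently.
Year indexing follows the reproduction: vector 0 is 2015 and each
application of T advances one calendar year.

## Matrix construction from marginals

With no longitudinal data, off-diagonal transition probabilities are taken
proportional to the destination-state marginals with the origin excluded
from the normalizer:

    T_mn = P_n / Σ_{j≠m} P_j  (n ≠ m)

equivalently a Bayes posterior with priors P (origin removed) and a flat
likelihood. The diagonal is set to `diagonal_floor` (default 1e-5, the
magnitude used on the diagonal of the reference matrix) and the row
rescaled to sum to exactly 1. The assumption encoded is that year-to-year
self-transition among these risk states is negligible; the one row of the
reference matrix that violates it (obesity, diagonal 0.214) is not
special-cased — the reference matrix is shipped verbatim and is never
recomputed, and reproduction runs always load it. Zero prevalences are
rejected rather than smoothed: the excluded-sum normalizer is ill-posed at
zero and no smoothing rule is part of the model.

Construction satisfies two exact properties used as tests: rows sum to 1
at machine precision for any valid profile, and relabelling states
conjugates the matrix by the same permutation.

## Long-run behaviour

`stationary_distribution` solves π·T = π by eigen-decomposition of Tᵀ,
requiring eigenvalue 1 to be simple and to be the only eigenvalue on the
unit circle; a repeated 1 (reducible chain) or another unit-modulus
eigenvalue (periodic chain, e.g. any permutation matrix) raises
"no unique stationary distribution" rather than returning a vector the
iterates never approach. If the eigenvector is numerically unusable the
solver falls back to deterministic power iteration (cap 1e5 steps, tol
1e-12); at k = 5 both routes are microseconds. π is scaled to a requested
total mass so it is comparable with profiles that do not sum to 1.
`convergence_horizon` reports the first step whose max-norm distance to π
drops below a tolerance, with an explicit `ConvergenceError` at its step
cap (default 1e4) instead of a silent truncation.

## Gibbs machinery

Two faithful pieces are exposed without conflating them: (a) trajectory
sampling from the k-state chain itself, whose empirical occupancy after
burn-in converges to π — the Monte-Carlo counterpart of the eigenvector
computation; and (b) a systematic-scan bivariate Gibbs sampler for an
explicitly supplied joint table p(x, y), alternating x ~ p(x|y) then
y ~ p(y|x) in that fixed order. No joint over pairs of health states is
implied by the forecasting model, so the bivariate sampler takes its joint
as an argument.

Because the state space is finite, Gibbs correctness is checked exactly
rather than by simulation alone: `gibbs_kernel_exact` enumerates the
composed two-half-step kernel K[(r,c),(r′,c′)] = p(r′|c)·p(c′|r′) over all
pairs and eigen-solves it; for strictly positive joints its stationary
distribution equals the target joint to 1e-9. Sampler defaults where no
convention is forced by the model: burn-in 10% of the run (configurable),
no thinning, categorical draws by inverse CDF on cumulative sums in state
order (zero-probability states occupy zero width and are never selected),
one `numpy` Generator per call seeded by a single integer, so identical
seeds give bit-identical output.

## Synthetic data and recovery

The generators emulate the three input shapes the pipeline consumes:
Dirichlet profiles on the simplex (symmetric, concentration default 1 =
uniform on the simplex); multi-year panels obtained by projecting a known
chain, optionally adding independent Gaussian observation noise (sd on the
proportion scale, default 0) truncated to [0, 1]; and individual
trajectories under the same time-homogeneous first-order dynamics the
forecast assumes, so recovery tests exercise exactly the forecast's model
class. The noise model is a deliberate simplification: it represents
generic measurement error, not the weighting, clustering, or multistage
design of an actual STEPS survey, so passing recovery tests demonstrate
estimator correctness under the model, not robustness to survey design
effects. `estimate_matrix_from_counts` is the ML estimator (row-normalized
pooled transition counts); origin states with no observed exits are
returned as missing rows and reported, never imputed.

Problem sizes used by the recovery and occupancy checks — 2,000
individuals × 200 steps, 2×10⁵-step trajectories over 5 seeds, 20 random
joints up to 4×4, 1,000 random construction/projection instances — were
chosen so that expected sampling error sits comfortably inside the asserted
bands (e.g. ≈4×10⁵ pooled transitions put the max entrywise ML error well
under the 0.02 bound) while the whole suite stays in the seconds range.

## Numerical choices and limitations

- Full-precision `repr` in all text formats; rounding is display-only
  (`--round`), so 4-dp comparisons are never double-rounded.
- The circulated reference grid contains two misprints (2016 tobacco
  "0.02789" → 0.2789; 2025 "others" printed at 5 dp). The fixture stores
  the grid as printed plus machine-readable annotations; comparisons
  consult the annotations rather than editing history away.
- Matrix validation tolerance is 1e-4 on row sums at the type and IO
  boundary (5-dp published matrices cannot do better); constructed
  matrices meet 1e-12 and `validate_stochastic` takes any tolerance.
- Whether the 2025 figures should be read as the 10th iterate or the
  stationary limit is left open — the two differ by < 5e-3 here — so both
  are exposed and neither is privileged beyond the grid-reproduction test.
- Known limitations: time-homogeneous transitions only (no covariates, age
  or sex structure, or period effects); no uncertainty quantification on
  forecasts; rows 2–5 of the reference matrix are not derivable from any
  stated construction and are treated as data.
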