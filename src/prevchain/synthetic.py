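"""Synthetic data generators and a transition-matrix recovery estimator.

Real inputs to the forecasting pipeline are marginal prevalences from
repeated cross-sectional surveys; no individual-level longitudinal data are
available. These generators emulate each input shape under a *known* chain
so that every stage can be exercised end to end:

* random prevalence profiles on the simplex (symmetric Dirichlet);
* multi-year prevalence panels produced by projecting a known transition
  matrix, optionally with additive truncated-Gaussian observation noise on
  each proportion (a deliberately simple stand-in for survey error — no
  weighting, clustering, or multistage design);
* individual-level state trajectories under time-homogeneous first-order
  Markov dynamics — exactly the model class the forecast assumes.

:func:`estimate_matrix_from_counts` closes the loop: row-normalized
transition counts are the maximum-likelihood estimate of the matrix, so
simulating trajectories from a known ``T`` and re-estimating it measures
parameter recovery at a given sample size.
"""

from __future__ import annotations

from dataclasses import dataclass
from collections.abc import Iterable, Sequence

import numpy as np
import numpy.typing as npt

from .core import DiscreteDistribution, PrevalenceProfile, StateSpace, TransitionMatrix
from .forecast import ForecastSeries, project
from .gibbs import Trajectory

__all__ = [
    "PanelSpec",
    "MatrixEstimate",
    "RecoveryReport",
    "random_profile",
    "simulate_panel",
    "simulate_trajectories",
    "estimate_matrix_from_counts",
    "recovery_report",
]


@dataclass(frozen=True)
class PanelSpec:
    """Specification of a synthetic multi-year prevalence panel.

    ``noise_scale`` is the standard deviation (on the proportion scale) of
    additive Gaussian observation noise applied independently to every
    observed value and truncated to [0, 1]; 0 gives the exact projected path.
    """

    state_space: StateSpace
    transition: TransitionMatrix
    start: PrevalenceProfile
    years: int
    noise_scale: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.transition.state_space != self.state_space:
            raise ValueError("transition matrix state space does not match")
        if self.start.state_space != self.state_space:
            raise ValueError("start profile state space does not match")
        if self.years < 1:
            raise ValueError("years must be >= 1")
        if self.noise_scale < 0:
            raise ValueError("noise_scale must be >= 0")


def _default_labels(k: int) -> tuple[str, ...]:
    return tuple(f"state{i + 1}" for i in range(k))


def random_profile(
    k: int,
    concentration: float = 1.0,
    seed: int | None = None,
    labels: Sequence[str] | None = None,
    year: int | None = None,
) -> PrevalenceProfile:
    """A strictly positive profile drawn from a symmetric Dirichlet.

    Large ``concentration`` concentrates mass near the uniform profile
    ``1/k``; ``concentration = 1`` is uniform on the simplex. The profile
    sums to 1 at machine precision.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if concentration <= 0:
        raise ValueError("concentration must be positive")
    rng = np.random.default_rng(seed)
    values = rng.dirichlet(np.full(k, float(concentration)))
    space = StateSpace(labels if labels is not None else _default_labels(k))
    return PrevalenceProfile(space, values, year=year)


def simulate_panel(spec: PanelSpec) -> ForecastSeries:
    """Generate a ``spec.years``-year prevalence panel from a known chain.

    With ``noise_scale == 0`` the result is bit-identical to
    ``project(spec.start, spec.transition, spec.years - 1)``. Otherwise each
    observed proportion is the true value plus seeded Gaussian noise, clipped
    to [0, 1]; such a panel no longer conserves total mass and is returned
    with ``mass_conserving=False``.
    """
    truth = project(spec.start, spec.transition, spec.years - 1)
    if spec.noise_scale == 0:
        return truth
    rng = np.random.default_rng(spec.seed)
    noisy = truth.vectors + rng.normal(0.0, spec.noise_scale, truth.vectors.shape)
    noisy = np.clip(noisy, 0.0, 1.0)
    return ForecastSeries(
        spec.state_space, truth.start_year, noisy, mass_conserving=False
    )


def simulate_trajectories(
    T: TransitionMatrix,
    n_individuals: int,
    length: int,
    initial: DiscreteDistribution,
    seed: int,
) -> list[Trajectory]:
    """Independent individual state trajectories under the chain ``T``.

    Initial states are drawn from ``initial``; each later state is drawn
    from the current origin row of ``T``. Sampling is vectorized across
    individuals per time step but fully determined by ``seed``.
    """
    k = T.size
    if n_individuals < 1:
        raise ValueError("n_individuals must be >= 1")
    if length < 2:
        raise ValueError("length must be >= 2")
    if len(initial.labels) != k:
        raise ValueError("initial distribution does not match the state space")
    rng = np.random.default_rng(seed)
    cdf = np.cumsum(T.entries, axis=1)
    cdf[:, -1] = 1.0
    init_cdf = np.cumsum(initial.probabilities)
    init_cdf[-1] = 1.0

    states = np.empty((n_individuals, length), dtype=np.int64)
    states[:, 0] = np.searchsorted(init_cdf, rng.random(n_individuals), side="right")
    np.clip(states[:, 0], 0, k - 1, out=states[:, 0])
    for t in range(1, length):
        u = rng.random(n_individuals)
        cur = states[:, t - 1]
        nxt = np.empty(n_individuals, dtype=np.int64)
        for s in range(k):
            mask = cur == s
            if mask.any():
                nxt[mask] = np.searchsorted(cdf[s], u[mask], side="right")
        np.clip(nxt, 0, k - 1, out=nxt)
        states[:, t] = nxt
    return [Trajectory(T.state_space, states[i], seed=seed) for i in range(n_individuals)]


@dataclass(frozen=True)
class MatrixEstimate:
    """Row-normalized transition counts: the ML estimate of a chain's matrix.

    Rows for origin states with no observed exits are NaN in ``matrix`` and
    listed in ``missing_rows`` — they are reported, never silently imputed.
    """

    state_space: StateSpace
    matrix: npt.NDArray[np.float64]
    counts: npt.NDArray[np.int_]
    missing_rows: tuple[int, ...] = ()

    @property
    def transition_matrix(self) -> TransitionMatrix:
        """The estimate as a validated :class:`TransitionMatrix`.

        Raises ``ValueError`` when some origin state was never observed to
        transition (its row is undefined).
        """
        if self.missing_rows:
            labels = [self.state_space.labels[i] for i in self.missing_rows]
            raise ValueError(f"no observed transitions out of state(s) {labels}")
        return TransitionMatrix(self.state_space, self.matrix)


def estimate_matrix_from_counts(
    trajectories: Iterable[Trajectory],
) -> MatrixEstimate:
    """Pool transitions across trajectories and row-normalize the counts."""
    trajectories = list(trajectories)
    if not trajectories:
        raise ValueError("no trajectories given")
    space = trajectories[0].state_space
    k = space.size
    counts = np.zeros((k, k), dtype=np.int64)
    for traj in trajectories:
        if traj.state_space != space:
            raise ValueError("trajectories use different state spaces")
        s = traj.states
        if len(s) >= 2:
            np.add.at(counts, (s[:-1], s[1:]), 1)
    row_totals = counts.sum(axis=1)
    if row_totals.sum() == 0:
        raise ValueError("no transitions observed")
    matrix = np.full((k, k), np.nan)
    missing = []
    for m in range(k):
        if row_totals[m] > 0:
            matrix[m] = counts[m] / row_totals[m]
        else:
            missing.append(m)
    matrix.flags.writeable = False
    counts.flags.writeable = False
    return MatrixEstimate(space, matrix, counts, tuple(missing))


@dataclass(frozen=True)
class RecoveryReport:
    """Elementwise error summary between a true and an estimated matrix."""

    max_abs_error: float
    mean_abs_error: float
    per_row_max: npt.NDArray[np.float64]
    labels: tuple[str, ...] = ()


def recovery_report(
    truth: TransitionMatrix,
    estimate: TransitionMatrix | MatrixEstimate | npt.NDArray[np.float64],
) -> RecoveryReport:
    """Deterministic elementwise comparison; no row re-alignment is attempted.

    A permuted-state estimate therefore shows large errors rather than being
    silently matched back to the truth.
    """
    if isinstance(estimate, MatrixEstimate):
        if estimate.state_space != truth.state_space:
            raise ValueError("state spaces differ")
        est = estimate.matrix
    elif isinstance(estimate, TransitionMatrix):
        if estimate.state_space != truth.state_space:
            raise ValueError("state spaces differ")
        est = estimate.entries
    else:
        est = np.asarray(estimate, dtype=float)
    if est.shape != truth.entries.shape:
        raise ValueError(f"shape mismatch: {est.shape} vs {truth.entries.shape}")
    err = np.abs(est - truth.entries)
    per_row = err.max(axis=1)
    per_row.flags.writeable = False
    return RecoveryReport(
        max_abs_error=float(err.max()),
        mean_abs_error=float(err.mean()),
        per_row_max=per_row,
        labels=truth.state_space.labels,
    )
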