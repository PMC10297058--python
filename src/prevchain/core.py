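"""Domain types for finite-state prevalence chains and transition-matrix construction.

The central objects are a named finite state space (mutually exclusive health
states such as hypertension, tobacco use, overweight, obesity, and a residual
"others" category), a prevalence profile giving the proportion of the
population in each state at a reference time, and a row-stochastic transition
matrix ``T`` whose entry ``T[m, n]`` is the one-step probability of moving
from state ``m`` to state ``n``.

Orientation contract (fixed everywhere in this package): **rows are origin
states, columns are destination states**; forecasts therefore evolve a row
vector by right-multiplication, ``x_{t+1} = x_t @ T``.

When only marginal prevalences are available (no longitudinal data), a
transition matrix can be constructed by treating the conditional distribution
of the destination state, given that the chain leaves state ``m``, as the
destination marginals renormalized with the origin state excluded:

    T[m, n] = P[n] / sum_{j != m} P[j]        (n != m)

i.e. a Bayes posterior over destinations with the marginal prevalences as
priors and a constant likelihood. Diagonals are set to a small floor and the
row renormalized, reflecting the assumption that remaining in the same risk
state from one annual survey to the next is treated as negligible.
"""

from __future__ import annotations

import logging
from collections.abc import Mapping, Sequence
from dataclasses import dataclass

import numpy as np
import numpy.typing as npt

logger = logging.getLogger(__name__)

__all__ = [
    "StateSpace",
    "PrevalenceProfile",
    "TransitionMatrix",
    "DiscreteDistribution",
    "bayes_posterior",
    "build_transition_matrix",
    "validate_stochastic",
]


@dataclass(frozen=True)
class StateSpace:
    """An ordered set of named, mutually exclusive states."""

    labels: tuple[str, ...]

    def __init__(self, labels: Sequence[str]) -> None:
        object.__setattr__(self, "labels", tuple(labels))
        if len(self.labels) < 2:
            raise ValueError("a state space needs at least 2 states")
        if any(not isinstance(s, str) or not s for s in self.labels):
            raise ValueError("state labels must be non-empty strings")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("state labels must be unique")

    @property
    def size(self) -> int:
        return len(self.labels)

    def index(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise KeyError(f"unknown state {label!r}") from None

    def __iter__(self):
        return iter(self.labels)

    def __len__(self) -> int:
        return len(self.labels)


@dataclass(frozen=True)
class PrevalenceProfile:
    """Per-state prevalence proportions at a reference time.

    Values live on the 0-1 scale. The total is *not* forced to 1: marginal
    prevalences reported to limited precision routinely sum slightly off
    (e.g. 1.003); a deviation is logged, never rejected, as long as the total
    stays in (0, 2].
    """

    state_space: StateSpace
    values: npt.NDArray[np.float64]
    year: int | None = None

    def __init__(
        self,
        state_space: StateSpace,
        values: Sequence[float] | npt.NDArray[np.float64],
        year: int | None = None,
    ) -> None:
        arr = np.asarray(values, dtype=float)
        arr.flags.writeable = False
        object.__setattr__(self, "state_space", state_space)
        object.__setattr__(self, "values", arr)
        object.__setattr__(self, "year", year)
        if arr.shape != (state_space.size,):
            raise ValueError(
                f"expected {state_space.size} values, got shape {arr.shape}"
            )
        if np.any(arr < 0) or np.any(arr > 1):
            raise ValueError("prevalence values must lie in [0, 1]")
        total = float(arr.sum())
        if not 0 < total <= 2:
            raise ValueError(f"prevalence total {total} outside (0, 2]")
        if abs(total - 1.0) > 1e-6:
            logger.warning("prevalence profile sums to %.6f, not 1", total)

    @property
    def total(self) -> float:
        return float(self.values.sum())

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.state_space.labels, self.values.tolist()))


#: slack allowed on entries/row sums when accepting an externally supplied matrix
_ENTRY_EPS = 1e-12
_ROW_SUM_TOL = 1e-4


@dataclass(frozen=True)
class TransitionMatrix:
    """A row-stochastic matrix over a state space.

    ``entries[m, n]`` is the probability of a one-step transition from origin
    state ``m`` (row) to destination state ``n`` (column). Rows must sum to 1
    within a loose tolerance (1e-4, accommodating matrices published at
    limited precision); matrices built by :func:`build_transition_matrix` sum
    to 1 at machine precision.
    """

    state_space: StateSpace
    entries: npt.NDArray[np.float64]

    def __init__(
        self,
        state_space: StateSpace,
        entries: Sequence[Sequence[float]] | npt.NDArray[np.float64],
    ) -> None:
        arr = np.asarray(entries, dtype=float)
        arr.flags.writeable = False
        object.__setattr__(self, "state_space", state_space)
        object.__setattr__(self, "entries", arr)
        k = state_space.size
        if arr.shape != (k, k):
            raise ValueError(f"expected a {k}x{k} matrix, got shape {arr.shape}")
        problems = validate_stochastic(arr, tol=_ROW_SUM_TOL, labels=state_space.labels)
        if problems:
            raise ValueError("not row-stochastic: " + "; ".join(problems))

    @property
    def size(self) -> int:
        return self.state_space.size

    def row(self, origin: str) -> npt.NDArray[np.float64]:
        return self.entries[self.state_space.index(origin)]


@dataclass(frozen=True)
class DiscreteDistribution:
    """A probability distribution over finitely many labelled outcomes."""

    labels: tuple[str, ...]
    probabilities: npt.NDArray[np.float64]

    def __init__(
        self,
        labels: Sequence[str],
        probabilities: Sequence[float] | npt.NDArray[np.float64],
    ) -> None:
        labs = tuple(labels)
        arr = np.asarray(probabilities, dtype=float)
        arr.flags.writeable = False
        object.__setattr__(self, "labels", labs)
        object.__setattr__(self, "probabilities", arr)
        if arr.shape != (len(labs),):
            raise ValueError("one probability per outcome required")
        if np.any(arr < 0):
            raise ValueError("probabilities must be nonnegative")
        if abs(float(arr.sum()) - 1.0) > 1e-9:
            raise ValueError(f"probabilities sum to {arr.sum()}, not 1")

    def __getitem__(self, label: str) -> float:
        return float(self.probabilities[self.labels.index(label)])


def bayes_posterior(
    priors: DiscreteDistribution,
    likelihoods: Mapping[str, float] | Sequence[float] | npt.NDArray[np.float64],
) -> DiscreteDistribution:
    """Posterior over outcomes: normalize prior x likelihood.

    ``likelihoods`` may be a mapping keyed by outcome label or a sequence
    aligned with ``priors.labels``. Raises ``ValueError`` if the outcome sets
    differ, a likelihood is negative, or every product is zero (degenerate
    posterior).
    """
    if isinstance(likelihoods, Mapping):
        if set(likelihoods) != set(priors.labels):
            raise ValueError("likelihood outcomes do not match prior outcomes")
        lik = np.array([float(likelihoods[lab]) for lab in priors.labels])
    else:
        lik = np.asarray(likelihoods, dtype=float)
        if lik.shape != (len(priors.labels),):
            raise ValueError("likelihood outcomes do not match prior outcomes")
    if np.any(lik < 0):
        raise ValueError("likelihoods must be nonnegative")
    products = priors.probabilities * lik
    total = float(products.sum())
    if total <= 0:
        raise ValueError("degenerate posterior: all prior x likelihood products are zero")
    return DiscreteDistribution(priors.labels, products / total)


def build_transition_matrix(
    profile: PrevalenceProfile,
    diagonal_floor: float = 1e-5,
) -> TransitionMatrix:
    """Construct a transition matrix from marginal prevalences.

    For each origin state ``m`` the off-diagonal row is the Bayes posterior
    over destinations with the marginal prevalences (origin excluded) as
    priors and a flat likelihood:

        T[m, n] = P[n] / sum_{j != m} P[j],   n != m.

    The diagonal is set to ``diagonal_floor`` and the row rescaled to sum to
    exactly 1. All prevalences must be strictly positive (a zero prevalence
    makes the excluded-sum normalizer ill-posed and is rejected rather than
    smoothed).
    """
    values = profile.values
    k = profile.state_space.size
    if not 0 <= diagonal_floor < 1:
        raise ValueError("diagonal_floor must lie in [0, 1)")
    if np.any(values <= 0):
        bad = [
            lab for lab, v in zip(profile.state_space.labels, values) if v <= 0
        ]
        raise ValueError(f"zero prevalence for state(s) {bad}: construction undefined")
    entries = np.empty((k, k))
    for m in range(k):
        off = values.copy()
        off[m] = 0.0
        off /= off.sum()
        entries[m] = off * (1.0 - diagonal_floor)
        entries[m, m] = diagonal_floor
    return TransitionMatrix(profile.state_space, entries)


def validate_stochastic(
    matrix: TransitionMatrix | npt.NDArray[np.float64],
    tol: float = 1e-6,
    labels: Sequence[str] | None = None,
) -> list[str]:
    """Check row-stochasticity; return a list of human-readable violations.

    An empty list means every entry lies in [0, 1] and every row sums to 1
    within ``tol``. Accepts either a :class:`TransitionMatrix` or a raw square
    array (so that invalid candidate matrices can be diagnosed before
    construction). A non-square array raises ``ValueError``.
    """
    if isinstance(matrix, TransitionMatrix):
        arr = matrix.entries
        labels = matrix.state_space.labels
    else:
        arr = np.asarray(matrix, dtype=float)
    if arr.ndim != 2 or arr.shape[0] != arr.shape[1]:
        raise ValueError(f"matrix is not square: shape {arr.shape}")
    k = arr.shape[0]
    if labels is None:
        labels = [str(i) for i in range(k)]
    problems: list[str] = []
    for m in range(k):
        for n in range(k):
            v = arr[m, n]
            if not (-_ENTRY_EPS <= v <= 1 + _ENTRY_EPS):
                problems.append(
                    f"entry ({labels[m]} -> {labels[n]}) = {v} outside [0, 1]"
                )
        s = float(arr[m].sum())
        if abs(s - 1.0) > tol:
            problems.append(f"row {labels[m]} sums to {s} (off by {s - 1.0:+g})")
    return problems
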