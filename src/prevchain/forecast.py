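"""Iterated-matrix prevalence forecasting and long-run behaviour.

A prevalence row vector ``x_t`` is advanced one year at a time by
right-multiplication with the row-stochastic transition matrix,
``x_{t+1} = x_t @ T``. Because every row of ``T`` sums to 1, the total mass
``sum(x_t)`` is conserved exactly along the forecast, so a profile whose
marginals sum to 1.003 keeps summing to 1.003 at every horizon.

For an irreducible aperiodic chain the iterates converge to the unique
stationary vector ``pi`` with ``pi @ T = pi``; :func:`stationary_distribution`
extracts it from the left eigenvector at eigenvalue 1 (with a deterministic
power-iteration fallback) and :func:`convergence_horizon` reports how many
annual steps are needed to come within a given max-norm tolerance of it.
"""

from __future__ import annotations

from dataclasses import dataclass
from collections.abc import Sequence

import numpy as np
import numpy.typing as npt
import pandas as pd

from .core import PrevalenceProfile, StateSpace, TransitionMatrix

__all__ = [
    "ForecastSeries",
    "ConvergenceError",
    "step",
    "project",
    "stationary_distribution",
    "convergence_horizon",
]


class ConvergenceError(RuntimeError):
    """Raised when an iteration fails to converge within its step cap."""


@dataclass(frozen=True)
class ForecastSeries:
    """A year-indexed sequence of prevalence vectors.

    ``vectors`` has one row per year, starting at ``start_year``. By default
    the series must conserve total mass (each row sums to the row-0 total
    within 1e-9), which is the invariant of a noiseless projection; pass
    ``mass_conserving=False`` for observed/noisy panels where that identity
    intentionally fails.
    """

    state_space: StateSpace
    start_year: int
    vectors: npt.NDArray[np.float64]
    mass_conserving: bool = True

    def __init__(
        self,
        state_space: StateSpace,
        start_year: int,
        vectors: Sequence[Sequence[float]] | npt.NDArray[np.float64],
        mass_conserving: bool = True,
    ) -> None:
        arr = np.asarray(vectors, dtype=float)
        arr.flags.writeable = False
        object.__setattr__(self, "state_space", state_space)
        object.__setattr__(self, "start_year", int(start_year))
        object.__setattr__(self, "vectors", arr)
        object.__setattr__(self, "mass_conserving", bool(mass_conserving))
        if arr.ndim != 2 or arr.shape[1] != state_space.size:
            raise ValueError(
                f"expected (n_years, {state_space.size}) vectors, got {arr.shape}"
            )
        if arr.shape[0] < 1:
            raise ValueError("a forecast series needs at least one year")
        if np.any(arr < -1e-12) or np.any(arr > 1 + 1e-12):
            raise ValueError("prevalence entries must lie in [0, 1]")
        if mass_conserving:
            totals = arr.sum(axis=1)
            if np.any(np.abs(totals - totals[0]) > 1e-9):
                raise ValueError("projected vectors do not conserve total mass")

    @property
    def years(self) -> npt.NDArray[np.int_]:
        return self.start_year + np.arange(self.vectors.shape[0])

    @property
    def horizon(self) -> int:
        return self.vectors.shape[0] - 1

    def vector(self, year: int) -> npt.NDArray[np.float64]:
        offset = year - self.start_year
        if not 0 <= offset < self.vectors.shape[0]:
            raise KeyError(f"year {year} outside forecast range")
        return self.vectors[offset]

    def component(self, state: str) -> npt.NDArray[np.float64]:
        """The full time series for one state."""
        return self.vectors[:, self.state_space.index(state)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.vectors,
            index=pd.Index(self.years, name="year"),
            columns=list(self.state_space.labels),
        )


def step(
    x: Sequence[float] | npt.NDArray[np.float64],
    T: TransitionMatrix,
) -> npt.NDArray[np.float64]:
    """Advance a prevalence row vector one step: ``y[n] = sum_m x[m] T[m, n]``."""
    arr = np.asarray(x, dtype=float)
    if arr.shape != (T.size,):
        raise ValueError(f"vector length {arr.shape} does not match {T.size} states")
    return arr @ T.entries


def project(
    x0: PrevalenceProfile,
    T: TransitionMatrix,
    horizon: int,
    start_year: int | None = None,
) -> ForecastSeries:
    """Iterate the chain ``horizon`` steps from ``x0``.

    Returns ``horizon + 1`` vectors: index 0 is ``x0`` itself, index ``t`` is
    ``x0 @ T^t``. Year labels start at ``start_year`` (default: the profile's
    own year, else 0).
    """
    if x0.state_space != T.state_space:
        raise ValueError("profile and matrix state spaces differ")
    if horizon < 0:
        raise ValueError("horizon must be >= 0")
    if start_year is None:
        start_year = x0.year if x0.year is not None else 0
    out = np.empty((horizon + 1, T.size))
    out[0] = x0.values
    for t in range(horizon):
        out[t + 1] = out[t] @ T.entries
    return ForecastSeries(T.state_space, start_year, out)


def _power_iteration(
    entries: npt.NDArray[np.float64],
    max_steps: int = 100_000,
    tol: float = 1e-12,
) -> npt.NDArray[np.float64]:
    k = entries.shape[0]
    x = np.full(k, 1.0 / k)
    for _ in range(max_steps):
        y = x @ entries
        if np.max(np.abs(y - x)) < tol:
            return y
        x = y
    raise ConvergenceError("power iteration did not converge")


def stationary_distribution(
    T: TransitionMatrix,
    total_mass: float = 1.0,
) -> npt.NDArray[np.float64]:
    """The unique stationary vector ``pi`` with ``pi @ T = pi``, scaled to ``total_mass``.

    Solved by left-eigenvector extraction at eigenvalue 1; if the eigen route
    yields a numerically unusable vector, a deterministic power iteration
    (cap 1e5 steps, tol 1e-12) is used instead. Raises ``ValueError`` when no
    unique stationary distribution exists: eigenvalue 1 is repeated (the chain
    is reducible) or another eigenvalue lies on the unit circle (the chain is
    periodic, so iterates never settle).
    """
    entries = T.entries
    eigvals, eigvecs = np.linalg.eig(entries.T)
    near_one = np.abs(eigvals - 1.0) < 1e-9
    if near_one.sum() != 1:
        raise ValueError("no unique stationary distribution (reducible chain)")
    on_circle = np.abs(np.abs(eigvals) - 1.0) < 1e-9
    if on_circle.sum() != 1:
        raise ValueError("no unique stationary distribution (periodic chain)")
    vec = np.real(eigvecs[:, int(np.argmax(near_one))])
    if vec.sum() < 0:
        vec = -vec
    if np.any(vec < -1e-8) or vec.sum() <= 0:
        vec = _power_iteration(entries)
    pi = np.clip(vec, 0.0, None)
    pi = pi / pi.sum()
    if np.max(np.abs(pi @ entries - pi)) > 1e-9:
        pi = _power_iteration(entries)
        pi = pi / pi.sum()
    return pi * total_mass


def convergence_horizon(
    x0: Sequence[float] | npt.NDArray[np.float64] | PrevalenceProfile,
    T: TransitionMatrix,
    tol: float,
    max_steps: int = 10_000,
) -> int:
    """Smallest ``t`` with ``max |x0 @ T^t - pi| < tol``.

    The stationary vector is scaled to the total mass of ``x0`` so the
    comparison is meaningful for profiles that do not sum to exactly 1.
    Raises :class:`ConvergenceError` if the cap ``max_steps`` is reached
    first, and ``ValueError`` if the chain has no unique stationary
    distribution.
    """
    if tol <= 0:
        raise ValueError("tol must be positive")
    x = np.asarray(x0.values if isinstance(x0, PrevalenceProfile) else x0, dtype=float)
    pi = stationary_distribution(T, total_mass=float(x.sum()))
    for t in range(max_steps + 1):
        if np.max(np.abs(x - pi)) < tol:
            return t
        x = x @ T.entries
    raise ConvergenceError(f"not converged to tol={tol} within {max_steps} steps")
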