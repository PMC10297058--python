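"""Gibbs/Monte-Carlo sampling on finite state spaces.

Two complementary pieces:

* trajectory sampling from a row-stochastic transition matrix — long runs
  visit each state with frequency approaching the stationary distribution,
  which is the Monte-Carlo check that the forecasting chain and its
  closed-form long-run behaviour agree;
* a systematic-scan bivariate Gibbs sampler for an explicit joint table
  ``p(x, y)``, alternating draws from the conditionals ``p(x | y)`` and
  ``p(y | x)`` (row variable first), together with an exact enumeration of
  its per-sweep transition kernel. On small tables the kernel's stationary
  distribution can be eigen-solved directly and compared to the target
  joint, turning the Gibbs-correctness property into a machine-checkable
  statement rather than a sampling approximation.

All samplers draw categoricals by inverse CDF on cumulative sums in state
order (zero-probability states occupy zero width and are never selected),
from a single ``numpy`` generator seeded with one integer, so identical
seeds give bit-identical trajectories.
"""

from __future__ import annotations

from dataclasses import dataclass
from collections.abc import Sequence

import numpy as np
import numpy.typing as npt

from .core import DiscreteDistribution, StateSpace, TransitionMatrix

__all__ = [
    "Trajectory",
    "JointTable",
    "PairTrajectory",
    "ExactGibbsKernel",
    "sample_trajectory",
    "gibbs_scan_bivariate",
    "gibbs_kernel_exact",
    "empirical_occupancy",
]


@dataclass(frozen=True)
class Trajectory:
    """A sampled state-index sequence from a finite chain."""

    state_space: StateSpace
    states: npt.NDArray[np.int_]
    seed: int | None = None

    def __init__(
        self,
        state_space: StateSpace,
        states: Sequence[int] | npt.NDArray[np.int_],
        seed: int | None = None,
    ) -> None:
        arr = np.asarray(states, dtype=np.int64)
        arr.flags.writeable = False
        object.__setattr__(self, "state_space", state_space)
        object.__setattr__(self, "states", arr)
        object.__setattr__(self, "seed", seed)
        if arr.ndim != 1 or arr.shape[0] < 1:
            raise ValueError("a trajectory needs at least one state")
        if np.any(arr < 0) or np.any(arr >= state_space.size):
            raise ValueError("trajectory contains invalid state indices")

    def __len__(self) -> int:
        return int(self.states.shape[0])


@dataclass(frozen=True)
class JointTable:
    """A joint probability table over two categorical variables."""

    row_labels: tuple[str, ...]
    col_labels: tuple[str, ...]
    p: npt.NDArray[np.float64]

    def __init__(
        self,
        row_labels: Sequence[str],
        col_labels: Sequence[str],
        p: Sequence[Sequence[float]] | npt.NDArray[np.float64],
    ) -> None:
        arr = np.asarray(p, dtype=float)
        arr.flags.writeable = False
        object.__setattr__(self, "row_labels", tuple(row_labels))
        object.__setattr__(self, "col_labels", tuple(col_labels))
        object.__setattr__(self, "p", arr)
        if arr.shape != (len(self.row_labels), len(self.col_labels)):
            raise ValueError("joint table shape does not match labels")
        if np.any(arr < 0):
            raise ValueError("joint probabilities must be nonnegative")
        if abs(float(arr.sum()) - 1.0) > 1e-9:
            raise ValueError(f"joint probabilities sum to {arr.sum()}, not 1")

    @property
    def shape(self) -> tuple[int, int]:
        return self.p.shape  # type: ignore[return-value]


@dataclass(frozen=True)
class PairTrajectory:
    """(row, column) index pairs emitted by the bivariate Gibbs scan."""

    row_labels: tuple[str, ...]
    col_labels: tuple[str, ...]
    pairs: npt.NDArray[np.int_]  # shape (n, 2): initial point + one per sweep
    seed: int | None = None

    def __len__(self) -> int:
        return int(self.pairs.shape[0])


def _draw(cdf: npt.NDArray[np.float64], u: float) -> int:
    """Inverse-CDF categorical draw; zero-width (zero-probability) bins are skipped."""
    return min(int(np.searchsorted(cdf, u, side="right")), cdf.shape[0] - 1)


def sample_trajectory(
    T: TransitionMatrix,
    start_state: int,
    length: int,
    seed: int,
) -> Trajectory:
    """Sample a state trajectory of ``length`` steps from the chain ``T``.

    State 0 is ``start_state``; each subsequent state is drawn from the
    current origin's row by inverse CDF. Identical seeds reproduce identical
    trajectories bit for bit.
    """
    k = T.size
    if not 0 <= start_state < k:
        raise ValueError(f"start_state {start_state} outside [0, {k})")
    if length < 1:
        raise ValueError("length must be >= 1")
    cdf = np.cumsum(T.entries, axis=1)
    cdf[:, -1] = 1.0  # guard against rounding in the last bin
    rng = np.random.default_rng(seed)
    u = rng.random(length - 1)
    states = np.empty(length, dtype=np.int64)
    states[0] = start_state
    s = start_state
    for t in range(length - 1):
        s = _draw(cdf[s], u[t])
        states[t + 1] = s
    return Trajectory(T.state_space, states, seed=seed)


def gibbs_scan_bivariate(
    joint: JointTable,
    initial: tuple[int, int],
    sweeps: int,
    seed: int,
) -> PairTrajectory:
    """Systematic-scan Gibbs sampler for a bivariate joint table.

    Each sweep performs two half-steps in fixed order: first the row variable
    is redrawn from ``p(x | y=current)``, then the column variable from
    ``p(y | x=new)``. The output holds the initial pair followed by one pair
    per sweep. A conditioning slice with zero total mass raises
    ``ValueError`` ("degenerate conditional") at the moment it is needed.
    """
    kr, kc = joint.shape
    r, c = initial
    if not (0 <= r < kr and 0 <= c < kc):
        raise ValueError(f"initial pair {initial} outside the table")
    if sweeps < 1:
        raise ValueError("sweeps must be >= 1")

    col_mass = joint.p.sum(axis=0)
    row_mass = joint.p.sum(axis=1)
    # conditional CDFs; columns/rows with zero mass stay None and trip an
    # error only if the scan actually conditions on them
    x_cdf = [
        np.cumsum(joint.p[:, j] / col_mass[j]) if col_mass[j] > 0 else None
        for j in range(kc)
    ]
    y_cdf = [
        np.cumsum(joint.p[i, :] / row_mass[i]) if row_mass[i] > 0 else None
        for i in range(kr)
    ]

    rng = np.random.default_rng(seed)
    u = rng.random((sweeps, 2))
    pairs = np.empty((sweeps + 1, 2), dtype=np.int64)
    pairs[0] = (r, c)
    for t in range(sweeps):
        cdf = x_cdf[c]
        if cdf is None:
            raise ValueError(f"degenerate conditional: column {c} has zero mass")
        r = _draw(cdf, u[t, 0])
        cdf = y_cdf[r]
        if cdf is None:
            raise ValueError(f"degenerate conditional: row {r} has zero mass")
        c = _draw(cdf, u[t, 1])
        pairs[t + 1] = (r, c)
    pairs.flags.writeable = False
    return PairTrajectory(joint.row_labels, joint.col_labels, pairs, seed=seed)


@dataclass(frozen=True)
class ExactGibbsKernel:
    """Enumerated per-sweep Gibbs kernel over all (row, column) pair states.

    Pair ``(r, c)`` maps to flat index ``r * n_cols + c``. For a strictly
    positive joint the kernel's stationary distribution equals the target
    joint — the exact statement of Gibbs-sampler correctness on a finite
    table.
    """

    row_labels: tuple[str, ...]
    col_labels: tuple[str, ...]
    kernel: npt.NDArray[np.float64]  # (kr*kc, kr*kc), row-stochastic
    stationary: npt.NDArray[np.float64]  # flat, length kr*kc

    @property
    def stationary_table(self) -> npt.NDArray[np.float64]:
        return self.stationary.reshape(len(self.row_labels), len(self.col_labels))


def gibbs_kernel_exact(joint: JointTable) -> ExactGibbsKernel:
    """Enumerate the two-half-step Gibbs kernel and its stationary distribution.

    The kernel composes the x-update and y-update of one sweep:

        K[(r, c), (r', c')] = p(r' | y=c) * p(c' | x=r')

    (independent of ``r``, as the x-update overwrites it). Requires every
    row and column of the joint to carry positive mass, otherwise some
    conditional is undefined.
    """
    p = joint.p
    kr, kc = joint.shape
    col_mass = p.sum(axis=0)
    row_mass = p.sum(axis=1)
    if np.any(col_mass <= 0) or np.any(row_mass <= 0):
        raise ValueError("degenerate conditional: zero-mass row or column")
    x_given_y = p / col_mass  # [r', c] = p(r' | y=c)
    y_given_x = p / row_mass[:, None]  # [r', c'] = p(c' | x=r')
    # K[(r,c),(r',c')] = x_given_y[r', c] * y_given_x[r', c']
    n = kr * kc
    kernel = np.empty((n, n))
    for c in range(kc):
        block = x_given_y[:, c][:, None] * y_given_x  # (r', c')
        flat = block.reshape(-1)
        for r in range(kr):
            kernel[r * kc + c] = flat

    eigvals, eigvecs = np.linalg.eig(kernel.T)
    idx = int(np.argmin(np.abs(eigvals - 1.0)))
    pi = np.real(eigvecs[:, idx])
    if pi.sum() < 0:
        pi = -pi
    pi = np.clip(pi, 0.0, None)
    pi = pi / pi.sum()
    pi.flags.writeable = False
    kernel.flags.writeable = False
    return ExactGibbsKernel(joint.row_labels, joint.col_labels, kernel, pi)


def empirical_occupancy(traj: Trajectory, burn_in: int = 0) -> DiscreteDistribution:
    """Relative state frequencies over the post-burn-in segment of a trajectory."""
    if burn_in < 0:
        raise ValueError("burn_in must be >= 0")
    if burn_in >= len(traj):
        raise ValueError(f"burn_in {burn_in} >= trajectory length {len(traj)}")
    counts = np.bincount(traj.states[burn_in:], minlength=traj.state_space.size)
    return DiscreteDistribution(traj.state_space.labels, counts / counts.sum())
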