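"""Reference fixture: the Rwanda five-state hypertension chain.

The 2015 Rwanda WHO STEPS risk-factor survey gives marginal prevalences for
five mutually exclusive states — hypertension 15.3%, tobacco use 26.2%,
overweight 14.3%, obesity 2.8%, and a residual "others" 41.7%. A published
ten-year forecast of these prevalences iterates a 5x5 transition matrix
derived from those marginals from 2015 to 2025.

This module ships those reference values verbatim:

* :data:`REFERENCE_MATRIX` — the circulated 5x5 transition matrix at 5 dp.
  Its first row equals the excluded-sum construction from the survey
  marginals to within 1e-4; rows 2-5 deviate from any stated construction
  (row 4 substantially, with a 0.214 diagonal), so the matrix is stored and
  loaded as printed, never recomputed.
* :func:`start_2015` — the 2015 column of the circulated forecast table
  (0.1500, 0.2620, 0.1430, 0.0280, 0.4170), the start vector that reproduces
  the table exactly.
* :func:`survey_profile` — the 3-dp survey marginals (0.153, ...), which sum
  to 1.003; useful for the matrix-construction check.
* :data:`REFERENCE_TABLE` — the full circulated 2015-2025 grid, exactly as
  printed, with two known misprints machine-annotated in :data:`TYPOS`
  (the 2016 tobacco cell shows a shifted decimal, and the 2025 "others"
  cell is printed at 5 dp instead of 4).

Fixture values are data, not code: they are only ever loaded, and
reproduction tests compare freshly computed forecasts against them.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import PrevalenceProfile, StateSpace, TransitionMatrix
from .forecast import ForecastSeries, project

__all__ = [
    "STATE_SPACE",
    "REFERENCE_MATRIX",
    "REFERENCE_TABLE",
    "TYPOS",
    "TypoAnnotation",
    "start_2015",
    "survey_profile",
    "reference_matrix",
    "reference_table",
    "reference_forecast",
]

STATE_SPACE = StateSpace(
    ("hypertension", "tobacco_use", "overweight", "obesity", "others")
)

#: rows = origin state, columns = destination state, as circulated (5 dp)
_MATRIX_ENTRIES = np.array(
    [
        [0.00001, 0.30823, 0.16823, 0.03294, 0.49059],
        [0.20325, 0.00001, 0.19378, 0.03796, 0.56500],
        [0.17503, 0.30575, 0.00000, 0.03264, 0.48658],
        [0.15430, 0.05546, 0.14695, 0.21419, 0.42910],
        [0.25729, 0.44938, 0.24528, 0.04804, 0.00001],
    ]
)

REFERENCE_MATRIX = TransitionMatrix(STATE_SPACE, _MATRIX_ENTRIES)

_START_2015 = (0.1500, 0.2620, 0.1430, 0.0280, 0.4170)
_SURVEY_2015 = (0.153, 0.262, 0.143, 0.028, 0.417)  # sums to 1.003

#: circulated annual-prevalence grid, one row per year 2015-2025, exactly as
#: printed (including the two misprints annotated in TYPOS)
REFERENCE_TABLE = np.array(
    [
        # hypertension, tobacco_use, overweight, obesity, others
        [0.1500, 0.2620, 0.1430, 0.0280, 0.4170],  # 2015
        [0.1899, 0.02789, 0.1824, 0.0456, 0.3032],  # 2016
        [0.1737, 0.2531, 0.1671, 0.0471, 0.3591],  # 2017
        [0.1803, 0.2686, 0.1733, 0.0481, 0.3297],  # 2018
        [0.1772, 0.2594, 0.1703, 0.0479, 0.3452],  # 2019
        [0.1787, 0.2645, 0.1718, 0.0481, 0.3369],  # 2020
        [0.1779, 0.2617, 0.1710, 0.0480, 0.3413],  # 2021
        [0.1784, 0.2632, 0.1714, 0.0481, 0.3390],  # 2022
        [0.1781, 0.2624, 0.1712, 0.0480, 0.3402],  # 2023
        [0.1783, 0.2628, 0.1713, 0.0481, 0.3396],  # 2024
        [0.1782, 0.2626, 0.1713, 0.0480, 0.33999],  # 2025
    ]
)
REFERENCE_TABLE.flags.writeable = False

START_YEAR = 2015


@dataclass(frozen=True)
class TypoAnnotation:
    """A known misprint in the circulated forecast grid."""

    year: int
    state: str
    printed: float
    corrected: float | None  # None: no 4-dp correction; compare within abs_tol
    abs_tol: float
    note: str


TYPOS = (
    TypoAnnotation(
        year=2016,
        state="tobacco_use",
        printed=0.02789,
        corrected=0.2789,
        abs_tol=5e-5,
        note="decimal shifted one place; context (2015: 0.2620, 2017: 0.2531) "
        "and the freshly computed step fix it to 0.2789",
    ),
    TypoAnnotation(
        year=2025,
        state="others",
        printed=0.33999,
        corrected=None,
        abs_tol=1e-4,
        note="printed at 5 dp where the rest of the grid uses 4; compared "
        "within 1e-4 instead of by 4-dp rounding",
    ),
)


def start_2015() -> PrevalenceProfile:
    """The 2015 start vector of the circulated grid (sums to exactly 1)."""
    return PrevalenceProfile(STATE_SPACE, _START_2015, year=START_YEAR)


def survey_profile() -> PrevalenceProfile:
    """The 3-dp 2015 survey marginals (total 1.003, kept as reported)."""
    return PrevalenceProfile(STATE_SPACE, _SURVEY_2015, year=START_YEAR)


def reference_matrix() -> TransitionMatrix:
    """The circulated transition matrix (loaded verbatim, never recomputed)."""
    return REFERENCE_MATRIX


def reference_table(corrected: bool = True) -> np.ndarray:
    """The circulated 2015-2025 grid (years x states).

    With ``corrected=True`` the annotated misprints that have an unambiguous
    correction are fixed (the 2016 tobacco decimal shift); the 5-dp 2025
    "others" cell is left as printed either way.
    """
    grid = REFERENCE_TABLE.copy()
    if corrected:
        for typo in TYPOS:
            if typo.corrected is not None:
                y = typo.year - START_YEAR
                s = STATE_SPACE.index(typo.state)
                grid[y, s] = typo.corrected
    return grid


def reference_forecast(horizon: int = 10) -> ForecastSeries:
    """Freshly computed forecast from the fixture start vector and matrix."""
    return project(start_2015(), REFERENCE_MATRIX, horizon)
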