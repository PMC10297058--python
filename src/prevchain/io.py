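"""Readers and writers for the package's plain-text interchange formats.

Formats (all UTF-8 text):

* prevalence profile CSV — header ``state,value``, one row per state in
  state-space order; an optional leading comment line ``# year=YYYY``
  carries the reference year;
* transition matrix CSV — header ``state,<dest1>,...,<destk>``, one row per
  origin state; or JSON ``{"states": [...], "matrix": [[...]]}``;
* forecast series CSV — header ``year,<state1>,...,<statek>``, one row per
  year;
* joint table JSON — ``{"rows": [...], "cols": [...], "p": [[...]]}``.

Values are written with full ``repr`` precision so write -> read round-trips
are value-identical; rounding is a display concern handled by callers.
"""

from __future__ import annotations

import csv
import json
from pathlib import Path

import numpy as np

from .core import PrevalenceProfile, StateSpace, TransitionMatrix, validate_stochastic
from .forecast import ForecastSeries
from .gibbs import JointTable, Trajectory

__all__ = [
    "read_profile",
    "write_profile",
    "read_matrix",
    "write_matrix",
    "read_forecast",
    "write_forecast",
    "read_joint",
    "write_joint",
    "write_trajectory",
]


def _fmt(x: float) -> str:
    return repr(float(x))


def read_profile(path: str | Path) -> PrevalenceProfile:
    """Read a prevalence profile CSV; errors name the offending line."""
    path = Path(path)
    year: int | None = None
    labels: list[str] = []
    values: list[float] = []
    with path.open(newline="") as fh:
        lines = fh.read().splitlines()
    data_lines: list[tuple[int, str]] = []
    for lineno, line in enumerate(lines, start=1):
        stripped = line.strip()
        if not stripped:
            continue
        if stripped.startswith("#"):
            body = stripped.lstrip("#").strip()
            if body.startswith("year="):
                year = int(body.removeprefix("year="))
            continue
        data_lines.append((lineno, line))
    if not data_lines:
        raise ValueError(f"{path}: no data rows")
    header = next(csv.reader([data_lines[0][1]]))
    if [h.strip() for h in header] != ["state", "value"]:
        raise ValueError(f"{path}: line {data_lines[0][0]}: expected header 'state,value'")
    for lineno, line in data_lines[1:]:
        row = next(csv.reader([line]))
        if len(row) != 2:
            raise ValueError(f"{path}: line {lineno}: expected 2 fields, got {len(row)}")
        label = row[0].strip()
        try:
            value = float(row[1])
        except ValueError:
            raise ValueError(
                f"{path}: line {lineno}: non-numeric value {row[1]!r}"
            ) from None
        if not 0 <= value <= 1:
            raise ValueError(f"{path}: line {lineno}: value {value} outside [0, 1]")
        if label in labels:
            raise ValueError(f"{path}: line {lineno}: duplicate state {label!r}")
        labels.append(label)
        values.append(value)
    return PrevalenceProfile(StateSpace(labels), values, year=year)


def write_profile(path: str | Path, profile: PrevalenceProfile) -> None:
    path = Path(path)
    with path.open("w", newline="") as fh:
        if profile.year is not None:
            fh.write(f"# year={profile.year}\n")
        writer = csv.writer(fh)
        writer.writerow(["state", "value"])
        for label, value in zip(profile.state_space.labels, profile.values):
            writer.writerow([label, _fmt(value)])


def read_matrix(path: str | Path, tol: float = 1e-4) -> TransitionMatrix:
    """Read a transition matrix (CSV or JSON by suffix), validating on read.

    Raises ``ValueError`` for non-square input or a row-sum violation beyond
    ``tol``, naming the offending row.
    """
    path = Path(path)
    if path.suffix.lower() == ".json":
        data = json.loads(path.read_text())
        labels = data["states"]
        arr = np.asarray(data["matrix"], dtype=float)
    else:
        with path.open(newline="") as fh:
            rows = [r for r in csv.reader(fh) if r and any(f.strip() for f in r)]
        if not rows:
            raise ValueError(f"{path}: empty file")
        labels = [h.strip() for h in rows[0][1:]]
        origins = []
        entries = []
        for row in rows[1:]:
            origins.append(row[0].strip())
            entries.append([float(v) for v in row[1:]])
        if origins != labels:
            raise ValueError(f"{path}: origin labels {origins} do not match header {labels}")
        arr = np.asarray(entries, dtype=float)
    if arr.ndim != 2 or arr.shape[0] != arr.shape[1] or arr.shape[0] != len(labels):
        raise ValueError(f"{path}: non-square matrix of shape {arr.shape} for {len(labels)} states")
    problems = validate_stochastic(arr, tol=tol, labels=labels)
    if problems:
        raise ValueError(f"{path}: " + "; ".join(problems))
    return TransitionMatrix(StateSpace(labels), arr)


def write_matrix(path: str | Path, T: TransitionMatrix) -> None:
    path = Path(path)
    if path.suffix.lower() == ".json":
        payload = {
            "states": list(T.state_space.labels),
            "matrix": [[float(v) for v in row] for row in T.entries],
        }
        path.write_text(json.dumps(payload, indent=2) + "\n")
        return
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["state", *T.state_space.labels])
        for label, row in zip(T.state_space.labels, T.entries):
            writer.writerow([label, *(_fmt(v) for v in row)])


def write_forecast(
    path: str | Path, series: ForecastSeries, round_to: int | None = None
) -> None:
    """Write a forecast series CSV; ``round_to`` affects display only."""
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["year", *series.state_space.labels])
        for year, vec in zip(series.years, series.vectors):
            if round_to is None:
                writer.writerow([int(year), *(_fmt(v) for v in vec)])
            else:
                writer.writerow(
                    [int(year), *(f"{v:.{round_to}f}" for v in vec)]
                )


def read_forecast(path: str | Path, mass_conserving: bool = True) -> ForecastSeries:
    path = Path(path)
    with path.open(newline="") as fh:
        rows = [r for r in csv.reader(fh) if r]
    labels = rows[0][1:]
    years = [int(r[0]) for r in rows[1:]]
    if years != list(range(years[0], years[0] + len(years))):
        raise ValueError(f"{path}: years are not consecutive")
    vectors = np.asarray([[float(v) for v in r[1:]] for r in rows[1:]])
    return ForecastSeries(
        StateSpace(labels), years[0], vectors, mass_conserving=mass_conserving
    )


def read_joint(path: str | Path) -> JointTable:
    data = json.loads(Path(path).read_text())
    return JointTable(data["rows"], data["cols"], np.asarray(data["p"], dtype=float))


def write_joint(path: str | Path, joint: JointTable) -> None:
    payload = {
        "rows": list(joint.row_labels),
        "cols": list(joint.col_labels),
        "p": [[float(v) for v in row] for row in joint.p],
    }
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def write_trajectory(path: str | Path, traj: Trajectory) -> None:
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["step", "state"])
        for i, s in enumerate(traj.states):
            writer.writerow([i, traj.state_space.labels[int(s)]])
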