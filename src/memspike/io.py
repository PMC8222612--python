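"""Plain-text time-series and stimulus I/O (CSV, full precision).

Trajectories are written with the fixed column order
``t, Q, qM, iL, Is``; stimulus programs as ``t_start, area, width``.
Numbers are written with 17 significant digits so a write/read round trip
preserves every value bit-for-bit.
"""

from __future__ import annotations

import csv
from pathlib import Path

import pandas as pd

from .pulse_design import Pulse, StimulusProgram
from .simulator import Trajectory

__all__ = [
    "write_trajectory",
    "read_trajectory_frame",
    "write_stimulus",
    "read_stimulus",
]

TRAJECTORY_COLUMNS = ("t", "Q", "qM", "iL", "Is")


def write_trajectory(traj: Trajectory, path) -> None:
    """Write a trajectory as CSV with header ``t,Q,qM,iL,Is``."""
    frame = pd.DataFrame(
        {"t": traj.t, "Q": traj.Q, "qM": traj.qM, "iL": traj.iL, "Is": traj.Is}
    )
    frame.to_csv(path, index=False, float_format="%.17g")


def read_trajectory_frame(path) -> pd.DataFrame:
    """Read a trajectory CSV back as a DataFrame (column order enforced)."""
    frame = pd.read_csv(path, float_precision="round_trip")
    if tuple(frame.columns) != TRAJECTORY_COLUMNS:
        raise ValueError(
            f"{path}: expected columns {TRAJECTORY_COLUMNS}, got {tuple(frame.columns)}"
        )
    return frame


def write_stimulus(stimulus: StimulusProgram, path) -> None:
    """Write a stimulus program as CSV with header ``t_start,area,width``."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["t_start", "area", "width"])
        for p in stimulus.pulses:
            writer.writerow([f"{p.t_start:.17g}", f"{p.area:.17g}", f"{p.width:.17g}"])


def read_stimulus(path) -> StimulusProgram:
    """Read a stimulus CSV; malformed rows raise with their line number.

    An empty file (or header-only file) yields the empty program,
    ``Is = 0`` everywhere.
    """
    path = Path(path)
    pulses: list[Pulse] = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        for lineno, row in enumerate(reader, start=1):
            if not row or all(not cell.strip() for cell in row):
                continue
            if lineno == 1 and not _is_numeric_row(row):
                if [c.strip() for c in row] != list(["t_start", "area", "width"]):
                    raise ValueError(
                        f"{path} line {lineno}: expected header "
                        f"'t_start,area,width', got {','.join(row)!r}"
                    )
                continue
            if len(row) != 3:
                raise ValueError(
                    f"{path} line {lineno}: expected 3 fields, got {len(row)}"
                )
            try:
                t_start, area, width = (float(cell) for cell in row)
            except ValueError:
                raise ValueError(
                    f"{path} line {lineno}: non-numeric value in {row!r}"
                ) from None
            try:
                pulses.append(Pulse(t_start=t_start, area=area, width=width))
            except ValueError as exc:
                raise ValueError(f"{path} line {lineno}: {exc}") from None
    return StimulusProgram(tuple(pulses))


def _is_numeric_row(row: list[str]) -> bool:
    try:
        [float(cell) for cell in row]
    except ValueError:
        return False
    return True
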