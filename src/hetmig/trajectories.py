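"""Trajectory container and delimited-text I/O.

A trajectory table holds per-cell time series of 2-D positions. Times are in
minutes, positions in micrometres. Each cell lives on its own *regular* time
grid; different cells may use different sampling intervals (the step-based
temporal-noise models produce one grid per cell).

The on-disk format is plain delimited text with the header
``cell_id,t_min,x_um,y_um`` and one row per cell per frame.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = ["TrajectoryTable", "TrajectoryError", "read_trajectories", "write_trajectories"]

COLUMNS = ("cell_id", "t_min", "x_um", "y_um")

_TIME_ATOL = 1e-9


class TrajectoryError(ValueError):
    """Raised for malformed trajectory tables (irregular grids, duplicates, ...)."""


@dataclass
class TrajectoryTable:
    """Per-cell time series of 2-D positions on regular per-cell grids.

    Parameters
    ----------
    data
        Mapping from cell id to ``(t, xy)`` where ``t`` is a 1-D array of times
        in minutes and ``xy`` an ``(n_frames, 2)`` array of positions in μm.
    """

    data: dict[object, tuple[np.ndarray, np.ndarray]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        clean: dict[object, tuple[np.ndarray, np.ndarray]] = {}
        for cid, (t, xy) in self.data.items():
            t = np.asarray(t, dtype=float)
            xy = np.asarray(xy, dtype=float)
            if t.ndim != 1 or xy.shape != (t.size, 2):
                raise TrajectoryError(f"cell {cid!r}: need t (n,) and xy (n, 2)")
            if t.size < 2:
                raise TrajectoryError(f"cell {cid!r}: fewer than two frames")
            steps = np.diff(t)
            if np.any(steps <= 0):
                raise TrajectoryError(f"cell {cid!r}: times not strictly increasing")
            if not np.allclose(steps, steps[0], rtol=1e-8, atol=_TIME_ATOL):
                raise TrajectoryError(f"cell {cid!r}: irregular time grid")
            clean[cid] = (t, xy)
        self.data = clean

    # -- construction -----------------------------------------------------

    @classmethod
    def from_positions(
        cls,
        times: np.ndarray,
        positions: np.ndarray,
        cell_ids: Sequence | None = None,
    ) -> "TrajectoryTable":
        """Build a table from a common grid: ``positions`` is (n_cells, n_frames, 2)."""
        positions = np.asarray(positions, dtype=float)
        times = np.asarray(times, dtype=float)
        n_cells = positions.shape[0]
        if cell_ids is None:
            cell_ids = list(range(n_cells))
        return cls({cid: (times, positions[i]) for i, cid in enumerate(cell_ids)})

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "TrajectoryTable":
        missing = [c for c in COLUMNS if c not in df.columns]
        if missing:
            raise TrajectoryError(f"missing columns: {missing}")
        data = {}
        for cid, grp in df.groupby("cell_id", sort=False):
            grp = grp.sort_values("t_min")
            t = grp["t_min"].to_numpy(dtype=float)
            if np.unique(t).size != t.size:
                raise TrajectoryError(f"cell {cid!r}: duplicate (cell, frame) entries")
            data[cid] = (t, grp[["x_um", "y_um"]].to_numpy(dtype=float))
        return cls(data)

    # -- basic queries -----------------------------------------------------

    @property
    def cell_ids(self) -> list:
        return list(self.data.keys())

    @property
    def n_cells(self) -> int:
        return len(self.data)

    def positions(self, cell_id) -> tuple[np.ndarray, np.ndarray]:
        """Return ``(t, xy)`` for one cell."""
        return self.data[cell_id]

    def dt(self, cell_id) -> float:
        t, _ = self.data[cell_id]
        return float(t[1] - t[0])

    def duration(self, cell_id) -> float:
        t, _ = self.data[cell_id]
        return float(t[-1] - t[0])

    def items(self) -> Iterator[tuple[object, np.ndarray, np.ndarray]]:
        for cid, (t, xy) in self.data.items():
            yield cid, t, xy

    def subset(self, cell_ids: Sequence) -> "TrajectoryTable":
        """A new table restricted to ``cell_ids`` (order preserved)."""
        return TrajectoryTable({cid: self.data[cid] for cid in cell_ids})

    def common_dt(self) -> float:
        """Sampling interval shared by all cells; error if grids differ."""
        dts = {round(self.dt(c), 9) for c in self.cell_ids}
        if len(dts) != 1:
            raise TrajectoryError(f"cells use different sampling intervals: {sorted(dts)}")
        return dts.pop()

    def to_dataframe(self) -> pd.DataFrame:
        frames = []
        for cid, t, xy in self.items():
            frames.append(
                pd.DataFrame(
                    {"cell_id": cid, "t_min": t, "x_um": xy[:, 0], "y_um": xy[:, 1]}
                )
            )
        return pd.concat(frames, ignore_index=True)

    def round_positions(self, decimals: int = 1) -> "TrajectoryTable":
        """Positions rounded to the stored decimal precision (0.1 μm by default)."""
        return TrajectoryTable(
            {cid: (t, np.round(xy, decimals)) for cid, t, xy in self.items()}
        )

    def __eq__(self, other) -> bool:  # mainly for round-trip tests
        if not isinstance(other, TrajectoryTable):
            return NotImplemented
        if self.cell_ids != other.cell_ids:
            return False
        return all(
            np.array_equal(t, other.data[c][0]) and np.array_equal(xy, other.data[c][1])
            for c, (t, xy) in self.data.items()
        )


def write_trajectories(table: TrajectoryTable, path: str | Path, decimals: int = 1) -> None:
    """Write a table as delimited text, positions at 0.1 μm precision by default."""
    df = table.to_dataframe()
    df["x_um"] = df["x_um"].round(decimals)
    df["y_um"] = df["y_um"].round(decimals)
    df.to_csv(path, index=False)


def read_trajectories(path: str | Path) -> TrajectoryTable:
    """Read a delimited-text trajectory file, validating grid regularity.

    Errors carry the 1-based line number of the first offending row where the
    problem is local to a row (non-numeric fields, duplicates).
    """
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise TrajectoryError(f"{path}: cannot parse ({exc})") from exc
    missing = [c for c in COLUMNS if c not in df.columns]
    if missing:
        raise TrajectoryError(f"{path}: missing columns {missing}")
    for col in ("t_min", "x_um", "y_um"):
        bad = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()
        numeric = pd.to_numeric(df[col], errors="coerce")
        bad = numeric.isna()
        if bad.any():
            line = int(np.flatnonzero(bad.to_numpy())[0]) + 2  # +1 header, +1 one-based
            raise TrajectoryError(f"{path}:{line}: non-numeric value in column {col!r}")
        df[col] = numeric
    dup = df.duplicated(subset=["cell_id", "t_min"])
    if dup.any():
        line = int(np.flatnonzero(dup.to_numpy())[0]) + 2
        raise TrajectoryError(f"{path}:{line}: duplicate (cell_id, t_min) entry")
    try:
        return TrajectoryTable.from_dataframe(df)
    except TrajectoryError as exc:
        raise TrajectoryError(f"{path}: {exc}") from exc
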