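"""Named multivariate time-series tables: the package's universal I/O currency.

A :class:`PanelTable` is a thin, validated wrapper around a pandas DataFrame
with one column per variable and one row per time step.  On disk it is a
plain delimited text file with a header row; an optional leading column named
``t``/``time`` (or any strictly monotone first column) is treated as the time
index.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["PanelTable", "read_panel", "write_panel"]

_TIME_NAMES = {"t", "time"}


@dataclass
class PanelTable:
    """Rectangular panel of named, finite, numeric series.

    Parameters
    ----------
    data:
        One column per variable; the index is the time axis (integer steps or
        real times).
    """

    data: pd.DataFrame
    observed: tuple[str, ...] = ()
    hidden: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.data.columns.duplicated().any():
            dupes = self.data.columns[self.data.columns.duplicated()].tolist()
            raise ValueError(f"duplicate variable names: {dupes}")
        values = self.data.to_numpy(dtype=float)
        if values.size and not np.isfinite(values).all():
            bad = np.argwhere(~np.isfinite(values))[0]
            raise ValueError(
                f"non-finite value at row {bad[0]}, "
                f"column {self.data.columns[bad[1]]!r}")
        if self.observed or self.hidden:
            declared = set(self.observed) | set(self.hidden)
            if declared != set(self.data.columns):
                raise ValueError("observed + hidden must cover all columns")

    @property
    def columns(self) -> list[str]:
        return list(self.data.columns)

    @property
    def n_rows(self) -> int:
        return len(self.data)

    @property
    def time(self) -> np.ndarray:
        return self.data.index.to_numpy()

    def values(self, names: list[str] | None = None) -> np.ndarray:
        df = self.data if names is None else self.data[list(names)]
        return df.to_numpy(dtype=float)

    def column(self, name: str) -> np.ndarray:
        if name not in self.data.columns:
            raise KeyError(f"no such variable: {name!r}")
        return self.data[name].to_numpy(dtype=float)

    @classmethod
    def from_columns(cls, columns: dict[str, np.ndarray],
                     time: np.ndarray | None = None,
                     observed: tuple[str, ...] = (),
                     hidden: tuple[str, ...] = ()) -> "PanelTable":
        df = pd.DataFrame(columns)
        if time is not None:
            df.index = pd.Index(time, name="t")
        return cls(df, observed=observed, hidden=hidden)


def read_panel(path: str | Path, sep: str = ",") -> PanelTable:
    """Read a delimited panel; see module docstring for the layout.

    Raises ``ValueError`` naming the offending row and column on any
    non-numeric cell.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=sep, float_precision="round_trip")
    for col in df.columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            row = int(np.flatnonzero(bad)[0])
            raise ValueError(
                f"non-numeric cell at row {row}, column {col!r} in {path}")
        df[col] = coerced
    if len(df.columns) > 1:
        first = df.columns[0]
        vals = df[first].to_numpy()
        monotone = len(vals) > 1 and bool(np.all(np.diff(vals) > 0))
        if first.lower() in _TIME_NAMES or monotone:
            df = df.set_index(first)
            df.index.name = "t"
    return PanelTable(df)


def write_panel(panel: PanelTable, path: str | Path, sep: str = ",") -> Path:
    """Write the panel as delimited text at full float precision."""
    path = Path(path)
    df = panel.data.copy()
    include_index = panel.data.index.name is not None or not isinstance(
        panel.data.index, pd.RangeIndex)
    if include_index:
        df = df.reset_index().rename(columns={"index": "t"})
        if df.columns[0] != "t":
            df = df.rename(columns={df.columns[0]: "t"})
    df.to_csv(path, sep=sep, index=False, float_format="%.17g")
    return path
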