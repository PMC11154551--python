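"""Causal specifications and lagged design matrices.

A :class:`CausalSpec` names the target Y, the observed lagged causes X
(each with a lag >= 1, enforcing temporal priority) and the autoregressive
order k (Y_{t-k}..Y_{t-1} are included as causes).  ``build_lagged_design``
assembles the aligned training matrices: one row per time index t with
complete history, cause columns in spec order followed by the Y lags in
ascending order (oldest first).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .panel import PanelTable

__all__ = ["CausalSpec", "LaggedDesign", "build_lagged_design"]


@dataclass(frozen=True)
class CausalSpec:
    """Which lagged columns cause the target.

    ``observed_causes`` is a sequence of ``(variable, lag)`` pairs with
    lag >= 1; ``k >= 0`` is the autoregressive order.  At least one cause
    (lagged X or k >= 1) is required.
    """

    target: str
    observed_causes: tuple[tuple[str, int], ...] = ()
    k: int = 1

    def __post_init__(self) -> None:
        object.__setattr__(self, "observed_causes",
                           tuple((str(v), int(l))
                                 for v, l in self.observed_causes))
        for var, lag in self.observed_causes:
            if lag < 1:
                raise ValueError(
                    f"cause {var!r} has lag {lag}: temporal priority "
                    "requires lag >= 1")
        if self.k < 0:
            raise ValueError("autoregressive order k must be >= 0")
        if self.k == 0 and not self.observed_causes:
            raise ValueError("empty cause set: need lagged causes or k >= 1")

    @property
    def max_lag(self) -> int:
        lags = [lag for _, lag in self.observed_causes] + [self.k]
        return max(lags)

    @property
    def n_explicit(self) -> int:
        """Number of explicit cause columns: lagged X plus Y lags."""
        return len(self.observed_causes) + self.k

    def cause_labels(self) -> list[str]:
        labels = [f"{v}[t-{l}]" for v, l in self.observed_causes]
        labels += [f"{self.target}[t-{j}]" for j in range(self.k, 0, -1)]
        return labels


@dataclass(frozen=True)
class LaggedDesign:
    """Aligned training matrices for one causal specification."""

    rows: np.ndarray        # time indices t (into the panel) per design row
    x_block: np.ndarray     # (n, n_causes) lagged cause values
    y_past: np.ndarray      # (n, k) Y_{t-k}..Y_{t-1}, oldest first
    y_now: np.ndarray       # (n,) Y_t
    labels: tuple[str, ...]  # column labels of [x_block | y_past]

    def __post_init__(self) -> None:
        n = len(self.rows)
        if not (len(self.x_block) == len(self.y_past)
                == len(self.y_now) == n):
            raise ValueError("design blocks have mismatched row counts")

    @property
    def explicit(self) -> np.ndarray:
        """The full explicit-cause matrix [x_block | y_past]."""
        return np.hstack([self.x_block, self.y_past])

    @property
    def n_rows(self) -> int:
        return len(self.rows)


def build_lagged_design(panel: PanelTable, spec: CausalSpec) -> LaggedDesign:
    """Window a panel into the design matrices for ``spec``.

    Rows are exactly the time indices with complete history:
    ``max_lag .. n-1`` in 0-based step indexing (lag L means L rows earlier).
    """
    needed = {spec.target, *(v for v, _ in spec.observed_causes)}
    missing = sorted(needed - set(panel.columns))
    if missing:
        raise KeyError(f"panel is missing variable(s): {missing}")
    n = panel.n_rows
    m = spec.max_lag
    if n <= m:
        raise ValueError(
            f"panel length {n} too short for maximum lag {m}")
    rows = np.arange(m, n)
    y = panel.column(spec.target)
    x_cols = [panel.column(v)[rows - lag]
              for v, lag in spec.observed_causes]
    x_block = (np.column_stack(x_cols) if x_cols
               else np.empty((len(rows), 0)))
    y_cols = [y[rows - j] for j in range(spec.k, 0, -1)]
    y_past = (np.column_stack(y_cols) if y_cols
              else np.empty((len(rows), 0)))
    return LaggedDesign(rows=rows, x_block=x_block, y_past=y_past,
                        y_now=y[rows], labels=tuple(spec.cause_labels()))
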