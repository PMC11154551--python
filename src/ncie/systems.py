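"""Synthetic study systems: Boolean AND network, sinusoid drivers, Lotka-Volterra.

These generators produce every input the validation experiments need:

* a temporal Boolean network ``Y_t = X_{t-1} AND W_{t-1}`` with i.i.d. uniform
  bits, together with its exact joint truth tables (including two optimal
  implicit-variable constructions for the hidden cause W);
* three continuous driver systems in which an observable slow component X and
  a hidden fast component ``W(t) = sin(10 t)`` combine additively or
  multiplicatively into the target Y;
* a floored 4-species predator-prey ecosystem (wolves, sheep, rabbits, grass)
  in which the two intermediate species are hidden.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .information import DiscreteJoint
from .panel import PanelTable

__all__ = [
    "LVParams",
    "boolean_truth_table", "xor_z_truth_table", "ideal_posterior_z_table",
    "simulate_boolean", "simulate_case", "simulate_lv",
    "CASE_DEFAULTS",
]

#: Default time grids for the driver cases.  Case 1 covers several periods of
#: both sinusoids.  Cases 2-3 place the cubic trend's interior turning point
#: (t ~ 203) well inside the first 70% of the grid, so a chronological
#: train/test split evaluates inside the observed range of X rather than in
#: pure extrapolation.
CASE_DEFAULTS = {
    1: {"t_start": 0.0, "t_end": 60.0, "n": 3000},
    2: {"t_start": 0.0, "t_end": 300.0, "n": 3000},
    3: {"t_start": 0.0, "t_end": 300.0, "n": 3000},
}


# ---------------------------------------------------------------------------
# Boolean AND system and its exact joints
# ---------------------------------------------------------------------------

def boolean_truth_table() -> DiscreteJoint:
    """Joint of (X_{t-1}, W_{t-1}, Y_t) for Y = X AND W with uniform bits.

    All four (x, w) combinations are equally likely, so each surviving row
    has probability 1/4; (x=1, w=1, y=0) cannot occur.
    """
    support = [(0, 0, 0), (0, 1, 0), (1, 0, 0), (1, 1, 1)]
    return DiscreteJoint(("X", "W", "Y"), np.array(support),
                         np.full(4, 0.25))


def xor_z_truth_table() -> DiscreteJoint:
    """Joint of (X_{t-1}, Y_t, Z_{t-1}) for the implicit variable Z = X XOR Y.

    Obtained by pushing the AND joint through the deterministic map and
    marginalizing W; Z achieves the same conditional information about Y
    given X as the hidden cause W does.
    """
    table = boolean_truth_table()
    rows = []
    for (x, w, y), p in zip(table.support, table.probs):
        rows.append(((x, y, x ^ y), p))
    support = np.array([r for r, _ in rows])
    uniq, inverse = np.unique(support, axis=0, return_inverse=True)
    probs = np.zeros(len(uniq))
    np.add.at(probs, inverse, [p for _, p in rows])
    return DiscreteJoint(("X", "Y", "Z"), uniq, probs)


def ideal_posterior_z_table() -> DiscreteJoint:
    """Joint of (X_{t-1}, Y_t, Z_{t-1}) with Z reproducing W's posterior.

    Z is drawn from p(W | X, Y): deterministically 1 when (x, y) = (1, 1),
    deterministically 0 when (x, y) = (1, 0), and a fair coin when x = 0.
    """
    support = [(0, 0, 0), (0, 0, 1), (1, 0, 0), (1, 1, 1)]
    return DiscreteJoint(("X", "Y", "Z"), np.array(support),
                         np.full(4, 0.25))


def simulate_boolean(n: int, seed: int = 0) -> PanelTable:
    """Sample ``n`` steps of the Boolean AND system.

    Columns X, W are i.i.d. uniform bits; Y at row t equals
    ``X[t-1] AND W[t-1]`` (the first Y uses one extra hidden predecessor
    draw so every row is distributed identically).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    x = rng.integers(0, 2, size=n + 1)
    w = rng.integers(0, 2, size=n + 1)
    y = x[:-1] & w[:-1]
    return PanelTable.from_columns(
        {"X": x[1:].astype(float), "W": w[1:].astype(float),
         "Y": y.astype(float)},
        observed=("X", "Y"), hidden=("W",))


# ---------------------------------------------------------------------------
# continuous driver cases
# ---------------------------------------------------------------------------

def _cubic(t: np.ndarray) -> np.ndarray:
    return 0.05 * t ** 3 - 15 * t ** 2 - 80 * t + 2


def simulate_case(case_id: int, t_start: float | None = None,
                  t_end: float | None = None,
                  n: int | None = None) -> PanelTable:
    """Evaluate driver case 1, 2 or 3 on a uniform time grid.

    Case 1 (linear): ``Y = X + W`` with slow ``X = sin(t/10)`` and fast
    ``W = sin(10 t)``.  Cases 2-3 (non-linear): X is the cubic trend
    ``0.05 t^3 - 15 t^2 - 80 t + 2`` and W multiplies into Y through
    ``W (0.2 + X)`` (case 2) or ``0.2 W (0.2 + X)`` (case 3).  X and Y are
    observable; W is hidden.
    """
    if case_id not in (1, 2, 3):
        raise ValueError(f"invalid case_id {case_id!r}; expected 1, 2 or 3")
    defaults = CASE_DEFAULTS[case_id]
    t_start = defaults["t_start"] if t_start is None else t_start
    t_end = defaults["t_end"] if t_end is None else t_end
    n = defaults["n"] if n is None else n
    if not t_end > t_start:
        raise ValueError("t_end must exceed t_start")
    if n < 2:
        raise ValueError("n must be >= 2")
    t = np.linspace(t_start, t_end, n)
    w = np.sin(10.0 * t)
    if case_id == 1:
        x = np.sin(t / 10.0)
        y = x + w
    elif case_id == 2:
        x = _cubic(t)
        y = x + w * (0.2 + x)
    else:
        x = _cubic(t)
        y = x + 0.2 * w * (0.2 + x)
    return PanelTable.from_columns({"Y": y, "X": x, "W": w}, time=t,
                                   observed=("X", "Y"), hidden=("W",))


# ---------------------------------------------------------------------------
# floored Lotka-Volterra ecosystem
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LVParams:
    """Rates, initial populations and integrator settings for the ecosystem.

    The four species are wolves W (predator), sheep S and rabbits R (prey
    sharing the same food) and grass G.  ``floor`` resets any population that
    drops below it after every Euler step, preventing extinction from halting
    the dynamics; pass ``floor=None`` to disable.

    Defaults give sustained oscillations without permanent pinning at the
    floor.
    """

    a0: float = 1.0
    a1: float = 0.05
    a2: float = 0.02
    b0: float = 1.0
    b1: float = 0.1
    b2: float = 0.02
    c0: float = 0.8
    c1: float = 0.1
    c2: float = 0.02
    d0: float = 1.5
    d1: float = 0.05
    d2: float = 0.05
    init_w: float = 10.0
    init_s: float = 20.0
    init_r: float = 20.0
    init_g: float = 40.0
    dt: float = 0.01
    n_steps: int = 20000
    floor: float | None = 1.0

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.n_steps < 1:
            raise ValueError("n_steps must be >= 1")
        rates = [self.a0, self.a1, self.a2, self.b0, self.b1, self.b2,
                 self.c0, self.c1, self.c2, self.d0, self.d1, self.d2]
        if any(r < 0 for r in rates):
            raise ValueError("all rates must be nonnegative")
        if self.floor is not None:
            inits = [self.init_w, self.init_s, self.init_r, self.init_g]
            if any(v < self.floor for v in inits):
                raise ValueError("initial populations must be >= floor")


def lv_derivatives(params: LVParams, w, s, r, g):
    """Right-hand side of the coupled predator-prey ODEs."""
    dw = w * (-params.a0 + params.a1 * s + params.a2 * r)
    ds = s * (params.b0 - params.b1 * w + params.b2 * g)
    dr = r * (params.c0 - params.c1 * w + params.c2 * g)
    dg = g * (params.d0 - params.d1 * s - params.d2 * r)
    return dw, ds, dr, dg


def simulate_lv(params: LVParams = LVParams(), seed: int = 0) -> PanelTable:
    """Forward-Euler integration of the floored 4-species ecosystem.

    After every step any population below the floor is reset to the floor.
    The seed is accepted for interface uniformity; the dynamics are
    deterministic given ``params``.  Observed: wolves W and grass G; hidden:
    sheep S and rabbits R (intermediate species in the food chain).
    """
    state = np.array([params.init_w, params.init_s, params.init_r,
                      params.init_g], dtype=float)
    traj = np.empty((params.n_steps + 1, 4))
    traj[0] = state
    for k in range(params.n_steps):
        with np.errstate(over="ignore", invalid="ignore"):
            dw, ds, dr, dg = lv_derivatives(params, *state)
            state = state + params.dt * np.array([dw, ds, dr, dg])
        if not np.isfinite(state).all():
            raise FloatingPointError(
                f"population diverged at step {k + 1}; reduce dt")
        if params.floor is not None:
            np.maximum(state, params.floor, out=state)
        traj[k + 1] = state
    t = np.arange(params.n_steps + 1) * params.dt
    return PanelTable.from_columns(
        {"W": traj[:, 0], "S": traj[:, 1], "R": traj[:, 2], "G": traj[:, 3]},
        time=t, observed=("W", "G"), hidden=("S", "R"))
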