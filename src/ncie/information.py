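"""Information quantities: exact discrete oracle, histogram plug-in, DV neural bound.

Three estimation routes coexist, and every result carries its method and units:

* ``exact`` -- Shannon entropy / mutual information / conditional MI computed by
  direct summation over an enumerated finite joint distribution
  (:class:`DiscreteJoint`).  This is the ground-truth oracle for the worked
  Boolean examples.
* ``binning`` -- the classical histogram plug-in: partition each continuous
  column into bins, count, and apply the exact formulas to the empirical joint.
* ``dv_neural`` -- the Donsker-Varadhan variational lower bound on the KL
  divergence between the joint and the product of marginals,
  ``I >= E_P[T] - log E_Q[e^T]``, maximized over a neural statistics network T
  by stochastic gradient ascent with the moving-average bias-corrected
  gradient.  Natively in nats.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.special import logsumexp

from ._autodiff import Adam, Tensor, concat
from ._nn import MLP

__all__ = [
    "DiscreteJoint", "BinningSpec", "MIEstimate", "SamplePairBatch",
    "DVConfig", "DivergenceError",
    "entropy_discrete", "mi_discrete", "cmi_discrete",
    "discretize", "empirical_joint", "mi_binned", "entropy_binned",
    "dv_bound_value", "train_dv_estimator", "evaluate_dv_bound",
]

LN2 = np.log(2.0)
#: Plug-in MI over high-dimensional joint histograms is dominated by bias;
#: refuse beyond this many total dimensions.
MAX_HIST_DIMS = 4


class DivergenceError(RuntimeError):
    """Raised when DV training produces a non-finite or exploding bound."""


# ---------------------------------------------------------------------------
# exact discrete oracle
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DiscreteJoint:
    """An enumerated finite joint distribution.

    ``support`` has one row per outcome and one column per variable in
    ``variable_names``; ``probs`` are the matching probabilities.
    """

    variable_names: tuple[str, ...]
    support: np.ndarray
    probs: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "support", np.asarray(self.support))
        object.__setattr__(self, "probs",
                           np.asarray(self.probs, dtype=float))
        if self.support.ndim != 2 or self.support.shape[1] != len(
                self.variable_names):
            raise ValueError("support must be (n_outcomes, n_variables)")
        if len(self.probs) != len(self.support):
            raise ValueError("probs and support length mismatch")
        if (self.probs < 0).any():
            raise ValueError("negative probability")
        if abs(self.probs.sum() - 1.0) > 1e-12:
            raise ValueError(f"probabilities sum to {self.probs.sum()}, not 1")
        if len(np.unique(self.support, axis=0)) != len(self.support):
            raise ValueError("duplicate outcomes in support")

    def _cols(self, names: Sequence[str]) -> list[int]:
        missing = [n for n in names if n not in self.variable_names]
        if missing:
            raise KeyError(f"unknown variable(s): {missing}")
        return [self.variable_names.index(n) for n in names]

    def marginal(self, names: Sequence[str]) -> "DiscreteJoint":
        """Marginalize onto ``names`` (in the given order)."""
        cols = self._cols(names)
        sub = self.support[:, cols]
        uniq, inverse = np.unique(sub, axis=0, return_inverse=True)
        probs = np.zeros(len(uniq))
        np.add.at(probs, inverse, self.probs)
        return DiscreteJoint(tuple(names), uniq, probs)

    def map_variable(self, name: str, new_name: str, fn) -> "DiscreteJoint":
        """Apply ``fn`` to one variable's symbols (deterministic push-forward)."""
        col = self._cols([name])[0]
        support = self.support.copy()
        support[:, col] = [fn(v) for v in support[:, col]]
        names = list(self.variable_names)
        names[col] = new_name
        uniq, inverse = np.unique(support, axis=0, return_inverse=True)
        probs = np.zeros(len(uniq))
        np.add.at(probs, inverse, self.probs)
        return DiscreteJoint(tuple(names), uniq, probs)


@dataclass(frozen=True)
class MIEstimate:
    """An information value with its provenance.

    ``value`` is in ``units`` ('bits' or 'nats'); ``method`` is one of
    'exact', 'binning', 'dv_neural'.  ``diagnostics`` holds the per-epoch
    bound curve for the neural estimator and is None otherwise.
    """

    value: float
    units: str
    method: str
    n_samples: int = 0
    diagnostics: dict | None = None

    def __post_init__(self) -> None:
        if self.units not in ("bits", "nats"):
            raise ValueError(f"unknown units {self.units!r}")
        if self.method not in ("exact", "binning", "dv_neural"):
            raise ValueError(f"unknown method {self.method!r}")
        if (self.diagnostics is not None) != (self.method == "dv_neural"):
            raise ValueError("diagnostics present iff method='dv_neural'")

    def in_units(self, units: str) -> float:
        if units == self.units:
            return self.value
        if (self.units, units) == ("nats", "bits"):
            return self.value / LN2
        if (self.units, units) == ("bits", "nats"):
            return self.value * LN2
        raise ValueError(f"unknown units {units!r}")

    @property
    def bits(self) -> float:
        return self.in_units("bits")

    @property
    def nats(self) -> float:
        return self.in_units("nats")


def _entropy_from_probs(probs: np.ndarray, base) -> float:
    p = probs[probs > 0]
    h = -np.sum(p * np.log(p))
    return float(h / LN2) if base == 2 else float(h)


def _units(base) -> str:
    if base == 2:
        return "bits"
    if base in ("e", np.e):
        return "nats"
    raise ValueError("base must be 2 or 'e'")


def entropy_discrete(joint: DiscreteJoint, variables: Sequence[str],
                     base=2) -> MIEstimate:
    """Exact Shannon entropy of the marginal on ``variables``; 0*log0 := 0."""
    marg = joint.marginal(list(variables))
    return MIEstimate(_entropy_from_probs(marg.probs, base),
                      _units(base), "exact")


def _check_disjoint(*groups: Sequence[str]) -> None:
    flat = [n for g in groups for n in g]
    if len(flat) != len(set(flat)):
        raise ValueError(f"variable groups overlap: {flat}")
    if any(len(g) == 0 for g in groups):
        raise ValueError("empty variable group")


def mi_discrete(joint: DiscreteJoint, group_a: Sequence[str],
                group_b: Sequence[str], base=2) -> MIEstimate:
    """Exact I(A;B) = H(A) + H(B) - H(A,B) by summation over the support."""
    _check_disjoint(group_a, group_b)
    h_a = entropy_discrete(joint, group_a, base).value
    h_b = entropy_discrete(joint, group_b, base).value
    h_ab = entropy_discrete(joint, [*group_a, *group_b], base).value
    return MIEstimate(h_a + h_b - h_ab, _units(base), "exact")


def cmi_discrete(joint: DiscreteJoint, group_a: Sequence[str],
                 group_b: Sequence[str], conditioning: Sequence[str],
                 base=2) -> MIEstimate:
    """Exact I(A;B|C) = I(A; B,C) - I(A; C)."""
    _check_disjoint(group_a, group_b, conditioning)
    i_abc = mi_discrete(joint, group_a, [*group_b, *conditioning], base).value
    i_ac = mi_discrete(joint, group_a, list(conditioning), base).value
    return MIEstimate(i_abc - i_ac, _units(base), "exact")


# ---------------------------------------------------------------------------
# histogram plug-in
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BinningSpec:
    """How to partition continuous columns into discrete bins."""

    n_bins: int = 16
    strategy: str = "equal-width"  # or "equal-frequency"

    def __post_init__(self) -> None:
        if self.n_bins < 2:
            raise ValueError("n_bins must be >= 2")
        if self.strategy not in ("equal-width", "equal-frequency"):
            raise ValueError(f"unknown strategy {self.strategy!r}")


def discretize(columns: np.ndarray, spec: BinningSpec) -> np.ndarray:
    """Per-column bin indices in ``0..n_bins-1``.

    Equal-width splits [min, max] into ``n_bins`` half-open intervals with the
    top edge closed; equal-frequency uses empirical quantiles and refuses
    constant columns.
    """
    columns = np.atleast_2d(np.asarray(columns, dtype=float))
    if columns.ndim != 2:
        raise ValueError("expected a (rows, columns) matrix")
    if not np.isfinite(columns).all():
        raise ValueError("non-finite values cannot be binned")
    out = np.empty(columns.shape, dtype=np.int64)
    for j in range(columns.shape[1]):
        col = columns[:, j]
        lo, hi = col.min(), col.max()
        if spec.strategy == "equal-width":
            if hi == lo:
                out[:, j] = 0
                continue
            edges = np.linspace(lo, hi, spec.n_bins + 1)
        else:
            if hi == lo:
                raise ValueError(
                    f"column {j} is constant: equal-frequency bins undefined")
            edges = np.quantile(col, np.linspace(0, 1, spec.n_bins + 1))
        idx = np.searchsorted(edges, col, side="right") - 1
        out[:, j] = np.clip(idx, 0, spec.n_bins - 1)  # close the top edge
    return out


def empirical_joint(discrete: np.ndarray,
                    names: Sequence[str]) -> DiscreteJoint:
    """Empirical DiscreteJoint from rows of bin indices / symbols."""
    discrete = np.atleast_2d(np.asarray(discrete))
    uniq, counts = np.unique(discrete, axis=0, return_counts=True)
    return DiscreteJoint(tuple(names), uniq, counts / counts.sum())


def _binned_joint(arrays: dict[str, np.ndarray],
                  spec: BinningSpec) -> DiscreteJoint:
    names = list(arrays)
    if len(names) > MAX_HIST_DIMS:
        raise ValueError(
            f"joint histogram over {len(names)} dimensions refused "
            f"(limit {MAX_HIST_DIMS}): the plug-in estimate would be "
            "bias-dominated")
    mat = np.column_stack([arrays[n] for n in names])
    return empirical_joint(discretize(mat, spec), names)


def mi_binned(panel, group_a: Sequence[str], group_b: Sequence[str],
              spec: BinningSpec = BinningSpec(), base=2) -> MIEstimate:
    """Histogram plug-in MI between two groups of panel columns.

    ``panel`` may be a :class:`~ncie.panel.PanelTable` or a mapping of column
    name to 1-D array.  Groups referring to the same underlying values (e.g.
    a column paired with its copy) reduce to the binned entropy.
    """
    _check_disjoint(group_a, group_b)
    cols = {n: _get_col(panel, n) for n in [*group_a, *group_b]}
    n = len(next(iter(cols.values())))
    if n == 0:
        raise ValueError("empty panel")
    joint = _binned_joint(cols, spec)
    est = mi_discrete(joint, list(group_a), list(group_b), base)
    return MIEstimate(est.value, est.units, "binning", n_samples=n)


def entropy_binned(values: np.ndarray, spec: BinningSpec = BinningSpec(),
                   base=2) -> MIEstimate:
    """Binned entropy of a single column: the plug-in estimate of H(Y)."""
    values = np.asarray(values, dtype=float).reshape(-1, 1)
    joint = empirical_joint(discretize(values, spec), ["y"])
    return MIEstimate(_entropy_from_probs(joint.probs, base), _units(base),
                      "binning", n_samples=len(values))


def _get_col(panel, name: str) -> np.ndarray:
    if hasattr(panel, "column"):
        return panel.column(name)
    return np.asarray(panel[name], dtype=float)


# ---------------------------------------------------------------------------
# Donsker-Varadhan neural estimator
# ---------------------------------------------------------------------------

def dv_bound_value(t_joint: np.ndarray, t_marginal: np.ndarray) -> float:
    """DV bound in nats: mean(T_joint) - log mean exp(T_marginal), stable."""
    t_joint = np.asarray(t_joint, dtype=float).ravel()
    t_marginal = np.asarray(t_marginal, dtype=float).ravel()
    if t_joint.size == 0 or t_marginal.size == 0:
        raise ValueError("empty statistics vector")
    if not (np.isfinite(t_joint).all() and np.isfinite(t_marginal).all()):
        raise ValueError("non-finite statistics values")
    lme = logsumexp(t_marginal) - np.log(t_marginal.size)
    return float(t_joint.mean() - lme)


@dataclass(frozen=True)
class SamplePairBatch:
    """Aligned joint samples: row i of side_a was observed with row i of side_b."""

    side_a: np.ndarray
    side_b: np.ndarray

    def __post_init__(self) -> None:
        a = np.atleast_2d(np.asarray(self.side_a, dtype=float).T).T \
            if np.asarray(self.side_a).ndim == 1 else np.asarray(
                self.side_a, dtype=float)
        b = np.atleast_2d(np.asarray(self.side_b, dtype=float).T).T \
            if np.asarray(self.side_b).ndim == 1 else np.asarray(
                self.side_b, dtype=float)
        object.__setattr__(self, "side_a", a)
        object.__setattr__(self, "side_b", b)
        if len(self.side_a) != len(self.side_b):
            raise ValueError("side_a and side_b batch sizes differ")


@dataclass(frozen=True)
class DVConfig:
    """Training configuration for the DV statistics network."""

    hidden: tuple[int, ...] = (64, 64)
    learning_rate: float = 1e-3
    epochs: int = 200
    batch_size: int = 512
    ema_decay: float = 0.99
    seed: int = 0
    eval_tail: int = 10    # epochs averaged into the final readout
    ceiling: float = 50.0  # nats; beyond this T has exploded


def train_dv_estimator(pairs: SamplePairBatch,
                       config: DVConfig = DVConfig()) -> MIEstimate:
    """Train T_theta by stochastic gradient ascent on the DV bound.

    Marginal batches are formed by permuting side_a within each minibatch
    (re-drawn every batch).  The gradient of the log-partition term uses an
    exponential moving average of ``mean(exp T)`` as the denominator, which
    removes the minibatch bias of the naive gradient.  The returned value is
    the full-sample bound averaged over the last ``eval_tail`` epochs, in
    nats, with the full per-epoch curve in diagnostics.
    """
    rng = np.random.default_rng(config.seed)
    n, da = pairs.side_a.shape
    db = pairs.side_b.shape[1]
    net = MLP(rng, da + db, config.hidden, 1)
    opt = Adam(net.parameters(), lr=config.learning_rate)
    ema: float | None = None
    curve: list[float] = []
    for _ in range(config.epochs):
        order = rng.permutation(n)
        for start in range(0, n, config.batch_size):
            idx = order[start:start + config.batch_size]
            if len(idx) < 2:
                continue
            a, b = pairs.side_a[idx], pairs.side_b[idx]
            a_perm = a[rng.permutation(len(idx))]
            t_j = net(Tensor(np.hstack([a, b])))
            t_m = net(Tensor(np.hstack([a_perm, b])))
            m = t_m.exp().mean()
            if not np.isfinite(m.data):
                raise DivergenceError("exp(T) overflow in DV training")
            ema = float(m.data) if ema is None else (
                config.ema_decay * ema
                + (1 - config.ema_decay) * float(m.data))
            loss = -(t_j.mean() - m * (1.0 / ema))
            opt.zero_grad()
            loss.backward()
            opt.step()
        bound = _full_bound(net, pairs, rng)
        if not np.isfinite(bound) or bound > config.ceiling:
            raise DivergenceError(
                f"DV bound diverged ({bound:.3g} nats) at epoch {len(curve)}")
        curve.append(bound)
    tail = curve[-config.eval_tail:]
    return MIEstimate(float(np.mean(tail)), "nats", "dv_neural",
                      n_samples=n, diagnostics={"bound_curve": curve})


def _full_bound(net: MLP, pairs: SamplePairBatch,
                rng: np.random.Generator) -> float:
    perm = rng.permutation(len(pairs.side_a))
    t_j = net(Tensor(np.hstack([pairs.side_a, pairs.side_b])))
    t_m = net(Tensor(np.hstack([pairs.side_a[perm], pairs.side_b])))
    return dv_bound_value(t_j.data, t_m.data)


def evaluate_dv_bound(net, pairs: SamplePairBatch, seed: int = 0,
                      n_permutations: int = 10) -> float:
    """DV bound of a trained statistics network, averaged over permutations."""
    rng = np.random.default_rng(seed)
    return float(np.mean([_full_bound(net, pairs, rng)
                          for _ in range(n_permutations)]))
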