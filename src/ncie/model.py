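"""The causal information extractor: recurrent generator + DV discriminator.

The generator is a plain tanh RNN that rolls over the lagged design and emits
an implicit series Z_t from the explicit causes, the (estimated or true)
target value, and its own hidden state, so that Z is jointly shaped by the
explicit variables and by Z's own past.  The discriminator is a statistics
network whose Donsker-Varadhan bound estimates I(Y; explicit, Z).  Both are
trained *simultaneously* by gradient ascent on the same bound: the gradient
flows from the discriminator through Z into the generator, so the generator
learns to emit whatever extra signal makes the measured information largest
-- the footprint of the unobserved causes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from ._autodiff import Adam, Tensor, concat
from ._nn import MLP, RNNCell, Linear
from .design import CausalSpec, LaggedDesign, build_lagged_design
from .information import (BinningSpec, DivergenceError, DVConfig, MIEstimate,
                          SamplePairBatch, dv_bound_value, entropy_binned,
                          evaluate_dv_bound, mi_binned, train_dv_estimator,
                          MAX_HIST_DIMS)
from .panel import PanelTable

__all__ = ["NCIEConfig", "NCIEModel", "ImplicitSeries", "MIGapReport",
           "train_ncie", "generator_forward", "mi_gap_report"]


@dataclass(frozen=True)
class NCIEConfig:
    """Architecture and training settings.

    ``z_dim=None`` defaults to the number of explicit-cause columns
    (lagged X plus Y lags).  ``window_len`` is the truncated-history length:
    training batches are consecutive windows with the hidden state reset at
    each window start.  ``feed_target`` appends the current target value to
    the generator input (the original architecture; the leakage-free
    prediction pipeline feeds a pre-trained estimate instead).
    """

    z_dim: int | None = None
    hidden_dim: int = 32
    window_len: int = 32
    disc_hidden: tuple[int, ...] = (64, 64)
    learning_rate: float = 1e-3
    epochs: int = 500
    ema_decay: float = 0.99
    seed: int = 0
    eval_tail: int = 10
    feed_target: bool = True
    normalize: bool = True
    ceiling: float = 50.0

    def __post_init__(self) -> None:
        if self.z_dim is not None and self.z_dim < 1:
            raise ValueError("z_dim must be >= 1")
        if self.window_len < 1:
            raise ValueError("window_len must be >= 1")


@dataclass(frozen=True)
class ImplicitSeries:
    """Generated implicit variables aligned to the design rows."""

    rows: np.ndarray
    z: np.ndarray  # (n, z_dim)

    def __post_init__(self) -> None:
        if len(self.rows) != len(self.z):
            raise ValueError("rows and z length mismatch")
        if not np.isfinite(self.z).all():
            raise ValueError("non-finite implicit values")


class NCIEModel:
    """Trained generator/discriminator pair plus its normalization state."""

    def __init__(self, spec: CausalSpec, config: NCIEConfig, z_dim: int,
                 cell: RNNCell, readout: Linear, disc: MLP,
                 norm: dict[str, tuple[float, float]]):
        self.spec = spec
        self.config = config
        self.z_dim = z_dim
        self.cell = cell
        self.readout = readout
        self.disc = disc
        self.norm = norm  # per-variable (mean, std)
        self.trained = False
        self.estimate: MIEstimate | None = None

    # -- normalization ----------------------------------------------------
    def normalize_panel(self, panel: PanelTable) -> PanelTable:
        if not self.norm:
            return panel
        data = panel.data.copy()
        for name, (mu, sd) in self.norm.items():
            if name in data.columns:
                data[name] = (data[name] - mu) / sd
        return PanelTable(data)

    def generator_input_dim(self) -> int:
        return (self.spec.n_explicit
                + (1 if self.config.feed_target else 0))

    def parameters(self):
        return (self.cell.parameters() + self.readout.parameters()
                + self.disc.parameters())


def _fit_norm(panel: PanelTable, names: list[str],
              rows: np.ndarray | None = None) -> dict[str, tuple[float, float]]:
    norm = {}
    for name in names:
        col = panel.column(name)
        if rows is not None:
            col = col[rows]
        sd = float(col.std())
        norm[name] = (float(col.mean()), sd if sd > 0 else 1.0)
    return norm


def _gen_inputs(design: LaggedDesign, feed: np.ndarray | None) -> np.ndarray:
    blocks = [design.x_block, design.y_past]
    if feed is not None:
        blocks.append(np.asarray(feed, dtype=float).reshape(-1, 1))
    return np.hstack(blocks)


def _roll_generator(cell: RNNCell, readout: Linear, inputs: np.ndarray,
                    window_len: int | None) -> Tensor:
    """Run the generator over ``inputs`` and return Z for every row.

    With ``window_len`` set, rows are chunked into consecutive windows
    processed as a batch with H reset at each window start (truncated
    history); trailing rows that do not fill a window are processed as one
    shorter window.  With ``window_len=None`` the whole sequence is one
    window (H propagated throughout).
    """
    n = len(inputs)
    if window_len is None or window_len >= n:
        chunks = [(np.arange(n), inputs[None, :, :])]
    else:
        n_trim = (n // window_len) * window_len
        main = inputs[:n_trim].reshape(-1, window_len, inputs.shape[1])
        chunks = [(np.arange(n_trim), main)]
        if n_trim < n:
            chunks.append((np.arange(n_trim, n), inputs[None, n_trim:, :]))
    pieces: list[Tensor] = []
    orders: list[np.ndarray] = []
    for rows_idx, batch in chunks:
        n_win, length, _ = batch.shape
        h = cell.init_state(n_win)
        for s in range(length):
            h = cell.step(Tensor(batch[:, s, :]), h)
            pieces.append(readout(h))  # (n_win, z_dim)
            orders.append(rows_idx.reshape(n_win, length)[:, s])
    z = concat(pieces, axis=0)
    order = np.concatenate(orders)
    inv = np.empty_like(order)
    inv[order] = np.arange(len(order))
    return z.take_rows(inv)  # back to time order


def generator_forward(model: NCIEModel, design: LaggedDesign,
                      feed: np.ndarray | None = None,
                      windowed: bool = False) -> ImplicitSeries:
    """Deterministically emit Z over the design rows with frozen parameters.

    By default the hidden state is propagated over the whole sequence (one
    continuous pass); ``windowed=True`` reproduces the truncated windows used
    during training.
    """
    if feed is None and model.config.feed_target:
        feed = design.y_now
    if not model.config.feed_target:
        feed = None
    inputs = _gen_inputs(design, feed)
    if inputs.shape[1] != model.generator_input_dim():
        raise ValueError("design width does not match the generator input")
    z = _roll_generator(model.cell, model.readout, inputs,
                        model.config.window_len if windowed else None)
    if not np.isfinite(z.data).all():
        raise FloatingPointError("non-finite generator activations")
    return ImplicitSeries(rows=design.rows.copy(), z=z.data.copy())


def train_ncie(panel: PanelTable, spec: CausalSpec,
               config: NCIEConfig = NCIEConfig(),
               feed: np.ndarray | None = None,
               train_rows: np.ndarray | None = None,
               norm: dict[str, tuple[float, float]] | None = None,
               ) -> tuple[NCIEModel, ImplicitSeries, MIEstimate]:
    """Jointly train generator and discriminator on the DV bound.

    Each epoch runs the generator over the (windowed) design in-graph, forms
    joint samples (Y_t, [explicit, Z_t]) and marginal samples with Y_t
    permuted within the batch, and takes one Adam step on the
    moving-average-corrected DV objective for *all* parameters.

    ``feed`` overrides the generator's target input (used by the
    leakage-free pipeline, which passes a pre-trained estimate of Y_t);
    ``train_rows`` restricts the training objective to a subset of design
    rows (e.g. a chronological training split); ``norm`` supplies fixed
    normalization statistics (defaults to full-panel statistics).

    Returns the trained model, Z over all design rows from one continuous
    frozen pass, and the final bound estimate (nats, mean of the last
    ``eval_tail`` epochs) with the per-epoch curve in diagnostics.
    """
    rng = np.random.default_rng(config.seed)
    used = [spec.target] + [v for v, _ in spec.observed_causes]
    used = list(dict.fromkeys(used))
    if config.normalize:
        norm = _fit_norm(panel, used) if norm is None else norm
    else:
        norm = {}
    work = panel
    if norm:
        data = panel.data.copy()
        for name, (mu, sd) in norm.items():
            data[name] = (data[name] - mu) / sd
        work = PanelTable(data)
    design = build_lagged_design(work, spec)
    z_dim = config.z_dim if config.z_dim is not None else spec.n_explicit
    din = spec.n_explicit + (1 if config.feed_target else 0)
    cell = RNNCell(rng, din, config.hidden_dim)
    readout = Linear(rng, config.hidden_dim, z_dim)
    disc = MLP(rng, 1 + spec.n_explicit + z_dim, config.disc_hidden, 1)
    model = NCIEModel(spec, config, z_dim, cell, readout, disc, norm)

    if config.feed_target:
        feed_all = design.y_now if feed is None else np.asarray(feed, float)
        if len(feed_all) != design.n_rows:
            raise ValueError("feed must align with the design rows")
    else:
        feed_all = None
    inputs = _gen_inputs(design, feed_all)
    sub = (np.arange(design.n_rows) if train_rows is None
           else np.asarray(train_rows))
    train_inputs = inputs[sub]
    explicit = design.explicit[sub]
    y_now = design.y_now[sub].reshape(-1, 1)

    opt = Adam(model.parameters(), lr=config.learning_rate)
    ema: float | None = None
    curve: list[float] = []
    for epoch in range(config.epochs):
        z = _roll_generator(cell, readout, train_inputs, config.window_len)
        feat = concat([Tensor(explicit), z], axis=1)
        t_j = disc(concat([Tensor(y_now), feat], axis=1))
        perm = rng.permutation(len(y_now))
        t_m = disc(concat([Tensor(y_now[perm]), feat], axis=1))
        m = t_m.exp().mean()
        if not np.isfinite(m.data):
            raise DivergenceError(
                f"exp(T) overflow at epoch {epoch}")
        ema = float(m.data) if ema is None else (
            config.ema_decay * ema + (1 - config.ema_decay) * float(m.data))
        loss = -(t_j.mean() - m * (1.0 / ema))
        opt.zero_grad()
        loss.backward()
        opt.step()
        bound = dv_bound_value(t_j.data, t_m.data)
        if not np.isfinite(bound) or bound > config.ceiling:
            raise DivergenceError(
                f"DV bound diverged ({bound:.3g} nats) at epoch {epoch}")
        curve.append(bound)
    model.trained = True
    estimate = MIEstimate(float(np.mean(curve[-config.eval_tail:])), "nats",
                          "dv_neural", n_samples=len(y_now),
                          diagnostics={"bound_curve": curve})
    model.estimate = estimate
    z_series = generator_forward(model, design, feed=feed_all)
    return model, z_series, estimate


# ---------------------------------------------------------------------------
# information-gap report
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MIGapReport:
    """How much of H(Y) the explicit causes cover, with and without Z.

    Binned entries are histogram plug-in values in bits (None where the joint
    histogram would exceed the dimension limit); DV entries are neural
    lower bounds converted to bits.  ``h_y_bits`` is the binned entropy of
    the target, the reference ceiling for both.
    """

    h_y_bits: float
    binned_explicit_bits: float | None
    binned_with_z_bits: float | None
    dv_explicit_bits: float
    dv_with_z_bits: float
    n_rows: int
    bins: int

    @property
    def dv_explicit_ratio(self) -> float:
        return self.dv_explicit_bits / self.h_y_bits

    @property
    def dv_with_z_ratio(self) -> float:
        return self.dv_with_z_bits / self.h_y_bits

    def as_dict(self) -> dict:
        return {
            "H(Y) [binned, bits]": self.h_y_bits,
            "I(Y;explicit) [binned, bits]": self.binned_explicit_bits,
            "I(Y;explicit,Z) [binned, bits]": self.binned_with_z_bits,
            "I(Y;explicit) [dv, bits]": self.dv_explicit_bits,
            "I(Y;explicit,Z) [dv, bits]": self.dv_with_z_bits,
            "n_rows": self.n_rows,
            "bins": self.bins,
        }


def mi_gap_report(panel: PanelTable, spec: CausalSpec, model: NCIEModel,
                  z_series: ImplicitSeries | None = None,
                  bins: BinningSpec = BinningSpec(),
                  dv_config: DVConfig | None = None,
                  seed: int = 0) -> MIGapReport:
    """Compute {I(Y;explicit), I(Y;explicit,Z), H(Y)} for a trained model.

    H(Y) and (where the dimension limit allows) the MI terms are histogram
    plug-ins; the MI terms are additionally estimated with the DV route:
    I(Y;explicit) by training a fresh statistics network on the explicit
    block, I(Y;explicit,Z) by evaluating the model's own trained
    discriminator.
    """
    if not model.trained:
        raise ValueError("mi_gap_report requires a trained model")
    work = model.normalize_panel(panel)
    design = build_lagged_design(work, spec)
    if z_series is None:
        z_series = generator_forward(model, design)
    z = z_series.z
    y = design.y_now
    explicit = design.explicit
    h_y = entropy_binned(y, bins).bits

    names = ["__y__"] + list(design.labels)
    table = {"__y__": y}
    table.update({lab: explicit[:, j] for j, lab in enumerate(design.labels)})
    binned_x = None
    if 1 + explicit.shape[1] <= MAX_HIST_DIMS:
        binned_x = mi_binned(table, ["__y__"], list(design.labels), bins).bits
    binned_xz = None
    if 1 + explicit.shape[1] + z.shape[1] <= MAX_HIST_DIMS:
        z_names = [f"__z{j}__" for j in range(z.shape[1])]
        table_z = dict(table)
        table_z.update({nm: z[:, j] for j, nm in enumerate(z_names)})
        binned_xz = mi_binned(table_z, ["__y__"],
                              list(design.labels) + z_names, bins).bits

    dv_config = dv_config or DVConfig(seed=seed)
    dv_x = train_dv_estimator(
        SamplePairBatch(y.reshape(-1, 1), explicit), dv_config).bits
    feat = np.hstack([explicit, z])
    dv_xz = evaluate_dv_bound(
        model.disc, SamplePairBatch(y.reshape(-1, 1), feat),
        seed=seed) / np.log(2.0)
    return MIGapReport(h_y_bits=h_y, binned_explicit_bits=binned_x,
                       binned_with_z_bits=binned_xz, dv_explicit_bits=dv_x,
                       dv_with_z_bits=dv_xz, n_rows=design.n_rows,
                       bins=bins.n_bins)
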