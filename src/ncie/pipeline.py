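"""Leakage-free forecasting workflow with implicit causes.

Four stages run strictly in sequence, each consuming only the previous
stage's frozen outputs:

1. cause selection (a user-supplied list, or an external plugin hook);
2. a recurrent regressor pre-trains an estimate yhat_t of the target from
   the explicit causes alone;
3. the extractor is retrained with yhat_t fed to the generator *instead of*
   the true Y_t, so the implicit series Z carries no direct function of the
   value being predicted;
4. downstream predictors (NN / RNN / LSTM) are fitted with and without the Z
   columns on identical chronological splits and compared by held-out MSE.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from ._autodiff import Adam, Tensor, concat
from ._nn import LSTMCell, MLP, Linear, RNNCell
from .design import CausalSpec, LaggedDesign, build_lagged_design
from .information import MIEstimate
from .model import (ImplicitSeries, NCIEConfig, NCIEModel, _fit_norm,
                    _roll_generator, generator_forward, train_ncie)
from .panel import PanelTable

__all__ = [
    "select_causes", "ChronoSplit", "make_split",
    "PretrainConfig", "PretrainedEstimate", "pretrain_yhat",
    "train_modified_ncie",
    "PredictorConfig", "fit_predictor",
    "PredictionReport", "compare_with_without_z", "audit_no_leakage",
]


# ---------------------------------------------------------------------------
# stage 1: cause selection
# ---------------------------------------------------------------------------

def select_causes(panel: PanelTable, target: str, max_lag: int,
                  causes=None, k: int = 1, plugin=None) -> CausalSpec:
    """Build a validated :class:`CausalSpec`.

    ``causes`` is a list of ``"VAR:LAG"`` strings or ``(name, lag)`` pairs;
    alternatively ``plugin`` is a callable ``(panel, target, max_lag) ->
    [(name, lag), ...]`` (e.g. a wrapper around an external constraint-based
    discovery tool).  Either way the result is validated against the panel
    columns and temporal priority (lag >= 1).
    """
    if max_lag < 1:
        raise ValueError("max_lag must be >= 1")
    if plugin is not None:
        pairs = list(plugin(panel, target, max_lag))
    elif causes is not None:
        pairs = []
        for item in causes:
            if isinstance(item, str):
                name, _, lag = item.partition(":")
                pairs.append((name.strip(), int(lag) if lag else 1))
            else:
                name, lag = item
                pairs.append((str(name), int(lag)))
    else:
        pairs = []
    for name, lag in pairs:
        if name not in panel.columns:
            raise KeyError(f"cause variable {name!r} not in panel")
        if lag < 1:
            raise ValueError(
                f"cause {name!r} at lag {lag} violates temporal priority")
        if lag > max_lag:
            raise ValueError(f"cause {name!r} lag {lag} exceeds max_lag")
    return CausalSpec(target=target, observed_causes=tuple(pairs), k=k)


# ---------------------------------------------------------------------------
# chronological split
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ChronoSplit:
    """Contiguous train/validation/test index sets over design rows."""

    train: np.ndarray
    val: np.ndarray
    test: np.ndarray


def make_split(n: int, fractions: tuple[float, float] = (0.7, 0.15)
               ) -> ChronoSplit:
    """Chronological split: first 70% train, next 15% validation, rest test."""
    n_train = int(n * fractions[0])
    n_val = int(n * fractions[1])
    idx = np.arange(n)
    return ChronoSplit(train=idx[:n_train],
                       val=idx[n_train:n_train + n_val],
                       test=idx[n_train + n_val:])


# ---------------------------------------------------------------------------
# stage 2: pre-trained target estimate
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PretrainConfig:
    hidden_dim: int = 32
    window_len: int = 32
    learning_rate: float = 1e-3
    epochs: int = 200
    patience: int = 30
    seed: int = 0


@dataclass(frozen=True)
class PretrainedEstimate:
    """Frozen recurrent regression of Y_t on the explicit causes.

    ``yhat`` is aligned to the design rows and, for every row t, is computed
    exclusively from panel values at times < t.
    """

    yhat: np.ndarray
    cell_state: tuple
    readout_state: tuple
    split: ChronoSplit
    norm: dict[str, tuple[float, float]]
    train_mse: float
    val_mse: float
    config: PretrainConfig

    def recompute(self, design: LaggedDesign,
                  pconfig: PretrainConfig | None = None) -> np.ndarray:
        """Re-run the frozen regressor over a design (for audits)."""
        cfg = pconfig or self.config
        rng = np.random.default_rng(cfg.seed)
        cell = RNNCell(rng, design.explicit.shape[1], cfg.hidden_dim)
        readout = Linear(rng, cfg.hidden_dim, 1)
        cell.load_state(self.cell_state)
        readout.load_state(self.readout_state)
        return _roll_generator(cell, readout, design.explicit,
                               None).data.ravel()


def pretrain_yhat(panel: PanelTable, spec: CausalSpec,
                  config: PretrainConfig = PretrainConfig(),
                  split: ChronoSplit | None = None) -> PretrainedEstimate:
    """Fit the recurrent regressor of Y_t on (X, Y<t) by MSE.

    Normalization statistics come from the training split only; the
    validation split drives early stopping (best parameters restored);
    parameters are frozen afterward.  Returns yhat over all design rows from
    one continuous frozen pass.
    """
    rng = np.random.default_rng(config.seed)
    probe = build_lagged_design(panel, spec)
    if split is None:
        split = make_split(probe.n_rows)
    used = list(dict.fromkeys(
        [spec.target] + [v for v, _ in spec.observed_causes]))
    # panel rows feeding the training design rows only
    last_train_row = int(probe.rows[split.train[-1]])
    norm = _fit_norm(panel, used, rows=np.arange(last_train_row + 1))
    data = panel.data.copy()
    for name, (mu, sd) in norm.items():
        data[name] = (data[name] - mu) / sd
    design = build_lagged_design(PanelTable(data), spec)

    cell = RNNCell(rng, design.explicit.shape[1], config.hidden_dim)
    readout = Linear(rng, config.hidden_dim, 1)
    opt = Adam(cell.parameters() + readout.parameters(),
               lr=config.learning_rate)
    x_train = design.explicit[split.train]
    y_train = design.y_now[split.train].reshape(-1, 1)
    x_val = design.explicit[split.val]
    y_val = design.y_now[split.val].reshape(-1, 1)
    best = (np.inf, None, None)
    bad = 0
    train_mse = np.inf
    for _ in range(config.epochs):
        pred = _roll_generator(cell, readout, x_train, config.window_len)
        err = pred - Tensor(y_train)
        loss = (err * err).mean()
        opt.zero_grad()
        loss.backward()
        opt.step()
        train_mse = float(loss.data)
        val_pred = _roll_generator(cell, readout, x_val,
                                   config.window_len).data
        val_mse = float(np.mean((val_pred - y_val) ** 2))
        if val_mse < best[0] - 1e-12:
            best = (val_mse, cell.state(), readout.state())
            bad = 0
        else:
            bad += 1
            if bad > config.patience:
                break
    if best[1] is not None:
        cell.load_state(best[1])
        readout.load_state(best[2])
    yhat = _roll_generator(cell, readout, design.explicit, None).data.ravel()
    return PretrainedEstimate(
        yhat=yhat, cell_state=tuple(cell.state()),
        readout_state=tuple(readout.state()), split=split, norm=norm,
        train_mse=train_mse, val_mse=best[0], config=config)


# ---------------------------------------------------------------------------
# stage 3: modified extractor (yhat in place of Y_t)
# ---------------------------------------------------------------------------

def train_modified_ncie(panel: PanelTable, spec: CausalSpec,
                        pre: PretrainedEstimate,
                        config: NCIEConfig = NCIEConfig(),
                        ) -> tuple[NCIEModel, ImplicitSeries, MIEstimate]:
    """Train the extractor with yhat_t fed to the generator instead of Y_t.

    The discriminator's information side still uses the true Y_t -- the
    quantity whose information is being measured -- but the generated Z_t is
    a function of past values and yhat_t only, so no information can leak
    from the value being predicted.  Training uses the pre-training stage's
    normalization and is restricted to its training split; Z over validation
    and test rows comes from rolling the frozen generator forward.
    """
    return train_ncie(panel, spec, config, feed=pre.yhat,
                      train_rows=pre.split.train, norm=pre.norm)


# ---------------------------------------------------------------------------
# stage 4: downstream predictors
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PredictorConfig:
    family: str = "NN"            # NN | RNN | LSTM
    hidden: tuple[int, ...] = (64, 64)  # NN layer widths
    hidden_dim: int = 64          # recurrent state size
    window: int = 32              # sequence length for RNN/LSTM
    learning_rate: float = 1e-3
    epochs: int = 300
    patience: int = 30
    seed: int = 0

    def __post_init__(self) -> None:
        if self.family not in ("NN", "RNN", "LSTM"):
            raise ValueError(f"unknown predictor family {self.family!r}")


def _recurrent_predict(cell, readout, windows: np.ndarray) -> Tensor:
    """Run a recurrent cell over (n, w, d) windows; predict from the last state."""
    n, w, _ = windows.shape
    state = cell.init_state(n)
    is_lstm = isinstance(cell, LSTMCell)
    for s in range(w):
        x = Tensor(windows[:, s, :])
        if is_lstm:
            h, state = cell.step(x, state)
        else:
            state = cell.step(x, state)
            h = state
    return readout(h)


def fit_predictor(features: np.ndarray, y_now: np.ndarray,
                  split: ChronoSplit,
                  config: PredictorConfig = PredictorConfig()
                  ) -> tuple[object, float]:
    """Fit one predictor family and return (fitted modules, test MSE).

    NN consumes the flattened per-row feature vector; RNN/LSTM consume the
    trailing ``window`` rows of features ending at each row (rows without a
    full window are dropped from all splits identically).  Early stopping on
    validation MSE; the split must be fixed before calling and is shared by
    the with-Z and without-Z arms.
    """
    rng = np.random.default_rng(config.seed)
    features = np.asarray(features, dtype=float)
    y = np.asarray(y_now, dtype=float).reshape(-1, 1)
    if features.shape[0] != len(y):
        raise ValueError("features and target row counts differ")
    d = features.shape[1]
    if config.family == "NN":
        net = MLP(rng, d, config.hidden, 1, activation="relu")
        params = net.parameters()

        def forward(idx: np.ndarray) -> Tensor:
            return net(Tensor(features[idx]))
        usable = np.ones(len(y), dtype=bool)
        modules = net
    else:
        w = config.window
        cell_cls = RNNCell if config.family == "RNN" else LSTMCell
        cell = cell_cls(rng, d, config.hidden_dim)
        readout = Linear(rng, config.hidden_dim, 1)
        params = cell.parameters() + readout.parameters()
        pad = np.lib.stride_tricks.sliding_window_view(
            features, w, axis=0)          # (n-w+1, d, w)
        windows = np.ascontiguousarray(np.swapaxes(pad, 1, 2))
        usable = np.zeros(len(y), dtype=bool)
        usable[w - 1:] = True

        def forward(idx: np.ndarray) -> Tensor:
            return _recurrent_predict(cell, readout, windows[idx - (w - 1)])
        modules = (cell, readout)

    tr = split.train[usable[split.train]]
    va = split.val[usable[split.val]]
    te = split.test[usable[split.test]]
    if len(tr) == 0 or len(te) == 0:
        raise ValueError("split leaves no usable train or test rows")
    opt = Adam(params, lr=config.learning_rate)
    states = (modules.state if config.family == "NN"
              else lambda: (modules[0].state(), modules[1].state()))
    best: tuple[float, object] = (np.inf, None)
    bad = 0
    for _ in range(config.epochs):
        pred = forward(tr)
        err = pred - Tensor(y[tr])
        loss = (err * err).mean()
        opt.zero_grad()
        loss.backward()
        opt.step()
        if len(va):
            val_mse = float(np.mean((forward(va).data - y[va]) ** 2))
        else:
            val_mse = float(loss.data)
        if val_mse < best[0] - 1e-12:
            best = (val_mse, states())
            bad = 0
        else:
            bad += 1
            if bad > config.patience:
                break
    if best[1] is not None:
        if config.family == "NN":
            modules.load_state(best[1])
        else:
            modules[0].load_state(best[1][0])
            modules[1].load_state(best[1][1])
    test_mse = float(np.mean((forward(te).data - y[te]) ** 2))
    return modules, test_mse


# ---------------------------------------------------------------------------
# full comparison
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PredictionReport:
    """Held-out MSE per family, with and without the implicit columns."""

    mse_without_z: dict[str, float]
    mse_with_z: dict[str, float]
    config_echo: dict

    def __post_init__(self) -> None:
        if set(self.mse_without_z) != set(self.mse_with_z):
            raise ValueError("family sets differ between arms")
        for table in (self.mse_without_z, self.mse_with_z):
            if any(v < 0 for v in table.values()):
                raise ValueError("negative MSE")

    @property
    def winners(self) -> dict[str, str]:
        return {fam: ("with_z" if self.mse_with_z[fam]
                      <= self.mse_without_z[fam] else "without_z")
                for fam in self.mse_without_z}

    def as_dict(self) -> dict:
        return {"mse_without_z": self.mse_without_z,
                "mse_with_z": self.mse_with_z,
                "winners": self.winners,
                "config": self.config_echo}


def compare_with_without_z(panel: PanelTable, spec: CausalSpec,
                           families: tuple[str, ...] = ("NN", "RNN", "LSTM"),
                           pre_config: PretrainConfig = PretrainConfig(),
                           ncie_config: NCIEConfig = NCIEConfig(),
                           predictor_config: PredictorConfig = PredictorConfig(),
                           seed: int = 0) -> PredictionReport:
    """Run the full four-stage sequence and report the MSE grid.

    Both arms share the chronological split, the seeds, and the
    normalization; they differ only in the presence of the Z columns.
    """
    pre = pretrain_yhat(panel, spec,
                        replace(pre_config, seed=seed))
    model, z_series, _ = train_modified_ncie(
        panel, spec, pre, replace(ncie_config, seed=seed))
    work = model.normalize_panel(panel)
    design = build_lagged_design(work, spec)
    without = design.explicit
    with_z = np.hstack([design.explicit, z_series.z])
    mse_wo: dict[str, float] = {}
    mse_wz: dict[str, float] = {}
    for fam in families:
        cfg = replace(predictor_config, family=fam, seed=seed)
        _, mse_wo[fam] = fit_predictor(without, design.y_now, pre.split, cfg)
        _, mse_wz[fam] = fit_predictor(with_z, design.y_now, pre.split, cfg)
    echo = {"families": list(families), "seed": seed,
            "split": [len(pre.split.train), len(pre.split.val),
                      len(pre.split.test)],
            "z_dim": model.z_dim}
    return PredictionReport(mse_without_z=mse_wo, mse_with_z=mse_wz,
                            config_echo=echo)


def audit_no_leakage(panel: PanelTable, spec: CausalSpec,
                     pre: PretrainedEstimate, model: NCIEModel,
                     row: int, delta: float = 10.0,
                     atol: float = 1e-10) -> bool:
    """Perturb Y at one design row and check yhat and Z are unchanged there.

    Returns True when |yhat_t| and |Z_t| at the perturbed row move by less
    than ``atol`` -- i.e. neither quantity is a function of the value being
    predicted at that time.
    """
    def run(p: PanelTable) -> tuple[float, np.ndarray]:
        data = p.data.copy()
        for name, (mu, sd) in pre.norm.items():
            data[name] = (data[name] - mu) / sd
        design = build_lagged_design(PanelTable(data), spec)
        yhat = pre.recompute(design)
        z = generator_forward(model, design, feed=yhat)
        return yhat[row], z.z[row]

    base_yhat, base_z = run(panel)
    data = panel.data.copy()
    panel_row = build_lagged_design(panel, spec).rows[row]
    data.iloc[panel_row, data.columns.get_loc(spec.target)] += delta
    pert_yhat, pert_z = run(PanelTable(data))
    return (abs(pert_yhat - base_yhat) < atol
            and np.all(np.abs(pert_z - base_z) < atol))
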