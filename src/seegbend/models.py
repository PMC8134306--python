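"""The two bending-regression networks and their training protocol.

*HcF* regresses a 3-dof bending label from 96 handcrafted per-point
features: a dense 96->5 input stage with a parametric rectifier, three
hidden blocks (dense 5 -> PReLU -> dropout), and a final dense layer
with 3 outputs.

*E2E* is a two-branch network: the unit electrode direction passes
through dense 3->5 + ReLU; a one-channel 9x9x9 image window passes
through a 3x3x3 zero-padded 3D convolution + leaky ReLU + 2x2x2 max
pooling.  The flattened branches are stacked and fed to two blocks
(dense 32 and dense 8, each leaky ReLU + batch norm + dropout) and a
final dense layer with 3 outputs.

Both are trained with Adam (lr 1e-3, weight decay 1e-3) to minimize the
MSE loss, 200 epochs with validation every 5 epochs, reducing the
learning rate tenfold on a training-loss plateau; the checkpoint kept is
the one with the best validation loss.  Monte-Carlo-dropout inference
keeps dropout active (p = 0.1) over T = 200 forward passes and reports
the per-component mean and epistemic variance; batch-norm statistics
stay frozen during MC passes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from . import nn

__all__ = [
    "TrainConfig", "MCConfig", "Prediction",
    "HcFNet", "E2ENet", "build_hcf_model", "build_e2e_model",
    "train_model", "predict", "TrainedModel",
    "N_FEATURES", "WINDOW_SIZE",
]

N_FEATURES = 96
WINDOW_SIZE = 9


@dataclass
class TrainConfig:
    """Optimizer / schedule settings (defaults follow the training protocol)."""

    lr: float = 1e-3
    weight_decay: float = 1e-3
    epochs: int = 200
    validate_every: int = 5
    batch_size: int = 64
    dropout_p: float = 0.1
    scheduler_factor: float = 0.1
    scheduler_patience: int = 10
    min_lr: float = 1e-6
    seed: int = 0
    label_kind: str = "lu"

    def __post_init__(self):
        if self.lr <= 0 or self.epochs < 1 or self.batch_size < 1:
            raise ValueError("rates/counts must be positive")
        if self.label_kind not in ("lu", "eb"):
            raise ValueError("label_kind must be 'lu' or 'eb'")


@dataclass
class MCConfig:
    """Monte-Carlo-dropout inference settings."""

    dropout_p: float = 0.1
    n_passes: int = 200
    seed: int = 0

    def __post_init__(self):
        if not 0 <= self.dropout_p < 1:
            raise ValueError("dropout probability must be in [0, 1)")
        if self.n_passes < 1:
            raise ValueError("n_passes (T) must be >= 1")


@dataclass
class Prediction:
    """3-dof label estimate; per-component epistemic variance in MC mode only."""

    mean: np.ndarray
    variance: np.ndarray | None = None


class _Net:
    """Shared plumbing for both model families."""

    def params(self):
        raise NotImplementedError

    def forward(self, inputs: dict, **kw) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy) -> None:
        raise NotImplementedError

    def extra_state(self):
        raise NotImplementedError

    def load_extra_state(self, state):
        raise NotImplementedError

    def state(self) -> dict:
        return nn.clone_state(self.params(), self.extra_state())

    def load_state(self, state: dict) -> None:
        nn.load_state(self.params(), self.load_extra_state, state)

    def set_dropout_p(self, p: float) -> None:
        for layer in self._all_layers():
            if isinstance(layer, nn.Dropout):
                layer.p = p

    def dropout_p(self) -> float:
        for layer in self._all_layers():
            if isinstance(layer, nn.Dropout):
                return layer.p
        return 0.0

    def n_parameters(self) -> int:
        return sum(p.value.size for p in self.params())


class HcFNet(_Net):
    """Handcrafted-features regression network (96 -> 3)."""

    family = "hcf"
    input_keys = ("features",)

    def __init__(self, seed: int = 0, n_features: int = N_FEATURES,
                 hidden: int = 5, dropout_p: float = 0.1):
        rng = np.random.default_rng(seed)
        layers = [nn.Dense(n_features, hidden, rng), nn.PReLU()]
        for _ in range(3):
            layers += [nn.Dense(hidden, hidden, rng), nn.PReLU(),
                       nn.Dropout(dropout_p)]
        layers += [nn.Dense(hidden, 3, rng, init_scale=0.01)]
        self.net = nn.Sequential(*layers)
        self.n_features = n_features

    def _all_layers(self):
        return self.net.layers

    def params(self):
        return self.net.params()

    def forward(self, inputs, **kw):
        x = np.atleast_2d(inputs["features"])
        return self.net.forward(x, **kw)

    def backward(self, dy):
        self.net.backward(dy)

    def extra_state(self):
        return self.net.extra_state()

    def load_extra_state(self, state):
        self.net.load_extra_state(state)


class E2ENet(_Net):
    """Direction + image-window regression network.

    The convolution channel count is configurable (default 8); with a
    9x9x9 window the pooled image branch is ``channels * 4^3`` wide.
    """

    family = "e2e"
    input_keys = ("direction", "window")

    def __init__(self, conv_channels: int = 8, seed: int = 0,
                 window: int = WINDOW_SIZE, dropout_p: float = 0.1):
        if conv_channels < 1:
            raise ValueError("conv_channels must be >= 1")
        rng = np.random.default_rng(seed)
        self.window = window
        self.dir_branch = nn.Sequential(nn.Dense(3, 5, rng), nn.ReLU())
        self.img_branch = nn.Sequential(
            nn.Conv3d(1, conv_channels, rng, input_grad=False),
            nn.LeakyReLU(),
            nn.MaxPool3d(2),
            nn.Flatten(),
        )
        img_dim = conv_channels * (window // 2) ** 3
        self.head = nn.Sequential(
            nn.Dense(5 + img_dim, 32, rng), nn.LeakyReLU(),
            nn.BatchNorm1d(32), nn.Dropout(dropout_p),
            nn.Dense(32, 8, rng), nn.LeakyReLU(),
            nn.BatchNorm1d(8), nn.Dropout(dropout_p),
            nn.Dense(8, 3, rng, init_scale=0.01),
        )
        self._split = 5

    def _all_layers(self):
        return self.dir_branch.layers + self.img_branch.layers + self.head.layers

    def params(self):
        return (self.dir_branch.params() + self.img_branch.params()
                + self.head.params())

    def forward(self, inputs, **kw):
        d = np.atleast_2d(inputs["direction"])
        w = np.asarray(inputs["window"], dtype=float)
        if w.ndim == 3:
            w = w[None]
        if w.ndim == 4:  # (B, D, H, W) -> add channel axis
            w = w[:, None]
        a = self.dir_branch.forward(d, **kw)
        b = self.img_branch.forward(w, **kw)
        z = np.concatenate([a, b], axis=1)
        return self.head.forward(z, **kw)

    def backward(self, dy):
        dz = self.head.backward(dy)
        self.dir_branch.backward(dz[:, : self._split])
        self.img_branch.backward(dz[:, self._split :])

    def extra_state(self):
        return {
            "dir": self.dir_branch.extra_state(),
            "img": self.img_branch.extra_state(),
            "head": self.head.extra_state(),
        }

    def load_extra_state(self, state):
        self.dir_branch.load_extra_state(state.get("dir", {}))
        self.img_branch.load_extra_state(state.get("img", {}))
        self.head.load_extra_state(state.get("head", {}))


def build_hcf_model(seed: int = 0, dropout_p: float = 0.1) -> HcFNet:
    """Seeded construction of the handcrafted-features network."""
    return HcFNet(seed=seed, dropout_p=dropout_p)


def build_e2e_model(conv_channels: int = 8, seed: int = 0,
                    dropout_p: float = 0.1) -> E2ENet:
    """Seeded construction of the direction + image-window network."""
    return E2ENet(conv_channels=conv_channels, seed=seed, dropout_p=dropout_p)


# ---------------------------------------------------------------------------
# training


def _batch(inputs: dict, idx) -> dict:
    return {k: v[idx] for k, v in inputs.items()}


def _eval_loss(model: _Net, dataset: dict, batch_size: int = 512) -> float:
    n = len(dataset["y"])
    total = 0.0
    for start in range(0, n, batch_size):
        idx = slice(start, min(start + batch_size, n))
        pred = model.forward(_batch(dataset["inputs"], idx))
        diff = pred - dataset["y"][idx]
        total += float(np.sum(diff * diff))
    return total / (n * dataset["y"].shape[1])


def train_model(model: _Net, train_set: dict, val_set: dict,
                cfg: TrainConfig):
    """Train a network; returns ``(model_at_best_val, history)``.

    ``train_set`` / ``val_set`` are dicts ``{"inputs": {name: array},
    "y": (N, 3) array}``.  Records the train loss per epoch, validation
    loss every ``cfg.validate_every`` epochs, and the learning rate; the
    returned parameters are those of the best validation epoch.
    """
    for name, ds in (("train", train_set), ("validation", val_set)):
        if len(ds["y"]) == 0:
            raise ValueError(f"{name} dataset is empty")
    rng = np.random.default_rng(cfg.seed)
    opt = nn.Adam(model.params(), lr=cfg.lr, weight_decay=cfg.weight_decay)
    sched = nn.ReduceLROnPlateau(
        opt, factor=cfg.scheduler_factor, patience=cfg.scheduler_patience,
        min_lr=cfg.min_lr,
    )
    n = len(train_set["y"])
    rows = []
    best_val = np.inf
    best_state = model.state()
    # fixed subsample for the deterministic plateau monitor (cheap, seeded)
    mon_idx = (np.arange(n) if n <= 2048
               else np.sort(rng.choice(n, 2048, replace=False)))
    monitor_set = {"inputs": _batch(train_set["inputs"], mon_idx),
                   "y": train_set["y"][mon_idx]}

    for epoch in range(1, cfg.epochs + 1):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            opt.zero_grad()
            pred = model.forward(_batch(train_set["inputs"], idx),
                                 train=True, rng=rng)
            loss, dgrad = nn.mse_loss(pred, train_set["y"][idx])
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"non-finite training loss at epoch {epoch} "
                    f"(lr={opt.lr:.2e}, batch of {len(idx)})"
                )
            model.backward(dgrad)
            opt.step()
            epoch_loss += loss * len(idx)
        epoch_loss /= n
        # plateau detection on a deterministic (dropout-off) epoch loss:
        # the stochastic batch-mean loss carries dropout noise that makes
        # a lucky dip look like an unbeatable best
        monitor_loss = _eval_loss(model, monitor_set)
        sched.step(monitor_loss, epoch)

        val_loss = np.nan
        if epoch % cfg.validate_every == 0 or epoch == cfg.epochs:
            val_loss = _eval_loss(model, val_set)
            if val_loss < best_val:
                best_val = val_loss
                best_state = model.state()
        rows.append({"epoch": epoch, "train_loss": epoch_loss,
                     "monitor_loss": monitor_loss, "val_loss": val_loss,
                     "lr": opt.lr})

    model.load_state(best_state)
    history = pd.DataFrame(rows)
    history.attrs["lr_drop_epochs"] = list(sched.drop_epochs)
    history.attrs["best_val_loss"] = float(best_val)
    return model, history


# ---------------------------------------------------------------------------
# prediction


def predict(model: _Net, inputs: dict, mode: str = "direct",
            mc_cfg: MCConfig | None = None) -> Prediction:
    """Single deterministic pass, or T stochastic MC-dropout passes.

    Direct mode disables dropout.  MC mode runs ``mc_cfg.n_passes``
    forward passes with dropout active at ``mc_cfg.dropout_p`` (batch
    norm frozen at running statistics) and returns the per-component
    mean and population variance across passes.
    """
    if mode == "direct":
        out = model.forward(inputs)
        return Prediction(mean=np.squeeze(out))
    if mode != "mc":
        raise ValueError("mode must be 'direct' or 'mc'")
    mc_cfg = mc_cfg or MCConfig()
    rng = np.random.default_rng(mc_cfg.seed)
    saved_p = model.dropout_p()
    model.set_dropout_p(mc_cfg.dropout_p)
    try:
        outs = np.stack([
            model.forward(inputs, stochastic=True, rng=rng)
            for _ in range(mc_cfg.n_passes)
        ])
    finally:
        model.set_dropout_p(saved_p)
    return Prediction(
        mean=np.squeeze(outs.mean(axis=0)),
        variance=np.squeeze(outs.var(axis=0)),
    )


# ---------------------------------------------------------------------------
# trained-model bundle


@dataclass
class TrainedModel:
    """A trained network plus everything needed to run it on new points."""

    net: _Net
    label_kind: str
    family: str                      # 'hcf' | 'e2e'
    source: str = "tissue"           # e2e window source: 'intensity' | 'tissue'
    normalizer: object = None        # features.FeatureNormalizer for hcf
    feature_schema_version: str = "v1"
    train_config: TrainConfig | None = None
    history: pd.DataFrame | None = field(default=None, repr=False)

    def predict(self, inputs: dict, mode: str = "direct",
                mc_cfg: MCConfig | None = None) -> Prediction:
        return predict(self.net, inputs, mode=mode, mc_cfg=mc_cfg)

    def save(self, path) -> None:
        """Checkpoint: parameters + running stats + config, as .npz."""
        state = self.net.state()
        arrays = {f"param_{i}": v for i, v in enumerate(state["params"])}
        meta = {
            "label_kind": self.label_kind,
            "family": self.family,
            "source": self.source,
            "feature_schema_version": self.feature_schema_version,
            "train_config": asdict(self.train_config) if self.train_config else None,
            "extra": _jsonify(state["extra"]),
            "normalizer": (self.normalizer.state_dict()
                           if self.normalizer is not None else None),
        }
        import json
        np.savez(path, __meta__=np.frombuffer(
            json.dumps(meta).encode(), dtype=np.uint8), **arrays)

    @classmethod
    def load(cls, path) -> "TrainedModel":
        import json
        from .features import FeatureNormalizer

        with np.load(path) as data:
            meta = json.loads(bytes(data["__meta__"]).decode())
            params = [data[f"param_{i}"]
                      for i in range(sum(k.startswith("param_") for k in data))]
        cfgd = meta["train_config"]
        cfg = TrainConfig(**cfgd) if cfgd else None
        dropout_p = cfg.dropout_p if cfg else 0.1
        if meta["family"] == "hcf":
            net = build_hcf_model(dropout_p=dropout_p)
        else:
            # infer channel count from the first conv kernel
            conv_shape = params[2].shape if params[2].ndim == 5 else None
            channels = conv_shape[0] if conv_shape else 8
            net = build_e2e_model(conv_channels=channels, dropout_p=dropout_p)
        net.load_state({"params": params, "extra": _unjsonify(meta["extra"])})
        normalizer = None
        if meta["normalizer"] is not None:
            normalizer = FeatureNormalizer.from_state_dict(meta["normalizer"])
        return cls(net=net, label_kind=meta["label_kind"], family=meta["family"],
                   source=meta["source"], normalizer=normalizer,
                   feature_schema_version=meta["feature_schema_version"],
                   train_config=cfg)


def _jsonify(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, np.ndarray):
        return {"__array__": obj.tolist()}
    return obj


def _unjsonify(obj):
    if isinstance(obj, dict):
        if "__array__" in obj:
            return np.asarray(obj["__array__"], dtype=float)
        return {k: _unjsonify(v) for k, v in obj.items()}
    return obj
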