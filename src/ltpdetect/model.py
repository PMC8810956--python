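"""The 3D convolutional patch classifier: model and results objects.

The network takes a three-channel 32×32×8 patch and emits one sigmoid
probability of local tumor progression.  Its printed stage shapes are
fixed by the architecture: three same-padded 3×3×3 convolutions with 16,
32 and 64 feature maps, the first two each followed by a 2×2×2 max pool
(so spatial size halves along all three axes), then fully connected
layers of 512 and 128 rectified-linear units and the sigmoid output:

    16@8×32×32 → 32@4×16×16 → 64@2×8×8 → flatten(8192) → 512 → 128 → σ

Usage follows the model/results pattern::

    clf = LTPClassifier(train_x, train_y, val_x, val_y)
    res = clf.fit(TrainConfig(epochs=20, seed=0))
    probs = res.predict_proba(test_x)
    print(res.summary())
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from . import _nn

__all__ = [
    "NetworkSpec",
    "TrainConfig",
    "infer_stage_shapes",
    "build_network",
    "LTPClassifier",
    "LTPClassifierResults",
    "TrainedModel",
    "train",
    "predict_proba",
]


@dataclass(frozen=True)
class NetworkSpec:
    """Architecture hyperparameters; defaults are the reference network."""

    input_shape: tuple[int, int, int, int] = (3, 8, 32, 32)  # (C, D, H, W)
    conv_kernel: int = 3
    pool_kernel: int = 2
    conv_feature_maps: tuple[int, ...] = (16, 32, 64)
    fc_units: tuple[int, ...] = (512, 128)

    @property
    def n_pools(self) -> int:
        # a pool follows every convolution except the last
        return len(self.conv_feature_maps) - 1


@dataclass(frozen=True)
class TrainConfig:
    """Training hyperparameters; every field is logged with the run."""

    loss: str = "binary_cross_entropy"
    optimizer: str = "adam"
    learning_rate: float = 1e-3
    batch_size: int = 32
    epochs: int = 100
    patience: int = 10          # early stopping on validation loss
    seed: int = 0


def infer_stage_shapes(spec: NetworkSpec) -> list[tuple[int, int, int, int]]:
    """Analytic feature-map shapes after each convolution stage.

    Same-padded convolutions preserve spatial size; each pooling stage
    halves all three spatial axes.  Returns ``(feature_maps, depth,
    height, width)`` per conv stage; raises if pooling does not divide a
    spatial dimension.
    """
    _, d, h, w = spec.input_shape
    k = spec.pool_kernel
    shapes = []
    for i, f in enumerate(spec.conv_feature_maps):
        shapes.append((f, d, h, w))
        if i < spec.n_pools:
            if d % k or h % k or w % k:
                raise ValueError(
                    f"pool kernel {k} does not divide stage shape {(d, h, w)}"
                )
            d, h, w = d // k, h // k, w // k
    return shapes


def flattened_size(spec: NetworkSpec) -> int:
    f, d, h, w = infer_stage_shapes(spec)[-1]
    return f * d * h * w


def build_network(spec: NetworkSpec, rng: np.random.Generator | None = None,
                  zero_init: bool = False) -> _nn.Sequential:
    """Instantiate the network for a spec (He-initialised, or all-zero)."""
    rng = rng or np.random.default_rng(0)
    layers: list[_nn.Layer] = []
    in_ch = spec.input_shape[0]
    for i, f in enumerate(spec.conv_feature_maps):
        layers.append(_nn.Conv3d(in_ch, f, spec.conv_kernel, rng=rng,
                                 first_layer=(i == 0)))
        layers.append(_nn.ReLU())
        if i < spec.n_pools:
            layers.append(_nn.MaxPool3d(spec.pool_kernel))
        in_ch = f
    layers.append(_nn.Flatten())
    n_in = flattened_size(spec)
    for units in spec.fc_units:
        layers.append(_nn.Dense(n_in, units, rng=rng))
        layers.append(_nn.ReLU())
        n_in = units
    layers.append(_nn.Dense(n_in, 1, rng=rng))  # logit; sigmoid applied outside
    net = _nn.Sequential(layers)
    if zero_init:
        for p in net.params:
            p[...] = 0
    return net


def _coerce_x(data, spec: NetworkSpec, what: str = "patches") -> np.ndarray:
    """Accept a PatchSet, list of Patch, or array; return float32 in [0, 1]."""
    if hasattr(data, "data") and hasattr(data, "labels"):  # PatchSet
        arr = data.data
    elif isinstance(data, (list, tuple)) and data and hasattr(data[0], "data"):
        arr = np.stack([p.data for p in data])
    else:
        arr = np.asarray(data)
    if arr.ndim == 4:
        arr = arr[None]
    if arr.ndim != 5 or arr.shape[1:] != spec.input_shape:
        raise ValueError(
            f"{what}: expected shape (n, {', '.join(map(str, spec.input_shape))}), "
            f"got {arr.shape}"
        )
    arr = arr.astype(np.float32)
    if arr.max() > 1.0:
        arr = arr / 255.0
    return arr


class LTPClassifier:
    """Model object: patch data plus architecture, ready to ``fit``.

    Parameters
    ----------
    train_x, train_y : patches and binary labels of the training split.
    val_x, val_y : held-out validation patches used for early stopping.
        Training and validation patches must come from disjoint cases;
        the constructor checks this when case ids are available.
    spec : NetworkSpec, optional
    """

    def __init__(self, train_x, train_y=None, val_x=None, val_y=None,
                 spec: NetworkSpec | None = None):
        self.spec = spec or NetworkSpec()
        if train_y is None and hasattr(train_x, "labels"):
            train_y = train_x.labels
        if val_y is None and hasattr(val_x, "labels"):
            val_y = val_x.labels
        if hasattr(train_x, "case_ids") and hasattr(val_x, "case_ids"):
            overlap = set(train_x.case_ids) & set(val_x.case_ids)
            if overlap:
                raise ValueError(
                    f"train and validation share cases: {sorted(overlap)[:5]}"
                )
        self.train_x = _coerce_x(train_x, self.spec, "training patches")
        self.train_y = np.asarray(train_y, dtype=np.float32).ravel()
        if val_x is None or (hasattr(val_x, "__len__") and len(val_x) == 0):
            raise ValueError("a non-empty validation set is required")
        self.val_x = _coerce_x(val_x, self.spec, "validation patches")
        self.val_y = np.asarray(val_y, dtype=np.float32).ravel()
        if len(self.train_x) != len(self.train_y):
            raise ValueError("training patches and labels differ in length")
        if len(np.unique(self.train_y)) < 2:
            raise ValueError("training set holds a single class; cannot train")

    @classmethod
    def from_patchset(cls, ps, spec: NetworkSpec | None = None,
                      train_split: str = "train", val_split: str = "val"):
        return cls(ps.subset(train_split), None, ps.subset(val_split), None,
                   spec=spec)

    def fit(self, config: TrainConfig | None = None) -> "LTPClassifierResults":
        """Train with mini-batch Adam and validation-loss early stopping.

        Returns the results object holding the parameters of the best
        epoch (lowest validation loss), the per-epoch training log, and
        the full configuration.
        """
        cfg = config or TrainConfig()
        rng = np.random.default_rng(cfg.seed)
        net = build_network(self.spec, rng=rng)
        opt = _nn.Adam(net.params, lr=cfg.learning_rate)
        n = len(self.train_x)
        log_rows = []
        best_loss, best_state, best_epoch = np.inf, net.get_state(), 0
        since_best = 0
        for epoch in range(1, cfg.epochs + 1):
            order = rng.permutation(n)
            total, seen = 0.0, 0
            for start in range(0, n, cfg.batch_size):
                idx = order[start:start + cfg.batch_size]
                z = net.forward(self.train_x[idx]).ravel()
                loss, dz = _nn.bce_with_logits(z, self.train_y[idx])
                net.backward(dz.reshape(-1, 1))
                opt.step(net.grads)
                total += loss * len(idx)
                seen += len(idx)
            val_z = _forward_batched(net, self.val_x)
            val_loss, _ = _nn.bce_with_logits(val_z, self.val_y)
            log_rows.append(
                {"epoch": epoch, "train_loss": total / seen, "val_loss": val_loss}
            )
            if val_loss < best_loss - 1e-6:
                best_loss, best_state, best_epoch = val_loss, net.get_state(), epoch
                since_best = 0
            else:
                since_best += 1
                if since_best >= cfg.patience:
                    break
        net.set_state(best_state)
        return LTPClassifierResults(
            spec=self.spec, config=cfg, parameters=best_state,
            training_log=pd.DataFrame(log_rows), best_epoch=best_epoch,
        )


@dataclass
class LTPClassifierResults:
    """A fitted classifier: learned parameters, log, and prediction API."""

    spec: NetworkSpec
    config: TrainConfig
    parameters: list[np.ndarray]
    training_log: pd.DataFrame
    best_epoch: int
    _net: _nn.Sequential | None = field(default=None, repr=False)

    def _network(self) -> _nn.Sequential:
        if self._net is None:
            self._net = build_network(self.spec)
            self._net.set_state(self.parameters)
        return self._net

    def predict_proba(self, patches) -> np.ndarray:
        """Sigmoid probabilities in [0, 1], one per patch; deterministic."""
        x = _coerce_x(patches, self.spec)
        return _nn.sigmoid(_forward_batched(self._network(), x))

    def predict(self, patches, threshold: float = 0.5) -> np.ndarray:
        return (self.predict_proba(patches) >= threshold).astype(int)

    def summary(self) -> str:
        shapes = infer_stage_shapes(self.spec)
        lines = [
            "LTP patch classifier (3D CNN)",
            "=" * 46,
            f"input: {self.spec.input_shape} (C, D, H, W), values scaled to [0,1]",
        ]
        for i, (f, d, h, w) in enumerate(shapes, 1):
            lines.append(f"conv{i} ({self.spec.conv_kernel}^3, same): {f}@{d}x{h}x{w}")
        lines.append(f"flatten: {flattened_size(self.spec)}")
        for units in self.spec.fc_units:
            lines.append(f"dense: {units} (ReLU)")
        lines.append("output: 1 (sigmoid)")
        lines.append("-" * 46)
        n_params = sum(p.size for p in self.parameters)
        last = self.training_log.iloc[-1]
        lines.append(f"parameters: {n_params:,}")
        lines.append(f"epochs run: {len(self.training_log)} "
                     f"(best: {self.best_epoch})")
        lines.append(f"final train loss: {last['train_loss']:.4f}")
        lines.append(f"best val loss:    "
                     f"{self.training_log['val_loss'].min():.4f}")
        lines.append(f"optimizer: {self.config.optimizer}, "
                     f"lr={self.config.learning_rate}, "
                     f"batch={self.config.batch_size}, seed={self.config.seed}")
        return "\n".join(lines)

    def save(self, path) -> None:
        """Persist spec + config + weights in one ``.npz`` archive."""
        meta = json.dumps({"spec": asdict(self.spec), "config": asdict(self.config),
                           "best_epoch": self.best_epoch})
        arrays = {f"param_{i}": p for i, p in enumerate(self.parameters)}
        np.savez_compressed(
            path, meta=np.frombuffer(meta.encode(), dtype=np.uint8),
            log=self.training_log.to_records(index=False), **arrays,
        )

    @classmethod
    def load(cls, path) -> "LTPClassifierResults":
        with np.load(path, allow_pickle=False) as fh:
            meta = json.loads(bytes(fh["meta"]).decode())
            n = len([k for k in fh.files if k.startswith("param_")])
            params = [fh[f"param_{i}"] for i in range(n)]
            log = pd.DataFrame(fh["log"])
        spec_d = meta["spec"]
        for key in ("input_shape", "conv_feature_maps", "fc_units"):
            spec_d[key] = tuple(spec_d[key])
        return cls(NetworkSpec(**spec_d), TrainConfig(**meta["config"]), params,
                   log, meta["best_epoch"])


#: alias used at the pipeline surface
TrainedModel = LTPClassifierResults


def _forward_batched(net: _nn.Sequential, x: np.ndarray,
                     batch: int = 64) -> np.ndarray:
    outs = [net.forward(x[i:i + batch]).ravel() for i in range(0, len(x), batch)]
    return np.concatenate(outs) if outs else np.empty(0)


def forward_stage_shapes(spec: NetworkSpec, batch: int = 2) -> list[tuple[int, ...]]:
    """Shapes actually produced by a forward pass, one per conv stage."""
    net = build_network(spec)
    x = np.zeros((batch, *spec.input_shape), dtype=np.float32)
    shapes = []
    for layer in net.layers:
        x = layer.forward(x)
        if isinstance(layer, _nn.Conv3d):
            shapes.append(tuple(x.shape[1:]))
    return shapes


def train(patches, labels, val_patches, val_labels,
          cfg: TrainConfig | None = None,
          spec: NetworkSpec | None = None) -> TrainedModel:
    """Functional wrapper over :class:`LTPClassifier`."""
    return LTPClassifier(patches, labels, val_patches, val_labels,
                         spec=spec).fit(cfg)


def predict_proba(model: TrainedModel, patches) -> np.ndarray:
    return model.predict_proba(patches)
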