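"""The CNN-ECA gesture classifier: architecture, training, persistence.

Layer order: [conv(3,3)+BN+ReLU] -> ECA -> [conv(4,3)+BN+ReLU] ->
[conv(5,3)+BN+ReLU] -> flatten -> FC+ReLU -> ECA -> dropout -> softmax.

Windows enter as 2-D maps of (time x electrode) with one feature plane, so
the stacked 2-D kernels span the temporal and electrode dimensions together.
The first ECA module attends over the electrode axis of the conv-1 feature
map (cross-channel interaction between the armband's sensors); the second
attends over the final fully connected features, gating the decision layer.

The adaptive ECA kernel size follows K = |log2(C)/gamma + b/gamma|_odd with
gamma=2, b=1 (set gamma=1 for the literal log2(C)+1/2 reading).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import nn
from .errors import ValidationError
from .nn import eca_kernel_size as _eca_kernel_size, eca_forward as _eca_forward
from .windows import WindowSet


@dataclass(frozen=True)
class EcaConfig:
    gamma: float = 2.0
    b: float = 1.0
    tie_break: str = "up"

    def validate(self) -> None:
        if self.gamma <= 0:
            raise ValidationError("gamma must be positive")
        if self.tie_break not in ("up", "down"):
            raise ValidationError("tie_break must be 'up' or 'down'")


def eca_kernel_size(C: int, cfg: EcaConfig | None = None) -> int:
    cfg = cfg or EcaConfig()
    cfg.validate()
    return _eca_kernel_size(C, cfg.gamma, cfg.b, cfg.tie_break)


def eca_forward(features, cfg: EcaConfig | None = None, conv_weights=None):
    if conv_weights is None:
        raise ValidationError("conv_weights is required")
    return _eca_forward(features, conv_weights)


@dataclass(frozen=True)
class ModelSpec:
    input_shape: tuple[int, int, int] = (300, 8, 1)
    conv_kernels: tuple = ((3, 3), (4, 3), (5, 3))
    conv_filters: tuple = (32, 64, 128)
    conv_strides: tuple = ((1, 1), (1, 1), (1, 1))
    padding: str = "same"
    fc_units: tuple = (128,)
    dropout_rate: float = 0.5
    n_classes: int = 8
    eca_after_first_conv: bool = True
    eca_after_final_fc: bool = True

    def validate(self) -> None:
        if len(self.conv_kernels) != len(self.conv_filters) or \
                len(self.conv_kernels) != len(self.conv_strides):
            raise ValidationError("conv_kernels/filters/strides lengths must match")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValidationError("dropout_rate must be in [0, 1)")
        if self.n_classes < 2:
            raise ValidationError("n_classes must be >= 2")
        if self.padding not in ("same", "valid"):
            raise ValidationError("padding must be 'same' or 'valid'")
        if len(self.input_shape) != 3:
            raise ValidationError("input_shape must be (window_len, width, planes)")


@dataclass(frozen=True)
class TrainConfig:
    learning_rate: float = 1e-4
    epochs: int = 300
    batch_size: int = 128
    seed: int = 0

    def validate(self) -> None:
        if self.learning_rate <= 0:
            raise ValidationError("learning_rate must be positive")
        if self.epochs < 1:
            raise ValidationError("epochs must be >= 1")
        if self.batch_size < 1:
            raise ValidationError("batch_size must be >= 1")


VARIANTS = ("conv1d", "conv2d", "conv2d_eca", "full")


def variant_spec(variant: str, window_len: int, n_channels: int,
                 n_classes: int = 8, compact: bool = True) -> ModelSpec:
    """ModelSpec for one ablation variant.

    'conv1d' collapses the electrode axis into input feature planes and uses
    1-D kernels of the same temporal extents; the others are 2-D.  Attention
    is enabled for 'conv2d_eca' and 'full' ('full' additionally consumes
    envelope rather than raw windows — the caller's responsibility).
    ``compact`` selects the desk-scale capacity (filters 8/16/32, temporal
    strides 3/2/2, FC 64) used for the package's own experiments.
    """
    if variant not in VARIANTS:
        raise ValidationError(f"unknown variant {variant!r}")
    filters = (8, 16, 32) if compact else (32, 64, 128)
    strides = ((3, 1), (2, 1), (2, 1)) if compact else ((1, 1), (1, 1), (1, 1))
    fc = (64,) if compact else (128,)
    eca = variant in ("conv2d_eca", "full")
    if variant == "conv1d":
        return ModelSpec(input_shape=(window_len, 1, n_channels),
                         conv_kernels=((3, 1), (4, 1), (5, 1)),
                         conv_filters=filters, conv_strides=strides,
                         fc_units=fc, n_classes=n_classes,
                         eca_after_first_conv=False, eca_after_final_fc=False)
    return ModelSpec(input_shape=(window_len, n_channels, 1),
                     conv_kernels=((3, 3), (4, 3), (5, 3)),
                     conv_filters=filters, conv_strides=strides,
                     fc_units=fc, n_classes=n_classes,
                     eca_after_first_conv=eca, eca_after_final_fc=eca)


def compact_spec(window_len: int, n_channels: int, n_classes: int = 8) -> ModelSpec:
    """Desk-scale CNN-ECA spec (see variant_spec)."""
    return variant_spec("full", window_len, n_channels, n_classes, compact=True)


def desk_train_config(seed: int = 0, epochs: int = 30) -> TrainConfig:
    """Training profile for desk-scale runs: Adam 1e-3, batch 64."""
    return TrainConfig(learning_rate=1e-3, epochs=epochs, batch_size=64, seed=seed)


class EcaNet(nn.Sequential):
    """Sequential CNN-ECA with its spec attached."""

    def __init__(self, layers, spec: ModelSpec, eca_cfg: EcaConfig):
        super().__init__(layers)
        self.spec = spec
        self.eca_cfg = eca_cfg

    @property
    def eca_layers(self) -> list[nn.EcaLayer]:
        return [l for l in self.layers if isinstance(l, nn.EcaLayer)]


def build_model(spec: ModelSpec, eca: EcaConfig | None = None,
                seed: int = 0) -> EcaNet:
    """Assemble an untrained CNN-ECA; raises at build time if shapes collapse."""
    eca = eca or EcaConfig()
    spec.validate()
    eca.validate()
    ss = np.random.SeedSequence(seed)
    rngs = [np.random.default_rng(s) for s in ss.spawn(16)]
    ri = iter(rngs)

    layers: list[nn.Layer] = []
    shape = tuple(spec.input_shape)  # (H, W, C)
    for i, (kern, nf, stride) in enumerate(
            zip(spec.conv_kernels, spec.conv_filters, spec.conv_strides)):
        conv = nn.Conv2D(kern[0], kern[1], shape[2], nf, stride=stride,
                         padding=spec.padding, rng=next(ri))
        shape = conv.out_shape(shape)
        if min(shape) < 1:
            raise ValidationError(f"feature map collapsed after conv {i + 1}: {shape}")
        layers += [conv, nn.BatchNorm(nf), nn.ReLU()]
        if i == 0 and spec.eca_after_first_conv:
            # attend over the electrode axis (W) of the conv-1 feature map
            layers.append(nn.EcaLayer(shape[1], eca.gamma, eca.b, eca.tie_break,
                                      axis=2))
    layers.append(nn.Flatten())
    width = int(np.prod(shape))
    for u in spec.fc_units:
        layers += [nn.Dense(width, u, rng=next(ri)), nn.ReLU()]
        width = u
    if spec.eca_after_final_fc:
        layers.append(nn.EcaLayer(width, eca.gamma, eca.b, eca.tie_break, axis=-1))
    layers.append(nn.Dropout(spec.dropout_rate, rng=next(ri)))
    layers.append(nn.Dense(width, spec.n_classes, rng=next(ri)))
    return EcaNet(layers, spec, eca)


def arrange_input(windows: np.ndarray, spec: ModelSpec) -> np.ndarray:
    """Map [n, window_len, n_channels] windows onto the spec's input layout."""
    windows = np.asarray(windows, dtype=float)
    if windows.ndim == 2:
        windows = windows[None]
    h, w, c = spec.input_shape
    if windows.shape[1] != h:
        raise ValidationError(
            f"window length {windows.shape[1]} does not match spec input {h}")
    if w == 1 and c == windows.shape[2]:      # 1-D layout: channels as planes
        return windows[:, :, None, :]
    if c == 1 and w == windows.shape[2]:      # 2-D layout: channels as width
        return windows[:, :, :, None]
    raise ValidationError(
        f"windows with {windows.shape[2]} channels do not fit input_shape {spec.input_shape}")


@dataclass
class TrainedModel:
    net: EcaNet
    history: pd.DataFrame          # per-epoch train/val loss and accuracy
    best_epoch: int                # 1-based epoch whose checkpoint is loaded
    label_map: dict[int, int]      # class id -> output column
    train_cfg: TrainConfig

    @property
    def spec(self) -> ModelSpec:
        return self.net.spec


def _evaluate_split(net: EcaNet, x: np.ndarray, y: np.ndarray,
                    batch: int = 256) -> tuple[float, float]:
    losses, correct = [], 0
    for i in range(0, len(x), batch):
        logits = net.forward(x[i:i + batch], training=False)
        loss, p, _ = nn.softmax_cross_entropy(logits, y[i:i + batch])
        losses.append(loss * len(p))
        correct += int((p.argmax(axis=1) == y[i:i + batch]).sum())
    return float(np.sum(losses) / len(x)), correct / len(x)


def train(model: EcaNet, ws: WindowSet, cfg: TrainConfig | None = None) -> TrainedModel:
    """Adam / categorical cross-entropy training with per-epoch validation
    checkpointing: parameters are stored whenever validation accuracy strictly
    improves and the checkpointed (not final) parameters are returned."""
    cfg = cfg or TrainConfig()
    cfg.validate()
    x_tr, y_tr = ws.subset("train")
    x_va, y_va = ws.subset("val")
    if len(x_tr) == 0 or len(x_va) == 0:
        raise ValidationError("train and val splits must be non-empty")
    classes = np.unique(ws.labels)
    for name in ("train", "val"):
        present = np.unique(ws.subset(name)[1])
        if len(present) < len(classes):
            raise ValidationError(f"not every class is represented in the {name} split")

    x_tr = arrange_input(x_tr, model.spec)
    x_va = arrange_input(x_va, model.spec)
    ss = np.random.SeedSequence(cfg.seed)
    shuffle_rng, drop_rng = (np.random.default_rng(s) for s in ss.spawn(2))
    for layer in model.layers:          # reseed dropout from the training seed
        if isinstance(layer, nn.Dropout):
            layer.rng = drop_rng

    opt = nn.Adam(model, lr=cfg.learning_rate)
    best_acc, best_epoch, best_state = -np.inf, 0, None
    rows = []
    for epoch in range(1, cfg.epochs + 1):
        order = shuffle_rng.permutation(len(x_tr))
        ep_loss, ep_correct = 0.0, 0
        for i in range(0, len(order), cfg.batch_size):
            idx = order[i:i + cfg.batch_size]
            logits = model.forward(x_tr[idx], training=True)
            loss, p, dlogits = nn.softmax_cross_entropy(logits, y_tr[idx])
            model.backward(dlogits)
            opt.step()
            ep_loss += loss * len(idx)
            ep_correct += int((p.argmax(axis=1) == y_tr[idx]).sum())
        val_loss, val_acc = _evaluate_split(model, x_va, y_va)
        rows.append({"epoch": epoch,
                     "train_loss": ep_loss / len(x_tr),
                     "train_acc": ep_correct / len(x_tr),
                     "val_loss": val_loss, "val_acc": val_acc})
        if val_acc > best_acc:
            best_acc, best_epoch, best_state = val_acc, epoch, model.state()
    model.load_state(best_state)
    history = pd.DataFrame(rows)
    label_map = {int(c): int(c) for c in classes}
    return TrainedModel(model, history, best_epoch, label_map, cfg)


def train_model(spec: ModelSpec, ws: WindowSet, cfg: TrainConfig,
                eca: EcaConfig | None = None) -> TrainedModel:
    """Build (seeded from cfg.seed) and train in one call."""
    return train(build_model(spec, eca, seed=cfg.seed), ws, cfg)


def predict_proba(tm: TrainedModel, windows: np.ndarray,
                  batch: int = 256) -> np.ndarray:
    """Class probabilities per window (dropout off, deterministic)."""
    x = arrange_input(windows, tm.spec)
    out = [nn.softmax(tm.net.forward(x[i:i + batch], training=False))
           for i in range(0, len(x), batch)]
    return np.concatenate(out)


def first_eca_attention(tm: TrainedModel, windows: np.ndarray) -> np.ndarray:
    """Attention weights of the first ECA module, per window and electrode."""
    ecas = tm.net.eca_layers
    if not ecas:
        raise ValidationError("model has no ECA modules")
    predict_proba(tm, windows)
    return ecas[0].last_attention.copy()


def n_parameters(net: EcaNet) -> int:
    """Stored parameter count (conv/dense weights+biases, 4 per BN channel,
    K per ECA module), matching a Keras-style total including BN statistics."""
    return net.n_params()


# -- persistence ------------------------------------------------------------

def save_model(tm: TrainedModel, out_dir: str | Path) -> Path:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    meta = {
        "spec": _spec_to_json(tm.spec),
        "eca": asdict(tm.net.eca_cfg),
        "train_cfg": asdict(tm.train_cfg),
        "best_epoch": tm.best_epoch,
        "label_map": {str(k): v for k, v in tm.label_map.items()},
    }
    (out_dir / "model.json").write_text(json.dumps(meta, indent=2))
    arrays = {}
    for li, (variables, buffers) in enumerate(tm.net.state()):
        for k, v in variables.items():
            arrays[f"l{li}.var.{k}"] = v
        for k, v in buffers.items():
            arrays[f"l{li}.buf.{k}"] = v
    np.savez(out_dir / "params.npz", **arrays)
    tm.history.to_csv(out_dir / "history.csv", index=False)
    return out_dir


def _spec_to_json(spec: ModelSpec) -> dict:
    d = asdict(spec)
    for k in ("input_shape", "conv_kernels", "conv_filters", "conv_strides", "fc_units"):
        d[k] = [list(v) if isinstance(v, tuple) else v for v in d[k]] \
            if k in ("conv_kernels", "conv_strides") else list(d[k])
    return d


def load_model(in_dir: str | Path) -> TrainedModel:
    in_dir = Path(in_dir)
    meta = json.loads((in_dir / "model.json").read_text())
    sd = meta["spec"]
    spec = ModelSpec(
        input_shape=tuple(sd["input_shape"]),
        conv_kernels=tuple(tuple(k) for k in sd["conv_kernels"]),
        conv_filters=tuple(sd["conv_filters"]),
        conv_strides=tuple(tuple(s) for s in sd["conv_strides"]),
        padding=sd["padding"], fc_units=tuple(sd["fc_units"]),
        dropout_rate=sd["dropout_rate"], n_classes=sd["n_classes"],
        eca_after_first_conv=sd["eca_after_first_conv"],
        eca_after_final_fc=sd["eca_after_final_fc"],
    )
    net = build_model(spec, EcaConfig(**meta["eca"]))
    with np.load(in_dir / "params.npz") as data:
        for name in data.files:
            lpart, kind, key = name.split(".", 2)
            li = int(lpart[1:])
            target = net.layers[li].variables if kind == "var" else net.layers[li].buffers
            target[key] = data[name]
    history = pd.read_csv(in_dir / "history.csv")
    label_map = {int(k): v for k, v in meta["label_map"].items()}
    return TrainedModel(net, history, meta["best_epoch"], label_map,
                        TrainConfig(**meta["train_cfg"]))
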