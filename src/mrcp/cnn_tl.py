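"""VGG-style CNN classifier with parameter transfer learning, plus an
SVM-RBF baseline.

The architecture follows the 16-layer VGG pattern: 13 convolutional layers
(3x3 kernels, ReLU, same padding, max pooling between blocks) and 3 fully
connected layers ending in a softmax head. EEG input is channels x
datapoints x 1; because the 8-row channel axis cannot be halved five
times, the first two pools are 2x2 and the remaining three are 1x2
(temporal only) — the layer counts are unchanged. A ``width_multiplier``
scales every layer width so desk-scale CPU training stays tractable.

Parameter transfer: copy all pretrained weights into an identical target
network, replace the softmax head (sized to the target task), freeze the
low-level convolutional layers, and fine-tune the high-level layers on
target-domain data with the softmax cross-entropy loss.
"""

from __future__ import annotations

import copy
import hashlib
from dataclasses import dataclass, field, asdict

import numpy as np
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from mrcp import nn

#: VGG-16 convolutional widths; "P" marks a pooling boundary
_VGG16_PLAN = [64, 64, "P", 128, 128, "P", 256, 256, 256, "P",
               512, 512, 512, "P", 512, 512, 512, "P"]
_FC_WIDTH = 4096
#: pool shapes in order; 2x2 until the 8-row spatial axis is exhausted,
#: then temporal-only
_POOLS = [(2, 2), (2, 2), (1, 2), (1, 2), (1, 2)]


@dataclass
class ModelSpec:
    """Architecture description: 13 conv + 3 FC layers and their widths."""

    input_shape: tuple[int, int, int]  # (channels, datapoints, 1)
    n_classes: int = 2
    width_multiplier: float = 0.25
    conv_widths: list[int] = field(default_factory=list)
    fc_widths: list[int] = field(default_factory=list)
    pools: list[tuple[int, int]] = field(default_factory=lambda: list(_POOLS))
    #: microvolts per network input unit — fixed input normalization so the
    #: He-initialized stack starts in a well-conditioned regime
    input_scale: float = 5.0
    #: dropout rate on the two hidden fully connected layers (the classic
    #: VGG regularizer); applied during training only
    dropout: float = 0.5

    def __post_init__(self) -> None:
        c, t, d = self.input_shape
        if d != 1:
            raise ValueError("input must be channels x datapoints x 1")
        if t < 32:
            raise ValueError(
                f"datapoints {t} too short for the five-stage pooling cascade; need >= 32"
            )
        if not self.conv_widths:
            self.conv_widths = [max(1, int(w * self.width_multiplier))
                                for w in _VGG16_PLAN if w != "P"]
        if not self.fc_widths:
            fc = max(2, int(_FC_WIDTH * self.width_multiplier))
            self.fc_widths = [fc, fc, self.n_classes]

    @property
    def n_conv(self) -> int:
        return len(self.conv_widths)

    @property
    def n_fc(self) -> int:
        return len(self.fc_widths)

    def feature_map_shapes(self) -> list[tuple[int, int, int]]:
        """(C, H, W) after every conv/pool stage, following the VGG plan."""
        c_spatial, t, _ = self.input_shape
        shapes = []
        c_in, h, w = 1, c_spatial, t
        wi = 0
        pi = 0
        for item in _VGG16_PLAN:
            if item == "P":
                ph, pw = self.pools[pi]
                h, w = h // ph, w // pw
                pi += 1
            else:
                c_in = self.conv_widths[wi]
                wi += 1
            shapes.append((c_in, h, w))
        return shapes

    def param_count(self) -> int:
        count = 0
        c_in = 1
        for c_out in self.conv_widths:
            count += c_out * (c_in * 9 + 1)
            c_in = c_out
        c, h, w = self.feature_map_shapes()[-1]
        n_in = c * h * w
        for n_out in self.fc_widths:
            count += n_in * n_out + n_out
            n_in = n_out
        return count


@dataclass
class TrainConfig:
    """Training hyperparameters; all fields are recorded in run history."""

    lr: float = 1e-3
    epochs: int = 50
    batch_size: int = 32
    optimizer: str = "adam"
    seed: int = 0
    patience: int = 5
    weight_decay: float = 1e-4

    def __post_init__(self) -> None:
        if self.optimizer != "adam":
            raise ValueError("only the adam optimizer is implemented")


@dataclass
class TransferConfig:
    """Transfer strategy: freeze the first ``frozen_depth`` convolutional
    layers; the softmax head is always replaced and resized."""

    frozen_depth: int = 8
    replace_head: bool = True
    seed: int = 0


class CNNModel:
    """A ModelSpec realized as an initialized layer stack."""

    def __init__(self, spec: ModelSpec, seed: int = 0) -> None:
        self.spec = spec
        rng = np.random.default_rng(seed)
        layers: list[nn.Layer] = []
        c_in = 1
        wi = 0
        pi = 0
        for item in _VGG16_PLAN:
            if item == "P":
                layers.append(nn.MaxPool(*spec.pools[pi]))
                pi += 1
            else:
                c_out = spec.conv_widths[wi]
                layers.append(nn.Conv2D(c_in, c_out, rng))
                layers.append(nn.ReLU())
                c_in = c_out
                wi += 1
        layers.append(nn.Flatten())
        c, h, w = spec.feature_map_shapes()[-1]
        n_in = c * h * w
        for j, n_out in enumerate(spec.fc_widths):
            layers.append(nn.Dense(n_in, n_out, rng))
            if j < len(spec.fc_widths) - 1:
                layers.append(nn.ReLU())
                if spec.dropout > 0:
                    layers.append(nn.Dropout(spec.dropout, seed=seed + 1000 + j))
            n_in = n_out
        self.net = nn.Sequential(layers)

    def set_training(self, training: bool) -> None:
        for layer in self.net.layers:
            if isinstance(layer, nn.Dropout):
                layer.training = training

    # -- introspection -------------------------------------------------
    def conv_layers(self) -> list[nn.Conv2D]:
        return [l for l in self.net.layers if isinstance(l, nn.Conv2D)]

    def dense_layers(self) -> list[nn.Dense]:
        return [l for l in self.net.layers if isinstance(l, nn.Dense)]

    @property
    def head(self) -> nn.Dense:
        return self.dense_layers()[-1]

    def n_params(self) -> int:
        return sum(l.n_params for l in self.net.layers)

    def copy(self) -> "CNNModel":
        return copy.deepcopy(self)

    def _to_nchw(self, batch: np.ndarray) -> np.ndarray:
        # (N, channels, datapoints, 1) -> (N, 1, channels, datapoints)
        if batch.ndim != 4 or batch.shape[1:] != tuple(self.spec.input_shape):
            raise ValueError(
                f"batch shape {batch.shape[1:]} does not match spec input "
                f"{tuple(self.spec.input_shape)}"
            )
        return (batch.transpose(0, 3, 1, 2) / self.spec.input_scale).astype(nn.DTYPE)

    def forward_logits(self, batch: np.ndarray) -> np.ndarray:
        return self.net.forward(self._to_nchw(batch))


def build_vgg(
    input_shape: tuple[int, int, int],
    n_classes: int = 2,
    width_multiplier: float = 0.25,
) -> ModelSpec:
    """Describe the 13-conv + 3-FC VGG-style architecture for this input."""
    return ModelSpec(
        input_shape=tuple(input_shape),
        n_classes=n_classes,
        width_multiplier=width_multiplier,
    )


def softmax_xent(p: np.ndarray, x: np.ndarray) -> float:
    """Cross-entropy H(x, p) = -sum_i x_i log p_i for one prediction.

    ``p`` are output probabilities, ``x`` the one-hot truth. Zero
    probabilities are epsilon-clipped at 1e-12.
    """
    p = np.asarray(p, dtype=float)
    x = np.asarray(x, dtype=float)
    return float(-np.sum(x * np.log(np.clip(p, 1e-12, None))))


def _batches(n: int, batch_size: int, rng: np.random.Generator):
    idx = rng.permutation(n)
    for start in range(0, n, batch_size):
        yield idx[start : start + batch_size]


def _evaluate_loss(model: CNNModel, X: np.ndarray, y: np.ndarray,
                   batch_size: int = 256) -> float:
    total, count = 0.0, 0
    for start in range(0, len(X), batch_size):
        xb = X[start : start + batch_size]
        yb = y[start : start + batch_size]
        logits = model.forward_logits(xb)
        loss, _ = nn.softmax_xent_from_logits(logits, yb)
        total += loss * len(xb)
        count += len(xb)
    return total / max(count, 1)


def _fit(model: CNNModel, X: np.ndarray, y: np.ndarray, cfg: TrainConfig,
         val: tuple[np.ndarray, np.ndarray] | None = None) -> dict:
    """Shared training loop: Adam + early stopping on validation loss."""
    rng = np.random.default_rng(cfg.seed)
    opt = nn.Adam(model.net, lr=cfg.lr, weight_decay=cfg.weight_decay)
    history: dict = {"train_loss": [], "val_loss": [], "config": asdict(cfg)}
    best_val = np.inf
    stale = 0
    for _epoch in range(cfg.epochs):
        epoch_loss, seen = 0.0, 0
        for idx in _batches(len(X), cfg.batch_size, rng):
            model.set_training(True)
            logits = model.forward_logits(X[idx])
            model.set_training(False)
            loss, dlogits = nn.softmax_xent_from_logits(logits, y[idx])
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"training diverged at epoch {_epoch}: loss={loss}"
                )
            model.net.backward(dlogits)
            opt.step()
            epoch_loss += loss * len(idx)
            seen += len(idx)
        history["train_loss"].append(epoch_loss / max(seen, 1))
        if val is not None:
            vl = _evaluate_loss(model, *val)
            history["val_loss"].append(vl)
            if vl < best_val - 1e-6:
                best_val = vl
                stale = 0
            else:
                stale += 1
                if stale > cfg.patience:
                    break
    return history


def train(
    spec: ModelSpec,
    data: tuple[np.ndarray, np.ndarray],
    cfg: TrainConfig | None = None,
    val: tuple[np.ndarray, np.ndarray] | None = None,
) -> tuple[CNNModel, dict]:
    """Train a freshly initialized network from the spec.

    ``data`` is (X, y) with X shaped (N, channels, datapoints, 1) and
    integer labels y. Deterministic for a fixed cfg.seed. With
    ``cfg.epochs == 0`` the initialization is returned untouched.
    """
    if cfg is None:
        cfg = TrainConfig()
    X, y = data
    if len(X) and len(np.unique(y)) < min(spec.n_classes, 2):
        raise ValueError("need at least one example of each class to train")
    model = CNNModel(spec, seed=cfg.seed)
    history = _fit(model, X, y, cfg, val) if cfg.epochs > 0 else {
        "train_loss": [], "val_loss": [], "config": asdict(cfg)}
    return model, history


def transfer(
    pretrained: CNNModel,
    target_n_classes: int,
    tcfg: TransferConfig | None = None,
) -> CNNModel:
    """Build the target model: copy weights, new head, freeze low layers.

    Every non-head parameter is copied from the pretrained model; the
    softmax head is re-initialized with ``target_n_classes`` outputs; the
    first ``frozen_depth`` convolutional layers are marked non-trainable.
    """
    if tcfg is None:
        tcfg = TransferConfig()
    target_spec = ModelSpec(
        input_shape=pretrained.spec.input_shape,
        n_classes=target_n_classes,
        width_multiplier=pretrained.spec.width_multiplier,
        conv_widths=list(pretrained.spec.conv_widths),
        fc_widths=list(pretrained.spec.fc_widths[:-1]) + [target_n_classes],
        pools=list(pretrained.spec.pools),
    )
    model = pretrained.copy()
    model.spec = target_spec
    # replace the head; zero-initialized so the transferred model starts at
    # uniform class probabilities and fine-tuning moves it monotonically
    rng = np.random.default_rng(tcfg.seed)
    penultimate = model.spec.fc_widths[-2] if len(model.spec.fc_widths) > 1 else (
        int(np.prod(model.spec.feature_map_shapes()[-1])))
    new_head = nn.Dense(penultimate, target_n_classes, rng)
    new_head.params["W"][:] = 0.0
    head_pos = [i for i, l in enumerate(model.net.layers)
                if isinstance(l, nn.Dense)][-1]
    model.net.layers[head_pos] = new_head
    # freeze low-level conv layers
    convs = model.conv_layers()
    if tcfg.frozen_depth > len(convs):
        raise ValueError(
            f"frozen_depth {tcfg.frozen_depth} exceeds {len(convs)} conv layers"
        )
    for layer in convs[: tcfg.frozen_depth]:
        layer.trainable = False
    return model


def fine_tune(
    model: CNNModel,
    data: tuple[np.ndarray, np.ndarray],
    cfg: TrainConfig | None = None,
    val: tuple[np.ndarray, np.ndarray] | None = None,
) -> tuple[CNNModel, dict]:
    """Fine-tune a transferred model; only unfrozen parameters move."""
    if cfg is None:
        cfg = TrainConfig(lr=1e-4)
    X, y = data
    history = _fit(model, X, y, cfg, val) if cfg.epochs > 0 else {
        "train_loss": [], "val_loss": [], "config": asdict(cfg)}
    return model, history


def predict(model: CNNModel, batch: np.ndarray, batch_size: int = 256) -> np.ndarray:
    """Class probability matrix; each row sums to 1."""
    if len(batch) == 0:
        return np.zeros((0, model.spec.n_classes))
    probs = []
    for start in range(0, len(batch), batch_size):
        logits = model.forward_logits(batch[start : start + batch_size])
        probs.append(nn.softmax(logits.astype(np.float64)))
    return np.concatenate(probs)


def frozen_checksums(model: CNNModel) -> dict[int, str]:
    """SHA-256 of every frozen layer's parameter bytes (freeze audit)."""
    out = {}
    for i, layer in enumerate(model.net.layers):
        if layer.params and not layer.trainable:
            h = hashlib.sha256()
            for name in sorted(layer.params):
                h.update(np.ascontiguousarray(layer.params[name]).tobytes())
            out[i] = h.hexdigest()
    return out


def svm_baseline(
    train_data: tuple[np.ndarray, np.ndarray],
    test_X: np.ndarray,
    C: float = 1.0,
    gamma: str | float = "scale",
) -> np.ndarray:
    """RBF-kernel SVM reference classifier on flattened, standardized windows."""
    X, y = train_data
    if len(np.unique(y)) < 2:
        raise ValueError("SVM baseline needs at least two classes in training data")
    clf = make_pipeline(StandardScaler(), SVC(kernel="rbf", C=C, gamma=gamma))
    clf.fit(X.reshape(len(X), -1), y)
    return clf.predict(test_X.reshape(len(test_X), -1))
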