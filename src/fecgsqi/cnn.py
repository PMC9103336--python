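"""Four-path residual spectrogram CNN for NI-FECG quality classification.

One convolutional path per ECG channel (maternal chest plus three
abdominal leads, or abdominal-only in the three-path variant).  Each path
stacks three residual blocks — a pair of stride-1 Conv2D layers with
batch normalization and ReLU, summed with a 1x1-convolution bypass —
followed by a 24-unit fully connected layer.  The per-path outputs are
concatenated into a single sigmoid output unit giving the probability
that the input segment is of good quality.  Training minimizes binary
cross-entropy with Adam (lr 0.0005); the weights kept are those of the
epoch with the highest validation AUC.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.metrics import roc_auc_score

from fecgsqi.errors import ConfigError
from fecgsqi.nn import Adam, BatchNorm2d, Conv2d, Dense, MaxPool2x2, ReLU, bce_with_logits

__all__ = [
    "ArchConfig",
    "TrainConfig",
    "FourPathCNN",
    "build_model",
    "train",
    "predict",
    "save_model",
    "load_model",
    "REDUCED_ARCH",
]

_INPUT_SHAPE = (40, 126)
_PIXEL_SCALE = 128.0  # greyscale range of the input images


@dataclass(frozen=True)
class ArchConfig:
    """Architecture parameters.

    ``filters`` gives the width of the three residual blocks; ``pool``
    inserts 2x2 max pooling after each block, which shrinks the dense
    layer and is the recommended setting for CPU-bound runs.
    """

    n_paths: int = 4
    filters: tuple[int, int, int] = (16, 32, 64)
    kernel: tuple[int, int] = (3, 3)
    fc_units: int = 24
    input_shape: tuple[int, int] = _INPUT_SHAPE
    pool: bool = False

    def __post_init__(self) -> None:
        if self.n_paths not in (3, 4):
            raise ConfigError("n_paths must be 4 (with maternal) or 3 (abdominal only)")
        if len(self.filters) != 3:
            raise ConfigError("exactly three residual blocks per path")
        if len(self.input_shape) != 2 or min(self.input_shape) < 8:
            raise ConfigError("invalid input_shape")


#: Desk-scale architecture for CPU runs: narrower blocks plus pooling.
REDUCED_ARCH = ArchConfig(filters=(8, 16, 32), pool=True)


@dataclass(frozen=True)
class TrainConfig:
    epochs: int = 200
    batch_size: int = 28
    learning_rate: float = 5e-4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise ConfigError("epochs must be >= 1")
        if self.learning_rate <= 0:
            raise ConfigError("learning_rate must be positive")


class _ResidualBlock:
    """conv-BN-ReLU-conv-BN summed with a batch-normalized 1x1 bypass."""

    def __init__(self, c_in: int, c_out: int, kernel, rng):
        self.conv1 = Conv2d(c_in, c_out, kernel, rng)
        self.bn1 = BatchNorm2d(c_out)
        self.relu1 = ReLU()
        self.conv2 = Conv2d(c_out, c_out, kernel, rng)
        self.bn2 = BatchNorm2d(c_out)
        self.bypass = Conv2d(c_in, c_out, (1, 1), rng)
        self.bn_bypass = BatchNorm2d(c_out)
        self.relu_out = ReLU()

    @property
    def layers(self):
        return [self.conv1, self.bn1, self.relu1, self.conv2, self.bn2, self.bypass, self.bn_bypass, self.relu_out]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        main = self.relu1.forward(self.bn1.forward(self.conv1.forward(x, train), train), train)
        main = self.bn2.forward(self.conv2.forward(main, train), train)
        side = self.bn_bypass.forward(self.bypass.forward(x, train), train)
        return self.relu_out.forward(main + side, train)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        d = self.relu_out.backward(dout)
        d_side = self.bypass.backward(self.bn_bypass.backward(d))
        d_main = self.conv1.backward(
            self.relu1.backward(self.bn1.backward(self.conv2.backward(self.bn2.backward(d))))
        )
        return d_main + d_side


class FourPathCNN:
    """The multi-path residual CNN (one convolutional path per channel)."""

    def __init__(self, config: ArchConfig, seed: int = 0):
        self.config = config
        rng = np.random.default_rng(seed)
        h, w = config.input_shape
        self.paths = []
        for _ in range(config.n_paths):
            blocks = []
            c_in = 1
            ph, pw = h, w
            for f in config.filters:
                blocks.append(_ResidualBlock(c_in, f, config.kernel, rng))
                if config.pool:
                    blocks.append(MaxPool2x2())
                    ph, pw = ph // 2, pw // 2
                c_in = f
            fc = Dense(c_in * ph * pw, config.fc_units, rng)
            self.paths.append({"blocks": blocks, "fc": fc, "fc_relu": ReLU(), "flat_dim": c_in * ph * pw})
        self.head = Dense(config.n_paths * config.fc_units, 1, rng)

    # -- parameter plumbing -------------------------------------------------
    def _layers(self):
        for path in self.paths:
            for blk in path["blocks"]:
                if isinstance(blk, _ResidualBlock):
                    yield from blk.layers
                else:
                    yield blk
            yield path["fc"]
            yield path["fc_relu"]
        yield self.head

    def parameters(self):
        for layer in self._layers():
            yield from layer.params

    def get_weights(self):
        return [p.copy() for p, _ in self.parameters()] + [
            np.concatenate([bn.running_mean, bn.running_var])
            for bn in self._layers()
            if isinstance(bn, BatchNorm2d)
        ]

    def set_weights(self, weights) -> None:
        params = list(self.parameters())
        for (p, _), saved in zip(params, weights[: len(params)]):
            p[...] = saved
        bns = [l for l in self._layers() if isinstance(l, BatchNorm2d)]
        for bn, saved in zip(bns, weights[len(params) :]):
            c = saved.size // 2
            bn.running_mean = saved[:c].copy()
            bn.running_var = saved[c:].copy()

    # -- forward / backward -------------------------------------------------
    def forward(self, images: np.ndarray, train: bool = False) -> np.ndarray:
        """Logits for a batch of images shaped (N, n_paths, 40, 126)."""
        images = np.asarray(images, dtype=np.float32)
        expected = (self.config.n_paths,) + tuple(self.config.input_shape)
        if images.ndim != 4 or images.shape[1:] != expected:
            raise ConfigError(f"expected input of shape (N,) + {expected}, got {images.shape}")
        x = images / _PIXEL_SCALE
        feats = []
        self._batch_n = images.shape[0]
        for p, path in enumerate(self.paths):
            h = x[:, p, :, :, None]  # (N, H, W, 1) channels-last
            for blk in path["blocks"]:
                h = blk.forward(h, train)
            h = h.reshape(h.shape[0], -1)
            h = path["fc_relu"].forward(path["fc"].forward(h, train), train)
            feats.append(h)
        return self.head.forward(np.concatenate(feats, axis=1), train)[:, 0]

    def backward(self, dlogits: np.ndarray) -> None:
        d = self.head.backward(dlogits[:, None])
        fc_units = self.config.fc_units
        for p, path in enumerate(self.paths):
            dp = d[:, p * fc_units : (p + 1) * fc_units]
            dp = path["fc"].backward(path["fc_relu"].backward(dp))
            shape = self._feat_shape(path)
            dp = dp.reshape((self._batch_n,) + shape)
            for blk in reversed(path["blocks"]):
                dp = blk.backward(dp)

    def _feat_shape(self, path) -> tuple[int, int, int]:
        h, w = self.config.input_shape
        if self.config.pool:
            for _ in self.config.filters:
                h, w = h // 2, w // 2
        return (h, w, self.config.filters[-1])


def build_model(config: ArchConfig | None = None, seed: int = 0) -> FourPathCNN:
    """Construct the multi-path residual CNN with seeded initialization."""
    return FourPathCNN(config or ArchConfig(), seed=seed)


def predict(model: FourPathCNN, images: np.ndarray, batch_size: int = 64) -> np.ndarray:
    """Good-quality probabilities in (0, 1), one per input segment."""
    images = np.asarray(images, dtype=np.float32)
    if images.shape[0] == 0:
        return np.empty(0)
    probs = []
    for i in range(0, images.shape[0], batch_size):
        logits = model.forward(images[i : i + batch_size], train=False)
        probs.append(1.0 / (1.0 + np.exp(-logits.astype(np.float64))))
    return np.concatenate(probs)


def train(
    model: FourPathCNN,
    train_images: np.ndarray,
    train_labels: np.ndarray,
    val_images: np.ndarray,
    val_labels: np.ndarray,
    config: TrainConfig | None = None,
) -> tuple[list, dict]:
    """Train with Adam/BCE, keeping the weights of the best-val-AUC epoch.

    Returns ``(best_weights, history)`` where ``history`` holds per-epoch
    training loss, training accuracy and validation AUC.  On ties the
    earliest epoch wins.  The model is left loaded with the best weights.
    """
    config = config or TrainConfig()
    train_labels = np.asarray(train_labels, dtype=np.float32)
    val_labels = np.asarray(val_labels, dtype=np.float32)
    if train_labels.size == 0 or val_labels.size == 0:
        raise ConfigError("train and validation sets must be non-empty")
    if np.unique(val_labels).size < 2:
        raise ConfigError("validation set must contain both classes (AUC undefined)")

    rng = np.random.default_rng(config.seed)
    opt = Adam(model.parameters(), lr=config.learning_rate)
    history: dict = {"train_loss": [], "train_acc": [], "val_auc": []}
    best_auc, best_weights = -np.inf, None

    n = train_labels.size
    for _epoch in range(config.epochs):
        order = rng.permutation(n)
        losses, correct = [], 0
        for i in range(0, n, config.batch_size):
            idx = order[i : i + config.batch_size]
            logits = model.forward(train_images[idx], train=True)
            loss, dz = bce_with_logits(logits, train_labels[idx])
            model.backward(dz)
            opt.step()
            losses.append(loss * idx.size)
            correct += int(np.sum((logits > 0) == (train_labels[idx] > 0.5)))
        val_scores = predict(model, val_images)
        val_auc = float(roc_auc_score(val_labels, val_scores))
        history["train_loss"].append(float(np.sum(losses) / n))
        history["train_acc"].append(correct / n)
        history["val_auc"].append(val_auc)
        if val_auc > best_auc:
            best_auc = val_auc
            best_weights = model.get_weights()

    model.set_weights(best_weights)
    history["best_epoch"] = int(np.argmax(history["val_auc"]))
    history["best_val_auc"] = best_auc
    return best_weights, history


def save_model(model: FourPathCNN, out_dir) -> None:
    """Persist weights (NPZ) plus the architecture as JSON."""
    import json
    from pathlib import Path

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    weights = model.get_weights()
    np.savez(out_dir / "weights.npz", **{f"w{i}": w for i, w in enumerate(weights)})
    cfg = model.config
    (out_dir / "architecture.json").write_text(
        json.dumps(
            {
                "n_paths": cfg.n_paths,
                "filters": list(cfg.filters),
                "kernel": list(cfg.kernel),
                "fc_units": cfg.fc_units,
                "input_shape": list(cfg.input_shape),
                "pool": cfg.pool,
            },
            indent=2,
        )
        + "\n"
    )


def load_model(model_dir) -> FourPathCNN:
    """Rebuild a model from ``save_model`` output."""
    import json
    from pathlib import Path

    model_dir = Path(model_dir)
    spec = json.loads((model_dir / "architecture.json").read_text())
    config = ArchConfig(
        n_paths=spec["n_paths"],
        filters=tuple(spec["filters"]),
        kernel=tuple(spec["kernel"]),
        fc_units=spec["fc_units"],
        input_shape=tuple(spec["input_shape"]),
        pool=spec["pool"],
    )
    model = build_model(config, seed=0)
    with np.load(model_dir / "weights.npz") as data:
        model.set_weights([data[f"w{i}"] for i in range(len(data.files))])
    return model
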