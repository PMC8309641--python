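"""The classifier: a compact CNN with CBAM attention, trained with Adamax.

Architecture (input 64 x 64 x 1)::

    conv 7x7 (same, stride 1) -> ReLU -> [CBAM] -> maxpool 2x2/2
    conv 7x7 (same, stride 1) -> ReLU -> [CBAM] -> maxpool 2x2/2
    dropout -> flatten -> fully connected -> softmax over {left, right}

Attention sits between each convolution and its pooling stage; switching
``use_cbam`` off yields the plain-CNN ablation with *identical* weights in
the shared layers (each parameter has its own seeded stream, so the CBAM
parameters do not perturb the others' initialisation).

Fixed design constants are the 7x7 kernels, 2x2/2 pooling, dropout
probability 0.8 and the Adamax optimiser at learning rate 3e-4; filter
counts, batch size, epochs and the attention reduction ratio are free
hyperparameters exposed on :class:`ModelConfig`.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from . import nn
from .core import LABELS
from .tfr import IMAGE_SIZE, ClassifierImage


@dataclass
class ModelConfig:
    """Every architecture and training hyperparameter in one place."""

    input_size: int = IMAGE_SIZE
    conv_kernel: int = 7
    conv_filters: tuple[int, int] = (32, 64)
    pool: int = 2
    dropout_rate: float = 0.8
    use_cbam: bool = True
    cbam_placement: str = "both"  # "both" or "first"
    cbam_reduction: int = 16
    cbam_spatial_kernel: int = 7
    learning_rate: float = 3e-4
    optimizer: str = "adamax"
    n_classes: int = 2
    batch_size: int = 32
    max_epochs: int = 200
    patience: int = 20
    validation_fraction: float = 0.0
    seed: int = 0
    dtype: str = "float32"

    def __post_init__(self) -> None:
        if len(self.conv_filters) != 2 or any(f < 1 for f in self.conv_filters):
            raise ValueError("conv_filters must be two counts >= 1")
        if not 0 <= self.dropout_rate < 1:
            raise ValueError("dropout_rate must lie in [0, 1)")
        if not 1 <= self.cbam_reduction <= min(self.conv_filters):
            raise ValueError(
                "cbam_reduction must lie in [1, min(conv_filters)] so the "
                "attention MLP has at least one hidden unit per block"
            )
        if self.cbam_placement not in ("both", "first"):
            raise ValueError("cbam_placement must be 'both' or 'first'")
        if self.optimizer != "adamax":
            raise ValueError("only the adamax optimizer is supported")
        if self.n_classes != 2:
            raise ValueError("the classifier head is binary (left vs right)")
        if not 0 <= self.validation_fraction < 1:
            raise ValueError("validation_fraction must lie in [0, 1)")


def encode_labels(labels) -> np.ndarray:
    """Map 'left'/'right' to 0/1 (already-integer labels pass through)."""
    arr = np.asarray(labels)
    if arr.dtype.kind in "iu":
        return arr.astype(int)
    try:
        return np.array([LABELS.index(str(lab)) for lab in arr])
    except ValueError as err:
        raise ValueError(f"labels must be in {LABELS}") from err


class CbamCnn:
    """The trainable network.  ``fit`` re-initialises from ``config.seed``."""

    def __init__(self, config: ModelConfig | None = None):
        self.config = config or ModelConfig()
        self.params: dict[str, np.ndarray] = {}
        self.log_: pd.DataFrame | None = None
        self._init_params()

    # -- initialisation -----------------------------------------------------

    def _rng_for(self, name: str) -> np.random.Generator:
        return np.random.default_rng([self.config.seed, zlib.crc32(name.encode())])

    def _init_params(self) -> None:
        cfg = self.config
        dtype = np.dtype(cfg.dtype)
        k = cfg.conv_kernel
        f1, f2 = cfg.conv_filters
        p: dict[str, np.ndarray] = {}

        def uni(name, shape, fan_in):
            bound = 1.0 / np.sqrt(fan_in)
            p[name] = (
                self._rng_for(name).uniform(-bound, bound, size=shape).astype(dtype)
            )

        uni("conv1_W", (f1, 1, k, k), k * k)
        p["conv1_b"] = np.zeros(f1, dtype=dtype)
        uni("conv2_W", (f2, f1, k, k), f1 * k * k)
        p["conv2_b"] = np.zeros(f2, dtype=dtype)
        side = cfg.input_size // (cfg.pool**2)
        uni("fc_W", (f2 * side * side, cfg.n_classes), f2 * side * side)
        p["fc_b"] = np.zeros(cfg.n_classes, dtype=dtype)
        # CBAM parameters are always initialised (from their own streams) so
        # that toggling use_cbam leaves every shared layer's weights intact.
        for blk, ch in (("cbam1_", f1), ("cbam2_", f2)):
            p.update(
                nn.init_cbam_params(
                    ch,
                    cfg.cbam_reduction,
                    cfg.cbam_spatial_kernel,
                    self._rng_for,
                    prefix=blk,
                    dtype=dtype,
                )
            )
        self.params = p

    def _cbam_active(self) -> tuple[bool, bool]:
        if not self.config.use_cbam:
            return False, False
        return True, self.config.cbam_placement == "both"

    # -- forward / backward -------------------------------------------------

    def _coerce_images(self, images) -> np.ndarray:
        if isinstance(images, ClassifierImage):
            images = images.pixels
        x = np.asarray(images, dtype=self.config.dtype)
        if x.ndim == 2:
            x = x[None]
        if x.ndim == 3:
            x = x[:, None]
        s = self.config.input_size
        if x.ndim != 4 or x.shape[1:] != (1, s, s):
            raise ValueError(
                f"expected images of shape ({s}, {s}) (optionally batched), "
                f"got {np.asarray(images).shape}"
            )
        return x

    def _forward(self, x, train=False, dropout_rng=None):
        p = self.params
        cbam1, cbam2 = self._cbam_active()
        caches = {}
        a, caches["conv1"] = nn.conv2d_forward(x, p["conv1_W"], p["conv1_b"])
        caches["relu1"] = a
        a = nn.relu(a)
        if cbam1:
            a, caches["cbam1"] = nn.cbam_forward(a, p, "cbam1_")
        a, caches["pool1"] = nn.maxpool_forward(a)
        a, caches["conv2"] = nn.conv2d_forward(a, p["conv2_W"], p["conv2_b"])
        caches["relu2"] = a
        a = nn.relu(a)
        if cbam2:
            a, caches["cbam2"] = nn.cbam_forward(a, p, "cbam2_")
        a, caches["pool2"] = nn.maxpool_forward(a)
        caches["shape"] = a.shape
        a = a.reshape(len(a), -1)
        if train and self.config.dropout_rate > 0:
            a, caches["drop"] = nn.dropout_forward(
                a, self.config.dropout_rate, dropout_rng
            )
        else:
            caches["drop"] = None
        logits, caches["fc"] = nn.dense_forward(a, p["fc_W"], p["fc_b"])
        return logits, caches

    def _backward(self, dlogits, caches):
        cbam1, cbam2 = self._cbam_active()
        grads: dict[str, np.ndarray] = {}
        da, grads["fc_W"], grads["fc_b"] = nn.dense_backward(dlogits, caches["fc"])
        da = nn.dropout_backward(da, caches["drop"])
        da = da.reshape(caches["shape"])
        da = nn.maxpool_backward(da, caches["pool2"])
        if cbam2:
            da, g = nn.cbam_backward(da, caches["cbam2"])
            grads.update(g)
        da = da * nn.relu_grad(caches["relu2"])
        da, grads["conv2_W"], grads["conv2_b"] = nn.conv2d_backward(
            da, caches["conv2"]
        )
        da = nn.maxpool_backward(da, caches["pool1"])
        if cbam1:
            da, g = nn.cbam_backward(da, caches["cbam1"])
            grads.update(g)
        da = da * nn.relu_grad(caches["relu1"])
        _, grads["conv1_W"], grads["conv1_b"] = nn.conv2d_backward(
            da, caches["conv1"]
        )
        return grads

    def loss_and_grads(self, images, labels, dropout_rng=None):
        x = self._coerce_images(images)
        y = encode_labels(labels)
        logits, caches = self._forward(x, train=True, dropout_rng=dropout_rng)
        loss, dlogits = nn.cross_entropy_loss(logits, y)
        return loss, self._backward(dlogits.astype(x.dtype), caches)

    # -- inference ----------------------------------------------------------

    def predict_proba(self, images) -> np.ndarray:
        """Class probabilities ``(n, 2)`` in (left, right) order; eval mode."""
        x = self._coerce_images(images)
        outs = []
        for start in range(0, len(x), self.config.batch_size):
            logits, _ = self._forward(x[start : start + self.config.batch_size])
            outs.append(nn.softmax(logits))
        return np.concatenate(outs, axis=0)

    def forward(self, image) -> np.ndarray:
        """Probability pair for a single image."""
        return self.predict_proba(image)[0]

    def predict(self, images) -> np.ndarray:
        return self.predict_proba(images).argmax(axis=1)

    def predict_labels(self, images) -> list[str]:
        return [LABELS[i] for i in self.predict(images)]

    # -- training -----------------------------------------------------------

    def fit(self, images, labels) -> "CbamCnn":
        """Train from scratch (seeded): Adamax on mean cross-entropy.

        Dropout is active only here; ``log_`` records per-epoch mean batch
        loss and full-train accuracy.  With ``validation_fraction > 0`` a
        stratified split is held out and training stops after ``patience``
        epochs without validation-loss improvement (best weights restored).
        """
        cfg = self.config
        x = self._coerce_images(images)
        y = encode_labels(labels)
        counts = np.bincount(y, minlength=2)
        if counts.min() < 1 or len(np.unique(y)) < 2:
            raise ValueError("training data must contain both classes")

        self._init_params()
        shuffle_rng = np.random.default_rng([cfg.seed, 10**6 + 1])
        dropout_rng = np.random.default_rng([cfg.seed, 10**6 + 2])

        x_val = y_val = None
        if cfg.validation_fraction > 0:
            x, y, x_val, y_val = _stratified_holdout(
                x, y, cfg.validation_fraction, np.random.default_rng([cfg.seed, 10**6 + 3])
            )

        opt = nn.Adamax(self.params, lr=cfg.learning_rate)
        n = len(x)
        rows = []
        best_val = np.inf
        best_params = None
        stale = 0
        for epoch in range(cfg.max_epochs):
            order = shuffle_rng.permutation(n)
            batch_losses = []
            correct = 0
            for start in range(0, n, cfg.batch_size):
                idx = order[start : start + cfg.batch_size]
                logits, caches = self._forward(
                    x[idx], train=True, dropout_rng=dropout_rng
                )
                loss, dlogits = nn.cross_entropy_loss(logits, y[idx])
                grads = self._backward(dlogits.astype(x.dtype), caches)
                opt.step(self.params, grads)
                batch_losses.append(loss)
                correct += int((logits.argmax(axis=1) == y[idx]).sum())
            row = {
                "epoch": epoch,
                "loss": float(np.mean(batch_losses)),
                # accuracy of the training-mode passes (dropout active)
                "train_accuracy": correct / n,
            }
            if x_val is not None:
                logits, _ = self._forward(x_val)
                val_loss, _ = nn.cross_entropy_loss(logits, y_val)
                row["val_loss"] = val_loss
                if val_loss < best_val - 1e-6:
                    best_val = val_loss
                    best_params = {k: v.copy() for k, v in self.params.items()}
                    stale = 0
                else:
                    stale += 1
                    if stale >= cfg.patience:
                        rows.append(row)
                        break
            rows.append(row)
        if best_params is not None:
            self.params = best_params
        self.log_ = pd.DataFrame(rows)
        return self

    # -- persistence --------------------------------------------------------

    def save(self, path) -> None:
        """Model state (config + weights) in one ``.npz`` file."""
        np.savez(
            path, __config__=np.frombuffer(
                json.dumps(asdict(self.config)).encode(), dtype=np.uint8
            ), **self.params
        )

    @classmethod
    def load(cls, path) -> "CbamCnn":
        with np.load(path) as data:
            raw = bytes(data["__config__"].tobytes()).decode()
            cfg_dict = json.loads(raw)
            cfg_dict["conv_filters"] = tuple(cfg_dict["conv_filters"])
            model = cls(ModelConfig(**cfg_dict))
            model.params = {
                k: data[k].copy() for k in data.files if k != "__config__"
            }
        return model


def _stratified_holdout(x, y, fraction, rng):
    val_idx = []
    for cls in np.unique(y):
        cls_idx = np.flatnonzero(y == cls)
        n_val = max(1, int(round(fraction * len(cls_idx))))
        val_idx.extend(rng.permutation(cls_idx)[:n_val])
    val_idx = np.sort(val_idx)
    mask = np.ones(len(y), bool)
    mask[val_idx] = False
    return x[mask], y[mask], x[val_idx], y[val_idx]


def train(images, labels, config: ModelConfig | None = None) -> CbamCnn:
    """Build and fit a :class:`CbamCnn`; returns the trained model.

    The per-epoch training log is on ``model.log_``.
    """
    model = CbamCnn(config)
    return model.fit(images, labels)
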