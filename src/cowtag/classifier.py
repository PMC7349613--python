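"""Digit classification for ear-tag work numbers.

Two interchangeable classifiers share the ``predict_proba`` interface:

* :class:`CnnClassifier` — a small convolutional network: conv 16@5x5 +
  batch norm + ReLU, conv 32@3x3 + ReLU, conv 32@3x3 + ReLU, average
  pool 2x2 stride 2, then fully connected layers of width 100 and 10
  with a softmax output.  Input is a 64 x 32 binary digit image.
  Training uses stochastic gradient descent with momentum (momentum
  0.9, learning rate 1e-4).  Implemented directly on numpy (im2col +
  BLAS matmul), float32 throughout.

* :class:`TemplateClassifier` — a deterministic normalized-cross-
  correlation matcher against per-class mean glyph templates; needs no
  training time, so full-pipeline tests do not depend on SGD runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Protocol

import numpy as np

from .errors import InputError
from .segmentation import prepare_digit

__all__ = [
    "CnnClassifier",
    "TemplateClassifier",
    "TrainedClassifier",
    "train_classifier",
    "classify_digit",
    "recognize_tag",
    "save_classifier",
    "load_classifier",
]

INPUT_SHAPE = (64, 32)
N_CLASSES = 10
WEIGHTS_FORMAT_VERSION = 1


class DigitModel(Protocol):
    def predict_proba(self, images: np.ndarray) -> np.ndarray: ...


def _as_batch(images: np.ndarray) -> np.ndarray:
    """Validate and shape digit images to (N, 1, 64, 32) float32,
    zero-centred (binary {0,1} -> {-0.5, +0.5})."""
    arr = np.asarray(images)
    if arr.ndim == 2:
        arr = arr[None]
    if arr.ndim != 3 or arr.shape[1:] != INPUT_SHAPE:
        raise InputError(f"expected (N, 64, 32) digit images, got {arr.shape}")
    return (arr.astype(np.float32) - 0.5)[:, None]


# ---------------------------------------------------------------------------
# Convolution via im2col


def _im2col(x: np.ndarray, kh: int, kw: int):
    """(N, C, H, W) -> (N*Ho*Wo, C*kh*kw) patch matrix, valid convolution."""
    view = np.lib.stride_tricks.sliding_window_view(x, (kh, kw), axis=(2, 3))
    n, c, ho, wo, _, _ = view.shape
    cols = np.ascontiguousarray(view.transpose(0, 2, 3, 1, 4, 5)).reshape(
        n * ho * wo, c * kh * kw
    )
    return cols, ho, wo


def _conv_forward(x, w, b):
    """One BLAS sgemm over the whole batch."""
    f, c, kh, kw = w.shape
    cols, ho, wo = _im2col(x, kh, kw)
    out = cols @ w.reshape(f, -1).T + b  # (N*L, F)
    out = out.reshape(x.shape[0], ho, wo, f).transpose(0, 3, 1, 2)
    return out, cols


def _conv_backward(dout, cols, x_shape, w):
    """Returns (dx, dw, db)."""
    n, c, h, wd = x_shape
    f, _, kh, kw = w.shape
    ho, wo = h - kh + 1, wd - kw + 1
    dflat = np.ascontiguousarray(dout.transpose(0, 2, 3, 1)).reshape(-1, f)
    dw = (dflat.T @ cols).reshape(w.shape)
    db = dflat.sum(axis=0)
    dcols = dflat @ w.reshape(f, -1)  # (N*L, C*kh*kw)
    dcols = dcols.reshape(n, ho, wo, c, kh, kw)
    dx = np.zeros(x_shape, dtype=dout.dtype)
    for i in range(kh):
        for j in range(kw):
            dx[:, :, i : i + ho, j : j + wo] += dcols[:, :, :, :, i, j].transpose(
                0, 3, 1, 2
            )
    return dx, dw, db


class CnnClassifier:
    """The digit CNN; see module docstring for the architecture."""

    def __init__(self, seed: int = 0):
        rng = np.random.default_rng(seed)

        def he(shape, fan_in):
            return rng.normal(0, np.sqrt(2.0 / fan_in), shape).astype(np.float32)

        self.params: dict[str, np.ndarray] = {
            "w1": he((16, 1, 5, 5), 25),
            "b1": np.zeros(16, np.float32),
            "gamma": np.ones(16, np.float32),
            "beta": np.zeros(16, np.float32),
            "w2": he((32, 16, 3, 3), 16 * 9),
            "b2": np.zeros(32, np.float32),
            "w3": he((32, 32, 3, 3), 32 * 9),
            "b3": np.zeros(32, np.float32),
            # after avg-pool: 32 x 28 x 12 = 10752 features
            "w4": he((10752, 100), 10752),
            "b4": np.zeros(100, np.float32),
            "w5": he((100, N_CLASSES), 100),
            "b5": np.zeros(N_CLASSES, np.float32),
        }
        self.bn_mean = np.zeros(16, np.float32)
        self.bn_var = np.ones(16, np.float32)
        self.bn_momentum = 0.1
        self.bn_eps = 1e-5
        self.seed = seed

    # -- forward -----------------------------------------------------------

    def _forward(self, x: np.ndarray, train: bool):
        p = self.params
        cache: dict = {"x": x}
        a1, cols1 = _conv_forward(x, p["w1"], p["b1"])
        if train:
            mu = a1.mean(axis=(0, 2, 3))
            var = a1.var(axis=(0, 2, 3))
            self.bn_mean = (1 - self.bn_momentum) * self.bn_mean + self.bn_momentum * mu
            self.bn_var = (1 - self.bn_momentum) * self.bn_var + self.bn_momentum * var
        else:
            mu, var = self.bn_mean, self.bn_var
        inv_std = 1.0 / np.sqrt(var + self.bn_eps)
        xhat = (a1 - mu[None, :, None, None]) * inv_std[None, :, None, None]
        bn = p["gamma"][None, :, None, None] * xhat + p["beta"][None, :, None, None]
        r1 = np.maximum(bn, 0)
        a2, cols2 = _conv_forward(r1, p["w2"], p["b2"])
        r2 = np.maximum(a2, 0)
        a3, cols3 = _conv_forward(r2, p["w3"], p["b3"])
        r3 = np.maximum(a3, 0)
        n, c, h, w = r3.shape
        pooled = r3.reshape(n, c, h // 2, 2, w // 2, 2).mean(axis=(3, 5))
        flat = pooled.reshape(n, -1)
        z4 = flat @ p["w4"] + p["b4"]
        r4 = np.maximum(z4, 0)
        logits = r4 @ p["w5"] + p["b5"]
        cache.update(
            a1=a1, cols1=cols1, xhat=xhat, inv_std=inv_std, bn=bn, r1=r1,
            a2=a2, cols2=cols2, r2=r2, a3=a3, cols3=cols3, r3=r3,
            flat=flat, z4=z4, r4=r4,
        )
        return logits, cache

    @staticmethod
    def _softmax(logits: np.ndarray) -> np.ndarray:
        z = logits - logits.max(axis=1, keepdims=True)
        e = np.exp(z)
        return e / e.sum(axis=1, keepdims=True)

    def predict_proba(self, images: np.ndarray) -> np.ndarray:
        x = _as_batch(images)
        out = []
        for i in range(0, len(x), 256):
            logits, _ = self._forward(x[i : i + 256], train=False)
            out.append(self._softmax(logits))
        return np.concatenate(out, axis=0)

    # -- backward ----------------------------------------------------------

    def _backward(self, cache, probs, labels):
        p = self.params
        n = len(labels)
        dlogits = probs.copy()
        dlogits[np.arange(n), labels] -= 1.0
        dlogits /= n
        g = {}
        g["w5"] = cache["r4"].T @ dlogits
        g["b5"] = dlogits.sum(axis=0)
        dr4 = dlogits @ p["w5"].T
        dz4 = dr4 * (cache["z4"] > 0)
        g["w4"] = cache["flat"].T @ dz4
        g["b4"] = dz4.sum(axis=0)
        dflat = dz4 @ p["w4"].T
        nb, c, h, w = cache["r3"].shape
        dpool = dflat.reshape(nb, c, h // 2, w // 2)
        dr3 = np.repeat(np.repeat(dpool, 2, axis=2), 2, axis=3) / 4.0
        da3 = dr3 * (cache["a3"] > 0)
        dr2, g["w3"], g["b3"] = _conv_backward(
            da3, cache["cols3"], cache["r2"].shape, p["w3"]
        )
        da2 = dr2 * (cache["a2"] > 0)
        dr1, g["w2"], g["b2"] = _conv_backward(
            da2, cache["cols2"], cache["r1"].shape, p["w2"]
        )
        dbn = dr1 * (cache["bn"] > 0)
        g["gamma"] = (dbn * cache["xhat"]).sum(axis=(0, 2, 3))
        g["beta"] = dbn.sum(axis=(0, 2, 3))
        # batch-norm backward (per channel over N*H*W samples)
        m = dbn.shape[0] * dbn.shape[2] * dbn.shape[3]
        dxhat = dbn * p["gamma"][None, :, None, None]
        inv = cache["inv_std"][None, :, None, None]
        sum_dxhat = dxhat.sum(axis=(0, 2, 3), keepdims=True)
        sum_dxhat_xhat = (dxhat * cache["xhat"]).sum(axis=(0, 2, 3), keepdims=True)
        da1 = inv / m * (m * dxhat - sum_dxhat - cache["xhat"] * sum_dxhat_xhat)
        _, g["w1"], g["b1"] = _conv_backward(
            da1, cache["cols1"], cache["x"].shape, p["w1"]
        )
        return g

    def loss_and_grads(self, images, labels):
        x = _as_batch(images)
        labels = np.asarray(labels)
        logits, cache = self._forward(x, train=True)
        probs = self._softmax(logits)
        eps = 1e-12
        loss = -np.log(probs[np.arange(len(labels)), labels] + eps).mean()
        return float(loss), self._backward(cache, probs, labels)

    def weights_digest(self) -> str:
        import hashlib

        h = hashlib.sha256()
        for k in sorted(self.params):
            h.update(k.encode())
            h.update(self.params[k].tobytes())
        h.update(self.bn_mean.tobytes())
        h.update(self.bn_var.tobytes())
        return h.hexdigest()


class TemplateClassifier:
    """Normalized-cross-correlation matcher against per-class mean
    templates built from the synthetic digit renderer.  Deterministic."""

    def __init__(self, n_per_class: int = 24, seed: int = 12345,
                 sharpness: float = 20.0):
        from .synthetic import generate_digit_dataset

        images, labels = generate_digit_dataset(n_per_class, seed=seed)
        self.templates = np.stack(
            [images[labels == d].mean(axis=0) for d in range(N_CLASSES)]
        ).astype(np.float32)
        centred = self.templates.reshape(N_CLASSES, -1)
        centred = centred - centred.mean(axis=1, keepdims=True)
        norms = np.linalg.norm(centred, axis=1, keepdims=True)
        self._t = centred / np.maximum(norms, 1e-9)
        self.sharpness = sharpness

    def predict_proba(self, images: np.ndarray) -> np.ndarray:
        x = _as_batch(images).reshape(-1, 64 * 32)
        x = x - x.mean(axis=1, keepdims=True)
        x = x / np.maximum(np.linalg.norm(x, axis=1, keepdims=True), 1e-9)
        corr = x @ self._t.T  # in [-1, 1]
        z = self.sharpness * corr
        z -= z.max(axis=1, keepdims=True)
        e = np.exp(z)
        return e / e.sum(axis=1, keepdims=True)


@dataclass
class TrainedClassifier:
    """A classifier plus its training provenance."""

    model: CnnClassifier
    train_meta: dict = field(default_factory=dict)


def _accuracy(model: DigitModel, images, labels) -> float:
    pred = model.predict_proba(images).argmax(axis=1)
    return float((pred == np.asarray(labels)).mean())


def train_classifier(
    dataset: tuple[np.ndarray, np.ndarray],
    seed: int = 7,
    epochs: int = 10,
    learning_rate: float = 1e-4,
    momentum: float = 0.9,
    batch_size: int = 64,
    test_data: Optional[tuple[np.ndarray, np.ndarray]] = None,
    early_stop_acc: float = 0.998,
    verbose: bool = False,
) -> TrainedClassifier:
    """Train the CNN with SGD-with-momentum on a labelled digit set.

    A tenth of the training set is held out as a validation split (it
    drives early stopping); ``test_data``, when given, is evaluated once
    at the end and reported as ``test_acc``.  Fully seeded.
    """
    images, labels = dataset
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise InputError("need at least 2 classes to train")
    # compound seed: keeps the trainer's permutations decoupled from the
    # dataset generator's even when both are given the same seed
    rng = np.random.default_rng([seed, 0x7A6])
    n = len(images)
    order = rng.permutation(n)
    n_val = max(1, n // 10)
    val_idx, train_idx = order[:n_val], order[n_val:]
    model = CnnClassifier(seed=seed)
    velocity = {k: np.zeros_like(v) for k, v in model.params.items()}
    history = []
    for epoch in range(epochs):
        perm = rng.permutation(train_idx)
        losses = []
        for i in range(0, len(perm), batch_size):
            idx = perm[i : i + batch_size]
            loss, grads = model.loss_and_grads(images[idx], labels[idx])
            losses.append(loss)
            for k, gk in grads.items():
                velocity[k] = momentum * velocity[k] - learning_rate * gk.astype(
                    np.float32
                )
                model.params[k] += velocity[k]
        val_acc = _accuracy(model, images[val_idx], labels[val_idx])
        history.append({"epoch": epoch + 1,
                        "train_loss": float(np.mean(losses)),
                        "val_acc": val_acc})
        if verbose:
            print(f"epoch {epoch + 1}: loss={np.mean(losses):.4f} "
                  f"val_acc={val_acc:.4f}")
        if val_acc >= early_stop_acc:
            break
    train_acc = _accuracy(model, images[train_idx], labels[train_idx])
    meta = {
        "seed": seed,
        "epochs": len(history),
        "learning_rate": learning_rate,
        "momentum": momentum,
        "batch_size": batch_size,
        "train_acc": train_acc,
        "val_acc": history[-1]["val_acc"] if history else None,
        "history": history,
    }
    if test_data is not None:
        meta["test_acc"] = _accuracy(model, *test_data)
    return TrainedClassifier(model, meta)


def classify_digit(model: DigitModel, image: np.ndarray) -> tuple[int, float]:
    """Classify one prepared 64 x 32 binary digit image."""
    image = np.asarray(image)
    if image.shape != INPUT_SHAPE:
        raise InputError(f"expected shape {INPUT_SHAPE}, got {image.shape}")
    probs = model.predict_proba(image[None])[0]
    digit = int(probs.argmax())
    return digit, float(probs[digit])


def recognize_tag(model: DigitModel, crops) -> str:
    """Concatenate per-crop classifications, left to right.

    Crops may be RGB digit crops of any size (they are passed through
    the standard digit preprocessing) or already-prepared 64 x 32 binary
    images.  Zero crops yield the empty string.
    """
    out = []
    for crop in crops:
        crop = np.asarray(crop)
        if crop.ndim == 3 or crop.shape != INPUT_SHAPE:
            crop = prepare_digit(crop)
        digit, _ = classify_digit(model, crop)
        out.append(str(digit))
    return "".join(out)


def save_classifier(trained: TrainedClassifier, path: str | Path) -> Path:
    """Serialize weights plus metadata to a single versioned .npz file."""
    import json

    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    meta = dict(trained.train_meta)
    meta.pop("history", None)
    np.savez(
        path,
        format_version=WEIGHTS_FORMAT_VERSION,
        bn_mean=trained.model.bn_mean,
        bn_var=trained.model.bn_var,
        meta=json.dumps(meta),
        **trained.model.params,
    )
    return path if path.suffix == ".npz" else path.with_suffix(path.suffix + ".npz")


def load_classifier(path: str | Path) -> TrainedClassifier:
    import json

    with np.load(path, allow_pickle=False) as data:
        version = int(data["format_version"])
        if version != WEIGHTS_FORMAT_VERSION:
            raise InputError(f"unsupported weights format version {version}")
        model = CnnClassifier()
        for k in model.params:
            model.params[k] = data[k]
        model.bn_mean = data["bn_mean"]
        model.bn_var = data["bn_var"]
        meta = json.loads(str(data["meta"]))
    return TrainedClassifier(model, meta)
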