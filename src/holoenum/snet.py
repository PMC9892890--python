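"""s-Net: a shallow CNN for two-class PoBF crop classification.

Architecture (36x36x1 input): conv3x3(8)-BN-ReLU-maxpool2 ->
conv3x3(16)-BN-ReLU-maxpool2 -> conv3x3(32)-BN-ReLU -> flatten(2592)
-> FC(2) -> softmax.  "Same" padding and stride 1 throughout the
convolutions; spatial sizes 36 -> 18 -> 9.  With batch norm the
network has 11 186 learnable parameters (~11k), which is what makes it
trainable in minutes on a CPU.

The implementation is pure numpy: im2col convolutions, batch
normalization with running statistics (frozen at inference), softmax
cross-entropy, and Adam.  Everything is deterministic given the seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "SNetArch",
    "SNet",
    "ClassScore",
    "ConfusionMetrics",
    "build_snet",
    "count_learnables",
    "split_dataset",
    "train",
    "predict",
    "predict_proba",
    "confusion",
    "save_model",
    "load_model",
]


@dataclass(frozen=True)
class SNetArch:
    """Hyperparameters of the shallow network."""

    input_hw: tuple[int, int] = (36, 36)
    conv_filters: tuple[int, int, int] = (8, 16, 32)
    kernel: int = 3
    pool_after: tuple[bool, bool, bool] = (True, True, False)
    n_classes: int = 2
    batch_norm: bool = True
    flatten_dim: int = 2592

    def computed_flatten_dim(self) -> int:
        h, w = self.input_hw
        for pooled in self.pool_after:
            if pooled:
                h //= 2
                w //= 2
        return h * w * self.conv_filters[-1]


def build_snet(arch: SNetArch | None = None, seed: int = 0) -> "SNet":
    """Instantiate an s-Net with He-uniform initialized weights.

    Raises ValueError when the declared flatten dimension disagrees
    with the one implied by the conv/pool stack.
    """
    arch = arch or SNetArch()
    actual = arch.computed_flatten_dim()
    if actual != arch.flatten_dim:
        raise ValueError(
            f"declared flatten_dim {arch.flatten_dim} != computed {actual}"
        )
    return SNet(arch, seed=seed)


def count_learnables(arch: SNetArch | None = None, include_batch_norm: bool = True) -> int:
    """Closed-form learnable-parameter count (weights + biases).

    Default architecture: 11 186 with batch-norm scale/offset included,
    11 074 without; both round to ~11k.
    """
    arch = arch or SNetArch()
    total = 0
    c_in = 1
    for f in arch.conv_filters:
        total += arch.kernel * arch.kernel * c_in * f + f
        if arch.batch_norm and include_batch_norm:
            total += 2 * f
        c_in = f
    total += arch.computed_flatten_dim() * arch.n_classes + arch.n_classes
    return total


# ---------------------------------------------------------------- layers


def _im2col(x: np.ndarray, k: int) -> np.ndarray:
    """(N, H, W, C) -> (N*H*W, k*k*C) patch matrix with same padding."""
    p = k // 2
    xp = np.pad(x, ((0, 0), (p, p), (p, p), (0, 0)))
    win = sliding_window_view(xp, (k, k), axis=(1, 2))  # (N, H, W, C, k, k)
    n, h, w = x.shape[:3]
    return win.transpose(0, 1, 2, 4, 5, 3).reshape(n * h * w, k * k * x.shape[3])


def _col2im(cols: np.ndarray, shape: tuple[int, ...], k: int) -> np.ndarray:
    """Adjoint of _im2col (scatter-add patches back)."""
    n, h, w, c = shape
    p = k // 2
    out = np.zeros((n, h + 2 * p, w + 2 * p, c))
    cols = cols.reshape(n, h, w, k, k, c)
    for i in range(k):
        for j in range(k):
            out[:, i : i + h, j : j + w, :] += cols[:, :, :, i, j, :]
    return out[:, p : p + h, p : p + w, :]


class _Conv:
    def __init__(self, c_in: int, c_out: int, k: int, rng: np.random.Generator):
        fan_in = k * k * c_in
        limit = np.sqrt(6.0 / fan_in)  # He-uniform
        self.W = rng.uniform(-limit, limit, size=(fan_in, c_out))
        self.b = np.zeros(c_out)
        self.k = k

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._shape = x.shape
        self._cols = _im2col(x, self.k)
        n, h, w, _ = x.shape
        return (self._cols @ self.W + self.b).reshape(n, h, w, -1)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        n, h, w, c_out = grad.shape
        g = grad.reshape(-1, c_out)
        self.dW = self._cols.T @ g
        self.db = g.sum(axis=0)
        return _col2im(g @ self.W.T, self._shape, self.k)


class _BatchNorm:
    eps = 1e-5
    momentum = 0.1

    def __init__(self, c: int):
        self.gamma = np.ones(c)
        self.beta = np.zeros(c)
        self.running_mean = np.zeros(c)
        self.running_var = np.ones(c)

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        if training:
            mean = x.mean(axis=(0, 1, 2))
            var = x.var(axis=(0, 1, 2))
            self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * mean
            self.running_var = (1 - self.momentum) * self.running_var + self.momentum * var
        else:
            mean, var = self.running_mean, self.running_var
        self._inv = 1.0 / np.sqrt(var + self.eps)
        self._xhat = (x - mean) * self._inv
        return self.gamma * self._xhat + self.beta

    def backward(self, grad: np.ndarray) -> np.ndarray:
        m = grad.shape[0] * grad.shape[1] * grad.shape[2]
        self.dgamma = (grad * self._xhat).sum(axis=(0, 1, 2))
        self.dbeta = grad.sum(axis=(0, 1, 2))
        gx = self.gamma * self._inv / m * (
            m * grad
            - self.dbeta
            - self._xhat * self.dgamma
        )
        return gx


class _ReLU:
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad * self._mask


class _MaxPool2:
    def forward(self, x: np.ndarray) -> np.ndarray:
        n, h, w, c = x.shape
        xr = x.reshape(n, h // 2, 2, w // 2, 2, c)
        out = xr.max(axis=(2, 4))
        # route gradients to (the first of) the argmax positions
        mask = xr == out[:, :, np.newaxis, :, np.newaxis, :]
        counts = mask.sum(axis=(2, 4), keepdims=True)
        self._mask = mask / counts
        self._shape = x.shape
        return out

    def backward(self, grad: np.ndarray) -> np.ndarray:
        g = grad[:, :, np.newaxis, :, np.newaxis, :] * self._mask
        return g.reshape(self._shape)


class _Dense:
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator):
        limit = np.sqrt(6.0 / d_in)
        self.W = rng.uniform(-limit, limit, size=(d_in, d_out))
        self.b = np.zeros(d_out)

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.W + self.b

    def backward(self, grad: np.ndarray) -> np.ndarray:
        self.dW = self._x.T @ grad
        self.db = grad.sum(axis=0)
        return grad @ self.W.T


class SNet:
    """The assembled network.  Use :func:`build_snet` to construct."""

    def __init__(self, arch: SNetArch, seed: int = 0):
        self.arch = arch
        rng = np.random.default_rng(seed)
        self.convs: list[_Conv] = []
        self.bns: list[_BatchNorm | None] = []
        c_in = 1
        for f in arch.conv_filters:
            self.convs.append(_Conv(c_in, f, arch.kernel, rng))
            self.bns.append(_BatchNorm(f) if arch.batch_norm else None)
            c_in = f
        self.relus = [_ReLU() for _ in arch.conv_filters]
        self.pools = [_MaxPool2() if p else None for p in arch.pool_after]
        self.fc = _Dense(arch.computed_flatten_dim(), arch.n_classes, rng)

    # forward returns softmax probabilities
    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        if x.ndim == 3:
            x = x[..., np.newaxis]
        h = x.astype(np.float64)
        for conv, bn, relu, pool in zip(self.convs, self.bns, self.relus, self.pools):
            h = conv.forward(h)
            if bn is not None:
                h = bn.forward(h, training)
            h = relu.forward(h)
            if pool is not None:
                h = pool.forward(h)
        self._flat_shape = h.shape
        logits = self.fc.forward(h.reshape(len(h), -1))
        logits = logits - logits.max(axis=1, keepdims=True)
        e = np.exp(logits)
        return e / e.sum(axis=1, keepdims=True)

    def backward(self, probs: np.ndarray, onehot: np.ndarray) -> None:
        grad = (probs - onehot) / len(probs)
        grad = self.fc.backward(grad).reshape(self._flat_shape)
        for conv, bn, relu, pool in zip(
            reversed(self.convs), reversed(self.bns), reversed(self.relus), reversed(self.pools)
        ):
            if pool is not None:
                grad = pool.backward(grad)
            grad = relu.backward(grad)
            if bn is not None:
                grad = bn.backward(grad)
            grad = conv.backward(grad)

    def parameters(self) -> list[tuple[object, str]]:
        out: list[tuple[object, str]] = []
        for conv in self.convs:
            out += [(conv, "W"), (conv, "b")]
        for bn in self.bns:
            if bn is not None:
                out += [(bn, "gamma"), (bn, "beta")]
        out += [(self.fc, "W"), (self.fc, "b")]
        return out

    def gradients(self) -> list[np.ndarray]:
        grads = []
        for obj, name in self.parameters():
            grads.append(getattr(obj, {"W": "dW", "b": "db", "gamma": "dgamma", "beta": "dbeta"}[name]))
        return grads


@dataclass
class ClassScore:
    """Softmax output for one crop."""

    p_tumor: float
    p_wbc: float

    @property
    def predicted(self) -> str:
        return "TUMOR" if self.p_tumor > 0.5 else "WBC"


@dataclass
class ConfusionMetrics:
    """Confusion counts with the usual rate definitions.

    When a class is absent the corresponding rate is vacuously perfect
    (sensitivity/specificity 1, FPR 0), which keeps the identity
    fpr = 1 - specificity valid on degenerate inputs.
    """

    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def accuracy(self) -> float:
        return (self.tp + self.tn) / (self.tp + self.tn + self.fp + self.fn)

    @property
    def sensitivity(self) -> float:
        return self.tp / (self.tp + self.fn) if self.tp + self.fn else 1.0

    @property
    def specificity(self) -> float:
        return self.tn / (self.tn + self.fp) if self.tn + self.fp else 1.0

    @property
    def fpr(self) -> float:
        return self.fp / (self.fp + self.tn) if self.fp + self.tn else 0.0


def split_dataset(
    n_per_class: int,
    train_fraction: float = 0.7,
    seed: int = 0,
    n_classes: int = 2,
) -> tuple[np.ndarray, np.ndarray]:
    """Stratified random train/test split over per-class blocks.

    Samples are indexed 0..n_classes*n_per_class-1 in class-major
    order; each class contributes round(n * fraction) training
    indices, the remainder to test (52 340 at 70/30 -> 36 638/15 702).
    Disjoint and exhaustive; identical seeds give identical splits.
    """
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must lie in (0, 1)")
    n_train = round(n_per_class * train_fraction)
    if n_train < 1 or n_train >= n_per_class:
        raise ValueError("n_per_class too small for the requested split")
    rng = np.random.default_rng(seed)
    train_idx, test_idx = [], []
    for c in range(n_classes):
        perm = rng.permutation(n_per_class) + c * n_per_class
        train_idx.append(perm[:n_train])
        test_idx.append(perm[n_train:])
    return np.concatenate(train_idx), np.concatenate(test_idx)


def train(
    model: SNet,
    crops: np.ndarray,
    labels: np.ndarray,
    minibatch: int = 32,
    epochs: int = 20,
    learning_rate: float = 1e-3,
    seed: int = 0,
) -> dict[str, list[float]]:
    """Train with softmax cross-entropy and Adam.

    ``labels`` are 1 = tumor, 0 = WBC; ``crops`` are (n, 36, 36) in
    [0, 1].  Shuffling and weight updates are deterministic given the
    seed.  Returns a history dict with per-epoch loss and accuracy.
    Aborts with FloatingPointError if the loss goes non-finite.
    """
    crops = np.asarray(crops)
    labels = np.asarray(labels).astype(int)
    n = len(crops)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x5EED]))
    params = model.parameters()
    m_state = [np.zeros_like(getattr(obj, name)) for obj, name in params]
    v_state = [np.zeros_like(getattr(obj, name)) for obj, name in params]
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    t = 0
    history: dict[str, list[float]] = {"loss": [], "accuracy": []}
    onehot_eye = np.eye(model.arch.n_classes)
    for _ in range(epochs):
        order = rng.permutation(n)
        losses, correct = [], 0
        for start in range(0, n, minibatch):
            idx = order[start : start + minibatch]
            xb, yb = crops[idx], labels[idx]
            probs = model.forward(xb, training=True)
            p_true = np.clip(probs[np.arange(len(yb)), yb], 1e-12, None)
            loss = -float(np.mean(np.log(p_true)))
            if not np.isfinite(loss):
                raise FloatingPointError("training diverged: non-finite loss")
            losses.append(loss * len(yb))
            correct += int((probs.argmax(axis=1) == yb).sum())
            model.backward(probs, onehot_eye[yb])
            t += 1
            for i, ((obj, name), g) in enumerate(zip(params, model.gradients())):
                m_state[i] = beta1 * m_state[i] + (1 - beta1) * g
                v_state[i] = beta2 * v_state[i] + (1 - beta2) * g * g
                m_hat = m_state[i] / (1 - beta1**t)
                v_hat = v_state[i] / (1 - beta2**t)
                setattr(
                    obj,
                    name,
                    getattr(obj, name) - learning_rate * m_hat / (np.sqrt(v_hat) + eps),
                )
        history["loss"].append(sum(losses) / n)
        history["accuracy"].append(correct / n)
    return history


def predict_proba(model: SNet, crops: np.ndarray, batch: int = 256) -> np.ndarray:
    """Tumor-class probability per crop (batch-norm frozen)."""
    crops = np.asarray(crops)
    if crops.ndim == 2:
        crops = crops[np.newaxis]
    if crops.shape[1:3] != model.arch.input_hw:
        raise ValueError(f"crops must be {model.arch.input_hw}, got {crops.shape[1:3]}")
    out = np.empty(len(crops))
    for start in range(0, len(crops), batch):
        probs = model.forward(crops[start : start + batch], training=False)
        out[start : start + len(probs)] = probs[:, 1]
    return out


def predict(model: SNet, crops: np.ndarray, batch: int = 256) -> list[ClassScore]:
    p = predict_proba(model, crops, batch=batch)
    return [ClassScore(p_tumor=float(pi), p_wbc=float(1.0 - pi)) for pi in p]


def confusion(
    p_tumor: Sequence[float] | np.ndarray,
    labels: Sequence[int] | np.ndarray,
    alpha: float = 0.5,
) -> ConfusionMetrics:
    """Confusion counts with a cell called tumor iff p_tumor > alpha."""
    p = np.asarray([s.p_tumor if isinstance(s, ClassScore) else s for s in p_tumor])
    y = np.asarray(labels).astype(int)
    if len(p) != len(y):
        raise ValueError("scores and labels differ in length")
    if len(p) == 0:
        raise ValueError("empty input")
    pos = p > alpha
    return ConfusionMetrics(
        tp=int(np.sum(pos & (y == 1))),
        tn=int(np.sum(~pos & (y == 0))),
        fp=int(np.sum(pos & (y == 0))),
        fn=int(np.sum(~pos & (y == 1))),
    )


def save_model(model: SNet, path) -> None:
    """Serialize architecture + weights + running stats to an .npz."""
    arrays: dict[str, np.ndarray] = {}
    for i, conv in enumerate(model.convs):
        arrays[f"conv{i}_W"] = conv.W
        arrays[f"conv{i}_b"] = conv.b
    for i, bn in enumerate(model.bns):
        if bn is not None:
            arrays[f"bn{i}_gamma"] = bn.gamma
            arrays[f"bn{i}_beta"] = bn.beta
            arrays[f"bn{i}_mean"] = bn.running_mean
            arrays[f"bn{i}_var"] = bn.running_var
    arrays["fc_W"] = model.fc.W
    arrays["fc_b"] = model.fc.b
    arch = {
        "input_hw": list(model.arch.input_hw),
        "conv_filters": list(model.arch.conv_filters),
        "kernel": model.arch.kernel,
        "pool_after": list(model.arch.pool_after),
        "n_classes": model.arch.n_classes,
        "batch_norm": model.arch.batch_norm,
        "flatten_dim": model.arch.flatten_dim,
    }
    arrays["arch_json"] = np.frombuffer(json.dumps(arch).encode(), dtype=np.uint8)
    np.savez(path, **arrays)


def load_model(path) -> SNet:
    with np.load(path) as data:
        arch_d = json.loads(bytes(data["arch_json"]).decode())
        arch = SNetArch(
            input_hw=tuple(arch_d["input_hw"]),
            conv_filters=tuple(arch_d["conv_filters"]),
            kernel=arch_d["kernel"],
            pool_after=tuple(arch_d["pool_after"]),
            n_classes=arch_d["n_classes"],
            batch_norm=arch_d["batch_norm"],
            flatten_dim=arch_d["flatten_dim"],
        )
        model = build_snet(arch, seed=0)
        for i, conv in enumerate(model.convs):
            conv.W = data[f"conv{i}_W"]
            conv.b = data[f"conv{i}_b"]
        for i, bn in enumerate(model.bns):
            if bn is not None:
                bn.gamma = data[f"bn{i}_gamma"]
                bn.beta = data[f"bn{i}_beta"]
                bn.running_mean = data[f"bn{i}_mean"]
                bn.running_var = data[f"bn{i}_var"]
        model.fc.W = data["fc_W"]
        model.fc.b = data["fc_b"]
    return model
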