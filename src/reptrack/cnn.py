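"""Compact 1-D convolutional window classifier.

Architecture (input 50 samples x 6 channels, one feature map):

    conv   — 5 filters, 7x1 kernel (7 along time, shared across channels),
             no padding, ReLU                        -> (44, 6, 5)
    pool   — max over non-overlapping 2x1 time pairs -> (22, 6, 5)
    flat   —                                         -> 660
    dense  — softmax over the 4 classes              -> 4

Total trainable parameters: 5*(7+1) + 4*(660+1) = 2684.  The network is
small enough that forward pass, backprop and Adam are implemented here
directly on numpy arrays; training minimizes cross-entropy against the
class-fraction soft targets, with early stopping on validation loss.

Streaming inference exploits that the valid convolution of a window starting
at sample t equals rows t..t+43 of the convolution of the whole recording,
so the conv layer runs once per recording and only pooling and the dense
layer run per window.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .signals import N_CLASSES, DataError, SignalMatrix
from .windows import ChannelStats, WindowedDataset, apply_normalizer

WINDOW = 50
KERNEL = 7
N_FILTERS = 5
POOL = 2
CONV_OUT = WINDOW - KERNEL + 1          # 44
FLAT = (CONV_OUT // POOL) * 6 * N_FILTERS  # 660


class TrainingError(RuntimeError):
    """Raised when optimization diverges (non-finite loss)."""


@dataclass
class ModelConfig:
    input_shape: tuple[int, int] = (WINDOW, 6)
    n_filters: int = N_FILTERS
    kernel: tuple[int, int] = (KERNEL, 1)
    pool: tuple[int, int] = (POOL, 1)
    n_classes: int = N_CLASSES
    learning_rate: float = 1e-3
    batch_size: int = 64
    max_epochs: int = 200
    patience: int = 10
    seed: int = 0

    @property
    def n_parameters(self) -> int:
        t_out = self.input_shape[0] - self.kernel[0] + 1
        flat = (t_out // self.pool[0]) * self.input_shape[1] * self.n_filters
        return (self.n_filters * (self.kernel[0] * self.kernel[1] + 1)
                + self.n_classes * (flat + 1))


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def _cross_entropy(p: np.ndarray, targets: np.ndarray) -> float:
    return float(-(targets * np.log(np.clip(p, 1e-12, None))).sum(axis=1).mean())


@dataclass
class CNNClassifier:
    """The window classifier: weights, config and training history."""

    config: ModelConfig = field(default_factory=ModelConfig)
    normalization: str = "raw"
    channel_stats: ChannelStats | None = None

    def __post_init__(self) -> None:
        cfg = self.config
        if cfg.kernel[0] > cfg.input_shape[0] or cfg.kernel[1] != 1:
            raise ValueError("kernel must be (k, 1) with k <= window size")
        rng = np.random.default_rng(cfg.seed)
        k = cfg.kernel[0]
        t_out = cfg.input_shape[0] - k + 1
        flat = (t_out // cfg.pool[0]) * cfg.input_shape[1] * cfg.n_filters
        # Glorot-uniform initialization
        lim_k = np.sqrt(6.0 / (k + 1))
        self.K = rng.uniform(-lim_k, lim_k, size=(cfg.n_filters, k))
        self.b = np.zeros(cfg.n_filters)
        lim_w = np.sqrt(6.0 / (flat + cfg.n_classes))
        self.W = rng.uniform(-lim_w, lim_w, size=(flat, cfg.n_classes))
        self.c = np.zeros(cfg.n_classes)
        self.history: dict[str, list[float]] = {}

    # -- forward ------------------------------------------------------------

    @property
    def n_parameters(self) -> int:
        return self.K.size + self.b.size + self.W.size + self.c.size

    def _conv_relu(self, x: np.ndarray) -> np.ndarray:
        """Valid conv along time + ReLU. x: (..., T, 6) -> (..., T-6, 6, 5)."""
        v = np.lib.stride_tricks.sliding_window_view(x, KERNEL, axis=-2)
        z = np.einsum("...tcw,fw->...tcf", v, self.K) + self.b
        return np.maximum(z, 0.0)

    def _pool_dense(self, a: np.ndarray) -> np.ndarray:
        """a: (B, 44, 6, 5) -> softmax probabilities (B, 4)."""
        B = a.shape[0]
        pooled = a.reshape(B, CONV_OUT // POOL, POOL, 6, N_FILTERS).max(axis=2)
        flat = pooled.reshape(B, FLAT)
        return _softmax(flat @ self.W + self.c)

    def predict_proba(self, windows: np.ndarray) -> np.ndarray:
        """Forward pass on (B, 50, 6) (or a single (50, 6)) windows."""
        w = np.asarray(windows, dtype=np.float64)
        single = w.ndim == 2
        if single:
            w = w[None]
        if w.shape[1:] != tuple(self.config.input_shape):
            raise ValueError(f"expected windows of shape "
                             f"{self.config.input_shape}, got {w.shape[1:]}")
        p = self._pool_dense(self._conv_relu(w))
        return p[0] if single else p

    def predict_window(self, window: np.ndarray) -> np.ndarray:
        return self.predict_proba(window)

    # -- training -----------------------------------------------------------

    def _loss(self, windows: np.ndarray, targets: np.ndarray) -> float:
        return _cross_entropy(self.predict_proba(windows), targets)

    def fit(self, train: WindowedDataset, val: WindowedDataset
            ) -> "CNNClassifier":
        """Adam + early stopping on validation loss; restores best weights."""
        if len(train) == 0 or len(val) == 0:
            raise ValueError("training and validation sets must be nonempty")
        if train.normalization != val.normalization:
            raise ValueError("train/val normalization modes differ")
        self.normalization = train.normalization
        self.channel_stats = train.channel_stats
        cfg = self.config
        rng = np.random.default_rng(cfg.seed + 1)
        xw = np.asarray(train.windows, dtype=np.float64)
        yt = np.asarray(train.soft_labels, dtype=np.float64)

        params = [self.K, self.b, self.W, self.c]
        m = [np.zeros_like(p) for p in params]
        v = [np.zeros_like(p) for p in params]
        t_step = 0
        beta1, beta2, eps = 0.9, 0.999, 1e-8

        best_val = np.inf
        best_weights = [p.copy() for p in params]
        best_epoch = 0
        hist: dict[str, list[float]] = {"loss": [], "val_loss": [],
                                        "accuracy": [], "val_accuracy": []}

        for epoch in range(cfg.max_epochs):
            order = rng.permutation(len(xw))
            for lo in range(0, len(order), cfg.batch_size):
                idx = order[lo:lo + cfg.batch_size]
                grads = self._gradients(xw[idx], yt[idx])
                t_step += 1
                for p, g, mi, vi in zip(params, grads, m, v):
                    mi *= beta1
                    mi += (1 - beta1) * g
                    vi *= beta2
                    vi += (1 - beta2) * g * g
                    mhat = mi / (1 - beta1 ** t_step)
                    vhat = vi / (1 - beta2 ** t_step)
                    p -= cfg.learning_rate * mhat / (np.sqrt(vhat) + eps)

            tr_p = self.predict_proba(xw)
            va_p = self.predict_proba(val.windows)
            tr_loss = _cross_entropy(tr_p, yt)
            va_loss = _cross_entropy(va_p, val.soft_labels)
            if not (np.isfinite(tr_loss) and np.isfinite(va_loss)):
                raise TrainingError(
                    f"non-finite loss at epoch {epoch}: "
                    f"train={tr_loss}, val={va_loss}")
            hist["loss"].append(tr_loss)
            hist["val_loss"].append(va_loss)
            hist["accuracy"].append(_soft_accuracy(tr_p, yt))
            hist["val_accuracy"].append(_soft_accuracy(va_p, val.soft_labels))
            if va_loss < best_val - 1e-12:
                best_val = va_loss
                best_weights = [p.copy() for p in params]
                best_epoch = epoch
            elif epoch - best_epoch >= cfg.patience:
                break

        self.K, self.b, self.W, self.c = (w.copy() for w in best_weights)
        self.history = hist
        return self

    def _gradients(self, x: np.ndarray, y: np.ndarray) -> list[np.ndarray]:
        B = x.shape[0]
        v = np.lib.stride_tricks.sliding_window_view(x, KERNEL, axis=-2)
        z = np.einsum("btcw,fw->btcf", v, self.K) + self.b
        a = np.maximum(z, 0.0)
        ar = a.reshape(B, CONV_OUT // POOL, POOL, 6, N_FILTERS)
        pooled = ar.max(axis=2)
        flat = pooled.reshape(B, FLAT)
        p = _softmax(flat @ self.W + self.c)

        dlogits = (p - y) / B
        dW = flat.T @ dlogits
        dc = dlogits.sum(axis=0)
        dflat = dlogits @ self.W.T
        dpool = dflat.reshape(B, CONV_OUT // POOL, 6, N_FILTERS)
        # route gradient to the argmax member of each pooled pair
        idx = ar.argmax(axis=2)[:, :, None, :, :]
        dar = np.zeros_like(ar)
        np.put_along_axis(dar, idx, dpool[:, :, None, :, :], axis=2)
        dz = dar.reshape(B, CONV_OUT, 6, N_FILTERS) * (z > 0)
        dK = np.einsum("btcf,btcw->fw", dz, v)
        db = dz.sum(axis=(0, 1, 2))
        return [dK, db, dW, dc]

    # -- streaming ----------------------------------------------------------

    def stream_probabilities(self, sig: SignalMatrix,
                             chunk: int = 4096) -> "ProbabilityStream":
        """Step-1 sliding-window inference over a whole recording.

        Returns one probability row per window start t = 0 .. N-50; row t is
        the forward pass of the window covering samples [t, t+50).
        """
        n = sig.n_samples
        if n < WINDOW:
            raise DataError("recording shorter than one window")
        x = np.asarray(sig.values, dtype=np.float64)
        if self.normalization == "zscore":
            if self.channel_stats is None:
                raise ValueError("zscore model is missing channel stats")
            x = apply_normalizer(x, self.channel_stats)
        a = self._conv_relu(x)                       # (n-6, 6, 5)
        t_total = n - WINDOW + 1
        probs = np.empty((t_total, self.config.n_classes))
        win_view = np.lib.stride_tricks.sliding_window_view(
            a, CONV_OUT, axis=0)                     # (t_total, 6, 5, 44)
        for lo in range(0, t_total, chunk):
            hi = min(lo + chunk, t_total)
            block = np.ascontiguousarray(
                win_view[lo:hi].transpose(0, 3, 1, 2))  # (b, 44, 6, 5)
            probs[lo:hi] = self._pool_dense(block)
        return ProbabilityStream(probs=probs, n_samples=n)

    # -- persistence ---------------------------------------------------------

    def save(self, path: str | Path) -> None:
        """Weights as .npz plus a JSON config sidecar."""
        path = Path(path)
        if path.suffix != ".npz":
            path = path.with_suffix(path.suffix + ".npz")
        arrays = {"K": self.K, "b": self.b, "W": self.W, "c": self.c}
        if self.channel_stats is not None:
            arrays["channel_mean"] = self.channel_stats.mean
            arrays["channel_sd"] = self.channel_stats.sd
        np.savez(path, **arrays)
        cfg = {k: (list(v) if isinstance(v, tuple) else v)
               for k, v in vars(self.config).items()}
        meta = {"config": cfg, "normalization": self.normalization}
        path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta))

    @classmethod
    def load(cls, path: str | Path) -> "CNNClassifier":
        path = Path(path)
        meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
        cfg_d = meta["config"]
        for key in ("input_shape", "kernel", "pool"):
            cfg_d[key] = tuple(cfg_d[key])
        model = cls(config=ModelConfig(**cfg_d),
                    normalization=meta["normalization"])
        with np.load(path) as data:
            model.K = data["K"]
            model.b = data["b"]
            model.W = data["W"]
            model.c = data["c"]
            if "channel_mean" in data:
                model.channel_stats = ChannelStats(data["channel_mean"],
                                                   data["channel_sd"])
        return model


def _soft_accuracy(p: np.ndarray, targets: np.ndarray) -> float:
    from .windows import hard_labels
    return float((hard_labels(p) == hard_labels(targets)).mean())


@dataclass
class ProbabilityStream:
    """Per-window-start class probabilities from step-1 streaming.

    Row t covers samples [t, t+50).  The per-sample view assigns row t to
    sample t+49 (the newest sample the window has seen — the causal choice
    for live use); the first 49 samples inherit row 0.
    """

    probs: np.ndarray
    n_samples: int
    offset: int = WINDOW - 1

    def __post_init__(self) -> None:
        if self.probs.shape[0] != self.n_samples - WINDOW + 1:
            raise ValueError("row count must equal n_samples - window + 1")

    def per_sample(self) -> np.ndarray:
        """(n_samples, 4) matrix of per-sample probabilities."""
        head = np.repeat(self.probs[:1], self.offset, axis=0)
        return np.concatenate([head, self.probs], axis=0)
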