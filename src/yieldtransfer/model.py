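"""CNN yield regressor on histogram tensors.

The network treats a county-season histogram tensor as a 2-D image
(timesteps x bins) with 9 spectral channels.  Downsampling comes exclusively
from strided convolutions — pooling would make the net invariant to *where*
probability mass sits along the bin axis, which is exactly the signal
(histogram location/shape encodes crop state).  Six stride-2 convolutional
blocks (batch norm + ReLU + dropout) feed a dense head whose penultimate
activation vector ``h(x)`` is exposed: the prediction is the affine map
``h(x) @ w_last + b_last``, the decomposition the Gaussian-process correction
head builds on.

Training minimizes mean-squared error plus any supplied penalty terms
(see :mod:`yieldtransfer.transfer`), with Adam, early stopping on a
held-out validation split, and restoration of the best-validation weights.
"""

from __future__ import annotations

from collections import OrderedDict
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from ._net import Adam, BatchNorm2d, Conv2d, Dense, Dropout, ReLU, SGD
from .features import HistogramTensor

__all__ = [
    "ModelConfig",
    "WeightSet",
    "YieldCNN",
    "build_model",
    "train",
    "predict",
    "penultimate_features",
    "save_weights",
    "load_weights",
]


@dataclass
class ModelConfig:
    """Architecture and training hyperparameters.

    ``channels_per_layer`` must have one entry per convolutional layer;
    widths double with depth by default.  ``stride`` applies to every
    convolutional layer (2 halves each spatial dimension).
    """

    n_conv_layers: int = 6
    stride: int = 2
    channels_per_layer: tuple[int, ...] = (16, 16, 32, 32, 64, 64)
    kernel_size: int = 3
    dense_dim: int = 64
    dropout_rate: float = 0.1
    batch_norm: bool = True
    early_stopping_patience: int = 15
    max_epochs: int = 150
    learning_rate: float = 3e-3
    batch_size: int = 64
    optimizer: str = "adam"
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.channels_per_layer) != self.n_conv_layers:
            raise ValueError(
                "channels_per_layer must have n_conv_layers entries "
                f"({len(self.channels_per_layer)} != {self.n_conv_layers})"
            )
        if self.stride < 1:
            raise ValueError("stride must be >= 1")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must be in [0, 1)")
        if self.optimizer not in ("adam", "sgd"):
            raise ValueError(f"unknown optimizer {self.optimizer!r}")


class WeightSet:
    """Named, ordered model parameters partitioned into conv stack and head.

    Keys look like ``conv_3/W`` or ``dense/W2``; :meth:`partition_of` maps a
    key to its partition label (``conv_1`` .. ``conv_6`` or ``dense``).
    Batch-norm running statistics travel with their layer so that copying a
    partition transfers the layer's full state.
    """

    def __init__(self, arrays: "OrderedDict[str, np.ndarray]"):
        self.arrays = arrays

    @staticmethod
    def partition_of(name: str) -> str:
        return name.split("/")[0]

    def partition(self, label: str) -> "OrderedDict[str, np.ndarray]":
        return OrderedDict(
            (k, v) for k, v in self.arrays.items() if self.partition_of(k) == label
        )

    @property
    def partitions(self) -> list[str]:
        seen: list[str] = []
        for k in self.arrays:
            p = self.partition_of(k)
            if p not in seen:
                seen.append(p)
        return seen

    def copy(self) -> "WeightSet":
        return WeightSet(OrderedDict((k, v.copy()) for k, v in self.arrays.items()))

    def flat(self, labels: Iterable[str] | None = None) -> np.ndarray:
        labels = None if labels is None else set(labels)
        parts = [
            v.ravel()
            for k, v in self.arrays.items()
            if labels is None or self.partition_of(k) in labels
        ]
        return np.concatenate(parts) if parts else np.zeros(0)

    def __iter__(self):
        return iter(self.arrays.items())

    def __getitem__(self, key: str) -> np.ndarray:
        return self.arrays[key]

    def keys(self):
        return self.arrays.keys()


class YieldCNN:
    """Six strided convolutional blocks plus a two-layer dense head."""

    def __init__(self, config: ModelConfig, input_shape: tuple[int, int, int] = (9, 32, 32)):
        self.config = config
        self.input_shape = tuple(input_shape)
        self.frozen_n = 0
        self.trained = False
        rng = np.random.default_rng(config.seed)

        c, h, w = self.input_shape
        self.blocks: list[dict] = []
        for i, c_out in enumerate(config.channels_per_layer):
            block = {
                "conv": Conv2d(c, c_out, config.kernel_size, config.stride, rng),
                "bn": BatchNorm2d(c_out) if config.batch_norm else None,
                "relu": ReLU(),
                "drop": Dropout(config.dropout_rate),
            }
            self.blocks.append(block)
            pad = config.kernel_size // 2
            h = (h + 2 * pad - config.kernel_size) // config.stride + 1
            w = (w + 2 * pad - config.kernel_size) // config.stride + 1
            if h < 1 or w < 1:
                dim = "timestep" if h < 1 else "bin"
                raise ValueError(
                    f"{dim} dimension collapses below 1 at conv layer {i + 1}; "
                    f"input {self.input_shape} cannot survive "
                    f"{config.n_conv_layers} stride-{config.stride} reductions"
                )
            c = c_out
        self.flat_dim = c * h * w
        self.dense1 = Dense(self.flat_dim, config.dense_dim, rng)
        self.relu_h = ReLU()
        self.drop_h = Dropout(config.dropout_rate)
        self.dense2 = Dense(config.dense_dim, 1, rng)
        self._flat_shape = None

    # -- parameter access ---------------------------------------------------

    def get_weights(self) -> WeightSet:
        arrays: "OrderedDict[str, np.ndarray]" = OrderedDict()
        for i, blk in enumerate(self.blocks, start=1):
            arrays[f"conv_{i}/W"] = blk["conv"].W.copy()
            arrays[f"conv_{i}/b"] = blk["conv"].b.copy()
            if blk["bn"] is not None:
                arrays[f"conv_{i}/bn_gamma"] = blk["bn"].gamma.copy()
                arrays[f"conv_{i}/bn_beta"] = blk["bn"].beta.copy()
                arrays[f"conv_{i}/bn_mean"] = blk["bn"].run_mean.copy()
                arrays[f"conv_{i}/bn_var"] = blk["bn"].run_var.copy()
        arrays["dense/W1"] = self.dense1.W.copy()
        arrays["dense/b1"] = self.dense1.b.copy()
        arrays["dense/W2"] = self.dense2.W.copy()
        arrays["dense/b2"] = self.dense2.b.copy()
        return WeightSet(arrays)

    def set_weights(self, ws: WeightSet) -> None:
        refs = self._param_refs(include_stats=True)
        for name, arr in ws.arrays.items():
            if name not in refs:
                raise KeyError(f"unknown parameter {name!r}")
            if refs[name].shape != arr.shape:
                raise ValueError(
                    f"shape mismatch for {name!r}: model has {refs[name].shape}, "
                    f"weight set has {arr.shape}"
                )
            np.copyto(refs[name], arr)

    def _param_refs(self, include_stats: bool = False) -> "OrderedDict[str, np.ndarray]":
        refs: "OrderedDict[str, np.ndarray]" = OrderedDict()
        for i, blk in enumerate(self.blocks, start=1):
            refs[f"conv_{i}/W"] = blk["conv"].W
            refs[f"conv_{i}/b"] = blk["conv"].b
            if blk["bn"] is not None:
                refs[f"conv_{i}/bn_gamma"] = blk["bn"].gamma
                refs[f"conv_{i}/bn_beta"] = blk["bn"].beta
                if include_stats:
                    refs[f"conv_{i}/bn_mean"] = blk["bn"].run_mean
                    refs[f"conv_{i}/bn_var"] = blk["bn"].run_var
        refs["dense/W1"] = self.dense1.W
        refs["dense/b1"] = self.dense1.b
        refs["dense/W2"] = self.dense2.W
        refs["dense/b2"] = self.dense2.b
        return refs

    def trainable_params(self) -> "OrderedDict[str, np.ndarray]":
        refs = self._param_refs(include_stats=False)
        frozen = {f"conv_{i}" for i in range(1, self.frozen_n + 1)}
        return OrderedDict(
            (k, v) for k, v in refs.items() if WeightSet.partition_of(k) not in frozen
        )

    # -- forward / backward -------------------------------------------------

    def forward(
        self,
        x: np.ndarray,
        training: bool = False,
        rng: np.random.Generator | None = None,
    ) -> tuple[np.ndarray, np.ndarray]:
        """Returns (predictions [n], penultimate features h [n, dense_dim])."""
        out = np.asarray(x, dtype=np.float64)
        if out.ndim == 3:
            out = out[None]
        if out.shape[1:] != self.input_shape:
            raise ValueError(
                f"input shape {out.shape[1:]} does not match model input "
                f"{self.input_shape}"
            )
        for i, blk in enumerate(self.blocks, start=1):
            frozen = i <= self.frozen_n
            out = blk["conv"].forward(out)
            if blk["bn"] is not None:
                # frozen layers normalize with (and never update) running stats
                out = blk["bn"].forward(out, training=training and not frozen)
            out = blk["relu"].forward(out)
            out = blk["drop"].forward(out, training, rng)
        self._flat_shape = out.shape
        flat = out.reshape(out.shape[0], -1)
        h = self.relu_h.forward(self.dense1.forward(flat))
        hd = self.drop_h.forward(h, training, rng)
        pred = self.dense2.forward(hd)[:, 0]
        return pred, h

    def backward(self, gy: np.ndarray, h_extra_grad: np.ndarray | None = None) -> dict:
        """Backpropagate d(loss)/d(pred); returns name->grad for trainables."""
        g = self.drop_h.backward(self.dense2.backward(gy[:, None]))
        if h_extra_grad is not None:
            g = g + h_extra_grad
        g = self.dense1.backward(self.relu_h.backward(g))
        g = g.reshape(self._flat_shape)
        for i in range(len(self.blocks), self.frozen_n, -1):
            blk = self.blocks[i - 1]
            g = blk["relu"].backward(blk["drop"].backward(g))
            if blk["bn"] is not None:
                g = blk["bn"].backward(g)
            g = blk["conv"].backward(g)

        grads: dict[str, np.ndarray] = {}
        for i in range(self.frozen_n + 1, len(self.blocks) + 1):
            blk = self.blocks[i - 1]
            grads[f"conv_{i}/W"] = blk["conv"].gW
            grads[f"conv_{i}/b"] = blk["conv"].gb
            if blk["bn"] is not None:
                grads[f"conv_{i}/bn_gamma"] = blk["bn"].ggamma
                grads[f"conv_{i}/bn_beta"] = blk["bn"].gbeta
        grads["dense/W1"] = self.dense1.gW
        grads["dense/b1"] = self.dense1.gb
        grads["dense/W2"] = self.dense2.gW
        grads["dense/b2"] = self.dense2.gb
        return grads


def build_model(
    config: ModelConfig, input_shape: tuple[int, int, int] = (9, 32, 32)
) -> tuple[YieldCNN, WeightSet]:
    """Deterministically construct the CNN and return it with its weights."""
    model = YieldCNN(config, input_shape)
    return model, model.get_weights()


def _as_arrays(data) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(data, tuple) and len(data) == 2:
        X, y = data
        return np.asarray(X, dtype=np.float64), np.asarray(y, dtype=np.float64)
    tensors, ys = zip(*data)
    X = np.stack(
        [t.data if isinstance(t, HistogramTensor) else np.asarray(t) for t in tensors]
    )
    return X.astype(np.float64), np.asarray(ys, dtype=np.float64)


def train(
    model: YieldCNN,
    data,
    loss_terms: Sequence = (),
    config: ModelConfig | None = None,
    seasons: np.ndarray | None = None,
    val_fraction: float = 0.1,
) -> tuple[YieldCNN, dict]:
    """Fit the CNN by minimizing MSE plus the supplied penalty terms.

    ``data`` is either a list of ``(HistogramTensor, yield)`` pairs or an
    ``(X, y)`` tuple.  The validation split for early stopping is the last
    season when ``seasons`` is given (respecting temporal ordering),
    otherwise the trailing ``val_fraction`` of records.  Targets are
    standardized internally; the scaling is folded back into the output layer
    afterwards, so the returned model predicts bu/ac directly and the
    decomposition ``predict = h(x) @ W2 + b2`` holds in raw units.
    """
    cfg = config or model.config
    X, y = _as_arrays(data)
    n = X.shape[0]
    if n == 0:
        raise ValueError("empty training set")

    if n < 2:
        raise ValueError("need at least two records to form a validation split")

    def trailing_split() -> np.ndarray:
        first_val = min(n - 1, int(np.ceil(n * (1 - val_fraction))))
        mask = np.zeros(n, dtype=bool)
        mask[max(1, first_val):] = True
        return mask

    if seasons is not None:
        seasons = np.asarray(seasons)
        val_mask = seasons == seasons.max()
        if val_mask.all():  # single-season data: fall back to a record split
            val_mask = trailing_split()
    else:
        val_mask = trailing_split()
    Xtr, ytr = X[~val_mask], y[~val_mask]
    Xva, yva = X[val_mask], y[val_mask]

    y_mean, y_std = float(ytr.mean()), float(ytr.std())
    if y_std == 0.0:
        y_std = 1.0
    # move the output layer into standardized-target space for this fit
    model.dense2.W /= y_std
    model.dense2.b[:] = (model.dense2.b - y_mean) / y_std
    ytr_s = (ytr - y_mean) / y_std
    yva_s = (yva - y_mean) / y_std

    rng = np.random.default_rng(np.random.SeedSequence((cfg.seed, 0x7E41)))
    opt = Adam(cfg.learning_rate) if cfg.optimizer == "adam" else SGD(cfg.learning_rate)
    params = model.trainable_params()

    best_val = np.inf
    best_ws = model.get_weights()
    patience_left = cfg.early_stopping_patience
    history: dict = {"train_loss": [], "val_loss": [], "best_epoch": 0}

    n_tr = Xtr.shape[0]
    bs = min(cfg.batch_size, n_tr)
    for epoch in range(cfg.max_epochs):
        order = rng.permutation(n_tr)
        epoch_loss = 0.0
        for bi, start in enumerate(range(0, n_tr, bs)):
            idx = order[start : start + bs]
            xb, yb = Xtr[idx], ytr_s[idx]
            pred, h = model.forward(xb, training=True, rng=rng)
            resid = pred - yb
            mse = float(np.mean(resid**2))
            loss = mse
            extra_wgrads: dict[str, np.ndarray] = {}
            h_extra = None
            for term in loss_terms:
                value, wgrads, hgrad = term(model, h)
                loss += value
                if wgrads:
                    for k, g in wgrads.items():
                        extra_wgrads[k] = extra_wgrads.get(k, 0.0) + g
                if hgrad is not None:
                    h_extra = hgrad if h_extra is None else h_extra + hgrad
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"non-finite loss {loss!r} at epoch {epoch}, batch {bi} "
                    f"(batch size {len(idx)}, mse={mse!r})"
                )
            gy = 2.0 * resid / len(idx)
            grads = model.backward(gy, h_extra_grad=h_extra)
            for k, g in extra_wgrads.items():
                if k in grads:
                    grads[k] = grads[k] + g
            opt.step(params, grads)
            epoch_loss += loss * len(idx)
        history["train_loss"].append(epoch_loss / n_tr)

        val_pred, _ = model.forward(Xva, training=False)
        val_mse = float(np.mean((val_pred - yva_s) ** 2))
        history["val_loss"].append(val_mse)
        if val_mse < best_val - 1e-12:
            best_val = val_mse
            best_ws = model.get_weights()
            history["best_epoch"] = epoch
            patience_left = cfg.early_stopping_patience
        else:
            patience_left -= 1
            if patience_left < 0:
                break

    model.set_weights(best_ws)
    # fold target standardization back into the output layer: raw-unit output
    model.dense2.W *= y_std
    model.dense2.b[:] = model.dense2.b * y_std + y_mean
    model.trained = True
    return model, history


def predict(model: YieldCNN, tensors, batch_size: int = 256) -> np.ndarray:
    """Deterministic predictions in bu/ac (dropout off, batch norm frozen)."""
    if isinstance(tensors, np.ndarray):
        X = tensors
    elif isinstance(tensors, HistogramTensor):
        X = tensors.data[None]
    else:
        X = np.stack(
            [t.data if isinstance(t, HistogramTensor) else np.asarray(t) for t in tensors]
        )
    X = np.asarray(X, dtype=np.float64)
    if X.ndim == 3:
        X = X[None]
    out = [model.forward(X[i : i + batch_size], training=False)[0]
           for i in range(0, X.shape[0], batch_size)]
    return np.concatenate(out)


def save_weights(ws: WeightSet, path) -> None:
    """Persist a weight set (names are preserved; ``/`` is npz-safe)."""
    np.savez(path, **dict(ws.arrays))


def load_weights(path) -> WeightSet:
    with np.load(path) as data:
        return WeightSet(OrderedDict((k, data[k].copy()) for k in data.files))


def penultimate_features(model: YieldCNN, tensors, batch_size: int = 256) -> np.ndarray:
    """The dense head's input vectors h(x), one row per input."""
    if isinstance(tensors, np.ndarray):
        X = tensors
    else:
        X = np.stack(
            [t.data if isinstance(t, HistogramTensor) else np.asarray(t) for t in tensors]
        )
    X = np.asarray(X, dtype=np.float64)
    if X.ndim == 3:
        X = X[None]
    out = [model.forward(X[i : i + batch_size], training=False)[1]
           for i in range(0, X.shape[0], batch_size)]
    return np.concatenate(out)
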