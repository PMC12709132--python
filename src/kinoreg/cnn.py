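"""1D convolutional regression network for percent-inhibition prediction.

The network regresses percent inhibition (0-100) on the concatenated
kinase/compound feature vector treated as a 1D signal: a stack of
convolutional layers (kernels slide over the feature axis),

    Conv(x)_{i,k} = F( sum_{m=0}^{M-1} w^k_m x_{i+m} + b_k ),

with ReLU activations, interleaved pooling layers, and a fully connected
head ending in a single linear output.  The canonical configuration is 20
convolutional layers, two pooling layers (after conv layers 10 and 20) and
three fully connected layers, trained with the RMSprop optimizer on an RMSE
loss at learning rate 1e-6 for 150 epochs; every unstated architectural
detail (kernel size 3, 'same' padding, 32 filters doubling after each
pooling layer, max pooling with window 2, FC sizes 512/128/1) is an
explicit, overridable :class:`ModelConfig` default.

The module is organised like a statsmodels estimator:
:class:`PercentInhibitionCNN` is built from a :class:`~kinoreg.dataset.PairDataset`
(standardisation statistics come from the training split only) and its
``fit()`` returns a :class:`CNNRegressionResults` carrying the per-epoch
loss history, the best-validation-loss parameters, ``predict``,
``evaluate`` and ``summary``.  Everything runs in numpy on the CPU and is
bit-reproducible for a fixed seed on a single thread.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Callable, Literal, Sequence

import numpy as np
import pandas as pd

from .dataset import PairDataset
from .errors import ConfigurationError, SchemaError, ValidationError
from . import metrics as _metrics


# ---------------------------------------------------------------------------
# Eq.-style single-layer forward pass (the reference operation)


@dataclass
class ConvLayerSpec:
    """One convolutional layer: weights (n_kernels, n_channels, M), bias per kernel."""

    weights: np.ndarray
    bias: np.ndarray | float = 0.0
    activation: Literal["relu", "linear"] = "linear"
    padding: Literal["valid", "same"] = "valid"

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.ndim == 1:          # (M,) -> one kernel, one channel
            w = w[None, None, :]
        elif w.ndim == 2:        # (K, M) -> one channel
            w = w[:, None, :]
        if w.ndim != 3 or w.shape[2] < 1 or w.shape[0] < 1:
            raise ConfigurationError(f"kernel tensor must be (K, C, M) with K,M >= 1, got {w.shape}")
        self.weights = w
        b = np.asarray(self.bias, dtype=float)
        if b.ndim == 0:
            b = np.full(w.shape[0], float(b))
        if b.shape != (w.shape[0],):
            raise ConfigurationError(f"bias must be scalar or per-kernel, got shape {b.shape}")
        self.bias = b
        if self.activation not in ("relu", "linear"):
            raise ConfigurationError(f"unknown activation {self.activation!r}")

    @property
    def kernel_size(self) -> int:
        return self.weights.shape[2]

    @property
    def n_kernels(self) -> int:
        return self.weights.shape[0]


def conv1d_forward(x: np.ndarray, spec: ConvLayerSpec) -> np.ndarray:
    """Single-layer 1D convolution (cross-correlation) forward pass.

    ``x`` is (L,) or (C, L); output is (n_kernels, L_out) with
    ``output[k, i] = F(sum_{c,m} w[k,c,m] * x[c, i+m] + b[k])``.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim == 1:
        x = x[None, :]
    if x.ndim != 2:
        raise ValidationError(f"x must be (L,) or (C, L), got shape {x.shape}")
    K, C, M = spec.weights.shape
    if x.shape[0] != C:
        raise ValidationError(f"x has {x.shape[0]} channels, kernels expect {C}")
    if spec.padding == "same":
        pad_l = (M - 1) // 2
        x = np.pad(x, ((0, 0), (pad_l, M - 1 - pad_l)))
    if x.shape[1] < M:
        raise ValidationError(f"input length {x.shape[1]} < kernel size {M} under 'valid' padding")
    windows = np.lib.stride_tricks.sliding_window_view(x, M, axis=1)  # (C, L_out, M)
    out = np.einsum("clm,kcm->kl", windows, spec.weights) + spec.bias[:, None]
    if spec.activation == "relu":
        out = np.maximum(out, 0.0)
    return out


# ---------------------------------------------------------------------------
# network layers (internal)


_DTYPE = np.float32  # network-internal dtype: halves memory traffic on the CPU


class _Conv1D:
    """Channels-last 1D convolution: activations are (N, L, C) throughout.

    The kernel is stored as a GEMM-ready matrix ``W`` of shape (M * C_in,
    C_out), rows ordered offset-major (offset m, then input channel), so
    forward/backward are single matrix products over stacked shifted views.
    """

    kind = "conv"

    def __init__(self, c_in: int, c_out: int, kernel_size: int, padding: str,
                 rng: np.random.Generator):
        fan_in = c_in * kernel_size
        self.W = rng.normal(0.0, np.sqrt(2.0 / fan_in),
                            size=(kernel_size * c_in, c_out)).astype(_DTYPE)
        self.b = np.zeros(c_out, dtype=_DTYPE)
        self.kernel_size = kernel_size
        self.c_in = c_in
        self.padding = padding
        self._cache = None

    def _im2col(self, x: np.ndarray) -> tuple[np.ndarray, int, tuple]:
        M = self.kernel_size
        if self.padding == "same":
            pad_l = (M - 1) // 2
            xp = np.pad(x, ((0, 0), (pad_l, M - 1 - pad_l), (0, 0)))
        else:
            xp = x
        L_out = xp.shape[1] - M + 1
        cols = np.concatenate([xp[:, m : m + L_out, :] for m in range(M)], axis=2)
        return cols, L_out, xp.shape

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        n = x.shape[0]
        cols, L_out, xp_shape = self._im2col(x)
        flat = cols.reshape(n * L_out, -1)
        out = (flat @ self.W).reshape(n, L_out, -1)
        out += self.b
        if train:
            self._cache = (flat, x.shape[1], xp_shape, L_out)
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        flat, L_in, xp_shape, L_out = self._cache
        n, _, c_out = dout.shape
        M = self.kernel_size
        dflat = dout.reshape(n * L_out, c_out)
        self.dW = flat.T @ dflat
        self.db = dflat.sum(axis=0)
        dcols = (dflat @ self.W.T).reshape(n, L_out, M, self.c_in)
        dxp = np.zeros(xp_shape, dtype=_DTYPE)
        for m in range(M):
            dxp[:, m : m + L_out, :] += dcols[:, :, m, :]
        if self.padding == "same":
            pad_l = (M - 1) // 2
            return dxp[:, pad_l : pad_l + L_in, :]
        return dxp


class _Dense:
    kind = "fc"

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator, he: bool):
        scale = np.sqrt((2.0 if he else 1.0) / n_in)
        self.W = rng.normal(0.0, scale, size=(n_in, n_out)).astype(_DTYPE)
        self.b = np.zeros(n_out, dtype=_DTYPE)

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if train:
            self._x = x
        return x @ self.W + self.b

    def backward(self, dout: np.ndarray) -> np.ndarray:
        self.dW = self._x.T @ dout
        self.db = dout.sum(axis=0)
        return dout @ self.W.T


class _ReLU:
    kind = "act"

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if train:
            self._mask = x > 0
            return x * self._mask
        return np.maximum(x, 0.0)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout * self._mask


class _Pool1D:
    """Pooling over the length axis of channels-last (N, L, C) activations."""

    kind = "pool"

    def __init__(self, window: int, mode: str):
        self.window = window
        self.mode = mode

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        n, L, c = x.shape
        L_out = L // self.window
        xr = x[:, : L_out * self.window, :].reshape(n, L_out, self.window, c)
        if self.mode == "max":
            out = xr.max(axis=2)
            if train:
                self._argmax = xr.argmax(axis=2)
                self._shape = x.shape
        else:
            out = xr.mean(axis=2)
            if train:
                self._shape = x.shape
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, L, c = self._shape
        L_out = dout.shape[1]
        dx = np.zeros((n, L_out, self.window, c), dtype=_DTYPE)
        if self.mode == "max":
            np.put_along_axis(dx, self._argmax[:, :, None, :], dout[:, :, None, :], axis=2)
        else:
            dx += dout[:, :, None, :] / self.window
        full = np.zeros((n, L, c), dtype=_DTYPE)
        full[:, : L_out * self.window, :] = dx.reshape(n, L_out * self.window, c)
        return full


class _Flatten:
    kind = "flatten"

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout.reshape(self._shape)


# ---------------------------------------------------------------------------
# configuration


TargetTransform = Literal["identity", "scale01", "other"]


@dataclass
class ModelConfig:
    """Architecture and training configuration.

    Defaults are the canonical configuration: 20 convolutional layers, max
    pooling (window 2) after layers 10 and 20, three fully connected layers,
    RMSprop on an RMSE loss with learning rate 1e-6 for 150 epochs.  All
    unreported details are explicit here and overridable.
    """

    n_conv_layers: int = 20
    pooling_after: tuple[int, ...] = (10, 20)
    pool_kind: Literal["max", "average"] = "max"
    pool_window: int = 2
    kernel_size: int = 3
    n_filters: int = 32
    double_filters_after_pool: bool = True
    padding: Literal["same", "valid"] = "same"
    fc_sizes: tuple[int, ...] = (512, 128, 1)
    learning_rate: float = 1e-6
    epochs: int = 150
    batch_size: int = 64
    optimizer: str = "rmsprop"  # fixed
    loss: str = "rmse"          # fixed
    rmsprop_rho: float = 0.9
    rmsprop_eps: float = 1e-7
    seed: int = 0
    target_transform: TargetTransform = "identity"
    clip_predictions: bool = False
    shuffle_each_epoch: bool = True

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ConfigurationError("learning_rate must be > 0")
        if self.n_conv_layers < 1 or self.kernel_size < 1 or self.n_filters < 1:
            raise ConfigurationError("layer counts, kernel size and filters must be >= 1")
        if self.epochs < 0 or self.batch_size < 1:
            raise ConfigurationError("epochs must be >= 0 and batch_size >= 1")
        if self.fc_sizes[-1] != 1:
            raise ConfigurationError("final fully connected layer must have a single output")
        if any(p < 1 or p > self.n_conv_layers for p in self.pooling_after):
            raise ConfigurationError("pooling_after indices must lie in [1, n_conv_layers]")
        if self.optimizer != "rmsprop" or self.loss != "rmse":
            raise ConfigurationError("optimizer is fixed to rmsprop and loss to rmse")

    @property
    def is_paper_fidelity(self) -> bool:
        """True when the layer counts match the canonical 20/2/3 stack."""
        return (
            self.n_conv_layers == 20
            and len(self.pooling_after) == 2
            and len(self.fc_sizes) == 3
        )


def _target_transform_fns(cfg: ModelConfig,
                          custom: tuple[Callable, Callable] | None):
    if cfg.target_transform == "identity":
        return (lambda y: y), (lambda y: y)
    if cfg.target_transform == "scale01":
        return (lambda y: y / 100.0), (lambda y: y * 100.0)
    if cfg.target_transform == "other":
        if custom is None:
            raise ConfigurationError(
                "target_transform='other' requires custom (transform, inverse) functions"
            )
        return custom
    raise ConfigurationError(f"unknown target transform {cfg.target_transform!r}")


# ---------------------------------------------------------------------------
# network assembly


class NetworkArchitecture:
    """A built (untrained) layer stack plus its architecture report."""

    def __init__(self, cfg: ModelConfig, input_width: int):
        if input_width < 1:
            raise ConfigurationError("input_width must be >= 1")
        rng = np.random.default_rng(cfg.seed)
        layers: list = []
        shapes: list[tuple] = []
        c, L = 1, input_width
        filters = cfg.n_filters
        pool_set = set(cfg.pooling_after)
        for i in range(1, cfg.n_conv_layers + 1):
            layers.append(_Conv1D(c, filters, cfg.kernel_size, cfg.padding, rng))
            layers.append(_ReLU())
            if cfg.padding == "valid":
                L = L - cfg.kernel_size + 1
            if L < 1:
                raise ConfigurationError(
                    f"input too narrow: width collapses to {L} at conv layer {i}"
                )
            c = filters
            shapes.append(("conv", i, c, L))
            if i in pool_set:
                layers.append(_Pool1D(cfg.pool_window, cfg.pool_kind))
                L //= cfg.pool_window
                if L < 1:
                    raise ConfigurationError(
                        f"input too narrow: width collapses to {L} at pooling after layer {i}"
                    )
                shapes.append(("pool", i, c, L))
                if cfg.double_filters_after_pool:
                    filters *= 2
        layers.append(_Flatten())
        dim = c * L
        for j, size in enumerate(cfg.fc_sizes):
            last = j == len(cfg.fc_sizes) - 1
            layers.append(_Dense(dim, size, rng, he=not last))
            if not last:
                layers.append(_ReLU())
            shapes.append(("fc", j + 1, size, None))
            dim = size
        self.config = cfg
        self.input_width = input_width
        self.layers = layers
        self._shapes = shapes

    # --- inspection -------------------------------------------------------

    def architecture_report(self) -> dict:
        counts = {
            "conv_layers": sum(1 for s in self._shapes if s[0] == "conv"),
            "pooling_layers": sum(1 for s in self._shapes if s[0] == "pool"),
            "fc_layers": sum(1 for s in self._shapes if s[0] == "fc"),
        }
        return {
            "counts": counts,
            "layers": [
                {"kind": k, "index": i, "channels_or_units": c, "length": L}
                for (k, i, c, L) in self._shapes
            ],
            "n_parameters": int(sum(p.size for p in self.parameters())),
            "input_width": self.input_width,
        }

    def parameters(self) -> list[np.ndarray]:
        out = []
        for layer in self.layers:
            if hasattr(layer, "W"):
                out += [layer.W, layer.b]
        return out

    def initial_parameters(self) -> list[np.ndarray]:
        return [p.copy() for p in self.parameters()]

    def set_parameters(self, params: Sequence[np.ndarray]) -> None:
        own = self.parameters()
        if len(own) != len(params):
            raise ValidationError("parameter count mismatch")
        for dst, src in zip(own, params):
            if dst.shape != np.asarray(src).shape:
                raise ValidationError("parameter shape mismatch")
            dst[...] = src

    # --- execution --------------------------------------------------------

    def forward(self, X: np.ndarray, train: bool = False) -> np.ndarray:
        out = np.ascontiguousarray(X, dtype=_DTYPE)[:, :, None]  # (N, L, 1) channels-last
        for layer in self.layers:
            out = layer.forward(out, train)
        return out[:, 0].astype(float)

    def backward(self, dpred: np.ndarray) -> None:
        grad = np.asarray(dpred, dtype=_DTYPE)[:, None]
        for layer in reversed(self.layers):
            grad = layer.backward(grad)

    def gradients(self) -> list[np.ndarray]:
        out = []
        for layer in self.layers:
            if hasattr(layer, "W"):
                out += [layer.dW, layer.db]
        return out


def build_model(cfg: ModelConfig, input_width: int) -> NetworkArchitecture:
    """Build the untrained network and its architecture report."""
    return NetworkArchitecture(cfg, input_width)


class _RMSProp:
    def __init__(self, params: list[np.ndarray], lr: float, rho: float, eps: float):
        self.params = params
        self.cache = [np.zeros_like(p) for p in params]
        self.lr, self.rho, self.eps = lr, rho, eps

    def step(self, grads: list[np.ndarray]) -> None:
        for p, c, g in zip(self.params, self.cache, grads):
            c *= self.rho
            c += (1.0 - self.rho) * g * g
            p -= self.lr * g / (np.sqrt(c) + self.eps)


# ---------------------------------------------------------------------------
# model / results


class _Standardizer:
    """Per-column z-scoring; statistics always come from the training split."""

    def __init__(self, mean: np.ndarray, std: np.ndarray):
        self.mean = mean
        self.std = std

    @classmethod
    def fit(cls, X: np.ndarray) -> "_Standardizer":
        std = X.std(axis=0)
        return cls(X.mean(axis=0), np.where(std < 1e-8, 1.0, std))

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (X - self.mean) / self.std


def _schema_hash(feature_names: Sequence[str]) -> str:
    return hashlib.sha256("\n".join(feature_names).encode()).hexdigest()[:16]


class PercentInhibitionCNN:
    """CNN regression model bound to a split :class:`PairDataset`.

    Parameters
    ----------
    dataset : PairDataset
        Must carry split labels with a nonempty train split; the validation
        split (if present) drives checkpoint selection.
    config : ModelConfig, optional
    custom_target_transform : (callable, callable), optional
        Forward/inverse pair, used when ``config.target_transform='other'``.
    """

    def __init__(
        self,
        dataset: PairDataset | None,
        config: ModelConfig | None = None,
        custom_target_transform: tuple[Callable, Callable] | None = None,
    ):
        self.config = config or ModelConfig()
        self._fwd, self._inv = _target_transform_fns(self.config, custom_target_transform)
        if dataset is not None:
            train = dataset.subset("train")
            self.feature_names = list(dataset.feature_names)
            self.scaler = _Standardizer.fit(train.X)
            self._X_train = self.scaler.transform(train.X)
            self._y_train = self._fwd(train.y)
            try:
                val = dataset.subset("val")
                self._X_val = self.scaler.transform(val.X)
                self._y_val = self._fwd(val.y)
            except ValidationError:
                self._X_val = self._y_val = None
            self.network = build_model(self.config, dataset.n_features)

    @classmethod
    def from_arrays(
        cls,
        X_train: np.ndarray,
        y_train: np.ndarray,
        X_val: np.ndarray | None = None,
        y_val: np.ndarray | None = None,
        feature_names: Sequence[str] | None = None,
        config: ModelConfig | None = None,
    ) -> "PercentInhibitionCNN":
        """Construct directly from train (and optional validation) arrays."""
        X_train = np.asarray(X_train, dtype=float)
        if feature_names is None:
            feature_names = [f"f{i}" for i in range(X_train.shape[1])]
        obj = cls(None, config)
        obj.feature_names = list(feature_names)
        obj.scaler = _Standardizer.fit(X_train)
        obj._X_train = obj.scaler.transform(X_train)
        obj._y_train = obj._fwd(np.asarray(y_train, dtype=float))
        if X_val is not None:
            obj._X_val = obj.scaler.transform(np.asarray(X_val, dtype=float))
            obj._y_val = obj._fwd(np.asarray(y_val, dtype=float))
        else:
            obj._X_val = obj._y_val = None
        obj.network = build_model(obj.config, X_train.shape[1])
        return obj

    # -----------------------------------------------------------------

    def fit(self, epochs: int | None = None, verbose: bool = False) -> "CNNRegressionResults":
        """Train with RMSprop on the RMSE loss; returns the results object.

        The per-epoch history records train and validation RMSE (on the
        transformed target scale); the parameters with the lowest
        validation loss are retained as the checkpoint (final parameters
        when no validation split exists).
        """
        cfg = self.config
        n_epochs = cfg.epochs if epochs is None else epochs
        net = self.network
        opt = _RMSProp(net.parameters(), cfg.learning_rate, cfg.rmsprop_rho, cfg.rmsprop_eps)
        rng = np.random.default_rng(cfg.seed + 1)
        n = self._X_train.shape[0]

        best_val = np.inf
        best_params = [p.copy() for p in net.parameters()]
        history = []
        for epoch in range(n_epochs):
            order = rng.permutation(n) if cfg.shuffle_each_epoch else np.arange(n)
            sq_sum = 0.0
            for start in range(0, n, cfg.batch_size):
                idx = order[start : start + cfg.batch_size]
                xb, yb = self._X_train[idx], self._y_train[idx]
                pred = net.forward(xb, train=True)
                err = pred - yb
                batch_rmse = float(np.sqrt(np.mean(err**2)))
                if not np.isfinite(batch_rmse):
                    raise RuntimeError(
                        f"NaN/inf loss at epoch {epoch}; training diverged — "
                        "consider a lower learning rate"
                    )
                sq_sum += float(np.sum(err**2))
                if batch_rmse > 0:
                    net.backward(err / (len(idx) * batch_rmse))
                    opt.step(net.gradients())
            train_rmse = float(np.sqrt(sq_sum / n))
            val_rmse = np.nan
            if self._X_val is not None and len(self._X_val):
                val_pred = self._forward_batched(net, self._X_val)
                val_rmse = float(np.sqrt(np.mean((val_pred - self._y_val) ** 2)))
                if val_rmse < best_val:
                    best_val = val_rmse
                    best_params = [p.copy() for p in net.parameters()]
            history.append({"epoch": epoch + 1, "train_rmse": train_rmse, "val_rmse": val_rmse})
            if verbose:
                print(f"epoch {epoch + 1:4d}  train {train_rmse:.5f}  val {val_rmse:.5f}")

        if self._X_val is None or not np.isfinite(best_val):
            best_params = [p.copy() for p in net.parameters()]
        return CNNRegressionResults(
            config=cfg,
            network=net,
            parameters=best_params,
            final_parameters=[p.copy() for p in net.parameters()],
            history=pd.DataFrame(history, columns=["epoch", "train_rmse", "val_rmse"]),
            scaler=self.scaler,
            feature_names=self.feature_names,
            inverse_transform=self._inv,
        )

    @staticmethod
    def _forward_batched(net: NetworkArchitecture, X: np.ndarray, batch: int = 256) -> np.ndarray:
        return np.concatenate(
            [net.forward(X[i : i + batch]) for i in range(0, X.shape[0], batch)]
        )


@dataclass
class CNNRegressionResults:
    """Fitted-model results: checkpoint parameters, history and prediction."""

    config: ModelConfig
    network: NetworkArchitecture
    parameters: list  # best-validation checkpoint
    final_parameters: list
    history: pd.DataFrame
    scaler: _Standardizer
    feature_names: list
    inverse_transform: Callable = field(default=lambda y: y)

    @property
    def schema_hash(self) -> str:
        return _schema_hash(self.feature_names)

    def predict(self, X: np.ndarray, clip: bool | None = None,
                use_checkpoint: bool = True) -> np.ndarray:
        """Predicted percent inhibition for rows of ``X`` (training schema).

        Predictions are inverse-transformed back to the 0-100 scale when a
        target transform was used; clipping to [0, 100] is off by default.
        """
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != len(self.feature_names):
            raise SchemaError(
                f"feature width mismatch: expected {len(self.feature_names)}, "
                f"observed {X.shape[1] if X.ndim == 2 else X.shape}"
            )
        self.network.set_parameters(self.parameters if use_checkpoint else self.final_parameters)
        pred = PercentInhibitionCNN._forward_batched(self.network, self.scaler.transform(X))
        pred = np.asarray(self.inverse_transform(pred), dtype=float)
        if clip if clip is not None else self.config.clip_predictions:
            pred = np.clip(pred, 0.0, 100.0)
        return pred

    def evaluate(self, ds: PairDataset, split: str = "test",
                 tolerance: float = _metrics.DEFAULT_AIR_TOLERANCE) -> _metrics.EvalReport:
        return _metrics.evaluate(self, ds, split=split, tolerance=tolerance)

    def summary(self) -> str:
        """Human-readable architecture and training summary."""
        rep = self.network.architecture_report()
        lines = [
            "Percent-inhibition CNN regression results",
            "=" * 45,
            f"input width:        {rep['input_width']}",
            f"conv layers:        {rep['counts']['conv_layers']}",
            f"pooling layers:     {rep['counts']['pooling_layers']} ({self.config.pool_kind})",
            f"fc layers:          {rep['counts']['fc_layers']} {self.config.fc_sizes}",
            f"parameters:         {rep['n_parameters']:,}",
            f"optimizer:          RMSprop (lr={self.config.learning_rate:g})",
            f"loss:               RMSE, target transform {self.config.target_transform}",
            f"epochs run:         {len(self.history)}",
        ]
        if len(self.history):
            lines.append(f"final train RMSE:   {self.history['train_rmse'].iloc[-1]:.5f}")
            if np.isfinite(self.history["val_rmse"]).any():
                lines.append(f"best val RMSE:      {np.nanmin(self.history['val_rmse']):.5f}")
        return "\n".join(lines)

    # --- persistence -------------------------------------------------------

    def save(self, outdir: str | Path) -> None:
        """Write a checkpoint directory: config, weights, scaler, schema, history."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        (outdir / "config.json").write_text(json.dumps(asdict(self.config), indent=1))
        np.savez_compressed(
            outdir / "weights.npz",
            **{f"p{i}": p for i, p in enumerate(self.parameters)},
        )
        np.savez_compressed(outdir / "scaler.npz", mean=self.scaler.mean, std=self.scaler.std)
        (outdir / "schema.json").write_text(
            json.dumps({"feature_names": list(map(str, self.feature_names)),
                        "hash": self.schema_hash})
        )
        self.history.to_csv(outdir / "history.csv", index=False)

    @classmethod
    def load(cls, indir: str | Path) -> "CNNRegressionResults":
        indir = Path(indir)
        raw = json.loads((indir / "config.json").read_text())
        for key in ("pooling_after", "fc_sizes", "pocket_length_range"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        cfg = ModelConfig(**raw)
        schema = json.loads((indir / "schema.json").read_text())
        weights = np.load(indir / "weights.npz")
        params = [weights[f"p{i}"] for i in range(len(weights.files))]
        scaler_npz = np.load(indir / "scaler.npz")
        scaler = _Standardizer(scaler_npz["mean"], scaler_npz["std"])
        net = build_model(cfg, len(schema["feature_names"]))
        net.set_parameters(params)
        fwd, inv = _target_transform_fns(cfg, None) if cfg.target_transform != "other" else (None, None)
        if inv is None:
            raise ConfigurationError("checkpoints with custom target transforms cannot be reloaded")
        return cls(
            config=cfg,
            network=net,
            parameters=params,
            final_parameters=[p.copy() for p in params],
            history=pd.read_csv(indir / "history.csv"),
            scaler=scaler,
            feature_names=schema["feature_names"],
            inverse_transform=inv,
        )


def train(ds: PairDataset, cfg: ModelConfig | None = None,
          epochs: int | None = None, verbose: bool = False) -> CNNRegressionResults:
    """Functional wrapper: build the model from a split dataset and fit it."""
    return PercentInhibitionCNN(ds, cfg).fit(epochs=epochs, verbose=verbose)
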