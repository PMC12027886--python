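"""The shallow grading CNN, exposed as a scikit-learn estimator.

Architecture (shared by both flavors): two 7x7 valid convolutions with 8
and 16 filters (each followed by batch normalization and ReLU), two 2x2 max
poolings, then three dense layers of 64, 32, and 7 units with a softmax
output — 2 conv + 2 pool + 3 dense.  The input canvas is resized to
72 (tall) x 24 (wide).  Training uses Adam at learning rate 0.001, batch
size 100, cross-entropy loss.

The two flavors differ only in how size information reaches the network:

``without_rgb``
    the baseline — canvases have a black background and the calibrated
    (height, width, area) triplet is concatenated to the flattened
    convolutional features before the dense block; no dropout.

``with_rgb``
    the size triplet is already encoded in the canvas background, so there
    is no numeric side channel; four dropout layers (after each pooling
    stage and after the 64- and 32-unit dense layers) regularize training.

Everything else — filters, kernels, pooling, dense widths, optimizer — is
identical, so a with/without comparison isolates the encoding itself.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from skimage.transform import resize
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from . import nn
from .encode import Canvas, NormRanges, normalize_measures
from .errors import ConfigurationError
from .vision import Measure

VARIANTS = ("with_rgb", "without_rgb")

#: Model input size, (height, width).
INPUT_HW = (72, 24)


@dataclass(frozen=True)
class ModelConfig:
    """Hyperparameters of the grading CNN."""

    variant: str = "with_rgb"
    conv_filters: tuple[int, int] = (8, 16)
    kernel_size: int = 7
    pool_size: int = 2
    dense_units: tuple[int, int, int] = (64, 32, 7)
    dropout_rate: float = 0.1
    conv_dropout_rate: float | None = None  # defaults to dropout_rate
    input_hw: tuple[int, int] = INPUT_HW
    learning_rate: float = 0.001
    batch_size: int = 100
    max_steps: int = 10_000

    def __post_init__(self) -> None:
        if self.variant not in VARIANTS:
            raise ConfigurationError(f"variant must be one of {VARIANTS}")
        if not 0 <= self.dropout_rate < 1:
            raise ConfigurationError("dropout_rate must lie in [0, 1)")


class _GradeNet:
    """Assembled layer stack with an optional scalar side channel."""

    def __init__(self, cfg: ModelConfig, n_classes: int, rng: np.random.Generator):
        h, w = cfg.input_hw
        k = cfg.kernel_size
        conv_rate = (
            cfg.conv_dropout_rate
            if cfg.conv_dropout_rate is not None
            else cfg.dropout_rate
        )
        use_dropout = cfg.variant == "with_rgb"
        self.concat_scalars = cfg.variant == "without_rgb"

        feat: list[nn.Layer] = []
        ch = 3
        for f in cfg.conv_filters:
            feat.append(nn.Conv2D(ch, f, k, rng))
            feat.append(nn.BatchNorm(f))
            feat.append(nn.ReLU())
            feat.append(nn.MaxPool2())
            if use_dropout:
                feat.append(nn.Dropout(conv_rate, rng))
            h, w, ch = (h - k + 1) // 2, (w - k + 1) // 2, f
            if h < 1 or w < 1:
                raise ConfigurationError("input too small for the conv stack")
        feat.append(nn.Flatten())
        feat[0].needs_input_grad = False  # first layer: no image gradient needed
        self.feature_layers = feat

        n_flat = h * w * ch + (3 if self.concat_scalars else 0)
        dense: list[nn.Layer] = []
        widths = list(cfg.dense_units)
        if widths[-1] != n_classes:
            raise ConfigurationError(
                f"output layer has {widths[-1]} units but {n_classes} classes"
            )
        n_in = n_flat
        for i, units in enumerate(widths):
            dense.append(nn.Dense(n_in, units, rng))
            if i < len(widths) - 1:
                dense.append(nn.ReLU())
                if use_dropout:
                    dense.append(nn.Dropout(cfg.dropout_rate, rng))
            n_in = units
        self.dense_layers = dense

    @property
    def layers(self) -> list[nn.Layer]:
        return self.feature_layers + self.dense_layers

    def forward(
        self, x: np.ndarray, scalars: np.ndarray | None, train: bool
    ) -> np.ndarray:
        h = x
        for layer in self.feature_layers:
            h = layer.forward(h, train)
        if self.concat_scalars:
            if scalars is None:
                raise ValueError(
                    "the without_rgb model requires the 3-vector of normalized "
                    "measures alongside each image"
                )
            h = np.concatenate([h, scalars.astype(np.float32)], axis=1)
        self._n_scalars = 3 if self.concat_scalars else 0
        for layer in self.dense_layers:
            h = layer.forward(h, train)
        return h

    def backward(self, grad: np.ndarray) -> None:
        g = grad
        for layer in reversed(self.dense_layers):
            g = layer.backward(g)
        if self._n_scalars:
            g = g[:, : -self._n_scalars]
        for layer in reversed(self.feature_layers):
            g = layer.backward(g)

    def params_and_grads(self) -> tuple[list[np.ndarray], list[np.ndarray]]:
        params: list[np.ndarray] = []
        grads: list[np.ndarray] = []
        for layer in self.layers:
            params.extend(layer.params)
            grads.extend(layer.grads)
        return params, grads


class CucumberGradeCNN(ClassifierMixin, BaseEstimator):
    """Shallow CNN grade classifier with scikit-learn semantics.

    Parameters mirror :class:`ModelConfig`.  ``X`` may be a 4-D image array
    ``(n, 72, 24, 3)`` with values in [0, 1] (pass the numeric side channel
    separately via ``scalars=`` for the ``without_rgb`` variant), or the
    flat 2-D layout produced by :func:`pack_inputs`, in which the last three
    columns carry the scalars when the variant needs them.

    Training runs exactly ``max_steps`` Adam updates on batches of
    ``batch_size`` drawn with replacement; ``max_steps=0`` leaves the
    freshly initialized weights untouched.  With a fixed ``random_state``
    the run is reproducible on the same platform.
    """

    def __init__(
        self,
        variant: str = "with_rgb",
        conv_filters: tuple[int, int] = (8, 16),
        kernel_size: int = 7,
        dense_units: tuple[int, int, int] = (64, 32, 7),
        dropout_rate: float = 0.1,
        conv_dropout_rate: float | None = None,
        input_hw: tuple[int, int] = INPUT_HW,
        learning_rate: float = 0.001,
        batch_size: int = 100,
        max_steps: int = 10_000,
        random_state: int | None = None,
    ):
        self.variant = variant
        self.conv_filters = conv_filters
        self.kernel_size = kernel_size
        self.dense_units = dense_units
        self.dropout_rate = dropout_rate
        self.conv_dropout_rate = conv_dropout_rate
        self.input_hw = input_hw
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.max_steps = max_steps
        self.random_state = random_state

    def _config(self) -> ModelConfig:
        return ModelConfig(
            variant=self.variant,
            conv_filters=tuple(self.conv_filters),
            kernel_size=self.kernel_size,
            dense_units=tuple(self.dense_units),
            dropout_rate=self.dropout_rate,
            conv_dropout_rate=self.conv_dropout_rate,
            input_hw=tuple(self.input_hw),
            learning_rate=self.learning_rate,
            batch_size=self.batch_size,
            max_steps=self.max_steps,
        )

    def _split_X(
        self, X: np.ndarray, scalars: np.ndarray | None
    ) -> tuple[np.ndarray, np.ndarray | None]:
        X = np.asarray(X)
        h, w = self.input_hw
        if X.ndim == 4:
            imgs = X.astype(np.float32)
        elif X.ndim == 2:
            d_img = h * w * 3
            if self.variant == "without_rgb" and X.shape[1] == d_img + 3:
                scalars = X[:, d_img:].astype(np.float32)
                X = X[:, :d_img]
            if X.shape[1] != d_img:
                raise ValueError(
                    f"expected {d_img} flat image features"
                    + (" (+3 scalars)" if self.variant == "without_rgb" else "")
                    + f", got {X.shape[1]}"
                )
            imgs = X.reshape(-1, h, w, 3).astype(np.float32)
        else:
            raise ValueError("X must be 2-D (flat) or 4-D (n, h, w, 3)")
        if imgs.shape[1:3] != (h, w):
            raise ValueError(f"images must be {h}x{w}, got {imgs.shape[1:3]}")
        if self.variant == "without_rgb" and scalars is None:
            raise ValueError(
                "the without_rgb variant requires a (n, 3) scalars array "
                "(append it to flat X or pass scalars=)"
            )
        if scalars is not None:
            scalars = np.asarray(scalars, dtype=np.float32).reshape(len(imgs), 3)
        return imgs, scalars

    def fit(self, X, y, scalars: np.ndarray | None = None):
        y = np.asarray(y)
        self.classes_, y_idx = np.unique(y, return_inverse=True)
        imgs, scal = self._split_X(X, scalars)
        if len(imgs) != len(y_idx):
            raise ValueError("X and y length mismatch")
        cfg = self._config()
        if cfg.dense_units[-1] != len(self.classes_):
            raise ConfigurationError(
                f"dense_units ends in {cfg.dense_units[-1]} but y has "
                f"{len(self.classes_)} classes"
            )
        rng = np.random.default_rng(self.random_state)
        self.net_ = _GradeNet(cfg, len(self.classes_), rng)
        params, grads = self.net_.params_and_grads()
        opt = nn.Adam(params, lr=cfg.learning_rate)
        trace = []
        n = len(imgs)
        for _ in range(int(self.max_steps)):
            idx = rng.integers(0, n, size=cfg.batch_size)
            logits = self.net_.forward(
                imgs[idx], None if scal is None else scal[idx], train=True
            )
            loss, gl = nn.softmax_cross_entropy(logits, y_idx[idx])
            self.net_.backward(gl)
            opt.step(grads)
            trace.append(loss)
        self.loss_trace_ = np.asarray(trace)
        self.n_features_in_ = int(np.prod(imgs.shape[1:])) + (
            3 if self.variant == "without_rgb" else 0
        )
        return self

    def decision_function(self, X, scalars: np.ndarray | None = None) -> np.ndarray:
        check_is_fitted(self, "net_")
        imgs, scal = self._split_X(X, scalars)
        # chunked inference keeps the im2col workspace bounded
        out = []
        for i in range(0, len(imgs), 256):
            out.append(
                self.net_.forward(
                    imgs[i : i + 256],
                    None if scal is None else scal[i : i + 256],
                    train=False,
                )
            )
        return np.concatenate(out, axis=0)

    def predict_proba(self, X, scalars: np.ndarray | None = None) -> np.ndarray:
        return nn.softmax(self.decision_function(X, scalars))

    def predict(self, X, scalars: np.ndarray | None = None) -> np.ndarray:
        proba = self.predict_proba(X, scalars)
        return self.classes_[np.argmax(proba, axis=1)]

    def architecture_summary(self) -> dict:
        """Layer census and shape summary (JSON-serializable).

        Available before fitting: the census is a property of the
        configuration, not of the data.
        """
        cfg = self._config()
        rng = np.random.default_rng(0)
        net = getattr(self, "net_", None) or _GradeNet(
            cfg, cfg.dense_units[-1], rng
        )
        census: dict[str, int] = {}
        for layer in net.layers:
            census[layer.kind] = census.get(layer.kind, 0) + 1
        params, _ = net.params_and_grads()
        return {
            "variant": cfg.variant,
            "layer_census": census,
            "n_conv": census.get("conv", 0),
            "n_pool": census.get("pool", 0),
            "n_dense": census.get("dense", 0),
            "n_dropout": census.get("dropout", 0),
            "input_hw": list(cfg.input_hw),
            "conv_filters": list(cfg.conv_filters),
            "kernel": [cfg.kernel_size, cfg.kernel_size],
            "output_dim": cfg.dense_units[-1],
            "uses_scalar_concat": cfg.variant == "without_rgb",
            "n_params": int(sum(p.size for p in params)),
        }

    def architecture_json(self) -> str:
        return json.dumps(self.architecture_summary(), indent=2, sort_keys=True)


def build_model(cfg: ModelConfig, random_state: int | None = None) -> CucumberGradeCNN:
    """Construct an (unfitted) estimator from a :class:`ModelConfig`."""
    return CucumberGradeCNN(
        variant=cfg.variant,
        conv_filters=cfg.conv_filters,
        kernel_size=cfg.kernel_size,
        dense_units=cfg.dense_units,
        dropout_rate=cfg.dropout_rate,
        conv_dropout_rate=cfg.conv_dropout_rate,
        input_hw=cfg.input_hw,
        learning_rate=cfg.learning_rate,
        batch_size=cfg.batch_size,
        max_steps=cfg.max_steps,
        random_state=random_state,
    )


def prepare_input(
    canvas: Canvas,
    variant: str = "with_rgb",
    measure: Measure | None = None,
    ranges: NormRanges | None = None,
    input_hw: tuple[int, int] = INPUT_HW,
) -> tuple[np.ndarray, np.ndarray | None]:
    """Canvas -> model input: resized to 72x24, intensities in [0, 1].

    For ``without_rgb`` the normalized measure triplet is returned as the
    scalar side channel; the measure is then required.
    """
    if variant not in VARIANTS:
        raise ConfigurationError(f"variant must be one of {VARIANTS}")
    img = resize(
        canvas.pixels.astype(np.float32) / 255.0,
        input_hw,
        order=1,
        anti_aliasing=True,
        preserve_range=True,
    ).astype(np.float32)
    if variant == "without_rgb":
        if measure is None:
            raise ValueError("without_rgb input requires the Measure side channel")
        scal = np.asarray(normalize_measures(measure, ranges), dtype=np.float32)
        return img, scal
    return img, None


def pack_inputs(images: np.ndarray, scalars: np.ndarray | None = None) -> np.ndarray:
    """Flatten images (and optional scalars) into the 2-D sklearn layout."""
    flat = np.asarray(images, dtype=np.float32).reshape(len(images), -1)
    if scalars is None:
        return flat
    return np.concatenate(
        [flat, np.asarray(scalars, dtype=np.float32).reshape(len(flat), 3)], axis=1
    )
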