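"""The CNN-LSTM movement classifier and the load-conditioned two-step decoder.

Architecture (features mode, N selected features): each 210 ms window's
(20, N, 4) feature tensor is split into two 10-sub-window halves, the two
LSTM time steps. Per step, each of the four channel branches applies a
32-filter kernel-3 convolution, a 32-filter kernel-2 convolution (both
length-preserving, ReLU), max-pool 2 and flatten; the branch outputs
concatenate (4 x 5 x 32 = 640) and feed a 50-unit LSTM whose final state
passes dropout (0.6), a 100-unit ReLU dense layer, dropout, and a 6-way
softmax. With N = 7 the model has 155,042 trainable parameters; raw mode
(two 25-sample decimated half-windows per channel) has 331,938.

The two-step decoder first predicts the load level from window RMS, then
routes the feature tensor to the movement model trained under that load
and returns its argmax class:

    y_hat = argmax_y p(y | X; theta_L),   L in {low, medium, high}.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as _signal
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from ._nn import Adam, CnnLstmNet, cross_entropy_loss, softmax
from .features import FeatureSpec, FeatureTensor
from .load_stage import LoadClassifier
from .preprocessing import LargeWindow, WindowingSpec
from .synthetic_data import LOADS, MOVEMENTS

__all__ = [
    "LayerInfo",
    "ModelSpec",
    "build_model",
    "cross_entropy",
    "tensor_to_steps",
    "window_to_raw_steps",
    "CnnLstmClassifier",
    "train_movement",
    "TwoStepClassifier",
    "two_step_predict",
]


@dataclass(frozen=True)
class LayerInfo:
    name: str
    output_shape: tuple
    n_params: int


@dataclass(frozen=True)
class ModelSpec:
    """Declarative CNN-LSTM architecture with closed-form parameter counts.

    ``input_mode`` is "features" (per-step per-channel input (10, N)) or
    "raw" (per-step per-channel input (25, 1)).
    """

    input_mode: str = "features"
    n_features: int = 7
    n_channels: int = 4
    n_steps: int = 2
    step_len: int = 10
    raw_step_len: int = 25
    conv_filters: int = 32
    conv1_kernel: int = 3
    conv2_kernel: int = 2
    pool: int = 2
    lstm_units: int = 50
    dense_units: int = 100
    n_classes: int = 6
    dropout: float = 0.6

    def __post_init__(self):
        if self.input_mode not in ("features", "raw"):
            raise ValueError("input_mode must be 'features' or 'raw'")
        if self.in_len // self.pool < 1:
            raise ValueError("pooled length < 1: input too short for pool size")
        if not 0 <= self.dropout < 1:
            raise ValueError("dropout must lie in [0, 1)")

    @property
    def in_len(self) -> int:
        return self.step_len if self.input_mode == "features" else self.raw_step_len

    @property
    def in_feat(self) -> int:
        return self.n_features if self.input_mode == "features" else 1

    @property
    def pooled_len(self) -> int:
        return self.in_len // self.pool

    @property
    def concat_dim(self) -> int:
        return self.n_channels * self.pooled_len * self.conv_filters

    def layer_table(self) -> list[LayerInfo]:
        """Per-layer output shapes and trainable-parameter counts.

        Conv parameters: kernel x in_channels x filters + filters.
        LSTM: 4 x ((input + units) x units + units), single bias per gate.
        Dense: in x out + out.
        """
        L, F, nf = self.in_len, self.in_feat, self.conv_filters
        conv1_p = self.conv1_kernel * F * nf + nf
        conv2_p = self.conv2_kernel * nf * nf + nf
        rows: list[LayerInfo] = []
        for c in range(self.n_channels):
            rows.append(LayerInfo(f"Conv1D_{c + 1}", (L, nf), conv1_p))
        for c in range(self.n_channels):
            rows.append(LayerInfo(f"Conv1D_{self.n_channels + c + 1}", (L, nf), conv2_p))
        for c in range(self.n_channels):
            rows.append(LayerInfo(f"Maxpooling1D_{c + 1}", (self.pooled_len, nf), 0))
        for c in range(self.n_channels):
            rows.append(LayerInfo(f"Flatten_{c + 1}", (self.pooled_len * nf,), 0))
        rows.append(LayerInfo("Concatenate", (self.concat_dim,), 0))
        H = self.lstm_units
        lstm_p = 4 * ((self.concat_dim + H) * H + H)
        rows.append(LayerInfo("LSTM", (H,), lstm_p))
        rows.append(LayerInfo("Dropout_2", (H,), 0))
        dense1_p = H * self.dense_units + self.dense_units
        rows.append(LayerInfo("Dense_1", (self.dense_units,), dense1_p))
        rows.append(LayerInfo("Dropout_3", (self.dense_units,), 0))
        dense2_p = self.dense_units * self.n_classes + self.n_classes
        rows.append(LayerInfo("Dense_2", (self.n_classes,), dense2_p))
        return rows

    def total_params(self) -> int:
        return sum(r.n_params for r in self.layer_table())

    def to_dict(self) -> dict:
        return {
            "input_mode": self.input_mode,
            "n_features": self.n_features,
            "total_params": self.total_params(),
            "layers": [
                {"name": r.name, "output_shape": list(r.output_shape), "params": r.n_params}
                for r in self.layer_table()
            ],
        }


def cross_entropy(probabilities: np.ndarray, labels, eps: float = 1e-12) -> float:
    """Mean categorical cross-entropy: -(1/N) sum_i log p_{i, y_i}.

    Rows of ``probabilities`` must sum to 1 (tolerance 1e-6); a zero
    probability at the true class is guarded by ``eps``.
    """
    probs = np.asarray(probabilities, dtype=float)
    labels = np.asarray(labels)
    if probs.ndim != 2 or probs.shape[0] != labels.shape[0]:
        raise ValueError("probabilities must be (batch, classes) aligned with labels")
    if not np.allclose(probs.sum(axis=1), 1.0, atol=1e-6):
        raise ValueError("probability rows must sum to 1")
    return cross_entropy_loss(probs, labels, eps=eps)


def tensor_to_steps(t: FeatureTensor | np.ndarray) -> np.ndarray:
    """Split a (20, N, 4) feature tensor into the two LSTM step inputs.

    Returns shape (2, 4, 10, N): step 1 holds sub-windows 1-10, step 2
    sub-windows 11-20, channel-major for the per-channel branches.
    """
    values = t.values if isinstance(t, FeatureTensor) else np.asarray(t, dtype=float)
    if values.ndim != 3 or values.shape[0] % 2 != 0:
        raise ValueError(f"expected (2k, N, C) tensor, got shape {values.shape}")
    if values.shape[0] != 20:
        raise ValueError(f"expected 20 sub-windows, got {values.shape[0]}")
    half = values.shape[0] // 2
    steps = np.stack([values[:half], values[half:]])  # (2, 10, N, C)
    return steps.transpose(0, 3, 1, 2)  # (2, C, 10, N)


def window_to_raw_steps(win: LargeWindow | np.ndarray, step_len: int = 25) -> np.ndarray:
    """Convert a 210-sample window to raw-mode input (2, 4, step_len, 1).

    Each channel's window splits into two halves (the LSTM steps); each
    105-sample half is polyphase-resampled down to ``step_len`` samples.
    """
    data = win.data if isinstance(win, LargeWindow) else np.asarray(win, dtype=float)
    n_ch, n_samp = data.shape
    if n_samp % 2 != 0:
        data = data[:, :-1]
        n_samp -= 1
    half = n_samp // 2
    halves = np.stack([data[:, :half], data[:, half:]])  # (2, C, half)
    from math import gcd

    g = gcd(step_len, half)
    out = _signal.resample_poly(halves, step_len // g, half // g, axis=2)
    return out[..., None]  # (2, C, step_len, 1)


def build_model(spec: ModelSpec = ModelSpec(), **train_kwargs) -> "CnnLstmClassifier":
    """Instantiate an (unfitted) classifier for a model spec.

    The returned estimator exposes the spec's per-layer accounting via
    ``layer_table()`` and ``total_parameters()``.
    """
    return CnnLstmClassifier(spec=spec, **train_kwargs)


class CnnLstmClassifier(ClassifierMixin, BaseEstimator):
    """Seeded CNN-LSTM movement classifier with an sklearn interface.

    ``fit``/``predict`` take stacked feature tensors of shape
    (n, 20, N, 4) in features mode, or raw windows (n, 4, 210) in raw
    mode, with integer movement labels 0-5 (order PF, DF, IV, EV, IR,
    ER). Inputs are standardized per (feature, channel) using training
    statistics before entering the network. Dropout is active only
    during training.
    """

    def __init__(
        self,
        spec: ModelSpec = ModelSpec(),
        epochs: int = 100,
        batch_size: int = 256,
        learning_rate: float = 0.001,
        standardize: bool = True,
        random_state: int = 0,
    ):
        self.spec = spec
        self.epochs = epochs
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.standardize = standardize
        self.random_state = random_state

    # -- accounting ----------------------------------------------------
    def layer_table(self):
        return self.spec.layer_table()

    def total_parameters(self) -> int:
        return self.spec.total_params()

    # -- data plumbing -------------------------------------------------
    def _to_net_input(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if self.spec.input_mode == "features":
            if X.ndim != 4:
                raise ValueError("features mode expects (n, 20, N, C) tensors")
            return np.stack([tensor_to_steps(t) for t in X])
        if X.ndim != 3:
            raise ValueError("raw mode expects (n, C, samples) windows")
        return np.stack(
            [window_to_raw_steps(w, self.spec.raw_step_len) for w in X]
        )

    def _scale(self, Xn: np.ndarray) -> np.ndarray:
        if not self.standardize:
            return Xn
        return (Xn - self.scaler_mean_) / self.scaler_std_

    # -- estimator API -------------------------------------------------
    def fit(self, X, y):
        y = np.asarray(y, dtype=int)
        if len(y) == 0:
            raise ValueError("empty training set")
        if y.min() < 0 or y.max() >= self.spec.n_classes:
            raise ValueError(f"labels must lie in [0, {self.spec.n_classes})")
        Xn = self._to_net_input(X)
        if self.standardize:
            axes = (0, 1)  # pool over samples and steps; keep channel/len/feat
            self.scaler_mean_ = Xn.mean(axis=axes, keepdims=True)[0]
            std = Xn.std(axis=axes, keepdims=True)[0]
            std[std == 0] = 1.0
            self.scaler_std_ = std
        Xn = self._scale(Xn)

        self.net_ = CnnLstmNet(
            in_len=self.spec.in_len,
            in_feat=self.spec.in_feat,
            n_channels=self.spec.n_channels,
            n_steps=self.spec.n_steps,
            conv_filters=self.spec.conv_filters,
            conv1_kernel=self.spec.conv1_kernel,
            conv2_kernel=self.spec.conv2_kernel,
            pool=self.spec.pool,
            lstm_units=self.spec.lstm_units,
            dense_units=self.spec.dense_units,
            n_classes=self.spec.n_classes,
            dropout=self.spec.dropout,
            seed=self.random_state,
        )
        opt = Adam(self.net_.params, lr=self.learning_rate)
        rng = np.random.default_rng(self.random_state)
        n = len(y)
        history = []
        for _ in range(self.epochs):
            order = rng.permutation(n)
            losses = []
            for start in range(0, n, self.batch_size):
                idx = order[start : start + self.batch_size]
                probs, cache = self.net_.forward(Xn[idx], train=True, rng=rng)
                losses.append(cross_entropy_loss(probs, y[idx]))
                grads = self.net_.backward(cache, y[idx])
                opt.step(self.net_.params, grads)
            history.append(float(np.mean(losses)))
        self.history_ = history
        self.classes_ = np.arange(self.spec.n_classes)
        self.n_features_in_ = int(np.prod(Xn.shape[1:]))
        return self

    def predict_proba(self, X):
        check_is_fitted(self, "net_")
        Xn = self._scale(self._to_net_input(X))
        out = []
        for start in range(0, len(Xn), 1024):  # bound peak memory
            probs, _ = self.net_.forward(Xn[start : start + 1024], train=False)
            out.append(probs)
        return np.concatenate(out)

    def predict(self, X):
        return self.predict_proba(X).argmax(axis=1)

    # -- persistence ---------------------------------------------------
    def save(self, directory) -> None:
        """Serialize a fitted model: JSON spec/layer table plus an .npz of
        weights and scaler statistics."""
        import json
        from dataclasses import asdict
        from pathlib import Path

        check_is_fitted(self, "net_")
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        meta = {
            "spec": asdict(self.spec),
            "layer_table": self.spec.to_dict()["layers"],
            "total_params": self.total_parameters(),
            "epochs": self.epochs,
            "batch_size": self.batch_size,
            "learning_rate": self.learning_rate,
            "standardize": self.standardize,
            "random_state": self.random_state,
        }
        (directory / "modelspec.json").write_text(json.dumps(meta, indent=1))
        arrays = {f"param_{k}": v for k, v in self.net_.params.items()}
        if self.standardize:
            arrays["scaler_mean"] = self.scaler_mean_
            arrays["scaler_std"] = self.scaler_std_
        np.savez(directory / "weights.npz", **arrays)

    @classmethod
    def load(cls, directory) -> "CnnLstmClassifier":
        import json
        from pathlib import Path

        directory = Path(directory)
        meta = json.loads((directory / "modelspec.json").read_text())
        model = cls(
            spec=ModelSpec(**meta["spec"]),
            epochs=meta["epochs"],
            batch_size=meta["batch_size"],
            learning_rate=meta["learning_rate"],
            standardize=meta["standardize"],
            random_state=meta["random_state"],
        )
        spec = model.spec
        model.net_ = CnnLstmNet(
            in_len=spec.in_len, in_feat=spec.in_feat, n_channels=spec.n_channels,
            n_steps=spec.n_steps, conv_filters=spec.conv_filters,
            conv1_kernel=spec.conv1_kernel, conv2_kernel=spec.conv2_kernel,
            pool=spec.pool, lstm_units=spec.lstm_units,
            dense_units=spec.dense_units, n_classes=spec.n_classes,
            dropout=spec.dropout, seed=model.random_state,
        )
        with np.load(directory / "weights.npz") as data:
            for k in model.net_.params:
                model.net_.params[k] = data[f"param_{k}"]
            if model.standardize:
                model.scaler_mean_ = data["scaler_mean"]
                model.scaler_std_ = data["scaler_std"]
        model.classes_ = np.arange(spec.n_classes)
        return model


def train_movement(
    model: CnnLstmClassifier, X, y, epochs: int | None = None, seed: int | None = None
) -> CnnLstmClassifier:
    """Fit a movement classifier; returns the fitted estimator (history on
    ``history_``)."""
    if epochs is not None:
        model.set_params(epochs=epochs)
    if seed is not None:
        model.set_params(random_state=seed)
    return model.fit(X, y)


class TwoStepClassifier(BaseEstimator):
    """Load-then-movement decoder.

    Holds the fitted load classifier and one fitted movement model per
    load level. ``predict(X, rms)`` first classifies each window's load
    from its RMS vector, then routes its feature tensor to that load's
    movement model (the load-conditioned argmax rule). Passing
    ``loads=...`` instead of routing by prediction evaluates the decoder
    with oracle load labels.
    """

    def __init__(
        self,
        load_model: LoadClassifier,
        movement_models: dict,
        feature_spec: FeatureSpec = FeatureSpec(),
        windowing: WindowingSpec = WindowingSpec(),
    ):
        missing = [l for l in LOADS if l not in movement_models]
        if missing:
            raise ValueError(f"missing movement model(s) for load(s) {missing}")
        specs = {id(m.spec) for m in movement_models.values()}
        first = next(iter(movement_models.values())).spec
        for m in movement_models.values():
            if m.spec != first:
                raise ValueError("all movement models must share one ModelSpec")
        self.load_model = load_model
        self.movement_models = dict(movement_models)
        self.feature_spec = feature_spec
        self.windowing = windowing

    def predict_load(self, rms: np.ndarray) -> np.ndarray:
        check_is_fitted(self.load_model, "forest_")
        return self.load_model.predict(np.asarray(rms, dtype=float))

    def predict(self, X, rms: np.ndarray | None = None, loads=None) -> np.ndarray:
        if loads is None:
            if rms is None:
                raise ValueError("provide per-window RMS vectors or oracle loads")
            loads = self.predict_load(rms)
        loads = np.asarray(loads)
        X = np.asarray(X, dtype=float)
        if len(loads) != len(X):
            raise ValueError("loads and X length mismatch")
        out = np.empty(len(X), dtype=int)
        for load in np.unique(loads):
            if load not in self.movement_models:
                raise ValueError(f"no movement model for predicted load {load!r}")
            mask = loads == load
            out[mask] = self.movement_models[load].predict(X[mask])
        return out


def two_step_predict(
    clf: TwoStepClassifier,
    win: LargeWindow,
    wspec: WindowingSpec | None = None,
) -> str:
    """Classify one analysis window end to end; returns the movement name.

    The window must carry the filtered (un-normalized) signal so that its
    RMS is informative about the load.
    """
    from .features import extract_tensor
    from .load_stage import window_rms

    wspec = wspec or clf.windowing
    sample = window_rms(win)
    tensor = extract_tensor(win, wspec, clf.feature_spec)
    label = clf.predict(tensor.values[None], rms=sample.rms[None, :])[0]
    return MOVEMENTS[int(label)]
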