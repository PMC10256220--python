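"""Five-layer symmetric deep autoencoder (N -> dim -> dim -> dim -> N).

The three equal-width hidden layers use ReLU and the output layer sigmoid;
training minimizes the mean squared reconstruction error
MSE = (1/NM) * sum_ij (X5_ij - X1_ij)^2 over all genes and samples jointly,
with mini-batch Adam. Latent features are the activations of the *second*
hidden layer (the bottleneck's middle), one non-negative vector per sample.

Implemented directly in numpy with hand-written backpropagation so that a
fixed seed yields bit-identical weights, loss trajectories and latent
matrices across runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .types import ExpressionMatrix

__all__ = [
    "DeepAutoencoder",
    "TrainingReport",
    "LatentMatrix",
    "build_autoencoder",
    "train_autoencoder",
    "encode",
    "reconstruction_mse",
    "sweep_hidden_dims",
]

_ADAM_BETA1, _ADAM_BETA2, _ADAM_EPS = 0.9, 0.999, 1e-8


@dataclass
class TrainingReport:
    """Loss trajectory and hyperparameters of one training run."""

    epoch_mse: list = field(default_factory=list)
    final_mse: float | None = None
    val_mse: float | None = None
    hyperparameters: dict = field(default_factory=dict)


@dataclass
class LatentMatrix:
    """Samples x dim latent features (second hidden layer activations)."""

    sample_ids: list
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != len(self.sample_ids):
            raise ValueError("latent values must be samples x dim")

    @property
    def dim(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values,
            index=self.sample_ids,
            columns=[f"z{j}" for j in range(self.dim)],
        )


def _relu(x: np.ndarray) -> np.ndarray:
    return np.maximum(x, 0.0)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


class DeepAutoencoder(BaseEstimator, TransformerMixin):
    """Sklearn-style estimator for the symmetric deep autoencoder.

    Parameters
    ----------
    hidden_dim : int
        Width of all three hidden layers.
    epochs, batch_size, learning_rate :
        Adam training schedule; defaults follow the reference protocol
        (100 epochs, batch 16, learning rate 1e-3).
    random_state : int
        Seed for weight initialization and per-epoch shuffling.

    Attributes
    ----------
    weights_, biases_ : lists of arrays for layers 2..5.
    loss_curve_ : per-epoch full-data training MSE.
    gene_ids_ : training gene order (set when fitting on ExpressionMatrix
        inputs through :func:`train_autoencoder`).
    """

    def __init__(
        self,
        hidden_dim: int = 64,
        epochs: int = 100,
        batch_size: int = 16,
        learning_rate: float = 1e-3,
        random_state: int = 0,
        shuffle: bool = True,
    ):
        self.hidden_dim = hidden_dim
        self.epochs = epochs
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.random_state = random_state
        self.shuffle = shuffle

    # -- construction ------------------------------------------------------

    def initialize(self, n_genes: int) -> "DeepAutoencoder":
        """Glorot-uniform initial weights from the seed; biases zero."""
        if n_genes < 1 or self.hidden_dim < 1:
            raise ValueError("n_genes and hidden_dim must be positive")
        self._rng = np.random.default_rng(self.random_state)
        d = self.hidden_dim
        sizes = [n_genes, d, d, d, n_genes]
        self.layer_sizes_ = sizes
        self.weights_, self.biases_ = [], []
        for fan_in, fan_out in zip(sizes[:-1], sizes[1:]):
            limit = np.sqrt(6.0 / (fan_in + fan_out))
            self.weights_.append(self._rng.uniform(-limit, limit, size=(fan_in, fan_out)))
            self.biases_.append(np.zeros(fan_out))
        self.n_features_in_ = n_genes
        self.loss_curve_ = []
        self.trained_ = False
        self.gene_ids_ = None
        return self

    @property
    def n_parameters(self) -> int:
        return sum(w.size + b.size for w, b in zip(self.weights_, self.biases_))

    # -- forward pass ------------------------------------------------------

    def _forward(self, X: np.ndarray):
        acts = [X]
        h = X
        for k, (w, b) in enumerate(zip(self.weights_, self.biases_)):
            z = h @ w + b
            h = _sigmoid(z) if k == len(self.weights_) - 1 else _relu(z)
            acts.append(h)
        return acts

    def reconstruct(self, X: np.ndarray) -> np.ndarray:
        return self._forward(np.asarray(X, dtype=float))[-1]

    def transform(self, X) -> np.ndarray:
        """Second-hidden-layer activations (samples x hidden_dim)."""
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.n_features_in_:
            raise ValueError("input width does not match the model's gene count")
        return self._forward(X)[2]

    def mse(self, X) -> float:
        X = np.asarray(X, dtype=float)
        if X.size == 0:
            raise ValueError("cannot compute MSE of an empty matrix")
        return float(np.mean((self.reconstruct(X) - X) ** 2))

    # -- training ----------------------------------------------------------

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be 2-D (samples x genes)")
        if not hasattr(self, "weights_"):
            self.initialize(X.shape[1])
        if X.shape[1] != self.n_features_in_:
            raise ValueError("input width does not match the model's gene count")
        n = X.shape[0]
        adam_m = [np.zeros_like(p) for p in self.weights_ + self.biases_]
        adam_v = [np.zeros_like(p) for p in self.weights_ + self.biases_]
        t = 0
        for _ in range(self.epochs):
            order = self._rng.permutation(n) if self.shuffle else np.arange(n)
            for start in range(0, n, self.batch_size):
                batch = X[order[start : start + self.batch_size]]
                t += 1
                self._adam_step(batch, adam_m, adam_v, t)
            self.loss_curve_.append(self.mse(X))
        self.trained_ = self.epochs > 0 or self.trained_
        return self

    def _adam_step(self, X: np.ndarray, m, v, t: int) -> None:
        acts = self._forward(X)
        b_sz, n_genes = X.shape
        out = acts[-1]
        delta = 2.0 * (out - X) / (b_sz * n_genes) * out * (1.0 - out)
        grads_w, grads_b = [], []
        for k in range(len(self.weights_) - 1, -1, -1):
            grads_w.append(acts[k].T @ delta)
            grads_b.append(delta.sum(axis=0))
            if k > 0:
                delta = (delta @ self.weights_[k].T) * (acts[k] > 0)
        grads = grads_w[::-1] + grads_b[::-1]
        params = self.weights_ + self.biases_
        lr = self.learning_rate
        for i, (p, g) in enumerate(zip(params, grads)):
            m[i] = _ADAM_BETA1 * m[i] + (1 - _ADAM_BETA1) * g
            v[i] = _ADAM_BETA2 * v[i] + (1 - _ADAM_BETA2) * g * g
            m_hat = m[i] / (1 - _ADAM_BETA1**t)
            v_hat = v[i] / (1 - _ADAM_BETA2**t)
            p -= lr * m_hat / (np.sqrt(v_hat) + _ADAM_EPS)


# -- functional surface ----------------------------------------------------


def build_autoencoder(n_genes: int, hidden_dim: int, seed: int) -> DeepAutoencoder:
    """Untrained N -> dim -> dim -> dim -> N model, deterministically
    initialized from ``seed``."""
    model = DeepAutoencoder(hidden_dim=hidden_dim, random_state=seed)
    model.initialize(n_genes)
    return model


def _check_minmax_input(model: DeepAutoencoder, X: ExpressionMatrix) -> np.ndarray:
    if X.scale_tag != "minmax":
        raise ValueError("autoencoder inputs must be min-max renormalized")
    if X.n_genes != model.n_features_in_:
        raise ValueError(
            f"matrix has {X.n_genes} genes but model expects {model.n_features_in_}"
        )
    if model.gene_ids_ is not None and X.gene_ids != model.gene_ids_:
        raise KeyError("gene order differs from the model's training order")
    return X.samples_by_genes()


def train_autoencoder(
    model: DeepAutoencoder,
    X: ExpressionMatrix,
    epochs: int | None = None,
    batch_size: int | None = None,
    learning_rate: float | None = None,
) -> TrainingReport:
    """Train in place on a min-max-scaled cohort; returns the loss report."""
    if epochs is not None:
        model.epochs = epochs
    if batch_size is not None:
        model.batch_size = batch_size
    if learning_rate is not None:
        model.learning_rate = learning_rate
    data = _check_minmax_input(model, X)
    model.gene_ids_ = X.gene_ids
    before = len(model.loss_curve_)
    model.fit(data)
    curve = model.loss_curve_[before:]
    return TrainingReport(
        epoch_mse=list(curve),
        final_mse=curve[-1] if curve else None,
        hyperparameters={
            "epochs": model.epochs,
            "batch_size": model.batch_size,
            "learning_rate": model.learning_rate,
            "optimizer": "adam",
            "seed": model.random_state,
        },
    )


def encode(model: DeepAutoencoder, X: ExpressionMatrix) -> LatentMatrix:
    """Latent features from the second hidden layer; entries are >= 0."""
    data = _check_minmax_input(model, X)
    return LatentMatrix(X.sample_ids, model.transform(data))


def reconstruction_mse(model: DeepAutoencoder, X: ExpressionMatrix) -> float:
    """Eq-style MSE over all N*M entries of the reconstruction error."""
    data = _check_minmax_input(model, X)
    return model.mse(data)


def sweep_hidden_dims(
    train: ExpressionMatrix,
    val: ExpressionMatrix,
    dims: list,
    seed: int,
    epochs: int = 100,
    batch_size: int = 16,
    learning_rate: float = 1e-3,
) -> pd.DataFrame:
    """Train one autoencoder per hidden width; tabulate train/val MSE.

    The validation-MSE minimum marks the elbow; widths up to and including
    it are flagged ``candidate`` (larger widths start overfitting). Returns
    a DataFrame with columns dim, train_mse, val_mse, candidate, and the
    trained models in ``df.attrs["models"]``.
    """
    if not dims:
        raise ValueError("dims list must be non-empty")
    rows, models = [], {}
    for dim in dims:
        model = DeepAutoencoder(
            hidden_dim=dim,
            epochs=epochs,
            batch_size=batch_size,
            learning_rate=learning_rate,
            random_state=seed,
        )
        model.initialize(train.n_genes)
        train_autoencoder(model, train)
        rows.append(
            {
                "dim": dim,
                "train_mse": reconstruction_mse(model, train),
                "val_mse": reconstruction_mse(model, val),
            }
        )
        models[dim] = model
    df = pd.DataFrame(rows)
    elbow = int(df["val_mse"].idxmin())
    df["candidate"] = df.index <= elbow
    df.attrs["models"] = models
    return df
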