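"""Scikit-learn style estimator wrapping the transformer and its recipe.

:class:`TransformerSequenceClassifier` is the package's main entry point:
``fit(X, y)`` on windows ``X`` of shape (n, T, C) with labels per window
(shape ``(n,)``) or per timestep (``(n, T)``), then ``predict`` returns a
per-timestep label track for every window. It composes with sklearn model
selection (``get_params``/``set_params``/``clone``); ``score`` is
per-timestep accuracy.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from .model import (
    HARTransformerParams,
    ModelConfig,
    fit_normalizer,
    forward,
    init_params,
)
from .training import TrainConfig, TrainState, per_timestep_accuracy, train

__all__ = ["TransformerSequenceClassifier"]


class TransformerSequenceClassifier(ClassifierMixin, BaseEstimator):
    """Per-timestep activity classifier built on a pre-norm transformer
    encoder with learned position embeddings.

    Parameters mirror the model and training recipe defaults (embedding
    size 128, feed-forward 256, 6 heads, 3 layers, dropout 0.1; 50 epochs,
    batch 64, peak lr 1e-3 after 10 warmup steps with cosine decay, global
    clipnorm 3.0, label smoothing 0.1). For desk-scale experiments pass a
    smaller architecture.

    Attributes set by :meth:`fit`
    -----------------------------
    classes_ : original class labels in sorted order
    params_ : trained :class:`HARTransformerParams` (best validation epoch)
    train_state_ : :class:`TrainState` with per-epoch history
    best_validation_accuracy_ : best per-timestep validation accuracy
    """

    def __init__(
        self,
        d_model: int = 128,
        d_ff: int = 256,
        n_heads: int = 6,
        n_layers: int = 3,
        dropout_rate: float = 0.1,
        attention_dropout_rate: float = 0.1,
        activation: str = "gelu",
        epochs: int = 50,
        batch_size: int = 64,
        max_lr: float = 1e-3,
        warmup_steps: int = 10,
        global_clipnorm: float = 3.0,
        label_smoothing: float = 0.1,
        validation_fraction: float = 0.15,
        normalizer_epsilon: float = 1e-6,
        random_state: int = 0,
    ):
        self.d_model = d_model
        self.d_ff = d_ff
        self.n_heads = n_heads
        self.n_layers = n_layers
        self.dropout_rate = dropout_rate
        self.attention_dropout_rate = attention_dropout_rate
        self.activation = activation
        self.epochs = epochs
        self.batch_size = batch_size
        self.max_lr = max_lr
        self.warmup_steps = warmup_steps
        self.global_clipnorm = global_clipnorm
        self.label_smoothing = label_smoothing
        self.validation_fraction = validation_fraction
        self.normalizer_epsilon = normalizer_epsilon
        self.random_state = random_state

    # -- helpers ---------------------------------------------------------

    def _validate_xy(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 3:
            raise ValueError(
                f"X must have shape (n_windows, T, C); got {X.shape}"
            )
        if not np.all(np.isfinite(X)):
            raise ValueError("X contains non-finite values")
        if y is None:
            return X, None
        y = np.asarray(y)
        if y.ndim == 1:
            y = np.repeat(y[:, None], X.shape[1], axis=1)
        if y.shape != X.shape[:2]:
            raise ValueError(
                f"y must have shape (n,) or (n, T)={X.shape[:2]}; got {y.shape}"
            )
        return X, y

    # -- sklearn API -----------------------------------------------------

    def fit(self, X, y, validation_data=None):
        """Train on windows ``X`` (n, T, C) and labels ``y`` (n,) or (n, T).

        Without explicit ``validation_data`` a stratified
        ``validation_fraction`` of the windows (keyed by first/last label)
        is held out for best-epoch selection.
        """
        X, y = self._validate_xy(X, y)
        if len(X) == 0:
            raise ValueError("cannot fit on an empty dataset")
        self.classes_, y_enc = np.unique(y, return_inverse=True)
        y_enc = y_enc.reshape(y.shape)

        config = ModelConfig(
            n_steps=X.shape[1],
            n_channels=X.shape[2],
            n_classes=len(self.classes_),
            d_model=self.d_model,
            d_ff=self.d_ff,
            n_heads=self.n_heads,
            n_layers=self.n_layers,
            dropout_rate=self.dropout_rate,
            attention_dropout_rate=self.attention_dropout_rate,
            activation=self.activation,
        )

        if validation_data is not None:
            x_val, y_val = self._validate_xy(*validation_data)
            lookup = {c: i for i, c in enumerate(self.classes_)}
            y_val = np.vectorize(lookup.__getitem__)(y_val)
            x_train, y_train = X, y_enc
        else:
            x_train, y_train, x_val, y_val = self._holdout_split(X, y_enc)

        params = init_params(config, seed=self.random_state)
        params.normalizer = fit_normalizer(x_train, epsilon=self.normalizer_epsilon)
        train_cfg = TrainConfig(
            epochs=self.epochs,
            batch_size=self.batch_size,
            max_lr=self.max_lr,
            warmup_steps=self.warmup_steps,
            global_clipnorm=self.global_clipnorm,
            label_smoothing=self.label_smoothing,
            seed=self.random_state,
        )
        self.params_, self.train_state_ = train(
            params, (x_train, y_train), (x_val, y_val), train_cfg
        )
        self.best_validation_accuracy_ = self.train_state_.best_validation_accuracy
        self.model_config_ = config
        self.n_features_in_ = X.shape[2]
        return self

    def _holdout_split(self, X, y_enc):
        frac = self.validation_fraction
        if not 0.0 < frac < 1.0:
            raise ValueError("validation_fraction must be in (0, 1)")
        strata: dict[tuple[int, int], list[int]] = {}
        for i in range(len(X)):
            strata.setdefault((int(y_enc[i, 0]), int(y_enc[i, -1])), []).append(i)
        rng = np.random.default_rng(self.random_state)
        val_idx: list[int] = []
        for key in sorted(strata):
            members = np.array(strata[key])
            rng.shuffle(members)
            n_val = max(1, int(round(len(members) * frac))) if len(members) > 1 else 0
            val_idx.extend(members[:n_val].tolist())
        val_mask = np.zeros(len(X), dtype=bool)
        val_mask[val_idx] = True
        if not val_mask.any() or val_mask.all():
            raise ValueError("validation split produced an empty partition")
        return X[~val_mask], y_enc[~val_mask], X[val_mask], y_enc[val_mask]

    def decision_function(self, X):
        """Raw per-timestep logits, shape (n, T, K)."""
        check_is_fitted(self, "params_")
        X, _ = self._validate_xy(X)
        return forward(X, self.params_, training=False)

    def predict(self, X):
        """Per-timestep labels, shape (n, T), in the original label space."""
        logits = self.decision_function(X)
        return self.classes_[logits.argmax(axis=-1)]

    def predict_windows(self, X):
        """One label per window by majority vote over timesteps."""
        tracks = self.predict(X)
        idx = np.stack(
            [(tracks == c).sum(axis=1) for c in self.classes_], axis=1
        ).argmax(axis=1)
        return self.classes_[idx]

    def score(self, X, y):
        """Per-timestep accuracy against window or per-timestep labels."""
        X, y = self._validate_xy(X, y)
        tracks = self.predict(X)
        return float((tracks == y).mean())

    def attention_records(self, window):
        """Per-layer/per-head attention matrices for one window."""
        check_is_fitted(self, "params_")
        _, records = forward(
            np.asarray(window, dtype=float),
            self.params_,
            training=False,
            return_attention=True,
        )
        return records

    def __sklearn_tags__(self):
        tags = super().__sklearn_tags__()
        tags.input_tags.three_d_array = True
        tags.target_tags.single_output = False
        return tags
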