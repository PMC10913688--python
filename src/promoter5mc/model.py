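"""Scikit-learn estimator facade over the network, trainer and encoders.

``CbamDenseGruClassifier`` accepts either raw sequences (strings,
:class:`~promoter5mc.seqio.DnaSequence` objects or a
:class:`~promoter5mc.seqio.LabeledDataset`) or pre-encoded feature arrays of
shape (n, rows, length), and composes with sklearn pipelines and model
selection (clone, get_params/set_params, fit/predict/predict_proba).
"""

from __future__ import annotations

import numbers

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from .encode import encode_sequences
from .nn import ModelConfig, build_model
from .seqio import LabeledDataset
from .train import ClassWeights, TrainSpec, compute_class_weights, fit as _fit

__all__ = ["CbamDenseGruClassifier"]


class CbamDenseGruClassifier(ClassifierMixin, BaseEstimator):
    """Promoter 5mC site classifier.

    A CBAM-augmented densely connected convolutional trunk over the merged
    one-hot + chemical-property encoding, read out through a bidirectional
    GRU and self-attention, trained with class-weighted cross-entropy.

    Parameters mirror :class:`~promoter5mc.nn.ModelConfig` and
    :class:`~promoter5mc.train.TrainSpec`. ``class_weight`` may be
    ``"balanced"`` (w_pos = n_neg/n_pos computed from the training data),
    ``None`` (unweighted) or a positive number used as w_pos directly.

    Attributes (after fit)
    ----------------------
    model_ : the trained network
    config_ : the resolved ModelConfig
    class_weights_ : the ClassWeights used (or None)
    history_ : per-epoch loss history
    classes_ : ndarray [0, 1]
    """

    def __init__(self, num_dense_blocks: int = 4, layers_per_block: int = 2,
                 growth_rate: int = 8, compression: float = 0.5,
                 cbam_reduction: int = 4, spatial_kernel: int = 3,
                 gru_hidden: int = 24, attention_dim: int = 24,
                 dropout: float = 0.1, window_length: int = 41,
                 use_cbam: bool = True, attn_scale: bool = True,
                 epochs: int = 5, batch_size: int = 128,
                 learning_rate: float = 1e-3, patience: int = 5,
                 class_weight: str | float | None = "balanced",
                 threshold: float = 0.5, random_state: int = 0):
        self.num_dense_blocks = num_dense_blocks
        self.layers_per_block = layers_per_block
        self.growth_rate = growth_rate
        self.compression = compression
        self.cbam_reduction = cbam_reduction
        self.spatial_kernel = spatial_kernel
        self.gru_hidden = gru_hidden
        self.attention_dim = attention_dim
        self.dropout = dropout
        self.window_length = window_length
        self.use_cbam = use_cbam
        self.attn_scale = attn_scale
        self.epochs = epochs
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.patience = patience
        self.class_weight = class_weight
        self.threshold = threshold
        self.random_state = random_state

    # -- input handling -----------------------------------------------------
    def _encode(self, X) -> np.ndarray:
        if isinstance(X, np.ndarray) and X.ndim == 3:
            return np.asarray(X, dtype=float)
        if isinstance(X, LabeledDataset) or (len(X) and not isinstance(X[0], numbers.Number)):
            return encode_sequences(X, scheme="merged")
        raise ValueError("X must be sequences or an (n, rows, length) array")

    def _config(self) -> ModelConfig:
        return ModelConfig(
            num_dense_blocks=self.num_dense_blocks,
            layers_per_block=self.layers_per_block,
            growth_rate=self.growth_rate,
            compression=self.compression,
            cbam_reduction=self.cbam_reduction,
            spatial_kernel=self.spatial_kernel,
            gru_hidden=self.gru_hidden,
            attention_dim=self.attention_dim,
            dropout=self.dropout,
            window_length=self.window_length,
            use_cbam=self.use_cbam,
            attn_scale=self.attn_scale,
            seed=self.random_state,
        )

    def _weights(self, y: np.ndarray) -> ClassWeights | None:
        if self.class_weight is None:
            return None
        if self.class_weight == "balanced":
            return compute_class_weights(int((y == 1).sum()), int((y == 0).sum()))
        if isinstance(self.class_weight, numbers.Number):
            return ClassWeights(w_pos=float(self.class_weight), w_neg=1.0)
        raise ValueError(f"unsupported class_weight {self.class_weight!r}")

    # -- sklearn API --------------------------------------------------------
    def fit(self, X, y=None, X_val=None, y_val=None):
        if y is None:
            if not isinstance(X, LabeledDataset):
                raise ValueError("y is required unless X is a LabeledDataset")
            y = X.labels()
        y = np.asarray(y, dtype=int)
        if set(np.unique(y)) - {0, 1}:
            raise ValueError("labels must be binary 0/1")
        enc = self._encode(X)
        if enc.shape[0] != y.shape[0]:
            raise ValueError("X and y disagree in length")
        config = self._config().replace(input_rows=enc.shape[1],
                                        window_length=enc.shape[2])
        self.config_ = config
        self.model_ = build_model(config)
        spec = TrainSpec(epochs=self.epochs, batch_size=self.batch_size,
                         learning_rate=self.learning_rate, patience=self.patience,
                         seed=self.random_state)
        self.class_weights_ = self._weights(y)
        enc_val = self._encode(X_val) if X_val is not None else None
        self.history_ = _fit(self.model_, enc, y, spec, self.class_weights_,
                             x_val=enc_val, y_val=y_val)
        self.classes_ = np.array([0, 1])
        self.n_features_in_ = enc.shape[1] * enc.shape[2]
        return self

    def predict_proba(self, X) -> np.ndarray:
        check_is_fitted(self, "model_")
        scores = self.model_.predict_scores(self._encode(X))
        return np.column_stack([1.0 - scores, scores])

    def decision_function(self, X) -> np.ndarray:
        return self.predict_proba(X)[:, 1]

    def predict(self, X) -> np.ndarray:
        return (self.predict_proba(X)[:, 1] >= self.threshold).astype(int)
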