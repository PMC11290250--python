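"""Scikit-learn style estimator facade.

``AMSNetClassifier`` wraps model construction and the training protocol in
the familiar fit/predict interface so the network composes with sklearn
pipelines and model selection.  ``X`` is a stack of square grayscale images
shaped ``(n_samples, side, side)`` with values in [0, 1].
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.model_selection import train_test_split

from .backbone import AMSNet, ModelConfig
from .nn.losses import softmax
from .training import TrainConfig, fit_arrays

__all__ = ["AMSNetClassifier"]


class AMSNetClassifier(BaseEstimator, ClassifierMixin):
    """Attention-enhanced multi-scale residual network classifier.

    Parameters mirror the architecture/ablation flags and the training
    protocol; fitted attributes carry the trained network (``model_``),
    its training history (``history_``) and the class labels (``classes_``).
    A stratified fraction of the training data is held out internally as
    the validation set that drives checkpoint selection.
    """

    def __init__(self, use_mvggc: bool = True, use_adcp: bool = True,
                 use_se: bool = True, depth: int = 18,
                 stage_channels: tuple = (64, 128, 256, 512),
                 se_reduction: int = 16, batch_size: int = 4,
                 learning_rate: float = 1e-4, min_epochs: int = 50,
                 max_epochs: int = 200, validation_fraction: float = 0.2,
                 class_weights="auto", random_state: int = 0):
        self.use_mvggc = use_mvggc
        self.use_adcp = use_adcp
        self.use_se = use_se
        self.depth = depth
        self.stage_channels = stage_channels
        self.se_reduction = se_reduction
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.min_epochs = min_epochs
        self.max_epochs = max_epochs
        self.validation_fraction = validation_fraction
        self.class_weights = class_weights
        self.random_state = random_state

    def _check_x(self, x):
        x = np.asarray(x, dtype=np.float64)
        if x.ndim != 3 or x.shape[1] != x.shape[2]:
            raise ValueError(
                "X must be (n_samples, side, side) grayscale images")
        return x

    def fit(self, X, y):
        x = self._check_x(X)
        y = np.asarray(y)
        self.classes_, y_idx = np.unique(y, return_inverse=True)
        if len(self.classes_) != 2:
            raise ValueError("binary classification requires 2 classes")
        cfg = ModelConfig(
            use_mvggc=self.use_mvggc, use_adcp=self.use_adcp,
            use_se=self.use_se, backbone_depth=self.depth,
            stage_channels=tuple(self.stage_channels),
            se_reduction=self.se_reduction, num_classes=2,
            input_side=x.shape[1], seed=self.random_state)
        tcfg = TrainConfig(
            batch_size=self.batch_size, initial_lr=self.learning_rate,
            min_epochs=self.min_epochs, max_epochs=self.max_epochs,
            class_weights=self.class_weights, seed=self.random_state)
        x_tr, x_va, y_tr, y_va = train_test_split(
            x, y_idx, test_size=self.validation_fraction,
            stratify=y_idx, random_state=self.random_state)
        self.model_ = AMSNet(cfg)
        self.model_, self.history_ = fit_arrays(
            self.model_, x_tr, y_tr, x_va, y_va, tcfg)
        return self

    def decision_function(self, X):
        x = self._check_x(X)
        logits = []
        for i in range(0, len(x), 16):
            logits.append(self.model_.predict_logits(x[i:i + 16]))
        return np.concatenate(logits)

    def predict_proba(self, X):
        return softmax(self.decision_function(X), axis=1)

    def predict(self, X):
        return self.classes_[self.decision_function(X).argmax(axis=1)]
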