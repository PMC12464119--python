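"""Scikit-learn style estimator facade over the segmentation pipeline.

:class:`OralSegSegmenter` wraps network construction, the training protocol
and sliding-window inference behind the familiar ``fit`` / ``predict`` /
``score`` surface, so the segmenter composes with scikit-learn model
selection utilities.  Samples are whole cases: ``X`` is a list of
:class:`~oralseg.volume_io.Volume` and ``y`` a list of aligned
:class:`~oralseg.volume_io.LabelVolume`.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator

from .inference import InferenceConfig, predict_volume
from .label_scheme import default_scheme
from .metrics import EvaluationPolicy, evaluate_case
from .model import ModelConfig, build_model
from .training import TrainConfig, fit
from .transforms import AugmentConfig
from .volume_io import LabelVolume, Volume

__all__ = ["OralSegSegmenter"]


class OralSegSegmenter(BaseEstimator):
    """Tooth-level instance segmenter with a scikit-learn interface.

    Parameters mirror :class:`ModelConfig` and :class:`TrainConfig`; fitted
    state lives in trailing-underscore attributes (``model_``, ``curves_``).
    """

    def __init__(self, embed_size: int = 48, feature_dim: int = 8,
                 attention_window: tuple = (7, 7, 7), smamba_state_dim: int = 16,
                 ablation: str = "full", num_classes: int = 37,
                 lr: float = 1e-5, epochs: int = 50,
                 patch: tuple = (64, 64, 64), warmup_epochs: int | None = None,
                 overlap: float = 0.5, blend: str = "gaussian",
                 target_spacing: float | None = 0.3,
                 augment: bool = False, random_state: int = 0):
        self.embed_size = embed_size
        self.feature_dim = feature_dim
        self.attention_window = attention_window
        self.smamba_state_dim = smamba_state_dim
        self.ablation = ablation
        self.num_classes = num_classes
        self.lr = lr
        self.epochs = epochs
        self.patch = patch
        self.warmup_epochs = warmup_epochs
        self.overlap = overlap
        self.blend = blend
        self.target_spacing = target_spacing
        self.augment = augment
        self.random_state = random_state

    # ------------------------------------------------------------------
    def _model_config(self) -> ModelConfig:
        return ModelConfig(embed_size=self.embed_size,
                           feature_dim=self.feature_dim,
                           attention_window=tuple(self.attention_window),
                           smamba_state_dim=self.smamba_state_dim,
                           ablation=self.ablation,
                           num_classes=self.num_classes)

    def _train_config(self) -> TrainConfig:
        aug = AugmentConfig(seed=self.random_state) if self.augment else None
        return TrainConfig(lr=self.lr, epochs=self.epochs,
                           patch=tuple(self.patch),
                           warmup_epochs=self.warmup_epochs,
                           seed=self.random_state, augment=aug,
                           val_every=max(1, self.epochs // 10))

    def _inference_config(self) -> InferenceConfig:
        return InferenceConfig(window=tuple(self.patch), overlap=self.overlap,
                               blend=self.blend,
                               target_spacing=self.target_spacing)

    # ------------------------------------------------------------------
    def fit(self, X: list[Volume], y: list[LabelVolume],
            X_val=None, y_val=None) -> "OralSegSegmenter":
        if len(X) != len(y):
            raise ValueError("X and y must have equal length")
        for v, lv in zip(X, y):
            if v.shape != lv.shape:
                raise ValueError("image/label grids must match")
        self.model_ = build_model(self._model_config(), seed=self.random_state)
        cohort = list(zip(X, y))
        val = list(zip(X_val, y_val)) if X_val is not None else None
        result = fit(self.model_, cohort, self._train_config(), val_cohort=val)
        self.model_.load_state_dict(result.best_state)
        self.curves_ = result.curves
        self.best_epoch_ = result.best_epoch
        self.scheme_ = default_scheme()
        self.n_parameters_ = self.model_.n_parameters()
        return self

    def predict(self, X: list[Volume]) -> list[LabelVolume]:
        self._check_fitted()
        cfg = self._inference_config()
        return [predict_volume(v, self.model_, cfg) for v in X]

    def score(self, X: list[Volume], y: list[LabelVolume]) -> float:
        """Mean foreground macro-Dice across cases."""
        self._check_fitted()
        preds = self.predict(X)
        dices = []
        for pred, gt in zip(preds, y):
            report, _ = evaluate_case(pred, gt, self.scheme_,
                                      EvaluationPolicy())
            dices.append(report.macro["mDice"])
        return float(np.mean(dices))

    def _check_fitted(self):
        if not hasattr(self, "model_"):
            raise RuntimeError("estimator is not fitted; call fit() first")
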