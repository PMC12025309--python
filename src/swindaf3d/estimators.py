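"""scikit-learn style estimators wrapping the segmentation networks.

``SwinDAF3DSegmenter`` and ``UNet3DSegmenter`` follow the fit/predict
contract — hyperparameters in ``__init__`` (so ``get_params``/``set_params``
and :func:`sklearn.base.clone` work), learned state in trailing-underscore
attributes — and compose with sklearn model selection.  ``X`` is a sequence
of 3D volumes in [0, 1]; ``y`` the matching binary masks.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator

from .encoder import EncoderConfig
from .head import HeadConfig
from .metrics import dice_score
from .model import ModelConfig, SwinDAF3D
from .pipeline import TrainConfig, train
from .unet3d import UNet3D
from .volume_io import Case, LabelMask, Volume, normalize_intensity


def _to_cases(X, y, prefix="case") -> list[Case]:
    if len(X) != len(y):
        raise ValueError(f"got {len(X)} volumes but {len(y)} masks")
    cases = []
    for i, (vol, mask) in enumerate(zip(X, y)):
        vol = np.asarray(vol, dtype=np.float32)
        if vol.ndim != 3:
            raise ValueError(f"volume {i} must be 3D, got shape {vol.shape}")
        if vol.min() < 0 or vol.max() > 1:
            vol = normalize_intensity(Volume(vol)).data
        cases.append(Case(id=f"{prefix}_{i:04d}", volume=Volume(vol),
                          mask=LabelMask(np.asarray(mask))))
    return cases


class _BaseSegmenter(BaseEstimator):
    """Shared fit/predict plumbing; subclasses build the network."""

    def _build(self):  # pragma: no cover - abstract
        raise NotImplementedError

    def _train_config(self) -> TrainConfig:
        return TrainConfig(lr=self.lr, weight_decay=self.weight_decay,
                           epochs=self.epochs, batch_size=self.batch_size,
                           seed=self.seed, threshold=self.threshold,
                           max_steps=self.max_steps, eval_every=self.eval_every,
                           stop_at_val_dsc=self.stop_at_val_dsc,
                           verbose=self.verbose)

    def fit(self, X, y, X_val=None, y_val=None):
        """Train on (X, y); validation defaults to the training set."""
        cases = _to_cases(X, y)
        if X_val is not None:
            val_cases = _to_cases(X_val, y_val, prefix="val")
        else:
            val_cases = cases
        self.model_ = self._build()
        record = train(self.model_, cases, val_cases, self._train_config())
        self.history_ = record.epochs
        self.best_val_dsc_ = record.best_val_dsc
        self.n_iter_ = record.steps
        return self

    def _check_fitted(self):
        if not hasattr(self, "model_"):
            raise RuntimeError("estimator is not fitted; call fit first")

    def predict_proba(self, X):
        self._check_fitted()
        return [self.model_.predict_proba(np.asarray(v, dtype=np.float32)) for v in X]

    def predict(self, X):
        self._check_fitted()
        return [(p > self.threshold).astype(np.uint8) for p in self.predict_proba(X)]

    def score(self, X, y):
        """Mean Dice of binarised predictions."""
        preds = self.predict(X)
        return float(np.mean([dice_score(p, np.asarray(m)) for p, m in zip(preds, y)]))


class SwinDAF3DSegmenter(_BaseSegmenter):
    """Shifted-window transformer pyramid + deep attentive fusion segmenter.

    Defaults follow the clinical-scale protocol (feature size 48, window 7,
    Adam lr 1e-4 / weight decay 1e-4, 50 epochs, batch 1); desk-scale
    experiments shrink ``embed_dim``/``window``/``lateral_channels``.
    """

    def __init__(self, embed_dim=48, window=7, depths=(2, 2, 2, 2),
                 heads=(3, 6, 12, 24), use_relative_bias=True,
                 lateral_channels=64, aspp_rates=(1, 2, 3, 4), groupnorm_groups=8,
                 lr=1e-4, weight_decay=1e-4, epochs=50, batch_size=1,
                 max_steps=None, eval_every=1, stop_at_val_dsc=None,
                 threshold=0.5, seed=0, verbose=False):
        self.embed_dim = embed_dim
        self.window = window
        self.depths = depths
        self.heads = heads
        self.use_relative_bias = use_relative_bias
        self.lateral_channels = lateral_channels
        self.aspp_rates = aspp_rates
        self.groupnorm_groups = groupnorm_groups
        self.lr = lr
        self.weight_decay = weight_decay
        self.epochs = epochs
        self.batch_size = batch_size
        self.max_steps = max_steps
        self.eval_every = eval_every
        self.stop_at_val_dsc = stop_at_val_dsc
        self.threshold = threshold
        self.seed = seed
        self.verbose = verbose

    def _build(self) -> SwinDAF3D:
        cfg = ModelConfig(
            encoder=EncoderConfig(embed_dim=self.embed_dim, window=self.window,
                                  depths=tuple(self.depths), heads=tuple(self.heads),
                                  use_relative_bias=self.use_relative_bias),
            head=HeadConfig(lateral_channels=self.lateral_channels,
                            aspp_rates=tuple(self.aspp_rates),
                            groupnorm_groups=self.groupnorm_groups),
            seed=self.seed)
        return SwinDAF3D(cfg)


class UNet3DSegmenter(_BaseSegmenter):
    """Classic 3D UNet baseline with the same estimator surface."""

    def __init__(self, base_width=32, lr=1e-4, weight_decay=1e-4, epochs=50,
                 batch_size=1, max_steps=None, eval_every=1, stop_at_val_dsc=None,
                 threshold=0.5, seed=0, verbose=False):
        self.base_width = base_width
        self.lr = lr
        self.weight_decay = weight_decay
        self.epochs = epochs
        self.batch_size = batch_size
        self.max_steps = max_steps
        self.eval_every = eval_every
        self.stop_at_val_dsc = stop_at_val_dsc
        self.threshold = threshold
        self.seed = seed
        self.verbose = verbose

    def _build(self) -> UNet3D:
        return UNet3D(base_width=self.base_width, seed=self.seed)
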