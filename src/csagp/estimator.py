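"""Scikit-learn-style estimator wrapping the dual-branch network.

``CsAGPClassifier`` exposes the whole pipeline — tokenization, per-branch
encoders, cross-attention fusion, graph pooling, training loop — behind
``fit`` / ``predict`` / ``predict_proba`` so it composes with sklearn
model selection and pipelines.  Defaults follow the reference
configuration (K=3, M=1, N=3, r=0.5, 224x224 input, Adam lr 1e-5, weight
decay 5e-4, batch 128, 300 epochs); desk-scale experiments should pass
smaller settings explicitly.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from .config import ModelConfig, TrainConfig
from .model import CsAGPNet
from .train import fit_model
from .types import ImagePair

__all__ = ["CsAGPClassifier"]


def _as_pairs(X, y=None) -> tuple[list[ImagePair], np.ndarray]:
    """Coerce (n, 2, H, W) / (n, 2, 3, H, W) arrays or ImagePair lists."""
    if len(X) and isinstance(X[0], ImagePair):
        pairs = list(X)
        labels = np.array([p.label for p in pairs]) if y is None else np.asarray(y)
        return pairs, labels
    X = np.asarray(X, dtype=np.float64)
    if X.ndim not in (4, 5) or X.shape[1] != 2:
        raise ValueError(
            "X must be (n_samples, 2, H, W) or (n_samples, 2, 3, H, W) with "
            "the two modalities on axis 1, or a list of ImagePair")
    if y is None:
        raise ValueError("y is required when X is an array")
    y = np.asarray(y)
    pairs = [ImagePair(mri=x[0], pet=x[1], label=int(lbl), subject_id=str(i))
             for i, (x, lbl) in enumerate(zip(X, y))]
    return pairs, y


class CsAGPClassifier(BaseEstimator, ClassifierMixin):
    """Dual-branch cross-attention + graph-pooling image-pair classifier.

    Parameters mirror :class:`csagp.config.ModelConfig` plus the optimizer
    settings.  Fitted attributes: ``model_`` (the trained network),
    ``classes_``, ``config_``, ``history_`` (per-epoch log).
    """

    def __init__(self, K=3, M=1, N_enc=3, r=0.5, D=192, h=4, ffn_mult=4,
                 img_size=(224, 224), lr=1e-5, weight_decay=5e-4,
                 batch_size=128, epochs=300, validation_fraction=0.0,
                 disable_cafm=False, share_stem=False, fblm_variant="conv",
                 sflm_variant="conv", head_mode="concat", activation="gelu",
                 conventional_prenorm=False, gat_heads=2,
                 add_self_loops=False, rpr_blocks=None, seed=0,
                 verbose=False):
        self.K = K
        self.M = M
        self.N_enc = N_enc
        self.r = r
        self.D = D
        self.h = h
        self.ffn_mult = ffn_mult
        self.img_size = img_size
        self.lr = lr
        self.weight_decay = weight_decay
        self.batch_size = batch_size
        self.epochs = epochs
        self.validation_fraction = validation_fraction
        self.disable_cafm = disable_cafm
        self.share_stem = share_stem
        self.fblm_variant = fblm_variant
        self.sflm_variant = sflm_variant
        self.head_mode = head_mode
        self.activation = activation
        self.conventional_prenorm = conventional_prenorm
        self.gat_heads = gat_heads
        self.add_self_loops = add_self_loops
        self.rpr_blocks = rpr_blocks
        self.seed = seed
        self.verbose = verbose

    # -- sklearn API ----------------------------------------------------------

    def _model_config(self, n_classes: int) -> ModelConfig:
        return ModelConfig(
            K=self.K, M=self.M, N_enc=self.N_enc, r=self.r, D=self.D,
            h=self.h, ffn_mult=self.ffn_mult, C=n_classes,
            img_size=tuple(self.img_size), seed=self.seed,
            share_stem=self.share_stem, disable_cafm=self.disable_cafm,
            activation=self.activation,
            conventional_prenorm=self.conventional_prenorm,
            add_self_loops=self.add_self_loops, gat_heads=self.gat_heads,
            fblm_variant=self.fblm_variant, sflm_variant=self.sflm_variant,
            head_mode=self.head_mode,
            rpr_blocks=None if self.rpr_blocks is None else tuple(self.rpr_blocks))

    def fit(self, X, y=None) -> "CsAGPClassifier":
        pairs, labels = _as_pairs(X, y)
        if not pairs:
            raise ValueError("cannot fit on an empty dataset")
        self.classes_, y_idx = np.unique(labels, return_inverse=True)
        if len(self.classes_) < 2:
            raise ValueError("need at least two classes")
        pairs = [ImagePair(mri=p.mri, pet=p.pet, label=int(k),
                           subject_id=p.subject_id)
                 for p, k in zip(pairs, y_idx)]
        self.config_ = self._model_config(len(self.classes_))
        if pairs[0].spatial_shape != self.config_.img_size:
            raise ValueError(
                f"images are {pairs[0].spatial_shape} but img_size is "
                f"{self.config_.img_size}")
        self.model_ = CsAGPNet(self.config_)
        val_pairs = None
        if self.validation_fraction > 0:
            rng = np.random.default_rng(self.seed)
            order = rng.permutation(len(pairs))
            n_val = max(1, int(self.validation_fraction * len(pairs)))
            val_pairs = [pairs[i] for i in order[:n_val]]
            pairs = [pairs[i] for i in order[n_val:]]
        train_cfg = TrainConfig(lr=self.lr, weight_decay=self.weight_decay,
                                batch_size=self.batch_size,
                                epochs=self.epochs, seed=self.seed)
        self.history_ = fit_model(self.model_, pairs, train_cfg,
                                  val_pairs=val_pairs, verbose=self.verbose)
        return self

    def predict_proba(self, X) -> np.ndarray:
        check_is_fitted(self, "model_")
        pairs, _ = _as_pairs(X, y=np.zeros(len(X)))
        return self.model_.predict_proba(pairs)

    def predict(self, X) -> np.ndarray:
        return self.classes_[np.argmax(self.predict_proba(X), axis=1)]
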