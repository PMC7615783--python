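"""Seeded training and evaluation loops."""

from __future__ import annotations

import logging

import numpy as np

from .config import TrainConfig
from .metrics import compute_metrics
from .model import CsAGPNet
from .nn import Adam, cross_entropy
from .types import ImagePair

__all__ = ["fit_model", "evaluate", "evaluate_report"]

log = logging.getLogger(__name__)


def fit_model(model: CsAGPNet, train_pairs: list[ImagePair],
              cfg: TrainConfig, val_pairs: list[ImagePair] | None = None,
              verbose: bool = False) -> list[dict]:
    """Adam + cross-entropy minibatch training; returns per-epoch history.

    Gradients are averaged over each minibatch (per-sample backward passes
    accumulate into the shared parameter gradients).  When a validation set
    is given, the parameters of the best-validation-accuracy epoch are
    restored at the end.
    """
    rng = np.random.default_rng(cfg.seed)
    opt = Adam(model.parameters(), lr=cfg.lr, weight_decay=cfg.weight_decay)
    history: list[dict] = []
    best_acc, best_state = -np.inf, None
    for epoch in range(cfg.epochs):
        model.train()
        order = rng.permutation(len(train_pairs))
        epoch_loss = 0.0
        for start in range(0, len(order), cfg.batch_size):
            batch = order[start:start + cfg.batch_size]
            opt.zero_grad()
            inv = 1.0 / len(batch)
            for i in batch:
                pair = train_pairs[i]
                logits = model.forward_logits(pair.mri, pair.pet)
                loss = cross_entropy(logits, pair.label)
                epoch_loss += float(loss.data)
                (loss * inv).backward()
            opt.step()
        record = {"epoch": epoch,
                  "train_loss": epoch_loss / len(train_pairs)}
        if val_pairs:
            val_report = evaluate_report(model, val_pairs)
            record["val_accuracy"] = val_report["accuracy"]
            if val_report["accuracy"] > best_acc:
                best_acc = val_report["accuracy"]
                best_state = model.state_dict()
        history.append(record)
        if verbose:
            log.info("epoch %d: %s", epoch, record)
    if best_state is not None:
        model.load_state_dict(best_state)
    return history


def evaluate(model: CsAGPNet, pairs: list[ImagePair]
             ) -> tuple[np.ndarray, np.ndarray]:
    """Labels and predicted probabilities over a dataset."""
    y_true = np.array([p.label for p in pairs])
    y_prob = model.predict_proba(pairs)
    return y_true, y_prob


def evaluate_report(model: CsAGPNet, pairs: list[ImagePair]) -> dict:
    y_true, y_prob = evaluate(model, pairs)
    return compute_metrics(y_true, y_prob)
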