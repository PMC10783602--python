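"""Training protocol: minibatch Adam on the ranking loss, early stopping, a
bounded queue of best checkpoints, ensembling, and 5-fold cross-validation.

The protocol mirrors the weakly supervised slide-level setup: batches of 8
slides, Adam at learning rate 1e-3 with weight decay 1e-4, up to 300 epochs
with early stopping after 20 epochs without validation improvement.  A
checkpoint enters a FIFO queue of capacity 10 whenever the validation loss at
epoch n improves on epoch n-1; test-time predictions average the queued
models.  Multi-slide patients are handled as bags of graphs whose per-slide
ensemble scores are averaged.
"""

from __future__ import annotations

import json
import os
from collections import deque
from dataclasses import asdict, dataclass, field

import numpy as np
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import KFold

from .graph import WSIGraph
from .model import ModelConfig, Prediction, SlideGraphModel, ranking_loss_grad
from .nn import Adam, add_params, clone_params, zeros_like_params


@dataclass
class TrainConfig:
    epochs: int = 300
    batch_size: int = 8
    learning_rate: float = 1e-3
    weight_decay: float = 1e-4
    patience_epochs: int = 20
    model_queue_size: int = 10
    n_folds: int = 5
    val_fraction_of_train: float = 0.10
    # exponential decay of the learning rate from its initial value, floored
    # at lr_final; the stated 1e-3 is the *initial* rate.  Decay within the
    # early-stopping window lets the optimizer refine weight directions after
    # the ranking margins are first satisfied.
    lr_decay: float = 0.93
    lr_final: float = 1e-5
    seed: int = 0

    def __post_init__(self):
        if min(self.epochs, self.batch_size, self.patience_epochs,
               self.model_queue_size, self.n_folds) <= 0:
            raise ValueError("all TrainConfig sizes must be positive")
        if not 0 < self.val_fraction_of_train < 1:
            raise ValueError("val_fraction_of_train must lie in (0, 1)")


@dataclass
class TrainResult:
    model: SlideGraphModel
    queue: deque                      # parameter snapshots, oldest first
    val_history: list[float]
    stopped_epoch: int

    def queue_models(self) -> list[SlideGraphModel]:
        models = []
        for params in self.queue:
            m = self.model.clone()
            m.set_params(params)
            models.append(m)
        return models

    def save(self, out_dir) -> None:
        os.makedirs(out_dir, exist_ok=True)
        with open(os.path.join(out_dir, "config.json"), "w") as fh:
            json.dump(
                {"model": asdict(self.model.config),
                 "feature_dim": self.model.feature_dim,
                 "val_history": self.val_history,
                 "stopped_epoch": self.stopped_epoch},
                fh,
            )
        for i, params in enumerate(self.queue):
            np.savez(os.path.join(out_dir, f"checkpoint_{i:02d}.npz"),
                     *params)

    @classmethod
    def load(cls, out_dir) -> "TrainResult":
        with open(os.path.join(out_dir, "config.json")) as fh:
            meta = json.load(fh)
        model = SlideGraphModel(ModelConfig(**meta["model"]), meta["feature_dim"])
        queue: deque = deque()
        i = 0
        while os.path.exists(os.path.join(out_dir, f"checkpoint_{i:02d}.npz")):
            with np.load(os.path.join(out_dir, f"checkpoint_{i:02d}.npz")) as z:
                queue.append([z[k] for k in z.files])
            i += 1
        if queue:
            model.set_params(clone_params(queue[-1]))
        return cls(model, queue, meta["val_history"], meta["stopped_epoch"])


def _check_pairs(labels: np.ndarray) -> None:
    y = np.asarray(labels, dtype=float)
    has_pair = ((y == 1).any(axis=0) & (y == 0).any(axis=0)).any()
    if not has_pair:
        raise ValueError(
            "no output has both a status-1 and a status-0 slide in the "
            "training set; the ranking loss has no valid pair to optimise"
        )


def _set_loss(model: SlideGraphModel, graphs, labels, batch_size: int) -> float:
    """Mean per-slide ranking loss over a graph set (deterministic batches)."""
    total = 0.0
    n = len(graphs)
    scores = np.stack([model.slide_score(g) for g in graphs])
    for start in range(0, n, batch_size):
        sl = slice(start, start + batch_size)
        loss, _ = ranking_loss_grad(scores[sl], labels[sl])
        total += loss
    return total / n


def train(
    graphs: list[WSIGraph],
    labels: np.ndarray,
    model_config: ModelConfig | None = None,
    train_config: TrainConfig | None = None,
    val_graphs: list[WSIGraph] | None = None,
    val_labels: np.ndarray | None = None,
    model: SlideGraphModel | None = None,
) -> TrainResult:
    """Train a slide-graph model with the ranking loss.

    If no validation set is given, ``val_fraction_of_train`` of the training
    slides is held out (seeded).  Labels are (N, K) binary with NaN allowed
    for missing entries.
    """
    cfg = train_config or TrainConfig()
    labels = np.asarray(labels, dtype=float)
    if labels.ndim == 1:
        labels = labels[:, None]
    if val_graphs is None:
        rng = np.random.default_rng(cfg.seed)
        n_val = max(1, int(round(cfg.val_fraction_of_train * len(graphs))))
        perm = rng.permutation(len(graphs))
        val_idx, train_idx = perm[:n_val], perm[n_val:]
        val_graphs = [graphs[i] for i in val_idx]
        val_labels = labels[val_idx]
        graphs = [graphs[i] for i in train_idx]
        labels = labels[train_idx]
    if len(graphs) == 0 or len(val_graphs) == 0:
        raise ValueError("need at least one training and one validation graph")
    _check_pairs(labels)

    if model is None:
        mc = model_config or ModelConfig()
        model = SlideGraphModel(mc, graphs[0].feature_dim)
    opt = Adam(model.params, lr=cfg.learning_rate, weight_decay=cfg.weight_decay)
    rng = np.random.default_rng(cfg.seed + 1)

    queue: deque = deque(maxlen=cfg.model_queue_size)
    val_history: list[float] = []
    best_val = np.inf
    since_best = 0
    stopped = cfg.epochs
    for epoch in range(cfg.epochs):
        opt.lr = max(cfg.lr_final, cfg.learning_rate * cfg.lr_decay**epoch)
        order = rng.permutation(len(graphs))
        for start in range(0, len(order), cfg.batch_size):
            batch = order[start : start + cfg.batch_size]
            passes = [model.forward_pass(graphs[i]) for i in batch]
            scores = np.stack([s for s, _ in passes])
            _, g_scores = ranking_loss_grad(scores, labels[batch])
            if not g_scores.any():
                continue
            total = zeros_like_params(model.params)
            for row in range(len(batch)):
                if not g_scores[row].any():
                    continue
                add_params(total, model.backward_pass(passes[row][1], g_scores[row]))
            opt.step(model.params, total)

        val_loss = _set_loss(model, val_graphs, val_labels, cfg.batch_size)
        if val_history and val_loss < val_history[-1]:
            queue.append(clone_params(model.params))  # FIFO eviction via maxlen
        val_history.append(val_loss)
        if val_loss < best_val - 1e-12:
            best_val = val_loss
            since_best = 0
        else:
            since_best += 1
            if since_best >= cfg.patience_epochs:
                stopped = epoch + 1
                break
    if not queue:  # e.g. validation loss never decreased epoch-on-epoch
        queue.append(clone_params(model.params))
    return TrainResult(model, queue, val_history, stopped)


def predict_ensemble(
    models: list[SlideGraphModel] | TrainResult,
    graphs: list[WSIGraph],
) -> list[Prediction]:
    """Mean node and slide scores over an ensemble (e.g. the model queue)."""
    if isinstance(models, TrainResult):
        models = models.queue_models()
    if not models:
        raise ValueError("empty model ensemble")
    out = []
    for graph in graphs:
        ns = np.mean([m.node_scores(graph) for m in models], axis=0)
        out.append(Prediction(graph.slide_id, ns, ns.sum(axis=0)))
    return out


def predict_bag(
    models: list[SlideGraphModel] | TrainResult,
    bag: list[WSIGraph],
) -> np.ndarray:
    """Patient-level score for a bag of graphs: mean of per-slide ensemble
    slide scores."""
    preds = predict_ensemble(models, bag)
    return np.mean([p.slide_scores for p in preds], axis=0)


@dataclass
class CVResult:
    oof_scores: np.ndarray          # (N, K) out-of-fold ensemble slide scores
    auroc: np.ndarray               # (K,) per-output AUROC, NaN if one class
    fold_of: np.ndarray             # (N,) test-fold index per slide
    fold_results: list[TrainResult] = field(default_factory=list)


def cross_validate(
    graphs: list[WSIGraph],
    labels: np.ndarray,
    model_config: ModelConfig | None = None,
    train_config: TrainConfig | None = None,
    keep_models: bool = True,
) -> CVResult:
    """5-fold CV: 80/20 non-overlapping splits, 10% of each training split
    held out for validation, out-of-fold ensemble predictions concatenated,
    AUROC per output on the pooled out-of-fold scores."""
    cfg = train_config or TrainConfig()
    labels = np.asarray(labels, dtype=float)
    if labels.ndim == 1:
        labels = labels[:, None]
    if len(graphs) < cfg.n_folds:
        raise ValueError("need at least n_folds labeled slides")
    oof = np.full(labels.shape, np.nan)
    fold_of = np.full(len(graphs), -1)
    results = []
    kf = KFold(n_splits=cfg.n_folds, shuffle=True, random_state=cfg.seed)
    for fold, (train_idx, test_idx) in enumerate(kf.split(graphs)):
        res = train(
            [graphs[i] for i in train_idx],
            labels[train_idx],
            model_config=model_config,
            train_config=cfg,
        )
        preds = predict_ensemble(res, [graphs[i] for i in test_idx])
        oof[test_idx] = np.stack([p.slide_scores for p in preds])
        fold_of[test_idx] = fold
        if keep_models:
            results.append(res)

    auroc = np.full(labels.shape[1], np.nan)
    for k in range(labels.shape[1]):
        mask = ~np.isnan(labels[:, k])
        y = labels[mask, k]
        if len(np.unique(y)) == 2:
            auroc[k] = roc_auc_score(y, oof[mask, k])
    return CVResult(oof, auroc, fold_of, results)
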