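"""Downstream predictors on the predicted gene-group latent representation.

A patient's predicted group scores (length-d vector) act as a compressed
latent representation from which clinical targets — receptor status, PAM50
subtype (one-vs-rest), point-mutation and copy-number status, pathway
alteration — are predicted by a one-hidden-layer multi-output perceptron
trained with the same ranking loss, early-stopping and model-queue protocol
as the slide-graph network.  Evaluation subsamples 67% of patients 1,000
times with replacement and reports the AUROC distribution.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import roc_auc_score

from .graph import WSIGraph
from .model import ModelConfig
from .training import CVResult, TrainConfig, TrainResult, cross_validate, train

logger = logging.getLogger(__name__)


@dataclass
class DownstreamTask:
    """T binary targets per patient (NaN = missing)."""

    name: str
    target_names: list[str]
    labels: np.ndarray  # (m, T) in {0, 1, NaN}

    def __post_init__(self):
        vals = self.labels[~np.isnan(self.labels)]
        if not np.isin(vals, (0, 1)).all():
            raise ValueError("labels must be binary where present")


def one_vs_rest(name: str, classes: np.ndarray) -> DownstreamTask:
    """Expand a multi-class column (e.g. PAM50 subtype) into T binary targets."""
    classes = np.asarray(classes)
    present = ~(classes == None)  # noqa: E711  (object arrays from pandas)
    uniq = sorted({str(c) for c in classes[present]})
    labels = np.full((len(classes), len(uniq)), np.nan)
    for t, c in enumerate(uniq):
        labels[present, t] = (classes[present].astype(str) == c).astype(float)
    return DownstreamTask(name, uniq, labels)


def binarize_scores(features: np.ndarray) -> np.ndarray:
    """Threshold continuous group scores at the per-column median.

    Continuous ensemble scores are the default input representation (they
    keep rank information); this helper supports the binarised alternative.
    """
    features = np.asarray(features, dtype=float)
    return (features > np.median(features, axis=0)).astype(float)


def _as_graphs(features: np.ndarray) -> list[WSIGraph]:
    """Each patient becomes a single-node graph, so the shared trainer reduces
    exactly to a one-hidden-layer perceptron on the feature vector (single
    node, no edges: slide score = f_0(h))."""
    features = np.asarray(features, dtype=float)
    return [
        WSIGraph(slide_id=f"P{i}", coords=np.zeros((1, 2)),
                 features=features[i : i + 1], edges=np.empty((0, 2), dtype=int))
        for i in range(len(features))
    ]


def train_downstream(
    features: np.ndarray,
    task: DownstreamTask,
    train_config: TrainConfig | None = None,
    hidden_width: int = 64,
    binarize: bool = False,
) -> TrainResult:
    """Fit the multi-output perceptron for one task (all targets jointly).

    Targets with a single observed class are excluded with a warning (they
    contribute no ranking pairs)."""
    if binarize:
        features = binarize_scores(features)
    labels = np.array(task.labels, dtype=float)
    for t in range(labels.shape[1]):
        col = labels[:, t]
        seen = np.unique(col[~np.isnan(col)])
        if len(seen) < 2:
            logger.warning("target %r has a single class; excluded",
                           task.target_names[t])
            labels[:, t] = np.nan
    cfg = ModelConfig(n_layers=0, n_outputs=labels.shape[1],
                      head_hidden_width=hidden_width, score_scale=1.0,
                      seed=(train_config or TrainConfig()).seed)
    return train(_as_graphs(features), labels, model_config=cfg,
                 train_config=train_config)


def cross_validate_downstream(
    features: np.ndarray,
    task: DownstreamTask,
    train_config: TrainConfig | None = None,
    hidden_width: int = 64,
    binarize: bool = False,
) -> CVResult:
    """Same 5-fold protocol as the slide model, on the latent representation."""
    if binarize:
        features = binarize_scores(features)
    cfg = ModelConfig(n_layers=0, n_outputs=task.labels.shape[1],
                      head_hidden_width=hidden_width, score_scale=1.0,
                      seed=(train_config or TrainConfig()).seed)
    return cross_validate(_as_graphs(features), task.labels, model_config=cfg,
                          train_config=train_config)


@dataclass
class BootstrapResult:
    """Per-resample AUROC distribution for one target."""

    aurocs: np.ndarray
    fraction: float
    n_resamples: int
    seed: int
    n_skipped: int = 0
    summary: dict = field(default_factory=dict)

    def __post_init__(self):
        if len(self.aurocs):
            self.summary = {
                "median": float(np.median(self.aurocs)),
                "p2.5": float(np.percentile(self.aurocs, 2.5)),
                "p97.5": float(np.percentile(self.aurocs, 97.5)),
            }


def bootstrap_auroc(
    scores: np.ndarray,
    labels: np.ndarray,
    fraction: float = 0.67,
    n_resamples: int = 1000,
    seed: int = 0,
) -> BootstrapResult:
    """AUROC over seeded resamples of ceil(fraction*m) patients drawn with
    replacement; single-class resamples are skipped and counted."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=float)
    keep = ~np.isnan(labels)
    scores, labels = scores[keep], labels[keep]
    if len(np.unique(labels)) < 2:
        raise ValueError("both classes must be present overall")
    m = len(labels)
    size = math.ceil(fraction * m)
    rng = np.random.default_rng(seed)
    aurocs = []
    skipped = 0
    for _ in range(n_resamples):
        idx = rng.integers(0, m, size=size)
        y = labels[idx]
        if y.min() == y.max():
            skipped += 1
            logger.debug("skipping single-class bootstrap resample")
            continue
        aurocs.append(roc_auc_score(y, scores[idx]))
    return BootstrapResult(np.array(aurocs), fraction, n_resamples, seed,
                           n_skipped=skipped)
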