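"""Spatially resolved interpretation of node-level predictions.

Covers heatmap export (diverging colormap centred at 0: blue = status-0
evidence, red = status-1 evidence), selection of accurately predicted
exemplar patients, top/bottom-percentile patch harvesting, k-medoid (PAM)
motif mining, and the sub-patch aggregation geometry used by pluggable patch
annotators (e.g. 16 children of 256 px @ 0.25 MPP per 512 px @ 0.50 MPP
parent).
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import dataclass
from typing import Protocol, runtime_checkable

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from sklearn.metrics import roc_curve

from .graph import WSIGraph
from .model import Prediction

CELL_TYPES = ("neoplastic", "inflammatory", "connective", "epithelial")


# ---------------------------------------------------------------------------
# heatmaps


@dataclass
class Heatmap:
    slide_id: str
    centroids: np.ndarray        # (n, 2)
    patch_size_px: int
    factor_ids: list[int]
    scores: np.ndarray           # (n, len(factor_ids))


def export_heatmap(
    prediction: Prediction,
    graph: WSIGraph,
    factor_ids: list[int],
    out_png=None,
    out_geojson=None,
) -> Heatmap:
    """Per-node scores painted flat over each patch footprint.

    Rendering is deterministic; the PNG uses a diverging colormap centred at
    zero (negative scores blue, positive red) and the GeoJSON-style export
    carries the exact per-patch polygon and score values.
    """
    if prediction.node_scores.shape[0] != graph.n_nodes:
        raise ValueError("prediction and graph node counts differ")
    for f in factor_ids:
        if not 0 <= f < prediction.node_scores.shape[1]:
            raise ValueError(f"unknown factor id {f}")
    scores = prediction.node_scores[:, factor_ids]
    hm = Heatmap(graph.slide_id, graph.coords, graph.patch_size_px,
                 list(factor_ids), scores)
    if out_geojson is not None:
        _write_geojson(hm, out_geojson)
    if out_png is not None:
        _render_png(hm, out_png)
    return hm


def _write_geojson(hm: Heatmap, path) -> None:
    half = hm.patch_size_px / 2
    features = []
    for i, (cx, cy) in enumerate(hm.centroids):
        ring = [
            [cx - half, cy - half], [cx + half, cy - half],
            [cx + half, cy + half], [cx - half, cy + half],
            [cx - half, cy - half],
        ]
        props = {f"factor_{f}": float(hm.scores[i, j])
                 for j, f in enumerate(hm.factor_ids)}
        features.append({
            "type": "Feature",
            "geometry": {"type": "Polygon", "coordinates": [ring]},
            "properties": props,
        })
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh)


def _render_png(hm: Heatmap, path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    p = hm.patch_size_px
    cols = np.round((hm.centroids[:, 0] - p / 2) / p).astype(int)
    rows = np.round((hm.centroids[:, 1] - p / 2) / p).astype(int)
    n_r, n_c = rows.max() + 1, cols.max() + 1
    n_f = len(hm.factor_ids)
    fig, axes = plt.subplots(1, n_f, figsize=(4 * n_f, 4), squeeze=False)
    for j, f in enumerate(hm.factor_ids):
        img = np.full((n_r, n_c), np.nan)
        img[rows, cols] = hm.scores[:, j]
        vmax = np.nanmax(np.abs(img)) or 1.0
        ax = axes[0, j]
        im = ax.imshow(img, cmap="coolwarm", vmin=-vmax, vmax=vmax)
        ax.set_title(f"factor {f}")
        ax.axis("off")
        fig.colorbar(im, ax=ax, shrink=0.8)
    fig.savefig(path, dpi=100, bbox_inches="tight")
    plt.close(fig)


# ---------------------------------------------------------------------------
# exemplar patients and patch harvesting


def youden_threshold(scores: np.ndarray, labels: np.ndarray) -> float:
    """Score threshold maximising sensitivity + specificity - 1."""
    fpr, tpr, thr = roc_curve(labels, scores)
    return float(thr[np.argmax(tpr - fpr)])


def select_exemplar_patients(
    scores: np.ndarray,
    labels: np.ndarray,
    n_per_status: int = 50,
    threshold: float | None = None,
):
    """Indices of the most confidently correct patients per status.

    A patient is correctly classified when ``score > threshold`` matches the
    label (threshold defaults to the Youden-optimal point on the provided
    data); within each status, patients are ranked by the label-concordant
    signed margin, largest first.  Returns (status0_idx, status1_idx).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if threshold is None:
        threshold = youden_threshold(scores, labels)
    predicted = (scores > threshold).astype(int)
    out = []
    for status in (0, 1):
        correct = np.flatnonzero((labels == status) & (predicted == status))
        margin = (scores[correct] - threshold) * (1 if status == 1 else -1)
        order = np.argsort(-margin, kind="stable")
        out.append(correct[order[:n_per_status]])
    return out[0], out[1]


def harvest_patches(
    node_scores: np.ndarray,
    status: int,
    fraction: float = 0.01,
) -> np.ndarray:
    """Top (status=1) or bottom (status=0) ceil(fraction*n) node indices by
    score; at least one patch; ties broken by node index."""
    if not 0 < fraction <= 1:
        raise ValueError("fraction must lie in (0, 1]")
    s = np.asarray(node_scores, dtype=float)
    count = max(1, math.ceil(fraction * len(s)))
    key = -s if status == 1 else s
    order = np.argsort(key, kind="stable")  # stable: equal scores -> low index
    return order[:count]


# ---------------------------------------------------------------------------
# k-medoid motif mining


@dataclass
class MotifSet:
    group_id: int
    status: int
    medoid_indices: np.ndarray    # indices into the harvested patch set
    labels: np.ndarray            # cluster membership of every input patch


def kmedoids(X: np.ndarray, k: int, seed: int = 0, max_iter: int = 100):
    """Partitioning around medoids (build + swap), Euclidean, seeded.

    Returns (medoid_indices, labels).  With n <= k every point is a medoid.
    """
    X = np.asarray(X, dtype=float)
    n = len(X)
    if n == 0:
        raise ValueError("need at least one point")
    if n <= k:
        return np.arange(n), np.arange(n)
    D = cdist(X, X)
    rng = np.random.default_rng(seed)

    # BUILD: greedy, first medoid minimises total distance; ties by index
    medoids = [int(np.argmin(D.sum(axis=1)))]
    while len(medoids) < k:
        cur = D[:, medoids].min(axis=1)
        gain = np.maximum(cur[None, :] - D, 0).sum(axis=1)
        gain[medoids] = -np.inf
        medoids.append(int(np.argmax(gain)))

    # SWAP: replace (medoid, candidate) pairs while total cost decreases
    medoids = np.array(medoids)
    for _ in range(max_iter):
        dist_to = D[:, medoids]
        cost = dist_to.min(axis=1).sum()
        best = (0.0, None)
        for mi in range(k):
            others = np.delete(medoids, mi)
            base = D[:, others].min(axis=1) if k > 1 else np.full(n, np.inf)
            for h in rng.permutation(n):
                if h in medoids:
                    continue
                new_cost = np.minimum(base, D[:, h]).sum()
                if cost - new_cost > best[0] + 1e-12:
                    best = (cost - new_cost, (mi, h))
        if best[1] is None:
            break
        mi, h = best[1]
        medoids[mi] = h
    labels = np.argmin(D[:, medoids], axis=1)
    return np.sort(medoids), np.argmin(D[:, np.sort(medoids)], axis=1)


def mine_motifs(
    features: np.ndarray,
    group_id: int,
    status: int,
    k: int = 25,
    seed: int = 0,
) -> MotifSet:
    """Cluster harvested patches in feature space; the k medoid patches are
    the visual motifs of the group/status."""
    medoid_idx, labels = kmedoids(features, k, seed=seed)
    return MotifSet(group_id, status, medoid_idx, labels)


# ---------------------------------------------------------------------------
# sub-patch geometry and pluggable annotators


def subpatch_grid(
    parent_origin: tuple[int, int],
    parent_size_px: int,
    parent_mpp: float,
    child_size_px: int,
    child_mpp: float,
) -> list[tuple[int, int]]:
    """Child-tile origins (at the child MPP) exactly covering the parent's
    physical footprint; e.g. a 512 px @ 0.50 MPP parent yields 16 children of
    256 px @ 0.25 MPP."""
    if child_mpp > parent_mpp:
        raise ValueError("child_mpp must be <= parent_mpp")
    ratio = parent_size_px * parent_mpp / (child_size_px * child_mpp)
    if abs(ratio - round(ratio)) > 1e-9:
        raise ValueError(
            f"parent footprint {parent_size_px}px@{parent_mpp}mpp is not an "
            f"integer multiple of child {child_size_px}px@{child_mpp}mpp "
            f"(ratio {ratio:g})"
        )
    side = int(round(ratio))
    scale = parent_mpp / child_mpp
    x0 = int(round(parent_origin[0] * scale))
    y0 = int(round(parent_origin[1] * scale))
    return [
        (x0 + c * child_size_px, y0 + r * child_size_px)
        for r in range(side)
        for c in range(side)
    ]


@runtime_checkable
class PatchAnnotator(Protocol):
    """Contract: per child tile, counts of the four cell types and mitoses."""

    name: str

    def __call__(self, slide_id: str, origin: tuple[int, int],
                 size_px: int, mpp: float) -> dict: ...


class ConstantAnnotator:
    """Synthetic stub annotator returning fixed counts per child tile."""

    name = "constant-stub"

    def __init__(self, **counts):
        self.counts = {c: counts.get(c, 0) for c in CELL_TYPES}
        self.counts["mitotic"] = counts.get("mitotic", 0)

    def __call__(self, slide_id, origin, size_px, mpp):
        return dict(self.counts)


def annotate_patches(
    patches,
    annotator: PatchAnnotator,
    parent_mpp: float = 0.50,
    child_size_px: int = 256,
    child_mpp: float = 0.25,
) -> pd.DataFrame:
    """Parent-patch annotations = sum of child-tile annotator outputs over the
    sub-patch grid; cellularity is the four-way cell-count sum."""
    rows = []
    for patch in patches:
        totals = {c: 0 for c in (*CELL_TYPES, "mitotic")}
        for origin in subpatch_grid(patch.origin, patch.size_px, parent_mpp,
                                    child_size_px, child_mpp):
            out = annotator(patch.slide_id, origin, child_size_px, child_mpp)
            for c in totals:
                v = out.get(c, 0)
                if v < 0:
                    raise ValueError(
                        f"annotator contract violation: negative {c} count"
                    )
                totals[c] += v
        totals["cellularity"] = sum(totals[c] for c in CELL_TYPES)
        rows.append({"slide_id": patch.slide_id, "x": patch.origin[0],
                     "y": patch.origin[1], **totals})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# localization metric (used by recovery tests and the acceptance run)


def localization_auc(predictions, masks, factor: int) -> float:
    """AUROC of pooled node scores for one factor against the planted spatial
    masks across slides (ground-truth blobs as positives)."""
    from sklearn.metrics import roc_auc_score

    scores = np.concatenate([p.node_scores[:, factor] for p in predictions])
    truth = np.concatenate([np.asarray(m)[:, factor] for m in masks]).astype(int)
    if truth.min() == truth.max():
        return float("nan")
    return float(roc_auc_score(truth, scores))
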