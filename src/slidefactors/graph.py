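"""Patch-graph construction: Delaunay triangulation pruned by distance.

A slide graph G = (V, E) has one node per retained patch, carrying the patch
centroid g_i and feature vector h_i; edges come from the Delaunay
triangulation of centroids with edges longer than ``edge_distance_max``
(default 4000 px at the working resolution) removed.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import Delaunay, QhullError, distance


@dataclass
class WSIGraph:
    """Graph representation of one slide."""

    slide_id: str
    coords: np.ndarray               # (n, 2) patch centroids, working pixels
    features: np.ndarray             # (n, D)
    edges: np.ndarray                # (E, 2) undirected, i < j, lexicographic
    patch_size_px: int = 512
    _adj: object = field(default=None, repr=False, compare=False)

    @property
    def n_nodes(self) -> int:
        return self.coords.shape[0]

    @property
    def feature_dim(self) -> int:
        return self.features.shape[1]

    def edge_lengths(self) -> np.ndarray:
        if len(self.edges) == 0:
            return np.empty(0)
        d = self.coords[self.edges[:, 0]] - self.coords[self.edges[:, 1]]
        return np.linalg.norm(d, axis=1)

    def directed_edges(self) -> np.ndarray:
        """Both orientations of every edge, (2E, 2) as (target m, neighbor k)."""
        if len(self.edges) == 0:
            return np.empty((0, 2), dtype=int)
        return np.concatenate([self.edges, self.edges[:, ::-1]], axis=0)


def _all_pairs_within(coords: np.ndarray, dmax: float) -> np.ndarray:
    n = len(coords)
    if n < 2:
        return np.empty((0, 2), dtype=int)
    dm = distance.squareform(distance.pdist(coords))
    i, j = np.nonzero(np.triu(dm <= dmax, k=1))
    return np.stack([i, j], axis=1)


def build_graph(
    patches_or_coords,
    features: np.ndarray,
    edge_distance_max: float = 4000.0,
    slide_id: str = "slide",
    patch_size_px: int = 512,
) -> WSIGraph:
    """Delaunay edges over patch centroids, pruned at ``edge_distance_max``.

    Accepts a list of :class:`~slidefactors.wsi.Patch` or an (n, 2) centroid
    array.  Degenerate inputs (fewer than 3 nodes, collinear points) fall back
    to connecting all pairs within the distance bound.  Node order follows the
    input patch order; edges are unique, self-loop-free, and every edge's
    Euclidean length is <= the bound.
    """
    if hasattr(patches_or_coords, "shape"):
        coords = np.asarray(patches_or_coords, dtype=float)
    else:
        coords = np.array([p.centroid for p in patches_or_coords], dtype=float)
        if patches_or_coords and hasattr(patches_or_coords[0], "size_px"):
            patch_size_px = patches_or_coords[0].size_px
    features = np.asarray(features, dtype=float)
    if len(coords) == 0:
        raise ValueError("graph needs at least one patch")
    if len(coords) != len(features):
        raise ValueError("coords and features disagree on patch count")

    if len(coords) < 3:
        edges = _all_pairs_within(coords, edge_distance_max)
    else:
        try:
            tri = Delaunay(coords)
            simplices = tri.simplices
            pairs = np.concatenate(
                [simplices[:, [0, 1]], simplices[:, [1, 2]], simplices[:, [0, 2]]]
            )
            pairs = np.sort(pairs, axis=1)
            edges = np.unique(pairs, axis=0)
            lengths = np.linalg.norm(
                coords[edges[:, 0]] - coords[edges[:, 1]], axis=1
            )
            edges = edges[lengths <= edge_distance_max]
        except QhullError:  # collinear or otherwise degenerate point set
            edges = _all_pairs_within(coords, edge_distance_max)
    return WSIGraph(slide_id, coords, features, edges.astype(int), patch_size_px)


def save_graph(graph: WSIGraph, out_dir) -> None:
    """Write node and edge tables as TSV (round-trips with :func:`load_graph`)."""
    os.makedirs(out_dir, exist_ok=True)
    nodes = pd.DataFrame(
        graph.features, columns=[f"f{i}" for i in range(graph.feature_dim)]
    )
    nodes.insert(0, "y", graph.coords[:, 1])
    nodes.insert(0, "x", graph.coords[:, 0])
    nodes.insert(0, "slide_id", graph.slide_id)
    nodes.to_csv(os.path.join(out_dir, "nodes.tsv"), sep="\t", index=False)
    pd.DataFrame(graph.edges, columns=["i", "j"]).to_csv(
        os.path.join(out_dir, "edges.tsv"), sep="\t", index=False
    )


def load_graph(out_dir) -> WSIGraph:
    nodes = pd.read_csv(os.path.join(out_dir, "nodes.tsv"), sep="\t")
    edges = pd.read_csv(os.path.join(out_dir, "edges.tsv"), sep="\t")
    feat_cols = [c for c in nodes.columns if c.startswith("f")]
    return WSIGraph(
        slide_id=str(nodes["slide_id"].iloc[0]) if len(nodes) else "slide",
        coords=nodes[["x", "y"]].to_numpy(float),
        features=nodes[feat_cols].to_numpy(float),
        edges=edges.to_numpy(int).reshape(-1, 2),
    )
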