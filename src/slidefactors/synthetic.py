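"""Synthetic cohorts with planted ground truth.

Two coupled generators make every pipeline stage testable without external
downloads: (i) expression matrices with overlapping gene blocks driven by
binary latent factors plus Gaussian noise, and (ii) slides whose patch
features carry spatially contiguous signal blobs tied to the same factor
statuses.  Every generator is a pure function of its config and seed.
"""

from __future__ import annotations

import json
import os
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from .expression import ExpressionMatrix
from .graph import WSIGraph, build_graph, load_graph, save_graph


@dataclass
class SynthExpressionConfig:
    n_samples: int = 300
    n_factors: int = 10
    genes_per_factor: int = 30
    n_background_genes: int = 200
    status_prevalence: float = 0.5
    effect_size: float = 2.0       # z-units added to a planted gene when active
    noise_sd: float = 1.0
    overlap_fraction: float = 0.1  # genes shared between adjacent factors
    seed: int = 0                  # sample-level randomness: statuses, noise
    structure_seed: int = 0        # gene-level randomness: per-gene directions

    def __post_init__(self):
        if not 0 < self.status_prevalence < 1:
            raise ValueError("status_prevalence must lie in (0, 1)")


@dataclass
class SynthSlideConfig:
    grid: tuple[int, int] = (24, 24)      # patches (rows, cols)
    feature_dim: int = 64                 # 1024 matches the full-scale pipeline
    blob_area_fraction: float = 0.15
    shift_magnitude: float = 1.5          # feature shift along a unit direction
    noise_sd: float = 1.0
    patch_size_px: int = 512
    render_pixels: bool = False
    seed: int = 0


@dataclass
class SynthExpression:
    matrix: ExpressionMatrix
    statuses: np.ndarray                      # (m, d*) binary
    memberships: dict[str, list[int]]         # gene -> factors containing it
    directions: np.ndarray                    # (n_genes,) +-1 per gene
    config: SynthExpressionConfig


@dataclass
class SyntheticCohort:
    expression: SynthExpression
    graphs: list[WSIGraph]
    masks: list[np.ndarray]                   # (n_nodes, d*) bool per slide
    factor_directions: np.ndarray             # (d*, feature_dim) unit vectors
    slide_config: SynthSlideConfig

    @property
    def statuses(self) -> np.ndarray:
        return self.expression.statuses


def generate_expression(cfg: SynthExpressionConfig) -> SynthExpression:
    """Planted-block expression: value = sum over owning factors of
    direction * effect_size * status, plus N(0, noise_sd); background genes are
    pure noise.  Adjacent factors share ``overlap_fraction`` of their genes.

    ``seed`` draws fresh samples (statuses and noise) while ``structure_seed``
    fixes the gene-level structure (per-gene direction signs), so two cohorts
    differing only in ``seed`` come from the same generative process — the
    setting for independent-cohort validation."""
    rng = np.random.default_rng(cfg.seed)
    d, gpf = cfg.n_factors, cfg.genes_per_factor
    n_overlap = int(round(cfg.overlap_fraction * gpf))

    gene_ids: list[str] = []
    memberships: dict[str, list[int]] = {}
    for k in range(d):
        start = 0 if k == 0 else n_overlap  # first n_overlap genes shared with k-1
        for j in range(start, gpf):
            g = f"F{k}_G{j}"
            gene_ids.append(g)
            memberships[g] = [k]
            if j >= gpf - n_overlap and k + 1 < d:
                memberships[g].append(k + 1)
    for j in range(cfg.n_background_genes):
        g = f"BG_{j}"
        gene_ids.append(g)
        memberships[g] = []

    n = len(gene_ids)
    statuses = (rng.random((cfg.n_samples, d)) < cfg.status_prevalence).astype(np.int8)
    structure_rng = np.random.default_rng([cfg.structure_seed, 1])
    directions = structure_rng.choice([-1, 1], size=n)
    values = rng.normal(0.0, cfg.noise_sd, size=(cfg.n_samples, n))
    for i, g in enumerate(gene_ids):
        for k in memberships[g]:
            values[:, i] += directions[i] * cfg.effect_size * statuses[:, k]

    matrix = ExpressionMatrix(
        sample_ids=[f"S{i}" for i in range(cfg.n_samples)],
        gene_ids=gene_ids,
        values=values,
    )
    return SynthExpression(matrix, statuses, memberships, directions, cfg)


def _grow_blob(grid, n_target, rng):
    """Random-walk region growth: contiguous, irregular patch region."""
    rows, cols = grid
    start = (int(rng.integers(rows)), int(rng.integers(cols)))
    region = {start}
    frontier = [start]
    while len(region) < n_target and frontier:
        r, c = frontier[int(rng.integers(len(frontier)))]
        nbrs = [
            (r + dr, c + dc)
            for dr, dc in ((1, 0), (-1, 0), (0, 1), (0, -1))
            if 0 <= r + dr < rows and 0 <= c + dc < cols and (r + dr, c + dc) not in region
        ]
        if not nbrs:
            frontier.remove((r, c))
            continue
        nxt = nbrs[int(rng.integers(len(nbrs)))]
        region.add(nxt)
        frontier.append(nxt)
    return region


def unit_directions(d: int, dim: int, seed: int) -> np.ndarray:
    """d seeded random unit vectors in feature space, one per factor."""
    rng = np.random.default_rng(seed)
    v = rng.normal(size=(d, dim))
    return v / np.linalg.norm(v, axis=1, keepdims=True)


def generate_slide(
    cfg: SynthSlideConfig,
    sample_statuses: np.ndarray,
    factor_directions: np.ndarray,
    seed: int,
    slide_id: str = "slide",
    edge_distance_max: float = 4000.0,
) -> tuple[WSIGraph, np.ndarray]:
    """One slide graph: base-noise features; each active factor shifts the
    features of a contiguous blob of ~blob_area_fraction of the patches along
    its unit direction.  Returns (graph, mask) with mask (n_nodes, d*) bool."""
    rng = np.random.default_rng(seed)
    rows, cols = cfg.grid
    n = rows * cols
    p = cfg.patch_size_px
    rr, cc = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
    coords = np.stack([cc.ravel() * p + p / 2, rr.ravel() * p + p / 2], axis=1).astype(float)

    d = len(sample_statuses)
    features = rng.normal(0.0, cfg.noise_sd, size=(n, cfg.feature_dim))
    masks = np.zeros((n, d), dtype=bool)
    n_blob = max(1, int(round(cfg.blob_area_fraction * n)))
    for k in range(d):
        blob = _grow_blob(cfg.grid, n_blob, rng)  # draw regardless, for determinism
        if sample_statuses[k]:
            idx = np.array([r * cols + c for r, c in sorted(blob)])
            masks[idx, k] = True
            features[idx] += cfg.shift_magnitude * factor_directions[k]

    graph = build_graph(coords, features, edge_distance_max=edge_distance_max,
                        slide_id=slide_id)
    return graph, masks


def render_slide_raster(
    cfg: SynthSlideConfig,
    seed: int,
    tissue_grid: tuple[int, int] = (3, 3),
    margin_patches: int = 1,
    patch_px: int = 16,
) -> np.ndarray:
    """A tiny RGB raster with a dark-textured tissue block surrounded by a
    white margin, so tiling and the informative-pixel filter can be exercised
    end to end at desk scale."""
    rng = np.random.default_rng(seed)
    rows, cols = tissue_grid
    h = (rows + 2 * margin_patches) * patch_px
    w = (cols + 2 * margin_patches) * patch_px
    img = np.full((h, w, 3), 255, dtype=np.uint8)
    y0 = x0 = margin_patches * patch_px
    tissue = rng.integers(40, 160, size=(rows * patch_px, cols * patch_px, 3))
    img[y0 : y0 + rows * patch_px, x0 : x0 + cols * patch_px] = tissue
    return img


def generate_cohort(
    expr_cfg: SynthExpressionConfig,
    slide_cfg: SynthSlideConfig,
) -> SyntheticCohort:
    """Coupled cohort: one slide per sample whose blobs follow the sample's
    expression-derived factor statuses."""
    expr = generate_expression(expr_cfg)
    directions = unit_directions(expr_cfg.n_factors, slide_cfg.feature_dim,
                                 slide_cfg.seed)
    graphs, masks = [], []
    for i in range(expr_cfg.n_samples):
        g, mk = generate_slide(
            slide_cfg,
            expr.statuses[i],
            directions,
            seed=int(np.random.default_rng([slide_cfg.seed, i]).integers(2**31)),
            slide_id=f"S{i}",
        )
        graphs.append(g)
        masks.append(mk)
    return SyntheticCohort(expr, graphs, masks, directions, slide_cfg)


# ---------------------------------------------------------------------------
# fixtures on disk (plain TSV/JSON)


def write_cohort(cohort: SyntheticCohort, out_dir) -> None:
    os.makedirs(out_dir, exist_ok=True)
    expr = cohort.expression
    expr.matrix.to_frame().to_csv(os.path.join(out_dir, "expression.tsv"), sep="\t")
    pd.DataFrame(
        expr.statuses,
        index=expr.matrix.sample_ids,
        columns=[f"factor{k}" for k in range(expr.statuses.shape[1])],
    ).to_csv(os.path.join(out_dir, "statuses.tsv"), sep="\t")
    np.savetxt(os.path.join(out_dir, "factor_directions.tsv"),
               cohort.factor_directions, delimiter="\t")
    with open(os.path.join(out_dir, "config.json"), "w") as fh:
        json.dump(
            {"expression": asdict(expr.config), "slide": asdict(cohort.slide_config)},
            fh, indent=1,
        )
    for i, (g, mk) in enumerate(zip(cohort.graphs, cohort.masks)):
        sdir = os.path.join(out_dir, f"slide_{i:04d}")
        save_graph(g, sdir)
        np.savetxt(os.path.join(sdir, "mask.tsv"), mk.astype(int),
                   fmt="%d", delimiter="\t")


def read_cohort(out_dir) -> SyntheticCohort:
    with open(os.path.join(out_dir, "config.json")) as fh:
        cfgs = json.load(fh)
    expr_cfg = SynthExpressionConfig(**cfgs["expression"])
    slide_cfg = SynthSlideConfig(**{
        k: tuple(v) if k == "grid" else v for k, v in cfgs["slide"].items()
    })
    edf = pd.read_csv(os.path.join(out_dir, "expression.tsv"), sep="\t", index_col=0)
    sdf = pd.read_csv(os.path.join(out_dir, "statuses.tsv"), sep="\t", index_col=0)
    regen = generate_expression(expr_cfg)  # memberships/directions are config-derived
    expr = SynthExpression(
        matrix=ExpressionMatrix(list(edf.index.astype(str)),
                                list(edf.columns.astype(str)), edf.to_numpy(float)),
        statuses=sdf.to_numpy(np.int8),
        memberships=regen.memberships,
        directions=regen.directions,
        config=expr_cfg,
    )
    directions = np.loadtxt(os.path.join(out_dir, "factor_directions.tsv"),
                            delimiter="\t", ndmin=2)
    graphs, masks = [], []
    for i in range(expr_cfg.n_samples):
        sdir = os.path.join(out_dir, f"slide_{i:04d}")
        graphs.append(load_graph(sdir))
        masks.append(np.loadtxt(os.path.join(sdir, "mask.tsv"),
                                delimiter="\t", ndmin=2).astype(bool))
    return SyntheticCohort(expr, graphs, masks, directions, slide_cfg)
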