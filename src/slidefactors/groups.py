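"""Discovery of binary gene-group latent factors by total-correlation explanation.

A gene group is a binary latent variable Y_k whose status across samples
carries high mutual information with the expression of an (overlapping) set of
genes, so that conditioning on the d factors "explains away" the co-dependence
between genes.  The fitted model records, per group, the gene<->group mutual
information (nats), the total correlation the group explains, the per-sample
binary statuses, and a per-gene direction sign (+1 where a gene's median
expression is higher at status=1).

The optimisation alternates (1) hard gene-to-factor assignment by mutual
information and (2) a per-sample factor posterior under a conditional
independence (naive-Bayes) model of the assigned genes, with expression
discretised into equal-mass bins for MI estimation; posteriors are binarised
at 0.5.  Initial statuses come from the top principal directions of the gene
correlation matrix, which separates co-expression blocks deterministically.
Statuses stored on the model are produced by the same inference routine that
is applied to new cohorts, so re-inferring on the training matrix reproduces
them exactly.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment

from .expression import ExpressionMatrix

logger = logging.getLogger(__name__)

_SMOOTH = 0.5  # Laplace pseudo-count for bin/status tables


@dataclass
class GroupModel:
    """A fitted set of d binary latent factors over n genes and m samples."""

    n_groups: int
    gene_ids: list[str]
    sample_ids: list[str]
    mi: np.ndarray          # (n, d) gene<->group mutual information, nats
    tc: np.ndarray          # (d,) total correlation per group, non-increasing
    statuses: np.ndarray    # (m, d) binary, as inferred on the training matrix
    direction: np.ndarray   # (n, d) in {-1, 0, +1}
    seed: int
    n_bins: int
    bin_edges: np.ndarray          # (n, n_bins - 1) training quantile edges
    log_ratio: np.ndarray = field(repr=False, default=None)  # (d, n, n_bins)
    log_prior_ratio: np.ndarray = field(repr=False, default=None)  # (d,)
    assignment: np.ndarray = field(repr=False, default=None)  # (n,) group per gene

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    def save(self, path) -> None:
        import os

        os.makedirs(path, exist_ok=True)
        with open(os.path.join(path, "model.json"), "w") as fh:
            json.dump(
                {
                    "n_groups": self.n_groups,
                    "gene_ids": self.gene_ids,
                    "sample_ids": self.sample_ids,
                    "seed": self.seed,
                    "n_bins": self.n_bins,
                },
                fh,
            )
        np.savez(
            os.path.join(path, "arrays.npz"),
            mi=self.mi,
            tc=self.tc,
            statuses=self.statuses,
            direction=self.direction,
            bin_edges=self.bin_edges,
            log_ratio=self.log_ratio,
            log_prior_ratio=self.log_prior_ratio,
            assignment=self.assignment,
        )

    @classmethod
    def load(cls, path) -> "GroupModel":
        import os

        with open(os.path.join(path, "model.json")) as fh:
            meta = json.load(fh)
        arr = np.load(os.path.join(path, "arrays.npz"))
        return cls(
            n_groups=meta["n_groups"],
            gene_ids=meta["gene_ids"],
            sample_ids=meta["sample_ids"],
            seed=meta["seed"],
            n_bins=meta["n_bins"],
            mi=arr["mi"],
            tc=arr["tc"],
            statuses=arr["statuses"],
            direction=arr["direction"],
            bin_edges=arr["bin_edges"],
            log_ratio=arr["log_ratio"],
            log_prior_ratio=arr["log_prior_ratio"],
            assignment=arr["assignment"],
        )


@dataclass
class GroupComposition:
    """Genes defining one group, ranked by descending mutual information."""

    group_id: int
    genes: list[tuple[str, float, int]]  # (gene_id, mi, direction)


@dataclass
class StatusResult:
    """Inferred statuses plus reliability metadata for a new cohort."""

    statuses: np.ndarray            # (m_new, d) binary
    unreliable_groups: np.ndarray   # (d,) bool: >50% of composition genes absent
    missing_gene_ids: list[str]

    def __array__(self, dtype=None, copy=None):
        return np.asarray(self.statuses, dtype=dtype)


# ---------------------------------------------------------------------------
# discretisation and information measures


def _fit_bin_edges(values: np.ndarray, n_bins: int) -> np.ndarray:
    qs = np.linspace(0, 1, n_bins + 1)[1:-1]
    return np.quantile(values, qs, axis=0).T  # (n, n_bins - 1)


def _discretize(values: np.ndarray, edges: np.ndarray) -> np.ndarray:
    out = np.empty(values.shape, dtype=np.int8)
    for j in range(values.shape[1]):
        out[:, j] = np.searchsorted(edges[j], values[:, j], side="left")
    return out


def _bin_counts(disc: np.ndarray, y: np.ndarray, n_bins: int) -> np.ndarray:
    """Counts (2, n_bins, n): joint table of status c and bin b per gene."""
    n = disc.shape[1]
    counts = np.empty((2, n_bins, n))
    for c in (0, 1):
        sub = disc[y == c]
        for b in range(n_bins):
            counts[c, b] = (sub == b).sum(axis=0)
    return counts


def _mi_from_counts(counts: np.ndarray) -> np.ndarray:
    """Plugin MI (nats) per gene from smoothed (2, B, n) joint counts."""
    c = counts + _SMOOTH
    total = c.sum(axis=(0, 1))
    p = c / total  # (2, B, n)
    pc = p.sum(axis=1)  # (2, n)
    pb = p.sum(axis=0)  # (B, n)
    ratio = p / (pc[:, None, :] * pb[None, :, :])
    return np.maximum((p * np.log(ratio)).sum(axis=(0, 1)), 0.0)


def _entropy_bernoulli(p: float) -> float:
    p = min(max(p, 1e-12), 1 - 1e-12)
    return float(-p * np.log(p) - (1 - p) * np.log(1 - p))


def _nb_parameters(disc, y, n_bins):
    """Naive-Bayes tables for one factor: per-gene log p(b|y=1)-log p(b|y=0)."""
    counts = _bin_counts(disc, y, n_bins) + _SMOOTH
    p = counts / counts.sum(axis=1, keepdims=True)  # (2, B, n) p(b | c)
    log_ratio = np.log(p[1]) - np.log(p[0])  # (B, n)
    m = len(y)
    prior = np.clip(y.mean(), 1.0 / (m + 1), m / (m + 1.0))
    return log_ratio.T, float(np.log(prior) - np.log1p(-prior))  # (n, B)


def _posterior_status(disc, log_ratio, log_prior_ratio, member):
    """Binarised posterior (llr > 0 <=> posterior > 0.5) for one factor."""
    if not member.any():
        return np.zeros(disc.shape[0], dtype=np.int8)
    idx = np.flatnonzero(member)
    llr = log_prior_ratio + np.take_along_axis(
        log_ratio[idx].T, disc[:, idx], axis=0
    ).sum(axis=1)
    return (llr > 0).astype(np.int8)


# ---------------------------------------------------------------------------
# fitting


def _initial_statuses(values: np.ndarray, d: int, rng: np.random.Generator):
    """Seed statuses from the top-d principal directions of the correlation
    matrix: co-expression blocks dominate separate eigenvectors, so distinct
    planted factors start from distinct, near-orthogonal score vectors."""
    m, n = values.shape
    sd = values.std(axis=0)
    z = values / np.where(sd == 0, 1.0, sd)
    corr = (z.T @ z) / m
    w, v = np.linalg.eigh(corr)
    order = np.argsort(-w, kind="stable")
    statuses = np.zeros((m, d), dtype=np.int8)
    for k in range(d):
        if k < n:
            scores = values @ v[:, order[k]]
        else:  # more groups than genes is rejected upstream; guard anyway
            scores = rng.normal(size=m)
        y = (scores > np.median(scores)).astype(np.int8)
        if y.min() == y.max():  # degenerate split: randomise deterministically
            y = (rng.random(m) < 0.5).astype(np.int8)
        statuses[:, k] = y
    return statuses


def discover_groups(
    matrix: ExpressionMatrix,
    n_groups: int,
    n_iterations: int = 100,
    seed: int = 0,
    n_bins: int = 3,
    tol: float = 1e-6,
) -> GroupModel:
    """Fit d binary latent factors explaining gene co-dependence.

    Deterministic for fixed (matrix, n_groups, n_iterations, seed).  Groups
    are returned sorted by non-increasing explained total correlation.
    """
    if n_groups < 1 or n_iterations < 1:
        raise ValueError("n_groups and n_iterations must be >= 1")
    if n_groups > matrix.n_genes:
        raise ValueError("n_groups cannot exceed the number of genes")
    rng = np.random.default_rng(seed)
    values = matrix.values
    m, n = values.shape
    edges = _fit_bin_edges(values, n_bins)
    disc = _discretize(values, edges)

    statuses = _initial_statuses(values, n_groups, rng)
    assignment = None
    prev_total_tc = -np.inf
    mi = np.zeros((n, n_groups))
    for _ in range(n_iterations):
        # (a) information of each gene about each factor's current status
        for k in range(n_groups):
            mi[:, k] = _mi_from_counts(_bin_counts(disc, statuses[:, k], n_bins))
        # (b) hard assignment: each gene joins its most informative factor
        assignment = np.argmax(mi, axis=1)  # ties -> lowest group index
        # (c) per-sample posterior status under the assigned genes
        total_tc = 0.0
        for k in range(n_groups):
            member = assignment == k
            log_ratio, lpr = _nb_parameters(disc, statuses[:, k], n_bins)
            statuses[:, k] = _posterior_status(disc, log_ratio, lpr, member)
            h = _entropy_bernoulli(statuses[:, k].mean())
            total_tc += max(0.0, mi[member, k].sum() - h)
        if abs(total_tc - prev_total_tc) < tol:
            break
        prev_total_tc = total_tc

    # final parameters + polarity, then statuses via the inference path
    for k in range(n_groups):
        mi[:, k] = _mi_from_counts(_bin_counts(disc, statuses[:, k], n_bins))
    assignment = np.argmax(mi, axis=1)
    log_ratio = np.zeros((n_groups, n, n_bins))
    log_prior_ratio = np.zeros(n_groups)
    for k in range(n_groups):
        lr, lpr = _nb_parameters(disc, statuses[:, k], n_bins)
        top = int(np.argmax(mi[:, k]))  # ties -> gene-id (column) order
        med1 = np.median(values[statuses[:, k] == 1, top]) if statuses[:, k].any() else 0.0
        med0 = np.median(values[statuses[:, k] == 0, top]) if (statuses[:, k] == 0).any() else 0.0
        if med1 < med0:  # orient so the top gene is over-expressed at status 1
            lr, lpr = -lr, -lpr
            statuses[:, k] = 1 - statuses[:, k]
        log_ratio[k] = lr
        log_prior_ratio[k] = lpr
        statuses[:, k] = _posterior_status(disc, lr, lpr, assignment == k)

    # report MI/TC/direction with respect to the stored statuses
    tc = np.zeros(n_groups)
    direction = np.zeros((n, n_groups), dtype=np.int8)
    for k in range(n_groups):
        mi[:, k] = _mi_from_counts(_bin_counts(disc, statuses[:, k], n_bins))
        member = assignment == k
        tc[k] = max(
            0.0,
            mi[member, k].sum() - _entropy_bernoulli(statuses[:, k].mean()),
        )
        on, off = statuses[:, k] == 1, statuses[:, k] == 0
        med1 = np.median(values[on], axis=0) if on.any() else np.zeros(n)
        med0 = np.median(values[off], axis=0) if off.any() else np.zeros(n)
        direction[:, k] = np.where(med1 > med0, 1, -1)
    direction[mi <= 0] = 0

    order = np.argsort(-tc, kind="stable")
    model = GroupModel(
        n_groups=n_groups,
        gene_ids=list(matrix.gene_ids),
        sample_ids=list(matrix.sample_ids),
        mi=mi[:, order],
        tc=tc[order],
        statuses=statuses[:, order].astype(np.int8),
        direction=direction[:, order],
        seed=seed,
        n_bins=n_bins,
        bin_edges=edges,
        log_ratio=log_ratio[order],
        log_prior_ratio=log_prior_ratio[order],
        assignment=_remap(assignment, order),
    )
    return model


def _remap(assignment: np.ndarray, order: np.ndarray) -> np.ndarray:
    """Relabel gene assignments after groups were reordered by ``order``."""
    inv = np.empty(len(order), dtype=int)
    inv[order] = np.arange(len(order))
    return inv[assignment]


def infer_status(model: GroupModel, matrix: ExpressionMatrix) -> StatusResult:
    """Apply a trained factor model to new samples (no refitting; idempotent).

    Genes the model knows but the matrix lacks are mean-imputed (zero on the
    z-score scale) and logged; a group with more than half of its member genes
    absent is flagged unreliable in the result metadata.
    """
    col = {g: j for j, g in enumerate(matrix.gene_ids)}
    n = model.n_genes
    values = np.zeros((matrix.n_samples, n))
    missing = []
    for i, g in enumerate(model.gene_ids):
        j = col.get(g)
        if j is None:
            missing.append(g)
        else:
            values[:, i] = matrix.values[:, j]
    if missing:
        logger.warning("%d model genes absent from matrix; mean-imputed", len(missing))
    present = np.array([g not in set(missing) for g in model.gene_ids])

    disc = _discretize(values, model.bin_edges)
    d = model.n_groups
    statuses = np.zeros((matrix.n_samples, d), dtype=np.int8)
    unreliable = np.zeros(d, dtype=bool)
    for k in range(d):
        member = model.assignment == k
        statuses[:, k] = _posterior_status(
            disc, model.log_ratio[k], model.log_prior_ratio[k], member
        )
        if member.any():
            unreliable[k] = present[member].mean() < 0.5
        else:
            unreliable[k] = True
    return StatusResult(statuses, unreliable, missing)


def group_composition(
    model: GroupModel,
    group_id: int,
    max_genes: int = 400,
    mi_threshold: float = 0.002,
) -> GroupComposition:
    """Top genes of one group: descending MI, above threshold, capped."""
    if not 0 <= group_id < model.n_groups:
        raise ValueError(f"group_id {group_id} out of range")
    mi_k = model.mi[:, group_id]
    order = np.argsort(-mi_k, kind="stable")
    genes = [
        (model.gene_ids[i], float(mi_k[i]), int(model.direction[i, group_id]))
        for i in order
        if mi_k[i] > mi_threshold
    ][:max_genes]
    return GroupComposition(group_id=group_id, genes=genes)


def tc_curve(
    matrix: ExpressionMatrix,
    d_grid: list[int],
    n_iterations: int = 100,
    seed: int = 0,
) -> list[tuple[int, float]]:
    """Total explained TC at each candidate d; used to locate the plateau."""
    if not d_grid:
        raise ValueError("d_grid must be non-empty")
    out = []
    for d in d_grid:
        model = discover_groups(matrix, d, n_iterations=n_iterations, seed=seed)
        out.append((d, float(model.tc.sum())))
    return out


def state_similarity(predicted, truth) -> float:
    """Cosine similarity between a predicted and a true state vector."""
    p = np.asarray(predicted, dtype=float).ravel()
    t = np.asarray(truth, dtype=float).ravel()
    if p.shape != t.shape:
        raise ValueError("state vectors must have equal length")
    np_, nt = np.linalg.norm(p), np.linalg.norm(t)
    if np_ == 0 or nt == 0:
        raise ValueError("cosine similarity undefined for zero-norm vectors")
    return float(p @ t / (np_ * nt))


def match_statuses(predicted: np.ndarray, truth: np.ndarray):
    """Optimally match predicted factors to planted factors (with polarity).

    Returns (mapping, agreement, flipped): ``mapping[j]`` is the predicted
    column matched to true factor j, ``agreement[j]`` the per-factor fraction
    of samples agreeing after the optimal polarity flip.
    """
    predicted = np.asarray(predicted)
    truth = np.asarray(truth)
    m = truth.shape[0]
    agree = (predicted[:, None, :] == truth[:, :, None]).mean(axis=0)  # (true, pred)
    best = np.maximum(agree, 1 - agree)
    ti, pi = linear_sum_assignment(-best)
    mapping = np.empty(truth.shape[1], dtype=int)
    agreement = np.empty(truth.shape[1])
    flipped = np.zeros(truth.shape[1], dtype=bool)
    for t, p in zip(ti, pi):
        mapping[t] = p
        agreement[t] = best[t, p]
        flipped[t] = agree[t, p] < 0.5
    return mapping, agreement, flipped
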