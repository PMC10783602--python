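"""Expression-matrix containers, normalisation and gene selection.

Input matrices are samples x genes (cBioPortal-style log2 values or raw
counts).  Normalisation applies log2(x+1) where needed followed by a per-gene
z-score; gene selection keeps the top-k genes by variance of the log2 values
(computed before z-scoring) plus an always-keep list of known driver genes.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


@dataclass
class ExpressionMatrix:
    """A samples x genes numeric matrix with identifiers.

    ``values`` holds log2-transformed, per-gene z-scored expression.
    ``log2_variance`` is the per-gene variance of the log2 values *before*
    z-scoring; it is carried so that variance-based gene selection operates on
    the scale the variance ranking is defined on.
    """

    sample_ids: list[str]
    gene_ids: list[str]
    values: np.ndarray
    log2_variance: np.ndarray | None = field(default=None, repr=False)

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    def gene_index(self, gene_id: str) -> int:
        return self.gene_ids.index(gene_id)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.gene_ids)

    def subset_genes(self, gene_ids: list[str]) -> "ExpressionMatrix":
        idx = [self.gene_ids.index(g) for g in gene_ids]
        lv = None if self.log2_variance is None else self.log2_variance[idx]
        return ExpressionMatrix(
            sample_ids=list(self.sample_ids),
            gene_ids=list(gene_ids),
            values=self.values[:, idx],
            log2_variance=lv,
        )


def read_expression(path, genes_in: str = "auto") -> pd.DataFrame:
    """Read a TSV/CSV expression table into a samples x genes DataFrame.

    ``genes_in`` is "columns", "rows" or "auto".  Auto-detection assumes the
    axis with more entries is the gene axis (cohorts have far fewer samples
    than genes); cBioPortal exports (genes as rows) are read directly.
    """
    sep = "," if str(path).endswith(".csv") else "\t"
    df = pd.read_csv(path, sep=sep, index_col=0)
    bad = df.map(lambda v: isinstance(v, str))
    if bad.to_numpy().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise ValueError(
            f"non-numeric entry at row {df.index[r]!r}, column {df.columns[c]!r}"
        )
    if genes_in == "rows" or (genes_in == "auto" and df.shape[0] > df.shape[1]):
        df = df.T
    return df


def normalize_expression(
    raw,
    already_log2: bool = False,
    sample_ids: list[str] | None = None,
    gene_ids: list[str] | None = None,
    ddof: int = 0,
    max_missing_fraction: float = 0.20,
) -> ExpressionMatrix:
    """log2-transform (unless ``already_log2``) and per-gene z-score a matrix.

    Accepts a samples x genes DataFrame or array.  Missing values: genes with
    more than ``max_missing_fraction`` missing entries are dropped, the rest
    are mean-imputed before transformation.  Constant genes map to all-zero
    columns (zero-variance guard).  The z-score uses the population standard
    deviation by default (``ddof=0``).
    """
    if isinstance(raw, pd.DataFrame):
        sample_ids = list(map(str, raw.index))
        gene_ids = list(map(str, raw.columns))
        values = raw.to_numpy(dtype=float)
    else:
        values = np.asarray(raw, dtype=float)
        if values.ndim != 2:
            raise ValueError("expression matrix must be 2-D (samples x genes)")
        if sample_ids is None:
            sample_ids = [f"S{i}" for i in range(values.shape[0])]
        if gene_ids is None:
            gene_ids = [f"G{j}" for j in range(values.shape[1])]
    if values.size == 0:
        raise ValueError("empty expression matrix")

    missing = np.isnan(values)
    if missing.any():
        frac = missing.mean(axis=0)
        keep = frac <= max_missing_fraction
        dropped = [g for g, k in zip(gene_ids, keep) if not k]
        if dropped:
            logger.warning("dropping %d genes with >%d%% missing values",
                           len(dropped), int(100 * max_missing_fraction))
        values = values[:, keep]
        gene_ids = [g for g, k in zip(gene_ids, keep) if k]
        missing = missing[:, keep]
        col_mean = np.nanmean(values, axis=0)
        values = np.where(missing, col_mean[None, :], values)

    if not already_log2:
        if (values < 0).any():
            raise ValueError("raw expression must be non-negative before log2(x+1)")
        values = np.log2(values + 1.0)

    log2_variance = values.var(axis=0, ddof=ddof)
    sd = np.sqrt(log2_variance)
    mean = values.mean(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (values - mean[None, :]) / sd[None, :]
    z[:, sd == 0] = 0.0  # constant genes -> all-zero column
    return ExpressionMatrix(sample_ids, list(gene_ids), z, log2_variance)


def select_genes(
    matrix: ExpressionMatrix,
    top_k_by_variance: int,
    always_keep: list[str] | None = None,
) -> ExpressionMatrix:
    """Keep the top-k genes by pre-z-scoring (log2) variance plus ``always_keep``.

    The returned gene set is the union, in the matrix's stable gene-id order,
    so the identical selection can be re-applied to validation cohorts via
    :meth:`ExpressionMatrix.subset_genes`.  Absent always-keep genes are
    skipped with a warning.
    """
    if top_k_by_variance > matrix.n_genes:
        raise ValueError("top_k_by_variance exceeds the number of genes")
    variance = matrix.log2_variance
    if variance is None:
        variance = matrix.values.var(axis=0)
    order = np.argsort(-variance, kind="stable")
    chosen = set(np.asarray(matrix.gene_ids)[order[:top_k_by_variance]])
    for g in always_keep or []:
        if g in matrix.gene_ids:
            chosen.add(g)
        else:
            warnings.warn(f"always_keep gene {g!r} absent from matrix; skipped")
            logger.warning("always_keep gene %r absent from matrix; skipped", g)
    kept = [g for g in matrix.gene_ids if g in chosen]
    return matrix.subset_genes(kept)
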