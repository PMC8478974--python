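"""Diffusion-based denoising of normalized expression.

A row-stochastic cell-cell Markov operator is built from an adaptive
Gaussian-like kernel on a k-nearest-neighbour graph in PC space; the
imputed matrix is the operator applied ``t`` times to the cell profiles.
Imputation runs on log-normalized values because downstream correlation
analyses are scale-sensitive.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors

from .containers import GeneMatrix

logger = logging.getLogger(__name__)

__all__ = ["DiffusionOperator", "build_diffusion_operator", "impute", "co_expression"]


@dataclass
class DiffusionOperator:
    """Row-stochastic cell x cell transition matrix plus its parameters."""

    matrix: sp.csr_matrix
    cell_ids: np.ndarray
    params: dict

    def __post_init__(self):
        rows = np.asarray(self.matrix.sum(axis=1)).ravel()
        if not np.allclose(rows, 1.0, atol=1e-10):
            raise ValueError("operator rows must sum to 1 within 1e-10")
        if self.matrix.data.size and self.matrix.data.min() < 0:
            raise ValueError("operator entries must be non-negative")


def build_diffusion_operator(normalized: GeneMatrix, k: int = 15, ka: int = 4,
                             decay: float = 2.0, n_pcs: int = 20) -> DiffusionOperator:
    """Adaptive-kernel kNN Markov operator over cells.

    Distances are Euclidean in ``n_pcs`` principal components.  Each
    cell's bandwidth is its distance to the ``ka``-th neighbour; the
    affinity to a neighbour at distance d is ``exp(-(d / sigma)**decay)``.
    The affinity matrix is symmetrised by summation before row
    normalization.  Duplicate cells (zero bandwidth) get a bandwidth
    floored at machine epsilon with a warning.
    """
    n_cells = normalized.n_cells
    if n_cells <= k:
        raise ValueError(f"need more than k={k} cells, got {n_cells}")
    if not 1 <= ka <= k:
        raise ValueError("ka must lie in [1, k]")
    X = normalized.dense().T  # cells x genes
    n_comp = min(n_pcs, n_cells - 1, X.shape[1])
    if n_comp < n_pcs:
        logger.warning("n_pcs=%d clipped to %d", n_pcs, n_comp)
    if n_comp >= 1 and X.std(axis=0).max() > 0:
        Y = PCA(n_components=n_comp, random_state=0).fit_transform(X)
    else:
        Y = X
    nn = NearestNeighbors(n_neighbors=k + 1).fit(Y)
    dist, idx = nn.kneighbors(Y)
    # drop self by index (duplicated points can shadow the self column)
    keep_d = np.empty((n_cells, k))
    keep_i = np.empty((n_cells, k), dtype=int)
    for i in range(n_cells):
        mask = idx[i] != i
        keep_d[i] = dist[i, mask][:k]
        keep_i[i] = idx[i, mask][:k]
    dist, idx = keep_d, keep_i

    sigma = dist[:, ka - 1].copy()
    dup = sigma <= 0
    if dup.any():
        logger.warning("%d cells have zero bandwidth (duplicates); flooring", int(dup.sum()))
        sigma[dup] = np.finfo(float).eps
    aff = np.exp(-np.power(dist / sigma[:, None], decay))
    rows = np.repeat(np.arange(n_cells), k)
    A = sp.csr_matrix((aff.ravel(), (rows, idx.ravel())), shape=(n_cells, n_cells))
    A = A + A.T
    rowsum = np.asarray(A.sum(axis=1)).ravel()
    P = sp.diags(1.0 / rowsum) @ A
    # renormalize exactly to guard against floating error
    P = sp.diags(1.0 / np.asarray(P.sum(axis=1)).ravel()) @ P
    return DiffusionOperator(P.tocsr(), normalized.cell_ids.copy(),
                             {"k": k, "ka": ka, "decay": decay, "n_pcs": n_pcs})


def impute(normalized: GeneMatrix, operator: DiffusionOperator, t: int = 3) -> GeneMatrix:
    """Apply the diffusion operator ``t`` times to the cell profiles.

    ``t = 0`` returns the input unchanged.  Each imputed value is a
    convex combination of observed values of the same gene, so the
    per-gene range can only shrink.
    """
    if t < 0:
        raise ValueError("t must be a non-negative integer")
    if list(operator.cell_ids) != list(normalized.cell_ids):
        raise ValueError("operator and matrix must share the same cell set")
    Y = normalized.dense().T  # cells x genes
    for _ in range(int(t)):
        Y = operator.matrix @ Y
    return GeneMatrix(Y.T, normalized.gene_ids.copy(), normalized.cell_ids.copy(),
                      normalized.species)


def co_expression(imputed: GeneMatrix, gene_a: str, gene_b: str, labels,
                  positive_threshold: float = 0.0):
    """Per-cell-type Pearson correlation and co-positive fraction.

    Returns a DataFrame with one row per cell type: correlation of the
    two genes' imputed values, the fraction of cells where both exceed
    ``positive_threshold``, and a degeneracy flag raised when either
    gene has zero variance within the type (correlation reported as 0).
    """
    import pandas as pd

    labels = np.asarray(labels)
    if len(labels) != imputed.n_cells:
        raise ValueError("labels must align with cells")
    xa = imputed.expression(gene_a)
    xb = imputed.expression(gene_b)
    rows = []
    for t in pd.unique(labels):
        mask = labels == t
        a, b = xa[mask], xb[mask]
        degenerate = bool(a.std() == 0 or b.std() == 0)
        r = 0.0 if degenerate else float(np.corrcoef(a, b)[0, 1])
        co_pos = float(np.mean((a > positive_threshold) & (b > positive_threshold)))
        rows.append({"cell_type": t, "correlation": r, "co_positive_fraction": co_pos,
                     "degenerate": degenerate})
    return pd.DataFrame(rows)
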