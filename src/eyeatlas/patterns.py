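"""Non-negative expression patterns and their cross-species projection.

Patterns are learned by deterministic multiplicative-update NMF (a
seedable stand-in with the same non-negativity semantics as Bayesian
sparse factorizations used for single-cell pattern discovery).  The
model is a gene-side amplitude matrix (columns L1-normalised) and a
cell-side weight matrix.  Projection into a second dataset fixes the
amplitudes — translated through an explicit ortholog map — and fits
each new cell by non-negative least squares.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import nnls

from .containers import GeneMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "PatternModel",
    "learn_patterns",
    "project_patterns",
    "pattern_celltype_correlation",
    "top_pattern_genes",
]

_EPS = 1e-12


@dataclass
class PatternModel:
    """NMF factors: amplitude (genes x patterns, columns sum to 1) and
    weights (patterns x cells), plus the objective trace."""

    amplitude: np.ndarray
    weights: np.ndarray
    gene_ids: np.ndarray
    cell_ids: np.ndarray
    objective: np.ndarray
    seed: int

    @property
    def n_patterns(self) -> int:
        return self.amplitude.shape[1]

    def __post_init__(self):
        if (self.amplitude < 0).any() or (self.weights < 0).any():
            raise ValueError("factors must be non-negative")
        if not np.allclose(self.amplitude.sum(axis=0), 1.0, atol=1e-8):
            raise ValueError("amplitude columns must sum to 1")


def learn_patterns(normalized: GeneMatrix, n_patterns: int, seed: int = 0,
                   max_iter: int = 500, tol: float = 1e-6) -> PatternModel:
    """Multiplicative-update NMF minimising squared reconstruction error.

    Iterates until the relative objective change drops below ``tol`` or
    ``max_iter`` is reached; the objective is asserted non-increasing at
    every iteration (the multiplicative-update guarantee).  Amplitude
    columns are L1-normalised afterwards, with the scale moved into the
    weights, making the factorization unique up to pattern permutation.
    """
    X = normalized.dense()
    if (X < 0).any():
        raise ValueError("input must be non-negative")
    n_genes, n_cells = X.shape
    if not 1 <= n_patterns <= min(n_genes, n_cells):
        raise ValueError("n_patterns must lie in [1, min(genes, cells)]")
    rng = np.random.default_rng(seed)
    scale = np.sqrt(X.mean() / n_patterns) + _EPS
    W = rng.uniform(0.1, 1.0, size=(n_genes, n_patterns)) * scale
    H = rng.uniform(0.1, 1.0, size=(n_patterns, n_cells)) * scale

    trace = [float(np.linalg.norm(X - W @ H) ** 2)]
    for it in range(max_iter):
        H *= (W.T @ X) / (W.T @ W @ H + _EPS)
        W *= (X @ H.T) / (W @ (H @ H.T) + _EPS)
        obj = float(np.linalg.norm(X - W @ H) ** 2)
        assert obj <= trace[-1] * (1 + 1e-9) + 1e-12, "objective increased"
        rel = abs(trace[-1] - obj) / max(trace[-1], _EPS)
        trace.append(obj)
        if rel < tol:
            break
    colsum = W.sum(axis=0)
    colsum[colsum == 0] = 1.0
    A = W / colsum
    Hs = H * colsum[:, None]
    return PatternModel(A, Hs, normalized.gene_ids.copy(), normalized.cell_ids.copy(),
                        np.asarray(trace), seed)


def project_patterns(model: PatternModel, new_normalized: GeneMatrix,
                     ortholog_map: pd.DataFrame = None) -> np.ndarray:
    """Fit new cells onto fixed (ortholog-mapped) amplitudes by NNLS.

    ``ortholog_map`` translates model genes into the new dataset's gene
    identifiers (two columns: model gene, target gene); omit it when the
    datasets share identifiers.  Amplitude columns are re-normalised
    after subsetting to the mapped genes.  Fewer than 10% mapped genes
    is an error; fewer than 50% a warning.  Returns a non-negative
    patterns x cells weight matrix.
    """
    if ortholog_map is None:
        lut = {g: g for g in model.gene_ids}
    else:
        a_col, b_col = ortholog_map.columns[:2]
        lut = dict(zip(ortholog_map[a_col], ortholog_map[b_col]))
    present = set(new_normalized.gene_ids)
    keep, new_names = [], []
    for i, g in enumerate(model.gene_ids):
        tgt = lut.get(g)
        if tgt is not None and tgt in present:
            keep.append(i)
            new_names.append(tgt)
    frac = len(keep) / len(model.gene_ids)
    if len(keep) == 0:
        raise ValueError("no model genes mapped into the new dataset")
    if frac < 0.10:
        raise ValueError(f"only {frac:.1%} of amplitude genes mapped (< 10%)")
    if frac < 0.50:
        warnings.warn(f"only {frac:.1%} of amplitude genes mapped (< 50%)")

    A = model.amplitude[keep]
    colsum = A.sum(axis=0)
    colsum[colsum == 0] = 1.0
    A = A / colsum
    X = new_normalized.to_frame(new_names).to_numpy()
    weights = np.empty((model.n_patterns, new_normalized.n_cells))
    for c in range(new_normalized.n_cells):
        weights[:, c] = nnls(A, X[:, c])[0]
    return weights


def pattern_celltype_correlation(weights: np.ndarray, labels) -> pd.DataFrame:
    """Pearson correlation of each pattern with each cell-type indicator.

    A point-biserial heat-map semantics: pattern weight vectors are
    correlated with one-hot type indicators across cells.  A constant
    pattern correlates 0 with every type and is flagged in the attached
    ``degenerate`` column.
    """
    weights = np.atleast_2d(np.asarray(weights, dtype=float))
    labels = np.asarray(labels)
    if weights.shape[1] != len(labels):
        raise ValueError("labels must align with weight columns (cells)")
    types = list(pd.unique(labels))
    if len(types) < 2:
        raise ValueError("need at least 2 cell types")
    out = np.zeros((weights.shape[0], len(types)))
    degenerate = np.zeros(weights.shape[0], dtype=bool)
    for p in range(weights.shape[0]):
        w = weights[p]
        if w.std() == 0:
            degenerate[p] = True
            continue
        for j, t in enumerate(types):
            ind = (labels == t).astype(float)
            if ind.std() == 0:
                continue
            out[p, j] = np.corrcoef(w, ind)[0, 1]
    df = pd.DataFrame(out, index=[f"P{p + 1}" for p in range(weights.shape[0])],
                      columns=types)
    df["degenerate"] = degenerate
    return df


def top_pattern_genes(model: PatternModel, pattern_id: int, n: int = 20,
                      exclude=(), against=None):
    """Top-``n`` genes of one pattern by amplitude weight, after exclusion.

    ``exclude`` lists genes removed before truncation (artefact genes).
    When ``against`` (a second gene list) is supplied, overlap
    statistics (intersection size, Jaccard) of the returned list against
    it are reported.  Returns ``(genes, overlap)`` where ``overlap`` is
    None without ``against``.
    """
    if not 0 <= pattern_id < model.n_patterns:
        raise KeyError(f"unknown pattern id {pattern_id}")
    excl = set(exclude)
    order = np.argsort(-model.amplitude[:, pattern_id], kind="mergesort")
    ranked = [model.gene_ids[i] for i in order if model.gene_ids[i] not in excl]
    top = ranked[:n]
    overlap = None
    if against is not None:
        other = set(against)
        inter = len(set(top) & other)
        union = len(set(top) | other)
        overlap = {"intersection": inter, "jaccard": inter / union if union else 0.0}
    return top, overlap
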