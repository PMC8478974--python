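"""Reading/writing 10x-style matrices, normalization, clustering, markers.

Marker detection follows the common single-cell convention: a one-sided
Wilcoxon rank-sum test per gene and group (group greater than rest) with
an average log2 fold-change filter on pseudocounted, back-transformed
group means.  Defaults are p < 0.01 and |avg_log2FC| > 0.25.
"""

from __future__ import annotations

import gzip
import logging
import warnings
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp
from scipy.stats import norm

from .containers import CountMatrix, GeneMatrix, validate_annotation

logger = logging.getLogger(__name__)

__all__ = [
    "read_counts",
    "write_counts",
    "read_annotation",
    "normalize_log",
    "cluster_cells",
    "rank_markers",
    "wilcoxon_one_sided",
    "compare_proportions",
]

# ---------------------------------------------------------------------------
# MTX triplet IO
# ---------------------------------------------------------------------------

_MATRIX_NAMES = ["matrix.mtx", "matrix.mtx.gz"]
_FEATURE_NAMES = ["features.tsv", "features.tsv.gz", "genes.tsv", "genes.tsv.gz"]
_BARCODE_NAMES = ["barcodes.tsv", "barcodes.tsv.gz"]


def _find(path: Path, names) -> Path:
    for n in names:
        p = path / n
        if p.exists():
            return p
    raise FileNotFoundError(f"none of {names} found under {path}")


def _read_lines(p: Path):
    opener = gzip.open if p.suffix == ".gz" else open
    with opener(p, "rt") as fh:
        return [ln.rstrip("\n") for ln in fh if ln.strip()]


def read_counts(path, species: str = "") -> CountMatrix:
    """Read an MTX triplet directory (plain or gzipped) into a CountMatrix.

    Accepts both ``features.tsv`` and the older ``genes.tsv`` name; only
    the first tab-separated column is used as the gene identifier.
    """
    path = Path(path)
    mtx = _find(path, _MATRIX_NAMES)
    feats = _find(path, _FEATURE_NAMES)
    bars = _find(path, _BARCODE_NAMES)
    if mtx.suffix == ".gz":
        with gzip.open(mtx, "rb") as fh:
            mat = scipy.io.mmread(fh)
    else:
        mat = scipy.io.mmread(mtx)
    genes = [ln.split("\t")[0] for ln in _read_lines(feats)]
    cells = [ln.split("\t")[0] for ln in _read_lines(bars)]
    if mat.shape != (len(genes), len(cells)):
        raise ValueError(
            f"matrix header declares {mat.shape} but found "
            f"{len(genes)} features and {len(cells)} barcodes"
        )
    return CountMatrix(sp.csr_matrix(mat), np.array(genes, dtype=object),
                       np.array(cells, dtype=object), species=species)


def write_counts(matrix: CountMatrix, path) -> None:
    """Write matrix.mtx + features.tsv + barcodes.tsv under ``path``."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    scipy.io.mmwrite(str(path / "matrix.mtx"), sp.coo_matrix(matrix.values))
    (path / "features.tsv").write_text("\n".join(str(g) for g in matrix.gene_ids) + "\n")
    (path / "barcodes.tsv").write_text("\n".join(str(c) for c in matrix.cell_ids) + "\n")


def read_annotation(path) -> pd.DataFrame:
    """Read a header-carrying annotation TSV and validate its invariants."""
    return validate_annotation(pd.read_csv(path, sep="\t"))


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------

def normalize_log(counts: CountMatrix, scale: float = 1e4) -> GeneMatrix:
    """Library-size normalize then log1p: log1p(count / cell_total * scale).

    Raises if any cell has zero total count, naming the offending cell.
    """
    totals = np.asarray(counts.values.sum(axis=0)).ravel().astype(float)
    if (totals <= 0).any():
        bad = counts.cell_ids[int(np.argmax(totals <= 0))]
        raise ValueError(f"cell {bad!r} has zero total count; cannot normalize")
    X = counts.values.tocsc(copy=True).astype(float)
    X = X.multiply(scale / totals[None, :]).tocsr()
    X.data = np.log1p(X.data)
    return GeneMatrix(X.tocsr(), counts.gene_ids.copy(), counts.cell_ids.copy(), counts.species)


# ---------------------------------------------------------------------------
# clustering
# ---------------------------------------------------------------------------

def cluster_cells(normalized: GeneMatrix, n_hvg: int = 2000, n_pcs: int = 20,
                  resolution: float = 1.0, seed: int = 0) -> np.ndarray:
    """Cluster cells: HVG selection, PCA, kNN graph, Leiden communities.

    The stack (dispersion-ranked highly-variable genes, principal
    components, k-nearest-neighbour graph, modularity community
    detection) is a stated stand-in for the original unsupervised graph
    clustering; it is deterministic given ``seed``.  Requested ``n_hvg``
    / ``n_pcs`` exceeding the data are clipped with a logged warning.
    Returns contiguous integer labels from 0.
    """
    import scanpy as sc

    if normalized.n_cells < 2:
        raise ValueError("need at least 2 cells to cluster")
    X = normalized.dense()
    # degenerate input: no gene varies across cells -> one cluster
    if np.allclose(X.max(axis=1), X.min(axis=1)):
        return np.zeros(normalized.n_cells, dtype=int)

    adata = normalized.to_anndata()
    if n_hvg > normalized.n_genes:
        logger.warning("n_hvg=%d clipped to %d available genes", n_hvg, normalized.n_genes)
        n_hvg = normalized.n_genes
    if n_hvg < normalized.n_genes:
        sc.pp.highly_variable_genes(adata, n_top_genes=n_hvg, flavor="seurat")
        adata = adata[:, adata.var["highly_variable"]].copy()
    max_pcs = min(adata.n_obs - 1, adata.n_vars - 1)
    if n_pcs > max_pcs:
        logger.warning("n_pcs=%d clipped to %d", n_pcs, max_pcs)
        n_pcs = max(1, max_pcs)
    sc.pp.pca(adata, n_comps=n_pcs, random_state=seed)
    n_neighbors = min(15, adata.n_obs - 1)
    sc.pp.neighbors(adata, n_neighbors=n_neighbors, random_state=seed)
    sc.tl.leiden(adata, resolution=resolution, random_state=seed,
                 flavor="igraph", n_iterations=2, directed=False)
    labels = adata.obs["leiden"].astype(int).to_numpy()
    # re-index contiguously in first-appearance order
    _, labels = np.unique(labels, return_inverse=True)
    return labels.astype(int)


# ---------------------------------------------------------------------------
# Wilcoxon rank-sum marker test
# ---------------------------------------------------------------------------

def wilcoxon_one_sided(values: np.ndarray, in_group: np.ndarray,
                       exact_max_n: int = 12) -> np.ndarray:
    """Vectorized one-sided (group > rest) rank-sum p-values per gene.

    ``values`` is genes x cells; ``in_group`` a boolean cell mask.  For
    small samples (total cells <= ``exact_max_n``) the p-value is the
    exact permutation tail P(W >= W_obs) over all label assignments,
    computed on midranks so ties are handled exactly.  Larger samples
    use the tie-corrected normal approximation without continuity
    correction, so swapping the groups maps p to 1 - p.  Genes tied
    across every cell carry no information and report p = 0.5.
    """
    values = np.atleast_2d(np.asarray(values, dtype=float))
    in_group = np.asarray(in_group, dtype=bool)
    n = values.shape[1]
    n1 = int(in_group.sum())
    n2 = n - n1
    if n1 == 0 or n2 == 0:
        raise ValueError("both groups must be non-empty")
    if n1 == 1 or n2 == 1:
        logger.warning("rank-sum test with a single-cell group; p-values are coarse")

    from scipy.stats import rankdata

    ranks = rankdata(values, method="average", axis=1)
    W = ranks[:, in_group].sum(axis=1)
    all_tied = np.isclose(values.max(axis=1), values.min(axis=1))
    if n <= exact_max_n:
        p = np.empty(values.shape[0])
        idx = np.arange(n)
        splits = list(combinations(idx, n1))
        for g in range(values.shape[0]):
            if all_tied[g]:
                p[g] = 0.5
                continue
            sums = np.array([ranks[g, list(s)].sum() for s in splits])
            p[g] = np.mean(sums >= W[g] - 1e-9)
        return p

    mu = n1 * (n + 1) / 2.0
    # tie correction on the variance
    tie_term = np.zeros(values.shape[0])
    for g in range(values.shape[0]):
        _, counts = np.unique(values[g], return_counts=True)
        t = counts[counts > 1]
        if t.size:
            tie_term[g] = (t ** 3 - t).sum()
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    p = np.full(values.shape[0], 0.5)
    ok = var > 0
    z = (W[ok] - mu) / np.sqrt(var[ok])
    p[ok] = norm.sf(z)
    return p


def _group_stats(dense: np.ndarray, mask: np.ndarray):
    """Back-transformed group means and expressing fractions."""
    expr = np.expm1(dense)
    mean_in = expr[:, mask].mean(axis=1)
    mean_out = expr[:, ~mask].mean(axis=1)
    pct_in = (dense[:, mask] > 0).mean(axis=1)
    pct_out = (dense[:, ~mask] > 0).mean(axis=1)
    return mean_in, mean_out, pct_in, pct_out


def rank_markers(normalized: GeneMatrix, labels, p_cut: float = 0.01,
                 lfc_cut: float = 0.25) -> pd.DataFrame:
    """Per-group marker table via one-sided rank-sum test plus fold filter.

    For each label and gene the one-sided (group greater than rest)
    rank-sum p-value and ``avg_log2FC = log2((mean_in + 1)/(mean_out + 1))``
    on back-transformed normalized values are computed.  Records passing
    ``p < p_cut`` and ``|avg_log2FC| > lfc_cut`` are returned, sorted by
    ascending p within each group.  Pass ``p_cut > 1`` and a negative
    ``lfc_cut`` to retrieve the unfiltered table.
    """
    labels = np.asarray(labels)
    if len(labels) != normalized.n_cells:
        raise ValueError("labels must align with cells")
    groups = pd.unique(labels)
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    dense = normalized.dense()
    out = []
    for g in groups:
        mask = labels == g
        p = wilcoxon_one_sided(dense, mask)
        mean_in, mean_out, pct_in, pct_out = _group_stats(dense, mask)
        lfc = np.log2((mean_in + 1.0) / (mean_out + 1.0))
        tab = pd.DataFrame(
            {
                "gene": normalized.gene_ids,
                "cell_type": g,
                "p_value": p,
                "avg_log2FC": lfc,
                "pct_in": pct_in,
                "pct_out": pct_out,
            }
        )
        tab = tab[(tab["p_value"] < p_cut) & (tab["avg_log2FC"].abs() > lfc_cut)]
        out.append(tab.sort_values("p_value", kind="mergesort"))
    return pd.concat(out, ignore_index=True)


# ---------------------------------------------------------------------------
# cell-type proportion shifts between conditions
# ---------------------------------------------------------------------------

def compare_proportions(annot_a: pd.DataFrame, annot_b: pd.DataFrame,
                        n_perm: int = 1000, seed: int = 0) -> pd.DataFrame:
    """Per-type proportion difference B - A with a permutation p-value.

    Condition labels are permuted over the pooled cells; the two-sided
    p-value is ``(1 + #{|perm delta| >= |observed delta|}) / (1 + n_perm)``.
    Deltas sum to zero across types by construction.
    """
    validate_annotation(annot_a)
    validate_annotation(annot_b)
    if annot_a.empty or annot_b.empty:
        raise ValueError("both annotations must be non-empty")
    types = sorted(set(annot_a["cell_type"]) | set(annot_b["cell_type"]))
    ta = np.asarray(annot_a["cell_type"], dtype=object)
    tb = np.asarray(annot_b["cell_type"], dtype=object)
    na, nb = len(ta), len(tb)
    pooled = np.concatenate([ta, tb])
    onehot = np.stack([(pooled == t).astype(float) for t in types])  # types x cells

    obs = onehot[:, na:].mean(axis=1) - onehot[:, :na].mean(axis=1)
    rng = np.random.default_rng(seed)
    exceed = np.zeros(len(types))
    for _ in range(n_perm):
        perm = rng.permutation(na + nb)
        d = onehot[:, perm[na:]].mean(axis=1) - onehot[:, perm[:na]].mean(axis=1)
        exceed += np.abs(d) >= np.abs(obs) - 1e-12
    pvals = (1.0 + exceed) / (1.0 + n_perm)
    return pd.DataFrame({"cell_type": types, "delta": obs, "p_value": pvals})
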