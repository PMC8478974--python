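"""Regulon inference, rank-AUC activity, TF-module detection, conservation.

A regulon is a transcription factor (TF) with an inferred, weighted
target set.  Per-cell activity is the area under the target-set
recovery curve within the top-ranked genes of each cell's expression
ranking (rank-based, hence normalization-free).  Activity and imputed
TF expression are combined into one score per TF and cell, whose
pairwise Pearson correlation across cells defines the TF modules.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
from scipy.spatial.distance import squareform
from scipy.stats import spearmanr

from .containers import GeneMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "Regulon",
    "TFModule",
    "infer_regulons",
    "regulon_activity",
    "combined_tf_score",
    "detect_tf_modules",
    "module_activity",
    "tf_conservation",
]


@dataclass
class Regulon:
    """A TF with its weighted target genes; unusable when too small."""

    tf: str
    targets: list  # list of (gene, importance >= 0)
    min_targets: int = 10

    @property
    def usable(self) -> bool:
        return len(self.targets) >= self.min_targets

    @property
    def target_genes(self) -> list:
        return [g for g, _ in self.targets]

    def __post_init__(self):
        genes = self.target_genes
        if self.tf in genes:
            raise ValueError(f"regulon {self.tf}: TF cannot be its own target")
        if len(set(genes)) != len(genes):
            raise ValueError(f"regulon {self.tf}: duplicate targets")
        if any(w < 0 for _, w in self.targets):
            raise ValueError(f"regulon {self.tf}: negative importance weight")


@dataclass
class TFModule:
    """A disjoint group of co-active TFs with a per-cell activity vector."""

    module_id: str
    member_tfs: list
    activity: np.ndarray = None


# ---------------------------------------------------------------------------
# regulon inference (co-expression stage; motif pruning is out of scope)
# ---------------------------------------------------------------------------

def infer_regulons(normalized: GeneMatrix, tf_list, n_targets: int = 50,
                   method: str = "spearman", min_targets: int = 10,
                   seed: int = 0) -> list:
    """Per TF, the ``n_targets`` genes with highest positive co-expression.

    ``method="spearman"`` ranks candidate targets by Spearman
    correlation with the TF (fast mode); ``method="trees"`` uses
    feature importances of an extra-trees regression of each TF on all
    other genes, signed by correlation.  Only positively associated
    genes are retained.  A constant-expression TF yields an empty,
    flagged regulon.
    """
    if n_targets >= normalized.n_genes:
        raise ValueError("n_targets must be smaller than the number of genes")
    tf_list = list(tf_list)
    normalized.gene_index(tf_list)  # raises on unknown TFs
    X = normalized.dense()
    gene_pos = {g: i for i, g in enumerate(normalized.gene_ids)}
    regulons = []
    for tf in tf_list:
        i = gene_pos[tf]
        x = X[i]
        if x.std() == 0:
            logger.warning("TF %s has constant expression; empty regulon", tf)
            regulons.append(Regulon(tf, [], min_targets=min_targets))
            continue
        if method == "spearman":
            rho = _spearman_vs_all(x, X)
        elif method == "trees":
            rho = _tree_importance(x, X, i, seed)
        else:
            raise ValueError(f"unknown method {method!r}")
        rho[i] = -np.inf  # never select the TF itself
        order = np.argsort(-rho, kind="mergesort")
        targets = []
        for j in order[: n_targets]:
            if rho[j] <= 0 or not np.isfinite(rho[j]):
                break
            targets.append((normalized.gene_ids[j], float(rho[j])))
        regulons.append(Regulon(tf, targets, min_targets=min_targets))
    return regulons


def _spearman_vs_all(x: np.ndarray, X: np.ndarray) -> np.ndarray:
    from scipy.stats import rankdata

    rx = rankdata(x)
    RX = rankdata(X, axis=1)
    rx = rx - rx.mean()
    RX = RX - RX.mean(axis=1, keepdims=True)
    denom = np.sqrt((RX ** 2).sum(axis=1) * (rx ** 2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = (RX @ rx) / denom
    rho[~np.isfinite(rho)] = 0.0
    return rho


def _tree_importance(x: np.ndarray, X: np.ndarray, tf_row: int, seed: int) -> np.ndarray:
    from sklearn.ensemble import ExtraTreesRegressor

    feats = np.delete(np.arange(X.shape[0]), tf_row)
    model = ExtraTreesRegressor(n_estimators=50, random_state=seed, n_jobs=1)
    model.fit(X[feats].T, x)
    imp = np.zeros(X.shape[0])
    imp[feats] = model.feature_importances_
    # sign by correlation: keep positive associations only
    with np.errstate(invalid="ignore"):
        sign = np.array([np.corrcoef(X[j], x)[0, 1] if X[j].std() > 0 else 0.0
                         for j in range(X.shape[0])])
    imp[sign <= 0] = 0.0
    return imp


# ---------------------------------------------------------------------------
# rank-AUC activity
# ---------------------------------------------------------------------------

def regulon_activity(normalized: GeneMatrix, regulons, top_frac: float = 0.05,
                     seed: int = 0) -> pd.DataFrame:
    """TF x cell activity matrix: area under the target recovery curve.

    Per cell, genes are ranked by expression descending with ties broken
    by one seeded global gene permutation; the activity of a regulon is
    the area under the step curve of recovered targets within the top
    ``ceil(top_frac * n_genes)`` ranks, normalized by the maximal
    achievable area, hence in [0, 1].
    """
    if not 0 < top_frac <= 1:
        raise ValueError("top_frac must lie in (0, 1]")
    regulons = [r for r in regulons if r.usable or r.targets]
    if not regulons:
        raise ValueError("no usable regulons")
    for r in regulons:
        present = [g for g in r.target_genes if g in set(normalized.gene_ids)]
        if not present:
            raise ValueError(f"regulon {r.tf}: no target genes present in matrix")
    n_genes = normalized.n_genes
    T = int(np.ceil(top_frac * n_genes))
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n_genes)

    X = normalized.dense()
    # per cell: rank of every gene (1 = highest expression, ties by perm)
    ranks = np.empty((n_genes, normalized.n_cells), dtype=int)
    for c in range(normalized.n_cells):
        order = np.lexsort((perm, -X[:, c]))
        ranks[order, c] = np.arange(1, n_genes + 1)

    gene_pos = {g: i for i, g in enumerate(normalized.gene_ids)}
    out = np.zeros((len(regulons), normalized.n_cells))
    for k, reg in enumerate(regulons):
        tpos = np.array([gene_pos[g] for g in reg.target_genes if g in gene_pos], dtype=int)
        r = ranks[tpos]  # targets x cells
        inside = r <= T
        auc = np.where(inside, T - r + 1, 0).sum(axis=0).astype(float)
        S = min(len(tpos), T)
        max_auc = float(sum(min(k_, S) for k_ in range(1, T + 1)))
        out[k] = auc / max_auc
    return pd.DataFrame(out, index=[r.tf for r in regulons],
                        columns=list(normalized.cell_ids))


# ---------------------------------------------------------------------------
# combination and module detection
# ---------------------------------------------------------------------------

def _zscore_rows(df: pd.DataFrame) -> pd.DataFrame:
    vals = df.to_numpy(dtype=float)
    mu = vals.mean(axis=1, keepdims=True)
    sd = vals.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return pd.DataFrame((vals - mu) / sd, index=df.index, columns=df.columns)


def combined_tf_score(activity: pd.DataFrame, expression: pd.DataFrame,
                      weight: float = 0.5) -> pd.DataFrame:
    """Weighted sum of z-scored activity and z-scored imputed expression.

    Both inputs are TF x cell frames on the same cell set; TFs present
    in only one input are excluded with a warning.  Output rows are
    re-standardized to mean 0, sd 1.
    """
    if list(activity.columns) != list(expression.columns):
        raise ValueError("activity and expression must share the same cell set")
    common = [tf for tf in activity.index if tf in set(expression.index)]
    dropped = (set(activity.index) | set(expression.index)) - set(common)
    if dropped:
        warnings.warn(f"TFs present in only one input excluded: {sorted(dropped)}")
    if not common:
        raise ValueError("no TFs shared between activity and expression")
    za = _zscore_rows(activity.loc[common])
    ze = _zscore_rows(expression.loc[common])
    combined = weight * za + (1.0 - weight) * ze
    return _zscore_rows(combined)


def detect_tf_modules(combined: pd.DataFrame, min_size: int = 3,
                      n_modules: int = None, min_intra_r: float = 0.3):
    """Average-linkage modules on the TF x TF Pearson correlation matrix.

    Distance is 1 - r.  With ``n_modules`` given the tree is cut there;
    otherwise a dynamic cut maximizes the total within-module pairwise
    correlation in excess of ``min_intra_r`` (so weakly linked pairs
    penalize a merge) over all cuts, keeping only clusters of at least
    ``min_size`` TFs whose mean pairwise correlation reaches
    ``min_intra_r`` (so mutually independent TFs yield no modules).
    Ties prefer more assigned TFs, then the finer cut.  Returns
    ``(modules, corr)`` with module ids M1... ordered by descending size.
    """
    n_tfs = combined.shape[0]
    if n_tfs < 2:
        raise ValueError("need at least 2 TFs")
    vals = combined.to_numpy(dtype=float)
    sd = vals.std(axis=1)
    corr = np.corrcoef(vals)
    corr[~np.isfinite(corr)] = 0.0
    np.fill_diagonal(corr, 1.0)
    corr_df = pd.DataFrame(corr, index=combined.index, columns=combined.index)
    if n_tfs < min_size:
        warnings.warn("fewer TFs than min_size; no modules detected")
        return [], corr_df

    dist = 1.0 - corr
    dist = (dist + dist.T) / 2.0
    np.fill_diagonal(dist, 0.0)
    Z = sch.linkage(squareform(dist, checks=False), method="average")

    def _assigned(labels):
        mods = []
        for lab in np.unique(labels):
            members = np.flatnonzero(labels == lab)
            if len(members) < min_size:
                continue
            sub = corr[np.ix_(members, members)]
            r_mean = (sub.sum() - len(members)) / (len(members) * (len(members) - 1))
            if n_modules is None and r_mean < min_intra_r:
                continue
            mods.append((members, r_mean))
        return mods

    if n_modules is not None:
        labels = sch.fcluster(Z, t=n_modules, criterion="maxclust")
        best = _assigned(labels)
    else:
        best, best_key = [], None
        for k in range(1, n_tfs + 1):
            labels = sch.fcluster(Z, t=k, criterion="maxclust")
            mods = _assigned(labels)
            if not mods:
                continue
            sizes = np.array([len(m) for m, _ in mods])
            rs = np.array([r for _, r in mods])
            n_pairs = sizes * (sizes - 1) / 2.0
            key = (float((n_pairs * (rs - min_intra_r)).sum()), int(sizes.sum()), k)
            if best_key is None or key > best_key:
                best, best_key = mods, key

    best = sorted(best, key=lambda m: (-len(m[0]), m[0][0]))
    tfs = np.asarray(combined.index, dtype=object)
    modules = []
    for i, (members, _) in enumerate(best):
        member_tfs = list(tfs[members])
        act = combined.loc[member_tfs].to_numpy().mean(axis=0)
        modules.append(TFModule(module_id=f"M{i + 1}", member_tfs=member_tfs, activity=act))
    return modules, corr_df


def module_activity(combined: pd.DataFrame, modules, labels) -> tuple:
    """Per-cell module scores and per-cell-type mean table.

    The per-cell score of a module is the mean of its member TFs'
    combined scores.  Returns ``(scores, type_means)``: module x cell
    and module x cell-type DataFrames.
    """
    if not modules:
        raise ValueError("modules must be non-empty")
    labels = np.asarray(labels)
    if len(labels) != combined.shape[1]:
        raise ValueError("labels must align with cells")
    rows = {}
    for mod in modules:
        unknown = [tf for tf in mod.member_tfs if tf not in set(combined.index)]
        if unknown:
            raise KeyError(f"module {mod.module_id} references unknown TFs {unknown}")
        rows[mod.module_id] = combined.loc[mod.member_tfs].to_numpy().mean(axis=0)
    scores = pd.DataFrame(rows).T
    scores.columns = combined.columns
    type_means = pd.DataFrame(
        {t: scores.loc[:, labels == t].mean(axis=1) for t in pd.unique(labels)}
    )
    return scores, type_means


# ---------------------------------------------------------------------------
# cross-species conservation
# ---------------------------------------------------------------------------

def tf_conservation(combined_a: pd.DataFrame, labels_a, combined_b: pd.DataFrame,
                    labels_b, ortholog_map: pd.DataFrame, type_map,
                    r_cut: float = 0.5):
    """Per-TF Pearson correlation of type-mean activity across species.

    ``ortholog_map`` is a two-column frame (species-A gene, species-B
    gene), one-to-one on shared TFs; ``type_map`` lists at least three
    matched (type-A, type-B) pairs.  A TF is flagged conserved when its
    across-type correlation reaches ``r_cut``.  Returns ``(records,
    unmapped)``: a DataFrame and the list of species-A TFs absent from
    the map.
    """
    type_map = list(type_map)
    if len(type_map) < 3:
        raise ValueError("need at least 3 matched cell types for a meaningful correlation")
    labels_a = np.asarray(labels_a)
    labels_b = np.asarray(labels_b)
    a_col, b_col = ortholog_map.columns[:2]
    lut = dict(zip(ortholog_map[a_col], ortholog_map[b_col]))
    if len(set(lut.values())) != len(lut):
        raise ValueError("ortholog map must be one-to-one")

    means_a = {t: combined_a.loc[:, labels_a == ta].mean(axis=1) for t, (ta, _) in enumerate(type_map)}
    means_b = {t: combined_b.loc[:, labels_b == tb].mean(axis=1) for t, (_, tb) in enumerate(type_map)}

    records, unmapped = [], []
    for tf in combined_a.index:
        partner = lut.get(tf)
        if partner is None or partner not in set(combined_b.index):
            unmapped.append(tf)
            continue
        pa = np.array([means_a[t][tf] for t in range(len(type_map))])
        pb = np.array([means_b[t][partner] for t in range(len(type_map))])
        if pa.std() == 0 or pb.std() == 0:
            r = 0.0
        else:
            r = float(np.corrcoef(pa, pb)[0, 1])
        records.append({"tf_a": tf, "tf_b": partner, "r": r, "conserved": bool(r >= r_cut)})
    return pd.DataFrame(records), unmapped
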