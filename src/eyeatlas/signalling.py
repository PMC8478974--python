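"""Ligand-receptor signalling probabilities between cell clusters.

The probability that a ligand-receptor pair signals from a sender to a
receiver cluster is a Hill-saturated product of robust cluster-level
summaries: with L = Tukey trimean of the ligand in the sender and R =
the trimean of the receptor in the receiver,

    probability = (L * R) / (kh + L * R)          in [0, 1)

and the p-value comes from a permutation null that shuffles cluster
labels over cells.  Downstream helpers rank highly variable pairs,
cluster per-cluster signalling profiles and aggregate significant pairs
into a weighted directed cluster network.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch

from .containers import GeneMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "InteractionScore",
    "trimean",
    "interaction_probability",
    "select_variable_pairs",
    "cluster_signalling_profiles",
    "aggregate_network",
]


@dataclass
class InteractionScore:
    ligand: str
    receptor: str
    sender: object
    receiver: object
    probability: float
    p_value: float

    def __post_init__(self):
        if not 0 <= self.probability < 1:
            raise ValueError("probability must lie in [0, 1)")
        if not 0 < self.p_value <= 1:
            raise ValueError("p-value must lie in (0, 1]")


def trimean(x: np.ndarray) -> float:
    """Tukey trimean (Q1 + 2*Q2 + Q3) / 4 — a robust location summary."""
    q1, q2, q3 = np.percentile(np.asarray(x, dtype=float), [25, 50, 75])
    return float((q1 + 2 * q2 + q3) / 4.0)


def hill_probability(lig_summary: float, rec_summary: float, kh: float = 0.5) -> float:
    """Saturating product: (L*R)/(kh + L*R); 0 whenever either summary is 0."""
    if kh <= 0:
        raise ValueError("kh must be strictly positive")
    lr = lig_summary * rec_summary
    return float(lr / (kh + lr))


def _cluster_trimeans(X: np.ndarray, labels: np.ndarray, clusters) -> np.ndarray:
    """genes x clusters trimeans."""
    out = np.empty((X.shape[0], len(clusters)))
    for j, c in enumerate(clusters):
        sub = X[:, labels == c]
        q = np.percentile(sub, [25, 50, 75], axis=1)
        out[:, j] = (q[0] + 2 * q[1] + q[2]) / 4.0
    return out


def interaction_probability(normalized: GeneMatrix, labels, lr_pairs,
                            kh: float = 0.5, n_perm: int = 100,
                            seed: int = 0) -> pd.DataFrame:
    """Score every (pair, sender, receiver) combination with a permutation p.

    ``lr_pairs`` is an iterable of (ligand, receptor) gene tuples; pairs
    whose genes are absent from the matrix are skipped with a warning.
    The permutation p-value is ``(1 + #{perm prob >= observed}) /
    (1 + n_perm)`` under random relabelling of cells, one shared label
    stream for all scores, deterministic given ``seed``.
    """
    if kh <= 0:
        raise ValueError("kh must be strictly positive")
    labels = np.asarray(labels)
    if len(labels) != normalized.n_cells:
        raise ValueError("labels must align with cells")
    clusters = list(pd.unique(labels))
    if len(clusters) < 2:
        raise ValueError("need at least 2 clusters")
    present = set(normalized.gene_ids)
    pairs = []
    for lig, rec in [(p[0], p[1]) for p in lr_pairs]:
        if lig in present and rec in present:
            pairs.append((lig, rec))
        else:
            warnings.warn(f"pair ({lig}, {rec}) skipped: gene missing from matrix")
    if not pairs:
        raise ValueError("no ligand-receptor pair present in the matrix")

    genes = sorted({g for p in pairs for g in p})
    gidx = {g: i for i, g in enumerate(genes)}
    X = normalized.to_frame(genes).to_numpy()

    tm = _cluster_trimeans(X, labels, clusters)
    obs = np.empty((len(pairs), len(clusters), len(clusters)))
    for k, (lig, rec) in enumerate(pairs):
        lr = np.outer(tm[gidx[lig]], tm[gidx[rec]])
        obs[k] = lr / (kh + lr)

    rng = np.random.default_rng(seed)
    exceed = np.zeros_like(obs)
    for _ in range(int(n_perm)):
        perm_labels = labels[rng.permutation(len(labels))]
        tmp = _cluster_trimeans(X, perm_labels, clusters)
        for k, (lig, rec) in enumerate(pairs):
            lr = np.outer(tmp[gidx[lig]], tmp[gidx[rec]])
            exceed[k] += (lr / (kh + lr)) >= obs[k] - 1e-12
    pvals = (1.0 + exceed) / (1.0 + n_perm)

    rows = []
    for k, (lig, rec) in enumerate(pairs):
        for i, s in enumerate(clusters):
            for j, r in enumerate(clusters):
                rows.append(
                    {
                        "ligand": lig,
                        "receptor": rec,
                        "sender": s,
                        "receiver": r,
                        "probability": float(obs[k, i, j]),
                        "p_value": float(pvals[k, i, j]),
                    }
                )
    return pd.DataFrame(rows)


def select_variable_pairs(scores: pd.DataFrame, top_n: int) -> pd.DataFrame:
    """Rank LR pairs by variance of probability across cluster combinations."""
    if top_n <= 0:
        raise ValueError("top_n must be positive")
    if scores[["sender", "receiver"]].drop_duplicates().shape[0] < 2:
        raise ValueError("scores must cover at least 2 cluster pairs")
    var = (
        scores.groupby(["ligand", "receptor"], sort=False)["probability"]
        .var(ddof=0)
        .reset_index(name="variance")
    )
    var = var.sort_values(["variance", "ligand", "receptor"],
                          ascending=[False, True, True], kind="mergesort")
    return var.head(top_n).reset_index(drop=True)


def cluster_signalling_profiles(scores: pd.DataFrame, k: int = None,
                                seed: int = 0) -> pd.DataFrame:
    """Group clusters by similarity of their signalling probability profiles.

    A cluster's profile concatenates its outgoing probabilities (as
    sender, over pairs x receivers) and incoming ones (as receiver);
    profiles are grouped by average-linkage hierarchical clustering on
    Euclidean distance, cut at ``k`` groups when given (default: 2, or
    1 when every profile is zero).  A deterministic 2-D layout of the
    profiles (classical MDS seeded by ``seed``) is attached.
    """
    mat_out = scores.pivot_table(index="sender", columns=["ligand", "receptor", "receiver"],
                                 values="probability", sort=True)
    mat_in = scores.pivot_table(index="receiver", columns=["ligand", "receptor", "sender"],
                                values="probability", sort=True)
    profiles = pd.concat([mat_out, mat_in], axis=1).fillna(0.0)
    if profiles.shape[0] < 2:
        raise ValueError("need at least 2 cluster profiles")
    X = profiles.to_numpy()
    if np.allclose(X, 0):
        warnings.warn("all signalling profiles are zero; single group")
        groups = np.ones(len(profiles), dtype=int)
    else:
        Z = sch.linkage(X, method="average", metric="euclidean")
        groups = sch.fcluster(Z, t=(k or 2), criterion="maxclust")
    from sklearn.manifold import MDS

    n_comp = min(2, X.shape[0] - 1) or 1
    mds = MDS(n_components=n_comp, random_state=seed, n_init=1, init="random",
              normalized_stress="auto")
    with np.errstate(invalid="ignore", divide="ignore"):
        layout = mds.fit_transform(X)
    if layout.shape[1] < 2:
        layout = np.column_stack([layout, np.zeros(len(layout))])
    return pd.DataFrame(
        {"cluster": list(profiles.index), "group": groups.astype(int),
         "x": layout[:, 0], "y": layout[:, 1]}
    )


def aggregate_network(scores: pd.DataFrame, p_cut: float = 0.05,
                      pathway_genes=None, reducer: str = "sum") -> pd.DataFrame:
    """Weighted directed cluster network from significant pairs.

    Edge weight sender -> receiver reduces (sum by default; mean / max
    available) the probabilities of pairs with ``p <= p_cut``; when
    ``pathway_genes`` is given only pairs whose ligand belongs to the
    set contribute.  The edge list is sorted deterministically; an empty
    network is a valid result.
    """
    if reducer not in {"sum", "mean", "max"}:
        raise ValueError("reducer must be sum, mean or max")
    sig = scores[scores["p_value"] <= p_cut]
    if pathway_genes is not None:
        sig = sig[sig["ligand"].isin(set(pathway_genes))]
    if sig.empty:
        return pd.DataFrame(columns=["sender", "receiver", "weight", "n_pairs"])
    grouped = sig.groupby(["sender", "receiver"], sort=False)["probability"]
    agg = getattr(grouped, reducer)().reset_index(name="weight")
    agg["n_pairs"] = grouped.size().to_numpy()
    agg = agg.sort_values(["sender", "receiver"], kind="mergesort").reset_index(drop=True)
    return agg


def to_networkx(edges: pd.DataFrame):
    """Edge-list DataFrame to a weighted networkx DiGraph."""
    import networkx as nx

    g = nx.DiGraph()
    for _, row in edges.iterrows():
        g.add_edge(row["sender"], row["receiver"], weight=float(row["weight"]))
    return g
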