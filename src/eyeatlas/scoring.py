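"""Per-cell gene-set scores, cell-cycle phases, network potency, ORA.

``gene_set_score`` is the expression-matched control-bin score used for
disease and viral-entry maps: each set gene is compared against control
genes drawn from its average-expression bin, so the null expectation is
zero.  ``potency_sr`` computes the normalized signalling-entropy rate
of an expression-weighted random walk on a user-supplied interaction
network — a proxy for differentiation potency: flatter expression over
the network gives a more uniform walk and hence a higher score.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import networkx as nx
from scipy.stats import hypergeom

from .containers import GeneMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "GeneSetScore",
    "PotencyRecord",
    "read_gmt",
    "gene_set_score",
    "cell_cycle_phase",
    "potency_sr",
    "potency_states",
    "enrichment_test",
    "enrichment_table",
]


@dataclass
class GeneSetScore:
    """Named per-cell score vector with the parameters that produced it."""

    name: str
    scores: pd.Series  # indexed by cell id
    params: dict


@dataclass
class PotencyRecord:
    cell_id: str
    sr: float
    state: int = -1

    def __post_init__(self):
        if not 0 <= self.sr <= 1 + 1e-9:
            raise ValueError("SR must lie in [0, 1]")


def read_gmt(path) -> dict:
    """Read a GMT gene-set file: set name, description, member genes."""
    sets = {}
    with open(path) as fh:
        for ln in fh:
            parts = ln.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            sets[parts[0]] = [g for g in parts[2:] if g]
    return sets


# ---------------------------------------------------------------------------
# control-matched gene-set scoring
# ---------------------------------------------------------------------------

def gene_set_score(normalized: GeneMatrix, gene_set, n_bins: int = 24,
                   n_ctrl: int = 100, seed: int = 0, name: str = "set") -> GeneSetScore:
    """Score = mean(set genes) - mean(expression-matched control genes).

    All genes are binned into ``n_bins`` by average expression; for each
    set gene, ``n_ctrl`` control genes are sampled from its bin (with
    replacement when the bin is smaller than ``n_ctrl``, without
    otherwise).  Set genes absent from the matrix are dropped with a
    warning; an empty effective set is an error.
    """
    present = set(normalized.gene_ids)
    kept = [g for g in gene_set if g in present]
    dropped = [g for g in gene_set if g not in present]
    if dropped:
        warnings.warn(f"{len(dropped)} set genes absent from matrix; dropped")
    if not kept:
        raise ValueError("no set gene present in the matrix")
    X = normalized.dense()
    avg = X.mean(axis=1)
    order = np.argsort(avg, kind="mergesort")
    bins = np.empty(len(avg), dtype=int)
    bins[order] = (np.arange(len(avg)) * n_bins) // len(avg)

    gene_pos = {g: i for i, g in enumerate(normalized.gene_ids)}
    rng = np.random.default_rng(seed)
    set_rows = np.array(sorted(gene_pos[g] for g in kept), dtype=int)
    ctrl_rows = []
    for i in set_rows:
        pool = np.flatnonzero(bins == bins[i])
        replace = len(pool) < n_ctrl
        ctrl_rows.append(rng.choice(pool, size=n_ctrl, replace=replace))
    ctrl_rows = np.concatenate(ctrl_rows)
    scores = X[set_rows].mean(axis=0) - X[ctrl_rows].mean(axis=0)
    return GeneSetScore(
        name=name,
        scores=pd.Series(scores, index=list(normalized.cell_ids)),
        params={"n_bins": n_bins, "n_ctrl": n_ctrl, "seed": seed,
                "n_genes_used": len(kept)},
    )


def cell_cycle_phase(normalized: GeneMatrix, s_genes, g2m_genes, seed: int = 0,
                     clusters=None):
    """Assign S / G2M / G1 phases and per-cluster phase proportions.

    S and G2M scores come from :func:`gene_set_score`; a cell is called
    for the higher-scoring phase when that score is positive, else G1.
    Returns ``(phases, proportions)``; ``proportions`` is None without
    ``clusters``.
    """
    present = set(normalized.gene_ids)
    if not (set(s_genes) & present) or not (set(g2m_genes) & present):
        raise ValueError("both phase gene lists must intersect the matrix")
    s = gene_set_score(normalized, s_genes, seed=seed, name="S").scores
    g2m = gene_set_score(normalized, g2m_genes, seed=seed + 1, name="G2M").scores
    phase = np.where(np.maximum(s, g2m) <= 0, "G1", np.where(s > g2m, "S", "G2M"))
    phases = pd.Series(phase, index=s.index, name="phase")
    proportions = None
    if clusters is not None:
        clusters = np.asarray(clusters)
        proportions = (
            pd.crosstab(clusters, phases.to_numpy(), normalize="index")
            .rename_axis(index="cluster", columns="phase")
        )
    return phases, proportions


# ---------------------------------------------------------------------------
# signalling-entropy potency
# ---------------------------------------------------------------------------

def potency_sr(normalized: GeneMatrix, network, pseudocount: float = 1e-3) -> list:
    """Normalized signalling-entropy rate (SR) of each cell.

    ``network`` is an undirected edge list (iterable of gene pairs) or a
    networkx Graph over gene identifiers present in the matrix; it must
    be connected.  Per cell, with x the (pseudocounted) expression over
    network genes and A the adjacency, the walk p_ij = x_j A_ij / (A x)_i
    has stationary distribution pi_i = x_i (A x)_i / sum, entropy rate
    ER = sum_i pi_i * (-sum_j p_ij log p_ij), and SR = ER / log
    lambda_max(A).  SR is invariant to rescaling a cell's expression.
    """
    if isinstance(network, nx.Graph):
        g = network
    else:
        g = nx.Graph()
        g.add_edges_from((str(a), str(b)) for a, b in network)
    if g.number_of_nodes() < 2:
        raise ValueError("network needs at least 2 genes")
    if not nx.is_connected(g):
        comps = [sorted(c)[:3] for c in nx.connected_components(g)]
        raise ValueError(f"network must be connected; components start with {comps}")
    nodes = sorted(g.nodes())
    missing = [n for n in nodes if n not in set(normalized.gene_ids)]
    if missing:
        raise KeyError(f"network genes absent from matrix: {missing[:5]}")
    A = nx.to_numpy_array(g, nodelist=nodes, weight="weight")
    lam = float(np.max(np.linalg.eigvalsh(A)))
    logA = np.where(A > 0, np.log(np.where(A > 0, A, 1.0)), 0.0)

    X = normalized.to_frame(nodes).to_numpy() + pseudocount  # genes x cells
    S = A @ X                       # (A x)_i per cell
    T = (A * logA) @ X + A @ (X * np.log(X))
    H = np.log(S) - T / S           # per-node conditional entropies
    pi = X * S
    pi = pi / pi.sum(axis=0, keepdims=True)
    er = (pi * H).sum(axis=0)
    sr = np.clip(er / np.log(lam), 0.0, 1.0 + 1e-12)
    return [PotencyRecord(cid, float(min(v, 1.0))) for cid, v in zip(normalized.cell_ids, sr)]


def potency_states(sr_values, seed: int = 0, max_states: int = 3,
                   bic_margin: float = 6.0):
    """Potency states: 1-D Gaussian mixture on logit(SR), BIC-selected.

    Component count is chosen by BIC over 1..``max_states``, accepting a
    more complex mixture only when it improves BIC by ``bic_margin``
    (the conventional "positive evidence" gap, which guards against
    spurious extra components).  Assignment is by maximum posterior, and
    states are relabelled 0.. by ascending mean SR.  All-identical SR
    collapses to a single state.  Accepts either floats or
    :class:`PotencyRecord` objects; returns ``(states, n_states)``.
    """
    sr_values = list(sr_values)
    if sr_values and isinstance(sr_values[0], PotencyRecord):
        vals = np.array([r.sr for r in sr_values])
    else:
        vals = np.asarray(sr_values, dtype=float)
    if len(vals) < 10:
        raise ValueError("need at least 10 cells to fit potency states")
    if np.allclose(vals, vals[0]):
        return np.zeros(len(vals), dtype=int), 1
    z = np.clip(vals, 1e-6, 1 - 1e-6)
    z = np.log(z / (1 - z)).reshape(-1, 1)

    from sklearn.mixture import GaussianMixture

    best, best_bic = None, np.inf
    for n in range(1, max_states + 1):
        gm = GaussianMixture(n_components=n, random_state=seed, n_init=3).fit(z)
        bic = gm.bic(z)
        if bic < best_bic - (bic_margin if best is not None else 0.0):
            best, best_bic = gm, bic
    labels = best.predict(z)
    # relabel in ascending mean-SR order
    means = [vals[labels == c].mean() if (labels == c).any() else np.inf
             for c in range(best.n_components)]
    order = np.argsort(means)
    remap = {int(c): r for r, c in enumerate(order)}
    states = np.array([remap[int(c)] for c in labels])
    return states, int(len(set(states)))


# ---------------------------------------------------------------------------
# over-representation
# ---------------------------------------------------------------------------

def enrichment_test(query_genes, gene_set, universe):
    """Upper-tail (cumulative) hypergeometric over-representation test.

    With N = |universe|, K = |set|, n = |query| and k the observed
    overlap, p = P(X >= k).  Query genes outside the universe are an
    error.  Returns ``(p_value, overlap)``.
    """
    universe = set(universe)
    query = set(query_genes)
    gset = set(gene_set) & universe
    outside = query - universe
    if outside:
        raise ValueError(f"query genes outside universe: {sorted(outside)[:5]}")
    N, K, n = len(universe), len(gset), len(query)
    k = len(query & gset)
    p = float(hypergeom.sf(k - 1, N, K, n))
    return min(p, 1.0), k


def enrichment_table(query_genes, gene_sets: dict, universe,
                     adjust: bool = False) -> pd.DataFrame:
    """ORA over many sets, optionally Benjamini-Hochberg adjusted."""
    rows = []
    for name, genes in gene_sets.items():
        p, k = enrichment_test(query_genes, genes, universe)
        rows.append({"set": name, "p_value": p, "overlap": k})
    df = pd.DataFrame(rows)
    if adjust and not df.empty:
        from statsmodels.stats.multitest import multipletests

        df["p_adjusted"] = multipletests(df["p_value"], method="fdr_bh")[1]
    return df
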