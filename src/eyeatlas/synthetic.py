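"""Synthetic multi-species single-cell atlases with planted ground truth.

The generator emulates the statistical structure a multi-compartment
ocular atlas analysis rests on, with every latent quantity recorded:

* cell types with disjoint marker genes carrying a known fold change;
* transcription factors (TFs) whose target blocks are switched on per
  cell type, grouped into disjoint co-activated modules;
* a non-negative low-rank (amplitude x weights) mean over background
  genes, giving recoverable expression "patterns";
* ligand/receptor genes boosted in designated sender/receiver types;
* a progenitor cell type with a deliberately flattened (higher-entropy)
  mean profile, so a potency ordering is planted;
* additional species that reuse the ortholog-shared part of the gene
  space under an explicit two-column ortholog map (gene orders are
  shuffled per species so identifiers can never be matched by name).

Counts are negative-binomial (gamma-Poisson) around cell-specific
log-normal library sizes, then thinned by independent dropout.
Everything is deterministic given the config seed.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .containers import CountMatrix, make_annotation

# shape of the gamma law behind background amplitude rows; its product with
# the pattern rank is the expected background base mean, which is also the
# constant baseline given to every planted gene so fold changes are clean
_BG_GAMMA_SHAPE = 2.0

__all__ = [
    "SyntheticConfig",
    "GroundTruth",
    "generate_atlas",
    "generate_null_pair",
    "inject_dropout",
    "write_atlas",
]


@dataclass
class SyntheticConfig:
    """Parameters of the synthetic atlas generator.

    Defaults describe a small two-species atlas with five cell types
    (type 0 is the progenitor), twenty TFs in four modules of five, ten
    targets per TF, ten markers per type and three ligand-receptor
    pairs.  ``marker_fold`` is the multiplicative boost applied to
    markers, active TFs/targets and ligand/receptor genes in their
    designated types.
    """

    n_cells: int = 2000
    n_genes: int = 600
    n_cell_types: int = 5
    n_tfs: int = 20
    targets_per_tf: int = 10
    marker_fold: float = 4.0
    n_markers_per_type: int = 10
    module_blocks: list = None  # list of disjoint TF-index lists
    lr_pairs: list = None  # (ligand idx, receptor idx, sender type, receiver type)
    n_lr_pairs: int = 3
    pattern_rank: int = 5
    libsize_log_mean: float = 8.5
    libsize_log_sd: float = 0.35
    nb_dispersion: float = 0.25
    dropout_rate: float = 0.2
    potency_flatten: float = 0.7  # mixing weight toward a flat progenitor profile
    species: tuple = (("human", 1.0), ("pig", 0.7))
    seed: int = 0

    def __post_init__(self):
        if self.module_blocks is None:
            # one block per cell type when possible, so every type carries the
            # same planted boost mass and no type is systematically heavier
            n_blocks = min(self.n_cell_types, max(1, self.n_tfs // 3))
            block = self.n_tfs // n_blocks
            self.module_blocks = [
                list(range(b * block, (b + 1) * block if b < n_blocks - 1 else self.n_tfs))
                for b in range(n_blocks)
            ]
        if self.lr_pairs is None:
            self.lr_pairs = self._default_lr_pairs()

    def _special_gene_count(self) -> int:
        n = self.n_tfs * (1 + self.targets_per_tf)
        n += self.n_cell_types * self.n_markers_per_type
        n += 2 * len(self.lr_pairs)
        return n

    def _default_lr_pairs(self):
        base = self.n_tfs * (1 + self.targets_per_tf) + self.n_cell_types * self.n_markers_per_type
        pairs = []
        n_types = self.n_cell_types
        for i in range(self.n_lr_pairs):
            lig, rec = base + 2 * i, base + 2 * i + 1
            sender = i % n_types
            receiver = (i + 1) % n_types if n_types > 1 else 0
            pairs.append((lig, rec, sender, receiver))
        return pairs

    def validate(self) -> "SyntheticConfig":
        for name in ("n_cells", "n_genes", "n_cell_types", "n_tfs", "targets_per_tf", "pattern_rank"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be a positive integer")
        for name in ("libsize_log_sd", "nb_dispersion", "marker_fold"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.marker_fold <= 1:
            raise ValueError("marker_fold must exceed 1")
        if not 0 <= self.dropout_rate <= 1:
            raise ValueError("dropout_rate must lie in [0, 1]")
        if not 0 <= self.potency_flatten < 1:
            raise ValueError("potency_flatten must lie in [0, 1)")
        if self._special_gene_count() > self.n_genes:
            raise ValueError(
                "planted structure does not fit: "
                f"{self._special_gene_count()} structured genes > {self.n_genes} genes"
            )
        seen = set()
        for blk in self.module_blocks:
            for i in blk:
                if i in seen:
                    raise ValueError("module_blocks must be disjoint TF-index sets")
                if not 0 <= i < self.n_tfs:
                    raise ValueError(f"TF index {i} out of range")
                seen.add(i)
        for lig, rec, s, r in self.lr_pairs:
            if not (0 <= lig < self.n_genes and 0 <= rec < self.n_genes):
                raise ValueError("ligand/receptor gene index out of range")
            if not (0 <= s < self.n_cell_types and 0 <= r < self.n_cell_types):
                raise ValueError("sender/receiver type out of range")
        tags = [s[0] for s in self.species]
        if len(set(tags)) != len(tags) or not tags:
            raise ValueError("species tags must be unique and non-empty")
        for tag, frac in self.species:
            if not 0 <= frac <= 1:
                raise ValueError("ortholog_fraction must lie in [0, 1]")
        for tag, frac in self.species[1:]:
            if round(frac * self.n_genes) < self._special_gene_count():
                raise ValueError(
                    f"species {tag!r}: ortholog fraction too small to share the planted genes"
                )
        return self


@dataclass
class GroundTruth:
    """Everything the generator planted, keyed by first-species gene names."""

    type_names: list
    potency_rank: dict  # type name -> rank, 0 = progenitor (most potent)
    labels: dict  # species tag -> int array of per-cell type indices
    markers: dict  # type name -> list of marker genes
    regulons: dict  # tf gene -> list of target genes
    tf_modules: dict  # tf gene -> module index (0-based)
    tf_activation: pd.DataFrame  # tfs x type names, bool
    lr_pairs: list  # dicts: ligand, receptor, sender, receiver
    amplitude: dict  # species tag -> genes x rank array
    weights: np.ndarray  # rank x n_types
    type_means: dict  # species tag -> genes x n_types relative mean profiles
    ortholog_maps: dict = field(default_factory=dict)  # (tagA, tagB) -> DataFrame

    def cell_types(self, species: str) -> np.ndarray:
        """Per-cell type-name labels for one species."""
        return np.array([self.type_names[i] for i in self.labels[species]], dtype=object)

    def annotation(self, species: str, condition: str = "ctrl") -> pd.DataFrame:
        labs = self.labels[species]
        cells = [f"{species}_c{i:05d}" for i in range(len(labs))]
        return make_annotation(cells, labs, self.cell_types(species), donor="sim0", condition=condition)


# ---------------------------------------------------------------------------
# mean construction
# ---------------------------------------------------------------------------

def _gene_layout(cfg: SyntheticConfig):
    """Index blocks of the planted genes within the first-species gene order."""
    tf_idx = np.arange(cfg.n_tfs)
    target_idx = {
        i: np.arange(cfg.n_tfs + i * cfg.targets_per_tf, cfg.n_tfs + (i + 1) * cfg.targets_per_tf)
        for i in range(cfg.n_tfs)
    }
    m0 = cfg.n_tfs * (1 + cfg.targets_per_tf)
    marker_idx = {
        t: np.arange(m0 + t * cfg.n_markers_per_type, m0 + (t + 1) * cfg.n_markers_per_type)
        for t in range(cfg.n_cell_types)
    }
    return tf_idx, target_idx, marker_idx


def _tf_activation(cfg: SyntheticConfig) -> np.ndarray:
    """Binary TF x type activation: module block b switches on in type
    ``b mod n_cell_types``, so blocks spread evenly over the types."""
    act = np.zeros((cfg.n_tfs, cfg.n_cell_types), dtype=bool)
    for b, blk in enumerate(cfg.module_blocks):
        act[np.asarray(blk, dtype=int), b % cfg.n_cell_types] = True
    return act


def _mean_profiles(cfg: SyntheticConfig, amplitude: np.ndarray, weights: np.ndarray):
    """Relative (column-stochastic) genes x types mean profiles.

    The low-rank product ``amplitude @ weights`` gives the base mean;
    the progenitor column is mixed toward the flat baseline level, then
    marker / TF-target / ligand-receptor folds are applied.
    """
    tf_idx, target_idx, marker_idx = _gene_layout(cfg)
    act = _tf_activation(cfg)
    M = amplitude @ weights  # genes x types, non-negative
    # flatten the progenitor's background profile toward its expected level;
    # planted genes sit at a constant baseline across types already, and using
    # the expectation (not the realised mean) keeps column masses balanced
    n_special = cfg._special_gene_count()
    bg_level = _BG_GAMMA_SHAPE * cfg.pattern_rank
    if cfg.n_cell_types > 1 and cfg.potency_flatten > 0:
        M[n_special:, 0] = (
            (1 - cfg.potency_flatten) * M[n_special:, 0] + cfg.potency_flatten * bg_level
        )
    for t in range(cfg.n_cell_types):
        M[marker_idx[t], t] *= cfg.marker_fold
    for i in range(cfg.n_tfs):
        for t in np.flatnonzero(act[i]):
            M[tf_idx[i], t] *= cfg.marker_fold
            M[target_idx[i], t] *= cfg.marker_fold
    for lig, rec, s, r in cfg.lr_pairs:
        M[lig, s] *= cfg.marker_fold
        M[rec, r] *= cfg.marker_fold
    P = M / M.sum(axis=0, keepdims=True)
    return P, act


def _amplitude(cfg: SyntheticConfig, rng: np.random.Generator, n_background_rows: int, baseline: float):
    """Amplitude rows: flat rows for planted genes, gamma rows for background.

    Flat rows make every planted gene's base mean identical across types
    (so planted folds translate into clean in/out ratios); background
    rows carry the heterogeneous low-rank pattern structure.  Weight
    columns all sum to ``rank``, hence a flat row at ``baseline / rank``
    yields a base mean of exactly ``baseline`` in every type.
    """
    rank = cfg.pattern_rank
    n_special = cfg._special_gene_count()
    A = np.empty((n_special + n_background_rows, rank))
    A[:n_special] = baseline / rank
    A[n_special:] = rng.gamma(shape=_BG_GAMMA_SHAPE, scale=1.0, size=(n_background_rows, rank))
    return A


def _weights(cfg: SyntheticConfig) -> np.ndarray:
    """Pattern x type weights: each pattern prefers one type; columns sum to rank."""
    rank, n_types = cfg.pattern_rank, cfg.n_cell_types
    W = np.full((rank, n_types), 0.3)
    for t in range(n_types):
        W[t % rank, t] += 1.0
    W *= rank / W.sum(axis=0, keepdims=True)
    return W


def _draw_counts(cfg, P, labels, rng):
    """NB (gamma-Poisson) counts with log-normal library sizes plus dropout."""
    libs = rng.lognormal(mean=cfg.libsize_log_mean, sigma=cfg.libsize_log_sd, size=len(labels))
    mu = P[:, labels] * libs[None, :]
    shape = 1.0 / cfg.nb_dispersion
    lam = rng.gamma(shape=shape, scale=mu / shape)
    counts = rng.poisson(lam)
    if cfg.dropout_rate > 0:
        keep = rng.random(counts.shape) >= cfg.dropout_rate
        counts = counts * keep
    return counts


def _balanced_labels(n_cells, n_types, rng):
    labels = np.arange(n_cells) % n_types
    rng.shuffle(labels)
    return labels


# ---------------------------------------------------------------------------
# public operations
# ---------------------------------------------------------------------------

def generate_atlas(config: SyntheticConfig):
    """Generate one count matrix per species plus the full ground truth.

    Returns
    -------
    matrices : dict of species tag -> CountMatrix
    truth : GroundTruth
    """
    cfg = config.validate()
    rng = np.random.default_rng(cfg.seed)
    n_special = cfg._special_gene_count()
    n_bg = cfg.n_genes - n_special
    W = _weights(cfg)
    A0 = _amplitude(cfg, rng, n_bg, baseline=_BG_GAMMA_SHAPE * cfg.pattern_rank)
    P0, act = _mean_profiles(cfg, A0, W)

    tf_idx, target_idx, marker_idx = _gene_layout(cfg)
    type_names = [f"type{t}" for t in range(cfg.n_cell_types)]
    tag0 = cfg.species[0][0]
    genes0 = np.array([f"{tag0}_g{i:04d}" for i in range(cfg.n_genes)], dtype=object)

    matrices, labels_by_sp, amp_by_sp, means_by_sp, ortho = {}, {}, {}, {}, {}
    for si, (tag, frac) in enumerate(cfg.species):
        if si == 0:
            A, P, shared = A0, P0, cfg.n_genes
        else:
            shared = int(round(frac * cfg.n_genes))
            n_new = cfg.n_genes - shared
            A = np.vstack([A0[:shared], rng.gamma(shape=_BG_GAMMA_SHAPE, scale=1.0,
                                                  size=(n_new, cfg.pattern_rank))])
            P, _ = _mean_profiles(cfg, A, W)
        labels = _balanced_labels(cfg.n_cells, cfg.n_cell_types, rng)
        counts = _draw_counts(cfg, P, labels, rng)
        if si == 0:
            order = np.arange(cfg.n_genes)
            gene_names = genes0
        else:
            # shuffle gene order so numeric suffixes never align across species
            order = rng.permutation(cfg.n_genes)
            gene_names = np.array([f"{tag}_g{j:04d}" for j in range(cfg.n_genes)], dtype=object)
            inv = np.empty(cfg.n_genes, dtype=int)
            inv[order] = np.arange(cfg.n_genes)
            ortho[(tag0, tag)] = pd.DataFrame(
                {f"gene_{tag0}": genes0[:shared], f"gene_{tag}": gene_names[inv[:shared]]}
            )
        cells = np.array([f"{tag}_c{i:05d}" for i in range(cfg.n_cells)], dtype=object)
        matrices[tag] = CountMatrix(sp.csr_matrix(counts[order]), gene_names, cells, species=tag)
        labels_by_sp[tag] = labels
        amp_by_sp[tag] = A[order]
        means_by_sp[tag] = P[order]

    truth = GroundTruth(
        type_names=type_names,
        potency_rank={name: t for t, name in enumerate(type_names)},
        labels=labels_by_sp,
        markers={type_names[t]: list(genes0[marker_idx[t]]) for t in range(cfg.n_cell_types)},
        regulons={genes0[i]: list(genes0[target_idx[i]]) for i in range(cfg.n_tfs)},
        tf_modules={genes0[i]: b for b, blk in enumerate(cfg.module_blocks) for i in blk},
        tf_activation=pd.DataFrame(act, index=list(genes0[tf_idx]), columns=type_names),
        lr_pairs=[
            {
                "ligand": genes0[lig],
                "receptor": genes0[rec],
                "sender": type_names[s],
                "receiver": type_names[r],
            }
            for lig, rec, s, r in cfg.lr_pairs
        ],
        amplitude=amp_by_sp,
        weights=W,
        type_means=means_by_sp,
        ortholog_maps=ortho,
    )
    return matrices, truth


def generate_null_pair(config: SyntheticConfig):
    """Two condition-labelled matrices drawn from one identical law.

    ``config.n_cells`` cells per side are drawn from the first species'
    generative law with no condition effect whatsoever: any downstream
    condition contrast is a pure null.  Returns ``(matA, matB, annot)``
    where the annotation covers both matrices with condition labels
    ``"A"`` / ``"B"``.
    """
    cfg = config.validate()
    rng = np.random.default_rng(cfg.seed)
    n_special = cfg._special_gene_count()
    W = _weights(cfg)
    A0 = _amplitude(cfg, rng, cfg.n_genes - n_special, baseline=_BG_GAMMA_SHAPE * cfg.pattern_rank)
    P0, _ = _mean_profiles(cfg, A0, W)
    tag = cfg.species[0][0]
    genes = np.array([f"{tag}_g{i:04d}" for i in range(cfg.n_genes)], dtype=object)

    n_total = 2 * cfg.n_cells
    labels = _balanced_labels(n_total, cfg.n_cell_types, rng)
    counts = _draw_counts(cfg, P0, labels, rng)
    cond = np.array(["A"] * cfg.n_cells + ["B"] * cfg.n_cells, dtype=object)
    rng.shuffle(cond)

    cells = np.array([f"{tag}_n{i:05d}" for i in range(n_total)], dtype=object)
    annots = []
    mats = {}
    for c in ("A", "B"):
        mask = cond == c
        mats[c] = CountMatrix(sp.csr_matrix(counts[:, mask]), genes, cells[mask], species=tag)
        annots.append(make_annotation(cells[mask], labels[mask],
                                      [f"type{t}" for t in labels[mask]],
                                      donor="sim0", condition=c))
    annot = pd.concat(annots, ignore_index=True)
    return mats["A"], mats["B"], annot


def inject_dropout(matrix: CountMatrix, rate: float, seed: int) -> CountMatrix:
    """Zero each nonzero entry independently with probability ``rate``."""
    if not 0 <= rate <= 1:
        raise ValueError("dropout rate must lie in [0, 1]")
    out = matrix.values.tocsr(copy=True)
    if rate > 0 and out.nnz:
        rng = np.random.default_rng(seed)
        keep = rng.random(out.nnz) >= rate
        out.data = out.data * keep
        out.eliminate_zeros()
    return CountMatrix(out, matrix.gene_ids.copy(), matrix.cell_ids.copy(), matrix.species)


# ---------------------------------------------------------------------------
# persistence
# ---------------------------------------------------------------------------

def write_atlas(matrices: dict, truth: GroundTruth, outdir) -> None:
    """Write MTX triplets, annotation TSVs and the ground-truth sidecars."""
    from .io_preprocess import write_counts

    outdir = Path(outdir)
    for tag, mat in matrices.items():
        d = outdir / tag
        write_counts(mat, d)
        truth.annotation(tag).to_csv(d / "annotation.tsv", sep="\t", index=False)

    tdir = outdir / "truth"
    tdir.mkdir(parents=True, exist_ok=True)
    payload = {
        "type_names": truth.type_names,
        "potency_rank": truth.potency_rank,
        "markers": truth.markers,
        "regulons": truth.regulons,
        "tf_modules": truth.tf_modules,
        "lr_pairs": truth.lr_pairs,
        "labels": {k: np.asarray(v).tolist() for k, v in truth.labels.items()},
    }
    (tdir / "ground_truth.json").write_text(json.dumps(payload, indent=1))
    truth.tf_activation.to_csv(tdir / "tf_activation.tsv", sep="\t")
    pd.DataFrame(truth.weights).to_csv(tdir / "weights.tsv", sep="\t", index=False)
    for tag, amp in truth.amplitude.items():
        pd.DataFrame(amp).to_csv(tdir / f"amplitude_{tag}.tsv", sep="\t", index=False)
    for (a, b), df in truth.ortholog_maps.items():
        df.to_csv(tdir / f"orthologs_{a}_{b}.tsv", sep="\t", index=False)
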