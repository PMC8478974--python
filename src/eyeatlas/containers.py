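"""Core in-memory containers shared by every pipeline stage.

The central object is a genes x cells matrix with string identifiers on
both axes and a species tag.  Raw data is held as a :class:`CountMatrix`
(sparse, non-negative integers); normalized / imputed data is held as a
:class:`GeneMatrix` with float values, dense or sparse.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

__all__ = ["GeneMatrix", "CountMatrix", "make_annotation", "validate_annotation"]

ANNOTATION_COLUMNS = ["cell_id", "cluster", "cell_type", "donor", "condition"]


@dataclass
class GeneMatrix:
    """A genes x cells expression matrix with identifiers.

    Parameters
    ----------
    values
        2-D array or scipy sparse matrix, shape ``(n_genes, n_cells)``.
    gene_ids, cell_ids
        Unique string identifiers for rows / columns.
    species
        Free-form species tag carried through the pipeline.
    """

    values: object
    gene_ids: np.ndarray
    cell_ids: np.ndarray
    species: str = ""

    def __post_init__(self) -> None:
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        self.cell_ids = np.asarray(self.cell_ids, dtype=object)
        if not sp.issparse(self.values):
            self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D (genes x cells)")
        n_genes, n_cells = self.values.shape
        if len(self.gene_ids) != n_genes:
            raise ValueError(
                f"{len(self.gene_ids)} gene ids for {n_genes} matrix rows"
            )
        if len(self.cell_ids) != n_cells:
            raise ValueError(
                f"{len(self.cell_ids)} cell ids for {n_cells} matrix columns"
            )
        if len(set(self.gene_ids)) != n_genes:
            raise ValueError("duplicate gene identifiers")
        if len(set(self.cell_ids)) != n_cells:
            raise ValueError("duplicate cell identifiers")

    # -- basic geometry -------------------------------------------------
    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]

    def dense(self) -> np.ndarray:
        """Return the values as a dense float array (copy if sparse)."""
        if sp.issparse(self.values):
            return np.asarray(self.values.todense(), dtype=float)
        return np.asarray(self.values, dtype=float)

    def copy(self) -> "GeneMatrix":
        vals = self.values.copy()
        return type(self)(vals, self.gene_ids.copy(), self.cell_ids.copy(), self.species)

    # -- lookups ---------------------------------------------------------
    def gene_index(self, genes) -> np.ndarray:
        """Row positions of ``genes``; raises KeyError on unknown genes."""
        lut = {g: i for i, g in enumerate(self.gene_ids)}
        try:
            return np.array([lut[g] for g in np.atleast_1d(genes)], dtype=int)
        except KeyError as err:
            raise KeyError(f"gene {err.args[0]!r} not in matrix") from None

    def expression(self, gene) -> np.ndarray:
        """Dense expression vector of one gene across cells."""
        i = self.gene_index([gene])[0]
        row = self.values[i]
        if sp.issparse(row):
            return np.asarray(row.todense(), dtype=float).ravel()
        return np.asarray(row, dtype=float).ravel()

    def to_frame(self, genes=None) -> pd.DataFrame:
        """Genes x cells DataFrame, optionally restricted to ``genes``."""
        if genes is None:
            idx = np.arange(self.n_genes)
            names = self.gene_ids
        else:
            idx = self.gene_index(genes)
            names = np.atleast_1d(genes)
        block = self.values[idx]
        if sp.issparse(block):
            block = np.asarray(block.todense(), dtype=float)
        return pd.DataFrame(block, index=list(names), columns=list(self.cell_ids))

    def to_anndata(self):
        """Cells x genes AnnData view for scanpy-based steps."""
        import anndata as ad

        X = self.values.T
        if sp.issparse(X):
            X = X.tocsr().astype(np.float32)
        else:
            X = np.asarray(X, dtype=np.float32)
        adata = ad.AnnData(X=X)
        adata.obs_names = [str(c) for c in self.cell_ids]
        adata.var_names = [str(g) for g in self.gene_ids]
        return adata


class CountMatrix(GeneMatrix):
    """Sparse non-negative integer counts (genes x cells)."""

    def __post_init__(self) -> None:
        if not sp.issparse(self.values):
            self.values = sp.csr_matrix(np.asarray(self.values))
        else:
            self.values = self.values.tocsr()
        super().__post_init__()
        data = self.values.data
        if data.size:
            if data.min() < 0:
                raise ValueError("counts must be non-negative")
            if not np.allclose(data, np.round(data)):
                raise ValueError("counts must be integers")
        self.values.data = np.asarray(np.round(self.values.data), dtype=np.int64)


def make_annotation(cell_ids, cluster, cell_type, donor="sim0", condition="ctrl") -> pd.DataFrame:
    """Assemble a per-cell annotation table (one row per cell)."""
    n = len(cell_ids)
    df = pd.DataFrame(
        {
            "cell_id": list(cell_ids),
            "cluster": np.broadcast_to(np.asarray(cluster), (n,)).astype(int),
            "cell_type": np.broadcast_to(np.asarray(cell_type, dtype=object), (n,)),
            "donor": np.broadcast_to(np.asarray(donor, dtype=object), (n,)),
            "condition": np.broadcast_to(np.asarray(condition, dtype=object), (n,)),
        }
    )
    validate_annotation(df)
    return df


def validate_annotation(annot: pd.DataFrame) -> pd.DataFrame:
    """Check annotation invariants: required columns, one row per cell."""
    missing = [c for c in ANNOTATION_COLUMNS if c not in annot.columns]
    if missing:
        raise ValueError(f"annotation missing columns {missing}")
    if annot["cell_id"].duplicated().any():
        raise ValueError("annotation has duplicated cell ids")
    return annot
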