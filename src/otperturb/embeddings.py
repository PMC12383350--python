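"""Injection of precomputed cell/perturbation embeddings into the encoder input.

Embeddings come from external models and are consumed as files; their
dimensions generally differ from the gene dimension, so learned linear
projections (zero-initialized, trained jointly with the autoencoder)
reconcile them before the element-wise addition. Zero initialization
guarantees that at training start the injected input equals the plain
expression matrix, i.e. the no-embedding ablation arm.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from otperturb.data_io import STIMULATED, ExpressionDataset


@dataclass
class EmbeddingSet:
    """Optional per-cell embedding matrix and per-perturbation vector plus
    their learned projections to gene space."""

    cell_embedding: np.ndarray | None = None  # (n, e)
    perturb_embedding: np.ndarray | None = None  # (p,)
    cell_proj: np.ndarray | None = None  # (e, d)
    perturb_proj: np.ndarray | None = None  # (p, d)
    cell_ids: np.ndarray | None = None
    perturb_scope: str = "all"  # {all | stimulated}
    condition: np.ndarray | None = field(default=None, repr=False)

    @property
    def enabled(self) -> bool:
        return self.cell_embedding is not None or self.perturb_embedding is not None

    def init_projections(self, n_genes: int) -> None:
        """Zero-initialize any missing projection for the given gene count."""
        if self.cell_embedding is not None and self.cell_proj is None:
            self.cell_proj = np.zeros((self.cell_embedding.shape[1], n_genes))
        if self.perturb_embedding is not None and self.perturb_proj is None:
            self.perturb_proj = np.zeros((self.perturb_embedding.shape[0], n_genes))

    def align_to(self, dataset: ExpressionDataset) -> "EmbeddingSet":
        """Reorder cell embedding rows to match ``dataset.cell_ids``."""
        if self.cell_embedding is None:
            return EmbeddingSet(
                cell_embedding=None,
                perturb_embedding=self.perturb_embedding,
                cell_proj=self.cell_proj,
                perturb_proj=self.perturb_proj,
                perturb_scope=self.perturb_scope,
                condition=dataset.condition,
            )
        if self.cell_ids is None:
            raise ValueError("cell embedding carries no cell ids to align by")
        pos = {cid: i for i, cid in enumerate(self.cell_ids)}
        missing = [c for c in dataset.cell_ids if c not in pos]
        if missing:
            raise ValueError(f"cell embedding missing id(s): {missing[:5]}")
        order = np.array([pos[c] for c in dataset.cell_ids])
        return EmbeddingSet(
            cell_embedding=self.cell_embedding[order],
            perturb_embedding=self.perturb_embedding,
            cell_proj=self.cell_proj,
            perturb_proj=self.perturb_proj,
            cell_ids=dataset.cell_ids.copy(),
            perturb_scope=self.perturb_scope,
            condition=dataset.condition,
        )


def load_embeddings(
    cell_path: str | None,
    perturb_path: str | None,
    dataset: ExpressionDataset,
    perturb_scope: str = "all",
) -> EmbeddingSet:
    """Load delimited embedding files and align them to the dataset.

    The cell file has a cell-id first column; rows are realigned to the
    dataset order. The perturbation file is a single-row vector. Absent
    paths yield disabled components (injection becomes a no-op).
    """
    cell_embedding = None
    cell_ids = None
    if cell_path is not None:
        sep = "," if str(cell_path).endswith(".csv") else "\t"
        df = pd.read_csv(cell_path, sep=sep, index_col=0, header=None)
        if len(df) != dataset.n_cells:
            raise ValueError(
                f"cell embedding has {len(df)} rows but dataset has "
                f"{dataset.n_cells} cells"
            )
        cell_ids = df.index.to_numpy(dtype=object).astype(object)
        cell_embedding = df.to_numpy(dtype=np.float64)
    perturb_embedding = None
    if perturb_path is not None:
        sep = "," if str(perturb_path).endswith(".csv") else None
        perturb_embedding = np.atleast_1d(
            np.loadtxt(perturb_path, delimiter=sep, dtype=np.float64)
        ).ravel()
    emb = EmbeddingSet(
        cell_embedding=cell_embedding,
        perturb_embedding=perturb_embedding,
        cell_ids=cell_ids,
        perturb_scope=perturb_scope,
    )
    return emb.align_to(dataset)


def inject(
    dataset_matrix: np.ndarray,
    emb: EmbeddingSet,
    rows: np.ndarray | None = None,
) -> np.ndarray:
    """Return ``D + proj(cell_embedding) + broadcast(proj(perturb_embedding))``.

    ``rows`` selects the cell-embedding rows (and condition labels) matching
    a batch slice of the matrix. With both components disabled this returns
    the input unchanged (same object).
    """
    out = dataset_matrix
    d = dataset_matrix.shape[1]
    if emb.cell_embedding is not None:
        if emb.cell_proj is None:
            raise ValueError("cell projection not initialized")
        ce = emb.cell_embedding if rows is None else emb.cell_embedding[rows]
        if ce.shape[0] != dataset_matrix.shape[0]:
            raise ValueError(
                f"cell embedding rows ({ce.shape[0]}) != matrix rows "
                f"({dataset_matrix.shape[0]})"
            )
        contrib = ce @ emb.cell_proj
        if contrib.shape[1] != d:
            raise ValueError("cell projection output dimension mismatch")
        out = out + contrib
    if emb.perturb_embedding is not None:
        if emb.perturb_proj is None:
            raise ValueError("perturbation projection not initialized")
        v = emb.perturb_embedding @ emb.perturb_proj
        if v.shape[0] != d:
            raise ValueError("perturbation projection output dimension mismatch")
        if emb.perturb_scope == STIMULATED and emb.condition is not None:
            cond = emb.condition if rows is None else emb.condition[rows]
            mask = (cond == STIMULATED).astype(np.float64)[:, None]
            out = out + mask * v[None, :]
        else:
            out = out + v[None, :]
    return out
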