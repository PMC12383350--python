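"""Shared data model, file I/O, configuration and seeding.

Cells are rows and genes are columns everywhere in this package. The two
experimental conditions are always mapped onto the canonical labels
``"control"`` and ``"stimulated"``; model outputs carry ``"predicted"``.
"""

from __future__ import annotations

import dataclasses
import logging
import os
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("otperturb")

CONTROL = "control"
STIMULATED = "stimulated"
PREDICTED = "predicted"
_ALLOWED_CONDITIONS = {CONTROL, STIMULATED, PREDICTED}

RAW_COUNTS = "raw_counts"
NORMALIZED_LOG = "normalized_log"


class DataValidationError(ValueError):
    """Raised when a dataset violates the data-model contract."""


@dataclass
class ExpressionDataset:
    """A cells x genes expression matrix with per-cell metadata.

    Parameters
    ----------
    matrix
        Dense ``(n_cells, n_genes)`` float array; raw counts or
        log-normalized values depending on ``layer_tag``.
    cell_ids, gene_ids
        Unique string identifiers for rows and columns.
    cell_type
        Categorical label per cell.
    condition
        Per-cell condition, each entry one of ``control``, ``stimulated``
        or ``predicted``.
    layer_tag
        Which transform the matrix currently carries:
        ``"raw_counts"`` or ``"normalized_log"``.
    """

    matrix: np.ndarray
    cell_ids: np.ndarray
    gene_ids: np.ndarray
    cell_type: np.ndarray
    condition: np.ndarray
    layer_tag: str = RAW_COUNTS

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.float64)
        self.cell_ids = np.asarray(self.cell_ids, dtype=object)
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        self.cell_type = np.asarray(self.cell_type, dtype=object)
        self.condition = np.asarray(self.condition, dtype=object)
        self.validate()

    # -- contract ---------------------------------------------------------
    def validate(self) -> None:
        n, d = self.matrix.shape
        if n == 0:
            raise DataValidationError("dataset has zero cells")
        if d == 0:
            raise DataValidationError("dataset has zero genes")
        if len(self.cell_ids) != n:
            raise DataValidationError(
                f"{len(self.cell_ids)} cell_ids for {n} matrix rows"
            )
        if len(self.gene_ids) != d:
            raise DataValidationError(
                f"{len(self.gene_ids)} gene_ids for {d} matrix columns"
            )
        for name, arr in (("cell_type", self.cell_type), ("condition", self.condition)):
            if len(arr) != n:
                raise DataValidationError(f"{name} has {len(arr)} entries for {n} cells")
            if any(x is None or (isinstance(x, float) and np.isnan(x)) for x in arr):
                raise DataValidationError(f"column '{name}' contains missing labels")
        bad = set(self.condition) - _ALLOWED_CONDITIONS
        if bad:
            raise DataValidationError(
                f"unexpected condition level(s) {sorted(bad)}; "
                f"expected subset of {sorted(_ALLOWED_CONDITIONS)}"
            )
        if self.layer_tag not in (RAW_COUNTS, NORMALIZED_LOG):
            raise DataValidationError(f"unknown layer_tag '{self.layer_tag}'")
        if self.layer_tag == RAW_COUNTS and np.any(self.matrix < 0):
            raise DataValidationError("raw_counts matrix contains negative entries")
        if self.layer_tag == NORMALIZED_LOG and not np.all(np.isfinite(self.matrix)):
            raise DataValidationError("normalized_log matrix contains non-finite entries")

    # -- convenience ------------------------------------------------------
    @property
    def n_cells(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_genes(self) -> int:
        return self.matrix.shape[1]

    def subset_cells(self, index: np.ndarray) -> "ExpressionDataset":
        """Row subset (boolean mask or integer index), order-preserving."""
        return ExpressionDataset(
            matrix=self.matrix[index],
            cell_ids=self.cell_ids[index],
            gene_ids=self.gene_ids,
            cell_type=self.cell_type[index],
            condition=self.condition[index],
            layer_tag=self.layer_tag,
        )

    def subset_genes(self, index: np.ndarray) -> "ExpressionDataset":
        return ExpressionDataset(
            matrix=self.matrix[:, index],
            cell_ids=self.cell_ids,
            gene_ids=self.gene_ids[index],
            cell_type=self.cell_type,
            condition=self.condition,
            layer_tag=self.layer_tag,
        )

    def copy(self) -> "ExpressionDataset":
        return ExpressionDataset(
            matrix=self.matrix.copy(),
            cell_ids=self.cell_ids.copy(),
            gene_ids=self.gene_ids.copy(),
            cell_type=self.cell_type.copy(),
            condition=self.condition.copy(),
            layer_tag=self.layer_tag,
        )

    def to_anndata(self):
        import anndata as ad

        obs = pd.DataFrame(
            {
                "cell_type": pd.Categorical(self.cell_type.astype(str)),
                "condition": pd.Categorical(self.condition.astype(str)),
            },
            index=pd.Index(self.cell_ids.astype(str), name="cell_id"),
        )
        var = pd.DataFrame(index=pd.Index(self.gene_ids.astype(str), name="gene_id"))
        adata = ad.AnnData(X=self.matrix.copy(), obs=obs, var=var)
        adata.uns["layer_tag"] = self.layer_tag
        return adata


@dataclass
class RunConfig:
    """Flat configuration for an end-to-end run; every field has a default
    and every field is overridable from the CLI or a YAML config file."""

    seed: int = 0
    latent_dim: int = 100
    hidden_widths: Sequence[int] = field(default_factory=lambda: [800, 800])
    alpha: float = 1.0
    kernel_bandwidth: float = 1.0
    batch_size: int = 256
    epochs: int = 100
    learning_rate: float = 1e-3
    dropout: float = 0.2
    top_k: int = 30
    regularizer: str = "mmd"
    use_cell_embedding: bool = False
    use_perturb_embedding: bool = False
    perturb_embed_scope: str = "all"  # {all | stimulated}
    ot_max_cells: int = 5000
    ot_equalize: bool = True
    literal_delta: bool = False
    hvg_count: int = 6998
    target_sum: float = 1e4
    min_genes_per_cell: int = 500
    min_cells_per_gene: int = 5

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.alpha < 0:
            raise ValueError("alpha must be >= 0")
        if self.kernel_bandwidth <= 0:
            raise ValueError("kernel_bandwidth must be > 0")
        if self.top_k < 1:
            raise ValueError("top_k must be >= 1")
        if self.hvg_count < 1:
            raise ValueError("hvg_count must be >= 1")
        if self.regularizer not in ("mmd", "kl"):
            raise ValueError("regularizer must be 'mmd' or 'kl'")
        if self.perturb_embed_scope not in ("all", "stimulated"):
            raise ValueError("perturb_embed_scope must be 'all' or 'stimulated'")
        if not 0 <= self.dropout < 1:
            raise ValueError("dropout must be in [0, 1)")
        if self.latent_dim < 1 or self.batch_size < 1 or self.epochs < 0:
            raise ValueError("latent_dim/batch_size must be >= 1; epochs >= 0")
        if self.learning_rate <= 0 or self.target_sum <= 0:
            raise ValueError("learning_rate and target_sum must be > 0")

    def replace(self, **kwargs) -> "RunConfig":
        return dataclasses.replace(self, **kwargs)

    def to_dict(self) -> dict:
        out = dataclasses.asdict(self)
        out["hidden_widths"] = list(self.hidden_widths)
        return out

    def to_yaml(self, path: str | os.PathLike) -> str:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)
        return str(path)

    @classmethod
    def from_yaml(cls, path: str | os.PathLike) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


# ---------------------------------------------------------------------------
# seeding

_GLOBAL_SEED: int | None = None
_GLOBAL_RNG = np.random.default_rng(0)


def set_global_seed(seed: int) -> None:
    """Seed every random stream in the package (and legacy numpy global)."""
    global _GLOBAL_SEED, _GLOBAL_RNG
    _GLOBAL_SEED = int(seed)
    _GLOBAL_RNG = np.random.default_rng(_GLOBAL_SEED)
    np.random.seed(_GLOBAL_SEED % (2**32))
    logger.debug("global seed set to %d", _GLOBAL_SEED)


def get_rng(seed: int | None = None) -> np.random.Generator:
    """A generator derived from an explicit seed, or the global stream."""
    if seed is not None:
        return np.random.default_rng(seed)
    return _GLOBAL_RNG


def configure_logging(level: int = logging.INFO, logfile: str | None = None) -> None:
    handlers: list[logging.Handler] = [logging.StreamHandler()]
    if logfile:
        handlers.append(logging.FileHandler(logfile))
    fmt = "%(asctime)s %(levelname)s %(name)s: %(message)s"
    logging.basicConfig(level=level, format=fmt, handlers=handlers, force=True)


# ---------------------------------------------------------------------------
# reading / writing


def _infer_layer_tag(matrix: np.ndarray) -> str:
    if np.all(matrix >= 0) and np.allclose(matrix, np.round(matrix)):
        return RAW_COUNTS
    return NORMALIZED_LOG


def read_dataset(
    path: str | os.PathLike,
    cell_type_key: str = "cell_type",
    condition_key: str = "condition",
    control_level: str = CONTROL,
    stimulated_level: str = STIMULATED,
) -> ExpressionDataset:
    """Read an expression dataset from H5AD or delimited text.

    Delimited files must contain the two metadata columns named by
    ``cell_type_key``/``condition_key``; all remaining columns are treated
    as genes. Condition levels are mapped onto {control, stimulated}.
    """
    path = str(path)
    if path.endswith(".h5ad"):
        import anndata as ad

        adata = ad.read_h5ad(path)
        obs = adata.obs
        for key in (cell_type_key, condition_key):
            if key not in obs.columns:
                raise DataValidationError(f"obs column '{key}' not found in {path}")
        matrix = adata.X
        if not isinstance(matrix, np.ndarray):
            matrix = matrix.toarray()
        matrix = np.asarray(matrix, dtype=np.float64)
        cell_ids = obs.index.to_numpy(dtype=object)
        gene_ids = adata.var.index.to_numpy(dtype=object)
        cell_type = obs[cell_type_key].astype(str).to_numpy(dtype=object)
        condition_raw = obs[condition_key].astype(str).to_numpy(dtype=object)
        layer_tag = adata.uns.get("layer_tag", _infer_layer_tag(matrix))
    else:
        sep = "," if path.endswith(".csv") else "\t"
        df = pd.read_csv(path, sep=sep, index_col=0)
        for key in (cell_type_key, condition_key):
            if key not in df.columns:
                raise DataValidationError(f"column '{key}' not found in {path}")
        meta = df[[cell_type_key, condition_key]]
        expr = df.drop(columns=[cell_type_key, condition_key])
        non_numeric = [c for c in expr.columns if not pd.api.types.is_numeric_dtype(expr[c])]
        if non_numeric:
            raise DataValidationError(
                f"non-numeric expression column(s): {non_numeric[:5]}"
            )
        matrix = expr.to_numpy(dtype=np.float64)
        cell_ids = df.index.to_numpy(dtype=object)
        gene_ids = expr.columns.to_numpy(dtype=object)
        cell_type = meta[cell_type_key].astype(str).to_numpy(dtype=object)
        condition_raw = meta[condition_key].astype(str).to_numpy(dtype=object)
        layer_tag = _infer_layer_tag(matrix)

    mapping = {str(control_level): CONTROL, str(stimulated_level): STIMULATED,
               PREDICTED: PREDICTED}
    unexpected = sorted(set(condition_raw) - set(mapping))
    if unexpected:
        raise DataValidationError(
            f"column '{condition_key}' contains unexpected level(s) {unexpected}; "
            f"expected {{{control_level!r}, {stimulated_level!r}}}"
        )
    condition = np.array([mapping[str(c)] for c in condition_raw], dtype=object)
    return ExpressionDataset(
        matrix=matrix,
        cell_ids=cell_ids,
        gene_ids=gene_ids,
        cell_type=cell_type,
        condition=condition,
        layer_tag=layer_tag,
    )


def write_dataset(dataset: ExpressionDataset, path: str | os.PathLike) -> str:
    """Write to H5AD (``.h5ad``) or delimited text (``.tsv``/``.csv``)."""
    dataset.validate()
    path = str(path)
    parent = os.path.dirname(os.path.abspath(path))
    if parent and not os.path.isdir(parent):
        raise OSError(f"directory does not exist: {parent}")
    if path.endswith(".h5ad"):
        dataset.to_anndata().write_h5ad(path)
        return path
    sep = "," if path.endswith(".csv") else "\t"
    df = pd.DataFrame(
        dataset.matrix,
        index=pd.Index(dataset.cell_ids.astype(str), name="cell_id"),
        columns=dataset.gene_ids.astype(str),
    )
    df.insert(0, "cell_type", dataset.cell_type.astype(str))
    df.insert(1, "condition", dataset.condition.astype(str))
    df.to_csv(path, sep=sep)
    return path
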