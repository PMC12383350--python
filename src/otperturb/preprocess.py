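"""Quality filtering, normalization, HVG selection, splitting, subsampling."""

from __future__ import annotations

import logging

import numpy as np

from otperturb.data_io import (
    CONTROL,
    NORMALIZED_LOG,
    RAW_COUNTS,
    STIMULATED,
    ExpressionDataset,
)

logger = logging.getLogger("otperturb")


def filter_cells_genes(
    dataset: ExpressionDataset,
    min_genes_per_cell: int = 500,
    min_cells_per_gene: int = 5,
) -> ExpressionDataset:
    """Drop low-complexity cells, then rarely detected genes.

    A cell survives if it has at least ``min_genes_per_cell`` genes with
    nonzero counts; a gene survives if it is nonzero in at least
    ``min_cells_per_gene`` of the surviving cells. Single pass each,
    cells first.
    """
    if dataset.layer_tag != RAW_COUNTS:
        raise ValueError("filter_cells_genes expects raw counts")
    nonzero = dataset.matrix > 0
    keep_cells = nonzero.sum(axis=1) >= min_genes_per_cell
    if not keep_cells.any():
        raise ValueError(
            f"all {dataset.n_cells} cells removed at min_genes_per_cell="
            f"{min_genes_per_cell}"
        )
    filtered = dataset.subset_cells(keep_cells)
    keep_genes = (filtered.matrix > 0).sum(axis=0) >= min_cells_per_gene
    out = filtered.subset_genes(keep_genes)
    logger.info(
        "filter: %d -> %d cells, %d -> %d genes",
        dataset.n_cells, out.n_cells, dataset.n_genes, out.n_genes,
    )
    return out


def normalize_log(dataset: ExpressionDataset, target_sum: float = 1e4) -> ExpressionDataset:
    """Library-size normalize each cell to ``target_sum``, then log1p."""
    if dataset.layer_tag != RAW_COUNTS:
        raise ValueError("normalize_log expects raw counts")
    if target_sum <= 0:
        raise ValueError("target_sum must be positive")
    totals = dataset.matrix.sum(axis=1)
    zero = np.flatnonzero(totals == 0)
    if zero.size:
        raise ValueError(
            f"cell(s) with zero total counts: {list(dataset.cell_ids[zero[:5]])}"
        )
    scaled = dataset.matrix / totals[:, None] * target_sum
    out = dataset.copy()
    out.matrix = np.log1p(scaled)
    out.layer_tag = NORMALIZED_LOG
    return out


def dispersion_scores(matrix: np.ndarray, n_bins: int = 20) -> np.ndarray:
    """Mean-binned normalized dispersion per gene (Seurat-style).

    Dispersion is variance/mean on the provided (log-normalized) values;
    genes are binned by mean expression and their dispersions z-scored
    within each bin so that variability is compared among genes of similar
    abundance.
    """
    mean = matrix.mean(axis=0)
    var = matrix.var(axis=0, ddof=1) if matrix.shape[0] > 1 else np.zeros_like(mean)
    with np.errstate(divide="ignore", invalid="ignore"):
        disp = np.where(mean > 0, var / mean, 0.0)
    # quantile bins on the mean; keep bins >= ~10 genes so within-bin
    # z-scores stay meaningful, and floor the std to avoid 0/0
    d = mean.size
    n_bins = max(1, min(n_bins, d // 10))
    order = np.argsort(mean, kind="stable")
    bin_of = np.empty(d, dtype=int)
    bin_of[order] = np.minimum((np.arange(d) * n_bins) // d, n_bins - 1)
    score = np.zeros(d)
    for b in range(n_bins):
        members = bin_of == b
        if not members.any():
            continue
        mu = disp[members].mean()
        sd = disp[members].std(ddof=1) if members.sum() > 1 else 0.0
        sd = max(sd, 1e-12)
        score[members] = (disp[members] - mu) / sd
    return score


def select_hvg(dataset: ExpressionDataset, n_top: int = 6998) -> ExpressionDataset:
    """Keep the ``min(n_top, d)`` most variable genes; input gene order
    is preserved among the selected."""
    if n_top < 1:
        raise ValueError("n_top must be >= 1")
    if dataset.layer_tag != NORMALIZED_LOG:
        raise ValueError("select_hvg expects normalized_log values")
    d = dataset.n_genes
    if n_top >= d:
        return dataset
    score = dispersion_scores(dataset.matrix)
    # rank by score descending with deterministic tie-break on gene order
    ranked = np.lexsort((np.arange(d), -score))
    keep = np.zeros(d, dtype=bool)
    keep[ranked[:n_top]] = True
    return dataset.subset_genes(keep)


def holdout_split(
    dataset: ExpressionDataset,
    holdout_type: str,
    include_holdout_control_in_train: bool = True,
) -> tuple[ExpressionDataset, ExpressionDataset, ExpressionDataset]:
    """Split off one cell type's stimulated cells as the test set.

    Returns ``(train, test_control, test_stimulated)``: train is every
    cell except the held-out type's stimulated cells (the held-out type's
    control cells stay in train unless ``include_holdout_control_in_train``
    is False); test_control are that type's control cells; test_stimulated
    its stimulated ground truth, never seen in training.
    """
    is_type = dataset.cell_type == holdout_type
    is_ctrl = dataset.condition == CONTROL
    is_stim = dataset.condition == STIMULATED
    if not (is_type & is_ctrl).any():
        raise ValueError(f"holdout type {holdout_type!r} absent from control condition")
    if not (is_type & is_stim).any():
        raise ValueError(f"holdout type {holdout_type!r} absent from stimulated condition")
    train_mask = ~(is_type & is_stim)
    if not include_holdout_control_in_train:
        train_mask &= ~(is_type & is_ctrl)
    return (
        dataset.subset_cells(train_mask),
        dataset.subset_cells(is_type & is_ctrl),
        dataset.subset_cells(is_type & is_stim),
    )


def subsample_train(
    train: ExpressionDataset, fraction: float, seed: int
) -> ExpressionDataset:
    """Uniform subsample without replacement, stratified by
    (cell_type, condition); every stratum keeps at least one cell."""
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    if fraction == 1.0:
        return train
    rng = np.random.default_rng(seed)
    keep = np.zeros(train.n_cells, dtype=bool)
    strata = [
        (t, c)
        for t in sorted(set(train.cell_type))
        for c in sorted(set(train.condition))
    ]
    for t, c in strata:
        idx = np.flatnonzero((train.cell_type == t) & (train.condition == c))
        if idx.size == 0:
            continue
        n_keep = int(round(fraction * idx.size))
        if n_keep == 0:
            logger.warning(
                "stratum (%s, %s) would be emptied at fraction %.3f; keeping 1 cell",
                t, c, fraction,
            )
            n_keep = 1
        keep[rng.choice(idx, size=n_keep, replace=False)] = True
    return train.subset_cells(keep)
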