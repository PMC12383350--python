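"""Synthetic unpaired perturbation datasets with known ground truth.

Counts are negative binomial around gene baselines modulated by a
cell-type effect and a low-rank per-cell factor model (continuous cell
states, the kind of heterogeneity a latent-variable model can actually
capture); stimulated cells additionally apply a shared response program
(per-gene log-fold-changes on a fixed response gene set) scaled by a
per-type responsiveness factor. Control and stimulated cells are drawn
independently, so the data are unpaired by construction, and the response
direction is shared across types — the structural assumption the delta-
transfer predictor exploits.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from otperturb.data_io import CONTROL, RAW_COUNTS, STIMULATED, ExpressionDataset

logger = logging.getLogger("otperturb")


@dataclass
class SimConfig:
    n_cell_types: int = 3
    cells_per_type_per_condition: int | Sequence[int] = 400  # int or (ctrl, stim)
    n_genes: int = 1000
    n_response_genes: int = 100
    base_mean_log_mu: float = 0.5
    base_mean_log_sd: float = 1.0
    type_effect_sd: float = 0.05
    n_latent_factors: int = 8
    factor_loading_sd: float = 0.3
    lfc_mu: float = 1.0
    lfc_sd: float = 0.5
    lfc_positive_fraction: float = 1.0  # share of up-regulated response genes
    response_baseline_quantile: float = 0.5  # draw response genes above this
    type_response_scale: Sequence[float] | None = None  # default: U(0.7, 1.3)
    nb_dispersion: float = 50.0
    library_size_cv: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_response_genes > self.n_genes:
            raise ValueError("n_response_genes must be <= n_genes")
        if self.n_cell_types < 1 or self.n_genes < 1:
            raise ValueError("need at least one cell type and one gene")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be positive")
        if self.library_size_cv < 0 or self.lfc_sd < 0:
            raise ValueError("scale parameters must be nonnegative")
        if not 0 <= self.lfc_positive_fraction <= 1:
            raise ValueError("lfc_positive_fraction must be in [0, 1]")
        if not 0 <= self.response_baseline_quantile < 1:
            raise ValueError("response_baseline_quantile must be in [0, 1)")
        if self.type_response_scale is not None and len(
            self.type_response_scale
        ) != self.n_cell_types:
            raise ValueError("type_response_scale length must equal n_cell_types")

    def cells_for(self, condition: str) -> int:
        c = self.cells_per_type_per_condition
        if isinstance(c, (tuple, list)):
            return int(c[0] if condition == CONTROL else c[1])
        return int(c)


@dataclass
class GroundTruth:
    """Response gene set and the per-type expected log-expression shifts."""

    gene_ids: np.ndarray
    response_mask: np.ndarray  # bool per gene
    lfc: np.ndarray  # per-gene log-fold-change (0 off the response set)
    type_scales: dict = field(default_factory=dict)

    def to_json(self, path: str) -> str:
        with open(path, "w") as fh:
            json.dump(
                {
                    "gene_ids": [str(g) for g in self.gene_ids],
                    "response_genes": [
                        str(g) for g in self.gene_ids[self.response_mask]
                    ],
                    "lfc": self.lfc.tolist(),
                    "type_scales": {k: float(v) for k, v in self.type_scales.items()},
                },
                fh,
            )
        return path


def simulate_dataset(config: SimConfig) -> tuple[ExpressionDataset, GroundTruth]:
    """Draw a raw-count dataset plus its ground truth, fully seeded."""
    rng = np.random.default_rng(config.seed)
    d = config.n_genes
    types = [f"type{t}" for t in range(config.n_cell_types)]
    gene_ids = np.array([f"gene{g:04d}" for g in range(d)], dtype=object)

    baseline = np.exp(
        rng.normal(config.base_mean_log_mu, config.base_mean_log_sd, size=d)
    )
    type_effect = np.exp(
        rng.normal(0.0, config.type_effect_sd, size=(config.n_cell_types, d))
    )
    # response genes are drawn among reasonably expressed genes (a response
    # program on barely detected genes would be invisible after log1p)
    cutoff = np.quantile(baseline, config.response_baseline_quantile)
    eligible = np.flatnonzero(baseline >= cutoff)
    if eligible.size < config.n_response_genes:
        eligible = np.arange(d)
    response_idx = rng.choice(eligible, size=config.n_response_genes, replace=False)
    response_mask = np.zeros(d, dtype=bool)
    response_mask[response_idx] = True
    lfc = np.zeros(d)
    if config.n_response_genes:
        mags = rng.normal(config.lfc_mu, config.lfc_sd, size=config.n_response_genes)
        signs = np.where(
            rng.random(config.n_response_genes) < config.lfc_positive_fraction,
            1.0,
            -1.0,
        )
        lfc[response_idx] = signs * np.abs(mags)
    if config.type_response_scale is None:
        scales = rng.uniform(0.7, 1.3, size=config.n_cell_types)
    else:
        scales = np.asarray(config.type_response_scale, dtype=np.float64)
    q = config.n_latent_factors
    loadings = (
        rng.normal(0.0, config.factor_loading_sd, size=(q, d)) if q > 0 else None
    )

    blocks, cell_types, conditions, cell_ids = [], [], [], []
    counter = 0
    for t, tname in enumerate(types):
        for cond in (CONTROL, STIMULATED):
            n = config.cells_for(cond)
            mean = baseline * type_effect[t]
            if cond == STIMULATED:
                mean = mean * np.exp(lfc * scales[t])
            lib = np.exp(
                rng.normal(0.0, config.library_size_cv, size=n)
            ) if config.library_size_cv > 0 else np.ones(n)
            mu = lib[:, None] * mean[None, :]
            if loadings is not None:
                factors = rng.standard_normal((n, q))
                mu = mu * np.exp(factors @ loadings)
            # gamma-Poisson mixture == negative binomial with size r
            r = config.nb_dispersion
            lam = rng.gamma(shape=r, scale=mu / r)
            counts = rng.poisson(lam).astype(np.float64)
            blocks.append(counts)
            cell_types.extend([tname] * n)
            conditions.extend([cond] * n)
            cell_ids.extend(f"c{counter + i:06d}" for i in range(n))
            counter += n

    dataset = ExpressionDataset(
        matrix=np.vstack(blocks),
        cell_ids=np.array(cell_ids, dtype=object),
        gene_ids=gene_ids,
        cell_type=np.array(cell_types, dtype=object),
        condition=np.array(conditions, dtype=object),
        layer_tag=RAW_COUNTS,
    )
    truth = GroundTruth(
        gene_ids=gene_ids,
        response_mask=response_mask,
        lfc=lfc,
        type_scales={tname: float(scales[t]) for t, tname in enumerate(types)},
    )
    return dataset, truth


def ground_truth_shift(truth: GroundTruth, cell_type: str) -> np.ndarray:
    """Expected per-gene log-expression shift for one cell type; zero off
    the response gene set."""
    if cell_type not in truth.type_scales:
        raise KeyError(f"unknown cell type {cell_type!r}")
    return truth.lfc * truth.type_scales[cell_type]
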