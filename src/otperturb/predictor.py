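"""Prediction of stimulated profiles for unseen control cells.

Each test control cell is encoded to its latent mean, matched to its top-k
most cosine-similar training control cells, shifted by the similarity-
weighted combination of their transport deltas, and decoded back to gene
space.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from otperturb.data_io import NORMALIZED_LOG, PREDICTED, ExpressionDataset, RunConfig
from otperturb.embeddings import EmbeddingSet
from otperturb.mmdvae import MMDVAE
from otperturb.transport import DeltaMatrix

logger = logging.getLogger("otperturb")


@dataclass
class SimilarityWeights:
    """Top-k training-control indices and convex weights per test cell."""

    indices: np.ndarray  # (n_test, k_eff)
    weights: np.ndarray  # (n_test, k_eff), rows sum to 1

    def check(self, tol: float = 1e-12) -> None:
        if np.any(self.weights < 0):
            raise AssertionError("negative similarity weights")
        if not np.allclose(self.weights.sum(axis=1), 1.0, atol=tol):
            raise AssertionError("weights do not sum to 1")


def similarity_weights(
    z_test: np.ndarray, Z_ctrl_train: np.ndarray, top_k: int
) -> SimilarityWeights:
    """Cosine-similarity weights over the top-k nearest training controls.

    Negative similarities are clamped to zero before normalization; if all
    selected similarities clamp to zero the weights fall back to uniform.
    """
    if top_k < 1:
        raise ValueError("top_k must be >= 1")
    single = np.asarray(z_test).ndim == 1
    Zt = np.atleast_2d(np.asarray(z_test, dtype=np.float64))
    Zc = np.atleast_2d(np.asarray(Z_ctrl_train, dtype=np.float64))
    t_norm = np.linalg.norm(Zt, axis=1)
    c_norm = np.linalg.norm(Zc, axis=1)
    zero_t = np.flatnonzero(t_norm == 0)
    if zero_t.size:
        raise ValueError(f"zero-norm test latent at row(s) {zero_t[:5].tolist()}")
    zero_c = np.flatnonzero(c_norm == 0)
    if zero_c.size:
        raise ValueError(f"zero-norm training latent at row(s) {zero_c[:5].tolist()}")
    cos = (Zt / t_norm[:, None]) @ (Zc / c_norm[:, None]).T
    k_eff = min(top_k, Zc.shape[0])
    # stable sort on negated similarity gives a deterministic lowest-index
    # tie-break
    order = np.argsort(-cos, axis=1, kind="stable")[:, :k_eff]
    sims = np.take_along_axis(cos, order, axis=1)
    w = np.clip(sims, 0.0, None)
    totals = w.sum(axis=1)
    flat = totals == 0
    if flat.any():
        w[flat] = 1.0 / k_eff
        totals[flat] = 1.0
    w = w / totals[:, None]
    out = SimilarityWeights(indices=order, weights=w)
    out.check()
    return out


def aggregate_delta(weights: SimilarityWeights, deltas: DeltaMatrix) -> np.ndarray:
    """Convex combination of the selected delta rows per test cell."""
    D = deltas.deltas if isinstance(deltas, DeltaMatrix) else np.asarray(deltas)
    if weights.indices.max() >= D.shape[0]:
        raise IndexError("similarity index out of range for the delta matrix")
    picked = D[weights.indices]  # (n_test, k_eff, latent)
    return np.einsum("tk,tkd->td", weights.weights, picked)


def shift_and_decode(
    z_test: np.ndarray, delta_pred: np.ndarray, model: MMDVAE
) -> np.ndarray:
    """Decoder(z_test + delta_pred)."""
    z_test = np.asarray(z_test, dtype=np.float64)
    delta_pred = np.asarray(delta_pred, dtype=np.float64)
    if z_test.shape != delta_pred.shape:
        raise ValueError("z_test and delta_pred shapes must agree")
    return model.decode(z_test + delta_pred)


def predict_perturbed(
    test_control: ExpressionDataset,
    model: MMDVAE,
    deltas: DeltaMatrix,
    Z_ctrl_train: np.ndarray,
    config: RunConfig,
    emb: EmbeddingSet | None = None,
) -> ExpressionDataset:
    """Predict one stimulated profile per test control cell.

    Composition of encode -> similarity_weights -> aggregate_delta ->
    shift_and_decode; inference uses latent means, so the result is fully
    deterministic given a trained model.
    """
    if test_control.n_cells == 0:
        raise ValueError("empty test control set")
    mu, _ = model.encode(test_control.matrix, emb=emb)
    sw = similarity_weights(mu, Z_ctrl_train, config.top_k)
    delta_pred = aggregate_delta(sw, deltas)
    predicted = shift_and_decode(mu, delta_pred, model)
    return ExpressionDataset(
        matrix=predicted,
        cell_ids=np.array([f"{c}_pred" for c in test_control.cell_ids], dtype=object),
        gene_ids=test_control.gene_ids.copy(),
        cell_type=test_control.cell_type.copy(),
        condition=np.full(test_control.n_cells, PREDICTED, dtype=object),
        layer_tag=NORMALIZED_LOG,
    )
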