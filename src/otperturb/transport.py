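"""Exact optimal-transport alignment of latent populations and delta building.

The control and stimulated training populations are embedded with the
trained encoder (latent means), an exact earth-mover's coupling under
uniform marginals is solved, and each control cell's perturbation delta is
the barycentric projection of its transported mass minus its own latent.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import sparse
from scipy.optimize import linear_sum_assignment, linprog
from scipy.spatial.distance import cdist

from otperturb.data_io import CONTROL, STIMULATED, ExpressionDataset
from otperturb.embeddings import EmbeddingSet
from otperturb.mmdvae import MMDVAE

logger = logging.getLogger("otperturb")

_MARGINAL_TOL = 1e-8


@dataclass
class TransportResult:
    """Optimal coupling with its cost matrix, marginals and objective."""

    cost: np.ndarray
    coupling: np.ndarray
    source_marginal: np.ndarray
    target_marginal: np.ndarray
    objective: float

    def check(self, tol: float = _MARGINAL_TOL) -> None:
        if np.any(self.coupling < -tol):
            raise AssertionError("negative coupling entries")
        if not np.allclose(self.coupling.sum(axis=1), self.source_marginal, atol=tol):
            raise AssertionError("row sums violate source marginal")
        if not np.allclose(self.coupling.sum(axis=0), self.target_marginal, atol=tol):
            raise AssertionError("column sums violate target marginal")
        if abs(float((self.coupling * self.cost).sum()) - self.objective) > max(
            tol, 1e-8 * max(1.0, abs(self.objective))
        ):
            raise AssertionError("objective inconsistent with coupling x cost")


@dataclass
class DeltaMatrix:
    """Per-training-control-cell latent perturbation displacement."""

    deltas: np.ndarray  # (n_ctrl, k)


def latent_populations(
    model: MMDVAE,
    train: ExpressionDataset,
    max_cells: int = 5000,
    seed: int = 0,
    emb: EmbeddingSet | None = None,
    equalize: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Latent means of the training control and stimulated populations.

    Each population is subsampled (seeded, without replacement) to at most
    ``max_cells``; with ``equalize`` both are cut to a common size so the
    coupling problem is square and solvable by exact assignment.
    """
    ctrl_rows = np.flatnonzero(train.condition == CONTROL)
    stim_rows = np.flatnonzero(train.condition == STIMULATED)
    if ctrl_rows.size == 0 or stim_rows.size == 0:
        raise ValueError("both control and stimulated populations must be nonempty")
    rng = np.random.default_rng(seed)
    cap = max_cells
    if equalize:
        cap = min(cap, ctrl_rows.size, stim_rows.size)
    if ctrl_rows.size > cap:
        ctrl_rows = np.sort(rng.choice(ctrl_rows, size=cap, replace=False))
    if stim_rows.size > cap:
        stim_rows = np.sort(rng.choice(stim_rows, size=cap, replace=False))
    mu_ctrl, _ = model.encode(train.matrix[ctrl_rows], emb=emb, rows=ctrl_rows)
    mu_stim, _ = model.encode(train.matrix[stim_rows], emb=emb, rows=stim_rows)
    return mu_ctrl, mu_stim


def cost_matrix(Z_ctrl: np.ndarray, Z_stim: np.ndarray) -> np.ndarray:
    """Pairwise squared Euclidean distances, C[i, j] = ||z_i - z_j||^2."""
    Z_ctrl = np.atleast_2d(np.asarray(Z_ctrl, dtype=np.float64))
    Z_stim = np.atleast_2d(np.asarray(Z_stim, dtype=np.float64))
    if Z_ctrl.shape[1] != Z_stim.shape[1]:
        raise ValueError("latent dimensions differ")
    return cdist(Z_ctrl, Z_stim, metric="sqeuclidean")


def solve_emd(cost: np.ndarray) -> TransportResult:
    """Exact earth-mover's coupling under uniform marginals (1/n, 1/m).

    Square problems reduce to an optimal assignment (a Birkhoff vertex is
    optimal); rectangular ones are solved as a sparse linear program.
    """
    cost = np.asarray(cost, dtype=np.float64)
    if cost.ndim != 2:
        raise ValueError("cost must be a 2-D matrix")
    if not np.all(np.isfinite(cost)) or np.any(cost < 0):
        raise ValueError("cost must be finite and nonnegative")
    n, m = cost.shape
    mu = np.full(n, 1.0 / n)
    nu = np.full(m, 1.0 / m)
    if n == m:
        rows, cols = linear_sum_assignment(cost)
        coupling = np.zeros((n, m))
        coupling[rows, cols] = 1.0 / n
    else:
        # LP over vec(gamma): row-sum and column-sum equality constraints
        # (one column constraint dropped as redundant)
        row_A = sparse.kron(sparse.eye(n), np.ones((1, m)), format="csr")
        col_A = sparse.kron(np.ones((1, n)), sparse.eye(m), format="csr")[:-1]
        A_eq = sparse.vstack([row_A, col_A], format="csr")
        b_eq = np.concatenate([mu, nu[:-1]])
        res = linprog(
            cost.ravel(), A_eq=A_eq, b_eq=b_eq, bounds=(0, None), method="highs"
        )
        if not res.success:
            raise RuntimeError(
                f"EMD solver failed on a {n}x{m} cost matrix: {res.message}"
            )
        coupling = np.clip(res.x.reshape(n, m), 0.0, None)
    objective = float((coupling * cost).sum())
    result = TransportResult(
        cost=cost,
        coupling=coupling,
        source_marginal=mu,
        target_marginal=nu,
        objective=objective,
    )
    result.check()
    return result


def delta_matrix(
    result: TransportResult,
    Z_ctrl: np.ndarray,
    Z_stim: np.ndarray,
    literal: bool = False,
) -> DeltaMatrix:
    """Per-control-cell latent displacement toward its transported mass.

    Default is the barycentric projection: the coupling-weighted average of
    stimulated latents (row mass normalized) minus the control latent. With
    ``literal=True`` the row-mass normalization is omitted, i.e. the raw
    gamma-weighted sum is used, which shrinks the target barycenter by the
    row mass (kept as a debug reading).
    """
    gamma = result.coupling
    Z_ctrl = np.atleast_2d(Z_ctrl)
    Z_stim = np.atleast_2d(Z_stim)
    if gamma.shape != (Z_ctrl.shape[0], Z_stim.shape[0]):
        raise ValueError("coupling shape does not match the populations")
    row_mass = gamma.sum(axis=1)
    if np.any(row_mass <= 0):
        raise AssertionError("zero transported mass for some control cell")
    transported = gamma @ Z_stim
    if literal:
        deltas = transported - Z_ctrl
    else:
        deltas = transported / row_mass[:, None] - Z_ctrl
    return DeltaMatrix(deltas=deltas)
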