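"""MMD-regularized variational autoencoder with a pure-NumPy training loop.

The encoder maps the (optionally embedding-injected) expression matrix to a
Gaussian latent (mu, sigma); z = mu + eps * sigma via the reparameterization
trick; the decoder reconstructs expression from z. The total objective is

    L = mean_i ||x_i - x_hat_i||^2  +  alpha * regularizer

where the regularizer is either the squared maximum mean discrepancy between
the latent batch and a fresh standard-normal draw (V-statistic with an RBF
kernel) or, as an ablation arm, the closed-form KL to N(0, I).

Gradients are computed analytically (the graph is a small MLP plus the two
kernel sums), and parameters are updated with Adam. Randomness is split into
independent child streams (init / shuffling / eps / prior / dropout) so that
switching the regularizer arm changes only the regularizer pathway.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

from otperturb.data_io import NORMALIZED_LOG, ExpressionDataset, RunConfig
from otperturb.embeddings import EmbeddingSet, inject

logger = logging.getLogger("otperturb")

_LOGSIG_CLAMP = 5.0


# ---------------------------------------------------------------------------
# kernel / divergence primitives


def rbf_kernel(x: np.ndarray, y: np.ndarray, bandwidth: float) -> float:
    """Gaussian RBF kernel exp(-||x - y||^2 / (2 * bandwidth^2))."""
    if bandwidth <= 0:
        raise ValueError("bandwidth must be positive")
    x = np.asarray(x, dtype=np.float64).ravel()
    y = np.asarray(y, dtype=np.float64).ravel()
    if x.shape != y.shape:
        raise ValueError("x and y must have equal dimensions")
    sq = float(np.sum((x - y) ** 2))
    return float(np.exp(-sq / (2.0 * bandwidth**2)))


def _rbf_matrix(X: np.ndarray, Y: np.ndarray, bandwidth: float) -> np.ndarray:
    sq = cdist(X, Y, metric="sqeuclidean")
    return np.exp(-sq / (2.0 * bandwidth**2))


def mmd2(Z: np.ndarray, Z_prior: np.ndarray, bandwidth: float = 1.0) -> float:
    """Squared MMD between two samples (biased V-statistic, self-pairs kept).

    Nonnegative by construction for this estimator.
    """
    if bandwidth <= 0:
        raise ValueError("bandwidth must be positive")
    Z = np.atleast_2d(np.asarray(Z, dtype=np.float64))
    Zp = np.atleast_2d(np.asarray(Z_prior, dtype=np.float64))
    if Z.shape[0] == 0 or Zp.shape[0] == 0:
        raise ValueError("mmd2 requires nonempty samples")
    kzz = _rbf_matrix(Z, Z, bandwidth).mean()
    kpp = _rbf_matrix(Zp, Zp, bandwidth).mean()
    kzp = _rbf_matrix(Z, Zp, bandwidth).mean()
    return max(float(kzz + kpp - 2.0 * kzp), 0.0)


def _mmd2_grad_z(Z: np.ndarray, Zp: np.ndarray, bandwidth: float) -> np.ndarray:
    """d mmd2 / dZ for the V-statistic estimator."""
    B, Bp = Z.shape[0], Zp.shape[0]
    s2 = bandwidth**2
    Kzz = _rbf_matrix(Z, Z, bandwidth)
    Kzp = _rbf_matrix(Z, Zp, bandwidth)
    # within-sample term: (1/B^2) sum_ab k(z_a, z_b); symmetric double count
    g = (-2.0 / (B * B * s2)) * (Kzz.sum(axis=1)[:, None] * Z - Kzz @ Z)
    # cross term: -(2/(B*Bp)) sum_ij k(z_i, p_j)
    g += (2.0 / (B * Bp * s2)) * (Kzp.sum(axis=1)[:, None] * Z - Kzp @ Zp)
    return g


def kl_regularizer(mu: np.ndarray, sigma: np.ndarray) -> float:
    """Closed-form KL(N(mu, sigma^2) || N(0, I)), summed over latent
    dimensions and averaged over the batch."""
    mu = np.atleast_2d(np.asarray(mu, dtype=np.float64))
    sigma = np.atleast_2d(np.asarray(sigma, dtype=np.float64))
    per_cell = 0.5 * np.sum(mu**2 + sigma**2 - 1.0 - 2.0 * np.log(sigma), axis=1)
    return float(per_cell.mean())


def total_loss(
    D: np.ndarray,
    D_hat: np.ndarray,
    Z: np.ndarray,
    prior_draw: np.ndarray,
    alpha: float,
    regularizer: str = "mmd",
    bandwidth: float = 1.0,
    mu: np.ndarray | None = None,
    sigma: np.ndarray | None = None,
) -> float:
    """Reconstruction (mean per-cell squared error norm) + alpha * regularizer."""
    recon = float(np.sum((D - D_hat) ** 2, axis=1).mean())
    if alpha == 0:
        return recon
    if regularizer == "mmd":
        reg = mmd2(Z, prior_draw, bandwidth)
    elif regularizer == "kl":
        if mu is None or sigma is None:
            raise ValueError("kl regularizer needs mu and sigma")
        reg = kl_regularizer(mu, sigma)
    else:
        raise ValueError(f"unknown regularizer {regularizer!r}")
    return recon + alpha * reg


# ---------------------------------------------------------------------------
# model


def _relu(x: np.ndarray) -> np.ndarray:
    return np.maximum(x, 0.0)


@dataclass
class MMDVAE:
    """Encoder/decoder parameters plus optimizer state and loss history."""

    config: RunConfig
    input_dim: int
    params: dict = field(default_factory=dict)
    loss_history: list = field(default_factory=list)
    epochs_completed: int = 0
    input_center: np.ndarray | None = None
    _adam_m: dict = field(default_factory=dict, repr=False)
    _adam_v: dict = field(default_factory=dict, repr=False)
    _adam_t: int = 0

    # -- initialization ---------------------------------------------------
    def init_params(
        self,
        rng: np.random.Generator,
        emb: EmbeddingSet | None = None,
        output_bias: np.ndarray | None = None,
    ) -> None:
        d, k = self.input_dim, self.config.latent_dim
        widths = list(self.config.hidden_widths)
        p = {}
        dims = [d] + widths
        for i in range(len(widths)):
            p[f"enc_W{i}"] = rng.normal(0, np.sqrt(2.0 / dims[i]), (dims[i], dims[i + 1]))
            p[f"enc_b{i}"] = np.zeros(dims[i + 1])
        last = dims[-1]
        p["enc_Wmu"] = rng.normal(0, np.sqrt(1.0 / last), (last, k))
        p["enc_bmu"] = np.zeros(k)
        p["enc_Wls"] = rng.normal(0, np.sqrt(1.0 / last), (last, k))
        p["enc_bls"] = np.full(k, -1.0)  # start with small sigma
        rdims = [k] + widths[::-1]
        for i in range(len(widths)):
            p[f"dec_W{i}"] = rng.normal(0, np.sqrt(2.0 / rdims[i]), (rdims[i], rdims[i + 1]))
            p[f"dec_b{i}"] = np.zeros(rdims[i + 1])
        p["dec_Wout"] = rng.normal(0, np.sqrt(1.0 / rdims[-1]), (rdims[-1], d))
        # starting the output bias at the training gene means removes the
        # large mean component from the residual the decoder has to learn
        p["dec_bout"] = (
            np.zeros(d) if output_bias is None else np.asarray(output_bias, float).copy()
        )
        if emb is not None:
            emb.init_projections(d)
            if emb.cell_proj is not None:
                p["proj_cell"] = emb.cell_proj
            if emb.perturb_proj is not None:
                p["proj_perturb"] = emb.perturb_proj
        self.params = p

    def _sync_emb(self, emb: EmbeddingSet | None) -> EmbeddingSet | None:
        """Point the embedding projections at the learned parameters."""
        if emb is None or not emb.enabled:
            return emb
        if emb.cell_embedding is not None:
            emb.cell_proj = self.params.get("proj_cell")
        if emb.perturb_embedding is not None:
            emb.perturb_proj = self.params.get("proj_perturb")
        return emb

    # -- forward pieces ---------------------------------------------------
    def encode(
        self,
        x: np.ndarray,
        emb: EmbeddingSet | None = None,
        rows: np.ndarray | None = None,
    ) -> tuple[np.ndarray, np.ndarray]:
        """Deterministic map to (mu, sigma); accepts a row or a batch."""
        single = np.asarray(x).ndim == 1
        X = np.atleast_2d(np.asarray(x, dtype=np.float64))
        if X.shape[1] != self.input_dim:
            raise ValueError(f"input dimension {X.shape[1]} != {self.input_dim}")
        emb = self._sync_emb(emb)
        if emb is not None and emb.enabled:
            X = inject(X, emb, rows=rows)
        if self.input_center is not None:
            X = X - self.input_center
        h = X
        for i in range(len(self.config.hidden_widths)):
            h = _relu(h @ self.params[f"enc_W{i}"] + self.params[f"enc_b{i}"])
        mu = h @ self.params["enc_Wmu"] + self.params["enc_bmu"]
        ls = np.clip(
            h @ self.params["enc_Wls"] + self.params["enc_bls"],
            -_LOGSIG_CLAMP, _LOGSIG_CLAMP,
        )
        sigma = np.exp(ls)
        if single:
            return mu[0], sigma[0]
        return mu, sigma

    @staticmethod
    def reparameterize(mu: np.ndarray, sigma: np.ndarray, eps: np.ndarray) -> np.ndarray:
        """z = mu + eps * sigma, elementwise."""
        mu, sigma, eps = (np.asarray(a, dtype=np.float64) for a in (mu, sigma, eps))
        if not (mu.shape == sigma.shape == eps.shape):
            raise ValueError("mu, sigma, eps shapes must agree")
        return mu + eps * sigma

    def decode(self, z: np.ndarray) -> np.ndarray:
        single = np.asarray(z).ndim == 1
        Z = np.atleast_2d(np.asarray(z, dtype=np.float64))
        if Z.shape[1] != self.config.latent_dim:
            raise ValueError(
                f"latent dimension {Z.shape[1]} != {self.config.latent_dim}"
            )
        h = Z
        for i in range(len(self.config.hidden_widths)):
            h = _relu(h @ self.params[f"dec_W{i}"] + self.params[f"dec_b{i}"])
        out = h @ self.params["dec_Wout"] + self.params["dec_bout"]
        return out[0] if single else out

    # -- training ---------------------------------------------------------
    def _adam_step(self, grads: dict) -> None:
        lr, b1, b2, eps = self.config.learning_rate, 0.9, 0.999, 1e-8
        self._adam_t += 1
        t = self._adam_t
        for name, g in grads.items():
            if name not in self._adam_m:
                self._adam_m[name] = np.zeros_like(g)
                self._adam_v[name] = np.zeros_like(g)
            m = self._adam_m[name] = b1 * self._adam_m[name] + (1 - b1) * g
            v = self._adam_v[name] = b2 * self._adam_v[name] + (1 - b2) * g * g
            mhat = m / (1 - b1**t)
            vhat = v / (1 - b2**t)
            self.params[name] -= lr * mhat / (np.sqrt(vhat) + eps)

    def _train_batch(
        self,
        Xraw: np.ndarray,
        rows: np.ndarray,
        emb: EmbeddingSet | None,
        rng_eps: np.random.Generator,
        rng_prior: np.random.Generator,
        rng_drop: np.random.Generator,
    ) -> tuple[float, float]:
        """One forward/backward/update step; returns (recon, reg) values."""
        cfg = self.config
        k = cfg.latent_dim
        nh = len(cfg.hidden_widths)
        B = Xraw.shape[0]
        keep = 1.0 - cfg.dropout
        use_emb = emb is not None and emb.enabled

        X = inject(Xraw, emb, rows=rows) if use_emb else Xraw
        if self.input_center is not None:
            # constant shift for conditioning; gradients w.r.t. X unchanged
            X = X - self.input_center

        # ---- forward (cached) ----
        enc_pre, enc_act, enc_mask = [], [X], []
        h = X
        for i in range(nh):
            pre = h @ self.params[f"enc_W{i}"] + self.params[f"enc_b{i}"]
            h = _relu(pre)
            if cfg.dropout > 0:
                mask = (rng_drop.random(h.shape) < keep) / keep
                h = h * mask
            else:
                mask = None
            enc_pre.append(pre)
            enc_mask.append(mask)
            enc_act.append(h)
        pre_mu = h @ self.params["enc_Wmu"] + self.params["enc_bmu"]
        pre_ls = h @ self.params["enc_Wls"] + self.params["enc_bls"]
        ls = np.clip(pre_ls, -_LOGSIG_CLAMP, _LOGSIG_CLAMP)
        ls_mask = (pre_ls > -_LOGSIG_CLAMP) & (pre_ls < _LOGSIG_CLAMP)
        mu, sigma = pre_mu, np.exp(ls)
        eps = rng_eps.standard_normal((B, k))
        Z = mu + eps * sigma

        dec_pre, dec_act, dec_mask = [], [Z], []
        h = Z
        for i in range(nh):
            pre = h @ self.params[f"dec_W{i}"] + self.params[f"dec_b{i}"]
            h = _relu(pre)
            if cfg.dropout > 0:
                mask = (rng_drop.random(h.shape) < keep) / keep
                h = h * mask
            else:
                mask = None
            dec_pre.append(pre)
            dec_mask.append(mask)
            dec_act.append(h)
        Xhat = h @ self.params["dec_Wout"] + self.params["dec_bout"]

        recon = float(np.sum((Xraw - Xhat) ** 2, axis=1).mean())

        # ---- regularizer value and dZ/dmu/dls contributions ----
        reg = 0.0
        dZ_reg = np.zeros_like(Z)
        dmu_reg = np.zeros_like(mu)
        dls_reg = np.zeros_like(ls)
        if cfg.alpha > 0:
            if cfg.regularizer == "mmd":
                Zp = rng_prior.standard_normal((B, k))
                reg = mmd2(Z, Zp, cfg.kernel_bandwidth)
                dZ_reg = cfg.alpha * _mmd2_grad_z(Z, Zp, cfg.kernel_bandwidth)
            else:
                reg = kl_regularizer(mu, sigma)
                dmu_reg = cfg.alpha * mu / B
                dls_reg = cfg.alpha * (sigma**2 - 1.0) / B

        # ---- backward ----
        grads: dict[str, np.ndarray] = {}
        dXhat = (2.0 / B) * (Xhat - Xraw)
        grads["dec_Wout"] = dec_act[-1].T @ dXhat
        grads["dec_bout"] = dXhat.sum(axis=0)
        dh = dXhat @ self.params["dec_Wout"].T
        for i in range(nh - 1, -1, -1):
            if dec_mask[i] is not None:
                dh = dh * dec_mask[i]
            dpre = dh * (dec_pre[i] > 0)
            grads[f"dec_W{i}"] = dec_act[i].T @ dpre
            grads[f"dec_b{i}"] = dpre.sum(axis=0)
            dh = dpre @ self.params[f"dec_W{i}"].T
        dZ = dh + dZ_reg
        dmu = dZ + dmu_reg
        dls = (dZ * eps * sigma + dls_reg) * ls_mask

        grads["enc_Wmu"] = enc_act[-1].T @ dmu
        grads["enc_bmu"] = dmu.sum(axis=0)
        grads["enc_Wls"] = enc_act[-1].T @ dls
        grads["enc_bls"] = dls.sum(axis=0)
        dh = dmu @ self.params["enc_Wmu"].T + dls @ self.params["enc_Wls"].T
        for i in range(nh - 1, -1, -1):
            if enc_mask[i] is not None:
                dh = dh * enc_mask[i]
            dpre = dh * (enc_pre[i] > 0)
            grads[f"enc_W{i}"] = enc_act[i].T @ dpre
            grads[f"enc_b{i}"] = dpre.sum(axis=0)
            dh = dpre @ self.params[f"enc_W{i}"].T
        if use_emb:
            # dh is the gradient w.r.t. the injected input
            if emb.cell_embedding is not None:
                grads["proj_cell"] = emb.cell_embedding[rows].T @ dh
            if emb.perturb_embedding is not None:
                if emb.perturb_scope == "stimulated" and emb.condition is not None:
                    sel = (emb.condition[rows] == "stimulated").astype(float)[:, None]
                    dvec = (dh * sel).sum(axis=0)
                else:
                    dvec = dh.sum(axis=0)
                grads["proj_perturb"] = np.outer(emb.perturb_embedding, dvec)

        self._adam_step(grads)
        return recon, reg

    def fit(self, train_set: ExpressionDataset, emb: EmbeddingSet | None = None) -> "MMDVAE":
        cfg = self.config
        if train_set.layer_tag != NORMALIZED_LOG:
            raise ValueError("train expects a normalized_log dataset")
        X = train_set.matrix
        ss = np.random.SeedSequence(cfg.seed)
        rng_init, rng_shuf, rng_eps, rng_prior, rng_drop = (
            np.random.default_rng(c) for c in ss.spawn(5)
        )
        if not self.params:
            self.input_center = X.mean(axis=0)
            self.init_params(rng_init, emb, output_bias=self.input_center)
        emb = self._sync_emb(emb)
        n = X.shape[0]
        bs = min(cfg.batch_size, n)
        for epoch in range(cfg.epochs):
            perm = rng_shuf.permutation(n)
            recs, regs = [], []
            for start in range(0, n, bs):
                rows = perm[start : start + bs]
                if rows.size < 2:
                    continue  # MMD and batch statistics need >= 2 cells
                rec, reg = self._train_batch(
                    X[rows], rows, emb, rng_eps, rng_prior, rng_drop
                )
                if not (np.isfinite(rec) and np.isfinite(reg)):
                    raise RuntimeError(
                        f"non-finite loss at epoch {epoch}, batch starting {start}: "
                        f"recon={rec}, reg={reg}"
                    )
                recs.append(rec)
                regs.append(reg)
            entry = {
                "epoch": epoch,
                "recon": float(np.mean(recs)),
                "reg": float(np.mean(regs)),
            }
            entry["total"] = entry["recon"] + cfg.alpha * entry["reg"]
            self.loss_history.append(entry)
            self.epochs_completed += 1
            if epoch == 0 or (epoch + 1) % 20 == 0:
                logger.info(
                    "epoch %d: recon=%.4f reg=%.6f total=%.4f",
                    epoch, entry["recon"], entry["reg"], entry["total"],
                )
        return self

    # -- persistence ------------------------------------------------------
    def save(self, path: str) -> str:
        meta = json.dumps(
            {
                "config": self.config.to_dict(),
                "input_dim": self.input_dim,
                "loss_history": self.loss_history,
                "epochs_completed": self.epochs_completed,
            }
        )
        extra = {}
        if self.input_center is not None:
            extra["__center__"] = self.input_center
        np.savez(path, __meta__=np.array(meta), **extra, **self.params)
        return path

    @classmethod
    def load(cls, path: str) -> "MMDVAE":
        data = np.load(path if str(path).endswith(".npz") else str(path) + ".npz",
                       allow_pickle=False)
        meta = json.loads(str(data["__meta__"]))
        model = cls(config=RunConfig(**meta["config"]), input_dim=meta["input_dim"])
        model.params = {
            k: data[k] for k in data.files if k not in ("__meta__", "__center__")
        }
        if "__center__" in data.files:
            model.input_center = data["__center__"]
        model.loss_history = meta["loss_history"]
        model.epochs_completed = meta["epochs_completed"]
        return model


# alias matching the domain-type name used throughout the docs
ModelState = MMDVAE


def train(
    train_set: ExpressionDataset,
    emb: EmbeddingSet | None = None,
    config: RunConfig | None = None,
) -> MMDVAE:
    """Train an MMD-VAE on a normalized_log dataset; fully seeded by
    ``config.seed``."""
    config = config or RunConfig()
    if emb is not None:
        if not config.use_cell_embedding:
            emb = EmbeddingSet(
                perturb_embedding=emb.perturb_embedding,
                perturb_proj=emb.perturb_proj,
                perturb_scope=emb.perturb_scope,
                condition=emb.condition,
            )
        if not config.use_perturb_embedding:
            emb = EmbeddingSet(
                cell_embedding=emb.cell_embedding,
                cell_proj=emb.cell_proj,
                cell_ids=emb.cell_ids,
                condition=emb.condition,
            )
    model = MMDVAE(config=config, input_dim=train_set.n_genes)
    return model.fit(train_set, emb)


def tune_alpha(
    candidate_alphas: list[float],
    train_set: ExpressionDataset,
    config: RunConfig,
    emb: EmbeddingSet | None = None,
    probe_epochs: int = 3,
    val_fraction: float = 0.1,
    ratio_bounds: tuple[float, float] = (0.1, 10.0),
) -> float:
    """Grid-search alpha subject to the reconstruction:regularizer magnitude
    ratio lying in ``ratio_bounds`` after a short probe run.

    Candidates whose probe-run ratio falls outside the bounds are discarded;
    among the admissible ones the candidate with the best (lowest)
    validation reconstruction wins. Returns ``config.alpha`` if every
    candidate is discarded.
    """
    if not candidate_alphas:
        raise ValueError("candidate_alphas must be nonempty")
    rng = np.random.default_rng(config.seed)
    n = train_set.n_cells
    n_val = max(2, int(round(val_fraction * n)))
    perm = rng.permutation(n)
    val_idx, tr_idx = perm[:n_val], perm[n_val:]
    probe_train = train_set.subset_cells(tr_idx)
    val = train_set.subset_cells(val_idx)
    best_alpha, best_val = None, np.inf
    for alpha in candidate_alphas:
        if alpha <= 0:
            raise ValueError("candidate alphas must be positive")
        probe_cfg = config.replace(alpha=float(alpha), epochs=probe_epochs)
        model = train(probe_train, emb, probe_cfg)
        last = model.loss_history[-1]
        reg_mag = alpha * last["reg"]
        ratio = last["recon"] / reg_mag if reg_mag > 0 else np.inf
        if not ratio_bounds[0] <= ratio <= ratio_bounds[1]:
            logger.info("alpha=%g discarded (recon:reg ratio %.3g)", alpha, ratio)
            continue
        mu, _ = model.encode(val.matrix)
        val_recon = float(np.sum((val.matrix - model.decode(mu)) ** 2, axis=1).mean())
        logger.info("alpha=%g admissible (ratio %.3g, val recon %.4f)",
                    alpha, ratio, val_recon)
        if val_recon < best_val:
            best_alpha, best_val = float(alpha), val_recon
    return best_alpha if best_alpha is not None else config.alpha
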