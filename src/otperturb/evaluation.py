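"""Scoring of predictions against held-out stimulated ground truth.

Gene-wise mean and variance vectors of the predicted and observed
stimulated populations are compared by squared Pearson correlation, with
95% confidence intervals via the Fisher-z transform; biological relevance
is assessed by the overlap of the top-N differentially expressed genes
(rank-sum test against the shared control group).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from otperturb.data_io import NORMALIZED_LOG, ExpressionDataset

logger = logging.getLogger("otperturb")


@dataclass
class EvalReport:
    r_mean: float
    r2_mean: float
    r_var: float
    r2_var: float
    ci_low: float
    ci_high: float
    p_value: float
    n_genes: int
    deg_true: list = field(default_factory=list)
    deg_pred: list = field(default_factory=list)
    deg_overlap: int = 0

    def to_row(self) -> dict:
        return {
            "r2_mean": self.r2_mean,
            "r2_var": self.r2_var,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "p_value": self.p_value,
            "n_genes": self.n_genes,
            "deg_overlap": self.deg_overlap,
        }


def gene_stats(dataset: ExpressionDataset) -> tuple[np.ndarray, np.ndarray]:
    """Per-gene mean and (unbiased, ddof=1) variance over cells."""
    if dataset.layer_tag != NORMALIZED_LOG:
        raise ValueError("gene_stats expects normalized_log values")
    X = dataset.matrix
    if X.shape[0] == 0:
        raise ValueError("zero cells")
    means = X.mean(axis=0)
    if X.shape[0] == 1:
        variances = np.zeros_like(means)
    else:
        variances = X.var(axis=0, ddof=1)
    return means, variances


def regression_r2(
    pred_stat: np.ndarray, true_stat: np.ndarray
) -> tuple[float, float, tuple[float, float], float]:
    """Pearson r, r^2, Fisher-z 95% CI on r^2, and two-sided p for r = 0.

    The CI is built on the z scale with half-width 1.96/sqrt(d - 3),
    transformed back to r, clamped to [-1, 1], and squared (intervals that
    straddle zero get a lower endpoint of 0 so the point estimate stays
    inside).
    """
    pred_stat = np.asarray(pred_stat, dtype=np.float64)
    true_stat = np.asarray(true_stat, dtype=np.float64)
    if pred_stat.shape != true_stat.shape or pred_stat.ndim != 1:
        raise ValueError("statistic vectors must be 1-D with equal length")
    d = pred_stat.size
    if d < 3:
        raise ValueError("need at least 3 genes")
    if np.ptp(pred_stat) == 0 or np.ptp(true_stat) == 0:
        raise ValueError("constant statistic vector; correlation undefined")
    r, p = stats.pearsonr(pred_stat, true_stat)
    r = float(r)
    r2 = r * r
    z = np.arctanh(np.clip(r, -1 + 1e-15, 1 - 1e-15))
    half = 1.96 / np.sqrt(d - 3)
    lo = float(np.clip(np.tanh(z - half), -1.0, 1.0))
    hi = float(np.clip(np.tanh(z + half), -1.0, 1.0))
    if lo >= 0:
        ci = (lo * lo, hi * hi)
    elif hi <= 0:
        ci = (hi * hi, lo * lo)
    else:
        ci = (0.0, max(lo * lo, hi * hi))
    return r, r2, ci, float(p)


def _ranksum_scores(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Standardized two-sample rank-sum statistic per gene (column)."""
    return np.asarray(stats.ranksums(A, B, axis=0).statistic, dtype=np.float64)


def top_degs(
    group_a: ExpressionDataset, group_b: ExpressionDataset, n_top: int = 100
) -> list:
    """Genes ranked by absolute standardized rank-sum score between the two
    groups, largest first; ties broken by input gene order."""
    if group_a.n_cells < 2 or group_b.n_cells < 2:
        raise ValueError("each group needs at least 2 cells")
    if list(group_a.gene_ids) != list(group_b.gene_ids):
        raise ValueError("groups must share the gene axis")
    score = np.abs(_ranksum_scores(group_a.matrix, group_b.matrix))
    score = np.nan_to_num(score, nan=0.0)
    d = score.size
    order = np.lexsort((np.arange(d), -score))
    return list(group_a.gene_ids[order[: min(n_top, d)]])


def deg_overlap(list_a, list_b) -> int:
    """Size of the set intersection of two gene-id lists."""
    return len(set(list_a) & set(list_b))


def evaluate_experiment(
    predicted: ExpressionDataset,
    test_stimulated: ExpressionDataset,
    test_control: ExpressionDataset,
    n_top: int = 100,
) -> EvalReport:
    """Full report: mean/variance regressions of predicted vs observed
    stimulated plus top-N DEG overlap, both DEG lists taken against the
    same control group."""
    if list(predicted.gene_ids) != list(test_stimulated.gene_ids):
        raise ValueError("predicted and stimulated gene axes differ")
    mean_pred, var_pred = gene_stats(predicted)
    mean_true, var_true = gene_stats(test_stimulated)
    r_mean, r2_mean, ci, p = regression_r2(mean_pred, mean_true)
    r_var, r2_var, _, _ = regression_r2(var_pred, var_true)
    degs_true = top_degs(test_stimulated, test_control, n_top)
    degs_pred = top_degs(predicted, test_control, n_top)
    return EvalReport(
        r_mean=r_mean,
        r2_mean=r2_mean,
        r_var=r_var,
        r2_var=r2_var,
        ci_low=ci[0],
        ci_high=ci[1],
        p_value=p,
        n_genes=predicted.n_genes,
        deg_true=degs_true,
        deg_pred=degs_pred,
        deg_overlap=deg_overlap(degs_true, degs_pred),
    )
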