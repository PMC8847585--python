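"""Count normalization and differential expression.

The test is a self-contained negative-binomial Wald test: counts are
normalized by median-of-ratios size factors, per-gene dispersions are
estimated by the method of moments and pooled across genes of similar
mean, and the log2 fold change is tested against its delta-method
standard error. DEGs are called at |log2FC| >= 1 with BH-adjusted
p <= 0.05 by default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "size_factors",
    "nb_wald_test",
    "bh_adjust",
    "call_degs",
    "fpkm",
    "ddct_fold_change",
    "DEResult",
]


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios normalization factors, one per sample (column).

    Each sample's factor is the median, over genes with all-positive
    counts, of that gene's count divided by its across-sample geometric
    mean.
    """
    mat = counts.to_numpy(dtype=float)
    positive = (mat > 0).all(axis=1)
    if not positive.any():
        raise ValueError("no gene with all-positive counts; size factors undefined")
    ref = mat[positive]
    log_geomean = np.log(ref).mean(axis=1, keepdims=True)
    ratios = np.exp(np.log(ref) - log_geomean)
    return pd.Series(np.median(ratios, axis=0), index=counts.columns, name="size_factor")


@dataclass
class DEResult:
    """Per-gene differential-expression table (gene, log2fc, p, padj, call)."""

    table: pd.DataFrame

    @property
    def log2fc(self) -> pd.Series:
        return self.table["log2fc"]

    @property
    def p(self) -> pd.Series:
        return self.table["p"]

    @property
    def padj(self) -> pd.Series:
        return self.table["padj"]


def _pooled_dispersion(norm: np.ndarray, conditions: np.ndarray, n_bins: int = 20) -> np.ndarray:
    """Method-of-moments dispersion, pooled within bins of similar mean.

    Per gene alpha solves var = mu + alpha * mu^2 using within-condition
    variances; the per-gene estimates are then replaced by the mean of
    their log-mean bin. The bin mean (not median) is used because the
    few-replicate variance estimate is right-skewed: it is unbiased in
    expectation, so averaging ~n/20 genes per bin keeps the pooled
    dispersion unbiased while washing out the per-gene noise.
    """
    overall = norm.mean(axis=1)
    groups = np.unique(conditions)
    resid_var = np.zeros(len(norm))
    for cond in groups:
        resid_var += norm[:, conditions == cond].var(axis=1, ddof=1)
    resid_var /= len(groups)
    mu = np.maximum(overall, 1e-8)
    alpha = np.maximum((resid_var - mu) / mu**2, 0.0)

    order = np.argsort(np.log1p(mu), kind="mergesort")
    pooled = np.zeros_like(alpha)
    edges = np.linspace(0, len(alpha), n_bins + 1).astype(int)
    for lo, hi in zip(edges[:-1], edges[1:]):
        idx = order[lo:hi]
        if len(idx):
            pooled[idx] = alpha[idx].mean()
    return pooled


def nb_wald_test(
    counts: pd.DataFrame, conditions, pseudocount: float = 1.0
) -> DEResult:
    """NB Wald test of treated vs control on normalized counts.

    ``conditions`` labels each column 'control' or 'treated' (>= 2
    replicates each). log2fc = log2((mean_trt + pc) / (mean_ctrl + pc));
    the Wald statistic divides it by a delta-method SE built from the
    pooled moment dispersion; p is two-sided normal.
    """
    conditions = np.asarray(list(conditions))
    if len(conditions) != counts.shape[1]:
        raise ValueError("one condition label per sample column is required")
    for cond in ("control", "treated"):
        if (conditions == cond).sum() < 2:
            raise ValueError(f"need >= 2 replicates in condition {cond!r}")
    sf = size_factors(counts).to_numpy()
    norm = counts.to_numpy(dtype=float) / sf[None, :]

    is_t = conditions == "treated"
    n_c, n_t = int((~is_t).sum()), int(is_t.sum())
    mean_c = norm[:, ~is_t].mean(axis=1)
    mean_t = norm[:, is_t].mean(axis=1)
    log2fc = np.log2((mean_t + pseudocount) / (mean_c + pseudocount))

    alpha = _pooled_dispersion(norm, conditions)
    ln2sq = np.log(2.0) ** 2
    var_c = (mean_c + alpha * mean_c**2) / n_c
    var_t = (mean_t + alpha * mean_t**2) / n_t
    se_sq = (var_c / (mean_c + pseudocount) ** 2 + var_t / (mean_t + pseudocount) ** 2) / ln2sq
    se = np.sqrt(se_sq)

    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, log2fc / np.where(se > 0, se, 1.0), 0.0)
    p = 2.0 * stats.norm.sf(np.abs(z))
    p = np.clip(p, 0.0, 1.0)

    table = pd.DataFrame(
        {"log2fc": log2fc, "p": p, "padj": bh_adjust(p), "se": se},
        index=counts.index,
    )
    return DEResult(table)


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, capped at 1."""
    p = np.asarray(pvals, dtype=float)
    if p.size and (np.nanmin(p) < 0 or np.nanmax(p) > 1):
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p.copy()
    return stats.false_discovery_control(p, method="bh")


def call_degs(result: DEResult, lfc: float = 1.0, alpha: float = 0.05) -> tuple[list, list]:
    """Up/down DEG lists: |log2FC| >= lfc and padj <= alpha (inclusive)."""
    t = result.table
    up = t.index[(t["log2fc"] >= lfc) & (t["padj"] <= alpha)].tolist()
    down = t.index[(t["log2fc"] <= -lfc) & (t["padj"] <= alpha)].tolist()
    return up, down


def fpkm(counts: pd.DataFrame, gene_lengths_bp, library_sizes) -> pd.DataFrame:
    """Fragments per kilobase per million: count * 1e9 / (length * libsize)."""
    lengths = np.asarray(gene_lengths_bp, dtype=float)
    libs = np.asarray(library_sizes, dtype=float)
    if np.any(lengths <= 0):
        raise ValueError("gene lengths must be positive")
    if np.any(libs <= 0):
        raise ValueError("library sizes must be positive")
    mat = counts.to_numpy(dtype=float) * 1e9 / (lengths[:, None] * libs[None, :])
    return pd.DataFrame(mat, index=counts.index, columns=counts.columns)


def ddct_fold_change(
    ct_target_treated: float,
    ct_ref_treated: float,
    ct_target_control: float,
    ct_ref_control: float,
) -> float:
    """Relative qPCR quantification by the 2^-ddCt method."""
    ddct = (ct_target_treated - ct_ref_treated) - (ct_target_control - ct_ref_control)
    return float(2.0 ** (-ddct))
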