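"""Epigenetic typing of genes and signature extraction.

Genes are clustered on four z-scored features — expression log2FC,
promoter DNA methylation, H3K4me3 and chromatin accessibility — while
the H3K27me3 promoter signal is deliberately held out. After k-means
with silhouette-based selection of k, the cluster with the highest mean
held-out H3K27me3 is labeled the PRC2-target type, mirroring the
post-hoc characterization of bivalent, de-repressible genes. The final
signature is the intersection of that type with the up-regulated DEGs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score

logger = logging.getLogger(__name__)

__all__ = [
    "CLUSTER_FEATURES",
    "HELDOUT_FEATURE",
    "build_feature_matrix",
    "zscore_features",
    "kmeans_fit",
    "mean_silhouette",
    "select_k",
    "assign_types",
    "overlap_signature",
    "KMeansModel",
    "TypeMap",
    "SignatureResult",
]

CLUSTER_FEATURES = ["expression_log2fc", "methylation", "h3k4me3", "atac"]
HELDOUT_FEATURE = "h3k27me3"


def build_feature_matrix(
    log2fc: pd.Series,
    methylation: pd.Series,
    h3k4me3: pd.Series,
    atac: pd.Series,
    h3k27me3: pd.Series,
) -> tuple[pd.DataFrame, list[str]]:
    """Align per-gene features into one matrix; drop and report incomplete genes."""
    frame = pd.DataFrame(
        {
            "expression_log2fc": log2fc,
            "methylation": methylation,
            "h3k4me3": h3k4me3,
            "atac": atac,
            "h3k27me3": h3k27me3,
        }
    )
    complete = frame.dropna()
    dropped = sorted(set(frame.index) - set(complete.index))
    if dropped:
        logger.warning("dropping %d genes with missing features", len(dropped))
    return complete, dropped


def zscore_features(features: pd.DataFrame) -> pd.DataFrame:
    """Standardize the clustering columns to mean 0, population SD 1.

    Zero-variance columns map to all zeros. Non-clustering columns (the
    held-out H3K27me3) pass through untouched.
    """
    if len(features) < 2:
        raise ValueError("need at least 2 genes to z-score")
    out = features.copy()
    cols = [c for c in CLUSTER_FEATURES if c in features.columns]
    if not cols:
        raise ValueError("no clustering feature columns present")
    for col in cols:
        x = features[col].to_numpy(dtype=float)
        sd = x.std()  # population SD
        out[col] = np.zeros_like(x) if sd == 0 else (x - x.mean()) / sd
    return out


@dataclass
class KMeansModel:
    k: int
    centroids: np.ndarray
    assignments: pd.Series  # gene -> cluster index
    inertia: float
    seed: int
    n_init: int


def _cluster_columns(z: pd.DataFrame) -> pd.DataFrame:
    cols = [c for c in CLUSTER_FEATURES if c in z.columns]
    return z[cols] if cols else z


def kmeans_fit(
    z: pd.DataFrame,
    k: int,
    seed: int = 0,
    n_init: int = 10,
    tol: float = 1e-6,
    max_iter: int = 300,
) -> KMeansModel:
    """Lloyd k-means with k-means++ init; best of ``n_init`` restarts."""
    X = _cluster_columns(z).to_numpy(dtype=float)
    n_distinct = len(np.unique(X, axis=0))
    if k > n_distinct:
        raise ValueError(f"k={k} exceeds the {n_distinct} distinct rows")
    km = KMeans(
        n_clusters=k, init="k-means++", n_init=n_init, tol=tol,
        max_iter=max_iter, random_state=seed,
    ).fit(X)
    assignments = pd.Series(km.labels_, index=z.index, name="cluster")
    return KMeansModel(k, km.cluster_centers_, assignments, float(km.inertia_), seed, n_init)


def mean_silhouette(z: pd.DataFrame, assignments: pd.Series) -> float:
    """Mean silhouette (b - a)/max(a, b) over genes; singleton clusters score 0."""
    labels = assignments.loc[z.index].to_numpy()
    if len(np.unique(labels)) < 2:
        raise ValueError("silhouette requires at least 2 clusters")
    X = _cluster_columns(z).to_numpy(dtype=float)
    return float(silhouette_score(X, labels))


def select_k(
    z: pd.DataFrame,
    k_range=range(2, 11),
    seed: int = 0,
    n_init: int = 10,
) -> tuple[int, pd.DataFrame]:
    """Fit each k, score by mean silhouette, return the argmax (ties -> smaller k).

    The full per-k table (silhouette, inertia) is returned for audit so a
    user can override the automatic choice.
    """
    ks = [k for k in k_range]
    if not ks:
        raise ValueError("empty k range")
    rows = []
    models: dict[int, KMeansModel] = {}
    for k in ks:
        model = kmeans_fit(z, k, seed=seed, n_init=n_init)
        models[k] = model
        rows.append((k, mean_silhouette(z, model.assignments), model.inertia))
    table = pd.DataFrame(rows, columns=["k", "silhouette", "inertia"])
    best = int(table.loc[table["silhouette"].idxmax(), "k"])  # idxmax keeps first = smallest k
    return best, table


@dataclass
class TypeMap:
    """Semantic label per cluster; exactly one cluster is the PRC2-target type."""

    labels: dict[int, str]
    prc2_cluster: int
    mean_heldout: pd.Series = field(repr=False, default=None)

    def types_for(self, assignments: pd.Series) -> pd.Series:
        return assignments.map(self.labels).rename("type")


_FEATURE_TYPE_NAMES = {
    "methylation": "methylated",
    "h3k4me3": "active",
    "atac": "accessible",
    "expression_log2fc": "induced",
}


def assign_types(model: KMeansModel, heldout_h3k27me3: pd.Series) -> TypeMap:
    """Label clusters; the max-mean held-out H3K27me3 cluster is ``prc2_target``.

    Remaining clusters are named for their strongest mean z-scored
    clustering feature (or ``quiescent`` when every feature mean is
    negative); name collisions get a cluster-index suffix. Ties on the
    held-out mean resolve to the lower cluster index with a warning.
    """
    genes = model.assignments.index
    missing = sorted(set(genes) - set(heldout_h3k27me3.dropna().index))
    if missing:
        raise ValueError(f"genes missing held-out H3K27me3 values: {missing[:5]} ...")
    heldout = heldout_h3k27me3.loc[genes]
    mean_heldout = heldout.groupby(model.assignments).mean().sort_index()
    top = mean_heldout.max()
    winners = mean_heldout.index[mean_heldout == top].tolist()
    if len(winners) > 1:
        logger.warning("tied mean H3K27me3 across clusters %s; taking the lowest", winners)
    prc2 = int(min(winners))

    labels: dict[int, str] = {prc2: "prc2_target"}
    used = {"prc2_target"}
    centroid_cols = [c for c in CLUSTER_FEATURES]
    for idx in sorted(set(model.assignments.unique())):
        if idx == prc2:
            continue
        center = model.centroids[idx]
        if center.max() < 0:
            name = "quiescent"
        else:
            name = _FEATURE_TYPE_NAMES[centroid_cols[int(np.argmax(center))]]
        if name in used:
            name = f"{name}_{idx}"
        labels[idx] = name
        used.add(name)
    return TypeMap(labels, prc2, mean_heldout)


@dataclass
class SignatureResult:
    """Intersection of the PRC2-target type with the up-regulated DEGs."""

    type_genes: list[str]
    up_degs: list[str]
    signature: list[str]
    counts: tuple[int, int, int]  # |type|, |up|, |intersection|


def overlap_signature(type_genes, up_degs) -> SignatureResult:
    """Order-stable (sorted) intersection with Venn counts."""
    a, b = set(type_genes), set(up_degs)
    inter = sorted(a & b)
    return SignatureResult(
        sorted(a), sorted(b), inter, (len(a), len(b), len(inter))
    )
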