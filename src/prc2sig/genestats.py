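"""Gene-set statistics: Fisher-exact enrichment, preranked GSEA, Kruskal-Wallis.

The GSEA here is a minimal preranked reimplementation: a running sum
walks the ranked gene list, incrementing on gene-set hits by
|score|^weight (normalized by the hit total) and decrementing on misses
by 1/(N - |S|); the enrichment score is the signed maximal deviation,
and significance comes from a seeded gene-label permutation null.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .diffexpr import bh_adjust

logger = logging.getLogger(__name__)

__all__ = [
    "fisher_enrich",
    "enrich_genesets",
    "gsea_preranked",
    "kruskal_wallis",
    "GseaResult",
]


def fisher_enrich(a: int, b: int, c: int, d: int) -> tuple[float, float]:
    """One-sided (greater) Fisher exact p and odds ratio for a 2x2 table.

    a = signature AND set, b = signature only, c = set only, d = rest of
    the universe. p is the hypergeometric upper-tail probability of an
    overlap >= a at fixed margins; OR = ad/bc (inf when bc = 0).
    """
    cells = (a, b, c, d)
    if any(int(x) != x or x < 0 for x in cells):
        raise ValueError("contingency cells must be nonnegative integers")
    p = float(stats.fisher_exact([[a, b], [c, d]], alternative="greater")[1])
    odds = float("inf") if b * c == 0 else (a * d) / (b * c)
    return p, odds


def enrich_genesets(
    signature, genesets: dict[str, list[str]], universe
) -> pd.DataFrame:
    """Fisher-exact enrichment of the signature in each gene set, BH across sets.

    Sets are intersected with the universe first; sets disjoint from the
    universe are skipped with a warning. Result is sorted by p.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    sig = set(signature)
    if not sig <= universe:
        raise ValueError("signature must be a subset of the universe")
    rows = []
    for name, members in genesets.items():
        gene_set = set(members) & universe
        if not gene_set:
            logger.warning("gene set %r is disjoint from the universe; skipped", name)
            continue
        a = len(sig & gene_set)
        b = len(sig - gene_set)
        c = len(gene_set - sig)
        d = len(universe) - a - b - c
        p, odds = fisher_enrich(a, b, c, d)
        rows.append((name, a, b, c, d, odds, p))
    table = pd.DataFrame(rows, columns=["set", "a", "b", "c", "d", "odds_ratio", "p"])
    if len(table):
        table["padj"] = bh_adjust(table["p"].to_numpy())
        table = table.sort_values("p", kind="mergesort", ignore_index=True)
    return table


@dataclass(frozen=True)
class GseaResult:
    es: float
    nes: float
    p_perm: float
    n_perm: int
    seed: int


def _running_es(scores_desc: np.ndarray, hit_mask: np.ndarray, weight: float) -> float:
    """Signed maximal deviation of the GSEA running sum."""
    n = len(scores_desc)
    n_hit = int(hit_mask.sum())
    inc = np.abs(scores_desc) ** weight
    hit_total = inc[hit_mask].sum()
    if hit_total == 0:  # all hit scores are zero at this weight -> flat increments
        steps_hit = np.full(n, 1.0 / max(n_hit, 1))
    else:
        steps_hit = inc / hit_total
    steps = np.where(hit_mask, steps_hit, -1.0 / (n - n_hit))
    running = np.cumsum(steps)
    return float(running[np.argmax(np.abs(running))])


def gsea_preranked(
    ranked_scores: pd.Series,
    geneset,
    weight: float = 1.0,
    n_perm: int = 1000,
    seed: int = 0,
) -> GseaResult:
    """Preranked GSEA of one gene set against a gene -> score ranking.

    Genes are ranked by descending score (ties broken by gene id for
    determinism). The null permutes gene labels; p_perm uses the +1
    correction, and NES divides ES by the mean |permuted ES| of the same
    sign.
    """
    s = ranked_scores.dropna()
    if not np.isfinite(s.to_numpy()).all():
        raise ValueError("scores must be finite")
    order = sorted(s.index, key=lambda g: (-s[g], str(g)))
    scores = s.loc[order].to_numpy(dtype=float)
    hits = np.array([g in set(geneset) for g in order])
    n_hit = int(hits.sum())
    if n_hit == 0:
        raise ValueError("gene set does not intersect the ranked list")
    if n_hit == len(order):
        raise ValueError("gene set covers the whole ranked list")

    es = _running_es(scores, hits, weight)
    rng = np.random.default_rng(seed)
    perm_es = np.empty(n_perm)
    idx = np.arange(len(order))
    for i in range(n_perm):
        perm_hits = np.zeros(len(order), dtype=bool)
        perm_hits[rng.choice(idx, size=n_hit, replace=False)] = True
        perm_es[i] = _running_es(scores, perm_hits, weight)
    p_perm = (1 + int((np.abs(perm_es) >= abs(es)).sum())) / (n_perm + 1)
    same_sign = perm_es[np.sign(perm_es) == np.sign(es)] if es != 0 else perm_es
    denom = np.abs(same_sign).mean() if len(same_sign) else np.abs(perm_es).mean()
    nes = es / denom if denom > 0 else 0.0
    return GseaResult(es, float(nes), float(p_perm), n_perm, seed)


def kruskal_wallis(groups) -> tuple[float, float]:
    """Kruskal-Wallis H (midrank ties correction) and chi-square p.

    Degenerate input where every value is identical returns (0, 1).
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    if any(len(g) == 0 for g in groups):
        raise ValueError("each group must be non-empty")
    pooled = np.concatenate(groups)
    if len(pooled) < 3:
        raise ValueError("need at least 3 observations in total")
    if np.all(pooled == pooled[0]):
        return 0.0, 1.0
    h, p = stats.kruskal(*groups)
    return float(h), float(p)
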