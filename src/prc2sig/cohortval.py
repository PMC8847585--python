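"""Cross-cohort validation by regulator-expression quartile stratification.

Samples are split into low and high groups by the quartiles of a marker
gene's expression (the PRC2 catalytic subunit in the motivating study);
per-gene fold changes of low vs high then test whether the PRC2-target
gene type is de-repressed where the regulator is weakly expressed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .diffexpr import bh_adjust
from .genestats import kruskal_wallis

logger = logging.getLogger(__name__)

__all__ = [
    "quartile_split",
    "stratified_fc",
    "call_cohort_updegs",
    "type_fc_summary",
    "QuartileSplit",
]


@dataclass(frozen=True)
class QuartileSplit:
    low_ids: list[str]
    high_ids: list[str]
    low_bound: float
    high_bound: float


def quartile_split(cohort: pd.DataFrame, marker: str) -> QuartileSplit:
    """Tie-inclusive quartile split of samples by marker expression.

    Low group: marker value <= 25th percentile; high group: value >=
    75th percentile. Group sizes are reported via the returned ids so
    uneven, tie-driven splits stay auditable.
    """
    if len(cohort) < 8:
        raise ValueError("need at least 8 samples for a quartile split")
    if marker not in cohort.columns:
        raise ValueError(f"marker gene {marker!r} absent from the cohort matrix")
    values = cohort[marker].to_numpy(dtype=float)
    q25, q75 = np.percentile(values, [25, 75])
    if q25 == q75:
        raise ValueError("degenerate marker distribution: 25th and 75th percentiles equal")
    low = cohort.index[values <= q25].tolist()
    high = cohort.index[values >= q75].tolist()
    return QuartileSplit(low, high, float(q25), float(q75))


def stratified_fc(
    cohort: pd.DataFrame, split: QuartileSplit, pseudocount: float = 1.0
) -> pd.Series:
    """Per-gene log2 fold change of the low-marker vs high-marker group.

    Expression is taken back to the linear (RPM) scale as 2^x, averaged
    within each group, and compared with a pseudocount:
    fc = log2((mean_low + pc) / (mean_high + pc)).
    """
    if not split.low_ids or not split.high_ids:
        raise ValueError("both groups must be non-empty")
    linear = 2.0 ** cohort.astype(float)
    mean_low = linear.loc[split.low_ids].mean(axis=0)
    mean_high = linear.loc[split.high_ids].mean(axis=0)
    fc = np.log2((mean_low + pseudocount) / (mean_high + pseudocount))
    return fc.rename("log2fc")


def call_cohort_updegs(
    fc: pd.Series,
    threshold: float = 1.0,
    cohort: pd.DataFrame | None = None,
    split: QuartileSplit | None = None,
    alpha: float = 0.05,
) -> list[str]:
    """Genes with fc >= threshold (inclusive).

    When ``cohort`` and ``split`` are supplied, a per-gene Wilcoxon
    rank-sum test (low vs high) with BH correction additionally requires
    padj <= alpha.
    """
    called = fc.index[fc >= threshold]
    if cohort is not None and split is not None:
        low = cohort.loc[split.low_ids]
        high = cohort.loc[split.high_ids]
        genes = list(called)
        if genes:
            pvals = np.array(
                [
                    stats.mannwhitneyu(low[g], high[g], alternative="two-sided")[1]
                    for g in genes
                ]
            )
            padj = bh_adjust(pvals)
            called = [g for g, q in zip(genes, padj) if q <= alpha]
    return list(called)


def type_fc_summary(
    fc: pd.Series, type_assignments: pd.Series
) -> tuple[pd.DataFrame, float, float, list[str]]:
    """Per-type fold-change quartile summary plus a Kruskal-Wallis test.

    Genes without a type label are dropped (and returned). Requires at
    least two non-empty types.
    """
    labeled = fc.index.intersection(type_assignments.dropna().index)
    dropped = sorted(set(fc.index) - set(labeled))
    if dropped:
        logger.warning("%d genes in the fc table have no type label", len(dropped))
    fc_l = fc.loc[labeled]
    types = type_assignments.loc[labeled]
    groups = {t: fc_l[types == t].to_numpy() for t in sorted(types.unique())}
    groups = {t: v for t, v in groups.items() if len(v)}
    if len(groups) < 2:
        raise ValueError("need at least 2 non-empty types to compare")
    rows = [
        (t, len(v), float(np.percentile(v, 25)), float(np.median(v)), float(np.percentile(v, 75)))
        for t, v in groups.items()
    ]
    summary = pd.DataFrame(rows, columns=["type", "n", "q25", "median", "q75"])
    h, p = kruskal_wallis(list(groups.values()))
    return summary, h, p, dropped
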