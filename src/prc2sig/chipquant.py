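"""Spike-in normalization and promoter-window signal quantification.

Spike-in (exogenous-genome) normalization makes ChIP signal comparable
across libraries even under global mark loss: the sample with the fewest
spike-in reads anchors the scale, and every other library is shrunk by

    SF_i = min_j(UMD_j) / UMD_i ,    NH_i = SF_i * OH_i

where UMD_i counts deduplicated reads matched to the spike-in genome and
OH_i reads matched to the target genome.

Promoter quantification is strand-aware: the TSS of a plus-strand gene
is its start, of a minus-strand gene its last base (end - 1, 0-based);
windows are half-open and signal is averaged length-weighted, with
uncovered bases counting as zero.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "spikein_factors",
    "apply_spikein",
    "library_stats",
    "IntervalTrack",
    "promoter_signal",
    "metagene_profile",
    "methylation_level",
    "MetageneProfile",
]


def spikein_factors(umd_counts) -> np.ndarray:
    """Standardization factor per sample: min(UMD) / UMD_i (max factor is 1)."""
    umd = np.asarray(umd_counts, dtype=float)
    if umd.size == 0:
        raise ValueError("no spike-in counts given")
    if np.any(umd <= 0):
        raise ValueError("spike-in (UMD) counts must be positive; scaling is undefined")
    return umd.min() / umd


def apply_spikein(oh_counts, sf) -> np.ndarray:
    """Element-wise normalized counts NH_i = SF_i * OH_i."""
    oh = np.asarray(oh_counts, dtype=float)
    factors = np.asarray(sf, dtype=float)
    if oh.shape != factors.shape:
        raise ValueError(f"length mismatch: {oh.shape} counts vs {factors.shape} factors")
    return factors * oh


def library_stats(sample_ids, umd_counts, oh_counts) -> pd.DataFrame:
    """Per-sample table of UMD, OH, SF and NH."""
    sf = spikein_factors(umd_counts)
    return pd.DataFrame(
        {
            "sample": list(sample_ids),
            "umd": np.asarray(umd_counts),
            "oh": np.asarray(oh_counts),
            "sf": sf,
            "nh": apply_spikein(oh_counts, sf),
        }
    )


class IntervalTrack:
    """Sorted, non-overlapping (chrom, start, end, value) signal intervals.

    Bases not covered by any interval have value 0. Built from a
    bedGraph-shaped DataFrame.
    """

    def __init__(self, frame: pd.DataFrame):
        if (frame["start"] >= frame["end"]).any():
            raise ValueError("track intervals must satisfy start < end")
        if (frame["value"] < 0).any():
            raise ValueError("track values must be nonnegative")
        self._per_chrom: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        for chrom, sub in frame.groupby("chrom", sort=False):
            sub = sub.sort_values("start", kind="mergesort")
            starts = sub["start"].to_numpy(dtype=np.int64)
            ends = sub["end"].to_numpy(dtype=np.int64)
            if np.any(starts[1:] < ends[:-1]):
                raise ValueError(f"overlapping intervals on {chrom}")
            self._per_chrom[str(chrom)] = (starts, ends, sub["value"].to_numpy(dtype=float))

    @property
    def chromosomes(self) -> list[str]:
        return list(self._per_chrom)

    def window_sum(self, chrom: str, start: int, end: int) -> float:
        """Sum of value * covered-length over [start, end)."""
        if chrom not in self._per_chrom or end <= start:
            return 0.0
        starts, ends, values = self._per_chrom[chrom]
        i = int(np.searchsorted(ends, start, side="right"))
        j = int(np.searchsorted(starts, end, side="left"))
        if i >= j:
            return 0.0
        ov = np.minimum(ends[i:j], end) - np.maximum(starts[i:j], start)
        return float(np.dot(np.clip(ov, 0, None), values[i:j]))

    def window_mean(self, chrom: str, start: int, end: int) -> float:
        """Length-weighted mean over [start, end); uncovered bases are 0."""
        start = max(start, 0)
        if end <= start:
            return 0.0
        return self.window_sum(chrom, start, end) / (end - start)


def _tss_and_strand(annotation: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    plus = annotation["strand"].to_numpy() == "+"
    tss = np.where(plus, annotation["start"].to_numpy(), annotation["end"].to_numpy() - 1)
    return tss, plus


def promoter_signal(
    track: IntervalTrack | pd.DataFrame, annotation: pd.DataFrame, window_bp: int = 3000
) -> pd.Series:
    """Mean signal over [TSS - window_bp, TSS + window_bp) per gene.

    Genes on chromosomes absent from the track get signal 0 (a warning is
    logged); windows are clipped at position 0.
    """
    if window_bp <= 0:
        raise ValueError("window_bp must be positive")
    if isinstance(track, pd.DataFrame):
        track = IntervalTrack(track)
    tss, _ = _tss_and_strand(annotation)
    missing = sorted(set(annotation["chrom"]) - set(track.chromosomes))
    if missing:
        logger.warning("chromosomes absent from track (signal set to 0): %s", missing)
    values = [
        track.window_mean(chrom, int(t - window_bp), int(t + window_bp))
        for chrom, t in zip(annotation["chrom"], tss)
    ]
    return pd.Series(values, index=annotation["name"].to_numpy(), name="signal")


@dataclass(frozen=True)
class MetageneProfile:
    """Composite (mean-over-genes) TSS-centered signal profile."""

    bin_centers: np.ndarray  # bp offsets relative to the TSS, 5'->3'
    mean_signal: np.ndarray
    n_genes: int


def metagene_profile(
    track: IntervalTrack | pd.DataFrame,
    annotation: pd.DataFrame,
    flank: int = 3000,
    n_bins: int = 60,
) -> MetageneProfile:
    """Average signal in ``n_bins`` equal bins over [TSS - flank, TSS + flank).

    Minus-strand genes contribute in flipped orientation so the profile
    always runs 5' -> 3' relative to transcription.
    """
    if len(annotation) == 0:
        raise ValueError("empty annotation")
    if flank <= 0:
        raise ValueError("flank must be positive")
    if n_bins <= 0 or n_bins % 2 != 0:
        raise ValueError("n_bins must be a positive even number")
    if isinstance(track, pd.DataFrame):
        track = IntervalTrack(track)
    bin_w = 2 * flank / n_bins
    tss, plus = _tss_and_strand(annotation)
    total = np.zeros(n_bins)
    for chrom, t, is_plus in zip(annotation["chrom"], tss, plus):
        edges = t - flank + np.round(np.arange(n_bins + 1) * bin_w).astype(int)
        vals = np.array(
            [track.window_mean(chrom, int(a), int(b)) for a, b in zip(edges[:-1], edges[1:])]
        )
        total += vals if is_plus else vals[::-1]
    centers = -flank + (np.arange(n_bins) + 0.5) * bin_w
    return MetageneProfile(centers, total / len(annotation), len(annotation))


def methylation_level(
    cpg_table: pd.DataFrame, annotation: pd.DataFrame, window_bp: int = 3000
) -> tuple[pd.Series, list[str]]:
    """Pooled promoter methylation beta per gene: sum(meth) / sum(total).

    Returns the per-gene series (NaN where the window holds no CpG) and
    the list of CpG-free genes.
    """
    if window_bp <= 0:
        raise ValueError("window_bp must be positive")
    bad = cpg_table[cpg_table["meth"] > cpg_table["total"]]
    if len(bad):
        site = bad.iloc[0]
        raise ValueError(
            f"methylated count exceeds total at {site['chrom']}:{int(site['pos'])}"
        )
    tss, _ = _tss_and_strand(annotation)
    by_chrom = {
        str(chrom): sub.sort_values("pos", kind="mergesort")
        for chrom, sub in cpg_table.groupby("chrom", sort=False)
    }
    betas: list[float] = []
    empty: list[str] = []
    for chrom, t, name in zip(annotation["chrom"], tss, annotation["name"]):
        sub = by_chrom.get(str(chrom))
        if sub is None:
            betas.append(np.nan)
            empty.append(name)
            continue
        pos = sub["pos"].to_numpy()
        i, j = np.searchsorted(pos, [t - window_bp, t + window_bp])
        if i == j:
            betas.append(np.nan)
            empty.append(name)
            continue
        betas.append(float(sub["meth"].iloc[i:j].sum() / sub["total"].iloc[i:j].sum()))
    if empty:
        logger.warning("%d genes have no CpG in the promoter window", len(empty))
    return pd.Series(betas, index=annotation["name"].to_numpy(), name="methylation"), empty
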