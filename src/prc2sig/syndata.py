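"""Synthetic multi-omic benchmark generator with known ground truth.

Emulates the statistical structure of a PRC2-inhibitor study in a
SWI/SNF-deficient tumor line: five promoter archetypes (baseline, DNA-
methylated, quiescent, active, and PRC2-target/bivalent), spike-in
sequencing depths, negative-binomial RNA counts where the PRC2-target
archetype is de-repressed under treatment, and an expression cohort in
which one regulator gene (the "EZH2 analog") anti-correlates with the
PRC2-target genes.

Every generator is fully deterministic given ``SynthConfig.seed``: each
output matrix draws from its own named substream, so results do not
depend on the order in which generators are called.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import chipquant

__all__ = [
    "SynthConfig",
    "ARCHETYPES",
    "ARCHETYPE_LABELS",
    "make_genes",
    "make_truth",
    "make_multiomics",
    "make_counts",
    "make_cohort",
    "ConfigurationError",
    "PlacementError",
]


class ConfigurationError(ValueError):
    """A SynthConfig field violates its constraints."""


class PlacementError(RuntimeError):
    """A chromosome is too small for the requested gene layout."""


#: 50 bp track resolution; gene coordinates are placed on this grid so
#: promoter windows align exactly with painted signal bins.
BIN_BP = 50
GENE_LEN_BP = 2000
PROMOTER_FLANK_BP = 3000
#: minimum gap between gene bodies so that +-3 kb promoter windows
#: (rounded out to bin boundaries) of neighbors never overlap
MIN_GAP_BP = 2 * PROMOTER_FLANK_BP + 4 * BIN_BP

ARCHETYPE_LABELS = ["baseline", "methylated", "quiescent", "active", "prc2_target"]

#: Mean promoter profile per archetype. Signal units are arbitrary
#: depth-normalized track units; methylation is a beta fraction. The
#: PRC2-target archetype is bivalent: high H3K27me3 with moderate
#: H3K4me3, low accessibility, and treatment-induced up-regulation.
ARCHETYPES: dict[str, dict[str, float]] = {
    "baseline": {"h3k27me3": 1.0, "h3k4me3": 5.0, "atac": 5.0, "methylation": 0.25},
    "methylated": {"h3k27me3": 0.8, "h3k4me3": 1.0, "atac": 1.0, "methylation": 0.85},
    "quiescent": {"h3k27me3": 1.5, "h3k4me3": 0.3, "atac": 0.3, "methylation": 0.05},
    "active": {"h3k27me3": 0.3, "h3k4me3": 10.0, "atac": 10.0, "methylation": 0.10},
    "prc2_target": {"h3k27me3": 8.0, "h3k4me3": 3.0, "atac": 2.0, "methylation": 0.15},
}

MARKS = ["h3k27me3", "h3k4me3", "atac"]


def _default_fractions() -> dict[str, float]:
    return {
        "baseline": 0.30,
        "methylated": 0.20,
        "quiescent": 0.15,
        "active": 0.20,
        "prc2_target": 0.15,
    }


def _default_chrom_sizes() -> dict[str, int]:
    return {"chr1": 6_000_000, "chr2": 6_000_000, "chr3": 6_000_000, "chr4": 4_000_000}


@dataclass(frozen=True)
class SynthConfig:
    """Study-condition parameters of the synthetic benchmark.

    Defaults mirror the source study's scale where it is desk-feasible:
    2000 genes, triplicate RNA arms, a mean treatment effect of +2 log2
    units on the PRC2-target archetype, and a 500-sample validation
    cohort whose marker gene anti-correlates (r = -0.8) with PRC2-target
    expression.
    """

    n_genes: int = 2000
    chrom_sizes: dict[str, int] = field(default_factory=_default_chrom_sizes)
    archetype_fractions: dict[str, float] = field(default_factory=_default_fractions)
    effect_log2fc: float = 2.0
    nb_dispersion: float = 0.05
    mean_count: float = 200.0
    n_replicates: int = 3
    spikein_depths: tuple[int, ...] = (50_000, 25_000, 20_000, 40_000, 30_000, 22_000)
    cohort_n: int = 500
    cohort_marker_corr: float = -0.8
    signal_noise_sd: float = 0.25
    meth_noise_sd: float = 0.06
    seed: int = 42

    def __post_init__(self) -> None:
        if self.n_genes < 0:
            raise ConfigurationError("n_genes must be nonnegative")
        if not self.chrom_sizes or any(s <= 0 for s in self.chrom_sizes.values()):
            raise ConfigurationError("chrom_sizes must be positive")
        total = sum(self.archetype_fractions.values())
        if abs(total - 1.0) > 1e-9:
            raise ConfigurationError(
                f"archetype_fractions must sum to 1 (got {total!r})"
            )
        unknown = set(self.archetype_fractions) - set(ARCHETYPES)
        if unknown:
            raise ConfigurationError(f"unknown archetype labels: {sorted(unknown)}")
        if any(d <= 0 for d in self.spikein_depths):
            raise ConfigurationError("spikein_depths must be positive")
        if self.nb_dispersion <= 0:
            raise ConfigurationError("nb_dispersion must be positive")
        if self.mean_count <= 0:
            raise ConfigurationError("mean_count must be positive")
        if self.n_replicates < 1:
            raise ConfigurationError("n_replicates must be >= 1")
        if self.signal_noise_sd < 0 or self.meth_noise_sd < 0:
            raise ConfigurationError("noise standard deviations must be >= 0")
        if not -1.0 <= self.cohort_marker_corr <= 1.0:
            raise ConfigurationError("cohort_marker_corr must lie in [-1, 1]")

    def with_(self, **kwargs) -> "SynthConfig":
        return replace(self, **kwargs)


def _rng(seed: int, name: str) -> np.random.Generator:
    """Named substream: independent of the order generators are invoked."""
    return np.random.default_rng(np.random.SeedSequence([seed, zlib.crc32(name.encode())]))


def make_genes(config: SynthConfig) -> pd.DataFrame:
    """Place non-overlapping gene models (BED6 frame) on the configured chromosomes.

    Genes are laid on a 50 bp grid with at least ``MIN_GAP_BP`` between
    bodies, so every +-3 kb promoter window is disjoint from its
    neighbors'. Strand is drawn at random from the seeded stream.
    """
    rng = _rng(config.seed, "genes")
    rows = []
    remaining = config.n_genes
    margin = PROMOTER_FLANK_BP + 2 * BIN_BP
    chrom = None
    for chrom, size in config.chrom_sizes.items():
        pos = margin
        while remaining > 0:
            jitter = int(rng.integers(0, 11)) * BIN_BP
            start = pos + jitter
            end = start + GENE_LEN_BP
            if end + margin > size:
                break
            strand = "+" if rng.random() < 0.5 else "-"
            gid = f"g{config.n_genes - remaining:04d}"
            rows.append((chrom, start, end, gid, 0, strand))
            remaining -= 1
            pos = end + MIN_GAP_BP
    if remaining > 0:
        raise PlacementError(
            f"cannot place {remaining} of {config.n_genes} genes; "
            f"ran out of space on chromosome {chrom!r}"
        )
    genes = pd.DataFrame(rows, columns=["chrom", "start", "end", "name", "score", "strand"])
    return genes


def make_truth(annotation: pd.DataFrame, config: SynthConfig) -> pd.Series:
    """Assign each gene an archetype label at the configured proportions."""
    n = len(annotation)
    counts = {a: int(np.floor(f * n)) for a, f in config.archetype_fractions.items()}
    # distribute rounding remainder to the largest fractions, deterministically
    short = n - sum(counts.values())
    order = sorted(config.archetype_fractions, key=lambda a: (-config.archetype_fractions[a], a))
    for a in order[:short]:
        counts[a] += 1
    labels = np.repeat([a for a in order], [counts[a] for a in order])
    _rng(config.seed, "truth").shuffle(labels)
    return pd.Series(labels, index=annotation["name"].to_numpy(), name="archetype")


def _tss(annotation: pd.DataFrame) -> np.ndarray:
    plus = annotation["strand"].to_numpy() == "+"
    return np.where(plus, annotation["start"].to_numpy(), annotation["end"].to_numpy() - 1)


def make_multiomics(
    annotation: pd.DataFrame, truth: pd.Series, config: SynthConfig
) -> tuple[dict[str, pd.DataFrame], pd.DataFrame]:
    """Generate promoter signal tracks (bedGraph frames) and a CpG table.

    Each gene's +-3 kb promoter window (rounded out to 50 bp bins) is
    painted with a constant level equal to its archetype mean times a
    lognormal noise factor; at ``signal_noise_sd = 0`` the promoter mean
    equals the archetype mean exactly. CpG sites are spaced every 150 bp
    across the window with binomial methylation counts around the
    archetype's beta.
    """
    missing = set(annotation["name"]) - set(truth.index)
    if missing:
        raise ConfigurationError(f"genes without truth label: {sorted(missing)[:5]} ...")
    unknown = set(truth.unique()) - set(ARCHETYPES)
    if unknown:
        raise ConfigurationError(f"unknown archetype labels in truth: {sorted(unknown)}")

    labels = truth.loc[annotation["name"]].to_numpy()
    tss = _tss(annotation)
    lo = np.maximum((tss - PROMOTER_FLANK_BP) // BIN_BP * BIN_BP, 0)
    hi = -(-(tss + PROMOTER_FLANK_BP) // BIN_BP) * BIN_BP
    sizes = annotation["chrom"].map(config.chrom_sizes).to_numpy()
    hi = np.minimum(hi, sizes)

    tracks: dict[str, pd.DataFrame] = {}
    for mark in MARKS:
        rng = _rng(config.seed, f"track:{mark}")
        mean = np.array([ARCHETYPES[a][mark] for a in labels])
        noise = (
            rng.lognormal(0.0, config.signal_noise_sd, len(mean))
            if config.signal_noise_sd > 0
            else np.ones(len(mean))
        )
        frame = pd.DataFrame(
            {
                "chrom": annotation["chrom"].to_numpy(),
                "start": lo,
                "end": hi,
                "value": mean * noise,
            }
        ).sort_values(["chrom", "start"], kind="mergesort", ignore_index=True)
        tracks[mark] = frame

    rng = _rng(config.seed, "methylation")
    cpg_rows = []
    for (chrom, g_lo, g_hi, archetype) in zip(annotation["chrom"], lo, hi, labels):
        beta = ARCHETYPES[archetype]["methylation"]
        if config.meth_noise_sd > 0:
            beta = float(np.clip(beta + rng.normal(0.0, config.meth_noise_sd), 0.02, 0.98))
        positions = np.arange(g_lo + 75, g_hi, 150)
        totals = rng.poisson(30, len(positions)) + 1
        meths = rng.binomial(totals, beta)
        for pos, tot, met in zip(positions, totals, meths):
            cpg_rows.append((chrom, int(pos), int(met), int(tot)))
    cpg = pd.DataFrame(cpg_rows, columns=["chrom", "pos", "meth", "total"])
    cpg = cpg.sort_values(["chrom", "pos"], kind="mergesort", ignore_index=True)
    return tracks, cpg


def make_counts(
    annotation: pd.DataFrame, truth: pd.Series, config: SynthConfig
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Negative-binomial control/treated count matrices plus library stats.

    The PRC2-target archetype has expected treated-vs-control log2 fold
    change equal to ``effect_log2fc``; every other archetype is null.
    Per-sample spike-in depths (UMD) are drawn around the configured
    depths and converted to standardization factors.
    """
    if config.n_replicates < 2:
        raise ConfigurationError("need >= 2 replicates per arm for testing")
    genes = annotation["name"].to_numpy()
    labels = truth.loc[genes].to_numpy()

    rng = _rng(config.seed, "counts")
    base_mu = rng.lognormal(np.log(config.mean_count) - 0.18, 0.6, len(genes))
    fold = np.where(labels == "prc2_target", 2.0 ** config.effect_log2fc, 1.0)
    size = 1.0 / config.nb_dispersion

    def draw(mu: np.ndarray) -> np.ndarray:
        p = size / (size + mu)
        return rng.negative_binomial(size, p)

    ctrl = {f"ctrl_{i + 1}": draw(base_mu) for i in range(config.n_replicates)}
    trt = {f"trt_{i + 1}": draw(base_mu * fold) for i in range(config.n_replicates)}
    control = pd.DataFrame(ctrl, index=genes)
    treated = pd.DataFrame(trt, index=genes)

    samples = list(control.columns) + list(treated.columns)
    depths = np.resize(np.asarray(config.spikein_depths), len(samples))
    spike_rng = _rng(config.seed, "spikein")
    umd = np.maximum(spike_rng.poisson(depths), 1)
    oh = np.concatenate([control.sum(axis=0).to_numpy(), treated.sum(axis=0).to_numpy()])
    sf = chipquant.spikein_factors(umd)
    stats = pd.DataFrame(
        {
            "sample": samples,
            "condition": ["control"] * config.n_replicates + ["treated"] * config.n_replicates,
            "umd": umd,
            "oh": oh,
            "sf": sf,
            "nh": chipquant.apply_spikein(oh, sf),
        }
    )
    return control, treated, stats


MARKER_GENE = "EZH2"


def make_cohort(truth: pd.Series, config: SynthConfig) -> pd.DataFrame:
    """Samples x genes cohort matrix on the log2(RPM) scale.

    One designated marker column (``EZH2``) carries the regulator's
    expression; PRC2-target genes load on a shared latent factor built so
    their mean expression correlates with the marker at
    ``cohort_marker_corr`` in expectation.
    """
    if config.cohort_n < 8:
        raise ConfigurationError("cohort_n must be >= 8 for a quartile split")
    rng = _rng(config.seed, "cohort")
    n = config.cohort_n
    genes = truth.index.to_numpy()
    is_target = (truth.to_numpy() == "prc2_target").astype(float)

    z = rng.normal(size=n)            # drives the marker
    u = rng.normal(size=n)            # target-specific shared factor
    rho = config.cohort_marker_corr
    c, d = rho, np.sqrt(1.0 - rho * rho)
    shared = c * z + d * u            # corr(marker, shared) = rho

    base = rng.normal(4.0, 1.0, len(genes))
    noise = rng.normal(0.0, 0.5, (n, len(genes)))
    expr = base[None, :] + is_target[None, :] * shared[:, None] + noise
    marker = 5.0 + z

    cohort = pd.DataFrame(expr, columns=genes)
    cohort.insert(0, MARKER_GENE, marker)
    cohort.index = pd.Index([f"s{i + 1:04d}" for i in range(n)], name="sample")
    return cohort
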