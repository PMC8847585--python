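"""End-to-end orchestration: simulate -> quantify -> test -> cluster -> enrich -> validate.

A single YAML-able config drives every stage; one top-level seed is
fanned out into named per-stage seeds, all of which are recorded in the
machine-readable run report. Every artifact is plain text and listed in
a checksum manifest, so two runs with the same config are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
import zlib
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, chipquant, cohortval, diffexpr, epitype, genestats, io, syndata

logger = logging.getLogger(__name__)

__all__ = ["DEFAULTS", "validate_config", "run_pipeline", "ConfigValidationError"]


class ConfigValidationError(ValueError):
    """Aggregate of every contradiction found in a run config."""

    def __init__(self, problems: list[str]):
        self.problems = problems
        super().__init__("; ".join(problems))


DEFAULTS: dict = {
    "seed": 42,
    "stages": {
        "simulate": True,
        "quantify": True,
        "deg": True,
        "cluster": True,
        "enrich": True,
        "cohort": True,
    },
    "syn": {
        "n_genes": 2000,
        "effect_log2fc": 2.0,
        "nb_dispersion": 0.05,
        "mean_count": 200.0,
        "n_replicates": 3,
        "cohort_n": 500,
        "cohort_marker_corr": -0.8,
        "signal_noise_sd": 0.25,
        "meth_noise_sd": 0.06,
    },
    "quantify": {"window_bp": 3000, "flank": 3000, "n_bins": 60},
    "deg": {"lfc": 1.0, "alpha": 0.05, "pseudocount": 1.0},
    "cluster": {"kmin": 2, "kmax": 10, "n_init": 10},
    "enrich": {"gmt": None, "n_perm": 200},
    "cohort": {"pseudocount": 1.0, "fc_threshold": 1.0, "marker": syndata.MARKER_GENE},
}

#: stage -> stages it needs completed first
_STAGE_DEPS = {
    "simulate": [],
    "quantify": ["simulate"],
    "deg": ["simulate"],
    "cluster": ["quantify", "deg"],
    "enrich": ["cluster", "deg"],
    "cohort": ["simulate", "cluster"],
}


def _deep_merge(base: dict, override: dict) -> dict:
    merged = dict(base)
    for key, value in override.items():
        if isinstance(value, dict) and isinstance(base.get(key), dict):
            merged[key] = _deep_merge(base[key], value)
        else:
            merged[key] = value
    return merged


def validate_config(config: dict | None) -> dict:
    """Fill defaults and report every contradiction at once.

    Idempotent: validating an already-normalized config returns it
    unchanged.
    """
    doc = config or {}
    problems = [f"unknown config section: {k!r}" for k in doc if k not in DEFAULTS]
    merged = _deep_merge(DEFAULTS, {k: v for k, v in doc.items() if k in DEFAULTS})

    deg = merged["deg"]
    if not 0 < deg["alpha"] <= 1:
        problems.append(f"deg.alpha must lie in (0, 1], got {deg['alpha']}")
    if deg["lfc"] < 0:
        problems.append("deg.lfc must be >= 0")
    cl = merged["cluster"]
    if cl["kmin"] < 2:
        problems.append("cluster.kmin must be >= 2")
    if cl["kmin"] > cl["kmax"]:
        problems.append(f"cluster.kmin ({cl['kmin']}) exceeds cluster.kmax ({cl['kmax']})")
    q = merged["quantify"]
    if q["window_bp"] <= 0 or q["flank"] <= 0:
        problems.append("quantify windows must be positive")
    if q["n_bins"] <= 0 or q["n_bins"] % 2:
        problems.append("quantify.n_bins must be positive and even")
    if merged["enrich"]["n_perm"] < 1:
        problems.append("enrich.n_perm must be >= 1")
    if merged["cohort"]["pseudocount"] <= 0:
        problems.append("cohort.pseudocount must be positive")
    if problems:
        raise ConfigValidationError(problems)
    return merged


def _stage_seed(seed: int, name: str) -> int:
    return int(
        np.random.SeedSequence([seed, zlib.crc32(name.encode())]).generate_state(1)[0]
        % (2**31)
    )


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: dict | None, outdir: str | Path) -> dict:
    """Run the enabled stages in order and return the run report.

    A stage whose dependency did not complete is marked skipped; a stage
    that raises is marked failed and its dependents skip. Artifacts,
    ``report.json`` and a checksum ``manifest.json`` (covering every
    other file in the output directory) are written under ``outdir``.
    """
    cfg = validate_config(config)
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    seed = cfg["seed"]
    report: dict = {
        "version": __version__,
        "seed": seed,
        "config": cfg,
        "stages": {},
    }
    state: dict = {}

    order = ["simulate", "quantify", "deg", "cluster", "enrich", "cohort"]
    done: set[str] = set()
    for stage in order:
        entry: dict = {"seed": _stage_seed(seed, stage)}
        report["stages"][stage] = entry
        if not cfg["stages"].get(stage, False):
            entry["status"] = "disabled"
            continue
        missing = [d for d in _STAGE_DEPS[stage] if d not in done]
        if missing:
            entry["status"] = f"skipped (missing dependency: {', '.join(missing)})"
            continue
        try:
            _RUNNERS[stage](cfg, state, entry, out)
        except Exception as exc:  # stage isolation: downstream stages skip
            logger.exception("stage %s failed", stage)
            entry["status"] = "failed"
            entry["error"] = f"{type(exc).__name__}: {exc}"
            continue
        entry["status"] = "completed"
        done.add(stage)

    io.write_json(report, out / "report.json")
    manifest = {
        p.name: _sha256(p)
        for p in sorted(out.iterdir())
        if p.is_file() and p.name != "manifest.json"
    }
    io.write_json(manifest, out / "manifest.json")
    return report


def synthetic_features(
    syn: syndata.SynthConfig, window_bp: int = 3000
) -> dict:
    """Generate the synthetic benchmark and quantify it into a feature matrix.

    Convenience for in-memory use (no files written): returns a dict with
    the annotation, truth labels, complete per-gene feature matrix
    (clustering features plus held-out H3K27me3), the DE result and the
    up/down DEG lists.
    """
    genes = syndata.make_genes(syn)
    truth = syndata.make_truth(genes, syn)
    tracks, cpg = syndata.make_multiomics(genes, truth, syn)
    control, treated, libstats = syndata.make_counts(genes, truth, syn)

    signals = {mark: chipquant.promoter_signal(frame, genes, window_bp)
               for mark, frame in tracks.items()}
    meth, _ = chipquant.methylation_level(cpg, genes, window_bp)

    counts = pd.concat([control, treated], axis=1)
    conditions = ["control"] * control.shape[1] + ["treated"] * treated.shape[1]
    de_result = diffexpr.nb_wald_test(counts, conditions)
    up, down = diffexpr.call_degs(de_result)

    features, dropped = epitype.build_feature_matrix(
        log2fc=de_result.log2fc,
        methylation=meth,
        h3k4me3=signals["h3k4me3"],
        atac=signals["atac"],
        h3k27me3=signals["h3k27me3"],
    )
    return {
        "genes": genes,
        "truth": truth,
        "tracks": tracks,
        "cpg": cpg,
        "control": control,
        "treated": treated,
        "libstats": libstats,
        "de_result": de_result,
        "up_degs": up,
        "down_degs": down,
        "features": features,
        "dropped": dropped,
    }


def _run_simulate(cfg: dict, state: dict, entry: dict, out: Path) -> None:
    syn = syndata.SynthConfig(seed=cfg["seed"], **cfg["syn"])
    genes = syndata.make_genes(syn)
    truth = syndata.make_truth(genes, syn)
    tracks, cpg = syndata.make_multiomics(genes, truth, syn)
    control, treated, libstats = syndata.make_counts(genes, truth, syn)
    cohort = syndata.make_cohort(truth, syn)
    state.update(
        syn=syn, genes=genes, truth=truth, tracks=tracks, cpg=cpg,
        control=control, treated=treated, libstats=libstats, cohort=cohort,
    )
    io.write_bed6(genes, out / "genes.bed")
    io.write_json(truth.to_dict(), out / "truth.json")
    for mark, frame in tracks.items():
        io.write_bedgraph(frame, out / f"{mark}.bedgraph")
    io.write_cpg_table(cpg, out / "cpg.tsv")
    io.write_counts(control, out / "counts_control.tsv")
    io.write_counts(treated, out / "counts_treated.tsv")
    libstats.to_csv(out / "library_stats.tsv", sep="\t", index=False)
    io.write_matrix(cohort, out / "cohort.tsv", index_label="sample")
    entry["n_genes"] = len(genes)
    entry["n_cohort_samples"] = len(cohort)


def _run_quantify(cfg: dict, state: dict, entry: dict, out: Path) -> None:
    window = cfg["quantify"]["window_bp"]
    genes = state["genes"]
    signals = {}
    for mark, frame in state["tracks"].items():
        signals[mark] = chipquant.promoter_signal(frame, genes, window)
    meth, no_cpg = chipquant.methylation_level(state["cpg"], genes, window)
    signals["methylation"] = meth
    table = pd.DataFrame(signals)
    table.index.name = "gene"
    state["promoter"] = table
    state["no_cpg_genes"] = no_cpg
    io.write_matrix(table, out / "promoter_signals.tsv", index_label="gene")
    profile = chipquant.metagene_profile(
        state["tracks"]["h3k27me3"], genes,
        flank=cfg["quantify"]["flank"], n_bins=cfg["quantify"]["n_bins"],
    )
    pd.DataFrame({"offset": profile.bin_centers, "mean": profile.mean_signal}).to_csv(
        out / "metagene_h3k27me3.tsv", sep="\t", index=False
    )
    entry["window_bp"] = window
    entry["genes_without_cpg"] = len(no_cpg)


def _run_deg(cfg: dict, state: dict, entry: dict, out: Path) -> None:
    counts = pd.concat([state["control"], state["treated"]], axis=1)
    conditions = ["control"] * state["control"].shape[1] + ["treated"] * state["treated"].shape[1]
    result = diffexpr.nb_wald_test(counts, conditions, pseudocount=cfg["deg"]["pseudocount"])
    up, down = diffexpr.call_degs(result, lfc=cfg["deg"]["lfc"], alpha=cfg["deg"]["alpha"])
    table = result.table.copy()
    table["call"] = "ns"
    table.loc[up, "call"] = "up"
    table.loc[down, "call"] = "down"
    state.update(de_result=result, up_degs=up, down_degs=down)
    table.to_csv(out / "deg.tsv", sep="\t", index_label="gene")
    entry["n_up"] = len(up)
    entry["n_down"] = len(down)


def _run_cluster(cfg: dict, state: dict, entry: dict, out: Path) -> None:
    promoter = state["promoter"]
    features, dropped = epitype.build_feature_matrix(
        log2fc=state["de_result"].log2fc,
        methylation=promoter["methylation"],
        h3k4me3=promoter["h3k4me3"],
        atac=promoter["atac"],
        h3k27me3=promoter["h3k27me3"],
    )
    z = epitype.zscore_features(features)
    k, sil_table = epitype.select_k(
        z, range(cfg["cluster"]["kmin"], cfg["cluster"]["kmax"] + 1),
        seed=entry["seed"], n_init=cfg["cluster"]["n_init"],
    )
    model = epitype.kmeans_fit(z, k, seed=entry["seed"], n_init=cfg["cluster"]["n_init"])
    type_map = epitype.assign_types(model, features[epitype.HELDOUT_FEATURE])
    types = type_map.types_for(model.assignments)
    type_genes = types.index[types == "prc2_target"].tolist()
    signature = epitype.overlap_signature(type_genes, state["up_degs"])
    state.update(
        features=features, z=z, model=model, type_map=type_map,
        types=types, signature=signature, dropped_genes=dropped,
    )
    io.write_matrix(features, out / "features.tsv", index_label="gene")
    assignments = pd.DataFrame({"cluster": model.assignments, "type": types})
    io.write_matrix(assignments, out / "assignments.tsv", index_label="gene")
    sil_table.to_csv(out / "silhouette.tsv", sep="\t", index=False)
    (out / "signature.txt").write_text("\n".join(signature.signature) + "\n")
    io.write_json(
        {
            "n_type_genes": signature.counts[0],
            "n_up_degs": signature.counts[1],
            "n_signature": signature.counts[2],
        },
        out / "venn.json",
    )
    entry["selected_k"] = k
    entry["n_dropped"] = len(dropped)
    entry["n_type_genes"] = signature.counts[0]
    entry["n_signature"] = signature.counts[2]


def _run_enrich(cfg: dict, state: dict, entry: dict, out: Path) -> None:
    universe = state["features"].index.tolist()
    if cfg["enrich"]["gmt"]:
        genesets = io.read_gmt(cfg["enrich"]["gmt"])
    else:
        # benchmark gene sets: the ground-truth archetype lists
        truth = state["truth"]
        genesets = {
            f"TRUTH_{label.upper()}": truth.index[truth == label].tolist()
            for label in sorted(truth.unique())
        }
    table = genestats.enrich_genesets(state["signature"].signature, genesets, universe)
    table.to_csv(out / "enrichment.tsv", sep="\t", index=False)
    ranked = state["de_result"].log2fc
    top_set = table.iloc[0]["set"] if len(table) else None
    gsea = None
    if top_set is not None:
        gsea = genestats.gsea_preranked(
            ranked, genesets[top_set], weight=1.0,
            n_perm=cfg["enrich"]["n_perm"], seed=entry["seed"],
        )
        io.write_json(
            {"set": top_set, "es": gsea.es, "nes": gsea.nes, "p_perm": gsea.p_perm,
             "n_perm": gsea.n_perm},
            out / "gsea.json",
        )
    state["enrichment"] = table
    entry["n_sets"] = len(table)
    entry["top_set"] = top_set


def _run_cohort(cfg: dict, state: dict, entry: dict, out: Path) -> None:
    cohort = state["cohort"]
    marker = cfg["cohort"]["marker"]
    split = cohortval.quartile_split(cohort, marker)
    fc = cohortval.stratified_fc(cohort, split, pseudocount=cfg["cohort"]["pseudocount"])
    fc = fc.drop(index=marker, errors="ignore")
    up = cohortval.call_cohort_updegs(fc, threshold=cfg["cohort"]["fc_threshold"])
    summary, h, p, dropped = cohortval.type_fc_summary(fc, state["types"])
    io.write_json(
        {
            "marker": marker,
            "low_ids": split.low_ids,
            "high_ids": split.high_ids,
            "low_bound": split.low_bound,
            "high_bound": split.high_bound,
        },
        out / "cohort_split.json",
    )
    fc.to_frame().to_csv(out / "cohort_fc.tsv", sep="\t", index_label="gene")
    summary.to_csv(out / "cohort_type_summary.tsv", sep="\t", index=False)
    state.update(cohort_split=split, cohort_fc=fc, cohort_up=up, cohort_summary=summary)
    entry["n_low"] = len(split.low_ids)
    entry["n_high"] = len(split.high_ids)
    entry["n_cohort_up"] = len(up)
    entry["kruskal_h"] = h
    entry["kruskal_p"] = p


_RUNNERS = {
    "simulate": _run_simulate,
    "quantify": _run_quantify,
    "deg": _run_deg,
    "cluster": _run_cluster,
    "enrich": _run_enrich,
    "cohort": _run_cohort,
}
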