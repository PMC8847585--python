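"""Readers and writers for the plain-text formats the pipeline exchanges.

All genomic coordinates are 0-based half-open (BED convention). Tables are
plain TSV so every artifact can be inspected, diffed and version-controlled.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

BED6_COLUMNS = ["chrom", "start", "end", "name", "score", "strand"]
BEDGRAPH_COLUMNS = ["chrom", "start", "end", "value"]
CPG_COLUMNS = ["chrom", "pos", "meth", "total"]


def write_bed6(genes: pd.DataFrame, path: str | Path) -> None:
    genes.to_csv(path, sep="\t", header=False, index=False, columns=BED6_COLUMNS)


def read_bed6(path: str | Path) -> pd.DataFrame:
    genes = pd.read_csv(path, sep="\t", header=None, names=BED6_COLUMNS)
    return genes


def write_bedgraph(track: pd.DataFrame, path: str | Path) -> None:
    track.to_csv(path, sep="\t", header=False, index=False, columns=BEDGRAPH_COLUMNS)


def read_bedgraph(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", header=None, names=BEDGRAPH_COLUMNS)


def write_cpg_table(cpg: pd.DataFrame, path: str | Path) -> None:
    cpg.to_csv(path, sep="\t", index=False, columns=CPG_COLUMNS)


def read_cpg_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_counts(counts: pd.DataFrame, path: str | Path) -> None:
    """Gene x sample integer count matrix; first column is the gene id."""
    counts.to_csv(path, sep="\t", index=True, index_label="gene")


def read_counts(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="gene")


def write_matrix(matrix: pd.DataFrame, path: str | Path, index_label: str = "id") -> None:
    matrix.to_csv(path, sep="\t", index=True, index_label=index_label)


def read_matrix(path: str | Path, index_label: str = "id") -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=index_label)


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """GMT: one gene set per line — name, description, then member genes."""
    sets: dict[str, list[str]] = {}
    with open(path) as handle:
        for line in handle:
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                continue
            sets[fields[0]] = [g for g in fields[2:] if g]
    return sets


def write_gmt(sets: dict[str, list[str]], path: str | Path) -> None:
    with open(path, "w") as handle:
        for name, genes in sets.items():
            handle.write("\t".join([name, "na", *genes]) + "\n")


def write_json(obj, path: str | Path) -> None:
    with open(path, "w") as handle:
        json.dump(obj, handle, indent=2, sort_keys=True)
        handle.write("\n")


def read_json(path: str | Path):
    with open(path) as handle:
        return json.load(handle)
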