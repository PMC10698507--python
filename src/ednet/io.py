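"""Readers and writers for the plain-text formats the pipeline exchanges.

All tables are tab-separated UTF-8 with a header row, except BED which is
headerless per convention. Coordinates are 0-based half-open throughout.
"""

from __future__ import annotations

import json
from pathlib import Path

import networkx as nx
import pandas as pd

BED_COLUMNS = ["chrom", "start", "end"]
EDGE_COLUMNS = ["node_a", "node_b", "weight"]


def read_bed(path: str | Path) -> pd.DataFrame:
    """Read a BED3/BED6 file into a (chrom, start, end[, name, score, strand]) frame."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    names = BED_COLUMNS + ["name", "score", "strand"]
    df.columns = names[: df.shape[1]]
    df["start"] = df["start"].astype(int)
    df["end"] = df["end"].astype(int)
    return df.sort_values(["chrom", "start"], kind="mergesort").reset_index(drop=True)


def write_bed(df: pd.DataFrame, path: str | Path) -> None:
    cols = [c for c in ["chrom", "start", "end", "name", "score", "strand"] if c in df.columns]
    df[cols].to_csv(path, sep="\t", header=False, index=False)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_screen_table(path: str | Path) -> pd.DataFrame:
    """Read a per-well screen table (`plate  well  condition  <readouts...>`)."""
    sep = "," if str(path).endswith(".csv") else "\t"
    df = pd.read_csv(path, sep=sep)
    required = {"plate", "well", "condition"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"screen table missing columns: {sorted(missing)}")
    return df


def read_edge_list(path: str | Path) -> nx.Graph:
    """Read a weighted undirected edge list (`node_a  node_b  weight`) into a graph."""
    df = pd.read_csv(path, sep="\t")
    if not set(EDGE_COLUMNS) <= set(df.columns):
        df = pd.read_csv(path, sep="\t", header=None, names=EDGE_COLUMNS)
    g = nx.Graph()
    for a, b, w in df[EDGE_COLUMNS].itertuples(index=False):
        g.add_edge(a, b, weight=float(w))
    return g


def write_edge_list(g: nx.Graph, path: str | Path) -> None:
    rows = [(a, b, d.get("weight", 1.0)) for a, b, d in g.edges(data=True)]
    pd.DataFrame(rows, columns=EDGE_COLUMNS).to_csv(path, sep="\t", index=False)


def write_graphml(g: nx.Graph, path: str | Path) -> None:
    nx.write_graphml(g, path)


def read_gene_models(path: str | Path) -> list:
    """Read simplified gene models (see :class:`ednet.regions.GeneModel`) from TSV."""
    from .regions import GeneModel

    df = pd.read_csv(path, sep="\t")
    models = []
    for row in df.itertuples(index=False):
        models.append(
            GeneModel(
                gene=row.gene,
                chrom=row.chrom,
                strand=row.strand,
                tss=int(row.tss),
                gene_span=_parse_block(row.gene_span)[0],
                exons=_parse_block(row.exons),
                utr5=_parse_block(getattr(row, "utr5", "")),
                utr3=_parse_block(getattr(row, "utr3", "")),
            )
        )
    return models


def write_gene_models(models: list, path: str | Path) -> None:
    rows = []
    for m in models:
        rows.append(
            {
                "gene": m.gene,
                "chrom": m.chrom,
                "strand": m.strand,
                "tss": m.tss,
                "gene_span": _format_block([m.gene_span]),
                "exons": _format_block(m.exons),
                "utr5": _format_block(m.utr5),
                "utr3": _format_block(m.utr3),
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def _parse_block(text) -> list[tuple[int, int]]:
    if text is None or (isinstance(text, float)) or text == "":
        return []
    out = []
    for part in str(text).split(","):
        if part:
            lo, hi = part.split("-")
            out.append((int(lo), int(hi)))
    return out


def _format_block(intervals) -> str:
    return ",".join(f"{lo}-{hi}" for lo, hi in intervals)


def write_json(obj, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")
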