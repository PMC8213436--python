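"""Readers and writers for the pipeline's plain-text formats.

Formats: CSV tables with explicit headers (features, compound library,
predictions, DEG tables), two-column TSV edge lists, GMT gene sets,
MatrixMarket count matrices with separate gene/sample index files, GraphML
network export and JSON reports.  Parsing is strict: malformed rows are
reported with their line number.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import pandas as pd
from scipy import io as spio
from scipy import sparse

from .annotate import CompoundRecord, MSFeature
from .diffexpr import CountMatrix
from .network import clean_edges

__all__ = [
    "read_feature_csv", "write_feature_csv",
    "read_library_csv", "write_library_csv",
    "read_edge_tsv", "write_edge_tsv",
    "read_gmt", "write_gmt",
    "read_counts", "write_counts",
    "write_graphml", "write_json",
]

FEATURE_COLS = ["rt", "mz", "response", "polarity"]
LIBRARY_COLS = ["name", "formula", "herb", "response"]


def _require_columns(df: pd.DataFrame, cols: Sequence[str], path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}; found {list(df.columns)}")


def read_feature_csv(path) -> list[MSFeature]:
    """Read an observed-feature table (columns rt, mz, response, polarity)."""
    df = pd.read_csv(path)
    _require_columns(df, FEATURE_COLS, path)
    out = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        try:
            out.append(MSFeature(float(row.rt), float(row.mz),
                                 float(row.response), str(row.polarity)))
        except (TypeError, ValueError) as exc:
            raise ValueError(f"{path}: line {i}: {exc}") from None
    return out


def write_feature_csv(features: Iterable[MSFeature], path) -> None:
    pd.DataFrame(
        [(f.rt, f.mz, f.response, f.polarity) for f in features],
        columns=FEATURE_COLS,
    ).to_csv(path, index=False)


def read_library_csv(path) -> list[CompoundRecord]:
    """Read a compound library (columns name, formula, herb, response)."""
    df = pd.read_csv(path)
    _require_columns(df, LIBRARY_COLS, path)
    out = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        try:
            out.append(CompoundRecord(str(row.name), str(row.formula),
                                      str(row.herb), float(row.response)))
        except (TypeError, ValueError) as exc:
            raise ValueError(f"{path}: line {i}: {exc}") from None
    return out


def write_library_csv(library: Iterable[CompoundRecord], path) -> None:
    pd.DataFrame(
        [(r.name, r.formula, r.herb, r.response) for r in library],
        columns=LIBRARY_COLS,
    ).to_csv(path, index=False)


def read_edge_tsv(path) -> list[tuple[str, str]]:
    """Read a two-column TSV edge list; self-loops and duplicates are dropped
    (with a logged warning), per the undirected simple-graph contract."""
    edges = []
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2 or not all(parts):
                raise ValueError(f"{path}: line {i}: expected two tab-separated node ids")
            edges.append((parts[0], parts[1]))
    return clean_edges(edges)


def write_edge_tsv(edges: Iterable[tuple[str, str]], path) -> None:
    with open(path, "w") as fh:
        for u, v in edges:
            fh.write(f"{u}\t{v}\n")


def read_gmt(path) -> tuple[dict[str, frozenset[str]], dict[str, str]]:
    """Read GMT gene sets; returns (sets, descriptions).  Empty sets error."""
    sets: dict[str, frozenset[str]] = {}
    desc: dict[str, str] = {}
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(
                    f"{path}: line {i}: GMT rows need name, description and >= 1 gene"
                )
            name, d, genes = parts[0], parts[1], [g for g in parts[2:] if g]
            if not genes:
                raise ValueError(f"{path}: line {i}: gene set {name!r} is empty")
            if name in sets:
                raise ValueError(f"{path}: line {i}: duplicate gene set {name!r}")
            sets[name] = frozenset(genes)
            desc[name] = d
    return sets, desc


def write_gmt(sets: dict[str, frozenset[str]], path, descriptions=None) -> None:
    descriptions = descriptions or {}
    with open(path, "w") as fh:
        for name in sorted(sets):
            genes = "\t".join(sorted(sets[name]))
            fh.write(f"{name}\t{descriptions.get(name, 'na')}\t{genes}\n")


def read_counts(prefix) -> CountMatrix:
    """Read a count matrix written by :func:`write_counts`.

    ``prefix`` names three files: ``<prefix>.mtx`` (MatrixMarket),
    ``<prefix>.genes.txt`` and ``<prefix>.samples.tsv`` (sample, group).
    """
    prefix = Path(prefix)
    mat = spio.mmread(f"{prefix}.mtx").toarray().astype(int)
    genes = Path(f"{prefix}.genes.txt").read_text().split()
    samples = pd.read_csv(f"{prefix}.samples.tsv", sep="\t")
    counts = pd.DataFrame(mat, index=genes, columns=list(samples["sample"]))
    groups = pd.Series(samples["group"].to_numpy(), index=list(samples["sample"]))
    return CountMatrix(counts, groups)


def write_counts(m: CountMatrix, prefix) -> None:
    prefix = Path(prefix)
    spio.mmwrite(f"{prefix}.mtx", sparse.csr_matrix(m.counts.to_numpy()))
    Path(f"{prefix}.genes.txt").write_text("\n".join(m.counts.index) + "\n")
    pd.DataFrame({"sample": list(m.counts.columns),
                  "group": [m.groups[s] for s in m.counts.columns]}
                 ).to_csv(f"{prefix}.samples.tsv", sep="\t", index=False)


def write_graphml(net: nx.Graph, path, centrality_table: pd.DataFrame = None) -> None:
    """Export a network with role tags (and optional centralities) as GraphML."""
    g = net.copy()
    for n, data in g.nodes(data=True):
        if "roles" in data:
            data["roles"] = ";".join(data["roles"])
        if centrality_table is not None and n in centrality_table.index:
            row = centrality_table.loc[n]
            data["degree"] = int(row["degree"])
            data["betweenness"] = float(row["betweenness"])
            data["closeness"] = float(row["closeness"])
    nx.write_graphml(g, path)


def write_json(obj, path) -> None:
    def _default(o):
        if isinstance(o, (set, frozenset)):
            return sorted(o)
        if hasattr(o, "item"):
            return o.item()
        raise TypeError(f"not JSON-serializable: {type(o)}")

    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1, sort_keys=True, default=_default)
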