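"""Readers and writers for the plain-text interchange formats.

Networks travel as GraphML (threshold metadata in graph attributes) or as an
edge-list TSV ``gene_a<TAB>gene_b<TAB>r`` with ``#``-prefixed header lines
carrying the threshold, mode and any isolated nodes so the round trip is
lossless. Tables (metrics, coordinates, histograms) are TSV.
"""

from __future__ import annotations

from pathlib import Path

import networkx as nx
import pandas as pd

from .layout import LayoutState

__all__ = [
    "write_edgelist",
    "read_edgelist",
    "write_graphml",
    "read_graphml",
    "read_network",
    "write_metrics",
    "write_coords",
    "write_correlation",
]

MAX_CORR_GENES = 2000  # a dense TSV beyond this is no longer a small input


def write_edgelist(net: nx.Graph, path) -> None:
    with open(path, "w") as fh:
        if "tau" in net.graph:
            fh.write(f"# tau: {net.graph['tau']}\n")
        if "mode" in net.graph:
            fh.write(f"# mode: {net.graph['mode']}\n")
        isolated = sorted(n for n, d in net.degree() if d == 0)
        if isolated:
            fh.write("# isolated: " + ",".join(map(str, isolated)) + "\n")
        fh.write("gene_a\tgene_b\tr\n")
        for u, v in sorted(map(sorted, net.edges())):
            r = net.edges[u, v].get("r", "")
            fh.write(f"{u}\t{v}\t{r}\n")


def read_edgelist(path) -> nx.Graph:
    g = nx.Graph()
    header_seen = False
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                key, _, val = line[1:].partition(":")
                key, val = key.strip(), val.strip()
                if key == "tau":
                    g.graph["tau"] = float(val)
                elif key == "mode":
                    g.graph["mode"] = val
                elif key == "isolated" and val:
                    g.add_nodes_from(val.split(","))
                continue
            parts = line.split("\t")
            if not header_seen:
                header_seen = True
                if parts[:2] == ["gene_a", "gene_b"]:
                    continue
            if len(parts) < 2:
                raise ValueError(f"malformed edge-list line: {line!r}")
            u, v = parts[0], parts[1]
            attrs = {}
            if len(parts) > 2 and parts[2] != "":
                attrs["r"] = float(parts[2])
            g.add_edge(u, v, **attrs)
    return g


def write_graphml(net: nx.Graph, path) -> None:
    nx.write_graphml(net, path)


def read_graphml(path) -> nx.Graph:
    return nx.read_graphml(path)


def read_network(path) -> nx.Graph:
    """Dispatch on extension: ``.graphml`` or edge-list ``.tsv``/``.edges``."""
    suffix = Path(path).suffix.lower()
    if suffix == ".graphml":
        return read_graphml(path)
    if suffix in (".tsv", ".edges", ".txt"):
        return read_edgelist(path)
    raise ValueError(
        f"unrecognized network format {suffix!r} for {path}; "
        "expected .graphml or an edge-list .tsv/.edges"
    )


def write_metrics(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False, float_format="%.6g")


def write_coords(state: LayoutState, path) -> None:
    cols = ["x", "y", "z"][: state.positions.shape[1]]
    df = pd.DataFrame(state.positions, columns=cols)
    df.insert(0, "gene_id", state.nodes)
    df.to_csv(path, sep="\t", index=False, float_format="%.8g")


def write_correlation(corr, path, max_genes: int = MAX_CORR_GENES) -> None:
    """Dense correlation TSV; refuses matrices beyond ``max_genes`` genes."""
    if len(corr.gene_ids) > max_genes:
        raise ValueError(
            f"{len(corr.gene_ids)} genes exceeds the {max_genes}-gene guard for "
            "dense TSV output; persist the edge list instead"
        )
    corr.to_frame().to_csv(path, sep="\t", index_label="gene_id")
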