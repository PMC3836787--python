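"""Pearson correlation matrices and correlation-threshold networks.

A gene network here is an undirected simple :class:`networkx.Graph` whose
nodes are gene identifiers; the construction threshold and thresholding mode
are recorded as graph attributes ``tau`` and ``mode``. An edge joins two genes
whose expression profiles co-vary (positively or negatively) at least as
strongly as the threshold.

Threshold choice follows a stability rule: scan candidate thresholds from
high to low and keep the largest one at which (a) the required fraction of
non-isolated genes already sits in the largest connected component and (b)
small changes of the threshold no longer reshape the network (relative change
of edge count and giant-component size between adjacent grid points below a
tolerance).
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .expression import ExpressionMatrix

__all__ = [
    "CorrelationMatrix",
    "pearson_matrix",
    "threshold_network",
    "auto_threshold",
    "AutoThresholdError",
    "prune_isolated",
    "giant_component",
]


@dataclass
class CorrelationMatrix:
    """Symmetric gene × gene Pearson correlation matrix with unit diagonal."""

    gene_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        n = len(self.gene_ids)
        if v.shape != (n, n):
            raise ValueError(f"matrix shape {v.shape} does not match {n} gene ids")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("correlation matrix is not symmetric (tol 1e-12)")
        if np.any(np.abs(v) > 1 + 1e-12):
            raise ValueError("correlation entries outside [-1, 1]")
        if not np.allclose(np.diag(v), 1.0, atol=1e-12):
            raise ValueError("correlation diagonal is not 1")
        v = np.clip((v + v.T) / 2.0, -1.0, 1.0)
        np.fill_diagonal(v, 1.0)
        self.values = v

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.gene_ids)


def pearson_matrix(
    matrix: ExpressionMatrix,
    sample_subset: list[str] | None = None,
) -> CorrelationMatrix:
    """Pearson correlation of every gene pair across the selected samples.

    ``sample_subset`` restricts the computation, e.g. to the samples of one
    phenotypic group. At least 3 samples are required and every gene must
    vary over the subset.
    """
    if sample_subset is not None:
        missing = set(sample_subset) - set(matrix.sample_ids)
        if missing:
            raise ValueError(f"unknown sample id(s): {sorted(missing)}")
        data = matrix.data[list(sample_subset)]
    else:
        data = matrix.data
    if data.shape[1] < 3:
        raise ValueError(f"need >= 3 samples to correlate, got {data.shape[1]}")
    if data.isna().any().any():
        raise ValueError("missing values present; run clean() first")
    vals = data.to_numpy(dtype=float)
    sd = vals.std(axis=1)
    flat = np.flatnonzero(sd == 0)
    if flat.size:
        raise ValueError(
            f"zero-variance gene {data.index[flat[0]]!r} over the selected samples"
        )
    r = np.corrcoef(vals)
    return CorrelationMatrix(list(data.index), r)


def threshold_network(
    corr: CorrelationMatrix,
    tau: float,
    mode: str = "absolute",
) -> nx.Graph:
    """Build the network with an edge wherever correlation reaches ``tau``.

    ``mode="absolute"`` uses ``|r| >= tau`` (co-variation of either sign);
    ``mode="positive"`` uses ``r >= tau``.
    """
    if not 0 < tau <= 1:
        raise ValueError(f"tau must lie in (0, 1], got {tau}")
    if mode not in ("absolute", "positive"):
        raise ValueError(f"mode must be 'absolute' or 'positive', got {mode!r}")
    v = np.abs(corr.values) if mode == "absolute" else corr.values
    iu, ju = np.triu_indices(len(corr.gene_ids), k=1)
    hit = v[iu, ju] >= tau
    g = nx.Graph(tau=float(tau), mode=mode)
    g.add_nodes_from(corr.gene_ids)
    ids = corr.gene_ids
    g.add_edges_from(
        (ids[i], ids[j], {"r": float(corr.values[i, j])})
        for i, j in zip(iu[hit], ju[hit])
    )
    return g


class AutoThresholdError(RuntimeError):
    """No grid point satisfies the connectivity and stability criteria."""


def _grid_stats(corr: CorrelationMatrix, taus: np.ndarray, mode: str):
    """Edge count, giant size and giant fraction of non-isolated nodes per tau."""
    rows = []
    for tau in taus:
        g = threshold_network(corr, float(tau), mode)
        n_edges = g.number_of_edges()
        non_isolated = [n for n, d in g.degree() if d > 0]
        if non_isolated:
            giant = max(nx.connected_components(g.subgraph(non_isolated)), key=len)
            giant_size = len(giant)
            frac = giant_size / len(non_isolated)
        else:
            giant_size, frac = 0, 0.0
        rows.append((float(tau), n_edges, giant_size, frac))
    return pd.DataFrame(rows, columns=["tau", "n_edges", "giant_size", "giant_frac"])


def _rel_change(a: float, b: float) -> float:
    return abs(a - b) / max(a, b, 1.0)


def auto_threshold(
    corr: CorrelationMatrix,
    grid_hi: float = 0.9999,
    grid_lo: float = 0.90,
    step: float = 0.0005,
    connect_frac: float = 1.0,
    stability_eps: float = 0.05,
    mode: str = "absolute",
) -> tuple[float, pd.DataFrame]:
    """Stability-based threshold selection.

    Scans tau from ``grid_hi`` down to ``grid_lo`` in steps of ``step`` and
    returns the largest tau at which (a) at least ``connect_frac`` of the
    non-isolated nodes lie in the largest connected component and (b) the
    relative changes in edge count and giant-component size between tau and
    tau - step are both at most ``stability_eps``. The report lists
    (tau, n_edges, giant_size, giant_frac) for every grid point.
    """
    if grid_hi <= grid_lo:
        raise ValueError("grid_hi must exceed grid_lo")
    if step <= 0:
        raise ValueError("step must be positive")
    if not 0 < connect_frac <= 1:
        raise ValueError("connect_frac must lie in (0, 1]")
    if stability_eps <= 0:
        raise ValueError("stability_eps must be positive")

    n_steps = int(np.floor((grid_hi - grid_lo) / step + 1e-9))
    taus = grid_hi - step * np.arange(n_steps + 1)
    # one extra grid point below grid_lo so the stability test covers grid_lo
    taus_ext = np.append(taus, taus[-1] - step)
    report = _grid_stats(corr, taus_ext, mode)

    for i in range(len(taus)):
        cur, nxt = report.iloc[i], report.iloc[i + 1]
        if cur.n_edges == 0 or cur.giant_frac < connect_frac:
            continue
        stable = (
            _rel_change(cur.n_edges, nxt.n_edges) <= stability_eps
            and _rel_change(cur.giant_size, nxt.giant_size) <= stability_eps
        )
        if stable:
            return float(cur.tau), report.iloc[: len(taus)].reset_index(drop=True)
    raise AutoThresholdError(
        "no threshold on the grid satisfies both the connectivity and the "
        "stability criterion; widen the grid (grid_lo), relax connect_frac / "
        "stability_eps, or supply a fixed tau"
    )


def prune_isolated(net: nx.Graph) -> nx.Graph:
    """Drop all degree-0 nodes; edges are untouched."""
    keep = [n for n, d in net.degree() if d > 0]
    out = net.subgraph(keep).copy()
    out.graph.update(net.graph)
    return out


def giant_component(net: nx.Graph) -> nx.Graph:
    """Subgraph induced by the largest connected component.

    Ties on size are broken toward the component containing the smallest
    gene id lexicographically.
    """
    if net.number_of_nodes() == 0:
        raise ValueError("empty network has no components")
    comps = [sorted(c) for c in nx.connected_components(net)]
    top = max(len(c) for c in comps)
    best = min((c for c in comps if len(c) == top), key=lambda c: c[0])
    out = net.subgraph(best).copy()
    out.graph.update(net.graph)
    return out
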