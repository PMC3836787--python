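"""Synthetic expression matrices and benchmark graphs with planted structure.

Every stage of the pipeline is testable without microarray data:

* :func:`gen_expression` draws latent-factor Gaussian expression profiles
  whose population correlation is ``rho_in`` inside planted gene modules and
  ``rho_bg`` elsewhere, and reports the planted adjacency (the gene pairs a
  correlation threshold placed between ``rho_bg`` and ``rho_in`` should
  recover).
* :func:`gen_motif_graph` realizes the hub / VIP / high-hub archetypes as an
  explicit graph: hubs carry private leaves, VIPs attach only to hubs,
  high-hubs attach to many leaves and to several hubs, over a sparse random
  background.
* :func:`gen_scale_free` wraps preferential attachment as a scale-free
  test bed.

All generators require an explicit seed; none touches global random state.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .expression import ExpressionMatrix

__all__ = ["SyntheticSpec", "gen_expression", "gen_motif_graph", "gen_scale_free"]


@dataclass
class SyntheticSpec:
    """Study design for the synthetic generators.

    ``group_sizes`` mirrors the two-phenotype case/control design (default: 6
    vs 12 samples). ``modules`` lists (size, within-module correlation);
    ``rho_bg`` is the background correlation between everything else.
    ``planted_roles`` parameterizes the motif graph.
    """

    group_sizes: dict[str, int] = field(
        default_factory=lambda: {"FS": 6, "NFS": 12}
    )
    modules: list[tuple[int, float]] = field(
        default_factory=lambda: [(5, 0.95), (5, 0.95)]
    )
    rho_bg: float = 0.0
    n_background_genes: int = 10
    # motif-graph parameters
    n_hubs: int = 10
    leaves_per_hub: int = 30
    n_vips: int = 5
    hubs_per_vip: int = 3
    n_high_hubs: int = 2
    high_hub_leaves: int = 25
    high_hub_hubs: int = 5
    background_p: float = 2e-4
    seed: int = 0

    def __post_init__(self) -> None:
        for size, rho in self.modules:
            if not (0 <= self.rho_bg < rho <= 1):
                raise ValueError(
                    f"need 0 <= rho_bg < rho_in <= 1, got rho_bg={self.rho_bg}, "
                    f"rho_in={rho}"
                )
            if size < 2:
                raise ValueError("modules need at least 2 genes")
        if min(self.group_sizes.values(), default=0) < 1:
            raise ValueError("every group needs at least one sample")


def gen_expression(spec: SyntheticSpec) -> tuple[ExpressionMatrix, set]:
    """Latent-factor Gaussian expression with planted correlated modules.

    Each gene in module ``m`` is
    ``sqrt(rho_bg)*g + sqrt(rho_m - rho_bg)*f_m + sqrt(1 - rho_m)*eps`` with
    independent standard normal global factor ``g``, module factor ``f_m``
    and private noise ``eps`` (drawn per sample), so the population
    correlation is exactly ``rho_m`` within the module and ``rho_bg`` across.
    Values are shifted to a log2-intensity-like scale (mean 8, sd 1). The
    second element is the planted adjacency: all within-module gene pairs.
    """
    rng = np.random.default_rng(spec.seed)
    gene_ids: list[str] = []
    module_of: list[int] = []
    for m, (size, _) in enumerate(spec.modules):
        for g in range(size):
            gene_ids.append(f"M{m + 1:02d}G{g + 1:03d}")
            module_of.append(m)
    for b in range(spec.n_background_genes):
        gene_ids.append(f"BG{b + 1:04d}")
        module_of.append(-1)

    sample_ids, groups = [], {}
    for grp, n in spec.group_sizes.items():
        for s in range(n):
            sid = f"{grp}{s + 1:03d}"
            sample_ids.append(sid)
            groups[sid] = grp

    n_genes, n_samples = len(gene_ids), len(sample_ids)
    g_fac = rng.standard_normal(n_samples)
    mod_fac = rng.standard_normal((len(spec.modules), n_samples))
    eps = rng.standard_normal((n_genes, n_samples))

    values = np.empty((n_genes, n_samples))
    for i, m in enumerate(module_of):
        rho_m = spec.modules[m][1] if m >= 0 else spec.rho_bg
        values[i] = (
            np.sqrt(spec.rho_bg) * g_fac
            + (np.sqrt(rho_m - spec.rho_bg) * mod_fac[m] if m >= 0 else 0.0)
            + np.sqrt(1.0 - rho_m) * eps[i]
        )
    values = 8.0 + values  # log2-intensity-like location

    data = pd.DataFrame(values, index=gene_ids, columns=sample_ids)
    planted = {
        frozenset((gene_ids[i], gene_ids[j]))
        for i in range(n_genes)
        for j in range(i + 1, n_genes)
        if module_of[i] == module_of[j] and module_of[i] >= 0
    }
    return ExpressionMatrix(data, groups=groups, scale="log2"), planted


def gen_motif_graph(spec: SyntheticSpec) -> tuple[nx.Graph, dict]:
    """Benchmark graph with planted hub / VIP / high-hub roles.

    Returns ``(graph, roles)`` where roles maps every node to one of
    ``hub``, ``vip``, ``high_hub``, ``leaf``. A sparse Erdős–Rényi background
    (edge probability ``background_p``) is overlaid on the planted motif.
    """
    if spec.n_vips > 0 and spec.hubs_per_vip > spec.n_hubs:
        raise ValueError(
            f"hubs_per_vip={spec.hubs_per_vip} exceeds available hubs "
            f"({spec.n_hubs})"
        )
    if spec.n_high_hubs > 0 and spec.high_hub_hubs > spec.n_hubs:
        raise ValueError(
            f"high_hub_hubs={spec.high_hub_hubs} exceeds available hubs "
            f"({spec.n_hubs})"
        )
    rng = np.random.default_rng(spec.seed)
    g = nx.Graph()
    roles: dict[str, str] = {}

    hubs = [f"H{i + 1:03d}" for i in range(spec.n_hubs)]
    for i, h in enumerate(hubs):
        roles[h] = "hub"
        g.add_node(h)
        for l in range(spec.leaves_per_hub):
            leaf = f"LH{i + 1:03d}x{l + 1:03d}"
            roles[leaf] = "leaf"
            g.add_edge(h, leaf)

    for i in range(spec.n_vips):
        v = f"V{i + 1:03d}"
        roles[v] = "vip"
        g.add_node(v)
        for h in rng.choice(hubs, size=spec.hubs_per_vip, replace=False):
            g.add_edge(v, h)

    for i in range(spec.n_high_hubs):
        x = f"X{i + 1:03d}"
        roles[x] = "high_hub"
        g.add_node(x)
        for l in range(spec.high_hub_leaves):
            leaf = f"LX{i + 1:03d}x{l + 1:03d}"
            roles[leaf] = "leaf"
            g.add_edge(x, leaf)
        for h in rng.choice(hubs, size=spec.high_hub_hubs, replace=False):
            g.add_edge(x, h)

    if spec.background_p > 0:
        nodes = sorted(g.nodes())
        n = len(nodes)
        iu, ju = np.triu_indices(n, k=1)
        hit = rng.random(iu.size) < spec.background_p
        for a, b in zip(iu[hit], ju[hit]):
            g.add_edge(nodes[a], nodes[b])

    g.graph["planted"] = True
    return g, roles


def gen_scale_free(n: int, m: int, seed: int) -> nx.Graph:
    """Preferential-attachment (Barabási–Albert) graph with string node ids.

    Growth starts from ``m`` unconnected seed nodes; each arriving node
    attaches ``m`` edges preferentially, giving exactly ``m * (n - m)`` edges
    and minimum degree ``m`` for every non-seed node.
    """
    if not n > m >= 1:
        raise ValueError(f"need n > m >= 1, got n={n}, m={m}")
    ba = nx.barabasi_albert_graph(n, m, seed=seed)
    width = len(str(n - 1))
    return nx.relabel_nodes(ba, {i: f"G{i:0{width}d}" for i in ba.nodes()})
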