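"""Co-expression network construction, module detection and node roles.

Builds a gene co-expression graph by all-pairs correlation with a
high-confidence filter (default |r| > 0.8 and BH-adjusted q < 0.05, both
strict), partitions it into modules by greedy modularity maximisation, and
classifies each gene's topological role from the Guimerà–Amaral cartography:

* within-module degree z-score ``Z_i = (k_i - mean_s) / sd_s`` where ``k_i``
  counts i's neighbours inside its own module s and mean/sd are over the
  members of s (``sd = 0`` maps to ``Z_i = 0``);
* participation coefficient ``P_i = 1 - sum_s (k_is / k_i)^2``.

Nodes with Z above 2.5 are module hubs, nodes with P above 0.62 are
connectors (both thresholds strict; exceeding both makes a network hub);
hubs and connectors together are the network's key nodes. A module quality
report applies the annotation-based filters (>=10 annotated genes, >=50%
annotation rate, >=3 distinct functions, >=3 genes for the top function).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from typing import Mapping

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats as sps

from .stats import benjamini_hochberg

__all__ = [
    "CoexprNetwork",
    "ModulePartition",
    "build_network",
    "detect_modules",
    "within_module_degree_z",
    "participation_coefficient",
    "node_topology",
    "classify_roles",
    "filter_modules",
]


@dataclass
class CoexprNetwork:
    """Thresholded correlation graph plus bookkeeping about dropped genes.

    ``graph`` is an undirected networkx graph whose edges carry ``r`` (the
    correlation) and ``q`` (the BH-adjusted p-value); genes whose every
    correlation failed the filter (isolates) are listed separately rather
    than kept as degree-0 nodes.
    """

    graph: nx.Graph
    n_genes_tested: int
    isolates: list
    dropped_zero_variance: list

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()


@dataclass
class ModulePartition:
    """Disjoint gene -> module assignment with the partition's modularity."""

    labels: dict
    modularity: float

    @property
    def module_sizes(self) -> dict:
        sizes: dict = {}
        for m in self.labels.values():
            sizes[m] = sizes.get(m, 0) + 1
        return sizes

    def members(self, module) -> list:
        return [n for n, m in self.labels.items() if m == module]


def build_network(
    expr: pd.DataFrame,
    r_min: float = 0.8,
    q_max: float = 0.05,
    method: str = "pearson",
    log2_transform: bool = False,
) -> CoexprNetwork:
    """All-pairs correlation network with |r| > r_min and q < q_max (strict).

    Parameters
    ----------
    expr
        Genes x samples matrix (rows indexed by gene id). At least 4 samples
        are required for stable correlation p-values. Zero-variance genes
        are dropped with a warning.
    method
        "pearson" (default) or "spearman".
    log2_transform
        Apply log2(x + 1) first, for raw normalized counts; leave off when
        the matrix is already on a log scale.

    Correlation p-values come from the exact t-transform of r with n - 2
    degrees of freedom; BH adjustment is over all tested pairs of one build.
    Both the positive and negative tails are kept (edges store signed r).
    """
    if expr.shape[1] < 4:
        raise ValueError("at least 4 samples are required to build a network")
    x = expr.to_numpy(dtype=float)
    if log2_transform:
        x = np.log2(x + 1.0)
    genes = list(expr.index)
    variances = x.var(axis=1)
    dropped = [g for g, v in zip(genes, variances) if v == 0]
    if dropped:
        warnings.warn(f"dropping {len(dropped)} zero-variance genes")
        keep = variances > 0
        x, genes = x[keep], [g for g, k in zip(genes, keep) if k]

    n_samples = x.shape[1]
    if method == "spearman":
        x = sps.rankdata(x, axis=1)
    elif method != "pearson":
        raise ValueError(f"unknown correlation method: {method}")
    r = np.corrcoef(x)
    iu = np.triu_indices(len(genes), k=1)
    r_flat = np.clip(r[iu], -1.0, 1.0)
    # two-sided p-value of the correlation t-test, t = r sqrt(n-2)/sqrt(1-r^2)
    with np.errstate(divide="ignore"):
        t = r_flat * np.sqrt((n_samples - 2) / np.maximum(1.0 - r_flat**2, 1e-300))
    p = 2.0 * sps.t.sf(np.abs(t), df=n_samples - 2)
    p[np.abs(r_flat) >= 1.0] = 0.0
    q = benjamini_hochberg(p) if p.size else p

    g = nx.Graph()
    g.add_nodes_from(genes)
    mask = (np.abs(r_flat) > r_min) & (q < q_max)
    for idx in np.flatnonzero(mask):
        i, j = iu[0][idx], iu[1][idx]
        g.add_edge(genes[i], genes[j], r=float(r_flat[idx]), q=float(q[idx]))
    isolates = [n for n in genes if g.degree(n) == 0]
    g.remove_nodes_from(isolates)
    return CoexprNetwork(
        graph=g,
        n_genes_tested=len(genes),
        isolates=isolates,
        dropped_zero_variance=dropped,
    )


def _as_graph(net) -> nx.Graph:
    return net.graph if isinstance(net, CoexprNetwork) else net


def detect_modules(net, seed: int = 0) -> ModulePartition:
    """Partition the network into modules by greedy modularity maximisation.

    Deterministic for a given graph: nodes are processed in sorted order and
    the underlying agglomeration breaks ties deterministically. ``seed`` is
    accepted for interface stability (the default algorithm consumes no
    randomness). Connected components are handled jointly; singleton
    components come out as singleton modules.
    """
    g = _as_graph(net)
    if g.number_of_nodes() == 0:
        raise ValueError("network is empty")
    def order(n):  # total order even for mixed node types
        return (type(n).__name__, str(n))

    h = nx.Graph()
    h.add_nodes_from(sorted(g.nodes(), key=order))
    h.add_edges_from(
        sorted((sorted(e, key=order) for e in g.edges()), key=lambda e: list(map(order, e)))
    )
    if h.number_of_edges() == 0:
        communities = [{n} for n in h.nodes()]
    else:
        communities = [set(c) for c in nx.community.greedy_modularity_communities(h)]
    labels = {}
    # stable module ids: order communities by size desc, then smallest member
    for mid, com in enumerate(
        sorted(communities, key=lambda c: (-len(c), sorted(c)))
    ):
        for node in com:
            labels[node] = mid
    mod = (
        nx.community.modularity(h, communities) if h.number_of_edges() else 0.0
    )
    return ModulePartition(labels=labels, modularity=float(mod))


def within_module_degree_z(net, partition: ModulePartition) -> dict:
    """Guimerà–Amaral within-module degree z-score for every node."""
    g = _as_graph(net)
    labels = partition.labels
    _check_cover(g, labels)
    within = {
        n: sum(1 for nb in g.neighbors(n) if labels[nb] == labels[n]) for n in g.nodes()
    }
    z = {}
    for module in set(labels[n] for n in g.nodes()):
        members = [n for n in g.nodes() if labels[n] == module]
        k = np.array([within[n] for n in members], dtype=float)
        sd = k.std()  # population sd over the module, the cartography convention
        mean = k.mean()
        for n, ki in zip(members, k):
            z[n] = float((ki - mean) / sd) if sd > 0 else 0.0
    return z


def participation_coefficient(net, partition: ModulePartition) -> dict:
    """Guimerà–Amaral participation coefficient; isolated nodes get 0."""
    g = _as_graph(net)
    labels = partition.labels
    _check_cover(g, labels)
    p = {}
    for n in g.nodes():
        k_total = g.degree(n)
        if k_total == 0:
            p[n] = 0.0
            continue
        per_module: dict = {}
        for nb in g.neighbors(n):
            per_module[labels[nb]] = per_module.get(labels[nb], 0) + 1
        p[n] = float(1.0 - sum((k / k_total) ** 2 for k in per_module.values()))
    return p


def _check_cover(g: nx.Graph, labels: Mapping) -> None:
    uncovered = [n for n in g.nodes() if n not in labels]
    if uncovered:
        raise ValueError(f"partition does not cover nodes: {uncovered[:5]}")


def node_topology(net, partition: ModulePartition) -> pd.DataFrame:
    """Tidy frame ``gene, module, degree, Z, P`` for every network node."""
    g = _as_graph(net)
    z = within_module_degree_z(g, partition)
    p = participation_coefficient(g, partition)
    return pd.DataFrame(
        {
            "gene": list(g.nodes()),
            "module": [partition.labels[n] for n in g.nodes()],
            "degree": [g.degree(n) for n in g.nodes()],
            "Z": [z[n] for n in g.nodes()],
            "P": [p[n] for n in g.nodes()],
        }
    )


def classify_roles(
    topology: pd.DataFrame, z_min: float = 2.5, p_min: float = 0.62
) -> pd.DataFrame:
    """Assign each node a cartographic role from its (Z, P) coordinates.

    module_hub: Z > z_min and P <= p_min; connector: P > p_min and
    Z <= z_min; network_hub: both exceeded; peripheral: neither. Thresholds
    are strict, so a node sitting exactly on a threshold is peripheral (or
    keeps only the role whose threshold it strictly exceeds). Key nodes are
    the non-peripheral ones (``is_key`` column).
    """
    out = topology.copy()
    z = out["Z"].to_numpy(dtype=float)
    p = out["P"].to_numpy(dtype=float)
    role = np.where(
        (z > z_min) & (p > p_min),
        "network_hub",
        np.where(z > z_min, "module_hub", np.where(p > p_min, "connector", "peripheral")),
    )
    out["role"] = role
    out["is_key"] = out["role"] != "peripheral"
    return out


def filter_modules(
    partition: ModulePartition, annotation: Mapping[str, set]
) -> pd.DataFrame:
    """Module quality report from a (possibly partial) gene -> functions map.

    A module passes when it has >= 10 annotated genes, >= 50% of its genes
    annotated, >= 3 distinct functions, and >= 3 genes carrying its top
    function (the function annotating the most genes; ties broken
    lexicographically).
    """
    rows = []
    for module in sorted(set(partition.labels.values())):
        members = partition.members(module)
        annotated = [g for g in members if annotation.get(g)]
        func_counts: dict = {}
        for g in annotated:
            for f in annotation[g]:
                func_counts[f] = func_counts.get(f, 0) + 1
        if func_counts:
            top_function = min(func_counts, key=lambda f: (-func_counts[f], f))
            top_count = func_counts[top_function]
        else:
            top_function, top_count = None, 0
        n_annotated = len(annotated)
        rate = n_annotated / len(members) if members else 0.0
        rows.append(
            {
                "module": module,
                "n_genes": len(members),
                "n_annotated": n_annotated,
                "annotation_rate": rate,
                "n_distinct_functions": len(func_counts),
                "top_function": top_function,
                "top_function_gene_count": top_count,
                "passes": (
                    n_annotated >= 10
                    and rate >= 0.5
                    and len(func_counts) >= 3
                    and top_count >= 3
                ),
            }
        )
    return pd.DataFrame(rows)
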