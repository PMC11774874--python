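"""Thresholded root-trait phenotypic networks and their comparison.

Traits are nodes; an edge joins two traits when their phylogenetic
correlation is both strong (|r| above a threshold, 0.5 by default) and
significant (p below alpha, or an externally supplied significance
flag).  Edge weight is |r|, with the sign of r kept as an attribute.
Path-based metrics (average path length, betweenness) use the edge
weight |r| itself as the additive cost of traversing an edge; this is
the convention under which the published whole-network values are
internally consistent.  Connectance divides the edge count by
n(n+1)/2 — the self-loop-inclusive pair count — which is the only
denominator consistent with the published values; plain edge density
uses n(n-1)/2.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .comparative import TraitCorrelations

__all__ = [
    "PhenotypeNetwork",
    "NetworkSummary",
    "NetworkComparison",
    "build_network",
    "exclude_trait",
    "single_trait_metrics",
    "whole_network_metrics",
    "network_summary",
    "paired_t_test",
    "compare_networks",
    "round_half_up",
]


def round_half_up(x: float, decimals: int = 1) -> float:
    """Round with ties away from zero (display convention for report tables)."""
    if math.isnan(x):
        return x
    factor = 10 ** decimals
    return math.copysign(math.floor(abs(x) * factor + 0.5) / factor, x)


@dataclass
class PhenotypeNetwork:
    """Weighted undirected signed trait graph.

    ``adjacency[i, j] = |r_ij|`` for retained edges, else 0; ``signs``
    holds +1/-1 for retained edges and 0 elsewhere.
    """

    names: tuple
    adjacency: np.ndarray = field(repr=False)
    signs: np.ndarray = field(repr=False)
    threshold: float = 0.5
    alpha: float = 0.05

    def __post_init__(self):
        A = np.asarray(self.adjacency, dtype=float)
        if not np.allclose(A, A.T) or np.any(np.diag(A) != 0):
            raise ValueError("adjacency must be symmetric with zero diagonal")
        if A.min() < 0 or A.max() > 1:
            raise ValueError("edge weights must lie in [0, 1]")
        self.adjacency = A
        self.names = tuple(self.names)

    @property
    def n(self) -> int:
        return len(self.names)

    @property
    def n_edges(self) -> int:
        return int(np.count_nonzero(np.triu(self.adjacency, 1)))

    def edges(self):
        """Iterate (trait_a, trait_b, weight, sign) over retained edges."""
        for i, j in zip(*np.triu_indices(self.n, 1)):
            if self.adjacency[i, j] > 0:
                yield (self.names[i], self.names[j],
                       float(self.adjacency[i, j]), int(self.signs[i, j]))

    def to_networkx(self) -> nx.Graph:
        G = nx.Graph()
        G.add_nodes_from(self.names)
        for a, b, w, s in self.edges():
            # 'cost' duplicates the weight: shortest paths price an edge
            # at its correlation strength |r|
            G.add_edge(a, b, weight=w, sign=s, cost=w)
        return G

    def edge_frame(self) -> pd.DataFrame:
        rows = [{"trait_a": a, "trait_b": b, "r": w * s, "sign": s}
                for a, b, w, s in self.edges()]
        return pd.DataFrame(rows, columns=["trait_a", "trait_b", "r", "sign"])


@dataclass
class NetworkSummary:
    """Per-trait and whole-network metrics of one phenotype network."""

    names: tuple
    degree: np.ndarray
    weighted_degree: np.ndarray
    betweenness: np.ndarray
    hub_traits: tuple
    n_nodes: int
    n_edges: int
    edge_density: float
    connectance: float
    clustering: float          # global transitivity; NaN when n < 3
    average_path_length: float  # NaN when the graph is disconnected
    connected: bool

    def per_trait_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"degree": self.degree, "weighted_degree": self.weighted_degree,
             "betweenness": self.betweenness},
            index=list(self.names))

    def whole_network_dict(self) -> dict:
        return {
            "n_nodes": self.n_nodes, "n_edges": self.n_edges,
            "edge_density": self.edge_density, "connectance": self.connectance,
            "clustering": self.clustering,
            "average_path_length": self.average_path_length,
            "connected": self.connected,
        }


@dataclass
class NetworkComparison:
    """Paired t-tests of per-trait metrics with vs without a focal trait."""

    focal: str
    shared: tuple
    with_focal: NetworkSummary
    without_focal: NetworkSummary
    tests: dict  # metric -> (t, df, p)


def build_network(corr: TraitCorrelations, threshold: float = 0.5,
                  alpha: float = 0.05) -> PhenotypeNetwork:
    """Edges are the pairs with |r| > threshold AND p < alpha.

    When the correlation object carries explicit significance flags
    (published-table fixtures), those replace the p-value rule.
    """
    if corr.p < 2:
        raise ValueError("need at least 2 traits to build a network")
    if not (0 <= threshold < 1):
        raise ValueError("threshold must be in [0, 1)")
    r = corr.corr
    if corr.significant is not None:
        sig = corr.significant.astype(bool)
    else:
        if corr.pvalues is None:
            raise ValueError("correlations carry neither p-values nor "
                             "significance flags")
        sig = corr.pvalues < alpha
    keep = (np.abs(r) > threshold) & sig
    np.fill_diagonal(keep, False)
    A = np.where(keep, np.abs(r), 0.0)
    S = np.where(keep, np.sign(r), 0.0).astype(int)
    return PhenotypeNetwork(names=corr.names, adjacency=A, signs=S,
                            threshold=threshold, alpha=alpha)


def exclude_trait(corr: TraitCorrelations, trait: str) -> TraitCorrelations:
    """Drop one trait's row/column; all other entries are untouched."""
    return corr.drop(trait)


def single_trait_metrics(net: PhenotypeNetwork) -> NetworkSummary:
    """Degree, weighted degree (strength) and normalized betweenness.

    Betweenness uses weighted shortest paths with additive edge cost
    |r| and fractional counting over tied shortest paths, normalized by
    (n-1)(n-2)/2.  Hub traits are the argmax of weighted degree (all
    maxima on ties).
    """
    G = net.to_networkx()
    k = np.array([G.degree(t) for t in net.names], dtype=float)
    D = net.adjacency.sum(axis=1)
    if net.n > 2:
        bc = nx.betweenness_centrality(G, weight="cost", normalized=True)
        b = np.array([bc[t] for t in net.names])
    else:
        b = np.zeros(net.n)
    if D.max() > 0:
        hubs = tuple(net.names[i] for i in np.flatnonzero(
            np.isclose(D, D.max(), rtol=0, atol=1e-12)))
    else:
        hubs = ()
    whole = whole_network_metrics(net)
    return NetworkSummary(
        names=net.names, degree=k.astype(int), weighted_degree=D,
        betweenness=b, hub_traits=hubs, n_nodes=whole.n_nodes,
        n_edges=whole.n_edges, edge_density=whole.edge_density,
        connectance=whole.connectance, clustering=whole.clustering,
        average_path_length=whole.average_path_length,
        connected=whole.connected)


def whole_network_metrics(net: PhenotypeNetwork) -> NetworkSummary:
    """Whole-network metrics only (per-trait arrays left empty).

    * average path length: mean weighted shortest-path distance (cost
      |r|) over unordered node pairs; NaN with ``connected=False`` when
      any pair is unreachable;
    * edge density L / (n(n-1)/2);
    * clustering: global transitivity, 3 x triangles / connected triples
      (unweighted); NaN when n < 3;
    * connectance L / (n(n+1)/2).
    """
    G = net.to_networkx()
    n, L = net.n, net.n_edges
    density = L / (n * (n - 1) / 2) if n > 1 else float("nan")
    connectance = L / (n * (n + 1) / 2)
    clustering = nx.transitivity(G) if n >= 3 else float("nan")
    lengths = dict(nx.all_pairs_dijkstra_path_length(G, weight="cost"))
    dists = []
    connected = True
    for a, b in itertools.combinations(net.names, 2):
        if b in lengths.get(a, {}):
            dists.append(lengths[a][b])
        else:
            connected = False
    apl = float(np.mean(dists)) if (connected and dists) else float("nan")
    return NetworkSummary(
        names=net.names, degree=np.zeros(n, dtype=int),
        weighted_degree=np.zeros(n), betweenness=np.zeros(n), hub_traits=(),
        n_nodes=n, n_edges=L, edge_density=float(density),
        connectance=float(connectance), clustering=float(clustering),
        average_path_length=apl, connected=connected)


def network_summary(net: PhenotypeNetwork) -> NetworkSummary:
    """Per-trait and whole-network metrics in one bundle."""
    return single_trait_metrics(net)


def paired_t_test(a, b):
    """Paired t-test: t = mean(d) / (sd(d)/sqrt(m)), df = m - 1.

    All-zero differences give (0, m-1, 1); nonzero differences with zero
    variance are degenerate and raise.
    """
    a = np.asarray(a, dtype=float).reshape(-1)
    b = np.asarray(b, dtype=float).reshape(-1)
    if a.shape != b.shape or a.size < 2:
        raise ValueError("paired samples must have equal length >= 2")
    d = a - b
    m = d.size
    sd = d.std(ddof=1)
    if sd == 0:
        if np.all(d == 0):
            return 0.0, m - 1, 1.0
        raise ValueError("degenerate paired test: identical nonzero differences")
    t = d.mean() / (sd / np.sqrt(m))
    p = 2.0 * stats.t.sf(abs(t), df=m - 1)
    return float(t), m - 1, float(p)


def compare_networks(corr: TraitCorrelations, focal: str,
                     threshold: float = 0.5, alpha: float = 0.05) -> NetworkComparison:
    """Build networks with and without the focal trait and compare.

    Per-trait degree, weighted degree and betweenness are paired over
    the traits shared by both networks (everything except the focal
    trait) and tested with paired t-tests (df = shared - 1).
    """
    if focal not in corr.names:
        raise KeyError(f"focal trait {focal!r} not present")
    net_with = build_network(corr, threshold=threshold, alpha=alpha)
    net_without = build_network(exclude_trait(corr, focal),
                                threshold=threshold, alpha=alpha)
    sum_with = single_trait_metrics(net_with)
    sum_without = single_trait_metrics(net_without)
    shared = tuple(t for t in corr.names if t != focal)
    iw = [sum_with.names.index(t) for t in shared]
    io = [sum_without.names.index(t) for t in shared]
    tests = {}
    for metric in ("degree", "weighted_degree", "betweenness"):
        va = getattr(sum_with, metric).astype(float)[iw]
        vb = getattr(sum_without, metric).astype(float)[io]
        tests[metric] = paired_t_test(va, vb)
    return NetworkComparison(focal=focal, shared=shared, with_focal=sum_with,
                             without_focal=sum_without, tests=tests)
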