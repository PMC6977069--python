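"""Pairwise-group subnetwork extraction and topology metrics.

Metrics follow the NetworkAnalyzer conventions: density is realized
over possible edges, centralization is Freeman degree centralization
(1 = star, 0 = regular), betweenness is shortest-path betweenness
normalized to [0, 1], and the diameter is taken over the largest
connected component since bipartite pair subnetworks are routinely
disconnected.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy import stats

from .network_model import (
    SIGN_COPRESENCE,
    SIGN_EXCLUSION,
    AnnotatedEdge,
    InteractionNetwork,
)

__all__ = [
    "Subnetwork",
    "TopologyReport",
    "extract_pair_subnetwork",
    "connected_components",
    "density",
    "degree_centralization",
    "betweenness",
    "largest_component_diameter",
    "exclusion_strength",
    "compare_strengths",
    "topology_report",
]


@dataclass
class Subnetwork:
    """Inter-group edge records between a focal and a partner group.

    Nodes are exactly the endpoints of retained edges, so the object is
    bipartite between the two groups' node sets and carries no isolated
    nodes.
    """

    focal_group: str
    partner_group: str
    edges: list[AnnotatedEdge] = field(default_factory=list)

    @property
    def nodes(self) -> set[str]:
        return {e.a for e in self.edges} | {e.b for e in self.edges}

    def graph(self, sign_filter: str | None = None) -> nx.Graph:
        """Simple undirected view (parallel stratum records collapsed)."""
        g = nx.Graph()
        for e in self.edges:
            if sign_filter is None or e.sign == sign_filter:
                g.add_edge(e.a, e.b, score=e.score, sign=e.sign)
        return g

    def scores(self, sign: str) -> list[float]:
        return [e.score for e in self.edges if e.sign == sign]


@dataclass(frozen=True)
class TopologyReport:
    """Bundle of the topology metrics for one pair subnetwork."""

    focal_group: str
    partner_group: str
    n_nodes: int
    n_edges: int
    density: float
    centralization: float
    diameter: int
    avg_neighbors: float
    n_components: int
    n_components_copresence: int
    n_components_exclusion: int
    mean_exclusion_score: float
    sd_exclusion_score: float
    betweenness: dict[str, float]


def extract_pair_subnetwork(
    network: InteractionNetwork,
    focal: str,
    partner: str,
    sign_filter: str | None = None,
) -> Subnetwork:
    """Retain exactly the focal<->partner inter-group edges.

    Intra-group edges are excluded; ``sign_filter`` optionally keeps a
    single sign.  Extraction is symmetric in (focal, partner).
    """
    for g in (focal, partner):
        if g not in network.groups():
            raise KeyError(f"group {g!r} not present in network annotations")
    if sign_filter not in (None, SIGN_COPRESENCE, SIGN_EXCLUSION):
        raise ValueError(f"invalid sign_filter {sign_filter!r}")
    ann = network.annotations
    edges = [
        e
        for e in network.edges
        if {ann[e.a].group, ann[e.b].group} == {focal, partner}
        and focal != partner
        and (sign_filter is None or e.sign == sign_filter)
    ]
    return Subnetwork(focal_group=focal, partner_group=partner, edges=edges)


def connected_components(graph: nx.Graph) -> int:
    """Number of connected components over non-isolated nodes."""
    g = graph.subgraph(n for n, d in graph.degree() if d > 0)
    return nx.number_connected_components(g)


def density(graph: nx.Graph) -> float:
    """Realized / possible edges: 2m / (n(n-1)) for a simple graph."""
    n = graph.number_of_nodes()
    if n < 2:
        raise ValueError(f"density requires >= 2 nodes, got {n}")
    return 2.0 * graph.number_of_edges() / (n * (n - 1))


def degree_centralization(graph: nx.Graph) -> float:
    """Freeman degree centralization: sum(d_max - d_i) / ((n-1)(n-2))."""
    n = graph.number_of_nodes()
    if n < 3:
        raise ValueError(f"degree centralization requires >= 3 nodes, got {n}")
    degrees = np.array([d for _, d in graph.degree()], dtype=float)
    return float((degrees.max() - degrees).sum() / ((n - 1) * (n - 2)))


def betweenness(graph: nx.Graph) -> dict[str, float]:
    """Normalized shortest-path betweenness centrality per node.

    Contributions are split equally across equal-length shortest paths
    and normalized by (n-1)(n-2)/2, so values lie in [0, 1].
    """
    return nx.betweenness_centrality(graph, normalized=True)


def largest_component_diameter(graph: nx.Graph) -> int:
    """Longest shortest path within the largest connected component."""
    if graph.number_of_nodes() == 0:
        raise ValueError("empty graph has no diameter")
    largest = max(nx.connected_components(graph), key=len)
    return int(nx.diameter(graph.subgraph(largest)))


def exclusion_strength(subnetwork: Subnetwork) -> tuple[float, float]:
    """Mean and sample SD (n-1 denominator) of exclusion-edge scores."""
    scores = subnetwork.scores(SIGN_EXCLUSION)
    if not scores:
        raise ValueError(
            f"no exclusion edges in {subnetwork.focal_group!r}-"
            f"{subnetwork.partner_group!r} subnetwork"
        )
    mean = float(np.mean(scores))
    if len(scores) == 1:
        warnings.warn(
            "single exclusion score: sample SD undefined, reporting 0",
            stacklevel=2,
        )
        return mean, 0.0
    return mean, float(np.std(scores, ddof=1))


def compare_strengths(
    x: list[float], y: list[float]
) -> tuple[float, float, float]:
    """Welch two-sample t test on two score samples.

    Returns ``(t_statistic, df, p_value)`` with the Welch-Satterthwaite
    degrees of freedom and a two-sided p-value.  Identical samples give
    t = 0, p = 1; swapping the samples negates t and preserves p.
    """
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if len(xa) < 2 or len(ya) < 2:
        raise ValueError("both samples need >= 2 observations")
    vx, vy = xa.var(ddof=1), ya.var(ddof=1)
    if vx + vy == 0.0:
        raise ValueError("degenerate comparison: both samples have zero variance")
    nx_, ny_ = len(xa), len(ya)
    se2 = vx / nx_ + vy / ny_
    t = float((xa.mean() - ya.mean()) / math.sqrt(se2))
    df = se2**2 / (
        (vx / nx_) ** 2 / (nx_ - 1) + (vy / ny_) ** 2 / (ny_ - 1)
    )
    p = float(2.0 * stats.t.sf(abs(t), df))
    return t, float(df), p


def topology_report(subnetwork: Subnetwork) -> TopologyReport:
    """Compute the full metric bundle for a pair subnetwork.

    Diameter is the longest shortest path on the largest connected
    component; avg_neighbors is the mean degree; sign-specific component
    counts are computed on sign-filtered subgraphs.  density and
    centralization are NaN when the subnetwork is too small for them.
    """
    if not subnetwork.edges:
        raise ValueError("empty subnetwork")
    g = subnetwork.graph()
    n = g.number_of_nodes()
    diam = largest_component_diameter(g)
    mean_ex, sd_ex = (math.nan, math.nan)
    if subnetwork.scores(SIGN_EXCLUSION):
        mean_ex, sd_ex = exclusion_strength(subnetwork)
    return TopologyReport(
        focal_group=subnetwork.focal_group,
        partner_group=subnetwork.partner_group,
        n_nodes=n,
        n_edges=g.number_of_edges(),
        density=density(g) if n >= 2 else math.nan,
        centralization=degree_centralization(g) if n >= 3 else math.nan,
        diameter=diam,
        avg_neighbors=2.0 * g.number_of_edges() / n,
        n_components=connected_components(g),
        n_components_copresence=connected_components(subnetwork.graph(SIGN_COPRESENCE)),
        n_components_exclusion=connected_components(subnetwork.graph(SIGN_EXCLUSION)),
        mean_exclusion_score=mean_ex,
        sd_exclusion_score=sd_ex,
        betweenness=betweenness(g),
    )
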