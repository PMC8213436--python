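"""Gene interaction networks and median-threshold hub extraction.

The screen works in two stages.  Stage 1 builds the tripartite node set
(anti-inflammatory genes, putative targets, disease genes) connected by PPI
edges and selects *core* nodes: degree >= 2x the median degree AND
betweenness >= the median betweenness AND closeness >= the median closeness
(all medians over the current network, all comparisons inclusive).  Stage 2
re-induces the PPI network on the core nodes, recomputes centralities and
medians, and applies the same rule again to yield the *hub* set.  Density is
tracked per stage under the ordered-pair convention E/(N(N-1)); the stage-2
density is expected to rise, and a warning (not an error) is recorded if it
does not.

Centrality conventions: degree is the raw edge count; betweenness is the
raw (unnormalized) count of shortest paths through a node; closeness is
(n_c - 1) / sum of distances within the node's connected component of size
n_c, so isolated nodes score 0.  Only medians and ranks enter the rule, so
any positive rescaling of betweenness leaves the selection unchanged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional

import networkx as nx
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "ROLE_ANTI",
    "ROLE_TARGET",
    "ROLE_DISEASE",
    "build_network",
    "centralities",
    "select_core",
    "density",
    "NetworkSummary",
    "HubResult",
    "extract_hubs",
]

ROLE_ANTI = "anti_inflammatory"
ROLE_TARGET = "putative_target"
ROLE_DISEASE = "disease"

Edge = tuple[str, str]


def clean_edges(edges: Iterable[Edge]) -> list[Edge]:
    """Drop self-loops and duplicate (undirected) edges, preserving order."""
    seen: set[frozenset] = set()
    out: list[Edge] = []
    n_loops = n_dup = 0
    for u, v in edges:
        if u == v:
            n_loops += 1
            continue
        key = frozenset((u, v))
        if key in seen:
            n_dup += 1
            continue
        seen.add(key)
        out.append((u, v))
    if n_loops or n_dup:
        logger.warning("dropped %d self-loop(s) and %d duplicate edge(s)", n_loops, n_dup)
    return out


def build_network(
    anti_genes: Iterable[str],
    target_map: Optional[pd.DataFrame],
    disease_genes: Iterable[str],
    ppi: Iterable[Edge],
    include_compound_edges: bool = False,
) -> nx.Graph:
    """Build the tripartite gene network.

    Nodes are the union of the anti-inflammatory genes, the genes of the
    constituent->target table (columns ``constituent``, ``gene``) and the
    disease genes; edges are the PPI edges with both endpoints in that node
    set.  Role tags are recorded per node (tags may overlap).  With
    ``include_compound_edges`` the constituents join the graph as nodes
    connected to their predicted targets; by default the network is genes-only.
    """
    anti = set(anti_genes)
    disease = set(disease_genes)
    targets = set() if target_map is None else set(target_map["gene"])
    nodes = anti | targets | disease
    if not nodes:
        raise ValueError("empty node set: all three gene collections are empty")

    g = nx.Graph()
    for n in sorted(nodes):
        g.add_node(
            n,
            roles=sorted(
                r
                for r, s in ((ROLE_ANTI, anti), (ROLE_TARGET, targets), (ROLE_DISEASE, disease))
                if n in s
            ),
        )
    kept = [(u, v) for u, v in clean_edges(ppi) if u in nodes and v in nodes]
    g.add_edges_from(kept)
    if include_compound_edges and target_map is not None:
        for row in target_map.itertuples(index=False):
            c = f"compound::{row.constituent}"
            if c not in g:
                g.add_node(c, roles=["compound"])
            if row.gene in nodes and c != row.gene:
                g.add_edge(c, row.gene)
    if g.number_of_edges() == 0:
        logger.warning("network has %d nodes but no edges", g.number_of_nodes())
    return g


def centralities(net: nx.Graph) -> pd.DataFrame:
    """Degree, raw betweenness and component-wise closeness per node."""
    if net.number_of_nodes() == 0:
        raise ValueError("empty network")
    deg = dict(net.degree())
    bet = nx.betweenness_centrality(net, normalized=False)
    clo = nx.closeness_centrality(net, wf_improved=False)
    df = pd.DataFrame(
        {
            "degree": pd.Series(deg, dtype=int),
            "betweenness": pd.Series(bet, dtype=float),
            "closeness": pd.Series(clo, dtype=float),
        }
    )
    return df.loc[list(net.nodes())]


def select_core(
    net: nx.Graph,
    table: Optional[pd.DataFrame] = None,
    degree_mult: float = 2.0,
    betweenness_mult: float = 1.0,
    closeness_mult: float = 1.0,
) -> set[str]:
    """Median-threshold topological screen.

    Keeps nodes with degree >= degree_mult x median(degree) AND
    betweenness >= betweenness_mult x median(betweenness) AND
    closeness >= closeness_mult x median(closeness); medians over all nodes
    of ``net``, comparisons inclusive.
    """
    if table is None:
        table = centralities(net)
    missing = [n for n in net.nodes() if n not in table.index]
    if missing:
        raise ValueError(f"centrality table misses {len(missing)} node(s), e.g. {missing[:5]}")
    table = table.loc[list(net.nodes())]
    med = table.median()
    keep = (
        (table["degree"] >= degree_mult * med["degree"])
        & (table["betweenness"] >= betweenness_mult * med["betweenness"])
        & (table["closeness"] >= closeness_mult * med["closeness"])
    )
    return set(table.index[keep])


def density(n_nodes: int, n_edges: int) -> float:
    """Network density under the ordered-pair convention E / (N(N-1))."""
    if n_nodes < 2:
        raise ValueError(f"density needs >= 2 nodes, got {n_nodes}")
    return n_edges / (n_nodes * (n_nodes - 1))


@dataclass(frozen=True)
class NetworkSummary:
    """Node/edge counts and density of one stage's network."""

    n_nodes: int
    n_edges: int
    density: Optional[float]  # None when n_nodes < 2

    @classmethod
    def of(cls, net: nx.Graph) -> "NetworkSummary":
        n, e = net.number_of_nodes(), net.number_of_edges()
        return cls(n, e, density(n, e) if n >= 2 else None)


@dataclass
class HubResult:
    """Outcome of the two-stage median-threshold hub extraction."""

    stage1: NetworkSummary
    core: set[str]
    stage2: Optional[NetworkSummary]
    hubs: set[str]
    medians_stage1: dict[str, float]
    medians_stage2: Optional[dict[str, float]]
    warnings: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "stage1": vars(self.stage1),
            "core": sorted(self.core),
            "stage2": None if self.stage2 is None else vars(self.stage2),
            "hubs": sorted(self.hubs),
            "medians_stage1": self.medians_stage1,
            "medians_stage2": self.medians_stage2,
            "warnings": list(self.warnings),
        }


def extract_hubs(
    net: nx.Graph,
    ppi: Iterable[Edge],
    degree_mult: float = 2.0,
    betweenness_mult: float = 1.0,
    closeness_mult: float = 1.0,
) -> HubResult:
    """Two-stage hub extraction with density accounting.

    Stage 1 screens ``net``; stage 2 builds the PPI subnetwork induced by the
    core nodes, recomputes centralities and medians and screens again.  When
    fewer than two core nodes survive stage 1, stage 2 is skipped and the
    hub set is empty.
    """
    mults = dict(
        degree_mult=degree_mult,
        betweenness_mult=betweenness_mult,
        closeness_mult=closeness_mult,
    )
    t1 = centralities(net)
    core = select_core(net, t1, **mults)
    s1 = NetworkSummary.of(net)
    warnings: list[str] = []
    med1 = t1.median().to_dict()

    if len(core) < 2:
        warnings.append(f"stage 2 skipped: core has {len(core)} node(s)")
        return HubResult(s1, core, None, set(), med1, None, warnings)

    induced = nx.Graph()
    induced.add_nodes_from(sorted(core))
    induced.add_edges_from(
        (u, v) for u, v in clean_edges(ppi) if u in core and v in core
    )
    t2 = centralities(induced)
    hubs = select_core(induced, t2, **mults)
    s2 = NetworkSummary.of(induced)
    if s1.density is not None and s2.density is not None and s2.density < s1.density:
        warnings.append(
            f"stage-2 density {s2.density:.4f} did not exceed stage-1 density {s1.density:.4f}"
        )
    return HubResult(s1, core, s2, hubs, med1, t2.median().to_dict(), warnings)
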