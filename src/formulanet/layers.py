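"""Multilayer subnetwork construction around a query gene set.

Three nested layers are cut from a reference PPI:

* **CN** (core net) — induced subgraph on the query genes themselves;
* **SPEN** (shortest-path-extending net) — query genes plus every
  intermediate node on any shortest path of <= ``max_len`` edges between a
  query pair, induced;
* **NEN** (neighbor-extending net) — query genes plus all their direct
  PPI neighbors, induced.

Node sets obey CN ⊆ SPEN ⊆ NEN whenever ``max_len >= 2``. Queries absent
from the PPI are dropped and reported, not raised.
"""

from __future__ import annotations

import itertools
import logging
import statistics
from dataclasses import dataclass

import networkx as nx

logger = logging.getLogger(__name__)


@dataclass
class LayerSet:
    cn: nx.Graph
    spen: nx.Graph
    nen: nx.Graph
    dropped_queries: frozenset[str]


def _present_queries(ppi: nx.Graph, query) -> tuple[set[str], set[str]]:
    query = set(query)
    present = query & set(ppi.nodes)
    dropped = query - present
    if not present:
        raise ValueError("no query gene is present in the PPI")
    if dropped:
        logger.warning("dropped %d query genes absent from PPI", len(dropped))
    return present, dropped


def build_core_net(ppi: nx.Graph, query) -> nx.Graph:
    """Induced subgraph on the query genes found in the PPI."""
    present, _ = _present_queries(ppi, query)
    return ppi.subgraph(present).copy()


def build_spen(ppi: nx.Graph, query, max_len: int = 3) -> nx.Graph:
    """Query genes plus all intermediates of shortest paths <= ``max_len`` edges.

    Every shortest path between a qualifying pair contributes its interior
    nodes (a node v lies on a shortest a-b path iff d(a,v)+d(v,b)=d(a,b)),
    so the construction is deterministic and path-enumeration free.
    """
    present, _ = _present_queries(ppi, query)
    dist = {
        q: nx.single_source_shortest_path_length(ppi, q, cutoff=max_len)
        for q in present
    }
    augmented = set(present)
    for a, b in itertools.combinations(sorted(present), 2):
        d_ab = dist[a].get(b)
        if d_ab is None or d_ab > max_len:
            continue
        for v, d_av in dist[a].items():
            d_vb = dist[b].get(v)
            if d_vb is not None and d_av + d_vb == d_ab:
                augmented.add(v)
    return ppi.subgraph(augmented).copy()


def build_nen(ppi: nx.Graph, query) -> nx.Graph:
    """Query genes plus their direct neighbors, induced."""
    present, _ = _present_queries(ppi, query)
    augmented = set(present)
    for q in present:
        augmented.update(ppi.neighbors(q))
    return ppi.subgraph(augmented).copy()


def build_layers(ppi: nx.Graph, query, max_len: int = 3) -> LayerSet:
    """All three layers for one query set, with the dropped queries recorded."""
    present, dropped = _present_queries(ppi, query)
    return LayerSet(
        cn=build_core_net(ppi, present),
        spen=build_spen(ppi, present, max_len=max_len),
        nen=build_nen(ppi, present),
        dropped_queries=frozenset(dropped),
    )


def node_similarity(net_a: nx.Graph, net_b: nx.Graph) -> float:
    """Node-overlap similarity |A ∩ B| / min(|A|, |B|) of two networks."""
    na, nb = set(net_a.nodes), set(net_b.nodes)
    if not na or not nb:
        raise ValueError("node similarity undefined for an empty network")
    return len(na & nb) / min(len(na), len(nb))


@dataclass
class NetworkStats:
    """Descriptive statistics panel of one layer network.

    Path metrics (diameter, average shortest path) are computed over
    connected pairs only; betweenness is unnormalised; both the mean local
    clustering coefficient and the global transitivity are reported since
    the two differ sharply on sparse graphs.
    """

    n_nodes: int
    n_edges: int
    n_isolated: int
    degree_mean: float
    degree_sd: float
    betweenness_mean: float
    betweenness_sd: float
    density: float
    clustering_local_mean: float
    transitivity: float
    diameter: int
    avg_shortest_path: float

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def _mean_sd(values) -> tuple[float, float]:
    vals = list(values)
    if not vals:
        return 0.0, 0.0
    mean = statistics.fmean(vals)
    sd = statistics.pstdev(vals) if len(vals) > 1 else 0.0
    return mean, sd


def network_stats(net: nx.Graph) -> NetworkStats:
    """Compute the descriptive panel; single-node/edgeless graphs yield zeros."""
    n = net.number_of_nodes()
    degrees = [d for _, d in net.degree()]
    deg_mean, deg_sd = _mean_sd(degrees)
    if n > 1:
        btw = nx.betweenness_centrality(net, normalized=False)
        btw_mean, btw_sd = _mean_sd(btw.values())
        density = nx.density(net)
        clustering = statistics.fmean(nx.clustering(net).values())
        transitivity = nx.transitivity(net)
    else:
        btw_mean = btw_sd = density = clustering = transitivity = 0.0
    diameter = 0
    path_sum, path_pairs = 0, 0
    for comp in nx.connected_components(net):
        if len(comp) < 2:
            continue
        sub = net.subgraph(comp)
        for src, lengths in nx.all_pairs_shortest_path_length(sub):
            for tgt, d in lengths.items():
                if src != tgt:
                    path_sum += d
                    path_pairs += 1
                    diameter = max(diameter, d)
    avg_sp = path_sum / path_pairs if path_pairs else 0.0
    return NetworkStats(
        n_nodes=n,
        n_edges=net.number_of_edges(),
        n_isolated=sum(1 for d in degrees if d == 0),
        degree_mean=deg_mean,
        degree_sd=deg_sd,
        betweenness_mean=btw_mean,
        betweenness_sd=btw_sd,
        density=density,
        clustering_local_mean=clustering,
        transitivity=transitivity,
        diameter=diameter,
        avg_shortest_path=avg_sp,
    )


def stats_panel(layers: dict[str, LayerSet]) -> "pd.DataFrame":  # noqa: F821
    """Tabulate the stats of every layer of every labelled query set."""
    import pandas as pd

    rows = []
    for label, ls in layers.items():
        for level in ("cn", "spen", "nen"):
            stats = network_stats(getattr(ls, level)).to_dict()
            rows.append({"set": label, "level": level.upper(), **stats})
    return pd.DataFrame(rows)
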