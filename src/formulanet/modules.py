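"""Network-module scoring and detection.

A candidate decomposition of an interactome subnet is scored by

    MS = Q + BHI,

where Q is Newman-Girvan modularity (within-module edge density relative
to the degree-preserving random expectation) and BHI is the biological
homogeneity index — the fraction of within-module ordered pairs of
pathway-annotated genes that share at least one pathway, averaged over
modules. MS lets structurally tight but functionally incoherent
partitions be ranked against looser, functionally pure ones on one scale.

Two reference detectors are bundled (greedy modularity agglomeration and
a seeded local-density expansion); partitions produced by external
detectors are ingested from membership tables and scored the same way.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import pandas as pd

from . import io
from .enrich import AnnotationCollection
from .proximity import RWRConfig, rwr

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ModulePartition:
    """A list of gene modules (each >= 2 genes), possibly overlapping."""

    modules: tuple[frozenset[str], ...]
    detector: str = ""
    allow_overlap: bool = False

    def __post_init__(self):
        mods = tuple(frozenset(m) for m in self.modules)
        object.__setattr__(self, "modules", mods)
        if any(len(m) < 2 for m in mods):
            raise ValueError("every module must contain at least 2 genes")
        seen: set[str] = set()
        overlap = False
        for m in mods:
            if m & seen:
                overlap = True
            seen |= m
        if overlap and not self.allow_overlap:
            object.__setattr__(self, "allow_overlap", True)

    @property
    def genes(self) -> frozenset[str]:
        out: set[str] = set()
        for m in self.modules:
            out |= m
        return frozenset(out)

    def sizes(self) -> list[int]:
        return [len(m) for m in self.modules]


@dataclass(frozen=True)
class ModuleScore:
    q: float
    bhi: float

    @property
    def ms(self) -> float:
        return self.q + self.bhi


def _hard_assignment(net: nx.Graph, partition: ModulePartition) -> dict[str, int]:
    """Map every network node to one community label.

    Overlapping genes go to the module where they have most internal
    edges (ties: smaller module, then lower module index); nodes uncovered
    by the partition become singleton communities.
    """
    membership: dict[str, list[int]] = {}
    for idx, module in enumerate(partition.modules):
        for g in module:
            membership.setdefault(g, []).append(idx)
    labels: dict[str, int] = {}
    next_label = len(partition.modules)
    for node in net.nodes:
        mods = membership.get(node)
        if not mods:
            labels[node] = next_label
            next_label += 1
        elif len(mods) == 1:
            labels[node] = mods[0]
        else:
            neighbors = set(net.neighbors(node))
            best = min(
                mods,
                key=lambda i: (
                    -len(neighbors & partition.modules[i]),
                    len(partition.modules[i]),
                    i,
                ),
            )
            labels[node] = best
    return labels


def modularity_q(net: nx.Graph, partition: ModulePartition) -> float:
    """Newman-Girvan modularity of the partition on ``net``.

    Q = (1/2E) sum_ij [A_ij - D_i D_j / 2E] delta(C_i, C_j) over all
    ordered node pairs (diagonal included). Overlapping modules are
    hard-assigned first; uncovered nodes count as singletons.
    """
    e = net.number_of_edges()
    if e == 0:
        raise ValueError("modularity undefined on an edgeless network")
    labels = _hard_assignment(net, partition)
    internal: dict[int, int] = {}
    degree_sum: dict[int, int] = {}
    for node, deg in net.degree():
        c = labels[node]
        degree_sum[c] = degree_sum.get(c, 0) + deg
    for u, v in net.edges():
        if labels[u] == labels[v]:
            c = labels[u]
            internal[c] = internal.get(c, 0) + 1
    q = 0.0
    for c, dsum in degree_sum.items():
        q += internal.get(c, 0) / e - (dsum / (2.0 * e)) ** 2
    return q


def bhi(partition: ModulePartition, pathways: AnnotationCollection) -> float:
    """Biological homogeneity index of the partition under ``pathways``.

    Per module only pathway-annotated genes count; the module term is the
    fraction of ordered annotated pairs sharing >= 1 pathway, and modules
    with fewer than two annotated genes contribute zero. The average runs
    over all K modules.
    """
    if not partition.modules:
        return 0.0
    gene_terms: dict[str, frozenset[str]] = {}
    for term, (_, genes) in pathways.terms.items():
        for g in genes:
            gene_terms[g] = gene_terms.get(g, frozenset()) | {term}
    total = 0.0
    for module in partition.modules:
        annotated = [g for g in sorted(module) if g in gene_terms]
        n_k = len(annotated)
        if n_k < 2:
            continue
        matches = 0
        for i in range(n_k):
            for j in range(i + 1, n_k):
                if gene_terms[annotated[i]] & gene_terms[annotated[j]]:
                    matches += 2  # ordered pairs
        total += matches / (n_k * (n_k - 1))
    return total / len(partition.modules)


def module_score(
    net: nx.Graph, partition: ModulePartition, pathways: AnnotationCollection
) -> ModuleScore:
    """MS = Q + BHI with the two components reported separately."""
    return ModuleScore(q=modularity_q(net, partition), bhi=bhi(partition, pathways))


def detect_modules_greedy(net: nx.Graph) -> ModulePartition:
    """Agglomerative greedy modularity maximisation (Clauset-Newman-Moore).

    Modules that end up as singletons are dropped from the partition (they
    still count as singleton communities when Q is recomputed).
    """
    if net.number_of_edges() == 0:
        raise ValueError("cannot detect modules on an edgeless network")
    communities = nx.community.greedy_modularity_communities(net)
    modules = sorted(
        (frozenset(c) for c in communities if len(c) >= 2),
        key=lambda m: (-len(m), min(m)),
    )
    return ModulePartition(modules=tuple(modules), detector="greedy")


def _density(net: nx.Graph, members: set[str]) -> float:
    k = len(members)
    if k < 2:
        return 1.0
    e = net.subgraph(members).number_of_edges()
    return 2.0 * e / (k * (k - 1))


def detect_modules_density(
    net: nx.Graph, min_size: int = 4, density_threshold: float = 0.7
) -> ModulePartition:
    """Seeded local-density expansion in the spirit of molecular-complex
    detection: seeds are taken in descending clustering-weight order and
    greedily absorb the neighbor that keeps module density highest, while
    the density stays >= ``density_threshold``; modules smaller than
    ``min_size`` are discarded.
    """
    clustering = nx.clustering(net)
    weight = {v: clustering[v] * d for v, d in net.degree()}
    order = sorted(net.nodes, key=lambda v: (-weight[v], v))
    used: set[str] = set()
    modules: list[frozenset[str]] = []
    for seed in order:
        if seed in used:
            continue
        members = {seed}
        while True:
            candidates = set()
            for m in members:
                candidates.update(net.neighbors(m))
            candidates -= members | used
            best, best_density = None, -1.0
            for c in sorted(candidates):
                d = _density(net, members | {c})
                if d > best_density:
                    best, best_density = c, d
            if best is None or best_density < density_threshold:
                break
            members.add(best)
        if len(members) >= min_size:
            modules.append(frozenset(members))
            used |= members
    return ModulePartition(
        modules=tuple(sorted(modules, key=lambda m: (-len(m), min(m)))),
        detector="density",
    )


def load_partition(path, net: nx.Graph | None = None) -> ModulePartition:
    """Read a (module_id, gene) membership table into a partition.

    Genes absent from ``net`` (when given) are dropped with a warning;
    modules left with fewer than two genes are discarded.
    """
    df = io.read_partition_table(path)
    if net is not None:
        known = set(net.nodes)
        absent = set(df["gene"]) - known
        if absent:
            logger.warning("load_partition: dropping %d genes absent from network", len(absent))
            df = df[df["gene"].isin(known)]
    modules = []
    for _, sub in df.groupby("module_id"):
        genes = frozenset(sub["gene"])
        if len(genes) >= 2:
            modules.append(genes)
    if not modules:
        raise ValueError(f"{path}: no module with >= 2 usable genes")
    return ModulePartition(modules=tuple(modules), detector=str(path), allow_overlap=True)


def compare_partitions(
    net: nx.Graph,
    partitions: dict[str, ModulePartition],
    pathways: AnnotationCollection,
) -> pd.DataFrame:
    """Score several partitions on one network; sorted by MS descending."""
    rows = []
    for name, part in partitions.items():
        score = module_score(net, part, pathways)
        sizes = part.sizes()
        rows.append(
            {
                "method": name,
                "modules": len(part.modules),
                "module_size": f"{min(sizes)}~{max(sizes)}",
                "q": score.q,
                "bhi": score.bhi,
                "ms": score.ms,
            }
        )
    return (
        pd.DataFrame(rows)
        .sort_values(["ms", "method"], ascending=[False, True])
        .reset_index(drop=True)
    )


def module_disease_association(
    partition: ModulePartition,
    disease,
    ppi: nx.Graph,
    config: RWRConfig | None = None,
) -> pd.DataFrame:
    """Rank modules by the scaled mean RWR mass their members receive from
    a diffusion seeded at the disease genes."""
    config = config or RWRConfig()
    x = rwr(ppi, disease, config)
    rows = []
    any_mass = False
    for idx, module in enumerate(partition.modules, start=1):
        present = [g for g in module if g in x.index]
        score = float(config.score_scale * x.loc[present].mean()) if present else float("nan")
        if present and score > 0:
            any_mass = True
        rows.append(
            {"module_id": f"M{idx}", "size": len(module), "score": score}
        )
    if not any_mass:
        raise ValueError("no module intersects the component containing the seeds")
    return (
        pd.DataFrame(rows)
        .sort_values(["score", "module_id"], ascending=[False, True])
        .reset_index(drop=True)
    )
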