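"""Synthetic inputs with planted ground truth.

Every table the pipeline consumes can be generated here at desk scale: a
heavy-tailed PPI with planted dense modules, a bipartite compound-target
profile with a planted set of over-targeted genes, descriptor tables with
a controlled drug-like fraction, disease gene sets at controlled network
proximity to an anchor set, and annotation collections aligned to the
planted modules. The planted truths suffice to measure precision/recall
of every downstream recovery claim. All randomness flows from the explicit
``seed`` argument; the same seed reproduces byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .enrich import AnnotationCollection

#: the seven herb labels used for synthetic compound assignment (the herb
#: codes of the Ban-Xia-Xie-Xin-Tang formula, whose pooled compounds are
#: the motivating use case)
DEFAULT_HERBS = ("BX", "GJ", "HL", "HQ", "RS", "DZ", "RGC")


@dataclass
class SyntheticTruth:
    """What was planted, so recovery can be scored downstream."""

    planted_core_targets: frozenset[str] = frozenset()
    planted_modules: tuple[frozenset[str], ...] = ()
    druglike_labels: dict[str, bool] = field(default_factory=dict)
    disease_seed_distance: float | None = None
    disease_mode: str | None = None

    def to_dict(self) -> dict:
        return {
            "planted_core_targets": sorted(self.planted_core_targets),
            "planted_modules": [sorted(m) for m in self.planted_modules],
            "druglike_labels": dict(sorted(self.druglike_labels.items())),
            "disease_seed_distance": self.disease_seed_distance,
            "disease_mode": self.disease_mode,
        }


def _gene_name(i: int) -> str:
    return f"G{i + 1:04d}"


def gen_ppi(
    n_nodes: int,
    mean_degree: float = 6.0,
    n_planted_modules: int = 0,
    module_size: int = 10,
    seed: int = 0,
    intra_module_p: float = 0.65,
) -> tuple[nx.Graph, SyntheticTruth]:
    """Scale-free PPI backbone with planted dense modules.

    A preferential-attachment backbone (m = mean_degree / 2) supplies the
    heavy-tailed degree distribution; each planted module is a disjoint
    random node set densified to internal edge probability
    ``intra_module_p`` (connectivity enforced) and recorded in the truth.
    """
    if n_nodes <= 0 or module_size <= 0:
        raise ValueError("n_nodes and module_size must be positive")
    if mean_degree <= 0:
        raise ValueError("mean_degree must be positive")
    if n_planted_modules < 0:
        raise ValueError("n_planted_modules must be non-negative")
    if n_planted_modules * module_size > n_nodes:
        raise ValueError("planted modules cannot exceed the node budget")
    rng = np.random.default_rng(seed)
    m = max(1, int(round(mean_degree / 2.0)))
    if n_nodes <= m:
        raise ValueError("n_nodes must exceed mean_degree / 2")
    backbone = nx.barabasi_albert_graph(n_nodes, m, seed=int(rng.integers(2**31)))
    g = nx.relabel_nodes(backbone, {i: _gene_name(i) for i in range(n_nodes)})

    planted: list[frozenset[str]] = []
    pool = rng.permutation(n_nodes)
    for b in range(n_planted_modules):
        members = sorted(_gene_name(i) for i in pool[b * module_size : (b + 1) * module_size])
        for i in range(len(members)):
            for j in range(i + 1, len(members)):
                if rng.random() < intra_module_p:
                    g.add_edge(members[i], members[j])
        # densified blocks are almost surely connected; patch the rare miss
        sub = g.subgraph(members)
        comps = list(nx.connected_components(sub))
        for extra in comps[1:]:
            g.add_edge(sorted(comps[0])[0], sorted(extra)[0])
        planted.append(frozenset(members))
    truth = SyntheticTruth(planted_modules=tuple(planted))
    return g, truth


def gen_compound_targets(
    n_compounds: int,
    n_targets: int,
    n_core: int = 0,
    lift: float = 8.0,
    seed: int = 0,
    base_rate: float = 0.01,
    herbs: tuple[str, ...] = DEFAULT_HERBS,
) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Bipartite compound-target table with ``n_core`` over-targeted genes.

    Background (compound, target) links appear independently at
    ``base_rate``; the planted core targets receive links at
    ``base_rate * lift``. Each compound is assigned one herb uniformly.
    """
    if n_compounds <= 0 or n_targets <= 0:
        raise ValueError("n_compounds and n_targets must be positive")
    if not 0 <= n_core <= n_targets:
        raise ValueError("require 0 <= n_core <= n_targets")
    if n_core > 0 and lift <= 1.0:
        raise ValueError("lift must exceed 1 for planted targets to be detectable")
    rng = np.random.default_rng(seed)
    targets = [_gene_name(i) for i in range(n_targets)]
    core_idx = rng.choice(n_targets, size=n_core, replace=False) if n_core else np.array([], dtype=int)
    p = np.full(n_targets, base_rate)
    p[core_idx] = min(base_rate * lift, 1.0)
    hits = rng.random((n_compounds, n_targets)) < p[None, :]
    herb_of = rng.choice(len(herbs), size=n_compounds)
    rows = []
    for ci in range(n_compounds):
        cid = f"C{ci + 1:04d}"
        herb = herbs[herb_of[ci]]
        for ti in np.flatnonzero(hits[ci]):
            rows.append({"compound_id": cid, "gene": targets[ti], "herb": herb})
    frame = pd.DataFrame(rows, columns=["compound_id", "gene", "herb"])
    truth = SyntheticTruth(
        planted_core_targets=frozenset(targets[i] for i in core_idx)
    )
    return frame, truth


# descriptor sampling centres: the drug-like class sits near the QED
# desirability maxima, the non-drug-like class in the penalised tails
# (very large mass, many alerts/donors), guaranteeing filter separation
_DRUGLIKE = dict(mw=(320.0, 60.0), alogp=(2.5, 1.0), psa=(65.0, 20.0))
_NON_DRUGLIKE = dict(mw=(950.0, 120.0), alogp=(8.5, 1.5), psa=(260.0, 40.0))


def gen_descriptors(
    n_compounds: int,
    druglike_fraction: float = 0.5,
    seed: int = 0,
    herbs: tuple[str, ...] = DEFAULT_HERBS,
) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Descriptor table with a tunable fraction of drug-like compounds."""
    if n_compounds < 0:
        raise ValueError("n_compounds must be non-negative")
    if not 0.0 <= druglike_fraction <= 1.0:
        raise ValueError("druglike_fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    n_druglike = int(round(n_compounds * druglike_fraction))
    labels = np.zeros(n_compounds, dtype=bool)
    labels[:n_druglike] = True
    rng.shuffle(labels)
    rows = []
    truth_labels: dict[str, bool] = {}
    for ci in range(n_compounds):
        cid = f"C{ci + 1:04d}"
        druglike = bool(labels[ci])
        centres = _DRUGLIKE if druglike else _NON_DRUGLIKE
        if druglike:
            counts = dict(
                hba=int(rng.poisson(2)), hbd=int(rng.poisson(1)),
                rotb=int(rng.poisson(3)), arom=1 + int(rng.poisson(1)),
                alerts=0,
            )
        else:
            counts = dict(
                hba=12 + int(rng.poisson(3)), hbd=8 + int(rng.poisson(2)),
                rotb=16 + int(rng.poisson(4)), arom=6 + int(rng.poisson(2)),
                alerts=3 + int(rng.poisson(1)),
            )
        row = {
            "compound_id": cid,
            "herb": herbs[int(rng.integers(len(herbs)))],
            "mw": max(50.0, rng.normal(*centres["mw"])),
            "alogp": rng.normal(*centres["alogp"]),
            "psa": max(0.0, rng.normal(*centres["psa"])),
            **counts,
        }
        rows.append(row)
        truth_labels[cid] = druglike
    cols = ["compound_id", "herb", "mw", "alogp", "hba", "hbd", "psa", "rotb", "arom", "alerts"]
    frame = pd.DataFrame(rows, columns=cols)
    return frame, SyntheticTruth(druglike_labels=truth_labels)


def gen_disease_genes(
    ppi: nx.Graph,
    anchor_set,
    size: int,
    proximity_mode: str = "near",
    seed: int = 0,
    max_hops: int = 2,
    hop_weights: tuple[float, ...] | None = None,
) -> tuple[frozenset[str], SyntheticTruth]:
    """Disease gene set at controlled proximity to ``anchor_set``.

    ``near`` samples from nodes within ``max_hops`` of any anchor,
    stratified over hop distance (weights ``hop_weights``, default
    0.3/0.4/0.3 over hops 0/1/2 so the intended mean hop distance is ~1);
    the 0-hop stratum mirrors the overlap real disease sets show with
    formula targets. ``random`` samples uniformly from all PPI nodes.
    """
    if proximity_mode not in ("near", "random"):
        raise ValueError("proximity_mode must be 'near' or 'random'")
    if size <= 0:
        raise ValueError("size must be positive")
    if size > ppi.number_of_nodes():
        raise ValueError("size exceeds the number of PPI nodes")
    anchors = set(anchor_set)
    missing = anchors - set(ppi.nodes)
    if missing:
        raise KeyError(f"anchor gene(s) absent from PPI: {sorted(missing)[:5]}")
    rng = np.random.default_rng(seed)
    if proximity_mode == "near":
        hop_of: dict[str, int] = {}
        for a in anchors:
            for node, d in nx.single_source_shortest_path_length(ppi, a, cutoff=max_hops).items():
                if d < hop_of.get(node, max_hops + 1):
                    hop_of[node] = d
        strata = [sorted(n for n, d in hop_of.items() if d == h) for h in range(max_hops + 1)]
        if size > len(hop_of):
            raise ValueError(
                f"only {len(hop_of)} genes lie within {max_hops} hops of the anchors"
            )
        if hop_weights is None:
            hop_weights = (0.3, 0.4, 0.3)[: max_hops + 1]
        w = np.asarray(hop_weights, dtype=float)
        if len(w) != max_hops + 1 or w.sum() <= 0:
            raise ValueError("hop_weights must give one non-negative weight per hop level")
        # target counts per stratum, spilling over when a stratum is small
        quota = np.floor(size * w / w.sum()).astype(int)
        while quota.sum() < size:
            quota[int(rng.integers(max_hops + 1))] += 1
        chosen: list[str] = []
        deficit = 0
        for h in range(max_hops + 1):
            want = int(quota[h]) + deficit
            take = min(want, len(strata[h]))
            deficit = want - take
            if take:
                idx = rng.choice(len(strata[h]), size=take, replace=False)
                chosen.extend(strata[h][i] for i in idx)
        if deficit:  # spill back to the widest stratum
            leftovers = sorted(set(hop_of) - set(chosen))
            idx = rng.choice(len(leftovers), size=deficit, replace=False)
            chosen.extend(leftovers[i] for i in idx)
        genes = frozenset(chosen)
        mean_hop = float(np.mean([hop_of[g] for g in genes]))
    else:
        pool_list = sorted(ppi.nodes)
        idx = rng.choice(len(pool_list), size=size, replace=False)
        genes = frozenset(pool_list[i] for i in idx)
        mean_hop = None
    truth = SyntheticTruth(
        disease_mode=proximity_mode,
        disease_seed_distance=mean_hop,
    )
    return genes, truth


def gen_annotations(
    planted_modules,
    n_noise_terms: int = 0,
    universe=None,
    seed: int = 0,
    noise_genes: int = 1,
) -> AnnotationCollection:
    """One annotation term per planted module plus random noise terms.

    Module terms carry the module's genes with small noise (up to
    ``noise_genes`` dropped and added); noise terms are random universe
    subsets. The result serialises to GMT via :func:`formulanet.io.write_gmt`.
    """
    modules = [frozenset(m) for m in planted_modules]
    if universe is None:
        universe = set()
        for m in modules:
            universe |= m
    universe = sorted(set(universe))
    for i, m in enumerate(modules):
        if not m <= set(universe):
            raise ValueError(f"module {i} has genes outside the universe")
    rng = np.random.default_rng(seed)
    terms: dict[str, tuple[str, frozenset[str]]] = {}
    for i, module in enumerate(modules, start=1):
        genes = set(module)
        for _ in range(noise_genes):
            if len(genes) > 2 and rng.random() < 0.5:
                genes.discard(sorted(genes)[int(rng.integers(len(genes)))])
            if rng.random() < 0.5:
                genes.add(universe[int(rng.integers(len(universe)))])
        terms[f"MODTERM{i}"] = (f"planted module {i}", frozenset(genes))
    for j in range(1, n_noise_terms + 1):
        size = int(rng.integers(5, 21))
        size = min(size, len(universe))
        idx = rng.choice(len(universe), size=size, replace=False)
        terms[f"NOISE{j}"] = (f"noise term {j}", frozenset(universe[i] for i in idx))
    return AnnotationCollection(terms=terms, universe=frozenset(universe))
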