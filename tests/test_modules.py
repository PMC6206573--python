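"""Modularity Q, biological homogeneity BHI, MS scoring and detectors."""

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from formulanet import datasets, io, modules as md, synthetic
from formulanet.enrich import AnnotationCollection


def brute_force_q(net: nx.Graph, labels: dict) -> float:
    """Literal double sum over all ordered node pairs (diagonal included)."""
    e = net.number_of_edges()
    adj = {frozenset((u, v)) for u, v in net.edges()}
    q = 0.0
    for i in net.nodes:
        for j in net.nodes:
            if labels[i] != labels[j]:
                continue
            a_ij = 1.0 if i != j and frozenset((i, j)) in adj else 0.0
            q += a_ij - net.degree(i) * net.degree(j) / (2.0 * e)
    return q / (2.0 * e)


def collection_from(pairs: dict[str, set[str]]) -> AnnotationCollection:
    return AnnotationCollection(terms={t: (t, frozenset(g)) for t, g in pairs.items()})


class TestModularityQ:
    def test_whole_network_single_module_is_zero(self):
        g = nx.gnp_random_graph(15, 0.3, seed=1)
        part = md.ModulePartition(modules=(frozenset(g.nodes),))
        assert md.modularity_q(g, part) == pytest.approx(0.0, abs=1e-12)

    def test_two_disjoint_triangles(self):
        g = nx.Graph([(1, 2), (2, 3), (1, 3), (4, 5), (5, 6), (4, 6)])
        part = md.ModulePartition(modules=(frozenset({1, 2, 3}), frozenset({4, 5, 6})))
        assert md.modularity_q(g, part) == pytest.approx(0.5, abs=1e-12)

    def test_matches_brute_force_double_sum(self):
        rng = np.random.default_rng(11)
        for trial in range(10):
            n = int(rng.integers(8, 50))
            g = nx.gnp_random_graph(n, 0.15, seed=int(rng.integers(2**31)))
            if g.number_of_edges() == 0:
                continue
            # random partition covering a random subset; the rest are singletons
            labels = {v: int(rng.integers(0, 4)) for v in g.nodes}
            covered = [v for v in g.nodes if rng.random() < 0.8]
            groups: dict[int, set] = {}
            for v in covered:
                groups.setdefault(labels[v], set()).add(v)
            modules = tuple(frozenset(s) for s in groups.values() if len(s) >= 2)
            if not modules:
                continue
            part = md.ModulePartition(modules=modules)
            full_labels = md._hard_assignment(g, part)
            assert md.modularity_q(g, part) == pytest.approx(
                brute_force_q(g, full_labels), abs=1e-12
            )

    def test_overlap_reduces_to_standard_q_when_disjoint(self):
        g = nx.gnp_random_graph(40, 0.12, seed=7)
        comms = [c for c in nx.community.greedy_modularity_communities(g) if len(c) >= 2]
        part = md.ModulePartition(modules=tuple(frozenset(c) for c in comms))
        expected = nx.community.modularity(g, comms)
        assert md.modularity_q(g, part) == pytest.approx(expected, abs=1e-12)

    def test_random_partition_near_zero(self):
        qs = []
        rng = np.random.default_rng(0)
        for seed in range(50):
            g = nx.gnm_random_graph(40, 80, seed=seed)
            labels = rng.integers(0, 4, size=40)
            groups: dict[int, set] = {}
            for v, c in zip(g.nodes, labels):
                groups.setdefault(int(c), set()).add(v)
            part = md.ModulePartition(
                modules=tuple(frozenset(s) for s in groups.values() if len(s) >= 2)
            )
            qs.append(md.modularity_q(g, part))
        assert abs(float(np.mean(qs))) <= 0.05

    def test_edgeless_network_rejected(self):
        g = nx.empty_graph(4)
        with pytest.raises(ValueError):
            md.modularity_q(g, md.ModulePartition(modules=(frozenset({0, 1}),)))


class TestBHI:
    def test_fully_shared_pathway(self):
        part = md.ModulePartition(modules=(frozenset({"A", "B", "C"}),))
        coll = collection_from({"P1": {"A", "B", "C"}})
        assert md.bhi(part, coll) == 1.0

    def test_partial_sharing_counts_ordered_pairs(self):
        part = md.ModulePartition(modules=(frozenset({"A", "B", "C"}),))
        coll = collection_from({"P1": {"A", "B"}, "P2": {"C", "Z"}})
        assert md.bhi(part, coll) == pytest.approx(1 / 3)

    def test_vacuous_modules_contribute_zero(self):
        part = md.ModulePartition(modules=(frozenset({"A", "B"}),))
        coll = collection_from({"P1": {"X", "Y"}})
        assert md.bhi(part, coll) == 0.0

    def test_module_order_invariance(self):
        m1, m2 = frozenset({"A", "B"}), frozenset({"C", "D"})
        coll = collection_from({"P1": {"A", "B"}, "P2": {"C", "Z", "D"}})
        a = md.bhi(md.ModulePartition(modules=(m1, m2)), coll)
        b = md.bhi(md.ModulePartition(modules=(m2, m1)), coll)
        assert a == b


class TestModuleScore:
    def test_published_detector_panel_arithmetic(self):
        """MS = Q + BHI reproduces the printed per-detector module scores."""
        panel = datasets.load_module_method_scores().set_index("method")
        expected = {"MOfinder": 0.7874, "FG": 0.3758, "IPCA": 0.7613}
        for method, ms in expected.items():
            row = panel.loc[method]
            score = md.ModuleScore(q=row["q"], bhi=row["bhi"])
            assert score.ms == pytest.approx(ms, abs=1e-9)

    def test_additivity(self):
        assert md.ModuleScore(q=0.0, bhi=0.0).ms == 0.0
        assert md.ModuleScore(q=0.2, bhi=0.5).ms > md.ModuleScore(q=0.2, bhi=0.4).ms


class TestDetectors:
    def test_greedy_recovers_disjoint_triangles(self):
        g = nx.Graph([(1, 2), (2, 3), (1, 3), (4, 5), (5, 6), (4, 6)])
        part = md.detect_modules_greedy(g)
        assert set(part.modules) == {frozenset({1, 2, 3}), frozenset({4, 5, 6})}
        assert md.modularity_q(g, part) == pytest.approx(0.5)

    def test_greedy_single_module_on_complete_graph(self):
        g = nx.complete_graph(6)
        part = md.detect_modules_greedy(g)
        assert len(part.modules) == 1

    def test_greedy_recovers_planted_blocks(self):
        ppi, truth = synthetic.gen_ppi(60, 2.0, 5, 10, seed=3)
        part = md.detect_modules_greedy(ppi)
        true_label = {g: i for i, m in enumerate(truth.planted_modules) for g in m}
        pred_label: dict[str, int] = {}
        for i, m in enumerate(part.modules):
            for g in m:
                pred_label.setdefault(g, i)
        planted_nodes = sorted(true_label)
        ari = adjusted_rand_score(
            [true_label[g] for g in planted_nodes],
            [pred_label.get(g, -1) for g in planted_nodes],
        )
        assert ari >= 0.8

    def test_density_extracts_clique_from_pendants(self):
        g = nx.relabel_nodes(nx.complete_graph(5), {i: f"K{i}" for i in range(5)})
        g.add_edges_from([("K0", "P1"), ("P1", "P2"), ("K1", "P3"), ("P3", "P4")])
        part = md.detect_modules_density(g, min_size=4, density_threshold=0.8)
        assert part.modules == (frozenset({"K0", "K1", "K2", "K3", "K4"}),)

    def test_density_zero_threshold_swallows_components(self):
        g = nx.disjoint_union(nx.path_graph(6), nx.path_graph(5))
        part = md.detect_modules_density(g, min_size=4, density_threshold=0.0)
        assert sorted(len(m) for m in part.modules) == [5, 6]

    def test_density_modules_meet_threshold(self, small_ppi):
        ppi, _ = small_ppi
        part = md.detect_modules_density(ppi, min_size=4, density_threshold=0.5)
        for module in part.modules:
            assert nx.density(ppi.subgraph(module)) >= 0.5


class TestPartitionIO:
    def test_round_trip(self, tmp_path, small_ppi):
        ppi, truth = small_ppi
        path = tmp_path / "part.tsv"
        io.write_partition_table(truth.planted_modules, path)
        loaded = md.load_partition(path, net=ppi)
        assert set(loaded.modules) == set(truth.planted_modules)

    def test_overlap_flag_set(self, tmp_path):
        path = tmp_path / "part.tsv"
        pd.DataFrame(
            {"module_id": ["M1", "M1", "M2", "M2"], "gene": ["A", "B", "A", "C"]}
        ).to_csv(path, sep="\t", index=False)
        part = md.load_partition(path)
        assert part.allow_overlap

    def test_comparison_ranks_true_partition_above_shuffled(self, small_ppi):
        ppi, truth = small_ppi
        coll = synthetic.gen_annotations(
            truth.planted_modules, n_noise_terms=10, universe=set(ppi.nodes), seed=2
        )
        true_part = md.ModulePartition(modules=truth.planted_modules)
        rng = np.random.default_rng(4)
        pool = sorted(true_part.genes)
        rng.shuffle(pool)
        shuffled, start = [], 0
        for size in true_part.sizes():
            shuffled.append(frozenset(pool[start : start + size]))
            start += size
        rand_part = md.ModulePartition(modules=tuple(shuffled))
        report = md.compare_partitions(
            ppi, {"true": true_part, "shuffled": rand_part}, coll
        )
        assert report.iloc[0]["method"] == "true"
        assert report["ms"].is_monotonic_decreasing


class TestModuleDiseaseAssociation:
    def test_seed_module_ranks_first(self, small_ppi):
        ppi, truth = small_ppi
        disease = set(sorted(truth.planted_modules[0]))
        part = md.ModulePartition(modules=truth.planted_modules)
        ranking = md.module_disease_association(part, disease, ppi)
        assert ranking.iloc[0]["module_id"] == "M1"

    def test_no_overlap_with_seed_component_rejected(self):
        g = nx.Graph([("A", "B"), ("C", "D")])
        part = md.ModulePartition(modules=(frozenset({"C", "D"}),))
        with pytest.raises(ValueError):
            md.module_disease_association(part, {"A"}, g)
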