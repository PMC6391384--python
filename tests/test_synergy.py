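import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from netsynergy.connectivity import select_and_weight
from netsynergy.io import DrugProfileSet, PPINetwork
from netsynergy.subnetwork import build_subnetwork
from netsynergy.synergy import (
    centrality_table,
    drug_communities,
    filter_targeted_drugs,
    rank_combinations,
    synergy_score,
)

# ---------------------------------------------------------------------------
# independent centrality oracles
# ---------------------------------------------------------------------------


def oracle_betweenness(g: nx.Graph) -> dict:
    """Path-counting betweenness via explicit BFS shortest-path enumeration."""
    bet = {n: 0.0 for n in g}
    for s, t in itertools.combinations(sorted(g), 2):
        try:
            paths = list(nx.all_shortest_paths(g, s, t))
        except nx.NetworkXNoPath:
            continue
        for n in g:
            if n in (s, t):
                continue
            through = sum(1 for p in paths if n in p)
            bet[n] += through / len(paths)
    return bet


def oracle_closeness(g: nx.Graph) -> dict:
    """BFS closeness with the reachable-fraction scaling for disconnected graphs."""
    n = g.number_of_nodes()
    out = {}
    for v in g:
        dists = nx.single_source_shortest_path_length(g, v)
        reach = len(dists) - 1
        total = sum(dists.values())
        out[v] = (reach / total) * (reach / (n - 1)) if total > 0 and n > 1 else 0.0
    return out


def oracle_pagerank(g: nx.Graph, alpha=0.85, iters=500) -> dict:
    """Dense power iteration on the Google matrix with uniform teleport."""
    nodes = sorted(g)
    n = len(nodes)
    idx = {v: i for i, v in enumerate(nodes)}
    M = np.zeros((n, n))
    for v in nodes:
        nbrs = list(g[v])
        if nbrs:
            for u in nbrs:
                M[idx[u], idx[v]] = 1 / len(nbrs)
        else:
            M[:, idx[v]] = 1 / n  # dangling: spread uniformly
    x = np.full(n, 1 / n)
    for _ in range(iters):
        x = alpha * M @ x + (1 - alpha) / n
    return {v: x[idx[v]] for v in nodes}


def _subnet_from_graph(g: nx.Graph):
    ppi = PPINetwork.from_edges((u, v, 1.0) for u, v in g.edges)
    for n in g.nodes:
        ppi.graph.add_node(n)
    return ppi


class TestCentralities:
    def test_path_graph_bridge_node(self):
        ct = centrality_table(nx.path_graph(["A", "B", "C"]))
        assert ct.table["betweenness"].to_dict() == {"A": 0.0, "B": 1.0, "C": 0.0}
        assert ct.table["cs"].idxmax() == "B"

    def test_five_cycle_pagerank_uniform_by_symmetry(self):
        ct = centrality_table(nx.cycle_graph([f"N{i}" for i in range(5)]))
        assert np.allclose(ct.table["pagerank"], 0.2, atol=1e-9)
        # every metric is constant on a vertex-transitive graph → cs all zero
        assert np.allclose(ct.table["cs"], 0.0)

    def test_singleton_conventions(self):
        g = nx.Graph()
        g.add_node("X")
        ct = centrality_table(g)
        row = ct.table.loc["X"]
        assert row["betweenness"] == 0.0
        assert row["closeness"] == 0.0
        assert row["pagerank"] == 1.0
        assert row["cs"] == 0.0

    @pytest.mark.parametrize("trial", range(15))
    def test_oracle_agreement_on_random_graphs(self, trial):
        rng = np.random.default_rng(8200 + trial)
        n = int(rng.integers(5, 50))
        g = nx.gnp_random_graph(n, 0.15, seed=int(rng.integers(2**31)))
        g = nx.relabel_nodes(g, {i: f"N{i:02d}" for i in g.nodes})
        ct = centrality_table(g).table
        bet = oracle_betweenness(g)
        clo = oracle_closeness(g)
        pr = oracle_pagerank(g)
        for v in g:
            assert ct.at[v, "betweenness"] == pytest.approx(bet[v], abs=1e-9)
            assert ct.at[v, "closeness"] == pytest.approx(clo[v], abs=1e-9)
            assert ct.at[v, "pagerank"] == pytest.approx(pr[v], abs=1e-6)

    def test_pagerank_sums_to_one_even_when_disconnected(self):
        g = nx.Graph([("A", "B"), ("C", "D")])
        g.add_node("E")
        ct = centrality_table(g)
        assert ct.table["pagerank"].sum() == pytest.approx(1.0, abs=1e-9)


class TestTargetFilterAndScore:
    def _setup(self):
        ppi = PPINetwork.from_edges(
            [("R", "A", 0.99), ("A", "B", 0.99), ("B", "C", 0.99)]
        )
        net = build_subnetwork(ppi, {"A": 10.0, "B": 10.0, "C": 10.0}, ["R"], lam=0.2)
        ranking = select_and_weight(
            pd.Series({"d1": -0.9, "d2": -0.7, "d3": -0.6})
        )
        return net, ranking

    def test_drug_without_network_target_excluded(self):
        net, ranking = self._setup()
        targets = {"d1": {"A"}, "d2": {"ZZ"}, "d3": {"B", "QQ"}}
        filtered, in_net = filter_targeted_drugs(ranking, targets, net)
        assert filtered.selected == ["d1", "d3"]
        assert in_net["d3"] == frozenset({"B"})  # effective set is the overlap

    def test_ranks_frozen_after_target_filter(self):
        net, ranking = self._setup()
        targets = {"d1": {"ZZ"}, "d2": {"A"}, "d3": {"B"}}
        filtered, _ = filter_targeted_drugs(ranking, targets, net)
        # d1 (rank 1) dropped, yet d2 keeps rank 2 / weight frozen at n_d=3
        assert filtered.table.at["d2", "rank"] == 2
        assert filtered.weight("d2") == pytest.approx(1 + (1 - 2 / 3))
        # recomputing instead would give d2 rank 1 and weight ≈ 2 − 1/2
        recomputed = select_and_weight(pd.Series({"d2": -0.7, "d3": -0.6}))
        assert recomputed.weight("d2") != pytest.approx(filtered.weight("d2"))

    def test_synergy_arithmetic_symmetry_and_union(self):
        net, ranking = self._setup()
        ct = centrality_table(net.as_graph())
        targets = {"d1": frozenset({"A", "B"}), "d2": frozenset({"B", "C"})}
        s12 = synergy_score("d1", "d2", ranking, ct, targets)
        s21 = synergy_score("d2", "d1", ranking, ct, targets)
        assert s12 == pytest.approx(s21)
        w1, w2 = ranking.weight("d1"), ranking.weight("d2")
        union_cs = sum(ct.cs(t) for t in {"A", "B", "C"})  # shared B counted once
        assert s12 == pytest.approx(w1 * w2 * union_cs)

    def test_direct_worked_example(self):
        table = pd.DataFrame(
            {
                "betweenness": [0, 0],
                "closeness": [0, 0],
                "pagerank": [0, 0],
                "cs": [0.4, 0.6],
            },
            index=["T1", "T2"],
        )
        from netsynergy.synergy import CentralityTable

        ct = CentralityTable(table)
        ranking = select_and_weight(pd.Series({"i": -1.0, "j": -0.5}))
        assert ranking.weight("i") == pytest.approx(1.5)
        assert ranking.weight("j") == pytest.approx(1.0)
        s = synergy_score("i", "j", ranking, ct, {"i": frozenset({"T1"}), "j": frozenset({"T2"})})
        assert s == pytest.approx(1.5 * 1.0 * 1.0)

    def test_empty_combined_target_set_scores_zero(self):
        net, ranking = self._setup()
        ct = centrality_table(net.as_graph())
        assert synergy_score("d1", "d2", ranking, ct, {}) == 0.0

    def test_adding_central_target_strictly_increases_score(self):
        net, ranking = self._setup()
        ct = centrality_table(net.as_graph())
        base = {"d1": frozenset({"A"}), "d2": frozenset({"C"})}
        more = {"d1": frozenset({"A"}), "d2": frozenset({"C", "B"})}
        assert ct.cs("B") > 0
        assert synergy_score("d1", "d2", ranking, ct, more) > synergy_score(
            "d1", "d2", ranking, ct, base
        )


class TestCommunities:
    def _block_profiles(self, rng, n_per_block=10, n_genes=120, rho=0.95):
        base1 = rng.normal(size=n_genes)
        base2 = rng.normal(size=n_genes)
        cols = {}
        for i in range(n_per_block):
            cols[f"A{i:02d}"] = rho * base1 + np.sqrt(1 - rho**2) * rng.normal(size=n_genes)
        for i in range(n_per_block):
            cols[f"B{i:02d}"] = rho * base2 + np.sqrt(1 - rho**2) * rng.normal(size=n_genes)
        return DrugProfileSet(pd.DataFrame(cols, index=[f"G{i}" for i in range(n_genes)]))

    def test_identical_profiles_share_community(self, rng):
        z = rng.normal(size=60)
        profiles = DrugProfileSet(
            pd.DataFrame({"d1": z, "d2": z, "d3": -z}, index=[f"G{i}" for i in range(60)])
        )
        labels = drug_communities(profiles, seed=0)
        assert labels["d1"] == labels["d2"]

    def test_two_planted_blocks_recovered(self, rng):
        profiles = self._block_profiles(rng)
        labels = drug_communities(profiles, method="affinity", seed=0)
        a_labels = {labels[d] for d in profiles.drugs if d.startswith("A")}
        b_labels = {labels[d] for d in profiles.drugs if d.startswith("B")}
        assert len(a_labels) == 1
        assert len(b_labels) == 1
        assert a_labels != b_labels

    def test_affinity_and_pam_agree_on_separable_blocks(self, rng):
        profiles = self._block_profiles(rng)
        ap = drug_communities(profiles, method="affinity", seed=0)
        pam = drug_communities(profiles, method="pam", k=2)
        # identical partitions up to label renaming
        mapping = {}
        for d in profiles.drugs:
            mapping.setdefault(ap[d], set()).add(pam[d])
        assert all(len(v) == 1 for v in mapping.values())

    @pytest.mark.parametrize("method", ["hierarchical", "dbscan"])
    def test_alternative_methods_label_every_drug(self, rng, method):
        profiles = self._block_profiles(rng)
        labels = drug_communities(profiles, method=method, k=2, eps=0.5, min_samples=3)
        assert set(labels) == set(profiles.drugs)

    def test_constant_profile_gets_singleton_community(self, rng):
        z = rng.normal(size=(40, 3))
        z[:, 2] = 1.0
        profiles = DrugProfileSet(
            pd.DataFrame(z, index=[f"G{i}" for i in range(40)], columns=["d1", "d2", "flat"])
        )
        labels = drug_communities(profiles, seed=0)
        assert labels["flat"] not in {labels["d1"], labels["d2"]}

    def test_unknown_method_rejected(self, rng):
        profiles = self._block_profiles(rng, n_per_block=3)
        with pytest.raises(ValueError):
            drug_communities(profiles, method="kmeans")


class TestRankCombinations:
    def test_single_community_yields_no_pairs(self):
        scores = {("a", "b"): 2.0, ("a", "c"): 1.0, ("b", "c"): 3.0}
        assert rank_combinations(scores, {"a": 0, "b": 0, "c": 0}) == []

    def test_cross_community_ordering_example(self):
        scores = {("A", "B"): 2.0, ("A", "C"): 1.0, ("B", "C"): 9.0}
        preds = rank_combinations(scores, {"A": 0, "B": 1, "C": 1})
        assert [(p.drug_a, p.drug_b) for p in preds] == [("A", "B"), ("A", "C")]
        assert [p.rank for p in preds] == [1, 2]

    def test_zero_scores_suppressed_unless_kept(self):
        scores = {("A", "B"): 0.0}
        communities = {"A": 0, "B": 1}
        assert rank_combinations(scores, communities) == []
        kept = rank_combinations(scores, communities, keep_zero=True)
        assert len(kept) == 1

    def test_output_is_strict_total_order(self, rng):
        drugs = [f"d{i}" for i in range(12)]
        communities = {d: i % 3 for i, d in enumerate(drugs)}
        scores = {
            (a, b): float(rng.integers(0, 4))
            for a, b in itertools.combinations(drugs, 2)
        }
        preds = rank_combinations(scores, communities)
        pairs = [(p.drug_a, p.drug_b) for p in preds]
        assert len(pairs) == len(set(pairs))
        assert all(p.drug_a < p.drug_b for p in preds)
        assert [p.rank for p in preds] == list(range(1, len(preds) + 1))
        svals = [p.score for p in preds]
        assert svals == sorted(svals, reverse=True)
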