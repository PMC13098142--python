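"""Bipartite construction, Louvain communities, host-range grades, core
proteomes and ANI networks."""

from __future__ import annotations

import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from oracles import deepest_common_rank, partitions

from t6sscope.network import (TransferCommunity, ani_network, build_bipartite,
                              community_cross_tab, core_proteome,
                              detect_communities, host_range_grade,
                              replicon_projection)
from t6sscope.synthetic_data import simulate_hpc_table


def metadata_for(replicons, kind="plasmid", ptu="none", taxonomy=None):
    taxonomy = taxonomy or ("s", "g", "f", "o", "c")
    return pd.DataFrame([{
        "replicon_id": r, "kind": kind, "ptu": ptu,
        "species": taxonomy[0], "genus": taxonomy[1], "family": taxonomy[2],
        "order": taxonomy[3], "class": taxonomy[4]} for r in replicons])


class TestBuildBipartite:
    def test_shared_hpc_gives_path_of_length_two(self):
        table = pd.DataFrame({"protein_id": ["p1", "p2"],
                              "replicon_id": ["A", "B"],
                              "hpc_id": ["H1", "H1"]})
        graph = build_bipartite(table, metadata_for(["A", "B"]))
        assert nx.shortest_path_length(graph, "A", "B") == 2

    def test_protein_multiplicity_collapses_to_one_edge(self):
        table = pd.DataFrame({"protein_id": ["p1", "p2", "p3"],
                              "replicon_id": ["A", "A", "A"],
                              "hpc_id": ["H1", "H1", "H1"]})
        graph = build_bipartite(table, metadata_for(["A"]))
        assert graph.number_of_edges() == 1

    def test_hpc_degree_equals_distinct_replicon_count(self):
        rng = np.random.default_rng(0)
        replicons = [f"R{i}" for i in range(8)]
        rows = []
        for i in range(200):
            rows.append({"protein_id": f"p{i}",
                         "replicon_id": str(rng.choice(replicons)),
                         "hpc_id": f"H{int(rng.integers(0, 12))}"})
        table = pd.DataFrame(rows)
        graph = build_bipartite(table, metadata_for(replicons))
        for hpc in {r for r in graph if str(r).startswith("H")}:
            expected = table.loc[table["hpc_id"] == hpc, "replicon_id"].nunique()
            assert graph.degree(hpc) == expected

    def test_empty_table_empty_network(self):
        table = pd.DataFrame(columns=["protein_id", "replicon_id", "hpc_id"])
        graph = build_bipartite(table, metadata_for(["A"]))
        assert graph.number_of_edges() == 0

    def test_missing_metadata_rejected_with_id(self):
        table = pd.DataFrame({"protein_id": ["p1"], "replicon_id": ["ghost"],
                              "hpc_id": ["H1"]})
        with pytest.raises(ValueError, match="ghost"):
            build_bipartite(table, metadata_for(["A"]))


class TestCommunities:
    def test_two_disconnected_cliques_match_bruteforce_modularity(self):
        # two planted 4-replicon communities; brute-force over all partitions
        spec = {"c1": ([f"A{i}" for i in range(4)], 6),
                "c2": ([f"B{i}" for i in range(4)], 6)}
        table = simulate_hpc_table(spec, noise=0.0, seed=0)
        meta = metadata_for([f"A{i}" for i in range(4)] + [f"B{i}" for i in range(4)])
        graph = build_bipartite(table, meta)
        projection = replicon_projection(graph)
        best_q, best_partition = -1.0, None
        for part in partitions(sorted(projection.nodes)):
            q = nx.community.modularity(projection, part, weight="weight")
            if q > best_q:
                best_q, best_partition = q, part
        communities = detect_communities(graph, seed=1)
        got = {frozenset(c.members) for c in communities}
        assert got == {frozenset(p) for p in best_partition}
        assert len([c for c in communities if not c.is_singleton]) == 2

    def test_isolated_replicon_is_singleton(self):
        table = pd.DataFrame({"protein_id": ["p1", "p2"],
                              "replicon_id": ["A", "B"],
                              "hpc_id": ["H1", "H1"]})
        meta = metadata_for(["A", "B", "lonely"])
        graph = build_bipartite(table, meta)
        communities = detect_communities(graph, seed=0)
        singletons = [c for c in communities if c.is_singleton]
        assert any(c.members == ["lonely"] for c in singletons)

    def test_partition_covers_every_replicon_once(self):
        spec = {"c1": (["A", "B", "C"], 5), "c2": (["D", "E"], 5)}
        table = simulate_hpc_table(spec, noise=0.3, seed=2)
        meta = metadata_for(["A", "B", "C", "D", "E"])
        communities = detect_communities(build_bipartite(table, meta), seed=0)
        members = sorted(m for c in communities for m in c.members)
        assert members == ["A", "B", "C", "D", "E"]

    def test_modularity_at_least_singleton_partition(self):
        spec = {"c1": (["A", "B", "C", "D"], 4)}
        table = simulate_hpc_table(spec, noise=0.0, seed=3)
        graph = build_bipartite(table, metadata_for(["A", "B", "C", "D"]))
        projection = replicon_projection(graph)
        communities = detect_communities(graph, seed=0)
        q = nx.community.modularity(
            projection, [set(c.members) for c in communities], weight="weight")
        q_singletons = nx.community.modularity(
            projection, [{n} for n in projection.nodes], weight="weight")
        assert q >= q_singletons

    def test_planted_recovery_ari(self):
        from sklearn.metrics import adjusted_rand_score

        spec = {f"c{k}": ([f"R{k}_{i}" for i in range(5)], 8) for k in range(4)}
        truth = {r: k for k, (members, _) in spec.items() for r in members}
        for noise, floor in ((0.0, 1.0), (0.3, 0.9)):
            scores = []
            for seed in range(20):
                table = simulate_hpc_table(spec, noise=noise, seed=seed)
                meta = metadata_for(sorted(truth))
                communities = detect_communities(
                    build_bipartite(table, meta), seed=seed)
                label_of = {m: c.community_id for c in communities for m in c.members}
                keys = sorted(truth)
                scores.append(adjusted_rand_score(
                    [truth[k] for k in keys], [label_of[k] for k in keys]))
            assert np.mean(scores) >= floor


class TestHostRange:
    def test_same_species_grade_one(self):
        taxa = [("E. coli", "Escherichia", "Enterobacteriaceae", "Enterobacterales", "Gamma")] * 2
        assert host_range_grade(taxa) == "I"

    def test_same_genus_grade_two(self):
        taxa = [("E. coli", "Escherichia", "Enterobacteriaceae", "Enterobacterales", "Gamma"),
                ("E. albertii", "Escherichia", "Enterobacteriaceae", "Enterobacterales", "Gamma")]
        assert host_range_grade(taxa) == "II"

    def test_beyond_class_flagged(self):
        taxa = [("a", "b", "c", "d", "Gamma"), ("e", "f", "g", "h", "Alpha")]
        assert host_range_grade(taxa) == "beyond V"

    def test_matches_rank_walk_oracle(self):
        rng = np.random.default_rng(4)
        pools = [[f"{rank}{i}" for i in range(3)] for rank in "sgfoc"]
        grade_of = {"species": "I", "genus": "II", "family": "III",
                    "order": "IV", "class": "V", None: "beyond V"}
        for _ in range(200):
            taxa = [tuple(str(rng.choice(pool)) for pool in pools)
                    for _ in range(int(rng.integers(2, 5)))]
            assert host_range_grade(taxa) == grade_of[deepest_common_rank(taxa)]

    def test_order_invariant_and_monotone(self):
        base = [("s1", "g1", "f1", "o1", "c1"), ("s2", "g1", "f1", "o1", "c1")]
        grades = "I II III IV V".split()
        for perm in itertools.permutations(base):
            assert host_range_grade(list(perm)) == host_range_grade(base)
        wider = base + [("s3", "g2", "f1", "o1", "c1")]
        assert grades.index(host_range_grade(wider)) >= grades.index(
            host_range_grade(base))


class TestCoreProteome:
    @pytest.mark.parametrize("n_carrying,expected", [(8, True), (7, False), (10, True)])
    def test_eighty_percent_boundary(self, n_carrying, expected):
        replicons = [f"R{i}" for i in range(10)]
        rows = [{"protein_id": f"p{i}", "replicon_id": r, "hpc_id": "core"}
                for i, r in enumerate(replicons[:n_carrying])]
        rows += [{"protein_id": f"q{i}", "replicon_id": r, "hpc_id": f"priv{i}"}
                 for i, r in enumerate(replicons)]
        meta = metadata_for(replicons, ptu="PTU-X")
        graph = build_bipartite(pd.DataFrame(rows), meta)
        core = core_proteome(graph, "PTU-X", threshold=0.8)
        assert ("core" in core) is expected


class TestANINetwork:
    def test_coverage_threshold_inclusive(self):
        table = pd.DataFrame([
            {"query": "A", "subject": "B", "ani": 0.98, "coverage": 0.50},
            {"query": "A", "subject": "C", "ani": 0.99, "coverage": 0.49},
            {"query": "A", "subject": "A", "ani": 1.0, "coverage": 1.0},
        ])
        graph = ani_network(table, min_cov=0.5)
        assert graph.has_edge("A", "B")
        assert graph["A"]["B"]["weight"] == pytest.approx(0.98)
        assert not graph.has_edge("A", "C")
        assert not graph.has_edge("A", "A")

    def test_out_of_range_values_rejected(self):
        table = pd.DataFrame([{"query": "A", "subject": "B",
                               "ani": 1.2, "coverage": 0.6}])
        with pytest.raises(ValueError):
            ani_network(table)


class TestCrossTab:
    def test_mixed_community_links_ptu_to_chromosome(self):
        meta = pd.concat([
            metadata_for(["P1"], kind="plasmid", ptu="PTU-A"),
            metadata_for(["C1"], kind="chromosome"),
        ])
        table = pd.DataFrame({"protein_id": ["x", "y"],
                              "replicon_id": ["P1", "C1"], "hpc_id": ["H", "H"]})
        graph = build_bipartite(table, meta)
        communities = [TransferCommunity(0, ["P1", "C1"], "mixed")]
        cross, flags = community_cross_tab(communities, graph,
                                           {"P1": frozenset({"IS3"}),
                                            "C1": frozenset({"IS3"})})
        assert cross.iloc[0].tolist() == ["Chr", "PTU-A", 1]
        assert flags[0] is True

    def test_plasmid_only_community_no_chr_link(self):
        meta = metadata_for(["P1", "P2"], kind="plasmid", ptu="PTU-A")
        table = pd.DataFrame({"protein_id": ["x", "y"],
                              "replicon_id": ["P1", "P2"], "hpc_id": ["H", "H"]})
        graph = build_bipartite(table, meta)
        communities = [TransferCommunity(0, ["P1", "P2"], "plasmid_only")]
        cross, flags = community_cross_tab(communities, graph)
        assert "Chr" not in set(cross.get("entity_a", [])) | set(cross.get("entity_b", []))
        assert flags[0] is False

    def test_different_is_families_do_not_set_flag(self):
        meta = pd.concat([
            metadata_for(["P1"], kind="plasmid"),
            metadata_for(["C1"], kind="chromosome"),
        ])
        table = pd.DataFrame({"protein_id": ["x", "y"],
                              "replicon_id": ["P1", "C1"], "hpc_id": ["H", "H"]})
        graph = build_bipartite(table, meta)
        communities = [TransferCommunity(0, ["P1", "C1"], "mixed")]
        _, flags = community_cross_tab(communities, graph,
                                       {"P1": frozenset({"IS3"}),
                                        "C1": frozenset({"IS110"})})
        assert flags[0] is False
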