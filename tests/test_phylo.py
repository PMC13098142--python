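"""Patristic distances, ECDF/closest-homolog logic, co-resident comparison,
and the F81/MPPA ancestral reconstruction."""

from __future__ import annotations

import math

import dendropy
import numpy as np
import pandas as pd
import pytest

from oracles import exhaustive_marginals, patristic_lca_oracle

from t6sscope.phylo import (TipMetadata, ancestral_states, closest_homolog,
                            coresident_comparison, count_transitions, ecdf,
                            load_tree, patristic_matrix)
from t6sscope.synthetic_data import simulate_compartment_tree


def random_tree(rng, n_tips, scale=1.0):
    newick, _, _ = simulate_compartment_tree(
        n_tips=n_tips, branch_rate=1.0 / scale, switch_rate=0.0,
        seed=int(rng.integers(0, 2**31 - 1)))
    return load_tree(newick)


class TestPatristic:
    def test_two_tip_tree(self):
        dist = patristic_matrix(load_tree("(A:0.1,B:0.2);"))
        assert dist.loc["A", "B"] == pytest.approx(0.3)
        assert dist.loc["A", "A"] == 0.0

    def test_malformed_newick_rejected(self):
        with pytest.raises(ValueError, match="malformed newick"):
            load_tree("(A:0.1,B:0.2;")

    def test_matches_lca_path_oracle(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            tree = random_tree(rng, int(rng.integers(4, 10)))
            dist = patristic_matrix(tree)
            oracle = patristic_lca_oracle(tree)
            for (a, b), want in oracle.items():
                assert dist.loc[a, b] == pytest.approx(want, rel=1e-10)

    def test_ultrametric_tree_equidistant_through_root(self):
        tree = load_tree("((A:1,B:1):1,(C:1,D:1):1);")
        dist = patristic_matrix(tree)
        for a, b in (("A", "C"), ("A", "D"), ("B", "C"), ("B", "D")):
            assert dist.loc[a, b] == pytest.approx(4.0)

    def test_four_point_condition_spot_check(self):
        rng = np.random.default_rng(6)
        tree = random_tree(rng, 8)
        d = patristic_matrix(tree)
        tips = list(d.index)[:4]
        a, b, c, e = tips
        sums = sorted([d.loc[a, b] + d.loc[c, e],
                       d.loc[a, c] + d.loc[b, e],
                       d.loc[a, e] + d.loc[b, c]])
        assert sums[1] == pytest.approx(sums[2], rel=1e-9)


class TestClosestHomolog:
    def _fixture(self):
        tree = load_tree("((A:0.1,B:0.2):0.3,(C:0.4,D:0.1):0.2);")
        dist = patristic_matrix(tree)
        meta = TipMetadata(
            compartment={"A": "plasmid", "B": "plasmid",
                         "C": "chromosome", "D": "plasmid"})
        return dist, meta

    def test_minima_match_exhaustive_search(self):
        dist, meta = self._fixture()
        result = closest_homolog(dist, meta).per_tip.set_index("tip")
        for tip in ("A", "B", "D"):
            others_p = [t for t in dist.index
                        if meta.compartment[t] == "plasmid" and t != tip]
            assert result.loc[tip, "d_plasmid"] == pytest.approx(
                min(dist.loc[tip, o] for o in others_p))
            assert result.loc[tip, "d_chromosome"] == pytest.approx(dist.loc[tip, "C"])

    def test_identity_cluster_forces_zero(self):
        dist, meta = self._fixture()
        meta.identity_cluster = {"A": "hpc1", "D": "hpc1"}
        result = closest_homolog(dist, meta).per_tip.set_index("tip")
        assert result.loc["A", "d_plasmid"] == 0.0
        assert bool(result.loc["A", "zero_plasmid"])
        assert result.loc["B", "d_plasmid"] > 0.0

    def test_single_compartment_flagged_undefined(self):
        tree = load_tree("(A:0.1,B:0.2);")
        dist = patristic_matrix(tree)
        meta = TipMetadata(compartment={"A": "plasmid", "B": "plasmid"})
        result = closest_homolog(dist, meta)
        assert "chromosome" in result.undefined_compartments

    def test_ecdf_reaches_one_and_monotone(self):
        x, f = ecdf([0.3, 0.1, 0.5, 0.2])
        assert f[-1] == pytest.approx(1.0)
        assert (np.diff(f) >= 0).all()
        assert (np.diff(x) >= 0).all()


class TestCoresident:
    def test_coresident_at_least_global_minimum(self):
        rng = np.random.default_rng(7)
        tree = random_tree(rng, 12)
        dist = patristic_matrix(tree)
        tips = list(dist.index)
        compartment = {t: ("plasmid" if i % 2 else "chromosome")
                       for i, t in enumerate(tips)}
        host = {t: f"h{i // 2}" for i, t in enumerate(tips)}
        meta = TipMetadata(compartment=compartment, host=host)
        paired, _ = coresident_comparison(dist, meta)
        assert len(paired)
        assert (paired["coresident"] >= paired["global_closest"] - 1e-12).all()

    def test_no_dual_compartment_host_empty(self):
        tree = load_tree("(A:0.1,B:0.2);")
        dist = patristic_matrix(tree)
        meta = TipMetadata(compartment={"A": "plasmid", "B": "plasmid"},
                           host={"A": "h1", "B": "h2"})
        paired, p = coresident_comparison(dist, meta)
        assert paired.empty and p is None

    def test_planted_distant_coresidents_detected(self):
        # hosts whose co-resident plasmid homolog is a distant relative while
        # close non-resident homologs exist: the one-sided test should fire
        n_detect = 0
        n_seeds = 40
        for seed in range(n_seeds):
            rng = np.random.default_rng(300 + seed)
            blocks = []
            n_hosts = 25
            for h in range(n_hosts):
                # chromosome tip pairs with a *far* co-resident plasmid and a
                # near foreign plasmid
                blocks.append(
                    f"((chr{h}:0.01,near{h}:0.01):{1.0 + rng.random():.3f},far{h}:2.0)")
            newick = "(" + ",".join(blocks) + ");"
            tree = load_tree(newick)
            dist = patristic_matrix(tree)
            compartment, host = {}, {}
            for h in range(n_hosts):
                compartment[f"chr{h}"] = "chromosome"
                compartment[f"near{h}"] = "plasmid"
                compartment[f"far{h}"] = "plasmid"
                host[f"chr{h}"] = f"h{h}"
                host[f"far{h}"] = f"h{h}"    # co-resident is the far one
                host[f"near{h}"] = f"x{h}"
            meta = TipMetadata(compartment=compartment, host=host)
            _, p = coresident_comparison(dist, meta)
            if p is not None and p < 0.05:
                n_detect += 1
        assert n_detect >= 0.95 * n_seeds


class TestAncestralStates:
    def test_all_tips_one_state_every_node_that_state(self):
        tree = load_tree("((A:0.1,B:0.2):0.1,C:0.3);")
        rec = ancestral_states(tree, {t: "plasmid" for t in "ABC"},
                               pi=(0.5, 0.5))
        assert all(s == frozenset({"plasmid"}) for s in rec.mppa.values())

    def test_posteriors_normalized(self):
        rng = np.random.default_rng(8)
        tree = random_tree(rng, 7, scale=0.5)
        states = {leaf.taxon.label: ("plasmid" if i % 2 else "chromosome")
                  for i, leaf in enumerate(tree.leaf_node_iter())}
        rec = ancestral_states(tree, states)
        for post in rec.posteriors.values():
            assert sum(post.values()) == pytest.approx(1.0)

    def test_three_tip_tree_matches_exhaustive_enumeration(self):
        tree = load_tree("((A:0.13,B:0.41):0.27,C:0.09);")
        states = {"A": "plasmid", "B": "chromosome", "C": "chromosome"}
        pi = (0.35, 0.65)
        rec = ancestral_states(tree, states, pi=pi)
        marginals, _ = exhaustive_marginals(tree, states, pi)
        for node, want in marginals.items():
            got = rec.posteriors[node.ar_id]
            assert got["plasmid"] == pytest.approx(want[0], rel=1e-10)
            assert got["chromosome"] == pytest.approx(want[1], rel=1e-10)

    def test_random_trees_match_exhaustive_enumeration(self):
        rng = np.random.default_rng(9)
        for _ in range(20):
            tree = random_tree(rng, int(rng.integers(3, 9)), scale=0.7)
            states = {leaf.taxon.label: ("plasmid" if rng.random() < 0.5
                                         else "chromosome")
                      for leaf in tree.leaf_node_iter()}
            if len(set(states.values())) < 2:
                states[next(iter(states))] = "plasmid"
            pi = (0.4, 0.6)
            rec = ancestral_states(tree, states, pi=pi)
            marginals, total = exhaustive_marginals(tree, states, pi)
            assert rec.log_likelihood == pytest.approx(math.log(total), rel=1e-10)
            for node, want in marginals.items():
                assert rec.posteriors[node.ar_id]["plasmid"] == pytest.approx(
                    want[0], rel=1e-10, abs=1e-12)

    def test_zero_length_branch_pins_parent_state(self):
        # shorter branch to a plasmid tip -> more parent posterior on plasmid
        posts = []
        for t in (1e-9, 0.5, 2.0):
            tree = load_tree(f"((A:{t},B:0.5):0.2,C:0.5);")
            rec = ancestral_states(
                tree, {"A": "plasmid", "B": "chromosome", "C": "chromosome"},
                pi=(0.5, 0.5))
            parent = next(n for n in tree.preorder_node_iter()
                          if not n.is_leaf() and n.parent_node is not None)
            posts.append(rec.posteriors[parent.ar_id]["plasmid"])
        assert posts[0] > posts[1] > posts[2]

    def test_unidentifiable_zero_tree_rejected(self):
        tree = load_tree("(A:0.0,B:0.0);")
        with pytest.raises(ValueError, match="unidentifiable"):
            ancestral_states(tree, {"A": "plasmid", "B": "chromosome"},
                             pi=(0.5, 0.5))

    def test_equilibrium_from_tip_proportions(self):
        tree = load_tree("((A:0.1,B:0.1):0.1,(C:0.1,D:0.1):0.1);")
        rec = ancestral_states(tree, {"A": "plasmid", "B": "plasmid",
                                      "C": "plasmid", "D": "chromosome"})
        assert rec.pi["plasmid"] > rec.pi["chromosome"]

    def test_mppa_keeps_both_states_when_ambiguous(self):
        # symmetric tree, conflicting tips -> root posterior 0.5/0.5
        tree = load_tree("(A:0.3,B:0.3);")
        rec = ancestral_states(tree, {"A": "plasmid", "B": "chromosome"},
                               pi=(0.5, 0.5))
        root_id = next(n.ar_id for n in tree.preorder_node_iter()
                       if n.parent_node is None)
        assert rec.mppa[root_id] == frozenset({"plasmid", "chromosome"})


class TestTransitions:
    def test_single_switch_chain(self):
        tree = load_tree("((A:0.05,B:0.05):1.5,(C:0.05,D:0.05):0.05);")
        rec = ancestral_states(tree, {"A": "plasmid", "B": "plasmid",
                                      "C": "chromosome", "D": "chromosome"})
        counts = count_transitions(rec, tree)
        assert counts["chromosome->plasmid"] + counts["plasmid->chromosome"] >= 1

    def test_zero_switch_simulation_zero_events(self):
        newick, tips, truth = simulate_compartment_tree(
            30, switch_rate=0.0, seed=4, root_state="plasmid")
        assert set(tips.values()) == {"plasmid"}
        assert truth.planted_transitions == []
        tree = load_tree(newick)
        rec = ancestral_states(tree, tips, pi=(0.5, 0.5))
        counts = count_transitions(rec, tree)
        assert counts == {"plasmid->chromosome": 0, "chromosome->plasmid": 0}

    def test_ambiguous_branches_contribute_nothing(self):
        tree = load_tree("(A:0.3,B:0.3);")
        rec = ancestral_states(tree, {"A": "plasmid", "B": "chromosome"},
                               pi=(0.5, 0.5))
        counts = count_transitions(rec, tree)
        # the root keeps both states, so neither branch is a clean switch
        assert sum(counts.values()) == 0


class TestCompartmentTreeSimulation:
    def test_stationary_tip_fraction(self):
        # symmetric switching: long-run plasmid fraction 0.5
        fractions = []
        for seed in range(100):
            _, tips, _ = simulate_compartment_tree(
                50, branch_rate=2.0, switch_rate=3.0, seed=seed,
                root_state="chromosome")
            fractions.append(
                sum(s == "plasmid" for s in tips.values()) / len(tips))
        se = np.std(fractions, ddof=1) / np.sqrt(len(fractions))
        assert abs(np.mean(fractions) - 0.5) < 4 * se

    def test_determinism(self):
        a = simulate_compartment_tree(25, seed=11)
        b = simulate_compartment_tree(25, seed=11)
        assert a[0] == b[0] and a[1] == b[1]
        assert a[2].planted_transitions == b[2].planted_transitions

    def test_too_few_tips_rejected(self):
        with pytest.raises(ValueError):
            simulate_compartment_tree(1)
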