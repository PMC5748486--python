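"""Topology enumeration, compatibility scoring, search, newick output."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from conftest import presence_from_incidence
from crcith.matrix import MISSING
from crcith.phylo import (
    best_tree,
    canonicalize,
    count_rooted_trees,
    enumerate_rooted_trees,
    nni_neighbors,
    score_tree,
    to_newick,
    tree_leaves,
    _topology_newick,
)
from crcith.simulate import simulate_clone_phylogeny, simulate_cohort


def _inc(rows: dict[str, list[int]], samples: list[str]) -> pd.DataFrame:
    return pd.DataFrame(rows, index=samples).T.astype(bool)


class TestEnumeration:
    @pytest.mark.parametrize("n,count", [(2, 1), (3, 3), (4, 15), (5, 105), (6, 945)])
    def test_counts_and_uniqueness(self, n, count):
        labels = [f"S{i}" for i in range(n)]
        seen = {
            _topology_newick(canonicalize(t)) for t in enumerate_rooted_trees(labels)
        }
        assert len(seen) == count == count_rooted_trees(n)

    def test_double_factorial_closed_form(self):
        assert [count_rooted_trees(n) for n in range(2, 8)] == [
            1, 3, 15, 105, 945, 10395,
        ]

    def test_limit_directs_to_heuristic(self):
        with pytest.raises(ValueError, match="hill_climb"):
            list(enumerate_rooted_trees([f"S{i}" for i in range(12)]))


class TestScoring:
    samples = ["A", "B", "C"]

    def _presence(self):
        return presence_from_incidence(
            _inc({"m1": [1, 1, 1], "m2": [1, 1, 0], "m3": [1, 0, 0]}, self.samples)
        )

    def test_nested_mutations_score_three_on_matching_tree(self):
        score, assignment, homoplasies = score_tree((("A", "B"), "C"), self._presence())
        assert score == 3
        assert homoplasies == []
        support = {clade: len(m) for clade, m in assignment.items()}
        assert support[frozenset("ABC")] == 1  # trunk: m1
        assert support[frozenset("AB")] == 1   # m2
        assert support[frozenset("A")] == 1    # m3

    def test_incompatible_mutation_detected(self):
        score, _, homoplasies = score_tree((("A", "C"), "B"), self._presence())
        assert score == 2
        assert homoplasies == ["m2"]

    def test_matching_tree_is_the_enumeration_optimum(self):
        pm = self._presence()
        scores = {
            _topology_newick(canonicalize(t)): score_tree(t, pm)[0]
            for t in enumerate_rooted_trees(self.samples)
        }
        assert max(scores.values()) == 3
        assert scores["((A,B),C)"] == 3

    def test_universal_mutation_always_on_trunk(self):
        pm = presence_from_incidence(_inc({"m1": [1, 1, 1]}, self.samples))
        for t in enumerate_rooted_trees(self.samples):
            score, assignment, _ = score_tree(t, pm)
            assert score == 1
            assert assignment[frozenset("ABC")] == ["m1"]

    def test_missing_cells_relax_compatibility(self):
        pm = presence_from_incidence(
            _inc({"m1": [1, 1, 0], "m2": [1, 0, 1]}, self.samples)
        )
        states = pm.states.copy()
        states.at["m2", "B"] = MISSING  # m2 = {A, C}, B unknown
        pm.states = states
        # on ((A,B),C): m2's carriers {A,C} only fit the trunk, which its
        # explicit non-carriers would forbid -- but B is missing, not absent
        score, assignment, homoplasies = score_tree((("A", "B"), "C"), pm)
        assert score == 2
        assert "m2" in assignment[frozenset("ABC")]

    def test_no_carrier_mutation_skipped_with_warning(self):
        pm = presence_from_incidence(_inc({"m1": [0, 0, 0], "m2": [1, 1, 1]}, self.samples))
        with pytest.warns(UserWarning, match="no carriers"):
            score, _, _ = score_tree((("A", "B"), "C"), pm)
        assert score == 1


class TestBestTree:
    def test_two_samples_forced_shape(self):
        pm = presence_from_incidence(
            _inc({"m1": [1, 1], "m2": [1, 1], "m3": [1, 0], "m4": [0, 1], "m5": [0, 1]},
                 ["A", "B"])
        )
        bt = best_tree(pm)
        assert bt.topology == ("A", "B")
        assert bt.edge_support[frozenset("AB")] == 2
        assert bt.edge_support[frozenset("A")] == 1
        assert bt.edge_support[frozenset("B")] == 2
        assert to_newick(bt) == "(A:1,B:2):2;"

    def test_laminar_matrix_recovered_exactly(self):
        samples = ["A", "B", "C", "D"]
        pm = presence_from_incidence(
            _inc(
                {
                    "m1": [1, 1, 1, 1],
                    "m2": [1, 1, 0, 0],
                    "m3": [0, 0, 1, 1],
                    "m4": [1, 0, 0, 0],
                    "m5": [0, 0, 0, 1],
                },
                samples,
            )
        )
        bt = best_tree(pm)
        assert bt.score == 5 == bt.n_characters
        assert bt.homoplasies == ()
        assert bt.supported_clades() == {
            frozenset("ABCD"): 1,
            frozenset("AB"): 1,
            frozenset("CD"): 1,
            frozenset("A"): 1,
            frozenset("D"): 1,
        }

    def test_branch_length_sum_bounded_by_characters(self):
        rng = np.random.default_rng(5)
        samples = [f"S{i}" for i in range(5)]
        for _ in range(10):
            inc = pd.DataFrame(
                rng.random((12, 5)) < 0.4, index=[f"m{i}" for i in range(12)],
                columns=samples,
            )
            inc = inc[inc.any(axis=1)]
            bt = best_tree(presence_from_incidence(inc))
            assert sum(bt.edge_support.values()) == bt.score <= len(inc)
            assert len(bt.homoplasies) == len(inc) - bt.score

    def test_hill_climb_never_beats_exhaustive(self):
        rng = np.random.default_rng(11)
        samples = [f"S{i}" for i in range(5)]
        for k in range(10):
            inc = pd.DataFrame(
                rng.random((15, 5)) < 0.35, index=[f"m{i}" for i in range(15)],
                columns=samples,
            )
            inc = inc[inc.any(axis=1)]
            pm = presence_from_incidence(inc)
            exact = best_tree(pm, method="exhaustive")
            heur = best_tree(pm, method="hill_climb", seed=k, restarts=5)
            assert heur.score <= exact.score

    def test_hill_climb_deterministic_given_seed(self):
        rng = np.random.default_rng(3)
        inc = pd.DataFrame(
            rng.random((20, 7)) < 0.4,
            index=[f"m{i}" for i in range(20)],
            columns=[f"S{i}" for i in range(7)],
        )
        inc = inc[inc.any(axis=1)]
        pm = presence_from_incidence(inc)
        a = best_tree(pm, method="hill_climb", seed=9)
        b = best_tree(pm, method="hill_climb", seed=9)
        assert to_newick(a) == to_newick(b)

    def test_exhaustive_above_limit_rejected(self):
        rng = np.random.default_rng(0)
        inc = pd.DataFrame(
            rng.random((5, 6)) < 0.5, index=[f"m{i}" for i in range(5)],
            columns=[f"S{i}" for i in range(6)],
        )
        inc.iloc[0] = True
        pm = presence_from_incidence(inc)
        with pytest.raises(ValueError, match="hill_climb"):
            best_tree(pm, method="exhaustive", exhaustive_limit=4)

    def test_auto_falls_back_to_hill_climb(self, caplog):
        import logging

        rng = np.random.default_rng(0)
        inc = pd.DataFrame(
            rng.random((8, 6)) < 0.5, index=[f"m{i}" for i in range(8)],
            columns=[f"S{i}" for i in range(6)],
        )
        inc.iloc[0] = True
        pm = presence_from_incidence(inc)
        with caplog.at_level(logging.INFO, logger="crcith.phylo"):
            bt = best_tree(pm, method="auto", exhaustive_limit=4)
        assert bt.method == "hill_climb"
        assert any("falling back" in r.message for r in caplog.records)

    def test_duplicate_character_never_decreases_score(self):
        samples = ["A", "B", "C", "D"]
        inc = _inc({"m1": [1, 1, 1, 1], "m2": [1, 1, 0, 0], "m3": [1, 0, 1, 0]}, samples)
        base = best_tree(presence_from_incidence(inc)).score
        inc2 = pd.concat([inc, inc.loc[["m2"]].rename(index={"m2": "m2b"})])
        extended = best_tree(presence_from_incidence(inc2)).score
        assert extended >= base + 1

    def test_perfect_phylogeny_simulation_recovered(self):
        """Noise-free deep-coverage simulation: the sample tree and its branch
        supports equal the simulated clone structure."""
        from crcith.matrix import call_presence, classify_sharing
        from crcith.simulate import (
            SampleSpec,
            SamplingDesign,
            assign_mutations,
            simulate_read_counts,
        )

        tree = simulate_clone_phylogeny(6, seed=17)
        asg = assign_mutations(tree, n_truncal=25, n_per_branch=10, seed=18)
        samples = [
            SampleSpec(f"X{i}", "biopsy", f"T{i}", 0.8, {f"C{i}": 1.0})
            for i in range(6)
        ]
        design = SamplingDesign(samples=samples, mean_depth=300,
                                depth_dispersion=40.0, error_rate=0.0)
        counts, truth = simulate_read_counts(tree, asg, design, seed=19)
        pm = classify_sharing(call_presence(counts))
        bt = best_tree(pm)
        assert bt.score == bt.n_characters == 75
        assert bt.homoplasies == ()
        assert bt.supported_clades() == truth.sample_carrier_sets()


class TestNewick:
    def test_canonical_child_order(self):
        assert canonicalize((("C", "B"), "A")) == ("A", ("B", "C"))

    def test_round_trip_against_dendropy(self):
        """Newick output re-parses (via dendropy) to the same topology and
        branch lengths."""
        import dendropy

        rng = np.random.default_rng(7)
        samples = [f"S{i}" for i in range(6)]
        inc = pd.DataFrame(
            rng.random((25, 6)) < 0.45, index=[f"m{i}" for i in range(25)],
            columns=samples,
        )
        inc.iloc[0] = True
        inc = inc[inc.any(axis=1)]
        bt = best_tree(presence_from_incidence(inc))
        parsed = dendropy.Tree.get(data=to_newick(bt), schema="newick")
        clades = {}
        for node in parsed.preorder_node_iter():
            leaves = frozenset(l.taxon.label for l in node.leaf_iter())
            clades[leaves] = int(node.edge.length or 0)
        assert {c: s for c, s in bt.edge_support.items() if s} == {
            c: s for c, s in clades.items() if s
        }

    def test_nni_neighbors_preserve_leaves(self):
        tree = ((("A", "B"), "C"), ("D", "E"))
        for nb in nni_neighbors(tree):
            assert tree_leaves(nb) == tree_leaves(tree)
        assert len(nni_neighbors(tree)) > 0
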