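"""Distances, clustering, concordance, clone blocks, purity, rank tests."""

from __future__ import annotations

import math
from itertools import combinations, product

import numpy as np
import pandas as pd
import pytest

from conftest import presence_from_incidence
from crcith.matrix import MISSING, call_presence, classify_sharing
from crcith.phylo import best_tree
from crcith.simulate import simulate_cohort
from crcith.stats import (
    BlockPattern,
    average_linkage,
    binary_distance_matrix,
    clone_blocks,
    concordance_stats,
    matched_pair_distance_test,
    purity_from_af,
    rank_sum_test,
    signed_rank_test,
    tree_path_distance,
)


def _inc(rows: dict[str, list[int]], samples: list[str]) -> pd.DataFrame:
    return pd.DataFrame(rows, index=samples).T.astype(bool)


class TestBinaryDistance:
    def test_identical_rows_zero(self):
        pm = presence_from_incidence(_inc({"m1": [1, 1], "m2": [0, 0], "m3": [1, 1]}, ["A", "B"]))
        assert binary_distance_matrix(pm).loc["A", "B"] == 0.0

    def test_mismatch_over_union(self):
        pm = presence_from_incidence(
            _inc({"m1": [1, 1], "m2": [1, 0], "m3": [0, 1]}, ["A", "B"])
        )
        assert binary_distance_matrix(pm).loc["A", "B"] == pytest.approx(2 / 3)

    def test_disjoint_support_distance_one(self):
        pm = presence_from_incidence(
            _inc({"m1": [1, 0], "m2": [0, 1], "m3": [0, 1]}, ["A", "B"])
        )
        assert binary_distance_matrix(pm).loc["A", "B"] == pytest.approx(1.0)

    def test_joint_absences_ignored(self):
        with_absences = presence_from_incidence(
            _inc({"m1": [1, 0], "m2": [0, 1], "m3": [0, 0], "m4": [0, 0]}, ["A", "B"])
        )
        assert binary_distance_matrix(with_absences).loc["A", "B"] == 1.0

    def test_no_joint_observation_warns_nan(self):
        pm = presence_from_incidence(_inc({"m1": [1, 1], "m2": [1, 1]}, ["A", "B"]))
        states = pm.states.copy()
        states.loc["m1", "A"] = MISSING
        states.loc["m2", "B"] = MISSING
        pm.states = states
        with pytest.warns(UserWarning, match="no observed"):
            dist = binary_distance_matrix(pm)
        assert math.isnan(dist.loc["A", "B"])


class TestAverageLinkage:
    def test_hand_traced_merge_order(self):
        dist = pd.DataFrame(
            [[0.0, 0.1, 0.8], [0.1, 0.0, 0.8], [0.8, 0.8, 0.0]],
            index=["A", "B", "C"], columns=["A", "B", "C"],
        )
        link = average_linkage(dist)
        assert link.merges[0][2] == pytest.approx(0.1)
        assert link.merges[1][2] == pytest.approx(0.8)
        assert frozenset(("A", "B")) in link.pair_clusters()

    def test_tied_distances_merge_at_equal_heights(self):
        dist = pd.DataFrame(0.5, index=list("ABCD"), columns=list("ABCD"))
        np.fill_diagonal(dist.to_numpy(), 0.0)  # no-op on a copy; set explicitly
        for s in "ABCD":
            dist.loc[s, s] = 0.0
        link = average_linkage(dist)
        assert np.allclose(link.merges[:, 2], 0.5)

    def test_missing_distance_rejected(self):
        dist = pd.DataFrame(
            [[0.0, np.nan], [np.nan, 0.0]], index=["A", "B"], columns=["A", "B"]
        )
        with pytest.raises(ValueError, match="missing"):
            average_linkage(dist)

    def test_matched_pairs_merge_before_cross_area(self):
        cohort = simulate_cohort(seed=31)
        pm = classify_sharing(call_presence(cohort.counts))
        link = average_linkage(binary_distance_matrix(pm))
        pairs = link.pair_clusters()
        for region in ("T1", "T2", "T3"):
            assert frozenset((f"{region}_B", f"{region}_S")) in pairs


class TestConcordance:
    samples = ["A1_B", "A1_S", "A2_B", "A2_S"]

    def test_identical_pair_full_concordance(self):
        pm = presence_from_incidence(
            _inc({"m1": [1, 1, 0, 0], "m2": [1, 1, 1, 1]}, self.samples)
        )
        rep = concordance_stats(pm, {"A1": ("A1_B", "A1_S")})
        row = rep.per_area.iloc[0]
        assert row["concordant_frac"] == 1.0
        assert row["tumor_only"] == row["spheroid_only"] == 0

    def test_toy_set_arithmetic(self):
        """Biopsy {m1,m2,m3}, spheroid {m1,m2,m4}, other samples {m1}:
        concordant 2/4, each side private 1/4; m3 and m4 cohort-private;
        m2 is pairwise-private (in both pair members and nowhere else)."""
        pm = presence_from_incidence(
            _inc(
                {
                    "m1": [1, 1, 1, 1],
                    "m2": [1, 1, 0, 0],
                    "m3": [1, 0, 0, 0],
                    "m4": [0, 1, 0, 0],
                },
                self.samples,
            )
        )
        rep = concordance_stats(pm, {"A1": ("A1_B", "A1_S")})
        row = rep.per_area.iloc[0]
        assert row["n_union"] == 4
        assert row["concordant_frac"] == pytest.approx(0.5)
        assert row["tumor_only_frac"] == pytest.approx(0.25)
        assert row["spheroid_only_frac"] == pytest.approx(0.25)
        assert row["pairwise_private"] == 1  # m2
        private = rep.per_sample.set_index("sample")["n_private"]
        assert private["A1_B"] == 1 and private["A1_S"] == 1

    def test_pairwise_private_definition(self):
        pm = presence_from_incidence(
            _inc({"m1": [1, 1, 1, 1], "m5": [0, 0, 1, 1]}, self.samples)
        )
        rep = concordance_stats(
            pm, {"A1": ("A1_B", "A1_S"), "A2": ("A2_B", "A2_S")}
        )
        a2 = rep.per_area.set_index("area").loc["A2"]
        assert a2["pairwise_private"] == 1

    def test_fractions_sum_to_one(self):
        rng = np.random.default_rng(2)
        inc = pd.DataFrame(
            rng.random((30, 4)) < 0.5, index=[f"m{i}" for i in range(30)],
            columns=self.samples,
        )
        pm = presence_from_incidence(inc[inc.any(axis=1)])
        rep = concordance_stats(pm, {"A1": ("A1_B", "A1_S"), "A2": ("A2_B", "A2_S")})
        sums = (
            rep.per_area["concordant_frac"]
            + rep.per_area["tumor_only_frac"]
            + rep.per_area["spheroid_only_frac"]
        )
        assert np.allclose(sums, 1.0)

    def test_missing_member_skipped_with_warning(self):
        pm = presence_from_incidence(_inc({"m1": [1, 1, 1, 1]}, self.samples))
        with pytest.warns(UserWarning, match="skipped"):
            rep = concordance_stats(
                pm, {"A1": ("A1_B", "A1_S"), "A9": ("A9_B", "A9_S")}
            )
        assert list(rep.per_area["area"]) == ["A1"]


class TestCloneBlocks:
    def test_empty_pattern_matches_everything(self):
        pm = presence_from_incidence(
            _inc({"m1": [1, 0], "m2": [0, 1]}, ["A", "B"])
        )
        blocks = clone_blocks(pm, {"all": BlockPattern()})
        assert set(blocks["all"]) == {"m1", "m2"}

    def test_unknown_sample_rejected(self):
        pm = presence_from_incidence(_inc({"m1": [1, 0]}, ["A", "B"]))
        with pytest.raises(ValueError, match="unknown samples"):
            clone_blocks(pm, {"bad": BlockPattern(present_in_all=frozenset(["Z"]))})

    def test_lnm_seeding_blocks_recovered_from_truth(self):
        """Metastatic and nonmetastatic presence patterns isolate exactly the
        mutations of the seeding and non-seeding clone branches."""
        cohort = simulate_cohort(seed=41, n_lnm=3, error_rate=0.0,
                                 mean_depth=400, depth_dispersion=40.0)
        pm = classify_sharing(call_presence(cohort.counts))
        lnms = [f"L{j}" for j in (1, 2, 3)]
        tumors = [f"T{i}_B" for i in (1, 2, 3)] + [f"T{i}_S" for i in (1, 2, 3)]
        blocks = clone_blocks(
            pm,
            {
                "metastatic": BlockPattern(
                    present_in_all=frozenset(lnms + ["T2_B"]),
                    absent_in_all=frozenset(["T1_B", "T3_B"]),
                ),
                "nonmetastatic": BlockPattern(
                    present_in_all=frozenset(tumors),
                    absent_in_all=frozenset(lnms),
                ),
            },
        )
        truth_blocks = cohort.truth.branch_blocks()
        assert set(blocks["metastatic"]) == set(truth_blocks["MET"])
        assert set(blocks["nonmetastatic"]) == set(truth_blocks["NONMET"])


class TestPurity:
    def test_closed_form(self):
        af = pd.DataFrame({"X": [0.25, 0.25, 0.25, 0.24, 0.26]},
                          index=[f"m{i}" for i in range(5)])
        est = purity_from_af(af, list(af.index))
        assert est["X"] == pytest.approx(0.5)

    def test_clipped_at_one(self):
        af = pd.DataFrame({"X": [0.6, 0.6, 0.61]}, index=["m1", "m2", "m3"])
        assert purity_from_af(af, ["m1", "m2", "m3"])["X"] == 1.0

    def test_too_few_truncal_missing_with_warning(self):
        af = pd.DataFrame({"X": [0.3, np.nan, np.nan]}, index=["m1", "m2", "m3"])
        with pytest.warns(UserWarning, match="purity estimate missing"):
            est = purity_from_af(af, ["m1", "m2", "m3"])
        assert math.isnan(est["X"])

    def test_unbiased_at_saturating_depth(self):
        """Median estimate over many replicates is within 0.02 of truth when
        depth is effectively infinite."""
        from crcith.simulate import (
            SampleSpec,
            SamplingDesign,
            assign_mutations,
            simulate_clone_phylogeny,
            simulate_read_counts,
        )
        from crcith.matrix import _af_frame

        tree = simulate_clone_phylogeny(1)
        asg = assign_mutations(tree, n_truncal=60, n_per_branch=0, seed=0)
        errors = []
        for p in (0.3, 0.6, 0.9):
            estimates = []
            for seed in range(40):
                design = SamplingDesign(
                    samples=[SampleSpec("X", "biopsy", "T1", p, {"C0": 1.0})],
                    mean_depth=10_000, depth_dispersion=50.0, error_rate=0.0,
                )
                counts, _ = simulate_read_counts(tree, asg, design, seed=seed)
                af = _af_frame(counts.ref[["X"]], counts.alt[["X"]])
                estimates.append(purity_from_af(af, list(af.index))["X"])
            errors.append(abs(float(np.median(estimates)) - p))
        assert max(errors) <= 0.02


class TestRankTests:
    def test_identical_groups_p_one(self):
        with pytest.warns(UserWarning, match="identical"):
            res = rank_sum_test([1.0, 1.0], [1.0, 1.0])
        assert res.pvalue == 1.0

    def test_exact_small_sample_value(self):
        """a=(1,2), b=(3,4): 1 of C(4,2)=6 assignments is as extreme,
        two-sided doubles the tail: p = 1/3."""
        res = rank_sum_test([1.0, 2.0], [3.0, 4.0])
        assert res.method == "exact"
        assert res.pvalue == pytest.approx(1 / 3)

    def test_signed_rank_all_zero_differences(self):
        with pytest.warns(UserWarning, match="zero"):
            res = signed_rank_test([1.0, 2.0], [1.0, 2.0])
        assert res.pvalue == 1.0

    def test_signed_rank_exact_small_sample(self):
        """Differences (+1,+2,+3): one of 2^3 sign patterns reaches W=6;
        two-sided p = 2/8 = 0.25."""
        res = signed_rank_test([2.0, 4.0, 6.0], [1.0, 2.0, 3.0])
        assert res.method == "exact"
        assert res.pvalue == pytest.approx(0.25)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            rank_sum_test([], [1.0])
        with pytest.raises(ValueError):
            signed_rank_test([1.0], [1.0, 2.0])


class TestTreeDistance:
    def test_path_length_sums_edge_supports(self):
        pm = presence_from_incidence(
            _inc(
                {
                    "m1": [1, 1, 1], "m2": [1, 1, 1],
                    "m3": [1, 1, 0], "m4": [1, 0, 0], "m5": [0, 0, 1],
                },
                ["A", "B", "C"],
            )
        )
        bt = best_tree(pm)
        # A and B differ by A's private m4 only; trunk and AB edge are shared
        assert tree_path_distance(bt, "A", "B") == 1
        # A vs C crosses the AB edge (m3), A's private (m4), C's private (m5)
        assert tree_path_distance(bt, "A", "C") == 3

    def test_matched_pairs_closer_than_cross_area(self):
        cohort = simulate_cohort(seed=51)
        pm = classify_sharing(call_presence(cohort.counts))
        bt = best_tree(pm)
        pairing = {r: (f"{r}_B", f"{r}_S") for r in ("T1", "T2", "T3")}
        matched, cross, res = matched_pair_distance_test(bt, pairing)
        assert len(matched) == 3 and len(cross) == 12
        assert max(matched) < min(cross)
        assert res.pvalue < 0.05
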