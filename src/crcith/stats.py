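"""Heterogeneity statistics: clustering, concordance, clone blocks, purity.

Implements the cohort-level descriptive and inferential statistics of the
multi-region design: binary (Jaccard-mismatch) sample distances with
average-linkage clustering for heatmap ordering, biopsy/spheroid concordance
and private-mutation fractions, presence-pattern clone blocks (metastatic vs
nonmetastatic mutation sets), a median-AF purity estimator under diploid
heterozygosity, and the two nonparametric tests used on them (Wilcoxon rank
sum for matched-pair vs cross-area tree distances, Wilcoxon signed rank for
paired spheroid-vs-biopsy purity).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import squareform

from .matrix import ABSENT, MISSING, PRESENT, PresenceMatrix
from .phylo import PhyloTree

__all__ = [
    "binary_distance_matrix",
    "average_linkage",
    "LinkageResult",
    "concordance_stats",
    "ConcordanceReport",
    "BlockPattern",
    "clone_blocks",
    "purity_from_af",
    "rank_sum_test",
    "signed_rank_test",
    "RankTestResult",
    "tree_path_distance",
    "matched_pair_distance_test",
]


# ---------------------------------------------------------------------------
# Binary distance and clustering
# ---------------------------------------------------------------------------


def binary_distance_matrix(presence: PresenceMatrix) -> pd.DataFrame:
    """Pairwise Jaccard-mismatch distance between samples.

    d(x, y) = (#mutations called in exactly one) / (#called in at least one),
    over mutations where both samples are non-missing; joint absences are
    ignored, matching the 'binary' distance of standard statistical software.
    Identical rows give 0; a pair with no jointly observed mutation gets NaN
    with a warning.
    """
    samples = presence.samples
    if len(samples) < 2:
        raise ValueError("distance matrix needs at least 2 samples")
    states = presence.states
    dist = pd.DataFrame(0.0, index=samples, columns=samples)
    for x, y in combinations(samples, 2):
        both = (states[x] != MISSING) & (states[y] != MISSING)
        if not both.any():
            warnings.warn(f"samples {x!r} and {y!r} share no observed mutations")
            dist.loc[x, y] = dist.loc[y, x] = np.nan
            continue
        px = (states.loc[both, x] == PRESENT).to_numpy()
        py = (states.loc[both, y] == PRESENT).to_numpy()
        union = int(np.logical_or(px, py).sum())
        diff = int((px != py).sum())
        d = diff / union if union else 0.0
        dist.loc[x, y] = dist.loc[y, x] = d
    return dist


@dataclass
class LinkageResult:
    """Average-linkage dendrogram: scipy merge matrix plus leaf order."""

    merges: np.ndarray  # scipy linkage matrix
    labels: tuple[str, ...]
    leaf_order: tuple[str, ...]

    def pair_clusters(self) -> set[frozenset]:
        """Leaf pairs merged directly as singletons (tight two-sample clades)."""
        n = len(self.labels)
        out = set()
        for a, b, _, _ in self.merges:
            if a < n and b < n:
                out.add(frozenset((self.labels[int(a)], self.labels[int(b)])))
        return out


def average_linkage(dist: pd.DataFrame) -> LinkageResult:
    """Agglomerative clustering with unweighted average (UPGMA-style) linkage."""
    if dist.isna().to_numpy().any():
        raise ValueError("distance matrix contains missing entries")
    labels = tuple(dist.index)
    Z = linkage(squareform(dist.to_numpy(), checks=False), method="average")
    order = tuple(labels[i] for i in leaves_list(Z))
    return LinkageResult(merges=Z, labels=labels, leaf_order=order)


# ---------------------------------------------------------------------------
# Biopsy/spheroid concordance
# ---------------------------------------------------------------------------


@dataclass
class ConcordanceReport:
    """Per-area concordance and cohort private-mutation fractions.

    ``per_area`` rows: area, biopsy, spheroid, n_union, concordant,
    tumor_only, spheroid_only, the matching fractions (summing to 1 over the
    pair's union), and pairwise-private counts/fractions.  ``per_sample``
    rows: sample, n_present, n_private, private_fraction.
    """

    per_area: pd.DataFrame
    per_sample: pd.DataFrame
    coding_only: bool


def concordance_stats(
    presence: PresenceMatrix,
    pairing: Mapping[str, tuple[str, str]],
    coding_only: bool = False,
) -> ConcordanceReport:
    """Concordant / biopsy-only / spheroid-only fractions per matched area.

    For each area, fractions are over the union of mutations called in the
    biopsy or spheroid of that area.  Pairwise-private mutations are called
    in both members of one area and in no other sample; private mutations are
    called in exactly one sample cohort-wide.  ``coding_only`` restricts to
    coding point mutations (silent, missense and nonsense all count).
    """
    if not pairing:
        raise ValueError("pairing must cover at least one area")
    inc = presence.incidence()
    if coding_only:
        coding = presence.mutations["coding_class"].isin(
            ("silent", "missense", "nonsense")
        )
        inc = inc.loc[coding]

    carrier_count = inc.sum(axis=1)
    samples = presence.samples

    area_rows = []
    for area, members in pairing.items():
        biopsy, spheroid = members
        if biopsy not in samples or spheroid not in samples:
            warnings.warn(f"area {area!r}: member missing from matrix; skipped")
            continue
        b, s = inc[biopsy], inc[spheroid]
        union = b | s
        n_union = int(union.sum())
        concordant = int((b & s).sum())
        tumor_only = int((b & ~s).sum())
        spheroid_only = int((~b & s).sum())
        pairwise_private = int(((b & s) & (carrier_count == 2)).sum())
        area_rows.append(
            {
                "area": area,
                "biopsy": biopsy,
                "spheroid": spheroid,
                "n_union": n_union,
                "concordant": concordant,
                "tumor_only": tumor_only,
                "spheroid_only": spheroid_only,
                "concordant_frac": concordant / n_union if n_union else 0.0,
                "tumor_only_frac": tumor_only / n_union if n_union else 0.0,
                "spheroid_only_frac": spheroid_only / n_union if n_union else 0.0,
                "pairwise_private": pairwise_private,
                "pairwise_private_frac": pairwise_private / n_union if n_union else 0.0,
            }
        )
    if not area_rows:
        raise ValueError("no usable areas in pairing")

    sample_rows = []
    for sample in samples:
        n_present = int(inc[sample].sum())
        n_private = int((inc[sample] & (carrier_count == 1)).sum())
        sample_rows.append(
            {
                "sample": sample,
                "n_present": n_present,
                "n_private": n_private,
                "private_fraction": n_private / n_present if n_present else 0.0,
            }
        )
    return ConcordanceReport(
        per_area=pd.DataFrame(area_rows),
        per_sample=pd.DataFrame(sample_rows),
        coding_only=coding_only,
    )


# ---------------------------------------------------------------------------
# Clone blocks (presence-pattern mutation sets)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BlockPattern:
    """A sample-subset presence pattern: called in all of ``present_in_all``,
    explicitly absent in all of ``absent_in_all``, unconstrained elsewhere."""

    present_in_all: frozenset[str] = frozenset()
    absent_in_all: frozenset[str] = frozenset()


def clone_blocks(
    presence: PresenceMatrix,
    patterns: Mapping[str, BlockPattern],
) -> dict[str, tuple[str, ...]]:
    """Mutation sets matching named presence/absence patterns.

    Used to isolate clone-level blocks, e.g. the metastatic block (present in
    all lymph-node metastases and the seeding tumor region, absent in the
    other regions) or the nonmetastatic block (present in all tumor samples,
    absent in all LNMs).  Missing cells satisfy neither requirement.
    """
    samples = set(presence.samples)
    out: dict[str, tuple[str, ...]] = {}
    states = presence.states
    for name, pat in patterns.items():
        unknown = (set(pat.present_in_all) | set(pat.absent_in_all)) - samples
        if unknown:
            raise ValueError(f"pattern {name!r} references unknown samples {sorted(unknown)}")
        mask = pd.Series(True, index=states.index)
        for s in pat.present_in_all:
            mask &= states[s] == PRESENT
        for s in pat.absent_in_all:
            mask &= states[s] == ABSENT
        out[name] = tuple(states.index[mask])
    return out


# ---------------------------------------------------------------------------
# Purity from allele fractions
# ---------------------------------------------------------------------------


def purity_from_af(
    af: pd.DataFrame,
    truncal_ids: Sequence[str],
    min_truncal: int = 3,
) -> pd.Series:
    """Per-sample purity = min(1, 2 x median AF over truncal mutations).

    Under the diploid-heterozygous model a clonal mutation's AF is purity/2,
    so twice the median truncal AF estimates the cancer-cell fraction.
    Samples with fewer than ``min_truncal`` usable truncal AFs get NaN with a
    warning.
    """
    truncal = [m for m in truncal_ids if m in af.index]
    estimates = {}
    for sample in af.columns:
        values = af.loc[truncal, sample].dropna()
        if len(values) < min_truncal:
            warnings.warn(
                f"sample {sample!r}: only {len(values)} usable truncal AFs "
                f"(< {min_truncal}); purity estimate missing"
            )
            estimates[sample] = np.nan
            continue
        estimates[sample] = min(1.0, 2.0 * float(values.median()))
    return pd.Series(estimates, name="purity_estimate")


# ---------------------------------------------------------------------------
# Nonparametric tests
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RankTestResult:
    statistic: float
    pvalue: float
    method: str  # exact | approx


def rank_sum_test(group_a: Sequence[float], group_b: Sequence[float]) -> RankTestResult:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test.

    Exact null by enumeration when the combined size is at most 12 and there
    are no ties; otherwise the normal approximation with midranks and tie
    correction (no continuity correction, to track the permutation null).
    """
    a, b = np.asarray(group_a, float), np.asarray(group_b, float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        warnings.warn("rank_sum_test: all values identical; p = 1")
        return RankTestResult(statistic=float(len(a) * len(b) / 2), pvalue=1.0, method="degenerate")
    ties = len(np.unique(pooled)) < len(pooled)
    exact = (len(a) + len(b) <= 12) and not ties
    res = sps.mannwhitneyu(
        a, b, alternative="two-sided",
        method="exact" if exact else "asymptotic",
        use_continuity=False,
    )
    return RankTestResult(
        statistic=float(res.statistic),
        pvalue=float(min(res.pvalue, 1.0)),
        method="exact" if exact else "approx",
    )


def signed_rank_test(paired_a: Sequence[float], paired_b: Sequence[float]) -> RankTestResult:
    """Two-sided Wilcoxon signed-rank test on paired values.

    Zero differences are dropped; the null is exact (sign-pattern
    enumeration) for up to 15 non-zero differences without tied magnitudes,
    otherwise the normal approximation with tie correction.
    """
    a, b = np.asarray(paired_a, float), np.asarray(paired_b, float)
    if len(a) != len(b) or len(a) == 0:
        raise ValueError("paired groups must be non-empty and equal length")
    d = a - b
    d = d[d != 0]
    if len(d) == 0:
        warnings.warn("signed_rank_test: all differences zero; p = 1")
        return RankTestResult(statistic=0.0, pvalue=1.0, method="degenerate")
    mags = np.abs(d)
    ties = len(np.unique(mags)) < len(mags)
    exact = len(d) <= 15 and not ties
    res = sps.wilcoxon(
        d, alternative="two-sided", correction=False,
        method="exact" if exact else "approx",
        zero_method="wilcox",
    )
    return RankTestResult(
        statistic=float(res.statistic),
        pvalue=float(min(res.pvalue, 1.0)),
        method="exact" if exact else "approx",
    )


# ---------------------------------------------------------------------------
# Tree distances: matched pairs vs cross-area
# ---------------------------------------------------------------------------


def tree_path_distance(ptree: PhyloTree, a: str, b: str) -> int:
    """Mutations separating two samples on the tree: the sum of supporting
    mutation counts over edges on the path between the leaves."""
    if a not in ptree.leaves or b not in ptree.leaves:
        raise ValueError("both samples must be leaves of the tree")
    total = 0
    for clade, muts in ptree.edge_mutations.items():
        if (a in clade) != (b in clade):
            total += len(muts)
    return total


def matched_pair_distance_test(
    ptree: PhyloTree,
    pairing: Mapping[str, tuple[str, str]],
    area_of: Optional[Mapping[str, str]] = None,
) -> tuple[list[int], list[int], RankTestResult]:
    """Compare matched biopsy/spheroid tree distances with cross-area ones.

    Matched distances are the path lengths between each area's biopsy and
    spheroid; cross distances are path lengths between samples from
    different areas (``area_of`` defaults to the areas implied by
    ``pairing``; samples outside it are ignored).  Returns (matched, cross,
    rank-sum result).
    """
    if area_of is None:
        area_of = {}
        for area, (biopsy, spheroid) in pairing.items():
            area_of[biopsy] = area
            area_of[spheroid] = area
    matched = [
        tree_path_distance(ptree, b, s)
        for b, s in pairing.values()
        if b in ptree.leaves and s in ptree.leaves
    ]
    in_tree = [s for s in ptree.leaves if s in area_of]
    cross = [
        tree_path_distance(ptree, x, y)
        for x, y in combinations(in_tree, 2)
        if area_of[x] != area_of[y]
    ]
    return matched, cross, rank_sum_test(matched, cross)
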