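"""Synthetic multi-region tumor cohorts with known clonal ground truth.

The simulator emulates the sampling design of a multi-region colorectal-cancer
study: 3-5 spatially distinct tumor regions, each split into a biopsy and a
matched spheroid culture, optionally with lymph-node metastases seeded from an
ancestral clone.  Mutations live on the edges of a clone phylogeny (a perfect
phylogeny: every mutation occurs once and is inherited by all descendant
clones).  Each sample is a mixture of clones diluted by normal cells (purity),
and read counts are drawn from a negative-binomial depth / binomial
alt-fraction model under diploid heterozygosity, so that the expected allele
fraction of a mutation in a sample is ``0.5 * purity * carrier_fraction``.

Every latent quantity (clone tree, mutation-to-branch map, per-sample clone
mixtures, purity, expected AF, true incidence) is recorded in a
:class:`CohortTruth` so downstream stages can be verified exactly.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SUB_CLASSES",
    "CODING_CLASSES",
    "DEFAULT_TRUNCAL_SPECTRUM",
    "DEFAULT_REGIONAL_SPECTRUM",
    "ClonePhylogeny",
    "MutationAssignment",
    "SampleSpec",
    "SamplingDesign",
    "ReadCounts",
    "CohortTruth",
    "Cohort",
    "simulate_clone_phylogeny",
    "assign_mutations",
    "simulate_read_counts",
    "simulate_cohort",
]

#: The six pyrimidine-reference substitution classes.
SUB_CLASSES = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")

#: Coding consequence classes tracked per mutation (all exonic point changes).
CODING_CLASSES = ("silent", "missense", "nonsense")

# Default substitution spectra over (class, at-CpG) cells.  The truncal
# spectrum is dominated by C>T at CpG (the age-related deamination pattern seen
# in trunk mutations of colorectal tumors); the regional spectrum has less C>T
# at CpG and more C>A.  These weights are simulator configuration chosen to
# make the spectrum contrast detectable, not measured values.
DEFAULT_TRUNCAL_SPECTRUM: Mapping[tuple[str, bool], float] = {
    ("C>T", True): 0.45,
    ("C>T", False): 0.15,
    ("C>A", False): 0.10,
    ("C>G", False): 0.05,
    ("T>A", False): 0.05,
    ("T>C", False): 0.15,
    ("T>G", False): 0.05,
}

DEFAULT_REGIONAL_SPECTRUM: Mapping[tuple[str, bool], float] = {
    ("C>T", True): 0.15,
    ("C>T", False): 0.15,
    ("C>A", False): 0.25,
    ("C>G", False): 0.10,
    ("T>A", False): 0.10,
    ("T>C", False): 0.15,
    ("T>G", False): 0.10,
}

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}


# ---------------------------------------------------------------------------
# Clone phylogeny
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ClonePhylogeny:
    """A rooted clone tree given as a child -> parent map (root maps to None)."""

    parent: Mapping[str, Optional[str]]

    def __post_init__(self) -> None:
        roots = [c for c, p in self.parent.items() if p is None]
        if len(roots) != 1:
            raise ValueError(f"clone tree must have exactly one root, found {len(roots)}")
        # every non-root must reach the root without cycles
        for clone in self.parent:
            seen = set()
            cur: Optional[str] = clone
            while cur is not None:
                if cur in seen:
                    raise ValueError(f"cycle in clone tree at {cur!r}")
                seen.add(cur)
                if cur not in self.parent:
                    raise ValueError(f"parent {cur!r} is not a known clone")
                cur = self.parent[cur]

    @property
    def root(self) -> str:
        return next(c for c, p in self.parent.items() if p is None)

    @property
    def nodes(self) -> tuple[str, ...]:
        return tuple(self.parent)

    def children(self, clone: str) -> tuple[str, ...]:
        return tuple(c for c, p in self.parent.items() if p == clone)

    def descendants(self, clone: str) -> frozenset[str]:
        """Clone plus all clones below it (the carriers of its edge mutations)."""
        out = {clone}
        stack = [clone]
        while stack:
            for child in self.children(stack.pop()):
                out.add(child)
                stack.append(child)
        return frozenset(out)

    def ancestors(self, clone: str) -> frozenset[str]:
        """Clone plus all clones on its path to the root."""
        out = []
        cur: Optional[str] = clone
        while cur is not None:
            out.append(cur)
            cur = self.parent[cur]
        return frozenset(out)


def simulate_clone_phylogeny(n_clones: int, seed: int = 0) -> ClonePhylogeny:
    """Draw a uniform random recursive tree over ``n_clones`` clones.

    Clone ``i`` attaches to a parent chosen uniformly among clones ``0..i-1``;
    clone 0 is the ancestral (root) clone.
    """
    if n_clones < 1:
        raise ValueError(f"n_clones must be >= 1, got {n_clones}")
    rng = np.random.default_rng(seed)
    names = [f"C{i}" for i in range(n_clones)]
    parent: dict[str, Optional[str]] = {names[0]: None}
    for i in range(1, n_clones):
        parent[names[i]] = names[int(rng.integers(0, i))]
    return ClonePhylogeny(parent)


# ---------------------------------------------------------------------------
# Mutation assignment
# ---------------------------------------------------------------------------


@dataclass
class MutationAssignment:
    """Mutations mapped to clone-tree branches.

    ``table`` is indexed by mutation id with columns: branch (clone whose
    incoming edge carries the mutation), sub_class, cpg, chrom, pos, ref, alt,
    context, gene, coding_class.
    """

    table: pd.DataFrame

    @property
    def mutation_ids(self) -> tuple[str, ...]:
        return tuple(self.table.index)

    def carriers(self, tree: ClonePhylogeny, mutation_id: str) -> frozenset[str]:
        return tree.descendants(self.table.at[mutation_id, "branch"])


def _validate_spectrum(spectrum: Mapping[tuple[str, bool], float], name: str) -> None:
    total = 0.0
    for (cls, cpg), w in spectrum.items():
        if cls not in SUB_CLASSES:
            raise ValueError(f"{name}: unknown substitution class {cls!r}")
        if cpg and not cls.startswith("C"):
            raise ValueError(f"{name}: CpG flag requires a C-reference class, got {cls}")
        if w < 0:
            raise ValueError(f"{name}: negative weight for {(cls, cpg)}")
        total += w
    if abs(total - 1.0) > 1e-8:
        raise ValueError(f"{name}: weights sum to {total}, expected 1")


def _draw_context(cls: str, cpg: bool, rng: np.random.Generator) -> str:
    """Reference trinucleotide consistent with the class and CpG flag."""
    ref = cls[0]
    five = "ACGT"[int(rng.integers(0, 4))]
    if ref == "C":
        three = "G" if cpg else "ACT"[int(rng.integers(0, 3))]
    else:  # T reference: never CpG
        three = "ACGT"[int(rng.integers(0, 4))]
    return five + ref + three


def assign_mutations(
    tree: ClonePhylogeny,
    n_truncal: int,
    n_per_branch: int,
    truncal_spectrum: Optional[Mapping[tuple[str, bool], float]] = None,
    regional_spectrum: Optional[Mapping[tuple[str, bool], float]] = None,
    coding_probs: Optional[Mapping[str, float]] = None,
    seed: int = 0,
    chrom: str = "1",
    start_pos: int = 10_000,
    spacing: int = 1_000,
) -> MutationAssignment:
    """Place mutations on clone-tree edges with class-specific spectra.

    ``n_truncal`` mutations go on the root's incoming edge (the trunk) drawn
    from ``truncal_spectrum``; ``n_per_branch`` go on every non-root edge drawn
    from ``regional_spectrum``.  Coding classes are drawn from
    ``coding_probs`` (default uniform over silent/missense/nonsense).
    """
    if n_truncal < 0 or n_per_branch < 0:
        raise ValueError("mutation counts must be non-negative")
    truncal_spectrum = dict(truncal_spectrum or DEFAULT_TRUNCAL_SPECTRUM)
    regional_spectrum = dict(regional_spectrum or DEFAULT_REGIONAL_SPECTRUM)
    _validate_spectrum(truncal_spectrum, "truncal_spectrum")
    _validate_spectrum(regional_spectrum, "regional_spectrum")
    coding_probs = dict(coding_probs or {c: 1 / 3 for c in CODING_CLASSES})
    if abs(sum(coding_probs.values()) - 1.0) > 1e-8 or min(coding_probs.values()) < 0:
        raise ValueError("coding_probs must be a probability vector")

    rng = np.random.default_rng(seed)
    root = tree.root
    branches = [root] * n_truncal
    for clone in tree.nodes:
        if clone != root:
            branches.extend([clone] * n_per_branch)

    coding_names = list(coding_probs)
    coding_p = np.array([coding_probs[c] for c in coding_names])

    rows = []
    pos = start_pos
    for i, branch in enumerate(branches):
        spectrum = truncal_spectrum if branch == root else regional_spectrum
        cells = list(spectrum)
        weights = np.array([spectrum[c] for c in cells])
        cls, cpg = cells[int(rng.choice(len(cells), p=weights))]
        context = _draw_context(cls, cpg, rng)
        coding = coding_names[int(rng.choice(len(coding_names), p=coding_p))]
        mid = f"m{i:05d}"
        rows.append(
            {
                "mutation_id": mid,
                "branch": branch,
                "sub_class": cls,
                "cpg": bool(cpg),
                "chrom": chrom,
                "pos": pos,
                "ref": cls[0],
                "alt": cls[2],
                "context": context,
                "gene": f"G{i:05d}",
                "coding_class": coding,
            }
        )
        pos += spacing
    table = pd.DataFrame(rows).set_index("mutation_id")
    return MutationAssignment(table)


# ---------------------------------------------------------------------------
# Sampling design and read counts
# ---------------------------------------------------------------------------


@dataclass
class SampleSpec:
    """One sequenced sample: a clone mixture observed at a given purity."""

    name: str
    role: str  # biopsy | spheroid | lnm
    area: Optional[str]
    purity: float
    mixture: Mapping[str, float]

    def validate(self, tree: ClonePhylogeny) -> None:
        if not 0.0 < self.purity <= 1.0:
            raise ValueError(f"sample {self.name}: purity must be in (0, 1], got {self.purity}")
        if self.role not in ("biopsy", "spheroid", "lnm"):
            raise ValueError(f"sample {self.name}: unknown role {self.role!r}")
        total = 0.0
        for clone, frac in self.mixture.items():
            if clone not in tree.parent:
                raise ValueError(f"sample {self.name}: unknown clone {clone!r} in mixture")
            if frac < 0:
                raise ValueError(f"sample {self.name}: negative mixture fraction for {clone}")
            total += frac
        if abs(total - 1.0) > 1e-8:
            raise ValueError(f"sample {self.name}: mixture sums to {total}, expected 1")


@dataclass
class SamplingDesign:
    """Cohort-level observation model: samples, depth model, error rate."""

    samples: Sequence[SampleSpec]
    mean_depth: float = 79.0
    depth_dispersion: float = 10.0  # negative-binomial size parameter k
    error_rate: float = 0.001
    germline_name: str = "germline"

    def validate(self, tree: ClonePhylogeny) -> None:
        if self.mean_depth <= 0 or self.depth_dispersion <= 0:
            raise ValueError("depth parameters must be positive")
        if not 0.0 <= self.error_rate < 0.5:
            raise ValueError("error_rate must be in [0, 0.5)")
        names = [s.name for s in self.samples]
        if len(set(names)) != len(names):
            raise ValueError("duplicate sample names in design")
        if self.germline_name in names:
            raise ValueError("germline name collides with a tumor sample")
        for s in self.samples:
            s.validate(tree)


@dataclass
class ReadCounts:
    """Observed ref/alt read counts per mutation x sample, plus germline.

    ``ref`` and ``alt`` are mutation x sample integer DataFrames sharing an
    index with the ``mutations`` metadata table (chrom, pos, ref, alt,
    context, gene, coding_class).  The germline column is included in both
    count frames under ``germline`` name.
    """

    ref: pd.DataFrame
    alt: pd.DataFrame
    mutations: pd.DataFrame
    germline: str = "germline"

    @property
    def samples(self) -> list[str]:
        return [c for c in self.alt.columns if c != self.germline]

    @property
    def depth(self) -> pd.DataFrame:
        return self.ref + self.alt


@dataclass
class CohortTruth:
    """All latent values of one simulated cohort."""

    tree: ClonePhylogeny
    assignment: MutationAssignment
    design: SamplingDesign
    incidence: pd.DataFrame  # bool, mutation x sample: any carrier clone in mixture
    expected_af: pd.DataFrame  # 0.5 * purity * carrier fraction (error excluded)
    purity: pd.Series

    def branch_blocks(self) -> dict[str, tuple[str, ...]]:
        """Mutation ids grouped by the clone edge that carries them."""
        groups: dict[str, tuple[str, ...]] = {}
        for branch, sub in self.assignment.table.groupby("branch"):
            groups[str(branch)] = tuple(sub.index)
        return groups

    def sample_carrier_sets(self) -> dict[frozenset[str], int]:
        """Count of mutations per distinct sample-level carrier set."""
        out: dict[frozenset[str], int] = {}
        inc = self.incidence
        for mid in inc.index:
            carriers = frozenset(inc.columns[inc.loc[mid].to_numpy(bool)])
            if carriers:
                out[carriers] = out.get(carriers, 0) + 1
        return out


@dataclass
class Cohort:
    counts: ReadCounts
    truth: CohortTruth


def simulate_read_counts(
    tree: ClonePhylogeny,
    assignment: MutationAssignment,
    design: SamplingDesign,
    seed: int = 0,
) -> tuple[ReadCounts, CohortTruth]:
    """Draw sequencing read counts for every sample x mutation cell.

    Depth is negative-binomial with the design's mean and dispersion; alt
    reads are binomial with success probability
    ``0.5 * purity * carrier_fraction + error_rate`` (diploid heterozygous
    model plus a flat sequencing-error floor).  The germline column sees only
    error reads.
    """
    design.validate(tree)
    rng = np.random.default_rng(seed)

    mut_ids = list(assignment.table.index)
    sample_names = [s.name for s in design.samples]
    n_m, n_s = len(mut_ids), len(sample_names)

    # carrier fraction per mutation x sample
    desc_cache = {clone: tree.descendants(clone) for clone in tree.nodes}
    frac = np.zeros((n_m, n_s))
    branches = assignment.table["branch"].to_numpy()
    for j, spec in enumerate(design.samples):
        per_branch = {b: sum(f for c, f in spec.mixture.items() if c in desc_cache[b])
                      for b in set(branches)}
        frac[:, j] = [per_branch[b] for b in branches]

    purity = np.array([s.purity for s in design.samples])
    p_alt = np.clip(0.5 * purity[None, :] * frac + design.error_rate, 0.0, 1.0)

    k = design.depth_dispersion
    p_nb = k / (k + design.mean_depth)
    all_cols = sample_names + [design.germline_name]
    depth = rng.negative_binomial(k, p_nb, size=(n_m, n_s + 1))
    p_full = np.concatenate([p_alt, np.full((n_m, 1), design.error_rate)], axis=1)
    alt = rng.binomial(depth, p_full)
    ref = depth - alt

    counts = ReadCounts(
        ref=pd.DataFrame(ref, index=mut_ids, columns=all_cols),
        alt=pd.DataFrame(alt, index=mut_ids, columns=all_cols),
        mutations=assignment.table.drop(columns=["branch", "sub_class", "cpg"]).copy(),
        germline=design.germline_name,
    )
    truth = CohortTruth(
        tree=tree,
        assignment=assignment,
        design=design,
        incidence=pd.DataFrame(frac > 0, index=mut_ids, columns=sample_names),
        expected_af=pd.DataFrame(0.5 * purity[None, :] * frac, index=mut_ids, columns=sample_names),
        purity=pd.Series(purity, index=sample_names),
    )
    return counts, truth


# ---------------------------------------------------------------------------
# High-level cohort builder (the study design)
# ---------------------------------------------------------------------------


def _region_mixtures(
    region: str,
    has_lnm: bool,
    is_seeding: bool,
) -> tuple[dict[str, float], dict[str, float]]:
    """Biopsy and spheroid clone mixtures for one tumor region.

    The biopsy mixes the ancestral clone, the regional clone, and a
    biopsy-private subclone; the spheroid culture subsamples the regional
    clone and selects a rare spheroid-private subclone.  In LNM cohorts a
    nonmetastatic clone is present in every tumor sample and the metastatic
    clone additionally enters the seeding region.
    """
    r, pb, ps = f"R_{region}", f"PB_{region}", f"PS_{region}"
    if not has_lnm:
        biopsy = {"C0": 0.15, r: 0.60, pb: 0.25}
        spheroid = {r: 0.70, ps: 0.30}
    elif is_seeding:
        biopsy = {"C0": 0.10, "NONMET": 0.20, r: 0.30, "MET": 0.20, pb: 0.20}
        spheroid = {"NONMET": 0.25, r: 0.25, "MET": 0.25, ps: 0.25}
    else:
        biopsy = {"C0": 0.10, "NONMET": 0.25, r: 0.45, pb: 0.20}
        spheroid = {"NONMET": 0.30, r: 0.45, ps: 0.25}
    return biopsy, spheroid


def simulate_cohort(
    n_regions: int = 3,
    n_truncal: int = 80,
    n_per_branch: int = 30,
    n_lnm: int = 0,
    seeding_region: int = 1,
    seed: int = 0,
    mean_depth: float = 79.0,
    depth_dispersion: float = 10.0,
    error_rate: float = 0.001,
    biopsy_purity: tuple[float, float] = (0.4, 0.7),
    spheroid_purity: tuple[float, float] = (0.75, 0.95),
    truncal_spectrum: Optional[Mapping[tuple[str, bool], float]] = None,
    regional_spectrum: Optional[Mapping[tuple[str, bool], float]] = None,
) -> Cohort:
    """Simulate one patient's multi-region biopsy/spheroid cohort.

    Each of ``n_regions`` tumor regions contributes a biopsy and a matched
    spheroid.  The clone tree has an ancestral clone C0, one regional clone
    per region, and per-sample private subclones; with ``n_lnm > 0`` a
    metastatic clone (seeding all LNMs and present only in ``seeding_region``
    of the tumor) and a nonmetastatic clone (all tumor samples, no LNM) are
    added, mirroring the two-clone seeding scenario of stage-III tumors.

    Spheroid purity is drawn above biopsy purity (cultures enrich cancer
    cells); depth follows a negative binomial with mean 79 by default.
    """
    if n_regions < 1:
        raise ValueError("n_regions must be >= 1")
    if n_lnm and not 0 <= seeding_region < n_regions:
        raise ValueError("seeding_region out of range")
    rng = np.random.default_rng(seed)
    regions = [f"T{i + 1}" for i in range(n_regions)]
    has_lnm = n_lnm > 0

    parent: dict[str, Optional[str]] = {"C0": None}
    if has_lnm:
        parent["NONMET"] = "C0"
        parent["MET"] = "C0"
        for j in range(n_lnm):
            parent[f"L_{j + 1}"] = "MET"
    for reg in regions:
        parent[f"R_{reg}"] = "C0"
        parent[f"PB_{reg}"] = f"R_{reg}"
        parent[f"PS_{reg}"] = f"R_{reg}"
    tree = ClonePhylogeny(parent)

    assignment = assign_mutations(
        tree,
        n_truncal=n_truncal,
        n_per_branch=n_per_branch,
        truncal_spectrum=truncal_spectrum,
        regional_spectrum=regional_spectrum,
        seed=int(rng.integers(0, 2**31 - 1)),
    )

    samples: list[SampleSpec] = []
    for i, reg in enumerate(regions):
        bmix, smix = _region_mixtures(reg, has_lnm, is_seeding=(i == seeding_region))
        bp = float(rng.uniform(*biopsy_purity))
        sp = float(rng.uniform(*spheroid_purity))
        samples.append(SampleSpec(f"{reg}_B", "biopsy", reg, bp, bmix))
        samples.append(SampleSpec(f"{reg}_S", "spheroid", reg, sp, smix))
    for j in range(n_lnm):
        lp = float(rng.uniform(*biopsy_purity))
        samples.append(
            SampleSpec(f"L{j + 1}", "lnm", None, lp, {"MET": 0.4, f"L_{j + 1}": 0.6})
        )

    design = SamplingDesign(
        samples=samples,
        mean_depth=mean_depth,
        depth_dispersion=depth_dispersion,
        error_rate=error_rate,
    )
    counts, truth = simulate_read_counts(
        tree, assignment, design, seed=int(rng.integers(0, 2**31 - 1))
    )
    return Cohort(counts=counts, truth=truth)
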