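# Methods

## The observation model

Every analysis in `crcith` starts from per-sample read counts at somatic SNV
sites.  The generative model behind both the simulator and the statistics is
deliberately minimal: each sample is a mixture of tumor clones diluted by
normal cells, every somatic SNV is diploid heterozygous in the cells that
carry it, and mutations obey a perfect phylogeny at the clone level — a
mutation arises once on an edge of the clone tree and is inherited by all
descendant clones.  The expected allele fraction of mutation *m* in sample
*s* is therefore

    AF(m, s) = 0.5 · purity(s) · f(m, s) + ε

where `f(m, s)` is the summed mixture fraction of the carrier clones and ε a
flat sequencing-error floor.  Read depth is negative-binomial with mean 79
(dispersion/size parameter k = 10, giving a per-site spread of roughly
20–200X around a 79X mean, matching the coverage scale of exome cohorts);
alt reads are binomial given depth.  Copy-number events, indels,
multi-allelic sites and context-dependent error are out of scope.

Note that laminarity holds at the clone level only.  Because samples mix
clones, the *sample-level* incidence matrix is laminar exactly when each
sample is effectively one clone; the lymph-node-metastasis (LNM) design
deliberately produces non-laminar sample patterns (the metastatic and
nonmetastatic blocks overlap on the seeding region), which is what makes
homoplasy counts on real-style cohorts non-zero.

## Simulator defaults and what they emulate

`simulate_cohort()` builds one patient: `n_regions = 3` tumor regions (the
sampling design uses 3–5 depending on tumor size; 3 is the default study
condition), each contributing a biopsy and a matched spheroid culture.  The
clone tree has an ancestral clone C0, one regional clone per region, and one
private subclone per biopsy and per spheroid.  Default mixtures — biopsy
`{C0: 0.15, regional: 0.60, biopsy-private: 0.25}`, spheroid
`{regional: 0.70, spheroid-private: 0.30}` — encode the two observations the
design is meant to reproduce: spheroids subsample the biopsy's clonal
composition, and both sample types retain private subclones (cultures select
rare subclones, biopsies contain cells the culture missed).  With
`n_lnm > 0` a metastatic clone (present in all LNMs and in exactly one
seeding tumor region) and a nonmetastatic sister clone (all tumor samples,
no LNM) are added, reproducing the two-clone seeding scenario observed in
stage-III tumors.

Mutation counts default to 80 truncal and 30 per non-root branch, so the
trunk dominates — the long shared-mutation block seen in real multi-region
heatmaps.  Purity is drawn uniformly from (0.4, 0.7) for biopsies and
(0.75, 0.95) for spheroids, reflecting that cultures are purer than tissue;
the disjoint ranges also make the spheroid ≥ biopsy purity invariant hold by
construction.  The sequencing-error rate defaults to ε = 0.001 so that the
0–1-germline-read filter is actually exercised by noise.

The truncal spectrum puts weight 0.45 on C>T at CpG (the age-related
deamination signature that dominates truncal colorectal mutations) versus
0.15 in the regional spectrum, which instead has elevated C>A.  These
weights are simulator configuration — chosen to make the truncal/regional
contrast detectable at realistic mutation counts — not estimates of any
cohort.  What passing tests show is that the pipeline detects a contrast of
this size at ~300–500 mutations; they say nothing about spectra of real
tumors, where signatures are mixtures and counts vary by orders of
magnitude.

Everything the simulator does not emulate — subclonal copy-number states,
regional depth variation, FFPE artefacts, alignment error, germline
contamination — means that exact-recovery results (see below) are
best-case statements about the algorithmic pipeline, not about wet-lab
performance.

## Filtering rules

Presence requires ≥ 2 alt reads; somatic status requires ≤ 1 alt read in
the matched germline (read literally: one stray germline read is tolerated,
two exclude the site).  Sharing uses the n / n−1 rule: a mutation called in
at least n−1 of n samples is shared, in 1..n−2 regional, in 0 uncalled and
dropped.  The low-coverage guard applies to regional mutations only: a
negative (absent) call backed by fewer than 10 reads is unreliable, so the
mutation is either dropped entirely ("drop", used for heatmap/distance
matrices) or the cell becomes missing ("missing", used for tree scoring,
where a missing cell constrains nothing).  Both modes exist because the
dropping rule is stated for heatmaps while the phylogeny treatment is an
open choice; defaults are drop for heatmaps, missing for trees.

## Tree scoring and search

The score of a rooted tree is the number of mutations whose carriers can be
explained by a single clade: some clade contains all carriers and excludes
all explicit non-carriers.  Each compatible mutation is assigned to the
smallest such clade's incoming edge, so edge lengths count supporting
mutations and the trunk (edge above the root) collects fully shared ones.
Incompatible mutations (homoplasies — in this model usually subclone
mixing, dropout, or error) support no edge and are listed separately.
Scoring is unweighted: an AF-weighted variant was considered and rejected
because presence calls already threshold AF and weighting would entangle
purity with topology.

Search is exhaustive up to 9 leaves ((2·9−3)!! ≈ 2.0M topologies,
enumerated once per leaf count and scored vectorised over bitmask clade
tables).  Beyond that, greedy ascent over subtree-prune-regraft (SPR) and
rerooting moves starts from the average-linkage join tree plus random
restarts (default 10).  SPR was chosen over plain nearest-neighbour
interchange after pilot runs showed rooted NNI stalling on plateaus of
conflicting character matrices (~89% optimum-attainment vs 98% for SPR at
6–8 leaves); SPR strictly contains the NNI moves.  Ties anywhere are broken
by lexicographically smallest canonical newick (children ordered by
smallest leaf label), making results seed-stable.

Binary trees express multifurcations through zero-support edges, so
"topology recovery" in tests compares the *supported* clades (those with at
least one mutation) against the true carrier-set blocks — the resolution of
zero-length edges is arbitrary and not asserted.

## Statistics

* **Binary distance**: Jaccard mismatch — mismatched calls over the union
  of calls, joint absences ignored, computed over cells non-missing in both
  samples; this is the "binary" distance of standard statistical software.
* **Concordance** (per matched biopsy/spheroid area): over the union of the
  pair's called mutations, concordant / tumor-only / spheroid-only
  fractions sum to exactly 1.  Pairwise-private (called in both pair
  members and nowhere else) is reported as a separate, overlapping count.
  Private means called in exactly one sample cohort-wide; the per-sample
  private fraction is over that sample's calls.  "Coding" includes silent,
  missense and nonsense — all exonic point changes.
* **Purity**: `min(1, 2 × median AF)` over truncal (shared-in-≥n−1)
  mutations, requiring ≥ 3 usable AFs.  Under the diploid model this is
  unbiased until the clip at 1 (estimates for purity near 1 are biased
  slightly low).  It is a deliberately simple stand-in for CNA-aware purity
  callers and inherits the diploid assumption.
* **Rank tests**: Wilcoxon rank-sum and signed-rank, two-sided.  Exact
  enumeration when the combined size is ≤ 12 (rank-sum) or ≤ 15 non-zero
  differences (signed-rank) without ties; otherwise normal approximation
  with midranks and tie correction and no continuity correction, so the
  approximate p tracks the permutation null it stands in for.
* **Tree distance** between samples is the path length on the best tree in
  supporting-mutation units; the matched-vs-cross comparison feeds matched
  pair distances and all cross-area distances to the rank-sum test.
* **CpG test**: Pearson χ² without continuity correction (flag available)
  on {C>T at CpG, everything else} × {shared, regional}; refused when a
  margin is zero.  CpG is defined post-normalisation: the mutated C (after
  reverse-complementing purine-reference changes) immediately followed by
  G.  The trinucleotide context must be supplied in the input — the package
  never fetches a reference genome.

## Numerical and I/O choices

Coordinates are 1-based VCF convention; sites are keyed
`(chrom, pos, ref, alt)` with no left-alignment (SNVs only).  Multi-allelic
records take the first alternate with a warning.  Missing count data is
depth 0, never presence.  AF at zero depth is undefined (NaN), excluded
from medians.  Pipeline summaries embed the seed and a config hash but no
timings (those go to the log), so equal-seed reruns are byte-identical.

## Problem sizes used in the test suite

The acceptance-style tests run: 100 noise-free 6-sample cohorts for exact
tree recovery; 50 random matrices per leaf count 3–8 for the
heuristic-vs-exhaustive comparison; 1000 replicates of 500+500 mutations
for χ² calibration and power; 9 purity levels × 50 replicates × 200
truncal mutations at 79X for purity recovery; full enumeration oracles up
to 8 values and 50 permutation-oracle instances (10,000 draws) for the rank
tests; and 100 default cohorts for the matched-pair clustering property.
`scripts/acceptance.py` uses one default cohort, one LNM cohort, 25 tree-
recovery replicates and a 9 × 10 purity sweep — sizes chosen so the whole
script is a desk-scale run while keeping Monte-Carlo noise well inside the
asserted tolerances.

## Known limitations

Diploid-heterozygous everywhere: copy-number alterations, LOH and
subclonal copy states are not modelled, so purity and AF expectations are
wrong for CNA-dense genomes.  The maximum-compatibility score treats every
mutation equally and missing cells as unconstrained, which can overstate
support when missingness is informative.  Exhaustive search is factorial;
beyond ~13 samples even the heuristic's O(n²) SPR neighbourhood grows
noticeable.  The concordance denominators follow the union-of-pair
convention; other published denominators (per-biopsy, per-cohort) will give
different percentages on the same data.
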