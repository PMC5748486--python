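"""Presence/absence calling and shared-vs-regional classification.

Filtering rules applied to per-sample somatic read counts:

* a mutation enters the matrix only if the matched germline shows at most one
  alt read (0-1 germline reads tolerated);
* within admitted mutations, a sample is *present* when it has two or more
  alt reads, otherwise *absent*;
* a mutation is *shared* when called in n or n-1 of the patient's samples and
  *regional* when called in fewer;
* to avoid false negatives, a regional mutation whose negative (absent)
  samples include one with fewer than ten reads is either dropped from the
  matrix ("drop" mode, used for heatmaps) or that cell is set to *missing*
  ("missing" mode, used for tree scoring, where a missing cell constrains
  nothing).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Optional, Union

import numpy as np
import pandas as pd

from .simulate import ReadCounts

__all__ = [
    "PRESENT",
    "ABSENT",
    "MISSING",
    "PresenceMatrix",
    "compute_af",
    "call_presence",
    "classify_sharing",
    "apply_coverage_mask",
    "annotate_genes",
    "read_gene_list",
]

PRESENT = "present"
ABSENT = "absent"
MISSING = "missing"

#: minimum alt reads for a presence call
MIN_ALT_READS = 2
#: maximum germline alt reads for a somatic mutation ("0-1 read" rule)
MAX_GERMLINE_ALT = 1
#: default minimum depth for a trusted negative call
DEFAULT_MIN_DEPTH = 10


@dataclass
class PresenceMatrix:
    """Called presence states with companion allele fractions.

    ``states`` is a mutation x sample frame of {present, absent, missing};
    ``af`` the matching allele-fraction frame (NaN at zero depth);
    ``mutations`` carries per-mutation metadata, including ``sharing`` and
    ``carrier_count`` once :func:`classify_sharing` has run.
    """

    states: pd.DataFrame
    af: pd.DataFrame
    mutations: pd.DataFrame
    germline_excluded: tuple[str, ...] = ()
    uncalled: tuple[str, ...] = ()
    mask_dropped: tuple[str, ...] = ()

    @property
    def samples(self) -> list[str]:
        return list(self.states.columns)

    @property
    def n_samples(self) -> int:
        return self.states.shape[1]

    def carriers(self, mutation_id: str) -> frozenset[str]:
        row = self.states.loc[mutation_id]
        return frozenset(row.index[row == PRESENT])

    def incidence(self) -> pd.DataFrame:
        """Boolean present/not-present view (missing counts as not present)."""
        return self.states == PRESENT


def compute_af(ref_reads: int, alt_reads: int) -> float:
    """Allele fraction alt/(ref+alt); NaN when total depth is zero."""
    if ref_reads < 0 or alt_reads < 0:
        raise ValueError("read counts must be non-negative")
    depth = ref_reads + alt_reads
    if depth == 0:
        return math.nan
    return alt_reads / depth


def _af_frame(ref: pd.DataFrame, alt: pd.DataFrame) -> pd.DataFrame:
    depth = ref + alt
    with np.errstate(invalid="ignore", divide="ignore"):
        af = alt / depth
    return af.where(depth > 0)


def call_presence(counts: ReadCounts) -> PresenceMatrix:
    """Call per-sample presence from read counts, applying the germline rule.

    Mutations with two or more alt reads in the matched germline are removed
    from the matrix entirely; among the rest, presence requires at least two
    alt reads in the sample.
    """
    if counts.germline not in counts.alt.columns:
        raise ValueError(f"germline column {counts.germline!r} missing from counts")
    if (counts.ref.to_numpy() < 0).any() or (counts.alt.to_numpy() < 0).any():
        raise ValueError("read counts must be non-negative")

    germline_alt = counts.alt[counts.germline]
    admitted = germline_alt <= MAX_GERMLINE_ALT
    excluded = tuple(counts.alt.index[~admitted])

    samples = counts.samples
    alt = counts.alt.loc[admitted, samples]
    ref = counts.ref.loc[admitted, samples]
    states = pd.DataFrame(
        np.where(alt.to_numpy() >= MIN_ALT_READS, PRESENT, ABSENT),
        index=alt.index,
        columns=samples,
    )
    mutations = counts.mutations.loc[admitted].copy()
    return PresenceMatrix(
        states=states,
        af=_af_frame(ref, alt),
        mutations=mutations,
        germline_excluded=excluded,
    )


def classify_sharing(presence: PresenceMatrix, n_samples: Optional[int] = None) -> PresenceMatrix:
    """Label each mutation shared (called in >= n-1 samples) or regional.

    Mutations called in no sample are dropped and recorded as uncalled.
    Missing cells do not count as carriers.
    """
    n = n_samples if n_samples is not None else presence.n_samples
    if n < 2:
        raise ValueError("sharing classification needs at least 2 samples")
    carrier_count = (presence.states == PRESENT).sum(axis=1)
    sharing = pd.Series(
        np.where(carrier_count >= n - 1, "shared", "regional"),
        index=presence.states.index,
    )
    called = carrier_count >= 1
    uncalled = tuple(presence.states.index[~called])

    mutations = presence.mutations.loc[called].copy()
    mutations["sharing"] = sharing[called]
    mutations["carrier_count"] = carrier_count[called].astype(int)
    return replace(
        presence,
        states=presence.states.loc[called],
        af=presence.af.loc[called],
        mutations=mutations,
        uncalled=presence.uncalled + uncalled,
    )


def apply_coverage_mask(
    presence: PresenceMatrix,
    counts: ReadCounts,
    min_depth: int = DEFAULT_MIN_DEPTH,
    mode: str = "drop",
) -> PresenceMatrix:
    """Guard regional mutations against false-negative calls at low depth.

    A regional mutation with any absent sample covered by fewer than
    ``min_depth`` reads is dropped (``mode="drop"``, heatmap behaviour) or has
    those cells set to missing (``mode="missing"``, tree-scoring behaviour).
    Shared mutations are never touched.
    """
    if mode not in ("drop", "missing"):
        raise ValueError(f"mask mode must be 'drop' or 'missing', got {mode!r}")
    if "sharing" not in presence.mutations.columns:
        raise ValueError("classify_sharing must run before apply_coverage_mask")

    depth = counts.depth.loc[presence.states.index, presence.samples]
    regional = presence.mutations["sharing"] == "regional"
    low = (presence.states == ABSENT) & (depth < min_depth)
    affected = regional & low.any(axis=1)

    if mode == "drop":
        keep = ~affected
        return replace(
            presence,
            states=presence.states.loc[keep],
            af=presence.af.loc[keep],
            mutations=presence.mutations.loc[keep].copy(),
            mask_dropped=presence.mask_dropped + tuple(presence.states.index[affected]),
        )
    states = presence.states.copy()
    mask_cells = low & regional.to_numpy()[:, None]
    states[mask_cells] = MISSING
    return replace(presence, states=states)


def read_gene_list(path: Union[str, Path]) -> dict[str, str]:
    """Parse a two-column gene/category TSV; first occurrence wins.

    Lines starting with '#' are ignored.  Malformed lines raise with the
    offending line number; duplicated genes with conflicting categories keep
    the first category and emit a warning.
    """
    table: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2 or not parts[0] or not parts[1]:
                raise ValueError(f"{path}: malformed gene-list line {lineno}: {line!r}")
            gene, category = parts
            if gene in table:
                if table[gene] != category:
                    warnings.warn(
                        f"{path}: duplicate gene {gene!r} at line {lineno} with "
                        f"conflicting category {category!r}; keeping {table[gene]!r}"
                    )
                continue
            table[gene] = category
    return table


def annotate_genes(
    presence: PresenceMatrix,
    gene_list: Union[str, Path, Mapping[str, str]],
) -> PresenceMatrix:
    """Attach per-mutation category flags from a user gene list.

    Genes not covered by the list get category "none".
    """
    if "gene" not in presence.mutations.columns:
        raise ValueError("mutations table has no 'gene' column")
    if not isinstance(gene_list, Mapping):
        gene_list = read_gene_list(gene_list)
    mutations = presence.mutations.copy()
    mutations["gene_category"] = [
        gene_list.get(g, "none") for g in mutations["gene"]
    ]
    return replace(presence, mutations=mutations)
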