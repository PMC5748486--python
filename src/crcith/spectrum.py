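"""Mutational spectrum: six-class substitution typing and CpG enrichment.

Point substitutions are reduced to the six pyrimidine-reference classes
(C>A, C>G, C>T, T>A, T>C, T>G) by reverse-complementing purine-reference
changes.  A C-reference substitution counts as "at CpG" when the mutated C is
immediately followed by G in the (possibly complemented) reference
trinucleotide context — the standard convention for the age-related
C>T-at-CpG deamination signature.

The shared-vs-regional contrast is tested with Pearson's chi-squared on the
2x2 collapse {C>T at CpG, everything else} x {shared, regional}.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .simulate import SUB_CLASSES

__all__ = [
    "substitution_class",
    "classify_mutations",
    "spectrum_table",
    "cpg_enrichment_test",
    "SpectrumTestResult",
]

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}


def _revcomp(seq: str) -> str:
    return "".join(_COMPLEMENT[b] for b in reversed(seq))


def substitution_class(
    ref_base: str, alt_base: str, trinucleotide_context: str
) -> Optional[tuple[str, bool]]:
    """Return (class, at_cpg) for a single-base substitution.

    The context is the reference trinucleotide centred on the mutated base.
    Purine-reference changes are reverse-complemented, so the function is
    strand-symmetric.  Returns None (unclassifiable) if any base is ambiguous.
    """
    ref, alt = ref_base.upper(), alt_base.upper()
    ctx = trinucleotide_context.upper()
    if ref == alt:
        raise ValueError("ref and alt must differ")
    if len(ref) != 1 or len(alt) != 1 or len(ctx) != 3:
        raise ValueError("expected single ref/alt bases and a trinucleotide context")
    bases = set("ACGT")
    if ref not in bases or alt not in bases or not set(ctx) <= bases:
        return None
    if ctx[1] != ref:
        raise ValueError(f"context middle base {ctx[1]!r} does not match ref {ref!r}")
    if ref in "AG":
        ref, alt, ctx = _COMPLEMENT[ref], _COMPLEMENT[alt], _revcomp(ctx)
    cls = f"{ref}>{alt}"
    at_cpg = ref == "C" and ctx[2] == "G"
    return cls, at_cpg


def classify_mutations(mutations: pd.DataFrame) -> pd.DataFrame:
    """Add ``sub_class`` and ``cpg`` columns from ref/alt/context columns.

    Unclassifiable rows (ambiguous bases) get sub_class=None and are excluded
    from downstream tables.
    """
    out = mutations.copy()
    classes: list[Optional[str]] = []
    cpgs: list[Optional[bool]] = []
    for ref, alt, ctx in zip(out["ref"], out["alt"], out["context"]):
        res = substitution_class(ref, alt, ctx)
        if res is None:
            classes.append(None)
            cpgs.append(None)
        else:
            classes.append(res[0])
            cpgs.append(res[1])
    out["sub_class"] = classes
    out["cpg"] = cpgs
    return out


def spectrum_table(
    mutations: pd.DataFrame,
    groups: Sequence[str] = ("shared", "regional"),
) -> pd.DataFrame:
    """Contingency counts by (class, cpg) x sharing group, with fractions.

    ``mutations`` needs ``sub_class``, ``cpg`` and ``sharing`` columns (see
    :func:`classify_mutations` and the matrix module).  Empty groups yield
    zero columns with a warning.
    """
    for col in ("sub_class", "cpg", "sharing"):
        if col not in mutations.columns:
            raise ValueError(f"mutations table has no {col!r} column")
    idx = pd.MultiIndex.from_tuples(
        [(c, f) for c in SUB_CLASSES for f in (False, True)], names=["sub_class", "cpg"]
    )
    table = pd.DataFrame(0, index=idx, columns=list(groups))
    usable = mutations.dropna(subset=["sub_class"])
    for group in groups:
        sub = usable[usable["sharing"] == group]
        if sub.empty:
            warnings.warn(f"spectrum group {group!r} is empty")
            continue
        counts = sub.groupby(["sub_class", "cpg"]).size()
        for key, n in counts.items():
            table.loc[key, group] = int(n)
    totals = table.sum(axis=0)
    for group in groups:
        denom = totals[group]
        table[f"{group}_frac"] = table[group] / denom if denom > 0 else 0.0
    return table


@dataclass(frozen=True)
class SpectrumTestResult:
    statistic: float
    df: int
    pvalue: float
    table: pd.DataFrame  # the 2x2 collapse actually tested


def cpg_enrichment_test(
    table: pd.DataFrame,
    groups: Sequence[str] = ("shared", "regional"),
    correction: bool = False,
) -> SpectrumTestResult:
    """Pearson chi-squared test of C>T-at-CpG fraction between groups.

    Collapses the full spectrum table to a 2x2: {C>T at CpG, all other
    substitutions} x groups.  No continuity correction by default (large-count
    usage); any zero margin refuses the test.
    """
    counts = table[list(groups)]
    ct_cpg = counts.loc[("C>T", True)]
    other = counts.sum(axis=0) - ct_cpg
    collapsed = pd.DataFrame(
        {g: [ct_cpg[g], other[g]] for g in groups},
        index=["C>T_CpG", "other"],
    )
    arr = collapsed.to_numpy(float)
    if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        raise ValueError(
            "cpg_enrichment_test: a margin of the 2x2 table is zero; "
            "the chi-squared test is undefined on degenerate tables"
        )
    res = sps.chi2_contingency(arr, correction=correction)
    return SpectrumTestResult(
        statistic=float(res.statistic),
        df=int(res.dof),
        pvalue=float(res.pvalue),
        table=collapsed,
    )
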