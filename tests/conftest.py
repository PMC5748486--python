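"""Shared fixtures: toy count matrices and presence-matrix builders."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from crcith.matrix import ABSENT, MISSING, PRESENT, PresenceMatrix
from crcith.simulate import ReadCounts

SAMPLES = ["S1", "S2", "S3", "S4", "S5", "S6"]


def make_counts(cells: dict[str, dict[str, tuple[int, int]]],
                germline: str = "G") -> ReadCounts:
    """Build ReadCounts from {mutation: {sample: (ref, alt)}} literals."""
    ids = list(cells)
    columns = SAMPLES + [germline]
    ref = pd.DataFrame(0, index=ids, columns=columns)
    alt = pd.DataFrame(0, index=ids, columns=columns)
    for mid, row in cells.items():
        for sample, (r, a) in row.items():
            ref.at[mid, sample] = r
            alt.at[mid, sample] = a
    meta = pd.DataFrame(
        {
            "chrom": "1",
            "pos": np.arange(len(ids)) * 1000 + 5000,
            "ref": "C",
            "alt": "T",
            "context": "ACG",
            "gene": [f"G{i:03d}" for i in range(len(ids))],
            "coding_class": "missense",
        },
        index=ids,
    )
    return ReadCounts(ref=ref, alt=alt, mutations=meta, germline=germline)


def presence_from_incidence(inc: pd.DataFrame) -> PresenceMatrix:
    """PresenceMatrix from a boolean mutation x sample incidence frame."""
    states = pd.DataFrame(
        np.where(inc.to_numpy(bool), PRESENT, ABSENT),
        index=inc.index, columns=inc.columns,
    )
    af = pd.DataFrame(
        np.where(inc.to_numpy(bool), 0.4, 0.0), index=inc.index, columns=inc.columns
    )
    meta = pd.DataFrame(
        {"gene": [f"G{i}" for i in range(len(inc))], "coding_class": "missense"},
        index=inc.index,
    )
    meta["carrier_count"] = inc.sum(axis=1).astype(int)
    n = inc.shape[1]
    meta["sharing"] = np.where(meta["carrier_count"] >= n - 1, "shared", "regional")
    return PresenceMatrix(states=states, af=af, mutations=meta)


def _spread(pairs, samples=SAMPLES):
    return dict(zip(samples, pairs))


@pytest.fixture(scope="session")
def toy_counts() -> ReadCounts:
    """20-mutation x 6-sample matrix exercising every filtering rule.

    Hand-designed so that presence calls, germline exclusions, sharing labels
    and the <10-read coverage mask have exactly known outcomes (documented in
    TOY_EXPECTED).
    """
    G = "G"
    c = {
        # trunk: present everywhere, clean germline
        "m01": {**_spread([(40, 10)] * 6), G: (50, 0)},
        # present in 5 of 6 -> still shared (n-1 rule)
        "m02": {**_spread([(45, 5)] * 5 + [(50, 0)]), G: (50, 0)},
        # germline alt=2 -> excluded entirely
        "m03": {**_spread([(30, 20)] * 6), G: (48, 2)},
        # germline alt=1 -> boundary pass
        "m04": {**_spread([(40, 8)] * 6), G: (49, 1)},
        # private to S1 at the alt=2 presence boundary
        "m05": {**_spread([(28, 2)] + [(30, 0)] * 5), G: (30, 0)},
        # single alt read everywhere it occurs -> called nowhere -> uncalled
        "m06": {**_spread([(29, 1)] + [(30, 0)] * 5), G: (30, 0)},
        # regional, one negative sample at depth 9 -> masked
        "m07": {**_spread([(22, 8), (22, 8), (9, 0)] + [(30, 0)] * 3), G: (30, 0)},
        # regional, all negative samples well covered -> retained
        "m08": {**_spread([(22, 8), (22, 8)] + [(30, 0)] * 4), G: (30, 0)},
        # shared with a depth-3 negative sample -> mask does not apply
        "m09": {**_spread([(40, 6)] * 5 + [(3, 0)]), G: (40, 0)},
        # regional in 3 samples
        "m10": {**_spread([(33, 7)] * 3 + [(40, 0)] * 3), G: (40, 0)},
        # AF arithmetic check: 25/(75+25) = 0.25
        "m11": {**_spread([(75, 25)] + [(30, 0)] * 5), G: (30, 0)},
        # shared with one zero-depth cell (AF undefined there)
        "m12": {**_spread([(10, 10)] * 5 + [(0, 0)]), G: (40, 0)},
        # second germline exclusion (alt=3)
        "m13": {**_spread([(20, 20)] * 6), G: (47, 3)},
        # presence with zero ref reads: AF = 1
        "m14": {**_spread([(0, 2)] + [(30, 0)] * 5), G: (30, 0)},
        # boundary presence (alt=2) in every sample
        "m15": {**_spread([(25, 2)] * 6), G: (30, 0)},
        # regional with a depth-9 negative (alt=1 does not rescue it)
        "m16": {**_spread([(12, 3), (12, 3), (8, 1)] + [(30, 0)] * 3), G: (30, 0)},
        # regional in 4 = n-2 samples -> regional, retained
        "m17": {**_spread([(35, 5)] * 4 + [(35, 0)] * 2), G: (35, 0)},
        # 5 carriers, S4 below threshold -> shared via n-1
        "m18": {**_spread([(20, 4), (20, 4), (20, 4), (20, 1), (20, 4), (20, 4)]), G: (30, 0)},
        # regional private with a depth-5 negative -> masked
        "m19": {**_spread([(25, 0), (18, 9), (25, 0), (25, 0), (5, 0), (25, 0)]), G: (30, 0)},
        # regional private to S6, retained
        "m20": {**_spread([(40, 0)] * 5 + [(14, 6)]), G: (30, 0)},
    }
    return make_counts(c)


TOY_EXPECTED = {
    "germline_excluded": {"m03", "m13"},
    "uncalled": {"m06"},
    "shared": {"m01", "m02", "m04", "m09", "m12", "m15", "m18"},
    "regional_retained": {"m05", "m08", "m10", "m11", "m14", "m17", "m20"},
    "mask_dropped": {"m07", "m16", "m19"},
    "carriers": {
        "m01": {"S1", "S2", "S3", "S4", "S5", "S6"},
        "m02": {"S1", "S2", "S3", "S4", "S5"},
        "m05": {"S1"},
        "m08": {"S1", "S2"},
        "m10": {"S1", "S2", "S3"},
        "m17": {"S1", "S2", "S3", "S4"},
        "m18": {"S1", "S2", "S3", "S5", "S6"},
        "m20": {"S6"},
    },
}
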