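"""Sample/taxon filtering, genus aggregation, rarefaction and clr transforms.

Count tables are pandas DataFrames with samples as rows (index =
sample_id) and taxa as columns (lineage strings with rank prefixes, or
plain ``g__Genus`` labels when already aggregated).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "filter_depth",
    "filter_near_zero_variance",
    "aggregate_genus",
    "rarefy",
    "clr_transform",
    "merge_segments",
]

RANK_ORDER = ("d__", "k__", "p__", "c__", "o__", "f__", "g__", "s__")

#: anatomical segment -> class under each merging scheme; the right/left
#: split pools cecum + ascending (right) and descending + rectum (left),
#: leaving other colonic sites unassigned for that analysis
SEGMENT_SCHEMES = {
    "colon_unified": {
        "ileum": "ileum",
        "cecum": "colon",
        "ascending": "colon",
        "transverse": "colon",
        "descending": "colon",
        "sigmoid": "colon",
        "rectum": "colon",
    },
    "right_left": {
        "ileum": "ileum",
        "cecum": "right",
        "ascending": "right",
        "transverse": "other",
        "descending": "left",
        "sigmoid": "other",
        "rectum": "left",
    },
}


def filter_depth(table: pd.DataFrame, min_reads: int = 10000) -> pd.DataFrame:
    """Drop samples whose total read count is strictly below `min_reads`."""
    if min_reads <= 0:
        raise ValueError("min_reads must be positive")
    keep = table.sum(axis=1) >= min_reads
    if not keep.any():
        raise ValueError(f"no samples survive the {min_reads}-read depth filter")
    return table.loc[keep]


def filter_near_zero_variance(
    table: pd.DataFrame, freq_ratio_cut: float = 19.0, unique_cut_pct: float = 10.0
) -> pd.DataFrame:
    """Drop low-information taxa by the near-zero-variance rule.

    A column is dropped when BOTH hold: the ratio of the most common
    value's frequency to the second most common exceeds `freq_ratio_cut`
    (infinite for constant columns), and the percentage of distinct
    values relative to the number of samples is below `unique_cut_pct`.
    """
    if table.empty:
        raise ValueError("empty table")
    n = len(table)
    keep = []
    for col in table.columns:
        counts = table[col].value_counts().values
        ratio = np.inf if len(counts) == 1 else counts[0] / counts[1]
        pct_unique = 100.0 * len(counts) / n
        if ratio > freq_ratio_cut and pct_unique < unique_cut_pct:
            continue
        keep.append(col)
    return table[keep]


def _genus_key(label: str) -> str:
    parts = [p.strip() for p in str(label).split(";")]
    named = {}
    for part in parts:
        for rank in RANK_ORDER:
            if part.startswith(rank) and len(part) > len(rank):
                named[rank] = part
    if not named:
        raise ValueError(f"unparseable taxonomy label: {label!r}")
    if "g__" in named:
        return named["g__"]
    # unassigned at genus: pool at the deepest named rank
    for rank in reversed(RANK_ORDER):
        if rank in named and rank != "s__":
            return f"{named[rank]}_unclassified"
    raise ValueError(f"unparseable taxonomy label: {label!r}")


def aggregate_genus(table: pd.DataFrame) -> pd.DataFrame:
    """Sum feature columns sharing a genus; pool genus-unassigned features
    at their deepest named rank. Idempotent on genus-level tables."""
    keys = [_genus_key(c) for c in table.columns]
    out = table.T.groupby(pd.Index(keys, name="genus"), sort=False).sum().T
    return out


def rarefy(table: pd.DataFrame, depth: int = 10000, seed: int = 0) -> pd.DataFrame:
    """Subsample each sample without replacement to exactly `depth` reads."""
    totals = table.sum(axis=1)
    low = totals < depth
    if low.any():
        bad = table.index[low][0]
        raise ValueError(
            f"sample {bad!r} has {int(totals[bad])} < {depth} reads; filter by depth first"
        )
    rng = np.random.default_rng(seed)
    mat = table.to_numpy(dtype=np.int64)
    out = np.empty_like(mat)
    for i in range(mat.shape[0]):
        out[i] = rng.multivariate_hypergeometric(mat[i], depth)
    return pd.DataFrame(out, index=table.index, columns=table.columns)


def clr_transform(table: pd.DataFrame, pseudocount: float = 0.5) -> pd.DataFrame:
    """Centered log-ratio transform after adding a pseudocount to all cells.

    Each row of the result sums to zero. The pseudocount used is recorded
    in ``result.attrs["pseudocount"]``.
    """
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    x = np.log(table.to_numpy(dtype=float) + pseudocount)
    x -= x.mean(axis=1, keepdims=True)
    out = pd.DataFrame(x, index=table.index, columns=table.columns)
    out.attrs["pseudocount"] = float(pseudocount)
    return out


def merge_segments(info: pd.DataFrame, scheme: str = "colon_unified") -> pd.DataFrame:
    """Add a `segment_class` column mapping anatomical sites per scheme.

    The ileum is always its own class.
    """
    if scheme not in SEGMENT_SCHEMES:
        raise ValueError(f"unknown scheme {scheme!r}; choose from {sorted(SEGMENT_SCHEMES)}")
    mapping = SEGMENT_SCHEMES[scheme]
    unknown = set(info["segment"]) - set(mapping)
    if unknown:
        raise ValueError(f"unknown segment label(s): {sorted(unknown)}")
    out = info.copy()
    out["segment_class"] = out["segment"].map(mapping)
    return out
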