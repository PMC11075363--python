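"""Lightweight genomic-interval utilities.

All coordinates are 0-based half-open. Interval sets are plain pandas
DataFrames with columns ``chrom``, ``start``, ``end`` (plus optional
``name``/``score``), kept sorted by (chrom, start, end).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

REGION_COLUMNS = ["chrom", "start", "end"]


def as_regions(df: pd.DataFrame) -> pd.DataFrame:
    """Validate and canonically sort an interval DataFrame."""
    missing = [c for c in REGION_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"interval frame lacks columns: {missing}")
    out = df.copy()
    out["start"] = out["start"].astype(np.int64)
    out["end"] = out["end"].astype(np.int64)
    if (out["start"] >= out["end"]).any():
        raise ValueError("intervals must satisfy start < end")
    return out.sort_values(REGION_COLUMNS, kind="mergesort").reset_index(drop=True)


def merge_intervals(regions: pd.DataFrame, gap_bp: int = 0) -> pd.DataFrame:
    """Union intervals whose gap is <= gap_bp (inclusive), per chromosome."""
    regions = as_regions(regions)
    rows = []
    for chrom, sub in regions.groupby("chrom", sort=True):
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        cur_s, cur_e = starts[0], ends[0]
        for s, e in zip(starts[1:], ends[1:]):
            if s - cur_e <= gap_bp:
                cur_e = max(cur_e, e)
            else:
                rows.append((chrom, cur_s, cur_e))
                cur_s, cur_e = s, e
        rows.append((chrom, cur_s, cur_e))
    return pd.DataFrame(rows, columns=REGION_COLUMNS)


def overlaps_any(query: pd.DataFrame, target: pd.DataFrame) -> np.ndarray:
    """Boolean flag per query interval: does it overlap (>=1 bp) any target?

    Targets are merged first so a searchsorted test against disjoint
    intervals suffices.
    """
    query = as_regions(query)
    target = merge_intervals(target, gap_bp=-1) if len(target) else target
    flags = np.zeros(len(query), dtype=bool)
    if len(target) == 0:
        return flags
    by_chrom = {c: s for c, s in target.groupby("chrom")}
    for chrom, sub in query.groupby("chrom"):
        tgt = by_chrom.get(chrom)
        if tgt is None:
            continue
        t_start = tgt["start"].to_numpy()
        t_end = tgt["end"].to_numpy()
        qs = sub["start"].to_numpy()
        qe = sub["end"].to_numpy()
        # candidate target: the last one starting before the query end
        idx = np.searchsorted(t_start, qe, side="left") - 1
        ok = idx >= 0
        hit = np.zeros(len(sub), dtype=bool)
        hit[ok] = t_end[idx[ok]] > qs[ok]
        flags[query.index.get_indexer(sub.index)] = hit
    return flags


def count_overlapping(query: pd.DataFrame, target: pd.DataFrame) -> int:
    """Number of query intervals overlapping the target set."""
    return int(overlaps_any(query, target).sum())


def contains(outer: tuple, inner: tuple) -> bool:
    """Does interval ``outer`` fully encompass ``inner`` (same chrom)?"""
    oc, os_, oe = outer
    ic, is_, ie = inner
    return oc == ic and os_ <= is_ and oe >= ie
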