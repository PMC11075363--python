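"""H3K27me3 domain statistics and region-overlap enrichment.

Broad histone peaks are merged into domains (gap <= 5 kb, inclusive),
quantified as RPKM (reads per kilobase of region per million mapped
library fragments), and called differential by the effect-size rule
|mean(PE) - mean(control)| / (sd(PE) + sd(control)) > 2. Region-set
enrichment is tested two ways: a Fisher exact test on universe elements
and a permutation test that relocates query intervals uniformly within
the genome space (length- and chromosome-preserving by default).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .intervals import as_regions, count_overlapping, merge_intervals, overlaps_any

DIFFERENTIAL_THRESHOLD = 2.0


def merge_domains(peaks: pd.DataFrame, gap_bp: int = 5000) -> pd.DataFrame:
    """Union peaks within +/- gap_bp (inclusive) into disjoint domains."""
    return merge_intervals(peaks, gap_bp=gap_bp)


def domain_rpkm(counts: pd.DataFrame, library_size: dict | None = None) -> pd.DataFrame:
    """RPKM per domain per sample: count / (length/1e3) / (libsize/1e6).

    ``counts`` is indexed by domain with one integer column per sample
    plus a ``length`` column; library sizes come from the argument or
    ``counts.attrs['library_size']``.
    """
    library_size = library_size or counts.attrs.get("library_size")
    if library_size is None:
        raise ValueError("library sizes required")
    samples = [c for c in counts.columns if c != "length"]
    length = counts["length"]
    if (length <= 0).any():
        raise ValueError("domain lengths must be > 0")
    out = pd.DataFrame(index=counts.index)
    for s in samples:
        lib = library_size[s]
        if lib <= 0:
            raise ValueError(f"library size for {s} must be > 0")
        out[s] = counts[s] / (length / 1e3) / (lib / 1e6)
    return out


def differential_domains(
    rpkm: pd.DataFrame,
    groups: dict,
    threshold: float = DIFFERENTIAL_THRESHOLD,
) -> pd.DataFrame:
    """Label each domain PE_gain / PE_lost / unchanged.

    statistic s = |mean_PE - mean_ctrl| / (sd_PE + sd_ctrl) with sample
    (ddof=1) standard deviations; differential iff s > threshold, the
    direction given by the sign of the mean difference. When both sds
    are zero the statistic is infinite if the means differ (flagged in
    ``degenerate``) and the domain is unchanged otherwise.
    """
    pe = [s for s, g in groups.items() if g == "PE"]
    ctrl = [s for s, g in groups.items() if g == "control"]
    if len(pe) < 2 or len(ctrl) < 2:
        raise ValueError("need >=2 samples per group")
    m_pe = rpkm[pe].mean(axis=1)
    m_ct = rpkm[ctrl].mean(axis=1)
    sd_sum = rpkm[pe].std(axis=1, ddof=1) + rpkm[ctrl].std(axis=1, ddof=1)
    diff = m_pe - m_ct
    with np.errstate(divide="ignore", invalid="ignore"):
        s = np.abs(diff) / sd_sum
    s = np.where((sd_sum == 0) & (diff != 0), np.inf, np.where(sd_sum == 0, 0.0, s))
    label = np.where(
        s > threshold, np.where(diff > 0, "PE_gain", "PE_lost"), "unchanged"
    )
    return pd.DataFrame(
        {
            "mean_PE": m_pe,
            "mean_control": m_ct,
            "statistic": s,
            "label": label,
            "degenerate": (sd_sum == 0) & (diff != 0),
        },
        index=rpkm.index,
    )


def fisher_region_enrichment(
    query: pd.DataFrame, target: pd.DataFrame, universe: pd.DataFrame
) -> dict:
    """Fisher exact enrichment of query elements among target-overlappers.

    The 2x2 table partitions universe elements by {in query} x
    {overlaps target by >= 1 bp}; query membership is by exact
    (chrom, start, end) identity. Returns the sample odds ratio and the
    two-sided p.
    """
    universe = as_regions(universe)
    if len(universe) == 0:
        raise ValueError("universe must be non-empty")
    query_keys = set(map(tuple, as_regions(query)[["chrom", "start", "end"]].to_numpy()))
    in_query = np.array(
        [tuple(r) in query_keys for r in universe[["chrom", "start", "end"]].to_numpy()]
    )
    hits = overlaps_any(universe, target)
    a = int((in_query & hits).sum())
    b = int((in_query & ~hits).sum())
    c = int((~in_query & hits).sum())
    d = int((~in_query & ~hits).sum())
    table = np.array([[a, b], [c, d]])
    _, p = stats.fisher_exact(table, alternative="two-sided")
    odds = (a * d) / (b * c) if b * c > 0 else float("inf") if a * d > 0 else float("nan")
    return {"table": table, "odds_ratio": float(odds), "p_value": float(p)}


def permutation_overlap_z(
    query: pd.DataFrame,
    target: pd.DataFrame,
    genome_space: pd.DataFrame,
    n_perm: int = 1000,
    seed: int = 0,
    preserve_chromosome: bool = True,
) -> dict:
    """Permutation enrichment of query-target element overlap.

    observed = number of query intervals overlapping the target set.
    Each permutation relocates every query interval uniformly at random
    within the genome space, preserving its length; the chromosome is
    kept (default) or redrawn weighted by chromosome length.
    z = (observed - mean_perm) / sd_perm; the empirical p is
    (1 + #{perm >= observed}) / (n_perm + 1), greater-than alternative.
    ``genome_space`` has columns chrom, length.
    """
    query = as_regions(query)
    space = {r["chrom"]: int(r["length"]) for _, r in genome_space.iterrows()}
    lengths = (query["end"] - query["start"]).to_numpy()
    chroms = query["chrom"].to_numpy()
    for ch, ln in zip(chroms, lengths):
        if ch not in space:
            raise ValueError(f"chromosome {ch} absent from genome space")
        if space[ch] < ln:
            raise ValueError("genome-space chromosome shorter than a query interval")

    observed = count_overlapping(query, target)
    rng = np.random.default_rng(seed)

    # merged target per chromosome for fast vectorized overlap tests
    tgt = merge_intervals(target, gap_bp=-1) if len(target) else target
    tgt_by_chrom = {c: (s["start"].to_numpy(), s["end"].to_numpy()) for c, s in tgt.groupby("chrom")} if len(tgt) else {}

    chrom_names = list(space)
    chrom_len = np.array([space[c] for c in chrom_names], dtype=float)
    chrom_p = chrom_len / chrom_len.sum()

    perm_counts = np.zeros(n_perm, dtype=int)
    for ci, ch in enumerate(chrom_names):
        if preserve_chromosome:
            sel = chroms == ch
            if not sel.any():
                continue
            lens = np.broadcast_to(lengths[sel], (n_perm, int(sel.sum())))
        else:
            # number of intervals landing on this chromosome varies per perm
            pass
        if preserve_chromosome:
            starts = (rng.random(lens.shape) * (space[ch] - lens + 1)).astype(np.int64)
            hits = _overlap_matrix(starts, starts + lens, tgt_by_chrom.get(ch))
            perm_counts += hits
    if not preserve_chromosome:
        for b in range(n_perm):
            new_chrom = rng.choice(len(chrom_names), size=len(query), p=chrom_p)
            # redraw until the interval fits its chromosome
            for qi in range(len(query)):
                while chrom_len[new_chrom[qi]] < lengths[qi]:
                    new_chrom[qi] = rng.choice(len(chrom_names), p=chrom_p)
            starts = (
                rng.random(len(query)) * (chrom_len[new_chrom] - lengths + 1)
            ).astype(np.int64)
            n_hit = 0
            for qi in range(len(query)):
                t = tgt_by_chrom.get(chrom_names[new_chrom[qi]])
                if t is not None:
                    s, e = starts[qi], starts[qi] + lengths[qi]
                    idx = np.searchsorted(t[0], e, side="left") - 1
                    if idx >= 0 and t[1][idx] > s:
                        n_hit += 1
            perm_counts[b] = n_hit

    mean_perm = float(perm_counts.mean())
    sd_perm = float(perm_counts.std(ddof=1))
    z = (observed - mean_perm) / sd_perm if sd_perm > 0 else float("nan")
    p_emp = (1 + int((perm_counts >= observed).sum())) / (n_perm + 1)
    return {
        "observed": int(observed),
        "perm_mean": mean_perm,
        "perm_sd": sd_perm,
        "z": z,
        "p_empirical": float(p_emp),
        "perm_counts": perm_counts,
    }


def _overlap_matrix(starts: np.ndarray, ends: np.ndarray, target) -> np.ndarray:
    """Per-row (permutation) count of intervals overlapping the target.

    starts/ends are (n_perm, n_intervals); target is (t_start, t_end)
    arrays of disjoint sorted intervals or None.
    """
    if target is None:
        return np.zeros(starts.shape[0], dtype=int)
    t_start, t_end = target
    idx = np.searchsorted(t_start, ends, side="left") - 1
    ok = idx >= 0
    hit = np.zeros(starts.shape, dtype=bool)
    hit[ok] = t_end[idx[ok]] > starts[ok]
    return hit.sum(axis=1)
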