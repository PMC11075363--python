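"""Differentially methylated region (DMR) calling.

The pipeline mirrors a capture-bisulfite workflow comparing preeclamptic
(PE) with non-preeclamptic (nonPE) placentas:

1. ``call_dml`` — per-CpG Welch t-test; a differentially methylated locus
   (DML) needs p < 0.01 and |delta beta| > 0.1, where
   delta beta = mean(PE) - mean(nonPE).
2. ``merge_dml`` — DMLs within 100 bp are merged into candidate regions.
3. ``seed_dmr`` — per candidate, betas are averaged over the covered CpGs
   per sample and re-tested; p < 0.01 candidates become "seed" DMRs.
4. ``segment_delta`` — circular binary segmentation (CBS) of the per-CpG
   delta-beta track per chromosome with a permutation reference.
5. ``cluster_segments`` — exact 1-D k-means on segment mean delta beta.
6. ``finalize_dmr`` — clusters holding a segment that fully encompasses a
   seed are selected; each seed-encompassing segment with
   |mean delta beta| above the DML effect threshold becomes a DMR,
   classified hypo (PE lower) or hyper (PE higher).

Coordinates: input CpG positions are 1-based; every emitted interval is
0-based half-open (BED convention). No multiple-testing correction is
applied at the DML stage (raw p < 0.01).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

DML_P = 0.01
DML_DELTA = 0.1


@dataclass
class Segment:
    chrom: str
    start: int  # 0-based half-open, genomic
    end: int
    mean_delta_beta: float
    n_cpg: int
    cluster_id: int = -1


@dataclass
class DMRRecord:
    chrom: str
    start: int
    end: int
    direction: str  # hypo = PE lower, hyper = PE higher
    mean_delta_beta: float
    n_cpg: int
    cluster_id: int
    seed_ids: list = field(default_factory=list)
    segment_ids: list = field(default_factory=list)


def _group_columns(table: pd.DataFrame, groups: dict) -> tuple[list, list]:
    pe = [s for s, g in groups.items() if g == "PE"]
    non = [s for s, g in groups.items() if g == "nonPE"]
    if len(pe) < 2 or len(non) < 2:
        raise ValueError("need >=2 samples per group")
    missing = [s for s in pe + non if s not in table.columns]
    if missing:
        raise ValueError(f"samples absent from table: {missing}")
    return pe, non


def call_dml(
    table: pd.DataFrame,
    groups: dict,
    p_threshold: float = DML_P,
    delta_threshold: float = DML_DELTA,
) -> pd.DataFrame:
    """Per-CpG Welch t-test between PE and nonPE beta values.

    Parameters
    ----------
    table : DataFrame with ``chrom``, ``pos`` (1-based) and one beta column
        per sample; missing betas as NaN.
    groups : sample -> {"PE", "nonPE"}.

    Returns a DataFrame (chrom, pos, delta_beta, p_value) containing
    exactly the loci passing both thresholds. CpGs with fewer than two
    non-missing betas in either group are skipped (count logged).
    """
    pe_cols, non_cols = _group_columns(table, groups)
    a = table[pe_cols].to_numpy(dtype=float)
    b = table[non_cols].to_numpy(dtype=float)

    n_a = np.sum(~np.isnan(a), axis=1)
    n_b = np.sum(~np.isnan(b), axis=1)
    testable = (n_a >= 2) & (n_b >= 2)
    n_skipped = int((~testable).sum())
    if n_skipped:
        logger.info("call_dml: skipped %d CpGs with <2 betas in a group", n_skipped)

    with np.errstate(invalid="ignore", divide="ignore"):
        res = stats.ttest_ind(a, b, axis=1, equal_var=False, nan_policy="omit")
        delta = np.nanmean(a, axis=1) - np.nanmean(b, axis=1)
    p = np.asarray(res.pvalue, dtype=float)
    # zero within-group variance in both groups with equal means -> p = 1
    p = np.where(np.isnan(p) & (delta == 0), 1.0, p)

    keep = testable & (p < p_threshold) & (np.abs(delta) > delta_threshold)
    out = table.loc[keep, ["chrom", "pos"]].copy()
    out["delta_beta"] = delta[keep]
    out["p_value"] = p[keep]
    return out.reset_index(drop=True)


def merge_dml(dmls: pd.DataFrame, gap_bp: int = 100) -> pd.DataFrame:
    """Merge DMLs whose successive gaps are <= gap_bp into candidates.

    Returns intervals (chrom, start, end) in 0-based half-open coordinates:
    [first_pos - 1, last_pos). Singleton DMLs yield 1-bp candidates.
    """
    if len(dmls) == 0:
        return pd.DataFrame(columns=["chrom", "start", "end", "n_dml"])
    dmls = dmls.sort_values(["chrom", "pos"], kind="mergesort")
    rows = []
    for chrom, sub in dmls.groupby("chrom", sort=True):
        pos = sub["pos"].to_numpy()
        breaks = np.where(np.diff(pos) > gap_bp)[0]
        start_idx = np.concatenate(([0], breaks + 1))
        end_idx = np.concatenate((breaks, [len(pos) - 1]))
        for i0, i1 in zip(start_idx, end_idx):
            rows.append((chrom, int(pos[i0] - 1), int(pos[i1]), int(i1 - i0 + 1)))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "n_dml"])


def seed_dmr(
    candidates: pd.DataFrame,
    table: pd.DataFrame,
    groups: dict,
    p_threshold: float = DML_P,
) -> pd.DataFrame:
    """Average-beta t-test per candidate; keep p < 0.01 as seed DMRs."""
    pe_cols, non_cols = _group_columns(table, groups)
    rows = []
    for _, cand in candidates.iterrows():
        sel = (
            (table["chrom"] == cand["chrom"])
            & (table["pos"] - 1 >= cand["start"])
            & (table["pos"] - 1 < cand["end"])
        )
        sub = table.loc[sel]
        assert len(sub) >= 1, "candidate covers no CpG"
        mean_pe = sub[pe_cols].mean(axis=0, skipna=True)
        mean_non = sub[non_cols].mean(axis=0, skipna=True)
        t = stats.ttest_ind(mean_pe, mean_non, equal_var=False, nan_policy="omit")
        if t.pvalue < p_threshold:
            rows.append(
                (
                    cand["chrom"],
                    int(cand["start"]),
                    int(cand["end"]),
                    float(mean_pe.mean() - mean_non.mean()),
                    float(t.pvalue),
                )
            )
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "mean_delta_beta", "p_value"])


# ---------------------------------------------------------------------------
# circular binary segmentation
# ---------------------------------------------------------------------------


def _arc_weights(n: int) -> tuple[np.ndarray, np.ndarray]:
    """Cached (weight, drift) matrices for arc statistics at track length n.

    weight[i, j] = sqrt(n / (k (n-k))) and drift[i, j] = k / n with
    k = j - i; invalid pairs (k < 1 or k > n-1) carry weight 0.
    """
    idx = np.arange(n + 1)
    K = idx[None, :] - idx[:, None]  # K[i, j] = j - i
    valid = (K >= 1) & (K <= n - 1)
    Ksafe = np.where(valid, K, 1)
    with np.errstate(divide="ignore"):
        W = np.where(valid, np.sqrt(n / (Ksafe * (n - Ksafe))), 0.0)
    return W, K / n


def _max_arc_stat(x: np.ndarray, W: np.ndarray, F: np.ndarray) -> tuple[float, int, int]:
    """Best circular arc split of x.

    For every arc [i, j) (its complement wraps around, so linear pairs
    cover all circular two-arc splits), the statistic is
    |mean_arc - mean_rest| * sqrt(k (n-k) / n). The variance denominator
    is omitted: permutations of the same values share it, so it cancels
    in both the argmax and the permutation comparison.
    """
    S = np.concatenate(([0.0], np.cumsum(x)))
    stat = np.abs((S[None, :] - S[:, None]) - F * S[-1]) * W
    i, j = np.unravel_index(int(np.argmax(stat)), stat.shape)
    return float(stat[i, j]), int(i), int(j)


def _max_arc_value(x: np.ndarray, W: np.ndarray, F: np.ndarray) -> float:
    """Max arc statistic only (used for permutations)."""
    S = np.concatenate(([0.0], np.cumsum(x)))
    return float(np.max(np.abs((S[None, :] - S[:, None]) - F * S[-1]) * W))


def _segment_one(
    x: np.ndarray,
    lo: int,
    hi: int,
    alpha: float,
    nperm: int,
    rng: np.random.Generator,
    breakpoints: list,
) -> None:
    """Recursive CBS on x[lo:hi]; appends accepted changepoints."""
    n = hi - lo
    if n < 4:
        return
    sub = x[lo:hi]
    W, F = _arc_weights(n)
    obs, i, j = _max_arc_stat(sub, W, F)
    if not np.isfinite(obs) or obs <= 0:
        return
    # permutation reference with early rejection: once the exceedance
    # count guarantees p > alpha, stop permuting
    reject_at = int(np.floor(alpha * (nperm + 1)))  # p <= alpha iff exceed < reject_at
    if reject_at == 0:
        return  # alpha below the permutation resolution: nothing can pass
    exceed = 0
    perm = sub.copy()
    for _ in range(nperm):
        rng.shuffle(perm)
        if _max_arc_value(perm, W, F) >= obs:
            exceed += 1
            if exceed >= reject_at:
                return
    # significant split: changepoints at i and j (skip trivial edges)
    cuts = sorted({i, j} - {0, n})
    if not cuts:
        return
    pieces = [0] + cuts + [n]
    for c in cuts:
        breakpoints.append(lo + c)
    for a, b in zip(pieces[:-1], pieces[1:]):
        _segment_one(x, lo + a, lo + b, alpha, nperm, rng, breakpoints)


def segment_delta(
    table: pd.DataFrame,
    groups: dict,
    alpha: float = 0.01,
    nperm: int = 1000,
    seed: int = 0,
) -> list[Segment]:
    """CBS of the ordered per-CpG delta-beta track, per chromosome.

    Accepted splits require permutation p <= alpha. Chromosomes with
    fewer than 4 CpGs form a single segment. Segments tile each
    chromosome in CpG-index space; genomic bounds span from the first
    to the last CpG of the run.
    """
    pe_cols, non_cols = _group_columns(table, groups)
    rng = np.random.default_rng(seed)
    segments: list[Segment] = []
    for chrom, sub in table.groupby("chrom", sort=True):
        sub = sub.sort_values("pos")
        delta = (
            sub[pe_cols].mean(axis=1, skipna=True)
            - sub[non_cols].mean(axis=1, skipna=True)
        ).to_numpy()
        pos = sub["pos"].to_numpy()
        n = len(delta)
        breakpoints: list[int] = []
        if n >= 4:
            _segment_one(delta, 0, n, alpha, nperm, rng, breakpoints)
        bounds = [0] + sorted(breakpoints) + [n]
        for a, b in zip(bounds[:-1], bounds[1:]):
            segments.append(
                Segment(
                    chrom=chrom,
                    start=int(pos[a] - 1),
                    end=int(pos[b - 1]),
                    mean_delta_beta=float(np.mean(delta[a:b])),
                    n_cpg=int(b - a),
                )
            )
    return segments


# ---------------------------------------------------------------------------
# clustering and finalization
# ---------------------------------------------------------------------------


def _kmeans_1d(values: np.ndarray, k: int) -> np.ndarray:
    """Exact 1-D k-means by dynamic programming on the sorted values.

    Returns cluster labels (0..k-1) ordered by ascending centroid. The
    optimum of 1-D k-means is a contiguous partition of the sorted
    sequence, so a DP over split points finds it exactly — the result is
    deterministic and invariant to input order.
    """
    n = len(values)
    order = np.argsort(values, kind="mergesort")
    x = values[order]
    S = np.concatenate(([0.0], np.cumsum(x)))
    S2 = np.concatenate(([0.0], np.cumsum(x * x)))

    def sse(i, j):  # cost of cluster x[i:j]
        s = S[j] - S[i]
        return (S2[j] - S2[i]) - s * s / (j - i)

    INF = np.inf
    cost = np.full((k + 1, n + 1), INF)
    back = np.zeros((k + 1, n + 1), dtype=int)
    cost[0, 0] = 0.0
    for m in range(1, k + 1):
        for j in range(m, n + 1):
            best, arg = INF, m - 1
            for i in range(m - 1, j):
                c = cost[m - 1, i] + sse(i, j)
                if c < best:
                    best, arg = c, i
            cost[m, j] = best
            back[m, j] = arg
    labels_sorted = np.empty(n, dtype=int)
    j = n
    for m in range(k, 0, -1):
        i = back[m, j]
        labels_sorted[i:j] = m - 1
        j = i
    labels = np.empty(n, dtype=int)
    labels[order] = labels_sorted
    return labels


def cluster_segments(segments: list[Segment], k: int = 6, seed: int = 0) -> list[Segment]:
    """k-means on the scalar mean delta beta of each segment.

    Solved exactly by dynamic programming in 1-D, so the assignment is
    deterministic and order-invariant; cluster ids are ordered by
    ascending centroid. ``seed`` is accepted for API stability but the
    exact solver needs no randomness.
    """
    if k > len(segments):
        raise ValueError(f"k={k} exceeds number of segments ({len(segments)})")
    values = np.array([s.mean_delta_beta for s in segments])
    labels = _kmeans_1d(values, k)
    # relabel by ascending centroid (DP labels already sorted, but be safe)
    centroids = [values[labels == c].mean() for c in range(k)]
    rank = np.argsort(np.argsort(centroids))
    out = []
    for seg, lab in zip(segments, labels):
        seg = Segment(**{**seg.__dict__})
        seg.cluster_id = int(rank[lab])
        out.append(seg)
    return out


def finalize_dmr(
    segments: list[Segment],
    seeds: pd.DataFrame,
    min_delta: float = DML_DELTA,
) -> list[DMRRecord]:
    """Select DMRs: clusters holding seed-encompassing segments.

    A cluster is selected when at least one of its segments fully
    encompasses (contains) a seed interval; within selected clusters,
    every seed-encompassing segment with |mean delta beta| > ``min_delta``
    becomes a DMR. The effect guard keeps chance whole-chromosome
    segments (mean delta near 0) from swallowing isolated seeds.
    """
    if any(s.cluster_id < 0 for s in segments):
        raise ValueError("segments must carry cluster ids (run cluster_segments)")
    seed_hits: dict[int, list[int]] = {}
    for si, seg in enumerate(segments):
        for qi, seed in seeds.iterrows():
            if (
                seg.chrom == seed["chrom"]
                and seg.start <= seed["start"]
                and seg.end >= seed["end"]
            ):
                seed_hits.setdefault(si, []).append(qi)
    if not seed_hits:
        logger.warning("finalize_dmr: no seed encompassed by any segment")
        return []
    selected_clusters = {segments[si].cluster_id for si in seed_hits}
    dmrs = []
    for si, qids in sorted(seed_hits.items()):
        seg = segments[si]
        if seg.cluster_id not in selected_clusters:
            continue
        if abs(seg.mean_delta_beta) <= min_delta:
            continue
        dmrs.append(
            DMRRecord(
                chrom=seg.chrom,
                start=seg.start,
                end=seg.end,
                direction="hypo" if seg.mean_delta_beta < 0 else "hyper",
                mean_delta_beta=seg.mean_delta_beta,
                n_cpg=seg.n_cpg,
                cluster_id=seg.cluster_id,
                seed_ids=list(qids),
                segment_ids=[si],
            )
        )
    return dmrs


def call_dmrs(
    table: pd.DataFrame,
    groups: dict,
    k: int = 6,
    alpha: float = 0.01,
    nperm: int = 1000,
    seed: int = 0,
    gap_bp: int = 100,
) -> dict:
    """Run the full DML -> merge -> seed -> CBS -> cluster -> finalize chain."""
    dmls = call_dml(table, groups)
    candidates = merge_dml(dmls, gap_bp=gap_bp)
    seeds = seed_dmr(candidates, table, groups)
    segments = segment_delta(table, groups, alpha=alpha, nperm=nperm, seed=seed)
    k_eff = min(k, len(segments))
    segments = cluster_segments(segments, k=k_eff, seed=seed)
    dmrs = finalize_dmr(segments, seeds)
    return {
        "dmls": dmls,
        "candidates": candidates,
        "seeds": seeds,
        "segments": segments,
        "dmrs": dmrs,
    }


def conversion_qc(chh_fraction: pd.Series, threshold: float = 0.99) -> pd.DataFrame:
    """Bisulfite conversion QC: pass iff unmethylated-CHH fraction > 0.99."""
    if ((chh_fraction.dropna() < 0) | (chh_fraction.dropna() > 1)).any():
        raise ValueError("CHH fractions must lie in [0, 1]")
    passed = chh_fraction > threshold  # NaN compares False
    reason = np.where(
        chh_fraction.isna(),
        "missing CHH fraction",
        np.where(passed, "", f"CHH fraction <= {threshold}"),
    )
    return pd.DataFrame({"chh_fraction": chh_fraction, "pass": passed, "reason": reason})


def interval_recall(truth: pd.DataFrame, called: pd.DataFrame) -> float:
    """Fraction of planted DMR bases covered by called DMR intervals."""
    if len(truth) == 0:
        return float("nan")
    covered = 0
    total = 0
    for _, t in truth.iterrows():
        total += t["end"] - t["start"]
        sub = called[called["chrom"] == t["chrom"]] if len(called) else called
        for _, c in (sub.iterrows() if len(sub) else []):
            lo = max(t["start"], c["start"])
            hi = min(t["end"], c["end"])
            if hi > lo:
                covered += hi - lo
    return covered / total
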