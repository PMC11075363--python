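"""Single-cell expression statistics.

Rank-sum differential expression with expressed-fraction bookkeeping,
bin-matched gene-set module scores, maternal/fetal origin assignment,
and the imprinted-gene direction summary.

Conventions
-----------
Normalization is log1p of library-size-scaled counts (scale 1e4). Fold
changes are stored in natural log — ``log_fc = ln((mean expm1 + 1)_a /
(mean expm1 + 1)_b)`` — matching the convention of the single-cell
toolkit generation that used natural-log ``avg_logFC``; ``log2_fc`` is
derived from it for the printed log2-based significance rule
(Bonferroni-adjusted p < 0.05 and |log2FC| > 0.5). Bonferroni
correction runs over tested genes only.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from anndata import AnnData
from scipy import sparse, stats

logger = logging.getLogger(__name__)

DE_PADJ = 0.05
DE_LOG2FC = 0.5
NORM_SCALE = 1e4


def lognormalize(adata: AnnData, layer: str | None = None) -> np.ndarray:
    """log1p(counts / libsize * 1e4) as a dense array (cells x genes)."""
    X = adata.layers[layer] if layer else adata.X
    X = X.toarray() if sparse.issparse(X) else np.asarray(X, dtype=float)
    lib = X.sum(axis=1, keepdims=True)
    lib[lib == 0] = 1.0
    return np.log1p(X / lib * NORM_SCALE)


def _pct_expressed(X: np.ndarray, mask: np.ndarray) -> np.ndarray:
    return (X[mask] > 0).mean(axis=0)


def wilcoxon_de(
    adata: AnnData,
    groupby: str,
    group_a: str,
    group_b: str | None = None,
    min_pct: float = 0.1,
    layer: str | None = None,
) -> pd.DataFrame:
    """Two-sided rank-sum differential expression, group_a vs group_b/rest.

    Genes whose expressed fraction reaches ``min_pct`` in either group
    are tested on log-normalized expression; genes expressed in no cell
    are skipped. Returns a DataFrame with gene, log_fc (natural log),
    log2_fc, pct1, pct2, p_value, p_adj (Bonferroni over tested genes)
    and a ``significant`` flag at the p_adj < 0.05, |log2FC| > 0.5 rule.
    """
    labels = adata.obs[groupby].astype(str)
    mask_a = (labels == str(group_a)).to_numpy()
    mask_b = (
        ~mask_a if group_b is None else (labels == str(group_b)).to_numpy()
    )
    if mask_a.sum() == 0 or mask_b.sum() == 0:
        raise ValueError("both groups must be non-empty")

    X = lognormalize(adata, layer=layer)
    pct1 = _pct_expressed(X, mask_a)
    pct2 = _pct_expressed(X, mask_b)
    expressed = (pct1 > 0) | (pct2 > 0)
    tested = expressed & (np.maximum(pct1, pct2) >= min_pct)
    if not tested.any():
        return pd.DataFrame(
            columns=["gene", "log_fc", "log2_fc", "pct1", "pct2", "p_value", "p_adj", "significant"]
        )

    Xa, Xb = X[mask_a][:, tested], X[mask_b][:, tested]
    res = stats.mannwhitneyu(
        Xa, Xb, axis=0, alternative="two-sided", method="asymptotic", use_continuity=True
    )
    p = np.asarray(res.pvalue, dtype=float)
    # identical constant columns yield sd 0 -> scipy returns NaN; no evidence
    p = np.where(np.isnan(p), 1.0, p)

    mean_a = np.expm1(Xa).mean(axis=0)
    mean_b = np.expm1(Xb).mean(axis=0)
    log_fc = np.log(mean_a + 1) - np.log(mean_b + 1)
    n_tested = int(tested.sum())
    p_adj = np.minimum(p * n_tested, 1.0)

    out = pd.DataFrame(
        {
            "gene": np.asarray(adata.var_names)[tested],
            "log_fc": log_fc,
            "log2_fc": log_fc / np.log(2),
            "pct1": pct1[tested],
            "pct2": pct2[tested],
            "p_value": p,
            "p_adj": p_adj,
        }
    )
    out["significant"] = (out["p_adj"] < DE_PADJ) & (out["log2_fc"].abs() > DE_LOG2FC)
    return out.reset_index(drop=True)


def select_origin_markers(
    de_fetal_vs_maternal: pd.DataFrame,
    p_adj_max: float = 0.001,
    logfc_min: float = 1.0,
    dpct_min: float = 0.3,
) -> dict:
    """Pick origin marker genes from a fetal-vs-maternal DE table.

    A marker satisfies p_adj < 0.001, |avg_logFC| > 1 (natural log) and
    |pct1 - pct2| > 0.3; the sign of the fold change decides the set
    (positive -> fetal, negative -> maternal, for DE computed fetal vs
    maternal).
    """
    de = de_fetal_vs_maternal
    ok = (
        (de["p_adj"] < p_adj_max)
        & (de["log_fc"].abs() > logfc_min)
        & ((de["pct1"] - de["pct2"]).abs() > dpct_min)
    )
    fetal = sorted(de.loc[ok & (de["log_fc"] > 0), "gene"])
    maternal = sorted(de.loc[ok & (de["log_fc"] < 0), "gene"])
    if not fetal or not maternal:
        logger.warning(
            "select_origin_markers: empty marker set (fetal=%d, maternal=%d)",
            len(fetal),
            len(maternal),
        )
    return {"fetal_markers": fetal, "maternal_markers": maternal}


def module_score(
    adata: AnnData,
    gene_set: list,
    n_bins: int = 24,
    n_ctrl: int = 100,
    seed: int = 0,
    layer: str | None = None,
) -> pd.Series:
    """Bin-matched gene-set activity score per cell.

    Genes are ranked by mean log-normalized expression across cells and
    cut into ``n_bins`` equal-frequency bins (ties broken by gene name,
    so the score is invariant to gene and cell order). For each set
    gene, ``n_ctrl`` control genes are drawn from its bin (with
    replacement when the bin is smaller); the score is mean expression
    over the set minus mean over the pooled controls.
    """
    genes = list(adata.var_names)
    present = [g for g in gene_set if g in set(genes)]
    dropped = set(gene_set) - set(present)
    if dropped:
        logger.warning("module_score: dropping absent genes: %s", sorted(dropped))
    if not present:
        raise ValueError("gene_set has no genes present in the matrix")

    X = lognormalize(adata, layer=layer)
    avg = X.mean(axis=0)
    order = np.lexsort((np.asarray(genes), avg))  # ascending avg, name tie-break
    rank = np.empty(len(genes), dtype=int)
    rank[order] = np.arange(len(genes))
    bins = np.minimum((rank * n_bins) // len(genes), n_bins - 1)
    gene_idx = {g: i for i, g in enumerate(genes)}

    rng = np.random.default_rng(seed)
    ctrl_idx = []
    for g in sorted(present):  # sorted: independent of caller's set order
        b = bins[gene_idx[g]]
        # pool ordered by gene name so sampling is gene-order invariant
        pool = np.array(sorted(np.where(bins == b)[0], key=lambda i: genes[i]))
        replace = len(pool) < n_ctrl
        ctrl_idx.append(rng.choice(pool, size=n_ctrl, replace=replace))
    ctrl_idx = np.concatenate(ctrl_idx)
    set_idx = np.array([gene_idx[g] for g in present])

    score = X[:, set_idx].mean(axis=1) - X[:, ctrl_idx].mean(axis=1)
    return pd.Series(score, index=adata.obs_names, name="module_score")


def assign_origin(score_maternal: pd.Series, score_fetal: pd.Series) -> pd.Series:
    """Per-cell origin label: argmax of the two module scores; tie -> unassigned."""
    sm, sf = score_maternal.align(score_fetal)
    label = np.where(sf > sm, "fetal", np.where(sm > sf, "maternal", "unassigned"))
    return pd.Series(label, index=sm.index, name="origin")


def imprint_direction_summary(
    de: pd.DataFrame,
    annotation: pd.DataFrame,
    p_adj_max: float = DE_PADJ,
    log2fc_min: float = DE_LOG2FC,
) -> dict:
    """Up/down counts of significant imprinted genes by expressed allele.

    ``annotation`` maps gene -> expressed_allele in {maternal, paternal}
    (experimentally validated imprints only). Significant genes
    (p_adj < 0.05, |log2FC| > 0.5) are classified up/down by fold-change
    sign; a two-sided Fisher exact test runs on the 2x2
    {paternal, maternal} x {up, down} table. With an empty allele class
    the p-value is NaN and only counts are reported.
    """
    ann = annotation.set_index("gene")["expressed_allele"]
    sig = de[(de["p_adj"] < p_adj_max) & (de["log2_fc"].abs() > log2fc_min)].copy()
    sig = sig[sig["gene"].isin(ann.index)]
    sig["expressed_allele"] = sig["gene"].map(ann)
    sig["direction"] = np.where(sig["log2_fc"] > 0, "up", "down")
    counts = (
        sig.groupby(["expressed_allele", "direction"])
        .size()
        .unstack(fill_value=0)
        .reindex(index=["paternal", "maternal"], columns=["up", "down"], fill_value=0)
    )
    table = counts.to_numpy()
    if (table.sum(axis=1) == 0).any():
        p, odds = float("nan"), float("nan")
    else:
        odds, p = stats.fisher_exact(table, alternative="two-sided")
    return {"counts": counts, "odds_ratio": float(odds), "p_value": float(p), "genes": sig}
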