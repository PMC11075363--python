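"""Virus-like-particle (VLP) cargo-gene analysis.

A cargo gene is a transcript present in a receiver cell type (placental
endothelium) whose genomic locus is chromatin-inaccessible there —
consistent with trans-cellular RNA delivery rather than local
transcription. This module implements the cargo filter with a
per-criterion audit trail, the 3' UTR read-bias statistic, allele-of-
origin tracing at a trio-informative SNP, seeded UTR motif discovery,
PWM similarity with a background Z-score, and cargo expression-profile
correlation between cell types.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

INACCESSIBILITY_EPSILON = 0.01
FETAL_CALL_THRESHOLD = 0.95
BASES = ("A", "C", "G", "T")


# ---------------------------------------------------------------------------
# cargo filter
# ---------------------------------------------------------------------------


def _criterion_de(de_row, logfc_min=0.5, padj_max=0.01, positive_only=False):
    if de_row is None:
        return False
    fc = de_row["log2_fc"]
    fc_ok = fc > logfc_min if positive_only else abs(fc) > logfc_min
    return bool(fc_ok or de_row["p_adj"] < padj_max)


def identify_cargo(
    de_endo: pd.DataFrame,
    de_troph: pd.DataFrame,
    accessibility: pd.DataFrame,
    mode: str = "all",
    endothelial_types: tuple = ("endothelial_PE", "endothelial_control"),
    trophoblast_type: str = "trophoblast",
    epsilon: float = INACCESSIBILITY_EPSILON,
) -> pd.DataFrame:
    """Select putative VLP cargo genes.

    mode="all": (|logFC_endo| > 0.5 OR p_adj_endo < 0.01) AND completely
    inaccessible chromatin in both PE and control endothelial cells.

    mode="pe_specific" additionally requires (logFC_endo > 0.5 OR
    p_adj_endo < 0.01), (logFC_troph > 0.5 OR p_adj_troph < 0.01) and an
    accessible trophoblast peak.

    "Completely inaccessible" = no called peak overlapping the gene
    region and per-cell fragment-presence score < epsilon in every
    endothelial type. Genes missing from the accessibility table are
    excluded (logged). Each row records which criteria fired so rejected
    genes report the rule they violate.
    """
    if mode not in ("all", "pe_specific"):
        raise ValueError(f"unknown mode: {mode}")
    endo = de_endo.set_index("gene")
    troph = de_troph.set_index("gene") if de_troph is not None else pd.DataFrame()
    acc = accessibility.set_index(["gene", "cell_type"])

    rows = []
    for gene in endo.index:
        try:
            endo_acc = [acc.loc[(gene, ct)] for ct in endothelial_types]
            troph_acc = acc.loc[(gene, trophoblast_type)]
        except KeyError:
            logger.info("identify_cargo: %s missing from accessibility table", gene)
            continue
        e = endo.loc[gene]
        t = troph.loc[gene] if gene in troph.index else None
        crit = {
            "endo_de": _criterion_de(e),
            "endo_de_up": _criterion_de(e, positive_only=True),
            "endo_inaccessible": all(
                (not a["accessible"]) and a["score"] < epsilon for a in endo_acc
            ),
            "troph_de_up": _criterion_de(t, positive_only=True) if t is not None else False,
            "troph_peak": bool(troph_acc["accessible"]),
        }
        if mode == "all":
            selected = crit["endo_de"] and crit["endo_inaccessible"]
            required = ["endo_de", "endo_inaccessible"]
        else:
            selected = (
                crit["endo_de_up"]
                and crit["troph_de_up"]
                and crit["troph_peak"]
                and crit["endo_inaccessible"]
            )
            required = ["endo_de_up", "troph_de_up", "troph_peak", "endo_inaccessible"]
        rows.append(
            {
                "gene": gene,
                "selected": selected,
                **crit,
                "violated": ";".join(c for c in required if not crit[c]),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# 3' UTR bias
# ---------------------------------------------------------------------------


def utr_bias(read_counts: pd.DataFrame, trophoblast_groups: tuple = ("fetal_trophoblast",)) -> dict:
    """3' UTR read fraction per cell group.

    ``read_counts`` has columns cell_group, five_utr, body, three_utr —
    one row per cell (or one aggregate row per group). The fraction is
    three_utr / total; groups with zero total reads report NaN. When
    multiple rows per group exist, a two-sided rank-sum test compares
    per-cell fractions between trophoblast and non-trophoblast groups.
    """
    if (read_counts[["five_utr", "body", "three_utr"]] < 0).to_numpy().any():
        raise ValueError("read counts must be non-negative")
    rc = read_counts.copy()
    total = rc[["five_utr", "body", "three_utr"]].sum(axis=1)
    rc["fraction_3utr"] = np.where(total > 0, rc["three_utr"] / total.replace(0, np.nan), np.nan)
    agg = rc.groupby("cell_group")[["five_utr", "body", "three_utr"]].sum()
    tot = agg.sum(axis=1)
    per_group = (agg["three_utr"] / tot.where(tot > 0)).rename("fraction_3utr")
    is_troph = rc["cell_group"].isin(trophoblast_groups)
    troph = rc.loc[is_troph, "fraction_3utr"].dropna()
    non = rc.loc[~is_troph, "fraction_3utr"].dropna()
    if len(troph) >= 2 and len(non) >= 2:
        res = stats.mannwhitneyu(non, troph, alternative="two-sided", method="asymptotic")
        p = float(res.pvalue)
    else:
        p = float("nan")
    return {
        "per_group": per_group,
        "per_cell": rc,
        "diff_non_minus_troph": float(non.mean() - troph.mean()) if len(troph) and len(non) else float("nan"),
        "p_value": p,
    }


# ---------------------------------------------------------------------------
# allele tracing
# ---------------------------------------------------------------------------


def trace_allele(
    reads: pd.DataFrame,
    trio: dict | None = None,
    fetal_threshold: float = FETAL_CALL_THRESHOLD,
) -> dict:
    """Trace the parental origin of transcripts at a trio-informative SNP.

    The paternal-specific allele is the base carried by father and
    progeny but absent from the mother. Per cell group, the paternal
    fraction = paternal-allele reads / informative reads (reads showing
    either parental allele); a group is called "fetal transcript" when
    the fraction exceeds ``fetal_threshold``. A trio in which the mother
    carries the candidate allele (or no such allele exists) raises an
    uninformative-trio error.
    """
    trio = trio or reads.attrs.get("trio")
    if trio is None:
        raise ValueError("trio genotypes required (argument or reads.attrs['trio'])")
    mother, father, progeny = (set(trio[k]) for k in ("mother", "father", "progeny"))
    candidates = (father & progeny) - mother
    if not candidates:
        raise ValueError(
            "uninformative trio: no allele carried by father and progeny but absent in mother"
        )
    if len(candidates) > 1:
        raise ValueError("ambiguous trio: multiple paternal-specific alleles")
    paternal = next(iter(candidates))
    maternal_alleles = mother

    rows = []
    for group, sub in reads.groupby("cell_group", sort=True):
        counts = sub["base"].value_counts().reindex(list(BASES), fill_value=0)
        informative = int(counts[paternal] + sum(counts[a] for a in maternal_alleles))
        frac = counts[paternal] / informative if informative else float("nan")
        rows.append(
            {
                "cell_group": group,
                **{f"n_{b}": int(counts[b]) for b in BASES},
                "n_informative": informative,
                "paternal_fraction": float(frac),
                "fetal_transcript": bool(informative and frac > fetal_threshold),
            }
        )
    return {
        "paternal_allele": paternal,
        "maternal_alleles": sorted(maternal_alleles),
        "per_group": pd.DataFrame(rows),
    }


# ---------------------------------------------------------------------------
# motif discovery and similarity
# ---------------------------------------------------------------------------


@dataclass
class MotifPWM:
    """Position weight matrix: (width, 4) probabilities over A, C, G, T."""

    matrix: np.ndarray

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != 4 or self.matrix.shape[0] < 4:
            raise ValueError("PWM must be (width>=4, 4)")
        if not np.allclose(self.matrix.sum(axis=1), 1.0):
            raise ValueError("PWM columns must sum to 1")

    @property
    def width(self) -> int:
        return self.matrix.shape[0]

    @property
    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.matrix.argmax(axis=1))


def _kmer_counts(seqs: list[str], width: int) -> dict:
    counts: dict[str, int] = {}
    for s in seqs:
        for i in range(len(s) - width + 1):
            w = s[i : i + width]
            counts[w] = counts.get(w, 0) + 1
    return counts


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def motif_discover(sequences: dict | list, width: int = 8, pseudocount: float = 0.25) -> MotifPWM:
    """PWM of the most over-represented width-mer family.

    Seed = the most frequent exact width-mer (ties broken
    lexicographically); all occurrences within Hamming distance
    <= floor(width/4) of the seed are aligned and base frequencies
    averaged with a pseudocount of 0.25 per base.
    """
    seqs = list(sequences.values()) if isinstance(sequences, dict) else list(sequences)
    if len(seqs) < 5:
        raise ValueError("need >=5 sequences")
    if any(len(s) < width for s in seqs):
        raise ValueError(f"every sequence must be >= {width} nt")
    counts = _kmer_counts(seqs, width)
    seed, n_seed = min(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    if n_seed < 2:
        raise ValueError("no width-mer occurs at least twice")
    max_dist = width // 4
    freq = np.full((width, 4), pseudocount)
    base_idx = {b: i for i, b in enumerate(BASES)}
    for w, c in counts.items():
        if _hamming(w, seed) <= max_dist:
            for k, b in enumerate(w):
                freq[k, base_idx[b]] += c
    return MotifPWM(freq / freq.sum(axis=1, keepdims=True))


def _column_corr(a: np.ndarray, b: np.ndarray) -> float:
    """Pearson r between two PWM columns; constant columns contribute 0."""
    if np.std(a) == 0 or np.std(b) == 0:
        return 0.0
    return float(np.corrcoef(a, b)[0, 1])


def motif_similarity(pwm_a: MotifPWM, pwm_b: MotifPWM, min_overlap: int = 4) -> float:
    """Max over alignment offsets of the mean column-wise Pearson r."""
    A, B = pwm_a.matrix, pwm_b.matrix
    wa, wb = len(A), len(B)
    best = -np.inf
    for offset in range(-(wb - min_overlap), wa - min_overlap + 1):
        a_lo, a_hi = max(0, offset), min(wa, offset + wb)
        if a_hi - a_lo < min_overlap:
            continue
        cols = [
            _column_corr(A[i], B[i - offset]) for i in range(a_lo, a_hi)
        ]
        best = max(best, float(np.mean(cols)))
    return best


def motif_similarity_z(
    pwm_a: MotifPWM, pwm_b: MotifPWM, background: list[MotifPWM], min_overlap: int = 4
) -> tuple[float, float]:
    """Similarity of a vs b and its Z-score against background motifs.

    z = (similarity - mean(background similarities to pwm_a)) /
    sd(background similarities).
    """
    if len(background) < 20:
        raise ValueError("need >=20 background motifs")
    sim = motif_similarity(pwm_a, pwm_b, min_overlap=min_overlap)
    bg = np.array([motif_similarity(pwm_a, m, min_overlap=min_overlap) for m in background])
    sd = bg.std(ddof=1)
    z = (sim - bg.mean()) / sd if sd > 0 else float("nan")
    return sim, float(z)


# ---------------------------------------------------------------------------
# cargo expression correlation
# ---------------------------------------------------------------------------


def cargo_expression_correlation(mean_expr: pd.DataFrame) -> pd.DataFrame:
    """Pearson correlation between cell types over cargo-gene mean expression.

    ``mean_expr`` is cargo genes x cell types (one matrix per phenotype).
    Constant columns yield NaN correlations; the diagonal is 1 for
    non-constant columns.
    """
    if len(mean_expr) < 3:
        raise ValueError("need >=3 cargo genes")
    return mean_expr.corr(method="pearson")
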