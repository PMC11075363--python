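# Methods

`pcomics` re-implements, as a tested library, the bespoke statistical
procedures of a placental multi-omic comparison between preeclamptic (PE)
and non-preeclamptic pregnancies. Every stage can be exercised on synthetic
data with planted ground truth; this note documents the models, the
defaults and why, the numerical choices, and what the synthetic data does
and does not emulate.

## DMR calling (`pcomics.methylation`)

**Model.** Per-CpG methylation is a beta value (methylated reads / total
coverage) per sample, compared between groups of PE and nonPE placentas.

**Procedure.**

1. *DML*: per CpG, a two-sided Welch t-test on betas; a differentially
   methylated locus requires raw p < 0.01 **and** |Δβ| > 0.1 where
   Δβ = mean(PE) − mean(nonPE). Welch rather than pooled variance is used
   wherever a t-test appears, for robustness to unequal group dispersion.
   No multiple-testing correction is applied at this stage — the raw-p rule
   is the published definition. CpGs with fewer than two non-missing betas
   in a group are skipped and counted.
2. *Merge*: DMLs within 100 bp merge into candidate regions.
3. *Seed*: per candidate, betas are averaged over covered CpGs per sample
   and re-tested; p < 0.01 candidates are "seed" DMRs.
4. *Segmentation*: circular binary segmentation (CBS) of the per-CpG Δβ
   track per chromosome. For a track of length n, every circular two-arc
   split is scored by |mean_arc − mean_rest|·√(k(n−k)/n); the variance
   denominator of the classical t statistic is dropped because
   permutations of the same values share it, so it cancels both in the
   argmax and in the permutation reference. A split is accepted when its
   permutation p ≤ α (default α = 0.01, mirroring the DML cut-off;
   nperm = 1000) and recursion continues on the sub-segments. Permutations
   stop early as soon as the exceedance count proves p > α. Chromosomes
   with < 4 CpGs form a single segment. Segments tile each chromosome in
   CpG-index space; their genomic bounds run from the first to the last
   CpG of the run.
5. *Clustering*: k-means on the scalar mean Δβ of each segment, solved
   **exactly** by dynamic programming over the sorted values (the 1-D
   optimum is a contiguous partition). This makes the assignment
   deterministic and order-invariant; cluster ids are ordered by ascending
   centroid. Default k = 6 (the published analysis reports several hypo-
   and hyper-methylated clusters), overridable.
6. *Finalize*: clusters containing a segment that fully encompasses a seed
   are selected; within them, each seed-encompassing segment becomes a DMR,
   classified hypo (Δβ < 0, PE lower) or hyper. A segment qualifies only if
   |mean Δβ| exceeds the DML effect threshold (0.1). Without this guard a
   null genome — whose CBS output is one whole-chromosome segment with
   mean Δβ ≈ 0 — would convert every chance seed into a whole-chromosome
   DMR; the guard restricts DMRs to segments showing the same minimum
   effect the locus-level rule demands.

Coordinates: CpG inputs are 1-based; all emitted intervals are 0-based
half-open (BED). Conversion QC passes a sample iff its unmethylated-CHH
fraction exceeds 0.99 (strict).

## Trophoblast state (`pcomics.trophoblast`)

Latent time (RNA-velocity developmental progress, [0,1]), CytoTRACE
(stemness, [0,1]) and mitotic age are **inputs**; inferring them is out of
scope. The two-component Gaussian mixture over control latent times is
fitted by EM (k-means++ init, tol 1e−8, ≤ 500 iterations; degenerate fits
are restarted up to 10 times) and reported ascending, as a diagnostic of
the juvenile/adult segregation. The canonical immature classifier is the
fixed published rule — CytoTRACE < 0.2 AND latent time < 0.4, both strict —
with thresholds exposed as configuration. Immature frequency is compared
between phenotypes by a Welch t-test on per-donor fractions (raw p);
mitosis aging rate = mitotic age / gestational week, compared per lineage
by a two-sided Wilcoxon rank-sum test (raw p). Cell-cycle activity is the
sum of the provided G2M and S scores.

## Expression statistics (`pcomics.expression`)

Normalization is log1p of library-size-scaled counts (scale 1e4).
Rank-sum DE tests genes whose expressed fraction reaches min.pct = 0.1 in
either group, using the asymptotic tie-corrected normal approximation with
continuity correction; Bonferroni correction runs over tested genes only.
Fold changes are stored in natural log (log((mean expm1 + 1)ₐ /
(mean expm1 + 1)_b)) — the convention of the single-cell toolkit generation
the origin-marker rule (avg_logFC > 1) comes from — and log2 is derived
from it for the significance rule (p_adj < 0.05, |log2FC| > 0.5). Origin
markers additionally require p_adj < 0.001 and |pct1 − pct2| > 0.3; the
fold-change sign decides the maternal or fetal set. Module scores follow
the bin-matched control scheme: genes are ranked by mean expression (gene
name as tie-break, so scores are order-invariant), cut into 24
equal-frequency bins, and each set gene draws 100 controls from its bin
(with replacement when the bin is smaller); score = set mean − control
mean per cell. Origin is the argmax of the maternal and fetal scores, ties
unassigned. The imprinted-gene direction summary counts significantly up-
vs down-regulated genes by expressed parental allele and applies a
two-sided Fisher exact test to the 2×2 table.

## Cargo genes (`pcomics.cargo`)

"Completely inaccessible" chromatin is operationalized as: no called peak
overlapping the gene region AND a per-cell fragment-presence score < 0.01
in both PE and control endothelium (the published workflow added manual
track inspection; the ε rule makes the filter reproducible). The two
filter modes follow the published criteria verbatim, including the
disjunction inside the expression criterion (|logFC| > 0.5 **or**
p_adj < 0.01); each gene records which arm fired so rejected genes report
the criterion they violate. Allele tracing derives the paternal-specific
allele from trio genotypes (carried by father and progeny, absent in
mother; anything else is an uninformative trio and errors). A cell group
is called "fetal transcript" when its paternal fraction exceeds 0.95 — the
observed fraction in the motivating family was 100%, but a strict 1.0 rule
would break on a single sequencing error. Motif discovery is a transparent
seeded k-mer method (most frequent exact width-mer, neighbors within
Hamming width/4 averaged, pseudocount 0.25) rather than a stochastic EM
discovery tool; the similarity contract — max over offsets (≥ 4
overlapping columns) of mean column-wise Pearson r, Z-scored against a
background motif collection — does not depend on how the PWM was found.
Constant PWM columns contribute correlation 0.

## Histone domains and enrichment (`pcomics.domains`)

Broad peaks merge into domains when their gap ≤ 5 kb (inclusive).
RPKM = count / (length/10³) / (libsize/10⁶). The differential rule is the
published effect-size statistic s = |mean_PE − mean_ctrl| / (sd_PE +
sd_ctrl) > 2 with sample sds; at n = 3 vs 3 this rule has a small inherent
false-positive rate (~1–2%), which the tests acknowledge. Fisher
enrichment counts universe *elements* (not base pairs) overlapping a
target by ≥ 1 bp. The permutation test relocates each query interval
uniformly within its chromosome (length-preserving; chromosome-preserving
by default, with a length-weighted redraw as an option) and reports
z = (obs − mean_perm)/sd_perm and the empirical p with the +1 correction.

## Synthetic data (`pcomics.simulate`)

One global seed is split into per-generator substreams by CRC-hashing the
generator name, so outputs are reproducible independently. Defaults are
the study conditions the analyses are validated under:

- *Methylation*: 5,000 CpGs over 10 chromosomes (CpG gaps 10–80 bp),
  10 vs 10 samples, betas from Beta(μc, (1−μ)c) with concentration c = 50
  and baseline μ ~ U(0.2, 0.8); five planted 50-CpG DMRs with Δβ = ±0.3.
  The Beta parameterization keeps betas in [0,1] with tunable dispersion.
  Bisulfite conversion chemistry and read-level artifacts are not modeled.
- *Trophoblast*: control latent times from an equal-weight two-component
  normal mixture at means 0.15/0.56 (sd 0.08, rejection-sampled into
  [0,1]); PE cells from a single intermediate component at 0.35 (sd 0.08),
  between the two printed means. CytoTRACE = clip(1 − latent + N(0, 0.1)),
  a noisy decreasing proxy — the two scores are linked only empirically in
  real data. Because that proxy alone can never satisfy the immature rule
  (low latent implies high CytoTRACE), the generator plants an explicit
  immature subpopulation (CytoTRACE overridden below 0.2 for a configured
  fraction of low-latent cells; defaults 4% control, 12% PE) representing
  the PE excess; latent-time marginals are untouched. Mitotic age = rate ×
  gestational week + N(0, 2), rates 1.0 (control) vs 0.6 (PE).
- *Cargo fixture*: four cargo genes expressed in PE endothelium with
  closed endothelial chromatin and open trophoblast peaks; four control
  genes each violating exactly one criterion; a 50-gene housekeeping block
  (mean 50) keeps library sizes balanced so composition effects cannot
  fake differential expression; UTRs (150 nt) carry one planted motif
  (default consensus TGACGTCA) each; allele reads reproduce the
  informative-trio configuration with paternal fraction 1.0.
- *Histone*: 200 domains (5–100 kb), 3 vs 3 samples, RPKM noise sd 1.0 per
  group; 10% gain / 5% lost domains shifted by 3×(sd_PE + sd_ctrl).
- *Origin cells*: 30 fetal + 30 maternal marker genes, 8-fold (log2 = 3)
  origin shifts on a Poisson base of 0.3 — origin markers in real data
  (XIST, Y-linked genes, HLA) are similarly near-binary.

Passing tests on these data show the *procedures* are implemented
correctly and recover planted truth under idealized noise; they do not
show robustness to batch effects, doublets, coverage heterogeneity,
ambient RNA, or the genome-scale LD/locus structure of real placentas.

## Problem sizes and budgets

Deterministic seeds are fixed in tests. The DMR recovery check runs at the
full stated condition (5,000 CpGs, 10 vs 10, nperm = 1000); the null
false-positive check averages 100 seeds at the same size. The
recovery-monotonicity property uses 300-CpG single-chromosome tables at
3 effect sizes × 30 replicates with nperm = 200 — sizes chosen to give a
clear Monte-Carlo signal per property. Null permutation-z calibration uses
300 replicates of 300 permutations so the mean's Monte-Carlo error (~0.06)
sits well inside the ±0.15 tolerance being asserted.

## Known limitations

- The published genome-wide counts (tens of thousands of DMLs, thousands
  of DMRs, tens of thousands of differential H3K27me3 domains) derive from
  controlled-access patient data and are not reproducible here; the
  package validates procedure behavior, not those tallies.
- CBS accepts splits by an unpruned permutation rule; very long tracks
  with slowly drifting means may over-segment relative to pruned
  implementations.
- The k for segment clustering and the printed immature thresholds are
  taken as given constants; how they were derived upstream is not modeled.
- `cluster_segments` accepts a seed argument for interface stability, but
  the exact DP solver needs no randomness.
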