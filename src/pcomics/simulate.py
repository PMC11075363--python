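"""Synthetic placental multi-omic data with planted ground truth.

Every input the analysis stages consume can be generated here: per-CpG
methylation beta tables with planted differentially methylated regions,
trophoblast metadata with a bimodal latent-time mixture, cargo-gene
single-cell fixtures (expression + chromatin accessibility + UTR
sequences + allele-tagged reads at a SNP), and histone-domain read
counts with planted group shifts.

All generators are pure functions of their configuration: one global
seed is split into independent per-generator substreams by stable
hashing of the generator name, so regenerating any one data type never
perturbs the others.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from anndata import AnnData
from scipy import sparse

__all__ = [
    "MethylationSim",
    "TrophoblastSim",
    "CargoSim",
    "HistoneSim",
    "ExpressionSim",
    "SimConfig",
    "gen_methylation_cohort",
    "gen_trophoblast_cells",
    "gen_cargo_fixture",
    "gen_histone_coverage",
    "gen_origin_cells",
]

BASES = np.array(["A", "C", "G", "T"])


def substream(seed: int, name: str) -> np.random.Generator:
    """Independent RNG substream keyed by (seed, crc32(name))."""
    return np.random.default_rng(np.random.SeedSequence([int(seed), zlib.crc32(name.encode())]))


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------


@dataclass
class MethylationSim:
    """Planted-DMR bisulfite cohort.

    Betas are drawn per CpG per sample from Beta(mu*c, (1-mu)*c) where c is
    ``beta_noise_conc``; group means differ by the planted delta-beta inside
    planted regions and by 0 outside.
    """

    n_cpg: int = 5000
    n_chroms: int = 10
    n_samples_per_group: int = 10
    beta_noise_conc: float = 50.0
    # either explicit genomic intervals (chrom, start, end, delta) or
    # auto-placement of n_planted blocks of width_cpg CpGs
    planted_dmrs: list | None = None
    n_planted: int = 5
    width_cpg: int = 50
    planted_delta: float = 0.3

    def validate(self) -> None:
        if self.n_samples_per_group < 2:
            raise ValueError("need >=2 samples per group")
        if abs(self.planted_delta) > 1:
            raise ValueError("|delta_beta| must be <= 1")
        if self.planted_dmrs is not None:
            iv = sorted((d[0], d[1], d[2]) for d in self.planted_dmrs)
            for a, b in zip(iv, iv[1:]):
                if a[0] == b[0] and b[1] < a[2]:
                    raise ValueError("planted DMR intervals must be disjoint")


@dataclass
class TrophoblastSim:
    """Trophoblast metadata with bimodal control latent time.

    Control latent times come from a two-component normal mixture at the
    juvenile/adult means; preeclamptic cells sit in a single intermediate
    component. CytoTRACE is a noisy decreasing function of latent time
    except for a planted immature subpopulation whose score is forced
    below the immature threshold.
    """

    n_cells_per_type: dict = field(
        default_factory=lambda: {"VCTp": 500, "VCT": 2000, "SCT": 2000, "EVT": 500}
    )
    mean_juvenile: float = 0.15
    mean_adult: float = 0.56
    latent_sd: float = 0.08
    weight_juvenile: float = 0.5
    pe_mean: float = 0.35
    pe_sd: float = 0.08
    cytotrace_noise_sd: float = 0.1
    immature_rate: dict = field(default_factory=lambda: {"control": 0.04, "PE": 0.12})
    n_donors_per_phenotype: int = 4
    aging_rate: dict = field(default_factory=lambda: {"control": 1.0, "PE": 0.6})
    aging_noise_sd: float = 2.0

    def validate(self) -> None:
        for m in (self.mean_juvenile, self.mean_adult, self.pe_mean):
            if not 0 <= m <= 1:
                raise ValueError("latent-time mixture means must lie in [0, 1]")
        if not 0 <= self.weight_juvenile <= 1:
            raise ValueError("weight_juvenile must lie in [0, 1]")


@dataclass
class CargoSim:
    """VLP cargo-gene fixture: expression, accessibility, UTRs, allele reads.

    Cargo genes are expressed in receiver endothelial cells whose chromatin
    there is fully closed; each control gene violates exactly one selection
    criterion so the filter's audit trail is testable.
    """

    cargo_genes: tuple = ("NOTUM", "S100P", "TIMP2", "PAPPA2")
    n_cells_per_group: int = 60
    expr_mean_hi: float = 6.0
    expr_mean_lo: float = 1.5
    n_background_genes: int = 20
    # locally transcribed housekeeping block; keeps library sizes balanced
    # across groups so composition alone cannot fake differential expression
    n_housekeeping_genes: int = 50
    housekeeping_mean: float = 50.0
    utr_length: int = 150
    motif_consensus: str = "TGACGTCA"
    motif_noise: float = 0.0
    trio: dict = field(
        default_factory=lambda: {"mother": ("T", "T"), "father": ("T", "A"), "progeny": ("T", "A")}
    )
    snp: str = "chr7:94665871"
    reads_per_group: dict = field(
        default_factory=lambda: {
            "fetal_trophoblast": 200,
            "fetal_endothelial": 60,
            "maternal_endothelial": 40,
            "maternal_immune": 40,
        }
    )
    paternal_fraction: float = 1.0

    def validate(self) -> None:
        if len(set(self.cargo_genes)) != len(self.cargo_genes):
            raise ValueError("cargo gene names must be unique")
        if not 0 <= self.paternal_fraction <= 1:
            raise ValueError("paternal_fraction must lie in [0, 1]")


@dataclass
class HistoneSim:
    """H3K27me3 domain counts with planted gain/lost RPKM shifts."""

    n_domains: int = 200
    frac_gain: float = 0.10
    frac_lost: float = 0.05
    n_samples_per_group: int = 3
    sd_rpkm: float = 1.0
    shift_mult: float = 3.0  # planted shift = shift_mult * (sd_PE + sd_ctrl)
    library_size: int = 20_000_000
    min_length: int = 5_000
    max_length: int = 100_000

    def validate(self) -> None:
        if self.sd_rpkm <= 0:
            raise ValueError("group sds must be > 0")


@dataclass
class ExpressionSim:
    """Cell-by-gene counts with planted maternal/fetal marker effects."""

    n_genes: int = 300
    n_markers_per_origin: int = 30
    n_cells_per_origin: int = 200
    base_mean: float = 0.3
    effect_size: float = 3.0  # log2 shift of marker genes in their origin

    def validate(self) -> None:
        if self.n_markers_per_origin * 2 > self.n_genes:
            raise ValueError("too many marker genes for the gene count")


@dataclass
class SimConfig:
    """One seed plus the per-data-type sub-configurations."""

    seed: int = 0
    methylation: MethylationSim = field(default_factory=MethylationSim)
    trophoblast: TrophoblastSim = field(default_factory=TrophoblastSim)
    cargo: CargoSim = field(default_factory=CargoSim)
    histone: HistoneSim = field(default_factory=HistoneSim)
    expression: ExpressionSim = field(default_factory=ExpressionSim)


# ---------------------------------------------------------------------------
# methylation cohort
# ---------------------------------------------------------------------------


def gen_methylation_cohort(cfg: SimConfig):
    """Simulate a per-CpG beta table with planted DMRs.

    Returns
    -------
    table : pandas.DataFrame
        Columns ``chrom``, ``pos`` (1-based), one beta column per sample.
    groups : dict
        sample -> {"PE", "nonPE"}.
    truth : pandas.DataFrame
        Planted intervals (chrom, start, end, delta, direction), BED-style
        0-based half-open.
    """
    mc = cfg.methylation
    mc.validate()
    rng = substream(cfg.seed, "methylation")

    per_chrom = mc.n_cpg // mc.n_chroms
    chroms, positions = [], []
    for c in range(mc.n_chroms):
        gaps = rng.integers(10, 81, size=per_chrom)
        pos = 1000 + np.cumsum(gaps)
        chroms.append(np.repeat(f"chr{c + 1}", per_chrom))
        positions.append(pos)
    chrom = np.concatenate(chroms)
    pos = np.concatenate(positions)
    n = len(pos)

    mu = rng.uniform(0.2, 0.8, size=n)
    delta = np.zeros(n)

    truth_rows = []
    if mc.planted_dmrs is not None:
        for chrom_p, start_p, end_p, d in [tuple(x)[:4] for x in mc.planted_dmrs]:
            sel = (chrom == chrom_p) & (pos - 1 >= start_p) & (pos - 1 < end_p)
            delta[sel] = d
            truth_rows.append((chrom_p, start_p, end_p, d))
    else:
        # auto-placement: one block per chromosome, alternating direction
        for k in range(mc.n_planted):
            c = k % mc.n_chroms
            lo = c * per_chrom + per_chrom // 4
            hi = lo + mc.width_cpg
            if hi > (c + 1) * per_chrom:
                raise ValueError("planted DMR wider than chromosome")
            d = mc.planted_delta if k % 2 == 0 else -mc.planted_delta
            delta[lo:hi] = d
            truth_rows.append((chrom[lo], int(pos[lo] - 1), int(pos[hi - 1]), d))

    # keep both group means inside (0, 1) where an effect is planted
    margin = 0.02
    lo_ok = np.maximum(margin, margin - delta)
    hi_ok = np.minimum(1 - margin, 1 - margin - delta)
    if (lo_ok > hi_ok).any():
        raise ValueError("planted effect pushes a group mean outside (0, 1)")
    mu = np.clip(mu, lo_ok, hi_ok)

    mu_non = mu
    mu_pe = mu + delta
    c = mc.beta_noise_conc
    ns = mc.n_samples_per_group
    data = {"chrom": chrom, "pos": pos.astype(np.int64)}
    groups = {}
    for i in range(ns):
        s = f"nonPE_{i + 1}"
        data[s] = rng.beta(mu_non * c, (1 - mu_non) * c)
        groups[s] = "nonPE"
    for i in range(ns):
        s = f"PE_{i + 1}"
        data[s] = rng.beta(mu_pe * c, (1 - mu_pe) * c)
        groups[s] = "PE"

    table = pd.DataFrame(data)
    truth = pd.DataFrame(truth_rows, columns=["chrom", "start", "end", "delta"])
    truth["direction"] = np.where(truth["delta"] < 0, "hypo", "hyper")
    return table, groups, truth


# ---------------------------------------------------------------------------
# trophoblast cells
# ---------------------------------------------------------------------------


def _trunc_normal(rng, mean, sd, size, lo=0.0, hi=1.0):
    """Rejection-sample a normal restricted to [lo, hi]."""
    out = rng.normal(mean, sd, size=size)
    bad = (out < lo) | (out > hi)
    while bad.any():
        out[bad] = rng.normal(mean, sd, size=int(bad.sum()))
        bad = (out < lo) | (out > hi)
    return out


def gen_trophoblast_cells(cfg: SimConfig) -> AnnData:
    """Simulate trophoblast per-cell metadata (latent time, CytoTRACE, age).

    Returns an AnnData whose ``obs`` carries lineage, donor, phenotype,
    gestational_week, latent_time, cytotrace, mitotic_age, G2M/S scores and
    the planted ``immature_truth`` flag; ``uns['aging_rate_truth']`` records
    the planted per-phenotype mitotic aging rates. X is a small Poisson
    count matrix so the frame is a complete expression container.
    """
    tc = cfg.trophoblast
    tc.validate()
    rng = substream(cfg.seed, "trophoblast")

    rows = []
    for phenotype in ("control", "PE"):
        for lineage, n_cells in tc.n_cells_per_type.items():
            rows.append(
                pd.DataFrame(
                    {"lineage": lineage, "phenotype": phenotype, "cell": np.arange(n_cells)}
                )
            )
    obs = pd.concat(rows, ignore_index=True)
    n = len(obs)
    obs["cell_id"] = [f"cell_{i:06d}" for i in range(n)]
    obs = obs.set_index("cell_id").drop(columns="cell")

    # donors and gestational weeks
    week_choices = {"control": [38, 39, 40, 39], "PE": [34, 35, 36, 37]}
    donor = np.empty(n, dtype=object)
    week = np.empty(n, dtype=float)
    for phenotype in ("control", "PE"):
        mask = (obs["phenotype"] == phenotype).to_numpy()
        ids = rng.integers(0, tc.n_donors_per_phenotype, size=int(mask.sum()))
        donor[mask] = [f"{phenotype}_donor{j + 1}" for j in ids]
        week[mask] = np.asarray(week_choices[phenotype], dtype=float)[
            ids % len(week_choices[phenotype])
        ]
    obs["donor"] = donor
    obs["gestational_week"] = week

    # latent time: control = bimodal mixture, PE = intermediate component
    latent = np.empty(n)
    ctrl = (obs["phenotype"] == "control").to_numpy()
    n_ctrl = int(ctrl.sum())
    juvenile = rng.random(n_ctrl) < tc.weight_juvenile
    lat_ctrl = np.empty(n_ctrl)
    lat_ctrl[juvenile] = _trunc_normal(rng, tc.mean_juvenile, tc.latent_sd, int(juvenile.sum()))
    lat_ctrl[~juvenile] = _trunc_normal(rng, tc.mean_adult, tc.latent_sd, int((~juvenile).sum()))
    latent[ctrl] = lat_ctrl
    latent[~ctrl] = _trunc_normal(rng, tc.pe_mean, tc.pe_sd, int((~ctrl).sum()))
    obs["latent_time"] = latent
    obs["latent_component_truth"] = "PE"
    comp = np.where(juvenile, "juvenile", "adult")
    obs.loc[obs.index[ctrl], "latent_component_truth"] = comp

    # CytoTRACE: noisy decreasing function of latent time ...
    cyto = np.clip(1.0 - latent + rng.normal(0, tc.cytotrace_noise_sd, size=n), 0, 1)
    # ... except for the planted immature subpopulation (low score, low latent)
    immature = np.zeros(n, dtype=bool)
    for phenotype, rate in tc.immature_rate.items():
        eligible = ((obs["phenotype"] == phenotype).to_numpy()) & (latent < 0.4)
        pick = eligible & (rng.random(n) < rate)
        cyto[pick] = rng.uniform(0.0, 0.18, size=int(pick.sum()))
        immature[pick] = True
    obs["cytotrace"] = cyto
    obs["immature_truth"] = immature

    # mitotic age = rate * gestational week + noise
    rate = obs["phenotype"].map(tc.aging_rate).to_numpy(dtype=float)
    obs["mitotic_age"] = np.clip(
        rate * week + rng.normal(0, tc.aging_noise_sd, size=n), 0, None
    )

    # cell-cycle scores: proliferating cells cluster at low latent time
    obs["g2m_score"] = rng.normal(0.3 * (1 - latent), 0.1)
    obs["s_score"] = rng.normal(0.2 * (1 - latent), 0.1)
    obs["origin"] = "fetal"

    n_genes = 50
    X = sparse.csr_matrix(
        rng.poisson(1.0, size=(n, n_genes)).astype(np.float32)
    )
    var = pd.DataFrame(index=[f"gene_{j}" for j in range(n_genes)])
    adata = AnnData(X=X, obs=obs, var=var)
    adata.uns["aging_rate_truth"] = dict(tc.aging_rate)
    return adata


# ---------------------------------------------------------------------------
# cargo fixture
# ---------------------------------------------------------------------------

# each control gene violates exactly one criterion of the cargo filter
CONTROL_GENES = {
    "CTRL_ACC": "accessible_in_endothelium",
    "CTRL_DE": "not_de_in_endothelium",
    "CTRL_TROPH": "not_de_in_trophoblast",
    "CTRL_TROPHACC": "no_trophoblast_peak",
}


def _plant_motif(rng, seq: np.ndarray, consensus: str, noise: float) -> int:
    """Overwrite a random window of ``seq`` with the (noised) consensus."""
    w = len(consensus)
    start = int(rng.integers(0, len(seq) - w + 1))
    for k, base in enumerate(consensus):
        if noise > 0 and rng.random() < noise:
            seq[start + k] = BASES[rng.integers(0, 4)]
        else:
            seq[start + k] = base
    return start


def gen_cargo_fixture(cfg: SimConfig):
    """Simulate the cargo-gene inputs.

    Returns
    -------
    adata : AnnData
        Cells x genes counts; obs has ``cell_type`` in {trophoblast,
        endothelial} and ``phenotype`` in {control, PE}.
    accessibility : pandas.DataFrame
        (gene, cell_type, accessible, score) rows for endothelial_PE,
        endothelial_control and trophoblast.
    utrs : dict
        name -> sequence string for the 5'/3' UTR of each cargo gene, with
        the configured motif planted once in each; ``truth`` key positions
        under adata.uns.
    reads : pandas.DataFrame
        Allele-tagged read records (read_id, cell_barcode, cell_group, base)
        plus the trio genotypes in ``reads.attrs['trio']``.
    """
    cc = cfg.cargo
    cc.validate()
    rng = substream(cfg.seed, "cargo")

    genes = (
        list(cc.cargo_genes)
        + list(CONTROL_GENES)
        + [f"BG_{i}" for i in range(cc.n_background_genes)]
        + [f"HK_{i}" for i in range(cc.n_housekeeping_genes)]
    )
    groups = [
        ("trophoblast", "control"),
        ("trophoblast", "PE"),
        ("endothelial", "control"),
        ("endothelial", "PE"),
    ]
    n_per = cc.n_cells_per_group
    obs = pd.DataFrame(
        [(ct, ph) for ct, ph in groups for _ in range(n_per)],
        columns=["cell_type", "phenotype"],
    )
    obs.index = [f"c{i:05d}" for i in range(len(obs))]

    hi, lo = cc.expr_mean_hi, cc.expr_mean_lo

    def lam(gene, cell_type, phenotype):
        if gene.startswith("HK_"):
            return cc.housekeeping_mean
        if gene.startswith("BG_"):
            return 0.5
        if gene in cc.cargo_genes or gene == "CTRL_ACC" or gene == "CTRL_TROPHACC":
            # RNA present in PE endothelium, absent in control endothelium;
            # up in PE trophoblast
            if cell_type == "endothelial":
                return hi if phenotype == "PE" else 0.0
            return hi if phenotype == "PE" else lo
        if gene == "CTRL_DE":
            # flat in endothelium, up in PE trophoblast
            if cell_type == "endothelial":
                return lo
            return hi if phenotype == "PE" else lo
        if gene == "CTRL_TROPH":
            # DE in endothelium but flat in trophoblast
            if cell_type == "endothelial":
                return hi if phenotype == "PE" else 0.0
            return lo
        raise AssertionError(gene)

    X = np.zeros((len(obs), len(genes)))
    for j, g in enumerate(genes):
        for (ct, ph) in groups:
            mask = ((obs["cell_type"] == ct) & (obs["phenotype"] == ph)).to_numpy()
            X[mask, j] = rng.poisson(lam(g, ct, ph), size=int(mask.sum()))
    adata = AnnData(
        X=sparse.csr_matrix(X.astype(np.float32)),
        obs=obs,
        var=pd.DataFrame(index=genes),
    )

    # accessibility: cargo genes are chromatin-silent in endothelium but
    # carry trophoblast peaks; controls break one rule each
    acc_rows = []
    for g in genes:
        # background and housekeeping genes are ordinary locally transcribed
        # loci: open chromatin everywhere
        ordinary = g.startswith("BG_") or g.startswith("HK_")
        endo_open = g == "CTRL_ACC" or ordinary
        troph_open = not (g == "CTRL_TROPHACC") or ordinary
        for ct in ("endothelial_PE", "endothelial_control"):
            acc_rows.append(
                (g, ct, endo_open, float(rng.uniform(0.3, 0.7)) if endo_open else 0.0)
            )
        acc_rows.append(
            (g, "trophoblast", troph_open, float(rng.uniform(0.3, 0.7)) if troph_open else 0.0)
        )
    accessibility = pd.DataFrame(acc_rows, columns=["gene", "cell_type", "accessible", "score"])

    # UTR sequences with the planted motif
    utrs, motif_truth = {}, {}
    for g in cc.cargo_genes:
        for side in ("5utr", "3utr"):
            seq = BASES[rng.integers(0, 4, size=cc.utr_length)].copy()
            start = _plant_motif(rng, seq, cc.motif_consensus, cc.motif_noise)
            name = f"{g}_{side}"
            utrs[name] = "".join(seq)
            motif_truth[name] = start
    adata.uns["motif_truth"] = motif_truth
    adata.uns["cargo_truth"] = {
        "all": sorted(list(cc.cargo_genes) + ["CTRL_TROPH", "CTRL_TROPHACC"]),
        "pe_specific": sorted(cc.cargo_genes),
        "violations": dict(CONTROL_GENES),
    }

    # allele-tagged reads at the SNP
    mother = cc.trio["mother"]
    father = cc.trio["father"]
    paternal = sorted(set(father) - set(mother))
    maternal_base = mother[0]
    pat_base = paternal[0] if paternal else "A"
    read_rows = []
    i = 0
    for group, n_reads in cc.reads_per_group.items():
        is_pat = rng.random(n_reads) < cc.paternal_fraction
        for flag in is_pat:
            read_rows.append(
                (
                    f"read_{i:06d}",
                    f"BC{rng.integers(0, 10 ** 6):06d}",
                    group,
                    pat_base if flag else maternal_base,
                )
            )
            i += 1
    reads = pd.DataFrame(read_rows, columns=["read_id", "cell_barcode", "cell_group", "base"])
    reads.attrs["trio"] = {k: tuple(v) for k, v in cc.trio.items()}
    reads.attrs["snp"] = cc.snp
    return adata, accessibility, utrs, reads


# ---------------------------------------------------------------------------
# histone domains
# ---------------------------------------------------------------------------


def gen_histone_coverage(cfg: SimConfig):
    """Simulate H3K27me3 domain intervals and per-sample read counts.

    Returns (domains, counts, truth): domains is an interval frame with a
    ``domain_id``; counts a DataFrame indexed by domain_id with per-sample
    read counts plus ``length``; ``counts.attrs['library_size']`` maps
    sample -> library size; truth labels each domain PE_gain/PE_lost/
    unchanged.
    """
    hc = cfg.histone
    hc.validate()
    rng = substream(cfg.seed, "histone")

    n = hc.n_domains
    lengths = rng.integers(hc.min_length, hc.max_length + 1, size=n)
    starts = np.cumsum(rng.integers(10_000, 50_000, size=n)) + np.concatenate(
        ([0], np.cumsum(lengths[:-1]))
    )
    domains = pd.DataFrame(
        {
            "chrom": "chr1",
            "start": starts,
            "end": starts + lengths,
            "domain_id": [f"dom_{i:04d}" for i in range(n)],
        }
    )

    n_gain = int(round(hc.frac_gain * n))
    n_lost = int(round(hc.frac_lost * n))
    labels = np.array(["unchanged"] * n, dtype=object)
    picks = rng.choice(n, size=n_gain + n_lost, replace=False)
    labels[picks[:n_gain]] = "PE_gain"
    labels[picks[n_gain:]] = "PE_lost"

    base = rng.uniform(5, 40, size=n)
    shift = hc.shift_mult * (hc.sd_rpkm + hc.sd_rpkm)
    mean_pe = base + np.where(labels == "PE_gain", shift, 0) - np.where(labels == "PE_lost", shift, 0)
    mean_pe = np.clip(mean_pe, 0.5, None)

    ns = hc.n_samples_per_group
    counts = pd.DataFrame(index=domains["domain_id"])
    libsizes = {}
    for grp, means in (("control", base), ("PE", mean_pe)):
        for i in range(ns):
            s = f"{grp}_{i + 1}"
            rpkm = np.clip(rng.normal(means, hc.sd_rpkm), 0, None)
            counts[s] = np.round(rpkm * (lengths / 1000.0) * (hc.library_size / 1e6)).astype(
                np.int64
            )
            libsizes[s] = hc.library_size
    counts["length"] = lengths
    counts.attrs["library_size"] = libsizes
    counts.attrs["groups"] = {
        s: ("PE" if s.startswith("PE") else "control") for s in libsizes
    }
    truth = pd.Series(labels, index=domains["domain_id"], name="label")
    return domains, counts, truth


# ---------------------------------------------------------------------------
# origin expression cells
# ---------------------------------------------------------------------------


def gen_origin_cells(cfg: SimConfig) -> AnnData:
    """Simulate cells with planted maternal/fetal marker expression.

    The first ``n_markers_per_origin`` genes are fetal markers, the next
    block maternal markers; marker genes are up-shifted by ``effect_size``
    (log2 units) in cells of their origin. obs carries ``origin_truth``.
    """
    ec = cfg.expression
    ec.validate()
    rng = substream(cfg.seed, "origin")

    n_cells = 2 * ec.n_cells_per_origin
    origin = np.array(["fetal"] * ec.n_cells_per_origin + ["maternal"] * ec.n_cells_per_origin)
    lam = np.full((n_cells, ec.n_genes), ec.base_mean)
    mult = 2.0 ** ec.effect_size
    fet = slice(0, ec.n_markers_per_origin)
    mat = slice(ec.n_markers_per_origin, 2 * ec.n_markers_per_origin)
    lam[origin == "fetal", fet] *= mult
    lam[origin == "maternal", mat] *= mult
    X = rng.poisson(lam).astype(np.float32)
    obs = pd.DataFrame(
        {"origin_truth": origin}, index=[f"oc{i:05d}" for i in range(n_cells)]
    )
    var = pd.DataFrame(index=[f"g{j:04d}" for j in range(ec.n_genes)])
    var["marker_truth"] = "none"
    var.iloc[fet, var.columns.get_loc("marker_truth")] = "fetal"
    var.iloc[mat, var.columns.get_loc("marker_truth")] = "maternal"
    return AnnData(X=sparse.csr_matrix(X), obs=obs, var=var)
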