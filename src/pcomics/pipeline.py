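"""End-to-end pipeline orchestration on a YAML config.

Stages run in dependency order (simulate -> dmr / state / de -> cargo /
domains); every output file is sha256-hashed into a JSON manifest along
with the parameters and seeds, so two runs of the same config can be
compared byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import cargo as cargo_mod
from . import domains as domains_mod
from . import expression, io, methylation, simulate, trophoblast

logger = logging.getLogger(__name__)

STAGE_ORDER = ["simulate", "dmr", "state", "de", "cargo", "domains"]


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _build_sim_config(cfg: dict) -> simulate.SimConfig:
    sim = simulate.SimConfig(seed=int(cfg.get("seed", 0)))
    for section, cls_field in (
        ("methylation", sim.methylation),
        ("trophoblast", sim.trophoblast),
        ("cargo", sim.cargo),
        ("histone", sim.histone),
        ("expression", sim.expression),
    ):
        overrides = cfg.get(section, {}) or {}
        valid = {f.name for f in dataclasses.fields(cls_field)}
        unknown = set(overrides) - valid
        if unknown:
            raise ValueError(f"unknown {section} config fields: {sorted(unknown)}")
        for k, v in overrides.items():
            setattr(cls_field, k, v)
    return sim


def validate_config(cfg: dict) -> list[str]:
    stages = cfg.get("stages", STAGE_ORDER)
    unknown = [s for s in stages if s not in STAGE_ORDER]
    if unknown:
        raise ValueError(f"unknown stages: {unknown}")
    if "outdir" not in cfg:
        raise ValueError("config field 'outdir' is required")
    for key in ("betas", "groups", "cells"):
        path = cfg.get("inputs", {}).get(key)
        if path is not None and not Path(path).exists():
            raise ValueError(f"inputs.{key}: file not found: {path}")
    return [s for s in STAGE_ORDER if s in stages]


def run_pipeline(cfg: dict) -> dict:
    """Execute the configured stages; return (and write) the run manifest."""
    stages = validate_config(cfg)
    outdir = Path(cfg["outdir"])
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(cfg.get("seed", 0))
    sim = _build_sim_config(cfg)
    manifest: dict = {"seed": seed, "stages": stages, "parameters": {}, "artifacts": {}}
    ctx: dict = {}

    def emit(name: str, path: Path):
        manifest["artifacts"][name] = {"path": str(path), "sha256": _sha256(path)}

    for stage in stages:
        logger.info("stage %s: start", stage)
        if stage == "simulate":
            table, groups, truth = simulate.gen_methylation_cohort(sim)
            ctx.update(betas=table, groups=groups, dmr_truth=truth)
            io.write_beta_table(table, outdir / "betas.tsv")
            io.write_yaml(groups, outdir / "groups.yaml")
            io.write_tsv(truth, outdir / "dmr_truth.tsv")
            emit("betas", outdir / "betas.tsv")
            emit("groups", outdir / "groups.yaml")
            emit("dmr_truth", outdir / "dmr_truth.tsv")

            cells = simulate.gen_trophoblast_cells(sim)
            ctx["cells"] = cells
            io.write_tsv(cells.obs, outdir / "cells.tsv", index=True)
            emit("cells", outdir / "cells.tsv")

            adata, acc, utrs, reads = simulate.gen_cargo_fixture(sim)
            ctx.update(cargo_adata=adata, accessibility=acc, utrs=utrs, allele_reads=reads)
            io.write_expression(adata, outdir / "cargo_expr")
            io.write_tsv(acc, outdir / "accessibility.tsv")
            io.write_fasta(utrs, outdir / "utrs.fasta")
            io.write_tsv(reads, outdir / "allele_reads.tsv")
            io.write_yaml(
                {k: list(v) for k, v in reads.attrs["trio"].items()}, outdir / "trio.yaml"
            )
            for name in ("cargo_expr.mtx", "cargo_expr.cells.tsv", "cargo_expr.genes.tsv",
                         "accessibility.tsv", "utrs.fasta", "allele_reads.tsv", "trio.yaml"):
                emit(name, outdir / name)

            dom, counts, dom_truth = simulate.gen_histone_coverage(sim)
            ctx.update(domains=dom, domain_counts=counts, domain_truth=dom_truth)
            io.write_bed(dom.assign(name=dom["domain_id"], score=0), outdir / "domains.bed")
            io.write_tsv(counts, outdir / "domain_counts.tsv", index=True)
            emit("domains", outdir / "domains.bed")
            emit("domain_counts", outdir / "domain_counts.tsv")

        elif stage == "dmr":
            params = cfg.get("dmr", {})
            k = int(params.get("k", 6))
            alpha = float(params.get("alpha", 0.01))
            nperm = int(params.get("nperm", 1000))
            manifest["parameters"]["dmr"] = {"k": k, "alpha": alpha, "nperm": nperm}
            res = methylation.call_dmrs(
                ctx["betas"], ctx["groups"], k=k, alpha=alpha, nperm=nperm, seed=seed
            )
            io.write_tsv(res["dmls"], outdir / "dmls.tsv")
            io.write_bed(io.dmrs_to_bed(res["dmrs"]), outdir / "dmrs.bed")
            emit("dmls", outdir / "dmls.tsv")
            emit("dmrs", outdir / "dmrs.bed")
            report = {
                "n_dml": len(res["dmls"]),
                "n_seed": len(res["seeds"]),
                "n_segment": len(res["segments"]),
                "n_dmr": len(res["dmrs"]),
            }
            if "dmr_truth" in ctx:
                called = pd.DataFrame(
                    [{"chrom": d.chrom, "start": d.start, "end": d.end} for d in res["dmrs"]]
                )
                report["interval_recall"] = methylation.interval_recall(
                    ctx["dmr_truth"], called
                )
            io.write_json(report, outdir / "dmr_report.json")
            emit("dmr_report", outdir / "dmr_report.json")

        elif stage == "state":
            obs = ctx["cells"].obs
            ctrl_latent = obs.loc[obs["phenotype"] == "control", "latent_time"].to_numpy()
            fit = trophoblast.fit_bimodal_latent(ctrl_latent, seed=seed)
            freq = trophoblast.immature_frequency_test(obs)
            _, aging = trophoblast.mitosis_aging_rate(obs)
            io.write_tsv(freq["fractions"], outdir / "immature_fractions.tsv")
            io.write_tsv(aging, outdir / "aging_rates.tsv")
            io.write_json(
                {
                    "mixture_means": fit.means,
                    "mixture_sds": fit.sds,
                    "mixture_weights": fit.weights,
                    "immature_p": freq["p_value"],
                },
                outdir / "state_report.json",
            )
            for name in ("immature_fractions.tsv", "aging_rates.tsv", "state_report.json"):
                emit(name, outdir / name)

        elif stage == "de":
            adata = ctx["cargo_adata"]
            endo = adata[adata.obs["cell_type"] == "endothelial"].copy()
            troph = adata[adata.obs["cell_type"] == "trophoblast"].copy()
            de_endo = expression.wilcoxon_de(endo, "phenotype", "PE", "control")
            de_troph = expression.wilcoxon_de(troph, "phenotype", "PE", "control")
            ctx.update(de_endo=de_endo, de_troph=de_troph)
            io.write_tsv(de_endo, outdir / "de_endothelial.tsv")
            io.write_tsv(de_troph, outdir / "de_trophoblast.tsv")
            emit("de_endothelial", outdir / "de_endothelial.tsv")
            emit("de_trophoblast", outdir / "de_trophoblast.tsv")

        elif stage == "cargo":
            hits = cargo_mod.identify_cargo(
                ctx["de_endo"], ctx["de_troph"], ctx["accessibility"], mode="pe_specific"
            )
            io.write_tsv(hits, outdir / "cargo_genes.tsv")
            emit("cargo_genes", outdir / "cargo_genes.tsv")
            trace = cargo_mod.trace_allele(ctx["allele_reads"])
            io.write_json(
                {
                    "paternal_allele": trace["paternal_allele"],
                    "per_group": trace["per_group"].to_dict(orient="records"),
                },
                outdir / "allele_report.json",
            )
            emit("allele_report", outdir / "allele_report.json")
            pwm = cargo_mod.motif_discover(ctx["utrs"], width=len(sim.cargo.motif_consensus))
            io.write_tsv(
                pd.DataFrame(pwm.matrix, columns=["A", "C", "G", "T"]),
                outdir / "utr_motif_pfm.tsv",
            )
            emit("utr_motif_pfm", outdir / "utr_motif_pfm.tsv")

        elif stage == "domains":
            counts = ctx["domain_counts"]
            rpkm = domains_mod.domain_rpkm(counts)
            diff = domains_mod.differential_domains(rpkm, counts.attrs["groups"])
            io.write_tsv(diff, outdir / "differential_domains.tsv", index=True)
            emit("differential_domains", outdir / "differential_domains.tsv")
            if "domain_truth" in ctx:
                truth = ctx["domain_truth"]
                changed = truth != "unchanged"
                recall = (
                    float((diff.loc[changed.to_numpy(), "label"] == truth[changed]).mean())
                    if changed.any()
                    else float("nan")
                )
                io.write_json({"differential_recall": recall}, outdir / "domain_report.json")
                emit("domain_report", outdir / "domain_report.json")
        logger.info("stage %s: done", stage)

    io.write_json(manifest, outdir / "manifest.json")
    return manifest
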