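"""Readers and writers for the standard formats the pipeline touches.

BED is 0-based half-open; CpG beta tables are TSV with 1-based
positions; expression is MatrixMarket sparse plus cell/gene metadata
TSVs; UTRs are FASTA; configs are YAML; reports are JSON. Writing then
reading reproduces every container (floats to 1e-9); explicit zeros in
sparse matrices are dropped on write (the COO dialect stores structural
non-zeros only).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from anndata import AnnData
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from scipy import io as spio
from scipy import sparse

FLOAT_FMT = "%.9g"


# --- TSV tables -----------------------------------------------------------


def write_beta_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)


def read_beta_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    for col in ("chrom", "pos"):
        if col not in df.columns:
            raise ValueError(f"beta table {path} lacks column '{col}'")
    return df


def write_tsv(df: pd.DataFrame, path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index, float_format=FLOAT_FMT)


def read_tsv(path, index_col=None) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=index_col)


# --- BED ------------------------------------------------------------------


def write_bed(regions: pd.DataFrame, path) -> None:
    """BED with optional name/score columns (score floored from |value|*1000)."""
    cols = ["chrom", "start", "end"]
    out = regions[cols].copy()
    if "name" in regions.columns:
        out["name"] = regions["name"]
        out["score"] = regions["score"] if "score" in regions.columns else 0
        if "strand" in regions.columns:
            out["strand"] = regions["strand"]
    out.to_csv(path, sep="\t", index=False, header=False)


def read_bed(path) -> pd.DataFrame:
    names = ["chrom", "start", "end", "name", "score", "strand"]
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    df.columns = names[: df.shape[1]]
    for i, row in df.iterrows():
        if row["start"] >= row["end"]:
            raise ValueError(f"{path} line {i + 1}: start >= end")
    return df


def dmrs_to_bed(dmrs) -> pd.DataFrame:
    """DMRRecords to a BED6 frame: name=direction;cluster, score=floor(1000|dB|)."""
    rows = [
        {
            "chrom": d.chrom,
            "start": d.start,
            "end": d.end,
            "name": f"{d.direction};cluster{d.cluster_id}",
            "score": int(np.floor(1000 * abs(d.mean_delta_beta))),
            "strand": ".",
        }
        for d in dmrs
    ]
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name", "score", "strand"])


# --- expression matrices --------------------------------------------------


def write_expression(adata: AnnData, prefix) -> None:
    """MatrixMarket counts + cells.tsv + genes.tsv next to ``prefix``."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    X = adata.X if sparse.issparse(adata.X) else sparse.csr_matrix(adata.X)
    spio.mmwrite(str(prefix) + ".mtx", X.tocoo())
    adata.obs.to_csv(str(prefix) + ".cells.tsv", sep="\t", float_format=FLOAT_FMT)
    adata.var.to_csv(str(prefix) + ".genes.tsv", sep="\t", float_format=FLOAT_FMT)


def read_expression(prefix) -> AnnData:
    prefix = str(prefix)
    X = sparse.csr_matrix(spio.mmread(prefix + ".mtx"))
    obs = pd.read_csv(prefix + ".cells.tsv", sep="\t", index_col=0)
    var = pd.read_csv(prefix + ".genes.tsv", sep="\t", index_col=0)
    obs.index = obs.index.astype(str)
    var.index = var.index.astype(str)
    return AnnData(X=X, obs=obs, var=var)


# --- FASTA ----------------------------------------------------------------


def write_fasta(sequences: dict, path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path) -> dict:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


# --- YAML / JSON ----------------------------------------------------------


def write_yaml(obj, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(obj, fh, sort_keys=True)


def read_yaml(path):
    with open(path) as fh:
        return yaml.safe_load(fh)


def write_json(obj, path) -> None:
    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON-serializable: {type(o)}")

    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=default)
        fh.write("\n")


def read_json(path):
    with open(path) as fh:
        return json.load(fh)
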