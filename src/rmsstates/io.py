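"""Readers and writers for the plain-text formats the pipeline exchanges.

10x-style MatrixMarket triplets (matrix.mtx + features.tsv + barcodes.tsv),
GMT gene-set files, and TSV metadata tables.  Matrices are stored cells x
genes in memory (AnnData convention) but written genes x cells on disk (10x
convention, 1-based MatrixMarket indices).
"""

from __future__ import annotations

import os
from pathlib import Path
from typing import Iterable, Mapping

import anndata as ad
import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

__all__ = [
    "write_10x", "read_10x",
    "read_gmt", "write_gmt",
    "write_cell_meta", "read_bulk_tpm", "write_bulk_tpm",
]


def write_10x(adata: ad.AnnData, outdir: str | os.PathLike) -> None:
    """Write counts as a 10x triplet plus a cell-metadata TSV."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    X = adata.X if sp.issparse(adata.X) else sp.csr_matrix(adata.X)
    scipy.io.mmwrite(
        str(outdir / "matrix.mtx"), X.T.tocoo(), field="integer"
    )
    gene_ids = (
        adata.var["gene_id"]
        if "gene_id" in adata.var
        else pd.Series(adata.var_names, index=adata.var_names)
    )
    feats = pd.DataFrame({"gene_id": gene_ids.values, "symbol": adata.var_names})
    feats.to_csv(outdir / "features.tsv", sep="\t", header=False, index=False)
    pd.Series(adata.obs_names).to_csv(
        outdir / "barcodes.tsv", sep="\t", header=False, index=False
    )
    if len(adata.obs.columns):
        write_cell_meta(adata.obs, outdir / "cell_meta.tsv")


def read_10x(indir: str | os.PathLike) -> ad.AnnData:
    """Read a 10x triplet written by :func:`write_10x` (or Cell Ranger)."""
    indir = Path(indir)
    X = scipy.io.mmread(str(indir / "matrix.mtx")).T.tocsr()
    feats = pd.read_csv(indir / "features.tsv", sep="\t", header=None)
    barcodes = pd.read_csv(indir / "barcodes.tsv", sep="\t", header=None)[0]
    var = pd.DataFrame(
        {"gene_id": feats[0].values},
        index=pd.Index(feats[1].astype(str), name="symbol"),
    )
    var["is_mitochondrial"] = var.index.str.upper().str.startswith("MT-")
    obs = pd.DataFrame(index=pd.Index(barcodes.astype(str), name="barcode"))
    meta_path = indir / "cell_meta.tsv"
    if meta_path.exists():
        meta = pd.read_csv(meta_path, sep="\t", index_col=0)
        obs = obs.join(meta)
    return ad.AnnData(X=X, obs=obs, var=var)


def write_cell_meta(obs: pd.DataFrame, path: str | os.PathLike) -> None:
    obs.to_csv(path, sep="\t", index=True, index_label="barcode")


# ----------------------------------------------------------------------
def read_gmt(path: str | os.PathLike) -> dict[str, list[str]]:
    """Parse a GMT file into ``{set_name: [genes...]}`` (order preserved)."""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"malformed GMT line (need name, description, >=1 gene): {line[:80]!r}"
                )
            name, genes = fields[0], [g for g in fields[2:] if g]
            sets[name] = genes
    return sets


def write_gmt(
    sets: Mapping[str, Iterable[str]],
    path: str | os.PathLike,
    description: str = "",
) -> None:
    with open(path, "w") as fh:
        for name, genes in sets.items():
            fh.write("\t".join([name, description, *genes]) + "\n")


# ----------------------------------------------------------------------
def write_bulk_tpm(tpm: pd.DataFrame, path: str | os.PathLike) -> None:
    tpm.to_csv(path, sep="\t", index=True, index_label="gene")


def read_bulk_tpm(path: str | os.PathLike) -> pd.DataFrame:
    tpm = pd.read_csv(path, sep="\t", index_col=0)
    if (tpm.values < 0).any():
        raise ValueError("bulk TPM table contains negative values")
    return tpm
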