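"""Signature scoring of cells and samples.

The module score of a gene set in a cell is the difference between the
mean log-normalized expression of the set's genes and that of an
expression-matched control pool: genes are binned by average expression
across cells, and each signature gene contributes ``n_ctrl`` control genes
sampled from its bin.  This centers scores at zero for sets with no
coordinated signal regardless of expression level.

The muscle lineage score (MLS) of cell *i* is ``D_i - P_i``: the
differentiated-signature score minus the progenitor-signature score,
positioning each tumor cell on the progenitor <-> differentiated continuum
of myogenic gene expression.  Cells are called high-cycling when either the
S-phase or the G2/M score is positive, low-cycling when both are negative
or zero.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp

from .signatures import GeneSignature

logger = logging.getLogger(__name__)

__all__ = [
    "ScoreParams",
    "CellScores",
    "module_score",
    "scale_scores",
    "muscle_lineage_score",
    "cell_cycle",
    "score_states",
    "pseudobulk_scores",
    "score_bulk",
    "load_cell_cycle_signatures",
]


@dataclass
class ScoreParams:
    """Control-gene sampling parameters for module scoring."""

    n_ctrl: int = 100
    n_bins: int = 24
    seed: int = 0
    scale_scores: bool = True

    def __post_init__(self) -> None:
        if self.n_ctrl < 1 or self.n_bins < 1:
            raise ValueError("n_ctrl and n_bins must be >= 1")


@dataclass
class CellScores:
    """Per-cell program scores plus derived quantities.

    ``scores`` columns are signature names (e.g. ``progenitor``,
    ``differentiated``, ``proliferative``, ``S``, ``G2M``, ``MLS``);
    ``cycling_class`` holds ``high`` / ``low`` per cell once cell-cycle
    scoring has run; ``scaled`` records whether columns were standardized.
    """

    scores: pd.DataFrame
    cycling_class: pd.Series | None = None
    scaled: bool = False


def _lognorm_dense(adata: ad.AnnData) -> np.ndarray:
    if "lognorm" not in adata.layers:
        raise ValueError("run lognormalize first")
    L = adata.layers["lognorm"]
    return L.toarray() if sp.issparse(L) else np.asarray(L)


def module_score(
    adata: ad.AnnData,
    signature: GeneSignature,
    params: ScoreParams | None = None,
) -> pd.Series:
    """Expression-bin-matched control score of one signature per cell.

    Genes are ranked by mean log-normalized expression and split into
    ``n_bins`` equal-frequency bins.  For every detected signature gene,
    ``n_ctrl`` control genes are sampled from its bin (without replacement
    when the bin is large enough, with replacement otherwise) and pooled
    with multiplicity.  The score is the mean expression of the signature
    genes minus the mean over the control pool.
    """
    params = params or ScoreParams()
    X = _lognorm_dense(adata)
    var_names = adata.var_names
    upper = pd.Index([g.upper() for g in var_names])
    sig_pos = upper.get_indexer([g.upper() for g in signature.genes])
    missing = int((sig_pos < 0).sum())
    if missing:
        logger.info(
            "signature %s: %d/%d genes absent from matrix",
            signature.name, missing, len(signature),
        )
    sig_idx = sig_pos[sig_pos >= 0]
    if len(sig_idx) == 0:
        raise ValueError(
            f"no gene of signature {signature.name!r} detected in the matrix"
        )

    avg = X.mean(axis=0)
    # deterministic equal-frequency binning: order by (avg expr, gene name)
    order = sorted(range(len(var_names)), key=lambda i: (avg[i], var_names[i]))
    bin_of = np.empty(len(var_names), dtype=int)
    for b, chunk in enumerate(np.array_split(np.asarray(order), params.n_bins)):
        bin_of[chunk] = b
    bin_members = [np.flatnonzero(bin_of == b) for b in range(params.n_bins)]

    rng = np.random.default_rng(params.seed)
    ctrl_pool = []
    for gi in sig_idx:
        members = bin_members[bin_of[gi]]
        replace = len(members) < params.n_ctrl
        ctrl_pool.append(rng.choice(members, size=params.n_ctrl, replace=replace))
    ctrl_idx = np.concatenate(ctrl_pool)

    score = X[:, sig_idx].mean(axis=1) - X[:, ctrl_idx].mean(axis=1)
    return pd.Series(score, index=adata.obs_names, name=signature.name)


def scale_scores(scores: pd.DataFrame) -> pd.DataFrame:
    """Center each score column to mean 0, variance 1 (sample SD); constant
    columns become all zeros."""
    if len(scores) < 2:
        raise ValueError("score scaling needs >= 2 observations")
    mu = scores.mean(axis=0)
    sd = scores.std(axis=0, ddof=1)
    out = (scores - mu).div(sd.where(sd > 0, 1.0), axis=1)
    out.loc[:, sd == 0] = 0.0
    return out


def muscle_lineage_score(cs: CellScores) -> CellScores:
    """Fill ``MLS = differentiated - progenitor`` (on the scores as stored,
    i.e. scaled when scaling was requested)."""
    for col in ("differentiated", "progenitor"):
        if col not in cs.scores:
            raise ValueError(f"missing {col!r} score")
    cs.scores["MLS"] = cs.scores["differentiated"] - cs.scores["progenitor"]
    return cs


def cell_cycle(
    adata: ad.AnnData,
    s_genes: GeneSignature,
    g2m_genes: GeneSignature,
    params: ScoreParams | None = None,
) -> CellScores:
    """S and G2/M module scores plus the high/low cycling call.

    High cycling: S score > 0 or G2/M score > 0; low cycling otherwise
    (scores exactly 0 count as low).  The threshold applies to the raw
    module scores, not the scaled ones.
    """
    params = params or ScoreParams()
    s = module_score(adata, s_genes, params)
    g2m = module_score(
        adata, g2m_genes,
        ScoreParams(params.n_ctrl, params.n_bins, params.seed + 1, params.scale_scores),
    )
    cls = pd.Series(
        np.where((s > 0) | (g2m > 0), "high", "low"),
        index=adata.obs_names, name="cycling_class",
    )
    df = pd.DataFrame({"S": s, "G2M": g2m})
    return CellScores(scores=df, cycling_class=cls, scaled=False)


def score_states(
    adata: ad.AnnData,
    signatures: Mapping[str, GeneSignature],
    params: ScoreParams | None = None,
    s_genes: GeneSignature | None = None,
    g2m_genes: GeneSignature | None = None,
) -> CellScores:
    """Score every state signature, optionally cell cycle, scale, derive MLS.

    Each signature gets an independent control draw (seed offset by its
    position so adding a signature does not perturb the others).
    """
    params = params or ScoreParams()
    cols = {}
    for k, (name, sig) in enumerate(sorted(signatures.items())):
        p = ScoreParams(params.n_ctrl, params.n_bins, params.seed + 101 * (k + 1),
                        params.scale_scores)
        cols[name] = module_score(adata, sig, p)
    df = pd.DataFrame(cols)
    cycling = None
    if s_genes is not None and g2m_genes is not None:
        cc = cell_cycle(adata, s_genes, g2m_genes,
                        ScoreParams(params.n_ctrl, params.n_bins,
                                    params.seed + 9973, params.scale_scores))
        df[["S", "G2M"]] = cc.scores
        cycling = cc.cycling_class
    scaled = False
    if params.scale_scores:
        df = scale_scores(df)
        scaled = True
    cs = CellScores(scores=df, cycling_class=cycling, scaled=scaled)
    if {"progenitor", "differentiated"} <= set(df.columns):
        muscle_lineage_score(cs)
    return cs


def pseudobulk_scores(cs: CellScores, sample_ids: pd.Series) -> pd.DataFrame:
    """Per-sample mean of every score column, with cell counts."""
    sample_ids = sample_ids.reindex(cs.scores.index)
    if sample_ids.isna().any():
        raise ValueError("every scored cell needs a sample id")
    out = cs.scores.groupby(sample_ids.astype(str), observed=True).mean()
    out["n_cells"] = cs.scores.groupby(sample_ids.astype(str), observed=True).size()
    return out


def score_bulk(
    tpm: pd.DataFrame,
    signatures: Mapping[str, GeneSignature],
    params: ScoreParams | None = None,
) -> pd.DataFrame:
    """Score bulk TPM profiles with the single-cell code path.

    ``ln(TPM + 1)`` per gene, then module scoring treating samples as cells,
    then (by default) scaling across samples.  Returns samples x signatures.
    """
    params = params or ScoreParams()
    if (tpm.values < 0).any():
        raise ValueError("TPM table contains negative values")
    if tpm.shape[1] < 2 and params.scale_scores:
        raise ValueError(
            "score scaling needs >= 2 samples; pass scale_scores=False for a "
            "single profile"
        )
    bulk = ad.AnnData(
        X=sp.csr_matrix(tpm.to_numpy().T),
        obs=pd.DataFrame(index=pd.Index(tpm.columns.astype(str), name="sample")),
        var=pd.DataFrame(index=pd.Index(tpm.index.astype(str), name="symbol")),
    )
    bulk.layers["lognorm"] = sp.csr_matrix(np.log1p(tpm.to_numpy().T))
    cols = {}
    for k, (name, sig) in enumerate(sorted(signatures.items())):
        p = ScoreParams(params.n_ctrl, params.n_bins, params.seed + 101 * (k + 1),
                        params.scale_scores)
        cols[name] = module_score(bulk, sig, p)
    df = pd.DataFrame(cols)
    if params.scale_scores:
        df = scale_scores(df)
    return df


def load_cell_cycle_signatures() -> tuple[GeneSignature, GeneSignature]:
    """The canonical S-phase and G2/M gene lists shipped with the package."""
    from .io import read_gmt

    path = resources.files("rmsstates.data") / "cell_cycle_genes.gmt"
    with resources.as_file(path) as p:
        sets = read_gmt(p)
    return (
        GeneSignature("S", sets["S_PHASE"], source="packaged"),
        GeneSignature("G2M", sets["G2M_PHASE"], source="packaged"),
    )
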