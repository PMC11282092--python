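"""Reference-based label transfer onto tumor cells.

Maps each test cell to its most similar developmental cell type in a
labeled reference (e.g. the SkM.Mesen / MP / MB / MC / MB-MC / satellite
stages of human skeletal myogenesis).  The scheme follows the established
correlation-and-fine-tune recipe: Spearman correlation of each test cell
against every reference cell on label-discriminating genes, per-label
aggregation at a high quantile of the correlations, then iterative
fine-tuning that drops weakly scoring labels and re-correlates on markers
of the surviving candidates until one label remains.
"""

from __future__ import annotations

from dataclasses import dataclass

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import stats

__all__ = ["TransferResult", "select_transfer_genes", "transfer_labels", "summarize_mapping"]


@dataclass
class TransferResult:
    best_label: pd.Series            # arg-max of the aggregated scores
    fine_label: pd.Series            # label after fine-tuning
    scores: pd.DataFrame             # cells x labels aggregated correlations
    delta: pd.Series                 # best minus second-best aggregated score


def _lognorm(adata: ad.AnnData) -> np.ndarray:
    if "lognorm" not in adata.layers:
        raise ValueError("run lognormalize on the object first")
    L = adata.layers["lognorm"]
    return L.toarray() if sp.issparse(L) else np.asarray(L)


def _pair_markers(
    ref: np.ndarray, labels: np.ndarray, gene_names: pd.Index, n_per_pair: int
) -> dict[tuple[str, str], list[str]]:
    """Top ``n_per_pair`` genes by median log-expression difference for every
    ordered label pair (first over second)."""
    med = {}
    for lab in np.unique(labels):
        med[lab] = np.median(ref[labels == lab], axis=0)
    out = {}
    labs = sorted(med)
    for a in labs:
        for b in labs:
            if a == b:
                continue
            diff = med[a] - med[b]
            order = sorted(
                range(len(diff)), key=lambda i: (-diff[i], gene_names[i])
            )
            out[(a, b)] = [gene_names[i] for i in order[:n_per_pair]]
    return out


def select_transfer_genes(
    atlas: ad.AnnData, n_per_pair: int = 50
) -> list[str]:
    """Union over ordered label pairs of the top differential genes
    (by median log-expression difference); deterministic."""
    labels = atlas.obs["label"].to_numpy()
    if len(np.unique(labels)) < 2:
        raise ValueError("reference atlas needs >= 2 labels")
    pairs = _pair_markers(_lognorm(atlas), labels, atlas.var_names, n_per_pair)
    union: dict[str, None] = {}
    for genes in pairs.values():
        for g in genes:
            union[g] = None
    return sorted(union)


def _rank_rows(X: np.ndarray) -> np.ndarray:
    return np.apply_along_axis(stats.rankdata, 1, X)


def _spearman_block(test: np.ndarray, ref: np.ndarray) -> np.ndarray:
    """Spearman correlations between rows of ``test`` and rows of ``ref``
    (rank each row, then Pearson via standardized dot products)."""
    rt, rr = _rank_rows(test), _rank_rows(ref)

    def _standardize(R):
        Z = R - R.mean(axis=1, keepdims=True)
        norm = np.sqrt((Z**2).sum(axis=1, keepdims=True))
        norm[norm == 0] = 1.0
        return Z / norm

    return _standardize(rt) @ _standardize(rr).T


def _aggregate_reference(
    ref_X: np.ndarray,
    ref_labels: np.ndarray,
    n_pseudo: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Pool each label's cells into up to ``n_pseudo`` pseudo-profiles
    (seeded partition, mean log-normalized expression).  Individual droplet
    profiles are too shallow to serve as correlation anchors; pooling a
    handful of cells per profile removes most reference-side noise while
    keeping within-label variability for the quantile aggregation."""
    profiles, labels = [], []
    for lab in np.unique(ref_labels):
        idx = rng.permutation(np.flatnonzero(ref_labels == lab))
        k = min(n_pseudo, len(idx))
        for chunk in np.array_split(idx, k):
            profiles.append(ref_X[chunk].mean(axis=0))
            labels.append(lab)
    return np.stack(profiles), np.asarray(labels)


def transfer_labels(
    adata: ad.AnnData,
    atlas: ad.AnnData,
    quantile: float = 0.8,
    tune_delta: float = 0.05,
    n_per_pair: int = 50,
    max_cells_per_label: int = 200,
    n_pseudo_per_label: int = 20,
    seed: int = 0,
) -> TransferResult:
    """Assign each test cell the reference label it correlates with best.

    Reference cells are pooled into ``n_pseudo_per_label`` pseudo-profiles
    per label; per-label score = the ``quantile`` of the cell's Spearman
    correlations with that label's profiles, computed on the union of
    pairwise differential genes.  Labels scoring within ``tune_delta`` of
    the best enter fine-tuning: correlations are recomputed on markers of
    the surviving labels only, iteratively, until one label remains or no
    label can be dropped (final ties keep the label with the higher
    pre-tuning score).  The reference is capped at ``max_cells_per_label``
    cells per label (seeded subsample) for tractability.
    """
    shared = atlas.var_names.intersection(adata.var_names)
    if len(shared) < 50:
        raise ValueError(
            f"only {len(shared)} genes shared between matrix and atlas (need >= 50)"
        )
    rng = np.random.default_rng(seed)
    labels_all = atlas.obs["label"].to_numpy()
    keep = []
    for lab in np.unique(labels_all):
        idx = np.flatnonzero(labels_all == lab)
        if len(idx) > max_cells_per_label:
            idx = np.sort(rng.choice(idx, max_cells_per_label, replace=False))
        keep.append(idx)
    atlas = atlas[np.sort(np.concatenate(keep))]

    ref_sub = atlas[:, shared]
    test_sub = adata[:, shared]
    test_X = _lognorm(test_sub)
    ref_X, ref_labels = _aggregate_reference(
        _lognorm(ref_sub), atlas.obs["label"].to_numpy(), n_pseudo_per_label, rng
    )
    label_set = sorted(np.unique(ref_labels))

    pair_markers = _pair_markers(ref_X, ref_labels, shared, n_per_pair)
    union: dict[str, None] = {}
    for genes in pair_markers.values():
        for g in genes:
            union[g] = None
    gene_idx = shared.get_indexer(sorted(union))

    corr = _spearman_block(test_X[:, gene_idx], ref_X[:, gene_idx])
    label_cols = {lab: np.flatnonzero(ref_labels == lab) for lab in label_set}
    scores = np.column_stack(
        [np.quantile(corr[:, cols], quantile, axis=1) for lab, cols in
         ((lab, label_cols[lab]) for lab in label_set)]
    )
    scores_df = pd.DataFrame(scores, index=adata.obs_names, columns=label_set)
    order = np.argsort(-scores, axis=1)
    best = np.array([label_set[i] for i in order[:, 0]])
    second = scores[np.arange(len(scores)), order[:, 1]]
    delta = scores[np.arange(len(scores)), order[:, 0]] - second

    fine = best.copy()
    for i in range(len(best)):
        candidates = [
            lab for lab in label_set
            if scores_df.iat[i, label_set.index(lab)] >= scores_df.iloc[i].max() - tune_delta
        ]
        while len(candidates) > 1:
            genes: dict[str, None] = {}
            for a in candidates:
                for b in candidates:
                    if a != b:
                        for g in pair_markers[(a, b)]:
                            genes[g] = None
            gi = shared.get_indexer(sorted(genes))
            ref_rows = np.concatenate([label_cols[lab] for lab in candidates])
            c = _spearman_block(test_X[i: i + 1, gi], ref_X[ref_rows][:, gi])[0]
            sub_labels = ref_labels[ref_rows]
            cand_scores = {
                lab: np.quantile(c[sub_labels == lab], quantile) for lab in candidates
            }
            top = max(cand_scores.values())
            surviving = [lab for lab in candidates if cand_scores[lab] >= top - tune_delta]
            if len(surviving) == len(candidates):
                # no label droppable: resolve by pre-tuning score
                surviving = sorted(
                    candidates,
                    key=lambda lab: -scores_df.iat[i, label_set.index(lab)],
                )[:1]
            candidates = surviving
        fine[i] = candidates[0]

    return TransferResult(
        best_label=pd.Series(best, index=adata.obs_names, name="best_label"),
        fine_label=pd.Series(fine, index=adata.obs_names, name="fine_label"),
        scores=scores_df,
        delta=pd.Series(delta, index=adata.obs_names, name="delta"),
    )


def summarize_mapping(result: TransferResult, cell_state: pd.Series) -> pd.DataFrame:
    """Per tumor state, the fraction of cells mapped to each reference label
    (rows sum to 1) — the table behind Sankey-style mapping plots."""
    cell_state = cell_state.reindex(result.fine_label.index)
    if cell_state.isna().all():
        raise ValueError("cell ids of states and transfer result are disjoint")
    tab = pd.crosstab(cell_state, result.fine_label)
    return tab.div(tab.sum(axis=1), axis=0)
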