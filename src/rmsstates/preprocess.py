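"""QC, normalization, dimensionality reduction, clustering and markers.

The processing chain mirrors the standard droplet single-cell recipe: filter
low-quality cells with per-study thresholds, subsample each sample to a
common size, log-normalize to a fixed total, select highly variable genes,
z-score genes, PCA, KNN graph + modularity clustering, and one-vs-rest
Wilcoxon marker detection.

Layers on the AnnData carrier: ``X`` holds raw counts throughout;
``layers["lognorm"]`` and ``layers["scaled"]`` are populated by
:func:`lognormalize` and :func:`scale_genes`.
"""

from __future__ import annotations

import itertools
import random
import warnings
from dataclasses import dataclass

import anndata as ad
import igraph
import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import stats
from sklearn.neighbors import NearestNeighbors
from statsmodels.stats.multitest import multipletests

__all__ = [
    "QCThresholds",
    "QC_PRESETS",
    "ClusterResult",
    "qc_filter",
    "subsample_cells",
    "lognormalize",
    "select_hvg",
    "center_batches",
    "scale_genes",
    "pca",
    "cluster_cells",
    "select_elbow_pcs",
    "select_stable_resolution",
    "find_markers",
]


class EmptyResultError(ValueError):
    """All cells were removed by a filter."""


@dataclass
class QCThresholds:
    """Cell-level quality thresholds.

    A cell is removed when its mitochondrial fraction exceeds
    ``max_mito_fraction``, its detected-gene count falls outside
    ``[min_genes, max_genes]``, or (xenograft presets) its fraction of
    mouse-assigned reads exceeds ``max_mouse_fraction``.
    """

    max_mito_fraction: float
    min_genes: int
    max_genes: int
    max_mouse_fraction: float | None = None
    preset_name: str = "custom"

    def __post_init__(self) -> None:
        if not 0 <= self.max_mito_fraction <= 1:
            raise ValueError("max_mito_fraction must be in [0, 1]")
        if self.min_genes >= self.max_genes:
            raise ValueError("min_genes must be < max_genes")


#: Source-study presets.  danielli: primary cultures / cell lines;
#: wei: patients + PDXs with mouse-read filtering; patel: patients/PDXs;
#: rh41: the single cell-line dataset.
QC_PRESETS: dict[str, QCThresholds] = {
    "danielli": QCThresholds(0.15, 200, 8000, None, "danielli"),
    "wei": QCThresholds(0.20, 1000, 8000, 0.05, "wei"),
    "patel": QCThresholds(0.10, 400, 7000, None, "patel"),
    "rh41": QCThresholds(0.15, 200, 8000, None, "rh41"),
}


def _counts(adata: ad.AnnData) -> sp.csr_matrix:
    X = adata.X
    return X.tocsr() if sp.issparse(X) else sp.csr_matrix(X)


def qc_filter(
    adata: ad.AnnData, thresholds: QCThresholds | str
) -> ad.AnnData:
    """Remove low-quality cells; per-criterion removal counts go to
    ``.uns["qc_report"]``."""
    if isinstance(thresholds, str):
        try:
            thresholds = QC_PRESETS[thresholds]
        except KeyError:
            raise KeyError(
                f"unknown QC preset {thresholds!r}; choose from {sorted(QC_PRESETS)}"
            ) from None
    if "is_mitochondrial" not in adata.var:
        raise ValueError("gene metadata lacks the is_mitochondrial flag")
    X = _counts(adata)
    totals = np.asarray(X.sum(axis=1)).ravel()
    mito = np.asarray(X[:, adata.var["is_mitochondrial"].to_numpy()].sum(axis=1)).ravel()
    with np.errstate(invalid="ignore", divide="ignore"):
        mito_frac = np.where(totals > 0, mito / np.maximum(totals, 1), 0.0)
    n_genes_det = np.asarray((X > 0).sum(axis=1)).ravel()

    fail_mito = mito_frac > thresholds.max_mito_fraction
    fail_low = n_genes_det < thresholds.min_genes
    fail_high = n_genes_det > thresholds.max_genes
    fails = fail_mito | fail_low | fail_high
    report = {
        "preset": thresholds.preset_name,
        "n_input": int(adata.n_obs),
        "removed_mito": int(fail_mito.sum()),
        "removed_low_genes": int(fail_low.sum()),
        "removed_high_genes": int(fail_high.sum()),
    }
    if thresholds.max_mouse_fraction is not None:
        if "mouse_read_fraction" not in adata.obs:
            raise ValueError(
                "preset requires mouse_read_fraction in cell metadata"
            )
        fail_mouse = (
            adata.obs["mouse_read_fraction"].to_numpy()
            > thresholds.max_mouse_fraction
        )
        fails |= fail_mouse
        report["removed_mouse"] = int(fail_mouse.sum())
    keep = ~fails
    report["n_kept"] = int(keep.sum())
    if report["n_kept"] == 0:
        raise EmptyResultError(
            f"QC preset {thresholds.preset_name!r} removed all {adata.n_obs} cells"
        )
    out = adata[keep].copy()
    out.uns["qc_report"] = report
    return out


def subsample_cells(adata: ad.AnnData, n_per_sample: int, seed: int) -> ad.AnnData:
    """Subsample each sample to at most ``n_per_sample`` cells without
    replacement; smaller samples are kept whole."""
    if n_per_sample < 1:
        raise ValueError("n_per_sample must be >= 1")
    rng = np.random.default_rng(seed)
    keep_idx = []
    for sample in sorted(adata.obs["sample_id"].unique()):
        idx = np.flatnonzero((adata.obs["sample_id"] == sample).to_numpy())
        if len(idx) > n_per_sample:
            idx = np.sort(rng.choice(idx, size=n_per_sample, replace=False))
        keep_idx.append(idx)
    keep = np.concatenate(keep_idx)
    return adata[np.sort(keep)].copy()


def lognormalize(adata: ad.AnnData, scale_total: float = 1e4) -> ad.AnnData:
    """``lognorm = ln(1 + count * scale_total / cell_total)`` per cell.

    Zero-total cells get a zero vector and a warning.  Mutates and returns
    ``adata``.
    """
    if scale_total <= 0:
        raise ValueError("scale_total must be > 0")
    X = _counts(adata).astype(np.float64)
    totals = np.asarray(X.sum(axis=1)).ravel()
    zero = totals == 0
    if zero.any():
        warnings.warn(f"{int(zero.sum())} cells have zero total counts")
    factors = np.divide(scale_total, totals, out=np.zeros_like(totals), where=~zero)
    X = sp.diags(factors) @ X
    X.data = np.log1p(X.data)
    adata.layers["lognorm"] = X.tocsr()
    adata.uns["scale_total"] = float(scale_total)
    return adata


def select_hvg(adata: ad.AnnData, n_top: int = 2000) -> list[str]:
    """Rank genes by standardized dispersion and return the top ``n_top``.

    Dispersion = log(variance/mean) of the log-normalized values, z-scored
    within 20 equal-frequency mean-expression bins (a mean-variance trend
    correction).  Zero-variance or undetected genes rank last.
    """
    if "lognorm" not in adata.layers:
        raise ValueError("run lognormalize first")
    if n_top > adata.n_vars:
        raise ValueError(f"n_top={n_top} exceeds {adata.n_vars} genes")
    L = adata.layers["lognorm"]
    mean = np.asarray(L.mean(axis=0)).ravel()
    sq = np.asarray(L.multiply(L).mean(axis=0)).ravel()
    var = np.maximum(sq - mean**2, 0.0) * adata.n_obs / max(adata.n_obs - 1, 1)

    disp = np.full(adata.n_vars, -np.inf)
    ok = (mean > 0) & (var > 0)
    disp[ok] = np.log(var[ok] / mean[ok])

    score = np.full(adata.n_vars, -np.inf)
    if ok.sum():
        n_bins = min(20, max(1, int(ok.sum())))
        ranks = stats.rankdata(mean[ok], method="average")
        bins = np.minimum((ranks - 1) * n_bins // ok.sum(), n_bins - 1).astype(int)
        d = disp[ok]
        z = np.empty_like(d)
        for b in range(n_bins):
            m = bins == b
            mu, sd = d[m].mean(), d[m].std()
            z[m] = (d[m] - mu) / sd if sd > 0 else 0.0
        score[ok] = z
    # stable deterministic order: score desc, then gene name
    order = sorted(range(adata.n_vars), key=lambda i: (-score[i], adata.var_names[i]))
    return [adata.var_names[i] for i in order[:n_top]]


def center_batches(
    adata: ad.AnnData,
    batch_key: str = "sample_id",
    layer: str = "lognorm",
    out_layer: str = "lognorm_centered",
) -> ad.AnnData:
    """Subtract per-batch per-gene means from the log-normalized layer
    (restoring the global gene mean), a lightweight batch correction that
    removes additive per-sample shifts before scaling/PCA.  Downstream
    scoring and marker detection keep using the uncorrected layer."""
    if layer not in adata.layers:
        raise ValueError(f"layer {layer!r} missing; run lognormalize first")
    L = adata.layers[layer]
    X = L.toarray() if sp.issparse(L) else np.asarray(L, dtype=float).copy()
    global_mean = X.mean(axis=0)
    batches = adata.obs[batch_key].to_numpy()
    for b in pd.unique(batches):
        m = batches == b
        X[m] += global_mean - X[m].mean(axis=0)
    adata.layers[out_layer] = X
    return adata


def scale_genes(
    adata: ad.AnnData, clip: float = 10.0, layer: str = "lognorm"
) -> ad.AnnData:
    """Per-gene z-score of the (optionally batch-centered) log-normalized
    layer, clipped to ``±clip``; constant genes become 0.  Stored dense in
    ``layers["scaled"]``."""
    if layer not in adata.layers:
        raise ValueError(f"layer {layer!r} missing; run lognormalize first")
    L = adata.layers[layer]
    X = L.toarray() if sp.issparse(L) else np.asarray(L, dtype=float)
    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1) if X.shape[0] > 1 else np.zeros(X.shape[1])
    sd_safe = np.where(sd > 0, sd, 1.0)
    Z = (X - mu) / sd_safe
    Z[:, sd == 0] = 0.0
    np.clip(Z, -clip, clip, out=Z)
    adata.layers["scaled"] = Z
    return adata


def pca(
    adata: ad.AnnData,
    n_pcs: int = 15,
    genes: list[str] | None = None,
) -> np.ndarray:
    """PC scores of the scaled (optionally HVG-restricted) matrix.

    Signs are fixed so each component's largest-magnitude loading is
    positive.  The embedding is also stored in ``obsm["X_pca"]``.
    """
    if "scaled" not in adata.layers:
        raise ValueError("run scale_genes first")
    Z = adata.layers["scaled"]
    if genes is not None:
        idx = adata.var_names.get_indexer(genes)
        if (idx < 0).any():
            missing = [g for g, i in zip(genes, idx) if i < 0]
            raise KeyError(f"genes absent from matrix: {missing[:5]}...")
        Z = Z[:, idx]
    if n_pcs > min(Z.shape):
        raise ValueError(f"n_pcs={n_pcs} exceeds min(cells, genes)={min(Z.shape)}")
    Zc = Z - Z.mean(axis=0)
    U, S, Vt = np.linalg.svd(Zc, full_matrices=False)
    signs = np.sign(Vt[np.arange(Vt.shape[0]), np.argmax(np.abs(Vt), axis=1)])
    signs[signs == 0] = 1.0
    scores = (U * S)[:, :n_pcs] * signs[:n_pcs]
    adata.obsm["X_pca"] = scores
    adata.uns["pca_variance"] = (S**2 / max(Z.shape[0] - 1, 1))[:n_pcs].tolist()
    return scores


# ----------------------------------------------------------------------
@dataclass
class ClusterResult:
    labels: pd.Series            # categorical cluster id per cell
    resolution: float
    n_neighbors: int
    n_pcs: int
    modularity: float


def cluster_cells(
    embedding: np.ndarray,
    n_neighbors: int = 20,
    resolution: float = 0.3,
    seed: int = 0,
    method: str = "louvain",
    cell_names: pd.Index | None = None,
    snn_prune: float = 1 / 15,
) -> ClusterResult:
    """SNN graph (Euclidean KNN in PC space, Jaccard edge weights) +
    modularity community detection.

    Edges connect cells sharing neighbors, weighted by the Jaccard overlap
    of their neighbor sets (self included) and pruned below ``snn_prune``.
    ``method`` is ``louvain`` (multilevel) or ``leiden``; both optimize the
    same resolution-scaled modularity and only cluster structure is
    consumed downstream.  Cluster ids are relabeled by decreasing size.
    """
    n_cells = embedding.shape[0]
    if n_neighbors >= n_cells:
        raise ValueError(f"n_neighbors={n_neighbors} must be < n_cells={n_cells}")
    nn = NearestNeighbors(n_neighbors=n_neighbors).fit(embedding)
    _, idx = nn.kneighbors(embedding)        # row i includes i itself
    adj = sp.csr_matrix(
        (
            np.ones(idx.size),
            (np.repeat(np.arange(n_cells), n_neighbors), idx.ravel()),
        ),
        shape=(n_cells, n_cells),
    )
    shared = (adj @ adj.T).tocoo()           # neighbor-set intersections
    mask = shared.row < shared.col
    inter = shared.data[mask]
    jacc = inter / (2 * n_neighbors - inter)
    keep = jacc >= snn_prune
    edges = list(zip(shared.row[mask][keep], shared.col[mask][keep]))
    weights = jacc[keep]
    order = np.lexsort((shared.col[mask][keep], shared.row[mask][keep]))
    edges = [edges[i] for i in order]
    weights = list(weights[order])
    g = igraph.Graph(n=n_cells, edges=edges, directed=False)
    g.es["weight"] = weights
    if method == "leiden":
        import leidenalg

        part = leidenalg.find_partition(
            g,
            leidenalg.RBConfigurationVertexPartition,
            weights="weight",
            resolution_parameter=resolution,
            seed=seed,
            n_iterations=2,
        )
        membership = part.membership
    elif method == "louvain":
        igraph.set_random_number_generator(random.Random(seed))
        part = g.community_multilevel(weights="weight", resolution=resolution)
        membership = part.membership
        igraph.set_random_number_generator(random)
    else:
        raise ValueError(f"unknown clustering method {method!r}")

    membership = np.asarray(membership)
    sizes = pd.Series(membership).value_counts()
    relabel = {old: new for new, old in enumerate(sizes.index)}
    labels = pd.Series(
        pd.Categorical([str(relabel[m]) for m in membership]),
        index=cell_names if cell_names is not None else pd.RangeIndex(n_cells),
        name="cluster",
    )
    return ClusterResult(
        labels=labels,
        resolution=resolution,
        n_neighbors=n_neighbors,
        n_pcs=embedding.shape[1],
        modularity=float(g.modularity(membership, weights="weight")),
    )


def select_elbow_pcs(
    variances,
    floor_factor: float = 1.25,
    padding: float = 2.0,
    min_pcs: int = 5,
) -> int:
    """Elbow-style choice of the PC count from an eigenvalue spectrum.

    The noise floor is the median of the supplied eigenvalues; components
    above ``floor_factor`` times the floor count as signal, and the returned
    dimension is ``padding`` times that count (clipped to
    ``[min_pcs, len(variances)]``).  The buffer above the elbow keeps the
    neighbor graph from over-fragmenting when only the few signal
    dimensions would remain.
    """
    v = np.asarray(variances, dtype=float)
    floor = np.median(v)
    n_signal = int((v > floor_factor * floor).sum())
    return int(np.clip(int(np.ceil(padding * max(n_signal, 1))), min_pcs, len(v)))


def select_stable_resolution(
    embedding: np.ndarray,
    grid: tuple[float, ...] = (0.4, 0.5, 0.6, 0.7, 0.8, 0.9, 1.0),
    n_neighbors: int = 20,
    seed: int = 0,
    method: str = "louvain",
) -> float:
    """Pick the clustering resolution by cluster-count stability.

    Clusters the embedding at every grid resolution, finds the modal
    cluster count, and returns the median resolution among those achieving
    it — the plateau where the partition stops changing with resolution.
    """
    ks = {}
    for res in grid:
        part = cluster_cells(embedding, n_neighbors=n_neighbors,
                             resolution=res, seed=seed, method=method)
        ks[res] = len(part.labels.cat.categories)
    counts = pd.Series(ks)
    modal_k = counts.value_counts().index[0]
    stable = sorted(r for r, k in ks.items() if k == modal_k)
    return stable[len(stable) // 2]


# ----------------------------------------------------------------------
def _exact_ranksum_p(pooled_ranks: np.ndarray, n1: int) -> float:
    """Two-sided exact rank-sum p by enumerating all group-1 assignments.

    Handles ties through midranks; feasible for small groups only.
    """
    n = len(pooled_ranks)
    obs = pooled_ranks[:n1].sum()
    mean = n1 * pooled_ranks.sum() / n
    d_obs = abs(obs - mean)
    count = total = 0
    for comb in itertools.combinations(range(n), n1):
        s = pooled_ranks[list(comb)].sum()
        total += 1
        if abs(s - mean) >= d_obs - 1e-12:
            count += 1
    return count / total


def find_markers(
    adata: ad.AnnData,
    clusters: ClusterResult,
    lfc_min: float = 0.25,
    min_pct: float = 0.25,
    exact_max_cells: int = 20,
) -> pd.DataFrame:
    """One-vs-rest Wilcoxon rank-sum markers per cluster.

    Reports genes with natural-log fold-change >= ``lfc_min`` (cluster vs
    rest, on de-logged normalized means + 1) expressed in at least
    ``min_pct`` of the cluster's cells, with BH-adjusted p-values per
    cluster.  Groups small enough (total cells <= ``exact_max_cells`` and
    cluster <= 10) use exact enumeration of the rank-sum null; otherwise the
    tie-corrected normal approximation.
    """
    if "lognorm" not in adata.layers:
        raise ValueError("run lognormalize first")
    L = adata.layers["lognorm"]
    X = L.toarray() if sp.issparse(L) else np.asarray(L)
    labels = clusters.labels.to_numpy()
    out = []
    for cl in clusters.labels.cat.categories:
        in_mask = labels == cl
        n1, n2 = int(in_mask.sum()), int((~in_mask).sum())
        if n1 < 3:
            warnings.warn(f"cluster {cl} has {n1} cells; skipped")
            continue
        xin, xout = X[in_mask], X[~in_mask]
        pct_in = (xin > 0).mean(axis=0)
        pct_out = (xout > 0).mean(axis=0)
        lfc = np.log(np.expm1(xin).mean(axis=0) + 1) - np.log(
            np.expm1(xout).mean(axis=0) + 1
        )
        keep = (lfc >= lfc_min) & (pct_in >= min_pct)
        if not keep.any():
            continue
        gidx = np.flatnonzero(keep)
        if n1 + n2 <= exact_max_cells and n1 <= 10:
            pvals = np.empty(len(gidx))
            for k, gi in enumerate(gidx):
                pooled = np.concatenate([xin[:, gi], xout[:, gi]])
                ranks = stats.rankdata(pooled)
                pvals[k] = _exact_ranksum_p(ranks, n1)
        else:
            res = stats.mannwhitneyu(
                xin[:, gidx], xout[:, gidx], alternative="two-sided",
                method="asymptotic", axis=0,
            )
            pvals = np.atleast_1d(res.pvalue)
        padj = multipletests(pvals, method="fdr_bh")[1]
        for k, gi in enumerate(gidx):
            out.append(
                {
                    "cluster": cl,
                    "gene": adata.var_names[gi],
                    "lfc": float(lfc[gi]),
                    "p": float(pvals[k]),
                    "p_adj": float(padj[k]),
                    "pct_in": float(pct_in[gi]),
                    "pct_out": float(pct_out[gi]),
                }
            )
    df = pd.DataFrame(
        out,
        columns=["cluster", "gene", "lfc", "p", "p_adj", "pct_in", "pct_out"],
    )
    return df.sort_values(["cluster", "p", "gene"], kind="stable").reset_index(drop=True)
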