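"""Synthetic single-cell cohorts with planted cell states.

Generates multi-sample negative-binomial count matrices that emulate the
statistical structure of a merged rhabdomyosarcoma single-cell atlas:
per-state marker-gene blocks, a dedicated cell-cycle block elevated in
proliferative cells, per-sample batch shifts on the log-mean, lognormal
library-size variation, a mitochondrial gene block with per-cell
mitochondrial fractions drawn from a Beta distribution, and
treatment-dependent state composition. Also builds a labeled developmental
reference atlas (for label-transfer benchmarks) and bulk TPM mixtures of
state pseudobulks.

All outputs are deterministic functions of the configuration seed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp

__all__ = [
    "STATES",
    "SimConfig",
    "GroundTruth",
    "generate_cohort",
    "generate_reference",
    "generate_bulk",
    "alias_symbols",
]

#: Canonical cell-state names understood by the generator.  ``ground`` cells
#: carry no marker block by construction.
STATES = (
    "progenitor",
    "proliferative",
    "differentiated",
    "ground",
    "neuronal",
    "ifn",
    "apoptotic",
)

_DEFAULT_PROPORTIONS = {
    "progenitor": 0.30,
    "proliferative": 0.25,
    "differentiated": 0.25,
    "ground": 0.20,
}


class ConfigurationError(ValueError):
    """Raised when a simulation configuration violates its invariants."""


@dataclass
class SimConfig:
    """Parameters of the synthetic cohort.

    Parameters
    ----------
    n_samples
        Number of samples (tumors / models) in the cohort.
    cells_per_sample
        Cells simulated per sample.
    n_genes
        Total genes, including marker blocks, the cell-cycle block and the
        mitochondrial block.
    state_proportions
        Either a single ``state -> fraction`` map applied to every sample, or
        a per-sample list of such maps (length ``n_samples``).  Fractions of
        each map must be nonnegative and sum to 1.
    marker_genes_per_state
        Size of the disjoint marker block planted for each non-ground state.
    marker_log_fold_change
        Natural-log shift added to the log-mean of a state's marker genes in
        cells of that state.
    baseline_mean
        Mean counts per gene per cell before library-size scaling; low values
        give the sparsity typical of droplet data.
    dispersion
        Negative-binomial size parameter ``r`` (variance = mu + mu^2 / r);
        smaller values mean more overdispersion.
    batch_sd
        SD of the per-sample per-gene Gaussian shift applied on the log-mean
        (the batch effect seen when merging samples without integration).
    library_size_cv
        Coefficient of variation of the lognormal per-cell library-size
        factor.
    cycle_genes
        Size of the cell-cycle block additionally elevated in proliferative
        cells (split into S-like and G2/M-like halves).
    cycle_log_fold_change
        Natural-log elevation of the cycle block in proliferative cells.
        Kept separate from ``marker_log_fold_change`` because cell-cycle
        transcripts are near-silent outside cycling cells, a much larger
        contrast than typical state markers show.
    n_mito_genes
        Number of ``MT-`` prefixed genes; per-cell mitochondrial fraction is
        drawn from ``Beta(mito_beta_a, mito_beta_b)``.
    treatment_shift
        ``state -> multiplier`` applied to the state fractions of on-treatment
        samples (renormalized afterwards).
    treatment_status
        Per-sample ``"pre"`` or ``"on"`` labels; default all ``"pre"``.
    subtypes
        Per-sample molecular subtype labels (e.g. ``FN``, ``P3F``, ``P7F``);
        default all ``FN``.
    quota_allocation
        If True (default) cells are allocated to states by largest-remainder
        quotas so realized fractions are exact; otherwise a multinomial draw.
    """

    n_samples: int = 6
    cells_per_sample: int = 300
    n_genes: int = 2000
    state_proportions: Mapping[str, float] | Sequence[Mapping[str, float]] = field(
        default_factory=lambda: dict(_DEFAULT_PROPORTIONS)
    )
    marker_genes_per_state: int = 60
    marker_log_fold_change: float = 1.0
    baseline_mean: float = 1.0
    dispersion: float = 2.0
    batch_sd: float = 0.2
    library_size_cv: float = 0.3
    cycle_genes: int = 60
    cycle_log_fold_change: float = 2.0
    n_mito_genes: int = 20
    mito_beta_a: float = 2.0
    mito_beta_b: float = 38.0
    treatment_shift: Mapping[str, float] = field(default_factory=dict)
    treatment_status: Sequence[str] | None = None
    subtypes: Sequence[str] | None = None
    quota_allocation: bool = True
    seed: int = 0

    # ------------------------------------------------------------------
    def per_sample_proportions(self) -> list[dict[str, float]]:
        """Expand ``state_proportions`` to one validated map per sample."""
        props = self.state_proportions
        if isinstance(props, Mapping):
            maps = [dict(props) for _ in range(self.n_samples)]
        else:
            maps = [dict(p) for p in props]
            if len(maps) != self.n_samples:
                raise ConfigurationError(
                    f"state_proportions lists {len(maps)} samples, "
                    f"config declares n_samples={self.n_samples}"
                )
        status = self.statuses()
        for i, (m, st) in enumerate(zip(maps, status)):
            if st == "on" and self.treatment_shift:
                for state, mult in self.treatment_shift.items():
                    if state in m:
                        m[state] = m[state] * mult
                total = sum(m.values())
                for state in m:
                    m[state] /= total
            for state, frac in m.items():
                if state not in STATES:
                    raise ConfigurationError(
                        f"sample {i}: unknown state {state!r}"
                    )
                if frac < 0:
                    raise ConfigurationError(
                        f"sample {i}: negative fraction for state {state!r}"
                    )
            if abs(sum(m.values()) - 1.0) > 1e-9:
                raise ConfigurationError(
                    f"sample {i}: state fractions sum to {sum(m.values()):.6g}, not 1"
                )
        return maps

    def statuses(self) -> list[str]:
        if self.treatment_status is None:
            return ["pre"] * self.n_samples
        status = list(self.treatment_status)
        if len(status) != self.n_samples:
            raise ConfigurationError("treatment_status length != n_samples")
        if any(s not in ("pre", "on") for s in status):
            raise ConfigurationError("treatment_status entries must be 'pre' or 'on'")
        return status

    def sample_subtypes(self) -> list[str]:
        if self.subtypes is None:
            return ["FN"] * self.n_samples
        subs = list(self.subtypes)
        if len(subs) != self.n_samples:
            raise ConfigurationError("subtypes length != n_samples")
        return subs

    def validate(self) -> None:
        for name in ("n_samples", "cells_per_sample", "n_genes",
                     "marker_genes_per_state"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be strictly positive")
        for name in ("baseline_mean", "dispersion", "library_size_cv"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be strictly positive")
        if self.batch_sd < 0:
            raise ConfigurationError("batch_sd must be nonnegative")
        maps = self.per_sample_proportions()
        used_states = sorted({s for m in maps for s in m if m[s] > 0})
        n_marked = len([s for s in used_states if s != "ground"])
        needed = (n_marked * self.marker_genes_per_state
                  + self.cycle_genes + self.n_mito_genes)
        if self.n_genes < needed:
            raise ConfigurationError(
                f"n_genes={self.n_genes} too small: {needed} genes needed for "
                f"{n_marked} marker blocks + cycle + mitochondrial blocks"
            )

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


@dataclass
class GroundTruth:
    """Per-cell truth recorded by the generator."""

    cell_state: pd.Series            # categorical state per cell (index = barcode)
    sample_id: pd.Series
    subtype: pd.Series
    treatment_status: pd.Series
    marker_assignment: dict[str, list[str]]   # state -> marker gene symbols
    cycle_genes: dict[str, list[str]]         # {"S": [...], "G2M": [...]}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "cell_state": self.cell_state,
                "sample_id": self.sample_id,
                "subtype": self.subtype,
                "treatment_status": self.treatment_status,
            }
        )


# ----------------------------------------------------------------------
def _allocate_states(
    rng: np.random.Generator,
    n_cells: int,
    proportions: dict[str, float],
    quota: bool,
) -> np.ndarray:
    states = [s for s in STATES if proportions.get(s, 0) > 0]
    fracs = np.array([proportions[s] for s in states], dtype=float)
    if quota:
        # largest-remainder quotas: realized fractions are exact when the
        # target fractions are exact multiples of 1/n_cells
        raw = fracs * n_cells
        counts = np.floor(raw).astype(int)
        remainder = n_cells - counts.sum()
        order = np.argsort(-(raw - counts), kind="stable")
        counts[order[:remainder]] += 1
    else:
        counts = rng.multinomial(n_cells, fracs)
    labels = np.repeat(states, counts)
    return labels


def _gene_table(config: SimConfig, used_states: list[str]) -> pd.DataFrame:
    """Lay out the gene blocks: markers per state, cycle block, mito block."""
    n = config.n_genes
    symbols = np.array([f"G{i + 1:06d}" for i in range(n)], dtype=object)
    block = np.array(["background"] * n, dtype=object)
    pos = 0
    marker_assignment: dict[str, list[str]] = {}
    for state in used_states:
        if state == "ground":
            continue
        sl = slice(pos, pos + config.marker_genes_per_state)
        block[sl] = f"marker:{state}"
        marker_assignment[state] = list(symbols[sl])
        pos += config.marker_genes_per_state
    half = config.cycle_genes // 2
    block[pos:pos + half] = "cycle:S"
    block[pos + half:pos + config.cycle_genes] = "cycle:G2M"
    pos += config.cycle_genes
    mito_sl = slice(n - config.n_mito_genes, n)
    block[mito_sl] = "mito"
    symbols[mito_sl] = [f"MT-G{i + 1:04d}" for i in range(config.n_mito_genes)]
    df = pd.DataFrame(
        {
            "gene_id": [f"ENSG{i + 1:08d}" for i in range(n)],
            "symbol": symbols,
            "block": block,
            "is_mitochondrial": block == "mito",
        }
    )
    df.index = pd.Index(symbols, name="symbol")
    return df, marker_assignment


def generate_cohort(config: SimConfig) -> tuple[ad.AnnData, GroundTruth]:
    """Simulate a multi-sample cohort with known per-cell states.

    Returns an :class:`anndata.AnnData` of raw counts (cells x genes, CSR)
    with per-cell metadata in ``.obs`` and gene metadata in ``.var``, plus the
    :class:`GroundTruth` describing every planted structure.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    prop_maps = config.per_sample_proportions()
    statuses = config.statuses()
    subtypes = config.sample_subtypes()
    used_states = sorted(
        {s for m in prop_maps for s in m if m[s] > 0},
        key=STATES.index,
    )

    genes, marker_assignment = _gene_table(config, used_states)
    n_genes = config.n_genes
    mito_mask = genes["is_mitochondrial"].to_numpy()
    cycle_s = list(genes.index[genes["block"] == "cycle:S"])
    cycle_g2m = list(genes.index[genes["block"] == "cycle:G2M"])

    # baseline gene abundance profile: lognormal spread, scaled to
    # baseline_mean counts per gene on average
    base = rng.lognormal(mean=0.0, sigma=1.0, size=n_genes)
    base *= config.baseline_mean * n_genes / base.sum()
    log_base = np.log(base)

    # marker shift matrix: state -> additive log-mean shift per gene
    shifts = {}
    for state in used_states:
        shift = np.zeros(n_genes)
        if state in marker_assignment:
            idx = genes.index.get_indexer(marker_assignment[state])
            shift[idx] = config.marker_log_fold_change
        if state == "proliferative":
            idx = genes.index.get_indexer(cycle_s + cycle_g2m)
            shift[idx] = config.cycle_log_fold_change
        shifts[state] = shift

    sigma_lib = np.sqrt(np.log(1.0 + config.library_size_cv ** 2))
    nonmito = ~mito_mask

    blocks, obs_rows = [], []
    for i in range(config.n_samples):
        sample = f"S{i + 1:02d}"
        n_cells = config.cells_per_sample
        labels = _allocate_states(rng, n_cells, prop_maps[i], config.quota_allocation)
        batch = rng.normal(0.0, config.batch_sd, size=n_genes)
        lib = rng.lognormal(-0.5 * sigma_lib ** 2, sigma_lib, size=n_cells)
        mito_frac = rng.beta(config.mito_beta_a, config.mito_beta_b, size=n_cells)

        log_mu = log_base[None, :] + batch[None, :]
        shift_mat = np.stack([shifts[s] for s in labels])
        mu = np.exp(log_mu + shift_mat) * lib[:, None]
        # rescale the mitochondrial block so its expected share of the cell's
        # library equals the Beta-drawn fraction
        tot_non = mu[:, nonmito].sum(axis=1)
        tot_mito = mu[:, mito_mask].sum(axis=1)
        factor = mito_frac / (1 - mito_frac) * tot_non / np.maximum(tot_mito, 1e-12)
        mu[:, mito_mask] *= factor[:, None]

        r = config.dispersion
        counts = rng.poisson(rng.gamma(shape=r, scale=mu / r))
        blocks.append(sp.csr_matrix(counts))
        for j, state in enumerate(labels):
            obs_rows.append(
                (f"{sample}_C{j + 1:05d}", sample, state, subtypes[i], statuses[i])
            )

    X = sp.vstack(blocks, format="csr")
    obs = pd.DataFrame(
        obs_rows,
        columns=["barcode", "sample_id", "true_state", "subtype", "treatment_status"],
    ).set_index("barcode")
    adata = ad.AnnData(X=X, obs=obs, var=genes.copy())
    adata.uns["sim_config"] = config.to_dict()

    truth = GroundTruth(
        cell_state=obs["true_state"].copy(),
        sample_id=obs["sample_id"].copy(),
        subtype=obs["subtype"].copy(),
        treatment_status=obs["treatment_status"].copy(),
        marker_assignment=marker_assignment,
        cycle_genes={"S": cycle_s, "G2M": cycle_g2m},
    )
    return adata, truth


# ----------------------------------------------------------------------
def generate_reference(
    config: SimConfig,
    labels: Sequence[str],
    cells_per_label: int = 150,
    overlap: Mapping[tuple[str, str], float] | None = None,
) -> ad.AnnData:
    """Simulate a labeled developmental reference atlas.

    Each label receives a disjoint marker block whose log-mean is shifted by
    ``config.marker_log_fold_change``.  ``overlap`` maps ordered label pairs
    ``(a, b)`` to a mixing weight in [0, 1]: label ``b``'s shift vector
    becomes ``(1-w)*own + w*shift_of_a``, so ``w=1`` makes the two labels
    transcriptionally indistinguishable (emulating adjacent developmental
    stages such as SkM.Mesen and myogenic progenitors).

    Returns an AnnData of raw counts with ``obs["label"]``.
    """
    labels = list(labels)
    if len(labels) < 2:
        raise ConfigurationError("generate_reference requires >= 2 labels")
    if len(set(labels)) != len(labels):
        raise ConfigurationError("reference labels must be unique")
    rng = np.random.default_rng(config.seed + 7919)
    n_genes = config.n_genes
    block_size = config.marker_genes_per_state
    if n_genes < block_size * len(labels):
        raise ConfigurationError(
            f"n_genes={n_genes} too small for {len(labels)} disjoint blocks "
            f"of {block_size} genes"
        )
    symbols = [f"G{i + 1:06d}" for i in range(n_genes)]
    base = rng.lognormal(0.0, 1.0, size=n_genes)
    base *= config.baseline_mean * n_genes / base.sum()
    log_base = np.log(base)

    shifts = {}
    for k, lab in enumerate(labels):
        v = np.zeros(n_genes)
        v[k * block_size:(k + 1) * block_size] = config.marker_log_fold_change
        shifts[lab] = v
    if overlap:
        mixed = {lab: shifts[lab].copy() for lab in labels}
        for (a, b), w in overlap.items():
            if not 0 <= w <= 1:
                raise ConfigurationError(f"overlap weight for {(a, b)} not in [0,1]")
            mixed[b] = (1 - w) * shifts[b] + w * shifts[a]
        shifts = mixed

    sigma_lib = np.sqrt(np.log(1.0 + config.library_size_cv ** 2))
    r = config.dispersion
    blocks, names, cell_labels = [], [], []
    for lab in labels:
        lib = rng.lognormal(-0.5 * sigma_lib ** 2, sigma_lib, size=cells_per_label)
        mu = np.exp(log_base[None, :] + shifts[lab][None, :]) * lib[:, None]
        counts = rng.poisson(rng.gamma(shape=r, scale=mu / r))
        blocks.append(sp.csr_matrix(counts))
        safe = lab.replace(" ", "_")
        names.extend(f"REF_{safe}_{j + 1:04d}" for j in range(cells_per_label))
        cell_labels.extend([lab] * cells_per_label)

    X = sp.vstack(blocks, format="csr")
    var = pd.DataFrame(
        {
            "gene_id": [f"ENSG{i + 1:08d}" for i in range(n_genes)],
            "symbol": symbols,
            "is_mitochondrial": False,
        },
        index=pd.Index(symbols, name="symbol"),
    )
    atlas = ad.AnnData(
        X=X,
        obs=pd.DataFrame({"label": cell_labels}, index=pd.Index(names, name="barcode")),
        var=var,
    )
    atlas.uns["label_blocks"] = {
        lab: symbols[k * block_size:(k + 1) * block_size]
        for k, lab in enumerate(labels)
    }
    return atlas


# ----------------------------------------------------------------------
def alias_symbols(
    adata: ad.AnnData, fraction: float = 0.1, seed: int = 0
) -> dict[str, str]:
    """Rename a random fraction of gene symbols to ``ALIAS-`` variants,
    returning the old->new table.  Exercises symbol-mismatch handling
    (signatures built on the original symbols will miss these genes unless
    translated through the alias table)."""
    if not 0 <= fraction <= 1:
        raise ConfigurationError("fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    n = int(round(fraction * adata.n_vars))
    idx = np.sort(rng.choice(adata.n_vars, size=n, replace=False))
    mapping = {adata.var_names[i]: f"ALIAS-{adata.var_names[i]}" for i in idx}
    adata.var_names = [mapping.get(g, g) for g in adata.var_names]
    return mapping


# ----------------------------------------------------------------------
def generate_bulk(
    truth: GroundTruth,
    adata: ad.AnnData,
    mixtures: Sequence[Mapping[str, float]],
    sample_names: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Build bulk TPM profiles as fraction-weighted mixtures of state pseudobulks.

    Each mixture maps states to fractions summing to 1.  The state pseudobulk
    is the mean count vector over all cells of that state; the mixture profile
    is the fraction-weighted average, then scaled so every column sums to 1e6
    (gene lengths are taken as equal for synthetic genes).

    Returns a genes x samples DataFrame.
    """
    states_present = set(truth.cell_state.unique())
    X = adata.X
    X = X.toarray() if sp.issparse(X) else np.asarray(X)
    pseudobulk = {}
    for state in states_present:
        mask = (truth.cell_state == state).to_numpy()
        pseudobulk[state] = X[mask].mean(axis=0)

    cols = {}
    for k, mix in enumerate(mixtures):
        total = sum(mix.values())
        if abs(total - 1.0) > 1e-9:
            raise ConfigurationError(f"mixture {k}: fractions sum to {total:.6g}, not 1")
        profile = np.zeros(adata.n_vars)
        for state, frac in mix.items():
            if state not in pseudobulk:
                raise ConfigurationError(
                    f"mixture {k}: state {state!r} absent from the cohort"
                )
            profile += frac * pseudobulk[state]
        tpm = profile / profile.sum() * 1e6
        name = sample_names[k] if sample_names is not None else f"B{k + 1:02d}"
        cols[name] = tpm
    return pd.DataFrame(cols, index=adata.var_names.copy())
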