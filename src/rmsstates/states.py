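"""Cell-state assignment and compositional statistics.

Cluster-level annotation labels each cluster by the state signature most
over-represented among its markers (hypergeometric test), collapsing
clusters that map to the same state; clusters with no significant or a tied
enrichment fall back to the Ground state.  The per-cell rule is a two-tier
threshold on scaled signature scores: the arg-max state when its score
clears tau, the transiting (TR-) variant when it sits between tau and
tau_hi, Proliferative for otherwise-unassigned high-cycling cells, Ground
for the rest.

Composition differences between sample groups are tested on centered-log-
ratio transformed state counts with permutation p-values and BH control — a
deliberately lightweight compositional test with the same decision
semantics (per-state flagged / not flagged at a given FDR) as Bayesian
compositional models; count tables in the exported layout can be fed to
such tools directly.  Paired pre/post score shifts use the exact Wilcoxon
signed-rank null (full distribution over sign assignments) up to n=25 pairs
and a continuity-corrected normal approximation beyond.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .scoring import CellScores
from .signatures import GeneSignature, enrichment_test

__all__ = [
    "StateTable",
    "ShiftTestResult",
    "STATE_PRIORITY",
    "annotate_clusters",
    "assign_cell_states",
    "composition",
    "compare_composition",
    "paired_shift_test",
]

#: Fixed tie-breaking priority for the per-cell arg-max (first wins).
STATE_PRIORITY = (
    "Progenitor",
    "Differentiated",
    "Proliferative",
    "Neuronal",
    "IFN",
    "Apoptotic",
    "Ground",
)

_DISPLAY = {
    "progenitor": "Progenitor",
    "differentiated": "Differentiated",
    "proliferative": "Proliferative",
    "neuronal": "Neuronal",
    "ifn": "IFN",
    "apoptotic": "Apoptotic",
    "ground": "Ground",
}

#: States that get a transiting tier between tau and tau_hi.
_TR_STATES = {"Progenitor": "TR-Progenitor", "Differentiated": "TR-Differentiated"}


def display_state(name: str) -> str:
    return _DISPLAY.get(name.lower(), name)


@dataclass
class StateTable:
    """Per-cell state calls plus (optional) per-sample composition."""

    cell_state: pd.Series
    sample_id: pd.Series
    composition_fractions: pd.DataFrame | None = None
    composition_counts: pd.DataFrame | None = None
    neuronal_positive: pd.Series | None = None


@dataclass
class ShiftTestResult:
    score_name: str
    group_labels: tuple[str, str]
    statistic: float
    p_value: float
    direction: int
    n_pairs: int


# ----------------------------------------------------------------------
def annotate_clusters(
    markers: pd.DataFrame,
    state_signatures: dict[str, GeneSignature],
    universe_size: int,
    alpha: float = 0.05,
) -> dict[str, str]:
    """Map each cluster id to a state via marker-list over-representation.

    A cluster takes the state whose signature is most significantly
    enriched among its markers (BH-adjusted hypergeometric p < ``alpha``,
    unique minimum); otherwise Ground.  Clusters mapping to the same state
    are thereby collapsed into one category.
    """
    mapping: dict[str, str] = {}
    for cl, sub in markers.groupby("cluster", observed=True):
        genes = list(sub["gene"])
        if not genes:
            warnings.warn(f"cluster {cl} has no markers; labeled Ground")
            mapping[str(cl)] = "Ground"
            continue
        table = enrichment_test(
            GeneSignature(f"cluster_{cl}", genes), state_signatures, universe_size
        )
        top = table.iloc[0]
        tied = (table["p_adj"] <= top["p_adj"] + 1e-300).sum() > 1 and (
            table["p_adj"].iloc[1] == top["p_adj"]
        )
        if top["p_adj"] >= alpha or tied:
            mapping[str(cl)] = "Ground"
        else:
            mapping[str(cl)] = display_state(str(top["term"]))
    # clusters whose id never appeared in the marker table
    return mapping


# ----------------------------------------------------------------------
def assign_cell_states(
    cs: CellScores,
    tau: float = 0.0,
    tau_hi: float = 1.0,
    sample_ids: pd.Series | None = None,
) -> StateTable:
    """Two-tier per-cell state assignment on scaled signature scores.

    Every cell receives exactly one state: the arg-max state (ties broken
    by the fixed priority order) when its scaled score exceeds ``tau`` —
    demoted to the TR- variant when the score is below ``tau_hi`` —
    Proliferative for high-cycling cells with no score above ``tau``, and
    Ground otherwise.
    """
    score_cols = [c for c in cs.scores.columns if c.lower() in _DISPLAY]
    if not score_cols:
        raise ValueError("no state score columns present")
    if not cs.scaled:
        warnings.warn("assign_cell_states expects scaled scores")
    # order columns by priority so np.argmax ties resolve deterministically
    prio = {s: i for i, s in enumerate(STATE_PRIORITY)}
    score_cols = sorted(score_cols, key=lambda c: prio.get(display_state(c), 99))
    S = cs.scores[score_cols].to_numpy()
    best = np.argmax(S, axis=1)          # first max wins = priority order
    best_score = S[np.arange(len(S)), best]

    states = np.empty(len(S), dtype=object)
    for i, (b, sc) in enumerate(zip(best, best_score)):
        if sc > tau:
            name = display_state(score_cols[b])
            if sc < tau_hi and name in _TR_STATES:
                name = _TR_STATES[name]
            states[i] = name
        else:
            high = (
                cs.cycling_class is not None
                and cs.cycling_class.iloc[i] == "high"
            )
            states[i] = "Proliferative" if high else "Ground"

    cell_state = pd.Series(states, index=cs.scores.index, name="state")
    if sample_ids is None:
        sample_ids = pd.Series("all", index=cs.scores.index, name="sample_id")
    return StateTable(cell_state=cell_state, sample_id=sample_ids.reindex(cs.scores.index))


# ----------------------------------------------------------------------
def composition(table: StateTable, neuronal_threshold: float = 0.01) -> StateTable:
    """Fill per-sample state counts, fractions and the neuronal-positive flag
    (neuronal fraction strictly above ``neuronal_threshold``)."""
    if table.sample_id.isna().any():
        raise ValueError("every cell needs a sample id")
    counts = (
        pd.crosstab(table.sample_id, table.cell_state)
        .rename_axis(index="sample_id", columns="state")
    )
    fractions = counts.div(counts.sum(axis=1), axis=0)
    neuronal = (
        fractions["Neuronal"]
        if "Neuronal" in fractions
        else pd.Series(0.0, index=fractions.index)
    )
    table.composition_counts = counts
    table.composition_fractions = fractions
    table.neuronal_positive = neuronal > neuronal_threshold
    return table


# ----------------------------------------------------------------------
def _clr(counts: np.ndarray, pseudocount: float = 0.5) -> np.ndarray:
    logc = np.log(counts + pseudocount)
    return logc - logc.mean(axis=1, keepdims=True)


def compare_composition(
    counts: pd.DataFrame,
    groups: pd.Series,
    fdr: float = 0.05,
    n_perm: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-state test of composition differences between two sample groups.

    Counts (samples x states) are CLR-transformed with a 0.5 pseudocount;
    the statistic is the difference of group means per state, with a
    label-permutation two-sided p-value and BH control at ``fdr``.
    """
    groups = groups.reindex(counts.index)
    levels = sorted(groups.dropna().unique())
    if len(levels) != 2:
        raise ValueError(f"need exactly 2 groups, got {levels}")
    ga, gb = (groups == levels[0]).to_numpy(), (groups == levels[1]).to_numpy()
    if ga.sum() < 2 or gb.sum() < 2:
        raise ValueError("each group needs >= 2 samples")

    Z = _clr(counts.to_numpy(dtype=float))
    obs = Z[ga].mean(axis=0) - Z[gb].mean(axis=0)

    rng = np.random.default_rng(seed)
    n, na = len(Z), int(ga.sum())
    perm_idx = rng.permuted(
        np.tile(np.arange(n), (n_perm, 1)), axis=1
    )
    perm_stats = Z[perm_idx[:, :na]].mean(axis=1) - Z[perm_idx[:, na:]].mean(axis=1)
    pvals = (1 + (np.abs(perm_stats) >= np.abs(obs)[None, :] - 1e-12).sum(axis=0)) / (
        n_perm + 1
    )
    padj = multipletests(pvals, method="fdr_bh")[1]
    return pd.DataFrame(
        {
            "state": counts.columns,
            "effect_clr": obs,
            "direction": np.sign(obs).astype(int),
            "p": pvals,
            "p_adj": padj,
            "credible": padj < fdr,
            "group_high": np.where(obs > 0, levels[0], levels[1]),
        }
    ).reset_index(drop=True)


# ----------------------------------------------------------------------
def _signed_rank_exact_p(w_plus: float, ranks: np.ndarray) -> float:
    """Exact two-sided p for the signed-rank statistic via the full null
    distribution over sign assignments (dynamic program over rank sums;
    midranks handled by doubling to integers)."""
    r2 = np.rint(ranks * 2).astype(int)
    total = int(r2.sum())
    dist = np.zeros(total + 1)
    dist[0] = 1.0
    for r in r2:
        shifted = np.zeros_like(dist)
        shifted[r:] = dist[: total + 1 - r]
        dist = dist + shifted
    dist /= dist.sum()
    w2 = int(round(w_plus * 2))
    cdf = dist[: w2 + 1].sum()
    sf = dist[w2:].sum()
    return float(min(1.0, 2 * min(cdf, sf)))


def paired_shift_test(
    pre: pd.Series,
    post: pd.Series,
    score_name: str = "score",
    group_labels: tuple[str, str] = ("pre", "on"),
    exact_max_n: int = 25,
) -> ShiftTestResult:
    """Two-sided Wilcoxon signed-rank test on paired per-sample scores.

    Pairs are aligned on the index; zero differences are dropped before
    ranking (an all-zero set returns p = 1 with a warning).  The exact null
    is used for up to ``exact_max_n`` informative pairs, the
    continuity-corrected normal approximation beyond.  ``direction`` is the
    sign of the mean paired difference (post minus pre).
    """
    pre, post = pre.align(post, join="inner")
    if len(pre) != len(post) or len(pre) < 2:
        raise ValueError("paired test needs >= 2 aligned pairs")
    d = (post - pre).to_numpy(dtype=float)
    n_pairs = len(d)
    direction = int(np.sign(d.mean()))
    nz = d[d != 0]
    if len(nz) == 0:
        warnings.warn("all paired differences are zero")
        return ShiftTestResult(score_name, group_labels, 0.0, 1.0, 0, n_pairs)
    ranks = stats.rankdata(np.abs(nz))
    w_plus = float(ranks[nz > 0].sum())
    n = len(nz)
    if n <= exact_max_n:
        p = _signed_rank_exact_p(w_plus, ranks)
    else:
        mean = n * (n + 1) / 4
        _, tie_counts = np.unique(ranks, return_counts=True)
        var = n * (n + 1) * (2 * n + 1) / 24 - (
            (tie_counts**3 - tie_counts).sum() / 48
        )
        cc = 0.5 * np.sign(w_plus - mean)
        z = (w_plus - mean - cc) / np.sqrt(var)
        p = float(min(1.0, 2 * stats.norm.sf(abs(z))))
    return ShiftTestResult(score_name, group_labels, w_plus, p, direction, n_pairs)
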