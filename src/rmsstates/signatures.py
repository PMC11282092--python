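"""Consensus metaprogram construction from multiple marker lists.

Cell-state marker lists published for the same tumor entity by independent
studies rarely coincide gene-for-gene.  The consensus rule implemented here
keeps a gene when it is supported by at least ``min_sources`` of the source
lists, or — when ``atlas_counts_as_source`` — by one source list plus the
marker list of the merged-atlas cluster for that state.  Provenance (which
sources supported each gene) is retained so downstream tables can report it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

__all__ = [
    "GeneSignature",
    "SignatureSet",
    "ConsensusRule",
    "build_consensus",
    "apply_aliases",
    "overlap_table",
    "enrichment_test",
]


def _normalize(genes) -> list[str]:
    out, seen = [], set()
    for g in genes:
        g = str(g).strip().upper()
        if g and g not in seen:
            seen.add(g)
            out.append(g)
    return out


@dataclass
class GeneSignature:
    """A named, ordered list of unique gene symbols."""

    name: str
    genes: list[str]
    source: str = ""
    provenance: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.genes = _normalize(self.genes)
        if not self.genes:
            raise ValueError(f"signature {self.name!r} is empty")

    def __len__(self) -> int:
        return len(self.genes)

    def __contains__(self, gene: str) -> bool:
        return str(gene).strip().upper() in set(self.genes)


SignatureSet = Mapping[str, GeneSignature]


@dataclass
class ConsensusRule:
    """How many independent sources a consensus gene needs.

    ``min_sources`` applies to the study marker lists; when
    ``atlas_counts_as_source`` is set, one study list plus membership in the
    atlas cluster markers also qualifies.
    """

    min_sources: int = 2
    atlas_counts_as_source: bool = True

    def __post_init__(self) -> None:
        if self.min_sources < 1:
            raise ValueError("min_sources must be >= 1")


def build_consensus(
    source_lists: Mapping[str, GeneSignature],
    atlas_markers: GeneSignature | None = None,
    rule: ConsensusRule | None = None,
    name: str = "consensus",
) -> GeneSignature:
    """Apply the consensus rule to a family of marker lists.

    Output genes are sorted by number of supporting sources (descending,
    the atlas counting as a source where enabled), then alphabetically;
    per-gene provenance is stored on the returned signature.  An empty
    result returns an empty-bodied signature object (bypassing the
    non-empty invariant) after a warning.
    """
    if not source_lists:
        raise ValueError("build_consensus needs at least one source list")
    rule = rule or ConsensusRule()
    support: dict[str, list[str]] = {}
    for src, sig in source_lists.items():
        for g in sig.genes:
            support.setdefault(g, []).append(src)
    atlas_genes = set(atlas_markers.genes) if atlas_markers is not None else set()

    kept: dict[str, list[str]] = {}
    for g, srcs in support.items():
        n = len(srcs)
        in_atlas = g in atlas_genes
        if n >= rule.min_sources or (
            rule.atlas_counts_as_source and in_atlas and n >= 1
        ):
            kept[g] = srcs + (["atlas"] if in_atlas else [])

    if not kept:
        import warnings

        warnings.warn(f"consensus {name!r} is empty under the given rule")
        sig = GeneSignature.__new__(GeneSignature)
        sig.name, sig.genes, sig.source, sig.provenance = name, [], "consensus", {}
        return sig

    order = sorted(kept, key=lambda g: (-len(kept[g]), g))
    return GeneSignature(
        name=name, genes=order, source="consensus", provenance={g: kept[g] for g in order}
    )


def consensus_provenance_table(sig: GeneSignature) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "gene": list(sig.provenance),
            "n_sources": [len(v) for v in sig.provenance.values()],
            "sources": [",".join(v) for v in sig.provenance.values()],
        }
    )


def apply_aliases(
    sig: GeneSignature, alias_map: Mapping[str, str]
) -> GeneSignature:
    """Translate signature symbols through an alias table (case-insensitive
    keys); symbols without an entry pass through unchanged.  No alias
    resolution happens by default anywhere — this is the explicit hook for
    matrices whose gene symbols use a different nomenclature."""
    table = {str(k).strip().upper(): str(v).strip().upper()
             for k, v in alias_map.items()}
    genes = [table.get(g, g) for g in sig.genes]
    return GeneSignature(sig.name, genes, source=sig.source)


# ----------------------------------------------------------------------
def overlap_table(lists: Mapping[str, GeneSignature]) -> pd.DataFrame:
    """Counts of every membership region among k lists (2^k - 1 rows).

    Each row flags membership per list plus the number of genes exactly in
    that region — the counts a Venn diagram displays.
    """
    if len(lists) < 2:
        raise ValueError("overlap_table needs >= 2 lists")
    names = list(lists)
    sets = {n: set(lists[n].genes) for n in names}
    universe = set().union(*sets.values())
    region_counts: dict[tuple[bool, ...], int] = {}
    for g in universe:
        key = tuple(g in sets[n] for n in names)
        region_counts[key] = region_counts.get(key, 0) + 1
    rows = []
    for k in range(1, 2 ** len(names)):
        key = tuple(bool(k & (1 << i)) for i in range(len(names)))
        rows.append({**{n: key[i] for i, n in enumerate(names)},
                     "count": region_counts.get(key, 0)})
    return pd.DataFrame(rows)


# ----------------------------------------------------------------------
def enrichment_test(
    query: GeneSignature,
    term_sets: Mapping[str, GeneSignature],
    universe_size: int,
) -> pd.DataFrame:
    """Hypergeometric over-representation of a gene list in each term set.

    ``p = P(X >= overlap)`` for ``X ~ Hypergeom(universe, term, |query|)``,
    BH-adjusted across terms.  A local replacement for web-service
    enrichment used during cluster annotation.
    """
    if len(query) == 0:
        raise ValueError("enrichment query is empty")
    q = set(query.genes)
    if universe_size < max(len(q), *(len(t) for t in term_sets.values())):
        raise ValueError("universe smaller than a gene set")
    rows = []
    for term, sig in term_sets.items():
        t = set(sig.genes)
        k = len(q & t)
        p = float(hypergeom.sf(k - 1, universe_size, len(t), len(q)))
        rows.append({"term": term, "overlap": k, "term_size": len(t),
                     "query_size": len(q), "p": min(p, 1.0)})
    df = pd.DataFrame(rows)
    df["p_adj"] = multipletests(df["p"], method="fdr_bh")[1]
    df = df.sort_values(["p", "term"], kind="stable").reset_index(drop=True)
    return df
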