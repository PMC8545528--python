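"""Over-representation analysis of node sets against gene-set collections.

Modules and hub gene lists are tested against user-supplied collections
(GO-like, pathway-like) by the upper-tail hypergeometric test, with
Benjamini-Hochberg correction across the collection.  Only coding genes
are meaningful queries; lncRNA nodes are excluded upstream.  The default
universe is the union of all collection genes plus the query.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd
from scipy import stats

from .errors import ValidationError
from .expression import bh_adjust


@dataclass
class GeneSetCollection:
    """Named, non-empty gene sets with a source label."""

    sets: dict[str, frozenset] = field(default_factory=dict)
    source: str = "custom"

    def __post_init__(self) -> None:
        empty = [n for n, s in self.sets.items() if not s]
        if empty:
            raise ValidationError(f"empty gene sets not allowed: {empty[:3]}")

    def all_genes(self) -> frozenset:
        out: set = set()
        for s in self.sets.values():
            out |= s
        return frozenset(out)

    def __len__(self) -> int:
        return len(self.sets)


def hypergeom_overrep(
    query: Iterable[str], geneset: Iterable[str], universe: Iterable[str]
) -> float:
    """P(X >= overlap) under sampling |query| genes from the universe."""
    query, geneset, universe = set(query), set(geneset), set(universe)
    if not query <= universe:
        raise ValidationError("query must be a subset of the universe")
    if not geneset <= universe:
        raise ValidationError("gene set must be a subset of the universe")
    overlap = len(query & geneset)
    return float(
        stats.hypergeom.sf(overlap - 1, len(universe), len(geneset), len(query))
    )


def enrich(
    query: Iterable[str],
    collection: GeneSetCollection,
    universe: Iterable[str] | None = None,
) -> pd.DataFrame:
    """One row per set with BH-adjusted p-values, sorted by (padj, name)."""
    query = set(query)
    if universe is None:
        universe = collection.all_genes() | query
    universe = set(universe)
    rows = []
    for name in sorted(collection.sets):
        members = collection.sets[name] & universe
        overlap = len(query & members)
        p = hypergeom_overrep(query, members, universe)
        rows.append((name, overlap, len(members), len(query),
                     len(universe), p))
    df = pd.DataFrame(
        rows,
        columns=["set_name", "overlap", "set_size", "query_size",
                 "universe_size", "p"],
    )
    if not df.empty:
        df["p_bh"] = bh_adjust(df["p"])
        df = df.sort_values(["p_bh", "set_name"], kind="mergesort")
        df = df.reset_index(drop=True)
    else:
        df["p_bh"] = []
    return df


def read_gmt(path: str, source: str | None = None) -> GeneSetCollection:
    """GMT format: name <tab> description <tab> gene1 <tab> gene2 ..."""
    sets: dict[str, frozenset] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3 or not parts[0]:
                continue
            if parts[0] in sets:
                raise ValidationError(f"duplicate set name {parts[0]!r}")
            genes = frozenset(g for g in parts[2:] if g)
            if genes:
                sets[parts[0]] = genes
    return GeneSetCollection(sets, source or "gmt")


def write_gmt(collection: GeneSetCollection | Mapping[str, frozenset],
              path: str) -> None:
    sets = collection.sets if isinstance(collection, GeneSetCollection) \
        else collection
    source = collection.source if isinstance(collection, GeneSetCollection) \
        else "custom"
    with open(path, "w") as fh:
        for name in sorted(sets):
            genes = "\t".join(sorted(sets[name]))
            fh.write(f"{name}\t{source}\t{genes}\n")
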