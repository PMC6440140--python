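"""Hypergeometric over-representation of gene lists in user-supplied sets.

Given a DEG list L, a universe U and a gene set S (both restricted to U),
the enrichment p-value is the upper-tail hypergeometric probability of
drawing at least the observed overlap when |L| genes are sampled from U
without replacement. BH FDR is applied across all sets of a collection.
No ontology structure is used: sets are flat GMT entries.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from scipy import stats

from .cellcomp import bh_fdr
from .io import FormatError

__all__ = [
    "GeneSetCollection",
    "EnrichmentRecord",
    "read_gmt",
    "hypergeom_enrich",
    "write_enrichment",
]


@dataclass(frozen=True)
class GeneSetCollection:
    """Named gene sets restricted to a universe."""

    sets: Mapping[str, frozenset[int]]
    universe: frozenset[int]

    def __post_init__(self) -> None:
        restricted = {
            name: frozenset(genes) & self.universe for name, genes in self.sets.items()
        }
        object.__setattr__(self, "sets", restricted)
        object.__setattr__(self, "universe", frozenset(self.universe))
        if not self.universe:
            raise ValueError("empty gene universe")


@dataclass(frozen=True)
class EnrichmentRecord:
    set_name: str
    overlap: int
    set_size: int
    list_size: int
    universe_size: int
    p_value: float
    fdr: float

    def __post_init__(self) -> None:
        if self.overlap > min(self.set_size, self.list_size):
            raise ValueError("overlap cannot exceed set or list size")


def read_gmt(path, universe: Iterable[int]) -> GeneSetCollection:
    """Read GMT: ``set_name<TAB>description<TAB>gene1<TAB>gene2...`` per line."""
    sets: dict[str, frozenset[int]] = {}
    with open(path, "rt", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}:{lineno}: expected name, description, genes...")
            name = parts[0]
            if name in sets:
                raise FormatError(f"{path}:{lineno}: duplicate set name {name!r}")
            try:
                sets[name] = frozenset(int(g) for g in parts[2:] if g.strip())
            except ValueError:
                raise FormatError(f"{path}:{lineno}: non-integer gene ID") from None
    return GeneSetCollection(sets, frozenset(int(g) for g in universe))


def hypergeom_enrich(
    deg_list: Iterable[int], collection: GeneSetCollection
) -> list[EnrichmentRecord]:
    """Upper-tail hypergeometric p per set, BH FDR across sets.

    The DEG list is restricted to the universe first; sets with zero overlap
    get p = 1 by convention. Records come back sorted by set name so results
    do not depend on the collection's iteration order.
    """
    genes = frozenset(int(g) for g in deg_list) & collection.universe
    if not genes:
        raise ValueError("DEG list is disjoint from the gene universe")
    m = len(collection.universe)
    n_list = len(genes)
    names = sorted(collection.sets)
    pvals: list[float] = []
    overlaps: list[int] = []
    for name in names:
        members = collection.sets[name]
        k = len(genes & members)
        overlaps.append(k)
        if k == 0:
            pvals.append(1.0)
        else:
            # P(X >= k), X ~ Hypergeom(M=m, K=|set|, N=|list|)
            pvals.append(float(stats.hypergeom.sf(k - 1, m, len(members), n_list)))
    fdrs = bh_fdr(pvals)
    return [
        EnrichmentRecord(
            name, k, len(collection.sets[name]), n_list, m, p, float(q)
        )
        for name, k, p, q in zip(names, overlaps, pvals, fdrs)
    ]


def write_enrichment(records: Sequence[EnrichmentRecord], path) -> None:
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write("set_name\toverlap\tset_size\tlist_size\tuniverse_size\tp\tfdr\n")
        for r in records:
            fh.write(
                f"{r.set_name}\t{r.overlap}\t{r.set_size}\t{r.list_size}\t"
                f"{r.universe_size}\t{r.p_value:.6g}\t{r.fdr:.6g}\n"
            )
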