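"""Expression-matrix containers, probe-to-gene collapsing and text I/O.

Within-sample relative expression orderings (REOs) only ever compare two
values measured in the *same* sample, so the expression scale may be linear
or log and no normalization is applied anywhere in this package: any
strictly increasing per-sample transform (the usual model of a batch
effect) leaves every REO, and therefore every downstream result, unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ProbeMatrix",
    "PlatformMap",
    "ExpressionMatrix",
    "map_probes_to_genes",
    "read_expression_tsv",
    "write_expression_tsv",
    "read_platform_map",
    "read_geo_series_matrix",
    "pool_matrices",
]

# Entrez gene IDs are positive and comfortably below 2**31; the bound lets
# pair keys be packed into a single int64 downstream.
_MAX_GENE_ID = 2**31 - 1


class FormatError(ValueError):
    """Raised when an input file violates its documented layout."""


@dataclass(frozen=True)
class ProbeMatrix:
    """Probe-level expression values, probes x samples."""

    probe_ids: tuple[str, ...]
    sample_ids: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", vals)
        if vals.shape != (len(self.probe_ids), len(self.sample_ids)):
            raise ValueError(
                f"value shape {vals.shape} does not match "
                f"{len(self.probe_ids)} probes x {len(self.sample_ids)} samples"
            )
        if len(set(self.probe_ids)) != len(self.probe_ids):
            raise ValueError("duplicate probe IDs")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample IDs")
        if not np.all(np.isfinite(vals)):
            raise ValueError("non-finite expression values")


@dataclass(frozen=True)
class PlatformMap:
    """Probe ID -> set of Entrez gene IDs; an empty set marks an unmapped probe."""

    entries: Mapping[str, frozenset[int]]

    def __post_init__(self) -> None:
        clean = {}
        for probe, genes in self.entries.items():
            gs = frozenset(int(g) for g in genes)
            for g in gs:
                if not (0 < g <= _MAX_GENE_ID):
                    raise ValueError(f"gene ID {g} for probe {probe!r} out of range")
            clean[str(probe)] = gs
        object.__setattr__(self, "entries", clean)

    def genes_for(self, probe: str) -> frozenset[int]:
        return self.entries.get(probe, frozenset())


@dataclass(frozen=True)
class ExpressionMatrix:
    """Gene-level expression, genes x samples, gene IDs unique and ascending."""

    gene_ids: np.ndarray
    sample_ids: tuple[str, ...]
    values: np.ndarray
    condition_label: str | None = None

    def __post_init__(self) -> None:
        genes = np.asarray(self.gene_ids, dtype=np.int64)
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "gene_ids", genes)
        object.__setattr__(self, "values", vals)
        object.__setattr__(self, "sample_ids", tuple(str(s) for s in self.sample_ids))
        if genes.ndim != 1:
            raise ValueError("gene_ids must be one-dimensional")
        if vals.shape != (genes.size, len(self.sample_ids)):
            raise ValueError(
                f"value shape {vals.shape} does not match "
                f"{genes.size} genes x {len(self.sample_ids)} samples"
            )
        if len(self.sample_ids) < 1:
            raise ValueError("at least one sample required")
        if genes.size and (np.any(genes[:-1] >= genes[1:])):
            raise ValueError("gene_ids must be strictly increasing")
        if genes.size and (genes[0] <= 0 or genes[-1] > _MAX_GENE_ID):
            raise ValueError("gene IDs must be positive 31-bit integers")
        if not np.all(np.isfinite(vals)):
            raise ValueError("non-finite expression values")

    @property
    def n_genes(self) -> int:
        return int(self.gene_ids.size)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def sample_values(self, sample_id: str) -> dict[int, float]:
        """Gene -> value map for one sample."""
        j = self.sample_ids.index(sample_id)
        return dict(zip(self.gene_ids.tolist(), self.values[:, j].tolist()))

    def restrict_genes(self, gene_ids: Iterable[int]) -> "ExpressionMatrix":
        keep = np.isin(self.gene_ids, np.asarray(sorted(set(gene_ids)), dtype=np.int64))
        return ExpressionMatrix(
            self.gene_ids[keep], self.sample_ids, self.values[keep], self.condition_label
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=list(self.sample_ids))


def map_probes_to_genes(probes: ProbeMatrix, platform: PlatformMap) -> ExpressionMatrix:
    """Collapse a probe matrix to a gene matrix.

    Probes mapping to zero or multiple genes are deleted; when several probes
    map uniquely to one gene the gene's value is the arithmetic mean of those
    probes' values, per sample. A probe absent from the platform map counts
    as unmapped.
    """
    per_gene: dict[int, list[int]] = {}
    for i, probe in enumerate(probes.probe_ids):
        genes = platform.genes_for(probe)
        if len(genes) != 1:
            continue
        (gene,) = genes
        per_gene.setdefault(gene, []).append(i)
    if not per_gene:
        raise ValueError("no genes after mapping: every probe maps to zero or multiple genes")
    gene_ids = np.array(sorted(per_gene), dtype=np.int64)
    values = np.empty((gene_ids.size, len(probes.sample_ids)))
    for row, gene in enumerate(gene_ids.tolist()):
        values[row] = probes.values[per_gene[gene]].mean(axis=0)
    return ExpressionMatrix(gene_ids, probes.sample_ids, values)


def _parse_gene_id(token: str, where: str) -> int:
    try:
        gid = int(token)
    except ValueError:
        raise FormatError(f"{where}: gene ID {token!r} is not an integer") from None
    if not (0 < gid <= _MAX_GENE_ID):
        raise FormatError(f"{where}: gene ID {gid} out of range")
    return gid


def read_expression_tsv(path) -> ExpressionMatrix:
    """Read a gene-level expression TSV: header ``gene_id<TAB>sample...``, numeric body."""
    with open(path, "rt", encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n")
        if not header:
            raise FormatError(f"{path}: empty file")
        cols = header.split("\t")
        sample_ids = cols[1:]
        if not sample_ids:
            raise FormatError(f"{path}: header has no sample columns")
        gene_ids: list[int] = []
        rows: list[list[float]] = []
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != len(cols):
                raise FormatError(
                    f"{path}:{lineno}: expected {len(cols)} fields, found {len(parts)}"
                )
            gene_ids.append(_parse_gene_id(parts[0], f"{path}:{lineno}"))
            try:
                rows.append([float(x) for x in parts[1:]])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-numeric cell ({exc})") from None
    if len(set(gene_ids)) != len(gene_ids):
        dupes = sorted({g for g in gene_ids if gene_ids.count(g) > 1})
        raise FormatError(f"{path}: duplicated gene IDs {dupes[:5]}")
    order = np.argsort(np.asarray(gene_ids, dtype=np.int64), kind="stable")
    genes = np.asarray(gene_ids, dtype=np.int64)[order]
    vals = np.asarray(rows, dtype=float)[order]
    try:
        return ExpressionMatrix(genes, tuple(sample_ids), vals)
    except ValueError as exc:
        raise FormatError(f"{path}: {exc}") from None


def write_expression_tsv(matrix: ExpressionMatrix, path) -> None:
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write("gene_id\t" + "\t".join(matrix.sample_ids) + "\n")
        for gid, row in zip(matrix.gene_ids.tolist(), matrix.values):
            fh.write(str(gid) + "\t" + "\t".join(repr(v) for v in row.tolist()) + "\n")


def read_platform_map(path) -> PlatformMap:
    """Read ``probe_id<TAB>gene_id[;gene_id...]``; an empty second field = unmapped."""
    entries: dict[str, frozenset[int]] = {}
    with open(path, "rt", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) not in (1, 2):
                raise FormatError(f"{path}:{lineno}: expected 2 tab-separated fields")
            probe = parts[0]
            if probe in entries:
                raise FormatError(f"{path}:{lineno}: probe {probe!r} listed twice")
            gene_field = parts[1] if len(parts) == 2 else ""
            if gene_field.strip():
                genes = frozenset(
                    _parse_gene_id(tok, f"{path}:{lineno}")
                    for tok in gene_field.split(";")
                    if tok.strip()
                )
            else:
                genes = frozenset()
            entries[probe] = genes
    return PlatformMap(entries)


_TABLE_BEGIN = "!series_matrix_table_begin"
_TABLE_END = "!series_matrix_table_end"


def read_geo_series_matrix(path) -> ProbeMatrix:
    """Read the probe table embedded in a GEO series-matrix text file.

    Metadata lines (prefixed ``!``) are ignored apart from locating the table
    delimiters; the table's header row supplies sample IDs. Values quoted with
    double quotes are accepted, as GEO emits them for the ID column.
    """
    probe_ids: list[str] = []
    sample_ids: list[str] = []
    rows: list[list[float]] = []
    in_table = False
    saw_begin = saw_end = False
    with open(path, "rt", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if line.startswith(_TABLE_BEGIN):
                saw_begin, in_table = True, True
                continue
            if line.startswith(_TABLE_END):
                saw_end, in_table = True, False
                continue
            if not in_table or not line:
                continue
            parts = [p.strip('"') for p in line.split("\t")]
            if not sample_ids:
                sample_ids = parts[1:]
                continue
            probe_ids.append(parts[0])
            try:
                rows.append([float(x) for x in parts[1:]])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-numeric cell ({exc})") from None
    if not saw_begin or not saw_end:
        raise FormatError(f"{path}: missing {_TABLE_BEGIN}/{_TABLE_END} delimiters")
    if not sample_ids or not probe_ids:
        raise FormatError(f"{path}: series-matrix table is empty")
    return ProbeMatrix(tuple(probe_ids), tuple(sample_ids), np.asarray(rows, dtype=float))


def pool_matrices(matrices: Sequence[ExpressionMatrix], condition_label: str | None = None) -> ExpressionMatrix:
    """Pool samples from several datasets over the intersection of their genes.

    Every pair must be evaluable in every accumulated sample, so the pooled
    gene universe is the intersection of the contributing gene universes.
    Sample IDs are prefixed with the dataset index on collision.
    """
    if not matrices:
        raise ValueError("no matrices to pool")
    common = matrices[0].gene_ids
    for m in matrices[1:]:
        common = np.intersect1d(common, m.gene_ids)
    if common.size == 0:
        raise ValueError("pooled gene universe is empty: matrices share no genes")
    blocks = []
    sample_ids: list[str] = []
    seen = set()
    for k, m in enumerate(matrices):
        idx = np.searchsorted(m.gene_ids, common)
        blocks.append(m.values[idx])
        for s in m.sample_ids:
            name = s if s not in seen else f"ds{k}:{s}"
            if name in seen:  # still colliding: disambiguate deterministically
                i = 2
                while f"{name}.{i}" in seen:
                    i += 1
                name = f"{name}.{i}"
            seen.add(name)
            sample_ids.append(name)
    return ExpressionMatrix(common, tuple(sample_ids), np.hstack(blocks), condition_label)
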