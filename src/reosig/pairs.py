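"""Stable gene-pair discovery and reversal-signature construction.

A gene pair (Gi, Gj) within one sample is a two-outcome event: Gi > Gj or
Gi < Gj (a tie supports neither outcome). A *highly stable* pair holds the
same strict ordering in (by default all of) the accumulated samples of one
condition; a *stable reversal* pair is stable in two conditions with
opposite orderings. The reversal set, stored with the mature-condition
direction, is the qualitative signature everything downstream consumes.

Pairs are stored canonically as (gene_a, gene_b, direction) with
gene_a < gene_b and direction +1 for expr(gene_a) > expr(gene_b), -1 for <.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .io import ExpressionMatrix, FormatError

__all__ = [
    "GT",
    "LT",
    "StablePairSet",
    "ReversalSignature",
    "find_stable_pairs",
    "intersect_reversal",
    "write_signature",
    "read_signature",
]

logger = logging.getLogger(__name__)

GT: int = 1   # expr(gene_a) > expr(gene_b)
LT: int = -1  # expr(gene_a) < expr(gene_b)

_DIR_TOKEN = {GT: "gt", LT: "lt"}
_TOKEN_DIR = {v: k for k, v in _DIR_TOKEN.items()}


def _pack(gene_a: np.ndarray, gene_b: np.ndarray) -> np.ndarray:
    """Pack a canonical pair into one int64 key (gene IDs are < 2**31)."""
    return (gene_a.astype(np.int64) << np.int64(31)) | gene_b.astype(np.int64)


@dataclass(frozen=True)
class _PairTable:
    """Shared storage for canonical pair triples, sorted by (gene_a, gene_b)."""

    gene_a: np.ndarray
    gene_b: np.ndarray
    direction: np.ndarray

    def __post_init__(self) -> None:
        a = np.ascontiguousarray(self.gene_a, dtype=np.int64)
        b = np.ascontiguousarray(self.gene_b, dtype=np.int64)
        d = np.ascontiguousarray(self.direction, dtype=np.int8)
        if not (a.shape == b.shape == d.shape) or a.ndim != 1:
            raise ValueError("pair arrays must be one-dimensional and equal-length")
        if np.any(a >= b):
            raise ValueError("pairs must be canonical: gene_a < gene_b")
        if a.size and not np.all(np.isin(d, (GT, LT))):
            raise ValueError("direction must be +1 (gt) or -1 (lt)")
        keys = _pack(a, b)
        order = np.argsort(keys, kind="stable")
        keys = keys[order]
        if keys.size > 1 and np.any(keys[:-1] == keys[1:]):
            raise ValueError("duplicate gene pair")
        object.__setattr__(self, "gene_a", a[order])
        object.__setattr__(self, "gene_b", b[order])
        object.__setattr__(self, "direction", d[order])

    @property
    def n_pairs(self) -> int:
        return int(self.gene_a.size)

    def keys(self) -> np.ndarray:
        return _pack(self.gene_a, self.gene_b)

    def as_set(self) -> set[tuple[int, int, int]]:
        """Pairs as python triples (gene_a, gene_b, direction) — small sets only."""
        return set(
            zip(self.gene_a.tolist(), self.gene_b.tolist(), self.direction.tolist())
        )


@dataclass(frozen=True)
class StablePairSet(_PairTable):
    """Gene pairs ordered identically in >= ceil(fraction * n_samples) samples."""

    condition_label: str = ""
    n_samples: int = 1
    stability_fraction: float = 1.0

    def __post_init__(self) -> None:
        super().__post_init__()
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        if not (0.5 < self.stability_fraction <= 1.0):
            raise ValueError("stability_fraction must lie in (0.5, 1]")


@dataclass(frozen=True)
class ReversalSignature(_PairTable):
    """Pairs stable in both conditions with opposite directions.

    ``direction`` is the mature-condition ordering — the golden standard a
    sample is scored against.
    """

    mature_label: str = "mature"
    immature_label: str = "immature"

    @property
    def n(self) -> int:
        return self.n_pairs


def find_stable_pairs(
    matrix: ExpressionMatrix,
    stability_fraction: float = 1.0,
    block_size: int = 512,
) -> StablePairSet:
    """Find every gene pair with a condition-wide stable strict ordering.

    Ties count as neither outcome, so at the default ``stability_fraction``
    of 1.0 a single tied sample disqualifies a pair. Comparisons run in
    gene-row blocks of ``block_size`` against all genes, accumulating
    per-pair outcome counts in int16, so peak memory is
    O(block_size * n_genes) regardless of the (possibly ~1e8) pair count.
    """
    if not (0.5 < stability_fraction <= 1.0):
        raise ValueError("stability_fraction must lie in (0.5, 1]")
    if block_size < 1:
        raise ValueError("block_size must be positive")
    n, m = matrix.n_genes, matrix.n_samples
    if m > np.iinfo(np.int16).max:
        raise ValueError("more samples than the int16 accumulator supports")
    need = math.ceil(stability_fraction * m)
    vals = matrix.values
    genes = matrix.gene_ids
    a_chunks: list[np.ndarray] = []
    b_chunks: list[np.ndarray] = []
    d_chunks: list[np.ndarray] = []
    for i0 in range(0, n, block_size):
        i1 = min(i0 + block_size, n)
        block = vals[i0:i1]  # (b, m)
        gt = np.zeros((i1 - i0, n), dtype=np.int16)
        lt = np.zeros((i1 - i0, n), dtype=np.int16)
        for s in range(m):
            col = vals[:, s]
            bcol = block[:, s][:, None]
            gt += bcol > col[None, :]
            lt += bcol < col[None, :]
        # keep only the upper triangle (j > global row index) for canonical pairs
        rows, cols = np.nonzero(
            ((gt >= need) | (lt >= need))
            & (np.arange(n)[None, :] > (np.arange(i0, i1)[:, None]))
        )
        if rows.size:
            a_chunks.append(genes[rows + i0])
            b_chunks.append(genes[cols])
            d_chunks.append(np.where(gt[rows, cols] >= need, GT, LT).astype(np.int8))
    if a_chunks:
        gene_a = np.concatenate(a_chunks)
        gene_b = np.concatenate(b_chunks)
        direction = np.concatenate(d_chunks)
    else:
        gene_a = np.empty(0, dtype=np.int64)
        gene_b = np.empty(0, dtype=np.int64)
        direction = np.empty(0, dtype=np.int8)
    label = matrix.condition_label or ""
    logger.info(
        "find_stable_pairs[%s]: %d genes, %d samples -> %d stable pairs",
        label, n, m, gene_a.size,
    )
    return StablePairSet(
        gene_a, gene_b, direction,
        condition_label=label, n_samples=m, stability_fraction=stability_fraction,
    )


def intersect_reversal(mature: StablePairSet, immature: StablePairSet) -> ReversalSignature:
    """Pairs stable in both conditions with opposite directions.

    The stored direction is the mature-condition ordering.
    """
    keys_m = mature.keys()
    keys_i = immature.keys()
    common, idx_m, idx_i = np.intersect1d(
        keys_m, keys_i, assume_unique=True, return_indices=True
    )
    reversed_mask = mature.direction[idx_m] == -immature.direction[idx_i]
    sel = idx_m[reversed_mask]
    sig = ReversalSignature(
        mature.gene_a[sel], mature.gene_b[sel], mature.direction[sel],
        mature_label=mature.condition_label or "mature",
        immature_label=immature.condition_label or "immature",
    )
    if sig.n == 0:
        logger.warning(
            "intersect_reversal: empty signature (%d and %d stable pairs, "
            "%d shared, none reversed)", mature.n_pairs, immature.n_pairs, common.size,
        )
    else:
        logger.info(
            "intersect_reversal: %d shared stable pairs, %d reversed",
            common.size, sig.n,
        )
    return sig


def write_signature(sig: ReversalSignature, path) -> None:
    """Write a signature TSV: ``#mature=``/``#immature=``/``#n=`` header, then
    ``gene_a<TAB>gene_b<TAB>direction`` rows with direction in {gt, lt}."""
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write(f"#mature={sig.mature_label}\n")
        fh.write(f"#immature={sig.immature_label}\n")
        fh.write(f"#n={sig.n}\n")
        for a, b, d in zip(sig.gene_a.tolist(), sig.gene_b.tolist(), sig.direction.tolist()):
            fh.write(f"{a}\t{b}\t{_DIR_TOKEN[d]}\n")


def read_signature(path) -> ReversalSignature:
    mature_label = "mature"
    immature_label = "immature"
    declared_n: int | None = None
    gene_a: list[int] = []
    gene_b: list[int] = []
    direction: list[int] = []
    with open(path, "rt", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                key, _, value = line[1:].partition("=")
                if key == "mature":
                    mature_label = value
                elif key == "immature":
                    immature_label = value
                elif key == "n":
                    declared_n = int(value)
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise FormatError(f"{path}:{lineno}: expected 3 fields")
            try:
                a, b = int(parts[0]), int(parts[1])
            except ValueError:
                raise FormatError(f"{path}:{lineno}: non-integer gene ID") from None
            if parts[2] not in _TOKEN_DIR:
                raise FormatError(
                    f"{path}:{lineno}: direction {parts[2]!r} not in {{gt, lt}}"
                )
            if not a < b:
                raise FormatError(f"{path}:{lineno}: pair not canonical (gene_a < gene_b)")
            gene_a.append(a)
            gene_b.append(b)
            direction.append(_TOKEN_DIR[parts[2]])
    try:
        sig = ReversalSignature(
            np.asarray(gene_a, dtype=np.int64),
            np.asarray(gene_b, dtype=np.int64),
            np.asarray(direction, dtype=np.int8),
            mature_label=mature_label,
            immature_label=immature_label,
        )
    except ValueError as exc:
        raise FormatError(f"{path}: {exc}") from None
    if declared_n is not None and declared_n != sig.n:
        raise FormatError(f"{path}: header n={declared_n} but {sig.n} pairs in body")
    return sig
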