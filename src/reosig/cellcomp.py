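"""REO-based differential expression for 1-3 replicate samples (CellComp).

Each gene carries a backbone of ordering partners derived from the stable
pairs of an accumulated reference condition: partners the gene stably
exceeds (Ng) and partners stably exceeding it (Nl). In the test sample(s)
each partner is re-classified by the consensus of the replicates — counted
only when every replicate agrees strictly on the ordering. A gene whose
(greater, less) partner split shifts between reference and test betrays a
large expression change; the shift is tested with Fisher's exact test on

    [[Ng_ref, Nl_ref],
     [ng_test, nl_test]]

(both rows over the consensus partners), with Benjamini-Hochberg FDR
control across genes. This rank-disruption test retains power at two or
three technical replicates where variance-based tests cannot be estimated.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import ExpressionMatrix
from .pairs import GT, StablePairSet

__all__ = [
    "ReferenceBackbone",
    "Contingency2x2",
    "DEGRecord",
    "build_backbone",
    "gene_contingency",
    "fisher_exact_two_sided",
    "bh_fdr",
    "call_degs",
    "write_degs",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Contingency2x2:
    """Partner-count table: rows (reference, test), columns (greater, less)."""

    n_greater_ref: int
    n_less_ref: int
    n_greater_test: int
    n_less_test: int

    def __post_init__(self) -> None:
        if min(self.n_greater_ref, self.n_less_ref, self.n_greater_test, self.n_less_test) < 0:
            raise ValueError("contingency entries must be non-negative")
        if self.n_greater_ref + self.n_less_ref != self.n_greater_test + self.n_less_test:
            raise ValueError("reference and test rows must cover the same partners")

    @property
    def table(self) -> np.ndarray:
        return np.array(
            [[self.n_greater_ref, self.n_less_ref],
             [self.n_greater_test, self.n_less_test]],
            dtype=np.int64,
        )

    @property
    def n_partners(self) -> int:
        return self.n_greater_ref + self.n_less_ref


@dataclass(frozen=True)
class ReferenceBackbone:
    """Per-gene ordering-partner index derived from reference stable pairs."""

    stable_pairs: StablePairSet
    below: dict[int, np.ndarray]  # gene -> partners the gene stably exceeds
    above: dict[int, np.ndarray]  # gene -> partners stably exceeding the gene

    @property
    def genes(self) -> list[int]:
        return sorted(set(self.below) | set(self.above))

    def partners(self, gene: int) -> tuple[np.ndarray, np.ndarray]:
        empty = np.empty(0, dtype=np.int64)
        return self.below.get(gene, empty), self.above.get(gene, empty)


def build_backbone(reference_stable: StablePairSet) -> ReferenceBackbone:
    """Index each gene's below/above partner sets from the stable pairs.

    For a pair (a, b, gt): a exceeds b, so b is a below-partner of a and a
    an above-partner of b; (a, b, lt) is the mirror image.
    """
    below: dict[int, list[int]] = {}
    above: dict[int, list[int]] = {}
    for a, b, d in zip(
        reference_stable.gene_a.tolist(),
        reference_stable.gene_b.tolist(),
        reference_stable.direction.tolist(),
    ):
        hi, lo = (a, b) if d == GT else (b, a)
        below.setdefault(hi, []).append(lo)
        above.setdefault(lo, []).append(hi)
    return ReferenceBackbone(
        reference_stable,
        {g: np.asarray(sorted(v), dtype=np.int64) for g, v in below.items()},
        {g: np.asarray(sorted(v), dtype=np.int64) for g, v in above.items()},
    )


def _consensus_counts(
    gene: int, backbone: ReferenceBackbone, test: ExpressionMatrix
) -> Contingency2x2:
    pos = int(np.searchsorted(test.gene_ids, gene))
    if pos >= test.n_genes or test.gene_ids[pos] != gene:
        raise ValueError(f"gene {gene} absent from test samples")
    below_ref, above_ref = backbone.partners(gene)
    if below_ref.size + above_ref.size == 0:
        raise ValueError(f"gene {gene} has no reference partners")
    gvals = test.values[pos]  # (replicates,)
    ngr = nlr = ngt = nlt = 0
    for partners, is_below_ref in ((below_ref, True), (above_ref, False)):
        if partners.size == 0:
            continue
        idx = np.searchsorted(test.gene_ids, partners)
        present = (idx < test.n_genes) & (test.gene_ids[np.minimum(idx, test.n_genes - 1)] == partners)
        if not present.any():
            continue
        pvals = test.values[idx[present]]  # (P, replicates)
        test_below = np.all(pvals < gvals[None, :], axis=1)
        test_above = np.all(pvals > gvals[None, :], axis=1)
        consensus = test_below | test_above  # others: tied/inconsistent, excluded
        k = int(consensus.sum())
        if is_below_ref:
            ngr += k
        else:
            nlr += k
        ngt += int(test_below.sum())
        nlt += int(test_above.sum())
    return Contingency2x2(ngr, nlr, ngt, nlt)


def gene_contingency(
    gene: int, backbone: ReferenceBackbone, test_samples: ExpressionMatrix
) -> Contingency2x2:
    """Partner table for one gene against 1-3 test replicates.

    A partner enters the table only when all replicates agree strictly on
    its ordering against the gene; tied or inconsistent partners shrink the
    margins. Partners missing from the test matrix are dropped.
    """
    if not (1 <= test_samples.n_samples <= 3):
        raise ValueError("CellComp targets 1-3 technical replicates")
    return _consensus_counts(gene, backbone, test_samples)


def fisher_exact_two_sided(table: Contingency2x2 | np.ndarray) -> float:
    """Two-sided Fisher exact p: the hypergeometric mass of all tables with
    the observed margins no more probable than the observed one. Degenerate
    (zero-margin) tables give p = 1."""
    arr = table.table if isinstance(table, Contingency2x2) else np.asarray(table, dtype=np.int64)
    if arr.shape != (2, 2) or np.any(arr < 0):
        raise ValueError("need a non-negative 2x2 table")
    if arr.sum() == 0:
        return 1.0
    p = float(stats.fisher_exact(arr, alternative="two-sided")[1])
    return min(max(p, np.nextafter(0.0, 1.0)), 1.0)


def bh_fdr(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass(frozen=True)
class DEGRecord:
    gene_id: int
    n_greater_ref: int
    n_less_ref: int
    n_greater_test: int
    n_less_test: int
    p_value: float
    fdr: float
    direction: str  # up / down / none; none iff fdr >= threshold


def call_degs(
    backbone: ReferenceBackbone,
    test_samples: ExpressionMatrix,
    fdr_threshold: float = 0.05,
    min_partners: int = 5,
) -> list[DEGRecord]:
    """Test every backbone gene measured in the test replicates.

    Genes whose consensus partner count falls below ``min_partners`` are
    skipped (Fisher's test on tiny margins is uninformative). Direction is
    up when the gene exceeds a larger share of its partners in the test
    consensus than in the reference, down when smaller, and only assigned
    below the FDR threshold. Records are ordered by gene ID.
    """
    if not (1 <= test_samples.n_samples <= 3):
        raise ValueError("CellComp targets 1-3 technical replicates")
    test_gene_set = set(test_samples.gene_ids.tolist())
    rows: list[tuple[int, Contingency2x2]] = []
    for gene in backbone.genes:
        if gene not in test_gene_set:
            continue
        tab = _consensus_counts(gene, backbone, test_samples)
        if tab.n_partners < min_partners:
            continue
        rows.append((gene, tab))
    if not rows:
        logger.warning("call_degs: no testable genes")
        return []
    pvals = np.array([fisher_exact_two_sided(tab) for _, tab in rows])
    fdrs = bh_fdr(pvals)
    records: list[DEGRecord] = []
    for (gene, tab), p, q in zip(rows, pvals.tolist(), fdrs.tolist()):
        if q < fdr_threshold:
            direction = "up" if tab.n_greater_test > tab.n_greater_ref else "down"
        else:
            direction = "none"
        records.append(
            DEGRecord(
                gene, tab.n_greater_ref, tab.n_less_ref,
                tab.n_greater_test, tab.n_less_test, p, q, direction,
            )
        )
    n_sig = sum(r.direction != "none" for r in records)
    logger.info("call_degs: %d genes tested, %d below FDR %g", len(records), n_sig, fdr_threshold)
    return records


def write_degs(records: Sequence[DEGRecord], path) -> None:
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write("gene_id\tNg\tNl\tng_test\tnl_test\tp\tfdr\tdirection\n")
        for r in records:
            fh.write(
                f"{r.gene_id}\t{r.n_greater_ref}\t{r.n_less_ref}\t"
                f"{r.n_greater_test}\t{r.n_less_test}\t{r.p_value:.6g}\t"
                f"{r.fdr:.6g}\t{r.direction}\n"
            )
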