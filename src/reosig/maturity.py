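"""Maturity scoring of samples against a reversal signature.

A sample's maturity score is k/n: of the n signature pairs evaluable in the
sample (both genes measured), k hold the mature-condition ordering. A tied
pair is not the mature ordering, so it counts against k but stays in the
denominator. Scores of technical replicates are averaged (unweighted) into
a final group score.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .io import ExpressionMatrix, FormatError
from .pairs import ReversalSignature

__all__ = [
    "MaturityScore",
    "ReplicateGroupScore",
    "score_sample",
    "score_matrix",
    "write_scores",
    "write_group_scores",
    "read_replicate_groups",
]


@dataclass(frozen=True)
class MaturityScore:
    sample_id: str
    k: int
    n_evaluable: int
    n_signature: int
    score: float

    def __post_init__(self) -> None:
        if not (0 <= self.k <= self.n_evaluable <= self.n_signature):
            raise ValueError("need 0 <= k <= n_evaluable <= n_signature")


@dataclass(frozen=True)
class ReplicateGroupScore:
    group_id: str
    member_scores: tuple[MaturityScore, ...]
    final_score: float


def _score_arrays(
    gene_ids: np.ndarray, values: np.ndarray, sig: ReversalSignature, sample_id: str
) -> MaturityScore:
    idx_a = np.searchsorted(gene_ids, sig.gene_a)
    idx_b = np.searchsorted(gene_ids, sig.gene_b)
    ok_a = (idx_a < gene_ids.size) & (gene_ids[np.minimum(idx_a, gene_ids.size - 1)] == sig.gene_a)
    ok_b = (idx_b < gene_ids.size) & (gene_ids[np.minimum(idx_b, gene_ids.size - 1)] == sig.gene_b)
    evaluable = ok_a & ok_b
    n_eval = int(evaluable.sum())
    if n_eval == 0:
        raise ValueError(
            f"signature not evaluable on sample {sample_id!r}: "
            "no signature pair has both genes measured"
        )
    va = values[idx_a[evaluable]]
    vb = values[idx_b[evaluable]]
    observed = np.sign(va - vb)  # 0 on ties: matches neither direction
    k = int(np.count_nonzero(observed == sig.direction[evaluable]))
    return MaturityScore(sample_id, k, n_eval, sig.n, k / n_eval)


def score_sample(sample_values: Mapping[int, float], sig: ReversalSignature) -> MaturityScore:
    """Score one gene->value map against the signature's mature orderings."""
    if sig.n == 0:
        raise ValueError("cannot score against an empty signature")
    genes = np.asarray(sorted(sample_values), dtype=np.int64)
    vals = np.asarray([sample_values[g] for g in genes.tolist()], dtype=float)
    return _score_arrays(genes, vals, sig, sample_id="<sample>")


def score_matrix(
    matrix: ExpressionMatrix,
    sig: ReversalSignature,
    replicate_groups: Mapping[str, str] | None = None,
) -> tuple[list[MaturityScore], list[ReplicateGroupScore]]:
    """Score every sample; average technical replicates into group scores.

    ``replicate_groups`` maps sample_id -> group_id for a subset of samples.
    Output follows input sample order; groups follow first-member order.
    """
    if sig.n == 0:
        raise ValueError("cannot score against an empty signature")
    if replicate_groups:
        unknown = set(replicate_groups) - set(matrix.sample_ids)
        if unknown:
            raise ValueError(f"replicate group references unknown samples {sorted(unknown)}")
    scores = [
        _score_arrays(matrix.gene_ids, matrix.values[:, j], sig, sid)
        for j, sid in enumerate(matrix.sample_ids)
    ]
    groups: list[ReplicateGroupScore] = []
    if replicate_groups:
        by_group: dict[str, list[MaturityScore]] = {}
        order: list[str] = []
        for s in scores:
            gid = replicate_groups.get(s.sample_id)
            if gid is None:
                continue
            if gid not in by_group:
                by_group[gid] = []
                order.append(gid)
            by_group[gid].append(s)
        for gid in order:
            members = tuple(by_group[gid])
            final = float(np.mean([m.score for m in members]))
            groups.append(ReplicateGroupScore(gid, members, final))
    return scores, groups


def write_scores(scores: Sequence[MaturityScore], path) -> None:
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write("sample_id\tk\tn_evaluable\tn_signature\tscore\n")
        for s in scores:
            fh.write(f"{s.sample_id}\t{s.k}\t{s.n_evaluable}\t{s.n_signature}\t{s.score:.6g}\n")


def write_group_scores(groups: Sequence[ReplicateGroupScore], path) -> None:
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write("group_id\tmembers\tfinal_score\n")
        for g in groups:
            members = ",".join(m.sample_id for m in g.member_scores)
            fh.write(f"{g.group_id}\t{members}\t{g.final_score:.6g}\n")


def read_replicate_groups(path) -> dict[str, str]:
    """Read a ``sample_id<TAB>group_id`` table."""
    groups: dict[str, str] = {}
    with open(path, "rt", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("sample_id\t"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise FormatError(f"{path}:{lineno}: expected sample_id<TAB>group_id")
            if parts[0] in groups:
                raise FormatError(f"{path}:{lineno}: sample {parts[0]!r} listed twice")
            groups[parts[0]] = parts[1]
    return groups
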