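"""Synthetic two-condition expression data with known REO structure.

The generator plants a pair of condition templates on an arbitrary log-like
scale: the mature template assigns each gene a distinct base value; the
immature template is identical except that the two members of each planted
reversal pair swap values. Planted pairs occupy disjoint, value-adjacent
gene pairs, so a swap changes only the pair's own ordering — no incidental
template reversals can arise. Samples are template + i.i.d. Gaussian noise,
optionally followed by a random strictly increasing piecewise-linear map
per sample (a batch effect that provably preserves every within-sample
ordering). Mixture samples interpolate the two templates, emulating
partially matured cells. An optional set of planted differentially
expressed genes receives large log-scale shifts in the test replicates.

Because the downstream method only reads within-sample orderings, the
absolute scale of the templates is irrelevant; what matters is the ratio
of the planted between-gene margin to the noise standard deviation.

All randomness flows from one integer seed; per-purpose substreams are
derived with numpy's SeedSequence, so equal seeds give bit-identical data.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass

import numpy as np

from .io import ExpressionMatrix
from .pairs import GT, LT

__all__ = [
    "SyntheticConfig",
    "SyntheticTruth",
    "make_truth",
    "sample_condition",
    "sample_mixture",
    "sample_test_replicates",
    "write_truth_json",
]

MATURE = "mature"
IMMATURE = "immature"

_NOISE_STREAM = 11
_BATCH_STREAM = 13
_MIX_STREAM = 17
_TEST_STREAM = 19


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for the generator.

    ``spacing`` is the gap between value-adjacent genes on the template's
    log-like scale; it is also the planted reversal margin, which must
    exceed 4 * noise_sd for planted pairs to be recoverable. ``deg_log2_fold``
    is the log2 shift applied to planted DEG genes in test replicates; when
    DEG genes are requested it must clear the whole template range so a
    shifted gene passes all of its former partners by construction.
    """

    n_genes: int = 200
    n_samples_per_condition: int = 30
    n_reversal_pairs: int = 20
    noise_sd: float = 0.2
    spacing: float = 1.0
    batch_distortion: bool = False
    mixture_alphas: tuple[float, ...] = tuple(round(0.1 * i, 1) for i in range(11))
    n_deg_genes: int = 0
    deg_log2_fold: float = math.log2(20.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 2 or self.n_samples_per_condition < 1:
            raise ValueError("counts must be positive (and >= 2 genes)")
        if not (0 <= self.n_reversal_pairs <= self.n_genes // 2):
            raise ValueError("n_reversal_pairs must be <= floor(n_genes / 2)")
        if self.noise_sd < 0 or self.spacing <= 0:
            raise ValueError("noise_sd must be >= 0 and spacing > 0")
        if any(not (0.0 <= a <= 1.0) for a in self.mixture_alphas):
            raise ValueError("mixture alphas must lie in [0, 1]")
        if self.n_deg_genes < 0 or self.n_deg_genes + 2 * self.n_reversal_pairs > self.n_genes:
            raise ValueError("DEG genes must be disjoint from reversal-pair genes")


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground truth: templates, planted reversal pairs and planted DEG shifts.

    Templates are aligned with ``gene_ids`` (ascending). ``pair_gene_a/b``
    are canonical (gene_a < gene_b) and ``pair_direction`` is the
    mature-condition ordering. ``deg_shifts`` maps gene -> signed log2 shift
    applied in test replicates.
    """

    config: SyntheticConfig
    gene_ids: np.ndarray
    mature_template: np.ndarray
    immature_template: np.ndarray
    pair_gene_a: np.ndarray
    pair_gene_b: np.ndarray
    pair_direction: np.ndarray
    deg_shifts: dict[int, float]

    def template(self, condition: str) -> np.ndarray:
        if condition == MATURE:
            return self.mature_template
        if condition == IMMATURE:
            return self.immature_template
        raise ValueError(f"unknown condition {condition!r}")

    def planted_pairs(self) -> set[tuple[int, int, int]]:
        return set(
            zip(
                self.pair_gene_a.tolist(),
                self.pair_gene_b.tolist(),
                self.pair_direction.tolist(),
            )
        )


def make_truth(config: SyntheticConfig) -> SyntheticTruth:
    """Build templates with planted reversal pairs and optional DEG genes."""
    if (
        config.n_reversal_pairs > 0
        and config.noise_sd > 0
        and config.spacing <= 4.0 * config.noise_sd
    ):
        raise ValueError(
            f"planted margin (spacing={config.spacing}) must exceed "
            f"4 * noise_sd = {4 * config.noise_sd}; raise spacing or lower noise_sd"
        )
    rng = np.random.default_rng([config.seed, 2])
    n = config.n_genes
    # pseudo-Entrez IDs: unique, positive, ascending
    gene_ids = np.sort(rng.choice(np.arange(1001, 1001 + 20 * n), size=n, replace=False))
    # random assignment of value ranks to genes, base values on a log-like scale
    rank_of_gene = rng.permutation(n)
    base = 6.0 + config.spacing * np.arange(n)
    mature = base[rank_of_gene].astype(float)

    # planted pairs: disjoint value-adjacent rank slots (2s, 2s+1)
    slots = np.sort(rng.choice(n // 2, size=config.n_reversal_pairs, replace=False))
    gene_at_rank = np.argsort(rank_of_gene)
    immature = mature.copy()
    pa, pb, pd = [], [], []
    paired_gene_idx: set[int] = set()
    for s in slots.tolist():
        lo_idx = int(gene_at_rank[2 * s])      # lower template value
        hi_idx = int(gene_at_rank[2 * s + 1])  # higher template value
        immature[lo_idx], immature[hi_idx] = mature[hi_idx], mature[lo_idx]
        paired_gene_idx.update((lo_idx, hi_idx))
        ga, gb = int(gene_ids[lo_idx]), int(gene_ids[hi_idx])
        if ga < gb:
            pa.append(ga)
            pb.append(gb)
            pd.append(LT)  # gene_a (lower value) < gene_b in the mature condition
        else:
            pa.append(gb)
            pb.append(ga)
            pd.append(GT)

    deg_shifts: dict[int, float] = {}
    if config.n_deg_genes:
        span = config.spacing * (n - 1)
        if config.deg_log2_fold <= span:
            raise ValueError(
                f"deg_log2_fold={config.deg_log2_fold:g} does not clear the template "
                f"range {span:g}; shrink spacing or raise the fold"
            )
        free = np.array(sorted(set(range(n)) - paired_gene_idx))
        chosen = rng.choice(free, size=config.n_deg_genes, replace=False)
        for j, idx in enumerate(np.sort(chosen).tolist()):
            sign = 1.0 if j % 2 == 0 else -1.0
            deg_shifts[int(gene_ids[idx])] = sign * config.deg_log2_fold

    order = np.argsort(_pair_keys(np.asarray(pa), np.asarray(pb))) if pa else np.empty(0, int)
    return SyntheticTruth(
        config=config,
        gene_ids=gene_ids.astype(np.int64),
        mature_template=mature,
        immature_template=immature,
        pair_gene_a=np.asarray(pa, dtype=np.int64)[order],
        pair_gene_b=np.asarray(pb, dtype=np.int64)[order],
        pair_direction=np.asarray(pd, dtype=np.int8)[order],
        deg_shifts=deg_shifts,
    )


def _pair_keys(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    return (a.astype(np.int64) << np.int64(31)) | b.astype(np.int64)


def _monotone_map(values: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Apply a random strictly increasing piecewise-linear map to one sample."""
    lo = float(values.min()) - 1.0
    hi = float(values.max()) + 1.0
    knots_x = np.linspace(lo, hi, 9)
    increments = rng.uniform(0.25, 4.0, size=8) * (knots_x[1] - knots_x[0])
    knots_y = rng.uniform(-5.0, 5.0) + np.concatenate([[0.0], np.cumsum(increments)])
    return np.interp(values, knots_x, knots_y)


def _finalize(
    template: np.ndarray,
    truth: SyntheticTruth,
    n_samples: int,
    noise_sd: float,
    batch_distortion: bool,
    seed: int,
    prefix: str,
    noise_stream: int,
    condition_label: str | None,
) -> ExpressionMatrix:
    noise_rng = np.random.default_rng([seed, noise_stream])
    values = template[:, None] + noise_rng.normal(0.0, noise_sd, size=(template.size, n_samples))
    if batch_distortion:
        batch_rng = np.random.default_rng([seed, _BATCH_STREAM])
        for j in range(n_samples):
            values[:, j] = _monotone_map(values[:, j], batch_rng)
    sample_ids = tuple(f"{prefix}_{j + 1}" for j in range(n_samples))
    return ExpressionMatrix(truth.gene_ids, sample_ids, values, condition_label)


def sample_condition(
    truth: SyntheticTruth,
    condition: str,
    n_samples: int | None = None,
    noise_sd: float | None = None,
    batch_distortion: bool | None = None,
    seed: int | None = None,
) -> ExpressionMatrix:
    """Draw samples from one condition's template.

    Noise and batch distortion use separate substreams of the seed, so
    toggling the distortion does not change the noise draw — the distorted
    and undistorted matrices realize identical within-sample orderings.
    """
    cfg = truth.config
    n_samples = cfg.n_samples_per_condition if n_samples is None else n_samples
    noise_sd = cfg.noise_sd if noise_sd is None else noise_sd
    batch = cfg.batch_distortion if batch_distortion is None else batch_distortion
    seed = cfg.seed if seed is None else seed
    stream = _NOISE_STREAM if condition == MATURE else _NOISE_STREAM + 1
    return _finalize(
        truth.template(condition), truth, n_samples, noise_sd, batch,
        seed, condition, stream, condition,
    )


def sample_mixture(
    truth: SyntheticTruth,
    alpha: float,
    n_samples: int,
    noise_sd: float | None = None,
    seed: int | None = None,
    batch_distortion: bool = False,
) -> ExpressionMatrix:
    """Samples from the convex template combination (1-alpha)*immature + alpha*mature."""
    if not (0.0 <= alpha <= 1.0):
        raise ValueError("alpha must lie in [0, 1]")
    cfg = truth.config
    noise_sd = cfg.noise_sd if noise_sd is None else noise_sd
    seed = cfg.seed if seed is None else seed
    template = (1.0 - alpha) * truth.immature_template + alpha * truth.mature_template
    return _finalize(
        template, truth, n_samples, noise_sd, batch_distortion,
        seed, f"mix{alpha:g}", _MIX_STREAM, f"mixture(alpha={alpha:g})",
    )


def sample_test_replicates(
    truth: SyntheticTruth,
    n_replicates: int = 3,
    noise_sd: float | None = None,
    seed: int | None = None,
) -> ExpressionMatrix:
    """Mature-template replicates with the planted DEG shifts applied.

    Because the configured fold clears the whole template range, every
    up-shifted gene exceeds, and every down-shifted gene undershoots, all
    of its former ordering partners in expectation (exactly at zero noise).
    """
    cfg = truth.config
    noise_sd = cfg.noise_sd if noise_sd is None else noise_sd
    seed = cfg.seed if seed is None else seed
    template = truth.mature_template.copy()
    if truth.deg_shifts:
        gene_pos = {int(g): i for i, g in enumerate(truth.gene_ids.tolist())}
        for gene, shift in truth.deg_shifts.items():
            template[gene_pos[gene]] += shift
    return _finalize(
        template, truth, n_replicates, noise_sd, False,
        seed, "test", _TEST_STREAM, "test",
    )


def write_truth_json(truth: SyntheticTruth, path) -> None:
    payload = {
        "config": asdict(truth.config),
        "gene_ids": truth.gene_ids.tolist(),
        "mature_template": truth.mature_template.tolist(),
        "immature_template": truth.immature_template.tolist(),
        "planted_reversal_pairs": [
            {"gene_a": int(a), "gene_b": int(b), "mature_direction": "gt" if d == GT else "lt"}
            for a, b, d in zip(
                truth.pair_gene_a.tolist(),
                truth.pair_gene_b.tolist(),
                truth.pair_direction.tolist(),
            )
        ],
        "planted_deg_shifts": {str(g): s for g, s in truth.deg_shifts.items()},
    }
    with open(path, "wt", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=1)
        fh.write("\n")
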