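# Methods

## Model

`reosig` treats a gene pair (Gᵢ, Gⱼ) within one sample as a two-outcome
event: Gᵢ > Gⱼ or Gᵢ < Gⱼ. The package's objects and operations follow
from three definitions:

- **Highly stable pair** — a pair whose strict ordering is identical in at
  least ⌈f·m⌉ of the m accumulated samples of one condition. The default
  stability fraction f = 1.0 is the strict "all samples" rule; f < 1 is an
  explicit relaxation for noisy cohorts (valid range (0.5, 1], so a
  direction is always a majority). A tied sample supports neither outcome,
  so at f = 1.0 a single within-sample tie disqualifies the pair — the
  conservative deterministic reading; ties are rare in continuous
  expression data.
- **Reversal signature** — pairs stable in both conditions with opposite
  directions, stored with the mature-condition direction. Its size n is
  the signature length.
- **Maturity score** — for a sample, k/n over the signature pairs
  evaluable in it (both genes measured): k counts pairs realizing the
  mature ordering. Ties and missing-gene pairs never count toward k; ties
  remain in the denominator (a tie is not the mature ordering, and
  removing it would inflate the score), while pairs with an unmeasured
  gene are excluded from the denominator (cross-platform use should not be
  penalized for genes never measured). Both n_evaluable and the full
  signature size are reported. Technical replicates are combined by the
  unweighted arithmetic mean of their scores.

Because every quantity is a function of within-sample orderings only, all
results are exactly invariant under any strictly increasing transform
applied per sample — the model of a batch effect or normalization change.
This invariance is asserted bit-for-bit in the tests.

### CellComp differential expression

For small-replicate designs (1–3 technical replicates) variance-based
tests cannot be estimated. CellComp instead asks whether a gene's
*ordering neighbourhood* was disrupted. From the reference condition's
stable pairs, each gene g gets a backbone: the partners it stably exceeds
(count Ng) and the partners stably exceeding it (Nl). In the test
replicates each partner is re-classified by unanimous consensus — counted
as "below" ("above") only if every replicate orders it strictly below
(above) g; tied or discordant partners are dropped, shrinking the table
margins rather than being imputed. The test statistic is Fisher's exact
test (two-sided, minimum-likelihood rule) on

    [[Ng_ref, Nl_ref],
     [ng_test, nl_test]]

with both rows restricted to the consensus partners, so the two rows
describe the same partner set before and after. Under no change the rows
are identical and p = 1; a large monotone shift moves mass between the
columns of the test row. Benjamini–Hochberg step-up adjustment is applied
across genes; direction is *up* when the gene exceeds a larger share of
its consensus partners in the test than in the reference, *down* when
smaller, and assigned only below the FDR threshold (default 0.05).

Design choices here that were genuinely open:

- **Table orientation.** The rows are (reference, test) over the partner
  classification, not a partner-by-partner matched table. A matched table
  degenerates (zero column margin, p = 1) exactly in the case of interest —
  a gene shifted past *all* of its partners — so it cannot detect full
  disruptions; the row layout used here is the one under which the
  procedure has power, and it matches the published RankComp/CellComp
  family.
- **One-pass testing.** No iterative re-estimation of the backbone after
  excluding called DEGs; the single Fisher-test pass is the procedure
  implemented.
- **Minimum partner count.** Genes with fewer than `min_partners`
  (default 5) consensus partners are skipped: Fisher's test on smaller
  margins cannot reach conventional significance and only dilutes the FDR
  correction. The threshold is configurable.

### Enrichment

Over-representation of a gene list L in a set S within universe U is the
upper-tail hypergeometric probability P(X ≥ |L∩S|) with parameters
(|U|, |S|, |L|), after restricting both list and sets to U. Zero-overlap
sets get p = 1 by convention. BH FDR is applied across the sets of a
collection; results are emitted in set-name order so collection iteration
order is irrelevant. Sets are flat GMT entries; no ontology-graph
propagation or parent–child redundancy elimination is attempted, keeping
results independent of any annotation release.

## Input handling

Probe-level matrices are collapsed to Entrez genes by the standard
microarray rules: probes mapping to zero or to multiple genes are deleted;
several probes mapping uniquely to one gene are averaged (arithmetic mean,
per sample). Gene IDs are integers internally (canonical sort order for
pair representation; validated < 2³¹ so a pair packs into one int64 key).
Missing values are rejected at parse time. When pooling several datasets
into one condition, the gene universe is the intersection of the
contributing universes — the stability definition requires every pair to
be evaluable in every accumulated sample. No normalization of any kind is
applied, for the invariance reason above.

## Algorithmics and numerics

- Pair discovery runs in gene-row blocks (default 512 rows) against all
  genes, accumulating per-pair greater/less counts in int16; peak memory
  is O(block_size × n_genes) regardless of the output size, and stable
  pairs are kept as compact (int64, int64, int8) column arrays. A
  20,000-gene universe (~2×10⁸ unordered pairs) fits in a few GB at worst;
  5,000 genes × 50 samples completes in seconds on one CPU. Pairs are
  always emitted sorted by (gene_a, gene_b), so outputs and files are
  byte-reproducible.
- Fisher's exact two-sided p sums the hypergeometric probabilities of all
  tables with the observed margins no more probable than the observed one
  (relative slack 1e-7 for ties); degenerate tables with an empty margin
  give p = 1. The implementation is checked against an exhaustive
  integer-arithmetic enumeration oracle for every table with N ≤ 60
  (agreement ≤ 1e-9).
- BH adjustment is the textbook step-up: adjᵢ = min over ranks j ≥ rank(i)
  of p₍ⱼ₎·m/j, capped at 1, returned in input order.

## Synthetic data

The generator emulates the study design the method targets: two cell
states measured across noisy, batch-distorted cohorts.

- **Templates.** Each gene receives a distinct base value on an arbitrary
  log-like scale, uniformly spaced by `spacing` (default 1.0). The
  immature template equals the mature one except that the two members of
  each planted reversal pair swap values. Planted pairs occupy disjoint
  *value-adjacent* gene pairs: swapping adjacent values changes only the
  pair's own ordering, so the planted set is provably the complete set of
  template reversals (asserted by brute force in the tests). Since only
  orderings matter downstream, the scale is arbitrary; the meaningful
  quantity is the margin-to-noise ratio `spacing / noise_sd`.
- **Noise.** i.i.d. Gaussian, default sd 0.2 (margin = 5 sd): a planted
  pair then survives 30+30 strict-ordering checks with high probability,
  while being far from deterministic. Construction rejects
  `spacing ≤ 4·noise_sd` as an infeasible margin.
- **Batch distortion.** A random strictly increasing piecewise-linear map
  (9 knots, slopes uniform in [0.25, 4]) applied per sample after noise.
  It is exactly order-preserving, and it is drawn from a substream
  independent of the noise substream, so toggling it changes every raw
  value but no ordering — the invariance tests exploit this.
- **Mixtures.** Per-gene convex combination (1−α)·immature + α·mature
  before noise; α = 0/1 reduce exactly to the pure conditions. Noiseless
  endpoint samples score exactly 0 and 1; under default noise the mean
  score rises monotonically with α (Spearman ≥ 0.95 over a 0–1 grid).
- **Planted DEGs.** A disjoint set of genes receives signed log2 shifts
  (default log₂20 ≈ 4.32, alternating up/down) in the test replicates.
  DEG simulations use a compressed template (`spacing = 4/(n−1)`, so the
  whole range spans 4 log2 units — a plausible dynamic-range window —
  and noise `spacing/5`): the fold then clears the entire range, so every
  shifted gene passes all of its former partners by construction, which
  makes the planted truth unambiguous for sensitivity/FDR accounting.
  `make_truth` rejects configurations whose fold does not clear the range.
- **Determinism.** One integer seed; per-purpose substreams are derived
  through numpy `SeedSequence` spawn keys (PCG64), so equal seeds give
  bit-identical matrices across runs and platforms.

What the generator does *not* emulate: realistic cardiomyocyte expression
distributions, probe-level effects, correlated gene modules, or
missing-value patterns. Passing tests therefore demonstrate the
correctness and invariances of the algorithms under the planted model,
not biological performance on real cohorts — on real data the signature
size and score dynamics depend entirely on the accumulated cohorts used.

## Problem sizes used in the checks

The bundled verification uses 200-gene universes with 20–30 samples per
condition for recovery/scoring properties (20 seeds), 50 null and 20
planted-shift CellComp simulations, the complete Fisher table sweep to
N = 60, and one 5,000 × 50 stable-pair scan — sizes at which the
brute-force oracles remain exact and the full suite runs in about a
minute. The noisy signature-recovery check runs at `stability_fraction`
0.95: at noise = margin/4 the per-sample flip probability is
Φ(−4/√2) ≈ 0.0023, so the strict all-samples rule retains a planted pair
in only ≈ 0.9977⁶⁰ ≈ 0.87 of cases, whereas allowing one discordant
sample per condition lifts expected recall to ≈ 0.996 with spurious pairs
still requiring ≥ 29 coordinated flips (probability ≈ 0) — precisely the
use case the relaxed threshold exists for. The noiseless check runs at
the strict f = 1.0.

## Known limitations

- Stable-pair discovery is exact and exhaustive; there is no sampling
  shortcut for very large universes beyond the blocked accumulator.
- CellComp's Fisher test treats the consensus partner classification as
  fixed margins; partner correlations (a gene's partners are themselves
  ordered) are ignored, as in the published procedure — the null
  simulations show the test is conservative under this approximation.
- The maturity score is undefined (raises) when no signature pair is
  evaluable in a sample; it does not fall back to a partial universe.
- GEO series-matrix support covers the common text dialect (one table,
  quoted IDs); exotic multi-table files are out of scope.
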