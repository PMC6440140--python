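import numpy as np
import pytest

from oracles import backbone_oracle, bh_oracle, fisher_two_sided_oracle

from reosig.cellcomp import (
    Contingency2x2,
    bh_fdr,
    build_backbone,
    call_degs,
    fisher_exact_two_sided,
    gene_contingency,
    write_degs,
)
from reosig.io import ExpressionMatrix
from reosig.pairs import GT, LT, StablePairSet, find_stable_pairs


def stable(pairs, n_samples=2):
    return StablePairSet(
        np.array([p[0] for p in pairs], dtype=np.int64),
        np.array([p[1] for p in pairs], dtype=np.int64),
        np.array([p[2] for p in pairs], dtype=np.int8),
        condition_label="ref", n_samples=n_samples,
    )


def replicate_matrix(gene_values: dict[int, list[float]]) -> ExpressionMatrix:
    genes = sorted(gene_values)
    vals = np.array([gene_values[g] for g in genes], dtype=float)
    reps = tuple(f"rep{j}" for j in range(vals.shape[1]))
    return ExpressionMatrix(np.asarray(genes), reps, vals)


class TestBackbone:
    def test_partner_index_example(self):
        bb = build_backbone(stable([(1, 2, GT), (1, 3, GT)]))  # gene1 > gene2, gene1 > gene3
        below, above = bb.partners(1)
        assert below.tolist() == [2, 3] and above.size == 0
        below2, above2 = bb.partners(2)
        assert below2.size == 0 and above2.tolist() == [1]

    def test_empty_backbone(self):
        bb = build_backbone(stable([]))
        assert bb.genes == []

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_direct_scan(self, seed):
        rng = np.random.default_rng(seed)
        gene_ids = np.sort(rng.choice(np.arange(1, 100), size=15, replace=False))
        em = ExpressionMatrix(gene_ids, ("a", "b", "c"), rng.normal(size=(15, 3)))
        sp = find_stable_pairs(em)
        bb = build_backbone(sp)
        o_below, o_above = backbone_oracle(sp.as_set())
        for g in bb.genes:
            below, above = bb.partners(g)
            assert set(below.tolist()) == o_below.get(g, set())
            assert set(above.tolist()) == o_above.get(g, set())
            assert not (set(below.tolist()) & set(above.tolist()))


class TestGeneContingency:
    BACKBONE = None

    @classmethod
    def setup_class(cls):
        # gene 10 exceeds 5 and 6, is exceeded by 20 and 21
        cls.BACKBONE = build_backbone(
            stable([(5, 10, LT), (6, 10, LT), (10, 20, LT), (10, 21, LT)])
        )

    def test_preserved_orderings(self):
        test = replicate_matrix({5: [1, 1], 6: [2, 2], 10: [5, 5], 20: [8, 8], 21: [9, 9]})
        tab = gene_contingency(10, self.BACKBONE, test)
        assert (tab.n_greater_ref, tab.n_less_ref) == (2, 2)
        assert (tab.n_greater_test, tab.n_less_test) == (2, 2)

    def test_full_reversal_of_below_partners(self):
        bb = build_backbone(stable([(5, 10, LT), (6, 10, LT)]))  # Ng=2, Nl=0
        test = replicate_matrix({5: [9, 9], 6: [8, 8], 10: [1, 1]})
        tab = gene_contingency(10, bb, test)
        assert (tab.n_greater_ref, tab.n_less_ref) == (2, 0)
        assert (tab.n_greater_test, tab.n_less_test) == (0, 2)

    def test_disagreeing_replicates_shrink_margins(self):
        test = replicate_matrix({5: [1, 9], 6: [2, 2], 10: [5, 5], 20: [8, 8], 21: [9, 9]})
        tab = gene_contingency(10, self.BACKBONE, test)  # gene 5 inconsistent
        assert tab.n_partners == 3
        assert (tab.n_greater_ref, tab.n_less_ref) == (1, 2)

    def test_tied_partner_excluded(self):
        test = replicate_matrix({5: [5, 5], 6: [2, 2], 10: [5, 5], 20: [8, 8], 21: [9, 9]})
        assert gene_contingency(10, self.BACKBONE, test).n_partners == 3

    def test_missing_partner_dropped(self):
        test = replicate_matrix({6: [2, 2], 10: [5, 5], 20: [8, 8]})
        assert gene_contingency(10, self.BACKBONE, test).n_partners == 2

    def test_absent_gene_raises(self):
        test = replicate_matrix({5: [1, 1]})
        with pytest.raises(ValueError, match="10"):
            gene_contingency(10, self.BACKBONE, test)

    def test_more_than_three_replicates_rejected(self):
        test = replicate_matrix({5: [1] * 4, 10: [5] * 4})
        with pytest.raises(ValueError, match="1-3"):
            gene_contingency(10, self.BACKBONE, test)


class TestFisher:
    @pytest.mark.parametrize(
        "table,expected",
        [
            ([[5, 0], [0, 5]], 2 / 252),
            ([[3, 1], [1, 3]], 34 / 70),
            ([[1, 1], [1, 1]], 1.0),
        ],
    )
    def test_worked_values(self, table, expected):
        assert fisher_exact_two_sided(np.array(table)) == pytest.approx(expected, rel=1e-9)

    @pytest.mark.parametrize("table", [[[0, 0], [0, 0]], [[3, 2], [0, 0]], [[3, 0], [2, 0]]])
    def test_degenerate_margins_give_one(self, table):
        assert fisher_exact_two_sided(np.array(table)) == 1.0

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        table = rng.integers(0, 15, size=(2, 2))
        assert fisher_exact_two_sided(table) == pytest.approx(
            fisher_two_sided_oracle(table), abs=1e-9
        )

    def test_contingency_object_accepted(self):
        assert fisher_exact_two_sided(Contingency2x2(5, 0, 0, 5)) == pytest.approx(2 / 252)

    def test_negative_entry_rejected(self):
        with pytest.raises(ValueError):
            fisher_exact_two_sided(np.array([[1, -1], [0, 2]]))


class TestBH:
    @pytest.mark.parametrize(
        "p,expected",
        [
            ([0.01, 0.04], [0.02, 0.04]),
            ([0.5], [0.5]),
            ([0.03, 0.01, 0.02], [0.03, 0.03, 0.03]),
        ],
    )
    def test_worked_examples(self, p, expected):
        assert bh_fdr(p) == pytest.approx(expected)

    def test_matches_stepup_oracle_and_permutation_invariance(self):
        rng = np.random.default_rng(7)
        p = rng.uniform(size=200)
        adjusted = bh_fdr(p)
        assert adjusted == pytest.approx(bh_oracle(p.tolist()))
        assert np.all(adjusted <= 1.0)
        perm = rng.permutation(200)
        assert bh_fdr(p[perm]) == pytest.approx(adjusted[perm])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.5])


class TestCallDegs:
    @staticmethod
    def noiseless_reference(n_genes=120, n_samples=20):
        gene_ids = np.arange(101, 101 + n_genes)
        template = np.arange(n_genes, dtype=float)
        values = np.tile(template[:, None], (1, n_samples))
        return ExpressionMatrix(
            gene_ids, tuple(f"ref{j}" for j in range(n_samples)), values, "reference"
        )

    def test_planted_shifts_called_with_direction(self):
        ref = self.noiseless_reference()
        backbone = build_backbone(find_stable_pairs(ref))
        up_genes = [121, 135, 150, 164, 178]     # mid-range: both partner sides populated
        down_genes = [130, 144, 158, 172, 186]
        values = ref.values[:, :3].copy()
        for g in up_genes:
            values[g - 101, :] = 1e4
        for g in down_genes:
            values[g - 101, :] = -1e4
        test = ExpressionMatrix(ref.gene_ids, ("t1", "t2", "t3"), values)
        records = call_degs(backbone, test)
        called = {r.gene_id: r.direction for r in records if r.direction != "none"}
        assert all(called.get(g) == "up" for g in up_genes)
        assert all(called.get(g) == "down" for g in down_genes)
        assert set(called) == set(up_genes + down_genes)

    def test_unshifted_replicates_yield_no_calls(self):
        ref = self.noiseless_reference()
        backbone = build_backbone(find_stable_pairs(ref))
        test = ExpressionMatrix(ref.gene_ids, ("t1", "t2"), ref.values[:, :2].copy())
        records = call_degs(backbone, test)
        assert records and all(r.direction == "none" for r in records)

    def test_single_replicate_runs(self):
        ref = self.noiseless_reference(n_genes=30)
        backbone = build_backbone(find_stable_pairs(ref))
        values = ref.values[:, :1].copy()
        values[15, 0] = 1e4
        test = ExpressionMatrix(ref.gene_ids, ("t1",), values)
        called = [r for r in call_degs(backbone, test) if r.direction != "none"]
        assert [r.gene_id for r in called] == [116]

    def test_min_partner_threshold_skips_sparse_genes(self):
        bb = build_backbone(stable([(5, 10, LT), (6, 10, LT)]))
        test = replicate_matrix({5: [9], 6: [8], 10: [1]})
        assert call_degs(bb, test, min_partners=5) == []
        assert len(call_degs(bb, test, min_partners=1)) > 0

    def test_records_sorted_and_tsv_written(self, tmp_path):
        ref = self.noiseless_reference(n_genes=30)
        backbone = build_backbone(find_stable_pairs(ref))
        test = ExpressionMatrix(ref.gene_ids, ("t1",), ref.values[:, :1].copy())
        records = call_degs(backbone, test)
        genes = [r.gene_id for r in records]
        assert genes == sorted(genes)
        write_degs(records, tmp_path / "degs.tsv")
        lines = (tmp_path / "degs.tsv").read_text().splitlines()
        assert lines[0].startswith("gene_id\tNg\tNl")
        assert len(lines) == len(records) + 1
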