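"""Association scan: filters, LD pruning, Fisher exact, FDR, summaries."""

import math
import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import supergene as sg
from supergene.io import MISSING

from conftest import genotype_table_from_matrix


# ---------------------------------------------------------------------------
# Independent oracle: exhaustive hypergeometric enumeration for the
# two-sided Fisher exact test (sum of tables with point prob ≤ observed).


def fisher_oracle(table):
    (a, b), (c, d) = table
    row1, col1, n = a + b, a + c, a + b + c + d
    lo, hi = max(0, row1 + col1 - n), min(row1, col1)

    def point(x):
        return (
            math.comb(col1, x)
            * math.comb(n - col1, row1 - x)
            / math.comb(n, row1)
        )

    p_obs = point(a)
    return sum(point(x) for x in range(lo, hi + 1) if point(x) <= p_obs * (1 + 1e-9))


class TestDominantFisher:
    def test_perfect_separation_matches_enumeration(self):
        # 7 S-morph carriers vs 12 L-morph non-carriers: the observed table is
        # the unique most extreme one, p = 1/C(19,7) by enumeration.
        d = np.array([1] * 7 + [0] * 12)
        m = np.array(["S"] * 7 + ["L"] * 12)
        table, p = sg.dominant_fisher_test(d, m)
        assert table.tolist() == [[7, 0], [0, 12]]
        assert p == pytest.approx(fisher_oracle(table))
        assert p == pytest.approx(1 / math.comb(19, 7))

    def test_degenerate_margin_gives_p_one(self):
        # all 19 samples carriers → degenerate margin, p = 1
        d = np.array([1] * 19)
        m = np.array(["S"] * 7 + ["L"] * 12)
        _, p = sg.dominant_fisher_test(d, m)
        assert p == 1.0

    def test_3113_table_matches_enumeration(self):
        d = np.array([1, 1, 1, 0, 1, 0, 0, 0])
        m = np.array(["S", "S", "S", "S", "L", "L", "L", "L"])
        table, p = sg.dominant_fisher_test(d, m)
        assert table.tolist() == [[3, 1], [1, 3]]
        assert p == pytest.approx(fisher_oracle([[3, 1], [1, 3]]))

    def test_minor_allele_recoding(self):
        # alt is the major allele → carriers are those with ≥1 ref copy
        d = np.array([2, 2, 2, 2, 1, 1, 1, 1])
        m = np.array(["S"] * 4 + ["L"] * 4)
        table, _ = sg.dominant_fisher_test(d, m)
        assert table.tolist() == [[0, 4], [4, 0]]

    def test_single_morph_rejected(self):
        with pytest.raises(ValueError):
            sg.dominant_fisher_test(np.array([0, 1]), np.array(["S", "S"]))

    def test_missing_dosages_rejected(self):
        with pytest.raises(ValueError):
            sg.dominant_fisher_test(np.array([0, MISSING]), np.array(["S", "L"]))

    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(
        st.tuples(
            st.integers(0, 8), st.integers(0, 8), st.integers(0, 8), st.integers(0, 8)
        ).filter(lambda t: 0 < t[0] + t[2] and 0 < t[1] + t[3] and sum(t) <= 30)
    )
    def test_matches_enumeration_for_random_tables(self, cells):
        a, b, c, d = cells
        dos = np.array([1] * (a + b) + [0] * (c + d))
        morphs = np.array(["S"] * a + ["L"] * b + ["S"] * c + ["L"] * d)
        table, p = sg.dominant_fisher_test(dos, morphs)
        assert p == pytest.approx(fisher_oracle(table.tolist()), rel=1e-9)


class TestFilters:
    def test_missing_and_rare_sites_removed(self):
        # 11 samples: site0 has one missing call; site1 has MAF 1/22 < 0.05;
        # site2 is clean and common
        dosages = np.zeros((11, 3), dtype=np.int8)
        dosages[0, 0] = MISSING
        dosages[3, 1] = 1  # single alt allele → MAF ≈ 0.045
        dosages[:5, 2] = 1
        gt = genotype_table_from_matrix(dosages, [10, 20, 30])
        out = sg.filter_for_association(gt)
        assert out.variants["pos"].tolist() == [30]

    def test_maf_boundary(self):
        # 10 samples, 20 alleles: one alt allele → MAF 0.05 exactly: kept
        d = np.zeros((10, 1), dtype=np.int8)
        d[0, 0] = 1
        out = sg.filter_for_association(genotype_table_from_matrix(d, [10]))
        assert out.n_variants == 1
        # monomorphic → removed
        out2 = sg.filter_for_association(
            genotype_table_from_matrix(np.zeros((10, 1), dtype=np.int8), [10])
        )
        assert out2.n_variants == 0

    def test_all_removed_warns_not_raises(self):
        d = np.zeros((4, 2), dtype=np.int8)
        with pytest.warns(UserWarning):
            out = sg.filter_for_association(genotype_table_from_matrix(d, [1, 2]))
        assert out.n_variants == 0


class TestLdPrune:
    def test_duplicate_columns_one_survives(self):
        col = np.array([0, 0, 1, 1, 2, 2], dtype=np.int8)
        gt = genotype_table_from_matrix(np.column_stack([col, col]), [1000, 2000])
        out = sg.ld_prune(gt)
        assert out.n_variants == 1

    def test_distant_duplicates_both_survive(self):
        col = np.array([0, 0, 1, 1, 2, 2], dtype=np.int8)
        gt = genotype_table_from_matrix(np.column_stack([col, col]), [1000, 61000])
        out = sg.ld_prune(gt)
        assert out.n_variants == 2

    def test_independent_snps_survive_and_invariant_holds(self):
        rng = np.random.default_rng(0)
        d = rng.binomial(2, 0.4, size=(60, 3)).astype(np.int8)
        gt = genotype_table_from_matrix(d, [1000, 2000, 3000])
        out = sg.ld_prune(gt)
        # verify directly that no surviving close pair exceeds the threshold
        for i, j in itertools.combinations(range(out.n_variants), 2):
            r2 = sg.dosage_r2(out.dosages[:, i], out.dosages[:, j])
            assert np.isnan(r2) or r2 <= 0.2
        assert out.n_variants == 3

    def test_output_guarantee_on_block_correlated_data(self, small_population):
        _, gt, _ = small_population
        out = sg.ld_prune(sg.filter_for_association(gt))
        pos = out.variants["pos"].to_numpy()
        contigs = out.variants["contig"].to_numpy()
        for i, j in itertools.combinations(range(out.n_variants), 2):
            if contigs[i] != contigs[j] or abs(pos[i] - pos[j]) >= 50_000:
                continue
            r2 = sg.dosage_r2(out.dosages[:, i], out.dosages[:, j])
            assert np.isnan(r2) or r2 <= 0.2 + 1e-12


class TestBhFdr:
    def test_hand_computed_step_up(self):
        np.testing.assert_allclose(sg.bh_fdr([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_single_p_identity(self):
        assert sg.bh_fdr([0.04])[0] == pytest.approx(0.04)

    def test_all_ones(self):
        np.testing.assert_allclose(sg.bh_fdr([1.0, 1.0, 1.0]), 1.0)

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            sg.bh_fdr([0.5, 1.5])

    @settings(max_examples=30, derandomize=True, deadline=None)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=40))
    def test_monotone_and_order_invariant(self, ps):
        q = sg.bh_fdr(ps)
        assert (q >= np.asarray(ps) - 1e-12).all()
        order = np.argsort(ps, kind="stable")
        assert np.all(np.diff(q[order]) >= -1e-12)
        perm = np.random.default_rng(1).permutation(len(ps))
        q_perm = sg.bh_fdr(np.asarray(ps)[perm])
        np.testing.assert_allclose(q_perm, q[perm])


class TestAssociationScan:
    def test_perfect_snps_attain_minimum_p_and_are_flagged(self, small_population):
        cfg, gt, sheet = small_population
        filtered = sg.filter_for_association(gt)
        res = sg.association_scan(filtered, sheet)
        min_p = 1 / math.comb(18, 7)
        sig = res.significant
        assert len(sig) == cfg.assoc_snp_count
        assert np.allclose(sig["p_raw"], min_p)
        c, s, e = cfg.s_locus
        assert (sig["contig"] == c).all()
        assert sig["pos"].between(s, e).all()

    def test_null_scan_mean_fdp_controlled(self):
        # BH guarantee under (near) independence, checked at reduced replicates
        fdp = []
        for rep in range(40):
            cfg = sg.SupergeneSimConfig(
                n_S=9, n_L=9, n_snps=150, assoc_snp_count=0,
                ld_block_bp=1, block_copy_prob=0.0, seed=1000 + rep,
            )
            gt, sheet = sg.simulate_supergene_population(cfg)
            res = sg.association_scan(sg.filter_for_association(gt), sheet)
            n_sig = int(res.table["significant"].sum())
            fdp.append(n_sig / max(len(res.table), 1) if n_sig else 0.0)
        assert np.mean(fdp) <= 0.05

    def test_empty_input(self, small_population):
        _, gt, sheet = small_population
        empty = gt.take_variants([])
        res = sg.association_scan(empty, sheet)
        assert len(res.table) == 0


class TestContigHitSummary:
    def test_published_style_counts(self):
        out = sg.contig_hit_summary(
            {"A": 124, "B": 33, "C": 2, "D": 20},
            {"A": "chr1", "B": "chr1", "C": "chr2", "D": "chr3"},
        )
        top = out.iloc[0]
        assert top["chromosome"] == "chr1"
        assert top["pct_of_hits"] == 87.7

    def test_single_contig_all_hits(self):
        out = sg.contig_hit_summary({"A": 57}, {"A": "chr9"})
        assert out.iloc[0]["pct_of_hits"] == 100.0

    def test_even_split_and_unplaced(self):
        out = sg.contig_hit_summary({"A": 1, "B": 1}, {"A": "chr1"})
        assert set(out["chromosome"]) == {"chr1", "unplaced"}
        assert (out["pct_of_hits"] == 50.0).all()
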