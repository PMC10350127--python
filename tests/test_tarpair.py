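import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import pearsonr, rankdata

from lnctar.annotation import GeneLocus
from lnctar.diffexpr import DERecord
from lnctar.expression import ExpressionTable
from lnctar.tarpair import (
    TarPair,
    call_trans_targets,
    classify_cis_trans,
    duplex_energy,
    pair_correlations,
    refine_tarpairs,
    select_interaction_pairs,
)


def _expr(rows, ids=None):
    mat = np.asarray(rows, dtype=float)
    ids = ids or [f"g{i}" for i in range(mat.shape[0])]
    return ExpressionTable(ids, [f"s{j}" for j in range(mat.shape[1])], mat)


class TestPairCorrelations:
    def test_identical_vectors(self):
        expr = _expr([[1, 2, 3, 4], [1, 2, 3, 4]], ids=["l", "m"])
        row = pair_correlations(expr, ["l"], ["m"]).iloc[0]
        assert row.pearson == pytest.approx(1.0)
        assert row.spearman == pytest.approx(1.0)

    def test_negated_vector_perfectly_anticorrelated(self):
        expr = _expr([[1, 2, 3, 4], [-1, -2, -3, -4]], ids=["l", "m"])
        row = pair_correlations(expr, ["l"], ["m"]).iloc[0]
        assert row.pearson == pytest.approx(-1.0)

    def test_monotone_nonlinear_pair(self):
        # x vs x^2: perfect rank agreement, Pearson on raw values
        expr = _expr([[1, 2, 3, 4], [1, 4, 9, 16]], ids=["l", "m"])
        row = pair_correlations(expr, ["l"], ["m"]).iloc[0]
        assert row.spearman == pytest.approx(1.0)
        assert row.pearson == pytest.approx(0.9843740386976971)

    def test_fewer_than_three_columns_rejected(self):
        expr = _expr([[1, 2], [3, 4]], ids=["l", "m"])
        with pytest.raises(ValueError):
            pair_correlations(expr, ["l"], ["m"])

    def test_overlapping_id_lists_rejected(self):
        expr = _expr([[1, 2, 3]], ids=["g"])
        with pytest.raises(ValueError):
            pair_correlations(expr, ["g"], ["g"])

    def test_zero_variance_pairs_excluded(self):
        expr = _expr([[5, 5, 5, 5], [1, 2, 3, 4]], ids=["l", "m"])
        assert len(pair_correlations(expr, ["l"], ["m"])) == 0

    @settings(max_examples=40, deadline=None)
    @given(
        rows=st.lists(
            st.lists(st.integers(0, 9), min_size=6, max_size=6),
            min_size=2,
            max_size=2,
        )
    )
    def test_spearman_is_pearson_of_average_ranks(self, rows):
        a, b = np.array(rows, dtype=float)
        if a.std() == 0 or b.std() == 0:
            return
        expr = _expr(rows, ids=["l", "m"])
        row = pair_correlations(expr, ["l"], ["m"]).iloc[0]
        expected = pearsonr(rankdata(a), rankdata(b))[0]
        assert row.spearman == pytest.approx(expected)


class TestSelectInteractionPairs:
    def _corr(self, s, p):
        return pd.DataFrame(
            [("l", "m", s, p)], columns=["lnc_id", "mrna_id", "spearman", "pearson"]
        )

    def test_threshold_is_inclusive(self):
        assert len(select_interaction_pairs(self._corr(0.6, 0.6))) == 1

    def test_conjunction_of_both_coefficients(self):
        assert len(select_interaction_pairs(self._corr(0.9, 0.4))) == 0

    def test_absolute_mode_admits_inverse_pairs(self):
        corr = self._corr(-0.9, -0.9)
        assert len(select_interaction_pairs(corr, use_absolute=True)) == 1
        assert len(select_interaction_pairs(corr, use_absolute=False)) == 0


def _locus(gene, start, end, strand="+", chrom="chr1"):
    return GeneLocus(gene, chrom, strand, start, end)


def oracle_cis(lnc, mrna, up=10_000, down=20_000, strand_aware=True):
    """Brute force: per-base membership of the lncRNA span in the window."""
    if lnc.chrom != mrna.chrom:
        return "trans"
    if not strand_aware or mrna.strand == "+":
        window = range(mrna.start - up, mrna.end + down + 1)
    else:
        window = range(mrna.start - down, mrna.end + up + 1)
    for base in range(lnc.start, lnc.end + 1):
        if base in window:
            return "cis"
    return "trans"


class TestClassifyCisTrans:
    def test_upstream_lncrna_within_window(self):
        mrna = _locus("m", 50_000, 60_000, "+")
        lnc = _locus("l", 44_500, 45_000, "+")  # 5 kb upstream
        assert classify_cis_trans(lnc, mrna) == "cis"

    def test_upstream_boundary_exact_and_one_past(self):
        mrna = _locus("m", 50_000, 60_000, "+")
        at_edge = _locus("l", 39_500, 40_000)  # ends exactly 10 kb upstream
        past_edge = _locus("l", 39_499, 39_999)
        assert classify_cis_trans(at_edge, mrna) == "cis"
        assert classify_cis_trans(past_edge, mrna) == "trans"

    def test_downstream_boundary_on_minus_strand(self):
        # '-' strand: 20 kb downstream extends below mrna.start
        mrna = _locus("m", 50_000, 60_000, "-")
        at_edge = _locus("l", 29_500, 30_000)
        past_edge = _locus("l", 29_499, 29_999)
        assert classify_cis_trans(at_edge, mrna) == "cis"
        assert classify_cis_trans(past_edge, mrna) == "trans"

    def test_different_chromosome_is_trans(self):
        mrna = _locus("m", 100, 200, "+", chrom="chr1")
        lnc = _locus("l", 100, 200, "+", chrom="chr2")
        assert classify_cis_trans(lnc, mrna) == "trans"

    def test_overlapping_loci_are_cis(self):
        mrna = _locus("m", 50_000, 60_000)
        lnc = _locus("l", 55_000, 56_000)
        assert classify_cis_trans(lnc, mrna) == "cis"

    def test_agrees_with_bruteforce_membership(self):
        rng = np.random.default_rng(7)
        for _ in range(200):
            chrom_l = f"chr{rng.integers(1, 3)}"
            chrom_m = f"chr{rng.integers(1, 3)}"
            ms = int(rng.integers(40_000, 120_000))
            me = ms + int(rng.integers(100, 30_000))
            ls = int(rng.integers(1, 200_000))
            le = ls + int(rng.integers(50, 3_000))
            strand = "+" if rng.random() < 0.5 else "-"
            lnc = _locus("l", ls, le, "+", chrom_l)
            mrna = _locus("m", ms, me, strand, chrom_m)
            assert classify_cis_trans(lnc, mrna) == oracle_cis(lnc, mrna)

    def test_translation_invariance(self):
        rng = np.random.default_rng(11)
        for _ in range(50):
            ms = int(rng.integers(40_000, 100_000))
            me = ms + 5_000
            ls = int(rng.integers(1, 150_000))
            le = ls + 800
            shift = int(rng.integers(1, 10**6))
            before = classify_cis_trans(_locus("l", ls, le), _locus("m", ms, me, "-"))
            after = classify_cis_trans(
                _locus("l", ls + shift, le + shift),
                _locus("m", ms + shift, me + shift, "-"),
            )
            assert before == after

    def test_strandless_mode_ignores_strand(self):
        mrna_minus = _locus("m", 50_000, 60_000, "-")
        lnc = _locus("l", 75_000, 75_500)  # 15 kb past end
        assert classify_cis_trans(lnc, mrna_minus) == "trans"
        assert (
            classify_cis_trans(lnc, mrna_minus, strand_aware=False) == "cis"
        )


class TestDuplexEnergy:
    def test_perfect_gc_ten_mer(self):
        assert duplex_energy("GCGCGCGCGC", "GCGCGCGCGC") == -20.0

    def test_no_complementarity(self):
        assert duplex_energy("AAAAAA", "AAAAAA") == 0.0

    @settings(max_examples=60, deadline=None)
    @given(
        a=st.text(alphabet="ACGU", min_size=1, max_size=40),
        b=st.text(alphabet="ACGU", min_size=1, max_size=40),
    )
    def test_symmetry(self, a, b):
        assert duplex_energy(a, b) == duplex_energy(b, a)

    def test_invalid_alphabet_rejected(self):
        with pytest.raises(ValueError):
            duplex_energy("ACGX", "ACGU")
        with pytest.raises(ValueError):
            duplex_energy("", "ACGU")

    def test_matches_quadratic_reference(self):
        weights = {"AT": 1, "TA": 1, "GC": 2, "CG": 2}

        def reference(x, y):
            best = 0
            n, m = len(x), len(y)
            for s in range(n + m - 1):
                run = 0
                for i in range(max(0, s - m + 1), min(n - 1, s) + 1):
                    w = weights.get(x[i] + y[s - i], 0)
                    run = run + w if w else 0
                    best = max(best, run)
            return -float(best)

        rng = np.random.default_rng(3)
        for _ in range(60):
            x = "".join(rng.choice(list("ACGT"), rng.integers(1, 70)))
            y = "".join(rng.choice(list("ACGT"), rng.integers(1, 70)))
            assert duplex_energy(x, y) == reference(x, y)


class TestCallTransTargets:
    def _pair(self, energy, mode="trans"):
        return TarPair("l", "m", 0.9, 0.9, mode=mode, energy=energy)

    def test_boundary_inclusive(self):
        kept = call_trans_targets([self._pair(-20.0)], energy_max=-20.0)
        assert len(kept) == 1

    def test_empty_input(self):
        assert call_trans_targets([], energy_max=-20.0) == []

    def test_hand_filter_at_minus_thirty(self):
        pairs = [self._pair(-20.0), self._pair(-35.0)]
        kept = call_trans_targets(pairs, energy_max=-30.0)
        assert [p.energy for p in kept] == [-35.0]


class TestRefineTarpairs:
    def _de(self, gene, lfc):
        return DERecord(
            gene_id=gene,
            count_a=0,
            count_b=0,
            lib_a=1,
            lib_b=1,
            log2fc=lfc,
            pvalue=0.0,
            fdr=0.0,
        )

    def _run(self, lnc_lfc, mrna_lfc, fold_min=5.0):
        pairs = [TarPair("l", "m", 0.9, 0.9, mode="cis")]
        return refine_tarpairs(
            pairs,
            de_mrna=[self._de("m", mrna_lfc)],
            de_lnc=[self._de("l", lnc_lfc)],
            fold_min=fold_min,
            comparison="c",
        )

    def test_exact_fivefold_both_members_kept(self):
        kept = self._run(np.log2(5), np.log2(5))
        assert len(kept) == 1
        assert kept[0].comparison == "c"

    def test_inverse_regulation_kept(self):
        assert len(self._run(np.log2(6), -np.log2(6))) == 1

    def test_one_member_below_threshold_dropped(self):
        assert len(self._run(np.log2(6), np.log2(3))) == 0

    def test_member_missing_from_de_tables_dropped(self):
        pairs = [TarPair("l", "m", 0.9, 0.9)]
        kept = refine_tarpairs(pairs, de_mrna=[], de_lnc=[self._de("l", 3.0)])
        assert kept == []
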