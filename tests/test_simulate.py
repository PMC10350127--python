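import numpy as np
import pytest

from conftest import small_sim_config
from lnctar.annotation import write_gtf
from lnctar.ddct import ddct_relative_expression
from lnctar.lncrna import consensus_classify
from lnctar.simulate import (
    SimConfig,
    plan_truth,
    simulate_annotation,
    simulate_coding_calls,
    simulate_counts,
    simulate_ct_table,
    simulate_sequences,
)
from lnctar.tarpair import classify_cis_trans, duplex_energy


class TestSimConfigValidation:
    def test_too_many_pairs_rejected(self):
        with pytest.raises(ValueError):
            SimConfig(n_mrna=5, n_lncrna=5, n_cis_pairs=4, n_trans_pairs=3)

    def test_bad_rho_rejected(self):
        with pytest.raises(ValueError):
            SimConfig(pair_rho=0.0)

    def test_condition_names(self):
        assert SimConfig(n_conditions=3).conditions == [
            "control",
            "mutantA",
            "mutantB",
        ]


class TestSimulateAnnotation:
    def test_planted_cis_pairs_satisfy_window_predicate(self, small_cfg):
        records, loci_list, truth = simulate_annotation(small_cfg)
        loci = {l.gene_id: l for l in loci_list}
        cis = [(l, m) for l, m, mode, _ in truth.pairs if mode == "cis"]
        assert len(cis) == small_cfg.n_cis_pairs
        for lnc, mrna in cis:
            assert classify_cis_trans(loci[lnc], loci[mrna]) == "cis"

    def test_planted_trans_pairs_on_different_chromosomes(self, small_cfg):
        _records, loci_list, truth = simulate_annotation(small_cfg)
        loci = {l.gene_id: l for l in loci_list}
        for lnc, mrna, mode, _ in truth.pairs:
            if mode == "trans":
                assert loci[lnc].chrom != loci[mrna].chrom

    def test_decoy_lncrnas_are_trans_to_every_mrna(self, small_cfg):
        records, loci_list, truth = simulate_annotation(small_cfg)
        loci = {l.gene_id: l for l in loci_list}
        planted = {l for l, _, _, _ in truth.pairs}
        decoys = [g for g in truth.lnc_ids if g not in planted][:10]
        for lnc in decoys:
            for mrna in truth.mrna_ids:
                assert classify_cis_trans(loci[lnc], loci[mrna]) == "trans"

    def test_exon_count_ranges_by_biotype(self, small_cfg):
        records, _loci, _truth = simulate_annotation(small_cfg)
        for rec in records:
            if rec.biotype == "mRNA" and rec.transcript_id.endswith(".t1"):
                assert 2 <= rec.exon_count <= 15
            elif rec.biotype == "lncRNA":
                assert 1 <= rec.exon_count <= 3

    def test_trans_pairs_need_two_chromosomes(self):
        cfg = small_sim_config(n_chrom=1, n_cis_pairs=0, n_trans_pairs=2)
        with pytest.raises(ValueError, match="chromosome"):
            simulate_annotation(cfg)

    def test_infeasible_layout_suggests_larger_chromosome(self):
        cfg = small_sim_config(chrom_length=100_000)
        with pytest.raises(ValueError, match="chrom_length"):
            simulate_annotation(cfg)

    def test_same_seed_gives_byte_identical_gtf(self, tmp_path, small_cfg):
        for name in ("a.gtf", "b.gtf"):
            records, _loci, _truth = simulate_annotation(small_cfg)
            write_gtf(records, tmp_path / name)
        assert (tmp_path / "a.gtf").read_bytes() == (tmp_path / "b.gtf").read_bytes()


class TestSimulateCounts:
    def test_same_seed_identical_matrices(self, small_cfg):
        truth = plan_truth(small_cfg)
        a, _, _ = simulate_counts(small_cfg, truth)
        b, _, _ = simulate_counts(small_cfg, truth)
        assert (a.counts == b.counts).all()

    def test_column_layout_matches_design(self, small_cfg):
        truth = plan_truth(small_cfg)
        table, _, _ = simulate_counts(small_cfg, truth)
        assert table.sample_ids == small_cfg.sample_ids
        assert len(table.sample_ids) == 9

    def test_planted_folds_visible_in_condition_means(self):
        cfg = small_sim_config(dispersion=0.0, mean_expression=500.0)
        truth = plan_truth(cfg)
        table, de_truth, _ = simulate_counts(cfg, truth)
        up = de_truth[de_truth.direction > 0].gene_id.iloc[0]
        i = table.gene_ids.index(up)
        ctrl = table.counts[i, :3].mean()
        mut = table.counts[i, 3:6].mean()
        assert mut / ctrl == pytest.approx(cfg.de_fold, rel=0.35)

    def test_truth_tables_cover_plan(self, small_cfg):
        truth = plan_truth(small_cfg)
        _, de_truth, pair_truth = simulate_counts(small_cfg, truth)
        assert len(pair_truth) == small_cfg.n_cis_pairs + small_cfg.n_trans_pairs
        assert set(pair_truth.columns) == {"lnc_id", "mrna_id", "mode", "direction"}
        # pair members plus extra DE genes
        assert len(de_truth) == len(truth.de_direction)


class TestSimulateSequences:
    def test_sequences_match_spliced_lengths(self, small_cfg):
        records, _loci, truth = simulate_annotation(small_cfg)
        seqs = simulate_sequences(records, small_cfg, truth)
        for rec in records:
            assert len(seqs[rec.transcript_id]) == rec.length

    def test_coding_calls_reproduce_biotypes(self, small_cfg):
        records, _loci, truth = simulate_annotation(small_cfg)
        seqs = simulate_sequences(records, small_cfg, truth)
        calls = simulate_coding_calls(records, seqs)
        biotypes = consensus_classify(calls)
        for rec in records:
            assert biotypes[rec.transcript_id] == rec.biotype

    def test_planted_trans_pairs_pass_energy_screen(self, small_cfg):
        records, _loci, truth = simulate_annotation(small_cfg)
        seqs = simulate_sequences(records, small_cfg, truth)
        for lnc, mrna, mode, _ in truth.pairs:
            if mode == "trans":
                e = duplex_energy(seqs[f"{lnc}.t1"], seqs[f"{mrna}.t1"])
                assert e <= -25.0

    def test_decoy_pairs_rarely_pass_energy_screen(self):
        cfg = small_sim_config(seed=9, n_mrna=40, n_lncrna=40)
        records, _loci, truth = simulate_annotation(cfg)
        seqs = simulate_sequences(records, cfg, truth)
        planted = {g for l, m, _, _ in truth.pairs for g in (l, m)}
        lncs = [g for g in truth.lnc_ids if g not in planted]
        mrnas = [g for g in truth.mrna_ids if g not in planted]
        rng = np.random.default_rng(0)
        n, passing = 200, 0
        for _ in range(n):
            l = lncs[rng.integers(len(lncs))]
            m = mrnas[rng.integers(len(mrnas))]
            if duplex_energy(seqs[f"{l}.t1"], seqs[f"{m}.t1"]) <= -25.0:
                passing += 1
        assert passing / n <= 0.01

    def test_determinism(self, small_cfg):
        records, _loci, truth = simulate_annotation(small_cfg)
        assert simulate_sequences(records, small_cfg, truth) == simulate_sequences(
            records, small_cfg, truth
        )


class TestSimulateCtTable:
    def test_noise_free_roundtrip_recovers_planted_folds(self, small_cfg):
        truth = plan_truth(small_cfg)
        table, ct_truth = simulate_ct_table(small_cfg, truth, noise_sd=0.0)
        for gene in ct_truth.gene_id.unique():
            res = ddct_relative_expression(table, gene, ["HPRT", "GAPDH"])
            for _, row in res.iterrows():
                expected = ct_truth[
                    (ct_truth.gene_id == gene) & (ct_truth.condition == row.condition)
                ].rel_expr.iloc[0]
                assert row.rel_expr == pytest.approx(expected)

    def test_control_recovers_exactly_one(self, small_cfg):
        truth = plan_truth(small_cfg)
        table, ct_truth = simulate_ct_table(small_cfg, truth, noise_sd=0.0)
        gene = ct_truth.gene_id.iloc[0]
        res = ddct_relative_expression(table, gene, ["HPRT", "GAPDH"])
        assert res[res.condition == "control"].rel_expr.iloc[0] == 1.0

    def test_seed_determinism(self, small_cfg):
        truth = plan_truth(small_cfg)
        a, _ = simulate_ct_table(small_cfg, truth)
        b, _ = simulate_ct_table(small_cfg, truth)
        assert a.equals(b)
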