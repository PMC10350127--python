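"""End-to-end orchestration: simulate -> FPKM -> DE -> classify -> pairs.

``run_pipeline`` wires the stages into the pooled-library workflow: counts
are pooled per condition for the unreplicated exact test (control vs each
mutant), biotypes come from the consensus of the coding-potential calls,
and target pairs are predicted from replicate-level FPKM correlations, the
cis/trans window, the duplex-energy screen and the fold-change refinement.
Every threshold is a named field of :class:`PipelineConfig` with the
standard value as default.  Runs are deterministic given config + seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path

import pandas as pd

from . import annotation, ddct, diffexpr, expression, lncrna, simulate, tarpair

log = logging.getLogger(__name__)


def qc_summary(raw_reads: int, clean_reads: int) -> float:
    """Clean-read percentage, rounded half-up to 3 decimals."""
    if raw_reads <= 0 or clean_reads <= 0:
        raise ValueError("read counts must be positive")
    if clean_reads > raw_reads:
        raise ValueError("clean reads cannot exceed raw reads")
    pct = Decimal(100 * clean_reads) / Decimal(raw_reads)
    return float(pct.quantize(Decimal("0.001"), rounding=ROUND_HALF_UP))


@dataclass
class PipelineConfig:
    """All thresholds of the workflow, with their standard defaults."""

    sim: simulate.SimConfig = field(default_factory=simulate.SimConfig)
    screen_p: float = 0.05
    screen_lfc: float = 1.5
    fc_min: float = 2.0
    fdr_max: float = 0.001
    pseudocount: float = 1.0
    rho_min: float = 0.6
    use_absolute_corr: bool = False
    upstream_bp: int = 10_000
    downstream_bp: int = 20_000
    window_strandless: bool = False
    energy_max: float = -25.0
    fold_min: float = 5.0
    ct_noise_sd: float = 0.2


@dataclass
class PipelineResult:
    """Everything one run produces, plus the planted truth for comparison."""

    records: list
    loci: dict
    truth: simulate.SimTruth
    counts: expression.CountTable
    pooled: expression.CountTable
    fpkm: expression.ExpressionTable
    biotypes: dict[str, str]  # gene-level
    de: dict[str, list[diffexpr.DERecord]]  # comparison -> all-gene records
    de_mrna: dict[str, list[diffexpr.DERecord]]
    de_lnc: dict[str, list[diffexpr.DERecord]]
    candidate_pairs: dict[str, list[tarpair.TarPair]]
    refined_pairs: dict[str, list[tarpair.TarPair]]
    validation: pd.DataFrame
    ct_truth: pd.DataFrame
    known_novel: pd.DataFrame
    filter_log: dict[str, dict[str, int]]


def gene_biotypes(
    records: list[annotation.TranscriptRecord], tx_biotypes: dict[str, str]
) -> dict[str, str]:
    """Collapse transcript-level consensus calls to gene level.

    A gene with any coding transcript is mRNA; otherwise lncRNA if it has a
    consensus-noncoding transcript; otherwise unclassified.
    """
    out: dict[str, str] = {}
    for rec in records:
        b = tx_biotypes.get(rec.transcript_id, "unclassified")
        prev = out.get(rec.gene_id)
        if b == "mRNA" or prev == "mRNA":
            out[rec.gene_id] = "mRNA"
        elif b == "lncRNA" or prev == "lncRNA":
            out[rec.gene_id] = "lncRNA"
        else:
            out[rec.gene_id] = "unclassified"
    return out


def run_pipeline(cfg: PipelineConfig, outdir: str | None = None) -> PipelineResult:
    """Run the whole workflow on a simulated dataset."""
    sim = cfg.sim
    log.info("simulating annotation (seed=%d)", sim.seed)
    records, loci_list, truth = simulate.simulate_annotation(sim)
    loci = {l.gene_id: l for l in loci_list}
    lengths = annotation.gene_lengths(records)

    counts, truth_de, truth_pairs = simulate.simulate_counts(sim, truth)
    fpkm = expression.compute_fpkm(counts, lengths)

    sequences = simulate.simulate_sequences(records, sim, truth)
    calls = simulate.simulate_coding_calls(records, sequences)
    tx_biotypes = lncrna.consensus_classify(calls)
    biotypes = gene_biotypes(records, tx_biotypes)
    reference_ids = simulate.simulate_reference_ids(records)
    known_novel = lncrna.known_novel_partition(
        {"simulated": tx_biotypes}, reference_ids
    )

    mrna_genes = [g for g in counts.gene_ids if biotypes.get(g) == "mRNA"]
    lnc_genes = [g for g in counts.gene_ids if biotypes.get(g) == "lncRNA"]

    # Longest-transcript sequence per gene, for the trans energy screen.
    longest_tx: dict[str, str] = {}
    best_len: dict[str, int] = {}
    for rec in records:
        if rec.length > best_len.get(rec.gene_id, 0):
            best_len[rec.gene_id] = rec.length
            longest_tx[rec.gene_id] = rec.transcript_id
    gene_seq = {g: sequences[tx] for g, tx in longest_tx.items()}

    groups = {s: s.rsplit("_r", 1)[0] for s in counts.sample_ids}
    pooled = expression.pool_samples(counts, groups)
    comparisons = [
        ("control", cond) for cond in sim.conditions if cond != "control"
    ]

    de: dict[str, list[diffexpr.DERecord]] = {}
    de_mrna: dict[str, list[diffexpr.DERecord]] = {}
    de_lnc: dict[str, list[diffexpr.DERecord]] = {}
    candidate_pairs: dict[str, list[tarpair.TarPair]] = {}
    refined_pairs: dict[str, list[tarpair.TarPair]] = {}
    filter_log: dict[str, dict[str, int]] = {}
    energy_cache: dict[tuple[str, str], float] = {}

    for cond_a, cond_b in comparisons:
        label = f"{cond_a}-vs-{cond_b}"
        ja, jb = pooled.sample_ids.index(cond_a), pooled.sample_ids.index(cond_b)
        recs = diffexpr.de_test(
            pooled.counts[:, ja],
            pooled.counts[:, jb],
            int(pooled.library_sizes[ja]),
            int(pooled.library_sizes[jb]),
            pooled.gene_ids,
            pseudocount=cfg.pseudocount,
        )
        recs = diffexpr.call_de(
            recs,
            screen_p=cfg.screen_p,
            screen_lfc=cfg.screen_lfc,
            fc_min=cfg.fc_min,
            fdr_max=cfg.fdr_max,
        )
        de[label] = recs
        by_id = {r.gene_id: r for r in recs}
        de_mrna[label] = [by_id[g] for g in mrna_genes]
        de_lnc[label] = [by_id[g] for g in lnc_genes]
        dels = [r.gene_id for r in de_lnc[label] if r.call != "not_significant"]
        degs = [r.gene_id for r in de_mrna[label] if r.call != "not_significant"]

        stage = {
            "genes_tested": len(recs),
            "DEG": len(degs),
            "DEL": len(dels),
        }
        if dels and mrna_genes:
            corr = tarpair.pair_correlations(fpkm, dels, mrna_genes)
            selected = tarpair.select_interaction_pairs(
                corr, rho_min=cfg.rho_min, use_absolute=cfg.use_absolute_corr
            )
            stage["correlation_pairs"] = len(selected)
            classified: list[tarpair.TarPair] = []
            for p in selected:
                mode = tarpair.classify_cis_trans(
                    loci[p.lnc_id],
                    loci[p.mrna_id],
                    upstream_bp=cfg.upstream_bp,
                    downstream_bp=cfg.downstream_bp,
                    strand_aware=not cfg.window_strandless,
                )
                p.mode = mode
                if mode == "trans":
                    key = (p.lnc_id, p.mrna_id)
                    if key not in energy_cache:
                        energy_cache[key] = tarpair.duplex_energy(
                            gene_seq[p.lnc_id], gene_seq[p.mrna_id]
                        )
                    p.energy = energy_cache[key]
                classified.append(p)
            cis = [p for p in classified if p.mode == "cis"]
            trans = tarpair.call_trans_targets(classified, energy_max=cfg.energy_max)
            stage["cis_pairs"] = len(cis)
            stage["trans_pairs_passing_energy"] = len(trans)
            candidates = cis + trans
            candidate_pairs[label] = candidates
            refined_pairs[label] = tarpair.refine_tarpairs(
                candidates,
                de_mrna[label],
                de_lnc[label],
                fold_min=cfg.fold_min,
                comparison=label,
            )
            stage["refined_TAR_pairs"] = len(refined_pairs[label])
        else:
            candidate_pairs[label] = []
            refined_pairs[label] = []
            stage["correlation_pairs"] = 0
            stage["refined_TAR_pairs"] = 0
        filter_log[label] = stage
        log.info("%s: %s", label, stage)

    ct_table, ct_truth = simulate.simulate_ct_table(
        sim, truth, noise_sd=cfg.ct_noise_sd
    )
    targets = sorted(ct_truth["gene_id"].unique())
    validation = (
        ddct.validation_report(ct_table, targets, ["HPRT", "GAPDH"])
        if targets
        else pd.DataFrame()
    )

    result = PipelineResult(
        records=records,
        loci=loci,
        truth=truth,
        counts=counts,
        pooled=pooled,
        fpkm=fpkm,
        biotypes=biotypes,
        de=de,
        de_mrna=de_mrna,
        de_lnc=de_lnc,
        candidate_pairs=candidate_pairs,
        refined_pairs=refined_pairs,
        validation=validation,
        ct_truth=ct_truth,
        known_novel=known_novel,
        filter_log=filter_log,
    )
    if outdir is not None:
        _write_outputs(result, truth_de, truth_pairs, Path(outdir))
    return result


def _write_outputs(
    result: PipelineResult,
    truth_de: pd.DataFrame,
    truth_pairs: pd.DataFrame,
    outdir: Path,
) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    annotation.write_gtf(result.records, outdir / "annotation.gtf")
    expression.write_table_tsv(result.counts, outdir / "counts.tsv")
    expression.write_table_tsv(result.fpkm, outdir / "fpkm.tsv")
    truth_de.to_csv(outdir / "truth_de.tsv", sep="\t", index=False)
    truth_pairs.to_csv(outdir / "truth_pairs.tsv", sep="\t", index=False)
    for label, recs in result.de.items():
        diffexpr.de_frame(recs).to_csv(
            outdir / f"de_{label}.tsv", sep="\t", index=False
        )
        diffexpr.volcano_table(recs).to_csv(
            outdir / f"volcano_{label}.tsv", sep="\t", index=False
        )
    for label, pairs in result.refined_pairs.items():
        tarpair.tarpair_frame(pairs).to_csv(
            outdir / f"tarpairs_{label}.tsv", sep="\t", index=False
        )
    result.known_novel.to_csv(outdir / "known_novel.tsv", sep="\t", index=False)
    if len(result.validation):
        result.validation.to_csv(outdir / "validation.tsv", sep="\t", index=False)
    pd.DataFrame(
        [
            {"comparison": label, **stage}
            for label, stage in result.filter_log.items()
        ]
    ).to_csv(outdir / "run_log.tsv", sep="\t", index=False)
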