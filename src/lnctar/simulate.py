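"""Synthetic inputs with planted structure for the whole pipeline.

The generator emulates the pooled-triplicate, three-condition study design:
one control and two mutant conditions, three replicate cultures each.  The
differential-expression stage sees pooled single libraries per condition;
the correlation stage sees the replicate-level columns.  Planted structure:

* DE genes multiplied/divided by ``de_fold`` (default 8) in both mutant
  conditions, half up and half down;
* cis lncRNA-mRNA pairs placed so the lncRNA locus falls inside the
  10 kb-upstream/20 kb-downstream window of its partner mRNA on either
  strand;
* trans pairs on different chromosomes, with a complementary sequence
  window embedded so the duplex-energy proxy separates them from decoys;
* decoy lncRNAs placed > 50 kb from every mRNA;
* mRNA sequences carry long open reading frames and lncRNA sequences carry
  none (they are generated ATG-free), so ORF-based coding-potential calls
  reproduce the intended biotypes;
* pair members share a latent per-column factor tuned to the target
  cross-column correlation ``pair_rho``.

Counts are negative binomial around log-normal baseline means (Poisson at
``dispersion=0``, the assumption under which the exact test is calibrated).
All generators are pure functions of ``(cfg.seed, cfg)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .annotation import GeneLocus, TranscriptRecord, gene_loci
from .expression import CountTable
from .lncrna import CodingCall, baseline_coding_scorer

_LOGNORM_SIGMA = 1.0  # sd of log baseline expression across genes
_SHARED_SIGMA = 0.4  # sd of the shared latent log-factor within a pair
_NONSTOP_CODONS = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in ("TAA", "TAG", "TGA")
]
_CODING_TOOLS = {"orf_t270": 270, "orf_t300": 300, "orf_t330": 330}


@dataclass
class SimConfig:
    """Study-design parameters of the synthetic dataset."""

    seed: int = 0
    n_mrna: int = 2000
    n_lncrna: int = 1000
    n_chrom: int = 4
    chrom_length: int = 60_000_000
    n_conditions: int = 3
    replicates_per_condition: int = 3
    n_de_genes: int = 100
    de_fold: float = 8.0
    n_cis_pairs: int = 10
    n_trans_pairs: int = 10
    pair_rho: float = 0.95
    dispersion: float = 0.01
    mean_expression: float = 200.0

    def __post_init__(self) -> None:
        if self.n_cis_pairs + self.n_trans_pairs > min(self.n_mrna, self.n_lncrna):
            raise ValueError("more planted pairs than genes of one biotype")
        for name in (
            "n_mrna",
            "n_lncrna",
            "n_chrom",
            "n_conditions",
            "replicates_per_condition",
            "n_de_genes",
            "n_cis_pairs",
            "n_trans_pairs",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not (0 < self.pair_rho <= 1):
            raise ValueError("pair_rho must be in (0, 1]")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        if self.n_conditions < 2:
            raise ValueError("need >= 2 conditions (control + mutant)")

    @property
    def conditions(self) -> list[str]:
        return ["control"] + [
            f"mutant{chr(ord('A') + i)}" for i in range(self.n_conditions - 1)
        ]

    @property
    def sample_ids(self) -> list[str]:
        return [
            f"{cond}_r{r + 1}"
            for cond in self.conditions
            for r in range(self.replicates_per_condition)
        ]


@dataclass
class SimTruth:
    """Planted ground truth (first-class output, never re-derived)."""

    de_direction: dict[str, int]  # gene_id -> +1 (up in mutants) or -1
    pairs: list[tuple[str, str, str, int]]  # (lnc, mrna, mode, direction)
    mrna_ids: list[str] = field(default_factory=list)
    lnc_ids: list[str] = field(default_factory=list)

    def de_frame(self, de_fold: float) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gene_id": list(self.de_direction),
                "direction": list(self.de_direction.values()),
                "fold": [
                    de_fold if d > 0 else 1 / de_fold
                    for d in self.de_direction.values()
                ],
            }
        )

    def pair_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.pairs, columns=["lnc_id", "mrna_id", "mode", "direction"]
        )


def _rng(cfg: SimConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([cfg.seed, stream])


def plan_truth(cfg: SimConfig) -> SimTruth:
    """Deterministic role assignment: which genes are DE, which are paired.

    mRNA/lncRNA indices 0..n_cis-1 form the cis pairs, the next n_trans the
    trans pairs; the following genes carry the extra (unpaired) DE signal,
    two thirds of it on mRNAs.  Pair members are DE at ``de_fold`` with the
    pair's direction (congruent within a pair), alternating up/down.
    """
    mrna_ids = [f"MRNA_{i:05d}" for i in range(cfg.n_mrna)]
    lnc_ids = [f"LNC_{i:05d}" for i in range(cfg.n_lncrna)]
    n_pairs = cfg.n_cis_pairs + cfg.n_trans_pairs
    pairs = []
    de: dict[str, int] = {}
    for k in range(n_pairs):
        mode = "cis" if k < cfg.n_cis_pairs else "trans"
        direction = 1 if k % 2 == 0 else -1
        pairs.append((lnc_ids[k], mrna_ids[k], mode, direction))
        de[lnc_ids[k]] = direction
        de[mrna_ids[k]] = direction
    n_de_mrna = (2 * cfg.n_de_genes) // 3
    n_de_lnc = cfg.n_de_genes - n_de_mrna
    if n_pairs + n_de_mrna > cfg.n_mrna or n_pairs + n_de_lnc > cfg.n_lncrna:
        raise ValueError("n_de_genes too large for gene counts")
    for j in range(n_de_mrna):
        de[mrna_ids[n_pairs + j]] = 1 if j % 2 == 0 else -1
    for j in range(n_de_lnc):
        de[lnc_ids[n_pairs + j]] = 1 if j % 2 == 0 else -1
    return SimTruth(de_direction=de, pairs=pairs, mrna_ids=mrna_ids, lnc_ids=lnc_ids)


def _make_exons(
    rng: np.random.Generator,
    start: int,
    n_exons: int,
    exon_len_lo: int,
    exon_len_hi: int,
    intron_lo: int,
    intron_hi: int,
    min_spliced: int,
) -> tuple[tuple[int, int], ...]:
    lens = rng.integers(exon_len_lo, exon_len_hi + 1, n_exons)
    deficit = min_spliced - int(lens.sum())
    if deficit > 0:
        lens[0] += deficit
    exons = []
    pos = start
    for i, ln in enumerate(lens):
        exons.append((pos, pos + int(ln) - 1))
        pos += int(ln)
        if i < n_exons - 1:
            pos += int(rng.integers(intron_lo, intron_hi + 1))
    return tuple(exons)


def simulate_annotation(
    cfg: SimConfig,
) -> tuple[list[TranscriptRecord], list[GeneLocus], SimTruth]:
    """Place genes so planted pairs satisfy the cis/trans predicates.

    mRNAs get 2-15 exons, lncRNAs 1-3.  Planted cis lncRNAs start 0.5-5 kb
    past their partner's end, which lies inside the 10 kb/20 kb window on
    either strand; trans partners go to a different chromosome; all other
    lncRNAs live in a zone > 50 kb beyond the last mRNA of their
    chromosome.  Raises if the layout exceeds ``chrom_length``.
    """
    if cfg.n_trans_pairs > 0 and cfg.n_chrom < 2:
        raise ValueError(
            "trans pairs need >= 2 chromosomes (partners are placed on "
            "different chromosomes)"
        )
    truth = plan_truth(cfg)
    rng = _rng(cfg, 1)
    cis_partner = {m: l for l, m, mode, _ in truth.pairs if mode == "cis"}

    mrna_chrom = {g: i % cfg.n_chrom for i, g in enumerate(truth.mrna_ids)}
    lnc_chrom: dict[str, int] = {}
    for l, m, mode, _ in truth.pairs:
        lnc_chrom[l] = (
            mrna_chrom[m] if mode == "cis" else (mrna_chrom[m] + 1) % cfg.n_chrom
        )
    free_lncs = [g for g in truth.lnc_ids if g not in lnc_chrom]
    for i, g in enumerate(free_lncs):
        lnc_chrom[g] = i % cfg.n_chrom

    records: list[TranscriptRecord] = []

    def add_lnc(gene: str, chrom: str, start: int, known: bool) -> int:
        n_ex = int(rng.integers(1, 4))
        exons = _make_exons(rng, start, n_ex, 100, 300, 100, 400, 200)
        strand = "+" if rng.random() < 0.5 else "-"
        records.append(
            TranscriptRecord(
                transcript_id=f"{gene}.t1",
                gene_id=gene,
                chrom=chrom,
                strand=strand,
                start=exons[0][0],
                end=exons[-1][1],
                exons=exons,
                biotype="lncRNA",
                known=known,
            )
        )
        return exons[-1][1]

    chrom_last_end = [0] * cfg.n_chrom
    cursors = [10_000] * cfg.n_chrom
    for gene in truth.mrna_ids:
        c = mrna_chrom[gene]
        chrom = f"chr{c + 1}"
        n_ex = int(rng.integers(2, 16))
        exons = _make_exons(rng, cursors[c], n_ex, 120, 400, 200, 2000, 900)
        strand = "+" if rng.random() < 0.5 else "-"
        known = bool(rng.random() < 0.79)
        records.append(
            TranscriptRecord(
                transcript_id=f"{gene}.t1",
                gene_id=gene,
                chrom=chrom,
                strand=strand,
                start=exons[0][0],
                end=exons[-1][1],
                exons=exons,
                biotype="mRNA",
                known=known,
            )
        )
        if n_ex >= 3 and rng.random() < 0.2:  # occasional shorter isoform
            sub = exons[: n_ex - 1]
            records.append(
                TranscriptRecord(
                    transcript_id=f"{gene}.t2",
                    gene_id=gene,
                    chrom=chrom,
                    strand=strand,
                    start=sub[0][0],
                    end=sub[-1][1],
                    exons=sub,
                    biotype="mRNA",
                    known=known,
                )
            )
        gene_end = exons[-1][1]
        last_end = gene_end
        if gene in cis_partner:
            lnc_gene = cis_partner[gene]
            lnc_start = gene_end + int(rng.integers(500, 5001))
            lnc_known = bool(rng.random() < 0.85)
            last_end = add_lnc(lnc_gene, chrom, lnc_start, lnc_known)
        chrom_last_end[c] = last_end
        cursors[c] = last_end + int(rng.integers(45_000, 60_001))

    zone = [chrom_last_end[c] + 60_000 for c in range(cfg.n_chrom)]
    for gene in truth.lnc_ids:
        if gene in cis_partner.values():
            continue
        c = lnc_chrom[gene]
        known = bool(rng.random() < 0.85)
        end = add_lnc(gene, f"chr{c + 1}", zone[c], known)
        zone[c] = end + int(rng.integers(3_000, 6_001))

    overflow = [c for c in range(cfg.n_chrom) if max(cursors[c], zone[c]) > cfg.chrom_length]
    if overflow:
        raise ValueError(
            f"gene layout exceeds chrom_length on chromosomes {overflow}; "
            "increase chrom_length"
        )
    return records, gene_loci(records), truth


def simulate_counts(
    cfg: SimConfig, truth: SimTruth
) -> tuple[CountTable, pd.DataFrame, pd.DataFrame]:
    """Replicate-level counts with planted DE folds and pair correlation.

    Returns the count table plus the planted-DE and planted-pair truth
    tables.  Baseline means are log-normal around ``mean_expression``;
    replicate counts are negative binomial (Poisson when dispersion is 0);
    planted DE genes are scaled by ``de_fold`` in every mutant condition;
    pair members share a per-column latent log-factor whose share of the
    total latent variance is ``pair_rho``.
    """
    rng = _rng(cfg, 2)
    genes = truth.mrna_ids + truth.lnc_ids
    gene_index = {g: i for i, g in enumerate(genes)}
    n_genes, n_cols = len(genes), len(cfg.sample_ids)
    col_cond = [s.rsplit("_r", 1)[0] for s in cfg.sample_ids]

    mu = np.exp(
        rng.normal(np.log(cfg.mean_expression), _LOGNORM_SIGMA, size=n_genes)
    )
    # Planted pair members come from the expressed stratum: counting noise
    # at low baselines would otherwise dilute the planted correlation below
    # its nominal pair_rho.
    for lnc, mrna, _mode, _d in truth.pairs:
        for g in (lnc, mrna):
            i = gene_index[g]
            mu[i] = max(mu[i], cfg.mean_expression / 2)
    fold = np.ones((n_genes, n_cols))
    for g, direction in truth.de_direction.items():
        f = cfg.de_fold if direction > 0 else 1.0 / cfg.de_fold
        for j, cond in enumerate(col_cond):
            if cond != "control":
                fold[gene_index[g], j] = f

    # Latent pair factor: models within-condition covariation of a pair.
    # It is centered within each condition (and rescaled to keep its
    # nominal sd) so it produces cross-column correlation without
    # perturbing the pooled per-condition totals the DE stage sees.
    cond_of_col = np.array([cfg.conditions.index(c) for c in col_cond])
    n_rep = cfg.replicates_per_condition

    def _centered(sd: float) -> np.ndarray:
        z = rng.normal(0.0, sd, size=n_cols)
        if n_rep > 1:
            for k in range(len(cfg.conditions)):
                cols = cond_of_col == k
                z[cols] -= z[cols].mean()
            z *= np.sqrt(n_rep / (n_rep - 1))
        return z

    latent = np.zeros((n_genes, n_cols))
    sigma_ind = _SHARED_SIGMA * np.sqrt(max(1.0 / cfg.pair_rho - 1.0, 0.0))
    for lnc, mrna, _mode, _d in truth.pairs:
        shared = _centered(_SHARED_SIGMA)
        for g in (lnc, mrna):
            latent[gene_index[g], :] = shared + _centered(sigma_ind)

    mean = mu[:, None] * fold * np.exp(latent)
    if cfg.dispersion > 0:
        shape = 1.0 / cfg.dispersion
        mean = rng.gamma(shape, mean * cfg.dispersion)
    counts = rng.poisson(mean).astype(np.int64)
    table = CountTable(genes, list(cfg.sample_ids), counts)
    return table, truth.de_frame(cfg.de_fold), truth.pair_frame()


def _random_seq(rng: np.random.Generator, n: int, alphabet: str = "ACGT") -> str:
    return "".join(np.array(list(alphabet))[rng.integers(0, len(alphabet), n)])


def _scrub_atg(seq: str, protect: tuple[int, int] | None = None) -> str:
    """Remove every ATG by mutating its T to C (cannot create new ATGs).

    ``protect`` is a half-open index range that must not be touched; the
    embedded complementarity windows are T-free, so an ATG can never have
    its T inside a protected range.
    """
    chars = list(seq)
    i = 0
    while i <= len(chars) - 3:
        if chars[i] == "A" and chars[i + 1] == "T" and chars[i + 2] == "G":
            t_pos = i + 1
            if protect is not None and protect[0] <= t_pos < protect[1]:
                raise AssertionError("protected window unexpectedly contains T")
            chars[t_pos] = "C"
        i += 1
    return "".join(chars)


_REVCOMP = str.maketrans("ACGT", "TGCA")


def revcomp(seq: str) -> str:
    return seq.translate(_REVCOMP)[::-1]


def simulate_sequences(
    records: list[TranscriptRecord], cfg: SimConfig, truth: SimTruth
) -> dict[str, str]:
    """Spliced-length sequence per transcript with planted signals.

    mRNA transcripts carry an ORF spanning most of their length (well above
    every coding-call threshold); lncRNA sequences are ATG-free, so their
    longest ORF is 0.  Each planted trans pair shares a 20 nt embedded
    complementary window (the mRNA carries the window, the lncRNA its
    reverse complement) with >= 14 G/C pairings, i.e. a proxy duplex score
    of -34 or stronger.
    """
    rng = _rng(cfg, 3)
    trans_lnc_of_mrna = {
        m: l for l, m, mode, _ in truth.pairs if mode == "trans"
    }
    seqs: dict[str, str] = {}
    window_for_lnc: dict[str, str] = {}

    for rec in records:
        n = rec.length
        if rec.biotype == "mRNA":
            # 30 nt leader, then ATG + non-stop codons + stop, remainder 3'UTR
            utr5 = 30 if n >= 500 else 9
            orf_codons = max((n - utr5 - 40) // 3 - 2, 2)
            body = "".join(
                np.array(_NONSTOP_CODONS)[
                    rng.integers(0, len(_NONSTOP_CODONS), orf_codons)
                ]
            )
            seq = _random_seq(rng, utr5) + "ATG" + body + "TAA"
            seq = seq + _random_seq(rng, n - len(seq))
            gene = rec.gene_id
            if gene in trans_lnc_of_mrna and rec.transcript_id.endswith(".t1"):
                # window over {G,C,T}, 14 G/C: revcomp is T-free (no ATG risk)
                w = "".join(
                    rng.permutation(list("GC" * 7 + "T" * 6))
                )
                pos = n - 25
                seq = seq[:pos] + w + seq[pos + 20 :]
                window_for_lnc[trans_lnc_of_mrna[gene]] = w
            seqs[rec.transcript_id] = seq[:n]
        else:
            seq = _scrub_atg(_random_seq(rng, n))
            seqs[rec.transcript_id] = seq

    # Embed reverse complements into the trans lncRNAs, then re-scrub any
    # junction ATGs outside the protected window.
    for lnc, w in window_for_lnc.items():
        tx = f"{lnc}.t1"
        seq = seqs[tx]
        wrc = revcomp(w)
        pos = max((len(seq) - 20) // 2, 0)
        seq = seq[:pos] + wrc + seq[pos + 20 :]
        seqs[tx] = _scrub_atg(seq, protect=(pos, pos + 20))
    return seqs


def simulate_coding_calls(
    records: list[TranscriptRecord], sequences: dict[str, str]
) -> list[CodingCall]:
    """Three ORF-threshold pseudo-tools scoring every transcript."""
    calls = []
    for rec in records:
        for tool, thr in _CODING_TOOLS.items():
            calls.append(
                baseline_coding_scorer(
                    rec, sequences[rec.transcript_id], tool=tool, min_orf_nt=thr
                )
            )
    return calls


def simulate_ct_table(
    cfg: SimConfig,
    truth: SimTruth,
    noise_sd: float = 0.2,
    n_targets: int = 6,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Ct table for ddCt validation plus its expression ground truth.

    Targets are members of the first planted pairs (falling back to the
    first planted DE genes).  Ct = base - log2(relative expression) +
    Gaussian noise; housekeeping genes (HPRT, GAPDH) are constant across
    conditions up to noise.
    """
    rng = _rng(cfg, 4)
    targets: list[str] = []
    for lnc, mrna, _mode, _d in truth.pairs:
        for g in (lnc, mrna):
            if len(targets) < n_targets:
                targets.append(g)
    if not targets:
        targets = list(truth.de_direction)[:n_targets]

    base_ct = {"HPRT": 24.0, "GAPDH": 18.0}
    rows, truth_rows = [], []
    for gene in targets + list(base_ct):
        is_ref = gene in base_ct
        base = base_ct.get(gene, 26.0)
        for cond in cfg.conditions:
            if is_ref or cond == "control":
                rel = 1.0
            else:
                d = truth.de_direction.get(gene, 0)
                rel = cfg.de_fold**d if d else 1.0
            if not is_ref:
                truth_rows.append(
                    {"gene_id": gene, "condition": cond, "rel_expr": rel}
                )
            for rep in range(1, cfg.replicates_per_condition + 1):
                noise = rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0
                rows.append(
                    {
                        "sample_id": f"{cond}_r{rep}",
                        "condition": cond,
                        "gene_id": gene,
                        "replicate": rep,
                        "ct": base - np.log2(rel) + noise,
                    }
                )
    return (
        pd.DataFrame(rows, columns=["sample_id", "condition", "gene_id", "replicate", "ct"]),
        pd.DataFrame(truth_rows, columns=["gene_id", "condition", "rel_expr"]),
    )


def simulate_reference_ids(records: list[TranscriptRecord]) -> set[str]:
    """Reference (known) transcript-id list, standing in for a database."""
    return {r.transcript_id for r in records if r.known}


def write_fasta(sequences: dict[str, str], path) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")


def read_fasta(path) -> dict[str, str]:
    seqs: dict[str, str] = {}
    name = None
    chunks: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line.startswith(">"):
                if name is not None:
                    seqs[name] = "".join(chunks)
                name = line[1:].split()[0]
                chunks = []
            elif line:
                chunks.append(line)
    if name is not None:
        seqs[name] = "".join(chunks)
    return seqs
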