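"""Transcript annotation model and GTF input/output.

Coordinates are 1-based and inclusive at every external boundary, following
the GTF convention.  A :class:`TranscriptRecord` is the unit the rest of the
pipeline reasons about: spliced (exonic) length feeds FPKM, gene loci feed the
cis/trans window classification, and biotypes partition the transcriptome
into mRNA and lncRNA populations.
"""

from __future__ import annotations

import logging
import re
from collections import defaultdict
from dataclasses import dataclass, field, replace

import pandas as pd

log = logging.getLogger(__name__)

BIOTYPES = ("mRNA", "lncRNA", "unclassified")


class GtfParseError(ValueError):
    """A GTF line could not be parsed; the message names the line number."""


@dataclass(frozen=True)
class TranscriptRecord:
    """One annotated transcript with its exon structure.

    ``exons`` is a sorted tuple of non-overlapping 1-based inclusive
    ``(start, end)`` pairs; ``start``/``end`` are the genomic span (min/max
    over exons).  ``length`` is spliced length, i.e. the sum of exon lengths.
    """

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int
    exons: tuple[tuple[int, int], ...]
    biotype: str = "unclassified"
    known: bool = False

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.biotype not in BIOTYPES:
            raise ValueError(f"unknown biotype {self.biotype!r}")
        if not self.exons:
            raise ValueError(f"{self.transcript_id}: transcript needs >= 1 exon")
        prev_end = None
        for s, e in self.exons:
            if s > e:
                raise ValueError(f"{self.transcript_id}: exon start {s} > end {e}")
            if not (self.start <= s and e <= self.end):
                raise ValueError(
                    f"{self.transcript_id}: exon ({s},{e}) outside span "
                    f"({self.start},{self.end})"
                )
            if prev_end is not None and s <= prev_end:
                raise ValueError(
                    f"{self.transcript_id}: exons overlap or are unsorted"
                )
            prev_end = e
        if self.start > self.end:
            raise ValueError(f"{self.transcript_id}: start > end")

    @property
    def length(self) -> int:
        """Spliced length in bp (sum of exon lengths)."""
        return sum(e - s + 1 for s, e in self.exons)

    @property
    def exon_count(self) -> int:
        return len(self.exons)


@dataclass(frozen=True)
class GeneLocus:
    """Genomic span of a gene: min/max over its transcripts, one strand."""

    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"{self.gene_id}: start > end")
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.gene_id}: strand must be '+' or '-'")


# Attribute strings come in two dialects:  `key "value"; key2 "v2";`
# (Ensembl/StringTie) and `key=value;key2=v2` (GFF-ish).
_ATTR_QUOTED = re.compile(r'(\w+)\s+"([^"]*)"')
_ATTR_EQ = re.compile(r"(\w+)\s*=\s*\"?([^;\"]+)\"?")


def _parse_attributes(text: str) -> dict[str, str]:
    attrs = dict(_ATTR_QUOTED.findall(text))
    if not attrs:
        attrs = {k: v.strip() for k, v in _ATTR_EQ.findall(text)}
    return attrs


def _merge_exons(exons: list[tuple[int, int]]) -> tuple[tuple[int, int], ...]:
    """Sort exons and merge any that touch or overlap."""
    merged: list[list[int]] = []
    for s, e in sorted(exons):
        if merged and s <= merged[-1][1] + 1:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return tuple((s, e) for s, e in merged)


def read_gtf(path) -> list[TranscriptRecord]:
    """Parse a GTF file into one :class:`TranscriptRecord` per transcript.

    Only ``exon`` features are required; ``gene``/``transcript`` feature
    lines are accepted and cross-checked (a span contradicting the
    exon-derived span logs a warning, and the exon-derived span wins).
    Transcripts with no exon features are excluded with a warning.
    """
    exons_by_tx: dict[str, list[tuple[int, int]]] = defaultdict(list)
    meta: dict[str, dict] = {}
    declared_spans: dict[str, tuple[int, int]] = {}
    seen_tx_without_exons: dict[str, str] = {}

    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise GtfParseError(
                    f"{path}: line {lineno}: expected 9 tab-separated fields, "
                    f"got {len(fields)}"
                )
            chrom, _source, feature, start_s, end_s, _score, strand, _frame, attr_s = fields
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise GtfParseError(
                    f"{path}: line {lineno}: non-integer coordinates"
                ) from exc
            attrs = _parse_attributes(attr_s)
            tx_id = attrs.get("transcript_id")
            if feature == "exon":
                if tx_id is None or "gene_id" not in attrs:
                    raise GtfParseError(
                        f"{path}: line {lineno}: exon lacks gene_id/transcript_id"
                    )
                exons_by_tx[tx_id].append((start, end))
                meta.setdefault(
                    tx_id,
                    {
                        "gene_id": attrs["gene_id"],
                        "chrom": chrom,
                        "strand": strand,
                        "biotype": attrs.get("biotype", "unclassified"),
                        "known": attrs.get("known", "false").lower() == "true",
                    },
                )
            elif feature == "transcript" and tx_id is not None:
                declared_spans[tx_id] = (start, end)
                seen_tx_without_exons.setdefault(tx_id, f"line {lineno}")

    for tx_id, where in seen_tx_without_exons.items():
        if tx_id not in exons_by_tx:
            log.warning(
                "transcript %s (%s) has no exon features; excluded", tx_id, where
            )

    records = []
    for tx_id, exons in exons_by_tx.items():
        merged = _merge_exons(exons)
        start, end = merged[0][0], merged[-1][1]
        if tx_id in declared_spans and declared_spans[tx_id] != (start, end):
            log.warning(
                "transcript %s: declared span %s contradicts exon-derived span "
                "(%d, %d); using exon-derived span",
                tx_id,
                declared_spans[tx_id],
                start,
                end,
            )
        m = meta[tx_id]
        records.append(
            TranscriptRecord(
                transcript_id=tx_id,
                gene_id=m["gene_id"],
                chrom=m["chrom"],
                strand=m["strand"],
                start=start,
                end=end,
                exons=merged,
                biotype=m["biotype"] if m["biotype"] in BIOTYPES else "unclassified",
                known=m["known"],
            )
        )
    return records


def write_gtf(records: list[TranscriptRecord], path) -> None:
    """Write records as exon-only GTF (round-trips through :func:`read_gtf`)."""
    with open(path, "w") as fh:
        for rec in records:
            for s, e in rec.exons:
                attrs = (
                    f'gene_id "{rec.gene_id}"; transcript_id "{rec.transcript_id}"; '
                    f'biotype "{rec.biotype}"; known "{str(rec.known).lower()}";'
                )
                fh.write(
                    f"{rec.chrom}\tlnctar\texon\t{s}\t{e}\t.\t{rec.strand}\t.\t{attrs}\n"
                )


def gene_loci(records: list[TranscriptRecord]) -> list[GeneLocus]:
    """Collapse transcripts to one locus per gene (union of transcript spans).

    A gene whose transcripts sit on both strands is an error: the cis-window
    logic downstream is strand-dependent and cannot be resolved silently.
    """
    if not records:
        raise ValueError("gene_loci: empty record list")
    by_gene: dict[str, list[TranscriptRecord]] = defaultdict(list)
    for rec in records:
        by_gene[rec.gene_id].append(rec)
    mixed = [g for g, txs in by_gene.items() if len({t.strand for t in txs}) > 1]
    if mixed:
        raise ValueError(f"genes with transcripts on both strands: {sorted(mixed)}")
    loci = []
    for gene_id, txs in by_gene.items():
        loci.append(
            GeneLocus(
                gene_id=gene_id,
                chrom=txs[0].chrom,
                strand=txs[0].strand,
                start=min(t.start for t in txs),
                end=max(t.end for t in txs),
            )
        )
    return loci


def gene_lengths(records: list[TranscriptRecord]) -> dict[str, int]:
    """Gene length = spliced length of the gene's longest transcript."""
    lengths: dict[str, int] = {}
    for rec in records:
        lengths[rec.gene_id] = max(lengths.get(rec.gene_id, 0), rec.length)
    return lengths


def summarize_transcripts(
    records: list[TranscriptRecord], length_bin_bp: int = 500
) -> dict[str, pd.DataFrame]:
    """Histograms of exon counts, transcripts per gene and spliced length.

    Returns three tidy tables keyed ``exon_count``, ``transcripts_per_gene``
    and ``length`` with a ``biotype`` column each.  Length bins are
    half-open ``[k*bin, (k+1)*bin)`` labelled by their lower edge.  Bin
    counts sum to the number of input records per biotype.
    """
    exon_rows, tpg_rows, len_rows = [], [], []
    by_biotype: dict[str, list[TranscriptRecord]] = defaultdict(list)
    for rec in records:
        by_biotype[rec.biotype].append(rec)

    for biotype, recs in sorted(by_biotype.items()):
        exon_counts: dict[int, int] = defaultdict(int)
        length_bins: dict[int, int] = defaultdict(int)
        genes: dict[str, int] = defaultdict(int)
        for rec in recs:
            exon_counts[rec.exon_count] += 1
            length_bins[(rec.length // length_bin_bp) * length_bin_bp] += 1
            genes[rec.gene_id] += 1
        tpg: dict[int, int] = defaultdict(int)
        for n in genes.values():
            tpg[n] += 1
        exon_rows += [
            {"biotype": biotype, "exon_count": k, "n_transcripts": v}
            for k, v in sorted(exon_counts.items())
        ]
        tpg_rows += [
            {"biotype": biotype, "transcripts_per_gene": k, "n_genes": v}
            for k, v in sorted(tpg.items())
        ]
        len_rows += [
            {"biotype": biotype, "length_bin_start": k, "n_transcripts": v}
            for k, v in sorted(length_bins.items())
        ]
    return {
        "exon_count": pd.DataFrame(
            exon_rows, columns=["biotype", "exon_count", "n_transcripts"]
        ),
        "transcripts_per_gene": pd.DataFrame(
            tpg_rows, columns=["biotype", "transcripts_per_gene", "n_genes"]
        ),
        "length": pd.DataFrame(
            len_rows, columns=["biotype", "length_bin_start", "n_transcripts"]
        ),
    }


def with_biotypes(
    records: list[TranscriptRecord], biotypes: dict[str, str]
) -> list[TranscriptRecord]:
    """Return records with biotypes reassigned from a transcript_id map."""
    return [
        replace(rec, biotype=biotypes.get(rec.transcript_id, rec.biotype))
        for rec in records
    ]
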