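"""Consensus mRNA/lncRNA classification and known/novel partitioning.

Transcripts are classified by intersecting boolean coding-potential calls
from multiple predictors: a transcript is lncRNA only if every required tool
calls it non-coding, mRNA only if every tool calls it coding, and otherwise
unclassified (and excluded downstream).  The predictors themselves are
pluggable; a deterministic longest-ORF heuristic ships as the baseline so
fixtures never depend on external tools.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

from .annotation import TranscriptRecord

log = logging.getLogger(__name__)

_STOPS = {"TAA", "TAG", "TGA"}


@dataclass(frozen=True)
class CodingCall:
    transcript_id: str
    tool: str
    is_coding: bool


def consensus_classify(
    calls: list[CodingCall], tools_required: int | None = None
) -> dict[str, str]:
    """Intersect per-tool calls into {mRNA, lncRNA, unclassified}.

    ``tools_required`` defaults to the number of distinct tools present.
    Transcripts with fewer calls than required, or with disagreeing calls,
    are unclassified; a summary of those is logged.
    """
    tools = {c.tool for c in calls}
    if tools_required is None:
        tools_required = len(tools)
    if tools_required > len(tools):
        raise ValueError(
            f"tools_required={tools_required} but only {len(tools)} tools present"
        )
    by_tx: dict[str, list[bool]] = {}
    seen: set[tuple[str, str]] = set()
    for c in calls:
        key = (c.transcript_id, c.tool)
        if key in seen:
            raise ValueError(f"duplicate call for {key}")
        seen.add(key)
        by_tx.setdefault(c.transcript_id, []).append(c.is_coding)
    result: dict[str, str] = {}
    n_unclassified = 0
    for tx, votes in by_tx.items():
        if len(votes) < tools_required:
            result[tx] = "unclassified"
            n_unclassified += 1
        elif all(votes):
            result[tx] = "mRNA"
        elif not any(votes):
            result[tx] = "lncRNA"
        else:
            result[tx] = "unclassified"
            n_unclassified += 1
    if n_unclassified:
        log.info(
            "consensus_classify: %d of %d transcripts unclassified",
            n_unclassified,
            len(by_tx),
        )
    return result


def longest_orf(sequence: str) -> int:
    """Length in nt of the longest ATG..stop open reading frame (any frame).

    Counts the ORF from the A of ATG through the stop codon inclusive; an
    ATG without a downstream in-frame stop does not count as an ORF.
    """
    seq = sequence.upper().replace("U", "T")
    best = 0
    for frame in range(3):
        start = None
        for i in range(frame, len(seq) - 2, 3):
            codon = seq[i : i + 3]
            if start is None and codon == "ATG":
                start = i
            elif start is not None and codon in _STOPS:
                best = max(best, i + 3 - start)
                start = None
    return best


def baseline_coding_scorer(
    record: TranscriptRecord,
    sequence: str,
    tool: str = "orf300",
    min_orf_nt: int = 300,
) -> CodingCall:
    """Deterministic coding-potential heuristic: longest ORF >= threshold."""
    if len(sequence) != record.length:
        raise ValueError(
            f"{record.transcript_id}: sequence length {len(sequence)} != "
            f"spliced length {record.length}"
        )
    return CodingCall(record.transcript_id, tool, longest_orf(sequence) >= min_orf_nt)


def known_novel_partition(
    biotypes_per_sample: dict[str, dict[str, str]], reference_ids: set[str]
) -> pd.DataFrame:
    """Count known/novel lncRNA and mRNA per sample.

    ``biotypes_per_sample`` maps sample -> {transcript_id -> biotype}.  A
    transcript is "known" when its id is in the reference list (standing in
    for a database lookup).  Per biotype, known + novel equals the total.
    """
    rows = []
    for sample, biotypes in biotypes_per_sample.items():
        counts = {
            "known_lncRNA": 0,
            "novel_lncRNA": 0,
            "known_mRNA": 0,
            "novel_mRNA": 0,
        }
        for tx, biotype in biotypes.items():
            if biotype not in ("mRNA", "lncRNA"):
                continue
            prefix = "known" if tx in reference_ids else "novel"
            counts[f"{prefix}_{biotype}"] += 1
        rows.append({"sample": sample, **counts})
    return pd.DataFrame(
        rows, columns=["sample", "known_lncRNA", "novel_lncRNA", "known_mRNA", "novel_mRNA"]
    )


def read_coding_calls_tsv(path) -> list[CodingCall]:
    df = pd.read_csv(path, sep="\t")
    return [
        CodingCall(str(r.transcript_id), str(r.tool), bool(r.is_coding))
        for r in df.itertuples()
    ]


def write_coding_calls_tsv(calls: list[CodingCall], path) -> None:
    pd.DataFrame(
        {
            "transcript_id": [c.transcript_id for c in calls],
            "tool": [c.tool for c in calls],
            "is_coding": [c.is_coding for c in calls],
        }
    ).to_csv(path, sep="\t", index=False)
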