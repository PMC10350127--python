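"""Count tables, library-size bookkeeping and FPKM normalisation.

FPKM (fragments per kilobase of transcript per million mapped reads) is the
expression unit used throughout:

    fpkm[i, j] = 1e9 * counts[i, j] / (library_sizes[j] * length[i])

Library sizes default to assigned-count column sums but may be overridden
with mapped-read totals, which can exceed the assigned counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class CountTable:
    """Genes x samples matrix of non-negative integer read counts."""

    gene_ids: list[str]
    sample_ids: list[str]
    counts: np.ndarray
    library_sizes: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError(
                f"counts shape {self.counts.shape} != "
                f"({len(self.gene_ids)}, {len(self.sample_ids)})"
            )
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        if not np.issubdtype(self.counts.dtype, np.integer):
            if not np.allclose(self.counts, np.round(self.counts)):
                raise ValueError("counts must be integral")
            self.counts = self.counts.astype(np.int64)
        if self.library_sizes is None:
            self.library_sizes = self.counts.sum(axis=0).astype(np.int64)
        else:
            self.library_sizes = np.asarray(self.library_sizes, dtype=np.int64)
            if self.library_sizes.shape != (len(self.sample_ids),):
                raise ValueError("library_sizes must have one entry per sample")
        if np.any(self.library_sizes <= 0):
            raise ValueError("library sizes must be positive")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.gene_ids, columns=self.sample_ids)

    def column(self, sample_id: str) -> np.ndarray:
        return self.counts[:, self.sample_ids.index(sample_id)]


@dataclass
class ExpressionTable:
    """Genes x samples matrix of FPKM values."""

    gene_ids: list[str]
    sample_ids: list[str]
    fpkm: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.fpkm, index=self.gene_ids, columns=self.sample_ids)


def compute_fpkm(counts: CountTable, lengths: dict[str, int]) -> ExpressionTable:
    """Normalise counts to FPKM using per-gene lengths in bp.

    Every gene must have a positive length; genes with missing or
    non-positive lengths are reported together in one error.
    """
    missing = [g for g in counts.gene_ids if lengths.get(g, 0) <= 0]
    if missing:
        raise ValueError(f"genes with missing/zero length: {missing[:10]}"
                         + ("..." if len(missing) > 10 else ""))
    length_vec = np.array([lengths[g] for g in counts.gene_ids], dtype=float)
    fpkm = (
        1e9
        * counts.counts
        / (counts.library_sizes[np.newaxis, :].astype(float) * length_vec[:, np.newaxis])
    )
    return ExpressionTable(list(counts.gene_ids), list(counts.sample_ids), fpkm)


def pool_samples(counts: CountTable, groups: dict[str, str]) -> CountTable:
    """Sum replicate columns into one pooled column per condition.

    Emulates the pooled-library design: counts and library sizes are summed
    element-wise within each condition.  Pooled columns are ordered by first
    appearance of each condition in ``sample_ids``.
    """
    unassigned = [s for s in counts.sample_ids if s not in groups]
    if unassigned:
        raise ValueError(f"samples not assigned to a condition: {unassigned}")
    order: list[str] = []
    for s in counts.sample_ids:
        if groups[s] not in order:
            order.append(groups[s])
    pooled = np.zeros((len(counts.gene_ids), len(order)), dtype=np.int64)
    lib = np.zeros(len(order), dtype=np.int64)
    for j, s in enumerate(counts.sample_ids):
        k = order.index(groups[s])
        pooled[:, k] += counts.counts[:, j]
        lib[k] += counts.library_sizes[j]
    return CountTable(list(counts.gene_ids), order, pooled, lib)


def read_counts_tsv(path) -> CountTable:
    """Read a genes-as-rows TSV (first column gene id, header of sample ids)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return CountTable(list(df.index), list(df.columns), df.to_numpy())


def write_table_tsv(table, path) -> None:
    table.to_frame().to_csv(path, sep="\t", index_label="gene_id")
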