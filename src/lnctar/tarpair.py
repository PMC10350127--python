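"""lncRNA-mRNA target-pair (TAR-pair) prediction.

The chain mirrors the co-expression target-prediction recipe for pooled
RNA-seq designs:

1. **Correlation.** Spearman and Pearson coefficients between each
   differentially expressed lncRNA and each mRNA, computed across
   replicate-level expression columns; pairs with both coefficients >= 0.6
   (inclusive) become candidates.
2. **cis/trans.** A candidate is *cis* when the lncRNA locus overlaps the
   window from 10 kb upstream to 20 kb downstream of the mRNA gene
   (strand-aware by default), *trans* otherwise.  Trans candidates must also
   pass a duplex-energy filter; the default scorer is a documented
   complementarity proxy and is swappable for an adapter around a real
   hybridization tool.
3. **Refinement.** Pairs whose two members are each differentially regulated
   5-fold or more (in either direction, not necessarily the same one) in the
   same comparison are the final TAR pairs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .annotation import GeneLocus
from .diffexpr import DERecord
from .expression import ExpressionTable

log = logging.getLogger(__name__)

try:
    from numba import njit as _njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba present in supported envs
    _HAVE_NUMBA = False


@dataclass
class TarPair:
    """One lncRNA-mRNA candidate/called pair."""

    lnc_id: str
    mrna_id: str
    spearman: float
    pearson: float
    mode: str = ""  # "cis" or "trans"
    energy: float | None = None  # trans only
    lnc_log2fc: float = np.nan
    mrna_log2fc: float = np.nan
    comparison: str = ""


def _rowwise_corr(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pearson correlation of every row of ``a`` with every row of ``b``."""
    az = a - a.mean(axis=1, keepdims=True)
    bz = b - b.mean(axis=1, keepdims=True)
    asd = np.sqrt((az**2).sum(axis=1, keepdims=True))
    bsd = np.sqrt((bz**2).sum(axis=1, keepdims=True))
    with np.errstate(invalid="ignore", divide="ignore"):
        return (az @ bz.T) / (asd * bsd.T)


def pair_correlations(
    expr: ExpressionTable, lnc_ids: list[str], mrna_ids: list[str]
) -> pd.DataFrame:
    """Spearman and Pearson coefficients for every lncRNA x mRNA pair.

    Computed across all expression columns (replicate level).  Spearman uses
    average ranks for ties.  Pairs involving a zero-variance vector have no
    defined correlation and are excluded with a logged count.
    """
    if len(expr.sample_ids) < 3:
        raise ValueError("need >= 3 expression columns for correlations")
    if set(lnc_ids) & set(mrna_ids):
        raise ValueError("lncRNA and mRNA id lists must be disjoint")
    idx = {g: i for i, g in enumerate(expr.gene_ids)}
    lmat = expr.fpkm[[idx[g] for g in lnc_ids], :].astype(float)
    mmat = expr.fpkm[[idx[g] for g in mrna_ids], :].astype(float)

    pear = _rowwise_corr(lmat, mmat)
    spear = _rowwise_corr(
        rankdata(lmat, axis=1).astype(float), rankdata(mmat, axis=1).astype(float)
    )

    rows = []
    n_dropped = 0
    for i, lnc in enumerate(lnc_ids):
        for j, mrna in enumerate(mrna_ids):
            if np.isnan(pear[i, j]) or np.isnan(spear[i, j]):
                n_dropped += 1
                continue
            rows.append((lnc, mrna, float(spear[i, j]), float(pear[i, j])))
    if n_dropped:
        log.info("pair_correlations: %d pairs dropped (zero variance)", n_dropped)
    return pd.DataFrame(rows, columns=["lnc_id", "mrna_id", "spearman", "pearson"])


def select_interaction_pairs(
    correlations: pd.DataFrame, rho_min: float = 0.6, use_absolute: bool = False
) -> list[TarPair]:
    """Keep pairs with both coefficients >= rho_min (inclusive).

    ``use_absolute`` applies |.| to both coefficients first, admitting
    inversely co-regulated pairs.
    """
    s = correlations["spearman"].to_numpy()
    p = correlations["pearson"].to_numpy()
    if use_absolute:
        s, p = np.abs(s), np.abs(p)
    keep = (s >= rho_min) & (p >= rho_min)
    return [
        TarPair(r.lnc_id, r.mrna_id, float(r.spearman), float(r.pearson))
        for r, k in zip(correlations.itertuples(), keep)
        if k
    ]


def classify_cis_trans(
    lnc: GeneLocus,
    mrna: GeneLocus,
    upstream_bp: int = 10_000,
    downstream_bp: int = 20_000,
    strand_aware: bool = True,
) -> str:
    """Classify a locus pair as cis or trans by the mRNA-flanking window.

    cis iff the loci share a chromosome and the lncRNA locus overlaps (by at
    least 1 bp, boundaries inclusive) the interval stretching
    ``upstream_bp`` upstream and ``downstream_bp`` downstream of the mRNA
    gene.  With ``strand_aware`` (default), upstream/downstream follow the
    mRNA's strand: on '-' the upstream flank extends beyond ``mrna.end``
    toward larger coordinates and the downstream flank below ``mrna.start``.
    """
    if lnc.chrom != mrna.chrom:
        return "trans"
    if not strand_aware or mrna.strand == "+":
        win_start = mrna.start - upstream_bp
        win_end = mrna.end + downstream_bp
    else:
        win_start = mrna.start - downstream_bp
        win_end = mrna.end + upstream_bp
    return "cis" if (lnc.start <= win_end and lnc.end >= win_start) else "trans"


def _encode(seq: str, name: str) -> str:
    s = seq.upper().replace("U", "T")
    if not s or set(s) - set("ACGT"):
        raise ValueError(f"{name}: sequence must be non-empty over A/C/G/T/U")
    return s


def duplex_energy(lnc_seq: str, mrna_seq: str) -> float:
    """Proxy hybridization score: best antiparallel complementary run.

    Scores every maximal contiguous perfectly-complementary stretch in every
    ungapped antiparallel alignment of the two sequences at -2 per G.C pair
    and -1 per A.T(U) pair (mismatches contribute nothing and end a
    stretch), returning the minimum (strongest) stretch score, or 0 when no
    complementary window exists.  This is a screening proxy, not a
    thermodynamic model; adapters around a real duplex predictor can replace
    it wherever an energy scorer is accepted.
    """
    a = _encode(lnc_seq, "lnc_seq")
    b = _encode(mrna_seq, "mrna_seq")
    # Antiparallel ungapped alignments pair a[i] with b[j] along constant
    # i + j.  Rows of the weight matrix are staggered so those antidiagonals
    # become columns of one padded matrix; a cumulative-sum-with-reset scan
    # down the columns then yields the best run in every alignment at once.
    lut = np.zeros(256, dtype=np.int8)
    lut[ord("A")], lut[ord("C")], lut[ord("G")], lut[ord("T")] = 0, 1, 2, 3
    ai = lut[np.frombuffer(a.encode(), dtype=np.uint8)]
    bi = lut[np.frombuffer(b.encode(), dtype=np.uint8)]
    wtab = np.zeros((4, 4), dtype=np.int32)
    wtab[0, 3] = wtab[3, 0] = 1  # A.T
    wtab[1, 2] = wtab[2, 1] = 2  # C.G
    if _HAVE_NUMBA:
        return float(-_best_run_jit(ai, bi, wtab))

    weights = wtab[ai[:, None], bi[None, :]]  # (n, m)
    n, m = weights.shape
    if n > m:  # stagger along the shorter dimension
        weights = weights.T
        n, m = m, n
    padded = np.zeros((n + 1, n + m - 1), dtype=np.int32)
    for i in range(n):  # antidiagonal s = i + j -> column s, reversed rows
        padded[n - i, i : i + m] = weights[i, :]
    # Concatenate columns; the zero top row separates alignments, so every
    # complementary run is a maximal stretch between zeros of `flat` and its
    # score is a difference of cumulative sums at consecutive zeros.
    flat = padded.ravel(order="F")
    cs = np.cumsum(flat)
    zeros = np.flatnonzero(flat == 0)
    best = int(np.diff(cs[zeros]).max(initial=0))
    best = max(best, int(cs[-1] - cs[zeros[-1]]))
    return float(-best)


if _HAVE_NUMBA:

    @_njit(cache=False)
    def _best_run_jit(ai, bi, wtab):  # pragma: no cover - exercised via wrapper
        n, m = ai.size, bi.size
        best = 0
        for s in range(n + m - 1):
            i_lo = s - m + 1 if s >= m else 0
            i_hi = n - 1 if s >= n else s
            run = 0
            for i in range(i_lo, i_hi + 1):
                w = wtab[ai[i], bi[s - i]]
                if w:
                    run += w
                    if run > best:
                        best = run
                else:
                    run = 0
        return best


def call_trans_targets(
    candidates: list[TarPair], energy_max: float = -20.0
) -> list[TarPair]:
    """Keep trans candidates with energy <= energy_max (inclusive)."""
    return [
        p
        for p in candidates
        if p.mode == "trans" and p.energy is not None and p.energy <= energy_max
    ]


def refine_tarpairs(
    pairs: list[TarPair],
    de_mrna: list[DERecord],
    de_lnc: list[DERecord],
    fold_min: float = 5.0,
    comparison: str = "",
) -> list[TarPair]:
    """Keep pairs whose members are each >= fold_min-fold regulated.

    Directions need not agree: a pair with the lncRNA up and the mRNA down
    (or vice versa) passes as long as both magnitudes reach the threshold.
    Pairs with a member absent from the DE tables are dropped with a logged
    reason.
    """
    lfc_min = np.log2(fold_min)
    lnc_fc = {r.gene_id: r.log2fc for r in de_lnc}
    mrna_fc = {r.gene_id: r.log2fc for r in de_mrna}
    out = []
    for p in pairs:
        if p.lnc_id not in lnc_fc or p.mrna_id not in mrna_fc:
            log.info(
                "refine_tarpairs: dropping (%s, %s): member missing from DE tables",
                p.lnc_id,
                p.mrna_id,
            )
            continue
        lf, mf = lnc_fc[p.lnc_id], mrna_fc[p.mrna_id]
        if abs(lf) >= lfc_min and abs(mf) >= lfc_min:
            out.append(
                replace(p, lnc_log2fc=lf, mrna_log2fc=mf, comparison=comparison)
            )
    return out


def tarpair_frame(pairs: list[TarPair]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "lnc_id": [p.lnc_id for p in pairs],
            "mrna_id": [p.mrna_id for p in pairs],
            "spearman": [p.spearman for p in pairs],
            "pearson": [p.pearson for p in pairs],
            "mode": [p.mode for p in pairs],
            "energy": [p.energy for p in pairs],
            "lnc_log2fc": [p.lnc_log2fc for p in pairs],
            "mrna_log2fc": [p.mrna_log2fc for p in pairs],
            "comparison": [p.comparison for p in pairs],
        }
    )
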