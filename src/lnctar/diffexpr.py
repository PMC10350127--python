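"""Unreplicated pairwise differential expression between pooled libraries.

The test is the conditioned-Poisson exact test for two unreplicated count
libraries (Audic & Claverie): with independent Poisson counts x ~ Poi(r*n1)
and y ~ Poi(r*n2) and total t = x + y, the conditional law is

    y | t  ~  Binomial(t, q),    q = n2 / (n1 + n2),

so the null can be tested exactly without estimating the rate r.  The
two-sided p-value is the minimum-likelihood tail: the summed probability of
every outcome y' in 0..t whose conditional probability does not exceed that
of the observed y (ties included).  All pmf work is done in log space so
deeply significant genes (p ~ 1e-300) remain representable.

Significance calling applies the two-stage rule used for pooled-library
designs: a screen (p < 0.05 and |log2FC| >= 1.5) followed by a stringent
filter (fold change >= 2.00 and FDR <= 0.001, Benjamini-Hochberg).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp
from statsmodels.stats.multitest import multipletests

# Relative tolerance for "at most as probable as observed": outcomes whose
# log-pmf exceeds the observed one by less than this are counted as ties.
# Genuine non-ties on realistic totals differ by far more than 1e-8 in log.
_TIE_LOG_EPS = 1e-8

# -log10 p is capped where p underflows float64.
NEGLOG10_P_CAP = float(-np.log10(np.finfo(float).tiny))


@dataclass
class DERecord:
    """Per-gene result of one pairwise comparison (B over A)."""

    gene_id: str
    count_a: int
    count_b: int
    lib_a: int
    lib_b: int
    log2fc: float
    pvalue: float
    fdr: float = np.nan
    call: str = "not_significant"


def _binom_logpmf(k: np.ndarray, t: int, log_q: float, log_1mq: float) -> np.ndarray:
    return (
        gammaln(t + 1)
        - gammaln(k + 1)
        - gammaln(t - k + 1)
        + k * log_q
        + (t - k) * log_1mq
    )


def ac_pvalue(x: int, y: int, n1: float, n2: float) -> float:
    """Two-sided conditioned-Poisson exact p-value for counts (x, y).

    ``n1``/``n2`` are the library sizes of the two samples.  Returns 1.0 for
    the degenerate total x + y = 0.
    """
    if x < 0 or y < 0:
        raise ValueError("counts must be non-negative")
    if n1 <= 0 or n2 <= 0:
        raise ValueError("library sizes must be positive")
    t = int(x) + int(y)
    if t == 0:
        return 1.0
    q = n2 / (n1 + n2)
    log_q, log_1mq = np.log(q), np.log1p(-q)
    ks = np.arange(t + 1)
    logpmf = _binom_logpmf(ks, t, log_q, log_1mq)
    obs = logpmf[int(y)]
    included = logpmf <= obs + _TIE_LOG_EPS
    p = float(np.exp(logsumexp(logpmf[included])))
    return min(max(p, 0.0), 1.0)


def log2_fold_change(
    x: int, y: int, n1: float, n2: float, pseudocount: float = 1.0
) -> float:
    """log2 of the library-normalised fold change of y over x.

    A pseudocount (default 1) keeps the value finite for zero counts and
    makes the statistic antisymmetric under swapping (x, n1) <-> (y, n2).
    """
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    return float(np.log2(((y + pseudocount) / n2) / ((x + pseudocount) / n1)))


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (order-preserving)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def de_test(
    counts_a: np.ndarray,
    counts_b: np.ndarray,
    lib_a: int,
    lib_b: int,
    gene_ids: list[str],
    pseudocount: float = 1.0,
) -> list[DERecord]:
    """Run the exact test and fold change for every gene, then BH-adjust."""
    records = []
    for g, x, y in zip(gene_ids, counts_a, counts_b):
        records.append(
            DERecord(
                gene_id=g,
                count_a=int(x),
                count_b=int(y),
                lib_a=int(lib_a),
                lib_b=int(lib_b),
                log2fc=log2_fold_change(int(x), int(y), lib_a, lib_b, pseudocount),
                pvalue=ac_pvalue(int(x), int(y), lib_a, lib_b),
            )
        )
    fdrs = bh_fdr([r.pvalue for r in records])
    return [replace(r, fdr=float(q)) for r, q in zip(records, fdrs)]


def call_de(
    records: list[DERecord],
    screen_p: float = 0.05,
    screen_lfc: float = 1.5,
    fc_min: float = 2.0,
    fdr_max: float = 0.001,
    apply_screen: bool = True,
    apply_stringent: bool = True,
) -> list[DERecord]:
    """Assign up/down/not_significant calls with the two-stage filter.

    Screen: p < screen_p (strict) and |log2FC| >= screen_lfc (inclusive).
    Stringent: fold change >= fc_min, i.e. |log2FC| >= log2(fc_min), and
    FDR <= fdr_max (both inclusive).  Stages are conjunctive; either can be
    disabled.
    """
    out = []
    lfc_min = np.log2(fc_min)
    for r in records:
        ok = True
        if apply_screen:
            ok = ok and (r.pvalue < screen_p) and (abs(r.log2fc) >= screen_lfc)
        if apply_stringent:
            ok = ok and (abs(r.log2fc) >= lfc_min) and (r.fdr <= fdr_max)
        if ok and r.log2fc > 0:
            call = "up"
        elif ok and r.log2fc < 0:
            call = "down"
        else:
            call = "not_significant"
        out.append(replace(r, call=call))
    return out


def volcano_table(records: list[DERecord]) -> pd.DataFrame:
    """Tidy (gene_id, log2fc, -log10 p, call) table for volcano plotting.

    p-values below float64 tiny are capped at ``NEGLOG10_P_CAP``.
    """
    neglog = [
        NEGLOG10_P_CAP if r.pvalue < np.finfo(float).tiny else float(-np.log10(r.pvalue))
        for r in records
    ]
    return pd.DataFrame(
        {
            "gene_id": [r.gene_id for r in records],
            "log2fc": [r.log2fc for r in records],
            "neg_log10_p": neglog,
            "call": [r.call for r in records],
        }
    )


def de_frame(records: list[DERecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "gene_id": [r.gene_id for r in records],
            "count_a": [r.count_a for r in records],
            "count_b": [r.count_b for r in records],
            "log2fc": [r.log2fc for r in records],
            "pvalue": [r.pvalue for r in records],
            "fdr": [r.fdr for r in records],
            "call": [r.call for r in records],
        }
    )
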