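"""qPCR relative quantification by the 2^-ddCt method.

Per replicate, dCt = Ct(target) - mean Ct over the reference (housekeeping)
genes; ddCt = dCt - mean dCt of the control condition; relative expression
= 2^-ddCt.  Averaging dCt across references is the arithmetic-mean-in-Ct
(geometric-mean-in-expression) aggregation.  The per-condition headline
value is 2^-(mean ddCt) - the geometric mean of the replicate values -
which makes the control condition exactly 1 by construction.  Significance
between conditions uses a two-sided Student's t-test on the replicate
relative-expression values (Welch's variant available).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)

CT_COLUMNS = ["sample_id", "condition", "gene_id", "replicate", "ct"]


def validate_ct_table(table: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in CT_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"Ct table missing columns: {missing}")
    if (table["ct"] <= 0).any():
        raise ValueError("Ct values must be positive")
    return table


def ddct_relative_expression(
    table: pd.DataFrame,
    target: str,
    references: list[str],
    control_condition: str = "control",
) -> pd.DataFrame:
    """Per-condition relative expression of ``target`` by 2^-ddCt.

    Returns one row per condition with the per-replicate values, their
    geometric-mean summary (``rel_expr``, exactly 1 for the control), the
    arithmetic mean and SD of the replicate values, and the matching ddCt
    mean.  Requires the target and every reference in every condition.
    """
    table = validate_ct_table(table)
    if not references:
        raise ValueError("need >= 1 reference (housekeeping) gene")
    conditions = list(dict.fromkeys(table["condition"]))
    if control_condition not in conditions:
        raise ValueError(f"control condition {control_condition!r} absent")

    dct: dict[str, np.ndarray] = {}
    for cond in conditions:
        sub = table[table["condition"] == cond]
        reps = sorted(sub.loc[sub["gene_id"] == target, "replicate"].unique())
        if len(reps) == 0:
            raise ValueError(f"target {target!r} absent in condition {cond!r}")
        vals = []
        for rep in reps:
            rsub = sub[sub["replicate"] == rep]
            t_ct = rsub.loc[rsub["gene_id"] == target, "ct"]
            ref_cts = [
                rsub.loc[rsub["gene_id"] == ref, "ct"] for ref in references
            ]
            if t_ct.empty or any(r.empty for r in ref_cts):
                raise ValueError(
                    f"missing target/reference Ct for condition {cond!r}, "
                    f"replicate {rep}"
                )
            vals.append(
                float(t_ct.mean()) - float(np.mean([r.mean() for r in ref_cts]))
            )
        dct[cond] = np.array(vals)

    control_mean_dct = float(dct[control_condition].mean())
    rows = []
    for cond in conditions:
        ddct = dct[cond] - control_mean_dct
        rel = 2.0 ** (-ddct)
        rows.append(
            {
                "condition": cond,
                "gene_id": target,
                "n_replicates": len(rel),
                "rel_expr": float(2.0 ** (-ddct.mean())),
                "rel_expr_mean": float(rel.mean()),
                "rel_expr_sd": float(rel.std(ddof=1)) if len(rel) > 1 else 0.0,
                "mean_ddct": float(ddct.mean()),
                "replicate_rel_expr": rel.tolist(),
            }
        )
    return pd.DataFrame(rows)


def replicate_ttest(
    group_a, group_b, equal_var: bool = True
) -> tuple[float, float]:
    """Two-sided two-sample t-test (Student's by default, Welch optional).

    Degenerate identical zero-variance groups return (0.0, 1.0) by
    convention, with a log message.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs >= 2 values")
    if a.std() == 0 and b.std() == 0 and a.mean() == b.mean():
        log.info("replicate_ttest: identical zero-variance groups; p = 1")
        return 0.0, 1.0
    t, p = stats.ttest_ind(a, b, equal_var=equal_var)
    return float(t), float(p)


def validation_report(
    table: pd.DataFrame,
    targets: list[str],
    references: list[str],
    control_condition: str = "control",
    alpha: float = 0.05,
    equal_var: bool = True,
) -> pd.DataFrame:
    """ddCt + t-test report for a list of target genes.

    One row per (target, non-control condition): relative expression,
    SD, t statistic and p-value of condition vs control replicates, and the
    significance flag at ``alpha``.
    """
    rows = []
    for target in targets:
        res = ddct_relative_expression(table, target, references, control_condition)
        ctrl = res[res["condition"] == control_condition].iloc[0]
        for _, row in res[res["condition"] != control_condition].iterrows():
            t, p = replicate_ttest(
                row["replicate_rel_expr"],
                ctrl["replicate_rel_expr"],
                equal_var=equal_var,
            )
            rows.append(
                {
                    "gene_id": target,
                    "condition": row["condition"],
                    "rel_expr": row["rel_expr"],
                    "rel_expr_sd": row["rel_expr_sd"],
                    "t_statistic": t,
                    "pvalue": p,
                    "significant": p < alpha,
                }
            )
    return pd.DataFrame(rows)
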