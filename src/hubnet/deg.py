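"""Differential-expression ranking and the two-stage DEG selection.

Per-gene Welch two-sample t-tests on log2 values, Benjamini-Hochberg
adjustment across all tested genes, selection of the top-n genes by p-value,
and the significance filter FC > 2 (strict) AND p <= 0.05 (inclusive).
Fold change is two-sided: FC = 2^|log2FC|, so up- and down-regulated genes
are treated symmetrically.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from hubnet.expression_io import ExpressionMatrix, SampleGroups

logger = logging.getLogger(__name__)

# p-value floor for the degenerate zero-variance, unequal-means case: keeps the
# ranking well-defined without emitting an exact zero.
P_FLOOR = 1e-300

DEG_COLUMNS = ["gene_id", "log2fc", "fold_change", "p_value", "q_value", "significant"]


@dataclass
class DEGTable:
    """Per-gene DE statistics sorted ascending by (p_value, gene_id)."""

    records: pd.DataFrame
    n_top: int | None = None
    fc_cutoff: float = 2.0
    p_cutoff: float = 0.05

    def __post_init__(self) -> None:
        self.records = (
            self.records[DEG_COLUMNS]
            .sort_values(["p_value", "gene_id"], kind="mergesort")
            .reset_index(drop=True)
        )

    @property
    def n_significant(self) -> int:
        return int(self.records["significant"].sum())

    @property
    def significant_genes(self) -> list[str]:
        return self.records.loc[self.records["significant"], "gene_id"].tolist()

    def __len__(self) -> int:
        return len(self.records)

    def to_tsv(self, path) -> None:
        self.records.to_csv(path, sep="\t", index=False, float_format="%.6g")


def differential_expression(m: ExpressionMatrix, g: SampleGroups) -> DEGTable:
    """Welch t-test per gene; log2fc = mean(case) - mean(control); BH across all genes.

    Genes with zero variance in both groups get p = 1 when the means are equal
    (no evidence) and p clamped to a tiny floor when the means differ.
    """
    g.validate_against(m)
    case = m.values[g.case_samples].to_numpy(float)
    ctrl = m.values[g.control_samples].to_numpy(float)
    if case.shape[1] < 2 or ctrl.shape[1] < 2:
        raise ValueError("each group needs at least 2 samples")

    log2fc = case.mean(axis=1) - ctrl.mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        res = stats.ttest_ind(case, ctrl, axis=1, equal_var=False)
        p = np.asarray(res.pvalue, dtype=float)

    zero_var = (case.var(axis=1) == 0) & (ctrl.var(axis=1) == 0)
    degenerate_equal = zero_var & (log2fc == 0)
    degenerate_diff = zero_var & (log2fc != 0)
    if degenerate_equal.any():
        p[degenerate_equal] = 1.0
    if degenerate_diff.any():
        logger.info("%d genes with zero variance in both groups but unequal means; "
                    "p clamped to %g", int(degenerate_diff.sum()), P_FLOOR)
        p[degenerate_diff] = P_FLOOR
    p = np.clip(p, P_FLOOR, 1.0)

    q = multipletests(p, method="fdr_bh")[1]
    fold_change = np.exp2(np.abs(log2fc))
    df = pd.DataFrame({
        "gene_id": m.gene_ids,
        "log2fc": log2fc,
        "fold_change": fold_change,
        "p_value": p,
        "q_value": q,
        "significant": False,
    })
    return flag_significant(DEGTable(records=df))


def select_top(table: DEGTable, n: int = 250) -> DEGTable:
    """Keep the first min(n, size) records in (p_value, gene_id) order."""
    if n < 1:
        raise ValueError("n must be >= 1")
    kept = table.records.head(n).copy()
    return replace(table, records=kept, n_top=n)


def flag_significant(table: DEGTable, fc_cutoff: float = 2.0, p_cutoff: float = 0.05) -> DEGTable:
    """significant <=> fold_change > fc_cutoff (strict) AND p_value <= p_cutoff (inclusive)."""
    rec = table.records.copy()
    rec["significant"] = (rec["fold_change"] > fc_cutoff) & (rec["p_value"] <= p_cutoff)
    out = replace(table, records=rec, fc_cutoff=fc_cutoff, p_cutoff=p_cutoff)
    logger.info("%d of %d genes significant at FC>%g, p<=%g",
                out.n_significant, len(out), fc_cutoff, p_cutoff)
    return out
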