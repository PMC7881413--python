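"""Expression matrix I/O and between-sample comparability QC.

Expression values are kept on log2 scale throughout the pipeline.  The
comparability check mirrors the usual boxplot eyeball test on normalized
series: per-sample medians of comparable profiles line up, so the check
passes iff every per-sample median sits within a tolerance of the
cross-sample median of medians.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Fraction of missing cells above which a gene row is dropped instead of imputed.
MAX_MISSING_FRACTION = 0.20

#: If the matrix maximum exceeds this, values are assumed linear-scale and log2(x+1)-transformed.
LINEAR_SCALE_THRESHOLD = 50.0


@dataclass
class ExpressionMatrix:
    """Gene x sample matrix of log2 expression values.

    Wraps a pandas DataFrame indexed by gene id with sample ids as columns.
    """

    values: pd.DataFrame
    log2_transformed: bool = False

    def __post_init__(self) -> None:
        idx = self.values.index
        cols = self.values.columns
        dup_genes = sorted(idx[idx.duplicated()].unique().tolist())
        if dup_genes:
            raise ValueError(f"duplicate gene ids: {dup_genes}")
        dup_samples = sorted(cols[cols.duplicated()].unique().tolist())
        if dup_samples:
            raise ValueError(f"duplicate sample ids: {dup_samples}")
        if self.values.isna().any().any():
            raise ValueError("expression matrix contains missing values after imputation")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclass
class SampleGroups:
    """Two-level sample grouping (case vs control)."""

    mapping: dict[str, str]
    case_label: str = "case"
    control_label: str = "control"

    def __post_init__(self) -> None:
        labels = set(self.mapping.values())
        expected = {self.case_label, self.control_label}
        if labels != expected:
            raise ValueError(f"group labels {sorted(labels)} != expected {sorted(expected)}")
        if len(self.case_samples) < 2 or len(self.control_samples) < 2:
            raise ValueError("each group needs at least 2 samples")

    @property
    def case_samples(self) -> list[str]:
        return [s for s, g in self.mapping.items() if g == self.case_label]

    @property
    def control_samples(self) -> list[str]:
        return [s for s, g in self.mapping.items() if g == self.control_label]

    def validate_against(self, m: ExpressionMatrix) -> None:
        matrix_samples = set(m.sample_ids)
        mapped = set(self.mapping)
        missing = sorted(matrix_samples - mapped)
        if missing:
            raise ValueError(f"samples without a group label: {missing}")
        extra = sorted(mapped - matrix_samples)
        if extra:
            raise ValueError(f"group map refers to unknown samples: {extra}")


@dataclass
class ComparabilityReport:
    sample_medians: dict[str, float]
    global_median: float
    tol: float
    offending_samples: list[str] = field(default_factory=list)

    @property
    def passed(self) -> bool:
        return not self.offending_samples


def read_expression(path, log2_if_needed: bool = True) -> ExpressionMatrix:
    """Read a tab-separated expression matrix (first column gene ids, header sample ids).

    Blank / "NA" cells are imputed with the gene's row median; genes with more
    than 20% missing cells are dropped with a warning.  If ``log2_if_needed``
    and the value range looks linear-scale (max > 50), a log2(x+1) transform
    is applied.
    """
    raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str, na_values=["NA", ""], keep_default_na=True)
    idx = raw.index
    dups = sorted(idx[idx.duplicated()].unique().tolist())
    if dups:
        raise ValueError(f"duplicate gene ids in {path}: {dups}")

    numeric = raw.apply(pd.to_numeric, errors="coerce")
    # cells non-numeric but not originally missing -> hard error with location
    bad = numeric.isna() & raw.notna()
    if bad.any().any():
        gene = bad.index[bad.any(axis=1)][0]
        col = bad.columns[bad.loc[gene]][0]
        raise ValueError(f"non-numeric cell at gene {gene!r}, sample {col!r}: {raw.loc[gene, col]!r}")

    missing_frac = numeric.isna().mean(axis=1)
    dropped = numeric.index[missing_frac > MAX_MISSING_FRACTION]
    if len(dropped):
        logger.warning("dropping %d genes with >%.0f%% missing values: %s",
                       len(dropped), 100 * MAX_MISSING_FRACTION, list(dropped))
        numeric = numeric.drop(index=dropped)
    if numeric.isna().any().any():
        row_medians = numeric.median(axis=1)
        numeric = numeric.apply(lambda row: row.fillna(row_medians[row.name]), axis=1)

    log2_transformed = False
    if log2_if_needed and numeric.size and float(numeric.max().max()) > LINEAR_SCALE_THRESHOLD:
        numeric = np.log2(numeric + 1.0)
        log2_transformed = True
        logger.info("value range indicates linear scale; applied log2(x+1)")

    return ExpressionMatrix(values=numeric.astype(float), log2_transformed=log2_transformed)


def write_expression(m: ExpressionMatrix, path) -> None:
    """Write an expression matrix as TSV (full float precision round-trips)."""
    out = m.values.copy()
    out.index.name = "gene_id"
    out.to_csv(path, sep="\t", float_format="%.17g")


def read_sample_map(path, case_label: str = "case", control_label: str = "control") -> SampleGroups:
    """Read a two-column sample_id<TAB>group file."""
    df = pd.read_csv(path, sep="\t", header=None, names=["sample_id", "group"], dtype=str, comment="#")
    if df["sample_id"].str.lower().iloc[0] == "sample_id":  # tolerate a header row
        df = df.iloc[1:]
    mapping = dict(zip(df["sample_id"], df["group"]))
    return SampleGroups(mapping=mapping, case_label=case_label, control_label=control_label)


def write_sample_map(g: SampleGroups, path) -> None:
    with open(path, "w") as fh:
        for sample, group in g.mapping.items():
            fh.write(f"{sample}\t{group}\n")


def check_comparability(m: ExpressionMatrix, tol: float = 0.5) -> ComparabilityReport:
    """Check that per-sample medians agree within ``tol`` log2 units.

    Passes iff every per-sample median is within ``tol`` of the cross-sample
    median of medians; offending samples are listed in the report.
    """
    if tol <= 0:
        raise ValueError("tol must be positive")
    medians = m.values.median(axis=0)
    global_median = float(medians.median())
    offending = sorted(medians.index[(medians - global_median).abs() > tol].tolist())
    return ComparabilityReport(
        sample_medians={s: float(v) for s, v in medians.items()},
        global_median=global_median,
        tol=tol,
        offending_samples=offending,
    )
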