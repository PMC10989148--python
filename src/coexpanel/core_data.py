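"""Expression-matrix I/O, normalization and differential expression.

The working unit is FPKM. Normalization is ``log10(FPKM + 1)``. Differential
expression is a Welch t-test on log-normalized replicate values with a
pseudocount fold change; an externally computed table with the same schema
can be supplied instead.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigurationError, ParseError, StatisticsError, ValidationError

logger = logging.getLogger(__name__)

#: pseudocount added to condition means before the log2 ratio
FOLD_CHANGE_EPS = 1e-6

DEG_COLUMNS = ["gene_id", "log2_fold_change", "p_value", "mean_expression", "is_deg"]


@dataclass
class ExpressionMatrix:
    """Gene x sample FPKM matrix with a sample -> condition design.

    Parameters
    ----------
    data:
        Non-negative DataFrame, genes in rows, samples in columns.
    design:
        Mapping from sample id to condition label. Every column of ``data``
        must appear in the design.
    """

    data: pd.DataFrame
    design: Mapping[str, str]

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            dups = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate gene ids: {dups}")
        neg = self.data.lt(0)
        if neg.any().any():
            gene = self.data.index[neg.any(axis=1)][0]
            sample = self.data.columns[neg.loc[gene].values][0]
            raise ValidationError(
                f"negative expression value for gene {gene!r} in sample {sample!r}"
            )
        missing = [s for s in self.data.columns if s not in self.design]
        if missing:
            raise ValidationError(f"samples without condition labels: {missing}")
        self.design = {s: self.design[s] for s in self.data.columns}

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def conditions(self) -> list[str]:
        seen: dict[str, None] = {}
        for cond in self.design.values():
            seen.setdefault(cond, None)
        return list(seen)

    def samples_of(self, condition: str) -> list[str]:
        return [s for s, c in self.design.items() if c == condition]

    def subset(self, genes=None, samples=None) -> "ExpressionMatrix":
        data = self.data
        if genes is not None:
            data = data.loc[list(genes)]
        if samples is not None:
            data = data[list(samples)]
        return ExpressionMatrix(data, {s: self.design[s] for s in data.columns})


def read_design_table(path: str | Path) -> dict[str, str]:
    """Read a two-column (sample, condition) TSV/CSV into a design mapping."""
    df = _read_delimited(path)
    if df.shape[1] < 1:
        raise ParseError(f"design file {path} needs two columns (sample, condition)")
    return dict(zip(df.index.astype(str), df.iloc[:, 0].astype(str)))


def _read_delimited(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    try:
        return pd.read_csv(path, sep=sep, index_col=0)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise ParseError(f"could not parse {path}: {exc}") from exc


def read_expression_table(
    path: str | Path, design: Mapping[str, str]
) -> ExpressionMatrix:
    """Load a gene x sample table (first column gene id, header sample ids)."""
    df = _read_delimited(path)
    if df.columns.size == 0:
        raise ParseError(f"{path}: no sample columns found in header")
    try:
        df = df.astype(float)
    except (TypeError, ValueError) as exc:
        raise ParseError(f"{path}: non-numeric expression values: {exc}") from exc
    return ExpressionMatrix(df, dict(design))


def write_expression_table(expr: ExpressionMatrix, path: str | Path) -> None:
    expr.data.to_csv(path, sep="\t")


def log_normalize(values):
    """Elementwise ``log10(x + 1)``; shape preserving, strictly monotone.

    Accepts an ndarray or DataFrame; rejects negative values.
    """
    arr = values.values if isinstance(values, pd.DataFrame) else np.asarray(values)
    if np.any(arr < 0):
        raise ValidationError("log normalization requires non-negative values")
    if isinstance(values, pd.DataFrame):
        return np.log10(values + 1.0)
    return np.log10(arr + 1.0)


def differential_expression(
    expr: ExpressionMatrix,
    test_condition: str,
    control_condition: str,
    *,
    eps: float = FOLD_CHANGE_EPS,
    adjust: bool = False,
) -> pd.DataFrame:
    """Per-gene fold change and Welch t-test between two conditions.

    ``log2_fold_change = log2((mean_test + eps) / (mean_control + eps))`` on
    FPKM means; the p-value is a two-sided Welch t-test on the log-normalized
    replicate values. A gene is flagged ``is_deg`` when ``|log2FC| > 1`` and
    ``p < 0.05`` (strict inequalities). ``mean_expression`` is the FPKM mean
    over the test+control samples, used downstream by the low-expression
    filter.

    Set ``adjust=True`` for Benjamini–Hochberg corrected p-values (off by
    default; the DEG rule uses raw p).
    """
    for cond in (test_condition, control_condition):
        if cond not in expr.conditions:
            raise ConfigurationError(f"condition {cond!r} not present in design")
    test_samples = expr.samples_of(test_condition)
    ctrl_samples = expr.samples_of(control_condition)
    if len(test_samples) < 2 or len(ctrl_samples) < 2:
        raise StatisticsError(
            "each condition needs >= 2 replicates for the Welch t-test "
            f"(got {len(test_samples)} vs {len(ctrl_samples)})"
        )

    test_vals = expr.data[test_samples].to_numpy(float)
    ctrl_vals = expr.data[ctrl_samples].to_numpy(float)
    mean_test = test_vals.mean(axis=1)
    mean_ctrl = ctrl_vals.mean(axis=1)
    log2fc = np.log2((mean_test + eps) / (mean_ctrl + eps))

    with np.errstate(invalid="ignore", divide="ignore"):
        _, pvals = stats.ttest_ind(
            np.log10(test_vals + 1.0),
            np.log10(ctrl_vals + 1.0),
            axis=1,
            equal_var=False,
        )
    # zero within-group variance in both groups yields NaN: identical data
    pvals = np.where(np.isnan(pvals), 1.0, pvals)
    if adjust:
        pvals = _benjamini_hochberg(pvals)

    mean_expr = expr.data[test_samples + ctrl_samples].to_numpy(float).mean(axis=1)
    is_deg = (np.abs(log2fc) > 1.0) & (pvals < 0.05)
    return pd.DataFrame(
        {
            "gene_id": expr.gene_ids,
            "log2_fold_change": log2fc,
            "p_value": pvals,
            "mean_expression": mean_expr,
            "is_deg": is_deg,
        }
    )


def _benjamini_hochberg(pvals: np.ndarray) -> np.ndarray:
    n = len(pvals)
    order = np.argsort(pvals)
    ranked = pvals[order] * n / (np.arange(n) + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.clip(ranked, 0, 1)
    return out


def filter_valid_degs(
    degs: pd.DataFrame, min_mean_expression: float = 1.0
) -> pd.DataFrame:
    """Keep flagged DEGs whose mean expression is >= the cutoff.

    The rule removes low-expression DEGs with mean *below* the cutoff, so a
    gene sitting exactly at the cutoff is retained. Idempotent.
    """
    out = degs[degs["is_deg"] & (degs["mean_expression"] >= min_mean_expression)]
    logger.info(
        "valid DEGs: %d of %d flagged (cutoff %.3g FPKM)",
        len(out),
        int(degs["is_deg"].sum()),
        min_mean_expression,
    )
    if out.empty:
        logger.warning("no valid DEGs survive the low-expression filter")
    return out.reset_index(drop=True)


@dataclass
class ConditionDataset:
    """Valid DEGs of one test condition with test + control expression columns."""

    condition: str
    control: str
    expression: ExpressionMatrix
    degs: pd.DataFrame = field(repr=False)

    @property
    def gene_ids(self) -> list[str]:
        return self.expression.gene_ids


def split_condition_datasets(
    expr: ExpressionMatrix,
    valid_degs: Mapping[str, pd.DataFrame],
    control_condition: str,
) -> dict[str, ConditionDataset]:
    """One dataset per test condition: its valid DEGs, test+control columns."""
    out: dict[str, ConditionDataset] = {}
    for cond, degs in valid_degs.items():
        genes = degs["gene_id"].tolist()
        if not genes:
            logger.warning("condition %r has no valid DEGs; dataset is empty", cond)
        samples = expr.samples_of(cond) + expr.samples_of(control_condition)
        sub = expr.subset(genes=genes, samples=samples)
        out[cond] = ConditionDataset(cond, control_condition, sub, degs)
    return out


def read_deg_table(path: str | Path) -> pd.DataFrame:
    """Import an externally computed DEG table (same schema as produced here)."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in DEG_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: DEG table missing columns {missing}")
    return df[DEG_COLUMNS]


def write_deg_table(degs: pd.DataFrame, path: str | Path) -> None:
    degs.to_csv(path, sep="\t", index=False)
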