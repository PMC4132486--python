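"""Differential expression: Welch's t-test, BH-FDR, per-group gene selection.

This stage supplies the DE gene sets the network construction consumes. It is
deliberately plain — an unequal-variance two-sample t per gene with
Benjamini-Hochberg control — since downstream stages only need the selected
sets, not the test machinery itself.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .expression import ExpressionMatrix

logger = logging.getLogger(__name__)

__all__ = ["DEResult", "welch_test", "bh_fdr", "de_genes", "de_table", "common_de"]


@dataclass
class DEResult:
    gene: str
    statistic: float
    p: float
    q: float


def welch_test(x, y) -> tuple[float, float, float]:
    """Welch's unequal-variance t-test.

    Returns ``(t, df, p)`` with t carrying the sign of mean(x) - mean(y), df
    the Welch-Satterthwaite degrees of freedom, and p two-tailed.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each sample needs at least 2 values")
    if x.var(ddof=1) == 0.0 and y.var(ddof=1) == 0.0:
        if np.mean(x) == np.mean(y):
            # equal constants: no evidence of any difference
            return 0.0, float(x.size + y.size - 2), 1.0
        raise ValueError("both samples have zero variance; t is undefined")
    res = stats.ttest_ind(x, y, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted values, order-aligned with input."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return np.clip(q, 0.0, 1.0)


def de_table(expr: ExpressionMatrix, group_a: str = "affected",
             group_b: str = "control") -> pd.DataFrame:
    """Per-gene Welch t, p and BH q between the two sample groups.

    Genes constant in both groups have no defined statistic; they are dropped
    with a logged warning rather than assigned p = 1.
    """
    groups = set(expr.groups)
    if not {group_a, group_b} <= groups:
        raise ValueError(f"matrix must contain groups {group_a!r} and {group_b!r}; "
                         f"found {sorted(groups)}")
    mask_a = (expr.groups == group_a).to_numpy()
    mask_b = (expr.groups == group_b).to_numpy()
    if mask_a.sum() < 2 or mask_b.sum() < 2:
        raise ValueError("each group needs at least 2 samples")

    values = expr.data.to_numpy()
    a, b = values[:, mask_a], values[:, mask_b]
    var_a, var_b = a.var(axis=1, ddof=1), b.var(axis=1, ddof=1)
    constant = (var_a == 0.0) & (var_b == 0.0)
    if constant.any():
        names = [g for g, c in zip(expr.genes, constant) if c]
        logger.warning("excluding %d constant gene(s) from DE testing: %s",
                       len(names), ", ".join(names[:10]))

    keep = ~constant
    rows = []
    if keep.any():
        res = stats.ttest_ind(a[keep], b[keep], axis=1, equal_var=False)
        q = bh_fdr(res.pvalue)
        rows = list(zip(np.array(expr.genes)[keep], res.statistic, res.pvalue, q))
    return pd.DataFrame(rows, columns=["gene", "t", "p", "q"])


def de_genes(expr: ExpressionMatrix, q_threshold: float = 0.005,
             group_a: str = "affected", group_b: str = "control") -> set[str]:
    """Genes differentially expressed between the groups at BH FDR q_threshold."""
    table = de_table(expr, group_a, group_b)
    if table.empty:
        return set()
    return set(table.loc[table["q"] <= q_threshold, "gene"])


def common_de(set_a: set[str], set_b: set[str]) -> set[str]:
    """DE genes shared by two regions: the exact intersection."""
    return set(set_a) & set(set_b)


def write_de_table(table: pd.DataFrame, path, q_threshold: float = 0.005) -> None:
    out = table.copy()
    out["selected"] = out["q"] <= q_threshold
    out.to_csv(path, sep="\t", index=False)
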