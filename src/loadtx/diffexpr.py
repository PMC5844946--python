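"""In-house count-based differential expression.

The procedure: upper-quartile normalization of the count matrix, log2 fold
change of group means (with pseudocount), intra- vs inter-condition pairwise
fold-change diagnostics, a two-tailed Welch t-test per feature, Benjamini-
Hochberg correction, and selection of features with |log2FC| > 1 and
adjusted p < 0.05 (both strict).

Two testing modes are exposed because "comparing fold changes within and
between conditions" admits two readings:

* ``log_expression`` (default): Welch t on log2(normalized + c) between the
  two groups — the plain two-sample t-test on the log scale.
* ``fc_contrast``: a two-sample t of the inter-condition pairwise log2
  ratios against the pooled intra-condition pairwise log2 ratios, i.e. the
  literal pairwise fold-change comparison.

Both report the same fold-change diagnostics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

CONTROL = "control"
CASE = "case"

#: p-value reported when group variances vanish but means differ
P_FLOOR = float(np.finfo(float).tiny)


def _group_columns(matrix: pd.DataFrame, groups: pd.Series) -> tuple[list[str], list[str]]:
    groups = groups.reindex(matrix.columns)
    if groups.isna().any():
        missing = list(matrix.columns[groups.isna()])
        raise ValueError(f"samples without group label: {missing}")
    labels = set(groups.unique())
    if labels != {CONTROL, CASE}:
        raise ValueError(f"groups must be exactly {{{CONTROL!r}, {CASE!r}}}, got {sorted(labels)}")
    ctrl = [s for s in matrix.columns if groups[s] == CONTROL]
    case = [s for s in matrix.columns if groups[s] == CASE]
    return ctrl, case


# ---------------------------------------------------------------------------
# normalization


def uq_normalize(matrix: pd.DataFrame) -> tuple[pd.DataFrame, pd.Series]:
    """Upper-quartile normalization.

    The size factor of sample j is the 75th percentile (linear-interpolation
    quantile) of its counts over features that are nonzero in at least one
    sample. Values are divided by the size factor and rescaled by the
    geometric mean of all size factors, so the overall scale of the matrix
    is preserved and all samples end up with equal upper quartiles.
    """
    expressed = matrix.loc[matrix.sum(axis=1) > 0]
    if expressed.empty:
        raise ValueError("no feature is nonzero in any sample")
    size_factors = expressed.quantile(0.75, axis=0)
    zero = size_factors[size_factors <= 0]
    if not zero.empty:
        raise ValueError(f"upper quartile is zero for sample(s) {list(zero.index)}")
    geo_mean = float(np.exp(np.log(size_factors).mean()))
    normalized = matrix.div(size_factors, axis=1) * geo_mean
    return normalized, size_factors.rename("size_factor")


# ---------------------------------------------------------------------------
# fold changes


def log2_fold_change(
    normalized: pd.DataFrame,
    groups: pd.Series,
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Per-feature log2((mean_case + c) / (mean_ctrl + c)), case over control.

    Returns a frame with mean_ctrl, mean_case and log2fc columns.
    """
    ctrl, case = _group_columns(normalized, groups)
    mean_ctrl = normalized[ctrl].mean(axis=1)
    mean_case = normalized[case].mean(axis=1)
    if pseudocount <= 0:
        if (mean_ctrl <= 0).any() or (mean_case <= 0).any():
            raise ValueError("pseudocount must be > 0 when a group mean is zero")
        c = 0.0
    else:
        c = pseudocount
    log2fc = np.log2((mean_case + c) / (mean_ctrl + c))
    return pd.DataFrame({"mean_ctrl": mean_ctrl, "mean_case": mean_case, "log2fc": log2fc})


def pairwise_fc(
    normalized: pd.DataFrame,
    groups: pd.Series,
    pseudocount: float = 1.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise log2 ratios within conditions and between conditions.

    intra: for each unordered within-group sample pair (i, j) with i before j
    in column order, log2((x_i + c)/(x_j + c)); both groups pooled
    (|intra| = C(n1,2) + C(n2,2)). inter: every ordered case-vs-control pair,
    log2((x_case + c)/(x_ctrl + c)) (|inter| = n1*n2). Returned as
    feature x pair frames. A group of size 1 simply contributes no intra
    pairs (logged).
    """
    ctrl, case = _group_columns(normalized, groups)
    c = pseudocount
    logged = np.log2(normalized + c)
    intra_cols, inter_cols = {}, {}
    for members in (ctrl, case):
        if len(members) < 2:
            logger.warning("pairwise_fc: group of size %d yields no intra pairs", len(members))
        for i in range(len(members)):
            for j in range(i + 1, len(members)):
                a, b = members[i], members[j]
                intra_cols[f"{a}/{b}"] = logged[a] - logged[b]
    for a in case:
        for b in ctrl:
            inter_cols[f"{a}/{b}"] = logged[a] - logged[b]
    intra = pd.DataFrame(intra_cols, index=normalized.index)
    inter = pd.DataFrame(inter_cols, index=normalized.index)
    return intra, inter


# ---------------------------------------------------------------------------
# testing


def _welch_t(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Row-wise two-tailed Welch t-test p-values with degenerate conventions.

    Zero variance in both groups: p = 1 when the means agree, otherwise the
    smallest positive float (the p -> 0 limit), flagged via log.
    """
    p = stats.ttest_ind(x, y, axis=1, equal_var=False).pvalue
    var_x = x.var(axis=1, ddof=1)
    var_y = y.var(axis=1, ddof=1)
    degenerate = (var_x == 0) & (var_y == 0)
    if degenerate.any():
        equal = np.isclose(x.mean(axis=1), y.mean(axis=1))
        p = np.where(degenerate & equal, 1.0, p)
        p = np.where(degenerate & ~equal, P_FLOOR, p)
        if (degenerate & ~equal).any():
            logger.warning("_welch_t: %d feature(s) with zero variance and unequal means; "
                           "p reported as %.3g", int((degenerate & ~equal).sum()), P_FLOOR)
    return np.asarray(p, dtype=float)


def de_test(
    normalized: pd.DataFrame,
    groups: pd.Series,
    mode: str = "log_expression",
    pseudocount: float = 1.0,
) -> pd.Series:
    """Per-feature two-tailed p-value for differential expression.

    ``log_expression``: Welch t on log2(normalized + c) between groups.
    ``fc_contrast``: Welch t of the inter-condition pairwise log2 ratios
    against the pooled intra-condition ratios.
    """
    ctrl, case = _group_columns(normalized, groups)
    if len(ctrl) < 2 or len(case) < 2:
        raise ValueError("de_test requires >= 2 samples per group")
    if mode == "log_expression":
        logged = np.log2(normalized + pseudocount)
        p = _welch_t(logged[case].values, logged[ctrl].values)
    elif mode == "fc_contrast":
        intra, inter = pairwise_fc(normalized, groups, pseudocount)
        p = _welch_t(inter.values, intra.values)
    else:
        raise ValueError(f"unknown de_test mode {mode!r}")
    return pd.Series(p, index=normalized.index, name="p")


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved.

    padj_i = min over j with p_j >= p_i of (m * p_j / rank_j), capped at 1.
    """
    p = np.asarray(p, dtype=float)
    if p.ndim != 1:
        raise ValueError("bh_adjust expects a 1-d vector")
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    if m == 0:
        return p.copy()
    order = np.argsort(p, kind="mergesort")
    scaled = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(scaled[::-1])[::-1]
    out = np.empty(m, dtype=float)
    out[order] = np.minimum(adjusted, 1.0)
    return out


def select_de(
    results: pd.DataFrame,
    lfc_threshold: float = 1.0,
    alpha: float = 0.05,
) -> pd.Series:
    """The selection rule: |log2fc| > lfc_threshold AND padj < alpha, both strict."""
    return (results["log2fc"].abs() > lfc_threshold) & (results["padj"] < alpha)


# ---------------------------------------------------------------------------
# pipeline


@dataclass
class DEResult:
    """Full differential-expression output: per-feature table + metadata."""

    table: pd.DataFrame          # feature, mean_ctrl, mean_case, log2fc, p, padj, selected
    size_factors: pd.Series
    mode: str
    pseudocount: float


def run_de(
    counts: pd.DataFrame,
    groups: pd.Series,
    mode: str = "log_expression",
    pseudocount: float = 1.0,
    lfc_threshold: float = 1.0,
    alpha: float = 0.05,
) -> DEResult:
    """Normalize, compute fold changes and diagnostics, test, adjust, select."""
    normalized, size_factors = uq_normalize(counts)
    table = log2_fold_change(normalized, groups, pseudocount)
    intra, inter = pairwise_fc(normalized, groups, pseudocount)
    table["intra_fc_spread"] = intra.std(axis=1, ddof=1) if intra.shape[1] > 1 else np.nan
    table["inter_fc_mean"] = inter.mean(axis=1)
    table["p"] = de_test(normalized, groups, mode=mode, pseudocount=pseudocount)
    table["padj"] = bh_adjust(table["p"].values)
    table["selected"] = select_de(table, lfc_threshold, alpha)
    return DEResult(table=table, size_factors=size_factors, mode=mode, pseudocount=pseudocount)
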