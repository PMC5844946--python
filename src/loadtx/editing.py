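"""A-to-I RNA-editing quantification and differential-editing analysis.

Given per-site pileup counts (G-supporting reads over A+G reads), this module
computes per-site editing levels, per-sample editing indices — the Alu
Editing Index (AEI) over Alu-class sites and the Recoding Editing Index (REI)
over recoding-class sites, both as the coverage-weighted pooled ratio
sum(edited)/sum(total) — applies the recoding-site filters (coverage in at
least three samples per group; pooled median editing level strictly above
0.1), and tests each retained site for differential editing between control
and case samples with a two-tailed Welch t-test followed by Benjamini-
Hochberg correction at FDR 0.1.

Sign convention throughout: edit differences are control minus case, so a
positive difference means editing is lower in disease.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .diffexpr import CASE, CONTROL, _welch_t, bh_adjust
from .io import SITE_CLASSES

logger = logging.getLogger(__name__)


@dataclass
class EditingSiteTable:
    """Annotated editing sites with per-sample (edited, total) read counts.

    ``sites`` is indexed by "chrom:pos" ids with columns chrom, pos, strand,
    site_class, gene, aa_change; ``edited`` and ``total`` are integer
    site x sample frames on the same index; ``groups`` maps each sample to
    'control' or 'case'.
    """

    sites: pd.DataFrame
    edited: pd.DataFrame
    total: pd.DataFrame
    groups: pd.Series | None = None

    def __post_init__(self) -> None:
        if not (self.sites.index.equals(self.edited.index) and self.sites.index.equals(self.total.index)):
            raise ValueError("sites, edited and total must share one index")
        if list(self.edited.columns) != list(self.total.columns):
            raise ValueError("edited and total must share sample columns")
        if (self.edited.values < 0).any() or (self.edited.values > self.total.values).any():
            raise ValueError("require 0 <= edited <= total")

    @property
    def samples(self) -> list[str]:
        return list(self.edited.columns)

    def levels(self) -> pd.DataFrame:
        """Per-site, per-sample editing level; NaN where total == 0."""
        with np.errstate(divide="ignore", invalid="ignore"):
            lv = self.edited.values / self.total.values
        lv = np.where(self.total.values > 0, lv, np.nan)
        return pd.DataFrame(lv, index=self.sites.index, columns=self.samples)

    def subset(self, site_ids) -> "EditingSiteTable":
        return EditingSiteTable(
            sites=self.sites.loc[site_ids],
            edited=self.edited.loc[site_ids],
            total=self.total.loc[site_ids],
            groups=self.groups,
        )


def editing_level(edited, total):
    """edited/total as a float (or elementwise array); NaN where total == 0."""
    edited = np.asarray(edited, dtype=float)
    total = np.asarray(total, dtype=float)
    if (edited < 0).any() or (edited > total).any():
        raise ValueError("require 0 <= edited <= total")
    with np.errstate(divide="ignore", invalid="ignore"):
        level = np.where(total > 0, edited / total, np.nan)
    return float(level) if level.ndim == 0 else level


@dataclass(frozen=True)
class EditingIndex:
    sample: str
    index_class: str      # "AEI" or "REI"
    value: float          # NaN when no covered site
    n_sites_used: int


_CLASS_TO_INDEX = {"alu": "AEI", "recoding": "REI"}


def editing_index(
    table: EditingSiteTable,
    sample: str,
    site_class: str,
    weighted: bool = True,
) -> EditingIndex:
    """Editing index of one sample over sites of one class.

    Default is the coverage-weighted pooled ratio sum(edited)/sum(total)
    over covered sites; ``weighted=False`` gives the unweighted mean of
    per-site levels instead (sensitivity mode).
    """
    if site_class not in SITE_CLASSES:
        raise ValueError(f"unknown site class {site_class!r}")
    mask = (table.sites["site_class"] == site_class) & (table.total[sample] > 0)
    n = int(mask.sum())
    if n == 0:
        logger.warning("editing_index: sample %s has no covered %s site", sample, site_class)
        value = float("nan")
    elif weighted:
        value = float(table.edited.loc[mask, sample].sum() / table.total.loc[mask, sample].sum())
    else:
        value = float(
            (table.edited.loc[mask, sample] / table.total.loc[mask, sample]).mean()
        )
    return EditingIndex(sample=sample, index_class=_CLASS_TO_INDEX[site_class],
                        value=value, n_sites_used=n)


def editing_index_table(table: EditingSiteTable, weighted: bool = True) -> pd.DataFrame:
    """Per-sample AEI and REI as a sample x index frame (NaN if class absent)."""
    rows = {}
    for sample in table.samples:
        rows[sample] = {
            _CLASS_TO_INDEX[cls]: editing_index(table, sample, cls, weighted).value
            for cls in SITE_CLASSES
            if (table.sites["site_class"] == cls).any()
        }
    return pd.DataFrame.from_dict(rows, orient="index").rename_axis("sample")


# ---------------------------------------------------------------------------
# site filters


def filter_recoding_sites(
    table: EditingSiteTable,
    min_samples_per_group: int = 3,
    min_median: float = 0.1,
) -> tuple[list[str], pd.DataFrame]:
    """Apply the per-site filters; returns (retained ids, per-site report).

    A site is retained iff it is covered (total > 0) in at least
    ``min_samples_per_group`` control AND case samples, and the median of its
    defined per-sample levels — all samples pooled — is strictly greater
    than ``min_median``.
    """
    if table.groups is None:
        raise ValueError("filter_recoding_sites requires group labels")
    groups = table.groups.reindex(table.samples)
    ctrl = [s for s in table.samples if groups[s] == CONTROL]
    case = [s for s in table.samples if groups[s] == CASE]
    if not ctrl or not case:
        raise ValueError("both control and case samples are required")
    covered = table.total > 0
    n_ctrl = covered[ctrl].sum(axis=1)
    n_case = covered[case].sum(axis=1)
    pooled_median = table.levels().median(axis=1)
    coverage_ok = (n_ctrl >= min_samples_per_group) & (n_case >= min_samples_per_group)
    median_ok = pooled_median > min_median
    keep = coverage_ok & median_ok
    reason = np.where(~coverage_ok, "coverage",
                      np.where(~median_ok, "low_median", "."))
    report = pd.DataFrame({
        "n_ctrl_covered": n_ctrl, "n_case_covered": n_case,
        "pooled_median": pooled_median, "kept": keep, "exclusion_reason": reason,
    }, index=table.sites.index)
    return list(table.sites.index[keep]), report


# ---------------------------------------------------------------------------
# differential editing


def edit_difference(mean_ctrl: float, mean_case: float) -> float:
    """Control-minus-case difference of mean editing levels."""
    return mean_ctrl - mean_case


def differential_editing(
    table: EditingSiteTable,
    fdr: float = 0.1,
    min_samples_per_group: int = 3,
    min_median: float = 0.1,
    apply_filter: bool = True,
) -> pd.DataFrame:
    """Per-site differential-editing test over retained sites.

    For each retained site, group means are the unweighted means of defined
    per-sample levels, the test is a two-tailed Welch t on those levels, and
    p-values are BH-adjusted across the tested sites; a site is significant
    iff padj <= fdr (inclusive). Retained sites with fewer than two defined
    levels in a group are excluded from testing and logged.
    """
    if table.groups is None:
        raise ValueError("differential_editing requires group labels")
    if apply_filter:
        retained, _ = filter_recoding_sites(table, min_samples_per_group, min_median)
        sub = table.subset(retained)
    else:
        sub = table
    groups = table.groups.reindex(sub.samples)
    ctrl = [s for s in sub.samples if groups[s] == CONTROL]
    case = [s for s in sub.samples if groups[s] == CASE]
    levels = sub.levels()

    testable = (levels[ctrl].notna().sum(axis=1) >= 2) & (levels[case].notna().sum(axis=1) >= 2)
    dropped = int((~testable).sum())
    if dropped:
        logger.warning("differential_editing: %d retained site(s) lack >= 2 defined "
                       "levels per group and were excluded from testing", dropped)
    levels = levels.loc[testable]
    annot = sub.sites.loc[testable]

    mean_ctrl = levels[ctrl].mean(axis=1)
    mean_case = levels[case].mean(axis=1)
    p = np.array([
        _welch_t(
            levels.loc[[sid], case].dropna(axis=1).values,
            levels.loc[[sid], ctrl].dropna(axis=1).values,
        )[0]
        for sid in levels.index
    ]) if len(levels) else np.array([])
    padj = bh_adjust(p)
    out = pd.DataFrame({
        "gene": annot["gene"], "chrom": annot["chrom"], "pos": annot["pos"],
        "aa_change": annot["aa_change"],
        "mean_ctrl": mean_ctrl, "mean_case": mean_case,
        "edit_difference": mean_ctrl - mean_case,
        "p": p, "padj": padj, "significant": padj <= fdr if len(p) else [],
    }, index=levels.index)
    return out


# ---------------------------------------------------------------------------
# group comparison of indices, with box-plot summaries


def boxplot_stats(values) -> dict:
    """Tukey box-plot summary: quartiles, whisker fences at Q75 + 1.5*IQR and
    Q25 - 1.5*IQR, and the values falling outside the fences (outliers)."""
    v = np.asarray([x for x in np.asarray(values, dtype=float) if np.isfinite(x)])
    q1, q2, q3 = np.percentile(v, [25, 50, 75])
    iqr = q3 - q1
    upper = q3 + 1.5 * iqr
    lower = q1 - 1.5 * iqr
    return {
        "q1": float(q1), "median": float(q2), "q3": float(q3), "iqr": float(iqr),
        "upper_whisker": float(upper), "lower_whisker": float(lower),
        "outliers": [float(x) for x in v[(v > upper) | (v < lower)]],
    }


def compare_group_indices(index_table: pd.DataFrame, groups: pd.Series) -> pd.DataFrame:
    """Welch t-test of each editing index (AEI, REI) between groups, with BH
    correction across the index classes and per-group box-plot summaries."""
    groups = groups.reindex(index_table.index)
    ctrl = index_table.index[groups == CONTROL]
    case = index_table.index[groups == CASE]
    if len(ctrl) < 2 or len(case) < 2:
        raise ValueError("compare_group_indices requires >= 2 samples per group")
    rows = []
    for cls in index_table.columns:
        x = index_table.loc[case, cls].dropna().values
        y = index_table.loc[ctrl, cls].dropna().values
        p = _welch_t(x[None, :], y[None, :])[0]
        rows.append({
            "index_class": cls,
            "mean_ctrl": float(np.mean(y)), "mean_case": float(np.mean(x)),
            "difference_ctrl_minus_case": float(np.mean(y) - np.mean(x)),
            "p": float(p),
            "box_ctrl": boxplot_stats(y), "box_case": boxplot_stats(x),
        })
    out = pd.DataFrame(rows).set_index("index_class")
    out["padj"] = bh_adjust(out["p"].values)
    return out
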