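"""RT-qPCR relative quantification and reference-gene stability selection.

Workflow: technical replicate Cts are averaged per (sample, gene); candidate
housekeeping genes are ranked by two stability measures — the geNorm M value
(mean SD of a gene's pairwise Ct differences against every other candidate,
with iterative exclusion of the least stable gene) and a NormFinder-style
variance decomposition (intra-group variation plus inter-group bias on
sample-centered Cts) — and a consensus subset is selected; each target gene
is then quantified by the ddCt method: dCt = Ct_target - mean(Ct of selected
housekeepers) per sample, ddCt = dCt - mean(dCt over the control group), and
the reported log2 relative expression is -ddCt (log2 of 2^-ddCt), so
up-regulated targets have positive values and the control-group mean is zero
by construction. Group differences are assessed with a two-tailed Welch
t-test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .diffexpr import CASE, CONTROL, _welch_t

logger = logging.getLogger(__name__)


def collapse_replicates(ct_long: pd.DataFrame) -> tuple[pd.DataFrame, pd.Series]:
    """Average replicate Cts; returns (sample x gene mean-Ct frame, groups)."""
    wide = ct_long.pivot_table(index="sample", columns="gene", values="ct", aggfunc="mean")
    groups = ct_long.drop_duplicates("sample").set_index("sample")["group"]
    if (ct_long.groupby(["sample", "gene"])["group"].nunique() > 1).any():
        raise ValueError("a sample maps to more than one group")
    return wide, groups.reindex(wide.index)


# ---------------------------------------------------------------------------
# geNorm


def genorm_m(ct_wide: pd.DataFrame, candidates: list[str]) -> tuple[pd.Series, list[str]]:
    """geNorm M values and the iterative stability ranking.

    For genes j, k the pairwise variation V_jk is the sample SD (ddof=1) of
    Ct_j - Ct_k; M_j is the mean of V_jk over k != j, computed on the full
    candidate set. The ranking comes from iteratively recomputing M on the
    remaining set and excluding the gene with the highest M until two remain;
    those two are the most stable pair (unordered by geNorm itself; listed in
    ascending full-set M). Returns (full-set M values, ranking most stable
    first).
    """
    if len(candidates) < 3:
        raise ValueError("geNorm needs >= 3 candidate genes")
    sub = ct_wide[candidates]
    if sub.isna().any().any():
        missing = list(sub.columns[sub.isna().any()])
        raise ValueError(f"candidate(s) {missing} missing in some sample")

    def m_values(genes: list[str]) -> pd.Series:
        m = {}
        for j in genes:
            v = [float((sub[j] - sub[k]).std(ddof=1)) for k in genes if k != j]
            m[j] = float(np.mean(v))
        return pd.Series(m)

    full_m = m_values(candidates)
    remaining = list(candidates)
    excluded: list[str] = []
    while len(remaining) > 2:
        m = m_values(remaining)
        worst = m.idxmax()
        excluded.append(worst)
        remaining.remove(worst)
    final_pair = sorted(remaining, key=lambda g: full_m[g])
    ranking = final_pair + excluded[::-1]
    return full_m.rename("genorm_m"), ranking


# ---------------------------------------------------------------------------
# NormFinder-style stability


def normfinder_stability(
    ct_wide: pd.DataFrame,
    candidates: list[str],
    groups: pd.Series,
) -> tuple[pd.Series, list[str]]:
    """Model-based stability from intra-group variation and inter-group bias.

    Cts are sample-centered (each sample's mean over candidates subtracted),
    removing sample-specific loading. For gene i with centered values z:
    d_ig = group-g mean of z minus the gene's overall mean (inter-group
    bias), v_ig = within-group variance (ddof=1). The stability is

        rho_i = mean over groups of ( |d_ig| + sqrt(v_ig / n_g) ),

    larger meaning less stable — a gene is penalized both for differing
    systematically between groups and for noisy within-group behaviour.
    This follows the published variance-decomposition idea; it is not
    bit-compatible with the original applet. Returns (stabilities, ranking
    most stable first).
    """
    if len(candidates) < 3:
        raise ValueError("NormFinder-style stability needs >= 3 candidates")
    groups = groups.reindex(ct_wide.index)
    if groups.nunique() < 2 or (groups.value_counts() < 2).any():
        raise ValueError("need >= 2 groups with >= 2 samples each")
    sub = ct_wide[candidates]
    if sub.isna().any().any():
        missing = list(sub.columns[sub.isna().any()])
        raise ValueError(f"candidate(s) {missing} missing in some sample")
    z = sub.sub(sub.mean(axis=1), axis=0)
    rho = {}
    for gene in candidates:
        overall = z[gene].mean()
        parts = []
        for g, members in z.groupby(groups).groups.items():
            zg = z.loc[members, gene]
            bias = abs(zg.mean() - overall)
            var = float(zg.var(ddof=1))
            parts.append(bias + np.sqrt(var / len(zg)))
        rho[gene] = float(np.mean(parts))
    stab = pd.Series(rho, name="normfinder_stability")
    ranking = list(stab.sort_values(kind="mergesort").index)
    return stab, ranking


# ---------------------------------------------------------------------------
# consensus selection


@dataclass
class StabilityReport:
    genorm_m: pd.Series
    genorm_ranking: list[str]
    normfinder: pd.Series
    normfinder_ranking: list[str]
    selected: list[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        out = pd.DataFrame({"genorm_m": self.genorm_m, "normfinder_stability": self.normfinder})
        out["genorm_rank"] = [self.genorm_ranking.index(g) + 1 for g in out.index]
        out["normfinder_rank"] = [self.normfinder_ranking.index(g) + 1 for g in out.index]
        out["selected"] = [g in self.selected for g in out.index]
        return out.rename_axis("gene")


def rank_housekeepers(ct_wide: pd.DataFrame, candidates: list[str], groups: pd.Series) -> StabilityReport:
    m, m_rank = genorm_m(ct_wide, candidates)
    nf, nf_rank = normfinder_stability(ct_wide, candidates, groups)
    return StabilityReport(genorm_m=m, genorm_ranking=m_rank,
                           normfinder=nf, normfinder_ranking=nf_rank)


def select_housekeepers(report: StabilityReport, k: int = 3) -> list[str]:
    """Consensus of the two rankings: genes in both top-k sets first (in
    geNorm order), remaining slots filled by geNorm rank. Returns k genes."""
    if k > len(report.genorm_ranking):
        raise ValueError("k exceeds the number of candidates")
    top_g = report.genorm_ranking[:k]
    top_n = set(report.normfinder_ranking[:k])
    consensus = [g for g in top_g if g in top_n]
    for g in report.genorm_ranking:
        if len(consensus) == k:
            break
        if g not in consensus:
            consensus.append(g)
    report.selected = consensus
    return consensus


# ---------------------------------------------------------------------------
# ddCt quantification


@dataclass
class RelativeExpression:
    """ddCt output for one target gene.

    ``per_sample`` columns: group, delta_ct, ddct, log2_rel (= -ddct).
    ``summary`` has per-group mean, sd and n of log2_rel. ``p`` is the
    two-tailed Welch t-test p for case vs control log2_rel.
    """

    target: str
    housekeepers: list[str]
    per_sample: pd.DataFrame
    summary: pd.DataFrame
    p: float


def ddct_quantify(
    ct_long: pd.DataFrame,
    target: str,
    housekeepers: list[str],
    control_group: str = CONTROL,
) -> RelativeExpression:
    """ddCt relative quantification of one target against the control-group
    calibrator (see module docstring for the chain of definitions)."""
    if target in housekeepers:
        raise ValueError(f"target {target!r} cannot be its own housekeeper")
    wide, groups = collapse_replicates(ct_long)
    needed = [target, *housekeepers]
    missing_any = wide[needed].isna().any(axis=1)
    if missing_any.any():
        logger.warning("ddct_quantify(%s): excluding sample(s) %s with missing Cts",
                       target, list(wide.index[missing_any]))
    wide = wide.loc[~missing_any]
    groups = groups.loc[wide.index]
    if not (groups == control_group).any():
        raise ValueError(f"no samples in control group {control_group!r}")

    delta_ct = wide[target] - wide[housekeepers].mean(axis=1)
    calibrator = delta_ct[groups == control_group].mean()
    ddct = delta_ct - calibrator
    log2_rel = -ddct
    per_sample = pd.DataFrame({
        "group": groups, "delta_ct": delta_ct, "ddct": ddct, "log2_rel": log2_rel,
    })
    summary = per_sample.groupby("group")["log2_rel"].agg(["mean", "std", "count"])
    summary.columns = ["mean_log2_rel", "sd", "n"]
    x = log2_rel[groups == CASE].values
    y = log2_rel[groups == CONTROL].values
    p = float(_welch_t(x[None, :], y[None, :])[0]) if len(x) >= 2 and len(y) >= 2 else float("nan")
    return RelativeExpression(target=target, housekeepers=list(housekeepers),
                              per_sample=per_sample, summary=summary, p=p)
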