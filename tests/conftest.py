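"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from loadtx import simulate
from loadtx.mirna import (
    ASSIGNED,
    UNASSIGNED_AMBIGUOUS,
    UNASSIGNED_NO_HIT,
    AssignmentResult,
)


# ---------------------------------------------------------------------------
# independent oracles


def brute_force_assign(seq: str, reference: dict[str, str], min_overlap: int = 17) -> AssignmentResult:
    """Exhaustive per-base assignment scorer, independent of the production
    implementation: walks every miRNA and every ungapped offset, counting the
    overlap base-by-base and rejecting on the first mismatch."""
    per_mirna_best: dict[str, int] = {}
    for name, ref in reference.items():
        best = 0
        for off in range(-len(seq) + 1, len(ref)):
            overlap = 0
            ok = True
            for i in range(len(seq)):
                j = i + off
                if 0 <= j < len(ref):
                    overlap += 1
                    if seq[i] != ref[j]:
                        ok = False
                        break
            if ok and overlap >= min_overlap and overlap > best:
                best = overlap
        if best:
            per_mirna_best[name] = best
    if not per_mirna_best:
        return AssignmentResult("read", UNASSIGNED_NO_HIT)
    top = max(per_mirna_best.values())
    winners = sorted(n for n, v in per_mirna_best.items() if v == top)
    if len(winners) > 1:
        return AssignmentResult("read", UNASSIGNED_AMBIGUOUS, overlap_len=top,
                                best_mirnas=tuple(winners))
    return AssignmentResult("read", ASSIGNED, mirna=winners[0], overlap_len=top,
                            best_mirnas=(winners[0],))


def brute_force_bh(p: np.ndarray) -> np.ndarray:
    """Direct evaluation of the BH step-up definition:
    padj_i = min over j with p_j >= p_i of (m * p_j / rank_j), capped at 1."""
    p = np.asarray(p, dtype=float)
    m = p.size
    ranks = np.empty(m)
    order = np.argsort(p, kind="mergesort")
    ranks[order] = np.arange(1, m + 1)
    out = np.empty(m)
    for i in range(m):
        vals = [m * p[j] / ranks[j] for j in range(m) if p[j] >= p[i]]
        out[i] = min(1.0, min(vals))
    return out


def manual_welch(x, y) -> float:
    """Textbook Welch t-test p-value (statistic + Welch-Satterthwaite df),
    written out from the formulas; only the t distribution comes from scipy."""
    from scipy.stats import t as t_dist

    x, y = np.asarray(x, float), np.asarray(y, float)
    nx, ny = len(x), len(y)
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    se2 = vx / nx + vy / ny
    t = (x.mean() - y.mean()) / np.sqrt(se2)
    df = se2 ** 2 / ((vx / nx) ** 2 / (nx - 1) + (vy / ny) ** 2 / (ny - 1))
    return float(2.0 * t_dist.sf(abs(t), df))


# ---------------------------------------------------------------------------
# fixtures


@pytest.fixture(scope="session")
def reference_sim():
    return simulate.gen_mirna_reference(n_mirnas=20, n_family_pairs=3, seed=11)


@pytest.fixture(scope="session")
def small_reference(reference_sim):
    return reference_sim.reference


@pytest.fixture()
def toy_site_table():
    """A 3-site pileup table (2 recoding, 1 alu) over 2+2 samples."""
    from loadtx.editing import EditingSiteTable

    sites = pd.DataFrame({
        "chrom": ["chr1", "chr2", "chr3"],
        "pos": [100, 200, 300],
        "strand": ["+", "-", "+"],
        "site_class": ["recoding", "recoding", "alu"],
        "gene": ["G1", "G2", None],
        "aa_change": ["Q/R", "I/V", None],
    })
    sites.index = pd.Index(["chr1:100", "chr2:200", "chr3:300"], name="site_id")
    samples = ["c1", "c2", "a1", "a2"]
    edited = pd.DataFrame([[5, 6, 2, 1], [9, 8, 9, 9], [1, 3, 2, 2]],
                          index=sites.index, columns=samples)
    total = pd.DataFrame([[10, 10, 10, 10], [10, 10, 10, 10], [10, 10, 10, 10]],
                         index=sites.index, columns=samples)
    groups = pd.Series(["control", "control", "case", "case"], index=samples)
    return EditingSiteTable(sites=sites, edited=edited, total=total, groups=groups)
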