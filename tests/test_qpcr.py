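"""Reference-gene stability (geNorm M, NormFinder-style), consensus
selection, and ddCt quantification with its calibrator identity."""

import itertools

import numpy as np
import pandas as pd
import pytest

from loadtx import simulate
from loadtx.qpcr import (
    StabilityReport,
    collapse_replicates,
    ddct_quantify,
    genorm_m,
    normfinder_stability,
    rank_housekeepers,
    select_housekeepers,
)


def _wide(data, samples=None):
    samples = samples or [f"s{j}" for j in range(len(next(iter(data.values()))))]
    return pd.DataFrame(data, index=samples)


def brute_force_genorm_m(ct_wide, candidates):
    """Independent pairwise-SD evaluation of the geNorm M definition."""
    out = {}
    for j in candidates:
        sds = []
        for k in candidates:
            if k == j:
                continue
            diffs = ct_wide[j] - ct_wide[k]
            mean = sum(diffs) / len(diffs)
            sds.append((sum((d - mean) ** 2 for d in diffs) / (len(diffs) - 1)) ** 0.5)
        out[j] = sum(sds) / len(sds)
    return out


class TestGeNorm:
    def test_identical_genes_have_zero_pairwise_variation(self):
        ct = _wide({"A": [20, 21, 22, 23], "B": [20, 21, 22, 23], "C": [25, 24, 23, 26]})
        m, ranking = genorm_m(ct, ["A", "B", "C"])
        # V_AB = 0, so M_A = M_B = mean(0, sd(A-C)) and C is least stable
        assert ranking[-1] == "C"
        assert m["A"] == pytest.approx(m["B"])

    def test_constant_shift_invariance(self):
        ct = _wide({"A": [20.0, 21, 22, 23], "B": [19.5, 21.2, 21.8, 23.1],
                    "C": [25.0, 24, 23, 26]})
        m1, _ = genorm_m(ct, ["A", "B", "C"])
        shifted = ct.copy()
        shifted["A"] = shifted["A"] + 3.0
        m2, _ = genorm_m(shifted, ["A", "B", "C"])
        pd.testing.assert_series_equal(m1, m2)

    def test_toy_matches_hand_computation(self):
        ct = _wide({"A": [10.0, 11, 12, 13], "B": [10.0, 12, 12, 14],
                    "C": [11.0, 11, 13, 13]})
        m, _ = genorm_m(ct, ["A", "B", "C"])
        want = brute_force_genorm_m(ct, ["A", "B", "C"])
        for g in "ABC":
            assert m[g] == pytest.approx(want[g], rel=1e-12)

    def test_matches_brute_force_on_random_tables(self):
        rng = np.random.default_rng(21)
        for _ in range(20):
            n_genes = int(rng.integers(3, 7))
            n_samples = int(rng.integers(3, 9))
            genes = [f"g{i}" for i in range(n_genes)]
            ct = pd.DataFrame(rng.normal(25, 2, size=(n_samples, n_genes)), columns=genes)
            m, _ = genorm_m(ct, genes)
            want = brute_force_genorm_m(ct, genes)
            for g in genes:
                assert m[g] == pytest.approx(want[g], rel=1e-10)

    def test_missing_candidate_rejected(self):
        ct = _wide({"A": [20, 21, 22], "B": [20, np.nan, 22], "C": [25, 24, 23]})
        with pytest.raises(ValueError, match="B"):
            genorm_m(ct, ["A", "B", "C"])


class TestNormFinder:
    GROUPS = pd.Series(["control"] * 3 + ["case"] * 3,
                       index=[f"s{j}" for j in range(6)])

    def _noisy_table(self, rng, special=None):
        data = {}
        for i, sd in enumerate([0.05, 0.2, 0.4, 0.8]):
            data[f"g{i}"] = 22 + rng.normal(0, sd, size=6)
        if special is not None:
            data.update(special)
        return _wide(data)

    def test_quiet_gene_most_stable(self):
        rng = np.random.default_rng(31)
        ct = self._noisy_table(rng)
        stab, ranking = normfinder_stability(ct, list(ct.columns), self.GROUPS)
        assert ranking[0] == "g0"
        assert stab["g0"] == stab.min()

    def test_group_shift_is_worst(self):
        # four near-identical candidates; one gets a +2-cycle shift in cases only
        rng = np.random.default_rng(32)
        data = {f"g{i}": 22 + rng.normal(0, 0.05, size=6) for i in range(4)}
        data["g3"] = data["g3"] + np.array([0, 0, 0, 2, 2, 2])
        ct = _wide(data)
        stab, ranking = normfinder_stability(ct, list(ct.columns), self.GROUPS)
        assert ranking[-1] == "g3"

    def test_sample_permutation_invariance(self):
        rng = np.random.default_rng(33)
        ct = self._noisy_table(rng)
        stab1, _ = normfinder_stability(ct, list(ct.columns), self.GROUPS)
        perm = ["s3", "s1", "s5", "s0", "s4", "s2"]
        stab2, _ = normfinder_stability(ct.loc[perm], list(ct.columns), self.GROUPS.loc[perm])
        pd.testing.assert_series_equal(stab1, stab2)


class TestConsensusSelection:
    def _report(self, genorm_order, normfinder_order):
        genes = list(genorm_order)
        return StabilityReport(
            genorm_m=pd.Series(np.arange(len(genes), dtype=float), index=genes),
            genorm_ranking=list(genorm_order),
            normfinder=pd.Series(np.arange(len(genes), dtype=float), index=list(normfinder_order)),
            normfinder_ranking=list(normfinder_order),
        )

    def test_identical_rankings_give_top_k(self):
        rep = self._report("ABCDE", "ABCDE")
        assert select_housekeepers(rep, k=3) == ["A", "B", "C"]

    def test_five_candidates_three_selected(self):
        rep = self._report("ABCDE", "BACED")
        sel = select_housekeepers(rep, k=3)
        assert len(sel) == 3 and set(sel) <= set("ABCDE")

    def test_disagreement_resolved_by_genorm_rank(self):
        rep = self._report("ABCDE", "DEABC")
        # intersection of top-3 sets is empty except A? top3 geNorm {A,B,C},
        # top3 NormFinder {D,E,A}: consensus starts with A, filled by B, C
        assert select_housekeepers(rep, k=3) == ["A", "B", "C"]

    def test_k_equals_all_candidates(self):
        rep = self._report("ABC", "CBA")
        assert set(select_housekeepers(rep, k=3)) == set("ABC")

    def test_k_too_large_rejected(self):
        rep = self._report("ABC", "ABC")
        with pytest.raises(ValueError):
            select_housekeepers(rep, k=4)


class TestDdct:
    def _flat_ct(self):
        rows = []
        for s, grp in [("c1", "control"), ("c2", "control"), ("a1", "case"), ("a2", "case")]:
            for gene in ("T", "H1", "H2"):
                for rep in (1, 2):
                    rows.append({"sample": s, "group": grp, "gene": gene,
                                 "replicate": rep, "ct": 24.0})
        return pd.DataFrame(rows)

    def test_flat_table_gives_zero_everywhere(self):
        res = ddct_quantify(self._flat_ct(), "T", ["H1", "H2"])
        assert np.allclose(res.per_sample["log2_rel"], 0.0)
        assert res.p == 1.0

    def test_one_cycle_shift_gives_plus_one(self):
        ct = self._flat_ct()
        mask = (ct["gene"] == "T") & (ct["group"] == "case")
        ct.loc[mask, "ct"] -= 1.0
        res = ddct_quantify(ct, "T", ["H1", "H2"])
        case = res.per_sample.loc[res.per_sample["group"] == "case", "log2_rel"]
        ctrl = res.per_sample.loc[res.per_sample["group"] == "control", "log2_rel"]
        assert np.allclose(case, 1.0)
        assert np.allclose(ctrl, 0.0)

    def test_calibrator_identity(self):
        rng = np.random.default_rng(41)
        sim = simulate.gen_ct_table({"T1": 0.7}, {"H1": 0.1, "H2": 0.2, "H3": 0.3},
                                    seed=int(rng.integers(100)))
        res = ddct_quantify(sim.ct, "T1", sim.housekeepers)
        ctrl_mean = res.per_sample.loc[res.per_sample["group"] == "control", "log2_rel"].mean()
        assert ctrl_mean == pytest.approx(0.0, abs=1e-12)

    def test_housekeeper_shift_invariance(self):
        sim = simulate.gen_ct_table({"T1": 1.0}, {"H1": 0.1, "H2": 0.2, "H3": 0.3}, seed=42)
        res1 = ddct_quantify(sim.ct, "T1", sim.housekeepers)
        shifted = sim.ct.copy()
        shifted.loc[shifted["gene"].isin(sim.housekeepers), "ct"] += 5.0
        res2 = ddct_quantify(shifted, "T1", sim.housekeepers)
        pd.testing.assert_series_equal(res1.per_sample["log2_rel"],
                                       res2.per_sample["log2_rel"])

    def test_effect_recovered_within_three_se(self):
        effect, noise, n = 1.5, 0.1, 9
        sim = simulate.gen_ct_table({"T1": effect},
                                    {"H1": 0.02, "H2": 0.02, "H3": 0.02},
                                    replicate_sd=noise, target_sd=0.02,
                                    n_per_group=n, seed=43)
        res = ddct_quantify(sim.ct, "T1", sim.housekeepers)
        est = res.summary.loc["case", "mean_log2_rel"]
        assert abs(est - effect) < 3 * (0.1 / np.sqrt(n)) + 3 * 0.02

    def test_target_in_housekeepers_rejected(self):
        with pytest.raises(ValueError, match="housekeeper"):
            ddct_quantify(self._flat_ct(), "T", ["T", "H1"])

    def test_sample_missing_gene_excluded(self):
        ct = self._flat_ct()
        ct = ct[~((ct["sample"] == "c2") & (ct["gene"] == "T"))]
        res = ddct_quantify(ct, "T", ["H1", "H2"])
        assert "c2" not in res.per_sample.index


class TestEndToEndSelection:
    def test_graded_stability_recovered_and_selection_size(self):
        """Five candidates with graded noise: both rankings prefer the quiet
        genes and the consensus picks 3 of 5, mirroring a 5-candidate qPCR
        design that keeps three references."""
        hk = {"HK1": 0.03, "HK2": 0.06, "HK3": 0.12, "HK4": 0.6, "HK5": 1.2}
        sim = simulate.gen_ct_table({"T1": 1.0}, hk, n_per_group=9, seed=44)
        wide, groups = collapse_replicates(sim.ct)
        report = rank_housekeepers(wide, sim.housekeepers, groups)
        selected = select_housekeepers(report, k=3)
        assert len(selected) == 3
        assert {"HK4", "HK5"}.isdisjoint(selected)
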