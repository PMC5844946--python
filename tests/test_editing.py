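"""Editing levels, the coverage-weighted AEI/REI, the recoding-site filters,
per-site differential editing, and the group index comparison with Tukey
box-plot summaries."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import manual_welch
from loadtx import simulate
from loadtx.editing import (
    EditingSiteTable,
    boxplot_stats,
    compare_group_indices,
    differential_editing,
    edit_difference,
    editing_index,
    editing_index_table,
    editing_level,
    filter_recoding_sites,
)


def _table(edited_rows, total_rows, site_class="recoding", groups=None, n_ctrl=2):
    n_sites = len(edited_rows)
    n_samples = len(edited_rows[0])
    sites = pd.DataFrame({
        "chrom": ["chr1"] * n_sites, "pos": range(100, 100 + n_sites),
        "strand": ["+"] * n_sites, "site_class": [site_class] * n_sites,
        "gene": [f"G{i}" for i in range(n_sites)], "aa_change": ["Q/R"] * n_sites,
    })
    sites.index = pd.Index([f"chr1:{100 + i}" for i in range(n_sites)], name="site_id")
    samples = [f"s{j}" for j in range(n_samples)]
    edited = pd.DataFrame(edited_rows, index=sites.index, columns=samples)
    total = pd.DataFrame(total_rows, index=sites.index, columns=samples)
    if groups is None:
        groups = pd.Series(["control"] * n_ctrl + ["case"] * (n_samples - n_ctrl),
                           index=samples)
    return EditingSiteTable(sites=sites, edited=edited, total=total, groups=groups)


class TestEditingLevel:
    @pytest.mark.parametrize("edited,total,expected", [(5, 10, 0.5), (0, 10, 0.0), (10, 10, 1.0)])
    def test_ratio(self, edited, total, expected):
        assert editing_level(edited, total) == expected

    def test_uncovered_site_missing(self):
        assert np.isnan(editing_level(0, 0))

    def test_edited_exceeding_total_rejected(self):
        with pytest.raises(ValueError):
            editing_level(7, 5)


class TestEditingIndex:
    def test_single_site_equals_its_level(self):
        t = _table([[3, 3, 3, 3]], [[10, 10, 10, 10]])
        idx = editing_index(t, "s0", "recoding")
        assert idx.value == pytest.approx(0.3)
        assert idx.index_class == "REI" and idx.n_sites_used == 1

    def test_pooled_ratio_on_two_sites(self):
        # (1/10 and 3/10) pool to 4/20 = 0.2, not the unweighted mean 0.2 --
        # distinguishable once coverages differ
        t = _table([[1] * 4, [3] * 4], [[10] * 4, [10] * 4])
        assert editing_index(t, "s0", "recoding").value == pytest.approx(4 / 20)

    def test_weighting_follows_coverage(self):
        t = _table([[8] * 4, [1] * 4], [[80] * 4, [10] * 4])
        weighted = editing_index(t, "s0", "recoding").value
        unweighted = editing_index(t, "s0", "recoding", weighted=False).value
        assert weighted == pytest.approx(9 / 90)
        assert unweighted == pytest.approx(0.1)

    def test_fully_edited_reaches_one(self):
        t = _table([[10] * 4, [5] * 4], [[10] * 4, [5] * 4])
        assert editing_index(t, "s0", "recoding").value == 1.0

    def test_doubling_coverage_invariant(self):
        t = _table([[2, 0, 0, 0], [7, 0, 0, 0]], [[9, 1, 1, 1], [20, 1, 1, 1]])
        t2 = EditingSiteTable(sites=t.sites, edited=t.edited * 2, total=t.total * 2,
                              groups=t.groups)
        assert editing_index(t, "s0", "recoding").value == \
            pytest.approx(editing_index(t2, "s0", "recoding").value)

    def test_index_within_contributing_level_range(self):
        rng = np.random.default_rng(7)
        total = rng.integers(1, 50, size=(6, 4))
        edited = rng.binomial(total, 0.4)
        t = _table(edited.tolist(), total.tolist())
        lv = t.levels()["s0"]
        idx = editing_index(t, "s0", "recoding").value
        assert lv.min() <= idx <= lv.max()

    def test_uncovered_class_missing(self):
        t = _table([[0, 0, 0, 0]], [[0, 10, 10, 10]])
        assert np.isnan(editing_index(t, "s0", "recoding").value)
        assert editing_index(t, "s1", "recoding").value == 0.0


class TestSiteFilters:
    def test_hand_evaluated_keep_drop_decisions(self):
        """10-site toy, 5v5 samples: coverage and median predicates evaluated
        by hand for each site."""
        n = 10
        rng = np.random.default_rng(11)
        total = np.full((n, 10), 50)
        # site 0: covered in only 2 control samples -> dropped (coverage)
        total[0, 2:5] = 0
        # site 1: covered in only 2 case samples -> dropped (coverage)
        total[1, 7:10] = 0
        edited = (total * 0.4).astype(int)
        # site 2: pooled median level 0.05 -> dropped (low median)
        edited[2] = (total[2] * 0.05).astype(int)
        # site 3: exactly at the 0.1 boundary -> dropped (strict inequality)
        edited[3] = (total[3] * 0.1).astype(int)
        t = _table(edited.tolist(), total.tolist(), n_ctrl=5)
        retained, report = filter_recoding_sites(t, min_samples_per_group=3, min_median=0.1)
        dropped = {f"chr1:{100 + i}" for i in (0, 1, 2, 3)}
        assert set(retained) == set(t.sites.index) - dropped
        assert report.loc["chr1:100", "exclusion_reason"] == "coverage"
        assert report.loc["chr1:102", "exclusion_reason"] == "low_median"

    def test_well_covered_high_level_site_retained(self):
        t = _table([[20] * 10], [[50] * 10], n_ctrl=5)
        retained, _ = filter_recoding_sites(t)
        assert retained == ["chr1:100"]


class TestEditDifference:
    @pytest.mark.parametrize("ctrl,case,expected", [
        (0.972, 0.918, 0.054),   # GRIA2-type Q/R magnitude
        (0.524, 0.290, 0.234),
        (0.3, 0.3, 0.0),
    ])
    def test_control_minus_case(self, ctrl, case, expected):
        assert edit_difference(ctrl, case) == pytest.approx(expected)

    @given(st.floats(0, 1), st.floats(0, 1))
    @settings(max_examples=50, deadline=None)
    def test_antisymmetry(self, a, b):
        assert edit_difference(a, b) == -edit_difference(b, a)


class TestDifferentialEditing:
    def test_identical_levels_give_null_result(self):
        t = _table([[20] * 10], [[50] * 10], n_ctrl=5)
        res = differential_editing(t)
        assert res["edit_difference"].iloc[0] == 0.0
        assert res["p"].iloc[0] == 1.0
        assert not res["significant"].iloc[0]

    def test_matches_manual_welch_on_3v3_site(self):
        edited = [[10, 20, 30, 5, 10, 15]]
        total = [[100] * 6]
        t = _table(edited, total, n_ctrl=3)
        res = differential_editing(t, apply_filter=False)
        ctrl_levels = [0.10, 0.20, 0.30]
        case_levels = [0.05, 0.10, 0.15]
        assert res["p"].iloc[0] == pytest.approx(manual_welch(case_levels, ctrl_levels), rel=1e-12)
        assert res["edit_difference"].iloc[0] == pytest.approx(0.2 - 0.1)

    def test_significance_inclusive_at_fdr(self):
        rng = np.random.default_rng(5)
        sites = simulate.default_recoding_sites(6, seed=5)
        levels = pd.DataFrame({"control": [0.7] * 6, "case": [0.3] * 6}, index=sites.index)
        sim = simulate.gen_editing_pileups(sites, levels, concentration=500.0,
                                           coverage=800.0, n_per_group=6, seed=6)
        res = differential_editing(sim.table, fdr=0.1)
        assert res["significant"].all()
        assert (res["padj"] <= 0.1).all()

    def test_recovers_generator_truth_difference(self):
        """GRIK1-like group means (0.601 vs 0.393): the recovered difference
        sits within 0.05 of the generating 0.208 at high precision."""
        sites = simulate.default_recoding_sites(1, seed=7)
        levels = pd.DataFrame({"control": [0.601], "case": [0.393]}, index=sites.index)
        sim = simulate.gen_editing_pileups(sites, levels, concentration=1000.0,
                                           coverage=2000.0, n_per_group=5, seed=8)
        res = differential_editing(sim.table)
        assert res["edit_difference"].iloc[0] == pytest.approx(0.208, abs=0.05)


class TestGroupIndexComparison:
    def test_identical_groups_null(self):
        idx = pd.DataFrame({"REI": [0.4, 0.4, 0.4, 0.4]},
                           index=["c1", "c2", "a1", "a2"])
        groups = pd.Series(["control", "control", "case", "case"], index=idx.index)
        res = compare_group_indices(idx, groups)
        assert res.loc["REI", "p"] == 1.0
        assert res.loc["REI", "difference_ctrl_minus_case"] == 0.0

    def test_rei_decrease_detected(self):
        """Simulated recoding editing at 0.5 (control) vs 0.3 (case) with
        tight dispersion yields a significant REI drop at the 5% level."""
        sites = simulate.default_recoding_sites(8, seed=9)
        levels = pd.DataFrame({"control": [0.5] * 8, "case": [0.3] * 8}, index=sites.index)
        sim = simulate.gen_editing_pileups(sites, levels, concentration=800.0,
                                           coverage=500.0, n_per_group=5, seed=10)
        idx = editing_index_table(sim.table)
        res = compare_group_indices(idx, sim.table.groups)
        assert res.loc["REI", "p"] < 0.05
        assert res.loc["REI", "difference_ctrl_minus_case"] > 0

    def test_whisker_formula_and_outliers(self):
        stats = boxplot_stats(list(range(1, 10)) + [100])
        q1, q3 = np.percentile(list(range(1, 10)) + [100], [25, 75])
        iqr = q3 - q1
        assert stats["upper_whisker"] == pytest.approx(q3 + 1.5 * iqr)
        assert stats["lower_whisker"] == pytest.approx(q1 - 1.5 * iqr)
        assert stats["outliers"] == [100.0]
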