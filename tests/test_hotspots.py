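"""Hotspot delineation, inclusion rules, association tests and Venn counts."""

import numpy as np
from hypothesis import given, settings
from hypothesis import strategies as st
import pandas as pd
import pytest
from scipy import stats
from shapely.geometry import box

from katydid_hotspots import gridding, hotspots as hs


class TestTopPercentile:
    def test_top_cell_selected_from_ten(self):
        v = pd.Series(np.arange(1, 11), index=[f"c{i}" for i in range(10)])
        assert hs.top_percentile_cells(v, 0.10) == {"c9"}

    def test_ties_at_the_threshold_are_included(self):
        v = pd.Series([5, 5, 5, 1, 1, 1, 1, 1, 1, 1], index=[f"c{i}" for i in range(10)])
        assert hs.top_percentile_cells(v, 0.10) == {"c0", "c1", "c2"}

    def test_selected_count_at_least_ceiling(self, rng):
        v = pd.Series(rng.normal(size=122), index=[f"c{i}" for i in range(122)])
        sel = hs.top_percentile_cells(v, 0.10)
        assert len(sel) == int(np.ceil(0.10 * 122)) == 13  # no ties in continuous draws
        # oracle: the 13 largest values
        assert sel == set(v.sort_values(ascending=False).index[:13])

    def test_degenerate_equal_values_warn_and_return_all(self):
        v = pd.Series([2.0] * 8, index=[f"c{i}" for i in range(8)])
        with pytest.warns(UserWarning):
            assert hs.top_percentile_cells(v) == set(v.index)

    def test_invariant_under_monotone_transform_and_relabeling(self, rng):
        v = pd.Series(rng.normal(size=60), index=[f"c{i}" for i in range(60)])
        a = hs.top_percentile_cells(v)
        b = hs.top_percentile_cells(np.exp(v))
        assert a == b

    @given(st.lists(st.integers(0, 30), min_size=2, max_size=80).filter(
        lambda xs: len(set(xs)) > 1))
    @settings(derandomize=True, max_examples=100)
    def test_selection_respects_threshold_order(self, values):
        v = pd.Series(values, index=[f"c{i}" for i in range(len(values))],
                      dtype=float)
        sel = hs.top_percentile_cells(v, 0.10)
        cut = v[list(sel)].min()
        # every non-selected cell is strictly below every selected one
        assert (v.drop(list(sel)) < cut).all()
        assert len(sel) >= int(np.ceil(0.10 * len(v)))


class TestDelineation:
    def test_union_rule_for_count_based(self, fixture_dataset, sim_metrics):
        metrics = sim_metrics["metrics"]
        union = hs.count_based_hotspots(metrics)
        per_measure = [
            hs.top_percentile_cells(metrics.set_index("cell_id")[m])
            for m in hs.COUNT_MEASURES
        ]
        assert union == set().union(*per_measure)
        # a cell top-decile in a single measure is included
        only_one = per_measure[2] - set().union(per_measure[0], per_measure[1], per_measure[3])
        for cid in only_one:
            assert cid in union

    def test_score_based_is_top_decile_of_mean_score(self, sim_metrics):
        metrics = sim_metrics["metrics"]
        assert hs.score_based_hotspots(metrics) == hs.top_percentile_cells(
            metrics.set_index("cell_id")["mean_T+D+LH"]
        )


class TestPolygonInclusion:
    @pytest.fixture()
    def net(self):
        return gridding.build_fishnet(box(0, 0, 3, 1))

    def test_cell_fully_inside_true_under_every_rule(self, net):
        polys = [box(-0.5, -0.5, 1.5, 1.5)]
        fr = hs.inclusion_fractions(net, polys)
        for rule in hs.INCLUSION_RULES:
            assert hs.polygon_inclusion(net, polys, rule, fractions=fr)["A1"]

    def test_strict_rule_excludes_exact_half(self, net):
        polys = [box(0, 0, 1.5, 1)]  # second cell exactly half covered
        fr = hs.inclusion_fractions(net, polys)
        assert fr["A2"] == pytest.approx(0.5, abs=1e-6)
        flags = hs.polygon_inclusion(net, polys, 0.50, fractions=fr)
        assert flags["A1"] and not flags["A2"]

    def test_rules_are_nested(self, net):
        polys = [box(0.3, 0, 2.4, 1)]
        fr = hs.inclusion_fractions(net, polys)
        sets = [
            set(hs.polygon_inclusion(net, polys, r, fractions=fr).pipe(lambda s: s[s].index))
            for r in hs.INCLUSION_RULES
        ]
        assert sets[3] <= sets[2] <= sets[1] <= sets[0]


class TestChi2:
    def _flags(self, a, b):
        idx = [f"c{i}" for i in range(len(a))]
        return pd.Series(a, index=idx, dtype=bool), pd.Series(b, index=idx, dtype=bool)

    def test_exact_independence_gives_zero(self):
        a = [True] * 20 + [False] * 20
        b = ([True] * 10 + [False] * 10) * 2
        fa, fb = self._flags(a, b)
        chi2, df, p, table = hs.chi2_association(fa, fb)
        assert chi2 == 0.0 and p == 1.0 and df == 1

    def test_uncorrected_matches_closed_form(self):
        # table [[10, 20], [30, 40]]
        a = [False] * 30 + [True] * 70
        b = ([False] * 10 + [True] * 20) + ([False] * 30 + [True] * 40)
        fa, fb = self._flags(a, b)
        chi2, _, _, table = hs.chi2_association(fa, fb, continuity_correction=False)
        n, (aa, bb), (cc, dd) = 100, (10, 20), (30, 40)
        closed = n * (aa * dd - bb * cc) ** 2 / ((aa + bb) * (cc + dd) * (aa + cc) * (bb + dd))
        assert chi2 == pytest.approx(closed, rel=1e-12)
        assert chi2 == pytest.approx(0.7937, abs=5e-5)

    def test_correction_shrinks_the_statistic_and_is_symmetric(self):
        a = [True] * 25 + [False] * 35
        b = [True] * 15 + [False] * 20 + [True] * 10 + [False] * 15
        fa, fb = self._flags(a, b)
        raw = hs.chi2_association(fa, fb, continuity_correction=False)[0]
        corr = hs.chi2_association(fa, fb, continuity_correction=True)[0]
        assert corr <= raw
        assert hs.chi2_association(fb, fa)[0] == pytest.approx(
            hs.chi2_association(fa, fb)[0]
        )

    def test_degenerate_marginal_rejected(self):
        fa, fb = self._flags([True] * 10, [True] * 5 + [False] * 5)
        with pytest.raises(ValueError, match="degenerate"):
            hs.chi2_association(fa, fb)


class TestVenn:
    def test_empty_and_triple_cases(self):
        idx = ["a", "b", "c"]
        off = pd.Series(False, index=idx)
        assert hs.venn_counts(off, off, off)["total_flagged"] == 0
        one = pd.Series([True, False, False], index=idx)
        v = hs.venn_counts(one, one, one)
        assert v["all_three"] == 1 and v["total_flagged"] == 1
        assert sum(v[k] for k in v if k != "total_flagged") == 1

    def test_matches_brute_force_set_algebra(self, rng):
        idx = [f"c{i}" for i in range(200)]
        f = {k: pd.Series(rng.uniform(size=200) < 0.3, index=idx) for k in "csb"}
        v = hs.venn_counts(f["c"], f["s"], f["b"])
        c, s, b = (set(np.array(idx)[f[k].to_numpy()]) for k in "csb")
        assert v["count_only"] == len(c - s - b)
        assert v["all_three"] == len(c & s & b)
        assert v["score_biodiversity"] == len((s & b) - c)
        assert v["total_flagged"] == len(c | s | b)
        assert sum(v[k] for k in v if k != "total_flagged") == v["total_flagged"]


class TestRuleSensitivity:
    def test_identical_classifications_give_zero_h(self, sim_dataset, sim_metrics):
        # a cell-aligned polygon: every cell is fully in or fully out, so all
        # four rules produce the same classification and identical differences
        aligned = box(17, -35, 22, -27)
        table, kw = hs.inclusion_rule_sensitivity(
            sim_metrics["metrics"], sim_metrics["grid"], [aligned]
        )
        assert kw["H"] == pytest.approx(0.0, abs=1e-12)

    def test_differences_match_independent_recomputation(self, sim_dataset, sim_metrics):
        ds = sim_dataset
        metrics, grid = sim_metrics["metrics"], sim_metrics["grid"]
        table, kw = hs.inclusion_rule_sensitivity(metrics, grid, ds.hotspot_polygons)
        m = metrics[metrics["has_data"]].set_index("cell_id")
        fr = hs.inclusion_fractions(grid, ds.hotspot_polygons)
        probe = table[(table["rule"] == 0.5) & (table["measure"] == "richness_total")]
        flags = (fr > 0.5).reindex(m.index)
        expected = m.loc[flags, "richness_total"].median() - m.loc[~flags, "richness_total"].median()
        assert probe["median_difference"].iloc[0] == pytest.approx(expected)


class TestHotspotVsNon:
    def test_known_u_statistics(self):
        metrics = pd.DataFrame(
            {
                "cell_id": [f"c{i}" for i in range(6)],
                "has_data": True,
                "richness_total": [1, 2, 3, 4, 5, 6],
            }
        )
        flags = pd.Series([False, False, False, True, True, True],
                          index=[f"c{i}" for i in range(6)])
        rep = hs.compare_hotspot_vs_non(metrics, flags, measures=("richness_total",))
        # complete separation: U for the smaller group is n1*n2 (hotspot higher)
        assert rep["U"].iloc[0] in (0.0, 9.0)
        assert rep["median_hotspot"].iloc[0] == 5

    def test_power_at_one_sd_shift(self, rng):
        reject = 0
        for _ in range(500):
            a = rng.normal(0, 1, 50)
            b = rng.normal(1, 1, 50)
            _, p = stats.mannwhitneyu(a, b, alternative="two-sided")
            reject += p < 0.05
        assert reject / 500 >= 0.8

    def test_empty_group_rejected(self, sim_metrics):
        metrics = sim_metrics["metrics"]
        flags = pd.Series(True, index=metrics["cell_id"])
        with pytest.raises(ValueError):
            hs.compare_hotspot_vs_non(metrics, flags)
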