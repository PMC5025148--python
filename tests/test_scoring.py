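"""The trait-scoring chart: element scores, composites and status comparisons."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from katydid_hotspots import scoring
from katydid_hotspots.scoring import (
    ScoringError,
    SpeciesTraits,
    compare_traits_across_status,
    composite_scores,
    score_distribution,
    score_life_history,
    score_threat,
)


def make_traits(**kw):
    base = dict(
        species_id="sp",
        subfamily="SF",
        genus="G",
        species="x",
        status="LC",
        frac_SA=0.9,
        frac_sA=0.9,
        n_provinces=5,
        endemic_to_SA=False,
        marginal_in_SA=False,
        mobility_class="fully_flighted",
        trophic_class="omnivorous",
    )
    base.update(kw)
    return SpeciesTraits(**base)


@pytest.mark.parametrize("status,expected", [("LC", 0), ("VU", 1), ("EN", 2), ("CR", 3)])
def test_threat_score_ascends_with_red_list_category(status, expected):
    assert score_threat(status) == expected


@pytest.mark.parametrize("status", ["DD", "NE"])
def test_data_deficient_species_are_excluded_from_scoring(status):
    with pytest.raises(ScoringError, match="excluded"):
        score_threat(status)


@pytest.mark.parametrize(
    "kw,expected",
    [
        # provincial endemics score highest
        (dict(endemic_to_SA=True, n_provinces=2, frac_SA=0.2, frac_sA=0.2), 3),
        (dict(endemic_to_SA=True, n_provinces=1, frac_SA=0.1, frac_sA=0.1), 3),
        # national endemics over a wide area
        (dict(endemic_to_SA=True, n_provinces=4, frac_SA=0.5, frac_sA=0.5), 2),
        # widespread in southern Africa but marginal nationally
        (dict(marginal_in_SA=True, frac_SA=0.1, frac_sA=0.8, n_provinces=1), 2),
        # localized across a wide area
        (dict(frac_SA=0.7, frac_sA=0.7), 1),
        # very common in a few provinces, non-marginal
        (dict(frac_SA=0.1, frac_sA=0.8, n_provinces=3), 1),
        # very common everywhere
        (dict(frac_SA=0.9, frac_sA=0.9), 0),
        (dict(frac_SA=0.76, frac_sA=0.76), 0),
    ],
)
def test_distribution_decision_list(kw, expected):
    assert score_distribution(make_traits(**kw)) == expected


def test_distribution_rejects_unmatched_inputs_with_diagnostics():
    # sparse range, many provinces, not endemic: no rule fires
    t = make_traits(frac_SA=0.1, frac_sA=0.1, n_provinces=5)
    with pytest.raises(ScoringError, match="no distribution rule"):
        score_distribution(t)


def test_life_history_mapping_is_total_and_surjective():
    images = set()
    for m, tr in itertools.product(range(3), range(4)):
        lh = score_life_history(m, tr)
        expected = {0: 0, 1: 1, 2: 1, 3: 2, 4: 3, 5: 3}[m + tr]
        assert lh == expected
        images.add(lh)
    assert images == {0, 1, 2, 3}


@pytest.mark.parametrize("m,tr", [(-1, 0), (3, 0), (0, 4)])
def test_life_history_rejects_out_of_range(m, tr):
    with pytest.raises(ScoringError):
        score_life_history(m, tr)


def test_composites_are_sums_of_their_named_parts():
    s = scoring.SpeciesScore("x", T=1, D=2, M=2, Tr=2, LH=3)
    c = composite_scores(s)
    assert c == {"T+D": 3, "T+LH": 4, "D+LH": 5, "T+D+M": 5, "T+D+Tr": 5, "T+D+LH": 6}
    zero = scoring.SpeciesScore("z", T=0, D=0, M=0, Tr=0, LH=0)
    assert all(v == 0 for v in composite_scores(zero).values())


def test_maximum_composite_is_nine_by_exhaustive_enumeration():
    best = -1
    worst = 99
    for t, d, m, tr in itertools.product(range(4), range(4), range(3), range(4)):
        lh = score_life_history(m, tr)
        total = t + d + lh
        best = max(best, total)
        worst = min(worst, total)
    assert best == 9
    assert worst == 0


def test_score_table_drops_dd_and_emits_all_columns(fixture_dataset):
    table = scoring.score_table(fixture_dataset["traits"])
    assert list(table["species_id"]) == ["s1", "s2", "s3", "s4", "s5"]  # s6 is DD
    assert list(table.columns) == [
        "species_id", "T", "D", "M", "Tr", "LH", *scoring.COMPOSITE_NAMES
    ]
    assert table.set_index("species_id").loc["s1", "T+D+LH"] == 9


from hypothesis import given, settings
from hypothesis import strategies as st


@settings(derandomize=True, max_examples=200)
@given(
    frac_sa=st.floats(0, 1),
    frac_sA=st.floats(0, 1),
    n_prov=st.integers(0, 9),
    endemic=st.booleans(),
    marginal=st.booleans(),
)
def test_distribution_score_is_deterministic_and_in_range(
    frac_sa, frac_sA, n_prov, endemic, marginal
):
    """Any input either maps to a stable score in 0-3 or raises the
    diagnostic rejection; never anything else."""
    t = make_traits(
        frac_SA=frac_sa, frac_sA=frac_sA, n_provinces=n_prov,
        endemic_to_SA=endemic, marginal_in_SA=marginal,
    )
    try:
        first = score_distribution(t)
    except ScoringError:
        with pytest.raises(ScoringError):
            score_distribution(t)
        return
    assert first in (0, 1, 2, 3)
    assert score_distribution(t) == first


class TestTraitComparison:
    def _frame(self, groups):
        rows = []
        for status, values in groups.items():
            for i, v in enumerate(values):
                rows.append({"species_id": f"{status}{i}", "D": v, "M": v, "Tr": v, "LH": v})
        scores = pd.DataFrame(rows)
        statuses = {r["species_id"]: r["species_id"][:2] for r in rows}
        return scores, statuses

    def test_identical_groups_give_zero_h_and_unit_pvalues(self):
        scores, statuses = self._frame({"LC": [2, 2, 2], "VU": [2, 2, 2], "EN": [2, 2]})
        rep = compare_traits_across_status(scores, statuses)
        assert rep["D"]["H"] == 0.0
        assert np.all(rep["D"]["nemenyi_p"].to_numpy() >= 0.999)

    def test_h_matches_rank_formula_oracle(self):
        groups = {"LC": [1, 2, 3], "VU": [10, 11, 12], "EN": [20, 21, 22]}
        scores, statuses = self._frame(groups)
        rep = compare_traits_across_status(scores, statuses)
        # brute-force tie-corrected H
        pooled = np.concatenate(list(groups.values()))
        ranks = stats.rankdata(pooled)
        n = len(pooled)
        idx = 0
        h = 0.0
        for vals in groups.values():
            r = ranks[idx : idx + len(vals)]
            idx += len(vals)
            h += r.sum() ** 2 / len(vals)
        h = 12.0 / (n * (n + 1)) * h - 3 * (n + 1)
        assert rep["D"]["H"] == pytest.approx(h, abs=1e-12)

    def test_h_invariant_under_monotone_transform(self):
        groups = {"LC": [1, 5, 2, 8], "VU": [3, 9, 7], "EN": [4, 6, 10, 11]}
        scores, statuses = self._frame(groups)
        h1 = compare_traits_across_status(scores, statuses)["D"]["H"]
        transformed = {k: list(np.exp(np.asarray(v, float))) for k, v in groups.items()}
        scores2, statuses2 = self._frame(transformed)
        h2 = compare_traits_across_status(scores2, statuses2)["D"]["H"]
        assert h1 == pytest.approx(h2, rel=1e-12)

    def test_planted_low_scoring_group_is_flagged(self, rng):
        # LC species drawn with lower D than threatened species
        lc = rng.integers(0, 2, size=40)
        threatened = rng.integers(2, 4, size=30)
        rows = [{"species_id": f"lc{i}", "D": v, "M": 0, "Tr": 0, "LH": 0} for i, v in enumerate(lc)]
        rows += [
            {"species_id": f"cr{i}", "D": v, "M": 0, "Tr": 0, "LH": 0}
            for i, v in enumerate(threatened)
        ]
        scores = pd.DataFrame(rows)
        statuses = {r["species_id"]: ("LC" if r["species_id"].startswith("lc") else "CR")
                    for r in rows}
        rep = compare_traits_across_status(scores, statuses)
        assert rep["D"]["p"] < 0.001
        assert rep["D"]["nemenyi_p"].loc["LC", "CR"] < 0.05
        # significantly different groups share no letter
        letters = rep["D"]["letters"]
        assert not set(letters["LC"]) & set(letters["CR"])

    def test_single_member_category_is_excluded_with_warning(self):
        scores, statuses = self._frame({"LC": [1, 2, 3], "VU": [4, 5, 6]})
        scores.loc[len(scores)] = {"species_id": "CRx", "D": 9, "M": 9, "Tr": 9, "LH": 9}
        statuses["CRx"] = "CR"
        rep = compare_traits_across_status(scores, statuses)
        assert rep["excluded_categories"] == ["CR"]
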