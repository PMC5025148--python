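"""Composite biotic-index scoring of katydid species.

Each species is scored on four elements: Red List threat status (T, 0-3),
distribution (D, 0-3, narrower range scores higher), mobility (M, 0-2,
flightless scores highest) and trophic specialisation (Tr, 0-3, monophagous
herbivores score highest).  A life-history score LH (0-3) is derived from
M + Tr, and named combinations of the elements are summed into composite
scores, the fullest of which, T+D+LH, ranges 0-9: the higher, the more
threatened, narrowly distributed and specialised the species.

Data Deficient (DD) and Not Evaluated (NE) species never reach scoring; they
are excluded upstream and rejected here.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "COMPOSITE_NAMES",
    "ScoringError",
    "SpeciesTraits",
    "SpeciesScore",
    "score_threat",
    "score_distribution",
    "score_mobility",
    "score_trophic",
    "score_life_history",
    "composite_scores",
    "score_species",
    "score_table",
    "compare_traits_across_status",
]

COMPOSITE_NAMES = ("T+D", "T+LH", "D+LH", "T+D+M", "T+D+Tr", "T+D+LH")

THREAT_SCORES = {"LC": 0, "VU": 1, "EN": 2, "CR": 3}
MOBILITY_SCORES = {"fully_flighted": 0, "partial_or_one_sex": 1, "flightless": 2}
TROPHIC_SCORES = {
    "omnivorous": 0,
    "predatory": 1,
    "herbivorous_polyphagous": 2,
    "herbivorous_monophagous": 3,
}
#: LH score as a function of M + Tr
LH_FROM_SUM = {0: 0, 1: 1, 2: 1, 3: 2, 4: 3, 5: 3}


class ScoringError(ValueError):
    """Raised when a species cannot be scored (DD/NE status, no matching rule...)."""


@dataclass
class SpeciesTraits:
    """Raw per-species inputs to the scoring chart.

    ``frac_SA`` / ``frac_sA`` are the fractions of the species' range covered
    by South Africa(+Lesotho+Swaziland) and by southern Africa respectively.
    """

    species_id: str
    subfamily: str
    genus: str
    species: str
    status: str
    frac_SA: float
    frac_sA: float
    n_provinces: int
    endemic_to_SA: bool
    marginal_in_SA: bool
    mobility_class: str
    trophic_class: str
    tribe: str = ""
    subgenus: str = ""

    def __post_init__(self):
        if not (0.0 <= self.frac_SA <= 1.0 and 0.0 <= self.frac_sA <= 1.0):
            raise ScoringError(
                f"{self.species_id}: range fractions must lie in [0, 1], "
                f"got frac_SA={self.frac_SA}, frac_sA={self.frac_sA}"
            )
        if self.n_provinces < 0:
            raise ScoringError(f"{self.species_id}: n_provinces must be >= 0")


@dataclass
class SpeciesScore:
    species_id: str
    T: int
    D: int
    M: int
    Tr: int
    LH: int
    composites: dict = field(default_factory=dict)

    def __post_init__(self):
        if not self.composites:
            self.composites = composite_scores(self)


def score_threat(status: str) -> int:
    """Map a Red List status to the threat score T (LC=0 ... CR=3).

    DD and NE species are excluded from scoring and raise ``ScoringError``.
    """
    if status in ("DD", "NE"):
        raise ScoringError(f"status {status}: excluded from scoring")
    try:
        return THREAT_SCORES[status]
    except KeyError:
        raise ScoringError(f"unknown Red List status {status!r}") from None


def score_distribution(traits: SpeciesTraits) -> int:
    """Distribution score D from the chart's range-size rules.

    An explicit decision list over (frac_SA, frac_sA, n_provinces,
    endemic_to_SA, marginal_in_SA); the most specific rules are evaluated
    first and the first match wins.  All percentage thresholds are strict, as
    printed on the chart.  The numerically overlapping "widespread in sA but
    marginal in SA" clause is disambiguated by the ``marginal_in_SA`` flag.
    """
    f_sa, f_sA = traits.frac_SA, traits.frac_sA
    evaluations = []

    # 3: endemic/near-endemic, confined to 1-2 provinces
    rule3 = traits.endemic_to_SA and traits.n_provinces <= 2
    evaluations.append(("3: endemic and <=2 provinces", rule3))
    if rule3:
        return 3
    # 2: national endemic over >1/3 of SA, or widespread in sA but marginal in SA
    rule2 = (traits.endemic_to_SA and f_sa > 1 / 3) or (
        traits.marginal_in_SA and f_sa < 1 / 3 and f_sA > 2 / 3
    )
    evaluations.append(("2: endemic >33% SA, or marginal in SA & >66% sA", rule2))
    if rule2:
        return 2
    # 0 outranks the numerically overlapping ">66% both" clause of score 1:
    # "very common" (>75% of SA and sA) is the more specific condition.
    rule0 = f_sa > 3 / 4 and f_sA > 3 / 4
    evaluations.append(("0: very common, >75% SA and sA", rule0))
    if rule0:
        return 0
    # 1: localized over a wide area, or very common in only 1-3 provinces
    rule1 = (f_sa > 2 / 3 and f_sA > 2 / 3) or (
        not traits.marginal_in_SA and f_sa <= 1 / 3 and f_sA > 2 / 3 and traits.n_provinces <= 3
    )
    evaluations.append(("1: >66% both, or common in 1-3 provinces & >66% sA", rule1))
    if rule1:
        return 1
    lines = "; ".join(f"[{name} -> {hit}]" for name, hit in evaluations)
    raise ScoringError(
        f"{traits.species_id}: no distribution rule matches "
        f"(frac_SA={f_sa}, frac_sA={f_sA}, n_provinces={traits.n_provinces}, "
        f"endemic={traits.endemic_to_SA}, marginal={traits.marginal_in_SA}): {lines}"
    )


def score_mobility(mobility_class: str) -> int:
    try:
        return MOBILITY_SCORES[mobility_class]
    except KeyError:
        raise ScoringError(f"unknown mobility class {mobility_class!r}") from None


def score_trophic(trophic_class: str) -> int:
    try:
        return TROPHIC_SCORES[trophic_class]
    except KeyError:
        raise ScoringError(f"unknown trophic class {trophic_class!r}") from None


def score_life_history(M: int, Tr: int) -> int:
    """LH score: the chart image of M + Tr (0->0, 1-2->1, 3->2, 4-5->3)."""
    if not (0 <= M <= 2) or not (0 <= Tr <= 3):
        raise ScoringError(f"M={M} or Tr={Tr} out of range (M 0-2, Tr 0-3)")
    return LH_FROM_SUM[M + Tr]


def composite_scores(score: "SpeciesScore") -> dict:
    """The six named composite sums of the scoring elements."""
    T, D, M, Tr, LH = score.T, score.D, score.M, score.Tr, score.LH
    return {
        "T+D": T + D,
        "T+LH": T + LH,
        "D+LH": D + LH,
        "T+D+M": T + D + M,
        "T+D+Tr": T + D + Tr,
        "T+D+LH": T + D + LH,
    }


def score_species(traits: SpeciesTraits) -> SpeciesScore:
    """Score one species on all elements; raises ``ScoringError`` for DD/NE."""
    T = score_threat(traits.status)
    D = score_distribution(traits)
    M = score_mobility(traits.mobility_class)
    Tr = score_trophic(traits.trophic_class)
    LH = score_life_history(M, Tr)
    return SpeciesScore(species_id=traits.species_id, T=T, D=D, M=M, Tr=Tr, LH=LH)


def score_table(traits_df: pd.DataFrame) -> pd.DataFrame:
    """Score every scorable species in a trait table.

    DD/NE rows are dropped (they are excluded from all analyses); the output
    has one row per scored species with columns species_id, T, D, M, Tr, LH
    and the six composites.
    """
    rows = []
    for rec in traits_df.to_dict("records"):
        if rec["status"] in ("DD", "NE"):
            continue
        traits = SpeciesTraits(
            species_id=rec["species_id"],
            subfamily=rec.get("subfamily", ""),
            tribe=rec.get("tribe", "") or "",
            genus=rec.get("genus", ""),
            subgenus=rec.get("subgenus", "") or "",
            species=rec.get("species", ""),
            status=rec["status"],
            frac_SA=float(rec["frac_SA"]),
            frac_sA=float(rec["frac_sA"]),
            n_provinces=int(rec["n_provinces"]),
            endemic_to_SA=_as_bool(rec["endemic_to_SA"]),
            marginal_in_SA=_as_bool(rec["marginal_in_SA"]),
            mobility_class=rec["mobility_class"],
            trophic_class=rec["trophic_class"],
        )
        s = score_species(traits)
        row = {"species_id": s.species_id, "T": s.T, "D": s.D, "M": s.M, "Tr": s.Tr, "LH": s.LH}
        row.update(s.composites)
        rows.append(row)
    cols = ["species_id", "T", "D", "M", "Tr", "LH", *COMPOSITE_NAMES]
    return pd.DataFrame(rows, columns=cols)


def _as_bool(v) -> bool:
    if isinstance(v, str):
        return v.strip().lower() in ("true", "1", "yes", "t")
    return bool(v)


# ---------------------------------------------------------------------------
# trait comparison across threat categories
# ---------------------------------------------------------------------------


def _tie_correction(values: np.ndarray) -> float:
    n = len(values)
    _, counts = np.unique(values, return_counts=True)
    return 1.0 - (counts**3 - counts).sum() / (n**3 - n)


def nemenyi_posthoc(groups: dict) -> pd.DataFrame:
    """Pairwise Nemenyi test (chi-square approximation, tie-corrected).

    Suitable for unequal group sizes after a Kruskal-Wallis global test.
    Returns a symmetric DataFrame of p-values.
    """
    labels = list(groups)
    pooled = np.concatenate([np.asarray(groups[g], dtype=float) for g in labels])
    sizes = {g: len(groups[g]) for g in labels}
    n = len(pooled)
    ranks = stats.rankdata(pooled)
    mean_ranks, i = {}, 0
    for g in labels:
        mean_ranks[g] = ranks[i : i + sizes[g]].mean()
        i += sizes[g]
    corr = _tie_correction(pooled)
    k = len(labels)
    pmat = pd.DataFrame(np.ones((k, k)), index=labels, columns=labels)
    for a, b in combinations(labels, 2):
        if corr <= 0:  # every observation identical
            p = 1.0
        else:
            diff = mean_ranks[a] - mean_ranks[b]
            var = n * (n + 1) / 12.0 * (1.0 / sizes[a] + 1.0 / sizes[b])
            p = float(stats.chi2.sf(diff**2 / var / corr, k - 1))
        pmat.loc[a, b] = pmat.loc[b, a] = p
    return pmat


def compact_letter_display(labels, different) -> dict:
    """Assign letters so groups sharing a letter are not significantly different.

    ``different[(a, b)]`` is True when a and b differ significantly.
    Insert-and-absorb algorithm.
    """
    letters = [set(labels)]
    for a, b in combinations(labels, 2):
        if not different.get((a, b), different.get((b, a), False)):
            continue
        for s in list(letters):
            if a in s and b in s:
                letters.remove(s)
                letters.extend([s - {a}, s - {b}])
        # absorb subsets
        letters = [s for s in letters if not any(s < t for t in letters)]
    letters.sort(key=lambda s: min(labels.index(g) for g in s) if s else len(labels))
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    out = {g: "" for g in labels}
    for i, s in enumerate(letters):
        for g in s:
            out[g] += alphabet[i]
    return {g: "".join(sorted(v)) for g, v in out.items()}


def compare_traits_across_status(
    scores: pd.DataFrame,
    statuses: pd.Series | dict,
    traits=("D", "M", "Tr", "LH"),
    alpha: float = 0.05,
) -> dict:
    """Kruskal-Wallis + Nemenyi comparison of score elements across threat categories.

    Categories with fewer than 2 members are excluded (with a warning entry in
    the report).  Returns a dict per trait with the tie-corrected H, df, p,
    the pairwise Nemenyi p-value matrix and a letter display at ``alpha``.
    """
    status_of = dict(statuses) if not isinstance(statuses, dict) else statuses
    df = scores.copy()
    df["status"] = df["species_id"].map(status_of)
    counts = df["status"].value_counts()
    keep = [s for s in counts.index if counts[s] >= 2]
    excluded = [s for s in counts.index if counts[s] < 2]
    if len(keep) < 2:
        raise ValueError("need at least two threat categories with >= 2 members")
    df = df[df["status"].isin(keep)]
    report = {"excluded_categories": excluded}
    for trait in traits:
        groups = {s: df.loc[df["status"] == s, trait].to_numpy(float) for s in keep}
        pooled = np.concatenate(list(groups.values()))
        if np.ptp(pooled) == 0.0:
            H, p = 0.0, 1.0
        else:
            H, p = stats.kruskal(*groups.values())
        pmat = nemenyi_posthoc(groups)
        different = {
            (a, b): bool(pmat.loc[a, b] < alpha) for a, b in combinations(keep, 2)
        }
        report[trait] = {
            "H": float(H),
            "df": len(keep) - 1,
            "p": float(p),
            "nemenyi_p": pmat,
            "letters": compact_letter_display(list(keep), different),
            "group_medians": {s: float(np.median(groups[s])) for s in keep},
        }
    return report
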