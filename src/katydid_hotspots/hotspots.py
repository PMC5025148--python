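"""Hotspot delineation, polygon inclusion rules and association tests.

Count-based katydid hotspots are cells in the top decile of total, threatened,
endemic and/or sensitive species richness (union); score-based hotspots are
cells in the top decile of mean T+D+LH.  Cells are classified against
externally supplied biodiversity-hotspot polygons by the fraction of their
land area inside the polygons (inclusion rules > 25 / 50 / 75 / 100 %), and
the three kinds of hotspot are cross-tabulated with chi-squared tests.  All
percentile and association denominators are cells *with data* only.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from shapely.ops import unary_union

from .geometry import polygon_area_km2
from .gridding import Fishnet

__all__ = [
    "top_percentile_cells",
    "count_based_hotspots",
    "score_based_hotspots",
    "polygon_inclusion",
    "chi2_association",
    "venn_counts",
    "inclusion_rule_sensitivity",
    "compare_hotspot_vs_non",
]

COUNT_MEASURES = (
    "richness_total",
    "richness_threatened",
    "richness_endemic",
    "richness_sensitive",
)
SCORE_MEASURE = "mean_T+D+LH"
INCLUSION_RULES = (0.25, 0.50, 0.75, 1.00)


def top_percentile_cells(values: pd.Series, top_fraction: float = 0.10) -> set:
    """Cells whose value reaches the top ``top_fraction`` of cells with data.

    The threshold is the k-th largest value with k = ceil(top_fraction * n);
    all ties at the threshold are included, so the selected set has at least k
    members and exactly k when the threshold value is unique.
    """
    if not 0.0 < top_fraction < 1.0:
        raise ValueError("top_fraction must be in (0, 1)")
    v = values.dropna()
    if v.empty:
        raise ValueError("no cells with data")
    if v.nunique() == 1:
        warnings.warn("all cell values equal: every cell ties at the threshold")
        return set(v.index)
    k = int(np.ceil(top_fraction * len(v)))
    threshold = np.sort(v.to_numpy())[::-1][k - 1]
    return set(v.index[v >= threshold])


def count_based_hotspots(metrics: pd.DataFrame, top_fraction: float = 0.10) -> set:
    """Union of the top-decile cells over the four richness measures."""
    m = metrics.set_index("cell_id")
    out = set()
    for measure in COUNT_MEASURES:
        out |= top_percentile_cells(m[measure], top_fraction)
    return out


def score_based_hotspots(metrics: pd.DataFrame, top_fraction: float = 0.10) -> set:
    """Top-decile cells of mean T+D+LH."""
    m = metrics.set_index("cell_id")
    return top_percentile_cells(m[SCORE_MEASURE], top_fraction)


def inclusion_fractions(grid: Fishnet, hotspot_polygons) -> pd.Series:
    """Fraction of each cell's land area inside the hotspot polygons."""
    hp = unary_union(list(hotspot_polygons))
    if not hp.is_valid:
        raise ValueError("invalid hotspot geometry")
    fracs = {}
    for cell in grid.cells:
        if cell.land_area_km2 <= 0:
            fracs[cell.cell_id] = 0.0
            continue
        inter = cell.clipped_polygon.intersection(hp)
        a = 0.0 if inter.is_empty else polygon_area_km2(inter)
        fracs[cell.cell_id] = min(a / cell.land_area_km2, 1.0)
    return pd.Series(fracs, name="inclusion_fraction")


def polygon_inclusion(
    grid: Fishnet,
    hotspot_polygons,
    rule_fraction: float = 0.50,
    fractions: pd.Series | None = None,
    rel_tol: float = 1e-6,
) -> pd.Series:
    """Boolean biodiversity-hotspot flag per cell under one inclusion rule.

    Rules 0.25/0.50/0.75 are strict (fraction > rule); the 100% rule requires
    full inclusion.  Both comparisons carry the area-computation tolerance
    ``rel_tol`` so an exactly-half-covered cell is excluded under the 50% rule
    regardless of projection round-off.  Pass ``fractions`` to reuse
    precomputed overlap fractions across rules.
    """
    if fractions is None:
        fractions = inclusion_fractions(grid, hotspot_polygons)
    if rule_fraction >= 1.0:
        return fractions >= 1.0 - rel_tol
    return fractions > rule_fraction + rel_tol


def chi2_association(flags_a: pd.Series, flags_b: pd.Series, continuity_correction: bool = True):
    """Pearson chi-squared (df=1) association between two hotspot flag vectors.

    Yates continuity correction is applied by default, matching the stock
    2x2 behaviour of R's chisq.test.  Raises on degenerate tables (a zero
    marginal).
    """
    a, b = flags_a.align(flags_b, join="inner")
    table = pd.crosstab(a.astype(bool), b.astype(bool))
    table = table.reindex(index=[False, True], columns=[False, True], fill_value=0)
    t = table.to_numpy()
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        raise ValueError("degenerate table: a marginal total is zero")
    chi2, p, df, _ = stats.chi2_contingency(t, correction=continuity_correction)
    return float(chi2), int(df), float(p), table


def venn_counts(count_flags: pd.Series, score_flags: pd.Series, bio_flags: pd.Series) -> dict:
    """Counts of the 7 intersection regions of the three hotspot sets."""
    idx = count_flags.index.intersection(score_flags.index).intersection(bio_flags.index)
    c = set(idx[count_flags.loc[idx].astype(bool)])
    s = set(idx[score_flags.loc[idx].astype(bool)])
    b = set(idx[bio_flags.loc[idx].astype(bool)])
    regions = {
        "count_only": len(c - s - b),
        "score_only": len(s - c - b),
        "biodiversity_only": len(b - c - s),
        "count_score": len((c & s) - b),
        "count_biodiversity": len((c & b) - s),
        "score_biodiversity": len((s & b) - c),
        "all_three": len(c & s & b),
    }
    regions["total_flagged"] = len(c | s | b)
    return regions


def inclusion_rule_sensitivity(
    metrics: pd.DataFrame,
    grid: Fishnet,
    hotspot_polygons,
    measures=(*COUNT_MEASURES, SCORE_MEASURE),
    rules=INCLUSION_RULES,
):
    """Hotspot-minus-non-hotspot median differences under each inclusion rule.

    Returns (table, kruskal_result): one row per rule per measure with the
    median difference, plus a Kruskal-Wallis test across rules on those
    differences (H = 0 when the classifications agree).
    """
    fracs = inclusion_fractions(grid, hotspot_polygons)
    m = metrics.set_index("cell_id")
    m = m[m["has_data"]]
    rows, groups = [], {}
    for rule in rules:
        flags = polygon_inclusion(grid, hotspot_polygons, rule, fractions=fracs)
        flags = flags.reindex(m.index)
        diffs = []
        for measure in measures:
            hot = m.loc[flags, measure].dropna()
            non = m.loc[~flags, measure].dropna()
            diff = (
                float(hot.median() - non.median()) if len(hot) and len(non) else np.nan
            )
            diffs.append(diff)
            rows.append(
                {
                    "rule": rule,
                    "measure": measure,
                    "n_hotspot_cells": int(flags.sum()),
                    "median_difference": diff,
                }
            )
        groups[rule] = [d for d in diffs if np.isfinite(d)]
    vals = [v for v in groups.values() if v]
    pooled = np.concatenate(vals) if vals else np.array([])
    if len(pooled) == 0 or np.ptp(pooled) == 0.0:
        H, p = 0.0, 1.0
    else:
        H, p = stats.kruskal(*vals)
    return pd.DataFrame(rows), {"H": float(H), "df": len(rules) - 1, "p": float(p)}


def compare_hotspot_vs_non(
    metrics: pd.DataFrame,
    bio_flags: pd.Series,
    measures=(*COUNT_MEASURES, SCORE_MEASURE),
) -> pd.DataFrame:
    """Mann-Whitney comparison of each diversity measure: hotspot vs non-hotspot cells."""
    m = metrics.set_index("cell_id")
    m = m[m["has_data"]]
    flags = bio_flags.reindex(m.index).astype(bool)
    if flags.all() or not flags.any():
        raise ValueError("both hotspot and non-hotspot groups must be non-empty")
    rows = []
    for measure in measures:
        hot = m.loc[flags, measure].dropna().to_numpy()
        non = m.loc[~flags, measure].dropna().to_numpy()
        if np.ptp(np.concatenate([hot, non])) == 0.0:
            u, p = len(hot) * len(non) / 2.0, 1.0
        else:
            u, p = stats.mannwhitneyu(hot, non, alternative="two-sided")
        rows.append(
            {
                "measure": measure,
                "U": float(u),
                "p": float(p),
                "median_hotspot": float(np.median(hot)),
                "median_non_hotspot": float(np.median(non)),
                "n_hotspot": len(hot),
                "n_non_hotspot": len(non),
            }
        )
    return pd.DataFrame(rows)
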