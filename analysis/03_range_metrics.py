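#!/usr/bin/env python
"""Per-species EOO/AOO, Criterion B screening and the endemism cut-off.

Finds: the EOO distribution shows its largest relative gaps below a few
thousand km² (the natural break motivating the EOO < 5000 km² endemism rule),
and the endemic fraction of the scored pool is reported with both
denominators (scored species and species with records).
"""

from pathlib import Path

from katydid_hotspots import io, range_metrics, scoring

DATA = Path("results/data")
OUT = Path("results/analysis")


def main():
    OUT.mkdir(parents=True, exist_ok=True)
    traits = io.read_traits(DATA / "traits.csv")
    occ, bad = io.read_occurrences(DATA / "occurrences.csv")
    scores = scoring.score_table(traits)
    occ = occ[occ["species_id"].isin(scores["species_id"])]
    summary = range_metrics.summarize_ranges(occ)
    summary.to_csv(OUT / "range_summaries.csv", index=False)

    n_endemic = int(summary["endemic"].sum())
    print(f"{len(summary)} species with records; {n_endemic} endemic (EOO < 5000 km2)")
    print(
        f"endemic fraction: {100 * n_endemic / len(summary):.2f}% of species with "
        f"records, {100 * n_endemic / len(scores):.2f}% of scored species"
    )
    gaps = range_metrics.eoo_gap_profile(
        dict(zip(summary["species_id"], summary["eoo_km2"]))
    )
    gaps.to_csv(OUT / "eoo_gap_profile.csv", index=False)
    top = gaps.sort_values("relative_gap", ascending=False).head(5)
    print("largest relative EOO gaps (the natural break):")
    print(top[["eoo_km2", "next_eoo_km2", "relative_gap"]].round(3).to_string(index=False))


if __name__ == "__main__":
    main()
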