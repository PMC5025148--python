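#!/usr/bin/env python
"""Score every assessable species on the trait chart and compare trait scores
across Red List categories.

Finds: DD species are excluded; threatened (VU/EN/CR) species carry higher
distribution and life-history scores than LC species (Kruskal-Wallis with
Nemenyi letters), mirroring how narrow ranges drive both threat status and
the composite score.
"""

from pathlib import Path

import pandas as pd

from katydid_hotspots import io, scoring

DATA = Path("results/data")
OUT = Path("results/analysis")


def main():
    OUT.mkdir(parents=True, exist_ok=True)
    traits = io.read_traits(DATA / "traits.csv")
    scores = scoring.score_table(traits)
    scores.to_csv(OUT / "species_scores.csv", index=False)
    print(f"scored {len(scores)} of {len(traits)} species (DD excluded)")
    print(scores[["T", "D", "M", "Tr", "LH", "T+D+LH"]].describe().round(2).to_string())

    statuses = dict(zip(traits["species_id"], traits["status"]))
    report = scoring.compare_traits_across_status(scores, statuses)
    rows = []
    for trait in ("D", "M", "Tr", "LH"):
        r = report[trait]
        rows.append(
            {
                "trait": trait,
                "H": round(r["H"], 2),
                "df": r["df"],
                "p": r["p"],
                "letters": "; ".join(f"{k}:{v}" for k, v in sorted(r["letters"].items())),
            }
        )
        print(f"{trait}: H={r['H']:.2f} (df={r['df']}), p={r['p']:.2g}, letters {r['letters']}")
    pd.DataFrame(rows).to_csv(OUT / "trait_comparison_by_status.csv", index=False)


if __name__ == "__main__":
    main()
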