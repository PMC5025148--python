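#!/usr/bin/env python
"""Generate the synthetic study dataset every later step analyses.

Writes traits, occurrences, region and hotspot polygons (plus the planted
ground truth) for the default study conditions: 130 species, 1100 records,
4x enrichment of narrow-range specialists inside hotspot polygons, seed 0.
"""

import json
from pathlib import Path

from katydid_hotspots import io
from katydid_hotspots.synthetic import SimulationConfig, simulate_dataset

OUT = Path("results/data")


def main():
    OUT.mkdir(parents=True, exist_ok=True)
    ds = simulate_dataset(SimulationConfig(seed=0))
    ds.traits.to_csv(OUT / "traits.csv", index=False)
    ds.occurrences.to_csv(OUT / "occurrences.csv", index=False)
    io.write_geojson([(ds.region, {"name": "region"})], OUT / "region.geojson")
    io.write_geojson(
        [(p, {"name": f"hotspot_{i}"}) for i, p in enumerate(ds.hotspot_polygons)],
        OUT / "hotspots.geojson",
    )
    with open(OUT / "ground_truth.json", "w") as fh:
        json.dump(
            {
                "true_hotspot_cells": sorted(ds.truth.true_hotspot_cells),
                "true_lambda": ds.truth.true_lambda,
                "true_status": ds.truth.true_status,
            },
            fh,
            indent=1,
        )
    n_dd = (ds.traits["status"] == "DD").sum()
    print(
        f"wrote {len(ds.traits)} species ({n_dd} DD), {len(ds.occurrences)} records, "
        f"{len(ds.hotspot_polygons)} hotspot polygons -> {OUT}"
    )
    print(f"planted hotspot cells: {sorted(ds.truth.true_hotspot_cells)}")


if __name__ == "__main__":
    main()
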