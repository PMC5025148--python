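# katydid-hotspots

Where should insect conservation effort go, and do the classic "biodiversity
hotspots" — delineated from plant endemism — actually capture insect
diversity?  This package re-implements a complete analysis pipeline for that
question, built around South African katydids (Orthoptera: Tettigonioidea):
a trait-based species scoring system, range metrics, grid-based hotspot
delineation, and the statistics needed to compare hotspot definitions.  It is
aimed at conservation biologists and biodiversity informaticians who want a
tested, scriptable version of this workflow for katydids or any other taxon
with occurrence records and natural-history traits.

## What it computes

**Species scoring.** Each assessable species gets four integer scores:
threat `T` (LC=0 … CR=3), distribution `D` (0–3, narrower range → higher),
mobility `M` (0–2, flightless → 2) and trophic specialisation `Tr` (0–3,
monophagous herbivore → 3).  Life history is `LH = chart(M + Tr)` with the
image {0→0, 1–2→1, 3→2, 4–5→3}, and the composite `T + D + LH` ranges 0–9:
the higher, the more threatened, narrowly distributed and specialised the
species.  Data Deficient species are excluded throughout.

**Range metrics.** EOO (convex-hull area of the localities) and AOO (4 km²
per occupied 2×2 km cell) on an azimuthal equal-area projection; a
range-threshold Criterion B screen (CR/EN/VU/LC); and the endemism rule
`EOO < 5000 km²`.

**Gridding and hotspots.** A 1° fishnet clipped to the study region; per
cell: total / threatened / endemic / sensitive (`LH = 3`) species richness
and the mean of six composite scores over the species present.  Count-based
hotspots are the union of top-decile cells over the four richness measures;
score-based hotspots are the top decile of mean `T+D+LH`; cells are
classified against externally supplied hotspot polygons by the fraction of
their land area inside (> 25/50/75/100 % rules), and the three hotspot kinds
are cross-tabulated with Yates-corrected χ² tests, Venn counts and
Mann-Whitney comparisons.

**Statistics.** Pairwise relationships between diversity measures via a
spatial GLMM fitted by penalized quasi-likelihood (working covariance
`W⁻¹ + θ·exp(−d/ρ)`, with the field variance θ and range ρ REML-profiled),
with marginal r² and Moran's I of plain-GLM residuals; OLS vs PGLS
comparative regressions on a taxonomy-derived tree (unit branch lengths,
nested polytomies) with Pagel's λ estimated by bounded ML and models ranked
by AIC; sample-based and individual-based species accumulation curves whose
expectations and variances equal exact subset enumeration.

**Synthetic data.** `katydid_hotspots.synthetic` generates full datasets —
taxonomy, traits with phylogenetic signal, clustered occurrences whose range
sizes track the distribution score, a notched study region, and hotspot
polygons enriched (4× placement odds) in narrow-range specialists — with the
planted ground truth returned alongside, so every stage of the pipeline is
testable without any downloads.

## Worked example

```python
from katydid_hotspots import io, synthetic

fx = synthetic.worked_fixture()          # 6 species on a 3x3-degree grid
cfg = io.PipelineConfig(output_dir="out", run_phylogenetics=False,
                        run_rarefaction=False)
res = io.run_pipeline(cfg, traits=fx["traits"], occurrences=fx["occurrences"],
                      region=fx["region"],
                      hotspot_polygons=fx["hotspot_polygons"])
print(res.venn)
```

prints

```
{'count_only': 2, 'score_only': 0, 'biodiversity_only': 0, 'count_score': 0,
 'count_biodiversity': 2, 'score_biodiversity': 0, 'all_three': 1,
 'total_flagged': 5}
```

i.e. of the seven data-bearing cells, five are flagged by at least one
hotspot definition; the cell holding the two highest-scoring species (mean
`T+D+LH` = 8) is a hotspot under all three definitions, two cells are
count-based-only, and two are shared between the count-based set and the
polygon hotspots.  Every number in this fixture is checkable by hand; the
expected tables ship with the package
(`src/katydid_hotspots/data/worked_fixture/`).

The full synthetic analysis is the numbered scripts:

```bash
python analysis/01_simulate_dataset.py    # 130 species, 1100 records, seed 0
python analysis/02_score_species.py
python analysis/03_range_metrics.py
python analysis/04_grid_and_hotspots.py
python analysis/05_spatial_models.py
python analysis/06_phylogenetic_models.py
python analysis/07_rarefaction.py
```

Each prints what it found and writes its tables under `results/`.  On the
seed-0 dataset, for example, `04` reports 74 grid cells (27 count-based, 9
score-based, 24 polygon-hotspot cells), a strong count-vs-score association
(χ² = 14.85, p = 0.0001) and Jaccard 0.55 between the delineated score-based
hotspots and the planted cells; `05` finds every pairwise diversity-measure
slope positive and significant after spatial correction.

There is also a CLI (`katydids score|ranges|grid|hotspots|stats|pgls|sac|simulate|run`)
mirroring the library.

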