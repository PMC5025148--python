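"""Readers, writers and the end-to-end pipeline driver.

Conventions enforced here once for the whole package: coordinates are WGS84
decimal degrees, internal areas are km², grid cells use half-open
[min, max) membership, CSVs are UTF-8 with a header row, polygons travel as
GeoJSON (RFC 7946) and trees as Newick.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from shapely.geometry import mapping, shape
from shapely.ops import unary_union

from . import gridding, hotspots, phylo, range_metrics, rarefaction, scoring

log = logging.getLogger("katydid_hotspots")

OCCURRENCE_COLUMNS = ("species_id", "lon", "lat")
TRAIT_COLUMNS = (
    "species_id", "subfamily", "tribe", "genus", "subgenus", "species",
    "status", "frac_SA", "frac_sA", "n_provinces", "endemic_to_SA",
    "marginal_in_SA", "mobility_class", "trophic_class",
)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str, snapshot: str | None = None):
        self.stage = stage
        self.snapshot = snapshot
        super().__init__(
            f"stage '{stage}' failed: {message}"
            + (f" (inputs snapshot: {snapshot})" if snapshot else "")
        )


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def read_occurrences(path):
    """Read and validate an occurrence CSV.

    Returns (records, error_report): malformed rows (bad or out-of-range
    coordinates) are excluded but collected in the report, never silently
    dropped.  Missing required columns reject the whole file.
    """
    df = pd.read_csv(path)
    missing = [c for c in OCCURRENCE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"occurrence file {path} missing columns: {missing}")
    lon = pd.to_numeric(df["lon"], errors="coerce")
    lat = pd.to_numeric(df["lat"], errors="coerce")
    bad = (
        lon.isna() | lat.isna()
        | (lon < -180) | (lon > 180) | (lat < -90) | (lat > 90)
        | df["species_id"].isna()
    )
    report = df[bad].copy()
    report["reason"] = "invalid or out-of-range coordinates"
    good = df[~bad].copy()
    good["lon"] = lon[~bad]
    good["lat"] = lat[~bad]
    for opt in ("date", "collector"):
        if opt not in good.columns:
            good[opt] = ""
    return good.reset_index(drop=True), report.reset_index(drop=True)


def write_occurrences(df: pd.DataFrame, path):
    df.to_csv(path, index=False)


def read_traits(path) -> pd.DataFrame:
    df = pd.read_csv(path, keep_default_na=False, na_values=[])
    missing = [c for c in TRAIT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"trait file {path} missing columns: {missing}")
    dupes = df["species_id"][df["species_id"].duplicated()].tolist()
    if dupes:
        raise ValueError(f"duplicate species ids in trait table: {sorted(set(dupes))}")
    for col in ("frac_SA", "frac_sA"):
        df[col] = pd.to_numeric(df[col])
    df["n_provinces"] = pd.to_numeric(df["n_provinces"]).astype(int)
    for col in ("endemic_to_SA", "marginal_in_SA"):
        df[col] = df[col].map(scoring._as_bool)
    return df


def read_geojson_geometries(path) -> list:
    """All geometries of a GeoJSON file (FeatureCollection, Feature or geometry)."""
    with open(path) as fh:
        obj = json.load(fh)
    if obj.get("type") == "FeatureCollection":
        return [shape(f["geometry"]) for f in obj["features"]]
    if obj.get("type") == "Feature":
        return [shape(obj["geometry"])]
    return [shape(obj)]


def read_region(path):
    return unary_union(read_geojson_geometries(path))


def write_geojson(geoms_with_props, path):
    """Write [(geometry, properties-dict), ...] as a FeatureCollection."""
    features = [
        {"type": "Feature", "geometry": mapping(g), "properties": props}
        for g, props in geoms_with_props
    ]
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh)


def write_grid_geojson(grid: gridding.Fishnet, path):
    write_geojson(
        [
            (c.clipped_polygon, {"cell_id": c.cell_id, "land_area_km2": c.land_area_km2})
            for c in grid.cells
        ],
        path,
    )


# ---------------------------------------------------------------------------
# pipeline configuration and driver
# ---------------------------------------------------------------------------

_KNOWN_KEYS = {
    "traits_csv", "occurrences_csv", "region_geojson", "hotspots_geojson",
    "output_dir", "cell_deg", "grid_origin", "top_fraction", "inclusion_rule",
    "continuity_correction", "seed", "log_level", "run_spatial_models",
    "run_phylogenetics", "run_rarefaction", "n_permutations",
}


@dataclass
class PipelineConfig:
    traits_csv: str = ""
    occurrences_csv: str = ""
    region_geojson: str = ""
    hotspots_geojson: str = ""
    output_dir: str = "results/pipeline"
    cell_deg: float = 1.0
    grid_origin: tuple = (0.0, 0.0)
    top_fraction: float = 0.10
    inclusion_rule: float = 0.50
    continuity_correction: bool = True
    seed: int = 0
    log_level: str = "INFO"
    run_spatial_models: bool = False
    run_phylogenetics: bool = True
    run_rarefaction: bool = True
    n_permutations: int = 199

    @classmethod
    def from_yaml(cls, path):
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - _KNOWN_KEYS
        if unknown:
            raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def validate(self):
        if not 0 < self.top_fraction < 1:
            raise ValueError("top_fraction must be in (0, 1)")
        if self.inclusion_rule not in (0.25, 0.50, 0.75, 1.00):
            raise ValueError("inclusion_rule must be one of 0.25/0.50/0.75/1.00")
        if self.cell_deg <= 0:
            raise ValueError("cell_deg must be positive")

    def content_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class PipelineResult:
    scores: pd.DataFrame
    ranges: pd.DataFrame
    grid: gridding.Fishnet
    metrics: pd.DataFrame
    flags: pd.DataFrame
    associations: pd.DataFrame
    venn: dict
    manifest: dict
    pairwise: pd.DataFrame | None = None
    pgls_table: pd.DataFrame | None = None
    sac_comparison: dict | None = None


def run_pipeline(
    config: PipelineConfig,
    traits: pd.DataFrame | None = None,
    occurrences: pd.DataFrame | None = None,
    region=None,
    hotspot_polygons=None,
    write: bool = True,
) -> PipelineResult:
    """Run scoring -> ranges -> gridding -> hotspots (-> spatial stats,
    phylogenetics, rarefaction) and return every artefact.

    Inputs may be passed in memory (the synthetic generator's output) or read
    from the paths in ``config``.  With ``write=True`` all tables are written
    under ``config.output_dir`` together with a run manifest; the run is
    deterministic for fixed inputs and seed.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    counts = {}
    stage = "load_inputs"
    try:
        if traits is None:
            traits = read_traits(config.traits_csv)
        if occurrences is None:
            occurrences, occ_errors = read_occurrences(config.occurrences_csv)
            counts["n_malformed_records"] = int(len(occ_errors))
        if region is None:
            region = read_region(config.region_geojson)
        if hotspot_polygons is None:
            hotspot_polygons = read_geojson_geometries(config.hotspots_geojson)
        counts["n_species_total"] = int(len(traits))
        counts["n_dd_or_ne"] = int(traits["status"].isin(["DD", "NE"]).sum())
        counts["n_records"] = int(len(occurrences))
        log.info("inputs: %d species (%d DD/NE excluded), %d records",
                 counts["n_species_total"], counts["n_dd_or_ne"], counts["n_records"])

        stage = "scoring"
        scores = scoring.score_table(traits)
        counts["n_scored"] = int(len(scores))

        stage = "range_metrics"
        occ_scored = occurrences[occurrences["species_id"].isin(scores["species_id"])]
        ranges = range_metrics.summarize_ranges(occ_scored)
        counts["n_endemic"] = int(ranges["endemic"].sum())

        stage = "gridding"
        grid = gridding.build_fishnet(region, config.cell_deg, config.grid_origin)
        assigned, unassigned = gridding.assign_records(occ_scored, grid)
        metrics = gridding.cell_metrics(assigned, scores, ranges, grid)
        counts["n_cells"] = len(grid)
        counts["n_cells_with_data"] = int(metrics["has_data"].sum())
        counts["n_unassigned_records"] = int(len(unassigned))
        log.info("grid: %d cells, %d with data, %d unassigned records",
                 counts["n_cells"], counts["n_cells_with_data"], counts["n_unassigned_records"])

        stage = "hotspots"
        count_set = hotspots.count_based_hotspots(metrics, config.top_fraction)
        score_set = hotspots.score_based_hotspots(metrics, config.top_fraction)
        fracs = hotspots.inclusion_fractions(grid, hotspot_polygons)
        bio = hotspots.polygon_inclusion(grid, hotspot_polygons, config.inclusion_rule,
                                         fractions=fracs)
        data_cells = metrics.loc[metrics["has_data"], "cell_id"]
        flags = pd.DataFrame(
            {
                "cell_id": data_cells,
                "count_based": data_cells.isin(count_set).to_numpy(),
                "score_based": data_cells.isin(score_set).to_numpy(),
                "biodiversity": bio.reindex(data_cells).to_numpy(),
                "inclusion_fraction": fracs.reindex(data_cells).to_numpy(),
            }
        )
        counts["n_count_based"] = int(flags["count_based"].sum())
        counts["n_score_based"] = int(flags["score_based"].sum())
        counts["n_biodiversity"] = int(flags["biodiversity"].sum())
        f = flags.set_index("cell_id")
        assoc_rows = []
        for a, b in (("count_based", "biodiversity"), ("score_based", "biodiversity"),
                     ("count_based", "score_based")):
            try:
                chi2, df_, p, _ = hotspots.chi2_association(
                    f[a], f[b], config.continuity_correction
                )
            except ValueError:
                chi2, df_, p = np.nan, 1, np.nan
            assoc_rows.append({"flags_a": a, "flags_b": b, "chi2": chi2, "df": df_, "p": p})
        associations = pd.DataFrame(assoc_rows)
        venn = hotspots.venn_counts(f["count_based"], f["score_based"], f["biodiversity"])

        pairwise = None
        if config.run_spatial_models:
            stage = "spatial_stats"
            from . import spatial_stats

            pairwise = spatial_stats.pairwise_measure_models(
                metrics, n_permutations=config.n_permutations, seed=config.seed
            )

        pgls_table = None
        if config.run_phylogenetics:
            stage = "phylo_comparative"
            scored_traits = traits[traits["species_id"].isin(scores["species_id"])]
            tree = phylo.taxonomy_to_tree(scored_traits)
            pgls_table = phylo.fit_model_set(scores, tree)

        sac_comparison = None
        if config.run_rarefaction:
            stage = "rarefaction"
            sac_comparison = _hotspot_sac_comparison(assigned, f)

        stage = "manifest"
        manifest = {
            "config": {k: (list(v) if isinstance(v, tuple) else v)
                       for k, v in asdict(config).items()},
            "config_hash": config.content_hash(),
            "seed": config.seed,
            "versions": {
                "numpy": np.__version__,
                "pandas": pd.__version__,
            },
            "counts": counts,
        }
        manifest["manifest_hash"] = hashlib.sha256(
            json.dumps(manifest, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]

        result = PipelineResult(
            scores=scores, ranges=ranges, grid=grid, metrics=metrics, flags=flags,
            associations=associations, venn=venn, manifest=manifest,
            pairwise=pairwise, pgls_table=pgls_table, sac_comparison=sac_comparison,
        )
        if write:
            _write_outputs(config, result)
        return result
    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001 - annotate with the failing stage
        raise PipelineError(stage, str(exc)) from exc


def _hotspot_sac_comparison(assigned: pd.DataFrame, flags: pd.DataFrame) -> dict:
    """Sample- and individual-based SAC comparison of hotspot vs non-hotspot cells."""
    inc = pd.crosstab(assigned["cell_id"], assigned["species_id"])
    hot_ids = flags.index[flags["biodiversity"].astype(bool)]
    hot = inc.loc[inc.index.intersection(hot_ids)]
    non = inc.loc[inc.index.difference(hot_ids)]
    out = {}
    if len(hot) >= 2 and len(non) >= 2:
        out["sample_based"] = rarefaction.compare_sacs(hot.to_numpy(), non.to_numpy(),
                                                       kind="sample")
        out["individual_based"] = rarefaction.compare_sacs(
            hot.to_numpy().sum(axis=0), non.to_numpy().sum(axis=0), kind="individual"
        )
    return out


def _write_outputs(config: PipelineConfig, result: PipelineResult):
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    result.scores.to_csv(out / "species_scores.csv", index=False)
    result.ranges.to_csv(out / "range_summaries.csv", index=False)
    result.metrics.to_csv(out / "cell_metrics.csv", index=False, na_rep="NA")
    result.flags.to_csv(out / "hotspot_flags.csv", index=False)
    result.associations.to_csv(out / "hotspot_associations.csv", index=False)
    with open(out / "venn_counts.json", "w") as fh:
        json.dump(result.venn, fh, indent=1)
    write_grid_geojson(result.grid, out / "grid.geojson")
    if result.pairwise is not None:
        result.pairwise.to_csv(out / "pairwise_measure_models.csv", index=False)
    if result.pgls_table is not None:
        result.pgls_table.to_csv(out / "pgls_model_ranking.csv", index=False)
    if result.sac_comparison:
        for kind, rep in result.sac_comparison.items():
            rep["table"].to_csv(out / f"sac_{kind}.csv", index=False)
    with open(out / "run_manifest.json", "w") as fh:
        json.dump(result.manifest, fh, indent=1, default=str)
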