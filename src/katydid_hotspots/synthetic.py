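"""Synthetic occurrence datasets with planted structure for every pipeline stage.

The generator emulates the study system: ~130 katydid species on a
taxonomy-derived tree, traits (threat, distribution, mobility, trophic level)
with phylogenetic signal, spatially clustered occurrence records whose range
sizes shrink as the distribution score grows, a notched rectangular study
region standing in for a coastline, and "biodiversity hotspot" polygons in
which narrow-range specialist species are preferentially placed.  Everything
is deterministic given the seed; per-stage child seeds are spawned from it so
stages can be regenerated independently.

Defaults mirror the study conditions: 130 species, 1100 records, Red List
marginals ~57% LC / 13% VU / 8% EN / 11% CR among assessed species plus ~12%
DD, hotspot polygons covering ~30% of the region, and a 4x placement-odds
enrichment of narrow-range specialists inside hotspot polygons.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm
from shapely.geometry import Point, Polygon, box

from . import phylo
from .gridding import build_fishnet
from .hotspots import top_percentile_cells
from .range_metrics import screen_criterion_b
from .scoring import score_table

__all__ = ["SimulationConfig", "GroundTruth", "SimulatedDataset", "simulate_dataset", "worked_fixture"]

#: degrees of latitude per km (authalic sphere)
_DEG_PER_KM = 1.0 / 111.195

_STATUS_ORDER = ("CR", "EN", "VU", "LC")  # ascending range size

# log-uniform EOO target ranges (km²) per screened class
_EOO_RANGES = {"CR": (20.0, 95.0), "EN": (300.0, 4800.0), "VU": (6000.0, 19000.0), "LC": (25000.0, 250000.0)}


@dataclass
class SimulationConfig:
    seed: int = 0
    n_species: int = 130
    n_records: int = 1100
    region_extent: tuple = (17.0, -35.0, 10.0, 8.0)  # lon0, lat0, width, height (deg)
    hotspot_fraction: float = 0.3
    enrichment: float = 4.0
    n_subfamilies: int = 10
    true_lambda: float = 0.7
    status_probs: dict = field(
        default_factory=lambda: {"LC": 0.571, "VU": 0.128, "EN": 0.075, "CR": 0.105}
    )
    dd_frac: float = 0.12
    status_noise: float = 0.05
    trait_range_corr: float = 0.5  # latent correlation of M/Tr tendency with range size
    n_specialist_cores: int = 6  # micro-habitat core sites that specialists aggregate around
    core_spread_deg: float = 0.12  # spread of specialist kernels around their core
    specialist_fraction: float = 0.25  # share of scorable species in the specialist pool
    mobility_probs: dict = field(
        default_factory=lambda: {"flightless": 0.35, "partial_or_one_sex": 0.25, "fully_flighted": 0.40}
    )
    trophic_probs: dict = field(
        default_factory=lambda: {
            "herbivorous_monophagous": 0.18,
            "herbivorous_polyphagous": 0.34,
            "predatory": 0.18,
            "omnivorous": 0.30,
        }
    )

    def validate(self):
        if self.n_species < 10 or self.n_records < 2 * self.n_species:
            raise ValueError("need >= 10 species and >= 2 records per species")
        if not 0.0 < self.hotspot_fraction < 1.0:
            raise ValueError("hotspot_fraction must lie in (0, 1)")
        if self.enrichment < 1.0:
            raise ValueError("enrichment is an odds multiplier >= 1")
        if not 0.0 <= self.true_lambda <= 1.0:
            raise ValueError("true_lambda must lie in [0, 1]")


@dataclass
class GroundTruth:
    true_status: dict
    true_range_width_km: dict
    true_hotspot_cells: set
    true_lambda: float
    true_scores: pd.DataFrame
    true_cell_means: pd.Series
    kernel_centers: dict


@dataclass
class SimulatedDataset:
    traits: pd.DataFrame
    occurrences: pd.DataFrame
    region: Polygon
    hotspot_polygons: list
    truth: GroundTruth
    config: SimulationConfig


def _make_region(extent) -> Polygon:
    """Rectangle with a triangular 'coastline' notch cut from the southwest."""
    lon0, lat0, w, h = extent
    rect = box(lon0, lat0, lon0 + w, lat0 + h)
    notch = Polygon(
        [(lon0, lat0), (lon0 + 0.4 * w, lat0), (lon0, lat0 + 0.5 * h)]
    )
    return rect.difference(notch)


def _make_hotspot_polygons(region: Polygon, extent, fraction: float) -> list:
    """Coastal strips plus an inland pocket scaled to cover ~``fraction`` of the region."""
    lon0, lat0, w, h = extent
    s = fraction / 0.3  # widths calibrated so the default covers ~30%
    polys = [
        box(lon0, lat0 + 0.5 * h, lon0 + 0.2 * w * s, lat0 + h),  # west strip
        box(lon0 + 0.4 * w, lat0, lon0 + w, lat0 + 0.19 * h * s),  # south strip
        box(lon0 + 0.6 * w, lat0 + 0.5 * h, lon0 + (0.6 + 0.2 * s) * w, lat0 + 0.69 * h),
    ]
    out = [p.intersection(region) for p in polys]
    out = [p for p in out if not p.is_empty]
    cover = sum(p.area for p in out) / region.area
    if not 0.0 < cover < 0.95:
        raise ValueError(f"hotspot polygons cover {cover:.2f} of the region; infeasible")
    return out


def _taxonomy(rng, n_species: int, n_subfamilies: int) -> pd.DataFrame:
    sf_w = rng.dirichlet(np.full(n_subfamilies, 1.5))
    sf_idx = rng.choice(n_subfamilies, size=n_species, p=sf_w)
    rows = []
    genus_count = {}
    sg_count = {}
    n_genera = {k: rng.integers(1, 5) for k in range(n_subfamilies)}
    for i in range(n_species):
        sf = int(sf_idx[i])
        g = int(rng.integers(0, n_genera[sf]))
        key = (sf, g)
        if key not in sg_count:
            sg_count[key] = int(rng.integers(1, 4))
        sg = int(rng.integers(0, sg_count[key]))
        genus_count[key] = genus_count.get(key, 0) + 1
        rows.append(
            {
                "species_id": f"sp{i + 1:03d}",
                "subfamily": f"Subfamily{sf + 1:02d}",
                "tribe": "",
                "genus": f"Genus{sf + 1:02d}_{g + 1}",
                "subgenus": f"Subg{sf + 1:02d}_{g + 1}_{sg + 1}",
                "species": f"species_{i + 1:03d}",
            }
        )
    return pd.DataFrame(rows)


def _latent_with_signal(rng, chol: np.ndarray) -> np.ndarray:
    """One standard-normal latent vector with phylogenetic correlation."""
    return chol @ rng.standard_normal(chol.shape[0])


def _bin_by_quantile(u: np.ndarray, probs: dict) -> np.ndarray:
    """Map standard-normal latents to labelled classes with given marginals.

    Classes are filled in dict order from the lower tail of Phi(u).
    """
    q = norm.cdf(u)
    labels = list(probs)
    cuts = np.cumsum([probs[k] for k in labels])
    cuts = cuts / cuts[-1]
    out = np.empty(len(u), dtype=object)
    prev = 0.0
    for lab, c in zip(labels, cuts):
        out[(q >= prev) & (q < c)] = lab
        prev = c
    out[q >= prev] = labels[-1]
    return out


def _distribution_fields(rng, d_score: int) -> dict:
    """Trait-table fields that the scoring chart maps back to ``d_score``."""
    if d_score == 3:
        return dict(
            endemic_to_SA=True,
            marginal_in_SA=False,
            n_provinces=int(rng.integers(1, 3)),
            frac_SA=round(rng.uniform(0.05, 0.30), 3),
            frac_sA=round(rng.uniform(0.05, 0.35), 3),
        )
    if d_score == 2:
        if rng.uniform() < 0.7:  # national endemic over a wide area
            return dict(
                endemic_to_SA=True,
                marginal_in_SA=False,
                n_provinces=int(rng.integers(3, 7)),
                frac_SA=round(rng.uniform(0.35, 0.70), 3),
                frac_sA=round(rng.uniform(0.35, 0.70), 3),
            )
        return dict(  # widespread in southern Africa, marginal nationally
            endemic_to_SA=False,
            marginal_in_SA=True,
            n_provinces=int(rng.integers(1, 3)),
            frac_SA=round(rng.uniform(0.02, 0.30), 3),
            frac_sA=round(rng.uniform(0.70, 0.95), 3),
        )
    if d_score == 1:
        if rng.uniform() < 0.4:  # localized across a wide area
            return dict(
                endemic_to_SA=False,
                marginal_in_SA=False,
                n_provinces=int(rng.integers(4, 9)),
                frac_SA=round(rng.uniform(0.68, 0.74), 3),
                frac_sA=round(rng.uniform(0.68, 0.74), 3),
            )
        return dict(  # very common in 1-3 provinces
            endemic_to_SA=False,
            marginal_in_SA=False,
            n_provinces=int(rng.integers(1, 4)),
            frac_SA=round(rng.uniform(0.05, 0.33), 3),
            frac_sA=round(rng.uniform(0.70, 0.95), 3),
        )
    return dict(  # very common everywhere
        endemic_to_SA=False,
        marginal_in_SA=False,
        n_provinces=int(rng.integers(5, 10)),
        frac_SA=round(rng.uniform(0.78, 0.98), 3),
        frac_sA=round(rng.uniform(0.80, 0.99), 3),
    )


def _d_from_eoo(eoo: float) -> int:
    if eoo < 5000.0:
        return 3
    if eoo < 20000.0:
        return 2
    if eoo < 75000.0:
        return 1
    return 0


def _sample_point_in(rng, geom) -> Point:
    minx, miny, maxx, maxy = geom.bounds
    for _ in range(1000):
        p = Point(rng.uniform(minx, maxx), rng.uniform(miny, maxy))
        if geom.contains(p):
            return p
    raise RuntimeError("could not sample a point inside the region")


def simulate_dataset(config: SimulationConfig) -> SimulatedDataset:
    """Generate one complete synthetic dataset with planted ground truth."""
    config.validate()
    seeds = np.random.SeedSequence(config.seed).spawn(6)
    rng_tax, rng_trait, rng_geo, rng_place, rng_rec, rng_noise = (
        np.random.default_rng(s) for s in seeds
    )
    n = config.n_species

    taxonomy = _taxonomy(rng_tax, n, config.n_subfamilies)
    tree = phylo.taxonomy_to_tree(taxonomy)
    C = phylo.brownian_covariance(tree, tip_order=list(taxonomy["species_id"]))
    corr = C.to_numpy() / np.sqrt(np.outer(np.diag(C), np.diag(C)))
    V = corr * config.true_lambda
    np.fill_diagonal(V, 1.0)
    chol = np.linalg.cholesky(V)

    # --- range size and threat status --------------------------------------
    u_range = _latent_with_signal(rng_trait, chol)
    probs4 = {k: config.status_probs[k] for k in _STATUS_ORDER}
    range_class = _bin_by_quantile(u_range, probs4)
    eoo_target = np.array(
        [
            np.exp(rng_trait.uniform(*np.log(_EOO_RANGES[c])))
            for c in range_class
        ]
    )
    status = np.array([screen_criterion_b(e, max(e / 10.0, 4.0)) for e in eoo_target])
    # 5% of statuses are perturbed one step (expert judgement, Criterion D...)
    flip = rng_noise.uniform(size=n) < config.status_noise
    order = list(_STATUS_ORDER)
    for i in np.where(flip)[0]:
        j = order.index(status[i])
        j = int(np.clip(j + rng_noise.choice([-1, 1]), 0, 3))
        status[i] = order[j]
    dd = rng_noise.uniform(size=n) < config.dd_frac
    status[dd] = "DD"

    # --- mobility and trophic level with signal, tied to range size --------
    rho = config.trait_range_corr
    s_mob = rho * u_range + np.sqrt(1 - rho**2) * _latent_with_signal(rng_trait, chol)
    s_tro = rho * u_range + np.sqrt(1 - rho**2) * _latent_with_signal(rng_trait, chol)
    mobility = _bin_by_quantile(s_mob, config.mobility_probs)
    trophic = _bin_by_quantile(s_tro, config.trophic_probs)

    d_score = np.array([_d_from_eoo(e) for e in eoo_target])
    rows = []
    for i, rec in enumerate(taxonomy.to_dict("records")):
        fields = _distribution_fields(rng_trait, int(d_score[i]))
        rows.append(
            {
                **rec,
                "status": status[i],
                **fields,
                "mobility_class": mobility[i],
                "trophic_class": trophic[i],
            }
        )
    traits = pd.DataFrame(rows)[
        [
            "species_id", "subfamily", "tribe", "genus", "subgenus", "species",
            "status", "frac_SA", "frac_sA", "n_provinces", "endemic_to_SA",
            "marginal_in_SA", "mobility_class", "trophic_class",
        ]
    ]

    # --- geometry ----------------------------------------------------------
    region = _make_region(config.region_extent)
    hotspot_polys = _make_hotspot_polygons(region, config.region_extent, config.hotspot_fraction)
    from shapely.ops import unary_union

    hs_union = unary_union(hotspot_polys)

    # --- species scores and specialist pool ---------------------------------
    # the narrow-range specialist pool is the quarter of the scorable species
    # ranking highest on distribution + life-history (ties by composite, then
    # id, for determinism)
    scores = score_table(traits)
    scored = scores.set_index("species_id")
    pool_size = max(2, round(config.specialist_fraction * len(scored)))
    ranked = scored.assign(_key=scored["D"] + scored["LH"]).sort_values(
        ["_key", "T+D+LH", "species_id"], ascending=[False, False, True]
    )
    specialist_pool = list(ranked.index[:pool_size])
    specialist = {sp: sp in set(specialist_pool) for sp in scored.index}

    # --- kernel placement with hotspot enrichment --------------------------
    # Narrow-range specialists aggregate around a few micro-habitat core
    # sites (distinct endemic-vegetation pockets); the cores themselves are
    # placed inside hotspot polygons with odds multiplied by ``enrichment``,
    # so each specialist kernel carries those odds.  Everyone else is uniform.
    sigma_km = np.sqrt(eoo_target / np.pi) / 1.6
    sigma_of = dict(zip(taxonomy["species_id"], sigma_km))
    grid = build_fishnet(region)
    cores, used_cells = [], set()
    while len(cores) < config.n_specialist_cores:
        while True:
            p = _sample_point_in(rng_place, region)
            if config.enrichment <= 1.0:
                break
            if hs_union.contains(p) or rng_place.uniform() < 1.0 / config.enrichment:
                break
        # snap the core to the centre of its (whole-degree) grid cell so one
        # core anchors one cell; cores occupy distinct cells
        key = (int(np.floor(p.x)), int(np.floor(p.y)))
        if key in used_cells:
            continue
        used_cells.add(key)
        cores.append((key[0] + 0.5, key[1] + 0.5))
    shuffled = list(specialist_pool)
    rng_place.shuffle(shuffled)
    core_of = {sp: cores[i % len(cores)] for i, sp in enumerate(shuffled)}
    centers = {}
    for i, sp in enumerate(taxonomy["species_id"]):
        if specialist.get(sp, False):
            cx, cy = core_of[sp]
            for _try in range(200):
                p = Point(
                    cx + config.core_spread_deg * rng_place.standard_normal(),
                    cy + config.core_spread_deg * rng_place.standard_normal(),
                )
                if region.contains(p):
                    break
            else:
                p = Point(cx, cy)
        else:
            p = _sample_point_in(rng_place, region)
        centers[sp] = (p.x, p.y)

    # --- records for scorable (non-DD) species ------------------------------
    scorable = [sp for sp, st in zip(taxonomy["species_id"], status) if st != "DD"]
    base = 2
    # collection effort grows with range size: widespread species dominate
    # museum records, narrow endemics contribute a handful each
    weights = np.array([sigma_of[sp] for sp in scorable])
    weights = weights * rng_rec.gamma(16.0, 1.0 / 16.0, size=len(weights))
    extra = config.n_records - base * len(scorable)
    alloc = rng_rec.multinomial(extra, weights / weights.sum())
    rec_rows = []
    for sp, extra_i in zip(scorable, alloc):
        cx, cy = centers[sp]
        sd = sigma_of[sp] * _DEG_PER_KM
        for _ in range(base + int(extra_i)):
            for _try in range(100):
                lon = cx + sd * rng_rec.standard_normal()
                lat = cy + sd * rng_rec.standard_normal()
                if region.contains(Point(lon, lat)):
                    break
            else:
                lon, lat = cx, cy
            rec_rows.append({"species_id": sp, "lon": lon, "lat": lat, "date": "", "collector": ""})
    occurrences = pd.DataFrame(rec_rows)

    # --- analytic ground truth ----------------------------------------------
    from scipy.special import ndtr

    n_of = occurrences.groupby("species_id").size().to_dict()
    bounds = np.array([c.bounds for c in grid.cells])  # (ncells, 4)
    cxy = np.array([centers[sp] for sp in scorable])  # (S, 2)
    sd = np.array([sigma_of[sp] for sp in scorable]) * _DEG_PER_KM
    n_sp = np.array([n_of.get(sp, 0) for sp in scorable], dtype=float)
    # expected per-cell kernel mass: product of axis-aligned normal CDFs
    mx = ndtr((bounds[:, None, 2] - cxy[None, :, 0]) / sd) - ndtr(
        (bounds[:, None, 0] - cxy[None, :, 0]) / sd
    )
    my = ndtr((bounds[:, None, 3] - cxy[None, :, 1]) / sd) - ndtr(
        (bounds[:, None, 1] - cxy[None, :, 1]) / sd
    )
    # "truly present" where the species is more likely than not to be
    # collected at least once: expected records >= ln 2
    present = (mx * my) * n_sp[None, :] >= np.log(2.0)  # (ncells, S)
    score_vec = scored.loc[scorable, "T+D+LH"].to_numpy(float)
    cell_truth = {}
    for ci, cell in enumerate(grid.cells):
        if present[ci].any():
            cell_truth[cell.cell_id] = float(score_vec[present[ci]].mean())
    true_means = pd.Series(cell_truth, dtype=float)
    true_cells = top_percentile_cells(true_means, 0.10) if len(true_means) else set()

    truth = GroundTruth(
        true_status=dict(zip(taxonomy["species_id"], status)),
        true_range_width_km=sigma_of,
        true_hotspot_cells=true_cells,
        true_lambda=config.true_lambda,
        true_scores=scores,
        true_cell_means=true_means,
        kernel_centers=centers,
    )
    return SimulatedDataset(
        traits=traits,
        occurrences=occurrences,
        region=region,
        hotspot_polygons=hotspot_polys,
        truth=truth,
        config=config,
    )


# ---------------------------------------------------------------------------
# hand-built worked fixture
# ---------------------------------------------------------------------------


def worked_fixture():
    """A 6-species, 3x3-cell dataset whose metrics are all checkable by hand.

    Cells are labelled A1..C3 (row A = north).  One DD species exercises the
    exclusion rule; species s1 and s3 meet in the centre cell B2 with T+D+LH
    scores 9 and 3 (mean 6).  The single hotspot polygon covers the western
    column (A1, B1, C1) under the 50% inclusion rule.
    """
    traits = pd.DataFrame(
        [
            # id,   subfam,        tribe, genus, subgenus, species, status, fSA, fsA, nprov, endem, marg, mobility, trophic
            ("s1", "Mecopodinae", "", "GenA", "SgA", "alpha", "CR", 0.10, 0.10, 1, True, False, "flightless", "herbivorous_monophagous"),
            ("s2", "Conocephalinae", "", "GenB", "SgB", "beta", "LC", 0.80, 0.90, 9, False, False, "fully_flighted", "omnivorous"),
            ("s3", "Conocephalinae", "", "GenB", "SgC", "gamma", "VU", 0.20, 0.80, 3, False, False, "partial_or_one_sex", "predatory"),
            ("s4", "Mecopodinae", "", "GenC", "SgD", "delta", "EN", 0.10, 0.80, 1, False, True, "flightless", "herbivorous_polyphagous"),
            ("s5", "Phaneropterinae", "", "GenD", "SgE", "epsilon", "LC", 0.90, 0.90, 8, False, False, "flightless", "herbivorous_monophagous"),
            ("s6", "Phaneropterinae", "", "GenD", "SgE", "zeta", "DD", 0.50, 0.50, 2, False, False, "fully_flighted", "omnivorous"),
        ],
        columns=[
            "species_id", "subfamily", "tribe", "genus", "subgenus", "species",
            "status", "frac_SA", "frac_sA", "n_provinces", "endemic_to_SA",
            "marginal_in_SA", "mobility_class", "trophic_class",
        ],
    )
    occ = pd.DataFrame(
        [
            ("s1", 0.50, 1.50), ("s1", 0.55, 1.55), ("s1", 1.20, 1.50),
            ("s2", 0.50, 2.50), ("s2", 2.50, 2.50), ("s2", 1.50, 0.50),
            ("s2", 0.60, 0.60), ("s2", 2.60, 0.70),
            ("s3", 1.10, 1.90), ("s3", 0.50, 0.50), ("s3", 0.52, 0.48),
            ("s4", 0.80, 1.20), ("s4", 2.50, 0.50), ("s4", 2.55, 0.52),
            ("s5", 0.20, 2.20), ("s5", 0.25, 2.25),
        ],
        columns=["species_id", "lon", "lat"],
    )
    occ["date"] = ""
    occ["collector"] = ""
    region = box(0.0, 0.0, 3.0, 3.0)
    hotspot = box(0.0, 0.0, 1.2, 3.0)
    return {
        "traits": traits,
        "occurrences": occ,
        "region": region,
        "hotspot_polygons": [hotspot],
    }
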