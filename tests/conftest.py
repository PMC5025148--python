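import numpy as np
import pandas as pd
import pytest

from katydid_hotspots import gridding, range_metrics, scoring, synthetic


@pytest.fixture(scope="session")
def fixture_dataset():
    """The hand-built 6-species / 3x3-cell worked dataset."""
    return synthetic.worked_fixture()


@pytest.fixture(scope="session")
def sim_dataset():
    """One default synthetic dataset (seed 0), shared across tests."""
    return synthetic.simulate_dataset(synthetic.SimulationConfig(seed=0))


@pytest.fixture(scope="session")
def sim_metrics(sim_dataset):
    """Cell metrics computed from the shared synthetic dataset."""
    ds = sim_dataset
    scores = scoring.score_table(ds.traits)
    occ = ds.occurrences[ds.occurrences["species_id"].isin(scores["species_id"])]
    ranges = range_metrics.summarize_ranges(occ)
    grid = gridding.build_fishnet(ds.region)
    assigned, unassigned = gridding.assign_records(occ, grid)
    metrics = gridding.cell_metrics(assigned, scores, ranges, grid)
    return {
        "scores": scores,
        "ranges": ranges,
        "grid": grid,
        "assigned": assigned,
        "unassigned": unassigned,
        "metrics": metrics,
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(20160915)
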