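import numpy as np
import pandas as pd
import pytest

import gldm
from gldm.synth import default_substrate
from gldm.types import GroundTruth


@pytest.fixture(scope="session")
def small_scheme():
    """16^3 grid, 8 parcels: fast enough for per-test use."""
    return gldm.make_parcel_scheme((16, 16, 16), 8, seed=1)


@pytest.fixture(scope="session")
def default_scheme():
    """The default 64-parcel scheme used by the full analyses."""
    return gldm.make_parcel_scheme((20, 20, 20), 64, seed=5)


@pytest.fixture(scope="session")
def small_cohort(small_scheme):
    """40 patients + 20 controls on the small scheme, moderate effect."""
    truth = GroundTruth(
        substrate_parcels=default_substrate(small_scheme, 2),
        effect_beta=30.0,
        noise_sd=5.0,
    )
    masks, cohort = gldm.simulate_cohort(
        small_scheme, truth, n_patients=40, n_controls=20, seed=11
    )
    return truth, masks, cohort


def toy_graph(edge_rows, n_nodes=None, n_patients=10):
    """LayeredGraph from (j, k, support, w_les, w_def) tuples."""
    edges = pd.DataFrame(
        edge_rows, columns=["j", "k", "support", "w_les", "w_def"]
    )
    nodes = (
        np.arange(1, n_nodes + 1)
        if n_nodes
        else np.unique(edges[["j", "k"]].to_numpy())
    )
    return gldm.LayeredGraph(nodes=nodes, edges=edges, n_patients=n_patients)


def random_layered_graph(n, seed, p=0.5, n_patients=50):
    """Random graph with integer supports and gaussian deficit weights."""
    rng = np.random.default_rng(seed)
    rows = []
    for j in range(1, n + 1):
        for k in range(j + 1, n + 1):
            if rng.random() < p:
                sup = int(rng.integers(2, 10))
                rows.append((j, k, sup, sup / n_patients, rng.normal()))
    if not rows:
        rows = [(1, 2, 2, 2 / n_patients, 0.0)]
    return toy_graph(rows, n_nodes=n, n_patients=n_patients)
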