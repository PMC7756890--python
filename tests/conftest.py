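import numpy as np
import pytest
import scipy.sparse as sp

from raresig import ClusterLabels, ScCounts, SimConfig


@pytest.fixture
def toy_counts():
    """3 genes x 4 cells; cells c2, c3 form the target cluster 'mast'.

    gA: 5 reads in c0, 2 and 3 in the target cells -> fraction 0.5, min 2
    gB: expressed only inside the target cluster -> fraction 1.0
    gC: zero reads everywhere -> fraction 0, undefined min
    """
    dense = np.array(
        [
            [5, 0, 2, 3],
            [0, 0, 4, 0],
            [0, 0, 0, 0],
        ]
    )
    return ScCounts(
        genes=["gA", "gB", "gC"],
        cells=["c0", "c1", "c2", "c3"],
        counts=sp.csr_matrix(dense),
    )


@pytest.fixture
def toy_labels():
    return ClusterLabels(
        assignment={"c0": "epi", "c1": "epi", "c2": "mast", "c3": "mast"},
        target_cluster="mast",
    )


def small_sim_config(seed: int = 0, **overrides) -> SimConfig:
    """A scaled-down study for fast unit/property tests."""
    params = dict(
        n_cells=800,
        n_genes=400,
        cluster_names=("epithelial", "lymphocyte", "mast"),
        cluster_proportions=(0.90, 0.08, 0.02),
        markers_per_cluster=8,
        n_bulk_samples=15,
        bulk_depth=200_000,
        seed=seed,
    )
    params.update(overrides)
    return SimConfig(**params)


@pytest.fixture
def small_config():
    return small_sim_config()
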