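import logging

import pytest

from ddgnet.sim import SimConfig, simulate_population

logging.getLogger("ddgnet").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def default_population():
    """One desk-scale synthetic population shared across tests (seed 1)."""
    return simulate_population(SimConfig(seed=1))


@pytest.fixture(scope="session")
def default_pseudobulk(default_population):
    from ddgnet.qc import pseudobulk_pipeline

    counts, _, _, _ = default_population
    return pseudobulk_pipeline(counts)


@pytest.fixture(scope="session")
def default_trajectories(default_population):
    from ddgnet import qc
    from ddgnet.trajectory import compute_reduced_space, infer_lineages

    counts, _, _, _ = default_population
    filtered = qc.filter_genes_min_cells(qc.filter_cells(counts))
    pca = compute_reduced_space(filtered, seed=1)
    traj = infer_lineages(pca, filtered.cell_meta["cluster_label"], "MPC")
    return filtered, traj
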