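import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

import stigma


def make_annotated(counts, clusters, stages=None, pseudotime=None, **extra):
    """Small AnnotatedMatrix helper for unit tests."""
    counts = np.asarray(counts)
    n_cells, n_genes = counts.shape
    meta = pd.DataFrame({
        "cell_id": [f"c{i}" for i in range(n_cells)],
        "cluster": clusters,
        "stage": stages if stages is not None else ["E9.5"] * n_cells,
    })
    if pseudotime is not None:
        meta["pseudotime"] = pseudotime
    for key, vals in extra.items():
        meta[key] = vals
    return stigma.AnnotatedMatrix(
        counts=sp.csr_matrix(counts),
        cell_meta=meta,
        gene_ids=np.array([f"g{j}" for j in range(n_genes)], dtype=object),
    )


@pytest.fixture(scope="session")
def default_sim():
    """The default synthetic scenario: 3 clusters x 300 cells; 100 labeled
    disease-like, 100 held-out disease-like, 300 housekeeping, 500 noise."""
    return stigma.simulate_dataset(stigma.SimulationConfig(seed=1))


@pytest.fixture(scope="session")
def default_inputs(default_sim):
    qc = stigma.QCConfig()
    am = stigma.qc_filter(default_sim.am, qc)
    am = stigma.cluster_fraction_filter(am, qc)
    am = stigma.normalize(am)
    props = stigma.merge_properties(default_sim.constraints,
                                    all_genes=list(am.gene_ids))
    classes = stigma.build_training_classes(
        default_sim.disease_genes, default_sim.housekeeping_genes,
        default_sim.reference, props,
    )
    return am, props, classes


@pytest.fixture(scope="session")
def full_fit(default_inputs):
    """Full-feature pipeline fit on the default scenario, grid search included."""
    am, props, classes = default_inputs
    model = stigma.StigmaModel.from_annotated_matrix(am, props, classes, seed=1)
    return model.fit(seed=1)


@pytest.fixture(scope="session")
def small_normalized():
    """Deterministic 60-cell, 8-gene, 2-cluster normalized matrix."""
    rng = np.random.default_rng(7)
    counts = rng.poisson(2.0, size=(60, 8))
    counts[:, 7] = 0  # an entirely silent gene
    am = make_annotated(
        counts,
        clusters=["A"] * 30 + ["B"] * 30,
        stages=["E9.5"] * 15 + ["E10.5"] * 15 + ["E9.5"] * 15 + ["E10.5"] * 15,
        pseudotime=rng.uniform(0, 1, 60),
    )
    return stigma.normalize(am)
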