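import numpy as np
import pytest
import scipy.sparse as sp

from thalseq import (
    CountMatrix,
    PipelineConfig,
    SimulationSpec,
    normalize_cpt,
    simulate_progenitor_field,
)


@pytest.fixture(scope="session")
def config():
    return PipelineConfig()


@pytest.fixture(scope="session")
def progenitor_dataset():
    """Hard-boundary five-domain dataset shared across read-only tests."""
    return simulate_progenitor_field(SimulationSpec(rng_seed=0, n_cells_control=600))


@pytest.fixture(scope="session")
def progenitor_logcpt(progenitor_dataset, config):
    return normalize_cpt(progenitor_dataset.counts, config, log1p=True)


@pytest.fixture()
def tiny_counts():
    """3 genes x 4 cells with hand-checkable sums."""
    X = sp.csr_matrix(
        np.array([[5, 0, 2, 0], [0, 3, 0, 0], [1, 1, 1, 1]], dtype=int)
    )
    return CountMatrix(X, ["Xkr4", "Actb", "mt-Nd1"], ["AAAC", "AAAG", "AAAT", "AACA"])


def truth_gene_sets(spec: SimulationSpec | None = None):
    """Label -> generating marker genes, the oracle mapping for assign_cells."""
    spec = spec or SimulationSpec()
    return {d.name: list(d.genes) for d in spec.domains}
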