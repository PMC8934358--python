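import numpy as np
import pytest

import metabind as mb


@pytest.fixture
def toy_graph() -> mb.WeightedHeteroGraph:
    """Two drugs, two targets: DD(d1,d2)=0.5, TT(t1,t2)=0.4,
    A(d1,t1)=0.9, A(d2,t1)=0.8, all other affinity edges absent."""
    dd = np.array([[0.0, 0.5], [0.5, 0.0]])
    tt = np.array([[0.0, 0.4], [0.4, 0.0]])
    dt = np.array([[0.9, 0.0], [0.8, 0.0]])
    return mb.WeightedHeteroGraph(dd=dd, tt=tt, dt=dt, edge_mask=dt > 0)


def random_graph(rng: np.random.Generator, n_max: int = 8, density: float = 0.6):
    """A random valid heterogeneous graph for oracle-equivalence checks."""
    n, m = rng.integers(2, n_max + 1, 2)
    dd = rng.random((n, n)) * (rng.random((n, n)) < density)
    dd = np.triu(dd, 1)
    dd = dd + dd.T
    tt = rng.random((m, m)) * (rng.random((m, m)) < density)
    tt = np.triu(tt, 1)
    tt = tt + tt.T
    dt = rng.random((n, m)) * (rng.random((n, m)) < density)
    return mb.WeightedHeteroGraph(dd=dd, tt=tt, dt=dt, edge_mask=dt > 0)


@pytest.fixture
def small_synthetic() -> mb.SyntheticData:
    """A small, fast synthetic dataset for pipeline-level tests."""
    return mb.generate(
        mb.SyntheticSpec(n_drugs=25, m_targets=20, latent_dim=4, noise_sd=0.3, seed=7)
    )


@pytest.fixture
def pipeline_data(small_synthetic) -> mb.PipelineData:
    d = small_synthetic
    return mb.PipelineData(
        dataset=d.dataset,
        drug_similarity=d.drug_similarity,
        target_similarity=d.target_similarity,
        smiles=d.smiles,
        proteins=d.proteins,
    )
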