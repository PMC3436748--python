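import numpy as np
import pytest

from intescreen import (MultiStudyCollection, SimulationConfig, StudyDataset,
                        build_collection, simulate_collection, standardize)


def make_study(rng, study_id="s1", n=20, genes=("a", "b", "c"), y=None,
               do_standardize=True):
    """A random standardized study with both response classes present."""
    X = rng.standard_normal((n, len(genes)))
    if y is None:
        y = rng.integers(0, 2, n)
        while y.sum() in (0, n):
            y = rng.integers(0, 2, n)
    ds = StudyDataset(study_id=study_id, X=X, y=np.asarray(y), gene_ids=list(genes))
    return standardize(ds) if do_standardize else ds


@pytest.fixture
def rng():
    return np.random.default_rng(20260919)


@pytest.fixture
def small_collection(rng):
    """4 standardized studies over the same 30 genes, n=25 each."""
    genes = [f"g{i:02d}" for i in range(30)]
    studies = [make_study(rng, f"s{m}", n=25, genes=genes) for m in range(4)]
    return build_collection(studies)


@pytest.fixture
def tiny_sim():
    """A small simulated collection with signal (d=500, 100 truth genes)."""
    cfg = SimulationConfig(n_m=40, n_clusters=10, c=0.6, rho=0.3, seed=42)
    coll, truth, alphas = simulate_collection(cfg)
    return cfg, coll, truth, alphas
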