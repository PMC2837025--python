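import matplotlib
import numpy as np
import pytest

matplotlib.use("Agg")

from pathpower.datatypes import ExpressionMatrix, StudyDataset, SurvivalData
from pathpower.simulate import SimulationSpec, simulate_study


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_cox_data(n, m, beta, seed, censor_scale=2.0):
    """Plain Cox-model draw used by estimation tests."""
    r = np.random.default_rng(seed)
    x = r.normal(size=(n, m))
    eta = x @ np.asarray(beta, dtype=float)
    u = r.exponential(np.exp(-eta))
    v = r.exponential(censor_scale, size=n)
    t = np.minimum(u, v)
    d = (u <= v).astype(float)
    if d.sum() == 0:  # pragma: no cover
        d[np.argmin(t)] = 1.0
    return x, t, d


@pytest.fixture
def small_survival():
    """The hand-worked logrank instance: times 1-4, all events,
    alternating groups."""
    surv = SurvivalData(["a", "b", "c", "d"], [1.0, 2.0, 3.0, 4.0], [1, 1, 1, 1])
    group = np.array([True, False, True, False])
    return group, surv


@pytest.fixture(scope="session")
def null_study():
    """One pure-noise 8-gene study of 100 samples."""
    spec = SimulationSpec(
        n_per_study=(100,), n_genes=8, pathway_sizes=(8,),
        signal_pathways=(), effect_size=0.0,
        gene_overlap_fraction=1.0, seed=42,
    )
    return simulate_study(spec, 0), spec.pathway_collection().entries["PW000"]


@pytest.fixture(scope="session")
def signal_study():
    """One strong-signal study: 2 of 10 genes at unit effect, n=200."""
    spec = SimulationSpec(
        n_per_study=(200,), n_genes=10, pathway_sizes=(10,),
        signal_pathways=(0,), genes_per_signal_pathway=2, effect_size=1.0,
        gene_overlap_fraction=1.0, seed=7,
    )
    return simulate_study(spec, 0), spec.pathway_collection().entries["PW000"]


def study_from_arrays(label, x, t, d):
    n, m = x.shape
    genes = [f"g{j}" for j in range(m)]
    samples = [f"{label}_s{i}" for i in range(n)]
    return StudyDataset(
        label,
        ExpressionMatrix(genes, samples, x.T.copy()),
        SurvivalData(samples, t, d),
    )
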