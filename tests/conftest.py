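import numpy as np
import pytest

from angiosig import ExpressionMatrix, SimulationConfig, generate_cohort
from angiosig.simulate import ClusterSpec, ReceptorMixture


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def small_cohort():
    """One modest synthetic cohort shared by read-only tests."""
    cfg = SimulationConfig(n_tumor=250, n_normal=20, n_background_genes=40, seed=7)
    expr, ann, truth = generate_cohort(cfg)
    return cfg, expr, ann, truth


def three_cluster_config(seed=0, n_tumor=300, sep=3.0, noise=0.8):
    """Well-separated 3-cluster config used by recovery tests."""
    clusters = [
        ClusterSpec("C1", 1 / 3, {"VEGFA": sep, "SEMA3B": -sep, "SEMA3C": -sep}),
        ClusterSpec("C2", 1 / 3, {"VEGFC": sep, "KDR": sep, "NRP1": sep}),
        ClusterSpec("C3", 1 / 3, {"FLT1": sep, "FLT4": sep, "SEMA3A": sep, "VEGFA": -sep}),
    ]
    return SimulationConfig(
        n_tumor=n_tumor, n_normal=0, n_background_genes=0,
        cluster_spec=clusters, noise_sd=noise, seed=seed,
    )


def toy_matrix(values, genes=None, samples=None):
    values = np.asarray(values, dtype=float)
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    samples = samples or [f"s{j}" for j in range(values.shape[1])]
    return ExpressionMatrix(values, genes, samples)
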