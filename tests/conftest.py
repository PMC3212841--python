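import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import lgtnet as L

settings.register_profile(
    "ci", derandomize=True, deadline=None, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def five_leaf():
    return L.parse_newick("((A,B)0.99,(C,D)0.97,E);")


@pytest.fixture
def species12(rng):
    return L.simulate_species_tree(12, rng, branch_scale=0.03)


@pytest.fixture(scope="session")
def species12_session():
    return L.simulate_species_tree(12, np.random.default_rng(99),
                                   branch_scale=0.03)


@pytest.fixture(scope="session")
def tiny_run(tmp_path_factory):
    """A small end-to-end pipeline run shared by pipeline/CLI tests."""
    from lgtnet.pipeline import PipelineConfig, run_pipeline

    out = tmp_path_factory.mktemp("tiny_run")
    cfg = PipelineConfig(seed=3, n_permutations=100, k_global=4,
                         mrp_restarts=4)
    cfg.sim.n_families = 24
    cfg.sim.n_strains = 12
    cfg.sim.family_size_max = 12
    cfg.sim.n_tfs = 24
    cfg.sim.n_targets = 120
    cfg.sim.n_edges = 400
    cfg.sim.k_global = 4
    cfg.sim.n_heterodimer_global = 1
    cfg.sim.n_neighbour = 10
    summary = run_pipeline(cfg, out)
    return cfg, out, summary
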