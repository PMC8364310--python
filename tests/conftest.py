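import numpy as np
import pytest

import ddis


@pytest.fixture(scope="session")
def chain_gt():
    """6-node planted chain in the left hemisphere, mirrored null right."""
    return ddis.chain_ground_truth(n_nodes=6, beta1=0.5, alpha1=0.5, rng_seed=11)


@pytest.fixture(scope="session")
def chain_cohort(chain_gt):
    return ddis.simulate_cohort(chain_gt, n_subjects=120, rng_seed=12)


@pytest.fixture(scope="session")
def chain_backbone(chain_cohort):
    return ddis.build_backbone(chain_cohort)


@pytest.fixture(scope="session")
def chain_seeds(chain_cohort):
    pos = ddis.call_positivity(chain_cohort.node_signal_matrix("tau_suvr"), 1.23)
    prev = ddis.compute_prevalence(pos)
    return ddis.select_seeds(prev, chain_cohort.parcellation)


@pytest.fixture()
def md_config():
    return ddis.DdisConfig(metric="md", alpha=0.05)


@pytest.fixture(scope="session")
def cohort_dir(tmp_path_factory, chain_cohort):
    """The four input tables of the chain cohort on disk."""
    d = tmp_path_factory.mktemp("cohort")
    ddis.write_cohort(chain_cohort, d)
    return d


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2026)
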