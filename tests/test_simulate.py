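"""Generator contracts: determinism, validity, nulls, parameter recovery."""

import numpy as np
import pytest
from scipy import stats

import ddis

from helpers import ols_oracle


def test_template_graph_shapes_and_determinism():
    parc, edges = ddis.make_template_graph(42, model="desikan84", rng_seed=5)
    assert parc.n_rois == 84
    assert len(parc.hemisphere_ids("left")) == 42
    assert parc.off_target.sum() == 8  # four basal-ganglia ROIs per hemisphere
    parc2, edges2 = ddis.make_template_graph(42, model="desikan84", rng_seed=5)
    assert edges == edges2
    np.testing.assert_array_equal(parc.sizes, parc2.sizes)


def test_template_graph_connected_per_hemisphere():
    import networkx as nx

    parc, edges = ddis.make_template_graph(8, rng_seed=9)
    for hemi in ("left", "right"):
        ids = set(parc.hemisphere_ids(hemi).tolist())
        g = nx.Graph(e for e in edges if set(e) <= ids)
        g.add_nodes_from(ids)
        assert nx.is_connected(g)


def test_template_graph_minimum_size():
    parc, edges = ddis.make_template_graph(3, rng_seed=1)
    assert parc.n_rois == 6
    with pytest.raises(ValueError):
        ddis.make_template_graph(2, rng_seed=1)


def test_simulate_deterministic(chain_gt):
    a = ddis.simulate_cohort(chain_gt, 30, rng_seed=77)
    b = ddis.simulate_cohort(chain_gt, 30, rng_seed=77)
    np.testing.assert_array_equal(
        a.node_signal_matrix("tau_suvr"), b.node_signal_matrix("tau_suvr")
    )
    for sa, sb in zip(a.subjects, b.subjects):
        np.testing.assert_array_equal(sa.conn_counts, sb.conn_counts)
        np.testing.assert_array_equal(
            sa.edge_metric["md"], sb.edge_metric["md"], err_msg=sa.subject_id
        )


def test_all_outputs_pass_validation():
    gt = ddis.default_ground_truth(rng_seed=3)
    cohort = ddis.simulate_cohort(gt, 20, rng_seed=4)
    assert ddis.validate_cohort(cohort) == []


def test_null_cohort_has_no_planted_correlation(chain_gt):
    cohort = ddis.simulate_null_cohort(chain_gt, 400, rng_seed=41)
    tau = cohort.node_signal_matrix("tau_suvr")
    link = chain_gt.links[0]
    md = cohort.edge_values("md", link.up, link.down)
    r = np.corrcoef(tau[:, link.up], md)[0, 1]
    assert abs(r) < 3 / np.sqrt(400)


def test_null_prevalence_flat_outside_elevated(chain_gt):
    cohort = ddis.simulate_null_cohort(chain_gt, 200, rng_seed=42)
    prev = ddis.compute_prevalence(
        ddis.call_positivity(cohort.node_signal_matrix("tau_suvr"), 1.23)
    )
    background = [
        i for i in range(cohort.parcellation.n_rois) if i not in chain_gt.elevated_rois
    ]
    assert prev.values[background].max() < 0.15


def test_planted_slope_ci_coverage():
    """The recorded natural-unit slope is the true generative slope: OLS
    95% CIs on the first planted link cover it at nominal rate."""
    gt = ddis.chain_ground_truth(n_nodes=3, beta1=0.5, alpha1=0.5, rng_seed=55)
    link = gt.links[0]
    hits = 0
    n_rep = 100
    for rep in range(n_rep):
        cohort = ddis.simulate_cohort(gt, 200, rng_seed=1000 + rep)
        tau = cohort.node_signal_matrix("tau_suvr")
        md = cohort.edge_values("md", link.up, link.down)
        cov = cohort.covariate_matrix()
        ora = ols_oracle(md, np.column_stack([tau[:, link.up], cov]))
        half = stats.t.ppf(0.975, 200 - 4) * ora["stderr"]
        if abs(ora["coef"] - link.slope_up_natural) <= half:
            hits += 1
    assert hits >= 93


def test_metric_channels_independent_by_default(chain_gt):
    """Only the configured channel carries the planted signal; a non-target
    channel on the same edge stays null."""
    cohort = ddis.simulate_cohort(chain_gt, 300, rng_seed=60)
    link = chain_gt.links[0]
    tau = cohort.node_signal_matrix("tau_suvr")[:, link.up]
    fa = cohort.edge_values("fa", link.up, link.down)
    md = cohort.edge_values("md", link.up, link.down)
    assert abs(np.corrcoef(tau, fa)[0, 1]) < 3 / np.sqrt(300)
    assert np.corrcoef(tau, md)[0, 1] > 0.3


def test_chain_rejects_cross_hemisphere():
    parc, edges = ddis.make_template_graph(4, rng_seed=2)
    with pytest.raises(ValueError, match="one hemisphere"):
        ddis.build_ground_truth(parc, edges, chains=((0, 5),))
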