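"""The iterative search: candidate rules, termination, oracle equivalence."""

import numpy as np
import pytest

import ddis
from ddis.node_signal import SeedSet

from helpers import brute_force_ddis


def _seeds(ids):
    return SeedSet(roi_ids=frozenset(ids), threshold=None, provenance="explicit")


@pytest.fixture(scope="module")
def star_setup():
    """Star template: center (roi 0) planted toward three spokes."""
    names = ("hub", "s1", "s2", "s3")
    parc = ddis.Parcellation(
        names=names * 2,
        hemispheres=("left",) * 4 + ("right",) * 4,
        sizes=np.full(8, 2000.0),
        off_target=np.zeros(8, dtype=bool),
    )
    edges = [(0, 1), (0, 2), (0, 3), (4, 5), (4, 6), (4, 7)]
    gt = ddis.build_ground_truth(
        parc, edges, chains=((0, 1), (0, 2), (0, 3)),
        beta1=0.8, alpha1=0.8, rng_seed=21,
    )
    cohort = ddis.simulate_cohort(gt, 150, rng_seed=22)
    backbone = ddis.build_backbone(cohort)
    return gt, cohort, backbone


def test_star_graph_three_pathways(star_setup):
    gt, cohort, backbone = star_setup
    cfg = ddis.DdisConfig(metric="md")
    pattern = ddis.run_ddis(cohort, backbone, _seeds({0}), cfg)
    assert pattern.pathway_pairs == {(0, 1), (0, 2), (0, 3)}
    assert all(p.iteration == 1 for p in pattern.pathways)
    # spokes become seeds; iteration 2 has no candidates left
    assert pattern.seed_history["left"][-1] == frozenset({0, 1, 2, 3})


def test_seed_seed_connections_excluded(star_setup):
    _, cohort, backbone = star_setup
    cfg = ddis.DdisConfig(metric="md")
    pattern = ddis.run_ddis(cohort, backbone, _seeds({0, 1, 2, 3}), cfg)
    assert pattern.pathways == []
    assert pattern.tested_connections == []


def test_destination_seeded_once_but_both_pathways_kept():
    """Two seeds pointing at one destination record two pathways and seed
    the destination once."""
    names = ("a", "b", "c")
    parc = ddis.Parcellation(
        names=names * 2,
        hemispheres=("left",) * 3 + ("right",) * 3,
        sizes=np.full(6, 2000.0),
        off_target=np.zeros(6, dtype=bool),
    )
    # a-c and b-c edges; both a->c and b->c planted via separate chains
    gt = ddis.build_ground_truth(
        parc, [(0, 2), (1, 2)], chains=((0, 2),), beta1=0.9, alpha1=0.9, rng_seed=31,
    )
    cohort = ddis.simulate_cohort(gt, 200, rng_seed=32)
    # wire b to mirror a (same tau, same edge metric) so b->c is significant too
    for s in cohort.subjects:
        s.node_signal["tau_suvr"][1] = s.node_signal["tau_suvr"][0]
        for m in s.edge_metric.values():
            m[1, 2] = m[2, 1] = m[0, 2]
    backbone = ddis.build_backbone(cohort)
    cfg = ddis.DdisConfig(metric="md")
    pattern = ddis.run_ddis(cohort, backbone, _seeds({0, 1}), cfg)
    assert pattern.pathway_pairs == {(0, 2), (1, 2)}
    history = pattern.seed_history["left"]
    assert history[-1] == frozenset({0, 1, 2})


def test_empty_seed_set_yields_empty_pattern(chain_cohort, chain_backbone, md_config):
    pattern = ddis.run_ddis(chain_cohort, chain_backbone, _seeds(set()), md_config)
    assert pattern.pathways == []


def test_chain_recovered_in_order(chain_gt, chain_cohort, chain_backbone, chain_seeds, md_config):
    pattern = ddis.run_ddis(chain_cohort, chain_backbone, chain_seeds, md_config)
    found = {(p.up_roi, p.down_roi): p.iteration for p in pattern.pathways}
    planted = {(l.up, l.down) for l in chain_gt.links}
    assert set(found) == planted
    assert [found[(i, i + 1)] for i in range(5)] == [1, 2, 3, 4, 5]


def test_iteration_count_bounded(chain_cohort, chain_backbone, chain_seeds, md_config):
    pattern = ddis.run_ddis(chain_cohort, chain_backbone, chain_seeds, md_config)
    n_non_seed = chain_cohort.parcellation.n_rois - len(chain_seeds.roi_ids)
    assert pattern.n_iterations <= n_non_seed


def test_matches_brute_force_reference(chain_cohort, chain_backbone, chain_seeds, md_config):
    pattern = ddis.run_ddis(chain_cohort, chain_backbone, chain_seeds, md_config)
    ref = brute_force_ddis(chain_cohort, chain_backbone, chain_seeds.roi_ids, md_config)
    assert {(p.up_roi, p.down_roi): p.iteration for p in pattern.pathways} == ref


def test_alpha_monotone_on_fixed_data(chain_cohort, chain_backbone, chain_seeds):
    small = ddis.run_ddis(
        chain_cohort, chain_backbone, chain_seeds, ddis.DdisConfig(metric="md", alpha=0.01)
    )
    large = ddis.run_ddis(
        chain_cohort, chain_backbone, chain_seeds, ddis.DdisConfig(metric="md", alpha=0.05)
    )
    assert small.pathway_pairs <= large.pathway_pairs


def test_subject_order_invariance(chain_cohort, chain_backbone, chain_seeds, md_config, rng):
    perm = rng.permutation(chain_cohort.n_subjects).tolist()
    shuffled = chain_cohort.resample(perm, suffix="p")
    a = ddis.run_ddis(chain_cohort, chain_backbone, chain_seeds, md_config)
    b = ddis.run_ddis(shuffled, chain_backbone, chain_seeds, md_config)
    assert a.pathway_pairs == b.pathway_pairs
    assert {p.iteration for p in a.pathways} == {p.iteration for p in b.pathways}


def test_pooled_mode_crosses_hemispheres(star_setup):
    """With hemisphere_mode=pooled an inter-hemispheric edge is a legal
    candidate; with separate mode it never is."""
    gt, cohort, backbone = star_setup
    cfg_sep = ddis.DdisConfig(metric="md", hemisphere_mode="separate")
    pattern = ddis.run_ddis(cohort, backbone, _seeds({0, 4}), cfg_sep)
    tested = {(t["up_roi"], t["down_roi"]) for t in pattern.tested_connections}
    parc = cohort.parcellation
    assert all(
        parc.hemispheres[u] == parc.hemispheres[d] for u, d in tested
    )


def test_summarize_pattern_conservation(chain_cohort, chain_backbone, chain_seeds, md_config):
    pattern = ddis.run_ddis(chain_cohort, chain_backbone, chain_seeds, md_config)
    df = ddis.summarize_pattern(pattern)
    totals = df[df["iteration"] == "all"].iloc[0]
    per_iter = df[df["iteration"] != "all"]
    assert per_iter["n_pathways"].sum() == totals["n_pathways"] == len(pattern.pathways)
    assert totals["n_increase"] + totals["n_decrease"] == totals["n_pathways"]


def test_summarize_empty_pattern(chain_cohort, md_config):
    empty = ddis.AssociationPattern(
        pathways=[], seed_history={}, tested_connections=[],
        config=md_config, parcellation=chain_cohort.parcellation,
    )
    df = ddis.summarize_pattern(empty)
    assert list(df["n_pathways"]) == [0]


def test_connection_conjunction_rule(chain_cohort):
    """Acceptance needs BOTH chained models under alpha; an alpha between
    the two p-values rejects even though one model passes."""
    ct = ddis.test_connection(chain_cohort, 0, 1, metric="md", alpha=0.05)
    assert ct.accepted and ct.test_up.p < 0.05 and ct.test_down.p < 0.05
    between = (min(ct.test_up.p, ct.test_down.p) + max(ct.test_up.p, ct.test_down.p)) / 2
    ct_mid = ddis.test_connection(chain_cohort, 0, 1, metric="md", alpha=between)
    assert not ct_mid.accepted
    # pure-noise edge in the unplanted hemisphere at vanishing alpha
    ct_null = ddis.test_connection(chain_cohort, 6, 7, metric="md", alpha=1e-9)
    assert not ct_null.accepted
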