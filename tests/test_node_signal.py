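"""Positivity calling, prevalence maps and seed selection."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import ddis
from ddis.cohort import Parcellation


def _parc(n=3):
    return Parcellation(
        names=tuple(f"r{i}" for i in range(n)) * 2,
        hemispheres=("left",) * n + ("right",) * n,
        sizes=np.ones(2 * n),
        off_target=np.zeros(2 * n, dtype=bool),
    )


def test_positivity_comparators():
    vals = np.array([[1.30, 1.23, 1.0]])
    assert ddis.call_positivity(vals, 1.23).tolist() == [[True, False, False]]
    assert ddis.call_positivity(vals, 1.23, strict=False).tolist() == [[True, True, False]]
    assert ddis.call_positivity(vals, -1e9).all()


def test_positivity_rejects_missing():
    with pytest.raises(ValueError, match="missing"):
        ddis.call_positivity(np.array([[1.0, np.nan]]), 1.23)


def test_prevalence_fraction():
    suvr = np.array([[1.3], [1.1], [1.5], [1.0], [1.25]])
    prev = ddis.compute_prevalence(ddis.call_positivity(suvr, 1.23))
    assert prev.values[0] == pytest.approx(0.6)
    allpos = ddis.compute_prevalence(np.ones((4, 2), dtype=bool))
    assert np.all(allpos.values == 1.0)


@settings(deadline=None, derandomize=True)
@given(
    st.integers(2, 30).flatmap(
        lambda n: st.lists(
            st.lists(st.floats(0.5, 2.5), min_size=4, max_size=4),
            min_size=n, max_size=n,
        )
    ),
    st.floats(0.6, 2.0),
    st.floats(0.0, 0.4),
)
def test_prevalence_monotone_in_cutoff(rows, cutoff, bump):
    vals = np.array(rows)
    lo = ddis.compute_prevalence(ddis.call_positivity(vals, cutoff)).values
    hi = ddis.compute_prevalence(ddis.call_positivity(vals, cutoff + bump)).values
    assert np.all(hi <= lo)


def test_select_seeds_strictly_greater():
    parc = _parc(3)
    prev = ddis.PrevalenceMap(
        values=np.array([0.9, 0.8, 0.5, 0.1, 0.85, 0.0]),
        signal="tau_suvr", cutoff=1.23, n_subjects=20,
    )
    seeds = ddis.select_seeds(prev, parc, 0.8)
    assert seeds.roi_ids == frozenset({0, 4})  # 0.8 itself excluded
    assert seeds.partition(parc) == {"left": frozenset({0}), "right": frozenset({4})}


def test_select_seeds_invariant_to_subject_order(rng):
    vals = rng.uniform(0.8, 2.0, (40, 6))
    parc = _parc(3)
    perm = rng.permutation(40)
    a = ddis.select_seeds(
        ddis.compute_prevalence(ddis.call_positivity(vals, 1.23)), parc
    )
    b = ddis.select_seeds(
        ddis.compute_prevalence(ddis.call_positivity(vals[perm], 1.23)), parc
    )
    assert a.roi_ids == b.roi_ids


def test_explicit_seed_list():
    parc = _parc(3)
    seeds = ddis.seeds_from_names(parc, ["r1"])
    assert seeds.roi_ids == frozenset({1, 4})
    assert seeds.provenance == "explicit"
    with pytest.raises(KeyError):
        ddis.seeds_from_names(parc, ["missing"])


def test_planted_rois_dominate_prevalence(chain_gt, chain_cohort):
    """Severity-elevated chain roots reach far higher tau+ prevalence than
    background ROIs (the generator's prevalence-gradient contract)."""
    prev = ddis.compute_prevalence(
        ddis.call_positivity(chain_cohort.node_signal_matrix("tau_suvr"), 1.23)
    )
    elevated = sorted(chain_gt.elevated_rois)
    background = [i for i in range(chain_cohort.parcellation.n_rois) if i not in elevated]
    assert prev.values[elevated].min() > 0.8
    assert prev.values[background].max() < 0.3
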