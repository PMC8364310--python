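"""Round-trip, validation, and pathway-table contracts of the data layer."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

import ddis
from ddis.cohort import CohortLoadError


def _assert_cohorts_equal(a: ddis.Cohort, b: ddis.Cohort):
    assert a.parcellation.names == b.parcellation.names
    assert a.parcellation.hemispheres == b.parcellation.hemispheres
    np.testing.assert_allclose(a.parcellation.sizes, b.parcellation.sizes)
    assert a.n_subjects == b.n_subjects
    for sa, sb in zip(a.subjects, b.subjects):
        assert sa.subject_id == sb.subject_id
        assert (sa.age, sa.sex, sa.group) == (sb.age, sb.sex, sb.group)
        for sig in sa.node_signal:
            np.testing.assert_allclose(sa.node_signal[sig], sb.node_signal[sig])
        np.testing.assert_allclose(sa.conn_counts, sb.conn_counts)
        assert sa.total_streamlines == pytest.approx(sb.total_streamlines)
        for m in sa.edge_metric:
            np.testing.assert_allclose(
                sa.edge_metric[m], sb.edge_metric[m], equal_nan=True
            )


def test_write_load_round_trip(chain_cohort, tmp_path):
    paths = ddis.write_cohort(chain_cohort, tmp_path)
    loaded = ddis.load_cohort(
        paths["subjects"], paths["nodes"], paths["edges"], paths["parcellation"]
    )
    _assert_cohorts_equal(chain_cohort, loaded)


def test_load_rejects_self_connection(cohort_dir, tmp_path):
    edges = pd.read_csv(cohort_dir / "edges.tsv", sep="\t")
    bad = edges.copy()
    bad.loc[0, ["roi_j", "hemi_j"]] = bad.loc[0, ["roi_i", "hemi_i"]].to_numpy()
    bad_path = tmp_path / "edges.tsv"
    bad.to_csv(bad_path, sep="\t", index=False)
    with pytest.raises(CohortLoadError, match="self-connection"):
        ddis.load_cohort(
            cohort_dir / "subjects.tsv", cohort_dir / "nodes.tsv",
            bad_path, cohort_dir / "parcellation.tsv",
        )


def test_load_reports_missing_node_rows(cohort_dir, tmp_path):
    nodes = pd.read_csv(cohort_dir / "nodes.tsv", sep="\t")
    bad_path = tmp_path / "nodes.tsv"
    nodes.iloc[1:].to_csv(bad_path, sep="\t", index=False)
    with pytest.raises(CohortLoadError, match="incomplete|missing"):
        ddis.load_cohort(
            cohort_dir / "subjects.tsv", bad_path,
            cohort_dir / "edges.tsv", cohort_dir / "parcellation.tsv",
        )


def test_load_rejects_missing_columns(cohort_dir, tmp_path):
    subj = pd.read_csv(cohort_dir / "subjects.tsv", sep="\t").drop(columns=["age"])
    bad_path = tmp_path / "subjects.tsv"
    subj.to_csv(bad_path, sep="\t", index=False)
    with pytest.raises(CohortLoadError, match="age"):
        ddis.load_cohort(
            bad_path, cohort_dir / "nodes.tsv",
            cohort_dir / "edges.tsv", cohort_dir / "parcellation.tsv",
        )


def test_load_rejects_duplicate_edge_rows(cohort_dir, tmp_path):
    edges = pd.read_csv(cohort_dir / "edges.tsv", sep="\t")
    bad = pd.concat([edges, edges.iloc[[0]]], ignore_index=True)
    bad_path = tmp_path / "edges.tsv"
    bad.to_csv(bad_path, sep="\t", index=False)
    with pytest.raises(CohortLoadError, match="duplicate edge row"):
        ddis.load_cohort(
            cohort_dir / "subjects.tsv", cohort_dir / "nodes.tsv",
            bad_path, cohort_dir / "parcellation.tsv",
        )


def test_validate_clean_cohort_is_empty(chain_cohort):
    assert ddis.validate_cohort(chain_cohort) == []


@pytest.mark.parametrize(
    "mutate, expect",
    [
        (lambda s: s.conn_counts.__setitem__((0, 1), s.conn_counts[0, 1] + 1.0),
         "asymmetric"),
        (lambda s: s.conn_counts.__setitem__((0, 1), -3.0), "negative|asymmetric"),
        (lambda s: s.node_signal["tau_suvr"].__setitem__(2, np.nan), "missing"),
        (lambda s: s.edge_metric["md"].__setitem__((0, 5), 1.0), "where conn_counts is zero"),
    ],
    ids=["symmetry", "negative-count", "missing-node-signal", "metric-off-support"],
)
def test_validate_flags_injected_violations(chain_cohort, mutate, expect):
    import re

    cohort = ddis.Cohort(
        parcellation=chain_cohort.parcellation,
        subjects=[
            dataclasses.replace(
                s,
                node_signal={k: v.copy() for k, v in s.node_signal.items()},
                conn_counts=s.conn_counts.copy(),
                edge_metric={k: v.copy() for k, v in s.edge_metric.items()},
            )
            for s in chain_cohort.subjects
        ],
    )
    mutate(cohort.subjects[3])
    report = ddis.validate_cohort(cohort)
    assert len(report) >= 1
    assert any(re.search(expect, r) for r in report)
    assert all("sub003" in r for r in report)


def test_pathway_table_deterministic_and_ordered(
    chain_cohort, chain_backbone, chain_seeds, md_config, tmp_path
):
    pattern = ddis.run_ddis(chain_cohort, chain_backbone, chain_seeds, md_config)
    assert pattern.pathways, "expected a nonempty pattern on the planted chain"
    p1, p2 = tmp_path / "a.tsv", tmp_path / "b.tsv"
    ddis.write_pathway_table(pattern, p1)
    ddis.write_pathway_table(pattern, p2)
    assert p1.read_bytes() == p2.read_bytes()
    df = pd.read_csv(p1, sep="\t")
    assert list(df["iteration"]) == sorted(df["iteration"])


def test_empty_pathway_table_is_header_only(chain_cohort, md_config, tmp_path):
    empty = ddis.AssociationPattern(
        pathways=[], seed_history={}, tested_connections=[],
        config=md_config, parcellation=chain_cohort.parcellation,
    )
    path = tmp_path / "empty.tsv"
    df = ddis.write_pathway_table(empty, path)
    assert df.empty
    assert path.read_text().count("\n") == 1


def test_config_validation():
    with pytest.raises(ValueError):
        ddis.DdisConfig(alpha=1.5)
    with pytest.raises(ValueError):
        ddis.DdisConfig(metric="nope")
    with pytest.raises(ValueError):
        ddis.DdisConfig(backbone_fraction=0.0)
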