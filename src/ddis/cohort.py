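"""Data model and tabular I/O for DDIS cohorts.

A cohort bundles a brain parcellation (the ROI universe), per-subject
covariates, per-ROI node signals (tau-PET SUVR, amyloid centiloid), a
symmetric ROI x ROI streamline-count matrix per subject, and per-edge
diffusion metrics (FA, MD, Da, Dr, ICVF, OD).  All on-disk formats are
plain tab-separated tables; edges are stored long-format (one row per
subject x connected ROI pair) because diffusion metrics exist only on
connected pairs.

ROI identity on disk is the pair (roi_name, hemisphere); integer ids are
assigned on load in parcellation-table order and are file-local.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

HEMISPHERES = ("left", "right")
EDGE_METRICS = ("fa", "md", "da", "dr", "icvf", "od")
NODE_SIGNALS = ("tau_suvr", "amyloid_centiloid")
GROUPS = ("CN", "SCD", "MCI")


class CohortLoadError(ValueError):
    """Raised when an input table cannot be assembled into a valid cohort."""


@dataclass(frozen=True)
class Parcellation:
    """The ROI universe: names, hemispheres, sizes, off-target flags.

    ROI ids are the positions 0..n-1 in these arrays.  Off-target ROIs are
    basal-ganglia regions whose tau-PET signal reflects off-target tracer
    binding; they participate in the analysis like any other ROI and act as
    built-in negative controls.
    """

    names: tuple[str, ...]
    hemispheres: tuple[str, ...]
    sizes: np.ndarray
    off_target: np.ndarray

    def __post_init__(self) -> None:
        sizes = np.asarray(self.sizes, dtype=float)
        off = np.asarray(self.off_target, dtype=bool)
        object.__setattr__(self, "sizes", sizes)
        object.__setattr__(self, "off_target", off)
        n = len(self.names)
        if not (len(self.hemispheres) == sizes.shape[0] == off.shape[0] == n):
            raise ValueError("parcellation field lengths disagree")
        if any(h not in HEMISPHERES for h in self.hemispheres):
            raise ValueError(f"hemisphere labels must be in {HEMISPHERES}")
        if not np.all(sizes > 0):
            raise ValueError("ROI sizes must be positive")
        keys = list(zip(self.names, self.hemispheres))
        if len(set(keys)) != n:
            raise ValueError("duplicate (name, hemisphere) ROI keys")

    @property
    def n_rois(self) -> int:
        return len(self.names)

    @property
    def index(self) -> dict[tuple[str, str], int]:
        return {(n, h): i for i, (n, h) in enumerate(zip(self.names, self.hemispheres))}

    def hemisphere_ids(self, hemisphere: str) -> np.ndarray:
        """Ids of all ROIs in one hemisphere, ascending."""
        return np.array(
            [i for i, h in enumerate(self.hemispheres) if h == hemisphere], dtype=int
        )

    def roi_label(self, roi_id: int) -> str:
        return f"{self.hemispheres[roi_id][0].upper()}.{self.names[roi_id]}"

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "roi_name": self.names,
                "hemisphere": self.hemispheres,
                "size": self.sizes,
                "off_target": self.off_target.astype(int),
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "Parcellation":
        required = {"roi_name", "hemisphere", "size", "off_target"}
        missing = required - set(df.columns)
        if missing:
            raise CohortLoadError(f"parcellation table missing columns: {sorted(missing)}")
        return cls(
            names=tuple(df["roi_name"].astype(str)),
            hemispheres=tuple(df["hemisphere"].astype(str)),
            sizes=df["size"].to_numpy(dtype=float),
            off_target=df["off_target"].to_numpy().astype(bool),
        )


@dataclass
class SubjectRecord:
    """One participant: covariates, node signals, connectivity, edge metrics.

    ``node_signal`` maps signal name -> length-n_rois vector.
    ``conn_counts`` is the symmetric nonnegative streamline-count matrix with
    zero diagonal.  ``edge_metric`` maps metric name -> symmetric matrix with
    NaN wherever the metric is missing (always NaN off the connectivity
    support).  ``group`` (CN/SCD/MCI) is carried as metadata only; the search
    itself adjusts only for age and sex.
    """

    subject_id: str
    age: float
    sex: int
    group: str
    node_signal: dict[str, np.ndarray]
    conn_counts: np.ndarray
    total_streamlines: float
    edge_metric: dict[str, np.ndarray] = field(default_factory=dict)


@dataclass
class Cohort:
    parcellation: Parcellation
    subjects: list[SubjectRecord]

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    @property
    def ages(self) -> np.ndarray:
        return np.array([s.age for s in self.subjects], dtype=float)

    @property
    def sexes(self) -> np.ndarray:
        return np.array([s.sex for s in self.subjects], dtype=float)

    def covariate_matrix(self, names: Sequence[str] = ("age", "sex")) -> np.ndarray:
        """Subjects x covariates design block (no intercept)."""
        cols = []
        for name in names:
            if name == "age":
                cols.append(self.ages)
            elif name == "sex":
                cols.append(self.sexes)
            else:
                raise KeyError(f"unknown covariate {name!r}")
        return np.column_stack(cols) if cols else np.empty((self.n_subjects, 0))

    def node_signal_matrix(self, signal: str) -> np.ndarray:
        """Subjects x ROIs matrix of one node signal."""
        return np.vstack([s.node_signal[signal] for s in self.subjects])

    def edge_values(self, metric: str, i: int, j: int) -> np.ndarray:
        """Per-subject values of one edge metric on the (i, j) connection.

        NaN marks subjects where the metric is missing on that connection.
        """
        return np.array([s.edge_metric[metric][i, j] for s in self.subjects])

    def resample(self, indices: Sequence[int], suffix: str = "b") -> "Cohort":
        """Cohort of the subjects at ``indices`` (with repetition allowed)."""
        subjects = []
        for k, idx in enumerate(indices):
            s = self.subjects[idx]
            subjects.append(dataclasses.replace(s, subject_id=f"{s.subject_id}.{suffix}{k}"))
        return Cohort(parcellation=self.parcellation, subjects=subjects)


@dataclass
class DdisConfig:
    """Tunable knobs of the pathway search.

    metric            edge diffusion metric driving the run (one per run)
    signal            node signal regressed against the metric
    alpha             per-regression significance level; a connection is
                      accepted only when BOTH chained regressions pass
    positivity_cutoff signal units; tau SUVR 1.23 by convention
    seed_prevalence   positivity-prevalence fraction above which an ROI
                      seeds the search (strictly greater than)
    backbone_fraction backbone threshold as a fraction of the maximum
                      group-mean normalized streamline count
    covariates        nuisance regressors included in every model
    hemisphere_mode   'separate' runs each hemisphere independently and
                      drops inter-hemispheric edges; 'pooled' uses all edges
    size_correction   ROI-size correction of streamline counts
    strict_positivity use '>' (True) or '>=' (False) at the cutoff
    """

    metric: str = "md"
    signal: str = "tau_suvr"
    alpha: float = 0.05
    positivity_cutoff: float = 1.23
    seed_prevalence: float = 0.80
    backbone_fraction: float = 0.10
    covariates: tuple[str, ...] = ("age", "sex")
    hemisphere_mode: str = "separate"
    size_correction: str = "mean"
    strict_positivity: bool = True
    min_n: int = 5
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.metric not in EDGE_METRICS:
            raise ValueError(f"metric must be one of {EDGE_METRICS}, got {self.metric!r}")
        if self.signal not in NODE_SIGNALS:
            raise ValueError(f"signal must be one of {NODE_SIGNALS}, got {self.signal!r}")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if not 0 < self.seed_prevalence < 1:
            raise ValueError("seed_prevalence must be in (0, 1)")
        if not 0 < self.backbone_fraction < 1:
            raise ValueError("backbone_fraction must be in (0, 1)")
        if self.hemisphere_mode not in ("separate", "pooled"):
            raise ValueError("hemisphere_mode must be 'separate' or 'pooled'")
        if self.size_correction not in ("mean", "sum", "none"):
            raise ValueError("size_correction must be 'mean', 'sum' or 'none'")
        self.covariates = tuple(self.covariates)


# ---------------------------------------------------------------------------
# validation


def validate_cohort(cohort: Cohort) -> list[str]:
    """Check every structural invariant; return all violations (empty = valid).

    Reports rather than raises so callers can surface the complete list.
    """
    report: list[str] = []
    parc = cohort.parcellation
    n = parc.n_rois
    if cohort.n_subjects < 2 + 3:
        report.append(
            f"cohort has {cohort.n_subjects} subjects; need at least covariate count + 3"
        )
    seen_ids: set[str] = set()
    for s in cohort.subjects:
        tag = f"subject {s.subject_id!r}"
        if s.subject_id in seen_ids:
            report.append(f"{tag}: duplicate subject_id")
        seen_ids.add(s.subject_id)
        if s.sex not in (0, 1):
            report.append(f"{tag}: sex must be 0/1, got {s.sex!r}")
        for name, vec in s.node_signal.items():
            if vec.shape != (n,):
                report.append(f"{tag}: node signal {name!r} has length {vec.shape}, expected {n}")
            elif not np.all(np.isfinite(vec)):
                report.append(f"{tag}: node signal {name!r} has missing values")
        c = s.conn_counts
        if c.shape != (n, n):
            report.append(f"{tag}: conn_counts shape {c.shape}, expected {(n, n)}")
            continue
        asym = np.argwhere(c != c.T)
        if asym.size:
            i, j = asym[0]
            report.append(f"{tag}: conn_counts asymmetric at cell ({i}, {j})")
        if np.any(np.diag(c) != 0):
            report.append(f"{tag}: conn_counts diagonal must be zero")
        neg = np.argwhere(c < 0)
        if neg.size:
            i, j = neg[0]
            report.append(f"{tag}: negative streamline count at cell ({i}, {j})")
        if s.total_streamlines <= 0:
            report.append(f"{tag}: total_streamlines must be positive")
        for m, mat in s.edge_metric.items():
            if mat.shape != (n, n):
                report.append(f"{tag}: edge metric {m!r} shape {mat.shape}, expected {(n, n)}")
                continue
            bad = np.argwhere(np.isfinite(mat) & (c == 0))
            if bad.size:
                i, j = bad[0]
                report.append(
                    f"{tag}: edge metric {m!r} defined at ({i}, {j}) where conn_counts is zero"
                )
    return report


# ---------------------------------------------------------------------------
# readers / writers


def _require_columns(df: pd.DataFrame, cols: Iterable[str], table: str) -> None:
    missing = set(cols) - set(df.columns)
    if missing:
        raise CohortLoadError(f"{table} missing columns: {sorted(missing)}")


def load_cohort(
    subjects_table: str | Path,
    nodes_table: str | Path,
    edges_table: str | Path,
    parcellation_table: str | Path,
) -> Cohort:
    """Assemble a cohort from the four tab-separated input tables.

    Long-format edge rows are mirrored into symmetric matrices.  Raises
    :class:`CohortLoadError` on missing columns, ROI-set mismatches,
    self-connections, duplicate edge rows or incomplete node tables.
    """
    parc = Parcellation.from_frame(pd.read_csv(parcellation_table, sep="\t", float_precision="round_trip"))
    idx = parc.index
    n = parc.n_rois

    subj_df = pd.read_csv(subjects_table, sep="\t", dtype={"subject_id": str}, float_precision="round_trip")
    _require_columns(subj_df, ("subject_id", "age", "sex", "group"), "subjects table")
    if subj_df["subject_id"].duplicated().any():
        dup = subj_df.loc[subj_df["subject_id"].duplicated(), "subject_id"].iloc[0]
        raise CohortLoadError(f"duplicate subject_id {dup!r} in subjects table")

    nodes_df = pd.read_csv(nodes_table, sep="\t", dtype={"subject_id": str}, float_precision="round_trip")
    _require_columns(
        nodes_df,
        ("subject_id", "roi_name", "hemisphere") + tuple(NODE_SIGNALS),
        "nodes table",
    )
    edges_df = pd.read_csv(edges_table, sep="\t", dtype={"subject_id": str}, float_precision="round_trip")
    _require_columns(
        edges_df,
        ("subject_id", "roi_i", "hemi_i", "roi_j", "hemi_j", "streamline_count")
        + tuple(EDGE_METRICS),
        "edges table",
    )

    unknown = [
        (r, h)
        for r, h in zip(nodes_df["roi_name"], nodes_df["hemisphere"])
        if (r, h) not in idx
    ]
    if unknown:
        raise CohortLoadError(
            f"nodes table references ROIs absent from the parcellation: {sorted(set(unknown))[:5]}"
        )

    nodes_by_subj = dict(tuple(nodes_df.groupby("subject_id", sort=False)))
    edges_by_subj = dict(tuple(edges_df.groupby("subject_id", sort=False)))

    subjects: list[SubjectRecord] = []
    for row in subj_df.itertuples(index=False):
        sid = row.subject_id
        sub_nodes = nodes_by_subj.get(sid)
        if sub_nodes is None:
            raise CohortLoadError(f"nodes table has no rows for subject {sid!r}")
        keys = list(zip(sub_nodes["roi_name"], sub_nodes["hemisphere"]))
        if len(set(keys)) != len(keys):
            raise CohortLoadError(f"duplicate (subject, roi) node rows for subject {sid!r}")
        gaps = sorted(set(idx) - set(keys))
        if gaps:
            raise CohortLoadError(
                f"nodes table incomplete for subject {sid!r}: missing {gaps[:5]}"
            )
        signals: dict[str, np.ndarray] = {}
        order = np.array([idx[k] for k in keys])
        for sig in NODE_SIGNALS:
            vec = np.full(n, np.nan)
            vec[order] = sub_nodes[sig].to_numpy(dtype=float)
            signals[sig] = vec

        counts = np.zeros((n, n))
        metrics = {m: np.full((n, n), np.nan) for m in EDGE_METRICS}
        total = 0.0
        sub_edges = edges_by_subj.get(sid)
        if sub_edges is not None:
            seen_pairs: set[tuple[int, int]] = set()
            for e in sub_edges.itertuples(index=False):
                ki, kj = (e.roi_i, e.hemi_i), (e.roi_j, e.hemi_j)
                if ki not in idx or kj not in idx:
                    raise CohortLoadError(
                        f"edges table references unknown ROI {ki if ki not in idx else kj} "
                        f"for subject {sid!r}"
                    )
                i, j = idx[ki], idx[kj]
                if i == j:
                    raise CohortLoadError(
                        f"self-connection ({e.roi_i}, {e.hemi_i}) for subject {sid!r}"
                    )
                pair = (min(i, j), max(i, j))
                if pair in seen_pairs:
                    raise CohortLoadError(
                        f"duplicate edge row ({e.roi_i}-{e.roi_j}) for subject {sid!r}"
                    )
                seen_pairs.add(pair)
                counts[i, j] = counts[j, i] = e.streamline_count
                for m in EDGE_METRICS:
                    v = getattr(e, m)
                    if pd.notna(v):
                        metrics[m][i, j] = metrics[m][j, i] = float(v)
            if "total_streamlines" in sub_edges.columns:
                total = float(sub_edges["total_streamlines"].iloc[0])
        if total <= 0:
            total = float(counts.sum() / 2)
        subjects.append(
            SubjectRecord(
                subject_id=sid,
                age=float(row.age),
                sex=int(row.sex),
                group=str(row.group),
                node_signal=signals,
                conn_counts=counts,
                total_streamlines=total,
                edge_metric=metrics,
            )
        )

    cohort = Cohort(parcellation=parc, subjects=subjects)
    problems = validate_cohort(cohort)
    if problems:
        raise CohortLoadError("loaded cohort is invalid:\n" + "\n".join(problems))
    return cohort


def write_cohort(cohort: Cohort, out_dir: str | Path) -> dict[str, Path]:
    """Write the four input tables of a cohort; returns the file paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    parc = cohort.parcellation
    paths = {
        "parcellation": out / "parcellation.tsv",
        "subjects": out / "subjects.tsv",
        "nodes": out / "nodes.tsv",
        "edges": out / "edges.tsv",
    }
    parc.to_frame().to_csv(paths["parcellation"], sep="\t", index=False, float_format="%.17g")

    pd.DataFrame(
        {
            "subject_id": [s.subject_id for s in cohort.subjects],
            "age": [s.age for s in cohort.subjects],
            "sex": [s.sex for s in cohort.subjects],
            "group": [s.group for s in cohort.subjects],
        }
    ).to_csv(paths["subjects"], sep="\t", index=False, float_format="%.17g")

    node_rows = []
    edge_rows = []
    for s in cohort.subjects:
        for i in range(parc.n_rois):
            node_rows.append(
                {
                    "subject_id": s.subject_id,
                    "roi_name": parc.names[i],
                    "hemisphere": parc.hemispheres[i],
                    **{sig: s.node_signal[sig][i] for sig in NODE_SIGNALS},
                }
            )
        ii, jj = np.nonzero(np.triu(s.conn_counts, k=1))
        for i, j in zip(ii, jj):
            edge_rows.append(
                {
                    "subject_id": s.subject_id,
                    "roi_i": parc.names[i],
                    "hemi_i": parc.hemispheres[i],
                    "roi_j": parc.names[j],
                    "hemi_j": parc.hemispheres[j],
                    "streamline_count": s.conn_counts[i, j],
                    "total_streamlines": s.total_streamlines,
                    **{m: s.edge_metric[m][i, j] for m in EDGE_METRICS},
                }
            )
    pd.DataFrame(node_rows).to_csv(paths["nodes"], sep="\t", index=False, float_format="%.17g")
    pd.DataFrame(edge_rows).to_csv(paths["edges"], sep="\t", index=False, na_rep="", float_format="%.17g")
    return paths


PATHWAY_COLUMNS = (
    "hemisphere",
    "up_roi",
    "down_roi",
    "metric",
    "iteration",
    "coef_up",
    "p_up",
    "sign_up",
    "coef_down",
    "p_down",
    "sign_down",
    "r2_diff",
)


def write_pathway_table(pattern, path: str | Path) -> pd.DataFrame:
    """Write the discovered pathways, one row per pathway, Table-2 style.

    Rows are ordered by (iteration, up-ROI id, down-ROI id) so re-runs on
    identical inputs produce byte-identical files.  ``r2_diff`` is the extra
    adjusted variance of the destination tau signal explained by the
    diffusion metric beyond age and sex (the model-(b) figure of merit).
    """
    parc = pattern.parcellation
    rows = []
    for pw in sorted(pattern.pathways, key=lambda p: (p.iteration, p.up_roi, p.down_roi)):
        rows.append(
            {
                "hemisphere": pw.hemisphere,
                "up_roi": parc.names[pw.up_roi],
                "down_roi": parc.names[pw.down_roi],
                "metric": pw.metric,
                "iteration": pw.iteration,
                "coef_up": pw.test_up.coef,
                "p_up": pw.test_up.p,
                "sign_up": pw.test_up.sign,
                "coef_down": pw.test_down.coef,
                "p_down": pw.test_down.p,
                "sign_down": pw.test_down.sign,
                "r2_diff": pw.test_down.r2_diff,
            }
        )
    df = pd.DataFrame(rows, columns=PATHWAY_COLUMNS)
    df.to_csv(path, sep="\t", index=False)
    return df
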