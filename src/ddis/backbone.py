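"""Group-level binary "backbone" construction from streamline counts.

Per-subject streamline-count matrices are normalized by the subject's
whole-brain streamline total and corrected for ROI sizes, averaged across
the group, and binarized at a fraction (default 10%) of the maximum
group-mean entry.  The surviving edges form the backbone graph on which
all node-edge-node association testing runs.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .cohort import Cohort, Parcellation

DEFAULT_THRESHOLD = 0.10
DEFAULT_SWEEP = tuple(np.round(np.arange(0.04, 0.115, 0.01), 2))


@dataclass(frozen=True)
class Backbone:
    """Binary symmetric adjacency plus the group-mean matrix it came from."""

    adjacency: np.ndarray
    threshold_fraction: float
    group_mean: np.ndarray

    def __post_init__(self) -> None:
        adj = np.asarray(self.adjacency, dtype=bool)
        object.__setattr__(self, "adjacency", adj)
        if not np.array_equal(adj, adj.T) or np.any(np.diag(adj)):
            raise ValueError("backbone adjacency must be symmetric with zero diagonal")

    @property
    def edge_list(self) -> list[tuple[int, int]]:
        """Unordered ROI pairs (i < j), ascending."""
        ii, jj = np.nonzero(np.triu(self.adjacency, k=1))
        return list(zip(ii.tolist(), jj.tolist()))

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum() // 2)

    def neighbors(self, roi_id: int) -> np.ndarray:
        return np.nonzero(self.adjacency[roi_id])[0]


def normalize_connectivity(
    conn_counts: np.ndarray,
    total_streamlines: float,
    roi_sizes: np.ndarray,
    size_correction: str = "mean",
) -> np.ndarray:
    """Normalize one subject's count matrix by streamline total and ROI size.

    Entry (i, j) becomes ``counts[i, j] / total / f(size_i, size_j)`` where
    f is the mean (default), sum, or 1 of the endpoint sizes.  Units:
    streamline fraction per unit ROI size.
    """
    if total_streamlines <= 0:
        raise ValueError("total_streamlines must be positive")
    sizes = np.asarray(roi_sizes, dtype=float)
    if np.any(sizes <= 0):
        raise ValueError("ROI sizes must be positive")
    if size_correction == "mean":
        pair = (sizes[:, None] + sizes[None, :]) / 2.0
    elif size_correction == "sum":
        pair = sizes[:, None] + sizes[None, :]
    elif size_correction == "none":
        pair = np.ones((sizes.size, sizes.size))
    else:
        raise ValueError(f"unknown size_correction {size_correction!r}")
    return conn_counts / total_streamlines / pair


def group_mean_connectivity(normalized: Sequence[np.ndarray]) -> np.ndarray:
    """Element-wise mean of per-subject normalized matrices."""
    mats = list(normalized)
    if not mats:
        raise ValueError("need at least one matrix")
    shape = mats[0].shape
    if any(m.shape != shape for m in mats):
        raise ValueError("matrices must share one shape")
    return np.mean(mats, axis=0)


def binarize_backbone(
    group_mean: np.ndarray, threshold_fraction: float = DEFAULT_THRESHOLD
) -> Backbone:
    """Keep edges whose group-mean value is >= fraction x (maximum entry).

    The comparator is inclusive, so the maximal edge always survives and
    fraction -> 0+ keeps every positive entry.
    """
    gm = np.asarray(group_mean, dtype=float)
    if not np.allclose(gm, gm.T):
        raise ValueError("group-mean matrix must be symmetric")
    off = gm - np.diag(np.diag(gm))
    peak = off.max()
    if peak <= 0:
        raise ValueError("group-mean matrix has no positive off-diagonal entry")
    adj = off >= threshold_fraction * peak
    np.fill_diagonal(adj, False)
    return Backbone(adjacency=adj, threshold_fraction=threshold_fraction, group_mean=gm)


def backbone_sweep(
    group_mean: np.ndarray, fractions: Iterable[float] = DEFAULT_SWEEP
) -> pd.DataFrame:
    """Edge and connected-component counts over a grid of threshold fractions.

    Edge counts are non-increasing in the fraction; component counts include
    isolated ROIs.
    """
    rows = []
    n = group_mean.shape[0]
    for frac in fractions:
        if not 0 < frac < 1:
            raise ValueError(f"threshold fraction {frac} not in (0, 1)")
        bb = binarize_backbone(group_mean, frac)
        g = nx.from_numpy_array(bb.adjacency)
        g.add_nodes_from(range(n))
        rows.append(
            {
                "fraction": float(frac),
                "n_edges": bb.n_edges,
                "n_components": nx.number_connected_components(g),
            }
        )
    return pd.DataFrame(rows, columns=["fraction", "n_edges", "n_components"])


def build_backbone(
    cohort: Cohort,
    threshold_fraction: float = DEFAULT_THRESHOLD,
    size_correction: str = "mean",
) -> Backbone:
    """Normalize every subject, average, and binarize in one call."""
    sizes = cohort.parcellation.sizes
    normed = [
        normalize_connectivity(s.conn_counts, s.total_streamlines, sizes, size_correction)
        for s in cohort.subjects
    ]
    return binarize_backbone(group_mean_connectivity(normed), threshold_fraction)


def write_backbone_table(
    backbone: Backbone, parcellation: Parcellation, path: str | Path
) -> pd.DataFrame:
    """All ROI pairs with positive group-mean value, flagged kept/dropped."""
    rows = []
    gm = backbone.group_mean
    n = parcellation.n_rois
    for i in range(n):
        for j in range(i + 1, n):
            if gm[i, j] <= 0:
                continue
            rows.append(
                {
                    "roi_i": parcellation.names[i],
                    "hemi_i": parcellation.hemispheres[i],
                    "roi_j": parcellation.names[j],
                    "hemi_j": parcellation.hemispheres[j],
                    "group_mean_value": gm[i, j],
                    "kept": int(backbone.adjacency[i, j]),
                }
            )
    df = pd.DataFrame(
        rows, columns=["roi_i", "hemi_i", "roi_j", "hemi_j", "group_mean_value", "kept"]
    )
    df.to_csv(path, sep="\t", index=False)
    return df
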