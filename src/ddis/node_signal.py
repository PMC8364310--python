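"""Positivity calling, per-ROI prevalence maps, and seed selection.

Tau positivity follows the conventional flortaucipir cutoff (SUVR > 1.23);
prevalence is the fraction of subjects positive in each ROI.  ROIs whose
prevalence strictly exceeds the seed threshold (default 80%) initiate the
iterative search, each hemisphere judged from its own prevalence values.
An explicit seed list can bypass prevalence-based selection, e.g. for the
amyloid variant where seeds are named outright.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .cohort import Parcellation

TAU_SUVR_CUTOFF = 1.23
AMYLOID_CENTILOID_CUTOFF = 20.0
DEFAULT_SEED_PREVALENCE = 0.80


@dataclass(frozen=True)
class PrevalenceMap:
    """Per-ROI positivity prevalence for one node signal."""

    values: np.ndarray
    signal: str
    cutoff: float
    n_subjects: int

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if np.any((v < 0) | (v > 1)):
            raise ValueError("prevalence values must lie in [0, 1]")


@dataclass(frozen=True)
class SeedSet:
    """ROIs that initiate the search, with their selection provenance."""

    roi_ids: frozenset[int]
    threshold: float | None
    provenance: str  # "prevalence" or "explicit"

    def partition(self, parcellation: Parcellation) -> dict[str, frozenset[int]]:
        """Seeds split by hemisphere."""
        out: dict[str, frozenset[int]] = {}
        for hemi in ("left", "right"):
            ids = set(parcellation.hemisphere_ids(hemi).tolist())
            out[hemi] = frozenset(self.roi_ids & ids)
        return out

    def __len__(self) -> int:
        return len(self.roi_ids)


def call_positivity(
    values: np.ndarray, cutoff: float, strict: bool = True
) -> np.ndarray:
    """Boolean subject x ROI positivity matrix at a signal cutoff.

    ``strict`` selects the '>' comparator (the Methods convention); node
    signals must be complete — missing values raise.
    """
    v = np.asarray(values, dtype=float)
    if not np.isfinite(cutoff):
        raise ValueError("cutoff must be finite")
    if not np.all(np.isfinite(v)):
        raise ValueError("node signal contains missing values; positivity needs complete data")
    return v > cutoff if strict else v >= cutoff


def compute_prevalence(
    positivity: np.ndarray, signal: str = "tau_suvr", cutoff: float = TAU_SUVR_CUTOFF
) -> PrevalenceMap:
    """Column means of the positivity matrix: fraction positive per ROI."""
    pos = np.asarray(positivity, dtype=bool)
    if pos.ndim != 2 or pos.shape[0] < 1:
        raise ValueError("positivity must be a subject x ROI matrix with >= 1 subject")
    return PrevalenceMap(
        values=pos.mean(axis=0), signal=signal, cutoff=cutoff, n_subjects=pos.shape[0]
    )


def select_seeds(
    prevalence: PrevalenceMap,
    parcellation: Parcellation,
    threshold: float = DEFAULT_SEED_PREVALENCE,
) -> SeedSet:
    """ROIs with prevalence strictly above the threshold.

    Left and right hemisphere ROIs qualify independently from their own
    prevalence values; an empty result is legal (the search then returns an
    empty pattern).
    """
    if not 0 < threshold < 1:
        raise ValueError("seed threshold must be in (0, 1)")
    if prevalence.values.shape[0] != parcellation.n_rois:
        raise ValueError("prevalence length does not match parcellation")
    ids = frozenset(np.nonzero(prevalence.values > threshold)[0].tolist())
    return SeedSet(roi_ids=ids, threshold=threshold, provenance="prevalence")


def seeds_from_names(
    parcellation: Parcellation, names: Iterable[str], hemispheres: Sequence[str] = ("left", "right")
) -> SeedSet:
    """Explicit seed list by ROI name, expanded over the given hemispheres."""
    idx = parcellation.index
    ids: set[int] = set()
    for name in names:
        hit = False
        for hemi in hemispheres:
            if (name, hemi) in idx:
                ids.add(idx[(name, hemi)])
                hit = True
        if not hit:
            raise KeyError(f"seed ROI {name!r} not in parcellation")
    return SeedSet(roi_ids=frozenset(ids), threshold=None, provenance="explicit")


def write_prevalence_table(
    prevalence: PrevalenceMap,
    parcellation: Parcellation,
    seeds: SeedSet,
    path: str | Path,
) -> pd.DataFrame:
    df = pd.DataFrame(
        {
            "roi_name": parcellation.names,
            "hemisphere": parcellation.hemispheres,
            "prevalence": prevalence.values,
            "is_seed": [int(i in seeds.roi_ids) for i in range(parcellation.n_rois)],
        }
    )
    df.to_csv(path, sep="\t", index=False)
    return df
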