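"""Bootstrap resampling of subjects with full pipeline re-runs and voting.

Each replicate draws n subjects with replacement (n = cohort size),
recomputes positivity prevalence and seeds, re-runs the iterative search,
and casts one vote per discovered pathway identity.  Pathway identity is
directed (hemisphere, up ROI, down ROI, metric); iteration labels vary
across resamples and are ignored.  The backbone is, by default, the one
built once from the full sample; ``resample_backbone=True`` rebuilds it
per replicate.

Replicate random streams are spawned from (rng_seed, replicate index), so
the result is a pure function of (cohort, config, n_boot, rng_seed) and
identical for any worker-pool size.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from joblib import Parallel, delayed

from .backbone import Backbone, build_backbone
from .cohort import Cohort, DdisConfig, Parcellation
from .core import AssociationPattern, run_ddis
from .node_signal import call_positivity, compute_prevalence, select_seeds

DEFAULT_N_BOOT = 1000
DISPLAY_CUTOFF = 0.30

PathwayKey = tuple[str, int, int, str]  # hemisphere, up_roi, down_roi, metric


@dataclass(frozen=True)
class StabilityMap:
    """Votes per pathway identity over bootstrap replicates."""

    votes: dict[PathwayKey, int]
    n_boot: int
    rng_seed: int
    per_replicate_counts: tuple[int, ...]

    def __post_init__(self) -> None:
        if any(v > self.n_boot for v in self.votes.values()):
            raise ValueError("votes cannot exceed n_boot")

    @property
    def frequencies(self) -> dict[PathwayKey, float]:
        return {k: v / self.n_boot for k, v in self.votes.items()}

    def undirected(self) -> dict[tuple[str, int, int, str], float]:
        """Display-style aggregation ignoring pathway direction: the
        frequency of an unordered pair is the fraction of replicates where
        it appeared in either direction (votes were recorded per replicate
        as sets, so this is an upper bound only when both directions occur
        in disjoint replicates; with directed votes we report the max)."""
        out: dict[tuple[str, int, int, str], float] = {}
        for (hemi, up, down, metric), f in self.frequencies.items():
            key = (hemi, min(up, down), max(up, down), metric)
            out[key] = max(out.get(key, 0.0), f)
        return out


def pattern_keys(pattern: AssociationPattern) -> set[PathwayKey]:
    return {(p.hemisphere, p.up_roi, p.down_roi, p.metric) for p in pattern.pathways}


def vote_summary(patterns: Sequence[AssociationPattern], rng_seed: int = 0) -> StabilityMap:
    """Aggregate a list of patterns into identity-keyed vote frequencies."""
    if not patterns:
        raise ValueError("need at least one pattern")
    votes: dict[PathwayKey, int] = {}
    counts = []
    for pat in patterns:
        keys = pattern_keys(pat)
        counts.append(len(keys))
        for k in keys:
            votes[k] = votes.get(k, 0) + 1
    return StabilityMap(
        votes=votes,
        n_boot=len(patterns),
        rng_seed=rng_seed,
        per_replicate_counts=tuple(counts),
    )


def _one_replicate(
    cohort: Cohort,
    config: DdisConfig,
    backbone: Backbone | None,
    rng_seed: int,
    replicate: int,
    resample_backbone: bool,
) -> tuple[frozenset[PathwayKey], int]:
    rng = np.random.default_rng(np.random.SeedSequence([rng_seed, replicate]))
    n = cohort.n_subjects
    idx = rng.integers(0, n, size=n)
    sample = cohort.resample(idx.tolist(), suffix=f"r{replicate}_")
    bb = build_backbone(sample, config.backbone_fraction, config.size_correction) \
        if resample_backbone else backbone
    pos = call_positivity(
        sample.node_signal_matrix(config.signal),
        config.positivity_cutoff,
        strict=config.strict_positivity,
    )
    prev = compute_prevalence(pos, config.signal, config.positivity_cutoff)
    seeds = select_seeds(prev, sample.parcellation, config.seed_prevalence)
    pattern = run_ddis(sample, bb, seeds, config)
    keys = frozenset(pattern_keys(pattern))
    return keys, len(keys)


def bootstrap_ddis(
    cohort: Cohort,
    config: DdisConfig,
    n_boot: int = DEFAULT_N_BOOT,
    rng_seed: int | None = None,
    resample_backbone: bool = False,
    backbone: Backbone | None = None,
    n_jobs: int = 1,
) -> StabilityMap:
    """Full-pipeline bootstrap with one vote per pathway per replicate.

    A replicate whose resample yields zero seeds contributes zero votes but
    still counts in the denominator.
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    seed = config.rng_seed if rng_seed is None else rng_seed
    bb = backbone
    if bb is None and not resample_backbone:
        bb = build_backbone(cohort, config.backbone_fraction, config.size_correction)

    if n_jobs == 1:
        results = [
            _one_replicate(cohort, config, bb, seed, r, resample_backbone)
            for r in range(n_boot)
        ]
    else:
        results = Parallel(n_jobs=n_jobs)(
            delayed(_one_replicate)(cohort, config, bb, seed, r, resample_backbone)
            for r in range(n_boot)
        )

    votes: dict[PathwayKey, int] = {}
    counts = []
    for keys, n_found in results:
        counts.append(n_found)
        for k in keys:
            votes[k] = votes.get(k, 0) + 1
    return StabilityMap(
        votes=votes, n_boot=n_boot, rng_seed=seed, per_replicate_counts=tuple(counts)
    )


def filter_stability(smap: StabilityMap, min_frequency: float = DISPLAY_CUTOFF) -> StabilityMap:
    """Keep pathways whose frequency is >= min_frequency (display filter)."""
    if not 0 <= min_frequency <= 1:
        raise ValueError("min_frequency must be in [0, 1]")
    keep = {k: v for k, v in smap.votes.items() if v / smap.n_boot >= min_frequency}
    return StabilityMap(
        votes=keep,
        n_boot=smap.n_boot,
        rng_seed=smap.rng_seed,
        per_replicate_counts=smap.per_replicate_counts,
    )


def write_stability_table(
    smap: StabilityMap, parcellation: Parcellation, path: str | Path
) -> pd.DataFrame:
    rows = []
    for (hemi, up, down, metric) in sorted(smap.votes):
        rows.append(
            {
                "hemisphere": hemi,
                "up_roi": parcellation.names[up],
                "down_roi": parcellation.names[down],
                "metric": metric,
                "votes": smap.votes[(hemi, up, down, metric)],
                "frequency": smap.votes[(hemi, up, down, metric)] / smap.n_boot,
            }
        )
    df = pd.DataFrame(
        rows, columns=["hemisphere", "up_roi", "down_roi", "metric", "votes", "frequency"]
    )
    df.to_csv(path, sep="\t", index=False)
    return df
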