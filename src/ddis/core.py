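"""The DDIS regression engine and iterative pathway search.

A candidate connection from a seed ROI ("up") across a backbone edge to a
destination ROI ("down") is accepted as an association pathway when two
chained linear models are BOTH significant at alpha:

  (a)  Diff_WM  ~  TAU_up  + age + sex      (node signal -> edge metric)
  (b)  TAU_down ~  Diff_WM + age + sex      (edge metric -> node signal)

Accepted destinations become seeds of the next iteration; connections
among current seeds are never tested, and no connection is tested twice.
The search stops when an iteration yields no new pathway.  With
hemisphere_mode="separate" (the default) the two hemispheres are searched
independently over intra-hemispheric edges only and merged afterwards.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .backbone import Backbone
from .cohort import Cohort, DdisConfig, Parcellation
from .node_signal import SeedSet

logger = logging.getLogger(__name__)


class DegenerateModelError(ValueError):
    """A single connection test cannot be fit (constant predictor,
    rank-deficient design, or too few complete observations)."""


@dataclass(frozen=True)
class RegressionResult:
    """OLS fit summary for the predictor of interest.

    ``r2_diff`` is the adjusted-R2 gain of the full model over the
    covariates-only model fit on the same subjects.
    """

    coef: float
    stderr: float
    tstat: float
    p: float
    n_used: int
    adj_r2_full: float
    adj_r2_covariates_only: float

    @property
    def r2_diff(self) -> float:
        return self.adj_r2_full - self.adj_r2_covariates_only

    @property
    def sign(self) -> str:
        return "+" if self.coef >= 0 else "-"


def fit_glm(
    response: np.ndarray,
    predictor: np.ndarray,
    covariates: np.ndarray | None = None,
    min_n: int = 5,
) -> RegressionResult:
    """OLS of ``response`` on ``predictor`` plus covariates, with intercept.

    Rows with any missing value are dropped (listwise deletion).  The
    reported p is the two-sided t-test on the predictor's coefficient; the
    covariates-only adjusted R2 comes from refitting the same rows without
    the predictor.
    """
    y = np.asarray(response, dtype=float)
    x = np.asarray(predictor, dtype=float)
    if covariates is None:
        cov = np.empty((y.shape[0], 0))
    else:
        cov = np.asarray(covariates, dtype=float)
        if cov.ndim == 1:
            cov = cov[:, None]
    mask = np.isfinite(y) & np.isfinite(x) & np.all(np.isfinite(cov), axis=1)
    y, x, cov = y[mask], x[mask], cov[mask]
    n = y.shape[0]
    k = 2 + cov.shape[1]  # intercept + predictor + covariates
    if n < max(min_n, k + 1):
        raise DegenerateModelError(f"only {n} complete observations for {k}-column design")
    if np.ptp(x) == 0:
        raise DegenerateModelError("degenerate predictor (constant)")
    design = np.column_stack([np.ones(n), x, cov])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise DegenerateModelError("rank-deficient design")

    full = sm.OLS(y, design).fit()
    reduced = sm.OLS(y, np.column_stack([np.ones(n), cov])).fit()
    return RegressionResult(
        coef=float(full.params[1]),
        stderr=float(full.bse[1]),
        tstat=float(full.tvalues[1]),
        p=float(full.pvalues[1]),
        n_used=n,
        adj_r2_full=float(full.rsquared_adj),
        adj_r2_covariates_only=float(reduced.rsquared_adj),
    )


@dataclass(frozen=True)
class ConnectionTest:
    """Outcome of testing one directed candidate connection."""

    up_roi: int
    down_roi: int
    metric: str
    accepted: bool
    test_up: RegressionResult | None = None
    test_down: RegressionResult | None = None
    reason: str | None = None


def test_connection(
    cohort: Cohort,
    up_roi: int,
    down_roi: int,
    metric: str,
    signal: str = "tau_suvr",
    alpha: float = 0.05,
    covariates: tuple[str, ...] = ("age", "sex"),
    min_n: int = 5,
) -> ConnectionTest:
    """Run the two chained models on one connection; accept if both pass.

    A fit failure (too much missing data, degenerate predictor) rejects the
    single connection with a reason, never the whole run.
    """
    node = cohort.node_signal_matrix(signal)
    edge = cohort.edge_values(metric, up_roi, down_roi)
    cov = cohort.covariate_matrix(covariates)
    try:
        up = fit_glm(edge, node[:, up_roi], cov, min_n=min_n)
        down = fit_glm(node[:, down_roi], edge, cov, min_n=min_n)
    except DegenerateModelError as err:
        return ConnectionTest(
            up_roi=up_roi, down_roi=down_roi, metric=metric, accepted=False, reason=str(err)
        )
    return ConnectionTest(
        up_roi=up_roi,
        down_roi=down_roi,
        metric=metric,
        accepted=bool(up.p < alpha and down.p < alpha),
        test_up=up,
        test_down=down,
    )


@dataclass(frozen=True)
class Pathway:
    """One accepted up-ROI -> edge -> down-ROI association."""

    up_roi: int
    down_roi: int
    hemisphere: str
    metric: str
    iteration: int
    test_up: RegressionResult
    test_down: RegressionResult


@dataclass
class AssociationPattern:
    """Everything one DDIS run discovered, plus its audit trail."""

    pathways: list[Pathway]
    seed_history: dict[str, list[frozenset[int]]]
    tested_connections: list[dict]
    config: DdisConfig
    parcellation: Parcellation

    @property
    def pathway_pairs(self) -> set[tuple[int, int]]:
        return {(p.up_roi, p.down_roi) for p in self.pathways}

    @property
    def n_iterations(self) -> int:
        return max((p.iteration for p in self.pathways), default=0)


def run_iteration(
    cohort: Cohort,
    backbone: Backbone,
    current_seeds: frozenset[int],
    tested: set[tuple[int, int]],
    config: DdisConfig,
    allowed_rois: frozenset[int] | None = None,
) -> tuple[list[ConnectionTest], list[int]]:
    """Test every untested backbone connection leaving the current seeds.

    Candidates have their up endpoint in the seed set, their down endpoint
    outside it (seed-seed connections are never considered), and both
    endpoints inside ``allowed_rois`` when given (hemisphere restriction).
    Returns all test records and the deduplicated, sorted list of accepted
    destination ROIs.
    """
    candidates: list[tuple[int, int]] = []
    for up in sorted(current_seeds):
        for down in backbone.neighbors(up):
            down = int(down)
            if down in current_seeds:
                continue
            if allowed_rois is not None and (up not in allowed_rois or down not in allowed_rois):
                continue
            if (up, down) in tested:
                continue
            candidates.append((up, down))
    candidates.sort()

    results: list[ConnectionTest] = []
    new_seeds: set[int] = set()
    for up, down in candidates:
        ct = test_connection(
            cohort,
            up,
            down,
            metric=config.metric,
            signal=config.signal,
            alpha=config.alpha,
            covariates=config.covariates,
            min_n=config.min_n,
        )
        tested.add((up, down))
        results.append(ct)
        if ct.accepted:
            new_seeds.add(down)
    return results, sorted(new_seeds)


def _search_one_scope(
    cohort: Cohort,
    backbone: Backbone,
    seeds: frozenset[int],
    config: DdisConfig,
    hemisphere: str,
    allowed_rois: frozenset[int] | None,
    pathways: list[Pathway],
    log: list[dict],
    history: list[frozenset[int]],
) -> None:
    current = frozenset(seeds)
    tested: set[tuple[int, int]] = set()
    iteration = 0
    while True:
        iteration += 1
        history.append(current)
        results, accepted = run_iteration(
            cohort, backbone, current, tested, config, allowed_rois
        )
        for ct in results:
            log.append(
                {
                    "hemisphere": hemisphere,
                    "iteration": iteration,
                    "up_roi": ct.up_roi,
                    "down_roi": ct.down_roi,
                    "accepted": ct.accepted,
                    "p_up": ct.test_up.p if ct.test_up else np.nan,
                    "p_down": ct.test_down.p if ct.test_down else np.nan,
                    "reason": ct.reason or "",
                }
            )
            if ct.accepted:
                pathways.append(
                    Pathway(
                        up_roi=ct.up_roi,
                        down_roi=ct.down_roi,
                        hemisphere=hemisphere,
                        metric=ct.metric,
                        iteration=iteration,
                        test_up=ct.test_up,
                        test_down=ct.test_down,
                    )
                )
        if not accepted:
            break
        current = current | frozenset(accepted)


def run_ddis(
    cohort: Cohort,
    backbone: Backbone,
    seeds: SeedSet,
    config: DdisConfig,
) -> AssociationPattern:
    """Iterate seed propagation until no further pathway is detected.

    With ``hemisphere_mode="separate"`` the left and right hemispheres run
    independently (inter-hemispheric backbone edges are excluded) and their
    patterns are merged with hemisphere tags; iteration labels restart per
    hemisphere.  An empty seed set yields an empty pattern.
    """
    parc = cohort.parcellation
    pathways: list[Pathway] = []
    log: list[dict] = []
    seed_history: dict[str, list[frozenset[int]]] = {}

    if not seeds.roi_ids:
        logger.warning("empty seed set: returning empty association pattern")
        return AssociationPattern(
            pathways=[], seed_history={}, tested_connections=[], config=config, parcellation=parc
        )

    if config.hemisphere_mode == "separate":
        parts = seeds.partition(parc)
        for hemi in ("left", "right"):
            hemi_ids = frozenset(parc.hemisphere_ids(hemi).tolist())
            hemi_seeds = parts[hemi]
            history: list[frozenset[int]] = []
            seed_history[hemi] = history
            if not hemi_seeds:
                continue
            _search_one_scope(
                cohort, backbone, hemi_seeds, config, hemi, hemi_ids, pathways, log, history
            )
    else:
        history = []
        seed_history["pooled"] = history
        _search_one_scope(
            cohort, backbone, frozenset(seeds.roi_ids), config, "pooled", None,
            pathways, log, history,
        )

    pathways.sort(key=lambda p: (p.hemisphere, p.iteration, p.up_roi, p.down_roi))
    return AssociationPattern(
        pathways=pathways,
        seed_history=seed_history,
        tested_connections=log,
        config=config,
        parcellation=parc,
    )


def summarize_pattern(pattern: AssociationPattern) -> pd.DataFrame:
    """Per-iteration pathway counts, mean/min/max model-(b) r2_diff, and the
    direction-of-change tally from model-(a) coefficient signs.

    A totals row (iteration = "all") closes the table; per-iteration counts
    sum to the total.
    """
    rows = []
    iters = sorted({p.iteration for p in pattern.pathways})
    groups = [(str(it), [p for p in pattern.pathways if p.iteration == it]) for it in iters]
    groups.append(("all", list(pattern.pathways)))
    for label, pws in groups:
        r2 = [p.test_down.r2_diff for p in pws]
        rows.append(
            {
                "iteration": label,
                "n_pathways": len(pws),
                "mean_r2_diff": float(np.mean(r2)) if r2 else 0.0,
                "min_r2_diff": float(np.min(r2)) if r2 else 0.0,
                "max_r2_diff": float(np.max(r2)) if r2 else 0.0,
                "n_increase": sum(1 for p in pws if p.test_up.sign == "+"),
                "n_decrease": sum(1 for p in pws if p.test_up.sign == "-"),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "iteration",
            "n_pathways",
            "mean_r2_diff",
            "min_r2_diff",
            "max_r2_diff",
            "n_increase",
            "n_decrease",
        ],
    )
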