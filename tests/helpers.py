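"""Independent oracles used across the test suite.

These deliberately avoid the package's own code paths: the OLS oracle is
plain normal equations plus the t distribution, and the search oracle is
an exhaustive fixed-point rescan of all backbone edges.
"""

from __future__ import annotations

import numpy as np
from scipy import stats


def ols_oracle(y: np.ndarray, predictors: np.ndarray) -> dict:
    """Ordinary least squares via normal equations, intercept prepended.

    Returns coefficient/stderr/t/p for the FIRST predictor column plus the
    adjusted R^2 of the full fit.
    """
    y = np.asarray(y, dtype=float)
    X = np.column_stack([np.ones(len(y)), np.asarray(predictors, dtype=float)])
    n, k = X.shape
    xtx = X.T @ X
    beta = np.linalg.solve(xtx, X.T @ y)
    resid = y - X @ beta
    rss = float(resid @ resid)
    dof = n - k
    sigma2 = rss / dof
    cov = sigma2 * np.linalg.inv(xtx)
    se = np.sqrt(np.diag(cov))
    t = beta / se
    p = 2.0 * stats.t.sf(np.abs(t), dof)
    tss = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - rss / tss
    adj_r2 = 1.0 - (1.0 - r2) * (n - 1) / dof
    return {
        "coef": float(beta[1]),
        "stderr": float(se[1]),
        "tstat": float(t[1]),
        "p": float(p[1]),
        "adj_r2": float(adj_r2),
    }


def _oracle_connection_significant(cohort, up, down, metric, signal, alpha, covariates):
    node = cohort.node_signal_matrix(signal)
    edge = cohort.edge_values(metric, up, down)
    cov = cohort.covariate_matrix(covariates)
    mask = np.isfinite(edge)
    if mask.sum() < 5:
        return False
    e, c = edge[mask], cov[mask]
    a = ols_oracle(e, np.column_stack([node[mask, up], c]))
    b = ols_oracle(node[mask, down], np.column_stack([e, c]))
    return a["p"] < alpha and b["p"] < alpha


def brute_force_ddis(cohort, backbone, seed_ids, config):
    """Exhaustive fixed-point reference for the iterative search.

    Every backbone edge is rescanned against the current seed set each
    round (rejected connections included); accepted connections are
    labelled with the round number and their destinations join the seeds.
    Returns {(up, down): iteration} per hemisphere-merged run.
    """
    parc = cohort.parcellation
    found: dict[tuple[int, int], int] = {}
    if config.hemisphere_mode == "separate":
        scopes = [
            set(parc.hemisphere_ids(h).tolist()) & set(seed_ids)
            for h in ("left", "right")
        ]
        allowed = [set(parc.hemisphere_ids(h).tolist()) for h in ("left", "right")]
    else:
        scopes = [set(seed_ids)]
        allowed = [set(range(parc.n_rois))]
    n = parc.n_rois
    for seeds, ok in zip(scopes, allowed):
        if not seeds:
            continue
        seeds = set(seeds)
        iteration = 0
        while True:
            iteration += 1
            accepted = []
            for up in range(n):
                for down in range(n):
                    if not backbone.adjacency[up, down]:
                        continue
                    if up not in seeds or down in seeds:
                        continue
                    if up not in ok or down not in ok:
                        continue
                    if (up, down) in found:
                        continue
                    if _oracle_connection_significant(
                        cohort, up, down, config.metric, config.signal,
                        config.alpha, config.covariates,
                    ):
                        accepted.append((up, down))
            if not accepted:
                break
            for up, down in accepted:
                found[(up, down)] = iteration
            seeds |= {d for _, d in accepted}
    return found
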