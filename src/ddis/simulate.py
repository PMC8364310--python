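"""Synthetic cohorts with planted node-edge-node association chains.

The generator emulates the statistical structure the iterative search
assumes: a two-hemisphere parcellation graph with "true" high-count
structural connections plus low-count spurious ones; a subject-level tau
severity factor (Gamma-distributed) that elevates seed-region SUVR and
produces a positivity-prevalence gradient; and planted chains where each
link first writes the upstream ROI's tau into the connecting edge's
diffusion metric and then writes that metric into the downstream ROI's
tau, with age and sex acting as confounders on both sides.

Planted effects are parameterized in standardized units (slope in
residual-SD units per predictor-SD); predictor SDs are propagated
analytically along the chain and the resulting raw slopes, in the natural
units of each diffusion metric, are recorded per link so parameter
recovery can be checked against ground truth.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Iterable, Sequence

import networkx as nx
import numpy as np

from .cohort import EDGE_METRICS, Cohort, Parcellation, SubjectRecord

# Desikan-Killiany cortical labels (34 per hemisphere) plus the eight
# subcortical structures of the standard 84-node connectome parcellation.
DESIKAN_CORTICAL = (
    "bankssts", "caudalanteriorcingulate", "caudalmiddlefrontal", "cuneus",
    "entorhinal", "frontalpole", "fusiform", "inferiorparietal",
    "inferiortemporal", "insula", "isthmuscingulate", "lateraloccipital",
    "lateralorbitofrontal", "lingual", "medialorbitofrontal", "middletemporal",
    "paracentral", "parahippocampal", "parsopercularis", "parsorbitalis",
    "parstriangularis", "pericalcarine", "postcentral", "posteriorcingulate",
    "precentral", "precuneus", "rostralanteriorcingulate",
    "rostralmiddlefrontal", "superiorfrontal", "superiorparietal",
    "superiortemporal", "supramarginal", "temporalpole", "transversetemporal",
)
DESIKAN_SUBCORTICAL = (
    "thalamus", "caudate", "putamen", "pallidum",
    "hippocampus", "amygdala", "accumbens", "ventraldc",
)
# Basal-ganglia regions with known off-target tau-tracer binding.
OFF_TARGET_ROIS = ("pallidum", "caudate", "putamen", "thalamus")

# Natural-unit (location, scale) mapping per diffusion metric channel;
# generated latents are unit-SD and mapped affinely onto these.
METRIC_UNITS = {
    "fa": (0.45, 0.06),
    "md": (8.0e-4, 0.6e-4),
    "da": (1.2e-3, 0.8e-4),
    "dr": (6.0e-4, 0.6e-4),
    "icvf": (0.55, 0.05),
    "od": (0.25, 0.04),
}

DEFAULT_EFFECT = 0.55  # standardized planted slope (see docs/methods.md)


@dataclass(frozen=True)
class PlantedLink:
    """One planted node->edge->node link with its true raw slopes."""

    up: int
    down: int
    slope_up_latent: float     # d latent-metric / d tau
    slope_down_latent: float   # d tau / d latent-metric
    slope_up_natural: float    # d metric (natural units) / d tau
    slope_down_natural: float  # d tau / d metric (natural units)


@dataclass(frozen=True)
class GroundTruth:
    """Template graph, planted chains, and all generative parameters."""

    parcellation: Parcellation
    edges: tuple[tuple[int, int], ...]
    chains: tuple[tuple[int, ...], ...]
    links: tuple[PlantedLink, ...]
    metric: str
    beta1: float
    alpha1: float
    elevated_rois: frozenset[int]
    tau_noise_sd: float
    metric_noise_sd: float
    gamma_age_tau: float
    gamma_sex_tau: float
    gamma_age_metric: float
    gamma_sex_metric: float
    root_gamma_shape: float
    root_gamma_scale: float
    edge_mean_counts: np.ndarray
    count_dispersion: float
    spurious_pairs: tuple[tuple[int, int], ...]
    spurious_mean: float
    amyloid_loadings: np.ndarray

    @property
    def planted_pairs(self) -> set[tuple[int, int]]:
        """Directed (up, down) pairs of every planted link."""
        return {(l.up, l.down) for l in self.links}

    def link_for(self, up: int, down: int) -> PlantedLink:
        for l in self.links:
            if (l.up, l.down) == (up, down):
                return l
        raise KeyError((up, down))

    def null(self) -> "GroundTruth":
        """Same template and severity structure with all planted effects zero."""
        zeroed = tuple(
            dataclasses.replace(
                l, slope_up_latent=0.0, slope_down_latent=0.0,
                slope_up_natural=0.0, slope_down_natural=0.0,
            )
            for l in self.links
        )
        return dataclasses.replace(self, beta1=0.0, alpha1=0.0, links=zeroed)


def _geometric_hemisphere(n: int, rng: np.random.Generator, radius: float) -> list[tuple[int, int]]:
    """Connected random geometric graph on n nodes; grows the radius until
    connectivity is reached."""
    pos = {i: rng.uniform(0.0, 1.0, 2) for i in range(n)}
    r = radius
    for _ in range(12):
        g = nx.random_geometric_graph(n, r, pos=pos)
        if nx.is_connected(g):
            return sorted(tuple(sorted(e)) for e in g.edges)
        r *= 1.3
    raise RuntimeError("could not build a connected hemisphere graph")


def make_template_graph(
    nodes_per_hemisphere: int = 42,
    model: str = "random_geometric",
    rng_seed: int = 0,
    radius: float = 0.30,
    homotopic_prob: float = 0.30,
    size_log_mean: float = np.log(3000.0),
    size_log_sd: float = 0.25,
) -> tuple[Parcellation, tuple[tuple[int, int], ...]]:
    """Two-hemisphere template: parcellation plus "true" structural edges.

    ``model="desikan84"`` uses the 84-node cortical/subcortical naming (42
    per hemisphere, off-target basal ganglia flagged); ``random_geometric``
    uses generic names.  Intra-hemisphere subgraphs are connected random
    geometric graphs; homotopic (mirror-pair) inter-hemispheric edges are
    added with probability ``homotopic_prob``.
    """
    rng = np.random.default_rng(np.random.SeedSequence([rng_seed, 0]))
    if model == "desikan84":
        if nodes_per_hemisphere != 42:
            raise ValueError("desikan84 template has 42 ROIs per hemisphere")
        hemi_names = DESIKAN_CORTICAL + DESIKAN_SUBCORTICAL
        off = tuple(n in OFF_TARGET_ROIS for n in hemi_names)
    elif model == "random_geometric":
        if nodes_per_hemisphere < 3:
            raise ValueError("need at least 3 nodes per hemisphere")
        hemi_names = tuple(f"roi{i:02d}" for i in range(nodes_per_hemisphere))
        off = tuple(False for _ in hemi_names)
    else:
        raise ValueError(f"unknown template model {model!r}")

    n = len(hemi_names)
    names = hemi_names + hemi_names
    hemis = ("left",) * n + ("right",) * n
    sizes = rng.lognormal(size_log_mean, size_log_sd, 2 * n)
    parc = Parcellation(
        names=names, hemispheres=hemis, sizes=sizes, off_target=np.array(off + off)
    )

    edges: set[tuple[int, int]] = set()
    for offset in (0, n):
        for i, j in _geometric_hemisphere(n, rng, radius):
            edges.add((i + offset, j + offset))
    for i in range(n):
        if rng.uniform() < homotopic_prob:
            edges.add((i, i + n))
    return parc, tuple(sorted(edges))


def build_ground_truth(
    parcellation: Parcellation,
    edges: Iterable[tuple[int, int]],
    chains: Sequence[Sequence[int]] = (),
    beta1: float = DEFAULT_EFFECT,
    alpha1: float = DEFAULT_EFFECT,
    metric: str = "md",
    elevated_rois: Iterable[int] | None = None,
    tau_noise_sd: float = 0.10,
    metric_noise_sd: float = 1.0,
    gamma_age_tau: float = 0.05,
    gamma_sex_tau: float = 0.03,
    gamma_age_metric: float = 0.30,
    gamma_sex_metric: float = 0.20,
    root_gamma_shape: float = 4.0,
    root_gamma_scale: float = 0.15,
    count_scale: float = 500.0 / 3000.0,
    count_dispersion: float = 20.0,
    spurious_fraction: float = 0.05,
    spurious_mean: float = 3.0,
    rng_seed: int = 0,
) -> GroundTruth:
    """Freeze a generative model: graph, chains, slopes, count parameters.

    Chain edges absent from ``edges`` are added.  Per-edge mean streamline
    counts are proportional to the mean endpoint ROI size (uniform 0.75-1.25
    base factor), so size-corrected normalized means are homogeneous across
    true edges and every true edge clears liberal relative thresholds while
    spurious counts stay far below them.
    """
    if metric not in EDGE_METRICS:
        raise ValueError(f"metric must be one of {EDGE_METRICS}")
    rng = np.random.default_rng(np.random.SeedSequence([rng_seed, 1]))
    n = parcellation.n_rois
    edge_set = {tuple(sorted(e)) for e in edges}
    chains = tuple(tuple(int(r) for r in c) for c in chains)
    interior: set[int] = set()
    for chain in chains:
        if len(chain) < 2:
            raise ValueError("planted chains need at least two nodes")
        hemi = {parcellation.hemispheres[r] for r in chain}
        if len(hemi) != 1:
            raise ValueError("a planted chain must stay within one hemisphere")
        for u, v in zip(chain, chain[1:]):
            edge_set.add(tuple(sorted((u, v))))
        body = set(chain[1:])
        if body & interior:
            raise ValueError("planted chains may not share downstream nodes")
        interior |= body

    if elevated_rois is None:
        elevated = {c[0] for c in chains} | set(np.nonzero(parcellation.off_target)[0].tolist())
    else:
        elevated = set(int(r) for r in elevated_rois)

    # Analytic variance propagation -> raw slopes per planted link.
    var_sev = root_gamma_shape * root_gamma_scale**2
    base_tau_var = gamma_age_tau**2 + 0.25 * gamma_sex_tau**2 + tau_noise_sd**2
    scale_m = METRIC_UNITS[metric][1]
    links: list[PlantedLink] = []
    for chain in chains:
        var_tau = base_tau_var + (var_sev if chain[0] in elevated else 0.0)
        for u, v in zip(chain, chain[1:]):
            b = beta1 * metric_noise_sd / np.sqrt(var_tau)
            var_edge = (
                b**2 * var_tau
                + gamma_age_metric**2
                + 0.25 * gamma_sex_metric**2
                + metric_noise_sd**2
            )
            a = alpha1 * tau_noise_sd / np.sqrt(var_edge)
            links.append(
                PlantedLink(
                    up=u,
                    down=v,
                    slope_up_latent=float(b),
                    slope_down_latent=float(a),
                    slope_up_natural=float(b * scale_m),
                    slope_down_natural=float(a / scale_m),
                )
            )
            var_tau = a**2 * var_edge + base_tau_var

    mean_counts = np.zeros((n, n))
    sizes = parcellation.sizes
    for i, j in sorted(edge_set):
        base = rng.uniform(0.75, 1.25)
        mean_counts[i, j] = mean_counts[j, i] = base * count_scale * (sizes[i] + sizes[j]) / 2.0

    non_edges = [
        (i, j)
        for i in range(n)
        for j in range(i + 1, n)
        if (i, j) not in edge_set
    ]
    n_spur = int(round(spurious_fraction * len(non_edges)))
    spur_idx = rng.choice(len(non_edges), size=n_spur, replace=False) if n_spur else []
    spurious = tuple(sorted(non_edges[k] for k in np.sort(spur_idx)))

    loadings = rng.uniform(0.2, 1.2, n)

    return GroundTruth(
        parcellation=parcellation,
        edges=tuple(sorted(edge_set)),
        chains=chains,
        links=tuple(links),
        metric=metric,
        beta1=beta1,
        alpha1=alpha1,
        elevated_rois=frozenset(elevated),
        tau_noise_sd=tau_noise_sd,
        metric_noise_sd=metric_noise_sd,
        gamma_age_tau=gamma_age_tau,
        gamma_sex_tau=gamma_sex_tau,
        gamma_age_metric=gamma_age_metric,
        gamma_sex_metric=gamma_sex_metric,
        root_gamma_shape=root_gamma_shape,
        root_gamma_scale=root_gamma_scale,
        edge_mean_counts=mean_counts,
        count_dispersion=count_dispersion,
        spurious_pairs=spurious,
        spurious_mean=spurious_mean,
        amyloid_loadings=loadings,
    )


def chain_ground_truth(
    n_nodes: int = 6,
    beta1: float = 0.5,
    alpha1: float = 0.5,
    metric: str = "md",
    bilateral: bool = False,
    rng_seed: int = 0,
    **kwargs,
) -> GroundTruth:
    """Minimal template: one planted chain per (requested) hemisphere.

    The left hemisphere holds a simple path of ``n_nodes`` ROIs whose head
    is severity-elevated; the right hemisphere mirrors it, planted only
    when ``bilateral``.
    """
    if n_nodes < 2:
        raise ValueError("need at least 2 chain nodes")
    names = tuple(f"roi{i:02d}" for i in range(n_nodes))
    rng = np.random.default_rng(np.random.SeedSequence([rng_seed, 2]))
    sizes = rng.lognormal(np.log(3000.0), 0.25, 2 * n_nodes)
    parc = Parcellation(
        names=names + names,
        hemispheres=("left",) * n_nodes + ("right",) * n_nodes,
        sizes=sizes,
        off_target=np.zeros(2 * n_nodes, dtype=bool),
    )
    left = tuple(range(n_nodes))
    right = tuple(range(n_nodes, 2 * n_nodes))
    edges = [tuple(sorted(p)) for p in zip(left, left[1:])]
    edges += [tuple(sorted(p)) for p in zip(right, right[1:])]
    chains = (left, right) if bilateral else (left,)
    return build_ground_truth(
        parc, edges, chains, beta1=beta1, alpha1=alpha1, metric=metric,
        rng_seed=rng_seed, **kwargs,
    )


# Default posterior-to-anterior chain on the 84-node template, following
# the Braak-like anatomy of tau spread: medial temporal ->
# occipital/parietal -> postcentral.
DEFAULT_CHAIN_NAMES = (
    "entorhinal",
    "fusiform",
    "inferiortemporal",
    "inferiorparietal",
    "superiorparietal",
    "postcentral",
)
DEFAULT_ELEVATED_NAMES = ("entorhinal", "hippocampus", "amygdala") + OFF_TARGET_ROIS


def default_ground_truth(
    rng_seed: int = 0,
    beta1: float = DEFAULT_EFFECT,
    alpha1: float = DEFAULT_EFFECT,
    metric: str = "md",
    **kwargs,
) -> GroundTruth:
    """Study-condition template: 84-ROI parcellation, bilateral planted
    chains, medial-temporal plus off-target severity elevation."""
    parc, edges = make_template_graph(42, model="desikan84", rng_seed=rng_seed)
    idx = parc.index
    chains = tuple(
        tuple(idx[(name, hemi)] for name in DEFAULT_CHAIN_NAMES)
        for hemi in ("left", "right")
    )
    elevated = [
        idx[(name, hemi)] for name in DEFAULT_ELEVATED_NAMES for hemi in ("left", "right")
    ]
    return build_ground_truth(
        parc, edges, chains, beta1=beta1, alpha1=alpha1, metric=metric,
        elevated_rois=elevated, rng_seed=rng_seed, **kwargs,
    )


def simulate_cohort(
    ground_truth: GroundTruth, n_subjects: int = 62, rng_seed: int = 0
) -> Cohort:
    """Draw one cohort from a frozen generative model.

    Per subject: age ~ N(70, 8^2) years, sex ~ Bernoulli(0.5), a shared tau
    severity ~ Gamma(shape, scale) added to every elevated ROI.  Planted
    links are generated in chain order; every other node and edge carries
    covariate effects plus independent noise only.  Streamline counts are
    negative-binomial on true edges and Poisson on the spurious pairs;
    diffusion metrics exist exactly where a subject's count is positive.
    """
    if n_subjects < 10:
        raise ValueError("n_subjects must be >= 10")
    gt = ground_truth
    parc = gt.parcellation
    n_roi = parc.n_rois
    rng = np.random.default_rng(np.random.SeedSequence([rng_seed, 3]))

    age = rng.normal(70.0, 8.0, n_subjects)
    z_age = (age - 70.0) / 8.0
    sex = rng.integers(0, 2, n_subjects).astype(int)
    severity = rng.gamma(gt.root_gamma_shape, gt.root_gamma_scale, n_subjects)

    tau = np.empty((n_subjects, n_roi))
    for i in range(n_roi):
        tau[:, i] = (
            1.0
            + gt.gamma_age_tau * z_age
            + gt.gamma_sex_tau * sex
            + rng.normal(0.0, gt.tau_noise_sd, n_subjects)
        )
        if i in gt.elevated_rois:
            tau[:, i] += severity

    # Per-edge latent metric channels: covariates + noise everywhere first.
    support = list(gt.edges) + list(gt.spurious_pairs)
    latents: dict[str, dict[tuple[int, int], np.ndarray]] = {m: {} for m in EDGE_METRICS}
    for pair in support:
        for m in EDGE_METRICS:
            latents[m][pair] = (
                gt.gamma_age_metric * z_age
                + gt.gamma_sex_metric * sex
                + rng.normal(0.0, gt.metric_noise_sd, n_subjects)
            )

    # Planted chains overwrite the configured channel and downstream tau.
    for chain in gt.chains:
        for u, v in zip(chain, chain[1:]):
            link = gt.link_for(u, v)
            pair = (min(u, v), max(u, v))
            eps_e = rng.normal(0.0, gt.metric_noise_sd, n_subjects)
            lat = (
                link.slope_up_latent * (tau[:, u] - tau[:, u].mean())
                + gt.gamma_age_metric * z_age
                + gt.gamma_sex_metric * sex
                + eps_e
            )
            latents[gt.metric][pair] = lat
            eps_t = rng.normal(0.0, gt.tau_noise_sd, n_subjects)
            tau[:, v] = (
                1.0
                + link.slope_down_latent * (lat - lat.mean())
                + gt.gamma_age_tau * z_age
                + gt.gamma_sex_tau * sex
                + eps_t
            )

    amyloid_burden = rng.gamma(2.0, 10.0, n_subjects)
    amyloid = amyloid_burden[:, None] * gt.amyloid_loadings[None, :] + rng.normal(
        0.0, 5.0, (n_subjects, n_roi)
    )

    # Streamline counts per subject on true and spurious pairs.
    counts = np.zeros((n_subjects, len(support)))
    k = gt.count_dispersion
    for e_idx, (i, j) in enumerate(support):
        if gt.edge_mean_counts[i, j] > 0:
            mu = gt.edge_mean_counts[i, j]
            counts[:, e_idx] = np.maximum(
                rng.negative_binomial(k, k / (k + mu), n_subjects), 1
            )
        else:
            counts[:, e_idx] = rng.poisson(gt.spurious_mean, n_subjects)

    subjects: list[SubjectRecord] = []
    order = np.argsort(np.argsort(severity))  # severity rank -> group label
    tertile = np.ceil((order + 1) / (n_subjects / 3.0)).astype(int)
    group_names = {1: "CN", 2: "SCD", 3: "MCI"}
    for s in range(n_subjects):
        conn = np.zeros((n_roi, n_roi))
        metrics = {m: np.full((n_roi, n_roi), np.nan) for m in EDGE_METRICS}
        for e_idx, (i, j) in enumerate(support):
            c = counts[s, e_idx]
            if c > 0:
                conn[i, j] = conn[j, i] = c
                for m in EDGE_METRICS:
                    loc, scale = METRIC_UNITS[m]
                    val = loc + scale * latents[m][(i, j)][s]
                    metrics[m][i, j] = metrics[m][j, i] = val
        subjects.append(
            SubjectRecord(
                subject_id=f"sub{s:03d}",
                age=float(age[s]),
                sex=int(sex[s]),
                group=group_names[min(int(tertile[s]), 3)],
                node_signal={
                    "tau_suvr": tau[s].copy(),
                    "amyloid_centiloid": amyloid[s].copy(),
                },
                conn_counts=conn,
                total_streamlines=float(conn.sum() / 2.0 * 1.25),
                edge_metric=metrics,
            )
        )
    return Cohort(parcellation=parc, subjects=subjects)


def simulate_null_cohort(
    ground_truth: GroundTruth, n_subjects: int = 62, rng_seed: int = 0
) -> Cohort:
    """Matched negative control: identical template and severity structure,
    every planted effect set to zero."""
    return simulate_cohort(ground_truth.null(), n_subjects, rng_seed)
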