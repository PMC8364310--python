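"""End-to-end orchestration: backbone -> seeds -> search -> bootstrap -> tables.

A run is described by a YAML/dict config and writes deterministic
tab-separated outputs plus a JSON manifest (config snapshot, input
checksums, seeds, row counts) sufficient to re-run bit-identically.

Config schema (all analysis keys optional, defaults shown)::

    inputs:                  # either four tables ...
      parcellation: path
      subjects: path
      nodes: path
      edges: path
    simulate:                # ... or a synthetic cohort
      template: default | chain
      n_subjects: 62
      rng_seed: 7
      beta1: 0.55
      alpha1: 0.55
    metric: md               # or "all" to loop over every channel
    signal: tau_suvr
    alpha: 0.05
    positivity_cutoff: 1.23
    seed_prevalence: 0.80
    backbone_fraction: 0.10
    hemisphere_mode: separate
    seed_list: [name, ...]   # optional explicit seeds
    sweep: true
    bootstrap:
      n_boot: 200
      rng_seed: 17
      min_frequency: 0.30
      resample_backbone: false
      n_jobs: 1
"""

from __future__ import annotations

import hashlib
import json
import logging
from datetime import datetime, timezone
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .backbone import backbone_sweep, build_backbone, group_mean_connectivity, \
    normalize_connectivity, write_backbone_table
from .bootstrap import bootstrap_ddis, filter_stability, write_stability_table
from .cohort import (
    Cohort,
    DdisConfig,
    EDGE_METRICS,
    load_cohort,
    validate_cohort,
    write_cohort,
    write_pathway_table,
)
from .core import run_ddis, summarize_pattern
from .node_signal import (
    AMYLOID_CENTILOID_CUTOFF,
    call_positivity,
    compute_prevalence,
    seeds_from_names,
    select_seeds,
    write_prevalence_table,
)
from .simulate import chain_ground_truth, default_ground_truth, simulate_cohort

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failure, tagged with the stage that raised it."""


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _load_config(config: str | Path | dict) -> dict:
    if isinstance(config, dict):
        return dict(config)
    with open(config) as fh:
        return yaml.safe_load(fh)


def _build_ddis_config(cfg: dict, metric: str) -> DdisConfig:
    signal = cfg.get("signal", "tau_suvr")
    default_cutoff = 1.23 if signal == "tau_suvr" else AMYLOID_CENTILOID_CUTOFF
    try:
        return DdisConfig(
            metric=metric,
            signal=signal,
            alpha=float(cfg.get("alpha", 0.05)),
            positivity_cutoff=float(cfg.get("positivity_cutoff", default_cutoff)),
            seed_prevalence=float(cfg.get("seed_prevalence", 0.80)),
            backbone_fraction=float(cfg.get("backbone_fraction", 0.10)),
            hemisphere_mode=cfg.get("hemisphere_mode", "separate"),
            size_correction=cfg.get("size_correction", "mean"),
            rng_seed=int(cfg.get("rng_seed", 0)),
        )
    except ValueError as err:
        raise PipelineError(f"[config] {err}") from err


def _acquire_cohort(cfg: dict, out: Path, manifest: dict) -> Cohort:
    if "inputs" in cfg:
        paths = {k: Path(v) for k, v in cfg["inputs"].items()}
        try:
            cohort = load_cohort(
                paths["subjects"], paths["nodes"], paths["edges"], paths["parcellation"]
            )
        except Exception as err:
            raise PipelineError(f"[load] {err}") from err
        manifest["input_checksums"] = {k: _sha256(p) for k, p in paths.items()}
    elif "simulate" in cfg:
        sim = cfg["simulate"] or {}
        template = sim.get("template", "default")
        seed = int(sim.get("rng_seed", 7))
        kwargs = {
            k: sim[k] for k in ("beta1", "alpha1", "metric") if k in sim
        }
        if template == "default":
            gt = default_ground_truth(rng_seed=seed, **kwargs)
        elif template == "chain":
            gt = chain_ground_truth(
                n_nodes=int(sim.get("n_nodes", 6)),
                bilateral=bool(sim.get("bilateral", False)),
                rng_seed=seed,
                **kwargs,
            )
        else:
            raise PipelineError(f"[simulate] unknown template {template!r}")
        cohort = simulate_cohort(gt, int(sim.get("n_subjects", 62)), rng_seed=seed)
        table_paths = write_cohort(cohort, out / "inputs")
        manifest["input_checksums"] = {k: _sha256(p) for k, p in table_paths.items()}
    else:
        raise PipelineError("[config] config needs either 'inputs' or 'simulate'")

    problems = validate_cohort(cohort)
    if problems:
        raise PipelineError("[validate] cohort invalid:\n" + "\n".join(problems))
    return cohort


def run_pipeline(config: str | Path | dict, out_dir: str | Path) -> Path:
    """Execute every stage and write all output tables plus a manifest.

    Returns the output directory.  Any stage error aborts with a
    stage-tagged :class:`PipelineError` before later stages run.
    """
    cfg = _load_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "ddis_version": __version__,
        "config": cfg,
        "started_utc": datetime.now(timezone.utc).isoformat(),
        "row_counts": {},
    }

    cohort = _acquire_cohort(cfg, out, manifest)
    metric_cfg = cfg.get("metric", "md")
    metrics = list(EDGE_METRICS) if metric_cfg == "all" else [metric_cfg]

    base_config = _build_ddis_config(cfg, metrics[0])
    try:
        backbone = build_backbone(
            cohort, base_config.backbone_fraction, base_config.size_correction
        )
    except Exception as err:
        raise PipelineError(f"[backbone] {err}") from err
    bb_df = write_backbone_table(backbone, cohort.parcellation, out / "backbone_edges.tsv")
    manifest["row_counts"]["backbone_edges.tsv"] = len(bb_df)

    if cfg.get("sweep", True):
        sizes = cohort.parcellation.sizes
        gm = group_mean_connectivity(
            [
                normalize_connectivity(
                    s.conn_counts, s.total_streamlines, sizes, base_config.size_correction
                )
                for s in cohort.subjects
            ]
        )
        sweep_df = backbone_sweep(gm)
        sweep_df.to_csv(out / "sweep.tsv", sep="\t", index=False)
        manifest["row_counts"]["sweep.tsv"] = len(sweep_df)

    pos = call_positivity(
        cohort.node_signal_matrix(base_config.signal),
        base_config.positivity_cutoff,
        strict=base_config.strict_positivity,
    )
    prevalence = compute_prevalence(pos, base_config.signal, base_config.positivity_cutoff)
    if cfg.get("seed_list"):
        seeds = seeds_from_names(cohort.parcellation, cfg["seed_list"])
    else:
        seeds = select_seeds(prevalence, cohort.parcellation, base_config.seed_prevalence)
    prev_df = write_prevalence_table(
        prevalence, cohort.parcellation, seeds, out / "prevalence.tsv"
    )
    manifest["row_counts"]["prevalence.tsv"] = len(prev_df)
    manifest["n_seeds"] = len(seeds)

    for metric in metrics:
        config = _build_ddis_config(cfg, metric)
        suffix = f".{metric}" if len(metrics) > 1 else ""
        try:
            pattern = run_ddis(cohort, backbone, seeds, config)
        except Exception as err:
            raise PipelineError(f"[ddis:{metric}] {err}") from err
        pw_df = write_pathway_table(pattern, out / f"pathways{suffix}.tsv")
        manifest["row_counts"][f"pathways{suffix}.tsv"] = len(pw_df)
        summary = summarize_pattern(pattern)
        summary.to_csv(out / f"summary{suffix}.tsv", sep="\t", index=False)
        pd.DataFrame(pattern.tested_connections).to_csv(
            out / f"tested_connections{suffix}.tsv", sep="\t", index=False
        )

        boot_cfg = cfg.get("bootstrap")
        if boot_cfg:
            try:
                smap = bootstrap_ddis(
                    cohort,
                    config,
                    n_boot=int(boot_cfg.get("n_boot", 200)),
                    rng_seed=int(boot_cfg.get("rng_seed", config.rng_seed)),
                    resample_backbone=bool(boot_cfg.get("resample_backbone", False)),
                    backbone=None if boot_cfg.get("resample_backbone") else backbone,
                    n_jobs=int(boot_cfg.get("n_jobs", 1)),
                )
            except Exception as err:
                raise PipelineError(f"[bootstrap:{metric}] {err}") from err
            st_df = write_stability_table(
                smap, cohort.parcellation, out / f"stability{suffix}.tsv"
            )
            manifest["row_counts"][f"stability{suffix}.tsv"] = len(st_df)
            kept = filter_stability(
                smap, float(boot_cfg.get("min_frequency", 0.30))
            )
            write_stability_table(
                kept, cohort.parcellation, out / f"stability_filtered{suffix}.tsv"
            )

    manifest["finished_utc"] = datetime.now(timezone.utc).isoformat()
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return out
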