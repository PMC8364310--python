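"""The amyloid variant: same search with the node signal swapped.

Replacing tau SUVR with amyloid centiloid (positivity at 20 centiloid)
re-seeds the search from the amyloid prevalence map.  The generator plants
no amyloid-diffusion effects, so the expected result is a (near-)empty
pattern — the negative-control behavior of the method.  An explicit seed
list can also bypass prevalence-based seeding entirely.
"""

import ddis

gt = ddis.default_ground_truth(rng_seed=7)  # 84-ROI template, tau chains only
cohort = ddis.simulate_cohort(gt, n_subjects=62, rng_seed=8)
backbone = ddis.build_backbone(cohort)

config = ddis.DdisConfig(metric="md", signal="amyloid_centiloid", positivity_cutoff=20.0)
pos = ddis.call_positivity(cohort.node_signal_matrix("amyloid_centiloid"), 20.0)
prevalence = ddis.compute_prevalence(pos, "amyloid_centiloid", 20.0)
seeds = ddis.select_seeds(prevalence, cohort.parcellation, threshold=0.80)
pattern = ddis.run_ddis(cohort, backbone, seeds, config)
print(f"amyloid seeds: {len(seeds)}   amyloid-MD pathways: {len(pattern.pathways)}")

explicit = ddis.seeds_from_names(
    cohort.parcellation, ["precentral", "pericalcarine", "pallidum", "putamen", "thalamus"]
)
pattern2 = ddis.run_ddis(cohort, backbone, explicit, config)
print(f"explicit-seed run: {len(explicit)} seeds, {len(pattern2.pathways)} pathways")
# Few or zero pathways: amyloid burden here has no planted relation to the
# diffusion metrics, so the dual-regression gate rejects the candidates.
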