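"""One-config run of the whole workflow: simulate -> rarefy -> diversity ->
enrichment -> per-compartment networks -> robustness.

Writes all tables (TSV/GraphML) plus a machine-readable summary to a
directory; the same config + master seed gives byte-identical outputs.
"""

import json

from meadownet import PipelineConfig, SimulationConfig, run_pipeline

config = PipelineConfig(
    out_dir="scratch/example_pipeline",
    master_seed=1,
    simulation=SimulationConfig(
        n_fungi=10,
        n_bacteria=18,
        n_archaea=4,
        replicates={"s": 6, "bk": 8, "rp": 8, "rt": 8, "rz": 8, "w": 6, "lp": 8, "lf": 8},
        depth_range=(800, 2000),
        planted_edges=[("FOTU0002", "BOTU0001", 0.8)],
    ),
    sparcc_resamples=10,
    network_permutations=49,
    diversity_permutations=499,
    simper_permutations=99,
    robustness_replicates=200,
    robustness_fractions=[0.0, 0.25, 0.5, 0.75, 1.0],
)
summary = run_pipeline(config)

print(f"rarefied fungi to {summary['rarefaction_depth_fungi']} reads, "
      f"prokaryotes to {summary['rarefaction_depth_prokaryotes']}")
comp = summary["permanova_fungi"]["compartment"]
print(f"fungal PERMANOVA (compartment): r2={comp['r2']:.3f} p={comp['p']:.3f}")
for name, topo in summary.get("networks", {}).items():
    print(f"  {name}: {topo['nodes']} nodes, {topo['edges']} edges, "
          f"avg degree {topo['average_degree']:.2f}")
for group, rate in summary.get("decline_rates", {}).items():
    print(f"  decline rate {group}: {rate:.2f}")
print(json.dumps(summary.get("enriched_counts_fungi", {}), indent=2))
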