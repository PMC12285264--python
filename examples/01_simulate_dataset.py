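"""Generate a synthetic compartment-resolved dataset and inspect its shape.

The generator draws paired fungal (ITS2-like) and prokaryotic (16S-like) OTU
count tables over the eight compartments of a seagrass meadow survey, with a
dominant endophytic fungal keystone pinned to per-compartment target
abundances.
"""

from meadownet import SimulationConfig, generate_dataset, to_relative

config = SimulationConfig(
    n_fungi=20,
    n_bacteria=40,
    n_archaea=6,
    replicates={"s": 6, "bk": 12, "rp": 12, "rt": 12, "rz": 12, "w": 8, "lp": 12, "lf": 12},
    seed=42,
)
fungal, prok, taxonomy, metadata, truth = generate_dataset(config)

print(f"fungal table:     {len(fungal.sample_ids)} samples x {len(fungal.taxon_ids)} OTUs")
print(f"prokaryote table: {len(prok.sample_ids)} samples x {len(prok.taxon_ids)} OTUs")

rel = to_relative(fungal)
for comp in ("rz", "rt", "w"):
    ids = metadata.samples_in([comp])
    mean_ra = rel.data.loc[ids, truth.keystone_taxon].mean()
    print(f"keystone mean relative abundance in {comp}: {mean_ra:.3f}")
# The keystone fungus dominates the below-ground tissues (rhizome ~0.9,
# root ~0.8) and is rare in the water column, emulating a host-restricted
# endophyte's distribution.
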