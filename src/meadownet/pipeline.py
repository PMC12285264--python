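"""End-to-end workflow: ingest/simulate -> rarefy -> diversity -> enrichment
-> per-compartment networks -> robustness.

One :class:`PipelineConfig` drives every stage; per-stage seeds are derived
from the master seed by hashing the stage name (CRC32), so adding a stage
never perturbs the randomness of earlier stages and the whole run is
byte-reproducible.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import diversity as dv
from . import network as nw
from . import enrichment as sp
from . import stability as st
from .io import (
    FeatureTable,
    SampleMetadata,
    TaxonomyTable,
    read_feature_table,
    read_metadata,
    read_taxonomy,
    to_relative,
    write_feature_table,
    write_metadata,
    write_taxonomy,
)
from .simulate import SimulationConfig, generate_dataset

logger = logging.getLogger(__name__)

DEFAULT_NETWORK_GROUPS: dict[str, tuple[str, ...]] = {
    "leaf": ("lf",),
    "root": ("rt",),
    "rhizome": ("rz",),
    "phylloplane": ("lp",),
    "sediment": ("bk", "rp"),
}


def stage_seed(master: int, stage: str) -> int:
    """Deterministic per-stage seed: CRC32 of ``"<master>:<stage>"`` mod 2^31."""
    return zlib.crc32(f"{master}:{stage}".encode()) % (2**31)


@dataclass
class PipelineConfig:
    out_dir: str = "meadownet_out"
    master_seed: int = 0
    # inputs: either four paths or a simulation config
    fungal_table: str | None = None
    prokaryote_table: str | None = None
    taxonomy: str | None = None
    metadata: str | None = None
    simulation: SimulationConfig | None = None
    # stage parameters
    network_groups: Mapping[str, Sequence[str]] = field(
        default_factory=lambda: dict(DEFAULT_NETWORK_GROUPS)
    )
    rarefaction_depth: int | None = None
    prevalence: float = 0.5
    r_threshold: float = 0.2
    p_threshold: float = 0.05
    sparcc_resamples: int = 20
    sparcc_exclusion_iterations: int = 10
    sparcc_exclusion_threshold: float = 0.1
    network_permutations: int = 100
    diversity_permutations: int = 999
    simper_permutations: int = 99
    robustness_fractions: Sequence[float] = tuple(np.round(np.arange(0, 1.01, 0.1), 10))
    robustness_replicates: int = 1000
    ego_focus: str | None = None

    def validate(self) -> None:
        simulated = self.simulation is not None
        paths = (self.fungal_table, self.prokaryote_table, self.taxonomy, self.metadata)
        if not simulated and any(p is None for p in paths):
            raise ValueError("provide either a simulation config or all four input paths")
        if not 0.0 < self.prevalence < 1.0:
            raise ValueError("prevalence must be in (0, 1)")
        if not 0.0 <= self.r_threshold < 1.0:
            raise ValueError("r_threshold must be in [0, 1)")
        if not 0.0 < self.p_threshold <= 1.0:
            raise ValueError("p_threshold must be in (0, 1]")

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        """Load a flat key/value config (YAML syntax). Keys starting with
        ``simulation.`` populate the embedded :class:`SimulationConfig`."""
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim_keys = {k[len("simulation."):]: v for k, v in raw.items() if k.startswith("simulation.")}
        top = {k: v for k, v in raw.items() if not k.startswith("simulation.")}
        if "simulation" in top and isinstance(top["simulation"], dict):
            sim_keys.update(top.pop("simulation"))
        if sim_keys or top.pop("simulate", False):
            top["simulation"] = SimulationConfig(**sim_keys)
        cfg = cls(**top)
        cfg.validate()
        return cfg


def _load_inputs(config: PipelineConfig):
    if config.simulation is not None:
        sim = dataclasses.replace(
            config.simulation, seed=stage_seed(config.master_seed, "simulate")
        )
        return generate_dataset(sim)
    fungal = read_feature_table(config.fungal_table)
    prok = read_feature_table(config.prokaryote_table)
    taxonomy = read_taxonomy(config.taxonomy)
    metadata = read_metadata(config.metadata)
    return fungal, prok, taxonomy, metadata, None


def _all_pairs(compartments: list[str]) -> list[tuple[str, str]]:
    return [
        (a, b)
        for i, a in enumerate(compartments)
        for b in compartments[i + 1:]
    ]


def _diversity_stage(
    marker: str,
    table: FeatureTable,
    metadata: SampleMetadata,
    config: PipelineConfig,
    out: Path,
    summary: dict,
) -> None:
    seed = stage_seed(config.master_seed, f"diversity:{marker}")
    alpha = dv.alpha_diversity(table)
    alpha.to_csv(out / f"alpha_{marker}.tsv", sep="\t", index_label="sample_id")

    present = sorted(set(metadata.data.loc[table.sample_ids, "compartment"]))
    pairs = _all_pairs(present)
    if pairs:
        dv.pairwise_wilcoxon(alpha["shannon"], metadata, pairs).to_csv(
            out / f"alpha_tests_{marker}.tsv", sep="\t", index=False
        )

    dm = dv.bray_curtis(to_relative(table))
    dm.to_frame().to_csv(out / f"bray_curtis_{marker}.tsv", sep="\t", index_label="sample_id")
    ord_res = dv.pcoa(dm)
    ord_res.coordinates.to_csv(out / f"pcoa_{marker}.tsv", sep="\t", index_label="sample_id")

    factors = ["compartment", "month", "pH", "temperature", "salinity"]
    perma = dv.permanova(
        dm, metadata, factors, permutations=config.diversity_permutations, seed=seed
    )
    an = dv.anosim(
        dm,
        metadata.data.loc[dm.ids, "compartment"],
        permutations=config.diversity_permutations,
        seed=seed + 1,
    )
    rows = [
        {
            "test": "PERMANOVA",
            "factor": r.factor,
            "statistic": r.statistic,
            "effect_size": r.effect_size,
            "p": r.p,
            "permutations": r.permutations,
        }
        for r in perma
    ]
    rows.append(
        {
            "test": "ANOSIM",
            "factor": an.factor,
            "statistic": an.statistic,
            "effect_size": an.effect_size,
            "p": an.p,
            "permutations": an.permutations,
        }
    )
    pd.DataFrame(rows).to_csv(out / f"beta_tests_{marker}.tsv", sep="\t", index=False)
    summary[f"permanova_{marker}"] = {
        r.factor: {"F": r.statistic, "r2": r.effect_size, "p": r.p} for r in perma
    }
    summary[f"anosim_{marker}"] = {"R": an.statistic, "p": an.p}


def _enrichment_stage(
    marker: str,
    kingdom: str,
    table: FeatureTable,
    metadata: SampleMetadata,
    config: PipelineConfig,
    out: Path,
    summary: dict,
) -> None:
    rel = to_relative(table)
    names = ["s_to_seagrass_sediment", "sediment_to_belowground", "w_to_lp", "w_to_lf"]
    counts = {}
    for name, (ga, gb) in zip(names, sp.CANONICAL_PAIRS):
        present = set(metadata.data.loc[table.sample_ids, "compartment"])
        if not (set(ga) & present and set(gb) & present):
            continue
        seed = stage_seed(config.master_seed, f"enrich:{marker}:{name}")
        records = sp.enrichment_screen(
            rel,
            metadata,
            (ga, gb),
            kingdom=kingdom,
            permutations=config.simper_permutations,
            seed=seed,
        )
        sp.records_to_frame(records).to_csv(
            out / f"enrichment_{marker}_{name}.tsv", sep="\t", index_label="taxon"
        )
        counts[name] = int(sum(r.enriched for r in records))
    summary[f"enriched_counts_{marker}"] = counts


def _network_stage(
    group: str,
    compartments: Sequence[str],
    fungal: FeatureTable,
    prok: FeatureTable,
    taxonomy: TaxonomyTable,
    metadata: SampleMetadata,
    config: PipelineConfig,
    out: Path,
    summary: dict,
    topo_rows: list,
) -> None:
    ids = [s for s in fungal.sample_ids if metadata.compartment(s) in set(compartments)]
    ids = [s for s in ids if s in set(prok.sample_ids)]
    if len(ids) < 4:
        logger.warning("network group %s has %d samples; skipped", group, len(ids))
        return
    combined = fungal.subset_samples(ids).concat_taxa(prok.subset_samples(ids))
    filtered = nw.prevalence_filter(combined, config.prevalence)
    logger.info(
        "network %s: %d samples, %d/%d taxa pass prevalence",
        group, len(ids), len(filtered.taxon_ids), len(combined.taxon_ids),
    )
    seed = stage_seed(config.master_seed, f"network:{group}")
    corr = nw.sparcc(
        filtered,
        n_exclusion_iterations=config.sparcc_exclusion_iterations,
        exclusion_threshold=config.sparcc_exclusion_threshold,
        n_resamples=config.sparcc_resamples,
        seed=seed,
    )
    nw.sparcc_pvalues(filtered, corr, config.network_permutations, seed=seed + 1)
    rel = to_relative(filtered)
    abundances = rel.data.mean(axis=0).to_dict()
    domains = taxonomy.domains(filtered.taxon_ids)
    whole = nw.build_network(
        corr, domains, abundances, config.r_threshold, config.p_threshold
    )
    inter = nw.extract_interdomain(whole)
    for net, label in ((whole, "whole"), (inter, "interdomain")):
        nw.write_edge_list(net, out / f"edges_{group}_{label}.tsv")
        nw.write_graphml(net, out / f"network_{group}_{label}.graphml")
        topo = nw.topology(net, seed=stage_seed(config.master_seed, f"modules:{group}:{label}"))
        topo_rows.append({"group": group, "network": label, **vars(topo)})
    if inter.n_edges >= 1:
        part = nw.detect_modules(
            inter, seed=stage_seed(config.master_seed, f"modules:{group}:interdomain")
        )
        roles = nw.zi_pi(inter, part)
        nw.roles_to_frame(roles).to_csv(
            out / f"node_roles_{group}.tsv", sep="\t", index_label="node"
        )
        summary.setdefault("keystones", {})[group] = int(
            sum(r.category != "Peripheral" for r in roles)
        )
        focus = config.ego_focus
        if focus and focus in inter.graph:
            _, (pos, neg) = nw.ego_network(inter, focus)
            summary.setdefault("ego_edges", {})[group] = {"positive": pos, "negative": neg}
        if any(d == "fungi" for d in inter.domains().values()):
            curve = st.robustness_curve(
                inter,
                fractions=np.asarray(config.robustness_fractions, dtype=float),
                n_replicates=config.robustness_replicates,
                seed=stage_seed(config.master_seed, f"robustness:{group}"),
            )
            curve.to_frame().to_csv(out / f"robustness_{group}.tsv", sep="\t", index=False)
            summary.setdefault("decline_rates", {})[group] = st.decline_rate(curve).rate


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all stages, writing TSV/GraphML outputs and a summary JSON to
    ``config.out_dir``; returns the summary as a dict."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {"master_seed": config.master_seed}

    fungal, prok, taxonomy, metadata, truth = _load_inputs(config)
    metadata.validate_against(fungal)
    metadata.validate_against(prok)
    if config.simulation is not None:
        write_feature_table(fungal, out / "input_fungal_counts.tsv")
        write_feature_table(prok, out / "input_prokaryote_counts.tsv")
        write_taxonomy(taxonomy, out / "input_taxonomy.tsv")
        write_metadata(metadata, out / "input_metadata.tsv")
        if config.ego_focus is None and truth is not None:
            config.ego_focus = truth.keystone_taxon

    rare = {}
    for marker, table in (("fungi", fungal), ("prokaryotes", prok)):
        depth = config.rarefaction_depth or int(table.data.sum(axis=1).min())
        rare[marker] = dv.rarefy(
            table, depth, seed=stage_seed(config.master_seed, f"rarefy:{marker}")
        )
        summary[f"rarefaction_depth_{marker}"] = depth
        summary[f"samples_retained_{marker}"] = len(rare[marker].sample_ids)
        logger.info(
            "%s: rarefied %d samples to depth %d", marker, len(rare[marker].sample_ids), depth
        )

    for marker in ("fungi", "prokaryotes"):
        _diversity_stage(marker, rare[marker], metadata, config, out, summary)
        _enrichment_stage(
            marker, marker, rare[marker], metadata, config, out, summary
        )

    # networks use samples present in both rarefied tables
    shared = [s for s in rare["fungi"].sample_ids if s in set(rare["prokaryotes"].sample_ids)]
    fungal_r = rare["fungi"].subset_samples(shared)
    prok_r = rare["prokaryotes"].subset_samples(shared)
    topo_rows: list = []
    for group, comps in config.network_groups.items():
        _network_stage(
            group, tuple(comps), fungal_r, prok_r, taxonomy, metadata, config,
            out, summary, topo_rows,
        )
    if topo_rows:
        pd.DataFrame(topo_rows).to_csv(out / "topology.tsv", sep="\t", index=False)
        summary["networks"] = {
            f"{row['group']}/{row['network']}": {
                "nodes": row["total_nodes"],
                "edges": row["total_edges"],
                "average_degree": row["average_degree"],
                "modularity": row["modularity"],
            }
            for row in topo_rows
        }

    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    return summary
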