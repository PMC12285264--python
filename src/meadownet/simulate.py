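"""Synthetic paired fungal/prokaryotic communities with planted structure.

The generator emulates the data shape of a compartment-resolved seagrass
microbiome survey: two marker-gene OTU count tables (fungal ITS2-like and
prokaryotic 16S-like) over the same samples, a taxonomy table, sample
metadata over the eight compartment codes, and a ground-truth record of what
was planted.

Latent model
------------
Each taxon *t* has a latent log-abundance

    log a_t = mu_t + delta_{c(s),t} + sigma * z_t,

where ``mu_t`` is a taxon base level, ``delta`` a compartment-specific shift
applied to a configurable fraction of taxa, and ``z`` a standard multivariate
normal whose correlation matrix carries the planted fungal-prokaryote edges
(a Gaussian copula on the log scale). Counts are then drawn multinomially per
sample and marker at that sample's sequencing depth, which induces the
compositional closure that SparCC-style inference is designed for. An
optional keystone fungus is pinned to a target relative abundance per
compartment (emulating a single dominant endophyte) while keeping its copula
variate, so planted keystone edges survive the pinning.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import COMPARTMENTS, FeatureTable, SampleMetadata, TaxonomyTable

_FUNGAL_PHYLA = (
    "Ascomycota",
    "Basidiomycota",
    "Chytridiomycota",
    "Aphelidiomycota",
    "Mortierellomycota",
)
_BACTERIAL_PHYLA = (
    "Proteobacteria",
    "Bacteroidota",
    "Desulfobacterota",
    "Actinobacteriota",
    "Cyanobacteria",
)
_ARCHAEAL_PHYLA = ("Crenarchaeota", "Thermoplasmatota", "Asgardarchaeota")

_MONTHS = ("Dec", "Mar", "Jun", "Aug")
_MONTH_TEMP = {"Dec": 18.0, "Mar": 21.0, "Jun": 29.0, "Aug": 30.0}


@dataclass
class SimulationConfig:
    """Parameters of the synthetic community generator.

    Defaults mirror the shape of the study design the package targets:
    8 compartments with 12-36 replicates each, uneven sequencing depths
    (default 2,000-10,000 reads), a log-normal community, compartment shifts
    on a fraction of taxa, one dominant endophytic fungal keystone and a
    planted fungal-prokaryote correlation structure.
    """

    compartments: Sequence[str] = COMPARTMENTS
    replicates: Mapping[str, int] | int = field(
        default_factory=lambda: {
            "s": 12, "bk": 36, "rp": 36, "rt": 36, "rz": 36, "w": 20, "lp": 36, "lf": 36,
        }
    )
    n_fungi: int = 60
    n_bacteria: int = 120
    n_archaea: int = 20
    depth_range: tuple[int, int] = (2_000, 10_000)
    latent_mean_sd: float = 1.5      # spread of taxon base levels mu_t (log scale)
    latent_sigma: float = 1.0        # per-sample residual sd on the log scale
    effect_fraction: float = 0.3     # fraction of taxa shifted per compartment
    effect_size: float = 1.0         # sd of the compartment log-scale shift
    keystone_taxon: str | None = "FOTU0001"
    keystone_targets: Mapping[str, float] = field(
        default_factory=lambda: {
            "rz": 0.90, "rt": 0.80, "bk": 0.55, "rp": 0.55,
            "lf": 0.55, "lp": 0.55, "s": 0.15, "w": 0.10,
        }
    )
    keystone_sigma: float = 0.3      # residual log-sd of the pinned keystone
    planted_edges: Sequence[tuple[str, str, float]] = ()
    unclassified_fraction: float = 0.1
    store_latent: bool = False   # keep latent log-abundances on the GroundTruth
    seed: int = 0

    def validate(self) -> None:
        bad = set(self.compartments) - set(COMPARTMENTS)
        if bad:
            raise ValueError(f"unknown compartment codes: {sorted(bad)}")
        for a, b, rho in self.planted_edges:
            if a == b:
                raise ValueError(f"self-edge planted on {a!r}")
            if not -1.0 < rho < 1.0:
                raise ValueError(f"planted correlation must be in (-1, 1), got {rho}")
        for comp, target in self.keystone_targets.items():
            if not 0.0 < target < 1.0:
                raise ValueError(f"keystone target for {comp!r} must be in (0, 1)")
        if self.depth_range[0] <= 0 or self.depth_range[1] < self.depth_range[0]:
            raise ValueError("invalid depth range")

    def n_replicates(self, comp: str) -> int:
        if isinstance(self.replicates, int):
            return self.replicates
        return int(self.replicates[comp])


@dataclass
class GroundTruth:
    """What the generator planted: edges with signs, compartment shifts, keystone."""

    planted_edges: list[tuple[str, str, float]]
    compartment_effects: dict[str, dict[str, float]]
    keystone_taxon: str | None
    latent: "pd.DataFrame | None" = None  # samples x taxa log-abundances, if stored

    def __post_init__(self) -> None:
        for a, b, _ in self.planted_edges:
            if a == b:
                raise ValueError("ground truth contains a self-edge")


def _taxon_ids(config: SimulationConfig) -> tuple[list[str], list[str], list[str]]:
    fungi = [f"FOTU{i + 1:04d}" for i in range(config.n_fungi)]
    bacteria = [f"BOTU{i + 1:04d}" for i in range(config.n_bacteria)]
    archaea = [f"AOTU{i + 1:04d}" for i in range(config.n_archaea)]
    return fungi, bacteria, archaea


def _build_taxonomy(
    config: SimulationConfig, rng: np.random.Generator
) -> TaxonomyTable:
    fungi, bacteria, archaea = _taxon_ids(config)
    lineages: dict[str, str] = {}
    for i, t in enumerate(fungi):
        if t == config.keystone_taxon:
            lineages[t] = (
                "k__Fungi;p__Ascomycota;c__Sordariomycetes;o__Lulworthiales;"
                "f__Lulworthiaceae;g__Halophilomyces;s__hongkongensis"
            )
        elif rng.random() < config.unclassified_fraction:
            lineages[t] = "k__Fungi"
        else:
            p = _FUNGAL_PHYLA[i % len(_FUNGAL_PHYLA)]
            lineages[t] = f"k__Fungi;p__{p};g__Fgen{i % 17:02d}"
    for i, t in enumerate(bacteria):
        if rng.random() < config.unclassified_fraction:
            lineages[t] = "d__Bacteria"
        else:
            p = _BACTERIAL_PHYLA[i % len(_BACTERIAL_PHYLA)]
            lineages[t] = f"d__Bacteria;p__{p};f__Bfam{i % 23:02d};g__Bgen{i % 31:02d}"
    for i, t in enumerate(archaea):
        p = _ARCHAEAL_PHYLA[i % len(_ARCHAEAL_PHYLA)]
        lineages[t] = f"d__Archaea;p__{p};g__Agen{i % 7:02d}"
    return TaxonomyTable(lineages)


def _correlation_matrix(
    taxa: list[str], planted: Sequence[tuple[str, str, float]]
) -> np.ndarray:
    index = {t: i for i, t in enumerate(taxa)}
    R = np.eye(len(taxa))
    for a, b, rho in planted:
        if a not in index or b not in index:
            raise ValueError(f"planted edge references unknown taxon: ({a}, {b})")
        R[index[a], index[b]] = rho
        R[index[b], index[a]] = rho
    try:
        np.linalg.cholesky(R)
    except np.linalg.LinAlgError as exc:
        raise ValueError(
            "planted correlation matrix is not positive definite"
        ) from exc
    return R


def generate_dataset(
    config: SimulationConfig,
) -> tuple[FeatureTable, FeatureTable, TaxonomyTable, SampleMetadata, GroundTruth]:
    """Draw a full synthetic dataset.

    Returns ``(fungal_counts, prokaryote_counts, taxonomy, metadata, truth)``.
    Deterministic under ``config.seed``; per-sample totals equal the drawn
    sequencing depths exactly.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    fungi, bacteria, archaea = _taxon_ids(config)
    taxa = fungi + bacteria + archaea
    D = len(taxa)

    taxonomy = _build_taxonomy(config, rng)
    R = _correlation_matrix(taxa, config.planted_edges)
    chol = np.linalg.cholesky(R)

    mu = rng.normal(0.0, config.latent_mean_sd, size=D)
    effects: dict[str, dict[str, float]] = {}
    delta = {}
    for comp in config.compartments:
        mask = rng.random(D) < config.effect_fraction
        shift = np.where(mask, rng.normal(0.0, config.effect_size, size=D), 0.0)
        delta[comp] = shift
        effects[comp] = {taxa[i]: float(shift[i]) for i in np.flatnonzero(mask)}

    keystone_idx = taxa.index(config.keystone_taxon) if config.keystone_taxon else None
    n_f = len(fungi)

    sample_rows = []
    meta_rows = []
    fungal_counts = []
    prok_counts = []
    latent_rows = []
    counter = 0
    for comp in config.compartments:
        for rep in range(config.n_replicates(comp)):
            counter += 1
            sid = f"S{counter:04d}_{comp}"
            month = _MONTHS[rep % len(_MONTHS)]
            z = chol @ rng.standard_normal(D)
            loga = mu + delta[comp] + config.latent_sigma * z
            a = np.exp(loga)
            if keystone_idx is not None and comp in config.keystone_targets:
                t = config.keystone_targets[comp]
                # target is relative abundance within the keystone's own marker
                # table (the fungal community), matching how dominance is
                # reported for amplicon data
                other = a[:n_f].sum() - a[keystone_idx]
                # pin the keystone's expected fraction at t, keep its copula variate
                a[keystone_idx] = (
                    t / (1.0 - t) * other * np.exp(config.keystone_sigma * z[keystone_idx])
                )
            if config.store_latent:
                latent_rows.append(np.log(a))
            frac_f = a[:n_f] / a[:n_f].sum()
            frac_p = a[n_f:] / a[n_f:].sum()
            depth_f = int(rng.integers(config.depth_range[0], config.depth_range[1] + 1))
            depth_p = int(rng.integers(config.depth_range[0], config.depth_range[1] + 1))
            fungal_counts.append(rng.multinomial(depth_f, frac_f))
            prok_counts.append(rng.multinomial(depth_p, frac_p))
            sample_rows.append(sid)
            meta_rows.append(
                {
                    "compartment": comp,
                    "month": month,
                    "pH": round(float(rng.normal(8.0, 0.15)), 3),
                    "temperature": round(float(_MONTH_TEMP[month] + rng.normal(0, 0.8)), 2),
                    "salinity": round(float(rng.normal(30.0, 1.5)), 2),
                }
            )

    fungal = FeatureTable(
        pd.DataFrame(np.asarray(fungal_counts), index=sample_rows, columns=fungi),
        mode="count",
    )
    prok = FeatureTable(
        pd.DataFrame(np.asarray(prok_counts), index=sample_rows, columns=bacteria + archaea),
        mode="count",
    )
    metadata = SampleMetadata(pd.DataFrame(meta_rows, index=pd.Index(sample_rows)))
    truth = GroundTruth(
        planted_edges=list(config.planted_edges),
        compartment_effects=effects,
        keystone_taxon=config.keystone_taxon,
        latent=(
            pd.DataFrame(np.asarray(latent_rows), index=sample_rows, columns=taxa)
            if config.store_latent
            else None
        ),
    )
    return fungal, prok, taxonomy, metadata, truth


def planted_edge_recall(inferred, truth: GroundTruth) -> float:
    """Fraction of planted edges recovered with matching sign.

    ``inferred`` is a :class:`~meadownet.network.Network`. A truth with no
    planted edges yields recall 1.0 by convention (nothing to miss).
    """
    if not truth.planted_edges:
        return 1.0
    hit = 0
    g = inferred.graph
    for a, b, rho in truth.planted_edges:
        if g.has_edge(a, b):
            sign = g.edges[a, b]["sign"]
            if (sign == "+") == (rho > 0):
                hit += 1
    return hit / len(truth.planted_edges)


def planted_edge_sign_accuracy(inferred, truth: GroundTruth) -> float:
    """Among planted edges present in the network, the fraction whose sign matches.

    Returns 1.0 when no planted edge was recovered (vacuous case).
    """
    if not truth.planted_edges:
        return 1.0
    found = 0
    correct = 0
    g = inferred.graph
    for a, b, rho in truth.planted_edges:
        if g.has_edge(a, b):
            found += 1
            if (g.edges[a, b]["sign"] == "+") == (rho > 0):
                correct += 1
    return correct / found if found else 1.0
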