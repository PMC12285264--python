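"""Validation experiments: planted-edge recovery and null calibration.

These routines exercise the full inference chain on synthetic data with
known ground truth — the package's substitute for re-running the analyses on
deposited sequencing data. They are used by the test suite and by the
acceptance script.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from . import diversity as dv
from . import enrichment as en
from . import network as nw
from .io import FeatureTable, SampleMetadata, to_relative
from .simulate import (
    SimulationConfig,
    generate_dataset,
    planted_edge_recall,
    planted_edge_sign_accuracy,
)


def sparcc_edge_recovery(
    seed: int = 0,
    n_runs: int = 10,
    n_samples: int = 60,
    n_fungi: int = 20,
    n_bacteria: int = 25,
    n_archaea: int = 5,
    rho: float = 0.8,
    n_edges: int = 8,
    n_resamples: int = 20,
    n_permutations: int = 100,
) -> dict[str, float]:
    """Recovery of planted fungal-prokaryote edges by the full SparCC chain.

    Plants ``n_edges`` disjoint fungus-bacterium edges at latent correlation
    ``+/-rho`` (alternating signs) in a 50-taxon community of ``n_samples``
    samples, runs prevalence filter -> SparCC -> permutation p-values ->
    thresholding at |r| > 0.2, p < 0.05, and averages planted-edge recall and
    sign accuracy over ``n_runs`` independent datasets.
    """
    edges = []
    for k in range(n_edges):
        sign = 1.0 if k % 2 == 0 else -1.0
        edges.append((f"FOTU{k + 2:04d}", f"BOTU{k + 1:04d}", sign * rho))
    rng = np.random.default_rng(seed)
    recalls, signs = [], []
    for _ in range(n_runs):
        cfg = SimulationConfig(
            compartments=("rz",),
            replicates=n_samples,
            n_fungi=n_fungi,
            n_bacteria=n_bacteria,
            n_archaea=n_archaea,
            keystone_taxon=None,
            effect_fraction=0.0,
            planted_edges=edges,
            depth_range=(5_000, 10_000),
            seed=int(rng.integers(2**31)),
        )
        fungal, prok, taxonomy, metadata, truth = generate_dataset(cfg)
        combined = fungal.concat_taxa(prok)
        filtered = nw.prevalence_filter(combined, 0.5)
        corr = nw.sparcc(
            filtered, n_resamples=n_resamples, seed=int(rng.integers(2**31))
        )
        nw.sparcc_pvalues(
            filtered, corr, n_permutations=n_permutations,
            seed=int(rng.integers(2**31)), n_resamples=0,
        )
        abundances = to_relative(filtered).data.mean(axis=0).to_dict()
        net = nw.build_network(
            corr, taxonomy.domains(filtered.taxon_ids), abundances, 0.2, 0.05
        )
        recalls.append(planted_edge_recall(net, truth))
        signs.append(planted_edge_sign_accuracy(net, truth))
    return {
        "recall": float(np.mean(recalls)),
        "sign_accuracy": float(np.mean(signs)),
        "n_runs": n_runs,
        "n_samples": n_samples,
        "n_taxa": n_fungi + n_bacteria + n_archaea,
    }


def _null_table(rng: np.random.Generator, n_samples: int, n_taxa: int) -> FeatureTable:
    latent = np.exp(rng.normal(0, 1, size=(n_samples, n_taxa)))
    frac = latent / latent.sum(axis=1, keepdims=True)
    counts = np.vstack([rng.multinomial(2000, f) for f in frac])
    return FeatureTable(
        pd.DataFrame(
            counts,
            index=[f"s{i}" for i in range(n_samples)],
            columns=[f"t{j}" for j in range(n_taxa)],
        )
    )


def _null_metadata(sample_ids: list[str], split: int) -> SampleMetadata:
    return SampleMetadata(
        pd.DataFrame(
            {
                "compartment": ["rt"] * split + ["w"] * (len(sample_ids) - split),
                "month": "Dec",
                "pH": 8.0,
                "temperature": 20.0,
                "salinity": 30.0,
            },
            index=pd.Index(sample_ids),
        )
    )


def null_pvalues(
    test: str, n_reps: int = 200, seed: int = 0, permutations: int = 199
) -> np.ndarray:
    """p-values of one test under structure-free (null) data, ``n_reps`` times.

    ``test`` is one of permanova / anosim / kruskal / simper. Under the null
    the p-values should be (discretely) uniform on (0, 1]. Each test draws
    from its own substream of ``seed`` so the four checks are independent.
    All nulls use 16 samples in two groups of 8; group sizes much smaller
    than that leave too few distinct label splits and visibly discretize the
    permutation distribution.
    """
    tests = ("permanova", "anosim", "kruskal", "simper")
    if test not in tests:
        raise ValueError(f"unknown test {test!r}")
    rng = np.random.default_rng([seed, tests.index(test)])
    out = np.empty(n_reps)
    for i in range(n_reps):
        rep_seed = int(rng.integers(2**31))
        if test == "permanova":
            table = _null_table(rng, 16, 10)
            meta = _null_metadata(table.sample_ids, 8)
            dm = dv.bray_curtis(table)
            out[i] = dv.permanova(
                dm, meta, ["compartment"], permutations=permutations, seed=rep_seed
            )[0].p
        elif test == "anosim":
            table = _null_table(rng, 16, 10)
            dm = dv.bray_curtis(table)
            groups = pd.Series(["a"] * 8 + ["b"] * 8, index=dm.ids)
            out[i] = dv.anosim(dm, groups, permutations=permutations, seed=rep_seed).p
        elif test == "kruskal":
            table = _null_table(rng, 16, 8)
            meta = _null_metadata(table.sample_ids, 8)
            out[i] = dv.kruskal_wallis_by_taxon(to_relative(table), meta)["p"].iloc[0]
        elif test == "simper":
            table = to_relative(_null_table(rng, 16, 8))
            meta = _null_metadata(table.sample_ids, 8)
            res = en.simper(
                table, meta, "rt", "w", permutations=permutations, seed=rep_seed
            )
            out[i] = res["p"].iloc[0]
    return out


def ks_uniformity(pvalues: np.ndarray) -> float:
    """KS-test p-value of the hypothesis that p-values are Uniform(0, 1)."""
    return float(stats.kstest(pvalues, "uniform").pvalue)
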