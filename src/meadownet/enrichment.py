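"""SIMPER contribution analysis and the fold-change enrichment screen.

SIMPER decomposes the average between-group Bray-Curtis dissimilarity into
per-taxon contributions; the screen then flags taxa as enriched in the
"latter" compartment of a pair when the log2 fold change of mean relative
abundance exceeds a kingdom-specific cutoff and the SIMPER permutation
p-value is below 0.05, after discarding taxa rarer than 0.01% in the latter
compartment. A zero mean in the denominator compartment is replaced by that
compartment's smallest non-zero mean relative abundance so the ratio stays
defined.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import FeatureTable, SampleMetadata

#: log2(fold change) cutoffs by kingdom for calling enrichment
LOG2FC_CUTOFFS = {"fungi": 0.0, "prokaryotes": 2.0}

#: canonical compartment comparisons (denominator group A -> numerator group B)
CANONICAL_PAIRS = (
    (("s",), ("bk", "rp")),          # non-seagrass sediment -> seagrass sediment
    (("bk", "rp"), ("rt", "rz")),    # seagrass sediment -> below-ground tissues
    (("w",), ("lp",)),               # water -> leaf phylloplane
    (("w",), ("lf",)),               # water -> leaf tissue
)


@dataclass
class EnrichmentRecord:
    taxon: str
    mean_a: float           # mean relative abundance in the denominator group
    mean_b: float           # mean relative abundance in the numerator group
    fold_change: float
    log2_fold_change: float
    contribution: float     # normalized SIMPER contribution fraction
    p: float
    enriched: bool


def _group_matrix(
    table: FeatureTable, metadata: SampleMetadata, compartments: tuple[str, ...]
) -> np.ndarray:
    ids = [s for s in table.sample_ids if metadata.compartment(s) in compartments]
    if not ids:
        raise ValueError(f"no samples in compartments {compartments}")
    return table.data.loc[ids].to_numpy(dtype=float)


def _contributions(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Per-taxon mean raw contribution to between-group Bray-Curtis.

    For each inter-group sample pair (x, y) the taxon term is
    |x_i - y_i| / sum_k (x_k + y_k); terms are averaged over all pairs. The
    raw contributions sum to the mean between-group dissimilarity; the
    permutation test operates on these, and they are normalized to fractions
    only for reporting.
    """
    denom = a.sum(axis=1)[:, None] + b.sum(axis=1)[None, :]        # n_a x n_b
    diff = np.abs(a[:, None, :] - b[None, :, :])                   # n_a x n_b x D
    return (diff / denom[:, :, None]).mean(axis=(0, 1))


def simper(
    table: FeatureTable,
    metadata: SampleMetadata,
    group_a: tuple[str, ...] | str,
    group_b: tuple[str, ...] | str,
    permutations: int = 999,
    seed: int | None = 0,
) -> pd.DataFrame:
    """SIMPER contributions of every taxon with a one-sided permutation test.

    Returns a DataFrame indexed by taxon with columns ``contribution`` (sums
    to 1) and ``p`` (probability of a permuted-label contribution at least as
    large, (b+1)/(m+1)).
    """
    if table.mode != "relative":
        raise ValueError("SIMPER expects a relative-mode table")
    ga = (group_a,) if isinstance(group_a, str) else tuple(group_a)
    gb = (group_b,) if isinstance(group_b, str) else tuple(group_b)
    a = _group_matrix(table, metadata, ga)
    b = _group_matrix(table, metadata, gb)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 samples for the permutation test")
    obs = _contributions(a, b)
    total = obs.sum()
    if total <= 0:
        raise ValueError("groups are identical; SIMPER contributions undefined")
    rng = np.random.default_rng(seed)
    pooled = np.vstack([a, b])
    n_a = len(a)
    exceed = np.zeros_like(obs)
    for _ in range(permutations):
        perm = rng.permutation(len(pooled))
        pa, pb = pooled[perm[:n_a]], pooled[perm[n_a:]]
        exceed += _contributions(pa, pb) >= obs - 1e-15
    p = (exceed + 1) / (permutations + 1)
    return pd.DataFrame({"contribution": obs / total, "p": p}, index=table.taxon_ids)


def fold_change(
    mean_b: float, mean_a: float, min_nonzero_a: float
) -> tuple[float, float]:
    """Fold change B/A with the zero-replacement rule for the denominator.

    A zero denominator mean is replaced by the smallest non-zero mean
    relative abundance observed in that compartment. A zero numerator yields
    fc = 0 and log2fc = -inf (downstream the abundance filter removes it).
    """
    if min_nonzero_a <= 0:
        raise ValueError("min_nonzero_a must be positive")
    if mean_b < 0 or mean_a < 0:
        raise ValueError("mean abundances must be non-negative")
    denom = mean_a if mean_a > 0 else min_nonzero_a
    fc = mean_b / denom
    log2fc = math.log2(fc) if fc > 0 else -math.inf
    return fc, log2fc


def enrichment_screen(
    table: FeatureTable,
    metadata: SampleMetadata,
    pair: tuple[tuple[str, ...] | str, tuple[str, ...] | str],
    kingdom: str,
    permutations: int = 999,
    seed: int | None = 0,
    min_abundance: float = 1e-4,
    p_cutoff: float = 0.05,
    log2fc_cutoff: float | None = None,
    fdr: bool = False,
) -> list[EnrichmentRecord]:
    """Fold-change + SIMPER enrichment screen for one compartment pair.

    Taxa whose mean relative abundance in the numerator group B is not above
    ``min_abundance`` (0.01%) are excluded before testing. A taxon is
    enriched when log2(fold change) exceeds the kingdom cutoff (0 for fungi,
    2 for prokaryotes) and p < 0.05. ``fdr=True`` applies Benjamini-Hochberg
    to the retained taxa's p-values first (off by default).
    """
    if log2fc_cutoff is None:
        if kingdom not in LOG2FC_CUTOFFS:
            raise ValueError(
                f"unknown kingdom {kingdom!r}; expected one of {sorted(LOG2FC_CUTOFFS)}"
            )
        log2fc_cutoff = LOG2FC_CUTOFFS[kingdom]
    group_a, group_b = pair
    ga = (group_a,) if isinstance(group_a, str) else tuple(group_a)
    gb = (group_b,) if isinstance(group_b, str) else tuple(group_b)
    res = simper(table, metadata, ga, gb, permutations=permutations, seed=seed)

    a = _group_matrix(table, metadata, ga)
    b = _group_matrix(table, metadata, gb)
    mean_a = a.mean(axis=0)
    mean_b = b.mean(axis=0)
    nz = mean_a[mean_a > 0]
    if not nz.size:
        raise ValueError("denominator group has no non-zero taxon means")
    min_nonzero_a = float(nz.min())

    keep = np.flatnonzero(mean_b > min_abundance)
    pvals = res["p"].to_numpy()
    if fdr:
        adj = _bh_adjust(pvals[keep])
        pmap = dict(zip(keep, adj))
    else:
        pmap = {i: pvals[i] for i in keep}

    records = []
    for i in keep:
        taxon = table.taxon_ids[i]
        fc, log2fc = fold_change(float(mean_b[i]), float(mean_a[i]), min_nonzero_a)
        p = float(pmap[i])
        records.append(
            EnrichmentRecord(
                taxon=taxon,
                mean_a=float(mean_a[i]),
                mean_b=float(mean_b[i]),
                fold_change=fc,
                log2_fold_change=log2fc,
                contribution=float(res["contribution"].iloc[i]),
                p=p,
                enriched=bool(log2fc > log2fc_cutoff and p < p_cutoff),
            )
        )
    return records


def _bh_adjust(p: np.ndarray) -> np.ndarray:
    n = len(p)
    order = np.argsort(p)
    ranked = p[order] * n / (np.arange(n) + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(ranked, 1.0)
    return out


def records_to_frame(records: list[EnrichmentRecord]) -> pd.DataFrame:
    return pd.DataFrame([vars(r) for r in records]).set_index("taxon")
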