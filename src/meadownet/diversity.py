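"""Rarefaction, alpha/beta diversity, ordination and group-difference tests.

Implements the statistical toolkit used for compartment comparisons of
amplicon communities: rarefaction to a common depth, observed-OTU and Shannon
alpha diversity, Bray-Curtis dissimilarity with PCoA ordination, and the
permutation tests PERMANOVA and ANOSIM alongside Kruskal-Wallis and Wilcoxon
rank-sum screens.

Conventions
-----------
* Shannon uses the natural logarithm.
* Permutation p-values follow ``(b + 1) / (m + 1)`` with the observed
  statistic included, so the minimum attainable p at 999 permutations is
  0.001.
* PERMANOVA uses the Gower-centered trace formulation, which handles both
  categorical factors (dummy-coded) and continuous covariates; with several
  factors the sums of squares are sequential (Type I) in the order given,
  and a marginal single-factor mode is available.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist, squareform

from .io import FeatureTable, SampleMetadata, to_relative

logger = logging.getLogger(__name__)

STAR_THRESHOLDS = ((1e-4, "****"), (1e-3, "***"), (1e-2, "**"), (5e-2, "*"))


def significance_stars(p: float) -> str:
    """Map a p-value to the conventional star annotation (ns above 0.05)."""
    for cut, stars in STAR_THRESHOLDS:
        if p < cut:
            return stars
    return "ns"


@dataclass
class DistanceMatrix:
    """Symmetric sample-by-sample dissimilarity with zero diagonal."""

    ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.ids), len(self.ids)):
            raise ValueError("distance matrix shape does not match ids")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("distance matrix is not symmetric")
        if np.any(np.diag(v) != 0):
            raise ValueError("distance matrix diagonal must be exactly zero")
        if np.any(v < 0):
            raise ValueError("distances must be non-negative")
        self.values = v

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)

    def subset(self, ids: list[str]) -> "DistanceMatrix":
        idx = [self.ids.index(i) for i in ids]
        return DistanceMatrix(list(ids), self.values[np.ix_(idx, idx)])


@dataclass
class OrdinationResult:
    coordinates: pd.DataFrame          # samples x axes, axes named PC1, PC2, ...
    eigenvalues: np.ndarray            # all eigenvalues, descending
    proportion_explained: np.ndarray   # per retained (positive) axis


@dataclass
class GroupTestResult:
    factor: str
    statistic: float
    p: float
    permutations: int | None = None
    effect_size: float | None = None

    def __post_init__(self) -> None:
        if not 0.0 < self.p <= 1.0:
            raise ValueError(f"p-value out of range: {self.p}")

    @property
    def stars(self) -> str:
        return significance_stars(self.p)


# ---------------------------------------------------------------------------
# rarefaction & alpha diversity
# ---------------------------------------------------------------------------


def rarefy(
    table: FeatureTable, depth: int | None = None, seed: int | None = 0
) -> FeatureTable:
    """Subsample every sample without replacement to a common depth.

    ``depth`` defaults to the minimum sample total. Samples below ``depth``
    are dropped with a logged warning. Deterministic under ``seed``.
    """
    if table.mode != "count":
        raise ValueError("rarefaction requires a count-mode table")
    totals = table.data.sum(axis=1)
    if depth is None:
        depth = int(totals.min())
    if depth <= 0:
        raise ValueError(f"rarefaction depth must be positive, got {depth}")
    keep = totals[totals >= depth].index
    dropped = sorted(set(table.sample_ids) - set(keep))
    if dropped:
        logger.warning(
            "rarefy: dropping %d sample(s) below depth %d: %s",
            len(dropped), depth, dropped[:5],
        )
    if not len(keep):
        raise ValueError("no sample reaches the rarefaction depth")
    rng = np.random.default_rng(seed)
    out = np.empty((len(keep), table.data.shape[1]), dtype=np.int64)
    for i, sid in enumerate(keep):
        counts = table.data.loc[sid].to_numpy()
        out[i] = rng.multivariate_hypergeometric(counts, depth)
    return FeatureTable(
        pd.DataFrame(out, index=list(keep), columns=table.taxon_ids), mode="count"
    )


def alpha_diversity(table: FeatureTable) -> pd.DataFrame:
    """Observed taxa and Shannon index (natural log) per sample."""
    v = table.values
    totals = v.sum(axis=1)
    zero = np.flatnonzero(totals == 0)
    if zero.size:
        raise ValueError(f"all-zero sample: {table.sample_ids[zero[0]]!r}")
    p = v / totals[:, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(p > 0, p * np.log(p), 0.0)
    return pd.DataFrame(
        {
            "observed": (v > 0).sum(axis=1),
            "shannon": -plogp.sum(axis=1),
        },
        index=table.sample_ids,
    )


# ---------------------------------------------------------------------------
# beta diversity & ordination
# ---------------------------------------------------------------------------


def bray_curtis(table: FeatureTable) -> DistanceMatrix:
    """Pairwise Bray-Curtis dissimilarity, BC = 1 - 2*sum(min)/sum(total)."""
    if len(table.sample_ids) < 2:
        raise ValueError("Bray-Curtis needs at least two samples")
    v = table.values
    if np.any(v.sum(axis=1) == 0):
        raise ValueError("all-zero samples make Bray-Curtis undefined")
    dm = squareform(pdist(v, metric="braycurtis"))
    np.fill_diagonal(dm, 0.0)
    return DistanceMatrix(table.sample_ids, (dm + dm.T) / 2.0)


def _gower_center(d: np.ndarray) -> np.ndarray:
    a = -0.5 * d**2
    n = d.shape[0]
    j = np.eye(n) - np.full((n, n), 1.0 / n)
    return j @ a @ j


def pcoa(dm: DistanceMatrix) -> OrdinationResult:
    """Classical metric MDS (principal coordinates) of a distance matrix.

    Coordinates are computed from the positive eigenvalues only; negative
    eigenvalues (Bray-Curtis is non-Euclidean) are retained in the
    ``eigenvalues`` field but contribute no axis. No Cailliez correction.
    """
    g = _gower_center(dm.values)
    eigvals, eigvecs = np.linalg.eigh((g + g.T) / 2.0)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    tol = max(1e-12, 1e-10 * max(abs(eigvals[0]), 1.0))
    pos = eigvals > tol
    coords = eigvecs[:, pos] * np.sqrt(eigvals[pos])
    axes = [f"PC{i + 1}" for i in range(coords.shape[1])]
    prop = eigvals[pos] / eigvals[pos].sum() if pos.any() else np.array([])
    return OrdinationResult(
        coordinates=pd.DataFrame(coords, index=dm.ids, columns=axes),
        eigenvalues=eigvals,
        proportion_explained=prop,
    )


# ---------------------------------------------------------------------------
# permutation tests
# ---------------------------------------------------------------------------


def _model_matrix(values: pd.Series) -> np.ndarray:
    """Dummy-code a categorical factor or center a numeric covariate."""
    if values.dtype.kind in "if":
        x = values.to_numpy(dtype=float)
        return (x - x.mean())[:, None]
    levels = sorted(values.unique())
    if len(levels) < 2:
        raise ValueError(f"factor {values.name!r} is constant across samples")
    return np.column_stack([(values == lv).to_numpy(float) for lv in levels[1:]])


def _hat(x: np.ndarray) -> np.ndarray:
    return x @ np.linalg.pinv(x.T @ x) @ x.T


def permanova(
    dm: DistanceMatrix,
    metadata: SampleMetadata,
    factors: list[str],
    permutations: int = 999,
    seed: int | None = 0,
    mode: str = "sequential",
) -> list[GroupTestResult]:
    """Permutational multivariate ANOVA on a distance matrix.

    Pseudo-F per factor from among/within sums of squared distances via the
    Gower-centered trace form; r^2 = SS_factor / SS_total; the p-value counts
    permuted F >= observed with the (b+1)/(m+1) convention. ``mode`` is
    ``"sequential"`` (Type I SS, factors fitted in order) or ``"marginal"``
    (each factor fitted alone).
    """
    if permutations < 99:
        raise ValueError("use at least 99 permutations")
    if mode not in ("sequential", "marginal"):
        raise ValueError(f"unknown mode {mode!r}")
    meta = metadata.data.loc[dm.ids]
    n = len(dm.ids)
    g = _gower_center(dm.values)
    ss_total = float(np.trace(g))
    rng = np.random.default_rng(seed)
    perms = [rng.permutation(n) for _ in range(permutations)]

    def fit(order: list[str]) -> list[tuple[str, float, int, np.ndarray]]:
        """Per factor: (name, SS, df, hat-matrix increment pair)."""
        x = np.ones((n, 1))
        hat_prev = _hat(x)
        rank_prev = 1
        out = []
        for name in order:
            x = np.hstack([x, _model_matrix(meta[name])])
            hat = _hat(x)
            rank = int(np.round(np.trace(hat)))
            out.append((name, hat_prev.copy(), hat.copy(), rank - rank_prev))
            hat_prev, rank_prev = hat, rank
        return out

    results = []
    factor_sets = [factors] if mode == "sequential" else [[f] for f in factors]
    for fset in factor_sets:
        fitted = fit(fset)
        _, _, hat_full, _ = fitted[-1]
        rank_full = int(np.round(np.trace(hat_full)))
        df_res = n - rank_full
        if df_res <= 0:
            raise ValueError("model saturates the samples; no residual df")

        def f_stats(gm: np.ndarray) -> list[float]:
            ss_res = float(np.trace(gm)) - float(np.trace(hat_full @ gm))
            out = []
            for name, h0, h1, df in fitted:
                ss = float(np.trace(h1 @ gm)) - float(np.trace(h0 @ gm))
                out.append((ss / df) / (ss_res / df_res))
            return out

        obs_f = f_stats(g)
        exceed = [0] * len(fitted)
        for perm in perms:
            gp = g[np.ix_(perm, perm)]
            for k, fp in enumerate(f_stats(gp)):
                if fp >= obs_f[k] - 1e-12:
                    exceed[k] += 1
        for k, (name, h0, h1, df) in enumerate(fitted):
            ss = float(np.trace(h1 @ g)) - float(np.trace(h0 @ g))
            results.append(
                GroupTestResult(
                    factor=name,
                    statistic=obs_f[k],
                    p=(exceed[k] + 1) / (permutations + 1),
                    permutations=permutations,
                    effect_size=ss / ss_total,
                )
            )
    return results


def anosim(
    dm: DistanceMatrix,
    groups: pd.Series | dict[str, str],
    permutations: int = 999,
    seed: int | None = 0,
) -> GroupTestResult:
    """Analysis of similarities on ranked distances.

    R = (mean rank between - mean rank within) / (n(n-1)/4), permutation p
    with the (b+1)/(m+1) convention.
    """
    if isinstance(groups, dict):
        groups = pd.Series(groups)
    labels = np.asarray(groups.loc[dm.ids])
    if len(set(labels)) < 2:
        raise ValueError("ANOSIM needs at least two groups")
    n = len(labels)
    iu = np.triu_indices(n, k=1)
    ranks = stats.rankdata(dm.values[iu])
    denom = n * (n - 1) / 4.0

    def r_stat(lab: np.ndarray) -> float:
        within = lab[iu[0]] == lab[iu[1]]
        if within.all() or not within.any():
            raise ValueError("ANOSIM undefined: no within- or between-group pairs")
        return (ranks[~within].mean() - ranks[within].mean()) / denom

    obs = r_stat(labels)
    rng = np.random.default_rng(seed)
    b = sum(
        r_stat(rng.permutation(labels)) >= obs - 1e-12 for _ in range(permutations)
    )
    return GroupTestResult(
        factor=str(groups.name or "group"),
        statistic=obs,
        p=(b + 1) / (permutations + 1),
        permutations=permutations,
        effect_size=obs,
    )


# ---------------------------------------------------------------------------
# per-taxon rank tests
# ---------------------------------------------------------------------------


def kruskal_wallis_by_taxon(
    table: FeatureTable, metadata: SampleMetadata, grouping: str = "compartment"
) -> pd.DataFrame:
    """Kruskal-Wallis H test of each taxon's abundance across groups.

    Constant taxa are degenerate and reported with H = 0, p = 1.
    """
    meta = metadata.data.loc[table.sample_ids]
    labels = meta[grouping]
    levels = sorted(labels.unique())
    if len(levels) < 2:
        raise ValueError(f"grouping {grouping!r} has fewer than two levels")
    rows = []
    for taxon in table.taxon_ids:
        x = table.data[taxon]
        samples = [x[labels == lv].to_numpy(dtype=float) for lv in levels]
        if np.ptp(x.to_numpy(dtype=float)) == 0:
            rows.append((taxon, 0.0, 1.0))
            continue
        h, p = stats.kruskal(*samples)
        rows.append((taxon, float(h), float(p)))
    df = pd.DataFrame(rows, columns=["taxon", "H", "p"]).set_index("taxon")
    df["stars"] = df["p"].map(significance_stars)
    return df


def pairwise_wilcoxon(
    values: pd.Series,
    metadata: SampleMetadata,
    pairs: list[tuple[str, str]],
    grouping: str = "compartment",
) -> pd.DataFrame:
    """Wilcoxon rank-sum (Mann-Whitney, normal approximation with tie
    correction) between compartment pairs, with star annotations."""
    meta = metadata.data.loc[values.index]
    labels = meta[grouping]
    rows = []
    for a, b in pairs:
        xa = values[labels == a].to_numpy(dtype=float)
        xb = values[labels == b].to_numpy(dtype=float)
        if len(xa) < 2 or len(xb) < 2:
            raise ValueError(f"pair ({a}, {b}) has a group with fewer than 2 samples")
        if np.ptp(np.concatenate([xa, xb])) == 0:
            stat, p = 0.0, 1.0
        else:
            stat, p = stats.mannwhitneyu(xa, xb, alternative="two-sided", method="asymptotic")
        rows.append((a, b, float(stat), float(p), significance_stars(p)))
    return pd.DataFrame(rows, columns=["group_a", "group_b", "statistic", "p", "stars"])


def alpha_diversity_tests(
    table: FeatureTable,
    metadata: SampleMetadata,
    pairs: list[tuple[str, str]],
    metric: str = "shannon",
) -> pd.DataFrame:
    """Convenience: alpha diversity followed by pairwise Wilcoxon screens."""
    alpha = alpha_diversity(table)
    return pairwise_wilcoxon(alpha[metric], metadata, pairs)
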