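"""Robustness of interdomain networks to random fungal node removal.

Robustness is the proportion of nodes remaining after a fraction of the
target-domain (by default fungal) nodes is removed at random and secondary
extinctions have cascaded to a fixed point. A remaining node goes extinct
when it has lost all its edges, or when its abundance-weighted mean
interaction strength

    s_i = (1 / k_i) * sum_{j in remaining neighbors} r_ij * a_j

drops to zero or below (r_ij the signed correlation, a_j the partner's mean
relative abundance, k_i the remaining degree). The decline rate summarizes a
curve as |R(0.5) - R(0)| / 0.5.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .network import Network


@dataclass
class RobustnessCurve:
    fractions: np.ndarray
    mean: np.ndarray
    sd: np.ndarray
    n_replicates: int
    target_domain: str
    seed: int | None

    def __post_init__(self) -> None:
        if np.any(self.mean < -1e-12) or np.any(self.mean > 1 + 1e-12):
            raise ValueError("robustness must lie in [0, 1]")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"fraction": self.fractions, "mean": self.mean, "sd": self.sd}
        )


@dataclass
class DeclineRate:
    rate: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.rate <= 2.0:
            raise ValueError(f"decline rate out of [0, 2]: {self.rate}")


def _as_arrays(net: Network):
    nodes = list(net.graph.nodes)
    index = {n: i for i, n in enumerate(nodes)}
    n = len(nodes)
    w = np.zeros((n, n))
    for u, v, data in net.graph.edges(data=True):
        w[index[u], index[v]] = w[index[v], index[u]] = data["weight"]
    a = np.array([net.graph.nodes[n_]["abundance"] for n_ in nodes], dtype=float)
    domains = np.array([net.graph.nodes[n_]["domain"] for n_ in nodes])
    return nodes, w, a, domains


def _cascade(
    w: np.ndarray,
    a: np.ndarray,
    alive: np.ndarray,
    use_isolation: bool = True,
    use_strength: bool = True,
) -> np.ndarray:
    adj = w != 0
    while True:
        k = adj[:, alive].sum(axis=1)
        s = w[:, alive] @ a[alive]
        dead = np.zeros_like(alive)
        if use_isolation:
            dead |= alive & (k == 0)
        if use_strength:
            with np.errstate(invalid="ignore", divide="ignore"):
                mean_strength = np.where(k > 0, s / np.maximum(k, 1), 0.0)
            dead |= alive & (k > 0) & (mean_strength <= 0)
        if not dead.any():
            return alive
        alive = alive & ~dead


def robustness_once(
    net: Network,
    removal_fraction: float,
    target_domain: str = "fungi",
    seed: int | None = 0,
    use_isolation: bool = True,
    use_strength: bool = True,
) -> float:
    """One random removal draw: remove ``ceil(fraction * n_target)`` nodes of
    the target domain, cascade secondary extinctions, return the fraction of
    the original nodes remaining. A removal fraction of 0 returns exactly 1.
    """
    if not 0.0 <= removal_fraction <= 1.0:
        raise ValueError(f"removal fraction out of [0, 1]: {removal_fraction}")
    nodes, w, a, domains = _as_arrays(net)
    targets = np.flatnonzero(domains == target_domain)
    if targets.size == 0:
        raise ValueError(f"network has no {target_domain!r} nodes")
    n_remove = math.ceil(removal_fraction * targets.size)
    if n_remove == 0:
        return 1.0
    rng = np.random.default_rng(seed)
    removed = rng.choice(targets, size=n_remove, replace=False)
    alive = np.ones(len(nodes), dtype=bool)
    alive[removed] = False
    alive = _cascade(w, a, alive, use_isolation, use_strength)
    return float(alive.sum() / len(nodes))


def robustness_curve(
    net: Network,
    fractions: np.ndarray | list[float] | None = None,
    n_replicates: int = 1000,
    target_domain: str = "fungi",
    seed: int | None = 0,
    use_isolation: bool = True,
    use_strength: bool = True,
) -> RobustnessCurve:
    """Mean and sd of robustness over independent removal replicates per
    removal fraction (default grid 0 to 1 in steps of 0.05)."""
    if fractions is None:
        fractions = np.round(np.arange(0.0, 1.0001, 0.05), 10)
    fractions = np.asarray(fractions, dtype=float)
    nodes, w, a, domains = _as_arrays(net)
    targets = np.flatnonzero(domains == target_domain)
    if targets.size == 0:
        raise ValueError(f"network has no {target_domain!r} nodes")
    rng = np.random.default_rng(seed)
    n = len(nodes)
    means = np.empty(len(fractions))
    sds = np.empty(len(fractions))
    for fi, f in enumerate(fractions):
        if not 0.0 <= f <= 1.0:
            raise ValueError(f"removal fraction out of [0, 1]: {f}")
        n_remove = math.ceil(f * targets.size)
        if n_remove == 0:
            means[fi], sds[fi] = 1.0, 0.0
            continue
        vals = np.empty(n_replicates)
        for rep in range(n_replicates):
            removed = rng.choice(targets, size=n_remove, replace=False)
            alive = np.ones(n, dtype=bool)
            alive[removed] = False
            alive = _cascade(w, a, alive, use_isolation, use_strength)
            vals[rep] = alive.sum() / n
        means[fi], sds[fi] = vals.mean(), vals.std(ddof=0)
    return RobustnessCurve(
        fractions=fractions,
        mean=means,
        sd=sds,
        n_replicates=n_replicates,
        target_domain=target_domain,
        seed=seed,
    )


def decline_rate(curve: RobustnessCurve) -> DeclineRate:
    """|mean R(0.5) - mean R(0)| / 0.5 from a curve containing both fractions."""
    def at(f: float) -> float:
        idx = np.flatnonzero(np.isclose(curve.fractions, f))
        if idx.size == 0:
            raise ValueError(f"curve lacks removal fraction {f}")
        return float(curve.mean[idx[0]])

    return DeclineRate(rate=abs(at(0.5) - at(0.0)) / 0.5)
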