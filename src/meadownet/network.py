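"""SparCC correlation inference and interdomain co-occurrence networks.

The inference chain mirrors the standard amplicon network workflow:
prevalence filtering (taxa present in strictly more than 50% of the group's
samples), SparCC correlation estimation on the compositional counts,
permutation p-values, edge thresholding (|r| > 0.2, p < 0.05), and then
network summaries — whole vs interdomain extraction, topology metrics,
Louvain module detection and Zi-Pi keystone classification.

SparCC
------
For taxa i, j with fractions x, the log-ratio variance
``t_ij = var(log(x_i / x_j))`` decomposes as
``t_ij = w_i + w_j - 2 rho_ij sqrt(w_i w_j)`` where ``w`` are basis
variances. Under the sparsity assumption the correlation terms average out,
giving the linear system ``sum_{j != i} t_ij = (D - 2) w_i + sum_j w_j``
(for D = 3 the system is exactly determined). Correlations follow as
``rho_ij = (w_i + w_j - t_ij) / (2 sqrt(w_i w_j))``; strongly correlated
pairs above an exclusion threshold are iteratively removed from the system
and it is re-solved. Fractions are drawn from a per-sample Dirichlet
posterior (pseudocount 1) and the final correlation is the median over
resamples; ``n_resamples=0`` uses the pseudocounted empirical fractions
deterministically.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import networkx as nx
import numpy as np
import pandas as pd

from .io import FeatureTable

#: Zi-Pi thresholds for keystone classification
ZI_THRESHOLD = 2.5
PI_THRESHOLD = 0.62

_PROKARYOTE_DOMAINS = {"bacteria", "archaea"}


@dataclass
class CorrelationResult:
    taxon_ids: list[str]
    r: np.ndarray
    p: np.ndarray | None = None
    settings: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        d = len(self.taxon_ids)
        if self.r.shape != (d, d):
            raise ValueError("correlation matrix shape does not match taxa")
        if not np.allclose(self.r, self.r.T, atol=1e-12):
            raise ValueError("correlation matrix is not symmetric")
        if not np.allclose(np.diag(self.r), 1.0):
            raise ValueError("correlation matrix must have unit diagonal")


@dataclass
class Network:
    """Undirected signed co-occurrence graph.

    Nodes carry ``domain`` (fungi/bacteria/archaea) and ``abundance`` (mean
    relative abundance over the group's samples); edges carry ``weight``
    (the correlation) and ``sign`` ('+'/'-').
    """

    graph: nx.Graph
    provenance: str = "whole"

    def __post_init__(self) -> None:
        for u, v, data in self.graph.edges(data=True):
            if u == v:
                raise ValueError("self-loops are not allowed")
            expected = "+" if data["weight"] > 0 else "-"
            if data.get("sign", expected) != expected:
                raise ValueError(f"edge ({u}, {v}) sign inconsistent with weight")
            data["sign"] = expected

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def edge_signs(self) -> tuple[int, int]:
        pos = sum(1 for *_, d in self.graph.edges(data=True) if d["sign"] == "+")
        return pos, self.n_edges - pos

    def domains(self) -> dict[str, str]:
        return dict(self.graph.nodes(data="domain"))


@dataclass
class ModulePartition:
    assignment: dict[str, int]
    modularity: float

    def __post_init__(self) -> None:
        if not -0.5 - 1e-9 <= self.modularity <= 1.0 + 1e-9:
            raise ValueError(f"modularity out of range: {self.modularity}")


@dataclass
class NodeRole:
    node: str
    zi: float
    pi: float
    category: str


@dataclass
class TopologySummary:
    total_nodes: int
    total_edges: int
    positive_edges: int
    negative_edges: int
    average_degree: float
    modularity: float
    modularity_defined: bool = True


# ---------------------------------------------------------------------------
# SparCC
# ---------------------------------------------------------------------------


def prevalence_filter(table: FeatureTable, min_fraction: float = 0.5) -> FeatureTable:
    """Keep taxa with non-zero counts in strictly more than ``min_fraction``
    of the samples (the 50% rule: present in 18 of 36 samples is removed,
    19 of 36 retained)."""
    if table.mode != "count":
        raise ValueError("prevalence filter expects a count-mode table")
    n = len(table.sample_ids)
    presence = (table.data > 0).sum(axis=0) / n
    keep = [t for t in table.taxon_ids if presence[t] > min_fraction]
    if not keep:
        raise ValueError(
            f"no taxon exceeds prevalence {min_fraction:.0%}; lower the threshold"
        )
    return table.subset_taxa(keep)


def _variation_matrix(fractions: np.ndarray) -> np.ndarray:
    """t_ij = var(log(x_i / x_j)) computed from the log-covariance matrix."""
    logf = np.log(fractions)
    cov = np.cov(logf, rowvar=False)
    v = np.diag(cov)
    return v[:, None] + v[None, :] - 2.0 * cov


def _basis_correlations(
    t: np.ndarray, exclusion_threshold: float, n_exclusion_iterations: int
) -> np.ndarray:
    """Solve the basis-variance system and iteratively exclude strong pairs."""
    d = t.shape[0]
    m = np.ones((d, d)) + np.diag(np.full(d, float(d - 2)))
    t_row = t.sum(axis=1)

    def solve() -> np.ndarray:
        w = np.linalg.solve(m, t_row)
        w = np.maximum(w, 1e-12)
        r = (w[:, None] + w[None, :] - t) / (2.0 * np.sqrt(np.outer(w, w)))
        np.fill_diagonal(r, 1.0)
        return np.clip(r, -1.0, 1.0)

    try:
        r = solve()
    except np.linalg.LinAlgError as exc:
        raise ValueError("basis-variance system is singular") from exc

    # iterative exclusion of the strongest pair; a component may lose at most
    # d - 3 of its pairs (beyond that the system degenerates), and if the
    # reduced system still turns singular the last valid solution is kept
    excluded: set[tuple[int, int]] = set()
    n_excluded = np.zeros(d, dtype=int)
    for _ in range(n_exclusion_iterations):
        masked = np.abs(r).copy()
        np.fill_diagonal(masked, 0.0)
        masked[n_excluded >= d - 3, :] = 0.0
        masked[:, n_excluded >= d - 3] = 0.0
        for i, j in excluded:
            masked[i, j] = masked[j, i] = 0.0
        i, j = np.unravel_index(int(np.argmax(masked)), masked.shape)
        if masked[i, j] <= exclusion_threshold:
            break
        excluded.add((min(i, j), max(i, j)))
        n_excluded[i] += 1
        n_excluded[j] += 1
        t_row[i] -= t[i, j]
        t_row[j] -= t[i, j]
        m[i, i] -= 1.0
        m[j, j] -= 1.0
        m[i, j] -= 1.0
        m[j, i] -= 1.0
        try:
            r = solve()
        except np.linalg.LinAlgError:
            break
    return r


def sparcc(
    table: FeatureTable,
    n_exclusion_iterations: int = 10,
    exclusion_threshold: float = 0.1,
    n_resamples: int = 20,
    pseudocount: float = 1.0,
    seed: int | None = 0,
) -> CorrelationResult:
    """SparCC correlation matrix for a count table.

    ``n_resamples`` Dirichlet draws of the per-sample fractions are each
    solved for basis correlations and the element-wise median is returned;
    ``n_resamples=0`` skips the Dirichlet step and uses pseudocounted
    empirical fractions (deterministic, used by the exact small-D oracle).
    """
    if table.mode != "count":
        raise ValueError("SparCC expects a count-mode table")
    x = table.values
    n, d = x.shape
    if d < 3:
        raise ValueError("SparCC requires at least 3 taxa")
    if n < 4:
        raise ValueError("SparCC requires at least 4 samples")
    if np.any(x.sum(axis=0) == 0):
        raise ValueError("all-zero taxon present; apply prevalence_filter first")
    rng = np.random.default_rng(seed)

    def one(fractions: np.ndarray) -> np.ndarray:
        t = _variation_matrix(fractions)
        return _basis_correlations(t, exclusion_threshold, n_exclusion_iterations)

    if n_resamples <= 0:
        f = (x + pseudocount) / (x + pseudocount).sum(axis=1, keepdims=True)
        r = one(f)
    else:
        draws = []
        for _ in range(n_resamples):
            g = rng.standard_gamma(x + pseudocount)
            f = g / g.sum(axis=1, keepdims=True)
            draws.append(one(f))
        r = np.median(np.stack(draws), axis=0)
    r = np.clip((r + r.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    return CorrelationResult(
        taxon_ids=table.taxon_ids,
        r=r,
        settings={
            "n_exclusion_iterations": n_exclusion_iterations,
            "exclusion_threshold": exclusion_threshold,
            "n_resamples": n_resamples,
            "pseudocount": pseudocount,
            "seed": seed,
        },
    )


def sparcc_pvalues(
    table: FeatureTable,
    observed: CorrelationResult,
    n_permutations: int = 100,
    seed: int | None = 0,
    n_resamples: int | None = None,
) -> np.ndarray:
    """Two-sided permutation p-values for a SparCC correlation matrix.

    Each permutation shuffles every taxon's counts across samples
    independently (destroying all real co-variation while keeping marginals)
    and recomputes SparCC with the observed run's settings;
    ``p_ij = (#{|r_perm| >= |r_obs|} + 1) / (n_permutations + 1)``.
    """
    if n_permutations < 19:
        raise ValueError("need at least 19 permutations to resolve p < 0.05")
    if table.taxon_ids != observed.taxon_ids:
        raise ValueError("table and correlation result cover different taxa")
    s = observed.settings
    if n_resamples is None:
        n_resamples = int(s.get("n_resamples", 20))
    rng = np.random.default_rng(seed)
    x = table.values.astype(np.int64)
    abs_obs = np.abs(observed.r)
    exceed = np.zeros_like(abs_obs)
    for k in range(n_permutations):
        perm = np.column_stack(
            [rng.permutation(x[:, j]) for j in range(x.shape[1])]
        )
        pt = FeatureTable(
            pd.DataFrame(perm, index=table.sample_ids, columns=table.taxon_ids),
            mode="count",
        )
        rp = sparcc(
            pt,
            n_exclusion_iterations=int(s.get("n_exclusion_iterations", 10)),
            exclusion_threshold=float(s.get("exclusion_threshold", 0.1)),
            n_resamples=n_resamples,
            pseudocount=float(s.get("pseudocount", 1.0)),
            seed=int(rng.integers(2**31)),
        ).r
        exceed += np.abs(rp) >= abs_obs - 1e-15
    p = (exceed + 1.0) / (n_permutations + 1.0)
    np.fill_diagonal(p, 1.0)
    observed.p = p
    return p


# ---------------------------------------------------------------------------
# network construction
# ---------------------------------------------------------------------------


def build_network(
    corr: CorrelationResult,
    domains: Mapping[str, str],
    abundances: Mapping[str, float],
    r_threshold: float = 0.2,
    p_threshold: float = 0.05,
    provenance: str = "whole",
) -> Network:
    """Threshold a correlation matrix into a signed network.

    Edge (i, j) exists iff |r_ij| > ``r_threshold`` and p_ij < ``p_threshold``;
    nodes left without edges are dropped.
    """
    if corr.p is None:
        raise ValueError("correlation result has no p-values; run sparcc_pvalues")
    g = nx.Graph()
    taxa = corr.taxon_ids
    d = len(taxa)
    for i in range(d):
        for j in range(i + 1, d):
            r = float(corr.r[i, j])
            if abs(r) > r_threshold and corr.p[i, j] < p_threshold:
                g.add_edge(taxa[i], taxa[j], weight=r, sign="+" if r > 0 else "-")
    for node in g.nodes:
        g.nodes[node]["domain"] = domains[node]
        g.nodes[node]["abundance"] = float(abundances[node])
    return Network(g, provenance=provenance)


def extract_interdomain(net: Network) -> Network:
    """Keep only fungus-prokaryote edges; drop nodes left isolated."""
    g = nx.Graph()
    for u, v, data in net.graph.edges(data=True):
        du, dv = net.graph.nodes[u]["domain"], net.graph.nodes[v]["domain"]
        fungal = {du, dv} & {"fungi"}
        prok = {du, dv} & _PROKARYOTE_DOMAINS
        if fungal and prok:
            g.add_edge(u, v, **data)
    for node in g.nodes:
        g.nodes[node].update(net.graph.nodes[node])
    return Network(g, provenance="interdomain")


def ego_network(net: Network, focus: str) -> tuple[Network, tuple[int, int]]:
    """Subgraph of a focus taxon and its prokaryotic neighbors.

    Only edges incident to the focus are kept. Returns the ego network and
    its (positive, negative) edge counts.
    """
    if focus not in net.graph:
        raise KeyError(f"focus taxon {focus!r} not in network")
    g = nx.Graph()
    g.add_node(focus, **net.graph.nodes[focus])
    for nbr in net.graph.neighbors(focus):
        if net.graph.nodes[nbr]["domain"] in _PROKARYOTE_DOMAINS:
            g.add_node(nbr, **net.graph.nodes[nbr])
            g.add_edge(focus, nbr, **net.graph.edges[focus, nbr])
    ego = Network(g, provenance="ego")
    return ego, ego.edge_signs()


def detect_modules(net: Network, seed: int | None = 0) -> ModulePartition:
    """Louvain community detection on the unweighted, unsigned graph."""
    if net.n_edges < 1:
        raise ValueError("module detection needs at least one edge")
    unsigned = nx.Graph()
    unsigned.add_nodes_from(net.graph.nodes)
    unsigned.add_edges_from(net.graph.edges)
    comms = nx.community.louvain_communities(unsigned, seed=seed)
    q = nx.community.modularity(unsigned, comms)
    assignment = {node: k for k, comm in enumerate(comms) for node in comm}
    return ModulePartition(assignment=assignment, modularity=float(q))


def topology(net: Network, seed: int | None = 0) -> TopologySummary:
    """Node/edge counts, signed edge split, average degree and modularity.

    Average degree uses the undirected convention 2E/N. An empty network
    reports zeros with ``modularity_defined=False``.
    """
    if net.n_nodes == 0:
        return TopologySummary(0, 0, 0, 0, 0.0, 0.0, modularity_defined=False)
    pos, neg = net.edge_signs()
    avg_degree = 2.0 * net.n_edges / net.n_nodes
    if net.n_edges:
        q = detect_modules(net, seed=seed).modularity
        defined = True
    else:
        q, defined = 0.0, False
    return TopologySummary(
        total_nodes=net.n_nodes,
        total_edges=net.n_edges,
        positive_edges=pos,
        negative_edges=neg,
        average_degree=avg_degree,
        modularity=q,
        modularity_defined=defined,
    )


# ---------------------------------------------------------------------------
# Zi-Pi keystone classification
# ---------------------------------------------------------------------------


def classify_role(zi: float, pi: float) -> str:
    """Four-quadrant keystone category at thresholds Zi > 2.5 and Pi > 0.62."""
    if zi > ZI_THRESHOLD:
        return "Network hub" if pi > PI_THRESHOLD else "Module hub"
    return "Connector" if pi > PI_THRESHOLD else "Peripheral"


def zi_pi(net: Network, partition: ModulePartition) -> list[NodeRole]:
    """Within-module degree z-score (Zi) and participation coefficient (Pi).

    Zi standardizes a node's within-module degree against its module's mean
    and sd (Zi = 0 when the sd is 0); Pi = 1 - sum_m (k_im / k_i)^2. Nodes
    are then binned into Peripheral / Connector / Module hub / Network hub.
    """
    nodes = list(net.graph.nodes)
    missing = set(nodes) - set(partition.assignment)
    if missing:
        raise ValueError(f"partition does not cover nodes: {sorted(missing)[:5]}")
    module_of = partition.assignment
    within = {}
    per_module_links: dict[str, dict[int, int]] = {}
    for node in nodes:
        k = net.graph.degree(node)
        if k == 0:
            raise ValueError(f"isolated node {node!r}; drop it before classification")
        counts: dict[int, int] = {}
        for nbr in net.graph.neighbors(node):
            m = module_of[nbr]
            counts[m] = counts.get(m, 0) + 1
        per_module_links[node] = counts
        within[node] = counts.get(module_of[node], 0)

    # module-wise mean/sd of within-module degree
    by_module: dict[int, list[str]] = {}
    for node in nodes:
        by_module.setdefault(module_of[node], []).append(node)
    stats = {}
    for m, members in by_module.items():
        vals = np.array([within[n] for n in members], dtype=float)
        stats[m] = (vals.mean(), vals.std(ddof=0))

    roles = []
    for node in nodes:
        mean, sd = stats[module_of[node]]
        zi = (within[node] - mean) / sd if sd > 0 else 0.0
        k = net.graph.degree(node)
        pi = 1.0 - sum((c / k) ** 2 for c in per_module_links[node].values())
        roles.append(NodeRole(node=node, zi=float(zi), pi=float(pi), category=classify_role(zi, pi)))
    return roles


def roles_to_frame(roles: list[NodeRole]) -> pd.DataFrame:
    return pd.DataFrame([vars(r) for r in roles]).set_index("node")


# ---------------------------------------------------------------------------
# export
# ---------------------------------------------------------------------------


def write_edge_list(net: Network, path) -> None:
    rows = [
        {"source": u, "target": v, "weight": d["weight"], "sign": d["sign"]}
        for u, v, d in net.graph.edges(data=True)
    ]
    pd.DataFrame(rows, columns=["source", "target", "weight", "sign"]).to_csv(
        path, sep="\t", index=False
    )


def write_graphml(net: Network, path) -> None:
    nx.write_graphml(net.graph, path)
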