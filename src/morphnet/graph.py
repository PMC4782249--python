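"""Sparsity thresholding and graph-theoretic characterization.

A similarity matrix is converted into binary and weighted networks by a
subject-specific similarity cut chosen so the edge count hits a target
sparsity S exactly; global (Cp, Lp, Eloc, Eglob, Q) and nodal (degree or
strength, efficiency, betweenness) metrics are computed at every S in a
grid, normalized against degree-preserving rewired nulls, and summarized
threshold-independently by the trapezoidal area under the metric curve.
Hubs are nodes that repeatedly rank in the top 10% of centrality maps.

Conventions (Rubinov & Sporns): weighted path lengths use reciprocal-weight
edge lengths; weighted clustering uses the Onnela geometric-mean form;
characteristic path length is averaged over connected node pairs (the
sparsest thresholds can disconnect nodes), with global efficiency as the
robust companion.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, fields, replace

import networkx as nx
import numpy as np

from .errors import UndefinedRatioError
from .similarity import SimilarityMatrix

logger = logging.getLogger(__name__)

DEFAULT_SPARSITIES = tuple(np.round(np.arange(0.05, 0.40, 0.02), 2))  # 0.05 .. 0.39
NODAL_METRICS = ("degree", "efficiency", "betweenness")
NETWORK_TYPES = ("binary", "weighted")


@dataclass
class ThresholdedNetwork:
    """Binary and weighted adjacency at one sparsity level."""

    adjacency_binary: np.ndarray
    adjacency_weighted: np.ndarray
    sparsity: float
    kls_threshold: float
    n_edges: int

    @property
    def n_nodes(self) -> int:
        return self.adjacency_binary.shape[0]

    def adjacency(self, kind: str) -> np.ndarray:
        if kind == "binary":
            return self.adjacency_binary.astype(float)
        if kind == "weighted":
            return self.adjacency_weighted
        raise ValueError(f"unknown network type {kind!r}")

    def graph(self, kind: str) -> nx.Graph:
        g: nx.Graph = nx.from_numpy_array(self.adjacency(kind))
        return g


@dataclass
class GlobalMetrics:
    """Scalar whole-network topology summary."""

    cp: float
    lp: float
    eloc: float
    eglob: float
    q: float | None = None
    connected: bool = True

    def as_dict(self) -> dict[str, float]:
        d = {f.name: getattr(self, f.name) for f in fields(self) if f.name != "connected"}
        return {k: v for k, v in d.items() if v is not None}


@dataclass
class NodalMetrics:
    """Per-node centrality vectors (degree/strength, efficiency, betweenness)."""

    degree: np.ndarray
    efficiency: np.ndarray
    betweenness: np.ndarray

    def as_dict(self) -> dict[str, np.ndarray]:
        return {"degree": self.degree, "efficiency": self.efficiency, "betweenness": self.betweenness}


@dataclass
class MetricCurve:
    """A metric as a function of sparsity plus its trapezoidal AUC."""

    sparsities: np.ndarray
    values: np.ndarray  # (n_sparsity,) or (n_sparsity, n_nodes)
    auc: float | np.ndarray


# ---------------------------------------------------------------------------
# thresholding
# ---------------------------------------------------------------------------


def edge_count_for_sparsity(n_nodes: int, sparsity: float) -> int:
    """Target edge count: round-half-away-from-zero of S * N(N-1)/2."""
    e_max = n_nodes * (n_nodes - 1) // 2
    return int(math.floor(sparsity * e_max + 0.5))


def threshold_by_sparsity(m: SimilarityMatrix | np.ndarray, sparsity: float) -> ThresholdedNetwork:
    """Keep exactly the E strongest connections for target sparsity S.

    E = round(S * N(N-1)/2); ties at the cut are broken by raster index
    order (and logged), so every subject's network has identical node and
    edge counts.
    """
    if not (0.0 < sparsity < 1.0):
        raise ValueError(f"sparsity must lie in (0, 1), got {sparsity}")
    w = m.kls if isinstance(m, SimilarityMatrix) else np.asarray(m, dtype=float)
    n = w.shape[0]
    iu = np.triu_indices(n, k=1)
    vals = w[iu]
    e_target = edge_count_for_sparsity(n, sparsity)
    order = np.lexsort((iu[1], iu[0], -vals))  # strongest first, then index order
    keep = order[:e_target]
    if e_target:
        cut = vals[keep[-1]]
        n_at_cut = int(np.sum(np.abs(vals - cut) < 1e-15))
        if n_at_cut > 1 and e_target < vals.size:
            logger.info("threshold_by_sparsity: %d entries tie at the cut %.6g", n_at_cut, cut)
    else:
        cut = float("inf")
    a = np.zeros((n, n), dtype=np.uint8)
    a[iu[0][keep], iu[1][keep]] = 1
    a = a + a.T
    wt = np.where(a > 0, w, 0.0)
    return ThresholdedNetwork(
        adjacency_binary=a,
        adjacency_weighted=wt,
        sparsity=float(sparsity),
        kls_threshold=float(cut),
        n_edges=e_target,
    )


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------


def _distance_matrix(adj: np.ndarray, kind: str) -> np.ndarray:
    """All-pairs shortest-path distances; weighted edges have length 1/w."""
    from scipy.sparse import csr_matrix
    from scipy.sparse.csgraph import shortest_path

    if kind == "binary":
        g = csr_matrix((adj > 0).astype(float))
        return shortest_path(g, method="D", unweighted=True, directed=False)
    lengths = np.zeros_like(adj)
    nz = adj > 0
    lengths[nz] = 1.0 / adj[nz]
    return shortest_path(csr_matrix(lengths), method="D", directed=False)


def _efficiency_from_distances(d: np.ndarray) -> tuple[np.ndarray, float]:
    """Nodal and global efficiency from a distance matrix (inf-safe)."""
    n = d.shape[0]
    if n < 2:
        return np.zeros(n), 0.0
    with np.errstate(divide="ignore"):
        inv = 1.0 / d
    np.fill_diagonal(inv, 0.0)
    inv[~np.isfinite(inv)] = 0.0
    nodal = inv.sum(axis=1) / (n - 1)
    return nodal, float(nodal.mean())


def _characteristic_path_length(d: np.ndarray) -> tuple[float, bool]:
    """Mean shortest path over connected pairs; flags disconnection."""
    n = d.shape[0]
    mask = ~np.eye(n, dtype=bool)
    finite = np.isfinite(d) & mask
    connected = bool(finite.sum() == mask.sum())
    if finite.sum() == 0:
        return float("inf"), False
    if not connected:
        logger.info("network is disconnected; Lp averaged over connected pairs only")
    return float(d[finite].mean()), connected


def _clustering(g: nx.Graph, kind: str) -> np.ndarray:
    weight = "weight" if kind == "weighted" else None
    cc = nx.clustering(g, weight=weight)
    return np.array([cc[i] for i in range(g.number_of_nodes())])


def _local_efficiency(adj: np.ndarray, kind: str) -> float:
    """Mean over nodes of the global efficiency of the neighbor subgraph."""
    n = adj.shape[0]
    out = np.zeros(n)
    for i in range(n):
        nbrs = np.flatnonzero(adj[i] > 0)
        if nbrs.size < 2:
            continue
        sub = adj[np.ix_(nbrs, nbrs)]
        d = _distance_matrix(sub, kind)
        _, eg = _efficiency_from_distances(d)
        out[i] = eg
    return float(out.mean())


def global_metrics(
    net: ThresholdedNetwork,
    kind: str = "binary",
    with_modularity: bool = False,
    seed: int = 0,
    n_restarts: int = 100,
) -> GlobalMetrics:
    """Clustering, path length, local/global efficiency and (optionally) Q."""
    adj = net.adjacency(kind)
    if net.n_edges == 0:
        raise ValueError("network has no edges")
    g = net.graph(kind)
    d = _distance_matrix(adj, kind)
    lp, connected = _characteristic_path_length(d)
    _, eglob = _efficiency_from_distances(d)
    cp = float(_clustering(g, kind).mean())
    eloc = _local_efficiency(adj, kind)
    q = None
    if with_modularity:
        q = modular_partition(net, kind=kind, seed=seed, n_restarts=n_restarts)["q"]
    return GlobalMetrics(cp=cp, lp=lp, eloc=eloc, eglob=eglob, q=q, connected=connected)


def nodal_metrics(net: ThresholdedNetwork, kind: str = "binary") -> NodalMetrics:
    """Degree (binary count / weighted strength), efficiency, betweenness.

    Betweenness is the unnormalized count of shortest paths through a node
    (each unordered pair counted once); weighted betweenness uses
    reciprocal-weight edge lengths.
    """
    adj = net.adjacency(kind)
    degree = adj.sum(axis=1) if kind == "weighted" else (adj > 0).sum(axis=1).astype(float)
    d = _distance_matrix(adj, kind)
    eff, _ = _efficiency_from_distances(d)
    if kind == "weighted":
        g = net.graph("weighted")
        for _, _, data in g.edges(data=True):
            data["length"] = 1.0 / data["weight"]
        bc = nx.betweenness_centrality(g, weight="length", normalized=False)
    else:
        bc = nx.betweenness_centrality(net.graph("binary"), normalized=False)
    betweenness = np.array([bc[i] for i in range(net.n_nodes)])
    return NodalMetrics(degree=degree, efficiency=eff, betweenness=betweenness)


# ---------------------------------------------------------------------------
# degree-preserving nulls
# ---------------------------------------------------------------------------


def rewire_null(
    net: ThresholdedNetwork,
    n_nulls: int = 100,
    iterations_per_edge: int = 10,
    seed: int = 0,
) -> list[ThresholdedNetwork]:
    """Maslov-Sneppen degree-preserving rewired surrogates.

    Each null keeps the binary degree sequence exactly; the weighted
    surrogate reassigns the original weight multiset uniformly at random
    over the rewired topology. Fully seeded and reproducible.
    """
    g0 = net.graph("binary")
    e = net.n_edges
    rng = np.random.default_rng(seed)
    weights = net.adjacency_weighted[np.triu_indices(net.n_nodes, k=1)]
    weights = weights[weights > 0]
    nulls = []
    degseq = sorted(d for _, d in g0.degree())
    can_swap = e >= 2 and len(set(g0.edges())) >= 2
    for _ in range(n_nulls):
        g = g0.copy()
        if can_swap:
            nswap = iterations_per_edge * e
            try:
                nx.double_edge_swap(
                    g, nswap=nswap, max_tries=100 * nswap, seed=int(rng.integers(2**31))
                )
            except nx.NetworkXError as exc:
                logger.warning("rewiring stopped early: %s", exc)
        else:
            logger.warning("too few independent edge pairs to rewire; null is a copy")
        assert sorted(d for _, d in g.degree()) == degseq
        a = nx.to_numpy_array(g, nodelist=range(net.n_nodes))
        a = (a > 0).astype(np.uint8)
        iu = np.triu_indices(net.n_nodes, k=1)
        edge_pos = np.flatnonzero(a[iu])
        w_null = np.zeros((net.n_nodes, net.n_nodes))
        perm = rng.permutation(weights)
        w_null[iu[0][edge_pos], iu[1][edge_pos]] = perm
        w_null = w_null + w_null.T
        nulls.append(
            ThresholdedNetwork(
                adjacency_binary=a,
                adjacency_weighted=w_null,
                sparsity=net.sparsity,
                kls_threshold=net.kls_threshold,
                n_edges=e,
            )
        )
    return nulls


def normalize_metrics(real: GlobalMetrics, nulls: list[GlobalMetrics]) -> dict[str, dict[str, float]]:
    """Divide each global metric by its null-ensemble mean.

    Returns ``{metric: {"real": ..., "null_mean": ..., "normalized": ...}}``.
    A zero null mean raises :class:`UndefinedRatioError`.
    """
    if not nulls:
        raise ValueError("need at least one null network")
    out: dict[str, dict[str, float]] = {}
    for name, value in real.as_dict().items():
        null_vals = [n.as_dict().get(name) for n in nulls]
        null_vals = [v for v in null_vals if v is not None and np.isfinite(v)]
        if not null_vals:
            continue
        mu = float(np.mean(null_vals))
        if mu == 0:
            raise UndefinedRatioError(f"null mean of {name} is zero")
        out[name] = {"real": float(value), "null_mean": mu, "normalized": float(value) / mu}
    return out


# ---------------------------------------------------------------------------
# sparsity curves and AUC
# ---------------------------------------------------------------------------


def metric_over_sparsity(
    m: SimilarityMatrix | np.ndarray,
    metric: str,
    s_grid: tuple[float, ...] = DEFAULT_SPARSITIES,
    kind: str = "binary",
    seed: int = 0,
) -> MetricCurve:
    """Evaluate one metric across the sparsity grid; AUC by trapezoid.

    ``metric`` is one of ``cp, lp, eloc, eglob, q`` (scalar curves) or
    ``degree, efficiency, betweenness`` (one curve per node; the AUC is
    then a per-node vector).
    """
    s_grid = np.asarray(sorted(s_grid), dtype=float)
    if s_grid.size < 2:
        raise ValueError("sparsity grid needs at least two points for an AUC")
    rows = []
    for s in s_grid:
        net = threshold_by_sparsity(m, float(s))
        if metric in ("cp", "lp", "eloc", "eglob", "q"):
            gm = global_metrics(net, kind=kind, with_modularity=(metric == "q"), seed=seed)
            rows.append(getattr(gm, metric))
        elif metric in NODAL_METRICS:
            rows.append(getattr(nodal_metrics(net, kind=kind), metric))
        else:
            raise ValueError(f"unknown metric {metric!r}")
    values = np.asarray(rows, dtype=float)
    auc = np.trapezoid(values, s_grid, axis=0)
    return MetricCurve(sparsities=s_grid, values=values, auc=auc if values.ndim > 1 else float(auc))


# ---------------------------------------------------------------------------
# modularity
# ---------------------------------------------------------------------------


def modular_partition(
    net: ThresholdedNetwork,
    kind: str = "binary",
    seed: int = 0,
    n_restarts: int = 100,
    nulls: list[ThresholdedNetwork] | None = None,
) -> dict:
    """Modularity-maximizing partition (seeded Louvain, best of restarts).

    Returns partition labels (one module id per node), the modularity Q,
    and — when a rewired null ensemble is supplied — the z score
    ``(Q - mean(Q_null)) / sd(Q_null)``.
    """
    g = net.graph(kind)
    weight = "weight" if kind == "weighted" else None

    def best_partition(graph: nx.Graph, restarts: int, rng: np.random.Generator):
        best_q, best_comms = -np.inf, None
        for _ in range(restarts):
            comms = nx.community.louvain_communities(
                graph, weight=weight, seed=int(rng.integers(2**31))
            )
            q = nx.community.modularity(graph, comms, weight=weight or "weight")
            if q > best_q:
                best_q, best_comms = q, comms
        return best_q, best_comms

    rng = np.random.default_rng(seed)
    q, comms = best_partition(g, n_restarts, rng)
    labels = np.empty(net.n_nodes, dtype=int)
    for mi, comm in enumerate(sorted(comms, key=min)):
        for node in comm:
            labels[node] = mi
    out = {"partition": labels, "q": float(q), "n_modules": len(comms), "z_score": None}
    if nulls:
        null_restarts = max(1, n_restarts // 10)
        q_nulls = [
            best_partition(nu.graph(kind), null_restarts, rng)[0] for nu in nulls
        ]
        sd = float(np.std(q_nulls, ddof=1)) if len(q_nulls) > 1 else 0.0
        out["q_null_mean"] = float(np.mean(q_nulls))
        out["z_score"] = (q - out["q_null_mean"]) / sd if sd > 0 else float("inf")
    return out


# ---------------------------------------------------------------------------
# hub scoring
# ---------------------------------------------------------------------------


def top_fraction_nodes(values: np.ndarray, top_fraction: float = 0.10) -> np.ndarray:
    """Indices of the floor(top_fraction * N) largest entries.

    Ties are broken by ascending index (deterministic); a tie across the
    cut is logged.
    """
    values = np.asarray(values, dtype=float)
    n_top = int(math.floor(top_fraction * values.size))
    order = np.lexsort((np.arange(values.size), -values))
    if 0 < n_top < values.size and values[order[n_top - 1]] == values[order[n_top]]:
        logger.info("top_fraction_nodes: tie at the selection boundary")
    return np.sort(order[:n_top])


def hub_score(
    centrality_maps: list[np.ndarray] | dict[str, np.ndarray],
    top_fraction: float = 0.10,
    score_threshold: int = 3,
) -> dict:
    """Consistency-of-centrality hub score.

    Each map flags its top-10% nodes; a node's score is the number of maps
    flagging it (0..len(maps); 6 for the standard 3 metrics x 2 network
    types). Nodes scoring strictly above ``score_threshold`` are the
    consistent hubs.
    """
    maps = list(centrality_maps.values()) if isinstance(centrality_maps, dict) else list(centrality_maps)
    if not maps:
        raise ValueError("need at least one centrality map")
    n = np.asarray(maps[0]).size
    scores = np.zeros(n, dtype=int)
    for m in maps:
        m = np.asarray(m)
        if m.size != n:
            raise ValueError("centrality maps have inconsistent lengths")
        scores[top_fraction_nodes(m, top_fraction)] += 1
    return {
        "scores": scores,
        "hubs": np.flatnonzero(scores > score_threshold),
        "n_flagged_per_map": int(math.floor(top_fraction * n)),
    }
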