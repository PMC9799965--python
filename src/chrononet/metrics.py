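"""Global and local graph measures on binary connectomes.

All topology is computed on binary undirected graphs (the thresholded
connectomes).  Conventions for disconnected graphs: shortest-path based
quantities are averaged over reachable pairs only; a node with no
reachable partner is excluded from the characteristic path length; nodal
efficiency treats unreachable pairs as 1/∞ = 0.  A degree-0 node has
clustering, efficiency and participation 0.

Small-worldness compares clustering and path length against a seeded
ensemble of degree-preserving (double-edge-swap) random references.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy.sparse.csgraph import shortest_path

from .connectome import BinaryNetwork, WeightedNetwork
from .parcellation import Parcellation

LOCAL_METRICS = ("degree", "path_length", "clustering", "efficiency",
                 "betweenness", "participation")


def _to_nx(a: np.ndarray) -> nx.Graph:
    g = nx.from_numpy_array(np.asarray(a, dtype=int))
    return g


def distance_matrix(net: BinaryNetwork) -> np.ndarray:
    """All-pairs shortest path lengths (np.inf where unreachable)."""
    return shortest_path(net.a, method="D", unweighted=True, directed=False)


def nodal_path_length(net: BinaryNetwork) -> np.ndarray:
    """Mean distance to *reachable* other nodes; NaN for isolated nodes."""
    d = distance_matrix(net)
    np.fill_diagonal(d, np.inf)
    finite = np.isfinite(d)
    cnt = finite.sum(axis=1)
    out = np.full(net.n_nodes, np.nan)
    ok = cnt > 0
    out[ok] = np.where(finite, d, 0.0).sum(axis=1)[ok] / cnt[ok]
    return out


def nodal_efficiency(net: BinaryNetwork) -> np.ndarray:
    """Mean inverse distance to all other nodes (unreachable contributes 0)."""
    d = distance_matrix(net)
    with np.errstate(divide="ignore"):
        inv = 1.0 / d
    np.fill_diagonal(inv, 0.0)
    n = net.n_nodes
    return inv.sum(axis=1) / (n - 1)


def nodal_clustering(net: BinaryNetwork) -> np.ndarray:
    """Fraction of closed triangles around each node (0 for degree < 2)."""
    a = net.a.astype(float)
    k = a.sum(axis=1)
    tri = np.diag(a @ a @ a)
    denom = k * (k - 1)
    return np.where(denom > 0, tri / np.where(denom > 0, denom, 1), 0.0)


def betweenness(net: BinaryNetwork) -> np.ndarray:
    """Shortest-path betweenness normalized to [0, 1] by (n−1)(n−2)/2 pairs."""
    g = _to_nx(net.a)
    bc = nx.betweenness_centrality(g, normalized=True)
    return np.array([bc[i] for i in range(net.n_nodes)])


def participation_coefficient(net: BinaryNetwork, modules: np.ndarray) -> np.ndarray:
    """Guimerà–Amaral participation over a module partition (0 if degree 0)."""
    modules = np.asarray(modules)
    a = net.a.astype(float)
    k = a.sum(axis=1)
    n_mod = modules.max() + 1
    km = np.zeros((net.n_nodes, n_mod))
    for m in range(n_mod):
        km[:, m] = a[:, modules == m].sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = km / k[:, None]
    p = 1.0 - np.nansum(frac**2, axis=1)
    return np.where(k > 0, p, 0.0)


def local_metrics(net: BinaryNetwork, parcellation: Parcellation) -> pd.DataFrame:
    """All six nodal measures; participation uses the 7-system partition."""
    df = pd.DataFrame(
        {
            "region_id": parcellation.table["region_id"].to_numpy(),
            "degree": net.degrees(),
            "path_length": nodal_path_length(net),
            "clustering": nodal_clustering(net),
            "efficiency": nodal_efficiency(net),
            "betweenness": betweenness(net),
            "participation": participation_coefficient(net, parcellation.system_of()),
        }
    )
    return df


# ---------------------------------------------------------------------------
# Global measures


@dataclass
class GlobalMetrics:
    char_path_length: float
    clustering: float
    efficiency: float
    assortativity: float  # NaN when undefined
    synchronization: float
    lambda2: float
    lambda_max: float
    density: float
    n_edges: int

    def as_dict(self) -> dict:
        return dict(vars(self))


def characteristic_path_length(net: BinaryNetwork) -> float:
    """Mean nodal path length over nodes with at least one reachable partner."""
    li = nodal_path_length(net)
    ok = np.isfinite(li)
    if not ok.any():
        return float("nan")
    return float(li[ok].mean())


def assortativity(net: BinaryNetwork) -> float:
    """Newman degree assortativity over undirected links; NaN if the
    endpoint-degree variance vanishes (e.g. regular graphs)."""
    iu, ju = np.nonzero(np.triu(net.a, k=1))
    if len(iu) < 2:
        return float("nan")
    k = net.degrees().astype(float)
    ki, kj = k[iu], k[ju]
    m1 = np.mean(0.5 * (ki + kj))
    num = np.mean(ki * kj) - m1**2
    den = np.mean(0.5 * (ki**2 + kj**2)) - m1**2
    if np.isclose(den, 0.0):
        return float("nan")
    return float(num / den)


def synchronization(net: BinaryNetwork) -> tuple[float, float, float]:
    """Laplacian eigenratio S = λ2/λmax (D − A spectrum); 0 if disconnected.

    Returns ``(S, lambda2, lambda_max)``.
    """
    a = net.a.astype(float)
    lap = np.diag(a.sum(axis=1)) - a
    vals = np.linalg.eigvalsh(lap)
    lam2, lam_max = float(vals[1]), float(vals[-1])
    if lam2 < 1e-12:
        lam2 = max(lam2, 0.0)
    s = lam2 / lam_max if lam_max > 0 else 0.0
    return float(s), lam2, lam_max


def global_metrics(net: BinaryNetwork) -> GlobalMetrics:
    if net.n_edges == 0:
        raise ValueError("global metrics need at least one edge")
    s, lam2, lam_max = synchronization(net)
    return GlobalMetrics(
        char_path_length=characteristic_path_length(net),
        clustering=float(nodal_clustering(net).mean()),
        efficiency=float(nodal_efficiency(net).mean()),
        assortativity=assortativity(net),
        synchronization=s,
        lambda2=lam2,
        lambda_max=lam_max,
        density=net.density,
        n_edges=net.n_edges,
    )


# ---------------------------------------------------------------------------
# Random references and small-worldness


def random_reference(
    net: BinaryNetwork, n_swaps_per_edge: int = 10, seed: int = 0
) -> BinaryNetwork:
    """Degree-preserving rewiring (Maslov–Sneppen double edge swaps).

    Uses igraph's C rewiring (simple-graph preserving) with a dedicated
    seeded PRNG, so results are reproducible and independent of global
    random state.
    """
    import random as _pyrandom

    import igraph as ig

    m = net.n_edges
    if n_swaps_per_edge <= 0 or m < 2:
        return BinaryNetwork(net.a.copy(), density=net.density)
    iu, ju = np.nonzero(np.triu(net.a, k=1))
    g = ig.Graph(n=net.n_nodes, edges=list(zip(iu.tolist(), ju.tolist())))
    ig.set_random_number_generator(_pyrandom.Random(int(seed)))
    try:
        g.rewire(n=n_swaps_per_edge * m, mode="simple")
    finally:
        ig.set_random_number_generator(_pyrandom)
    a = np.zeros_like(net.a)
    for u, v in g.get_edgelist():
        a[u, v] = a[v, u] = 1
    return BinaryNetwork(a, density=net.density)


@dataclass
class SmallWorldResult:
    sigma: float
    clustering: float
    char_path_length: float
    c_rand: float
    l_rand: float
    n_null: int


def small_worldness(
    net: BinaryNetwork,
    n_null: int = 100,
    seed: int = 0,
    n_swaps_per_edge: int = 10,
) -> SmallWorldResult:
    """σ = (C/C_rand)/(L/L_rand) against a seeded null ensemble.

    ``C_rand`` and ``L_rand`` are means over ``n_null`` degree-preserving
    rewirings.  Returns NaN σ when the null clustering or path length is
    degenerate (0 or undefined).
    """
    c = float(nodal_clustering(net).mean())
    l = characteristic_path_length(net)
    ss = np.random.SeedSequence(seed)
    cs, ls = [], []
    for sub in ss.spawn(n_null):
        ref = random_reference(net, n_swaps_per_edge, seed=int(sub.generate_state(1)[0] % (2**31)))
        cs.append(float(nodal_clustering(ref).mean()))
        ls.append(characteristic_path_length(ref))
    c_rand = float(np.mean(cs))
    l_rand = float(np.nanmean(ls))
    if c_rand <= 0 or not np.isfinite(l_rand) or l_rand <= 0 or not np.isfinite(l):
        sigma = float("nan")
    else:
        sigma = (c / c_rand) / (l / l_rand)
    return SmallWorldResult(float(sigma), c, l, c_rand, l_rand, n_null)


# ---------------------------------------------------------------------------
# Single-slice modularity (delegates to the multilayer optimizer)


def modularity_single(
    net: WeightedNetwork | BinaryNetwork,
    gamma: float = 1.0,
    seed: int = 0,
    n_reps: int = 10,
):
    """Newman–Girvan modularity via Louvain-style maximization.

    Negative weights are zeroed first (the configuration null model is
    undefined for signed matrices).  Returns ``(q, labels)`` for the best
    of ``n_reps`` seeded restarts.
    """
    from .mesoscale import optimize_multilayer

    w = net.z if isinstance(net, WeightedNetwork) else net.a.astype(float)
    part = optimize_multilayer(
        [WeightedNetwork(np.maximum(w, 0.0))], gamma=gamma, omega=0.0,
        seed=seed, n_reps=n_reps,
    )
    return part.q, part.labels[0]


# ---------------------------------------------------------------------------
# Auxiliary centralities (connectogram rings)


def extra_centralities(net: BinaryNetwork) -> pd.DataFrame:
    """k-coreness, eigenvector centrality and PageRank per region.

    Eigenvector centrality is computed on the largest connected component
    (other nodes get 0) and L2-normalized; PageRank uses damping 0.85.
    """
    g = _to_nx(net.a)
    n = net.n_nodes
    core = nx.core_number(g)
    comp = max(nx.connected_components(g), key=len)
    sub = g.subgraph(comp)
    ev = np.zeros(n)
    if sub.number_of_edges() > 0:
        nodes = sorted(comp)
        a = nx.to_numpy_array(sub, nodelist=nodes)
        vals, vecs = np.linalg.eigh(a)
        v = np.abs(vecs[:, -1])
        ev[nodes] = v / np.linalg.norm(v)
    pr = nx.pagerank(g, alpha=0.85)
    return pd.DataFrame(
        {
            "region_id": np.arange(1, n + 1),
            "kcore": [core[i] for i in range(n)],
            "eigenvector": ev,
            "pagerank": [pr[i] for i in range(n)],
        }
    )


# ---------------------------------------------------------------------------
# Curves and AUC


def auc_over_thresholds(grid, values) -> float:
    """Trapezoidal area under a metric-vs-density curve."""
    grid = np.asarray(grid, dtype=float)
    values = np.asarray(values, dtype=float)
    if grid.size < 2:
        raise ValueError("need at least 2 grid points")
    if np.any(np.diff(grid) <= 0):
        raise ValueError("density grid must be strictly increasing")
    return float(np.trapezoid(values, grid))
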