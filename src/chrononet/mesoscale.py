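"""Multilayer modularity, module allegiance, recruitment and integration.

Layers are subjects (one weighted connectivity matrix each), so interlayer
coupling is *categorical*: every node is coupled with strength ω to its
copies in all other layers, and community labels live in one shared label
space across layers.  The multilayer quality function is

    Q = (1/2μ) Σ_ijsr [ (A_ijs − γ k_is k_js / 2m_s) δ_sr + ω δ_ij ] δ(σ_is, σ_jr)

with the Newman–Girvan null within each layer and 2μ the total intra-layer
strength plus the total coupling.  Maximization is a Louvain-style two-phase
iteration (greedy node moves + aggregation) directly on the supra-modularity
matrix, best of n seeded restarts.

Module allegiance P_ij is the fraction of layers in which regions i and j
share a community; recruitment/integration are its within-/between-system
row means against the parcellation's seven systems.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .connectome import WeightedNetwork
from .parcellation import Parcellation


def _clean_layers(layers) -> list[np.ndarray]:
    """Extract nonnegative weight matrices; zero negatives with a warning."""
    out = []
    n_neg = 0
    n = None
    for lay in layers:
        w = lay.z if isinstance(lay, WeightedNetwork) else np.asarray(lay, float)
        if n is None:
            n = w.shape[0]
        elif w.shape[0] != n:
            raise ValueError("layers must share the same region count")
        neg = w < 0
        n_neg += int(neg.sum())
        out.append(np.where(neg, 0.0, w))
    if n_neg:
        warnings.warn(
            f"zeroed {n_neg // 2} negative-weight edges before modularity",
            stacklevel=3,
        )
    return out


def _supra_modularity(layers: list[np.ndarray], gamma: float, omega: float):
    """Dense supra-modularity matrix B and normalization 2μ."""
    n = layers[0].shape[0]
    nl = len(layers)
    big = nl * n
    b = np.zeros((big, big))
    two_mu = 0.0
    for s, a in enumerate(layers):
        k = a.sum(axis=1)
        two_m = k.sum()
        blk = a.copy()
        if two_m > 0:
            blk = blk - gamma * np.outer(k, k) / two_m
        sl = slice(s * n, (s + 1) * n)
        b[sl, sl] = blk
        two_mu += two_m
    if omega:
        idx = np.arange(n)
        for s in range(nl):
            for r in range(nl):
                if s != r:
                    b[s * n + idx, r * n + idx] += omega
        two_mu += omega * n * nl * (nl - 1)
    return b, two_mu


def multilayer_q(layers, labels: np.ndarray, gamma: float, omega: float) -> float:
    """Evaluate the multilayer quality function for given labels.

    ``labels`` is (n_layers, n_regions) in a shared label space.  The i=j,
    s=r self terms of the null model are included (σ_is always equals
    itself), matching the plain double-sum reading of the formula.
    """
    layers = _clean_layers(layers)
    labels = np.asarray(labels)
    if labels.shape != (len(layers), layers[0].shape[0]):
        raise ValueError("labels must be (n_layers, n_regions)")
    num = 0.0
    two_mu = 0.0
    for s, a in enumerate(layers):
        k = a.sum(axis=1)
        two_m = k.sum()
        two_mu += two_m
        same = labels[s][:, None] == labels[s][None, :]
        num += a[same].sum()
        if two_m > 0:
            kk = np.outer(k, k)[same].sum()
            num -= gamma * kk / two_m
    if omega:
        nl, n = labels.shape
        same_node = (labels[:, None, :] == labels[None, :, :]).sum() - nl * n
        num += omega * same_node
        two_mu += omega * n * nl * (nl - 1)
    if two_mu == 0:
        return 0.0
    return float(num / two_mu)


# ---------------------------------------------------------------------------
# Louvain-style maximization on an arbitrary symmetric quality matrix


def _sweep(b: np.ndarray, labels: np.ndarray, rng: np.random.Generator) -> bool:
    """Greedy node moves until no single move improves quality.

    A node may also detach into a fresh singleton community (the zero-gain
    slot), which lets the search leave communities whose internal quality
    contribution for that node is negative.
    """
    n = b.shape[0]
    moved_any = False
    improved = True
    while improved:
        improved = False
        for i in rng.permutation(n):
            li = labels[i]
            # the minlength+1 slot is always an empty (fresh) community
            w = np.bincount(labels, weights=b[i], minlength=labels.max() + 2)
            w[li] -= b[i, i]  # link to own community excluding self
            best = int(np.argmax(w))
            if w[best] > w[li] + 1e-12:
                labels[i] = best
                improved = True
                moved_any = True
    return moved_any


def _relabel(labels: np.ndarray) -> np.ndarray:
    _, inv = np.unique(labels, return_inverse=True)
    return inv


def _aggregate(b: np.ndarray, labels: np.ndarray) -> np.ndarray:
    nc = labels.max() + 1
    s = np.zeros((b.shape[0], nc))
    s[np.arange(b.shape[0]), labels] = 1.0
    return s.T @ b @ s


def _louvain_from(b: np.ndarray, rng: np.random.Generator,
                  init: np.ndarray) -> np.ndarray:
    """One two-phase (sweep + aggregate) pass from an initial labelling."""
    labels = init.copy()
    _sweep(b, labels, rng)
    node_of = _relabel(labels)
    bcur = _aggregate(b, node_of)
    while bcur.shape[0] > 1:
        lab = np.arange(bcur.shape[0])
        if not _sweep(bcur, lab, rng):
            break
        lab = _relabel(lab)
        node_of = lab[node_of]
        if lab.max() + 1 == bcur.shape[0]:
            break
        bcur = _aggregate(bcur, lab)
    return _relabel(node_of)


def _louvain_matrix(b: np.ndarray, rng: np.random.Generator,
                    n_kicks: int = 2) -> np.ndarray:
    """Louvain with iterated-local-search kicks on a quality matrix.

    Greedy single-node moves can be trapped by configurations that need a
    coordinated multi-node change; after convergence the labelling is
    perturbed (30% of nodes reassigned at random) and re-optimized, keeping
    the perturbed solution only if it improves quality.
    """
    n = b.shape[0]
    best = _louvain_from(b, rng, np.arange(n))
    best_q = _quality(b, best)
    for _ in range(n_kicks):
        init = best.copy()
        mask = rng.random(n) < 0.3
        if mask.any():
            init[mask] = rng.integers(0, best.max() + 2, mask.sum())
        cand = _louvain_from(b, rng, init)
        q = _quality(b, cand)
        if q > best_q + 1e-13:
            best, best_q = cand, q
    return best


def _quality(b: np.ndarray, labels: np.ndarray) -> float:
    nc = labels.max() + 1
    s = np.zeros((b.shape[0], nc))
    s[np.arange(b.shape[0]), labels] = 1.0
    return float(np.einsum("ck,kl,lc->", s.T, b, s))


@dataclass
class MultilayerPartition:
    """Community labels across layers with the quality of the partition."""

    labels: np.ndarray  # (n_layers, n_regions), shared label space
    q: float
    gamma: float
    omega: float
    seed: int = 0
    n_reps: int = 1
    converged: bool = True

    @property
    def n_layers(self) -> int:
        return self.labels.shape[0]

    @property
    def n_communities(self) -> int:
        return int(self.labels.max()) + 1


def optimize_multilayer(
    layers,
    gamma: float = 1.0,
    omega: float = 0.1,
    seed: int = 0,
    n_reps: int = 10,
) -> MultilayerPartition:
    """Maximize multilayer modularity; best of ``n_reps`` seeded restarts."""
    mats = _clean_layers(layers)
    n = mats[0].shape[0]
    nl = len(mats)
    b, two_mu = _supra_modularity(mats, gamma, omega)
    if two_mu == 0:
        raise ValueError("all layers are empty")
    best_q, best_labels = -np.inf, None
    ss = np.random.SeedSequence(seed)
    for sub in ss.spawn(max(1, n_reps)):
        rng = np.random.default_rng(sub)
        lab = _louvain_matrix(b, rng)
        q = _quality(b, lab) / two_mu
        if q > best_q + 1e-15:
            best_q, best_labels = q, lab
    labels = best_labels.reshape(nl, n)
    return MultilayerPartition(
        labels=labels, q=float(best_q), gamma=gamma, omega=omega,
        seed=seed, n_reps=n_reps,
    )


@dataclass
class GridSearchResult:
    gamma: float
    omega: float
    q: float
    partition: MultilayerPartition
    surface: pd.DataFrame = field(repr=False)


def grid_search_gamma_omega(
    layers,
    gamma_grid,
    omega_grid,
    seed: int = 0,
    n_reps: int = 10,
) -> GridSearchResult:
    """Exhaustive (γ, ω) search; argmax Q, first cell winning ties.

    Cells are visited row-major over γ then ω, mirroring the emulated
    protocol (γ ∈ [0.5, 1.5], ω ∈ [0, 1], both step 0.05 by default there).
    Note Q is not scale-invariant across γ, so cross-γ comparison is a
    protocol choice, not a statistical principle.
    """
    gamma_grid = list(gamma_grid)
    omega_grid = list(omega_grid)
    if not gamma_grid or not omega_grid:
        raise ValueError("empty parameter grid")
    best = None
    rows = []
    for i, g in enumerate(gamma_grid):
        for j, o in enumerate(omega_grid):
            part = optimize_multilayer(
                layers, gamma=g, omega=o,
                seed=int(np.random.SeedSequence([seed, i, j]).generate_state(1)[0] % (2**31)),
                n_reps=n_reps,
            )
            rows.append(dict(gamma=g, omega=o, q=part.q,
                             n_communities=part.n_communities))
            if best is None or part.q > best.q:
                best = GridSearchResult(g, o, part.q, part, None)
    best.surface = pd.DataFrame(rows)
    return best


# ---------------------------------------------------------------------------
# Allegiance, recruitment, integration


@dataclass
class AllegianceMatrix:
    """Co-classification probabilities P_ij across layers."""

    p: np.ndarray = field(repr=False)
    n_layers: int = 0
    level: str = "regional"  # or "system"
    names: list[str] | None = None
    session: str | None = None

    def __post_init__(self) -> None:
        p = np.asarray(self.p, dtype=float)
        if not np.allclose(p, p.T):
            raise ValueError("allegiance matrix must be symmetric")
        if p.min() < -1e-12 or p.max() > 1 + 1e-12:
            raise ValueError("allegiance entries must lie in [0, 1]")
        self.p = p


def allegiance_matrix(partition: MultilayerPartition, session: str | None = None) -> AllegianceMatrix:
    """P_ij = fraction of layers in which i and j share a community."""
    lab = partition.labels
    nl, n = lab.shape
    counts = np.zeros((n, n))
    for s in range(nl):
        counts += lab[s][:, None] == lab[s][None, :]
    p = counts / nl
    np.fill_diagonal(p, 1.0)
    return AllegianceMatrix(p, n_layers=nl, level="regional", session=session)


def recruitment_integration(
    p: AllegianceMatrix, parcellation: Parcellation
) -> pd.DataFrame:
    """Per-region recruitment R_iS and integration I_iS.

    R_iS = (1/n_s) Σ_{j∈S} P_ij (self term included, as in the plain sum);
    I_iS = (1/(N−n_s)) Σ_{j∉S} P_ij.
    """
    if p.level != "regional":
        raise ValueError("needs a regional-level allegiance matrix")
    mat = p.p
    n = mat.shape[0]
    if parcellation.n_regions != n:
        raise ValueError("parcellation does not match allegiance size")
    sysidx = parcellation.system_of()
    rec = np.empty(n)
    integ = np.empty(n)
    for i in range(n):
        own = sysidx == sysidx[i]
        ns = own.sum()
        rec[i] = mat[i, own].sum() / ns
        integ[i] = mat[i, ~own].sum() / (n - ns) if ns < n else np.nan
    return pd.DataFrame(
        {
            "region_id": parcellation.table["region_id"].to_numpy(),
            "system": parcellation.table["system"].to_numpy(),
            "recruitment": rec,
            "integration": integ,
        }
    )


def system_allegiance(
    p: AllegianceMatrix,
    parcellation: Parcellation,
    merge_hemispheres: bool = True,
) -> AllegianceMatrix:
    """Block means of the regional allegiance over system pairs.

    Diagonal blocks (k = l) average over distinct region pairs i ≠ j, so
    system recruitment is not inflated by the unit diagonal; off-diagonal
    blocks average all cross pairs.  With ``merge_hemispheres`` the pairs
    from both hemispheres are pooled before averaging (7×7 output);
    otherwise (hemisphere, system) blocks are kept apart (14×14).
    """
    if p.level != "regional":
        raise ValueError("needs a regional-level allegiance matrix")
    t = parcellation.table
    if merge_hemispheres:
        keys = t["system"].tolist()
        names = list(dict.fromkeys(keys))
    else:
        keys = (t["hemisphere"] + "_" + t["system"]).tolist()
        names = list(dict.fromkeys(keys))
    idx = {nm: i for i, nm in enumerate(names)}
    block = np.array([idx[k] for k in keys])
    nb = len(names)
    out = np.zeros((nb, nb))
    for a in range(nb):
        ia = np.where(block == a)[0]
        for bix in range(a, nb):
            ib = np.where(block == bix)[0]
            sub = p.p[np.ix_(ia, ib)]
            if a == bix:
                mask = ~np.eye(len(ia), dtype=bool)
                val = sub[mask].mean() if mask.any() else 1.0
            else:
                val = sub.mean()
            out[a, bix] = out[bix, a] = val
    return AllegianceMatrix(out, n_layers=p.n_layers, level="system",
                            names=names, session=p.session)


def system_recruitment_integration(sysmat: AllegianceMatrix) -> pd.DataFrame:
    """System recruitment (diagonal) and mean integration to other systems."""
    if sysmat.level != "system":
        raise ValueError("needs a system-level allegiance matrix")
    m = sysmat.p
    nb = m.shape[0]
    off = m[~np.eye(nb, dtype=bool)].reshape(nb, nb - 1)
    return pd.DataFrame(
        {
            "system": sysmat.names,
            "recruitment": np.diag(m),
            "integration": off.mean(axis=1),
        }
    )


def export_system_edges(sysmat: AllegianceMatrix) -> pd.DataFrame:
    """Chord-diagram input: one row per system pair with its integration."""
    rows = []
    nb = sysmat.p.shape[0]
    for a in range(nb):
        for b in range(a + 1, nb):
            rows.append(dict(system_k=sysmat.names[a], system_l=sysmat.names[b],
                             integration=sysmat.p[a, b]))
    return pd.DataFrame(rows)
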