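"""Weighted graph measures and Small-World Propensity (SWP).

A functional network here is a symmetric nonnegative weighted adjacency
matrix (wPLI values).  Connection weight is converted to distance as
``1/w`` for all path-based measures — strong synchronization means a
short functional distance.

Small-World Propensity quantifies how close a weighted network sits to an
ideal small world by measuring its deviation from two surrogate families
constructed from the *same* weight set:

* a **lattice** surrogate — the weights sorted onto a ring lattice, the
  largest weights onto the nearest-neighbour slots — which maximises
  clustering for the given weights, and
* **random** surrogates — degree-preserving edge rewiring with the weights
  reshuffled over the edges — which destroy clustering while keeping the
  degree sequence and weight distribution.

With observed clustering ``C_obs`` and characteristic path length
``L_obs``::

    ΔC = (C_latt − C_obs) / (C_latt − C_rand)     (clamped to [0, 1])
    ΔL = (L_obs − L_rand) / (L_latt − L_rand)     (clamped to [0, 1])
    ϕ  = 1 − sqrt((ΔC² + ΔL²) / 2)

ϕ ≈ 1 means lattice-like clustering together with random-like path
length — the small-world balance of local segregation and global
integration; ϕ ≈ 0 means both deviations are maximal.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy.sparse.csgraph import shortest_path

__all__ = [
    "SWPResult", "threshold_proportional", "weighted_clustering",
    "char_path_length", "lattice_surrogate", "random_surrogate",
    "build_null_models", "small_world_propensity", "node_strength_bc",
    "edge_betweenness", "detect_hubs", "edge_importance",
]


def _check_adjacency(adj: np.ndarray) -> np.ndarray:
    adj = np.asarray(adj, dtype=float)
    if adj.ndim != 2 or adj.shape[0] != adj.shape[1]:
        raise ValueError("adjacency must be square")
    if not np.allclose(adj, adj.T):
        raise ValueError("adjacency must be symmetric")
    if (adj < 0).any():
        raise ValueError("adjacency weights must be nonnegative")
    adj = adj.copy()
    np.fill_diagonal(adj, 0.0)
    return adj


def threshold_proportional(adj: np.ndarray, density: float) -> np.ndarray:
    """Keep the strongest ``density`` fraction of off-diagonal weights.

    Proportional thresholding: weights below the (1 − density) quantile
    of the upper-triangle entries are set to zero (weights at the cut
    survive).  ``density = 1`` returns the matrix unchanged.
    """
    adj = _check_adjacency(adj)
    if not 0 < density <= 1:
        raise ValueError("density must lie in (0, 1]")
    if density == 1:
        return adj
    iu = np.triu_indices(adj.shape[0], k=1)
    cut = np.quantile(adj[iu], 1.0 - density)
    out = np.where(adj >= cut, adj, 0.0)
    np.fill_diagonal(out, 0.0)
    return out


def weighted_clustering(adj: np.ndarray) -> tuple[np.ndarray, float]:
    """Onnela weighted clustering per node, and its mean.

    ``C_i = (1/(k_i(k_i−1))) Σ_{j,h} (ŵ_ij ŵ_ih ŵ_jh)^{1/3}`` with weights
    normalised by the matrix maximum; nodes with degree < 2 get 0.
    Computed as the diagonal of the cubed element-wise cube-root matrix.
    """
    adj = _check_adjacency(adj)
    w_max = adj.max()
    if w_max == 0:
        return np.zeros(adj.shape[0]), 0.0
    a = np.cbrt(adj / w_max)
    triangles = np.einsum("ij,jk,ki->i", a, a, a)
    k = (adj > 0).sum(axis=1)
    denom = k * (k - 1)
    c = np.where(denom > 0, triangles / np.where(denom > 0, denom, 1), 0.0)
    return c, float(c.mean())


def _distance_matrix(adj: np.ndarray) -> np.ndarray:
    with np.errstate(divide="ignore"):
        dist = np.where(adj > 0, 1.0 / np.where(adj > 0, adj, 1.0), np.inf)
    np.fill_diagonal(dist, 0.0)
    return dist


def char_path_length(adj: np.ndarray,
                     max_unreachable_frac: float = 0.5
                     ) -> tuple[float, int]:
    """Characteristic path length on ``1/w`` edge costs.

    Returns the mean shortest-path length over finite off-diagonal pairs
    and the number of unreachable (infinite) pairs, which are excluded
    from the mean.  Raises if more than ``max_unreachable_frac`` of pairs
    are unreachable.
    """
    adj = _check_adjacency(adj)
    n = adj.shape[0]
    if n < 2:
        raise ValueError("need at least 2 nodes")
    sp = shortest_path(_distance_matrix(adj), method="D", directed=False)
    off = ~np.eye(n, dtype=bool)
    finite = np.isfinite(sp) & off
    n_pairs = n * (n - 1)
    n_unreachable = int(n_pairs - finite.sum())
    if n_unreachable > max_unreachable_frac * n_pairs:
        raise ValueError(
            f"{n_unreachable}/{n_pairs} node pairs unreachable")
    return float(sp[finite].mean()), n_unreachable


def lattice_surrogate(adj: np.ndarray) -> np.ndarray:
    """Regular-network surrogate: weights sorted onto a ring lattice.

    Slots are enumerated by ring distance d = 1, 2, … (all edges between
    nodes i and (i+d) mod n, in node order), and the observed weights are
    placed in descending order — the largest weights become the
    nearest-neighbour connections.  The slot order is fixed, making the
    construction deterministic.
    """
    adj = _check_adjacency(adj)
    n = adj.shape[0]
    iu = np.triu_indices(n, k=1)
    weights = np.sort(adj[iu])[::-1]
    latt = np.zeros_like(adj)
    slots = []
    for d in range(1, n // 2 + 1):
        if 2 * d == n:  # opposite nodes: each pair appears once
            slots.extend((i, i + d) for i in range(d))
        else:
            slots.extend((i, (i + d) % n) for i in range(n))
    for w, (i, j) in zip(weights, slots):
        if w == 0:
            break
        latt[i, j] = latt[j, i] = w
    return latt


def random_surrogate(adj: np.ndarray, rng: np.random.Generator,
                     swaps_per_edge: int = 5) -> np.ndarray:
    """Degree-preserving rewired surrogate with reshuffled weights.

    The binary connection pattern is randomised by double-edge swaps
    (a−b, c−d → a−d, c−b) that preserve every node's degree; attempts that
    would create multi-edges or self-loops are discarded.  The observed
    weights are then reassigned to the rewired edges in random order.  On
    a complete graph the swaps are all no-ops and the surrogate reduces to
    a pure weight shuffle.
    """
    adj = _check_adjacency(adj)
    n = adj.shape[0]
    if n < 4:
        raise ValueError("need at least 4 nodes for degree-preserving swaps")
    mask = adj > 0
    edge_arr = np.argwhere(np.triu(mask, k=1))
    m = len(edge_arr)
    if m < 2:
        return adj.copy()
    triu = np.triu(adj, k=1)
    weights = triu[triu > 0]
    if m == adj.shape[0] * (adj.shape[0] - 1) // 2:
        # complete graph: every swap is a topological no-op; the surrogate
        # reduces to a random reassignment of weights to edges
        out = np.zeros_like(adj)
        shuffled = weights[rng.permutation(m)]
        out[edge_arr[:, 0], edge_arr[:, 1]] = shuffled
        out[edge_arr[:, 1], edge_arr[:, 0]] = shuffled
        return out
    edges = [tuple(e) for e in edge_arr]
    n_target = swaps_per_edge * m
    max_attempts = 6 * n_target  # dense graphs reject most proposals; a
    # partially rewired dense surrogate is statistically equivalent
    prop = rng.integers(0, m, size=(max_attempts, 2))
    flip = rng.random(max_attempts) < 0.5
    done = 0
    for k in range(max_attempts):
        if done >= n_target:
            break
        e1, e2 = prop[k]
        if e1 == e2:
            continue
        a, b = edges[e1]
        c, d = edges[e2]
        if flip[k]:
            c, d = d, c
        # propose a−d, c−b
        if a == c or a == d or b == c or b == d:
            continue
        if mask[a, d] or mask[c, b]:
            continue
        mask[a, b] = mask[b, a] = False
        mask[c, d] = mask[d, c] = False
        mask[a, d] = mask[d, a] = True
        mask[c, b] = mask[b, c] = True
        edges[e1] = (a, d)
        edges[e2] = (c, b)
        done += 1
    perm = rng.permutation(len(weights))
    out = np.zeros_like(adj)
    final = np.asarray(edges)
    out[final[:, 0], final[:, 1]] = weights[perm]
    out[final[:, 1], final[:, 0]] = weights[perm]
    return out


@dataclass(frozen=True)
class NullModels:
    """Lattice and random null-model summary statistics."""

    c_latt: float
    l_latt: float
    c_rand: float
    l_rand: float
    n_nulls: int


def build_null_models(adj: np.ndarray, n_random: int = 100,
                      seed: int | None = None) -> NullModels:
    """Clustering and path length of the lattice and random surrogates.

    The random values are means over ``n_random`` independent surrogates;
    the lattice construction is deterministic.
    """
    adj = _check_adjacency(adj)
    rng = np.random.default_rng(seed)
    latt = lattice_surrogate(adj)
    _, c_latt = weighted_clustering(latt)
    l_latt, _ = char_path_length(latt)
    c_rs, l_rs = [], []
    for _ in range(n_random):
        surr = random_surrogate(adj, rng)
        _, c_r = weighted_clustering(surr)
        l_r, _ = char_path_length(surr)
        c_rs.append(c_r)
        l_rs.append(l_r)
    return NullModels(c_latt=c_latt, l_latt=l_latt,
                      c_rand=float(np.mean(c_rs)),
                      l_rand=float(np.mean(l_rs)), n_nulls=n_random)


@dataclass(frozen=True)
class SWPResult:
    """Small-World Propensity and the quantities that produced it."""

    phi: float
    delta_c: float
    delta_l: float
    c_obs: float
    l_obs: float
    c_rand: float
    l_rand: float
    c_latt: float
    l_latt: float
    n_nulls: int

    def as_dict(self) -> dict:
        return dict(self.__dict__)


def _clamped_ratio(num: float, den: float, what: str) -> float:
    if den == 0:
        if num != 0:
            warnings.warn(f"degenerate null models for {what}: zero "
                          "denominator; deviation clamped", stacklevel=3)
        return 0.0
    return float(np.clip(num / den, 0.0, 1.0))


def small_world_propensity(adj: np.ndarray,
                           nulls: NullModels | None = None,
                           n_random: int = 100,
                           seed: int | None = None) -> SWPResult:
    """Small-World Propensity ϕ of a weighted adjacency matrix.

    ``nulls`` may be precomputed with :func:`build_null_models`; otherwise
    they are built here with ``n_random`` surrogates.
    """
    adj = _check_adjacency(adj)
    if nulls is None:
        nulls = build_null_models(adj, n_random=n_random, seed=seed)
    _, c_obs = weighted_clustering(adj)
    l_obs, _ = char_path_length(adj)
    delta_c = _clamped_ratio(nulls.c_latt - c_obs, nulls.c_latt - nulls.c_rand,
                             "ΔC")
    delta_l = _clamped_ratio(l_obs - nulls.l_rand, nulls.l_latt - nulls.l_rand,
                             "ΔL")
    phi = 1.0 - np.sqrt((delta_c ** 2 + delta_l ** 2) / 2.0)
    return SWPResult(phi=float(phi), delta_c=delta_c, delta_l=delta_l,
                     c_obs=c_obs, l_obs=l_obs, c_rand=nulls.c_rand,
                     l_rand=nulls.l_rand, c_latt=nulls.c_latt,
                     l_latt=nulls.l_latt, n_nulls=nulls.n_nulls)


def _weighted_graph(adj: np.ndarray) -> nx.Graph:
    g = nx.Graph()
    n = adj.shape[0]
    g.add_nodes_from(range(n))
    for i, j in zip(*np.triu_indices(n, k=1)):
        if adj[i, j] > 0:
            g.add_edge(int(i), int(j), weight=adj[i, j],
                       dist=1.0 / adj[i, j])
    return g


def node_strength_bc(adj: np.ndarray,
                     channels: tuple[str, ...] | None = None) -> pd.DataFrame:
    """Per-node strength and betweenness centrality, raw and normalised.

    Strength is the sum of incident weights.  Betweenness (Brandes, on
    ``1/w`` costs) is the fraction of all-pairs shortest paths through the
    node, normalised by the ``(n−1)(n−2)/2`` pair count.  Normalised
    columns divide by the across-node mean, so they average to 1.
    """
    adj = _check_adjacency(adj)
    n = adj.shape[0]
    if n < 3:
        raise ValueError("betweenness undefined for fewer than 3 nodes")
    strength = adj.sum(axis=1)
    bc = np.array([
        v for _, v in sorted(
            nx.betweenness_centrality(_weighted_graph(adj), weight="dist",
                                      normalized=True).items())
    ])
    df = pd.DataFrame({
        "node": channels if channels else np.arange(n),
        "strength_raw": strength,
        "bc_raw": bc,
    })
    for col in ("strength", "bc"):
        mean = df[f"{col}_raw"].mean()
        df[f"{col}_norm"] = (df[f"{col}_raw"] / mean if mean > 0
                             else np.zeros(n))
    return df


def edge_betweenness(adj: np.ndarray) -> np.ndarray:
    """Symmetric matrix of edge betweenness (Brandes, ``1/w`` costs).

    Normalised by the ``n(n−1)/2`` pair count; absent edges get 0.
    """
    adj = _check_adjacency(adj)
    n = adj.shape[0]
    ebc = nx.edge_betweenness_centrality(_weighted_graph(adj), weight="dist",
                                         normalized=True)
    out = np.zeros_like(adj)
    for (i, j), v in ebc.items():
        out[i, j] = out[j, i] = v
    return out


def _one_sd_threshold(means: np.ndarray) -> float:
    return float(means.mean() + means.std(ddof=1))


def detect_hubs(metric_by_subject: np.ndarray,
                channels: tuple[str, ...] | None = None) -> pd.DataFrame:
    """Hub flags from a subjects × nodes metric array.

    A node is a hub when its across-participant mean metric is at least
    one (sample) standard deviation above the mean of all node means.
    Returns a per-node frame with ``mean``, ``hub`` and the threshold.
    """
    m = np.asarray(metric_by_subject, dtype=float)
    if m.ndim != 2 or m.shape[0] < 2:
        raise ValueError("need a subjects × nodes array with ≥ 2 subjects")
    node_means = m.mean(axis=0)
    if np.allclose(node_means.std(ddof=1), 0):
        warnings.warn("zero variance across node means: no hubs",
                      stacklevel=2)
        thr = np.inf
    else:
        thr = _one_sd_threshold(node_means)
    return pd.DataFrame({
        "node": channels if channels else np.arange(m.shape[1]),
        "mean": node_means,
        "hub": node_means >= thr,
        "threshold": thr,
    })


def edge_importance(edge_bc_by_subject: np.ndarray,
                    channels: tuple[str, ...] | None = None) -> pd.DataFrame:
    """Important-edge flags from subjects × nodes × nodes edge-BC arrays.

    An edge is important when its across-participant mean edge BC is at
    least one standard deviation above the mean over all edges.  Returns
    one row per (upper-triangle) node pair.
    """
    e = np.asarray(edge_bc_by_subject, dtype=float)
    if e.ndim != 3 or e.shape[0] < 2 or e.shape[1] != e.shape[2]:
        raise ValueError("need subjects × nodes × nodes with ≥ 2 subjects")
    mean_mat = e.mean(axis=0)
    iu = np.triu_indices(e.shape[1], k=1)
    means = mean_mat[iu]
    if np.allclose(means.std(ddof=1), 0):
        warnings.warn("zero variance across edge means: no important edges",
                      stacklevel=2)
        thr = np.inf
    else:
        thr = _one_sd_threshold(means)
    labels = channels if channels else [str(i) for i in
                                        range(e.shape[1])]
    return pd.DataFrame({
        "node_a": [labels[i] for i in iu[0]],
        "node_b": [labels[j] for j in iu[1]],
        "bc_edge_mean": means,
        "important": means >= thr,
        "threshold": thr,
    })
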