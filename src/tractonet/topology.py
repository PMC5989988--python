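"""Threshold-free weighted network topology indices.

Five indices are computed on the raw (unthresholded) weighted connectome:

* graph density D — fraction of realized edges, the only binary index;
* node strength s_i = sum_j w_ij;
* weighted clustering coefficient (Zhang-Horvath form) on weights
  normalized by the graph maximum, C_i in [0, 1];
* weighted path length — the *strength* of the optimal route between two
  nodes: edges carry distance d = 1/w, the optimal route minimizes total
  distance, and L(i, j) is the reciprocal of that total, so stronger
  routes score higher and L(i, j) = w_ij when the direct edge is optimal;
* small-worldness S — clustering and path length of the observed network
  relative to an Erdos-Renyi ensemble matched on node count, density and
  the observed weight pool.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import dijkstra

from .connectome import Connectome

__all__ = [
    "TopologyProfile",
    "NullEnsemble",
    "UndefinedSmallWorldError",
    "graph_density",
    "node_strength",
    "weighted_clustering",
    "path_strength",
    "path_strength_matrix",
    "global_indices",
    "er_null",
    "null_ensemble",
    "small_worldness",
]


class UndefinedSmallWorldError(ValueError):
    """Raised when the null ensemble has zero clustering or path length."""


@dataclass
class TopologyProfile:
    """Per-node and global topology indices of one connectome.

    Per-node path strength is the mean of L(i, .) over reachable partners;
    disconnected pairs are excluded from all path averages (NaN marks a
    node with no reachable partner).
    """

    labels: list[str]
    strength: np.ndarray
    clustering: np.ndarray
    path_strength: np.ndarray
    density: float
    mean_strength: float
    mean_clustering: float
    mean_path_length: float
    small_worldness: float | None = None

    @property
    def n_nodes(self) -> int:
        return len(self.labels)

    def to_tsv(self, path: str | Path) -> None:
        """One row per node plus a ``global`` summary row."""
        df = pd.DataFrame(
            {
                "node": self.labels + ["global"],
                "strength": np.append(self.strength, self.mean_strength),
                "clustering": np.append(self.clustering, self.mean_clustering),
                "path_strength": np.append(self.path_strength, self.mean_path_length),
                "density": [""] * self.n_nodes + [self.density],
                "small_worldness": [""] * self.n_nodes
                + ["" if self.small_worldness is None else self.small_worldness],
            }
        )
        df.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "TopologyProfile":
        df = pd.read_csv(path, sep="\t")
        body = df[df["node"] != "global"]
        tail = df[df["node"] == "global"].iloc[0]
        sw = tail["small_worldness"]
        return cls(
            labels=list(body["node"]),
            strength=body["strength"].to_numpy(float),
            clustering=body["clustering"].to_numpy(float),
            path_strength=body["path_strength"].to_numpy(float),
            density=float(tail["density"]),
            mean_strength=float(tail["strength"]),
            mean_clustering=float(tail["clustering"]),
            mean_path_length=float(tail["path_strength"]),
            small_worldness=None if pd.isna(sw) else float(sw),
        )


@dataclass
class NullEnsemble:
    """Erdos-Renyi null summaries for small-worldness."""

    n_realizations: int
    seed: int
    clustering: np.ndarray
    path_length: np.ndarray

    @property
    def mean_clustering(self) -> float:
        return float(np.mean(self.clustering))

    @property
    def mean_path_length(self) -> float:
        return float(np.nanmean(self.path_length))

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame(
            {
                "realization": np.arange(self.n_realizations),
                "mean_clustering": self.clustering,
                "mean_path_length": self.path_length,
            }
        ).to_csv(path, sep="\t", index=False)


def _weights(c: Connectome | np.ndarray) -> np.ndarray:
    return c.weights if isinstance(c, Connectome) else np.asarray(c, dtype=float)


def graph_density(c: Connectome | np.ndarray) -> float:
    """Fraction of strictly positive off-diagonal pairs among N(N-1)/2."""
    W = _weights(c)
    n = W.shape[0]
    if n < 2:
        raise ValueError("graph density needs at least two nodes")
    iu = np.triu_indices(n, k=1)
    return float(np.count_nonzero(W[iu] > 0) / (n * (n - 1) / 2))


def node_strength(c: Connectome | np.ndarray, i: int | None = None):
    """Node strength s_i = sum_j w_ij (all nodes when ``i`` is None)."""
    W = _weights(c)
    s = W.sum(axis=1)
    return s if i is None else float(s[i])


def weighted_clustering(c: Connectome | np.ndarray, i: int | None = None):
    """Zhang-Horvath weighted clustering on max-normalized weights.

    C_i = sum_{j != k} what_ij what_jk what_ki / ((sum_j what_ij)^2 -
    sum_j what_ij^2), with what = w / max(w); zero for nodes with fewer
    than two neighbors, and all zero (with a warning) on an empty graph.
    """
    W = _weights(c)
    wmax = W.max()
    if wmax == 0:
        warnings.warn("all-zero graph: clustering is zero everywhere", stacklevel=2)
        C = np.zeros(W.shape[0])
        return C if i is None else float(C[i])
    What = W / wmax
    num = np.diagonal(What @ What @ What)
    s = What.sum(axis=1)
    den = s**2 - (What**2).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        C = np.where(den > 0, num / den, 0.0)
    degree = (W > 0).sum(axis=1)
    C = np.where(degree >= 2, C, 0.0)
    return C if i is None else float(C[i])


def path_strength_matrix(c: Connectome | np.ndarray) -> np.ndarray:
    """L(i, j) = 1 / (minimal total 1/w distance); NaN marks disconnected
    pairs, and the diagonal is NaN."""
    W = _weights(c)
    n = W.shape[0]
    with np.errstate(divide="ignore"):
        dist = np.where(W > 0, 1.0 / W, 0.0)
    D = dijkstra(csr_matrix(dist), directed=False)
    with np.errstate(divide="ignore"):
        L = np.where(np.isfinite(D) & (D > 0), 1.0 / np.where(D > 0, D, 1.0), np.nan)
    np.fill_diagonal(L, np.nan)
    return L


def path_strength(c: Connectome | np.ndarray, i: int, j: int) -> float:
    """Strength of the optimal route between nodes i and j (NaN when no
    route exists)."""
    if i == j:
        raise ValueError("path strength is undefined for i == j")
    return float(path_strength_matrix(c)[i, j])


def global_indices(
    c: Connectome,
    small_world_realizations: int = 0,
    seed: int = 0,
) -> TopologyProfile:
    """Full per-node + global profile; optionally with small-worldness.

    Global means average per-node values over nodes, and path length over
    connected unordered pairs; a fully disconnected graph leaves the path
    indices NaN with a warning.
    """
    W = c.weights
    n = c.n_nodes
    s = node_strength(W)
    C = weighted_clustering(W) if W.max() > 0 else np.zeros(n)
    L = path_strength_matrix(W)
    iu = np.triu_indices(n, k=1)
    pair_vals = L[iu]
    if np.all(np.isnan(pair_vals)):
        warnings.warn("fully disconnected graph: path indices undefined", stacklevel=2)
        mean_L = float("nan")
        per_node_L = np.full(n, np.nan)
    else:
        mean_L = float(np.nanmean(pair_vals))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            per_node_L = np.nanmean(L, axis=1)
    profile = TopologyProfile(
        labels=list(c.labels),
        strength=s,
        clustering=C,
        path_strength=per_node_L,
        density=graph_density(W),
        mean_strength=float(np.mean(s)),
        mean_clustering=float(np.mean(C)),
        mean_path_length=mean_L,
    )
    if small_world_realizations > 0:
        profile.small_worldness = small_worldness(c, small_world_realizations, seed)
    return profile


# ---------------------------------------------------------------------------
# Erdos-Renyi nulls and small-worldness
# ---------------------------------------------------------------------------

def er_null(
    n_nodes: int,
    density: float,
    weight_pool: Sequence[float],
    seed: int | np.random.Generator = 0,
) -> Connectome:
    """Erdos-Renyi G(n, p) graph with weights resampled from a pool.

    Each unordered pair is present independently with probability
    ``density``; present edges draw a weight uniformly with replacement
    from ``weight_pool``.
    """
    if not 0 < density <= 1:
        raise ValueError(f"density must lie in (0, 1], got {density}")
    pool = np.asarray(weight_pool, dtype=float)
    if pool.size == 0:
        raise ValueError("weight pool is empty")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    W = np.zeros((n_nodes, n_nodes))
    iu = np.triu_indices(n_nodes, k=1)
    present = rng.random(len(iu[0])) < density
    draws = rng.choice(pool, size=len(iu[0]))
    vals = np.where(present, draws, 0.0)
    W[iu] = vals
    W += W.T
    return Connectome([f"er{k}" for k in range(n_nodes)], W)


def null_ensemble(
    c: Connectome, n_realizations: int = 20, seed: int = 0
) -> NullEnsemble:
    """Matched ER ensemble: same node count, density and weight pool."""
    if n_realizations < 1:
        raise ValueError("need at least one null realization")
    W = c.weights
    iu = np.triu_indices(c.n_nodes, k=1)
    pool = W[iu][W[iu] > 0]
    dens = graph_density(c)
    rng = np.random.default_rng(seed)
    Cs, Ls = [], []
    for _ in range(n_realizations):
        null = er_null(c.n_nodes, dens, pool, rng)
        prof_C = weighted_clustering(null.weights)
        L = path_strength_matrix(null.weights)
        Cs.append(float(np.mean(prof_C)))
        vals = L[np.triu_indices(c.n_nodes, k=1)]
        Ls.append(float(np.nanmean(vals)) if not np.all(np.isnan(vals)) else np.nan)
    return NullEnsemble(n_realizations, seed, np.array(Cs), np.array(Ls))


def small_worldness(c: Connectome, n_realizations: int = 20, seed: int = 0) -> float:
    """S = (C_obs / C_rand) / (L_obs / L_rand) against the matched ensemble."""
    prof_C = float(np.mean(weighted_clustering(c.weights)))
    L = path_strength_matrix(c.weights)
    vals = L[np.triu_indices(c.n_nodes, k=1)]
    if np.all(np.isnan(vals)):
        raise UndefinedSmallWorldError("observed graph has no connected pairs")
    prof_L = float(np.nanmean(vals))
    ens = null_ensemble(c, n_realizations, seed)
    if ens.mean_clustering <= 0 or not np.isfinite(ens.mean_path_length) or ens.mean_path_length <= 0:
        raise UndefinedSmallWorldError("degenerate null ensemble")
    return (prof_C / ens.mean_clustering) / (prof_L / ens.mean_path_length)
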