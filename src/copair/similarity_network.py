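"""Weighted sequence-similarity networks for one protein family.

Two flavors are supported.  In the *kNN network* each sequence is linked to
its k nearest sequences by Hamming distance (directionality is disregarded:
an edge is kept if present in at least one direction, and double edges are
merged, so degrees are >= k).  In the *orthology network* each sequence is
linked to its reciprocal best hit in every other species, a simple
operational definition of orthology; no intra-species edges can occur.

Edges are weighted ``w = exp(-d^2 / D^2)`` so that similar sequences carry
exponentially larger weight.  The scale ``D`` is the mean (over nodes) of the
distance to the k-th nearest neighbor (kNN flavor) or of the distance to the
most distant retained ortholog (orthology flavor).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .data_model import LabeledMSA, pairwise_hamming


@dataclass
class SimilarityNetwork:
    """Undirected weighted graph over the sequences of one family.

    ``edges`` is an ``(E, 2)`` int array with ``edges[:, 0] < edges[:, 1]``,
    no self-loops and no duplicates; ``distances`` and ``weights`` run
    parallel to it.
    """

    n_nodes: int
    edges: np.ndarray
    distances: np.ndarray
    weights: np.ndarray
    scale: float
    flavor: str  # "knn" or "orthology"
    k: Optional[int] = None

    def __post_init__(self) -> None:
        self.edges = np.asarray(self.edges, dtype=np.int64).reshape(-1, 2)
        self.distances = np.asarray(self.distances, dtype=np.float64)
        self.weights = np.asarray(self.weights, dtype=np.float64)
        if self.edges.size:
            if (self.edges[:, 0] >= self.edges[:, 1]).any():
                raise ValueError("edges must satisfy m < n (no self-loops)")
            key = self.edges[:, 0] * self.n_nodes + self.edges[:, 1]
            if np.unique(key).size != key.size:
                raise ValueError("duplicate edges")
        if self.scale <= 0:
            raise ValueError("scale D must be positive")

    @property
    def n_edges(self) -> int:
        return self.edges.shape[0]

    def degrees(self) -> np.ndarray:
        deg = np.zeros(self.n_nodes, dtype=np.int64)
        np.add.at(deg, self.edges.ravel(), 1)
        return deg

    def dense_weights(self) -> np.ndarray:
        """Symmetric ``(M, M)`` weight matrix, zero where there is no edge."""
        w = np.zeros((self.n_nodes, self.n_nodes))
        w[self.edges[:, 0], self.edges[:, 1]] = self.weights
        w[self.edges[:, 1], self.edges[:, 0]] = self.weights
        return w

    def adjacency_csr(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Both-directions adjacency as (indptr, neighbors, weights)."""
        src = np.concatenate([self.edges[:, 0], self.edges[:, 1]])
        dst = np.concatenate([self.edges[:, 1], self.edges[:, 0]])
        wts = np.concatenate([self.weights, self.weights])
        order = np.argsort(src, kind="stable")
        src, dst, wts = src[order], dst[order], wts[order]
        indptr = np.zeros(self.n_nodes + 1, dtype=np.int64)
        np.add.at(indptr, src + 1, 1)
        np.cumsum(indptr, out=indptr)
        return indptr, dst.astype(np.int64), wts.astype(np.float64)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "node_a": self.edges[:, 0],
                "node_b": self.edges[:, 1],
                "distance": self.distances,
                "weight": self.weights,
            }
        )

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def edge_weight(d, scale: float):
    """Gaussian-kernel edge weight ``exp(-d^2 / D^2)``; decreasing in d."""
    if scale <= 0:
        raise ValueError("scale D must be positive")
    d = np.asarray(d, dtype=np.float64)
    out = np.exp(-(d**2) / scale**2)
    return float(out) if out.ndim == 0 else out


def _finalize(n, pair_set, dist_mat, scale, flavor, k=None) -> SimilarityNetwork:
    if scale == 0:  # all duplicate sequences; keep weights defined (all 1)
        scale = 1.0
    if pair_set:
        edges = np.array(sorted(pair_set), dtype=np.int64)
        dists = dist_mat[edges[:, 0], edges[:, 1]].astype(np.float64)
    else:
        edges = np.empty((0, 2), dtype=np.int64)
        dists = np.empty(0)
    return SimilarityNetwork(
        n_nodes=n,
        edges=edges,
        distances=dists,
        weights=edge_weight(dists, scale),
        scale=float(scale),
        flavor=flavor,
        k=k,
    )


def build_knn_network(msa: LabeledMSA, k: int) -> SimilarityNetwork:
    """k-nearest-neighbor similarity network of one family.

    Neighbor lists use the tie-break (distance, node index) and exclude the
    node itself; same-species neighbors are allowed.  ``D`` is computed from
    each node's own k-th-neighbor distance, before symmetrization.
    """
    m = msa.depth
    if not 1 <= k <= m - 1:
        raise ValueError(f"k must satisfy 1 <= k <= M-1, got k={k}, M={m}")
    dist = pairwise_hamming(msa)
    dist_f = dist.astype(np.float64)
    np.fill_diagonal(dist_f, np.inf)
    # stable argsort realises the (distance, index) tie-break
    order = np.argsort(dist_f, axis=1, kind="stable")
    knn = order[:, :k]
    kth_dist = dist_f[np.arange(m), order[:, k - 1]]
    scale = float(kth_dist.mean())
    pairs = set()
    for i in range(m):
        for j in knn[i]:
            pairs.add((min(i, int(j)), max(i, int(j))))
    return _finalize(m, pairs, dist, scale, "knn", k=k)


def build_orthology_network(msa: LabeledMSA) -> SimilarityNetwork:
    """Reciprocal-best-hit orthology network of one family.

    For each sequence and each other species, the closest sequence in that
    species is its best hit (tie-break: lowest index); an edge is kept iff
    the choice is reciprocal.  ``D`` averages, over nodes with at least one
    retained ortholog, the distance to the most distant one.  Nodes without
    a reciprocal hit stay isolated; no edge joins two same-species nodes.
    """
    if msa.n_species < 2:
        raise ValueError("orthology network needs at least two species")
    m = msa.depth
    dist = pairwise_hamming(msa)
    species_list = list(msa.species_index)
    members = {sp: np.asarray(ix, dtype=np.int64) for sp, ix in msa.species_index.items()}
    sp_of = msa.species
    # best hit of node i in species sp (np.argmin takes the first minimum,
    # and members are in index order, giving the lowest-index tie-break)
    best: dict[tuple[int, str], int] = {}
    for i in range(m):
        for sp in species_list:
            if sp == sp_of[i]:
                continue
            cand = members[sp]
            best[(i, sp)] = int(cand[np.argmin(dist[i, cand])])
    pairs = set()
    for (i, sp), j in best.items():
        if best[(j, sp_of[i])] == i:
            pairs.add((min(i, j), max(i, j)))
    if pairs:
        max_d = np.full(m, -1.0)
        for i, j in pairs:
            d = float(dist[i, j])
            max_d[i] = max(max_d[i], d)
            max_d[j] = max(max_d[j], d)
        scale = float(max_d[max_d >= 0].mean())
    else:  # degenerate; cannot happen for valid input but keep D defined
        scale = 1.0
    return _finalize(m, pairs, dist, scale, "orthology")


def build_network(msa: LabeledMSA, flavor: str = "knn", k: int = 21) -> SimilarityNetwork:
    """Dispatch on network flavor."""
    if flavor == "knn":
        return build_knn_network(msa, k)
    if flavor == "orthology":
        return build_orthology_network(msa)
    raise ValueError(f"unknown network flavor {flavor!r}")
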