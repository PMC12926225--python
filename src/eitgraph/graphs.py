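"""Mesh graphs and cluster hierarchies for graph networks.

A FE mesh induces a graph: nodes are mesh nodes, edges are simplex edges.
Graph convolutions aggregate with the fixed symmetric normalizer
N = D^{-1/2} (A + I) D^{-1/2},  D_ii = 1 + sum_j A_ij,
so the trainable weights are independent of the graph — the same network
runs on 2D and 3D meshes of any size.

Pooling coarsens the graph through a hierarchy of node clusters computed
by k-means on node coordinates, each level keeping ~1/8 of the nodes.
Clusters at one level become the nodes of the next; two clusters are
adjacent iff any of their members are.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import sparse

from .mesh import FEMesh


@dataclass
class GraphStructure:
    """Undirected graph with the precomputed GCN normalizer."""

    n_nodes: int
    adjacency: sparse.csr_matrix     # symmetric, 0/1, zero diagonal
    normalizer: sparse.csr_matrix    # D^{-1/2} (A+I) D^{-1/2}
    coordinates: np.ndarray          # (N, d) cm, used for clustering


@dataclass
class ClusterHierarchy:
    """Multi-level cluster assignments and the coarse graphs."""

    assignments: list  # per level: (N_level,) int array of cluster ids
    graphs: list       # per level: coarse GraphStructure

    @property
    def levels(self) -> int:
        return len(self.assignments)


def _normalizer(A: sparse.csr_matrix) -> sparse.csr_matrix:
    n = A.shape[0]
    At = (A + sparse.eye(n, format="csr")).tocsr()
    deg = np.asarray(At.sum(axis=1)).ravel()
    dinv = 1.0 / np.sqrt(deg)
    D = sparse.diags(dinv)
    return (D @ At @ D).tocsr()


def graph_from_adjacency(A: sparse.spmatrix, coordinates) -> GraphStructure:
    A = sparse.csr_matrix(A)
    A.setdiag(0)
    A.eliminate_zeros()
    A.data[:] = 1.0
    return GraphStructure(
        n_nodes=A.shape[0],
        adjacency=A,
        normalizer=_normalizer(A),
        coordinates=np.asarray(coordinates, dtype=float),
    )


def mesh_to_graph(mesh: FEMesh) -> GraphStructure:
    """Graph of the mesh: simplex edges, deduplicated and symmetrized."""
    simp = mesh.simplices
    d1 = simp.shape[1]
    pairs = []
    for a in range(d1):
        for b in range(a + 1, d1):
            pairs.append(simp[:, [a, b]])
    E = np.concatenate(pairs, axis=0)
    rows = np.concatenate([E[:, 0], E[:, 1]])
    cols = np.concatenate([E[:, 1], E[:, 0]])
    A = sparse.csr_matrix(
        (np.ones(len(rows)), (rows, cols)), shape=(mesh.n_nodes, mesh.n_nodes)
    )
    A.data[:] = 1.0
    deg = np.asarray(A.sum(axis=1)).ravel()
    if np.any(deg == 0):
        raise ValueError("mesh graph has isolated nodes")
    return GraphStructure(
        n_nodes=mesh.n_nodes,
        adjacency=A,
        normalizer=_normalizer(A),
        coordinates=mesh.nodes.copy(),
    )


def build_cluster_hierarchy(
    graph: GraphStructure,
    levels: int = 3,
    reduction: int = 8,
    seed: int = 0,
) -> ClusterHierarchy:
    """Geometric k-means hierarchy with ~1/reduction nodes kept per level."""
    from sklearn.cluster import KMeans

    assignments, graphs = [], []
    g = graph
    for lvl in range(levels):
        k = int(np.ceil(g.n_nodes / reduction))
        if k >= g.n_nodes:
            lab = np.arange(g.n_nodes)
            centers = g.coordinates.copy()
        else:
            lab = None
            for attempt in range(3):
                km = KMeans(
                    n_clusters=k, random_state=seed + 1000 * attempt, n_init=4
                ).fit(g.coordinates)
                if len(np.unique(km.labels_)) == k:
                    lab = km.labels_.astype(np.int64)
                    centers = km.cluster_centers_
                    break
            if lab is None:
                raise RuntimeError("k-means produced empty clusters")
        B = sparse.csr_matrix(
            (np.ones(g.n_nodes), (np.arange(g.n_nodes), lab)),
            shape=(g.n_nodes, k),
        )
        Ac = (B.T @ (g.adjacency + sparse.eye(g.n_nodes)) @ B).tocsr()
        gc = graph_from_adjacency(Ac, centers)
        assignments.append(lab)
        graphs.append(gc)
        g = gc
    return ClusterHierarchy(assignments=assignments, graphs=graphs)


def permute_graph(graph: GraphStructure, perm: np.ndarray) -> GraphStructure:
    """Relabel nodes: new index of old node i is perm[i]."""
    n = graph.n_nodes
    P = sparse.csr_matrix(
        (np.ones(n), (perm, np.arange(n))), shape=(n, n)
    )
    A = (P @ graph.adjacency @ P.T).tocsr()
    inv = np.empty_like(perm)
    inv[perm] = np.arange(n)
    return graph_from_adjacency(A, graph.coordinates[inv])


def permute_hierarchy(h: ClusterHierarchy, perm: np.ndarray) -> ClusterHierarchy:
    """Hierarchy matching a permuted fine graph (cluster ids unchanged)."""
    inv = np.empty_like(perm)
    inv[perm] = np.arange(len(perm))
    assignments = [h.assignments[0][inv]] + [a.copy() for a in h.assignments[1:]]
    return ClusterHierarchy(assignments=assignments, graphs=list(h.graphs))
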