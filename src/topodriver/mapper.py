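"""Mapper construction of the cohort expression space.

The topological representation is the nerve of an overlapping cover of a
2-dimensional filter image of the cohort. The pipeline is: Pearson
correlation distance between samples over the top-variance genes; a k-nearest
neighbor graph whose geodesic (shortest-path) distances are embedded in 2D by
classical multidimensional scaling (a PCA filter is the supported
alternative); an overlapping square cover parameterized by ``resolution``
(number of bins per axis) and ``gain`` (interval width = bin spacing x gain,
so adjacent intervals overlap by a fraction 1 - 1/gain); and single-linkage
clustering of each bin's members in the original high-dimensional metric,
cut by the first-empty-histogram-bin heuristic. Each cluster becomes a node;
two nodes are joined by an edge when they share at least one sample.

This module is fully deterministic: no randomness enters the construction.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from functools import cached_property
from typing import Sequence

import numpy as np
import networkx as nx
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components, shortest_path
from scipy.spatial.distance import squareform

from .io import ExpressionMatrix

logger = logging.getLogger(__name__)

_FILTER_KINDS = ("geodesic_mds", "pca")


@dataclass(frozen=True)
class MapperConfig:
    """Cover and filter parameters of a single Mapper representation."""

    resolution: int
    gain: float
    k_neighbors: int = 30
    filter_kind: str = "geodesic_mds"
    linkage_histogram_bins: int = 10

    def __post_init__(self) -> None:
        if int(self.resolution) < 1:
            raise ValueError("resolution must be >= 1")
        if self.gain < 1.0:
            raise ValueError("gain must be >= 1 (values > 1 give overlapping bins)")
        if int(self.k_neighbors) < 1:
            raise ValueError("k_neighbors must be >= 1")
        if self.filter_kind not in _FILTER_KINDS:
            raise ValueError(f"filter_kind must be one of {_FILTER_KINDS}")
        if int(self.linkage_histogram_bins) < 1:
            raise ValueError("linkage_histogram_bins must be >= 1")


def correlation_distance(expression: ExpressionMatrix, genes: Sequence[str]) -> np.ndarray:
    """Pearson correlation distance ``d = 1 - r`` between sample profiles.

    Profiles are restricted to ``genes``; result is symmetric with zero
    diagonal and values in [0, 2]. A sample with zero variance over the
    selected genes has no defined correlation and raises.
    """
    genes = list(genes)
    if len(genes) < 2:
        raise ValueError("need at least 2 genes for a correlation distance")
    X = expression.data[genes].to_numpy()
    sd = X.std(axis=1)
    flat = np.flatnonzero(sd == 0)
    if flat.size:
        raise ValueError(
            f"sample {expression.sample_ids[flat[0]]!r} has zero variance over the selected genes"
        )
    R = np.corrcoef(X)
    D = 1.0 - R
    D = np.clip(0.5 * (D + D.T), 0.0, 2.0)
    np.fill_diagonal(D, 0.0)
    return D


def _fix_signs(coords: np.ndarray) -> np.ndarray:
    # eigenvector sign convention: largest-magnitude loading positive per axis
    out = coords.copy()
    for j in range(out.shape[1]):
        col = out[:, j]
        if col.size and col[np.argmax(np.abs(col))] < 0:
            out[:, j] = -col
    return out


def _classical_mds(G: np.ndarray, ndim: int = 2) -> np.ndarray:
    n = G.shape[0]
    G2 = G ** 2
    J = np.eye(n) - np.full((n, n), 1.0 / n)
    B = -0.5 * J @ G2 @ J
    B = 0.5 * (B + B.T)
    vals, vecs = np.linalg.eigh(B)
    order = np.argsort(vals)[::-1][:ndim]
    lam = np.clip(vals[order], 0.0, None)
    # eigenvalues at round-off scale carry no geometry; zero them so exact
    # low-dimensional structure embeds exactly
    lam[lam < lam.max() * 1e-12] = 0.0
    coords = vecs[:, order] * np.sqrt(lam)
    return _fix_signs(coords)


def _knn_graph(D: np.ndarray, k: int) -> csr_matrix:
    n = D.shape[0]
    if n <= k:
        raise ValueError(f"need more than k={k} samples (got {n})")
    rows, cols, vals = [], [], []
    for i in range(n):
        order = np.argsort(D[i], kind="stable")
        neigh = [j for j in order if j != i][:k]
        for j in neigh:
            rows.append(i)
            cols.append(j)
            # zero distances must stay edges; clamp to a tiny positive weight
            vals.append(max(D[i, j], 1e-12))
    W = csr_matrix((vals, (rows, cols)), shape=(n, n))
    # union symmetrization: edge if either endpoint lists the other
    return W.maximum(W.T)


def _bridge_components(W: csr_matrix, D: np.ndarray, labels: np.ndarray, n_comp: int) -> csr_matrix:
    """Connect components by adding, for every component pair, the single
    shortest inter-component edge at its original distance.

    Bridging every pair (rather than only a spanning tree) keeps the
    between-component geodesics close to the original metric, so the
    embedding does not artificially stretch whichever component a tree
    would route traffic through."""
    W = W.tolil()
    n_added = 0
    for a in range(n_comp):
        ia = np.flatnonzero(labels == a)
        for b in range(a + 1, n_comp):
            ib = np.flatnonzero(labels == b)
            sub = D[np.ix_(ia, ib)]
            idx = np.unravel_index(np.argmin(sub), sub.shape)
            i, j = ia[idx[0]], ib[idx[1]]
            w = max(D[i, j], 1e-12)
            W[i, j] = w
            W[j, i] = w
            n_added += 1
    logger.warning("kNN graph had %d components; bridged with %d extra edge(s)",
                   n_comp, n_added)
    return W.tocsr()


def filter_embedding(D: np.ndarray, cfg: MapperConfig,
                     expression: ExpressionMatrix | None = None,
                     genes: Sequence[str] | None = None) -> np.ndarray:
    """2D filter coordinates for every sample.

    Default (``geodesic_mds``): union-symmetrized kNN graph weighted by the
    correlation distances, all-pairs shortest paths, classical (Torgerson)
    MDS of the geodesic matrix. A disconnected graph is bridged by the
    shortest inter-component distances (logged) so all samples share one
    coordinate frame. ``pca`` instead takes the top-2 principal components of
    the expression submatrix and requires ``expression`` (and optionally
    ``genes``).
    """
    if cfg.filter_kind == "pca":
        if expression is None:
            raise ValueError("pca filter requires the expression matrix")
        X = expression.data[list(genes)].to_numpy() if genes is not None else expression.values
        from sklearn.decomposition import PCA

        coords = PCA(n_components=2, svd_solver="full").fit_transform(X)
        return _fix_signs(coords)

    W = _knn_graph(D, cfg.k_neighbors)
    n_comp, labels = connected_components(W, directed=False)
    if n_comp > 1:
        W = _bridge_components(W, D, labels, n_comp)
    G = shortest_path(W, method="D", directed=False)
    if np.any(np.isinf(G)):  # pragma: no cover - bridging guarantees connectivity
        raise RuntimeError("geodesic distance matrix is not finite after bridging")
    return _classical_mds(G, ndim=2)


def _axis_intervals(v: np.ndarray, resolution: int, gain: float) -> tuple[np.ndarray, np.ndarray]:
    vmin, vmax = float(v.min()), float(v.max())
    if vmax == vmin:
        return np.array([vmin - 0.5]), np.array([vmin + 0.5])
    s = (vmax - vmin) / resolution
    centers = vmin + s * (np.arange(resolution) + 0.5)
    half = s * gain / 2.0
    return centers - half, centers + half


def build_cover(coords: np.ndarray, cfg: MapperConfig) -> list[np.ndarray]:
    """Overlapping square cover of the filter image.

    Per axis, ``resolution`` evenly spaced interval centers span [min, max]
    with spacing s; each interval is [center - s*gain/2, center + s*gain/2]
    (boundaries inclusive), so adjacent intervals overlap by 1 - 1/gain.
    Returns the nonempty bins as arrays of sample indices.
    """
    coords = np.asarray(coords, dtype=float)
    if not np.all(np.isfinite(coords)):
        raise ValueError("filter coordinates must be finite")
    lo_x, hi_x = _axis_intervals(coords[:, 0], cfg.resolution, cfg.gain)
    lo_y, hi_y = _axis_intervals(coords[:, 1], cfg.resolution, cfg.gain)
    in_x = (coords[:, 0][:, None] >= lo_x) & (coords[:, 0][:, None] <= hi_x)
    in_y = (coords[:, 1][:, None] >= lo_y) & (coords[:, 1][:, None] <= hi_y)
    bins = []
    for i in range(in_x.shape[1]):
        xi = in_x[:, i]
        if not xi.any():
            continue
        for j in range(in_y.shape[1]):
            members = np.flatnonzero(xi & in_y[:, j])
            if members.size:
                bins.append(members)
    return bins


def cluster_bin(members: np.ndarray, D: np.ndarray, cfg: MapperConfig) -> list[np.ndarray]:
    """Single-linkage clusters of a bin's members in the original metric.

    The dendrogram cut follows the empty-histogram-bin heuristic: merge
    heights are histogrammed into ``linkage_histogram_bins`` equal-width bins
    over [0, max height]; the cut sits at the left edge of the first empty
    bin that follows an occupied one (i.e. at the first gap in the
    merge-height distribution - leading empty bins below the smallest merge
    height carry no information about cluster structure). With no such gap
    (or all heights zero) the bin is one cluster.
    """
    members = np.asarray(members)
    if members.size == 0:
        raise ValueError("bin is empty")
    if members.size == 1:
        return [members]
    sub = D[np.ix_(members, members)]
    Z = linkage(squareform(sub, checks=False), method="single")
    heights = Z[:, 2]
    hmax = float(heights.max())
    if hmax <= 0:
        return [members]
    edges = np.linspace(0.0, hmax, cfg.linkage_histogram_bins + 1)
    counts, _ = np.histogram(heights, bins=edges)
    occupied = np.flatnonzero(counts > 0)
    gaps = np.flatnonzero((counts == 0) & (np.arange(counts.size) > occupied[0]))
    if gaps.size == 0:
        return [members]
    t = edges[gaps[0]]
    labels = fcluster(Z, t=t, criterion="distance")
    return [members[labels == lab] for lab in np.unique(labels)]


@dataclass
class TopologicalRepresentation:
    """Mapper network: nodes are sample subsets, edges mark shared samples."""

    node_members: list[np.ndarray]  # sample indices into sample_ids
    sample_ids: list[str]
    adjacency: np.ndarray
    config: MapperConfig

    def __post_init__(self) -> None:
        A = np.asarray(self.adjacency)
        n = len(self.node_members)
        if A.shape != (n, n):
            raise ValueError("adjacency shape does not match the node count")
        if np.any(A != A.T) or np.any(np.diag(A) != 0):
            raise ValueError("adjacency must be symmetric with zero diagonal")

    @property
    def n_nodes(self) -> int:
        return len(self.node_members)

    @property
    def node_sizes(self) -> np.ndarray:
        return np.array([len(m) for m in self.node_members])

    @cached_property
    def membership(self) -> np.ndarray:
        """Boolean nodes x samples membership matrix."""
        B = np.zeros((self.n_nodes, len(self.sample_ids)), dtype=bool)
        for i, m in enumerate(self.node_members):
            B[i, m] = True
        return B

    def members_of(self, node: int) -> list[str]:
        return [self.sample_ids[i] for i in self.node_members[node]]

    def to_networkx(self, node_values: dict[str, np.ndarray] | None = None) -> nx.Graph:
        g = nx.Graph()
        for i, m in enumerate(self.node_members):
            attrs = {"size": int(len(m)),
                     "members": ";".join(self.sample_ids[j] for j in m)}
            if node_values:
                for name, vals in node_values.items():
                    attrs[name] = float(vals[i])
            g.add_node(i, **attrs)
        ii, jj = np.nonzero(np.triu(self.adjacency, k=1))
        g.add_edges_from(zip(ii.tolist(), jj.tolist()))
        return g

    def write_graphml(self, path, node_values: dict[str, np.ndarray] | None = None) -> None:
        nx.write_graphml(self.to_networkx(node_values), path)

    def to_node_link(self, node_values: dict[str, np.ndarray] | None = None) -> dict:
        return nx.node_link_data(self.to_networkx(node_values), edges="links")

    def write_node_link_json(self, path, node_values: dict[str, np.ndarray] | None = None) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_node_link(node_values), fh)


def build_representation(expression: ExpressionMatrix, cfg: MapperConfig,
                         genes: Sequence[str] | None = None,
                         distance: np.ndarray | None = None,
                         coords: np.ndarray | None = None) -> TopologicalRepresentation:
    """Assemble the Mapper network.

    ``distance`` and ``coords`` may be supplied to reuse work across a
    parameter scan (they depend only on the gene set and ``k_neighbors``,
    not on resolution/gain).
    """
    genes = list(genes) if genes is not None else expression.gene_ids
    D = distance if distance is not None else correlation_distance(expression, genes)
    if coords is None:
        coords = filter_embedding(D, cfg, expression=expression, genes=genes)
    bins = build_cover(coords, cfg)
    nodes: list[np.ndarray] = []
    for members in bins:
        nodes.extend(cluster_bin(members, D, cfg))
    B = np.zeros((len(nodes), expression.n_samples), dtype=bool)
    for i, m in enumerate(nodes):
        B[i, m] = True
    if not B.any(axis=0).all():  # pragma: no cover - the cover spans [min, max]
        raise RuntimeError("some samples are not covered by any node")
    adj = (B.astype(np.int32) @ B.T.astype(np.int32) > 0).astype(np.int8)
    np.fill_diagonal(adj, 0)
    return TopologicalRepresentation(nodes, list(expression.sample_ids), adj, cfg)
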