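"""Node feature engineering and distance-threshold graph construction.

Nodes are genes. Features are the log-normalized expression columns of the
dataset plus two binary subcellular columns (signal peptide, transmembrane).
Edges connect genes whose Euclidean distance in a 2D neighborhood-preserving
layout falls strictly below a threshold calibrated to a target mean degree.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.sparse import coo_matrix, csr_matrix
from scipy.spatial.distance import pdist, squareform
from sklearn.manifold import TSNE

from .core_data import log_normalize
from .errors import ConfigurationError, ParameterError

logger = logging.getLogger(__name__)

SUBCELLULAR_COLUMNS = ["signal_peptide", "transmembrane"]


@dataclass
class GeneGraph:
    """Undirected gene graph with node features and the 2D layout it came from.

    ``edges`` holds unique (i, j) index pairs with i < j; the adjacency is the
    symmetric 0/1 matrix they induce (zero diagonal).
    """

    node_ids: list[str]
    X: np.ndarray
    edges: np.ndarray
    layout2d: np.ndarray
    threshold: float
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.layout2d = np.asarray(self.layout2d, dtype=float)
        self.edges = np.asarray(self.edges, dtype=int).reshape(-1, 2)
        n = len(self.node_ids)
        if self.X.shape[0] != n or self.layout2d.shape != (n, 2):
            raise ConfigurationError("node_ids, X and layout2d sizes disagree")
        if len(self.edges) and (self.edges[:, 0] == self.edges[:, 1]).any():
            raise ConfigurationError("self-edges are not allowed")
        if not np.isfinite(self.layout2d).all():
            raise ConfigurationError("layout coordinates must be finite")

    @property
    def n_nodes(self) -> int:
        return len(self.node_ids)

    @property
    def mean_degree(self) -> float:
        return 2.0 * len(self.edges) / self.n_nodes if self.n_nodes else 0.0

    def adjacency(self) -> csr_matrix:
        n = self.n_nodes
        if len(self.edges) == 0:
            return csr_matrix((n, n))
        i, j = self.edges[:, 0], self.edges[:, 1]
        rows = np.concatenate([i, j])
        cols = np.concatenate([j, i])
        data = np.ones(len(rows))
        return coo_matrix((data, (rows, cols)), shape=(n, n)).tocsr()


def build_node_features(
    normalized_expression: pd.DataFrame, annotations: pd.DataFrame
) -> np.ndarray:
    """Concatenate log-normalized expression columns with the two subcellular
    flags, in that order: ``[expression..., signal_peptide, transmembrane]``.

    ``annotations`` must already be aligned to the expression gene order
    (see :func:`coexpanel.annotations.align_annotations`).
    """
    if not normalized_expression.index.equals(annotations.index):
        raise ConfigurationError(
            "annotation rows do not match expression gene order; "
            "align them with align_annotations() first"
        )
    expr = normalized_expression.to_numpy(float)
    flags = annotations[SUBCELLULAR_COLUMNS].to_numpy(float)
    return np.hstack([expr, flags])


def embed_layout_2d(
    X: np.ndarray,
    *,
    perplexity: float = 20.0,
    max_iter: int = 1000,
    theta: float = 0.4,
    seed: int = 0,
) -> np.ndarray:
    """tSNE-style 2D embedding (Barnes–Hut, angle=theta); deterministic per seed."""
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    if n <= 3 * perplexity:
        raise ParameterError(
            f"tSNE needs more than 3 x perplexity samples: got n={n} with "
            f"perplexity={perplexity}; lower the perplexity below {n / 3:.1f}"
        )
    tsne = TSNE(
        n_components=2,
        perplexity=perplexity,
        max_iter=max_iter,
        angle=theta,
        init="pca",
        random_state=seed,
        method="barnes_hut",
    )
    coords = tsne.fit_transform(X)
    return np.asarray(coords, dtype=float)


def mean_degree_at(distances: np.ndarray, n: int, threshold: float) -> float:
    """Mean degree of the graph with edges at pairwise distance < threshold."""
    return 2.0 * int(np.count_nonzero(distances < threshold)) / n


def calibrate_threshold(
    layout2d: np.ndarray,
    target_mean_degree: float = 5.0,
    tolerance: float = 0.25,
    max_iter: int = 60,
) -> tuple[float, float]:
    """Bisect the distance cutoff until the mean degree hits the target.

    Mean degree is a non-decreasing step function of the threshold, so
    bisection converges; when the target sits inside a jump the closest
    achievable value is returned with a warning. Returns
    ``(threshold, achieved_mean_degree)``.
    """
    layout2d = np.asarray(layout2d, dtype=float)
    n = layout2d.shape[0]
    if n < 2:
        raise ParameterError("calibration needs at least 2 nodes")
    if target_mean_degree > n - 1:
        raise ParameterError(
            f"target mean degree {target_mean_degree} unreachable: the complete "
            f"graph on {n} nodes has mean degree {n - 1}"
        )
    dists = pdist(layout2d)
    lo, hi = 0.0, float(dists.max()) * (1.0 + 1e-9) + 1e-12
    best_t, best_deg = hi, mean_degree_at(dists, n, hi)
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        deg = mean_degree_at(dists, n, mid)
        if abs(deg - target_mean_degree) < abs(best_deg - target_mean_degree):
            best_t, best_deg = mid, deg
        if abs(deg - target_mean_degree) <= tolerance:
            return mid, deg
        if deg < target_mean_degree:
            lo = mid
        else:
            hi = mid
    warnings.warn(
        f"mean degree target {target_mean_degree} not reached within tolerance "
        f"{tolerance}; closest achievable was {best_deg:.4g}",
        stacklevel=2,
    )
    return best_t, best_deg


def build_graph(
    node_ids: list[str],
    X: np.ndarray,
    layout2d: np.ndarray,
    threshold: float,
    metadata: dict | None = None,
) -> GeneGraph:
    """Connect every pair of nodes at Euclidean layout distance < threshold."""
    layout2d = np.asarray(layout2d, dtype=float)
    n = layout2d.shape[0]
    if n >= 2 and threshold > 0:
        close = squareform(pdist(layout2d) < threshold)
        i, j = np.nonzero(np.triu(close, k=1))
        edges = np.column_stack([i, j])
    else:
        edges = np.empty((0, 2), dtype=int)
    return GeneGraph(
        node_ids=list(node_ids),
        X=X,
        edges=edges,
        layout2d=layout2d,
        threshold=float(threshold),
        metadata=dict(metadata or {}),
    )


def graph_from_dataset(
    normalized_expression: pd.DataFrame,
    annotations: pd.DataFrame,
    *,
    use_subcellular: bool = True,
    perplexity: float = 20.0,
    max_iter: int = 1000,
    theta: float = 0.4,
    target_mean_degree: float = 5.0,
    degree_tolerance: float = 0.25,
    seed: int = 0,
) -> GeneGraph:
    """Full graph-construction stage: features -> layout -> calibrated edges.

    The layout is computed from the full feature matrix when
    ``use_subcellular`` is true and from the expression columns alone
    otherwise (the expression-only baseline variant).
    """
    X = build_node_features(normalized_expression, annotations)
    layout_input = X if use_subcellular else X[:, :-2]
    layout = embed_layout_2d(
        layout_input, perplexity=perplexity, max_iter=max_iter, theta=theta, seed=seed
    )
    threshold, achieved = calibrate_threshold(
        layout, target_mean_degree, degree_tolerance
    )
    graph = build_graph(
        list(normalized_expression.index),
        X,
        layout,
        threshold,
        metadata={
            "seed": seed,
            "perplexity": perplexity,
            "max_iter": max_iter,
            "theta": theta,
            "target_mean_degree": target_mean_degree,
            "achieved_mean_degree": achieved,
            "use_subcellular": use_subcellular,
        },
    )
    logger.info(
        "graph: %d nodes, %d edges, mean degree %.3f (threshold %.4g)",
        graph.n_nodes,
        len(graph.edges),
        graph.mean_degree,
        threshold,
    )
    return graph


def write_edge_list(graph: GeneGraph, path) -> None:
    rows = [
        (graph.node_ids[i], graph.node_ids[j], float(np.linalg.norm(graph.layout2d[i] - graph.layout2d[j])))
        for i, j in graph.edges
    ]
    pd.DataFrame(rows, columns=["source", "target", "distance"]).to_csv(
        path, sep="\t", index=False
    )


def write_layout(graph: GeneGraph, path) -> None:
    pd.DataFrame(graph.layout2d, index=graph.node_ids, columns=["x", "y"]).rename_axis(
        "gene_id"
    ).to_csv(path, sep="\t")


def to_networkx(graph: GeneGraph):
    """Export as a networkx Graph with gene id, features and layout attributes."""
    import networkx as nx

    g = nx.Graph()
    for idx, gene in enumerate(graph.node_ids):
        g.add_node(
            gene,
            x=float(graph.layout2d[idx, 0]),
            y=float(graph.layout2d[idx, 1]),
        )
    for i, j in graph.edges:
        g.add_edge(graph.node_ids[i], graph.node_ids[j])
    return g
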