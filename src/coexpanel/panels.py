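"""Cluster embeddings into gene panels and score the clusterings.

Two quality measures: the silhouette coefficient, computed on the DEG
expression matrix regardless of which representation produced the labels,
and the functional assignment score (FAS), a softplus statistic measuring
how strongly a pathway's genes concentrate in the top-k clusters relative to
the pathway's share of all genes.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from sklearn.metrics import silhouette_score

from .dgi import EmbeddingMatrix
from .errors import ParameterError, StatisticsError, ValidationError

logger = logging.getLogger(__name__)

DEFAULT_PCA_DIMS = 16
CLUSTER_NUMBER_CANDIDATES = (24, 10, 7)
DEFAULT_N_CLUSTERS = 7
DEFAULT_K = 2


@dataclass
class PanelAssignment:
    """Gene -> panel labels in {1..n_clusters} plus provenance."""

    node_ids: list[str]
    labels: np.ndarray
    n_clusters: int
    method: str
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if len(self.labels) != len(self.node_ids):
            raise ValidationError("labels and node ids differ in length")
        if len(self.labels) and (
            self.labels.min() < 1 or self.labels.max() > self.n_clusters
        ):
            raise ValidationError("labels must lie in {1..n_clusters}")

    def label_of(self, gene: str) -> int:
        return int(self.labels[self.node_ids.index(gene)])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gene_id": self.node_ids,
                "cluster": self.labels,
                "method": self.method,
                "n_clusters": self.n_clusters,
            }
        )

    def as_series(self) -> pd.Series:
        return pd.Series(self.labels, index=self.node_ids, name="cluster")


def _check_n(n_clusters: int, n_samples: int) -> None:
    if n_clusters < 2:
        raise ParameterError("need at least 2 clusters")
    if n_clusters > n_samples:
        raise ParameterError(
            f"n_clusters={n_clusters} exceeds the {n_samples} genes available"
        )


def cluster_panels(
    embeddings: EmbeddingMatrix,
    n_clusters: int,
    pca_dims: int = DEFAULT_PCA_DIMS,
    seed: int = 0,
) -> PanelAssignment:
    """PCA projection of the embeddings followed by seeded K-means."""
    H = embeddings.H
    _check_n(n_clusters, H.shape[0])
    dims = min(pca_dims, H.shape[1], H.shape[0])
    if np.allclose(H, H[0]):
        warnings.warn("all embeddings identical; clustering is arbitrary", stacklevel=2)
    reduced = PCA(n_components=dims, random_state=seed).fit_transform(H)
    km = KMeans(n_clusters=n_clusters, n_init=10, random_state=seed).fit(reduced)
    return PanelAssignment(
        node_ids=list(embeddings.node_ids),
        labels=km.labels_ + 1,
        n_clusters=n_clusters,
        method="dgi",
        provenance={"seed": seed, "pca_dims": dims},
    )


def baseline_clusterings(
    features: np.ndarray,
    node_ids: Sequence[str],
    method: str,
    n_clusters: int,
    seed: int = 0,
    with_subcellular: bool = True,
) -> PanelAssignment:
    """Benchmark clusterings directly on the (non-embedded) feature matrix.

    ``method`` is ``"hc"`` (agglomerative, Ward linkage on Euclidean
    distance) or ``"kmeans"``. When ``with_subcellular`` is false the last two
    feature columns (the binary subcellular flags) are dropped first.
    """
    X = np.asarray(features, dtype=float)
    if not with_subcellular:
        X = X[:, :-2]
    _check_n(n_clusters, X.shape[0])
    if method == "kmeans":
        labels = (
            KMeans(n_clusters=n_clusters, n_init=10, random_state=seed)
            .fit(X)
            .labels_
        )
    elif method == "hc":
        Z = linkage(X, method="ward")
        labels = fcluster(Z, t=n_clusters, criterion="maxclust") - 1
    else:
        raise ParameterError(f"unknown baseline method {method!r}")
    tag = method if with_subcellular else f"{method}_nosub"
    return PanelAssignment(
        node_ids=list(node_ids),
        labels=np.asarray(labels) + 1,
        n_clusters=n_clusters,
        method=tag,
        provenance={"seed": seed, "with_subcellular": with_subcellular},
    )


def silhouette_index(features: np.ndarray, labels: np.ndarray) -> float:
    """Mean silhouette over genes, Euclidean distance.

    Per the evaluation protocol this is computed on the DEG expression
    matrix — the genes are the samples, the panel labels the labels — even
    when the labels came from an embedding-based clustering.
    """
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    if len(uniq) < 2:
        raise StatisticsError("silhouette undefined for a single cluster")
    if len(uniq) >= len(labels):
        raise StatisticsError("silhouette undefined when every gene is its own cluster")
    return float(silhouette_score(np.asarray(features, dtype=float), labels))


def assignment_summary(
    assignment: PanelAssignment, pathway_genes: Iterable[str]
) -> pd.DataFrame:
    """Per-cluster gene counts and ratios for one pathway, sorted descending.

    Ratio ties are broken by cluster id ascending (deterministic ordering for
    the FAS ranking).
    """
    members = [g for g in dict.fromkeys(pathway_genes) if g in set(assignment.node_ids)]
    series = assignment.as_series()
    counts = series.loc[members].value_counts()
    n_w = int(counts.sum())
    rows = [
        {"cluster": int(c), "count": int(m), "ratio": m / n_w if n_w else 0.0}
        for c, m in counts.items()
    ]
    df = pd.DataFrame(rows, columns=["cluster", "count", "ratio"])
    return df.sort_values(
        ["ratio", "cluster"], ascending=[False, True], ignore_index=True
    )


def softplus(x: float) -> float:
    return float(np.logaddexp(0.0, x))


@dataclass
class FASInput:
    """Inputs to the functional assignment score for one pathway."""

    pathway: str
    member_genes: list[str]
    assignment: PanelAssignment
    k: int = DEFAULT_K
    total_genes: int | None = None  # defaults to the assignment's gene count

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ParameterError("k must be >= 1")
        if self.total_genes is None:
            self.total_genes = len(self.assignment.node_ids)


def functional_assignment_score(inp: FASInput) -> float:
    """Softplus concentration score of a pathway across clusters.

    With clusters sorted by member ratio ``r_i = m_i / N_w`` descending
    (ties by cluster id), and ``r_w = N_w / M_g`` the pathway's share of all
    genes: if the pathway spans n ≤ k clusters the score is
    ``ln(1 + exp(Σ r_i / r_w))`` (= softplus(1/r_w), its upper bound);
    otherwise ``ln(1 + exp((Σ_{i≤k} r_i − Σ_{i>k} r_i) / r_w))``.
    """
    summary = assignment_summary(inp.assignment, inp.member_genes)
    n_w = int(summary["count"].sum())
    if n_w == 0 or not inp.total_genes:
        raise ValidationError("FAS needs a non-empty pathway and M_g > 0")
    if inp.total_genes < n_w:
        raise ValidationError("total gene count smaller than the pathway size")
    r = summary["ratio"].to_numpy()
    r_w = n_w / inp.total_genes
    if len(r) <= inp.k:
        arg = r.sum() / r_w
    else:
        arg = (r[: inp.k].sum() - r[inp.k :].sum()) / r_w
    return softplus(arg)


def fas_bounds(r_w: float) -> tuple[float, float]:
    """(lower, upper) attainable FAS for a pathway with gene ratio ``r_w``."""
    return softplus(-1.0 / r_w), softplus(1.0 / r_w)


def select_cluster_number(
    assignments: Mapping[int, PanelAssignment],
    pathway_genes: Iterable[str],
    k: int = DEFAULT_K,
) -> tuple[int, pd.DataFrame]:
    """Pick the candidate cluster number maximizing the reference pathway's
    FAS; ties resolve to the smallest candidate. Returns (chosen n, report)."""
    if not assignments:
        raise ParameterError("no candidate assignments given")
    genes = list(pathway_genes)
    rows = []
    for n in sorted(assignments):
        fas = functional_assignment_score(
            FASInput("reference", genes, assignments[n], k=k)
        )
        rows.append({"n_clusters": n, "fas": fas})
    report = pd.DataFrame(rows)
    best = report.loc[report["fas"].idxmax(), "n_clusters"]  # idxmax -> first max
    return int(best), report


def evaluation_report(
    expression: np.ndarray,
    assignments: Iterable[PanelAssignment],
    pathways: Mapping[str, Sequence[str]],
    k: int = DEFAULT_K,
) -> pd.DataFrame:
    """SCI + per-pathway FAS for a collection of clusterings (one row each)."""
    rows = []
    for assign in assignments:
        row: dict = {
            "method": assign.method,
            "n_clusters": assign.n_clusters,
            "sci": silhouette_index(expression, assign.labels),
        }
        for name, genes in pathways.items():
            members = [g for g in genes if g in set(assign.node_ids)]
            if members:
                row[f"fas_{name}"] = functional_assignment_score(
                    FASInput(name, members, assign, k=k)
                )
            else:
                row[f"fas_{name}"] = np.nan
        rows.append(row)
    return pd.DataFrame(rows)
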